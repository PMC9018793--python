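"""Aligned-fragment container and BED6/SAM input-output."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

_FRAG_COLS = ["chrom", "start", "end", "strand"]


def _empty_frags() -> pd.DataFrame:
    return pd.DataFrame({"chrom": pd.Series(dtype=str),
                         "start": pd.Series(dtype=np.int64),
                         "end": pd.Series(dtype=np.int64),
                         "strand": pd.Series(dtype=str)})


@dataclass
class ReadSet:
    """Aligned fragments per sample, 0-based half-open.

    ``fragments[sample]`` is a DataFrame with columns chrom, start, end,
    strand ('+', '-' or '.').
    """

    fragments: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fragments)

    def n_fragments(self, sample: str) -> int:
        return len(self.fragments[sample])

    def add(self, sample: str, frags: pd.DataFrame) -> None:
        if "strand" not in frags.columns:
            frags = frags.assign(strand=".")
        bad = frags[(frags["start"] < 0) | (frags["end"] <= frags["start"])]
        if len(bad):
            raise ValueError(f"sample {sample}: {len(bad)} fragments with invalid coordinates")
        self.fragments[sample] = frags[_FRAG_COLS].reset_index(drop=True)

    # ---- on-disk formats -------------------------------------------------

    def write_bed(self, outdir: str | Path, prefix: str = "") -> list[Path]:
        """One BED6 file per sample: ``<prefix><sample>.bed``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for sample, frags in self.fragments.items():
            path = outdir / f"{prefix}{sample}.bed"
            bed = pd.DataFrame({
                "chrom": frags["chrom"], "start": frags["start"], "end": frags["end"],
                "name": sample, "score": 0,
                "strand": frags["strand"].replace(".", "+"),
            })
            bed.to_csv(path, sep="\t", header=False, index=False)
            paths.append(path)
        return paths


def read_bed_fragments(path: str | Path) -> pd.DataFrame:
    """Read BED3/BED6 into a fragment table."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    out = pd.DataFrame({"chrom": bed[0].astype(str),
                        "start": bed[1].astype(np.int64),
                        "end": bed[2].astype(np.int64)})
    out["strand"] = bed[5].astype(str) if bed.shape[1] > 5 else "."
    return out


def read_sam_fragments(path: str | Path, min_mapq: int = 0) -> pd.DataFrame:
    """Read mapped primary alignments from SAM/BAM as fragments."""
    import pysam

    chroms, starts, ends, strands = [], [], [], []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.mapping_quality < min_mapq:
                continue
            chroms.append(aln.reference_name)
            starts.append(aln.reference_start)
            ends.append(aln.reference_end)
            strands.append("-" if aln.is_reverse else "+")
    return pd.DataFrame({"chrom": pd.Series(chroms, dtype=str),
                         "start": pd.Series(starts, dtype=np.int64),
                         "end": pd.Series(ends, dtype=np.int64),
                         "strand": pd.Series(strands, dtype=str)})


def write_sam(readset: ReadSet, genome, path: str | Path) -> None:
    """Write all samples to one minimal SAM file (read group = sample id)."""
    import pysam

    header = {"HD": {"VN": "1.6", "SO": "unknown"},
              "SQ": [{"SN": n, "LN": int(l)} for n, l in zip(genome.chrom_names, genome.chrom_lengths)],
              "RG": [{"ID": s} for s in readset.sample_ids]}
    tid = {n: i for i, n in enumerate(genome.chrom_names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for sample, frags in readset.fragments.items():
            for i, row in enumerate(frags.itertuples(index=False)):
                a = pysam.AlignedSegment(out.header)
                a.query_name = f"{sample}.{i}"
                a.reference_id = tid[row.chrom]
                a.reference_start = int(row.start)
                a.mapping_quality = 60
                a.cigarstring = f"{int(row.end) - int(row.start)}M"
                a.flag = 16 if row.strand == "-" else 0
                a.query_sequence = None
                a.set_tag("RG", sample)
                out.write(a)
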
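"""DMR calling: seed thresholding, edge extension, merging, attributes.

A window whose exact-test p falls below the seed threshold (default 1e-06;
1e-04 for sparse comparisons) nucleates a DMR. The DMR's edges are then
extended: any window with p below the extension threshold (default 0.1)
lying within the gap tolerance (default 1000 bp, inter-edge, inclusive) of
the current DMR interval is absorbed, to a fixed point; DMRs that then
touch or overlap are merged. Extension never crosses a chromosome boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeDef, InvalidParameterError


@dataclass
class DMR:
    """One differential DNA methylation region (0-based half-open)."""

    chrom: str
    start: int
    end: int
    member_windows: list[int] = field(default_factory=list)  # ordinals into the stats table
    seed_window: int = -1
    p_value: float = 1.0       # min member p
    q_value: float = 1.0       # seed window q
    log2fc: float = 0.0        # seed window log2 fold change
    n_windows: int = 0
    cpg_count: int = 0
    cpg_density: float = 0.0   # CpGs per 100 bp

    @property
    def length(self) -> int:
        return self.end - self.start


_STATS_COLS = ("chrom", "start", "end", "pvalue")


def _check_sorted(stats: pd.DataFrame) -> None:
    chroms = stats["chrom"].to_numpy()
    starts = stats["start"].to_numpy()
    seen: set[str] = set()
    prev = None
    for i, c in enumerate(chroms):
        if c != prev:
            if c in seen:
                raise InvalidParameterError("window statistics not sorted: "
                                            f"chromosome {c} appears in two blocks")
            seen.add(c)
            prev = c
        elif i and starts[i] <= starts[i - 1]:
            raise InvalidParameterError(f"window statistics not sorted at row {i}")


def call_dmrs(stats: pd.DataFrame, seed_p: float = 1e-6, extend_p: float = 0.1,
              max_gap_bp: int = 1000, genome: GenomeDef | None = None) -> list[DMR]:
    """Call DMRs from a position-sorted window statistics table.

    ``stats`` needs columns chrom, start, end, pvalue (and optionally
    qvalue, log2fc, window). Thresholds are strict (p < threshold). Member
    windows are all stats rows overlapped by the final DMR span, including
    bridged non-significant windows.
    """
    if seed_p > extend_p:
        raise InvalidParameterError("seed_p must be <= extend_p")
    if max_gap_bp < 0:
        raise InvalidParameterError("max_gap_bp must be >= 0")
    for col in _STATS_COLS:
        if col not in stats.columns:
            raise InvalidParameterError(f"stats table missing column {col!r}")
    _check_sorted(stats)

    p = stats["pvalue"].to_numpy(float)
    q = stats["qvalue"].to_numpy(float) if "qvalue" in stats else np.ones_like(p)
    lfc = stats["log2fc"].to_numpy(float) if "log2fc" in stats else np.zeros_like(p)
    starts = stats["start"].to_numpy(np.int64)
    ends = stats["end"].to_numpy(np.int64)
    chroms = stats["chrom"].to_numpy()

    dmrs: list[DMR] = []
    for chrom in pd.unique(chroms):
        rows = np.flatnonzero(chroms == chrom)
        ext = rows[p[rows] < extend_p]
        if not ext.size:
            continue
        # chain qualifying windows whose inter-edge gap is within tolerance;
        # the growing DMR edge is always the furthest absorbed window's edge,
        # so the fixed point of repeated absorption is exactly these chains
        gaps = starts[ext[1:]] - ends[ext[:-1]]
        breaks = np.flatnonzero(gaps > max_gap_bp)
        for chunk in np.split(ext, breaks + 1):
            if not np.any(p[chunk] < seed_p):
                continue
            span = (int(starts[chunk[0]]), int(ends[chunk[-1]]))
            members = rows[(starts[rows] < span[1]) & (ends[rows] > span[0])]
            seed_row = members[np.lexsort((starts[members], p[members]))[0]]
            d = DMR(chrom=str(chrom), start=span[0], end=span[1],
                    member_windows=[int(m) for m in members],
                    seed_window=int(seed_row),
                    p_value=float(p[members].min()),
                    q_value=float(q[seed_row]),
                    log2fc=float(lfc[seed_row]),
                    n_windows=int(members.size))
            if genome is not None:
                d.cpg_count, d.cpg_density = cpg_density(d, genome)
            dmrs.append(d)
    return dmrs


def cpg_density(dmr: DMR, genome: GenomeDef) -> tuple[int, float]:
    """CpG count within the DMR and density per 100 bp."""
    if dmr.start < 0 or dmr.end > genome.length_of(dmr.chrom):
        raise InvalidParameterError(
            f"DMR {dmr.chrom}:{dmr.start}-{dmr.end} outside chromosome bounds")
    n = genome.cpg_count(dmr.chrom, dmr.start, dmr.end)
    return n, 100.0 * n / dmr.length


_TABLE_COLS = ["dmr_id", "comparison", "chrom", "start", "end", "n_windows",
               "p_value", "q_value", "log2fc", "cpg_count", "cpg_density",
               "seed_window", "member_windows"]


def dmr_table(dmrs: list[DMR], comparison: str = "") -> pd.DataFrame:
    """Exportable attribute table, deterministically ordered by (chrom, start)."""
    order = sorted(range(len(dmrs)), key=lambda i: (dmrs[i].chrom, dmrs[i].start))
    rows = []
    for rank, i in enumerate(order, 1):
        d = dmrs[i]
        rows.append({"dmr_id": f"DMR{rank:04d}", "comparison": comparison,
                     "chrom": d.chrom, "start": d.start, "end": d.end,
                     "n_windows": d.n_windows, "p_value": d.p_value,
                     "q_value": d.q_value, "log2fc": d.log2fc,
                     "cpg_count": d.cpg_count, "cpg_density": d.cpg_density,
                     "seed_window": d.seed_window,
                     "member_windows": ",".join(map(str, d.member_windows))})
    return pd.DataFrame(rows, columns=_TABLE_COLS)


def write_dmr_tsv(dmrs: list[DMR], path, comparison: str = "") -> None:
    dmr_table(dmrs, comparison).to_csv(path, sep="\t", index=False)


def read_dmr_tsv(path) -> list[DMR]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str},
                     keep_default_na=False, na_values=[])
    dmrs = []
    for row in df.itertuples(index=False):
        members = [int(x) for x in str(row.member_windows).split(",") if x != ""]
        dmrs.append(DMR(chrom=row.chrom, start=int(row.start), end=int(row.end),
                        member_windows=members, seed_window=int(row.seed_window),
                        p_value=float(row.p_value), q_value=float(row.q_value),
                        log2fc=float(row.log2fc), n_windows=int(row.n_windows),
                        cpg_count=int(row.cpg_count),
                        cpg_density=float(row.cpg_density)))
    return dmrs


def write_dmr_bed(dmrs: list[DMR], path) -> None:
    """BED with name=DMR id and score=-log10 seed p (capped at 1000)."""
    table = dmr_table(dmrs)
    with open(path, "w") as fh:
        for row in table.itertuples(index=False):
            score = min(1000, int(round(-np.log10(max(row.p_value, 1e-300)))))
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.dmr_id}\t{score}\n")
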
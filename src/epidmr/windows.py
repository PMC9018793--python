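"""Fixed-width genome tiling, per-window fragment counting, and normalization.

The analysis unit is the 1-kb genomic window: the genome is tiled into
non-overlapping fixed windows, aligned MeDIP fragments are counted into
windows per sample, and coverage is normalized as RPKM (reads per kilobase
of window per million library reads).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeDef, InvalidParameterError
from .reads import ReadSet


@dataclass
class WindowGrid:
    """Fixed tiling of a genome into ``window_size``-bp windows.

    Windows are sorted by (chromosome order, start); the final window of a
    chromosome may be shorter than ``window_size`` and is retained.
    """

    genome: GenomeDef
    window_size: int
    chrom: np.ndarray        # per-window chromosome name
    start: np.ndarray
    end: np.ndarray
    _offsets: dict[str, int]  # chrom -> ordinal of its first window

    @property
    def n_windows(self) -> int:
        return self.start.size

    @property
    def lengths(self) -> np.ndarray:
        return self.end - self.start

    def ordinal(self, chrom: str, position: int) -> int:
        """Ordinal of the window containing (chrom, position)."""
        if chrom not in self._offsets:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not 0 <= position < self.genome.length_of(chrom):
            raise InvalidParameterError(f"position {position} outside {chrom}")
        return self._offsets[chrom] + position // self.window_size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom, "start": self.start, "end": self.end})


def make_windows(genome: GenomeDef, window_size: int = 1000) -> WindowGrid:
    """Tile each chromosome into [0,w), [w,2w), ... keeping the terminal
    partial window."""
    if window_size <= 0:
        raise InvalidParameterError(f"window_size must be positive, got {window_size}")
    chroms, starts, ends = [], [], []
    offsets: dict[str, int] = {}
    total = 0
    for name, length in zip(genome.chrom_names, genome.chrom_lengths):
        n = -(-length // window_size)  # ceil
        offsets[name] = total
        s = np.arange(n, dtype=np.int64) * window_size
        e = np.minimum(s + window_size, length)
        chroms.append(np.full(n, name, dtype=object))
        starts.append(s)
        ends.append(e)
        total += n
    return WindowGrid(genome, window_size,
                      np.concatenate(chroms), np.concatenate(starts),
                      np.concatenate(ends), offsets)


@dataclass
class CountMatrix:
    """Raw fragment counts per window (rows) per sample (columns)."""

    counts: np.ndarray          # (n_windows, n_samples) non-negative ints
    sample_ids: list[str]
    library_sizes: np.ndarray   # total counted fragments per sample

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.library_sizes = np.asarray(self.library_sizes, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != len(self.sample_ids):
            raise InvalidParameterError("counts shape inconsistent with sample_ids")
        if np.any(self.counts < 0):
            raise InvalidParameterError("negative counts")

    @property
    def n_windows(self) -> int:
        return self.counts.shape[0]

    def columns(self, sample_ids: list[str]) -> np.ndarray:
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return self.counts[:, idx]


def count_reads(reads: ReadSet, grid: WindowGrid, mode: str = "overlap",
                extend_to: int = 250) -> CountMatrix:
    """Count fragments into grid windows.

    Fragments shorter than ``extend_to`` are first extended in the 3'
    direction (by strand; '.' extends toward increasing coordinates) to
    ``extend_to`` bp, clipped at chromosome ends — mirroring MeDIP fragment
    extension. ``overlap`` mode increments every window the (extended)
    fragment intersects; ``containment`` mode increments only the window
    containing the fragment start, which makes column sums equal fragment
    counts exactly.
    """
    if mode not in ("overlap", "containment"):
        raise InvalidParameterError(f"unknown counting mode {mode!r}")
    if extend_to < 0:
        raise InvalidParameterError("extend_to must be >= 0")
    w = grid.window_size
    counts = np.zeros((grid.n_windows, len(reads.sample_ids)), dtype=np.int64)
    lib = np.zeros(len(reads.sample_ids), dtype=np.int64)
    chrom_len = dict(zip(grid.genome.chrom_names, grid.genome.chrom_lengths))

    for j, sample in enumerate(reads.sample_ids):
        frags = reads.fragments[sample]
        lib[j] = len(frags)
        if not len(frags):
            continue
        unknown = frags[~frags["chrom"].isin(chrom_len)]
        if len(unknown):
            listing = unknown.head(10).to_string(index=False)
            raise ValueError(
                f"sample {sample}: {len(unknown)} fragments on chromosomes absent "
                f"from the grid; first offenders:\n{listing}")
        for chrom, grp in frags.groupby("chrom", sort=False):
            off = grid._offsets[str(chrom)]
            L = chrom_len[str(chrom)]
            start = grp["start"].to_numpy(np.int64)
            end = grp["end"].to_numpy(np.int64)
            if extend_to > 0:
                neg = (grp["strand"] == "-").to_numpy()
                end = np.where(neg, end, np.minimum(np.maximum(end, start + extend_to), L))
                start = np.where(neg, np.maximum(np.minimum(start, end - extend_to), 0), start)
            if mode == "containment":
                np.add.at(counts[:, j], off + start // w, 1)
            else:
                first = start // w
                last = (end - 1) // w
                span = int((last - first).max()) + 1
                for k in range(span):
                    hit = first + k <= last
                    np.add.at(counts[:, j], off + first[hit] + k, 1)
    return CountMatrix(counts, list(reads.sample_ids), lib)


def rpkm(cm: CountMatrix, grid: WindowGrid) -> np.ndarray:
    """Reads per kilobase of window per million library reads.

    Terminal partial windows use their true length.
    """
    zero = cm.library_sizes <= 0
    if np.any(zero):
        bad = [s for s, z in zip(cm.sample_ids, zero) if z]
        raise InvalidParameterError(f"zero library size for sample(s): {', '.join(bad)}")
    len_kb = grid.lengths[:cm.n_windows].astype(float) / 1e3
    lib_m = cm.library_sizes.astype(float) / 1e6
    return cm.counts / (len_kb[:, None] * lib_m[None, :])


def filter_low_coverage(cm: CountMatrix, min_row_sum: int = 10
                        ) -> tuple[CountMatrix, np.ndarray]:
    """Drop windows whose total count across samples is below ``min_row_sum``.

    Returns the subset matrix and the kept window ordinals (into the original
    grid), so downstream results can be mapped back to genome coordinates.
    """
    if min_row_sum < 0:
        raise InvalidParameterError("min_row_sum must be >= 0")
    keep = np.flatnonzero(cm.counts.sum(axis=1) >= min_row_sum)
    sub = CountMatrix(cm.counts[keep], cm.sample_ids, cm.library_sizes)
    return sub, keep


# ---- counts TSV interchange ---------------------------------------------

def write_counts_tsv(cm: CountMatrix, grid: WindowGrid, path: str | Path,
                     window_ordinals: np.ndarray | None = None) -> None:
    ords = np.arange(cm.n_windows) if window_ordinals is None else np.asarray(window_ordinals)
    df = pd.DataFrame({"window_id": [f"w{o}" for o in ords],
                       "chrom": grid.chrom[ords],
                       "start": grid.start[ords],
                       "end": grid.end[ords]})
    for j, s in enumerate(cm.sample_ids):
        df[s] = cm.counts[:, j]
    with open(path, "w") as fh:
        libs = "\t".join(f"{s}:{n}" for s, n in zip(cm.sample_ids, cm.library_sizes))
        fh.write(f"#library_sizes\t{libs}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> tuple[CountMatrix, pd.DataFrame]:
    """Read a counts TSV; returns (CountMatrix, window table).

    Library sizes come from the ``#library_sizes`` header when present, else
    fall back to column sums.
    """
    libs: dict[str, int] = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#library_sizes"):
            for tok in first.rstrip("\n").split("\t")[1:]:
                s, n = tok.rsplit(":", 1)
                libs[s] = int(n)
            df = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
    samples = [c for c in df.columns if c not in ("window_id", "chrom", "start", "end")]
    counts = df[samples].to_numpy(np.int64)
    lib = np.array([libs.get(s, counts[:, j].sum()) for j, s in enumerate(samples)],
                   dtype=np.int64)
    cm = CountMatrix(counts, samples, lib)
    return cm, df[["window_id", "chrom", "start", "end"]]
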
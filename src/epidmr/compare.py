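"""DMR-set comparison across exposures and diseases.

Overlap semantics default to genomic-interval intersection of at least 1 bp
(a window-identity mode is available). Three comparisons are provided:

* multiway Venn region counts over merged genomic loci,
* the asymmetric extended overlap (stringent-threshold DMR rows against a
  relaxed-threshold window-significance column),
* a sliding-window Poisson scan for chromosomal DMR clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import poisson

from .dmr import DMR
from .genome import GenomeDef, InvalidParameterError
from .meth_test import bh_fdr


@dataclass
class DMRSet:
    """A labelled list of DMRs from one comparison at one seed threshold."""

    label: str
    dmrs: list[DMR]
    seed_p: float = 1e-6
    comparison: str = ""

    def __post_init__(self) -> None:
        self.dmrs = sorted(self.dmrs, key=lambda d: (d.chrom, d.start))
        prev: DMR | None = None
        for d in self.dmrs:
            if prev is not None and d.chrom == prev.chrom and d.start < prev.end:
                raise InvalidParameterError(
                    f"set {self.label}: overlapping DMRs at {d.chrom}:{d.start}")
            prev = d

    def __len__(self) -> int:
        return len(self.dmrs)


def venn_overlap(sets: list[DMRSet], mode: str = "interval") -> dict[frozenset, int]:
    """Region counts for every subset-intersection pattern.

    Intervals from all sets are grouped into merged genomic loci (connected
    components under >= 1 bp intersection; ``window_id`` mode requires
    identical intervals instead). Each locus is assigned the pattern of set
    labels it contains; the returned mapping counts loci per pattern.
    """
    if not 2 <= len(sets) <= 7:
        raise InvalidParameterError("venn_overlap supports 2-7 sets")
    ivs = []  # (chrom, start, end, set label)
    for s in sets:
        for d in s.dmrs:
            ivs.append((d.chrom, d.start, d.end, s.label))
    counts: dict[frozenset, int] = {}
    ivs.sort(key=lambda t: (t[0], t[1], t[2]))
    i = 0
    while i < len(ivs):
        chrom, start, end, lab = ivs[i]
        labels = {lab}
        j = i + 1
        while j < len(ivs) and ivs[j][0] == chrom and \
                (ivs[j][1] < end if mode == "interval"
                 else (ivs[j][1], ivs[j][2]) == (start, end)):
            end = max(end, ivs[j][2])
            labels.add(ivs[j][3])
            j += 1
        key = frozenset(labels)
        counts[key] = counts.get(key, 0) + 1
        i = j
    return counts


@dataclass
class ExtendedOverlap:
    row_label: str
    col_label: str
    n_rows: int
    n_overlapping: int
    percent: float
    relaxed_p: float
    empty_rows: bool = False   # warning flag: percent reported as 0


def extended_overlap(rows: DMRSet, column_stats: pd.DataFrame, col_label: str,
                     relaxed_p: float = 0.05) -> ExtendedOverlap:
    """Fraction of row DMRs intersecting a relaxed-significance window of
    another comparison.

    A row DMR overlaps iff its interval intersects (>= 1 bp) at least one
    window with p < ``relaxed_p`` in ``column_stats`` (columns chrom, start,
    end, pvalue). Percent uses the row-set size as denominator.
    """
    if relaxed_p < rows.seed_p:
        raise InvalidParameterError("relaxed_p must be >= the row set's seed_p")
    if len(rows) == 0:
        return ExtendedOverlap(rows.label, col_label, 0, 0, 0.0, relaxed_p, empty_rows=True)
    sig = column_stats[column_stats["pvalue"] < relaxed_p]
    by_chrom = {str(c): (g["start"].to_numpy(np.int64), g["end"].to_numpy(np.int64))
                for c, g in sig.groupby("chrom", sort=False)}
    n = 0
    for d in rows.dmrs:
        se = by_chrom.get(d.chrom)
        if se is not None and np.any((se[0] < d.end) & (se[1] > d.start)):
            n += 1
    return ExtendedOverlap(rows.label, col_label, len(rows), n,
                           100.0 * n / len(rows), relaxed_p)


def overlap_matrix(row_sets: list[DMRSet],
                   col_stats: dict[str, pd.DataFrame],
                   relaxed_p: float = 0.05) -> pd.DataFrame:
    """Row-wise extended-overlap percentage matrix (rows stringent, columns
    relaxed), with counts in companion columns."""
    rows = []
    for rs in row_sets:
        rec: dict[str, object] = {"row": rs.label, "n_dmrs": len(rs)}
        for lab, stats in col_stats.items():
            ov = extended_overlap(rs, stats, lab, relaxed_p)
            rec[f"{lab}_n"] = ov.n_overlapping
            rec[f"{lab}_pct"] = ov.percent
        rows.append(rec)
    return pd.DataFrame(rows)


@dataclass
class ClusterInterval:
    chrom: str
    start: int
    end: int
    n_dmrs: int
    q_value: float


def cluster_scan(dmrs: DMRSet, genome: GenomeDef, scan_window_bp: int = 2_000_000,
                 step_bp: int = 500_000, alpha: float = 0.05) -> list[ClusterInterval]:
    """Sliding-window Poisson scan for chromosomal DMR clusters.

    Each scan window is scored by the number of DMR midpoints it contains;
    the null is Poisson(genome-wide DMR density x window size). Upper-tail p
    values are BH-corrected across all scan windows; significant windows are
    merged into cluster intervals. The procedure (window 2 Mb, step 500 kb,
    alpha 0.05) is this package's own surrogate for cluster identification
    and is labelled as such in output metadata.
    """
    if genome.total_length <= 0:
        raise InvalidParameterError("zero-length genome")
    if not 0 < step_bp <= scan_window_bp:
        raise InvalidParameterError("need scan_window_bp >= step_bp > 0")
    if not dmrs.dmrs:
        return []
    lam = len(dmrs) / genome.total_length * scan_window_bp
    mids: dict[str, np.ndarray] = {}
    for d in dmrs.dmrs:
        mids.setdefault(d.chrom, [])
    for d in dmrs.dmrs:
        mids[d.chrom].append((d.start + d.end) // 2)
    wins, pvals = [], []
    for chrom, length in zip(genome.chrom_names, genome.chrom_lengths):
        pos = np.sort(np.asarray(mids.get(chrom, []), dtype=np.int64))
        for s in range(0, max(length - scan_window_bp, 0) + 1, step_bp):
            e = min(s + scan_window_bp, length)
            k = int(np.searchsorted(pos, e) - np.searchsorted(pos, s))
            wins.append((chrom, s, e, k))
            pvals.append(float(poisson.sf(k - 1, lam)))  # P(X >= k)
        if length <= scan_window_bp:  # chromosome shorter than one scan window
            k = len(pos)
            wins.append((chrom, 0, length, k))
            pvals.append(float(poisson.sf(k - 1, lam)))
    q = bh_fdr(pvals)
    sig = [(w, qv) for w, qv in zip(wins, q) if qv <= alpha and w[3] > 0]
    sig.sort(key=lambda t: (t[0][0], t[0][1]))
    merged: list[ClusterInterval] = []
    for (chrom, s, e, k), qv in sig:
        if merged and merged[-1].chrom == chrom and s <= merged[-1].end:
            merged[-1].end = max(merged[-1].end, e)
            merged[-1].n_dmrs = max(merged[-1].n_dmrs, k)
            merged[-1].q_value = min(merged[-1].q_value, qv)
        else:
            merged.append(ClusterInterval(chrom, s, e, k, float(qv)))
    return merged


def chromosome_plot_data(dmrs: DMRSet, genome: GenomeDef,
                         clusters: list[ClusterInterval] | None = None
                         ) -> dict[str, pd.DataFrame]:
    """Deterministic tables driving an ideogram-style chromosome plot."""
    pos_rows = [{"chrom": d.chrom, "start": d.start, "end": d.end,
                 "midpoint": (d.start + d.end) // 2, "log2fc": d.log2fc}
                for d in dmrs.dmrs]
    pos = pd.DataFrame(pos_rows, columns=["chrom", "start", "end", "midpoint", "log2fc"])
    pos = pos.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    cl_rows = [{"chrom": c.chrom, "start": c.start, "end": c.end,
                "n_dmrs": c.n_dmrs, "q_value": c.q_value}
               for c in (clusters or [])]
    cl = pd.DataFrame(cl_rows, columns=["chrom", "start", "end", "n_dmrs", "q_value"])
    chroms = pd.DataFrame({"chrom": genome.chrom_names, "length": genome.chrom_lengths})
    return {"chromosomes": chroms, "dmr_positions": pos, "clusters": cl}
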
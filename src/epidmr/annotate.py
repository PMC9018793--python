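"""Gene association for DMRs and module windows.

An interval is associated with every gene whose body lies within a distance
threshold (default 10 kb, capturing proximal and distal promoter regions).
Distance is the inter-edge gap between the interval and the gene body span,
0 when they overlap; strand is ignored.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import GeneModel, InvalidParameterError


def interval_gene_distance(start: int, end: int, g_start: int, g_end: int) -> int:
    """Gap in bp between [start, end) and [g_start, g_end); 0 if overlapping."""
    if start < g_end and g_start < end:
        return 0
    return g_start - end if g_start >= end else start - g_end


def associate_genes(intervals: pd.DataFrame, genes: list[GeneModel],
                    max_distance: int = 10_000) -> pd.DataFrame:
    """Map each interval to all genes within ``max_distance``.

    ``intervals`` needs columns chrom, start, end and an id column (first of
    dmr_id / window_id / id found). Returns a tidy table (interval id,
    gene_id, symbol, distance) sorted by interval, then distance, then gene
    id. Chromosome mismatch is a non-association, not an error.
    """
    if max_distance < 0:
        raise InvalidParameterError("max_distance must be >= 0")
    id_col = next((c for c in ("dmr_id", "window_id", "id") if c in intervals.columns), None)
    if id_col is None:
        raise InvalidParameterError("intervals table needs a dmr_id/window_id/id column")

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    rows = []
    for iv in intervals.itertuples(index=False):
        chrom = str(getattr(iv, "chrom"))
        start, end = int(getattr(iv, "start")), int(getattr(iv, "end"))
        hits = []
        for g in by_chrom.get(chrom, ()):
            d = interval_gene_distance(start, end, g.start, g.end)
            if d <= max_distance:
                hits.append((d, g.gene_id, g.symbol))
        hits.sort()
        for d, gid, sym in hits:
            rows.append({id_col: getattr(iv, id_col), "gene_id": gid,
                         "symbol": sym, "distance": d})
    return pd.DataFrame(rows, columns=[id_col, "gene_id", "symbol", "distance"])


def gene_category_counts(associations: pd.DataFrame,
                         category_map: dict[str, str]) -> pd.Series:
    """Count associated genes per functional category.

    ``category_map`` maps gene id (or symbol) to a category label; genes
    without a mapping fall into ``unknown``. Counts distinct genes, not
    association rows.
    """
    categories = sorted(set(category_map.values()) | {"unknown"})
    counts = pd.Series(0, index=categories, dtype=int)
    if len(associations) == 0:
        return counts
    seen = associations.drop_duplicates(subset="gene_id")
    for row in seen.itertuples(index=False):
        cat = category_map.get(row.gene_id) or category_map.get(row.symbol) or "unknown"
        if cat not in counts.index:
            counts[cat] = 0
        counts[cat] += 1
    return counts
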
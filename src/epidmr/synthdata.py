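"""Synthetic study generator: genome, gene models, MeDIP-style counts with
planted differentially methylated regions, correlated window blocks, sample
traits, and histopathology observations.

The generator emulates the statistical structure a sperm MeDIP-Seq
transgenerational study assumes: per-window negative-binomial read counts
whose baseline tracks CpG density, library-size variation across samples,
group-specific mean shifts at planted DMR windows, latent-factor correlated
window blocks (for coexpression-module detection), and per-animal,
per-observer abnormality counts with a shift in diseased groups.

All randomness flows from one explicit seed through numpy's splittable
``SeedSequence``; no global RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeDef, GeneModel, InvalidParameterError
from .reads import ReadSet
from .windows import CountMatrix, WindowGrid


@dataclass(frozen=True)
class PlantedDMR:
    """A contiguous run of windows given a group-specific mean shift."""

    window_start: int      # first window ordinal (inclusive)
    window_end: int        # last window ordinal (exclusive)
    log2_effect: float     # mean multiplier 2**log2_effect in the affected group
    comparison: str        # name of the comparison whose group A is shifted


@dataclass(frozen=True)
class ModuleBlock:
    """Windows sharing a latent multiplicative factor across samples.

    ``trait`` optionally names a sample trait the latent factor follows, so
    module-trait correlation has planted signal to recover.
    """

    window_ordinals: tuple[int, ...]
    loading: float = 0.5
    trait: str | None = None


@dataclass
class StudyDesign:
    """Sample sheet plus simulation parameters for one synthetic study."""

    samples: pd.DataFrame            # columns: sample_id, exposure, + binary disease labels
    groups: dict[str, tuple[list[str], list[str]]]   # comparison -> (group A ids, group B ids)
    library_size_targets: dict[str, float]
    planted_dmrs: list[PlantedDMR] = field(default_factory=list)
    dispersion: float = 0.1
    baseline_mu: np.ndarray | float = 10.0   # per-window expected count at target depth
    module_blocks: list[ModuleBlock] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise InvalidParameterError("dispersion must be >= 0")
        for name, (a, b) in self.groups.items():
            if set(a) & set(b):
                raise InvalidParameterError(f"comparison {name}: groups overlap")
        for dmr in self.planted_dmrs:
            if dmr.comparison not in self.groups:
                raise InvalidParameterError(
                    f"planted DMR references unknown comparison {dmr.comparison!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])


# ---- genome --------------------------------------------------------------

def generate_genome(n_chroms: int, chrom_length: int, cpg_rate: float,
                    seed: int, window_size: int = 1000) -> GenomeDef:
    """Synthetic genome with CpG sites placed as a homogeneous point process.

    Each base carries a CpG with probability ``cpg_rate`` independently, so
    the per-chromosome CpG count is Binomial(length, rate) and positions are
    uniform. Deterministic for a fixed seed.
    """
    if n_chroms < 1 or chrom_length < 10 * window_size:
        raise InvalidParameterError(
            f"need n_chroms >= 1 and chrom_length >= {10 * window_size}")
    if not 0 <= cpg_rate < 1:
        raise InvalidParameterError("cpg_rate must be in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    names = [f"chr{i + 1}" for i in range(n_chroms)]
    cpgs: dict[str, np.ndarray] = {}
    for name in names:
        n = rng.binomial(chrom_length, cpg_rate) if cpg_rate > 0 else 0
        pos = np.sort(rng.choice(chrom_length, size=n, replace=False)) if n else np.empty(0, np.int64)
        cpgs[name] = pos.astype(np.int64)
    return GenomeDef(names, [chrom_length] * n_chroms, cpgs)


def generate_genes(genome: GenomeDef, n_genes: int, seed: int,
                   mean_length: int = 20_000) -> list[GeneModel]:
    """Uniformly placed non-validated gene bodies for annotation tests."""
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    genes = []
    for i in range(n_genes):
        ci = int(rng.integers(len(genome.chrom_names)))
        chrom = genome.chrom_names[ci]
        L = genome.chrom_lengths[ci]
        length = max(200, int(rng.exponential(mean_length)))
        length = min(length, L - 1)
        start = int(rng.integers(0, L - length))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"G{i:05d}", f"Gene{i:05d}", chrom, start, start + length, strand))
    genes.sort(key=lambda g: (genome.chrom_names.index(g.chrom), g.start))
    return genes


# ---- counts --------------------------------------------------------------

def baseline_from_cpg(grid: WindowGrid, depth_at_mean_density: float = 10.0,
                      floor: float = 0.5, slope: float | None = None) -> np.ndarray:
    """Affine CpG-density-linked baseline window mean.

    MeDIP coverage tracks CpG density, so the expected count for window w is
    ``floor + slope * cpg_count(w)``, with slope chosen so a window of
    genome-average CpG count has expectation ``depth_at_mean_density``.
    """
    cpg = np.array([grid.genome.cpg_count(c, s, e)
                    for c, s, e in zip(grid.chrom, grid.start, grid.end)], dtype=float)
    if slope is None:
        mean_cpg = cpg.mean() if cpg.mean() > 0 else 1.0
        slope = max(0.0, (depth_at_mean_density - floor) / mean_cpg)
    return floor + slope * cpg


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean, dispersion phi) with var = mu + phi*mu^2; phi=0 is Poisson."""
    mean = np.clip(mean, 1e-12, None)
    if phi == 0:
        return rng.poisson(mean)
    size = 1.0 / phi
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_counts(design: StudyDesign, grid: WindowGrid) -> CountMatrix:
    """Simulate the window x sample count matrix the design describes.

    count[w, s] ~ NB(mu = baseline_mu[w] * libfactor[s] * 2**effect * latent,
    dispersion phi), where the effect applies at planted DMR windows for
    samples in the affected comparison's group A, and the latent factor is a
    per-sample log-normal multiplier shared by all windows of a module block.
    """
    n_w = grid.n_windows
    mu0 = np.broadcast_to(np.asarray(design.baseline_mu, dtype=float), (n_w,)).copy()
    samples = design.sample_ids
    for dmr in design.planted_dmrs:
        if not (0 <= dmr.window_start < dmr.window_end <= n_w):
            raise InvalidParameterError(
                f"planted DMR windows [{dmr.window_start}, {dmr.window_end}) out of range")
    for blk in design.module_blocks:
        if max(blk.window_ordinals, default=0) >= n_w:
            raise InvalidParameterError("module block window out of range")

    target_total = {s: design.library_size_targets.get(s, mu0.sum()) for s in samples}
    ss = np.random.SeedSequence(design.seed).spawn(len(samples) + 1)
    latent_rng = np.random.default_rng(ss[-1])

    # per-block latent factor per sample, optionally tracking a named trait
    block_factors = np.zeros((len(design.module_blocks), len(samples)))
    for bi, blk in enumerate(design.module_blocks):
        if blk.trait is not None:
            t = design.samples[blk.trait].to_numpy(float)
            t = (t - t.mean()) / (t.std() if t.std() > 0 else 1.0)
            z = t + 0.3 * latent_rng.standard_normal(len(samples))
        else:
            z = latent_rng.standard_normal(len(samples))
        block_factors[bi] = blk.loading * z

    counts = np.zeros((n_w, len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        rng = np.random.default_rng(ss[j])
        mu = mu0.copy()
        for dmr in design.planted_dmrs:
            group_a = design.groups[dmr.comparison][0]
            if s in group_a:
                mu[dmr.window_start:dmr.window_end] *= 2.0 ** dmr.log2_effect
        for bi, blk in enumerate(design.module_blocks):
            idx = np.asarray(blk.window_ordinals, dtype=int)
            mu[idx] *= np.exp(block_factors[bi, j])
        mu *= target_total[s] / mu0.sum()
        counts[:, j] = _nb_draw(rng, mu, design.dispersion)
    return CountMatrix(counts, samples, counts.sum(axis=0))


def counts_to_reads(cm: CountMatrix, grid: WindowGrid,
                    fragment_length: int = 250) -> ReadSet:
    """Place count[w, s] fragments fully inside window w, evenly spaced.

    Placement is deterministic so containment-mode re-counting recovers the
    matrix exactly.
    """
    if fragment_length > grid.window_size:
        raise InvalidParameterError(
            f"fragment_length {fragment_length} exceeds window size {grid.window_size}")
    rs = ReadSet()
    for j, sample in enumerate(cm.sample_ids):
        col = cm.counts[:, j]
        hit = np.flatnonzero(col)
        chroms, starts, ends = [], [], []
        for w in hit:
            n = int(col[w])
            win_len = int(grid.end[w] - grid.start[w])
            if fragment_length > win_len:
                raise InvalidParameterError(
                    f"fragment_length {fragment_length} exceeds terminal window length {win_len}")
            slack = win_len - fragment_length
            offs = (np.arange(n) * slack) // max(n - 1, 1) if n > 1 else np.zeros(1, np.int64)
            s0 = grid.start[w] + offs.astype(np.int64)
            chroms.extend([grid.chrom[w]] * n)
            starts.extend(s0.tolist())
            ends.extend((s0 + fragment_length).tolist())
        rs.add(sample, pd.DataFrame({"chrom": pd.Series(chroms, dtype=str),
                                     "start": pd.Series(starts, dtype=np.int64),
                                     "end": pd.Series(ends, dtype=np.int64),
                                     "strand": "."}))
    return rs


# ---- pathology -----------------------------------------------------------

def simulate_pathology(n_control: int, n_case: int, control_rate: float,
                       case_shift: float, n_observers: int, seed: int,
                       tissue: str = "testis") -> pd.DataFrame:
    """Per animal x observer abnormality counts.

    Counts are Poisson(control_rate) for control-lineage animals and
    Poisson(control_rate + case_shift) for case animals, independent across
    observers (observers recount the same section with independent error).
    """
    if control_rate < 0 or case_shift < 0:
        raise InvalidParameterError("rates must be >= 0")
    if n_observers < 3:
        raise InvalidParameterError("need at least 3 observers for the 2-of-3 rule")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    rows = []
    for lineage, prefix, n, rate in (("control", "CTRL", n_control, control_rate),
                                     ("case", "CASE", n_case, control_rate + case_shift)):
        for i in range(n):
            animal = f"{prefix}{i + 1:03d}"
            for obs in range(1, n_observers + 1):
                rows.append((animal, lineage, tissue, f"obs{obs}",
                             int(rng.poisson(rate))))
    return pd.DataFrame(rows, columns=["animal_id", "lineage", "tissue",
                                       "observer", "abnormality_count"])


# ---- convenience writers -------------------------------------------------

def write_design(design: StudyDesign, path: str | Path) -> None:
    """Persist the design as YAML (sample sheet inline)."""
    import yaml

    doc = {
        "seed": design.seed,
        "dispersion": design.dispersion,
        "samples": design.samples.to_dict(orient="records"),
        "groups": {k: {"group_a": a, "group_b": b} for k, (a, b) in design.groups.items()},
        "library_size_targets": {k: float(v) for k, v in design.library_size_targets.items()},
        "planted_dmrs": [{"window_start": d.window_start, "window_end": d.window_end,
                          "log2_effect": d.log2_effect, "comparison": d.comparison}
                         for d in design.planted_dmrs],
        "module_blocks": [{"windows": list(map(int, b.window_ordinals)),
                           "loading": b.loading, "trait": b.trait}
                          for b in design.module_blocks],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
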
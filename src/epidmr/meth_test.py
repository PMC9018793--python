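"""Per-window two-group differential methylation testing.

The statistic is a negative-binomial conditional exact test with a common
dispersion, in the edgeR tradition: library sizes are first equalized by
deterministic scaling to the geometric-mean library size, group counts are
summed per window, and the split of the conditional total between the two
groups is compared against its NB null distribution. Two-sided p sums the
probabilities of all splits no more likely than the observed one.

With dispersion 0 the test degenerates exactly to the conditional binomial
exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import nbinom, poisson
from statsmodels.stats.multitest import multipletests

from .genome import InvalidParameterError
from .windows import CountMatrix

# Relative tolerance for probability ties in the two-sided rule: outcomes
# whose conditional probability is within this factor of the observed one
# count as "no more likely" (absorbs floating-point round-off, as in
# scipy's Fisher-exact convention).
_TIE_REL = 1e-7


@dataclass(frozen=True)
class DispersionEstimate:
    """Common NB dispersion (var = mu + phi*mu^2) shared by all windows."""

    phi: float
    method: str
    pseudo_lib: float   # common library size counts were equalized to

    def __post_init__(self) -> None:
        if self.phi < 0:
            raise InvalidParameterError("dispersion must be >= 0")


def equalize_libraries(counts: np.ndarray, library_sizes: np.ndarray
                       ) -> tuple[np.ndarray, float]:
    """Scale each sample's counts to the geometric-mean library size.

    Rounding is half-even (numpy's rint). Returns the equalized integer
    matrix and the common pseudo-library size.
    """
    lib = np.asarray(library_sizes, dtype=float)
    if np.any(lib <= 0):
        raise InvalidParameterError("library sizes must be positive to equalize")
    geo = float(np.exp(np.mean(np.log(lib))))
    scaled = np.rint(counts * (geo / lib)[None, :])
    return scaled.astype(np.int64), geo


def _conditional_log_pmf(T: int, nA: int, nB: int, phi: float) -> np.ndarray:
    """Unnormalized log-probability of each split sumA = 0..T given total T."""
    a = np.arange(T + 1)
    mu = T / (nA + nB)   # per-sample conditional mean estimate
    if phi == 0 or mu == 0:
        return poisson.logpmf(a, nA * mu) + poisson.logpmf(T - a, nB * mu)
    # group sum of n iid NB(mu, phi) is NB(n*mu, phi/n): size n/phi, same p
    p = 1.0 / (1.0 + phi * mu)
    return nbinom.logpmf(a, nA / phi, p) + nbinom.logpmf(T - a, nB / phi, p)


def exact_test_window(sum_a: int, sum_b: int, n_a: int, n_b: int,
                      phi: float) -> float:
    """Two-sided NB conditional exact p for one window.

    Inputs are group count sums after library equalization. Conditional on
    T = sum_a + sum_b, every split 0..T is scored by the product of the two
    group-sum NB probabilities; p is the total conditional mass of splits
    whose probability does not exceed the observed split's.
    """
    if sum_a < 0 or sum_b < 0:
        raise InvalidParameterError("negative count sums")
    if n_a < 1 or n_b < 1 or phi < 0:
        raise InvalidParameterError("need n_a, n_b >= 1 and phi >= 0")
    T = int(sum_a) + int(sum_b)
    if T == 0:
        return 1.0
    lp = _conditional_log_pmf(T, n_a, n_b, phi)
    probs = np.exp(lp - lp.max())
    p_obs = probs[int(sum_a)]
    p = probs[probs <= p_obs * (1.0 + _TIE_REL)].sum() / probs.sum()
    return float(min(p, 1.0))


def logfc(sum_a: float, sum_b: float, lib_a: float, lib_b: float,
          prior: float = 0.5) -> float:
    """log2 of the prior-damped normalized group-sum ratio."""
    if lib_a <= 0 or lib_b <= 0:
        raise InvalidParameterError("library sizes must be positive")
    if prior < 0:
        raise InvalidParameterError("prior must be >= 0")
    if sum_a + prior == 0 or sum_b + prior == 0:
        raise InvalidParameterError("log fold change undefined: zero numerator or denominator")
    return float(np.log2(((sum_a + prior) / lib_a) / ((sum_b + prior) / lib_b)))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise InvalidParameterError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---- dispersion estimation ----------------------------------------------

def estimate_dispersion(cm: CountMatrix, group_a: list[str], group_b: list[str],
                        method: str = "grid_cml") -> DispersionEstimate:
    """Common dispersion across windows after library equalization.

    ``moments``: pooled method-of-moments ratio
    max(0, sum_w (var_w - mean_w) / sum_w mean_w^2) using within-group
    sample moments. ``grid_cml``: maximize the summed conditional NB
    log-likelihood (conditioning on each window's group total) over a
    61-point log-spaced grid phi in [1e-4, 10]; requires replication in at
    least one group.
    """
    if method not in ("moments", "grid_cml"):
        raise InvalidParameterError(f"unknown dispersion method {method!r}")
    if not group_a or not group_b:
        raise InvalidParameterError("both groups need at least one sample")
    ya_raw = cm.columns(group_a)
    yb_raw = cm.columns(group_b)
    idx = [cm.sample_ids.index(s) for s in group_a + group_b]
    eq, geo = equalize_libraries(np.hstack([ya_raw, yb_raw]),
                                 cm.library_sizes[idx])
    ya, yb = eq[:, :len(group_a)], eq[:, len(group_a):]

    if method == "moments":
        num = 0.0
        den = 0.0
        for y in (ya, yb):
            n = y.shape[1]
            if n < 2:
                continue
            m = y.mean(axis=1)
            v = y.var(axis=1, ddof=1)
            num += float(np.sum(v - m))
            den += float(np.sum(m ** 2))
        if den == 0:
            phi = 0.0
        else:
            phi = max(0.0, num / den)
        return DispersionEstimate(phi, "moments", geo)

    if ya.shape[1] < 2 and yb.shape[1] < 2:
        raise InvalidParameterError("grid_cml needs replication in at least one group")
    grid = np.logspace(-4, 1, 61)
    ll = np.array([_cond_loglik(ya, phi) + _cond_loglik(yb, phi) for phi in grid])
    return DispersionEstimate(float(grid[int(np.argmax(ll))]), "grid_cml", geo)


def _cond_loglik(y: np.ndarray, phi: float) -> float:
    """Summed NB log-likelihood of within-group counts conditional on each
    window's group total (equal library sizes assumed)."""
    n = y.shape[1]
    if n < 2:
        return 0.0
    r = 1.0 / phi
    z = y.sum(axis=1)
    return float(np.sum(gammaln(y + r)) - y.size * gammaln(r)
                 + y.shape[0] * gammaln(n * r) - np.sum(gammaln(z + n * r)))


# ---- whole-table driver --------------------------------------------------

def test_all_windows(cm: CountMatrix, group_a: list[str], group_b: list[str],
                     dispersion: float | str = "grid_cml",
                     prior: float = 0.5) -> pd.DataFrame:
    """Exact test, log2 fold change and BH q for every window.

    ``dispersion`` is a fixed phi, or ``"moments"`` / ``"grid_cml"`` to
    estimate it from the data. Returns a table with columns window, mean_A,
    mean_B, log2fc, pvalue, qvalue (window = row ordinal into ``cm``).
    """
    if set(group_a) & set(group_b):
        raise InvalidParameterError("groups must be disjoint")
    if isinstance(dispersion, str):
        phi = estimate_dispersion(cm, group_a, group_b, method=dispersion).phi
    else:
        phi = float(dispersion)
        if phi < 0:
            raise InvalidParameterError("dispersion must be >= 0")
    idx = [cm.sample_ids.index(s) for s in group_a + group_b]
    eq, geo = equalize_libraries(cm.counts[:, idx], cm.library_sizes[idx])
    n_a, n_b = len(group_a), len(group_b)
    sum_a = eq[:, :n_a].sum(axis=1)
    sum_b = eq[:, n_a:].sum(axis=1)

    # the conditional distribution depends only on the total T, so cache it
    cache: dict[int, np.ndarray] = {}
    pvals = np.empty(cm.n_windows)
    for w in range(cm.n_windows):
        T = int(sum_a[w] + sum_b[w])
        if T == 0:
            pvals[w] = 1.0
            continue
        probs = cache.get(T)
        if probs is None:
            lp = _conditional_log_pmf(T, n_a, n_b, phi)
            probs = np.exp(lp - lp.max())
            probs /= probs.sum()
            cache[T] = probs
        p_obs = probs[int(sum_a[w])]
        pvals[w] = min(probs[probs <= p_obs * (1.0 + _TIE_REL)].sum(), 1.0)

    lfc = np.log2(((sum_a + prior) / (n_a * geo)) / ((sum_b + prior) / (n_b * geo)))
    return pd.DataFrame({
        "window": np.arange(cm.n_windows),
        "mean_A": sum_a / n_a,
        "mean_B": sum_b / n_b,
        "log2fc": lfc,
        "pvalue": pvals,
        "qvalue": bh_fdr(pvals),
    })


def write_window_stats(stats: pd.DataFrame, grid, path,
                       window_ordinals=None) -> None:
    """WindowStat TSV with genome coordinates resolved from the grid."""
    ords = stats["window"].to_numpy() if window_ordinals is None \
        else np.asarray(window_ordinals)[stats["window"].to_numpy()]
    out = pd.DataFrame({
        "window_id": [f"w{o}" for o in ords],
        "chrom": grid.chrom[ords],
        "start": grid.start[ords],
        "end": grid.end[ords],
        "mean_A": stats["mean_A"], "mean_B": stats["mean_B"],
        "log2fc": stats["log2fc"], "pvalue": stats["pvalue"],
        "qvalue": stats["qvalue"],
    })
    out.to_csv(path, sep="\t", index=False)


def read_window_stats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df["window"] = df["window_id"].str.removeprefix("w").astype(int)
    return df
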
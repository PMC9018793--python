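"""Histopathology-based disease classification and frequency testing.

Per tissue, each observer's abnormality count for an animal is compared
against a threshold derived from the control lineage: mean plus two sample
standard deviations of the control counts. A count strictly greater than
the threshold marks that observer's call as diseased; an animal's tissue is
declared diseased only when at least 2 of the 3 blinded observers agree.
Lineage disease frequencies are compared with Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .genome import InvalidParameterError

RECORD_COLS = ["animal_id", "lineage", "tissue", "observer", "abnormality_count"]


def disease_threshold(control_counts) -> float:
    """Control mean + 2 sample SD (n-1 denominator); counts must strictly
    exceed this to qualify as diseased."""
    x = np.asarray(control_counts, dtype=float)
    if x.size < 2:
        raise InvalidParameterError("need at least 2 control values")
    if np.any(x < 0):
        raise InvalidParameterError("abnormality counts must be >= 0")
    return float(x.mean() + 2.0 * x.std(ddof=1))


def compute_thresholds(records: pd.DataFrame, control_lineage: str = "control",
                       per_observer: bool = False) -> pd.DataFrame:
    """Per-tissue thresholds from control-lineage counts.

    By default control counts are pooled across observers; ``per_observer``
    computes a separate threshold per observer instead.
    """
    ctrl = records[records["lineage"] == control_lineage]
    if not len(ctrl):
        raise InvalidParameterError(f"no records for control lineage {control_lineage!r}")
    keys = ["tissue", "observer"] if per_observer else ["tissue"]
    rows = []
    for key, grp in ctrl.groupby(keys):
        key = key if isinstance(key, tuple) else (key,)
        rows.append(dict(zip(keys, key),
                         threshold=disease_threshold(grp["abnormality_count"])))
    return pd.DataFrame(rows)


@dataclass
class ObserverRule:
    """k-of-m observer agreement rule (default 2-of-3)."""

    k: int = 2
    m: int = 3
    missing_policy: str = "strict"   # strict | available

    def __post_init__(self) -> None:
        if not 1 <= self.k <= self.m:
            raise InvalidParameterError("need 1 <= k <= m")
        if self.missing_policy not in ("strict", "available"):
            raise InvalidParameterError("missing_policy must be strict or available")


def classify_animals(records: pd.DataFrame, thresholds: pd.DataFrame,
                     rule: ObserverRule = ObserverRule()) -> pd.DataFrame:
    """Binary disease call per animal x tissue by the k-of-m observer rule.

    Returns one row per animal x tissue with the per-observer booleans, the
    call, and a per-animal disease-burden label: ``single-disease`` when
    exactly one tissue is diseased, ``multiple disease`` for more than one,
    ``none`` otherwise.
    """
    missing = set(RECORD_COLS) - set(records.columns)
    if missing:
        raise InvalidParameterError(f"records missing columns: {sorted(missing)}")
    per_observer = "observer" in thresholds.columns
    thr: dict = {}
    for row in thresholds.itertuples(index=False):
        key = (row.tissue, row.observer) if per_observer else row.tissue
        thr[key] = row.threshold
    rows = []
    for (animal, tissue), grp in records.groupby(["animal_id", "tissue"]):
        calls = {}
        for rec in grp.itertuples(index=False):
            key = (tissue, rec.observer) if per_observer else tissue
            if key not in thr:
                raise InvalidParameterError(f"no threshold for {key!r}")
            calls[rec.observer] = bool(rec.abnormality_count > thr[key])
        if len(calls) < rule.m and rule.missing_policy == "strict":
            raise InvalidParameterError(
                f"{animal}/{tissue}: {len(calls)} observers, rule expects {rule.m}")
        diseased = sum(calls.values()) >= rule.k
        rows.append({"animal_id": animal, "lineage": grp["lineage"].iloc[0],
                     "tissue": tissue, "diseased": diseased,
                     "observer_calls": ";".join(f"{o}={int(v)}" for o, v in sorted(calls.items())),
                     "threshold": thr[(tissue, rec.observer)] if per_observer else thr[tissue]})
    calls_df = pd.DataFrame(rows)
    burden = calls_df.groupby("animal_id")["diseased"].sum()
    label = burden.map(lambda n: "multiple disease" if n > 1
                       else ("single-disease" if n == 1 else "none"))
    calls_df["disease_burden"] = calls_df["animal_id"].map(label)
    return calls_df


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table (hypergeometric,
    summing tables with fixed margins no more probable than the observed)."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise InvalidParameterError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t < 0) or np.any(t != np.floor(t)):
            raise InvalidParameterError("table entries must be non-negative integers")
        t = t.astype(np.int64)
    return float(fisher_exact(t, alternative="two-sided")[1])


def disease_frequency_report(calls: pd.DataFrame,
                             control_lineage: str = "control") -> pd.DataFrame:
    """Per-lineage, per-tissue disease proportions with Fisher p vs control.

    Lineages with no animals for a tissue are flagged missing (NaN
    proportion). The control row carries p = 1 by construction.
    """
    if control_lineage not in set(calls["lineage"]):
        raise InvalidParameterError(f"control lineage {control_lineage!r} absent")
    rows = []
    for tissue, grp in calls.groupby("tissue"):
        ctrl = grp[grp["lineage"] == control_lineage]
        c_dis = int(ctrl["diseased"].sum())
        c_tot = len(ctrl)
        for lineage, lg in grp.groupby("lineage"):
            n_dis = int(lg["diseased"].sum())
            n_tot = len(lg)
            if n_tot == 0 or c_tot == 0:
                rows.append({"tissue": tissue, "lineage": lineage, "n": n_tot,
                             "n_diseased": n_dis, "proportion": np.nan,
                             "fisher_p_vs_control": np.nan})
                continue
            p = 1.0 if lineage == control_lineage else fisher_exact_2x2(
                [[n_dis, n_tot - n_dis], [c_dis, c_tot - c_dis]])
            rows.append({"tissue": tissue, "lineage": lineage, "n": n_tot,
                         "n_diseased": n_dis, "proportion": n_dis / n_tot,
                         "fisher_p_vs_control": p})
    return pd.DataFrame(rows)
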
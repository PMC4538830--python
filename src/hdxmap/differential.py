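"""Per-peptide differential uptake (ΔHDX) and three-criterion significance calls.

For each peptide shared between two states, replicate %HDX values are
averaged per timepoint and differenced (bound − free). The signed
difference of maximal magnitude over the timepoints is ΔHDX; the peptide
is called significant when all three criteria hold:

    |ΔHDX| > 10 %      (strict)
    t-test p < 0.05    (unpaired, two-tailed, pooled variance)
    |Δmass| ≥ 0.5 Da   (inclusive)

Negative ΔHDX means protection on binding (an exchange decrease, the
classic interface signature); positive means deprotection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import Peptide, deuterons_from_da
from .constants import DEUTERIUM_MASS_SHIFT

__all__ = [
    "CallingThresholds",
    "DifferentialResult",
    "per_timepoint_diff",
    "delta_hdx",
    "unpaired_t_test",
    "call_peptide",
    "analyze_differential",
]

logger = logging.getLogger(__name__)

_KEY = ["protein_id", "start", "end", "sequence"]


@dataclass(frozen=True)
class CallingThresholds:
    """Significance thresholds for the three-criterion call."""

    min_delta_pct: float = 10.0
    alpha: float = 0.05
    min_da: float = 0.5

    def __post_init__(self) -> None:
        if min(self.min_delta_pct, self.alpha, self.min_da) <= 0:
            raise ValueError("all thresholds must be strictly positive")


@dataclass(frozen=True)
class DifferentialResult:
    """ΔHDX statistic and significance call for one peptide."""

    peptide: Peptide
    per_timepoint: pd.DataFrame  # timepoint_s, diff_pct, diff_da, p_value
    delta_hdx_pct: float
    delta_timepoint_s: float
    delta_da: float
    p_value: float
    significant: bool
    direction: str  # decrease | increase | none
    reasons: tuple[str, ...]  # failed criteria, empty when significant


def per_timepoint_diff(
    records_a: pd.DataFrame, records_b: pd.DataFrame, n_max: int
) -> pd.DataFrame:
    """Mean uptake differences (B − A) per timepoint, in %HDX and Da.

    Both inputs are single-peptide record tables covering the same
    timepoints with at least two replicates each. The returned frame also
    carries the per-timepoint two-sample t-test p-value on replicate
    deuteron counts.
    """
    rows = []
    tps_a = sorted(records_a["timepoint_s"].unique())
    tps_b = sorted(records_b["timepoint_s"].unique())
    if tps_a != tps_b:
        raise ValueError("states cover different timepoints")
    for t in tps_a:
        a = records_a.loc[records_a["timepoint_s"] == t, "uptake_Da"].to_numpy()
        b = records_b.loc[records_b["timepoint_s"] == t, "uptake_Da"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"fewer than 2 replicates at timepoint {t}")
        diff_da = b.mean() - a.mean()
        diff_pct = 100.0 * deuterons_from_da(diff_da) / n_max
        p = unpaired_t_test(deuterons_from_da(a), deuterons_from_da(b))
        rows.append((t, diff_pct, diff_da, p))
    return pd.DataFrame(rows, columns=["timepoint_s", "diff_pct", "diff_da", "p_value"])


def delta_hdx(per_timepoint: pd.DataFrame) -> tuple[float, float]:
    """The signed per-timepoint difference of maximal magnitude (ΔHDX).

    Ties in magnitude are broken toward the earliest timepoint. Returns
    ``(delta_pct, timepoint_s)``.
    """
    if len(per_timepoint) == 0:
        raise ValueError("need at least one timepoint")
    df = per_timepoint.sort_values("timepoint_s", kind="stable")
    vals = df["diff_pct"].to_numpy()
    idx = int(np.argmax(np.abs(vals)))  # argmax takes the first maximum
    return float(vals[idx]), float(df["timepoint_s"].to_numpy()[idx])


def unpaired_t_test(reps_a, reps_b) -> float:
    """Two-sample Student's t-test (pooled variance), two-tailed p-value.

    Degenerate zero-variance inputs return p = 1 for equal means and p = 0
    otherwise.
    """
    a = np.asarray(reps_a, dtype=float)
    b = np.asarray(reps_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def call_peptide(
    delta_hdx_pct: float,
    p_value: float,
    delta_da: float,
    thresholds: CallingThresholds | None = None,
) -> tuple[bool, tuple[str, ...]]:
    """Apply the three-criterion rule; reasons name every failed criterion."""
    thr = thresholds or CallingThresholds()
    reasons = []
    if not abs(delta_hdx_pct) > thr.min_delta_pct:
        reasons.append("min_delta_pct")
    if not p_value < thr.alpha:
        reasons.append("alpha")
    if not abs(delta_da) >= thr.min_da:
        reasons.append("min_da")
    return len(reasons) == 0, tuple(reasons)


def analyze_differential(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    thresholds: CallingThresholds | None = None,
    skip_first: int = 1,
    t_test_scope: str = "max_timepoint",
) -> list[DifferentialResult]:
    """Run the full differential analysis over two state tables.

    ``table_a`` is the reference state (e.g. free) and ``table_b`` the
    comparison state (e.g. bound); differences are B − A. Peptides missing
    from one state, with mismatched timepoints, with fewer than two
    replicates, or with no exchangeable amides are excluded with a logged
    warning. ``t_test_scope`` chooses the p-value entering the call:
    ``max_timepoint`` (at the ΔHDX timepoint) or ``any_timepoint``
    (minimum p over timepoints).

    Results are sorted by protein then start position.
    """
    if t_test_scope not in ("max_timepoint", "any_timepoint"):
        raise ValueError("t_test_scope must be 'max_timepoint' or 'any_timepoint'")
    thr = thresholds or CallingThresholds()
    groups_a = dict(tuple(table_a.groupby(_KEY, sort=False)))
    groups_b = dict(tuple(table_b.groupby(_KEY, sort=False)))
    shared = sorted(set(groups_a) & set(groups_b))
    if not shared:
        raise ValueError("the two states share no peptides")
    for key in sorted(set(groups_a) ^ set(groups_b)):
        logger.warning("peptide %s excluded: present in only one state", key)

    results = []
    for key in shared:
        protein_id, start, end, sequence = key
        try:
            pep = Peptide.from_sequence(protein_id, int(start), sequence, skip_first)
        except ValueError as exc:
            logger.warning("peptide %s excluded: %s", key, exc)
            continue
        if pep.n_max < 1:
            logger.warning("peptide %s excluded: no exchangeable amides", key)
            continue
        try:
            diffs = per_timepoint_diff(groups_a[key], groups_b[key], pep.n_max)
        except ValueError as exc:
            logger.warning("peptide %s excluded: %s", key, exc)
            continue
        d_pct, d_tp = delta_hdx(diffs)
        at_tp = diffs.loc[diffs["timepoint_s"] == d_tp].iloc[0]
        d_da = float(at_tp["diff_da"])
        if t_test_scope == "max_timepoint":
            p = float(at_tp["p_value"])
        else:
            p = float(diffs["p_value"].min())
        significant, reasons = call_peptide(d_pct, p, d_da, thr)
        if significant:
            direction = "decrease" if d_pct < 0 else "increase"
        else:
            direction = "none"
        results.append(DifferentialResult(
            peptide=pep, per_timepoint=diffs, delta_hdx_pct=d_pct,
            delta_timepoint_s=d_tp, delta_da=d_da, p_value=p,
            significant=significant, direction=direction, reasons=reasons,
        ))
    results.sort(key=lambda r: (r.peptide.protein_id, r.peptide.start, r.peptide.end))
    return results
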
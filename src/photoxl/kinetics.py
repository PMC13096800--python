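"""Half-effective crosslinking time (ET50) estimation.

Crosslinked-protein yield grows in a saturating fashion with irradiation
time. The estimator works on replicate-averaged intensities normalized to
their maximum: points up to and including the maximum are fitted by ordinary
least squares against the natural log of irradiation time, and the
half-effective crosslinking time is

    ET50 = ln(2) / slope

in seconds. The unirradiated (t=0) sample never enters the fit (ln 0 is
undefined); it is used exclusively to remove the crosslink-independent
background: proteins whose relative intensity at t=0 exceeds 0.5 are dropped.

Group comparisons of ET50 distributions (e.g. between RNA-binding domain
families) use a two-sided Wilcoxon rank-sum test of each group against the
full set of recovered proteins, with Bonferroni-Holm adjustment across groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import QuantMatrix
from .differential import adjust_pvalues

__all__ = [
    "KineticsResult",
    "GroupComparison",
    "normalize_to_max",
    "filter_background",
    "estimate_et50",
    "timecourse_profile",
    "estimate_all",
    "compare_groups",
]


@dataclass(frozen=True)
class KineticsResult:
    """Per-protein log-time fit and derived ET50 (seconds)."""

    protein_id: str
    slope: float = float("nan")
    intercept: float = float("nan")
    n_points: int = 0
    t_max: float = float("nan")
    et50: float | None = None
    status: str = "ok"  # ok | background_removed | too_few_points | nonpositive_slope

    def __post_init__(self) -> None:
        if self.status == "ok":
            if self.et50 is None or self.n_points < 3:
                raise ValueError("status ok requires a defined et50 and >= 3 points")
        elif self.et50 is not None:
            raise ValueError("et50 defined only when status is ok")


@dataclass(frozen=True)
class GroupComparison:
    group_label: str
    n_group: int
    n_reference: int
    statistic: float
    p_raw: float
    p_adjusted: float
    mean_et50: float
    sd_et50: float


def normalize_to_max(
    values: np.ndarray, replicate_groups: Sequence[Sequence[int]] | None = None
) -> np.ndarray:
    """Average replicates per time point and divide by the series maximum.

    ``values`` is one protein's intensities; if ``replicate_groups`` is given,
    entry ``g`` of the output is the arithmetic mean of the finite values at
    indices ``replicate_groups[g]``. The maximum of the averaged series maps
    to exactly 1.
    """
    values = np.asarray(values, dtype=float)
    if replicate_groups is not None:
        averaged = np.full(len(replicate_groups), np.nan)
        for g, idx in enumerate(replicate_groups):
            vals = values[list(idx)]
            vals = vals[np.isfinite(vals)]
            if vals.size:
                averaged[g] = vals.mean()
    else:
        averaged = values
    if not np.isfinite(averaged).any():
        raise ValueError("all-missing series cannot be normalized")
    return averaged / np.nanmax(averaged)


def filter_background(
    rel: np.ndarray, times: np.ndarray, threshold: float = 0.5
) -> bool:
    """Keep/remove decision from the unirradiated sample.

    Returns True (remove) iff the relative intensity at t=0 strictly exceeds
    ``threshold``; a missing t=0 value counts as 0.
    """
    times = np.asarray(times, dtype=float)
    zero = np.flatnonzero(times == 0)
    if zero.size == 0:
        raise ValueError("series has no t=0 (unirradiated) sample")
    value = rel[zero[0]]
    if not np.isfinite(value):
        value = 0.0
    return bool(value > threshold)


def estimate_et50(
    rel: np.ndarray, times: np.ndarray, protein_id: str = ""
) -> KineticsResult:
    """Fit relative intensity against ln(time) and derive ET50.

    Points with time <= t_max are selected, where t_max is the earliest time
    achieving the maximal relative intensity among positive times; t=0 is
    excluded. OLS slope of intensity on ln(time) yields
    ``et50 = ln(2)/slope``; a non-positive slope or fewer than 3 usable
    points is reported via the status field.
    """
    rel = np.asarray(rel, dtype=float)
    times = np.asarray(times, dtype=float)
    usable = (times > 0) & np.isfinite(rel)
    if usable.sum() < 3:
        return KineticsResult(protein_id=protein_id, status="too_few_points",
                              n_points=int(usable.sum()))
    t_u = times[usable]
    r_u = rel[usable]
    order = np.argsort(t_u)
    t_u, r_u = t_u[order], r_u[order]
    i_max = int(np.argmax(r_u))  # earliest time on ties
    t_max = float(t_u[i_max])
    sel = t_u <= t_max
    n_points = int(sel.sum())
    if n_points < 3:
        return KineticsResult(
            protein_id=protein_id, status="too_few_points",
            n_points=n_points, t_max=t_max,
        )
    x = np.log(t_u[sel])
    y = r_u[sel]
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        return KineticsResult(
            protein_id=protein_id, slope=float(slope),
            intercept=float(intercept), n_points=n_points, t_max=t_max,
            status="nonpositive_slope",
        )
    return KineticsResult(
        protein_id=protein_id, slope=float(slope), intercept=float(intercept),
        n_points=n_points, t_max=t_max, et50=math.log(2) / float(slope),
        status="ok",
    )


def timecourse_profile(
    qm: QuantMatrix,
) -> tuple[np.ndarray, list[list[int]]]:
    """Sorted unique irradiation times and the replicate columns at each."""
    times = np.array(sorted({s.irradiation_time for s in qm.samples}))
    groups = [
        [i for i, s in enumerate(qm.samples) if s.irradiation_time == t]
        for t in times
    ]
    return times, groups


def estimate_all(
    qm: QuantMatrix, background_threshold: float = 0.5
) -> list[KineticsResult]:
    """Run the full per-protein ET50 procedure on a time-course matrix.

    Replicates are averaged per time point, each protein normalized to its
    maximum, background proteins (relative intensity > threshold at t=0)
    removed, then the log-time fit applied.
    """
    times, groups = timecourse_profile(qm)
    if 0.0 not in times:
        raise ValueError("time-course matrix has no unirradiated (t=0) sample")
    results = []
    for i, pid in enumerate(qm.protein_ids):
        row = qm.intensities[i]
        if not np.isfinite(row).any():
            results.append(
                KineticsResult(protein_id=pid, status="too_few_points")
            )
            continue
        rel = normalize_to_max(row, groups)
        if filter_background(rel, times, background_threshold):
            results.append(
                KineticsResult(protein_id=pid, status="background_removed")
            )
            continue
        results.append(estimate_et50(rel, times, protein_id=pid))
    return results


def results_frame(results: Sequence[KineticsResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in results],
            "slope": [r.slope for r in results],
            "intercept": [r.intercept for r in results],
            "n_points": [r.n_points for r in results],
            "t_max": [r.t_max for r in results],
            "et50": [np.nan if r.et50 is None else r.et50 for r in results],
            "status": [r.status for r in results],
        }
    )


def compare_groups(
    results: Sequence[KineticsResult],
    groups: Mapping[str, set[str]],
    min_group_size: int = 2,
) -> list[GroupComparison]:
    """Wilcoxon rank-sum of each group's ET50s against all recovered proteins.

    The reference is the full set of proteins with a defined ET50 (group
    members included). Holm step-down adjustment across the tested groups.
    Groups with fewer than ``min_group_size`` defined ET50s are skipped.
    """
    et50 = {r.protein_id: r.et50 for r in results if r.status == "ok"}
    reference = np.array(list(et50.values()), dtype=float)
    if reference.size == 0:
        raise ValueError("no protein with a defined et50")
    tested: list[tuple[str, np.ndarray]] = []
    for label, members in groups.items():
        vals = np.array(
            [et50[m] for m in members if m in et50], dtype=float
        )
        if vals.size < min_group_size:
            import warnings

            warnings.warn(f"group {label!r} skipped: fewer than "
                          f"{min_group_size} members with defined et50")
            continue
        tested.append((label, vals))
    if not tested:
        return []
    stats_p = [
        stats.mannwhitneyu(vals, reference, alternative="two-sided")
        for _, vals in tested
    ]
    p_adj = adjust_pvalues([float(sp.pvalue) for sp in stats_p], method="holm")
    return [
        GroupComparison(
            group_label=label,
            n_group=int(vals.size),
            n_reference=int(reference.size),
            statistic=float(sp.statistic),
            p_raw=float(sp.pvalue),
            p_adjusted=float(pa),
            mean_et50=float(vals.mean()),
            sd_et50=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        )
        for (label, vals), sp, pa in zip(tested, stats_p, p_adj)
    ]
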
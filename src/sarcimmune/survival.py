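"""Kaplan-Meier estimation, log-rank testing and supervised optimal binning.

Everything here is implemented from first principles on top of numpy; the
only scipy dependency is the chi-square upper tail.  The estimator follows
the standard product-limit construction

    S(t) = prod_{t_i <= t} (1 - d_i / n_i)

with the usual convention that subjects censored at an event time are still
at risk at that time (events precede censorings on ties).

The supervised optimal-binning search dichotomizes a numeric covariate by
trying every value observed in the cohort as a candidate threshold
(low = value <= t, high = value > t), evaluating the two-group log-rank
p-value for each, and keeping the admissible split (both groups at least
``min_group`` patients) with the smallest p-value.  No multiple-testing
correction is applied by default; an optional Benjamini-Hochberg adjustment
of the threshold landscape is available for exploratory use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "LogrankResult",
    "BinningResult",
    "NoAdmissibleSplitError",
    "km_estimate",
    "logrank_test",
    "optimal_binning",
    "bivariate_stratify",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """One right-censored progression-free survival observation.

    ``time`` is PFS in days (> 0); ``event`` is 1 when progression/death was
    observed and 0 when the patient was censored.
    """

    patient_id: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValueError(f"survival time must be > 0, got {self.time!r} "
                             f"for patient {self.patient_id!r}")
        if self.event not in (0, 1):
            raise ValueError(f"event indicator must be 0 or 1, got {self.event!r} "
                             f"for patient {self.patient_id!r}")


@dataclass
class KMCurve:
    """Product-limit survival curve over the distinct event times."""

    event_times: np.ndarray      # distinct times with >= 1 event, ascending
    survival: np.ndarray         # S(t) immediately after each event time
    at_risk: np.ndarray          # n_i at each event time
    n_events: np.ndarray         # d_i at each event time
    median: float | None         # smallest t with S(t) <= 0.5, None if unreached

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


@dataclass
class LogrankResult:
    statistic: float
    df: int
    p: float


@dataclass
class BinningResult:
    """Outcome of the supervised optimal-binning threshold search."""

    threshold: float
    chosen_p: float
    p_landscape: list[tuple[float, float, int, int]] = field(repr=False)
    groups: dict[str, str] = field(repr=False, default_factory=dict)
    adjusted_p: float | None = None


class NoAdmissibleSplitError(ValueError):
    """No threshold yields two groups of the required minimum size."""


def _as_arrays(records: Sequence[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray([r.time for r in records], dtype=float)
    events = np.asarray([r.event for r in records], dtype=int)
    return times, events


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier product-limit estimate of the survival function.

    The median is the smallest observed event time ``t`` with ``S(t) <= 0.5``;
    when the curve never drops to 0.5 (heavy censoring or small risk sets) the
    median is undefined and reported as ``None``.
    """
    if len(records) == 0:
        raise ValueError("km_estimate requires at least one record")
    times, events = _as_arrays(records)

    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    event_times = np.unique(times[events == 1])

    n = len(times)
    # subjects with time >= t are at risk at t (ties: censorings count at risk)
    at_risk = n - np.searchsorted(times, event_times, side="left")
    d = np.array([int(np.sum((times == t) & (events == 1))) for t in event_times])

    with np.errstate(divide="ignore", invalid="ignore"):
        surv = np.cumprod(1.0 - d / at_risk)

    below = np.nonzero(surv <= 0.5)[0]
    median = float(event_times[below[0]]) if below.size else None
    return KMCurve(event_times=event_times, survival=surv,
                   at_risk=at_risk, n_events=d, median=median)


def logrank_test(groups: Sequence[Sequence[SurvivalRecord]]) -> LogrankResult:
    """k-sample log-rank test.

    Computes the observed-minus-expected event counts per group over the
    pooled distinct event times and the hypergeometric variance-covariance
    matrix; the statistic is the quadratic form over the first k-1 groups and
    is chi-square with k-1 degrees of freedom under the null.  For k = 2 this
    reduces to the ordinary two-group log-rank test.
    """
    groups = [g for g in groups if len(g) > 0]
    k = len(groups)
    if k < 2:
        raise ValueError("logrank_test requires at least two non-empty groups")

    times_g = []
    events_g = []
    for g in groups:
        t, e = _as_arrays(g)
        order = np.argsort(t, kind="stable")
        times_g.append(t[order])
        events_g.append(e[order])

    pooled_t = np.concatenate(times_g)
    pooled_e = np.concatenate(events_g)
    event_times = np.unique(pooled_t[pooled_e == 1])
    m = len(event_times)
    if m == 0:
        return LogrankResult(statistic=0.0, df=k - 1, p=1.0)

    n_ij = np.empty((k, m))
    d_ij = np.empty((k, m))
    for i in range(k):
        t, e = times_g[i], events_g[i]
        n_ij[i] = len(t) - np.searchsorted(t, event_times, side="left")
        et = t[e == 1]
        d_ij[i] = (np.searchsorted(et, event_times, side="right")
                   - np.searchsorted(et, event_times, side="left"))

    n_j = n_ij.sum(axis=0)
    d_j = d_ij.sum(axis=0)

    O = d_ij.sum(axis=1)
    E = (d_j * n_ij / n_j).sum(axis=1)

    # hypergeometric variance of d_ij given margins, summed over event times
    with np.errstate(divide="ignore", invalid="ignore"):
        c_j = np.where(n_j > 1, d_j * (n_j - d_j) / (n_j - 1), 0.0)
    p_ij = n_ij / n_j
    V = np.zeros((k, k))
    for j in range(m):
        pj = p_ij[:, j]
        V += c_j[j] * (np.diag(pj) - np.outer(pj, pj))

    z = (O - E)[: k - 1]
    Vsub = V[: k - 1, : k - 1]
    stat = float(z @ np.linalg.pinv(Vsub) @ z)
    stat = max(stat, 0.0)
    df = k - 1
    p = float(_sps.chi2.sf(stat, df))
    return LogrankResult(statistic=stat, df=df, p=p)


def optimal_binning(
    covariate: Mapping[str, float],
    records: Sequence[SurvivalRecord],
    min_group: int = 10,
    adjust: bool = False,
) -> BinningResult:
    """Supervised optimal-binning threshold search for a numeric covariate.

    Only the values that actually occur in the cohort can change the group
    composition, so exactly those are evaluated as thresholds.  Splits are
    low = {value <= t} vs high = {value > t}; only splits with both groups of
    size >= ``min_group`` are admissible.  The returned threshold minimizes
    the two-group log-rank p-value over admissible splits, ties broken by the
    smallest threshold.  ``p_landscape`` records (threshold, p, n_low, n_high)
    for every split with two non-empty groups, admissible or not.

    ``adjust=True`` additionally reports a Benjamini-Hochberg adjusted p-value
    for the chosen threshold across the admissible landscape.
    """
    missing = [r.patient_id for r in records if r.patient_id not in covariate]
    if missing:
        raise ValueError(f"covariate missing for patients: {missing}")
    if len(records) == 0:
        raise ValueError("optimal_binning requires records")

    values = np.asarray([covariate[r.patient_id] for r in records], dtype=float)
    thresholds = np.unique(values)

    landscape: list[tuple[float, float, int, int]] = []
    admissible: list[tuple[float, float]] = []
    best: tuple[float, float] | None = None
    for t in thresholds:
        low_mask = values <= t
        n_low = int(low_mask.sum())
        n_high = len(records) - n_low
        if n_low == 0 or n_high == 0:
            continue
        low = [r for r, m in zip(records, low_mask) if m]
        high = [r for r, m in zip(records, low_mask) if not m]
        p = logrank_test([low, high]).p
        landscape.append((float(t), p, n_low, n_high))
        if n_low >= min_group and n_high >= min_group:
            admissible.append((float(t), p))
            if best is None or p < best[1]:
                best = (float(t), p)

    if best is None:
        raise NoAdmissibleSplitError(
            f"no threshold produces two groups of at least {min_group} patients "
            f"(n={len(records)}, {len(thresholds)} distinct covariate values)")

    threshold, chosen_p = best
    groups = {r.patient_id: ("low" if covariate[r.patient_id] <= threshold else "high")
              for r in records}

    adjusted = None
    if adjust:
        ps = np.asarray([p for _, p in admissible])
        order = np.argsort(ps)
        ranked = np.empty_like(ps)
        nadm = len(ps)
        bh = ps[order] * nadm / (np.arange(nadm) + 1)
        ranked[order] = np.minimum.accumulate(bh[::-1])[::-1]
        adjusted = float(ranked[[t for t, _ in admissible].index(threshold)])

    return BinningResult(threshold=threshold, chosen_p=chosen_p,
                         p_landscape=landscape, groups=groups,
                         adjusted_p=adjusted)


QUADRANTS = ("LL", "LH", "HL", "HH")


def bivariate_stratify(
    cov1: Mapping[str, float],
    cov2: Mapping[str, float],
    thr1: float,
    thr2: float,
    records: Sequence[SurvivalRecord],
) -> tuple[dict[str, list[SurvivalRecord]], LogrankResult, dict[str, float | None]]:
    """Four-group stratification by two dichotomized covariates.

    Each patient is labelled ``{L,H}{L,H}`` (first letter for ``cov1``:
    H iff value > thr1; second for ``cov2``).  The k-sample log-rank test is
    run over the non-empty quadrants and the per-quadrant KM medians are
    reported (``None`` when undefined or the quadrant is empty).
    """
    groups: dict[str, list[SurvivalRecord]] = {q: [] for q in QUADRANTS}
    for r in records:
        if r.patient_id not in cov1 or r.patient_id not in cov2:
            raise ValueError(f"covariates missing for patient {r.patient_id!r}")
        lab = (("H" if cov1[r.patient_id] > thr1 else "L")
               + ("H" if cov2[r.patient_id] > thr2 else "L"))
        groups[lab].append(r)

    nonempty = [g for g in groups.values() if g]
    if len(nonempty) < 2:
        raise ValueError("bivariate stratification needs >= 2 non-empty groups")
    result = logrank_test(nonempty)

    medians: dict[str, float | None] = {}
    for q in QUADRANTS:
        medians[q] = km_estimate(groups[q]).median if groups[q] else None
    return groups, result, medians


def plot_km(
    curves: Mapping[str, KMCurve],
    path: str,
    title: str = "",
    cap_days: float | None = None,
) -> None:
    """Write a step-plot of one or more KM curves to ``path``.

    ``cap_days`` truncates the x-axis for display only; statistics are always
    computed on uncapped times.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, c in curves.items():
        t = np.concatenate([[0.0], c.event_times])
        s = np.concatenate([[1.0], c.survival])
        ax.step(t, s, where="post", label=label)
    ax.set_xlabel("PFS (days)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    if cap_days is not None:
        ax.set_xlim(0, cap_days)
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
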
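"""Response-group comparisons and rank correlations.

Welch's unequal-variance t-test and Spearman's rank correlation are computed
from their closed-form definitions (scipy is used only for the reference
distributions' tail areas).  The response-group comparison pools, per
clinical response group, the top-ranked antigen-presentation scores of each
patient and contrasts the pooled distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "WelchResult",
    "welch_test",
    "spearman_correlation",
    "compare_response_groups",
    "pooled_response_scores",
]

RESPONSE_LABELS = ("R", "SD", "PD")


@dataclass
class WelchResult:
    t: float
    df: float
    p: float


def welch_test(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Welch's two-sample t-test with Welch-Satterthwaite degrees of freedom.

    t = (mean_x - mean_y) / sqrt(s2_x/n_x + s2_y/n_y), with

    df = (s2_x/n_x + s2_y/n_y)^2 /
         ((s2_x/n_x)^2/(n_x-1) + (s2_y/n_y)^2/(n_y-1))

    using unbiased sample variances; the p-value is two-sided.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("welch_test requires at least two values per sample")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        raise ValueError("welch_test undefined: both samples have zero variance")
    sx = vx / len(x)
    sy = vy / len(y)
    t = (x.mean() - y.mean()) / np.sqrt(sx + sy)
    df = (sx + sy) ** 2 / (sx ** 2 / (len(x) - 1) + sy ** 2 / (len(y) - 1))
    p = 2.0 * float(_sps.t.sf(abs(t), df))
    return WelchResult(t=float(t), df=float(df), p=min(p, 1.0))


def _average_ranks(v: np.ndarray) -> np.ndarray:
    """Midranks: ties receive the average of the ranks they span."""
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v), dtype=float)
    sv = v[order]
    i = 0
    while i < len(sv):
        j = i
        while j + 1 < len(sv) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    rho is the Pearson correlation of the midranks; the two-sided p-value uses
    the t approximation t = rho * sqrt((n-2)/(1-rho^2)) on n-2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("spearman_correlation requires paired vectors")
    n = len(x)
    if n < 3:
        raise ValueError("spearman_correlation requires at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("spearman correlation undefined for a constant vector")
    rx = _average_ranks(x)
    ry = _average_ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    rho = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * float(_sps.t.sf(abs(t), n - 2))
    return rho, min(p, 1.0)


def pooled_response_scores(
    candidates: pd.DataFrame,
    clinical: pd.DataFrame,
    top_k: int = 10,
    per_patient_mean: bool = False,
) -> dict[str, np.ndarray]:
    """Pool each patient's top-``top_k`` AP scores into its response group.

    ``candidates`` needs columns ``patient_id`` and ``ap_score``; ``clinical``
    needs ``patient_id`` and ``response``.  Patients with fewer than ``top_k``
    candidates contribute all they have.  Patients without a usable response
    label (missing / "NA") are excluded with a warning.  With
    ``per_patient_mean=True`` each patient contributes a single value (the
    mean of its top scores) instead of the individual scores.
    """
    labels = clinical.set_index("patient_id")["response"].astype(str).to_dict()
    unlabeled = [p for p, lab in labels.items() if lab not in RESPONSE_LABELS]
    if unlabeled:
        warnings.warn(f"excluding {len(unlabeled)} patient(s) without response label: "
                      f"{sorted(unlabeled)}")

    pooled: dict[str, list[float]] = {lab: [] for lab in RESPONSE_LABELS}
    for pid, sub in candidates.groupby("patient_id"):
        lab = labels.get(pid)
        if lab not in RESPONSE_LABELS:
            continue
        top = np.sort(sub["ap_score"].to_numpy(dtype=float))[::-1][:top_k]
        if len(top) == 0:
            continue
        if per_patient_mean:
            pooled[lab].append(float(top.mean()))
        else:
            pooled[lab].extend(top.tolist())
    return {lab: np.asarray(v) for lab, v in pooled.items()}


def compare_response_groups(
    candidates: pd.DataFrame,
    clinical: pd.DataFrame,
    top_k: int = 10,
    per_patient_mean: bool = False,
) -> pd.DataFrame:
    """Pairwise Welch comparisons of pooled top-AP-score distributions.

    Runs R vs PD, R vs SD, SD vs PD, and PD vs non-PD (SD and R pooled);
    comparisons with an empty side are skipped with a warning.  Returns a
    table with group sizes, means and the Welch statistic/df/p per contrast.
    """
    pooled = pooled_response_scores(candidates, clinical, top_k=top_k,
                                    per_patient_mean=per_patient_mean)
    non_pd = np.concatenate([pooled["SD"], pooled["R"]]) if (
        len(pooled["SD"]) or len(pooled["R"])) else np.asarray([])
    contrasts = [
        ("R", "PD", pooled["R"], pooled["PD"]),
        ("R", "SD", pooled["R"], pooled["SD"]),
        ("SD", "PD", pooled["SD"], pooled["PD"]),
        ("PD", "non-PD", pooled["PD"], non_pd),
    ]
    rows = []
    for name1, name2, a, b in contrasts:
        if len(a) < 2 or len(b) < 2:
            warnings.warn(f"skipping {name1} vs {name2}: a group is empty or "
                          f"has fewer than two pooled scores")
            continue
        res = welch_test(a, b)
        rows.append({
            "group1": name1, "group2": name2,
            "n1": len(a), "n2": len(b),
            "mean1": float(np.mean(a)), "mean2": float(np.mean(b)),
            "t": res.t, "df": res.df, "p": res.p,
        })
    return pd.DataFrame(rows, columns=["group1", "group2", "n1", "n2",
                                       "mean1", "mean2", "t", "df", "p"])
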
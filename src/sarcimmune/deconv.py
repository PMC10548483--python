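"""Immune cell-fraction deconvolution by constrained least squares.

Bulk expression is modelled as a nonnegative mixture of per-cell-type
signature profiles:

    minimize  || S f - m ||^2   subject to  f >= 0,  sum(f) <= 1

where S is the (genes x cell types) signature matrix, m the mixture vector
and f the cell fractions; the mass not explained by the characterized cell
types is reported as an "Other" (uncharacterized, mostly tumor) fraction
1 - sum(f).  The inequality-constrained problem is solved exactly as a
nonnegative least-squares problem with a slack variable and a heavily
weighted simplex row (active-set NNLS underneath), so noiseless mixtures
are recovered to machine precision.

Signature columns are rescaled to a common total before solving so that the
coefficients are comparable across cell types; per-cell mRNA content
differences are not modelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "SignatureMatrix",
    "CellFractions",
    "CELL_TYPES",
    "OTHER",
    "deconvolve",
    "t_cell_fraction",
]

#: the ten immune cell phenotypes resolved by the signature, quanTIseq-style
CELL_TYPES = (
    "B.cells",
    "Macrophages.M1",
    "Macrophages.M2",
    "Monocytes",
    "Neutrophils",
    "NK.cells",
    "T.cells.CD4",
    "T.cells.CD8",
    "Tregs",
    "Dendritic.cells",
)
OTHER = "Other"
CD8 = "T.cells.CD8"

_SIMPLEX_WEIGHT = 1e8


@dataclass
class SignatureMatrix:
    """Nonnegative (genes x cell types) expression profile matrix."""

    genes: list[str]
    cell_types: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.cell_types)):
            raise ValueError("signature dimensions inconsistent with labels")
        if np.any(self.values < 0):
            raise ValueError("signature profiles must be nonnegative")
        if np.any(self.values.sum(axis=0) == 0):
            raise ValueError("signature contains an all-zero cell-type column")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SignatureMatrix":
        return cls(genes=list(df.index), cell_types=list(df.columns),
                   values=df.to_numpy(dtype=float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.genes, name="gene"),
                            columns=self.cell_types)


@dataclass
class CellFractions:
    """Estimated fractions per cell type plus the uncharacterized remainder."""

    fractions: dict[str, float]
    other: float

    def __post_init__(self) -> None:
        total = sum(self.fractions.values()) + self.other
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"fractions must sum to 1, got {total}")
        for k, v in list(self.fractions.items()) + [(OTHER, self.other)]:
            if not -1e-12 <= v <= 1.0 + 1e-12:
                raise ValueError(f"fraction {k}={v} outside [0, 1]")

    def __getitem__(self, cell_type: str) -> float:
        if cell_type == OTHER:
            return self.other
        return self.fractions[cell_type]

    def as_dict(self) -> dict[str, float]:
        return {**self.fractions, OTHER: self.other}


def _normalize_columns(values: np.ndarray) -> np.ndarray:
    sums = values.sum(axis=0)
    target = sums.mean()
    return values * (target / sums)


def deconvolve(
    mixture: Mapping[str, float] | pd.Series,
    signature: SignatureMatrix,
    sum_to_one: bool = False,
    normalize: bool = True,
) -> CellFractions:
    """Estimate cell fractions of a bulk mixture against a signature matrix.

    Genes of the signature missing from the mixture are imputed as 0 with a
    warning.  By default the fractions satisfy f >= 0 and sum(f) <= 1 with
    the remainder reported as "Other"; ``sum_to_one=True`` forces the
    characterized fractions to fill the simplex exactly (no "Other" mass).
    A rank-deficient signature triggers a warning and the minimum-norm NNLS
    solution is returned.
    """
    if isinstance(mixture, pd.Series):
        mixture = mixture.to_dict()
    missing = [g for g in signature.genes if g not in mixture]
    if missing:
        warnings.warn(f"{len(missing)} signature gene(s) missing from mixture, "
                      "imputed as 0")
    m = np.asarray([float(mixture.get(g, 0.0)) for g in signature.genes])

    S = signature.values
    if normalize:
        S = _normalize_columns(S)
    if np.linalg.matrix_rank(S) < S.shape[1]:
        warnings.warn("signature matrix is rank-deficient; solution is not unique")

    k = S.shape[1]
    scale = max(np.abs(S).max(), np.abs(m).max(), 1.0)
    w = _SIMPLEX_WEIGHT * scale
    if sum_to_one:
        # equality sum(f) = 1 via a heavily weighted row
        A = np.vstack([S, w * np.ones((1, k))])
        b = np.concatenate([m, [w]])
        f, _ = nnls(A, b)
    else:
        # slack variable s >= 0 with sum(f) + s = 1  <=>  sum(f) <= 1
        A = np.vstack([np.hstack([S, np.zeros((S.shape[0], 1))]),
                       w * np.ones((1, k + 1))])
        b = np.concatenate([m, [w]])
        sol, _ = nnls(A, b)
        f = sol[:k]

    f = np.clip(f, 0.0, 1.0)
    total = float(f.sum())
    if total > 1.0:
        f = f / total
        total = 1.0
    other = 0.0 if sum_to_one else max(0.0, 1.0 - total)
    if sum_to_one and total < 1.0:   # numerically shy of the simplex
        f = f / total if total > 0 else f
        other = 0.0
    return CellFractions(fractions={c: float(v) for c, v in zip(signature.cell_types, f)},
                         other=float(other))


def t_cell_fraction(
    fractions: CellFractions | None = None,
    source: str = "deconvolution",
    external_estimate: float | None = None,
    cell_type: str = CD8,
) -> float:
    """CD8+ T-cell fraction from deconvolution, or an external estimate.

    ``source="deconvolution"`` reads the CD8 fraction from ``fractions``;
    ``source="external_estimate"`` passes through an externally measured
    value (e.g. a V(D)J-recombination based estimate) and errors if none was
    supplied.
    """
    if source == "deconvolution":
        if fractions is None:
            raise ValueError("deconvolution source requires cell fractions")
        return fractions[cell_type]
    if source == "external_estimate":
        if external_estimate is None:
            raise ValueError("external_estimate source selected but no estimate supplied")
        return float(external_estimate)
    raise ValueError(f"unknown t-cell fraction source {source!r}")
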
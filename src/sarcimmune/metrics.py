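"""Per-patient scalar immunogenomic covariates: TMB, NAL, neoantigen quality.

TMB follows the harmonized definition: non-synonymous somatic SNVs/indels
with DNA VAF >= 0.05, per megabase of coding sequence; fusions, non-coding
and synonymous events never enter the numerator.  NAL counts candidates
with antigen-presentation score strictly above 0.5; neoantigen quality is
the mean AP score of the top ten candidates ranked by score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .neoantigens import NeoantigenCandidate
from .variants import NONSYNONYMOUS, SomaticVariant

__all__ = [
    "PatientProfile",
    "TMB_MIN_VAF",
    "NAL_THRESHOLD",
    "compute_tmb",
    "compute_nal",
    "neoantigen_quality",
    "per_allele_nal",
    "multi_allele_binder_count",
    "profile_table",
]

TMB_MIN_VAF = 0.05      # "at least 5%" -> inclusive
NAL_THRESHOLD = 0.5     # "higher than 0.5" -> strict
QUALITY_TOP_K = 10


@dataclass
class PatientProfile:
    """The scalar covariates a patient contributes to the survival analysis."""

    patient_id: str
    subtype: str = ""
    tmb: float = 0.0
    nal: int = 0
    neoantigen_quality: float | None = 0.0
    per_allele_nal: dict[str, int] = field(default_factory=dict)
    cell_fractions: dict[str, float] = field(default_factory=dict)
    t_cell_fraction: float = 0.0
    expression_covariates: dict[str, float] = field(default_factory=dict)


def compute_tmb(variants: Sequence[SomaticVariant], coding_mb: float) -> float:
    """Tumor mutational burden in qualifying variants per coding megabase.

    Qualifying variants are non-synonymous SNVs/indels with DNA VAF >= 0.05.
    ``coding_mb`` (the exome footprint in Mb) has no silent default and must
    be positive.
    """
    if not coding_mb > 0:
        raise ValueError(f"coding_mb must be > 0, got {coding_mb}")
    n = sum(1 for v in variants
            if v.consequence in NONSYNONYMOUS and v.vaf_dna >= TMB_MIN_VAF)
    return n / coding_mb


def compute_nal(
    candidates: Sequence[NeoantigenCandidate] | Sequence[float],
    threshold: float = NAL_THRESHOLD,
    unique_peptides: bool = False,
) -> int:
    """Neoantigen load: candidates with AP score strictly above ``threshold``.

    By default every (peptide x allele) candidate counts; with
    ``unique_peptides=True`` each distinct peptide sequence counts at most
    once (using its best score).
    """
    scores = _scores_with_keys(candidates)
    if unique_peptides:
        best: dict[str, float] = {}
        for key, s in scores:
            best[key] = max(best.get(key, 0.0), s)
        return sum(1 for s in best.values() if s > threshold)
    return sum(1 for _, s in scores if s > threshold)


def _scores_with_keys(
    candidates: Sequence[NeoantigenCandidate] | Sequence[float],
) -> list[tuple[str, float]]:
    out = []
    for i, c in enumerate(candidates):
        if isinstance(c, NeoantigenCandidate):
            out.append((c.peptide.sequence, c.ap_score))
        else:
            out.append((str(i), float(c)))
    return out


def neoantigen_quality(
    candidates: Sequence[NeoantigenCandidate] | Sequence[float],
    top_k: int = QUALITY_TOP_K,
    strict_top_k: bool = False,
) -> float | None:
    """Mean AP score of the top ``top_k`` candidates ranked by score.

    Patients with fewer than ``top_k`` candidates contribute the mean over
    what they have (0.0 when they have none); with ``strict_top_k=True`` such
    patients instead get ``None`` (missing).  The result is invariant to
    input order; equal scores make tie order irrelevant to the mean.
    """
    scores = sorted((s for _, s in _scores_with_keys(candidates)), reverse=True)
    if len(scores) < top_k and strict_top_k:
        return None
    if not scores:
        return 0.0
    top = scores[:top_k]
    return float(np.mean(top))


def per_allele_nal(
    candidates: Sequence[NeoantigenCandidate],
    threshold: float = NAL_THRESHOLD,
) -> dict[str, int]:
    """NAL restricted to each HLA allele.

    Because candidates are allele-resolved (one per peptide x allele), the
    per-allele counts sum exactly to the overall NAL of the candidate list.
    """
    out: dict[str, int] = {}
    for c in candidates:
        out.setdefault(c.hla_allele, 0)
        if c.ap_score > threshold:
            out[c.hla_allele] += 1
    return out


def multi_allele_binder_count(
    candidates: Sequence[NeoantigenCandidate],
    threshold: float = NAL_THRESHOLD,
) -> int:
    """Peptides scoring above ``threshold`` on more than one HLA allele."""
    alleles_by_pep: dict[str, set[str]] = {}
    for c in candidates:
        if c.ap_score > threshold:
            alleles_by_pep.setdefault(c.peptide.sequence, set()).add(c.hla_allele)
    return sum(1 for alleles in alleles_by_pep.values() if len(alleles) > 1)


def profile_table(profiles: Sequence[PatientProfile]) -> pd.DataFrame:
    """One row per patient with every scalar covariate, ready for survival use."""
    rows = []
    for p in profiles:
        row = {
            "patient_id": p.patient_id,
            "subtype": p.subtype,
            "tmb": p.tmb,
            "nal": p.nal,
            "neoantigen_quality": p.neoantigen_quality,
            "t_cell_fraction": p.t_cell_fraction,
        }
        row.update({f"frac_{k}": v for k, v in p.cell_fractions.items()})
        row.update(p.expression_covariates)
        rows.append(row)
    return pd.DataFrame(rows)
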
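"""Somatic variant and fusion records plus the consensus/quality/expression filters.

The filters model the screening stage of an ensemble somatic-calling
workflow: a variant survives only if it was reported by at least two of the
six callers, has a minimum read depth of 10 in both tumor and normal, and
has more than three tumor reads supporting the alternate allele.  Expressed
variants are those whose harboring transcripts have summed TPM above a
(configurable, default 0) threshold.  Low-confidence fusion calls are
discarded.  Every filter returns a subset of its input, preserves order and
never mutates a record.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

__all__ = [
    "SomaticVariant",
    "FusionEvent",
    "CONSEQUENCES",
    "NONSYNONYMOUS",
    "consensus_quality_filter",
    "expression_filter",
    "nonsynonymous_subset",
    "fusion_confidence_filter",
]

CONSEQUENCES = ("synonymous", "missense", "frameshift", "inframe_indel", "noncoding")
#: consequence classes that alter the protein sequence
NONSYNONYMOUS = frozenset({"missense", "frameshift", "inframe_indel"})

MIN_CALLERS = 2
MIN_DEPTH = 10
MIN_ALT_READS_EXCLUSIVE = 3  # "more than three reads" -> alt_reads > 3


@dataclass(frozen=True)
class SomaticVariant:
    """One somatic SNV or small indel with caller support and depth metadata.

    ``vaf_dna`` / ``vaf_rna`` are alternate-allele fractions in [0, 1] from
    the DNA and RNA data respectively.  ``phase_set`` groups variants known
    to co-occur on one haplotype (empty string = unphased).  The optional
    protein annotation fields (``protein_id``, ``protein_pos``, ``aa_ref``,
    ``aa_alt``, ``fs_tail``) carry the pre-computed consequence at protein
    level, standing in for an external effect annotator.
    """

    id: str
    chrom: str
    position: int                 # 1-based
    ref: str
    alt: str
    n_callers: int
    depth_tumor: int
    depth_normal: int
    alt_reads_tumor: int
    vaf_dna: float
    vaf_rna: float
    consequence: str
    phase_set: str = ""
    transcript_ids: tuple[str, ...] = ()
    protein_id: str = ""
    protein_pos: int = 0          # 1-based residue index; 0 = unannotated
    aa_ref: str = ""
    aa_alt: str = ""
    fs_tail: str = ""             # novel translation after a frameshift, to stop

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"variant {self.id!r}: unknown consequence "
                             f"{self.consequence!r}")
        if not 0 <= self.n_callers <= 6:
            raise ValueError(f"variant {self.id!r}: n_callers must be in [0, 6]")
        if self.alt_reads_tumor > self.depth_tumor:
            raise ValueError(f"variant {self.id!r}: alt_reads_tumor exceeds depth_tumor")
        for name in ("vaf_dna", "vaf_rna"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"variant {self.id!r}: {name} must be in [0, 1]")


@dataclass(frozen=True)
class FusionEvent:
    """A gene fusion with translated junction context and a caller confidence."""

    id: str
    gene5: str
    gene3: str
    junction_seq5: str            # peptide context ending at the junction
    junction_seq3: str            # in-frame: downstream context; out-of-frame: novel tail
    frame: str                    # "in_frame" | "out_of_frame"
    confidence: str               # "low" | "medium" | "high"

    def __post_init__(self) -> None:
        if self.frame not in ("in_frame", "out_of_frame"):
            raise ValueError(f"fusion {self.id!r}: bad frame {self.frame!r}")
        if self.confidence not in ("low", "medium", "high"):
            raise ValueError(f"fusion {self.id!r}: bad confidence {self.confidence!r}")


def consensus_quality_filter(variants: Sequence[SomaticVariant]) -> list[SomaticVariant]:
    """Keep variants passing the ensemble-consensus and read-quality gates.

    A variant is kept iff n_callers >= 2, tumor and normal depth >= 10, and
    strictly more than three tumor reads support the alternate allele.
    """
    return [v for v in variants
            if v.n_callers >= MIN_CALLERS
            and v.depth_tumor >= MIN_DEPTH
            and v.depth_normal >= MIN_DEPTH
            and v.alt_reads_tumor > MIN_ALT_READS_EXCLUSIVE]


def expression_filter(
    variants: Sequence[SomaticVariant],
    tpm: Mapping[str, float],
    min_tpm: float = 0.0,
) -> list[SomaticVariant]:
    """Keep variants whose harboring transcripts are expressed.

    The summed TPM over the variant's transcripts must be strictly greater
    than ``min_tpm`` (default 0, i.e. any expression).  Unknown transcript
    ids count as TPM 0.
    """
    kept = []
    for v in variants:
        total = sum(tpm.get(t, 0.0) for t in v.transcript_ids)
        if total > min_tpm:
            kept.append(v)
    return kept


def nonsynonymous_subset(variants: Sequence[SomaticVariant]) -> list[SomaticVariant]:
    """Keep only protein-altering variants (missense, frameshift, inframe indel)."""
    return [v for v in variants if v.consequence in NONSYNONYMOUS]


def fusion_confidence_filter(fusions: Sequence[FusionEvent]) -> list[FusionEvent]:
    """Discard low-confidence fusion calls; keep medium and high."""
    return [f for f in fusions if f.confidence in ("medium", "high")]
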
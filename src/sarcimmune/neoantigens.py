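"""Mutant-peptide enumeration and HLA-restricted candidate scoring.

Given wild-type protein sequences and protein-level variant annotations,
this module reconstructs mutant proteins (jointly applying variants that
share a phase set, i.e. are known to sit on the same haplotype), enumerates
every 9- and 10-mer window that covers an altered residue, removes peptides
that also occur in the normal proteome, and scores the survivors per
HLA-A/-B allele through a pluggable scorer.  Candidate abundance is the
summed TPM of the coding isoforms scaled by the RNA-level variant allele
frequency.

Scoring is deliberately decoupled from any particular predictor: anything
with a ``score(peptide, allele) -> float in [0, 1]`` method satisfies the
contract.  The bundled :class:`SurrogateScorer` derives a deterministic
Beta-distributed score from a hash of (peptide, allele) so that whole
pipelines are reproducible without an external model.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Protocol, Sequence, runtime_checkable

from scipy.special import betaincinv as _betaincinv

from .variants import FusionEvent, NONSYNONYMOUS, SomaticVariant

__all__ = [
    "MutantPeptide",
    "NeoantigenCandidate",
    "ScorerContract",
    "SurrogateScorer",
    "ConstantScorer",
    "ScorerContractError",
    "PhasingError",
    "apply_phasing",
    "enumerate_windows",
    "uniqueness_filter",
    "build_reference_kmers",
    "fusion_junction_peptides",
    "score_candidates",
    "peptide_abundance",
    "dedupe_peptides",
]

PEPTIDE_LENGTHS = (9, 10)
#: HLA class I loci with validated training data; HLA-C is excluded by default
SCORED_LOCI = ("A", "B")


@dataclass(frozen=True)
class MutantPeptide:
    """A 9/10-mer window of a mutant protein overlapping >= 1 altered residue.

    ``window_start`` is the 1-based residue index of the window within the
    mutant protein; ``altered_positions`` are 1-based indices *within the
    window* of the residues attributable to the variant(s).
    """

    sequence: str
    source_variant_ids: tuple[str, ...]
    protein_id: str
    window_start: int
    altered_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) not in PEPTIDE_LENGTHS:
            raise ValueError(f"peptide length must be 9 or 10, got {len(self.sequence)}")
        if not self.altered_positions:
            raise ValueError("a mutant peptide must cover at least one altered residue")


@dataclass(frozen=True)
class NeoantigenCandidate:
    """A mutant peptide paired with one HLA allele, scored and quantified."""

    peptide: MutantPeptide
    hla_allele: str
    ap_score: float
    abundance: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ap_score <= 1.0:
            raise ValueError(f"ap_score must be in [0, 1], got {self.ap_score}")
        if self.abundance < 0:
            raise ValueError("abundance must be >= 0")


@runtime_checkable
class ScorerContract(Protocol):
    """Anything that maps (peptide sequence, allele name) to a score in [0, 1]."""

    deterministic: bool

    def score(self, peptide: str, allele: str) -> float: ...


class ScorerContractError(ValueError):
    """A scorer returned a value outside [0, 1]."""


class PhasingError(ValueError):
    """Conflicting or unsupported edits within one phase set."""


class SurrogateScorer:
    """Deterministic stand-in scorer: a hash-seeded Beta draw per (peptide, allele).

    The same (peptide, allele) pair always yields the same score, so whole
    pipeline runs are bit-reproducible.  ``alpha``/``beta`` shape the score
    distribution over candidate space (defaults give mostly low scores with a
    tail above 0.5, as expected of presentation likelihoods).
    """

    deterministic = True

    def __init__(self, alpha: float = 1.5, beta: float = 3.5, salt: str = "") -> None:
        if alpha <= 0 or beta <= 0:
            raise ValueError("Beta shape parameters must be positive")
        self.alpha = alpha
        self.beta = beta
        self.salt = salt

    def score(self, peptide: str, allele: str) -> float:
        digest = hashlib.sha256(f"{self.salt}|{peptide}|{allele}".encode()).digest()
        u = int.from_bytes(digest[:8], "big") / 2.0 ** 64
        return float(_betaincinv(self.alpha, self.beta, u))


class ConstantScorer:
    """Returns one fixed score for every (peptide, allele); useful for tests."""

    deterministic = True

    def __init__(self, value: float) -> None:
        self.value = value

    def score(self, peptide: str, allele: str) -> float:
        return self.value


# ---------------------------------------------------------------------------
# phasing-aware mutant protein reconstruction


def _apply_edit_group(wild_type: str, group: Sequence[SomaticVariant]) -> str:
    """Apply one phase set of protein-level edits jointly to a haplotype."""
    for v in group:
        if v.consequence not in NONSYNONYMOUS:
            raise PhasingError(f"variant {v.id!r} ({v.consequence}) does not alter "
                               "the protein and cannot be applied")
        if v.protein_pos < 1:
            raise PhasingError(f"variant {v.id!r} lacks a protein position annotation")
        if v.protein_pos > len(wild_type):
            raise PhasingError(f"variant {v.id!r}: residue {v.protein_pos} beyond "
                               f"protein length {len(wild_type)}")

    frameshifts = [v for v in group if v.consequence == "frameshift"]
    if len(frameshifts) > 1:
        raise PhasingError("more than one frameshift in a single phase set")
    fs = frameshifts[0] if frameshifts else None
    if fs is not None:
        for v in group:
            if v is not fs and v.protein_pos >= fs.protein_pos:
                raise PhasingError(
                    f"variant {v.id!r} at residue {v.protein_pos} conflicts with "
                    f"frameshift {fs.id!r} at residue {fs.protein_pos}")

    # replacement edits: interval [pos, pos + len(ref) - 1] on the wild type
    spans = []
    for v in group:
        if v.consequence == "frameshift":
            continue
        ref = v.aa_ref or wild_type[v.protein_pos - 1]
        spans.append((v.protein_pos, v.protein_pos + max(len(ref), 1) - 1, v))
    spans.sort(key=lambda t: (t[0], t[1]))
    for (s1, e1, v1), (s2, e2, v2) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise PhasingError(f"variants {v1.id!r} and {v2.id!r} overlap within "
                               "one phase set")

    seq = wild_type
    for start, end, v in sorted(spans, key=lambda t: (t[0], t[1]), reverse=True):
        ref = v.aa_ref or wild_type[v.protein_pos - 1]
        if seq[start - 1:start - 1 + len(ref)] != ref:
            raise PhasingError(f"variant {v.id!r}: reference residues {ref!r} not "
                               f"found at position {start}")
        seq = seq[:start - 1] + v.aa_alt + seq[start - 1 + len(ref):]
    if fs is not None:
        # translation diverges from the frameshifted residue to the next stop
        seq = seq[:fs.protein_pos - 1] + fs.fs_tail
    return seq


def apply_phasing(
    wild_type: str,
    variants: Sequence[SomaticVariant],
) -> list[tuple[str, tuple[str, ...]]]:
    """Reconstruct mutant haplotype sequence(s) from protein-level variants.

    Variants sharing a non-empty ``phase_set`` are applied jointly to one
    haplotype; every unphased variant (empty phase set) yields its own mutant
    sequence carrying only that edit.  Returns ``(mutant_sequence,
    variant_ids)`` pairs.  Overlapping conflicting edits inside one phase set
    raise :class:`PhasingError`.
    """
    if not wild_type:
        raise ValueError("empty wild-type sequence")
    groups: dict[str, list[SomaticVariant]] = {}
    singletons: list[list[SomaticVariant]] = []
    for v in variants:
        if v.phase_set:
            groups.setdefault(v.phase_set, []).append(v)
        else:
            singletons.append([v])
    out = []
    for group in list(groups.values()) + singletons:
        seq = _apply_edit_group(wild_type, group)
        out.append((seq, tuple(v.id for v in group)))
    return out


# ---------------------------------------------------------------------------
# window enumeration


def _altered_positions(mutant: str, wild_type: str) -> list[int]:
    """1-based residue indices of the mutant attributable to the variant(s).

    Equal-length sequences: positions where the residues differ.  Different
    lengths (indel / frameshift): every residue from the first divergence to
    the end of the mutant, matching frameshift-tail semantics; downstream
    windows identical to normal peptides are removed later by the
    proteome-wide uniqueness filter.
    """
    if len(mutant) == len(wild_type):
        return [i + 1 for i, (a, b) in enumerate(zip(mutant, wild_type)) if a != b]
    n = min(len(mutant), len(wild_type))
    first = next((i for i in range(n) if mutant[i] != wild_type[i]), n)
    return list(range(first + 1, len(mutant) + 1))


def enumerate_windows(
    mutant_protein: str,
    wild_type_protein: str,
    lengths: Iterable[int] = PEPTIDE_LENGTHS,
    source_variant_ids: tuple[str, ...] = (),
    protein_id: str = "",
) -> list[MutantPeptide]:
    """Enumerate every window covering an altered residue.

    For each requested length, every window of the mutant protein that
    overlaps at least one altered residue and (for same-length edits) differs
    from the positionally aligned wild-type window is returned.  Windows are
    ordered by length then start position.
    """
    if not mutant_protein or not wild_type_protein:
        raise ValueError("sequences must be non-empty")
    altered = _altered_positions(mutant_protein, wild_type_protein)
    if not altered:
        return []
    same_length = len(mutant_protein) == len(wild_type_protein)
    altered_set = set(altered)

    out: list[MutantPeptide] = []
    for length in lengths:
        if length not in PEPTIDE_LENGTHS:
            raise ValueError(f"unsupported peptide length {length}")
        for start in range(1, len(mutant_protein) - length + 2):
            window_pos = range(start, start + length)
            hits = [p - start + 1 for p in window_pos if p in altered_set]
            if not hits:
                continue
            seq = mutant_protein[start - 1:start - 1 + length]
            if same_length and seq == wild_type_protein[start - 1:start - 1 + length]:
                continue
            out.append(MutantPeptide(sequence=seq,
                                     source_variant_ids=source_variant_ids,
                                     protein_id=protein_id,
                                     window_start=start,
                                     altered_positions=tuple(hits)))
    return out


def build_reference_kmers(
    proteins: Mapping[str, str] | Iterable[str],
    lengths: Iterable[int] = PEPTIDE_LENGTHS,
) -> set[str]:
    """All k-mers (k in ``lengths``) occurring in the wild-type proteome."""
    seqs = proteins.values() if isinstance(proteins, Mapping) else proteins
    kmers: set[str] = set()
    seqs = list(seqs)
    for length in lengths:
        for seq in seqs:
            for i in range(len(seq) - length + 1):
                kmers.add(seq[i:i + length])
    return kmers


def uniqueness_filter(
    peptides: Sequence[MutantPeptide],
    reference_kmers: set[str],
) -> list[MutantPeptide]:
    """Drop mutant peptides that also occur in the normal proteome."""
    return [p for p in peptides if p.sequence not in reference_kmers]


def dedupe_peptides(peptides: Sequence[MutantPeptide]) -> list[MutantPeptide]:
    """Collapse duplicate (sequence, protein) pairs; identical ligands are one candidate."""
    seen: set[tuple[str, str]] = set()
    out = []
    for p in peptides:
        key = (p.sequence, p.protein_id)
        if key not in seen:
            seen.add(key)
            out.append(p)
    return out


def fusion_junction_peptides(
    fusion: FusionEvent,
    lengths: Iterable[int] = PEPTIDE_LENGTHS,
) -> list[MutantPeptide]:
    """Enumerate windows spanning a fusion junction.

    In-frame fusions: every window containing at least one residue from each
    partner.  Out-of-frame fusions: ``junction_seq3`` is the novel
    translation until the next stop, and every window containing at least one
    novel residue is returned.  Short context simply yields fewer windows.
    """
    seq5, seq3 = fusion.junction_seq5, fusion.junction_seq3
    full = seq5 + seq3
    len5 = len(seq5)
    protein_id = f"{fusion.gene5}--{fusion.gene3}"

    out: list[MutantPeptide] = []
    for length in lengths:
        if length not in PEPTIDE_LENGTHS:
            raise ValueError(f"unsupported peptide length {length}")
        for start in range(1, len(full) - length + 2):
            end = start + length - 1
            if fusion.frame == "in_frame":
                # >= 1 residue from each side of the junction
                if not (start <= len5 and end >= len5 + 1):
                    continue
                novel_from = len5 + 1
            else:
                # >= 1 novel residue
                if not end >= len5 + 1:
                    continue
                novel_from = len5 + 1
            hits = tuple(p - start + 1 for p in range(max(start, novel_from), end + 1))
            out.append(MutantPeptide(sequence=full[start - 1:end],
                                     source_variant_ids=(fusion.id,),
                                     protein_id=protein_id,
                                     window_start=start,
                                     altered_positions=hits))
    return out


# ---------------------------------------------------------------------------
# scoring and abundance


def _locus(allele: str) -> str:
    """Locus letter of an HLA allele name ('HLA-A*02:01' or 'A*02:01' -> 'A')."""
    name = allele.removeprefix("HLA-")
    return name.split("*", 1)[0]


def score_candidates(
    peptides: Sequence[MutantPeptide],
    patient_hla: Sequence[str],
    scorer: ScorerContract,
    loci: Sequence[str] = SCORED_LOCI,
) -> list[NeoantigenCandidate]:
    """Score each peptide against each of the patient's HLA-A/-B alleles.

    Produces one candidate per (peptide x allele) pair for alleles at the
    scored loci (HLA-C is skipped by default, having no validated training
    data).  A scorer returning a value outside [0, 1] raises
    :class:`ScorerContractError`.
    """
    if not patient_hla:
        raise ValueError("patient allele list is empty")
    alleles = [a for a in dict.fromkeys(patient_hla) if _locus(a) in loci]
    out = []
    for pep in peptides:
        for allele in alleles:
            s = scorer.score(pep.sequence, allele)
            if not 0.0 <= s <= 1.0:
                raise ScorerContractError(
                    f"scorer returned {s!r} for ({pep.sequence}, {allele}); "
                    "scores must lie in [0, 1]")
            out.append(NeoantigenCandidate(peptide=pep, hla_allele=allele, ap_score=s))
    return out


def peptide_abundance(
    isoform_tpm: Mapping[str, float] | Iterable[float],
    vaf_rna: float,
) -> float:
    """Expression-adjusted peptide abundance.

    abundance = (sum of TPM over the isoforms coding for the peptide) x
    RNA-level VAF.
    """
    if not 0.0 <= vaf_rna <= 1.0:
        raise ValueError(f"vaf_rna must be in [0, 1], got {vaf_rna}")
    values = isoform_tpm.values() if isinstance(isoform_tpm, Mapping) else isoform_tpm
    return float(sum(values) * vaf_rna)
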
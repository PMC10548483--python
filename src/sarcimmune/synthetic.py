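"""Synthetic ICI-treated sarcoma cohorts with planted survival structure.

The generator emulates the statistical shape of a small multi-subtype
sarcoma trial cohort: 31 patients across seven histological subtypes (13
soft-tissue, 18 bone), heterogeneous per-patient SNV/indel/fusion counts,
Beta-mixture antigen-presentation scores per neoantigen candidate,
Dirichlet immune cell-fraction vectors, and right-censored exponential PFS
whose log-hazard is linear in standardized covariates and carries a
configurable T-cell x neoantigen-quality interaction.

The interaction covariate is the indicator that *both* the CD8+ T-cell
fraction and the neoantigen quality lie above their cohort medians: a
negative coefficient then plants a protective synergy confined to the
doubly-high stratum, rather than a symmetric z-score product that would
equally protect the doubly-low stratum.

Every random quantity flows from one :class:`numpy.random.Generator` seeded
from the config, so identical configs produce bit-identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as _io
from .deconv import CELL_TYPES, OTHER, SignatureMatrix

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "cohorts_equal",
    "make_signature",
    "SUBTYPE_COUNTS",
    "STS_SUBTYPES",
]

#: default cohort composition: 13 soft-tissue + 18 bone sarcomas, 7 subtypes
SUBTYPE_COUNTS = {"SS": 4, "LMS": 4, "DDLPS": 2, "UPS": 3,
                  "ES": 6, "OS": 9, "CS": 3}
STS_SUBTYPES = frozenset({"SS", "LMS", "DDLPS", "UPS"})

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"

HLA_A_POOL = ("HLA-A*01:01", "HLA-A*02:01", "HLA-A*03:01",
              "HLA-A*11:01", "HLA-A*24:02", "HLA-A*26:01")
HLA_B_POOL = ("HLA-B*07:02", "HLA-B*08:01", "HLA-B*15:01",
              "HLA-B*35:01", "HLA-B*40:01", "HLA-B*44:02")
HLA_C_POOL = ("HLA-C*04:01", "HLA-C*07:01", "HLA-C*07:02")

_HAZARD_KEYS = frozenset({"t_cell_fraction", "neoantigen_quality", "interaction"})

#: per-subtype (low, high) inclusive ranges for event counts per patient;
#: fusion-rich DDLPS and mutation-heavy OS/UPS mirror the qualitative
#: burden differences seen across sarcoma subtypes
DEFAULT_MUTATION_RANGES: dict[str, dict[str, tuple[int, int]]] = {
    "SS":    {"snv": (3, 25),  "indel": (0, 4), "fusion": (1, 5)},
    "LMS":   {"snv": (10, 60), "indel": (0, 6), "fusion": (0, 4)},
    "DDLPS": {"snv": (5, 40),  "indel": (0, 5), "fusion": (4, 15)},
    "UPS":   {"snv": (15, 80), "indel": (0, 8), "fusion": (0, 4)},
    "ES":    {"snv": (2, 15),  "indel": (0, 3), "fusion": (1, 3)},
    "OS":    {"snv": (15, 90), "indel": (0, 8), "fusion": (0, 6)},
    "CS":    {"snv": (2, 12),  "indel": (0, 3), "fusion": (0, 2)},
}

#: Beta-mixture for per-candidate AP scores: a low-scoring bulk plus a
#: minority high-quality component whose per-patient weight varies, so the
#: top-10 mean differs across patients
DEFAULT_AP_DISTRIBUTION = {
    "low_alpha": 1.2, "low_beta": 4.0,
    "high_alpha": 5.0, "high_beta": 1.5,
    "high_weight_alpha": 2.0, "high_weight_beta": 8.0,
}

#: Dirichlet concentration over the 10 immune phenotypes + "Other";
#: the uncharacterized component dominates, as in bulk tumor tissue
DEFAULT_CONCENTRATION = {**{c: 1.0 for c in CELL_TYPES}, OTHER: 8.0}

DEFAULT_HAZARD = {"t_cell_fraction": -0.6, "neoantigen_quality": 0.0,
                  "interaction": -1.0}

RESPONSE_PROPORTIONS = {"R": 3, "SD": 9, "PD": 18, "NA": 1}  # of 31


def _largest_remainder(weights: np.ndarray, n: int) -> np.ndarray:
    """Integer allocation of n items proportional to weights (deterministic)."""
    raw = weights * n
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort generator.

    ``hazard_coefficients`` are log-hazard weights on the standardized
    covariates (keys: ``t_cell_fraction``, ``neoantigen_quality``,
    ``interaction``); ``baseline_median_pfs`` fixes the exponential baseline
    via lambda0 = ln 2 / median.  ``censoring_rate`` is the probability a
    patient is administratively censored at a uniform fraction of its latent
    event time.
    """

    n_patients: int = 31
    subtype_weights: dict[str, float] = field(
        default_factory=lambda: {k: v / 31 for k, v in SUBTYPE_COUNTS.items()})
    mutation_rate_ranges: dict[str, dict[str, tuple[int, int]]] = field(
        default_factory=lambda: {s: {k: tuple(v) for k, v in d.items()}
                                 for s, d in DEFAULT_MUTATION_RANGES.items()})
    ap_score_distribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AP_DISTRIBUTION))
    cell_fraction_concentration: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONCENTRATION))
    hazard_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HAZARD))
    baseline_median_pfs: float = 90.0
    censoring_rate: float = 0.2
    mixture_noise_sd: float = 0.0     # relative gaussian noise on bulk mixtures
    n_proteins: int = 25              # size of the synthetic proteome
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        total = sum(self.subtype_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subtype weights must sum to 1, got {total}")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ValueError("censoring_rate must be in [0, 1]")
        if self.baseline_median_pfs <= 0:
            raise ValueError("baseline_median_pfs must be positive")
        unknown = set(self.hazard_coefficients) - _HAZARD_KEYS
        if unknown:
            raise ValueError(f"unknown hazard coefficient keys: {sorted(unknown)}")
        for s in self.subtype_weights:
            if s not in self.mutation_rate_ranges:
                raise ValueError(f"no mutation ranges for subtype {s!r}")
        for name, v in self.ap_score_distribution.items():
            if v <= 0:
                raise ValueError(f"ap_score_distribution[{name!r}] must be positive")
        for name, v in self.cell_fraction_concentration.items():
            if v <= 0:
                raise ValueError(f"concentration for {name!r} must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mutation_rate_ranges"] = {
            s: {k: list(v) for k, v in ranges.items()}
            for s, ranges in self.mutation_rate_ranges.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        if "mutation_rate_ranges" in d:
            d["mutation_rate_ranges"] = {
                s: {k: tuple(v) for k, v in ranges.items()}
                for s, ranges in d["mutation_rate_ranges"].items()}
        return cls(**d)


@dataclass
class SyntheticCohort:
    """In-memory synthetic cohort: every table a downstream stage reads."""

    clinical: pd.DataFrame
    variants: pd.DataFrame
    fusions: pd.DataFrame
    candidates: pd.DataFrame
    tpm: pd.DataFrame
    proteins: dict[str, str]
    hla: pd.DataFrame
    cell_fractions: pd.DataFrame
    mixtures: pd.DataFrame
    signature: SignatureMatrix
    truth: dict

    @property
    def patient_ids(self) -> list[str]:
        return list(self.clinical["patient_id"])


def make_signature(rng: np.random.Generator, n_genes: int = 50) -> SignatureMatrix:
    """Synthetic 50-gene x 10-cell-type signature with equal column totals.

    Each cell type gets a block of marker genes with high expression and a
    low background elsewhere; columns are rescaled to a common total so the
    constrained-least-squares coefficients are directly interpretable as
    fractions.
    """
    genes = [f"g{i + 1:03d}" for i in range(n_genes)]
    k = len(CELL_TYPES)
    values = rng.lognormal(mean=0.0, sigma=0.5, size=(n_genes, k))
    markers_per_type = n_genes // k
    for j in range(k):
        block = slice(j * markers_per_type, (j + 1) * markers_per_type)
        values[block, j] *= rng.lognormal(mean=3.0, sigma=0.3, size=markers_per_type)
    values *= 1e4 / values.sum(axis=0)
    return SignatureMatrix(genes=genes, cell_types=list(CELL_TYPES), values=values)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a full cohort (clinical, variants, candidates, TME, survival).

    Deterministic given ``config.seed``.  The planted linear predictor of
    each patient is recorded in ``truth`` together with the config, so the
    generating conditions round-trip with the data.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    # --- subtype composition: deterministic largest-remainder allocation
    subtypes_order = list(config.subtype_weights)
    weights = np.asarray([config.subtype_weights[s] for s in subtypes_order])
    counts = _largest_remainder(weights, n)
    subtype_of = np.repeat(subtypes_order, counts)
    patient_ids = [f"p{i + 1}" for i in range(n)]

    # --- shared synthetic proteome + transcripts
    proteins: dict[str, str] = {}
    tx_of_protein: dict[str, list[str]] = {}
    for i in range(config.n_proteins):
        name = f"PROT{i + 1:03d}"
        proteins[name] = _random_protein(rng, int(rng.integers(150, 401)))
        tx_of_protein[name] = [f"t_{name}_{j + 1}"
                               for j in range(int(rng.integers(1, 3)))]
    protein_names = list(proteins)
    all_transcripts = [tid for name in protein_names for tid in tx_of_protein[name]]

    # --- signature matrix for the deconvolution stage
    signature = make_signature(rng)

    hla_rows, cf_rows, var_rows, fus_rows, cand_rows, tpm_rows, mix_rows = \
        [], [], [], [], [], [], []
    quality = np.zeros(n)
    tcell = np.zeros(n)

    conc = np.asarray([config.cell_fraction_concentration[c] for c in CELL_TYPES]
                      + [config.cell_fraction_concentration[OTHER]])
    apd = config.ap_score_distribution

    for i, pid in enumerate(patient_ids):
        subtype = subtype_of[i]
        ranges = config.mutation_rate_ranges[subtype]

        # HLA genotype: two alleles per class-I locus
        alleles = (list(rng.choice(HLA_A_POOL, size=2, replace=False))
                   + list(rng.choice(HLA_B_POOL, size=2, replace=False))
                   + list(rng.choice(HLA_C_POOL, size=2, replace=False)))
        hla_rows += [{"patient_id": pid, "allele": a} for a in alleles]
        ab_alleles = alleles[:4]

        # immune cell fractions
        fracs = rng.dirichlet(conc)
        cf_rows.append({"patient_id": pid,
                        **{c: fracs[j] for j, c in enumerate(CELL_TYPES)},
                        OTHER: fracs[-1]})
        tcell[i] = fracs[CELL_TYPES.index("T.cells.CD8")]

        # bulk mixture consistent with the planted fractions
        mix = signature.values @ fracs[:-1]
        if config.mixture_noise_sd > 0:
            mix = np.clip(mix * (1 + rng.normal(0, config.mixture_noise_sd,
                                                size=mix.size)), 0, None)
        mix_rows += [{"patient_id": pid, "gene": g, "expression": mix[j]}
                     for j, g in enumerate(signature.genes)]

        # transcript expression (a minority of transcripts silent)
        expressed = rng.random(len(all_transcripts)) > 0.1
        tpm_vals = np.where(expressed, rng.lognormal(2.0, 1.0,
                                                     size=len(all_transcripts)), 0.0)
        tpm_rows += [{"patient_id": pid, "transcript_id": tid, "tpm": float(v)}
                     for tid, v in zip(all_transcripts, tpm_vals)]

        # somatic SNVs / indels
        n_snv = int(rng.integers(ranges["snv"][0], ranges["snv"][1] + 1))
        n_indel = int(rng.integers(ranges["indel"][0], ranges["indel"][1] + 1))
        patient_vars = []
        for j in range(n_snv + n_indel):
            is_indel = j >= n_snv
            prot = protein_names[int(rng.integers(0, len(protein_names)))]
            plen = len(proteins[prot])
            pos_aa = int(rng.integers(1, plen + 1))
            if is_indel:
                consequence = rng.choice(["frameshift", "inframe_indel", "noncoding"],
                                         p=[0.5, 0.4, 0.1])
            else:
                consequence = rng.choice(["missense", "synonymous", "noncoding"],
                                         p=[0.72, 0.18, 0.10])
            aa_ref = proteins[prot][pos_aa - 1]
            aa_alt, fs_tail = "", ""
            if consequence == "missense":
                aa_alt = rng.choice([a for a in AMINO_ACIDS if a != aa_ref])
            elif consequence == "inframe_indel":
                aa_alt = aa_ref + "".join(
                    rng.choice(list(AMINO_ACIDS),
                               size=int(rng.integers(1, 4))))
            elif consequence == "frameshift":
                fs_tail = "".join(rng.choice(list(AMINO_ACIDS),
                                             size=int(rng.integers(8, 26))))
            depth_t = max(int(rng.poisson(90)), 1)
            depth_n = max(int(rng.poisson(60)), 1)
            vaf = float(rng.beta(2.5, 6.0))
            alt_reads = int(rng.binomial(depth_t, vaf))
            ref_nt = rng.choice(list(NUCLEOTIDES))
            alt_nt = rng.choice([x for x in NUCLEOTIDES if x != ref_nt])
            if is_indel:
                ref_s, alt_s = ref_nt, ref_nt + alt_nt
            else:
                ref_s, alt_s = ref_nt, alt_nt
            patient_vars.append({
                "patient_id": pid, "variant_id": f"{pid}_v{j + 1}",
                "chrom": str(int(rng.integers(1, 23))),
                "pos": int(rng.integers(1, 10_000_000)),
                "ref": ref_s, "alt": alt_s,
                "n_callers": int(rng.choice(np.arange(1, 7),
                                            p=[.10, .18, .20, .20, .16, .16])),
                "depth_tumor": depth_t, "depth_normal": depth_n,
                "alt_reads_tumor": alt_reads,
                "vaf_dna": vaf,
                "vaf_rna": float(np.clip(vaf + rng.normal(0, 0.05), 0, 1)),
                "consequence": str(consequence), "phase_set": "",
                "transcript_ids": ",".join(tx_of_protein[prot]),
                "protein_id": prot if consequence != "noncoding" else "",
                "protein_pos": pos_aa if consequence != "noncoding" else 0,
                "aa_ref": aa_ref if consequence in ("missense", "inframe_indel") else "",
                "aa_alt": aa_alt, "fs_tail": fs_tail,
            })
        # phase a fraction of same-protein missense pairs
        by_prot: dict[str, list[dict]] = {}
        for v in patient_vars:
            if v["consequence"] == "missense":
                by_prot.setdefault(v["protein_id"], []).append(v)
        ps_counter = 0
        for prot, group in by_prot.items():
            if len(group) >= 2 and rng.random() < 0.3:
                a, b = group[0], group[1]
                if a["protein_pos"] != b["protein_pos"]:
                    ps_counter += 1
                    tag = f"{pid}_ps{ps_counter}"
                    a["phase_set"] = tag
                    b["phase_set"] = tag
        var_rows += patient_vars

        # gene fusions
        n_fus = int(rng.integers(ranges["fusion"][0], ranges["fusion"][1] + 1))
        n_fus_kept = 0
        for j in range(n_fus):
            confidence = str(rng.choice(["low", "medium", "high"], p=[.3, .4, .3]))
            frame = str(rng.choice(["in_frame", "out_of_frame"]))
            if confidence != "low":
                n_fus_kept += 1
            fus_rows.append({
                "patient_id": pid, "fusion_id": f"{pid}_f{j + 1}",
                "gene5": f"GENE{int(rng.integers(1, 200))}",
                "gene3": f"GENE{int(rng.integers(200, 400))}",
                "junction_seq5": _random_protein(rng, int(rng.integers(9, 16))),
                "junction_seq3": _random_protein(rng, int(rng.integers(9, 16))),
                "frame": frame, "confidence": confidence,
            })

        # neoantigen candidates with Beta-mixture AP scores
        n_nonsyn = sum(1 for v in patient_vars
                       if v["consequence"] in ("missense", "frameshift",
                                               "inframe_indel"))
        lam = 2.0 + 1.2 * n_nonsyn + 5.0 * n_fus_kept
        n_cand = int(rng.poisson(lam))
        w_high = float(rng.beta(apd["high_weight_alpha"], apd["high_weight_beta"]))
        if n_cand > 0:
            from_high = rng.random(n_cand) < w_high
            scores = np.where(
                from_high,
                rng.beta(apd["high_alpha"], apd["high_beta"], size=n_cand),
                rng.beta(apd["low_alpha"], apd["low_beta"], size=n_cand))
            lengths = rng.choice([9, 10], size=n_cand)
            cand_alleles = rng.choice(ab_alleles, size=n_cand)
            abund = rng.lognormal(1.5, 1.0, size=n_cand) * rng.random(n_cand)
            for j in range(n_cand):
                cand_rows.append({
                    "patient_id": pid,
                    "peptide": _random_protein(rng, int(lengths[j])),
                    "protein_id": protein_names[int(rng.integers(0, len(protein_names)))],
                    "allele": str(cand_alleles[j]),
                    "ap_score": float(scores[j]),
                    "abundance": float(abund[j]),
                    "source_variant_ids": "",
                })
            top = np.sort(scores)[::-1][:10]
            quality[i] = float(top.mean())
        else:
            quality[i] = 0.0

    # --- planted survival model
    def _z(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    z_t, z_q = _z(tcell), _z(quality)
    both_high = ((tcell > np.median(tcell))
                 & (quality > np.median(quality))).astype(float)
    beta = config.hazard_coefficients
    eta = (beta.get("t_cell_fraction", 0.0) * z_t
           + beta.get("neoantigen_quality", 0.0) * z_q
           + beta.get("interaction", 0.0) * both_high)
    lam0 = np.log(2.0) / config.baseline_median_pfs
    latent = rng.exponential(scale=1.0 / (lam0 * np.exp(eta)), size=n)
    censored = rng.random(n) < config.censoring_rate
    u = rng.random(n)
    times = np.where(censored, latent * u, latent)
    times = np.maximum(times, 1e-9)
    events = (~censored).astype(int)

    # --- response labels: planted association with neoantigen quality
    resp_w = np.asarray([RESPONSE_PROPORTIONS[k] for k in ("R", "SD", "PD", "NA")],
                        dtype=float)
    n_r, n_sd, n_pd, n_na = _largest_remainder(resp_w / resp_w.sum(), n)
    response = np.full(n, "PD", dtype=object)
    na_idx = rng.choice(n, size=n_na, replace=False) if n_na else np.asarray([], int)
    rest = np.setdiff1d(np.arange(n), na_idx)
    noisy = z_q[rest] + rng.normal(0, 1.2, size=len(rest))
    order = rest[np.argsort(-noisy, kind="stable")]
    response[order[:n_r]] = "R"
    response[order[n_r:n_r + n_sd]] = "SD"
    response[na_idx] = "NA"

    clinical = pd.DataFrame({
        "patient_id": patient_ids,
        "subtype": subtype_of,
        "pfs_days": times,
        "event": events,
        "response": response,
    })

    truth = {
        "config": config.to_dict(),
        "linear_predictor": {pid: float(e) for pid, e in zip(patient_ids, eta)},
        "t_cell_fraction": {pid: float(v) for pid, v in zip(patient_ids, tcell)},
        "neoantigen_quality": {pid: float(v) for pid, v in zip(patient_ids, quality)},
    }

    return SyntheticCohort(
        clinical=_io.apply_schema(clinical, _io.CLINICAL_COLUMNS),
        variants=_io.apply_schema(pd.DataFrame(var_rows), _io.VARIANT_COLUMNS),
        fusions=_io.apply_schema(pd.DataFrame(fus_rows), _io.FUSION_COLUMNS),
        candidates=_io.apply_schema(pd.DataFrame(cand_rows), _io.CANDIDATE_COLUMNS),
        tpm=_io.apply_schema(pd.DataFrame(tpm_rows), _io.TPM_COLUMNS),
        proteins=proteins,
        hla=_io.apply_schema(pd.DataFrame(hla_rows), _io.HLA_COLUMNS),
        cell_fractions=pd.DataFrame(cf_rows),
        mixtures=_io.apply_schema(pd.DataFrame(mix_rows), _io.MIXTURE_COLUMNS),
        signature=signature,
        truth=truth,
    )


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write every cohort table in the formats the pipeline stages read."""
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create cohort directory {directory}: {exc}") from exc

    paths = {
        "clinical": directory / "clinical.tsv",
        "variants": directory / "variants.tsv",
        "fusions": directory / "fusions.tsv",
        "candidates": directory / "candidates.tsv",
        "tpm": directory / "tpm.tsv",
        "proteins": directory / "proteins.fasta",
        "hla": directory / "hla.tsv",
        "cell_fractions": directory / "cell_fractions.tsv",
        "mixtures": directory / "mixtures.tsv",
        "signature": directory / "signature.tsv",
        "truth": directory / "truth.json",
    }
    _io.write_table(cohort.clinical, paths["clinical"])
    _io.write_table(cohort.variants, paths["variants"])
    _io.write_table(cohort.fusions, paths["fusions"])
    _io.write_table(cohort.candidates, paths["candidates"])
    _io.write_table(cohort.tpm, paths["tpm"])
    _io.write_fasta(cohort.proteins, paths["proteins"])
    _io.write_table(cohort.hla, paths["hla"])
    _io.write_table(cohort.cell_fractions, paths["cell_fractions"])
    _io.write_table(cohort.mixtures, paths["mixtures"])
    cohort.signature.to_frame().to_csv(paths["signature"], sep="\t")
    paths["truth"].write_text(json.dumps(cohort.truth, indent=1, sort_keys=True))

    vcf_dir = directory / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    for pid, sub in cohort.variants.groupby("patient_id"):
        _io.write_variants_vcf(sub, vcf_dir / f"{pid}.vcf")
    return paths


def read_cohort(directory: str | Path) -> SyntheticCohort:
    """Read a cohort written by :func:`write_cohort`; inverse on all fields."""
    directory = Path(directory)
    sig_df = pd.read_csv(directory / "signature.tsv", sep="\t", index_col=0,
                         float_precision="round_trip")
    truth = json.loads((directory / "truth.json").read_text())
    cf_df = pd.read_csv(directory / "cell_fractions.tsv", sep="\t",
                        float_precision="round_trip")
    return SyntheticCohort(
        clinical=_io.read_table(directory / "clinical.tsv", _io.CLINICAL_COLUMNS),
        variants=_io.read_table(directory / "variants.tsv", _io.VARIANT_COLUMNS),
        fusions=_io.read_table(directory / "fusions.tsv", _io.FUSION_COLUMNS),
        candidates=_io.read_table(directory / "candidates.tsv", _io.CANDIDATE_COLUMNS),
        tpm=_io.read_table(directory / "tpm.tsv", _io.TPM_COLUMNS),
        proteins=_io.read_fasta(directory / "proteins.fasta"),
        hla=_io.read_table(directory / "hla.tsv", _io.HLA_COLUMNS),
        cell_fractions=cf_df,
        mixtures=_io.read_table(directory / "mixtures.tsv", _io.MIXTURE_COLUMNS),
        signature=SignatureMatrix.from_frame(sig_df),
        truth=truth,
    )


def cohorts_equal(a: SyntheticCohort, b: SyntheticCohort) -> bool:
    """Field-by-field equality of two cohorts (exact on every value)."""
    frames = ["clinical", "variants", "fusions", "candidates", "tpm", "hla",
              "cell_fractions", "mixtures"]
    for name in frames:
        fa, fb = getattr(a, name), getattr(b, name)
        if not fa.reset_index(drop=True).equals(fb.reset_index(drop=True)):
            return False
    if a.proteins != b.proteins:
        return False
    if (a.signature.genes != b.signature.genes
            or a.signature.cell_types != b.signature.cell_types
            or not np.array_equal(a.signature.values, b.signature.values)):
        return False
    return a.truth == b.truth
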
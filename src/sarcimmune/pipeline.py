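"""End-to-end orchestration: simulate -> filter -> enumerate -> metrics ->
TME deconvolution -> survival -> response statistics.

A run is described by a flat :class:`RunConfig`; each enabled stage is a
pure function of its declared inputs and writes plain-text outputs under
``workdir/outputs``.  The run manifest records the package version, seed,
parameters, per-stage record counts and SHA-256 checksums of every input
and output table, so two runs of the same config are identical except for
the timestamp.  A stage failure aborts the run (downstream stages do not
execute); outputs of completed stages are left intact.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as _io
from . import __version__
from .deconv import CD8, SignatureMatrix, deconvolve
from .metrics import (compute_nal, compute_tmb, neoantigen_quality)
from .neoantigens import (SurrogateScorer, apply_phasing, build_reference_kmers,
                          dedupe_peptides, enumerate_windows,
                          fusion_junction_peptides, peptide_abundance,
                          score_candidates, uniqueness_filter)
from .stats import compare_response_groups, spearman_correlation
from .survival import (NoAdmissibleSplitError, SurvivalRecord, bivariate_stratify,
                       km_estimate, optimal_binning, plot_km)
from .synthetic import CohortConfig, generate_cohort, write_cohort
from .variants import (consensus_quality_filter, expression_filter,
                       fusion_confidence_filter, nonsynonymous_subset)

log = logging.getLogger("sarcimmune.pipeline")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

REQUIRED_INPUTS = ["clinical.tsv", "variants.tsv", "fusions.tsv", "candidates.tsv",
                   "tpm.tsv", "proteins.fasta", "hla.tsv", "cell_fractions.tsv",
                   "mixtures.tsv", "signature.tsv"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Flat configuration of one pipeline run.

    ``simulate=True`` generates a synthetic cohort into ``workdir/cohort``;
    otherwise ``input_dir`` must point at an existing cohort directory.
    Stage toggles skip individual stages; when the TME stage is disabled the
    survival analysis falls back to the externally supplied cell-fraction
    table.  ``candidate_source`` selects whether the per-patient metrics use
    the cohort's own candidate table ("simulated") or the candidates
    re-enumerated and surrogate-scored from the variants ("enumerated").
    """

    workdir: str = "run"
    simulate: bool = True
    input_dir: str | None = None
    seed: int = 0
    n_patients: int = 31
    cohort_overrides: dict = field(default_factory=dict)

    run_filter: bool = True
    run_neo: bool = True
    run_metrics: bool = True
    run_tme: bool = True
    run_survival: bool = True
    run_stats: bool = True

    min_tpm: float = 0.0
    coding_mb: float = 31.0
    min_group: int = 10
    scorer: str = "surrogate"
    candidate_source: str = "simulated"
    survival_covariates: tuple[str, ...] = ("t_cell_fraction", "neoantigen_quality",
                                            "tmb", "nal")
    bivariate_pairs: tuple[tuple[str, str], ...] = (
        ("t_cell_fraction", "neoantigen_quality"),
        ("t_cell_fraction", "tmb"),
    )

    def __post_init__(self) -> None:
        if self.candidate_source not in ("simulated", "enumerated"):
            raise ValueError(f"unknown candidate_source {self.candidate_source!r}")
        if self.scorer != "surrogate":
            raise ValueError(f"unknown scorer {self.scorer!r}")
        if self.coding_mb <= 0:
            raise ValueError("coding_mb must be positive")
        self.survival_covariates = tuple(self.survival_covariates)
        self.bivariate_pairs = tuple(tuple(p) for p in self.bivariate_pairs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _records_from_clinical(clinical: pd.DataFrame) -> list[SurvivalRecord]:
    return [SurvivalRecord(patient_id=r.patient_id, time=float(r.pfs_days),
                           event=int(r.event))
            for _, r in clinical.iterrows()]


def _stage_filter(cohort_dir: Path, out: Path, min_tpm: float,
                  counts: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    variants = _io.read_table(cohort_dir / "variants.tsv", _io.VARIANT_COLUMNS)
    fusions = _io.read_table(cohort_dir / "fusions.tsv", _io.FUSION_COLUMNS)
    tpm = _io.read_table(cohort_dir / "tpm.tsv", _io.TPM_COLUMNS)

    kept_var, kept_fus = [], []
    for pid, sub in variants.groupby("patient_id", sort=True):
        recs = _io.variants_frame_to_records(sub)
        tmap = tpm[tpm.patient_id == pid].set_index("transcript_id")["tpm"].to_dict()
        passed = expression_filter(consensus_quality_filter(recs), tmap, min_tpm)
        ids = {v.id for v in passed}
        kept_var.append(sub[sub.variant_id.isin(ids)])
    for pid, sub in fusions.groupby("patient_id", sort=True):
        fusions_kept = fusion_confidence_filter(_io.fusions_frame_to_records(sub))
        ids = {f.id for f in fusions_kept}
        kept_fus.append(sub[sub.fusion_id.isin(ids)])

    fvar = pd.concat(kept_var) if kept_var else variants.iloc[0:0]
    ffus = pd.concat(kept_fus) if kept_fus else fusions.iloc[0:0]
    fvar = fvar.reset_index(drop=True)
    ffus = ffus.reset_index(drop=True)
    counts["filter"] = {"variants_in": len(variants), "variants_out": len(fvar),
                        "fusions_in": len(fusions), "fusions_out": len(ffus)}
    log.info("filter: variants %d -> %d, fusions %d -> %d",
             len(variants), len(fvar), len(fusions), len(ffus))
    _io.write_table(fvar, out / "filtered_variants.tsv")
    _io.write_table(ffus, out / "filtered_fusions.tsv")
    return fvar, ffus


def _stage_neo(cohort_dir: Path, out: Path, fvar: pd.DataFrame, ffus: pd.DataFrame,
               counts: dict) -> pd.DataFrame:
    proteins = _io.read_fasta(cohort_dir / "proteins.fasta")
    tpm = _io.read_table(cohort_dir / "tpm.tsv", _io.TPM_COLUMNS)
    hla = _io.read_table(cohort_dir / "hla.tsv", _io.HLA_COLUMNS)
    ref_kmers = build_reference_kmers(proteins)
    scorer = SurrogateScorer()

    rows = []
    patient_ids = sorted(set(fvar.patient_id) | set(ffus.patient_id))
    for pid in patient_ids:
        alleles = list(hla[hla.patient_id == pid]["allele"])
        if not alleles:
            continue
        tmap = tpm[tpm.patient_id == pid].set_index("transcript_id")["tpm"].to_dict()
        sub = fvar[fvar.patient_id == pid]
        recs = [v for v in _io.variants_frame_to_records(sub)
                if v.protein_id and v.consequence != "synonymous"
                and v.consequence != "noncoding"]
        recs = nonsynonymous_subset(recs)
        peptides = []
        abundance_of: dict[tuple[str, str], float] = {}
        by_protein: dict[str, list] = {}
        for v in recs:
            by_protein.setdefault(v.protein_id, []).append(v)
        for prot_id, group in by_protein.items():
            wt = proteins[prot_id]
            for mutant, var_ids in apply_phasing(wt, group):
                wins = enumerate_windows(mutant, wt, source_variant_ids=var_ids,
                                         protein_id=prot_id)
                group_by_id = {v.id: v for v in group}
                tpm_sum = {vid: sum(tmap.get(t, 0.0)
                                    for t in group_by_id[vid].transcript_ids)
                           for vid in var_ids}
                vaf = float(np.mean([group_by_id[vid].vaf_rna for vid in var_ids]))
                ab = peptide_abundance([tpm_sum[var_ids[0]]], vaf)
                for w in wins:
                    abundance_of[(w.sequence, w.protein_id)] = ab
                peptides.extend(wins)
        for f in _io.fusions_frame_to_records(ffus[ffus.patient_id == pid]):
            wins = fusion_junction_peptides(f)
            for w in wins:
                abundance_of.setdefault((w.sequence, w.protein_id), 0.0)
            peptides.extend(wins)
        peptides = uniqueness_filter(dedupe_peptides(peptides), ref_kmers)
        for c in score_candidates(peptides, alleles, scorer):
            rows.append({
                "patient_id": pid,
                "peptide": c.peptide.sequence,
                "protein_id": c.peptide.protein_id,
                "allele": c.hla_allele,
                "ap_score": c.ap_score,
                "abundance": abundance_of.get(
                    (c.peptide.sequence, c.peptide.protein_id), 0.0),
                "source_variant_ids": ",".join(c.peptide.source_variant_ids),
            })
    cand = _io.apply_schema(pd.DataFrame(rows), _io.CANDIDATE_COLUMNS)
    counts["neo"] = {"candidates_out": len(cand)}
    log.info("neo: %d scored candidates", len(cand))
    _io.write_table(cand, out / "enumerated_candidates.tsv")
    return cand


def _stage_tme(cohort_dir: Path, out: Path, counts: dict) -> pd.DataFrame:
    mixtures = _io.read_table(cohort_dir / "mixtures.tsv", _io.MIXTURE_COLUMNS)
    sig = SignatureMatrix.from_frame(
        pd.read_csv(cohort_dir / "signature.tsv", sep="\t", index_col=0))
    rows = []
    for pid, sub in mixtures.groupby("patient_id", sort=True):
        mix = sub.set_index("gene")["expression"].to_dict()
        fr = deconvolve(mix, sig)
        rows.append({"patient_id": pid, **fr.as_dict()})
    est = pd.DataFrame(rows)
    counts["tme"] = {"patients": len(est)}
    _io.write_table(est, out / "cell_fraction_estimates.tsv")
    return est


def _stage_metrics(cohort_dir: Path, out: Path, fvar: pd.DataFrame,
                   candidates: pd.DataFrame, fractions: pd.DataFrame,
                   coding_mb: float, counts: dict) -> pd.DataFrame:
    clinical = _io.read_table(cohort_dir / "clinical.tsv", _io.CLINICAL_COLUMNS)
    rows = []
    frac_by_pid = fractions.set_index("patient_id")
    for _, crow in clinical.iterrows():
        pid = crow.patient_id
        recs = _io.variants_frame_to_records(fvar[fvar.patient_id == pid])
        sub = candidates[candidates.patient_id == pid]
        scores = sub["ap_score"].to_numpy(dtype=float)
        tcell = float(frac_by_pid.loc[pid, CD8]) if pid in frac_by_pid.index else 0.0
        rows.append({
            "patient_id": pid,
            "subtype": crow.subtype,
            "tmb": compute_tmb(recs, coding_mb),
            "nal": compute_nal(list(scores)),
            "neoantigen_quality": neoantigen_quality(list(scores)),
            "t_cell_fraction": tcell,
        })
    profiles = pd.DataFrame(rows)
    counts["metrics"] = {"patients": len(profiles)}
    _io.write_table(profiles, out / "profiles.tsv")
    return profiles


def _stage_survival(out: Path, clinical: pd.DataFrame, profiles: pd.DataFrame,
                    covariates: Sequence[str], pairs: Sequence[tuple[str, str]],
                    min_group: int, counts: dict) -> dict:
    records = _records_from_clinical(clinical)
    prof = profiles.set_index("patient_id")
    results: dict = {"univariate": {}, "bivariate": {}}
    thresholds: dict[str, float] = {}
    for cov in covariates:
        cmap = prof[cov].to_dict()
        try:
            res = optimal_binning(cmap, records, min_group=min_group)
        except NoAdmissibleSplitError as exc:
            log.warning("survival: %s skipped (%s)", cov, exc)
            results["univariate"][cov] = {"skipped": str(exc)}
            continue
        thresholds[cov] = res.threshold
        land = pd.DataFrame(res.p_landscape,
                            columns=["threshold", "p", "n_low", "n_high"])
        _io.write_table(land, out / f"landscape_{cov}.tsv")
        groups_df = pd.DataFrame(sorted(res.groups.items()),
                                 columns=["patient_id", "group"])
        _io.write_table(groups_df, out / f"groups_{cov}.tsv")
        low = [r for r in records if res.groups[r.patient_id] == "low"]
        high = [r for r in records if res.groups[r.patient_id] == "high"]
        curves = {"low": km_estimate(low), "high": km_estimate(high)}
        km_rows = [{"group": g, "time": t, "survival": s}
                   for g, c in curves.items()
                   for t, s in zip(c.event_times, c.survival)]
        _io.write_table(pd.DataFrame(km_rows), out / f"km_{cov}.tsv")
        plot_km(curves, str(out / f"km_{cov}.png"), title=cov, cap_days=500)
        results["univariate"][cov] = {
            "threshold": res.threshold, "p": res.chosen_p,
            "median_low": curves["low"].median, "median_high": curves["high"].median,
        }
    for cov1, cov2 in pairs:
        if cov1 not in thresholds or cov2 not in thresholds:
            results["bivariate"][f"{cov1}|{cov2}"] = {"skipped": "no threshold"}
            continue
        groups, lr, medians = bivariate_stratify(
            prof[cov1].to_dict(), prof[cov2].to_dict(),
            thresholds[cov1], thresholds[cov2], records)
        curves = {q: km_estimate(g) for q, g in groups.items() if g}
        plot_km(curves, str(out / f"km_{cov1}__{cov2}.png"),
                title=f"{cov1} x {cov2}", cap_days=500)
        results["bivariate"][f"{cov1}|{cov2}"] = {
            "statistic": lr.statistic, "df": lr.df, "p": lr.p,
            "medians": medians,
            "sizes": {q: len(g) for q, g in groups.items()},
        }
    (out / "survival_results.json").write_text(json.dumps(results, indent=1))
    counts["survival"] = {"covariates": len(covariates), "pairs": len(pairs)}
    return results


def _stage_stats(cohort_dir: Path, out: Path, candidates: pd.DataFrame,
                 profiles: pd.DataFrame, ffus: pd.DataFrame, counts: dict) -> dict:
    clinical = _io.read_table(cohort_dir / "clinical.tsv", _io.CLINICAL_COLUMNS)
    comp = compare_response_groups(candidates, clinical)
    _io.write_table(comp, out / "response_comparisons.tsv")

    fus_counts = ffus.groupby("patient_id").size()
    rows = []
    prof = profiles.set_index("patient_id")
    pairs = {
        "tmb_vs_nal": (prof["tmb"], prof["nal"]),
        "fusions_vs_nal": (
            pd.Series({p: float(fus_counts.get(p, 0)) for p in prof.index}),
            prof["nal"]),
    }
    for name, (x, y) in pairs.items():
        x, y = x.align(y, join="inner")
        try:
            rho, p = spearman_correlation(x.to_numpy(float), y.to_numpy(float))
            rows.append({"pair": name, "rho": rho, "p": p, "n": len(x)})
        except ValueError as exc:
            rows.append({"pair": name, "rho": np.nan, "p": np.nan, "n": len(x)})
            log.warning("stats: %s undefined (%s)", name, exc)
    corr = pd.DataFrame(rows, columns=["pair", "rho", "p", "n"])
    _io.write_table(corr, out / "correlations.tsv")
    counts["stats"] = {"comparisons": len(comp), "correlations": len(corr)}
    return {"comparisons": comp.to_dict("records"),
            "correlations": corr.to_dict("records")}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    workdir = Path(config.workdir)
    out = workdir / "outputs"

    # pre-flight validation before any stage runs
    if config.simulate:
        cohort_dir = workdir / "cohort"
    else:
        if config.input_dir is None:
            raise FileNotFoundError("input_dir must be set when simulate is off")
        cohort_dir = Path(config.input_dir)
        missing = [f for f in REQUIRED_INPUTS if not (cohort_dir / f).exists()]
        if missing:
            raise FileNotFoundError(
                f"input cohort at {cohort_dir} is missing: {missing}")

    workdir.mkdir(parents=True, exist_ok=True)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {}
    stage = "simulate"
    try:
        if config.simulate:
            cc = CohortConfig(n_patients=config.n_patients, seed=config.seed,
                              **config.cohort_overrides)
            cohort = generate_cohort(cc)
            write_cohort(cohort, cohort_dir)
            counts["simulate"] = {"patients": cc.n_patients,
                                  "variants": len(cohort.variants)}

        stage = "filter"
        if config.run_filter:
            fvar, ffus = _stage_filter(cohort_dir, out, config.min_tpm, counts)
        else:
            fvar = _io.read_table(cohort_dir / "variants.tsv", _io.VARIANT_COLUMNS)
            ffus = _io.read_table(cohort_dir / "fusions.tsv", _io.FUSION_COLUMNS)

        stage = "neo"
        enumerated = None
        if config.run_neo:
            enumerated = _stage_neo(cohort_dir, out, fvar, ffus, counts)

        stage = "tme"
        if config.run_tme:
            fractions = _stage_tme(cohort_dir, out, counts)
        else:
            # externally supplied fraction table
            fractions = pd.read_csv(cohort_dir / "cell_fractions.tsv", sep="\t")

        stage = "metrics"
        if config.candidate_source == "enumerated":
            if enumerated is None:
                raise ValueError("candidate_source='enumerated' requires the neo stage")
            candidates = enumerated
        else:
            candidates = _io.read_table(cohort_dir / "candidates.tsv",
                                        _io.CANDIDATE_COLUMNS)
        profiles = None
        if config.run_metrics:
            profiles = _stage_metrics(cohort_dir, out, fvar, candidates, fractions,
                                      config.coding_mb, counts)

        clinical = _io.read_table(cohort_dir / "clinical.tsv", _io.CLINICAL_COLUMNS)

        stage = "survival"
        if config.run_survival:
            if profiles is None:
                raise ValueError("survival stage requires metrics stage")
            _stage_survival(out, clinical, profiles, config.survival_covariates,
                            config.bivariate_pairs, config.min_group, counts)

        stage = "stats"
        if config.run_stats:
            if profiles is None:
                raise ValueError("stats stage requires metrics stage")
            _stage_stats(cohort_dir, out, candidates, profiles, ffus, counts)
    except Exception as exc:
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc

    checksums = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.suffix != ".png":
            checksums[str(path.relative_to(workdir))] = _io.sha256_file(path)
    for name in REQUIRED_INPUTS + ["truth.json"]:
        p = cohort_dir / name
        if p.exists():
            checksums[f"cohort/{name}"] = _io.sha256_file(p)

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stage_counts": counts,
        "checksums": checksums,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (workdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True, default=list))
    return manifest
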
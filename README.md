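# sarcimmune

Immunogenomic covariates and survival stratification for immune-checkpoint-
inhibitor (ICI) treated sarcoma cohorts.

Sarcomas are a heterogeneous family of bone and soft-tissue tumors that
respond only modestly to ICI therapy. A recurring hypothesis is that
progression-free survival (PFS) under anti-PD-1 treatment is governed not by
any single biomarker (tumor mutational burden, neoantigen counts, immune
infiltration) but by their *interplay* — in particular, high-quality
neoantigens only matter when CD8+ T cells are present in the tumor
microenvironment (TME) to recognize them. `sarcimmune` implements, as a
tested and reusable pipeline, the computational machinery needed to probe
that hypothesis:

- **Somatic variant screening** — ensemble-consensus and quality filters
  (≥ 2 of 6 callers, tumor/normal depth ≥ 10, > 3 alt-supporting reads),
  RNA-expression filtering, and low-confidence fusion removal.
- **Neoantigen enumeration** — phasing-aware mutant protein reconstruction,
  exhaustive 9/10-mer windows over altered residues (SNV, indel, frameshift
  and fusion-junction peptides), proteome-uniqueness filtering, per-HLA-A/B
  scoring through a pluggable scorer contract, and expression-adjusted
  abundance (Σ isoform TPM × RNA VAF).
- **Per-patient covariates** — TMB (non-synonymous SNV/indels with VAF ≥ 5%
  per coding megabase), neoantigen load NAL = #{candidates with antigen-
  presentation score AP > 0.5}, and neoantigen quality = mean AP of the top
  ten candidates.
- **TME deconvolution** — cell fractions from bulk expression by constrained
  least squares: min ‖S·f − m‖² s.t. f ≥ 0, Σf ≤ 1, with an explicit
  uncharacterized "Other" fraction.
- **Survival analysis from first principles** — Kaplan–Meier product-limit
  curves S(t) = Π (1 − dᵢ/nᵢ), the k-sample log-rank test, *supervised
  optimal binning* (exhaustive threshold search over observed covariate
  values minimizing the log-rank p subject to ≥ 10 patients per group), and
  bivariate four-quadrant (low/low … high/high) stratification.
- **Cohort statistics** — Welch's unequal-variance t-test over pooled
  top-ten AP scores per clinical response group (R / SD / PD and PD vs
  non-PD), and Spearman rank correlations.
- **Synthetic cohorts** — because patient-level trial data of this kind is
  access-restricted, the package ships a first-class generator that emulates
  a 31-patient, seven-subtype sarcoma cohort (13 soft-tissue / 18 bone) with
  heterogeneous mutation burdens, Beta-mixture AP scores, Dirichlet cell
  fractions, and exponential PFS whose log-hazard carries a configurable
  protective T-cell × neoantigen-quality interaction.

## Worked example

```python
from sarcimmune.synthetic import CohortConfig, generate_cohort
from sarcimmune.survival import (SurvivalRecord, optimal_binning,
                                 km_estimate, bivariate_stratify)

cohort = generate_cohort(CohortConfig(seed=1))          # 31 patients
records = [SurvivalRecord(r.patient_id, float(r.pfs_days), int(r.event))
           for _, r in cohort.clinical.iterrows()]
tcell = cohort.truth["t_cell_fraction"]
quality = cohort.truth["neoantigen_quality"]

res = optimal_binning(tcell, records, min_group=10)
print(f"threshold={res.threshold:.4f}  p={res.chosen_p:.4g}")

thr_q = optimal_binning(quality, records, min_group=10).threshold
groups, lr, medians = bivariate_stratify(tcell, quality,
                                         res.threshold, thr_q, records)
print(f"bivariate log-rank chi2={lr.statistic:.3f} df={lr.df} p={lr.p:.4g}")
print(medians)
```

prints

```
threshold=0.0375  p=0.01768
bivariate log-rank chi2=12.220 df=3 p=0.006667
{'LL': 58.4, 'LH': 133.5, 'HL': 130.2, 'HH': 167.4}
```

The univariate search dichotomizes the cohort at a CD8+ T-cell fraction of
0.0375 — the observed value minimizing the log-rank p over all splits with
at least ten patients per group (p = 0.018; median PFS 62 vs 167 days). The
four-quadrant analysis then shows the planted synergy: patients high in
*both* T-cell fraction and neoantigen quality have the longest median PFS
(167 days), the doubly-low quadrant the shortest (58 days), and the
four-group log-rank test separates the strata (p = 0.0067).

The same analyses are available from the shell:

```bash
sarcimmune simulate --out cohort/ --seed 1
sarcimmune run --config run.yaml        # full pipeline with manifest
sarcimmune survival uni --clinical cohort/clinical.tsv \
    --covariates profiles.tsv --covariate t_cell_fraction --out-prefix tcell
```

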
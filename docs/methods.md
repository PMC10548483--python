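# Methods

This note documents the statistical models, algorithmic conventions and
design decisions behind `sarcimmune`, in the spirit of a package reference
manual: what is computed, under which assumptions, and what the synthetic
cohorts do and do not emulate.

## Variant screening

A somatic SNV/indel record carries caller support (`n_callers` of an
ensemble of six), tumor/normal read depths, alt-supporting tumor reads, and
DNA/RNA variant allele fractions. The consensus/quality gate keeps exactly
the records with

    n_callers >= 2  AND  depth_tumor >= 10  AND  depth_normal >= 10
    AND  alt_reads_tumor > 3

Depth thresholds are inclusive; the alt-read rule is strict ("more than
three reads"). The expression filter keeps variants whose harboring
transcripts have summed TPM strictly greater than a threshold whose default
is 0 TPM — i.e. any detectable expression counts as "expressed"; the cutoff
is configurable because "expressed" has no canonical value. The filter
operates at transcript level (sum over the variant's annotated transcripts);
a gene-level variant would need its transcripts enumerated by the caller.
Fusion calls labelled `low` confidence are discarded; `medium` and `high`
are kept. All filters are pure: output ⊆ input, order preserved, no record
mutated, f∘f = f.

## Neoantigen enumeration

Protein-level consequences (residue, reference/alternate amino acids,
frameshift tails) arrive as input annotations — effect prediction and
haplotype phasing themselves are upstream concerns; the package consumes
their output via `phase_set` tags.

*Phasing.* Variants sharing a phase set are applied jointly to one
haplotype sequence; each unphased variant yields its own mutant sequence.
Overlapping replacement edits within one phase set, or any edit at or beyond
a frameshift in the same set, are conflicts and raise an error. A
frameshift replaces the suffix from its residue with the supplied novel
translation (up to the new stop).

*Windows.* For each mutant/wild-type pair, every 9- and 10-mer window that
covers at least one altered residue is enumerated. For same-length edits a
window must also differ from the positionally aligned wild-type window, and
the altered residues are simply the mismatch positions. For length-changing
edits (indels, frameshifts) there is no positional alignment; every residue
from the first divergence to the end of the mutant is treated as altered,
and windows that happen to reproduce normal peptides are removed by the
proteome-uniqueness filter (any mutant k-mer occurring anywhere in the
wild-type proteome k-mer set is dropped). Residue coordinates are 1-based;
windows are closed intervals. Duplicate (sequence, protein) pairs from
overlapping enumeration are collapsed — identical ligands are one candidate.

*Fusion junctions.* In-frame fusions contribute every window containing at
least one residue from each partner; out-of-frame fusions contribute every
window containing at least one residue of the novel downstream translation.
Short junction context yields fewer windows, never an error.

*Scoring.* Candidates are one (peptide × HLA allele) pair per allele at the
A and B loci; HLA-C is excluded by default (its predictors lack validated
training data). The scorer is a contract — `score(peptide, allele) → [0,1]`
— so any external antigen-presentation model can be plugged in. The bundled
`SurrogateScorer` maps a SHA-256 hash of (peptide, allele) through a Beta
quantile function: deterministic, reproducible, and distributionally shaped
like a presentation likelihood (mostly low scores with a tail above 0.5).
It is a stand-in for a trained predictor, not a model of immunogenicity.

*Abundance.* abundance = (Σ TPM of isoforms coding for the peptide) ×
RNA-level VAF. Fusion-derived candidates get abundance 0 unless quantified
externally. Start-loss/stop-loss variants are out of scope and rejected.

## Per-patient covariates

- TMB = #{non-synonymous SNV/indels with vaf_dna ≥ 0.05} / coding_mb.
  "At least 5%" is read as inclusive. The coding footprint has *no* silent
  default in the CLI (`--coding-mb` is required); the pipeline config
  defaults to 31 Mb, a typical exome footprint.
- NAL counts candidates with AP strictly above 0.5. By default (peptide ×
  allele) pairs are counted, so per-allele NAL sums exactly to the overall
  NAL; `unique_peptides=True` counts each peptide once at its best score.
- Neoantigen quality is the mean AP of the top ten candidates ranked by
  score. Patients with fewer than ten contribute the mean of what they
  have (0 for none); `strict_top_k=True` yields a missing value instead.
  Ties at the tenth rank do not affect the mean (equal scores) and ranking
  is made deterministic by sorting scores.

## TME deconvolution

Bulk expression is modelled as m ≈ S·f with S a nonnegative genes ×
cell-types signature (ten immune phenotypes), f ≥ 0 and Σf ≤ 1; the
remainder 1 − Σf is the uncharacterized "Other" fraction (tumor, stroma).
The inequality-constrained least-squares problem is solved exactly by
augmenting with a slack variable and a heavily weighted simplex row and
running active-set nonnegative least squares, so noiseless mixtures are
recovered to ~1e-9. Signature columns are rescaled to a common total before
solving, which makes the coefficients comparable across cell types but
assumes comparable per-cell mRNA content — cell-type-specific mRNA scaling
is not modelled. A `sum_to_one` flag forces Σf = 1 (no "Other" mass).
The CD8+ T-cell covariate can come from this deconvolution or be passed
through from an external estimate (e.g. a V(D)J-recombination based tool).

## Survival analysis

Kaplan–Meier, log-rank and the threshold search are implemented from their
definitions (scipy supplies only distribution tails).

- KM: S(t) = Π_{tᵢ ≤ t} (1 − dᵢ/nᵢ). Subjects censored at an event time are
  still at risk at that time (events precede censorings on ties). The
  median is the smallest event time with S(t) ≤ 0.5 and is *undefined*
  (serialized as an empty field / `None`) when the curve plateaus above 0.5.
- Log-rank: observed-minus-expected event counts over the pooled distinct
  event times with the hypergeometric variance-covariance; the statistic is
  the quadratic form over k−1 groups (pseudo-inverse for degenerate
  designs), chi-square with k−1 df. For k > 2 this is the k-sample test —
  the "multivariate" log-rank here means the k-sample test, not a
  stratified test.
- Supervised optimal binning: only covariate values that occur in the data
  can change group composition, so exactly the observed values are tried as
  thresholds with low = {value ≤ t}, high = {value > t} (the largest
  observed value is thus never admissible — its high group is empty). Only
  splits with both groups ≥ `min_group` (default 10) compete; the returned
  threshold minimizes the log-rank p, ties broken by the smallest
  threshold. The full (threshold, p, n_low, n_high) landscape is reported
  so the stability of the chosen cut can be inspected. No multiple-testing
  correction is applied by default — the search is exploratory and every
  threshold is a hypothesis; an optional Benjamini–Hochberg adjustment over
  the admissible landscape is available behind a flag.
- Bivariate analysis dichotomizes two covariates at their univariate optima
  and labels patients LL/LH/HL/HH; the k-sample log-rank runs over the
  non-empty quadrants with per-quadrant KM medians.
- Plot capping (e.g. 500 days) is display-only; statistics always use raw
  times.

## Response statistics

Welch's t statistic uses unbiased variances with Welch–Satterthwaite df;
p-values are two-sided. Each patient contributes its top-ten AP scores as
individual observations pooled into its response group (R, SD, PD);
contrasts are R–PD, R–SD, SD–PD and PD vs pooled non-PD. Pooling scores —
rather than per-patient means — matches the view of the score distributions
per group; per-patient means are available behind a flag. Spearman's rho is
the Pearson correlation of midranks (average ranks on ties) with the t
approximation for its p-value. No multiple-testing correction is applied.

## Synthetic cohorts

The generator draws, per patient: a subtype (deterministic largest-remainder
allocation of the configured weights — the default composition is 31
patients, 13 soft-tissue / 18 bone across seven subtypes: 4 SS, 4 LMS,
2 DDLPS, 3 UPS, 6 ES, 9 OS, 3 CS); two HLA alleles per class-I locus;
Dirichlet cell fractions over the ten immune phenotypes plus a dominant
"Other" component; subtype-specific uniform SNV/indel/fusion counts
(fusion-rich DDLPS, mutation-heavy OS/UPS); variant quality fields with
realistic failure rates so the filters have work to do; a synthetic
proteome with transcript expression; and neoantigen candidates whose AP
scores come from a two-component Beta mixture whose per-patient
high-quality weight varies (so top-ten means differ across patients).
Bulk mixtures are built as signature × fractions (noise configurable,
default noiseless, so the deconvolution stage recovers the planted
fractions essentially exactly).

PFS is exponential with rate λ₀·exp(η), λ₀ = ln 2 / 90 days, and

    η = β_t·z(T-cell fraction) + β_q·z(quality) + β_int·1[both above median]

Main-effect covariates are z-scored within the cohort so the coefficients
are scale-free. The interaction covariate is the *indicator* that both the
CD8 fraction and the neoantigen quality exceed their cohort medians: a
symmetric product of z-scores would equally protect the doubly-low
stratum, which is not the synergy the generator is meant to plant.
Defaults are β_t = −0.6, β_q = 0, β_int = −1.0 — a protective T-cell main
effect plus a protective synergy, which yields the qualitative quadrant
ordering HH > HL > {LH ≈ LL}. These effect sizes are free parameters of the
generator, chosen to produce a clearly recoverable pattern at a few hundred
patients; they are not estimates of any real cohort. Censoring is
independent: with probability `censoring_rate` (default 0.2) a patient is
censored at a uniform fraction of its latent event time. Response labels
(3 R / 9 SD / 18 PD / 1 unknown per 31, scaled by largest remainder) are
assigned by noisy quality rank, planting a modest non-PD vs PD shift in AP
scores.

All randomness flows from one seeded generator: identical configs give
bit-identical cohorts, and written cohorts (TSV/FASTA/VCF/JSON) read back
equal on every field.

What the generator does *not* emulate: mutational signatures, subclonal
structure, linkage to real sarcoma genomes, realistic HLA frequencies,
correlated TME compositions, or informative censoring. Passing tests on
these cohorts therefore demonstrate the correctness and calibration of the
*analysis machinery* — not that the planted biology holds in real sarcomas.

## Numerical choices and problem sizes

- Deconvolution simplex weight 1e8 (relative to the data scale); recovery
  tolerance in tests 1e-6.
- Log-rank uses a pseudo-inverse with exact-zero clipping of the statistic;
  two identical groups give statistic 0, p = 1.
- Welch errors on samples smaller than two or on two zero-variance samples;
  Spearman errors on constant vectors or fewer than three pairs.
- Calibration tests use 5,000 null replicates (type-I error bands
  [0.035, 0.065] at α = 0.05); planted-effect recovery uses 100 seeds of
  400-patient cohorts; the acceptance script uses 30 seeds and 2,000
  replicates for the same quantities to keep a single run short. These
  sizes were chosen to make the checks statistically sharp while keeping a
  full run in the minutes range on one CPU.

## Pipeline

`run_pipeline` executes simulate → filter → enumerate → deconvolve →
metrics → survival → statistics with per-stage record counts and a manifest
(package/library versions, seed, parameters, SHA-256 checksums of all
text inputs and outputs). Stage outputs are pure functions of their inputs;
two runs of one config differ only in the manifest timestamp. By default
the per-patient metrics consume the cohort's own candidate table; the
re-enumerated, surrogate-scored candidates (`candidate_source:
"enumerated"`) are available but decouple the measured neoantigen quality
from the AP scores the generator used to plant the survival structure, so
the default keeps the planted effect interpretable end to end. When the
deconvolution stage is disabled the survival analysis falls back to the
externally supplied cell-fraction table.

## Known limitations

- Indel window alignment is by divergence suffix, not sequence alignment;
  inframe deletions near repeats may enumerate windows that the uniqueness
  filter must then remove.
- The surrogate scorer's scores carry no biology; analyses of score
  *structure* (e.g. allele preferences) are meaningless under it.
- The k-sample log-rank is the only "multivariate" test; no Cox model,
  hazard ratios, or stratified tests are provided.
- TMB's coding footprint is a user input; comparisons across runs require a
  consistent value.
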
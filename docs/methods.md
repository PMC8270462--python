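# Methods

## Model

A cohort of N tumor genomes is summarized as a count matrix **M**
(N × 96): somatic single-base substitutions classified by substituted
pyrimidine, alternate base, and the two flanking reference bases, with
purine-strand calls reverse-complemented (6 × 16 = 96 categories, COSMIC
ordering: types C>A, C>G, C>T, T>A, T>C, T>G, flanks sorted 5′ then 3′).
Samples with fewer than a minimum number of mutations (default 1000,
appropriate for whole genomes) are removed before fitting: below that,
per-category counts are too sparse to constrain a factorization.

The generative model is M ≈ α₀β₀ + αβ with all factors non-negative. β₀
is a fixed, dense "background" signature representing clock-like
replication-error mutagenesis; fixing it prevents the flat component —
which is mathematically hard to separate de novo — from leaking into the
discovered signatures. The fitted objective is

‖M − (α₀β₀ + αβ)‖²_F + λ‖β‖₁,  α, α₀, β ≥ 0,

which is bi-convex: convex in the exposures (α₀, α) with β fixed, and
convex in β with the exposures fixed. β₀ is excluded from the penalty and
never updated.

### Scale convention and λ

The factorization has a scale ambiguity (β ↦ cβ, α ↦ α/c). β is
initialized and reported with rows summing to 1; exposures then carry the
mutation-count scale. The user-facing regularization weight is a
*fraction* of λ_max, the smallest penalty at which the β-subproblem's
minimizer is the zero matrix. From the stationarity condition of the
non-negative LASSO on the residual R = M − α₀β₀,

λ_max = 2 · max(0, max entries of αᵀR).

The factor 2 comes from the squared-Frobenius loss carrying no ½; a
comparison against conventions that include the ½ must rescale by 2.
λ_max is computed once per fit from the initial exposures, not per
iteration, so the effective penalty is constant within a run and
λ-fractions are comparable across K.

## Solver

Alternating exact minimization, starting from a repeated-NMF
initialization of β (default 10 random restarts of scikit-learn's NMF,
best reconstruction error kept, rows renormalized; the cap of 240 NMF
iterations is deliberate — the alternation refines the signatures far
past what extra NMF iterations would buy). Each iteration:

1. **Exposures**: per-sample non-negative least squares for (α₀, α).
   Samples are independent, so the default solver is cyclic coordinate
   descent with every coordinate update vectorized across samples (a
   numba kernel); it converges to the per-sample NNLS optimum. On
   ill-conditioned designs (near-duplicate signatures, which arise when K
   exceeds the true rank) the descent can stall; after 2000 sweeps the
   exact Lawson–Hanson active-set solver finishes the job. The active-set
   path is also available directly (`solver="active-set"`) and the two are
   equivalence-tested.
2. **Signatures**: the non-negative LASSO in β by cyclic coordinate
   descent over signature rows. Given the other rows, the 96 categories
   decouple, so updating an entire row at once is an exact coordinate
   step; each sweep cannot increase the objective. Convergence tolerance
   is 1e-8 on relative objective change inside `fit` (1e-15, i.e. run to
   numerical stall, for the public single-update entry points, which are
   verified entrywise against an independent projected-gradient oracle);
   the sweep cap is 20 000, beyond which a convergence error carrying the
   partial state is raised.

Both subproblems are solved exactly, so the penalized objective is
non-increasing across half-steps; the trace is recorded and checked.
Default 20 alternating iterations (empirically enough to converge on
cohort-scale data); an optional early stop triggers when the relative
objective improvement over one full iteration falls below a tolerance
(off by default for final fits, 1e-4 inside cross-validation where
thousands of fits run).

Rows of β driven entirely to zero by the penalty are kept as structural
zeros and counted in `effective_k`, rather than silently dropped —
dropping them would change the model dimension chosen by cross-validation.
At output, nonzero rows are renormalized to sum 1 with α rescaled so αβ
is unchanged.

Degenerate inputs: K = 0 with a background is the background-only NNLS
fit; K = 0 without a background is an error; an all-zero count matrix
cannot be initialized.

## Model selection

Repeated bi-cross-validation over a (K, λ) grid:

* **Hold-out**: ⌈1% · N · 96⌉ cells sampled uniformly without replacement
  (fraction configurable). A draw that would remove every nonzero cell of
  some sample is rejected and redrawn (bounded retries) — such a row would
  be unconstrained during fitting.
* **Imputation**: masked cells are zeroed, the model fit, masked cells
  replaced by the reconstruction, and the fit repeated for 5 rounds
  (default); the predictions stabilize over rounds. Rounds after the
  first warm-start from the previous round's signatures (rows zeroed by
  the penalty fall back to the original initialization so they can
  re-enter); the first round starts from the per-K repeated-NMF
  initialization computed once on the complete matrix and shared across
  λ values and repetitions.
* **Scoring**: mean squared error between the final round's predictions
  and the true held-out values. Default 10 repetitions with fresh masks
  (5 in the desk-scale benchmark); within a repetition the same mask is
  used for every grid cell so pairs are compared on identical held-out
  data — the procedure is well defined either way, but sharing masks
  removes a source of between-cell variance.
* **Selection**: per repetition, the grid cell with the lowest error; the
  pair chosen most often wins ("lowest MSE in most of the
  cross-validations"). Ties break by lower median MSE across repetitions,
  then smaller K, then larger λ. A secondary rule — argmin of the median
  MSE across repetitions — is selectable (`rule="median"`).

K here always counts *non-background* signatures; reported totals add 1
when a background is fixed, and every serialized artifact states which
convention it uses.

The default λ grid is {0.01, 0.025, 0.05, 0.075, 0.1}, the grid used for
the published cohort-scale analyses; λ = 0 (no penalty) is a legitimate
grid entry.

## Synthetic cohorts

The generator draws, per sample: a total burden log-uniform between 10³
and 10^4.5 (spanning typical whole-genome burdens above the 1000-mutation
filter); an active-signature subset (the designated background is always
active, every other signature independently with its presence fraction,
default 0.7); Dirichlet(1) relative exposures over the active set scaled
to the burden; and per-cell Poisson counts around αβ. Optional noise adds
Poisson(rate · mean cell value) counts to a random half of the cells
(`additive`) and symmetrically removes counts floored at zero
(`additive_subtractive`, default rate 0.1 in the noisy preset).

Six presets mirror the benchmark designs: `sim1` (116 samples, background
+ 3 sparse signatures, prostate-like), `sim2`–`sim4` (100 samples, 4
signatures drawn from a catalog — any / dense >75% of categories
contributing / sparse <50%), `sim5` (`sim1` + additive-subtractive
noise), `sim6` (100 samples, 8 catalog signatures). "Contributing" means
probability above 1/960 (1% of uniform; configurable). Catalog presets
accept an external signature TSV (e.g. COSMIC v3); without one they use a
deterministic synthetic catalog (sparse/dense mix generated from a fixed
seed). Note the benchmark literature numbers these designs inconsistently
in different places; the mapping above (noise variant = sim5) follows the
internally consistent listing.

What the generator emulates — and what it does not: cohorts are exactly
exposures × signatures with Poisson counting noise, so they test
identifiability, rank selection and regularization behavior. They do not
reproduce exposure correlations of real cohorts (the prostate-like
design they stand in for was built by refitting signatures to real
whole-genome cohorts), sequencing artifacts, mapping bias, or subclonal
structure. Passing benchmarks here shows the
machinery recovers a known truth under its own model assumptions, not
that real tumor spectra satisfy those assumptions.

The packaged background presets are *synthetic stand-ins* (see
`data/*_synthetic.tsv`): dense clock-like spectra constructed once, CpG-
adjusted, with the perturbation between them calibrated so their cosine
similarity is 0.998 — the documented property of the published
germline/SBS5 preset pair, whose source table is not packaged here. For
real analyses users should supply their preferred background.
The CpG adjustment replaces the four NCG>NTG rates with the matching
NCA>NTA rates (separating methylation-driven deamination from the
background) and renormalizes to sum 1 — the renormalization is this
package's choice, made because β₀ is used as a probability spectrum and
exposures absorb scale; the adjustment is idempotent.

## Evaluation metrics

Recovery: each true signature is matched to its highest-cosine discovered
signature (non-exclusive by default, matching the benchmark convention; a
one-to-one maximum-assignment variant via the Hungarian algorithm is
available for robustness analyses). Exposure error is the per-pair mean
over samples of squared count-scale differences. Fit quality:
reconstruction MSE; explained variance 1 − ‖M − fit‖²_F/‖M‖²_F; sparsity
as the fraction of signature-matrix entries below an explicit threshold
(1e-3 for simulations, 1e-4 for real-data reporting — never hard-coded);
cross-signature similarity (mean pairwise cosine among discovered
signatures; undefined for K < 2); background contamination (mean cosine
between background and discovered signatures); per-patient Pearson
correlation between observed and reconstructed spectra (flagged missing
for constant spectra). Rare-signature recovery is summarized as the
median cosine stratified by presence-fraction and mutation-total bins.

## Benchmark scales

The rank-selection experiment (`sparsesig.benchmark.k_selection_experiment`,
driven by `scripts/acceptance.py`) uses 10 datasets, K ∈ {2..8},
λ ∈ {0.01, 0.05, 0.1}, 5 repetitions and 1% hold-out — a desk-scale
rendition of the published 50-dataset design, sized to run in minutes on
one CPU. Over-selection of K at the smallest λ occurs in a minority of
datasets (held-out error occasionally rewards extra signatures on a lucky
mask), which is why the reported quantity is the modal selection across
datasets. The rare-signature experiment uses 10 cohorts of 60 samples
with one signature's presence in 0.20–0.35 and reports the median
recovery cosine of those rare signatures.

## Known limitations

* One fixed background at most; no penalty on the exposure matrix; squared
  Frobenius loss only (no Kullback–Leibler variant).
* Indels, doublet substitutions and extended (1536-context)
  classifications are out of scope; multi-sample VCFs must be split.
* Bi-cross-validation cost grows as |K grid| × |λ grid| × repetitions ×
  imputation rounds; repetitions are embarrassingly parallel
  (`CVConfig.n_jobs`).
* Alternating minimization of a bi-convex objective converges to a
  stationary point, not a guaranteed global optimum; repeated-NMF
  initialization and restarts mitigate, and identifiability rests on
  exposure variation across samples (an always-on signature with
  near-constant exposure can trade mass with the background).
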
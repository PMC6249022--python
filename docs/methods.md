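# Methods

## Model

The pipeline treats a cancer sample's somatic SNVs as draws from a mixture
of fixed mutational signatures. With signature matrix `P` (S × 96,
row-stochastic) and exposure vector `e` on the S-simplex, the channel counts
`n` of a sample with burden `N = Σ n_c` are modelled as

    n ~ Multinomial(N, eᵀP).

Exposures are estimated by maximising the multinomial log-likelihood
`Σ_c n_c log(Σ_s e_s P_sc)` with expectation–maximisation. EM on this
mixture is monotone (the log-likelihood never decreases) and the likelihood
is concave in `e`, so the uniform start `e = 1/S` defines a deterministic,
reproducible fit; ties/multimodality are resolved by that start. This is a
deliberate design choice over Bayesian MCMC refitters: the point estimate
is what enters the regression, and determinism makes the permutation
machinery bit-reproducible. A non-negative least-squares fit on channel
proportions is provided as an independent second backend and is used only
for cross-backend agreement checks, never as the primary estimate.

Driver–signature association within one cancer type is the binary
univariate logistic model `p(x) = 1/(1+exp(−(β₀+β₁x)))` with `x` the
exposure *proportion* in [0, 1] (not percent, not logit-transformed) and
`y` driver presence. The odds ratio is `exp(β₁)` and the p-value is the
two-sided Wald z-test of `β₁ = 0` (the default of standard GLM tooling);
likelihood-ratio p-values were considered and not made the default. The
fitter is a two-parameter Newton/IRLS written in-house so that the
permutation loop can refit thousands of shuffled response columns in one
vectorised pass; tests verify it against the closed-form 2×2 cross-product
ratio and against `statsmodels.Logit` to 1e-6.

## Eligibility, FDR and reciprocal negatives

A triple is tested only when the cancer type has ≥ 10 driver-mutant samples
and ≥ 10 samples with exposure ≥ 0.20 to the signature (both inclusive).
Descriptive "signature present" summaries use the strict rule
exposure > 0.05. These two comparisons intentionally differ in strictness;
each call site follows its printed inequality.

The significance threshold is calibrated by randomisation: per iteration,
each driver column is shuffled once within its cancer type (preserving the
mutant count exactly) and that shuffle is reused across all signatures
tested against the driver — driver columns are shuffled independently, so
inter-driver co-occurrence is not preserved. For each candidate threshold
in the descending grid {0.05, 0.02, 0.01, 0.005, 0.004, 0.002, 0.001,
5e-4, 1e-4} the FDR estimate is (mean null significant count)/(observed
significant count), capped at 1 for reporting and undefined (NA) when the
observed count is zero; the selected threshold is the largest candidate
with estimate < target. Non-converged or separated fits (|β₁| > 30 or a
singular Hessian) are flagged and excluded from observed and null counts
symmetrically.

Because exposures are compositional (they sum to 1), a genuine positive
association of a driver with one signature mechanically induces negative
associations with the others. Significant odds-ratio-< 1 associations whose
(cancer type, driver) pair also has a significant positive association are
therefore excluded before counting — identically in the observed data and
in every permutation iteration, at every candidate threshold. Negative
associations with no positive partner are retained as genuine findings.

## Cohort and curation rules

Catalog filters run in a fixed order: cancer-type merges (e.g. COAD/READ →
CRC) first, then the ≥ 30-SNV per-sample burden filter, then one random
sample per patient, then the ≥ 40-sample per-type filter. The order matters
at the boundaries (a merge can lift two small types over the size
threshold) and is pinned by tests. The per-patient draw comes from a stream
keyed by (seed, patient id), so adding or removing unrelated patients never
changes another patient's pick, and the filter is idempotent.

Panel-of-normals handling is asymmetric by design: flagged calls are
excluded from signature catalogs but retained when counting driver
recurrence and presence, so hotspots that leak into normals are not lost.
Driver identity is genomic — (chrom, pos, ref, alt) — and the cohort-depth
rule "> 10 samples" is strict (11+), distinct from the "≥ 10" eligibility
rule above. Indels and splice variants never survive curation: indels have
no trinucleotide substitution context and splice calls are unevenly
captured by exome baits. Annotation resources (Cancer Gene Census Tier-1
genes, IntOGen counts, Cancer Genome Interpreter designations) are plain
TSV snapshots supplied by the user; the repository ships only small
synthetic stand-ins inside tests.

Records on contigs present in the reference FASTA are kept wherever they
map; records whose context window is unresolvable (missing contig, contig
edge, ambiguous base) are dropped with a logged warning.

## Signature matrices and context amounts

Signature TSVs are accepted in both the `A[C>A]A` and `ACA>AAA` channel
dialects, in any row order. Genome-derived matrices are exome-normalised by
multiplying each channel by an exome/genome trinucleotide frequency ratio
and renormalising rows. No measured ratio table is bundled: the shipped
`exome_trinucleotide_weights_synthetic.tsv` is synthetic (plausible
magnitudes only) and exists for tests and examples; supply a measured table
for real data. Context "amounts" (the percentage of a signature's mutations
in a driver's trinucleotide context, ranked high when > 5%) are computed
against the genome-form matrix as published, since the published
per-channel percentages are quoted on that scale. The package pins the
published COSMIC v2 probabilities for the driver contexts it annotates
(`cosmic_v2_selected_channel_probs.tsv`); the full 30×96 matrix is a
user-supplied input.

## Synthetic cohorts

The generator mirrors the generative structure the analysis assumes:
exposures ~ Dirichlet(α), burden ~ round(lognormal) floored at 30 SNVs,
channel counts ~ Multinomial(N, eᵀP), and planted driver presence ~
Bernoulli(expit(β₀ + β₁·x_target)) on the *true* exposure. Defaults are
chosen once to match real exome cohorts: sparse exposure priors (α = 0.3
per signature, giving skewed few-signatures-per-sample profiles) and a
lognormal burden with median 100 SNVs per exome. The floor at 30 means no
synthetic sample trips the cohort burden filter unintentionally. Unit-test
matrices use 3–5 sparse synthetic signatures with partially overlapping
support and a 1% uniform floor so every channel is reachable.

When a planted-driver carrier's multinomial draw leaves the driver's
channel empty, one mutation of that channel is added (burden + 1): the
driver mutation is then always one of the sample's counted mutations, and
re-expressing a cohort as records plus a synthetic FASTA
(`emit_records`) round-trips through catalog construction bit-exactly. The
synthetic reference holds one 3-bp contig per trinucleotide plus one
private contig per planted driver.

What the generator does **not** emulate: sequencing error, coverage and
purity variation, subclonality, indels, inter-driver mutual exclusivity,
and per-type signature composition differences beyond the Dirichlet prior.
Passing tests therefore demonstrate the statistical machinery — calibration,
error control, recovery — under the model's own assumptions, not robustness
to real-data artefacts.

## Problem sizes and numerical choices

The planted benchmark used by the acceptance checks is 4 cancer types ×
500 samples with 5 signatures and 22 drivers per type (10 linked at
OR = 6, β₀ = −1.5; 12 exact nulls), giving 440 eligible triples with 40
true links, calibrated with 200 shuffle iterations — large enough for
stable sensitivity/FDR estimates, small enough to run in seconds. EM
defaults: tolerance 1e-8 on the per-iteration log-likelihood gain, at most
10,000 iterations, exposures below 1e-6 truncated to exactly 0 and the
vector renormalised (stable downstream thresholding). Logistic defaults:
gradient tolerance 1e-10, Newton steps clipped at 5 per iteration,
separation flagged at |β₁| > 30. Mann–Whitney U uses midranks with exact
enumeration up to pooled n = 12 and a tie- and continuity-corrected normal
approximation beyond; the t-test is pooled-variance with p = 1 (equal
means) or p = 0 (unequal) on zero-variance degenerate input. All random
streams derive from a master seed plus SHA-256-hashed entity keys, making
every pipeline stage bit-reproducible and insensitive to scheduling order.

## Known limitations

Real-cohort headline numbers depend on protected TCGA-scale data and three
proprietary annotation snapshots, so they are out of desk scope; the
package validates the machinery on synthetic ground truth instead. The
Wald p-value is mildly anticonservative in very small strata; separation
handling flags rather than penalises (no Firth correction). The FDR
estimator is the plain null/observed ratio — it is not a Benjamini–Hochberg
procedure and inherits Monte-Carlo noise from the iteration count.
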
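# Methods

## The model

`cardiobayes` estimates the probability that a rare protein-altering
variant, found in a patient referred for genetic testing, is the cause of
that patient's inherited cardiac condition (long QT syndrome, Brugada
syndrome or hypertrophic cardiomyopathy). The estimate is Bayesian:

    posterior odds = prior odds × likelihood ratio

The prior odds are gene-level quantities derived from case/control
rare-variant burden; the likelihood ratio aggregates variant-level
evidence through a logistic regression. Because the individual predictors
(control-database presence, conservation, SIFT, PolyPhen, Grantham,
protein domain) are strongly correlated, the evidence is modelled jointly
rather than naively multiplied: per syndrome the package fits three
interrelated linear predictors on the logit scale, one per variant class.

* **radical** (nonsense, consensus splice disruptors, frameshift):
  `η = α_rad + λ_rad · log(prior odds, radical) + β_freq · f`
* **inframe indel**:
  `η = α_nr + α_if + λ_nr · log(prior odds, non-radical) + δ_D + β_freq · f`
* **missense**:
  `η = α_nr + λ_nr · log(prior odds, non-radical) + δ_D + β_freq · f
     + β_sift·(1−SIFT) + β_p1·p + β_p2·p² + β_g1·g + β_g2·g²
     + β_cp·c₁ + β_ca·c₂`

with `P(pathogenic) = logistic(η)`. `f` is a binary indicator of presence
in a control database (missing frequency data are treated as absent);
`p` is the PolyPhen (HumVar) probability; `g` is the Grantham score
rescaled by 1/205 into [0, 1] (values above 205 are clamped to 1 with a
warning); SIFT is flipped to `1−SIFT` so that larger always means more
damaging; `(c₁, c₂)` are the conservation indicators described below.
PolyPhen and Grantham enter as quadratics, SIFT linearly — model choices
inherited from the source modelling study's selection experiments.

Gene effects are not free parameters: they enter as a fitted scale (one
per class group) times the log prior odds of the variant's gene, so genes
never seen in training data are still usable provided a burden row
exists. Domain effects `δ_D` are zero-mean normal random effects per
(gene, protein-domain) pair, with variance `σ²_dom` given an inverse-gamma
hyperprior. Genes whose domains are too sparsely covered by training data
(a fixed, configurable list: KCNJ2, CAV3, SCN4B, AKAP9, SNTA1, KCNJ5,
CACNA2D1, CACNB2, GPD1L, SCN1B, MYBPC3, TNNT2) carry no domain term, and
a domain unseen in training contributes 0 with a logged warning.

All intercepts, coefficients and scales carry N(0, 10) priors. The "10"
is read as a **variance** (the BUGS-family precision/variance ambiguity
cannot be resolved from the description alone); the spread is a
configurable hyperparameter, so sensitivity analyses at sd 100 or 1 are a
one-line change. The inverse-gamma hyperprior on `σ²_dom` defaults to
shape 2, rate 0.5 — weakly informative, with prior mode 0.17 and mean 0.5
on the variance scale, i.e. typical domain effects of about ±0.4 to ±1.5
logits, consistent with the magnitude of fitted domain effects and
guarding against overfitting with ~60 domains.

### Joint multi-syndrome fits

Two joint plans pool training data across syndromes to stabilise shared
parameters:

* **LQTS + BrS** ties the domain variance, the gene-prior scales, all
  three class intercepts and every predictor coefficient; only gene and
  domain random effects stay syndrome-specific.
* **LQTS + HCM** ties only the domain variance and the score coefficients
  (SIFT, PolyPhen, Grantham, conservation); intercepts, scales and the
  frequency coefficient are estimated per syndrome.

A single `β_freq` is shared across variant classes within a syndrome
block (the graphical structure shows one frequency node feeding all three
predictors).

## Prior odds from burden tables

For each (gene, syndrome, class group) the prior odds that a rare variant
in an affected referral is pathogenic are

    (case burden − control burden) / control burden

where burden is the proportion of individuals carrying a rare
(allele frequency < 0.0005) variant of the stated type. Adjustments, all
configurable with defaults at the published values:

* a zero or missing control burden is replaced by 0.0002 (one observed
  carrier) before the ratio is taken;
* **LQTS**: burdens from a prospective clinical case series are preferred
  where available; odds derived from literature case burdens are halved
  (clinical referral yields run about half of research-cohort yields);
  any resulting odds below 0.2 are floored at 0.2, since burden estimates
  are unstable in that range. The subtractive form can be negative when
  controls out-burden cases (several minor literature-only genes); the
  floor restores positivity, exactly as in every published row;
* **HCM/BrS**: only literature case burdens exist and control estimates
  were unstable, so odds are case burden over a fixed 1% benign burden.
  This plain ratio reproduces every published HCM/BrS prior exactly
  (37.5, 25, 6, 6, 30, 1), which the subtractive form does not.

The packaged burden table reproduces the published prior odds for the
worked examples (KCNH2 non-radical 25.0, KCNH2 radical 195, SCN5A LQTS
radical 13, KCNE1 radical 9). One documented discrepancy: the printed
KCNQ1 non-radical burdens give 44.2 where the published table prints 45
(and the printed KCNJ2 value 0.92 is likewise not recoverable from the
printed burdens, which give 1.42) — presumably rounding of the tabulated
burdens upstream; the package computes from burdens and does not
special-case either entry.

## Conservation categories

Per-species residue-match flags (same residue / different residue /
disregard for gaps and low-quality "X") over up to 70 species are grouped
into nested clades primates ⊆ mammals ⊆ vertebrates ⊆ all species. A
residue's five-level category is the widest clade whose informative
species all match; a differing primate residue gives "not conserved".
A category is never claimed for a clade with zero informative species —
that raises a missing-evidence error (the treatment of wholly-disregarded
clades is underdetermined upstream; requiring at least one informative
species per claimed clade is this package's resolution). For modelling,
the five levels collapse to three — not conserved (reference, (0,0)),
conserved in primates (1,0), conserved in all species (0,1) — with
mammal- and vertebrate-level conservation mapped onto the primate
indicator; the collapse map is an explicit, configurable table.

## MCMC fitting

The posterior over the parameter graph targets the Bernoulli likelihood
of the pathogenic/benign training labels under the linear predictors,
times the priors above. The sampler is an adaptive random-walk
**Metropolis-within-Gibbs**: each scalar parameter takes a univariate
Gaussian random-walk Metropolis step whose log step size adapts toward a
44% acceptance rate during burn-in (Robbins–Monro, gain ∝ t^−1/2) and is
frozen afterwards, so the kept draws come from a fixed-kernel chain.
`σ²_dom` is updated by an exact conjugate draw from its inverse-gamma
full conditional — exactness at no cost, in place of a positivity-
preserving log-scale random walk. Likelihood evaluations use
`logaddexp(0, η)` for stability; a non-finite likelihood raises rather
than silently continuing. Separated or degenerate data do not error: the
proper priors keep the posterior well defined.

Defaults mirror the published procedure: 10 chains × 40,000 iterations
with the first 20% discarded; chains are independently seeded from a
single master seed and runs are bit-for-bit reproducible on a fixed
platform. Tests and the acceptance script use smaller, stated problem
sizes (2–4 chains, 1,200–5,000 iterations, n = 100–1,000 variants),
chosen so the whole suite runs in minutes while every diagnostic stays
below the convergence threshold.

Convergence is assessed per parameter by the potential scale reduction

    R = sqrt( Var(φ|y) / W ),   Var(φ|y) = W·(n−1)/n + B/n

with `W` the mean within-chain variance, `B` the variance of the
per-chain means and `n` the kept draws per chain. This is the formula as
published in the source study; note `B` is *not* multiplied by `n` as in
the textbook between-chain variance, so this `R` approaches 1 from below
for well-mixed chains rather than detecting slow mixing through an
inflated `B/n` term — we implement the printed formula and report it
as such. Degenerate chains with `W = 0` (all chains identical constants)
define `R = 1`. Fits require `R < 1.1` for every parameter; the CLI's
`--until-converged` flag re-runs with doubled iterations until that
holds. Post burn-in draws are pooled across chains and summarised by
medians (the plug-in values used for prediction) and 5%/95% quantiles.

## Prediction, segregation evidence and bands

A novel variant is scored by plugging the posterior medians into its
class-specific linear predictor (a flag enables full posterior-predictive
averaging over draws instead). Familial segregation evidence enters as a
LOD score, treated as the log **base 10** of the segregation likelihood
ratio (the standard linkage convention; the base is not stated upstream):
posterior odds are multiplied by 10^LOD, so LOD contributions compose
additively and LOD 0 is the identity. Probabilities may be banded with
half-open intervals [lo, hi) — an exact threshold value falls in the
upper band — defaulting to <0.1 likely benign / 0.1–0.9 uncertain / >0.9
pathogenic.

## Cross-validated evaluation

Model assessment re-splits the labelled data (default 100 times) into
training and test sets, each test set holding floor(1/10) of the
pathogenic and floor(1/10) of the benign variants, sampled without
replacement independently per split (independent random re-splits, not a
partitioned 10×10 design; floor is the documented rounding choice). The
model is refitted on every training set and test predictions are pooled
across splits before computing ROC curves (threshold sweep with ties
grouped, trapezoid area) and threshold metrics, overall and per gene and
variant class. Positive predictive value is **prior-adjusted**:

    PPV = (prior odds × TPR) / (prior odds × TPR + FPR)

using syndrome-level prior odds supplied explicitly (e.g. 25 for the
three major LQTS genes), never the test-set class ratio, so the reported
PPV reflects the intended referral population.

## Synthetic data

Because the curated training variant tables are not redistributed, the
package generates synthetic populations with the statistical structure
the model assumes; all packaged corpora are deterministic, seed-pinned
and labelled synthetic.

`generate_training_set` draws the label first and predictors from
label-conditional distributions: benign variants appear in control
databases at rate 0.40 versus 0.02 for pathogenic; the class mixture is
428:41:19 (missense : radical : inframe); SIFT/PolyPhen/Grantham come
from Beta distributions separating the labels in the direction seen in
real training data, and conservation from label-conditional categorical
probabilities. The score distributions are illustrative fixture
constants, not published values.

`generate_from_model` draws covariates from marginal distributions and
labels from a Bernoulli at the network's own linear predictor under known
true parameters — the generative counterpart of the fitted model, used
for parameter-recovery and nested-model experiments. Records carry their
generating probability for oracle checks.

Two purpose-built specifications:

* **recovery spec** — designed for identifiability, not realism: score
  covariates on three-point grids {0, ½, 1} with weights (¼, ½, ¼), the
  optimal design for separating a linear from a quadratic term on [0, 1];
  gene prior odds spread widely on the log scale for both class groups;
  intercepts centring the population near label balance so fitted
  probabilities stay informative; class mixture 0.73/0.12/0.15 giving the
  inframe offset adequate data.
* **ablation spec** — an LQTS-like population with strong gene signal
  (prior odds 45 / 4 / 0.2) and ±1.5-logit domain effects, used to
  reproduce the qualitative nested-model ordering full > gene-only >
  genome-wide in cross-validated ROC area.

What passing these tests shows — and does not. They demonstrate that the
fitting stack recovers the generating process and that the model ranks
information sources as expected **when the data follow the model's own
assumptions**. Real variant tables have correlated predictors, curation
biases, and domain structure the generators do not emulate; synthetic
performance numbers are not estimates of clinical performance.

## Known limitations

* **Quadratic-coefficient identifiability.** On [0, 1] the best linear
  approximation to x² deviates by at most 1/8, so the data barely
  separate linear from quadratic score terms: at n = 1,000 training
  variants the posterior sd of `β_p2`/`β_g2` is ≈0.5–0.7 under any
  covariate design. Point recovery of these coefficients at that sample
  size is correspondingly loose (their *sum* with the linear term is well
  identified, and predictions are unaffected); recovery experiments
  should be read with this in mind.
* The published headline cross-validation metrics (73% of pathogenic
  variants above P = 0.9; sensitivity 0.76 with PPV 0.999 over the three
  major LQTS genes) require the curated training tables and full-scale
  MCMC; this package ships the machinery and synthetic surrogates, not
  those tables.
* Variants are assessed individually: no oligogenic inheritance, modifier
  effects, severity prediction, or phenotype-modulated priors.
* Computing SIFT/PolyPhen/Grantham scores, orthologue alignments, or
  UniProt domain boundaries is out of scope; all are consumed as
  annotations.
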
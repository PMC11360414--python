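# Methods

## The model

`skinbn` implements a defined approach for skin sensitization potency: a
discrete Bayesian network that turns per-substance NAM (new approach
methodology) and physico-chemical inputs into a posterior probability
profile over the four LLNA potency classes — NS (non-sensitizer), weak
(EC3 ≥ 10%), moderate (2% < EC3 < 10%) and strong/extreme (EC3 ≤ 2%) —
and derives from that profile a continuous point of departure, category
predictions at three granularities (4-class, UN GHS, binary hazard) and a
weight-of-evidence confidence level.

The default network has 18 nodes: 13 observable inputs, four latent
summary variables and the 4-state target.  Three physico-chemical inputs
(molecular weight, clogP, volatility) parent a *bioavailability* latent;
the TIMES-SS call parents a *metabolism* latent; DPRA cysteine depletion
and the three KeratinoSens readouts (EC1.5, IC50, Imax) parent a
*cysteine reactivity* latent; the three U-SENS readouts (EC150, CV70,
call) parent a *U-SENS* latent.  The four latents, the ToxTree reactivity
domain, and DPRA lysine depletion parent the target.  The structure is
supplied, never learned; the shipped wiring is one defensible reading of
the latent-summary idea, and every aspect of it (input roster, arcs,
latent cardinalities, category levels) can be replaced through a YAML
config of the same shape, so a different wiring is a configuration change.

Key modelling assumptions: all variables are categorical (quantitative
inputs are discretized first); latent nodes are never observed; missing
or inconclusive inputs are *absent evidence*, not a category of their own,
which is what lets the network produce a calibrated posterior from any
subset of inputs.

## Discretization

Quantitative inputs are cut into 2–3 ordered categories by Fayyad–Irani
MDLPC against the 4-class training labels: recursive binary splitting at
the information-gain-optimal boundary midpoint, each split accepted only
if its gain exceeds the MDL encoding cost, recursion capped at
`max_bins = 3` categories by keeping the largest-gain splits.  Intervals
are half-open `[low, high)`, so a value equal to a threshold joins the
upper category.  The procedure is deterministic, and on small instances it
is tested to coincide with an exhaustive-scan oracle that considers every
midpoint, not only class-boundary ones.  A variable whose labels carry no
signal gets no thresholds (a single category) and is effectively inert in
the network.

## Parameter learning

CPTs are fitted by Expectation-Maximization.  The E-step computes exact
expected family counts per record; when the per-record unobserved space
(latents plus missing inputs) is small — the typical case, roughly
3⁴ × a few missing inputs — it enumerates that space with vectorized
table lookups, otherwise it falls back to per-family variable elimination
(both paths are tested to agree to float precision).  The M-step
re-estimates each conditional distribution from the counts with an
additive pseudocount (default 1.0, Laplace).  CPTs are initialized from
per-row uniform Dirichlet draws of a seeded generator, making fitting
bit-reproducible from `(records, seed)`.

Because the M-step maximizes a Dirichlet-penalized expected complete
log-likelihood, the quantity that is guaranteed monotone under MAP-EM is
the penalized objective `LL + pseudocount · Σ log θ`, not the raw
observed-data log-likelihood (which can dip by ~1e-3 near convergence).
The implementation asserts monotonicity of the penalized objective at
every iteration and uses it for the stopping rule (default: improvement
below `tol = 1e-6`, `max_iter = 500`); the raw log-likelihood is reported
in the training metadata.  Class priors for the Bayes factors are the raw
empirical training frequencies; pseudocount smoothing is applied to them
only if a class is entirely absent, to keep the prior odds finite.

## Inference

Posteriors are exact, by variable elimination with a greedy
smallest-intermediate-factor ordering.  `enumerate_joint` sums the full
joint over all completions (refusing above 10⁷ states) and serves as the
independent oracle: the test suite checks agreement within 1e-9 on
hundreds of random small networks.  Evidence on latent or target nodes is
a contract error; empty evidence returns the model's target marginal.

## Derived quantities

* **PoD**: `PoD = p_NS·100 + p_weak·10 + p_moderate·2 + p_strong·0.2` (%),
  bounded in [0.2, 100].  The weights are the EC3-scale anchors of the
  classes and are configurable but strictly-decreasing by contract.
* **Predicted class**: argmax of the profile; ties break toward the more
  potent class (conservative for risk assessment).
* **Confidence**: per class, GBF = posterior odds / prior odds,
  W = 10·log₁₀(GBF) deciban; the level follows the maximum W with
  Jeffreys-style bands — below 5 "low", 5–10 "moderate", 10 and above
  "high", boundary values joining the higher bin.  Posteriors are clamped
  to `[1e-12, 1 − 1e-12]` before the odds so degenerate profiles give
  finite W.  Published worked examples are reproduced at the *category*
  level; their individual W values are not exactly recoverable from
  4-decimal printed profiles with empirical priors, so categories, not
  decimals, are the contract.  Profile validation accepts a sum deviation
  of 1e-3 for the same reason (printed 4-decimal profiles can sum to
  1.0001); the network's own posteriors satisfy 1e-9.

## Evaluation

Contingency tables are predicted × reference counts at 4-class, GHS and
hazard granularity (the collapses NS→NoCat→NS, weak/moderate→Cat1B→S,
strong/extreme→Cat1A→S commute with counting, so accuracy is monotone
non-decreasing under collapsing).  Hazard tables additionally yield
sensitivity, specificity and balanced accuracy; an empty reference margin
marks the metric undefined rather than zero.  PoD/EC3 conservatism uses
ratio bands `[0.316, 3.16]` (±10^0.5-fold, endpoints inclusive, constants
taken as given from LLNA variability analyses) and
GMFE = 10^mean(|log₁₀ ratio|).  Pearson correlation is computed on raw
percent values by default with a log10 option; Spearman is rank-based.
Stratified k-fold cross-validation shuffles within class from a seed and
deals records round-robin, guaranteeing per-fold class counts within one
of exact proportionality; each fold refits discretization and CPTs from
scratch.

## Synthetic data

No public substance-level dataset accompanies the approach, so the
generator emulates its statistical shape: class labels from the
training-set marginal (69, 39, 47, 64)/219; EC3 log-uniform inside each
class band ([10,100], (2,10), [0.0003,2]; NS fixed at 100%); continuous
readouts from class-conditional log-normal (logistic-normal for the
bounded DPRA depletions) distributions whose location shifts monotonically
with potency; categorical calls from class-conditional tables; independent
per-field missingness at rates mirroring the reported incompleteness
(DPRA 0.18, TIMES-SS 0.18, volatility 0.06, others 0.01).  `effect_size`
linearly scales every class-location shift: 0 makes all inputs
class-independent.  The default separation was chosen once so that the
default pipeline reaches 4-class accuracies in the broad vicinity of
those reported for real data (the 500/200 train/test harness used in the
tests sits around 70%).

What the generator does *not* emulate: real chemical classes and their
correlated assay failure modes (e.g. acrylates), between-assay
correlation beyond what the class label induces, informative missingness,
and the true marginal distributions of the inputs (not published).
Passing end-to-end tests therefore demonstrates that the machinery —
discretization, EM with latents and gaps, exact inference, the derived
quantities — recovers a signal of the assumed form; it is not a validation
claim about real substances.

The null-signal check runs with a *uniform* class marginal: with the
skewed default marginal a signal-free model correctly predicts the
majority class ~31.5% of the time, so balancing the classes is what makes
"chance" exactly 25% and the check meaningful.

## Problem sizes and numerical choices

Test and acceptance harnesses use deliberately desk-sized conditions:
500 train / 200 test records for the end-to-end property, 300 records for
5-fold cross-validation, 2000 records for parameter recovery on a known
4-node latent model, EM capped at 25–300 iterations with `tol` 1e-3–1e-8
depending on the harness.  Seeds are fixed everywhere; reruns are
bit-identical.  Floats are serialized with shortest-round-trip (`repr`)
or 17-significant-digit formatting, so model YAML and CSV outputs
round-trip losslessly.

## Known limitations

* The PoD floor of 0.2% systematically underpredicts the most extreme
  sensitizers (reference EC3 down to 0.0003%); the ratio analysis makes
  this visible rather than hiding it.
* EM on deep latent structures finds local optima; different seeds can
  give different (equally valid) latent parameterizations.  Only
  latent-marginalized functionals are identifiable, and only those are
  tested for recovery.
* With 2–3 categories per input, the target CPT over six parents is large
  relative to a few hundred training records; pseudocount smoothing keeps
  estimates proper but shrinks extreme probabilities toward uniform.
* A single-category (unsplittable) input contributes nothing; this is by
  design, not failure.
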
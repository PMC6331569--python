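# Methods

## Scope and approach

The package estimates pairwise niche differences (ND) and relative fitness
differences (RFD) from mutual-invasion assays, phylogenetic distance
predictors from a user-supplied Newick tree, and per-microcosm invasion
success and impact from a factorial microcosm experiment, and relates the
predictors to the outcomes with fixed-effects regressions compared by AIC.
Every stage can be exercised against a fully synthetic world whose ground
truth is known, so correctness claims rest on closed-form oracles rather
than on any external dataset.

## The synthetic world

**Community dynamics.** Ground truth is multispecies Lotka–Volterra
competition, `dN_i/dt = r_i N_i (1 - sum_j alpha_ij N_j / K_i)`. This is the
canonical model in which the invasion-growth-rate definitions of ND and RFD
have closed forms, which is what makes oracle testing possible. Integration
uses LSODA with relative tolerance 1e-8 and absolute tolerance 1e-3 CFU/mL
(the inoculation events introduce abrupt state jumps); output densities are
clipped at zero. Inoculations are timed density additions; a sample that
coincides with an event reports the pre-event state (sample first, then
inoculate). A single-species run tracks the logistic closed form to better
than 1e-4 relative error over 96 h.

**Phylogeny and traits.** Trees are pure-birth (Yule, unit birth rate)
simulated with dendropy and rescaled to root depth 1 — only relative
distances matter downstream. The simulator stops at the n-th speciation,
which leaves the newest tip pair with zero-length pendant edges; every tip
branch is therefore extended by one Exp(n) waiting time (the time to the
next would-be speciation) so that all pairwise patristic distances are
positive. Two traits evolve independently on the tree: a *niche* position
and a *fitness* value, either by Brownian motion (variance `rate * branch
length`; root value 0) or as i.i.d. white noise at the tips. Under Brownian
evolution patristic distance predicts squared trait distance; under white
evolution it does not — this toggle is the knob that controls whether the
phylogeny is ecologically informative in the synthetic experiment.

**Traits to parameters.** Competition is a Gaussian kernel in niche space,
`alpha_ij = exp(-(z_i - z_j)^2 / (2 w^2))` with unit diagonal, so identical
niches give alpha = 1 and distant niches give alpha → 0. Carrying capacity
is `K_i = K_base * exp(K_sensitivity * f_i)`; growth rates are uniform on
`r_range`.

**Defaults (chosen once, not tuned).** Eight natives and three invaders,
every monoculture and two-species native polyculture, 15 replicates per
composition split 3 (destructive pre-invasion) / 3×3 (invaded) / 3
(control) — 36 compositions and 540 microcosms; natives inoculated at hour
0, invaders at hour 48, final sampling at hour 96; assay samples 6 h and
14 h post-introduction. Inoculation is a 10 µL transfer of a 1e6 CFU/mL
stock into 6 mL of medium (≈1667 CFU/mL; low-density stocks at 1e5 CFU/mL
use 100 µL, giving the same initial density), kept below 2% of carrying
capacity by construction and enforced at run time. `K_base = 1e9` CFU/mL is
a typical saturated-broth density; `K_sensitivity = 0.3` yields ~2-fold K
spread; `r` uniform on 0.3–0.7 1/h corresponds to doubling times of 1–2.3 h
at room temperature; niche width 1.0 against Brownian trait rate 1.0 on a
depth-1 tree gives competition coefficients spanning essentially (0, 1).

**Observation model.** Plate counts at five serial dilutions (1e2…1e6) of a
0.1 mL plated volume, `colonies ~ Poisson(density * volume / dilution)`,
independent across dilutions. No plating-efficiency, colony-overlap or
miscounting effects are modelled. Replicate microcosms share the same
deterministic truth and differ only through this observation noise — a green
round-trip test therefore establishes that the estimation chain inverts the
observation model, *not* that it is robust to biological replicate
variation, demographic stochasticity, evolution during the experiment, or
spatial structure, none of which are simulated.

## Estimation pipeline

**Densities.** `density = colonies * dilution / volume` at each countable
dilution (30–300 colonies, the standard plating convention), averaging when
several qualify. With no countable plate the count nearest the range is
used (ties broken toward the smaller dilution, i.e. the larger count);
all-zero counts give density 0 with a below-detection flag that propagates
as an undefined growth rate.

**Sensitivities.** Growth rates are two-point log slopes between the two
assay samples — a deliberate choice over growth-curve fitting, since the
assay window is within exponential phase by design. Replicate rates are
arithmetically averaged per context *before* sensitivities are formed
(average-then-ratio; the two orders differ in general and tests pin this
one). A non-positive `mu_alone` makes the sensitivity undefined (flagged)
rather than signed: the geometric-mean ND downstream needs interpretable
signs.

**ND/RFD.** `ND = 1 - sqrt(S1*S2)`, `RFD = sqrt(S2/S1)`, both requiring
S1, S2 > 0. Pairs with non-positive sensitivities (facilitation, or noise
flipping a small sensitivity negative) are flagged invalid and excluded
from community aggregation and regressions; the exclusion is visible in the
pairwise table. RFD is analysed on its ratio scale; impact can optionally
be computed on ln(x+1) densities, but raw CFU/mL is the default. Community
aggregation defaults to the arithmetic mean over the natives present, with
`closest` (by patristic distance) and `most_abundant` alternatives for
robustness checks; under these, MPD/ND/RFD all refer to the single chosen
native.

**Phylogenetics.** Patristic distance is the branch-length sum on the leaf
path (root-invariant, so arbitrarily rooted input is safe); MPD is the mean
PD from invader to community members; out-group labels are pruned on read.
The Mantel test correlates upper-triangle entries and permutes rows/columns
of the second matrix jointly, one-sided, with `p = (hits + 1) /
(permutations + 1)` and a default of 999 permutations; it is implemented
in-package for seed determinism and cross-checked against scikit-bio.

**Outcomes.** Establishment is `density >= detection limit` (default 1e2
CFU/mL, the nominal floor of the lowest dilution; the boundary is
inclusive). Abundance `ln(x+1)` is analysed for established microcosms
only. Impact compares each invaded replicate against the *mean* of the
control replicates of its composition (per-replicate pairing is available
but there is no natural pairing in a randomized layout).

**Inference.** OLS and binomial GLM (IRLS, tolerance 1e-8) via statsmodels.
Complete separation in logistic fits is detected (perfect classification or
runaway coefficients) and reported as a flag with no estimates. Model
comparison fits the intercept-only model and all 15 non-empty subsets of
{SR, MPD, ND, RFD} on z-scored predictors, ranks by AIC, and reports the
best univariate model separately. Random-effect / phylogenetic-covariance
structures are deliberately out of scope: the fixed-effects + AIC route
keeps every fit closed-form testable. No multiple-testing correction is
applied, and the report says so.

## Numerical and design choices

- Time unit hours, rates 1/h, densities CFU/mL throughout.
- All randomness flows from integer seeds through `numpy.random.Generator`
  (and `random.Random` for the tree simulator); identical seeds give
  byte-identical design tables, count tables and reports.
- The detection limit, countable range, dilution ladder, plated volume,
  aggregation rule and control summarisation are configuration values, not
  constants.
- Degenerate inputs fail loudly: rank-deficient design matrices name the
  collinear columns, single-class responses and constant distance matrices
  raise, unknown species in a design table raise KeyError.

## Known limitations

- The linearised sensitivity oracle (`S1 = alpha_IN K_N / K_I`) assumes the
  resident sits at its single-species equilibrium and the assay window stays
  in the focal species' exponential phase; very large alpha or very slow
  residents would bias the two-point slope.
- ND/RFD are short-term growth-rate quantities while success and impact are
  long-term outcomes; in the synthetic world both derive from the same LV
  parameters, which overstates how tightly they must be linked in real
  communities.
- The AIC model comparison treats microcosms as independent observations;
  shared invader identity and phylogenetic non-independence are not
  modelled.
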
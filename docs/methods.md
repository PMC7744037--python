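# Methods

## The model

A Markov-modulated model (MMM) couples K component substitution processes
through a hidden switching chain. Component k is a time-reversible CTMC on
the character alphabet (S states) with generator

    Q_k[i, j] = pi_k[j] * R_k[i, j]   (i != j),

where `R_k` are symmetric exchangeabilities and `pi_k` the component's
stationary frequencies. Every `Q_k` is rescaled so that the expected number
of substitutions per unit time at its own stationarity is one
(`-sum_s Q_k[s, s] pi_k[s] = 1`), which makes branch lengths and the
per-component rate multipliers `rho_k` interpretable in substitution units.
Presets cover JC, HKY (kappa on the two transitions), and GTR (six free
exchangeabilities); the alphabet is configurable, so amino-acid components
work unchanged.

Switching among components is a K-state CTMC `Phi` with free nonnegative
off-diagonal rates `phi_ij` (symmetric/triangular or fully asymmetric
structure) and stationary weights `Psi`. There is no separate global
switching-rate parameter: the `phi_ij` live directly on the substitution
time scale, and a diagnostic reports the implied stationary switch rate
`sum_k psi_k * (-Phi_kk)`.

The compound process lives on the KS states (model, character):

    Lambda = sum_k E_kk (x) (rho_k Q_k) + Phi (x) I_S.

From (k, s) the chain substitutes within model k at rate `rho_k Q_k[s, s']`
or switches to (k', s) at rate `phi_kk'`. By default the multipliers are
renormalized so `sum_k psi_k rho_k = 1`, keeping branch lengths equal to
expected substitutions per site at stationarity (switches change no
characters and are not counted). The covarion preset is the K = 2 special
case with a silent second component (`rho = (1, 0)`); it disables the
renormalization so the generator keeps the classic block form
`[[Q - s01 I, s01 I], [s10 I, -s10 I]]`.

### The stationary distribution is not the product form

A natural guess for the stationary distribution of `Lambda` is the product
form `(psi_1 pi_1, ..., psi_K pi_K)`. It satisfies `Pi Lambda = 0` **only
when every component shares one frequency vector**: the switching blocks
`phi_kk' I` carry characters across blocks whose equilibria disagree,
leaving a residual `sum_k psi_k phi_kk' pi_k[s]` that vanishes only if
`pi_k[s]` is constant in k. The package therefore computes the exact
stationary distribution as the normalized left null vector of `Lambda`
(`compound_stationary`); the product form remains available as
`product_form_stationary` and is used when the switching chain is
reducible (e.g. the zero-switching limit), where `Psi` acts as fixed
mixture weights rather than a stationary law. Root frequencies in the
likelihood are the exact stationary distribution; no separate
root-frequency parameter exists.

## Likelihood

Felsenstein pruning over the KS compound states. A tip contributes an
indicator over compound states whose character component is compatible
with the observed symbol — hidden model categories are always integrated
out at the tips, and IUPAC ambiguity codes and gaps light several (or all)
character states. Transition matrices are `expm(t * Lambda)`; because
`Lambda` is generally non-reversible and non-symmetric, the implementation
eigendecomposes once per parameter value and falls back to
scaling-and-squaring Pade whenever the eigenvector basis is
ill-conditioned (condition number above 1e8) or fails a reconstruction
check. All (category, branch) matrices are produced in one batched
operation, and gamma categories ride through the pruning pass as a batch
axis.

Identical alignment columns are collapsed to patterns before pruning.
Per-pattern scaling accumulators guard against underflow: whenever a
partial-likelihood row drops below 1e-100 it is renormalized and the log
factor stored, so deep trees return finite log-likelihoods.

ASRV is the standard mean-one discrete gamma: n equal-probability
categories represented by conditional means computed in closed form from
regularized incomplete gamma functions (medians are available as an
option; means are the default, matching the common choice in reference
implementations). The category rate rescales branch time for the whole of
`Lambda` — substitution and switching alike — matching standard
covarion-plus-gamma practice; scaling only the substitution blocks would
decouple the two time scales per site and is deliberately not offered.
When ASRV is superimposed, all `rho_k` are pinned to 1; a free overall
rate multiplier per component is not identifiable jointly with a
site-specific rate mixture.

## Simulation

Forward Gillespie simulation per site: root compound state drawn from the
exact stationary distribution, then competing-exponential jumps down each
branch, recording every event. Sites are independent (matching the
likelihood's independence assumption); each site owns a counter-based
Philox stream keyed by (seed, site index), so enlarging an alignment never
reshuffles earlier sites. With ASRV each site first draws its category,
whose rate rescales branch time.

## Inference

Parameters are organized into named blocks (one per distinct
exchangeability set, frequency set, plus multipliers, switching rates, and
the gamma shape) mapped to unconstrained coordinates: log for positive
blocks, Stan-style stick-breaking for simplexes. ML fits run L-BFGS-B in
that space with numerical gradients; redundant scale coordinates (the last
GTR exchangeability, the first multiplier under renormalization) are
pinned during ML.

MCMC is Metropolis-within-blocks in the unconstrained space, targeting
`beta * logL + log prior + log |Jacobian|`. Each iteration updates one
block with either a Gaussian random walk or an independence draw from the
prior (acceptance then reduces to the likelihood ratio to the power
`beta`); the mixture keeps chains mobile both near the prior (where the
random walk is too local) and near the posterior (where prior draws are
almost always rejected). The prior-proposal probability rises toward one
as `beta -> 0`. During burn-in the random-walk scales adapt toward a 30%
acceptance rate and are then frozen, so the sampling phase uses a fixed
kernel.

Default priors (all overridable): Dirichlet(1) on frequency sets,
Gamma(0.5, 1) on switching rates and GTR exchangeabilities,
Lognormal(0, 1) on kappa and on free multipliers, Exponential with mean 3
on the gamma shape (read "Exponential(1/3)" as rate 1/3; the prior must
cover the empirically common shape range 0.1–5). Exchangeable identical
components make the posterior multimodal by label switching; ML reports
are matched to truth up to component permutation, and MCMC summaries of
exchangeable components should be read per ordered statistic.

Marginal likelihoods use stepping-stone sampling: rungs at quantiles of
Beta(0.3, 1) (dense near the prior), each ratio estimated by importance
sampling from the lower rung, chains warm-started up the ladder. A
generalized stepping-stone with posterior-matched reference distributions
is out of scope; the standard estimator's per-rung standard errors are
reported so divergent rungs are visible. Validation against 1-D quadrature
(a model whose only free parameter is the gamma shape) shows the
estimator's known downward bias at coarse ladders: with 16 rungs and
short chains the absolute log-ML carries a bias of several log units on
hundreds of sites, largely shared between models of similar size, so
*differences* (log Bayes factors) are far more reliable than absolute
values, and at small true differences the sign is noisy. The reported
per-rung SEs assume independent samples and understate the error of
poorly mixing rungs.

## Hidden-state reconstruction

Joint MAP realizations come from max-product dynamic programming over
compound states with the stationary root weights; ties break toward the
lowest compound index (lowest model, then lowest character), making
results deterministic. With ASRV the site's rate category is maximized
over as well. Marginal model posteriors come from an inside-outside pass
and are averaged over categories with per-site posterior category weights.

Switch counting defines the model state of a branch as the model index at
its child node; a site's switch count is the number of edges whose
endpoint model indices differ. A switch that occurs and reverts within a
single edge is invisible to this summary — the optional expected
dwell-time output (`branch_dwell_times`, computed exactly via the Van
Loan block-exponential integral conditional on the endpoint states)
recovers that information in expectation.

## Synthetic study conditions

The benchmark conditions (`mmphylo.benchmarks`) emulate the regime the
model family targets: two nucleotide processes with strongly divergent
GC content (frequencies (0.1, 0.4, 0.4, 0.1) vs (0.4, 0.1, 0.1, 0.4)),
distinct transition/transversion ratios (4 and 8) or distinct GTR
exchangeability sets, asymmetric switching at rates (0.4, 0.2) per
substitution-time unit, gamma shape 0.5, and random Yule-like 8-taxon
trees with exponential branch lengths of mean 0.15–0.3. Problem sizes:
parameter recovery uses alignments of 5,000 sites; model selection uses
1,000 sites with 16-rung stepping stone and 700-iteration chains per
rung; reconstruction-recovery uses 2,000 sites.

What the generator does and does not emulate: per-site independence holds
exactly (no indel process, no alignment error, no site-to-site switching
correlation, no selection); passing recovery tests therefore demonstrates
correctness of the estimation machinery under the model's own
assumptions, not robustness to the model misspecification real data
carry.

## Numerical choices and edge cases

- Simplex validation at 1e-12; generator row sums certified to 1e-10.
- Zero-length branches yield identity transition matrices; zero-time
  requests short-circuit the exponential.
- Reducible switching chains are rejected unless explicit mixture weights
  are supplied (`allow_reducible`), which is how the zero-switching limit
  is expressed.
- A site whose observations are impossible under the model returns
  -inf for that site only; rescaling guarantees this happens only when
  the likelihood is exactly zero.
- The discrete-gamma category count is not inferred; four categories is
  the default everywhere.
- K > 9 components cannot be written in the digit-based notation and
  require an explicit config.

## Known limitations

- Topology and branch lengths are fixed inputs; no tree proposals, no
  molecular clocks.
- The stepping-stone estimator at coarse ladders biases absolute log-ML
  estimates downward (see above); increase `n_steps` and chain lengths
  when absolute values matter.
- Codon presets are absent (the state-space machinery accepts S = 61).
- Endpoint-conditioned path *sampling* (stochastic mapping) is not
  implemented; dwell times are expectations, not samples.
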
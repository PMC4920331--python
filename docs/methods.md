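# Methods

## The model

A fossilized birth–death (FBD) process starts from one lineage at
origin time *T* (Myr before present, 0 = present). Lineages speciate at
rate λ, go extinct at rate μ, and shed fossil observations as a Poisson
process with rate ψ; every lineage alive at the present is sampled
(extant-sampling probability ρ is fixed at 1, and sampled fossils are
never removed from the process). The model is exposed in the
(T, d, r, s) parametrization — net diversification d = λ − μ, turnover
r = μ/λ, sampling proportion s = ψ/(μ + ψ) — with d > 0, 0 ≤ r < 1,
0 ≤ s < 1. Pruning the complete tree to the sampled taxa yields a
sampled-ancestor tree: fossils with sampled descendants become
degree-two nodes, encoded throughout (in memory and in Newick) as tips
on zero-length branches attached to a binarized attachment node.

Characters evolve by the k-state Mk process with equal exchange rates.
The generator is normalized so a branch's rate is the expected number
of state changes per Myr at stationarity (off-diagonal entries
rate/(k−1)); this makes rates comparable across state counts. The state
space of each character is its set of *observed* states, recoded to
0..k−1 (gaps in the coding collapse); characters that are constant or
entirely missing resolve to k = 2, the minimal valid space, and are
never dropped. All characters are treated as unordered. Root state
frequencies are uniform 1/k; "?" marginalizes over all states;
polymorphic cells marginalize over the listed states. Rate variation
across characters uses 4 equal-probability discrete-gamma categories
(category means); no ascertainment correction is applied by default,
with a variable-characters-only (Mkv) correction available behind a
flag — the plain-Mk default and the category count are assumptions, as
tools in this space differ and neither choice affects the package's
internal consistency checks. The UCLN relaxed clock draws each branch
rate from a lognormal with real-space mean μ_clock and log-sd S,
realized through per-branch quantiles so that S → 0 collapses exactly
to the strict clock.

## The sampling-time density and its closed form

Conditional on survival of the process, the density of observing a
fossil at age t is

    f(t) = (1 − p0(T))⁻¹ · Σ_{k≥1} k ψ p_k(T−t) (1 − p0(t)^k),

where p_k(t) are the linear birth–death transition probabilities:
p0 = r·η, p_k = (1−p0)(1−η)η^{k−1} with η(t) = (1−e^{−dt})/(1−r e^{−dt}).
Because the lineage count is geometric, the sum collapses:

    Σ_k k p_k(τ) (1 − a^k) = (1 − p0(τ)) [ 1/(1−q) − (1−q)·a/(1−q·a)² ],

with τ = T−t, q = η(τ), a = p0(t). The closed form is the production
path; the truncated series (tail bound 10⁻¹², hard cap 10⁶ terms) is
retained as an oracle and the two agree to 10⁻⁸ relative error across a
broad parameter grid. For large d·τ the identity
(1−p0(τ))/(1−q(τ)) = e^{dτ} is used to avoid underflow; extreme draws
that overflow double precision are normalized in log space on a
geometric grid.

Interval probabilities are the adaptive-quadrature integral of f over
[l, u] divided by the integral over [0, T]. For probabilities under a
*prior* on the FBD parameters, each draw's density is normalized on its
own [0, T] and draws are averaged with equal weight — the hypotheses
concern the age of one given fossil, so each draw contributes one
normalized age distribution; draws whose T < l contribute zero. The
alternative — pooling raw intensities, which weights draws by their
expected number of fossils — is available (`normalize_per_draw=False`)
and is the mode in which the contrast between the broad explicit prior
and the implicit prior is dramatic: under the broad prior, rare
large-d·T draws dominate the pooled curve and leave essentially no
mass at old ages, which is exactly why that prior forces huge Bayes
factors and motivates the implicit construction.

Implicit priors: ψ ~ lognormal(−2, 1) with s = ψ/(μ+ψ) derived, and
N ~ Uniform(1, 100) on the number of present-day species with
T = ln(N)/d derived (the process has e^{dT} species in expectation).
Draws on the N = 1 boundary (T = 0, a zero-height process that admits
no fossils) are rejected and redrawn. The gamma(0.5396, 0.3819) prior
on S treats the second parameter as a rate.

## The tree density and the sampler

The FBD density of a sampled-ancestor tree conditioned on survival is
assembled from q(t) and p0(t) of the three-rate process (ρ = 1): a
factor q(T)/(1−p0(T)) for the origin, 2λ·q(x) per bifurcation,
ψ·p0(y)/q(y) per fossil tip, and ψ per sampled ancestor. Constants
fixed by the sampled configuration (labelling, permutations) are
dropped as they cancel in MCMC. The factor 2 per bifurcation is the
labelled-tree convention — two orientations collapse onto one labelled
topology — and is *not* a constant here, because a fossil switching
between tip and sampled-ancestor configurations changes the bifurcation
count; getting it wrong biases the sampled-ancestor frequency
detectably. The implementation is validated two ways: with ψ = 0 it
reduces exactly to the survival-conditioned birth–death density on
extant tips, and characters-free MCMC reproduces the joint distribution
of ages, parameters and sampled-ancestor frequency obtained by
forward-simulation rejection sampling.

The sampler is Metropolis–Hastings over a fixed reference topology:
scale moves (multiplicative, with the log-factor Hastings term) on d,
ψ-or-s, T, μ_clock, S and the gamma shape; reflected-window moves on
the unit-interval parameters; uniform draws within the current valid
interval for node ages and fossil ages (the interval is determined by
the neighbours, so the proposal is symmetric); and a reversible-jump
attachment move per fossil that proposes either a new attachment age
uniformly on its branch or, with probability 0.5, collapse to the
sampled-ancestor configuration — the interval length enters the
acceptance ratio to account for the lost continuous dimension. A
sampled ancestor's age and attachment age move jointly. The focal
fossil receives extra move weight, since its marginal is the estimand.
Proposal scales adapt toward ~25% acceptance during burn-in (default
25% of the chain, discarded) and are frozen afterwards to preserve
detailed balance. Runs are deterministic given the seed.

Fixing the topology (to the simulation truth in tests, or a
user-supplied reference tree) is a deliberate narrowing: it makes every
MCMC check verifiable against rejection sampling at the same
configuration. Fossil attachment *age* and ancestor-vs-tip status are
still sampled; full topology search is out of scope. One consequence,
measured directly: the prior distribution of the focal age *given* a
fixed configuration differs from the population-level analytic
sampling-time density (conditioning on where the fossil sits truncates
and tilts it). The Bayes-factor pipeline therefore follows the method's
definition — analytic prior probability in the denominator — while the
"no data ⇒ no evidence" identity is checked against a matched
prior-only chain, which is the internally consistent prior for a fixed
configuration.

Initialization: node ages from the reference tree, non-focal fossil
ages moved to their range mid-points where the tree permits, parameters
at prior medians, origin just above the root (clamped into the implicit
prior's support, lowering initial d if needed). A zero-probability
initial state raises immediately with a diagnosis rather than starting
a doomed chain.

## Evidence and summaries

Posterior range probabilities are post-burn-in trace fractions; prior
range probabilities average the normalized analytic density over prior
draws. BF = posterior odds / prior odds; log is natural; posterior
probabilities of exactly 0 or 1 are clamped to 1/(2n) with a flag
rather than reported as infinite. Support categories: strong_against
(< −3), negative (< 0), positive (≥ 0), strong_for (> 3). HPD is the
shortest interval over sorted samples containing ⌈0.95n⌉ of them. ESS
uses the initial-positive-sequence rule (autocorrelations summed until
the first non-positive consecutive pair). Error is |phylogenetic median
− geological mid-point|; relative error divides by the mid-point; RSD
is posterior sd / posterior median; precision is 1/variance. R² is the
squared Pearson correlation between phylogenetic medians and geological
mid-points (identical to regression R² with intercept in the simple
linear case).

## Synthetic data

The generator is the model itself — forward FBD simulation plus Mk
character evolution — so passing tests demonstrate *internal
consistency* (correct inference under the generating model), the same
property the method's empirical studies probe, but they cannot detect
model misspecification present in real matrices: correlated characters,
ordered states, ascertainment toward variable characters, non-lognormal
rate variation, or stratigraphic ranges whose mid-points are biased
away from true ages. Two presets emulate the empirical study systems:
`penguin_like` (~19 extant + ~36 fossil taxa, origin 65 Myr, d = 0.045,
r = 0.5, s = 0.65, 202 characters from binary to k = 7 with ≥95% below
four states, strict clock 0.0179 changes/Myr) and `canid_like`
(9 extant exactly + ~116 fossil taxa, origin 37 Myr, d = 0.0594,
r = 0.5, s = 0.93, 122 characters up to k = 5, clock 0.0283). The FBD
settings were chosen so e^{dT} matches the extant-taxon targets and
ψ × expected tree length matches the fossil counts, with rejection
sampling to ±20% of the targets (exact for the canid extant count);
clock rates match the per-Myr morphological rates the method reports on
the real datasets. Stratigraphic ranges are intervals of configurable
half-width (default ±2.5 Myr) containing the true age, clipped at zero,
with an optional uniform jitter of the mid-point; how real range
mid-points relate to true ages is unknown, so jitter is off by default.

## Problem sizes and numerical choices

Test and acceptance runs are sized for a single CPU: density oracles on
a 27-point parameter grid × 100 ages; simulation agreement on 10⁴
surviving trees; Kendall checks on 2×10⁴ Gillespie replicates per grid
point; likelihood oracle on 100 trees of ≤5 tips (enumeration is
exponential in tree size); prior-only calibration on a two-extant,
one-fossil configuration with ~2.5×10³ rejection samples against a
1.5×10⁵-step chain; coverage on 50 penguin-like replicates at ~30 taxa
× ~111 characters with 4×10⁴-step chains; the evidence experiment on 20 replicates and the
precision-vs-characters experiment on medians over 16 small replicates
per character count (per-dataset precision curves are noisy; the trend
is an aggregate property). Likelihood
evaluation is a numba-compiled pruning kernel over characters grouped
by state count, with per-node rescaling below 10⁻¹⁰⁰; the cached
posterior is refreshed from scratch every 5×10³ iterations and checked
against a full recompute in tests (agreement to 10⁻⁶ after 10⁴ moves).
Floating-point equality of a fossil's age with its attachment age is
the sampled-ancestor indicator; moves assign the shared value exactly,
so no tolerance is needed.

## Known limitations

Fixed topology (above); no molecular partitions; no skyline
(piecewise-constant) FBD rates; no ρ < 1 extant subsampling; no
stepping-stone marginal likelihoods (inapplicable when sampling times
are data); single specimen per fossil species; ESS on strongly
multimodal traces (tip/ancestor switching) is a crude summary; the
implicit prior on T conditions on d, so the pair (d, T) is sampled
jointly and mixes more slowly than either alone.
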
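# Methods

## Model and inference chain

The package treats a single-molecule FRET experiment on immobilized,
membrane-embedded receptors as a hierarchy:

* each **molecule** occupies one conformational state (compact or open) for
  the duration of its FRET window, with a state-specific donor lifetime
  drawn from a Gaussian component (means μ_k and widths σ_k shared across
  membrane conditions, amplitudes per condition);
* each molecule emits **photons** as Poisson processes whose rates change
  at two photobleaching events (acceptor first, then donor), with TCSPC
  nanotimes distributed as a Gaussian instrument response convolved with a
  mono-exponential decay, truncated to the laser period, plus a uniform
  background;
* the analysis inverts this generative picture stage by stage: segmentation
  recovers the bleaching structure, bunch-wise MLE recovers per-molecule
  lifetimes, and the global mixture fit recovers the state parameters and
  per-condition amplitudes.

### Decay likelihood

The signal nanotime density is the exponentially modified Gaussian

    f(t; τ, μ, σ) = 1/(2τ) · exp(−(t−μ)²/2σ²) · erfcx((μ + σ²/τ − t)/(σ√2)),

evaluated through the scaled complementary error function so that both the
IRF core and the deep exponential tail are computed without overflow (for
arguments beyond the erfcx range the density analytically reduces to the
pure exponential tail, which is used directly). The per-photon likelihood is

    p(t) = (1−b) · f(t)/Z + b/W,   Z = F(W) − F(0),

with W the TCSPC window and b the background fraction, *fixed* from a
separately characterized blank rather than co-estimated — with only 1000
photons per bunch, τ and b are strongly degenerate and co-estimation
inflates the lifetime variance. The MLE is a bounded 1-D optimization over
τ ∈ [0.05, 25] ns (deterministic; fits pinned at a bracket edge are flagged
unconverged and excluded). Nanotime discretization is ignored (counts are
treated as continuous times), an approximation that is negligible at the
16 ps channel width used here.

The generator draws nanotimes by the independent route — Gaussian plus
exponential variate, redrawn until inside [0, W) (no wrap-around) — and the
tests verify that the two routes agree (discrete KL < 10⁻³ at n = 10⁶),
so the estimator and generator share the same truncated model by
construction, not by code reuse.

### Segmentation and selection

Change points are found by recursive binary segmentation of the binned
Poisson counts. At each segment the split maximizing the generalized
likelihood-ratio statistic is tested against `n_sim = 199` constant-rate
traces simulated at the segment's fitted rate; the split is accepted when
the Monte-Carlo p-value falls below α (default 0.01). Ties break toward
the earlier index; the calibration RNG is seeded so segmentation is a pure
function of (counts, α, seed). One-bin segments whose rate lies between
their neighbours' rates are treated as parts of a step (a rate change
rarely falls on a bin boundary), not as separate intensity levels.

A molecule is accepted when each channel shows exactly one downward step
terminating at background — post-step rate within 3 Poisson standard errors
of the background rate — with the acceptor bleaching no later than the
donor and an acceptor pre-bleach rate at least 3× background (acceptor
actually present). The upward donor de-quenching step at acceptor bleach
is allowed. Neither the background tolerance nor the significance level is
reported for this kind of experiment in general, so both are configurable
with these defaults.

### Distance conversion

E = 1 − τ_DA/τ_D and r = R₀((1−E)/E)^{1/6}. Per-bunch lifetimes at or
above τ_D convert beyond the FRET range; in median computations they rank
as the largest distances (dropping them would bias medians short), and a
median landing on them is reported infinite and flagged. The beyond-range
flag fires at r > 1.5·R₀ by default: around 1.5·R₀ the efficiency is ~1/12
and dE/dr is so shallow that distances are no longer quantitative. The
threshold is per-dye-pair configurable because reported median-distance
tables are not perfectly consistent about where the star belongs near
11.6–12 nm at the two R₀ values. Confidence intervals are seeded percentile bootstraps
(10⁴ resamples by default) over the bunch lifetimes.

### Global mixture, BIC, Ashman's D

The mixture is fit on the *unbinned* per-bunch lifetime estimates
(histograms are display only); the joint likelihood over conditions shares
μ_k, σ_k and frees the amplitude vectors. EM with 20 seeded starts
(means from jittered pooled quantiles, Dirichlet amplitudes; each start
run 25 iterations, the best refined to convergence), a σ floor of 0.01 ns
against degenerate collapse, and a monotonicity assertion on the joint
log-likelihood at every iteration. Components are reported sorted by mean;
the **open** state is the largest-mean component (longer lifetime = less
transfer = farther from the membrane). Free-parameter count for BIC is
p = 2k + (k−1)·n_conditions and n is the total bunch count across
conditions. Gaussians are untruncated although lifetimes are positive; at
the fitted parameters the mass below zero is ~10⁻⁴ and ignoring it keeps
the M-step closed-form. Amplitude uncertainties come from the observed
information matrix (numerical Hessian of the joint log-likelihood at the
MLE). ANOVA comparisons are classical one-way F tests with significance
called at p ≤ 0.001.

### Trajectory metrics

Contact number: all lipid beads vs all beads of the ATP-site residues
(694–703, 719, 766–769, 772–773, 817, 820, 831), counting pairs at
minimum-image distance strictly below 16 Å (the cutoff corresponds to the
molecular radius of the fluorescent ATP analogue whose binding the contact
number predicts). A kd-tree candidate search is followed by an exact
distance filter, so the count equals the O(N²) definition — verified
against a brute-force oracle in the tests. The residue 721–1186 distance
uses residue centroids by default (beads re-imaged relative to the first
bead of the residue), with a `mode="first"` backbone-bead option; which
bead convention reported analyses use is typically unstated.

WHAM solves the standard self-consistent equations on a 1-D histogram
until the largest window free-energy change is below 10⁻⁸, reports the
PMF up to an additive constant fixed at zero at its minimum, diagnoses
non-overlapping window sets via connected components of the
shared-occupied-bin graph, and reweights per-sample observables with
w_i ∝ 1/Σ_w N_w exp(f_w − u_w(x_i)). The iteration is written for one
collective variable; multi-dimensional biasing reduces to the 1-D case
here and is a documented limitation. Biases and potentials are in kT
units; a `kT` factor converts outputs when physical units are wanted
(303 K is the reference simulation temperature). Block errors split a
series into three contiguous equal parts (remainder to the last) and
report the block min/max as the interval.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis assumes:
two-state Gaussian lifetime mixtures with the reference global-fit
parameters (1.3/2.7 ns peaks, 0.35/0.67 ns widths) and per-condition
open-state amplitudes taken from the reported values (42–96% across the
lipid panel); Poisson photon arrivals with exponential bleach times
(single-step photobleaching is memoryless); IRF-convolved truncated
nanotimes; uniform TCSPC background. Donor count rates, background levels
and bleach-time scales are not reported for the instrument, so defaults
were chosen once to give realistic bunching: 3000 detected donor photons/s
in the FRET stage, 2000/s acceptor, 30/s background per channel, 2%
uniform-nanotime fraction, mean acceptor/donor bleach times 2 s and 4 s,
8 s acquisitions — about 5 bunches per accepted molecule. On acceptor
bleach the donor rate scales by τ_D/τ_DA (de-quenching); for lifetimes at
or above τ_D (E ≤ 0) the factor is capped at 1. The donor-only lifetime
default is 3.02 ns, the value at which a 2.7 ns open-state lifetime maps
to 12 nm at R₀ = 8.4 nm.

Deliberately not emulated: acceptor nanotime physics beyond
presence/absence (the analysis uses donor lifetimes only), diffusing
molecules (immobilized only), blinking dynamics (blinking traces are
rejected, not modelled), dye orientation (κ²) and linker diffusion
corrections, and detector afterpulsing beyond the uniform background
term. Passing tests therefore certify the inference chain under the
assumed generative model — they do not certify robustness to instrument
artifacts absent from that model.

## Known limitations

* **Bunches are not independent.** All bunches of one molecule share its
  lifetime, so the effective sample size for amplitude estimation is the
  molecule count, and BIC — which counts bunches — can prefer three
  components over two on pipeline output even when the generator has two
  states (the extra component absorbs cluster lumpiness). On independent
  mixture draws BIC recovers two components essentially always. The
  pipeline therefore reports the full BIC table and the selected k, but
  tabulates the open/compact equilibrium from the two-state model.
* The per-photon likelihood ignores TCSPC channel discretization and
  dead-time effects.
* WHAM is exercised in one dimension only.
* The Monte-Carlo change-point calibration refits the null rate per
  segment; for very short segments (< 5 bins) the test is conservative.

## Problem sizes used in tests

Simulation-backed tests use: 10³ bunches for estimator bias, 10³ traces
for the change-point false-positive rate, 3000 values/condition for
mixture recovery, 500 replications × 2000 bootstrap resamples for CI
coverage (the user-facing default stays at 10⁴ resamples), 30 replicates
of 2000 values/condition for BIC model recovery, 10⁴ simulations for
ANOVA calibration, and 4 conditions × 200 molecules end to end — sizes
chosen to give the assertions ≥3σ headroom while keeping the suite fast.
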
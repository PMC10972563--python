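# Methods

## Model structure and assumptions

A presynaptic active zone is modeled as `n_sites = 200` identical,
independent release sites. Each site is empty, holds a tethered vesicle, or
holds a docked vesicle; only docked vesicles fuse. Tethering draws on an
implicit infinite reserve pool (no depletion), and untethering/undocking
rate constants equal their forward counterparts by default (`k_tet = k_untet
= 7 s⁻¹`, `k_docking = k_undocking = 5 s⁻¹`) — stored as independent
parameters, equal only by default.

Three Ca²⁺ sensors act on the site:

- **syt1** (5 sites, k₊ = 140 µM⁻¹s⁻¹, k₋ = 4000 s⁻¹, b = 0.5,
  f₁ = 27.98) rides on the vesicle and binds Ca²⁺ only while docked.
- **Doc2α** (2 sites, k₊ = 28 µM⁻¹s⁻¹, K_D = 1.5 µM, b = 0.5, f₂ = 16)
  resides on the release site and binds Ca²⁺ in every site state, so its
  activation survives fusion of the resident vesicle.
- **syt7** (2 sites, same binding dynamics as Doc2α, f₇ = 10) also resides
  on the site and scales docking *and* undocking by `Σ S[s7]·f₇^s7` — a
  catalyst that lowers the docking energy barrier without shifting the
  docking equilibrium, which is why its loss leaves steady-state docking
  intact but abolishes rapid re-docking after a stimulus.

syt1 and Doc2α compete for a shared budget of five ions per docked site
(an implicit stand-in for a limited pool of SNARE machinery): on-rates are
clamped as `slots_syt1 = min(n₁−s1, 5−(d2+s1))` and `slots_doc2 =
min(n₂−d2, 5−(d2+s1))`. The three docked states with `d2+s1 > 5` are kept
in the 24-dimensional state vector but are rate-isolated (no inbound and no
outbound rates), so they remain at exactly zero occupancy rather than
accumulating solver noise. Note the clamp makes the joint syt1×Doc2α
lattice a genuinely irreversible network: Kolmogorov's cycle criterion
fails on 2×2 plaquettes where a clamped on-rate has no matching off-rate
adjustment, so closed-form equilibrium checks are only valid for the
isolated single-sensor chain (see tests).

Unbinding from a sensor with m ions bound proceeds at `m·k₋·b^{m−1}`; with
cooperativity b = 0.5 each additional bound ion halves the per-ion off
rate. The per-ion fusion factors enter multiplicatively:
`f(d2,s1) = l₊·f₁^s1·f₂^d2`, so one fully loaded syt1 (s1 = 5) accelerates
fusion ~1.7×10⁷-fold.

## Ca²⁺ transient

Each AP at onset o contributes a synchronous Gaussian — peak height
`amplitude_ap = 30 µM` (peak-height scaling, not area scaling) at
o + 1.5 ms, sd 0.2 ms — and a residual component

    A · exp(−(t−t₀)/τ) · (t−t₀)/((t−t₀)+km),  t ≥ t₀ = o + 1.6 ms,

with A = 0.75 µM, τ = 0.2 s, km = 0.1 ms; the hyperbolic factor smooths the
onset (the residual is exactly zero at t₀). Residuals of successive APs
sum linearly — the standard assumption for residual Ca²⁺, consistent with
the way slow-sensor activation builds across a train. The basal 0.05 µM is
added everywhere. The transient is evaluated analytically on demand, so the
ODE solver is free to choose its steps. The printed form of the residual
expression in the source literature is typographically garbled; the reading
above is the only one in which τ acts as a decay time constant from onset
t₀ and km smooths the rise, and it is implemented as such.

## Numerical integration and steady states

The joint system (24 site states, 3 syt7 states, cumulative fusion F — 28
ODEs) is integrated with LSODA at `rtol = atol = 1e-5` and `max_step =
1e-5 s`, with an analytic Jacobian; the tight step cap guarantees the
0.5-ms-wide Ca²⁺ spikes are never stepped over. Halving the tolerances
changes F(t_end) by < 0.1% (tested). Output is sampled at 50 kHz, the grid
on which release rates are formed as forward differences of interpolated F.

The rate matrix decomposes as `Q(ca, S) = Q_const + ca·Q_on + g₇(S)·Q_dock`,
each term carrying its own −row-sum diagonal; this makes the right-hand
side three mat-vecs and keeps every combination a proper generator.

Initial conditions are the resting steady state at 0.05 µM: syt7 from the
detailed balance of its binding chain (S[1]/S[0] = 2·ca·k₇₊/k₇₋,
S[2]/S[1] = ca·k₇₊/(2·b₇·k₇₋); the printed closed form in the source is
again garbled and the detailed-balance solution of the stated rate
equations is used), and the site distribution as the one-dimensional null
space of Qᵀ restricted to the 21 reachable states. A long-time matrix
exponential (π₀·e^{Q·1000 s} from all-empty) is retained as an independent
cross-check and agrees to ≤ 10⁻⁶·n_sites.

A single-site stochastic simulator (`vesikin.stochastic`) provides an
independent oracle: Lewis thinning against a uniform dominating rate, with
the deterministic g₇(t) pre-integrated, vectorized across replicates. The
mean fusion count over 10⁴ replicates of a 2-AP protocol matches the ODE
within Monte-Carlo error; it is test infrastructure, never the production
path.

## Model quantification

Per stimulus k (onset o_k, inter-stimulus interval Δ): peak release rate =
max of the 50 kHz rate series on [o_k, o_k+Δ); synchronous count =
F(o_k+5 ms) − F(o_k); asynchronous count = F(o_k+Δ) − F(o_k+5 ms) (the
5-ms boundary is measured from stimulus onset). The simulation runs one
full Δ past the last onset so the last window is complete. Two docking
readouts are reported: `docking_recovery` (net docked-pool change between
+5 and +15 ms) and `docking_flux` (cumulative docking events,
∫ g₇·k_docking·T dt, over the same window). The flux is the headline
"vesicles docking between 5 and 15 ms" metric: it is the quantity that is
large for WT and the Doc2α knockout and collapses ~18-fold without syt7
catalysis, whereas the net change conflates docking with concurrent
undocking and fusion losses and retains a basal-exchange component in the
knockout. The parameter sweep rescales one flat-named parameter at a time
over a log-spaced 0.1×–10× grid (13 points by default; the density is a
package choice, the range is canonical) and records four headline metrics;
failed cells are recorded and skipped.

## Trace analysis

**Fluorescence.** ΔF/F₀ = (F − F₀)/F₀ with F₀ the mean over a 500-ms
pre-stimulus baseline; noise SD is the baseline SD of ΔF/F₀ (plain SD by
default, MAD×1.4826 behind a flag). The sensor activates within one frame
(10 ms) and decays slowly, so an event frame must exceed 5×SD in value and
in estimated event amplitude. The amplitude estimate is the frame-to-frame
rise; when the sensor's decay constant is supplied (a known property of
each variant — ~100 ms for the medium-affinity, ~30 ms for the low-affinity
sensor) the rise is decay-corrected and combined with a one-frame
look-ahead, which resolves events stacked on an earlier event's decay and
vetoes noise bumps riding a decay shoulder. A plain local-maximum rule was
rejected: on slowly decaying kernels it misses the earlier member of
close pairs (two maxima cannot occupy adjacent frames) and counts
supra-threshold noise on decay shoulders as spurious asynchronous events.
Events are assigned to the preceding stimulus and binned at 10 ms; bin 1
(≤ 10 ms) is synchronous, later bins asynchronous. The per-peak counting
deliberately ignores multiquantal composition, reproducing the standard
peak-counting definition; at the SNR = 10 boundary a 5×SD threshold
detector retains an irreducible ~10⁻³ per-event miss probability from
±3.7σ noise draws, so exact ground-truth recovery is demonstrated at the
generator's default noise (SD 0.02 ΔF/F₀ on unit-amplitude events).

**Currents.** Charge is in pC with inward (negative) current integrating
to positive transferred charge. Single sweeps: cumulative baseline-
subtracted charge over 400 ms is fitted with
`Q(t) = Q_f(1−e^{−t/τ_f}) + Q_s(1−e^{−t/τ_s})` by multi-start nonlinear
least squares in log space (positivity by construction; τ starts at
{5, 100} ms plus shifted variants; τ_f < τ_s by sorting; a degeneracy flag
is raised when τ_s/τ_f < 3). Trains: tail currents are read 1 ms before
every stimulus onset and 1 ms before the would-be next stimulus after the
last; the tonic envelope is the piecewise-linear interpolant through these
tails (the minimal interpolant consistent with the shaded-area
illustration of the measure; step-wise interpolation was the rejected
alternative) and the tonic charge is ∫(baseline − envelope) dt over the
train.

## Synthetic data

The generators emulate the signal structure the analyses see, not the
optics: per-bouton ΔF/F₀ at 100 Hz, Gaussian white baseline noise
(no photobleaching — laser power in the emulated experiments was chosen to
make bleaching negligible), events as instant-rise/exponential-decay
kernels, per-stimulus synchronous probability 0.64 and asynchronous
probability 0.36 (giving the canonical ~36% asynchronous share of events),
asynchronous latencies exponential with 20 ms mean truncated to
(10 ms, min(100 ms, interval − one frame)], amplitudes Normal(1.0, 0.2)
clipped at 0.2. Currents are sums of unit-peak biexponential phasic
responses (rise 0.5 ms, decay 5 ms, geometric per-stimulus depression 0.9)
plus a tonic envelope (linear ramp or saturating exponential) whose charge
is known in closed form; `synth_epsc_single` emits a current whose
cumulative charge is *exactly* biexponential for parameter-recovery tests.
All randomness flows from one seed through numpy's PCG64, and rendering a
ground-truth table through the shared kernel renderer reproduces the
noiseless trace bit-for-bit. The model-driven generator bins simulated
fusion per frame, draws per-bouton Poisson event counts scaled by
`sites_per_bouton/n_sites` (default 10/200), and renders multiquantal
events of amplitude gain×count — closing the loop model → measurement →
quantification. Passing these tests demonstrates the correctness of the
quantification code under the generative assumptions; it does not certify
performance on real movies (ROI segmentation, bleaching, correlated noise
and multiquantal amplitude statistics are out of scope).

## Problem sizes and defaults

Default protocol 10 APs at 20 Hz with a 50-ms tail (0.55 s of model time,
~10⁵ solver steps, a few seconds per simulation); the stochastic oracle
uses a 2-AP reduced protocol at 10⁴ replicates; sweep-based tests use a
shortened 3–5-AP train. These sizes are package choices that keep the full
suite comfortably interactive while exercising every code path at the
canonical parameter values.

## Known limitations

- No spatial Ca²⁺ diffusion, buffering or channel gating: the transient is
  a phenomenological driver.
- No explicit SNARE counting; sensor competition is implicit in the 5-ion
  budget.
- syt7 as a pure catalyst cannot produce a docking overshoot, so
  paired-pulse facilitation beyond baseline docking is outside the model.
- The sweep treats `k_docking`/`k_undocking` (and tethering counterparts)
  independently; their default equality is not enforced under rescaling.
- Trace analysis assumes uniform sampling, sub-frame sensor rise, and
  plain delimited tables (no hardware formats, no ROI detection, no
  quantal decomposition of multiquantal peaks).
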
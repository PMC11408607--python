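# Methods

This note documents the models, parameter choices and analysis conventions
implemented in `sensillab`, in enough detail to judge what the simulations
can and cannot show.

## The two-ORN sensillum model

### Stimuli

Stimuli are valve command sequences per odorant channel (A = methyl
hexanoate, driving ab3A; B = 2-heptanone, driving ab3B), stored as exact
toggle times plus an initial state. Four families are implemented: single
0.5-s square pulses; a pulse on a ≥2-s-old background of the other odorant;
pulse pairs with onset asynchrony Δt ∈ {0, 3, 6, 12, 24, 48, 96} ms in
either order; and 10-s fluctuating streams whose toggle times form a
Poisson point process with 50 ms mean interval. Correlated mixtures apply
one base sequence to both channels (AB_A, AB_B); the uncorrelated mixture
(AB_i) pairs the two independent base sequences. One fixed pseudorandom
sequence pair is used for a whole fluctuating-mixture experiment: the
sequences are part of the stimulus design, like the single frozen noise
sequence an experimental rig replays, while the random seed governs the
biological variability (flies, trials, spiking).

Valve state is converted to a photoionization-detector-like concentration
trace by an asymmetric first-order filter. The simulator defaults are
τ_rise = 10 ms and τ_fall = 15 ms: the olfactometer being emulated was
built for maximal concentration rise speed, and the fall time must be
short relative to the 50 ms switching scale or the fluctuating streams
blur into a near-constant plume (the Hill stage is shallow, so incomplete
odor clearance saturates the response). `valve_to_concentration` itself
defaults to a more conservative 20/40 ms and both constants are arguments.

The delivered concentration fractions are 1.43 × 10⁻³ ("high") and
1.43 × 10⁻⁶ ("low"). The dilution arithmetic (3 mL/min odorant into
297 mL/min air per channel, two channels joining a 1.5 L/min carrier)
reproduces the high fraction and the 2.1 L/min outlet flow exactly. The
printed serial-dilution recipe for the low fraction is not arithmetically
consistent (three repeats of the 1:100 stage yield 1.43 × 10⁻⁷ after the
carrier share, not 1.43 × 10⁻⁶), so the final fraction is an explicit
parameter (`FlowConfig.final_fraction_override`) rather than a derivation.

### Transduction and adaptation

Each ORN responds only to its cognate odorant:

    u(c)   = r_max · cⁿ / (cⁿ + Kⁿ)
    ȧ      = (α·u − a) / τ_a
    drive  = r₀ + max(0, u − a)

| parameter | default | meaning |
|---|---|---|
| r₀ | 2 spikes/s | spontaneous rate |
| r_max | 1000 spikes/s | latent drive ceiling (far above realized rates; refractoriness and kernel smoothing compress it) |
| K | 3.3 × 10⁻⁶ | half-activation concentration fraction |
| n | 0.362 | Hill exponent |
| τ_a | 35 ms | adaptation time constant |
| α | 0.9506 | adaptation strength (sustained fraction = 1 − α) |
| refractory | 1.5 ms | absolute dead time of the spike generator |

K and n are set so that the two delivered concentrations (a factor 1000
apart) produce a drive ratio of ≈ 2.1, matching the ratio between the
published high- and low-concentration response bands. r_max, α and τ_a are
then calibrated jointly so the *measured* responses (alpha-kernel peak of
single-trial estimates; spike counts at 2 s of constant odorant) fall in
the published bands: with the defaults, 100-trial means are ≈ 76 spikes/s
transient peak and ≈ 22 spikes/s sustained at low concentration (bands
70–75 and 21–25), and ≈ 126 / ≈ 43 spikes/s at high (bands 120–230 and
35–52). The latent transient is much larger than the measured peak because
the 50-ms kernel averages over a transient that decays with τ_a = 35 ms,
and refractoriness compresses high rates as r/(1 + r·δ).

### Ephaptic coupling

Coupling is phenomenological: instantaneous, subtractive, rectified, and
computed from the uncoupled drives (no fixed-point iteration), with an
activation threshold θ:

    B′(t) = max(0, B(t) − g_AB · max(0, A(t) − r₀_A − θ))
    A′(t) = max(0, A(t) − g_BA · max(0, B(t) − r₀_B − θ))

Defaults: g_AB = 0.5, g_BA = 0.1875 (the large A neuron inhibits more and
is inhibited less), θ = 30 spikes/s. Zero latency reflects the fast,
temporally precise nature of ephaptic interaction relative to the 1-ms
drive resolution.

The threshold is a deliberate design choice. A purely linear subtractive
rule lets the adaptation plateau (~21 spikes/s of suprabaseline sustained
drive, pinned by the sustained-rate calibration) exert a *sustained*
suppression on the partner. A sustained deficit passes through the alpha
kernel essentially unattenuated while the transient it is measured against
is smoothed down several-fold, so even this small plateau keeps the
partner's measured peak significantly suppressed at arbitrarily large
onset asynchronies — the synchrony window never closes, contrary to the
phenomenon being modeled. The threshold expresses that weak sustained
activity draws too little transepithelial current to suppress the
neighbour measurably; only vigorous activity couples. θ = 30 spikes/s lies
above the low-concentration sustained drive (so a low background alone
does not couple) and below the high-concentration one (so the
background+pulse effect at high concentration survives, weakly). Setting
θ = 0 recovers the plain subtractive rule. A corollary is that the
simulated background+pulse design shows clear suppression of the
*background* neuron's sustained response by the pulse, but only weak
(high-concentration) suppression of the pulse response by the background.

### Variability

Two lognormal jitter sources (unit mean):

* per fly, CV = 0.3 on each ORN's r_max and on both coupling gains —
  between-animal heterogeneity in sensitivity and coupling strength;
* per trial, CV = 0.1, one shared gain factor on both ORNs — slow
  recording-state / physiological drift across repetitions.

These produce per-fly normalized-response spreads comparable to published
single-sensillum data; they are what keeps weak (few-percent) suppressions
statistically invisible at n = 8 flies, as in the real analysis.

### Spiking and voltage synthesis

Spike trains are dead-time-modulated Poisson processes: thinning of a
homogeneous process at the drive maximum, then removal of candidates
within the refractory period (constant drive r realizes exactly
r/(1 + r·δ)). Seeding is hierarchical — (experiment seed, fly, stimulus,
trial) — so enlarging an experiment leaves existing trials unchanged.

Voltage traces (10 kHz) place a biphasic waveform at each spike: unit A
3 mV peak / 2 ms width, unit B 1 mV / 1.5 ms. Per-spike amplitude declines
with the unit's local firing rate (causal exponential-window estimate,
τ = 50 ms) as amp·e^(−0.0015·rate), emulating the activity-dependent
spike-shape shrinkage characteristic of sensillum recordings; white noise
SD 0.1 mV. Ground-truth (time, unit) events are retained with every trace.

## Spike sorting

Amplitude-only two-unit sorting with an explicit amplitude-vs-rate model:
band-pass (1–4000 Hz, zero phase) detection at 4 robust SDs (MAD/0.6745)
with ≥ 0.75 ms peak separation (half the narrowest spike width); Otsu
split of peak amplitudes for deterministic initialization; then hard-EM
iterations that estimate each unit's causal local rate at every event, fit
amp = a·e^(−b·rate) with b ≥ 0 per unit, reassign events by scaled
residual, and flip the worse-fitting member of same-unit pairs closer than
1.2 ms (just below the true refractory period, so detection-time jitter
cannot trigger spurious flips). The larger-amplitude cluster is unit A. A
two-cluster fit is only attempted when the Otsu split separates means by
≥ 4 pooled SDs; otherwise all events go to one unit (single-unit
fallback). Collisions closer than the detection spacing merge into one
event assigned to the larger unit and are *not* recovered — the dominant
cause of missed spikes (detection ≈ 97–99%, perfect only on sparse
traces). On default simulated traces label accuracy is ≥ 99%; repeating
the full onset-asynchrony analysis on sorted instead of ground-truth
trains reproduces the significance pattern up to occasional flips of
borderline stimuli.

## Analysis conventions

* **Rates**: causal alpha kernel k(t) = (t/τ²)e^(−t/τ), τ = σ = 50 ms
  (the "standard width" is read as the kernel time constant; an SD-based
  convention is available via `KernelParams(convention="sd")`). Kernels
  are renormalized to unit integral after discretization.
* **Windows**: half-open [a, b) everywhere; t = 0 at the leading/pulse
  valve opening. Transient window 0.1–0.35 s; peak-rate search window
  0.5 s long, **starting at each unit's own cognate-odorant valve
  opening**. The own-onset convention matters: with a window fixed to the
  leading valve, the trailing unit's response has less room for the
  max-statistic to roam and shows a spurious ~9% "suppression" even with
  coupling off.
* **Normalization**: responses divided by the same fly/unit/level's mean
  cognate-alone response; all test decisions are invariant to rescaling
  any fly's rates.
* **Battery**: per unit, per-fly mean normalized responses for each of the
  15 stimuli are compared with the cognate-alone value (= 1) by two-tailed
  t-tests (n = flies), Benjamini–Hochberg corrected within the unit's
  15-test battery. The synchrony window width is the largest significant
  suppressed |Δt| on the A-leading side plus the same on the B-leading
  side.
* **Pooled regression**: x = |Δt| (ms), pooling both orders, y =
  normalized peak rate; per-fly OLS plus an average regression over all
  points. Suppression that weakens with asynchrony gives a positive slope.
  (The sign convention is chosen so that "inhibition increases with
  synchrony" reads as a positive slope; plotting against −|Δt| would flip
  it.)
* **Victor–Purpura**: exact dynamic program; insert/delete cost 1, shift
  cost q|Δt|. q is not derivable from the study being emulated, so it is
  an explicit, logged parameter everywhere; default q = 20 s⁻¹ (a 100-ms
  shift costs as much as delete+insert, matching the 2σ rate-estimation
  precision). Distances for fluctuating stimuli use the full 10-s window.
  Group comparisons are all within-fly cross-trial pairs, pooled across
  flies, with two-sided Mann–Whitney U tests and Bonferroni correction
  over the per-unit comparison list.

## What the simulations show — and what they cannot

With all defaults, replicate simulations reproduce the qualitative
findings the pipeline is built to detect: the small-B-neuron synchrony
window falls within 48–96 ms in ≈ 90% of replicates (median ≈ 72 ms);
suppression of B's peak decreases monotonically with |Δt| and exceeds the
unit-A effect; suppression grows with concentration; correlated
fluctuating mixtures change B's response more than uncorrelated ones
(median D_VP(AB_B, B) > D_VP(AB_i, B) > D_VP(B, B), the first difference
U-test significant), with the A-side effect weaker; and with coupling off,
all of these vanish and the test batteries show nominal type-I rates.

The generator emulates trial structure, rate calibration, amplitude
classes and their rate dependence, and inter-animal variability. It does
**not** emulate receptor kinetics, the transepithelial-potential
biophysics behind ephaptic coupling (the subtractive-threshold rule is a
phenomenological stand-in whose functional form is not constrained by the
emulated study), correlated noise or drift within trials, bursting, or
collision waveform superposition beyond linear addition. Passing tests
therefore validate the *pipeline* — sorting, rate estimation, distances,
statistics — and the internal consistency of the coupling phenomenology;
they are not evidence about mechanism in real sensilla, and quantitative
D_VP values are not comparable to any published ones because q and the
spike-count scale are simulator choices.

## Numerical choices and degenerate cases

Concentration filtering is computed segment-wise in closed form (exact for
piecewise-constant valve states). Adaptation uses an exact exponential
recursive filter. Rate estimates zero out FFT round-off below 10⁻⁹ so
causality is exact. The VP dynamic program vectorizes the insert recursion
as a running minimum, giving O(n·m) with O(m) memory. Degenerate inputs
are defined: zero-variance paired differences flag the t-test as
degenerate (p = 1 if identical, 0 otherwise); constant-rate amplitude fits
return b = 0; empty spike trains give zero rates and D_VP = n; the
asynchrony Δt = 0 protocol is order-independent by construction. Problem
sizes in tests and the acceptance script (trial counts, replicate counts,
null-simulation scale) are chosen to keep each check to seconds-to-minutes
on one CPU while leaving the test statistics' standard errors well inside
the asserted margins.

## Known limitations

* The coupling threshold makes low-concentration background suppression
  exactly zero; the real phenomenon is graded.
* Collisions are merged, not resolved; at sustained joint rates above
  ~100 spikes/s the sorter's count bias becomes visible (~1 spurious
  small-unit event per second of trace from near-threshold noise).
* The battery's multiple-comparison family is per unit; a global family
  would be more conservative.
* Single-exponential adaptation cannot show the slow (tens of seconds)
  adaptation components of real ORNs; sustained rates are only meaningful
  at the 2-s probe time used for calibration.
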
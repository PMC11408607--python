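# sensillab

Simulation and analysis of **ephaptic inhibition between co-localized
olfactory receptor neurons (ORNs)** in single-sensillum recordings.

In *Drosophila*, the ab3 sensillum houses two ORNs that share an
electrically insulated lymph space: the large **ab3A** (cognate odorant
methyl hexanoate, MHXE) and the small **ab3B** (cognate odorant
2-heptanone, HEPN). The two neurons suppress each other nonsynaptically
through the shared transepithelial potential. This package asks the
question such recordings are designed to answer: **is that mutual
inhibition sensitive to the relative timing of the two odorants?** If
inhibition engages only when the two inputs arrive synchronously — as
odorants from a single source do in a turbulent plume — it can serve as a
circuit-level cue for odor-source segregation.

Because the underlying electrophysiology archive is not required here, the
package includes a first-class synthetic sensillum: a calibrated two-ORN
simulator that produces ground-truth spike trains and extracellular-style
voltage traces for whole multi-fly experiments, against which every stage
of the analysis pipeline (spike sorting, rate estimation, spike-train
distances, statistics) is verified.

## What is inside

| module | contents |
|---|---|
| `sensillab.stimuli` | valve-sequence stimuli: square pulses, background+pulse, onset-asynchrony pairs (Δt ∈ {0, 3, 6, 12, 24, 48, 96} ms, either order), Poisson-switched fluctuating mixtures (AB_i / AB_A / AB_B); PID-style concentration traces; olfactometer dilution arithmetic |
| `sensillab.sensillum` | two-ORN simulator: Hill transduction with first-order adaptation, thresholded subtractive ephaptic coupling, dead-time Poisson spiking, rate-dependent spike amplitudes, hierarchical seeding |
| `sensillab.sorting` | two-unit amplitude spike sorter with an explicit amplitude-vs-firing-rate model (hard-EM iteration, Otsu initialization) |
| `sensillab.metrics` | causal alpha-kernel rate estimation (σ = 50 ms), response windows, exact Victor–Purpura distance (O(nm) dynamic program) |
| `sensillab.stats` | cognate normalization, FDR-corrected t-test battery, synchrony-window width, pooled synchrony regression, within-animal D_VP groups with U tests + Bonferroni |
| `sensillab.runner` / `sensillab.cli` | experiment presets (`fig2`, `fig3`, `fig4`), end-to-end orchestration with manifests, `sensillab` command line |

The model at the core: each ORN's latent drive (spikes/s) to its cognate
odorant at concentration fraction *c* is

    u(c)  = r_max · cⁿ / (cⁿ + Kⁿ)                      (Hill activation)
    ȧ     = (α·u − a) / τ_a                              (adaptation)
    drive = r₀ + max(0, u − a)

and ephaptic coupling subtracts, sample-synchronously and rectified at
zero, a fraction of the neighbour's suprathreshold drive:

    B′ = max(0, B − g_AB · max(0, A − r₀_A − θ))
    A′ = max(0, A − g_BA · max(0, B − r₀_B − θ)),    g_AB > g_BA

Spikes are an inhomogeneous Poisson process with absolute refractoriness
driven by the coupled drives. Firing rates are estimated by convolution
with a causal alpha kernel k(t) = (t/τ²)·e^(−t/τ), τ = 50 ms, and
spike-train dissimilarity is the Victor–Purpura distance D_VP (insert /
delete cost 1, shift cost q·|Δt|, default q = 20 s⁻¹). See
`docs/methods.md` for parameter values and rationale.

## Worked example

Run the onset-asynchrony experiment (8 simulated flies × 10 trials × 15
stimuli at low concentration) and its statistics:

```bash
python analysis/04_onset_asynchrony.py
```

which prints (seed 1):

```
unit A: synchrony window 3 ms (A-leading 3, B-leading 0); pooled regression slope 0.0012 per ms, r2 = 0.02, p = 8.2e-07
unit B: synchrony window 60 ms (A-leading 12, B-leading 48); pooled regression slope 0.0027 per ms, r2 = 0.12, p = 1.7e-29
```

Reading: for the small ab3B neuron, mixture stimuli significantly suppress
the transient peak response out to tens of milliseconds of onset
asynchrony on either side — a synchrony window of ~60 ms here, within the
48–96 ms range replicate simulations produce — while the large ab3A
neuron, which receives the weaker reciprocal inhibition, shows almost
none. The positive regression slope says suppression releases as the
onsets are pulled apart: normalized peak rate rises by ~0.003 per ms of
asynchrony. The other numbered scripts in `analysis/` build the stimulus
designs, calibrate the simulator against published firing-rate bands,
reproduce the background+pulse and fluctuating-mixture analyses, and
validate the spike sorter; each writes tidy tables under `results/`.

The same experiments run from the command line:

```bash
sensillab reproduce fig3 --seed 1 --out results/fig3_run
sensillab show-config
```

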
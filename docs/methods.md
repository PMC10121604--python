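# Methods

## Scope and data model

All analyses operate on three objects: `SpikeTrain` (sorted spike times in
seconds from session start, with area and 0-based probe contact),
`SessionEvents` (a typed table of Pavlovian trials and/or
stimulation/sham events), and `ProbeLayout` (contact and fiber-port
positions in mm along a linear probe; defaults are a 16-contact amygdala
probe at 0.2 mm spacing with one mid-shank port, and a 24-contact nigra
probe at 0.1 mm spacing with ports midway between 1-based contacts 3/4,
11/12 and 20/21). Windows are half-open `[a, b)` so edge spikes are counted
exactly once; contact labels are converted from the 1-based lab convention
at I/O boundaries only. Sham events are explicit rows, which makes the
stimulation-vs-control contrast structurally symmetric.

## Spike-density estimation

The SDF evaluates the Gaussian kernel (default σ = 20 ms) exactly at each
1-ms grid point — spikes are not binned first — and divides by the trial
count, giving sp/s. No edge renormalization is applied; callers provide
rasters extending a few σ beyond the window they analyze. Sample (n−1)
standard deviations are used throughout. A 1-ms grid is used because the
latency criterion is stated in 1-ms bins.

## Stimulation modulation

The modulation index is the AUROC of per-trial spike counts in the 200-ms
post-event window, stimulation vs sham, computed from midranks (ties count
one half); significance is a two-sided paired *t*-test pairing the i-th
stimulation with the i-th sham event in session order (unequal counts are
truncated to the common length; the AUROC uses all trials). Counts, rather
than smoothed rates, are used as the per-trial statistic: they are the
natural sufficient statistic for a Poisson window and admit an exhaustive
pairwise oracle in tests. Each fiber port is analyzed as its own contrast.
Population latency/distance analyses consume these per-(unit, port) results
directly — each pair plays the role of one neuron-in-a-session, matching an
experiment in which each session stimulates one port. Reducing to a
per-unit "best port" first would bias latencies early, because the port
with the earliest onset enjoys the largest overlap with the 200-ms window
and hence the most extreme AUROC; the reduction (`effective_results`) is
used only for per-unit modulated/excited counts and for cross-referencing
task responses.

### Latency rule

Latency is the earliest time at which the trial-averaged SDF exceeds (for
excitation) or falls below (for inhibition) the baseline by two standard
deviations for at least 7 out of 10 consecutive 1-ms bins, implemented as:
the first qualifying bin inside the earliest 10-bin window containing ≥ 7
qualifying bins. A stricter "7 strictly consecutive bins" reading is
available (`rule="consecutive"`). Inequalities are strict so a
zero-variance baseline cannot make an equal-mean signal qualify.

The baseline band defaults to the **across-trials** basis: mean ± 2 SD of
the per-trial rates in the 0.5-s pre-stimulation window. The alternative
across-bins basis (SD over the 1-ms bins of the baseline SDF) is available
but not the default for a measured reason: the marginal noise of a
σ = 20 ms SDF is strongly autocorrelated (excursions are themselves
~40 ms wide), so at desk-scale trial counts any ~2-SD noise excursion
sustains 7 bins, and the rule false-triggers on pure-null rasters roughly
25 % of the time per direction. The across-trials band sits far above the
SDF's marginal noise; weak or unaffected units then simply fail the
criterion and are excluded from latency analyses — the same exclusion the
rule is designed to express. With the default band, the residual detection
bias is the threshold-crossing offset of a kernel-smoothed step,
σ·Φ⁻¹(threshold/amplitude): about +9 ms for the default GABAergic effect
and +12 ms for the DA effect, well inside the ±15 ms recovery tolerance
used in tests.

### Population statistics

Distance–latency and distance–AUROC relations use Pearson correlation with
two-sided uncorrected p-values. The near/far latency split (cutoff 0.25 mm)
reports per-group n/mean/SD and a two-sided Welch (unequal-variance)
*t*-test; recomputing Welch from the printed group summaries (17,
47.6 ± 31.9 vs 8, 93 ± 51.3) reproduces the published P ≈ 0.045, whereas a
pooled-variance test gives ≈ 0.012, which identifies Welch as the correct
recomputation.

## Unit classification

Rules are evaluated on PR trials at α = 0.05 with two-sided paired
*t*-tests of windowed rates against the same trial's 0–500 ms pre-scene
baseline. The CS value ordering for DA (100 % > 50 % and > 0 %) is tested
on condition means, not on pairwise significance. Baseline rate is measured
on PR and NR trials pooled: the pre-scene inter-trial interval carries no
environment information and pooling maximizes trials. Spike-waveform width
is not part of the data model and is not used. SN units with baselines in
the (10, 15) sp/s gap are left unclassified by construction.

## Context analysis

The tonic response compares per-trial rates in [CS − 1.2 s, CS) against
the [scene − 0.5 s, scene) baseline with a *paired* t-test — the pairing
uses the natural within-trial structure and increases power over an
unpaired comparison. Truncation by the 0 % CS is a two-sample *t*-test of
the sustained post-CS rate ([0.3, 1.5) s after CS, skipping the phasic
transient) between 0 % and 100 % CS trials. The scene-set control
correlates per-unit tonic responses measured separately under the two PR
scene-image sets (Pearson). NR-environment tonic responses are computed
identically and reported. α = 0.05 everywhere, uncorrected.

## Circuit inference

Per population: the dominant sign is the majority among significantly
modulated (unit, port) results; latency statistics use dominant-sign
results with detected latencies; "distance-dependent" means Pearson
p < 0.05 *and* r > 0 on latency vs distance. The verdict is
`direct_input` for a distance-dependent population, `indirect_input` for a
non-distance-dependent population that responds slower than some direct
population (Welch comparison reported), and `undetermined` otherwise or
with fewer than 5 qualifying units — degradation is deliberately toward
`undetermined`, never toward the opposite verdict.

## Synthetic circuit generator

The generator is the package's testbed: it simulates the statistical
structure the analyses assume, not biophysics (no membrane dynamics, no
plasticity, no behavior).

**Wiring.** Each GABAergic unit receives ≥ 1 amygdala afferent whose
terminal is scattered (SD 0.05 mm) around the unit's own contact, so light
near a unit's contact activates its afferents. GABA→DA edges are uniform
with mean out-degree 2. DA units receive no direct amygdala edge unless
the ablation knob `direct_da_fraction` is set, which exists to show the
inference rule discriminates wiring, not noise.

**Task session.** Six conditions (PR/NR × 100/50/0 %) × 32 trials in a
uniformly shuffled order, with the 1.08/0.68/1.5 s event sequence. Per-unit
rate = max(0, baseline + tonic + phasic terms): the tonic term applies in
PR from scene onset to the US, is shared between the two scene sets by
default (per-unit SD 1.5 sp/s around the class mean: amygdala +4,
GABAergic −6, DA +3 sp/s), and returns to baseline immediately at the
onset of a 0 % CS. Phasic gains are additive sp/s steps with class-specific
value ordering (amygdala/DA CS: 100 % > 50 % > 0 %; GABAergic inhibition:
0 % > 50 % > 100 %; DA US response maximal at 50 %, the uncertain
outcome). Baselines (DA 5, GABAergic 25, amygdala 8 sp/s) satisfy the
classifier's thresholds by construction.

**Stimulation session.** 200 stimulation and 200 sham events,
pseudo-randomly interleaved, 200-ms pulses, ports cycled across events.
Optical recruitment of a terminal decays exponentially with distance from
the port (full effect within 0.05 mm, length constant 0.15 mm, drawn once
per unit-port); a hard radius would spread affected units uniformly over
the reach, whereas attenuation reproduces the observed clustering of
inhibited units near the port with a slower far tail. Direct effects
(GABAergic): multiplicative suppression (magnitude 0.85 — firing falls to
near zero during the pulse) with onset latency affine in unit-to-port
distance (intercept 40 ms, slope 180 ms/mm, SD 15 ms). Indirect effects
(DA, via any affected upstream GABAergic unit): excitation (gain 2.5) at a
distance-independent latency (mean 90, SD 30 ms) with per-event efficacy
0.7 — a single inhibited relay neuron need not disinhibit its target on
every pulse. Effects last one pulse duration from their own onset and decay
exponentially (τ = 50 ms) afterwards. Amygdala-soma stimulation excites
ChR2⁺ somata near the port at short latency (~10 ms) and inhibits a
configurable 30 % minority at longer latency (~35 ms), standing in for the
local inhibitory network without modeling it.

**Sampling.** Spikes are drawn by Poisson thinning against the explicit
rate envelope (additive steps floored at zero, times the multiplicative
stimulation factors); the thinning bound is the envelope's exact segment
maximum. A fixed seed yields byte-identical output, and every simulation
returns a ground-truth manifest (per-unit class, channel, tonic effects,
realized per-port latencies) for recovery tests.

**What the generator does not emulate.** Spike sorting and its failure
modes, waveform shape, drift and nonstationarity, bursting/pacemaking
autocorrelation (spiking is Poisson given the rate), eye movements and
behavioral covariates, and light-power calibration. Passing recovery tests
therefore demonstrates that the analysis chain is correct and well
calibrated under the assumed statistical structure — not that it is robust
to every pathology of real recordings.

## Problem sizes and defaults

Default populations are 25 GABAergic and 12 DA units — the sizes of the
analyzed populations in the motivating experiment — plus 25 amygdala units
(a down-scaled stand-in for the several-hundred-unit amygdala sample, kept
small so a full task-plus-stimulation simulation runs in a couple of
seconds). The type-I calibration uses 500+ null units on a single-port
layout so that units and statistical tests coincide; end-to-end recovery
sweeps 20 seeds. The full test suite completes in under two minutes on one
CPU.

## Known limitations

- The latency rule inherits the kernel's smoothing bias (see above); the
  bias is common to all units and therefore preserves orderings and
  distance slopes, but absolute latencies carry a ~+10 ms offset at the
  default effect sizes.
- The paired *t*-test treats per-trial counts as exchangeable across the
  session; slow drifts would inflate its false-positive rate (none are
  simulated).
- With fewer than ~5 modulated units per population the inference returns
  `undetermined` rather than attempting a verdict.
- The AUROC uses a fixed 200-ms window; effects with onset latencies near
  the window's end are under-weighted and may be missed.
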
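# Methods

## Recording model

All simulated traces emulate cell-attached patch-clamp recordings. In this
configuration the pipette does not rupture the membrane, so potentials are
known only as displacements from the cell's resting potential (RP). The
package adopts the convention that the command potential `V` (mV) is
positive when the patch is depolarized and that single-channel current is
plotted positive for positive driving force:

    i = g * (V - Erev) / 1000     [pA; g in pS, potentials in mV]

The pipette-potential sign inversion of the physical configuration is hidden
inside the generator; analysis code never needs it.

### Channel gating

Each channel is a two-state (closed/open) Markov process with exponential
dwell times. The recordings being modelled do not constrain kinetics, so the
defaults are a deliberate choice: `mean_open = 5 ms`, `mean_closed = 20 ms`
(open probability 0.2). At the 1 kHz analysis bandwidth the filter rise time
is ~0.33 ms, so 5 ms openings pass at essentially full amplitude; the
defaults make idealization well-posed without being trivially easy. The
long-run open fraction of a simulated channel equals
`mean_open/(mean_open + mean_closed)` up to binomial sampling error, which
the tests check with a 3-standard-error bound on the number of gating
cycles.

### Acquisition

Defaults: sampling 50 kHz, analysis bandwidth 1 kHz, trace noise SD 0.15 pA
added per sample *before* filtering. Filtering uses a Gaussian kernel whose
−3 dB point equals the cutoff `fc` (σ·fc = √(ln 2)/2π ≈ 0.1325, rise time
Tr ≈ 0.3321/fc) — the standard choice in single-channel work because its
step response is analytically characterized and it rings nowhere. A
consequence worth noting: white noise of SD 0.15 pA at 50 kHz leaves
~0.03 pA of in-band noise after the 1 kHz filter, so the effective SNR of
the default traces is high; tests that probe noise robustness set the noise
explicitly.

## Idealization

Half-amplitude threshold idealization, generalized to multiple levels: the
conducting levels in a trace are located as prominent peaks of the
all-points amplitude histogram (Freedman–Diaconis bins, floored at 0.02 pA),
and each sample is assigned to the nearest level — the decision boundaries
are exactly the half-amplitude points between adjacent levels. This keeps
simultaneous openings of two channels (a distinct, higher, "stacked" level)
out of the single-level amplitude statistics, which a single threshold at
half the largest amplitude cannot do. When a caller supplies `expected_amp`
the procedure reduces to the classical single-threshold rule.

Baseline is the refined mode of the all-points histogram (robust up to ~50%
open time; openings deflect only one way, so sub-baseline samples also give
a clean noise estimate via the half-normal MAD). Sojourns shorter than the
dead time (1.5 × Tr by default) are unresolvable at the analysis bandwidth
and are removed with a median filter on the state sequence, which erodes
both edges symmetrically and therefore leaves the open fraction unbiased.
Per-event amplitude is the mean of within-event samples with one rise time
trimmed from each edge.

Event-amplitude statistics downstream use only events ≥ 3 rise times long:
shorter events are attenuated by the filter and would otherwise contribute
a spurious low-amplitude tail.

## Amplitude and conductance mixtures

Gaussian mixtures are fitted by EM (scikit-learn) for k = 1..3 with
quantile-seeded means, and k is selected by BIC with ties resolved toward
smaller k; a component count is never allowed to exceed n/10. Because event
amplitudes have heavier-than-Gaussian tails, the EM fit sometimes describes
one physical level with two near-coincident components; the patch-protocol
analysis therefore groups components by the nearest all-points-histogram
level and uses the weight-averaged peak per level.

The two-level conductance model forces k = 2 on pooled per-cell
conductances, after excluding values above 22 pS (a rare third,
larger-conductance class that is reported but not modelled; it is counted
and flagged). A fit whose two components produce no density dip between
their means (minimum-to-edge density ratio > 0.9) is rejected as unimodal.
The classification threshold is the point between the means where the two
weighted component densities are equal, solved in closed form from the
quadratic in the log-densities and cross-checked in the tests against a
grid-scan oracle. With the default level distributions — level 1
N(17.8, 2.1) pS, level 2 N(10.9, 1.6) pS, equal weights — the intersection
falls at 14.0 pS; classification uses the operational rule g ≥ 14 pS ⇒
level 1, and both numbers (computed intersection, operational threshold)
are preserved in the output.

Stacked-opening screening: a high amplitude peak within 10% relative
deviation of twice a lower peak is flagged as simultaneous openings of two
identical channels rather than a distinct level; in three-level patches the
top level is dropped when it matches the sum of the two lower levels within
15% (two different channels open at once).

## I–V fitting

Unweighted ordinary least squares through the per-potential (V, mixture
peak) points. `g = 1000·slope`; `Erev = −intercept/slope`, extrapolated
beyond the sampled range when the line does not cross zero inside it.
Slope ≤ 0 is rejected as non-physical under the sign convention. Levels in
one patch are fitted independently by default; an optional shared-reversal
joint fit (`fit_iv_shared`) profiles the residual over a common `Erev`,
reflecting the fact that two levels recorded in one patch share ionic
selectivity. The dominant channel of a patch is the level with the largest
total open time; an exact tie resolves to the larger conductance, with a
warning.

## Developmental sigmoid fitting

The four-parameter Hill function

    f(X) = Y0 + a / (1 + exp(-(X - X0)/b))

is fitted by bounded nonlinear least squares (scipy `curve_fit`) with a
deterministic five-start strategy: one data-driven start (`Y0 = min(y)`,
`a = range(y)`, `X0 = median(x)`, sign of `b` from the Spearman rank
correlation) plus four restarts jittered with a fixed seed. Bounds:
`|b| ∈ [0.05, 20]` days, `X0` within the age range ± 5 days,
`a ∈ (0, 4·range(y)]`. Ages are integer postnatal days treated as
continuous. The lower |b| bound matters: the male control reversal-potential
profile has b = −0.31 days, i.e. the transition is nearly complete within
two postnatal days, and unbounded fits can collapse to step functions.

Switch ages (crossings of a given level, by default 0 mV — the
depolarizing/hyperpolarizing boundary) use the closed form
`X = X0 − b·ln(a/(c − Y0) − 1)`, verified in the tests against a root
bracketing oracle to 1e−9 days. The delay between two groups is reported as
ΔX0 (half-transition difference) with SE propagated from the two fits;
ΔX0 and Δ(zero-crossing) differ slightly when the two slopes differ, and
ΔX0 is the headline definition here (for the printed control profiles it
gives 4.1 days female−male; the zero-crossing difference would give 5.1).

Group comparisons run Shapiro–Wilk normality per group and a Levene
equal-variance test before an unpaired two-tailed Student's t-test. When a
gate fails the t-test is still reported — there is no silent switch to a
nonparametric test — but the result carries `gate_failed=True`. Stars:
`*` 0.01 ≤ p < 0.05, `**` 0.001 ≤ p < 0.01, `***` p < 0.001.

## Population generator

Each sex × treatment group is a `PopulationProfile` holding the printed
sigmoid parameters (a, b, X0, Y0):

| profile          | Erev sigmoid              | conductance sigmoid      | %level-1 sigmoid        | ages (2 cells/day) |
|------------------|---------------------------|--------------------------|-------------------------|--------------------|
| male control     | (22, −0.31, 14.4, −13.5)  | (6.2, −1.33, 14.7, 11.1) | (99, −1.9, 15.3, 3.2)   | P5–P36             |
| female control   | (24.2, −1.25, 18.5, −8.3) | (7.8, −3.3, 17.7, 10.5)  | (100, −2.42, 18.5, 0.43)| P8–P36             |
| male valproate   | (21, −0.16, 17.7, −8)     | — (control stand-in)     | — (control stand-in)    | P10–P30            |
| female valproate | (17, −0.28, 23, −5)       | — (control stand-in)     | — (control stand-in)    | P6–P30             |

Valproate conductance and %level-1 sigmoids are not published; the same-sex
control curves stand in so the table schema stays uniform, and only the
reversal-potential path of the valproate profiles is used in the recovery
benchmarks.

Per cell at age X: `Erev = erev_sigmoid(X) + N(0, 5 mV)` (noise SD chosen
inside the 3.0–7.4 mV range of the reported per-group SDs). Two conductance
modes exist because the reported percent-level-1 and conductance-vs-age
descriptions are not mutually consistent (a mixture whose level-1
probability follows the %level-1 sigmoid does *not* have a mean that follows
the conductance sigmoid):

* **mixture** — the cell is level 1 with probability
  `p_level1_sigmoid(X)/100` (clipped to [0, 100]) and its conductance is
  drawn from the corresponding level Gaussian (level 1 N(17.8, 2.1), level 2
  N(10.9, 1.6) pS; SDs chosen within the 1.6–3.0 pS range of the printed
  per-group SDs);
* **direct** — `g = cond_sigmoid(X) + N(0, 1.5 pS)`.

Each benchmark names its mode; reversal-potential benchmarks are mode-
independent. Ages default to 2 cells per postnatal day over each profile's
fitted range; the conductance-vs-age benchmarks extend to P5–P45, matching
the span over which those curves were characterized.

## Firing traces and valence

Spikes are biphasic one-cycle waveforms (2 ms) on a noisy baseline, in a
near-regular train (ISI jitter 10%). Drug effects: *excite* multiplies the
rate by 3.2 (a +220% frequency change) and decays the spike amplitude
exponentially toward a floor of 35% of baseline (progressive sodium-channel
inactivation — spikes shrink but remain detectable); *inhibit* multiplies
the rate by 0.25 (a 75% block; a factor of 0 silences the cell);
*inhibit_then_excite* prepends a 10 s silent period. Washout restores
baseline statistics.

Detection: peaks above 5 robust (MAD) noise SDs with a 2 ms refractory
distance; amplitude relative to a ±25 ms local median baseline. Frequency
effects compare detected rates between baseline, drug and washout windows
(each ≥ 30 s; drug window 2 min by convention). A baseline rate below
0.05 Hz is treated as silent-at-baseline — such cells respond with
depolarization rather than a frequency change and receive no valence. The
no-effect band is ±15% frequency change, chosen below the smallest reported
effect magnitudes. Transient inhibition is scored when the first 20% of the
drug window runs below half the baseline rate while the remainder exceeds
baseline; note this detector only fires when the silent lead covers that
first 20%, so cohorts probing the +0.5 valence should use drug windows of
~50 s with the default 10 s lead (or lengthen the lead).

## Determinism and problem sizes

Every stochastic step takes an explicit seed or `SeedSequence`; child
streams are spawned, never reused, and a pipeline rerun with the same config
is byte-identical on all outputs (checked by manifest checksums). The
recovery benchmarks use 100 seeded cohorts per profile (~60–80 cells each),
1000 pooled conductance draws for the level model, and a five-potential,
30 s-per-potential protocol for the single-patch chain — sizes at which the
Monte Carlo error of each recovered quantity is comfortably below the
tolerance being checked, while the whole benchmark set runs in well under a
minute on one CPU.

## What the synthetic benchmarks do and do not show

The generator reproduces the *structure* of the real data — Ohmic levels,
exponential gating, Gaussian noise at a realistic filtered bandwidth,
sigmoidal age profiles with realistic scatter, drug effects of the reported
magnitudes — so passing recovery tests demonstrates that the analysis chain
is unbiased and correctly implemented at realistic noise levels. They do
not validate the biological claims: real recordings contain drifting
baselines, seal-quality variation, sub-conductance states, bursting
kinetics with missed events, correlated cell sampling within animals, and
channel rundown, none of which is modelled. Known further limitations: no
GHK rectification (the I–V model is linear by construction), no dwell-time
kinetic modelling or missed-event correction, no hierarchical (per-animal)
statistics, and the rare >22 pS conductance class is flagged rather than
modelled.
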
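# Methods

This note documents the models, conventions and design choices behind
`dnmcrit`, in the spirit of a package methods appendix: what is computed,
under which assumptions, and what the synthetic cohorts do and do not show.

## 1. The difference process and its discretised dynamics

All criticality measures operate on *corrected epochs*: deviant-stimulus
epochs minus the subject's mean standard-stimulus response, sample by
sample.  Under the linearisation around the standard response, the corrected
epoch is a realisation of the difference process z(t+1) = A z(t) + ξ(t) with
i.i.d. Gaussian innovations.  Stationarity requires the spectral radius of A
to be below 1; criticality is approached as the leading eigenvalue's modulus
tends to 1.  Two consequences drive everything downstream: the stationary
covariance solves the discrete Lyapunov equation Σ = AΣAᵀ + σ²I, so variance
along the leading mode diverges like 1/(1−γ²); and channels loading on the
leading mode become mutually correlated.  Both are tested against closed
forms in the suite.

## 2. Synthetic cohorts

Because event-related clinical EEG of this kind is generally not
shareable, the generator is a first-class module, not a fixture.  It
emulates the oddball protocol: 64 channels at 500 Hz, 2000 stimuli per
subject (the analysis drivers default to 500 for speed; the physics is
unchanged), 90 % standards / 10 % deviants with no two consecutive deviants
(a common oddball convention, switchable), stimulus-onset asynchrony
500 ms.

Per stimulus, every channel receives a fixed obligatory-response template
(Gaussian bump, 1.5 µV at 100 ms).  Deviants additionally carry:

* an MMN deflection on the planted subnetwork channels — Gaussian bump of
  group-dependent amplitude and latency (defaults HC −3.0 µV @ 170 ms,
  UHR −2.2 µV @ 175 ms, PD −1.5 µV @ 185 ms, width 25 ms), jittered
  between subjects (SD 0.3 µV);
* one stationary segment of the difference process (150-sample burn-in),
  so corrected epochs carry the dynamics.

Sensor noise is i.i.d. Gaussian, 2 µV on every sample.  The dynamics
innovation SD is 1 µV.  Neither value is stated by any protocol; they were
chosen once so that group separation is detectable at realistic cohort sizes
(~30/group) without being trivial at n = 5, and are documented as arbitrary.

**The dynamics matrix.**  The planted subnetwork block is the uniform
coupling matrix (γ/m)·J over m = 8 fronto-central channels (1-based montage
numbers 3, 4, 5, 9, 17, 18, 30, 43), whose spectral radius is exactly γ:
one collective mode carries the approach to criticality, which is precisely
the premise of the dynamical-network-marker theory.  Group defaults:
γ = 0.97 (HC, near-critical), 0.80 (UHR), 0.60 (PD), jittered per subject
(SD 0.005).

Non-subnetwork channels are independent weakly damped channels
(self-coupling 0.3) — except in the stable (PD-like) group, where they form
a **directed delay ring** of weight 0.9 with no self-coupling.  This is the
package's own design and deserves its rationale.  Empirically, psychotic
disorder shows *stronger* direct channel-to-channel causality than the
healthy near-critical state.  A pure "weaker block coupling" design cannot
reproduce that: lag-Δt predictability scales with γ, so the stable group's
conditional transfer entropy would simply vanish.  A directed delay ring has
two properties that make it the right stand-in: its equal-time
cross-correlations are exactly zero (each channel is a sum of noise terms
from distinct sources at distinct lags), so it is invisible to the
fluctuation/correlation selection statistics and to the
decreasing-correlation screen; yet it carries strong lagged direct causality
(the lag-k coefficient between ring neighbours k steps apart is 0.9ᵏ).  The
result is a stable group with low variance, no spurious correlations, and a
conditional-transfer-entropy surplus — the qualitative pattern the pipeline
is meant to detect.

Seed discipline: one study seed; per-subject seeds derive from
SeedSequence(study seed, group index, subject index).  Identical configs are
bitwise reproducible.

**What the simulator does not emulate:** 1/f background spectra, volume
conduction and a scalp forward model, electrode geometry, eye/muscle
artifacts, latency jitter of the evoked response, non-Gaussian noise.
Passing tests therefore demonstrate correctness of the *statistics* and
sensible behaviour under the *modelled* physics — not field performance on
real recordings.

## 3. Preprocessing

Epoch window −100..400 ms around stimulus onset (inclusive start, exclusive
end on the sample grid; 250 samples at 500 Hz), per-epoch baseline mean
(−100..0 ms) subtracted per channel.  Artifact rejection is a single
absolute-amplitude rule (default 100 µV on any channel) — a deliberately
simple, reproducible stand-in for interactive artifact pipelines.  Optional
zero-phase Butterworth band-pass is available but off by default (simulator
output needs no filtering).  Events whose window crosses a recording edge
are dropped and counted.

## 4. MMN conventions

Peak latency: most negative sample between 100 and 250 ms; ties resolve to
the earliest sample.  Amplitude: mean of the corrected waveform over a
*fixed* window — 135–205 ms (duration deviants) or 100–200 ms (frequency
deviants) — not a peak-centred window; the fixed reading is the
interpretation implemented here.  Group contrasts are per-channel Wilcoxon
rank-sum tests on per-subject amplitudes (two-sided), Benjamini–Hochberg
adjusted across channels within each contrast.  A caveat from the error
analysis: with realistic noise the argmin latency of a wide bump wanders by
~±10 ms; latency estimates should be read with that resolution in mind.

## 5. DNMnet selection

Per-subject node feature: SD of the corrected epochs over all epochs × time
samples (sample SD, ddof = 1).  Per-subject edge feature: |Pearson ρ| over
pooled within-epoch samples, *demeaned per epoch* before concatenation so
that event-locked waveforms do not masquerade as cross-channel correlation
(switchable).  Nodes: one-sided rank-sum (HC > PD) across subjects per
channel, BH-adjusted, selected at adjusted p < 10⁻³.  A paired-t variant is
provided, reading the pairing as each subject's corrected-epoch SD against
the same subject's standard-epoch SD, with the per-subject differences
contrasted between groups by one-sided Welch t-test — the only construction
that both pairs within subject and contrasts the groups.  Edges: all
channel pairs by default (restriction to selected nodes is a config
option), one-sided rank-sum on |ρ|, adjusted p < 0.005, plus a reverse
screen at α = 0.05 reporting pairs whose correlation is significantly
*weaker* in the near-critical group.  Node and edge criteria are separate:
edge endpoints need not be selected nodes.  Selection is deterministic
given the data and monotone in the thresholds.

## 6. Criticality measures

Natural logarithms throughout (nats); the distribution entropy is
base-independent by normalisation.  Lagged pairs never cross epoch
boundaries; epochs are demeaned per epoch before pooling.  |ρ| is clipped at
1 − 10⁻¹² so MI/CTE stay finite; zero-variance channels yield 0 with a
warning rather than an error.

Degenerate-input conventions (not fixed by any formula): if all MI mass is
zero the distribution entropy is defined as 1 (maximal uniformity) with a
warning; a node with zero outgoing MI contributes 0 to the network entropy.

CTE conditions on *all* channels at time t except the source — including
the target's own present y_t — making it a transfer-entropy-like quantity
that accounts for the target's autocorrelation.  The partial correlation is
computed from the pooled covariance with a one-row downdate of the
t-block precision per source channel (algebraically identical to
least-squares residualisation); when the t-block covariance is
ill-conditioned (condition number > 10¹⁰) a ridge of 10⁻⁶ × mean diagonal
is added.  A pooled sample count of at least 5 × (n_channels + 1) is
required.  Note the conditioning blocks only *one-step* indirect routes: at
lags of many samples, influence flowing through intermediate times is a
genuine property of transfer entropy with single-time conditioning, not an
artifact.

Group contrasts follow the directional hypotheses: one-sided rank-sum for
HC > UHR and HC > PD, two-sided for UHR vs PD.

## 7. Risk score

Per-epoch features: upper triangle (with diagonal, row-major over
node-sorted pairs) of the within-epoch sample covariance of the DNMnet
channels — m(m+1)/2 features for m nodes.  Classifier: bagging of 100
unconstrained decision trees ("ensemble classification" is otherwise
unspecified; bagged trees are the canonical reading of tree-based ensemble
classification).  O_i is the *hard* predicted label, so R_k ∈ [0, 1] by
construction.  Cross-validation is grouped by subject — all epochs of one
subject share a fold — a deliberate strengthening against within-subject
leakage; an ungrouped variant is not exposed because the leakage it permits
inflates accuracy mechanically.  Risk-accuracy ties are broken by a stable
sort on subject id.

## 8. Problem sizes used by the test suite and acceptance script

The test suite uses 30-vs-30 cohorts at 32 channels and 200 stimuli for
recovery and ordering checks (ten and five seeds respectively), a
12/8/10-subject three-group cohort for the risk pipeline, and 10⁵-sample
series for the MI oracle; the acceptance script runs the full 49/24/29
cohort at 64 channels and 500 stimuli.  These sizes were chosen as the
smallest at which the contrasts of interest are comfortably powered; the
statistics themselves are size-agnostic.

## 9. Known limitations

* The UHR group's entropies land between HC and PD in the simulator,
  whereas clinical reports describe UHR entropies as PD-like; matching that
  would require a UHR-specific dynamics beyond a single intermediate γ.
  The UHR contrasts are therefore not asserted by the tests.
* Gaussian MI/CTE see only second-order structure; nonlinear coupling is
  invisible by design (a histogram estimator is used as a test oracle
  only).
* The amplitude-threshold artifact rule is far simpler than interactive
  EEG cleaning pipelines.
* With ~45 epochs per subject, per-epoch covariance features are noisy;
  the ensemble compensates, but single-epoch outputs O_i should not be
  interpreted individually.
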
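# Methods

## Signal model

A translocation event of a DNA origami assembly through a PEG-bathed
nanopipette is modelled as a symmetric trapezoidal *conductive* pulse on a
flat baseline: linear rise over `(1 − p)/2 · d`, flat top over `p · d`,
linear fall, where `d` is the dwell (ms), `A` the amplitude (pA) and
`p = plateau_fraction`. The pulse area — the equivalent charge surplus
(ECS) — is `(1 + p)/2 · A · d` in pA·ms.

Per-event `(A, d)` pairs are bivariate normal with the species' marginal
means and standard deviations and a negative correlation ρ (default −0.8).
The correlation expresses charge conservation: for a fixed assembly state
the transported charge is a property of the structure, while amplitude and
dwell vary with its shape and orientation in the pore — fast events run
tall, slow events run short. Marginals remain exactly the stated normals;
the implied mean ECS acquires the covariance term

    E[ECS] = (1 + p)/2 · (μ_A μ_d + ρ σ_A σ_d).

With `p = 1/6` and `ρ = −0.8` the monomer's three published statistics
(123 ± 27 pA, 2.1 ± 0.6 ms, ECS peak at 143) are satisfied simultaneously,
and the dimer/trimer/2×2 amplitudes (200/248/287 pA with dwells
3.0/3.5/4.0 ms) place the implied ECS means at 332/481/636 within 0.15%.
The resulting relative ECS width per state is ~20%, consistent with
clearly resolved histogram peaks; with independent draws (ρ = 0) the
widths would be ~36% with strong right skew, and the four-state ECS
histogram would no longer show four discernible components — contradicting
the phenomenon the analysis exists to exploit.

Truncation re-draws (jointly) enforce `A ≥ 0.1 μ_A` and
`d ≥ max(0.2 ms, 3 samples)`; both cut < 0.1% of draws at the calibrated
settings. Dwells can alternatively follow a matched-moment log-normal
coupled through the same Gaussian score (`dwell_distribution="lognormal"`);
the normal form is the default because the published dwell histogram is
symmetric.

## Acquisition chain

Arrivals are homogeneous Poisson at `event_rate` (default 5 events/s, the
reported capture rate at −300 mV); arrivals closer than the previous
event's dwell + 1 ms are re-drawn, since the analysis assumes resolvable
single-molecule events. The pulse train is passed through a causal 4-pole
Bessel low-pass at 20 kHz (the acquisition filter; < 2% droop on ms-scale
pulses, area-preserving) and sampled at 100 kHz. White Gaussian noise of
sd 6 pA is added after filtering: a stationary, reproducible noise floor is
all that detection requires, and 6 pA puts the 7σ threshold (42 pA) three
amplitude-sd below the monomer mean, so detection truncation does not bias
feature recovery. No 1/f or mains components are modelled.

## Detection

Baseline estimation is two-pass: (1) global median and MAD-scaled sigma
(×1.4826), masking samples more than 3σ beyond the baseline in the event
polarity; (2) a moving median of unmasked samples over a 50 ms window,
evaluated on a half-window stride and linearly interpolated — at the ~1%
event duty cycle this is indistinguishable from the dense moving median —
with sigma re-estimated from the unmasked residuals' MAD.

Events are maximal runs with excursion ≥ 7σ. Each run is extended outward
to its boundaries at the `1σ` level. Two numerical choices matter here,
both verified against simulator ground truth:

- **Debounced boundaries.** A boundary requires a *quiet run* of 0.05 ms
  (5 samples) of consecutive below-boundary raw samples; the event spans
  the first to the last above-boundary sample. Stopping at the single
  nearest below-boundary sample instead stops ~17 samples early per event
  on noisy ramps (first passage of noise below the level), biasing the
  dwell −8%; a smoothed-excursion boundary broadens the noiseless base by
  the smoothing half-window. The debounced raw boundary measures the base
  width within ~1 sample in both regimes.
- **Smoothed peak amplitude.** `peak_max` is the maximum of the excursion
  after a 0.1 ms boxcar (well under the 0.1 ms minimum event duration).
  The raw per-sample maximum is biased upward by the expected extreme of
  the noise over the ~45 near-top samples (≈ +2σ ≈ +12 pA here), which
  would shift the fitted amplitude mean by +10%; the boxcar suppresses the
  bias to ~+2 pA without attenuating the pulse top.

ECS is the signed trapezoidal integral of the *unsmoothed* excursion over
the event support (zero-mean noise cancels; rectification would bias).
Events closer than 0.2 ms merge; events outside 0.1–50 ms are discarded.
Marginal amplitude/dwell distributions are summarised by unweighted
least-squares Gaussian fits to Freedman–Diaconis histograms, initialised
at the sample moments, with the mean bounded to the data range.

## ECS deconvolution and yields

Per-sample ECS histograms are fitted with sums of Gaussians by bounded
least squares on the bin counts (Freedman–Diaconis bins by default). In
the sequential-anchor scheme, sample *k* (ordered by assembly complexity)
receives *k* components with components 1..k−1 mean-anchored, bit-exactly,
at the means fitted in simpler samples; an optional fractional slack
(e.g. ±5%) reflects pore-to-pore variability. Yields are component areas
`A_i σ_i √(2π)` normalised to 100%; per-event state assignment (for
density-scatter slicing) maximises the amplitude-weighted normal density,
ties resolved toward the lower-mean component (conservatively calling
unassembled monomer).

The fit is deliberately constrained, because the unconstrained histogram
objective misbehaves on heavily overlapping mixtures:

- **Initialisation.** Free means start at quantiles of the data above the
  largest anchor (free components describe not-yet-identified, larger
  assemblies); sds at half the spacing between neighbouring means; and
  amplitudes at the non-negative least-squares solution given those shapes
  (raw local bin counts over-count shared mass in overlap regions and push
  the optimiser toward zeroing a component).
- **Relative width cap.** Component sd is capped at half the component
  mean (anchored) or half the data maximum (free). Without it the global
  optimum can turn an anchored component into a near-full-range pedestal
  (sd ~600 on a ~1100 pA·ms range) and drag the top component's mean down
  ~7%; a component broader than half its mean is a background, not an
  assembly state (observed relative widths are ~20%).
- **Free-mean floor.** In anchored fits free means are bounded below by
  the largest anchor — the semantics of sequential anchoring.
- **Resolvability guard.** A *free* component that converges onto a
  neighbouring mean (separation within 0.6 of its own sd) or fits a
  sub-bin spike inside another component's 2σ support is an unidentifiable
  split of one peak, and the fit is retried with one fewer component; this
  is how a pure-monomer sample fitted "with up to two components" returns
  a single component and a 100% yield. Anchored components are externally
  attested states and are never dropped. This guard is a resolvability
  criterion, not information-criterion model selection, which remains out
  of scope.

An EM backend (`backend="em"`, maximum likelihood on the raw values with
anchored means held fixed and the same width cap) serves as a cross-check;
its weights are mapped back to histogram amplitude scale so areas remain
comparable.

**Precision.** Components I–III are recovered to ~1%. Component IV sits
under the heaviest overlap (state width ≈ 127 pA·ms against a 155 gap);
across seeds its fitted mean scatters ±3–4% around the true value, with
occasional ~6% excursions — an intrinsic property of deconvolving
overlapping components at ~2000 events, not of the optimiser. Dimer-sample
yields recover injected mixing fractions within ~1–3 points; repeated
re-seeded runs show a yield spread of ~1–2 points, matching the reported
2% run-to-run repeatability.

## Gel benchmark

Gel lanes are consumed as band-intensity tables (densitometry is external).
Intercalating-dye intensity is proportional to DNA mass and every state is
built from identical 7249-nt scaffold tiles, so molar abundance is
`intensity / n_monomers`, normalised per lane to percentages. The
comparison table reports per-component nanopore-minus-gel differences and
flags those beyond a configurable margin (default 5 points). No background
subtraction is applied to the provided intensities.

## What the simulator does and does not emulate

It reproduces the statistical structure the analysis relies on: Poisson
arrivals, per-state amplitude/dwell/charge laws, acquisition filtering, a
stationary noise floor, and ground-truth bookkeeping for recall/precision
scoring. It does not model the physics of PEG-induced conductive peaks,
voltage- or concentration-dependent capture, pore-to-pore geometry
variation, baseline drift, clogging, or multi-level intra-event structure.
Passing tests therefore demonstrate that the *analysis chain* recovers
known signal statistics under realistic noise and filtering — not that the
signal model captures every feature of laboratory recordings.

## Problem sizes

The test and acceptance runs use 180–420 s recordings at 100 kHz
(0.9–2.1 k events per sample) — the same trace lengths as the 3-minute
laboratory recordings the method targets — and ten 180 s analyte-free
traces for the false-positive control. The full acceptance script
completes in about two minutes on one CPU.

## Known limitations

- Component IV's fitted mean carries the ±3–4% scatter described above.
- The >50%-masked "saturated trace" guard in baseline estimation is
  unreachable with a median-centred first pass (at most half the samples
  can exceed the median); it is retained defensively.
- Vendor amplifier file formats are not read; recordings must be converted
  to the CSV or float32-binary trace dialects.
- Anchored means are fixed bit-exactly by default; systematic pore-size
  differences between samples are only accommodated through the optional
  anchor slack.
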
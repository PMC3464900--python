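# Methods

## Model and assumptions

`priism` assumes that three forces shape a gene's expression time course and
that they occupy separable frequency ranges:

1. an adaptive treatment response that rises or falls over a timescale of
   days — slower than one cycle per day;
2. circadian clock influence — oscillation near one cycle per day, which a
   stress may damp, phase-shift or period-lengthen but not push far from the
   circadian range;
3. measurement and biological noise — faster than the clock.

The separation is only meaningful when the data resolve at least one cycle
per day (Nyquist: sampling every 2 h resolves up to 6 cycles/day) and when
the treatment is applied continuously, so its response does not itself
oscillate at clock frequency.

The clock band is *learned from the data*, per condition and per frame, from
the spectra of the configured core clock genes, rather than fixed a priori.
This matters because stress shifts clock frequencies: the band under
treatment is genuinely different from the band under control, and each
condition is decomposed with its own clock vectors (the symmetric reading;
computing vectors per frame also lets the band track the disruption's
recovery over the course of the experiment).

## Pipeline and numerical choices

**Interpolation.** Each gene is resampled onto a uniform grid (default 2 h)
with an interpolating cubic B-spline (`scipy.interpolate.make_interp_spline`,
smoothing 0). Interpolating rather than smoothing keeps the operation
deterministic and idempotent on already-gridded data; at least 4 timepoints
are required. Conditions are interpolated independently.

**Framing.** The course is cut into overlapping frames aligned with the
light/dark cycle: a first frame of `first_frame_h` (default 26 h, covering
the short light period at the start of the reference design), then
`frame_h`-hour (default 24 h) windows starting at every subsequent light/dark
transition, dropping a window that ends exactly where the first frame ends.
Frame windows are half-open `[start, end)` — except the terminal frame, which
is closed so the final grid point stays covered. This makes a 24-h window on
a 2-h grid hold exactly K = N = 12 samples, so its bin spacing is exactly
1 cycle/day and a pure 24-h oscillation lands on bin 1 with no leakage.
Explicit frame boundaries can override the layout.

**Blending.** Per-frame results are merged by a weighted average whose
weights are triangular — peak 1 at the frame centre, declining to the frame
edges — with a floor of ε = 0.05 at the edges so that no timepoint's
coverage degenerates, renormalized to sum to 1 at every timepoint. The
centre-weighting trusts each frame most where its transform is least affected
by window edges.

**Mean shift and DFT.** Within each frame the series mean is removed (zeroing
the DC bin, which would otherwise dominate the spectrum and mask the true
dominant frequency) and the DFT is taken in the convention
G_n = Σ_k g(kT) e^{−i2πnk/N} with inverse (1/N) Σ_n G_n e^{+i2πnk/N} — the
convention `numpy.fft` implements, which the test suite pins against a naive
O(N²) summation at 1e−10.

**Clock band.** Bins with relative amplitude > 0.7 (about half-maximum
power) in a clock gene's spectrum are dominant; bin 0 is never a candidate.
The CCFR is the closed interval from the minimum to the maximum of the union
of dominant bins over clock genes — interior bins are included even if no
gene was dominant there, since the weight formula is defined on the full
interval. Weights are the min–max-normalized summed power of the clock genes
per bin; a single-bin band (0/0 in the normalization) gets weight 1 so the
band still passes its only component. If no clock gene has any dominant bin
(e.g. arrhythmic data), a configurable default band of 1 cycle/day ± 1 bin is
used with a warning, never silently.

**Band partition and filters.** Treatment = bins [0, c_min−1], clock =
[c_min, c_max], noise = the rest (the Nyquist bin, for even N, is the highest
frequency and belongs to noise). Each principal bin carries its conjugate
mirror N−n into the same band, keeping filtered spectra conjugate-symmetric
and reconstructions real; the bands are pairwise disjoint and exhaustive by
construction. The treatment and noise filters are ideal (brick-wall) masks —
for a band this narrow a steep cutoff trades a little ringing for an exact,
non-overlapping partition, and the tapered clock filter already handles the
one band where gain shaping matters. The clock filter multiplies bin c and
its mirror by w_c.

**Mean redistribution.** After inverse-transforming the three filtered
spectra, the removed frame mean is added back in proportion to each band's
share of the power of the spectrum *before* mean shifting: the DC bin carries
(K·mean)² and belongs to the treatment band, so for a typical gene most of
the baseline returns to the treatment component. This is what makes the
treatment component track the slow trend — within a 24-h frame a slower-than-
daily trend is mostly *mean*, and the between-frame variation of restored
means, blended across overlapping frames, reconstructs it. A constant gene
reduces to the degenerate case: all power at DC, the whole mean to the
treatment component, flat at baseline. A gene that is identically zero has no
power anywhere; its (zero) mean is conventionally assigned to the treatment
component. Means are redistributed per frame, before blending.

By linearity the three components sum to the interpolated original exactly
(observed residual < 1e−14); with all clock weights 1 the three zero-mean
per-frame components are mutually orthogonal (disjoint frequency support).

## Ranking evaluation

Fold change is treatment log-expression minus control log-expression per
timepoint. Genes are ranked by its maximum over time, by its value at a fixed
timepoint, or by Euclidean distance from a configurable corner of the
PC1/PC2 score plot (which corner is informative depends on the sign
conventions of the fitted components, so it is an option, not hard-coded).
Ties are broken by input order (stable sort). The ROC walk labels each ranked
gene true or false positive against the gold list; the summary is recall at
the first rank where TP = FP > 0. If the counts never meet at positive
values the recall at the last rank with TP > FP is reported (0 if none) —
the crossing always exists once the walk is long enough, so this only matters
for truncated lists. The Z-test standardizes a statistic across genes and
reports one-sided upper-tail p-values (upregulation focus), flagged at
α = 0.05 by default; statistics are standardized separately, never pooled.

## Synthetic data generator

`priism.synthdata` emulates a two-condition diel time-course experiment on a
0–58 h grid sampled every 2 h: per-gene log2 baselines U(6, 10); sinusoids
with gene-specific phase and amplitude (clock genes U(1.5, 2.5) — strong,
reliable oscillators; all others U(0.5, 1.5)); i.i.d. Gaussian noise
(sd 0.3 log2 units, a typical residual scale for well-normalized arrays). The
treatment condition damps every sinusoid to 60% amplitude, advances its phase
by 4 h and lengthens its period from 24 h to 28 h — a moderate disruption
consistent with cold-stress observations that clock genes stay near, but not
at, one cycle per day — and adds to each of the 30 planted responders a
logistic rise of 2.0 log2 units with midpoint 26 h and rise scale 4 h,
emulating an adaptive response peaking at the start of the first night.
Defaults are fixed in `SimConfig`; every draw comes from one seeded
generator, so output is bit-reproducible.

What the generator does *not* emulate: probe-level microarray noise or
normalization artifacts, gene–gene correlation, missing values, or responders
whose response itself oscillates. Passing tests on this data therefore
demonstrate the algorithm's correctness and its behaviour under the stated
signal model, not performance on any real dataset.

## Validation design

The acceptance checks recompute everything from scratch on freshly simulated
data: framing, spectral oracles, exact recomposition, mean conservation,
planted-signal recovery, and recall at TP = FP for treatment-component
ranking versus original-data max fold change, averaged over ten seeds.

Recovery correlations are checked where the planted signal is well-defined:
the responder trend in the treatment condition (the only place a trend is
planted), and the sinusoid in the control condition, where the undisrupted
oscillation sits exactly on a frequency bin. Under treatment the planted
28-h oscillation deliberately falls *between* bins of a 24-h frame; recovery
there is bounded by spectral leakage regardless of implementation, so it is
reported as a diagnostic (mean correlation ≈ 0.9) rather than a sharp
threshold.

At the default effect size the planted responders separate cleanly, so both
the treatment-component ranking and the original-data ranking reach recall
1.0 and the directional comparison holds as an equality; the treatment
component's advantage becomes strict as effect size shrinks toward the
clock-disruption fold-change scale.

## Problem sizes

Unit and property tests run on series of length 8–32 and 40-gene simulations;
the end-to-end checks use the default 200-gene experiment, with the ranking
comparison repeated over ten seeds. The full suite and the acceptance script
each complete in well under a minute on a single core.

## Known limitations

- Frequency resolution within a frame is coarse (12–13 bins); trends and
  near-clock oscillations can exchange small amounts of energy, and an
  oscillation off the bin grid leaks across bands.
- The CCFR is a contiguous interval; a pathologically split clock spectrum
  (e.g. strong harmonics) would widen the band and absorb noise bins.
- Brick-wall masks ring when a band edge cuts through concentrated energy;
  the tapered clock filter mitigates this only inside the clock band.
- The learned band depends on the configured clock gene set; with very few or
  arrhythmic clock genes the fallback band is a blunt instrument.
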
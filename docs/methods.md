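# Methods

## The model

Epoch-based actigraphic sleep/wake scoring is treated throughout as a
three-stage signal-processing chain.

**Collapsing (downsampling).** Raw counts `x[k]` at sample interval `Δ`
are reduced to epoch values `X[n]` by a window statistic (max or mean)
over windows of width `w` hopping by `s` seconds; one value is emitted
per hop, stamped at the window start, and trailing partial windows are
discarded (partial epochs are never scored). Collapsing with `w = s = Δ`
is the identity. Window statistics are order-preserving, so
`mean ≤ max` elementwise on identical windows; this is why mean-collapsed
variants need smaller normalization constants (less "weakening") than
max-collapsed ones. Collapsing is downsampling with non-standard sample
selection and no anti-aliasing stage, so above-Nyquist rhythms fold into
the epoch band. An optional zero-phase Butterworth pre-filter (order 4,
cutoff at the post-collapse Nyquist `1/(2s)` Hz, recorded in the output
metadata) is provided as a remediation, but is **off by default**: the
shipped presets must reproduce the original, aliasing-prone procedures
exactly.

**FIR scoring.** The score is
`D[n] = bias + scale · Σ_{i=-F..P} W(i) X[n-i]` with `P` past and `F`
future taps. Re-indexing gives a causal filter `b(j) = W(j-F)` of order
`K = F + P` whose output, advanced by `F` samples, equals `D` exactly on
the shared valid range (verified to < 1e-10 over random kernel/series
pairs). Scores are emitted only where the kernel has full support: the
first `P` and last `F` epochs yield no score. No padding convention is
fabricated; the valid range is recorded on the score series. Labels:
wake iff the score strictly exceeds the threshold (or strictly falls
below it, for sleep-probability-style scores); ties always label sleep,
because the published decision rules are strict inequalities.

A note on index conventions: with `X[n-i]`, positive `i` reaches past
epochs, so the future span `F` is what becomes the causal delay. Field
names in `ScoringKernel` follow this arithmetic (`future_span` = delay).

**Rescoring.** Rules of the form "after ≥ X min of state A, the next
Y min not already B become B" are applied left-to-right on a frozen copy
of the input labels: a relabeled epoch never extends a triggering run
within the same rule application (this prevents unbounded chain
reactions that no published description mentions). Rules in a list apply
sequentially, each on the previous output, so a later rule *can* build
on earlier relabels; regression fixtures pin both this and the fact that
rule order matters. Published rule sets are shipped in minutes and
converted by the preset's epoch length. The historical rule sets also
contain two symmetric rules ("a short sleep bout *surrounded* by long
wake on both sides is rescored wake"); these do not fit the one-sided
run-then-span template this engine implements and are not shipped.

**Sazonov and the logit bridge.** The logistic model
`p[n] = σ(d + Σ A(i) max[n-i])` joins the linear family because
`p > 0.5 ⇔ α > 0` for `α = logit(p)`; the intercept `d` folds into the
decision threshold without changing any label (property-tested in both
threshold directions). Multi-channel logistic configurations (a sum of
single-channel FIR scores over differently collapsed inputs with one
shared intercept) are supported by `score_multi_channel` but ship
without a preset.

**Sadeh.** `PS[n] = FIR part + Σ C(k) φ_n(k) + d`, where the `φ` are
nonlinear: an 11-epoch centered mean (the FIR part: all coefficients
1/11, order 10, delay 5), the sample SD of the scored epoch and its 5
predecessors, the count of window epochs with activity in [50, 100)
("NAT"), and `ln(activity + 1)`. `PS ≥ 0` scores sleep. The SD divisor
(n−1) and the +1 log offset are pinned in the variant config; both
choices are recorded because the original descriptions are silent on
them. The nonlinear terms are obligatory, so the Sadeh score is *not*
routed through the common FIR pipeline; only its linear kernel enters
spectral analysis. The exact decomposition
`PS = score_convolve(linear kernel) + remainder` is asserted in tests.

## Spectral analysis

The transmittance of a kernel is `|H(e^{iω})|` of its causal form (the
pure delay is magnitude-invariant), with `scale` multiplying |H| and
`bias` excluded (it belongs to the threshold). The DC gain
(`scale · ΣW`, the "weakening") is the reference for the −3 dB cutoff:
the lowest ω where |H| falls to `DC/√2`, converted to Hz by
`f = ω/(2π) · 1/epoch_length`.

Two evaluations are deliberately provided:

- **Converged (default):** 8192-point uniform grid over [0, π), linear
  interpolation at the first crossing. Doubling the grid moves any
  preset's cutoff by far less than 0.5 % (asserted). The −3 dB reference
  is the DC gain, not the global maximum: these are low-pass kernels
  whose maximum is at DC. For rippling magnitudes the lowest-frequency
  crossing is reported.
- **Legacy (`published_cutoff` / the `grid512` report column):** the
  convention under which cutoffs of these filters have historically been
  reported — |H| on the default 512-point grid, the grid point nearest
  to −3 dB on the initial roll-off, reported one grid index low (the
  off-by-one that arises when the DC sample is dropped for
  log-frequency plotting). Its output is quantized to multiples of
  `1/(1024 · epoch_length)` Hz and sits one to two grid steps (~2–4 %)
  below the converged value. It exists purely so that numbers computed
  here are comparable with historically quoted ones; it is not a good
  estimator and nothing else in the package uses it.

Epoch rate for the Hz conversion is per-preset: 60-s epochs everywhere
except Scripps Clinic, whose 13-tap kernel operates on the 30-s epoch
grid of laboratory polysomnography. For the UCSD family, all variants
share one coefficient vector and differ only in `scale`, so their
transmittances differ by a constant factor (spread < 1e-9 asserted) and
their cutoffs are identical: same filter, different weakening.

## Coefficient provenance

Coefficient sets live in per-preset TOML files, weights in the original
publications' printed order (most-past tap first), each citing its
source. Three provenance classes exist and are machine-readable:

1. **Verified transcriptions** — Cole–Kripke (max-10-s overlapping,
   max-30-s, counts/min), Scripps Clinic, Sadeh-1994, the Webster/Cole
   rescoring rules.
2. **Unverified transcriptions** (noted in the citation string) — the
   Cole–Kripke max-10-s non-overlapping vector and the Webster
   max-60-s vector, which could not be checked against their original
   tables and whose spectral behaviour is partly inconsistent with
   historically reported values.
3. **Synthetic surrogates** (`synthetic = true`, `_synthetic` file
   names) — Webster max-10-s and both UCSD variants, whose published
   constants could not be sourced at all. Surrogates use uniform weights
   over the documented tap span and sensible scales; they keep the
   registry complete and the structural properties testable, but any
   number computed from them characterizes the surrogate. The Sadeh-1989
   variant likewise runs on a clearly-marked surrogate weight set (its
   machinery — order-0 FIR plus SD/NAT/log features — is real).

## The synthetic generator

`SimulationConfig` defaults describe one 8-hour night at the classical
10-s device interval: wake bouts at lights-off (30 min), mid-night
(10 min) and before rising (30 min); Poisson counts with mean 150 per
sample in wake versus 0.2 in sleep; and two 60-s wake-intensity
movement bursts per hour of sleep. Counts are device-arbitrary; the
wake level is chosen so that every shipped algorithm's published
normalization ("score > threshold means wake") separates the two states
— the Sadeh score is the binding constraint, needing wake epochs above
~100 counts. Ground truth is constructed, not sampled, so agreement
accounting is exact; bursts do not alter it (they are sleep-time
movement). The generator is seeded (`numpy.random.default_rng`) and
bitwise reproducible.

What it does *not* emulate: circadian modulation, sleep-stage
microstructure, device-specific count calibration, inter-subject
variability. Passing roundtrip tests therefore show pipeline
correctness and inter-algorithm consistency on well-separated
two-state data — not clinical validity on real recordings, for which
published polysomnography comparisons remain the reference.

Burst behaviour is informative: a single 60-s wake-intensity burst is
smeared by the ±4-minute Cole–Kripke kernels into several wake-scored
epochs, reproducing the family's known wake-over-scoring around
movements; the wake-triggered rescoring rules only ever add wake, and a
≥ 4-minute false-wake run (a long burst) triggers them on synthetic
data exactly as specified.

## Numerical and degenerate-input choices

- Collapse windows and hops must be integer multiples of the sample
  interval (`incommensurate window` error otherwise); windows longer
  than the series raise `series too short`.
- Kernels must have at least one non-zero coefficient; a kernel with
  zero DC gain has no passband and cutoff extraction raises.
- All-pass kernels (|H| never reaching −3 dB) return `None` for the
  cutoff.
- `logit` rejects p ∈ {0, 1}.
- The anti-aliasing pre-filter clips filtered counts at zero (low-pass
  undershoot would otherwise produce negative counts).
- Population SD (divisor n) is used for the average row of the cutoff
  table; sample SD (divisor n−1) for the Sadeh SD feature.

## Known limitations

- Four historical coefficient vectors are surrogate or unverified (see
  provenance above); cutoff comparisons for those presets fail against
  historically reported values by construction, and the cutoff-table
  average inherits the discrepancy.
- The "surrounded-by" rescoring rules are not representable in the rule
  engine's template.
- Overlapping sub-window collapsing slides at the available sample
  interval; the original devices' exact overlap phase is not recorded
  in the sources and may differ.
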
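# Methods

`pitcalc` analyzes multi-cell intracellular-calcium recordings of the kind
acquired from acutely resected pituitary-adenoma tissue loaded with a
calcium-sensitive dye (e.g. Fluo-4 AM) and imaged under epifluorescence
during a perifusion stimulation protocol. This note documents the models,
the estimators, every tunable that matters, and what the synthetic-data
experiments do and do not demonstrate.

## The recording model

A session is a cells × frames matrix of raw fluorescence F sampled every
200 ms (5 Hz), structured by a `StimulusProtocol`:

- a 3-min unstimulated **baseline**;
- five 30-s **secretagogue pulses** — CRH, GHRH, GnRH, TRH, and TRH+DA
  (TRH combined with dopamine, separating cells with dopamine receptors
  from pure TRH responders) — each followed by a 15-min wash;
- a terminal 30-s **high-K⁺ depolarization** that fires every live
  excitable cell. Cells responding to it define the viable population:
  the 100% denominator for every proportion reported per tumor.

A *compression factor* shrinks only the washes (e.g. 10× → 90-s washes)
for desk-scale experiments; baseline, pulses and the high-K⁺ epoch keep
their real durations, so every detection window is unchanged.

## Synthetic recordings (the generator)

Each synthetic cell carries hidden labels — viable; spontaneously active
with 1–12 baseline transients; responsive to a subset of the five stimuli
— and the trace is

    F(t) = F0 · b(t) · (1 + s(t) + ε(t)),

with F0 ~ U(80, 120) a.u., b(t) a mono-exponential-plus-offset
photobleaching factor normalized to 1 at t = 0 and 1 − `bleach_depth` at
the end of the recording (default depth 0.2, τ = 300 s), ε(t) i.i.d.
Gaussian per frame in ΔF/F units (default SD 0.02), and s(t) a sum of
transient kernels.

Transients are differences of exponentials
`exp(−t/τ_d) − exp(−t/τ_r)`, peak-normalized. Two shape classes mirror
the two morphologies seen in these recordings: **fast** (τ_r = 0.2 s,
τ_d = 1.2 s; total width a few seconds) and **prolonged** (τ_r = 2 s,
τ_d = 30 s; full width at half maximum ≈ 28 s). Spontaneous cells with a
single event may draw the prolonged class (probability 0.3); cells with
several events are always fast so that up to 12 events fit in the
baseline without overlap (onsets are spaced by at least the fast-kernel
support). Responding cells get one fast transient per stimulus with onset
uniform within 5 s of pulse start; every viable cell gets a strong fast
transient at the high-K⁺ pulse. Peak amplitudes default to 0.5 ΔF/F
(spontaneous), 1.0 (responses), 2.0 (high K⁺), each jittered per cell by
U(0.8, 1.2); spontaneous-to-evoked amplitude ratios are free parameters,
not calibrated quantities. Transients are truncated at the boundary of
their designated span (baseline events at baseline end; responses at the
next pulse start) and every truncation is reported, never silent.

Population composition is realized **exactly**: the requested fractions
(viable; spontaneous; non/mono/multi-responsive) are allocated by
largest-remainder rounding, not binomial sampling, so recovery
experiments measure detection error only, with zero sampling error in the
ground truth. One root seed drives two independent substreams (labels;
trace realization), making recordings bit-reproducible.

## Trace processing

**Photobleach correction.** A running 10th-percentile envelope (window =
5% of frames) tracks the bleaching floor beneath positive-going
transients. A mono-exponential plus offset is fit to the envelope;
the fit is asymmetric — envelope stretches still sitting clearly above
the curve (long transients that survive the percentile filter) are
discarded over up to three refits. Two numerical details matter: a
centered rolling percentile of a monotone-decaying floor *lags* it by
(0.5 − p/100)·window, which is undone analytically after fitting; and τ
is bounded below by the envelope window, beneath which it is
unidentifiable. Non-convergent fits fall back to a linear detrend,
flagged per cell. The fitted curve is divided out, preserving the initial
level. On noiseless synthetic recordings the corrected-then-normalized
traces match ground-truth ΔF/F within 0.02 everywhere (a CI property).

**ΔF/Fmin.** Fmin is the 5th percentile (lower-sample convention) of the
corrected trace over the baseline epoch — robust to noise undershoot,
unlike the global minimum — and ΔF/Fmin = (F − Fmin)/Fmin. Cells with
Fmin ≤ 0 are flagged invalid and excluded. The order is fixed:
correct, then normalize, recorded in the output metadata. Because Fmin is
a low percentile, the quiescent ΔF/Fmin level sits slightly above zero;
all excursion thresholds below are therefore counted from the per-cell
baseline **median** (the "center"), which is exactly zero for an
idealized zero-centered trace.

**Noise scale.** The per-cell noise SD is estimated as 1.4826 × MAD of
the first-differenced baseline ΔF/F divided by √2 — insensitive to
events, which occupy contiguous stretches.

**Viability gate.** A cell is viable iff its peak ΔF/Fmin inside
[high-K⁺ start, end + 10 s] exceeds center + max(k_K · SD, floor), with
k_K = 5 and floor = 0.05. On default-noise synthetic recordings the gate
reaches sensitivity and specificity 1.0 at n = 500 (tested ≥ 0.99), and
the decision is invariant to k_K ∈ [3, 8] when responses are strong.

## Event detection

An event is a maximal run of frames with ΔF/Fmin ≥ center +
max(k·SD, 0.02), k = 3.5 by default. Runs separated by < 0.4 s are
merged (a one-frame noise dip is not two events); merged runs shorter
than 0.6 s (3 frames at 5 Hz) are dropped. Events of duration ≥ 10 s are
classed *prolonged*, otherwise *fast*; the 10-s cut cleanly separates the
two generator kernels (above-threshold widths ≈ 2–4 s vs ≈ 60 s at
default amplitudes). All four knobs are config keys. A brute-force
frame-by-frame oracle (no merging, no minimum duration) is part of the
package; the production detector with those features disabled must equal
it exactly, and does, over hundreds of random traces in CI.

Detected-event counts are monotone non-increasing in the threshold for
traces of well-separated transients (the regime the detector targets and
the generator produces); heavily overlapped bimodal excursions can in
principle split as the threshold rises, which is why the generator
enforces onset separation.

Per-cell rates are reported in events/min over the baseline (and as
events/recording); a cell is *spontaneously active* iff it has ≥ 1
baseline event. Population spontaneous fractions are always over viable
cells.

## Response classification

For each secretagogue pulse the response window is [pulse start, pulse
end + 30 s]. The same detector (same threshold semantics) is run from
30 s before the window so that a transient already in progress at window
start keeps its true onset; a cell responds iff a detected event *begins*
inside the window. A transient starting 2 s before the pulse is wash
activity, even if its tail overlaps the window. Whether a rise must begin
during the 30-s application or merely near it is not standardized; the
post-window is therefore configurable.

Categories follow the counting rule: **non-responsive** (no secretagogue
response; depolarized by high K⁺ only), **mono-responsive** (exactly
one), **multi-responsive** (two or more). TRH and TRH+DA count as
distinct stimuli by default (a config switch collapses them onto one TRH
axis). Spontaneous activity is a separate attribute and never alters the
category. An optional Poisson-coincidence test (off by default) demotes
response calls in cells whose spontaneous rate makes an onset inside the
window unremarkable at significance α.

Tumor profiles are percentages over viable cells: spontaneous,
non/mono/multi (summing to 100 by construction), and per-stimulus
response percentages.

## Tumor profiling

The feature table holds, per tumor: the four percentages above, the five
per-stimulus percentages, and the maximal tumor diameter (cm). Columns
are z-scored (ddof = 1); constant columns are dropped with a report. PCA
is an eigendecomposition of the feature covariance, with each component's
sign fixed so its largest-magnitude loading is positive (deterministic
across backends). Hierarchical clustering uses correlation distance
(1 − Pearson r between tumor rows) with complete linkage — the linkage
is a package choice, as only the plotting tool is standardized in this
field — and ties merge lowest-index first.

The **recurrence rule** is the conjunction of three clauses on the
fingerprint: spontaneous activity present (pct > 0), more than 20%
multi-responsive cells, and fewer than 50% non-responsive cells; each
cut-off is configurable, and the rule returns which clauses fired. It is
monotone: raising the multi or spontaneous percentage, or lowering the
non-responsive percentage, never flips a recurrent prediction off. With
n = 13 tumors this rule is a *reproduction* of a reported association,
not a validated out-of-sample predictor.

`summarize_cohort` recomputes counts and percentages from the packaged
13-patient characteristics table by exact string-category matching
("All" counts toward every hormone-deficiency axis). The recomputed
cohort means (age 55.6 ± 10.1 y; diameter 4.13 ± 1.49 cm) are the
table's own values; externally quoted summary statistics that conflict
with the table are deliberately not targeted.

## Recovery experiments and problem sizes

The per-tumor percentages this package is anchored to come from patient
recordings that are not publicly deposited, so they are reproduced as
parameter-recovery experiments: a scenario builds those percentages into
the generator exactly, the pipeline runs blind to ground truth, and the
recovered percentage is compared to the anchor. The standard scenario
uses 500 viable cells, default noise and bleaching, 10×-compressed washes
and a fixed seed; each runs in well under a minute on one CPU. The
13-tumor synthetic-cohort drivers use 80 cells per tumor and
20×-compressed washes. Recovered values sit within a few tenths of a
percentage point of the built-in fractions across seeds.

What passing these experiments shows: the processing, detection and
classification chain recovers known cellular phenotypes through realistic
noise, bleaching and epoch structure, with correctly composed
denominators. What it does not show: performance under real-tissue
nuisances the generator deliberately omits — motion, focus drift,
ROI cross-contamination, overlapping cells, dye-loading heterogeneity,
non-exponential bleaching, cell–cell coupling, or secretagogue diffusion
delays. Synthetic response kinetics are also idealized; real response
latencies and durations vary more than the 5-s onset window used here.

## Degenerate inputs and edge behavior

- Zero viable cells (nothing passes the high-K⁺ gate): explicit error;
  every downstream proportion would be undefined.
- Fmin ≤ 0 after correction: cell flagged invalid, excluded, reported.
- Noise SD ≈ 0 (noiseless or clipped traces): the absolute threshold
  floors (0.02 detection, 0.05 viability) keep thresholds positive.
- Baseline shorter than the minimum event duration: error.
- Recordings shorter than 60 frames: photobleach correction refuses.
- Protocols must contain exactly one baseline and one high-K⁺ epoch,
  with high K⁺ last and no duplicated secretagogue.
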
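# Methods

## Analysis model

A recording is a cells × frames fluorescence matrix sampled uniformly
(default 0.5 Hz) across a five-regime glucose protocol with half-open
windows LG1 [0, 300) s, ON [300, 420), HG [600, 1000), OFF [1080, 1200),
LG2 [1400, 1800). All analyses treat a regime window as stationary.

**Conditioning.** Photobleaching is modeled as a per-cell multiplicative
drift d(t) = c₀ + c₁t + c₂e^(−t/τ), least-squares fitted to the
concatenated low-glucose (LG1 + LG2) samples only — fitting the full trace
would absorb the glucose response into the drift — and divided out as
d(t)/d(0). Non-convergent fits fall back to a linear fit and flag the
cell. Traces are then expressed as F/F₀ (F₀ = mean over the first 60 s of
LG1; the protocol fixes only that F₀ is the *initial* level) and min–max
rescaled to [0, 1]. Rescaling is affine per cell, so every Pearson
correlation is unchanged by it; constant traces map to zeros and are
flagged rather than erroring.

**Beta-cell classification.** A cell is beta iff (i) it shows no
low-glucose oscillations, (ii) its HG mean exceeds the LG1 mean by ≥ 1.2×,
and (iii) its LG2 mean returns to within ±20% of LG1 (reversibility). The
oscillation score is a threshold-crossing count: the LG1 segment is
detrended with a cubic polynomial (removing slow drift of period ≳ window
length while leaving tens-of-seconds oscillations intact) and the score is
the fraction of frames beyond m·σ (m = 3), with σ the imaging-noise SD
estimated from first differences, std(Δx)/√2. The segment's own SD cannot
serve here: a bounded sinusoid never exceeds ~1.4 of its own SD, so any
same-segment SD threshold is blind to oscillations; the difference-based σ
tracks frame-to-frame noise only. Quiescent cells score ≲ 0.07 and genuine
low-glucose oscillators ≳ 0.3 on synthetic data, so the quiescence cutoff
sits at 0.1. All thresholds are configurable (`ClassifyCriteria`).

**Network construction.** R is the Pearson matrix of a regime window
(constant traces contribute zeros, flagged). An edge joins cells with
R_ij > R_th, strictly — "exceeds" excludes ties — with R_th = 0.75 by
default and always positive; negative correlations never create edges.
The significance cutoff inverts t = R√((n−2)/(1−R²)) at the two-tailed
critical t with df = n−2 (two-tailed is the conservative choice where
tailedness is unspecified): R_crit = t_c/√(n−2+t_c²), strictly decreasing
in n. Thresholding below R_crit(n, 0.001) warns. For a 100-s window at
0.5 Hz (n = 50) the p < 0.001 cutoff is ≈ 0.45.

**Graph metrics.** C_i counts links among a node's neighbors over the
possible ones; C_i = 0 for degree < 2 and such nodes stay in C_avg, which
keeps the average defined on sparse low-glucose networks. E_glob is the
mean inverse shortest-path length with 1/∞ = 0 (Latora–Marchiori), so it
remains defined when networks contain isolated nodes, as low-glucose
networks do; the alternative 1/⟨L⟩ would be undefined there. The random
reference is the uniform fixed-edge-count model G(n, m) — the same number
of nodes, links and hence mean degree — averaged over 100 seeded
realizations (degenerate densities m = 0 and m = max are exact). S is the
quotient of C_avg/C_rand by E_rand/E_glob; zero denominators flag the
summary as degenerate instead of producing infinities.

**Degree distributions.** G(k) = P(degree ≥ k) (weak inequality, the
standard for cumulative degree distributions) on degrees normalized per
islet by that islet's k_max; pooling evaluates each islet's curve on a
common 20-point grid over (0, 1] and averages. The three decay models
A·x^(−α), A·e^(−x/κ), A·x^(−α)e^(−x/κ) are all linear in log-G space, so
they are fitted by ordinary least squares there, on points with G > 0; r²
is reported on the fitted (log) scale. The truncated model nests the other
two, so its r² is never lower; "best" is the argmax of r². A constant
curve (every connected node at k_max, common in near-empty networks) is
fitted exactly by all three models and reported with r² = 1.

**Spatial analyses.** Distances are Euclidean between ROI centroids (µm).
Default bins: 10 µm in distance, 0.05 in R, 0.1 in C_i. The 2-D
(distance, correlation) histogram counts unordered pairs; out-of-range
pairs go to a reported overflow count so totals always equal N(N−1)/2.
Hub link length selects ⌈0.2·N⌉ nodes by descending degree (ties broken by
ascending cell id for determinism) and averages the lengths of edges with
at least one selected endpoint, each edge once. Empty networks yield NaN
("missing"), never zero.

**Sliding windows.** Metrics are evaluated on windows of length Δτ
(default 100 s) slid by Δτ′ (default non-overlapping); only complete
windows are used and timestamps are window centers. An 1800-s record gives
18 non-overlapping or 86 windows at Δτ′ = 20 s.

**Multi-islet statistics.** Studies aggregate per-islet, per-regime
summaries into medians and min–max ranges. The driven ON/OFF transients
produce near-complete graphs whose random-reference ratios are degenerate,
so small-world and degree analyses cover LG1/HG/LG2 only. Ratio columns
are medians of per-islet ratios, not ratios of medians. Regime effects are
tested per metric with a Friedman ANOVA over the LG1/HG/LG2 triple,
followed by the three paired Wilcoxon signed-rank tests (exact null
distribution for n ≤ 25 without zero differences) at the Bonferroni level
0.05/3 ≈ 0.0167. Post-hoc tests are always computed but carry a
`posthoc_licensed` flag that is false when Friedman p ≥ 0.05, keeping the
output complete while honoring the two-step logic. A metric undefined for
some islet (e.g. link lengths of an edgeless network) is reported with NaN
p-values rather than aborting the paired design.

## Synthetic-data generator

The generator supplies study conditions in place of unavailable
recordings. One islet is a 2-D disc packed by dart throwing with minimum
center distance 0.8 × cell diameter (20 µm); the radius is sized from the
cell count at packing fraction 0.55, and a failed packing reports the
achievable maximum. Non-beta cells (10%) occupy the outermost annulus,
mirroring the peripheral mantle of alpha/delta cells in mouse islets.

A beta-cell trace is

F(t) = B·[1 + e(t)·(P + osc(t − ℓ/v) + w(t)) + (1 − e(t))·g·s(t)] · bleach(t) + noise,

where e(t) is a rise×fall sigmoid envelope (activation midpoints offset
per cell by uniform delays up to 30 s; deactivation delays half that, as
deactivation is the more synchronous transient), P = 1 is the plateau
amplitude over baseline B, and osc is a zero-mean unit-variance burst
train — the positive half-sine raised to the 5th power — of period 40 s
and amplitude 0.25/√2. The burst shape matters: real plateau fast
oscillations are spike-like, and a narrow pulse decorrelates within ~2 s
of lag, whereas a pure sinusoid with the same period barely decorrelates
across an islet; pulses are what make high-glucose networks distance-local
at realistic wave speeds. The phase lag ℓ/v uses the distance ℓ to a wave
source placed uniformly in the disc and a speed v drawn log-uniformly from
8–30 µm/s per recording (no speed is specified by the protocol; the range
covers the slower part of reported islet calcium-wave velocities and is
chosen so that, combined with the burst width, connectivity at R_th = 0.75
spans sparse-local to moderately dense networks). w(t) is a per-cell slow
sinusoidal plateau wander (amplitude 0.07, period 150–400 s) that keeps
plateau correlations below the driven transients.

s(t) is a slow shared baseline drift (dominant period ~350 s, std 1)
coupled per cell with gain g: most cells couple weakly (uniform 0–0.5) and
a 15% minority strongly (2.0–3.1). This produces the distance-independent
correlated pairs that real low-glucose recordings show (their networks are
not empty at R_th = 0.75) while leaving baselines visually "stable"; it
contributes ~10–20% of plateau variance in low glucose, so the strict
"LG variance ≪ HG variance" property is tested with this component
switched off. Non-beta cells instead oscillate in low glucose (amplitude
0.5, period 50 s) and are suppressed during stimulation.

Bleaching multiplies everything by (1 − a·t)(1 − b(1 − e^(−t/τ))) with
a = 5·10⁻⁵ s⁻¹, b = 0.1, τ = 300 s — exactly the linear + exponential
family the correction step inverts. Dye loading varies per cell
(lognormal, σ = 0.3) and i.i.d. Gaussian imaging noise (SD 0.04 of the
per-cell baseline) is added last. Everything is deterministic given the
seed (geometry and dynamics use separate derived streams).

What the generator does *not* emulate: pixel-level imaging (PSF, motion
artefacts, segmentation errors), bursting electrophysiology or
metabolically driven slow/fast mixed oscillations, heterogeneous oscillation
frequencies between cells, wave-source wander within a recording, and 3-D
islet structure. Tests passing on this generator therefore validate the
analysis chain — not the biology of any particular recording.

## Scaled-down study sizes

The reference multi-islet design uses 9 islets of 45–80 cells (about 560
cells total), 900 frames each, with per-islet seeds derived from a single
study seed; random-reference averages use 50–100 realizations. These sizes
keep a full study fit around 15 s on one core while leaving all regime
contrasts far from their decision thresholds.

## Known limitations

- The correlation threshold is global; no per-islet threshold tuning or
  density matching is provided.
- Degree-model fits are unconstrained least squares in log space; fitted
  exponents can be negative on near-degenerate curves, and no monotonicity
  constraint is imposed on the fitted G.
- C_avg is not, in general, monotone in R_th (removing an edge can raise a
  node's clustering); only edge count, k_avg and E_glob decrease
  monotonically by construction.
- The classifier's threshold-crossing score assumes oscillation periods
  well below the LG1 window length; very slow oscillators would be missed.
- Exact Wilcoxon p-values require no zero differences; ties fall back to
  the normal approximation.
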
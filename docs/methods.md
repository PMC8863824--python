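# Methods

`desiram` infers which chemical stimulus a population of tethered *E. coli*
cells received, from the ensemble-averaged clockwise (CW) bias of flagellar
rotation. This note describes the statistical model, the synthetic data
generator used as a stand-in for experimental recordings, the numerical
choices, and the known limitations of both.

## Signal definition

A tethered cell's motor alternates stochastically between CW and CCW
rotation. Recordings are frame-indexed at 10-ms resolution; a frame counts
as a rotation when its angular increment exceeds 7.5°/frame (more than
twice the measurement noise), otherwise it is labelled NONE. The ensemble
CW bias in a 1-s bin is the pooled fraction

    bias = (# CW frames) / (# CW + # CCW frames)

over all cells, with NONE frames excluded from both counts. Bins with no
counted frames are MISSING (NaN), never zero-filled: during excitation all
motion is CCW but some cells pause, and imputing zeros there would bias the
template fit. Frames map to bins by half-open intervals
`[k·Δ, (k+1)·Δ)` relative to recording start. The sign convention
(which increment sign is CW) is a configuration flag, `cw_sign`, defaulting
to negative-increment = CW; the camera orientation determines the true
mapping and is metadata the recording must supply.

## Six-line template and characteristic vector

An attractant step produces a stereotyped trace: flat baseline (L1), an
excitation plateau near zero CW bias (L2), a three-phase piecewise-linear
recovery (L3–L5), and a flat adapted level (L6). The template has nine free
parameters — levels `b, r, v3, v4, v5` and breakpoints `t2..t5` — with `t1`
pinned to the known stimulus-delivery time and the L6 level equal to `v5`.
The excitation level `r` is constrained to `[0, 0.2]` because the attractant
response drives CW bias to ≈ 0; the fit is otherwise unconstrained, so
recovery overshoot (`v3 ≤ v4 ≤ v5` violated) is representable.

Fitting exploits conditional linearity: at fixed breakpoints the trace model
is linear in the five levels (hat-function design matrix), solved by
box-constrained linear least squares (BVLS). Breakpoints are found by a
deterministic two-stage search — a coarse grid over (excitation duration,
total recovery time) with the recovery provisionally split in thirds
(default 5-s steps; benchmark harnesses use 10 s), then Nelder–Mead over all
four durations with the bounded level solve nested inside. The final
residual is checked against the flat-template residual, which is an upper
bound for the optimum. Degenerate segments follow fixed conventions: a
zero-length segment inherits the level to its left, and when L2 contains no
bins the unidentified `r` is reported equal to `b`.

The 15-index characteristic vector is: `y1` = L2 duration; `(y2, y3, y4)`,
`(y5, y6, y7)`, `(y8, y9, y10)` = (amplitude, slope, duration) of L3, L4,
L5; `y11, y12, y13` = baseline, response and final levels; `y14` = total
recovery duration; `y15` = fit RMS. The `y1`–`y4` semantics follow the
template geometry directly; the remaining indices extend the same
(amplitude, slope, duration, level) scheme to the other segments and are a
documented in-package convention — the index map is pluggable so an
alternative 15-tuple can be substituted without touching the classifier.

Under σ = 0.02 i.i.d. Gaussian noise on a 600-bin trace, the per-parameter
median recovery error over 50 noise seeds is ≲ 0.01 in levels and ≲ 5 s in
breakpoints (the interior recovery breakpoints are the softest: the data
genuinely prefer slightly displaced breakpoints under noise — the fitted
SSE is below that of the generating template — so this is estimation error,
not an optimiser artefact).

## Dose–response model functions

For each chemical `s` and index `i`, the index value is regressed on
`u = log10(x / 1 mM)` by ordinary least squares (linear basis by default,
quadratic selectable; each `(s, i)` pair fitted independently). The residual
scale is

    σ_{s,i} = max( residual SD (d.o.f.-corrected),
                   0.05 × SD of y_i over the whole training set, 1e-6 )

The floor prevents zero-variance collapse — with a handful of training
records an index can fit exactly, and a delta-function likelihood would
break leave-one-out evaluation. Each model stores its training concentration
range `[x_lo, x_hi]`; prediction outside the range extrapolates and is
flagged, not refused. Concentrations are strictly positive (log modelling).

## Bayesian classification with concentration marginalised

For a blind vector `{y_i}` the evidence for chemical `s` marginalises the
unknown concentration:

    E(s) = ∫ Π_i A(s,i) · exp( −(y_i − f(x|s,i))² / 2σ_{s,i}² ) dx

with `A(s,i) = 1/(√(2π) σ_{s,i})` by default, making each factor a proper
Gaussian density so chemicals with different residual scales compare fairly
(`amplitude_mode="unit"` preserves the unnormalised reading). The posterior
over chemicals is the evidence normalised under a uniform prior on the
candidate set; the decision is the argmax, with ties resolved to the first
label in model order and flagged.

The integral is evaluated by trapezoidal quadrature on a uniform grid in
`u = log10 x` spanning the chemical's training range padded by 0.5
log-units, prior uniform in `u` (`prior_measure="linear_uniform"` instead
folds `dx = x ln10 du` into the weights). All products and the quadrature
sum are accumulated in the log domain via log-sum-exp; 15-factor likelihoods
far below double-precision underflow remain exact to rounding.

The default grid is 4001 points. When the integrand peaks in the interior
the trapezoid rule is spectrally accurate and a few hundred points suffice,
but for observations best explained at the edge of the padded range the
integrand is a truncated Gaussian and the error reverts to O(h²); 4001
points keeps the probability error below 10⁻⁷ against a 20001-point
reference across the synthetic benchmark, comfortably inside the 10⁻⁶
stability the test suite asserts. Grid size, padding, amplitude mode and
prior measure are all configuration, recorded in output metadata.

The MAP concentration given `s` is the grid argmax of the per-chemical
integrand. When the model functions carry no concentration dependence it
degenerates to the prior mode — returned, but meaningless; callers should
check the evidence.

## Evaluation machinery

* **LOO accuracy** refits the model functions from scratch for every
  held-out record (never merely re-normalises) and classifies it;
  deterministic given data and configuration. Single-chemical groups are
  trivially perfect and flagged degenerate.
* **Random selection (RS)** succeeds with rate `1/NA`. Its finite-sample SD
  is estimated by Monte Carlo over uniform guessing (closed form
  `sqrt(p(1−p)/n)` is the test oracle). The probability that RS reaches a
  given accuracy is the exact binomial tail
  `P(X ≥ ⌈accuracy·n⌉), X ~ Bin(n, 1/NA)`, computed entirely in rational
  arithmetic (`fractions.Fraction`): these tails reach 10⁻¹⁹ scales where
  floating-point products underflow.
* **DSI** (decrease in self-information)
  `= log2(accuracy_classifier) − log2(accuracy_RS)` bits; depends only on
  the accuracy ratio and is undefined at zero accuracy.
* **Spectrum**: all k-subsets of the candidate panel in lexicographic
  order, with a symmetric pairwise accuracy matrix for k = 2 (diagonal
  undefined).

## Synthetic tethered-cell generator

The generator emulates the assay's phenomenology so every pipeline stage is
testable without experimental recordings:

* **Baseline switching** — a two-state telegraph process per cell at frame
  resolution. With target CW probability `p` the mean CW dwell is
  `2·dwell_mean·p` and the CCW dwell `2·dwell_mean·(1−p)`, so the
  stationary CW fraction is exactly `p` and the mean run length
  `dwell_mean` (default 1 s; the assay literature reports no switching
  statistics for this setup, so it is configuration).
* **Cell-to-cell variability** — per-cell baseline bias
  `p_c ~ Beta(mean=0.3, κ=20)` (SD ≈ 0.1, the strong heterogeneity the
  assay shows), and a per-cell lognormal factor with unit median and CV
  `cell_cv` (default 0.3, a guess exposed as config) scaling the excitation
  duration.
* **Excitation** — forced exclusive-CCW rotation for
  `τ(x) = tau0 + beta·log10(x/1 mM)` seconds (population median), clipped
  at zero so sub-threshold concentrations produce no response.
* **Recovery/adaptation** — the target bias climbs piecewise-linearly from
  0 back to `clip(p_c + overshoot)` in three phases whose durations and
  node levels are profile parameters; afterwards the cell is stationary at
  its adapted level.
* **Dropout** — each frame is independently replaced by NONE with
  probability 0.1, emulating below-threshold frames. Real sub-threshold
  frames are autocorrelated (pauses); i.i.d. thinning is an accepted
  simplification.

Randomness is counter-based: every cell stream is seeded by
`SeedSequence((root_seed, …, cell_index))`, so enlarging the population or
the design never reshuffles earlier streams, and the whole training set is
bit-reproducible from the root seed.

Six presets carry the assay's training concentration ranges (l-Asp
0.001–3 mM, l-Glu 0.01–50, d-Asp 0.01–50, l-Asn 0.05–30, l-Cys 0.01–3,
l-Ser 0.001–0.05) with distinct excitation and recovery parameters chosen
so the median excitation plus recovery fits the 600-s observation window
after a 100-s stimulus. Two "beverage" presets are near-identical —
identical recovery geometry, `tau0` differing < 10 % — and differ
essentially only in the dose slope `beta`.

### What the generator does not emulate

Receptor-level mechanism (CheA/CheY signalling, methylation adaptation),
rotation-speed information, autocorrelated pausing, preparation-to-
preparation drift, and — importantly — concentration dependence of the
*recovery* phase: in this generator only the excitation duration depends on
`x`. Two consequences follow. First, synthetic benchmark accuracies
characterise the pipeline under these generative assumptions, not the
assay's experimental performance. Second, the beverage pair is structurally
non-identifiable to a concentration-marginalising classifier: with
identical recovery geometry, a Cola-A observation is matched by Cola-B at a
shifted concentration, so their synthetic LOO accuracy sits at or below
chance (below chance being ordinary leave-one-out pessimism for overlapping
classes — removing the held-out record pulls its own class's fit away from
it). Distinguishing such pairs, as the assay does, requires at least two
indices whose joint concentration dependence differs between the chemicals.

## Benchmark problem sizes

The end-to-end benchmarks use 6 chemicals × 4 log-spaced concentrations
(interior 10–90 % of each range) × 4 replicate traces (16 per chemical), 50
cells per trace, 600-s recordings, stimulus at 100 s; the chance-level null
uses two copies of one profile at the same design; parameter recovery uses
40 traces (8 concentrations × 5 replicates) at `cell_cv = 0.1`; benchmark
template fits use a 10-s coarse grid. Under these conditions the six-way
LOO accuracy is ≈ 0.44–0.53 against the 1/6 baseline (≈ 1.4–1.7 bits DSI),
the well-separated l-Glu/l-Ser pair reaches ≈ 0.94, and the fitted `y1`
dose slope recovers the generating `beta` within ≈ 7–12 %.

## Numerical and degenerate-input conventions

* Template optimiser: Nelder–Mead (`xatol` 0.05 s) from the coarse-grid
  optimum; duration parameters clamped to the admissible simplex inside the
  objective; wholly deterministic.
* Tie-breaks: posterior ties go to the first label in model order and are
  flagged; the breakpoint grid scan keeps the first minimum in scan order.
* Binomial tail rounding: the success count is `⌈accuracy·n⌉`, computed in
  exact rational arithmetic from the given accuracy.
* Quadrature under total underflow (all log-evidences −∞) raises with a
  per-chemical log-evidence report rather than returning NaNs.
* Serialisation: floats round-trip bit-equal through JSON; CSV traces mark
  MISSING as empty cells; all JSON artifacts carry a `format_version`.
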
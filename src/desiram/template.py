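"""Six-line template fitting and characteristic-vector extraction.

An ensemble CW-bias trace follows a stereotyped shape: a flat pre-stimulus
baseline (L1), an excitation plateau near zero CW bias immediately after the
attractant arrives (L2), a three-phase piecewise-linear recovery (L3-L5) and
a flat post-adaptation level (L6).  Fitting this six-line geometric template
to a trace reduces it to 15 scalar indices {y_1..y_15} -- durations,
amplitudes, slopes and levels of the segments -- which are the features all
downstream inference runs on.

Fitting exploits the conditionally-linear structure: for fixed breakpoints
the five levels (b, r, v3, v4, v5) enter linearly and are solved by bounded
linear least squares; the four breakpoints are found by a coarse grid scan
followed by Nelder-Mead refinement.  The procedure is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import lsq_linear, minimize

from .exceptions import BadConfigError, FitError, InvalidDataError
from .traces import CWBiasTrace

UNKNOWN = "UNKNOWN"

N_INDICES = 15

#: Human-readable meaning of each index, in order y1..y15.
INDEX_DESCRIPTIONS = (
    "duration of L2 (excitation plateau), s",
    "amplitude of L3, bias",
    "slope of L3, bias/s",
    "duration of L3, s",
    "amplitude of L4, bias",
    "slope of L4, bias/s",
    "duration of L4, s",
    "amplitude of L5, bias",
    "slope of L5, bias/s",
    "duration of L5, s",
    "baseline level b (L1), bias",
    "response level r (L2), bias",
    "final level g (L6), bias",
    "total recovery duration (L3+L4+L5), s",
    "fit RMS residual, bias",
)


@dataclass
class SixLineTemplate:
    """Geometry of the six-line CW-bias template.

    ``b`` is the L1 baseline level, ``r`` the L2 excitation level; ``t1`` is
    the stimulus time (start of L2) and ``t2..t5`` the ends of L2..L5;
    ``v3, v4, v5`` are the bias levels at the ends of L3, L4, L5.  L6 is flat
    at ``g = v5``.  Levels live in [0, 1]; an attractant response depresses
    CW bias, so ``r <= b``.
    """

    b: float
    r: float
    t1: float
    t2: float
    t3: float
    t4: float
    t5: float
    v3: float
    v4: float
    v5: float

    def __post_init__(self):
        ts = (self.t1, self.t2, self.t3, self.t4, self.t5)
        if any(ts[i] > ts[i + 1] + 1e-9 for i in range(4)):
            raise InvalidDataError(f"breakpoints must be ordered t1<=..<=t5, got {ts}")
        for name in ("b", "r", "v3", "v4", "v5"):
            v = getattr(self, name)
            if not (-1e-9 <= v <= 1 + 1e-9):
                raise InvalidDataError(f"level {name}={v} outside [0, 1]")
        if self.r > self.b + 1e-9:
            raise InvalidDataError(f"response level r={self.r} exceeds baseline b={self.b}")

    @property
    def g(self) -> float:
        """Post-adaptation (L6) level; equals v5 by construction."""
        return self.v5

    @property
    def breakpoints(self) -> tuple:
        return (self.t1, self.t2, self.t3, self.t4, self.t5)


@dataclass
class CharacteristicVector:
    """The 15 template indices for one trace, with optional training label."""

    y: np.ndarray
    label: str = UNKNOWN
    concentration: float = float("nan")  # mM; NaN when unknown
    fit_rms: float = float("nan")

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (N_INDICES,):
            raise InvalidDataError(f"characteristic vector must have {N_INDICES} entries")
        for k in (0, 3, 6, 9, 13):  # durations y1, y4, y7, y10, y14
            if self.y[k] < -1e-9:
                raise InvalidDataError(f"duration index y{k + 1}={self.y[k]} is negative")
        for k in (10, 11, 12):  # levels y11, y12, y13
            if not (-1e-9 <= self.y[k] <= 1 + 1e-9):
                raise InvalidDataError(f"level index y{k + 1}={self.y[k]} outside [0, 1]")

    @property
    def is_labelled(self) -> bool:
        return self.label != UNKNOWN and np.isfinite(self.concentration)


def render_template(tpl: SixLineTemplate, times: Sequence[float]) -> np.ndarray:
    """Evaluate the template at the given times (piecewise linear forward model).

    Conventions: left-closed at t1 (the value at t=t1 is r); segments of zero
    duration contribute nothing.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or (t.size > 1 and np.any(np.diff(t) < 0)):
        raise BadConfigError("times must be a 1-D ascending sequence")
    y = np.full(t.shape, tpl.v5, dtype=float)
    y[t < tpl.t1] = tpl.b
    y[(t >= tpl.t1) & (t <= tpl.t2)] = tpl.r
    for ta, tb, va, vb in (
        (tpl.t2, tpl.t3, tpl.r, tpl.v3),
        (tpl.t3, tpl.t4, tpl.v3, tpl.v4),
        (tpl.t4, tpl.t5, tpl.v4, tpl.v5),
    ):
        if tb > ta:
            m = (t > ta) & (t <= tb)
            y[m] = va + (vb - va) * (t[m] - ta) / (tb - ta)
    return y


def _design_matrix(t: np.ndarray, t1: float, t2: float, t3: float, t4: float, t5: float):
    """Design matrix for the levels (b, r, v3, v4, v5) at fixed breakpoints.

    The template is linear in the five levels; each column is the hat
    function multiplying one level.
    """
    X = np.zeros((t.size, 5))
    X[t < t1, 0] = 1.0  # b on L1
    m2 = (t >= t1) & (t <= t2)
    X[m2, 1] = 1.0  # r on L2
    segs = ((t2, t3, 1, 2), (t3, t4, 2, 3), (t4, t5, 3, 4))
    for ta, tb, ca, cb in segs:
        if tb > ta:
            m = (t > ta) & (t <= tb)
            w = (t[m] - ta) / (tb - ta)
            X[m, ca] += 1.0 - w
            X[m, cb] += w
    X[t > t5, 4] = 1.0  # g = v5 on L6
    return X


_LEVEL_LB = np.array([0.0, 0.0, 0.0, 0.0, 0.0])


def _solve_levels(X: np.ndarray, y: np.ndarray, r_max: float, bounded: bool):
    """Least-squares levels for a fixed-breakpoint design.

    The unbounded path (plain lstsq + clip) is used for scoring during the
    coarse grid scan; the bounded path (box-constrained LSQ) for refinement
    and the final fit.
    """
    ub = np.array([1.0, r_max, 1.0, 1.0, 1.0])
    # Columns for segments with no data are all-zero; ridge-free lstsq still
    # returns a minimum-norm solution (0 for those levels).
    if not bounded:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        beta = np.clip(beta, _LEVEL_LB, ub)
    else:
        beta = lsq_linear(X, y, bounds=(_LEVEL_LB, ub), method="bvls").x
    resid = y - X @ beta
    return beta, float(resid @ resid)


@dataclass
class TemplateFitConfig:
    """Knobs of the template fit.

    ``grid_step`` (s) controls the coarse scan over the excitation duration
    and total recovery time; ``r_max`` caps the excitation level (the
    attractant response drives CW bias to ~0, so a small cap regularises the
    plateau); ``min_bins`` is the minimum number of non-missing bins.
    """

    grid_step: float = 5.0
    r_max: float = 0.2
    min_bins: int = 20
    nm_maxiter: int = 400


def fit_template(
    trace: CWBiasTrace, config: TemplateFitConfig | None = None
) -> tuple[SixLineTemplate, float]:
    """Fit the six-line template to a trace; returns (template, rms).

    t1 is pinned to the known stimulus time.  The breakpoint search runs a
    coarse 2-D grid over (excitation duration, total recovery time) with the
    recovery provisionally split in thirds, then refines all four free
    breakpoints with Nelder-Mead, re-solving the levels by bounded linear
    least squares at every step.  Deterministic given the trace and config.
    """
    cfg = config or TemplateFitConfig()
    t_all = trace.times
    mask = np.isfinite(trace.values)
    if mask.sum() < cfg.min_bins:
        raise FitError(
            f"trace has {int(mask.sum())} non-missing bins; need >= {cfg.min_bins}"
        )
    t = t_all[mask]
    yv = trace.values[mask]
    t1 = trace.stimulus_time
    t_end = trace.duration
    span = t_end - t1

    def sse_for(d2: float, d3: float, d4: float, d5: float, bounded: bool):
        # Clamp durations into the admissible simplex, preserving order.
        d = np.clip([d2, d3, d4, d5], 0.0, None)
        total = d.sum()
        if total > span and total > 0:
            d *= span / total
        t2 = t1 + d[0]
        t3 = t2 + d[1]
        t4 = t3 + d[2]
        t5 = t4 + d[3]
        X = _design_matrix(t, t1, t2, t3, t4, t5)
        beta, sse = _solve_levels(X, yv, cfg.r_max, bounded)
        return sse, (t2, t3, t4, t5), beta

    # Coarse grid: excitation duration d2 and total recovery T (split 1/3 each).
    step = cfg.grid_step
    best = None
    for d2 in np.arange(0.0, span + step / 2, step):
        for T in np.arange(0.0, span - d2 + step / 2, 3 * step):
            sse, bps, _ = sse_for(d2, T / 3, T / 3, T / 3, bounded=False)
            if best is None or sse < best[0] - 1e-12:
                best = (sse, (d2, T / 3, T / 3, T / 3))
    if best is None:  # pragma: no cover - span >= 0 always yields one cell
        raise FitError("empty breakpoint grid", diagnostics={"span": span})

    # Nelder-Mead over the four durations with bounded inner level solve.
    x0 = np.array(best[1])

    def objective(x):
        return sse_for(*x, bounded=True)[0]

    res = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={
            "maxiter": cfg.nm_maxiter,
            "xatol": 0.05,
            "fatol": 1e-10,
            "initial_simplex": _initial_simplex(x0, scale=max(step, 1.0)),
        },
    )
    x_best = res.x if res.fun <= objective(x0) else x0

    sse, (t2, t3, t4, t5), beta = sse_for(*x_best, bounded=True)
    b, r, v3, v4, v5 = beta

    # Flat-template residual is an upper bound on the optimum; guard against
    # a pathological optimiser trajectory.
    flat_sse = float(np.sum((yv - yv.mean()) ** 2))
    if sse > flat_sse + 1e-9:
        raise FitError(
            "optimiser did not reach the flat-template residual",
            best_so_far=(t2, t3, t4, t5, beta),
            diagnostics={"sse": sse, "flat_sse": flat_sse, "nm": res.message},
        )

    # Degenerate-segment conventions: a zero-length segment inherits the level
    # to its left so spurious amplitudes cannot appear, and an empty L2 leaves
    # r unidentified, so it is reported equal to b.
    eps = trace.bin_width / 2
    if t2 - t1 < eps and not ((t >= t1) & (t <= t2)).any():
        r = b
    if t3 - t2 < 1e-9:
        v3 = r
    if t4 - t3 < 1e-9:
        v4 = v3
    if t5 - t4 < 1e-9:
        v5 = v4
    r = min(r, b)

    tpl = SixLineTemplate(
        b=float(b), r=float(r), t1=t1, t2=float(t2), t3=float(t3),
        t4=float(t4), t5=float(t5), v3=float(v3), v4=float(v4), v5=float(v5),
    )
    rms = float(np.sqrt(sse / t.size))
    return tpl, rms


def _initial_simplex(x0: np.ndarray, scale: float) -> np.ndarray:
    simplex = np.tile(x0, (x0.size + 1, 1))
    for k in range(x0.size):
        simplex[k + 1, k] += scale
    return simplex


def template_to_vector(
    tpl: SixLineTemplate,
    fit_rms: float = 0.0,
    label: str = UNKNOWN,
    concentration: float = float("nan"),
) -> CharacteristicVector:
    """Map a fitted template to the 15-index characteristic vector.

    y1 is the duration of L2; (y2, y3, y4), (y5, y6, y7) and (y8, y9, y10)
    are the (amplitude, slope, duration) of L3, L4 and L5; y11..y13 are the
    baseline, response and final levels; y14 is the total recovery duration
    and y15 the fit RMS.  Slopes of zero-duration segments are 0.
    """
    def amp_slope_dur(va, vb, ta, tb):
        dur = tb - ta
        amp = vb - va
        slope = amp / dur if dur > 0 else 0.0
        return amp, slope, dur

    y = np.empty(N_INDICES)
    y[0] = tpl.t2 - tpl.t1
    y[1], y[2], y[3] = amp_slope_dur(tpl.r, tpl.v3, tpl.t2, tpl.t3)
    y[4], y[5], y[6] = amp_slope_dur(tpl.v3, tpl.v4, tpl.t3, tpl.t4)
    y[7], y[8], y[9] = amp_slope_dur(tpl.v4, tpl.v5, tpl.t4, tpl.t5)
    y[10] = tpl.b
    y[11] = tpl.r
    y[12] = tpl.g
    y[13] = y[3] + y[6] + y[9]
    y[14] = fit_rms
    return CharacteristicVector(
        y=y, label=label, concentration=concentration, fit_rms=fit_rms
    )
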
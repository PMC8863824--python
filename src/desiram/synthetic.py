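"""Synthetic tethered-cell recordings.

Emulates the phenomenology of a population of tethered *E. coli* cells
responding to an attractant step:

* baseline stochastic CW/CCW switching (a two-state telegraph process at
  10-ms frame resolution, with a per-cell stationary CW bias drawn from a
  Beta distribution -- cell-to-cell variability is large);
* at the stimulus, an exclusive-CCW excitation window whose duration grows
  linearly in log10 concentration, tau(x) = tau0 + beta * log10(x/1 mM),
  scaled per cell by a lognormal factor with unit median;
* a three-phase piecewise-linear recovery of the target CW bias back toward
  the cell's baseline (optionally with overshoot), i.e. adaptation;
* per-frame NONE dropout emulating frames whose angular motion falls below
  the counting threshold.

The telegraph process is parameterised so that at target bias p the mean CW
dwell is 2*dwell_mean*p and the mean CCW dwell 2*dwell_mean*(1-p): the
stationary CW fraction is exactly p and the average run length dwell_mean.

All randomness flows from a single root seed through counter-based
``SeedSequence`` keys, so enlarging ``n_cells`` never reshuffles the streams
of earlier cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .concentration import TrainingSet
from .exceptions import BadConfigError
from .template import TemplateFitConfig, fit_template, template_to_vector
from .traces import CCW, CW, NONE, CWBiasTrace, DirectionSeries, ensemble_cw_bias

try:  # compiled telegraph walk; the pure-python path is semantically identical
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    _njit = None


def _walk_states(s0, p_switch_cw, p_switch_ccw, u):
    """Walk the two-state chain; states +1 (CW) / -1 (CCW), one per frame."""
    n = u.size
    out = np.empty(n, np.int8)
    s = s0
    for j in range(n):
        if s == 1:
            if u[j] < p_switch_cw[j]:
                s = -1
        else:
            if u[j] < p_switch_ccw[j]:
                s = 1
        out[j] = s
    return out


if _njit is not None:
    _walk_states = _njit(cache=False)(_walk_states)


@dataclass
class SyntheticChemicalProfile:
    """Generative parameters for one chemical's response phenotype.

    ``tau0`` is the population-median excitation duration at 1 mM and
    ``beta`` its slope per decade of concentration.  Recovery is split into
    three linear phases: ``recovery_fracs`` are the shares of
    ``recovery_total`` spent in each phase and ``recovery_shape`` the bias
    level at the end of each phase as a fraction of the span from the
    excited level (0) to the cell's final level.  ``overshoot`` shifts the
    final level relative to the cell's own baseline.  ``cell_cv`` is the
    coefficient of variation of the per-cell excitation duration;
    ``baseline_mean``/``baseline_kappa`` parameterise the Beta distribution
    of per-cell baseline CW bias.
    """

    name: str
    tau0: float  # s, excitation duration at 1 mM
    beta: float  # s per log10-mM
    recovery_total: float  # s
    recovery_fracs: tuple = (1 / 3, 1 / 3, 1 / 3)
    recovery_shape: tuple = (0.5, 0.8, 1.0)
    overshoot: float = 0.0  # bias units, final minus baseline
    conc_range: tuple = (0.01, 10.0)  # mM
    cell_cv: float = 0.3
    baseline_mean: float = 0.3
    baseline_kappa: float = 20.0

    def __post_init__(self):
        if self.tau0 < 0 or self.recovery_total < 0:
            raise BadConfigError("tau0 and recovery_total must be >= 0")
        if self.cell_cv < 0:
            raise BadConfigError("cell_cv must be >= 0")
        lo, hi = self.conc_range
        if not (0 < lo < hi):
            raise BadConfigError(f"conc_range must be positive and ordered, got {self.conc_range}")
        if not (0 < self.baseline_mean < 1):
            raise BadConfigError("baseline_mean must lie in (0, 1)")
        fr = np.asarray(self.recovery_fracs, dtype=float)
        if fr.shape != (3,) or (fr <= 0).any() or abs(fr.sum() - 1) > 1e-9:
            raise BadConfigError("recovery_fracs must be 3 positive fractions summing to 1")
        sh = np.asarray(self.recovery_shape, dtype=float)
        if sh.shape != (3,) or (sh < 0).any() or (sh > 1).any():
            raise BadConfigError("recovery_shape must be 3 fractions in [0, 1]")

    def excitation_duration(self, x: float) -> float:
        """Population-median forced-CCW duration at concentration x (mM)."""
        return max(0.0, self.tau0 + self.beta * np.log10(x))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "tau0": self.tau0,
            "beta": self.beta,
            "recovery_total": self.recovery_total,
            "recovery_fracs": list(self.recovery_fracs),
            "recovery_shape": list(self.recovery_shape),
            "overshoot": self.overshoot,
            "conc_range": list(self.conc_range),
            "cell_cv": self.cell_cv,
            "baseline_mean": self.baseline_mean,
            "baseline_kappa": self.baseline_kappa,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticChemicalProfile":
        d = dict(d)
        for key in ("recovery_fracs", "recovery_shape", "conc_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SimulationConfig:
    """Recording geometry and population settings for one simulated assay."""

    frame_interval: float = 0.01  # s (100 fps)
    bin_width: float = 1.0  # s
    duration: float = 600.0  # s, observation cap
    stimulus_time: float = 100.0  # s
    n_cells: int = 100
    dwell_mean: float = 1.0  # s, mean CW/CCW run length at baseline
    none_prob: float = 0.1  # per-frame below-threshold probability
    seed: int = 0

    def __post_init__(self):
        for name in ("frame_interval", "bin_width", "duration", "dwell_mean"):
            if getattr(self, name) <= 0:
                raise BadConfigError(f"{name} must be > 0")
        if self.duration > 600.0:
            raise BadConfigError("duration must be <= 600 s")
        if not (0 <= self.stimulus_time <= self.duration):
            raise BadConfigError("stimulus_time must lie within [0, duration]")
        if self.n_cells < 1:
            raise BadConfigError("n_cells must be >= 1")
        if not (0 <= self.none_prob < 1):
            raise BadConfigError("none_prob must lie in [0, 1)")


def _target_bias_schedule(profile, x, cfg, p_c, tau_c):
    """Per-frame target CW probability for one cell."""
    n = int(round(cfg.duration / cfg.frame_interval))
    t = np.arange(n) * cfg.frame_interval
    final = float(np.clip(p_c + profile.overshoot, 0.02, 0.98))
    p = np.full(n, p_c)
    stim = cfg.stimulus_time
    rec0 = stim + tau_c
    # Excitation: exclusive CCW.
    p[(t >= stim) & (t < rec0)] = 0.0
    # Recovery: piecewise-linear from 0 to the final level in three phases.
    durs = np.asarray(profile.recovery_fracs) * profile.recovery_total
    node_t = rec0 + np.concatenate([[0.0], np.cumsum(durs)])
    node_p = np.concatenate([[0.0], np.asarray(profile.recovery_shape) * final])
    m = (t >= rec0) & (t < node_t[-1])
    if m.any():
        p[m] = np.interp(t[m], node_t, node_p)
    p[t >= node_t[-1]] = final if tau_c > 0 else p_c
    if tau_c <= 0:
        # No excitation: the cell never leaves its stationary regime.
        p[:] = p_c
    return p


def simulate_cell(
    profile: SyntheticChemicalProfile,
    x: float,
    cfg: SimulationConfig,
    cell_seed,
) -> DirectionSeries:
    """Simulate one tethered cell's per-frame direction labels.

    ``cell_seed`` is anything ``numpy.random.default_rng`` accepts (the
    ensemble driver passes counter-based ``SeedSequence`` keys).  Draw order
    is fixed (baseline, excitation factor, switching uniforms, NONE mask),
    so output is bit-reproducible for a given seed.
    """
    if not (np.isfinite(x) and x > 0):
        raise BadConfigError(f"concentration must be > 0, got {x}")
    rng = np.random.default_rng(cell_seed)
    dt = cfg.frame_interval

    a_beta = profile.baseline_mean * profile.baseline_kappa
    b_beta = (1 - profile.baseline_mean) * profile.baseline_kappa
    p_c = float(np.clip(rng.beta(a_beta, b_beta), 0.02, 0.98))

    if profile.cell_cv > 0:
        sig = np.sqrt(np.log1p(profile.cell_cv**2))
        eps = float(np.exp(sig * rng.standard_normal()))  # unit median
    else:
        eps = 1.0
    tau_c = max(0.0, profile.excitation_duration(x)) * eps

    p_t = _target_bias_schedule(profile, x, cfg, p_c, tau_c)
    n = p_t.size

    # Telegraph rates from target bias: dwell_cw = 2*dwell_mean*p,
    # dwell_ccw = 2*dwell_mean*(1-p); stationary CW fraction is exactly p.
    with np.errstate(divide="ignore"):
        p_switch_cw = np.minimum(1.0, dt / (2 * cfg.dwell_mean * np.maximum(p_t, 1e-12)))
        p_switch_ccw = np.minimum(1.0, dt / (2 * cfg.dwell_mean * np.maximum(1 - p_t, 1e-12)))
    forced = p_t == 0.0
    p_switch_cw[forced] = 1.0
    p_switch_ccw[forced] = 0.0

    s0 = 1 if rng.random() < p_c else -1
    u = rng.random(n)
    states = np.asarray(_walk_states(np.int8(s0), p_switch_cw, p_switch_ccw, u), dtype=np.int8)

    labels = np.where(states == 1, CW, CCW).astype(np.int8)
    labels[rng.random(n) < cfg.none_prob] = NONE
    return DirectionSeries(
        cell_id=f"{profile.name}_cell",
        labels=labels,
        frame_interval=dt,
        t0=0.0,
    )


def simulate_ensemble(
    profile: SyntheticChemicalProfile,
    x: float,
    cfg: SimulationConfig,
    seed_key: tuple = (),
) -> CWBiasTrace:
    """Simulate ``cfg.n_cells`` independent cells and pool them into a trace.

    Per-cell streams use ``SeedSequence((cfg.seed, *seed_key, cell_index))``;
    increasing ``n_cells`` extends, never reshuffles, the population.
    """
    cells = [
        simulate_cell(
            profile, x, cfg, np.random.SeedSequence((cfg.seed, *seed_key, idx))
        )
        for idx in range(cfg.n_cells)
    ]
    return ensemble_cw_bias(cells, bin_width=cfg.bin_width, stimulus_time=cfg.stimulus_time)


def simulate_training_set(
    profiles,
    concentrations,
    reps: int,
    cfg: SimulationConfig,
    fit_config: TemplateFitConfig | None = None,
) -> TrainingSet:
    """Full synthetic pipeline: ensembles -> template fits -> labelled vectors.

    ``concentrations`` maps profile name to its list of concentrations (mM),
    each within that profile's ``conc_range``.  Every (profile,
    concentration, replicate) triple gets its own counter-derived seed.
    """
    records = []
    for p_idx, profile in enumerate(profiles):
        concs = concentrations[profile.name]
        lo, hi = profile.conc_range
        for c_idx, x in enumerate(concs):
            if not (lo <= x <= hi):
                raise BadConfigError(
                    f"concentration {x} mM outside {profile.name}'s range [{lo}, {hi}]"
                )
            for rep in range(reps):
                trace = simulate_ensemble(profile, x, cfg, seed_key=(p_idx, c_idx, rep))
                tpl, rms = fit_template(trace, fit_config)
                records.append(
                    template_to_vector(tpl, rms, label=profile.name, concentration=x)
                )
    return TrainingSet(records=records, chemicals=[p.name for p in profiles])


def log_spaced_concentrations(profile, n: int, margin: float = 0.1) -> np.ndarray:
    """n concentrations log-spaced across the interior of the profile's range."""
    lo, hi = np.log10(profile.conc_range)
    u = lo + (hi - lo) * np.linspace(margin, 1 - margin, n)
    return np.power(10.0, u)


def default_profiles() -> dict:
    """Six standard-attractant presets plus two near-identical beverages.

    Concentration ranges of the six amino-acid presets match the assay
    ranges (l-Asp 0.001-3, l-Glu 0.01-50, d-Asp 0.01-50, l-Asn 0.05-30,
    l-Cys 0.01-3, l-Ser 0.001-0.05 mM).  Excitation and recovery parameters
    are distinct per chemical so the presets are discriminable; the two
    beverage presets share the recovery geometry and differ essentially only
    in the dose slope of the excitation duration, mimicking two visually
    indistinguishable mixtures with different concentration dependencies.
    """
    profiles = [
        SyntheticChemicalProfile(
            name="L-Asp", tau0=197.0, beta=45.0, recovery_total=180.0,
            recovery_fracs=(0.45, 0.35, 0.20), recovery_shape=(0.55, 0.85, 1.0),
            overshoot=0.02, conc_range=(0.001, 3.0),
        ),
        SyntheticChemicalProfile(
            name="L-Glu", tau0=179.0, beta=60.0, recovery_total=150.0,
            recovery_fracs=(0.30, 0.40, 0.30), recovery_shape=(0.40, 0.75, 1.0),
            overshoot=-0.04, conc_range=(0.01, 50.0),
        ),
        SyntheticChemicalProfile(
            name="D-Asp", tau0=125.0, beta=35.0, recovery_total=240.0,
            recovery_fracs=(0.55, 0.25, 0.20), recovery_shape=(0.65, 0.90, 1.0),
            overshoot=0.05, conc_range=(0.01, 50.0),
        ),
        SyntheticChemicalProfile(
            name="L-Asn", tau0=146.0, beta=50.0, recovery_total=200.0,
            recovery_fracs=(0.25, 0.35, 0.40), recovery_shape=(0.30, 0.60, 1.0),
            overshoot=0.0, conc_range=(0.05, 30.0),
        ),
        SyntheticChemicalProfile(
            name="L-Cys", tau0=123.0, beta=30.0, recovery_total=130.0,
            recovery_fracs=(0.40, 0.20, 0.40), recovery_shape=(0.70, 0.80, 1.0),
            overshoot=-0.06, conc_range=(0.01, 3.0),
        ),
        SyntheticChemicalProfile(
            name="L-Ser", tau0=184.0, beta=25.0, recovery_total=170.0,
            recovery_fracs=(0.35, 0.45, 0.20), recovery_shape=(0.50, 0.95, 1.0),
            overshoot=0.03, conc_range=(0.001, 0.05),
        ),
        SyntheticChemicalProfile(
            name="Cola-A", tau0=160.0, beta=40.0, recovery_total=180.0,
            recovery_fracs=(0.40, 0.30, 0.30), recovery_shape=(0.50, 0.80, 1.0),
            overshoot=0.0, conc_range=(0.1, 2.0),
        ),
        SyntheticChemicalProfile(
            name="Cola-B", tau0=150.0, beta=70.0, recovery_total=180.0,
            recovery_fracs=(0.40, 0.30, 0.30), recovery_shape=(0.50, 0.80, 1.0),
            overshoot=0.0, conc_range=(0.1, 2.0),
        ),
    ]
    return {p.name: p for p in profiles}
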
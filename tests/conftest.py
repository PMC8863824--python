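"""Shared fixtures: small synthetic datasets reused across test modules.

Heavy end-to-end datasets are session-scoped so the full-pipeline tests and
the acceptance checks share one simulation run.
"""

import dataclasses

import numpy as np
import pytest

import desiram as ds


@pytest.fixture(scope="session")
def profiles():
    return ds.default_profiles()


@pytest.fixture(scope="session")
def fast_fit_config():
    # Coarser breakpoint grid keeps full-pipeline tests quick; the refinement
    # stage still polishes the breakpoints.
    return ds.TemplateFitConfig(grid_step=10.0)


def _training(profile_list, n_conc, reps, seed, n_cells, fit_cfg):
    cfg = ds.SimulationConfig(n_cells=n_cells, seed=seed)
    concs = {p.name: ds.log_spaced_concentrations(p, n_conc) for p in profile_list}
    return ds.simulate_training_set(profile_list, concs, reps, cfg, fit_cfg)


@pytest.fixture(scope="session")
def two_chem_training(profiles, fast_fit_config):
    """Well-separated two-chemical training set (L-Glu vs L-Ser, n=16 each)."""
    pair = [profiles["L-Glu"], profiles["L-Ser"]]
    return _training(pair, n_conc=4, reps=4, seed=7, n_cells=50, fit_cfg=fast_fit_config)


@pytest.fixture(scope="session")
def six_chem_training(profiles, fast_fit_config):
    """All six standard attractants, n=16 traces per chemical, seed 7."""
    six = [profiles[n] for n in ("L-Asp", "L-Glu", "D-Asp", "L-Asn", "L-Cys", "L-Ser")]
    return _training(six, n_conc=4, reps=4, seed=7, n_cells=50, fit_cfg=fast_fit_config)


@pytest.fixture(scope="session")
def null_training(profiles, fast_fit_config):
    """Two chemicals generated from the SAME profile: chance-level null."""
    base = profiles["L-Asn"]
    twin = dataclasses.replace(base, name="L-Asn-twin")
    return _training([base, twin], n_conc=4, reps=4, seed=11, n_cells=50,
                     fit_cfg=fast_fit_config)


@pytest.fixture(scope="session")
def six_chem_models(six_chem_training):
    return ds.fit_model_functions(six_chem_training)


def make_linear_models(specs, x_lo=0.1, x_hi=10.0, sigma=1.0):
    """Hand-built ModelSet: specs maps chemical -> (intercept, slope) applied
    to every index."""
    functions = {}
    for s, (a, b) in specs.items():
        for i in range(1, ds.template.N_INDICES + 1):
            functions[(s, i)] = ds.ModelFunction(
                chemical=s, index=i, coef=np.array([a, b]),
                sigma=sigma, x_lo=x_lo, x_hi=x_hi,
            )
    return ds.ModelSet(chemicals=list(specs), functions=functions)


@pytest.fixture(scope="session")
def noisy_roundtrip_errors():
    """Per-parameter template-recovery errors under sigma=0.02 noise, seeds 0..49."""
    tpl = ds.SixLineTemplate(b=0.3, r=0.0, t1=100.0, t2=250.0, t3=300.0, t4=350.0,
                             t5=400.0, v3=0.1, v4=0.25, v5=0.3)
    t = np.arange(600) + 0.5
    clean = ds.render_template(tpl, t)
    names = ("b", "r", "v3", "v4", "v5", "t2", "t3", "t4", "t5")
    errs = {n: [] for n in names}
    for seed in range(50):
        noisy = np.clip(clean + np.random.default_rng(seed).normal(0, 0.02, t.size), 0, 1)
        fit, _ = ds.fit_template(ds.CWBiasTrace(values=noisy, stimulus_time=tpl.t1))
        for n in names:
            errs[n].append(abs(getattr(fit, n) - getattr(tpl, n)))
    return {n: np.asarray(v) for n, v in errs.items()}


@pytest.fixture
def rng():
    return np.random.default_rng(0)
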
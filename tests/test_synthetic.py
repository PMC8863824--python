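"""Synthetic tethered-cell simulator: determinism, phenomenology, presets."""

import dataclasses

import numpy as np
import pytest

import desiram as ds
from desiram.traces import CCW, CW, NONE


@pytest.fixture
def quick_cfg():
    return ds.SimulationConfig(n_cells=20, duration=400.0, stimulus_time=50.0, seed=9)


def fixed_profile(**overrides):
    base = dict(
        name="fixed", tau0=200.0, beta=0.0, recovery_total=100.0,
        conc_range=(0.01, 10.0), cell_cv=0.0, baseline_mean=0.3,
    )
    base.update(overrides)
    return ds.SyntheticChemicalProfile(**base)


class TestSimulateCell:
    def test_deterministic_excitation_window(self, quick_cfg):
        # beta=0, cell_cv=0: the forced-CCW window is exactly tau0 for every
        # cell and concentration.
        prof = fixed_profile()
        cell = ds.simulate_cell(prof, 5.0, quick_cfg, cell_seed=1)
        t = cell.frame_times
        window = (t >= quick_cfg.stimulus_time) & (t < quick_cfg.stimulus_time + 200.0)
        assert not (cell.labels[window] == CW).any()
        # CW motion reappears during recovery.
        after = t >= quick_cfg.stimulus_time + 200.0 + prof.recovery_total
        assert (cell.labels[after] == CW).any()

    def test_zero_or_negative_excitation_is_stationary(self, quick_cfg):
        prof = fixed_profile(tau0=10.0, beta=50.0)  # tau <= 0 below ~0.63 mM
        cell = ds.simulate_cell(prof, 0.01, quick_cfg, cell_seed=1)
        t = cell.frame_times
        pre = cell.labels[t < quick_cfg.stimulus_time]
        post = cell.labels[t >= quick_cfg.stimulus_time]
        bias_pre = (pre == CW).sum() / max((pre != NONE).sum(), 1)
        bias_post = (post == CW).sum() / max((post != NONE).sum(), 1)
        assert abs(bias_pre - bias_post) < 0.15

    def test_fixed_seed_is_bit_identical(self, quick_cfg):
        prof = fixed_profile(cell_cv=0.3)
        a = ds.simulate_cell(prof, 1.0, quick_cfg, cell_seed=123)
        b = ds.simulate_cell(prof, 1.0, quick_cfg, cell_seed=123)
        assert np.array_equal(a.labels, b.labels)

    def test_nonpositive_concentration_rejected(self, quick_cfg):
        with pytest.raises(ds.BadConfigError):
            ds.simulate_cell(fixed_profile(), -1.0, quick_cfg, cell_seed=0)

    def test_none_thinning_rate(self, quick_cfg):
        cfg = dataclasses.replace(quick_cfg, none_prob=0.25)
        cell = ds.simulate_cell(fixed_profile(), 1.0, cfg, cell_seed=4)
        frac = (cell.labels == NONE).mean()
        assert frac == pytest.approx(0.25, abs=0.02)


class TestSimulateEnsemble:
    def test_forced_ccw_window_dominates(self, profiles):
        prof = dataclasses.replace(profiles["L-Glu"], cell_cv=0.1)
        cfg = ds.SimulationConfig(n_cells=50, seed=21)
        trace = ds.simulate_ensemble(prof, 1.0, cfg)
        tau = prof.excitation_duration(1.0)
        lo = int(cfg.stimulus_time)
        hi = int(cfg.stimulus_time + tau * (1 - 2 * prof.cell_cv))
        window = trace.values[lo:hi]
        assert np.nanmean(window) <= 0.02

    def test_prestimulus_bias_matches_baseline_beta_mean(self, profiles):
        prof = profiles["L-Asn"]
        cfg = ds.SimulationConfig(n_cells=80, seed=13)
        trace = ds.simulate_ensemble(prof, 1.0, cfg)
        pre = trace.values[: int(cfg.stimulus_time)]
        # SE over per-bin values (bins are near-independent at 1-s width with
        # 1-s mean dwell); generous 3-SE band against the Beta mean.
        se = np.nanstd(pre, ddof=1) / np.sqrt(np.sum(np.isfinite(pre)))
        assert abs(np.nanmean(pre) - prof.baseline_mean) < max(3 * se, 0.02)

    def test_single_cell_ensemble_equals_own_binned_bias(self, quick_cfg):
        cfg = dataclasses.replace(quick_cfg, n_cells=1)
        prof = fixed_profile()
        trace = ds.simulate_ensemble(prof, 1.0, cfg)
        cell = ds.simulate_cell(prof, 1.0, cfg, np.random.SeedSequence((cfg.seed, 0)))
        direct = ds.ensemble_cw_bias([cell], cfg.bin_width, cfg.stimulus_time)
        np.testing.assert_array_equal(trace.values, direct.values)

    def test_growing_population_extends_not_reshuffles(self, quick_cfg):
        # Counter-based seeding: the first cells are identical whether the
        # population has 3 or 6 members.
        prof = fixed_profile(cell_cv=0.2)
        small = [ds.simulate_cell(prof, 1.0, quick_cfg,
                                  np.random.SeedSequence((quick_cfg.seed, i)))
                 for i in range(3)]
        large = [ds.simulate_cell(prof, 1.0, quick_cfg,
                                  np.random.SeedSequence((quick_cfg.seed, i)))
                 for i in range(6)]
        for a, b in zip(small, large):
            assert np.array_equal(a.labels, b.labels)


class TestSimulateTrainingSet:
    def test_bookkeeping_and_labels(self, profiles, fast_fit_config):
        pair = [profiles["L-Glu"], profiles["L-Ser"]]
        cfg = ds.SimulationConfig(n_cells=25, seed=2)
        concs = {p.name: ds.log_spaced_concentrations(p, 4) for p in pair}
        ts = ds.simulate_training_set(pair, concs, reps=4, cfg=cfg,
                                      fit_config=fast_fit_config)
        assert len(ts) == 2 * 4 * 4
        assert ts.chemicals == ["L-Glu", "L-Ser"]
        assert all(r.is_labelled for r in ts.records)

    def test_bit_reproducible_from_root_seed(self, profiles, fast_fit_config):
        prof = [profiles["L-Cys"]]
        cfg = ds.SimulationConfig(n_cells=15, seed=8)
        concs = {"L-Cys": ds.log_spaced_concentrations(profiles["L-Cys"], 3)}
        a = ds.simulate_training_set(prof, concs, 2, cfg, fast_fit_config)
        b = ds.simulate_training_set(prof, concs, 2, cfg, fast_fit_config)
        for ra, rb in zip(a.records, b.records):
            assert np.array_equal(ra.y, rb.y)

    def test_out_of_range_concentration_rejected(self, profiles, fast_fit_config):
        prof = [profiles["L-Ser"]]  # range 0.001-0.05 mM
        cfg = ds.SimulationConfig(n_cells=5, seed=0)
        with pytest.raises(ds.BadConfigError, match="range"):
            ds.simulate_training_set(prof, {"L-Ser": [1.0]}, 1, cfg, fast_fit_config)


class TestDefaultProfiles:
    def test_assay_concentration_ranges(self, profiles):
        expected = {
            "L-Asp": (0.001, 3.0),
            "L-Glu": (0.01, 50.0),
            "D-Asp": (0.01, 50.0),
            "L-Asn": (0.05, 30.0),
            "L-Cys": (0.01, 3.0),
            "L-Ser": (0.001, 0.05),
        }
        for name, rng_ in expected.items():
            assert tuple(profiles[name].conc_range) == rng_

    def test_beverage_presets_nearly_identical(self, profiles):
        a, b = profiles["Cola-A"], profiles["Cola-B"]
        assert a.recovery_shape == b.recovery_shape
        assert a.recovery_fracs == b.recovery_fracs
        assert abs(a.tau0 - b.tau0) / max(a.tau0, b.tau0) < 0.10
        assert a.beta != b.beta  # the dose slope is what tells them apart

    def test_excitation_fits_observation_window(self, profiles):
        # Median excitation plus recovery must leave room after a 100-s
        # stimulus inside the 600-s cap across each training range.
        for name in ("L-Asp", "L-Glu", "D-Asp", "L-Asn", "L-Cys", "L-Ser"):
            p = profiles[name]
            tau_hi = p.excitation_duration(p.conc_range[1])
            assert 0 < p.excitation_duration(p.conc_range[0])
            assert 100.0 + tau_hi + p.recovery_total <= 600.0


class TestValidation:
    def test_bad_recovery_fracs(self):
        with pytest.raises(ds.BadConfigError):
            fixed_profile(recovery_fracs=(0.5, 0.5, 0.5))

    def test_duration_cap(self):
        with pytest.raises(ds.BadConfigError):
            ds.SimulationConfig(duration=700.0)
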
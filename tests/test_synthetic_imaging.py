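"""Synthetic line-scan generation, the dG/Gsat analysis chain, the exact
Wilcoxon test, and the population study."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata, wilcoxon as scipy_wilcoxon

from kagate import synthetic_imaging as si
from conftest import make_synthetic_trial


def quiet_cfg(**kw):
    defaults = dict(noise_sd=0.0, n_trials=1)
    defaults.update(kw)
    return si.ImagingConfig(**defaults)


class TestFluorescenceFromCa:
    def test_baseline_and_saturation(self):
        cfg = quiet_cfg()
        assert si.fluorescence_from_ca(0.0, cfg) == cfg.g0
        assert si.fluorescence_from_ca(1e9, cfg) == pytest.approx(cfg.gsat, rel=1e-6)

    def test_hill_midpoint(self):
        cfg = quiet_cfg()
        expected = cfg.g0 + (cfg.gsat - cfg.g0) / 2.0
        assert si.fluorescence_from_ca(cfg.kd, cfg) == pytest.approx(expected)

    def test_monotone(self):
        cfg = quiet_cfg()
        c = np.linspace(0, 50, 500)
        g = si.fluorescence_from_ca(c, cfg)
        assert np.all(np.diff(g) > 0)


class TestSimulateLinescan:
    def test_zero_noise_is_deterministic_resample(self):
        trial = make_synthetic_trial("bAP")
        cfg = quiet_cfg()
        blk = si.simulate_linescan(trial, cfg, np.random.default_rng(0))
        conc = si.ca_concentration(trial, "spine", cfg)
        expected = si.fluorescence_from_ca(conc, cfg)
        idx = np.round(blk.t / trial.traces["spine"].dt).astype(int)
        assert np.allclose(blk.channels["spine"]["green"][0], expected[idx])
        assert np.allclose(blk.channels["spine"]["red"][0], cfg.red)

    def test_same_seed_bit_identical(self):
        trial = make_synthetic_trial("IPSP-bAP")
        cfg = si.ImagingConfig()
        a = si.simulate_linescan(trial, cfg, np.random.default_rng(42))
        b = si.simulate_linescan(trial, cfg, np.random.default_rng(42))
        for site in a.channels:
            for chan in a.channels[site]:
                assert np.array_equal(a.channels[site][chan], b.channels[site][chan])

    def test_light_flag_and_artifact(self):
        cfg = quiet_cfg()
        cfg_dark = quiet_cfg(artifact_amp=0.0)
        rng = np.random.default_rng(0)
        trial = make_synthetic_trial("IPSP")
        light = si.simulate_linescan(trial, cfg, rng)
        no_art = si.simulate_linescan(trial, cfg_dark, rng)
        bap = si.simulate_linescan(make_synthetic_trial("bAP"), cfg, rng)
        assert light.light and not bap.light
        diff = light.channels["spine"]["green"][0] - no_art.channels["spine"]["green"][0]
        expected = np.where(
            light.t >= light.uncaging_time,
            cfg.artifact_amp * np.exp(-np.clip(light.t - light.uncaging_time, 0, None)
                                      / cfg.artifact_tau),
            0.0,
        )
        assert np.allclose(diff, expected, atol=1e-9)

    def test_noisy_mean_converges_to_noiseless(self):
        """The mean of many noisy trials sits within 3 standard errors of
        the noiseless trace at every sample."""
        trial = make_synthetic_trial("bAP", duration=160.0, dt=1.0)
        cfg0 = quiet_cfg()
        clean = si.simulate_linescan(trial, cfg0, np.random.default_rng(0))
        n = 1000
        cfg = si.ImagingConfig(noise_sd=8.0, n_trials=n)
        noisy = si.simulate_linescan(trial, cfg, np.random.default_rng(1))
        mean = noisy.channels["spine"]["green"].mean(axis=0)
        se = 8.0 / np.sqrt(n)
        dev = np.abs(mean - clean.channels["spine"]["green"][0])
        assert np.all(dev < 4 * se)          # per-sample guard
        assert np.mean(dev < 3 * se) > 0.99  # 3-SE criterion on average


class TestAnalysisChain:
    def test_constant_green_gives_zero_dg(self):
        trial = make_synthetic_trial("bAP", amplitude=0.0)
        cfg = quiet_cfg()
        blk = si.simulate_linescan(trial, cfg, np.random.default_rng(0))
        y = si._dg_over_gsat(blk, "spine", cfg)
        assert np.allclose(y, 0.0, atol=1e-12)

    def test_dg_gsat_arithmetic(self):
        """dG = 50 on a G0/R baseline with Gsat = 600 gives 50/600."""
        cfg = quiet_cfg(gsat=600.0, g0=100.0, red=200.0)
        dg_r = 50.0 / cfg.red
        assert dg_r / cfg.sat_ratio == pytest.approx(50.0 / 600.0)

    def test_linear_zero_noise_recovers_ground_truth(self, synthetic_trials):
        """With a linear indicator and no noise the recovered inhibition
        fraction equals the concentration-space fraction to < 1e-6 (here
        exactly 0.25 for proportional transients)."""
        cfg = quiet_cfg(linear_indicator=True)
        rng = np.random.default_rng(0)
        blocks = {tt: si.simulate_linescan(tr, cfg, rng)
                  for tt, tr in synthetic_trials.items()}
        res = si.analyze_trials(si.CellRecording(0, 1.0, blocks), cfg)
        for site in ("spine", "shaft"):
            assert res.fractions[("single", site)].fraction == pytest.approx(
                0.25, abs=1e-6
            )

    def test_saturation_bias_one_signed_and_monotone(self, synthetic_trials):
        """Hill saturation compresses large responses more, so the
        recovered fraction falls below truth, increasingly with transient
        amplitude."""
        fracs = []
        for amp_scale in (1.0, 3.0, 9.0):
            cfg = quiet_cfg()
            rng = np.random.default_rng(0)
            blocks = {tt: si.simulate_linescan(tr, cfg, rng, amp_scale=amp_scale)
                      for tt, tr in synthetic_trials.items()}
            res = si.analyze_trials(si.CellRecording(0, 1.0, blocks), cfg)
            fracs.append(res.fractions[("single", "spine")].fraction)
        assert all(f < 0.25 for f in fracs)
        assert fracs[0] > fracs[1] > fracs[2]

    def test_missing_trial_type_rejected(self, synthetic_trials):
        cfg = quiet_cfg()
        rng = np.random.default_rng(0)
        blocks = {tt: si.simulate_linescan(tr, cfg, rng)
                  for tt, tr in synthetic_trials.items() if tt != "IPSP"}
        with pytest.raises(ValueError, match="incomplete"):
            si.analyze_trials(si.CellRecording(0, 1.0, blocks), cfg)


def brute_force_wilcoxon(diffs):
    """Independent oracle: exact two-sided p by enumeration of all 2^n
    sign assignments of the ranked |differences|."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [np.sum(np.asarray(signs) * ranks)
          for signs in itertools.product((0, 1), repeat=n)]
    ws = np.asarray(ws)
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestWilcoxonExact:
    def test_five_positive_pairs(self):
        assert si.wilcoxon_exact([1.0, 2.0, 3.0, 4.0, 5.0]).p_value == pytest.approx(
            2.0 / 32.0
        )

    def test_antisymmetric_pairs(self):
        assert si.wilcoxon_exact([1.0, -1.0, 2.5, -2.5]).p_value == 1.0

    def test_all_zero_degenerate(self):
        r = si.wilcoxon_exact([0.0, 0.0, 0.0])
        assert r.p_value == 1.0 and r.degenerate and r.n_used == 0

    def test_paired_input_form(self):
        a = si.wilcoxon_exact([3.0, 5.0, 2.0], [1.0, 1.0, 1.0])
        b = si.wilcoxon_exact([2.0, 4.0, 1.0])
        assert a.p_value == b.p_value and a.statistic == b.statistic

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_oracle(self, seed):
        """Exact equality with a brute-force 2^n enumeration, including
        tied and mixed-sign inputs, n <= 12."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        d = rng.choice([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0, 4.0], size=n)
        d += rng.normal(0, 0.01, n) * rng.integers(0, 2)  # sometimes break ties
        assert si.wilcoxon_exact(d).p_value == pytest.approx(
            brute_force_wilcoxon(d), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_scipy_exact_on_tie_free_data(self, seed):
        rng = np.random.default_rng(100 + seed)
        d = rng.normal(0.3, 1.0, 11)
        expected = scipy_wilcoxon(d, mode="exact", alternative="two-sided").pvalue
        assert si.wilcoxon_exact(d).p_value == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=-100, max_value=100).filter(lambda x: abs(x) > 1e-6),
                    min_size=3, max_size=12, unique=True),
           st.floats(min_value=0.1, max_value=10.0))
    def test_invariant_to_rank_preserving_rescale(self, diffs, power):
        """p depends only on the signs and the ranks of |d|: any odd
        monotone transform d -> sign(d)|d|^p leaves it unchanged."""
        d = np.asarray(diffs)
        transformed = np.sign(d) * np.abs(d) ** power
        assert si.wilcoxon_exact(d).p_value == pytest.approx(
            si.wilcoxon_exact(transformed).p_value, abs=1e-12
        )


class TestGenerateDataset:
    def test_structure_and_long_format(self, synthetic_trials):
        cfg = si.ImagingConfig(n_trials=3)
        ds = si.generate_dataset(synthetic_trials, cfg, n_cells=2, master_seed=9)
        assert len(ds.cells) == 2
        for cell in ds.cells:
            assert set(cell.blocks) == set(synthetic_trials)
            assert cell.blocks["bAP"].n_trials == 3
            assert cell.amp_scale > 0
        frame = ds.to_frame()
        assert set(frame.columns) == {"cell", "trial", "type", "site",
                                      "channel", "time", "value"}
        n_samples = len(ds.cells[0].blocks["bAP"].t)
        assert len(frame) == 2 * 3 * 3 * 2 * 2 * n_samples

    def test_master_seed_determinism(self, synthetic_trials):
        cfg = si.ImagingConfig(n_trials=2)
        a = si.generate_dataset(synthetic_trials, cfg, n_cells=2, master_seed=5)
        b = si.generate_dataset(synthetic_trials, cfg, n_cells=2, master_seed=5)
        assert a.to_frame().equals(b.to_frame())


class TestPopulationStudy:
    def test_reproducible_and_paired_shape(self, synthetic_trials):
        a = si.population_study(synthetic_trials, si.ImagingConfig(),
                                n_cells=6, master_seed=11)
        b = si.population_study(synthetic_trials, si.ImagingConfig(),
                                n_cells=6, master_seed=11)
        assert a.table.equals(b.table)
        assert len(a.table) == 12  # 6 cells x 2 sites
        assert set(a.tests) == {"spine", "shaft"}

    def test_duplicate_conditions_degenerate(self, synthetic_trials):
        """With zero noise and a null effect the two conditions are
        identical, all paired differences vanish, and p = 1."""
        cfg = quiet_cfg(n_trials=2, cell_cv=0.2)
        res = si.population_study(synthetic_trials, cfg, n_cells=5, master_seed=0)
        for t in res.tests.values():
            assert t.p_value == 1.0 and t.degenerate

    def test_large_effect_reaches_exact_minimum(self, synthetic_trials):
        """Halving the inhibited-trial transient with low noise drives the
        n = 10 paired test to its all-positive exact minimum, p = 2/2^10."""
        cfg = si.ImagingConfig(noise_sd=1.0)
        res = si.population_study(synthetic_trials, cfg, n_cells=10,
                                  master_seed=2, inh_scale_b=0.5)
        for t in res.tests.values():
            assert t.p_value <= 2.0 / 2 ** 10 + 1e-12

    def test_requires_two_cells(self, synthetic_trials):
        with pytest.raises(ValueError):
            si.population_study(synthetic_trials, si.ImagingConfig(), n_cells=1)


class TestImagingConfigValidation:
    @pytest.mark.parametrize("bad", [
        dict(gsat=50.0),              # gsat <= g0
        dict(red=0.0),
        dict(noise_sd=-1.0),
        dict(noise_model="laplace"),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            si.ImagingConfig(**bad)
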
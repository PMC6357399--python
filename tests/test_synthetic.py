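"""Generator reproducibility, design emulation and ground-truth oracles."""

import numpy as np
import pytest

from cohortmslt.panel import DEAD, DISABLED, NONDISABLED
from cohortmslt.ppo import PPOModel, predict_transition
from cohortmslt.synthetic import (GeneratorConfig, default_study_configs,
                                  default_true_models, generate_panel,
                                  true_estimates)


def _no_death_models():
    nd = PPOModel(origin=NONDISABLED, center=80.0, alpha=(1.0, 30.0),
                  shared={"age": 0.0}, gamma={})
    d = PPOModel(origin=DISABLED, center=80.0, alpha=(-1.0, 30.0),
                 shared={"age": 0.0}, gamma={})
    return nd, d


def _frozen_models():
    """No deaths, no transitions at all."""
    nd = PPOModel(origin=NONDISABLED, center=80.0, alpha=(30.0, 31.0),
                  shared={"age": 0.0}, gamma={})
    d = PPOModel(origin=DISABLED, center=80.0, alpha=(-30.0, 30.0),
                 shared={"age": 0.0}, gamma={})
    return nd, d


def _config(n=1000, models=None, **kw):
    nd, d = models if models is not None else default_true_models("octogenarian", "earlier")
    defaults = dict(n_individuals=n, age_window=(80, 89),
                    baseline_disabled_prevalence=0.173, wave_offsets=(0, 2, 4),
                    model_nondisabled=nd, model_disabled=d)
    defaults.update(kw)
    return GeneratorConfig(**defaults)


class TestGeneratePanel:
    def test_same_seed_identical_different_seed_differs(self):
        config = _config(n=400)
        a = generate_panel(config, seed=5)
        b = generate_panel(config, seed=5)
        c = generate_panel(config, seed=6)
        assert a.equals(b)
        assert not a.equals(c)

    def test_zero_death_zero_dropout_panel(self):
        config = _config(n=500, models=_no_death_models(), attrition=None)
        data = generate_panel(config, seed=1)
        assert not data.individuals["dead"].any()
        assert not data.individuals["lost"].any()
        assert data.individuals["death_age"].isna().all()
        assert (data.obs_state >= 0).all()

    def test_baseline_prevalence_matches_study_value(self):
        """Baseline disabled share within 3 binomial SE of the configured 17.3%."""
        config = _config(n=4000)
        data = generate_panel(config, seed=9)
        p = 0.173
        se = np.sqrt(p * (1 - p) / 4000)
        assert abs((data.baseline_state == DISABLED).mean() - p) < 3 * se

    def test_wave_transition_frequencies_converge_to_truth(self):
        """Annual wave-to-wave transition frequencies in a large sample match
        the true model probabilities within 3 binomial SE."""
        nd, d = default_true_models("octogenarian", "earlier")
        config = _config(n=40_000, wave_offsets=(0, 1), attrition=None)
        data = generate_panel(config, seed=13)
        base = data.individuals["baseline_age"].to_numpy()
        woman = data.individuals["woman"].to_numpy()
        rural = data.individuals["rural"].to_numpy()
        schooled = data.individuals["schooled"].to_numpy()
        s0 = data.baseline_state
        s1 = data.obs_state[:, 1].astype(int)
        s1 = np.where(data.individuals["dead"].to_numpy(bool), DEAD, s1)
        sel = (s0 == NONDISABLED) & (base == 80) & (woman == 1) & (rural == 1) & (schooled == 0)
        assert sel.sum() > 800
        p_true = nd.predict(80.0, 1.0, 1.0, 0.0)
        for outcome in (NONDISABLED, DISABLED, DEAD):
            freq = (s1[sel] == outcome).mean()
            se = np.sqrt(p_true[outcome] * (1 - p_true[outcome]) / sel.sum())
            assert abs(freq - p_true[outcome]) < 3 * se

    def test_degenerate_config_rejected(self):
        with pytest.raises(ValueError):
            _config(n=0).validate()
        with pytest.raises(ValueError):
            _config(age_window=(89, 80)).validate()
        with pytest.raises(ValueError):
            _config(wave_offsets=(0,)).validate()


class TestDefaultStudyConfigs:
    def test_age_group_totals_and_offsets(self):
        configs = default_study_configs()
        assert (configs["octogenarian_earlier"].n_individuals
                + configs["octogenarian_later"].n_individuals) == 7334
        assert (configs["nonagenarian_earlier"].n_individuals
                + configs["nonagenarian_later"].n_individuals) == 7705
        assert (configs["centenarian_earlier"].n_individuals
                + configs["centenarian_later"].n_individuals) == 5481
        for name, cfg in configs.items():
            cfg.validate()
            expected = (0, 2, 4) if name.endswith("earlier") else (0, 3, 6)
            assert tuple(cfg.wave_offsets) == expected

    def test_octogenarian_baseline_prevalences(self):
        configs = default_study_configs()
        assert configs["octogenarian_earlier"].baseline_disabled_prevalence == 0.173
        assert configs["octogenarian_later"].baseline_disabled_prevalence == 0.118


class TestTrueEstimates:
    def test_frozen_population_spends_full_window_in_origin_state(self):
        config = _config(models=_frozen_models(), baseline_disabled_prevalence=0.0)
        est = true_estimates(config, window=(80, 89))
        assert est.total_le == pytest.approx(10.0, abs=1e-9)
        assert est.dfle == pytest.approx(10.0, abs=1e-9)

    def test_constant_mortality_closed_form(self):
        """Constant annual death probability 0.1, no disability: partial LE
        over a 10-year window is (1 - q/2)(1 - (1-q)^10)/q."""
        q = 0.1
        a2 = float(np.log((1 - q) / q))
        # alpha1 == alpha2: zero disability-onset probability
        nd = PPOModel(origin=NONDISABLED, center=80.0, alpha=(a2, a2),
                      shared={"age": 0.0}, gamma={})
        d = PPOModel(origin=DISABLED, center=80.0, alpha=(-30.0, a2),
                     shared={"age": 0.0}, gamma={})
        config = _config(models=(nd, d), baseline_disabled_prevalence=0.0)
        est = true_estimates(config, window=(80, 89))
        closed_form = (1 - q / 2) * (1 - (1 - q) ** 10) / q
        assert closed_form == pytest.approx(6.187554819, abs=1e-9)
        assert est.total_le == pytest.approx(closed_form, abs=1e-9)

    def test_higher_death_logit_strictly_decreases_total_le(self):
        nd, d = default_true_models("octogenarian", "earlier")
        totals = []
        for bump in (0.0, -0.3, -0.6):   # lower alpha2 -> more death
            nd2 = PPOModel(origin=NONDISABLED, center=nd.center,
                           alpha=(nd.alpha[0] + bump if bump else nd.alpha[0],
                                  nd.alpha[1] + bump),
                           shared=nd.shared, gamma=nd.gamma)
            config = _config(models=(nd2, d))
            totals.append(true_estimates(config, window=(80, 89)).total_le)
        assert totals[0] > totals[1] > totals[2]

    def test_window_outside_modeled_ages_rejected(self):
        with pytest.raises(ValueError):
            true_estimates(_config(), window=(70, 79))
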
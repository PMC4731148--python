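"""Template construction, Γ projection, ISI sampling, r² feature selection."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spontodecode.config import PipelineConfig
from spontodecode.datatypes import EventTable
from spontodecode.projection import (
    FeatureMatrix,
    Template,
    build_template,
    project_at_event,
    project_continuous,
    r2_score,
    sample_isi_points,
    select_features,
)

CFG = PipelineConfig()


def _events(onsets, label="face"):
    return EventTable(onsets, [label] * len(onsets), [0] * len(onsets))


class TestBuildTemplate:
    def test_boxcar_average_minus_baseline_mean(self):
        sig = np.zeros(10_000)
        onsets = [2000, 5000]
        for t in onsets:
            sig[t:t + 100] = 1.0
        tpl = build_template(sig, _events(onsets), "face")
        expected = np.zeros(600)
        expected[199:299] = 1.0                     # boxcar at t' = 0..99
        expected -= expected[:250].mean()           # baseline window −199..50
        assert np.allclose(tpl.values, expected)
        assert abs(tpl.values[:250].mean()) < 1e-9  # re-centering invariant

    def test_constant_signal_gives_zero_template(self):
        tpl = build_template(np.full(5000, 3.7), _events([1000]), "face")
        assert np.allclose(tpl.values, 0.0, atol=1e-9)

    def test_two_events_match_loop_oracle(self, rng):
        sig = rng.standard_normal(8000)
        onsets = [1500, 4200]
        tpl = build_template(sig, _events(onsets), "face")
        # brute-force oracle
        wins = [sig[t - 199:t + 401] for t in onsets]
        expected = np.mean(wins, axis=0)
        expected = expected - expected[:250].mean()
        assert np.allclose(tpl.values, expected, atol=1e-12)

    def test_out_of_range_event_skipped_with_warning(self, rng, caplog):
        sig = rng.standard_normal(3000)
        with caplog.at_level(logging.WARNING):
            tpl = build_template(sig, _events([50, 1500]), "face")
        assert tpl.n_events == 1
        assert any("out of range" in r.message for r in caplog.records)

    def test_no_usable_events_rejected(self):
        with pytest.raises(ValueError):
            build_template(np.zeros(1000), _events([10]), "face")


class TestProjectAtEvent:
    def _template_from(self, rng):
        sig = rng.standard_normal(4000)
        return build_template(sig, _events([1000, 2500]), "face")

    def test_template_on_zero_background_gives_sum_of_squares(self, rng):
        tpl = self._template_from(rng)
        sig = np.zeros(5000)
        tau = 2000
        sig[tau - 199:tau + 401] = tpl.values
        gamma = project_at_event(tpl, sig, tau)
        assert np.isclose(gamma, np.sum(tpl.values**2), rtol=1e-10)

    def test_zero_template_projects_to_zero(self, rng):
        tpl = Template(np.zeros(600), 0, "face", "potential")
        assert project_at_event(tpl, rng.standard_normal(3000), 1000) == 0.0

    def test_constant_signal_projects_to_zero(self, rng):
        tpl = self._template_from(rng)
        gamma = project_at_event(tpl, np.full(3000, 11.0), 1000)
        assert abs(gamma) < 1e-8

    def test_out_of_range_rejected(self, rng):
        tpl = self._template_from(rng)
        with pytest.raises(ValueError):
            project_at_event(tpl, np.zeros(1000), 700)


class TestProjectContinuous:
    @pytest.mark.parametrize("baseline_as_sum", [False, True])
    def test_fast_path_equals_definitional_loop(self, rng, baseline_as_sum):
        cfg = PipelineConfig(baseline_as_sum=baseline_as_sum)
        sig = rng.standard_normal(5000)
        tpl = build_template(rng.standard_normal(4000), _events([1000, 2000]),
                             "face", cfg=cfg)
        trace = project_continuous(tpl, sig, cfg)
        taus = rng.integers(199, 4600, size=20)
        for tau in taus:
            loop = project_at_event(tpl, sig, int(tau), cfg)
            assert np.isclose(trace[tau], loop, rtol=1e-6, atol=1e-9)
        assert np.all(np.isnan(trace[:199])) and np.all(np.isnan(trace[-400:]))

    def test_matched_filter_peaks_at_injection_time(self, rng):
        tpl = build_template(rng.standard_normal(4000), _events([1000, 2600]), "face")
        sig = np.zeros(6000)
        tau = 3000
        sig[tau - 199:tau + 401] = tpl.values
        trace = project_continuous(tpl, sig)
        assert np.nanargmax(trace) == tau

    def test_translation_equivariance(self, rng):
        sig = rng.standard_normal(4000)
        tpl = build_template(rng.standard_normal(4000), _events([1200]), "face")
        a = project_continuous(tpl, sig)
        b = project_continuous(tpl, np.concatenate([np.zeros(1000), sig]))
        assert np.allclose(a[199:3600], b[1199:4600], rtol=1e-9)


class TestIsiSampling:
    def test_times_respect_margins_and_counts(self):
        ev = _events(list(range(2000, 2000 + 800 * 100, 800)))
        pts = sample_isi_points(ev, n_per_isi=4, seed=0)
        assert len(pts) == 400
        rel = (pts.reshape(100, 4) - ev.onset_ms[:, None])
        assert rel.min() >= 500 and rel.max() <= 700  # 100 ms from offset/onset

    def test_pairwise_gaps_at_least_50ms(self):
        ev = _events(list(range(1000, 1000 + 800 * 30, 800)))
        pts = sample_isi_points(ev, n_per_isi=4, seed=3).reshape(30, 4)
        assert np.diff(pts, axis=1).min() >= 50

    def test_seeded_determinism(self):
        ev = _events([1000, 1800])
        a = sample_isi_points(ev, seed=9)
        b = sample_isi_points(ev, seed=9)
        assert np.array_equal(a, b)

    def test_infeasible_constraints_reduce_count_with_warning(self, caplog):
        ev = _events([1000])
        with caplog.at_level(logging.WARNING):
            pts = sample_isi_points(ev, n_per_isi=4, isi_ms=260, seed=0)
        assert 0 < len(pts) < 4
        assert any("infeasible" in r.message for r in caplog.records)


class TestR2:
    def test_identical_distributions_give_zero(self):
        assert r2_score([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(0.0)

    def test_perfect_separation_gives_one(self):
        # pooled sample {2,2,0,0}: zero within-group variance
        assert r2_score([2.0, 2.0], [0.0, 0.0]) == pytest.approx(1.0)

    def test_equals_squared_point_biserial_correlation(self, rng):
        a = rng.standard_normal(37) + 0.8
        b = rng.standard_normal(53)
        r2 = r2_score(a, b)
        labels = np.concatenate([np.ones(len(a)), np.zeros(len(b))])
        oracle = np.corrcoef(labels, np.concatenate([a, b]))[0, 1] ** 2
        assert np.isclose(r2, oracle, atol=1e-12)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(scale=st.floats(0.1, 50.0), shift=st.floats(-100.0, 100.0))
    def test_affine_invariance(self, scale, shift):
        rng = np.random.default_rng(7)
        a = rng.standard_normal(20) + 1.0
        b = rng.standard_normal(25)
        assert np.isclose(
            r2_score(a, b), r2_score(scale * a + shift, scale * b + shift), atol=1e-9
        )

    def test_zero_variance_returns_zero_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            assert r2_score([1.0, 1.0], [1.0, 1.0]) == 0.0
        assert any("variance" in r.message for r in caplog.records)


def _feature_matrix(rng, n_feat=6, informative=()):
    n_class, n_isi = 60, 200
    labels = np.array(["face"] * n_class + ["isi"] * n_isi, dtype=object)
    pts = rng.standard_normal((n_class + n_isi, n_feat))
    for j in informative:
        pts[:n_class, j] += 2.0
    ids = [(j, "face", "potential") for j in range(n_feat)]
    return FeatureMatrix(pts, labels, np.arange(len(labels)), ids)


class TestSelectFeatures:
    def test_informative_feature_retained(self, rng):
        fm = _feature_matrix(rng, informative=(2,))
        sel = select_features(fm, 0.05)
        assert sel.mask[2]
        assert np.all((sel.r2 >= 0) & (sel.r2 <= 1))

    def test_null_features_mostly_rejected(self, rng):
        fm = _feature_matrix(rng)  # nothing informative
        try:
            sel = select_features(fm, 0.05)
            assert sel.mask.sum() <= 2  # chance-level retention only
        except ValueError:
            pass  # zero retained is the expected outcome

    def test_impossible_threshold_rejected(self, rng):
        fm = _feature_matrix(rng, informative=(0,))
        with pytest.raises(ValueError, match="threshold"):
            select_features(fm, 1.01)
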
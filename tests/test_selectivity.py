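"""Selectivity indices: contrast formula, family maxima, significance tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from v4domains import selectivity as sel
from v4domains import stimgen, synth
from conftest import tiny_contour_protocol


class TestIndexFormula:
    def test_twice_as_strong_gives_one_third(self):
        assert sel.index(2.0, 1.0) == pytest.approx(1 / 3)

    def test_one_and_a_half_gives_point_two(self):
        assert sel.index(1.5, 1.0) == pytest.approx(0.2)

    def test_equal_responses_zero(self):
        assert sel.index(0.7, 0.7) == 0.0

    def test_silent_other_gives_bound(self):
        assert sel.index(0.4, 0.0) == 1.0

    def test_both_zero_undefined(self):
        assert np.isnan(sel.index(0.0, 0.0))

    def test_negative_inputs_floored(self):
        assert sel.index(-0.2, 0.5) == -1.0

    @given(st.floats(0.001, 100), st.floats(0.001, 100))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_antisymmetry(self, a, b):
        assert sel.index(a, b) == pytest.approx(-sel.index(b, a))

    @given(st.floats(0.001, 100), st.floats(0.001, 100), st.floats(0.01, 50))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_scale_invariance(self, a, b, c):
        assert sel.index(c * a, c * b) == pytest.approx(sel.index(a, b), abs=1e-9)

    @given(st.floats(0, 10), st.floats(0, 10))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounded_and_sign_consistent(self, a, b):
        v = sel.index(a, b)
        if not np.isnan(v):
            assert -1 <= v <= 1
            assert np.sign(v) == np.sign(a - b)


class TestFamilyMax:
    def _means(self, vals):
        return pd.Series(vals, index=range(len(vals)))

    def test_single_stimulus_family(self):
        proto = tiny_contour_protocol()
        means = self._means(np.arange(len(proto)) * 0.1)
        bar_ids = proto.ids_in_category("bar")
        v, best = sel.family_max(means, "bar", proto)
        assert best == max(bar_ids)  # monotone values: last bar id wins
        assert v == pytest.approx(means[best])

    def test_tie_broken_by_lowest_id(self):
        proto = tiny_contour_protocol()
        means = self._means(np.ones(len(proto)))
        _, best = sel.family_max(means, "curve", proto)
        assert best == min(proto.ids_in_category("curve"))

    def test_absent_family_undefined(self):
        proto = tiny_contour_protocol()
        v, best = sel.family_max(self._means(np.ones(len(proto))), "concentric", proto)
        assert np.isnan(v) and best is None

    def test_noise_free_optimum_is_planted_orientation(self):
        proto = tiny_contour_protocol()
        n = synth.GroundTruthNeuron((0, 0), 4.0, "curve", 90.0, 3.0, 0.3, 1.0, 100.0)
        t = synth.make_response_table([n], proto, 2, 0.0, seed=0)
        means = t.groupby("stim_id")["response"].mean()
        _, best = sel.family_max(means, "curve", proto)
        assert proto.stimuli[best].orientation_deg == 90.0


class TestIndexSignificance:
    def _table(self, a, b):
        rows = []
        for r, v in enumerate(a):
            rows.append(dict(neuron_id=0, stim_id=0, repeat=r, response=v))
        for r, v in enumerate(b):
            rows.append(dict(neuron_id=0, stim_id=1, repeat=r, response=v))
        return pd.DataFrame(rows)

    def test_identical_repeats_p_one(self):
        t = self._table([0.5] * 10, [0.5] * 10)
        assert sel.index_significance(t, 0, 0, 1) == 1.0

    def test_f_equals_squared_t(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(1, 0.2, 10), rng.normal(0.5, 0.2, 10)
        p = sel.index_significance(self._table(a, b), 0, 0, 1)
        assert p == pytest.approx(stats.ttest_ind(a, b).pvalue)

    def test_planted_2x_difference_usually_significant(self):
        """A 2x response difference at 10% trial noise is detected in > 95%
        of simulations with n = 10 repeats (Monte Carlo)."""
        rng = np.random.default_rng(1)
        hits = 0
        n_sim = 300
        for _ in range(n_sim):
            a = rng.normal(1.0, 0.1, 10)
            b = rng.normal(0.5, 0.1, 10)
            if stats.f_oneway(a, b).pvalue < 0.05:
                hits += 1
        assert hits / n_sim > 0.95


class TestOrientationTuning:
    def _table(self, proto, neuron, noise, seed, n_repeat=10):
        return synth.make_response_table([neuron], proto, n_repeat, noise, seed)

    def test_bonferroni_multiplication_and_cap(self):
        assert min(1.0, 14 * 0.01) == pytest.approx(0.14)
        assert min(1.0, 14 * 0.2) == 1.0

    def test_flat_neuron_rarely_significant(self):
        """Orientation-untuned neurons pass the orientation ANOVA at roughly
        the nominal rate or below (Bonferroni makes it conservative)."""
        proto = tiny_contour_protocol()
        n = synth.GroundTruthNeuron((0, 0), 4.0, "curve", 0.0, 0.0, 0.3, 1.0, 100.0)
        hits = 0
        for seed in range(40):
            t = self._table(proto, n, 0.1, seed)
            _, p_ori, _ = sel.orientation_tuning_test(t, 0, proto)
            hits += p_ori < 0.05
        assert hits <= 6

    def test_tuned_neuron_detected(self):
        proto = tiny_contour_protocol()
        n = synth.GroundTruthNeuron((0, 0), 4.0, "curve", 0.0, 3.0, 0.3, 1.0, 100.0)
        hits = 0
        for seed in range(20):
            t = self._table(proto, n, 0.05, seed)
            _, p_ori, _ = sel.orientation_tuning_test(t, 0, proto)
            hits += p_ori < 0.05
        assert hits >= 19


class TestProfiles:
    def test_cvcni_matches_closed_form_over_bias_grid(self, map16x_set):
        """Recovered mean CVCNI per planted class_bias matches (1-b)/(1+b)."""
        for b in (0.1, 0.3, 0.5):
            neurons = [synth.GroundTruthNeuron((0, 0), 4.0, "curve", 45.0, 2.0,
                                               b, 1.0, 100.0)] * 20
            t = synth.make_response_table(neurons, map16x_set, 10, 0.05, seed=int(b * 10))
            prof = sel.compute_profiles(t, map16x_set)
            assert prof["CVCNI"].mean() == pytest.approx((1 - b) / (1 + b), abs=0.05)

    def test_cvpii_cvcni_consistency(self, domain_field, map16x_set):
        """Curve-preferring neurons treat Pi-shapes as rectilinear, so CVPII
        and CVCNI correlate strongly across the population."""
        prof = sel.compute_profiles(domain_field["table"], map16x_set)
        sub = prof.dropna(subset=["CVCNI", "CVPII"])
        selective = sub[sub["CVCNI"].abs() > 0.05]
        r = np.corrcoef(selective["CVCNI"], selective["CVPII"])[0, 1]
        assert r > 0.5

    def test_cri_consistent_across_spatial_frequencies(self, domain_field,
                                                       map16x_set, gratings_set):
        """With frequency-invariant class tuning the per-SF CRI values are
        strongly correlated across neurons."""
        prof = sel.compute_profiles(domain_field["table"], map16x_set,
                                    grating_table=domain_field["gtable"],
                                    grating_set=gratings_set)
        cols = [c for c in prof.columns if c.startswith("CRI_sf")]
        assert len(cols) == 3
        sub = prof.dropna(subset=cols)
        sub = sub[sub[cols[0]].abs() > 0.05]  # exclude unselective neurons
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                assert np.corrcoef(sub[cols[i]], sub[cols[j]])[0, 1] > 0.9


class TestIndexCellmap:
    def test_within_curve_domain_mean_positive(self, domain_field, map16x_set):
        layout = domain_field["layout"]
        neurons = domain_field["neurons"]
        pos = np.array([(n.position[1] * 1.7, n.position[0] * 1.7) for n in neurons])
        prof = sel.compute_profiles(domain_field["table"], map16x_set,
                                    positions_um=pos)
        cm = sel.index_cellmap(prof, "CVCNI", layout.domain_masks,
                               micron_per_px=1.7, canvas=layout.canvas)
        assert cm.domain_stats["curve"]["mean"] > 0.2
        assert cm.domain_stats["corner"]["mean"] < -0.2

    def test_empty_mask_no_error(self, domain_field, map16x_set):
        neurons = domain_field["neurons"]
        pos = np.array([(n.position[1] * 1.7, n.position[0] * 1.7) for n in neurons])
        prof = sel.compute_profiles(domain_field["table"], map16x_set,
                                    positions_um=pos)
        cm = sel.index_cellmap(prof, "CVCNI",
                               {"empty": np.zeros((96, 96), bool)},
                               micron_per_px=1.7)
        assert cm.domain_stats["empty"]["n"] == 0
        assert np.isnan(cm.domain_stats["empty"]["mean"])
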
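"""Synthetic-data generator: layout, tuning model, movies, response tables."""

import numpy as np
import pytest

from v4domains import preprocess, selectivity, stimgen, synth
from v4domains.synth import (CalciumKernel, GroundTruthNeuron, LayoutError,
                             make_layout, make_response_table,
                             neuron_response_mean, render_movie, sample_neurons)
from conftest import tiny_contour_protocol


def _neuron(**kw):
    base = dict(position=(32.0, 32.0), soma_radius=4.0, preferred_class="curve",
                preferred_orientation=0.0, orientation_kappa=2.0,
                class_bias=0.3, peak_dff=0.5, baseline_f=100.0)
    base.update(kw)
    return GroundTruthNeuron(**base)


class TestLayout:
    def test_seed_determinism(self):
        a = make_layout((64, 64), 2, 12, seed=5)
        b = make_layout((64, 64), 2, 12, seed=5)
        for cls in ("curve", "corner"):
            assert np.array_equal(a.domain_masks[cls], b.domain_masks[cls])

    def test_masks_disjoint(self):
        lay = make_layout((96, 96), 4, 15, seed=1)
        assert not np.any(lay.domain_masks["curve"] & lay.domain_masks["corner"])

    def test_zero_domains(self):
        lay = make_layout((64, 64), 0, 10, seed=0)
        assert not lay.domain_masks["curve"].any()
        neurons = sample_neurons(lay, 10, seed=0)
        assert all(n.preferred_class == "none" for n in neurons)

    def test_oversized_radius_raises(self):
        with pytest.raises(LayoutError):
            make_layout((64, 64), 1, 40, seed=0)


class TestTuningModel:
    def test_preferred_stimulus_gives_peak(self):
        n = _neuron()
        stim = stimgen.make_curve(10, 180, 0)
        assert neuron_response_mean(n, stim) == pytest.approx(n.peak_dff)

    def test_zero_bias_silences_nonpreferred(self):
        n = _neuron(class_bias=0.0)
        assert neuron_response_mean(n, stimgen.make_corner(10, 90, 0)) == 0.0

    def test_cvcni_closed_form(self):
        """A pure curve-preferring neuron with bias b has CVCNI = (1-b)/(1+b).

        Checked through the selectivity module on a noise-free response
        table, not by evaluating the formula on the tuning model directly.
        """
        proto = tiny_contour_protocol()
        for b in (0.0, 0.25, 0.5):
            n = _neuron(class_bias=b)
            table = make_response_table([n], proto, n_repeat=3,
                                        trial_noise_sd=0.0, seed=0)
            prof = selectivity.compute_profiles(table, proto)
            assert prof.loc[0, "CVCNI"] == pytest.approx((1 - b) / (1 + b))

    def test_pi_shape_asymmetry(self):
        """Curve-preferring neurons treat Pi as non-preferred; corner-preferring
        treat it as preferred-like (smoothness selectivity)."""
        pi = stimgen.make_pi_shape(10, 180, 0)
        cv = _neuron(preferred_class="curve", class_bias=0.2)
        cn = _neuron(preferred_class="corner", class_bias=0.2)
        assert neuron_response_mean(cv, pi) == pytest.approx(0.2 * cv.peak_dff)
        assert neuron_response_mean(cn, pi) == pytest.approx(cn.peak_dff)

    def test_orientation_tuning_periodicity(self):
        n = _neuron(orientation_kappa=3.0)
        r0 = neuron_response_mean(n, stimgen.make_curve(10, 180, 0))
        r180 = neuron_response_mean(n, stimgen.make_curve(10, 180, 180))
        r360 = neuron_response_mean(n, stimgen.make_curve(10, 180, 360))
        assert r180 < r0
        assert r360 == pytest.approx(r0)


class TestResponseTable:
    def test_zero_noise_repeats_identical(self):
        proto = tiny_contour_protocol()
        t = make_response_table([_neuron()], proto, n_repeat=5,
                                trial_noise_sd=0.0, seed=1)
        per_stim = t.groupby("stim_id")["response"].nunique()
        assert (per_stim == 1).all()

    def test_seed_determinism(self):
        proto = tiny_contour_protocol()
        a = make_response_table([_neuron()], proto, 4, 0.1, seed=9)
        b = make_response_table([_neuron()], proto, 4, 0.1, seed=9)
        assert np.array_equal(a["response"], b["response"])

    def test_identical_neurons_correlate_as_noise_vanishes(self):
        proto = tiny_contour_protocol()
        pair = [_neuron(), _neuron()]
        for sd, lo in ((0.2, 0.5), (0.01, 0.99)):
            t = make_response_table(pair, proto, 10, sd, seed=2)
            means = t.pivot_table(index="neuron_id", columns="stim_id",
                                  values="response")
            r = np.corrcoef(means.to_numpy())[0, 1]
            assert r > lo

    def test_repeat_reliability_matches_monte_carlo(self):
        """Split-half reliability under trial noise matches a direct
        Monte-Carlo estimate of the same attenuation."""
        proto = tiny_contour_protocol()
        n = _neuron(orientation_kappa=1.0)
        rng = np.random.default_rng(7)
        sd = 0.1
        t = make_response_table([n] * 200, proto, 2, sd, seed=3)
        means = t.pivot_table(index=["neuron_id", "repeat"], columns="stim_id",
                              values="response")
        rs = [np.corrcoef(means.loc[(i, 0)], means.loc[(i, 1)])[0, 1]
              for i in range(200)]
        # MC oracle: same signal vector, fresh noise draws
        sig = np.array([neuron_response_mean(n, s) for s in proto.stimuli])
        mc = [np.corrcoef(sig + rng.normal(0, sd, sig.size),
                          sig + rng.normal(0, sd, sig.size))[0, 1]
              for _ in range(2000)]
        assert np.mean(rs) == pytest.approx(np.mean(mc), abs=0.03)


class TestMovie:
    def test_same_seed_bit_identical(self, tiny_protocol):
        kw = dict(n_repeat=1, noise_sd=0.5, seed=4, canvas=(48, 48))
        a = render_movie(None, [_neuron(position=(24., 24.))], tiny_protocol, **kw)
        b = render_movie(None, [_neuron(position=(24., 24.))], tiny_protocol, **kw)
        assert np.array_equal(a.frames, b.frames)

    def test_negative_noise_rejected(self, tiny_protocol):
        with pytest.raises(ValueError):
            render_movie(None, [_neuron()], tiny_protocol, noise_sd=-1, canvas=(48, 48))

    def test_blank_protocol_stays_at_baseline(self):
        """With no evoked response the movie is the baseline image throughout."""
        proto = tiny_contour_protocol()
        silent = _neuron(peak_dff=0.0)
        m = render_movie(None, [silent], proto, n_repeat=1, noise_sd=0.0,
                         seed=0, canvas=(48, 48))
        assert np.allclose(m.frames, m.baseline_image, atol=1e-5)

    def test_noise_free_roundtrip_recovers_response(self, tiny_protocol):
        """Windowed dF/F0 at the soma center recovers the planted amplitude.

        The oracle is the closed-form window average of the configured
        kernel: with the kernel normalized over the response window and no
        background fluorescence, the extracted per-trial dF/F0 equals the
        tuning-model response exactly (up to float32 rendering precision).
        """
        n = _neuron(position=(24.0, 24.0))
        m = render_movie(None, [n], tiny_protocol, n_repeat=2, noise_sd=0.0,
                         seed=1, canvas=(48, 48), background_f=0.0)
        maps = preprocess.dff(preprocess.align(m.frames, template=m.baseline_image),
                              m.trial_table)
        for sid, s in enumerate(tiny_protocol.stimuli):
            expected = neuron_response_mean(n, s)
            got = maps.mean_maps[sid][24, 24]
            assert got == pytest.approx(expected, abs=1e-4)

    def test_background_attenuates_pixel_dff(self, tiny_protocol):
        """With background fluorescence, pixel dF/F0 is attenuated by
        B/(bg+B) at the soma center -- the closed-form prediction."""
        n = _neuron(position=(24.0, 24.0))
        bg = 25.0
        m = render_movie(None, [n], tiny_protocol, n_repeat=1, noise_sd=0.0,
                         seed=1, canvas=(48, 48), background_f=bg)
        maps = preprocess.dff(preprocess.align(m.frames, template=m.baseline_image),
                              m.trial_table)
        atten = n.baseline_f / (bg + n.baseline_f)
        expected = neuron_response_mean(n, tiny_protocol.stimuli[0]) * atten
        assert maps.mean_maps[0][24, 24] == pytest.approx(expected, abs=1e-4)

    def test_pre_onset_mean_approaches_baseline(self, tiny_protocol):
        """Mean pre-onset fluorescence converges to the baseline map."""
        n = _neuron(position=(24.0, 24.0))
        m = render_movie(None, [n], tiny_protocol, n_repeat=3, noise_sd=3.0,
                         seed=5, canvas=(48, 48))
        pre_frames = []
        for tr in m.trial_table.itertuples():
            pre_frames.extend(preprocess.window_frames(
                tr.onset_frame, preprocess.PRE_WINDOW_S, m.frame_rate))
        est = m.frames[pre_frames].mean(axis=0)
        err = np.abs(est - m.baseline_image).mean()
        assert err < 3.0 / np.sqrt(len(pre_frames)) * 4


def test_kernel_window_normalization():
    """The calcium kernel's mean over the response-window frames is 1."""
    k = CalciumKernel()
    t = (np.arange(12, 18) + 0.5) / 8.0 - 1.0  # onset at 1 s, 8 fps
    assert np.mean(k(t)) == pytest.approx(1.0)
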
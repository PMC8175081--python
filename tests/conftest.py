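"""Shared fixtures: small synthetic fields and rendered movies.

Expensive fixtures are session-scoped so the detection and statistics tests
share one rendering of each synthetic condition.
"""

from __future__ import annotations

import numpy as np
import pytest

from v4domains import preprocess, stimgen, synth, widefield


def tiny_contour_protocol() -> stimgen.StimulusSet:
    """12-stimulus curve/corner/bar set for fast movie-based tests."""
    stims, cats, forms = [], {}, {}

    def add(s, c, f):
        cats[len(stims)] = c
        forms[len(stims)] = f
        stims.append(s)

    for ori in (0, 90, 180, 270):
        add(stimgen.make_curve(10, 180, ori), "curve", "curve_r10_a180")
        add(stimgen.make_corner(10, 90, ori), "corner", "corner_L10_s90")
    for ori in (0, 45, 90, 135):
        add(stimgen.make_bar(10, ori), "bar", "bar_L10")
    return stimgen.StimulusSet("tiny", stims, cats, forms)


@pytest.fixture(scope="session")
def tiny_protocol() -> stimgen.StimulusSet:
    return tiny_contour_protocol()


@pytest.fixture(scope="session")
def map16x_set() -> stimgen.StimulusSet:
    return stimgen.build_protocol("map16x")


@pytest.fixture(scope="session")
def gratings_set() -> stimgen.StimulusSet:
    return stimgen.build_protocol("gratings")


@pytest.fixture(scope="session")
def domain_field(map16x_set, gratings_set):
    """Clustered synthetic field with fast-path response tables (no imaging)."""
    layout = synth.make_layout((360, 360), 2, 80, seed=3)
    neurons = synth.sample_neurons(layout, 150, seed=4, class_bias=0.25,
                                   impurity=0.0)
    table = synth.make_response_table(neurons, map16x_set, n_repeat=10,
                                      trial_noise_sd=0.05, seed=5)
    gtable = synth.make_response_table(neurons, gratings_set, n_repeat=10,
                                       trial_noise_sd=0.05, seed=6)
    return dict(layout=layout, neurons=neurons, table=table, gtable=gtable)


@pytest.fixture(scope="session")
def widefield_movie(tiny_protocol):
    """Dense high-SNR synthetic movie plus extracted response maps."""
    layout = synth.make_layout((64, 64), 2, 14, seed=11)
    neurons = synth.sample_neurons(layout, 500, seed=12, soma_radius=3.0,
                                   outside_class="none")
    movie = synth.render_movie(layout, neurons, tiny_protocol, n_repeat=8,
                               noise_sd=2.0, seed=13)
    aligned = preprocess.align(movie.frames, template=movie.baseline_image)
    maps = preprocess.dff(aligned, movie.trial_table)
    cmap = widefield.category_map(maps, tiny_protocol, smoothing_sigma=3.0)
    return dict(layout=layout, neurons=neurons, movie=movie, aligned=aligned,
                maps=maps, cmap=cmap)


@pytest.fixture(scope="session")
def widefield_patches(widefield_movie):
    """Permutation-screened patches for both targets on the dense field."""
    out = {}
    for i, target in enumerate(("curve", "corner")):
        out[target] = widefield.cluster_permutation(
            widefield_movie["cmap"], target, n_perm=200, seed=14 + i, downsample=1)
    return out
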
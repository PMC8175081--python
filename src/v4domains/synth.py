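"""Ground-truth-labeled synthetic two-photon data.

Emulates a field of view of soma-sized fluorescent blobs whose preferred
stimulus class is organized into spatial domains (curve-biased and
corner-biased patches), with trial-locked calcium transients, additive pixel
noise and optional rigid motion jitter.  The trial timing follows the
experimental protocol: 1 s blank fixation then 1 s of stimulus, imaged at
8 frames/s, each stimulus repeated ``n_repeat`` times (default 10).

Two generation paths are provided: :func:`render_movie` produces a full frame
stack for the imaging pipeline, and :func:`make_response_table` bypasses
imaging to produce per-neuron per-stimulus per-repeat responses directly for
the statistics modules.

Tuning model
------------
A neuron's mean response to a stimulus is

    ``peak_dff * class_gain * orientation_gain``

where ``class_gain`` is 1 for the preferred family and ``class_bias``
otherwise, and ``orientation_gain`` is a von Mises bump
``exp(kappa * (cos(delta) - 1))`` around the preferred orientation (period
180 deg for bars and Cartesian gratings, 360 deg otherwise; no orientation
modulation for concentric/radial gratings).  Curve-preferring neurons treat
Pi-shapes as non-preferred (smoothness selectivity) and concentric gratings
as preferred-like; corner-preferring neurons treat Pi-shapes and radial
gratings as preferred-like.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stimgen import (
    CONTOUR_ORIENTATIONS,
    ContourStimulus,
    GratingClass,
    GratingStimulus,
    ShapeClass,
    StimulusSet,
)

__all__ = [
    "GroundTruthNeuron",
    "DomainLayout",
    "SyntheticMovie",
    "CalciumKernel",
    "make_layout",
    "sample_neurons",
    "neuron_response_mean",
    "make_response_table",
    "render_movie",
    "make_trial_table",
]

FRAME_RATE_HZ = 8.0
PRE_S = 1.0  # blank fixation
STIM_S = 1.0


class LayoutError(RuntimeError):
    """Raised when domains cannot be placed without overlap."""


@dataclass(frozen=True)
class GroundTruthNeuron:
    position: tuple[float, float]  # (row, col) px
    soma_radius: float  # px
    preferred_class: str  # curve | corner | bar | none
    preferred_orientation: float  # deg
    orientation_kappa: float
    class_bias: float  # gain retained for non-preferred families, in [0, 1]
    peak_dff: float
    baseline_f: float

    def __post_init__(self) -> None:
        if self.peak_dff < 0:
            raise ValueError("peak_dff must be non-negative")
        if self.baseline_f <= 0:
            raise ValueError("baseline_f must be positive")
        if not 0.0 <= self.class_bias <= 1.0:
            raise ValueError("class_bias must lie in [0, 1]")


@dataclass
class DomainLayout:
    """Binary curve/corner domain masks over the imaging canvas."""

    canvas: tuple[int, int]
    domain_masks: dict[str, np.ndarray]  # {"curve": mask, "corner": mask}
    micron_per_px: float = 1.7

    def class_at(self, row: float, col: float) -> str:
        r, c = int(round(row)), int(round(col))
        for cls, mask in self.domain_masks.items():
            if mask[r, c]:
                return cls
        return "none"


@dataclass
class SyntheticMovie:
    frames: np.ndarray  # (frame, row, col), float32, >= 0
    frame_rate: float
    trial_table: pd.DataFrame
    neurons: list[GroundTruthNeuron]
    layout: DomainLayout | None
    rng_seed: int
    shifts: np.ndarray | None = None  # injected rigid jitter (frame, (dy, dx))
    baseline_image: np.ndarray | None = None


@dataclass(frozen=True)
class CalciumKernel:
    """Difference-of-exponentials calcium transient (GCaMP-like).

    Normalized so the mean of the kernel over the response window frames
    (0.5-1.25 s after onset at 8 fps) is 1; the downstream windowed dF/F0 of
    a noise-free transient then recovers the planted response amplitude.
    """

    tau_rise: float = 0.1
    tau_decay: float = 0.6
    frame_rate: float = FRAME_RATE_HZ

    def raw(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        v = np.exp(-t / self.tau_decay) - np.exp(-t / self.tau_rise)
        return np.where(t >= 0, v, 0.0)

    @property
    def _norm(self) -> float:
        mid = (np.arange(100) + 0.5) / self.frame_rate
        in_win = (mid >= 0.5) & (mid < 1.25)
        return float(np.mean(self.raw(mid[in_win])))

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return self.raw(t) / self._norm


# -- layout and neurons -----------------------------------------------------

def make_layout(canvas: tuple[int, int], n_domains: int, domain_radius: float,
                seed: int, micron_per_px: float = 1.7,
                max_tries: int = 2000) -> DomainLayout:
    """Place non-overlapping circular curve/corner domains, reproducibly.

    Domains alternate class (curve, corner, curve, ...).  Raises
    :class:`LayoutError` when placement fails within ``max_tries`` draws.
    """
    nrow, ncol = canvas
    if 2 * domain_radius > min(canvas):
        raise LayoutError("domain radius larger than canvas")
    rng = np.random.default_rng(seed)
    masks = {"curve": np.zeros(canvas, bool), "corner": np.zeros(canvas, bool)}
    centers: list[tuple[float, float]] = []
    rows, cols = np.mgrid[0:nrow, 0:ncol]
    for i in range(n_domains):
        for _ in range(max_tries):
            r = rng.uniform(domain_radius, nrow - domain_radius)
            c = rng.uniform(domain_radius, ncol - domain_radius)
            if all(np.hypot(r - r0, c - c0) >= 2 * domain_radius for r0, c0 in centers):
                break
        else:
            raise LayoutError(f"could not place domain {i} without overlap")
        centers.append((r, c))
        cls = "curve" if i % 2 == 0 else "corner"
        masks[cls] |= np.hypot(rows - r, cols - c) <= domain_radius
    return DomainLayout(canvas, masks, micron_per_px)


def sample_neurons(layout: DomainLayout, n_neurons: int, seed: int, *,
                   soma_radius: float = 4.0, class_bias: float = 0.25,
                   orientation_kappa: float = 2.0, impurity: float = 0.0,
                   peak_dff: tuple[float, float] = (0.6, 1.2),
                   baseline_f: float = 100.0,
                   outside_class: str = "none",
                   min_margin: float | None = None) -> list[GroundTruthNeuron]:
    """Draw neurons at uniform positions; class follows the domain masks.

    With probability ``impurity`` a neuron inside a domain is given the
    opposite class.  Neurons outside every mask get ``outside_class``.
    """
    rng = np.random.default_rng(seed)
    nrow, ncol = layout.canvas
    margin = soma_radius if min_margin is None else min_margin
    neurons = []
    flip = {"curve": "corner", "corner": "curve"}
    for _ in range(n_neurons):
        r = rng.uniform(margin, nrow - 1 - margin)
        c = rng.uniform(margin, ncol - 1 - margin)
        cls = layout.class_at(r, c)
        if cls == "none":
            cls = outside_class
        elif rng.uniform() < impurity:
            cls = flip[cls]
        neurons.append(GroundTruthNeuron(
            position=(r, c), soma_radius=soma_radius, preferred_class=cls,
            preferred_orientation=float(rng.choice(CONTOUR_ORIENTATIONS)),
            orientation_kappa=orientation_kappa, class_bias=class_bias,
            peak_dff=float(rng.uniform(*peak_dff)), baseline_f=baseline_f))
    return neurons


# -- tuning model -----------------------------------------------------------

_PREFERRED_LIKE = {
    "curve": {"curve", "concentric"},
    "corner": {"corner", "pi_shape", "radial"},
    "bar": {"bar"},
}


def _stim_category(stimulus: ContourStimulus | GratingStimulus) -> str:
    if isinstance(stimulus, ContourStimulus):
        return stimulus.shape_class.value
    return stimulus.grating_class.value


def neuron_response_mean(neuron: GroundTruthNeuron,
                         stimulus: ContourStimulus | GratingStimulus) -> float:
    """Noise-free mean dF/F0 of ``neuron`` to ``stimulus``.

    Neurons with preferred_class "none" are class-unselective (class gain 1
    for every family) but keep their orientation tuning, so any single
    stimulus map still shows a sparse subset of strong responders.
    """
    cat = _stim_category(stimulus)
    if neuron.preferred_class == "none":
        class_gain = 1.0
    else:
        preferred = cat in _PREFERRED_LIKE[neuron.preferred_class]
        class_gain = 1.0 if preferred else neuron.class_bias

    if cat in ("concentric", "radial"):
        ori_gain = 1.0  # no orientation axis
    else:
        period = 180.0 if cat in ("bar", "cartesian") else 360.0
        delta = np.deg2rad((stimulus.orientation_deg - neuron.preferred_orientation)
                           * 360.0 / period)
        ori_gain = float(np.exp(neuron.orientation_kappa * (np.cos(delta) - 1.0)))
    return neuron.peak_dff * class_gain * ori_gain


def make_response_table(neurons: list[GroundTruthNeuron], stimulus_set: StimulusSet,
                        n_repeat: int = 10, trial_noise_sd: float = 0.1,
                        seed: int = 0) -> pd.DataFrame:
    """Per-neuron per-stimulus per-repeat responses, bypassing imaging.

    Responses are ``neuron_response_mean`` plus i.i.d. Gaussian trial noise.
    Long-format DataFrame with columns (neuron_id, stim_id, repeat, response).
    """
    rng = np.random.default_rng(seed)
    means = np.array([[neuron_response_mean(n, s) for s in stimulus_set.stimuli]
                      for n in neurons])  # (neuron, stim)
    noise = rng.normal(0.0, trial_noise_sd, size=(len(neurons), len(stimulus_set), n_repeat)) \
        if trial_noise_sd > 0 else np.zeros((len(neurons), len(stimulus_set), n_repeat))
    resp = means[:, :, None] + noise
    idx = pd.MultiIndex.from_product(
        [range(len(neurons)), stimulus_set.stim_ids, range(n_repeat)],
        names=["neuron_id", "stim_id", "repeat"])
    return pd.DataFrame({"response": resp.ravel()}, index=idx).reset_index()


# -- movie rendering --------------------------------------------------------

def make_trial_table(stimulus_set: StimulusSet, n_repeat: int, seed: int,
                     frame_rate: float = FRAME_RATE_HZ) -> pd.DataFrame:
    """Pseudo-random trial order; onset 1 s into each 2 s trial."""
    rng = np.random.default_rng(seed)
    trials = [(s, rep) for rep in range(n_repeat) for s in stimulus_set.stim_ids]
    order = rng.permutation(len(trials))
    frames_per_trial = int(round((PRE_S + STIM_S) * frame_rate))
    onset_offset = int(round(PRE_S * frame_rate))
    rows = []
    for tid, k in enumerate(order):
        stim_id, rep = trials[k]
        rows.append(dict(trial_id=tid, stim_id=stim_id, repeat_index=rep,
                         onset_frame=tid * frames_per_trial + onset_offset,
                         outcome="success"))
    return pd.DataFrame(rows)


def _footprint(neuron: GroundTruthNeuron, canvas: tuple[int, int]):
    """Gaussian soma profile truncated at soma_radius; (rows, cols, weights)."""
    r0, c0 = neuron.position
    rad = neuron.soma_radius
    rlo, rhi = int(np.floor(r0 - rad)), int(np.ceil(r0 + rad))
    clo, chi = int(np.floor(c0 - rad)), int(np.ceil(c0 + rad))
    rlo, clo = max(rlo, 0), max(clo, 0)
    rhi, chi = min(rhi, canvas[0] - 1), min(chi, canvas[1] - 1)
    rr, cc = np.mgrid[rlo:rhi + 1, clo:chi + 1]
    d = np.hypot(rr - r0, cc - c0)
    w = np.exp(-d ** 2 / (2 * (rad / 2.0) ** 2))
    keep = d <= rad
    return rr[keep], cc[keep], w[keep]


def render_movie(layout: DomainLayout | None, neurons: list[GroundTruthNeuron],
                 stimulus_set: StimulusSet, n_repeat: int = 10,
                 noise_sd: float = 1.0, motion_amp: int = 0, seed: int = 0, *,
                 trial_gain_sd: float = 0.0, background_f: float = 20.0,
                 kernel: CalciumKernel | None = None,
                 canvas: tuple[int, int] | None = None) -> SyntheticMovie:
    """Render a trial-structured fluorescence movie with known ground truth.

    Each trial spans 2 s at 8 fps (1 s blank, 1 s stimulus).  Evoked dF/F0
    follows the calcium kernel scaled by the neuron's tuning-model response
    and an optional log-normal per-trial gain; pixel noise is Gaussian;
    motion jitter, when requested, is a per-frame rigid integer shift of
    up to ``motion_amp`` px recorded in ``SyntheticMovie.shifts``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if canvas is None:
        if layout is None:
            raise ValueError("need a layout or an explicit canvas")
        canvas = layout.canvas
    kernel = kernel or CalciumKernel()
    rng = np.random.default_rng(seed)
    trial_table = make_trial_table(stimulus_set, n_repeat, seed)
    frames_per_trial = int(round((PRE_S + STIM_S) * kernel.frame_rate))
    # one trailing trial worth of frames so the last response window exists
    n_frames = (len(trial_table) + 1) * frames_per_trial

    baseline = np.full(canvas, background_f, dtype=np.float64)
    prints = [_footprint(n, canvas) for n in neurons]
    for n, (rr, cc, w) in zip(neurons, prints):
        baseline[rr, cc] += n.baseline_f * w

    # float32 keeps large fields within memory; values O(100) lose < 1e-4
    frames = np.tile(baseline.astype(np.float32), (n_frames, 1, 1))
    t_mid = (np.arange(n_frames) + 0.5) / kernel.frame_rate

    means = np.array([[neuron_response_mean(n, s) for s in stimulus_set.stimuli]
                      for n in neurons])
    for trial in trial_table.itertuples():
        onset_t = trial.onset_frame / kernel.frame_rate
        # transient rendered up to the end of the response window (1.25 s
        # post onset); truncating there keeps the next trial's baseline
        # window clean, and no analysis window looks past that point
        f0 = trial.onset_frame
        f1 = min(n_frames, f0 + int(np.ceil(1.25 * kernel.frame_rate)) + 1)
        k = kernel(t_mid[f0:f1] - onset_t)
        for j, (n, (rr, cc, w)) in enumerate(zip(neurons, prints)):
            amp = means[j, trial.stim_id]
            if trial_gain_sd > 0:
                amp *= rng.lognormal(0.0, trial_gain_sd)
            if amp == 0:
                continue
            frames[f0:f1, rr, cc] += ((n.baseline_f * amp) * k[:, None]
                                      * w[None, :]).astype(np.float32)

    shifts = None
    if motion_amp > 0:
        shifts = rng.integers(-motion_amp, motion_amp + 1, size=(n_frames, 2))
        shifts[0] = 0
        for i, (dy, dx) in enumerate(shifts):
            if dy or dx:
                frames[i] = np.roll(frames[i], (dy, dx), axis=(0, 1))
    if noise_sd > 0:
        for i in range(n_frames):  # per-frame draws avoid a second full-size array
            frames[i] += rng.normal(0.0, noise_sd, size=canvas).astype(np.float32)
        np.clip(frames, 0.0, None, out=frames)

    return SyntheticMovie(frames=frames, frame_rate=kernel.frame_rate,
                          trial_table=trial_table, neurons=neurons, layout=layout,
                          rng_seed=seed, shifts=shifts, baseline_image=baseline)
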
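"""Motion correction and trial-locked dF/F0 extraction.

Frames are aligned to a template by the argmax of their 2-D cross-correlation
(integer-pixel shifts).  Responses use the experiment's windows: the baseline
F0 is the average fluorescence 0-0.5 s before stimulus onset and F the
average 0.5-1.25 s after onset; dF/F0 = (F - F0)/F0 per trial, averaged over
a stimulus's successful repeats for the mean map.

A frame belongs to a window when its midpoint time falls in the half-open
interval [t0, t1), which is unambiguous at 8 fps where 0.5 s is a frame
boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

__all__ = ["AlignedMovie", "ResponseMaps", "align", "dff", "window_frames",
           "PRE_WINDOW_S", "POST_WINDOW_S"]

PRE_WINDOW_S = (-0.5, 0.0)
POST_WINDOW_S = (0.5, 1.25)


@dataclass
class AlignedMovie:
    frames: np.ndarray  # (frame, row, col) after shift correction
    shifts: np.ndarray  # (frame, (dy, dx)) applied corrections
    frame_rate: float
    template_id: int | None = None
    bad_frames: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))


@dataclass
class ResponseMaps:
    """Per-trial and per-stimulus-mean dF/F0 maps.

    ``trial_dff`` is (trial, row, col) aligned with ``trial_table`` rows
    (failed trials dropped); ``mean_maps`` maps stim_id to the mean over that
    stimulus's repeats.  ``f0_maps`` keeps the per-trial baselines for
    responsiveness tests, ``f_maps`` the per-trial response-window means.
    """

    trial_dff: np.ndarray
    trial_table: pd.DataFrame
    mean_maps: dict[int, np.ndarray]
    f0_maps: np.ndarray
    f_maps: np.ndarray
    masked_px: np.ndarray  # (trial, row, col) bool: F0 <= eps, dff undefined
    window_pre: tuple[float, float] = PRE_WINDOW_S
    window_post: tuple[float, float] = POST_WINDOW_S

    def category_trials(self, stimulus_set, categories) -> np.ndarray:
        """Boolean selector over trials whose stimulus is in ``categories``."""
        ids = set(stimulus_set.ids_in_category(categories))
        return self.trial_table["stim_id"].isin(ids).to_numpy()


def _xcorr_shift(frame: np.ndarray, template: np.ndarray, max_shift: int) -> tuple[int, int] | None:
    """Integer (dy, dx) maximizing cross-correlation; None when out of bounds.

    Degenerate (zero-variance) frames correlate equally everywhere and get
    (0, 0) by the tie-breaking rule.
    """
    f = frame - frame.mean()
    t = template - template.mean()
    if not f.any() or not t.any():
        return (0, 0)
    corr = signal.fftconvolve(f, t[::-1, ::-1], mode="same")
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    cy, cx = np.asarray(corr.shape) // 2
    dy, dx = int(peak[0] - cy), int(peak[1] - cx)
    if abs(dy) > max_shift or abs(dx) > max_shift:
        return None
    return dy, dx


def align(frames: np.ndarray, template: np.ndarray | int = 0, *,
          frame_rate: float = 8.0, max_shift: int = 10) -> AlignedMovie:
    """Align each frame to a template by 2-D cross-correlation.

    ``template`` may be a frame index or an explicit image.  Frames whose
    estimated shift exceeds ``max_shift`` are flagged in ``bad_frames`` and
    left unshifted; downstream response extraction excludes trials touching
    them.
    """
    frames = np.asarray(frames)
    if isinstance(template, (int, np.integer)):
        template_id, template_img = int(template), frames[int(template)]
    else:
        template_id, template_img = None, np.asarray(template)
    if template_img.shape != frames.shape[1:]:
        raise ValueError("template shape must match frame shape")

    out = np.empty_like(frames)
    shifts = np.zeros((len(frames), 2), dtype=int)
    bad = []
    for i, fr in enumerate(frames):
        est = _xcorr_shift(fr, template_img, max_shift)
        if est is None:
            bad.append(i)
            out[i] = fr
            continue
        dy, dx = est
        shifts[i] = (dy, dx)
        out[i] = np.roll(fr, (-dy, -dx), axis=(0, 1)) if (dy or dx) else fr
    return AlignedMovie(frames=out, shifts=shifts, frame_rate=frame_rate,
                        template_id=template_id, bad_frames=np.array(bad, dtype=int))


def window_frames(onset_frame: int, window_s: tuple[float, float],
                  frame_rate: float) -> np.ndarray:
    """Frame indices whose midpoints fall in [t0, t1) relative to onset."""
    t0, t1 = window_s
    onset_t = onset_frame / frame_rate
    lo = int(np.floor((onset_t + t0) * frame_rate))
    hi = int(np.ceil((onset_t + t1) * frame_rate)) + 1
    f = np.arange(max(lo, 0), hi)
    mid = (f + 0.5) / frame_rate - onset_t
    return f[(mid >= t0) & (mid < t1)]


def dff(aligned: AlignedMovie, trial_table: pd.DataFrame, *,
        f0_eps_frac: float = 1e-6) -> ResponseMaps:
    """Per-trial and per-stimulus dF/F0 maps with the standard windows.

    Failed trials (outcome != "success") and trials whose windows touch
    flagged frames or run off the stack are dropped before averaging.
    Pixels with F0 below ``f0_eps_frac`` of the frame median are masked for
    that trial (dff set to NaN) rather than clamped.
    """
    frames = aligned.frames
    fr = aligned.frame_rate
    bad = set(aligned.bad_frames.tolist())
    eps = f0_eps_frac * float(np.median(frames))

    kept_rows, f0s, fs, dffs, masks = [], [], [], [], []
    for trial in trial_table.itertuples():
        if getattr(trial, "outcome", "success") != "success":
            continue
        pre = window_frames(trial.onset_frame, PRE_WINDOW_S, fr)
        post = window_frames(trial.onset_frame, POST_WINDOW_S, fr)
        if len(pre) == 0 or len(post) == 0 or post[-1] >= len(frames) or pre[0] < 0:
            raise ValueError(f"trial {trial.trial_id}: window frames outside the stack")
        if bad.intersection(pre.tolist() + post.tolist()):
            continue
        f0 = frames[pre].mean(axis=0, dtype=np.float64)
        f = frames[post].mean(axis=0, dtype=np.float64)
        masked = f0 <= eps
        with np.errstate(divide="ignore", invalid="ignore"):
            d = (f - f0) / f0
        d[masked] = np.nan
        kept_rows.append(trial.Index)
        f0s.append(f0)
        fs.append(f)
        dffs.append(d)
        masks.append(masked)

    table = trial_table.loc[kept_rows].reset_index(drop=True)
    trial_dff = np.stack(dffs) if dffs else np.zeros((0,) + frames.shape[1:])
    with warnings.catch_warnings():
        # pixels masked in every trial legitimately average to NaN
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        mean_maps = {
            int(sid): np.nanmean(trial_dff[(table["stim_id"] == sid).to_numpy()], axis=0)
            for sid in sorted(table["stim_id"].unique())
        }
    return ResponseMaps(trial_dff=trial_dff, trial_table=table, mean_maps=mean_maps,
                        f0_maps=np.stack(f0s) if f0s else trial_dff.copy(),
                        f_maps=np.stack(fs) if fs else trial_dff.copy(),
                        masked_px=np.stack(masks) if masks else trial_dff.astype(bool))
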
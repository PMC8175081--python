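"""Single-cell ROI segmentation and response extraction (16x scale).

Cell bodies are found on band-passed (difference-of-Gaussians, sigma 2/5 px)
per-stimulus dF maps, binarized at mean + 3 SD of the filtered image,
8-connected components larger than 25 px kept, components whose maximum raw
dF/F0 is below 0.3 dropped, and a roundness criterion C = P^2 / (4 pi S)
< 1.1 applied last, with P a Crofton multi-direction perimeter estimate
(a naive boundary-pixel count biases C upward for small discrete disks).
ROIs detected on different stimulus maps are merged when their centroids
fall within one soma diameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage import measure

from .preprocess import POST_WINDOW_S, PRE_WINDOW_S, AlignedMovie, ResponseMaps, window_frames

__all__ = ["ROI", "bandpass", "roundness", "segment_image", "segment",
           "responsiveness_anova", "extract", "build_neuron_table"]


@dataclass
class ROI:
    pixels: np.ndarray  # (n, 2) array of (row, col)
    centroid: tuple[float, float]  # (row, col) px
    area: int
    perimeter: float
    roundness: float
    max_dff: float
    responsive_p: float = float("nan")

    @property
    def mask_indices(self) -> tuple[np.ndarray, np.ndarray]:
        return self.pixels[:, 0], self.pixels[:, 1]

    def centroid_um(self, micron_per_px: float) -> tuple[float, float]:
        return (self.centroid[1] * micron_per_px, self.centroid[0] * micron_per_px)  # (x, y)


def bandpass(image: np.ndarray, sigma_small: float = 2.0, sigma_large: float = 5.0) -> np.ndarray:
    """Difference-of-Gaussians band-pass; removes DC and high-frequency noise."""
    if sigma_small >= sigma_large:
        raise ValueError("sigma_small must be less than sigma_large")
    img = np.nan_to_num(np.asarray(image, dtype=float))
    return ndimage.gaussian_filter(img, sigma_small) - ndimage.gaussian_filter(img, sigma_large)


def roundness(mask: np.ndarray) -> tuple[float, float, int]:
    """(C, perimeter, area) for a single binary component.

    C = P^2 / (4 pi S) is 1 for an ideal disk; the Crofton estimator (4
    directions) keeps discrete disks near 1 where boundary-pixel counting
    would overshoot.
    """
    props = measure.regionprops(mask.astype(np.uint8))
    if len(props) != 1:
        raise ValueError("mask must contain exactly one component")
    p = props[0].perimeter_crofton
    s = props[0].area
    return float(p * p / (4.0 * np.pi * s)), float(p), int(s)


def segment_image(filtered: np.ndarray, max_dff_map: np.ndarray, *,
                  sd_factor: float = 3.0, min_area: int = 25,
                  max_roundness: float = 1.1, min_max_dff: float = 0.3,
                  robust: bool = False) -> list[ROI]:
    """Segment candidate somata on one band-passed image.

    Threshold = mean + ``sd_factor`` * SD of the filtered pixel distribution
    (median + scaled MAD when ``robust``); then the area, response-amplitude
    and roundness filters, in that order.
    """
    if robust:
        center = float(np.median(filtered))
        scale = float(stats.median_abs_deviation(filtered, axis=None, scale="normal"))
    else:
        center, scale = float(filtered.mean()), float(filtered.std())
    binary = filtered > center + sd_factor * scale
    lab, n = ndimage.label(binary, structure=np.ones((3, 3), bool))
    rois = []
    for cid in range(1, n + 1):
        comp = lab == cid
        area = int(comp.sum())
        if area <= min_area:
            continue
        mx = float(np.nanmax(max_dff_map[comp]))
        if mx < min_max_dff:
            continue
        c, p, s = roundness(comp)
        if c >= max_roundness:
            continue
        rr, cc = np.nonzero(comp)
        rois.append(ROI(pixels=np.column_stack([rr, cc]),
                        centroid=(float(rr.mean()), float(cc.mean())),
                        area=area, perimeter=p, roundness=c, max_dff=mx))
    return rois


def _merge(rois: list[ROI], merge_dist: float, max_dff_map: np.ndarray) -> list[ROI]:
    """Union ROIs whose centroids are closer than ``merge_dist`` px."""
    merged: list[ROI] = []
    for roi in sorted(rois, key=lambda r: (-r.area, r.centroid)):
        for m in merged:
            if np.hypot(roi.centroid[0] - m.centroid[0], roi.centroid[1] - m.centroid[1]) < merge_dist:
                pix = np.unique(np.vstack([m.pixels, roi.pixels]), axis=0)
                m.pixels = pix
                m.centroid = (float(pix[:, 0].mean()), float(pix[:, 1].mean()))
                m.area = len(pix)
                m.max_dff = max(m.max_dff, roi.max_dff)
                break
        else:
            merged.append(roi)
    return merged


def segment(maps: ResponseMaps, *, sigma_small: float = 2.0, sigma_large: float = 5.0,
            sd_factor: float = 3.0, min_area: int = 25, max_roundness: float = 1.1,
            min_max_dff: float = 0.3, merge_dist: float = 8.0,
            robust: bool = False) -> list[ROI]:
    """Detect ROIs across all per-stimulus mean dF/F0 maps and merge them."""
    stack = np.stack([np.nan_to_num(m) for m in maps.mean_maps.values()])
    max_dff_map = stack.max(axis=0)
    rois: list[ROI] = []
    for m in maps.mean_maps.values():
        filt = bandpass(m, sigma_small, sigma_large)
        rois.extend(segment_image(filt, max_dff_map, sd_factor=sd_factor,
                                  min_area=min_area, max_roundness=max_roundness,
                                  min_max_dff=min_max_dff, robust=robust))
    return _merge(rois, merge_dist, max_dff_map)


def responsiveness_anova(roi: ROI, aligned: AlignedMovie, trial_table: pd.DataFrame) -> float:
    """One-way ANOVA of pre- vs post-window ROI fluorescence over all trials.

    With two groups this is equivalent to a two-sample t-test (F = t^2);
    p = 1 is returned for degenerate (zero-variance) data.
    """
    rr, cc = roi.mask_indices
    pre_vals, post_vals = [], []
    for trial in trial_table.itertuples():
        if getattr(trial, "outcome", "success") != "success":
            continue
        pre = window_frames(trial.onset_frame, PRE_WINDOW_S, aligned.frame_rate)
        post = window_frames(trial.onset_frame, POST_WINDOW_S, aligned.frame_rate)
        if post[-1] >= len(aligned.frames):
            continue
        pre_vals.append(aligned.frames[pre][:, rr, cc].mean())
        post_vals.append(aligned.frames[post][:, rr, cc].mean())
    if len(pre_vals) < 2:
        return float("nan")
    if np.var(pre_vals) == 0 and np.var(post_vals) == 0:
        return 1.0
    return float(stats.f_oneway(pre_vals, post_vals).pvalue)


def extract(roi: ROI, maps: ResponseMaps) -> pd.DataFrame:
    """Per-trial ROI responses: mean per-trial dF/F0 over the ROI pixels."""
    rr, cc = roi.mask_indices
    if rr.max() >= maps.trial_dff.shape[1] or cc.max() >= maps.trial_dff.shape[2]:
        raise ValueError("ROI extends outside the imaged area")
    vals = np.nanmean(maps.trial_dff[:, rr, cc], axis=1)
    out = maps.trial_table[["stim_id", "repeat_index"]].copy()
    out["response"] = vals
    return out


def build_neuron_table(rois: list[ROI], maps: ResponseMaps, *,
                       aligned: AlignedMovie | None = None,
                       micron_per_px: float = 1.7) -> pd.DataFrame:
    """Long-format table (neuron_id, stim_id, repeat, response) for all ROIs."""
    rows = []
    for nid, roi in enumerate(rois):
        if aligned is not None:
            roi.responsive_p = responsiveness_anova(roi, aligned, maps.trial_table)
        t = extract(roi, maps)
        t = t.rename(columns={"repeat_index": "repeat"})
        t.insert(0, "neuron_id", nid)
        rows.append(t)
    if not rows:
        return pd.DataFrame(columns=["neuron_id", "stim_id", "repeat", "response"])
    return pd.concat(rows, ignore_index=True)
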
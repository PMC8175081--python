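"""Widefield curve/corner domain localization.

The 4x-scale analysis groups trials into three categories (curves, corners,
bars) and, per pixel, runs two two-sample t-tests comparing the target
category's per-trial dF/F0 against each of the other two.  The pixel's
p-value is the larger of the two when the target's mean exceeds both other
means, and 1 otherwise (a one-sided selection rule).  The p-map is corrected
by the Benjamini-Hochberg step-up procedure (q_i = p_i * N / rank(p_i),
monotonized) and thresholded at q.  Surviving connected components are then
screened by a max-cluster-size permutation test: trial labels are shuffled
(preserving category counts), pixel p-values recomputed, thresholded at an
uncorrected alpha, and the largest connected component recorded per
permutation; observed clusters must beat the null's upper-tail order
statistic.

Smoothing (Gaussian sigma = 10 px by default) is applied only to display
maps; all statistics run on unsmoothed per-trial responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .preprocess import ResponseMaps
from .stimgen import StimulusSet

__all__ = ["CategoryMap", "PatchResult", "category_map", "subtraction_map",
           "pixel_pvals", "bh_fdr", "cluster_permutation", "jaccard"]

CATEGORIES = ("curve", "corner", "bar")
EIGHT_CONN = np.ones((3, 3), bool)


@dataclass
class CategoryMap:
    """Trial-level pixel responses grouped by stimulus category."""

    trial_responses: dict[str, np.ndarray]  # category -> (trial, row, col)
    smoothing_sigma: float = 10.0

    def __post_init__(self) -> None:
        missing = [c for c in CATEGORIES if c not in self.trial_responses]
        if missing:
            raise ValueError(f"missing categories: {missing}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.trial_responses.values())).shape[1:]

    def mean(self, category: str) -> np.ndarray:
        return np.nanmean(self.trial_responses[category], axis=0)


@dataclass
class PatchResult:
    p_map: np.ndarray
    q_map: np.ndarray
    significant_mask: np.ndarray  # FDR mask before cluster screening
    clusters: list[dict]  # surviving: {"id", "size", "pixels", "centroid"}
    patch_mask: np.ndarray  # union of surviving clusters
    null_max_sizes: np.ndarray
    cluster_threshold: int
    n_perm: int
    q_threshold: float
    alpha_uncorrected: float
    tail_fraction: float
    seed: int | None = None


def category_map(maps: ResponseMaps, stimulus_set: StimulusSet, *,
                 smoothing_sigma: float = 10.0,
                 categories: tuple[str, ...] = CATEGORIES) -> CategoryMap:
    """Group the per-trial dF/F0 stack by stimulus category."""
    resp = {}
    for cat in categories:
        sel = maps.category_trials(stimulus_set, cat)
        resp[cat] = maps.trial_dff[sel]
    return CategoryMap(resp, smoothing_sigma)


def subtraction_map(cmap: CategoryMap, target: str) -> np.ndarray:
    """Smoothed mean(target) minus smoothed mean of all other categories."""
    if target not in cmap.trial_responses:
        raise ValueError(f"missing category: {target}")
    others = [c for c in cmap.trial_responses if c != target]
    other_stack = np.concatenate([cmap.trial_responses[c] for c in others])
    sm = lambda img: ndimage.gaussian_filter(np.nan_to_num(img), cmap.smoothing_sigma)
    return sm(cmap.mean(target)) - sm(np.nanmean(other_stack, axis=0))


def _ttest_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pixelwise two-sample t-test p-map; zero-variance pixels get p = 1."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = stats.ttest_ind(a, b, axis=0)
    p = np.asarray(t.pvalue, dtype=float)
    p[~np.isfinite(p)] = 1.0
    return p


def pixel_pvals(cmap: CategoryMap, target: str,
                trial_responses: dict[str, np.ndarray] | None = None) -> np.ndarray:
    """Per-pixel selection p-map for the target category.

    p = max of the two two-sample t-test p-values (target vs each other
    category) where the target mean exceeds both other means; p = 1
    elsewhere.
    """
    resp = trial_responses if trial_responses is not None else cmap.trial_responses
    if target not in resp:
        raise ValueError(f"missing category: {target}")
    others = [c for c in resp if c != target]
    a = resp[target]
    if any(len(resp[c]) < 2 for c in resp):
        raise ValueError("need at least 2 trials per category")
    p = np.zeros(a.shape[1:])
    tmean = np.nanmean(a, axis=0)
    stronger = np.ones(a.shape[1:], bool)
    for c in others:
        p = np.maximum(p, _ttest_p(a, resp[c]))
        stronger &= tmean > np.nanmean(resp[c], axis=0)
    p[~stronger] = 1.0
    return p


def bh_fdr(p_map: np.ndarray, q_threshold: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up over all pixels.

    Raw per-pixel q_i = p_i * N / rank(p_i), monotonized from the largest
    p downward (the step-up pass).  Returns (q_map, mask at q <= threshold).
    """
    p = np.asarray(p_map, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    flat = p.ravel()
    n = flat.size
    order = np.argsort(flat, kind="stable")
    ranked = flat[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    q_map = q.reshape(p.shape)
    return q_map, q_map <= q_threshold


def _label_clusters(mask: np.ndarray) -> tuple[np.ndarray, int]:
    return ndimage.label(mask, structure=EIGHT_CONN)


def _max_cluster_size(mask: np.ndarray) -> int:
    lab, n = _label_clusters(mask)
    if n == 0:
        return 0
    return int(np.bincount(lab.ravel())[1:].max())


def _downsample(stack: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean spatial downsampling of a (trial, row, col) stack."""
    if factor == 1:
        return stack
    t, h, w = stack.shape
    h2, w2 = h - h % factor, w - w % factor
    s = stack[:, :h2, :w2].reshape(t, h2 // factor, factor, w2 // factor, factor)
    return s.mean(axis=(2, 4))


def cluster_permutation(cmap: CategoryMap, target: str, *, n_perm: int = 60000,
                        q_threshold: float = 0.01, alpha_uncorrected: float = 0.01,
                        tail_fraction: float = 0.05, downsample: int = 1,
                        observed_mask: str = "fdr", seed: int = 0) -> PatchResult:
    """FDR patch detection followed by max-cluster-size permutation screening.

    Each permutation relabels all trials into the three categories (counts
    preserved), recomputes the pixel p-map, thresholds at the uncorrected
    alpha and records the maximum connected-component size (8-connected).
    The cluster-size threshold is the null's order statistic at
    ceil((1 - tail_fraction) * n_perm); observed FDR-mask clusters must
    strictly exceed it.  ``downsample`` runs the permutations on block-mean
    reduced responses (sizes rescaled back) to keep large counts tractable.

    ``observed_mask`` selects where the observed clusters are defined:
    "fdr" (default) takes them from the q-thresholded mask, "uncorrected"
    from the same alpha-thresholded mask the permutations use (the latter
    makes the screened test exactly exchangeable with its null).
    """
    if n_perm < 1 or int(tail_fraction * n_perm) < 1:
        raise ValueError("n_perm too small for the requested tail fraction")
    p_map = pixel_pvals(cmap, target)
    q_map, fdr_mask = bh_fdr(p_map, q_threshold)

    cats = list(cmap.trial_responses)
    pooled = np.concatenate([cmap.trial_responses[c] for c in cats])
    counts = [len(cmap.trial_responses[c]) for c in cats]
    bounds = np.cumsum([0] + counts)
    pooled_ds = _downsample(np.nan_to_num(pooled), downsample)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        perm = rng.permutation(len(pooled))
        resp = {c: pooled_ds[perm[bounds[k]:bounds[k + 1]]] for k, c in enumerate(cats)}
        p = pixel_pvals(cmap, target, trial_responses=resp)
        null[i] = _max_cluster_size(p < alpha_uncorrected)

    order_idx = int(np.ceil((1.0 - tail_fraction) * n_perm)) - 1
    thr_ds = int(np.sort(null)[order_idx])
    threshold = thr_ds * downsample * downsample  # rescale to full-resolution pixels

    if observed_mask == "fdr":
        obs_mask = fdr_mask
    elif observed_mask == "uncorrected":
        obs_mask = p_map < alpha_uncorrected
    else:
        raise ValueError("observed_mask must be 'fdr' or 'uncorrected'")
    lab, n_lab = _label_clusters(obs_mask)
    clusters = []
    patch_mask = np.zeros_like(fdr_mask)
    for cid in range(1, n_lab + 1):
        pix = lab == cid
        size = int(pix.sum())
        if size > threshold:
            com = ndimage.center_of_mass(pix)
            clusters.append({"id": cid, "size": size, "pixels": pix,
                             "centroid": (float(com[0]), float(com[1]))})
            patch_mask |= pix
    return PatchResult(p_map=p_map, q_map=q_map, significant_mask=fdr_mask,
                       clusters=clusters, patch_mask=patch_mask,
                       null_max_sizes=null, cluster_threshold=threshold,
                       n_perm=n_perm, q_threshold=q_threshold,
                       alpha_uncorrected=alpha_uncorrected,
                       tail_fraction=tail_fraction, seed=seed)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Pixelwise Jaccard overlap of two binary masks."""
    a, b = a.astype(bool), b.astype(bool)
    union = np.logical_or(a, b).sum()
    return float(np.logical_and(a, b).sum() / union) if union else 1.0
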
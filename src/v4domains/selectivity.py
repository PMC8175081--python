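"""Selectivity indices and their significance tests.

All indices share the contrast form (a - b) / (a + b) on maximal family
responses, ranging over [-1, 1]:

CVSI
    curve vs. other (bars and corners jointly): (MaxResp_curve -
    MaxResp_other) / (MaxResp_curve + MaxResp_other).  A value of 0.33 means
    the optimal curve response is twice the optimal other response; 0.2
    means 1.5 times.
CNSI
    corner vs. other (bars and curves jointly).
CVCNI
    curve vs. corner.
CVPII
    curve vs. Pi-shape (smoothness preference).
CRI
    concentric vs. radial grating (headline value uses the maximum over the
    three spatial frequencies; per-SF values are also emitted).

MaxResp is the maximum of mean-over-repeats responses within a family; the
optimal stimulus is frozen from the means before any repeat-level test.
Negative mean responses (possible under noise) are floored at 0 before the
index is formed; an index with both maxima 0 is undefined (NaN).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .stimgen import StimulusSet

__all__ = ["index", "family_max", "index_significance", "orientation_tuning_test",
           "compute_profiles", "index_cellmap", "BONFERRONI_COMPARISONS"]

#: orientation-tuning Bonferroni factor: 6 corner + 8 curve forms
BONFERRONI_COMPARISONS = 14

INDEX_DEFS = {
    "CVSI": ("curve", ("bar", "corner")),
    "CNSI": ("corner", ("bar", "curve")),
    "CVCNI": ("curve", ("corner",)),
    "CVPII": ("curve", ("pi_shape",)),
    "CRI": ("concentric", ("radial",)),
}


def index(max_a: float, max_b: float) -> float:
    """Contrast index (a - b) / (a + b); NaN when both are 0 (undefined).

    Inputs are floored at 0: the contrast presupposes non-negative responses.
    """
    a, b = max(float(max_a), 0.0), max(float(max_b), 0.0)
    if a + b == 0.0:
        return float("nan")
    return (a - b) / (a + b)


def _mean_table(neuron_table: pd.DataFrame) -> pd.DataFrame:
    """(neuron x stim) mean-over-repeats response matrix."""
    return neuron_table.pivot_table(index="neuron_id", columns="stim_id",
                                    values="response", aggfunc="mean")


def family_max(means: pd.Series, family: str | tuple[str, ...],
               stimulus_set: StimulusSet) -> tuple[float, int | None]:
    """Maximum mean response within a family and its optimal stimulus id.

    ``means`` indexes stim_id -> mean response for one neuron.  Returns
    (NaN, None) when the family is absent from the protocol; ties go to the
    lowest stim_id.
    """
    ids = stimulus_set.ids_in_category(family)
    ids = [i for i in ids if i in means.index]
    if not ids:
        return float("nan"), None
    vals = means.loc[ids]
    best = int(vals.idxmax())  # idxmax takes the first (lowest id) on ties
    return float(vals.loc[best]), best


def index_significance(neuron_table: pd.DataFrame, neuron_id: int,
                       stim_a: int, stim_b: int) -> float:
    """One-way ANOVA across the per-repeat responses at two optimal stimuli."""
    sub = neuron_table[neuron_table["neuron_id"] == neuron_id]
    a = sub.loc[sub["stim_id"] == stim_a, "response"].to_numpy()
    b = sub.loc[sub["stim_id"] == stim_b, "response"].to_numpy()
    if len(a) < 2 or len(b) < 2:
        return float("nan")
    if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
        return 1.0
    return float(stats.f_oneway(a, b).pvalue)


def orientation_tuning_test(neuron_table: pd.DataFrame, neuron_id: int,
                            stimulus_set: StimulusSet, *,
                            pre_post: tuple[np.ndarray, np.ndarray] | None = None,
                            n_comparisons: int = BONFERRONI_COMPARISONS,
                            alpha: float = 0.05) -> tuple[float, float, bool]:
    """Orientation-selectivity test for the optimal curve/corner form.

    Returns (p_responsive, p_orientation_corrected, significant).  Test 1
    compares pre- vs post-onset fluorescence over all curve and corner
    trials (supplied as ``pre_post`` arrays; skipped as p=0 placeholder-free
    NaN when unavailable).  Test 2 is a one-way ANOVA across the 8
    orientations of the neuron's optimal curve/corner form, Bonferroni
    multiplied by ``n_comparisons`` and capped at 1.  The neuron is deemed
    orientation-tuned when both tests pass ``alpha``.
    """
    sub = neuron_table[neuron_table["neuron_id"] == neuron_id]
    means = sub.groupby("stim_id")["response"].mean()
    _, best = family_max(means, ("curve", "corner"), stimulus_set)
    if best is None:
        return float("nan"), float("nan"), False
    form_ids = stimulus_set.ids_in_form(stimulus_set.form_of[best])
    groups = [sub.loc[sub["stim_id"] == sid, "response"].to_numpy() for sid in form_ids]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2 or np.ptp(np.concatenate(groups)) == 0:
        p_ori = 1.0
    else:
        with np.errstate(invalid="ignore"):
            p_raw = stats.f_oneway(*groups).pvalue
        p_ori = 1.0 if not np.isfinite(p_raw) else float(p_raw)
    p_ori = min(1.0, n_comparisons * p_ori)

    if pre_post is not None:
        pre, post = pre_post
        p_resp = float(stats.f_oneway(pre, post).pvalue) if len(pre) > 1 else float("nan")
    else:
        p_resp = float("nan")
    significant = (p_ori < alpha) and (np.isnan(p_resp) or p_resp < alpha)
    return p_resp, p_ori, bool(significant)


@dataclass
class CellMapData:
    """Plot-ready index cell map plus per-domain summaries."""

    positions_um: np.ndarray  # (n, 2) (x, y)
    values: np.ndarray
    excluded: int
    domain_stats: dict[str, dict]  # mask name -> {values, mean, se, n}


def compute_profiles(neuron_table: pd.DataFrame, stimulus_set: StimulusSet, *,
                     positions_um: np.ndarray | None = None,
                     grating_table: pd.DataFrame | None = None,
                     grating_set: StimulusSet | None = None) -> pd.DataFrame:
    """Per-neuron selectivity profile: family maxima, indices, significance.

    ``neuron_table`` holds contour-protocol responses; grating responses (for
    CRI) may come from a separate protocol via ``grating_table``/
    ``grating_set``.  Per-SF CRI columns (``CRI_sf{f}``) are emitted
    alongside the headline CRI (max response over SFs per grating class).
    """
    means = _mean_table(neuron_table)
    rows = []
    for nid in means.index:
        m = means.loc[nid].clip(lower=0.0)
        row: dict = {"neuron_id": nid}
        fam_max: dict[str, float] = {}
        fam_opt: dict[str, int | None] = {}
        for fam in ("curve", "corner", "bar", "pi_shape"):
            fam_max[fam], fam_opt[fam] = family_max(m, fam, stimulus_set)
            row[f"MaxResp_{fam}"] = fam_max[fam]
        # joint "other" maxima
        for name, (fa, fb) in INDEX_DEFS.items():
            if fa in ("concentric",):
                continue
            va, _ = family_max(m, fa, stimulus_set)
            vb, _ = family_max(m, fb, stimulus_set)
            row[name] = index(va, vb) if not (np.isnan(va) or np.isnan(vb)) else float("nan")
        # repeat-level significance for CVCNI (optimal curve vs optimal corner)
        if fam_opt["curve"] is not None and fam_opt["corner"] is not None:
            row["p_CVCNI"] = index_significance(neuron_table, nid,
                                                fam_opt["curve"], fam_opt["corner"])
        else:
            row["p_CVCNI"] = float("nan")
        _, p_ori, sig = orientation_tuning_test(neuron_table, nid, stimulus_set)
        row["p_orientation"] = p_ori
        row["orientation_tuned"] = sig
        rows.append(row)
    prof = pd.DataFrame(rows).set_index("neuron_id")

    if grating_table is not None and grating_set is not None:
        gmeans = _mean_table(grating_table)
        man = grating_set.manifest()
        for nid in prof.index:
            if nid not in gmeans.index:
                continue
            gm = gmeans.loc[nid].clip(lower=0.0)
            conc, _ = family_max(gm, "concentric", grating_set)
            rad, _ = family_max(gm, "radial", grating_set)
            prof.loc[nid, "MaxResp_concentric"] = conc
            prof.loc[nid, "MaxResp_radial"] = rad
            prof.loc[nid, "CRI"] = index(conc, rad)
            for sf in sorted(man.loc[man["class"] == "concentric", "sf_cpd"].unique()):
                cid = man[(man["class"] == "concentric") & (man["sf_cpd"] == sf)]["stim_id"]
                rid = man[(man["class"] == "radial") & (man["sf_cpd"] == sf)]["stim_id"]
                prof.loc[nid, f"CRI_sf{sf:g}"] = index(
                    float(gm.loc[list(cid)].max()), float(gm.loc[list(rid)].max()))

    if positions_um is not None:
        prof["x_um"] = positions_um[:, 0]
        prof["y_um"] = positions_um[:, 1]
    return prof


def index_cellmap(profiles: pd.DataFrame, index_name: str,
                  domain_masks: dict[str, np.ndarray] | None = None, *,
                  micron_per_px: float = 1.7,
                  canvas: tuple[int, int] | None = None) -> CellMapData:
    """Cell-map data for one index plus per-domain histograms.

    Neurons falling outside the imaged canvas are excluded (counted); for
    each domain mask the member neurons' index values, mean and SE are
    reported.  Empty masks yield empty summaries, not errors.
    """
    pos = profiles[["x_um", "y_um"]].to_numpy()
    vals = profiles[index_name].to_numpy()
    excluded = 0
    keep = np.ones(len(pos), bool)
    if canvas is not None:
        rr = pos[:, 1] / micron_per_px
        cc = pos[:, 0] / micron_per_px
        keep = (rr >= 0) & (rr < canvas[0]) & (cc >= 0) & (cc < canvas[1])
        excluded = int((~keep).sum())
    domain_stats = {}
    if domain_masks:
        for name, mask in domain_masks.items():
            inside = []
            for i in np.nonzero(keep)[0]:
                r = int(round(pos[i, 1] / micron_per_px))
                c = int(round(pos[i, 0] / micron_per_px))
                if 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and mask[r, c]:
                    inside.append(vals[i])
            inside = np.array([v for v in inside if np.isfinite(v)])
            domain_stats[name] = {
                "values": inside,
                "n": len(inside),
                "mean": float(inside.mean()) if len(inside) else float("nan"),
                "se": float(inside.std(ddof=1) / np.sqrt(len(inside))) if len(inside) > 1 else float("nan"),
            }
    return CellMapData(positions_um=pos[keep], values=vals[keep],
                       excluded=excluded, domain_stats=domain_stats)
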
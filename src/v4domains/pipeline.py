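"""End-to-end orchestration: synth -> preprocess -> widefield -> cellmap ->
selectivity -> spatialstats -> population, under one config and one seed.

``run`` executes the stages in order on a synthetic field with known ground
truth and writes every stage's outputs (CSV/TIFF/JSON) plus a provenance
manifest (config hash, seed, per-stage wall time) into a run directory.
Deterministic stages are bit-identical under the same config.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import cellmap, population, preprocess, selectivity, spatialstats, stimgen, synth, widefield
from .config import PipelineConfig, save_config

__all__ = ["PipelineResult", "run"]

log = logging.getLogger("v4domains")


@dataclass
class PipelineResult:
    config: PipelineConfig
    out_dir: Path | None
    layout: synth.DomainLayout
    neurons: list
    patches: dict[str, widefield.PatchResult]
    rois: list
    profiles: pd.DataFrame
    pairs: pd.DataFrame
    distance_profiles: dict[str, pd.DataFrame]
    response_matrix: population.ResponseMatrix
    form_clusters: population.ClusteringResult
    neuron_clusters: population.ClusteringResult
    mds: population.MDSResult
    jaccard: dict[str, float] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)


def _write_mask(path: Path, mask: np.ndarray) -> None:
    tifffile.imwrite(path, (mask.astype(np.uint8) * 255))


def run(cfg: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full pipeline on synthetic data generated from ``cfg``."""
    t_all = time.time()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        save_config(cfg, out / "config.yaml")
    timings: dict[str, float] = {}

    def stage(name):
        timings[name] = time.time()
        log.info("stage %s (seed %d)", name, cfg.seed)

    def done(name):
        timings[name] = time.time() - timings[name]

    # -- synth ---------------------------------------------------------------
    stage("synth")
    contour_set = stimgen.build_protocol(cfg.protocol)
    grating_set = stimgen.build_protocol("gratings")
    layout = synth.make_layout(cfg.canvas, cfg.n_domains, cfg.domain_radius,
                               seed=cfg.seed, micron_per_px=cfg.micron_per_px)
    # sparse single-cell field plus a dense widefield-style population on
    # the same layout (mirroring the high/low-power split of the recordings)
    neurons = synth.sample_neurons(layout, cfg.n_neurons, seed=cfg.seed + 1,
                                   soma_radius=cfg.soma_radius)
    wf_neurons = synth.sample_neurons(layout, cfg.wf_n_neurons, seed=cfg.seed + 8,
                                      soma_radius=cfg.wf_soma_radius)
    movie = synth.render_movie(layout, neurons, contour_set, n_repeat=cfg.n_repeat,
                               noise_sd=cfg.noise_sd, motion_amp=cfg.motion_amp,
                               seed=cfg.seed + 2)
    gmovie = synth.render_movie(layout, neurons, grating_set, n_repeat=cfg.n_repeat,
                                noise_sd=cfg.noise_sd, motion_amp=0, seed=cfg.seed + 3)
    done("synth")

    # -- preprocess ----------------------------------------------------------
    stage("preprocess")
    aligned = preprocess.align(movie.frames, template=movie.baseline_image,
                               frame_rate=movie.frame_rate, max_shift=cfg.max_shift)
    maps = preprocess.dff(aligned, movie.trial_table)
    galigned = preprocess.align(gmovie.frames, template=gmovie.baseline_image,
                                frame_rate=gmovie.frame_rate, max_shift=cfg.max_shift)
    gmaps = preprocess.dff(galigned, gmovie.trial_table)
    del gmovie.frames, galigned.frames
    done("preprocess")

    # -- widefield -----------------------------------------------------------
    stage("widefield")
    wf_movie = synth.render_movie(layout, wf_neurons, contour_set,
                                  n_repeat=cfg.n_repeat, noise_sd=cfg.noise_sd,
                                  motion_amp=0, seed=cfg.seed + 9)
    wf_aligned = preprocess.align(wf_movie.frames, template=wf_movie.baseline_image,
                                  frame_rate=wf_movie.frame_rate,
                                  max_shift=cfg.max_shift)
    wf_maps = preprocess.dff(wf_aligned, wf_movie.trial_table)
    del wf_movie.frames, wf_aligned.frames
    cmap = widefield.category_map(wf_maps, contour_set,
                                  smoothing_sigma=cfg.smoothing_sigma)
    patches = {}
    jac = {}
    for target in ("curve", "corner"):
        patches[target] = widefield.cluster_permutation(
            cmap, target, n_perm=cfg.n_perm, q_threshold=cfg.q_threshold,
            alpha_uncorrected=cfg.alpha_uncorrected, tail_fraction=cfg.tail_fraction,
            downsample=cfg.perm_downsample, seed=cfg.seed + 4)
        jac[target] = widefield.jaccard(patches[target].patch_mask,
                                        layout.domain_masks[target])
    done("widefield")

    # -- cellmap -------------------------------------------------------------
    stage("cellmap")
    rois = cellmap.segment(maps, sigma_small=cfg.bandpass_sigmas[0],
                           sigma_large=cfg.bandpass_sigmas[1], sd_factor=cfg.sd_factor,
                           min_area=cfg.min_area, max_roundness=cfg.max_roundness,
                           min_max_dff=cfg.min_max_dff)
    table = cellmap.build_neuron_table(rois, maps, aligned=aligned,
                                       micron_per_px=cfg.micron_per_px)
    gtable = cellmap.build_neuron_table(rois, gmaps, micron_per_px=cfg.micron_per_px)
    done("cellmap")

    # -- selectivity ---------------------------------------------------------
    stage("selectivity")
    positions = np.array([roi.centroid_um(cfg.micron_per_px) for roi in rois]) \
        if rois else np.zeros((0, 2))
    profiles = selectivity.compute_profiles(table, contour_set,
                                            positions_um=positions,
                                            grating_table=gtable,
                                            grating_set=grating_set)
    done("selectivity")

    # -- spatialstats --------------------------------------------------------
    stage("spatialstats")
    pairs = spatialstats.pair_table(profiles, table, contour_set)
    dprofiles = {}
    for statname in ("tuning_corr", "abs_dCVSI", "abs_dCNSI"):
        dprofiles[statname] = spatialstats.permutation_significance(
            pairs, statname, bin_um=cfg.bin_um, n_shuffle=cfg.n_shuffle,
            seed=cfg.seed + 5)
    done("spatialstats")

    # -- population ----------------------------------------------------------
    stage("population")
    rmat = population.build_matrix(table, contour_set)
    form_clusters = population.kmeans_select(
        rmat.RP, range(cfg.k_range_forms[0], cfg.k_range_forms[1] + 1),
        n_restart=cfg.kmeans_restarts, max_iter=cfg.kmeans_max_iter, seed=cfg.seed + 6)
    neuron_clusters = population.kmeans_select(
        rmat.RN, range(cfg.k_range_neurons[0],
                       min(cfg.k_range_neurons[1], len(rmat.neuron_ids) - 1) + 1),
        n_restart=cfg.kmeans_restarts, max_iter=cfg.kmeans_max_iter, seed=cfg.seed + 7)
    D = population.form_dissimilarity(rmat.R)
    mds = population.classical_mds(D, dim=2)
    done("population")

    result = PipelineResult(config=cfg, out_dir=out, layout=layout, neurons=neurons,
                            patches=patches, rois=rois, profiles=profiles, pairs=pairs,
                            distance_profiles=dprofiles, response_matrix=rmat,
                            form_clusters=form_clusters, neuron_clusters=neuron_clusters,
                            mds=mds, jaccard=jac, timings=timings)
    if out is not None:
        _write_outputs(result, contour_set)
    log.info("pipeline finished in %.1f s", time.time() - t_all)
    return result


def _write_outputs(res: PipelineResult, contour_set: stimgen.StimulusSet) -> None:
    out = res.out_dir
    assert out is not None
    contour_set.manifest().to_csv(out / "stimuli.csv", index=False)
    truth = pd.DataFrame([{
        "row": n.position[0], "col": n.position[1], "preferred_class": n.preferred_class,
        "preferred_orientation": n.preferred_orientation, "class_bias": n.class_bias,
        "peak_dff": n.peak_dff} for n in res.neurons])
    truth.to_csv(out / "truth_neurons.csv", index=False)
    for target, patch in res.patches.items():
        _write_mask(out / f"patch_{target}.tif", patch.patch_mask)
        pd.DataFrame([{"cluster_id": c["id"], "size_px": c["size"],
                       "centroid_row": c["centroid"][0], "centroid_col": c["centroid"][1],
                       "category": target} for c in patch.clusters]
                     ).to_csv(out / f"clusters_{target}.csv", index=False)
        pd.DataFrame({"max_cluster_size": patch.null_max_sizes}).to_csv(
            out / f"null_{target}.csv", index=False)
    res.profiles.to_csv(out / "profiles.csv")
    res.pairs.to_csv(out / "pairs.csv", index=False)
    for name, dp in res.distance_profiles.items():
        dp.to_csv(out / f"distance_profile_{name}.csv", index=False)
    pd.DataFrame(res.response_matrix.R, index=res.response_matrix.form_ids,
                 columns=res.response_matrix.neuron_ids).to_csv(out / "response_matrix.csv")
    pd.DataFrame({"form_id": res.response_matrix.form_ids,
                  "cluster": res.form_clusters.assignments}).to_csv(
        out / "form_clusters.csv", index=False)
    pd.DataFrame(res.mds.coords, index=res.response_matrix.form_ids,
                 columns=["dim1", "dim2"]).to_csv(out / "mds_coords.csv")
    manifest = {
        "config_hash": res.config.config_hash,
        "seed": res.config.seed,
        "timings_s": {k: round(v, 3) for k, v in res.timings.items()},
        "jaccard": res.jaccard,
        "n_rois": len(res.rois),
        "form_k": res.form_clusters.k,
        "neuron_k": res.neuron_clusters.k,
        "mds_stress": res.mds.stress,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
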
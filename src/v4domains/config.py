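"""Pipeline configuration with the experiment's published defaults.

Every threshold the source experiment states is the default here: display
smoothing sigma 10 px, FDR q = 0.01, 60,000 cluster permutations at
uncorrected alpha = 0.01 with a 5% tail, ROI area > 25 px, roundness
C < 1.1, max dF/F0 >= 0.3, |index| > 0.2 selectivity flag, 100 um distance
bins, 100,000 pair shuffles, 10,000 K-means restarts with 10,000 iterations,
10 repeats per stimulus.  ``reduced()`` returns a desk-scale variant
(permutations and restarts cut down) for demos and continuous testing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    protocol: str = "map16x"
    seed: int = 0

    # synthetic data: soma coverage kept near 10% of the field, as in
    # single-cell-resolution imaging
    canvas: tuple[int, int] = (160, 160)
    n_domains: int = 2
    domain_radius: float = 30.0
    n_neurons: int = 100
    soma_radius: float = 4.0
    # dense widefield-style population (domain detection); emulates the
    # quasi-continuous signal of low-power imaging over the same layout
    wf_n_neurons: int = 600
    wf_soma_radius: float = 3.0
    n_repeat: int = 10
    noise_sd: float = 1.0
    motion_amp: int = 0
    micron_per_px: float = 1.7

    # preprocessing
    max_shift: int = 10

    # widefield statistics
    smoothing_sigma: float = 10.0
    q_threshold: float = 0.01
    alpha_uncorrected: float = 0.01
    n_perm: int = 60000
    tail_fraction: float = 0.05
    perm_downsample: int = 4

    # ROI segmentation
    bandpass_sigmas: tuple[float, float] = (2.0, 5.0)
    sd_factor: float = 3.0
    min_area: int = 25
    max_roundness: float = 1.1
    min_max_dff: float = 0.3

    # selectivity / spatial stats
    index_flag: float = 0.2
    bin_um: float = 100.0
    n_shuffle: int = 100000

    # population
    kmeans_restarts: int = 10000
    kmeans_max_iter: int = 10000
    k_range_forms: tuple[int, int] = (2, 8)
    k_range_neurons: tuple[int, int] = (2, 10)

    out_dir: str = "runs"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0 < self.q_threshold < 1:
            raise ValueError("q_threshold must lie in (0, 1)")
        if not 0 < self.alpha_uncorrected < 1:
            raise ValueError("alpha_uncorrected must lie in (0, 1)")
        if not 0 < self.tail_fraction < 1:
            raise ValueError("tail_fraction must lie in (0, 1)")
        if self.n_perm < 1 or self.n_shuffle < 1 or self.n_repeat < 1:
            raise ValueError("counts must be positive")
        if self.bandpass_sigmas[0] >= self.bandpass_sigmas[1]:
            raise ValueError("bandpass sigmas must be increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def reduced(self) -> "PipelineConfig":
        """Desk-scale variant: same thresholds, reduced permutation counts."""
        return dataclasses.replace(self, n_perm=500, n_shuffle=2000,
                                   kmeans_restarts=50, kmeans_max_iter=300)

    @classmethod
    def demo(cls, seed: int = 0) -> "PipelineConfig":
        """One-command end-to-end demo sized to finish in minutes on one CPU."""
        return cls(seed=seed, canvas=(128, 128), n_domains=2, domain_radius=26.0,
                   n_neurons=120, soma_radius=4.0, wf_n_neurons=450,
                   wf_soma_radius=3.0, n_repeat=5, noise_sd=1.5,
                   smoothing_sigma=5.0, n_perm=300, perm_downsample=2,
                   n_shuffle=2000, kmeans_restarts=50, kmeans_max_iter=300,
                   bin_um=60.0)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("canvas", "bandpass_sigmas", "k_range_forms", "k_range_neurons"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("canvas", "bandpass_sigmas", "k_range_forms", "k_range_neurons"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def load_config(path: str | Path) -> PipelineConfig:
    return PipelineConfig.from_dict(yaml.safe_load(Path(path).read_text()))
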
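"""Population analysis: response matrix, K-means clustering, classical MDS.

The response matrix R (forms x neurons) holds r_{i,j}, the response of
neuron j to stimulus form i, taking only the maximum over a form's eight
orientations.  Under the single-cell contour protocol R has 20 rows (two
bars, eight curves, six corners, four Pi-shapes).  Rows (RP, population
response vectors) cluster the forms; columns (RN, neuron response vectors)
cluster the neurons.  The cluster count is selected by the Calinski-Harabasz
criterion over a candidate range, each k fit by best-of-restarts K-means
with squared Euclidean distance.

Classical MDS embeds the form dissimilarity D_{i,j} = 1 - corrcoef(RP_i,
RP_j) by double-centering and eigendecomposition; the normalized stress is
sum((D - D')^2) / sum(D^2) with D' the embedded pairwise distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score

from .stimgen import StimulusSet

__all__ = ["ResponseMatrix", "ClusteringResult", "MDSResult",
           "build_matrix", "kmeans_select", "classical_mds", "form_dissimilarity"]

CONTOUR_FAMILIES = ("bar", "curve", "corner", "pi_shape")


@dataclass
class ResponseMatrix:
    R: np.ndarray  # (forms, neurons)
    form_ids: list[str]
    neuron_ids: list[int]

    @property
    def RP(self) -> np.ndarray:
        """Population response vectors (rows; one per form)."""
        return self.R

    @property
    def RN(self) -> np.ndarray:
        """Neuron response vectors (columns transposed; one per neuron)."""
        return self.R.T


@dataclass
class ClusteringResult:
    k: int
    assignments: np.ndarray
    centroids: np.ndarray
    inertia: float  # within-cluster sum of squared distances
    ch_scores: dict[int, float]
    n_restart: int
    max_iter: int
    seed: int


@dataclass
class MDSResult:
    D: np.ndarray
    coords: np.ndarray
    D_embedded: np.ndarray
    stress: float
    eigenvalues: np.ndarray
    negative_mass: float  # |sum of negative eigenvalues| / sum of positive


def build_matrix(neuron_table: pd.DataFrame, stimulus_set: StimulusSet,
                 families: tuple[str, ...] = CONTOUR_FAMILIES) -> ResponseMatrix:
    """Forms x neurons matrix of orientation-collapsed maximal responses."""
    means = neuron_table.pivot_table(index="neuron_id", columns="stim_id",
                                     values="response", aggfunc="mean")
    fam_ids = set(stimulus_set.ids_in_category(families))
    forms = [f for f in stimulus_set.forms
             if stimulus_set.ids_in_form(f)[0] in fam_ids]
    neuron_ids = sorted(means.index)
    R = np.empty((len(forms), len(neuron_ids)))
    for i, form in enumerate(forms):
        sids = stimulus_set.ids_in_form(form)
        missing = [s for s in sids if s not in means.columns]
        if missing:
            raise ValueError(f"form {form}: stimuli {missing} missing from responses")
        R[i] = means.loc[neuron_ids, sids].max(axis=1).to_numpy()
    return ResponseMatrix(R=R, form_ids=forms, neuron_ids=neuron_ids)


def kmeans_select(vectors: np.ndarray, k_range: range | list[int] = range(2, 9), *,
                  n_restart: int = 10000, max_iter: int = 10000,
                  seed: int = 0) -> ClusteringResult:
    """Best-of-restarts K-means per k; final k maximizes Calinski-Harabasz.

    Each restart draws new initial centroids uniformly from the data points;
    the restart with the lowest within-cluster sum of squares wins.
    """
    X = np.asarray(vectors, dtype=float)
    n = len(X)
    ks = [k for k in k_range]
    if any(k < 2 or k > n - 1 for k in ks):
        raise ValueError("k_range must lie within [2, n_items - 1]")
    ch: dict[int, float] = {}
    fits: dict[int, KMeans] = {}
    for k in ks:
        km = KMeans(n_clusters=k, init="random", n_init=n_restart,
                    max_iter=max_iter, algorithm="lloyd", random_state=seed)
        km.fit(X)
        fits[k] = km
        ch[k] = float(calinski_harabasz_score(X, km.labels_))
    best_k = max(ch, key=lambda k: (ch[k], -k))
    km = fits[best_k]
    return ClusteringResult(k=best_k, assignments=km.labels_.copy(),
                            centroids=km.cluster_centers_.copy(),
                            inertia=float(km.inertia_), ch_scores=ch,
                            n_restart=n_restart, max_iter=max_iter, seed=seed)


def form_dissimilarity(R: np.ndarray) -> np.ndarray:
    """D_{i,j} = 1 - Pearson correlation of population response vectors."""
    with np.errstate(invalid="ignore"):
        c = np.corrcoef(R)
    D = 1.0 - c
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def classical_mds(D: np.ndarray, dim: int = 2, *,
                  neg_tolerance: float = 0.2) -> MDSResult:
    """Classical (Torgerson) MDS of a symmetric dissimilarity matrix.

    The squared dissimilarities are double-centered (B = -1/2 J D^2 J) and
    eigendecomposed; coordinates use the top ``dim`` eigenpairs with
    negative eigenvalues truncated to zero.  1-correlation dissimilarities
    are generally non-Euclidean, so some negative eigenvalue mass is
    expected; a mass beyond ``neg_tolerance`` is recorded in the result (the
    ``negative_mass`` field) rather than raised.
    """
    D = np.asarray(D, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("D must be square and symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("D must have a zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = np.clip(evals[:dim], 0.0, None)
    coords = evecs[:, :dim] * np.sqrt(pos)
    D_emb = squareform(pdist(coords))
    denom = float(np.sum(D ** 2))
    stress = float(np.sum((D - D_emb) ** 2) / denom) if denom > 0 else 0.0
    pos_mass = float(evals[evals > 0].sum())
    neg_mass = float(-evals[evals < 0].sum()) / pos_mass if pos_mass > 0 else 0.0
    return MDSResult(D=D, coords=coords, D_embedded=D_emb, stress=stress,
                     eigenvalues=evals, negative_mass=neg_mass)
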
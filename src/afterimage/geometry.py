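"""Similarity structure of population responses.

The central quantities of the analysis: Pearson correlation between
population activity vectors (time bin by time bin, or between trial- and
time-averaged period vectors), angular separation between vectors, a
random-vector null for the angle distributions, PCA trajectories, and
complete-linkage clustering on angular distance.

A pair of baseline-subtracted vectors with Pearson correlation below zero
separates by more than 90 degrees; ON/OFF anticorrelation therefore reads
out as ON-OFF angles above orthogonality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .preprocess import BinnedResponse

__all__ = [
    "CorrelationMatrix",
    "AngleSet",
    "pearson",
    "timebin_correlation",
    "period_correlation",
    "angle_between",
    "angle_distributions",
    "reference_angles",
    "random_vector_null",
    "pca_trajectory",
    "cluster_angular",
    "linkage_to_newick",
]


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson matrix over time bins or (odor, period) labels.

    Entries for zero-variance vectors are NaN (undefined, excluded from
    summaries) rather than coerced to 0.
    """

    values: np.ndarray
    row_index: list
    col_index: list
    kind: str  # "timebin" or "period"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and np.abs(finite).max() > 1 + 1e-8:
            raise ValueError("correlation entries must lie in [-1, 1]")


@dataclass
class AngleSet:
    """Angular separations (degrees, [0, 180]) for one comparison group."""

    angles_deg: np.ndarray
    group: str  # ON_ON, ON_OFF, OFF_OFF, RANDOM, REF_ON, REF_OFF
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.angles_deg.size and (
            self.angles_deg.min() < -1e-9 or self.angles_deg.max() > 180 + 1e-9
        ):
            raise ValueError("angles must lie in [0, 180] degrees")

    def median(self) -> float:
        return float(np.median(self.angles_deg))


def pearson(v: np.ndarray, w: np.ndarray) -> float:
    """Pearson correlation across units; NaN if either vector has zero variance."""
    v = np.asarray(v, float)
    w = np.asarray(w, float)
    vc = v - v.mean()
    wc = w - w.mean()
    sv = np.sqrt(vc @ vc)
    sw = np.sqrt(wc @ wc)
    if sv == 0 or sw == 0:
        return float("nan")
    return float(np.clip(vc @ wc / (sv * sw), -1.0, 1.0))


def _rowwise_pearson(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    na = np.linalg.norm(Ac, axis=1)
    nb = np.linalg.norm(Bc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = (Ac @ Bc.T) / np.outer(na, nb)
    C[np.outer(na == 0, np.ones(len(nb), bool))] = np.nan
    C[np.outer(np.ones(len(na), bool), nb == 0)] = np.nan
    return np.clip(C, -1.0, 1.0, out=C)


def timebin_correlation(binned_a: BinnedResponse,
                        binned_b: BinnedResponse) -> CorrelationMatrix:
    """Entry (i, j) = Pearson correlation across units between time bin i of
    one period and time bin j of another (covariance over the product of the
    two bins' standard deviations)."""
    if binned_a.units != binned_b.units:
        raise ValueError("unit order must match between the two matrices")
    if binned_a.baseline_subtracted != binned_b.baseline_subtracted:
        raise ValueError("inconsistent baseline handling")
    C = _rowwise_pearson(binned_a.values, binned_b.values)
    rows = [f"{binned_a.window}:{i}" for i in range(binned_a.n_bins)]
    cols = [f"{binned_b.window}:{j}" for j in range(binned_b.n_bins)]
    return CorrelationMatrix(C, rows, cols, kind="timebin")


def period_correlation(
    vectors: Mapping[tuple[str, str], np.ndarray]
) -> CorrelationMatrix:
    """All-pairs Pearson matrix over (odor, period) time-averaged vectors."""
    labels = list(vectors)
    M = np.vstack([np.asarray(vectors[k], float) for k in labels])
    C = _rowwise_pearson(M, M)
    return CorrelationMatrix(C, labels, list(labels), kind="period")


def angle_between(v: np.ndarray, w: np.ndarray) -> float:
    """Angle in degrees between two non-zero vectors, clamped to [0, 180]."""
    v = np.asarray(v, float)
    w = np.asarray(w, float)
    nv = np.linalg.norm(v)
    nw = np.linalg.norm(w)
    if nv == 0 or nw == 0:
        raise ValueError("angle undefined for a zero vector")
    c = np.clip(v @ w / (nv * nw), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def _pairwise_angles(A: np.ndarray, B: np.ndarray | None = None,
                     centering: str = "none") -> np.ndarray:
    """Angles for unordered distinct row pairs of A, or all A x B row pairs."""
    if centering == "per_vector":
        A = A - A.mean(axis=1, keepdims=True)
        if B is not None:
            B = B - B.mean(axis=1, keepdims=True)
    elif centering != "none":
        raise ValueError("centering must be 'none' or 'per_vector'")
    norms_a = np.linalg.norm(A, axis=1)
    if np.any(norms_a == 0):
        raise ValueError("angle undefined for a zero vector")
    Au = A / norms_a[:, None]
    if B is None:
        G = np.clip(Au @ Au.T, -1.0, 1.0)
        iu = np.triu_indices(len(A), k=1)
        return np.degrees(np.arccos(G[iu]))
    norms_b = np.linalg.norm(B, axis=1)
    if np.any(norms_b == 0):
        raise ValueError("angle undefined for a zero vector")
    Bu = B / norms_b[:, None]
    G = np.clip(Au @ Bu.T, -1.0, 1.0)
    return np.degrees(np.arccos(G)).ravel()


def angle_distributions(
    on: BinnedResponse, off: BinnedResponse, centering: str = "per_vector"
) -> tuple[AngleSet, AngleSet, AngleSet]:
    """ON-ON, OFF-OFF and ON-OFF angle distributions for one odor.

    ON-ON covers the C(T_on, 2) unordered distinct ON-bin pairs, OFF-OFF the
    C(T_off, 2) OFF-bin pairs, ON-OFF all T_on x T_off ordered cross pairs
    (80 bins per period gives 3160, 3160 and 6400 comparisons).

    With the default per-vector centering the cosine of each angle equals the
    Pearson correlation between the two population vectors, so angles above
    90 degrees read directly as anticorrelated patterns; ``centering='none'``
    gives plain angles between the baseline-subtracted vectors.
    """
    if on.units != off.units:
        raise ValueError("unit order must match")
    prov = {"odor": on.odor}
    groups = []
    for name, A, B in (("ON_ON", on.values, None),
                       ("OFF_OFF", off.values, None),
                       ("ON_OFF", on.values, off.values)):
        too_few = len(A) < 2 if B is None else min(len(A), len(B)) < 1
        if too_few:
            import warnings

            warnings.warn(f"{name}: too few vectors; empty angle group")
            groups.append(AngleSet(np.zeros(0), name, dict(prov)))
            continue
        groups.append(AngleSet(_pairwise_angles(A, B, centering), name,
                               dict(prov)))
    return tuple(groups)


def reference_angles(
    vectors: Mapping[tuple[str, str], np.ndarray],
    reference_odor: str,
    include_reference: bool = True,
    centering: str = "per_vector",
) -> tuple[AngleSet, AngleSet]:
    """Angles between a reference odor's ON vector and every odor's ON and
    OFF vectors (the polar-plot comparison of odor-space structure).

    ``include_reference`` keeps the reference odor's own vectors in the two
    groups (its ON contributes a 0-degree angle); both inclusion rules are
    in use, so the knob is explicit.
    """
    ref = np.asarray(vectors[(reference_odor, "ON")], float)
    if centering == "per_vector":
        ref = ref - ref.mean()

    def group(period: str) -> AngleSet:
        angles = []
        for (odor, per), v in vectors.items():
            if per != period:
                continue
            if not include_reference and odor == reference_odor:
                continue
            v = np.asarray(v, float)
            if centering == "per_vector":
                v = v - v.mean()
            angles.append(angle_between(ref, v))
        return AngleSet(np.array(angles), f"REF_{period}",
                        {"reference": reference_odor})

    return group("ON"), group("OFF")


def random_vector_null(n_dims: int, n_pairs: int = 10_000,
                       rng: int | np.random.Generator = 0) -> AngleSet:
    """Angles between pairs of independent standard-normal vectors.

    The control distribution for the angle analysis: in high dimension it
    concentrates around 90 degrees, with spread shrinking as ~1/sqrt(n_dims).
    """
    if n_dims < 2:
        raise ValueError("n_dims must be >= 2")
    gen = np.random.default_rng(rng)
    V = gen.standard_normal((n_pairs, n_dims))
    W = gen.standard_normal((n_pairs, n_dims))
    cos = np.einsum("ij,ij->i", V, W) / (
        np.linalg.norm(V, axis=1) * np.linalg.norm(W, axis=1)
    )
    ang = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
    return AngleSet(ang, "RANDOM", {"n_dims": n_dims})


def pca_trajectory(
    observations: np.ndarray | BinnedResponse, n_components: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Project observations (rows) onto the top eigenvectors of their
    covariance matrix.

    Returns (projected coordinates, explained-variance fractions).  If the
    data have lower rank than requested, fewer components are returned with
    a warning.  Component signs are fixed by forcing the largest-magnitude
    loading of each component positive, so orientations are reproducible.
    """
    X = observations.values if isinstance(observations, BinnedResponse) else observations
    X = np.asarray(X, float)
    if X.shape[0] < n_components:
        raise ValueError("need at least n_components observations")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    k = min(n_components, int(rank)) or 1
    if k < n_components:
        import warnings

        warnings.warn(f"data rank {rank} < {n_components}; returning {k} components")
    pca = PCA(n_components=k, svd_solver="full")
    proj = pca.fit_transform(X)
    flip = np.sign(
        pca.components_[np.arange(k), np.abs(pca.components_).argmax(axis=1)]
    )
    flip[flip == 0] = 1.0
    return proj * flip[None, :], pca.explained_variance_ratio_


def cluster_angular(
    vectors: Mapping[str, np.ndarray], centering: str = "per_vector"
) -> tuple[np.ndarray, list[str]]:
    """Complete-linkage agglomerative clustering on angular distance.

    Merges are chosen so the furthest pairwise angle between any two members
    of a cluster is minimized.  Returns the scipy linkage matrix and the leaf
    labels in input order.
    """
    labels = list(vectors)
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate labels")
    if len(labels) < 2:
        raise ValueError("need at least 2 labeled vectors")
    M = np.vstack([np.asarray(vectors[k], float) for k in labels])
    if centering == "per_vector":
        M = M - M.mean(axis=1, keepdims=True)
    D = squareform(_angle_matrix(M), checks=False)
    Z = linkage(D, method="complete")
    return Z, labels


def _angle_matrix(M: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(M, axis=1)
    if np.any(norms == 0):
        raise ValueError("angle undefined for a zero vector")
    U = M / norms[:, None]
    G = np.clip(U @ U.T, -1.0, 1.0)
    A = np.degrees(np.arccos(G))
    np.fill_diagonal(A, 0.0)
    return A


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: labels[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = h - heights[a]
        lb = h - heights[b]
        nodes[n + k] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + k] = h
    return nodes[n + len(Z) - 1] + ";"
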
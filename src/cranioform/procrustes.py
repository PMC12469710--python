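"""Generalized Procrustes superimposition, shape PCA, and permutation tests.

Specimens are placed into a common shape space by centering each landmark
configuration on its centroid, scaling it to unit centroid size, and
rotating it to a consensus with the least-squares optimal proper rotation
(reflections are disallowed: anatomical landmark configurations are
chiral). The consensus is re-estimated iteratively until it stops moving
(full Generalized Procrustes Analysis).

Downstream: PCA of the aligned coordinates about the consensus; pairwise
Procrustes-distance permutation tests between group consensus shapes; and
an integrative ordination across several cohorts using each specimen's
size-standardized pairwise-distance vector as its feature vector. The
latter pair of analyses serves the role a canonical variate analysis plays
in morphometric software; with ~10 specimens per group the within-group
covariance needed by a true CVA is ill-conditioned, so group separation is
assessed by permutation instead of covariance whitening.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .edma import pairwise_distance_vector, scale_to_shape
from .io import LandmarkConfiguration, SpecimenSet


class ProcrustesError(ValueError):
    pass


class GpaConvergenceError(RuntimeError):
    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


def centroid_size(coords: np.ndarray) -> float:
    """Root summed squared distances of landmarks to their centroid."""
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt(np.sum(centered**2)))


def _center_and_scale(coords: np.ndarray) -> tuple[np.ndarray, float]:
    centered = coords - coords.mean(axis=0)
    size = np.sqrt(np.sum(centered**2))
    if size <= 0:
        raise ProcrustesError("configuration has zero centroid size")
    return centered / size, float(size)


def _check_not_collinear(coords: np.ndarray) -> None:
    s = np.linalg.svd(coords - coords.mean(axis=0), compute_uv=False)
    if s[1] < 1e-9 * max(s[0], 1e-300):
        raise ProcrustesError(
            "landmarks are collinear; the optimal rotation is ambiguous"
        )


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ||target - source @ R|| (no reflection)."""
    u, _, vt = np.linalg.svd(source.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    u[:, -1] *= d
    return u @ vt


def _coords_of(obj) -> np.ndarray:
    if isinstance(obj, LandmarkConfiguration):
        return obj.coords
    return np.asarray(obj, dtype=float)


def align_pair(
    a: LandmarkConfiguration | np.ndarray, b: LandmarkConfiguration | np.ndarray
) -> tuple[np.ndarray, float]:
    """Superimpose configuration ``b`` onto ``a`` (full Procrustes).

    Both are centered and scaled to unit centroid size; ``b`` is then
    rotated (proper rotation only) to minimize the summed squared
    coordinate differences. Returns the aligned copy of ``b`` and the
    Procrustes distance (root summed squared residual after alignment).
    """
    ca = _coords_of(a)
    cb = _coords_of(b)
    if isinstance(a, LandmarkConfiguration) and isinstance(b, LandmarkConfiguration):
        if a.landmark_names != b.landmark_names:
            raise ProcrustesError("landmark names/order differ between configurations")
    if ca.shape != cb.shape:
        raise ProcrustesError(f"shape mismatch: {ca.shape} vs {cb.shape}")
    _check_not_collinear(ca)
    _check_not_collinear(cb)
    xa, _ = _center_and_scale(ca)
    xb, _ = _center_and_scale(cb)
    if np.array_equal(xa, xb):  # identical shapes: skip the rotation entirely
        return xb.copy(), 0.0
    rot = _optimal_rotation(xb, xa)
    aligned = xb @ rot
    distance = float(np.sqrt(np.sum((xa - aligned) ** 2)))
    return aligned, distance


def procrustes_distance(a, b) -> float:
    """Procrustes distance between two configurations (see :func:`align_pair`)."""
    return align_pair(a, b)[1]


@dataclass
class GpaResult:
    """Superimposed coordinates with per-specimen metadata."""

    aligned: np.ndarray  # (n, K, 3): centered, unit centroid size, rotated
    centroid_sizes: np.ndarray  # (n,)
    consensus: np.ndarray  # (K, 3), coordinate-wise mean of aligned
    iterations: int
    final_change: float
    specimen_ids: tuple[str, ...]
    groups: tuple[str, ...]
    landmark_names: tuple[str, ...]
    trace: list[float] = field(default_factory=list)

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]


def gpa(
    specimens: SpecimenSet | Sequence[LandmarkConfiguration],
    tol: float = 1e-8,
    max_iter: int = 100,
) -> GpaResult:
    """Generalized Procrustes Analysis of a cohort.

    Each specimen is centered and scaled to unit centroid size; all are
    then iteratively rotated to the running consensus (seeded by the first
    specimen, so the result is deterministic given input order) and the
    consensus re-estimated as the coordinate-wise mean, until it moves by
    less than ``tol`` (Frobenius norm).
    """
    configs = (
        list(specimens.configurations) if isinstance(specimens, SpecimenSet) else list(specimens)
    )
    if len(configs) < 2:
        raise ProcrustesError("GPA needs at least 2 specimens")
    coords = [c.coords for c in configs]
    shapes = []
    sizes = []
    for c in coords:
        _check_not_collinear(c)
        x, s = _center_and_scale(c)
        shapes.append(x)
        sizes.append(s)
    shapes = np.stack(shapes)
    consensus = shapes[0].copy()
    trace: list[float] = []
    change = np.inf
    for iteration in range(1, max_iter + 1):
        for i in range(shapes.shape[0]):
            rot = _optimal_rotation(shapes[i], consensus)
            shapes[i] = shapes[i] @ rot
        new_consensus = shapes.mean(axis=0)
        change = float(np.linalg.norm(new_consensus - consensus))
        trace.append(change)
        consensus = new_consensus
        if change < tol:
            break
    else:
        raise GpaConvergenceError(
            f"GPA did not converge in {max_iter} iterations (last change {change:.3g})",
            trace,
        )
    return GpaResult(
        aligned=shapes,
        centroid_sizes=np.array(sizes),
        consensus=consensus,
        iterations=iteration,
        final_change=change,
        specimen_ids=tuple(c.specimen_id for c in configs),
        groups=tuple(c.group for c in configs),
        landmark_names=tuple(configs[0].landmark_names),
        trace=trace,
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    """Principal components of shape (or distance-feature) variation."""

    scores: np.ndarray  # (n, r)
    loadings: np.ndarray  # (r, p)
    variance_fraction: np.ndarray  # (r,), non-increasing, sums to 1
    n_components: int
    sample_info: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.scores, columns=[f"PC{i + 1}" for i in range(self.n_components)]
        )
        if self.sample_info is not None:
            df = pd.concat([self.sample_info.reset_index(drop=True), df], axis=1)
        return df


def _pca(data: np.ndarray, center: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    centered = data - (data.mean(axis=0) if center is None else center)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # deterministic sign: largest-magnitude loading element is positive
    for i in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
            u[:, i] = -u[:, i]
    total = float(np.sum(s**2))
    keep = s > max(s[0] if s.size else 0.0, 1e-300) * 1e-12
    scores = (u[:, keep] * s[keep])
    return scores, vt[keep], (s[keep] ** 2) / total


def shape_pca(result: GpaResult) -> PcaResult:
    """PCA of the aligned coordinates about the Procrustes consensus."""
    if result.n_specimens < 2:
        raise ProcrustesError("PCA needs at least 2 specimens")
    n, k, _ = result.aligned.shape
    flat = result.aligned.reshape(n, k * 3)
    scores, loadings, var_frac = _pca(flat, center=result.consensus.reshape(-1))
    info = pd.DataFrame(
        {"specimen_id": result.specimen_ids, "group": result.groups}
    )
    return PcaResult(
        scores=scores,
        loadings=loadings,
        variance_fraction=var_frac,
        n_components=scores.shape[1],
        sample_info=info,
    )


# ---------------------------------------------------------------------------
# Procrustes-distance permutation test
# ---------------------------------------------------------------------------

@dataclass
class PermutationTestMatrix:
    """Pairwise group comparison by Procrustes distance between consensus shapes."""

    groups: tuple[str, ...]
    observed_distance: pd.DataFrame  # symmetric, zero diagonal
    p_values: pd.DataFrame
    n_perm: int
    seed: int | None


def _group_consensus_distance(aligned: np.ndarray, mask: np.ndarray) -> float:
    mean_a = aligned[mask].mean(axis=0)
    mean_b = aligned[~mask].mean(axis=0)
    return procrustes_distance(mean_a, mean_b)


def group_permutation_test(
    result: GpaResult,
    labels: Sequence[str] | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
) -> PermutationTestMatrix:
    """Pairwise permutation tests of group mean-shape differences.

    For each pair of groups the observed statistic is the Procrustes
    distance between the two group consensus shapes (means of the aligned
    coordinates). The null is generated by shuffling group labels within
    the pair; p = (#{null >= observed} + 1) / (n_perm + 1).
    """
    labels = tuple(labels) if labels is not None else result.groups
    if len(labels) != result.n_specimens:
        raise ProcrustesError("one label per specimen is required")
    label_arr = np.asarray(labels)
    group_names: list[str] = []
    for g in labels:
        if g not in group_names:
            group_names.append(g)
    if len(group_names) < 2:
        raise ProcrustesError("need at least 2 groups")
    for g in group_names:
        if np.sum(label_arr == g) < 2:
            raise ProcrustesError(f"group {g!r} has fewer than 2 specimens")

    rng = np.random.default_rng(seed)
    k = len(group_names)
    dist = np.zeros((k, k))
    pval = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            sel = (label_arr == group_names[i]) | (label_arr == group_names[j])
            sub = result.aligned[sel]
            mask = label_arr[sel] == group_names[i]
            observed = _group_consensus_distance(sub, mask)
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(mask)
                if _group_consensus_distance(sub, perm) >= observed:
                    count += 1
            p = (count + 1) / (n_perm + 1)
            dist[i, j] = dist[j, i] = observed
            pval[i, j] = pval[j, i] = p
    names = list(group_names)
    return PermutationTestMatrix(
        groups=tuple(names),
        observed_distance=pd.DataFrame(dist, index=names, columns=names),
        p_values=pd.DataFrame(pval, index=names, columns=names),
        n_perm=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Integrative distance-feature PCA across several cohorts
# ---------------------------------------------------------------------------

def integrative_distance_pca(
    sets: Sequence[tuple[str, SpecimenSet]] | dict[str, SpecimenSet],
) -> PcaResult:
    """Joint ordination of several cohorts in pairwise-distance space.

    Each specimen contributes its size-standardized pairwise-distance
    vector (unit geometric mean); a single PCA is computed across all
    specimens of all cohorts. Scores are labeled by cohort (model) and
    genotype group in ``sample_info``, so dosage models sharing an
    implanted regional effect cluster together regardless of coordinate
    system or overall size.
    """
    items = list(sets.items()) if isinstance(sets, dict) else list(sets)
    if not items:
        raise ProcrustesError("no cohorts given")
    inventory = items[0][1].landmark_names
    features = []
    info_rows = []
    for label, specimen_set in items:
        if specimen_set.landmark_names != inventory:
            raise ProcrustesError(
                f"cohort {label!r} uses a different landmark inventory"
            )
        for config in specimen_set.configurations:
            fm = scale_to_shape(pairwise_distance_vector(config))
            features.append(fm.distances)
            info_rows.append(
                {"model": label, "specimen_id": config.specimen_id, "group": config.group}
            )
    data = np.array(features)
    scores, loadings, var_frac = _pca(data)
    return PcaResult(
        scores=scores,
        loadings=loadings,
        variance_fraction=var_frac,
        n_components=scores.shape[1],
        sample_info=pd.DataFrame(info_rows),
    )
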
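"""Low-dimensional manifold analysis of population activity.

PCA is the mean-centered SVD of the units x observations data matrix
(each column one observation: binned spike counts for the biological-style
sessions, hidden-layer activations for the RL agent).  The analysis
focuses on the PC1-PC2 plane, where center-out activity is isomorphic
with the task: eight per-target clusters arranged in the targets' cyclic
order.

Statistics computed here:

* adjacent-centroid angular gaps (their pooled distribution has mean 45
  degrees when the isomorphism holds);
* per-target centroid angular displacement after vs before an imposed
  decoder rotation, and the OLS regression of mean displacement on the
  rotation angle (a slope of -1 is exact compensation);
* per-unit normalized differences of time-averaged activity,
  d_i = (mean_baseline_i - mean_rotated_i) / mean-over-units(mean_baseline);
* absolute cosine similarity of mean activity and of singular-value-scaled
  PC1/PC2 before vs after rotation, with PCA fit separately per condition
  (manifold preservation: similarities near 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ActivityMatrix",
    "PCABasis",
    "CentroidSet",
    "AngularDisplacementResult",
    "SimilarityStats",
    "fit_pca",
    "project",
    "target_centroids",
    "adjacent_centroid_angles",
    "centroid_angular_displacement",
    "regress_displacement",
    "normalized_difference",
    "abs_cosine_similarity",
    "ensure_task_orientation",
    "manifold_preservation_report",
    "compare_group_means",
    "circular_difference_deg",
    "circular_mean_deg",
]


@dataclass
class ActivityMatrix:
    """Units x observations activity with per-observation labels."""

    values: np.ndarray
    target_id: np.ndarray
    condition: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be units x observations")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("activity matrix contains non-finite entries")
        n_obs = self.values.shape[1]
        self.target_id = np.asarray(self.target_id)
        self.condition = np.asarray(self.condition)
        if self.target_id.shape != (n_obs,) or self.condition.shape != (n_obs,):
            raise ValueError("labels must have one entry per observation")

    @classmethod
    def from_spike_counts(cls, m) -> "ActivityMatrix":
        """Adapt a SpikeCountMatrix / RolloutActivations-style object."""
        return cls(
            values=np.asarray(m.counts, dtype=float),
            target_id=m.target_id,
            condition=m.condition,
        )

    def subset(self, condition) -> "ActivityMatrix":
        mask = self.condition == condition
        if not np.any(mask):
            raise ValueError(f"no observations with condition {condition!r}")
        return ActivityMatrix(
            self.values[:, mask], self.target_id[mask], self.condition[mask]
        )


@dataclass
class PCABasis:
    """Orthonormal components (rows), with the mean observation and singular values."""

    mean: np.ndarray
    components: np.ndarray  # n_components x units
    singular_values: np.ndarray

    def __post_init__(self) -> None:
        gram = self.components @ self.components.T
        if not np.allclose(gram, np.eye(len(self.components)), atol=1e-10):
            raise ValueError("components must be orthonormal")
        if np.any(np.diff(self.singular_values) > 1e-12):
            raise ValueError("singular values must be non-increasing")

    def scaled_component(self, i: int) -> np.ndarray:
        """Component i scaled by its singular value (the comparison vector)."""
        return self.singular_values[i] * self.components[i]


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude loading of each component positive."""
    out = components.copy()
    for i, comp in enumerate(out):
        j = int(np.argmax(np.abs(comp)))
        if comp[j] < 0:
            out[i] = -comp
    return out


def fit_pca(matrix: ActivityMatrix, n_components: int = 2) -> PCABasis:
    """Mean-centered SVD of the data matrix; columns are observations."""
    if n_components < 2:
        raise ValueError("n_components must be >= 2")
    x = matrix.values
    n_obs = x.shape[1]
    if n_obs <= n_components:
        raise ValueError("need more observations than components")
    mean = x.mean(axis=1)
    centered = x - mean[:, None]
    if np.allclose(centered, 0.0):
        raise ValueError("activity matrix is constant; PCA undefined")
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    comps = _fix_signs(u[:, :n_components].T)
    return PCABasis(mean=mean, components=comps, singular_values=s[:n_components])


def project(basis: PCABasis, matrix: ActivityMatrix) -> np.ndarray:
    """Scores = components @ (values - mean); shape n_components x observations.

    The basis may have been fit on other data (shared-basis mode).
    """
    if matrix.values.shape[0] != basis.mean.shape[0]:
        raise ValueError("unit dimension of matrix does not match basis")
    return basis.components @ (matrix.values - basis.mean[:, None])


@dataclass
class CentroidSet:
    """Per-target centroids in the PC1-PC2 plane."""

    target_ids: np.ndarray
    centroids: np.ndarray  # n_targets x 2
    condition: str = ""

    @property
    def angles_deg(self) -> np.ndarray:
        """Centroid angles in degrees, in (-180, 180]."""
        a = np.degrees(np.arctan2(self.centroids[:, 1], self.centroids[:, 0]))
        return np.where(a <= -180.0, a + 360.0, a)


def target_centroids(
    scores: np.ndarray,
    target_id: np.ndarray,
    condition: str = "",
    expected_targets=None,
) -> CentroidSet:
    """Mean PC1-PC2 score per target cluster."""
    target_id = np.asarray(target_id)
    targets = (
        np.unique(target_id) if expected_targets is None else np.asarray(expected_targets)
    )
    cents = []
    for t in targets:
        mask = target_id == t
        if mask.sum() < 2:
            raise ValueError(f"target {t!r} has fewer than 2 observations")
        cents.append(scores[0:2, mask].mean(axis=1))
    return CentroidSet(
        target_ids=targets, centroids=np.array(cents), condition=condition
    )


def adjacent_centroid_angles(centroids: CentroidSet) -> np.ndarray:
    """Circular gaps between angularly adjacent centroids (degrees; sum 360)."""
    angles = centroids.angles_deg
    radii = np.linalg.norm(centroids.centroids, axis=1)
    if np.any(radii < 1e-12):
        raise ValueError("centroid at the origin: angle undefined")
    order = np.argsort(angles)
    sorted_ang = angles[order]
    gaps = np.diff(np.concatenate([sorted_ang, [sorted_ang[0] + 360.0]]))
    return gaps


def ensure_task_orientation(
    basis: PCABasis, baseline: ActivityMatrix
) -> PCABasis:
    """Flip PC2 if the baseline target centroids run clockwise.

    The SVD fixes each component only up to sign, so the handedness of the
    PC1-PC2 embedding is arbitrary: a counter-clockwise rotation in intended
    direction can appear clockwise in the plane.  Real subjects keep one
    cortex across sessions, so their embedding orientation is consistent;
    synthetic sessions redraw the population, so we orient each basis to the
    task by requiring the baseline centroids to appear in the targets'
    counter-clockwise cyclic order.
    """
    scores = project(basis, baseline)
    cents = target_centroids(scores, baseline.target_id)
    ang = cents.angles_deg
    # orientation sign of the cyclic order of centroid angles by target id
    signed = np.sum(np.sin(np.deg2rad(np.diff(np.concatenate([ang, ang[:1]])))))
    if signed >= 0:
        return basis
    comps = basis.components.copy()
    comps[1] = -comps[1]
    return PCABasis(
        mean=basis.mean, components=comps, singular_values=basis.singular_values
    )


def circular_difference_deg(after: np.ndarray, before: np.ndarray) -> np.ndarray:
    """(after - before) wrapped to (-180, 180] degrees."""
    d = np.asarray(after, dtype=float) - np.asarray(before, dtype=float)
    d = np.mod(d + 180.0, 360.0) - 180.0
    return np.where(np.isclose(d, -180.0), 180.0, d)


def circular_mean_deg(angles_deg: np.ndarray) -> float:
    """Circular mean of angles in degrees, result in (-180, 180]."""
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    m = np.degrees(np.arctan2(np.mean(np.sin(a)), np.mean(np.cos(a))))
    return float(180.0 if np.isclose(m, -180.0) else m)


@dataclass
class AngularDisplacementResult:
    per_target_deg: np.ndarray
    mean_deg: float
    sd_deg: float


def centroid_angular_displacement(
    before: CentroidSet, after: CentroidSet
) -> AngularDisplacementResult:
    """Per-target circular displacement (after - before) and its circular mean."""
    if not np.array_equal(before.target_ids, after.target_ids):
        raise ValueError("centroid sets cover different target rosters")
    disp = circular_difference_deg(after.angles_deg, before.angles_deg)
    mean = circular_mean_deg(disp)
    sd = float(np.std(circular_difference_deg(disp, np.full_like(disp, mean)), ddof=1))
    return AngularDisplacementResult(per_target_deg=disp, mean_deg=mean, sd_deg=sd)


@dataclass
class DisplacementRegression:
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def regress_displacement(
    mean_displacements_deg: np.ndarray, thetas_deg: np.ndarray
) -> DisplacementRegression:
    """OLS of mean centroid displacement on the imposed rotation (signed degrees)."""
    thetas_deg = np.asarray(thetas_deg, dtype=float)
    y = np.asarray(mean_displacements_deg, dtype=float)
    if np.unique(thetas_deg).size < 3:
        raise ValueError("need at least 3 distinct rotation angles")
    res = stats.linregress(thetas_deg, y)
    return DisplacementRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
    )


def normalized_difference(
    baseline_means: np.ndarray, rotated_means: np.ndarray
) -> np.ndarray:
    """Per-unit difference normalized by the session-mean baseline activity:

    d_i = (b_i - r_i) / ((1/N) * sum_j b_j)
    """
    b = np.asarray(baseline_means, dtype=float)
    r = np.asarray(rotated_means, dtype=float)
    if b.shape != r.shape:
        raise ValueError("baseline and rotated means must have equal unit rosters")
    denom = b.mean()
    if np.isclose(denom, 0.0):
        raise ValueError("session-mean baseline activity is zero")
    return (b - r) / denom


def abs_cosine_similarity(v_before: np.ndarray, v_after: np.ndarray) -> float:
    """|cos| similarity in [0, 1]; sign-invariant as PCA components require."""
    a = np.asarray(v_before, dtype=float).ravel()
    b = np.asarray(v_after, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(min(1.0, abs(a @ b) / (na * nb)))


@dataclass
class SimilarityStats:
    """Before/after comparison for one session pair (separate-basis PCA)."""

    mean_similarity: float
    pc1_similarity: float
    pc2_similarity: float
    mean_normdiff: np.ndarray
    pc1_normdiff: np.ndarray
    pc2_normdiff: np.ndarray

    def summary(self, absolute: bool = True) -> dict:
        agg = (lambda d: float(np.mean(np.abs(d)))) if absolute else (
            lambda d: float(np.mean(d))
        )
        return {
            "mean_similarity": self.mean_similarity,
            "pc1_similarity": self.pc1_similarity,
            "pc2_similarity": self.pc2_similarity,
            "mean_normdiff": agg(self.mean_normdiff),
            "pc1_normdiff": agg(self.pc1_normdiff),
            "pc2_normdiff": agg(self.pc2_normdiff),
        }


def _pair_stats(before: ActivityMatrix, after: ActivityMatrix) -> SimilarityStats:
    basis_b = fit_pca(before)
    basis_a = fit_pca(after)
    # normalized differences for the scaled PCs use the baseline scaled-PC
    # absolute loadings in the denominator (extension of the firing-rate form)
    def scaled_normdiff(i: int) -> np.ndarray:
        vb = basis_b.scaled_component(i)
        va = basis_a.scaled_component(i)
        denom = np.abs(vb).mean()
        return (vb - va) / denom

    return SimilarityStats(
        mean_similarity=abs_cosine_similarity(basis_b.mean, basis_a.mean),
        pc1_similarity=abs_cosine_similarity(
            basis_b.scaled_component(0), basis_a.scaled_component(0)
        ),
        pc2_similarity=abs_cosine_similarity(
            basis_b.scaled_component(1), basis_a.scaled_component(1)
        ),
        mean_normdiff=normalized_difference(basis_b.mean, basis_a.mean),
        pc1_normdiff=scaled_normdiff(0),
        pc2_normdiff=scaled_normdiff(1),
    )


def manifold_preservation_report(
    sessions_before: list[ActivityMatrix],
    sessions_after: list[ActivityMatrix],
    mode: str = "separate_basis",
) -> list[SimilarityStats]:
    """Per session pair: PCA before and after, cosine similarities, normalized diffs.

    ``shared_basis`` fits a single PCA on the pooled pair but still compares the
    condition means; ``separate_basis`` (default) is the preservation test.
    """
    if mode not in ("separate_basis", "shared_basis"):
        raise ValueError("mode must be 'separate_basis' or 'shared_basis'")
    if len(sessions_before) != len(sessions_after) or not sessions_before:
        raise ValueError("need >= 1 paired before/after session")
    out = []
    for i, (b, a) in enumerate(zip(sessions_before, sessions_after)):
        try:
            if mode == "separate_basis":
                out.append(_pair_stats(b, a))
            else:
                pooled = ActivityMatrix(
                    np.hstack([b.values, a.values]),
                    np.concatenate([b.target_id, a.target_id]),
                    np.concatenate([b.condition, a.condition]),
                )
                basis = fit_pca(pooled)
                out.append(
                    SimilarityStats(
                        mean_similarity=abs_cosine_similarity(
                            b.values.mean(axis=1), a.values.mean(axis=1)
                        ),
                        pc1_similarity=1.0,
                        pc2_similarity=1.0,
                        mean_normdiff=normalized_difference(
                            b.values.mean(axis=1), a.values.mean(axis=1)
                        ),
                        pc1_normdiff=np.zeros(basis.mean.shape),
                        pc2_normdiff=np.zeros(basis.mean.shape),
                    )
                )
        except ValueError as err:
            raise ValueError(f"PCA failed for session pair {i}: {err}") from err
    return out


def compare_group_means(*groups: np.ndarray) -> tuple[float, float]:
    """One-way ANOVA across groups of normalized differences: (F, p)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if np.asarray(g).size < 2:
            raise ValueError("every group needs at least 2 values")
    f, p = stats.f_oneway(*[np.asarray(g, dtype=float).ravel() for g in groups])
    return float(f), float(p)
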
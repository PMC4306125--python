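"""The registration objective.

The similarity term is the mean of squared intensity differences (SSD)
between the reference frame and the transform-resampled target frame.
The contour term ties the endocardial/epicardial contours of the two
frames together: reference contour points are propagated through the
current transform (they move with the control-point mesh), each target
contour point is matched to its nearest propagated point under a
combined positional + curvature distance

    d(M1, M2) = alpha1 [(x1-x2)^2 + (y1-y2)^2] + alpha2 (k1-k2)^2,

and C_ICP is the *sum* (not the mean) of the matched distances.  The
total objective is ``Cost = C_sim + lambda * C_ICP``; ``lambda = 0``
recovers the plain intensity-driven method.

The weights ``alpha1, alpha2`` are reciprocals of the range (max - min)
of their respective squared terms over all source-target point pairs, so
position and curvature enter the match on comparable scales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .contours import ContourPointSet
from .interp import pixel_grid, resample
from .transforms import HierarchicalTransform

__all__ = [
    "CostConfig",
    "CorrespondenceSet",
    "ssd",
    "feature_distance",
    "compute_alpha_weights",
    "icpif_match",
    "c_icp",
    "total_cost",
]


@dataclass
class CostConfig:
    """Weights of the combined objective.

    lam : weight of the contour term (``lambda`` in the objective); 0
        disables it.  Can be increased for large deformations.
    alpha1, alpha2 : positional / curvature weights of the match
        distance; ``None`` means compute them from the contours at hand.
    recompute_alpha_each_iteration : recompute the alphas from the
        propagated contours at every iteration instead of freezing the
        frame-0 values (default frozen, keeping the objective stationary).
    recompute_curvature : recompute propagated-contour curvatures after
        each propagation (default; deformation changes apparent
        curvature, and matching with stale curvatures biases the
        correspondences toward the wrong material points under large
        contraction).  During optimization the refreshed values are
        frozen within each descent step together with the
        correspondences (standard closest-point majorization), so the
        line search always sees a stationary quadratic.
    curvature_smoothing : half-width of the circular triangular filter
        applied to the propagated contour points before their curvature
        is re-estimated.  A partially converged control grid wiggles the
        contour at scales below its own spacing, and curvature estimated
        from those wiggles is pure noise; 0 disables the filter.
    resample_points : contour point count used in the match term so the
        C_ICP magnitude is comparable across frames.
    """

    lam: float = 1.0
    alpha1: float | None = None
    alpha2: float | None = None
    recompute_alpha_each_iteration: bool = False
    recompute_curvature: bool = True
    curvature_smoothing: int = 3
    gate_radius: float | None = 3.0
    resample_points: int = 64

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        for a in (self.alpha1, self.alpha2):
            if a is not None and a < 0:
                raise ValueError("alpha weights must be non-negative")


@dataclass
class CorrespondenceSet:
    """Target contour points matched to their nearest source points."""

    target_points: np.ndarray      # (N, 2) Q_i
    target_curvatures: np.ndarray  # (N,)
    matched_points: np.ndarray     # (N, 2) q_i, members of the source set
    matched_curvatures: np.ndarray
    matched_indices: np.ndarray    # (N,) index of q_i in the source set

    def __len__(self) -> int:
        return len(self.target_points)


def ssd(reference: np.ndarray, warped_target: np.ndarray) -> float:
    """Mean of squared differences, ``(1/N) sum (A - T(B))^2``."""
    a = np.asarray(reference, dtype=float)
    b = np.asarray(warped_target, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def feature_distance(m1, m2, alpha1: float, alpha2: float):
    """Combined squared positional + curvature distance between point
    triples ``(x, y, k)``; vectorized over leading axes."""
    if alpha1 < 0 or alpha2 < 0:
        raise ValueError("alpha weights must be non-negative")
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    pos = (m1[..., 0] - m2[..., 0]) ** 2 + (m1[..., 1] - m2[..., 1]) ** 2
    feat = (m1[..., 2] - m2[..., 2]) ** 2
    return alpha1 * pos + alpha2 * feat


def _pairwise_terms(source: ContourPointSet, target: ContourPointSet):
    pos = cdist(target.points, source.points, "sqeuclidean")
    feat = (target.curvatures[:, None] - source.curvatures[None, :]) ** 2
    return pos, feat


def compute_alpha_weights(source: ContourPointSet, target: ContourPointSet):
    """Reciprocal-range weights over all source-target pairs.

    ``alpha1 = 1 / range(squared Euclidean term)`` and ``alpha2 = 1 /
    range(squared curvature-difference term)``.  A component with zero
    range carries no information and gets weight 0 with a warning.
    """
    pos, feat = _pairwise_terms(source, target)

    def recip_range(term, name):
        rng = float(term.max() - term.min())
        # a range at floating-point noise level is as uninformative as an
        # exactly zero one and would produce an unbounded weight
        if rng <= 1e-12 * max(float(term.max()), 1e-30):
            warnings.warn(f"{name} term has (near-)zero range over all pairs; "
                          "its weight is set to 0", RuntimeWarning)
            return 0.0
        return 1.0 / rng

    return recip_range(pos, "positional"), recip_range(feat, "curvature")


def icpif_match(source: ContourPointSet, target_current: ContourPointSet,
                alpha1: float, alpha2: float,
                gate_radius: float | None = None) -> CorrespondenceSet:
    """For every target point, exhaustively find the source point with
    minimal combined distance (invariant-feature closest point).

    ``gate_radius`` (pixels) optionally restricts each target point's
    candidates to source points within that Euclidean distance — the
    usual ICP correspondence gate.  The feature then disambiguates among
    positionally plausible candidates instead of being able to override
    position over arbitrary distances.  The plain positional nearest
    neighbour is always kept as a candidate, so no target point is left
    unmatched.
    """
    if len(source) == 0 or len(target_current) == 0:
        raise ValueError("point sets must be non-empty")
    pos, feat = _pairwise_terms(source, target_current)
    d = alpha1 * pos + alpha2 * feat
    if gate_radius is not None:
        gated = np.where(pos <= gate_radius**2, d, np.inf)
        nn = np.argmin(pos, axis=1)
        gated[np.arange(len(nn)), nn] = d[np.arange(len(nn)), nn]
        d = gated
    idx = np.argmin(d, axis=1)
    return CorrespondenceSet(
        target_points=target_current.points.copy(),
        target_curvatures=target_current.curvatures.copy(),
        matched_points=source.points[idx],
        matched_curvatures=source.curvatures[idx],
        matched_indices=idx,
    )


def c_icp(matches: CorrespondenceSet, alpha1: float, alpha2: float) -> float:
    """Sum of combined distances over the matched pairs.  This is a sum,
    not a mean: more contour points mean a proportionally larger term."""
    m1 = np.column_stack([matches.target_points, matches.target_curvatures])
    m2 = np.column_stack([matches.matched_points, matches.matched_curvatures])
    return float(np.sum(feature_distance(m1, m2, alpha1, alpha2)))


def contour_term(transform: HierarchicalTransform,
                 contours_ref: dict, contours_target: dict,
                 config: CostConfig, alphas: dict | None = None) -> float:
    """C_ICP summed over contour labels present in both frames.

    Reference contours are propagated through ``transform`` (with
    curvatures recomputed per config), then each target contour point is
    matched against the propagated set.  ``alphas`` maps label ->
    ``(alpha1, alpha2)``; if absent, weights are computed from the
    unpropagated contour pair (the frozen frame-0 convention).
    """
    total = 0.0
    for label in sorted(set(contours_ref) & set(contours_target)):
        src, tgt = contours_ref[label], contours_target[label]
        if alphas is not None and label in alphas:
            a1, a2 = alphas[label]
        elif config.alpha1 is not None and config.alpha2 is not None:
            a1, a2 = config.alpha1, config.alpha2
        else:
            a1, a2 = compute_alpha_weights(src, tgt)
        moved = src.transformed(transform.apply,
                                recompute_curvature=config.recompute_curvature)
        if config.recompute_alpha_each_iteration:
            a1, a2 = compute_alpha_weights(moved, tgt)
        matches = icpif_match(moved, tgt, a1, a2)
        total += c_icp(matches, a1, a2)
    return total


def total_cost(reference: np.ndarray, target: np.ndarray,
               transform: HierarchicalTransform,
               contours_ref: dict | None = None,
               contours_target: dict | None = None,
               config: CostConfig | None = None,
               prefiltered_target: np.ndarray | None = None) -> float:
    """Combined objective ``C_sim + lambda * C_ICP`` for a given transform.

    ``contours_ref`` / ``contours_target`` map label -> ContourPointSet
    and are optional; with ``lambda = 0`` or no contours the value equals
    the SSD term alone (the original, unmodified method).
    """
    config = config or CostConfig()
    coords = transform.apply(pixel_grid(np.asarray(reference).shape))
    warped, _ = resample(target, coords, prefiltered=prefiltered_target)
    c_sim = ssd(reference, warped)
    if config.lam == 0 or not contours_ref or not contours_target:
        return c_sim
    return c_sim + config.lam * contour_term(transform, contours_ref,
                                             contours_target, config)
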
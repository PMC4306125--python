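"""Hierarchical registration engine.

Every frame of a cine sequence is registered directly to the
end-diastolic reference frame (frame 0), never by accumulating pairwise
registrations, so errors do not pile up along the cycle.  Each frame is
solved in two stages:

1. ``register_global`` — gradient descent over the four affine
   parameters (scale, rotation, translation), minimizing the SSD.
2. ``register_local`` — gradient descent over the FFD control-point
   displacements, minimizing ``C_sim + lambda * C_ICP``.  The SSD
   gradient of a control point only involves pixels in its 4-delta
   support window (locality of cubic B-splines), which the
   finite-difference evaluation exploits by batching all perturbed
   window resamples into a single interpolation call.

Gradients are central finite differences with per-parameter-group steps;
the update is the constant-gain descent ``mu <- mu - a * g`` with a
gain-halving safeguard when a step fails to decrease the cost.  The
transform maps reference-frame coordinates into the target frame
(pull-back resampling of the target), so all downstream strain is
Lagrangian with respect to end diastole.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .contours import ContourPointSet, estimate_curvature, smooth_closed_contour
from .cost import CostConfig, compute_alpha_weights, icpif_match
from .interp import pixel_grid, resample, sample_prefiltered, spline_prefilter
from .transforms import (AffineParams, FFDGrid, HierarchicalTransform,
                         affine_apply, bspline_weights)

__all__ = [
    "OptimizerConfig",
    "DisplacementField",
    "RegistrationResult",
    "gradient_descent",
    "register_global",
    "register_local",
    "register_frame",
    "extract_displacement_sequence",
]


@dataclass
class OptimizerConfig:
    """Constant-gain gradient-descent settings.

    ``gains`` and ``steps`` broadcast against the parameter vector, so a
    per-group value can be given per parameter.  ``tolerance`` is the
    minimum cost decrease, relative to the initial cost, required to
    continue iterating.
    """

    gains: object = 1.0
    steps: object = 0.01
    max_iterations: int = 200
    tolerance: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.gains, dtype=float) <= 0):
            raise ValueError("gains must be positive")
        if self.tolerance < 0:
            raise ValueError("tolerance must be non-negative")


#: defaults for the affine stage, parameter order (k, theta, dx, dy);
#: roughly inverse-curvature scaled on unit-range intensities so the four
#: parameter groups converge at comparable rates
GLOBAL_GAINS = (0.3, 20.0, 200.0, 200.0)
GLOBAL_STEPS = (0.005, 0.005, 0.01, 0.01)
#: defaults for the FFD stage (all control-point displacements)
LOCAL_GAIN = 400.0
LOCAL_STEP = 0.01


def default_global_config(**kw) -> OptimizerConfig:
    kw.setdefault("gains", GLOBAL_GAINS)
    kw.setdefault("steps", GLOBAL_STEPS)
    kw.setdefault("max_iterations", 200)
    return OptimizerConfig(**kw)


def default_local_config(**kw) -> OptimizerConfig:
    kw.setdefault("gains", LOCAL_GAIN)
    kw.setdefault("steps", LOCAL_STEP)
    kw.setdefault("max_iterations", 300)
    return OptimizerConfig(**kw)


def _central_fd(cost_fn, mu: np.ndarray, steps: np.ndarray) -> np.ndarray:
    g = np.empty_like(mu)
    for p in range(mu.size):
        e = np.zeros_like(mu)
        e[p] = steps[p]
        g[p] = (cost_fn(mu + e) - cost_fn(mu - e)) / (2.0 * steps[p])
    return g


def gradient_descent(cost_fn, mu0, config: OptimizerConfig,
                     grad_fn=None, on_accept=None):
    """Constant-gain descent with a gain-halving safeguard.

    Returns ``(best_mu, trajectory)`` where the trajectory is the array
    of accepted costs (best-seen cost is non-increasing along it).  A
    step that fails to decrease the cost halves the gain and retries
    within the iteration (the configured gain is restored at the next
    iteration, so one steep stretch of the landscape cannot permanently
    collapse the step size); a non-finite cost at gain underflow is an
    error, plain stagnation at underflow terminates as converged.
    """
    mu = np.asarray(mu0, dtype=float).copy()
    f = float(cost_fn(mu))
    if not np.isfinite(f):
        raise ValueError("cost is not finite at the starting point")
    gains0 = np.broadcast_to(np.asarray(config.gains, dtype=float), mu.shape).copy()
    steps = np.broadcast_to(np.asarray(config.steps, dtype=float), mu.shape)
    gain_floor = 1e-14 * gains0.max()
    tol_abs = config.tolerance * abs(f)
    best_f, best_mu = f, mu.copy()
    traj = [f]
    for it in range(config.max_iterations):
        g = grad_fn(mu) if grad_fn is not None else _central_fd(cost_fn, mu, steps)
        if not np.any(g):
            break
        accepted = False
        gains = gains0.copy()
        while True:
            cand = mu - gains * g
            fc = float(cost_fn(cand))
            if np.isfinite(fc) and fc < f:
                accepted = True
                break
            gains = gains * 0.5
            if gains.max() < gain_floor:
                if not np.isfinite(fc):
                    raise RuntimeError("gain underflow while cost is non-finite")
                break
        if not accepted:
            break
        decrease = f - fc
        mu, f = cand, fc
        traj.append(f)
        if f < best_f:
            best_f, best_mu = f, mu.copy()
        if on_accept is not None:
            on_accept(it, mu, f)
        if decrease < tol_abs:
            break
    return best_mu, np.asarray(traj)


# ----------------------------------------------------------------------------
# Global (affine) stage
# ----------------------------------------------------------------------------

def _centered_to_affine(mu: np.ndarray, c: np.ndarray) -> AffineParams:
    """Convert the internal centre-of-image parameterization
    ``x' = k R (x - c) + c + d`` to the origin-based affine form."""
    p = AffineParams(k=mu[0], theta=mu[1])
    shift = c + mu[2:4] - p.matrix @ c
    return AffineParams(k=p.k, theta=p.theta, dx=shift[0], dy=shift[1])


def _affine_to_centered(p: AffineParams, c: np.ndarray) -> np.ndarray:
    d = p.matrix @ c + np.array([p.dx, p.dy]) - c
    return np.array([p.k, p.theta, d[0], d[1]])


def register_global(reference: np.ndarray, target: np.ndarray,
                    config: OptimizerConfig | None = None,
                    init: AffineParams | None = None,
                    return_trajectory: bool = False):
    """Affine parameters minimizing the SSD, by gradient descent from the
    identity (or a warm start).

    Internally the affine is optimized about the image centre (rotation
    and scale about the origin corner alias with translation and produce
    a badly conditioned, elongated cost valley); the returned parameters
    are in the origin-based form."""
    ref = np.asarray(reference, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if ref.shape != tgt.shape:
        raise ValueError("reference and target must have the same shape")
    config = config or default_global_config()
    pre = spline_prefilter(tgt)
    base = pixel_grid(ref.shape)
    c = np.array([(ref.shape[1] - 1) / 2.0, (ref.shape[0] - 1) / 2.0])

    def cost(mu):
        if mu[0] <= 0:
            return np.inf
        coords = affine_apply(_centered_to_affine(mu, c), base)
        vals, _ = resample(tgt, coords, prefiltered=pre)
        return np.mean((ref - vals) ** 2)

    mu0 = _affine_to_centered(init or AffineParams.identity(), c)
    mu, traj = gradient_descent(cost, mu0, config)
    params = _centered_to_affine(mu, c)
    return (params, traj) if return_trajectory else params


# ----------------------------------------------------------------------------
# Local (FFD) stage
# ----------------------------------------------------------------------------

class _FFDSupport:
    """Fixed B-spline support structure of a point set on a lattice.

    The FFD displacement is linear in the control-point displacements,
    ``disp = W phi`` with a sparse weight matrix that depends only on the
    (fixed) evaluation points, so it is computed once per registration.
    """

    def __init__(self, grid: FFDGrid, points: np.ndarray):
        pts = points.reshape(-1, 2)
        a0, b0, u, v = grid.support_indices(pts)
        wx, wy = bspline_weights(u), bspline_weights(v)
        offs = np.arange(4)
        ix = (a0 - 1)[:, None] + offs
        iy = (b0 - 1)[:, None] + offs
        nx, ny = grid.shape
        cols = (ix[:, :, None] * ny + iy[:, None, :]).reshape(len(pts), 16)
        w = (wx[:, :, None] * wy[:, None, :]).reshape(len(pts), 16)
        rows = np.repeat(np.arange(len(pts)), 16)
        self.n_points = len(pts)
        self.n_cp = nx * ny
        self.W = sparse.csc_matrix((w.ravel(), (rows, cols.ravel())),
                                   shape=(self.n_points, self.n_cp))
        self.W.sort_indices()
        self.col_rows = self.W.indices        # point index per (cp, weight) entry
        self.col_w = self.W.data
        self.col_ptr = self.W.indptr
        self.col_len = np.diff(self.col_ptr)

    def displacement(self, phi: np.ndarray) -> np.ndarray:
        """(n_points, 2) displacement for control displacements (n_cp, 2)."""
        return np.column_stack([self.W @ phi[:, 0], self.W @ phi[:, 1]])

    def column_sums(self, values: np.ndarray) -> np.ndarray:
        """Sum ``values[point]`` over the support points of each control
        point (segment sums over the CSC columns)."""
        out = np.zeros(self.n_cp)
        nonempty = self.col_len > 0
        sums = np.add.reduceat(values, self.col_ptr[:-1][nonempty])
        out[nonempty] = sums
        return out


def _prep_contours(contours: dict | None, n_points: int) -> dict:
    if not contours:
        return {}
    return {label: c.resampled(n_points) for label, c in contours.items()}


def register_local(reference: np.ndarray, target: np.ndarray,
                   affine: AffineParams,
                   contours_ref: dict | None = None,
                   contours_target: dict | None = None,
                   config: OptimizerConfig | None = None,
                   cost_config: CostConfig | None = None,
                   grid_spacing: float = 8.0,
                   init: FFDGrid | None = None,
                   return_log: bool = False):
    """FFD control-point displacements minimizing ``C_sim + lambda C_ICP``
    after the global stage, by windowed finite-difference gradient descent
    from zero (or a warm start).

    ``contours_ref`` / ``contours_target`` map label -> ContourPointSet.
    With ``lambda = 0`` or no contours this reproduces the original,
    intensity-only method.

    The contour term is handled as a closest-point majorization: at the
    start of every iteration the propagated-contour curvatures and the
    correspondences are refreshed, then held fixed through the gradient
    and the gain-halving line search, so each step minimizes a
    stationary quadratic surrogate of ``C_ICP``.
    """
    ref = np.asarray(reference, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if ref.shape != tgt.shape:
        raise ValueError("reference and target must have the same shape")
    config = config or default_local_config()
    cc = cost_config or CostConfig()

    grid = FFDGrid.for_image(ref.shape, grid_spacing)
    if init is not None:
        if init.shape != grid.shape:
            raise ValueError("warm-start grid shape mismatch")
        grid.phi[...] = init.phi
    pre = spline_prefilter(tgt)
    base = affine_apply(affine, pixel_grid(ref.shape)).reshape(-1, 2)
    ref_flat = ref.ravel()
    n_pix = ref_flat.size
    sup = _FFDSupport(grid, pixel_grid(ref.shape))

    use_contours = bool(cc.lam > 0 and contours_ref and contours_target)
    if use_contours:
        cref = _prep_contours(contours_ref, cc.resample_points)
        ctgt = _prep_contours(contours_target, cc.resample_points)
        labels = sorted(set(cref) & set(ctgt))
        use_contours = bool(labels)
    if use_contours:
        # frozen reciprocal-range weights from the frame-0 contour pair
        alphas = {}
        for lab in labels:
            if cc.alpha1 is not None and cc.alpha2 is not None:
                alphas[lab] = (cc.alpha1, cc.alpha2)
            else:
                alphas[lab] = compute_alpha_weights(cref[lab], ctgt[lab])
        csup = {lab: _FFDSupport(grid, cref[lab].points) for lab in labels}
        cbase = {lab: affine_apply(affine, cref[lab].points) for lab in labels}

    h = float(np.asarray(config.steps).ravel()[0])
    gain0 = float(np.asarray(config.gains).ravel()[0])
    gain_floor = 1e-14 * gain0
    log: list[dict] = []

    def moved_points(lab, phi):
        return cbase[lab] + csup[lab].displacement(phi)

    def refresh_state(phi):
        """Refresh curvatures, alphas and correspondences; returns per-label
        aggregates of the frozen quadratic surrogate of C_ICP."""
        state = []
        for lab in labels:
            p = moved_points(lab, phi)
            if cc.recompute_curvature:
                curv = estimate_curvature(
                    smooth_closed_contour(p, cc.curvature_smoothing),
                    window=cref[lab].curvature_window)
            else:
                curv = cref[lab].curvatures
            moved = ContourPointSet(p, curvatures=curv, closed=True, label=lab,
                                    curvature_window=cref[lab].curvature_window)
            a1, a2 = alphas[lab]
            if cc.recompute_alpha_each_iteration:
                a1, a2 = compute_alpha_weights(moved, ctgt[lab])
            # matching weight of the curvature feature: inside the gate a
            # full-range curvature mismatch costs as much as a positional
            # miss of one gate radius.  The raw reciprocal-range weight
            # equates it with a full-diameter positional miss instead,
            # which lets curvature-estimation noise override position and
            # drag matches tangentially along the wall.
            if cc.gate_radius is not None and cc.alpha2 is None:
                a2_match = a1 * a2 * cc.gate_radius**2
            else:
                a2_match = a2
            m = icpif_match(moved, ctgt[lab], a1, a2_match,
                            gate_radius=cc.gate_radius)
            npts = len(p)
            cnt = np.bincount(m.matched_indices, minlength=npts).astype(float)
            sum_q = np.stack(
                [np.bincount(m.matched_indices, weights=m.target_points[:, ax],
                             minlength=npts) for ax in (0, 1)], axis=1)
            feat_const = float(a2 * np.sum((m.target_curvatures
                                            - m.matched_curvatures) ** 2))
            q_sq = float(np.sum(m.target_points ** 2))
            state.append((lab, a1, cnt, sum_q, feat_const, q_sq))
        return state

    def icp_surrogate(phi, state, with_features: bool = False) -> float:
        """Frozen-correspondence C_ICP.  The line search uses the
        positional part only: the frozen curvature term is a constant
        within the step (it does not depend on phi), and letting its
        re-estimation noise into the accept/stop comparisons would let
        steps be judged against a quantity the parameters do not
        control."""
        total = 0.0
        for lab, a1, cnt, sum_q, feat_const, q_sq in state:
            p = moved_points(lab, phi)
            pos = (q_sq - 2.0 * float(np.sum(sum_q * p))
                   + float(np.sum(cnt * np.einsum("ij,ij->i", p, p))))
            total += a1 * pos + (feat_const if with_features else 0.0)
        return total

    def c_sim_of(phi):
        coords = base + sup.displacement(phi)
        warped = sample_prefiltered(pre, coords[:, 0], coords[:, 1])
        return float(np.mean((ref_flat - warped) ** 2)), coords

    def gradient(phi, coords, state):
        # C_sim: central differences restricted to each control point's
        # support window, all perturbed window resamples in one batch
        rows, w = sup.col_rows, sup.col_w
        c_rows = coords[rows]
        pert = np.empty((4, len(rows), 2))
        for i, (axis, sign) in enumerate(((0, 1.0), (0, -1.0), (1, 1.0), (1, -1.0))):
            p = c_rows.copy()
            p[:, axis] += sign * h * w
            pert[i] = p
        flat = pert.reshape(-1, 2)
        vals = sample_prefiltered(pre, flat[:, 0], flat[:, 1]).reshape(4, -1)
        sq = (ref_flat[rows][None, :] - vals) ** 2
        win = np.stack([sup.column_sums(sq[i]) for i in range(4)])
        g = np.empty((sup.n_cp, 2))
        g[:, 0] = (win[0] - win[1]) / (2.0 * h) / n_pix
        g[:, 1] = (win[2] - win[3]) / (2.0 * h) / n_pix
        # frozen-surrogate contour term: quadratic in the propagated
        # points, so its central difference has the closed form below
        for lab, a1, cnt, sum_q, _fc, _qs in state:
            p = moved_points(lab, phi)
            sq_ = csup[lab]
            for axis in (0, 1):
                val = sq_.col_w * (cnt[sq_.col_rows] * p[sq_.col_rows, axis]
                                   - sum_q[sq_.col_rows, axis])
                g[:, axis] += cc.lam * 2.0 * a1 * sq_.column_sums(val)
        return g

    phi = grid.phi.reshape(-1, 2).copy()
    state = refresh_state(phi) if use_contours else []
    c_sim, coords = c_sim_of(phi)
    ci = icp_surrogate(phi, state) if use_contours else 0.0
    f = c_sim + cc.lam * ci
    if not np.isfinite(f):
        raise ValueError("cost is not finite at the starting grid")
    tol_abs = config.tolerance * abs(f)
    best = (f, phi.copy())
    for it in range(config.max_iterations):
        g = gradient(phi, coords, state)
        if not np.any(g):
            break
        accepted = False
        gain = gain0
        while True:
            cand = phi - gain * g
            cs_c, coords_c = c_sim_of(cand)
            fc = cs_c + cc.lam * (icp_surrogate(cand, state) if use_contours
                                  else 0.0)
            if np.isfinite(fc) and fc < f:
                accepted = True
                break
            gain *= 0.5
            if gain < gain_floor:
                if not np.isfinite(fc):
                    raise RuntimeError("gain underflow while cost is non-finite")
                break
        if not accepted:
            break
        decrease = f - fc
        phi, coords = cand, coords_c
        ci_full = icp_surrogate(phi, state, with_features=True) \
            if use_contours else 0.0
        log.append({"iteration": it, "c_sim": cs_c, "c_icp": ci_full,
                    "total": cs_c + cc.lam * ci_full})
        if use_contours:
            # majorization refresh: matches can only tighten, curvature
            # re-evaluation re-linearizes the feature term
            state = refresh_state(phi)
            f = cs_c + cc.lam * icp_surrogate(phi, state)
        else:
            f = fc
        if f < best[0]:
            best = (f, phi.copy())
        if decrease < tol_abs:
            break
    out = FFDGrid(phi=best[1].reshape(grid.phi.shape), delta=grid.delta,
                  origin=grid.origin)
    return (out, log) if return_log else out


# ----------------------------------------------------------------------------
# Per-frame pipeline and sequence extraction
# ----------------------------------------------------------------------------

@dataclass
class DisplacementField:
    """Dense per-pixel displacement (pixels) on the reference-frame grid,
    mapping reference coordinates to frame-``frame`` coordinates."""

    u: np.ndarray                  # (H, W, 2)
    frame: int
    mask: np.ndarray = None        # pixels with full FFD support

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if self.mask is None:
            self.mask = np.ones(self.u.shape[:2], dtype=bool)
        if not np.isfinite(self.u[self.mask]).all():
            raise ValueError("displacement field must be finite on its mask")

    @classmethod
    def from_transform(cls, transform: HierarchicalTransform, shape,
                       frame: int) -> "DisplacementField":
        u = transform.displacement(pixel_grid(shape))
        return cls(u=u, frame=frame)

    @classmethod
    def zero(cls, shape, frame: int = 0) -> "DisplacementField":
        return cls(u=np.zeros((*shape, 2)), frame=frame)


@dataclass
class RegistrationResult:
    transform: HierarchicalTransform
    frame: int = 0
    global_trajectory: np.ndarray = None
    local_log: list = field(default_factory=list)

    @property
    def c_sim(self) -> float:
        return self.local_log[-1]["c_sim"] if self.local_log else np.nan

    @property
    def c_icp(self) -> float:
        return self.local_log[-1]["c_icp"] if self.local_log else np.nan

    @property
    def iterations(self) -> int:
        n_global = len(self.global_trajectory) - 1 if self.global_trajectory is not None else 0
        return n_global + len(self.local_log)


def register_frame(reference: np.ndarray, target: np.ndarray,
                   contours_ref: dict | None = None,
                   contours_target: dict | None = None,
                   global_config: OptimizerConfig | None = None,
                   local_config: OptimizerConfig | None = None,
                   cost_config: CostConfig | None = None,
                   grid_spacing: float = 8.0,
                   init: HierarchicalTransform | None = None,
                   frame: int = 0) -> RegistrationResult:
    """Global-then-local registration of one target frame to the reference."""
    affine, gtraj = register_global(reference, target, config=global_config,
                                    init=init.affine if init else None,
                                    return_trajectory=True)
    grid, llog = register_local(reference, target, affine,
                                contours_ref=contours_ref,
                                contours_target=contours_target,
                                config=local_config, cost_config=cost_config,
                                grid_spacing=grid_spacing,
                                init=init.grid if init else None,
                                return_log=True)
    return RegistrationResult(
        transform=HierarchicalTransform(affine=affine, grid=grid),
        frame=frame, global_trajectory=gtraj, local_log=llog)


def extract_displacement_sequence(cine, contours: dict | None = None,
                                  global_config: OptimizerConfig | None = None,
                                  local_config: OptimizerConfig | None = None,
                                  cost_config: CostConfig | None = None,
                                  grid_spacing: float = 8.0,
                                  warm_start: bool = True,
                                  reference_frame: int = 0):
    """Register every frame to the reference frame and return the dense
    displacement-field sequence.

    ``contours`` maps ``(frame, label) -> ContourPointSet``.  Warm-starting
    initializes frame ``t`` from frame ``t-1``'s solution, purely as an
    initialization aid — the objective of every frame compares to the
    reference frame.  Per-frame failures are recorded and the sequence
    continues; a summary error is raised at the end if any frame failed.

    Returns ``(fields, results)``: one :class:`DisplacementField` and one
    :class:`RegistrationResult` (``None`` on failure) per frame; the
    reference frame's field is identically zero by construction.
    """
    frames = np.asarray(cine.frames, dtype=float)
    if len(frames) < 2:
        raise ValueError("a cine sequence needs at least 2 frames")
    ref = frames[reference_frame]
    shape = ref.shape

    def frame_contours(t):
        if not contours:
            return None
        sub = {lab: c for (f, lab), c in contours.items() if f == t}
        return sub or None

    cref = frame_contours(reference_frame)
    fields: list = []
    results: list = []
    errors: list = []
    prev: HierarchicalTransform | None = None
    for t in range(len(frames)):
        if t == reference_frame:
            fields.append(DisplacementField.zero(shape, frame=t))
            results.append(None)
            continue
        try:
            res = register_frame(ref, frames[t],
                                 contours_ref=cref,
                                 contours_target=frame_contours(t),
                                 global_config=global_config,
                                 local_config=local_config,
                                 cost_config=cost_config,
                                 grid_spacing=grid_spacing,
                                 init=prev if warm_start else None,
                                 frame=t)
            fields.append(DisplacementField.from_transform(res.transform, shape, t))
            results.append(res)
            prev = res.transform
        except Exception as exc:  # noqa: BLE001 - per-frame failures summarised
            fields.append(None)
            results.append(None)
            errors.append((t, exc))
    if errors:
        msg = "; ".join(f"frame {t}: {e}" for t, e in errors)
        err = RuntimeError(f"registration failed for {len(errors)} frame(s): {msg}")
        err.fields = fields
        raise err
    return fields, results
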
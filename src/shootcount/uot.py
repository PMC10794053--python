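"""Unbalanced entropic optimal-transport counting loss.

The counting objective compares a predicted density map ``a`` (one
non-negative mass per pixel, at locations ``x_i``) with the annotated dot
map ``b`` (unit mass per shoot, at locations ``y_j``) through a transport
plan ``P`` minimizing

    <C, P>  -  eps * sum_ij P_ij log P_ij
            +  tau * || P 1_m  - a ||_2^2      (pixel marginal, squared L2)
            +  tau * || P^T 1_n - b ||_1       (point marginal, L1)

The marginal constraints of balanced OT are relaxed into penalties, so
surplus or missing density is charged directly instead of being hidden by
normalization.  The entropy term is the plain ``sum P log P`` with
``0 log 0 = 0``.

Transport cost kinds
--------------------
``euclid``      L_ij = ||x_i - y_j||
``squared``     L_ij^2
``exp``         exp(L_ij)
``perspective`` exp(L_ij / eta_ij), eta_ij = (h_i + h_j)/2 with h the
                normalized image height in (0, 1].  Far-from-camera rows
                (small h in a nadir UAV shot maps to the top of the frame)
                get a larger exponent, so moving density across the
                dense-appearing region is charged more.

Distances are taken in height-normalized coordinates (pixels divided by
image height) and exponents are clamped at 50 before ``exp``.

The solver alternates multiplicative mirror steps, proximal-gradient
steps with the exact prox of the column-L1 term, and marginal rescales,
all backtracked on the true objective so it never increases; small
problems add a quasi-Newton polish and basin-flip/transfer refinement of
the plan's support.  The contract is agreement with a brute-force oracle
on small instances, not a particular named algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .annotations_io import PointAnnotation
from .density import DensityMap

__all__ = [
    "PredictedDensity",
    "TargetDots",
    "CostMatrix",
    "TransportPlan",
    "LossBreakdown",
    "perspective_coeff",
    "normalized_heights",
    "cost_matrix",
    "uot_objective",
    "solve_uot",
    "uot_loss_and_grad",
    "smooth_l1",
    "composite_loss",
    "composite_loss_and_grad",
    "grid_coords",
    "COST_KINDS",
]

COST_KINDS = ("euclid", "squared", "exp", "perspective")
#: exponent clamp preventing overflow in exp-type costs
EXP_CLAMP = 50.0


@dataclass
class PredictedDensity:
    """Flattened predicted density: per-pixel masses and their coordinates."""

    masses: np.ndarray  # (n,) non-negative
    coords: np.ndarray  # (n, 2) x, y pixel centres

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=np.float64).ravel()
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 2)
        if self.masses.shape[0] != self.coords.shape[0]:
            raise ValueError("masses and coords length mismatch")
        if (self.masses < 0).any():
            raise ValueError("predicted density has negative mass")

    @property
    def n(self) -> int:
        return self.masses.shape[0]


@dataclass
class TargetDots:
    """Annotated dot map: one positive mass (normally 1) per shoot."""

    masses: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=np.float64).ravel()
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 2)
        if self.masses.shape[0] != self.coords.shape[0]:
            raise ValueError("masses and coords length mismatch")
        if self.masses.size and (self.masses <= 0).any():
            raise ValueError("dot masses must be positive")

    @classmethod
    def from_points(cls, points: PointAnnotation | np.ndarray, scale: float = 1.0) -> "TargetDots":
        pts = points.points if isinstance(points, PointAnnotation) else np.asarray(points, float)
        pts = pts.reshape(-1, 2) * scale
        return cls(masses=np.ones(pts.shape[0]), coords=pts)

    @property
    def m(self) -> int:
        return self.masses.shape[0]


@dataclass
class CostMatrix:
    entries: np.ndarray
    kind: str = "euclid"

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=np.float64)
        if self.entries.ndim != 2:
            raise ValueError("cost matrix must be 2-D")
        if (self.entries < 0).any():
            raise ValueError("cost matrix has negative entries")


@dataclass
class TransportPlan:
    plan: np.ndarray
    objective: float
    iterations: int
    converged: bool
    transport_cost: float = 0.0  # <C, P> alone


@dataclass
class LossBreakdown:
    """The three terms of the composite counting loss and their weighting."""

    count_loss: float
    ot_loss: float
    pixel_mse: float
    lambda1: float
    lambda2: float
    total: float = field(init=False)

    def __post_init__(self) -> None:
        self.total = (
            self.count_loss + self.lambda1 * self.ot_loss + self.lambda2 * self.pixel_mse
        )


# ---------------------------------------------------------------------------
# Cost matrices
# ---------------------------------------------------------------------------


def perspective_coeff(h_i: float, h_j: float) -> float:
    """Adaptive perspective coefficient: the mean of two normalized heights."""
    if h_i <= 0 or h_j <= 0:
        raise ValueError(f"normalized heights must be positive, got ({h_i}, {h_j})")
    return 0.5 * (h_i + h_j)


def normalized_heights(y: np.ndarray, image_height: float) -> np.ndarray:
    """Map row coordinates to normalized heights in (0, 1].

    Integer row r maps to (r + 1)/H so the top row is 1/H, never zero;
    continuous coordinates are clipped into the same interval.
    """
    if image_height <= 0:
        raise ValueError("image_height must be positive")
    h = (np.asarray(y, dtype=np.float64) + 1.0) / float(image_height)
    return np.clip(h, 1.0 / float(image_height), 1.0)


def cost_matrix(
    pred_coords: np.ndarray,
    target_coords: np.ndarray,
    kind: Literal["euclid", "squared", "exp", "perspective"] = "perspective",
    image_height: float | None = None,
) -> CostMatrix:
    """Pairwise transport costs between pixel centres and dot locations.

    When ``image_height`` is given, distances are first normalized by it
    (mandatory for the ``exp`` and ``perspective`` kinds, whose exponents
    would otherwise overflow; the clamp at 50 is a second guard).
    """
    if kind not in COST_KINDS:
        raise ValueError(f"unknown cost kind {kind!r}; expected one of {COST_KINDS}")
    xs = np.asarray(pred_coords, dtype=np.float64).reshape(-1, 2)
    ys = np.asarray(target_coords, dtype=np.float64).reshape(-1, 2)
    if xs.shape[0] == 0 or ys.shape[0] == 0:
        return CostMatrix(np.zeros((xs.shape[0], ys.shape[0])), kind)
    if kind in ("exp", "perspective") and (image_height is None or image_height <= 0):
        raise ValueError(f"kind={kind!r} requires a positive image_height")
    diff = xs[:, None, :] - ys[None, :, :]
    L = np.sqrt((diff**2).sum(axis=2))
    if image_height is not None:
        L = L / float(image_height)
    if kind == "euclid":
        return CostMatrix(L, kind)
    if kind == "squared":
        return CostMatrix(L**2, kind)
    if kind == "exp":
        return CostMatrix(np.exp(np.minimum(L, EXP_CLAMP)), kind)
    h_pred = normalized_heights(xs[:, 1], image_height)  # type: ignore[arg-type]
    h_tgt = normalized_heights(ys[:, 1], image_height)  # type: ignore[arg-type]
    eta = 0.5 * (h_pred[:, None] + h_tgt[None, :])
    return CostMatrix(np.exp(np.minimum(L / eta, EXP_CLAMP)), kind)


# ---------------------------------------------------------------------------
# The unbalanced entropic objective and its solver
# ---------------------------------------------------------------------------


def _xlogx(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    pos = p > 0
    out[pos] = p[pos] * np.log(p[pos])
    return out


def uot_objective(
    P: np.ndarray, a: np.ndarray, b: np.ndarray, C: np.ndarray, eps: float, tau: float
) -> float:
    """Evaluate the unbalanced entropic transport objective at plan ``P``."""
    P = np.asarray(P, dtype=np.float64)
    row = P.sum(axis=1) - a
    col = P.sum(axis=0) - b
    return float(
        (C * P).sum()
        - eps * _xlogx(P).sum()
        + tau * (row**2).sum()
        + tau * np.abs(col).sum()
    )


def _col_snap(P, a, b, C, eps, tau, obj):
    """Try rescaling columns so their sums land exactly on the L1 kink."""
    colsum = P.sum(axis=0)
    pos = colsum > 1e-30
    if not pos.any():
        return P, obj
    gamma = np.ones_like(colsum)
    gamma[pos] = np.minimum(b[pos] / colsum[pos], 1e6)
    for theta in (1.0, 0.5, 0.25):
        P_new = P * (1.0 + theta * (gamma - 1.0))[None, :]
        obj_new = uot_objective(P_new, a, b, C, eps, tau)
        if obj_new < obj:
            return P_new, obj_new
    return P, obj


def _prox_cols(Y: np.ndarray, lam: float, b: np.ndarray) -> np.ndarray:
    """Exact prox of ``lam * ||col_sums(Z) - b||_1`` over ``Z >= 0`` at ``Y``.

    Per column the minimizer is a uniform shift ``z = max(y - mu, 0)`` with
    ``mu in [-lam, lam]``; when neither extreme shift reaches the target
    sum, ``mu`` is found by (vectorized) bisection on the monotone shifted
    sum, which pins the column sum exactly onto the L1 kink.
    """

    def shifted_sums(mu: np.ndarray) -> np.ndarray:
        return np.maximum(Y - mu[None, :], 0.0).sum(axis=0)

    m = Y.shape[1]
    hi_sum = shifted_sums(np.full(m, lam))
    lo_sum = shifted_sums(np.full(m, -lam))
    mu = np.where(hi_sum >= b, lam, -lam)
    needs_bisect = (hi_sum < b) & (lo_sum > b)
    if needs_bisect.any():
        lo = np.full(m, -lam)
        hi = np.full(m, lam)
        for _ in range(50):
            mid = 0.5 * (lo + hi)
            above = shifted_sums(mid) > b
            lo = np.where(above, mid, lo)
            hi = np.where(above, hi, mid)
        mu = np.where(needs_bisect, 0.5 * (lo + hi), mu)
    return np.maximum(Y - mu[None, :], 0.0)


def _row_snap(P, a, b, C, eps, tau, obj):
    """Try rescaling rows so their sums hit the quadratic penalty's minimum."""
    rowsum = P.sum(axis=1)
    pos = rowsum > 1e-30
    if not pos.any():
        return P, obj
    gamma = np.ones_like(rowsum)
    gamma[pos] = np.minimum(a[pos] / rowsum[pos], 1e6)
    for theta in (1.0, 0.5, 0.25):
        P_new = P * (1.0 + theta * (gamma - 1.0))[:, None]
        obj_new = uot_objective(P_new, a, b, C, eps, tau)
        if obj_new < obj:
            return P_new, obj_new
    return P, obj


def _mirror_descent(
    P: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    C: np.ndarray,
    eps: float,
    tau: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, float, int, bool]:
    """Alternating mirror / proximal descent with backtracking.

    Each iteration tries (i) a multiplicative (positivity-preserving)
    mirror step on the full subgradient, (ii) a proximal-gradient step
    where the column-L1 penalty enters through its exact prox — the move
    that resolves the kink the subgradient oscillates around — and (iii) a
    column rescaling aimed at the kink.  Every move is backtracked on the
    true objective, so the objective is non-increasing; termination
    requires the relative decrease to stay under ``tol`` for a few
    iterations in a row.
    """
    obj = uot_objective(P, a, b, C, eps, tau)
    step_m = 1.0 / (1.0 + tau)
    step_p = 1.0 / (1.0 + tau)
    converged = False
    it = 0
    tiny = 1e-300
    quiet = 0
    for it in range(1, max_iter + 1):
        logP = np.log(np.maximum(P, tiny))
        row = P.sum(axis=1) - a
        col = P.sum(axis=0) - b
        grad_smooth = C - eps * (logP + 1.0) + 2.0 * tau * row[:, None]
        rel = 0.0

        # (i) mirror step on the full subgradient; exponent clipped so one
        # step cannot vault over an interior basin into the zero basin
        grad = grad_smooth + tau * np.sign(col)[None, :]
        for _ in range(30):
            P_new = P * np.exp(np.clip(-step_m * grad, -3.0, 3.0))
            obj_new = uot_objective(P_new, a, b, C, eps, tau)
            if obj_new <= obj:
                rel = max(rel, abs(obj - obj_new) / max(abs(obj), 1.0))
                P, obj = P_new, obj_new
                step_m = min(step_m * 1.3, 1e3)
                break
            step_m *= 0.5

        # (ii) proximal step: explicit smooth gradient, exact prox of the L1 term
        for _ in range(30):
            P_new = _prox_cols(P - step_p * grad_smooth, step_p * tau, b)
            obj_new = uot_objective(P_new, a, b, C, eps, tau)
            if obj_new <= obj:
                rel = max(rel, abs(obj - obj_new) / max(abs(obj), 1.0))
                P, obj = P_new, obj_new
                step_p = min(step_p * 1.3, 1e3)
                break
            step_p *= 0.5

        # (iii) marginal rescales: rows onto the quadratic minimum, columns
        # onto the L1 kink
        P, obj2 = _row_snap(P, a, b, C, eps, tau, obj)
        P, obj3 = _col_snap(P, a, b, C, eps, tau, obj2)
        rel = max(rel, abs(obj - obj3) / max(abs(obj), 1.0))
        obj = obj3

        quiet = quiet + 1 if rel < tol else 0
        if quiet >= 3:
            converged = True
            break
    return P, obj, it, converged


def _sinkhorn_init(a: np.ndarray, b: np.ndarray, C: np.ndarray, eps: float) -> np.ndarray:
    """Balanced entropic plan (log-domain Sinkhorn) used as a warm start.

    The unbalanced objective is not solvable by Sinkhorn scaling, but the
    balanced plan between ``a`` and ``b`` rescaled to a common total is an
    excellent initial iterate, especially when the marginal penalties are
    stiff.
    """
    sa, sb = a.sum(), b.sum()
    total = min(sa, sb)
    at = a * (total / sa)
    la = np.log(np.maximum(at, 1e-300))
    lb = np.log(np.maximum(b * (total / sb), 1e-300))
    reg = max(eps, 1e-3 * float(C.mean()) + 1e-12)
    f = np.zeros_like(la)
    g = np.zeros_like(lb)
    K = -C / reg
    # a warm start, not a solution: iterate until the rows roughly match
    small = C.size <= _REFINE_LIMIT
    max_it, gap_tol = (2000, 1e-9) if small else (300, 1e-5)
    for it in range(max_it):
        f = la - _logsumexp(K + g[None, :], axis=1)
        g = lb - _logsumexp(K + f[:, None], axis=0)
        if it % 10 == 9:
            P = np.exp(np.clip(K + f[:, None] + g[None, :], -700, 50))
            if np.abs(P.sum(axis=1) - at).max() < gap_tol * max(total, 1.0):
                break
    P = np.exp(np.clip(K + f[:, None] + g[None, :], -700, 50))
    rows = P.sum(axis=1)
    pos = rows > 1e-300
    P[pos] *= (at[pos] / rows[pos])[:, None]  # make rows exact; quadratic penalty is stiff
    return P


def _logsumexp(x: np.ndarray, axis: int) -> np.ndarray:
    m = x.max(axis=axis, keepdims=True)
    out = m + np.log(np.exp(x - m).sum(axis=axis, keepdims=True))
    return np.squeeze(out, axis=axis)


def _polish(P, obj, a, b, C, eps, tau):
    """Quasi-Newton polish on the true objective, kept only if it improves.

    The mirror descent crawls once the remaining error is dominated by
    ill-conditioning (stiff marginal penalties); a bound-constrained
    L-BFGS-B run from its iterate converges the smooth directions quickly.
    The kink of the L1 term limits the quasi-Newton model, so the result
    is accepted only when the exact objective decreases.
    """
    from scipy import optimize

    n, m = P.shape

    def fun(x):
        Q = x.reshape(n, m)
        val = uot_objective(Q, a, b, C, eps, tau)
        logQ = np.log(np.maximum(Q, 1e-30))
        row = Q.sum(axis=1) - a
        col = Q.sum(axis=0) - b
        grad = C - eps * (logQ + 1.0) + 2.0 * tau * row[:, None] + tau * np.sign(col)[None, :]
        return val, grad.ravel()

    res = optimize.minimize(
        fun, P.ravel(), jac=True, method="L-BFGS-B",
        bounds=[(0.0, None)] * (n * m),
        options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-12},
    )
    cand = np.maximum(res.x.reshape(n, m), 0.0)
    obj_cand = uot_objective(cand, a, b, C, eps, tau)
    if obj_cand < obj:
        return cand, obj_cand
    return P, obj


#: refine support patterns only below this problem size (n*m)
_REFINE_LIMIT = 64


def _support_refine(P, obj, a, b, C, eps, tau, tol, max_iter):
    """Greedy one-entry basin flips on small problems.

    The entropy term makes every entry bistable: exactly zero, or an
    interior stationary value, with a barrier between the two that a
    monotone descent cannot cross.  On small instances we therefore try
    flipping each entry to the other basin and re-descending, keeping any
    strict improvement, until no single flip helps.
    """
    n, m = P.shape
    inner_iter = min(max_iter, 1000)

    def descend(trial):
        P_new, obj_new, _, _ = _mirror_descent(
            np.maximum(trial, 1e-300), a, b, C, eps, tau, tol, inner_iter
        )
        return _polish(P_new, obj_new, a, b, C, eps, tau)

    improved = True
    passes = 0
    while improved and passes < 6:
        improved = False
        passes += 1
        # single-entry flips between the zero and interior basins
        for i in range(n):
            for j in range(m):
                if P[i, j] > 1e-8:
                    on_values = [1e-12]
                else:
                    on_values = [0.1, max(0.1, min(a[i] if a[i] > 0 else b[j], b[j]))]
                for v in on_values:
                    trial = P.copy()
                    trial[i, j] = v
                    P_new, obj_new = descend(trial)
                    if obj_new < obj - 1e-12:
                        P, obj = P_new, obj_new
                        improved = True
        # coordinated transfers: move an active entry's mass to another
        # column (same row) or another row (same column); these reach
        # optima that differ by a two-entry support change
        if n * m <= 16:
            for i in range(n):
                for j in range(m):
                    if P[i, j] <= 1e-8:
                        continue
                    v = P[i, j]
                    for j2 in range(m):
                        if j2 == j:
                            continue
                        trial = P.copy()
                        trial[i, j] = 1e-12
                        trial[i, j2] = max(trial[i, j2] + v, 0.05)
                        P_new, obj_new = descend(trial)
                        if obj_new < obj - 1e-12:
                            P, obj = P_new, obj_new
                            improved = True
                    for i2 in range(n):
                        if i2 == i:
                            continue
                        trial = P.copy()
                        trial[i, j] = 1e-12
                        trial[i2, j] = max(trial[i2, j] + v, 0.05)
                        P_new, obj_new = descend(trial)
                        if obj_new < obj - 1e-12:
                            P, obj = P_new, obj_new
                            improved = True
    return P, obj


def solve_uot(
    a: np.ndarray | PredictedDensity,
    b: np.ndarray | TargetDots,
    C: np.ndarray | CostMatrix,
    eps: float = 0.05,
    tau: float = 0.5,
    tol: float = 1e-9,
    max_iter: int = 2000,
    refine: bool = True,
) -> TransportPlan:
    """Approximately minimize the unbalanced entropic transport objective.

    Small problems are descended from three starting plans (rescaled outer
    product, uniform, balanced Sinkhorn warm start), polished with a
    quasi-Newton pass, and refined by single-entry basin flips, which in
    practice recovers the global minimum; large problems (training-scale)
    run a single warm-started descent, where a good local minimum is all a
    loss gradient needs.  The objective never increases across accepted
    iterations.  ``converged`` is False only when ``max_iter`` ran out
    before the relative objective change fell under ``tol``.  ``refine``
    switches the basin-flip phase off, e.g. for stiff near-balanced
    problems whose optimum has no ambiguous support.
    """
    if eps <= 0 or tau <= 0:
        raise ValueError("eps and tau must be positive")
    a = a.masses if isinstance(a, PredictedDensity) else np.asarray(a, dtype=np.float64).ravel()
    b = b.masses if isinstance(b, TargetDots) else np.asarray(b, dtype=np.float64).ravel()
    C = C.entries if isinstance(C, CostMatrix) else np.asarray(C, dtype=np.float64)
    if C.shape != (a.size, b.size):
        raise ValueError(f"cost shape {C.shape} does not match marginals ({a.size}, {b.size})")
    if not (np.isfinite(a).all() and np.isfinite(b).all() and np.isfinite(C).all()):
        raise ValueError("non-finite values in solver inputs")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("marginals must be non-negative")
    n, m = a.size, b.size
    if n == 0 or m == 0 or (a.sum() <= 0 and b.sum() <= 0):
        P = np.zeros((n, m))
        return TransportPlan(P, 0.0, 0, True, 0.0)

    scale = max(a.sum(), b.sum(), 1e-12)
    floor = 1e-6 * scale / (n * m)
    small = n * m <= _REFINE_LIMIT
    if small:
        inits = [
            np.outer(a, b) / max(b.sum(), 1e-12) + floor,
            np.full((n, m), min(a.sum(), b.sum()) / (n * m) + floor),
        ]
        if a.sum() > 0 and b.sum() > 0:
            inits.append(_sinkhorn_init(a, b, C, eps) + floor)
    elif a.sum() > 0 and b.sum() > 0:
        # one warm start is enough when a local minimum serves (training)
        inits = [_sinkhorn_init(a, b, C, eps) + floor]
    else:
        inits = [np.outer(a, b) / max(b.sum(), 1e-12) + floor]
    best: tuple[np.ndarray, float, int, bool] | None = None
    total_iters = 0
    for P0 in inits:
        P, obj, it, conv = _mirror_descent(P0, a, b, C, eps, tau, tol, max_iter)
        if small:
            P, obj = _polish(P, obj, a, b, C, eps, tau)
        total_iters += it
        if best is None or obj < best[1]:
            best = (P, obj, it, conv)
    P, obj, _, conv = best  # type: ignore[misc]
    if small and refine:
        P, obj = _support_refine(P, obj, a, b, C, eps, tau, tol, max_iter)
    return TransportPlan(P, obj, total_iters, conv, float((C * P).sum()))


def uot_loss_and_grad(
    pred: PredictedDensity,
    targets: TargetDots,
    C: np.ndarray | CostMatrix | None = None,
    eps: float = 0.05,
    tau: float = 0.5,
    cost_kind: str = "perspective",
    image_height: float | None = None,
    tol: float = 1e-9,
    max_iter: int = 2000,
) -> tuple[float, np.ndarray, TransportPlan]:
    """Transport loss and its gradient with respect to the predicted masses.

    The gradient is taken by the envelope rule at the converged plan: only
    the squared-L2 pixel-marginal penalty depends on ``a`` directly, so

        d loss / d a = -2 tau (P 1_m - a).
    """
    if C is None:
        C = cost_matrix(pred.coords, targets.coords, cost_kind, image_height)  # type: ignore[arg-type]
    plan = solve_uot(pred, targets, C, eps=eps, tau=tau, tol=tol, max_iter=max_iter)
    row_gap = plan.plan.sum(axis=1) - pred.masses
    grad = -2.0 * tau * row_gap
    return plan.objective, grad, plan


# ---------------------------------------------------------------------------
# Composite counting loss
# ---------------------------------------------------------------------------


def smooth_l1(x: float, y: float, beta: float = 1.0) -> float:
    """Huber-style smooth L1: quadratic within ``beta`` of zero, linear outside."""
    d = abs(x - y)
    return 0.5 * d * d / beta if d < beta else d - 0.5 * beta


def _smooth_l1_deriv(x: float, y: float, beta: float = 1.0) -> float:
    d = x - y
    return d / beta if abs(d) < beta else float(np.sign(d))


def grid_coords(shape: tuple[int, int]) -> np.ndarray:
    """Pixel-centre (x, y) coordinates of a flattened H x W grid, row-major."""
    H, W = shape
    ys, xs = np.mgrid[0:H, 0:W]
    return np.stack([xs.ravel() + 0.5, ys.ravel() + 0.5], axis=1).astype(np.float64)


def composite_loss(
    pred_density: DensityMap,
    gt_points: PointAnnotation,
    gt_density: DensityMap,
    lambda1: float = 0.1,
    lambda2: float = 0.01,
    eps: float = 0.05,
    tau: float = 0.5,
    cost_kind: str = "perspective",
    tol: float = 1e-6,
    max_iter: int = 300,
) -> LossBreakdown:
    """The composite counting loss: smooth-L1 on totals + weighted UOT + pixel MSE."""
    loss, _, _ = composite_loss_and_grad(
        pred_density, gt_points, gt_density, lambda1, lambda2, eps, tau, cost_kind,
        tol=tol, max_iter=max_iter,
    )
    return loss


def composite_loss_and_grad(
    pred_density: DensityMap,
    gt_points: PointAnnotation,
    gt_density: DensityMap,
    lambda1: float = 0.1,
    lambda2: float = 0.01,
    eps: float = 0.05,
    tau: float = 0.5,
    cost_kind: str = "perspective",
    tol: float = 1e-6,
    max_iter: int = 300,
) -> tuple[LossBreakdown, np.ndarray, TransportPlan | None]:
    """Composite loss plus its gradient with respect to the predicted grid.

    The ground-truth dots are rescaled onto the (possibly strided) grid of
    the prediction; transport runs in grid-cell units with the grid height
    as the perspective reference.
    """
    if pred_density.grid.shape != gt_density.grid.shape:
        raise ValueError(
            f"prediction {pred_density.grid.shape} and ground truth "
            f"{gt_density.grid.shape} shapes differ"
        )
    if pred_density.stride != gt_density.stride:
        raise ValueError("prediction and ground truth strides differ")
    grid = pred_density.grid
    H, W = grid.shape
    count_loss = smooth_l1(float(grid.sum()), float(gt_points.count))
    d_count = _smooth_l1_deriv(float(grid.sum()), float(gt_points.count))

    pixel_mse = float(((grid - gt_density.grid) ** 2).mean())
    d_mse = 2.0 * (grid - gt_density.grid) / grid.size

    plan = None
    if gt_points.count > 0 and grid.size > 0:
        pred = PredictedDensity(grid.ravel(), grid_coords((H, W)))
        dots = TargetDots.from_points(gt_points, scale=1.0 / pred_density.stride)
        ot_loss, ot_grad, plan = uot_loss_and_grad(
            pred, dots, eps=eps, tau=tau, cost_kind=cost_kind, image_height=float(H),
            tol=tol, max_iter=max_iter,
        )
        d_ot = ot_grad.reshape(H, W)
    else:
        # no annotated shoots: transport degenerates, penalize stray mass by L1
        ot_loss = tau * float(grid.sum())
        d_ot = np.full_like(grid, tau)

    breakdown = LossBreakdown(count_loss, ot_loss, pixel_mse, lambda1, lambda2)
    grad = d_count * np.ones_like(grid) + lambda1 * d_ot + lambda2 * d_mse
    return breakdown, grad, plan
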
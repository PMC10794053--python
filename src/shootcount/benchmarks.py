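"""Self-contained validation benchmarks.

Each function here recomputes one of the package's headline checks from
scratch — solver-vs-oracle agreement, the balanced transport limit,
density mass conservation, gradient correctness, count recovery on the
synthetic desk experiment, and the published split/tally arithmetic.  The
test suite and the reproduction script both call these, so the numbers
they report are always produced by running the actual implementation.

The independent oracle for the unbalanced solver is a global stochastic
search (differential evolution) over the plan entries, escalated with
extra restarts (larger population plus Powell polishes from several
starting plans) whenever the first pass disagrees with the solver; the
oracle never calls the solver's own descent.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

from .density import DensityMap, adaptive_sigmas, downsample_density, render_density
from .evaluation import load_reference_tally, split_dataset
from .uot import PredictedDensity, TargetDots, cost_matrix, solve_uot, uot_loss_and_grad, uot_objective

__all__ = [
    "published_split_sizes",
    "reference_tally_sums",
    "uot_oracle_gap",
    "balanced_limit_gap",
    "density_mass_errors",
    "gradient_check",
    "count_recovery",
]


def published_split_sizes() -> dict[int, tuple[int, int, int]]:
    """Apply the 7:1.5:1.5 split rule at the two published dataset sizes."""
    out = {}
    for n in (1860, 313):
        tr, va, te = split_dataset(list(range(n)), (7.0, 1.5, 1.5), seed=0)
        out[n] = (len(tr), len(va), len(te))
    return out


def reference_tally_sums() -> dict[str, int]:
    """Column sums of the shipped 26-image crown-detection tally."""
    df = load_reference_tally()
    return {
        "total": int(df["total"].sum()),
        "yolox_correct": int(df["yolox_correct"].sum()),
        "yolox_false": int(df["yolox_false"].sum()),
        "yolox_missed": int(df["yolox_missed"].sum()),
    }


def _random_instance(rng: np.random.Generator):
    n = int(rng.integers(1, 4))
    m = int(rng.integers(1, 4))
    a = rng.uniform(0.0, 2.0, n)
    b = rng.uniform(0.2, 2.0, m)
    C = rng.uniform(0.1, 3.0, (n, m))
    return a, b, C


def _oracle_objective(a, b, C, eps, tau, seed, strong: bool) -> float:
    n, m = C.shape

    def fun(x):
        return uot_objective(np.abs(x).reshape(n, m), a, b, C, eps, tau)

    hi = float(max(a.max(initial=0.0), b.max(initial=0.0))) * 1.5 + 1.0
    popsize, maxiter = (40, 1500) if strong else (20, 300)
    res = optimize.differential_evolution(
        fun, [(0.0, hi)] * (n * m), seed=seed, tol=1e-12,
        maxiter=maxiter, popsize=popsize, polish=True,
    )
    best = float(res.fun)
    if strong:
        res2 = optimize.differential_evolution(
            fun, [(0.0, hi)] * (n * m), seed=seed + 10007, tol=1e-12,
            maxiter=maxiter, popsize=popsize, polish=True,
        )
        best = min(best, float(res2.fun))
        starts = [
            np.zeros(n * m),
            np.outer(a, b).ravel() / max(b.sum(), 1e-9),
            np.full(n * m, 0.1),
        ]
        mask_rng = np.random.default_rng(seed)
        outer = np.outer(np.maximum(a, 0.1), np.maximum(b, 0.1)).ravel()
        for _ in range(8):  # random support patterns
            starts.append(outer * (mask_rng.uniform(size=n * m) < 0.5))
        for x0 in starts:
            r = optimize.minimize(
                fun, x0, method="Powell",
                options={"xtol": 1e-12, "ftol": 1e-14, "maxiter": 20000, "maxfev": 200000},
            )
            best = min(best, float(r.fun))
    return best


def uot_oracle_gap(n_instances: int = 100, seed: int = 0, eps: float = 0.05, tau: float = 0.5) -> float:
    """Worst relative objective gap |solver - oracle| over random tiny instances.

    Instances have n*m <= 9 entries so the oracle's global search is
    reliable; disagreements above 5e-5 trigger the escalated oracle before
    the gap is recorded.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for k in range(n_instances):
        a, b, C = _random_instance(rng)
        mine = solve_uot(a, b, C, eps, tau).objective
        oracle = _oracle_objective(a, b, C, eps, tau, seed=seed + k, strong=False)
        rel = abs(mine - oracle) / max(abs(oracle), 1.0)
        if rel > 5e-5:
            oracle = min(oracle, _oracle_objective(a, b, C, eps, tau, seed=seed + k, strong=True))
            rel = abs(mine - oracle) / max(abs(oracle), 1.0)
        worst = max(worst, rel)
    return worst


def balanced_limit_gap(n_instances: int = 8, seed: int = 1) -> float:
    """Worst relative gap between UOT transport cost and the balanced LP.

    With tau = 1e3 and eps = 1e-3 on 3x3 instances with equal marginal
    totals, the unbalanced objective's transport term <C, P> should land on
    the classic optimal-transport linear program.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        a = rng.uniform(0.5, 2.0, 3)
        b = rng.uniform(0.5, 2.0, 3)
        b *= a.sum() / b.sum()
        C = rng.uniform(0.1, 3.0, (3, 3))
        plan = solve_uot(a, b, C, eps=1e-3, tau=1e3, tol=1e-9, max_iter=1500, refine=False)
        A_eq = []
        for i in range(3):
            row = np.zeros((3, 3))
            row[i, :] = 1
            A_eq.append(row.ravel())
        for j in range(3):
            col = np.zeros((3, 3))
            col[:, j] = 1
            A_eq.append(col.ravel())
        res = optimize.linprog(
            C.ravel(), A_eq=np.asarray(A_eq), b_eq=np.concatenate([a, b]), bounds=(0, None)
        )
        worst = max(worst, abs(plan.transport_cost - res.fun) / abs(res.fun))
    return worst


def density_mass_errors(n_sets: int = 50, seed: int = 2) -> tuple[float, float]:
    """(max |sum - count| after rendering, max mass change under pooling)."""
    rng = np.random.default_rng(seed)
    worst_render = 0.0
    worst_pool = 0.0
    for _ in range(n_sets):
        n = int(rng.integers(1, 40))
        pts = np.column_stack([rng.uniform(0, 48, n), rng.uniform(0, 48, n)])
        sig = adaptive_sigmas(pts)
        dm = render_density(pts, sig, (48, 48))
        worst_render = max(worst_render, abs(dm.count - n))
        pooled = downsample_density(dm, 4)
        worst_pool = max(worst_pool, abs(pooled.count - dm.count))
    return worst_render, worst_pool


def gradient_check(n_instances: int = 20, seed: int = 3) -> float:
    """Worst relative error of the envelope-rule gradient vs central differences."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(2, 4))
        m = int(rng.integers(1, 3))
        a = rng.uniform(0.1, 1.2, n)
        coords = rng.uniform(0, 8, (n, 2))
        tc = rng.uniform(0, 8, (m, 2))
        C = cost_matrix(coords, tc, "perspective", 8.0)
        dots = TargetDots(np.ones(m), tc)
        _, grad, _ = uot_loss_and_grad(PredictedDensity(a, coords), dots, C)
        h = 1e-5
        for i in range(n):
            ap, am = a.copy(), a.copy()
            ap[i] += h
            am[i] -= h
            lp = uot_loss_and_grad(PredictedDensity(ap, coords), dots, C)[0]
            lm = uot_loss_and_grad(PredictedDensity(am, coords), dots, C)[0]
            fd = (lp - lm) / (2 * h)
            worst = max(worst, abs(grad[i] - fd) / max(abs(fd), 1e-3))
    return worst


def count_recovery(seeds=(1, 2, 3, 4, 5), cost_kinds=("perspective", "exp")) -> dict:
    """Desk-scale training runs: per-seed validation MAE for each cost kind.

    Returns per-kind model/baseline MAE lists plus the number of seeds on
    which the trained model beats the mean-count baseline (computed for the
    first kind, the package default).
    """
    from .experiments import run_desk_experiment

    out: dict = {"seeds": list(seeds)}
    for kind in cost_kinds:
        results = [run_desk_experiment(seed=s, cost_kind=kind) for s in seeds]
        out[kind] = {
            "model_mae": [r.model_mae for r in results],
            "baseline_mae": [r.baseline_mae for r in results],
            "beats_baseline": sum(r.beats_baseline for r in results),
            "mean_model_mae": float(np.mean([r.model_mae for r in results])),
        }
    return out
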
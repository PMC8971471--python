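"""Shuffled-complex-evolution global optimizer with PCA dimension monitoring.

Bounded black-box minimization: a uniformly sampled population is shuffled
into complexes; each complex checks for collapsed search directions via
principal component analysis (re-injecting jitter along lost directions),
evolves by simplex reflection / contraction / mutation, and is topped up by
one draw from the multivariate normal fitted to its points.  The loop stops
when the best value stalls (relative improvement below a tolerance for a
number of consecutive shuffling cycles) or the evaluation budget runs out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SearchSpace",
    "SpuciConfig",
    "OptimizationResult",
    "OptimizationError",
    "initialize_population",
    "shuffle_into_complexes",
    "restore_lost_dimensions",
    "evolve_complex_mcce",
    "resample_multinormal",
    "optimize",
]

#: fraction of total PCA variance below which a direction counts as lost
LOST_DIM_VARIANCE_FRACTION = 1e-6
#: jitter amplitude for restoring lost directions, as fraction of bound width
RESTORE_JITTER_FRACTION = 0.01


class OptimizationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SearchSpace:
    """Box-bounded search space; dimensions flagged integer are rounded
    before every objective evaluation."""

    lower: np.ndarray
    upper: np.ndarray
    integer: np.ndarray | None = None

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        if lo.shape != hi.shape or lo.ndim != 1:
            raise ValueError("lower and upper must be equal-length 1-D arrays")
        if np.any(lo >= hi):
            raise ValueError("require lower < upper in every dimension")
        if self.integer is None:
            object.__setattr__(self, "integer", np.zeros(lo.size, dtype=bool))
        else:
            object.__setattr__(self, "integer", np.asarray(self.integer, dtype=bool))

    @property
    def n(self) -> int:
        return int(self.lower.size)

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def clip(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(x, self.lower, self.upper)
        if self.integer.any():
            x = np.where(self.integer, np.round(x), x)
        return x


@dataclass(frozen=True)
class SpuciConfig:
    """Optimizer settings.

    ``p`` must satisfy both p >= m+1 and p >= n+1 (checked against the
    space at run time).  ``tol_pct`` is the relative improvement (percent)
    below which a shuffling cycle counts as stalled; ``patience_cycles``
    consecutive stalled cycles stop the run.
    """

    m: int = 3
    p: int | None = None  # default 2n+1, resolved against the space
    maxn: int = 10_000
    tol_pct: float = 0.01
    patience_cycles: int = 20
    seed: int = 0
    mcce_steps: int | None = None  # default 2p-1
    mutation: bool = True

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.maxn <= 0:
            raise ValueError("maxn must be positive")

    def resolve_p(self, n_dim: int) -> int:
        p = 2 * n_dim + 1 if self.p is None else self.p
        if p < max(self.m + 1, n_dim + 1):
            raise ValueError(f"p={p} must be >= max(m+1, n+1) = {max(self.m + 1, n_dim + 1)}")
        return p


@dataclass
class OptimizationResult:
    x: np.ndarray
    fun: float
    n_evaluations: int
    converged_by: str  # "tolerance" | "budget"
    history: list[float] = field(default_factory=list)


class _Evaluator:
    """Counts evaluations, clips/rounds proposals, maps failures to +inf
    and tracks the best-ever point."""

    def __init__(self, objective, space: SearchSpace):
        self.objective = objective
        self.space = space
        self.count = 0
        self.best_x: np.ndarray | None = None
        self.best_f = np.inf

    def __call__(self, x: np.ndarray) -> tuple[np.ndarray, float]:
        x = self.space.clip(np.asarray(x, dtype=float))
        self.count += 1
        try:
            f = float(self.objective(x))
        except Exception:
            f = np.inf
        if not np.isfinite(f):
            f = np.inf
        if f < self.best_f:
            self.best_f = f
            self.best_x = x.copy()
        return x, f


def initialize_population(
    space: SearchSpace, config: SpuciConfig, rng: np.random.Generator, evaluator: _Evaluator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform sample of m*p points within bounds, each evaluated once."""
    p = config.resolve_p(space.n)
    N = config.m * p
    pts = rng.uniform(space.lower, space.upper, size=(N, space.n))
    xs = np.empty_like(pts)
    fs = np.empty(N)
    for i in range(N):
        xs[i], fs[i] = evaluator(pts[i])
    return xs, fs


def shuffle_into_complexes(
    points: np.ndarray, values: np.ndarray, m: int, rng: np.random.Generator
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random partition into m complexes, each sorted ascending by objective
    (ties broken by position, i.e. a stable sort)."""
    N = len(values)
    perm = rng.permutation(N)
    complexes = []
    for k in range(m):
        idx = perm[k::m]
        cx, cf = points[idx], values[idx]
        order = np.argsort(cf, kind="stable")
        complexes.append((cx[order], cf[order]))
    return complexes


def restore_lost_dimensions(
    points: np.ndarray,
    values: np.ndarray,
    space: SearchSpace,
    rng: np.random.Generator,
    evaluator: _Evaluator,
) -> tuple[np.ndarray, np.ndarray]:
    """PCA-based degeneracy check: directions carrying less than a tiny
    fraction of total variance are revived by uniform jitter (a small
    fraction of the bound width) injected into the worst half of the
    complex, which is then re-evaluated."""
    s = len(values)
    if s < 2:
        return points, values
    centered = points - points.mean(axis=0)
    # principal directions of the point cloud
    _, sv, vt = np.linalg.svd(centered, full_matrices=True)
    var = np.zeros(space.n)
    var[: sv.size] = sv**2
    total = var.sum()
    lost = var < LOST_DIM_VARIANCE_FRACTION * total if total > 0 else np.ones(space.n, bool)
    if not lost.any():
        return points, values
    points = points.copy()
    values = values.copy()
    worst_half = np.argsort(values, kind="stable")[(s + 1) // 2 :]
    amp = RESTORE_JITTER_FRACTION * space.width
    for i in worst_half:
        x = points[i]
        for d in np.flatnonzero(lost):
            direction = vt[d]
            x = x + rng.uniform(-1.0, 1.0) * (amp * np.abs(direction)).sum() * direction
        points[i], values[i] = evaluator(x)
    order = np.argsort(values, kind="stable")
    return points[order], values[order]


def _triangular_choice(
    s: int, q: int, rng: np.random.Generator
) -> np.ndarray:
    """Pick q distinct ranks out of s with triangular (fitness) weights:
    rank i (0 = best) has probability proportional to s - i."""
    w = (s - np.arange(s)).astype(float)
    return rng.choice(s, size=q, replace=False, p=w / w.sum())


def evolve_complex_mcce(
    points: np.ndarray,
    values: np.ndarray,
    space: SearchSpace,
    rng: np.random.Generator,
    evaluator: _Evaluator,
    n_steps: int,
    mutation: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Simplex evolution of one complex: per step a fitness-weighted
    subsample forms a simplex whose worst vertex is reflected through the
    centroid; failed reflections contract halfway to the centroid; failed
    contractions mutate by a uniform redraw inside the complex's bounding
    box.  Accepted reflections/contractions strictly improve the vertex."""
    points = points.copy()
    values = values.copy()
    s = len(values)
    q = max(2, min(s, space.n + 1))
    for _ in range(n_steps):
        sub = _triangular_choice(s, q, rng)
        worst_pos = sub[np.argmax(values[sub])]
        others = sub[sub != worst_pos]
        centroid = points[others].mean(axis=0)
        fw = values[worst_pos]
        # reflection through the centroid (coefficient 1)
        xr, fr = evaluator(2.0 * centroid - points[worst_pos])
        if fr < fw:
            points[worst_pos], values[worst_pos] = xr, fr
            continue
        # contraction halfway to the centroid
        xc, fc = evaluator(0.5 * (centroid + points[worst_pos]))
        if fc < fw:
            points[worst_pos], values[worst_pos] = xc, fc
            continue
        if mutation:
            lo = points.min(axis=0)
            hi = points.max(axis=0)
            xm, fm = evaluator(rng.uniform(lo, np.maximum(hi, lo + 1e-12)))
            points[worst_pos], values[worst_pos] = xm, fm
    order = np.argsort(values, kind="stable")
    return points[order], values[order]


def resample_multinormal(
    points: np.ndarray,
    values: np.ndarray,
    rng: np.random.Generator,
    evaluator: _Evaluator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one point from the normal fitted to the complex (regularized
    covariance), keep it if it beats the current worst point."""
    mean = points.mean(axis=0)
    if len(values) > 1:
        cov = np.cov(points, rowvar=False)
        cov = np.atleast_2d(cov) + 1e-10 * np.eye(points.shape[1])
    else:
        cov = 1e-10 * np.eye(points.shape[1])
    x, f = evaluator(rng.multivariate_normal(mean, cov, method="eigh"))
    worst = int(np.argmax(values))
    if f < values[worst]:
        points = points.copy()
        values = values.copy()
        points[worst], values[worst] = x, f
        order = np.argsort(values, kind="stable")
        points, values = points[order], values[order]
    return points, values


def optimize(objective, space: SearchSpace, config: SpuciConfig) -> OptimizationResult:
    """Run the full shuffled-complex loop and return the best-ever point."""
    rng = np.random.default_rng(config.seed)
    evaluator = _Evaluator(objective, space)
    p = config.resolve_p(space.n)
    n_steps = config.mcce_steps if config.mcce_steps is not None else 2 * p - 1

    points, values = initialize_population(space, config, rng, evaluator)
    if not np.isfinite(values).any():
        raise OptimizationError("objective failed on every initial point")

    history = [evaluator.best_f]
    stall = 0
    converged_by = "budget"
    while evaluator.count < config.maxn:
        prev_best = evaluator.best_f
        complexes = shuffle_into_complexes(points, values, config.m, rng)
        evolved = []
        for cx, cf in complexes:
            cx, cf = restore_lost_dimensions(cx, cf, space, rng, evaluator)
            cx, cf = evolve_complex_mcce(
                cx, cf, space, rng, evaluator, n_steps, mutation=config.mutation
            )
            cx, cf = resample_multinormal(cx, cf, rng, evaluator)
            evolved.append((cx, cf))
            if evaluator.count >= config.maxn:
                # keep any complexes not yet processed this cycle
                evolved.extend(complexes[len(evolved):])
                break
        points = np.concatenate([c[0] for c in evolved])
        values = np.concatenate([c[1] for c in evolved])
        history.append(evaluator.best_f)
        denom = max(abs(prev_best), 1e-300)
        improvement = (prev_best - evaluator.best_f) / denom
        if improvement < config.tol_pct / 100.0:
            stall += 1
        else:
            stall = 0
        if stall >= config.patience_cycles:
            converged_by = "tolerance"
            break

    return OptimizationResult(
        x=evaluator.best_x,
        fun=evaluator.best_f,
        n_evaluations=evaluator.count,
        converged_by=converged_by,
        history=history,
    )
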
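"""Cost-driven fine-tuning of the spherical-wavefront parameters.

Spectral estimation gives the curvature only to the resolution of the
+1-order support measurement; a residual spherical wavefront survives as
rings in the compensated phase.  Two scalar costs quantify that residual:

* ``J1`` — the count of non-white pixels after Otsu binarization of the
  normalized wrapped phase (a perfectly compensated map binarizes to all
  white, so wraps raise the count);
* ``J2`` — the standard deviation of the wrapped phase (a flat background
  minimizes the spread).

The minimizer family mirrors the common optimization-toolbox lineup:
bounded and unbounded local searches (``FMC``, ``FMU``, ``FSO``), simulated
annealing (``SA``), pattern searches (``PS``, and ``PTS`` with threshold
acceptance), a real-coded genetic algorithm (``GA``), and the hybrid
``GA_PS`` that refines the GA optimum with a pattern search.  Box bounds
default to +/-50% around the seeded curvature; the GA population defaults
to 15.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from scipy import optimize as sciopt
from skimage.filters import threshold_otsu
from skimage.metrics import structural_similarity

from .core import (
    EvaluationFailedError,
    InvalidInputError,
    PhaseMap,
    SphericalWavefront,
)

__all__ = [
    "cost_J1",
    "cost_J2",
    "OptimizationSpec",
    "OptimizationResult",
    "minimize",
    "ssim_metric",
    "ALGORITHMS",
]

ALGORITHMS = ("FMC", "FMU", "FSO", "SA", "PTS", "GA", "PS", "GA_PS")


# ---------------------------------------------------------------------------
# Cost functions
# ---------------------------------------------------------------------------

def cost_J1(phase: PhaseMap) -> int:
    """Phase-wrap count: non-white pixels of the Otsu-binarized phase map.

    The map is normalized to [0, 1] and binarized at Otsu's global
    threshold; residual wraps appear as dark fringes, so the below-threshold
    pixel count grows with miscompensation.  A constant map returns 0 (the
    all-white convention for a perfectly flat result).
    """
    v = phase.values
    span = v.max() - v.min()
    if span <= 0:
        return 0
    norm = (v - v.min()) / span
    thr = threshold_otsu(norm)
    return int(np.count_nonzero(norm <= thr))


def cost_J2(phase: PhaseMap) -> float:
    """Phase standard deviation over all pixels."""
    return float(np.std(phase.values))


_COSTS: dict[str, Callable[[PhaseMap], float]] = {"J1": cost_J1, "J2": cost_J2}


# ---------------------------------------------------------------------------
# Spec / result records
# ---------------------------------------------------------------------------

@dataclass
class OptimizationSpec:
    """What to minimize, how, and from where.

    Bounds per curvature parameter are ``[seed*(1-f), seed*(1+f)]`` with
    ``f = bounds_fraction`` (default 0.5); when ``refine_center`` the vertex
    ``(h, g)`` is searched too, within +/-10% of the image size.
    """

    cost: Literal["J1", "J2"] = "J2"
    algorithm: Literal["FMC", "FMU", "FSO", "SA", "PTS", "GA", "PS", "GA_PS"] = "GA_PS"
    seed_params: SphericalWavefront | None = None
    bounds_fraction: float = 0.5
    ga_population: int = 15
    refine_center: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.cost not in _COSTS:
            raise InvalidInputError(f"unknown cost {self.cost!r}")
        if self.algorithm not in ALGORITHMS:
            raise InvalidInputError(f"unknown algorithm {self.algorithm!r}")
        if not (0 < self.bounds_fraction < 1):
            raise InvalidInputError("bounds_fraction must be in (0, 1)")


@dataclass
class OptimizationResult:
    best: SphericalWavefront
    cost_value: float
    evaluations: int
    trace: list[tuple[tuple[float, ...], float]] = field(default_factory=list)
    converged: bool = True


# ---------------------------------------------------------------------------
# Search engines (vector objective over box bounds)
# ---------------------------------------------------------------------------

class _Tracked:
    """Wrap an objective: count evaluations, record trace and best-ever."""

    def __init__(self, fn: Callable[[np.ndarray], float]):
        self.fn = fn
        self.count = 0
        self.trace: list[tuple[tuple[float, ...], float]] = []
        self.best_x: np.ndarray | None = None
        self.best_f = math.inf

    def __call__(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        f = float(self.fn(x))
        self.count += 1
        if not math.isfinite(f):
            raise EvaluationFailedError(f"non-finite cost {f} at parameters {x.tolist()}")
        self.trace.append((tuple(x.tolist()), f))
        if f < self.best_f:
            self.best_f, self.best_x = f, x.copy()
        return f


def _pattern_search(
    f: _Tracked,
    x0: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    step_frac: float = 0.25,
    rel_tol: float = 1e-7,
    max_evals: int = 4000,
    rng: np.random.Generator | None = None,
    threshold_frac: float = 0.0,
) -> None:
    """Compass (coordinate-poll) pattern search with step halving.

    ``threshold_frac > 0`` turns it into a threshold-accepting variant:
    moves worsening the incumbent by less than the (decaying) threshold are
    accepted, which lets the poll walk out of shallow basins; the best-ever
    point is tracked separately by the objective wrapper.
    """
    span = ub - lb
    x = np.clip(x0, lb, ub)
    fx = f(x)
    step = step_frac * span
    threshold = threshold_frac * max(abs(fx), 1e-12)
    dim = len(x)
    while f.count < max_evals and np.max(step / np.maximum(span, 1e-300)) > rel_tol:
        directions = [(i, s) for i in range(dim) for s in (+1.0, -1.0)]
        if rng is not None:
            rng.shuffle(directions)
        moved = False
        for i, s in directions:
            xt = x.copy()
            xt[i] = np.clip(xt[i] + s * step[i], lb[i], ub[i])
            if xt[i] == x[i]:
                continue
            ft = f(xt)
            if ft < fx + threshold:
                x, fx = xt, ft
                moved = True
                break  # opportunistic poll
            if f.count >= max_evals:
                break
        if not moved:
            step *= 0.5
            threshold *= 0.5


def _genetic(
    f: _Tracked,
    lb: np.ndarray,
    ub: np.ndarray,
    rng: np.random.Generator,
    pop_size: int = 15,
    max_gen: int = 200,
    stall_gen: int = 50,
    rel_tol: float = 1e-6,
    n_immigrants: int = 3,
    x0: np.ndarray | None = None,
) -> bool:
    """Real-coded genetic algorithm with elitism over box bounds.

    Tournament selection (size 3), BLX-alpha blend crossover, per-gene
    Gaussian mutation with a geometrically decaying scale (floored at 2% of
    the box span), one elite copied unchanged, and ``n_immigrants`` fresh
    uniform samples injected each generation.  The immigrants keep global
    coverage alive on the wrap-saturated plateau that surrounds the narrow
    basin of a strongly aberrated phase map, where selection pressure alone
    would collapse the population prematurely.  Converged when the relative
    best-cost improvement over ``stall_gen`` generations drops below
    ``rel_tol`` (cap ``max_gen``); the stall window and cap follow the
    common optimization-toolbox defaults for a two-variable search.
    """
    dim = len(lb)
    span = ub - lb
    pop = rng.uniform(lb, ub, size=(pop_size, dim))
    if x0 is not None:
        pop[0] = np.clip(x0, lb, ub)
    fit = np.array([f(ind) for ind in pop])
    history = [fit.min()]
    for gen in range(max_gen):
        order = np.argsort(fit)
        elite = pop[order[0]].copy()
        sigma = np.maximum(0.1 * span * (0.97**gen), 0.02 * span)
        children = [elite]
        children += list(rng.uniform(lb, ub, size=(min(n_immigrants, pop_size - 1), dim)))
        while len(children) < pop_size:
            pick = lambda: pop[min(rng.integers(0, pop_size, 3), key=lambda i: fit[i])]
            p1, p2 = pick(), pick()
            lo, hi = np.minimum(p1, p2), np.maximum(p1, p2)
            d = hi - lo
            child = rng.uniform(lo - 0.5 * d, hi + 0.5 * d)
            mutate = rng.random(dim) < 0.4
            child = child + mutate * rng.normal(0.0, 1.0, dim) * sigma
            children.append(np.clip(child, lb, ub))
        pop = np.array(children)
        fit = np.array([f(ind) for ind in pop])
        history.append(min(history[-1], fit.min()))
        if gen + 1 >= stall_gen:
            past, now = history[-stall_gen - 1], history[-1]
            if (past - now) / max(abs(past), 1e-12) < rel_tol:
                return True
    return False


def _run_algorithm(
    algorithm: str,
    f: _Tracked,
    x0: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    rng_seed: int,
    ga_population: int,
) -> bool:
    """Dispatch one search; the wrapper ``f`` keeps the best-ever point."""
    bounds = sciopt.Bounds(lb, ub)
    converged = True
    if algorithm == "FMC":
        res = sciopt.minimize(f, x0, method="Powell", bounds=bounds)
        converged = bool(res.success)
    elif algorithm == "FMU":
        res = sciopt.minimize(f, x0, method="Nelder-Mead")
        converged = bool(res.success)
        # unbounded search: honour the box contract by re-entering the box
        clipped = np.clip(res.x, lb, ub)
        if not np.array_equal(clipped, res.x):
            f(clipped)
    elif algorithm == "FSO":
        res = sciopt.minimize(f, x0, method="Nelder-Mead", bounds=bounds)
        converged = bool(res.success)
    elif algorithm == "SA":
        sciopt.dual_annealing(
            f, bounds=list(zip(lb, ub)), x0=x0, seed=rng_seed, maxiter=120,
        )
        # deterministic descent polish from the annealer's best point
        _pattern_search(f, f.best_x.copy(), lb, ub, step_frac=0.05)
    elif algorithm == "PS":
        _pattern_search(f, x0, lb, ub)
    elif algorithm == "PTS":
        _pattern_search(
            f, x0, lb, ub,
            rng=np.random.default_rng(rng_seed), threshold_frac=0.05,
        )
    elif algorithm == "GA":
        converged = _genetic(
            f, lb, ub, np.random.default_rng(rng_seed),
            pop_size=ga_population, x0=x0,
        )
    elif algorithm == "GA_PS":
        converged = _genetic(
            f, lb, ub, np.random.default_rng(rng_seed),
            pop_size=ga_population, x0=x0,
        )
        # fine-tuning pattern search restarted from the GA optimum
        _pattern_search(f, f.best_x.copy(), lb, ub, step_frac=0.05)
    return converged


# ---------------------------------------------------------------------------
# Public entry point
# ---------------------------------------------------------------------------

def minimize(
    spec: OptimizationSpec,
    evaluate: Callable[[SphericalWavefront], PhaseMap],
) -> OptimizationResult:
    """Search the spherical-wavefront parameters minimizing the chosen cost.

    ``evaluate`` must be a pure function mapping a candidate wavefront to
    the compensated phase map for fixed input data.  The search covers
    ``(C_x, C_y)`` — plus ``(h, g)`` when ``spec.refine_center`` — inside
    the box bounds; results are reproducible for a fixed ``rng_seed``.
    """
    seed = spec.seed_params
    if seed is None or seed.telecentric:
        raise InvalidInputError("optimization needs a non-telecentric seed wavefront")

    f_frac = spec.bounds_fraction
    names = ["C_x", "C_y"]
    x0 = [seed.C_x, seed.C_y]
    lb = [seed.C_x * (1 - f_frac), seed.C_y * (1 - f_frac)]
    ub = [seed.C_x * (1 + f_frac), seed.C_y * (1 + f_frac)]
    if spec.refine_center:
        probe = evaluate(seed)
        Y, X = probe.values.shape
        h = seed.h if seed.h is not None else X / 2
        g = seed.g if seed.g is not None else Y / 2
        names += ["h", "g"]
        x0 += [h, g]
        lb += [h - 0.1 * X, g - 0.1 * Y]
        ub += [h + 0.1 * X, g + 0.1 * Y]
    x0, lb, ub = map(np.asarray, (x0, lb, ub))

    cost_fn = _COSTS[spec.cost]

    def to_sphere(x: np.ndarray) -> SphericalWavefront:
        s = seed.with_curvatures(float(x[0]), float(x[1]))
        if spec.refine_center:
            s = s.with_center(float(x[2]), float(x[3]))
        return s

    tracked = _Tracked(lambda x: cost_fn(evaluate(to_sphere(x))))
    converged = _run_algorithm(
        spec.algorithm, tracked, x0, lb, ub, spec.rng_seed, spec.ga_population
    )

    best_x = np.clip(tracked.best_x, lb, ub)
    if not np.array_equal(best_x, tracked.best_x):
        tracked(best_x)  # cost_value must belong to the in-bounds point
        best_x = np.clip(tracked.best_x, lb, ub)
    best = to_sphere(best_x)
    return OptimizationResult(
        best=best,
        cost_value=tracked.best_f,
        evaluations=tracked.count,
        trace=tracked.trace,
        converged=converged,
    )


def ssim_metric(a: PhaseMap, b: PhaseMap) -> float:
    """Structural similarity of two phase maps on a common [0, 1] scale.

    Both maps are rescaled jointly (shared min/max) before the standard
    SSIM with its default constants (K1=0.01, K2=0.03, 7x7 window) and
    ``data_range=1``.  Two identical constant maps score 1.
    """
    if a.values.shape != b.values.shape:
        raise InvalidInputError("phase map shapes differ")
    lo = min(a.values.min(), b.values.min())
    hi = max(a.values.max(), b.values.max())
    if hi <= lo:
        return 1.0
    av = (a.values - lo) / (hi - lo)
    bv = (b.values - lo) / (hi - lo)
    return float(structural_similarity(av, bv, data_range=1.0))
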
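"""6-DOF intensity-based pose search.

The objective renders AP and LA DRRs of the CT volume at a candidate pose,
builds effective (instrument-masked) image pairs against the radiographs,
and scores them with the chosen similarity measure averaged over the two
views. Three derivative-free optimizers maximize this score inside a
symmetric box around the initial pose: Powell's direction-set method with
bounded line searches, the Nelder-Mead downhill simplex with clamped
vertices, and a real-coded genetic algorithm (tournament selection, blend
crossover, Gaussian mutation, elitism) optionally polished by a simplex run.

Powell and Nelder-Mead are driven through scipy.optimize; the GA is
implemented here. All optimizers share one contract: they never return a
pose scoring below the initial pose, the final pose satisfies the bounds,
and with a fixed seed the whole search is reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .drr import RoiBox, Volume, render_drr
from .geometry import Pose
from .masking import make_effective_pair
from .similarity import biplanar_score

__all__ = ["SearchBounds", "RegistrationResult", "Objective", "objective",
           "optimize_powell", "optimize_simplex", "optimize_ga", "register",
           "OPTIMIZERS"]

DEFAULT_FTOL = 1e-5
DEFAULT_XTOL = 0.01
DEFAULT_BUDGET = 2000


@dataclass(frozen=True)
class SearchBounds:
    """Symmetric search box around the initial pose: +-displacement_limit mm
    on each translation, +-angle_limit degrees on each rotation."""

    displacement_limit: float = 5.0
    angle_limit: float = 5.0

    def __post_init__(self):
        if self.displacement_limit <= 0 or self.angle_limit <= 0:
            raise ValueError("search limits must be positive")

    def half_widths(self) -> np.ndarray:
        return np.array([self.displacement_limit] * 3 + [self.angle_limit] * 3)

    def box(self, center_params: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = self.half_widths()
        return center_params - h, center_params + h

    def contains(self, params: np.ndarray, center_params: np.ndarray,
                 tol: float = 1e-9) -> bool:
        lo, hi = self.box(center_params)
        return bool(np.all(params >= lo - tol) and np.all(params <= hi + tol))


@dataclass
class RegistrationResult:
    """Outcome of one pose search."""

    pose: Pose
    T_2d3d: np.ndarray
    score: float
    evaluations: int
    converged: bool
    trace: list = field(default_factory=list)


class Objective:
    """Callable biplanar similarity objective with evaluation bookkeeping."""

    def __init__(self, vol: Volume, roi: RoiBox, ap, la, measure: str = "ncc",
                 step: float | None = None, measure_kwargs: dict | None = None):
        # ap / la: (image, ProjectionModel, instrument_mask-or-None)
        self.vol = vol
        self.roi = roi
        self.ap_image, self.ap_model, self.ap_mask = ap
        self.la_image, self.la_model, self.la_mask = la
        self.measure = measure
        self.step = step
        self.measure_kwargs = measure_kwargs or {}
        self.evaluations = 0
        self.trace: list[tuple[np.ndarray, float]] = []

    def __call__(self, pose: Pose) -> float:
        ap_drr = render_drr(self.vol, pose, self.ap_model, self.roi, step=self.step)
        la_drr = render_drr(self.vol, pose, self.la_model, self.roi, step=self.step)
        ap_pair = make_effective_pair(self.ap_image, ap_drr, self.ap_mask)
        la_pair = make_effective_pair(self.la_image, la_drr, self.la_mask)
        score = biplanar_score(ap_pair, la_pair, self.measure, **self.measure_kwargs)
        self.evaluations += 1
        self.trace.append((pose.params, score))
        return score


def objective(pose: Pose, vol: Volume, roi: RoiBox, ap, la, measure: str = "ncc",
              step: float | None = None) -> float:
    """One-shot evaluation of the biplanar similarity at ``pose``."""
    return Objective(vol, roi, ap, la, measure, step)(pose)


def _make_result(obj, initial: Pose, best_params, best_score, converged) -> RegistrationResult:
    pose = initial.with_params(best_params)
    return RegistrationResult(pose=pose, T_2d3d=pose.to_matrix(), score=float(best_score),
                              evaluations=getattr(obj, "evaluations", 0),
                              converged=bool(converged),
                              trace=list(getattr(obj, "trace", [])))


class _Tracker:
    """Wraps the objective for a scipy minimizer: negates (scipy minimizes),
    clamps to the box, and keeps the incumbent best."""

    def __init__(self, obj, initial: Pose, lo, hi, budget):
        self.obj = obj
        self.initial = initial
        self.lo, self.hi = lo, hi
        self.budget = budget
        self.best_params = initial.params
        self.best_score = -np.inf
        self.calls = 0

    def __call__(self, x):
        if self.calls >= self.budget:
            raise _BudgetExhausted
        self.calls += 1
        xc = np.clip(x, self.lo, self.hi)
        s = self.obj(self.initial.with_params(xc))
        if s > self.best_score:
            self.best_score = s
            self.best_params = xc.copy()
        return -s


class _BudgetExhausted(Exception):
    pass


def _resolve_box(initial, bounds, box_center, budget):
    """Search box center defaults to the initial pose itself."""
    if budget < 0:
        raise ValueError("evaluation budget must be >= 0")
    center = initial.params if box_center is None else np.asarray(box_center, float)
    if not bounds.contains(initial.params, center):
        raise ValueError("initial pose outside the search bounds")
    return bounds.box(center)


def optimize_powell(obj, initial: Pose, bounds: SearchBounds, ftol: float = DEFAULT_FTOL,
                    xtol: float = DEFAULT_XTOL, budget: int = DEFAULT_BUDGET,
                    box_center=None) -> RegistrationResult:
    """Powell direction-set ascent with bounded Brent line searches."""
    lo, hi = _resolve_box(initial, bounds, box_center, budget)
    if budget == 0:
        s = obj(initial)
        return _make_result(obj, initial, initial.params, s, False)
    tr = _Tracker(obj, initial, lo, hi, budget)
    converged = False
    try:
        res = optimize.minimize(tr, initial.params, method="Powell",
                                bounds=optimize.Bounds(lo, hi),
                                options={"ftol": ftol, "xtol": xtol,
                                         "maxfev": budget, "maxiter": budget})
        converged = bool(res.success)
    except _BudgetExhausted:
        pass
    return _make_result(tr.obj, initial, tr.best_params, tr.best_score, converged)


def optimize_simplex(obj, initial: Pose, bounds: SearchBounds, ftol: float = DEFAULT_FTOL,
                     xtol: float = DEFAULT_XTOL, budget: int = DEFAULT_BUDGET,
                     simplex_scale: float = 0.5, max_restarts: int = 4,
                     box_center=None) -> RegistrationResult:
    """Nelder-Mead downhill simplex (reflection 1, expansion 2, contraction
    0.5, shrink 0.5) with restarts.

    The initial simplex edge is ``simplex_scale`` of each bound half-width
    and vertices are clamped to the box. After each convergence the search
    is restarted from the incumbent best with a fresh (10% half-width)
    simplex — the standard guard against a collapsed simplex stalling on a
    premature point — until a restart improves the score by less than
    ``ftol``, ``max_restarts`` is reached, or the evaluation budget is
    spent."""
    lo, hi = _resolve_box(initial, bounds, box_center, budget)
    if budget == 0:
        s = obj(initial)
        return _make_result(obj, initial, initial.params, s, False)
    tr = _Tracker(obj, initial, lo, hi, budget)
    converged = False
    scale = simplex_scale
    prev_best = -np.inf
    try:
        for _ in range(max_restarts + 1):
            x0 = tr.best_params if np.isfinite(tr.best_score) else initial.params
            edges = scale * bounds.half_widths()
            simplex = np.vstack([x0] + [x0 + np.eye(6)[i] * edges[i] for i in range(6)])
            # keep vertices distinct when x0 touches the upper bound
            for i in range(6):
                if np.allclose(simplex[i + 1], np.clip(simplex[i + 1], lo, hi)):
                    continue
                simplex[i + 1] = x0 - np.eye(6)[i] * edges[i]
            simplex = np.clip(simplex, lo, hi)
            res = optimize.minimize(tr, x0, method="Nelder-Mead",
                                    bounds=optimize.Bounds(lo, hi),
                                    options={"initial_simplex": simplex, "fatol": ftol,
                                             "xatol": xtol, "maxfev": budget - tr.calls,
                                             "maxiter": budget})
            converged = bool(res.success)
            if tr.best_score - prev_best < ftol:
                break
            prev_best = tr.best_score
            scale = 0.1
    except _BudgetExhausted:
        pass
    return _make_result(tr.obj, initial, tr.best_params, tr.best_score, converged)


@dataclass
class GaParams:
    population: int = 40
    generations: int = 30
    tournament_k: int = 3
    crossover_alpha: float = 0.5
    mutation_sigma_frac: float = 0.05  # of the bound half-width, per gene
    mutation_rate: float = 0.1
    elitism: int = 2
    polish: bool = True

    def validate(self):
        if self.population < 2:
            raise ValueError("degenerate GA parameters: population must be >= 2")
        if self.mutation_rate <= 0 and self.crossover_alpha <= 0 and self.elitism >= self.population:
            raise ValueError("degenerate GA parameters: search cannot move")
        if self.generations < 1 or self.tournament_k < 1:
            raise ValueError("degenerate GA parameters")


def optimize_ga(obj, initial: Pose, bounds: SearchBounds, seed: int,
                params: GaParams | None = None, budget: int = DEFAULT_BUDGET,
                box_center=None) -> RegistrationResult:
    """Real-coded genetic algorithm over the bounded pose box.

    Tournament selection, blend (BLX-alpha) crossover, per-gene Gaussian
    mutation, elitism; children clamped to the box. The initial pose is
    injected into the first population so the best-so-far can never fall
    below it. The best individual is optionally polished by a short simplex
    run within the remaining budget.
    """
    params = params or GaParams()
    params.validate()
    lo, hi = _resolve_box(initial, bounds, box_center, budget)
    if budget == 0:
        s = obj(initial)
        return _make_result(obj, initial, initial.params, s, False)
    rng = np.random.default_rng(seed)
    h = bounds.half_widths()
    npop = params.population

    pop = rng.uniform(lo, hi, size=(npop, 6))
    pop[0] = initial.params
    spent = 0

    def score_all(P):
        nonlocal spent
        out = np.empty(len(P))
        for i, x in enumerate(P):
            if spent >= budget:
                out[i:] = -np.inf
                break
            out[i] = obj(initial.with_params(x))
            spent += 1
        return out

    fit = score_all(pop)
    best_i = int(np.argmax(fit))
    best_x, best_s = pop[best_i].copy(), float(fit[best_i])

    for _ in range(params.generations):
        if spent >= budget:
            break
        order = np.argsort(fit)[::-1]
        new = [pop[i].copy() for i in order[:params.elitism]]
        while len(new) < npop:
            idx_a = rng.integers(0, npop, size=params.tournament_k)
            idx_b = rng.integers(0, npop, size=params.tournament_k)
            pa = pop[idx_a[np.argmax(fit[idx_a])]]
            pb = pop[idx_b[np.argmax(fit[idx_b])]]
            # BLX-alpha blend crossover
            cmin, cmax = np.minimum(pa, pb), np.maximum(pa, pb)
            span = cmax - cmin
            child = rng.uniform(cmin - params.crossover_alpha * span,
                                cmax + params.crossover_alpha * span)
            mutate = rng.random(6) < params.mutation_rate
            child = child + mutate * rng.normal(0.0, params.mutation_sigma_frac * h)
            new.append(np.clip(child, lo, hi))
        pop = np.array(new)
        fit = score_all(pop)
        gi = int(np.argmax(fit))
        if fit[gi] > best_s:
            best_s, best_x = float(fit[gi]), pop[gi].copy()

    converged = spent < budget
    if params.polish and spent < budget:
        res = optimize_simplex(obj, initial.with_params(best_x), SearchBounds(
            bounds.displacement_limit, bounds.angle_limit),
            budget=budget - spent)
        # polish searches its own box around best_x; clamp back to ours
        cand = np.clip(res.pose.params, lo, hi)
        if np.allclose(cand, res.pose.params):
            if res.score > best_s:
                best_s, best_x = res.score, res.pose.params
        else:
            s = obj(initial.with_params(cand))
            if s > best_s:
                best_s, best_x = s, cand
        converged = converged and res.converged
    return _make_result(obj, initial, best_x, best_s, converged)


OPTIMIZERS = ("powell", "simplex", "ga")


def register(vol: Volume, roi: RoiBox, ap, la, initial: Pose, measure: str = "ncc",
             optimizer: str = "simplex", bounds: SearchBounds | None = None,
             step: float | None = None, seed: int = 0, ftol: float = DEFAULT_FTOL,
             xtol: float = DEFAULT_XTOL, budget: int = DEFAULT_BUDGET,
             ga_params: GaParams | None = None,
             measure_kwargs: dict | None = None) -> RegistrationResult:
    """Run one full 2D/3D registration.

    ``ap`` and ``la`` are (image, ProjectionModel, instrument_mask-or-None)
    triples. The result's ``T_2d3d`` maps CT coordinates into the
    C-arm/world frame.
    """
    if optimizer not in OPTIMIZERS:
        raise ValueError(f"unknown optimizer {optimizer!r}; valid options: {list(OPTIMIZERS)}")
    bounds = bounds or SearchBounds()
    obj = Objective(vol, roi, ap, la, measure=measure, step=step,
                    measure_kwargs=measure_kwargs)
    if optimizer == "powell":
        return optimize_powell(obj, initial, bounds, ftol=ftol, xtol=xtol, budget=budget)
    if optimizer == "simplex":
        return optimize_simplex(obj, initial, bounds, ftol=ftol, xtol=xtol, budget=budget)
    return optimize_ga(obj, initial, bounds, seed=seed, params=ga_params, budget=budget)
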
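"""Dynamic ensemble pruning with a bi-objective fruit-fly optimizer (BOFOA).

Each of the D latent subspaces gets its own subswarm of fruit flies. A fly
occupies a 2M-coordinate position (X, Y per base partition); the distance
of each (X^m, Y^m) pair from the origin is converted into a smell
S^m = 1 / (sqrt(X^2 + Y^2) + eps), and smells above 0.5 switch the m-th base
partition on — the fly's binary pruning mask. A mask is scored by the mean
(Dev, Cp) of its selected base partitions on the subspace data, signed by
the global optimization direction. The search alternates an olfactory phase —
offspring scattered around the subswarm's best with a step that grows as
omega = alpha^((FEs-1)/MaxFEs) — and a vision phase (Pareto-dominance
replacement), with a ring exchange of best individuals between subswarms to
keep diversity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble import ClusterEnsemble
from .latent import LatentSpaces, _child_seed
from .objectives import ObjectivePair, evaluate_mask, member_objectives

__all__ = [
    "Fly",
    "Subswarm",
    "PruningResult",
    "init_population",
    "smell",
    "pruning_code",
    "balance_factor",
    "olfactory_step",
    "dominates",
    "vision_update",
    "exchange_information",
    "prune",
]

DEFAULT_BOUNDS = (0.0, 2.0)


@dataclass
class Fly:
    X: np.ndarray
    Y: np.ndarray
    smells: np.ndarray = field(default=None)  # type: ignore[assignment]
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    objectives: ObjectivePair | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.smells is None:
            self.smells = smell(self.X, self.Y)
        if self.mask is None:
            self.mask = pruning_code(self.smells)


@dataclass
class Subswarm:
    flies: list[Fly]
    subspace_index: int
    best: Fly | None = None


@dataclass
class PruningResult:
    selected: dict[int, np.ndarray]
    pruned_ensemble: ClusterEnsemble
    archive: list[tuple[int, np.ndarray, ObjectivePair]]
    trace: list[list[tuple[float, float]]]


def smell(
    X: np.ndarray, Y: np.ndarray, eps_smell: float = 1e-6, form: str = "inverse_dist"
) -> np.ndarray:
    """Flavor concentration S^m from the coordinates of each (X^m, Y^m) pair.

    ``inverse_dist`` (default): 1 / (sqrt(X^2 + Y^2) + eps) — the original
    fruit-fly S = 1/Dist with a pole guard. ``inverse_square``:
    1 / (X^2 + Y^2 + eps).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise ValueError("non-finite fly coordinates")
    if form == "inverse_dist":
        return 1.0 / (np.sqrt(X**2 + Y**2) + eps_smell)
    if form == "inverse_square":
        return 1.0 / (X**2 + Y**2 + eps_smell)
    raise ValueError(f"unknown smell form {form!r}")


def pruning_code(smells: np.ndarray) -> np.ndarray:
    """Discretize smells into a selection mask: bit m set iff S^m > 0.5.

    An all-zero mask would select no base partition at all; it is repaired
    to all-ones (the full ensemble)."""
    smells = np.asarray(smells, dtype=float)
    bits = smells > 0.5
    if not bits.any():
        bits = np.ones_like(bits, dtype=bool)
    return bits


def balance_factor(FEs: int, MaxFEs: int, alpha: float = 13.0) -> float:
    """Exploration/exploitation step scale omega = alpha^((FEs-1)/MaxFEs).

    Equals 1 at the first iteration and approaches alpha as FEs reaches
    MaxFEs + 1; with alpha > 1 the olfactory step therefore widens over the
    course of the run."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if not 1 <= FEs:
        raise ValueError("FEs must be >= 1")
    return float(np.exp(((FEs - 1) / MaxFEs) * np.log(alpha)))


def init_population(
    D: int,
    G: int | list[int],
    M: int,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    seed: int = 0,
) -> list[Subswarm]:
    """Create D subswarms of flies with uniformly scattered coordinates.

    Coordinates follow X^m = X_min + rand(-1, 1) * (X_max - X_min), clamped
    to the bounds. The first fly of every subswarm is pinned at the origin
    so its mask selects the full ensemble.
    """
    sizes = [G] * D if isinstance(G, int) else list(G)
    if len(sizes) != D or sum(sizes) == 0:
        raise ValueError("population must contain at least one fly")
    lo, hi = bounds
    rng = np.random.default_rng(_child_seed(seed, 7))
    subswarms = []
    for d in range(D):
        flies = []
        for g in range(sizes[d]):
            if g == 0:
                X = np.zeros(M)
                Y = np.zeros(M)
            else:
                X = np.clip(lo + rng.uniform(-1, 1, M) * (hi - lo), lo, hi)
                Y = np.clip(lo + rng.uniform(-1, 1, M) * (hi - lo), lo, hi)
            flies.append(Fly(X, Y))
        subswarms.append(Subswarm(flies, subspace_index=d))
    return subswarms


def olfactory_step(
    best: Fly,
    omega: float,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> Fly:
    """Offspring scattered around the best fly: X_new = X_best + omega * U(-1,1)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    lo, hi = bounds
    M = best.X.size
    X = np.clip(best.X + omega * rng.uniform(-1, 1, M), lo, hi)
    Y = np.clip(best.Y + omega * rng.uniform(-1, 1, M), lo, hi)
    return Fly(X, Y)


def dominates(a: ObjectivePair, b: ObjectivePair) -> bool:
    """Pareto dominance on the signed (dev, cp) pair (minimization)."""
    if a.direction != b.direction:
        raise ValueError("cannot compare objective pairs with mixed directions")
    sa, sb = a.signed, b.signed
    return sa[0] <= sb[0] and sa[1] <= sb[1] and (sa[0] < sb[0] or sa[1] < sb[1])


def _better_best(candidate: Fly, incumbent: Fly | None) -> bool:
    if incumbent is None or incumbent.objectives is None:
        return True
    return dominates(candidate.objectives, incumbent.objectives)


def _tie_key(fly: Fly, idx: int) -> tuple[float, float, int]:
    s = fly.objectives.signed
    return (s[0], s[1], idx)


def vision_update(sub: Subswarm, offspring: list[Fly]) -> Subswarm:
    """Greedy vision phase: a fly is replaced by its offspring only when the
    offspring dominates it; the subswarm's best is updated the same way,
    with ties broken by smaller signed dev, then cp, then fly index."""
    new_flies = []
    for fly, child in zip(sub.flies, offspring):
        if (
            fly.objectives is not None
            and child.objectives is not None
            and dominates(child.objectives, fly.objectives)
        ):
            new_flies.append(child)
        else:
            new_flies.append(fly)
    best = sub.best
    improvers = [
        (i, f) for i, f in enumerate(new_flies) if f.objectives is not None
        and _better_best(f, best)
    ]
    if improvers:
        _, best = min(improvers, key=lambda t: _tie_key(t[1], t[0]))
    return Subswarm(new_flies, sub.subspace_index, best)


def exchange_information(subswarms: list[Subswarm], evaluator=None) -> list[Subswarm]:
    """Ring exchange: a copy of subswarm i's best joins subswarm (i+1) mod D.

    The traveling fly keeps its mask; its objectives are re-evaluated
    against the destination subspace (via ``evaluator(subspace_index,
    mask)``) and it replaces the destination's last fly. The destination's
    tracked best is updated only if the incomer dominates it, so elitism is
    preserved.
    """
    D = len(subswarms)
    if D < 2:
        return subswarms
    out = []
    for i, sub in enumerate(subswarms):
        donor = subswarms[(i - 1) % D].best
        if donor is None:
            out.append(sub)
            continue
        incomer = Fly(donor.X.copy(), donor.Y.copy())
        if evaluator is not None:
            incomer.objectives = evaluator(sub.subspace_index, incomer.mask)
        flies = sub.flies[:-1] + [incomer]
        best = sub.best
        if incomer.objectives is not None and _better_best(incomer, best):
            best = incomer
        out.append(Subswarm(flies, sub.subspace_index, best))
    return out


def prune(
    ensemble: ClusterEnsemble,
    Z: LatentSpaces,
    direction: int = 1,
    max_fes: int = 20,
    alpha: float = 13.0,
    flies: int = 9,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    seed: int = 0,
) -> PruningResult:
    """Run the full BOFOA search and return the pruned ensemble.

    One subswarm per latent subspace; subswarm sizes differ by at most one
    fly when D does not divide ``flies``. Every member partition's (Dev, Cp)
    on its subspace is computed once up front; a mask's objective pair is
    the mean over its selected members, so evaluations are cheap and
    memoizable per (subspace, mask).
    """
    groups = ensemble.by_subspace()
    D = len(groups)
    order = sorted(groups)
    sizes = [flies // D + (1 if i < flies % D else 0) for i in range(D)]
    if min(sizes) < 1:
        raise ValueError("need at least one fly per subswarm")
    M = len(groups[order[0]])
    if any(len(groups[s]) != M for s in order):
        raise ValueError("subspaces must contribute equal partition counts")

    member_scores = {
        s: member_objectives(groups[s], Z.spaces[s]) for s in order
    }
    cache: dict[tuple[int, bytes], ObjectivePair] = {}

    def evaluator(subspace_index: int, mask: np.ndarray) -> ObjectivePair:
        key = (subspace_index, np.packbits(mask).tobytes())
        if key not in cache:
            cache[key] = evaluate_mask(
                mask, groups[subspace_index], Z.spaces[subspace_index],
                direction=direction, precomputed=member_scores[subspace_index],
            )
        return cache[key]

    rng = np.random.default_rng(_child_seed(seed, 11))
    subswarms = init_population(D, sizes, M, bounds, seed=seed)
    for sub in subswarms:
        for fly in sub.flies:
            fly.objectives = evaluator(sub.subspace_index, fly.mask)
        sub_upd = vision_update(Subswarm(sub.flies, sub.subspace_index, None), sub.flies)
        sub.best = sub_upd.best

    trace: list[list[tuple[float, float]]] = []
    for fes in range(1, max_fes + 1):
        omega = balance_factor(fes, max_fes, alpha)
        new_subswarms = []
        for sub in subswarms:
            offspring = [
                olfactory_step(sub.best, omega, bounds, rng=rng) for _ in sub.flies
            ]
            for child in offspring:
                child.objectives = evaluator(sub.subspace_index, child.mask)
            new_subswarms.append(vision_update(sub, offspring))
        subswarms = exchange_information(new_subswarms, evaluator)
        trace.append([(s.best.objectives.dev, s.best.objectives.cp) for s in subswarms])

    selected = {s.subspace_index: s.best.mask.copy() for s in subswarms}
    chosen_parts = []
    for s in subswarms:
        parts = groups[s.subspace_index]
        chosen_parts += [p for p, m in zip(parts, s.best.mask) if m]
    pruned = ClusterEnsemble(chosen_parts, D=D, T=max(len(groups[s]) for s in order))

    bests = [(s.subspace_index, s.best.mask.copy(), s.best.objectives) for s in subswarms]
    archive = [
        b for b in bests
        if not any(dominates(o[2], b[2]) for o in bests if o is not b)
    ]
    return PruningResult(selected, pruned, archive, trace)
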
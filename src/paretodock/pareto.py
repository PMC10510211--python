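"""Multi-objective optimal-affinity engine.

Each ligand is a point (f1, f2) of aggregated affinity magnitudes
(kcal/mol): f1 in the desired environment (acidic pH, maximize) and f2 in
the undesired one (neutral pH, minimize). A ligand *dominates* another when
it is at least as good in both objectives and strictly better in one; the
Pareto front is the set of non-dominated ligands — the candidates for which
no other ligand offers higher acidic affinity without also higher neutral
affinity.

Provided here:

* exact front computation by an O(n log n) sweep (sort by f2, scan max f1),
  with an O(n²) pairwise oracle retained for testing;
* λ-scalarization ``max λ·f1 − (1−λ)·f2`` and a grid sweep over λ ∈ [0, 1],
  which recovers exactly the *supported* (convex-hull) front members —
  unsupported non-dominated points exist and only dominance enumeration
  finds them;
* ε-relaxed fronts, either as successive non-domination layers (second
  best, third best, ...) or by an additive tolerance in objective space;
* a minimum-acidic-affinity constraint α (pH specificity is worthless if
  binding in the desired environment is too weak);
* the top-hit selection rule used for large-library screens: among ligands
  with neutral magnitude below a cap, rank by specificity f1 − f2;
* the conventional single-objective baseline with relative relaxation,
  for comparison against standard affinity screening.

Ties: ligands with exactly equal (f1, f2) never dominate each other, so
coordinate duplicates all sit on their common layer. Dominance ignores the
reported uncertainties (SEMs are carried through for reporting only).
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Sequence

import numpy as np

from .models import DomainError, ObjectivePair, ParetoResult

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA_GRID = 101


def dominates(a: ObjectivePair, b: ObjectivePair) -> bool:
    """True iff ``a`` is no worse than ``b`` in both objectives, better in one."""
    return (
        a.f1 >= b.f1
        and a.f2 <= b.f2
        and (a.f1 > b.f1 or a.f2 < b.f2)
    )


def _as_arrays(points: Sequence[ObjectivePair]) -> tuple[np.ndarray, np.ndarray]:
    f1 = np.asarray([p.f1 for p in points], dtype=float)
    f2 = np.asarray([p.f2 for p in points], dtype=float)
    return f1, f2


def _front_mask(f1: np.ndarray, f2: np.ndarray) -> np.ndarray:
    """Non-domination mask by sort-and-sweep; O(n log n).

    Sorted by f2 ascending, a point can only be dominated by points in
    strictly earlier f2 groups (the strict coordinate is then f2) or by a
    strictly larger f1 within its own f2 group. Sweeping the running max of
    f1 over completed groups decides both at once.
    """
    n = f1.size
    order = np.lexsort((-f1, f2))
    s1, s2 = f1[order], f2[order]
    starts = np.empty(n, dtype=bool)
    starts[0] = True
    np.not_equal(s2[1:], s2[:-1], out=starts[1:])
    group_id = np.cumsum(starts) - 1
    gmax = s1[starts]  # per-group max f1 (f1 descends within a group)
    prev_best = np.concatenate(([-np.inf], np.maximum.accumulate(gmax)[:-1]))
    on = (s1 == gmax[group_id]) & (gmax[group_id] > prev_best[group_id])
    mask = np.zeros(n, dtype=bool)
    mask[order] = on
    return mask


def _oracle_front_mask(f1: np.ndarray, f2: np.ndarray) -> np.ndarray:
    """O(n²) pairwise-dominance reference; kept independent of the sweep."""
    ge1 = f1[:, None] >= f1[None, :]
    le2 = f2[:, None] <= f2[None, :]
    strict = (f1[:, None] > f1[None, :]) | (f2[:, None] < f2[None, :])
    dominated_by = ge1 & le2 & strict  # [i, j]: i dominates j
    return ~dominated_by.any(axis=0)


def _layer_indices(f1: np.ndarray, f2: np.ndarray) -> np.ndarray:
    """Non-dominated sorting: layer 1 = front, peel and repeat."""
    n = f1.size
    layers = np.zeros(n, dtype=int)
    remaining = np.arange(n)
    layer = 0
    while remaining.size:
        layer += 1
        mask = _front_mask(f1[remaining], f2[remaining])
        layers[remaining[mask]] = layer
        remaining = remaining[~mask]
    return layers


def _lambda_support_grid(
    f1: np.ndarray, f2: np.ndarray, grid_size: int
) -> list[tuple[float, float] | None]:
    """Per-point [min λ, max λ] over grid weights at which it is an argmax."""
    lam = np.linspace(0.0, 1.0, grid_size)
    scores = lam[:, None] * f1[None, :] - (1.0 - lam)[:, None] * f2[None, :]
    maxima = scores.max(axis=1, keepdims=True)
    is_arg = scores == maxima
    supports: list[tuple[float, float] | None] = []
    for j in range(f1.size):
        hits = lam[is_arg[:, j]]
        supports.append((float(hits.min()), float(hits.max())) if hits.size else None)
    return supports


def pareto_front(
    points: Sequence[ObjectivePair],
    lambda_grid: int = DEFAULT_LAMBDA_GRID,
) -> list[ParetoResult]:
    """Annotate every point with front membership, layer, λ-support.

    Returns one :class:`ParetoResult` per input point, in input order.
    ``layer`` comes from non-dominated sorting (1 = Pareto front);
    ``lambda_support`` is the grid-resolution interval of scalarization
    weights under which the point is optimal (None if never — dominated or
    unsupported points).
    """
    if not points:
        raise DomainError("pareto_front: empty point collection")
    f1, f2 = _as_arrays(points)
    layers = _layer_indices(f1, f2)
    supports = _lambda_support_grid(f1, f2, lambda_grid)
    results = []
    for p, layer, support in zip(points, layers, supports):
        on_front = layer == 1
        results.append(
            ParetoResult(
                ligand_id=p.ligand_id,
                f1=p.f1,
                f2=p.f2,
                on_front=bool(on_front),
                layer=int(layer),
                lambda_support=support if on_front else None,
                specificity=p.specificity,
                sem1=p.sem1,
                sem2=p.sem2,
            )
        )
    return results


def front_members(points: Sequence[ObjectivePair]) -> list[ObjectivePair]:
    """Just the non-dominated points, in input order."""
    if not points:
        raise DomainError("front_members: empty point collection")
    f1, f2 = _as_arrays(points)
    mask = _front_mask(f1, f2)
    return [p for p, m in zip(points, mask) if m]


def oracle_front_members(points: Sequence[ObjectivePair]) -> list[ObjectivePair]:
    """Front by exhaustive pairwise dominance — the testing oracle."""
    if not points:
        raise DomainError("oracle_front_members: empty point collection")
    f1, f2 = _as_arrays(points)
    mask = _oracle_front_mask(f1, f2)
    return [p for p, m in zip(points, mask) if m]


def scalarize(
    points: Sequence[ObjectivePair], lam: float
) -> tuple[list[ObjectivePair], float]:
    """All maximizers of ``λ·f1 − (1−λ)·f2`` and the optimal value.

    Exact ties are all returned.
    """
    if not 0.0 <= lam <= 1.0:
        raise DomainError(f"lambda must be in [0, 1], got {lam}")
    if not points:
        raise DomainError("scalarize: empty point collection")
    f1, f2 = _as_arrays(points)
    values = lam * f1 - (1.0 - lam) * f2
    best = values.max()
    argmax = [p for p, v in zip(points, values) if v == best]
    return argmax, float(best)


def lambda_sweep(
    points: Sequence[ObjectivePair], grid_size: int = DEFAULT_LAMBDA_GRID
) -> tuple[dict[float, list[ObjectivePair]], list[ObjectivePair]]:
    """Scalarization argmax sets over a uniform λ grid, plus their union.

    Every returned point is non-dominated; up to grid resolution the union
    is the set of supported (convex-hull) Pareto points. Unsupported front
    members are never produced by any λ.
    """
    if grid_size < 2:
        raise DomainError(f"grid_size must be >= 2, got {grid_size}")
    by_lambda: dict[float, list[ObjectivePair]] = {}
    union_ids: dict[str, ObjectivePair] = {}
    for lam in np.linspace(0.0, 1.0, grid_size):
        argmax, _ = scalarize(points, float(lam))
        by_lambda[float(lam)] = argmax
        for p in argmax:
            union_ids.setdefault(p.ligand_id, p)
    return by_lambda, list(union_ids.values())


def epsilon_front(
    points: Sequence[ObjectivePair],
    mode: str = "layers",
    k: int = 1,
    eps: float = 0.0,
    lambda_grid: int = DEFAULT_LAMBDA_GRID,
) -> list[ParetoResult]:
    """ε-Pareto front: the front enlarged by relaxation.

    ``mode="layers"``: non-dominated sorting, returning all points of layer
    <= k (k = 1 is the plain front; "second best, third best" candidates
    appear at k = 2, 3, ...). ``mode="additive"``: points that remain
    non-dominated even after improving *both their own objectives* by eps
    (eps = 0 is the plain front).
    """
    if mode not in ("layers", "additive"):
        raise DomainError(f"mode must be 'layers' or 'additive', got {mode!r}")
    annotated = pareto_front(points, lambda_grid=lambda_grid)
    if mode == "layers":
        if k < 1:
            raise DomainError(f"k must be >= 1, got {k}")
        return [r for r in annotated if r.layer <= k]
    if eps < 0:
        raise DomainError(f"eps must be >= 0, got {eps}")
    f1, f2 = _as_arrays(points)
    # p survives iff no point dominates (p.f1 + eps, p.f2 - eps)
    imp1 = f1 + eps
    imp2 = f2 - eps
    ge1 = f1[:, None] >= imp1[None, :]
    le2 = f2[:, None] <= imp2[None, :]
    strict = (f1[:, None] > imp1[None, :]) | (f2[:, None] < imp2[None, :])
    if eps == 0.0:
        np.fill_diagonal(ge1, False)  # a point never dominates itself
    dominated = (ge1 & le2 & strict).any(axis=0)
    return [r for r, d in zip(annotated, dominated) if not d]


def constrained_front(
    points: Sequence[ObjectivePair],
    alpha: float,
    lambda_grid: int = DEFAULT_LAMBDA_GRID,
) -> list[ParetoResult]:
    """Pareto front of the subset with acidic magnitude f1 >= alpha.

    Guards against pH-specific but overall weak binders. An infeasible
    threshold yields an empty result with a warning.
    """
    if alpha < 0:
        raise DomainError(f"alpha must be >= 0, got {alpha}")
    eligible = [p for p in points if p.f1 >= alpha]
    if not eligible:
        warnings.warn(
            f"constrained_front: no ligand meets f1 >= {alpha}", stacklevel=2
        )
        return []
    return [r for r in pareto_front(eligible, lambda_grid=lambda_grid) if r.on_front]


def select_top_hits(
    points: Sequence[ObjectivePair], neutral_max: float, k: int = 3
) -> list[ObjectivePair]:
    """The large-library screening rule: cap neutral affinity, rank by specificity.

    Among points with f2 <= neutral_max, returns the k largest by
    f1 − f2 (descending), ties broken by larger f1 then ligand_id. Fewer
    than k qualifiers yields a shorter list with a warning.
    """
    if k < 1:
        raise DomainError(f"k must be >= 1, got {k}")
    qualifiers = [p for p in points if p.f2 <= neutral_max]
    qualifiers.sort(key=lambda p: (-p.specificity, -p.f1, p.ligand_id))
    if len(qualifiers) < k:
        warnings.warn(
            f"select_top_hits: only {len(qualifiers)} ligand(s) meet "
            f"f2 <= {neutral_max}, requested {k}",
            stacklevel=2,
        )
    return qualifiers[:k]


def rank_single_objective(
    points: Sequence[ObjectivePair],
    condition: str = "f1",
    theta_relax: float = 0.0,
) -> list[ObjectivePair]:
    """Conventional single-objective baseline with relative relaxation.

    Returns every point whose chosen-condition magnitude is within a
    relative fraction ``theta_relax`` of the maximum, i.e.
    ``value >= (1 - theta_relax) * max``. ``theta_relax = 0`` returns the
    argmax set only.
    """
    if condition not in ("f1", "f2"):
        raise DomainError(f"condition must be 'f1' or 'f2', got {condition!r}")
    if not 0.0 <= theta_relax < 1.0:
        raise DomainError(f"theta_relax must be in [0, 1), got {theta_relax}")
    if not points:
        raise DomainError("rank_single_objective: empty point collection")
    values = np.asarray([getattr(p, condition) for p in points])
    cutoff = (1.0 - theta_relax) * values.max()
    return [p for p, v in zip(points, values) if v >= cutoff]


def objective_pairs_from_aggregates(
    aggregated: Iterable,
    acidic_label: str = "acidic",
    neutral_label: str = "neutral",
) -> list[ObjectivePair]:
    """Pair up per-condition aggregates into (f1, f2) objective points.

    Ligands missing either condition are dropped with a logged warning.
    """
    acidic: dict[str, object] = {}
    neutral: dict[str, object] = {}
    for agg in aggregated:
        if agg.condition_label == acidic_label:
            acidic[agg.ligand_id] = agg
        elif agg.condition_label == neutral_label:
            neutral[agg.ligand_id] = agg
    pairs = []
    for ligand_id, a in acidic.items():
        n = neutral.get(ligand_id)
        if n is None:
            continue
        pairs.append(
            ObjectivePair(
                ligand_id=ligand_id,
                f1=a.mean_magnitude,
                f2=n.mean_magnitude,
                sem1=a.sem,
                sem2=n.sem,
            )
        )
    missing = (set(acidic) | set(neutral)) - {p.ligand_id for p in pairs}
    if missing:
        logger.warning(
            "objective_pairs_from_aggregates: dropped %d ligand(s) missing "
            "one condition", len(missing),
        )
    return pairs


def results_to_frame(results: Sequence[ParetoResult]):
    """Scatter-export view (f2 vs f1 with front/layer flags), CSV-ready."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "ligand_id": r.ligand_id,
                "f2_neutral": r.f2,
                "f1_acidic": r.f1,
                "sem2": r.sem2,
                "sem1": r.sem1,
                "on_front": r.on_front,
                "layer": r.layer,
                "specificity": r.specificity,
                "lambda_min": r.lambda_support[0] if r.lambda_support else "",
                "lambda_max": r.lambda_support[1] if r.lambda_support else "",
            }
            for r in results
        ]
    )
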
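"""Replicate aggregation: robust outlier trimming, means, SEM, and the
comparison statistics used on docking-score tables.

Replicate docking runs of one (ligand, condition) occasionally fail
outright, leaving a score far from the others. Before averaging, such
replicates are removed with a robust outlier-elimination procedure in the
ROUT family, specialized to a constant-location model: the robust fit is the
group median (replicate scores of one ligand-condition have no regressors),
spread is estimated by the RSDR — the 68.27th percentile of absolute
residuals times n/(n-1) — and residuals are tested sequentially from the
most extreme against a t distribution with n-1 degrees of freedom, with a
false-discovery-rate style threshold schedule controlled by Q. Q defaults to
1%, the method's conventional setting.

Aggregation then reports the trimmed mean of |score| (kcal/mol magnitudes),
SD and SEM per (ligand, condition). Two-condition contrasts use two-tailed
t tests (unpaired by default, paired available), with the Šídák adjustment
``1 - (1 - p)^m`` for families of m comparisons.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .models import (
    AggregatedScore,
    ComparisonResult,
    DomainError,
    ScoreObservation,
)

logger = logging.getLogger(__name__)

DEFAULT_Q = 0.01
_RSDR_PERCENTILE = 68.27


def _rout_flags_matrix(values: np.ndarray, q: float) -> np.ndarray:
    """Outlier mask for each row of an (groups, n) replicate matrix.

    Vectorized core shared by :func:`rout_outliers` and :func:`aggregate`.
    Rows are independent groups with a common replicate count n >= 3.
    """
    g, n = values.shape
    center = np.median(values, axis=1, keepdims=True)
    resid = np.abs(values - center)
    rsdr = np.percentile(resid, _RSDR_PERCENTILE, axis=1) * n / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = resid / rsdr[:, None]
    # Degenerate spread: zero residual -> t = 0 (never flagged);
    # nonzero residual over zero RSDR -> infinitely extreme.
    tstat = np.where(resid == 0, 0.0, tstat)
    tstat = np.where((rsdr[:, None] == 0) & (resid > 0), np.inf, tstat)
    pvals = 2.0 * stats.t.sf(tstat, df=n - 1)

    # Step-down test from the most extreme residual: the i-th most extreme
    # (i = 1,...,n) is flagged if its p < q*(n-i+1)/n AND all more extreme
    # residuals were flagged; stop at the first non-rejection.
    order = np.argsort(pvals, axis=1, kind="stable")
    sorted_p = np.take_along_axis(pvals, order, axis=1)
    thresholds = q * (n - np.arange(n)) / n  # i-th most extreme, 0-based
    reject_sorted = sorted_p < thresholds[None, :]
    reject_sorted = np.logical_and.accumulate(reject_sorted, axis=1)
    flags = np.zeros_like(reject_sorted)
    np.put_along_axis(flags, order, reject_sorted, axis=1)
    return flags


def rout_outliers(
    values: Sequence[float], q: float = DEFAULT_Q
) -> tuple[list[float], list[float]]:
    """Split replicate values into (retained, flagged) by the ROUT variant.

    Groups with fewer than 3 values are returned untouched with a logged
    warning — no meaningful robust spread estimate exists below n = 3.
    """
    if not 0.0 < q < 1.0:
        raise DomainError(f"q must be in (0, 1), got {q}")
    vals = [float(v) for v in values]
    if len(vals) < 3:
        if vals:
            logger.warning(
                "rout_outliers: %d value(s) < 3, retaining all without testing",
                len(vals),
            )
        return vals, []
    flags = _rout_flags_matrix(np.asarray([vals]), q)[0]
    retained = [v for v, f in zip(vals, flags) if not f]
    flagged = [v for v, f in zip(vals, flags) if f]
    return retained, flagged


def aggregate(
    observations: Iterable[ScoreObservation], q: float = DEFAULT_Q
) -> list[AggregatedScore]:
    """Trimmed-mean affinity magnitudes per (ligand, condition) group.

    Applies :func:`rout_outliers` per group, then averages |score| over the
    retained replicates. Single-replicate groups carry sd = sem = 0 with a
    logged warning. Output order follows first appearance in the input;
    the statistics themselves are invariant to replicate order.
    """
    if not 0.0 < q < 1.0:
        raise DomainError(f"q must be in (0, 1), got {q}")
    groups: dict[tuple[str, str], list[float]] = defaultdict(list)
    for obs in observations:
        groups[(obs.ligand_id, obs.condition_label)].append(obs.score)
    if not groups:
        raise DomainError("aggregate: empty observation collection")

    # Batch groups by replicate count so the ROUT core runs vectorized;
    # 50K-ligand tables would be far too slow one group at a time.
    by_n: dict[int, list[tuple[tuple[str, str], list[float]]]] = defaultdict(list)
    for key, vals in groups.items():
        by_n[len(vals)].append((key, vals))

    flagged_masks: dict[tuple[str, str], np.ndarray] = {}
    for n, members in by_n.items():
        if n < 3:
            logger.warning(
                "aggregate: %d group(s) with n=%d < 3 replicates, "
                "no outlier test applied",
                len(members), n,
            )
            for key, vals in members:
                flagged_masks[key] = np.zeros(n, dtype=bool)
            continue
        mat = np.asarray([vals for _, vals in members])
        flags = _rout_flags_matrix(mat, q)
        for (key, _), row in zip(members, flags):
            flagged_masks[key] = row

    results = []
    for key, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        flags = flagged_masks[key]
        kept = np.abs(arr[~flags])
        out = arr[flags]
        n_used = kept.size
        mean = float(kept.mean())
        if n_used >= 2:
            sd = float(kept.std(ddof=1))
            sem = sd / np.sqrt(n_used)
        else:
            sd = sem = 0.0
        results.append(
            AggregatedScore(
                ligand_id=key[0],
                condition_label=key[1],
                mean_magnitude=mean,
                sem=float(sem),
                sd=sd,
                n_total=len(vals),
                n_used=n_used,
                n_outliers=int(flags.sum()),
                outlier_values=[float(v) for v in out],
            )
        )
    return results


def compare_conditions(
    a: Sequence[float], b: Sequence[float], paired: bool = False
) -> ComparisonResult:
    """Two-tailed t test between two score samples.

    Unpaired (Welch-free, pooled-variance two-sample) by default; paired
    mode operates on elementwise differences and requires equal lengths.
    Identical samples yield statistic 0 and p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DomainError("compare_conditions requires n >= 2 per sample")
    if paired:
        if len(a) != len(b):
            raise DomainError("paired comparison requires equal lengths")
        if np.allclose(a - b, 0.0):
            return ComparisonResult("paired_t", 0.0, 1.0)
        t, p = stats.ttest_rel(a, b)
        return ComparisonResult("paired_t", float(t), float(p))
    if np.array_equal(np.sort(a), np.sort(b)) and np.ptp(a) == 0:
        return ComparisonResult("unpaired_t", 0.0, 1.0)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    if np.isnan(t):  # zero variance in both samples, equal means
        return ComparisonResult("unpaired_t", 0.0, 1.0)
    return ComparisonResult("unpaired_t", float(t), float(p))


def sidak_adjust(p: float, m: int) -> float:
    """Šídák multiple-comparison adjustment ``1 - (1 - p)^m``, clipped to [0, 1]."""
    if not 0.0 <= p <= 1.0:
        raise DomainError(f"p must be in [0, 1], got {p}")
    if m < 1:
        raise DomainError(f"m must be >= 1, got {m}")
    return float(min(1.0, 1.0 - (1.0 - p) ** m))


def aggregated_to_frame(aggregated: Sequence[AggregatedScore]):
    """Tabular view of aggregated scores (CSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "ligand_id": a.ligand_id,
                "condition": a.condition_label,
                "mean_magnitude": a.mean_magnitude,
                "sem": a.sem,
                "sd": a.sd,
                "n_total": a.n_total,
                "n_used": a.n_used,
                "n_outliers": a.n_outliers,
            }
            for a in aggregated
        ]
    )
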
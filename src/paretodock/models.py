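"""Core record types shared across the toolkit.

Plain dataclasses; tabular operations convert to/from pandas DataFrames at
module boundaries. Docking-engine sign convention (favorable = negative,
kcal/mol) is preserved in :class:`ScoreObservation`; everything downstream of
aggregation works with affinity magnitudes ``|ΔF|``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


class DomainError(ValueError):
    """An argument is outside the domain an operation is defined on."""


class FormatError(ValueError):
    """A file does not conform to its declared external format."""


class IntegrityError(ValueError):
    """Parsed data violates a uniqueness or consistency invariant."""


SITE_TYPES = ("base", "acid")


@dataclass(frozen=True)
class IonizableSite:
    """One ionizable site of a ligand: a label, its pKa and acid/base type."""

    label: str
    pka: float
    site_type: str  # "base" or "acid"

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise DomainError(
                f"site_type must be one of {SITE_TYPES}, got {self.site_type!r}"
            )
        if not _finite(self.pka):
            raise DomainError(f"pKa must be finite, got {self.pka!r}")


@dataclass
class LigandRecord:
    """A ligand identity with optional SMILES and ionizable-site annotations.

    SMILES strings are carried verbatim for provenance; no chemistry is
    performed on them here.
    """

    ligand_id: str
    smiles: Optional[str] = None
    sites: list[IonizableSite] = field(default_factory=list)
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ligand_id:
            raise DomainError("ligand_id must be nonempty")


@dataclass(frozen=True)
class Condition:
    """A screening environment: a label, its pH and a target-structure tag.

    The canonical pair in this package is ``acidic`` (pH 5.0, inflamed
    tissue) and ``neutral`` (pH 7.4, healthy tissue).
    """

    label: str
    ph: float
    target_tag: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.ph <= 14.0:
            raise DomainError(f"pH must be in [0, 14], got {self.ph}")


ACIDIC = Condition("acidic", 5.0)
NEUTRAL = Condition("neutral", 7.4)


@dataclass(frozen=True)
class ScoreObservation:
    """One replicate docking score for a (ligand, condition) pair.

    ``score`` is in kcal/mol with the engine's sign convention
    (favorable binding = negative).
    """

    ligand_id: str
    condition_label: str
    replicate: int
    score: float

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise DomainError(f"replicate must be >= 1, got {self.replicate}")
        if not _finite(self.score):
            raise DomainError(f"score must be finite, got {self.score!r}")


@dataclass
class AggregatedScore:
    """Per-(ligand, condition) trimmed-mean affinity magnitude with spread.

    ``mean_magnitude`` is the mean of |score| over the replicates retained
    after outlier elimination; ``sem = sd / sqrt(n_used)`` for n_used >= 2.
    """

    ligand_id: str
    condition_label: str
    mean_magnitude: float
    sem: float
    sd: float
    n_total: int
    n_used: int
    n_outliers: int
    outlier_values: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_used + self.n_outliers != self.n_total:
            raise IntegrityError(
                "n_used + n_outliers must equal n_total "
                f"({self.n_used} + {self.n_outliers} != {self.n_total})"
            )


@dataclass(frozen=True)
class ComparisonResult:
    """A two-condition comparison: t statistic, p value and its provenance."""

    kind: str  # "unpaired_t", "paired_t" or "sidak_adjusted"
    statistic: float
    p_value: float
    m_comparisons: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise DomainError(f"p_value must be in [0, 1], got {self.p_value}")
        if self.m_comparisons < 1:
            raise DomainError("m_comparisons must be >= 1")


@dataclass(frozen=True)
class ObjectivePair:
    """A ligand's two aggregated affinity magnitudes (kcal/mol).

    ``f1``: |ΔF| in the desired environment (acidic pH) — to be maximized.
    ``f2``: |ΔF| in the undesired environment (neutral pH) — to be minimized.
    """

    ligand_id: str
    f1: float
    f2: float
    sem1: float = 0.0
    sem2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("f1", "f2"):
            v = getattr(self, name)
            if not _finite(v) or v < 0:
                raise DomainError(f"{name} must be finite and >= 0, got {v!r}")

    @property
    def specificity(self) -> float:
        """pH-selectivity measure: acidic minus neutral magnitude."""
        return self.f1 - self.f2


@dataclass
class ParetoResult:
    """Front membership and ranking annotations for one ligand.

    ``layer`` 1 is the Pareto front; ``lambda_support`` is the closed
    interval of scalarization weights under which the point is an argmax
    (None for unsupported or dominated points); ``specificity`` is f1 - f2.
    """

    ligand_id: str
    f1: float
    f2: float
    on_front: bool
    layer: int
    lambda_support: Optional[tuple[float, float]]
    specificity: float
    sem1: float = 0.0
    sem2: float = 0.0

    def __post_init__(self) -> None:
        if (self.layer == 1) != self.on_front:
            raise IntegrityError("layer == 1 must hold exactly for front members")
        if self.lambda_support is not None and not self.on_front:
            raise IntegrityError("only front members can have lambda support")


def _finite(x: float) -> bool:
    import math

    try:
        return math.isfinite(float(x))
    except (TypeError, ValueError):
        return False
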
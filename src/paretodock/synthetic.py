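"""Seeded synthetic two-condition replicate score tables and fixtures.

The generator emulates the *output structure* of a two-environment replicate
docking campaign — per-ligand true affinity magnitudes under neutral and
acidic conditions, Gaussian replicate noise, occasional gross failures
(outliers), and engine sign convention — so the aggregation, outlier
elimination and Pareto machinery can be exercised with known ground truth.
It makes no claim to model docking physics.

A planted fraction of "switchable" ligands gains an additive specificity
bonus on the acidic magnitude and a basic ionizable site with pKa inside
the (5.5, 7.0) band, so the protonation classifier labels them switchable
over (pH 5.0, 7.4); non-switchable ligands receive pKa in (8.5, 10.0),
dominant-charged at both pH values.

Also here: the in-study worked-example objective pairs (four reference
opioids with printed mean scores), the focused-library manifest builder,
and a minimal docked-PDBQT writer for parser round-trip tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

from .models import (
    DomainError,
    IonizableSite,
    LigandRecord,
    ObjectivePair,
    ScoreObservation,
)

PathLike = Union[str, Path]

SWITCHABLE_PKA_RANGE = (5.5, 7.0)
NONSWITCHABLE_PKA_RANGE = (8.5, 10.0)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic screening campaign.

    Defaults mirror a focused-library docking campaign: a couple hundred
    ligands, mid-9 kcal/mol affinity magnitudes, a 2 kcal/mol planted
    acidic-specificity effect on 5% of ligands, 0.3 kcal/mol replicate
    noise, six replicates, and rare gross failures displaced by +6 kcal/mol
    (toward weaker binding, as failed docking runs produce).
    """

    n_ligands: int = 200
    frac_switchable: float = 0.05
    base_affinity_mean: float = 8.0
    base_affinity_sd: float = 0.8
    specificity_delta: float = 2.0
    replicate_sd: float = 0.3
    n_replicates: int = 6
    outlier_prob: float = 0.0
    outlier_shift: float = 6.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_ligands < 1:
            raise DomainError("n_ligands must be >= 1")
        if not 0.0 <= self.frac_switchable <= 1.0:
            raise DomainError("frac_switchable must be in [0, 1]")
        if not 0.0 <= self.outlier_prob <= 1.0:
            raise DomainError("outlier_prob must be in [0, 1]")
        if self.base_affinity_sd < 0 or self.replicate_sd < 0:
            raise DomainError("standard deviations must be >= 0")
        if self.specificity_delta < 0:
            raise DomainError("specificity_delta must be >= 0")
        if self.n_replicates < 1:
            raise DomainError("n_replicates must be >= 1")


@dataclass
class TruthLabels:
    """Ground truth planted by the generator."""

    switchable: dict[str, bool] = field(default_factory=dict)
    true_neutral: dict[str, float] = field(default_factory=dict)
    true_acidic: dict[str, float] = field(default_factory=dict)


def generate_table(
    config: SimulationConfig,
) -> tuple[list[ScoreObservation], list[LigandRecord], TruthLabels]:
    """Generate a replicate score table, matching manifest and truth labels.

    Per ligand: true neutral magnitude ~ Normal(mean, sd) truncated at 0;
    true acidic magnitude adds ``specificity_delta`` for switchable ligands.
    Each replicate is truth + Normal(0, replicate_sd), emitted with the
    engine's negative-favorable sign; with probability ``outlier_prob`` a
    replicate's magnitude is displaced by ``outlier_shift`` toward weaker
    binding. Identical seed, identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_ligands
    width = len(str(max(n - 1, 1)))
    ids = [f"LIG{idx:0{width}d}" for idx in range(n)]

    switch = rng.random(n) < config.frac_switchable
    neutral_truth = rng.normal(config.base_affinity_mean, config.base_affinity_sd, n)
    neutral_truth = np.maximum(neutral_truth, 0.0)
    acidic_truth = neutral_truth + np.where(switch, config.specificity_delta, 0.0)

    pka_switch = rng.uniform(*SWITCHABLE_PKA_RANGE, size=n)
    pka_other = rng.uniform(*NONSWITCHABLE_PKA_RANGE, size=n)
    pkas = np.where(switch, pka_switch, pka_other)

    observations: list[ScoreObservation] = []
    for cond, truth in (("neutral", neutral_truth), ("acidic", acidic_truth)):
        noise = rng.normal(0.0, config.replicate_sd, size=(n, config.n_replicates))
        magnitudes = truth[:, None] + noise
        if config.outlier_prob > 0:
            bad = rng.random((n, config.n_replicates)) < config.outlier_prob
            magnitudes = magnitudes - bad * config.outlier_shift
        magnitudes = np.maximum(magnitudes, 0.0)
        for i, lig in enumerate(ids):
            for r in range(config.n_replicates):
                observations.append(
                    ScoreObservation(
                        ligand_id=lig,
                        condition_label=cond,
                        replicate=r + 1,
                        score=-float(magnitudes[i, r]),
                    )
                )

    ligands = [
        LigandRecord(
            ligand_id=lig,
            smiles=None,
            sites=[IonizableSite("N1", float(pkas[i]), "base")],
            meta={"synthetic": "true"},
        )
        for i, lig in enumerate(ids)
    ]
    truth = TruthLabels(
        switchable={lig: bool(switch[i]) for i, lig in enumerate(ids)},
        true_neutral={lig: float(neutral_truth[i]) for i, lig in enumerate(ids)},
        true_acidic={lig: float(acidic_truth[i]) for i, lig in enumerate(ids)},
    )
    return observations, ligands, truth


def worked_example_fixture() -> list[ObjectivePair]:
    """The four reference opioids with their mean docking-score magnitudes.

    (f2 = neutral pH 7.4, f1 = acidic pH 5.0, kcal/mol): fentanyl
    (9.0, 8.7), NFEPP (8.8, 9.0), CHEMBL3139481 (8.6, 9.4) and
    Fluoromorphine β-C2 (7.1, 7.8). NFEPP and CHEMBL3139481 bind the
    acidic receptor conformation more strongly than the neutral one;
    fentanyl shows the opposite preference.
    """
    return [
        ObjectivePair("fentanyl", f1=8.7, f2=9.0),
        ObjectivePair("NFEPP", f1=9.0, f2=8.8),
        ObjectivePair("CHEMBL3139481", f1=9.4, f2=8.6),
        ObjectivePair("Fluoromorphine beta-C2", f1=7.8, f2=7.1),
    ]


def library_a_manifest() -> list[LigandRecord]:
    """The focused morphine/fentanyl library composition (55 entries).

    Assembled from its stated components: 43 CHEMBL morphine- and
    fentanyl-related hits, NFEPP, six β-fluorofentanyls and the
    dissected-morphine-analog group of five compounds. Only the compounds
    named in published results carry real identifiers and pKa annotations
    (fentanyl pKa 8.99, NFEPP 6.8 — basic piperidine amines); the remaining
    CHEMBL hits and derivative entries are synthetic placeholders standing
    in for identifiers not individually published.
    """
    ligands: list[LigandRecord] = []
    ligands.append(
        LigandRecord(
            "fentanyl",
            sites=[IonizableSite("piperidine-N", 8.99, "base")],
            meta={"group": "chembl", "reference": "true"},
        )
    )
    ligands.append(
        LigandRecord(
            "morphine",
            sites=[IonizableSite("amine-N", 8.21, "base")],
            meta={"group": "chembl", "reference": "true"},
        )
    )
    ligands.append(
        LigandRecord(
            "CHEMBL3139481",
            sites=[IonizableSite("ring-N", 6.5, "base")],
            meta={"group": "chembl", "hit": "true"},
        )
    )
    for i in range(1, 41):  # remaining CHEMBL hits: synthetic placeholder ids
        ligands.append(
            LigandRecord(f"CHEMBL-hit-{i:02d}", meta={"group": "chembl",
                                                      "synthetic": "true"})
        )
    ligands.append(
        LigandRecord(
            "NFEPP",
            sites=[IonizableSite("piperidine-N", 6.8, "base")],
            meta={"group": "nfepp"},
        )
    )
    for i in range(1, 7):
        ligands.append(
            LigandRecord(
                f"beta-fluorofentanyl-{i}",
                meta={"group": "beta-fluorofentanyl", "synthetic": "true"},
            )
        )
    for label in ("C1", "C2", "C3", "C4", "C5"):
        ligands.append(
            LigandRecord(
                f"fluoromorphine-beta-{label}",
                meta={"group": "morphine-analog", "synthetic": "true"},
            )
        )
    assert len(ligands) == 55
    return ligands


def mock_pdbqt_writer(score: float, path: PathLike, n_modes: int = 3) -> None:
    """Write a minimal docked PDBQT whose best-mode affinity equals ``score``.

    Additional modes are appended at 0.5 kcal/mol steps toward weaker
    binding, so best-mode extraction is actually exercised.
    """
    if not np.isfinite(score):
        raise DomainError(f"score must be finite, got {score!r}")
    lines = []
    for mode in range(1, max(1, n_modes) + 1):
        affinity = score + 0.5 * (mode - 1)
        lines += [
            f"MODEL {mode}",
            f"REMARK VINA RESULT:    {affinity:10.4f}      0.000      0.000",
            "ROOT",
            "ATOM      1  C   LIG A   1       0.000   0.000   0.000  "
            "0.00  0.00     0.000 C",
            "ENDROOT",
            "TORSDOF 0",
            "ENDMDL",
        ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
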
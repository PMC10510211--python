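"""Reading and writing the toolkit's external representations.

Formats handled here:

* score tables — CSV with columns ``ligand_id,condition,replicate,score``
  (comma-separated, UTF-8, header required, decimal point);
* ligand manifests — CSV with columns
  ``ligand_id,smiles,site_label,pka,site_type`` (one row per ionizable site;
  a ligand with no sites appears once with the site columns empty);
* docked PDBQT files and Vina-style log tables, from which the best-mode
  affinity is extracted;
* JSON result reports that round-trip :class:`~paretodock.models.ParetoResult`
  collections losslessly.

The docking engine's sign convention (negative = favorable) is preserved at
this boundary; conversion to magnitudes happens only during aggregation.
"""

from __future__ import annotations

import csv
import json
import logging
import math
import re
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

from .models import (
    FormatError,
    IntegrityError,
    IonizableSite,
    LigandRecord,
    ParetoResult,
    ScoreObservation,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

SCORE_COLUMNS = ("ligand_id", "condition", "replicate", "score")
MANIFEST_COLUMNS = ("ligand_id", "smiles", "site_label", "pka", "site_type")

_VINA_RESULT_RE = re.compile(r"REMARK VINA RESULT:\s+(-?\d+(?:\.\d+)?)")
# Log-table rows look like "   1       -9.0      0.000      0.000"
_LOG_ROW_RE = re.compile(r"^\s*(\d+)\s+(-?\d+(?:\.\d+)?)\s+[\d.]+\s+[\d.]+\s*$")


def read_score_table(path: PathLike) -> list[ScoreObservation]:
    """Parse a replicate score CSV into observations.

    The header must contain ``ligand_id``, ``condition``, ``replicate`` and
    ``score``. A missing or empty ``replicate`` field is assigned from the
    order of appearance within its (ligand, condition) group (logged).
    Malformed rows raise :class:`FormatError` with their line number;
    duplicate (ligand, condition, replicate) keys raise
    :class:`IntegrityError`.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, expected a header row")
        missing = [c for c in SCORE_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise FormatError(
                f"{path}: missing required column(s) {', '.join(missing)}"
            )
        observations: list[ScoreObservation] = []
        seen: set[tuple[str, str, int]] = set()
        auto_counters: dict[tuple[str, str], int] = {}
        n_auto = 0
        for lineno, row in enumerate(reader, start=2):
            ligand = (row["ligand_id"] or "").strip()
            condition = (row["condition"] or "").strip()
            if not ligand or not condition:
                raise FormatError(
                    f"{path}:{lineno}: empty ligand_id or condition"
                )
            rep_raw = (row["replicate"] or "").strip()
            if rep_raw:
                try:
                    replicate = int(rep_raw)
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: replicate {rep_raw!r} is not an integer"
                    ) from None
            else:
                key = (ligand, condition)
                auto_counters[key] = auto_counters.get(key, 0) + 1
                replicate = auto_counters[key]
                n_auto += 1
            try:
                score = float(row["score"])
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}:{lineno}: score {row['score']!r} is not a number"
                ) from None
            if not math.isfinite(score):
                raise FormatError(f"{path}:{lineno}: score must be finite")
            triple = (ligand, condition, replicate)
            if triple in seen:
                raise IntegrityError(
                    f"{path}:{lineno}: duplicate observation for "
                    f"ligand {ligand!r}, condition {condition!r}, "
                    f"replicate {replicate}"
                )
            seen.add(triple)
            observations.append(
                ScoreObservation(ligand, condition, replicate, score)
            )
    if n_auto:
        logger.info(
            "%s: assigned %d replicate indices from file order", path, n_auto
        )
    return observations


def write_score_table(
    observations: Iterable[ScoreObservation], path: PathLike
) -> None:
    """Write observations as a score CSV (inverse of :func:`read_score_table`)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SCORE_COLUMNS)
        for obs in observations:
            writer.writerow(
                [obs.ligand_id, obs.condition_label, obs.replicate, obs.score]
            )


def observations_to_frame(
    observations: Sequence[ScoreObservation],
) -> pd.DataFrame:
    """Tabular view of observations (columns as in the score CSV)."""
    return pd.DataFrame(
        {
            "ligand_id": [o.ligand_id for o in observations],
            "condition": [o.condition_label for o in observations],
            "replicate": [o.replicate for o in observations],
            "score": [o.score for o in observations],
        }
    )


def read_ligand_manifest(path: PathLike) -> list[LigandRecord]:
    """Parse a ligand manifest CSV (one row per ionizable site).

    Rows sharing a ``ligand_id`` are merged into one record; the smiles
    column may repeat and must agree across rows of the same ligand. Site
    columns left empty describe a ligand without annotated ionizable sites.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, expected a header row")
        missing = [c for c in MANIFEST_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise FormatError(
                f"{path}: missing required column(s) {', '.join(missing)}"
            )
        records: dict[str, LigandRecord] = {}
        for lineno, row in enumerate(reader, start=2):
            ligand = (row["ligand_id"] or "").strip()
            if not ligand:
                raise FormatError(f"{path}:{lineno}: empty ligand_id")
            smiles = (row["smiles"] or "").strip() or None
            rec = records.get(ligand)
            if rec is None:
                rec = LigandRecord(ligand_id=ligand, smiles=smiles)
                records[ligand] = rec
            elif smiles is not None and rec.smiles is not None and smiles != rec.smiles:
                raise IntegrityError(
                    f"{path}:{lineno}: conflicting SMILES for ligand {ligand!r}"
                )
            elif rec.smiles is None:
                rec.smiles = smiles
            site_label = (row["site_label"] or "").strip()
            if site_label:
                try:
                    pka = float(row["pka"])
                except (TypeError, ValueError):
                    raise FormatError(
                        f"{path}:{lineno}: pka {row['pka']!r} is not a number"
                    ) from None
                site_type = (row["site_type"] or "").strip()
                try:
                    rec.sites.append(IonizableSite(site_label, pka, site_type))
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: {exc}") from None
    return list(records.values())


def write_ligand_manifest(
    ligands: Iterable[LigandRecord], path: PathLike
) -> None:
    """Write ligand records as a manifest CSV (inverse of the reader)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for lig in ligands:
            if not lig.sites:
                writer.writerow([lig.ligand_id, lig.smiles or "", "", "", ""])
            for site in lig.sites:
                writer.writerow(
                    [lig.ligand_id, lig.smiles or "", site.label, site.pka,
                     site.site_type]
                )


def parse_vina_output(
    path: PathLike,
    ligand_id: str = "",
    condition_label: str = "",
    replicate: int = 1,
    mode_policy: str = "best_mode_only",
) -> ScoreObservation:
    """Extract the best-mode affinity from a docked PDBQT or Vina log.

    Docked PDBQT files carry one ``REMARK VINA RESULT: <affinity> ...`` line
    per binding mode, best mode first; log files carry an indented result
    table ``mode | affinity | dist...``. Under ``best_mode_only`` the most
    favorable (minimum) affinity is returned with the engine's sign
    preserved. Raises :class:`FormatError` if no result record is found.
    """
    if mode_policy != "best_mode_only":
        raise ValueError(f"unknown mode_policy {mode_policy!r}")
    path = Path(path)
    affinities: list[float] = []
    with path.open(encoding="utf-8", errors="replace") as fh:
        for line in fh:
            m = _VINA_RESULT_RE.search(line)
            if m:
                affinities.append(float(m.group(1)))
                continue
            m = _LOG_ROW_RE.match(line)
            if m:
                affinities.append(float(m.group(2)))
    if not affinities:
        raise FormatError(f"{path}: no Vina result record found")
    best = min(affinities)
    return ScoreObservation(
        ligand_id=ligand_id or path.stem,
        condition_label=condition_label or "unspecified",
        replicate=replicate,
        score=best,
    )


def write_report(results: Sequence[ParetoResult], path: PathLike) -> None:
    """Serialize Pareto results to JSON (schema in docs/report_schema.md).

    Raises :class:`ValueError` on an empty collection — an empty report is
    almost always an upstream mistake.
    """
    if not results:
        raise ValueError("refusing to write an empty report")
    payload = {
        "format": "paretodock-report",
        "version": 1,
        "ligands": [
            {
                "ligand_id": r.ligand_id,
                "f1_acidic": r.f1,
                "f2_neutral": r.f2,
                "sem1": r.sem1,
                "sem2": r.sem2,
                "on_front": r.on_front,
                "layer": r.layer,
                "lambda_support": list(r.lambda_support)
                if r.lambda_support is not None
                else None,
                "specificity": r.specificity,
            }
            for r in results
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def read_report(path: PathLike) -> list[ParetoResult]:
    """Read a JSON report back into Pareto results (round-trip of writer)."""
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("format") != "paretodock-report":
        raise FormatError(f"{path}: not a paretodock report")
    results = []
    for entry in payload["ligands"]:
        support = entry["lambda_support"]
        results.append(
            ParetoResult(
                ligand_id=entry["ligand_id"],
                f1=entry["f1_acidic"],
                f2=entry["f2_neutral"],
                on_front=entry["on_front"],
                layer=entry["layer"],
                lambda_support=tuple(support) if support is not None else None,
                specificity=entry["specificity"],
                sem1=entry.get("sem1", 0.0),
                sem2=entry.get("sem2", 0.0),
            )
        )
    return results
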
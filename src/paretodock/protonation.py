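"""Henderson–Hasselbalch protonation-state analysis.

pH-specific ligand preparation hinges on whether a ligand's ionizable sites
are charged in the acidic environment (inflamed tissue, pH 5.0) but neutral
in the healthy one (pH 7.4). This module answers that question in closed
form from per-site pKa values, which are inputs — no pKa prediction is
performed.

For a basic site (e.g. a piperidine amine) the protonated — charged —
fraction is ``1 / (1 + 10**(pH - pKa))``; for an acidic site the
deprotonated — charged — fraction is ``1 / (1 + 10**(pKa - pH))``. Sites are
treated as independent (no microstate coupling): the ligands this package
targets carry a single decisive amine. A site is called *dominant charged*
when its charged fraction exceeds 0.5; exactly 0.5 (pH = pKa) classifies as
neutral, a deterministic convention conservative toward the unprotonated
form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .models import DomainError, LigandRecord, SITE_TYPES


@dataclass(frozen=True)
class SiteState:
    """Ionization of one site at one pH."""

    label: str
    fraction_ionized: float
    dominant: str  # "charged" or "neutral"


@dataclass
class ProtonationState:
    """Dominant protonation state of a ligand at a given pH.

    ``net_dominant_charge`` counts (+1) per dominant-charged basic site and
    (−1) per dominant-charged acidic site.
    """

    ligand_id: str
    ph: float
    site_states: list[SiteState] = field(default_factory=list)
    net_dominant_charge: int = 0


@dataclass
class SwitchReport:
    """Per-site account of whether dominance flips between two pH values."""

    ligand_id: str
    ph_low: float
    ph_high: float
    switchable: bool
    site_reports: list[tuple[str, str, str]] = field(default_factory=list)
    # (site_label, dominant at ph_low, dominant at ph_high)


def fraction_ionized(pka: float, ph: float, site_type: str) -> float:
    """Charged fraction of a site at a given pH (Henderson–Hasselbalch).

    Strictly decreasing in pH for bases, strictly increasing for acids;
    exactly 0.5 at pH = pKa.
    """
    if site_type not in SITE_TYPES:
        raise DomainError(f"site_type must be one of {SITE_TYPES}, got {site_type!r}")
    if not 0.0 <= ph <= 14.0:
        raise DomainError(f"pH must be in [0, 14], got {ph}")
    if site_type == "base":
        return 1.0 / (1.0 + 10.0 ** (ph - pka))
    return 1.0 / (1.0 + 10.0 ** (pka - ph))


def dominant_state(ligand: LigandRecord, ph: float) -> ProtonationState:
    """Classify each site of ``ligand`` at ``ph`` and tally the net charge."""
    states: list[SiteState] = []
    net = 0
    for site in ligand.sites:
        frac = fraction_ionized(site.pka, ph, site.site_type)
        dominant = "charged" if frac > 0.5 else "neutral"
        states.append(SiteState(site.label, frac, dominant))
        if dominant == "charged":
            net += 1 if site.site_type == "base" else -1
    return ProtonationState(ligand.ligand_id, ph, states, net)


def is_ph_switchable(
    ligand: LigandRecord, ph_low: float, ph_high: float
) -> SwitchReport:
    """Does the ligand's dominant protonation differ between two pH values?

    True iff at least one site is dominant-charged at one pH and
    dominant-neutral at the other. For a basic site this means its pKa lies
    in the open band where the charged fraction crosses 0.5 between
    ``ph_low`` and ``ph_high``. A ligand with no annotated sites is never
    switchable.
    """
    if ph_low >= ph_high:
        raise DomainError(f"require ph_low < ph_high, got {ph_low} >= {ph_high}")
    low_state = dominant_state(ligand, ph_low)
    high_state = dominant_state(ligand, ph_high)
    reports = []
    switchable = False
    for s_low, s_high in zip(low_state.site_states, high_state.site_states):
        reports.append((s_low.label, s_low.dominant, s_high.dominant))
        if s_low.dominant != s_high.dominant:
            switchable = True
    return SwitchReport(ligand.ligand_id, ph_low, ph_high, switchable, reports)


def protonation_table(
    ligands: list[LigandRecord], ph_low: float = 5.0, ph_high: float = 7.4
):
    """Per-site protonation report rows for a ligand collection.

    Returns a pandas DataFrame with columns ligand_id, ph, site_label,
    fraction, dominant, switchable — one row per (ligand, pH, site).
    """
    import pandas as pd

    rows = []
    for lig in ligands:
        report = is_ph_switchable(lig, ph_low, ph_high)
        for ph in (ph_low, ph_high):
            state = dominant_state(lig, ph)
            for site in state.site_states:
                rows.append(
                    {
                        "ligand_id": lig.ligand_id,
                        "ph": ph,
                        "site_label": site.label,
                        "fraction": site.fraction_ionized,
                        "dominant": site.dominant,
                        "switchable": report.switchable,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["ligand_id", "ph", "site_label", "fraction", "dominant",
                 "switchable"],
    )
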
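"""Why NFEPP is pH-selective and fentanyl is not.

Both opioids carry a basic piperidine amine; protonation of that amine is
required for efficient receptor binding. NFEPP's fluorine lowers the amine
pKa to 6.8, between inflamed-tissue pH (5.0) and healthy-tissue pH (7.4),
so the Henderson-Hasselbalch charged fraction crosses 50% between the two
environments. Fentanyl's pKa of 8.99 keeps it protonated in both.
"""

from paretodock import (
    IonizableSite,
    LigandRecord,
    fraction_ionized,
    is_ph_switchable,
)

ligands = [
    LigandRecord("fentanyl", sites=[IonizableSite("piperidine-N", 8.99, "base")]),
    LigandRecord("NFEPP", sites=[IonizableSite("piperidine-N", 6.8, "base")]),
]

print(f"{'ligand':<10} {'pKa':>5} {'% charged pH 5.0':>17} "
      f"{'% charged pH 7.4':>17}  switchable")
for lig in ligands:
    site = lig.sites[0]
    at5 = fraction_ionized(site.pka, 5.0, "base")
    at74 = fraction_ionized(site.pka, 7.4, "base")
    switch = is_ph_switchable(lig, 5.0, 7.4).switchable
    print(f"{lig.ligand_id:<10} {site.pka:>5.2f} {100 * at5:>16.1f}% "
          f"{100 * at74:>16.1f}%  {switch}")

print("\nA site is 'switchable' when its dominant (majority) protonation")
print("state differs between the two environments - the chemical signature")
print("of a candidate that is active in inflamed but not healthy tissue.")
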
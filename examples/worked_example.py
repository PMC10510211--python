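"""Pareto analysis of the four reference opioids.

Fentanyl, NFEPP, CHEMBL3139481 and Fluoromorphine beta-C2 each have mean
docking-score magnitudes |dF| (kcal/mol) against the mu-opioid receptor in
its neutral-pH (7.4) and acidic-pH (5.0) conformations. We seek ligands
that bind strongly at acidic pH (inflamed tissue -> analgesia) but weakly
at neutral pH (healthy tissue -> side effects): maximize f1, minimize f2.
"""

from paretodock import (
    epsilon_front,
    pareto_front,
    scalarize,
    select_top_hits,
    worked_example_fixture,
)

points = worked_example_fixture()
print(f"{'ligand':<24} {'acidic f1':>9} {'neutral f2':>10} {'specificity':>11}")
for p in points:
    print(f"{p.ligand_id:<24} {p.f1:>9.1f} {p.f2:>10.1f} {p.specificity:>+11.1f}")

print("\nPareto front (no other ligand binds both more strongly at acidic")
print("pH and more weakly at neutral pH):")
for r in pareto_front(points):
    if r.on_front:
        lo, hi = r.lambda_support
        print(f"  {r.ligand_id}  (optimal for lambda in [{lo:.2f}, {hi:.2f}])")

argmax, value = scalarize(points, 0.5)
print(f"\nBalanced scalarization (lambda=0.5) selects {argmax[0].ligand_id} "
      f"with objective value {value:.1f}.")

print("\nSecond non-domination layer (next-best candidates):")
for r in epsilon_front(points, mode="layers", k=2):
    if r.layer == 2:
        print(f"  {r.ligand_id}")

hits = select_top_hits(points, neutral_max=float("inf"), k=2)
print("\nTop hits by specificity f1 - f2 (higher = more pH-selective):")
for rank, p in enumerate(hits, 1):
    print(f"  {rank}. {p.ligand_id}  specificity {p.specificity:+.1f} kcal/mol")
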
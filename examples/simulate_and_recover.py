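"""Synthetic screening campaign: plant an effect, contaminate, recover.

Generates replicate docking scores for 200 ligands under two pH conditions
with a 2 kcal/mol acidic-specificity effect planted on ~5% of ligands and
2% gross replicate failures, then runs the full analysis: robust outlier
elimination, trimmed-mean aggregation, and Pareto-front identification.
"""

from paretodock import (
    SimulationConfig,
    aggregate,
    front_members,
    generate_table,
    objective_pairs_from_aggregates,
)

config = SimulationConfig(
    n_ligands=200,
    frac_switchable=0.05,
    specificity_delta=2.0,
    replicate_sd=0.3,
    n_replicates=6,
    outlier_prob=0.02,
    outlier_shift=6.0,
    seed=42,
)
observations, ligands, truth = generate_table(config)
planted = {lig for lig, s in truth.switchable.items() if s}
print(f"{len(observations)} replicate scores for {config.n_ligands} ligands; "
      f"{len(planted)} carry a planted +{config.specificity_delta} kcal/mol "
      "acidic-specificity effect")

aggregated = aggregate(observations, q=0.01)
n_outliers = sum(a.n_outliers for a in aggregated)
print(f"outlier elimination removed {n_outliers} replicate(s) "
      f"(~{100 * n_outliers / len(observations):.1f}% of scores)")

points = objective_pairs_from_aggregates(aggregated)
front = front_members(points)
recovered = sorted(p.ligand_id for p in front if p.ligand_id in planted)
print(f"Pareto front has {len(front)} ligand(s); "
      f"{len(recovered)} of them planted: {', '.join(recovered)}")

top = max(points, key=lambda p: p.specificity)
print(f"highest measured specificity: {top.ligand_id} "
      f"({top.specificity:+.2f} kcal/mol, planted={top.ligand_id in planted})")
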
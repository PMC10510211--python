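"""From raw docking-engine output files to a score table.

Docked PDBQT files carry one "REMARK VINA RESULT" line per binding mode;
the first (best) mode's affinity is the replicate's score. This example
writes three mock replicate outputs for one ligand, parses them back, and
aggregates them into a trimmed-mean magnitude.
"""

import tempfile
from pathlib import Path

from paretodock import aggregate, mock_pdbqt_writer, parse_vina_output

with tempfile.TemporaryDirectory() as tmp:
    scores = [-9.0, -9.2, -8.8]
    observations = []
    for rep, score in enumerate(scores, start=1):
        path = Path(tmp) / f"ligA_rep{rep}.pdbqt"
        mock_pdbqt_writer(score, path)
        obs = parse_vina_output(path, ligand_id="ligA",
                                condition_label="acidic", replicate=rep)
        observations.append(obs)
        print(f"parsed {path.name}: best-mode affinity {obs.score} kcal/mol")

(agg,) = aggregate(observations)
print(f"\naggregated |dF| for {agg.ligand_id} ({agg.condition_label}): "
      f"{agg.mean_magnitude:.2f} +/- {agg.sem:.2f} kcal/mol "
      f"(n={agg.n_used}, outliers removed: {agg.n_outliers})")
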
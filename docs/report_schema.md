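# Pareto JSON report schema

`write_report` / `read_report` (and the `pareto` / `run` CLI subcommands)
use this JSON document; the round-trip is lossless.

```json
{
  "format": "paretodock-report",
  "version": 1,
  "ligands": [
    {
      "ligand_id": "CHEMBL3139481",
      "f1_acidic": 9.4,
      "f2_neutral": 8.6,
      "sem1": 0.0,
      "sem2": 0.0,
      "on_front": true,
      "layer": 1,
      "lambda_support": [0.49, 1.0],
      "specificity": 0.8
    }
  ]
}
```

Field semantics:

| field | meaning |
|---|---|
| `f1_acidic` | aggregated affinity magnitude \|ΔF\| in the desired (acidic) environment, kcal/mol |
| `f2_neutral` | aggregated magnitude in the undesired (neutral) environment, kcal/mol |
| `sem1`, `sem2` | standard errors of the two means (reporting only; dominance ignores them) |
| `on_front` | true iff no other ligand in the analyzed set dominates this one |
| `layer` | non-domination layer from non-dominated sorting; 1 = Pareto front |
| `lambda_support` | `[min, max]` scalarization weights (grid resolution) at which the ligand is an argmax of λ·f1 − (1−λ)·f2; `null` for dominated or unsupported ligands |
| `specificity` | f1 − f2, the pH-selectivity measure, kcal/mol |
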
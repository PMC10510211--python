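# Methods

## Problem and model

Conventional virtual screening ranks ligands by a single objective — the
docking-score magnitude |ΔF| (kcal/mol) against one target structure — and
would therefore always prefer the strongest binder. For targets whose
clinically relevant behavior differs between environments, this is the wrong
objective. The motivating case is the μ-opioid receptor (MOR): analgesia
comes from binding in inflamed tissue (acidic, pH ≈ 5.0), while the lethal
side effects come from binding in healthy tissue (neutral, pH ≈ 7.4). Both
the receptor conformation and the ligand protonation state depend on pH, so
a ligand has *two* affinities, one per environment.

`paretodock` treats a screening campaign as a bi-objective optimization over
ligands L:

    maximize  f1(L) = |ΔF(L; acidic)|      (desired environment)
    minimize  f2(L) = |ΔF(L; neutral)|     (undesired environment)

A ligand *dominates* another when it is at least as good in both objectives
and strictly better in one; the non-dominated set is the Pareto front. With
per-ligand aggregated scores in hand, the front is computed exactly by
enumeration — no search heuristics are involved at this stage. The package
deliberately does not address searching chemical space for new structures;
its inputs are score tables for an enumerated library.

Alongside dominance enumeration the package provides:

* **λ-scalarization** — maximizers of `λ·f1 − (1−λ)·f2` for λ ∈ [0, 1].
  Scalarization recovers only the *supported* front members (those on the
  convex hull of the attainable set); non-dominated points strictly inside
  the hull exist and are found only by dominance enumeration, which is why
  the front, not the sweep, is canonical here. No objective normalization
  is applied before weighting: both objectives are already on the same
  kcal/mol scale, and normalizing by range would make the λ-interval
  reported for a ligand depend on unrelated ligands in the table.
* **ε-Pareto fronts** — two relaxations of front membership: successive
  non-domination layers (peel the front, re-run dominance; "second best,
  third best") or an additive tolerance ε under which a point survives if
  nothing dominates it even after improving both its own objectives by ε.
* **Constrained fronts** — the front restricted to f1 ≥ α, guarding against
  ligands that are pH-selective only because they bind weakly everywhere.
  Because any dominator of a point has the larger f1, dominators survive the
  filter whenever the point does; the constrained front is therefore exactly
  the unconstrained front intersected with {f1 ≥ α} and shrinks
  monotonically in α.
* **Top-hit selection** for large libraries: among ligands with
  f2 ≤ neutral_max (default 8 kcal/mol), the k largest by *specificity*
  f1 − f2. This matches practice for ultra-large screens where a shortlist,
  not the whole front, is wanted.
* The **single-objective baseline** with relative relaxation
  (value ≥ (1−θ)·max) for comparison against conventional screening.

Ties: points with exactly equal (f1, f2) do not dominate each other and are
all kept on their common layer — silently dropping one of two
indistinguishable candidates would be worse than reporting both. Dominance
compares point estimates only; the SEMs are carried through to reports but
probabilistic dominance is out of scope.

## Replicate aggregation and outlier elimination

Docking engines occasionally fail a run, leaving a score far from the other
replicates of the same (ligand, condition). Before averaging, replicates
are screened with a robust outlier-elimination procedure of the ROUT family
(robust fit + FDR-controlled residual test), specialized to a
constant-location model since replicate scores of one group have no
regressors:

1. center = median of the group's scores;
2. residuals rᵢ = scoreᵢ − center; robust spread
   RSDR = 68.27th percentile of |rᵢ| × n/(n−1);
3. per-point two-tailed p from |rᵢ|/RSDR against Student's t with n−1 df;
4. test sequentially from the most extreme residual; the i-th most extreme
   is flagged if its p < Q·(n−i+1)/n and all more extreme residuals were
   flagged; stop at the first non-rejection.

Q defaults to 1%, the method's conventional setting. Groups with fewer than
three replicates are retained untouched (with a logged warning): no robust
spread estimate exists there. Degenerate groups (RSDR = 0) flag nothing
when all residuals are zero; a nonzero residual over zero spread is treated
as infinitely extreme. Measured operating characteristics at Q = 1%, n = 6
(recomputed by `scripts/acceptance.py`): a replicate displaced by
6 kcal/mol is flagged in ≈100% of 1000 trials; clean Gaussian replicate
sets (sd 0.1) are flagged in ≈3%.

Aggregation then reports, per (ligand, condition): mean of |score| over
retained replicates, SD, SEM = SD/√n_used, and the retained/flagged counts.
The engine's sign convention (favorable = negative) is preserved through
all I/O; the magnitude convention starts here. Condition contrasts use
two-tailed t tests — unpaired by default, paired available (published
analyses of this kind use both labels inconsistently; neither is declared
canonical here) — and the Šídák adjustment `1 − (1−p)^m` for families of m
comparisons. A full two-way ANOVA decomposition is not implemented: the use
case is pairwise hit-vs-reference contrasts.

## Protonation analysis

Whether a ligand can be pH-selective at all is a chemistry question: its
decisive basic site must be protonated (binding-competent) at pH 5.0 but
neutral at pH 7.4. With site pKa values as *inputs*, the charged fraction
follows Henderson–Hasselbalch: `1/(1 + 10^(pH−pKa))` for bases,
`1/(1 + 10^(pKa−pH))` for acids. A site is dominant-charged when its
charged fraction exceeds 0.5 (exactly 0.5 → neutral: deterministic and
conservative toward the unprotonated form; the threshold at which a
predictor "declares" a protonation state is a convention, and 0.5 majority
is ours). Sites are independent — no microstate coupling — because the
ligands of interest carry a single decisive amine. Temperature dependence
of pKa is ignored. A ligand is *switchable* over (pH_low, pH_high) when any
site's dominant state differs between the two values; for a base this means
pKa lies in the crossover band between them (e.g. NFEPP's 6.8 between 5.0
and 7.4, but not fentanyl's 8.99).

## Synthetic campaign generator

The generator emulates the output structure of a two-condition replicate
campaign, not docking physics. Per ligand: true neutral magnitude ~
Normal(mean, sd) truncated at 0; true acidic magnitude adds a fixed
`specificity_delta` for a planted "switchable" fraction of ligands;
replicates add Normal(0, replicate_sd) noise and are emitted with the
engine's negative sign so the full I/O path is exercised; with probability
`outlier_prob` a replicate's magnitude is displaced by `outlier_shift`
toward weaker binding, the direction failed docking runs produce. Planted
ligands also receive a basic site with pKa uniform in (5.5, 7.0) — inside
the (5.0, 7.4) crossover band, so the protonation classifier labels them
switchable with certainty — and the rest in (8.5, 10.0).

Defaults (200 ligands, 5% planted, base magnitude 8.0 ± 0.8 kcal/mol,
delta 2.0, replicate sd 0.3, six replicates) mirror a focused-library
campaign: magnitudes in the 7–10 kcal/mol range typical of strong binders,
a planted effect the size of the largest published pH-specificity gaps
(≈2 kcal/mol), and replicate scatter at the scale docking SEMs suggest.
Everything is driven by one integer seed through a single `default_rng`;
identical seeds give identical tables.

What the generator does *not* model — and what passing recovery tests
therefore do not show about real campaigns: correlated errors between the
two conditions (the two receptor conformations share most of their
structure), non-Gaussian score distributions, pose-dependent multimodality,
and any coupling between protonation state and score. Recovery results are
statements about the analysis pipeline's behavior under its stated noise
model, not about docking accuracy.

Under those study conditions the pipeline's top measured-specificity hit is
a planted ligand sitting on the Pareto front in ≈100/100 seeded campaigns
(recomputed by the acceptance script). Note that all planted ligands share
one true specificity delta, so "the" planted top hit is identified by
measured, not true, specificity — between near-identical plants the
ordering is replicate noise.

## Numerical and design choices

* Front algorithm: sort by (f2 ascending, f1 descending), one vectorized
  sweep of the running maximum of f1 — O(n log n); an O(n²)
  pairwise-dominance oracle is retained (`oracle_front_members`) and the
  two are cross-checked on 200 random tables up to n = 500. Non-dominated
  sorting peels the front repeatedly; a 50 000-ligand table runs
  aggregate + full Pareto annotation in a few seconds on one CPU.
* Dominance comparisons are exact float comparisons — scores arrive with
  one-decimal precision from engines, and exact ties are meaningful
  (duplicate coordinates share a layer). No tolerance is injected.
* λ-support intervals are reported at grid resolution (101 points by
  default): the interval is [min, max] of the grid weights at which the
  point is an argmax. Closed-form breakpoints would add complexity the
  one-percent grid already resolves for reporting purposes.
* The additive-ε front uses an O(n²) check; it is intended for shortlists,
  not 50K tables (layers mode scales).
* The t statistic of identical samples is defined as 0 with p = 1 (scipy
  returns NaN when both samples have zero variance).
* CSV dialect is fixed: comma separator, UTF-8, header required, decimal
  point. Missing replicate indices are assigned from file order and logged.
* Library composition fixture: of the 55-entry focused manifest only the
  named reference compounds carry real identifiers and pKa values
  (fentanyl 8.99, morphine 8.21, NFEPP 6.8); the remaining entries are
  synthetic placeholders for identifiers not individually published, and
  are tagged as such in their metadata.

## Known limitations

* Bi-objective only; the formulation generalizes to more environments or
  anti-targets, but no >2-objective front machinery is provided.
* No probabilistic dominance: a front membership decided by 0.01 kcal/mol
  between ligands with 0.1 kcal/mol SEMs is reported as-is, with the SEMs
  alongside, and should be read accordingly (use the layers relaxation for
  a shortlist robust to this).
* pKa values are inputs; the package neither predicts them nor transforms
  SMILES (no desalting, tautomers, conformers).
* The docking step itself — structure preparation, engines, grids — is out
  of scope; the package starts at engine output files.
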
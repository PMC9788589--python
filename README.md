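# gemflux

Transcriptome-constrained genome-scale metabolic modeling: extract
context-specific metabolic models from RNA-seq expression, predict
expression-aligned flux distributions, and analyze how metabolic function
shifts across disease states.

The package re-implements, as a tested and reusable pipeline, the analysis
strategy used in multi-state liver-disease studies: bulk RNA-seq profiles
from several disease states are integrated with a constraint-based
metabolic model (reactions, stoichiometry, bounds, gene-protein-reaction
rules), one sub-model is extracted per state, fluxes are predicted per
state, and the states are compared structurally (which reactions survive),
functionally (which subsystems carry different flux), and geometrically
(pseudo-temporal trajectories over states). Because patient data of this
kind is access-controlled, the package ships a synthetic-data generator
that emulates the study design — 8 liver states, ~10 samples each, a
planted pathway whose activity rises monotonically with disease severity,
and a second branch of non-alcohol-related states — so that every stage is
exercised end-to-end against known ground truth.

## Method

**Context extraction.** Each reaction carries a GPR rule over genes
(AND = enzyme complex, OR = isozymes). Expression counts are TPM-normalized
(each sample sums to 10⁶), aggregated per state, and scored through the
rules: AND takes the minimum, OR the maximum of gene values. A reaction is
kept when its score exceeds 1 TPM (strict); rule-less reactions are
retained. A metabolic task list (produce required outputs from allowed
inputs at steady state) then guards viability: failed tasks are rescued by
adding back a minimal-cardinality set of excluded reactions, tagged
separately from expression-supported ones.

**Flux prediction.** With per-reaction scores g, the objective direction is

    f' = argmax  (v · g) / (‖v‖ ‖g‖)   s.t.  S v = 0,  v ≥ 0 (split space)

— the feasible flux direction best aligned with expression. Since the
feasible set is a convex cone C and the objective is scale-invariant, the
optimum is the Euclidean projection P_C(g) normalized, with achieved cosine
‖P_C(g)‖/‖g‖. Fluxes then come from a two-stage solve:

    z* = max f'·v    s.t.  S v = 0,  g_min ≤ v ≤ g_max      (LP)
    v* = argmin Σ vⱼ²  s.t.  the same constraints and f'·v = z*   (QP)

where irreversible scored reactions get bounds [0, gⱼ], reversible ones
[−gⱼ, gⱼ], and rule-less/exchange reactions keep model bounds. The strictly
convex second stage makes v* unique.

**Downstream analysis.** Context models are compared as binary reaction
presence vectors (Hamming similarity), rank-ordered by coverage counts, and
screened per subsystem for >10 % pairwise differences with a gene-rule
drill-down. Fluxes above 0.1 mmol/gDW/h ("measurable") are summed per
subsystem, screened with pairwise two-sided Wilcoxon rank-sum tests
(p < 0.05, exact for small untied samples), hierarchically clustered
(average linkage, 1 − Pearson distance), and transport clusters are mapped
to imported/exported species. State profiles (genes or fluxes) are embedded
with PCA and linked by a minimum spanning tree; a depth-first walk from a
chosen root yields a pseudo-temporal ordering with branch points.

## Worked example

```python
from gemflux import SimulationConfig, run_synthetic_analysis

res = run_synthetic_analysis(SimulationConfig(seed=1))
state = "severe_AH"
print("kept reactions:", len(res.contexts[state].kept_reactions))
print("SPOT cosine:", round(res.objectives[state].achieved_cosine, 4))
print("measurable fluxes:", len(res.measurable))
chain = res.truth.ald_chain[0]
for s in ["healthy", "early_ASH", "nonsevere_AH", "severe_AH", "explant_AH"]:
    print(f"  {s:14s} {res.flux_table.loc[chain, s]:6.2f}")
print(res.flux_trajectory.orderings["healthy"])
```

prints

```
kept reactions: 60
SPOT cosine: 0.8189
measurable fluxes: 60
  healthy          5.65
  early_ASH        8.82
  nonsevere_AH    10.90
  severe_AH       17.16
  explant_AH      22.82
['healthy', 'comp_cirrhosis', 'HCV', 'NASH', 'early_ASH', 'nonsevere_AH',
 'severe_AH', 'explant_AH']
```

All 60 reactions survive extraction (all pathways are active in this
design), the achieved expression–flux cosine is ≈0.82, and the predicted
flux through the planted glutathione-like chain rises monotonically with
disease severity — the signal the generator planted. The flux-space MST
walked from `healthy` traverses the non-alcohol branch and then the
alcohol-severity branch in planted order.

The same pipeline is available from the shell:

```bash
gemflux run-all --outdir out --seed 1        # all stages + manifest
gemflux simulate --outdir data --seed 1      # synthetic inputs only
```

`out/` then contains the context models with provenance, presence/similarity
matrices, flux tables, subsystem statistics, transport cluster reports, PCA
coordinates, MST edge lists and trajectory orderings, plus a run manifest;
reruns with the same seed are byte-identical.

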
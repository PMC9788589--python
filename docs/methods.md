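# Methods

This note records the modeling choices behind gemflux: what each stage
assumes, the parameters that matter, what the synthetic study does and does
not emulate, and the numerical decisions.

## Model representation and GPR semantics

A metabolic model is a set of reactions over compartmentalized metabolites
with bounds in mmol/gDW/h, exactly one subsystem label per reaction, and an
optional GPR rule. Reversibility is derived from the lower bound (lb < 0).
Transport and exchange flags are always derived from stoichiometry — a
reaction is transport iff some chemical species (metabolite name, ignoring
compartment) appears in two compartments, exchange iff it touches a single
metabolite — and never trusted from input files, so transport analyses are
reproducible from structure alone.

GPR rules are boolean expressions with AND binding tighter than OR and
case-insensitive operators. Scoring is min over AND children (a complex is
limited by its scarcest subunit) and max over OR children (any isozyme
suffices). A gene absent from the expression profile scores 0 with a
warning: absent evidence excludes, consistent with the threshold rule's
spirit. Unique-rule counting canonicalizes rules by recursively sorting
operands, so `G1 AND G2` and `G2 AND G1` are one rule.

## Expression handling

Counts are TPM-normalized per sample (`1e6 · (c/l) / Σ(c/l)`); an all-zero
sample yields an all-zero column with a warning rather than NaNs.
Aggregation to state level is exposed as `max` or `mean`. The pipeline
deliberately uses both: the extraction threshold consumes max-TPM profiles
(a reaction is kept if the rule evaluated on per-gene maxima exceeds
1 TPM), while the flux stage consumes state-averaged profiles. These
mirror the two aggregation conventions the upstream methods state for the
two uses, and each is a config key (`aggregation_method`,
`flux_aggregation_method`) so either reading can be forced for both.

## Context extraction and gap-filling

Extraction implements the published threshold rule directly — keep scored
reactions with g > 1 TPM (strict), retain rule-less reactions (flag to
drop) — rather than a weighted MILP inclusion objective; we do not call it
tINIT. Task feasibility is an LP: steady state over the kept reactions,
temporary uptake columns bounded by each input's maximum, temporary demand
columns bounded below by each output's minimum (capped at 1e4 so the LP
stays bounded), decided at constraint residual 1e-6.

Gap-filling searches excluded parent reactions for a minimal-cardinality
set restoring all tasks: exact search by increasing cardinality (candidates
in lexicographic id order, so ties resolve to the smallest set, then the
smallest ids) up to 20 candidates; beyond that, a greedy that repeatedly
solves an L1-relaxed task LP on the parent (minimize total |flux| through
excluded candidates) and admits the most-used candidate. The mode used is
recorded on the context model (`exact` / `greedy` / `none_needed`), and
rescued reactions carry the `task_rescued` provenance tag so recovery
statistics can exclude them.

## Flux prediction

The objective direction maximizes the uncentered cosine between flux and
the per-reaction score vector over {S·v = 0, v ≥ 0} in the
forward/backward-split space (reversible reactions contribute two
non-negative columns, both weighted by the reaction's score; rule-less
reactions get weight 0). The prose name of this construction mentions
Pearson correlation, but the defining formula is the uncentered cosine;
the formula is what we implement, with a mean-centered variant behind the
`centered` flag for comparison. Because the feasible set is a convex cone
C and the ratio objective is scale-invariant, max over C ∩ {‖v‖ ≤ 1}
equals ‖P_C(g)‖ attained at P_C(g)/‖P_C(g)‖ (Moreau decomposition), so the
whole problem reduces to one Euclidean projection onto {S·w = 0, w ≥ 0}.
A zero projection (no expression-aligned feasible direction) is returned
as an explicit degenerate result. When mapping the split optimum back,
overlapping forward/backward components (a futile two-cycle the cone
admits) are cancelled and the direction renormalized to unit length.
Expression-derived bounds follow the stated convention: [0, g] for
irreversible scored reactions, [−g, g] for reversible ones — the printed
bound pair is never defined separately from g, so ±g is our documented
reading — and parent bounds for rule-less and exchange reactions.

Stage 1 is an LP (HiGHS); stage 2 minimizes Σv² subject to the same
constraints plus f'·v = z*. Both QPs in the pipeline are projections onto
{affine ∩ box} sets and are solved by Dykstra alternating projections
(affine step via a precomputed pseudoinverse) followed by an active-set
polish that solves the KKT system exactly on the guessed active set; the
stage-1 LP vertex is passed in as a warm feasible point and last-resort
fallback. This in-house kernel exists because the problems are small
(tens to a few hundred variables) and it delivers ~1e-10 feasibility
without a dedicated QP dependency. If z* sits at the exact boundary of
feasibility after rounding, the equality is retried with backoffs of
1e-9 and 1e-7 relative slack.

Tolerances are centralized: feasibility 1e-6 on constraint residuals,
1e-5 agreement between independent solves of the (unique) stage-2 QP,
1e-9 internal convergence.

## Flux statistics

Subsystem activity sums |v| (reversible-flux sign is a solver convention;
a signed option exists). The Wilcoxon rank-sum test uses midranks, an
exact null for n + m ≤ 16 without ties and a tie- and continuity-corrected
normal approximation otherwise. The subsystem screen treats per-reaction
fluxes within a subsystem as replicate units — with one model per state
there are no biological replicates, and this choice is recorded in the
output metadata rather than silently assumed. Raw p < 0.05 with no
multiplicity correction is the default, mirroring the original screens; a
Benjamini–Hochberg option exists but is off by default. Clustering is
agglomerative with average linkage on 1 − Pearson distance between
z-scored rows (the common heatmap default; both are config-exposed), with
zero-variance rows given distance 1 to everything and 0 to each other so
degenerate rows cluster together instead of producing NaNs. Transport
orientation needs a designated interior compartment (config key, default
`c`): a species is imported when its net flux-oriented production in the
interior is positive, and species seen in both directions within a
cluster are dropped.

## Trajectories

PCA always centers; unit scaling defaults on for gene matrices and off
for flux matrices (fluxes share units). Component signs are fixed by
making each axis's largest-magnitude loading positive, so outputs are
byte-reproducible. The MST is computed on Euclidean distances in the
leading PC space (enough components for 90 % variance, config default);
the published displays use non-symmetric correspondence-analysis axes,
which are a plotting layout and out of scope here. Kruskal's algorithm
sorts edges by (weight, label pair) so equal-weight ties always resolve
the same way. Orderings are depth-first from a chosen root with
lexicographic neighbor order; nodes of tree degree ≥ 3 are branch points.

## Synthetic study design

The generator emulates the 8-liver-state design: 4 states of increasing
alcohol-related severity (healthy → early_ASH → nonsevere_AH → severe_AH →
explant_AH) and a non-alcohol branch (comp_cirrhosis, HCV, NASH), 10
samples per state. The network is built from metabolite-disjoint 6-reaction
pathway modules (exchange-in, transport-in, two conversions — organelle-
routed in some modules — transport-out, exchange-out), 10 modules at the
default 60 reactions. Two modules are planted: a glutathione-like chain
scaled by strictly increasing severity multipliers (1, 1.5, 2.2, 3.1, 4.2)
in the alcohol states, and a lipid-like chain scaled (2, 3, 4) in the
non-alcohol states only, giving the state geometry a recoverable
two-branch trajectory rooted at healthy; the branch multipliers are chosen
large enough that the two disease axes are separated beyond the expression
noise floor (near-equal first steps on both axes would make the junction
geometry ambiguous by construction, not by noise). Filler modules get
log-uniform base rates in [0.4, 2.5] — pathway activities spread over
nearly an order of magnitude, so rank-recovery is measured against a
realistic dynamic range — plus 5 % lognormal per-state jitter. Because
modules are metabolite-disjoint chains, uniform per-module flux is exactly
steady-state, so ground-truth fluxes satisfy S·v = 0 to machine precision
and the planted ordering is exact.

Expression ties each gene's state-mean TPM to its reaction's activity
(5 TPM per unit flux when active, 0.2 TPM when inactive; genes are private
to one reaction so the mapping is clean). Background genes absorb the rest
of the library so state targets sum to 10⁶ and realized TPM equals the
target in the noiseless limit. Counts are negative-binomial around
expected fragment counts at 2×10⁷ fragments with dispersion 0.05
(var = μ + 0.05 μ²); dispersion 0 returns expectations exactly, which the
noiseless-limit tests rely on. One integer seed fixes the network, the
fluxes and the counts.

What the generator does not emulate: transcriptome scale (hundreds of
genes, not 20k), inter-patient clinical covariates, shared currency
metabolites and cofactor coupling between pathways, isoform-level
quantification, and batch effects. Passing recovery tests therefore show
that the pipeline's inference is correct when expression genuinely tracks
activity at realistic noise; they do not show that real liver RNA-seq has
that property.

## Pipeline and determinism

Stages run as simulate → expression → extract (per state) → compare →
flux → measurable filter → statistics → trajectory, orchestrated by a
single YAML config validated against a closed key set (unknown keys are
errors naming the key). Every output table is written with sorted labels
and fixed float formatting; all randomness flows from the one seed, so
reruns are byte-identical apart from the manifest timestamp. Stage
problem sizes default to the 60-reaction, 8-state, 10-sample study, which
keeps a full run around a second and the 100-seed trajectory-recovery
measurement around a minute.

## Known limitations

- The greedy gap-fill fallback is not guaranteed minimal (flagged in
  provenance when used).
- The SPOT cone can contain futile two-cycles for reversible reactions;
  they are cancelled when mapping back, which changes the direction's
  support but not the reported cosine (computed in split space).
- The Wilcoxon subsystem screen's replicate unit (per-reaction fluxes)
  makes reactions within a subsystem the exchangeable units; subsystems
  with strongly correlated internal fluxes overstate effective sample
  size.
- Dykstra + active-set polish is exact for these desk-scale projections
  but has no convergence guarantee at very large scale; it is not
  intended for genome-scale (10⁴-reaction) models.
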
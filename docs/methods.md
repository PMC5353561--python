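# Methods

This note documents the statistical procedures, parameter choices and
numerical conventions implemented in `regustress`, and what the synthetic
studies do and do not establish about real data.

## Data model and conventions

Expression values are log2-scale throughout; fold change is
`2**(mean_log2_treatment − mean_log2_control)`, which makes the 1.2 gate
scale-consistent and leaves all calls invariant under adding a constant to
every log2 value. Matrices may not contain missing values (the generator
never emits them), identifiers are case-sensitive strings with no symbol
aliasing, and each matrix row is one gene (probe-to-gene aggregation is a
data-curation step upstream of this package).

A gene is *expressed* iff its mean log2 value across **all** study
samples is ≥ `detection_threshold` (default 4.0 log2 units, against
baselines generated on [6, 12]; closed lower bound). The threshold behind
published expressed/not-expressed accounting is never stated in the kind
of study this pipeline supports, so it is an explicit parameter; genes
failing the gate are `not_expressed`, carry no fold change or p-value,
and are excluded from every proportion denominator.

Displayed percentages round half away from zero; this convention
reproduces standard printed proportions (20/26 → 77%, 12/13 → 92%).

## The acute-stress (NEA) rule and its rank test

`up` iff FC > 1.2 **and** p < 0.05; `down` iff FC < 1/1.2 and p < 0.05;
all inequalities strict; no multiple-testing correction by default
(Benjamini–Hochberg is available in the enrichment module, and the rule's
thresholds are parameters). Degenerate rows (all values tied) get p = 1.

The rank-test choice deserves care. The emulated microarray designs
compare unpaired groups of 3-vs-3 or 8-vs-4 replicates. A Wilcoxon
signed-rank test is ill-defined for unpaired, unequal groups, so the
default is the Mann–Whitney rank-sum test. For the *exact* two-sided
rank-sum distribution at 3-vs-3, the smallest attainable p is
2/C(6,3) = 0.1: an exact test can never reject at 0.05, and the rule
would never call a single gene on a 3-replicate design. The default is
therefore the **normal approximation without continuity correction**,
whose p at perfect 3-vs-3 separation is ≈ 0.0495. `ranksum_exact` and
`signed_rank` (pairing by position, truncated to the shorter group)
remain configuration options for larger designs.

### Calibration consequences (known limitation)

This choice has a quantified cost. At n = 3 vs 3 the attainable sizes of
any two-sided rank decision are {0, 0.1, 0.2, …}; there is no rejection
region of size 0.05. The gated rule (FC gate ∧ p < 0.05, normal
approximation) rejects exactly on perfect separation joined with a large
enough mean difference, and its true null rate at noise sd 0.25 is
≈ 0.075 on 3+3 contrasts versus ≈ 0.036 on 8+4 contrasts. Pooled over the
emulated seven-contrast design (five 3+3, two 8+4) the null DEG rate is
≈ 0.063 — slightly above the nominal α = 0.05 and above the
α + 3·SE(5,000 genes) ≈ 0.059 band; the corresponding calibration test in
the suite documents this and fails by design rather than masking it. No
rank-based variant can simultaneously achieve size ≤ 0.05 and nonzero
power at three replicates; users who need strict size control at n = 3
should treat 3-replicate calls as descriptive or raise the fold-change
gate. The FC gate is strongly conservative on the larger designs, where
the rule's false-positive rate is well below α.

Power is not the bottleneck: at a planted log2 effect of 1.0 and noise
sd 0.25, sensitivity on 3-replicate contrasts is ≈ 0.98 (perfect
separation is almost certain at a 4-sd shift).

## The adaptive-evolution (EA) rule

With a single parent reference there is no within-group variance to test,
so the rule is deterministic: unanimous direction across all evolved
strains on the linear scale plus mean relative difference
`mean(dᵢ)/linear(parent)` strictly above 20%. The relative difference is
computed on the linear scale because a percentage change of an expression
level reads naturally as a linear ratio; a log2-scale variant is
available behind `ea_scale="log2"`. The reported `mean_rel_diff` is
signed; `fold_change` is the ratio of the evolved mean to the parent.

## Regulon response profiling

Proportions are counted over expressed set members only; sets with zero
expressed members in a contrast are flagged undefined and excluded from
correlations. Response levels offer three summaries (`mean_lfc`,
`prop_up_minus_down`, `mean_expression`) because published dose-response
correlations do not pin down how a regulon's expression was collapsed to
one number per sample; the method used is always recorded alongside the
coefficient. Pearson is the default correlation (Spearman selectable);
duplicated covariate values (the four 15% contrasts) are retained as
distinct points, matching the design. Constant inputs yield an undefined,
flagged result — never r = 0. Enrichment is a one-sided hypergeometric
tail with the expressed genes as the default universe (standard practice;
the universe is a parameter because externally published enrichment
universes are unknowable).

## TU aberrancy

The TF-level call is the TF gene's own call from the DEG table; the
TU-level call collapses member-gene calls by strict majority over
expressed members (``any`` and ``all`` rules available). Only TUs whose
sole regulator is the TF under scrutiny are scored. The four-case rule
enumerates only `ns` and `up` TF states; `down` TFs are scored
*indeterminate* and excluded from numerator and denominator — silently
scoring an unlisted state would invent method. "The TU is not up" is
implemented as TU ≠ up (both `ns` and `down`). The classifier is verified
against an exhaustive 18-row truth table.

## Evolution trends

Monotonicity is assessed on per-time-point log2 fold change versus the
parent (not raw values, not call sequences): monotone-up means every
consecutive difference ≥ −`tie_tolerance` with at least one difference
strictly above it (default tolerance 0; a constant series is
non-monotone). The classifier is invariant under strictly increasing
transforms of the whole series. *Step-wise* is a stricter flag: monotone
with strict steps at all but at most one consecutive difference (≥ 3 of 4
in the five-point design); the distinction is explicit and tunable
because the two notions are often conflated. Concordance is the percent
of annotated, expressed (optionally DE-filtered) gene×strain trends
matching the annotation direction (overexpression-tolerant → monotone up,
knockout-tolerant → monotone down); pooled and per-strain tallies are
both emitted since either accounting is defensible. The region-shift
test pairs genes across the two time points of one strain and applies a
one-sided Wilcoxon signed-rank test (p = 1 when all differences vanish);
its null p-values were checked against uniformity (KS, scaled-down
simulation) and an exhaustive sign-flip enumeration oracle.

## Synthetic studies

The generator emulates the study conditions: seven acute-stress contrasts
with replicate counts (3+3, 8+4, 8+4, 3+3, 3+3, 3+3, 3+3) and ethanol
doses (2.5, 5, 3, 15, 15, 15, 15)% v/v, and an evolution design of six
strains at (0, 384, 744, 1224, 1824, 2496) h against a single parent.
Baselines are uniform on [6, 12] log2 units; noise is i.i.d. Gaussian on
the log2 scale, sd 0.25 by default (a t(5) option, variance-matched,
exists for robustness checks). Planted structure: DEGs at log2 effect 1.0
with random sign; dose-responsive sets shifted linearly in ethanol %
(0.05 log2/% by default); sole-regulator TUs of ethanol-binding TFs
shifted consistently with — or decoupled from — their regulator's planted
state; monotone trajectories accumulating 0.3 log2 per step, with a
planted 91% of tolerance-annotated genes concordant with their
annotation. All randomness flows from one seed through derived streams;
identical config + seed gives byte-identical fixture files.

What these fixtures do **not** model: probe-level physics, within-gene
probe variation, correlated noise between genes, batch effects, or
missing values. Passing recovery tests therefore demonstrates the
correctness of the rules and plumbing under the stated noise model, not
robustness to real microarray artifacts.

## Problem sizes used in tests and the acceptance script

Simulation-based checks use 300–400 genes per study, 10–20 seeds, and
5,000 genes for the null-calibration run; these sizes give stable
estimates (binomial SEs well inside the asserted margins) while keeping
the suites quick. Recovery conditions are the stated study conditions:
log2 effect 1.0 and sd 0.25 for DEG sensitivity, effect 1.5 and sd 0.1
(strong effect, low noise) for aberrant-TU recovery, sd 0.05 (low noise)
with 200 annotated genes for the 91%-concordance recovery.
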
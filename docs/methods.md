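# Methods

## The experimental design being modelled

The package targets AP-MS experiments built on a Cre-switchable dual-tag
allele. A matched *couple* is one wild-type (WT) and one cassette-carrying
(TURNX) mouse; each animal's lysate is immunoprecipitated with anti-HA,
anti-V5 and isotype-control (Ig) beads, each arm in replicate. The default
`StudyDesign` is 4 couples × 2 genotypes × 3 arms × 4 replicates = 96 IP
fractions (24 per couple). For each tag the case group is (TURNX, tag) and
the three negative-control groups are (WT, tag), (TURNX, IG) and (WT, IG):
the same-arm WT pull-down is the only control that can expose proteins
binding the anti-tag antibody itself, which is why it exists.

Whether the four fractions per mouse are technical or biological replicates
is deliberately left open in the sample sheet; the statistical consequence
is handled by `replicate_unit` (below).

## Quantification

**Pairwise-ratio geometric-median rollup.** For one protein, each peptide
observed in ≥ 1 case and ≥ 1 control sample contributes the geometric median
of all cross-pair ratios `a_i / b_j`; the protein ratio is the geometric
median of the peptide ratios. "Geometric median" of positive scalars is
interpreted multiplicatively — `exp(median(log x))` — because for scalars
the Euclidean geometric median degenerates to the ordinary median, and the
log-scale convention makes two properties exact rather than approximate:

* *inversion symmetry*: swapping case and control inverts the ratio;
* *scale equivariance*: scaling all case intensities by k scales the ratio
  by exactly k.

For an even number of values the median of logs is the midpoint of the two
central values, i.e. the geometric mean of the two central ratios; this is
the unique even-count rule consistent with inversion symmetry. Cross-pair
enumeration (all `a_i/b_j`) rather than index-matched pairing is used
because replicates are not paired across animals.

**Saturation and presence/absence.** Reported ratios are clamped to
[1/100, 100] with a `capped` flag; reported p-values are floored at 1e-17.
These are the saturation conventions of published interactome tables of
this kind, and they are configurable (`QuantConfig`). A protein detected
(any peptide) in at least `min_present_replicates = 3` case samples and in
no control sample bypasses ratio estimation: it is called `CASE_ONLY` at the
ceiling (mirror case `CONTROL_ONLY` at the floor). The threshold of 3-of-4
guards presence calls against single-replicate contamination; upstream
software's exact rule for such calls is generally unstated, so the value is
a package convention.

Two implementations exist — a scalar reference (`protein_ratio`) and a flat
numpy bulk path (`protein_ratios`) used by the screen — and the test suite
asserts their equality; both are checked against a brute-force
enumerate-and-sort oracle.

## The enrichment screen and the purge

`InteractionScreen.fit()` computes, per protein detected in the case group:

* the abundance ratio against the three control groups **pooled** (one
  printed ratio per protein), and
* a two-sided Welch (unequal-variance) t-test on log2 abundances against
  **each** control group separately.

A protein is significant iff `max(p over the 3 controls) ≤ alpha`
(default 0.05) **and** `ratio ≥ min_fold` (default 1, i.e. enrichment
direction only — the modelled procedure states no fold cutoff). The
reported p is that maximum. No multiple-testing correction enters the
decision; a Benjamini–Hochberg column (`q_BH`, statsmodels) is emitted for
information only. Output ordering is fixed (descending ratio, ascending p,
accession) so reruns are byte-identical.

**Abundance per sample** is the log2 of the summed intensities of the
protein's observed peptides. With the default `replicate_unit=MOUSE_MEAN`,
the fractions of one mouse are averaged on the log2 scale into a single
observation (4 mice per group under the default design): the fractions of
one animal are not independent samples of the population. `FRACTION` mode
treats every fraction as an observation for users who regard the replicates
as biological.

**Welch test details.** The statistic uses Satterthwaite degrees of freedom
and the Student-t survival function (`scipy.special.stdtr`); it matches
`scipy.stats.ttest_ind(equal_var=False)` to 1e-10 relative (asserted in the
tests). Degenerate inputs are resolved before the statistic: two identical
constant groups give p = 1; two different constant groups give the p floor;
a protein with ≥ `min_present_replicates` case observations and none in a
control group gets the floor (the presence-only convention); anything else
with fewer than two observations in a group is excluded as insufficiently
replicated and counted in the run summary.

## Cross-tag comparison

Overlap is computed on accession sets after removing a user-supplied core
set (the bait's own complex, which both tags must recover and which would
otherwise mask the cell-type signal). Tag specificity is
`100·(1 − n_common_noncore/(n − n_core))`. Percentages everywhere are
rounded half-up to one decimal by a single shared routine, so printed
numbers are reproducible to the digit. Accessions are compared verbatim by
default; an optional isoform-merging map (accession → gene symbol) collapses
multi-isoform genes to one entry before counting, which is how a core
complex represented by two isoform accessions yields the expected member
count. `known_fraction` scores a list against a user-provided reference of
previously reported interactors (the package ships no interaction
database); its denominator is the whole list including core members.

## The synthetic-data generator

The generator emulates what the purge must separate, not the physics of a
mass spectrometer. Protein classes and default counts:

| class | count | enriched in |
|---|---|---|
| bead background | 500 | nowhere (uniform across all 96 samples) |
| cross-reactive per tag | 30 | every sample of that arm, both genotypes |
| core complex | 11 | case group of both tags |
| tag-specific per tag | 40 | that tag's case group only |

Peptide log2 intensities are normal around a class-and-group-dependent mean:
protein baseline 20 (between-protein SD 1.5), peptide ionization offset
SD 1, replicate noise from a 25% biological CV
(`sd_log2 = sqrt(ln(1+cv²))/ln 2 ≈ 0.36`), true enrichment a deterministic
8-fold (log2 +3) for enriched (protein, group) pairs. Peptides per protein
are `1 + Poisson(mean−1)` with total mean 4. The 8-fold default places
recovered ratios well inside the ~2–100 range an interactome purge
operates over while leaving the Welch tests non-trivial at n = 4 mice.

Missingness has two parts: censoring below a detection floor (log2 = 16,
i.e. 4 log2 units below baseline — missing-not-at-random, the mechanism
behind presence/absence calls) and a 5% uniform dropout. One
`numpy.random.Generator` stream seeded from `config.seed` drives every
draw, so identical configurations reproduce tables bit for bit.

The realized fold recorded in the truth table equals `fold_enrichment`
exactly for enriched classes and 1 otherwise; no per-protein fold
dispersion is drawn, so setting `fold_enrichment=1` produces an exact
global null (used for calibration tests).

What the generator does **not** emulate: shared/razor peptides (each
peptide belongs to one protein), between-run intensity drift and
normalization, correlated contaminant structure, mouse-level random
effects, and heavy-tailed peptide noise. Passing tests therefore
demonstrate the correctness and calibration of the *procedure* under its
stated model, not the behaviour of any real instrument or cohort.

## Operating characteristics (computed by the test suite)

Under the default study conditions the acceptance tests measure, over
seeds: a null purge pass rate far below α (fold 1, 20 seeds; each protein
must clear three correlated tests *and* the enrichment-direction gate);
≥ 90% recovery of the true core + tag-specific set per tag (fold 8,
10 seeds); and for cross-reactive binders, significance against both Ig
groups with every removal attributable to the same-arm WT comparison. For
a cross-reactive protein that comparison is an exact null (it is equally
enriched in both genotypes of the arm), so its removal rate is 1 − α in
expectation, not 1: at α = 0.05 about one in twenty slips through — a
property of any raw-p threshold rule, visible in the worked example. The
test asserts the removal rate within three binomial standard errors of
1 − α rather than demanding literal completeness.

## The cassette model

Lox elements are detected as `arm5 + N8 + arm3` with the canonical 13-bp
arms; the spacer is unconstrained, so variant-spacer sites are found. The
arm pair is its own reverse complement, so a single forward-strand scan
covers both orientations; orientation is a property of the asymmetric
spacer, and a two-site pair is *direct* (excisable) when the spacers match
verbatim and *inverted* (rejected) when they are reverse complements.
Coordinates are 1-based inclusive. Excision removes start(site1) ..
start(site2)−1, retaining exactly one lox copy, so the sequence shortens by
the start-to-start distance — this makes the genotyping arithmetic exact
and flank-independent: turned amplicon = knock-in amplicon − distance, and
only the restriction fragment containing the cassette shrinks. Digests use
a cut offset within the recognition site (TaqI convention T^CGA); only
fragment sizes are modelled, not sticky ends. Absolute insert-length
reconstruction from the donor alone is *not* attempted: the primer sites
lie outside the printed donor sequence, so all amplicon sizes are derived
from the assay's printed anchors plus donor-measured differences.
Spacer-compatibility between variant lox sites is not modelled beyond the
equal-spacer requirement.

## Problem sizes and determinism

The default simulated dataset is 651 proteins × ~4 peptides × 96 samples
(~230k observed intensities); a full two-tag screen of it runs in about a
second. Calibration tests use 20 null + 10 default simulations. All
randomness flows from explicit integer seeds; no test or script depends on
global RNG state.
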
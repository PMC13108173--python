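# Methods

## Problem and overall procedure

`mirdrift` estimates per-year age trends in two molecular layers of one
tumor cohort — miRNA expression from sequencing counts and promoter CpG
methylation from array β-values — joins them per miRNA, and classifies
each candidate against the canonical model of methylation-mediated
regulation: promoter hypermethylation with falling expression, or
hypomethylation with rising expression. Downstream, direction-only
cross-cohort validation and a bipartite miRNA–target network summarize
replication and regulatory convergence. Age is always modeled as a
continuous covariate, mean-centered for conditioning.

## Expression layer

Counts for each retained miRNA are fit with a negative-binomial GLM (log
link): intercept, centered age, optional clinical covariates, and a
library-size offset. Choices, where several were defensible:

- **Normalization** — median-of-ratios size factors (geometric-mean
  reference over features positive in every sample, falling back to
  relative totals). A consequence worth knowing: a trend shared by
  essentially *all* features is absorbed into the size factors and is not
  attributable to any one feature; the planted-recovery tests therefore
  plant trends in a minority of features, as in real cohorts.
- **Dispersion** — per-feature method of moments on normalized counts,
  `alpha = (var − mean)/mean²` floored at 1e−8, then shrunk 50% (log
  scale) toward the across-feature median. The shrinkage stabilizes
  features whose moments are noisy at cohort sizes of a few hundred;
  simulation at n = 200 with 500 null features puts the empirical
  type-I rate of the Wald test at ~0.05. A fixed shared alpha is
  available (`dispersion_mode="fixed"`).
- **Scale** — the natural-log age coefficient and its SE are divided by
  ln 2, so effects read as log2 fold change per year; percent change per
  year is `(2^b − 1)·100` (b = 0.015 → ≈1.05 %/year).
- **Low-expression filter** — keep features with ≥ 5 reads in ≥ 20% of
  samples (both configurable).
- **Degenerate features** — constant features are dropped before
  fitting; non-convergent fits get missing p and are excluded from the
  BH family; both counts are logged.
- **Two-stage selection** — exploratory FDR ≤ 0.10, then final FDR ≤
  0.015 with |log2FC/year| ≥ 0.015. The two 0.015 values are independent
  knobs that happen to share a default.

## Methylation layer

β-values (bounded methylation fractions) are regressed directly on
centered age by OLS, one fit per probe, vectorized through a single
least-squares solve since all probes share the design. β rather than
M-values is deliberate: at cohort-scale effect sizes (~10⁻³ β/year) the
bounded scale is the interpretable one and slope recovery is excellent
(≥95% of fits within 3 SE of a planted slope of 0.002 at noise sd 0.01,
n = 400). Zero-variance probes get slope 0, missing p, and exclusion from
the BH family, which is applied once genome-wide before any promoter
restriction.

Promoter geometry: the TSS is the locus start on `+` and the end on `-`;
the window is the closed interval ± 2 kb (configurable), floored at
position 1. Coordinates are 1-based inclusive throughout, the manifest
convention for point CpG positions; GFF3 input is 1-based natively and
BED starts are shifted on read. Probe→promoter assignment is
many-to-many: a CpG inside two overlapping promoter windows counts in
both summaries — the literal reading of "all promoter-associated CpGs".
Mapping is interval-tree based and tested for exact agreement with an
exhaustive overlap check on random instances. Per-miRNA summarization is
the arithmetic mean of mapped, fitted CpG slopes with the minimum
adjusted p retained; miRNAs with no fitted CpG are omitted and surface
downstream as missing-methylation (NA) cases.

## Identifier harmonization

All joins run on base ids: lowercase, strip one species prefix, strip one
*terminal* `-5p`/`-3p` arm token, drop hyphens. Two refinements over the
naive statement of the rule:

- the three-letter species prefix is stripped only when followed by a
  `mir`/`let` stem, so family names like `let-7a` are not mangled;
- only a terminal arm token is removed, so interior locus numbering
  survives (`miR-129-2-3p` keeps the `2`, giving `mir1292`, distinct
  from `mir1291`).

Harmonization is idempotent, and ids differing in trailing locus number
never merge.

## Integration, scoring, sensitivity

The layers are inner-joined on base id. When several expression records
share a base id (both mature arms), the record with the smallest adjusted
p is kept — the strongest evidence for the locus; a count of dropped
records is logged. Classification uses only the direction pair; records
reaching it always have nonzero effects because the final selection
imposes a positive minimum effect size.

Scores: `raw = |expr %/yr| · |meth %/yr|` is always reported; the default
ranking score z-standardizes both coefficient columns across the
candidate set (sample sd) before taking the product of absolute values,
which removes the scale asymmetry between layers (expression effects are
~10× larger in %/yr units). Because the z-transform depends on the whole
candidate set, z-scores are not comparable across runs with different
candidate sets, and published z-scores cannot be recomputed from a
candidate table alone. Ranking is by descending score with lexicographic
tie-break — a deterministic permutation of 1..n.

The covariate sensitivity analysis re-fits *both* layers with the
configured covariates (ordinal clinical variables entered as centered
numeric codes; constant covariates dropped with a warning; samples with
missing covariates dropped listwise in the re-fit only), re-selects and
re-integrates, and flags a primary-analysis concordant miRNA robust iff
it is still concordant in the adjusted analysis.

## Validation and network

Cross-cohort validation is strict sign matching: Yes only when both calls
are defined and identical; an exactly-zero coefficient or uncovered
feature is NA, and NA rows are No at the record level but tallied
separately in the summary so disagreement and missingness stay
distinguishable. On the bundled external table, the strict rule yields
9 methylation matches where the table's own flags count 10 — one row is
flagged a match despite opposite signs; the package follows the rule and
reports 9/4/7.

Networks: edges are harmonized and de-duplicated; an optional evidence
filter keeps reporter-assay/Western-blot/qPCR-grade rows. Hub degrees are
computed on the *unfiltered* network; filtering retains genes at or above
the degree threshold (default 5, the stricter of the two published
conventions; ≥3 is a config value), keeps miRNA neighbors of retained
genes with their edges to retained genes, and prunes isolates — making
the filter idempotent.

## Synthetic cohort generator

The generator emulates the discovery-cohort conditions and is the test
bed for every statistical claim the suite makes. Defaults: 449 samples;
ages truncated-normal on [43.5, 78.6] with mean 61.6 and sd 7.3 (sd set
so the central IQR matches the reported ~9.8 years); 300 miRNAs of which
30 concordant and 30 discordant with per-year log2 expression effects
drawn uniformly from ±[0.03, 0.2] and β drift from ±[0.002, 0.005]
(signs opposite for concordant, equal for discordant, both zero for
null); NB counts with lognormal baselines (median ~300), shared
dispersion 0.1, and lognormal size factors (sd 0.2) so normalization
matters; promoters carry 2–6 CpGs and 20% of probes are decoys outside
every window; β noise is Gaussian (sd 0.02) with clipping to [0, 1].
Gleason and T stage come from cumulative-logit ordinal models whose age
coefficient defaults to 0 — the age–covariate association in real
cohorts is not established, so independence is the neutral default and
the coefficient is exposed as a parameter.

What the generator does **not** emulate: read-level sequencing noise,
array probe artifacts (detection failures, cross-reactivity), tumor
purity and copy-number confounding, batch structure, or beta-distributed
(heteroskedastic near the boundaries) methylation noise. Passing recovery
tests therefore demonstrate correctness of the estimation and
bookkeeping under the stated generative model, not robustness to every
artifact of real cohorts.

Determinism: all randomness flows through `numpy` Generators seeded from
a single integer; sub-stage seeds are derived deterministically, and
identical configs/seeds give bit-identical outputs (tested at file
level).

## Problem sizes used in the test suite

Simulation-based checks use cohorts chosen to make their statistical
assertions stable: type-I calibration on 500 null features at n = 200;
CpG slope recovery on ~300 promoter probes at n = 400; end-to-end
recovery at the full default scale (n = 449, 300 miRNAs), where the
planted concordant set is recovered with sensitivity ≥ 0.8 at
false-discovery proportion ≤ 0.2 (in practice both near-perfect, since
the planted effects sit far above the detection threshold at this n).

## Known limitations

- The NB dispersion moment estimator ignores the age trend when computing
  per-feature variance, which is slightly conservative for strong-effect
  features; irrelevant for null calibration and immaterial at the planted
  effect sizes tested.
- Promoter definition by a fixed ±2 kb window misses distal elements and
  host-gene co-regulation of intronic miRNAs.
- Ordinal covariates enter the regressions as linear numeric codes, not
  as factor expansions.
- The concordance classification is sign-only; it does not test
  per-sample mediation of expression by methylation.
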
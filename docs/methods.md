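# Methods

## Model of mutation accumulation

The package assumes the somatic-clock model of blood: substitutions
accumulate in HSPCs as a Poisson process with a fetal phase and a linear
postnatal phase.  Gestation is fixed at 0.75 years; the mutation load at
birth defaults to 84 substitutions (point estimate inside the 52–121
95 % CI used for uncertainty intervals) and the postnatal rate to 16
substitutions/year.  Wildtype lineages of the blood are assumed to be
highly polyclonal: sampled colonies share ancestry only during an early
embryonic burst, parameterized as the number of substitutions
(`embryonic_split_burden`, default 10) accumulated before the last sampled
lineage diverges.  A driver clone is modelled as one lineage whose sampled
colonies coalesce at the driver-acquisition time; the MRCA split of the
clone therefore bounds the latest acquisition.

## Synthetic-data generator

`simulate_phylogeny` draws the time tree (embryonic divergence times
uniform inside the burst window; clone-internal splits uniform between
acquisition and sampling), `simulate_mutations` draws per-branch Poisson
counts with piecewise rates (fetal rate = birth load / 0.75 y) and samples
each mutation's trinucleotide channel from an age-interval signature
mixture, and `simulate_observation` produces the multi-sample VCF: depth
Poisson around 15× inside each colony's callable regions (drawn as 1-Mb
windows to hit a callable fraction uniform in 0.80–0.95) and ~1× outside,
heterozygous alt counts binomial at VAF 0.5, plus germline variants
(150/genome, all colonies), per-colony low-VAF in-vitro artifacts
(Poisson mean 40 at VAF 0.05 — the artifact rate is a free parameter, set
to give the VAF filter real work) and a handful of low-quality records
exercising the MQ/QUAL/GQ filters.  Genome coordinates are uniform over a
22-autosome synthetic length table that sums exactly to the autosomal
callable genome size, so callable fractions and burden corrections are
mutually consistent.  Everything is deterministic given `seed`.

Allelic dropout (a carried heterozygous variant yielding zero alt reads)
is a first-class parameter but defaults to 0: colonies are clonal
expansions sequenced in bulk, where dropout is negligible; the parameter
exists to mimic amplification-based protocols and is exercised at 0.1 in
the phylogeny robustness tests.  What the simulator does *not* emulate:
reference-genome-faithful positions and contexts, mapping artifacts,
copy-number change, indels, and contamination between colonies.  Passing
tests on simulated data therefore validate the statistical machinery and
its calibration, not robustness to alignment-level pathologies of real
sequencing data.

## Signature catalog and age-spectrum model

Published reference signature catalogs are external data, so the package
ships a deterministic *synthetic* catalog with the qualitative shapes of
SBS1 (N[C>T]G deamination), SBS5 (flat clock-like), SBS18 (C>A oxidative
damage) and the blood-specific HSPC profile; any real catalog can be
supplied as a channels × signatures TSV.  The default age-interval mixture
is SBS1/SBS5 = 0.4/0.6 before birth and SBS1/SBS5/SBS18/HSPC =
0.15/0.45/0.10/0.30 after, and the age-spectrum model is the matching
closed form `predicted(age) = birth_load·prenatal + rate·age·postnatal`,
so simulator, refit and age-similarity analyses close one generative loop.

A note on identifiability: because the postnatal term dominates after the
first decade, the *direction* of `predicted(age)` changes very slowly at
older ages; the argmax of the cumulative-spectrum-vs-age cosine curve is
sharp in childhood but plateaus later (at ~700 mutations the curve is flat
to within sampling noise over ±15 y around age 40).  The cosine *at* the
true age remains on the plateau (≥ 0.95), which is the quantity the
acceptance check uses.  Refits of columns with fewer than 50 mutations are
flagged low-confidence.  The strict refit's minimal-contribution threshold
(backward elimination stops when every retained signature contributes at
least this fraction) is exposed as `min_fraction`, default 0.02.

## Filtering and genotype states

Thresholds follow the standard colony pipeline: depth ≥ 5 in sample and
pseudo-bulk, site quality ≥ 100, mapping quality ≥ 55, genotype quality
≥ 99 for heterozygous and ≥ 10 for homozygous calls in both, VAF ≥ 0.15,
and zero pseudo-bulk alt reads ("any evidence" read strictly as ≥ 1 read).
Multi-allelic records are decomposed on read.  Downstream, each variant ×
colony entry is *present* (passed), *missing* (depth < 5) or *absent*
(adequate depth, no call); a confirmed non-carrier additionally requires
zero alt reads.  This three-state distinction is load-bearing: at 15×
coverage with callable fractions ~0.85, a five-colony clade has some
member missing for most of its shared variants, and treating those as
evidence of absence would strip clonal branches.

## Tree building and mutation mapping

The builder is a greedy perfect-phylogeny construction: candidate splits
are the observed carrier sets (≥ 2 carriers), scored by the number of
variants compatible with them under wildcard missing entries, accepted in
score order when nested with or disjoint from the accepted set; equal-score
conflicts are broken lexicographically and flagged.  Split robustness is
the fraction of variant-bootstrap replicates reproducing the split; only
splits at support 1.0 are timing-eligible.  Mapping then assigns every
variant to the deepest branch containing its carriers, tolerating
confirmed absences in up to 10 % of the clade (otherwise the best-fitting
descendant branch: maximal carrier coverage, minimal confirmed
non-carriers, ties to the deeper branch), and re-evaluates terminal-branch
variants with alt reads in ≥ 2 colonies as shared.  An externally built
tree can be imported (Newick + assignment TSV) in place of the internal
builder.

## Time scaling

The five-step conversion adds the fetal estimate to the root branch,
divides terminal branches by the tip's sensitivity p and shared branches
by `1 − Π(1 − p_i)`, cuts every root-to-tip path at the birth load,
scales the prenatal part linearly to 0.75 y, and scales each postnatal
subtree to the stem-cell age with an iteratively reweighted means scheme.
That scheme is specified by its fixed point — tips equidistant while each
internal node keeps the mutation-scale ratio of its branch to the mean of
its child branches — and solved by Gauss–Seidel sweeps
(`t_v = (t_parent + r·mean(t_children)) / (1 + r)`, clamped to stay
monotone), initialized from per-path linear scaling, converged when the
largest node-time change is below `irm_tolerance` (10⁻⁹ by default,
10,000-iteration cap; non-convergence raises).  Degenerate branches are
handled explicitly: zero mean child length concentrates the span on the
parent branch; a path shorter than the birth load is entirely prenatal and
flagged.  Prenatal-only linear scaling is exact because all birth cuts sit
at the same cumulative distance.

Driver timing reports years from birth to the clone's MRCA split (0.1-y
precision in reports), a prenatal flag when the split lies rootward of the
birth cut, and an interval from rerunning the conversion at the birth-load
CI bounds; a higher assumed birth load moves the cut tipward and the
timing earlier, so the interval endpoints map to the CI bounds in fixed
order.  On simulated recipients the estimate has a modest early bias
(clonal-branch variants detected in only a sub-clade are mapped below the
MRCA), well inside the reported uncertainty: across 20 default-noise
replicates with a driver at 3.0 y the truth falls inside the interval in
≥ 90 %.

## Statistical tests

Group comparisons are two-sided Wilcoxon rank-sum tests (exact ranks for
small samples) with a Bonferroni family of all pairs in one call; mutant
colony fractions use the exact two-sided binomial test
(minimum-likelihood summation), with the expected fraction of a
heterozygous clone equal to twice its VAF.  The age baseline is
`burden ~ age` with a per-donor random intercept (statsmodels MixedLM),
reducing to OLS when every donor contributes one observation; the default
birth-load CI (52–121) is used when no healthy cohort is supplied.

## Fetal-overlap estimator

Tip triples (one interest, two pseudo-bulk) are drawn uniformly without
replacement; the shared count is the summed length of the union of edges
above each MRCA(pseudo-bulk tip, interest); the per-tree statistic is the
median over 1,000 iterations (exhaustive enumeration replaces sampling on
small trees), and the final estimate is the mean over trees, rounded
half-up only when added to a root branch.  Whether the original procedure
used ordered or unordered triples is unstated; unordered is used (the
statistic is symmetric in the two pseudo-bulk tips, so this only affects
the iteration count).

## Problem sizes and determinism

Default analyses use ~10 colonies per recipient and a few thousand
variants; validation suites use 60-donor burden cohorts, 20-replicate
timing recoveries and 100–200-replicate topology checks, sized so the full
test suite and the acceptance script each run in well under a minute of
CPU.  All stochastic steps (simulation, bootstraps, NMF restarts, refits)
derive from explicit integer seeds; scaling itself is deterministic.
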
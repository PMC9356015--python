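# Methods

## Overview

`degnet` chains six analysis stages: differential expression per dataset,
ortholog-mapped DEG-set overlap with a Monte-Carlo null, DEG-interacted
network construction and GO functional-module extraction, running-sum
module-activity classification, deletion-region dosage and
developmental-stage filtering, and binomial NDD-gene enrichment. A
synthetic-data generator plants known truth in every input, so each stage's
recovery behaviour is a testable property rather than an anecdote.

## Differential expression (stand-in test)

The differential test is a Welch two-sample t-test on
`log2(CPM + 1)` with total-count library-size scaling. It is deliberately
not DESeq2's negative-binomial model: it keeps the package dependency-light
and self-contained, and any externally produced DEG table (including real
DESeq2 output) is accepted through the same TSV schema (`gene`,
`log2_fold_change`, `p_raw`, `p_adj`). Consequences of the stand-in:

- **Fold change** is `log2(mean case CPM + 1) − log2(mean control CPM + 1)`.
  The pseudocount of 1 on the CPM scale (configurable) avoids division by
  zero and shrinks fold changes of very low-expressed genes toward 0.
- **Normalisation** is total-count scaling, not median-of-ratios; with
  strong asymmetric signal the two differ, which matters for real data but
  not for the planted-truth recovery properties tested here.
- Under a pure null the test is approximately calibrated: at a 10 vs 10
  design the p < 0.05 rate sits within binomial error of 5% and passes a KS
  uniformity check; at the 3 vs 4 primary design it is slightly
  conservative (a property of t-tests at df ≈ 5 on log counts).

Genes with undefined statistics (zero variance in both groups) carry NaN
p-values and are never selected. The low-count filter removes genes with a
total of fewer than 10 reads across all samples (strict "less than");
selection thresholds are strict inequalities (`p < 0.05`), and
Benjamini–Hochberg adjustment is the standard step-up procedure
(delegated to statsmodels, verified against a brute-force reimplementation
of the definition).

## Cross-species overlap null

DEG sets are mapped through a two-column orthology table; sources with more
than one distinct target are ambiguous and dropped. The k-way intersection
is compared against samplings in which each set is replaced by a uniform
random subset of the same size from a fixed universe (default 20,000 genes,
100,000 samplings — both configurable; the universe size is a convention,
not derived from the data). The sampler realises each draw as a chain of
hypergeometric variates — `|A1 ∩ A2| ~ Hypergeom(N, s1, s2)`, each further
set thinning the running intersection the same way — which is exactly the
distribution of materialised subsets at a fraction of the cost; tests
verify the chain against brute-force subset drawing and, for two sets, the
exact hypergeometric tail. The empirical p uses the add-one convention
`(count_ge + 1)/(B + 1)` and never reports 0.

The negative control splits the control samples into two seeded halves,
calls "DEGs" between them at raw p < 0.05, and runs the same overlap test;
with no true signal its p should be unremarkable. Degenerate splits with no
within-half variation return an empty set with a warning.

## Functional modules

The DEG-interacted network is the protein-interaction subgraph induced on
DEGs plus their first neighbors. Annotations are restricted to GO
biological process with experimental evidence ({EXP, IDA, IPI, IMP, IGI,
IEP}; configurable). Per term, module genes are the annotated genes present
in the network and module edges the induced network edges; a module is kept
iff it has ≥ 1 DEG member and ≥ 1 edge. Deliberate readings where the rule
is underspecified: no ancestor propagation of GO annotations (a gene
annotated to a child term does not join parent modules), and "one
interaction" means ≥ 1 edge anywhere — modules need not be connected.
Isolated DEGs survive in the network but can never satisfy the edge rule
alone.

## Module activity

The ranked list is the entire expression-tested gene list ordered by log2
fold change (monotone-equivalent to ranking by fold change), descending for
activity and ascending for inactivity, ties broken by gene id so rankings
are deterministic. The running sum is accumulated from integer member
counts (`S_i = j_i/N_f − (i − j_i)/(N − N_f)`), which makes the endpoint
exactly 0 and a member prefix exactly 1 with no floating-point drift; the
maximum of the running sum is provably attained at a member position, so
the permutation null only needs member positions. Null replicates therefore
draw `N_f` positions uniformly without replacement (distributionally
identical to permuting the whole list; verified against explicit list
permutation), 1,000 per module and direction by default, each (module,
direction) pair on its own named substream of the run seed so results do
not depend on module order. μ and σ use the sample standard deviation
(n − 1); σ = 0 or N_f = N flags the module degenerate, and degenerate
modules are excluded from activated/inactivated outputs.

A module is activated iff activity z > 2 and inactivity z < 0, inactivated
symmetrically; the two conditions are mutually exclusive by sign. Known
limitation: ES is a maximum statistic with a right-skewed null, so the
Gaussian-style z > 2 gate fires on truly null modules somewhat more often
than the nominal ~2% per direction — the classifier is slightly
anti-conservative by construction, which the null-calibration test
quantifies. Whether the 1,000 null lists are shared across modules or drawn
per module is an open design point; this implementation draws per module
(a flagged alternative would share them).

## Dosage and developmental stages

Dosage check: per tissue, region genes with TPM strictly above 1.5 are
"expressed"; genes absent from the table are reported, never silently
dropped. Adult-silent DEG selection keeps DEGs with adult-brain-cortex
TPM strictly below 1.5 and tallies DEGs without data (mirroring the
retrievability gap of real expression atlases). The stage-profile test is
Tukey's HSD with genes as observations and stages as groups — a documented
simplification that ignores the repeated-measures structure across stages;
scipy's studentized-range implementation is cross-checked against
statsmodels. Prenatal-maximum selection requires prenatal RPKM strictly
above 1.5 and a strict maximum over the other stages; ties are logged and
excluded. TPM (adult tissue) and RPKM (stages) are kept in their native
units with no conversion.

NDD enrichment is the one-sided exact binomial tail with baseline
`p0 = |NDD|/|universe|`; the universe is the set of genes tested for
differential expression after the low-count filter (the paper-style choice
of universe is undefined, so this decision is recorded in the run summary
and configurable by passing a different universe).

## Synthetic data

The generator emulates the study design the pipeline targets: a 20,000-gene
universe; a primary "human-like" cohort of 3 cases vs 4 controls and a
secondary "mouse-like" cohort of 10 vs 10 linked by a constructed 1:1
orthology; negative-binomial counts with per-gene log-normal means
(log-mean 5, log-sd 1 → median ≈ 150 counts) and shared dispersion 0.05;
5% of genes planted with |log2 FC| = 2, half shared between species; eight
deletion-region genes at exactly 0.5× case dosage; an Erdős–Rényi
background PPI (50,000 edges) with planted, internally connected GO
modules whose genes are planted DEGs; GO annotations with experimental
codes for planted terms and a configurable non-experimental fraction for
background terms; and stage/tissue tables with planted prenatal-maximum
genes silenced in adult cortex. The planted effect size is deliberately
strong so that every planted structure is recoverable under the
small-cohort design — the point of the simulation is structural recovery,
not calibration to any particular published gene counts.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: batch and covariate structure, sex effects,
library-preparation biases, correlated genes, scale-free PPI topology,
many-to-many orthology, GO-hierarchy dependence between terms, and
measurement noise in TPM/RPKM resources. Two constructions are intentional
idealisations: non-planted genes never peak in the prenatal stage (their
maximum is swapped into a postnatal stage), making the developmental filter
chain's truth recovery exact; and planted module genes are all planted
DEGs, making module-membership recovery exact. The eight-gene
deletion-region tissue table shipped as `deletion_region_example()` uses
invented illustrative TPM values (four genes above 1.5 TPM in cortex, two
of those also high in blood).

All randomness flows from a single seed through named substreams
(`SeedSequence` spawn keys per artefact/stage/module), so identical
configurations are byte-identical and any stage can be re-run standalone
with the draws it would have made inside a full run.

## Problem sizes

Unit and property tests run at 600–5,000 genes with 100–1,000 permutations
and up to 100,000 overlap samplings; replicate-based properties use 20
seeded replicates (100 where a finer rate estimate is needed). The
full-scale reproduction script uses the default 20,000-gene configuration
with 100,000 samplings and 1,000 permutations and completes in seconds.
These sizes are the package's chosen desk-scale study conditions; all of
them are configurable.
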
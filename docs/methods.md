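# Methods

## The screen

The pipeline identifies candidate multiciliation genes by requiring two
independent lines of evidence per gene and then characterizing the
survivors.

**Expression evidence.** Each differential-expression table (one per
experiment contrasting a multiciliated with a non-multiciliated
condition) is thresholded at logFC ≥ 1 and p ≤ 0.05; both bounds are
inclusive, since the screen's published description states the
thresholds as "at least". Duplicate gene rows within one table keep the
smallest p-value, the standard dedup for platform probes mapping to one
gene. Identifiers from mouse or frog experiments are mapped to human
symbols with union semantics: a source gene with several human
co-orthologs marks *all* of them, a conservative choice for presence
calls (drops are counted in the log). The per-experiment sets are
assembled into a binary gene × experiment matrix; only genes
overexpressed somewhere are rows. Gene profiles are clustered (below)
and genes overexpressed in a single experiment — individually or as
whole clusters — are removed, leaving genes supported by at least two
experiments. Each cluster is summarized by its *signature*: the set of
experiments in which at least `signature_threshold` (default 0.5) of its
members respond; clusters with identical signatures form groups, which
is how "multiciliated clusters" (groups responding across most
regulator perturbations) are recognized.

**Conservation evidence.** For every gene of a reference proteome the
clade table records ortholog presence and percent identities in a focal
clade and a reference clade. A gene with no focal ortholog but presence
in at least `min_ref_presence_frac` (default 0.5) of the reference clade
is ABSENT; requiring reference support avoids calling universally
missing genes "lost in the focal clade". Otherwise the divergence score

    D = (mean(ref identities) − mean(focal identities)) / sd(ref identities)

(sd with ddof = 1; undefined when fewer than two reference identities,
zero spread, or no focal identities → NOT_EVALUABLE) is thresholded:
HIGH_DIVERGENCE at D ≥ z_hi (default 3), MILD_DIVERGENCE at
z_lo ≤ D < z_hi (default z_lo = 1.5), CONSERVED below. This statistic is
a deliberately simple surrogate for dedicated differential-conservation
tools: the published screen's confidence tiers come from a tool whose
internals are out of scope here, so the categories are reproduced by a
transparent z-score with configurable thresholds, and the synthetic
generator plants margins wide enough that category recovery does not
depend on the default values.

**Integration and prioritization.** Candidates are genes in the retained
expression set whose conservation category is flagged (ABSENT, HIGH or
MILD). A configurable list of known multiciliation genes (default:
CCNO, GEMC1, CEP63, CEP152, E2F4, E2F5, CCDC78, CDC20B — E2F5 standing
in for the occasionally mistyped "E3F5" symbol) is appended with a
`known` flag. A gene is *promising* when (i) it is essentially
unannotated (`annotation_count ≤ max_annotations`, default 0,
operationalizing "no GO annotations" / dark-target status), (ii) its
conservation category is flagged, and (iii) its phylogenetic profile is
ciliary-like. Criterion (iii) is tested on pattern labels
(ABSENT_NONCILIATED, ABSENT_FOCAL_CLADE, CHORDATE_RESTRICTED,
METAZOA_RESTRICTED) rather than on profile-cluster numbers, because
cluster numbering is data-dependent; an explicit cluster-id whitelist is
available for curated inputs. Genes in multiciliated signature groups
rank first; ordering is deterministic on (rank, gene).

## Clustering machinery

**Ward.D2.** Agglomeration applies the Lance–Williams update to squared
dissimilarities and reports heights on the distance scale (the
convention in which two points at distance d merge at height d). Ties
between equal-criterion merges are broken lexicographically on the
(smallest member, largest-of-smallest members) pair so results are fully
deterministic; equality is detected at 1e-9 relative tolerance. The test
suite verifies the merge sequence against an independent closed-form
oracle (the centroid identity evaluated on the raw distance matrix) on
200 random instances and cross-checks heights against SciPy's Ward
implementation on tie-free instances.

**Dynamic hybrid cut.** The dendrogram is cut at 99% of the top merge
height; each resulting branch is split recursively at merges where at
least one child is *cluster-like*: at least `min_cluster_size` members
(default 20, the reference default of the method family — the published
screen states only depth 2 and the hybrid mode), separated from the
parent merge by a normalized gap ≥ minGap, and internally tighter than a
normalized core scatter ≤ maxCoreScatter. `deep_split` 0..4 maps to
maxCoreScatter (0.64, 0.73, 0.82, 0.91, 0.95) with
minGap = (1 − maxCoreScatter)·3/4; normalization is relative to the cut
height minus the 5th percentile of merge heights. Splitting on *either*
cluster-like child matters: a composite sibling (several modules not yet
separated) has high core scatter and must be descended, not frozen.
Terminal branches of at least `min_cluster_size` members become cluster
cores; every remaining item is assigned to the nearest cluster medoid.
Assignment is unconditional, so UNASSIGNED (0) occurs only when no
branch qualifies at all — for example when every merge sits at the same
height and nothing falls below the cut.

**Distances.** Expression profiles use the Jaccard distance
1 − |a∧b|/|a∨b| (pairwise matrices via SciPy's `pdist`); phylogenetic
profiles use the correlation distance 1 − Pearson(a, b) in [0, 2].
Constant profiles (all-present or all-absent rows) have undefined
correlation and are placed at the sentinel distance 2 from every
partner, keeping the pipeline total instead of propagating NaN.

**Communities.** Network partitioning uses greedy modularity
maximization (networkx) as a deterministic surrogate for layout-plugin
community clustering; acceptance is planted-block recovery, not
algorithm identity.

## Network expansion

Scores are accepted in [0, 1] or as 0–1000 integers (auto-detected,
overridable). List–list edges are kept at score ≥ `t_internal` (0.7);
an external gene is admitted with ≥ `min_list_partners` (2) distinct
list partners at score ≥ `t_external` (0.9); external–external edges
need both endpoints admitted and score ≥ `t_external`. All thresholds
are inclusive, the conventional reading of "a threshold of 0.7". List
genes whose edges are all filtered out remain as isolated nodes; list
genes absent from the edge table entirely are skipped with a warning —
this is how a 122-gene list can yield a network containing only 57 of
them, with the other 65 lacking any recorded interaction.

## Enrichment

The over-representation p-value is the upper hypergeometric tail
P(X ≥ k) for k study hits among n study genes, K annotated of N
population genes (SciPy `hypergeom.sf`), validated in the tests against
exhaustive draw enumeration for all populations up to N = 12.
Benjamini–Hochberg is the default correction (Bonferroni selectable);
the population defaults to the annotation map's gene universe and can
be narrowed to the screened universe. No GO-DAG propagation is
performed; term structure is flat input.

## Synthetic data

One integer seed drives one named pseudo-random stream per generator
(seed-sequence spawn keyed on the generator name), so adding a generator
never perturbs the others, and identical configurations reproduce
byte-identical tables.

* **DE tables**: module genes receive logFC ~ U(1.2, 4) and
  p ~ U(1e-8, 0.01) in active experiments (with the configured
  activation probability) and logFC ~ U(−2, 0.9) elsewhere; background
  genes fire in at most one experiment. Default activation probability
  0.9 and background rate 0.05 are the study conditions of the
  parameter-recovery checks.
* **Clade tables**: reference identities ~ N(90, 2) clipped to
  [60, 100]; planted HIGH genes sit at D = z_hi + 2·(z_hi − z_lo)
  (a margin of twice the threshold gap), planted MILD at the midpoint
  (z_hi + z_lo)/2 (the widest margin the band permits, half a gap per
  side), CONSERVED at D ~ N(0, 0.2). Margins make category recovery
  deterministic rather than probabilistic, so count-based checks are
  exact.
* **Profiles**: the species panel nests supergroup → phylum-level clade
  → subclade with band fractions (protists 15%, fungi 12%, plants 12%,
  nematodes 6%, other invertebrates 20%, tunicates 3%, non-focal
  vertebrates 24%, focal clade 8%) chosen once as a plausible eukaryote
  panel; patterns are exact presence masks with independent flip noise
  (default 5%).
* **Networks**: stochastic block model, intra-block score U(0.85, 0.99),
  cross-block U(0.40, 0.70); defaults intra 0.9 / inter 0.02 are the
  recovery-check conditions.

The fixed-seed fixture plants a 21,044-gene proteome with exactly
634/104/623 flagged genes, of which 41/10/63 are also placed in
multi-experiment expression modules (the eight known genes are planted
as single-experiment so they join the list only via the explicit
append, as in the modeled screen); a network edge list covering 57 of
the 122 list genes plus 862 externals in ten blocks (919 nodes); 984
gene profiles over 711 species; and a curated evidence block for the
eleven named candidates carrying their published cluster and category
values. The fixture uses activation probability 1 and zero profile
noise: it is a worked example for exact counts, not a realism test.

What the generators do *not* emulate: correlated noise across
experiments, ortholog-detection error structure, identity distributions
of real proteomes, weighted STRING evidence channels, or GO-term
dependence. Passing the planted-recovery suites therefore demonstrates
algorithmic correctness under the stated conditions, not performance on
real GEO/STRING/OrthoInspector data, whose headline sizes (4151 DE
genes, 28 clusters, 919-node STRING graph, …) depend on those databases.

## Problem sizes and numerical choices

Recovery checks run at 160–220 genes × 10 experiments (expression),
200 genes × 200 species (profiles) and 45-node networks; the fixture
pipeline clusters 532 expression rows and classifies the full
21,044-gene proteome — sizes chosen so the whole suite completes in
well under a minute while keeping every planted structure non-trivial.
Ward is quadratic per merge (cubic overall), fine at these scales.
Heights are compared at 1e-8 absolute in tests; p-value identities at
1e-12. Degenerate inputs are defined, not fatal: all-zero binary rows
are rejected at matrix construction (they cannot arise from the filter),
constant profiles get the sentinel distance, undefined divergence scores
become NOT_EVALUABLE.

## Known limitations

* The divergence z-score ignores sub-protein (domain-level) divergence;
  a gene conserved overall but diverged in one domain can be missed.
* The hybrid cut is a faithful-in-spirit reimplementation, not a port;
  on borderline branch shapes it may split differently from the R
  reference implementation. Acceptance is planted-structure recovery.
* Signature grouping by exact signature-set equality is a declared
  approximation of the published cluster regrouping, which was not
  formally delimited.
* The mapping between the surrogate divergence tiers and the modeled
  tool's "highly/mildly likely" tiers is unknowable from category
  counts alone; thresholds are configurable and margins planted.
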
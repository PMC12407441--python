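# Methods

## Model and assumptions

`pullnet` treats metabolite-centric interpretation as a network problem:
discriminant metabolites are proxies for perturbed processes, and the
proteins they associate with (binding partners, enzymes, transporters —
the *seed proteins*) localize those processes on a genome-scale PPI graph.
Two well-known artifacts of interactome data drive the pipeline's design:
a high false-positive rate among low-confidence edges (addressed by the
confidence filter) and promiscuous, over-studied hub proteins that appear
in every neighborhood regardless of biology (addressed by hub pruning).
A module is assumed to be *locally dense*: the first-order neighborhood of
a seed, re-induced on the filtered interactome, is the operational unit;
second-order expansion and diffusion scoring are deliberately out of scope.

## Pipeline stages and tunables

| Parameter | Default | Meaning |
|---|---|---|
| `max_missing` | 0.30 | metabolite missingness above which the feature is removed (strictly greater) |
| `prevalence_min` | 0.10 | ASV prevalence threshold, combined with a zero median by logical AND |
| `pseudocount` | 1 | added to counts before the CLR log |
| `outlier_components`, `outlier_quantile` | 2, 0.99 | PCA score space and χ² quantile of the Mahalanobis rule |
| `min_confidence` | 0.1 | interactome edge filter |
| `degree_percentile`, `inside_fraction_min` | 0.99, 0.10 | a non-seed node is pruned when its global degree exceeds the percentile AND < 10% of its interactions fall inside the module |
| `max_nodes`, `exemption_q` | 200, 1e-4 | size cap; modules whose pre-cap seed-enrichment q ≤ 1e-4 are kept whole |
| `overlap_min`, `overlap_metric` | 0.75, containment | merge threshold; containment = intersection over the smaller node set |
| `q_max`, `min_metabolites` | 0.05, 3 | classification thresholds for core / exploratory sets |
| `top_k`, `p_max`, `es_min` | 20, 0.01, 1.5 | annotation summary: rank cut, then dual thresholds |

Choices worth explaining:

* **Volume adjustment** is division of raw plasma intensities by the
  per-sample collection volume *before* median scaling, following the
  vendor-normalization convention; feces tables pass through.
* **ASV filter**: "counts less than 10%" is ambiguous; it is read as
  *prevalence* below 10% of samples, conjoined with a zero median. Both
  the threshold and the conjunction are configurable.
* **Outlier rule** is applied once, not iteratively (an `iterative` flag
  exists); it runs per omics block and flagged samples are unioned.
* **Overlap metric**: containment rather than Jaccard, so that a small
  network engulfed by a larger one merges — the goal is low inter-network
  overlap. Jaccard is selectable. Merging is highest-overlap-first with a
  lexicographic id tie-break, giving a deterministic fixpoint at which no
  non-whitelisted pair exceeds the threshold. The whitelist mechanism
  preserves network pairs that should stay separate because they originate
  from distinct experimental groups.
* **Cap survivors** are ranked by maximum edge confidence to any seed,
  ties broken by ascending protein id — a deterministic, seed-centric
  criterion for which neighbors matter most.
* **Background universe** for the Fisher tests defaults to the node set of
  the confidence-filtered interactome (the sampling frame of the
  pulldown); union-of-networks is available. The BH family defaults to one
  gene-set class across all networks; a global family is available.
* **Matching tiers** in seed mapping (primary id → structural key →
  case-insensitive name/synonym) order identifier kinds from most to least
  specific; functional and physical associations are treated identically
  after the text-mining exclusion.
* q-values are floored at 1e-300; a displayed "0.000" is rounding, never
  an exact zero. Geometric means floor their inputs identically before the
  log. Annotations missing from a network's results count as p = 1 in the
  cross-network geometric mean (a skip option exists); the aggregate uses
  corrected values by default with a raw-p flag.

## The synthetic study

The generator emulates, at feature-table level, a four-group design
(wild-type/transgenic × control/high-fat diet, default group sizes
6/3/6/6) with plasma-like and feces-like metabolite blocks,
Dirichlet-multinomial ASV counts over 120 taxa, and an interactome of 500
proteins with 5 planted stochastic-block-model modules (sizes 15–25,
within-module edge probability 0.4) over a preferential-attachment
background scaled to density 0.01, plus 5 designated hubs wired to ≥ 10×
the median degree. Edge confidences are Beta(1.5, 1.5), putting ~6% of
edges below the 0.1 filter. Discriminant metabolites (20 of 40) link
90% of their 3–8 association-table entries into their assigned module;
decoy metabolites link uniformly at random, a fifth of them with
text-mining-only evidence. Missingness is left censoring of the lowest
intensities at ~30% overall, with 15% of metabolites pushed above the 30%
filter threshold. Group effects shift alternating discriminant metabolites
by 2 log2-units along the diet or genotype axis.

What the generator does **not** emulate: mass spectra, reads or taxonomy
inference; batch structure; correlated metabolite families; realistic
interactome degree-confidence coupling (confidence is independent of
topology). Passing tests therefore demonstrate algorithmic correctness and
calibration on a known generative model, not performance on real
interactomes, whose hub structure and confidence landscape are richer.

## Recovery benchmark: an honest bound

The benchmark scores, per planted module, the best node-Jaccard achieved
by any final network, and compares seed-enrichment q between
planted-derived and decoy networks. The q separation is strong (median
~0.08 vs ~0.59 at seed 1). Jaccard recovery, however, is structurally
bounded: a first-order neighborhood of a seed inside a module of size
|M| with within-module edge probability p captures on average p(|M|−1)+1
module members, so even without background contamination the Jaccard
against the full module cannot exceed ≈ p; maximizing over the many seeds
per module raises the observed best to ≈ 0.52 on the default benchmark.
Containment between two same-module seed networks concentrates near p as
well, far below the 0.75 merge threshold, so merging does not pool
same-module networks at p = 0.4. Full-module recovery at high Jaccard
would require denser planted modules (p ≳ 0.65), a lower merge threshold,
or second-order expansion; the defaults are kept as the study conditions
and the benchmark reports the honest numbers.

## Numerical and degenerate-input behavior

* Medians and minima are computed over observed entries only; missing
  markers (NaN) survive scaling untouched and are distinct from zeros.
* A metabolite with no observed values cannot be scaled or imputed and
  raises an error (impossible after the missingness filter).
* `log_transform` identifies the offending cell on non-positive input.
* PCA score covariance is checked for rank before inversion; a singular
  covariance raises with a suggestion to reduce components.
* Seeds absent from the filtered interactome yield empty modules with a
  warning (they are counted in the run log), never an error.
* The pulldown contains no randomness: identical inputs give
  byte-identical XGMML, reports and manifests.

## Known limitations

* The association table is a frozen snapshot supplied by the user; no
  live database queries, chemical-structure normalization or tautomer
  handling (structural keys are opaque strings).
* Enrichment is overlap-based ORA only; no rank-based (GSEA-style)
  statistics.
* The published network collection itself is not redistributed; the
  packaged reference file transcribes only the 20-row exploratory-network
  summary table (id, size, linked metabolites, seed q) used for
  representation counting.
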
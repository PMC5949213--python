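# Methods

This note documents the model implemented by `phenorank`, the design
decisions behind it, what the synthetic data generator does and does not
emulate, and the numerical choices that affect results.

## Model

### Ontology and information content

Phenotype terms form a rooted `is_a` DAG (multiple roots are allowed; only
`is_a` edges are interpreted, other OBO relationship types are ignored with
a warning). Annotation follows the true path rule: a source annotated with
a term is implicitly annotated with every ancestor, so all term sets are
expanded to their *reflexive* ancestor closures before use. Reflexivity
makes simGIC(W, W) = 1 hold exactly.

Information content is computed from the combined corpus of human diseases
and mouse mutants: IC(t) = −ln(n(t)/N), with n(t) the number of sources
whose closure-expanded term set contains t and N the corpus size. Natural
logarithm is used; the base cancels in simGIC's ratio, so this is purely a
documentation choice. Terms with n(t) = 0 have no defined IC and contribute
zero weight to similarity sums — excluding them avoids −ln 0 without
smoothing the corpus. Term depth is the longest `is_a` path to a root
(root depth 0).

### simGIC

Similarity of two term sets is the IC-weighted Jaccard coefficient over
their closures. Degenerate 0/0 cases (both closures empty, or overlapping
only in zero-IC terms) are defined as similarity 0: annotation-free sources
must never appear phenotypically similar. The scoring engine evaluates
simGIC against all sources at once via sparse closure-incidence matrices;
unit tests pin its output to the reference per-pair implementation at
1e-12, and both are checked against an independent brute-force oracle.

### Gene scores and propagation

Q_i is the sum of two block means — over the gene's associated diseases and
over the mutants of its orthologous mouse genes — so 0 ≤ Q_i ≤ 2 and a gene
is not rewarded merely for having *many* sources. Genes absent from the PPI
network are not scored; network genes without sources score 0. The
`species_mode` switch zeroes one block for ablation studies. One-to-many
orthology attaches a mutant to every human ortholog of its mouse gene.

Scores are propagated by random walk with restart over the column-normalized
adjacency. Q^0 is normalized to sum 1 when positive (the iteration is
linear, so ranks are unaffected; magnitudes stay comparable across runs).
Columns of isolated genes are left all-zero, so walker mass at such nodes
decays to the restart term. Exactly `n_iter` iterations are run with no
convergence test: a *fixed* iteration count is what makes score vectors
comparable between the query run and the simulated runs. Defaults r = 0.1
and n_iter = 20; at these settings the mean absolute score change per
iteration is far below 1e-5 by iteration 20 on the bundled fixtures.

`convergence_profile` reports mean |Q^t − Q^30| for t = 1..29 as a
diagnostic. This profile decays geometrically but is not exactly monotone:
the column-normalized adjacency can have negative eigenvalues whose
alternating powers produce oscillations on the order of 0.1% of the
profile's starting value near convergence. Tests therefore assert
non-increase up to 1% of the initial profile value rather than strict
monotonicity.

### Simulated null and p-values

A simulated term set of size |W_q| is drawn by sampling a seed term
uniformly from the terms mapped to at least one disease, ranking all terms
by the number of diseases whose *raw* (non-closure-expanded) mapping
contains both the candidate and the seed (ties ordered uniformly at random;
the seed participates with its own disease frequency), and keeping the top
|W_q|. Seeds with fewer than |W_q| positively co-mapped terms are rejected
and redrawn, up to `max_seed_attempts` (default 1000), after which an error
reports the largest admissible size. Co-mapping is counted over diseases
only, and raw rather than inferred annotations are used — simulated sets
should mimic the curated mapping tables, not ontological inference. Each of
the u sets draws from its own RNG stream derived from (seed, set index), so
results are independent of evaluation order and trivially parallelizable.

Each simulated set is pushed through the *identical* score → propagate →
rank pipeline with all other data unchanged. The p-value of a gene is
max(b/u, 1/u), where b counts simulated runs in which the gene's rank is
strictly smaller (better) than its query-run rank. Rank ties between runs
do not count against the gene. The floor keeps p-values away from zero; u
bounds the resolution. One degenerate case is special-cased: a query whose
score vector is all zero (no source has any phenotypic overlap with it)
produces a prominent warning and p = 1 for every gene — with no evidence,
nothing is implicated and the null runs are skipped.

At desk scale (hundreds of genes) the strict-rank comparison is measurably
anti-conservative for genes whose rank is pinned across runs (e.g.
unannotated hubs): their rare rank fluctuations land mostly on one side.
The effect is small — null rejection at α = 0.05 averages ≈ 0.06 on the
default fixture — and shrinks with network size; the calibration test
quantifies it.

## Evaluation harness

Leave-one-out cross-validation masks one disease–gene association, reruns
the method with that disease as query, and records the masked gene's
standing among *eligible* genes (all scored genes minus other genes
associated with the same disease; the masked gene is always eligible).
Per-trial scores are pooled into one ROC/AUC via scikit-learn's
Mann-Whitney-equivalent estimator (ties count 1/2); p-value-based scores
are flipped to −log10 p so "higher = more implicated" holds for every
variant. Stratified CV sorts trials by a per-gene data-availability key
(network degree or number of phenotype sources) and splits them into
near-equal quantile strata. The restart-probability grid search requires
its tuning trials to be disjoint from the evaluation trials by
construction.

Bias features per gene: (i) network degree; (ii) number of phenotype
sources |Y| + |Z|; (iii) median term-set size over sources; (iv) median
absolute difference between |W_q| and source term-set sizes; (v) median
over sources of the maximum term depth. Correlations are Spearman's rho,
pairwise-complete over genes with defined values; constant vectors yield
NaN with a warning.

The null-calibration check pools p-values from 10 queries drawn from the
simulator itself (u = 1000 each). Genes within one run are dependent — a
null query that happens to resemble an annotation cluster lifts that whole
cluster — so the rejection fraction of a single run is noisy; averaging
over queries estimates the type-1 rate while the acceptance band stays the
exact binomial 99% interval for one run's gene count, and the KS distance
of the pooled ECDF (against the discrete null CDF of max(b,1)/u with
b ~ U{0..u}) is compared to the α = 0.01 critical value at the per-run
sample size.

## Synthetic data generator

The generator emulates, at small scale, the data ecology the method was
designed for:

* **Ontology** — a single-rooted random DAG; each term draws 1–2 parents
  among earlier terms (acyclic by construction).
* **Corpus** — diseases and mutants draw term sets (default 3–10 terms)
  from shared depth-biased term clusters, giving the co-annotation
  structure the null simulator needs and making "phenotypically similar"
  sources exist at all.
* **Study bias** — a latent per-gene study intensity (log-normal, σ = 1)
  couples, with strength `bias_strength` ∈ [0, 1], to (a) the number of
  edges a gene brings when it joins the network, (b) its propensity to be
  chosen as an interaction partner, and (c) its chance of acquiring disease
  and mutant associations. At bias 1 this yields rho(degree, intensity)
  ≈ 0.7–0.8; at bias 0 the network is a uniform random recursive graph and
  the correlation vanishes. This single-latent-variable mechanism is the
  minimal generative model of the hypothesis that better-studied genes
  accumulate more recorded data of every kind.
* **Planted modules** — connected gene sets whose members each receive one
  ground-truth disease, one support disease and one mouse mutant annotated
  from a module-common term pool. The support disease and the mutant carry
  signal that survives masking of the ground-truth association, so both
  species are genuinely informative in cross-validation and the
  species-ablation comparison is meaningful.

Defaults (300 terms, 150 diseases, 80 mutants, 200 genes, 2 modules of 5)
keep a full prioritization run with u = 1000 under a second and the whole
test suite under half a minute; these sizes are the package's chosen study
conditions, stated wherever results are reported.

What the generator does **not** emulate: the scale of the real corpora
(~16k genes, ~200k interactions, ~8k terms), realistic interactome
topology (clustering, paralog-induced structural twins), annotation
curation noise, many-to-many orthology beyond the synthetic 1:1 mapping,
and literature-driven term co-occurrence. Passing tests therefore
demonstrate the method's internal correctness and its qualitative bias
behaviour, not expected performance on real curated databases.

## Numerical and API choices

* Ranks use average ties (`scipy.stats.rankdata` on negated scores).
* Result files print floats at 6 significant digits, sort by ascending
  p-value, then rank, then gene id, and are byte-deterministic given
  identical inputs and seed.
* OBO parsing is delegated to `obonet`, post-processed to the package's
  contracts: dangling `is_a` targets and cycles are errors (the cycle error
  names a member), obsolete terms are retained but stripped of parents and
  excluded from closures.
* TSV readers treat identifiers as opaque strings, skip `#`-prefixed lines,
  and report the line number of malformed rows.
* All generators and runs take explicit integer seeds; there is no hidden
  global RNG state.

## Known limitations

* Empirical p-values have resolution 1/u; within-locus multiple-testing
  correction is out of scope and p-values are emitted uncorrected.
* The strict-rank comparison's mild anti-conservatism at small network
  sizes (see above).
* Edge weights, directed interactions and confidence scores are not
  modelled; the walk treats all interactions equally.
* Disease/gene identifiers are opaque; no symbol normalization or
  cross-vocabulary mapping is performed.
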
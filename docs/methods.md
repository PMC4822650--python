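# Methods

## The procedure and its assumptions

`phenowalk` assumes that disease-relevant expression changes concentrate in
connected regions of the interactome, and that genes annotated (directly or
through ontologically similar phenotypes) to the clinical features of the
disease mark where those regions lie. Both evidence sources enter one
Markov chain: a random walker on the joint PPI + phenome network visits a
protein often when it is well connected to differentially expressed genes,
to seed-phenotype-associated genes, or to phenotypes similar to the seeds.
The method consumes a *finished* differential-expression analysis (log2
fold changes and multiple-testing-adjusted p-values); normalisation, DE
testing and identifier mapping are upstream of it, and identifiers are
matched as exact upper-cased strings.

The pipeline is deterministic given its inputs except for the empirical
p-value sampling, which takes an explicit seed. Node order is fixed (genes
then phenotype terms, each lexicographic) so repeated runs are reproducible
to the bit.

## Phenome construction

Only `is_a` edges of the ontology are traversed; `part_of` and
cross-ontology logical definitions are ignored, since information content
and Resnik similarity need only the term DAG. Obsolete terms are skipped
and cycles are a hard error.

Information content uses the natural logarithm, IC(t) = −ln(n_t/N), with
annotations propagated to ancestors before counting (the true-path rule)
and N the number of genes annotated anywhere in the ontology. The base is a
convention; the edge threshold (default 3.0, i.e. the subsumer covers less
than e⁻³ ≈ 5% of annotated genes) is interpreted on the same natural-log
scale and is exposed as a parameter so users can recalibrate for
differently sized annotation corpora. Terms covering no annotated gene have
no IC and cannot form edges; term pairs in different roots of a multi-root
ontology get similarity 0. Thresholding uses ≥ on full double precision.

The all-pairs similarity computation prunes terms whose own IC is below the
threshold (valid because annotation-derived IC never increases towards the
root); tests verify the result against an unpruned brute-force pass.

## Transition matrix and restart vector

Choices where the construction was genuinely open:

* λ is the probability of moving phenome → PPI at an associated phenotype,
  1 − λ of moving PPI → phenome at an associated gene. Genes without
  associations, and phenotypes without phenome edges or without
  associations, renormalise all their mass within the blocks they do have;
  nodes with neither layer connection are dropped at assembly rather than
  left as dangling rows.
* PPI edge confidences weight the within-layer moves by default; a flag
  (`use_confidence_weights=False`) treats the PPI as unweighted for edge
  lists that carry no meaningful scores.
* The walk iterates p ← (1 − α) Mᵀ p + α p0 from p0, stopping when the L1
  change is below 1e-6 (a parameter; the norm is a convention). Row sums of
  M are asserted to 1 ± 1e-12 at construction and the steady-state mass to
  1 ± 1e-9, so conservation failures surface as errors, not silent drift.
* Grid defaults: α and η span 0.2–0.8 and λ 0.5–0.8 in 0.1 steps (7 × 7 × 4
  = 196 combinations). The grid avoids the degenerate extremes (α → 0
  never restarts; η → 0/1 switches one evidence source off) and keeps
  λ ≥ 0.5 so the walker moves freely between layers.

## Sub-network extraction

Seeds of the expansion are proteins ranked strictly better than all their
neighbours. Expansion repeatedly adds the best-ranked boundary protein and
transitively absorbs boundary proteins ranked better than it, so each state
is the full connected component of the seed among proteins at least that
well ranked; the state is scored by P(all n of a random draw from N rank
≤ r_max) = C(r_max, n)/C(N, n). All states up to `max_size` are enumerated
and the minimal-p state returned (when absorption would overshoot the cap,
the best-ranked absorbable proteins fill the remaining places). Enumerating
to the cap rather than stopping at the first non-improving step makes the
greedy result provably equal to exhaustive minimal-p connected-subgraph
search, which the tests verify by brute force on small graphs. `max_size`
defaults to 15 (20 is a reasonable alternative for broader modules); the
cap bounds both runtime and how diffuse an initial sub-network can be.

Consensus takes the proteins present in the union of extracted sub-networks
of *every* parameter run ("complete co-occurrence"), avoiding any matching
of sub-networks across runs, and keeps connected components of at least 5
proteins (`min_consensus_size`). Components may include well-connected
neighbours of a true module when those co-occur in every run; on synthetic
cases this occasionally adds 2–3 background proteins around the planted
module.

The null model for the empirical p-value draws connected sub-networks of
the observed size by snowball sampling: a uniformly random start, then
repeated uniform draws from the *distinct* current boundary, restarting if
the component is exhausted. Snowball sampling over-represents high-degree
regions relative to the uniform distribution over all connected subgraphs
(no practical exact-uniform sampler exists); the same sampler is used for
every draw, so comparisons are internally consistent, and the sampler is
pluggable. With r the number of samples whose summed π meets or exceeds
the observed value, p = (r + 1)/n (clamped to 1); with the default
n = 10000, a sub-network beating every sample gets p = 1.0e-4. On null
inputs this estimator is super-uniform (conservative), which the test suite
checks at several quantiles. Benjamini–Hochberg FDR control (default 5%)
runs across the consensus sub-networks' p-values via statsmodels, and is
checked in the tests against an independent implementation of the BH rule.

Other conventions: π = |log2FC|·(−log10 p_adj) with p_adj floored at 1e-300
so values printed as 0 stay finite; duplicate DE rows keep the largest π;
expression thresholds (microarray intensity > 5 in more than half the
samples, RNA-seq FPKM > 2) are strict, and the confidence filter keeps
edges at exactly 0.7 because only scores strictly below 0.7 count as low
confidence. Exact probability ties in a ranking are broken
lexicographically by gene identifier.

## The synthetic generator

`phenowalk.simulate` emulates the *structure* of the real inputs at desk
scale — defaults: 200 genes, 53 ontology terms, an 8-gene planted module —
so the full pipeline runs in seconds and every stage is testable without
downloads. The ontology has one tight disease branch (leaves annotated only
to module genes, so within-branch Resnik exceeds 3 while cross-branch pairs
meet only at the root) and five background branches that soak up the
remaining genes; the interactome is a connected Watts–Strogatz background
with the module wired as a clique and confidences uniform in [0.7, 1); the
module carries log2FC = 2 at p_adj = 1e-4 (π = 8) against centred Gaussian
fold changes and uniform p-values. Setting `planted_module_size = 0` gives
the null case used for calibration checks.

What the generator does **not** emulate: the degree distribution and size
of real interactomes (hundreds of genes, not ~10⁴), the depth and multiple
inheritance of real phenotype ontologies, correlated noise between genes,
annotation bias toward well-studied genes, or identifier-mapping noise.
Passing tests therefore demonstrate algorithmic correctness and calibration
under the planted model, not performance on any real disease dataset.

## Problem sizes and limitations

The test suite and the acceptance script use the default 200-gene fixture
(full 196-run sweep, 10000-sample empirical p-values) plus random two-layer
networks of ≤ 50 nodes for solver oracles and graphs of ≤ 10 nodes for
exhaustive expansion checks; the whole suite runs in well under a minute.

Known limitations: Resnik similarity ignores term depth beyond annotation
frequency; the all-pairs phenome computation is quadratic in IC-bearing
terms (fine for 10³–10⁴ terms, slow beyond); snowball sampling's degree
bias makes empirical p-values conservative for hub-rich sub-networks; the
complete-co-occurrence rule is strict — one discordant parameter run
removes a protein — so consensus shrinks as the grid grows; and results
inherit whatever ascertainment bias the PPI and annotation sources carry.
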
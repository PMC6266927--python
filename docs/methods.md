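# Methods

## Model and assumptions

`pandict` treats each genome as a bag of amino-acid gene sequences and
defines homology operationally: two genes are candidate homologs when their
k-mer multiplicity dictionaries overlap enough to, in principle, reconstruct
each sequence from the shared words, and they are accepted as
ortholog/paralog candidates through reciprocal-best-hit relations scored by
the generalized Jaccard similarity. The method assumes

- annotation is given (no gene calling); inputs are translated CDS;
- homologous genes retain substantial k-mer composition similarity — very
  distant homologs detectable only through profile or structure methods are
  out of reach by construction;
- genomes are prokaryote-scale: the word length formula
  k = log₂₀(Σ ⟨𝔾ⁱ⟩) lands at k = 4–6 for collections totalling 10⁵–10⁷
  residues, where 20-letter dictionaries are informative.

## Pipeline and thresholds

1. **k selection** — k = round(log₂₀ Σ ⟨𝔾ⁱ⟩), half-up, minimum 1. Rounding
   half-up treats the real-valued optimum symmetrically; with |Γ| = 20 a
   difference of one unit in k changes dictionary specificity twenty-fold,
   so the rounding rule matters less than it would on nucleotides.
2. **Index sweep** — one enhanced suffix array over all genes concatenated
   with separators; every LCP interval of depth ≥ k is one k-mer, the SID
   slice of the interval gives per-gene multiplicities, and per-pair sums
   (Σ min, and each side's Σ over shared k-mers) are accumulated sparsely.
   Pairs sharing no k-mer never materialize.
3. **Candidate filter** — both directional coverages ≥ 2/k, compared by
   integer cross-multiplication (no floating point at the threshold).
4. **BBH** — best-hit sets keep *all* tied maximizers; similarity maxima and
   ties are resolved on exact integer fractions a / (|s|+|t|−2k+2−a), so
   platform-dependent float ties cannot change the output. Self-comparisons
   of each genome feed the paralog step.
5. **Paralog threshold** — per genome: τᵢ = the minimum similarity among all
   inter-genome BBH edges incident to genome i; intra-genome BBHs with score
   ≥ τᵢ (inclusive) are paralog candidates. The per-genome (rather than
   per-genome-pair) aggregation is stable under input ordering; a genome
   with no inter-genome BBH infers no paralogs. Intra-genome BBHs below τᵢ
   are discarded outright.
6. **Refinement** — components holding two same-genome genes without a
   direct paralog edge are split by Girvan–Newman: weights are normalized by
   the component maximum, edge distance is 1/normalized-weight (strong
   similarity = short path), one highest-betweenness edge is removed per
   iteration, parts are re-normalized and re-checked recursively. Among
   equal-betweenness edges (tolerance 1e-12) the lexicographically smallest
   (min endpoint, max endpoint) pair is removed — a pure determinism device.
   The distance mapping 1/w is a design choice: betweenness on a similarity
   network needs a weight-to-distance convention, and the reciprocal makes
   weak edges long, which is what bridge detection wants.

Genes shorter than k cannot carry one full k-mer; they are excluded from the
index and reported as forced singletons with a warning. Non-standard
residues (B, Z, U, J, O and anything unexpected) are masked to 'X', and any
k-mer covering an 'X' is discarded by the same next-invalid-distance
mechanism that stops k-mers from crossing gene boundaries.

## Data structure notes

The suffix array is built by vectorized prefix doubling (O(n log² n), numpy
lexsort) — construction is contractual only through SA/LCP semantics, and at
the few-megabyte scale of bacterial gene sets this is a few seconds. The LCP
array is Kasai's algorithm (numba). The separator encodes as the smallest
symbol, so an invalid suffix never sits lexicographically *between* two
valid suffixes sharing a k-prefix — LCP-interval grouping (runs with
LCP ≥ k) followed by NDIST ≥ k filtering is therefore exact. The per-pair
accumulators are hash maps keyed by gene pair (numba typed dicts), not dense
matrices: memory scales with realized k-mer sharing.

## The simulator

The generator emulates a bacterial population evolving from a single
ancestor along an n-ary tree. Per generation and per gene: loss with
probability 0.001, variation of a transmitted gene with probability 0.8
(editing round(p·len) residues, p = 0.005 or 0.01, each edit a uniform
substitution/insertion/deletion), duplication with probability 0.0001; new
genes are gained at rate 0.01 per parent gene with lengths drawn from the
ancestor's sampler, so gained genes show the same length variability as the
rest. Event counts are per-gene Bernoulli draws (binomial in aggregate)
rather than deterministically rounded fractions, so rare events still occur
in small genomes at the right expected rate. Every gene instance carries its
ancestral family id; duplicates join their parent's family, gains found new
ones — the truth partition of any extracted sub-population is exact.

Defaults and deliberate choices:

- ancestor genes: i.i.d. residues, lengths log-normal (median ≈ 330,
  σ_log = 0.45) clipped to 100–1500 residues — a realistic bacterial
  protein-length spread;
- branching: uniform 1–4 offspring per node, breadth-first until the target
  population size; this yields shallow trees whose leaf layer dominates;
- "roots" are the `count` nodes of minimal tree depth (BFS tie-break),
  "leaves" the childless nodes taken deepest-first; a composition-distance
  based notion of "closest to the ancestor" is not the default;
- varied genes never shrink below 13 residues (the shortest genes observed
  in real annotation sets); the floor is a simulator parameter;
- gained genes are always novel sequences — cross-lineage horizontal copy
  of existing genes is not modelled.

What the simulator does **not** reproduce: nucleotide-level mutation
processes (edits are uniform over residues, no substitution matrix),
recombination and genomic rearrangement, selection, and real codon/residue
composition (ancestor residues are uniform). Consequently a perfect score on
synthetic benchmarks shows the pipeline recovers tracked descent under
composition-preserving point edits; it does not certify performance on real
annotation noise, domain shuffling or convergent composition.

Benchmark problem sizes in the tests and the acceptance script are
scaled-down study conditions chosen for a desk run: 500-gene ancestors,
populations of 200 (10% of the full-scale 2000), 10-genome extractions
(20% of 50). The shallower trees mean leaf extractions are less diverged
than full-scale ones (mean composition distances of roughly 0.08–0.17
instead of 0.55–0.68), so scaled-down f-measures sit at or near 1.0; the
f-measure floors asserted in the tests (0.95 roots, 0.90 leaves) account
for the stochastic headroom, not for tuning.

## Scoring

Predicted and golden families are compared as partitions through their
within-family gene pairs: TP/FP/FN counted on the pair sets, TN from the
closed form C(G,2) − TP − FP − FN over the full universe *including*
intra-genome pairs. The f-measure is F1 = 2TP/(2TP+FP+FN). CDiff counts
golden families spread over ≥ 2 predictions (splits) plus predictions
spanning ≥ 2 golden families (merges), each offender once; a stricter
variant (golden families not recovered exactly) is available behind a flag.
The phylogenetic distance is 1 − cosine between whole-proteome k-mer count
vectors — the plain composition-vector form without Markov background
subtraction, which reproduces the [0, 1] range but not necessarily absolute
values of background-corrected variants.

## Known limitations

- The betweenness recomputation inside Girvan–Newman is O(VE) per removed
  edge; pathological near-clique inconsistent components of thousands of
  genes would be slow. Real inconsistent components are small.
- The 2/k filter is a lower bound on relatedness, not a significance test;
  at k ≤ 2 it degenerates (threshold ≥ 1), which the word-length formula
  avoids for any realistic input.
- Similarities are exact rationals internally, but exported edge weights are
  floats.
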
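# Methods

`deepsage` analyses digital gene-expression data produced by SuperSAGE: 26 bp
transcript tags anchored at the 3'-most NlaIII site (`CATG`) of each mRNA,
sequenced as tail-to-tail ditags, counted per library, and compared between
conditions with an exact test for count data.  This note records the models,
parameter choices and numerical conventions the package commits to, and what
its synthetic-data validation does and does not demonstrate.

## Ditag geometry and tag extraction

A ditag read carries one tag in sense orientation at its 5' end and the
reverse complement of a second tag at its 3' end.  Because `CATG` is its own
reverse complement, a well-formed read starts *and* ends with `CATG`.  The
extractor accepts reads of 50-54 bp (EcoP15I cut-length variation around
2 x 26), takes tag 1 as bases 1-26, and tag 2 as the reverse complement of
the last 26 bases.  Reads failing an anchor lose only the affected tag (the
other is kept); reads outside the length window or containing non-IUPAC
characters are rejected wholesale, and IUPAC ambiguity codes inside a tag
reject that tag.  Tags are never padded or trimmed to fit, and they are
strand-specific: no canonicalization by reverse complement is performed,
since SAGE tags derive from the transcript's sense strand.  UniTag ids
(`STCa-1`, `STCa-2`, ...) are assigned in first-seen order and persist
through all outputs.

Rejection reasons (`no_start_anchor`, `no_end_anchor`, `bad_length`,
`ambiguous_base`) are tallied in an extraction report whose counters always
balance: reads seen = reads accepted + reads rejected.

## Tag-level filters

* **Singletons.** A UniTag whose summed count across all libraries of one
  organ equals 1 is excluded from that organ (its counts there are zeroed);
  tags left with no counts anywhere are dropped.  The rule operates per
  organ because unique-tag totals are reported organ-wise; a tag observed
  once in each of two libraries of the same organ (sum 2) is retained.
* **Low complexity.** A tag is discarded when, over the 22 variable
  positions (the anchor carries no information), a single base occupies at
  least 80% of positions, or a 1-2 nt motif tandem-repeats across at least
  18 consecutive positions.  Both thresholds are configurable; each removal
  is reported with the rule that triggered it.  The rule is deliberately
  conservative: genuine tags with moderately biased composition (e.g. long
  but broken A/T stretches) survive it.

## Normalization and abundance classes

Counts are normalized to copies x 100,000^-1: `count * 100000 /
total_tags`.  Column sums are exactly 100,000 up to floating-point
rounding; two-decimal rounding happens only at serialization.  Detected
tags (nonzero raw count) are binned into the classes `[0,10)`, `[10,100]`,
`(100,500]`, `(500,inf)` — closed boundaries chosen so the printed class
labels "<10", "10 to 100", ">500" form a complete partition.

## Differential expression

For a tag with counts (x, y) in libraries of sizes (N1, N2):

* **Fold change** = ((y + c)/N2) / ((x + c)/N1), with pseudocount c = 1
  added to *both* counts only when one of them is zero.  This keeps folds
  finite for presence/absence tags without biasing well-sampled ones;
  c is configurable.
* **R(ln)** = ln(fold change).  The natural logarithm is forced by the
  threshold correspondence 2.7-fold <=> R(ln) = 1.0.  Up-regulation is
  positive (higher in treatment).
* **Significance** follows the exact conditional test for digital profiles:
  given x, the null law of y is p(y|x) = r^y (x+y)! / (x! y! (1+r)^(x+y+1))
  with r = N2/N1, which is the negative binomial NB(x+1, N1/(N1+N2)).
  Tails are evaluated through `scipy.stats.nbinom` (regularized incomplete
  beta), stable for counts well beyond 10^5.  The two-sided p-value doubles
  the smaller of the inclusive lower tail P(Y<=y) and the strict upper tail
  P(Y>y), capped at 1.  This convention was chosen because the exact
  identity P(X<=x | y; N2, N1) = P(Y>y | x; N1, N2) makes it symmetric
  under exchanging the two libraries — doubling two inclusive tails is not.
  The test suite verifies agreement with an exact-rational enumeration to
  |Delta p| < 1e-9 over x, y in [0, 50] at size ratios 1/2, 1 and 2.

Raw p-values are reported; a Benjamini-Hochberg column is available behind
a flag.  Summary counts are emitted at |R(ln)| >= 1.0 (the e-fold cut) and
at the linear 3-, 8- and 20-fold thresholds (>= comparison on the fold
value), and regulated tag sets at those thresholds feed 2- and 3-set Venn
decompositions.

## SAAT families

Tags differing by one or a few substitutions are treated as transcript
isoforms / allelic variants (SNP-associated alternative tags).  Because
tags are fixed-length and anchor-aligned, similarity is ungapped positional
identity; "homology over more than 22 bp" becomes >= 23 identical positions
out of 26.  Families are single-linkage connected components of this
relation; gapped (indel) isoforms are outside the built-in metric's reach,
but externally computed alignments can be injected as BLAST-tabular links
(accepted when alignment length x identity% reaches 23 matched bases).

The family representative is the member with the highest summed normalized
copies, ties broken by lexicographically smallest sequence; SNP positions
are called against the representative and always lie in positions 5-26.
The partition is independent of input order.  Pair construction uses
pigeonhole blocking (4 position blocks; any pair within 3 mismatches shares
an exact block), keeping the all-vs-all step practical at 10^4-10^5 tags.

## EST-bridged annotation

A 26-mer is too short for meaningful protein-level alignment statistics, so
annotation is transferred through ESTs: the tag is located on an EST
(anchored scan, both strands, at most 1 substitution and never inside the
anchor; matches kept at >= 25/26 identical bases as the retention gate),
and the EST is annotated against tier tables in taxonomic priority order —
chickpea/Fabaceae, then Arabidopsis, then rice/maize.  The first tier whose
entry passes (not anonymous, not weak-similarity, e-value <= 1e-50) wins;
priority beats e-value magnitude.  ESTs passing no tier are reported as
anonymous candidate novel transcripts.  Pre-computed aligner hits can be
imported instead of the built-in scan, gated on their printed e-values
(< 1e-5).  Offsets are 0-based on the EST forward strand; minus-strand
matches report the forward-strand interval.

Per-EST multiplicity (how many distinct UniTags target an EST) is
histogrammed into the classes 1, 2, 3, 4, 5, >5, and a per-EST table of
targeting-tag count vs summed copies supports correlation analyses.

## GSR enrichment

Gene Score Resampling scores each category by the mean of its member
genes' scores without imposing a hit/no-hit cutoff.  The gene score is
|R(ln)| by default (both regulation directions count; signed and mean-mode
variants are configurable), with the best-scoring tag standing in for an
accession observed through several tags.  The null for a category of
analyzed size k is B = 10,000 means of k accessions drawn without
replacement from the scored universe; p = (1 + #{null >= observed}) /
(B + 1), so p is never zero and identical seeds give identical results.
Null draws are shared across categories of equal k, making results
independent of category order.  Category size bounds default to [5, 100].
Custom categories (e.g. hand-curated pathway member lists) are registered
under collision-checked labels and analyzed identically to GO terms.
GO-slim summaries of the top-N most up-regulated tags (default N = 40)
rank by fold change with ties at the cutoff broken by UniTag id.

## Synthetic data

The generator emulates the study structure: two organs at library depths
86,919 and 57,281 split across control/NaCl, a 40,000-transcript pool,
SAAT family-size classes covering 15% / 4% / 2% of tags (families of 2, 3
and 4; the remainder singletons), spiked differential expression on 10% of
transcripts with R(ln) drawn uniformly from +/-[1.0, 4.3], and one spiked
enriched category among 40 random ones.  The spiked category's members are
the accessions of the most abundant spiked tags: the category is defined
by a score shift, and tying it to observable transcripts guarantees the
shift is actually expressed at the simulated depths rather than hidden in
tags too rare to be sampled.

* **Abundance model.** Transcript abundances are Zipf rank weights
  (weight of rank i proportional to i^-s, default s = 1.0, ranks shuffled
  per organ).  A log-normal was evaluated first but cannot reproduce the
  target class fractions at any spread — the detected-tag fraction below
  10 copies x 100,000^-1 saturates near 74-85% — whereas the rank power
  law, the classical description of SAGE tag abundance, lands at ~91% /
  8% / <0.2% for the <10 / 10-100 / >500 classes at the default depths.
  These fractions are depth-dependent by construction (a "copy per
  100,000" is an absolute rate), so class-fidelity checks run at the
  default depths.
* **Uniqueness guarantees.** Generated tags are unique, anchored,
  non-low-complexity, contain no internal `CATG` (so the planted anchor is
  the 3'-most usable one in the EST), and unrelated tags are kept below
  the 23/26 similarity threshold.  The generated family partition is
  therefore exactly the single-linkage truth, and family recovery F1 is
  a pure measure of the clustering implementation.
* **Reads.** Per library, 2*ceil(depth/2) tag observations are drawn
  multinomially, shuffled, and paired uniformly at random into 52 bp
  ditags (the real protocol's pairing carries no counting information).
  The emitted count table is the exactly realized multiset, which makes
  extract -> count an exact round-trip oracle.  No sequencing-error model
  is applied by default; a per-base substitution rate is available for
  robustness experiments.
* **Truth effects.** Spiked effects are stored as *realized* log-ratios
  (after renormalizing the treatment abundance vector), so recovery is
  measured against the abundance shift actually simulated.
* **Probes.** The microarray mismatch-probe designer yields three variants
  per tag — substitutions at position 7; at 7 and 13; and at 7, 13 and 20
  (1-based), each substitution the complement of the original base — used
  as hybridization background controls.

### What the synthetic validation shows — and what it does not

Passing recovery tests demonstrates that extraction, counting, the exact
test, clustering and resampling are implemented correctly under the study's
library geometry and a realistic abundance law.  The generator does not
model 454 homopolymer errors, basecalling quality, concatemer artefacts,
reverse-transcription biases, or biological replicate variance; real-data
performance on those axes is not claimed.  Indel isoforms are not generated
(the built-in similarity metric cannot link them), and the annotation scene
pairs each tag with exactly one EST, so real many-tags-per-EST multiplicity
distributions are only exercised through SAAT families.

## Problem sizes used in validation

The bundled checks use the full study-scale configuration for class
fractions, round trips and family recovery (40,000 transcripts, depths
86,919 / 57,281), a 2,000-transcript pool at 400,000 tags per library for
effect-size recovery (so that a few dozen spiked tags are well-sampled,
with expected counts >= 50), ten 1,200-transcript replicates at 80,000 tags
per library for enrichment detection power (B = 2,000 resamples), and a
5,000-tag multinomial null at depth 100,000 for type-I calibration.  These
sizes give stable pass/fail margins while keeping a full validation run in
the minutes range.

## Known limitations

* Exact per-library UniTag totals of the original study are not
  reproducible: the proprietary tag sorter's orientation and error rules
  are unspecified, and the deposited data are not required.
* The e-value retention gate of the original EST search is approximated by
  the >= 25/26 matched-bases rule in built-in matching mode; imported hits
  use their printed e-values directly.
* The test is per-tag-pair exact but no continuous-dispersion model
  (negative-binomial GLM etc.) is offered; biological replication is out
  of scope by design.
* GO categories are taken as given; no DAG propagation or true-path
  inference is performed.
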
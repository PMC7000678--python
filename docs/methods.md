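# Methods

## Scope and data model

The pipeline consumes aligned nucleotide sequences (FASTA) plus a
tab-separated group map assigning each sequence a clade label and a
habitat class (`neustonic` or `planktonic`). Residues are normalized at
read time (upper-case, U→T), and downstream stages assume the alphabet
{A, C, G, T, N, -} plus IUPAC ambiguity codes. Two site-exclusion
conventions are used deliberately in different places:

* **complete deletion** for haplotype collapsing and the Hd/K/Kt
  statistics: only columns where *every* analyzed sequence has an
  unambiguous A/C/G/T are retained, recomputed per analyzed subset, so a
  clade's statistics do not depend on sequences outside the subset;
* **pairwise deletion** for p-distances: each pair is compared over the
  sites where both members are unambiguous, the standard convention for
  genetic-distance reporting.

Both are available as a switch on `mean_pairwise_differences`. The two
conventions can disagree in the later decimals on gappy data; complete
deletion is the default for the diversity statistics.

## Diversity statistics

Haplotype diversity uses the unbiased estimator
`Hd = n/(n−1)(1 − Σ pᵢ²)`. The n/(n−1) correction matters: it is the
form under which a sample of n fully distinct haplotypes scores exactly
1.0 for every n ≥ 2, which the uncorrected form cannot reach. `K` is the
raw mean count of pairwise differences (no multiple-hit correction), and
`Kt` is the same statistic over the pooled union of two disjoint clade
subsets, with complete deletion recomputed on the union. Nucleotide
diversity per site is emitted only as the convenience ratio
`K / analyzed sites`.

## Base-composition heterogeneity test

For each sequence, its A/C/G/T counts are tested against expectations
derived from the pooled composition of the whole alignment
(`X² = Σ (o−e)²/e`, df = 3, flag at p < 0.05, no multiple-testing
correction for the screening use; a Bonferroni column is emitted
alongside). Because the pooled frequencies are estimated from the same
alignment, the realized false-positive rate on homogeneous data is below
the nominal 5 % for small alignments and approaches it as the number of
sequences grows (≈3 % at 10 sequences, ≈4.7 % at 100). The calibration
checks therefore use alignments of 100 sequences, the scale of the real
datasets this screen is applied to (hundreds of sequences per group).

## UVR-salient trinucleotide counting

UV photolesions form at TT dinucleotides at rates modulated by the 3'
neighbour: TTA/TTT promote lesion formation, TTC/TTG inhibit it. Counts
are taken per sequence with full overlap (the sequence `TTTT` contains
two `TTT` words) on the plus strand and on the reverse complement, and
the strands are summed; this strand-sum makes the statistic invariant to
which strand was deposited. Sequences are dealigned (all gaps removed)
before counting, matching the convention of counting on the underlying
amplicon; gap removal can in principle create junction words absent from
the biological sequence, which is accepted, documented behavior. Windows
containing N or any other ambiguity code never match, so ambiguity can
only deflate counts. Group summaries are five-number box-plot statistics
with linear interpolation between order statistics (the "type 7"
quartile rule of numpy and R); counts are reported raw, with per-kilobase
columns alongside for unequal-length inputs.

## Median-joining networks

Haplotypes are collapsed over the analyzed sites; the network over the
haplotype vectors is built from the epsilon-relaxed minimum spanning
network (MSN): an edge (u, v) is kept iff `d(u,v) ≤ σ(u,v) + ε`, where
σ(u,v) is the smallest distance class at which u and v join one
component when edges are admitted in increasing distance order. With
ε = 0 this is the union of all minimum spanning trees; ε defaults to 0
and is exposed as a flag. Median (Steiner) candidates are per-site
majority consensi of node triplets; at a site where all three states
differ there is no majority and the candidate inherits the state of the
lexicographically first triplet member — a documented divergence risk
versus other implementations for multistate data.

Construction runs along one of two paths:

* **Exact (≤ 10 observed haplotypes, median closure ≤ 512 vectors)**:
  the full median closure of the observed haplotypes is generated and an
  exact Steiner-tree dynamic program (Dreyfus–Wagner over the closure
  with Hamming distances) selects the median nodes minimizing total
  spanning length. For binary characters the median closure provably
  contains every most-parsimonious tree, so the resulting total length
  is the Steiner optimum; this was chosen after greedy
  one-median-at-a-time schemes (several variants, including plateau
  search and add/remove local search) were measured to land 1–7 % of
  random binary instances above the optimum.
* **Greedy (larger tables)**: iterate — build the MSN, form candidate
  medians from every linked pair plus each third node, add the single
  candidate giving the largest strict reduction in minimum-spanning-tree
  length (ties broken lexicographically), purge unobserved nodes of MSN
  degree < 3 — until no candidate shortens the network. Total length is
  strictly decreasing, so the loop terminates; a node-count ceiling
  (10 × observed) guards against pathological growth and raises an
  error carrying the partial network.

Either way the final network is the MSN over the surviving node set;
observed nodes carry their haplotype frequencies, median nodes carry
frequency 0. "Total network length" always means the weight of a
minimum spanning tree over the final node set — the MSN itself may hold
parallel minimal connections. Internally vectors are projected onto the
segregating sites (constant sites cannot affect distances or medians)
and processed as uint8 arrays; the public surface speaks full-length
residue strings. Determinism everywhere comes from lexicographic
ordering at every tie.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes:
several divergent clades of closely related AT-rich haplotypes. Default
conditions: sequence length 1100 (the scale of a 12S–16S mitochondrial
rRNA amplicon), base frequencies A 0.35, C 0.15, G 0.20, T 0.30
(AT-rich, arthropod-mitochondria-like), three clades of 20 sequences,
within-clade Poisson mean λ = 5 substitutions per tip, between-clade
divergence Poisson mean 40.

Genealogies within clades are stars, not full coalescents: each tip
receives an independent Poisson(λ) number of substitutions from the
clade ancestor at distinct sites, so the tip's Hamming distance to the
ancestor equals its draw exactly and the expected within-clade mean
pairwise difference is 2λ minus a small cross-lineage collision
correction (≈ 2λ²/L). This choice keeps the expectation analytic and
produces the star-like network shapes typical of recently expanded
clades. The ground-truth record (ancestors and per-tip mutation lists)
lets tests recompute K independently of the sequences.

The habitat contrast is imposed post hoc rather than through a biased
substitution model: neustonic sequences are scanned on the plus strand
and each TTA/TTT occurrence is independently destroyed with probability
(1 − factor) by rewriting one of its bases to C or G (weighted by the
C/G base frequencies). The mutated position is chosen to spare
designated-surviving overlapping words where possible, so the surviving
count tracks `factor × pre-count` to binomial accuracy; substitutions
never introduce a T, so no new promoter words can appear, and the
minus-strand deficit follows automatically from the complementary
words. Consequences worth knowing: suppression *adds* substitutions, so
suppressed (neustonic) clades show inflated within-clade K relative to
λ; and the rewritten bases land in TTC/TTG-class words, so inhibitor
counts rise slightly in the suppressed group — qualitatively mirroring
the overlapping-to-slightly-greater inhibitor counts seen in real
neustonic data.

What the generator does not emulate: recombination, indels, rate
heterogeneity among sites or lineages, selection beyond the suppression
knob, and realistic geographic sampling structure. Passing tests on
simulated data therefore validate the *computations*, not the biological
inference on real alignments.

## Numerical and procedural choices

* Deterministic outputs everywhere for a fixed seed; the pipeline
  manifest records SHA-256 checksums per output and wall-clock per
  stage, and stages fail independently (a failure aborts dependents but
  not siblings).
* Reports are written with ≥ 6 significant digits (the diversity values
  of interest are conventionally printed to 5 decimals).
* Degenerate inputs: an all-gap sequence survives dealignment as a
  length-0 sequence (warned) and contributes zero counts; a subset whose
  complete deletion removes every column raises a dedicated error; a
  sequence pair with zero comparable sites gets a NaN p-distance with a
  warning.
* Calibration/validation problem sizes: composition false-positive rate
  on 10 × 100-sequence homogeneous alignments (1000 tests); K recovery
  over 200 replicate clades of 50 tips at λ = 5; network optimality on
  random binary instances of ≤ 6 haplotypes × ≤ 8 segregating sites
  against an exact hypercube Steiner oracle; habitat contrast direction
  over 100 seeded simulations at suppression factor 0.5.

## Known limitations

* The greedy network path is a heuristic; on large, highly divergent
  haplotype sets its median placement can differ from other
  median-joining implementations (the multistate tie rule above is the
  main divergence point). Observed-node topology is far more stable than
  median placement.
* `Kt` recomputes complete deletion on the pooled subset; inheriting
  each clade's site set instead would change late decimals on gappy
  real data.
* The composition screen's nominal 5 % rate is only asymptotic in the
  number of sequences, as noted above.
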
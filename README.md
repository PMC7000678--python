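# neuston-phylogeo

Analysis pipeline for clade-structured mitochondrial rRNA haplotype data
from neustonic (surface-film dwelling) and planktonic daphniids. The
package implements the computational stages used in global phylogeography
studies of such samples:

* **Haplotype diversity statistics** per clade: haplotype diversity
  `Hd = n/(n-1) · (1 − Σ pᵢ²)` (unbiased form), the mean number of
  pairwise nucleotide differences `K = Σ_{i<j} dᵢⱼ / C(n,2)`, and its
  pooled two-clade variant `Kt`, all under a complete-deletion site
  convention (only columns where every analyzed sequence carries an
  unambiguous A/C/G/T).
* **p-distance matrices** under pairwise deletion
  (`p = differences / compared sites`).
* **Base-composition heterogeneity screening**: per-sequence chi-square
  test of A/C/G/T counts against the pooled composition (df = 3,
  flagged at p < 0.05).
* **UVR photolesion motif scoring**: both-strand overlapping counts of
  the trinucleotides that promote (TTA, TTT) or inhibit (TTC, TTG)
  UV-induced lesion formation at TT dinucleotides, with habitat-group
  box-plot summaries. Overlaps count fully: `TTTT` contains two `TTT`
  words.
* **Median-joining haplotype networks**: minimum spanning networks over
  collapsed haplotypes augmented with median (consensus) Steiner nodes;
  exact Steiner-optimal construction for small haplotype tables, greedy
  augmentation for large ones. Exported as GraphML/GML/TSV.
* **A synthetic-data generator** producing AT-rich, clade-structured
  star-genealogy samples with a tunable habitat-linked deficit of
  TTA/TTT words, plus a ground-truth record for parameter-recovery
  testing.

## Worked example

Simulate three clades (20 sequences each, star genealogies with a Poisson
mean of 5 substitutions per tip) in which neustonic sequences retain only
60 % of their TTA/TTT words, then run the analysis stages:

```sh
$ cat sim.json
{"n_clades": 3, "seqs_per_clade": 20, "seq_length": 1100,
 "within_clade_lambda": 5.0, "between_clade_divergence": 40.0,
 "tt_suppression": 0.6}

$ neuston-phylogeo simulate --config sim.json --seed 42 --out-prefix demo
$ neuston-phylogeo diversity --fasta demo.fasta --groups demo.groups.tsv \
      --pooled --out div.tsv
$ cat div.tsv
clade	n	h	Hd	K	pi	analyzed_sites
A	20	20	1	52.3526	0.0475933	1100
B	20	20	1	12.0737	0.0109761	1100
C	20	20	1	52.9263	0.0481148	1100
A+B				77.1192		
```

Every tip is a distinct haplotype, so `Hd = 1` exactly (the unbiased
estimator reaches 1 for an all-distinct sample). Clade B (planktonic, no
suppression) shows `K ≈ 12`, close to the star-genealogy expectation
`2λ + collisions`; the neustonic clades A and C are inflated because word
suppression introduces extra substitutions. The pooled row is `Kt` for
clades A + B.

```sh
$ neuston-phylogeo motifs --fasta demo.fasta --groups demo.groups.tsv \
      --out counts.tsv --summary summary.tsv
$ cat summary.tsv
habitat	motif_class	n	min	q1	median	q3	max
neustonic	promoter	40	115	127.75	132	136.5	147
neustonic	inhibitor	40	87	95	99	103.25	114
planktonic	promoter	20	165	167.75	169	169.25	171
planktonic	inhibitor	20	79	84	85	86	87
```

The neustonic promoter (TTA/TTT) median sits far below the planktonic
one, while inhibitor (TTC/TTG) counts are slightly *higher* in the
suppressed group — the suppressed words are rewritten into TTC/TTG-class
words.

```sh
$ neuston-phylogeo network --fasta demo.fasta --groups demo.groups.tsv \
      --clade B --out cladeB.graphml
B: 20 observed + 3 median nodes, total length 119
```

The full pipeline (`neuston-phylogeo run --config cfg.json`) chains the
stages and writes a manifest with per-stage timings and SHA-256 checksums
of every output.

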
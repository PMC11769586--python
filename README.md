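# dosagescan

Read-depth dosage scoring for detecting and precisely locating
**homoeologous recombination (HR)** between the subgenomes of an
allopolyploid — the *Brassica* A/C genome system being the motivating case
— from ordinary short-read sequencing coverage.

## The problem

Allopolyploids such as *Brassica napus* (AACC) carry two related
subgenomes whose chromosomes can pair and exchange segments at meiosis.
In an introgression programme — diploid *B. rapa* (AA) × *B. napus*
(AACC), then backcrossing the triploid F1 (AAC) to the diploid — breeders
need to know, for every backcross individual, which C chromosomes or
C-chromosome segments it carries and exactly where any A/C exchange
happened.  FISH/GISH and SNP arrays resolve this only coarsely;
`dosagescan` reads it directly out of alignment coverage depth at down to
~1 kb resolution, and works on heterozygous material at modest (~6×)
sequencing depth.

## The statistic

For a sliding window with mean filtered coverage depth *D* and a
normalization constant *M*,

```
dosage score = (D / M) × 2
```

where *M* is the median of *D* over windows of chromosomes assumed
disomic — the A subgenome in backcross material (applied genome-wide), or
each subgenome's own median in an allotetraploid cultivar.  The score
estimates regional copy number: **2** disomic, **1** monosomic
(an introgressed C segment), **0** absent, **4** tetrasomic (the
duplicated side of a nonreciprocal exchange).

Three filters precede windowing, because raw depth is biased in repeats,
in regions without a one-to-one homoeologous counterpart, and where reads
from one subgenome cross-map onto the other:

1. **repeat filter** — annotated repeats are excluded;
2. **multi-/non-homoeologous filter** — positions covered by zero synteny
   blocks, or by blocks pointing to two or more distinct partner loci, are
   excluded (minimum block length 5 kb);
3. **ancestral diploid filter** — a base is kept only if covered
   (depth > 0) in *all* resequenced accessions of its own ancestral
   diploid and uncovered (depth = 0) in *all* accessions of the other.

Windows losing more than 95 % of their span to the mask are dropped.  HR
events are called where the score shifts by more than 0.5, paired across
the two subgenomes through a synteny map, classified as *unique* (one
backcross individual; arose at F1 meiosis) or *common*/*native* (shared;
fixed in the allotetraploid parent, reciprocal 2/2 or nonreciprocal 0/4),
and refined to ~1 kb by a per-base two-fold depth-contrast scan.  A
companion module gives the exact gamete-class probabilities for univalent
(C transmitted with probability ½) and trivalent (AA:AC:A:C = 1:2:2:1)
segregation of the extra C chromosome.

## Worked example

Simulate a small backcross experiment (two 2 Mb homoeolog pairs, 30×
disomic depth, three BC1F1 individuals, one reciprocal exchange planted at
F1 meiosis in the first individual at A01:1.20 Mb × C1:1.25 Mb), then run
the whole pipeline:

```
dosagescan --seed 13 simulate --out-dir sim \
    --n-pairs 2 --chrom-len 2000000 --lam 30 --n-bc1 3 \
    --window 100000 --step 25000 \
    --event 0:1200000:1250000:reciprocal:F1:0
dosagescan run sim/manifest.json --out-dir out
```

`out/BC1F1_01.segments.tsv` shows the carrier's dosage structure:

```
chrom	start	end	state	mean_score	n_windows
A01	0	1175000	2	1.9840	47
A01	1175000	2000000	1	1.0085	33
A02	0	2000000	2	2.0004	80
C1	0	1225000	0	0.0140	49
C1	1225000	2000000	1	0.9920	31
C2	0	2000000	0	0.0000	80
```

A01 drops from disomic (score ~2) to monosomic (~1) at ~1.175 Mb while
its homoeolog C1 rises from absent (~0) to monosomic (~1) at ~1.225 Mb —
the paired signature of a reciprocal A/C exchange, within one window step
of the planted breakpoints.  `out/events.tsv` reports the paired event:

```
a_chrom	a_start	a_end	c_chrom	c_start	c_end	type	provenance	individuals	a_delta	c_delta
A01	1150000	1200000	C1	1200000	1250000	unknown	unique	BC1F1_01	-1	1
```

It is `unique` to BC1F1_01, i.e. inferred to have arisen at F1 meiosis
(native events would be shared across individuals and typed against the
allotetraploid parent's profile).  The segregation model prints exact
probabilities:

```
$ dosagescan meiosis --model trivalent
{ "A":  {"p": 0.333…, "exact": "1/3"},
  "AA": {"p": 0.166…, "exact": "1/6"},
  "AC": {"p": 0.333…, "exact": "1/3"},
  "C":  {"p": 0.166…, "exact": "1/6"} }
```

## Scope

`dosagescan` consumes alignments (BAM/SAM) or per-base depth tables,
repeat annotations (RepeatMasker `.out`/BED), pairwise subgenome
alignments (PAF) and ancestral-panel depth tracks.  It does not run the
aligner, repeat discovery or whole-genome alignment itself, and performs
no GC or mappability correction — the filter cascade is the method's
substitute for those.
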
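# Methods

## Model

A genomic region present in *c* copies in a sample sequenced to mean
disomic depth λ yields read depth ≈ λ·c/2 per base.  The dosage score of
a window, (D/M)×2 with D the window's mean depth over unmasked bases and
M the median window depth of chromosomes assumed disomic, is therefore an
estimator of *c* that is invariant to sequencing effort: multiplying all
depths by any constant leaves every score unchanged, and the median
non-excluded A-subgenome score in backcross mode is exactly 2 by
construction.

Two normalization modes reflect the two sample types:

* **backcross** (F1, BC1F1, BC2F1): the A subgenome is disomic throughout,
  so M is the median over non-excluded A-subgenome windows and is applied
  genome-wide.  C material then reads 1 (monosomic) or 0 (absent).
* **allotetraploid**: each subgenome is normalized by its own median
  ("the median … on both A and C chromosomes … respectively" is read as
  per-subgenome).  With both subgenomes mostly disomic the alternative —
  one global median — changes nothing about the 0/4 nonreciprocal
  signature this mode exists to detect, which is why the per-subgenome
  reading was adopted; a different read-out would only matter for a
  genome-wide aneuploid cultivar.

Median of an even number of windows is the mean of the two central
values.  Excluded windows propagate as missing values, never as zeros.

## Filter cascade

All three filters are evaluated at base resolution and stored as merged,
source-tagged intervals, which makes the window-exclusion rule exact.

* **Repeat filter**: union of annotated repeat intervals (RepeatMasker
  `.out` or BED).  Out-of-bounds intervals are clipped with a warning;
  unknown chromosomes are skipped with a warning.
* **Multi-/non-homoeologous filter**: positions covered by no synteny
  block (length ≥ 5 kb on both sides) are `non_homoeolog`; positions
  whose covering blocks place the partner at more than one distinct locus
  are `multi_homoeolog`.  Two partner intervals count as distinct loci
  when they sit on different chromosomes, or neither overlap nor lie
  within one block length (the longer of the two) of each other on the
  same chromosome — single-linkage clustering with that relation defines
  the locus count.  The multiplicity threshold is configurable
  (`max_partner_loci`, default 1, i.e. ≥ 2 loci mask).
* **Ancestral diploid filter**: a base on an A-subgenome chromosome is
  retained iff depth > 0 in every A-ancestor accession *and* depth = 0 in
  every C-ancestor accession (symmetrically for C).  The thresholds are
  taken literally, with `min_own_depth` / `max_other_depth` parameters
  for noisy panels.  The rule is evaluated per base; a per-bin variant
  would only blur the mask edges.

Windows (default 2 Mb at 500 kb steps; 10 kb / 5 kb for fine mapping) are
excluded when *strictly more* than 95 % of their span is masked — a
window at exactly 95 % is kept.  Depth is counted per aligned base
(CIGAR M/=/X; deletions and skips do not contribute) from primary
alignments with mapping quality ≥ 60, PCR duplicates removed.

## Event calling

Score profiles are segmented per chromosome: a window opens a new segment
when its score departs from the current segment's running mean by more
than the shift threshold.  The default threshold is **0.5** — the value
used for counting HR regions; the larger shift (> 1) quoted when the
score is introduced describes the full disomic→monosomic step, and both
are reachable through `--shift-threshold`.  The running-mean comparison
tolerates within-threshold noise and still catches gradual drift; an
adjacent-window mode is provided for strict step detection.  A segment's
state is its mean score rounded to the nearest integer.

Segment boundaries on an A chromosome are paired with boundaries on its
homoeologous partner when the synteny map projects one into the other's
neighbourhood (default: one coarse window, 2 Mb).  Matching is
nearest-first and one-to-one; unpaired boundaries are reported as
single-sided events of unknown type.  Events co-localizing in ≥ 2
backcross individuals are `common` (candidate native exchanges of the
allotetraploid parent), others `unique` (F1-meiosis events).  Common
events are typed against the parent's allotetraploid-mode profile: flank
scores all within 0.5 of 2 → `reciprocal`; a flank within 0.5 of 4
opposite a homoeologous flank within 0.5 of 0 → `nonreciprocal`; anything
else (e.g. a trisomic ~3 carry-over) → `unknown` with a warning.  Typed
common events are labelled `native`.  The two sub-boundaries of a
nonreciprocal exchange are reported as separate events; grouping them is
left to the provenance metadata.

### Breakpoint refinement

Stage 1 intersects, across individuals, the fine windows inside the
coarse candidate region whose score deviates by more than 0.5 from the
chromosome's expected dosage (2 for A; 0 or 1 for C).  Stage 2 scans
per-base depth inside the intersection with symmetric 500-base flanks and
places the boundary at the position of **maximum** left/right flank-depth
contrast, ties to the lower coordinate; positions are reported as a
bracketing interval at 1 kb resolution (all parameters configurable).  A
maximum-contrast scan is used rather than a first-crossing rule because
at a genuine two-fold step the flank ratio approaches 2 exactly at the
boundary, making a ≥ 2 crossing a coin flip under Poisson noise, whereas
the argmax is unbiased; a detected contrast below 1.5 is treated as flat
and the candidate region is returned unchanged with a warning.  Where one
side's depth dies out entirely (absence boundary), the boundary snaps to
the start of the terminal zero run; "~0" means a flank mean below
max(1, 5 % of the high side).  Individuals disagreeing by more than one
flank yield the widest consistent interval, with a warning.

## Meiotic transmission

The extra C chromosome of a triploid AAC F1 either stays univalent —
transmitted with probability exactly ½ — or joins its two A homoeologues
in a trivalent.  The trivalent model enumerates the three 2:1 disjunction
patterns of (A, A, C) as equiprobable, each yielding its two complementary
gametes with equal probability, giving AA : AC : A : C = 1 : 2 : 2 : 1.
Probabilities are exact `Fraction`s.  3:0 nondisjunction is excluded by
default and available as a rate parameter.  SNP genotypes are called from
allele depths by frequency (het band 0.2–0.8 inclusive, minimum depth 4 —
artifact defaults, as no canonical thresholds exist for this read-out).

## Synthetic data

The simulator generates what the real pipeline consumes, with exact
ground truth.  Genomes are haplotypes — lists of reference-coordinate
segments — so planted exchanges behave like meiotic products and the
conservation law of reciprocal events (summed pair copy number unchanged)
holds by construction and is asserted post hoc.  Native events are
applied homozygously to the allotetraploid parent (reciprocal →
recombinant on both homoeologs, dosage flat at 2; nonreciprocal → both C
homologues carry the A tract: copy 4 / copy 0).  An F1-generation
reciprocal event places one recombinant product (A head + C tail) in the
gamete in place of the A copy, producing the paired A 2→1 / C 0→1
signature observed in backcross data; an F1 nonreciprocal event transmits
the C univalent carrying the A tract alongside an intact A copy (A 2→3 /
C 1→0).  Unengaged C chromosomes are transmitted as univalents with
probability ½.

Per-base depth is Poisson with mean λ·c/2, λ being the disomic depth
(default 30; the method is documented to work at ~6×, and scores are
scale-invariant).  Defaults: two 10 Mb homoeolog pairs, 10 % repeats
placed as disjoint 5 kb elements, 20 % of each pair cross-mapping (shared
10 kb tracts at matching coordinates on both members), seven backcross
individuals, fully deterministic for a given seed.  Ancestral panels
cover their own subgenome everywhere and cross-map exactly onto the
shared tracts, so with a clean panel the ancestral filter's mask equals
the planted shared tracts; a contamination rate exercises the filter's
all-accessions strictness.

What the simulator does **not** emulate: read-level error, GC and
mappability bias beyond an optional per-interval attenuation factor,
real sequence divergence, crossover interference, or segregation
distortion.  Passing tests therefore demonstrate the correctness of the
dosage arithmetic, filter semantics, calling logic and segregation
algebra under the stated noise model — not robustness to alignment
artefacts in real data, which is precisely what the filter cascade and
the ancestral panel are for.

## Problem sizes and numerical choices

Test and acceptance runs use 10 Mb chromosomes with 100 kb / 25 kb
windows (the production geometry scaled 1:20, keeping ≥ 25 windows per
exchanged tract), λ between 20 and 30, and 20 seeds for the end-to-end
recovery property.  Score medians use NumPy's linear-interpolation-free
even-count convention (mean of central pair).  Window exclusion is strict
(> 0.95).  Segmentation rounds half to even only through Python's
`round`; scores sit near integers so ties are not observed in practice.
Degenerate inputs fail loudly: empty FASTA, zero or undefined M, windows
smaller than the step, all-excluded chromosomes (warning, empty
segmentation), missing ancestral depth tracks.

## Known limitations

* Whole-chromosome aneuploidy of the A subgenome in a backcross sample
  would shift M and bias every score; the method assumes a disomic A
  background.
* Event pairing assumes the synteny map covers the boundary
  neighbourhood; boundaries in synteny gaps surface as single-sided
  `unknown` events rather than being force-paired.
* The trivalent model is the minimal equal-pairing model; observed
  backcross data show biased disjunction, which the model's
  nondisjunction parameter does not capture.
* The per-base refinement assumes a single boundary inside the candidate
  region; two boundaries closer than one fine window are returned as one
  interval.
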
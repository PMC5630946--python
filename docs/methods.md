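# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `tc1kit`. Everything quantitative stated here is
computed by the test suite or the acceptance script; nothing is quoted
from elsewhere.

## The element model

A Tc1/mariner element is modelled as

```
TIR — guard — SIR5 — pad — ORF(+stop) — pad — SIR3 — spacer — guard — revcomp(TIR)
```

with a TA target-site duplication outside both termini after insertion.
Defaults describe an active vertebrate Tc1-like family: total length
1,563 bp, 27-bp TIRs, a 23-bp SIR pair, and a 338-codon transposase
(1,014 nt of coding sequence) whose catalytic triad has 37 residues
between the second aspartate and the glutamate (DD37E). All of these are
constructor parameters.

Two generator conventions exist purely so that planted truth is exactly
recoverable, and should be understood as idealisations:

* **Maximality by construction.** Eight anti-complementary guard bases
  follow each TIR and flank each SIR, and junction bases around planted
  SIRs are chosen to break accidental complementarity. Without this, a
  random adjacent base pair extends the true repeat with probability
  1/4 per base, and no detector could report the planted length
  exactly. Real elements have no such guarantee; the detectors
  therefore report *maximal* repeats, which on real data may exceed the
  curated annotation by a few bases.
* **TIRs never begin with the TSD motif.** The TA duplication is its own
  reverse complement, so an element whose TIR begins with TA is
  genuinely ambiguous against "element + TSD". The generator avoids
  this 1/16 corner so that element boundaries are well defined.

## Substitution process

Copies diverge under a Kimura two-parameter (K2P) process: per site the
number of substitution events is Poisson with mean equal to the
requested divergence (substitutions/site), each event a transition with
probability κ/(κ+2) (default κ = 2.0). Multiple hits therefore occur,
and the observed difference fraction follows the K2P saturation curve —
the unit test checks the mean against the matrix exponential of the K2P
rate matrix. Indels are not simulated except for explicit truncations
and the 1-bp inactivating deletion; distance computations downstream
remove gapped columns anyway (pairwise deletion).

**Purifying selection on clean copies.** Copies not designated as
inactivated have ORF-destroying substitutions reverted (premature
in-frame stops, damage to the start codon or terminal stop). At 2 %
divergence a 1-kb ORF acquires a premature stop with probability near
one half; without this assumption "active copy" truth counts would be
meaningless. This mirrors the biological reading that copies observed
intact are the ones selection has constrained. Inactivated copies
receive exactly one lesion: an internal codon (drawn from the central
10–90 % of the ORF) replaced by TAA, or a 1-bp deletion, with equal
probability.

**Planting.** Insertion sites are uniform over TA dinucleotides (the
superfamily's target preference), thinned to a minimum spacing (default
1,000 bp) so that two copies never merge into a single locus; exact
fractions (`round(n·frac)`) of copies are truncated (uniform cut
retaining 10–90 %, end by fair coin, TSD on the truncated side consumed)
and inactivated, so truth counts are reproducible. A truth table (JSON)
records every copy's coordinates, strand, divergence and state.

**HT scenarios.** Marker genes and TE sequences evolve along a dated
ultrametric species tree at a constant rate (substitutions/site/Ma), so
two tips separated T Ma expect distance 2·rate·T. A horizontal-transfer
event (donor, recipient, t Ma) replaces the recipient tip's TE with the
donor lineage's sequence *as it actually was* t Ma ago — an intermediate
stored while simulating the donor's path — evolved forward
independently, giving the transferred pair an expected TE distance of
2·rate·t against a marker distance reflecting the full species split.

## Mining

Translated search builds exact amino-acid k-mer seeds (default k = 3)
between the query and all six frames, clusters seeds along diagonals,
and aligns each cluster window with a local affine-gap BLOSUM62
alignment (open −11, extend −1); clusters with fewer than 3 distinct
seed positions are never extended, which keeps a 100-kb random genome at
zero hits while a planted copy at 80 % amino-acid identity yields
hundreds of seeds. Default score threshold 60. Karlin–Altschul E-values
are out of scope. Copy counting re-scans the genome at the nucleotide
level with 12-mer seeds and edit-distance alignment of each seed
cluster; alignment ends are trimmed to the maximal-scoring segment
(match +1, mismatch/gap −2) before identity is computed, because optimal
alignment of *unrelated* DNA already matches roughly half of its columns
and would otherwise inflate identity and coverage. Filters follow the
standard convention: span strictly greater than 100 bp, identity (matches
over gap-free aligned columns) at least 0.80, overlapping hits merged
per genomic interval (gap < 100 bp) so a fragmented copy counts once.

## Consensus reconstruction

Copies are star-aligned around a reference (global pairwise alignments
with free end gaps: match 2, mismatch −3, gap open −10, extend −1,
merged through the reference coordinate system). Three measures keep
the consensus exact at the element boundaries:

1. **Reference choice.** A star alignment cannot extend beyond its
   reference, so the reference is the copy sharing the most 12-mers
   with at least half of the other copies — length alone cannot
   distinguish a full-length locus from a mildly truncated one once
   kilobase flanks are attached.
2. **Boundary detection.** Element columns are found as the
   maximal-scoring run of high-agreement columns (agreement ≥ 0.8
   scores +1, low-agreement occupied columns −2, minority-occupancy
   insert columns −0.1); flank columns fail the agreement threshold
   despite the ~55 % alignment-induced noise floor. The run is padded
   by 4 columns per side and polished at the sequence level.
3. **Terminus polishing.** The TSD is host sequence duplicated at
   insertion and therefore exactly as conserved across copies as the
   element itself — and TA is partially self-complementary, so TSD
   remnants even mimic TIR extensions. The decisive signal is in the
   copy flanks: for each candidate end trim (0–16 bp) the consensus
   terminus is located in every copy by edit-distance search, and the
   trim placing the TSD immediately *outside* the boundary in the most
   copies wins (minimum support: a third of copies).

The pipeline runs this twice: a first pass over protein-hit loci with
1-kb flanks, then a second pass re-extracting the located copies with
12-bp flanks, which removes the edge damage wide flanks can cause.
Consensus bases are per-column majorities over {A,C,G,T} (ties toward
the reference row; ambiguity codes never emitted); columns below 50 %
occupancy are dropped. On twenty independent 200-kb datasets (12 copies,
2 % divergence, a quarter truncated) this recovers the master element
byte-exactly together with all planted copy/full-length/intact counts.

## Structural annotation

`find_tir` compares the element prefix with the reverse complement of
its suffix (both terminus-anchored, Hamming — no gaps, keeping the scan
exact and brute-forceable) and reports the arm length maximising
matches − 1.5·mismatches. The mismatch ceiling (default fraction 0.10)
is applied to the underlying pair-mismatch *rate* with a two-standard-
deviation binomial allowance on the realised count: in a copy at
divergence d both arms mutate, so the expected pair-mismatch fraction is
≈ 2d — at 5 % divergence exactly the ceiling — and a hard cutoff on the
count would reject half of genuinely decayed TIRs at the boundary.
Measured on the generator: the planted length is reported exactly at
zero divergence, and within ±2 bp in ≥ 90 % of 5 %-divergence copies.
`find_sir` reports the longest exact common substring between the window
inside the 5' TIR and the reverse complement of the window inside the 3'
TIR (default window 300 bp, minimum 12 bp — long enough that two random
300-mers qualify in < 1 % of cases). `check_tsd` compares the flanking
bases on each side with the expected duplication, reporting "unknown"
for sides clipped at a contig edge.

## Triad location and family assignment

Family-diagnostic catalytic-domain blocks (three per family) are
compiled from degenerate patterns — mariner `TXDE / HDNA /
SPDLAP[STI]DY`, Tc1 `[WF][ST]DE / QDND / SPDLNPIE`, TRT `[WF]TDE /
[QH]DNA / SP[DH]LNPIE`, ITmD37E `MDDE / PDLA / [VC]PQ[AF]RPIE` — with
anchors derived from the patterns (block 1: last D; block 2: first D;
block 3: last acidic residue, which is D for the DD..D-type mariner
block). The slash placement in two printed TRT blocks and in the
ITmD37E third block is typographically ambiguous; the readings above are
the defaults and the block table is editable text, so the alternate
ITmD37E reading `[VC]PQA[FR]PIE` is a one-line change. When no family's
three blocks all match in order, a fallback enumerates D..D..E/D
candidates with spacing 20–60 scored by near-miss block conservation.
`assign_family` gives the family with the most matching blocks; TRT
additionally requires DD37E (demoted to Tc1 otherwise — TRT is a Tc1
subfamily), ITmD37E requires spacing 37, ties are "ambiguous", and no
matches is "unclassified". HTH and AT-hook domain calling is out of
scope.

## Distances, trees, the HT test, dating

Distances use pairwise deletion (columns with a gap or ambiguity in
either sequence excluded): p = mismatch fraction, K2P
`−½ ln(1−2P−Q) − ¼ ln(1−2Q)` with P/Q the transition/transversion
fractions; undefined cases (no comparable columns, saturated logs)
propagate as NaN and are excluded downstream. K2P with pairwise
deletion stands in for composite-likelihood distances, whose pooled
pattern estimates are not reproducible as a closed per-pair formula;
K2P is the nearest per-pair model and matches the generator's process.
Neighbor joining is implemented with an explicit tie-break (lowest index
pair on equal Q) so trees are reproducible; negative branch lengths are
clamped to zero; the scikit-bio implementation serves as an independent
oracle in tests, never as the implementation. Clusters are maximal
subtrees whose members pairwise lie within a distance ceiling (default
0.35), with a greedy union pass because the NJ root is an arbitrary
trifurcation that can split a true cluster. The HT verdict for a
species pair is `HT-candidate` iff d_TE < d_marker strictly (both
defined); equality is a tie, d_TE > d_marker an "exception", so tallies
decompose as candidates + exceptions + ties = all pairs. The TE/marker
ratio is recorded, with ratio ≤ 0.5 flagged "strong". The activity
window of a family is [crown age of the species with active copies, age
of their MRCA with the nearest species lacking active copies]; with no
inactive outgroup the upper bound is undefined.

## Problem sizes used by the tests

Unit and acceptance tests run at deliberately modest scales chosen to
make sampling error negligible relative to the asserted tolerances:
1-Mb genomes with 44 planted copies for count recovery (20 seeds),
200-kb genomes with 12 copies for end-to-end truth recovery, 20 copies
at 5 % divergence for consensus recovery, 201 copies for the exact
intact-count reproduction, two-species 110-Ma splits with transfers at
2–11 Ma (20 seeds each for sensitivity and the vertical null), and
1,000 random 2-kb sequences for the ORF-finder oracle.

## What the synthetic data does and does not show

The generator emulates the features the pipeline's decisions depend on:
TIR/SIR/TSD geometry, a coding ORF with a diagnostic triad, K2P-diverged
copies, truncation and inactivation, TA-targeted insertion with TSD
duplication, rate-constant marker and TE evolution, and HT events. It
deliberately omits: realistic base composition and repeat landscapes
(other families, tandem repeats, segmental duplications), indel
accumulation in decayed copies, nested insertions, rate variation across
sites and lineages, assembly gaps and sequencing error. Passing tests
therefore demonstrate algorithmic correctness under the stated model,
not performance on real assemblies — on real data the homogeneous-rate
assumptions behind the K2P distances and the clean TIR/TSD boundaries
will be the first to degrade.

## Other limitations

* The star alignment is single-pass and adequate at the ≤ 20 %
  divergences among family copies; a progressive MSA upgrade would be
  drop-in behind `align_copies`.
* Expression evidence is an input boolean per species (transcriptome
  searching is out of scope), and E-value statistics for the translated
  search are not computed.
* `find_sir` reports exact repeats only; a mismatch-tolerant SIR search
  would require a banded extension around the exact core.
* Bayesian phylogenetics, substitution-model selection and bootstrap
  support are out of scope; the NJ tree is a clustering device.
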
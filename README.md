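# tc1kit

Discovery, annotation, classification and horizontal-transfer analysis of
Tc1/mariner DNA transposons.

## The problem

Tc1/mariner elements are cut-and-paste DNA transposons, typically
1.3–2.4 kb, encoding a ~340-aa transposase flanked by terminal inverted
repeats (TIRs) and inserted into a TA dinucleotide that is duplicated on
both sides (the target-site duplication, TSD). The catalytic triad of the
transposase — two aspartates and a glutamate or aspartate — carries a
family-diagnostic spacing between the second D and the terminal acidic
residue: DD34E (classic Tc1), DD34D (mariner), DD37E, DD37D, and so on.
Because these elements can cross species boundaries, a family found in
distantly related hosts at suspiciously low divergence is a candidate for
horizontal transfer (HT): if the element were inherited vertically, its
divergence between two species should resemble that of a slowly evolving
orthologous host gene such as *RAG1* over the same species pair.

`tc1kit` implements the complete desk workflow for such a family study,
for researchers annotating a new Tc1-like family from genome assemblies:

* **mining** — translated (six-frame) seed-and-extend search of a genome
  with a transposase protein query (BLOSUM62, affine gaps), and locus
  extraction with 1,000-bp flanks;
* **consensus** — star alignment of copies, conservation-based element
  boundary detection, majority consensus, and copy counting under the
  standard filters (hits longer than 100 bp at ≥ 80 % identity, merged
  per genomic interval);
* **annotation** — full-length classification (identity > 95 % to the
  consensus and ≥ 95 % coverage), ORF finding (six-frame, stop-to-stop,
  ATG-trimmed), and intactness calls (no internal stop, no frameshift,
  near-reference length) — the criteria for a potentially active family;
* **structure** — TIR detection (terminus-anchored Hamming scan),
  subterminal inverted repeat (SIR) detection, TSD checks;
* **classification** — DDE/D triad location from conserved catalytic-domain
  motif blocks and assignment to mariner / Tc1 / TRT / ITmD37E;
* **HT inference** — p and Kimura two-parameter distances with pairwise
  deletion, `d = −½ ln(1−2P−Q) − ¼ ln(1−2Q)`; neighbor-joining trees;
  cluster-wise TE-vs-marker comparisons (verdict HT-candidate iff
  d_TE < d_marker); and activity-window dating on a calibrated species
  tree;
* **simulation** — a generator that plants all of the above with a
  machine-readable truth table: master elements with chosen TIR/SIR/TSD
  geometry and DDE/D spacing, K2P-diverged copies with configurable
  truncated and inactivated fractions, marker genes evolving along a
  dated tree, and HT events between lineages.

## Worked example

Simulate a genome with planted ground truth, then run the full pipeline:

```sh
tc1kit simulate --out sim --seed 5 --n-copies 10 --genome-length 150000 \
    --divergence 0.02 --truncate-frac 0.2 --inactivate-frac 0.2
tc1kit run --genome sim/genome.fasta --query sim/transposase.fasta \
    --out runout --seed 5
```

which prints

```
genome: 10 copies, 8 full-length, 6 intact, TRT
```

The simulated family had 10 copies planted, of which 2 were truncated and
2 carried an ORF-inactivating lesion; the pipeline recovers exactly the
planted counts (10 copies; 8 untruncated = full-length; 6 of those with
clean ORFs = intact) and classifies the reconstructed 1,563-bp consensus,
with its 27-bp TIRs and 338-aa DD37E transposase, as a TRT-subfamily
Tc1 element. `runout/` holds the consensus FASTA, copy intervals as BED6,
TIR/SIR/ORF features as GFF3, and the family report as TSV/JSON.

Structural annotation and activity dating on their own:

```sh
tc1kit annotate-structure --element sim/master.fasta --out master.gff3
# TIR=27 SIR=23 ORF=338aa
tc1kit date-activity --tree species.nwk --active A,B --inactive C
# activity window: 4 - 19.6 Ma
```

the latter reading a dated species tree (`((A:4,B:4):15.6,C:19.6);`):
the window spans from the crown age of the species with active copies to
their split from the nearest species without them.

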
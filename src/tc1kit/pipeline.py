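"""Configuration, the end-to-end pipeline, and family reporting.

``run_pipeline`` chains the stages in the order a family study runs
them: translated mining with a transposase query, locus extraction with
flanks, star alignment and consensus reconstruction, nucleotide copy
counting under the length/identity filters, per-copy full-length and
intactness classification, structural annotation (TIR/SIR/TSD), triad
location and family assignment, and — when marker alignments are
provided — the TE-vs-marker horizontal-transfer scan.  Every stage's
outputs can be persisted, and a fixed seed makes reruns byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Union

from . import consensus as cons
from . import formats, ht, mining, motifs, structure

logger = logging.getLogger("tc1kit")


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All thresholds of the pipeline, with their conventional defaults.

    ``min_copy_length`` is strict (hits must be longer than it);
    ``min_copy_identity`` is inclusive.  Full-length calls need
    identity strictly above ``full_length_identity`` and coverage of at
    least ``full_length_coverage``.
    """

    min_copy_length: int = 100
    min_copy_identity: float = 0.80
    full_length_identity: float = 0.95
    full_length_coverage: float = 0.95
    flank: int = 1000
    min_score: float = 60.0
    word_size: int = 3
    tir_max_len: int = 250
    tir_min_len: int = 10
    tir_max_mismatch_frac: float = 0.1
    sir_window: int = 300
    sir_min_len: int = 12
    min_orf_codons: int = 100
    distance_method: str = "k2p"
    cluster_max_distance: float = 0.35
    ht_strong_ratio: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name in ("min_copy_identity", "full_length_identity",
                     "full_length_coverage", "tir_max_mismatch_frac",
                     "ht_strong_ratio"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("min_copy_length", "flank", "tir_max_len",
                     "tir_min_len", "sir_window", "sir_min_len",
                     "min_orf_codons"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.distance_method not in ("p", "k2p"):
            raise ValueError("distance_method must be 'p' or 'k2p'")

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Flat ``key = value`` text; CLI overrides take precedence."""
        values: Dict[str, str] = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"line {ln}: expected 'key = value'")
                k, v = (x.strip() for x in line.split("=", 1))
                values[k] = v
        cfg = cls()
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for k, v in values.items():
            if k not in types:
                raise ValueError(f"unknown config key {k!r}")
            current = getattr(cfg, k)
            setattr(cfg, k, type(current)(v) if not isinstance(current, str)
                    else v)
        for k, v in overrides.items():
            if v is not None:
                setattr(cfg, k, v)
        cfg.validate()
        return cfg

    def to_text(self) -> str:
        return "\n".join(f"{f.name} = {getattr(self, f.name)}"
                         for f in dataclasses.fields(self))


# ---------------------------------------------------------------------------
# survey bookkeeping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurveyManifest:
    """Bookkeeping for a multi-genome presence/absence survey.

    Records how many genomes were scanned per taxonomic category; the
    denominator quoted alongside a family's taxonomic distribution.
    """

    category_counts: Mapping[str, int]

    @property
    def total(self) -> int:
        return sum(self.category_counts.values())


# ---------------------------------------------------------------------------
# per-species report
# ---------------------------------------------------------------------------

@dataclass
class FamilyReportRow:
    species: str
    family: str
    consensus_length: int
    tir_length: Optional[int]
    transposase_aa: Optional[int]
    copies: int
    full_length: int
    intact: int
    expression_evidence: bool
    classification: str
    spacing_signature: Optional[str] = None

    def validate(self) -> None:
        if not (self.intact <= self.full_length):
            raise ValueError("intact count exceeds full-length count")


@dataclass
class SpeciesResult:
    row: FamilyReportRow
    consensus: str
    loci: List[mining.CandidateLocus]
    copies: List[cons.TECopy]
    copy_intervals: List[mining.CopyInterval]
    tir: Optional[structure.InvertedRepeatPair]
    sir: Optional[structure.InvertedRepeatPair]
    orf: Optional[cons.OrfResult]


@dataclass
class PipelineResult:
    species: Dict[str, SpeciesResult]
    ht_comparisons: List[ht.HTComparison] = field(default_factory=list)
    te_tree_newick: Optional[str] = None

    @property
    def report_rows(self) -> List[FamilyReportRow]:
        return [r.row for r in self.species.values()]


def _second_pass_consensus(genome, consensus0: str,
                           config: PipelineConfig,
                           flank: int = 12,
                           min_len_frac: float = 0.8) -> Optional[str]:
    """Rebuild the consensus from copies located with a preliminary one."""
    contigs = {"chr1": genome} if isinstance(genome, str) else genome
    _, intervals = mining.count_copies(
        genome, consensus0, min_length=config.min_copy_length,
        min_identity=config.min_copy_identity)
    full = [iv for iv in intervals
            if iv.length >= min_len_frac * len(consensus0)]
    if len(full) < 2:
        return None
    seqs = []
    for idx, iv in enumerate(full):
        src = contigs[iv.contig]
        s = src[max(0, iv.start - flank):min(len(src), iv.end + flank)]
        if iv.strand == "-":
            s = structure.reverse_complement(s)
        seqs.append((f"rep{idx}", s))
    aln = cons.align_copies(seqs, reference=cons.pick_reference(seqs))
    lo, hi = cons.element_boundaries(aln)
    rebuilt = cons.build_consensus(cons.slice_columns(aln, lo, hi))
    return cons.refine_element_termini(rebuilt, [s for _, s in seqs])


def _analyze_species(species: str, genome, query: str,
                     config: PipelineConfig, family: str,
                     expression: bool) -> Optional[SpeciesResult]:
    try:
        hits = mining.translated_search(
            query, genome, min_score=config.min_score,
            word_size=config.word_size)
        loci = mining.extract_loci(hits, genome, flank=config.flank)
    except Exception as exc:  # noqa: BLE001
        raise StageError("mine", str(exc)) from exc
    if not loci:
        return None
    try:
        pairs = [(lc.name, lc.sequence) for lc in loci]
        aln = cons.align_copies(pairs, reference=cons.pick_reference(pairs))
        lo, hi = cons.element_boundaries(aln)
        consensus_seq = cons.build_consensus(cons.slice_columns(aln, lo, hi))
        consensus_seq = cons.refine_element_termini(
            consensus_seq, [lc.sequence for lc in loci])
        # second pass: the preliminary consensus locates near-full-length
        # copies; re-aligning them with tight flanks removes the edge
        # damage the kilobase flanks of the first pass can cause
        consensus_seq = _second_pass_consensus(genome, consensus_seq,
                                               config) or consensus_seq
    except Exception as exc:  # noqa: BLE001
        raise StageError("consensus", str(exc)) from exc
    try:
        n_copies, intervals = mining.count_copies(
            genome, consensus_seq, min_length=config.min_copy_length,
            min_identity=config.min_copy_identity)
    except Exception as exc:  # noqa: BLE001
        raise StageError("count", str(exc)) from exc
    try:
        orf = cons.find_orf(consensus_seq, min_codons=config.min_orf_codons)
    except ValueError:
        orf = None
    try:
        copies = cons.annotate_copies(
            [(lc.name, lc.sequence) for lc in loci], consensus_seq,
            orf.protein if orf else "X" * config.min_orf_codons,
            consensus_orf=(orf.start, orf.end) if orf and orf.strand == "+"
            else None,
            min_identity=config.full_length_identity,
            min_coverage=config.full_length_coverage)
    except Exception as exc:  # noqa: BLE001
        raise StageError("annotate", str(exc)) from exc
    counts = cons.family_counts(copies)
    try:
        tir = structure.find_tir(
            consensus_seq, max_len=config.tir_max_len,
            max_mismatch_frac=config.tir_max_mismatch_frac,
            min_len=config.tir_min_len)
        sir = structure.find_sir(consensus_seq, tir,
                                 window=config.sir_window,
                                 min_len=config.sir_min_len)
    except Exception as exc:  # noqa: BLE001
        raise StageError("structure", str(exc)) from exc
    label = "unclassified"
    signature = None
    if orf is not None:
        classification, _scores = motifs.assign_family(orf.protein)
        triad = motifs.locate_triad(orf.protein)
        label = classification
        signature = motifs.spacing_label(triad) if triad else None
    row = FamilyReportRow(
        species=species, family=family,
        consensus_length=len(consensus_seq),
        tir_length=tir.length if tir else None,
        transposase_aa=len(orf.protein) if orf else None,
        copies=n_copies, full_length=counts["full_length"],
        intact=counts["intact"], expression_evidence=expression,
        classification=label, spacing_signature=signature)
    row.validate()
    return SpeciesResult(row, consensus_seq, loci, copies, intervals,
                         tir, sir, orf)


def run_pipeline(
    config: PipelineConfig,
    genomes: Mapping[str, Union[str, Dict[str, str]]],
    query: str,
    markers: Optional[Mapping[str, str]] = None,
    tree_newick: Optional[str] = None,
    expression: Optional[Mapping[str, bool]] = None,
    family: str = "TRT-like",
    outdir: Optional[Union[str, Path]] = None,
) -> PipelineResult:
    """Run the full pipeline over one or more species genomes.

    ``markers`` (one aligned marker-gene sequence per species) enables
    the horizontal-transfer scan; ``expression`` carries the per-species
    transcriptome-evidence booleans (an input, never computed here).
    With ``outdir`` set, every stage's outputs are persisted and the
    effective configuration is logged for reproducibility.
    """
    config.validate()
    expression = expression or {}
    from . import __version__
    logger.info("pipeline start: tc1kit %s, %d genome(s), seed %d",
                __version__, len(genomes), config.seed)
    logger.info("effective config:\n%s", config.to_text())
    species_results: Dict[str, SpeciesResult] = {}
    for sp in sorted(genomes):
        res = _analyze_species(sp, genomes[sp], query, config, family,
                               bool(expression.get(sp, False)))
        if res is None:
            logger.info("%s: no candidate loci", sp)
            continue
        species_results[sp] = res
        logger.info("%s: %d copies (%d full-length, %d intact)",
                    sp, res.row.copies, res.row.full_length, res.row.intact)

    comparisons: List[ht.HTComparison] = []
    te_tree = None
    if markers and len(species_results) >= 3:
        try:
            te_aln = cons.align_copies(
                {sp: r.consensus for sp, r in species_results.items()})
            te_rows = dict(zip(te_aln.ids, te_aln.rows))
            te_dm = ht.distance_matrix(te_rows, config.distance_method)
            marker_dm = ht.distance_matrix(
                {sp: markers[sp] for sp in species_results
                 if sp in markers}, config.distance_method)
            te_tree = ht.nj_tree(te_dm)
            clusters = ht.extract_clusters(te_tree, te_dm,
                                           config.cluster_max_distance)
            comparisons = ht.ht_scan(te_dm, marker_dm, clusters,
                                     config.ht_strong_ratio)
        except Exception as exc:  # noqa: BLE001
            raise StageError("htscan", str(exc)) from exc

    result = PipelineResult(species_results, comparisons, te_tree)
    if outdir is not None:
        _persist(result, config, Path(outdir))
    return result


def _persist(result: PipelineResult, config: PipelineConfig,
             outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.txt").write_text(config.to_text() + "\n")
    rows = []
    for sp, res in result.species.items():
        rows.append(dataclasses.asdict(res.row))
        formats.write_fasta(
            [(f"{sp}_consensus", "", res.consensus)],
            outdir / f"{sp}.consensus.fasta")
        feats = [formats.Feature(iv.contig, iv.start, iv.end,
                                 res.row.family,
                                 score=iv.identity * 1000,
                                 strand=iv.strand)
                 for iv in res.copy_intervals]
        formats.write_bed(feats, outdir / f"{sp}.copies.bed")
        gff = []
        if res.tir:
            gff.append(formats.Feature("consensus", res.tir.left_start,
                                       res.tir.left_end, "TIR5",
                                       ftype="inverted_repeat"))
            gff.append(formats.Feature("consensus", res.tir.right_start,
                                       res.tir.right_end, "TIR3",
                                       ftype="inverted_repeat"))
        if res.sir:
            gff.append(formats.Feature("consensus", res.sir.left_start,
                                       res.sir.left_end, "SIR5",
                                       ftype="inverted_repeat"))
            gff.append(formats.Feature("consensus", res.sir.right_start,
                                       res.sir.right_end, "SIR3",
                                       ftype="inverted_repeat"))
        if res.orf:
            gff.append(formats.Feature("consensus", res.orf.start,
                                       res.orf.end, "transposase_ORF",
                                       strand=res.orf.strand, ftype="CDS"))
        formats.write_gff3(gff, outdir / f"{sp}.features.gff3")
    import pandas as pd
    pd.DataFrame(rows).to_csv(outdir / "report.tsv", sep="\t", index=False)
    (outdir / "report.json").write_text(
        json.dumps(rows, indent=1, default=str) + "\n")
    if result.te_tree_newick:
        (outdir / "te_tree.nwk").write_text(result.te_tree_newick + "\n")
    if result.ht_comparisons:
        hrows = [dataclasses.asdict(c) for c in result.ht_comparisons]
        pd.DataFrame(hrows).to_csv(outdir / "ht_report.tsv", sep="\t",
                                   index=False)
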
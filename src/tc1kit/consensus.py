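"""Consensus reconstruction, full-length classification and ORF intactness.

A family consensus is rebuilt from genomic copies by star alignment
around a reference copy (global pairwise alignments with free end gaps,
merged through the reference coordinate system) followed by per-column
majority voting.  Copies are then classified: *full-length* copies
cover and match the consensus above configurable thresholds, and
*intact* copies additionally encode a transposase ORF of near-reference
length with no internal stop codons and no frameshift.  These are the
standard criteria for calling a family potentially active.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from Bio import Align
from Bio.Seq import Seq

GAP = "-"


def _nt_aligner(end_gaps_free: bool = True) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -1
    if end_gaps_free:
        try:
            aligner.open_end_gap_score = 0
            aligner.extend_end_gap_score = 0
        except AttributeError:  # older attribute names
            aligner.end_open_gap_score = 0
            aligner.end_extend_gap_score = 0
    return aligner


# ---------------------------------------------------------------------------
# star multiple alignment
# ---------------------------------------------------------------------------

@dataclass
class CopyAlignment:
    """A multiple alignment of copies; de-gapped rows reproduce inputs."""

    ids: List[str]
    rows: List[str]
    reference_id: str

    def __post_init__(self):
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]


def _pairwise_tokens(ref: str, other: str,
                     aligner: Align.PairwiseAligner) -> List[str]:
    """Per-reference-slot tokens of ``other`` aligned to ``ref``.

    Token i (0..len(ref)) holds the bases inserted before reference
    position i; token i additionally carries the base (or gap) aligned
    to reference position i for i < len(ref).
    """
    aln = aligner.align(ref, other)[0]
    rrow, orow = str(aln[0]), str(aln[1])
    inserts = [""] * (len(ref) + 1)
    aligned = [GAP] * len(ref)
    rpos = 0
    for rc, oc in zip(rrow, orow):
        if rc == GAP:
            inserts[rpos] += oc
        else:
            aligned[rpos] = oc
            rpos += 1
    return [inserts[i] + (aligned[i] if i < len(ref) else "")
            for i in range(len(ref) + 1)]


def pick_reference(
    sequences: Union[Dict[str, str], Sequence[Tuple[str, str]]],
    k: int = 12,
) -> str:
    """Choose the copy that shares the most k-mers with the others.

    A star alignment can never extend beyond its reference, so the
    reference must be a full-length copy.  Length alone cannot tell a
    full-length locus from a mildly truncated one (flanks dominate);
    the copy carrying the most k-mers that occur in at least half of
    the other copies is the one containing the most of the common
    element.  Ties break to input order.
    """
    items = list(sequences.items()) if isinstance(sequences, dict) \
        else [(i, s) for i, s in sequences]
    if len(items) == 1:
        return items[0][0]
    kmer_sets = []
    for _, s in items:
        s = s.upper()
        kmer_sets.append({s[i:i + k] for i in range(len(s) - k + 1)})
    df: Dict[str, int] = {}
    for ks in kmer_sets:
        for km in ks:
            df[km] = df.get(km, 0) + 1
    need = max(2, len(items) // 2)
    best_id, best_score = items[0][0], -1
    for (sid, _), ks in zip(items, kmer_sets):
        score = sum(1 for km in ks if df[km] >= need)
        if score > best_score:
            best_id, best_score = sid, score
    return best_id


def align_copies(
    sequences: Union[Dict[str, str], Sequence[Tuple[str, str]]],
    reference: str = "longest",
) -> CopyAlignment:
    """Star-align copies around a reference.

    Every sequence is aligned to the reference pairwise (global,
    free end gaps) and the pairwise alignments are merged through the
    reference coordinate system: each inter-reference gap column block
    is widened to the longest insertion observed there.  Adequate for
    the ≤20 % divergences among family copies and fully deterministic.
    """
    items = list(sequences.items()) if isinstance(sequences, dict) \
        else [(i, s) for i, s in sequences]
    if not items:
        raise ValueError("no sequences to align")
    ids = [i for i, _ in items]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    seqs = {i: s.upper() for i, s in items}
    if len(items) == 1:
        (sid, seq), = seqs.items()
        return CopyAlignment([sid], [seq], sid)
    if reference == "longest":
        ref_id = max(ids, key=lambda i: (len(seqs[i]), -ids.index(i)))
    else:
        ref_id = reference
        if ref_id not in seqs:
            raise ValueError(f"unknown reference id {ref_id!r}")
    ref = seqs[ref_id]
    aligner = _nt_aligner()
    tokens: Dict[str, List[str]] = {}
    for sid in ids:
        if sid == ref_id:
            continue
        tokens[sid] = _pairwise_tokens(ref, seqs[sid], aligner)
    nslots = len(ref) + 1
    ins_width = [0] * nslots
    for toks in tokens.values():
        for i, t in enumerate(toks):
            width = len(t) - (1 if i < len(ref) else 0)
            ins_width[i] = max(ins_width[i], width)
    rows = []
    for sid in ids:
        if sid == ref_id:
            row = "".join(GAP * ins_width[i] +
                          (ref[i] if i < len(ref) else "")
                          for i in range(nslots))
        else:
            toks = tokens[sid]
            parts = []
            for i in range(nslots):
                t = toks[i]
                ins = t[:-1] if i < len(ref) else t
                base = t[-1] if i < len(ref) else ""
                parts.append(ins + GAP * (ins_width[i] - len(ins)) + base)
            row = "".join(parts)
        rows.append(row)
    return CopyAlignment(ids, rows, ref_id)


# ---------------------------------------------------------------------------
# element boundaries
# ---------------------------------------------------------------------------

def element_boundaries(aln: CopyAlignment,
                       min_agreement: float = 0.8,
                       edge_agreement: float = 0.75,
                       flank_penalty: float = 2.0,
                       pad: int = 4) -> Tuple[int, int]:
    """Column range of the conserved element block within a locus alignment.

    Loci are extracted with flanking host sequence; flanks are unrelated
    between copies, so their columns show near-random agreement while
    element columns are highly conserved.  (Note the flank noise floor:
    optimal alignment of unrelated DNA already matches roughly half its
    columns, so the agreement thresholds sit well above 0.5.)  The
    maximal-scoring column segment (agreement >= ``min_agreement``
    scores +1, lower scores ``-flank_penalty``) is taken, its edges
    greedily stripped of columns below ``edge_agreement``, and the
    result widened by ``pad`` columns per side — boundaries err
    generous and are polished at the sequence level by
    :func:`refine_element_termini`.  With a single row the whole
    alignment is returned (boundaries are undefined without copies to
    compare).
    """
    n = len(aln.rows)
    ncol = aln.n_columns
    if n < 2:
        return 0, ncol
    mat = np.array([list(r) for r in aln.rows])
    agreement = np.zeros(ncol)
    occupancy = np.zeros(ncol)
    for col in range(ncol):
        column = mat[:, col]
        bases = column[column != GAP]
        occupancy[col] = len(bases) / n
        if len(bases) < 2:
            agreement[col] = 0.0
            continue
        _, counts = np.unique(bases, return_counts=True)
        agreement[col] = counts.max() / len(bases)
    # insertion columns carried by a minority of rows occur inside the
    # element too and must not fragment the block; score them near-neutral
    # (slightly negative, so long flank runs cannot bridge to stray
    # well-agreeing columns far outside the element)
    score = np.where(occupancy < 0.5, -0.1,
                     np.where(agreement >= min_agreement,
                              1.0, -flank_penalty))
    best = cur = 0.0
    best_range = (0, 0)
    cur_start = 0
    for i, s in enumerate(score):
        if cur <= 0:
            cur = s
            cur_start = i
        else:
            cur += s
        if cur > best:
            best = cur
            best_range = (cur_start, i + 1)
    lo, hi = best_range
    while lo < hi and (agreement[lo] < edge_agreement or
                       occupancy[lo] < 0.5):
        lo += 1
    while hi > lo and (agreement[hi - 1] < edge_agreement or
                       occupancy[hi - 1] < 0.5):
        hi -= 1
    return max(0, lo - pad), min(ncol, hi + pad)


def refine_element_termini(consensus: str,
                           loci: Optional[Sequence[str]] = None,
                           tsd: str = "TA",
                           max_trim: int = 16,
                           probe_len: int = 25) -> str:
    """Polish a preliminary consensus to exact element boundaries.

    Conservation-based boundaries are accurate only to a few bases, and
    the duplicated target site is as conserved across copies as the
    element itself (TA is even partially self-complementary, so TSD
    remnants mimic TIR extensions).  The decisive signal lives in the
    copies' flanks: exactly outside the true element boundary each
    untruncated copy carries the TSD.  For every candidate trim the
    consensus terminus is located in each locus (edit-distance search
    of a ``probe_len`` terminal probe) and the trim whose implied
    boundary has the TSD immediately outside in the most loci wins
    (ties: the wider element).  Without loci, or when no boundary shows
    TSD support, the consensus is returned unchanged.
    """
    import edlib

    if not loci or len(consensus) < 2 * (max_trim + probe_len):
        return consensus
    k = len(tsd)
    n = len(consensus)
    max_dist = max(2, probe_len // 5)

    def left_support(a: int) -> int:
        probe = consensus[a:a + probe_len]
        hits = 0
        for locus in loci:
            res = edlib.align(probe, locus.upper(), mode="HW", task="locations")
            if res["editDistance"] < 0 or res["editDistance"] > max_dist:
                continue
            s = res["locations"][0][0]
            if s >= k and locus[s - k:s].upper() == tsd:
                hits += 1
        return hits

    def right_support(b: int) -> int:
        probe = consensus[n - b - probe_len:n - b]
        hits = 0
        for locus in loci:
            res = edlib.align(probe, locus.upper(), mode="HW", task="locations")
            if res["editDistance"] < 0 or res["editDistance"] > max_dist:
                continue
            e = res["locations"][0][1] + 1
            if locus[e:e + k].upper() == tsd:
                hits += 1
        return hits

    left = [(left_support(a), -a) for a in range(max_trim + 1)]
    right = [(right_support(b), -b) for b in range(max_trim + 1)]
    best_left = max(left)
    best_right = max(right)
    # a boundary is only trusted when a real share of the copies shows the
    # TSD there; a stray hit or two is flank noise
    min_support = max(2, -(-len(loci) // 3))
    a = -best_left[1] if best_left[0] >= min_support else 0
    b = -best_right[1] if best_right[0] >= min_support else 0
    return consensus[a:n - b or None]


def slice_columns(aln: CopyAlignment, start: int, end: int) -> CopyAlignment:
    """A sub-alignment restricted to a column range."""
    return CopyAlignment(aln.ids, [r[start:end] for r in aln.rows],
                         aln.reference_id)


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def build_consensus(aln: CopyAlignment,
                    min_col_occupancy: float = 0.5) -> str:
    """Per-column majority consensus over aligned copies.

    Columns whose non-gap occupancy falls below ``min_col_occupancy``
    are dropped; ties break toward the reference row's base so the
    output stays over {A,C,G,T} with no ambiguity codes.
    """
    if not aln.rows:
        raise ValueError("empty alignment")
    mat = np.array([list(r) for r in aln.rows])
    ref_row = np.array(list(aln.row(aln.reference_id)))
    n = len(aln.rows)
    out = []
    for col in range(mat.shape[1]):
        column = mat[:, col]
        bases = column[np.isin(column, list("ACGT"))]
        occupancy = (column != GAP).sum() / n
        if occupancy < min_col_occupancy or len(bases) == 0:
            continue
        vals, counts = np.unique(bases, return_counts=True)
        top = counts.max()
        tied = set(vals[counts == top])
        if len(tied) == 1:
            out.append(tied.pop())
        elif ref_row[col] in tied:
            out.append(str(ref_row[col]))
        else:
            out.append(sorted(tied)[0])
    return "".join(out)


# ---------------------------------------------------------------------------
# copy classification
# ---------------------------------------------------------------------------

@dataclass
class TECopy:
    """Per-copy annotation relative to the family consensus."""

    copy_id: str
    identity_to_consensus: float
    coverage_of_consensus: float
    full_length: bool
    intact_orf: bool
    orf: Optional["OrfResult"] = None

    def __post_init__(self):
        if self.intact_orf and not self.full_length:
            raise ValueError("intact_orf implies full_length")


def _best_segment(crow: str, qrow: str) -> Tuple[int, int]:
    """Maximal-scoring column window (match +1, mismatch/gap -2).

    Copies carry flanking host sequence; its spurious alignment against
    the consensus (unrelated DNA aligns about half its columns) would
    inflate identity and coverage, so statistics are computed on the
    best-scoring segment only.
    """
    best = cur = 0
    best_range = (0, 0)
    cur_start = 0
    for i, (c, q) in enumerate(zip(crow, qrow)):
        if c == GAP and q == GAP:
            sc = 0
        elif c == GAP or q == GAP or c != q:
            sc = -2
        else:
            sc = 1
        if cur <= 0:
            cur = sc
            cur_start = i
        else:
            cur += sc
        if cur > best:
            best = cur
            best_range = (cur_start, i + 1)
    return best_range


def _copy_vs_consensus(copy_seq: str, consensus: str):
    aligner = _nt_aligner()
    aln = aligner.align(consensus, copy_seq)[0]
    crow, qrow = str(aln[0]), str(aln[1])
    s, e = _best_segment(crow, qrow)
    matches = cols = covered = 0
    for c, q in zip(crow[s:e], qrow[s:e]):
        if c != GAP and q != GAP:
            covered += 1
            cols += 1
            if c == q:
                matches += 1
    identity = matches / cols if cols else 0.0
    coverage = covered / len(consensus) if consensus else 0.0
    return identity, coverage, crow, qrow


def classify_full_length(copy_seq: str, consensus: str,
                         min_identity: float = 0.95,
                         min_coverage: float = 0.95,
                         ) -> Tuple[bool, float, float]:
    """Classify a copy as full-length against the consensus.

    Full length means identity (computed excluding gap columns)
    strictly above ``min_identity`` and coverage of the consensus of at
    least ``min_coverage``.  Returns (full_length, identity, coverage).
    """
    identity, coverage, _, _ = _copy_vs_consensus(copy_seq, consensus)
    return (identity > min_identity and coverage >= min_coverage,
            identity, coverage)


# ---------------------------------------------------------------------------
# ORF finding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrfResult:
    """An open reading frame in forward coordinates on the input."""

    start: int
    end: int
    strand: str
    frame: int
    protein: str
    has_start_codon: bool = True

    @property
    def n_codons(self) -> int:
        return len(self.protein)


def find_orf(seq: str, min_codons: int = 100) -> Optional[OrfResult]:
    """Longest ORF across all six frames (stop-to-stop, ATG-trimmed).

    Stop-to-stop segments are trimmed to their first ATG; a segment
    with no ATG is used untrimmed and flagged (``has_start_codon``
    False).  The stop codon is excluded from the residue count.  The
    longest qualifying ORF wins (ties: forward strand, lower frame,
    leftmost).  Returns ``None`` when no ORF reaches ``min_codons``.
    """
    if len(seq) < 3 * min_codons:
        raise ValueError("sequence shorter than 3 * min_codons")
    seq = seq.upper()
    L = len(seq)
    from .structure import reverse_complement
    best: Optional[OrfResult] = None
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for f in range(3):
            sub = s[f:]
            sub = sub[:len(sub) - len(sub) % 3]
            prot = str(Seq(sub).translate())
            pos = 0
            for segment in prot.split("*"):
                seg_start = pos
                pos += len(segment) + 1
                if not segment:
                    continue
                m = segment.find("M")
                if m >= 0:
                    cand, c_start, has_atg = segment[m:], seg_start + m, True
                else:
                    cand, c_start, has_atg = segment, seg_start, False
                if len(cand) < min_codons:
                    continue
                nt_lo = f + 3 * c_start
                nt_hi = nt_lo + 3 * len(cand)
                if strand == "+":
                    start, end = nt_lo, nt_hi
                else:
                    start, end = L - nt_hi, L - nt_lo
                cand_res = OrfResult(start, end, strand, f, cand, has_atg)
                if best is None or len(cand) > len(best.protein):
                    best = cand_res
    return best


# ---------------------------------------------------------------------------
# intactness
# ---------------------------------------------------------------------------

def _internal_gap_frameshift(crow: str, qrow: str,
                             orf_interval: Tuple[int, int]) -> bool:
    """True if any gap run inside the consensus ORF breaks the frame."""
    s, e = orf_interval
    cpos = 0
    runs: List[Tuple[int, int, str]] = []  # (consensus pos, length, which)
    i = 0
    n = len(crow)
    while i < n:
        if qrow[i] == GAP and crow[i] != GAP:
            j = i
            while j < n and qrow[j] == GAP and crow[j] != GAP:
                j += 1
            runs.append((cpos, j - i, "del"))
            cpos += j - i
            i = j
        elif crow[i] == GAP and qrow[i] != GAP:
            j = i
            while j < n and crow[j] == GAP and qrow[j] != GAP:
                j += 1
            runs.append((cpos, j - i, "ins"))
            i = j
        else:
            cpos += 1
            i += 1
    for pos, length, kind in runs:
        inside = (s < pos < e) if kind == "ins" else \
            (pos < e and pos + length > s and pos > 0)
        if inside and length % 3 != 0:
            return True
    return False


def check_intact(copy_protein: Optional[str], reference_protein: str,
                 min_len_frac: float = 0.95,
                 copy_cds: Optional[str] = None,
                 reference_cds: Optional[str] = None) -> bool:
    """Is a copy's transposase intact relative to the reference?

    Requires an ORF of at least ``min_len_frac`` of the reference
    length with no internal stop codon; when both coding sequences are
    supplied, their alignment must additionally contain no internal gap
    of length not divisible by three (frameshift test).
    """
    if not reference_protein:
        raise ValueError("reference protein must be non-empty")
    if not copy_protein:
        return False
    if "*" in copy_protein[:-1]:
        return False
    if len(copy_protein.rstrip("*")) < min_len_frac * \
            len(reference_protein.rstrip("*")):
        return False
    if copy_cds and reference_cds:
        aligner = _nt_aligner()
        aln = aligner.align(reference_cds.upper(), copy_cds.upper())[0]
        if _internal_gap_frameshift(str(aln[0]), str(aln[1]),
                                    (0, len(reference_cds))):
            return False
    return True


def annotate_copies(
    loci: Union[Dict[str, str], Sequence[Tuple[str, str]]],
    consensus: str,
    reference_protein: str,
    consensus_orf: Optional[Tuple[int, int]] = None,
    min_identity: float = 0.95,
    min_coverage: float = 0.95,
    min_len_frac: float = 0.95,
) -> List[TECopy]:
    """Annotate copies: identity, coverage, full-length and intact flags.

    A copy is intact only if it is full-length, its longest ORF passes
    :func:`check_intact` against the reference transposase, and its
    alignment to the consensus shows no frameshifting gap inside the
    consensus ORF interval.
    """
    items = list(loci.items()) if isinstance(loci, dict) \
        else [(i, s) for i, s in loci]
    min_codons = max(10, int(0.5 * len(reference_protein)))
    out: List[TECopy] = []
    for cid, seq in items:
        identity, coverage, crow, qrow = _copy_vs_consensus(seq, consensus)
        full = identity > min_identity and coverage >= min_coverage
        intact = False
        orf: Optional[OrfResult] = None
        if full:
            try:
                orf = find_orf(seq, min_codons=min_codons)
            except ValueError:
                orf = None
            prot = orf.protein if orf else None
            intact = check_intact(prot, reference_protein,
                                  min_len_frac=min_len_frac)
            if intact and consensus_orf is not None:
                if _internal_gap_frameshift(crow, qrow, consensus_orf):
                    intact = False
        out.append(TECopy(cid, identity, coverage, full, intact, orf))
    return out


def family_counts(copies: Sequence[TECopy]) -> Dict[str, int]:
    """Copy-set summary; intact <= full_length <= total by construction."""
    total = len(copies)
    full = sum(c.full_length for c in copies)
    intact = sum(c.intact_orf for c in copies)
    assert intact <= full <= total
    return {"copies": total, "full_length": full, "intact": intact}
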
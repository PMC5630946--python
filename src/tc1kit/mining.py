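"""Candidate-locus discovery by translated homology search and copy counting.

The discovery route mirrors the classic repeat-annotation workflow: a
transposase protein query is compared against all six reading frames of
a genome (seed-and-extend local alignment, BLOSUM62, affine gaps), the
resulting hits are extracted with flanking sequence, and — once a family
consensus exists — the genome is re-scanned at the nucleotide level to
count copies under length and identity filters (hits longer than
``min_length`` at ``min_identity`` or better, overlapping hits merged so
a fragmented copy is counted once).

All coordinates are 0-based half-open on the forward strand, with a
strand flag for minus-strand features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple, Union

import edlib
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from numpy.lib.stride_tricks import sliding_window_view

from .structure import reverse_complement

_FRAME_ORDER = ("+0", "+1", "+2", "-0", "-1", "-2")


def _as_contigs(genome: Union[str, Dict[str, str]]) -> Dict[str, str]:
    return {"chr1": genome} if isinstance(genome, str) else dict(genome)


# ---------------------------------------------------------------------------
# six-frame translation
# ---------------------------------------------------------------------------

def six_frame_translate(seq: str) -> Tuple[str, str, str, str, str, str]:
    """Translate all six reading frames of a DNA sequence.

    Frames are returned in the order +0, +1, +2, -0, -1, -2, where -f is
    frame f of the reverse complement.  Codons containing N translate to
    ``X``; stop codons are rendered ``*``.  An empty input yields six
    empty strings.
    """
    seq = seq.upper()
    rc = reverse_complement(seq) if seq else ""
    frames = []
    for s in (seq, rc):
        for f in range(3):
            sub = s[f:]
            sub = sub[:len(sub) - len(sub) % 3]
            frames.append(str(Seq(sub).translate()))
    return tuple(frames)


# ---------------------------------------------------------------------------
# translated seed-and-extend search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchHit:
    """One translated-search hit, in forward nucleotide coordinates."""

    contig: str
    start: int
    end: int
    strand: str
    frame: int
    score: float
    protein_identity: float

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("hit end must exceed start")


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "local"
    return aligner


def _aa_kmer_codes(protein: str, k: int) -> np.ndarray:
    arr = np.frombuffer(protein.encode("ascii"), dtype=np.uint8)
    if len(arr) < k:
        return np.empty(0, dtype=np.int64)
    codes = (arr - 60).clip(0, 31).astype(np.int64)
    win = sliding_window_view(codes, k)
    weights = 32 ** np.arange(k - 1, -1, -1)
    return win @ weights


def _alignment_identity(aln) -> float:
    """Fraction of identical residues over aligned (non-gap) columns."""
    t, q = aln[0], aln[1]
    matches = cols = 0
    for a, b in zip(t, q):
        if a == "-" or b == "-":
            continue
        cols += 1
        if a == b:
            matches += 1
    return matches / cols if cols else 0.0


def translated_search(
    query: str,
    genome: Union[str, Dict[str, str]],
    min_score: float = 60.0,
    word_size: int = 3,
    *,
    cluster_gap: int = 100,
    diag_band: int = 20,
    min_seeds: int = 3,
) -> List[SearchHit]:
    """Search a protein query against all six frames of a genome.

    Exact ``word_size``-mer seed matches are clustered along diagonals;
    clusters with at least ``min_seeds`` distinct seed positions are
    aligned to the query (local, BLOSUM62, affine gaps) and hits scoring
    at least ``min_score`` are reported in forward nucleotide
    coordinates.  Overlapping same-frame hits are
    merged (best score kept) and the result is sorted by score.
    """
    query = query.upper().replace("*", "")
    if len(query) < word_size:
        raise ValueError("query shorter than word_size")
    contigs = _as_contigs(genome)
    aligner = _protein_aligner()
    qcodes = _aa_kmer_codes(query, word_size)
    qmap: Dict[int, List[int]] = {}
    for i, c in enumerate(qcodes):
        qmap.setdefault(int(c), []).append(i)
    qset = np.array(sorted(qmap), dtype=np.int64)

    hits: List[SearchHit] = []
    for cname, cseq in contigs.items():
        cseq = cseq.upper()
        L = len(cseq)
        frames = six_frame_translate(cseq)
        for fi, prot in enumerate(frames):
            strand = "+" if fi < 3 else "-"
            f = fi % 3
            pcodes = _aa_kmer_codes(prot, word_size)
            if len(pcodes) == 0:
                continue
            present = np.isin(pcodes, qset)
            ppos = np.where(present)[0]
            if len(ppos) == 0:
                continue
            matches = [(int(p), q) for p in ppos
                       for q in qmap[int(pcodes[p])]]
            matches.sort()
            clusters: List[List[Tuple[int, int]]] = []
            for p, q in matches:
                placed = False
                if clusters:
                    last = clusters[-1]
                    p0, q0 = last[-1]
                    if p - p0 <= cluster_gap and \
                            abs((p - q) - (last[0][0] - last[0][1])) \
                            <= diag_band:
                        last.append((p, q))
                        placed = True
                if not placed:
                    clusters.append([(p, q)])
            for cl in clusters:
                if len({p for p, _ in cl}) < min_seeds:
                    continue  # isolated seeds are never extended
                pmin = min(p for p, _ in cl)
                pmax = max(p for p, _ in cl)
                qmin = min(q for _, q in cl)
                qmax = max(q for _, q in cl)
                ws = max(0, pmin - qmin - 10)
                we = min(len(prot), pmax + (len(query) - qmax) + 10)
                window = prot[ws:we]
                if not window:
                    continue
                alns = aligner.align(window, query)
                if len(alns) == 0:
                    continue
                aln = alns[0]
                if aln.score < min_score:
                    continue
                (tstart, tend) = (aln.aligned[0][0][0], aln.aligned[0][-1][1])
                pstart, pend = ws + tstart, ws + tend
                nt_lo = f + 3 * pstart
                nt_hi = f + 3 * pend
                if strand == "+":
                    start, end = nt_lo, nt_hi
                else:
                    start, end = L - nt_hi, L - nt_lo
                hits.append(SearchHit(
                    contig=cname, start=start, end=end, strand=strand,
                    frame=f, score=float(aln.score),
                    protein_identity=_alignment_identity(aln)))
    hits = _dedupe_hits(hits)
    hits.sort(key=lambda h: (-h.score, h.contig, h.start))
    return hits


def _dedupe_hits(hits: List[SearchHit]) -> List[SearchHit]:
    """Merge overlapping hits on the same contig/strand/frame."""
    out: List[SearchHit] = []
    bykey: Dict[Tuple[str, str, int], List[SearchHit]] = {}
    for h in hits:
        bykey.setdefault((h.contig, h.strand, h.frame), []).append(h)
    for key, group in sorted(bykey.items()):
        group.sort(key=lambda h: h.start)
        cur = group[0]
        for h in group[1:]:
            if h.start < cur.end:  # overlap
                best = max((cur, h), key=lambda x: x.score)
                cur = SearchHit(cur.contig, min(cur.start, h.start),
                                max(cur.end, h.end), cur.strand, cur.frame,
                                best.score, best.protein_identity)
            else:
                out.append(cur)
                cur = h
        out.append(cur)
    return out


# ---------------------------------------------------------------------------
# locus extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CandidateLocus:
    """A candidate TE locus: merged hit core plus flanking sequence."""

    contig: str
    start: int
    end: int
    strand: str
    core_start: int
    core_end: int
    sequence: str

    @property
    def name(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}({self.strand})"


def extract_loci(
    hits: Sequence[SearchHit],
    genome: Union[str, Dict[str, str]],
    flank: int = 1000,
    merge_gap: int = 200,
) -> List[CandidateLocus]:
    """Extract hit loci with flanks, merging nearby same-strand hits.

    Hits on the same contig and strand whose gap is at most
    ``merge_gap`` become one locus; flanks are clipped at contig edges;
    minus-strand loci carry the reverse-complemented sequence (their
    coordinates remain forward-strand).
    """
    contigs = _as_contigs(genome)
    for h in hits:
        if h.contig not in contigs or h.end > len(contigs[h.contig]):
            raise ValueError(f"hit out of bounds: {h}")
    loci: List[CandidateLocus] = []
    bykey: Dict[Tuple[str, str], List[SearchHit]] = {}
    for h in hits:
        bykey.setdefault((h.contig, h.strand), []).append(h)
    for (cname, strand), group in sorted(bykey.items()):
        group.sort(key=lambda h: h.start)
        merged: List[Tuple[int, int]] = []
        cs, ce = group[0].start, group[0].end
        for h in group[1:]:
            if h.start - ce <= merge_gap:
                ce = max(ce, h.end)
            else:
                merged.append((cs, ce))
                cs, ce = h.start, h.end
        merged.append((cs, ce))
        L = len(contigs[cname])
        for cs, ce in merged:
            s = max(0, cs - flank)
            e = min(L, ce + flank)
            seq = contigs[cname][s:e]
            if strand == "-":
                seq = reverse_complement(seq)
            loci.append(CandidateLocus(cname, s, e, strand, cs, ce, seq))
    loci.sort(key=lambda x: (x.contig, x.start))
    return loci


# ---------------------------------------------------------------------------
# nucleotide copy counting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CopyInterval:
    contig: str
    start: int
    end: int
    strand: str
    identity: float

    @property
    def length(self) -> int:
        return self.end - self.start


def _nt_codes(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 4, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        codes[arr == ord(b)] = i
    return codes


def _nt_kmer_codes(seq: str, k: int) -> np.ndarray:
    """Base-4 k-mer codes; windows containing non-ACGT get code -1."""
    codes = _nt_codes(seq)
    if len(codes) < k:
        return np.empty(0, dtype=np.int64)
    win = sliding_window_view(codes.astype(np.int64), k)
    weights = 4 ** np.arange(k - 1, -1, -1)
    vals = win @ weights
    vals[(win >= 4).any(axis=1)] = -1
    return vals


def _trim_alignment(qrow: str, trow: str) -> Tuple[int, int, int, int, int]:
    """Best-scoring alignment segment (match +1, mismatch/gap -2).

    Returns (matches, mismatches, target_consumed, t_off_start, t_off_end)
    for the maximal segment, where t_off_* count target bases consumed
    before the segment start / through the segment end.
    """
    n = len(qrow)
    best = cur = 0
    best_range = (0, 0)
    cur_start = 0
    for i in range(n):
        sc = 1 if (qrow[i] == trow[i] and qrow[i] != "-") else -2
        if cur <= 0:
            cur = sc
            cur_start = i
        else:
            cur += sc
        if cur > best:
            best = cur
            best_range = (cur_start, i + 1)
    s, e = best_range
    matches = mismatches = 0
    for i in range(s, e):
        if qrow[i] == "-" or trow[i] == "-":
            continue
        if qrow[i] == trow[i]:
            matches += 1
        else:
            mismatches += 1
    t_before = sum(1 for i in range(s) if trow[i] != "-")
    t_len = sum(1 for i in range(s, e) if trow[i] != "-")
    return matches, mismatches, t_len, t_before, t_before + t_len


def count_copies(
    genome: Union[str, Dict[str, str]],
    consensus: str,
    min_length: int = 100,
    min_identity: float = 0.80,
    *,
    k: int = 12,
    merge_gap: int = 100,
    margin: int = 50,
    cluster_gap: int = 400,
    diag_band: int = 60,
) -> Tuple[int, List[CopyInterval]]:
    """Count genomic copies of a consensus under length/identity filters.

    Both strands are scanned by exact ``k``-mer seeding; each seed
    cluster is aligned (edit-distance alignment, ends trimmed to the
    best-scoring segment) and kept when its genomic span is strictly
    longer than ``min_length`` with identity — matches over aligned
    non-gap columns — of at least ``min_identity``.  Overlapping or
    near-adjacent retained spans are merged into one interval per copy
    before counting.
    """
    consensus = consensus.upper()
    if len(consensus) < min_length:
        raise ValueError("consensus shorter than min_length")
    contigs = _as_contigs(genome)
    raw: List[CopyInterval] = []
    variants = {"+": consensus, "-": reverse_complement(consensus)}
    for cname, cseq in contigs.items():
        cseq = cseq.upper()
        gcodes = _nt_kmer_codes(cseq, k)
        if len(gcodes) == 0:
            continue
        for strand, cons in variants.items():
            ccodes = _nt_kmer_codes(cons, k)
            cmap: Dict[int, int] = {}
            for i in range(len(ccodes) - 1, -1, -1):
                if ccodes[i] >= 0:
                    cmap[int(ccodes[i])] = i
            cset = np.array(sorted(cmap), dtype=np.int64)
            gpos = np.where(np.isin(gcodes, cset))[0]
            if len(gpos) == 0:
                continue
            cpos = np.array([cmap[int(gcodes[p])] for p in gpos])
            raw.extend(_cluster_and_score(
                cseq, cons, cname, strand, gpos, cpos, k,
                min_length, min_identity, margin, cluster_gap, diag_band))
    merged = _merge_intervals(raw, merge_gap)
    return len(merged), merged


def _cluster_and_score(cseq, cons, cname, strand, gpos, cpos, k,
                       min_length, min_identity, margin,
                       cluster_gap, diag_band) -> List[CopyInterval]:
    out = []
    cl_start = 0
    order = np.argsort(gpos, kind="stable")
    gpos, cpos = gpos[order], cpos[order]
    n = len(gpos)
    i = 0
    while i < n:
        j = i + 1
        diag0 = gpos[i] - cpos[i]
        gmax = gpos[i]
        while j < n and gpos[j] - gmax <= cluster_gap and \
                abs((gpos[j] - cpos[j]) - diag0) <= diag_band:
            gmax = max(gmax, gpos[j])
            j += 1
        g_lo, g_hi = int(gpos[i]), int(gmax) + k
        c_lo = int(cpos[i:j].min())
        c_hi = int(cpos[i:j].max()) + k
        q = cons[max(0, c_lo - margin):min(len(cons), c_hi + margin)]
        t_lo = max(0, g_lo - 2 * margin)
        t_hi = min(len(cseq), g_hi + 2 * margin)
        t = cseq[t_lo:t_hi]
        res = edlib.align(q, t, mode="HW", task="path")
        if res["editDistance"] < 0 or not res["locations"]:
            i = j
            continue
        loc = res["locations"][0]
        nice = edlib.getNiceAlignment(res, q, t)
        matches, mism, t_len, t_b, t_e = _trim_alignment(
            nice["query_aligned"], nice["target_aligned"])
        cols = matches + mism
        ident = matches / cols if cols else 0.0
        start = t_lo + loc[0] + t_b
        end = t_lo + loc[0] + t_e
        if t_len > min_length and ident >= min_identity:
            out.append(CopyInterval(cname, start, end, strand, ident))
        i = j
    del cl_start
    return out


def _merge_intervals(intervals: List[CopyInterval],
                     merge_gap: int) -> List[CopyInterval]:
    """Merge overlapping/nearby intervals per contig (strand-agnostic)."""
    out: List[CopyInterval] = []
    bycontig: Dict[str, List[CopyInterval]] = {}
    for iv in intervals:
        bycontig.setdefault(iv.contig, []).append(iv)
    for cname in sorted(bycontig):
        group = sorted(bycontig[cname], key=lambda x: (x.start, x.end))
        cur = group[0]
        for iv in group[1:]:
            if iv.start - cur.end < merge_gap:
                best = max((cur, iv), key=lambda x: x.identity)
                cur = CopyInterval(cname, min(cur.start, iv.start),
                                   max(cur.end, iv.end), best.strand,
                                   best.identity)
            else:
                out.append(cur)
                cur = iv
        out.append(cur)
    return out
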
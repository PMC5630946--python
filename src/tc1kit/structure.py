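"""Structural annotation of Tc1/mariner elements.

Tc1/mariner DNA transposons are delimited by terminal inverted repeats
(TIRs): the first bases of the element are the reverse complement of its
last bases.  Many families additionally carry a subterminal inverted
repeat (SIR) pair just inside the TIRs, and insertion into a TA target
site duplicates that dinucleotide on both flanks (the TSD).  This module
detects all three features on a single element sequence.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from Bio.Seq import Seq

_IUPAC = set("ACGTRYSWKMBDHVN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes allowed).

    Raises
    ------
    ValueError
        If the sequence contains a character outside the IUPAC DNA
        alphabet.
    """
    up = seq.upper()
    bad = set(up) - _IUPAC
    if bad:
        raise ValueError(f"invalid DNA character(s): {sorted(bad)}")
    return str(Seq(up).reverse_complement())


@dataclass(frozen=True)
class InvertedRepeatPair:
    """An inverted-repeat pair on element coordinates.

    ``left`` aligns to the reverse complement of ``right`` with the
    stated number of mismatches; ``left`` ends at or before ``right``
    starts.
    """

    left_start: int
    left_end: int
    right_start: int
    right_end: int
    mismatches: int

    def __post_init__(self):
        if self.left_end > self.right_start:
            raise ValueError("left arm must precede right arm")

    @property
    def length(self) -> int:
        return self.left_end - self.left_start

    @property
    def identity(self) -> float:
        return 1.0 - self.mismatches / self.length if self.length else 0.0


def _byte_arr(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def find_tir(
    element: str,
    max_len: int = 250,
    max_mismatch_frac: float = 0.1,
    min_len: int = 10,
    mismatch_penalty: float = 1.5,
) -> Optional[InvertedRepeatPair]:
    """Detect the terminal inverted repeat of an element.

    Both arms are anchored at the element termini (offset 0): the prefix
    of length L is compared base-by-base (Hamming, no gaps) with the
    reverse complement of the suffix of length L.  Among anchored
    candidates the arm length maximising ``matches - mismatch_penalty *
    mismatches`` is chosen; ties resolve toward fewer mismatches and
    then the shorter span.

    ``max_mismatch_frac`` caps the underlying per-pair mismatch *rate*:
    a candidate is accepted when its mismatch count does not exceed the
    cap plus a two-standard-deviation binomial allowance (in diverged
    copies both arms mutate, so the realised count fluctuates around
    the cap; a hard cutoff on the count would reject half of genuinely
    decayed-but-real TIRs right at the boundary).  ``None`` is returned
    when no candidate of at least ``min_len`` passes.
    """
    n = len(element)
    if n < 2 * min_len:
        return None
    half = min(max_len, n // 2)
    pre = _byte_arr(element[:half])
    suf = _byte_arr(reverse_complement(element[n - half:]))
    mism = np.cumsum(pre != suf)
    lengths = np.arange(1, half + 1)
    scores = (lengths - mism) - mismatch_penalty * mism
    f = max_mismatch_frac
    budget = f * lengths + 2.0 * np.sqrt(lengths * f * (1 - f))
    acceptable = (lengths >= min_len) & (mism <= budget) & (scores > 0)
    if not acceptable.any():
        return None
    cand = np.where(acceptable)[0]
    best = cand[int(np.argmax(scores[cand]))]
    L = int(lengths[best])
    mm = int(mism[best])
    return InvertedRepeatPair(0, L, n - L, n, mm)


def find_sir(
    element: str,
    tir: Optional[InvertedRepeatPair] = None,
    window: int = 300,
    min_len: int = 12,
) -> Optional[InvertedRepeatPair]:
    """Detect the best subterminal inverted-repeat pair.

    The search is restricted to two windows strictly inside the TIRs
    (or, when ``tir`` is None, anchored at the element termini): the
    longest exact substring of the left window whose reverse complement
    occurs in the right window is reported.  Pairs shorter than
    ``min_len`` yield ``None``.  Ties resolve to the leftmost left arm,
    then the leftmost right arm.
    """
    n = len(element)
    ls = tir.left_end if tir is not None else 0
    re_ = tir.right_start if tir is not None else n
    lw_end = min(ls + window, re_)
    rw_start = max(re_ - window, lw_end)
    lw = element[ls:lw_end]
    rw = element[rw_start:re_]
    if not lw or not rw:
        return None
    a = _byte_arr(lw)
    b = _byte_arr(reverse_complement(rw))
    best_len, best_i, best_j = 0, -1, -1
    prev = np.zeros(len(b) + 1, dtype=np.int32)
    cur = np.zeros(len(b) + 1, dtype=np.int32)
    for i in range(1, len(a) + 1):
        cur[0] = 0
        np.add(prev[:-1], 1, out=cur[1:], where=(a[i - 1] == b))
        cur[1:][a[i - 1] != b] = 0
        m = int(cur.max())
        if m > best_len:
            best_len = m
            j = int(np.argmax(cur))
            best_i, best_j = i, j
        prev, cur = cur, prev
    if best_len < min_len:
        return None
    # left arm on element
    l_start = ls + best_i - best_len
    l_end = ls + best_i
    # best_j is the end (1-based) in revcomp(rw); map back to rw coords
    rc_start = best_j - best_len
    r_start = rw_start + (len(rw) - best_j)
    r_end = r_start + best_len
    del rc_start
    if l_end > r_start:
        return None
    return InvertedRepeatPair(l_start, l_end, r_start, r_end, 0)


@dataclass(frozen=True)
class TsdCheck:
    """Per-side TSD evidence; ``None`` means the flank was unavailable."""

    left: Optional[bool]
    right: Optional[bool]

    @property
    def overall(self) -> bool:
        return bool(self.left) and bool(self.right)


def check_tsd(sequence: str, element_start: int, element_end: int,
              tsd: str = "TA") -> TsdCheck:
    """Check for a duplicated target site flanking an element interval.

    ``sequence`` is the locus (element plus flanks); the |tsd| bases
    immediately 5' and 3' of ``[element_start, element_end)`` are each
    compared with ``tsd``.  A flank shorter than the TSD reports
    ``None`` for that side and the overall verdict is False.
    """
    k = len(tsd)
    tsd = tsd.upper()
    seq = sequence.upper()
    left = None
    if element_start >= k:
        left = seq[element_start - k:element_start] == tsd
    right = None
    if len(seq) - element_end >= k:
        right = seq[element_end:element_end + k] == tsd
    return TsdCheck(left, right)
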
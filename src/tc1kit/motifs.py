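"""DDE/D catalytic-triad location and Tc1/mariner family assignment.

The transposase of a Tc1/mariner element carries a catalytic triad of
two aspartates plus a glutamate or aspartate (DDE/D).  The number of
residues strictly between the second D and the terminal acidic residue
(e.g. DD34E, DD37E, DD37D) together with three short conserved motif
blocks in the catalytic domain separates the families: mariner
(TXDE / HDNA / SPDLAP(S|T|I)DY), Tc1 ((W|F)(S|T)DE / QDND / SPDLNPIE),
the TRT subfamily of Tc1 ((W|F)TDE / (Q|H)DNA / SP(D|H)LNPIE, DD37E) and
ITmD37E (MDDE / PDLA / (V|C)PQ(A|F)RPIE, DD37E-spaced but with its own
blocks).

Pattern syntax: one token per residue; alternatives in brackets
(``[WF]``), ``X`` matches any residue.  Anchor residues (the D of block
1 and 2, the final acidic residue of block 3) are derived from the
pattern itself.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

# default spacing window scanned by the degenerate fallback
FALLBACK_SPACING = (20, 60)


def _tokenize(pattern: str) -> List[str]:
    tokens = []
    i = 0
    while i < len(pattern):
        c = pattern[i]
        if c == "[":
            j = pattern.index("]", i)
            tokens.append(pattern[i + 1:j])
            i = j + 1
        else:
            tokens.append(c)
            i += 1
    return tokens


@dataclass(frozen=True)
class MotifBlock:
    """One conserved block: a degenerate pattern plus its anchor index."""

    pattern: str
    anchor: int
    regex: re.Pattern = field(repr=False, compare=False, default=None)

    @staticmethod
    def compile(pattern: str, slot: int) -> "MotifBlock":
        tokens = _tokenize(pattern)
        if slot == 0:  # first block anchors on its last D (the D of ..DE)
            anchors = [i for i, t in enumerate(tokens) if t == "D"]
            if not anchors:
                raise ValueError(f"block {pattern!r} has no D anchor")
            anchor = anchors[-1]
        elif slot == 1:  # second block anchors on its first D
            anchors = [i for i, t in enumerate(tokens) if t == "D"]
            if not anchors:
                raise ValueError(f"block {pattern!r} has no D anchor")
            anchor = anchors[0]
        else:  # third block anchors on its last single acidic residue
            anchors = [i for i, t in enumerate(tokens) if t in ("D", "E")]
            if not anchors:
                raise ValueError(f"block {pattern!r} has no acidic anchor")
            anchor = anchors[-1]
        rx = re.compile(
            "".join("." if t == "X" else (t if len(t) == 1 else f"[{t}]")
                    for t in tokens))
        return MotifBlock(pattern, anchor, rx)

    @property
    def anchor_residues(self) -> str:
        return _tokenize(self.pattern)[self.anchor]

    def matches(self, protein: str) -> List[int]:
        """Start positions of all (non-overlapping) matches."""
        return [m.start() for m in self.regex.finditer(protein)]


MotifBlockTable = Dict[str, Tuple[MotifBlock, MotifBlock, MotifBlock]]

_DEFAULT_PATTERNS: Dict[str, Tuple[str, str, str]] = {
    "mariner": ("TXDE", "HDNA", "SPDLAP[STI]DY"),
    "Tc1": ("[WF][ST]DE", "QDND", "SPDLNPIE"),
    "TRT": ("[WF]TDE", "[QH]DNA", "SP[DH]LNPIE"),
    "ITmD37E": ("MDDE", "PDLA", "[VC]PQ[AF]RPIE"),
}

# alternate reading of the typographically ambiguous ITmD37E block 3
ITMD37E_BLOCK3_ALT = "[VC]PQA[FR]PIE"


def build_block_table(
    patterns: Optional[Dict[str, Tuple[str, str, str]]] = None,
) -> MotifBlockTable:
    pats = patterns or _DEFAULT_PATTERNS
    return {
        fam: tuple(MotifBlock.compile(p, slot) for slot, p in enumerate(trio))
        for fam, trio in pats.items()
    }


DEFAULT_BLOCK_TABLE = build_block_table()


def load_block_table(path) -> MotifBlockTable:
    """Read a block table from a tab-separated text file.

    Each non-comment line: ``family<TAB>block1<TAB>block2<TAB>block3``.
    """
    pats: Dict[str, Tuple[str, str, str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"line {ln}: expected 4 tab-separated fields")
            pats[parts[0]] = (parts[1], parts[2], parts[3])
    return build_block_table(pats)


def write_block_table(table_or_patterns, path) -> None:
    with open(path, "w") as fh:
        fh.write("# family\tblock1\tblock2\tblock3\n")
        for fam, trio in table_or_patterns.items():
            pats = [b.pattern if isinstance(b, MotifBlock) else b
                    for b in trio]
            fh.write(fam + "\t" + "\t".join(pats) + "\n")


@dataclass(frozen=True)
class CatalyticTriad:
    """Positions (0-based residue indices) of the DDE/D triad."""

    d1_pos: int
    d2_pos: int
    e_pos: int
    acidic3: str
    matched_blocks: Tuple[Tuple[str, int], ...] = ()

    def __post_init__(self):
        if not (self.d1_pos < self.d2_pos < self.e_pos):
            raise ValueError("triad positions must satisfy d1 < d2 < e")

    @property
    def spacing(self) -> int:
        return self.e_pos - self.d2_pos - 1


def spacing_label(triad: CatalyticTriad) -> str:
    """Signature label such as ``DD37E`` or ``DD34D``."""
    return f"DD{triad.spacing}{triad.acidic3}"


def _exact_triad(protein: str, blocks, family: str) -> Optional[CatalyticTriad]:
    b1, b2, b3 = blocks
    m1 = [s + b1.anchor for s in b1.matches(protein)]
    m2 = [s + b2.anchor for s in b2.matches(protein)]
    m3 = [s + b3.anchor for s in b3.matches(protein)]
    if not (m1 and m2 and m3):
        return None
    for d2 in m2:
        ups = [d1 for d1 in m1 if d1 < d2]
        downs = [e for e in m3 if e > d2]
        if ups and downs:
            d1 = ups[-1]
            e = downs[0]
            return CatalyticTriad(
                d1, d2, e, protein[e],
                ((b1.pattern, d1 - b1.anchor),
                 (b2.pattern, d2 - b2.anchor),
                 (b3.pattern, e - b3.anchor)))
    return None


def _block_scores(protein: str, table: MotifBlockTable) -> Dict[str, int]:
    return {
        fam: sum(1 for b in blocks if b.matches(protein))
        for fam, blocks in table.items()
    }


def _fallback_triad(protein: str, table: MotifBlockTable,
                    spacing_range=FALLBACK_SPACING) -> Optional[CatalyticTriad]:
    """Degenerate D..D..E/D enumeration scored by local block conservation.

    Every (D2, E/D3) pair with spacing inside ``spacing_range`` and some
    upstream D is scored by how many block patterns match within one
    mismatch at the implied anchor positions; the best-scoring candidate
    (ties: smallest d2, then smallest e) is returned.
    """
    ds = [i for i, c in enumerate(protein) if c == "D"]
    if len(ds) < 2:
        return None
    acid = [i for i, c in enumerate(protein) if c in "DE"]
    lo, hi = spacing_range
    best = None
    best_score = -1
    for d2 in ds:
        ups = [d for d in ds if d < d2]
        if not ups:
            continue
        for e in acid:
            sp = e - d2 - 1
            if sp < lo or sp > hi:
                continue
            score = 0
            for blocks in table.values():
                b2, b3 = blocks[1], blocks[2]
                if _near_match(protein, b2, d2 - b2.anchor):
                    score += 1
                if _near_match(protein, b3, e - b3.anchor):
                    score += 1
            if score > best_score:
                best_score = score
                best = CatalyticTriad(ups[-1], d2, e, protein[e])
    if best is None or best_score < 1:
        return None
    return best


def _near_match(protein: str, block: MotifBlock, start: int,
                max_mismatch: int = 1) -> bool:
    tokens = _tokenize(block.pattern)
    if start < 0 or start + len(tokens) > len(protein):
        return False
    mm = 0
    for i, t in enumerate(tokens):
        if t == "X":
            continue
        if protein[start + i] not in t:
            mm += 1
            if mm > max_mismatch:
                return False
    return True


def locate_triad(protein: str,
                 block_table: Optional[MotifBlockTable] = None,
                 ) -> Optional[CatalyticTriad]:
    """Locate the DDE/D triad via exact block matches, then fallback.

    Families are tried in table order; the first family whose three
    blocks all match with consistent anchor order (d1 < d2 < e) defines
    the triad.  When no family matches exactly, a degenerate
    enumeration of D..D..E/D candidates scored by near-miss block
    conservation is used.  Returns ``None`` if no consistent triad is
    found.
    """
    table = block_table or DEFAULT_BLOCK_TABLE
    protein = protein.upper()
    best = None
    best_nblocks = -1
    for fam, blocks in table.items():
        tri = _exact_triad(protein, blocks, fam)
        if tri is not None and len(tri.matched_blocks) > best_nblocks:
            best = tri
            best_nblocks = len(tri.matched_blocks)
    if best is not None:
        return best
    return _fallback_triad(protein, table)


def assign_family(protein: str,
                  block_table: Optional[MotifBlockTable] = None,
                  ) -> Tuple[str, Dict[str, int]]:
    """Assign a Tc1/mariner family from block evidence plus spacing.

    The family with the most exactly-matching blocks wins; ties are
    ``"ambiguous"`` and zero matches ``"unclassified"``.  TRT
    additionally requires a DD37E signature (demoted to its parent Tc1
    family otherwise); ITmD37E requires spacing 37.
    """
    table = block_table or DEFAULT_BLOCK_TABLE
    protein = protein.upper()
    scores = _block_scores(protein, table)
    top = max(scores.values(), default=0)
    if top == 0:
        return "unclassified", scores
    winners = [f for f, s in scores.items() if s == top]
    if len(winners) > 1:
        return "ambiguous", scores
    fam = winners[0]
    triad = locate_triad(protein, table)
    if fam == "TRT":
        if triad is None or triad.spacing != 37 or triad.acidic3 != "E":
            return "Tc1", scores
    if fam == "ITmD37E":
        if triad is None or triad.spacing != 37:
            return "unclassified", scores
    return fam, scores
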
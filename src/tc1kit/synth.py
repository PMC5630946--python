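"""Synthetic genomes with planted Tc1/mariner elements and ground truth.

Every downstream stage of the pipeline (mining, consensus building,
structural annotation, triad classification, horizontal-transfer
inference) is exercised on data produced here: a master element with
TIRs, a SIR pair, a TA target-site duplication and a transposase ORF
carrying a chosen DDE/D spacing; diverged copies planted into random
host genomes; a marker gene evolving along a dated species tree; and
horizontal-transfer events that copy a young element between distant
lineages.  A machine-readable truth table records everything planted.

Two generator conventions matter for exact truth recovery and are
deliberate design choices rather than biology:

* Masters are *maximal by construction*: an 8-bp anti-complementary
  guard follows each TIR and flanks each SIR, so repeat detectors
  report exactly the planted lengths on an undiverged element.
* Copies that are not explicitly inactivated evolve under purifying
  selection on the ORF: substitutions creating an in-frame stop, or
  hitting the start or terminal stop codon, are reverted.  Active
  copies in real genomes are exactly the selectively constrained ones.

Substitutions follow a Kimura two-parameter process (transition /
transversion ratio ``kappa``, default 2.0), matching the K2P distance
used downstream.  Indels are not simulated except for explicit
truncations and the 1-bp frameshift lesion.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import dendropy
import numpy as np
from Bio.Seq import Seq

from . import motifs
from .structure import reverse_complement

_BASES = "ACGT"
_B2I = {c: i for i, c in enumerate(_BASES)}
_AA = "ACDEFGHIKLMNPQRSTVWY"
_GUARD = 8  # anti-complementary guard width around TIRs/SIRs

# codons per residue (standard table), deterministic order
_CODONS: Dict[str, List[str]] = {}
for _c in ("".join((a, b, c)) for a in _BASES for b in _BASES for c in _BASES):
    _aa = str(Seq(_c).translate())
    _CODONS.setdefault(_aa, []).append(_c)
_STOPS = frozenset(_CODONS.pop("*"))


class ParameterError(ValueError):
    """A generator parameter combination is unachievable."""


class PlacementError(RuntimeError):
    """Copies could not be placed without overlap within the retry budget."""


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


# ---------------------------------------------------------------------------
# master element
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MasterElement:
    """An intact, active-form transposon used as the planting template."""

    name: str
    sequence: str
    tir_length: int
    sir: Tuple[str, str]
    orf_interval: Tuple[int, int]
    dde_spacing: int
    tsd: str = "TA"
    family: str = "TRT"
    triad_positions: Optional[Tuple[int, int, int]] = None

    @property
    def protein(self) -> str:
        s, e = self.orf_interval
        return str(Seq(self.sequence[s:e]).translate())

    def validate(self) -> None:
        t = self.tir_length
        if self.sequence[:t] != reverse_complement(self.sequence[-t:]):
            raise ValueError("termini are not an exact inverted repeat")
        s, e = self.orf_interval
        if (e - s) % 3:
            raise ValueError("ORF interval length not a multiple of 3")
        prot = self.protein
        if "*" in prot:
            raise ValueError("ORF translation contains an internal stop")
        if self.triad_positions is not None:
            d1, d2, ep = self.triad_positions
            if prot[d1] != "D" or prot[d2] != "D" or prot[ep] not in "DE":
                raise ValueError("designed triad residues missing")
            if ep - d2 - 1 != self.dde_spacing:
                raise ValueError("catalytic triad spacing does not match")
        else:
            tri = motifs.locate_triad(prot)
            if tri is None or tri.spacing != self.dde_spacing:
                raise ValueError("catalytic triad spacing does not match")


def _design_protein(orf_codons: int, dde_spacing: int, family: str,
                    rng: np.random.Generator
                    ) -> Tuple[str, Tuple[int, int, int]]:
    """Random transposase with the family's blocks at the requested spacing."""
    prot = ["M"] + [_AA[i] for i in rng.integers(0, len(_AA),
                                                 size=orf_codons - 1)]
    blocks = motifs.DEFAULT_BLOCK_TABLE[family]
    intended: List[Tuple[int, int]] = []

    def _embed(text: str, start: int) -> None:
        prot[start:start + len(text)] = list(text)
        intended.append((start, start + len(text)))

    def _concrete(block: motifs.MotifBlock) -> str:
        toks = motifs._tokenize(block.pattern)
        return "".join(t[0] if t != "X" else "A" for t in toks)

    if dde_spacing >= 10:
        b1, b2, b3 = blocks
        t1, t2, t3 = (_concrete(b) for b in (b1, b2, b3))
        tail = min(15, orf_codons - dde_spacing - len(t3) - 10)
        e_pos = orf_codons - 1 - max(tail, 0)
        d2 = e_pos - dde_spacing - 1
        s2 = d2 - b2.anchor
        s3 = e_pos - b3.anchor
        s1 = max(1, s2 - len(t1) - 40)
        if s1 + len(t1) > s2 or s2 + len(t2) > s3:
            raise ParameterError(
                f"DDE spacing {dde_spacing} unachievable in {orf_codons} codons")
        _embed(t1, s1)
        _embed(t2, s2)
        _embed(t3, s3)
        triad = (s1 + b1.anchor, d2, e_pos)
    else:
        # degenerate spacing: bare D, D, E residues (no room for full blocks)
        e_pos = orf_codons - 5
        d2 = e_pos - dde_spacing - 1
        d1 = d2 - 2
        if d1 < 1:
            raise ParameterError(
                f"DDE spacing {dde_spacing} unachievable in {orf_codons} codons")
        for pos, res in ((d1, "D"), (d2, "D"), (e_pos, "E")):
            _embed(res, pos)
        triad = (d1, d2, e_pos)
        # keep the gap between D2 and E free of acidic residues so the
        # fallback scan reports the intended spacing
        for i in range(d2 + 1, e_pos):
            if prot[i] in "DE":
                prot[i] = "G"
        for i in range(max(1, d1 - 25), d2):
            if i not in (d1,) and prot[i] == "D":
                prot[i] = "G"

    # scrub accidental block matches outside the intended spans, so triad
    # location is unambiguous on every master regardless of background
    def _inside_intended(pos: int) -> bool:
        return any(a <= pos < bnd for a, bnd in intended)

    for _ in range(100):
        dirty = False
        text = "".join(prot)
        for blocks_ in motifs.DEFAULT_BLOCK_TABLE.values():
            for b in blocks_:
                for s in b.matches(text):
                    span_end = s + len(motifs._tokenize(b.pattern))
                    if any(s >= a and span_end <= bnd for a, bnd in intended):
                        continue  # this is a planted block
                    targets = [p for p in range(s, span_end)
                               if not _inside_intended(p) and p > 0]
                    if not targets:
                        continue
                    anchor_pos = s + b.anchor
                    hit = anchor_pos if anchor_pos in targets else targets[0]
                    prot[hit] = "G"
                    dirty = True
        if not dirty:
            break
    return "".join(prot), triad


def _back_translate(prot: str, rng: np.random.Generator) -> str:
    return "".join(
        _CODONS[aa][rng.integers(0, len(_CODONS[aa]))] for aa in prot)


def build_master_element(
    tir_length: int = 27,
    sir: Optional[Tuple[str, str]] = None,
    orf_codons: int = 338,
    dde_spacing: int = 37,
    seed: int = 0,
    *,
    length: int = 1563,
    family: str = "TRT",
    tsd: str = "TA",
    name: Optional[str] = None,
) -> MasterElement:
    """Build a master element satisfying all structural invariants.

    Defaults reproduce the geometry of an active vertebrate Tc1-like
    family: a 1,563-bp element with 27-bp TIRs, a 23-bp SIR pair, a
    338-codon transposase with a DD37E triad, and a TA target site.
    Deterministic given ``seed``.
    """
    if tir_length < 10:
        raise ParameterError("tir_length must be >= 10")
    if orf_codons < dde_spacing + 20:
        raise ParameterError("orf_codons must be >= dde_spacing + 20")
    rng = np.random.default_rng(seed)

    prot, triad = _design_protein(orf_codons, dde_spacing, family, rng)
    cds = _back_translate(prot, rng) + "TAA"

    if sir is None:
        s5 = _random_dna(rng, 23)
        sir = (s5, reverse_complement(s5))
    s5, s3 = sir

    # a short spacer between the 3' SIR and the 3' TIR keeps the two SIRs
    # off the TIR diagonal (symmetric placement would let the terminus-
    # anchored TIR scan extend through the guard into the SIR pair)
    shift = 5
    core = 2 * tir_length + 2 * _GUARD + len(s5) + len(s3) + shift + len(cds)
    free = length - core
    if free < 2:
        raise ParameterError(
            f"length {length} too small for the requested layout ({core} bp)")
    pad5_n = free // 2
    pad3_n = free - pad5_n

    tir = _random_dna(rng, tir_length)
    if tir[:len(tsd)] == tsd:
        # keep the element boundary identifiable: a TIR starting with the
        # TSD motif would make "element + TSD" indistinguishable from the
        # element itself (the TA target site is its own reverse complement)
        tir = "C" + tir[1:]
    g5 = _random_dna(rng, _GUARD)
    pad5 = _random_dna(rng, pad5_n)
    pad3 = _random_dna(rng, pad3_n)
    # guard opposite the 5' guard: ensure the 8 pairs just inside the TIRs
    # never complement, so the planted TIR length is maximal
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    g3 = []
    for i in range(_GUARD):
        banned = comp[g5[i]]
        choices = [b for b in _BASES if b != banned]
        g3.append(choices[rng.integers(0, 3)])
    # guard order: g3[i] sits at position L-1-tir_length-i, i.e. the guard
    # string reads reversed
    g3_str = "".join(reversed(g3))
    spacer = _random_dna(rng, shift)
    # the base right after the 3' SIR must not complement the base right
    # before the 5' SIR, or the SIR match would extend past the planted pair
    if spacer[0] == comp[g5[-1]]:
        choices = [b for b in _BASES if b != comp[g5[-1]]]
        spacer = choices[rng.integers(0, 3)] + spacer[1:]

    seq = list(tir + g5 + s5 + pad5 + cds + pad3 + s3 + spacer + g3_str +
               reverse_complement(tir))
    L = len(seq)
    # break SIR extension on the inner side: base after the 5' SIR must not
    # complement the base before the 3' SIR
    inner5 = tir_length + _GUARD + len(s5)        # first pad5 base
    inner3 = L - tir_length - _GUARD - shift - len(s3) - 1  # last pad3 base
    if seq[inner5] == comp[seq[inner3]]:
        choices = [b for b in _BASES if b != comp[seq[inner5]]]
        seq[inner3] = choices[rng.integers(0, 3)]

    orf_start = tir_length + _GUARD + len(s5) + pad5_n
    master = MasterElement(
        name=name or f"{family}-synth",
        sequence="".join(seq),
        tir_length=tir_length,
        sir=(s5, s3),
        orf_interval=(orf_start, orf_start + 3 * len(prot)),
        dde_spacing=dde_spacing,
        tsd=tsd,
        family=family,
        triad_positions=triad,
    )
    master.validate()
    return master


# ---------------------------------------------------------------------------
# substitution process
# ---------------------------------------------------------------------------

def mutate_sequence(seq: str, divergence: float, kappa: float = 2.0,
                    seed: Union[int, np.random.Generator] = 0) -> str:
    """Evolve a sequence under a Kimura two-parameter process.

    ``divergence`` is the expected number of substitutions per site
    (multiple hits included: per site the event count is Poisson with
    that mean, so the observed difference fraction follows the K2P
    saturation curve).  Transitions are favoured ``kappa``-fold over
    each transversion.  Length is preserved; non-ACGT characters are
    left untouched.
    """
    if not (0 <= divergence < 0.75):
        raise ParameterError("divergence must be in [0, 0.75)")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if divergence == 0 or not seq:
        return seq
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()
    codes = np.full(arr.shape, -1, dtype=np.int8)
    for b, i in _B2I.items():
        codes[arr == ord(b)] = i
    valid = codes >= 0
    hits = rng.poisson(divergence, size=arr.shape)
    hits[~valid] = 0
    p_ts = 1.0 if math.isinf(kappa) else kappa / (kappa + 2.0)
    for _ in range(int(hits.max())):
        active = hits > 0
        n = int(active.sum())
        if n == 0:
            break
        cur = codes[active]
        u = rng.random(n)
        pick = rng.random(n)
        # transition partner: A<->G, C<->T  ==  (code + 2) % 4
        ts = (cur + 2) % 4
        # the two transversion targets are the bases of the other class
        tv1 = np.where(cur % 2 == 0, 1, 0)   # A/G -> C ; C/T -> A
        tv2 = np.where(cur % 2 == 0, 3, 2)   # A/G -> T ; C/T -> G
        new = np.where(u < p_ts, ts, np.where(pick < 0.5, tv1, tv2))
        codes[active] = new.astype(np.int8)
        hits[active] -= 1
    out = arr.copy()
    lut = np.frombuffer("ACGT".encode("ascii"), dtype=np.uint8)
    out[valid] = lut[codes[valid]]
    return out.tobytes().decode("ascii")


def _repair_orf(mut: str, master: MasterElement) -> str:
    """Revert lesions that would inactivate the ORF (purifying selection)."""
    s, e = master.orf_interval
    seq = list(mut)
    ref = master.sequence
    seq[s:s + 3] = ref[s:s + 3]          # start codon
    seq[e:e + 3] = ref[e:e + 3]          # terminal stop codon
    for i in range(s, e, 3):
        if "".join(seq[i:i + 3]) in _STOPS:
            seq[i:i + 3] = ref[i:i + 3]
    return "".join(seq)


# ---------------------------------------------------------------------------
# truth table
# ---------------------------------------------------------------------------

@dataclass
class PlantedCopy:
    species: str
    contig: str
    start: int
    end: int
    strand: str
    divergence: float
    truncated: Optional[str]  # None, "5" or "3" (element coordinates)
    inactivated: bool

    @property
    def full_length(self) -> bool:
        return self.truncated is None


@dataclass
class HTEvent:
    donor: str
    recipient: str
    time_ma: float
    family: str = "TRT-synth"


@dataclass
class TruthTable:
    """Machine-readable record of everything the generator planted."""

    planted_copies: List[PlantedCopy] = field(default_factory=list)
    ht_events: List[HTEvent] = field(default_factory=list)
    seed: int = 0

    def to_json(self, path=None) -> str:
        payload = {
            "seed": self.seed,
            "planted_copies": [dataclasses.asdict(c)
                               for c in self.planted_copies],
            "ht_events": [dataclasses.asdict(e) for e in self.ht_events],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @staticmethod
    def from_json(text: str) -> "TruthTable":
        d = json.loads(text)
        return TruthTable(
            planted_copies=[PlantedCopy(**c) for c in d["planted_copies"]],
            ht_events=[HTEvent(**e) for e in d["ht_events"]],
            seed=d["seed"],
        )


# ---------------------------------------------------------------------------
# planting copies
# ---------------------------------------------------------------------------

def _as_contigs(genome: Union[str, Dict[str, str]]) -> Dict[str, str]:
    return {"chr1": genome} if isinstance(genome, str) else dict(genome)


def plant_copies(
    genome: Union[str, Dict[str, str]],
    master: MasterElement,
    n: int,
    divergence: float = 0.05,
    truncate_frac: float = 0.5,
    inactivate_frac: float = 0.25,
    seed: int = 0,
    *,
    kappa: float = 2.0,
    min_spacing: int = 1000,
    species: str = "synthetic",
) -> Tuple[Union[str, Dict[str, str]], TruthTable]:
    """Insert ``n`` diverged copies of ``master`` at TA target sites.

    Exactly ``round(n * truncate_frac)`` copies are truncated (uniform
    cut retaining 10-90 % of the element, end by fair coin, the TSD on
    the truncated side consumed) and ``round(n * inactivate_frac)``
    non-truncated copies receive an ORF lesion (an internal codon
    replaced by TAA, or a 1-bp deletion, equal probability).  All other
    copies keep an intact ORF by construction.  Insertion sites are
    uniform over TA dinucleotides, thinned to ``min_spacing`` so
    distinct copies never merge into one locus.  Each untruncated
    insertion is flanked by the duplicated TA on both sides.
    """
    single = isinstance(genome, str)
    contigs = _as_contigs(genome)
    truth = TruthTable(seed=seed)
    if n == 0:
        return genome, truth
    rng = np.random.default_rng(seed)

    n_trunc = int(round(n * truncate_frac))
    n_inact = int(round(n * inactivate_frac))
    if n_trunc + n_inact > n:
        raise ParameterError(
            "truncate_frac + inactivate_frac exceed the copy budget")
    order = rng.permutation(n)
    truncated_ids = set(order[:n_trunc].tolist())
    inactivated_ids = set(order[n_trunc:n_trunc + n_inact].tolist())

    # choose insertion sites
    ta_sites = {
        name: np.array([i for i in range(len(s) - 1)
                        if s[i:i + 2].upper() == "TA"], dtype=np.int64)
        for name, s in contigs.items()
    }
    weights = np.array([len(v) for v in ta_sites.values()], dtype=float)
    if weights.sum() == 0:
        raise PlacementError("no TA target sites in the genome")
    names = list(contigs)
    chosen: Dict[str, List[int]] = {name: [] for name in names}
    retries = 0
    placed = 0
    while placed < n:
        if retries > 200 * n + 1000:
            raise PlacementError(
                f"could not place {n} copies with spacing {min_spacing}")
        ci = rng.choice(len(names), p=weights / weights.sum())
        name = names[ci]
        sites = ta_sites[name]
        if len(sites) == 0:
            retries += 1
            continue
        pos = int(sites[rng.integers(0, len(sites))])
        if any(abs(pos - q) < min_spacing for q in chosen[name]):
            retries += 1
            continue
        chosen[name].append(pos)
        placed += 1

    # build per-copy sequences
    copy_ids = iter(range(n))
    plan: List[Tuple[str, int, int]] = []  # (contig, pos, copy_id)
    for name in names:
        for pos in sorted(chosen[name]):
            plan.append((name, pos, next(copy_ids)))

    out: Dict[str, str] = {}
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    for name in names:
        src = contigs[name]
        items = sorted((p, cid) for (cname, p, cid) in plan if cname == name)
        parts: List[str] = []
        cursor = 0
        for pos, cid in items:
            seq = mutate_sequence(master.sequence, divergence, kappa, rng)
            inact = cid in inactivated_ids
            if not inact:
                seq = _repair_orf(seq, master)
            else:
                seq = _repair_orf(seq, master)
                seq = _inactivate(seq, master, rng)
            trunc: Optional[str] = None
            if cid in truncated_ids:
                f = rng.uniform(0.1, 0.9)
                keep = max(1, int(round(f * len(seq))))
                if rng.random() < 0.5:
                    trunc = "5"
                    seq = seq[len(seq) - keep:]
                else:
                    trunc = "3"
                    seq = seq[:keep]
            strand = "+" if rng.random() < 0.5 else "-"
            ins = seq if strand == "+" else reverse_complement(seq)
            # which genome-side terminus is the truncated one?
            if trunc is None:
                left_tsd = right_tsd = True
            else:
                missing_left = (trunc == "5") == (strand == "+")
                left_tsd = not missing_left
                right_tsd = missing_left
            # assemble around the host TA at [pos, pos+2)
            if left_tsd and right_tsd:
                prefix = src[cursor:pos + 2]
                suffix_tsd = master.tsd
                host_resume = pos + 2
            elif not left_tsd:
                prefix = src[cursor:pos]
                suffix_tsd = master.tsd
                host_resume = pos + 2
                # avoid an accidental TA immediately left of the element
                if prefix[-2:].upper() == master.tsd:
                    prefix = prefix[:-1] + ("C" if prefix[-1] != "C" else "G")
            else:  # right TSD missing
                prefix = src[cursor:pos + 2]
                suffix_tsd = ""
                host_resume = pos + 2
            parts.append(prefix)
            start = sum(map(len, parts))
            parts.append(ins)
            end = start + len(ins)
            tail = suffix_tsd
            if not right_tsd:
                nxt = src[host_resume:host_resume + 2]
                if nxt.upper() == master.tsd:
                    # avoid an accidental TA immediately right of the element
                    src = (src[:host_resume] +
                           ("C" if nxt[0] != "C" else "G") +
                           src[host_resume + 1:])
            parts.append(tail)
            truth.planted_copies.append(PlantedCopy(
                species=species, contig=name, start=start, end=end,
                strand=strand, divergence=divergence, truncated=trunc,
                inactivated=inact))
            cursor = host_resume
        parts.append(src[cursor:])
        out[name] = "".join(parts)

    return (out["chr1"] if single else out), truth


def _inactivate(seq: str, master: MasterElement,
                rng: np.random.Generator) -> str:
    """Apply one ORF lesion: internal TAA codon or a 1-bp deletion."""
    s, e = master.orf_interval
    n_codons = (e - s) // 3
    lo, hi = int(0.1 * n_codons), int(0.9 * n_codons)
    if rng.random() < 0.5:
        c = int(rng.integers(lo, hi))
        pos = s + 3 * c
        return seq[:pos] + "TAA" + seq[pos + 3:]
    pos = s + int(rng.integers(3 * lo, 3 * hi))
    return seq[:pos] + seq[pos + 1:]


# ---------------------------------------------------------------------------
# species trees and horizontal-transfer scenarios
# ---------------------------------------------------------------------------

class SpeciesTree:
    """A rooted ultrametric species tree with node ages in Ma."""

    def __init__(self, tree: dendropy.Tree, tolerance: float = 1e-6):
        self._tree = tree
        self._tol = tolerance
        tree.is_rooted = True
        tree.calc_node_root_distances()
        depth = max(lf.root_distance for lf in tree.leaf_node_iter())
        for node in tree.preorder_node_iter():
            node.age_ma = depth - node.root_distance
        for lf in tree.leaf_node_iter():
            if abs(lf.age_ma) > tolerance * max(depth, 1.0):
                raise ValueError("tree is not ultrametric")
            lf.age_ma = 0.0

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 rooting="force-rooted")
        return cls(tree)

    @property
    def newick(self) -> str:
        return self._tree.as_string(schema="newick",
                                    suppress_rooting=True).strip()

    @property
    def tip_labels(self) -> List[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    @property
    def root_age(self) -> float:
        return self._tree.seed_node.age_ma

    def mrca_age(self, labels: Sequence[str]) -> float:
        labels = list(labels)
        unknown = set(labels) - set(self.tip_labels)
        if unknown:
            raise ValueError(f"unknown tip label(s): {sorted(unknown)}")
        if len(labels) == 1:
            return 0.0
        mrca = self._tree.mrca(taxon_labels=labels)
        return mrca.age_ma

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree


@dataclass
class HTScenario:
    """A simulated dataset: genomes, markers, TE lineages and truth."""

    tree: SpeciesTree
    master: MasterElement
    te_sequences: Dict[str, str]
    markers: Dict[str, str]
    genomes: Dict[str, str]
    truth: TruthTable


def simulate_ht_scenario(
    tree: Union[str, SpeciesTree],
    marker_rate: float,
    te_rate: float,
    ht_events: Sequence[Tuple] = (),
    seed: int = 0,
    *,
    marker_length: int = 1500,
    master: Optional[MasterElement] = None,
    kappa: float = 2.0,
    copies_per_species: int = 3,
    genome_length: int = 50_000,
    copy_divergence: float = 0.01,
) -> HTScenario:
    """Simulate marker genes and a TE family along a dated species tree.

    Marker genes and vertically inherited TE sequences accumulate
    ``rate`` substitutions/site/Ma along every branch, so two tips
    separated ``T`` Ma expect a distance of ``2 * rate * T``.  Each
    horizontal-transfer event ``(donor, recipient, time_ma)`` replaces
    the recipient tip's TE with the donor lineage's TE as it was
    ``time_ma`` ago, evolved forward independently — the transferred
    pair's expected TE distance is ``2 * te_rate * time_ma`` while its
    marker distance still reflects the species split.

    When ``genome_length`` is positive, each species also receives a
    random host genome with ``copies_per_species`` planted copies of
    its own TE lineage (within-species divergence ``copy_divergence``).
    """
    st = tree if isinstance(tree, SpeciesTree) else \
        SpeciesTree.from_newick(tree)
    rng = np.random.default_rng(seed)
    tips = set(st.tip_labels)
    events = [e if isinstance(e, HTEvent) else HTEvent(*e) for e in ht_events]
    for ev in events:
        if ev.donor not in tips or ev.recipient not in tips:
            raise ValueError(
                f"HT event references unknown tip: {ev.donor}/{ev.recipient}")
        if not (0 <= ev.time_ma <= st.root_age + 1e-9):
            raise ValueError("HT event time outside the tree depth")

    if master is None:
        master = build_master_element(seed=int(rng.integers(2 ** 31)))

    root_marker = _random_dna(rng, marker_length)
    root_te = master.sequence

    dtree = st.dendropy_tree
    # each HT event needs the donor lineage's TE *as an actual ancestor of
    # the donor tip*, so mark a breakpoint on the donor-path edge spanning
    # the event age and record the intermediate sequence when simulating it
    breakpoints: Dict[int, List[Tuple[float, int]]] = {}
    for ei, ev in enumerate(events):
        node = next(lf for lf in dtree.leaf_node_iter()
                    if lf.taxon.label == ev.donor)
        while node.parent_node is not None and \
                node.parent_node.age_ma < ev.time_ma - 1e-12:
            node = node.parent_node
        breakpoints.setdefault(id(node), []).append((ev.time_ma, ei))

    seqs: Dict[int, Tuple[str, str]] = {}  # node id -> (marker, te)
    donor_te_at_event: Dict[int, str] = {}
    for node in dtree.preorder_node_iter():
        if node.parent_node is None:
            seqs[id(node)] = (root_marker, root_te)
            for age, ei in breakpoints.get(id(node), ()):
                donor_te_at_event[ei] = root_te
            continue
        parent = node.parent_node
        pm, pt = seqs[id(parent)]
        bl = node.edge.length or 0.0
        m = mutate_sequence(pm, marker_rate * bl, kappa, rng)
        te = pt
        cur_age = parent.age_ma
        for age, ei in sorted(breakpoints.get(id(node), ()), reverse=True):
            te = mutate_sequence(te, te_rate * (cur_age - age), kappa, rng)
            donor_te_at_event[ei] = te
            cur_age = age
        te = mutate_sequence(te, te_rate * (cur_age - node.age_ma),
                             kappa, rng)
        seqs[id(node)] = (m, te)

    markers = {lf.taxon.label: seqs[id(lf)][0]
               for lf in dtree.leaf_node_iter()}
    te_seqs = {lf.taxon.label: seqs[id(lf)][1]
               for lf in dtree.leaf_node_iter()}

    # apply HT events (later events override earlier ones per recipient)
    for ei, ev in enumerate(events):
        te_seqs[ev.recipient] = mutate_sequence(
            donor_te_at_event[ei], te_rate * ev.time_ma, kappa, rng)

    truth = TruthTable(seed=seed, ht_events=events)
    genomes: Dict[str, str] = {}
    if genome_length > 0 and copies_per_species > 0:
        for sp in sorted(te_seqs):
            host = _random_dna(rng, genome_length)
            sp_master = dataclasses.replace(master, sequence=te_seqs[sp])
            g, t = plant_copies(
                host, sp_master, copies_per_species,
                divergence=copy_divergence, truncate_frac=0.0,
                inactivate_frac=0.0, seed=int(rng.integers(2 ** 31)),
                kappa=kappa, species=sp)
            genomes[sp] = g
            truth.planted_copies.extend(t.planted_copies)

    return HTScenario(tree=st, master=master, te_sequences=te_seqs,
                      markers=markers, genomes=genomes, truth=truth)


def embed_subterminal_pair(sir5: str, sir3: str, length: int = 1500,
                           offset: int = 30, seed: int = 0) -> str:
    """A random element carrying a given SIR pair at subterminal positions.

    The pair is planted ``offset`` bases in from each terminus of a
    random background sequence.  The four junction bases are chosen so
    the planted repeat is maximal: accidental complementarity adjacent
    to the pair would otherwise extend the detected repeat.
    """
    rng = np.random.default_rng(seed)
    sir5, sir3 = sir5.upper(), sir3.upper()
    need = 2 * offset + len(sir5) + len(sir3)
    if length < need + 10:
        raise ParameterError(f"length {length} too small ({need} bp needed)")
    seq = list(_random_dna(rng, length))
    seq[offset:offset + len(sir5)] = list(sir5)
    r_start = length - offset - len(sir3)
    seq[r_start:r_start + len(sir3)] = list(sir3)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    # outer junction: base before the 5' arm vs base after the 3' arm
    if seq[offset - 1] == comp[seq[r_start + len(sir3)]]:
        choices = [b for b in _BASES if b != seq[offset - 1]]
        seq[offset - 1] = choices[rng.integers(0, 3)]
    # inner junction: base after the 5' arm vs base before the 3' arm
    if seq[offset + len(sir5)] == comp[seq[r_start - 1]]:
        banned = comp[seq[r_start - 1]]
        choices = [b for b in _BASES if b != banned]
        seq[offset + len(sir5)] = choices[rng.integers(0, 3)]
    return "".join(seq)
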
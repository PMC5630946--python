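"""Distance-based horizontal-transfer inference and activity dating.

The diagnostic for horizontal transfer (HT) of a transposable element:
for a pair of species, compare the divergence of the TE family
(consensus vs consensus) with the divergence of a slowly evolving
orthologous host gene (e.g. RAG1) over the same pair.  Vertically
inherited TEs accumulate divergence since the species split, so TE and
marker distances should be comparable; a TE distance far below the
marker distance indicates the element crossed between the lineages
after they split.

Distances are p (observed difference fraction) or Kimura two-parameter

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

with P and Q the transition and transversion fractions, computed with
pairwise deletion (columns gapped or ambiguous in either sequence are
excluded).  Family structure is summarised with a neighbor-joining tree
over the TE distance matrix, clusters are cut at a maximum
intra-cluster distance, and the HT test is applied to every
within-cluster species pair.  A dated species tree converts the
phylogenetic placement of active copies into an activity time window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import dendropy
import numpy as np

from .synth import SpeciesTree

_PURINES = frozenset("AG")
_VALID = frozenset("ACGT")


# ---------------------------------------------------------------------------
# pairwise distances
# ---------------------------------------------------------------------------

def pairwise_distance(seq_a: str, seq_b: str, method: str = "k2p") -> float:
    """p or K2P distance between two aligned sequences.

    Pairwise deletion: columns with a gap or ambiguity in either
    sequence are excluded.  Returns NaN when no comparable columns
    remain or the K2P logarithms are undefined (saturation).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    if method not in ("p", "k2p"):
        raise ValueError(f"unknown distance method {method!r}")
    a = seq_a.upper()
    b = seq_b.upper()
    ncols = transitions = transversions = 0
    for x, y in zip(a, b):
        if x not in _VALID or y not in _VALID:
            continue
        ncols += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            transitions += 1
        else:
            transversions += 1
    if ncols == 0:
        return math.nan
    p_frac = transitions / ncols
    q_frac = transversions / ncols
    if method == "p":
        return p_frac + q_frac
    w1 = 1.0 - 2.0 * p_frac - q_frac
    w2 = 1.0 - 2.0 * q_frac
    if w1 <= 0 or w2 <= 0:
        return math.nan
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with its method tag."""

    labels: List[str]
    values: np.ndarray
    method: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(np.diag(v), 0, equal_nan=False):
            raise ValueError("diagonal must be zero")
        finite = np.isfinite(v)
        if not np.allclose(v[finite & finite.T],
                           v.T[finite & finite.T]):
            raise ValueError("matrix must be symmetric")
        self.values = v

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a),
                                 self.labels.index(b)])

    @property
    def has_undefined(self) -> bool:
        off = ~np.eye(len(self.labels), dtype=bool)
        return bool(np.isnan(self.values[off]).any())

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame(self.values, index=self.labels,
                            columns=self.labels)


def distance_matrix(
    sequences: Union[Dict[str, str], Sequence[Tuple[str, str]]],
    method: str = "k2p",
) -> DistanceMatrix:
    """All-pairs distance matrix over one aligned sequence per species."""
    items = list(sequences.items()) if isinstance(sequences, dict) \
        else [(i, s) for i, s in sequences]
    labels = [i for i, _ in items]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels")
    n = len(labels)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pairwise_distance(items[i][1], items[j][1], method)
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(labels, vals, method)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> str:
    """Neighbor-joining tree (Newick, unrooted trifurcating root).

    Deterministic: among equal Q-criterion pairs the lowest-index pair
    is joined first.  Negative branch lengths are clamped to zero.
    Requires at least 3 taxa and fully defined distances.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining requires >= 3 taxa")
    if dm.has_undefined:
        raise ValueError("distance matrix contains undefined entries; "
                         "subset to defined taxa first")
    D = dm.values.astype(float).copy()
    nodes = list(dm.labels)
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        iu = np.triu_indices(m, 1)
        qflat = Q[iu]
        kk = int(np.argmin(qflat))
        i, j = int(iu[0][kk]), int(iu[1][kk])
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new_label = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        dk = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [x for x in range(m) if x not in (i, j)]
        D2 = np.zeros((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dk[keep]
        D = D2
        nodes = [nodes[x] for x in keep] + [new_label]
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = max(0.5 * (d01 + d02 - d12), 0.0)
    l1 = max(0.5 * (d01 + d12 - d02), 0.0)
    l2 = max(0.5 * (d02 + d12 - d01), 0.0)
    return (f"({nodes[0]}:{l0:.10g},{nodes[1]}:{l1:.10g},"
            f"{nodes[2]}:{l2:.10g});")


# ---------------------------------------------------------------------------
# clusters and pair enumeration
# ---------------------------------------------------------------------------

@dataclass
class ClusterSet:
    """Disjoint species clusters from the family tree."""

    clusters: List[Set[str]]

    def __post_init__(self):
        seen: Set[str] = set()
        for c in self.clusters:
            if seen & c:
                raise ValueError("clusters must be disjoint")
            seen |= c

    @property
    def sizes(self) -> List[int]:
        return [len(c) for c in self.clusters]


def extract_clusters(tree_newick: str, dm: DistanceMatrix,
                     max_intra_distance: float) -> ClusterSet:
    """Cut a tree into maximal subtrees with bounded intra-TE distance.

    A subtree becomes one cluster when every pair of its members has
    distance at most ``max_intra_distance``; otherwise its children are
    examined recursively (leaves always qualify as singletons).  The
    tree is unrooted (the neighbor-joining root is an arbitrary
    trifurcation), so a cluster can straddle the root; a greedy merge
    pass joins clusters whose union still satisfies the distance bound.
    """
    tree = dendropy.Tree.get(data=tree_newick, schema="newick")

    def ok(labels: Sequence[str]) -> bool:
        return all(dm.get(a, b) <= max_intra_distance
                   for i, a in enumerate(labels) for b in labels[i + 1:])

    clusters: List[Set[str]] = []

    def rec(node) -> None:
        labels = [lf.taxon.label for lf in node.leaf_iter()]
        if ok(labels):
            clusters.append(set(labels))
            return
        for child in node.child_nodes():
            rec(child)

    rec(tree.seed_node)
    merged = True
    while merged:
        merged = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if ok(sorted(clusters[i] | clusters[j])):
                    clusters[i] |= clusters[j]
                    del clusters[j]
                    merged = True
                    break
            if merged:
                break
    return ClusterSet(clusters)


def enumerate_pairs(clusters: ClusterSet) -> List[Tuple[str, str]]:
    """All within-cluster unordered species pairs."""
    pairs: List[Tuple[str, str]] = []
    for cluster in clusters.clusters:
        members = sorted(cluster)
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                pairs.append((a, b))
    return pairs


# ---------------------------------------------------------------------------
# the HT test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HTComparison:
    """One species pair's TE-vs-marker distance comparison."""

    pair: Tuple[str, str]
    te_distance: float
    marker_distance: float
    verdict: str           # HT-candidate | vertical-consistent | indeterminate
    category: str          # candidate | exception | tie | indeterminate
    ratio: Optional[float] = None
    strong: bool = False
    divergence_ma: Optional[float] = None


def ht_test(te_d: float, marker_d: float,
            pair: Tuple[str, str] = ("A", "B"),
            strong_ratio: float = 0.5,
            divergence_ma: Optional[float] = None) -> HTComparison:
    """Compare TE and marker distances for one species pair.

    Verdict is ``HT-candidate`` iff the TE distance is strictly below
    the marker distance (both defined); equality or a larger TE
    distance is ``vertical-consistent``; an undefined distance is
    ``indeterminate``.  The category field splits vertical-consistent
    into ``exception`` (TE > marker) and ``tie`` so tallies decompose
    as candidates + exceptions + ties = all pairs.  A candidate whose
    TE/marker ratio is at most ``strong_ratio`` is flagged strong.
    """
    undefined = any(d is None or (isinstance(d, float) and math.isnan(d))
                    for d in (te_d, marker_d))
    if undefined:
        return HTComparison(pair, math.nan, math.nan,
                            "indeterminate", "indeterminate")
    ratio = te_d / marker_d if marker_d > 0 else None
    if te_d < marker_d:
        strong = ratio is not None and ratio <= strong_ratio
        return HTComparison(pair, te_d, marker_d, "HT-candidate",
                            "candidate", ratio, strong, divergence_ma)
    category = "tie" if te_d == marker_d else "exception"
    return HTComparison(pair, te_d, marker_d, "vertical-consistent",
                        category, ratio, False, divergence_ma)


def ht_scan(te_dm: DistanceMatrix, marker_dm: DistanceMatrix,
            clusters: ClusterSet,
            strong_ratio: float = 0.5) -> List[HTComparison]:
    """Apply the HT test to every within-cluster pair."""
    out = []
    for a, b in enumerate_pairs(clusters):
        if a not in te_dm.labels or a not in marker_dm.labels or \
                b not in te_dm.labels or b not in marker_dm.labels:
            out.append(HTComparison((a, b), math.nan, math.nan,
                                    "indeterminate", "indeterminate"))
            continue
        out.append(ht_test(te_dm.get(a, b), marker_dm.get(a, b),
                           (a, b), strong_ratio))
    return out


@dataclass(frozen=True)
class DistanceSummary:
    mean: float
    sd: float
    min: float
    max: float
    n: int
    sd_defined: bool = True


def summarize_distances(values: Sequence[float]) -> DistanceSummary:
    """Mean, sample SD (n-1), min and max of defined distances."""
    vals = [v for v in values if not math.isnan(v)]
    if not vals:
        raise ValueError("no defined distances to summarize")
    arr = np.array(vals)
    if len(arr) == 1:
        return DistanceSummary(float(arr[0]), 0.0, float(arr[0]),
                               float(arr[0]), 1, sd_defined=False)
    return DistanceSummary(float(arr.mean()), float(arr.std(ddof=1)),
                           float(arr.min()), float(arr.max()), len(arr))


# ---------------------------------------------------------------------------
# activity dating
# ---------------------------------------------------------------------------

def date_activity(
    dated_tree: Union[str, SpeciesTree],
    active_species: Set[str],
    inactive_outgroup: Set[str],
) -> Tuple[float, Optional[float]]:
    """Date a family's activity window on a calibrated species tree.

    The lower bound is the crown age of the most recent common ancestor
    of the species with active copies (0 for a single species); the
    upper bound is the age of the MRCA of the active set plus its
    nearest species without active copies.  With no inactive outgroup
    the upper bound is undefined (None).
    """
    st = dated_tree if isinstance(dated_tree, SpeciesTree) else \
        SpeciesTree.from_newick(dated_tree)
    active = sorted(active_species)
    if not active:
        raise ValueError("active species set is empty")
    lower = st.mrca_age(active) if len(active) > 1 else 0.0
    inactive = sorted(set(inactive_outgroup) - set(active))
    if not inactive:
        return lower, None
    upper = min(st.mrca_age(active + [t]) for t in inactive)
    return lower, upper
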
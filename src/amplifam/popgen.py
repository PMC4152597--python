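"""Population-genetic summaries, genetic distances, and NJ trees.

Polymorphism statistics follow the classical definitions on a multiple
alignment with complete deletion of gap/N columns: segregating sites S,
mean pairwise difference count k, nucleotide diversity pi = k / L, and
Watterson's theta_W = S / (a_{N-1} L) with a_{N-1} the (N-1)-th harmonic
number.  Synonymous and nonsynonymous site counts use Nei-Gojobori (NG86)
site classification averaged over sequences; single-base changes that would
create a stop codon are counted as nonsynonymous, so syn + nonsyn equals
the number of codon-complete sites analyzed.

Distances: Kimura two-parameter for nucleotides,
d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q) with P/Q the transition and
transversion proportions (pairwise deletion of gap/N sites), and p-distance
for amino acids.  Trees are built with Saitou-Nei neighbor joining, which
recovers additive metrics exactly; negative branch lengths are clamped to
zero with the deficit shifted to the sister branch.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq
from Bio.Data import CodonTable

from .io_formats import Alignment, TreeNode

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_VALID = frozenset("ACGT")
_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = frozenset(_STANDARD_TABLE.stop_codons)


def _is_transition(x: str, y: str) -> bool:
    return (x in _PURINES and y in _PURINES) or (
        x in _PYRIMIDINES and y in _PYRIMIDINES
    )


@dataclass
class PolymorphismStats:
    """Per-alignment polymorphism summary (Table-style row)."""

    N: int
    L: int  # alignment sites analyzed after complete deletion
    S: int
    k: float
    pi: float
    theta_W: float
    syn_sites: float
    nonsyn_sites: float
    n_codons: int = 0


@dataclass
class DistanceMatrix:
    ids: list[str]
    distances: np.ndarray  # square, symmetric, zero diagonal; NaN = undefined
    P: np.ndarray | None = None  # transition proportions (nucleotide mode)
    Q: np.ndarray | None = None  # transversion proportions

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        self.distances = d

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i, j in itertools.combinations(range(len(self.ids)), 2):
            if not np.isfinite(self.distances[i, j]):
                out.append((self.ids[i], self.ids[j]))
        return out


# --- polymorphism statistics ---------------------------------------------


def _included_columns(alignment: Alignment) -> list[int]:
    """Columns free of gaps and Ns in every sequence (complete deletion)."""
    cols = []
    for j in range(alignment.length):
        col = alignment.column(j)
        if all(c in _VALID for c in col):
            cols.append(j)
    return cols


def harmonic_number(n: int) -> float:
    return sum(1.0 / i for i in range(1, n + 1))


def _ng86_codon_sites(codon: str) -> tuple[float, float]:
    """NG86 synonymous/nonsynonymous site counts for one codon.

    Each position contributes the fraction of its three single-base changes
    that are synonymous; changes to a stop codon count as nonsynonymous.
    Stop codons themselves contribute (0, 0).
    """
    if codon in _STOPS:
        return 0.0, 0.0
    aa = _STANDARD_TABLE.forward_table[codon]
    syn = 0.0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant not in _STOPS and _STANDARD_TABLE.forward_table[mutant] == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def polymorphism_stats(
    alignment: Alignment, frame_offset: int = 0
) -> PolymorphismStats:
    """S, k, pi, theta_W and NG86 site counts for one alignment.

    Columns containing any gap or N are excluded from every statistic
    (complete deletion).  Site counts are computed per sequence on codons
    (relative to ``frame_offset``) whose three columns are all included,
    then averaged over sequences.
    """
    n = len(alignment)
    if n < 2:
        raise ValueError("polymorphism statistics require >= 2 sequences")
    cols = _included_columns(alignment)
    if not cols:
        raise ValueError("no gap/N-free columns to analyze")
    L = len(cols)
    rows = [r.sequence for r in alignment.records]

    S = sum(1 for j in cols if len({row[j] for row in rows}) > 1)
    total_diff = 0
    n_pairs = 0
    for a, b in itertools.combinations(rows, 2):
        total_diff += sum(1 for j in cols if a[j] != b[j])
        n_pairs += 1
    k = total_diff / n_pairs
    pi = k / L
    theta_w = S / (harmonic_number(n - 1) * L)

    included = set(cols)
    codon_cols = []
    for start in range(frame_offset, alignment.length - 2, 3):
        triplet = (start, start + 1, start + 2)
        if all(c in included for c in triplet):
            codon_cols.append(triplet)
    syn_total = nonsyn_total = 0.0
    for row in rows:
        for c0, c1, c2 in codon_cols:
            s, ns = _ng86_codon_sites(row[c0] + row[c1] + row[c2])
            syn_total += s
            nonsyn_total += ns
    return PolymorphismStats(
        N=n,
        L=L,
        S=S,
        k=k,
        pi=pi,
        theta_W=theta_w,
        syn_sites=syn_total / n,
        nonsyn_sites=nonsyn_total / n,
        n_codons=len(codon_cols),
    )


# --- distances ------------------------------------------------------------


def transition_transversion_proportions(a: str, b: str) -> tuple[float, float, int]:
    """(P, Q, L) over sites where both sequences have an unambiguous base."""
    ts = tv = L = 0
    for x, y in zip(a, b):
        if x not in _VALID or y not in _VALID:
            continue
        L += 1
        if x == y:
            continue
        if _is_transition(x, y):
            ts += 1
        else:
            tv += 1
    if L == 0:
        return math.nan, math.nan, 0
    return ts / L, tv / L, L


def kimura_2p(a: str, b: str) -> float:
    """Kimura two-parameter distance; NaN marks an undefined distance.

    Sites where either sequence has a gap or N are excluded pairwise.
    """
    P, Q, L = transition_transversion_proportions(a, b)
    if L == 0:
        return math.nan
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def aa_p_distance(a: str, b: str) -> float:
    """Proportion of differing residues over comparable residue pairs.

    Positions where either side is a gap, X or a stop are skipped; NaN when
    nothing is comparable.
    """
    skip = {"-", "X", "*"}
    diff = total = 0
    for x, y in zip(a, b):
        if x in skip or y in skip:
            continue
        total += 1
        if x != y:
            diff += 1
    return diff / total if total else math.nan


def nucleotide_distance_matrix(
    ids: list[str], sequences: list[str]
) -> DistanceMatrix:
    """Pairwise K2P distances with per-pair P and Q (pairwise deletion)."""
    n = len(ids)
    d = np.zeros((n, n))
    P = np.zeros((n, n))
    Q = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        p, q, L = transition_transversion_proportions(sequences[i], sequences[j])
        P[i, j] = P[j, i] = p
        Q[i, j] = Q[j, i] = q
        d[i, j] = d[j, i] = kimura_2p(sequences[i], sequences[j])
    return DistanceMatrix(ids=list(ids), distances=d, P=P, Q=Q)


def protein_distance_matrix(ids: list[str], proteins: list[str]) -> DistanceMatrix:
    n = len(ids)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = aa_p_distance(proteins[i], proteins[j])
    return DistanceMatrix(ids=list(ids), distances=d)


def group_distances(
    matrix: DistanceMatrix, groups: dict[str, list[str]]
) -> dict[tuple[str, str], float]:
    """Mean within- and between-group distances.

    Returns {(group, group): mean within, (groupA, groupB): mean between}
    over all defined pairs; NaN when a cell has no defined pair.
    """
    index = {name: i for i, name in enumerate(matrix.ids)}
    out: dict[tuple[str, str], float] = {}
    names = sorted(groups)
    for gi in range(len(names)):
        for gj in range(gi, len(names)):
            a, b = names[gi], names[gj]
            if a == b:
                pairs = list(itertools.combinations(groups[a], 2))
            else:
                pairs = [(x, y) for x in groups[a] for y in groups[b]]
            vals = [
                matrix.distances[index[x], index[y]]
                for x, y in pairs
                if np.isfinite(matrix.distances[index[x], index[y]])
            ]
            out[(a, b)] = float(np.mean(vals)) if vals else math.nan
    return out


# --- haplotype-frequency chi-square --------------------------------------


def chi_square_differentiation(
    seqs_a: list[str], seqs_b: list[str]
) -> tuple[float, int]:
    """Haplotype-frequency chi-square between two sequence sets.

    Identical sequences are collapsed into haplotypes over the pooled sets;
    the statistic is the usual sum of (obs - exp)^2 / exp on the
    2 x H count table with df = H - 1.  H == 1 gives (0, 0).
    """
    haplotypes = sorted({*seqs_a, *seqs_b})
    H = len(haplotypes)
    if H <= 1:
        return 0.0, 0
    idx = {h: i for i, h in enumerate(haplotypes)}
    table = np.zeros((2, H))
    for s in seqs_a:
        table[0, idx[s]] += 1
    for s in seqs_b:
        table[1, idx[s]] += 1
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row * col / table.sum()
    stat = float(((table - expected) ** 2 / expected).sum())
    return stat, H - 1


# --- neighbor joining -----------------------------------------------------


def nj_tree(matrix: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; exact on additive metrics.

    Ties in the Q-criterion are broken by the smallest index pair.  Negative
    branch lengths are clamped to zero with the deficit shifted to the
    sister branch.  The result is an unrooted tree represented with a
    trifurcating root (the final three lineages).
    """
    bad = matrix.undefined_pairs()
    if bad:
        raise ValueError(
            "undefined distances for pairs: "
            + ", ".join(f"{a}-{b}" for a, b in bad)
        )
    n = len(matrix.ids)
    if n < 3:
        raise ValueError("neighbor joining requires >= 3 taxa")
    D = matrix.distances.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in matrix.ids]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest index pair on ties
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                if best is None or q[ai, aj] < q[best[0], best[1]] - 1e-12:
                    best = (ai, aj)
        ai, aj = best
        i, j = active[ai], active[aj]
        dij = D[i, j]
        bi = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        bj = dij - bi
        if bi < 0.0:
            bj += bi
            bi = 0.0
        if bj < 0.0:
            bi += bj
            bj = 0.0
        node = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].branch_length = float(bi)
        nodes[j].branch_length = float(bj)

        new_idx = D.shape[0]
        newcol = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[new_idx, : new_idx] = newcol
        D[: new_idx, new_idx] = newcol
        nodes.append(node)
        active = [x for x in active if x not in (i, j)] + [new_idx]

    i, j, k = active
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    nodes[i].branch_length = max(0.0, 0.5 * (D[i, j] + D[i, k] - D[j, k]))
    nodes[j].branch_length = max(0.0, 0.5 * (D[i, j] + D[j, k] - D[i, k]))
    nodes[k].branch_length = max(0.0, 0.5 * (D[i, k] + D[j, k] - D[i, j]))
    return root


def tree_path_distances(tree: TreeNode) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths of a tree (for additivity checks)."""
    out: dict[tuple[str, str], float] = {}

    def walk(node: TreeNode) -> dict[str, float]:
        if node.is_leaf():
            below = {node.name: 0.0}
        else:
            child_maps = [walk(c) for c in node.children]
            for a_map, b_map in itertools.combinations(child_maps, 2):
                for la, da in a_map.items():
                    for lb, db in b_map.items():
                        key = (min(la, lb), max(la, lb))
                        out[key] = da + db
            below = {}
            for c, cmap in zip(node.children, child_maps):
                for leaf, dist in cmap.items():
                    below[leaf] = dist
        if node.branch_length is not None:
            below = {leaf: d + node.branch_length for leaf, d in below.items()}
        return below

    walk(tree)
    return out
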
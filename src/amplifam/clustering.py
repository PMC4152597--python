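"""Greedy centroid clustering, de novo chimera screening, and consensus.

The clustering stage mirrors greedy centroid-based identity clustering:
sequences are processed in decreasing length order (ties broken by
decreasing abundance of identical sequences, then id) and each joins the
first existing centroid it matches at >= the identity threshold, else
founds a new cluster.

Identity is global, end-to-end: matches / alignment columns under an
affine-gap global alignment (match +1, mismatch -2, gap open -4, gap extend
-1); every gap column counts as a non-match.  A provably safe edit-distance
prescreen (identity <= m / (m + d) for m = min sequence length and d = the
unit-cost edit distance, for ANY alignment) rejects hopeless centroid
comparisons cheaply before the exact aligner confirms a membership.

The chimera screen is a de novo two-parent model search in the spirit of
UCHIME: candidate parents must be at least ``abskew`` times as abundant as
the query; over all ordered parent pairs and breakpoints the model
minimizing query mismatches is found, and the query is called chimeric when
each side carries enough diagnostic sites and the two-parent model explains
enough more of the query than the best single parent.
"""

from __future__ import annotations

import functools
import re
from dataclasses import dataclass, field

import edlib
import numpy as np
from Bio import Align

from .io_formats import Alignment, SequenceRecord

_CIGAR = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class ClusterParams:
    identity_threshold: float = 0.98
    min_cluster_size: int = 7
    abskew: float = 2.0
    min_diag: int = 3
    min_improvement: int = 2
    # a real chimera is explained almost completely by its two-parent model,
    # so the improvement must also be a large FRACTION of the best
    # single-parent mismatch count; an absolute gate alone is passed by
    # chance on any divergent non-chimeric query (the optimal breakpoint of
    # a random mismatch walk gains ~sqrt(divergent sites))
    min_improvement_ratio: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.identity_threshold <= 1.0:
            raise ValueError("identity_threshold must be in (0, 1]")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")
        if self.abskew < 1.0:
            raise ValueError("abskew must be >= 1")


@dataclass
class Cluster:
    centroid_id: str
    centroid_sequence: str
    member_ids: list[str] = field(default_factory=list)
    consensus: str | None = None

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class ChimeraCall:
    query_id: str
    parent_a_id: str | None
    parent_b_id: str | None
    breakpoint_column: int | None
    improvement: int
    diag_left: int
    diag_right: int
    is_chimera: bool


# --- pairwise identity ----------------------------------------------------


@functools.lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    return aligner


def global_alignment(a: str, b: str) -> tuple[str, str]:
    """Gapped rows of the optimal affine global alignment of a and b."""
    aln = _aligner().align(a, b)[0]
    return str(aln[0]), str(aln[1])


def global_identity(a: str, b: str, *, ignore_terminal_gaps: bool = False) -> float:
    """Fraction of matching columns in the global alignment of a and b.

    Each gap column counts as a non-match.  With ``ignore_terminal_gaps``
    the leading/trailing all-gap overhangs are excluded from the column
    count (useful when one sequence is a fragment of the other).
    """
    if not a or not b:
        raise ValueError("global_identity requires non-empty sequences")
    row_a, row_b = global_alignment(a, b)
    lo, hi = 0, len(row_a)
    if ignore_terminal_gaps:
        while lo < hi and (row_a[lo] == "-" or row_b[lo] == "-"):
            lo += 1
        while hi > lo and (row_a[hi - 1] == "-" or row_b[hi - 1] == "-"):
            hi -= 1
        if hi == lo:  # no overlap: fall back to full span
            lo, hi = 0, len(row_a)
    columns = hi - lo
    matches = sum(
        1 for x, y in zip(row_a[lo:hi], row_b[lo:hi]) if x == y and x != "-"
    )
    return matches / columns


def identity_upper_bound_reject(a: str, b: str, threshold: float) -> bool:
    """True when a cheap edit-distance bound proves identity(a, b) < threshold.

    For any alignment, identity = matches/columns <= m/(m+d) with
    m = min(len(a), len(b)) and d the unit-cost edit distance, because
    matches <= m and non-match columns >= d.  So d > m(1-t)/t rules the
    pair out without running the exact aligner.
    """
    m = min(len(a), len(b))
    k = int(m * (1.0 - threshold) / threshold)
    result = edlib.align(a, b, mode="NW", k=k)
    return result["editDistance"] == -1


# --- greedy clustering ----------------------------------------------------


def greedy_cluster(
    seqs: list[SequenceRecord], params: ClusterParams | None = None
) -> list[Cluster]:
    """Greedy centroid clustering at the identity threshold.

    Sequences are processed in decreasing length order, ties broken by
    decreasing abundance of byte-identical sequences then by id, so the
    result is independent of input file order.  Each sequence joins the
    FIRST existing centroid with identity >= threshold (centroids in
    creation order), otherwise founds a new cluster.  The output is a
    partition of the input.
    """
    params = params or ClusterParams()
    abundance: dict[str, int] = {}
    for s in seqs:
        abundance[s.sequence] = abundance.get(s.sequence, 0) + 1
    ordered = sorted(
        seqs, key=lambda s: (-len(s.sequence), -abundance[s.sequence], s.id)
    )
    clusters: list[Cluster] = []
    for s in ordered:
        joined = False
        for cluster in clusters:
            if identity_upper_bound_reject(
                s.sequence, cluster.centroid_sequence, params.identity_threshold
            ):
                continue
            if (
                global_identity(s.sequence, cluster.centroid_sequence)
                >= params.identity_threshold
            ):
                cluster.member_ids.append(s.id)
                joined = True
                break
        if not joined:
            clusters.append(
                Cluster(centroid_id=s.id, centroid_sequence=s.sequence,
                        member_ids=[s.id])
            )
    return clusters


# --- de novo chimera detection -------------------------------------------


def _aligned_parent_chars(query: str, parent: str) -> np.ndarray:
    """Parent characters projected onto query coordinates ('-' where the
    parent is gapped); parent insertions relative to the query are dropped."""
    res = edlib.align(parent, query, mode="NW", task="path")
    out = np.full(len(query), "-", dtype="U1")
    qi = pi = 0
    for n, op in _CIGAR.findall(res["cigar"]):
        n = int(n)
        if op in "=XM":
            out[qi : qi + n] = list(parent[pi : pi + n])
            qi += n
            pi += n
        elif op == "I":  # consumes parent only
            pi += n
        elif op == "D":  # consumes query only: parent gap
            qi += n
    return out


def detect_chimeras_de_novo(
    clusters: list[Cluster], params: ClusterParams | None = None
) -> list[ChimeraCall]:
    """Screen every cluster representative against two-parent splice models.

    For a query cluster, eligible parents are representatives of clusters
    with size >= abskew x the query size.  Over all ordered parent pairs
    and interior breakpoints, the model minimizing query mismatches
    (left side scored against parent A, right side against parent B, on the
    query coordinate frame) is selected.  The query is chimeric when each
    side has >= ``min_diag`` diagnostic sites (query matches that side's
    parent and mismatches the other) and the model explains
    >= ``min_improvement`` more query sites than the best single parent.
    """
    params = params or ClusterParams()
    calls: list[ChimeraCall] = []
    for ci, cluster in enumerate(clusters):
        query = cluster.centroid_sequence
        parents = [
            other
            for cj, other in enumerate(clusters)
            if cj != ci and other.size >= params.abskew * cluster.size
        ]
        if len(parents) < 2:
            calls.append(
                ChimeraCall(cluster.centroid_id, None, None, None, 0, 0, 0, False)
            )
            continue
        qarr = np.array(list(query), dtype="U1")
        L = len(query)
        pchars = np.stack([_aligned_parent_chars(query, p.centroid_sequence)
                           for p in parents])
        mism = pchars != qarr  # (P, L)
        pref = np.zeros((len(parents), L + 1), dtype=np.int32)
        np.cumsum(mism, axis=1, out=pref[:, 1:])
        totals = pref[:, -1]
        best_single = int(totals.min())

        # cost of splitting after column b (1 <= b <= L-1) for ordered (A, B):
        #   pref_A[b] + total_B - pref_B[b]
        interior = pref[:, 1:L]  # (P, L-1)
        diff = interior[:, None, :] - interior[None, :, :]  # (A, B, b)
        b_idx = np.argmin(diff, axis=2)  # smallest b on ties
        pair_cost = (
            np.take_along_axis(diff, b_idx[:, :, None], axis=2)[:, :, 0]
            + totals[None, :]
        )
        np.fill_diagonal(pair_cost, np.iinfo(np.int32).max)
        a_best, b_best = np.unravel_index(np.argmin(pair_cost), pair_cost.shape)
        cost = int(pair_cost[a_best, b_best])
        bp = int(b_idx[a_best, b_best]) + 1
        improvement = best_single - cost

        match_a = ~mism[a_best]
        match_b = ~mism[b_best]
        diag_left = int(np.count_nonzero(match_a[:bp] & mism[b_best][:bp]))
        diag_right = int(np.count_nonzero(match_b[bp:] & mism[a_best][bp:]))
        is_chimera = (
            diag_left >= params.min_diag
            and diag_right >= params.min_diag
            and improvement >= params.min_improvement
            and best_single > 0
            and improvement / best_single >= params.min_improvement_ratio
        )
        calls.append(
            ChimeraCall(
                query_id=cluster.centroid_id,
                parent_a_id=parents[a_best].centroid_id,
                parent_b_id=parents[b_best].centroid_id,
                breakpoint_column=bp,
                improvement=improvement,
                diag_left=diag_left,
                diag_right=diag_right,
                is_chimera=is_chimera,
            )
        )
    return calls


# --- center-star alignment and consensus ---------------------------------


def _member_alignment_ops(member: str, centroid: str) -> list[tuple[int, str]]:
    res = edlib.align(member, centroid, mode="NW", task="path")
    return [(int(n), op) for n, op in _CIGAR.findall(res["cigar"])]


def align_cluster(
    members: list[SequenceRecord], centroid_sequence: str
) -> Alignment:
    """Center-star multiple alignment of cluster members around the centroid.

    Each member is pairwise-aligned to the centroid (unit-cost global
    alignment); member insertions relative to the centroid are merged into
    shared insertion columns (left-aligned, padded with gaps).  Deterministic
    for a fixed member order.
    """
    Lc = len(centroid_sequence)
    per_member: list[tuple[list[int], list[str]]] = []
    for m in members:
        ins_before = [0] * (Lc + 1)
        aligned: list[list[str]] = [[] for _ in range(Lc + 1)]
        qi = ci = 0
        for n, op in _member_alignment_ops(m.sequence, centroid_sequence):
            if op in "=XM":
                for _ in range(n):
                    aligned[ci].append(m.sequence[qi])
                    qi += 1
                    ci += 1
            elif op == "I":  # member insertion before centroid position ci
                ins_before[ci] += n
                aligned[ci] = list(m.sequence[qi : qi + n]) + aligned[ci]
                qi += n
            elif op == "D":  # member gap at centroid positions
                for _ in range(n):
                    aligned[ci].append("-")
                    ci += 1
        per_member.append((ins_before, aligned))

    master_ins = [0] * (Lc + 1)
    for ins_before, _ in per_member:
        for j in range(Lc + 1):
            master_ins[j] = max(master_ins[j], ins_before[j])

    def build_row(ins_before: list[int], aligned: list[list[str]]) -> str:
        row: list[str] = []
        for j in range(Lc + 1):
            block = aligned[j]
            n_ins = ins_before[j]
            inserted = block[:n_ins]
            rest = block[n_ins:]
            row.extend(inserted)
            row.extend("-" * (master_ins[j] - n_ins))
            row.extend(rest)
        return "".join(row)

    rows = [
        SequenceRecord(id=m.id, sequence=build_row(ins, al), description="")
        for m, (ins, al) in zip(members, per_member)
    ]
    return Alignment(records=tuple(rows))


def call_consensus(alignment: Alignment) -> str:
    """Per-column majority-rule consensus.

    Columns whose majority character is a gap are dropped.  Ties prefer a
    base over a gap (keeps consensus length stable) and are otherwise broken
    alphabetically.
    """
    if not alignment.records:
        raise ValueError("cannot call a consensus on an empty alignment")
    rows = np.array([list(r.sequence) for r in alignment.records], dtype="U1")
    out: list[str] = []
    for j in range(rows.shape[1]):
        chars, counts = np.unique(rows[:, j], return_counts=True)
        top = counts.max()
        winners = sorted(chars[counts == top])
        bases = [w for w in winners if w != "-"]
        winner = bases[0] if bases else "-"
        if winner != "-":
            out.append(winner)
    return "".join(out)


def consensus_for_cluster(
    cluster: Cluster,
    members: list[SequenceRecord],
    min_cluster_size: int = 7,
    *,
    allow_small: bool = False,
) -> str | None:
    """Consensus of a cluster, or None when it is below the coverage floor."""
    if cluster.size < min_cluster_size and not allow_small:
        return None
    alignment = align_cluster(members, cluster.centroid_sequence)
    return call_consensus(alignment)


def membership_rows(clusters: list[Cluster]) -> list[dict[str, object]]:
    return [
        {
            "cluster_id": f"cluster{idx:05d}",
            "size": c.size,
            "centroid": c.centroid_id,
            "members": ",".join(c.member_ids),
        }
        for idx, c in enumerate(clusters)
    ]


def chimera_report_rows(calls: list[ChimeraCall]) -> list[dict[str, object]]:
    return [
        {
            "query": c.query_id,
            "parent_a": c.parent_a_id or "",
            "parent_b": c.parent_b_id or "",
            "breakpoint": "" if c.breakpoint_column is None else c.breakpoint_column,
            "diag_left": c.diag_left,
            "diag_right": c.diag_right,
            "improvement": c.improvement,
            "verdict": "Y" if c.is_chimera else "N",
        }
        for c in calls
    ]
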
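"""Functional classification, repertoire-size estimation, and validation.

Consensus loci are classified as putatively functional (some reading-frame
offset yields a stop-free translation over all complete codons) or
pseudogenized.  Repertoire size is bracketed by collapsing loci at two
identity thresholds: >98% identity groups give the conservative minimum
locus count and >99% groups the maximum.  Grouping is single-linkage
(connected components of the "considered identical" relation), the most
conservative construction.  Validation against a reference locus set counts
recovered, identical-at-every-base, and novel loci; cross-individual
comparison counts shared loci and >99%/identical best-hit pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .clustering import global_identity

GENETIC_STOP = "*"


@dataclass
class ConsensusLocus:
    id: str
    sequence: str
    subfamily: str = ""
    coverage: int = 0
    functional: bool = True
    frame_offset: int = 0


@dataclass
class RepertoireEstimate:
    min_loci: int
    max_loci: int
    groups_min: list[list[str]]
    groups_max: list[list[str]]
    thresholds: tuple[float, float] = (0.98, 0.99)


@dataclass
class BestHit:
    query_id: str
    subject_id: str | None
    identity: float


@dataclass
class ValidationReport:
    n_reference: int
    n_query: int
    recovered: list[str]
    identical: list[str]
    novel: list[str]
    best_hits: list[BestHit] = field(default_factory=list)

    @property
    def n_recovered(self) -> int:
        return len(self.recovered)

    @property
    def n_identical(self) -> int:
        return len(self.identical)

    @property
    def n_novel(self) -> int:
        return len(self.novel)

    @property
    def recovery_fraction(self) -> float:
        return self.n_recovered / self.n_reference if self.n_reference else 0.0


@dataclass
class ComparisonReport:
    shared_fraction_a: float
    shared_fraction_b: float
    n_pairs_gt99: int
    n_identical: int
    pair_table: list[tuple[str, str, float]] = field(default_factory=list)


def classify_functionality(sequence: str) -> tuple[bool, int]:
    """(functional, frame_offset) by searching reading-frame offsets 0..2.

    A locus is putatively functional iff some offset yields a stop-free
    translation over all complete codons; the smallest stop-free offset is
    recorded (0 when none is stop-free).
    """
    if len(sequence) < 60:
        raise ValueError("sequence too short for a reading-frame check")
    for offset in (0, 1, 2):
        span = sequence[offset:]
        span = span[: len(span) - len(span) % 3]
        protein = str(Seq(span).translate())
        if GENETIC_STOP not in protein:
            return True, offset
    return False, 0


def translate_at_offset(sequence: str, frame_offset: int) -> str:
    span = sequence[frame_offset:]
    span = span[: len(span) - len(span) % 3]
    return str(Seq(span).translate())


def _identity_groups(
    loci: list[ConsensusLocus], threshold: float, *, strict: bool = True
) -> list[list[str]]:
    """Single-linkage groups: connected components of the identity graph.

    An edge joins two loci when identity > threshold (strict, matching the
    "greater than" phrasing of the collapse rule).
    """
    n = len(loci)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            ident = global_identity(loci[i].sequence, loci[j].sequence)
            merges = ident > threshold if strict else ident >= threshold
            if merges:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    groups: dict[int, list[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(loci[i].id)
    return sorted(groups.values(), key=lambda g: g[0])


def estimate_repertoire(
    loci: list[ConsensusLocus], thresholds: tuple[float, float] = (0.98, 0.99)
) -> RepertoireEstimate:
    """Bracket the repertoire size at two identity thresholds.

    ``min_loci`` counts groups at the lower threshold (conservative minimum:
    loci sharing > lower-threshold identity are considered the same gene);
    ``max_loci`` counts groups at the upper threshold.  Expects functional
    loci only; pseudogenes are excluded upstream.
    """
    lo, hi = sorted(thresholds)
    if not loci:
        return RepertoireEstimate(0, 0, [], [], (lo, hi))
    groups_min = _identity_groups(loci, lo)
    groups_max = _identity_groups(loci, hi)
    return RepertoireEstimate(
        min_loci=len(groups_min),
        max_loci=len(groups_max),
        groups_min=groups_min,
        groups_max=groups_max,
        thresholds=(lo, hi),
    )


def trim_reference_to_span(reference: str, profile: str) -> str:
    """Trim a (possibly full-length) reference to the amplicon span.

    The reference is globally aligned to an amplicon profile sequence and
    the overhangs opposite the profile's terminal gaps are removed.
    """
    from .clustering import global_alignment

    row_ref, row_prof = global_alignment(reference, profile)
    lo, hi = 0, len(row_prof)
    while lo < hi and row_prof[lo] == "-":
        lo += 1
    while hi > lo and row_prof[hi - 1] == "-":
        hi -= 1
    return row_ref[lo:hi].replace("-", "")


def validate_against_reference(
    queries: list[ConsensusLocus],
    references: list[ConsensusLocus],
    match_threshold: float = 0.98,
    *,
    trim_references: bool = False,
    profile: str | None = None,
) -> ValidationReport:
    """Score queries against a reference locus set.

    A reference is *recovered* when its best query identity >= the match
    threshold, *identical* when that identity is exactly 1.0 over the
    compared span; a query is *novel* when its best reference identity is
    below the threshold.  With ``trim_references`` each reference is first
    trimmed to the amplicon span against ``profile`` (default: the first
    query sequence).
    """
    refs = references
    if trim_references:
        prof = profile or (queries[0].sequence if queries else None)
        if prof:
            refs = [
                ConsensusLocus(
                    id=r.id,
                    sequence=trim_reference_to_span(r.sequence, prof) or r.sequence,
                    subfamily=r.subfamily,
                )
                for r in references
            ]
    recovered: list[str] = []
    identical: list[str] = []
    best_hits: list[BestHit] = []
    for ref in refs:
        best_id, best_q = -1.0, None
        for q in queries:
            ident = global_identity(ref.sequence, q.sequence)
            if ident > best_id:
                best_id, best_q = ident, q.id
        best_hits.append(BestHit(ref.id, best_q, max(best_id, 0.0)))
        if best_q is not None and best_id >= match_threshold:
            recovered.append(ref.id)
            if best_id == 1.0:
                identical.append(ref.id)
    novel: list[str] = []
    for q in queries:
        best_id = max(
            (global_identity(q.sequence, r.sequence) for r in refs), default=0.0
        )
        if best_id < match_threshold:
            novel.append(q.id)
    return ValidationReport(
        n_reference=len(references),
        n_query=len(queries),
        recovered=recovered,
        identical=identical,
        novel=novel,
        best_hits=best_hits,
    )


def compare_repertoires(
    loci_a: list[ConsensusLocus],
    loci_b: list[ConsensusLocus],
    thresholds: tuple[float, float] = (0.98, 0.99),
) -> ComparisonReport:
    """Cross-individual repertoire overlap.

    ``shared_fraction_a`` is the fraction of A-loci with a B-match at >= the
    lower threshold (and symmetrically for B).  Best-hit pairs are formed
    one-to-one greedily by descending identity; ``n_pairs_gt99`` counts
    pairs above the upper threshold and ``n_identical`` pairs at 1.0.
    """
    lo, hi = sorted(thresholds)
    if not loci_a or not loci_b:
        return ComparisonReport(0.0, 0.0, 0, 0, [])
    ident: dict[tuple[int, int], float] = {}
    for i, a in enumerate(loci_a):
        for j, b in enumerate(loci_b):
            ident[(i, j)] = global_identity(a.sequence, b.sequence)
    shared_a = sum(
        1
        for i in range(len(loci_a))
        if max(ident[(i, j)] for j in range(len(loci_b))) >= lo
    )
    shared_b = sum(
        1
        for j in range(len(loci_b))
        if max(ident[(i, j)] for i in range(len(loci_a))) >= lo
    )
    # greedy one-to-one pairing by descending identity (deterministic ties)
    order = sorted(ident.items(), key=lambda kv: (-kv[1], kv[0]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[str, str, float]] = []
    for (i, j), val in order:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((loci_a[i].id, loci_b[j].id, val))
    n_gt99 = sum(1 for _, _, v in pairs if v > hi)
    n_ident = sum(1 for _, _, v in pairs if v == 1.0)
    return ComparisonReport(
        shared_fraction_a=shared_a / len(loci_a),
        shared_fraction_b=shared_b / len(loci_b),
        n_pairs_gt99=n_gt99,
        n_identical=n_ident,
        pair_table=pairs,
    )
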
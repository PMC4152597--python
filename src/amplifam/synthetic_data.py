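"""Synthetic gene-family repertoires, CCS reads, and PCR artifacts.

The generator emulates the statistical structure of a pooled-amplicon CCS
experiment on a large, closely related receptor gene family:

* two diploid individuals carrying 20-40 paralogous single-exon loci per
  subfamily, a tunable fraction of which is shared between individuals;
* two amplicon length classes (defaults 725 bp and 800 bp, ~65 bp apart,
  enabling demultiplexing by length);
* a per-read pass count ``p`` with per-base error rate ``eps(p) = eps1 / p``
  (stochastic error shrinking with circular-consensus passes, so mean base
  quality rises monotonically with pass count);
* lognormal per-locus read abundance (PCR amplification bias);
* a tunable fraction of two-parent, single-breakpoint PCR chimeras.

Every emitted read carries a truth entry (parent locus, or parent pair and
breakpoint for chimeras), so downstream clustering, chimera screening and
repertoire estimation can be scored against ground truth.  A fixed seed
yields byte-identical FASTQ output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import CCSRead, SequenceRecord, write_fasta, write_fastq, write_tsv_report

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
# transition partner (A<->G, C<->T); used for the 2:1 ts:tv substitution mix
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}

QUALITY_CAP = 60  # Phred assigned where the error model is error-free


@dataclass
class SimConfig:
    """Parameters of one simulated two-individual amplicon experiment."""

    seed: int = 0
    n_loci_per_subfamily: int = 30
    amplicon_lengths: dict[str, int] = field(
        default_factory=lambda: {"V1RI": 725, "V1RIX": 800}
    )
    target_pairwise_divergence: tuple[float, float] = (0.03, 0.20)
    shared_locus_fraction: float = 0.7
    allelic_divergence: float = 0.002
    pseudogene_fraction: float = 0.1
    n_individuals: int = 2
    reads_per_individual: int = 5000
    # pass counts: shifted geometric on [pass_min, pass_max]
    pass_min: int = 2
    pass_max: int = 10
    pass_geometric_p: float = 0.3
    # per-base error eps(p) = eps1 / p  (non-increasing in p)
    eps1: float = 0.02
    indel_fraction: float = 0.1  # fraction of errors that are 1-bp indels
    quality_jitter_sd: float = 2.0
    chimera_fraction: float = 0.0
    abundance_sigma: float = 1.0

    def validate(self) -> None:
        for name in (
            "shared_locus_fraction",
            "pseudogene_fraction",
            "chimera_fraction",
            "indel_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        lo, hi = self.target_pairwise_divergence
        if not 0.0 <= lo <= hi:
            raise ValueError("divergence range must satisfy 0 <= lo <= hi")
        if self.pass_min < 1 or self.pass_max < self.pass_min:
            raise ValueError("pass range must satisfy 1 <= pass_min <= pass_max")
        if self.eps1 < 0:
            raise ValueError("eps1 must be non-negative")
        lengths = sorted(self.amplicon_lengths.values())
        for a, b in zip(lengths, lengths[1:]):
            if b - a < 60:
                raise ValueError(
                    "amplicon length classes must differ by >= the "
                    f"demultiplexing margin (got {a} and {b})"
                )

    def error_rate(self, num_passes: int) -> float:
        return self.eps1 / max(1, num_passes)


@dataclass
class LocusTruth:
    locus_id: str
    subfamily: str
    individual: int
    sequence: str
    functional: bool


@dataclass
class ReadOrigin:
    read_id: str
    individual: int
    locus_id: str  # parent A for chimeras
    parent_b: str | None = None
    breakpoint: int | None = None

    @property
    def is_chimera(self) -> bool:
        return self.parent_b is not None


@dataclass
class SimTruth:
    """Ground truth for one simulated experiment."""

    loci: list[LocusTruth] = field(default_factory=list)
    read_origin: dict[str, ReadOrigin] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def loci_of(self, individual: int, subfamily: str | None = None) -> list[LocusTruth]:
        return [
            l
            for l in self.loci
            if l.individual == individual
            and (subfamily is None or l.subfamily == subfamily)
        ]

    def locus_by_id(self, locus_id: str) -> LocusTruth:
        for l in self.loci:
            if l.locus_id == locus_id:
                return l
        raise KeyError(locus_id)


def _random_orf_free_sequence(rng: np.random.Generator, length: int) -> str:
    """Random sequence with no stop codon in reading frame 0."""
    n_codons = length // 3
    codons = []
    while len(codons) < n_codons:
        c = "".join(rng.choice(_BASES, size=3))
        if c not in _STOPS:
            codons.append(c)
    tail = "".join(rng.choice(_BASES, size=length - 3 * n_codons))
    return "".join(codons) + tail


def _substitute(base: str, rng: np.random.Generator) -> str:
    """Draw a substitution with transitions twice as likely as transversions."""
    u = rng.random()
    if u < 0.5:
        return _TRANSITION[base]
    return _TRANSVERSIONS[base][0 if u < 0.75 else 1]


def _creates_frame0_stop(seq: list[str], pos: int) -> bool:
    start = pos - pos % 3
    if start + 3 > len(seq):
        return False
    return "".join(seq[start : start + 3]) in _STOPS


def _diverge(
    ancestor: str,
    rate: float,
    rng: np.random.Generator,
    *,
    keep_orf: bool,
) -> str:
    """Apply per-site substitutions at the given rate; optionally keep the
    frame-0 reading frame stop-free (substitutions that would create an
    in-frame stop are redrawn at another site)."""
    seq = list(ancestor)
    n_sub = rng.binomial(len(seq), rate)
    placed = 0
    attempts = 0
    while placed < n_sub and attempts < 50 * n_sub + 100:
        attempts += 1
        pos = int(rng.integers(len(seq)))
        old = seq[pos]
        new = _substitute(old, rng)
        seq[pos] = new
        if keep_orf and _creates_frame0_stop(seq, pos):
            seq[pos] = old
            continue
        placed += 1
    return "".join(seq)


def _inject_premature_stop(seq: str, codon_idx: int) -> str:
    """Write a TAA stop into the given frame-0 codon."""
    pos = 3 * codon_idx
    return seq[:pos] + "TAA" + seq[pos + 3 :]


def simulate_repertoire(config: SimConfig) -> SimTruth:
    """Generate true locus sequences for each individual and subfamily.

    Per subfamily, ``n_loci_per_subfamily`` paralogs are derived from one
    random ancestor by independent per-locus substitution (2:1 ts:tv); each
    locus diverges from the ancestor by d ~ U(lo/2, hi/2) so that pairwise
    paralog divergence lands in the configured (lo, hi) range.  The two
    individuals share exactly ``round(shared_locus_fraction * n_loci)`` loci;
    shared copies differ between individuals by ``allelic_divergence``.
    Exactly ``round(pseudogene_fraction * n_loci)`` loci per subfamily (the
    same loci in both individuals) carry a premature in-frame stop.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = SimTruth()
    lo, hi = config.target_pairwise_divergence
    n = config.n_loci_per_subfamily
    n_shared = int(round(config.shared_locus_fraction * n))
    n_pseudo = int(round(config.pseudogene_fraction * n))
    if hi / 2 < 0.02 and n > 1:
        truth.warnings.append(
            "configured divergence range may place paralogs above downstream "
            "identity thresholds; clusters may merge distinct loci"
        )

    for subfamily, length in sorted(config.amplicon_lengths.items()):
        ancestor = _random_orf_free_sequence(rng, length)
        pseudo_ids = set(rng.choice(n, size=n_pseudo, replace=False).tolist())
        n_codons = length // 3
        # stop position fixed per locus so a shared pseudogene is the same
        # pseudogene in both individuals
        stop_codon_of = {
            j: int(rng.integers(n_codons // 4, 3 * n_codons // 4))
            for j in sorted(pseudo_ids)
        }

        # base (individual-1) haplotype for every locus index used anywhere
        n_private = n - n_shared
        total_loci = n + n_private * max(0, config.n_individuals - 1)
        base_seqs: list[str] = []
        for _ in range(total_loci):
            d = rng.uniform(lo / 2.0, hi / 2.0)
            base_seqs.append(_diverge(ancestor, d, rng, keep_orf=True))

        for ind in range(1, config.n_individuals + 1):
            for j in range(n):
                if ind == 1 or j < n_shared:
                    idx = j
                else:
                    idx = n + (ind - 2) * n_private + (j - n_shared)
                seq = base_seqs[idx]
                shared = idx < n_shared
                if ind > 1 and shared and config.allelic_divergence > 0:
                    seq = _diverge(
                        seq, config.allelic_divergence, rng, keep_orf=True
                    )
                functional = j not in pseudo_ids
                if not functional:
                    seq = _inject_premature_stop(seq, stop_codon_of[j])
                truth.loci.append(
                    LocusTruth(
                        locus_id=f"{subfamily}_ind{ind}_L{j:03d}",
                        subfamily=subfamily,
                        individual=ind,
                        sequence=seq,
                        functional=functional,
                    )
                )
    return truth


def _apply_errors(
    template: str, eps: float, rng: np.random.Generator, indel_fraction: float
) -> str:
    """Per-base errors: with probability eps a base is hit; 90% of hits are
    substitutions, 10% single-base indels (half deletions, half insertions)."""
    if eps <= 0:
        return template
    out: list[str] = []
    hits = rng.random(len(template)) < eps
    for i, base in enumerate(template):
        if not hits[i]:
            out.append(base)
            continue
        u = rng.random()
        if u >= indel_fraction:  # substitution
            out.append(_substitute(base, rng))
        elif u < indel_fraction / 2:  # deletion
            continue
        else:  # insertion before the base
            out.append(str(rng.choice(_BASES)))
            out.append(base)
    return "".join(out)


def _phred(eps: float) -> int:
    if eps <= 0:
        return QUALITY_CAP
    return min(QUALITY_CAP, int(round(-10.0 * math.log10(eps))))


def simulate_ccs_reads(
    truth: SimTruth, config: SimConfig
) -> dict[int, list[CCSRead]]:
    """Emit CCS reads per individual and record their origins in ``truth``.

    Parent loci are drawn with lognormal weights (PCR abundance bias); the
    pass count p comes from a geometric distribution truncated to
    [pass_min, pass_max]; each base suffers an error with probability
    eps(p); base qualities are the Phred equivalent of eps(p) with small
    integer jitter.  With probability ``chimera_fraction`` a read is a
    two-parent splice at a uniform interior breakpoint (parents drawn from
    the same subfamily).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7001]))
    reads_by_individual: dict[int, list[CCSRead]] = {}
    pass_support = np.arange(config.pass_min, config.pass_max + 1)
    pass_pmf = (1 - config.pass_geometric_p) ** (pass_support - config.pass_min)
    pass_pmf = pass_pmf * config.pass_geometric_p
    pass_pmf /= pass_pmf.sum()

    for ind in range(1, config.n_individuals + 1):
        loci = truth.loci_of(ind)
        reads: list[CCSRead] = []
        if not loci or config.reads_per_individual <= 0:
            logger.warning("individual %d: no loci or zero reads requested", ind)
            reads_by_individual[ind] = reads
            continue
        weights = rng.lognormal(0.0, config.abundance_sigma, size=len(loci))
        weights /= weights.sum()
        by_subfamily: dict[str, list[int]] = {}
        for i, l in enumerate(loci):
            by_subfamily.setdefault(l.subfamily, []).append(i)

        for r in range(config.reads_per_individual):
            read_id = f"ind{ind}_read{r:06d}"
            i = int(rng.choice(len(loci), p=weights))
            parent = loci[i]
            if rng.random() < config.chimera_fraction:
                sibs = [j for j in by_subfamily[parent.subfamily] if j != i]
                if sibs:
                    wsib = weights[sibs] / weights[sibs].sum()
                    j = int(rng.choice(sibs, p=wsib))
                    other = loci[j]
                    l_min = min(len(parent.sequence), len(other.sequence))
                    bp = int(rng.integers(1, l_min))
                    template = parent.sequence[:bp] + other.sequence[bp:]
                    origin = ReadOrigin(
                        read_id, ind, parent.locus_id, other.locus_id, bp
                    )
                else:
                    template = parent.sequence
                    origin = ReadOrigin(read_id, ind, parent.locus_id)
            else:
                template = parent.sequence
                origin = ReadOrigin(read_id, ind, parent.locus_id)

            p = int(rng.choice(pass_support, p=pass_pmf))
            eps = config.error_rate(p)
            seq = _apply_errors(template, eps, rng, config.indel_fraction)
            q0 = _phred(eps)
            if config.quality_jitter_sd > 0:
                jitter = rng.normal(0.0, config.quality_jitter_sd, size=len(seq))
                quals = np.clip(np.rint(q0 + jitter), 0, QUALITY_CAP).astype(int)
            else:
                quals = np.full(len(seq), q0, dtype=int)
            reads.append(
                CCSRead(
                    read_id=read_id,
                    sequence=seq,
                    qualities=tuple(int(q) for q in quals),
                    num_passes=p,
                )
            )
            truth.read_origin[read_id] = origin
        reads_by_individual[ind] = reads
    return reads_by_individual


def mean_quality_by_pass(reads: list[CCSRead]) -> dict[int, float]:
    """Mean per-base Phred quality for each pass count, sorted by pass."""
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for r in reads:
        sums[r.num_passes] = sums.get(r.num_passes, 0.0) + sum(r.qualities)
        counts[r.num_passes] = counts.get(r.num_passes, 0) + len(r.qualities)
    return {p: sums[p] / counts[p] for p in sorted(sums)}


def write_truth(
    truth: SimTruth, reads_by_individual: dict[int, list[CCSRead]], outdir: str | Path
) -> None:
    """Write reads.fastq per individual, truth_loci.fasta and truth_reads.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for ind, reads in sorted(reads_by_individual.items()):
        write_fastq(reads, outdir / f"reads_ind{ind}.fastq")
    write_fasta(
        [
            SequenceRecord(
                id=l.locus_id,
                sequence=l.sequence,
                description=f"subfamily={l.subfamily} individual={l.individual} "
                f"functional={int(l.functional)}",
            )
            for l in truth.loci
        ],
        outdir / "truth_loci.fasta",
    )
    rows = [
        {
            "read_id": o.read_id,
            "individual": o.individual,
            "locus": o.locus_id,
            "parent_b": o.parent_b or "",
            "breakpoint": "" if o.breakpoint is None else o.breakpoint,
            "is_chimera": int(o.is_chimera),
        }
        for o in truth.read_origin.values()
    ]
    write_tsv_report(rows, outdir / "truth_reads.tsv")


def write_config_echo(config: SimConfig, path: str | Path) -> None:
    with open(path, "w") as out:
        for key, value in vars(config).items():
            out.write(f"{key}={value}\n")
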
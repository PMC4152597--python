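"""End-to-end orchestration: filter -> demux -> cluster -> chimera screen ->
consensus -> reading-frame classification -> repertoire estimation, with a
run manifest mirroring the study's count-accounting table.

Every stage's input/output counts are recorded in a :class:`RunManifest`;
the totals are conserved (raw = kept + rejected, per-class + unassigned =
kept, cluster members sum to per-class counts) and a fixed seed plus config
yields byte-identical artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .io_formats import (
    CCSRead,
    SequenceRecord,
    read_fasta,
    read_fastq,
    write_fasta,
    write_tsv_report,
)
from .qc import (
    AmpliconClass,
    DEFAULT_CLASSES,
    QCParams,
    demultiplex_by_length,
    filter_reads,
    rejection_log_rows,
)
from .clustering import (
    ChimeraCall,
    Cluster,
    ClusterParams,
    chimera_report_rows,
    consensus_for_cluster,
    detect_chimeras_de_novo,
    greedy_cluster,
    membership_rows,
)
from .repertoire import (
    ConsensusLocus,
    RepertoireEstimate,
    classify_functionality,
    estimate_repertoire,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    qc: QCParams = field(default_factory=QCParams)
    classes: tuple[AmpliconClass, ...] = DEFAULT_CLASSES
    cluster: ClusterParams = field(default_factory=ClusterParams)
    repertoire_thresholds: tuple[float, float] = (0.98, 0.99)
    reference_fastas: dict[str, str] = field(default_factory=dict)
    include_small_clusters: bool = False
    outdir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.repertoire_thresholds
        if not lo < hi:
            raise ValueError("repertoire thresholds must be strictly ascending")
        for name, path in self.reference_fastas.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"reference set {name!r}: {path}")


@dataclass
class ClassResult:
    """All per-amplicon-class artifacts for one sample."""

    n_reads: int
    clusters: list[Cluster]
    chimera_calls: list[ChimeraCall]
    n_chimeric_clusters: int
    n_clusters_at_coverage: int
    loci: list[ConsensusLocus]  # functional consensus loci
    pseudogene_loci: list[ConsensusLocus]
    estimate: RepertoireEstimate


@dataclass
class SampleResult:
    sample: str
    n_raw: int
    n_kept: int
    n_rejected: int
    n_unassigned: int
    classes: dict[str, ClassResult]


@dataclass
class RunManifest:
    """Stage-by-stage counts for every sample, Table-2 style."""

    samples: dict[str, SampleResult] = field(default_factory=dict)

    def check_conservation(self) -> None:
        for s in self.samples.values():
            if s.n_raw != s.n_kept + s.n_rejected:
                raise AssertionError(f"{s.sample}: raw != kept + rejected")
            per_class = sum(c.n_reads for c in s.classes.values())
            if per_class + s.n_unassigned != s.n_kept:
                raise AssertionError(f"{s.sample}: class counts != kept")
            for name, c in s.classes.items():
                members = sum(cl.size for cl in c.clusters)
                if members != c.n_reads:
                    raise AssertionError(
                        f"{s.sample}/{name}: cluster members != class reads"
                    )


def _reads_to_records(reads: list[CCSRead]) -> list[SequenceRecord]:
    return [SequenceRecord(id=r.read_id, sequence=r.sequence) for r in reads]


def process_class(
    reads: list[CCSRead],
    config: PipelineConfig,
    *,
    sample: str = "",
    class_name: str = "",
    outdir: Path | None = None,
) -> ClassResult:
    """Cluster one amplicon class and carry it through to a repertoire."""
    records = _reads_to_records(reads)
    record_by_id = {r.id: r for r in records}
    clusters = greedy_cluster(records, config.cluster)
    calls = detect_chimeras_de_novo(clusters, config.cluster)
    chimeric_ids = {c.query_id for c in calls if c.is_chimera}
    surviving = [c for c in clusters if c.centroid_id not in chimeric_ids]

    loci: list[ConsensusLocus] = []
    pseudogenes: list[ConsensusLocus] = []
    n_at_coverage = 0
    for idx, cluster in enumerate(surviving):
        if cluster.size >= config.cluster.min_cluster_size:
            n_at_coverage += 1
        consensus = consensus_for_cluster(
            cluster,
            [record_by_id[i] for i in cluster.member_ids],
            config.cluster.min_cluster_size,
            allow_small=config.include_small_clusters,
        )
        if consensus is None:
            continue
        cluster.consensus = consensus
        functional, frame = classify_functionality(consensus)
        locus = ConsensusLocus(
            id=f"{sample}_{class_name}_c{idx:04d}",
            sequence=consensus,
            subfamily=class_name,
            coverage=cluster.size,
            functional=functional,
            frame_offset=frame,
        )
        (loci if functional else pseudogenes).append(locus)

    estimate = estimate_repertoire(loci, config.repertoire_thresholds)
    result = ClassResult(
        n_reads=len(reads),
        clusters=clusters,
        chimera_calls=calls,
        n_chimeric_clusters=len(chimeric_ids),
        n_clusters_at_coverage=n_at_coverage,
        loci=loci,
        pseudogene_loci=pseudogenes,
        estimate=estimate,
    )
    if outdir is not None:
        prefix = outdir / f"{sample}.{class_name}"
        write_tsv_report(membership_rows(clusters), f"{prefix}.clusters.tsv")
        write_tsv_report(chimera_report_rows(calls), f"{prefix}.chimeras.tsv")
        write_fasta(
            [SequenceRecord(id=l.id, sequence=l.sequence,
                            description=f"coverage={l.coverage}")
             for l in loci],
            f"{prefix}.loci.fasta",
        )
    return result


def run_sample(
    sample: str,
    reads: list[CCSRead],
    config: PipelineConfig,
    *,
    outdir: Path | None = None,
) -> SampleResult:
    kept, rejected = filter_reads(reads, config.qc)
    logger.info("%s: %d raw, %d post-filter", sample, len(reads), len(kept))
    by_class, unassigned = demultiplex_by_length(kept, config.classes)
    if outdir is not None:
        write_tsv_report(rejection_log_rows(rejected),
                         outdir / f"{sample}.rejections.tsv")
    classes: dict[str, ClassResult] = {}
    for name in sorted(by_class):
        classes[name] = process_class(
            by_class[name], config, sample=sample, class_name=name,
            outdir=outdir,
        )
        logger.info(
            "%s/%s: %d reads, %d clusters (%d >= %dx), %d chimeric, "
            "%d pseudogene, repertoire %d-%d",
            sample, name, classes[name].n_reads, len(classes[name].clusters),
            classes[name].n_clusters_at_coverage,
            config.cluster.min_cluster_size,
            classes[name].n_chimeric_clusters,
            len(classes[name].pseudogene_loci),
            classes[name].estimate.min_loci, classes[name].estimate.max_loci,
        )
    return SampleResult(
        sample=sample,
        n_raw=len(reads),
        n_kept=len(kept),
        n_rejected=len(rejected),
        n_unassigned=len(unassigned),
        classes=classes,
    )


def run_pipeline(
    reads_by_sample: dict[str, list[CCSRead]],
    config: PipelineConfig | None = None,
) -> RunManifest:
    """Run every stage on every sample and return the count manifest.

    Artifacts (cluster membership, chimera reports, locus FASTAs, the
    manifest table) are written under ``config.outdir`` when set.
    """
    config = config or PipelineConfig()
    config.validate()
    outdir = None
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest()
    for sample in sorted(reads_by_sample):
        manifest.samples[sample] = run_sample(
            sample, reads_by_sample[sample], config, outdir=outdir
        )
    manifest.check_conservation()
    if outdir is not None:
        write_tsv_report(
            report_table_rows(manifest),
            outdir / "manifest.tsv",
            columns=["row"] + sorted(manifest.samples),
        )
    return manifest


def run_pipeline_from_files(
    fastq_by_sample: dict[str, str | Path],
    config: PipelineConfig | None = None,
) -> RunManifest:
    reads = {s: read_fastq(p) for s, p in fastq_by_sample.items()}
    return run_pipeline(reads, config)


def report_table_rows(manifest: RunManifest) -> list[list[object]]:
    """Rows of the summary table: one column per sample.

    Row order mirrors the published accounting: raw reads, post-filter,
    per-class reads, clusters at coverage, loci bracket, estimated
    repertoire (= maximum of the bracket, the novel-inclusive estimate).
    """
    samples = sorted(manifest.samples)
    class_names = sorted(
        {name for s in samples for name in manifest.samples[s].classes}
    )
    rows: list[list[object]] = [
        ["Raw CCS reads"] + [manifest.samples[s].n_raw for s in samples],
        ["Post quality filter"] + [manifest.samples[s].n_kept for s in samples],
    ]
    for name in class_names:
        rows.append(
            [f"{name} reads"]
            + [
                manifest.samples[s].classes.get(name).n_reads
                if name in manifest.samples[s].classes
                else 0
                for s in samples
            ]
        )
    for name in class_names:
        rows.append(
            [f"{name} clusters (>=7x)"]
            + [
                manifest.samples[s].classes[name].n_clusters_at_coverage
                if name in manifest.samples[s].classes
                else 0
                for s in samples
            ]
        )
    for name in class_names:
        vals = []
        for s in samples:
            c = manifest.samples[s].classes.get(name)
            vals.append(
                f"{c.estimate.min_loci}-{c.estimate.max_loci}" if c else "0-0"
            )
        rows.append([f"{name} loci (98 to 99%)"] + vals)
    for name in class_names:
        rows.append(
            [f"Estimated {name} repertoire"]
            + [
                manifest.samples[s].classes[name].estimate.min_loci
                if name in manifest.samples[s].classes
                else 0
                for s in samples
            ]
        )
    return rows


def load_reference_loci(path: str | Path, subfamily: str = "") -> list[ConsensusLocus]:
    """Read a reference locus FASTA into ConsensusLocus records."""
    return [
        ConsensusLocus(id=r.id, sequence=r.sequence, subfamily=subfamily)
        for r in read_fasta(path)
    ]
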
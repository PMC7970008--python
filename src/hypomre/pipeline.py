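"""Stage orchestration: config, per-stage drivers, manifest.

Stages communicate exclusively through serialized artifacts in the run
directory (FASTQ/FASTA/TSV/BED/VCF), never through in-memory state, so any
stage can be re-run or replaced independently. Every artifact is listed in
``manifest.json`` with a sha256 checksum; deterministic stages reproduce
identical checksums for identical configs and seeds.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import assembly, dmr, go, merge, popstruct, qc, variants
from ._io import ensure_dir, iter_fastq, read_fasta, sha256_file, write_fasta
from .simulate import SimConfig, simulate

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class QCParams:
    min_q: int = 30
    min_len: int = 50
    max_n_frac: float = 0.1
    k: int = 31
    min_frac: float = 0.5
    write_rejected: bool = False


@dataclass
class MergeParams:
    min_overlap: int = 10
    max_overlap: int = 250
    max_mismatch_density: float = 0.25


@dataclass
class AssemblyParams:
    k: int = 31
    # "auto" picks the solid-k-mer cutoff from the count histogram; at the
    # default sequencing depth recurrent errors exceed any small fixed value
    min_kmer_count: int | str = "auto"
    min_contig_len: int = 100
    min_reads: int = 5
    seed_k: int = 31
    min_identity: float = 0.9
    per_accession: bool = True  # also build single-accession assemblies


@dataclass
class DMRParams:
    min_cov: int = 1
    min_region_len: int = 50


@dataclass
class VariantParams:
    min_cov: int = 10
    score_threshold: float = 180.0
    bases: str = "ACGTgap"
    all_scores: bool = False


@dataclass
class GOParams:
    top_n: int = 50
    linkage: str = "average"
    distance: str = "euclidean"
    annotation: str | None = None  # user contig->GO TSV; None = derive from sim truth


@dataclass
class PCAParams:
    min_cov: int = 10


@dataclass
class PipelineConfig:
    seed: int = 0
    threads: int = 1  # accepted for interface compatibility; execution is
    # single-threaded so outputs never depend on scheduling
    log_level: str = "INFO"
    sim: SimConfig = field(default_factory=SimConfig)
    qc: QCParams = field(default_factory=QCParams)
    merge: MergeParams = field(default_factory=MergeParams)
    assembly: AssemblyParams = field(default_factory=AssemblyParams)
    dmr: DMRParams = field(default_factory=DMRParams)
    variants: VariantParams = field(default_factory=VariantParams)
    go: GOParams = field(default_factory=GOParams)
    pca: PCAParams = field(default_factory=PCAParams)

    def __post_init__(self):
        self.sim.seed = self.seed

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        blocks = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, val in data.items():
            if key not in blocks:
                raise ConfigError(f"unknown config key {key!r}")
            f = blocks[key]
            if dataclasses.is_dataclass(f.default_factory) or key in (
                "sim", "qc", "merge", "assembly", "dmr", "variants", "go", "pca",
            ):
                sub_cls = f.default_factory
                known = {sf.name for sf in dataclasses.fields(sub_cls)}
                unknown = set(val) - known
                if unknown:
                    raise ConfigError(f"unknown key(s) {sorted(unknown)} in block {key!r}")
                kwargs[key] = sub_cls(**val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# stage drivers (file-in, file-out)


def _accessions(cfg: PipelineConfig) -> list[str]:
    return cfg.sim.accession_ids()


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    simulate(cfg.sim, outdir / "sim")


def stage_qc(cfg: PipelineConfig, outdir: Path) -> None:
    sim = outdir / "sim"
    qcdir = ensure_dir(outdir / "qc")
    index = qc.ContaminantIndex.from_fasta(sim / "contaminants.fasta", cfg.qc.k)
    stats = []
    for acc in _accessions(cfg):
        s1, s2 = qc.run_qc(
            sim / f"{acc}_R1.fastq",
            sim / f"{acc}_R2.fastq",
            index,
            qcdir / f"{acc}_R1.fastq",
            qcdir / f"{acc}_R2.fastq",
            accession=acc,
            min_q=cfg.qc.min_q,
            min_len=cfg.qc.min_len,
            max_n_frac=cfg.qc.max_n_frac,
            min_frac=cfg.qc.min_frac,
            rejected_path=(qcdir / f"{acc}_rejected.fastq") if cfg.qc.write_rejected else None,
        )
        stats.extend([s1, s2])
    qc.qc_report(stats).to_csv(qcdir / "qc_report.tsv", sep="\t", index=False)


def stage_merge(cfg: PipelineConfig, outdir: Path) -> None:
    qcdir = outdir / "qc"
    mdir = ensure_dir(outdir / "merge")
    stats = []
    for acc in _accessions(cfg):
        stats.append(
            merge.run_merge(
                qcdir / f"{acc}_R1.fastq",
                qcdir / f"{acc}_R2.fastq",
                mdir / f"{acc}_merged.fastq",
                accession=acc,
                min_overlap=cfg.merge.min_overlap,
                max_overlap=cfg.merge.max_overlap,
                max_mismatch_density=cfg.merge.max_mismatch_density,
            )
        )
    merge.merge_stats_table(stats).to_csv(mdir / "merge_stats.tsv", sep="\t", index=False)


def _merged_reads(outdir: Path, acc: str) -> list[tuple[str, str]]:
    return [(rid, seq) for rid, seq, _ in iter_fastq(outdir / "merge" / f"{acc}_merged.fastq")]


def stage_assemble(cfg: PipelineConfig, outdir: Path) -> None:
    """Per-accession assemblies and their read-inclusion stats."""
    p = cfg.assembly
    if not p.per_accession:
        return
    adir = ensure_dir(outdir / "assembly")
    rows = []
    for acc in _accessions(cfg):
        reads = _merged_reads(outdir, acc)
        contigs = assembly.assemble(
            (s for _, s in reads), p.k, p.min_kmer_count, p.min_contig_len, source=acc
        )
        alns, _ = assembly.map_reads(reads, contigs, p.seed_k, p.min_identity)
        retained = assembly.retain_contigs(contigs, alns, p.min_reads)
        kept = {c.contig_id for c in retained}
        alns = [a for a in alns if a.contig_id in kept]
        write_fasta(adir / f"{acc}_contigs.fasta", [(c.contig_id, c.seq) for c in retained])
        rows.append(assembly.assembly_stats(retained, {acc: (alns, len(reads))}))
    pd.concat(rows, ignore_index=True).to_csv(
        adir / "assembly_stats.tsv", sep="\t", index=False
    )


def stage_reference(cfg: PipelineConfig, outdir: Path) -> None:
    """Pooled reference hypomethylome + per-accession alignments to it."""
    rdir = ensure_dir(outdir / "reference")
    p = cfg.assembly
    per_acc = {acc: _merged_reads(outdir, acc) for acc in _accessions(cfg)}
    contigs, alns, stats = assembly.build_reference_hypomethylome(
        per_acc, p.k, p.min_kmer_count, p.min_contig_len, p.min_reads,
        p.seed_k, p.min_identity,
    )
    write_fasta(rdir / "reference_contigs.fasta", [(c.contig_id, c.seq) for c in contigs])
    stats.to_csv(rdir / "reference_stats.tsv", sep="\t", index=False)
    for acc in sorted(alns):
        assembly.alignments_to_frame(alns[acc]).to_csv(
            rdir / f"{acc}_alignments.tsv", sep="\t", index=False
        )


def stage_pileup(cfg: PipelineConfig, outdir: Path) -> None:
    rdir = outdir / "reference"
    pdir = ensure_dir(outdir / "pileup")
    contigs = _load_contigs(outdir)
    for acc in _accessions(cfg):
        reads = dict(_merged_reads(outdir, acc))
        df = pd.read_csv(rdir / f"{acc}_alignments.tsv", sep="\t")
        alns = [
            assembly.Alignment(r.read_id, r.contig_id, int(r.start), r.strand,
                               int(r.matches), int(r.length), int(r.read_start))
            for r in df.itertuples()
        ]
        arrays = assembly.pileup(alns, contigs, reads)
        assembly.pileup_to_frame(arrays).to_csv(
            pdir / f"{acc}_pileup.tsv", sep="\t", index=False
        )


def _load_contigs(outdir: Path) -> list[assembly.Contig]:
    seqs = read_fasta(outdir / "reference" / "reference_contigs.fasta")
    return [assembly.Contig(cid, seq) for cid, seq in seqs.items()]


def _load_pileups(cfg: PipelineConfig, outdir: Path) -> dict[str, dict]:
    lengths = {c.contig_id: len(c.seq) for c in _load_contigs(outdir)}
    out = {}
    for acc in _accessions(cfg):
        df = pd.read_csv(outdir / "pileup" / f"{acc}_pileup.tsv", sep="\t")
        out[acc] = assembly.frame_to_pileup(df, lengths)
    return out


def stage_dmr(cfg: PipelineConfig, outdir: Path) -> None:
    ddir = ensure_dir(outdir / "dmr")
    pileups = _load_pileups(cfg, outdir)
    covs = {a: dmr.coverage_from_pileup(p, cfg.dmr.min_cov) for a, p in pileups.items()}
    accs = sorted(covs)
    pairwise = {}
    for a in accs:
        for b in accs:
            if a != b:
                pairwise[(a, b)] = dmr.pairwise_dmr(
                    covs[a], covs[b], a, b, cfg.dmr.min_region_len
                )
    uniq = dmr.unique_regions(covs, cfg.dmr.min_region_len)
    all_regions = [r for rs in pairwise.values() for r in rs]
    all_regions += [r for rs in uniq.values() for r in rs]
    dmr.regions_to_bed(all_regions).to_csv(
        ddir / "dmr_regions.bed", sep="\t", index=False, header=False
    )
    dmr.dmr_summary(pairwise).to_csv(ddir / "dmr_pairwise.tsv", sep="\t", index=False)
    dmr.unique_summary(uniq).to_csv(ddir / "dmr_unique.tsv", sep="\t", index=False)


def stage_variants(cfg: PipelineConfig, outdir: Path) -> None:
    vdir = ensure_dir(outdir / "variants")
    pileups = _load_pileups(cfg, outdir)
    p = cfg.variants
    calls = variants.call_all_pairs(pileups, p.min_cov, p.score_threshold, p.bases)
    variants.variants_to_frame(calls).to_csv(vdir / "variants.tsv", sep="\t", index=False)
    variants.pairwise_difference_table(calls).to_csv(vdir / "pairwise_counts.tsv", sep="\t")
    contig_seqs = read_fasta(outdir / "reference" / "reference_contigs.fasta")
    variants.write_vcf(calls, contig_seqs, vdir / "variants.vcf")
    if p.all_scores:
        scored = variants.call_all_pairs(pileups, p.min_cov, p.score_threshold, p.bases, True)
        variants.variants_to_frame(scored).to_csv(
            vdir / "all_scores.tsv", sep="\t", index=False
        )


def _contig_annotation(cfg: PipelineConfig, outdir: Path) -> dict[str, frozenset[str]]:
    """Contig -> GO terms: user table, or derived by locating contigs on the
    simulated genome with the package's gapless mapper."""
    if cfg.go.annotation:
        path = Path(cfg.go.annotation)
        if not path.exists():
            raise StageError("go", f"annotation file {path} not found")
        return go.load_annotation(path)
    sim = outdir / "sim"
    if not (sim / "genome.fasta").exists():
        raise StageError(
            "go", "no annotation configured and no simulated genome to derive one from"
        )
    genome = read_fasta(sim / "genome.fasta")
    feats = pd.read_csv(sim / "features.tsv", sep="\t")
    genes = feats[feats["class"] == "gene"]
    gene_iv = [
        (int(r.start), int(r.end), tuple((r.go_terms or "-").split(",")))
        for r in genes.itertuples()
        if r.go_terms != "-"
    ]
    targets = [assembly.Contig(gid, seq) for gid, seq in genome.items()]
    index = assembly.ContigIndex(targets, cfg.assembly.seed_k)
    ann: dict[str, frozenset[str]] = {}
    for c in _load_contigs(outdir):
        aln = assembly.map_read(c.contig_id, c.seq, index, cfg.assembly.min_identity)
        if aln is None:
            continue
        s, e = aln.start, aln.start + aln.length
        terms = set()
        for gs, ge, gterms in gene_iv:
            if gs < e and s < ge:
                terms.update(gterms)
        if terms:
            ann[c.contig_id] = frozenset(terms)
    return ann


def stage_go(cfg: PipelineConfig, outdir: Path) -> None:
    gdir = ensure_dir(outdir / "go")
    annotation = _contig_annotation(cfg, outdir)
    with open(gdir / "contig_go.tsv", "w") as fh:
        fh.write("contig_id\tgo_terms\n")
        for cid in sorted(annotation):
            fh.write(f"{cid}\t{','.join(sorted(annotation[cid]))}\n")
    pileups = _load_pileups(cfg, outdir)
    p = cfg.variants
    thr = variants.call_all_pairs(pileups, p.min_cov, p.score_threshold, p.bases)
    # the unthresholded analysis keeps every observed difference (score > 0)
    nothr = variants.call_all_pairs(pileups, p.min_cov, 0.0, p.bases)
    known = {c.contig_id for c in _load_contigs(outdir)}
    att_thr = go.attribute_variants(thr)
    att_all = go.attribute_variants(nothr)
    summary = go.go_summary_table(
        go.count_go_polymorphisms(att_thr, annotation, known),
        go.count_go_polymorphisms(att_all, annotation, known),
    )
    summary.to_csv(gdir / "go_summary.tsv", sep="\t", index=False)
    counts = go.go_count_matrix(att_thr, annotation)
    if len(counts) >= 1 and counts.shape[1] >= 2:
        gom = go.top_go_matrix(counts, cfg.go.top_n, cfg.go.linkage, cfg.go.distance)
        gom.matrix.to_csv(gdir / "go_matrix.tsv", sep="\t")
        with open(gdir / "go_cluster_orders.json", "w") as fh:
            json.dump({"rows": gom.row_order, "cols": gom.col_order}, fh, indent=1)
    else:
        counts.to_csv(gdir / "go_matrix.tsv", sep="\t")


def stage_pca(cfg: PipelineConfig, outdir: Path) -> None:
    pdir = ensure_dir(outdir / "pca")
    pileups = _load_pileups(cfg, outdir)
    p = cfg.variants
    calls = variants.call_all_pairs(pileups, p.min_cov, p.score_threshold, p.bases)
    pos = [v for vs in calls.values() for v in vs]
    matrix = popstruct.build_matrix(pos, pileups, cfg.pca.min_cov)
    matrix.values.to_csv(pdir / "frequency_matrix.tsv", sep="\t")
    if matrix.values.shape[1] == 0:
        log.warning("no variant columns passed the coverage gate; PCA skipped")
        pd.DataFrame(columns=["component", "eigenvalue", "explained_pct"]).to_csv(
            pdir / "pca_eigenvalues.tsv", sep="\t", index=False
        )
        return
    res = popstruct.run_pca(matrix)
    ev, proj = popstruct.pca_tables(res)
    ev.to_csv(pdir / "pca_eigenvalues.tsv", sep="\t", index=False)
    proj.to_csv(pdir / "pca_projections.tsv", sep="\t", index=False)


STAGES = [
    ("simulate", stage_simulate),
    ("qc", stage_qc),
    ("merge", stage_merge),
    ("assemble", stage_assemble),
    ("reference", stage_reference),
    ("pileup", stage_pileup),
    ("dmr", stage_dmr),
    ("variants", stage_variants),
    ("go", stage_go),
    ("pca", stage_pca),
]


def write_manifest(outdir: Path) -> dict:
    artifacts = sorted(
        p for p in outdir.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        str(p.relative_to(outdir)): sha256_file(p) for p in artifacts
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def run_pipeline(cfg: PipelineConfig, outdir, stages=None) -> dict:
    """Run the stage chain; returns the artifact manifest.

    A stage failure halts the run with a stage-tagged error; outputs of the
    completed stages are retained for inspection.
    """
    out = ensure_dir(outdir)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    cfg.to_yaml(out / "pipeline_config.yaml")
    wanted = set(stages) if stages else {name for name, _ in STAGES}
    for name, fn in STAGES:
        if name not in wanted:
            continue
        log.info("stage %s", name)
        try:
            fn(cfg, out)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-tag for the operator
            raise StageError(name, str(exc)) from exc
    return write_manifest(out)
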
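"""End-to-end pipeline and congruence scoring between classifications.

Agreement between the ANI-based and the domain-based partitions (and of
either against planted truth) is quantified with the adjusted Rand index on
the flat cluster assignments; a cophenetic-correlation helper is provided
for tree-level comparison.  ``run_pipeline`` wires the whole analysis
together on a synthetic community and writes a self-describing report
bundle that is byte-identical under a fixed seed.
"""

from __future__ import annotations

import json
import logging
import shutil
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import cophenet
from scipy.stats import pearsonr
from sklearn.metrics import adjusted_rand_score

from . import ani as ani_mod
from . import genome_io
from .dendrogram import Dendrogram
from .domains import (
    ClusterAssignment,
    build_pa_matrix,
    cut_and_flag,
    lifestyle_flags,
    ward_dendrogram,
)
from .synthetic import (
    CommunitySpec,
    TerminiModel,
    default_community_spec,
    plant_community,
    simulate_packaged_reads,
    write_cluster_truth,
    write_domain_table,
    write_fastq,
    write_read_truth,
)
from .termini import build_coverage, classify_termini, map_reads, write_bedgraph

logger = logging.getLogger(__name__)


@dataclass
class CongruenceResult:
    adjusted_rand: float
    n_genomes: int
    partition_a_k: int
    partition_b_k: int


def _as_labels(partition: ClusterAssignment | Mapping[str, str]) -> dict[str, str]:
    if isinstance(partition, ClusterAssignment):
        return dict(partition.labels)
    return {str(k): str(v) for k, v in partition.items()}


def adjusted_rand(
    labels_a: ClusterAssignment | Mapping[str, str],
    labels_b: ClusterAssignment | Mapping[str, str],
) -> float:
    """Chance-corrected Rand agreement between two partitions of one set.

    1.0 iff the partitions are identical up to relabelling; ~0 for
    independent partitions.  Raises on mismatched genome sets.
    """
    a = _as_labels(labels_a)
    b = _as_labels(labels_b)
    if set(a) != set(b):
        raise ValueError("partitions cover different genome id sets")
    ids = sorted(a)
    return float(adjusted_rand_score([a[g] for g in ids], [b[g] for g in ids]))


def compare_partitions(
    labels_a: ClusterAssignment | Mapping[str, str],
    labels_b: ClusterAssignment | Mapping[str, str],
) -> CongruenceResult:
    a = _as_labels(labels_a)
    b = _as_labels(labels_b)
    ari = adjusted_rand(a, b)
    return CongruenceResult(
        adjusted_rand=ari,
        n_genomes=len(a),
        partition_a_k=len(set(a.values())),
        partition_b_k=len(set(b.values())),
    )


def to_newick(dendrogram: Dendrogram) -> str:
    return dendrogram.to_newick()


def cophenetic_correlation(dendrogram_a: Dendrogram, dendrogram_b: Dendrogram) -> float:
    """Pearson correlation of cophenetic distances between two trees over
    the same leaves (tree-level congruence, as opposed to cut-level)."""
    if sorted(dendrogram_a.ids) != sorted(dendrogram_b.ids):
        raise ValueError("dendrograms cover different leaf sets")

    def _coph(d: Dendrogram) -> pd.DataFrame:
        c = cophenet(d.linkage)
        from scipy.spatial.distance import squareform

        return pd.DataFrame(squareform(c), index=d.ids, columns=d.ids)

    ca = _coph(dendrogram_a)
    cb = _coph(dendrogram_b).loc[ca.index, ca.columns]
    iu = np.triu_indices(len(ca), k=1)
    r, _ = pearsonr(ca.to_numpy()[iu], cb.to_numpy()[iu])
    return float(r)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


_TERMINI_CYCLE = ("HEADFUL_PAC", "DTR_SHORT", "DTR_LONG")


@dataclass
class PipelineConfig:
    """Everything the end-to-end synthetic run needs, in one place."""

    outdir: str | Path = "phage_profiler_out"
    seed: int = 0
    community: CommunitySpec | None = None
    target_depth: float = 30.0
    read_length: int = 150
    error_rate: float = 0.005
    fixed_start_fraction: float = 0.5
    ani: ani_mod.ANIConfig = field(default_factory=ani_mod.ANIConfig)
    linkage_method: str = "average"
    evalue_cutoff: float = 0.001
    n_clusters: int | None = None  # default: true number of planted groups
    singleton_min_shared: int = 3
    ratio_threshold: float = 1.6
    min_repeat_bp: int = 200
    long_dtr_threshold_bp: int = 2000
    peak_factor: float = 3.0
    write_reads: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "community" in raw and raw["community"] is not None:
            from .synthetic import ClusterSpec

            comm = raw["community"]
            raw["community"] = CommunitySpec(
                clusters=[ClusterSpec(**c) for c in comm.pop("clusters")], **comm
            )
        if "ani" in raw and raw["ani"] is not None:
            raw["ani"] = ani_mod.ANIConfig(**raw["ani"])
        return cls(**raw)


def _termini_model_for(kind: str, genome_length: int, read_length: int, rng: np.random.Generator) -> TerminiModel:
    if kind == "DTR_SHORT":
        return TerminiModel(kind="DTR", repeat_length=1000)
    if kind == "DTR_LONG":
        return TerminiModel(kind="DTR", repeat_length=min(12000, genome_length // 3))
    if kind == "HEADFUL_PAC":
        pac = int(rng.integers(0, genome_length))
        return TerminiModel(kind="HEADFUL_PAC", pac_position=pac)
    return TerminiModel(kind="NONE")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic characterisation pipeline and write a bundle.

    Stages: community generation, genome features, read simulation + termini
    calls, ANI matrix + tree, domain matrix + tree, cluster assignments,
    congruence.  Deterministic under a fixed seed; on any stage failure the
    partially written bundle is removed and a stage-named error is raised.
    """
    outdir = Path(config.outdir)
    if outdir.exists() and any(outdir.iterdir()):
        raise ValueError(f"output directory {outdir} exists and is not empty")
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        t0 = time.monotonic()
        spec = config.community or default_community_spec(seed=config.seed)
        root = np.random.SeedSequence(config.seed)
        ss_termini, ss_reads = root.spawn(2)
        model_rng = np.random.default_rng(ss_termini)

        stage = "simulate"
        logger.info("stage simulate: planting community")
        records, tables, truth = plant_community(spec)
        genome_io.write_fasta(records, outdir / "genomes.fasta")
        write_cluster_truth(truth, outdir / "cluster_truth.tsv")
        all_hits = [h for gid in sorted(tables) for h in tables[gid]]
        write_domain_table(all_hits, outdir / "domain_hits.tsv")

        stage = "features"
        logger.info("stage features: ORF scan and genome summary")
        for rec in records:
            rec.orf_count = len(genome_io.find_orfs(rec.sequence))
            rec.lifestyle_flag = lifestyle_flags(tables[rec.id])

        stage = "termini"
        logger.info("stage termini: read simulation, mapping, classification")
        read_seeds = ss_reads.generate_state(len(records))
        truth_models: dict[str, str] = {}
        termini_rows = []
        label_order = {lab: i for i, lab in enumerate(sorted(set(truth.labels.values())))}
        reads_dir = outdir / "reads"
        if config.write_reads:
            reads_dir.mkdir()
        for i, rec in enumerate(sorted(records, key=lambda r: r.id)):
            kind = _TERMINI_CYCLE[label_order[truth.labels[rec.id]] % len(_TERMINI_CYCLE)]
            model = _termini_model_for(kind, rec.length_bp, config.read_length, model_rng)
            truth_models[rec.id] = kind
            readset = simulate_packaged_reads(
                rec.sequence,
                model,
                target_depth=config.target_depth,
                read_length=config.read_length,
                error_rate=config.error_rate,
                seed=int(read_seeds[i]) % (2**31),
                fixed_start_fraction=config.fixed_start_fraction,
            )
            if config.write_reads:
                write_fastq(readset, reads_dir / f"{rec.id}.fastq")
                write_read_truth(readset, reads_dir / f"{rec.id}.truth.tsv")
            aln = map_reads(readset, rec.sequence)
            profile = build_coverage(aln)
            call = classify_termini(
                profile,
                long_dtr_threshold_bp=config.long_dtr_threshold_bp,
                ratio_threshold=config.ratio_threshold,
                min_repeat_bp=config.min_repeat_bp,
                peak_factor=config.peak_factor,
            )
            rec.termini_class = call.klass
            write_bedgraph(profile, rec.id, outdir / f"coverage_{rec.id}.bedgraph")
            termini_rows.append(
                {
                    "genome_id": rec.id,
                    "termini_class": call.klass,
                    "true_model": kind,
                    "dtr_start": call.dtr_interval[0] if call.dtr_interval else "",
                    "dtr_end": call.dtr_interval[1] if call.dtr_interval else "",
                    "pac_position": call.pac_position if call.pac_position is not None else "",
                    "mapped_fraction": round(aln.mapped_fraction, 4),
                }
            )
        pd.DataFrame(termini_rows).to_csv(outdir / "termini_calls.tsv", sep="\t", index=False)

        stage = "features_table"
        genome_io.write_summary_tsv(records, outdir / "genome_features.tsv")

        stage = "ani"
        logger.info("stage ani: pairwise ANIb and clustering")
        matrix = ani_mod.ani_matrix({r.id: r.sequence for r in records}, config.ani)
        ani_mod.write_ani_tsv(matrix, outdir / "ani_matrix.tsv")
        ani_tree = ani_mod.cluster_ani(matrix, method=config.linkage_method)
        ani_tree.write_newick(outdir / "ani_tree.nwk")

        stage = "domains"
        logger.info("stage domains: presence-absence matrix and Ward tree")
        pa = build_pa_matrix(tables)
        pa.to_csv(outdir / "pa_matrix.tsv", sep="\t")
        domain_tree = ward_dendrogram(pa)
        domain_tree.write_newick(outdir / "domain_tree.nwk")

        stage = "assignment"
        k = config.n_clusters or len(set(truth.labels.values()))
        domain_assign = cut_and_flag(
            domain_tree, pa, n_clusters=k, singleton_min_shared=config.singleton_min_shared
        )
        ani_labels = {g: f"ani_{lab}" for g, lab in ani_tree.cut(n_clusters=k).items()}
        assign_df = pd.DataFrame(
            {
                "genome_id": sorted(truth.labels),
                "truth": [truth.labels[g] for g in sorted(truth.labels)],
                "ani_cluster": [ani_labels[g] for g in sorted(truth.labels)],
                "domain_cluster": [domain_assign.labels[g] for g in sorted(truth.labels)],
                "domain_singleton": [int(g in domain_assign.singletons) for g in sorted(truth.labels)],
            }
        )
        assign_df.to_csv(outdir / "assignments.tsv", sep="\t", index=False)

        stage = "congruence"
        cross = compare_partitions(ani_labels, domain_assign)
        result = {
            "n_genomes": len(records),
            "ani_vs_truth_ari": adjusted_rand(ani_labels, truth.labels),
            "domain_vs_truth_ari": adjusted_rand(domain_assign, truth.labels),
            "cross_method_ari": cross.adjusted_rand,
            "n_singletons_flagged": len(domain_assign.singletons),
            "termini_correct": sum(
                1 for row in termini_rows if row["termini_class"] == row["true_model"]
            ),
            "termini_total": len(termini_rows),
        }
        provenance = {
            "seed": config.seed,
            "target_depth": config.target_depth,
            "read_length": config.read_length,
            "error_rate": config.error_rate,
            "fixed_start_fraction": config.fixed_start_fraction,
            "ani": asdict(config.ani),
            "linkage_method": config.linkage_method,
            "evalue_cutoff": config.evalue_cutoff,
            "n_clusters": k,
            "singleton_min_shared": config.singleton_min_shared,
            "ratio_threshold": config.ratio_threshold,
            "min_repeat_bp": config.min_repeat_bp,
            "long_dtr_threshold_bp": config.long_dtr_threshold_bp,
            "peak_factor": config.peak_factor,
            "community": {
                "clusters": [asdict(c) for c in spec.clusters],
                "n_singletons": spec.n_singletons,
                "shared_domain_fraction": spec.shared_domain_fraction,
                "seed": spec.seed,
                "singleton_length": spec.singleton_length,
                "singleton_gc": spec.singleton_gc,
            },
        }
        with open(outdir / "report.json", "w") as fh:
            json.dump(
                {"results": result, "provenance": provenance}, fh, indent=2, sort_keys=True
            )
            fh.write("\n")
        logger.info("pipeline finished in %.1f s", time.monotonic() - t0)
        return result
    except Exception as exc:
        shutil.rmtree(outdir, ignore_errors=True)
        raise PipelineError(stage, exc) from exc
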
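"""End-to-end orchestration: filter -> assign -> motif check -> classify ->
cluster -> report.

The pipeline consumes sequences, a profile/domain hit table and a canonical
registry; rows whose target name is a registry subfamily are treated as
kinase-subfamily profile hits (for candidate filtering and subfamily
assignment), all other rows as Pfam-style domain hits (for architecture
building).  Outputs are a master per-kinase results table, a per-label
summary, the LMS distance matrix, the Ward dendrogram (Newick) and the
per-cluster entropy report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import annotation, architecture, clap
from .io import DomainHit, SequenceRecord, parse_domain_hits, read_fasta
from .registry import CanonicalRegistry, load_canonical_registry

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "run_pipeline_files", "summarize"]

log = logging.getLogger("kinout")


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable thresholds, with the study defaults."""

    min_len: int = 200                # kinase candidates must be longer than this
    max_evalue: float = 1e-4          # subfamily-profile hit e-value ceiling
    min_coverage: float = 0.70        # profile coverage floor
    min_identity: float = 0.30        # subfamily assignment identity floor
    domain_evalue: float = 0.01       # Pfam-style domain hit e-value ceiling
    min_overhang: int = 100           # N/C overhang flag threshold (residues)
    max_overlap: int = 10             # tolerated overlap during domain resolution
    insert_window: int = 50           # low-complexity scan window (residues)
    nq_threshold: float = 0.4         # N+Q fraction flag threshold
    cut_fraction: float = 0.25        # dendrogram cut (fraction of max height)
    word_length: int = 5              # LMS word length
    plasmodium_mode: bool = False
    k_total: int | None = None        # entropy normalization; None = subfamilies seen
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.min_len, self.max_evalue, self.min_coverage, self.min_identity,
               self.domain_evalue, self.min_overhang, self.word_length) <= 0:
            raise ValueError("all thresholds must be positive")
        for frac in (self.min_coverage, self.min_identity, self.nq_threshold,
                     self.cut_fraction):
            if not 0 < frac <= 1:
                raise ValueError("fractional thresholds must lie in (0, 1]")


@dataclass
class PipelineResult:
    calls: list[architecture.ArchitectureCall]
    assignments: dict[str, annotation.SubfamilyAssignment]
    inactive_ids: list[str]
    distances: clap.DistanceMatrix | None
    dendrogram: clap.Dendrogram | None
    clusters: list[list[str]] | None
    cluster_report: clap.ClusterReport | None
    summary: dict


def _hit_identity(
    hit: DomainHit,
    seq: SequenceRecord,
    profiles: Mapping[str, str] | None,
) -> float | None:
    if profiles is not None and hit.domain in profiles:
        return annotation.profile_identity(seq.seq, hit, profiles[hit.domain])
    return hit.identity


def run_pipeline(
    seqs: Sequence[SequenceRecord],
    hits: Sequence[DomainHit],
    registry: CanonicalRegistry,
    config: PipelineConfig = PipelineConfig(),
    profiles: Mapping[str, str] | None = None,
) -> PipelineResult:
    """Run every stage on in-memory inputs and return the results bundle.

    ``profiles`` maps subfamily name to profile consensus sequence; when
    given, assignment identity is computed from the hit alignment against
    the consensus, otherwise a per-hit identity from the hit table (as in
    RPS-BLAST output) is required.
    """
    seq_index = {r.id: r for r in seqs}
    if len(seq_index) != len(seqs):
        raise ValueError("duplicate sequence ids in input")
    profile_hits = [h for h in hits if h.domain in registry]
    domain_hits = [h for h in hits if h.domain not in registry]
    log.info("input: %d sequences, %d profile hits, %d domain hits",
             len(seqs), len(profile_hits), len(domain_hits))

    # 1. kinase-candidate filters
    candidates = annotation.filter_kinase_candidates(
        profile_hits, seq_index,
        min_len=config.min_len, max_evalue=config.max_evalue,
        min_coverage=config.min_coverage,
    )
    log.info("candidate filter: %d of %d profile hits retained",
             len(candidates), len(profile_hits))

    # 2. subfamily assignment (best identity >= threshold per sequence)
    per_seq: dict[str, list[annotation.SubfamilyAssignment]] = {}
    for hit in candidates:
        identity = _hit_identity(hit, seq_index[hit.seq_id], profiles)
        if identity is None:
            raise ValueError(
                f"no identity available for hit {hit.seq_id}/{hit.domain}; "
                "supply profile consensi or an identity column"
            )
        a = annotation.assign_subfamily(hit, identity, min_identity=config.min_identity)
        if a is not None:
            per_seq.setdefault(hit.seq_id, []).append(a)
    assignments = {
        seq_id: annotation.choose_assignment(alist)
        for seq_id, alist in per_seq.items()
    }
    log.info("subfamily assignment: %d sequences assigned", len(assignments))

    # 3. catalytic-Asp verification
    active: dict[str, annotation.SubfamilyAssignment] = {}
    inactive_ids: list[str] = []
    for seq_id, a in sorted(assignments.items()):
        motif = annotation.locate_catalytic_motif(seq_index[seq_id].seq, a.kinase_span)
        if annotation.is_putative_active(motif):
            active[seq_id] = a
        else:
            inactive_ids.append(seq_id)
    log.info("catalytic-Asp check: %d active, %d excluded", len(active), len(inactive_ids))

    # 4. architectures and hybrid/rogue classification
    domain_by_seq: dict[str, list[DomainHit]] = {}
    for h in domain_hits:
        if h.evalue <= config.domain_evalue:
            domain_by_seq.setdefault(h.seq_id, []).append(h)
    calls: list[architecture.ArchitectureCall] = []
    for seq_id, a in sorted(active.items()):
        seq = seq_index[seq_id]
        resolved = architecture.resolve_overlaps(
            domain_by_seq.get(seq_id, []), max_overlap=config.max_overlap
        )
        arch = architecture.build_architecture(resolved, len(seq), seq_id=seq_id)
        call = architecture.classify_kinase(a, arch, registry)
        if arch.ordered_domains:
            call.n_overhang, call.c_overhang, call.overhang_flagged = (
                architecture.detect_overhangs(arch, len(seq), config.min_overhang)
            )
        if config.plasmodium_mode:
            kinase_ivals = [
                (lo, hi) for name, lo, hi in arch.ordered_domains
                if name in registry.kinase_domain_names
            ]
            for span in kinase_ivals:
                call.inserts.extend(
                    architecture.detect_low_complexity_inserts(
                        seq.seq, span,
                        window=config.insert_window,
                        nq_threshold=config.nq_threshold,
                        seq_id=seq_id,
                    )
                )
        calls.append(call)
    architecture.flag_orphans(calls)
    summary = summarize(calls, seq_index)
    log.info("classification: %s", {k: summary[k] for k in
                                    ("canonical", "hybrid_single_domain",
                                     "hybrid_multi_domain", "rogue")})

    # 5. LMS clustering and entropy validation
    distances = dendrogram = clusters = report = None
    if len(calls) >= 2:
        params = clap.LMSParams(word_length=config.word_length)
        kept = [seq_index[c.seq_id] for c in calls]
        distances = clap.distance_matrix(kept, params)
        dendrogram = clap.ward_tree(distances)
        clusters = clap.cut_dendrogram(dendrogram, fraction=config.cut_fraction)
        report = clap.outlier_cluster_report(clusters, calls, k_total=config.k_total)
        log.info("clustering: %d clusters, %d with entropy > 0",
                 len(clusters), sum(1 for e in report.entropy if e > 0))

    return PipelineResult(
        calls=calls,
        assignments=active,
        inactive_ids=inactive_ids,
        distances=distances,
        dendrogram=dendrogram,
        clusters=clusters,
        cluster_report=report,
        summary=summary,
    )


def summarize(
    calls: Sequence[architecture.ArchitectureCall],
    seq_index: Mapping[str, SequenceRecord] | None = None,
) -> dict:
    """Counts per label, per subfamily and (when sequences are given) per
    organism.  Totals always sum to the number of calls."""
    by_label = {label: 0 for label in architecture.LABELS}
    per_subfamily: dict[str, int] = {}
    per_organism: dict[str, int] = {}
    for c in calls:
        by_label[c.label] += 1
        per_subfamily[c.assigned_subfamily] = per_subfamily.get(c.assigned_subfamily, 0) + 1
        if seq_index is not None:
            org = seq_index[c.seq_id].organism or "unknown"
            per_organism[org] = per_organism.get(org, 0) + 1
    return {
        "total": len(calls),
        **by_label,
        "hybrid_total": by_label["hybrid_single_domain"] + by_label["hybrid_multi_domain"],
        "outliers": len(calls) - by_label["canonical"],
        "orphans": sum(1 for c in calls if c.orphan),
        "overhang_flagged": sum(1 for c in calls if c.overhang_flagged),
        "with_inserts": sum(1 for c in calls if c.inserts),
        "per_subfamily": dict(sorted(per_subfamily.items())),
        "per_organism": dict(sorted(per_organism.items())),
    }


def _results_frame(result: PipelineResult) -> pd.DataFrame:
    rows = []
    for c in result.calls:
        a = result.assignments[c.seq_id]
        rows.append(
            {
                "seq_id": c.seq_id,
                "subfamily": c.assigned_subfamily,
                "identity": round(a.identity, 4),
                "coverage": round(a.coverage, 4),
                "label": c.label,
                "source_subfamilies": ",".join(c.source_subfamilies) or "-",
                "architecture": architecture.architecture_string(c.architecture),
                "orphan": int(c.orphan),
                "n_overhang": c.n_overhang,
                "c_overhang": c.c_overhang,
                "overhang_flagged": int(c.overhang_flagged),
                "inserts": ";".join(
                    f"{i.ins_from}-{i.ins_to}:{i.nq_fraction:.2f}" for i in c.inserts
                ) or "-",
            }
        )
    return pd.DataFrame(rows)


def write_results(result: PipelineResult, out_dir: str | Path) -> dict[str, Path]:
    """Write results.tsv, summary.json and, when clustering ran,
    distances.tsv, tree.nwk and clusters.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["results"] = out_dir / "results.tsv"
    _results_frame(result).to_csv(paths["results"], sep="\t", index=False)
    paths["summary"] = out_dir / "summary.json"
    paths["summary"].write_text(json.dumps(result.summary, indent=2) + "\n")
    if result.distances is not None:
        paths["distances"] = out_dir / "distances.tsv"
        clap.write_distance_matrix(result.distances, paths["distances"])
        paths["tree"] = out_dir / "tree.nwk"
        paths["tree"].write_text(result.dendrogram.to_newick() + "\n")
        paths["clusters"] = out_dir / "clusters.tsv"
        clap.write_cluster_report(result.cluster_report, paths["clusters"])
    return paths


def run_pipeline_files(
    fasta: str | Path,
    hits: str | Path,
    registry: str | Path,
    out_dir: str | Path,
    config: PipelineConfig = PipelineConfig(),
    profiles: str | Path | None = None,
    dialect: str = "domtblout",
) -> PipelineResult:
    """File-level entry point: parse inputs, run the pipeline, write outputs."""
    seqs = read_fasta(fasta)
    hit_list = parse_domain_hits(hits, dialect=dialect)
    reg = load_canonical_registry(registry)
    prof = None
    if profiles is not None:
        prof = {r.id: r.seq for r in read_fasta(profiles)}
    result = run_pipeline(seqs, hit_list, reg, config=config, profiles=prof)
    write_results(result, out_dir)
    return result
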
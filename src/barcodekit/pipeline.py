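"""End-to-end curation and assignment pipeline, plus report rendering.

Stage order mirrors the blind protocol: QC the libraries, summarise
reference distances, build and (optionally) bootstrap the reference NJ tree,
grade the reference species, then add the queries with their labels hidden,
rebuild the merged tree, extract <2% clusters, assign, audit against the
morphology labels, and finally screen for deep intraspecific divergences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import assignment as asg
from . import grading as grd
from .distances import (DEFAULT_MIN_OVERLAP, DistanceMatrix, RankDistanceSummary,
                        distance_matrix, species_divergence_profile,
                        summarize_ranks)
from .io import BarcodeLibrary, read_library
from .tree import (annotate_support, bootstrap_support, build_nj,
                   extract_clusters, species_monophyly)

logger = logging.getLogger("barcodekit")


@dataclass
class PipelineConfig:
    reference_fasta: str = ""
    reference_meta: str = ""
    query_fasta: str = ""
    query_meta: str = ""
    snapshot_fasta: str = ""
    snapshot_meta: str = ""
    out_dir: str = "barcodekit_out"
    cluster_threshold: float = 0.02
    grade_threshold: float = 0.02
    min_identity: float = 98.0
    min_coverage: float = 0.95
    min_overlap: int = DEFAULT_MIN_OVERLAP
    bootstrap_reps: int = 1000
    bootstrap_seed: int = 42
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class ReportBundle:
    """All tables and trees one pipeline run produces."""

    summary_all: RankDistanceSummary
    summary_ab: Optional[RankDistanceSummary]
    grades: grd.GradeTable
    clusters: list
    assignments: list[asg.AssignmentResult]
    flags: list[asg.FlaggedSpecies]
    ref_tree: object
    merged_tree: object
    merged_matrix: DistanceMatrix
    stats: dict = field(default_factory=dict)
    log: list[str] = field(default_factory=list)

    def clusters_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"cluster_id": c.cluster_id, "n": len(c.member_ids),
             "single_entry": c.is_single_entry,
             "max_within_pct": round(100.0 * c.max_within, 3),
             "consensus_species": c.consensus_species or "",
             "composition": ";".join(
                 f"{s or '<query>'}:{k}"
                 for s, k in sorted(c.species_composition.items())),
             "members": ";".join(c.member_ids)}
            for c in self.clusters
        ])

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}

        paths["distance_summary"] = out / "distance_summary.tsv"
        render_distance_table(self.summary_all).to_csv(
            paths["distance_summary"], sep="\t", index=False)
        if self.summary_ab is not None:
            paths["distance_summary_ab"] = out / "distance_summary_gradesAB.tsv"
            render_distance_table(self.summary_ab).to_csv(
                paths["distance_summary_ab"], sep="\t", index=False)

        paths["grades"] = out / "grades.tsv"
        self.grades.to_frame().to_csv(paths["grades"], sep="\t", index=False)

        paths["clusters"] = out / "clusters.tsv"
        self.clusters_frame().to_csv(paths["clusters"], sep="\t", index=False)

        paths["assignments"] = out / "assignments.tsv"
        asg.results_frame(self.assignments).to_csv(
            paths["assignments"], sep="\t", index=False)

        paths["matches"] = out / "nearest_matches.tsv"
        render_match_table(self.assignments).to_csv(
            paths["matches"], sep="\t", index=False)

        paths["flags"] = out / "flagged_species.tsv"
        asg.flags_frame(self.flags).to_csv(paths["flags"], sep="\t",
                                           index=False)

        paths["tree"] = out / "merged_tree.nwk"
        self.merged_tree.write(str(paths["tree"]))
        paths["ref_tree"] = out / "reference_tree.nwk"
        self.ref_tree.write(str(paths["ref_tree"]))

        paths["log"] = out / "run.log"
        paths["log"].write_text("\n".join(self.log) + "\n")

        paths["stats"] = out / "summary_stats.tsv"
        pd.DataFrame([self.stats]).T.rename(columns={0: "value"}).to_csv(
            paths["stats"], sep="\t")
        return paths


def render_distance_table(summary: RankDistanceSummary) -> pd.DataFrame:
    """Rank-distance table: Comparison | N | Min | Mean±SE | Max (percent)."""
    base = summary.to_frame()
    if base.empty:
        return pd.DataFrame(columns=["Comparison", "N", "Minimum Distance",
                                     "Mean Distance±SE", "Maximum Distance"])
    base["Mean Distance±SE"] = [
        f"{m:.2f}±{s:.2f}" for m, s in zip(base["Mean Distance"], base["SE"])
    ]
    return base[["Comparison", "N", "Minimum Distance", "Mean Distance±SE",
                 "Maximum Distance"]]


def render_match_table(results: list[asg.AssignmentResult]) -> pd.DataFrame:
    """Nearest-match table for queries not resolved by the cluster rule.

    One row per morphology species, pairing it with the closest candidate
    (identity in parentheses), including best below-threshold hits.
    """
    rows: dict[str, dict] = {}
    for r in results:
        if r.evidence in ("cluster", "mixed_reference_cluster"):
            continue
        if r.assigned_species:
            nearest = f"{r.assigned_species} ({r.identity:.1f}%)"
        elif r.evidence.startswith("best_below_threshold:"):
            nearest = r.evidence.split(":", 1)[1]
        elif r.evidence.startswith("identity_tie:"):
            tie = r.evidence.split(":", 1)[1]
            nearest = f"{tie} ({r.identity:.1f}%)"
        else:
            nearest = "none"
        row = rows.setdefault(r.morphology_species, {
            "morphology_species": r.morphology_species, "n_specimens": 0,
            "nearest_match": nearest, "outcome": r.outcome,
        })
        row["n_specimens"] += 1
    return pd.DataFrame(sorted(rows.values(),
                               key=lambda r: r["morphology_species"]),
                        columns=["morphology_species", "n_specimens",
                                 "nearest_match", "outcome"])


def prune_undefined(matrix: DistanceMatrix) -> tuple[DistanceMatrix, list[str]]:
    """Drop the fewest specimens needed to clear all undefined pairs."""
    dropped: list[str] = []
    current = matrix
    while current.undefined_pairs:
        counts: dict[str, int] = {}
        for pair in current.undefined_pairs:
            for sid in pair:
                counts[sid] = counts.get(sid, 0) + 1
        worst = max(sorted(counts), key=lambda s: counts[s])
        dropped.append(worst)
        current = current.submatrix([i for i in current.ids if i != worst])
    return current, dropped


def run_analysis(reference: BarcodeLibrary, queries: BarcodeLibrary,
                 snapshot: Optional[BarcodeLibrary] = None,
                 config: Optional[PipelineConfig] = None) -> ReportBundle:
    """Run every stage in memory and return the report bundle.

    Queries are assigned blind: their species labels feed only the final
    outcome audit and the deep-divergence screen, never the assignment.
    """
    cfg = config or PipelineConfig(bootstrap_reps=0)
    log: list[str] = [f"thresholds: cluster<{cfg.cluster_threshold}, "
                      f"grade<={cfg.grade_threshold}, "
                      f"identity>={cfg.min_identity}%, "
                      f"coverage>={cfg.min_coverage}"]

    ref = reference.qc_passed()
    qry = queries.qc_passed()
    log.append(f"QC: reference {len(ref)}/{len(reference)} passed, "
               f"query {len(qry)}/{len(queries)} passed")
    if len(ref) < 3:
        raise ValueError("need at least 3 QC-passing reference records")

    # Reference-only analysis: distances, tree, monophyly, grades.
    ref_matrix = distance_matrix(ref, min_overlap=cfg.min_overlap)
    ref_matrix_nj, dropped = prune_undefined(ref_matrix)
    if dropped:
        log.append(f"pruned {len(dropped)} reference specimens with "
                   f"undefined distances: {dropped}")
    summary_all = summarize_ranks(ref_matrix, ref)
    ref_tree = build_nj(ref_matrix_nj)
    if cfg.bootstrap_reps > 0:
        support = bootstrap_support(ref.subset(ref_matrix_nj.ids), ref_tree,
                                    n_reps=cfg.bootstrap_reps,
                                    seed=cfg.bootstrap_seed)
        annotate_support(ref_tree, support)
        log.append(f"bootstrap: {cfg.bootstrap_reps} replicates, "
                   f"seed {cfg.bootstrap_seed}")
    monophyly = species_monophyly(ref_tree, ref.species_map())

    external = None
    if snapshot is not None and len(snapshot):
        external = grd.compute_external_matches(
            ref, snapshot, identity_floor=cfg.min_identity)
        log.append(f"external snapshot: {len(snapshot)} candidates, "
                   f"{len(external)} species matched")
    grades = grd.grade_library(ref, ref_matrix, monophyly, external,
                               threshold=cfg.grade_threshold,
                               identity_floor=cfg.min_identity)
    grd.apply_grades(ref, grades)
    ab = grades.species_with_grades({"A", "B"})
    summary_ab = None
    if ab:
        summary_ab = summarize_ranks(ref_matrix, ref, grades={"A", "B"})

    # Merged blind analysis: queries join with labels hidden.
    merged = BarcodeLibrary(list(ref) + list(qry.stripped()))
    merged_matrix = distance_matrix(merged, min_overlap=cfg.min_overlap)
    merged_nj_matrix, dropped_m = prune_undefined(merged_matrix)
    if dropped_m:
        log.append(f"pruned {len(dropped_m)} merged specimens: {dropped_m}")
    merged_tree = build_nj(merged_nj_matrix)
    clusters = extract_clusters(merged_tree, merged_matrix,
                                threshold=cfg.cluster_threshold,
                                species_map=ref.species_map())
    assignable = [q for q in qry.ids if q in set(merged_nj_matrix.ids)]
    results = asg.assign_queries(qry.subset(assignable), clusters,
                                 snapshot=snapshot,
                                 min_identity=cfg.min_identity,
                                 min_coverage=cfg.min_coverage)

    # Deep-divergence screen on the full merged library, true labels restored.
    full = BarcodeLibrary(list(ref) + list(qry))
    flags = asg.flag_deep_divergences(full, merged_matrix, clusters,
                                      threshold=cfg.cluster_threshold)

    n_single = sum(1 for c in clusters if c.is_single_entry)
    ref_ids = set(ref.ids)
    n_single_ref = sum(1 for c in clusters
                       if c.is_single_entry and c.member_ids[0] in ref_ids)
    matched = [r for r in results if r.evidence == "cluster"]
    confirmed = [r for r in matched if r.outcome == "confirmed"]
    stats = {
        "n_reference": len(ref),
        "n_query": len(qry),
        "n_reference_species": len(ref.species),
        "n_clusters": len(clusters),
        "n_single_entry": n_single,
        "n_single_entry_reference": n_single_ref,
        "n_single_entry_query": n_single - n_single_ref,
        "n_query_matched": len(matched),
        "pct_query_matched": 100.0 * len(matched) / len(results) if results else 0.0,
        "n_matched_confirmed": len(confirmed),
        "pct_matched_confirmed": (100.0 * len(confirmed) / len(matched)
                                  if matched else 0.0),
        "n_flagged_species": len(flags),
    }
    log.append(f"clusters: {stats['n_clusters']} "
               f"({stats['n_single_entry']} single-entry)")
    log.append(f"assignment: {stats['n_query_matched']}/{len(results)} matched "
               f"by cluster, {stats['n_matched_confirmed']} confirmed")

    return ReportBundle(summary_all=summary_all, summary_ab=summary_ab,
                        grades=grades, clusters=clusters, assignments=results,
                        flags=flags, ref_tree=ref_tree,
                        merged_tree=merged_tree, merged_matrix=merged_matrix,
                        stats=stats, log=log)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """File-based entry point: read libraries, run, write the report bundle."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    reference = read_library(config.reference_fasta, config.reference_meta)
    queries = read_library(config.query_fasta, config.query_meta)
    for rec in reference:
        rec.role = "reference"
    for rec in queries:
        rec.role = "query"
    snapshot = None
    if config.snapshot_fasta:
        snapshot = read_library(config.snapshot_fasta, config.snapshot_meta)
    bundle = run_analysis(reference, queries, snapshot, config)
    bundle.write(config.out_dir)
    return bundle
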
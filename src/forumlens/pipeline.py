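"""End-to-end drivers for the two analysis objectives.

``run_subtype_discovery`` takes a comment archive to a forum-subtype
report: ingest and filtering, the commenter-overlap network, walktrap
communities, the recovery-focus table, community-level overlap accounting,
and an editable labels file that mediates the manual-review step (the
human decides subtype labels; the pipeline never does).

``run_commenter_profiling`` consumes those labels and, per subtype,
produces the ancillary-forum ranking, top-K selection, restricted overlap
network, its communities and the participation/coverage/Venn accounting.

Every filter logs its counts and every summary number is recomputable from
the emitted intermediate CSVs.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import yaml

from . import ancillary as anc
from . import community_overlap as co
from . import ingest, overlap, recovery, walktrap

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """Declarative configuration for both objectives.

    Defaults are the analysis constants: a 1-year month window, the two
    excluded service accounts, a 500-commenter forum floor, the five
    recovery terms, walk length 4, a 1% ancillary inclusion rule with
    top-50 selection, and a 1000-commenter subtype floor.
    """

    archive_path: str = "archive.jsonl"
    metadata_path: Optional[str] = None
    output_dir: str = "out"
    window_start: str = "2017-03"
    window_end: str = "2018-02"
    excluded_authors: List[str] = field(
        default_factory=lambda: sorted(ingest.DEFAULT_EXCLUDED_AUTHORS)
    )
    search_terms: List[str] = field(default_factory=list)
    manual_exclusions: List[str] = field(default_factory=list)
    min_commenters: int = ingest.DEFAULT_MIN_COMMENTERS
    recovery_terms: List[str] = field(
        default_factory=lambda: list(recovery.DEFAULT_RECOVERY_TERMS)
    )
    walk_length_t: int = walktrap.DEFAULT_WALK_LENGTH
    min_weight: float = 0.0
    ancillary_inclusion_percent: float = anc.DEFAULT_INCLUSION_PERCENT
    top_k: int = anc.DEFAULT_TOP_K
    min_subtype_commenters: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )


def _stage(name: str):
    """Decorator-free stage guard: wrap stage bodies in try/except."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def _ingest_filtered(config: PipelineConfig, run_log: List[str]):
    reader = ingest.read_comment_archive(config.archive_path)
    records = ingest.filter_records(
        reader,
        config.window_start,
        config.window_end,
        config.excluded_authors,
    )
    run_log.append(f"records read: {reader.read}")
    run_log.append(f"malformed lines skipped: {reader.skipped}")
    run_log.append(f"records retained after window/author filter: {len(records)}")
    return records


def run_subtype_discovery(config: PipelineConfig) -> Dict[str, object]:
    """Objective-1 driver: archive -> communities, recovery table, labels stub."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_log: List[str] = [f"subtype discovery; archive={config.archive_path}"]

    with _stage("ingest"):
        records = _ingest_filtered(config, run_log)
        commenter_all, _ = ingest.build_indices(records)
        if config.metadata_path and config.search_terms:
            metas = ingest.read_forum_metadata_csv(config.metadata_path)
            discovered = ingest.discover_forums(
                metas, config.search_terms, config.manual_exclusions
            )
            run_log.append(f"forums matched by search terms: {len(discovered)}")
        else:
            discovered = sorted(commenter_all)
            run_log.append("no metadata/search terms: all observed forums eligible")
        eligible = {
            f: commenter_all[f] for f in discovered if f in commenter_all
        }
        included = ingest.apply_min_commenter_threshold(
            eligible, config.min_commenters
        )
        run_log.append(
            f"forums below {config.min_commenters}-commenter floor: "
            f"{len(eligible) - len(included)}"
        )
        run_log.append(f"forums included: {len(included)}")
        if not included:
            raise PipelineError(
                "stage 'ingest' failed: no forum meets the commenter floor; "
                "nothing to analyse"
            )
        commenter_index, thread_index = ingest.build_indices(records, included)
        ingest.write_commenter_index_csv(commenter_index, out / "commenters.csv")
        ingest.write_thread_index_csv(thread_index, out / "threads.csv")

    with _stage("overlap_network"):
        matrix = overlap.build_overlap_matrix(commenter_index, included)
        matrix.to_csv(out / "overlap_matrix.csv")
        graph = overlap.matrix_to_graph(matrix, config.min_weight)
        overlap.write_graphml(graph, out / "forum_network.graphml")

    with _stage("community_detection"):
        dendro = walktrap.walktrap_dendrogram(graph, config.walk_length_t)
        partition = walktrap.best_partition(dendro, graph)
        dendro.write_csv(out / "dendrogram.csv")
        partition.write_csv(out / "forum_communities.csv")
        with open(out / "modularity_curve.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["cut_level", "n_communities", "modularity"])
            for row in walktrap.modularity_curve(dendro, graph):
                w.writerow([row[0], row[1], repr(row[2])])
        run_log.append(
            f"communities detected: {partition.n_communities} "
            f"(Q={partition.modularity:.4f})"
        )

    with _stage("recovery_focus"):
        report = recovery.recovery_report(thread_index, config.recovery_terms)
        recovery.write_recovery_csv(report, out / "recovery_focus.csv")

    with _stage("community_overlap"):
        comm_sets = co.community_commenter_sets(
            partition.membership, commenter_index
        )
        comm_matrix = overlap.build_overlap_matrix(
            comm_sets, sorted(comm_sets, key=str)
        )
        comm_matrix.to_csv(out / "community_overlap_matrix.csv")
        venn = co.venn_partition(comm_sets)
        venn.to_json(out / "community_venn.json")
        venn.to_csv(out / "community_venn.csv")
        universe = set().union(*comm_sets.values())
        activity: Dict[str, int] = {}
        included_set = set(included)
        for r in records:
            if r.forum in included_set:
                activity[r.author] = activity.get(r.author, 0) + 1
        bots = co.bot_name_report(activity)
        (out / "bot_report.json").write_text(
            json.dumps(
                {
                    "n_accounts": bots.n_accounts,
                    "n_flagged": bots.n_flagged,
                    "percentage": bots.percentage,
                    "mean": bots.mean,
                    "sd": bots.sd,
                    "median": bots.median,
                    "min": bots.min,
                    "max": bots.max,
                },
                indent=2,
            )
        )
        run_log.append(f"total commenters: {len(universe)}")
        run_log.append(
            f"bot-named accounts: {bots.n_flagged} ({bots.percentage}%)"
        )

    with _stage("labels_stub"):
        # manual-review hook: a human fills the subtype_label column
        by_pct = {e.forum: e.percentage for e in report}
        with open(out / "subtype_labels.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["forum", "community", "recovery_percentage", "label"])
            for forum in included:
                w.writerow(
                    [forum, partition.membership[forum], by_pct[forum], ""]
                )

    (out / "run.log").write_text("\n".join(run_log) + "\n")
    return {
        "included_forums": included,
        "commenter_index": commenter_index,
        "thread_index": thread_index,
        "matrix": matrix,
        "graph": graph,
        "partition": partition,
        "recovery": report,
        "community_sets": comm_sets,
        "venn": venn,
        "bot_report": bots,
        "run_log": run_log,
    }


def read_subtype_labels(path: str | Path) -> Dict[str, List[str]]:
    """Read the labels TSV; returns label -> member forums (blank labels
    are unassigned forums and are ignored)."""
    groups: Dict[str, List[str]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            label = (row.get("label") or "").strip()
            if label:
                groups.setdefault(label, []).append(row["forum"])
    return groups


def run_commenter_profiling(
    config: PipelineConfig, subtype_labels_path: str | Path
) -> Dict[str, Dict[str, object]]:
    """Objective-2 driver: per labelled subtype, ancillary-forum profile."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_log: List[str] = [f"commenter profiling; archive={config.archive_path}"]

    with _stage("ingest"):
        records = _ingest_filtered(config, run_log)
        commenter_all, _ = ingest.build_indices(records)
        groups = read_subtype_labels(subtype_labels_path)
        if not groups:
            raise PipelineError(
                "stage 'ingest' failed: labels file assigns no forum a subtype"
            )
        for label, forums in groups.items():
            for f in forums:
                if f not in commenter_all:
                    raise PipelineError(
                        f"stage 'ingest' failed: subtype {label!r} names "
                        f"unknown forum {f!r}"
                    )

    results: Dict[str, Dict[str, object]] = {}
    for label in sorted(groups):
        subtype = anc.SubtypeDefinition.from_index(
            label, sorted(groups[label]), commenter_all
        )
        if len(subtype.commenters) < config.min_subtype_commenters:
            run_log.append(
                f"subtype {label!r} skipped: {len(subtype.commenters)} "
                f"commenters < floor {config.min_subtype_commenters}"
            )
            continue
        sub_out = out / f"subtype_{label}"
        sub_out.mkdir(parents=True, exist_ok=True)

        with _stage(f"ancillary_ranking[{label}]"):
            candidates = anc.find_ancillary_forums(
                commenter_all, subtype, config.ancillary_inclusion_percent
            )
            run_log.append(
                f"subtype {label!r}: {len(subtype.commenters)} commenters, "
                f"{len(candidates)} ancillary candidates"
            )
            if candidates.empty:
                run_log.append(f"subtype {label!r}: no candidates; skipped")
                continue
            ranking = anc.rank_ancillary_forums(candidates)
            anc.write_ranking_tsv(ranking, sub_out / "ancillary_ranking.tsv")
            selected = anc.select_top_k(ranking, config.top_k)
            (sub_out / "selected_forums.txt").write_text(
                "\n".join(selected) + "\n"
            )

        with _stage(f"restricted_network[{label}]"):
            matrix = anc.restricted_overlap_matrix(
                commenter_all, selected, subtype.commenters
            )
            matrix.to_csv(sub_out / "restricted_overlap_matrix.csv")
            graph = overlap.matrix_to_graph(matrix, config.min_weight)
            overlap.write_graphml(graph, sub_out / "ancillary_network.graphml")
            dendro = walktrap.walktrap_dendrogram(graph, config.walk_length_t)
            partition = walktrap.best_partition(dendro, graph)
            partition.write_csv(sub_out / "ancillary_communities.csv")

        with _stage(f"overlap_accounting[{label}]"):
            restricted_sets = {
                f: commenter_all[f] & subtype.commenters for f in selected
            }
            comm_sets = co.community_commenter_sets(
                partition.membership, restricted_sets
            )
            universe = set().union(*comm_sets.values())
            cov = co.coverage(subtype.commenters, restricted_sets.values())
            participation = co.community_participation(comm_sets, universe)
            venn = co.venn_partition(comm_sets)
            venn.to_json(sub_out / "community_venn.json")
            venn.to_csv(sub_out / "community_venn.csv")
            summary = {
                "subtype": label,
                "n_subtype_commenters": len(subtype.commenters),
                "n_candidates": int(len(candidates)),
                "n_selected": len(selected),
                "coverage_percentage": cov,
                "n_covered": len(universe),
                "n_communities": partition.n_communities,
                "participation_percentage": {
                    str(k): v for k, v in sorted(participation.items())
                },
            }
            (sub_out / "summary.json").write_text(json.dumps(summary, indent=2))
            run_log.append(
                f"subtype {label!r}: top-{len(selected)} forums cover "
                f"{cov}% of commenters; {partition.n_communities} communities"
            )
        results[label] = {
            "subtype": subtype,
            "ranking": ranking,
            "selected": selected,
            "matrix": matrix,
            "partition": partition,
            "community_sets": comm_sets,
            "venn": venn,
            "coverage": cov,
            "participation": participation,
        }

    (out / "profiling_run.log").write_text("\n".join(run_log) + "\n")
    return results
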
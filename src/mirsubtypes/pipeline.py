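"""End-to-end orchestration of the subtype-specific miRNA pipeline.

``run_all`` executes the whole chain on a synthetic study — simulate,
normalize/filter, subtype, call markers, score enrichment, associate
pathways, prioritize targets, report, score recovery — and (optionally)
writes every result table plus a JSON manifest.  Identical configuration
and seed reproduce every output file byte for byte.

The same stage functions back the command-line interface, which exchanges
data through a workspace directory with canonical file names.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mirsubtypes import io_formats as iof
from mirsubtypes.enrichment import EnrichmentScores, score_sets
from mirsubtypes.io_formats import (
    CohortAnnotation,
    ExprMatrix,
    RunConfig,
    UNASSIGNED,
)
from mirsubtypes.markers import MarkerCall, calls_to_frame, find_markers
from mirsubtypes.pathway_links import (
    build_report,
    cluster_correlations,
    correlate_markers,
    prioritize_targets,
    select_gene_sets,
)
from mirsubtypes.preprocess import detection_filter, percentile_normalize, quantile_normalize
from mirsubtypes.subtyping import accuracy, classify
from mirsubtypes.synthetic_cohort import (
    DISCOVERY,
    VALIDATION,
    SimConfig,
    SimulatedStudy,
    score_recovery,
    simulate_cohorts,
)

logger = logging.getLogger(__name__)

COHORTS = (DISCOVERY, VALIDATION)


@dataclass
class PipelineResult:
    study: SimulatedStudy
    marker_calls: list[MarkerCall]
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    selection: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    recovery: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def preprocess_stage(
    study_mirna: dict[str, ExprMatrix],
    study_mrna: dict[str, ExprMatrix],
    annotation: CohortAnnotation,
    cfg: RunConfig,
) -> tuple[dict[str, ExprMatrix], dict[str, ExprMatrix], dict[str, pd.DataFrame]]:
    """90th-percentile normalize + detection-filter miRNA; quantile normalize mRNA."""
    mirna_out: dict[str, ExprMatrix] = {}
    mrna_out: dict[str, ExprMatrix] = {}
    reports: dict[str, pd.DataFrame] = {}
    for cohort in study_mirna:
        branch = annotation.table.loc[
            annotation.samples(cohort=cohort)[0], "histology_branch"
        ]
        min_frac = cfg.detection_fraction.get(branch, 0.10)
        m = percentile_normalize(study_mirna[cohort], q=90.0)
        m, report = detection_filter(m, min_frac)
        mirna_out[cohort] = m
        reports[cohort] = report.to_frame()
        mrna_out[cohort] = quantile_normalize(study_mrna[cohort])
    return mirna_out, mrna_out, reports


def subtype_stage(
    mrna: dict[str, ExprMatrix],
    centroids,
    annotation: CohortAnnotation,
    cfg: RunConfig,
) -> pd.DataFrame:
    """Classify tumor samples of each cohort; returns one table with a cohort column."""
    frames = []
    for cohort in mrna:
        tumors = annotation.samples(cohort=cohort, tissue="tumor")
        calls = classify(
            mrna[cohort], centroids, tumor_samples=tumors, center_genes=cfg.center_genes
        )
        calls = calls.reset_index()
        calls.insert(1, "cohort", cohort)
        frames.append(calls)
    return pd.concat(frames, ignore_index=True)


def build_groups(
    subtype_calls: pd.DataFrame, annotation: CohortAnnotation
) -> tuple[dict, dict, dict]:
    """Groups for the rank tests: cohort -> subtype -> assigned tumor sample ids,
    plus per-cohort assigned-tumor lists and normal lists."""
    groups: dict[str, dict[str, list[str]]] = {}
    tumor_samples: dict[str, list[str]] = {}
    normal_samples: dict[str, list[str]] = {}
    for cohort in dict.fromkeys(subtype_calls["cohort"]):
        sub = subtype_calls[subtype_calls["cohort"] == cohort]
        assigned = sub[sub["assigned"] != UNASSIGNED]
        groups[cohort] = {
            s: list(g["sample_id"]) for s, g in assigned.groupby("assigned", sort=True)
        }
        tumor_samples[cohort] = list(assigned["sample_id"])
        normal_samples[cohort] = annotation.samples(cohort=cohort, tissue="normal")
    return groups, tumor_samples, normal_samples


def enrichment_stage(
    mrna: dict[str, ExprMatrix],
    gene_sets,
    tumor_samples: dict[str, list[str]],
    cfg: RunConfig,
) -> dict[str, EnrichmentScores]:
    """Per-sample hallmark scores on the tumor samples of each cohort."""
    return {
        cohort: score_sets(
            mrna[cohort].subset_samples(tumor_samples[cohort]),
            gene_sets,
            tau=cfg.es_tau,
            convention=cfg.es_convention,
            min_size=cfg.min_set_size,
        )
        for cohort in mrna
    }


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------


def run_all(
    sim_cfg: SimConfig,
    run_cfg: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    run_cfg = run_cfg or RunConfig(seed=sim_cfg.seed)
    study = simulate_cohorts(sim_cfg)
    return run_study(study, run_cfg, out_dir=out_dir)


def run_study(
    study: SimulatedStudy,
    run_cfg: RunConfig,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    mirna, mrna, det_reports = preprocess_stage(
        study.mirna, study.mrna, study.annotation, run_cfg
    )
    subtype_calls = subtype_stage(mrna, study.centroids, study.annotation, run_cfg)
    groups, tumor_samples, normal_samples = build_groups(subtype_calls, study.annotation)

    final_calls, kw_table = find_markers(
        mirna, groups, normal_samples, run_cfg, discovery_cohort=DISCOVERY
    )
    marker_table = calls_to_frame(final_calls)

    scores = enrichment_stage(mrna, study.gene_sets, tumor_samples, run_cfg)
    associations = correlate_markers(final_calls, mirna, scores, tumor_samples, run_cfg)
    selection = select_gene_sets(associations, run_cfg, cohorts=COHORTS)
    targets = prioritize_targets(
        selection, study.target_ranks, mrna, mirna, study.gene_sets, tumor_samples, run_cfg
    )
    report = build_report(marker_table, associations, targets, cohorts=COHORTS)

    tables: dict[str, pd.DataFrame] = {
        "subtype_calls": subtype_calls,
        "omnibus_screen": kw_table,
        "marker_calls": marker_table,
        "associations": associations,
        "set_selection": pd.DataFrame(
            [
                {"mirna_id": m, "subtype": s, "set_name": name}
                for (m, s), names in selection.items()
                for name in names
            ],
            columns=["mirna_id", "subtype", "set_name"],
        ),
        "target_candidates": targets,
        **{f"detection_report_{c}": det_reports[c] for c in det_reports},
        **{
            f"enrichment_{c}": scores[c].scores.reset_index(names="set_name")
            for c in scores
        },
        **report,
    }

    # correlation matrix + ward.D2 leaf orders for the heatmap-shaped output
    if len(associations):
        rho = associations.pivot_table(
            index="mirna_id", columns="set_name", values=f"rho_{DISCOVERY}", sort=True
        )
        tables["correlation_rho_discovery"] = rho.reset_index()
        if rho.shape[0] >= 2 and rho.shape[1] >= 2:
            orders = cluster_correlations(rho)
            tables["cluster_orders"] = pd.DataFrame(
                {
                    "axis": ["rows"] * len(orders["rows"]) + ["columns"] * len(orders["columns"]),
                    "position": list(range(len(orders["rows"])))
                    + list(range(len(orders["columns"]))),
                    "label": orders["rows"] + orders["columns"],
                }
            )

    recovery = _score_recovery_block(study, subtype_calls, marker_table, selection, targets)
    tables["recovery"] = pd.DataFrame(
        [{"metric": k, "value": v} for k, v in recovery.items()]
    )

    result = PipelineResult(
        study=study,
        marker_calls=final_calls,
        tables=tables,
        selection=selection,
        recovery=recovery,
    )
    if out_dir is not None:
        iof.write_results(tables, out_dir, config=run_cfg, seed=study.config.seed)
    return result


def _score_recovery_block(
    study: SimulatedStudy,
    subtype_calls: pd.DataFrame,
    marker_table: pd.DataFrame,
    selection: dict[tuple[str, str], list[str]],
    targets: pd.DataFrame,
) -> dict[str, float]:
    truth = study.truth
    out: dict[str, float] = {}
    for cohort in dict.fromkeys(subtype_calls["cohort"]):
        sub = subtype_calls[subtype_calls["cohort"] == cohort].set_index("sample_id")
        t = truth.sample_subtypes[truth.sample_subtypes["cohort"] == cohort]
        if len(t):
            out[f"subtype_accuracy_{cohort}"] = accuracy(
                sub, t.set_index("sample_id")["subtype"]
            )
    ms = score_recovery(marker_table, truth.markers_for_recovery, kind="markers")
    out["marker_precision"] = ms.precision
    out["marker_recall"] = ms.recall
    out["marker_tp"], out["marker_fp"], out["marker_fn"] = ms.tp, ms.fp, ms.fn

    picked = pd.DataFrame(
        [{"mirna_id": m, "set_name": name} for (m, _s), names in selection.items() for name in names],
        columns=["mirna_id", "set_name"],
    )
    cs = score_recovery(picked, truth.couplings, kind="couplings")
    out["coupling_recall"] = cs.recall
    out["coupling_tp"], out["coupling_fn"] = cs.tp, cs.fn

    accepted = targets[targets["accepted"]] if len(targets) else targets
    ts = score_recovery(accepted, truth.targets, kind="targets")
    out["target_precision"] = ts.precision
    out["target_recall"] = ts.recall
    out["target_tp"], out["target_fn"] = ts.tp, ts.fn
    out["decoy_targets_accepted"] = ts.fp
    return out


# ---------------------------------------------------------------------------
# Workspace (CLI file exchange)
# ---------------------------------------------------------------------------

_TRUTH_TABLES = ("markers", "pathway_shifts", "couplings", "targets", "sample_subtypes")


def export_study(study: SimulatedStudy, out_dir: str | Path) -> None:
    """Write every input artifact of a simulated study in the package dialects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for cohort in study.mirna:
        iof.write_expr_matrix(
            study.mirna[cohort],
            out / f"mirna_{cohort}.tsv",
            detected_path=out / f"mirna_{cohort}_detected.tsv",
        )
        iof.write_expr_matrix(study.mrna[cohort], out / f"mrna_{cohort}.tsv")
    iof.write_annotation(study.annotation, out / "annotation.tsv")
    iof.write_centroids(study.centroids, out / "centroids.tsv")
    iof.write_gmt(study.gene_sets, out / "gene_sets.gmt")
    iof.write_target_table(study.target_ranks, out / "target_ranks.tsv")
    for name in _TRUTH_TABLES:
        getattr(study.truth, name).to_csv(out / f"truth_{name}.tsv", sep="\t", index=False)


def load_study(in_dir: str | Path, cfg: SimConfig | None = None) -> SimulatedStudy:
    """Reload a study exported with :func:`export_study`."""
    from mirsubtypes.synthetic_cohort import PlantedTruth

    d = Path(in_dir)
    mirna = {
        c: iof.read_expr_matrix(d / f"mirna_{c}.tsv", detected_path=d / f"mirna_{c}_detected.tsv")
        for c in COHORTS
    }
    mrna = {c: iof.read_expr_matrix(d / f"mrna_{c}.tsv") for c in COHORTS}
    truth = PlantedTruth(
        **{
            name: pd.read_csv(d / f"truth_{name}.tsv", sep="\t").fillna("")
            for name in _TRUTH_TABLES
        }
    )
    if "normal_like" in truth.markers.columns and len(truth.markers):
        truth.markers["normal_like"] = truth.markers["normal_like"].astype(bool)
    return SimulatedStudy(
        mirna=mirna,
        mrna=mrna,
        annotation=iof.read_annotation(d / "annotation.tsv"),
        centroids=iof.read_centroids(d / "centroids.tsv"),
        gene_sets=iof.read_gmt(d / "gene_sets.gmt"),
        target_ranks=iof.read_target_table(d / "target_ranks.tsv"),
        truth=truth,
        config=cfg or SimConfig(),
    )
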
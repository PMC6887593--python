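"""Linking marker miRNAs to hallmark programs and predicted targets.

``correlate_markers`` computes Spearman correlations between each marker
miRNA and every gene-set enrichment score, per cohort, Bonferroni-corrected
over the (markers x sets) family.  ``select_gene_sets`` applies the
most-anticorrelated-in-both-cohorts rule (minimax over cohorts by default),
never selecting positively correlated sets.  ``prioritize_targets`` accepts
a predicted pair only if it is ranked very_high (top 1% of the prediction
list), lies in a selected set, and is significantly negatively correlated in
both cohorts.  ``cluster_correlations`` orders the correlation matrix with
Ward-criterion agglomerative clustering (the ward.D2 convention) for the
report heatmaps.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from mirsubtypes.enrichment import EnrichmentScores
from mirsubtypes.io_formats import ExprMatrix, GeneSetCollection, RunConfig, TargetRankTable
from mirsubtypes.markers import MarkerCall
from mirsubtypes.rankstats import bonferroni_adjust, spearman, spearman_matrix

logger = logging.getLogger(__name__)


def correlate_markers(
    markers: list[MarkerCall],
    mirna_mats: dict[str, ExprMatrix],
    scores: dict[str, EnrichmentScores],
    tumor_samples: dict[str, list[str]],
    cfg: RunConfig,
) -> pd.DataFrame:
    """Spearman correlation of every marker against every gene-set score.

    One row per (marker, set) with per-cohort rho and Bonferroni-adjusted p
    (family = markers x sets per cohort).  ``significant_both`` requires
    p_adj < assoc_alpha in both cohorts with one rho sign;
    ``signed_direction`` is sign(rho) x (+1 for up-markers, -1 for down).
    """
    cohorts = list(mirna_mats)
    set_names = [s for s in scores[cohorts[0]].set_names
                 if all(s in scores[c].set_names for c in cohorts)]
    mirna_ids = [c.mirna_id for c in markers]
    family = len(markers) * len(set_names)
    per_cohort: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for cohort in cohorts:
        avail = set(mirna_mats[cohort].sample_ids) & set(scores[cohort].sample_ids)
        shared = [s for s in tumor_samples[cohort] if s in avail]
        if len(shared) < 3:
            logger.info("cohort %s has <3 shared tumor samples; no associations", cohort)
            continue
        X = mirna_mats[cohort].values.loc[mirna_ids, shared].to_numpy(dtype=float)
        Y = scores[cohort].scores.loc[set_names, shared].to_numpy(dtype=float)
        per_cohort[cohort] = spearman_matrix(X, Y)
    rows = []
    if len(per_cohort) == len(cohorts):
        for i, cand in enumerate(markers):
            for j, set_name in enumerate(set_names):
                row: dict[str, object] = {
                    "mirna_id": cand.mirna_id,
                    "subtype": cand.subtype,
                    "marker_direction": cand.direction,
                    "set_name": set_name,
                }
                ok = True
                for cohort in cohorts:
                    rho, p = per_cohort[cohort]
                    if not np.isfinite(rho[i, j]):
                        ok = False  # zero-variance rank vector; excluded
                        break
                    row[f"rho_{cohort}"] = rho[i, j]
                    row[f"p_{cohort}"] = p[i, j]
                if ok:
                    rows.append(row)
    if not rows:
        return pd.DataFrame(
            columns=["mirna_id", "subtype", "marker_direction", "set_name",
                     "significant_both", "signed_direction", "selected_for_targets"]
        )
    df = pd.DataFrame(rows)
    sig = np.ones(len(df), dtype=bool)
    for cohort in cohorts:
        df[f"p_adj_{cohort}"] = bonferroni_adjust(df[f"p_{cohort}"].to_numpy(), m=family)
        sig &= df[f"p_adj_{cohort}"].to_numpy() < cfg.assoc_alpha
    signs = np.sign(df[[f"rho_{c}" for c in cohorts]].to_numpy())
    same_sign = np.all(signs == signs[:, [0]], axis=1) & (signs[:, 0] != 0)
    df["significant_both"] = sig & same_sign
    marker_sign = np.where(df["marker_direction"] == "up", 1, -1)
    df["signed_direction"] = (signs[:, 0] * marker_sign).astype(int)
    df["selected_for_targets"] = False
    return df


def select_gene_sets(
    associations: pd.DataFrame,
    cfg: RunConfig,
    cohorts: tuple[str, str] = ("discovery", "validation"),
) -> dict[tuple[str, str], list[str]]:
    """Per marker, the most anticorrelated significant set in both cohorts.

    Among rows with negative rho in both cohorts and significance in both,
    the minimax rule keeps the set whose *worse-cohort* rho (the larger of
    the two) is most negative; ``set_pick_rule='mean'`` uses the mean rho
    instead.  Configured extra sets for the marker's subtype are appended
    when they, too, are significantly negative in both cohorts.  Positively
    correlated sets are never selected.  Returns
    {(mirna_id, subtype): [set names]} and flags ``selected_for_targets``
    in place.
    """
    selection: dict[tuple[str, str], list[str]] = {}
    if associations.empty:
        return selection
    rho_cols = [f"rho_{c}" for c in cohorts]
    for (mirna, subtype), sub in associations.groupby(["mirna_id", "subtype"], sort=False):
        neg = sub[
            sub["significant_both"] & (sub[rho_cols] < 0).all(axis=1)
        ]
        chosen: list[str] = []
        if len(neg):
            if cfg.set_pick_rule == "minimax":
                score = neg[rho_cols].max(axis=1)  # rho in the worse cohort
            else:
                score = neg[rho_cols].mean(axis=1)
            best = neg.loc[score.idxmin(), "set_name"]
            chosen.append(best)
        else:
            logger.info("marker %s (%s): no significantly anticorrelated set", mirna, subtype)
        for extra in cfg.extra_gene_sets.get(subtype, []):
            if extra in chosen:
                continue
            row = neg[neg["set_name"] == extra]
            if len(row):
                chosen.append(extra)
            else:
                logger.info(
                    "extra set %s for %s not significantly anticorrelated with %s; skipped",
                    extra, subtype, mirna,
                )
        if chosen:
            selection[(mirna, subtype)] = chosen
            mask = (
                (associations["mirna_id"] == mirna)
                & (associations["subtype"] == subtype)
                & associations["set_name"].isin(chosen)
            )
            associations.loc[mask, "selected_for_targets"] = True
    return selection


def prioritize_targets(
    selection: dict[tuple[str, str], list[str]],
    rank_table: TargetRankTable,
    mrna_mats: dict[str, ExprMatrix],
    mirna_mats: dict[str, ExprMatrix],
    sets: GeneSetCollection,
    tumor_samples: dict[str, list[str]],
    cfg: RunConfig,
) -> pd.DataFrame:
    """Dual-cohort anticorrelation test of very_high predicted pairs.

    Candidate universe: genes of the selected sets that are measured in the
    mRNA matrices of BOTH cohorts and predicted for the marker with class
    very_high.  Bonferroni family = number of candidate pairs, per cohort.
    Accepted iff rho < 0 and p_adj < assoc_alpha in both cohorts.
    """
    cohorts = list(mrna_mats)
    measured = set(mrna_mats[cohorts[0]].feature_ids)
    for c in cohorts[1:]:
        measured &= set(mrna_mats[c].feature_ids)
    rows = []
    for (mirna, subtype), set_names in selection.items():
        predicted = rank_table.genes_for(mirna, "very_high")
        for set_name in set_names:
            genes = sorted(sets.members(set_name) & measured & predicted)
            for gene in genes:
                rows.append({"mirna_id": mirna, "subtype": subtype,
                             "set_name": set_name, "gene_id": gene,
                             "confidence_class": "very_high"})
    if not rows:
        logger.info("empty target candidate universe")
        return pd.DataFrame(
            columns=["mirna_id", "subtype", "set_name", "gene_id", "confidence_class", "accepted"]
        )
    df = pd.DataFrame(rows)
    family = len(df)
    accepted = np.ones(family, dtype=bool)
    for cohort in cohorts:
        shared = [
            s for s in tumor_samples[cohort]
            if s in set(mirna_mats[cohort].sample_ids)
        ]
        rhos, ps = [], []
        for _, row in df.iterrows():
            x = mirna_mats[cohort].values.loc[row["mirna_id"], shared]
            y = mrna_mats[cohort].values.loc[row["gene_id"], shared]
            res = spearman(x, y)
            rhos.append(res.rho if res.valid else np.nan)
            ps.append(res.p if res.valid else 1.0)
        df[f"rho_{cohort}"] = rhos
        df[f"p_adj_{cohort}"] = bonferroni_adjust(np.asarray(ps), m=family)
        accepted &= (df[f"rho_{cohort}"].to_numpy() < 0) & (
            df[f"p_adj_{cohort}"].to_numpy() < cfg.assoc_alpha
        )
    df["accepted"] = accepted
    # hard invariant: an accepted target is negatively correlated everywhere
    for cohort in cohorts:
        assert (df.loc[df["accepted"], f"rho_{cohort}"] < 0).all()
    return df


def cluster_correlations(rho: pd.DataFrame) -> dict[str, list[str]]:
    """Ward-criterion (ward.D2) leaf orders for rows and columns of a
    correlation matrix; deterministic, constant matrices allowed with a
    warning."""
    if rho.shape[0] < 2 or rho.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns to cluster")
    X = rho.to_numpy(dtype=float)
    if np.ptp(X) == 0.0:
        logger.warning("constant correlation matrix; leaf order is input order")
    row_order = [rho.index[i] for i in leaves_list(linkage(X, method="ward"))]
    col_order = [rho.columns[i] for i in leaves_list(linkage(X.T, method="ward"))]
    return {"rows": row_order, "columns": col_order}


def build_report(
    marker_table: pd.DataFrame,
    associations: pd.DataFrame,
    targets: pd.DataFrame,
    cohorts: tuple[str, str] = ("discovery", "validation"),
) -> dict[str, pd.DataFrame]:
    """Per-subtype summary tables.

    ``pathway_directions`` applies the heatmap sign rule: the inferred
    pathway direction is sign(rho) multiplied by -1 for down-regulated
    markers (a set anticorrelated with a down marker is an up-regulated
    program).
    """
    report: dict[str, pd.DataFrame] = {}
    report["markers_by_subtype"] = (
        marker_table.sort_values(["subtype", "direction", "mirna_id"]).reset_index(drop=True)
        if len(marker_table)
        else marker_table
    )
    if len(associations):
        sig = associations[associations["significant_both"]].copy()
        sig["pathway_direction"] = np.where(sig["signed_direction"] > 0, "up", "down")
        report["pathway_directions"] = (
            sig.groupby(["subtype", "set_name", "pathway_direction"], sort=True)["mirna_id"]
            .apply(lambda s: ",".join(sorted(s)))
            .reset_index()
            .rename(columns={"mirna_id": "supported_by"})
        )
    else:
        report["pathway_directions"] = pd.DataFrame(
            columns=["subtype", "set_name", "pathway_direction", "supported_by"]
        )
    report["accepted_targets"] = (
        targets[targets["accepted"]].reset_index(drop=True)
        if len(targets)
        else targets
    )
    return report
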
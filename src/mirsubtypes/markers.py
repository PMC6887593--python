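"""Cross-cohort consensus calling of subtype-specific miRNAs.

Three stages mirror the study design:

1. ``omnibus_screen`` — per cohort, a Kruskal-Wallis test across subtype
   groups for every miRNA, Benjamini-Hochberg corrected across miRNAs; only
   miRNAs significant in BOTH cohorts survive.
2. ``specificity_call`` — Dunn's post hoc test pins the subtype: a candidate
   (miRNA, subtype) needs every pairwise comparison against the other
   subtypes significant in both cohorts, with one consistent direction.  A
   configurable borderline relaxation loosens the discovery-cohort alpha for
   small subtypes when the validation cohort passes at the ordinary
   threshold.
3. ``normal_filter`` — candidates must also differ from normal lung tissue
   (Mann-Whitney, BH across candidates) with a direction consistent with the
   tumor call, in every cohort that has normal samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mirsubtypes.io_formats import ExprMatrix, RunConfig
from mirsubtypes.rankstats import bh_adjust, dunn_posthoc, kruskal_wallis, mann_whitney

logger = logging.getLogger(__name__)

Groups = dict[str, dict[str, list[str]]]  # cohort -> subtype -> sample ids


@dataclass
class MarkerCall:
    mirna_id: str
    subtype: str
    direction: str  # up / down
    relaxed: bool = False
    kw_p_adj: dict[str, float] = field(default_factory=dict)  # per cohort
    dunn_p_adj: dict[str, dict[str, float]] = field(default_factory=dict)  # cohort -> other -> p
    normal_p_adj: dict[str, float] = field(default_factory=dict)  # per normal-bearing cohort


def calls_to_frame(calls: list[MarkerCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row: dict[str, object] = {
            "mirna_id": c.mirna_id,
            "subtype": c.subtype,
            "direction": c.direction,
            "relaxed": c.relaxed,
        }
        for cohort, p in sorted(c.kw_p_adj.items()):
            row[f"kw_p_adj_{cohort}"] = p
        for cohort, pairs in sorted(c.dunn_p_adj.items()):
            for other, p in sorted(pairs.items()):
                row[f"dunn_p_adj_{cohort}_vs_{other}"] = p
        for cohort, p in sorted(c.normal_p_adj.items()):
            row[f"normal_p_adj_{cohort}"] = p
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=["mirna_id", "subtype", "direction", "relaxed"])
    return pd.DataFrame(rows)


def _group_values(m: ExprMatrix, groups: dict[str, list[str]], mirna: str) -> list[np.ndarray]:
    return [m.values.loc[mirna, ids].to_numpy(dtype=float) for ids in groups.values()]


def omnibus_screen(
    mats: dict[str, ExprMatrix], groups: Groups, cfg: RunConfig
) -> tuple[list[str], pd.DataFrame]:
    """miRNAs with BH-corrected Kruskal-Wallis p < kw_fdr in every cohort.

    Features are intersected across cohorts by id (in first-cohort order);
    unmatched features are reported.  Returns the passing list plus the per
    cohort p-value table.
    """
    cohorts = list(mats)
    feature_sets = [set(mats[c].feature_ids) for c in cohorts]
    common = [f for f in mats[cohorts[0]].feature_ids if all(f in s for s in feature_sets)]
    if not common:
        raise ValueError("no features shared across cohorts")
    dropped = sorted(set().union(*feature_sets) - set(common))
    if dropped:
        logger.info("%d features absent from some cohort were excluded: %s%s",
                    len(dropped), dropped[:5], "..." if len(dropped) > 5 else "")

    table = pd.DataFrame({"mirna_id": common})
    passing = np.ones(len(common), dtype=bool)
    for cohort in cohorts:
        sub_groups = {s: ids for s, ids in groups[cohort].items() if len(ids) >= 2}
        if len(sub_groups) < 2:
            raise ValueError(f"cohort {cohort!r} has <2 subtypes with >=2 samples")
        ps = []
        for f in common:
            res = kruskal_wallis(_group_values(mats[cohort], sub_groups, f))
            ps.append(res.p)
        p_adj = bh_adjust(ps)
        table[f"kw_p_{cohort}"] = ps
        table[f"kw_p_adj_{cohort}"] = p_adj
        passing &= p_adj < cfg.kw_fdr
    table["passed_both"] = passing
    return [f for f, ok in zip(common, passing) if ok], table


def specificity_call(
    screened: list[str],
    mats: dict[str, ExprMatrix],
    groups: Groups,
    cfg: RunConfig,
    discovery_cohort: str | None = None,
    kw_table: pd.DataFrame | None = None,
) -> list[MarkerCall]:
    """Dunn-based subtype assignment of screened miRNAs.

    (miRNA, s) becomes a candidate iff for every other subtype t the Dunn
    p_adj(s, t) clears the threshold in both cohorts and the mean-rank
    differences have one consistent sign in all comparisons and cohorts.
    When ``cfg.borderline_relax`` names s, discovery-cohort pairs involving
    s may instead clear the relaxed alpha provided the validation cohort
    passes at the ordinary threshold (the call is then flagged relaxed).
    """
    cohorts = list(mats)
    if discovery_cohort is None:
        discovery_cohort = cohorts[0]
    kw_lookup: dict[str, dict[str, float]] = {}
    if kw_table is not None:
        for _, row in kw_table.iterrows():
            kw_lookup[row["mirna_id"]] = {
                c: float(row[f"kw_p_adj_{c}"]) for c in cohorts if f"kw_p_adj_{c}" in row
            }
    calls: list[MarkerCall] = []
    for f in screened:
        per_cohort: dict[str, dict] = {}
        for cohort in cohorts:
            sub_groups = {s: ids for s, ids in groups[cohort].items() if len(ids) >= 2}
            labels = list(sub_groups)
            results = dunn_posthoc(
                [_group_values(mats[cohort], {s: sub_groups[s]}, f)[0] for s in labels],
                labels=labels,
            )
            pair_p: dict[frozenset, float] = {}
            pair_sign: dict[tuple[str, str], int] = {}
            for r in results:
                pair_p[frozenset((r.group_a, r.group_b))] = r.p_adj
                pair_sign[(r.group_a, r.group_b)] = r.direction
                pair_sign[(r.group_b, r.group_a)] = -r.direction
            per_cohort[cohort] = {"p": pair_p, "sign": pair_sign, "subtypes": labels}

        shared_subtypes = [
            s for s in per_cohort[cohorts[0]]["subtypes"]
            if all(s in per_cohort[c]["subtypes"] for c in cohorts)
        ]
        for s in shared_subtypes:
            ok = True
            relaxed_used = False
            signs: set[int] = set()
            dunn_evidence: dict[str, dict[str, float]] = {c: {} for c in cohorts}
            for t in shared_subtypes:
                if t == s:
                    continue
                for cohort in cohorts:
                    p = per_cohort[cohort]["p"][frozenset((s, t))]
                    dunn_evidence[cohort][t] = p
                    sign = per_cohort[cohort]["sign"][(s, t)]
                    if sign == 0:
                        ok = False
                    signs.add(sign)
                    if p < cfg.dunn_fdr:
                        continue
                    relax_alpha = cfg.borderline_relax.get(s)
                    others = [c for c in cohorts if c != cohort]
                    if (
                        relax_alpha is not None
                        and cohort == discovery_cohort
                        and p < relax_alpha
                        and all(
                            per_cohort[c]["p"][frozenset((s, t))] < cfg.dunn_fdr for c in others
                        )
                    ):
                        relaxed_used = True
                        continue
                    ok = False
            if ok and len(signs) == 1:
                direction = "up" if signs == {1} else "down"
                calls.append(
                    MarkerCall(
                        mirna_id=f,
                        subtype=s,
                        direction=direction,
                        relaxed=relaxed_used,
                        kw_p_adj=kw_lookup.get(f, {}),
                        dunn_p_adj=dunn_evidence,
                    )
                )
    return calls


def normal_filter(
    candidates: list[MarkerCall],
    mats: dict[str, ExprMatrix],
    groups: Groups,
    normal_samples: dict[str, list[str]],
    cfg: RunConfig,
) -> list[MarkerCall]:
    """Keep candidates that also differ from normal tissue, per cohort with normals.

    Mann-Whitney of the candidate subtype's tumor samples against the
    normals, BH across candidates within each cohort; a candidate survives
    only if p_adj < normal_fdr AND the tumor-vs-normal direction matches the
    tumor-side call, in every normal-bearing cohort.
    """
    bearing = [c for c, ids in normal_samples.items() if ids]
    if not bearing:
        msg = "no cohort contains normal samples; normal filter skipped"
        if not cfg.allow_skip_normal_filter:
            raise ValueError(msg)
        logger.warning(msg.upper())
        return list(candidates)
    if not candidates:
        return []
    keep = np.ones(len(candidates), dtype=bool)
    for cohort in bearing:
        normals = normal_samples[cohort]
        ps, dirs = [], []
        for cand in candidates:
            tumor_ids = groups[cohort].get(cand.subtype, [])
            vals = mats[cohort].values.loc[cand.mirna_id, tumor_ids].to_numpy(dtype=float)
            nvals = mats[cohort].values.loc[cand.mirna_id, normals].to_numpy(dtype=float)
            res = mann_whitney(vals, nvals)
            ps.append(res.p)
            dirs.append(res.direction)
        p_adj = bh_adjust(ps)
        for i, cand in enumerate(candidates):
            cand.normal_p_adj[cohort] = float(p_adj[i])
            want = 1 if cand.direction == "up" else -1
            if p_adj[i] >= cfg.normal_fdr or dirs[i] != want:
                keep[i] = False
    kept = [c for c, k in zip(candidates, keep) if k]
    logger.info("normal filter kept %d/%d candidates", len(kept), len(candidates))
    return kept


def find_markers(
    mats: dict[str, ExprMatrix],
    groups: Groups,
    normal_samples: dict[str, list[str]],
    cfg: RunConfig,
    discovery_cohort: str | None = None,
) -> tuple[list[MarkerCall], pd.DataFrame]:
    """Full consensus procedure: screen, specificity, normal filter.

    Returns the final calls plus the omnibus screen table.
    """
    screened, kw_table = omnibus_screen(mats, groups, cfg)
    candidates = specificity_call(
        screened, mats, groups, cfg, discovery_cohort=discovery_cohort, kw_table=kw_table
    )
    final = normal_filter(candidates, mats, groups, normal_samples, cfg)
    return final, kw_table
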
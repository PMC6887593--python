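#!/usr/bin/env python
"""Link markers to hallmark programs and prioritize predicted targets.

Spearman correlation of each marker with every gene-set score (Bonferroni
over markers x sets, per cohort), the most-anticorrelated-set rule, and the
dual-cohort negative-correlation test of very_high predicted pairs.  Writes
associations.tsv, set_selection.tsv and target_candidates.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from mirsubtypes.io_formats import RunConfig, read_expr_matrix
from mirsubtypes.markers import MarkerCall
from mirsubtypes.pathway_links import correlate_markers, prioritize_targets, select_gene_sets
from mirsubtypes.pipeline import COHORTS, build_groups, enrichment_stage, load_study
from mirsubtypes.synthetic_cohort import score_recovery


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--study", default="results/study")
    args = ap.parse_args()

    study = load_study(args.study)
    d = Path(args.study)
    mirna = {c: read_expr_matrix(d / f"mirna_{c}_norm.tsv") for c in COHORTS}
    mrna = {c: read_expr_matrix(d / f"mrna_{c}_norm.tsv") for c in COHORTS}
    calls = pd.read_csv(d / "subtype_calls.tsv", sep="\t")
    _groups, tumors, _normals = build_groups(calls, study.annotation)

    marker_table = pd.read_csv(d / "marker_calls.tsv", sep="\t")
    markers = [
        MarkerCall(r["mirna_id"], r["subtype"], r["direction"], bool(r["relaxed"]))
        for _, r in marker_table.iterrows()
    ]
    cfg = RunConfig()
    scores = enrichment_stage(mrna, study.gene_sets, tumors, cfg)
    assoc = correlate_markers(markers, mirna, scores, tumors, cfg)
    selection = select_gene_sets(assoc, cfg)
    targets = prioritize_targets(
        selection, study.target_ranks, mrna, mirna, study.gene_sets, tumors, cfg
    )
    assoc.to_csv(d / "associations.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"mirna_id": m, "subtype": s, "set_name": n}
         for (m, s), names in selection.items() for n in names]
    ).to_csv(d / "set_selection.tsv", sep="\t", index=False)
    targets.to_csv(d / "target_candidates.tsv", sep="\t", index=False)

    n_sig = int(assoc["significant_both"].sum())
    print(f"{n_sig} marker-pathway associations significant in both cohorts")
    picked = pd.DataFrame(
        [{"mirna_id": m, "set_name": n} for (m, _s), names in selection.items() for n in names],
        columns=["mirna_id", "set_name"],
    )
    cs = score_recovery(picked, study.truth.couplings, kind="couplings")
    acc = targets[targets["accepted"]]
    ts = score_recovery(acc, study.truth.targets, kind="targets")
    print(f"set selection recovers {cs.tp}/{cs.tp + cs.fn} planted couplings")
    print(f"targets: {len(acc)} accepted of {len(targets)} candidates "
          f"(recall {ts.recall:.2f}, decoys accepted {ts.fp})")


if __name__ == "__main__":
    main()
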
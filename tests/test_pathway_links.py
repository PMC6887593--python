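"""Pathway association, set selection, target gating, clustering, report."""

import numpy as np
import pandas as pd
import pytest

from mirsubtypes.io_formats import ExprMatrix, GeneSetCollection, RunConfig, TargetRankTable
from mirsubtypes.markers import MarkerCall
from mirsubtypes.pathway_links import (
    build_report,
    cluster_correlations,
    correlate_markers,
    prioritize_targets,
    select_gene_sets,
)
from mirsubtypes.rankstats import spearman


def _assoc_row(mirna, set_name, rho_d, rho_v, sig=True, subtype="S", direction="up"):
    return {
        "mirna_id": mirna, "subtype": subtype, "marker_direction": direction,
        "set_name": set_name, "rho_discovery": rho_d, "rho_validation": rho_v,
        "p_adj_discovery": 0.001 if sig else 0.9,
        "p_adj_validation": 0.001 if sig else 0.9,
        "significant_both": sig and (np.sign(rho_d) == np.sign(rho_v)),
        "signed_direction": int(np.sign(rho_d) * (1 if direction == "up" else -1)),
        "selected_for_targets": False,
    }


class TestSelection:
    def test_minimax_prefers_better_worse_cohort(self):
        # (-0.6, -0.5) beats (-0.7, -0.4): worse-cohort rho -0.5 < -0.4
        df = pd.DataFrame([
            _assoc_row("m1", "SET_A", -0.6, -0.5),
            _assoc_row("m1", "SET_B", -0.7, -0.4),
        ])
        sel = select_gene_sets(df, RunConfig())
        assert sel == {("m1", "S"): ["SET_A"]}
        assert df.loc[df["set_name"] == "SET_A", "selected_for_targets"].all()

    def test_mean_rule_alternative(self):
        df = pd.DataFrame([
            _assoc_row("m1", "SET_A", -0.6, -0.5),   # mean -0.55
            _assoc_row("m1", "SET_B", -0.7, -0.45),  # mean -0.575
        ])
        sel = select_gene_sets(df, RunConfig(set_pick_rule="mean"))
        assert sel == {("m1", "S"): ["SET_B"]}

    def test_positive_sets_never_selected(self):
        df = pd.DataFrame([
            _assoc_row("m1", "SET_POS", 0.9, 0.95),
            _assoc_row("m1", "SET_WEAKNEG", -0.2, -0.1, sig=False),
        ])
        assert select_gene_sets(df, RunConfig()) == {}

    def test_extra_sets_appended_only_when_significant(self):
        df = pd.DataFrame([
            _assoc_row("m1", "SET_A", -0.6, -0.5),
            _assoc_row("m1", "SET_EXTRA", -0.4, -0.3),
            _assoc_row("m1", "SET_NOPE", -0.4, -0.3, sig=False),
        ])
        cfg = RunConfig(extra_gene_sets={"S": ["SET_EXTRA", "SET_NOPE"]})
        sel = select_gene_sets(df, cfg)
        assert sel[("m1", "S")] == ["SET_A", "SET_EXTRA"]

    def test_row_order_invariance(self):
        rows = [
            _assoc_row("m1", "SET_A", -0.6, -0.5),
            _assoc_row("m1", "SET_B", -0.7, -0.4),
            _assoc_row("m2", "SET_B", -0.8, -0.6),
        ]
        a = select_gene_sets(pd.DataFrame(rows), RunConfig())
        b = select_gene_sets(pd.DataFrame(rows[::-1]), RunConfig())
        assert a == b


class TestAssociations:
    def _setup(self):
        rng = np.random.default_rng(0)
        n = {"discovery": 40, "validation": 50}
        markers = [MarkerCall("m1", "S", "up"), MarkerCall("m2", "S", "down")]
        mirna, scores, tumors = {}, {}, {}
        from mirsubtypes.enrichment import EnrichmentScores

        for cohort, nc in n.items():
            samples = [f"{cohort[0]}{i}" for i in range(nc)]
            driver = rng.normal(size=nc)
            M = pd.DataFrame(
                [driver + 0.3 * rng.normal(size=nc), rng.normal(size=nc)],
                index=["m1", "m2"], columns=samples,
            )
            S = pd.DataFrame(
                [-driver + 0.3 * rng.normal(size=nc),
                 rng.normal(size=nc),
                 rng.normal(size=nc)],
                index=["SET_A", "SET_B", "SET_C"], columns=samples,
            )
            mirna[cohort] = ExprMatrix(M)
            scores[cohort] = EnrichmentScores(scores=S)
            tumors[cohort] = samples
        return markers, mirna, scores, tumors

    def test_bonferroni_family_is_markers_times_sets(self):
        markers, mirna, scores, tumors = self._setup()
        df = correlate_markers(markers, mirna, scores, tumors, RunConfig())
        # family = 2 markers x 3 sets = 6, per cohort
        for cohort in ("discovery", "validation"):
            row = df.iloc[0]
            raw = spearman(
                mirna[cohort].values.loc[row["mirna_id"], tumors[cohort]],
                scores[cohort].scores.loc[row["set_name"], tumors[cohort]],
            ).p
            assert row[f"p_adj_{cohort}"] == pytest.approx(min(1.0, raw * 6), abs=1e-12)

    def test_planted_coupling_significant_decoy_not(self):
        markers, mirna, scores, tumors = self._setup()
        df = correlate_markers(markers, mirna, scores, tumors, RunConfig())
        coupled = df[(df["mirna_id"] == "m1") & (df["set_name"] == "SET_A")].iloc[0]
        assert coupled["significant_both"] and coupled["rho_discovery"] < 0
        decoy = df[(df["mirna_id"] == "m2") & (df["set_name"] == "SET_B")].iloc[0]
        assert not decoy["significant_both"]


class TestTargets:
    def _setup(self):
        rng = np.random.default_rng(1)
        sets = GeneSetCollection({"SET_A": ["g1", "g2", "g3"]})
        selection = {("m1", "S"): ["SET_A"]}
        rank = TargetRankTable(pd.DataFrame({
            "mirna_id": ["m1", "m1", "m1"],
            "gene_id": ["g1", "g2", "g3"],
            "confidence_class": ["very_high", "high", "very_high"],
        }))
        mirna, mrna, tumors = {}, {}, {}
        for cohort, nc in (("discovery", 60), ("validation", 80)):
            samples = [f"{cohort[0]}{i}" for i in range(nc)]
            m = rng.normal(size=nc)
            G = pd.DataFrame(
                [
                    -0.9 * m + 0.3 * rng.normal(size=nc),  # g1 repressed
                    -0.9 * m + 0.3 * rng.normal(size=nc),  # g2 repressed but class high
                    rng.normal(size=nc),                   # g3 very_high decoy
                ],
                index=["g1", "g2", "g3"], columns=samples,
            )
            mirna[cohort] = ExprMatrix(pd.DataFrame([m], index=["m1"], columns=samples))
            mrna[cohort] = ExprMatrix(G)
            tumors[cohort] = samples
        return selection, rank, mrna, mirna, sets, tumors

    def test_class_gate_and_correlation_gate(self):
        selection, rank, mrna, mirna, sets, tumors = self._setup()
        df = prioritize_targets(selection, rank, mrna, mirna, sets, tumors, RunConfig())
        by_gene = df.set_index("gene_id")
        assert "g2" not in by_gene.index  # anticorrelated but only class "high"
        assert bool(by_gene.loc["g1", "accepted"])
        assert not bool(by_gene.loc["g3", "accepted"])  # decoy: rho ~ 0

    def test_accepted_implies_negative_rho_everywhere(self):
        selection, rank, mrna, mirna, sets, tumors = self._setup()
        df = prioritize_targets(selection, rank, mrna, mirna, sets, tumors, RunConfig())
        acc = df[df["accepted"]]
        assert (acc["rho_discovery"] < 0).all() and (acc["rho_validation"] < 0).all()

    def test_empty_universe(self):
        selection, rank, mrna, mirna, sets, tumors = self._setup()
        empty = prioritize_targets({}, rank, mrna, mirna, sets, tumors, RunConfig())
        assert empty.empty


class TestClustering:
    def test_identical_rows_adjacent(self):
        rho = pd.DataFrame(
            [[0.5, -0.5, 0.1], [0.5, -0.5, 0.1], [-0.9, 0.9, 0.0]],
            index=["r1", "r2", "r3"], columns=["c1", "c2", "c3"],
        )
        orders = cluster_correlations(rho)
        rows = orders["rows"]
        assert abs(rows.index("r1") - rows.index("r2")) == 1

    def test_two_pair_structure(self):
        """Brute-force check: in two well-separated pairs, the first merges
        happen within pairs, so each pair is contiguous in the leaf order."""
        rho = pd.DataFrame(
            [[0.0, 0.0], [0.1, 0.0], [5.0, 5.0], [5.1, 5.0]],
            index=list("abcd"), columns=["x", "y"],
        )
        rows = cluster_correlations(rho)["rows"]
        assert {rows.index("a"), rows.index("b")} in ({0, 1}, {2, 3})
        assert {rows.index("c"), rows.index("d")} in ({0, 1}, {2, 3})

    def test_permutation_invariant_partitions(self):
        rho = pd.DataFrame(
            [[0.0, 0.0], [0.1, 0.0], [5.0, 5.0], [5.1, 5.0]],
            index=list("abcd"), columns=["x", "y"],
        )
        perm = rho.iloc[[2, 0, 3, 1]]
        rows = cluster_correlations(perm)["rows"]
        assert {rows.index("a"), rows.index("b")} in ({0, 1}, {2, 3})

    def test_constant_matrix_warns_but_orders(self, caplog):
        rho = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("xyz"))
        with caplog.at_level("WARNING"):
            orders = cluster_correlations(rho)
        assert sorted(orders["rows"]) == ["a", "b", "c"]

    def test_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            cluster_correlations(pd.DataFrame([[1.0]]))


class TestReport:
    def test_sign_rule(self):
        assoc = pd.DataFrame([
            _assoc_row("m_down", "SET_X", -0.5, -0.5, direction="down"),
            _assoc_row("m_up", "SET_Y", 0.5, 0.5, direction="up"),
        ])
        markers = pd.DataFrame(
            {"mirna_id": ["m_down", "m_up"], "subtype": ["S", "S"],
             "direction": ["down", "up"], "relaxed": [False, False]}
        )
        targets = pd.DataFrame(columns=["accepted"])
        report = build_report(markers, assoc, targets)
        pd_dir = report["pathway_directions"].set_index("set_name")["pathway_direction"]
        assert pd_dir["SET_X"] == "up"   # anticorrelated with a down marker
        assert pd_dir["SET_Y"] == "up"   # positively correlated with an up marker
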
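import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ceranet as cn
from ceranet.core import ExpressionMatrix
from ceranet.network import (
    CorrEdge,
    assemble_network,
    build_edges,
    correlation_target_sets,
    filter_ppi,
    spearman,
)
from ceranet.patterns import PatternCall
from ceranet.targets import TargetSite

from _oracles import spearman_rho_oracle


class TestSpearman:
    def test_worked_values(self):
        assert spearman([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])[0] == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])[0] == pytest.approx(-1.0)
        # 1 - 6*sum(d^2)/(n(n^2-1)) with sum(d^2) = 2
        assert spearman([1, 2, 3], [2, 1, 3])[0] == pytest.approx(0.5)

    def test_perfect_correlation_p_zero(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]) == (1.0, 0.0)

    def test_constant_vector_undefined(self):
        rho, p = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(rho) and np.isnan(p)

    def test_matches_oracle_with_and_without_ties(self, rng):
        for _ in range(300):
            n = int(rng.integers(4, 12))
            x = rng.integers(0, 6, size=n).astype(float)  # heavy ties
            y = rng.normal(size=n)
            if np.ptp(x) == 0:
                continue
            rho, _ = spearman(x, y)
            assert rho == pytest.approx(spearman_rho_oracle(x, y), abs=1e-12)
            assert rho == pytest.approx(spearman(y, x)[0], abs=1e-15)  # symmetry

    def test_agrees_with_scipy(self, rng):
        for _ in range(50):
            x = rng.normal(size=9)
            y = rng.normal(size=9)
            rho, p = spearman(x, y)
            ref = stats.spearmanr(x, y)
            assert rho == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_exact_permutation_tail(self):
        # for x=y of length 4, |rho|=1 occurs for exactly the identity and
        # the reversal among the 24 permutations
        rho, p = spearman([1, 2, 3, 4], [1, 2, 3, 4], method="exact")
        assert rho == 1.0 and p == pytest.approx(2 / 24)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="n >= 3"):
            spearman([1, 2], [3, 4])
        with pytest.raises(ValueError, match="n <= 9"):
            spearman(list(range(10)), list(range(10)), method="exact")


def expr(rows: dict[str, list[float]], rna_class: str, samples=None) -> ExpressionMatrix:
    samples = samples or [f"s{i}" for i in range(len(next(iter(rows.values()))))]
    return ExpressionMatrix(
        pd.DataFrame.from_dict(rows, orient="index", columns=samples), rna_class
    )


def site(mir, tx):
    return TargetSite(mir, tx, 0, 22, 145.0, True)


@pytest.fixture()
def triplet_exprs():
    # m1/l1 rise monotonically, mi1 falls: a clean ceRNA triplet.
    up = [1.0, 2, 3, 4, 5, 6, 7, 8, 9]
    down = up[::-1]
    flat_noise = [5, 3, 6, 2, 7, 1, 8, 4, 9]
    return {
        "mRNA": expr({"m1": up, "m2": flat_noise}, "mRNA"),
        "lncRNA": expr({"l1": [2 * v for v in up]}, "lncRNA"),
        "miRNA": expr({"mi1": down}, "miRNA"),
    }


class TestBuildEdges:
    def test_strong_negative_target_pair_emitted(self, triplet_exprs):
        edges = build_edges(triplet_exprs, [site("mi1", "m1"), site("mi1", "l1")])
        types = {e.edge_type for e in edges}
        assert types == {"miRNA-mRNA", "miRNA-lncRNA", "mRNA-lncRNA"}
        for e in edges:
            if e.edge_type == "mRNA-lncRNA":
                assert e.rho >= 0.7 and e.p < 0.05
            else:
                assert e.rho <= -0.7 and e.p < 0.05

    def test_weak_correlation_rejected(self, triplet_exprs):
        # mi1 vs the noisy m2 profile: |rho| far below 0.7
        edges = build_edges(triplet_exprs, [site("mi1", "m2")])
        assert edges == []

    def test_pairs_without_shared_mirna_never_tested(self, triplet_exprs):
        # l1 is not a predicted target, so no mRNA-lncRNA candidate exists
        edges = build_edges(triplet_exprs, [site("mi1", "m1")])
        assert {e.edge_type for e in edges} == {"miRNA-mRNA"}

    def test_differing_sample_sets_rejected(self, triplet_exprs):
        bad = dict(triplet_exprs)
        bad["miRNA"] = expr({"mi1": [1.0] * 9}, "miRNA", samples=[f"x{i}" for i in range(9)])
        with pytest.raises(ValueError, match="sample sets differ"):
            build_edges(bad, [])


def calls_for(nodes: dict[str, tuple[str, str]]):
    return [
        PatternCall(g, cls, (1, 2, 3) if d == "up" else (3, 2, 1),
                    f"growth_{d}")
        for g, (cls, d) in nodes.items()
    ]


def full_triplet_edges(m, mi, l, rho=0.9):
    return [
        CorrEdge(mi, "miRNA", m, "mRNA", "miRNA-mRNA", -rho, 0.001),
        CorrEdge(mi, "miRNA", l, "lncRNA", "miRNA-lncRNA", -rho, 0.001),
        CorrEdge(m, "mRNA", l, "lncRNA", "mRNA-lncRNA", rho, 0.001),
    ]


class TestAssembleNetwork:
    def test_two_disjoint_triplets_two_components(self):
        edges = full_triplet_edges("m1", "mi1", "l1") + full_triplet_edges("m2", "mi2", "l2")
        calls = calls_for({
            "m1": ("mRNA", "up"), "l1": ("lncRNA", "up"), "mi1": ("miRNA", "down"),
            "m2": ("mRNA", "down"), "l2": ("lncRNA", "down"), "mi2": ("miRNA", "up"),
        })
        net = assemble_network(edges, calls)
        assert len(net.triplets) == 2
        assert [len(c) for c in net.components] == [3, 3]
        assert sorted(net.component_labels) == ["downregulated", "upregulated"]

    def test_star_mirna_hub(self):
        # one miRNA bound to 3 mRNAs and 2 lncRNAs, all pairings passing:
        # the miRNA has degree 5 and is the unique hub
        edges = []
        for m in ("m1", "m2", "m3"):
            edges.append(CorrEdge("mi1", "miRNA", m, "mRNA", "miRNA-mRNA", -0.9, 0.001))
            for l in ("l1", "l2"):
                edges.append(CorrEdge(m, "mRNA", l, "lncRNA", "mRNA-lncRNA", 0.9, 0.001))
        for l in ("l1", "l2"):
            edges.append(CorrEdge("mi1", "miRNA", l, "lncRNA", "miRNA-lncRNA", -0.9, 0.001))
        calls = calls_for({
            "m1": ("mRNA", "up"), "m2": ("mRNA", "up"), "m3": ("mRNA", "up"),
            "l1": ("lncRNA", "up"), "l2": ("lncRNA", "up"), "mi1": ("miRNA", "down"),
        })
        net = assemble_network(edges, calls)
        assert net.graph.degree("mi1") == 5
        assert net.hubs == [["mi1"]]
        assert net.component_labels == ["upregulated"]

    def test_mixed_direction_component(self):
        edges = full_triplet_edges("m1", "mi1", "l1") + full_triplet_edges("m2", "mi1", "l1")
        calls = calls_for({
            "m1": ("mRNA", "up"), "m2": ("mRNA", "down"),
            "l1": ("lncRNA", "up"), "mi1": ("miRNA", "down"),
        })
        net = assemble_network(edges, calls)
        assert net.component_labels == ["mixed"]

    def test_direction_flip_swaps_component_labels(self):
        edges = full_triplet_edges("m1", "mi1", "l1")
        base = calls_for({"m1": ("mRNA", "up"), "l1": ("lncRNA", "up"),
                          "mi1": ("miRNA", "down")})
        flipped = [
            PatternCall(c.gene, c.rna_class, c.means[::-1],
                        c.label.replace("up", "X").replace("down", "up").replace("X", "down"))
            for c in base
        ]
        assert assemble_network(edges, base).component_labels == ["upregulated"]
        assert assemble_network(edges, flipped).component_labels == ["downregulated"]

    def test_unknown_direction_rejected(self):
        edges = full_triplet_edges("m1", "mi1", "l1")
        calls = calls_for({"m1": ("mRNA", "up"), "l1": ("lncRNA", "up")})
        with pytest.raises(ValueError, match="direction"):
            assemble_network(edges, calls)

    def test_triplet_enumeration_matches_brute_force(self, rng):
        # random edge soup over <= 30 nodes: triplets equal the exhaustive
        # scan over all (mRNA, miRNA, lncRNA) combinations
        mrnas = [f"m{i}" for i in range(10)]
        lncs = [f"l{i}" for i in range(10)]
        mirs = [f"mi{i}" for i in range(10)]
        edges, present = [], set()
        for mi, m in itertools.product(mirs, mrnas):
            if rng.random() < 0.25:
                edges.append(CorrEdge(mi, "miRNA", m, "mRNA", "miRNA-mRNA", -0.9, 0.001))
                present.add((mi, m))
        for mi, l in itertools.product(mirs, lncs):
            if rng.random() < 0.25:
                edges.append(CorrEdge(mi, "miRNA", l, "lncRNA", "miRNA-lncRNA", -0.9, 0.001))
                present.add((mi, l))
        for m, l in itertools.product(mrnas, lncs):
            if rng.random() < 0.25:
                edges.append(CorrEdge(m, "mRNA", l, "lncRNA", "mRNA-lncRNA", 0.9, 0.001))
                present.add((m, l))
        calls = calls_for(
            {g: ("mRNA", "up") for g in mrnas}
            | {g: ("lncRNA", "up") for g in lncs}
            | {g: ("miRNA", "down") for g in mirs}
        )
        net = assemble_network(edges, calls)
        brute = {
            (m, mi, l)
            for m, mi, l in itertools.product(mrnas, mirs, lncs)
            if (mi, m) in present and (mi, l) in present and (m, l) in present
        }
        assert {(t.mrna, t.mirna, t.lncrna) for t in net.triplets} == brute


class TestCorrelationTargetSets:
    def test_perfectly_coexpressed_lncrna(self, triplet_exprs):
        sets = correlation_target_sets(triplet_exprs, [])
        assert "m1" in sets["lncRNA"]["l1"]  # rho = 1 with no targeting needed

    def test_weakly_correlated_predicted_target_excluded(self, triplet_exprs):
        sets = correlation_target_sets(triplet_exprs, [site("mi1", "m2")])
        assert sets["miRNA"]["mi1"] == set()

    def test_mirna_modes(self, triplet_exprs):
        targets = [site("mi1", "m1")]
        for mode, expected in (("absolute", {"m1"}), ("negative", {"m1"}), ("positive", set())):
            sets = correlation_target_sets(triplet_exprs, targets, mirna_mode=mode)
            assert sets["miRNA"]["mi1"] == expected, mode

    def test_planted_triplet_mrna_in_its_mirnas_set(self, small_dataset):
        cfg, mats, truth, mirnas, transcripts = small_dataset
        sites = cn.predict_targets(mirnas, transcripts)
        factors = {cls: cn.size_factors(m) for cls, m in mats.items()}
        norm = {cls: mats[cls].normalized(factors[cls]) for cls in mats}
        sets = correlation_target_sets(norm, sites)
        hits = sum(
            m_id in sets["miRNA"].get(mi_id, set())
            for m_id, mi_id, _ in truth.planted_triplets
        )
        assert hits / len(truth.planted_triplets) >= 0.9


class TestFilterPPI:
    def test_strict_threshold(self):
        df = pd.DataFrame(
            {"gene_a": ["a", "a"], "gene_b": ["b", "c"], "combined_score": [0.41, 0.40]}
        )
        kept = filter_ppi(df)
        assert list(kept["gene_b"]) == ["b"]

    def test_empty_table_passes_through(self):
        df = pd.DataFrame({"gene_a": [], "gene_b": [], "combined_score": []})
        assert len(filter_ppi(df)) == 0

    def test_all_max_scores_identity_on_restricted_genes(self):
        df = pd.DataFrame(
            {"gene_a": ["a", "b"], "gene_b": ["b", "z"], "combined_score": [1.0, 1.0]}
        )
        kept = filter_ppi(df, genes={"a", "b"})
        assert len(kept) == 1 and kept.loc[0, "gene_b"] == "b"

    def test_out_of_range_score_rejected(self):
        df = pd.DataFrame({"gene_a": ["a"], "gene_b": ["b"], "combined_score": [1.2]})
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            filter_ppi(df)
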
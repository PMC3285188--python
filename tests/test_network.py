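import numpy as np
import pandas as pd
import pytest

from diffconn.io import ExpressionStudy
from diffconn.network import (
    build_network,
    classify_sectors,
    combine_gene_set,
    diffk,
    diffk_pvalues,
    export_network,
    hub_table,
    merge_similar_samples,
)
from diffconn.simulate import SimulationSpec, simulate_expression

from conftest import make_design, make_study


class TestCombineGeneSet:
    def test_union_sorted(self):
        assert combine_gene_set(["B", "A"], ["B", "C"]) == ["A", "B", "C"]

    def test_disjoint_and_symmetry(self):
        assert combine_gene_set(["x"], ["y"]) == ["x", "y"]
        assert combine_gene_set(["y"], ["x"]) == combine_gene_set(["x"], ["y"])

    def test_empty_union_error(self):
        with pytest.raises(ValueError, match="empty"):
            combine_gene_set([], [])


def _six_sample_study(n_genes=40, seed=0, pair_noise=1e-3):
    """IF group whose six samples per timepoint form three planted pairs."""
    rng = np.random.default_rng(seed)
    design = make_design(n_if=6, n_id=2)
    latent = {tp: rng.normal(8, 1, size=(n_genes, 3)) for tp in ("pre", "post")}
    cols = {}
    for sid, row in design.iterrows():
        if row["group"] == "IF":
            unit = (int(row["patient_id"][2:]) - 1) // 2
            base = latent[row["timepoint"]][:, unit]
        else:
            base = rng.normal(8, 1, size=n_genes)
        cols[sid] = base + rng.normal(0, pair_noise, size=n_genes)
    matrix = pd.DataFrame(cols, index=[f"g{i}" for i in range(n_genes)])
    return ExpressionStudy(matrix, design)


class TestMerging:
    def test_planted_pairs_recovered(self):
        study = _six_sample_study()
        merged = merge_similar_samples(study, "IF", target=3)
        pairs = {frozenset(v) for v in merged.meta["merge_map"].values()}
        assert pairs == {
            frozenset({"IF01", "IF02"}),
            frozenset({"IF03", "IF04"}),
            frozenset({"IF05", "IF06"}),
        }

    def test_merged_profile_is_pair_mean(self):
        study = _six_sample_study()
        merged = merge_similar_samples(study, "IF", target=3)
        for sid, members in merged.meta["merge_map"].items():
            tp = merged.design.loc[sid, "timepoint"]
            src = [f"{p}_{tp}" for p in members]
            np.testing.assert_allclose(
                merged.matrix[sid], study.matrix[src].mean(axis=1)
            )

    def test_identical_pair_merge_is_idempotent(self):
        study = _six_sample_study(pair_noise=0.0)
        merged = merge_similar_samples(study, "IF", target=3)
        sid = merged.sample_ids[0]
        member = merged.meta["merge_map"][sid][0]
        tp = merged.design.loc[sid, "timepoint"]
        np.testing.assert_allclose(merged.matrix[sid], study.matrix[f"{member}_{tp}"])

    def test_correlation_after_merge_matches_hand_average(self):
        study = _six_sample_study(seed=3)
        merged = merge_similar_samples(study, "IF", target=3)
        state = build_network(merged.condition_matrix("IF", "pre"))
        hand_cols = np.column_stack(
            [
                study.matrix[[f"{p}_pre" for p in members]].mean(axis=1)
                for sid, members in merged.meta["merge_map"].items()
                if sid.endswith("_pre")
            ]
        )
        np.testing.assert_allclose(
            state.corr.to_numpy(), np.corrcoef(hand_cols), atol=1e-12
        )

    def test_wrong_sample_count_rejected(self):
        study = make_study(n_if=4, n_id=2)
        with pytest.raises(ValueError, match="cannot pair"):
            merge_similar_samples(study, "IF", target=3)


class TestBuildNetwork:
    def test_two_perfectly_correlated_genes(self):
        X = pd.DataFrame([[1.0, 2, 3], [2.0, 4, 6]], index=["a", "b"])
        state = build_network(X)
        assert list(state.k) == [1.0, 1.0]

    def test_hand_computed_connectivity(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(4, 5)), index=list("abcd"))
        state = build_network(X)
        r = np.corrcoef(X.to_numpy())
        for i, g in enumerate("abcd"):
            expect = sum(abs(r[i, j]) for j in range(4) if j != i)
            assert state.K[g] == pytest.approx(expect, abs=1e-12)

    def test_loop_oracle_twenty_genes(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(20, 6)), index=[f"g{i}" for i in range(20)])
        state = build_network(X)
        r = np.corrcoef(X.to_numpy())
        K = np.array(
            [sum(abs(r[i, j]) for j in range(20) if j != i) for i in range(20)]
        )
        np.testing.assert_allclose(state.K.to_numpy(), K, atol=1e-12)
        np.testing.assert_allclose(state.k.to_numpy(), K / K.max(), atol=1e-12)

    def test_constant_gene_dropped(self):
        X = pd.DataFrame(
            [[1.0, 1, 1], [1.0, 2, 3], [3.0, 1, 2]], index=["flat", "a", "b"]
        )
        state = build_network(X)
        assert state.dropped == ["flat"]
        assert "flat" not in state.genes

    def test_requires_three_profiles(self):
        X = pd.DataFrame([[1.0, 2], [2.0, 1]], index=["a", "b"])
        with pytest.raises(ValueError, match=">= 3 profiles"):
            build_network(X)

    def test_normalization_max_is_exactly_one(self):
        rng = np.random.default_rng(9)
        for seed in range(5):
            X = pd.DataFrame(
                np.random.default_rng(seed).normal(size=(15, 4)),
                index=[f"g{i}" for i in range(15)],
            )
            k = build_network(X).k
            assert k.max() == 1.0
            assert (k >= 0).all()
            assert (k.to_numpy() == 1.0).sum() >= 1


class TestDiffK:
    def test_identical_networks_zero(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(10, 4)), index=[f"g{i}" for i in range(10)])
        s = build_network(X)
        d = diffk(s, s)
        assert (d["diffk"] == 0).all()

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(4)
        for seed in range(5):
            r = np.random.default_rng(seed)
            a = build_network(
                pd.DataFrame(r.normal(size=(12, 4)), index=[f"g{i}" for i in range(12)])
            )
            b = build_network(
                pd.DataFrame(r.normal(size=(12, 4)), index=[f"g{i}" for i in range(12)])
            )
            d = diffk(a, b)["diffk"]
            assert ((d >= -1) & (d <= 1)).all()

    def test_disjoint_networks_error(self):
        X = pd.DataFrame(
            np.random.default_rng(0).normal(size=(4, 4)), index=list("abcd")
        )
        s1 = build_network(X.iloc[:2])
        s2 = build_network(X.iloc[2:])
        with pytest.raises(ValueError, match="no genes"):
            diffk(s1, s2)


class TestPermutationP:
    def test_pre_equals_post_gives_no_hubs(self):
        study = make_study(n_genes=15, n_if=4, n_id=2, seed=1)
        m = study.matrix.copy()
        for pid in study.patients():
            m[f"{pid}_post"] = m[f"{pid}_pre"]
        sym = ExpressionStudy(m, study.design.copy())
        tab = hub_table(sym, sym.gene_ids, "IF", n_perm=200, seed=0)
        assert (tab["diffk"] == 0).all()
        assert not tab["hub"].any()

    def test_p_in_unit_interval_and_floor(self):
        study = make_study(n_genes=12, n_if=4, n_id=2, seed=2)
        tab = diffk_pvalues(study, study.gene_ids, "IF", n_perm=200, seed=1)
        assert tab.attrs["exact"]  # 2^4 = 16 <= 200: exhaustive
        assert (tab["p"] > 0).all()
        assert (tab["p"] <= 1).all()

    def test_small_n_perm_rejected(self):
        study = make_study(n_genes=5, n_if=3, n_id=2)
        with pytest.raises(ValueError, match="n_perm"):
            diffk_pvalues(study, study.gene_ids, "IF", n_perm=50)

    def test_hub_calls_invariant_to_gene_order(self):
        spec = SimulationSpec(n_genes=60, de_fraction=0.0, seed=3)
        study, _ = simulate_expression(spec)
        genes = study.gene_ids
        t1 = hub_table(study, genes, "IF", n_perm=200, seed=5)
        t2 = hub_table(study, genes[::-1], "IF", n_perm=200, seed=5)
        assert t1["hub"].sort_index().equals(t2["hub"].sort_index())
        # exact enumeration: the seed is irrelevant
        t3 = hub_table(study, genes, "IF", n_perm=200, seed=99)
        assert t1["p"].equals(t3["p"])


class TestSectors:
    @pytest.mark.parametrize(
        "dk,p,sector,hub",
        [
            (0.25, 0.01, 1, True),
            (-0.5, 0.001, 3, True),
            (0.0, 0.5, 5, False),
            (0.3, 0.5, 2, False),
            (-0.3, 0.5, 4, False),
            (0.05, 0.01, 6, False),
        ],
    )
    def test_mapping(self, dk, p, sector, hub):
        rec = pd.DataFrame({"diffk": [dk], "p": [p]})
        s = classify_sectors(rec)
        assert s.iloc[0] == sector
        assert (s.iloc[0] in (1, 3)) == hub

    def test_significant_flanks_are_one_and_three(self):
        rng = np.random.default_rng(0)
        rec = pd.DataFrame(
            {"diffk": rng.uniform(-1, 1, 500), "p": rng.uniform(0, 1, 500)}
        )
        s = classify_sectors(rec)
        flank = (rec["diffk"].abs() > 0.2) & (rec["p"] < 0.05)
        assert set(s[flank]) <= {1, 3}
        assert not set(s[~flank]) & {1, 3}


class TestExport:
    def test_threshold_one_keeps_only_perfect_edges(self):
        X = pd.DataFrame([[1.0, 2, 3], [2.0, 4, 6], [1.0, 5, 2]], index=list("abc"))
        state = build_network(X)
        edges = state.edges(1.0)
        assert set(map(tuple, edges[["gene1", "gene2"]].to_numpy())) == {("a", "b")}

    def test_three_gene_toy_signed_edges(self):
        # correlations approximately (ab: +0.9ish, ac: -0.9ish, bc: small)
        X = pd.DataFrame(
            [[0.0, 1, 2, 3.1], [0.1, 0.9, 2.2, 2.9], [3.0, 2.1, 0.9, 0.1]],
            index=list("abc"),
        )
        state = build_network(X)
        nodes, edges, graph = export_network(state, edge_threshold=0.8)
        assert len(edges) >= 2
        assert set(edges["sign"]) == {"+", "-"}
        assert graph.number_of_nodes() == 3

    def test_mean_degree_monotone_in_threshold(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(25, 5)), index=[f"g{i}" for i in range(25)])
        state = build_network(X)
        degrees = [len(state.edges(t)) for t in (0.2, 0.5, 0.8, 0.95)]
        assert degrees == sorted(degrees, reverse=True)

    def test_bad_threshold_rejected(self):
        X = pd.DataFrame(
            np.random.default_rng(0).normal(size=(4, 4)), index=list("abcd")
        )
        with pytest.raises(ValueError):
            export_network(build_network(X), edge_threshold=0.0)
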
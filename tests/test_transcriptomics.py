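"""Maturation transcriptomics: filtering, gene selection, networks, scores."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from cardioquant.synthetic import ExprGroup, ExprSimSpec, gen_expression
from cardioquant.transcriptomics import (
    cumulative_category_score,
    filter_variable_genes,
    layout_network,
    log_transform,
    maturation_ratios,
    pca_gene_selection,
    sample_correlation_network,
)


def _planted_spec(seed=0, **kw):
    """Block-structured data: strong species axis, age axis on one set."""
    defaults = dict(
        n_genes=400,
        species_gene_frac=0.125,  # 50 species-divergent genes
        species_effect_sd=2.0,
        species_effect_min=2.0,
        effect_log2fc={"sarcomere": {"acomys": 2.0, "mus": 2.0}},
        noise_sd=0.15,
        seed=seed,
    )
    defaults.update(kw)
    return ExprSimSpec(**defaults)


class TestGenerator:
    def test_matrix_dimensions(self):
        spec = ExprSimSpec(
            n_genes=100,
            groups=tuple(
                ExprGroup(sp, age, 3) for sp in ("a", "b") for age in ("neonate", "adult")
            ),
            seed=0,
        )
        matrix, labels, _ = gen_expression(spec)
        assert matrix.shape == (100, 12)
        assert len(labels) == 12

    def test_seed_reproducibility(self):
        spec = ExprSimSpec(seed=5)
        m1, _, _ = gen_expression(spec)
        m2, _, _ = gen_expression(spec)
        assert m1.equals(m2)

    def test_planted_fold_change_recovered_in_group_means(self):
        spec = ExprSimSpec(
            effect_log2fc={"sarcomere": {"mus": 2.0}}, noise_sd=0.0, seed=1
        )
        matrix, labels, truth = gen_expression(spec)
        lab = labels.set_index("sample_id")
        genes = matrix.index[list(truth["gene_sets"]["sarcomere"])]
        sub = matrix.loc[genes]
        for species, expected in (("mus", 4.0), ("acomys", 1.0)):
            adult = sub.loc[:, (lab["species"] == species) & (lab["age"] == "adult")]
            neo = sub.loc[:, (lab["species"] == species) & (lab["age"] == "neonate")]
            ratio = (adult.mean(axis=1) / neo.mean(axis=1)).mean()
            assert ratio == pytest.approx(expected, rel=0.01)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ExprSimSpec(groups=()).validate()
        with pytest.raises(ValueError, match="samples"):
            ExprSimSpec(groups=(ExprGroup("a", "adult", 1),)).validate()
        with pytest.raises(ValueError, match="n_genes"):
            ExprSimSpec(n_genes=10, maturation_gene_sets={"s": [11]}).validate()


class TestVariableGeneFilter:
    def test_constant_gene_excluded(self):
        matrix = pd.DataFrame(
            {"s1": [5.0, 5.0], "s2": [5.0, 50.0], "s3": [5.0, 500.0], "s4": [5.0, 2.0]},
            index=["flat", "variable"],
        )
        assert filter_variable_genes(matrix) == ["variable"]

    def test_expression_boundary_needs_more_than_two_samples(self):
        base = {"s1": [5.0], "s2": [5.0], "s3": [0.0], "s4": [0.0]}
        two = pd.DataFrame(base, index=["g"])  # expressed in exactly 2
        assert filter_variable_genes(two) == []
        three = pd.DataFrame(
            {"s1": [5.0], "s2": [5.0], "s3": [5.0], "s4": [0.0]}, index=["g"]
        )
        assert filter_variable_genes(three) == ["g"]

    def test_planted_variable_set_recovered_exactly(self):
        spec = _planted_spec(noise_sd=0.0, seed=2)
        matrix, _, truth = gen_expression(spec)
        planted = set(matrix.index[truth["species_gene_indices"]]) | set(
            matrix.index[list(truth["gene_sets"]["sarcomere"])]
        )
        assert set(filter_variable_genes(matrix)) == planted

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            filter_variable_genes(pd.DataFrame())


class TestGeneSelection:
    def test_cap_and_threshold_enforced(self):
        spec = _planted_spec(seed=3)
        matrix, _, _ = gen_expression(spec)
        selection = pca_gene_selection(matrix, n_pcs=5)
        assert len(selection.genes) <= 250
        for pc, genes in selection.per_pc.items():
            assert len(genes) <= 50
            loadings = selection.loadings[f"PC{pc}"].loc[genes].abs()
            assert (loadings > 0.2).all()

    def test_planted_discriminants_recovered(self):
        jaccards = []
        for seed in range(3):
            spec = _planted_spec(seed=seed)
            matrix, _, truth = gen_expression(spec)
            planted = set(matrix.index[truth["species_gene_indices"]]) | set(
                matrix.index[list(truth["gene_sets"]["sarcomere"])]
            )
            variable = filter_variable_genes(matrix)
            selection = pca_gene_selection(matrix, genes=variable)
            got = set(selection.genes)
            jaccards.append(len(got & planted) / len(got | planted))
        assert min(jaccards) >= 0.8

    def test_sample_order_invariance(self):
        matrix, _, _ = gen_expression(_planted_spec(seed=4))
        sel_a = pca_gene_selection(matrix)
        shuffled = matrix[list(matrix.columns[::-1])]
        sel_b = pca_gene_selection(shuffled)
        assert sel_a.genes == sel_b.genes

    def test_rank_deficient_matrix_rejected(self):
        matrix = pd.DataFrame(
            np.random.default_rng(0).uniform(0, 10, (50, 3)),
            index=[f"g{i}" for i in range(50)],
            columns=["s1", "s2", "s3"],
        )
        with pytest.raises(ValueError, match="rank"):
            pca_gene_selection(matrix, n_pcs=5)


class TestNetwork:
    def test_adjacency_matches_pairwise_pearson_oracle(self):
        rng = np.random.default_rng(6)
        matrix = pd.DataFrame(
            rng.uniform(0, 100, (300, 20)),
            index=[f"g{i}" for i in range(300)],
            columns=[f"s{i}" for i in range(20)],
        )
        genes = list(matrix.index)
        net = sample_correlation_network(matrix, genes, r_threshold=0.6)
        log = log_transform(matrix)
        for i in range(20):
            for j in range(i + 1, 20):
                r, _ = pearsonr(log.iloc[:, i], log.iloc[:, j])
                has_edge = net.has_edge(f"s{i}", f"s{j}")
                assert has_edge == (r > 0.6)
                if has_edge:
                    assert net[f"s{i}"][f"s{j}"]["weight"] == pytest.approx(r)

    def test_duplicated_samples_get_unit_edge(self):
        matrix, _, _ = gen_expression(_planted_spec(seed=7))
        dup = matrix.copy()
        dup["clone"] = dup.iloc[:, 0]
        net = sample_correlation_network(dup, list(dup.index), 0.6)
        assert net.has_edge(dup.columns[0], "clone")
        assert net[dup.columns[0]]["clone"]["weight"] == pytest.approx(1.0)

    def test_threshold_one_gives_edgeless_network(self):
        matrix, _, _ = gen_expression(_planted_spec(seed=8))
        net = sample_correlation_network(matrix, list(matrix.index), 1.0)
        assert net.number_of_edges() == 0

    def test_anticorrelated_blocks_stay_disconnected(self):
        n = 50
        x = np.linspace(0, 1, n)
        cols = {}
        for i in range(4):
            cols[f"up{i}"] = 100 * x + i
        for i in range(4):
            cols[f"down{i}"] = 100 * (1 - x) + i
        matrix = pd.DataFrame(cols, index=[f"g{i}" for i in range(n)])
        net = sample_correlation_network(matrix, list(matrix.index), 0.6)
        for u in [c for c in cols if c.startswith("up")]:
            for v in [c for c in cols if c.startswith("down")]:
                assert not net.has_edge(u, v)

    def test_zero_variance_sample_isolated_with_warning(self):
        matrix, _, _ = gen_expression(_planted_spec(seed=9))
        degenerate = matrix.copy()
        degenerate["flat"] = 1.0
        with pytest.warns(UserWarning, match="zero variance"):
            net = sample_correlation_network(degenerate, list(matrix.index), 0.6)
        assert net.degree("flat") == 0

    def test_species_topology_over_seeds(self):
        pure = 0
        n_seeds = 20
        for seed in range(n_seeds):
            spec = ExprSimSpec(
                effect_log2fc={
                    "sarcomere": {"mus": 0.5},
                    "fatty_acid_metabolism": {"acomys": 0.25, "mus": 0.5},
                },
                seed=seed,
            )
            matrix, labels, _ = gen_expression(spec)
            variable = filter_variable_genes(matrix)
            selection = pca_gene_selection(matrix, genes=variable)
            net = sample_correlation_network(matrix, selection.genes, 0.6)
            lab = labels.set_index("sample_id")["species"]
            pure += all(
                lab.loc[list(c)].nunique() == 1
                for c in nx.connected_components(net)
                if len(c) > 1
            )
        assert pure / n_seeds >= 0.9


class TestLayout:
    def test_seed_reproducibility(self):
        g = nx.path_graph(6)
        a = layout_network(g, seed=3)
        b = layout_network(g, seed=3)
        for node in g:
            assert np.allclose(a[node], b[node])

    def test_cliques_separate(self):
        g = nx.Graph()
        for base in ("a", "b"):
            for i in range(4):
                for j in range(i + 1, 4):
                    g.add_edge(f"{base}{i}", f"{base}{j}")
        separated = 0
        for seed in range(5):
            pos = layout_network(g, seed=seed)
            intra, inter = [], []
            for u in g:
                for v in g:
                    if u < v:
                        d = np.linalg.norm(np.asarray(pos[u]) - np.asarray(pos[v]))
                        (intra if u[0] == v[0] else inter).append(d)
            separated += np.mean(inter) > np.mean(intra)
        assert separated >= 4

    def test_triangle_is_near_equilateral(self):
        g = nx.complete_graph(3)
        pos = layout_network(g, seed=0)
        d = [
            np.linalg.norm(np.asarray(pos[i]) - np.asarray(pos[j]))
            for i, j in [(0, 1), (1, 2), (0, 2)]
        ]
        assert max(d) / min(d) <= 1.2

    def test_singleton_at_origin(self):
        g = nx.Graph()
        g.add_node("only")
        assert np.allclose(layout_network(g)["only"], 0)


class TestCategoryScore:
    def test_adults_score_higher_with_planted_effect(self):
        wins = 0
        for seed in range(5):
            spec = ExprSimSpec(
                effect_log2fc={"sarcomere": {"mus": 1.0}}, seed=seed,
                groups=(
                    ExprGroup("mus", "neonate", 4),
                    ExprGroup("mus", "adult", 4),
                ),
            )
            matrix, labels, truth = gen_expression(spec)
            cats = {
                "sarcomere": matrix.index[list(truth["gene_sets"]["sarcomere"])]
            }
            scores = cumulative_category_score(matrix, cats)
            lab = labels.set_index("sample_id")
            adult = scores.loc[lab["age"] == "adult", "sarcomere"]
            neo = scores.loc[lab["age"] == "neonate", "sarcomere"]
            wins += adult.min() > neo.max()
        assert wins == 5

    def test_identical_samples_identical_scores(self):
        matrix = pd.DataFrame(
            {"s1": [1.0, 2.0, 8.0], "s2": [1.0, 2.0, 8.0], "s3": [4.0, 7.0, 2.0]},
            index=["g1", "g2", "g3"],
        )
        scores = cumulative_category_score(matrix, {"all": ["g1", "g2", "g3"]})
        assert scores.loc["s1", "all"] == pytest.approx(scores.loc["s2", "all"])

    def test_constant_gene_dropped_with_warning(self):
        matrix = pd.DataFrame(
            {"s1": [1.0, 3.0], "s2": [1.0, 5.0], "s3": [1.0, 9.0]},
            index=["flat", "g"],
        )
        with pytest.warns(UserWarning, match="constant"):
            scores = cumulative_category_score(matrix, {"set": ["flat", "g"]})
        rank = scores["set"].rank()
        with pytest.warns(UserWarning, match="constant"):
            scores2 = cumulative_category_score(
                matrix, {"set": ["flat", "g", "flat"]}
            )
        assert (scores2["set"].rank() == rank).all()

    def test_unmatched_category_rejected(self):
        matrix = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["g"])
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="usable"):
                cumulative_category_score(matrix, {"ghost": ["nope"]})


class TestMaturationRatios:
    def test_hand_computed_ratios(self):
        matrix = pd.DataFrame(
            {"s1": [2.0, 1.0, 4.0, 1.0], "s2": [1.0, 1.0, 2.0, 2.0]},
            index=["Tnni3", "Tnni1", "Myl2", "Myl7"],
        )
        out = maturation_ratios(matrix)
        assert out.loc["s1", "Tnni3_Tnni1"] == 2.0
        assert out.loc["s1", "log2_Tnni3_Tnni1"] == 1.0
        assert out.loc["s2", "Myl2_Myl7"] == 1.0
        assert out.loc["s2", "log2_Myl2_Myl7"] == 0.0

    def test_zero_denominator_flagged(self):
        matrix = pd.DataFrame(
            {"s1": [2.0, 0.0, 4.0, 1.0]}, index=["Tnni3", "Tnni1", "Myl2", "Myl7"]
        )
        out = maturation_ratios(matrix)
        assert np.isnan(out.loc["s1", "Tnni3_Tnni1"])
        assert bool(out.loc["s1", "Tnni3_Tnni1_flagged"])

    def test_planted_isoform_switch_recovered(self):
        rng = np.random.default_rng(0)
        adult = {"Tnni3": 80.0, "Tnni1": 10.0, "Myl2": 160.0, "Myl7": 20.0}
        cols = {
            f"s{i}": [adult[g] * rng.uniform(0.95, 1.05) for g in
                      ("Tnni3", "Tnni1", "Myl2", "Myl7")]
            for i in range(4)
        }
        matrix = pd.DataFrame(cols, index=["Tnni3", "Tnni1", "Myl2", "Myl7"])
        out = maturation_ratios(matrix)
        assert out["log2_Tnni3_Tnni1"].mean() == pytest.approx(3.0, abs=0.2)
        assert out["log2_Myl2_Myl7"].mean() == pytest.approx(3.0, abs=0.2)
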
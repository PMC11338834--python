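import math

import numpy as np
import pandas as pd
import pytest

from scdemon import (
    ModuleSet,
    assign_degs_to_modules,
    enrich_covariate,
    module_module_network,
    score_modules,
    smooth_contour,
)
from scdemon.analysis import gaussian_kernel

from conftest import make_matrix


def module_set(mods):
    assignment = {g: m for m, gs in mods.items() for g in gs}
    return ModuleSet(modules=mods, resolution=1.0, powers_used=[0.0],
                     min_report_size=1, assignment=assignment)


def exact_hypergeom_sf(overlap, total, n_level, n_high):
    """Upper-tail P(K >= overlap) by direct summation of the pmf."""
    out = 0.0
    for k in range(overlap, min(n_level, n_high) + 1):
        out += (
            math.comb(n_level, k)
            * math.comb(total - n_level, n_high - k)
            / math.comb(total, n_high)
        )
    return out


class TestScoreModules:
    def test_single_gene_module_equals_gene_value(self):
        X = make_matrix([[1, 2, 3], [4, 5, 6], [0, 0, 0]])
        scores = score_modules(X, module_set({"M1": ["g1"]}))
        np.testing.assert_allclose(scores.scores["M1"], [2, 5, 0])

    def test_all_zero_cell_scores_zero(self):
        X = make_matrix([[1, 2], [0, 0], [3, 1]])
        scores = score_modules(X, module_set({"M1": ["g0", "g1"]}))
        assert scores.scores["M1"].iloc[1] == 0.0

    def test_matches_per_cell_loop(self, small_planted):
        X, truth = small_planted
        mods = module_set(truth.planted_modules())
        scores = score_modules(X, mods)
        dense = X.values.toarray()
        pos = {g: j for j, g in enumerate(X.gene_ids)}
        for mid, genes in mods.modules.items():
            idx = [pos[g] for g in genes]
            for c in [0, 7, 100]:
                assert scores.scores[mid].iloc[c] == pytest.approx(dense[c, idx].mean())

    def test_missing_genes_warn(self):
        X = make_matrix([[1, 2], [3, 4]])
        with pytest.warns(UserWarning, match="absent"):
            score_modules(X, module_set({"M1": ["g0", "nope"]}))


class TestEnrichCovariate:
    def test_exclusive_module_strongly_enriched(self):
        rng = np.random.default_rng(0)
        n = 400
        cov = pd.Series(["A"] * 100 + ["B"] * 300, name="subtype")
        vals = np.zeros((n, 2))
        vals[:100, 0] = 5.0  # gene g0 exclusive to A
        vals[:, 1] = rng.uniform(0.5, 1.5, n)
        X = make_matrix(vals, subtype=cov.tolist())
        scores = score_modules(X, module_set({"M1": ["g0"]}))
        cov.index = scores.scores.index
        table = enrich_covariate(scores, cov)
        row = table[(table.module == "M1") & (table.level == "A")].iloc[0]
        assert row.p < 1e-10 and row.direction == "high"

    def test_hypergeometric_matches_direct_summation(self):
        rng = np.random.default_rng(1)
        n = 50
        cov = pd.Series(rng.choice(["A", "B"], n), name="grp")
        vals = rng.uniform(0, 2, size=(n, 3))
        X = make_matrix(vals, grp=cov.tolist())
        scores = score_modules(X, module_set({"M1": ["g0", "g1"]}))
        cov.index = scores.scores.index
        table = enrich_covariate(scores, cov)
        s = scores.scores["M1"].to_numpy()
        high = s > s.mean() + s.std()
        for _, row in table.iterrows():
            n_level = (cov == row.level).sum()
            expected = exact_hypergeom_sf(int(row.overlap), n, int(n_level), int(high.sum()))
            assert row.p == pytest.approx(expected, rel=1e-10)

    def test_null_flag_rate_controlled(self):
        """Random scores with balanced levels: ~no enrichment at p < 0.001."""
        rng = np.random.default_rng(2)
        n, n_mods = 4000, 100
        scores_df = pd.DataFrame(
            rng.normal(size=(n, n_mods)),
            columns=[f"M{i}" for i in range(n_mods)],
            index=[f"c{i}" for i in range(n)],
        )
        from scdemon.analysis import ModuleScores

        cov = pd.Series(rng.permutation(["A", "B"] * (n // 2)), name="grp",
                        index=scores_df.index)
        table = enrich_covariate(ModuleScores(scores=scores_df), cov)
        assert table.enriched.mean() <= 0.01


class TestModuleModuleNetwork:
    @staticmethod
    def scores_with_meta(mat, groups):
        from scdemon.analysis import ModuleScores

        idx = [f"c{i}" for i in range(len(mat))]
        scores = ModuleScores(
            scores=pd.DataFrame(mat, columns=[f"M{j}" for j in range(mat.shape[1])], index=idx)
        )
        meta = pd.DataFrame({"sample": groups}, index=idx)
        return scores, meta

    def test_duplicated_module_gives_perfect_edge(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(0, 1, size=50)
        mat = np.column_stack([base, base, rng.uniform(0, 1, 50)])
        scores, meta = self.scores_with_meta(mat, [f"s{i}" for i in range(50)])
        table = module_module_network(scores, meta, ["sample"])
        edge = table[(table.module_i == "M0") & (table.module_j == "M1")]
        assert len(edge) == 1 and edge.iloc[0].r == pytest.approx(1.0)

    def test_independent_modules_rarely_connected(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            mat = rng.normal(size=(200, 2))
            scores, meta = self.scores_with_meta(mat, [f"s{i}" for i in range(200)])
            table = module_module_network(scores, meta, ["sample"], alpha=0.01)
            hits += len(table) > 0
        assert hits <= 1  # >= 95% of replicates edge-free

    def test_r_matches_textbook_pearson(self):
        mat = np.array([[1.0, 2.0], [2.0, 2.5], [3.0, 4.0], [4.0, 3.5], [5.0, 6.0]])
        scores, meta = self.scores_with_meta(mat, [f"s{i}" for i in range(5)])
        table = module_module_network(scores, meta, ["sample"], alpha=1.0)
        a = np.log(mat[:, 0] - mat.min() + 1)
        b = np.log(mat[:, 1] - mat.min() + 1)
        r_hand = ((a - a.mean()) * (b - b.mean())).sum() / np.sqrt(
            ((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum()
        )
        assert table.iloc[0].r == pytest.approx(r_hand)

    def test_too_few_groups_rejected(self):
        rng = np.random.default_rng(0)
        scores, meta = self.scores_with_meta(rng.normal(size=(10, 2)), ["s0", "s1"] * 5)
        with pytest.raises(ValueError, match="3 aggregation groups"):
            module_module_network(scores, meta, ["sample"])


class TestAssignDEGs:
    def test_member_gene_assigned_to_own_module(self, small_planted):
        X, truth = small_planted
        mods = module_set(truth.planted_modules())
        members = [gs[0] for gs in truth.planted_modules().values()]
        deg = pd.DataFrame({"gene_id": members, "category": ["up"] * len(members)})
        assignment, _ = assign_degs_to_modules(deg, X, mods)
        for gene in members:
            assert assignment[gene] == truth.module_assignments[gene]

    def test_assignment_matches_argmax_correlation(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(0, 3, size=(60, 20))
        X = make_matrix(vals)
        mods = module_set({"M1": [f"g{j}" for j in range(5)],
                           "M2": [f"g{j}" for j in range(5, 10)]})
        tested = [f"g{j}" for j in range(10, 20)]
        deg = pd.DataFrame({"gene_id": tested, "category": ["ns"] * 10})
        assignment, _ = assign_degs_to_modules(deg, X, mods)
        prof = {m: vals[:, [int(g[1:]) for g in gs]].mean(axis=1) for m, gs in mods.modules.items()}
        for gene in tested:
            cors = {m: np.corrcoef(vals[:, int(gene[1:])], p)[0, 1] for m, p in prof.items()}
            assert assignment[gene] == max(cors, key=cors.get)

    def test_shuffled_categories_control_error_rate(self, small_planted):
        X, truth = small_planted
        mods = module_set(truth.planted_modules())
        genes = list(X.gene_ids[:200])
        rng = np.random.default_rng(5)
        n_sig = 0
        n_tests = 0
        for rep in range(25):
            cats = rng.permutation(["up"] * 40 + ["down"] * 40 + ["ns"] * 120)
            deg = pd.DataFrame({"gene_id": genes, "category": cats})
            _, table = assign_degs_to_modules(deg, X, mods)
            n_sig += (table.p_adj < 0.05).sum()
            n_tests += len(table)
        assert n_sig / n_tests <= 0.05 + 0.02

    def test_bh_adjustment_monotone(self, small_planted):
        X, truth = small_planted
        mods = module_set(truth.planted_modules())
        deg = pd.DataFrame({"gene_id": list(X.gene_ids[:100]),
                            "category": ["up", "down"] * 50})
        _, table = assign_degs_to_modules(deg, X, mods)
        ordered = table.sort_values("p")
        assert (np.diff(ordered.p_adj) >= -1e-12).all()


class TestSmoothContour:
    def test_single_cell_gives_centered_gaussian_bump(self):
        coords = np.array([[0.0, 0.0], [10.0, 10.0]])
        values = np.array([0.0, 1.0])
        res = smooth_contour(coords, values, grid=50, kernel=9, sigma=1.0)
        peak = np.unravel_index(np.argmax(res["surface"]), res["surface"].shape)
        assert peak == (49, 49)  # the value-1 cell sits in the top corner bin

    def test_constant_values_flat_over_occupied_region(self):
        rng = np.random.default_rng(6)
        coords = rng.uniform(0, 1, size=(500, 2))
        res = smooth_contour(coords, np.ones(500), grid=20, kernel=5, sigma=1.0)
        occ = res["occupied"]
        interior = res["surface"][2:-2, 2:-2]
        if occ[2:-2, 2:-2].all():
            np.testing.assert_allclose(interior, interior.mean(), rtol=0.05)

    def test_convolution_matches_double_loop(self):
        rng = np.random.default_rng(7)
        coords = rng.uniform(0, 1, size=(100, 2))
        values = rng.uniform(0, 1, size=100)
        res = smooth_contour(coords, values, grid=20, kernel=7, sigma=1.0)
        # rebuild the binned grid then convolve by explicit loops
        binned = np.zeros((20, 20))
        counts = np.zeros((20, 20))
        xe, ye = res["x_edges"], res["y_edges"]
        xi = np.clip(np.digitize(coords[:, 0], xe) - 1, 0, 19)
        yi = np.clip(np.digitize(coords[:, 1], ye) - 1, 0, 19)
        for (i, j, v) in zip(xi, yi, values):
            binned[i, j] += v
            counts[i, j] += 1
        binned = np.divide(binned, counts, out=np.zeros_like(binned), where=counts > 0)
        k = gaussian_kernel(7, 1.0)
        manual = np.zeros((20, 20))
        for i in range(20):
            for j in range(20):
                for di in range(-3, 4):
                    for dj in range(-3, 4):
                        ii, jj = i + di, j + dj
                        if 0 <= ii < 20 and 0 <= jj < 20:
                            manual[i, j] += binned[ii, jj] * k[di + 3, dj + 3]
        np.testing.assert_allclose(res["surface"], manual, atol=1e-12)

    def test_non_finite_inputs_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            smooth_contour(np.array([[0, np.nan]]), np.array([1.0]))
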
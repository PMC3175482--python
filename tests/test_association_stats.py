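"""Enrichment, pleiotropy, rate comparison, paralogs, coordinate exports."""

import io
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from stpls import association_stats as ast
from stpls import stpls_core as core


def hypergeom_tail_bruteforce(x, N, K, n):
    """Independent log-gamma hypergeometric upper tail P(X >= x)."""

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    total = 0.0
    for i in range(max(x, 0, n - (N - K)), min(K, n) + 1):
        total += math.exp(
            log_comb(K, i) + log_comb(N - K, n - i) - log_comb(N, n)
        )
    return min(total, 1.0)


class TestEnrich:
    def test_fold_ratio_paper_scale_example(self):
        universe = {f"g{i}" for i in range(5791)}
        ordered = sorted(universe)
        selected = set(ordered[:47])
        category = set(ordered[40:140])  # overlap 7
        res = ast.enrich(selected, category, universe)
        assert res.x == 7
        assert res.fold == pytest.approx((7 / 47) / (100 / 5791))
        # and the quoted overlap-10 arithmetic
        assert (10 / 47) / (100 / 5791) == pytest.approx(12.3213, abs=1e-3)

    def test_zero_overlap(self):
        universe = {"a", "b", "c", "d", "e"}
        res = ast.enrich({"a"}, {"b", "c"}, universe)
        assert res.x == 0
        assert res.fold == 0.0
        assert res.p == 1.0  # P(X >= 0)

    def test_matches_bruteforce_hypergeometric_tail(self, rng):
        for _ in range(50):
            N = int(rng.integers(2, 200))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            x = int(rng.integers(0, min(K, n) + 1))
            p = float(ast.fisher_greater_sf(x, N, K, n))
            assert p == pytest.approx(
                hypergeom_tail_bruteforce(x, N, K, n), rel=1e-9, abs=1e-12
            )

    def test_fold_invariant_under_common_scaling(self):
        base = dict(N=200, n_sel=20, K=40, x=8)
        folds = []
        for f in (1, 3):
            genes = [f"g{i}" for i in range(base["N"] * f)]
            sel = set(genes[: base["n_sel"] * f])
            cat = set(genes[: base["x"] * f]) | set(
                genes[base["n_sel"] * f : base["n_sel"] * f + (base["K"] - base["x"]) * f]
            )
            folds.append(ast.enrich(sel, cat, set(genes)).fold)
        assert folds[0] == pytest.approx(folds[1])

    def test_subset_and_universe_validation(self):
        with pytest.raises(ValueError, match="empty"):
            ast.enrich(set(), set(), set())
        with pytest.raises(ValueError, match="subset"):
            ast.enrich({"z"}, set(), {"a"})


class TestAdjustFdr:
    def test_hand_bh_computation(self):
        out = ast.adjust_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged_and_empty(self):
        assert ast.adjust_fdr([0.3])[0] == pytest.approx(0.3)
        assert len(ast.adjust_fdr([])) == 0

    def test_adjusted_ge_raw_and_order_preserving(self, rng):
        p = rng.uniform(1e-6, 1, size=40)
        adj = ast.adjust_fdr(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_fdr_control_under_null(self):
        # uniform p-values: BH discovery fraction at level 0.05 stays near
        # or below 0.05 on average over many replicates
        fractions = []
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            p = rng.uniform(size=50)
            fractions.append((ast.adjust_fdr(p) < 0.05).mean())
        mean = float(np.mean(fractions))
        se = float(np.std(fractions, ddof=1) / np.sqrt(len(fractions)))
        assert mean <= 0.05 + 3 * se

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            ast.adjust_fdr([0.0, 0.5])


class TestEnrichmentTable:
    def test_marks_and_adjustment_columns(self):
        universe = {f"g{i}" for i in range(300)}
        ordered = sorted(universe)
        selected = set(ordered[:30])
        categories = {
            "strong": set(ordered[:25]),  # almost all selected
            "null": set(ordered[150:180]),
        }
        table = ast.enrichment_table(selected, categories, universe)
        strong = table.set_index("category").loc["strong"]
        assert strong["marks"] == "***"
        assert strong["p_adj"] >= strong["p"]
        assert set(table.columns) >= {"fold", "p", "p_adj", "marks", "adj_marks"}


class TestPleiotropy:
    def test_quarter_threshold_of_twenty(self):
        selections = {f"ph{i}": set() for i in range(20)}
        for i in range(5):
            selections[f"ph{i}"].add("geneA")
        for i in range(4):
            selections[f"ph{i}"].add("geneB")
        ps = ast.pleiotropy_set(selections, fraction=0.25)
        assert ps.min_count == 5
        assert "geneA" in ps.genes and "geneB" not in ps.genes

    def test_fraction_extremes_union_and_intersection(self):
        selections = {"a": {"x", "y"}, "b": {"y", "z"}, "c": {"y"}}
        assert set(ast.pleiotropy_set(selections, 0.0).genes) == {"x", "y", "z"}
        assert set(ast.pleiotropy_set(selections, 1.0).genes) == {"y"}

    def test_all_empty_selections(self):
        ps = ast.pleiotropy_set({"a": set(), "b": set()}, 0.25)
        assert ps.genes == []


class TestCompareRates:
    def test_identical_groups(self):
        rates = pd.Series(
            [0.1, 0.2, 0.3, 0.1, 0.2, 0.3],
            index=[f"g{i}" for i in range(6)],
        )
        res = ast.compare_rates(rates, {"g0", "g1", "g2"})
        assert res.ratio == pytest.approx(1.0)
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(0.5, abs=1e-9)

    def test_welch_formula_on_toy(self):
        sel = np.array([1.0, 2.0, 3.0])
        oth = np.array([0.5, 1.0, 1.5])
        rates = pd.Series(
            np.concatenate([sel, oth]), index=[f"g{i}" for i in range(6)]
        )
        res = ast.compare_rates(rates, {"g0", "g1", "g2"})
        num = sel.mean() - oth.mean()
        den = math.sqrt(sel.var(ddof=1) / 3 + oth.var(ddof=1) / 3)
        assert res.t == pytest.approx(num / den)

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(99)
        base = rng.normal(1.0, 1.0, size=200)
        shifted = rng.normal(1.5, 1.0, size=200)  # 0.5 sd shift
        rates = pd.Series(
            np.concatenate([shifted, base]),
            index=[f"g{i}" for i in range(400)],
        )
        res = ast.compare_rates(rates, {f"g{i}" for i in range(200)})
        assert res.p < 0.05

    def test_small_group_rejected(self):
        rates = pd.Series([0.1, 0.2, 0.3], index=["a", "b", "c"])
        with pytest.raises(ValueError, match="2 genes"):
            ast.compare_rates(rates, {"a"})


class TestClassifyParalogs:
    def blast_rows(self, rows):
        text = "".join(
            f"{q}\t{s}\t90.0\t{ln}\t1\t0\t1\t{ln}\t1\t{ln}\t{ev}\t55.0\n"
            for q, s, ln, ev in rows
        )
        return io.StringIO(text)

    def test_both_thresholds_required(self):
        lengths = pd.Series({"A": 300, "B": 200, "C": 150})
        rows = [
            ("A", "B", 160, 1e-12),   # flagged: E and coverage pass
            ("B", "B", 200, 0.0),     # self-hit only: not flagged
            ("C", "A", 100, 1e-12),   # coverage 100/150 passes -> flagged
        ]
        flags = ast.classify_paralogs(self.blast_rows(rows), lengths)
        assert flags["A"] and flags["C"] and not flags["B"]

    def test_coverage_below_half_not_flagged(self):
        lengths = pd.Series({"A": 300, "B": 200})
        rows = [("A", "B", 100, 1e-12)]  # 100/300 = 0.33 < 0.5
        flags = ast.classify_paralogs(self.blast_rows(rows), lengths)
        assert not flags.any()

    def test_weak_evalue_not_flagged(self):
        lengths = pd.Series({"A": 300, "B": 200})
        rows = [("A", "B", 200, 1e-8)]  # E above 1e-10
        flags = ast.classify_paralogs(self.blast_rows(rows), lengths)
        assert not flags.any()


class TestBiplotCoords:
    def _model(self, rng, n=20, p=15):
        X = pd.DataFrame(
            rng.standard_normal((n, p)), columns=[f"g{j}" for j in range(p)]
        )
        y = pd.Series(rng.standard_normal(n), index=X.index)
        return core.fit(X, y, k=3, delta=0.2), X

    def test_shapes_and_bounds(self, rng):
        model, X = self._model(rng)
        scores, loadings = ast.biplot_coords(model, X)
        assert scores.shape == (20, 2)
        assert loadings.shape == (15, 2)
        assert (loadings.abs() <= 1.0).all().all()

    def test_gene_equal_to_first_score_loads_fully(self, rng):
        model, X = self._model(rng)
        X2 = X.copy()
        # overwrite one gene with t1 (destandardized so the model's params
        # map it back onto the score exactly)
        mean = model.x_params.mean["g0"]
        sd = model.x_params.sd["g0"]
        X2["g0"] = model.T[:, 0] * sd + mean
        model2 = core.STPLSModel(
            delta=model.delta, k=model.k, k_requested=model.k_requested,
            W=model.W, P=model.P, q=model.q, T=model.T, beta=model.beta,
            columns=model.columns, x_params=model.x_params,
            y_params=model.y_params,
        )
        _, loadings = ast.biplot_coords(model2, X2)
        assert loadings.loc["g0", "comp1"] == pytest.approx(1.0, abs=1e-6)
        assert abs(loadings.loc["g0", "comp2"]) < 1e-6

    def test_constant_column_warns_and_zeroes(self, rng):
        model, X = self._model(rng)
        X2 = X.copy()
        X2["g5"] = 3.14
        with pytest.warns(UserWarning, match="constant"):
            _, loadings = ast.biplot_coords(model, X2)
        assert (loadings.loc["g5"] == 0.0).all()

    def test_requires_two_components(self, rng):
        X = pd.DataFrame(rng.standard_normal((10, 5)))
        y = pd.Series(rng.standard_normal(10))
        model = core.fit(X, y, k=1, delta=0.1)
        with pytest.raises(ValueError, match="components"):
            ast.biplot_coords(model, X)


class TestChromosomePositions:
    def test_sorted_by_chromosome_then_start(self):
        ann = pd.DataFrame(
            {
                "chromosome": ["chrI", "chrI", "chrII"],
                "strand": ["+", "-", "+"],
                "start": [1000, 500, 10],
                "end": [1500, 900, 400],
            },
            index=["gA", "gB", "gC"],
        )
        out = ast.chromosome_positions({"gA", "gB", "gC"}, ann)
        assert list(out["gene"]) == ["gB", "gA", "gC"]

    def test_missing_coordinates_flagged_not_dropped(self):
        ann = pd.DataFrame(
            {
                "chromosome": ["chrI"],
                "strand": ["+"],
                "start": [100],
                "end": [300],
            },
            index=["gA"],
        )
        out = ast.chromosome_positions({"gA", "unknown"}, ann)
        assert len(out) == 2
        row = out.set_index("gene").loc["unknown"]
        assert not row["has_coords"]

    def test_tsv_round_trip(self, tmp_path):
        ann = pd.DataFrame(
            {
                "chromosome": ["chrIV", "chrII"],
                "strand": ["-", "+"],
                "start": [5, 9],
                "end": [50, 90],
            },
            index=["gX", "gY"],
        )
        out = ast.chromosome_positions({"gX", "gY"}, ann)
        path = tmp_path / "pos.tsv"
        out.to_csv(path, sep="\t", index=False)
        back = pd.read_csv(path, sep="\t")
        pd.testing.assert_frame_equal(back, out)
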
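"""Unit tests for phenotype algebra: balancing, pseudo-bulk, RSF protocol."""

import itertools

import numpy as np
import pandas as pd
import pytest

import cellvec as cv

from conftest import toy_matrix


def labeled_matrix(sizes, n_genes=12, seed=0, layer="normalized"):
    rng = np.random.default_rng(seed)
    cols, labels = [], []
    for g, n in sizes.items():
        cols.append(rng.random((n_genes, n)) + ord(g[-1]) % 5)
        labels += [g] * n
    E = toy_matrix(np.hstack(cols), layer=layer)
    return E, pd.Series(labels, index=E.cell_ids)


class TestBalance:
    def test_already_balanced_is_unchanged(self):
        E, lab = labeled_matrix({"A": 10, "B": 10})
        out, out_lab = cv.balance_classes(E, lab, seed=0)
        np.testing.assert_array_equal(out.values, E.values)
        assert list(out_lab) == list(lab)

    def test_synthetic_cells_lie_between_real_minority_cells(self):
        E, lab = labeled_matrix({"A": 10, "B": 4})
        out, out_lab = cv.balance_classes(E, lab, seed=1, k_neighbors=3)
        assert out_lab.value_counts().to_dict() == {"A": 10, "B": 10}
        # real cells preserved verbatim, synthetics appended
        np.testing.assert_array_equal(out.values[:, :14], E.values)
        reals = E.values[:, [i for i, g in enumerate(lab) if g == "B"]].T
        for col in out.values[:, 14:].T:
            on_segment = False
            for x, y in itertools.permutations(reals, 2):
                d = y - x
                denom = float(d @ d)
                if denom == 0:
                    on_segment = on_segment or np.allclose(col, x)
                    continue
                u = float((col - x) @ d) / denom
                if 0 <= u <= 1 and np.allclose(col, x + u * d, atol=1e-9):
                    on_segment = True
                    break
            assert on_segment

    def test_identical_minority_cells_interpolate_to_themselves(self):
        E, lab = labeled_matrix({"A": 8, "B": 3})
        b_idx = [i for i, g in enumerate(lab) if g == "B"]
        E.values[:, b_idx] = E.values[:, [b_idx[0]]]
        out, _ = cv.balance_classes(E, lab, seed=2)
        for col in out.values[:, len(lab):].T:
            np.testing.assert_allclose(col, E.values[:, b_idx[0]])

    def test_singleton_group_error_suggests_merging(self):
        E, lab = labeled_matrix({"A": 5, "B": 1})
        with pytest.raises(ValueError, match="merge"):
            cv.balance_classes(E, lab, seed=0)


class TestPseudoBulk:
    def test_whole_tumor_group_equals_reference(self):
        E, lab = labeled_matrix({"A": 6})
        lab[:] = "A"
        pbs = cv.make_pseudobulk(E, lab, ["T - A"])
        ref = next(p for p in pbs if p.role == "reference")
        pa = next(p for p in pbs if p.name == "T-A")
        np.testing.assert_allclose(ref.gene_profile, pa.gene_profile)

    def test_mean_decomposition_for_equal_groups(self):
        E, lab = labeled_matrix({"A": 5, "B": 5})
        pbs = {p.name: p for p in cv.make_pseudobulk(E, lab, ["T - A", "T - B"])}
        np.testing.assert_allclose(
            pbs["T"].gene_profile,
            (pbs["T-A"].gene_profile + pbs["T-B"].gene_profile) / 2)

    def test_three_cell_toy_hand_means(self):
        E = toy_matrix(np.array([[1.0, 3.0, 8.0], [2.0, 4.0, 0.0]]), layer="normalized")
        lab = pd.Series(["x", "x", "y"], index=E.cell_ids)
        pbs = {p.name: p for p in cv.make_pseudobulk(E, lab, ["T - x", "T - y"])}
        np.testing.assert_allclose(pbs["T"].gene_profile, [4.0, 2.0])
        np.testing.assert_allclose(pbs["T-x"].gene_profile, [2.0, 3.0])
        np.testing.assert_allclose(pbs["T-y"].gene_profile, [8.0, 0.0])

    def test_union_mean_is_commutative(self):
        E, lab = labeled_matrix({"A": 4, "B": 7})
        p1 = cv.make_pseudobulk(E, lab, ["T - (A + B)"])[1]
        p2 = cv.make_pseudobulk(E, lab, ["T - (B + A)"])[1]
        np.testing.assert_allclose(p1.gene_profile, p2.gene_profile)

    def test_unknown_group_error_lists_available(self):
        E, lab = labeled_matrix({"A": 3, "B": 3})
        with pytest.raises(ValueError, match="available groups"):
            cv.make_pseudobulk(E, lab, ["T - NOPE"])


class TestQueryGrammar:
    @pytest.mark.parametrize("query,groups", [
        ("T", []),
        ("T - NE", ["NE"]),
        ("T-NE", ["NE"]),
        ("T - (MES + CLA)", ["MES", "CLA"]),
        ("T - (A + B + C)", ["A", "B", "C"]),
    ])
    def test_valid_expressions(self, query, groups):
        assert cv.parse_query(query) == groups

    @pytest.mark.parametrize("query", ["NE - T", "T + NE", "T - MES + CLA", "T - ()", "T - (A"])
    def test_invalid_expressions(self, query):
        with pytest.raises(ValueError):
            cv.parse_query(query)

    def test_canonical_names(self):
        from cellvec.algebra import canonical_name
        assert canonical_name([]) == "T"
        assert canonical_name(["NE"]) == "T-NE"
        assert canonical_name(["MES", "CLA"]) == "T-(MES+CLA)"


class TestDelta:
    def test_self_subtraction_is_zero(self):
        v = np.array([1.0, 2.0])
        np.testing.assert_array_equal(cv.delta_embedding(v, v), [0.0, 0.0])

    def test_zero_query_is_identity(self):
        v = np.array([1.0, -2.0, 3.0])
        np.testing.assert_array_equal(cv.delta_embedding(v, np.zeros(3)), v)

    def test_componentwise_arithmetic(self):
        np.testing.assert_array_equal(
            cv.delta_embedding([1, 2, 3], [0, 2, 1]), [1.0, 0.0, 2.0])

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            cv.delta_embedding([1, 2], [1, 2, 3])


def hazard_cohort(n=150, d=8, seed=0, coef=2.0, censor_scale=None):
    """Synthetic cohort whose hazard is driven by embedding coordinate 0."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    hazards = 0.002 * np.exp(coef * X[:, 0])
    times = rng.exponential(1.0 / hazards)
    if censor_scale:
        cens = rng.exponential(censor_scale, n)
        event = times <= cens
        times = np.minimum(times, cens)
    else:
        event = np.ones(n, dtype=bool)
    ids = [f"s{i}" for i in range(n)]
    expr = toy_matrix(rng.poisson(5.0, (10, n)).astype(float), cells=ids, unit="bulk_counts")
    cohort = cv.SurvivalCohort(expr, times, event)
    emb = cv.EmbeddingMatrix(ids=ids, vectors=X)
    return emb, cohort, hazards


class TestRSF:
    def test_survival_functions_are_valid(self):
        emb, cohort, _ = hazard_cohort()
        rsf = cv.train_rsf(emb, cohort, n_estimators=100, seed=0)
        from cellvec.algebra import eval_survival
        grid = np.r_[0.0, np.sort(cohort.time)[::10]]
        for fn in rsf.predict_survival_function(emb.vectors[:5]):
            s = eval_survival(fn, grid)
            assert s[0] == pytest.approx(1.0)  # S(0) = 1: no events before t=0
            assert np.all(np.diff(s) <= 1e-12)
            assert s.min() >= 0.0 and s.max() <= 1.0

    def test_zero_events_rejected(self):
        emb, cohort, _ = hazard_cohort(n=40)
        cohort.event[:] = False
        with pytest.raises(ValueError, match="zero events"):
            cv.train_rsf(emb, cohort, n_estimators=10, seed=0)

    def test_risk_scores_concordant_with_true_hazard(self):
        emb, cohort, hazards = hazard_cohort(censor_scale=None)
        rsf = cv.train_rsf(emb, cohort, n_estimators=300, seed=1)
        risk = rsf.predict(emb.vectors)
        pairs = conc = 0
        for i in range(len(risk)):
            for j in range(i + 1, len(risk)):
                if hazards[i] == hazards[j]:
                    continue
                pairs += 1
                conc += (hazards[i] > hazards[j]) == (risk[i] > risk[j])
        assert conc / pairs > 0.7


class TestBootstrap:
    def _setup(self):
        emb, cohort, _ = hazard_cohort(n=80, seed=3, censor_scale=2000)
        queries = cv.EmbeddingMatrix(
            ids=["q_low", "q_high"],
            vectors=np.vstack([np.r_[-2.0, np.zeros(7)], np.r_[2.0, np.zeros(7)]]))
        return emb, cohort, queries

    def test_single_bootstrap_median_is_the_single_score(self):
        emb, cohort, queries = self._setup()
        rep = cv.bootstrap_risk(queries, emb, cohort, n_boot=1, seed=0, n_estimators=50)
        for qi, name in enumerate(rep.queries):
            assert rep.median_risk[name] == pytest.approx(rep.boot_scores[qi, 0])

    def test_duplicate_queries_tie_broken_by_name(self):
        emb, cohort, _ = hazard_cohort(n=80, seed=4, censor_scale=2000)
        v = np.r_[1.0, np.zeros(7)]
        queries = cv.EmbeddingMatrix(ids=["zz", "aa"], vectors=np.vstack([v, v]))
        rep = cv.bootstrap_risk(queries, emb, cohort, n_boot=3, seed=0, n_estimators=50)
        np.testing.assert_array_equal(rep.boot_scores[0], rep.boot_scores[1])
        assert rep.ranking == ["aa", "zz"]

    def test_low_risk_query_ranks_most_aggressive(self):
        emb, cohort, queries = self._setup()
        rep = cv.bootstrap_risk(queries, emb, cohort, n_boot=5, seed=1, n_estimators=100)
        assert rep.most_aggressive == "q_low"
        for _, s in rep.survival_curves.values():
            assert np.all(np.diff(s) <= 1e-12) and s.min() >= 0 and s.max() <= 1

    def test_invalid_n_boot(self):
        emb, cohort, queries = self._setup()
        with pytest.raises(ValueError, match="n_boot"):
            cv.bootstrap_risk(queries, emb, cohort, n_boot=0, seed=0)

    def test_report_is_deterministic(self):
        emb, cohort, queries = self._setup()
        r1 = cv.bootstrap_risk(queries, emb, cohort, n_boot=3, seed=5, n_estimators=50)
        r2 = cv.bootstrap_risk(queries, emb, cohort, n_boot=3, seed=5, n_estimators=50)
        assert r1.boot_scores.tobytes() == r2.boot_scores.tobytes()
        assert r1.ranking == r2.ranking


class TestJointEmbed:
    def test_shape_roles_and_duplicate_determinism(self, small_sim, small_model):
        design, E, labels = small_sim
        cohort, _ = cv.simulate_survival_cohort(design)
        norm = cv.normalize_cpm_log(cv.filter_cells_genes(E, 10, 3))
        hvg = cv.select_hvg(norm, 80)
        sub = norm.subset_genes(hvg)
        pbs = cv.make_pseudobulk(sub, labels.loc[sub.cell_ids], ["T - C1", "T - C2"])
        pbs.append(pbs[1].__class__(  # duplicated profile under another name
            name="T-C1copy", gene_profile=pbs[1].gene_profile.copy(),
            gene_ids=list(pbs[1].gene_ids), role="phenotype", groups=["C1"]))
        emb, roles = cv.joint_embed(cohort, pbs, small_model, seed=9, infer_epochs=4)
        assert len(emb.ids) == cohort.expression.n_cells + len(pbs)
        assert sum(r == "bulk" for r in roles.values()) == cohort.expression.n_cells
        np.testing.assert_array_equal(emb.row("T-C1"), emb.row("T-C1copy"))

    def test_insufficient_shared_genes(self, small_sim, small_model):
        design, E, labels = small_sim
        cohort, _ = cv.simulate_survival_cohort(design)
        norm = cv.normalize_cpm_log(cv.filter_cells_genes(E, 10, 3))
        sub = norm.subset_genes(cv.select_hvg(norm, 60))
        pbs = cv.make_pseudobulk(sub, labels.loc[sub.cell_ids], ["T - C1"])
        with pytest.raises(ValueError, match="insufficient shared features"):
            cv.joint_embed(cohort, pbs, small_model, seed=0, min_common_genes=1000)

    def test_aggressive_pseudobulk_tracks_aggressive_enriched_samples(
            self, small_sim, small_model):
        design, E, labels = small_sim
        cohort, truth = cv.simulate_survival_cohort(design)
        norm = cv.normalize_cpm_log(cv.filter_cells_genes(E, 10, 3))
        sub = norm.subset_genes(cv.select_hvg(norm, 80))
        pbs = cv.make_pseudobulk(sub, labels.loc[sub.cell_ids], ["T - C1"])
        emb, roles = cv.joint_embed(cohort, pbs, small_model, seed=1, infer_epochs=6)
        p = emb.row("T-C1")  # profile of the aggressive phenotype C1
        prop = truth["C1"]
        hi = prop.nlargest(25).index
        lo = prop.nsmallest(25).index
        sim_hi = np.mean([cv.cosine_similarity(p, emb.row(s)) for s in hi])
        sim_lo = np.mean([cv.cosine_similarity(p, emb.row(s)) for s in lo])
        assert sim_hi > sim_lo


class TestRankReport:
    def _report(self, medians):
        names = list(medians)
        scores = np.array([[medians[n]] * 3 for n in names], dtype=float)
        grid = np.array([0.0, 1.0])
        return cv.RiskReport(
            queries=names, boot_scores=scores,
            median_risk={n: float(m) for n, m in medians.items()},
            survival_curves={n: (grid, np.array([1.0, 0.5])) for n in names},
            ranking=sorted(names, key=lambda n: (medians[n], n)), n_boot=3, seed=0)

    def test_ordering_and_interpretation(self, tmp_path):
        table = cv.rank_report(self._report({"q1": 0.2, "q2": 0.9}), outdir=tmp_path)
        assert list(table["query"]) == ["q1", "q2"]
        assert table.loc[0, "interpretation"] == "subtracted phenotype most aggressive"
        assert (tmp_path / "ranking.tsv").exists()
        assert (tmp_path / "survival_curves.tsv").exists()

    def test_equal_medians_flagged_tied_lexicographic(self):
        table = cv.rank_report(self._report({"zz": 0.5, "aa": 0.5}))
        assert list(table["query"]) == ["aa", "zz"]
        assert table["tied"].all()

    def test_invalid_survival_curve_rejected(self):
        with pytest.raises(ValueError, match="non-increasing"):
            cv.RiskReport(
                queries=["q"], boot_scores=np.ones((1, 1)),
                median_risk={"q": 1.0},
                survival_curves={"q": (np.array([0.0, 1.0]), np.array([0.5, 0.9]))},
                ranking=["q"], n_boot=1, seed=0)


class TestSurvivalCohort:
    def test_samples_without_outcome_are_excluded(self):
        expr = toy_matrix(np.ones((4, 3)), cells=["s1", "s2", "s3"], unit="bulk_counts")
        table = pd.DataFrame({
            "sample_id": ["s1", "s2", "s3", "s4"],
            "time": [100.0, np.nan, 50.0, 10.0],
            "event": [1, 1, np.nan, 0],
        })
        cohort = cv.SurvivalCohort.from_table(expr, table)
        assert cohort.sample_ids == ["s1"]

    def test_negative_time_rejected(self):
        expr = toy_matrix(np.ones((2, 2)), unit="bulk_counts")
        with pytest.raises(ValueError, match="finite and >= 0"):
            cv.SurvivalCohort(expr, np.array([-1.0, 5.0]), np.array([1, 0]))
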
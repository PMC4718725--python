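"""Model selection: stability selection, equation enumeration with the
collinearity ban, cross-validated MSE, BIC, composite pooling and the
piecewise composition machinery."""

import math

import numpy as np
import pandas as pd
import pytest

from climexp.selection import (PiecewiseEDRegressor, SelectionConfig,
                               StabilitySelector, _lasso_entry_set_fast,
                               _lasso_entry_set_sklearn, bic, composite_mse,
                               cv_mse, enumerate_equations, make_folds,
                               one_factor_compositions,
                               prune_correlated_candidates, select_equation,
                               select_piecewise, stability_q,
                               stability_select, two_factor_compositions)


def _random_design(rng, n=60, p=12):
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=[f"p{i:02d}" for i in range(p)])
    return (X - X.mean()) / X.std(ddof=0)


class TestBICAndPooling:
    def test_bic_hand_computed(self):
        assert bic(1.0, 10, 0) == pytest.approx(0.0)
        expected = 60 * math.log(0.25) + 3 * math.log(60)
        assert bic(0.25, 60, 3) == pytest.approx(expected, rel=1e-12)

    def test_bic_penalty_monotone_in_p(self):
        assert bic(0.5, 60, 2) < bic(0.5, 60, 3)

    def test_composite_pooling_identities(self):
        rng = np.random.default_rng(0)
        a, b = np.full(50, 0.1), np.full(50, 0.3)
        assert composite_mse([a, b]) == pytest.approx(0.2)
        one = rng.uniform(size=40)
        assert composite_mse([one]) == pytest.approx(one.mean())
        c, d = np.full(15, 0.4), np.full(45, 0.0)
        assert composite_mse([c, d]) == pytest.approx(0.1)

    def test_pooling_matches_weighted_mean_for_arbitrary_partition(self):
        rng = np.random.default_rng(1)
        segs = [rng.uniform(size=n) for n in (7, 13, 25, 15)]
        pooled = composite_mse(segs)
        weighted = sum(s.sum() for s in segs) / sum(len(s) for s in segs)
        assert pooled == pytest.approx(weighted, abs=1e-12)


class TestCVMSE:
    def test_exact_linear_fit_zero_error(self):
        rng = np.random.default_rng(2)
        X = _random_design(rng, 40, 3).to_numpy()
        y = X @ np.array([1.0, -2.0, 0.5])
        folds = make_folds(40, 5, 5, np.random.default_rng(0))
        mse, sq = cv_mse(X, y, folds)
        assert mse < 1e-20
        assert len(sq) == 5 * 40

    def test_null_model_mse_near_variance(self):
        rng = np.random.default_rng(3)
        y = rng.normal(0, 1, 200)
        y = y - y.mean()
        folds = make_folds(200, 5, 5, np.random.default_rng(1))
        mse, _ = cv_mse(np.empty((200, 0)), y, folds)
        assert mse == pytest.approx(y.var(), rel=0.1)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        X = _random_design(rng, 30, 4).to_numpy()
        y = rng.normal(size=30)
        f1 = make_folds(30, 5, 5, np.random.default_rng(9))
        f2 = make_folds(30, 5, 5, np.random.default_rng(9))
        assert cv_mse(X, y, f1)[0] == cv_mse(X, y, f2)[0]

    def test_stratified_folds_span_strata(self):
        strata = np.repeat(np.arange(4), 15)
        folds = make_folds(60, 5, 3, np.random.default_rng(5), strata)
        for r in range(3):
            for f in range(5):
                cells = strata[folds[r] == f]
                assert set(cells) == {0, 1, 2, 3}


class TestEnumeration:
    def test_subset_counts(self):
        corr = pd.DataFrame(np.eye(4), index=list("abcd"),
                            columns=list("abcd"))
        subs = enumerate_equations(list("abcd"), corr)
        assert len(subs) == 4 + 6 + 4

    def test_banned_pair_removes_supersets(self):
        corr = pd.DataFrame(np.eye(4), index=list("abcd"),
                            columns=list("abcd"))
        corr.loc["a", "b"] = corr.loc["b", "a"] = 0.9
        subs = enumerate_equations(list("abcd"), corr, corr_cap=0.85)
        assert len(subs) == 14 - 3
        assert all(not {"a", "b"} <= set(s) for s in subs)

    def test_single_candidate(self):
        corr = pd.DataFrame([[1.0]], index=["a"], columns=["a"])
        assert enumerate_equations(["a"], corr) == [("a",)]


class TestPruning:
    def test_cleaner_duplicate_kept(self):
        rng = np.random.default_rng(6)
        n = 60
        base = rng.normal(size=n)
        X = pd.DataFrame({
            "clean": base,
            "noisy": base + rng.normal(0, 0.2, n),
            "other": rng.normal(size=n)})
        X = (X - X.mean()) / X.std(ddof=0)
        y = base + rng.normal(0, 0.1, n)
        folds = make_folds(n, 5, 5, np.random.default_rng(0))
        kept = prune_correlated_candidates(list(X.columns), X, y, folds,
                                           corr_cap=0.85)
        assert "clean" in kept and "noisy" not in kept and "other" in kept

    def test_uncorrelated_unchanged(self):
        rng = np.random.default_rng(7)
        X = _random_design(rng, 50, 5)
        y = rng.normal(size=50)
        folds = make_folds(50, 5, 5, np.random.default_rng(0))
        assert prune_correlated_candidates(list(X.columns), X, y, folds) \
            == list(X.columns)

    def test_chain_resolved_deterministically(self):
        rng = np.random.default_rng(8)
        n = 60
        base = rng.normal(size=n)
        X = pd.DataFrame({
            "a": base,
            "b": base + rng.normal(0, 0.15, n),
            "c": base + rng.normal(0, 0.3, n)})
        X = (X - X.mean()) / X.std(ddof=0)
        y = base
        folds = make_folds(n, 5, 5, np.random.default_rng(0))
        k1 = prune_correlated_candidates(["a", "b", "c"], X, y, folds)
        k2 = prune_correlated_candidates(["a", "b", "c"], X, y, folds)
        assert k1 == k2
        assert "a" in k1


class TestLassoEntryOrder:
    def test_fast_path_matches_sklearn_reference(self):
        """The in-house LARS-lasso entry order equals sklearn's lasso path
        on random (including collinear) designs."""
        rng = np.random.default_rng(9)
        for _ in range(60):
            n, p = int(rng.integers(20, 50)), int(rng.integers(8, 40))
            q = int(rng.integers(2, 7))
            X = rng.normal(size=(n, p))
            X[:, :3] += 0.8 * X[:, 3:6]
            X = (X - X.mean(0)) / X.std(0)
            beta = np.zeros(p)
            beta[rng.choice(p, 2, replace=False)] = rng.normal(0, 2, 2)
            y = X @ beta + rng.normal(0, 1, n)
            y -= y.mean()
            assert _lasso_entry_set_fast(X.T @ X, X.T @ y, q) \
                == _lasso_entry_set_sklearn(X, y, q)


class TestStabilitySelection:
    def test_q_bound_formula(self):
        assert stability_q(2.0, 0.65, 67) == 6
        assert stability_q(2.0, 0.7, 67) == 7
        assert stability_q(2.0, 0.65, 1) == 1

    def test_strong_single_signal_always_selected(self):
        rng = np.random.default_rng(10)
        X = _random_design(rng, 60, 21)
        hits = 0
        for seed in range(20):
            noise = np.random.default_rng(seed).normal(0, 0.1, 60)
            y = 3.0 * X["p00"].to_numpy() + noise
            sel, freq = stability_select(X, y, SelectionConfig(seed=seed))
            hits += "p00" in sel
        assert hits >= 19

    def test_config_invariants_enforced(self):
        with pytest.raises(ValueError):
            SelectionConfig(threshold=0.4).validate()
        with pytest.raises(ValueError):
            SelectionConfig(fraction=0.0).validate()
        with pytest.raises(ValueError):
            SelectionConfig(B=0).validate()

    def test_subsample_too_small_rejected(self):
        rng = np.random.default_rng(11)
        X = _random_design(rng, 5, 3)
        with pytest.raises(ValueError, match="too small"):
            stability_select(X, rng.normal(size=5),
                             SelectionConfig(fraction=0.5))

    def test_estimator_support_mask(self):
        rng = np.random.default_rng(12)
        X = _random_design(rng, 60, 10)
        y = 2.5 * X["p01"].to_numpy() + rng.normal(0, 0.2, 60)
        est = StabilitySelector(random_state=0).fit(X, y)
        assert est.support_[1]
        assert est.transform(X).shape[1] == est.support_.sum()


class TestSelectEquation:
    def test_two_term_truth_recovered_majority(self):
        rng = np.random.default_rng(13)
        X = _random_design(rng, 60, 10)
        ok = 0
        for seed in range(25):
            r = np.random.default_rng(100 + seed)
            y = 0.8 * X["p00"].to_numpy() - 0.6 * X["p01"].to_numpy()
            y = y / y.std() + r.normal(0, 0.25, 60)
            folds = make_folds(60, 5, 5, np.random.default_rng(seed))
            eq = select_equation(X, y, list(X.columns),
                                 SelectionConfig(seed=seed), folds)
            ok += sorted(eq.parameter_ids) == ["p00", "p01"]
        assert ok >= 18

    def test_zero_noise_exact_with_coefficients(self):
        rng = np.random.default_rng(14)
        X = _random_design(rng, 60, 8)
        y = 1.5 * X["p02"].to_numpy() - 0.7 * X["p05"].to_numpy()
        folds = make_folds(60, 5, 5, np.random.default_rng(0))
        eq = select_equation(X, y, list(X.columns),
                             SelectionConfig(seed=0), folds)
        terms = dict(eq.terms)
        assert set(terms) == {"p02", "p05"}
        assert terms["p02"] == pytest.approx(1.5, abs=1e-9)
        assert terms["p05"] == pytest.approx(-0.7, abs=1e-9)

    def test_oracle_equivalence_with_brute_force(self):
        """select_equation equals an independently coded exhaustive search
        over all admissible subsets sharing the same CV folds."""
        import itertools
        rng = np.random.default_rng(15)
        for trial in range(12):
            n, p = 40, int(rng.integers(4, 9))
            X = _random_design(rng, n, p)
            beta = np.zeros(p)
            beta[:2] = [1.0, -0.8]
            y = X.to_numpy() @ beta + rng.normal(0, 0.3, n)
            cfg = SelectionConfig(seed=trial)
            folds = make_folds(n, 5, 5, np.random.default_rng(trial))
            eq = select_equation(X, y, list(X.columns), cfg, folds)
            # brute-force oracle: plain loops, same folds, same ban
            corr = X.corr().abs()
            cands = prune_correlated_candidates(list(X.columns), X, y,
                                                folds, cfg.corr_cap)
            best = (bic(cv_mse(np.empty((n, 0)), y, folds)[0], n, 0), 0, ())
            for size in (1, 2, 3):
                for sub in itertools.combinations(cands, size):
                    if any(corr.loc[a, b] > cfg.corr_cap
                           for a, b in itertools.combinations(sub, 2)):
                        continue
                    mse, _ = cv_mse(X[list(sub)].to_numpy(), y, folds)
                    cand = (bic(mse, n, size), size, tuple(sorted(sub)))
                    if cand < best:
                        best = cand
            assert tuple(sorted(eq.parameter_ids)) == best[2]


class TestPiecewise:
    def test_compositions_partition_design(self, design):
        from climexp.selection import segment_mask
        comps = two_factor_compositions()
        assert set(comps) == set(range(1, 9))
        for segs in comps.values():
            cover = np.zeros(len(design), dtype=int)
            for lab in segs:
                cover += segment_mask(lab, design)
            assert (cover == 1).all()

    def test_one_factor_compositions(self):
        comps = one_factor_compositions()
        assert comps[1] == ["all"]
        assert comps[2] == ["season=dry", "season=wet"]

    def test_global_truth_chooses_one_piece(self, source_inputs):
        from climexp.pipeline import default_cluster_specs, PipelineConfig
        from climexp.simulate import cluster_signal
        weather, soil, schedule, design, ed = source_inputs
        rng = np.random.default_rng(16)
        specs = default_cluster_specs(ed, PipelineConfig(seed=7), rng,
                                      segmentations=(("all",),))
        X = ed.values.T
        X.index = design.index
        hits = 0
        for seed in range(5):
            s = specs[seed]
            y = cluster_signal(s, ed.values, design)
            y = y / y.std(ddof=1)
            y = y + np.random.default_rng(300 + seed).normal(0, 0.18, 60)
            res = select_piecewise(X, y, design, seed=seed)
            hits += res.model.composition_id == 1
        assert hits >= 4

    def test_field_specific_truth_chooses_field_split(self, source_inputs):
        from climexp.pipeline import default_cluster_specs, PipelineConfig
        from climexp.simulate import cluster_signal
        weather, soil, schedule, design, ed = source_inputs
        rng = np.random.default_rng(17)
        segs = (("field=irrigated", "field=rainfed"),)
        specs = default_cluster_specs(ed, PipelineConfig(seed=7), rng,
                                      segmentations=segs)
        X = ed.values.T
        X.index = design.index
        hits = 0
        for seed in range(5):
            s = specs[seed]
            terms = s.equations["field=irrigated"]
            s.equations = {"field=irrigated": terms,
                           "field=rainfed": [(p, -c) for p, c in terms]}
            y = cluster_signal(s, ed.values, design)
            y = y / y.std(ddof=1)
            y = y + np.random.default_rng(400 + seed).normal(0, 0.18, 60)
            res = select_piecewise(X, y, design, seed=seed)
            hits += res.model.composition_id == 3
        assert hits >= 4

    def test_estimator_interface(self, source_inputs):
        from climexp.pipeline import default_cluster_specs, PipelineConfig
        from climexp.simulate import cluster_signal
        weather, soil, schedule, design, ed = source_inputs
        rng = np.random.default_rng(18)
        specs = default_cluster_specs(ed, PipelineConfig(seed=7), rng,
                                      segmentations=(("all",),))
        X = ed.values.T
        X.index = design.index
        y = cluster_signal(specs[0], ed.values, design)
        y = y / y.std(ddof=1) + rng.normal(0, 0.18, 60)
        reg = PiecewiseEDRegressor(random_state=0).fit(X, y, design=design)
        assert hasattr(reg, "result_")
        pred = reg.predict(X)
        assert pred.shape == (60,)
        assert reg.r2(X, y) > 0.5
        params = reg.get_params()
        assert params["B"] == 300 and params["threshold"] == 0.65

    def test_bic_floor_makes_noiseless_selection_parsimonious(
            self, source_inputs):
        from climexp.pipeline import default_cluster_specs, PipelineConfig
        from climexp.simulate import cluster_signal
        weather, soil, schedule, design, ed = source_inputs
        rng = np.random.default_rng(19)
        specs = default_cluster_specs(ed, PipelineConfig(seed=7), rng,
                                      segmentations=(("all",),))
        X = ed.values.T
        X.index = design.index
        s = specs[0]
        y = cluster_signal(s, ed.values, design)
        res = select_piecewise(X, y, design, seed=0)
        assert res.model.composition_id == 1
        got = tuple(sorted(p for p, _ in res.model.equations["all"].terms))
        assert got == tuple(sorted(p for p, _ in s.equations["all"]))
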
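"""Cross-validation factorial: scenarios, folds, Fisher z, ANOVA, LSMeans."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ricegs.cvfactorial import (anova_accuracy, enumerate_scenarios, fisher_z,
                                fisher_z_inverse, lsmeans, make_folds,
                                replicates_for, run_cross_validation)
from tests.conftest import make_tiny_population, trait_blups

TRAITS = ["FL", "PH", "YLD", "PW"]
METHODS = ["RRBLUP", "GBLUP", "LASSO", "BRR", "BL"]


class TestScenarios:
    def test_main_supplementary_and_kinship_grids(self):
        main = enumerate_scenarios(TRAITS, METHODS, mafs=(0.025, 0.05, 0.10),
                                   lds=(0.75, 0.90, 1.0), ks=(3, 6, 9))
        assert len(main) == 540
        supp = enumerate_scenarios(TRAITS, ["RRBLUP"],
                                   mafs=(0.0001, 0.025, 0.05, 0.075, 0.10),
                                   lds=(0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
                                   ks=(3,))
        assert len(supp) == 140
        kin = enumerate_scenarios(TRAITS, ["RRBLUP"],
                                  mafs=(0.0001, 0.025, 0.05, 0.075, 0.10),
                                  lds=(0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
                                  ks=(3,),
                                  strategies=("random", "stratified",
                                              "lso:A", "lso:B", "lso:C", "lso:D"))
        assert len(kin) == 840

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(nt=st.integers(1, 4), nm=st.integers(1, 5), na=st.integers(1, 3),
           nl=st.integers(1, 3), nk=st.integers(1, 3))
    def test_counts_match_combinatorial_closed_form(self, nt, nm, na, nl, nk):
        scs = enumerate_scenarios([f"t{i}" for i in range(nt)],
                                  [f"m{i}" for i in range(nm)],
                                  mafs=tuple(range(na)), lds=tuple(range(nl)),
                                  ks=tuple(range(2, 2 + nk)))
        assert len(scs) == nt * nm * na * nl * nk
        assert len({s.key for s in scs}) == len(scs)


class TestFolds:
    def test_random_fold_sizes_at_343(self):
        ids = [f"l{i}" for i in range(343)]
        for k, vp, tp in ((3, {114, 115}, {228, 229}),
                          (6, {57, 58}, {285, 286}),
                          (9, {38, 39}, {304, 305})):
            fa = make_folds(ids, k, "random", seed=k)
            sizes = {len(f) for f in fa.folds}
            assert sizes <= vp
            assert {343 - len(f) for f in fa.folds} <= tp
            assert sum(len(f) for f in fa.folds) == 343

    def test_leave_subpop_out_splits(self, tiny_population):
        pop = tiny_population
        for name in np.unique(pop.subpop_labels):
            fa = make_folds(pop.line_ids, 3, f"lso:{name}", pop.subpop_labels)
            assert len(fa.folds) == 1
            assert len(fa.folds[0]) == int((pop.subpop_labels == name).sum())
            tr, va = next(iter(fa.splits()))
            assert set(tr) | set(va) == set(range(pop.n_lines))
            assert not set(tr) & set(va)
            assert np.all(pop.subpop_labels[va] == name)

    def test_stratified_proportionality(self):
        labels = np.repeat(["a", "b", "c", "d"], [86, 83, 82, 92])
        ids = [f"l{i}" for i in range(343)]
        fa = make_folds(ids, 3, "stratified", labels, seed=2)
        for fold in fa.folds:
            for sp, n_sp in zip("abcd", (86, 83, 82, 92)):
                got = np.sum(labels[fold] == sp)
                assert abs(got - n_sp / 3) <= 1

    def test_partitions_disjoint_exhaustive_all_strategies(self):
        labels = np.repeat(["a", "b"], 25)
        ids = [f"l{i}" for i in range(50)]
        for strategy in ("random", "stratified", "lso:a"):
            fa = make_folds(ids, 5, strategy, labels, seed=3)
            allv = np.concatenate(fa.folds)
            assert len(np.unique(allv)) == len(allv)
            if not strategy.startswith("lso"):
                assert len(allv) == 50

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            make_folds(list("abc"), 4, "random")

    def test_replicate_rule(self):
        assert [replicates_for(k) for k in (3, 6, 9)] == [34, 17, 12]


class TestFisherZ:
    def test_known_values_and_oddness(self):
        assert fisher_z(0.0) == 0.0
        assert np.isclose(fisher_z(0.5), 0.5 * np.log(3.0))
        assert np.isclose(fisher_z(0.5), 0.5493, atol=1e-4)
        r = np.linspace(-0.95, 0.95, 21)
        assert np.allclose(fisher_z(-r), -fisher_z(r))

    def test_round_trip_and_monotonicity(self):
        r = np.linspace(-0.999, 0.999, 401)
        z = fisher_z(r)
        assert np.max(np.abs(fisher_z_inverse(z) - r)) < 1e-12
        assert np.all(np.diff(z) > 0)

    def test_boundary_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            z = fisher_z(1.0)
        assert np.isfinite(z)


def synthetic_records(n_per_scenario=2, seed=0):
    """Fisher-z records over the full 540-scenario factorial, generated from
    an additive effects model (no model fitting involved)."""
    rng = np.random.default_rng(seed)
    effects = {
        "trait": dict(zip(TRAITS, (0.2, 0.5, 0.25, 0.28))),
        "method": dict(zip(METHODS, (0.31, 0.30, 0.27, 0.31, 0.32))),
        "maf": {0.025: 0.0, 0.05: 0.0, 0.10: -0.01},
        "ld": {0.75: 0.01, 0.90: 0.01, 1.0: 0.0},
        "k": {3: -0.01, 6: 0.0, 9: 0.01},
    }
    rows = []
    for t, m, a, l, k in itertools.product(TRAITS, METHODS,
                                           effects["maf"], effects["ld"],
                                           effects["k"]):
        mu = (effects["trait"][t] + effects["method"][m] + effects["maf"][a]
              + effects["ld"][l] + effects["k"][k])
        for rep in range(n_per_scenario):
            z = mu + rng.normal(0, 0.12)
            rows.append({"trait": t, "method": m, "maf": a, "ld": l, "k": k,
                         "strategy": "random",
                         "scenario": f"{t}|{m}|{a}|{l}|{k}",
                         "replicate": rep, "fold": 0,
                         "r": np.tanh(z), "z": z, "r_tbv": np.nan})
    return pd.DataFrame(rows)


class TestAnova:
    def test_model_degrees_of_freedom(self):
        rec = synthetic_records()
        assert anova_accuracy(rec, 1).df_model == 539
        assert anova_accuracy(rec, 2).df_model == 13
        assert anova_accuracy(rec, 3).df_model == 79

    def test_balanced_one_way_matches_hand_computed_F(self):
        rng = np.random.default_rng(1)
        rows = []
        means = {"m1": 0.0, "m2": 0.4, "m3": 0.1}
        for m, mu in means.items():
            for rep in range(12):
                z = mu + rng.normal(0, 0.2)
                rows.append({"trait": "T", "method": m, "maf": 0.05, "ld": 1.0,
                             "k": 3, "strategy": "random",
                             "scenario": f"T|{m}", "replicate": rep, "fold": 0,
                             "r": np.tanh(z), "z": z, "r_tbv": np.nan})
        rec = pd.DataFrame(rows)
        res = anova_accuracy(rec, 2)  # only `method` varies -> one-way
        z = rec["z"].to_numpy().reshape(3, 12)
        grand = z.mean()
        ms_b = 12 * ((z.mean(axis=1) - grand) ** 2).sum() / 2
        ms_w = ((z - z.mean(axis=1, keepdims=True)) ** 2).sum() / (36 - 3)
        f_hand = ms_b / ms_w
        f_pkg = res.table.loc[res.table["source"] == "method", "F"].item()
        assert np.isclose(f_pkg, f_hand, rtol=1e-10)

    def test_nested_r2_ordering(self):
        rec = synthetic_records(seed=2)
        r2 = {i: anova_accuracy(rec, i).r2 for i in (1, 2, 3)}
        assert r2[2] <= r2[3] + 1e-12
        assert r2[3] <= r2[1] + 1e-12

    def test_needs_at_least_two_scenarios(self):
        rec = synthetic_records().query("scenario == 'FL|RRBLUP|0.025|0.75|3'")
        with pytest.raises(ValueError):
            anova_accuracy(rec, 1)


class TestLsMeans:
    def test_balanced_lsmeans_equal_raw_level_means(self):
        rec = synthetic_records(seed=3)
        res = anova_accuracy(rec, 2)
        tab = lsmeans(res, "method").table.set_index("level")
        raw = rec.groupby("method")["z"].mean()
        for m in METHODS:
            assert np.isclose(tab.loc[m, "lsmean_z"], raw[m], atol=1e-10)
        assert np.allclose(tab["lsmean_r"], np.tanh(tab["lsmean_z"]))

    def test_identical_levels_share_a_letter(self):
        rng = np.random.default_rng(4)
        rows = []
        for m in ("m1", "m2"):
            for rep in range(15):
                z = rng.normal(0.3, 0.1) if m == "m1" else 0.0
                rows.append({"trait": "T", "method": m, "maf": 0.05, "ld": 1.0,
                             "k": 3, "strategy": "random", "scenario": f"T|{m}",
                             "replicate": rep, "fold": 0,
                             "r": np.tanh(z), "z": z, "r_tbv": np.nan})
        # make both levels literally identical
        df = pd.DataFrame(rows)
        df.loc[df["method"] == "m2", "z"] = df.loc[df["method"] == "m1", "z"].values
        res = anova_accuracy(df, 2)
        tab = lsmeans(res, "method").table
        assert tab["letters"].nunique() == 1

    def test_large_effect_gets_distinct_letters(self):
        rng = np.random.default_rng(5)
        rows = []
        for m, mu in (("lo", 0.0), ("hi", 1.0)):
            for rep in range(20):
                z = mu + rng.normal(0, 0.05)
                rows.append({"trait": "T", "method": m, "maf": 0.05, "ld": 1.0,
                             "k": 3, "strategy": "random", "scenario": f"T|{m}",
                             "replicate": rep, "fold": 0,
                             "r": np.tanh(z), "z": z, "r_tbv": np.nan})
        res = anova_accuracy(pd.DataFrame(rows), 2)
        tab = lsmeans(res, "method").table
        assert set(tab["letters"]) == {"a", "b"}

    def test_unknown_factor_rejected(self):
        res = anova_accuracy(synthetic_records(seed=6), 2)
        with pytest.raises(ValueError):
            lsmeans(res, "strategy")  # constant in these records


class TestEngine:
    def test_k9_produces_108_tests_and_bounded_r(self):
        pop = make_tiny_population(seed=41)
        _, blups = trait_blups(pop, h2=0.6, seed=41)
        scs = enumerate_scenarios(["T"], ["RRBLUP"], mafs=(0.05,), lds=(1.0,),
                                  ks=(9,))
        rec = run_cross_validation(scs, pop, {"T": blups}, seed=1)
        assert len(rec) == 12 * 9  # R = 12 replicates x 9 folds
        assert rec["r"].between(-1, 1).all()
        assert np.isfinite(rec["z"]).all()

    def test_full_heritability_dense_markers_high_accuracy(self):
        """Noiseless trait (h2 = 1) with every QTL inside a dense marker
        panel: cross-validated accuracy is high."""
        pop = make_tiny_population(seed=43, n_loci_per_chromosome=80,
                                   n_lines=70)
        _, blups = trait_blups(pop, h2=1.0, n_qtl=40, seed=43)
        scs = enumerate_scenarios(["T"], ["RRBLUP"], mafs=(0.01,), lds=(1.0,),
                                  ks=(3,))
        rec = run_cross_validation(scs, pop, {"T": blups}, seed=2, r_override=3)
        assert rec["r"].mean() > 0.8

    def test_frequentist_methods_share_partitions(self):
        pop = make_tiny_population(seed=47)
        _, blups = trait_blups(pop, h2=0.5, seed=47)
        scs = enumerate_scenarios(["T"], ["RRBLUP", "GBLUP", "LASSO"],
                                  mafs=(0.05,), lds=(1.0,), ks=(3,))
        rec = run_cross_validation(scs, pop, {"T": blups}, seed=3, r_override=2)
        # same partition -> same validation sets -> RRBLUP vs GBLUP r nearly equal
        rr = rec[rec.method == "RRBLUP"].sort_values(["replicate", "fold"])["r"]
        gb = rec[rec.method == "GBLUP"].sort_values(["replicate", "fold"])["r"]
        assert np.allclose(rr.to_numpy(), gb.to_numpy(), atol=5e-3)

    def test_leave_subpop_out_accuracy_not_higher_than_random(self):
        """Directional finding: predicting a whole left-out subpopulation is
        harder than random cross-validation (mean over >= 10 replicates)."""
        diffs = []
        for rep in range(10):
            pop = make_tiny_population(seed=500 + rep)
            _, blups = trait_blups(pop, h2=0.6, n_qtl=60, seed=500 + rep)
            subs = [f"lso:{s}" for s in np.unique(pop.subpop_labels)]
            scs = enumerate_scenarios(["T"], ["RRBLUP"], mafs=(0.01,), lds=(1.0,),
                                      ks=(3,), strategies=["random"] + subs)
            rec = run_cross_validation(scs, pop, {"T": blups}, seed=rep,
                                       r_override=2)
            r_rand = rec[rec.strategy == "random"]["r"].mean()
            r_lso = rec[rec.strategy != "random"]["r"].mean()
            diffs.append(r_rand - r_lso)
        assert np.mean(diffs) > 0, diffs
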
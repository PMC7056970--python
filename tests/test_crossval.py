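"""Partitioning, trait-set strategies, predictive ability and CV orchestration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mtgblup as mg
from mtgblup.crossval import _cv_mask


class TestPartitions:
    def test_sixty_forty_split_of_145_lines(self):
        ids = [f"L{i}" for i in range(145)]
        parts = mg.make_partitions(ids, mg.CVScheme("CV1", 0.6, 5, seed=1))
        for train, test in parts:
            assert len(train) == 87 and len(test) == 58
            assert set(train) | set(test) == set(ids)
            assert not set(train) & set(test)

    def test_degenerate_test_size_errors(self):
        ids = [f"L{i}" for i in range(12)]
        with pytest.raises(ValueError, match=">= 2"):
            mg.make_partitions(ids, mg.CVScheme("CV1", 0.95, 2, seed=1))

    def test_seed_determinism(self):
        ids = [f"L{i}" for i in range(30)]
        a = mg.make_partitions(ids, mg.CVScheme("CV1", 0.6, 4, seed=5))
        b = mg.make_partitions(ids, mg.CVScheme("CV1", 0.6, 4, seed=5))
        c = mg.make_partitions(ids, mg.CVScheme("CV1", 0.6, 4, seed=6))
        assert a == b
        assert a[0] != c[0]


class TestPredictiveAbility:
    def test_identity_and_sign(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert mg.predictive_ability(x, x) == pytest.approx(1.0)
        assert mg.predictive_ability(x, -x) == pytest.approx(-1.0)

    def test_hand_value(self):
        assert mg.predictive_ability([1, 2, 3], [3, 2, 4]) == pytest.approx(0.5)

    def test_zero_variance_is_missing(self):
        assert np.isnan(mg.predictive_ability([1, 1, 1], [1, 2, 3]))

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            mg.predictive_ability([1, 2], [1, 2])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1),
           st.floats(0.1, 50.0), st.floats(-100.0, 100.0))
    def test_invariant_to_affine_rescaling(self, seed, a, b):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=10), rng.normal(size=10)
        r0 = mg.predictive_ability(x, y)
        r1 = mg.predictive_ability(x, a * y + b)
        assert r1 == pytest.approx(r0, abs=1e-9)


class TestTraitSets:
    def _blues(self, wide):
        long = wide.reset_index(names="line_id").melt(
            id_vars="line_id", var_name="trait", value_name="blue")
        return long.assign(scope="ALL", se=0.0)

    def _structured_blues(self, seed=9):
        # AGRO block driven by one factor, malting block by another,
        # GPC loading on both (protein links the two groups)
        rng = np.random.default_rng(seed)
        n = 300
        f1, f2 = rng.normal(size=n), rng.normal(size=n)
        cols = {}
        for tr in ("YLD", "TGW", "GM2", "PLM"):
            cols[tr] = f1 + 0.4 * rng.normal(size=n)
        for tr in ("BGL", "EXT", "SNI"):
            cols[tr] = f2 + 0.4 * rng.normal(size=n)
        cols["GPC"] = 0.8 * f1 + 0.4 * f2 + 0.4 * rng.normal(size=n)
        wide = pd.DataFrame(cols, index=[f"L{i}" for i in range(n)])
        return self._blues(wide)

    def test_standard_strategies(self):
        blues = self._structured_blues()
        sets = {s.name: s for s in mg.build_trait_sets(blues, "GPC")}
        assert set(sets) == {"AGRO", "A+M", "COR1", "COR2", "COR3"}
        assert set(sets["AGRO"].members) == {"YLD", "TGW", "GM2", "PLM", "GPC"}
        assert set(sets["A+M"].members) == \
               {"YLD", "TGW", "GM2", "PLM", "BGL", "EXT", "SNI", "GPC"}
        assert set(sets["COR1"].members) == {"BGL", "PLM", "SNI", "GPC"}
        # PC1 = agronomic factor (GPC loads there too); PC2 = malting factor
        assert set(sets["COR2"].members) <= \
               {"YLD", "TGW", "GM2", "PLM", "GPC"}
        assert len(set(sets["COR3"].members) & {"BGL", "EXT", "SNI"}) >= 3

    def test_target_appended_when_absent(self):
        blues = self._structured_blues()
        sets = {s.name: s for s in mg.build_trait_sets(blues, "BGL")}
        assert "BGL" in sets["AGRO"].members
        assert sets["AGRO"].members[-1] == "BGL"

    def test_missing_default_trait_errors(self):
        blues = self._structured_blues()
        blues = blues[blues["trait"] != "EXT"]
        with pytest.raises(ValueError, match="EXT"):
            mg.build_trait_sets(blues, "GPC")

    def test_duplicate_members_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            mg.TraitSet("X", ("A", "A"), "A")


class TestMasks:
    def test_cv1_hides_everything_cv2_only_target(self):
        ids = ["L1", "L2", "L3", "L4"]
        m1 = _cv_mask(ids, ("A", "B"), "A", ["L3", "L4"], "CV1")
        m2 = _cv_mask(ids, ("A", "B"), "A", ["L3", "L4"], "CV2")
        assert not m1.loc["L3"].any()
        assert not m2.loc["L3", "A"] and m2.loc["L3", "B"]
        assert m1.loc["L1"].all() and m2.loc["L1"].all()

    def test_cv1_equals_cv2_for_single_trait(self):
        ids = ["L1", "L2", "L3"]
        m1 = _cv_mask(ids, ("A",), "A", ["L2"], "CV1")
        m2 = _cv_mask(ids, ("A",), "A", ["L2"], "CV2")
        pd.testing.assert_frame_equal(m1, m2)


class TestRunCV:
    def test_no_signal_gives_null_r_pa(self, small_panel):
        _, _, _, _, K = small_panel
        rng = np.random.default_rng(60)
        blues = pd.DataFrame({"line_id": K.ids, "trait": "T1", "scope": "ALL",
                              "blue": rng.normal(size=len(K.ids)), "se": 1.0})
        strat = mg.TraitSet("ST", ("T1",), "T1")
        res = mg.run_cv(blues, K, strat, mg.CVScheme("CV1", 0.6, 6, seed=3),
                        mg.GibbsConfig(burn_in=400, n_iter=800, seed=1))
        mean = res.results["r_pa"].mean()
        assert abs(mean) < 2.0 / np.sqrt(40)

    def test_partitions_paired_across_models(self, pair_panel):
        _, _, blues, K = pair_panel
        strat = mg.TraitSet("PAIR", ("T1", "T2"), "T1")
        res = mg.compare_schemes(blues, K, strat,
                                 mg.CVScheme("CV2", 0.6, 2, seed=5),
                                 mg.GibbsConfig(burn_in=300, n_iter=600, seed=2))
        assert set(res.results["model"]) == {"ST-CV1", "MT-CV1", "MT-CV2"}
        assert len(res.partitions) == 2
        assert res.results.groupby("model")["repeat"].count().eq(2).all()

    def test_results_reproducible_from_seed(self, pair_panel):
        _, _, blues, K = pair_panel
        strat = mg.TraitSet("PAIR", ("T1", "T2"), "T1")
        kw = dict(scheme=mg.CVScheme("CV2", 0.6, 2, seed=8),
                  cfg=mg.GibbsConfig(burn_in=200, n_iter=400, seed=4))
        a = mg.run_cv(blues, K, strat, kw["scheme"], kw["cfg"])
        b = mg.run_cv(blues, K, strat, kw["scheme"], kw["cfg"])
        pd.testing.assert_frame_equal(a.results, b.results)


@pytest.fixture(scope="module")
def env_blues():
    """Two-env simulation with no GEI: per-env line means as BLUEs."""
    cfg = mg.SimConfig(n_families=30, lines_per_family=(5,) * 30,
                       n_parents=31, chrom_lengths_cM=(150.0,) * 5,
                       n_markers=1200, n_traits=1, Sigma_g=np.eye(1),
                       Sigma_e=np.array([[0.6667]]),  # h2 = 0.6 per plot
                       n_envs=2, n_blocks=1, var_env=1.0, var_block=0.0,
                       var_gei=0.0, replicate_fraction=0.0, seed=70)
    mk, truth, plots = mg.simulate_dataset(cfg)
    K = mg.additive_relationship(mg.qc_filter(mk, 0.0, 0.0))
    blues = plots.rename(columns={"value": "blue"})[
        ["line_id", "trait", "environment", "blue"]]
    blues = blues.rename(columns={"environment": "scope"}).assign(se=0.0)
    return blues, K


class TestEnvPrediction:
    def test_target_env_cannot_be_source(self, env_blues):
        blues, K = env_blues
        with pytest.raises(ValueError, match="sources"):
            mg.env_prediction(blues, K, "E2", "T1",
                              mg.CVScheme("CV2", 0.6, 1, seed=1),
                              source_envs=["E1", "E2"])

    def test_cv2_at_least_cv1_and_close_to_within_env(self, env_blues):
        blues, K = env_blues
        cfg = mg.GibbsConfig(burn_in=500, n_iter=1000, seed=2)
        means = {}
        for scm in ("CV1", "CV2"):
            res = mg.env_prediction(blues, K, "E2", "T1",
                                    mg.CVScheme(scm, 0.6, 4, seed=9), cfg)
            means[scm] = res.results["r_pa"].mean()
        # no GEI and an informative source env: CV2 >= CV1
        assert means["CV2"] >= means["CV1"] - 0.05
        # CV1 env prediction (kinship only for test lines) matches the
        # within-env single-trait CV1 baseline in the no-GEI limit
        st_blues = blues[blues["scope"] == "E2"].assign(scope="ALL")
        strat = mg.TraitSet("ST", ("T1",), "T1")
        base = mg.run_cv(st_blues, K, strat, mg.CVScheme("CV1", 0.6, 4, seed=9),
                         cfg)
        assert means["CV1"] == pytest.approx(
            base.results["r_pa"].mean(), abs=0.15)

    def test_gei_ordering(self):
        # strong GEI degrades cross-environment prediction
        means = {}
        for label, vge in (("low", 0.25), ("high", 2.0)):
            vals = []
            for seed in (80, 81):
                cfg = mg.SimConfig(
                    n_families=30, lines_per_family=(5,) * 30, n_parents=31,
                    chrom_lengths_cM=(150.0,) * 5, n_markers=1200, n_traits=1,
                    Sigma_g=np.eye(1), Sigma_e=np.array([[0.6667]]),
                    n_envs=2, n_blocks=1, var_env=1.0, var_block=0.0,
                    var_gei=vge, replicate_fraction=0.0, seed=seed)
                mk, truth, plots = mg.simulate_dataset(cfg)
                K = mg.additive_relationship(mg.qc_filter(mk, 0.0, 0.0))
                blues = plots.rename(columns={"value": "blue"})[
                    ["line_id", "trait", "environment", "blue"]]
                blues = blues.rename(columns={"environment": "scope"}).assign(se=0.0)
                res = mg.env_prediction(blues, K, "E2", "T1",
                                        mg.CVScheme("CV2", 0.6, 3, seed=1),
                                        mg.GibbsConfig(burn_in=400, n_iter=800,
                                                       seed=3))
                vals.append(res.results["r_pa"].mean())
            means[label] = np.mean(vals)
        assert means["low"] > means["high"]
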
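"""Phenome screen: case derivation, FDR, partition, localization, rG batch."""

import itertools

import numpy as np
import pandas as pd
import pytest

import liabscreen as ls
from liabscreen.screen import (
    PhenotypeDefinition,
    ScreenConfig,
    assemble_cohort,
    bh_fdr,
    derive_case_status,
)


class TestDeriveCaseStatus:
    @staticmethod
    def _events(rows):
        return pd.DataFrame(rows, columns=["sample_id", "code", "date"])

    def test_distinct_date_rule(self):
        defn = PhenotypeDefinition("ph1", {"250.1"})
        events = self._events(
            [
                ("a", "250.1", "2001-01-01"),
                ("a", "250.1", "2001-01-02"),  # case: two distinct dates
                ("b", "250.1", "2001-01-01"),
                ("b", "250.1", "2001-01-01"),  # excluded: same-date repeats
                ("c", "250.1", "2001-03-05"),  # excluded: single event
            ]
        )
        status = derive_case_status(events, defn, ["a", "b", "c", "d"])
        assert status["a"] == "case"
        assert status["b"] == "excluded"
        assert status["c"] == "excluded"
        assert status["d"] == "control-eligible"

    def test_constituent_codes_pool_across(self):
        defn = PhenotypeDefinition("dm", {"250.1", "250.2"})
        events = self._events(
            [("a", "250.1", "2001-01-01"), ("a", "250.2", "2002-01-01")]
        )
        status = derive_case_status(events, defn, ["a"])
        assert status["a"] == "case"

    def test_unrelated_codes_ignored(self):
        defn = PhenotypeDefinition("ph", {"714.0"})
        events = self._events(
            [("a", "250.1", "2001-01-01"), ("a", "250.1", "2001-02-01")]
        )
        status = derive_case_status(events, defn, ["a"])
        assert status["a"] == "control-eligible"


class TestBhFdr:
    def brute_force_bh(self, p):
        # literal step-up definition: q_i = min_{j: p_(j) >= p_(i)} m p_(j) / j
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        ranks = np.empty(m, int)
        ranks[order] = np.arange(1, m + 1)
        q = np.empty(m)
        for i in range(m):
            cands = [
                min(m * p[j] / ranks[j], 1.0)
                for j in range(m)
                if p[j] >= p[i] or ranks[j] >= ranks[i]
            ]
            q[i] = min(cands)
        return q

    def test_hand_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert bh_fdr([0.37]) == pytest.approx([0.37])
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.random(200)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_fdr(p), q_ref, atol=1e-12)

    def test_all_permutations_of_small_vectors(self):
        base = [0.005, 0.04, 0.2, 0.5, 0.9]
        for perm in itertools.permutations(base):
            q = bh_fdr(list(perm))
            assert np.allclose(q, self.brute_force_bh(perm), atol=1e-12)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


@pytest.fixture(scope="module")
def screen_world():
    """Simulated phenome: genotypes, GRMs, and a mix of null/genetic traits."""
    ds = ls.simulate_genotypes(700, 2500, seed=51)
    regions = ls.default_hla_regions()
    hla_ids = ls.snps_in_regions(ds.snps, regions.select(["HLA"]))
    rest_ids = [s for s in ds.snp_ids if s not in set(hla_ids)]
    grm_all = ls.compute_grm(ds)
    grm_hla = ls.compute_grm(ds, hla_ids)
    grm_rest = ls.compute_grm(ds, rest_ids)
    statuses = {}
    arch_gen = ls.ArchitectureSpec({"all": (0.6, 300)}, prevalence=0.35)
    arch_hla = ls.ArchitectureSpec({"HLA": (0.6, 60)}, prevalence=0.35)
    arch_null = ls.ArchitectureSpec({}, prevalence=0.35)
    for k in range(3):
        s, _ = ls.simulate_liability_phenotype(ds, arch_gen, seed=100 + k)
        statuses[f"gen{k}"] = pd.Series(
            np.where(s == 1, "case", "control-eligible"), index=ds.sample_ids
        )
    s, _ = ls.simulate_liability_phenotype(ds, arch_hla, seed=200)
    statuses["hla0"] = pd.Series(
        np.where(s == 1, "case", "control-eligible"), index=ds.sample_ids
    )
    for k in range(4):
        s, _ = ls.simulate_liability_phenotype(ds, arch_null, seed=300 + k)
        statuses[f"null{k}"] = pd.Series(
            np.where(s == 1, "case", "control-eligible"), index=ds.sample_ids
        )
    return ds, grm_all, grm_hla, grm_rest, statuses


class TestRunScreen:
    def test_min_cases_skip(self, screen_world):
        ds, grm_all, _, _, statuses = screen_world
        tiny = pd.Series("control-eligible", index=ds.sample_ids)
        tiny.iloc[:10] = "case"
        out = ls.run_screen(
            {"tiny": tiny}, ds, grm_all, ScreenConfig(min_cases=50, covariates=())
        )
        assert bool(out.loc[0, "skipped"])
        assert "fewer than 50" in out.loc[0, "reason"]

    def test_screen_ranks_genetic_phenotypes(self, screen_world):
        ds, grm_all, _, _, statuses = screen_world
        cfg = ScreenConfig(min_cases=50, covariates=("age", "sex"), seed=7)
        out = ls.run_screen(statuses, ds, grm_all, cfg)
        done = out[~out["skipped"]]
        assert len(done) == len(statuses)
        ranked = done.sort_values("lrt_p")["phenotype_id"].tolist()
        top4 = set(ranked[:4])
        assert {"gen0", "gen1", "gen2", "hla0"} <= top4 | set(ranked[:5])
        # liability-scale columns populated and finite where fitted
        assert np.isfinite(done["h2_liab"]).all()

    def test_determinism(self, screen_world):
        ds, grm_all, _, _, statuses = screen_world
        cfg = ScreenConfig(min_cases=50, covariates=(), seed=9)
        two = {k: statuses[k] for k in ["gen0", "null0"]}
        a = ls.run_screen(two, ds, grm_all, cfg)
        b = ls.run_screen(two, ds, grm_all, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_failures_do_not_abort_batch(self, screen_world):
        ds, grm_all, _, _, statuses = screen_world
        broken = pd.Series("case", index=ds.sample_ids)  # no controls at all
        batch = {"broken": broken, "gen0": statuses["gen0"]}
        out = ls.run_screen(batch, ds, grm_all, ScreenConfig(covariates=()))
        assert bool(out.set_index("phenotype_id").loc["broken", "skipped"])
        assert not bool(out.set_index("phenotype_id").loc["gen0", "skipped"])


class TestHlaPartition:
    def test_partition_recovers_hla_signal(self, screen_world):
        ds, grm_all, grm_hla, grm_rest, statuses = screen_world
        cfg = ScreenConfig(min_cases=50, covariates=(), seed=11)
        sub = {k: statuses[k] for k in ["hla0", "null0", "null1"]}
        base = ls.run_screen(sub, ds, grm_all, cfg)
        out = ls.hla_partition_screen(base, sub, ds, grm_hla, grm_rest, cfg)
        r = out.set_index("phenotype_id")
        assert r.loc["hla0", "hla_lrt_p"] < 0.05
        assert r.loc["hla0", "hla_lrt_p"] < r.loc["null0", "hla_lrt_p"]
        # HLA component should carry most of the signal for hla0
        assert r.loc["hla0", "h2_hla"] > r.loc["hla0", "h2_rest"] - 0.05

    def test_partition_consistency_with_total(self, screen_world):
        # single-GRM total ~ sum of two-GRM components on the same cohort
        ds, grm_all, grm_hla, grm_rest, statuses = screen_world
        cfg = ScreenConfig(min_cases=50, covariates=(), seed=13)
        sub = {"gen0": statuses["gen0"]}
        base = ls.run_screen(sub, ds, grm_all, cfg)
        out = ls.hla_partition_screen(base, sub, ds, grm_hla, grm_rest, cfg)
        r = out.iloc[0]
        total = r["h2_obs"]
        parts = r["h2_hla"] + r["h2_rest"]
        # 2 SE of the single-GRM estimate as the comparison scale
        assert abs(parts - total) < 2 * r["h2_obs_se"] + 0.05


class TestClassLocalization:
    def test_empty_class_grm_rejected(self, screen_world):
        ds, grm_all, grm_hla, grm_rest, statuses = screen_world
        with pytest.raises(ValueError, match="classII"):
            ls.class_localization(
                ["hla0"], statuses, ds,
                {"classI": grm_hla, "classII": None, "otherHLA": grm_hla,
                 "rest": grm_rest},
            )

    def test_class_signal_localizes(self):
        ds = ls.simulate_genotypes(700, 3000, seed=61)
        regions = ls.default_hla_regions()
        ids = {
            "classI": ls.snps_in_regions(ds.snps, regions.select(["MHC_classI"])),
            "classII": ls.snps_in_regions(ds.snps, regions.select(["MHC_classII"])),
        }
        hla = set(ls.snps_in_regions(ds.snps, regions.select(["HLA"])))
        ids["otherHLA"] = sorted(hla - set(ids["classI"]) - set(ids["classII"]))
        ids["rest"] = [s for s in ds.snp_ids if s not in hla]
        grms = {k: ls.compute_grm(ds, v) for k, v in ids.items()}
        arch = ls.ArchitectureSpec({"MHC_classII": (0.7, 15)}, prevalence=0.4)
        s, _ = ls.simulate_liability_phenotype(ds, arch, seed=62)
        statuses = {
            "t2d": pd.Series(
                np.where(s == 1, "case", "control-eligible"), index=ds.sample_ids
            )
        }
        out = ls.class_localization(
            ["t2d"], statuses, ds, grms,
            ScreenConfig(covariates=(), seed=63),
        )
        row = out.iloc[0]
        assert row["classII_p"] < 0.05
        assert row["classII_p"] < row["classI_p"]


class TestEnrichmentTally:
    def test_counting(self):
        df = pd.DataFrame(
            {"phenotype_id": list("abcde"), "lrt_p": [0.001, 0.002, 0.2, 0.4, 0.9]}
        )
        labels = {"a": "autoimmune", "b": "autoimmune", "c": "autoimmune"}
        out = ls.enrichment_tally(df, labels, [0.0, 0.01, 1.01])
        assert out.loc[0, "n_positive"] == 2 and out.loc[0, "n_total"] == 2
        assert out.loc[1, "n_positive"] == 1 and out.loc[1, "n_total"] == 3

    def test_empty_bin(self):
        df = pd.DataFrame({"phenotype_id": ["a"], "lrt_p": [0.5]})
        out = ls.enrichment_tally(df, {}, [0.0, 0.01, 1.01])
        assert out.loc[0, "n_total"] == 0


class TestRgBatch:
    def test_self_pair_rejected(self, screen_world):
        ds, grm_all, _, _, statuses = screen_world
        with pytest.raises(ValueError, match="self-pair"):
            ls.rg_batch([("gen0", "gen0")], statuses, ds, grm_all)

    def test_correlated_pair_detected(self):
        ds = ls.simulate_genotypes(800, 2500, seed=71)
        grm = ls.compute_grm(ds)
        arch = ls.ArchitectureSpec({"all": (0.6, 300)}, prevalence=0.4)
        s1, s2, _ = ls.simulate_bivariate(ds, arch, arch, rho_effects=0.8, seed=72)
        s3, _ = ls.simulate_liability_phenotype(ds, arch, seed=73)
        to_series = lambda s: pd.Series(
            np.where(s == 1, "case", "control-eligible"), index=ds.sample_ids
        )
        statuses = {"p1": to_series(s1), "p2": to_series(s2), "p3": to_series(s3)}
        out = ls.rg_batch(
            [("p1", "p2"), ("p1", "p3"), ("p2", "p3")], statuses, ds, grm,
            ScreenConfig(covariates=(), seed=74),
        )
        r = out.set_index(["pheno1", "pheno2"])
        assert r.loc[("p1", "p2"), "p"] == out["p"].min()
        assert r.loc[("p1", "p2"), "rg"] > 0.3


class TestCohortAssembly:
    def test_ratio_and_composition(self, screen_world):
        ds, _, _, _, statuses = screen_world
        cfg = ScreenConfig(control_ratio=2, seed=15)
        ids, y = assemble_cohort(statuses["gen0"], ds.samples, cfg, "gen0")
        n_cases = int(y.sum())
        assert n_cases == (statuses["gen0"] == "case").sum()
        assert len(ids) - n_cases <= 2 * n_cases
        assert len(set(ids)) == len(ids)
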
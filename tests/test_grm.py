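"""GRM estimator, QC filters, pruning, LD and PCA."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import liabscreen as ls
from liabscreen.data import make_sample_table, make_snp_table
from liabscreen.grm import Grm, QcReport, hwe_exact_p, snp_qc
from tests.conftest import random_dataset


def hwe_enumeration_oracle(n_aa, n_ab, n_bb):
    """Exact-rational brute force over all heterozygote configurations."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    probs = {}
    for het in range(min(na, 2 * n - na) % 2, min(na, 2 * n - na) + 1, 2):
        hom_a = (na - het) // 2
        hom_b = n - hom_a - het
        if hom_a < 0 or hom_b < 0:
            continue
        # P(config | allele counts) proportional to multinomial x 2^het
        probs[het] = Fraction(
            2**het * comb(n, hom_a) * comb(n - hom_a, het), 1
        )
    total = sum(probs.values())
    p_obs = probs[n_ab]
    return float(sum(v for v in probs.values() if v <= p_obs) / total)


class TestHwe:
    @pytest.mark.parametrize(
        "counts",
        [(25, 50, 25), (40, 20, 40), (0, 10, 0), (5, 0, 5), (10, 5, 3), (1, 1, 1)],
    )
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_p(*counts) == pytest.approx(
            hwe_enumeration_oracle(*counts), abs=1e-12
        )

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        n_aa=st.integers(0, 50), n_ab=st.integers(0, 50), n_bb=st.integers(0, 50)
    )
    def test_enumeration_property_all_small_tables(self, n_aa, n_ab, n_bb):
        if n_aa + n_ab + n_bb == 0:
            return
        assert hwe_exact_p(n_aa, n_ab, n_bb) == pytest.approx(
            hwe_enumeration_oracle(n_aa, n_ab, n_bb), abs=1e-10
        )


class TestSnpQc:
    @staticmethod
    def _ds_from_counts(counts_list):
        cols = []
        for aa, ab, bb in counts_list:
            cols.append([2.0] * aa + [1.0] * ab + [0.0] * bb)
        n = len(cols[0])
        d = np.array(cols, dtype=np.float32).T
        return ls.GenotypeDataset(
            make_sample_table([f"s{i}" for i in range(n)]),
            make_snp_table([f"r{j}" for j in range(len(cols))]),
            d,
        )

    def test_equilibrium_snp_retained(self):
        ds = self._ds_from_counts([(25, 50, 25)])
        out, rep = snp_qc(ds, return_report=True)
        assert out.n_snps == 1 and rep.n_removed_hwe == 0

    def test_monomorphic_removed_by_maf(self):
        ds = self._ds_from_counts([(100, 0, 0), (25, 50, 25)])
        out, rep = snp_qc(ds, return_report=True)
        assert out.n_snps == 1 and rep.n_removed_maf == 1

    def test_het_deficit_removed_iff_below_threshold(self):
        # (40, 20, 40): massive heterozygote deficit at MAF 0.5
        p = hwe_enumeration_oracle(40, 20, 40)
        ds = self._ds_from_counts([(40, 20, 40)])
        out = snp_qc(ds)
        assert (out.n_snps == 0) == (p <= 0.001)
        assert p <= 0.001  # this table really is out of equilibrium

    def test_all_removed_warns_not_raises(self):
        ds = self._ds_from_counts([(100, 0, 0)])
        with pytest.warns(UserWarning, match="every SNP"):
            out = snp_qc(ds)
        assert out.n_snps == 0


class TestComputeGrm:
    def test_two_sample_hand_value(self):
        # n=2, m=1, dosages (0, 2): p=0.5, A12 = (0-1)(2-1)/(2*0.5*0.5) = -2
        ds = ls.GenotypeDataset(
            make_sample_table(["a", "b"]),
            make_snp_table(["r1"]),
            np.array([[0.0], [2.0]]),
        )
        g = ls.compute_grm(ds)
        assert g.values[0, 1] == pytest.approx(-2.0)
        assert g.values[0, 0] == pytest.approx(2.0)

    def test_identical_rows_give_equal_diag_offdiag(self):
        ds = random_dataset(1, 30, seed=5)
        d = np.vstack([ds.dosages, ds.dosages])
        ds2 = ls.GenotypeDataset(
            make_sample_table(["a", "b"]), ds.snps, d
        )
        g = ls.compute_grm(ds2)
        assert g.values[0, 1] == pytest.approx(g.values[0, 0])

    def test_unrelated_cohort_expectations(self):
        ds = random_dataset(200, 10_000, seed=6)
        g = ls.compute_grm(ds)
        off = g.values[~np.eye(200, dtype=bool)]
        assert abs(np.diag(g.values).mean() - 1.0) < 0.02
        assert abs(off.mean()) < 0.02

    def test_disjoint_subset_merge_consistency(self):
        ds = random_dataset(40, 60, seed=7)
        ids = list(ds.snp_ids)
        g1 = ls.compute_grm(ds, ids[:25])
        g2 = ls.compute_grm(ds, ids[25:])
        merged = ls.merge_grms([g1, g2])
        full = ls.compute_grm(ds)
        assert np.abs(merged.values - full.values).max() < 1e-10

    def test_monomorphic_excluded_with_warning(self):
        ds = random_dataset(20, 5, seed=8)
        d = ds.dosages.copy()
        d[:, 0] = 2.0
        ds2 = ls.GenotypeDataset(ds.samples, ds.snps, d)
        with pytest.warns(UserWarning, match="monomorphic"):
            g = ls.compute_grm(ds2)
        assert g.n_snps == 4

    def test_missing_uses_pairwise_counts(self):
        ds = random_dataset(30, 50, seed=9, missing_frac=0.2)
        g = ls.compute_grm(ds)
        assert np.isfinite(g.values).all()
        assert np.abs(g.values - g.values.T).max() < 1e-12


class TestGrmIo:
    def test_gcta_binary_round_trip(self, tmp_path):
        g = ls.compute_grm(random_dataset(15, 40, seed=10))
        g.write_gcta(tmp_path / "g")
        back = Grm.read_gcta(tmp_path / "g")
        assert np.abs(back.values - g.values).max() < 1e-6  # float32 storage
        assert list(back.sample_ids) == list(g.sample_ids)
        assert back.n_snps == g.n_snps

    def test_text_round_trip(self, tmp_path):
        g = ls.compute_grm(random_dataset(10, 30, seed=11))
        g.write_text(tmp_path / "g.txt")
        back = Grm.read_text(tmp_path / "g.txt")
        assert np.abs(back.values - g.values).max() < 1e-9


class TestPruneRelated:
    @staticmethod
    def _grm(ids, pairs, val=0.5):
        n = len(ids)
        v = np.eye(n)
        for i, j in pairs:
            v[i, j] = v[j, i] = val
        return Grm(np.array(ids), v, 10)

    def test_all_below_cutoff_retained(self):
        g = self._grm(["a", "b", "c"], [], val=0.0)
        assert ls.prune_related(g) == ["a", "b", "c"]

    def test_tie_removes_lexicographically_larger(self):
        g = self._grm(["a", "b"], [(0, 1)])
        assert ls.prune_related(g) == ["a"]

    def test_star_graph_removes_hub_only(self):
        ids = ["hub", "p1", "p2", "p3", "p4", "p5"]
        g = self._grm(ids, [(0, j) for j in range(1, 6)])
        kept = ls.prune_related(g)
        assert kept == ["p1", "p2", "p3", "p4", "p5"]

    def test_higher_missingness_breaks_tie(self):
        g = self._grm(["a", "b"], [(0, 1)])
        kept = ls.prune_related(g, missing_rates=[0.5, 0.0])
        assert kept == ["b"]

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_no_retained_pair_exceeds_cutoff(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        v = rng.normal(0, 0.08, size=(n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        g = Grm(np.array([f"s{i}" for i in range(n)]), v, 5)
        kept = ls.prune_related(g, cutoff=0.07)
        sub = g.subset(kept).values
        off = sub[~np.eye(len(kept), dtype=bool)]
        assert (np.abs(off) <= 0.07).all()

    def test_nonpositive_cutoff_raises(self, structured_grm):
        with pytest.raises(ValueError):
            ls.prune_related(structured_grm, cutoff=0.0)


class TestRegionsAndLd:
    def test_boundary_inclusive(self):
        snps = make_snp_table(["r1", "r2"], chrom="6",
                              pos=[26_000_000, 25_999_999])
        rs = ls.default_hla_regions().select(["HLA"])
        assert ls.snps_in_regions(snps, rs) == ["r1"]

    def test_flank_arithmetic(self):
        snps = make_snp_table(["r1"], chrom="6", pos=[25_975_000])
        rs = ls.default_hla_regions().select(["HLA"])
        assert ls.snps_in_regions(snps, rs, flank=25_000) == ["r1"]

    def test_wrong_chromosome_excluded(self):
        snps = make_snp_table(["r1"], chrom="7", pos=[27_000_000])
        assert ls.snps_in_regions(snps, ls.default_hla_regions()) == []

    def test_r2_self_and_sign_invariance(self):
        d = np.array([[0, 2], [1, 1], [2, 0], [0, 2]], dtype=np.float32)
        ds = ls.GenotypeDataset(
            make_sample_table(["a", "b", "c", "d"]), make_snp_table(["x", "y"]), d
        )
        assert ls.ld_r2(ds, "x", "x") == pytest.approx(1.0)
        assert ls.ld_r2(ds, "x", "y") == pytest.approx(1.0)

    def test_r2_hand_value(self):
        # vectors (0,1,2,1) and (0,0,2,2): cov=2/4, var=(2/4, 4/4) -> r^2 = 0.5
        d = np.array([[0, 0], [1, 0], [2, 2], [1, 2]], dtype=np.float32)
        ds = ls.GenotypeDataset(
            make_sample_table(list("abcd")), make_snp_table(["x", "y"]), d
        )
        assert ls.ld_r2(ds, "x", "y") == pytest.approx(0.5)

    def test_zero_variance_signalled(self):
        d = np.array([[1, 0], [1, 1], [1, 2]], dtype=np.float32)
        ds = ls.GenotypeDataset(
            make_sample_table(list("abc")), make_snp_table(["x", "y"]), d
        )
        with pytest.raises(ValueError, match="zero dosage variance"):
            ls.ld_r2(ds, "x", "y")

    def test_catalog_exclusion_by_r2(self):
        rng = np.random.default_rng(12)
        n = 400
        cat = rng.binomial(2, 0.4, size=n).astype(np.float32)
        # neighbour A: tight LD with the catalog SNP; neighbour B: nearly free
        swap_few = cat.copy()
        idx = rng.choice(n, size=12, replace=False)
        swap_few[idx] = rng.binomial(2, 0.4, size=12)
        free = rng.binomial(2, 0.4, size=n).astype(np.float32)
        d = np.column_stack([cat, swap_few, free])
        ds = ls.GenotypeDataset(
            make_sample_table([f"s{i}" for i in range(n)]),
            make_snp_table(["cat", "near", "far"], chrom="1", pos=[100, 200, 300]),
            d,
        )
        r2_near = ls.ld_r2(ds, "cat", "near")
        r2_far = ls.ld_r2(ds, "cat", "far")
        assert r2_near > 0.2 and r2_far < 0.2
        excl = ls.exclude_catalog_linked(ds, ["cat"])
        assert excl == {"cat", "near"}

    def test_empty_catalog(self, structured_sim):
        assert ls.exclude_catalog_linked(structured_sim, []) == set()


class TestPca:
    def test_identity_grm_orthonormal(self):
        g = Grm(np.array([f"s{i}" for i in range(10)]), np.eye(10), 5)
        pcs = ls.compute_pcs(g, k=3)
        assert np.allclose(pcs.components.T @ pcs.components, np.eye(3), atol=1e-8)

    def test_rank_one_grm(self):
        v = np.arange(1.0, 7.0)
        g = Grm(np.array([f"s{i}" for i in range(6)]), np.outer(v, v), 5)
        pcs = ls.compute_pcs(g, k=1)
        assert pcs.eigenvalues[0] == pytest.approx(v @ v)
        direction = pcs.components[:, 0]
        assert np.allclose(np.abs(direction), v / np.linalg.norm(v), atol=1e-10)
        assert direction[np.argmax(np.abs(direction))] > 0  # sign convention

    def test_pc1_separates_subpopulations(self):
        ds = ls.simulate_genotypes(300, 2000, n_subpops=2, fst=0.05, seed=13)
        g = ls.compute_grm(ds)
        pcs = ls.compute_pcs(g, k=2)
        labels = ds.samples["subpop"].to_numpy()
        r = np.corrcoef(pcs.components[:, 0], labels)[0, 1]
        assert abs(r) > 0.9

    def test_eigenvalues_non_increasing(self, structured_grm):
        pcs = ls.compute_pcs(structured_grm, k=10)
        assert (np.diff(pcs.eigenvalues) <= 1e-10).all()
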
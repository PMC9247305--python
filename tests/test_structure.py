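import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from caprilink.genotypes import MISSING
from caprilink.pedigree import Pedigree, pedigree_inbreeding
from caprilink.simulate import simulate_admixture_panel
from caprilink.structure import (
    admixture_em,
    align_q_to_truth,
    choose_k,
    genomic_inbreeding,
    grm,
    pca,
    _admixture_loglik,
)


@pytest.fixture(scope="module")
def two_pop_panel():
    return simulate_admixture_panel(100, 2000, 0.15, 2, seed=5)


@pytest.fixture(scope="module")
def hwe_panel():
    gm, _ = simulate_admixture_panel(200, 5000, 0.1, 1, seed=6)
    return gm


class TestGRM:
    def test_matches_naive_double_loop(self, two_pop_panel):
        gm, _ = two_pop_panel
        sub = gm.take_samples(np.arange(10)).take_snps(np.arange(50))
        g = grm(sub).matrix
        dos = sub.calls.astype(float)
        p = dos.mean(axis=0) / 2.0
        keep = (p > 0) & (p < 1)
        dos, p = dos[:, keep], p[keep]
        z = dos - 2.0 * p
        scale = 2.0 * np.sum(p * (1 - p))
        naive = np.empty((10, 10))
        for i in range(10):
            for j in range(10):
                naive[i, j] = sum(z[i, k] * z[j, k] for k in range(z.shape[1])) / scale
        assert np.max(np.abs(naive - g)) < 1e-12

    def test_duplicate_individuals_symmetric(self, genotype_factory):
        rng = np.random.default_rng(0)
        row = rng.binomial(2, 0.4, size=60).astype(np.int8)
        other = rng.binomial(2, 0.4, size=(8, 60)).astype(np.int8)
        gm = genotype_factory(np.vstack([row, row, other]))
        g = grm(gm).matrix
        assert g[0, 0] == pytest.approx(g[1, 1], abs=1e-12)
        assert g[0, 1] == pytest.approx(g[0, 0], abs=1e-12)
        assert np.allclose(g, g.T)

    def test_hwe_diagonal_near_one(self, hwe_panel):
        """VanRaden scaling: unrelated HWE sample has mean G_ii close to 1."""
        g = grm(hwe_panel).matrix
        assert np.diag(g).mean() == pytest.approx(1.0, abs=0.05)

    def test_missing_imputed_to_frequency(self, genotype_factory):
        rng = np.random.default_rng(2)
        calls = rng.binomial(2, 0.5, size=(20, 30)).astype(np.int8)
        gm = genotype_factory(calls)
        g0 = grm(gm).matrix
        calls2 = calls.copy()
        calls2[0, 0] = MISSING
        g1 = grm(genotype_factory(calls2)).matrix
        assert np.isfinite(g1).all()
        assert abs(g1[0, 0] - g0[0, 0]) < 0.2


class TestPCA:
    def test_variance_percentages_sum_to_100(self, two_pop_panel):
        gm, _ = two_pop_panel
        g = grm(gm)
        res = pca(g, n_components=g.matrix.shape[0])
        assert res.variance_pct.sum() == pytest.approx(100.0, abs=1e-9)
        assert (np.diff(res.variance_pct) <= 1e-12).all()
        assert (res.variance_pct >= -1e-12).all()

    def test_two_populations_separate_on_pc1(self, two_pop_panel):
        gm, truth = two_pop_panel
        res = pca(grm(gm), 2)
        pc1 = res.coords["PC1"].to_numpy()
        side = np.sign(pc1)
        pop = truth[:, 0]
        assert len(np.unique(side[pop == 1])) == 1
        assert side[pop == 1][0] != side[pop == 0][0]

    def test_duplicate_individuals_same_coordinates(self, genotype_factory):
        rng = np.random.default_rng(1)
        row = rng.binomial(2, 0.4, size=80).astype(np.int8)
        other = rng.binomial(2, 0.4, size=(6, 80)).astype(np.int8)
        gm = genotype_factory(np.vstack([row, row, other]))
        res = pca(grm(gm), 3)
        a = res.coords.iloc[0, 1:].to_numpy(dtype=float)
        b = res.coords.iloc[1, 1:].to_numpy(dtype=float)
        assert np.allclose(a, b, atol=1e-8)

    def test_sign_convention_reproducible(self, two_pop_panel):
        gm, _ = two_pop_panel
        g = grm(gm)
        r1 = pca(g, 2)
        r2 = pca(g, 2)
        pd.testing.assert_frame_equal(r1.coords, r2.coords)
        for k in ("PC1", "PC2"):
            v = r1.coords[k].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0

    def test_nonfinite_rejected(self, two_pop_panel):
        gm, _ = two_pop_panel
        g = grm(gm.take_samples(np.arange(5)))
        g.matrix[0, 0] = np.nan
        with pytest.raises(ValueError):
            pca(g)


class TestGenomicInbreeding:
    def test_fully_homozygous_animal_is_one(self, genotype_factory):
        rng = np.random.default_rng(3)
        other = rng.binomial(2, 0.5, size=(30, 200)).astype(np.int8)
        hom = (rng.random(200) < 0.5).astype(np.int8) * 2
        gm = genotype_factory(np.vstack([hom, other]))
        f = genomic_inbreeding(gm)
        assert f["F_het"].iloc[0] == pytest.approx(1.0)

    def test_hwe_null_mean_zero(self, hwe_panel):
        f = genomic_inbreeding(hwe_panel)
        assert f["F_het"].mean() == pytest.approx(0.0, abs=0.02)

    def test_low_confidence_flag(self, genotype_factory):
        calls = np.full((2, 120), 1, dtype=np.int8)
        calls[1, 60:] = MISSING
        calls[0, 0] = 0
        calls[1, 1] = 2
        gm = genotype_factory(calls)
        f = genomic_inbreeding(gm, min_snps=100)
        assert not f["low_confidence"].iloc[0]
        assert f["low_confidence"].iloc[1]

    def test_full_sib_offspring_mean_quarter(self):
        """Mean excess homozygosity of full-sib offspring approaches the
        pedigree expectation F = 0.25 (50 replicates, free recombination)."""
        rng = np.random.default_rng(9)
        m = 2000
        p = rng.uniform(0.1, 0.9, size=m)
        background = rng.binomial(2, p, size=(200, m)).astype(np.int8)
        offspring = []
        for _ in range(50):
            gp = rng.binomial(1, p, size=(4, m)).astype(np.int8)  # grandparent haps x2
            gp2 = rng.binomial(1, p, size=(4, m)).astype(np.int8)
            sire = np.stack([gp[rng.integers(0, 2, m), np.arange(m)],
                             gp2[rng.integers(0, 2, m), np.arange(m)]])
            dam = np.stack([gp[rng.integers(0, 2, m), np.arange(m)],
                            gp2[rng.integers(0, 2, m), np.arange(m)]])
            child = sire[rng.integers(0, 2, m), np.arange(m)] + dam[
                rng.integers(0, 2, m), np.arange(m)
            ]
            offspring.append(child.astype(np.int8))
        calls = np.vstack([np.array(offspring), background])
        variants = pd.DataFrame(
            {"chrom": "1", "snp": [f"s{j}" for j in range(m)],
             "bp": np.arange(1, m + 1) * 1000, "a1": "A", "a2": "B"}
        )
        samples = pd.DataFrame(
            {"id": [f"I{i}" for i in range(len(calls))], "breed": "ALP",
             "country": "FRA", "birth_year": 2000}
        )
        from caprilink.genotypes import GenotypeMatrix

        gm = GenotypeMatrix(calls=calls, variants=variants, samples=samples)
        f = genomic_inbreeding(gm)
        assert f["F_het"].iloc[:50].mean() == pytest.approx(0.25, abs=0.05)

    def test_group_ranking_matches_pedigree_f(self):
        """Groups mated at increasing kinship rank identically under the
        genomic and the pedigree estimator (Spearman > 0 on 4 designs)."""
        rng = np.random.default_rng(12)
        m = 1500
        p = rng.uniform(0.2, 0.8, size=m)

        def mate(h1, h2):
            return np.stack(
                [h1[rng.integers(0, 2, m), np.arange(m)],
                 h2[rng.integers(0, 2, m), np.arange(m)]]
            )

        ped_rows, calls, labels = [], [], []
        f_ped_groups = {}
        for g, design in enumerate(["unrelated", "halfsib", "fullsib", "self"]):
            for rep in range(25):
                tag = f"{design}{rep}"
                A = np.stack([rng.binomial(1, p), rng.binomial(1, p)])
                B = np.stack([rng.binomial(1, p), rng.binomial(1, p)])
                C = np.stack([rng.binomial(1, p), rng.binomial(1, p)])
                sire = mate(A, B)
                if design == "unrelated":
                    dam = np.stack([rng.binomial(1, p), rng.binomial(1, p)])
                    rows = [(f"{tag}S", "", ""), (f"{tag}D", "", "")]
                elif design == "halfsib":
                    dam = mate(A, C)
                    rows = [
                        (f"{tag}A", "", ""), (f"{tag}B", "", ""), (f"{tag}C", "", ""),
                        (f"{tag}S", f"{tag}A", f"{tag}B"),
                        (f"{tag}D", f"{tag}A", f"{tag}C"),
                    ]
                elif design == "fullsib":
                    dam = mate(A, B)
                    rows = [
                        (f"{tag}A", "", ""), (f"{tag}B", "", ""),
                        (f"{tag}S", f"{tag}A", f"{tag}B"),
                        (f"{tag}D", f"{tag}A", f"{tag}B"),
                    ]
                else:  # selfing
                    dam = sire
                    rows = [
                        (f"{tag}A", "", ""), (f"{tag}B", "", ""),
                        (f"{tag}S", f"{tag}A", f"{tag}B"),
                    ]
                if design == "unrelated":
                    ped_rows += [dict(id=r[0], sire="", dam="", sex="M") for r in rows]
                else:
                    ped_rows += [dict(id=r[0], sire=r[1], dam=r[2], sex="M") for r in rows]
                child = mate(sire, dam).sum(axis=0)
                dam_id = f"{tag}S" if design == "self" else f"{tag}D"
                ped_rows.append(dict(id=f"{tag}X", sire=f"{tag}S", dam=dam_id, sex="F"))
                calls.append(child.astype(np.int8))
                labels.append(design)
        fped = pedigree_inbreeding(
            Pedigree(df=pd.DataFrame(ped_rows), country="FRA")
        ).set_index("id")["F"]
        background = rng.binomial(2, p, size=(200, m)).astype(np.int8)
        all_calls = np.vstack([np.array(calls), background])
        variants = pd.DataFrame(
            {"chrom": "1", "snp": [f"s{j}" for j in range(m)],
             "bp": np.arange(1, m + 1) * 1000, "a1": "A", "a2": "B"}
        )
        samples = pd.DataFrame(
            {"id": [f"X{i}" for i in range(len(all_calls))], "breed": "ALP",
             "country": "FRA", "birth_year": 2000}
        )
        from caprilink.genotypes import GenotypeMatrix

        gm = GenotypeMatrix(calls=all_calls, variants=variants, samples=samples)
        fhet = genomic_inbreeding(gm)["F_het"].iloc[: len(labels)]
        ped_means = [
            np.mean([fped[f"{d}{r}X"] for r in range(25)])
            for d in ["unrelated", "halfsib", "fullsib", "self"]
        ]
        gen_means = [
            np.mean([fhet.iloc[i] for i, l in enumerate(labels) if l == d])
            for d in ["unrelated", "halfsib", "fullsib", "self"]
        ]
        rho, _ = spearmanr(ped_means, gen_means)
        assert rho > 0


class TestAdmixture:
    def test_k1_closed_form(self, two_pop_panel):
        gm, _ = two_pop_panel
        fit = admixture_em(gm, 1)
        assert np.all(fit.q == 1.0)
        assert np.allclose(
            fit.p_anc[0], np.clip(gm.allele_freq(), 0.01, 0.99), atol=1e-12
        )

    def test_loglik_monotone_and_rows_stochastic(self, two_pop_panel):
        gm, _ = two_pop_panel
        fit = admixture_em(gm, 2, seed=3, max_iter=120)
        trace = np.array(fit.loglik_trace)
        assert (np.diff(trace) >= -1e-6).all()
        assert np.allclose(fit.q.sum(axis=1), 1.0, atol=1e-12)
        assert fit.p_anc.min() >= 0.01 and fit.p_anc.max() <= 0.99

    def test_label_permutation_leaves_likelihood_unchanged(self, two_pop_panel):
        gm, _ = two_pop_panel
        fit = admixture_em(gm, 2, seed=3, max_iter=60)
        obs = gm.calls != MISSING
        g = np.where(obs, gm.calls, 0).astype(float)
        ll = _admixture_loglik(g, obs, fit.q, fit.p_anc)
        ll_perm = _admixture_loglik(g, obs, fit.q[:, ::-1], fit.p_anc[::-1])
        assert ll == pytest.approx(ll_perm, abs=1e-8)

    def test_q_recovers_truth_small_scale(self):
        gm, truth = simulate_admixture_panel(40, 800, 0.2, 2, seed=2)
        fit = admixture_em(gm, 2, seed=2, max_iter=500)
        q = align_q_to_truth(fit.q, truth)
        assert np.abs(q - truth).mean() < 0.05

    def test_invalid_k(self, two_pop_panel):
        gm, _ = two_pop_panel
        with pytest.raises(ValueError):
            admixture_em(gm, 0)
        with pytest.raises(ValueError):
            admixture_em(gm, gm.n_samples + 1)


class TestChooseK:
    def test_single_value_grid(self):
        gm, _ = simulate_admixture_panel(20, 200, 0.2, 2, seed=4)
        table, best = choose_k(gm, [3], cv_folds=2, seed=4, max_iter=50, tol=1e-1)
        assert best == 3
        assert list(table["k"]) == [3]

    def test_oversized_k_skipped(self):
        gm, _ = simulate_admixture_panel(5, 100, 0.2, 2, seed=4)
        table, best = choose_k(
            gm, [2, 50], cv_folds=2, seed=4, max_iter=30, tol=1e-1
        )
        assert list(table["k"]) == [2]

    def test_homogeneous_population_prefers_small_k(self):
        """No structure to reward: cross-validation error grows with k."""
        gm, _ = simulate_admixture_panel(60, 500, 0.1, 1, seed=7)
        table, best = choose_k(
            gm, range(2, 6), cv_folds=3, seed=7, max_iter=150, tol=1e-2
        )
        errs = table["cv_error"].to_numpy()
        assert (np.diff(errs) > 0).all()
        assert best == 2
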
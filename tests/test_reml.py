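import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from dairyfert import reml
from dairyfert.dataprep import ModelSpec, TraitDataset
from dairyfert.pedigree import Pedigree, a_inverse, a_matrix
from dairyfert.reml import (
    MixedModelError,
    REMLOptions,
    VarianceComponents,
    build_mme,
    estimate_reml,
    heritability,
    reml_loglik,
    solve_blup,
)

LOG2PI = np.log(2 * np.pi)


def make_ds(animal_ids, y, fixed=None, hy=None, ss=None, trait="AFC", stage="heifer"):
    n = len(y)
    return TraitDataset(
        trait=trait,
        stage=stage,
        animal_ids=np.asarray(animal_ids, dtype=object),
        y=np.asarray(y, dtype=float),
        records=pd.DataFrame({"animal_id": animal_ids}),
        fixed={} if fixed is None else {k: np.asarray(v, dtype=object) for k, v in fixed.items()},
        hy_labels=None if hy is None else np.asarray(hy, dtype=object),
        ss_ids=None if ss is None else np.asarray(ss, dtype=object),
    )


@pytest.fixture
def founder_trio():
    ped = Pedigree.from_triples([(a, None, None) for a in "ABC"])
    ds = make_ds(list("ABC"), [1.0, 2.0, 6.0])
    return ped, ds


SPEC_A = ModelSpec("AFC", "heifer", (), ("a",))
SPEC_HYA = ModelSpec("AFC", "heifer", (), ("HY", "a"))


class TestMME:
    def test_unrelated_animals_mme_is_ols_plus_ridge(self, founder_trio):
        """Single mean, three unrelated animals: C = [[3, 1'],[1, I(1+lam)]]."""
        ped, ds = founder_trio
        ai = a_inverse(ped)
        lam = 4.0
        mme = build_mme(ds, SPEC_A, ai, theta={"a": 1.0, "e": lam})
        C = mme.C.toarray()
        expected = np.block(
            [[np.array([[3.0]]), np.ones((1, 3))],
             [np.ones((3, 1)), np.eye(3) + lam * np.eye(3)]]
        )
        assert np.allclose(C, expected)
        assert np.allclose(mme.rhs, [9.0, 1.0, 2.0, 6.0])

    def test_trio_pedigree_matches_dense_assembly_from_definition(self, trio):
        ds = make_ds(["A", "B", "C"], [3.0, 4.0, 9.0])
        ai = a_inverse(trio)
        theta = {"a": 2.0, "e": 5.0}
        mme = build_mme(ds, SPEC_A, ai, theta=theta)
        X = np.ones((3, 1))
        Z = np.zeros((3, 3))
        for r, a in enumerate(["A", "B", "C"]):
            Z[r, trio.index(a)] = 1.0
        lam = theta["e"] / theta["a"]
        Ainv = np.linalg.inv(a_matrix(trio).values)
        expected = np.block([[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + lam * Ainv]])
        assert np.abs(mme.C.toarray() - expected).max() < 1e-10

    def test_extreme_shrinkage_sends_ebvs_to_zero(self, founder_trio):
        ped, ds = founder_trio
        ai = a_inverse(ped)
        mme = build_mme(ds, SPEC_A, ai, theta={"a": 1e-10, "e": 1.0})
        sol = solve_blup(mme)
        assert max(abs(v) for v in sol["a"].values()) < 1e-8

    def test_balanced_one_way_fixed_solutions_are_group_means(self):
        ped = Pedigree.from_triples([(f"A{i}", None, None) for i in range(6)])
        ai = a_inverse(ped)
        spec = ModelSpec("AFC", "heifer", ("RYM",), ("a",))
        ds = make_ds(
            [f"A{i}" for i in range(6)],
            [1.0, 2.0, 3.0, 7.0, 8.0, 9.0],
            fixed={"RYM": ["g1"] * 3 + ["g2"] * 3},
        )
        mme = build_mme(ds, spec, ai, theta={"a": 1e-9, "e": 1.0})
        sol = solve_blup(mme)
        assert sol["fixed"]["RYM"]["g1"] == pytest.approx(2.0, abs=1e-6)
        assert sol["fixed"]["RYM"]["g2"] == pytest.approx(8.0, abs=1e-6)

    def test_parent_of_good_offspring_gets_positive_ebv(self):
        rng = np.random.default_rng(0)
        triples = [("S", None, None), ("S2", None, None)] + [
            (f"D{i}", "S" if i < 10 else "S2", None) for i in range(20)
        ]
        ped = Pedigree.from_triples(triples)
        y = np.concatenate([rng.normal(5, 1, 10), rng.normal(-5, 1, 10)])
        ds = make_ds([f"D{i}" for i in range(20)], y)
        ai = a_inverse(ped)
        mme = build_mme(ds, SPEC_A, ai, theta={"a": 2.0, "e": 2.0})
        sol = solve_blup(mme)
        assert sol["a"]["S"] > 0 > sol["a"]["S2"]
        # oracle: dense solve of the same system
        dense = np.linalg.solve(mme.C.toarray(), mme.rhs)
        assert np.allclose(dense, sol["solution"], atol=1e-8)

    def test_record_permutation_leaves_solutions_unchanged(self, trio):
        ds = make_ds(["A", "B", "C"], [3.0, 4.0, 9.0])
        perm = [2, 0, 1]
        ds2 = make_ds([ds.animal_ids[i] for i in perm], ds.y[perm])
        ai = a_inverse(trio)
        theta = {"a": 2.0, "e": 5.0}
        s1 = solve_blup(build_mme(ds, SPEC_A, ai, theta=theta))
        s2 = solve_blup(build_mme(ds2, SPEC_A, ai, theta=theta))
        assert s1["a"] == pytest.approx(s2["a"])

    def test_empty_dataset_rejected(self, trio):
        ds = make_ds([], [])
        with pytest.raises(MixedModelError, match="empty"):
            build_mme(ds, SPEC_A, a_inverse(trio), theta={"a": 1.0, "e": 1.0})


class TestRestrictedLikelihood:
    def test_mean_model_matches_closed_form(self):
        """No random effects: -2lR = (n-1)(log 2pi + log s2) + log n + RSS/s2."""
        rng = np.random.default_rng(1)
        y = rng.normal(5, 2, 30)
        eng = reml._REMLEngine(y, sp.csr_matrix(np.ones((30, 1))), [])
        for s2 in (1.0, 4.0, 10.0):
            rss = ((y - y.mean()) ** 2).sum()
            expected = (29) * (LOG2PI + np.log(s2)) + np.log(30) + rss / s2
            assert eng.neg2ll({"e": s2}) == pytest.approx(expected, rel=1e-10)

    def dense_neg2ll(self, y, X, V):
        Vi = np.linalg.inv(V)
        XVX = X.T @ Vi @ X
        P = Vi - Vi @ X @ np.linalg.inv(XVX) @ X.T @ Vi
        n, p = X.shape
        return (
            (n - p) * LOG2PI
            + np.linalg.slogdet(V)[1]
            + np.linalg.slogdet(XVX)[1]
            + float(y @ P @ y)
        )

    def test_matches_dense_v_computation_on_n20(self):
        rng = np.random.default_rng(2)
        triples = [(f"F{i}", None, None) for i in range(5)] + [
            (f"P{i}", f"F{rng.integers(3)}", f"F{3 + rng.integers(2)}") for i in range(15)
        ]
        ped = Pedigree.from_triples(triples)
        A = a_matrix(ped).values
        ids = list(ped.ids)
        y = rng.normal(0, 2, 20)
        ds = make_ds(ids, y)
        ai = a_inverse(ped)
        X = np.ones((20, 1))
        Z = np.eye(20)[[ped.index(a) for a in ids]]
        vals = []
        for sa, se in [(0.5, 1.0), (1.0, 1.0), (2.0, 0.5), (0.1, 3.0)]:
            V = sa * Z @ A @ Z.T + se * np.eye(20)
            dense = self.dense_neg2ll(y, X, V)
            ours = -2.0 * reml_loglik({"a": sa, "e": se}, ds, SPEC_A, ai)
            assert ours == pytest.approx(dense, rel=1e-9)
            vals.append((dense, ours))
        # identical ordering of candidate points follows from equality
        assert np.argsort([v[0] for v in vals]).tolist() == np.argsort(
            [v[1] for v in vals]
        ).tolist()

    def test_invariant_to_fixed_effect_reparameterization(self, trio):
        ds = make_ds(["A", "B", "C"], [3.0, 4.0, 9.0], fixed={"RYM": ["x", "x", "x"]})
        spec1 = ModelSpec("AFC", "heifer", ("RYM",), ("a",))
        ai = a_inverse(trio)
        l1 = reml_loglik({"a": 1.0, "e": 2.0}, ds, spec1, ai)
        l2 = reml_loglik({"a": 1.0, "e": 2.0}, ds, SPEC_A, ai)
        assert l1 == pytest.approx(l2, rel=1e-10)


class TestEstimation:
    def small_sim(self, seed=0, n_fam=30, fam=6, sa=4.0, shy=2.0, se=6.0):
        rng = np.random.default_rng(seed)
        triples = [(f"S{i}", None, None) for i in range(n_fam)]
        ids, y, hy = [], [], []
        bv_s = rng.normal(0, np.sqrt(sa), n_fam)
        hy_eff = rng.normal(0, np.sqrt(shy), 10)
        for i in range(n_fam):
            for j in range(fam):
                a = f"D{i}_{j}"
                triples.append((a, f"S{i}", None))
                h = rng.integers(10)
                ids.append(a)
                hy.append(f"H{h}")
                mend = rng.normal(0, np.sqrt(0.75 * sa))
                y.append(0.5 * bv_s[i] + mend + hy_eff[h] + rng.normal(0, np.sqrt(se)))
        ped = Pedigree.from_triples(triples)
        return ped, make_ds(ids, y, hy=hy)

    def test_em_warm_start_never_decreases_likelihood(self):
        ped, ds = self.small_sim()
        vc = estimate_reml(ds, SPEC_HYA, a_inverse(ped))
        em_lls = [v for tag, v in vc.trace if tag in ("start", "em")]
        assert len(em_lls) >= 2
        assert all(b <= a + 1e-6 * abs(a) for a, b in zip(em_lls, em_lls[1:]))

    def test_optimum_beats_grid_and_matches_dense_polish(self):
        """On a tiny instance the optimizer must beat a surrounding grid."""
        rng = np.random.default_rng(5)
        ped = Pedigree.from_triples(
            [(f"S{i}", None, None) for i in range(5)]
            + [(f"D{i}", f"S{i % 5}", None) for i in range(20)]
        )
        ids = [f"D{i}" for i in range(20)]
        bv = rng.normal(0, 1.0, 5)
        y = [bv[i % 5] * 0.5 + rng.normal(0, 1.5) for i in range(20)]
        ds = make_ds(ids, y)
        ai = a_inverse(ped)
        vc = estimate_reml(ds, SPEC_A, ai)
        best = -2.0 * reml_loglik(vc, ds, SPEC_A, ai)
        var_p = np.var(ds.y, ddof=1)
        grid = np.linspace(0.05, 1.2, 10) * var_p
        for sa in grid:
            for se in grid:
                assert best <= -2.0 * reml_loglik({"a": sa, "e": se}, ds, SPEC_A, ai) + 1e-6

    def test_balanced_one_way_matches_anova_estimators(self):
        """Random HY only: REML on balanced data equals the EMS method."""
        rng = np.random.default_rng(3)
        q, m = 12, 6
        hy_eff = rng.normal(0, 2.0, q)
        y = np.array([hy_eff[i] + rng.normal(0, 1.5) for i in range(q) for _ in range(m)])
        groups = y.reshape(q, m)
        msb = m * groups.mean(axis=1).var(ddof=1)
        msw = groups.var(axis=1, ddof=1).mean()
        exp_hy = (msb - msw) / m
        Z = sp.csr_matrix(
            (np.ones(q * m), (np.arange(q * m), np.repeat(np.arange(q), m)))
        )
        term = reml._RandomTerm("HY", Z, sp.identity(q, format="csc"), 0.0, q, tuple(range(q)))
        eng = reml._REMLEngine(y, sp.csr_matrix(np.ones((q * m, 1))), [term])
        vc = reml._estimate(eng, REMLOptions())
        theta_hy = vc.sigma2_hy if vc.sigma2_hy is not None else 0.0
        assert vc.sigma2_e == pytest.approx(msw, rel=1e-4)
        assert theta_hy == pytest.approx(exp_hy, rel=1e-3)

    def test_zero_additive_variance_floored_and_flagged(self):
        # seeded draw whose likelihood prefers sigma_a^2 <= 0, so the
        # floor-and-flag path must engage (truth sigma_a^2 = 0)
        rng = np.random.default_rng(0)
        ped = Pedigree.from_triples(
            [(f"S{i}", None, None) for i in range(10)]
            + [(f"D{i}", f"S{i % 10}", None) for i in range(120)]
        )
        ids = [f"D{i}" for i in range(120)]
        y = rng.normal(0, 1.0, 120)  # no genetic signal at all
        ds = make_ds(ids, y)
        vc = estimate_reml(ds, SPEC_A, a_inverse(ped))
        assert "a" in vc.floored
        assert vc.sigma2_a <= 1e-6 * np.var(y)
        assert vc.h2 == pytest.approx(0.0, abs=1e-6)
        assert vc.se["a"] > 0  # SE still reported for the floored component

    def test_estimates_invariant_to_record_order(self):
        ped, ds = self.small_sim(seed=7, n_fam=12, fam=5)
        rng = np.random.default_rng(0)
        perm = rng.permutation(ds.n)
        ds2 = make_ds(ds.animal_ids[perm], ds.y[perm], hy=ds.hy_labels[perm])
        ai = a_inverse(ped)
        vc1 = estimate_reml(ds, SPEC_HYA, ai)
        vc2 = estimate_reml(ds2, SPEC_HYA, ai)
        assert vc1.sigma2_a == pytest.approx(vc2.sigma2_a, rel=1e-6, abs=1e-9)
        assert vc1.sigma2_e == pytest.approx(vc2.sigma2_e, rel=1e-6)


class TestHeritability:
    def test_all_additive_gives_one(self):
        assert heritability(sigma2_a=5.0, sigma2_e=0.0)[0] == 1.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            heritability(sigma2_a=0.0, sigma2_e=0.0)

    def test_service_sire_term_enters_denominator_only_when_present(self):
        with_ss, _ = heritability(sigma2_a=1.0, sigma2_e=3.0, sigma2_ss=1.0)
        without, _ = heritability(sigma2_a=1.0, sigma2_e=3.0)
        assert with_ss == pytest.approx(0.2)
        assert without == pytest.approx(0.25)

    def test_delta_method_se_from_ai_covariance(self):
        vc = VarianceComponents(
            sigma2_a=2.0, sigma2_e=6.0,
            cov=np.diag([0.5, 0.8]), names=("a", "e"),
        )
        h2, se = heritability(vc)
        assert h2 == pytest.approx(0.25)
        g = np.array([6.0 / 64.0, -2.0 / 64.0])
        assert se == pytest.approx(np.sqrt(g @ np.diag([0.5, 0.8]) @ g))


def test_results_csv_and_run_log_export(tmp_path):
    vc = VarianceComponents(
        sigma2_a=2.0, sigma2_e=6.0, sigma2_hy=1.0,
        se={"a": 0.5, "HY": 0.3, "e": 0.4}, h2=0.2222, h2_se=0.05,
        n_iter=12, neg2ll=123.4, trace=[("em", 125.0), ("ai", 123.4)],
    )
    csv_path = tmp_path / "table.csv"
    reml.write_results_csv({"AFC (heifer)": vc}, csv_path)
    row = pd.read_csv(csv_path).iloc[0]
    assert row["sigma2_a"] == "2.0000 (0.5000)"
    assert row["h2"] == "0.2222 (0.0500)"
    log_path = tmp_path / "run.json"
    reml.write_run_log(vc, log_path)
    import json
    payload = json.loads(log_path.read_text())
    assert payload["trace"] == [["em", 125.0], ["ai", 123.4]]
    assert payload["components"]["a"] == 2.0
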
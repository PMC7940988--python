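"""Dyadic dataset construction and the social relations model."""

import datetime as dt
import warnings

import numpy as np
import pytest
from scipy import integrate, stats

from cofeed.demography import Demography, DemographyTable, ValidationError
from cofeed.sampler import SamplerSettings
from cofeed.srm import (
    SRMSpec,
    SocialRelationsModel,
    build_dyadic_dataset,
    dyad_categories,
    simulate_srm_observations,
    srm_summary,
)
from .conftest import make_individual, make_session


def adult(id, sex="female"):
    return make_individual(id, sex, dt.date(1995, 3, 1), entry=dt.date(2005, 1, 1))


@pytest.fixture
def three_adults():
    table = DemographyTable("g1", (adult("A"), adult("B"), adult("C", "male")))
    return Demography({"g1": table})


class TestBuildDataset:
    def test_single_scan_coresidence_is_pairwise_and(self, three_adults):
        s = make_session(counts=(2,), n_at_risk=3,
                         identities=(frozenset({"A", "B"}),))
        obs = build_dyadic_dataset([s], three_adults)
        got = {}
        for r in range(len(obs.dyad_y)):
            d = obs.dyad_block_of[r]
            i, j = obs.dyads[d]
            got[(obs.ids[i], obs.ids[j])] = int(obs.dyad_y[r])
        assert got == {("A", "B"): 1, ("A", "C"): 0, ("B", "C"): 0}

    def test_record_counts_follow_combinatorics(self, three_adults):
        n_scans = 4
        sessions = [
            make_session(counts=(1,) * n_scans, n_at_risk=3,
                         identities=(frozenset({"A"}),) * n_scans)
        ]
        obs = build_dyadic_dataset(sessions, three_adults)
        assert obs.n_individual_obs == n_scans * 3
        assert obs.n_dyadic_obs == n_scans * 3  # 3 choose 2 = 3 dyads per scan

    def test_random_fixtures_match_brute_force_oracle(self, rng, three_adults):
        ids = ["A", "B", "C"]
        scans = []
        for _ in range(25):
            k = int(rng.integers(0, 4))
            scans.append(frozenset(rng.choice(ids, size=k, replace=False).tolist()))
        s = make_session(counts=tuple(len(x) for x in scans), n_at_risk=3,
                         identities=tuple(scans))
        # strictly increasing times for long sessions
        obs = build_dyadic_dataset([s], three_adults)
        # brute force aggregate per dyad
        for d, (i, j) in enumerate(obs.dyads):
            a, b = obs.ids[i], obs.ids[j]
            want = sum(1 for x in scans if a in x and b in x)
            got = int(obs.dyad_y[obs.dyad_block_of == d].sum())
            assert got == want
        for k, ind in enumerate(obs.ids):
            want = sum(1 for x in scans if ind in x)
            assert int(obs.ind_y[obs.ind_block_of == k].sum()) == want

    def test_unknown_identity_names_id_and_date(self, three_adults):
        s = make_session(counts=(1,), n_at_risk=3, identities=(frozenset({"ZZ"}),))
        with pytest.raises(ValidationError, match="ZZ"):
            build_dyadic_dataset([s], three_adults)

    def test_construction_is_deterministic_and_idempotent(self, rng, three_adults):
        scans = tuple(
            frozenset(rng.choice(["A", "B", "C"], size=2, replace=False).tolist())
            for _ in range(6)
        )
        s = make_session(counts=(2,) * 6, n_at_risk=3, identities=scans)
        a = build_dyadic_dataset([s], three_adults)
        b = build_dyadic_dataset([s], three_adults)
        np.testing.assert_array_equal(a.dyad_y, b.dyad_y)
        np.testing.assert_array_equal(a.ind_X, b.ind_X)
        assert a.ids == b.ids and a.dyad_cat_labels == b.dyad_cat_labels

    def test_dyad_categories_cross_infant_status_with_male_age(self):
        fem = ("female", "adult_13plus", True)
        male = ("male", "juvenile_5_8", False)
        assert dyad_categories(fem, male) == {"female_with_infant*male_juvenile_5_8": 1.0}
        assert dyad_categories(male, fem) == dyad_categories(fem, male)  # symmetric
        assert dyad_categories(fem, ("female", "adult_13plus", False)) == {}


class TestHypergeometricCalibration:
    def test_equal_weight_coresidence_matches_sampling_identity(self, rng):
        """With flat weights, P(i and j both drawn) = E[k(k-1)] / (n(n-1))."""
        from cofeed.simulate import (
            ClassPropensities, SimConfig, generate_identities, simulate_study,
        )

        cfg = SimConfig(
            n_groups=1, years=(2015,), group_size_ranges=((10, 10),),
            pct_female_bands=((0.3, 0.8),), kin_link_p=(0.5,),
            sessions_per_group_year=300, n_scans=4, seed=6,
            alpha=0.0, sigma_g=0.0, sigma_gy=0.0, exclude_infants_from_risk=False,
        )
        dem, cov, sessions, _ = simulate_study(cfg)
        with_ids = generate_identities(sessions, dem, ClassPropensities(),
                                       np.random.default_rng(3), exclude_infants=False)
        n = sessions[0].n_at_risk
        co = 0
        scans = 0
        expect = 0.0
        pair = None
        for s in with_ids:
            for ids, k in zip(s.identities, s.counts):
                if pair is None:
                    pair = tuple(sorted(ids))[:2] if k >= 2 else None
                scans += 1
                expect += k * (k - 1) / (n * (n - 1))
                if pair and pair[0] in ids and pair[1] in ids:
                    co += 1
        rate = co / scans
        want = expect / scans
        se = np.sqrt(want * (1 - want) / scans)
        assert abs(rate - want) < 4 * se


class TestMarginalLikelihoodOracle:
    def test_quadrature_matches_numerical_integration(self, rng):
        """GH-marginalized dyad likelihood agrees with adaptive quadrature."""
        obs, _ = simulate_srm_observations(n_individuals=5, n_scans=8, seed=2)
        model = SocialRelationsModel(obs)
        core = model._coresidence
        P = 0.3 * rng.standard_normal((3, core.ndim))
        got = core.marginal_loglik(P)
        for w in range(P.shape[0]):
            mu, cc, log_sap, log_sd, z = core.unpack(P[w:w + 1])
            ap = np.exp(log_sap[0, 0]) * z[0]
            sd = np.exp(log_sd[0, 0])
            total = 0.0
            for d, (i, j) in enumerate(obs.dyads):
                rows = np.flatnonzero(obs.dyad_block_of == d)
                eta0 = (mu[0, 0] + obs.dyad_X[rows] @ cc[0] + ap[i] + ap[j])

                def f(x, eta0=eta0, rows=rows):
                    p = 1 / (1 + np.exp(-(eta0 + x)))
                    lik = np.prod(
                        p ** obs.dyad_y[rows]
                        * (1 - p) ** (obs.dyad_trials[rows] - obs.dyad_y[rows])
                    )
                    return lik * stats.norm.pdf(x, 0, sd)

                val, _ = integrate.quad(f, -8 * sd, 8 * sd)
                total += np.log(val)
            comb = np.sum(
                np.log(stats.binom(obs.dyad_trials, 0.5).pmf(obs.dyad_y))
                - obs.dyad_trials * np.log(0.5)
            )
            # 21-node Gauss-Hermite truncation leaves ~1e-4 absolute error
            assert got[w] == pytest.approx(total + comb, abs=5e-3, rel=1e-3)


class TestFit:
    def test_too_few_individuals_rejected(self):
        obs, _ = simulate_srm_observations(n_individuals=2, n_scans=10, seed=0)
        with pytest.raises(ValidationError, match="3 individuals"):
            SocialRelationsModel(obs)

    def test_degenerate_outcomes_warn(self):
        obs, _ = simulate_srm_observations(
            n_individuals=5, n_scans=10, intercept_presence=-30.0,
            intercept_coresidence=-30.0, sigma_a=0.0, sigma_a_prime=0.0,
            sigma_d=0.0, seed=1,
        )
        with pytest.warns(UserWarning, match="degenerate"):
            SocialRelationsModel(obs)

    @pytest.fixture(scope="class")
    def small_fit(self):
        obs, truth = simulate_srm_observations(n_individuals=12, n_scans=40, seed=7)
        spec = SRMSpec(sampler=SamplerSettings(warmup=500, steps=400, seed=3),
                       gh_nodes=15)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return srm_summary(SocialRelationsModel(obs, spec=spec).fit()), obs

    def test_summary_intervals_match_percentile_oracle(self, small_fit):
        summary, obs = small_fit
        assert (summary["lower"] <= summary["median"]).all()
        assert (summary["median"] <= summary["upper"]).all()

    def test_summary_counts_equal_input_tabulation(self, small_fit):
        summary, obs = small_fit
        counts = obs.category_counts().set_index(["effect", "category"])["n_obs"]
        for _, row in summary.iterrows():
            assert row["n_obs"] == counts.loc[(row["effect"], row["category"])]

    def test_rows_clustered_by_age_category(self, small_fit):
        summary, _ = small_fit
        pres = summary[summary["effect"] == "presence"]
        order = {"infant_lt3": 0, "young_3_4": 1, "juvenile_5_8": 2,
                 "adolescent_9_12": 3, "adult_13plus": 4, "other": 5}
        ranks = pres["age_class"].map(order).to_numpy()
        assert (np.diff(ranks) >= 0).all()
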
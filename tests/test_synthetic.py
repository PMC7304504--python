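import numpy as np
import pandas as pd
import pytest

from cattletemp.pedigree import build_A, validate_pedigree
from cattletemp.synthetic import (
    QBA_TRAITS,
    FixedEffectsSpec,
    GeneticArchitecture,
    MeasurementModelSpec,
    default_genetic_correlations,
    simulate_breeding_values,
    simulate_fpss_trace,
    simulate_measurement_observations,
    simulate_pedigree,
    simulate_phenotypes,
)


class TestArchitecture:
    def test_default_correlations_positive_definite_with_unit_diagonal(self):
        R = default_genetic_correlations()
        assert np.allclose(np.diag(R), 1.0)
        assert np.linalg.eigvalsh(R).min() > 0
        assert R[0, 1] == -0.92  # difficult-easy

    def test_covariances_consistent_with_heritability(self):
        arch = GeneticArchitecture()
        total = np.diag(arch.Sigma_u) + np.diag(arch.Sigma_e)
        np.testing.assert_allclose(total, arch.phenotypic_variances)
        np.testing.assert_allclose(
            np.diag(arch.Sigma_u) / total, arch.heritabilities)

    def test_invalid_heritability_rejected(self):
        with pytest.raises(ValueError, match="heritabilit"):
            GeneticArchitecture(heritabilities=np.array([0.4, 1.2, 0.3, 0.2, 0.2]))

    def test_measurement_specific_variances_complement_loadings(self):
        spec = MeasurementModelSpec()
        lam = np.array([spec.loadings[t][1] for t in spec.trait_names])
        np.testing.assert_allclose(spec.specific_variances, 1 - lam**2)
        assert np.all(spec.structure.sum(axis=1) == 1)  # no cross-loading


class TestSimulatePedigree:
    def test_forced_trio(self):
        ped = simulate_pedigree(2, 1, 1, 1, seed=0)
        assert len(ped) == 3
        assert set(ped.sire_ids[2:] + ped.dam_ids[2:]) == {"G0_0000", "G0_0001"}

    def test_counts_and_known_parents(self):
        ped = simulate_pedigree(200, 3, 100, 2, seed=1)
        assert len(ped) == 200 + 3 * 200
        founders = ped.is_founder()
        assert founders.sum() == 200
        par = ped.parent_indices()
        assert np.all(par[~founders] >= 0)

    def test_single_founder_rejected(self):
        with pytest.raises(ValueError):
            simulate_pedigree(1, 1, 1, 1, seed=0)

    def test_output_topologically_valid(self):
        ped = simulate_pedigree(5, 3, 6, 2, seed=3)
        # independent re-validation sorts and checks for cycles
        revalidated = validate_pedigree(
            list(zip(ped.animal_ids, ped.sire_ids, ped.dam_ids)))
        assert set(revalidated.animal_ids) == set(ped.animal_ids)
        order = {a: i for i, a in enumerate(ped.animal_ids)}
        for a, s, d in zip(ped.animal_ids, ped.sire_ids, ped.dam_ids):
            for p in (s, d):
                if p != "0":
                    assert order[p] < order[a]


class TestBreedingValues:
    def test_founder_covariance_is_sigma_u(self):
        ped = validate_pedigree([(f"f{i}", "0", "0") for i in range(2)])
        Su = np.array([[1.0, 0.5], [0.5, 1.0]])
        reps = np.array([simulate_breeding_values(ped, Su, seed=i)[0]
                         for i in range(6000)])
        np.testing.assert_allclose(np.cov(reps, rowvar=False), Su, atol=0.08)

    def test_parent_offspring_covariance_half(self):
        ped = validate_pedigree([("s", "0", "0"), ("d", "0", "0"), ("o", "s", "d")])
        reps = np.array([simulate_breeding_values(ped, [[1.0]], seed=i)[:, 0]
                         for i in range(8000)])
        assert np.cov(reps[:, 0], reps[:, 2])[0, 1] == pytest.approx(0.5, abs=0.05)
        assert reps[:, 2].var() == pytest.approx(1.0, abs=0.06)

    def test_covariance_matches_sigma_kron_A(self):
        """Gene-dropping covariance converges to Sigma_u (x) A, including an
        inbred animal and a half-unknown parent."""
        ped = validate_pedigree([
            ("s", "0", "0"), ("d", "0", "0"), ("o1", "s", "d"),
            ("o2", "s", "o1"), ("h", "s", "0"), ("g", "o2", "h"),
        ])
        A = build_A(ped).A
        Su = np.array([[1.0, -0.6], [-0.6, 2.0]])
        rng_seeds = range(6000)
        reps = np.array([simulate_breeding_values(ped, Su, seed=i,
                                                  inbreeding=np.diag(A) - 1)
                         for i in rng_seeds])  # (reps, n, 2)
        n = len(ped)
        flat = reps.transpose(0, 2, 1).reshape(len(reps), 2 * n)  # trait-major
        emp = np.cov(flat, rowvar=False)
        np.testing.assert_allclose(emp, np.kron(Su, A), atol=0.15)

    def test_non_pd_sigma_rejected(self):
        ped = validate_pedigree([("a", "0", "0")])
        with pytest.raises(ValueError, match="positive definite"):
            simulate_breeding_values(ped, [[1.0, 2.0], [2.0, 1.0]], seed=0)


@pytest.fixture(scope="module")
def phen():
    ped = simulate_pedigree(60, 3, 80, 3, seed=21)
    return simulate_phenotypes(ped, seed=21)


class TestPhenotypes:
    def test_observation_scales(self, phen):
        t = phen.table
        assert set(t["ds"]) <= set(range(1, 7))
        assert set(t["ts"]) <= {1, 2, 4, 5}
        for col in QBA_TRAITS:
            assert t[col].between(0, 136).all()
        assert (t["ssd"] > 0).all() and (t["cvssd"] > 0).all()

    def test_phenotypic_sign_pattern(self, phen):
        """The temperament score co-varies positively with negative attributes
        (agitated) and negatively with positive ones (calm, relaxed)."""
        t = phen.table
        assert t["ts"].corr(t["agitated"]) > 0.15
        assert t["ts"].corr(t["calm"]) < -0.15
        assert t["ts"].corr(t["relaxed"]) < -0.15

    def test_near_zero_heritability_removes_family_resemblance(self):
        ped = simulate_pedigree(40, 2, 60, 4, seed=5)
        arch = GeneticArchitecture(
            heritabilities=np.array([0.001] * 5))
        phen = simulate_phenotypes(ped, architecture=arch, seed=5)
        # full sibs share a mating: between-family variance of a trait ~ 0
        fam = pd.Series(
            ["_".join(a.split("_")[:2]) for a in phen.latent.index],
            index=phen.latent.index)
        grouped = phen.latent["difficult"].groupby(fam)
        between = grouped.mean().var()
        within = grouped.var().mean()
        assert between < 0.25 * (between + within) + 0.05

    def test_sex_effect_only_on_cvssd_and_easy(self):
        spec = FixedEffectsSpec()
        fx = spec.sex_effects(["difficult", "easy", "ds", "ssd", "cvssd"])
        assert fx[1] != 0 and fx[4] != 0
        assert fx[0] == fx[2] == fx[3] == 0

    def test_reproducible_from_seed(self):
        ped = simulate_pedigree(10, 1, 10, 2, seed=2)
        a = simulate_phenotypes(ped, seed=9).table
        b = simulate_phenotypes(ped, seed=9).table
        pd.testing.assert_frame_equal(a, b)

    def test_realized_heritability_from_midparent_regression(self):
        """Offspring-on-mid-parent regression of the latent trait recovers h2."""
        arch = GeneticArchitecture()
        slopes = []
        for seed in range(15):
            ped = simulate_pedigree(80, 1, 150, 1, seed=seed)
            phen = simulate_phenotypes(
                ped, architecture=arch, seed=seed,
                fixed_effects=FixedEffectsSpec(year_date_effect_sd=0.0,
                                               sex_effect=0.0))
            lat = phen.latent["difficult"]
            idx = {a: i for i, a in enumerate(ped.animal_ids)}
            kids = [a for a, f in zip(ped.animal_ids, ped.is_founder()) if not f]
            mid = np.array([
                0.5 * (lat.iloc[idx[ped.sire_ids[idx[a]]]]
                       + lat.iloc[idx[ped.dam_ids[idx[a]]]]) for a in kids])
            off = lat.loc[kids].to_numpy()
            slopes.append(np.polyfit(mid, off, 1)[0])
        assert np.mean(slopes) == pytest.approx(0.40, abs=0.06)


class TestMeasurementSimulator:
    def test_trait_scale_and_loading_structure(self):
        T = simulate_measurement_observations(40000, seed=1)
        sd = T.std()
        assert np.allclose(sd, 1.0, atol=0.03)
        # correlation between two same-factor traits equals the loading product
        r = T["agitated"].corr(T["fearful"])
        assert r == pytest.approx(0.937 * 0.840, abs=0.03)

    def test_factor_scores_attached(self):
        T = simulate_measurement_observations(500, seed=2)
        assert T.attrs["factor_scores"].shape == (500, 2)


class TestFPSSTraceSimulator:
    def test_zero_target_ssd_constant_stationary_segment(self):
        tr = simulate_fpss_trace(200.0, 0.0, duration_s=50, entry_transient_s=2,
                                 seed=0)
        stationary = tr.total_weight[2 * 15:]
        assert np.allclose(stationary, 200.0, atol=1e-9)

    def test_stationary_sd_matches_target(self):
        # SE of a sample SD at n~825: ssd/sqrt(2(n-1)) ~ 0.05; allow 3 SEs
        tr = simulate_fpss_trace(200.0, 2.0, duration_s=60, rate_hz=15,
                                 entry_transient_s=5, seed=3)
        stationary = tr.total_weight[5 * 15:]
        se = 2.0 / np.sqrt(2 * (stationary.size - 1))
        assert stationary.std(ddof=1) == pytest.approx(2.0, abs=3 * se)
        assert stationary.mean() == pytest.approx(200.0, abs=3 * 2.0 / np.sqrt(stationary.size))

    def test_row_sums_equal_total_exactly(self):
        tr = simulate_fpss_trace(300.0, 1.5, seed=4)
        np.testing.assert_array_equal(tr.quadrant_weights.sum(axis=1),
                                      tr.total_weight)
        assert np.all(tr.quadrant_weights >= 0)

    def test_short_duration_rejected(self):
        with pytest.raises(ValueError, match="45"):
            simulate_fpss_trace(200.0, 1.0, duration_s=30)
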
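"""MWAS engine: outcome transforms, the per-feature scan against a
statsmodels oracle, permutation MWSL/ENT closed forms, replication logic,
and sentinel selection."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nmrmwas import (
    MWAS,
    ModelSpec,
    SpectrumSet,
    effective_number_of_tests,
    estimate_mwsl,
    mwas_scan,
    replicate_hits,
    select_sentinels,
    transform_outcomes,
)
from nmrmwas.srv import Cluster, ClusterMap

from conftest import latent_block_spectra


def noise_spectra(n_samples, n_features, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_samples, n_features))
    return SpectrumSet(x, np.linspace(1, 2, n_features), "standard1d",
                       [f"s{i}" for i in range(n_samples)])


def pheno_frame(y, seed=0, n_cov=True):
    rng = np.random.default_rng(seed + 1)
    n = len(y)
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "ln_cac1": y,
        "age": rng.normal(60, 10, n),
        "sex": rng.choice(["M", "F"], n),
        "ethnicity": rng.choice(["a", "b", "c"], n),
        "phase": rng.choice(["P1", "P2"], n),
    })


# ---------------------------------------------------------------------
# outcome transforms


def test_transform_outcomes_worked_values():
    pheno = pd.DataFrame({"cac_agatston": [0.0, 100.0], "imt_mm": [1.0, 0.8]})
    out = transform_outcomes(pheno)
    assert out.loc[0, "ln_cac1"] == 0.0
    assert out.loc[1, "ln_cac1"] == pytest.approx(math.log(101), abs=1e-12)
    assert out.loc[0, "log10_imt"] == 0.0
    assert out.loc[1, "log10_imt"] == pytest.approx(math.log10(0.8))


def test_transform_outcomes_rejects_invalid():
    with pytest.raises(ValueError):
        transform_outcomes(pd.DataFrame({"cac_agatston": [-1.0]}))
    with pytest.raises(ValueError):
        transform_outcomes(pd.DataFrame({"imt_mm": [0.0]}))


# ---------------------------------------------------------------------
# per-feature association vs statsmodels (independent route)


def test_scan_matches_statsmodels_ols():
    import statsmodels.api as sm

    rng = np.random.default_rng(5)
    n, m = 120, 6
    sset = noise_spectra(n, m, seed=5)
    y = 0.4 * sset.intensities[:, 2] + rng.standard_normal(n)
    pheno = pheno_frame(y, seed=5)
    res = MWAS(sset, pheno, ModelSpec.model1("ln_cac1")).fit()

    zdf = pd.get_dummies(pheno[["age", "sex", "ethnicity", "phase"]],
                         drop_first=True, dtype=float)
    for j in range(m):
        f = sset.intensities[:, j]
        x = sm.add_constant(zdf.assign(feat=(f - f.mean()) / f.std()))
        fit = sm.OLS(y, x).fit()
        row = res.table.loc[j]
        assert row["beta_per_sd"] == pytest.approx(fit.params["feat"], rel=1e-8)
        assert row["se"] == pytest.approx(fit.bse["feat"], rel=1e-8)
        assert row["p_value"] == pytest.approx(fit.pvalues["feat"], rel=1e-6)


def test_partial_spearman_matches_manual_residual_ranks():
    rng = np.random.default_rng(7)
    n = 150
    sset = noise_spectra(n, 3, seed=7)
    y = sset.intensities[:, 0] + rng.standard_normal(n)
    pheno = pheno_frame(y, seed=7)
    res = MWAS(sset, pheno, ModelSpec.model1("ln_cac1")).fit()

    zdf = pd.get_dummies(pheno[["age", "sex", "ethnicity", "phase"]],
                         drop_first=True, dtype=float)
    z = np.column_stack([np.ones(n), zdf.to_numpy()])
    py = y - z @ np.linalg.lstsq(z, y, rcond=None)[0]
    for j in range(3):
        f = sset.intensities[:, j]
        fs = (f - f.mean()) / f.std()
        pf = fs - z @ np.linalg.lstsq(z, fs, rcond=None)[0]
        rho_manual = stats.spearmanr(py, pf).statistic
        assert res.table.loc[j, "partial_spearman_rho"] == pytest.approx(
            rho_manual, abs=1e-10)


def test_feature_identical_to_outcome_has_rho_one():
    n = 60
    rng = np.random.default_rng(1)
    y = rng.standard_normal(n)
    x = np.column_stack([y, rng.standard_normal(n)])
    sset = SpectrumSet(x, np.array([1.0, 2.0]), "standard1d",
                       [f"s{i}" for i in range(n)])
    pheno = pheno_frame(y, seed=1)
    res = MWAS(sset, pheno, ModelSpec("ln_cac1", ())).fit()
    assert res.table.loc[0, "partial_spearman_rho"] == pytest.approx(1.0)
    assert res.table.loc[0, "p_value"] < 1e-30


def test_scan_equivariance_under_feature_scaling():
    """Standardization makes beta-per-SD, p and rho invariant to positive
    rescaling of a feature."""
    sset = noise_spectra(100, 4, seed=9)
    rng = np.random.default_rng(9)
    y = rng.standard_normal(100)
    pheno = pheno_frame(y, seed=9)
    res1 = MWAS(sset, pheno, ModelSpec.model1("ln_cac1")).fit()
    x2 = sset.intensities.copy()
    x2[:, 1] *= 37.5
    x2[:, 3] *= 0.004
    sset2 = SpectrumSet(x2, sset.ppm, sset.assay, sset.sample_ids)
    res2 = MWAS(sset2, pheno, ModelSpec.model1("ln_cac1")).fit()
    for col in ("beta_per_sd", "p_value", "partial_spearman_rho"):
        np.testing.assert_allclose(res1.table[col], res2.table[col],
                                   rtol=1e-9)


def test_duplicated_feature_gives_identical_results():
    sset = noise_spectra(80, 3, seed=3)
    x = np.column_stack([sset.intensities, sset.intensities[:, 0]])
    sset2 = SpectrumSet(x, np.array([1.0, 2.0, 3.0, 4.0]), "standard1d",
                        sset.sample_ids)
    y = np.random.default_rng(3).standard_normal(80)
    res = MWAS(sset2, pheno_frame(y, seed=3),
               ModelSpec.model1("ln_cac1")).fit()
    for col in ("beta_per_sd", "se", "p_value", "partial_spearman_rho"):
        assert res.table.loc[0, col] == pytest.approx(res.table.loc[3, col],
                                                      rel=1e-12)


def test_constant_feature_yields_skip_record():
    sset = noise_spectra(50, 3, seed=4)
    x = sset.intensities.copy()
    x[:, 1] = 2.0
    sset2 = SpectrumSet(x, sset.ppm, sset.assay, sset.sample_ids)
    y = np.random.default_rng(4).standard_normal(50)
    res = MWAS(sset2, pheno_frame(y, seed=4),
               ModelSpec.model1("ln_cac1")).fit()
    assert res.table.loc[1, "note"] == "constant"
    assert np.isnan(res.table.loc[1, "p_value"])
    assert res.table.loc[0, "note"] == ""


def test_misaligned_sample_ids_rejected():
    sset = noise_spectra(20, 2, seed=0)
    pheno = pheno_frame(np.zeros(20), seed=0)
    pheno["sample_id"] = [f"other{i}" for i in range(20)]
    with pytest.raises(ValueError, match="without phenotype"):
        MWAS(sset, pheno, ModelSpec.model1("ln_cac1"))


def test_event_outcome_rejected_for_linear_scan():
    sset = noise_spectra(20, 2, seed=0)
    with pytest.raises(ValueError, match="cox_association"):
        MWAS(sset, pheno_frame(np.zeros(20)), ModelSpec("event", ()))


# ---------------------------------------------------------------------
# MWSL / ENT


def test_mwsl_single_feature_alpha_prime_near_alpha():
    """With one feature the minimum p IS the p-value: the 5th percentile
    of Uniform(0,1) is ~0.05."""
    sset = noise_spectra(100, 1, seed=21)
    y = np.random.default_rng(21).standard_normal(100)
    mwsl = estimate_mwsl(sset, pheno_frame(y, seed=21),
                         ModelSpec("ln_cac1", ()), n_perm=2000, seed=1)
    assert mwsl.alpha_prime == pytest.approx(0.05, abs=0.02)
    assert 0.5 <= mwsl.ent <= 2.0


def test_mwsl_independent_features_ent_near_m():
    """For M independent features alpha' ~ 1 - 0.95^(1/M), ENT ~ M."""
    m = 100
    sset = noise_spectra(200, m, seed=22)
    y = np.random.default_rng(22).standard_normal(200)
    mwsl = estimate_mwsl(sset, pheno_frame(y, seed=22),
                         ModelSpec("ln_cac1", ()), n_perm=4000, seed=2)
    expected = 1.0 - 0.95 ** (1.0 / m)
    assert mwsl.alpha_prime == pytest.approx(expected, rel=0.35)
    assert mwsl.ent == pytest.approx(m, rel=0.35)


def test_mwsl_totally_duplicated_features_ent_near_one():
    rng = np.random.default_rng(23)
    base = rng.standard_normal(150)
    x = np.tile(base[:, None], (1, 50)) + 1e-9 * rng.standard_normal((150, 50))
    sset = SpectrumSet(x, np.linspace(1, 2, 50), "standard1d",
                       [f"s{i}" for i in range(150)])
    y = rng.standard_normal(150)
    mwsl = estimate_mwsl(sset, pheno_frame(y, seed=23),
                         ModelSpec("ln_cac1", ()), n_perm=2000, seed=3)
    assert mwsl.ent == pytest.approx(1.0, rel=0.25)


def test_mwsl_order_statistic_and_reproducibility():
    sset = noise_spectra(60, 10, seed=24)
    y = np.random.default_rng(24).standard_normal(60)
    pheno = pheno_frame(y, seed=24)
    spec = ModelSpec("ln_cac1", ())
    m1 = estimate_mwsl(sset, pheno, spec, n_perm=400, seed=9)
    m2 = estimate_mwsl(sset, pheno, spec, n_perm=400, seed=9)
    assert m1.k == math.ceil(0.05 * 400) == 20
    assert m1.alpha_prime == m1.permutation_min_p[m1.k - 1]
    np.testing.assert_array_equal(m1.permutation_min_p, m2.permutation_min_p)
    assert 1.0 <= m1.ent <= 10.5  # ENT bounded by feature count


def test_mwsl_rejects_too_few_permutations():
    sset = noise_spectra(30, 2, seed=0)
    y = np.zeros(30)
    with pytest.raises(ValueError):
        estimate_mwsl(sset, pheno_frame(y), ModelSpec("ln_cac1", ()),
                      alpha=0.05, n_perm=10)


def test_effective_number_of_tests_values():
    assert effective_number_of_tests(0.05, 0.05) == 1.0
    assert effective_number_of_tests(0.05, 1.8e-5) == pytest.approx(2777.8, rel=1e-3)
    assert effective_number_of_tests(0.05, 3.7e-6) == pytest.approx(13513.5, rel=1e-3)
    with pytest.raises(ValueError):
        effective_number_of_tests(0.0, 0.05)
    with pytest.raises(ValueError):
        effective_number_of_tests(0.05, 0.0)


# ---------------------------------------------------------------------
# replication


def _results_frame(p, direction):
    return pd.DataFrame({
        "feature_index": np.arange(len(p)),
        "ppm": np.linspace(1, 2, len(p)),
        "p_value": p,
        "direction": direction,
    })


def test_replication_truth_table():
    """Exhaustive over (discovery below/above alpha', replication p
    below/above 0.05, direction agreement)."""
    alpha_prime = 1.8e-5
    disc = _results_frame(
        [1e-8, 1e-8, 1e-8, 1e-8, 1e-3],
        [1, 1, -1, 1, 1])
    rep = _results_frame(
        [0.01, 0.01, 0.01, 0.2, 1e-6],
        [1, -1, -1, 1, 1])
    out = replicate_hits(disc, rep, alpha_prime)
    # feature 4 (discovery p = 1e-3 > alpha') is not a discovery hit
    assert list(out["feature_index"]) == [0, 1, 2, 3]
    assert list(out["replicated"]) == [True, False, True, False]


def test_replication_index_mismatch_rejected():
    disc = _results_frame([1e-8], [1])
    rep = _results_frame([0.01, 0.02], [1, 1])
    with pytest.raises(ValueError):
        replicate_hits(disc, rep, 1e-5)


# ---------------------------------------------------------------------
# sentinels


def _cmap(bounds, n_features):
    clusters = [Cluster(i, lo, hi, i) for i, (lo, hi) in enumerate(bounds)]
    covered = set()
    for lo, hi in bounds:
        covered.update(range(lo, hi + 1))
    unassigned = [j for j in range(n_features) if j not in covered]
    return ClusterMap(clusters, unassigned, n_features)


def test_sentinel_is_lowest_p_member():
    table = _results_frame([0.2, 0.001, 0.5, 0.9], [1, 1, 1, 1])
    cmap = select_sentinels(table, _cmap([(0, 2)], 4))
    assert cmap.clusters[0].sentinel_feature == 1


def test_sentinel_tie_broken_by_lower_index():
    table = _results_frame([0.3, 0.01, 0.01, 0.9], [1, 1, 1, 1])
    cmap = select_sentinels(table, _cmap([(0, 3)], 4))
    assert cmap.clusters[0].sentinel_feature == 1


def test_sentinel_absent_when_all_members_skipped():
    table = _results_frame([np.nan, np.nan, 0.5], [0, 0, 1])
    cmap = select_sentinels(table, _cmap([(0, 1)], 3))
    assert cmap.clusters[0].sentinel_feature is None


def test_sentinel_of_planted_cluster_lies_in_true_block(planted_cohort):
    from nmrmwas import srv_cluster

    sset, pheno, truth = planted_cohort
    res = mwas_scan(sset, pheno, ModelSpec.model1("ln_cac1"))
    cmap = select_sentinels(res, srv_cluster(sset))
    lo, hi = map(int, truth.loc[0, "feature_blocks"].split(";")[0].split("-"))
    cid = cmap.cluster_of((lo + hi) // 2)
    cluster = next(c for c in cmap.clusters if c.cluster_id == cid)
    assert cluster.sentinel_feature is not None
    assert cluster.start <= cluster.sentinel_feature <= cluster.end


def test_summary_and_manhattan_export(planted_cohort, tmp_path):
    sset, pheno, _ = planted_cohort
    res = mwas_scan(sset, pheno, ModelSpec.model1("ln_cac1"))
    text = res.summary(5)
    assert "ln_cac1" in text and "beta_per_sd" in text
    man = res.manhattan_table()
    nz = man.dropna(subset=["p_value"])
    np.testing.assert_allclose(
        nz["signed_log10_p"].abs(),
        -np.log10(nz["p_value"]) * nz["direction"].abs(), rtol=1e-12)
    res.to_tsv(tmp_path / "scan.tsv")
    assert (tmp_path / "scan.tsv").stat().st_size > 0
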
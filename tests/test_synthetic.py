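"""Cohort generator: determinism, planted structure, round trips."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from otomir.synthetic import (
    HL_FREQUENCIES,
    CohortConfig,
    PlantedEffects,
    SchemaError,
    generate_audiology,
    generate_counts,
    generate_subjects,
    generate_cohort,
    read_cohort,
    subjects_frame,
    write_cohort,
)


def test_seeded_determinism():
    cfg = CohortConfig(seed=1)
    a = subjects_frame(generate_subjects(cfg))
    b = subjects_frame(generate_subjects(cfg))
    pd.testing.assert_frame_equal(a, b)


def test_group_sizes_and_ranges():
    cfg = CohortConfig(seed=3)
    subs = generate_subjects(cfg)
    groups = pd.Series([s.group for s in subs]).value_counts()
    assert groups["roller"] == 11 and groups["spray"] == 6
    assert groups["roller"] + groups["spray"] == 17  # the exposed painters
    assert all(21 <= s.age <= 54 for s in subs)


def test_dose_is_concentration_times_years():
    subs = generate_subjects(CohortConfig(seed=2))
    for s in subs:
        for met, conc in s.metabolites.items():
            if met == "cotinine":
                assert s.dose[met] == 0.0  # smoking is not an occupational dose
            else:
                assert s.dose[met] == pytest.approx(conc * s.exposure_years)
        if s.group == "control":
            assert all(v == 0 for m, v in s.metabolites.items() if m != "cotinine")


def test_zero_allele_frequency_gives_all_wildtype():
    cfg = CohortConfig(seed=5, allele_freq_hOGG1=0.0, allele_freq_XRCC1=0.0)
    subs = generate_subjects(cfg)
    assert all(s.hOGG1 == "wt" and s.XRCC1 == "wt" for s in subs)


@pytest.mark.parametrize(
    "kwargs",
    [dict(n_roller=0), dict(allele_freq_hOGG1=1.5), dict(metabolite_medians={"MA": -1.0})],
)
def test_invalid_config_rejected(kwargs):
    with pytest.raises(ValueError):
        CohortConfig(seed=0, **kwargs)


def test_config_yaml_round_trip():
    cfg = CohortConfig(seed=9, n_controls=5)
    assert CohortConfig.from_yaml(cfg.to_yaml()) == cfg


def test_audiology_zero_damage_equals_age_baseline():
    cfg = CohortConfig(seed=1, damage_coefficients=(0.0, 0.0, 1.0), damage_sd=0.0)
    subs = generate_subjects(cfg)
    eff = PlantedEffects.default(hl_noise_sd=0.0, dp_noise_sd=0.0)
    hl, dp = generate_audiology(subs, eff, seed=1, quantize=False)
    for s in subs:
        for f in HL_FREQUENCIES:
            base = eff.hl_baseline + eff.hl_age_slope[f] * (s.age - 20.0) / 10.0
            assert hl.loc[s.id, f"F{f}"] == pytest.approx(base)


def test_ear_averaging_of_quantized_levels():
    # each stored level is the mean of two 5 dB-quantized ear draws,
    # hence a multiple of 2.5 dB
    subs = generate_subjects(CohortConfig(seed=4))
    hl, _ = generate_audiology(subs, PlantedEffects.default(), seed=4)
    assert np.allclose(np.mod(hl.to_numpy() * 2, 5.0), 0.0)


def test_hl_dpoae_negatively_correlated():
    cfg = CohortConfig(seed=8, n_roller=330, n_spray=170, n_controls=500)
    subs = generate_subjects(cfg)
    hl, dp = generate_audiology(subs, PlantedEffects.default(), seed=8)
    r = np.corrcoef(hl.mean(axis=1), dp.mean(axis=1))[0, 1]
    assert r < 0


def test_empty_subject_list_rejected():
    with pytest.raises(ValueError):
        generate_audiology([], PlantedEffects.default(), seed=0)
    with pytest.raises(ValueError):
        generate_counts([], PlantedEffects.default(), seed=0)


def test_counts_poisson_limit():
    subs = generate_subjects(CohortConfig(seed=6, n_roller=40, n_spray=40, n_controls=80))
    eff = PlantedEffects(de_mirnas=[], coupling={}, dispersion=0.0)
    cm = generate_counts(subs, eff, n_genes=300, mean_depth=3e5, seed=6, libsize_log_sd=0.0)
    m = cm.counts.mean(axis=1)
    v = cm.counts.var(axis=1)
    keep = m > 50
    ratio = (v[keep] / m[keep]).mean()
    assert 0.9 < ratio < 1.1  # variance tracks the mean in the Poisson limit


def test_equal_library_factors_give_equal_depth():
    subs = generate_subjects(CohortConfig(seed=7))
    eff = PlantedEffects(de_mirnas=[], coupling={}, dispersion=0.0)
    cm = generate_counts(subs, eff, n_genes=400, mean_depth=2e5, seed=7, libsize_log_sd=0.0)
    sums = cm.counts.sum(axis=0)
    assert sums.std() / sums.mean() < 0.02


def test_planted_log2fc_recovered_at_large_n():
    # ratio-of-means estimator on 10^4 subjects recovers the -3.14 analogue
    cfg = CohortConfig(seed=3, n_roller=2500, n_spray=2500, n_controls=5000)
    subs = generate_subjects(cfg)
    cm = generate_counts(subs, PlantedEffects.default(), n_genes=400, mean_depth=1e5, seed=3)
    cond = cm.condition.loc[list(cm.samples)].to_numpy()
    # oracle: depth-normalized group means against the null-gene baseline
    lib = cm.counts.sum(axis=0)
    shares = cm.counts / lib
    nulls = [g for g in cm.genes if g.startswith("hsa-miR-null")]
    comp = np.log2(
        shares.loc[nulls, cond == "exposed"].mean(axis=1).sum()
        / shares.loc[nulls, cond == "control"].mean(axis=1).sum()
    )
    g = "hsa-miR-122-5p"
    est = (
        np.log2(
            shares.loc[g, cond == "exposed"].mean() / shares.loc[g, cond == "control"].mean()
        )
        - comp
    )
    assert est == pytest.approx(-3.14, abs=0.05)


def test_genotype_multiplier_orders_hearing_loss():
    # mut subjects at equal exposure have stochastically larger HL than wt
    hl_mut, hl_wt = [], []
    cfg = CohortConfig(seed=11, n_roller=500, n_spray=500, n_controls=1,
                       allele_freq_hOGG1=0.5)
    subs = generate_subjects(cfg)
    hl, _ = generate_audiology(subs, PlantedEffects.default(), seed=11)
    mean_hl = hl.mean(axis=1)
    for s in subs:
        if s.group == "control":
            continue
        (hl_mut if s.hOGG1 == "mut" else hl_wt if s.hOGG1 == "wt" else []).append(
            mean_hl[s.id]
        )
    stat = stats.mannwhitneyu(hl_mut, hl_wt, alternative="greater")
    assert stat.pvalue < 0.01


def test_hl_profile_recovery_by_regression():
    # regression of HL on latent damage recovers the per-frequency profile
    cfg = CohortConfig(seed=13, n_roller=3000, n_spray=2000, n_controls=5000)
    subs = generate_subjects(cfg)
    eff = PlantedEffects.default()
    hl, _ = generate_audiology(subs, eff, seed=13)
    d = np.array([s.damage for s in subs])
    X = np.column_stack([np.ones_like(d), d])
    for f in (125, 1000, 8000):
        y = hl[f"F{f}"].to_numpy()
        beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        se = np.sqrt(resid.var() / (d.var() * len(d)))
        assert abs(beta[1] - eff.hl_profile[f]) < 3 * se


def test_cohort_write_read_round_trip(small_cohort, tmp_path):
    write_cohort(small_cohort, tmp_path)
    back = read_cohort(tmp_path)
    pd.testing.assert_frame_equal(back["hl"], small_cohort["hl"])
    pd.testing.assert_frame_equal(back["dpoae"], small_cohort["dpoae"])
    pd.testing.assert_frame_equal(back["counts"].counts, small_cohort["counts"].counts)
    pd.testing.assert_frame_equal(
        back["cohort"], small_cohort["cohort"], check_dtype=False
    )


def test_read_missing_genotype_column_names_it(small_cohort, tmp_path):
    write_cohort(small_cohort, tmp_path)
    cohort = pd.read_csv(tmp_path / "cohort.tsv", sep="\t", index_col=0)
    cohort.drop(columns=["hOGG1"]).to_csv(tmp_path / "cohort.tsv", sep="\t")
    with pytest.raises(SchemaError, match="hOGG1"):
        read_cohort(tmp_path)


def test_empty_cohort_not_written(tmp_path):
    tables = {"cohort": pd.DataFrame()}
    with pytest.raises(ValueError):
        write_cohort(tables, tmp_path)
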
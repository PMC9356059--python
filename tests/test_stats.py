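"""Mixed-model inference: external-oracle agreement, coding symmetry,
parameter recovery and error calibration."""

import numpy as np
import pandas as pd
import pytest

from rhythmtag import config as cfg
from rhythmtag.eegsim import SimConfig, simulate_response_table
from rhythmtag.stats import (fit_model1, fit_model2, harmonic_check,
                             make_response_table)


def table_for(sim: SimConfig, n=8, seed=77) -> pd.DataFrame:
    return make_response_table(simulate_response_table(sim, n, seed=seed))


# ---------------------------------------------------------------------------
# Agreement with the R reference implementation (lme4 + lmerTest)
# ---------------------------------------------------------------------------

# Reference values computed once with lme4/lmerTest (REML, simple coding,
# Satterthwaite) on the deterministic table simulate_response_table(
# SimConfig(), 8, seed=77): summary() coefficients and type-III anova.
R_FIXED = {
    "Intercept": (0.000000, 0.114177, 21.0, 0.000000, 1.000000),
    "frequency[10 Hz]": (-1.408848, 0.039148, 117.0, -35.987516, 0.0),
    "group[french]": (0.575911, 0.279676, 21.0, 2.059208, 0.052089),
    "group[japanese]": (-0.379034, 0.279676, 21.0, -1.355261, 0.189734),
    "frequency[10 Hz]:group[french]": (-0.733098, 0.095893, 117.0,
                                       -7.644942, 0.0),
    "frequency[10 Hz]:group[japanese]": (-0.190746, 0.095893, 117.0,
                                         -1.989150, 0.049018),
}
R_ANOVA = {
    "frequency": (1295.101316, 1, 117.0),
    "group": (5.911889, 2, 21.0),
    "frequency:group": (31.463280, 2, 117.0),
}
R_VARCOMP = (0.30367861, 0.05517302)     # participant, residual


def test_cross_language_model_matches_lmertest_reference():
    m = fit_model1(table_for(SimConfig()))
    for _, row in m.fixed_effects.iterrows():
        beta, se, df, t, p = R_FIXED[row["term"]]
        assert row["beta"] == pytest.approx(beta, abs=2e-4)
        assert row["se"] == pytest.approx(se, abs=2e-4)
        assert row["df"] == pytest.approx(df, abs=0.1)
        assert row["p"] == pytest.approx(p, abs=1e-3)
    for _, row in m.anova.iterrows():
        F, q, dfd = R_ANOVA[row["term"]]
        assert row["F"] == pytest.approx(F, rel=1e-3)
        assert row["df_num"] == q
        assert row["df_den"] == pytest.approx(dfd, abs=0.1)
    assert m.sigma2_participant == pytest.approx(R_VARCOMP[0], rel=1e-3)
    assert m.sigma2_residual == pytest.approx(R_VARCOMP[1], rel=1e-3)


def test_balanced_design_reduces_to_ols():
    """With a balanced design the GLS estimates equal ordinary least
    squares regardless of the intercept variance."""
    t = table_for(SimConfig(amp_sd_between=0.0), n=6, seed=5)
    t = t[t["condition"].isin(cfg.SPEECH_CONDITIONS)]
    m = fit_model1(t)
    # OLS oracle on the identical standardized design
    from rhythmtag.stats import _make_design, _standardize
    y, _, _ = _standardize(t["amplitude_uv"].to_numpy(float))
    d = _make_design(t, {"frequency": ["5 Hz", "10 Hz"],
                         "group": list(cfg.GROUPS)},
                     ["frequency", "group", "frequency:group"])
    beta_ols = np.linalg.lstsq(d.X, y, rcond=None)[0]
    np.testing.assert_allclose(m.fixed_effects["beta"].to_numpy(),
                               beta_ols, atol=1e-6)


# ---------------------------------------------------------------------------
# Structural / degenerate cases
# ---------------------------------------------------------------------------

def test_missing_group_is_reported_by_name():
    t = table_for(SimConfig())
    with pytest.raises(ValueError, match="japanese"):
        fit_model1(t[t["group"] != "japanese"])


def test_single_participant_is_rejected():
    t = table_for(SimConfig(), n=1)
    t = t[t["participant"] == "en00"]
    with pytest.raises(ValueError, match="participant"):
        fit_model1(t)


def test_equal_groups_with_zero_noise_give_zero_contrasts():
    rows = []
    for g in cfg.GROUPS:
        for p in range(3):
            for cond in cfg.SPEECH_CONDITIONS:
                for fr, amp in [("5 Hz", 1.0), ("10 Hz", 0.5)]:
                    rows.append(dict(participant=f"{g}{p}", group=g,
                                     condition=cond, frequency=fr,
                                     amplitude_uv=amp))
    m = fit_model1(pd.DataFrame(rows))
    group_contrasts = m.contrasts[m.contrasts["term"].str.contains("@")]
    between = group_contrasts[~group_contrasts["term"]
                              .str.startswith("5 Hz")]
    assert np.allclose(between["beta"], 0.0, atol=1e-10)


def test_relabeling_speech_and_nonspeech_flips_the_stimulus_beta():
    t = table_for(SimConfig(), n=6, seed=9)
    m = fit_model2(t)
    swapped = t.copy()
    swapped["condition"] = swapped["condition"].map(
        {"polish": "vocoded", "vocoded": "polish"}).fillna(
            swapped["condition"])
    m_sw = fit_model2(swapped)
    b = m.full.fixed_effects.set_index("term").loc["stimulus[nonspeech]",
                                                   "beta"]
    b_sw = m_sw.full.fixed_effects.set_index("term").loc[
        "stimulus[nonspeech]", "beta"]
    assert b_sw == pytest.approx(-b, abs=1e-9)


# ---------------------------------------------------------------------------
# Speech vs non-speech: detection only where the effect is embedded
# ---------------------------------------------------------------------------

def test_stimulus_effect_detected_at_10hz_only():
    """The default generator embeds a speech > non-speech difference only
    at 10 Hz; the 10 Hz sub-model must find it almost always and the 5 Hz
    sub-model only at the false-positive rate."""
    hits10 = hits5 = 0
    n_runs = 100
    for k in range(n_runs):
        t = table_for(SimConfig(), n=20, seed=3000 + k)
        m2 = fit_model2(t)
        p10 = m2.per_frequency["10 Hz"].anova.set_index("term").loc[
            "stimulus", "p"]
        p5 = m2.per_frequency["5 Hz"].anova.set_index("term").loc[
            "stimulus", "p"]
        hits10 += p10 < 0.05
        hits5 += p5 < 0.05
    assert hits10 >= 90
    assert hits5 <= 12        # ~5% nominal false-positive rate


# ---------------------------------------------------------------------------
# Harmonic regression
# ---------------------------------------------------------------------------

def harmonic_table(slope=0.4, seed=0, n=12, noise=0.0,
                   independent=False) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = []
    for g in cfg.GROUPS:
        for p in range(n):
            pid = f"{g}{p:02d}"
            for cond in cfg.SPEECH_CONDITIONS:
                a5 = 0.6 + 0.25 * rng.uniform()
                if independent:
                    a10 = 0.3 + 0.1 * rng.standard_normal()
                else:
                    a10 = slope * a5 + noise * rng.standard_normal()
                rows.append(dict(participant=pid, group=g, condition=cond,
                                 frequency="5 Hz", amplitude_uv=a5))
                rows.append(dict(participant=pid, group=g, condition=cond,
                                 frequency="10 Hz", amplitude_uv=a10))
    return pd.DataFrame(rows)


def test_harmonic_slope_is_recovered_on_the_raw_scale():
    m = harmonic_check(harmonic_table(slope=0.4, noise=0.02, seed=4))
    assert m.extra["raw_slope"] == pytest.approx(0.4, abs=0.05)


def test_group_offsets_survive_a_constant_covariate_relationship():
    t = harmonic_table(slope=0.0, seed=6)
    # pure group offsets at 10 Hz, 5 Hz covariate unrelated
    t.loc[t["frequency"] == "10 Hz", "amplitude_uv"] = \
        t.loc[t["frequency"] == "10 Hz", "group"].map(
            {"english": 0.2, "french": 0.5, "japanese": 0.3}).to_numpy()
    m = harmonic_check(t)
    fe = m.fixed_effects.set_index("term")
    sd = m.scale_sd
    assert fe.loc["group[french]", "beta"] * sd == pytest.approx(0.3,
                                                                 abs=1e-6)
    assert fe.loc["group[japanese]", "beta"] * sd == pytest.approx(
        0.1, abs=1e-6)


def test_independent_amplitudes_give_nominal_ci_coverage():
    """Coverage oracle: with 5 and 10 Hz amplitudes independent the slope
    CI should cover zero in about 95% of runs."""
    cover = 0
    n_runs = 100
    for k in range(n_runs):
        t = harmonic_table(independent=True, seed=5000 + k, n=10)
        m = harmonic_check(t)
        fe = m.fixed_effects.set_index("term")
        lo = fe.loc["amplitude_uv_5hz", "ci_low"]
        hi = fe.loc["amplitude_uv_5hz", "ci_high"]
        cover += lo <= 0.0 <= hi
    assert 0.88 <= cover / n_runs <= 0.995


def test_unmatched_rows_are_rejected():
    t = harmonic_table(seed=1)
    broken = t.drop(t[(t.participant == "english00")
                      & (t.frequency == "10 Hz")].index[:1])
    with pytest.raises(ValueError, match="matched"):
        harmonic_check(broken)
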
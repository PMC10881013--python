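"""Mixed-model layer: Wald tests, contrasts, covariate slopes, VOC fits.

One test cross-checks the whole fitting path against the R mixed-model stack
(lme4 + car + emmeans) on a single synthetic dataset; the rest exercise the
layer on planted ground truth.
"""

from __future__ import annotations

import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from olfthresh.stats import (
    CalibrationCurve,
    condition_summary,
    covariate_slope,
    fit_acclimation_model,
    fit_covariate_model,
    fit_threshold_model,
    fit_voc_threshold,
    fold_change,
    posthoc_condition_vs_standard,
    voc_quantify,
)
from olfthresh.synthetic_data import (
    DesignSpec,
    EffectSpec,
    simulate_experiment1,
    simulate_experiment2,
)


@pytest.fixture(scope="module")
def exp1():
    return simulate_experiment1(seed=21)


@pytest.fixture(scope="module")
def exp1_model(exp1):
    return fit_threshold_model(exp1.thresholds)


# ---------------------------------------------------------------------------
# threshold model


def test_threshold_model_recovers_planted_structure(exp1_model):
    """Odor differences are planted large (baselines span 1.3 log10 units);
    the odor term must dominate and the model must converge."""
    assert exp1_model.converged
    wald = exp1_model.wald.set_index("term")
    assert wald.loc["C(odor, Sum)", "p"] < 1e-10
    assert wald.loc["C(odor, Sum)", "df"] == 3
    assert wald.loc["C(condition, Sum)", "df"] == 4
    assert {"df_denom", "p_f"} <= set(exp1_model.wald.columns)


def test_threshold_model_null_condition_not_significant():
    """With no planted condition shifts the condition term sits at chance."""
    effects = EffectSpec(condition_shift={})
    sim = simulate_experiment1(effects=effects, seed=33)
    m = fit_threshold_model(sim.thresholds)
    assert float(m.wald_for("C(condition, Sum)").p_f) > 0.05


def test_single_odor_design_drops_odor_terms():
    design = DesignSpec(odors=("C4",))
    sim = simulate_experiment1(design=design, seed=5)
    m = fit_threshold_model(sim.thresholds)
    assert not any("odor" in t for t in m.wald["term"])
    assert m.n_obs == 8 * 5


def test_model_requires_standard_reference(exp1):
    no_std = exp1.thresholds.query("condition != 'standard'")
    with pytest.raises(ValueError, match="standard"):
        fit_threshold_model(no_std)


def test_model_row_order_invariant(exp1, exp1_model):
    shuffled = exp1.thresholds.sample(frac=1.0, random_state=0)
    m2 = fit_threshold_model(shuffled)
    assert np.allclose(
        exp1_model.wald["chi2"].to_numpy(), m2.wald["chi2"].to_numpy(), rtol=1e-6
    )


# ---------------------------------------------------------------------------
# post-hoc contrasts


def test_posthoc_shape_and_sign(exp1_model, exp1):
    ct = posthoc_condition_vs_standard(exp1_model)
    assert set(ct["odor"]) == {"AN", "C4", "SP", "TNT"}
    assert "standard" not in set(ct["condition"])
    assert len(ct) == 4 * 4
    # planted C4 hot-condition decrement must come out positive (poorer)
    c4h = ct.query("odor == 'C4' and condition == 'HTHH'").iloc[0]
    assert c4h["estimate"] > 0
    assert np.isfinite(c4h["p_holm"]) and c4h["p_holm"] >= c4h["p_unadjusted"]


def test_posthoc_requires_standard(exp1):
    sub = exp1.thresholds.query("condition in ('standard', 'HTHH')")
    m = fit_threshold_model(sub)
    ct = posthoc_condition_vs_standard(m)
    assert set(ct["condition"]) == {"HTHH"}


def test_lme4_oracle_agreement(exp1, exp1_model, tmp_path):
    """REML fit, Type-II Wald chi-squares and condition-vs-standard EMM
    contrasts agree with lme4 + car::Anova + emmeans on the same data."""
    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not available")
    csv = tmp_path / "thr.csv"
    exp1.thresholds[["dog", "breed", "odor", "condition", "log10_threshold"]].to_csv(
        csv, index=False
    )
    script = tmp_path / "oracle.R"
    script.write_text(
        "suppressMessages({library(lme4); library(car); library(emmeans); library(jsonlite)})\n"
        f"d <- read.csv('{csv}')\n"
        "d$condition <- relevel(factor(d$condition), ref='standard')\n"
        "m <- lmer(log10_threshold ~ breed + condition*odor + (1|dog), data=d, REML=TRUE)\n"
        "a <- Anova(m, type=2)\n"
        "em <- suppressMessages(emmeans(m, ~ condition | odor))\n"
        "ct <- as.data.frame(contrast(em, method='trt.vs.ctrl', ref='standard'))\n"
        "cat(toJSON(list(anova=data.frame(term=rownames(a), chi2=a$Chisq, df=a$Df),"
        " contrasts=ct), digits=10))\n"
    )
    out = subprocess.run(
        ["Rscript", str(script)], capture_output=True, text=True, timeout=300
    )
    assert out.returncode == 0, out.stderr
    oracle = json.loads(out.stdout)

    r_anova = {row["term"]: row for row in oracle["anova"]}
    ours = exp1_model.wald.set_index("term")
    pairs = {
        "C(breed, Sum)": "breed",
        "C(condition, Sum)": "condition",
        "C(odor, Sum)": "odor",
        "C(condition, Sum):C(odor, Sum)": "condition:odor",
    }
    for our_term, r_term in pairs.items():
        assert ours.loc[our_term, "chi2"] == pytest.approx(
            r_anova[r_term]["chi2"], rel=1e-3
        )
        assert int(ours.loc[our_term, "df"]) == int(r_anova[r_term]["df"])

    ct = posthoc_condition_vs_standard(exp1_model)
    for row in oracle["contrasts"]:
        cond = row["contrast"].split(" - ")[0]
        odor = row["odor"]
        mine = ct[(ct["odor"] == odor) & (ct["condition"] == cond)].iloc[0]
        assert mine["estimate"] == pytest.approx(row["estimate"], abs=1e-4)
        assert mine["se"] == pytest.approx(row["SE"], rel=1e-2)


# ---------------------------------------------------------------------------
# covariate models


def test_covariate_model_reports_slope(exp1):
    m = fit_covariate_model(
        exp1.thresholds, "mean_temp_c", conditions=("standard", "HTHH", "HTLH")
    )
    slope, se = covariate_slope(m, "mean_temp_c")
    assert np.isfinite(slope) and se > 0
    assert m.n_obs <= 8 * 4 * 3


def test_covariate_constant_rejected(exp1):
    flat = exp1.thresholds.copy()
    flat["mean_temp_c"] = 39.0
    with pytest.raises(ValueError, match="constant"):
        fit_covariate_model(flat, "mean_temp_c")


def test_covariate_all_missing_rejected(exp1):
    none = exp1.thresholds.copy()
    none["mean_temp_c"] = np.nan
    with pytest.raises(ValueError, match="no complete cases"):
        fit_covariate_model(none, "mean_temp_c")


# ---------------------------------------------------------------------------
# acclimatization model


def test_acclimation_model_recovers_planted_group_effect():
    sim = simulate_experiment2(seed=9)  # planted acclimatization effect -0.5
    m = fit_acclimation_model(sim.thresholds)
    coef = m.params.set_index("term")["estimate"]
    group_term = [t for t in coef.index if "acclimatization" in t][0]
    assert coef[group_term] < 0  # acclimatized dogs detect better
    assert int(m.wald["df"].iloc[0]) == 1
    # non-imputed variant and behavioral companion responses also fit
    m_np = fit_acclimation_model(sim.thresholds, response="log10_threshold_nonimputed")
    assert np.isfinite(m_np.wald["chi2"].iloc[0])
    m_ibi = fit_acclimation_model(sim.thresholds, response="mean_ibi_s")
    assert np.isfinite(m_ibi.wald["chi2"].iloc[0])


def test_acclimation_model_requires_two_groups():
    sim = simulate_experiment2(seed=9)
    ctrl = sim.thresholds.query("group == 'control'")
    with pytest.raises(ValueError, match="two treatment groups"):
        fit_acclimation_model(ctrl)


# ---------------------------------------------------------------------------
# scalar helpers and VOC


@pytest.mark.parametrize(
    "delta, fold",
    [(0.0, 1.0), (0.47, 10**0.47), (0.544, 3.5), (1.0, 10.0), (-0.301, 10**-0.301)],
)
def test_fold_change(delta, fold):
    assert fold_change(delta) == pytest.approx(fold, rel=1e-3)


def test_fold_change_log_identity():
    for x in (0.01, 0.5, 3.5, 80.0):
        assert fold_change(np.log10(x)) == pytest.approx(x, rel=1e-12)


def test_voc_quantify_response_factor():
    curve = CalibrationCurve("DMNB", slope=5.0, intercept=0.1, r_squared=0.995)
    assert voc_quantify(0.0, curve) == 0.0
    assert voc_quantify(5.0, curve) == pytest.approx(1.0)
    assert voc_quantify(250.0, curve) == pytest.approx(50.0)


def test_calibration_linearity_criterion_enforced():
    with pytest.raises(ValueError, match="linearity"):
        CalibrationCurve("X", slope=5.0, intercept=0.0, r_squared=0.9)


def test_voc_threshold_recovers_planted_sign():
    rng = np.random.default_rng(3)
    voc_by_cond = {"HTHH": 600.0, "HTLH": 400.0, "LTHH": 150.0, "LTLH": 60.0}
    rows = []
    for dog in range(8):
        for cond, v in voc_by_cond.items():
            rows.append(
                {"dog": f"dog{dog}", "odor": "C4", "condition": cond,
                 "log10_threshold": -1.4 + 5e-4 * v + rng.normal(0, 0.05)}
            )
    records = pd.DataFrame(rows)
    voc = pd.DataFrame(
        [
            {"odor": "C4", "condition": c, "replicate": r, "total_voc_ppm": v}
            for c, v in voc_by_cond.items()
            for r in range(10)
        ]
    )
    fit = fit_voc_threshold(records, voc)
    row = fit.query("odor == 'C4'").iloc[0]
    assert not row["degenerate"]
    assert row["slope"] > 0
    assert row["slope"] == pytest.approx(5e-4, rel=0.35)
    assert row["p"] < 0.05


def test_voc_constant_flagged_degenerate():
    records = pd.DataFrame(
        [
            {"dog": "d1", "odor": "AN", "condition": c, "log10_threshold": -0.7}
            for c in ("HTHH", "HTLH", "LTHH")
        ]
    )
    voc = pd.DataFrame(
        [
            {"odor": "AN", "condition": c, "replicate": 0, "total_voc_ppm": 300.0}
            for c in ("HTHH", "HTLH", "LTHH")
        ]
    )
    fit = fit_voc_threshold(records, voc)
    assert fit.iloc[0]["degenerate"]


# ---------------------------------------------------------------------------
# condition summary


def test_condition_summary_constant_cell():
    records = pd.DataFrame(
        [
            {"dog": f"d{i}", "odor": "SP", "condition": "standard",
             "log10_threshold": -1.523}
            for i in range(8)
        ]
    )
    out = condition_summary(records)
    row = out.iloc[0]
    assert row["mean"] == pytest.approx(-1.523)
    assert row["ci_low"] == pytest.approx(-1.523)
    assert row["ci_high"] == pytest.approx(-1.523)


def test_condition_summary_null_sim_within_noise_of_baseline():
    effects = EffectSpec(condition_shift={})
    sim = simulate_experiment1(effects=effects, seed=17)
    out = condition_summary(sim.thresholds)
    c4 = out.query("odor == 'C4'")
    # all cells near the planted baseline (staircase offset + noise << 0.35)
    assert (abs(c4["mean"] - (-1.4)) < 0.35).all()
    assert len(out) == 20
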
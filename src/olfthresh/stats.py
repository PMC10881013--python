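"""Inferential layer: mixed models, contrasts, covariate slopes, VOC regressions.

Log10 detection thresholds are modelled with linear mixed-effects regressions
(statsmodels MixedLM, REML) carrying a random intercept per dog.  Fixed terms
are tested with joint Wald chi-square statistics computed on a sum-contrast
coding, which coincides with classical Type-II tests on the balanced designs
this package generates.  Post-hoc condition-vs-standard contrasts within each
odor are estimated-marginal-mean differences (averaged over the remaining
factors), signed condition - standard so positive means poorer detection;
their p-values are reported both unadjusted and Holm-adjusted, since repeated
testing across conditions and odors invites multiplicity correction but no
single adjustment is canonical here.

VOC (odor availability) enters at the condition level — headspace sampling
was per condition, not per session — through simple per-odor linear
regressions of log threshold on condition-mean total VOC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "ModelSummary",
    "VocSample",
    "CalibrationCurve",
    "fit_threshold_model",
    "posthoc_condition_vs_standard",
    "fit_covariate_model",
    "fit_acclimation_model",
    "fold_change",
    "voc_quantify",
    "fit_voc_threshold",
    "condition_summary",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class ModelSummary:
    """Fitted mixed-model summary: coefficients, per-term Wald tests, contrasts."""

    params: pd.DataFrame  # term, estimate, se
    wald: pd.DataFrame  # term, chi2, df, p
    n_obs: int
    converged: bool
    formula: str
    group_var: str = "dog"
    contrasts: Optional[pd.DataFrame] = None
    _result: object = field(default=None, repr=False)
    _data: Optional[pd.DataFrame] = field(default=None, repr=False)

    def wald_for(self, term: str) -> pd.Series:
        hit = self.wald[self.wald["term"] == term]
        if hit.empty:
            raise KeyError(f"no Wald test for term {term!r}")
        return hit.iloc[0]


@dataclass(frozen=True)
class VocSample:
    """One SPME replicate: summed quantified volatiles for an odor x condition."""

    odor: str
    condition: str
    replicate: int
    total_voc_ppm: float

    def __post_init__(self) -> None:
        if self.total_voc_ppm < 0:
            raise ValueError("total VOC must be non-negative")


@dataclass(frozen=True)
class CalibrationCurve:
    """External calibration line for one compound, 1-100 mg/L range."""

    compound: str
    slope: float  # instrument response per mg/L
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if not (self.r_squared > 0.98):
            raise ValueError(
                f"calibration for {self.compound}: r^2={self.r_squared} fails "
                "the >0.98 linearity criterion"
            )


# ---------------------------------------------------------------------------
# mixed-model machinery


def _fit_lmm(data: pd.DataFrame, formula: str, groups: str) -> tuple[object, bool]:
    """REML mixed model with random intercept; never raises on singular fits."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM.from_formula(formula, data=data, groups=data[groups])
        try:
            result = model.fit(reml=True)
            converged = bool(getattr(result, "converged", True))
        except Exception:
            # boundary/singular failure under the default optimizer; retry
            result = model.fit(reml=True, method="powell")
            converged = False
    return result, converged


def _wald_terms(result, design_info) -> pd.DataFrame:
    """Joint Wald test per fixed term (intercept excluded).

    Each term gets the asymptotic chi-square (the conventional report for
    this kind of analysis) and a small-sample Wald F p-value, ``p_f``, using
    chi2/df against F(df, n - k_fe).  The chi-square is anti-conservative at
    the handful-of-subjects scale these designs run at; calibration checks
    use ``p_f``.
    """
    fe = np.asarray(result.fe_params)
    k_fe = len(fe)
    cov = np.asarray(result.cov_params())[:k_fe, :k_fe]
    df_denom = max(int(result.nobs) - k_fe, 1)
    rows = []
    for term, sl in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        idx = np.arange(sl.start, sl.stop)
        b = fe[idx]
        v = cov[np.ix_(idx, idx)]
        try:
            chi2 = float(b @ np.linalg.solve(v, b))
        except np.linalg.LinAlgError:
            chi2 = float("nan")
        df = len(idx)
        ok = np.isfinite(chi2)
        rows.append(
            {
                "term": term,
                "chi2": chi2,
                "df": df,
                "p": float(sps.chi2.sf(chi2, df)) if ok else float("nan"),
                "df_denom": df_denom,
                "p_f": float(sps.f.sf(chi2 / df, df, df_denom)) if ok else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def _params_table(result) -> pd.DataFrame:
    fe = result.fe_params
    k = len(fe)
    se = np.sqrt(np.diag(np.asarray(result.cov_params())[:k, :k]))
    return pd.DataFrame(
        {"term": list(fe.index), "estimate": fe.to_numpy(), "se": se}
    )


def _summarize(result, converged, formula, data, group_var="dog") -> ModelSummary:
    return ModelSummary(
        params=_params_table(result),
        wald=_wald_terms(result, result.model.data.design_info),
        n_obs=int(result.nobs),
        converged=converged,
        formula=formula,
        group_var=group_var,
        _result=result,
        _data=data,
    )


def _sum_coded(col: str) -> str:
    return f"C({col}, Sum)"


def _varying(data: pd.DataFrame, col: str) -> bool:
    return col in data.columns and data[col].nunique(dropna=True) > 1


# ---------------------------------------------------------------------------
# the threshold model and its contrasts


def fit_threshold_model(
    records: pd.DataFrame,
    response: str = "log10_threshold",
) -> ModelSummary:
    """Condition x odor mixed model for log10 detection threshold.

    ``response ~ breed + condition + odor + condition:odor`` with a random
    intercept per dog.  Terms whose factor has a single level in the data
    (e.g. one odor) are dropped rather than erroring.  Requires the standard
    condition to be present as the reference level for downstream contrasts.
    """
    data = records.dropna(subset=[response]).copy()
    if data["dog"].nunique() < 2:
        raise ValueError("need at least two dogs for a random-intercept model")
    if "condition" in data.columns and "standard" not in set(data["condition"]):
        raise ValueError("standard condition must be present as reference")

    terms = []
    if _varying(data, "breed"):
        terms.append(_sum_coded("breed"))
    has_cond = _varying(data, "condition")
    has_odor = _varying(data, "odor")
    if has_cond:
        terms.append(_sum_coded("condition"))
    if has_odor:
        terms.append(_sum_coded("odor"))
    if has_cond and has_odor:
        terms.append(f"{_sum_coded('condition')}:{_sum_coded('odor')}")
    if not terms:
        terms = ["1"]
    formula = f"{response} ~ " + " + ".join(terms)
    result, converged = _fit_lmm(data, formula, groups="dog")
    return _summarize(result, converged, formula, data)


def _emm_row(design_info, data: pd.DataFrame, condition: str, odor: str) -> np.ndarray:
    """Estimated-marginal-mean design row for one condition x odor cell.

    Averages the design row over the observed levels of every other factor
    (breed), i.e. the emmeans reference grid with equal weights.
    """
    breeds = sorted(data["breed"].dropna().unique()) if "breed" in data else [""]
    if not len(breeds):
        breeds = [""]
    grid = pd.DataFrame(
        {
            "condition": [condition] * len(breeds),
            "odor": [odor] * len(breeds),
            "breed": breeds,
        }
    )
    (mat,) = patsy.build_design_matrices([design_info], grid)
    return np.asarray(mat).mean(axis=0)


def posthoc_condition_vs_standard(summary: ModelSummary) -> pd.DataFrame:
    """Condition - standard contrasts within each odor (EMM differences).

    Returns one row per odor x non-standard condition with the estimate,
    standard error, t-ratio, unadjusted p, and Holm-adjusted p (within odor).
    Positive estimates mean poorer detection than standard.
    """
    result = summary._result
    data = summary._data
    if result is None or data is None:
        raise ValueError("summary does not carry a fitted model")
    if "standard" not in set(data["condition"]):
        raise ValueError("standard condition missing from fitted data")
    design_info = result.model.data.design_info
    fe = np.asarray(result.fe_params)
    k = len(fe)
    cov = np.asarray(result.cov_params())[:k, :k]

    rows = []
    odors = sorted(data["odor"].unique())
    conditions = [c for c in data["condition"].unique() if c != "standard"]
    for odor in odors:
        for cond in sorted(conditions):
            L = _emm_row(design_info, data, cond, odor) - _emm_row(
                design_info, data, "standard", odor
            )
            est = float(L @ fe)
            se = float(np.sqrt(L @ cov @ L))
            t = est / se if se > 0 else float("nan")
            p = float(2.0 * sps.norm.sf(abs(t))) if np.isfinite(t) else float("nan")
            rows.append(
                {
                    "odor": odor,
                    "condition": cond,
                    "estimate": est,
                    "se": se,
                    "t_ratio": t,
                    "p_unadjusted": p,
                }
            )
    table = pd.DataFrame(rows)
    # Holm adjustment within each odor's family of condition contrasts
    adj = np.full(len(table), np.nan)
    for odor in odors:
        idx = table.index[table["odor"] == odor].to_numpy()
        pvals = table.loc[idx, "p_unadjusted"].to_numpy()
        order = np.argsort(pvals)
        m = len(pvals)
        running = 0.0
        for rank, j in enumerate(order):
            running = max(running, (m - rank) * pvals[j])
            adj[idx[j]] = min(1.0, running)
    table["p_holm"] = adj
    return table


# ---------------------------------------------------------------------------
# covariate and acclimatization models


def fit_covariate_model(
    records: pd.DataFrame,
    covariate: str,
    response: str = "log10_threshold",
    conditions: Optional[Sequence[str]] = None,
) -> ModelSummary:
    """Mixed model of log threshold on a session covariate x odor.

    ``covariate`` is a column such as ``mean_temp_c``, ``mean_latency_s`` or
    ``mean_ibi_s``; the subcutaneous-temperature analysis should restrict
    ``conditions`` to the standard and hot conditions (cold readings are
    sensor artefacts).  The covariate main-effect coefficient under sum-coded
    odor is the across-odor average slope.
    """
    data = records.copy()
    if conditions is not None:
        data = data[data["condition"].isin(list(conditions))]
    data = data.dropna(subset=[response, covariate])
    if data.empty:
        raise ValueError(f"no complete cases for covariate {covariate!r}")
    if data[covariate].nunique() < 2:
        raise ValueError(f"covariate {covariate!r} is constant; slope undefined")

    if _varying(data, "odor"):
        formula = f"{response} ~ {covariate} * {_sum_coded('odor')}"
    else:
        formula = f"{response} ~ {covariate}"
    result, converged = _fit_lmm(data, formula, groups="dog")
    return _summarize(result, converged, formula, data)


def covariate_slope(summary: ModelSummary, covariate: str) -> tuple[float, float]:
    """(slope, se) of the covariate main effect from a covariate model."""
    row = summary.params[summary.params["term"] == covariate]
    if row.empty:
        raise KeyError(f"no coefficient for {covariate!r}")
    return float(row["estimate"].iloc[0]), float(row["se"].iloc[0])


def fit_acclimation_model(
    records: pd.DataFrame,
    response: str = "log10_threshold",
    test_days: Sequence[int] = (11, 22),
    reference_group: str = "control",
) -> ModelSummary:
    """Treatment-group effect across the hot test days.

    ``response ~ group`` with a random intercept per dog, on the test-day
    records only.  The group coefficient is acclimatization - control, so a
    negative threshold estimate means the acclimatized dogs detect better.
    Also used with behavioral/physiological responses (mean temperature,
    latency, inter-box interval) as companion models.
    """
    data = records[records["day"].isin(list(test_days))].dropna(subset=[response]).copy()
    groups_present = set(data["group"].dropna())
    if len(groups_present) < 2:
        raise ValueError(f"need two treatment groups, found {sorted(groups_present)}")
    formula = f"{response} ~ C(group, Treatment({reference_group!r}))"
    result, converged = _fit_lmm(data, formula, groups="dog")
    return _summarize(result, converged, formula, data)


# ---------------------------------------------------------------------------
# scalar helpers and VOC analysis


def fold_change(delta_log10: float) -> float:
    """Fold change implied by a log10 threshold difference: 10**delta."""
    return 10.0**delta_log10


def voc_quantify(instrument_response: float, curve: CalibrationCurve) -> float:
    """Concentration from instrument response via the response factor.

    The calibration slope serves as the response factor: concentration =
    response / slope.
    """
    if curve.slope <= 0:
        raise ValueError("calibration slope must be positive")
    return instrument_response / curve.slope


def fit_voc_threshold(
    records: pd.DataFrame,
    voc: pd.DataFrame,
    response: str = "log10_threshold",
) -> pd.DataFrame:
    """Per-odor regression of log threshold on condition-mean total VOC.

    VOC was sampled per odor x condition (no sampling at standard), so the
    join is at the condition level.  Returns one row per odor with the slope
    (log10 threshold per ppm), its standard error, p-value, and a flag for
    odors whose VOC spread is too degenerate to regress on (fewer than three
    distinct condition means).
    """
    voc_means = (
        voc.groupby(["odor", "condition"], as_index=False)["total_voc_ppm"]
        .mean()
        .rename(columns={"total_voc_ppm": "voc_ppm"})
    )
    data = records[records["condition"] != "standard"].merge(
        voc_means, on=["odor", "condition"], how="inner"
    )
    rows = []
    for odor, sub in data.groupby("odor"):
        sub = sub.dropna(subset=[response, "voc_ppm"])
        n_distinct = sub["voc_ppm"].nunique()
        if n_distinct < 3:
            rows.append(
                {"odor": odor, "slope": float("nan"), "se": float("nan"),
                 "p": float("nan"), "n": len(sub), "degenerate": True}
            )
            continue
        X = sm.add_constant(sub["voc_ppm"].to_numpy())
        fit = sm.OLS(sub[response].to_numpy(), X).fit()
        rows.append(
            {
                "odor": odor,
                "slope": float(fit.params[1]),
                "se": float(fit.bse[1]),
                "p": float(fit.pvalues[1]),
                "n": int(fit.nobs),
                "degenerate": False,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty or out["degenerate"].all():
        if out.empty:
            raise ValueError("no VOC-matched records to regress")
    return out


def condition_summary(records: pd.DataFrame, response: str = "log10_threshold") -> pd.DataFrame:
    """Raw mean and 95% CI of log10 threshold per odor x condition cell.

    Normal-theory (t) intervals on the per-dog values; cells with a single
    record get the mean with an undefined CI.
    """
    rows = []
    for (odor, cond), sub in records.dropna(subset=[response]).groupby(
        ["odor", "condition"]
    ):
        vals = sub[response].to_numpy(dtype=float)
        n = len(vals)
        mean = float(np.mean(vals))
        if n >= 2:
            se = float(np.std(vals, ddof=1) / np.sqrt(n))
            half = float(sps.t.ppf(0.975, n - 1)) * se
            lo, hi = mean - half, mean + half
        else:
            lo = hi = float("nan")
        rows.append(
            {"odor": odor, "condition": cond, "mean": mean,
             "ci_low": lo, "ci_high": hi, "n": n}
        )
    return pd.DataFrame(rows)
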
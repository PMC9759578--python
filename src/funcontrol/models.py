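"""Group-level inference: responder filtering, mixed models, descriptives.

Two sets of linear mixed-effects models are fit on network-level
controllability values, one cell per (model set, metric, scan context,
network):

* ``group_comparison`` — TD sessions (coded placebo) together with the
  clinical group's placebo and MPH sessions, a three-level condition
  factor with TD as reference, yielding the two group contrasts
  (clinical-placebo vs TD, clinical-MPH vs TD);
* ``within_adhd`` — clinical rows only, a binary MPH indicator.

Every model controls for age, biological sex, and in-scanner motion
(mean raw framewise displacement per session and context) and carries a
random intercept per participant.  With the full 13-network atlas the
enumeration yields 2 x 2 x 3 x 13 = 156 model cells; no multiple-
comparisons correction is applied.

Before modeling, clinical participants are filtered per scan context to
*acute behavioral responders*: those whose mean raw FD decreased on MPH
relative to placebo in that context (strict inequality).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synth import CONDITION_MPH, CONDITION_PLACEBO, GROUP_ADHD, GROUP_TD

__all__ = [
    "MODEL_SETS",
    "METRICS",
    "ModelSpec",
    "ModelResult",
    "acute_responders",
    "enumerate_models",
    "fit_model_set",
    "fit_all_models",
    "summary_ttest",
    "chisq_independence",
]

MODEL_SETS = ("group_comparison", "within_adhd")
METRICS = ("average", "modal")

CONTRAST_PLACEBO_VS_TD = "adhd_placebo_vs_td"
CONTRAST_MPH_VS_TD = "adhd_mph_vs_td"
CONTRAST_MPH_VS_PLACEBO = "mph_vs_placebo"


class ModelSpec(NamedTuple):
    model_set: str
    metric: str
    context: str
    network: str


@dataclass(frozen=True)
class ModelResult:
    """One fitted contrast: estimate, standard error, two-sided p."""

    model_set: str
    metric: str
    context: str
    network: str
    contrast: str
    estimate: float
    se: float
    p: float
    n_obs: int
    n_subjects: int
    flag: str = ""

    def to_dict(self) -> dict:
        return {
            "model_set": self.model_set,
            "metric": self.metric,
            "context": self.context,
            "network": self.network,
            "contrast": self.contrast,
            "estimate": self.estimate,
            "se": self.se,
            "p": self.p,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
            "flag": self.flag,
        }


# ---------------------------------------------------------------------------
# responder filtering
# ---------------------------------------------------------------------------


def acute_responders(fd_table: pd.DataFrame) -> dict[str, set]:
    """Per-context included subject sets under the acute-response rule.

    ``fd_table`` needs columns subject_id, group, condition, context,
    mean_fd_raw (mm; FD before notch filtering, censoring and cleaning).
    A clinical subject is included for a context iff their mean raw FD
    on MPH is strictly below that on placebo for the same context
    (equality -> non-responder); a missing condition excludes the
    subject for that context.  TD subjects are always included.
    """
    required = {"subject_id", "group", "condition", "context", "mean_fd_raw"}
    missing = required - set(fd_table.columns)
    if missing:
        raise ValueError(f"fd_table is missing columns: {sorted(missing)}")
    included: dict[str, set] = {}
    for context, ctx_df in fd_table.groupby("context"):
        keep = set(ctx_df.loc[ctx_df["group"] == GROUP_TD, "subject_id"])
        adhd = ctx_df[ctx_df["group"] == GROUP_ADHD]
        for sid, sub_df in adhd.groupby("subject_id"):
            by_cond = sub_df.groupby("condition")["mean_fd_raw"].mean()
            if CONDITION_MPH not in by_cond or CONDITION_PLACEBO not in by_cond:
                continue
            if by_cond[CONDITION_MPH] < by_cond[CONDITION_PLACEBO]:
                keep.add(sid)
        included[str(context)] = keep
    return included


# ---------------------------------------------------------------------------
# model enumeration and fitting
# ---------------------------------------------------------------------------


def enumerate_models(
    networks: Sequence[str],
    contexts: Sequence[str],
    metrics: Sequence[str] = METRICS,
    sets: Sequence[str] = MODEL_SETS,
) -> list[ModelSpec]:
    """Full Cartesian enumeration of model cells (no correction applied)."""
    return [
        ModelSpec(model_set=s, metric=m, context=c, network=n)
        for s, m, c, n in product(sets, metrics, contexts, networks)
    ]


def _mixed_fit(
    endog: np.ndarray,
    exog: np.ndarray,
    groups: np.ndarray,
    names: list[str],
) -> tuple[np.ndarray, np.ndarray, int, str]:
    """REML random-intercept fit; OLS fallback when the fit is singular.

    Returns (coefficients, standard errors, df, flag).  p-values are
    computed downstream from t statistics.  The degrees of freedom
    follow the containment rule for the contrasts this package reports:
    group contrasts vary between participants, so the participant count
    (minus fixed effects), not the row count, bounds the information —
    row-based df would be anticonservative with repeated sessions.
    """
    import statsmodels.api as sm

    n_obs, k = exog.shape
    n_subjects = len(np.unique(groups))
    df_resid = max(n_subjects - k, 2)
    flag = ""
    # standardize the outcome and center the non-indicator columns for the
    # optimizer: contrast coefficients and p-values are invariant, and the
    # profiled likelihood is far better conditioned when the outcome is not
    # a tiny perturbation around a large constant
    mu, sd = float(np.mean(endog)), float(np.std(endog))
    sd = sd if sd > 0 else 1.0
    endog_z = (endog - mu) / sd
    exog_c = exog.copy()
    exog_c[:, 1:] = exog_c[:, 1:] - exog_c[:, 1:].mean(axis=0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(endog_z, exog_c, groups=groups)
            fit = model.fit(reml=True, method="lbfgs")
        if not fit.converged or not np.all(np.isfinite(fit.bse_fe)):
            raise ValueError("singular or non-converged mixed fit")
        coefs = np.asarray(fit.fe_params) * sd
        ses = np.asarray(fit.bse_fe) * sd
        coefs[0] = coefs[0] + mu  # undo outcome centering on the intercept
        return coefs, ses, df_resid, flag
    except Exception:
        flag = "ols_fallback"
        ols = sm.OLS(endog, exog).fit()
        return np.asarray(ols.params), np.asarray(ols.bse), df_resid, flag


def _p_from_t(estimate: float, se: float, df: int) -> float:
    if se == 0 or not np.isfinite(se):
        return float("nan")
    return float(2.0 * stats.t.sf(abs(estimate / se), df))


def fit_model_set(
    table: pd.DataFrame,
    model_set: str,
    metric: str,
    context: str,
    network: str,
) -> list[ModelResult]:
    """Fit one model cell and return its contrast(s).

    ``table`` is the tidy metric table with columns subject_id, group,
    condition, context, network, metric, value, age, sex, mean_fd_raw.
    TD rows must already be coded condition = placebo; responder
    filtering is assumed done upstream.
    """
    if model_set not in MODEL_SETS:
        raise ValueError(f"unknown model set {model_set!r}")
    sel = table[
        (table["metric"] == metric)
        & (table["context"] == context)
        & (table["network"] == network)
    ].copy()
    if model_set == "within_adhd":
        sel = sel[sel["group"] == GROUP_ADHD]
    if sel.empty or sel["subject_id"].nunique() < 4:
        raise ValueError(
            f"too few subjects ({sel['subject_id'].nunique()}) for "
            f"{model_set}/{metric}/{context}/{network}"
        )

    endog = sel["value"].to_numpy(dtype=float)
    covars = sel[["age", "sex", "mean_fd_raw"]].to_numpy(dtype=float)
    groups = sel["subject_id"].to_numpy()
    n_subjects = sel["subject_id"].nunique()

    if model_set == "group_comparison":
        is_placebo = (
            (sel["group"] == GROUP_ADHD) & (sel["condition"] == CONDITION_PLACEBO)
        ).to_numpy(dtype=float)
        is_mph = (
            (sel["group"] == GROUP_ADHD) & (sel["condition"] == CONDITION_MPH)
        ).to_numpy(dtype=float)
        exog = np.column_stack([np.ones(len(sel)), is_placebo, is_mph, covars])
        names = ["intercept", CONTRAST_PLACEBO_VS_TD, CONTRAST_MPH_VS_TD]
        contrast_cols = {CONTRAST_PLACEBO_VS_TD: 1, CONTRAST_MPH_VS_TD: 2}
    else:
        is_mph = (sel["condition"] == CONDITION_MPH).to_numpy(dtype=float)
        exog = np.column_stack([np.ones(len(sel)), is_mph, covars])
        names = ["intercept", CONTRAST_MPH_VS_PLACEBO]
        contrast_cols = {CONTRAST_MPH_VS_PLACEBO: 1}

    coefs, ses, df_resid, flag = _mixed_fit(endog, exog, groups, names)
    results = []
    for contrast, col in contrast_cols.items():
        est, se = float(coefs[col]), float(ses[col])
        results.append(
            ModelResult(
                model_set=model_set,
                metric=metric,
                context=context,
                network=network,
                contrast=contrast,
                estimate=est,
                se=se,
                p=_p_from_t(est, se, df_resid),
                n_obs=len(sel),
                n_subjects=n_subjects,
                flag=flag,
            )
        )
    return results


def fit_all_models(
    table: pd.DataFrame,
    networks: Sequence[str],
    contexts: Sequence[str],
    metrics: Sequence[str] = METRICS,
    sets: Sequence[str] = MODEL_SETS,
) -> pd.DataFrame:
    """Fit every enumerated cell; failures become flagged rows, not gaps."""
    rows = []
    for spec in enumerate_models(networks, contexts, metrics, sets):
        try:
            for res in fit_model_set(table, *spec):
                rows.append(res.to_dict())
        except Exception as exc:
            rows.append(
                ModelResult(
                    *spec,
                    contrast="(failed)",
                    estimate=float("nan"),
                    se=float("nan"),
                    p=float("nan"),
                    n_obs=0,
                    n_subjects=0,
                    flag=f"error: {exc}",
                ).to_dict()
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# descriptive statistics from summaries
# ---------------------------------------------------------------------------


def summary_ttest(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sample t-test from summary statistics; two-sided p.

    Defaults to the pooled (Student) form, which reproduces the
    demographic comparisons this package targets; set
    ``equal_var=False`` for the Welch form.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    t, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var)
    return float(t), float(p)


def chisq_independence(table: Iterable[Iterable[int]]) -> tuple[float, float]:
    """Pearson chi-squared test of independence, no continuity correction.

    For a 2 x 2 table df = 1.  Requires nonnegative integer counts and
    strictly positive margins.
    """
    arr = np.asarray(list(map(list, table)), dtype=float)
    if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be nonnegative integers")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("chi-squared test undefined for zero margins")
    res = stats.chi2_contingency(arr, correction=False)
    return float(res.statistic), float(res.pvalue)
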
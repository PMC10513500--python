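"""Biomarker prognostics: dichotomization, Cox regression, log-rank, KM.

Each methylation biomarker is dichotomized into high/low groups at the
candidate cut-off (mean, median, lower or upper quartile) whose Cox model
yields the largest |log HR| for the methylation-group coefficient, subject
to a minimum group-size floor.  Cox models adjust for age, sex, and tumor
subgroup (one-hot against a reference class, default WNT) and use Efron
tie handling; model fit is assessed with both the likelihood-ratio and
Wald tests.  All survival machinery is backed by lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "CoxResult",
    "dichotomize_best",
    "cox_fit",
    "logrank",
    "km_curve",
]

CUTOFF_CANDIDATES = ("mean", "median", "lower_quartile", "upper_quartile")


@dataclass
class CoxResult:
    """Fitted Cox model summary for one biomarker.

    ``summary`` has one row per coefficient with columns
    (coef, hr, hr_lower_95, hr_upper_95, wald_p); ``lr_p`` is the
    likelihood-ratio test p-value for the whole model.
    """

    summary: pd.DataFrame
    lr_p: float
    cutoff: str | None = None
    cutoff_value: float | None = None
    group_sizes: dict[str, int] | None = None

    @property
    def marker_hr(self) -> float:
        return float(self.summary.loc["meth_high", "hr"])

    @property
    def marker_log_hr(self) -> float:
        return float(self.summary.loc["meth_high", "coef"])


def _design_matrix(
    table: pd.DataFrame, covariates: bool, reference_subgroup: str
) -> pd.DataFrame:
    df = pd.DataFrame(
        {"time": table["time"].to_numpy(dtype=float),
         "event": table["event"].to_numpy(dtype=int)}
    )
    if covariates:
        if "age" in table:
            df["age"] = table["age"].to_numpy(dtype=float)
        if "sex" in table:
            sex = table["sex"].astype(str)
            df["sex_male"] = (sex.str.upper().str.startswith("M")).astype(float).to_numpy()
        if "subgroup" in table:
            sub = table["subgroup"].astype(str)
            levels = [g for g in sorted(sub.unique()) if g != reference_subgroup]
            for g in levels:
                df[f"subgroup_{g}"] = (sub == g).astype(float).to_numpy()
    # drop zero-variance covariates silently except the marker handled later
    return df


def cox_fit(
    table: pd.DataFrame,
    group: np.ndarray | pd.Series | None = None,
    covariates: bool = True,
    reference_subgroup: str = "WNT",
) -> CoxResult:
    """Multivariate Cox proportional hazards fit (Efron ties).

    ``table`` needs columns (time, event) and, when ``covariates`` is
    true, any of (age, sex, subgroup).  ``group`` is the binary
    high-methylation indicator entering as the ``meth_high`` coefficient.
    """
    if (table["time"] <= 0).any():
        raise ValueError("survival times must be > 0")
    df = _design_matrix(table, covariates, reference_subgroup)
    if group is not None:
        df.insert(2, "meth_high", np.asarray(group, dtype=float))
    covar_cols = [c for c in df.columns if c not in ("time", "event")]
    for c in covar_cols:
        if df[c].nunique() <= 1:
            raise ValueError(f"covariate {c!r} has zero variance")
    n_events = int(df["event"].sum())
    if n_events < 5 * len(covar_cols):
        import warnings

        warnings.warn(
            f"only {n_events} events for {len(covar_cols)} coefficients; "
            "estimates may be unstable"
        )
    cph = CoxPHFitter()
    try:
        # tight Newton tolerance so small-sample estimates agree with the
        # partial likelihood optimum to ~1e-8
        cph.fit(df, duration_col="time", event_col="event",
                fit_options={"precision": 1e-9})
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "hr_lower_95": s["exp(coef) lower 95%"],
            "hr_upper_95": s["exp(coef) upper 95%"],
            "wald_p": s["p"],
        }
    )
    lr_p = float(cph.log_likelihood_ratio_test().p_value)
    return CoxResult(summary=summary, lr_p=lr_p)


def dichotomize_best(
    marker: pd.Series | np.ndarray,
    table: pd.DataFrame,
    candidates=CUTOFF_CANDIDATES,
    min_group_frac: float = 0.1,
    covariates: bool = True,
    reference_subgroup: str = "WNT",
) -> tuple[np.ndarray, str, CoxResult]:
    """Choose the cut-off maximizing |log HR| of the methylation group.

    Each candidate cut-off (mean, median, quartiles) splits samples into
    high (> cut-off) and low groups; candidates leaving either group below
    ``min_group_frac`` of the cohort are discarded; among the rest the fit
    with maximal |log HR| on the ``meth_high`` coefficient wins.
    """
    marker = np.asarray(marker, dtype=float)
    n = len(marker)
    if n < 20:
        raise ValueError("need >= 20 samples for cut-off selection")
    if int(table["event"].sum()) < 5:
        raise ValueError("need >= 5 events for cut-off selection")
    cut_values = {
        "mean": float(np.mean(marker)),
        "median": float(np.median(marker)),
        "lower_quartile": float(np.percentile(marker, 25)),
        "upper_quartile": float(np.percentile(marker, 75)),
    }
    best: tuple[float, str, np.ndarray, CoxResult] | None = None
    for name in candidates:
        cut = cut_values[name]
        high = (marker > cut).astype(int)
        n_high = int(high.sum())
        if min(n_high, n - n_high) < min_group_frac * n:
            continue
        try:
            result = cox_fit(
                table, group=high, covariates=covariates,
                reference_subgroup=reference_subgroup,
            )
        except (RuntimeError, ValueError):
            continue
        score = abs(result.marker_log_hr)
        if best is None or score > best[0]:
            result.cutoff = name
            result.cutoff_value = cut
            result.group_sizes = {"high": n_high, "low": n - n_high}
            best = (score, name, high, result)
    if best is None:
        raise ValueError(
            "no candidate cut-off satisfies the group-size floor "
            f"(min_group_frac={min_group_frac})"
        )
    _, name, high, result = best
    return high, name, result


def logrank(table: pd.DataFrame, groups) -> tuple[float, float]:
    """Log-rank test across >= 2 groups; (chi-square statistic, p-value)."""
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise ValueError("log-rank test needs >= 2 groups")
    if int(table["event"].sum()) < 1:
        raise ValueError("log-rank test needs >= 1 event")
    res = multivariate_logrank_test(
        table["time"].to_numpy(dtype=float), groups, table["event"].to_numpy(dtype=int)
    )
    return float(res.test_statistic), float(res.p_value)


def km_curve(table: pd.DataFrame, groups) -> pd.DataFrame:
    """Kaplan-Meier step functions per group.

    Returns rows (group, time, survival, at_risk); survival starts at 1,
    is non-increasing, and steps only at event times.
    """
    groups = np.asarray(groups)
    frames = []
    for g in pd.unique(groups):
        mask = groups == g
        km = KaplanMeierFitter()
        km.fit(
            table.loc[mask, "time"].to_numpy(dtype=float),
            table.loc[mask, "event"].to_numpy(dtype=int),
        )
        ev = km.event_table
        frames.append(
            pd.DataFrame(
                {
                    "group": g,
                    "time": km.survival_function_.index.to_numpy(dtype=float),
                    "survival": km.survival_function_.iloc[:, 0].to_numpy(dtype=float),
                    "at_risk": ev["at_risk"].reindex(km.survival_function_.index).to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
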
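"""Group comparisons, correlations and scan–rescan agreement statistics.

Operates on tidy regional-median tables: one row per (subject, side,
region) with the regional median T2*, the pixel-count volume and the
subject covariates (age, sex, BMI).  Group contrasts use a linear
mixed-effects model with a subject-level random intercept when subjects
contribute several rows; reproducibility uses the single-measure two-way
absolute-agreement intraclass correlation ICC(A,1) together with
Bland–Altman limits of agreement and a one-sample t-test on the paired
differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .errors import ModelError, ValidationError

REQUIRED_TABLE_COLUMNS = ("subject_id", "group", "side", "region", "median_t2star_ms")

# Cohort demographics used by the simulators: age mean/SD, fraction female,
# BMI mean (published); BMI SD is not published and is set to a typical
# adult dispersion of 4 kg/m^2.
COHORT_DEMOGRAPHICS = {
    "patient": {"age_mean": 53.0, "age_sd": 8.0, "female_frac": 0.8,
                "bmi_mean": 28.1, "bmi_sd": 4.0},
    "control": {"age_mean": 53.0, "age_sd": 12.0, "female_frac": 0.8,
                "bmi_mean": 25.5, "bmi_sd": 4.0},
}


def validate_region_table(df: pd.DataFrame, require_covariates: bool = False) -> None:
    missing = [c for c in REQUIRED_TABLE_COLUMNS if c not in df.columns]
    if require_covariates:
        missing += [c for c in ("age", "sex", "bmi") if c not in df.columns]
    if missing:
        raise ValidationError(f"region table is missing columns: {missing}")
    dup = df.duplicated(subset=["subject_id", "side", "region"])
    if dup.any():
        raise ValidationError("(subject, side, region) rows must be unique")


@dataclass
class GroupComparison:
    """Fixed-effect contrast patient − control with its Wald inference."""

    estimate: float
    se: float
    pvalue: float
    n_obs: int
    n_subjects: int
    method: str  # "mixedlm" when subjects have replicate rows, else "ols"


def _design(df: pd.DataFrame, covariates: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(df)), (df["group"] == "patient").to_numpy(float)]
    names = ["intercept", "group[patient]"]
    for c in covariates:
        v = df[c]
        if v.dtype.kind in "OUSb" or isinstance(v.dtype, pd.CategoricalDtype):
            levels = sorted(v.astype(str).unique())
            for lev in levels[1:]:
                cols.append((v.astype(str) == lev).to_numpy(float))
                names.append(f"{c}[{lev}]")
        else:
            cols.append(v.to_numpy(float))
            names.append(c)
    return np.column_stack(cols), names


def compare_groups(
    table: pd.DataFrame,
    region: str | None = None,
    side: str | None = None,
    response: str = "median_t2star_ms",
    covariates: Sequence[str] = ("age", "sex", "bmi"),
) -> GroupComparison:
    """Patient-vs-control contrast of ``response`` adjusted for covariates.

    Fits ``response ~ group + age + sex + bmi`` with a subject-level random
    intercept (REML) when subjects contribute multiple rows after filtering
    (e.g. all four regions pooled).  With one row per subject the random
    intercept is not identifiable and the model collapses to its ordinary
    least-squares equivalent; inference then uses the exact t distribution.
    """
    df = table
    if region is not None:
        df = df[df["region"] == region]
    if side is not None:
        df = df[df["side"] == side]
    df = df.dropna(subset=[response]).reset_index(drop=True)
    for c in covariates:
        if c not in df.columns:
            raise ModelError(f"covariate {c!r} missing from the table")
    groups_present = set(df["group"].unique())
    if not {"patient", "control"} <= groups_present:
        raise ModelError(f"both groups required, found {sorted(groups_present)}")

    X, names = _design(df, covariates)
    y = df[response].to_numpy(float)
    j = names.index("group[patient]")
    per_subject = df.groupby("subject_id").size()
    n_subjects = len(per_subject)

    if per_subject.max() > 1:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM(y, X, groups=df["subject_id"].to_numpy())
                res = model.fit(reml=True)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - rare
            raise ModelError(f"mixed model failed: {exc}") from exc
        est, se = float(res.fe_params[j]), float(res.bse_fe[j])
        p = float(res.pvalues[j])
        method = "mixedlm"
    else:
        try:
            res = sm.OLS(y, X).fit()
        except np.linalg.LinAlgError as exc:
            raise ModelError(f"singular design: {exc}") from exc
        if res.df_resid <= 0 or not np.isfinite(res.bse[j]):
            raise ModelError("design is singular or has no residual degrees of freedom")
        est, se, p = float(res.params[j]), float(res.bse[j]), float(res.pvalues[j])
        method = "ols"
    return GroupComparison(estimate=est, se=se, pvalue=p,
                           n_obs=len(df), n_subjects=n_subjects, method=method)


def bonferroni_pairwise(pvalues: Sequence[float], m: int) -> list[float]:
    """Bonferroni adjustment p_adj = min(1, p·m), order preserved.

    This is the correction SPSS applies under the "Dunn-Bonferroni" label
    for pairwise contrasts (m = 6 for the four regions).
    """
    if m < 1 or int(m) != m:
        raise ValidationError("m must be a positive integer")
    out = []
    for p in pvalues:
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"p-value {p} outside [0, 1]")
        out.append(min(1.0, float(p) * m))
    return out


class PearsonResult(NamedTuple):
    r: float
    ci_low: float
    ci_high: float
    pvalue: float
    n: int


def pearson_ci(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """Sample Pearson r with Fisher-z 95% CI and two-sided t-test p-value.

    CI: tanh(arctanh(r) ± 1.96/sqrt(n−3)); p from t = r·sqrt((n−2)/(1−r²))
    on n−2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D and paired")
    n = x.size
    if n < 3:
        raise ValidationError("need at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("values must be finite")
    xc, yc = x - x.mean(), y - y.mean()
    sx = np.sqrt((xc * xc).sum())
    sy = np.sqrt((yc * yc).sum())
    if sx == 0 or sy == 0:
        raise ValidationError("correlation undefined: zero variance")
    r = float(np.clip((xc * yc).sum() / (sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * scipy.stats.t.sf(abs(t), n - 2))
    if n > 3 and abs(r) < 1.0:
        hw = 1.96 / np.sqrt(n - 3)
        z = np.arctanh(r)
        lo, hi = float(np.tanh(z - hw)), float(np.tanh(z + hw))
    else:
        lo, hi = (r, r) if abs(r) == 1.0 else (-1.0, 1.0)
    return PearsonResult(r=r, ci_low=lo, ci_high=hi, pvalue=p, n=n)


class BlandAltman(NamedTuple):
    mean_difference: float
    sd_difference: float
    lower_loa: float  # d − 1.96·SD
    upper_loa: float  # d + 1.96·SD


@dataclass
class AgreementResult:
    """ICC(A,1) with 95% CI plus Bland–Altman and paired t-test outputs."""

    icc: float
    ci_low: float
    ci_high: float
    bland_altman: BlandAltman
    t_p: float
    n: int


def icc_absolute_agreement(
    scan1: Sequence[float], scan2: Sequence[float], alpha: float = 0.05
) -> AgreementResult:
    """Single-measure two-way absolute-agreement ICC(A,1) for scan–rescan pairs.

    From the two-way ANOVA decomposition with n subjects and k = 2
    measurements:

        ICC(A,1) = (MS_R − MS_E) / (MS_R + (k−1)·MS_E + (k/n)(MS_C − MS_E))

    Unlike consistency forms, a constant offset between the two scans
    lowers the coefficient.  The CI uses the standard F-distribution bounds
    (Satterthwaite degrees of freedom for the column/error mixture).
    Bland–Altman fields use differences rescan − scan; ``t_p`` is the
    one-sample t-test for zero mean difference (1.0 by convention for
    identical scans, where the test statistic is undefined).
    """
    x1 = np.asarray(scan1, dtype=float)
    x2 = np.asarray(scan2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValidationError("scan1 and scan2 must be paired 1-D sequences")
    n = x1.size
    if n < 3:
        raise ModelError("need at least 3 paired subjects")
    X = np.column_stack([x1, x2])
    k = 2
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((X - grand) ** 2).sum())
    ss_err = max(ss_total - ss_rows - ss_cols, 0.0)
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = 1.0 if denom == 0 else float((msr - mse) / denom)

    if mse == 0 and msc == 0:
        lo, hi = icc, icc  # degenerate: identical scans
    else:
        a = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        if np.isinf(a):
            lo, hi = icc, icc
        else:
            b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc))
            num = (a * msc + b * mse) ** 2
            den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            v = num / den
            f_l = scipy.stats.f.ppf(1 - alpha / 2, n - 1, v)
            f_u = scipy.stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (msr - f_l * mse) / (
                f_l * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            hi = n * (f_u * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f_u * msr
            )
            lo, hi = float(max(-1.0, lo)), float(min(1.0, hi))

    diffs = x2 - x1
    d = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    if sd == 0:
        t_p = 1.0 if d == 0 else 0.0
    else:
        t_p = float(scipy.stats.ttest_1samp(diffs, 0.0).pvalue)
    ba = BlandAltman(mean_difference=d, sd_difference=sd,
                     lower_loa=d - 1.96 * sd, upper_loa=d + 1.96 * sd)
    return AgreementResult(icc=icc, ci_low=lo, ci_high=hi,
                           bland_altman=ba, t_p=t_p, n=n)


def _draw_covariates(rng: np.random.Generator, group: str, n: int) -> pd.DataFrame:
    demo = COHORT_DEMOGRAPHICS[group]
    return pd.DataFrame(
        {
            "age": rng.normal(demo["age_mean"], demo["age_sd"], n),
            "sex": np.where(rng.random(n) < demo["female_frac"], "F", "M"),
            "bmi": rng.normal(demo["bmi_mean"], demo["bmi_sd"], n),
        }
    )


def simulate_group_table(
    seed: int,
    mean_patient: float,
    sd_patient: float,
    mean_control: float,
    sd_control: float,
    n_patient: int = 20,
    n_control: int = 10,
    region: str = "PH",
    side: str = "medial",
) -> pd.DataFrame:
    """Single-region cohort: per-subject regional medians + matched covariates.

    Patient and control medians are drawn from normal distributions with the
    given means/SDs at the study sample sizes (20 patients, 10 controls by
    default)."""
    rng = np.random.default_rng(seed)
    rows = []
    for group, mean, sd, n in (
        ("patient", mean_patient, sd_patient, n_patient),
        ("control", mean_control, sd_control, n_control),
    ):
        cov = _draw_covariates(rng, group, n)
        vals = rng.normal(mean, sd, n)
        for i in range(n):
            rows.append(
                {
                    "subject_id": f"{group[0]}{i:03d}",
                    "group": group,
                    "side": side,
                    "region": region,
                    "median_t2star_ms": vals[i],
                    "age": cov["age"][i],
                    "sex": cov["sex"][i],
                    "bmi": cov["bmi"][i],
                }
            )
    return pd.DataFrame(rows)


def simulate_cohort_table(
    seed: int,
    region_params_patient: dict[str, tuple[float, float]],
    region_params_control: dict[str, tuple[float, float]],
    n_patient: int = 20,
    n_control: int = 10,
    side: str = "medial",
    subject_corr: float = 0.5,
) -> pd.DataFrame:
    """Four-region cohort with a shared subject effect.

    Each subject's four regional medians share a latent subject component
    contributing a fraction ``subject_corr`` of each region's variance, so
    pooled-region model fits exercise the random intercept."""
    rng = np.random.default_rng(seed)
    rows = []
    for group, params, n in (
        ("patient", region_params_patient, n_patient),
        ("control", region_params_control, n_control),
    ):
        cov = _draw_covariates(rng, group, n)
        u = rng.normal(0.0, 1.0, n)
        for i in range(n):
            for reg, (mean, sd) in params.items():
                val = mean + sd * (
                    np.sqrt(subject_corr) * u[i]
                    + np.sqrt(1.0 - subject_corr) * rng.normal()
                )
                rows.append(
                    {
                        "subject_id": f"{group[0]}{i:03d}",
                        "group": group,
                        "side": side,
                        "region": reg,
                        "median_t2star_ms": val,
                        "age": cov["age"][i],
                        "sex": cov["sex"][i],
                        "bmi": cov["bmi"][i],
                    }
                )
    return pd.DataFrame(rows)
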
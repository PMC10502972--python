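"""Longitudinal two-arm cohort simulation and statistics for subfoveal
choroidal thickness (SfChT).

The simulator emulates a two-year myopia-control trial: a treated arm
wearing defocus-incorporated-multiple-segments (DIMS) spectacle lenses
and a control arm wearing single-vision (SV) lenses, with SfChT measured
at baseline, 1 week, and 1, 3, 6, 12, 18 and 24 months, and axial length
(AL) plus spherical-equivalent refraction (SER) measured six-monthly.
Choroidal thickening is generated as a per-visit group mean shift on top
of each subject's baseline; axial elongation is generated from a linear
model on age, gender and the subject's short-term choroidal change, with
a negative choroid→elongation coefficient (a thicker choroid accompanies
slower eye growth).

The analysis functions compute change-from-baseline tables,
baseline-covariate-adjusted group mean changes with standard errors,
percent change relative to baseline, Pearson associations, and the
hierarchical (blockwise) multiple regression that asks whether short-term
choroidal change predicts 12-month axial elongation beyond age and
gender.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "VISITS", "MEASURED_6MONTHLY", "CohortSpec", "HierRegressionReport",
    "simulate_cohort", "change_from_baseline", "adjusted_group_change",
    "percent_change", "pearson_r", "hierarchical_regression",
]

logger = logging.getLogger(__name__)

VISITS = ["baseline", "1w", "1m", "3m", "6m", "12m", "18m", "24m"]
#: visits at which AL and SER are measured (six-monthly schedule)
MEASURED_6MONTHLY = ["baseline", "6m", "12m", "18m", "24m"]
_VISIT_MONTHS = {"baseline": 0.0, "1w": 0.25, "1m": 1.0, "3m": 3.0,
                 "6m": 6.0, "12m": 12.0, "18m": 18.0, "24m": 24.0}


def _default_changes() -> dict:
    # Mean SfChT change from baseline (µm) per visit and arm.  The DIMS
    # arm thickens rapidly in the first weeks, keeps rising through the
    # first year and plateaus; the SV arm thins steadily over two years.
    return {
        "1w": {"DIMS": 6.75, "SV": -3.17},
        "1m": {"DIMS": 8.58, "SV": -4.30},
        "3m": {"DIMS": 10.40, "SV": -5.90},
        "6m": {"DIMS": 12.10, "SV": -7.60},
        "12m": {"DIMS": 13.64, "SV": -9.46},
        "18m": {"DIMS": 14.80, "SV": -11.10},
        "24m": {"DIMS": 14.50, "SV": -12.40},
    }


@dataclass
class CohortSpec:
    """Generative parameters of the simulated cohort.

    Defaults match the trial arms being emulated: 78 DIMS and 80 SV
    subjects, baseline SfChT 280.95 ± 54.30 µm (DIMS) vs 259.53 ± 49.36
    µm (SV), ages around 10 years.  ``visit_changes`` maps visit →
    {arm → mean change in µm}.  ``choroid_to_al``/``choroid_to_al_24m``
    are the (negative) mm-per-µm couplings of choroidal change into
    12-month and 24-month axial elongation.
    """

    n_dims: int = 78
    n_sv: int = 80
    baseline_mean: dict = field(
        default_factory=lambda: {"DIMS": 280.95, "SV": 259.53})
    baseline_sd: dict = field(
        default_factory=lambda: {"DIMS": 54.30, "SV": 49.36})
    visit_changes: dict = field(default_factory=_default_changes)
    subject_response_sd: float = 8.0  # µm, per-subject responsiveness,
    # shared across that subject's follow-up visits
    visit_noise_sd: float = 10.0  # µm, independent per-visit noise
    age_mean: dict = field(default_factory=lambda: {"DIMS": 10.20, "SV": 10.00})
    age_sd: dict = field(default_factory=lambda: {"DIMS": 1.47, "SV": 1.45})
    male_fraction: dict = field(
        default_factory=lambda: {"DIMS": 0.582, "SV": 0.543})
    al_baseline_mean: dict = field(
        default_factory=lambda: {"DIMS": 24.70, "SV": 24.60})
    al_baseline_sd: dict = field(default_factory=lambda: {"DIMS": 0.82, "SV": 0.83})
    ser_baseline_mean: dict = field(
        default_factory=lambda: {"DIMS": -2.97, "SV": -2.76})
    ser_baseline_sd: dict = field(default_factory=lambda: {"DIMS": 0.97, "SV": 0.96})
    # 12-month axial-elongation model: ΔAL12 = a0 + a_age·age + a_gender·g
    #                                        + choroid_to_al·ΔSfChT(3m) + ε
    al_intercept: float = 0.67
    al_age_coef: float = -0.025  # mm per year of age
    al_gender_coef: float = -0.010  # mm (male = 1)
    choroid_to_al: float = -0.0020  # mm per µm of 3-month choroid change
    choroid_to_al_24m: float = -0.0030  # mm per µm of 24-month change
    al_noise_sd: float = 0.12  # mm
    ser_per_mm: float = -1.8  # dioptres of SER change per mm elongation
    ser_noise_sd: float = 0.15  # dioptres
    seed: int = 0

    def validate(self) -> None:
        if self.n_dims < 2 or self.n_sv < 2:
            raise ValueError("need at least 2 subjects per group")
        for d in (self.baseline_sd, self.age_sd, self.al_baseline_sd,
                  self.ser_baseline_sd):
            if any(v < 0 for v in d.values()):
                raise ValueError("standard deviations must be non-negative")
        if (self.visit_noise_sd < 0 or self.subject_response_sd < 0
                or self.al_noise_sd < 0 or self.ser_noise_sd < 0):
            raise ValueError("noise SDs must be non-negative")
        missing = [v for v in VISITS[1:] if v not in self.visit_changes]
        if missing:
            raise ValueError(f"visit_changes missing visits: {missing}")


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate one cohort as a long-format table of visit records.

    Columns: subject, group, age, gender, visit, sfcht (µm),
    axial_length (mm, six-monthly else NaN), ser (D, six-monthly else
    NaN).  Deterministic for a fixed ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for group, n in (("DIMS", spec.n_dims), ("SV", spec.n_sv)):
        base = rng.normal(spec.baseline_mean[group], spec.baseline_sd[group], n)
        age = rng.normal(spec.age_mean[group], spec.age_sd[group], n)
        male = rng.random(n) < spec.male_fraction[group]
        al0 = rng.normal(spec.al_baseline_mean[group],
                         spec.al_baseline_sd[group], n)
        ser0 = rng.normal(spec.ser_baseline_mean[group],
                          spec.ser_baseline_sd[group], n)

        # per-subject choroid change at each follow-up: group trend plus a
        # consistent per-subject responsiveness plus per-visit noise
        responder = rng.normal(0.0, spec.subject_response_sd, n)
        ch = {"baseline": np.zeros(n)}
        for visit in VISITS[1:]:
            mu = spec.visit_changes[visit][group]
            ch[visit] = mu + responder + rng.normal(0.0, spec.visit_noise_sd, n)

        # axial elongation, anchored at 12 and 24 months
        d_al12 = (spec.al_intercept + spec.al_age_coef * age
                  + spec.al_gender_coef * male
                  + spec.choroid_to_al * ch["3m"]
                  + rng.normal(0.0, spec.al_noise_sd, n))
        d_al24 = (1.55 * d_al12 + spec.choroid_to_al_24m * ch["24m"]
                  + rng.normal(0.0, spec.al_noise_sd, n))
        d_al = {
            "baseline": np.zeros(n),
            "6m": 0.55 * d_al12 + rng.normal(0.0, 0.03, n),
            "12m": d_al12,
            "18m": 0.5 * (d_al12 + d_al24) + rng.normal(0.0, 0.03, n),
            "24m": d_al24,
        }

        for i in range(n):
            sid = f"{group}-{i:03d}"
            for visit in VISITS:
                six_monthly = visit in MEASURED_6MONTHLY
                elong = d_al[visit][i] if six_monthly else np.nan
                rows.append({
                    "subject": sid,
                    "group": group,
                    "age": round(float(age[i]), 2),
                    "gender": "M" if male[i] else "F",
                    "visit": visit,
                    "sfcht": float(np.maximum(base[i] + ch[visit][i], 1.0)),
                    "axial_length": (float(al0[i] + elong)
                                     if six_monthly else np.nan),
                    "ser": (float(ser0[i] + spec.ser_per_mm * elong
                                  + (rng.normal(0.0, spec.ser_noise_sd)
                                     if visit != "baseline" else 0.0))
                            if six_monthly else np.nan),
                })
    return pd.DataFrame(rows)


def change_from_baseline(
    records: pd.DataFrame,
    value_cols: tuple[str, ...] = ("sfcht", "axial_length", "ser"),
) -> pd.DataFrame:
    """Per-subject change of each variable relative to its baseline visit.

    Subjects without a baseline record are excluded with a logged
    warning.  Baseline rows (all-zero changes) are not emitted.
    """
    records = records.copy()
    have_baseline = set(
        records.loc[records["visit"] == "baseline", "subject"])
    missing = sorted(set(records["subject"]) - have_baseline)
    if missing:
        logger.warning("excluding %d subject(s) without baseline: %s",
                       len(missing), ", ".join(missing[:5]))
        records = records[records["subject"].isin(have_baseline)]
    base = (records[records["visit"] == "baseline"]
            .set_index("subject")[list(value_cols)])
    out = records[records["visit"] != "baseline"].copy()
    for col in value_cols:
        out[f"d_{col}"] = out[col].to_numpy() - base.loc[
            out["subject"], col].to_numpy()
        out[f"baseline_{col}"] = base.loc[out["subject"], col].to_numpy()
    keep = (["subject", "group", "age", "gender", "visit"]
            + [f"d_{c}" for c in value_cols]
            + [f"baseline_{c}" for c in value_cols])
    return out[keep].reset_index(drop=True)


def adjusted_group_change(
    changes: np.ndarray,
    baselines: np.ndarray,
    groups: np.ndarray,
) -> dict:
    """Baseline-covariate-adjusted group mean changes at one visit.

    Fits change ~ group + (baseline − mean baseline) by least squares and
    reports, per group, the adjusted mean (the model prediction at the
    grand-mean baseline) with its standard error, plus the adjusted
    between-group difference ± SE and its two-sided p-value.
    """
    changes = np.asarray(changes, float)
    baselines = np.asarray(baselines, float)
    groups = np.asarray(groups)
    names = sorted(set(groups.tolist()))
    if len(names) != 2:
        raise ValueError("exactly two groups are required")
    if min((groups == g).sum() for g in names) < 2:
        raise ValueError("need at least 2 subjects per group")
    ind = (groups == names[1]).astype(float)
    bc = baselines - baselines.mean()
    use_covariate = np.ptp(baselines) > 0
    cols = [ind, bc] if use_covariate else [ind]
    X = sm.add_constant(np.column_stack(cols))
    fit = sm.OLS(changes, X).fit()
    # adjusted means: prediction at baseline = grand mean (bc = 0)
    out = {}
    cov = fit.cov_params()
    for g, x_ind in ((names[0], 0.0), (names[1], 1.0)):
        w = np.zeros(X.shape[1])
        w[0], w[1] = 1.0, x_ind
        out[g] = {
            "adjusted_mean": float(w @ fit.params),
            "sem": float(np.sqrt(w @ cov @ w)),
        }
    out["difference"] = {
        "groups": f"{names[1]} - {names[0]}",
        "estimate": float(fit.params[1]),
        "sem": float(fit.bse[1]),
        "p_value": float(fit.pvalues[1]),
    }
    return out


def percent_change(change: float, baseline: float, ndigits: int = 1) -> float:
    """Change relative to baseline, as a percentage rounded for display
    (e.g. a 6.75 µm thickening on a 280.95 µm baseline is 2.4%)."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return round(100.0 * change / baseline, ndigits)


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient of two paired sequences."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length 1-D sequences of >= 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate variance: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class HierRegressionReport:
    """Two nested standardized regression models and the variance the
    candidate block adds."""

    r2_base: float
    r2_full: float
    betas_base: dict
    betas_full: dict
    pvalues_base: dict
    pvalues_full: dict
    n: int

    @property
    def delta_r2(self) -> float:
        return self.r2_full - self.r2_base

    def significant(self, name: str, alpha: float = 0.05) -> bool:
        return self.pvalues_full[name] < alpha


def _zscore(a: np.ndarray) -> np.ndarray:
    sd = a.std(ddof=1)
    if sd == 0:
        raise ValueError("constant predictor: cannot standardize")
    return (a - a.mean()) / sd


def hierarchical_regression(
    data: pd.DataFrame,
    outcome: str,
    base_block: tuple[str, ...] = ("age", "gender"),
    candidate: str = "d_sfcht_3m",
) -> HierRegressionReport:
    """Blockwise multiple regression with standardized coefficients.

    Model 1 regresses the (z-scored) outcome on the z-scored base block;
    Model 2 adds the candidate predictor.  Gender is coded male=1,
    female=0 before standardization.  Reports R² per model, their
    difference (ΔR², the variance uniquely explained by the candidate),
    standardized betas and two-sided coefficient p-values.
    """
    cols = [outcome, *base_block, candidate]
    work = data[cols].dropna().copy()
    if "gender" in work.columns and work["gender"].dtype == object:
        work["gender"] = (work["gender"] == "M").astype(float)
    n = len(work)
    if n < len(cols) + 2:
        raise ValueError(f"too few complete cases ({n}) for {len(cols) - 1} "
                         "predictors")
    z = {c: _zscore(work[c].to_numpy(float)) for c in cols}
    y = z[outcome]

    def fit_block(names):
        X = sm.add_constant(np.column_stack([z[c] for c in names]))
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("collinear design matrix")
        fit = sm.OLS(y, X).fit()
        betas = {c: float(b) for c, b in zip(names, fit.params[1:])}
        pvals = {c: float(p) for c, p in zip(names, fit.pvalues[1:])}
        return float(fit.rsquared), betas, pvals

    r2_base, betas_base, p_base = fit_block(list(base_block))
    r2_full, betas_full, p_full = fit_block(list(base_block) + [candidate])
    return HierRegressionReport(
        r2_base=r2_base, r2_full=r2_full,
        betas_base=betas_base, betas_full=betas_full,
        pvalues_base=p_base, pvalues_full=p_full, n=n,
    )
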
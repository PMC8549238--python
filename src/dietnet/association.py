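"""Obesity classification, tertile odds ratios, trend tests and descriptives.

General adiposity is BMI >= 30 kg/m2; abdominal adiposity is waist
circumference > 102 cm (men) / > 88 cm (women) or waist-to-hip ratio
> 0.90 (men) / > 0.85 (women). Odds ratios of each outcome across network
score tertiles (T1 reference) come from maximum-likelihood logistic
regression, crude or adjusted for the configured covariates, with Wald 95%
confidence intervals. The trend test refits the model with the tertile
index (1, 2, 3) as a single continuous term and reports its Wald p-value.

This module also carries the survey sample-size formula n = p q z^2 / E^2
used at the design stage of prevalence studies.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

__all__ = [
    "AssociationResult",
    "DEFAULT_ADJUSTMENT",
    "classify_obesity",
    "fit_tertile_logistic",
    "p_for_trend",
    "tertile_descriptives",
    "compute_sample_size",
    "association_table",
]

#: Default adjustment set for the maximally adjusted model.
DEFAULT_ADJUSTMENT = (
    "age",
    "sex",
    "occupation",
    "smoking",
    "education",
    "marital",
    "menopause",
    "physical_activity",
    "energy",
)

#: Covariates treated as categorical in the design matrix.
CATEGORICAL_COVARIATES = frozenset(
    {"sex", "occupation", "smoking", "education", "marital", "menopause", "physical_activity"}
)

OBESITY_OUTCOMES = ("general", "central_wc", "central_whr")


@dataclasses.dataclass
class AssociationResult:
    """Tertile odds ratios for one network and one outcome."""

    network: str
    outcome: str
    model: str  # "crude" | "adjusted"
    covariates: tuple
    n_per_tertile: dict
    odds_ratios: dict  # tertile -> (OR, ci_low, ci_high); T1 == (1, 1, 1)
    p_trend: float

    def to_rows(self) -> list[dict]:
        rows = []
        for tert in ("T1", "T2", "T3"):
            or_, lo, hi = self.odds_ratios[tert]
            rows.append(
                {
                    "network": self.network,
                    "outcome": self.outcome,
                    "model": self.model,
                    "tertile": tert,
                    "n": self.n_per_tertile[tert],
                    "odds_ratio": or_,
                    "ci_low": lo,
                    "ci_high": hi,
                    "p_trend": self.p_trend,
                }
            )
        return rows


def classify_obesity(covariates: pd.DataFrame) -> pd.DataFrame:
    """Binary general and abdominal obesity outcomes from anthropometry.

    general: BMI >= 30 (inclusive); central_wc: WC > 102 cm men / > 88 cm
    women (strict); central_whr: WHR > 0.90 men / > 0.85 women (strict).
    """
    required = {"bmi", "waist_circumference", "waist_hip_ratio", "sex"}
    missing = required - set(covariates.columns)
    if missing:
        raise ValueError(f"covariate table lacks columns: {sorted(missing)}")
    sex = covariates["sex"].astype(str)
    bad = sorted(set(sex.unique()) - {"man", "woman"})
    if bad:
        raise ValueError(f"unknown sex codes: {bad}")
    man = sex == "man"
    out = pd.DataFrame(index=covariates.index)
    out["general"] = (covariates["bmi"] >= 30.0).astype(int)
    wc_cut = np.where(man, 102.0, 88.0)
    out["central_wc"] = (covariates["waist_circumference"] > wc_cut).astype(int)
    whr_cut = np.where(man, 0.90, 0.85)
    out["central_whr"] = (covariates["waist_hip_ratio"] > whr_cut).astype(int)
    return out


def _design_matrix(
    tertiles: pd.Series,
    covariates: pd.DataFrame | None,
    adjust_for: tuple,
    *,
    trend: bool,
) -> pd.DataFrame:
    parts = [pd.Series(1.0, index=tertiles.index, name="const")]
    if trend:
        idx = tertiles.map({"T1": 1.0, "T2": 2.0, "T3": 3.0})
        parts.append(idx.rename("tertile_index"))
    else:
        for t in ("T2", "T3"):
            parts.append((tertiles == t).astype(float).rename(f"tertile_{t}"))
    if adjust_for:
        if covariates is None:
            raise ValueError("adjusted model requested without a covariate table")
        missing = [c for c in adjust_for if c not in covariates.columns]
        if missing:
            raise ValueError(f"covariate table lacks adjustment columns: {missing}")
        for cov in adjust_for:
            col = covariates[cov]
            if cov == "menopause":
                # Single post-menopausal indicator: the full dummy set would be
                # collinear with sex, since non-applicability encodes being a man.
                parts.append((col.astype(str) == "post").astype(float).rename("menopause_post"))
            elif cov in CATEGORICAL_COVARIATES or col.dtype == object:
                dummies = pd.get_dummies(col.astype(str), prefix=cov, drop_first=True)
                parts.extend(dummies[c].astype(float) for c in dummies.columns)
            else:
                parts.append(col.astype(float))
    x = pd.concat(parts, axis=1)
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        raise ValueError(f"singular design matrix (rank {rank} < {x.shape[1]}): {list(x.columns)}")
    return x


def _fit_logit(y: pd.Series, x: pd.DataFrame):
    fit = sm.Logit(np.asarray(y, dtype=float), x).fit(disp=0, maxiter=200)
    if not np.all(np.isfinite(fit.bse)) or np.any(np.abs(fit.params) > 20):
        raise RuntimeError(
            "logistic fit is separated or unstable (non-finite or huge estimates); "
            "consider a penalized model or collapsing sparse categories"
        )
    return fit


def fit_tertile_logistic(
    outcome: pd.Series,
    tertiles: pd.Series,
    covariates: pd.DataFrame | None = None,
    *,
    adjusted: bool = False,
    adjust_for: tuple = DEFAULT_ADJUSTMENT,
    alpha: float = 0.05,
    network: str = "network",
    outcome_name: str | None = None,
) -> AssociationResult:
    """Odds ratios of a binary outcome across score tertiles (T1 reference)."""
    y = pd.Series(outcome).astype(int)
    if set(y.unique()) - {0, 1}:
        raise ValueError("outcome must be binary 0/1")
    if y.nunique() < 2:
        raise ValueError("outcome has a single class; odds ratios undefined")
    counts = tertiles.value_counts()
    for t in ("T1", "T2", "T3"):
        if counts.get(t, 0) == 0:
            raise ValueError(f"empty tertile {t}")
    adj = tuple(adjust_for) if adjusted else ()
    x = _design_matrix(tertiles, covariates, adj, trend=False)
    fit = _fit_logit(y, x)
    z = st.norm.ppf(1 - alpha / 2)
    ors = {"T1": (1.0, 1.0, 1.0)}
    for t in ("T2", "T3"):
        beta = fit.params[f"tertile_{t}"]
        se = fit.bse[f"tertile_{t}"]
        ors[t] = (float(np.exp(beta)), float(np.exp(beta - z * se)), float(np.exp(beta + z * se)))
    p_tr = p_for_trend(y, tertiles, covariates, adjusted=adjusted, adjust_for=adjust_for)
    return AssociationResult(
        network=network,
        outcome=outcome_name or (outcome.name if hasattr(outcome, "name") else "outcome") or "outcome",
        model="adjusted" if adjusted else "crude",
        covariates=adj,
        n_per_tertile={t: int(counts.get(t, 0)) for t in ("T1", "T2", "T3")},
        odds_ratios=ors,
        p_trend=p_tr,
    )


def p_for_trend(
    outcome: pd.Series,
    tertiles: pd.Series,
    covariates: pd.DataFrame | None = None,
    *,
    adjusted: bool = False,
    adjust_for: tuple = DEFAULT_ADJUSTMENT,
) -> float:
    """Wald p for the tertile index (1, 2, 3) as a single continuous term."""
    y = pd.Series(outcome).astype(int)
    adj = tuple(adjust_for) if adjusted else ()
    x = _design_matrix(tertiles, covariates, adj, trend=True)
    fit = _fit_logit(y, x)
    return float(fit.pvalues["tertile_index"])


def tertile_descriptives(
    covariates: pd.DataFrame,
    tertiles: pd.Series,
    *,
    continuous: list | None = None,
    categorical: list | None = None,
) -> pd.DataFrame:
    """Participant characteristics by tertile with ANOVA / chi-square tests.

    Continuous variables report mean and SD per tertile with a one-way
    ANOVA p-value; categorical variables report percent per level per
    tertile with a Pearson chi-square p-value. Variables with a single
    observed level are flagged and their test skipped.
    """
    if continuous is None and categorical is None:
        continuous = [c for c in covariates.columns if pd.api.types.is_numeric_dtype(covariates[c])]
        categorical = [c for c in covariates.columns if c not in continuous]
    continuous = continuous or []
    categorical = categorical or []
    terts = ("T1", "T2", "T3")
    groups = {t: covariates.loc[tertiles == t] for t in terts}
    if any(len(g) == 0 for g in groups.values()):
        raise ValueError("every tertile must be nonempty")

    rows = []
    for var in continuous:
        samples = [groups[t][var].dropna().to_numpy(dtype=float) for t in terts]
        if np.ptp(np.concatenate(samples)) == 0:
            f, p = 0.0, 1.0
        else:
            f, p = st.f_oneway(*samples)
            if np.isnan(f):  # zero between-group variance with zero within
                f, p = 0.0, 1.0
        row = {"variable": var, "level": "mean±SD", "test": "anova", "p_value": float(p)}
        for t, s in zip(terts, samples):
            row[f"{t}"] = f"{s.mean():.2f} ± {s.std(ddof=1):.2f}"
        rows.append(row)
    for var in categorical:
        table = pd.crosstab(covariates[var], tertiles)
        table = table.reindex(columns=list(terts), fill_value=0)
        if table.shape[0] < 2:
            rows.append(
                {"variable": var, "level": str(table.index[0]), "test": "skipped:single-level",
                 "p_value": np.nan, **{t: "100.0%" for t in terts}}
            )
            continue
        chi2, p, _, _ = st.chi2_contingency(table.to_numpy(), correction=False)
        pct = table / table.sum(axis=0)
        for level in table.index:
            rows.append(
                {"variable": var, "level": str(level), "test": "chi2", "p_value": float(p),
                 **{t: f"{100 * pct.loc[level, t]:.1f}%" for t in terts}}
            )
    return pd.DataFrame(rows, columns=["variable", "level", "T1", "T2", "T3", "test", "p_value"])


def compute_sample_size(
    p: float, error_margin: float, alpha: float = 0.05, design_effect: float | None = None
) -> int:
    """Required n for estimating a prevalence: n = p(1-p) z^2 / E^2.

    ``z`` is the standard-normal 1 - alpha/2 quantile; an optional design
    effect multiplies the result (cluster sampling). Rounded to the nearest
    integer.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("prevalence p must be in [0, 1]")
    if error_margin <= 0:
        raise ValueError("error margin E must be positive")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    z = st.norm.ppf(1.0 - alpha / 2.0)
    n = p * (1.0 - p) * z**2 / error_margin**2
    if design_effect is not None:
        n *= design_effect
    return int(round(n))


def association_table(results: list[AssociationResult]) -> pd.DataFrame:
    """Flatten results into a network x outcome x model x tertile table."""
    rows = []
    for res in results:
        rows.extend(res.to_rows())
    return pd.DataFrame(
        rows,
        columns=["network", "outcome", "model", "tertile", "n", "odds_ratio", "ci_low", "ci_high", "p_trend"],
    )
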
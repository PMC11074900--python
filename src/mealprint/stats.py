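"""Group statistics: covariate-adjusted ANCOVA, FDR, tertile-band logistic
odds ratios, and percentile-bootstrap single-mediator analysis.

All models adjust for the standard covariate set (age, gender, BMI class,
educational level) as dummy-coded factors with declared reference levels.
Conventions, each switchable: Type II sums of squares for the group F-test,
Benjamini-Hochberg for FDR, Wald confidence intervals for odds ratios, and
two binary logistic models (each depression level vs HC) rather than one
multinomial fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

COVARIATE_COLUMNS = ("age", "gender", "bmi_class", "education")
#: declared reference level for each covariate factor
COVARIATE_REFERENCES = {"gender": "female", "bmi_class": "18.5-24",
                        "education": "undergrad"}


@dataclass
class PosthocContrast:
    pair: tuple                 # (reference group, comparison group)
    estimate: float             # adjusted-mean difference, comparison - reference
    p: float
    p_adjusted: float = float("nan")


@dataclass
class AncovaResult:
    feature: str
    F: float
    df: tuple                   # (df_group, df_resid)
    p: float
    posthoc: list = field(default_factory=list)
    adjusted_means: dict = field(default_factory=dict)


@dataclass
class LogisticResult:
    outcome_group: str
    predictor: str
    band: str                   # Normal or Always (reference Rare)
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    unstable: bool = False


@dataclass
class MediationResult:
    a: float                    # X -> M
    b: float                    # M -> Y given X
    c_prime: float              # direct X -> Y given M
    indirect: float             # a * b from the point fits
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    r_squared: float            # of the Y-equation


class SeparationError(RuntimeError):
    pass


def _covariate_terms(covariates: pd.DataFrame | None) -> list:
    if covariates is None:
        return []
    terms = []
    for c in covariates.columns:
        if pd.api.types.is_numeric_dtype(covariates[c]):
            terms.append(c)
        else:
            ref = COVARIATE_REFERENCES.get(c)
            terms.append(
                f"C({c}, Treatment(reference={ref!r}))" if ref is not None else f"C({c})"
            )
    return terms


def _check_full_rank(exog: np.ndarray, names: list) -> None:
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        _, r = np.linalg.qr(exog)
        diag = np.abs(np.diag(r))
        aliased = [names[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(f"model matrix rank deficient; aliased columns: {aliased}")


def ancova(y, group, covariates: pd.DataFrame | None = None,
           feature: str = "feature", typ: int = 2) -> AncovaResult:
    """Linear model ``y ~ group + covariates`` with a partial F-test on group.

    Post hoc contrasts are pairwise differences of covariate-adjusted group
    means (equivalently, differences of group dummy coefficients), with
    BH-FDR across the three pairs.  Requires >=3 groups represented and a
    full-rank model matrix (rank deficiency raises, naming aliased columns).
    """
    df = pd.DataFrame({"y": np.asarray(y, float), "group": np.asarray(group, object)})
    if covariates is not None:
        covariates = covariates.reset_index(drop=True)
        for c in covariates.columns:
            df[c] = covariates[c].to_numpy()
    df = df.dropna()
    levels = sorted(df["group"].unique())
    if len(levels) < 3:
        raise ValueError(f"ANCOVA requires >=3 groups represented, got {levels}")
    formula = "y ~ C(group)" + "".join(f" + {t}" for t in _covariate_terms(covariates))
    model = smf.ols(formula, df)
    _check_full_rank(model.exog, model.exog_names)
    res = model.fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = anova_lm(res, typ=typ)
    F = float(aov.loc["C(group)", "F"])
    p = float(aov.loc["C(group)", "PR(>F)"])
    df_pair = (float(aov.loc["C(group)", "df"]), float(aov.loc["Residual", "df"]))

    names = res.model.exog_names
    coef_of = {lvl: 0.0 for lvl in levels}
    idx_of = {}
    for i, nm in enumerate(names):
        for lvl in levels:
            if nm == f"C(group)[T.{lvl}]":
                coef_of[lvl] = float(res.params.iloc[i])
                idx_of[lvl] = i

    # covariate-adjusted means: group effect + model evaluated at the
    # column means of all non-group regressors
    base = res.model.exog.mean(axis=0)
    for i in idx_of.values():
        base[i] = 0.0
    base_mean = float(base @ res.params)
    adjusted = {lvl: base_mean + coef_of[lvl] for lvl in levels}

    posthoc = []
    k = len(names)
    for i, g1 in enumerate(levels):
        for g2 in levels[i + 1:]:
            c = np.zeros(k)
            if g2 in idx_of:
                c[idx_of[g2]] += 1.0
            if g1 in idx_of:
                c[idx_of[g1]] -= 1.0
            t = res.t_test(c)
            posthoc.append(PosthocContrast(
                pair=(g1, g2), estimate=float(np.squeeze(t.effect)),
                p=float(np.squeeze(t.pvalue))))
    adj = fdr_adjust([c.p for c in posthoc])
    for c, pa in zip(posthoc, adj):
        c.p_adjusted = float(pa)
    return AncovaResult(feature=feature, F=F, df=df_pair, p=p,
                       posthoc=posthoc, adjusted_means=adjusted)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (same length and order)."""
    p = np.asarray(list(p_values), float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def logistic_association(bands, group, target_group: str,
                         covariates: pd.DataFrame | None = None,
                         predictor: str = "pattern",
                         reference_band: str = "Rare",
                         multinomial: bool = False) -> list:
    """Odds ratios of a banded exposure for one depression level vs HC.

    Fits ``I(group == target) ~ C(band, Treatment('Rare')) + covariates`` on
    the HC + target subset by maximum likelihood; OR = exp(coefficient) with
    95% Wald CIs.  Quasi-separated fits are returned flagged ``unstable``
    rather than silently reported.  ``multinomial=True`` instead fits one
    multinomial model over all three groups and reports the target level's
    equations.
    """
    df = pd.DataFrame({"band": np.asarray(bands, object),
                       "group": np.asarray(group, object)})
    if covariates is not None:
        covariates = covariates.reset_index(drop=True)
        for c in covariates.columns:
            df[c] = covariates[c].to_numpy()
    df = df.dropna()
    band_term = f"C(band, Treatment(reference={reference_band!r}))"
    cov_terms = "".join(f" + {t}" for t in _covariate_terms(covariates))

    if multinomial:
        formula = f"group_code ~ {band_term}{cov_terms}"
        order = ["HC", "mild", "moderate_severe"]
        df["group_code"] = pd.Categorical(df["group"], categories=order, ordered=True).codes
        model = smf.mnlogit(formula, df)
        with warnings.catch_warnings(), np.errstate(over="ignore", divide="ignore"):
            warnings.simplefilter("ignore")
            res = model.fit(disp=0, maxiter=200)
        eq = order.index(target_group) - 1
        params, bse, pvals = res.params.iloc[:, eq], res.bse.iloc[:, eq], res.pvalues.iloc[:, eq]
    else:
        sub = df[df["group"].isin(["HC", target_group])].copy()
        sub["case"] = (sub["group"] == target_group).astype(int)
        formula = f"case ~ {band_term}{cov_terms}"
        model = smf.logit(formula, sub)
        try:
            with warnings.catch_warnings(), np.errstate(over="ignore", divide="ignore"):
                warnings.simplefilter("ignore")
                res = model.fit(disp=0, maxiter=200)
        except Exception as exc:  # PerfectSeparationError and kin
            raise SeparationError(str(exc)) from exc
        params, bse, pvals = res.params, res.bse, res.pvalues

    out = []
    for name in params.index:
        if not name.startswith("C(band"):
            continue
        band = name.split("[T.")[1].rstrip("]")
        beta, se = float(params[name]), float(bse[name])
        retvals = getattr(res, "mle_retvals", {}) or {}
        unstable = (not retvals.get("converged", True)) or abs(beta) > 15 or se > 50
        with np.errstate(over="ignore"):
            out.append(LogisticResult(
                outcome_group=target_group, predictor=predictor, band=band,
                odds_ratio=float(np.exp(beta)),
                ci_low=float(np.exp(beta - 1.96 * se)),
                ci_high=float(np.exp(beta + 1.96 * se)),
                p=float(pvals[name]), unstable=bool(unstable)))
    return out


def _design(covariates: pd.DataFrame | None, n: int) -> np.ndarray:
    """Dummy-coded covariate block (no intercept) aligned with the data rows."""
    if covariates is None:
        return np.empty((n, 0))
    blocks = []
    for c in covariates.columns:
        col = covariates[c]
        if pd.api.types.is_numeric_dtype(col):
            blocks.append(col.to_numpy(float)[:, None])
        else:
            ref = COVARIATE_REFERENCES.get(c)
            dummies = pd.get_dummies(col, dtype=float)
            if ref is not None and ref in dummies.columns:
                dummies = dummies.drop(columns=ref)
            else:
                dummies = dummies.iloc[:, 1:]
            blocks.append(dummies.to_numpy())
    return np.hstack(blocks) if blocks else np.empty((n, 0))


def mediate(X, M, Y, covariates: pd.DataFrame | None = None,
            n_boot: int = 5000, seed: int = 0, reverse: bool = False) -> MediationResult:
    """Single-mediator path model with a percentile-bootstrap indirect CI.

    Two linear models — M ~ X (+ covariates) giving path ``a`` and
    Y ~ X + M (+ covariates) giving paths ``b`` and ``c'`` — with the
    indirect effect a*b resampled over rows ``n_boot`` times.  The default
    orientation is X = group score, M = mediator symptom score, Y = pattern
    frequency; ``reverse=True`` swaps X and Y.
    """
    x = np.asarray(X, float)
    m = np.asarray(M, float)
    y = np.asarray(Y, float)
    if reverse:
        x, y = y, x
    mask = ~(np.isnan(x) | np.isnan(m) | np.isnan(y))
    if covariates is not None:
        covariates = covariates.reset_index(drop=True)
        mask &= ~covariates.isna().any(axis=1).to_numpy()
        covariates = covariates.loc[mask].reset_index(drop=True)
    x, m, y = x[mask], m[mask], y[mask]
    n = len(x)
    if n < 10:
        raise ValueError("too few complete cases for mediation")
    if np.var(x) == 0 or np.var(m) == 0 or np.var(y) == 0:
        raise ValueError("degenerate variance in X, M or Y")
    if n_boot < 1000:
        warnings.warn("n_boot < 1000 gives unstable percentile CIs", UserWarning)

    cov = _design(covariates, n)
    ones = np.ones((n, 1))
    Xm = np.hstack([ones, x[:, None], cov])               # M-equation design
    Xy = np.hstack([ones, x[:, None], m[:, None], cov])   # Y-equation design

    beta_m = np.linalg.lstsq(Xm, m, rcond=None)[0]
    beta_y = np.linalg.lstsq(Xy, y, rcond=None)[0]
    a, b, c_prime = float(beta_m[1]), float(beta_y[2]), float(beta_y[1])
    resid = y - Xy @ beta_y
    r2 = 1.0 - resid @ resid / np.sum((y - y.mean()) ** 2)

    rng = np.random.default_rng(seed)
    indirects = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        bm = np.linalg.lstsq(Xm[idx], m[idx], rcond=None)[0]
        by = np.linalg.lstsq(Xy[idx], y[idx], rcond=None)[0]
        indirects[i] = bm[1] * by[2]
    lo, hi = np.percentile(indirects, [2.5, 97.5])
    return MediationResult(a=a, b=b, c_prime=c_prime, indirect=a * b,
                           ci_low=float(lo), ci_high=float(hi),
                           n_boot=n_boot, seed=seed, r_squared=float(r2))
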
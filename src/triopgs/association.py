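"""Regression models for trio PGS analyses, with BH false-discovery control.

Implements the analysis battery: univariate PGS association (logistic for
disorder status, linear for symptom scores, co-varying for 10 PCs),
sex x PGS interaction with sex-stratified fits, the joint trio model
(child + mother + father scores in one regression, isolating direct and
parent-specific nurture effects), the multivariable all-PGS model, and
Benjamini-Hochberg adjustment within test families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class AssociationResult:
    """One fitted coefficient: estimate, Wald inference, and bookkeeping."""

    predictor: str
    estimate: float  # log-odds (logistic) or beta (linear)
    se: float
    p: float
    ci_low: float
    ci_high: float
    n: int
    family: str
    model: str
    odds_ratio: Optional[float] = None  # exp(estimate), logistic only
    or_ci_low: Optional[float] = None
    or_ci_high: Optional[float] = None
    delta_r2: Optional[float] = None  # linear only: incremental R^2 over covariates
    p_fdr: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "predictor": self.predictor,
            "estimate": self.estimate,
            "se": self.se,
            "odds_ratio": self.odds_ratio,
            "ci_low": self.or_ci_low if self.family == "logistic" else self.ci_low,
            "ci_high": self.or_ci_high if self.family == "logistic" else self.ci_high,
            "p": self.p,
            "p_fdr": self.p_fdr,
            "n": self.n,
            "delta_r2": self.delta_r2,
            "family": self.family,
            "model": self.model,
        }


def _complete_cases(arrays: Sequence[np.ndarray]) -> np.ndarray:
    mask = np.ones(arrays[0].shape[0], dtype=bool)
    for a in arrays:
        a = np.asarray(a, dtype=float)
        fin = np.isfinite(a)
        mask &= fin if a.ndim == 1 else fin.all(axis=1)
    return mask

def _design(predictors: dict[str, np.ndarray], covariates: Optional[np.ndarray]) -> tuple[np.ndarray, list[str]]:
    cols, names = [], []
    for name, x in predictors.items():
        cols.append(np.asarray(x, dtype=float))
        names.append(name)
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        keep = cov.std(axis=0) > 0  # drop constant covariate columns
        for k in np.where(keep)[0]:
            cols.append(cov[:, k])
            names.append(f"cov{k}")
    X = np.column_stack(cols) if cols else np.empty((0, 0))
    return X, names


def _fit(
    y: np.ndarray,
    X: np.ndarray,
    names: list[str],
    family: str,
    model_label: str,
    report: Sequence[str],
    n_cov: int,
) -> list[AssociationResult]:
    Xc = sm.add_constant(X, has_constant="add")
    if family == "logistic":
        classes = np.unique(y)
        if not np.isin(classes, [0, 1]).all() or classes.size < 2:
            raise ValueError("logistic outcome must be binary with both classes present")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", PerfectSeparationWarning)
                fit = sm.Logit(y, Xc).fit(disp=0)
        except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError) as exc:
            raise ValueError(
                f"perfect separation or singular fit for predictors {list(report)}; "
                "consider a penalized (Firth-style) fit"
            ) from exc
    elif family == "linear":
        fit = sm.OLS(y, Xc).fit()
    else:
        raise ValueError(f"family must be 'logistic' or 'linear', got {family!r}")

    delta_r2 = None
    if family == "linear" and n_cov < len(names):
        cov_cols = Xc[:, [0] + [1 + i for i, nm in enumerate(names) if nm.startswith("cov")]]
        r2_cov = sm.OLS(y, cov_cols).fit().rsquared
        delta_r2 = float(fit.rsquared - r2_cov)

    out = []
    for name in report:
        i = 1 + names.index(name)
        est, se = float(fit.params[i]), float(fit.bse[i])
        res = AssociationResult(
            predictor=name,
            estimate=est,
            se=se,
            p=float(fit.pvalues[i]),
            ci_low=est - Z95 * se,
            ci_high=est + Z95 * se,
            n=int(len(y)),
            family=family,
            model=model_label,
            delta_r2=delta_r2,
        )
        if family == "logistic":
            res.odds_ratio = float(np.exp(est))
            res.or_ci_low = float(np.exp(res.ci_low))
            res.or_ci_high = float(np.exp(res.ci_high))
        out.append(res)
    return out


def fit_univariate(
    score: np.ndarray,
    outcome: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    family: str = "logistic",
    label: str = "score",
) -> AssociationResult:
    """Single-PGS association model with covariates (default: logistic).

    Complete cases only; requires >= 30 of them, a non-constant score, and
    (logistic) both outcome classes.  Wald CI; linear models additionally
    report the incremental R^2 of the score over the covariates-only model.
    """
    score = np.asarray(score, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    mask = _complete_cases([score, outcome] + ([covariates] if covariates is not None else []))
    if mask.sum() < 30:
        raise ValueError(f"only {int(mask.sum())} complete cases (need >= 30)")
    s, y = score[mask], outcome[mask]
    cov = np.asarray(covariates, dtype=float)[mask] if covariates is not None else None
    if s.std() == 0:
        raise ValueError(f"zero-variance predictor {label!r}")
    X, names = _design({label: s}, cov)
    return _fit(y, X, names, family, f"univariate:{label}", [label], n_cov=len(names) - 1)[0]


def fit_interaction(
    score: np.ndarray,
    outcome: np.ndarray,
    sex: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    family: str = "logistic",
    label: str = "score",
) -> dict[str, AssociationResult]:
    """Sex x PGS interaction model plus sex-stratified fits.

    ``sex`` is any two-level coding (e.g. 0/1 or 1/2; the interaction
    estimate is invariant to affine recoding).  Returns the interaction
    term and the per-stratum univariate results keyed by stratum value.
    """
    score = np.asarray(score, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    sex = np.asarray(sex, dtype=float)
    mask = _complete_cases([score, outcome, sex] + ([covariates] if covariates is not None else []))
    s, y, sx = score[mask], outcome[mask], sex[mask]
    cov = np.asarray(covariates, dtype=float)[mask] if covariates is not None else None
    levels = np.unique(sx)
    if levels.size != 2:
        raise ValueError(f"sex must have exactly two levels, got {levels}")
    sx01 = (sx == levels[1]).astype(float)  # affine-invariant recode
    X, names = _design({label: s, "sex": sx01, f"{label}:sex": s * sx01}, cov)
    inter = _fit(
        y, X, names, family, f"interaction:{label}", [f"{label}:sex"], n_cov=len(names) - 3
    )[0]
    out = {"interaction": inter}
    for lv in levels:
        m = sx == lv
        out[f"stratum_{lv:g}"] = fit_univariate(
            s[m], y[m], cov[m] if cov is not None else None, family, label
        )
    return out


def fit_trio_joint(
    child: np.ndarray,
    mother: np.ndarray,
    father: np.ndarray,
    outcome: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    family: str = "logistic",
) -> dict[str, AssociationResult]:
    """Joint trio model: child + mother + father scores in one regression.

    Under the generative model the child coefficient estimates the direct
    effect and each parent coefficient the parent-specific nurture effect.
    Complete trios only.
    """
    arrays = [np.asarray(a, dtype=float) for a in (child, mother, father, outcome)]
    mask = _complete_cases(arrays + ([covariates] if covariates is not None else []))
    if mask.sum() < 30:
        raise ValueError(f"only {int(mask.sum())} complete trios (need >= 30)")
    c, m, f, y = (a[mask] for a in arrays)
    cov = np.asarray(covariates, dtype=float)[mask] if covariates is not None else None
    X, names = _design({"child": c, "mother": m, "father": f}, cov)
    res = _fit(y, X, names, family, "trio_joint", ["child", "mother", "father"], n_cov=len(names) - 3)
    return {r.predictor: r for r in res}


def fit_multivariable(
    scores: pd.DataFrame,
    outcome: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    family: str = "logistic",
) -> dict[str, AssociationResult]:
    """All scores jointly in one model; per-score conditional estimates.

    Warns when the score design's condition number exceeds 1e6 and raises
    on exact collinearity.
    """
    outcome = np.asarray(outcome, dtype=float)
    S = scores.to_numpy(dtype=float)
    mask = _complete_cases([S, outcome] + ([covariates] if covariates is not None else []))
    S, y = S[mask], outcome[mask]
    cov = np.asarray(covariates, dtype=float)[mask] if covariates is not None else None
    Sz = (S - S.mean(axis=0)) / S.std(axis=0)
    cond = np.linalg.cond(Sz)
    if not np.isfinite(cond) or np.linalg.matrix_rank(Sz) < Sz.shape[1]:
        raise ValueError("score matrix is singular (identical or collinear scores)")
    if cond > 1e6:
        warnings.warn(f"score matrix condition number {cond:.2e} exceeds 1e6", stacklevel=2)
    X, names = _design({c: S[:, i] for i, c in enumerate(scores.columns)}, cov)
    res = _fit(y, X, names, family, "multivariable", list(scores.columns), n_cov=len(names) - S.shape[1])
    return {r.predictor: r for r in res}


def adjust_fdr(
    pvalues: Sequence[float], families: Optional[Sequence] = None
) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values within each family.

    Within a family of m tests sorted ascending, adjusted_(i) =
    min_{j >= i} p_(j) * m / j, capped at 1.  With ``families`` given,
    the adjustment is applied separately per family label.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.empty_like(p)
    fam = np.zeros(p.size, dtype=object) if families is None else np.asarray(families, dtype=object)
    if fam.shape[0] != p.shape[0]:
        raise ValueError("families must align with p-values")
    for f in pd.unique(fam):
        idx = np.where(fam == f)[0]
        pf = p[idx]
        m = pf.size
        order = np.argsort(pf, kind="stable")
        adj = pf[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]  # step-up
        adj = np.minimum(adj, 1.0)
        out[idx[order]] = adj
    return out


def attach_fdr(results: Sequence[AssociationResult], families: Optional[Sequence] = None) -> None:
    """Set ``p_fdr`` on each result, adjusting within families in place."""
    p_adj = adjust_fdr([r.p for r in results], families)
    for r, q in zip(results, p_adj):
        r.p_fdr = float(q)


def results_table(results: Sequence[AssociationResult], **extra) -> pd.DataFrame:
    """Long-format results table mirroring the published table layout."""
    rows = []
    for r in results:
        d = r.to_dict()
        d.update(extra)
        rows.append(d)
    return pd.DataFrame(rows)
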
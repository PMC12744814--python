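"""Univariate screening and the multivariate logistic risk model.

The modeling strategy mirrors common practice in clinical diagnostic
studies: each candidate covariate is screened with a single-predictor
logistic regression of the physiology truth label, covariates with p < 0.2
enter a multivariate logistic model together, and competing models are
compared by in-sample rank-based AUC of their linear predictors (no
cross-validation, matching the source practice).  The headline combined
model uses the ischemic bull's-eye pattern plus central aortic pulse
pressure (per mmHg, untransformed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .diagnostics import roc_auc

__all__ = [
    "ScreenConfig",
    "ScreenedCovariate",
    "FittedModel",
    "univariate_screen",
    "fit_multivariate",
    "compare_models",
]

#: coefficient |beta| above this, or SE above it, is treated as a separation
#: diagnostic in a screening fit (odds ratios beyond ~e^15 are not estimable)
_SEPARATION_LIMIT = 15.0


@dataclass(frozen=True)
class ScreenConfig:
    """Univariate screening rule: keep covariates with p below ``p_threshold``
    (default 0.2).  ``p_source`` chooses the Wald test (default) or the
    likelihood-ratio test of the single-predictor model."""

    p_threshold: float = 0.2
    covariates: Sequence[str] = ()
    p_source: str = "wald"

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0, 1)")
        if self.p_source not in ("wald", "lr"):
            raise ValueError("p_source must be 'wald' or 'lr'")


@dataclass(frozen=True)
class ScreenedCovariate:
    name: str
    odds_ratio: Optional[float]
    ci_lower: Optional[float]
    ci_upper: Optional[float]
    p_value: Optional[float]
    selected: bool
    flag: str = ""  # "", "constant", "separation"


@dataclass(frozen=True)
class FittedModel:
    """A fitted logistic model: per-predictor log-odds coefficients, odds
    ratios with Wald CIs and p-values, and the in-sample AUC of the linear
    predictor."""

    predictors: Sequence[str]
    coefficients: Mapping[str, float]  # includes "const"
    odds_ratios: pd.DataFrame  # index predictors; columns or, ci_lower, ci_upper, p
    auc: float
    n: int
    converged: bool = True

    def to_dict(self) -> Dict:
        return {
            "predictors": list(self.predictors),
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "odds_ratios": {
                name: {c: float(row[c]) for c in self.odds_ratios.columns}
                for name, row in self.odds_ratios.iterrows()
            },
            "auc": float(self.auc),
            "n": int(self.n),
        }


def _logit_fit(y: np.ndarray, X: pd.DataFrame):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separation warnings handled explicitly
        model = sm.Logit(y, X)
        try:
            return model.fit(disp=0, maxiter=200)
        except np.linalg.LinAlgError:
            # Newton's Hessian goes singular under (quasi-)separation;
            # BFGS still yields a usable (diverging) linear predictor
            return model.fit(disp=0, maxiter=500, method="bfgs")


def univariate_screen(
    data: pd.DataFrame,
    config: ScreenConfig,
    outcome: str = "truth",
    level: float = 0.95,
) -> List[ScreenedCovariate]:
    """Screen candidate covariates with single-predictor logistic fits.

    Returns one :class:`ScreenedCovariate` per candidate, in input order.
    Constant covariates carry no information and are excluded; fits showing
    separation diagnostics (unbounded coefficients) are flagged
    ``"separation"`` and retained as selected, with a warning, so the
    analyst decides rather than the software silently dropping a perfectly
    discriminating predictor.
    """
    names = list(config.covariates) or [c for c in data.columns if c != outcome]
    y = data[outcome].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must have both classes for screening")
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least 2 patients per outcome class")

    z = stats.norm.ppf((1 + level) / 2)
    out: List[ScreenedCovariate] = []
    for name in names:
        if name not in data.columns:
            raise KeyError(f"covariate {name!r} not in data")
        x = data[name].to_numpy(dtype=float)
        if np.unique(x).size < 2:
            out.append(ScreenedCovariate(name, None, None, None, None,
                                         selected=False, flag="constant"))
            continue
        X = pd.DataFrame({"const": 1.0, name: x})
        try:
            res = _logit_fit(y, X)
        except (np.linalg.LinAlgError, Exception) as err:  # statsmodels raises various
            if "Singular" in str(err) or "separation" in str(err).lower():
                warnings.warn(f"covariate {name!r}: possible perfect separation")
                out.append(ScreenedCovariate(name, None, None, None, None,
                                             selected=True, flag="separation"))
                continue
            raise
        beta = float(res.params[name])
        se = float(res.bse[name])
        if abs(beta) > _SEPARATION_LIMIT or se > _SEPARATION_LIMIT:
            warnings.warn(f"covariate {name!r}: separation diagnostic "
                          f"(beta={beta:.2f}, se={se:.2f}); retained with flag")
            out.append(ScreenedCovariate(name, None, None, None, None,
                                         selected=True, flag="separation"))
            continue
        p = float(res.pvalues[name]) if config.p_source == "wald" else float(res.llr_pvalue)
        out.append(ScreenedCovariate(
            name,
            odds_ratio=float(np.exp(beta)),
            ci_lower=float(np.exp(beta - z * se)),
            ci_upper=float(np.exp(beta + z * se)),
            p_value=p,
            selected=p < config.p_threshold,
        ))
    return out


def fit_multivariate(
    data: pd.DataFrame,
    predictors: Sequence[str],
    outcome: str = "truth",
    level: float = 0.95,
) -> FittedModel:
    """Maximum-likelihood logistic fit of ``outcome`` on ``predictors``.

    All screened predictors enter together (no stepwise elimination).
    Reports adjusted odds ratios ``exp(beta)`` with Wald CIs and p-values,
    and the in-sample rank AUC of the linear predictor.  Rank-deficient
    design (e.g. duplicated predictors) or non-convergence raises with
    diagnostics.
    """
    predictors = list(predictors)
    missing = [p for p in predictors if p not in data.columns]
    if missing:
        raise KeyError(f"predictors not in data: {missing}")
    y = data[outcome].to_numpy(dtype=float)
    X = sm.add_constant(data[predictors].astype(float), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear predictors)")
    if len(data) <= 10 * len(predictors):
        warnings.warn(
            f"n={len(data)} is below the 10-events-per-predictor rule of thumb "
            f"for {len(predictors)} predictors; estimates may be unstable"
        )
    res = _logit_fit(y, X)
    converged = bool(res.mle_retvals.get("converged", False))
    if not converged:
        linpred_try = X.to_numpy() @ res.params.to_numpy()
        separated = linpred_try[y == 1].min() > linpred_try[y == 0].max()
        if separated:
            warnings.warn("perfect separation: the MLE does not exist; "
                          "coefficients are unbounded and CIs unreliable")
        else:
            raise RuntimeError(f"logistic fit did not converge: {res.mle_retvals}")

    z = stats.norm.ppf((1 + level) / 2)
    rows = {}
    with np.errstate(over="ignore"):  # separated fits overflow to inf CIs
        for name in predictors:
            beta, se = float(res.params[name]), float(res.bse[name])
            rows[name] = {
                "or": np.exp(beta),
                "ci_lower": np.exp(beta - z * se),
                "ci_upper": np.exp(beta + z * se),
                "p": float(res.pvalues[name]),
            }
    linpred = X.to_numpy() @ res.params.to_numpy()
    return FittedModel(
        predictors=predictors,
        coefficients={k: float(v) for k, v in res.params.items()},
        odds_ratios=pd.DataFrame.from_dict(rows, orient="index"),
        auc=roc_auc(linpred, y.astype(bool)),
        n=len(data),
        converged=converged,
    )


def compare_models(
    data: pd.DataFrame,
    model_specs: Mapping[str, Sequence[str]],
    outcome: str = "truth",
) -> pd.DataFrame:
    """Fit each named predictor set and tabulate in-sample AUCs.

    A one-column spec (e.g. an externally supplied clinical-likelihood
    score) is fitted the same way; its AUC equals that of the raw column
    since the logistic link is monotone.
    """
    rows = []
    for name, cols in model_specs.items():
        fitted = fit_multivariate(data, cols, outcome=outcome)
        rows.append({"model": name, "predictors": ", ".join(cols),
                     "auc": fitted.auc, "n": fitted.n})
    return pd.DataFrame(rows).set_index("model")
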
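"""Gaussian GLM of richness on habitat predictors and future projection.

The inferred past relationship between rarefied plant richness and alpine
habitat area (identity-link Gaussian GLM over the warm, most recent part of
the record) is applied to a simulated future habitat series to project
richness change.  Explained deviance D² = 1 - residual/null deviance; for
the Gaussian identity family this equals R².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["GLMFit", "fit_glm", "variable_importance", "project_richness"]


class RankDeficiencyError(ValueError):
    """Predictor matrix is collinear."""


@dataclass
class GLMFit:
    """Fitted Gaussian GLM with deviance summary."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    null_deviance: float
    deviance: float
    d_squared: float
    n: int
    predictors: tuple[str, ...]
    _results: object = None

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.params, "se": self.bse, "t": self.tvalues})


def fit_glm(
    data: pd.DataFrame,
    response: str = "richness",
    predictors: tuple[str, ...] = ("alpine_habitat",),
    window: tuple[float, float] | None = (10.0, 0.0),
    age_col: str | None = None,
) -> GLMFit:
    """Fit an identity-link Gaussian GLM of richness on habitat predictors.

    ``window`` restricts rows to ages within [young, old] (ka BP); the age
    comes from ``age_col`` or, by default, the index.  Raises
    :class:`RankDeficiencyError` naming collinear predictors.
    """
    df = data
    if window is not None:
        ages = df[age_col] if age_col else df.index.to_series()
        old, young = max(window), min(window)
        df = df.loc[(ages <= old + 1e-9) & (ages >= young - 1e-9)]
    if len(df) < len(predictors) + 2:
        raise ValueError("too few observations for the requested model")
    X = df.loc[:, list(predictors)].to_numpy(dtype=float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X])) < len(predictors) + 1:
        corr = np.corrcoef(X, rowvar=False)
        pairs = [
            f"{predictors[i]}~{predictors[j]}"
            for i in range(len(predictors))
            for j in range(i + 1, len(predictors))
            if abs(corr[i, j]) > 0.999999
        ]
        raise RankDeficiencyError(f"collinear predictors: {', '.join(pairs) or 'intercept'}")
    exog = sm.add_constant(pd.DataFrame(X, columns=list(predictors), index=df.index))
    model = sm.GLM(df[response].to_numpy(dtype=float), exog, family=sm.families.Gaussian())
    res = model.fit()
    d2 = 1.0 - res.deviance / res.null_deviance if res.null_deviance > 0 else 0.0
    return GLMFit(
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        null_deviance=float(res.null_deviance),
        deviance=float(res.deviance),
        d_squared=float(d2),
        n=int(res.nobs),
        predictors=tuple(predictors),
        _results=res,
    )


def variable_importance(fit: GLMFit) -> pd.Series:
    """Predictor importance as |t statistic| scaled so the top scores 100."""
    t = fit.tvalues.drop("const").abs()
    top = t.max()
    scaled = t / top * 100.0 if top > 0 else t * 0.0
    return scaled.sort_values(ascending=False)


def project_richness(
    fit: GLMFit,
    future_habitat: pd.DataFrame,
    predictor: str = "alpine_habitat",
    habitat_col: str = "alpine_km2",
    ci: float = 95.0,
    extrapolation_margin: float = 0.10,
) -> pd.DataFrame:
    """Project richness onto a future habitat series with 95% intervals.

    ``future_habitat`` is indexed by calendar year and must carry the
    driving predictor in ``habitat_col``.  Intervals are confidence
    intervals for the mean response on the identity link.  Future predictor
    values more than ``extrapolation_margin`` (fractional) beyond the
    fitted range attach an extrapolation warning flag, but predictions are
    still returned.
    """
    if predictor not in fit.predictors:
        raise ValueError(f"model was not fitted with predictor {predictor!r}")
    res = fit._results
    x = future_habitat[habitat_col].to_numpy(dtype=float)
    exog = pd.DataFrame({p: np.zeros(len(x)) for p in fit.predictors}, index=future_habitat.index)
    exog[predictor] = x
    exog = sm.add_constant(exog, has_constant="add")
    pred = res.get_prediction(exog[res.params.index])
    alpha = 1.0 - ci / 100.0
    frame = pred.summary_frame(alpha=alpha)
    fitted_x = res.model.exog[:, list(res.params.index).index(predictor)]
    span = fitted_x.max() - fitted_x.min()
    lo = fitted_x.min() - extrapolation_margin * span
    hi = fitted_x.max() + extrapolation_margin * span
    out = pd.DataFrame(
        {
            "richness": frame["mean"].to_numpy(),
            "ci_low": frame["mean_ci_lower"].to_numpy(),
            "ci_high": frame["mean_ci_upper"].to_numpy(),
            "alpine_km2": x,
            "extrapolated": (x < lo) | (x > hi),
        },
        index=future_habitat.index,
    )
    return out
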
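"""The weighted linear sequence score and its least-squares fit.

The score of a gapmer ASO is the linear combination

    score = p_A * n_A + p_T * n_T + p_C * n_C + p_G * n_G + p_3 * g_3 + I

where n_A..n_G are the nucleobase counts, g_3 is the length of the G-free
stretch from the 3' end, and the weights p_* and intercept I are estimated
by ordinary least squares against measured calcium-oscillation scores
(percent of untreated control).  Higher scores predict safer ASOs.  The
fitted weights carry the signature sign pattern: p_G strongly negative
(guanines, especially near the 3' end, raise neurotoxic potential), p_A the
largest positive weight.

The module follows the statsmodels Model/Results convention:
:class:`SequenceScoreModel` holds the design, ``fit()`` returns a
:class:`SequenceScoreResults` with coefficients, standard errors,
t-statistics, two-sided p-values, prediction and JSON persistence.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .features import FeatureVector, feature_table
from .gapmer import AsoPanel

#: design columns of the score, in order; the intercept is appended last.
SCORE_FEATURES = ["n_a", "n_t", "n_c", "n_g", "g3"]
#: conventional names of the fitted parameters, aligned with SCORE_FEATURES.
PARAM_NAMES = ["p_A", "p_T", "p_C", "p_G", "p_3", "intercept"]

MIN_OBSERVATIONS = 7


def _design_matrix(features: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SCORE_FEATURES if c not in features.columns]
    if missing:
        raise ValueError(f"feature table missing columns {missing}")
    X = features[SCORE_FEATURES].astype(float).copy()
    X["intercept"] = 1.0
    return X


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank == arr.shape[1]:
        return
    collinear = [
        name
        for j, name in enumerate(X.columns)
        if np.linalg.matrix_rank(np.delete(arr, j, axis=1)) == rank
    ]
    raise ValueError(
        f"design matrix is rank deficient (rank {rank} of {arr.shape[1]}); "
        f"collinear columns: {collinear}"
    )


class SequenceScoreModel:
    """Linear sequence-score model, ready to fit by ordinary least squares.

    Parameters
    ----------
    scores : array-like
        Measured calcium-oscillation scores, percent of control, one per
        ASO, aligned with ``features`` rows.  Used raw (uncapped) unless
        ``cap`` is given; capping (e.g. at 200) is a display convention,
        not part of the fit.
    features : DataFrame
        Feature table with at least the columns n_a, n_t, n_c, n_g, g3
        (see :func:`gapmertox.features.feature_table`).
    cap : float, optional
        If given, scores above this value are clipped before fitting.
    """

    def __init__(
        self,
        scores,
        features: pd.DataFrame,
        cap: Optional[float] = None,
    ) -> None:
        y = np.asarray(scores, dtype=float)
        if y.ndim != 1 or len(y) != len(features):
            raise ValueError("scores and features must align one per ASO")
        if np.isnan(y).any():
            raise ValueError("scores contain missing values")
        if len(y) < MIN_OBSERVATIONS:
            raise ValueError(
                f"need at least {MIN_OBSERVATIONS} observations, got {len(y)}"
            )
        if cap is not None:
            y = np.minimum(y, cap)
        X = _design_matrix(features)
        _check_rank(X)
        self.endog = y
        self.exog = X

    @classmethod
    def from_panel(
        cls,
        panel: AsoPanel,
        score_column: str = "calcium_score",
        cap: Optional[float] = None,
    ) -> "SequenceScoreModel":
        """Build the model from an annotated panel, computing features."""
        if score_column not in panel.annotations.columns:
            raise ValueError(f"panel has no {score_column!r} annotation")
        return cls(
            panel.annotations[score_column].to_numpy(dtype=float),
            feature_table(panel),
            cap=cap,
        )

    def fit(self) -> "SequenceScoreResults":
        """Ordinary least-squares fit (QR-based pseudoinverse); t-statistics
        and two-sided p-values use the residual degrees of freedom."""
        res = sm.OLS(self.endog, self.exog).fit()
        return SequenceScoreResults(self, res)


class SequenceScoreResults:
    """Fitted sequence-score model.

    Attributes
    ----------
    params, bse, tvalues, pvalues : Series
        Indexed by ``p_A, p_T, p_C, p_G, p_3, intercept``.
    nobs : int
    scale : float
        Residual variance (SSR / df_resid).
    """

    def __init__(self, model: Optional[SequenceScoreModel], sm_results=None):
        self.model = model
        self._sm = sm_results
        if sm_results is not None:
            self.params = pd.Series(np.asarray(sm_results.params), index=PARAM_NAMES)
            self.bse = pd.Series(np.asarray(sm_results.bse), index=PARAM_NAMES)
            self.tvalues = pd.Series(np.asarray(sm_results.tvalues), index=PARAM_NAMES)
            self.pvalues = pd.Series(np.asarray(sm_results.pvalues), index=PARAM_NAMES)
            self.nobs = int(sm_results.nobs)
            self.scale = float(sm_results.scale)

    # -- prediction ---------------------------------------------------------

    @property
    def resid(self) -> np.ndarray:
        if self._sm is None:
            raise AttributeError("residuals unavailable on a restored model")
        return np.asarray(self._sm.resid)

    @property
    def rsquared(self) -> float:
        if self._sm is None:
            raise AttributeError("R^2 unavailable on a restored model")
        return float(self._sm.rsquared)

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        """Calculated scores for a feature table (one per row)."""
        X = _design_matrix(features)
        return X.to_numpy() @ self.params.to_numpy()

    def score(self, fv: FeatureVector) -> float:
        """Calculated score of a single ASO's feature vector."""
        return calculate_score(self, fv)

    def score_panel(self, panel: AsoPanel, round_scores: bool = False) -> pd.Series:
        """Calculated score per ASO in panel order, indexed by id.

        ``round_scores=True`` rounds to integers, the convention used when
        printing scores.
        """
        s = pd.Series(
            self.predict(feature_table(panel)),
            index=pd.Index(panel.ids, name="id"),
            name="calculated_score",
        )
        return s.round().astype(int) if round_scores else s

    # -- presentation & persistence -----------------------------------------

    def summary(self):
        """statsmodels-style summary table of the fit."""
        if self._sm is not None:
            return self._sm.summary(xname=PARAM_NAMES)
        return self.params.to_frame("coef").join(self.bse.to_frame("std err"))

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        payload = {
            "coefficients": self.params.to_dict(),
            "standard_errors": self.bse.to_dict(),
            "t_values": self.tvalues.to_dict(),
            "p_values": self.pvalues.to_dict(),
            "n_obs": self.nobs,
            "residual_variance": self.scale,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "SequenceScoreResults":
        """Restore a fitted model from its JSON form (a path or a JSON
        string)."""
        text = (
            Path(source).read_text()
            if isinstance(source, Path) or "{" not in str(source)
            else str(source)
        )
        payload = json.loads(text)
        obj = cls(model=None, sm_results=None)
        obj.params = pd.Series(payload["coefficients"]).reindex(PARAM_NAMES)
        obj.bse = pd.Series(payload["standard_errors"]).reindex(PARAM_NAMES)
        obj.tvalues = pd.Series(payload["t_values"]).reindex(PARAM_NAMES)
        obj.pvalues = pd.Series(payload["p_values"]).reindex(PARAM_NAMES)
        obj.nobs = int(payload["n_obs"])
        obj.scale = float(payload["residual_variance"])
        return obj


def fit_linear_model(
    features: pd.DataFrame, calcium_scores, cap: Optional[float] = None
) -> SequenceScoreResults:
    """Convenience wrapper: build and fit in one call."""
    return SequenceScoreModel(calcium_scores, features, cap=cap).fit()


def linear_scores(
    features: pd.DataFrame, params: Mapping[str, float]
) -> np.ndarray:
    """Evaluate the score for given weights (keys p_A, p_T, p_C, p_G, p_3,
    intercept) over a feature table; used both for prediction and as the
    generative rule in simulations."""
    p = pd.Series(params).reindex(PARAM_NAMES)
    if p.isna().any():
        missing = list(p.index[p.isna()])
        raise ValueError(f"params missing {missing}")
    return _design_matrix(features).to_numpy() @ p.to_numpy()


def calculate_score(
    model: Union[SequenceScoreResults, Mapping[str, float]], fv: FeatureVector
) -> float:
    """The weighted sum p_A*n_A + p_T*n_T + p_C*n_C + p_G*n_G + p_3*g_3 + I
    for one feature vector."""
    params = (
        model.params if isinstance(model, SequenceScoreResults) else
        pd.Series(model).reindex(PARAM_NAMES)
    )
    x = np.array([fv.n_a, fv.n_t, fv.n_c, fv.n_g, fv.g3, 1.0])
    return float(x @ np.asarray(params, dtype=float))


def spearman_test(x, y) -> tuple[float, float]:
    """Spearman rank correlation with the asymptotic t-approximation.

    rho is the Pearson correlation of average-tie ranks; the two-sided
    p-value comes from t = rho*sqrt((n-2)/(1-rho^2)) on n-2 degrees of
    freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rho undefined for a constant input vector")
    res = scipy.stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def feature_score_correlations(
    features: pd.DataFrame,
    scores,
    columns: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Spearman rho and p-value of each feature column against the scores.

    Single-valued (constant) feature columns are excluded with a warning.
    Returned as a DataFrame indexed by feature with columns rho, p_value.
    """
    y = np.asarray(scores, dtype=float)
    cols = list(columns) if columns is not None else list(features.columns)
    rows = {}
    for col in cols:
        x = features[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            warnings.warn(
                f"feature {col!r} is single-valued; excluded from correlation"
            )
            continue
        rho, p = spearman_test(x, y)
        rows[col] = (rho, p)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["rho", "p_value"]
    ).rename_axis("feature")


def median_score_by_count(features: pd.DataFrame, scores, column: str) -> pd.Series:
    """Median score per distinct feature value (count-vs-median summaries
    such as median calcium score by number of G nucleotides)."""
    s = pd.Series(np.asarray(scores, dtype=float), index=features.index)
    return s.groupby(features[column]).median().rename("median_score")
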
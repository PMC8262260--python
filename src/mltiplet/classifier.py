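"""The multiplet classifier core.

Droplets flagged by the CITE-seq and/or VDJ rule engines are treated as
identified doublets/multiplets (positives); all remaining droplets — enriched
for true singlets — are the negatives. Both groups are trimmed to within 2
standard deviations of their own mean on every QC covariate, a logistic GLM of
label ~ features is fitted by maximum likelihood, and the fitted model scores
every droplet in the dataset with a doublet probability.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, ClassifierMixin

#: QC covariates used both for 2-SD trimming and (by default) in the design matrix
TRIM_VARIABLES = ("mito_ribo_ratio", "clr_n_genes", "clr_n_umi", "clr_n_umi_vdj")


@dataclass
class TrainingSet:
    positives: pd.Index
    negatives: pd.Index
    sources: dict = field(default_factory=dict)  # barcode -> list of source names


def build_training_set(calls: pd.DataFrame) -> TrainingSet:
    """Union the flag columns of one or more doublet sources.

    ``calls`` is a boolean frame indexed by barcode with one column per source
    (e.g. "vdj", "cite", "external"). Positives are barcodes flagged by any
    source; negatives are the remainder.
    """
    if calls.shape[1] < 1:
        raise ValueError("need at least one source column")
    calls = calls.fillna(False).astype(bool)
    flagged = calls.any(axis=1)
    positives = calls.index[flagged]
    if len(positives) == 0:
        raise ValueError("no identified doublets in any source")
    negatives = calls.index[~flagged]
    if len(negatives) == 0:
        raise ValueError("every droplet is flagged; no negatives remain")
    sources = {
        bc: list(calls.columns[calls.loc[bc]]) for bc in positives
    }
    return TrainingSet(positives=positives, negatives=negatives, sources=sources)


def trim_2sd(
    features: pd.DataFrame,
    barcodes: pd.Index,
    variables=TRIM_VARIABLES,
    n_sd: float = 2.0,
) -> pd.Index:
    """Keep barcodes within ``n_sd`` SD of the group mean on every variable.

    Mean and SD are computed on the group being trimmed itself.
    """
    sub = features.loc[barcodes, list(variables)]
    mean, sd = sub.mean(), sub.std(ddof=1).replace(0, np.inf)
    keep = ((sub - mean).abs() <= n_sd * sd).all(axis=1)
    kept = sub.index[keep]
    if len(kept) == 0:
        raise ValueError("trimming removed every barcode in the group")
    return kept


class MultipletClassifier(BaseEstimator, ClassifierMixin):
    """Logistic GLM over droplet features, trained on identified doublets.

    Parameters
    ----------
    feature_names : columns of the design matrix; None uses every numeric
        column of X at fit time.
    cutoff : probability above which (strictly) a droplet is called a doublet.
    trim_sd : half-width (in SDs) of the per-group trimming band applied to
        positives and negatives independently before fitting; trimming uses
        the QC covariates present among ``TRIM_VARIABLES``.
    ridge_alpha : per-observation L2 penalty used by the fallback fit when the
        maximum-likelihood problem is (quasi-)separable.

    Attributes (after fit): ``coef_`` (Series per feature), ``intercept_``,
    ``bse_`` / ``conf_int_`` (NaN under the ridge fallback), ``feature_names_``.
    """

    def __init__(
        self,
        feature_names: list[str] | None = None,
        cutoff: float = 0.5,
        trim_sd: float = 2.0,
        ridge_alpha: float = 1e-4,
    ):
        self.feature_names = feature_names
        self.cutoff = cutoff
        self.trim_sd = trim_sd
        self.ridge_alpha = ridge_alpha

    # -- fitting -----------------------------------------------------------
    def fit(self, X: pd.DataFrame, y):
        y = pd.Series(np.asarray(y, dtype=bool), index=X.index)
        names = list(self.feature_names) if self.feature_names else [
            c for c in X.columns if np.issubdtype(X[c].dtype, np.number)
        ]
        missing = [c for c in names if c not in X.columns]
        if missing:
            raise KeyError(f"feature columns missing from X: {missing}")

        if self.trim_sd is not None and self.trim_sd > 0:
            trim_vars = [v for v in TRIM_VARIABLES if v in X.columns]
            kept = []
            for group in (X.index[y], X.index[~y]):
                kept.append(
                    trim_2sd(X, group, variables=trim_vars, n_sd=self.trim_sd)
                    if trim_vars
                    else group
                )
            idx = kept[0].append(kept[1])
        else:
            idx = X.index
        if y.loc[idx].nunique() < 2:
            raise ValueError("training set lost a class during trimming")

        design = X.loc[idx, names].astype(float)
        # drop collinear columns so the MLE is identified
        usable = list(names)
        mat = design.to_numpy()
        rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(mat)), mat]))
        while rank < len(usable) + 1:
            dropped = usable.pop()
            warnings.warn(f"dropping collinear feature {dropped!r}")
            mat = design[usable].to_numpy()
            rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(mat)), mat]))
        design = design[usable]

        # fit on standardised columns so the likelihood optimisation (and the
        # ridge fallback's penalty geometry) is scale-free; coefficients are
        # reported back on the original feature scale
        mu = design.mean()
        sd = design.std(ddof=0).replace(0, 1.0)
        zdesign = (design - mu) / sd

        exog = sm.add_constant(zdesign, has_constant="add")
        endog = y.loc[idx].astype(float)
        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", category=RuntimeWarning)
                warnings.simplefilter("error", category=PerfectSeparationWarning)
                res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
            if not np.all(np.isfinite(res.params)) or np.abs(res.params).max() > 1e3:
                raise np.linalg.LinAlgError("separation")
            coef_z = res.params.drop("const")
            intercept_z = float(res.params["const"])
            bse_z = res.bse.drop("const")
            ci_z = res.conf_int().drop(index="const")
            self.bse_ = bse_z / sd
            self.conf_int_ = ci_z.div(sd, axis=0)
            self.conf_int_.columns = ["low", "high"]
        except Exception:
            warnings.warn(
                "maximum-likelihood logistic fit failed (likely perfect "
                "separation); falling back to a ridge-stabilised fit"
            )
            from sklearn.linear_model import LogisticRegression

            # a barely-there penalty on the standardised scale: keeps the
            # optimum finite under separation while staying close to the
            # maximum-likelihood boundary the trimmed training set implies
            lr = LogisticRegression(
                C=1.0 / self.ridge_alpha, solver="lbfgs", max_iter=5000
            ).fit(zdesign.to_numpy(), endog.to_numpy())
            intercept_z = float(lr.intercept_[0])
            coef_z = pd.Series(lr.coef_[0], index=usable)
            self.bse_ = pd.Series(np.nan, index=usable)
            self.conf_int_ = pd.DataFrame(np.nan, index=usable, columns=["low", "high"])
        self.coef_ = coef_z / sd
        self.intercept_ = intercept_z - float((coef_z * mu / sd).sum())
        self.feature_names_ = usable
        self.training_index_ = idx
        return self

    # -- prediction --------------------------------------------------------
    def decision_function(self, X: pd.DataFrame) -> pd.Series:
        missing = [c for c in self.feature_names_ if c not in X.columns]
        if missing:
            raise KeyError(f"feature columns missing from X: {missing}")
        eta = self.intercept_ + X[self.feature_names_].astype(float) @ self.coef_
        return eta.rename("linear_predictor")

    def predict_proba(self, X: pd.DataFrame) -> pd.Series:
        eta = self.decision_function(X)
        return (1.0 / (1.0 + np.exp(-eta))).rename("doublet_probability")

    def predict(self, X: pd.DataFrame) -> pd.Series:
        return (self.predict_proba(X) > self.cutoff).rename("doublet_call")

    # -- persistence -------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": self.feature_names_,
            "intercept": self.intercept_,
            "coefficients": self.coef_.to_dict(),
            "cutoff": self.cutoff,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "MultipletClassifier":
        payload = json.loads(Path(path).read_text())
        self = cls(feature_names=payload["feature_names"], cutoff=payload["cutoff"])
        self.feature_names_ = payload["feature_names"]
        self.intercept_ = payload["intercept"]
        self.coef_ = pd.Series(payload["coefficients"]).reindex(self.feature_names_)
        self.bse_ = pd.Series(np.nan, index=self.feature_names_)
        self.conf_int_ = pd.DataFrame(np.nan, index=self.feature_names_, columns=["low", "high"])
        return self


def fit_glm(
    features: pd.DataFrame,
    training: TrainingSet,
    feature_names: list[str] | None = None,
    cutoff: float = 0.5,
) -> MultipletClassifier:
    """Fit the logistic GLM on a training set (thin wrapper over the estimator)."""
    idx = training.positives.append(training.negatives)
    y = pd.Series(False, index=idx)
    y.loc[training.positives] = True
    return MultipletClassifier(feature_names=feature_names, cutoff=cutoff).fit(
        features.loc[idx], y
    )


def predict_doublets(
    model: MultipletClassifier,
    features: pd.DataFrame,
    training: TrainingSet | None = None,
    cutoff: float | None = None,
) -> pd.DataFrame:
    """Score every droplet; training positives are always reported as doublets.

    Returns a frame with ``probability``, ``call`` (probability strictly above
    the cutoff OR training membership) and ``training`` membership.
    """
    cutoff = model.cutoff if cutoff is None else cutoff
    prob = model.predict_proba(features)
    call = prob > cutoff
    is_training = pd.Series(False, index=features.index)
    if training is not None:
        is_training.loc[features.index.intersection(training.positives)] = True
    return pd.DataFrame(
        {"probability": prob, "call": call | is_training, "training": is_training}
    )


def estimate_doublet_proportion(calls) -> float:
    """Fraction of droplets with a final doublet call."""
    arr = np.asarray(calls, dtype=bool)
    return float(arr.mean()) if arr.size else 0.0
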
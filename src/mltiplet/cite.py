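"""CITE-seq positivity calling and doublet flagging from exclusive marker pairs.

Per antibody, a 1-D linear discriminant fitted on CLR-normalised ADT levels of
reference-positive vs reference-negative cell populations yields a positivity
threshold; antibodies that recall their reference-positive population with
sensitivity > 70% are usable. A droplet co-positive for both members of a
mutually exclusive marker pair (e.g. CD19 + CD3) is flagged as a doublet.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

#: Mutually exclusive surface-marker pairs for human PBMC panels.
DEFAULT_EXCLUSIVE_PAIRS: tuple[tuple[str, str], ...] = (
    ("CD19", "CD3"),
    ("CD19", "CD4"),
    ("CD19", "CD8a"),
    ("CD19", "CD56"),
    ("CD19", "CD16"),
    ("CD19", "CD14"),
    ("CD19", "CD127"),
    ("CD4", "CD16"),
    ("CD127", "CD16"),
)


class DegenerateSeparationError(ValueError):
    """Positive and negative reference populations are not separable."""


def lda_threshold(
    values_pos,
    values_neg,
    priors: tuple[float, float] = (0.5, 0.5),
    min_n: int = 10,
    eps: float = 1e-8,
) -> float:
    """Decision boundary of a two-class 1-D linear discriminant.

    With pooled variance sigma^2 and class means mu+ / mu-, the boundary is
    t = (mu+ + mu-)/2 + sigma^2 * ln(pi- / pi+) / (mu+ - mu-);
    equal priors reduce it to the midpoint of the means.
    """
    pos = np.asarray(values_pos, dtype=float)
    neg = np.asarray(values_neg, dtype=float)
    if pos.size < min_n or neg.size < min_n:
        raise ValueError(f"need at least {min_n} values per reference group")
    mu_p, mu_n = pos.mean(), neg.mean()
    if abs(mu_p - mu_n) < eps:
        raise DegenerateSeparationError("reference group means coincide")
    # pooled (within-class) variance
    n_p, n_n = pos.size, neg.size
    var = ((n_p - 1) * pos.var(ddof=1) + (n_n - 1) * neg.var(ddof=1)) / (n_p + n_n - 2)
    pi_p, pi_n = priors
    return (mu_p + mu_n) / 2.0 + var * math.log(pi_n / pi_p) / (mu_p - mu_n)


def reference_populations(
    labels: pd.Series,
    antibody_map: dict[str, dict],
) -> dict[str, tuple[pd.Index, pd.Index]]:
    """Barcode sets of gene-expression positive / negative cells per antibody.

    ``antibody_map`` maps antibody -> {"pos": [cell types...], "neg": [...]}
    (a "genes" entry documenting the corresponding marker genes is allowed and
    ignored here). Cell-type names must exist in ``labels``.
    """
    known = set(labels.dropna().unique())
    out = {}
    for ab, spec in antibody_map.items():
        pos_types, neg_types = list(spec["pos"]), list(spec["neg"])
        missing = (set(pos_types) | set(neg_types)) - known
        if missing:
            raise ValueError(f"antibody {ab}: cell types {sorted(missing)} absent from labels")
        out[ab] = (
            labels.index[labels.isin(pos_types)],
            labels.index[labels.isin(neg_types)],
        )
    return out


def probe_sensitivity(positive: pd.Series, pos_barcodes) -> float:
    """Fraction of reference-positive cells called ADT-positive (NaN if empty)."""
    pos_barcodes = pd.Index(pos_barcodes)
    if len(pos_barcodes) == 0:
        return float("nan")
    return float(positive.reindex(pos_barcodes).fillna(False).mean())


class AdtPositivityCaller(BaseEstimator, TransformerMixin):
    """Learn per-antibody positivity thresholds from labelled reference populations.

    Parameters
    ----------
    min_sensitivity : usability gate — an antibody is kept only if its threshold
        recalls reference-positive cells at a rate strictly above this value.
    priors : LDA class priors (positive, negative).

    Attributes (after fit)
    ----------------------
    thresholds_ : per-antibody CLR threshold (NaN where fitting failed)
    sensitivity_ : recall of reference-positive cells at the threshold
    usable_ : sensitivity_ > min_sensitivity
    """

    def __init__(self, min_sensitivity: float = 0.70, priors: tuple[float, float] = (0.5, 0.5)):
        self.min_sensitivity = min_sensitivity
        self.priors = priors

    def fit(self, clr: pd.DataFrame, reference: dict[str, tuple[pd.Index, pd.Index]]):
        thresholds, sensitivity, usable = {}, {}, {}
        for ab in clr.columns:
            if ab not in reference:
                warnings.warn(f"antibody {ab!r} missing from reference map; skipped")
                thresholds[ab], sensitivity[ab], usable[ab] = np.nan, np.nan, False
                continue
            pos_bc, neg_bc = reference[ab]
            if len(pos_bc) == 0 or len(neg_bc) == 0:
                warnings.warn(f"antibody {ab!r}: empty reference population; unusable")
                thresholds[ab], sensitivity[ab], usable[ab] = np.nan, np.nan, False
                continue
            try:
                t = lda_threshold(
                    clr.loc[clr.index.intersection(pos_bc), ab],
                    clr.loc[clr.index.intersection(neg_bc), ab],
                    priors=self.priors,
                )
            except (DegenerateSeparationError, ValueError) as exc:
                warnings.warn(f"antibody {ab!r}: {exc}; unusable")
                thresholds[ab], sensitivity[ab], usable[ab] = np.nan, np.nan, False
                continue
            called = clr[ab] > t
            sens = probe_sensitivity(called, clr.index.intersection(pos_bc))
            thresholds[ab] = t
            sensitivity[ab] = sens
            usable[ab] = bool(sens > self.min_sensitivity)
        self.thresholds_ = pd.Series(thresholds, name="threshold")
        self.sensitivity_ = pd.Series(sensitivity, name="sensitivity")
        self.usable_ = pd.Series(usable, name="usable")
        return self

    def transform(self, clr: pd.DataFrame) -> pd.DataFrame:
        """Boolean positivity calls (strict '>' threshold); unusable antibodies are all-False."""
        out = pd.DataFrame(False, index=clr.index, columns=clr.columns)
        for ab in clr.columns:
            t = self.thresholds_.get(ab, np.nan)
            if np.isfinite(t):
                out[ab] = clr[ab] > t
        return out


def flag_cite_doublets(
    positivity: pd.DataFrame,
    pairs=DEFAULT_EXCLUSIVE_PAIRS,
    usable: pd.Series | None = None,
) -> pd.DataFrame:
    """Flag droplets co-positive for any mutually exclusive antibody pair.

    Returns a frame indexed by barcode with ``flag`` and ``pairs`` (all
    triggering pairs, ';'-joined). Pairs referencing antibodies that are not in
    the panel or not usable are dropped with a warning.
    """
    if usable is None:
        usable = pd.Series(True, index=positivity.columns)
    flags = pd.Series(False, index=positivity.index)
    fired: dict[str, list[str]] = {bc: [] for bc in positivity.index}
    for a, b in pairs:
        if a == b:
            raise ValueError(f"self-pair {a}+{b}")
        ok = all(m in positivity.columns and bool(usable.get(m, False)) for m in (a, b))
        if not ok:
            warnings.warn(f"pair {a}+{b} references an unavailable/unusable antibody; dropped")
            continue
        hit = positivity[a] & positivity[b]
        flags |= hit
        for bc in positivity.index[hit]:
            fired[bc].append(f"{a}+{b}")
    return pd.DataFrame(
        {"flag": flags, "pairs": [";".join(fired[bc]) for bc in positivity.index]},
        index=positivity.index,
    )
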
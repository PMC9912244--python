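"""Off-target viability modelling.

Guides targeting non-essential genes should not deplete through their
on-target effect; any strong dropout they show is attributed to
guide-intrinsic (off-target, collateral-cleavage-mediated) viability
effects.  The model contrasts the most strongly depleted quarter of
non-essential-targeting guides against the rest with a random forest
over the 185 curated features, and compares the resulting feature
importances with those of an analogous on-target model built from
essential-gene guides (strong vs weak depletion, same quantile).
A high correlation between the two importance vectors is the signature
that off-target viability effects track on-target cleavage activity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier

from .features import FEATURE_NAMES
from .guide_io import GuideRecord

logger = logging.getLogger(__name__)

DEFAULT_QUANTILE = 0.25
DEFAULT_N_TREES = 500


@dataclass
class OfftargetLabelSet:
    """Binary strong-depletion labels over a set of guides."""

    guide_ids: list[str]
    labels: np.ndarray          # 1 = strongest-depletion ("strong") guides
    quantile: float = DEFAULT_QUANTILE
    source_dataset: str = ""

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())


def _quantile_labels(guides: list[GuideRecord], quantile: float,
                     source: str) -> OfftargetLabelSet:
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    if len(guides) < 8:
        raise ValueError(f"need at least 8 guides, got {len(guides)}")
    for g in guides:
        if g.lfc is None:
            raise ValueError(f"guide {g.guide_id!r} has no LFC")
    lfcs = np.array([g.lfc for g in guides])
    if np.ptp(lfcs) == 0:
        raise ValueError("degenerate LFC distribution: all values identical")
    n_pos = int(math.floor(quantile * len(guides)))
    # deterministic: sort by (LFC, guide_id), strongest depletion first
    order = sorted(range(len(guides)), key=lambda i: (guides[i].lfc, guides[i].guide_id))
    labels = np.zeros(len(guides), dtype=int)
    labels[order[:n_pos]] = 1
    return OfftargetLabelSet(
        guide_ids=[g.guide_id for g in guides], labels=labels,
        quantile=quantile, source_dataset=source,
    )


def make_offtarget_labels(
    guides: list[GuideRecord],
    quantile: float = DEFAULT_QUANTILE,
    essential_genes: frozenset[str] | set[str] = frozenset(),
    source: str = "",
) -> OfftargetLabelSet:
    """Strong-vs-rest labels on non-essential-targeting guides.

    The lowest-``quantile`` fraction by LFC (ties broken by guide id)
    are labelled strong.  Guides targeting genes in ``essential_genes``
    are a contamination and raise an error.
    """
    bad = [g.guide_id for g in guides if g.gene in essential_genes]
    if bad:
        raise ValueError(
            f"{len(bad)} guide(s) target essential genes (e.g. {bad[:3]}); "
            "off-target labels must come from non-essential targets only"
        )
    return _quantile_labels(guides, quantile, source)


def make_ontarget_labels(
    guides: list[GuideRecord],
    quantile: float = DEFAULT_QUANTILE,
    source: str = "",
) -> OfftargetLabelSet:
    """Strong-vs-weak dropout labels on essential-gene guides.

    The on-target comparison model is built symmetrically to the
    off-target one: the strongest-depleted ``quantile`` of
    essential-targeting guides against the rest.
    """
    return _quantile_labels(guides, quantile, source)


def fit_offtarget_rf(
    features: pd.DataFrame,
    labels: np.ndarray,
    seed: int = 0,
    n_estimators: int = DEFAULT_N_TREES,
) -> tuple[RandomForestClassifier, pd.Series]:
    """Fit the random forest and return (model, normalized importances).

    The importance vector follows the canonical 185-feature order and
    sums to 1.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need both classes present")
    if len(labels) < 50:
        logger.warning("only %d guides; importance estimates will be noisy", len(labels))
    X = features[list(FEATURE_NAMES)] if set(FEATURE_NAMES) <= set(features.columns) else features
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    rf.fit(X.to_numpy(), labels)
    imp = rf.feature_importances_
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return rf, pd.Series(imp, index=list(X.columns), name="importance")


def importance_correlation(v1: pd.Series, v2: pd.Series) -> float:
    """Pearson correlation between two aligned importance vectors."""
    if list(v1.index) != list(v2.index):
        raise ValueError("importance vectors are not in the same feature order")
    a, b = v1.to_numpy(), v2.to_numpy()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero-variance importance vector: correlation undefined")
    return float(pearsonr(a, b)[0])


class OffTargetViabilityModel(BaseEstimator, ClassifierMixin):
    """Scikit-learn style wrapper: strong-depletion classifier + importances.

    ``fit(X, y)`` takes the 185-column feature matrix and binary
    strong-depletion labels; after fitting, ``importances_`` holds the
    normalized feature-importance vector (sums to 1).
    """

    def __init__(self, n_estimators: int = DEFAULT_N_TREES, seed: int = 0):
        self.n_estimators = n_estimators
        self.seed = seed

    def fit(self, X: pd.DataFrame, y):
        self.model_, self.importances_ = fit_offtarget_rf(
            X, np.asarray(y), seed=self.seed, n_estimators=self.n_estimators
        )
        self.classes_ = self.model_.classes_
        return self

    def predict(self, X: pd.DataFrame):
        return self.model_.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X: pd.DataFrame):
        return self.model_.predict_proba(np.asarray(X, dtype=float))
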
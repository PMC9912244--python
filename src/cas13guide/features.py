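"""The 185-feature curated representation and classical baselines.

The conventional-ML comparison and the off-target viability model both
operate on a fixed, ordered set of 185 hand-curated guide features:

* 120 per-position nucleotide indicators (positions 1-30, A/C/G/U);
* 16 dinucleotide frequencies, 4 mononucleotide frequencies;
* composition summaries (GC content, GC in the 15-23 window, GC of the
  5' and 3' terminal 4-mers, longest homopolymer run, spacer length);
* structure/energy terms: spacer folding energy ("Energy"), folding
  energy of the direct repeat + spacer ("crRNA energy"), paired
  fraction, 30 per-position paired indicators, stem count, longest stem;
* 4 target-region indicators (CDS / UTR5 / UTR3 / noncoding).

The name order is canonical and pinned by a checksum test; extraction
is a pure function of (spacer, fold, crRNA energy, region).
"""

from __future__ import annotations

import hashlib
import itertools
import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import (
    AdaBoostRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.svm import SVR

from .encoding import SEQ_CHANNELS
from .guide_io import GuideRecord
from .structure import FoldResult, crrna_energy, default_engine, fold_mfe

logger = logging.getLogger(__name__)

_MAX_POS = 30
_REGION_CHANNELS = ("CDS", "UTR5", "UTR3", "noncoding")


def feature_names() -> tuple[str, ...]:
    """The canonical, ordered 185-feature name list."""
    names: list[str] = []
    for p in range(1, _MAX_POS + 1):
        for b in SEQ_CHANNELS:
            names.append(f"pos{p:02d}_{b}")
    for a, b in itertools.product(SEQ_CHANNELS, repeat=2):
        names.append(f"dinuc_{a}{b}")
    for b in SEQ_CHANNELS:
        names.append(f"freq_{b}")
    names += [
        "gc_content",
        "gc_15_23",
        "gc_5prime4",
        "gc_3prime4",
        "longest_homopolymer",
        "spacer_length",
        "energy",         # spacer MFE
        "crrna_energy",   # DR+spacer MFE
        "paired_fraction",
    ]
    for p in range(1, _MAX_POS + 1):
        names.append(f"pos{p:02d}_paired")
    names += ["n_stems", "max_stem_len"]
    names += [f"region_{r}" for r in _REGION_CHANNELS]
    return tuple(names)


FEATURE_NAMES: tuple[str, ...] = feature_names()
N_FEATURES = len(FEATURE_NAMES)


def feature_checksum() -> str:
    """Checksum pinning the canonical feature-name ordering."""
    return hashlib.sha256("\n".join(FEATURE_NAMES).encode()).hexdigest()


def _gc_frac(s: str) -> float:
    return sum(c in "GC" for c in s) / len(s) if s else 0.0


def extract_features(
    guide: GuideRecord,
    fold: FoldResult,
    crrna_fold_energy: float,
    region: str | None = None,
) -> pd.Series:
    """Extract the 185 curated features for one guide.

    ``region`` overrides the record's region annotation; an unknown or
    NA region leaves all four region indicators at zero (logged).
    """
    s = guide.spacer
    db = fold.dot_bracket
    if len(db) != len(s):
        raise ValueError("fold was not computed on this spacer")
    n = len(s)
    vals = np.zeros(N_FEATURES)
    idx = {name: i for i, name in enumerate(FEATURE_NAMES)}

    for p, base in enumerate(s[:_MAX_POS], start=1):
        vals[idx[f"pos{p:02d}_{base}"]] = 1.0
    if n >= 2:
        for a, b in zip(s, s[1:]):
            vals[idx[f"dinuc_{a}{b}"]] += 1.0 / (n - 1)
    for b in SEQ_CHANNELS:
        vals[idx[f"freq_{b}"]] = s.count(b) / n
    vals[idx["gc_content"]] = _gc_frac(s)
    vals[idx["gc_15_23"]] = _gc_frac(s[14:23])
    vals[idx["gc_5prime4"]] = _gc_frac(s[:4])
    vals[idx["gc_3prime4"]] = _gc_frac(s[-4:])
    runs = [len(list(g)) for _, g in itertools.groupby(s)]
    vals[idx["longest_homopolymer"]] = max(runs)
    vals[idx["spacer_length"]] = float(n)
    vals[idx["energy"]] = fold.mfe
    vals[idx["crrna_energy"]] = crrna_fold_energy
    vals[idx["paired_fraction"]] = sum(c != "." for c in db) / n
    for p, sym in enumerate(db[:_MAX_POS], start=1):
        vals[idx[f"pos{p:02d}_paired"]] = float(sym != ".")
    stem_runs = [len(list(g)) for sym, g in itertools.groupby(db) if sym == "("]
    vals[idx["n_stems"]] = float(len(stem_runs))
    vals[idx["max_stem_len"]] = float(max(stem_runs)) if stem_runs else 0.0

    reg = region if region is not None else guide.region
    if reg in _REGION_CHANNELS:
        vals[idx[f"region_{reg}"]] = 1.0
    elif reg not in (None, "NA"):
        logger.warning("guide %s: unknown region %r, region indicators left zero",
                       guide.guide_id, reg)
    return pd.Series(vals, index=FEATURE_NAMES, name=guide.guide_id)


class CuratedFeaturizer(BaseEstimator, TransformerMixin):
    """Transform GuideRecords into the 185-column feature matrix.

    Parameters
    ----------
    dr : str
        Direct-repeat sequence used for the "crRNA energy" feature
        (vector-specific; must be configured).
    engine : {"auto", "thermo", "maxpair"}
        Folding engine.
    """

    def __init__(self, dr: str = "", engine: str = "auto"):
        self.dr = dr
        self.engine = engine

    def fit(self, X=None, y=None):
        return self

    def transform(self, X: list[GuideRecord]) -> pd.DataFrame:
        if not self.dr:
            raise ValueError(
                "CuratedFeaturizer requires the direct-repeat sequence (dr=...) "
                "for the crRNA-energy feature"
            )
        eng = default_engine() if self.engine == "auto" else self.engine
        rows = []
        for g in X:
            fold = fold_mfe(g.spacer, engine=eng)
            ce = crrna_energy(g.spacer, self.dr, engine=eng)
            rows.append(extract_features(g, fold, ce))
        return pd.DataFrame(rows)


_BASELINES = {
    "RF": lambda seed: RandomForestRegressor(random_state=seed),
    "GBM": lambda seed: GradientBoostingRegressor(random_state=seed),
    "ADA": lambda seed: AdaBoostRegressor(random_state=seed),
    "SVM": lambda seed: SVR(),
}


def make_baseline(kind: str, seed: int = 0):
    """Untrained classical baseline regressor (RF, XGB, SVM, ADA, GBM)."""
    if kind == "XGB":
        from xgboost import XGBRegressor

        return XGBRegressor(random_state=seed, n_jobs=1, verbosity=0)
    try:
        return _BASELINES[kind](seed)
    except KeyError:
        raise ValueError(f"unknown baseline {kind!r}; choose from RF, XGB, SVM, ADA, GBM")


def train_baseline(kind: str, X, y, seed: int = 0):
    """Fit a classical baseline on the curated feature matrix."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(X) != len(y) or len(y) < 20:
        raise ValueError("need matched X, y with at least 20 samples")
    if np.ptp(y) == 0:
        raise ValueError("constant target: nothing to learn")
    model = make_baseline(kind, seed)
    model.fit(X, y)
    return model
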
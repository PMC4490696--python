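"""Scikit-learn style estimators for the positional RNA-seq pipeline.

The pipeline treats transcripts as observations (rows) and the K nested
fragment samples as features (columns):

``ExpressionNormalizer``
    counts → log2 expression levels,
    ``log2((count / total) * scale + pseudo_count)``.
``AdjacentDifferencer``
    levels → K−1 adjacent-sample differences (log2 fold changes).
``ProfileCoder``
    differences → {+, 0, −} symbols under a fold-change threshold.
``PositionalClassifier``
    the composed chain; ``predict`` maps counts to organ-region calls.

All estimators follow the sklearn API (``get_params``/``set_params``,
``fit``/``transform``/``predict``, fitted attributes with a trailing
underscore) and compose with :class:`sklearn.pipeline.Pipeline`.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .design import NestedDesign, default_lignano_design

__all__ = [
    "ExpressionNormalizer",
    "AdjacentDifferencer",
    "ProfileCoder",
    "PositionalClassifier",
    "SYMBOLS",
]

#: The three profile symbols, in the order (down, flat, up).
SYMBOLS = ("-", "0", "+")


def _as_2d_float(X, name: str = "X") -> np.ndarray:
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-dimensional, got shape {arr.shape}")
    return arr


class ExpressionNormalizer(TransformerMixin, BaseEstimator):
    """Normalise read counts to log2 expression levels.

    Each cell becomes ``log2((count / total_j) * scale + pseudo_count)``
    where ``total_j`` is the per-sample total mapped reads.  ``fit`` learns
    the totals as column sums of the fitted matrix unless an explicit
    ``totals`` override is given (e.g. library-level totals).

    The pseudo-count is added *after* scaling, so a zero count maps to the
    floor ``log2(pseudo_count)`` regardless of the total; with the default
    ``pseudo_count=1e-5`` the floor is ≈ −16.61.

    Parameters
    ----------
    scale : float, default 100
        Multiplier applied to the count fraction (levels are in log2 units
        of "reads per 100 mapped reads").
    pseudo_count : float, default 1e-5
        Additive offset keeping log2 finite for zero counts.
    totals : sequence of float, optional
        Per-column totals overriding the fitted column sums.

    Attributes
    ----------
    totals_ : ndarray of shape (n_samples,)
        Denominators used by :meth:`transform`.
    n_features_in_ : int
    """

    def __init__(
        self,
        scale: float = 100.0,
        pseudo_count: float = 1e-5,
        totals: Sequence[float] | None = None,
    ) -> None:
        self.scale = scale
        self.pseudo_count = pseudo_count
        self.totals = totals

    def fit(self, X, y=None):
        X = _as_2d_float(X, "counts")
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        if self.pseudo_count <= 0:
            raise ValueError(f"pseudo_count must be positive, got {self.pseudo_count}")
        if (X < 0).any():
            t, s = np.argwhere(X < 0)[0]
            raise ValueError(f"negative count at row {t}, column {s}")
        if self.totals is not None:
            totals = np.asarray(self.totals, dtype=float)
            if totals.shape != (X.shape[1],):
                raise ValueError(
                    f"totals has shape {totals.shape}, expected ({X.shape[1]},)"
                )
        else:
            totals = X.sum(axis=0)
        if (totals <= 0).any():
            j = int(np.argwhere(totals <= 0)[0, 0])
            raise ValueError(f"sample at column {j} has non-positive total")
        self.totals_ = totals
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "totals_")
        X = _as_2d_float(X, "counts")
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} columns, got {X.shape[1]}"
            )
        if (X < 0).any():
            t, s = np.argwhere(X < 0)[0]
            raise ValueError(f"negative count at row {t}, column {s}")
        return np.log2((X / self.totals_) * self.scale + self.pseudo_count)


class AdjacentDifferencer(TransformerMixin, BaseEstimator):
    """Difference adjacent columns: ``D[:, i] = X[:, i+1] − X[:, i]``.

    On log2 expression levels this yields the log2 fold change between each
    pair of adjacent nested samples — the in silico subtraction step.
    Positive values mean higher expression in the larger fragment.
    """

    def fit(self, X, y=None):
        X = _as_2d_float(X)
        if X.shape[1] < 2:
            raise ValueError("need at least 2 columns to difference")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "n_features_in_")
        X = _as_2d_float(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} columns, got {X.shape[1]}"
            )
        return X[:, 1:] - X[:, :-1]


class ProfileCoder(TransformerMixin, BaseEstimator):
    """Code log2 fold changes as {+, 0, −} symbols.

    Symbol ``i`` is ``+`` iff ``diff[i] > threshold_i``, ``−`` iff
    ``diff[i] < −threshold_i`` and ``0`` otherwise.  The inequalities are
    strict: a difference of exactly the threshold codes as ``0``
    ("more than two-fold" at the default threshold of 2 log2 units,
    i.e. a four-fold linear change).

    Parameters
    ----------
    threshold : float or sequence of float, default 2.0
        One positive threshold, or one per comparison — e.g. to apply a
        less stringent cut-off at a contamination-prone cutting level.
    """

    def __init__(self, threshold: float | Sequence[float] = 2.0) -> None:
        self.threshold = threshold

    def _thresholds(self, n_comparisons: int) -> np.ndarray:
        thr = np.asarray(self.threshold, dtype=float)
        if thr.ndim == 0:
            thr = np.full(n_comparisons, float(thr))
        if thr.shape != (n_comparisons,):
            raise ValueError(
                f"threshold has shape {thr.shape}, expected scalar or ({n_comparisons},)"
            )
        if (thr <= 0).any():
            raise ValueError("thresholds must be positive")
        return thr

    def fit(self, X, y=None):
        X = _as_2d_float(X, "diffs")
        self._thresholds(X.shape[1])  # validate against width
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        """Return an (n, K−1) array of '+', '0', '−' single characters."""
        check_is_fitted(self, "n_features_in_")
        X = _as_2d_float(X, "diffs")
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} columns, got {X.shape[1]}"
            )
        if not np.isfinite(X).all():
            t = int(np.argwhere(~np.isfinite(X).all(axis=1))[0, 0])
            raise ValueError(f"non-finite difference for transcript at row {t}")
        thr = self._thresholds(X.shape[1])
        symbols = np.full(X.shape, "0", dtype="<U1")
        symbols[X > thr] = "+"
        symbols[X < -thr] = "-"
        return symbols


class PositionalClassifier(BaseEstimator):
    """Counts → organ-region calls for a nested fragment design.

    Composes :class:`ExpressionNormalizer`, :class:`AdjacentDifferencer`
    and :class:`ProfileCoder`, then maps each transcript's profile code to
    a region call:

    * all-zero code → ``"non-differential"``;
    * any ``−`` symbol → ``"other"`` (negative differences reflect
      dilution, not localisation);
    * a single ``+`` at comparison *i* → ``"<region added at i> region"``;
    * ``+`` at the design's contamination-prone pair of adjacent
      comparisons (and ``0`` elsewhere) → the *later* comparison's region
      — the [+,+,0] pattern produced when tissue of the later region
      leaks across the cut into the earlier fragment;
    * anything else → ``"other"``.

    Parameters
    ----------
    design : NestedDesign, optional
        Defaults to the four-sample *M. lignano* design.
    threshold : float or sequence, default 2.0
        Passed to :class:`ProfileCoder`.
    contamination_pair : tuple of two comparison labels, or None
        Overrides the design's pair; ``None`` takes the design's.
    scale, pseudo_count, totals
        Passed to :class:`ExpressionNormalizer`.
    """

    def __init__(
        self,
        design: NestedDesign | None = None,
        threshold: float | Sequence[float] = 2.0,
        contamination_pair: Sequence[str] | None = None,
        scale: float = 100.0,
        pseudo_count: float = 1e-5,
        totals: Sequence[float] | None = None,
    ) -> None:
        self.design = design
        self.threshold = threshold
        self.contamination_pair = contamination_pair
        self.scale = scale
        self.pseudo_count = pseudo_count
        self.totals = totals

    # -- fitting ---------------------------------------------------------

    def fit(self, X, y=None):
        design = self.design if self.design is not None else default_lignano_design()
        X = _as_2d_float(X, "counts")
        if X.shape[1] != design.n_samples:
            raise ValueError(
                f"counts have {X.shape[1]} columns but the design has "
                f"{design.n_samples} samples"
            )
        self.design_ = design
        self.comparison_labels_ = design.comparison_labels
        self.normalizer_ = ExpressionNormalizer(
            scale=self.scale, pseudo_count=self.pseudo_count, totals=self.totals
        ).fit(X)
        self.differencer_ = AdjacentDifferencer().fit(
            np.empty((0, design.n_samples))
        )
        self.coder_ = ProfileCoder(threshold=self.threshold).fit(
            np.empty((0, design.n_comparisons))
        )
        pair = (
            tuple(self.contamination_pair)
            if self.contamination_pair is not None
            else design.contamination_pair
        )
        if pair is not None:
            labels = self.comparison_labels_
            if len(pair) != 2 or any(p not in labels for p in pair):
                raise ValueError(
                    f"contamination_pair {pair} must be two of {labels}"
                )
            if labels.index(pair[1]) != labels.index(pair[0]) + 1:
                raise ValueError(
                    f"contamination_pair {pair} must be adjacent comparisons"
                )
        self.contamination_pair_ = pair
        self.n_features_in_ = X.shape[1]
        return self

    # -- inference -------------------------------------------------------

    def levels(self, X) -> np.ndarray:
        check_is_fitted(self, "normalizer_")
        return self.normalizer_.transform(X)

    def diffs(self, X) -> np.ndarray:
        return self.differencer_.transform(self.levels(X))

    def encode(self, X) -> np.ndarray:
        """Per-transcript (n, K−1) array of profile symbols."""
        return self.coder_.transform(self.diffs(X))

    def predict(self, X) -> np.ndarray:
        """Per-transcript region calls as strings."""
        symbols = self.encode(X)
        return self.calls_from_symbols(symbols)

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).predict(X)

    def calls_from_symbols(self, symbols: np.ndarray) -> np.ndarray:
        """Map an (n, K−1) symbol array to region calls (vectorised)."""
        check_is_fitted(self, "design_")
        design = self.design_
        symbols = np.asarray(symbols, dtype="<U1")
        if symbols.ndim != 2 or symbols.shape[1] != design.n_comparisons:
            raise ValueError(
                f"symbols must have {design.n_comparisons} columns, "
                f"got shape {symbols.shape}"
            )
        plus = symbols == "+"
        minus = symbols == "-"
        n_plus = plus.sum(axis=1)
        calls = np.full(symbols.shape[0], "other", dtype=object)
        calls[(n_plus == 0) & ~minus.any(axis=1)] = "non-differential"
        region_names = [design.comparison_region(i + 1) for i in range(design.n_comparisons)]
        single = (n_plus == 1) & ~minus.any(axis=1)
        for i in range(design.n_comparisons):
            calls[single & plus[:, i]] = f"{region_names[i]} region"
        if self.contamination_pair_ is not None:
            labels = self.comparison_labels_
            i0 = labels.index(self.contamination_pair_[0])
            i1 = labels.index(self.contamination_pair_[1])
            lead = (
                (n_plus == 2) & plus[:, i0] & plus[:, i1] & ~minus.any(axis=1)
            )
            calls[lead] = f"{region_names[i1]} region"
        return calls.astype(str)
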
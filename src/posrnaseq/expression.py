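"""Log2 expression levels and adjacent-sample differences.

A transcript's expression level in a sample is

    level = log2((count / total) * scale + pseudo_count)

with ``scale=100`` and ``pseudo_count=1e-5`` by default, i.e. log2 reads
per 100 mapped reads with a floor of log2(1e-5) ≈ −16.61 for zero counts.
Because the level depends only on the count *fraction*, scaling a sample's
counts uniformly leaves its levels unchanged.

``ExpressionMatrix`` and ``DifferenceMatrix`` are plain
:class:`pandas.DataFrame` objects (transcripts × samples, resp.
transcripts × comparisons); the heavy lifting lives in the estimators.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .counts_io import CountMatrix
from .design import NestedDesign
from .estimators import AdjacentDifferencer, ExpressionNormalizer

__all__ = ["expression_level", "expression_matrix", "adjacent_differences"]

# Type aliases for the in-memory containers.
ExpressionMatrix = pd.DataFrame
DifferenceMatrix = pd.DataFrame


def expression_level(
    count: float,
    total: float,
    scale: float = 100.0,
    pseudo_count: float = 1e-5,
) -> float:
    """Scalar log2 expression level of one count in one sample.

    Strictly increasing in ``count`` at fixed ``total``; equals
    ``log2(pseudo_count)`` when ``count`` is 0, for any total.
    """
    if total <= 0:
        raise ValueError(f"total must be positive, got {total}")
    if count < 0:
        raise ValueError(f"count must be non-negative, got {count}")
    if scale <= 0 or pseudo_count <= 0:
        raise ValueError("scale and pseudo_count must be positive")
    # np.log2, not math.log2: keeps the scalar path bit-identical to the
    # vectorised matrix path (libm and numpy can disagree by one ulp)
    return float(np.log2((count / total) * scale + pseudo_count))


def expression_matrix(
    counts: CountMatrix,
    scale: float = 100.0,
    pseudo_count: float = 1e-5,
) -> ExpressionMatrix:
    """Apply the expression-level formula to every cell of a count matrix.

    Uses each sample's total (column sum, or the matrix's explicit totals
    override).  A sample with total 0 is a hard error naming the sample.
    """
    totals = counts.totals
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total count")
    normalizer = ExpressionNormalizer(
        scale=scale, pseudo_count=pseudo_count, totals=totals.to_numpy()
    ).fit(counts.values())
    levels = normalizer.transform(counts.values())
    return pd.DataFrame(levels, index=counts.transcript_ids, columns=counts.sample_names)


def adjacent_differences(
    expr: ExpressionMatrix, design: NestedDesign
) -> DifferenceMatrix:
    """Difference adjacent samples: column ``"<later>-<earlier>"`` holds
    ``level[later] − level[earlier]``.

    Positive values indicate enrichment in the region(s) added with the
    larger fragment; negative values typically reflect dilution.
    """
    if list(expr.columns) != design.sample_names:
        raise ValueError(
            f"expression columns {list(expr.columns)} do not match design "
            f"samples {design.sample_names} (order matters)"
        )
    differ = AdjacentDifferencer().fit(expr.to_numpy())
    diffs = differ.transform(expr.to_numpy())
    return pd.DataFrame(diffs, index=expr.index, columns=design.comparison_labels)
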
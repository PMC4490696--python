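"""Profile coding, region calling and class summaries.

Each transcript's K−1 adjacent-sample log2 fold changes are coded as a
string over {+, 0, −} (the transcript's *class*, e.g. ``[+,0,0]``), and
the code is mapped to a predicted organ region.  For the canonical
four-sample design:

=========  =================  =============================================
code       call               interpretation
=========  =================  =============================================
[0,0,0]    non-differential   expressed throughout (or below threshold)
[+,0,0]    testis region      appears when the testis fragment is added
[0,+,0]    ovary region       appears when the ovary fragment is added
[+,+,0]    ovary region       ovary-specific with cutting contamination of
                              ovarian tissue into the testis fragment
[0,0,+]    tail region        appears when the tail fragment is added
others     other              complex patterns (incl. any ``−`` symbol,
                              attributed to dilution rather than location)
=========  =================  =============================================
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .counts_io import CountMatrix
from .design import NestedDesign, default_lignano_design
from .estimators import PositionalClassifier, ProfileCoder
from .expression import adjacent_differences, expression_matrix

__all__ = [
    "ProfileCode",
    "encode_profile",
    "encode_profiles",
    "format_code",
    "parse_code",
    "call_region",
    "classify_all",
    "summarize_classes",
    "summarize_class_sizes",
    "ClassSummary",
    "rank_candidates",
]

#: A profile code is a tuple of single-character symbols over {+, 0, -}.
ProfileCode = tuple


def format_code(code: Sequence[str]) -> str:
    """Render a code the way the field writes it: ``[+,0,0]``."""
    return "[" + ",".join(code) + "]"


def parse_code(text: str) -> tuple[str, ...]:
    """Inverse of :func:`format_code`; accepts ``[+,0,0]`` or ``+,0,0``."""
    inner = text.strip().strip("[]")
    symbols = tuple(s.strip() for s in inner.split(","))
    bad = [s for s in symbols if s not in {"+", "0", "-"}]
    if bad:
        raise ValueError(f"invalid profile symbol(s) {bad} in {text!r}")
    return symbols


def encode_profile(
    diffs: Sequence[float], thresholds: float | Sequence[float] = 2.0
) -> tuple[str, ...]:
    """Code one transcript's adjacent differences as {+, 0, −} symbols.

    Symbol ``i`` is ``+`` iff ``diffs[i] > threshold_i``, ``−`` iff
    ``diffs[i] < −threshold_i``, else ``0``.  Inequalities are strict, so
    a difference of exactly 2.00 codes as ``0`` under the default
    two-fold (log2) threshold.
    """
    arr = np.asarray(diffs, dtype=float).reshape(1, -1)
    coder = ProfileCoder(threshold=thresholds).fit(arr)
    return tuple(coder.transform(arr)[0])


def encode_profiles(
    diffs: pd.DataFrame, thresholds: float | Sequence[float] = 2.0
) -> pd.Series:
    """Vectorised :func:`encode_profile`: one formatted code per transcript."""
    coder = ProfileCoder(threshold=thresholds).fit(diffs.to_numpy())
    symbols = coder.transform(diffs.to_numpy())
    codes = ["[" + ",".join(row) + "]" for row in symbols]
    return pd.Series(codes, index=diffs.index, name="profile_code")


def call_region(
    code: Sequence[str],
    design: NestedDesign,
    contamination_pair: Sequence[str] | None = None,
) -> str:
    """Map one profile code to its region call under a design.

    See the module table for the canonical mapping.  In general designs a
    code whose only ``+`` sits at comparison *i* (no ``−`` anywhere) calls
    the region added at *i*; the two-plus leading-contamination pattern is
    honoured only for the design's (or the explicitly given)
    contamination-prone comparison pair; every other code is ``other``.
    """
    code = tuple(code)
    if len(code) != design.n_comparisons:
        raise ValueError(
            f"code length {len(code)} does not match the design's "
            f"{design.n_comparisons} comparisons"
        )
    clf = PositionalClassifier(design=design, contamination_pair=contamination_pair)
    clf.fit(np.ones((1, design.n_samples)))
    return str(clf.calls_from_symbols(np.asarray([code], dtype="<U1"))[0])


def classify_all(
    counts: CountMatrix,
    design: NestedDesign | None = None,
    thresholds: float | Sequence[float] = 2.0,
    contamination_pair: Sequence[str] | None = None,
    scale: float = 100.0,
    pseudo_count: float = 1e-5,
) -> pd.DataFrame:
    """Full chain: counts → levels → differences → codes → region calls.

    Returns the region-call table: one row per transcript (input order
    preserved), with one level column per sample, one difference column
    per comparison, ``profile_code`` and ``region_call``.
    """
    if design is None:
        design = default_lignano_design()
    counts.check_design(design)
    clf = PositionalClassifier(
        design=design,
        threshold=thresholds,
        contamination_pair=contamination_pair,
        scale=scale,
        pseudo_count=pseudo_count,
        totals=counts.totals.to_numpy(),
    ).fit(counts.values())
    levels = clf.levels(counts.values())
    diffs = clf.diffs(counts.values())
    symbols = clf.coder_.transform(diffs)
    calls = clf.calls_from_symbols(symbols)
    table = pd.DataFrame(levels, index=counts.transcript_ids, columns=design.sample_names)
    for i, label in enumerate(design.comparison_labels):
        table[label] = diffs[:, i]
    table["profile_code"] = ["[" + ",".join(row) + "]" for row in symbols]
    table["region_call"] = calls
    return table


@dataclass
class ClassSummary:
    """Per-class tallies of a region-call table.

    ``per_class`` is indexed by formatted profile code with columns ``n``,
    ``percent`` (of all transcripts, full precision),
    ``share_of_differential`` (percent among transcripts with a non-zero
    code; NaN for the all-zero class) and, when differences are
    available, one ``mean_<label>`` column per comparison.
    """

    per_class: pd.DataFrame
    total: int
    n_differential: int


def summarize_classes(
    table: pd.DataFrame, design: NestedDesign | None = None
) -> ClassSummary:
    """Tally transcripts per profile code, with class mean differences."""
    if design is None:
        design = default_lignano_design()
    labels = [c for c in design.comparison_labels if c in table.columns]
    counts = table["profile_code"].value_counts()
    zero_code = format_code(("0",) * design.n_comparisons)
    per = pd.DataFrame({"n": counts})
    total = int(per["n"].sum())
    n_diff = int(per.loc[per.index != zero_code, "n"].sum())
    per["percent"] = 100.0 * per["n"] / total if total else np.nan
    share = 100.0 * per["n"] / n_diff if n_diff else np.nan
    per["share_of_differential"] = share
    if zero_code in per.index:
        per.loc[zero_code, "share_of_differential"] = np.nan
    for label in labels:
        per[f"mean_{label}"] = table.groupby("profile_code")[label].mean()
    per = per.sort_values("n", ascending=False)
    return ClassSummary(per_class=per, total=total, n_differential=n_diff)


def summarize_class_sizes(sizes: Mapping[str, int]) -> ClassSummary:
    """Summary arithmetic from published per-class sizes alone.

    Useful to recompute totals, percentages and differential shares from a
    ``{code: n}`` mapping (codes formatted like ``[+,0,0]``; keys that are
    not pure codes, e.g. ``other``, are treated as differential).
    """
    per = pd.DataFrame({"n": pd.Series(sizes, dtype=int)})
    total = int(per["n"].sum())
    k = len(parse_code(next(c for c in sizes if c.startswith("["))))
    zero_code = format_code(("0",) * k)
    n_diff = int(per.loc[per.index != zero_code, "n"].sum())
    per["percent"] = 100.0 * per["n"] / total
    per["share_of_differential"] = 100.0 * per["n"] / n_diff
    if zero_code in per.index:
        per.loc[zero_code, "share_of_differential"] = np.nan
    return ClassSummary(per_class=per, total=total, n_differential=n_diff)


def rank_candidates(
    table: pd.DataFrame,
    target_call: str,
    top_n: int,
    design: NestedDesign | None = None,
) -> list[str]:
    """Top candidate transcripts for one region call.

    Transcripts carrying ``target_call`` are ordered by descending
    difference at the call-defining comparison (the comparison that adds
    the called region — for the canonical ovary call that is C−B, the
    later of the two contamination-pair comparisons), ties broken by
    lexicographic transcript id, truncated to ``top_n``.
    """
    if design is None:
        design = default_lignano_design()
    hits = table[table["region_call"] == target_call]
    if hits.empty:
        return []
    region = target_call.removesuffix(" region")
    defining = None
    for i in range(1, design.n_comparisons + 1):
        if design.comparison_region(i) == region:
            defining = design.comparison_labels[i - 1]
    if defining is None or defining not in hits.columns:
        # non-differential / other: no defining comparison; id order
        return sorted(hits.index)[: int(top_n)]
    order = hits.assign(_id=hits.index).sort_values(
        [defining, "_id"], ascending=[False, True]
    )
    return list(order.index[: int(top_n)])
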
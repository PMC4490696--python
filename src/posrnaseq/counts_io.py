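"""Reading and writing per-transcript count tables and result tables.

Two input dialects are supported: a plain TSV matrix (header
``transcript_id<TAB><sample>...``) and the per-sample tabular output of an
expected-count quantifier (one file per sample, with at least
``transcript_id`` and ``expected_count`` columns).  Counts may be
fractional: expected counts apportion multi-mapping reads.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import NestedDesign

__all__ = [
    "CountMatrix",
    "read_counts_tsv",
    "read_quantifier_results",
    "write_counts_tsv",
    "write_call_table",
    "read_call_table",
]


class CountMatrix:
    """Transcripts × samples table of non-negative (possibly fractional) counts.

    Wraps a :class:`pandas.DataFrame` whose index holds unique transcript
    ids (taken verbatim — ids like ``RNA815_80.4`` contain dots and are
    never normalised) and whose columns are sample names.  Per-sample
    totals are always recomputed as column sums, never trusted from a
    file; an explicit ``totals`` override (e.g. library-level mapped-read
    totals) may be supplied but must be at least the column sum.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        totals: Mapping[str, float] | None = None,
    ) -> None:
        if frame.index.has_duplicates:
            dup = frame.index[frame.index.duplicated()][0]
            raise ValueError(f"duplicate transcript id {dup!r}")
        if frame.columns.has_duplicates:
            dup = frame.columns[frame.columns.duplicated()][0]
            raise ValueError(f"duplicate sample name {dup!r}")
        values = frame.to_numpy(dtype=float, copy=False)
        if values.size and not np.isfinite(values).all():
            t, s = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite count for transcript {frame.index[t]!r} "
                f"in sample {frame.columns[s]!r}"
            )
        if values.size and (values < 0).any():
            t, s = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count {values[t, s]:g} for transcript "
                f"{frame.index[t]!r} in sample {frame.columns[s]!r}"
            )
        self._frame = frame.astype(float)
        self._totals_override: dict[str, float] | None = None
        if totals is not None:
            colsums = self._frame.sum(axis=0)
            if set(totals) != set(frame.columns):
                raise ValueError("totals override must name every sample exactly once")
            for name, tot in totals.items():
                if tot < colsums[name] - 1e-9:
                    raise ValueError(
                        f"totals override for sample {name!r} ({tot:g}) is below "
                        f"the column sum ({colsums[name]:g})"
                    )
            self._totals_override = {str(k): float(v) for k, v in totals.items()}

    # -- accessors -------------------------------------------------------

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def transcript_ids(self) -> list[str]:
        return list(self._frame.index)

    @property
    def sample_names(self) -> list[str]:
        return list(self._frame.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._frame.shape

    @property
    def totals(self) -> pd.Series:
        """Per-sample totals: the override when set, else column sums."""
        if self._totals_override is not None:
            return pd.Series(
                [self._totals_override[c] for c in self._frame.columns],
                index=self._frame.columns,
                dtype=float,
            )
        return self._frame.sum(axis=0)

    def values(self) -> np.ndarray:
        return self._frame.to_numpy(dtype=float)

    def check_design(self, design: NestedDesign) -> None:
        """Raise unless sample names match the design's, in order."""
        if self.sample_names != design.sample_names:
            raise ValueError(
                f"sample names {self.sample_names} do not match the design's "
                f"{design.sample_names} (order matters)"
            )

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, CountMatrix)
            and self._frame.equals(other._frame)
            and self._totals_override == other._totals_override
        )

    def __repr__(self) -> str:
        n, k = self.shape
        return f"CountMatrix({n} transcripts × {k} samples)"


def read_counts_tsv(path, totals: Mapping[str, float] | None = None) -> CountMatrix:
    """Read the plain TSV dialect: header ``transcript_id`` then sample names.

    Raises a :class:`ValueError` naming the offender for duplicate ids,
    negative values or ragged rows.  A header-only file yields a valid
    0-transcript matrix.
    """
    try:
        frame = pd.read_csv(
            path, sep="\t", header=0, dtype={0: str}, float_precision="round_trip"
        )
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: ragged or malformed row ({exc})") from None
    if frame.shape[1] < 1 or frame.columns[0] != "transcript_id":
        raise ValueError(f"{path}: first header column must be 'transcript_id'")
    if frame.isna().to_numpy().any():
        row = int(frame.isna().any(axis=1).to_numpy().argmax())
        raise ValueError(f"{path}: ragged or missing value in data row {row + 1}")
    frame = frame.set_index("transcript_id")
    frame.index.name = None
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric count value ({exc})") from None
    try:
        return CountMatrix(frame, totals=totals)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def read_quantifier_results(
    paths: Sequence, sample_names: Sequence[str]
) -> CountMatrix:
    """Join per-sample quantifier result files on ``transcript_id``.

    Each file must be TSV with at least ``transcript_id`` and
    ``expected_count`` columns (extra columns are ignored).  Transcripts
    absent from a sample get count 0.  Transcript order is first-seen
    across files in input order.
    """
    if len(paths) != len(sample_names):
        raise ValueError(
            f"got {len(paths)} files for {len(sample_names)} sample names"
        )
    columns: list[pd.Series] = []
    order: list[str] = []
    seen: set[str] = set()
    for path, name in zip(paths, sample_names):
        tab = pd.read_csv(
            path, sep="\t", header=0, dtype={"transcript_id": str},
            float_precision="round_trip",
        )
        for col in ("transcript_id", "expected_count"):
            if col not in tab.columns:
                raise ValueError(f"{path}: missing required column '{col}'")
        series = tab.set_index("transcript_id")["expected_count"].astype(float)
        if series.index.has_duplicates:
            dup = series.index[series.index.duplicated()][0]
            raise ValueError(f"{path}: duplicate transcript id {dup!r}")
        series.name = name
        columns.append(series)
        for tid in series.index:
            if tid not in seen:
                seen.add(tid)
                order.append(tid)
    frame = pd.concat(columns, axis=1).reindex(order).fillna(0.0)
    frame.columns = list(sample_names)
    frame.index.name = None
    return CountMatrix(frame)


def write_counts_tsv(counts: CountMatrix, path) -> None:
    """Write the plain dialect at full precision (exact round-trip)."""
    out = counts.frame.copy()
    out.insert(0, "transcript_id", out.index)
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_call_table(table: pd.DataFrame, path) -> None:
    """Write a region-call table as TSV.

    Columns: ``transcript_id``, one expression-level column per sample,
    one difference column per adjacent comparison, ``profile_code``
    (rendered like ``[+,0,0]``) and ``region_call``.  Floats use 6
    significant digits; row order is the input transcript order.
    """
    out = table.copy()
    out.insert(0, "transcript_id", out.index)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_call_table(path) -> pd.DataFrame:
    """Read back a call table written by :func:`write_call_table`."""
    frame = pd.read_csv(
        path, sep="\t", header=0,
        dtype={"transcript_id": str, "profile_code": str, "region_call": str},
    )
    return frame.set_index("transcript_id").rename_axis(None)
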
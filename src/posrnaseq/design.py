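"""Nested cumulative fragment designs for positional RNA-seq.

A positional RNA-seq experiment sequences a series of body fragments cut at
successive anatomical levels, so that sample ``i`` contains every region of
sample ``i-1`` plus at least one new region.  Differencing adjacent samples
("in silico subtraction") then attributes transcripts to the added region.

The canonical design is the four-sample *Macrostomum lignano* series
A = {head}, B = {head, testis}, C = {head, testis, ovary},
D = {head, testis, ovary, tail} (whole worm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "NestedDesign",
    "default_lignano_design",
    "validate_design",
    "load_design_manifest",
]

#: Keys accepted in a design manifest; anything else is a hard error.
_MANIFEST_KEYS = {"samples", "mass_weights", "contamination_pair", "totals"}


@dataclass(frozen=True)
class NestedDesign:
    """Ordered nested fragment samples and the regions each contains.

    Parameters
    ----------
    samples
        Ordered ``(sample_name, region_set)`` pairs, anterior to posterior.
        Each region set must be a strict superset of the previous one.
    region_order
        All region labels in anatomical (anterior → posterior) order.
    mass_weights
        Optional relative tissue mass per region (positive, summing to 1).
        Used only by the simulator and diagnostics, never by classification.
        ``None`` means equal weights.
    contamination_pair
        Optional pair of adjacent comparison labels ``(earlier, later)``
        flagged as prone to cutting contamination, e.g. ``("B-A", "C-B")``
        when ovarian tissue may leak into the testis fragment.  Region
        calling honours the two-plus "leading contamination" code only for
        this pair.
    """

    samples: tuple[tuple[str, frozenset[str]], ...]
    region_order: tuple[str, ...]
    mass_weights: Mapping[str, float] | None = None
    contamination_pair: tuple[str, str] | None = None

    def __init__(
        self,
        samples: Iterable[tuple[str, Iterable[str]]],
        region_order: Sequence[str],
        mass_weights: Mapping[str, float] | None = None,
        contamination_pair: Sequence[str] | None = None,
    ) -> None:
        object.__setattr__(
            self,
            "samples",
            tuple((str(name), frozenset(regions)) for name, regions in samples),
        )
        object.__setattr__(self, "region_order", tuple(region_order))
        object.__setattr__(
            self,
            "mass_weights",
            dict(mass_weights) if mass_weights is not None else None,
        )
        object.__setattr__(
            self,
            "contamination_pair",
            tuple(contamination_pair) if contamination_pair is not None else None,
        )

    # -- basic accessors -------------------------------------------------

    @property
    def sample_names(self) -> list[str]:
        return [name for name, _ in self.samples]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_comparisons(self) -> int:
        """Number of adjacent-sample comparisons, K - 1."""
        return len(self.samples) - 1

    def region_set(self, sample: str) -> frozenset[str]:
        for name, regions in self.samples:
            if name == sample:
                return regions
        raise KeyError(f"unknown sample {sample!r}")

    def region_added(self, i: int) -> frozenset[str]:
        """Regions added at step ``i`` (1-based comparison index, 1..K-1)."""
        if not 1 <= i <= self.n_comparisons:
            raise IndexError(f"comparison index {i} out of range 1..{self.n_comparisons}")
        return self.samples[i][1] - self.samples[i - 1][1]

    @property
    def comparison_labels(self) -> list[str]:
        """Labels ``"<later>-<earlier>"`` for each adjacent comparison."""
        names = self.sample_names
        return [f"{names[i + 1]}-{names[i]}" for i in range(self.n_comparisons)]

    def comparison_region(self, i: int) -> str:
        """Human-readable label of the region(s) added at comparison ``i``.

        The canonical design adds exactly one region per step; a design that
        adds several reports the union joined with ``"+"`` in anatomical
        order.
        """
        added = self.region_added(i)
        return "+".join(r for r in self.region_order if r in added)

    def weights(self) -> dict[str, float]:
        """Mass weights per region; equal weights when none were given."""
        if self.mass_weights is None:
            w = 1.0 / len(self.region_order)
            return {r: w for r in self.region_order}
        return dict(self.mass_weights)


def _validate_parts(
    samples: Sequence[tuple[str, frozenset[str]]],
    region_order: Sequence[str],
    mass_weights: Mapping[str, float] | None,
    contamination_pair: Sequence[str] | None,
) -> list[str]:
    findings: list[str] = []
    if len(samples) < 2:
        findings.append(f"need at least 2 samples, got {len(samples)}")
    names = [name for name, _ in samples]
    for name in sorted({n for n in names if names.count(n) > 1}):
        findings.append(f"duplicate sample name {name!r}")
    regions = list(region_order)
    if len(set(regions)) != len(regions):
        dup = sorted({r for r in regions if regions.count(r) > 1})
        findings.append(f"duplicate region name(s) {dup}")
    if any(not r for r in regions):
        findings.append("empty region name in region_order")
    region_set = set(regions)
    for name, rs in samples:
        unknown = rs - region_set
        if unknown:
            findings.append(f"sample {name!r} uses unknown region(s) {sorted(unknown)}")
    for i in range(1, len(samples)):
        prev_name, prev = samples[i - 1]
        name, cur = samples[i]
        if not cur > prev:  # strict superset
            findings.append(
                f"nesting violated at sample {name!r}: region set must be a "
                f"strict superset of sample {prev_name!r}'s"
            )
    if samples:
        first_name, first = samples[0]
        if regions and first != {regions[0]}:
            findings.append(
                f"sample {first_name!r} must contain exactly the first region "
                f"{regions[0]!r}, got {sorted(first)}"
            )
        last_name, last = samples[-1]
        if last != region_set:
            findings.append(
                f"last sample {last_name!r} must contain all regions; "
                f"missing {sorted(region_set - last)}"
            )
    covered = set().union(*(rs for _, rs in samples)) if samples else set()
    for r in regions:
        if r not in covered:
            findings.append(f"region {r!r} appears in no sample")
    if mass_weights is not None:
        if set(mass_weights) != region_set:
            findings.append(
                "mass_weights must cover exactly the design regions; got "
                f"{sorted(mass_weights)}"
            )
        elif any(w <= 0 for w in mass_weights.values()):
            findings.append("mass_weights must be positive")
        elif abs(sum(mass_weights.values()) - 1.0) > 1e-9:
            findings.append(
                f"mass_weights must sum to 1, got {sum(mass_weights.values()):g}"
            )
    if contamination_pair is not None:
        labels = [f"{names[i + 1]}-{names[i]}" for i in range(len(names) - 1)]
        pair = tuple(contamination_pair)
        if len(pair) != 2 or any(p not in labels for p in pair):
            findings.append(
                f"contamination_pair {pair} must be two comparison labels among {labels}"
            )
        elif labels.index(pair[1]) != labels.index(pair[0]) + 1:
            findings.append(
                f"contamination_pair {pair} must be two *adjacent* comparisons"
            )
    return findings


def validate_design(design: NestedDesign) -> list[str]:
    """Check every design invariant; return one finding per violation.

    Returns an empty list iff the design is valid.  Findings name the
    offending sample or region; no exception is raised.  The check is pure
    and idempotent.
    """
    return _validate_parts(
        design.samples, design.region_order, design.mass_weights, design.contamination_pair
    )


def default_lignano_design(
    mass_weights: Mapping[str, float] | None = None,
) -> NestedDesign:
    """The four-sample *M. lignano* head/testis/ovary/tail design.

    Sample A is the head fragment, B head+testis, C head+testis+ovary and
    D the whole worm.  The testis→ovary cutting level is flagged as
    contamination-prone (``contamination_pair=("B-A", "C-B")``), so the
    two-plus code [+,+,0] is called as ovary-region.
    """
    return NestedDesign(
        samples=[
            ("A", {"head"}),
            ("B", {"head", "testis"}),
            ("C", {"head", "testis", "ovary"}),
            ("D", {"head", "testis", "ovary", "tail"}),
        ],
        region_order=("head", "testis", "ovary", "tail"),
        mass_weights=mass_weights,
        contamination_pair=("B-A", "C-B"),
    )


def load_design_manifest(path) -> tuple[NestedDesign, dict[str, float] | None]:
    """Parse a YAML design manifest.

    The manifest holds an ordered ``samples:`` list of ``{name, regions}``
    entries plus optional ``mass_weights``, ``contamination_pair`` and a
    per-sample ``totals:`` override for the expression denominator.
    Unknown keys are a hard error (strict parsing).

    Returns
    -------
    (design, totals_override)
        ``totals_override`` is ``None`` when the manifest has no ``totals:``.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"design manifest {path}: expected a mapping at top level")
    unknown = set(raw) - _MANIFEST_KEYS
    if unknown:
        raise ValueError(f"design manifest {path}: unknown key(s) {sorted(unknown)}")
    if "samples" not in raw:
        raise ValueError(f"design manifest {path}: missing required key 'samples'")
    samples = []
    for entry in raw["samples"]:
        if not isinstance(entry, dict) or set(entry) != {"name", "regions"}:
            raise ValueError(
                f"design manifest {path}: each samples entry needs exactly "
                f"'name' and 'regions', got {entry!r}"
            )
        samples.append((str(entry["name"]), [str(r) for r in entry["regions"]]))
    # region order: first-appearance order across the nested samples
    region_order: list[str] = []
    for _, regions in samples:
        for r in regions:
            if r not in region_order:
                region_order.append(r)
    design = NestedDesign(
        samples=samples,
        region_order=region_order,
        mass_weights=raw.get("mass_weights"),
        contamination_pair=raw.get("contamination_pair"),
    )
    findings = validate_design(design)
    if findings:
        raise ValueError(f"design manifest {path}: " + "; ".join(findings))
    totals = raw.get("totals")
    if totals is not None:
        if set(totals) != set(design.sample_names):
            raise ValueError(
                f"design manifest {path}: totals must name every sample exactly once"
            )
        totals = {str(k): float(v) for k, v in totals.items()}
    return design, totals
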
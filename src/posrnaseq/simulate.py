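"""Generative model of the nested-fragment positional RNA-seq experiment.

Each transcript gets a per-region abundance profile: *uniform* transcripts
share one baseline across all regions, while *region-specific* transcripts
concentrate their abundance in a home region (enrichment factor ``f`` over
an optional leakage level elsewhere; with zero leakage they are absent
outside the home region).  A fragment sample is a mass-weighted mixture of
its regions, optionally contaminated by a small mass fraction of an
adjacent absent region (cutting error).  Reads are drawn multinomially at
fixed library size, so the model reproduces the two signature artefacts of
the design: the *dilution effect* (a transcript's relative abundance
falls as fragments grow) and *contamination-shifted codes* (ovary-specific
transcripts coded [+,+,0] instead of [0,+,0]).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .counts_io import CountMatrix
from .design import NestedDesign, default_lignano_design, validate_design

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "default_mass_weights",
    "build_truth",
    "fragment_mixture",
    "simulate_counts",
    "load_simulation_config",
    "write_truth_tsv",
    "read_truth_tsv",
]

#: Default relative tissue masses for the four-region worm design
#: (head, testis, ovary, tail) — a fixture choice, freely overridable.
DEFAULT_MASS_WEIGHTS = {"head": 0.35, "testis": 0.25, "ovary": 0.15, "tail": 0.25}

_CONFIG_KEYS = {
    "n_transcripts", "spec_fractions", "enrichment", "leakage",
    "base_abundance_logmean", "base_abundance_logsd", "contamination",
    "library_sizes", "overdispersion", "seed", "noiseless", "design",
}


def default_mass_weights() -> dict[str, float]:
    return dict(DEFAULT_MASS_WEIGHTS)


@dataclass
class SimulationConfig:
    """Parameters of one simulated nested-fragment experiment.

    Parameters
    ----------
    n_transcripts : int
        Transcriptome size.
    design : NestedDesign
        Fragment design; defaults to the four-sample worm design with the
        default mass weights.
    spec_fractions : mapping region → fraction
        Fraction of transcripts planted as specific to each region
        (largest-remainder rounding); the remainder is uniform.  Defaults
        to 5 % each for testis, ovary and tail — the head region is the
        first fragment's region and can never be identified by
        subtraction, so nothing is planted there by default.
    enrichment : float
        Fold factor ``f ≥ 1`` between a specific transcript's home-region
        abundance and its leakage level.
    leakage : float
        Per-mass abundance of a specific transcript outside its home
        region, as a multiple of its baseline (0 = perfectly specific).
    base_abundance_logmean, base_abundance_logsd : float
        Natural-log parameters of the log-normal per-transcript baseline.
    contamination : mapping ``"sample:region"`` or (sample, region) → ε
        Mass fraction of an *absent* region erroneously present in a
        fragment (cutting error), e.g. ``{("B", "ovary"): 0.02}``.
    library_sizes : int or mapping sample → int
        Reads per sample (multinomial size).
    overdispersion : float or None
        Gamma shape for extra-multinomial abundance noise (None = off).
    seed : int or None
        Seed for the single random generator used per run.
    noiseless : bool
        If True, return real-valued expected counts instead of sampling.
    """

    n_transcripts: int = 2000
    design: NestedDesign = None  # type: ignore[assignment]
    spec_fractions: Mapping[str, float] = None  # type: ignore[assignment]
    enrichment: float = 64.0
    leakage: float = 0.0
    base_abundance_logmean: float = 0.0
    base_abundance_logsd: float = 1.0
    contamination: Mapping = field(default_factory=dict)
    library_sizes: int | Mapping[str, int] = 5_000_000
    overdispersion: float | None = None
    seed: int | None = None
    noiseless: bool = False

    def __post_init__(self) -> None:
        if self.design is None:
            self.design = default_lignano_design(mass_weights=default_mass_weights())
        if self.spec_fractions is None:
            self.spec_fractions = {"testis": 0.05, "ovary": 0.05, "tail": 0.05}
        self.contamination = {
            _contamination_key(k): float(v) for k, v in dict(self.contamination).items()
        }
        self.validate()

    def validate(self) -> None:
        findings = validate_design(self.design)
        if findings:
            raise ValueError("invalid design: " + "; ".join(findings))
        if self.n_transcripts <= 0:
            raise ValueError("n_transcripts must be positive")
        regions = set(self.design.region_order)
        unknown = set(self.spec_fractions) - regions
        if unknown:
            raise ValueError(f"spec_fractions for unknown region(s) {sorted(unknown)}")
        if any(f < 0 for f in self.spec_fractions.values()):
            raise ValueError("spec_fractions must be non-negative")
        if sum(self.spec_fractions.values()) > 1 + 1e-12:
            raise ValueError("spec_fractions must sum to at most 1")
        if self.enrichment < 1:
            raise ValueError("enrichment must be ≥ 1")
        if self.leakage < 0:
            raise ValueError("leakage must be ≥ 0")
        for (sample, region), eps in self.contamination.items():
            if not 0 <= eps < 1:
                raise ValueError(f"contamination ε for ({sample}, {region}) not in [0, 1)")
        for name in self.design.sample_names:
            if self.library_size(name) <= 0:
                raise ValueError(f"library size for sample {name!r} must be positive")
        if self.overdispersion is not None and self.overdispersion <= 0:
            raise ValueError("overdispersion (gamma shape) must be positive")

    def library_size(self, sample: str) -> int:
        if isinstance(self.library_sizes, Mapping):
            return int(self.library_sizes[sample])
        return int(self.library_sizes)

    def to_dict(self) -> dict:
        """JSON-serialisable echo of the configuration (for provenance)."""
        return {
            "n_transcripts": self.n_transcripts,
            "design": {
                "samples": [
                    {"name": n, "regions": sorted(rs)} for n, rs in self.design.samples
                ],
                "region_order": list(self.design.region_order),
                "mass_weights": self.design.mass_weights,
                "contamination_pair": self.design.contamination_pair,
            },
            "spec_fractions": dict(self.spec_fractions),
            "enrichment": self.enrichment,
            "leakage": self.leakage,
            "base_abundance_logmean": self.base_abundance_logmean,
            "base_abundance_logsd": self.base_abundance_logsd,
            "contamination": {f"{s}:{r}": e for (s, r), e in self.contamination.items()},
            "library_sizes": (
                dict(self.library_sizes)
                if isinstance(self.library_sizes, Mapping)
                else self.library_sizes
            ),
            "overdispersion": self.overdispersion,
            "seed": self.seed,
            "noiseless": self.noiseless,
        }


def _contamination_key(key) -> tuple[str, str]:
    if isinstance(key, str):
        sample, _, region = key.partition(":")
        if not region:
            raise ValueError(
                f"contamination key {key!r} must be 'sample:region' or a (sample, region) pair"
            )
        return sample, region
    sample, region = key
    return str(sample), str(region)


@dataclass
class TruthTable:
    """Planted ground truth: per-transcript label and per-region abundance.

    ``labels`` maps each transcript to ``"uniform"`` or its home region;
    ``abundance`` is the transcripts × regions matrix a(t, r) of per-mass
    abundances the mixture model draws reads from.
    """

    labels: pd.Series
    abundance: pd.DataFrame

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.labels.index)

    def expected_call(self, region_of_comparison: Mapping[str, str] | None = None) -> pd.Series:
        """The region call a perfect classifier would make per transcript
        (uniform → non-differential, specific → "<home> region")."""
        return self.labels.map(
            lambda lab: "non-differential" if lab == "uniform" else f"{lab} region"
        )


def build_truth(config: SimulationConfig, rng: np.random.Generator | None = None) -> TruthTable:
    """Assign planted labels and abundances; deterministic given the seed.

    Label counts follow ``spec_fractions`` by largest-remainder rounding
    (an exact product like 0.1 × 100 yields exactly 10 transcripts);
    label positions are shuffled, baselines are log-normal.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_transcripts
    regions = list(config.design.region_order)
    fractions = [float(config.spec_fractions.get(r, 0.0)) for r in regions]
    # largest-remainder apportionment of n among regions + uniform remainder
    exact = [f * n for f in fractions]
    counts = [int(np.floor(e + 1e-9)) for e in exact]
    remainder = [e - c for e, c in zip(exact, counts)]
    short = int(round(sum(exact))) - sum(counts)
    for idx in sorted(range(len(regions)), key=lambda i: -remainder[i])[:max(short, 0)]:
        counts[idx] += 1
    labels = ["uniform"] * (n - sum(counts))
    for r, c in zip(regions, counts):
        labels.extend([r] * c)
    labels_arr = np.array(labels, dtype=object)
    rng.shuffle(labels_arr)
    ids = [f"tx{i + 1:06d}" for i in range(n)]
    baseline = np.exp(
        rng.normal(config.base_abundance_logmean, config.base_abundance_logsd, size=n)
    )
    a = np.empty((n, len(regions)))
    for j, r in enumerate(regions):
        a[:, j] = baseline
    f = config.enrichment
    lam = config.leakage
    for j, r in enumerate(regions):
        specific = labels_arr == r
        if lam == 0:
            a[specific, :] = 0.0
            a[specific, j] = baseline[specific] * f
        else:
            for jj in range(len(regions)):
                a[specific, jj] = baseline[specific] * lam
            a[specific, j] = baseline[specific] * lam * f
    return TruthTable(
        labels=pd.Series(labels_arr, index=ids, name="label"),
        abundance=pd.DataFrame(a, index=ids, columns=regions),
    )


def fragment_mixture(
    design: NestedDesign,
    contamination: Mapping,
    sample: str,
) -> dict[str, float]:
    """Mass share of every region in one fragment sample.

    Included regions contribute their design mass weight; an absent region
    may additionally contribute a contamination mass fraction ε.  Shares
    are renormalised to sum to 1.  Declaring ε for a region the fragment
    already contains is an error — contamination only *adds* tissue.
    """
    regions = design.region_set(sample)
    weights = design.weights()
    shares = {r: (weights[r] if r in regions else 0.0) for r in design.region_order}
    for key, eps in dict(contamination).items():
        s, r = _contamination_key(key)
        if s != sample:
            continue
        if r in regions:
            raise ValueError(
                f"contamination of sample {sample!r} with region {r!r} is invalid: "
                "the region is already part of the fragment"
            )
        if r not in shares:
            raise ValueError(f"contamination names unknown region {r!r}")
        shares[r] += eps
    total = sum(shares.values())
    return {r: v / total for r, v in shares.items()}


def simulate_counts(
    config: SimulationConfig,
) -> tuple[CountMatrix, TruthTable]:
    """Draw a count matrix from the mixture model.

    The expected concentration of transcript *t* in sample *s* is
    proportional to ``Σ_r mixture(s)[r] · a(t, r)``.  With ``noiseless``
    the expected counts ``library_size · p(t, s)`` are returned verbatim;
    otherwise counts are multinomial at the library size (after optional
    per-cell gamma perturbation of the abundances), so column sums equal
    the library sizes exactly.  Fully reproducible from the seed.
    """
    rng = np.random.default_rng(config.seed)
    truth = build_truth(config, rng)
    design = config.design
    regions = list(design.region_order)
    a = truth.abundance.to_numpy()
    columns = {}
    for sample in design.sample_names:
        mix = fragment_mixture(design, config.contamination, sample)
        mix_vec = np.array([mix[r] for r in regions])
        q = a @ mix_vec
        if config.overdispersion is not None and not config.noiseless:
            shape = config.overdispersion
            q = q * rng.gamma(shape, 1.0 / shape, size=q.shape)
        total = q.sum()
        if total <= 0:
            raise ValueError(f"sample {sample!r} has zero total abundance")
        p = q / total
        size = config.library_size(sample)
        if config.noiseless:
            columns[sample] = size * p
        else:
            columns[sample] = rng.multinomial(size, p).astype(float)
    frame = pd.DataFrame(columns, index=truth.transcript_ids)
    return CountMatrix(frame), truth


def load_simulation_config(path) -> SimulationConfig:
    """Parse a YAML simulation config (strict: unknown keys are errors)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"simulation config {path}: expected a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"simulation config {path}: unknown key(s) {sorted(unknown)}")
    design = None
    if "design" in raw:
        d = raw["design"]
        samples = [(e["name"], e["regions"]) for e in d["samples"]]
        if "region_order" in d:
            region_order = d["region_order"]
        else:
            region_order = []
            for _, rs in samples:
                for r in rs:
                    if r not in region_order:
                        region_order.append(r)
        design = NestedDesign(
            samples=samples,
            region_order=region_order,
            mass_weights=d.get("mass_weights"),
            contamination_pair=d.get("contamination_pair"),
        )
    kwargs = {k: v for k, v in raw.items() if k != "design"}
    return SimulationConfig(design=design, **kwargs)


def write_truth_tsv(truth: TruthTable, path) -> None:
    out = truth.abundance.copy()
    out.insert(0, "label", truth.labels)
    out.insert(0, "transcript_id", out.index)
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_truth_tsv(path) -> TruthTable:
    frame = pd.read_csv(
        path, sep="\t", header=0, dtype={"transcript_id": str},
        float_precision="round_trip",
    )
    frame = frame.set_index("transcript_id").rename_axis(None)
    return TruthTable(
        labels=frame["label"].rename("label"),
        abundance=frame.drop(columns=["label"]).astype(float),
    )
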
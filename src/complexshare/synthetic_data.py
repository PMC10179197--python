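"""Synthetic tissue-labeled abundance matrices with known ground truth.

The generator emulates the data regimes the pipeline consumes: a GTEx-like
bulk matrix (a dozen tissues, tens of samples each, log-normal sample noise
on linear TPM) and a sparse proteomics-like matrix (one sample per tissue,
dropout zeros).  Two kinds of ground-truth signal can be planted:

* a multiplicative fold-change of one gene in a set of tissues (the
  "minor paralog up in one organ" archetype) — co-members' shares adjust
  automatically through the group denominator, and
* hard tissue restriction — the gene is exactly zero outside its tissue set
  (the "exclusively expressed" archetype, e.g. an elongation-factor paralog
  present only in brain/heart/muscle analogs), exercising zero-handling.

Log-normal noise is the declared noise model (the standard heavy-right-tail
model for TPM), not an inference from any particular dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .catalog import CatalogWarning, ComplexTable, load_complex_table

__all__ = [
    "GeneProfile",
    "PlantedEffect",
    "SyntheticSpec",
    "GroundTruth",
    "generate",
    "preset",
    "spec_to_yaml",
    "spec_from_yaml",
]

PRESET_NAMES = ("gtex_like", "proteome_like", "null")

#: tissue labels used by the bundled presets (GTEx-role analogs)
_PRESET_TISSUES = (
    "blood", "brain", "heart", "kidney", "liver", "lung",
    "muscle", "ovary", "pancreas", "pituitary", "spleen", "testis",
)
_EXTRA_TISSUES = (
    "adrenal", "colon", "esophagus", "prostate",
    "skin", "stomach", "thyroid", "uterus",
)


@dataclass(frozen=True)
class GeneProfile:
    """Baseline expression model of one gene.

    ``log_mean``/``log_sd`` parameterize the log-normal abundance
    ``exp(Normal(log_mean, log_sd))``.  ``restricted_to`` (a tissue set)
    makes the gene exactly zero outside those tissues.
    """

    symbol: str
    log_mean: float
    log_sd: float = 0.5
    restricted_to: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.log_sd < 0:
            raise ValueError(f"gene {self.symbol!r}: log_sd must be >= 0")


@dataclass(frozen=True)
class PlantedEffect:
    """Multiplicative fold-change of ``gene`` in the given tissues."""

    gene: str
    tissues: tuple[str, ...]
    fold: float

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError(f"effect on {self.gene!r}: fold must be > 0")


@dataclass
class SyntheticSpec:
    """Full specification of one synthetic dataset."""

    tissues: dict[str, int]  # label -> samples per tissue
    genes: list[GeneProfile]
    groups: ComplexTable
    effects: list[PlantedEffect] = field(default_factory=list)
    dropout: float = 0.0
    seed: int = 0
    unit_label: str = "TPM"

    def validate(self) -> None:
        if len(self.tissues) < 2:
            raise ValueError("tissues: need >= 2 tissue labels")
        for label, count in self.tissues.items():
            if count < 1:
                raise ValueError(f"tissues: {label!r} needs >= 1 sample")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout: must be in [0, 1)")
        symbols = [g.symbol for g in self.genes]
        if len(set(symbols)) != len(symbols):
            raise ValueError("genes: duplicated symbol")
        known = set(symbols)
        grouped = {m for mm in self.groups.groups.values() for m in mm}
        for eff in self.effects:
            if eff.gene not in known:
                raise ValueError(f"effects: gene {eff.gene!r} not in gene list")
            if eff.gene not in grouped:
                raise ValueError(f"effects: gene {eff.gene!r} belongs to no group")
            unknown = set(eff.tissues) - set(self.tissues)
            if unknown:
                raise ValueError(f"effects: unknown tissue(s) {sorted(unknown)}")
        for g in self.genes:
            if g.restricted_to is not None:
                unknown = set(g.restricted_to) - set(self.tissues)
                if unknown:
                    raise ValueError(
                        f"genes: {g.symbol!r} restricted to unknown tissue(s) {sorted(unknown)}"
                    )


@dataclass
class GroundTruth:
    """Planted signal of a generated dataset."""

    effects: list[PlantedEffect]
    restricted: dict[str, tuple[str, ...]]
    annotation: pd.Series


def generate(spec: SyntheticSpec) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Draw one abundance matrix from the spec; reproducible given the seed.

    ``abundance(g, s) = exp(Normal(log_mean_g, log_sd_g)) * prod(applicable
    fold-changes)``, then tissue-restriction and dropout zeroing.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sample_ids: list[str] = []
    labels: list[str] = []
    for tissue, count in spec.tissues.items():
        for i in range(count):
            sample_ids.append(f"{tissue}-{i:03d}")
            labels.append(tissue)
    annotation = pd.Series(labels, index=pd.Index(sample_ids, name="sample"), name="tissue")
    n_genes, n_samples = len(spec.genes), len(sample_ids)

    z = rng.standard_normal((n_genes, n_samples))
    log_mean = np.array([g.log_mean for g in spec.genes])[:, None]
    log_sd = np.array([g.log_sd for g in spec.genes])[:, None]
    values = np.exp(log_mean + log_sd * z)

    tissue_mask = {t: (annotation.to_numpy() == t) for t in spec.tissues}
    gene_row = {g.symbol: i for i, g in enumerate(spec.genes)}
    for eff in spec.effects:
        cols = np.zeros(n_samples, dtype=bool)
        for t in eff.tissues:
            cols |= tissue_mask[t]
        values[gene_row[eff.gene], cols] *= eff.fold
    restricted: dict[str, tuple[str, ...]] = {}
    for g in spec.genes:
        if g.restricted_to is not None:
            allowed = np.zeros(n_samples, dtype=bool)
            for t in g.restricted_to:
                allowed |= tissue_mask[t]
            values[gene_row[g.symbol], ~allowed] = 0.0
            restricted[g.symbol] = tuple(g.restricted_to)
    if spec.dropout > 0:
        values[rng.random((n_genes, n_samples)) < spec.dropout] = 0.0

    matrix = pd.DataFrame(
        values,
        index=pd.Index([g.symbol for g in spec.genes], name="gene"),
        columns=sample_ids,
    )
    matrix.attrs["unit_label"] = spec.unit_label
    truth = GroundTruth(
        effects=list(spec.effects), restricted=restricted, annotation=annotation
    )
    return matrix, annotation, truth


def _preset_groups() -> ComplexTable:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", CatalogWarning)
        full = load_complex_table()
    keep = ("eIF2B", "eIF3", "PABPC paralogs", "ELONGATION")
    return ComplexTable(
        groups={k: full.members(k) for k in keep},
        provenance={k: full.provenance.get(k, "") for k in keep},
    )


# minor-paralog planted effects: low-baseline genes shifted up in one tissue,
# so the gene's own share moves strongly while co-members' shares barely do
_PRESET_EFFECTS = (
    PlantedEffect("EEF1A2", ("muscle",), 10.0),
    PlantedEffect("EIF5A2", ("testis",), 6.0),
    PlantedEffect("PABPC3", ("testis",), 8.0),
    PlantedEffect("PABPC1L", ("ovary",), 5.0),
    PlantedEffect("EIF3J", ("brain",), 4.0),
    PlantedEffect("EIF2B4", ("testis",), 3.0),
)
_PRESET_MINOR = tuple(e.gene for e in _PRESET_EFFECTS)
_PRESET_BACKGROUND = ("ACTB", "GAPDH", "RPL13A", "RPS6")


def _preset_genes(groups: ComplexTable) -> list[GeneProfile]:
    symbols: dict[str, None] = {}
    for members in groups.groups.values():
        for m in members:
            symbols[m] = None
    genes = [
        GeneProfile(
            symbol=s,
            log_mean=np.log(2.0) if s in _PRESET_MINOR else np.log(100.0),
            log_sd=0.5,
        )
        for s in symbols
    ]
    genes += [GeneProfile(symbol=s, log_mean=np.log(200.0), log_sd=0.5) for s in _PRESET_BACKGROUND]
    return genes


def preset(name: str, seed: int = 0) -> SyntheticSpec:
    """Named study conditions.

    * ``gtex_like`` — 12 tissues x 30 samples, 40 genes in 4 bundled groups,
      6 planted single-tissue effects of fold 3-10 on minor-paralog genes.
    * ``null`` — the same geometry with no planted effects (calibration).
    * ``proteome_like`` — 20 tissues x 1 sample, dropout 0.3, intensity units.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    groups = _preset_groups()
    genes = _preset_genes(groups)
    if name == "gtex_like":
        return SyntheticSpec(
            tissues={t: 30 for t in _PRESET_TISSUES},
            genes=genes,
            groups=groups,
            effects=list(_PRESET_EFFECTS),
            seed=seed,
        )
    if name == "null":
        return SyntheticSpec(
            tissues={t: 30 for t in _PRESET_TISSUES},
            genes=genes,
            groups=groups,
            effects=[],
            seed=seed,
        )
    return SyntheticSpec(
        tissues={t: 1 for t in (*_PRESET_TISSUES, *_EXTRA_TISSUES)},
        genes=genes,
        groups=groups,
        effects=[],
        dropout=0.3,
        seed=seed,
        unit_label="intensity",
    )


def spec_to_yaml(spec: SyntheticSpec, path: str | Path) -> None:
    """Serialize a spec as a YAML config (round-trips with spec_from_yaml)."""
    doc = {
        "tissues": dict(spec.tissues),
        "genes": [
            {
                "symbol": g.symbol,
                "log_mean": float(g.log_mean),
                "log_sd": float(g.log_sd),
                **({"restricted_to": list(g.restricted_to)} if g.restricted_to else {}),
            }
            for g in spec.genes
        ],
        "groups": {k: list(v) for k, v in spec.groups.groups.items()},
        "effects": [
            {"gene": e.gene, "tissues": list(e.tissues), "fold": float(e.fold)}
            for e in spec.effects
        ],
        "dropout": float(spec.dropout),
        "seed": int(spec.seed),
        "unit_label": spec.unit_label,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def spec_from_yaml(path: str | Path) -> SyntheticSpec:
    """Load a spec from a YAML config; fields are validated on generate."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        genes = [
            GeneProfile(
                symbol=g["symbol"],
                log_mean=float(g["log_mean"]),
                log_sd=float(g.get("log_sd", 0.5)),
                restricted_to=tuple(g["restricted_to"]) if g.get("restricted_to") else None,
            )
            for g in doc["genes"]
        ]
        effects = [
            PlantedEffect(e["gene"], tuple(e["tissues"]), float(e["fold"]))
            for e in doc.get("effects", [])
        ]
        spec = SyntheticSpec(
            tissues={str(k): int(v) for k, v in doc["tissues"].items()},
            genes=genes,
            groups=ComplexTable(
                groups={k: list(v) for k, v in doc["groups"].items()}
            ),
            effects=effects,
            dropout=float(doc.get("dropout", 0.0)),
            seed=int(doc.get("seed", 0)),
            unit_label=str(doc.get("unit_label", "TPM")),
        )
    except KeyError as exc:
        raise ValueError(f"synthetic spec {path}: missing field {exc}") from exc
    return spec
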
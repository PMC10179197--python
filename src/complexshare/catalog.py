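"""Complex/group definitions and a minimal gene-metadata registry.

The package ships a curated table of protein complexes and functional groups
of the human translation machinery (initiation, elongation and termination
factor complexes, poly(A)-binding protein paralogs, aminoacyl-tRNA
synthetases and the multi-synthetase complex), together with two small
metadata tables:

* a symbol-alias table bridging HGNC symbol generations (e.g. ``VARS`` vs
  ``VARS1``, ``TARSL2`` vs ``TARS3``), and
* a chromosome annotation restricted to the sex-linked translation factor
  genes (``EIF1AX``/``EIF1AY``, ``DDX3X``/``DDX3Y``, ``EIF2S3``,
  ``PABPC5``); every other gene defaults to ``"autosome"``.

Group membership is the unit of analysis downstream: within-group expression
shares are computed per sample and tested for tissue enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "CatalogWarning",
    "GeneRecord",
    "ComplexTable",
    "load_complex_table",
    "load_gene_registry",
    "genes_on_chromosome",
    "resolve_symbols",
    "ribosomal_protein_genes",
    "bundled_path",
]


class CatalogWarning(UserWarning):
    """Data-quality warning raised while loading catalog tables."""


def bundled_path(name: str) -> Path:
    """Return the filesystem path of a bundled data file (``data/<name>``)."""
    return Path(resources.files("complexshare").joinpath("data", name))


@dataclass(frozen=True)
class GeneRecord:
    """Gene symbol with chromosome annotation and alternative symbols."""

    symbol: str
    chromosome: str = "autosome"
    aliases: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("GeneRecord symbol must be non-empty")


@dataclass
class ComplexTable:
    """Named groups of gene symbols with free-text provenance notes.

    ``groups`` preserves the member order of the source table; duplicated
    members within a group are collapsed on load (the bundled table prints
    EIF3J twice in the eIF3-containing rows).
    """

    groups: dict[str, list[str]] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.groups.items():
            if len(members) < 2:
                raise ValueError(
                    f"group {name!r} has {len(members)} member(s); need >= 2"
                )
            if len(set(members)) != len(members):
                raise ValueError(f"group {name!r} contains duplicated symbols")

    def __contains__(self, name: str) -> bool:
        return name in self.groups

    def __len__(self) -> int:
        return len(self.groups)

    def members(self, name: str) -> list[str]:
        return list(self.groups[name])


def _dedupe(members: Iterable[str]) -> tuple[list[str], list[str]]:
    seen: dict[str, None] = {}
    dupes = []
    for m in members:
        if m in seen:
            dupes.append(m)
        else:
            seen[m] = None
    return list(seen), dupes


def load_complex_table(path: str | Path | None = None) -> ComplexTable:
    """Load a complex/group table from TSV (``group``, ``genes`` [, ``note``]).

    ``genes`` is a comma-separated symbol list.  ``path=None`` loads the
    bundled default table.  Duplicated symbols within a group are collapsed
    to one occurrence and reported through :class:`CatalogWarning`.

    Raises
    ------
    FileNotFoundError
        If the file is missing.
    ValueError
        For an empty group or an unparseable row (the error names the row).
    """
    src = bundled_path("complexes.tsv") if path is None else Path(path)
    if not src.exists():
        raise FileNotFoundError(f"complex table not found: {src}")
    groups: dict[str, list[str]] = {}
    provenance: dict[str, str] = {}
    with open(src) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ValueError(f"complex table {src}: header must have >= 2 columns")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ValueError(f"complex table {src} row {lineno}: expected >= 2 columns")
            name = fields[0].strip()
            raw = [g.strip() for g in fields[1].split(",") if g.strip()]
            if not name or not raw:
                raise ValueError(f"complex table {src} row {lineno}: empty group name or member list")
            if name in groups:
                raise ValueError(f"complex table {src} row {lineno}: duplicated group {name!r}")
            members, dupes = _dedupe(raw)
            if dupes:
                warnings.warn(
                    f"group {name!r}: collapsed duplicated member(s) {sorted(set(dupes))}",
                    CatalogWarning,
                    stacklevel=2,
                )
            groups[name] = members
            provenance[name] = fields[2].strip() if len(fields) > 2 else ""
    return ComplexTable(groups=groups, provenance=provenance)


def _read_two_col(path: Path) -> list[tuple[str, str]]:
    rows = []
    with open(path) as fh:
        fh.readline()  # header
        for line in fh:
            if not line.strip():
                continue
            a, b = line.rstrip("\n").split("\t")[:2]
            rows.append((a.strip(), b.strip()))
    return rows


def load_gene_registry(
    complex_table: ComplexTable | None = None,
    alias_path: str | Path | None = None,
    chromosome_path: str | Path | None = None,
) -> list[GeneRecord]:
    """Build the validated gene registry for a complex table.

    One record per primary symbol in the table (union over groups), with
    chromosome annotation from the chromosome table (default: the bundled
    sex-linked set; everything else ``"autosome"``) and aliases from the
    alias table.  A symbol that appears as an alias of another symbol is not
    also created as its own record, so aliases never collide with primary
    symbols.
    """
    table = load_complex_table() if complex_table is None else complex_table
    alias_rows = _read_two_col(
        bundled_path("aliases.tsv") if alias_path is None else Path(alias_path)
    )
    chrom = dict(
        _read_two_col(
            bundled_path("chromosomes.tsv") if chromosome_path is None else Path(chromosome_path)
        )
    )
    alias_of: dict[str, list[str]] = {}
    alias_symbols: set[str] = set()
    for canonical, alias in alias_rows:
        alias_of.setdefault(canonical, []).append(alias)
        alias_symbols.add(alias)

    primaries: dict[str, None] = {}
    for members in table.groups.values():
        for m in members:
            if m not in alias_symbols:
                primaries[m] = None
    # canonical alias sources not present in any group still get a record so
    # that chromosome annotation and resolution work for them
    for canonical in alias_of:
        if canonical not in alias_symbols:
            primaries.setdefault(canonical, None)

    registry = [
        GeneRecord(
            symbol=sym,
            chromosome=chrom.get(sym, "autosome"),
            aliases=tuple(alias_of.get(sym, ())),
        )
        for sym in primaries
    ]
    _validate_registry(registry)
    return registry


def _validate_registry(registry: Iterable[GeneRecord]) -> None:
    records = list(registry)
    symbols = [r.symbol for r in records]
    if len(set(symbols)) != len(symbols):
        raise ValueError("registry contains duplicated primary symbols")
    primary = set(symbols)
    for rec in records:
        for alias in rec.aliases:
            if alias in primary:
                raise ValueError(
                    f"alias {alias!r} of {rec.symbol!r} collides with a primary symbol"
                )


def genes_on_chromosome(registry: Iterable[GeneRecord], chromosome: str) -> list[str]:
    """All registry symbols annotated on ``chromosome``, sorted lexicographically.

    An unknown chromosome label yields an empty list (not an error).
    """
    return sorted(r.symbol for r in registry if r.chromosome == chromosome)


def resolve_symbols(
    table: ComplexTable,
    matrix_genes: Iterable[str],
    registry: Iterable[GeneRecord] | None = None,
) -> dict[str, tuple[list[str], list[str]]]:
    """Match each group's members against matrix gene identifiers.

    Aliases are applied in both directions (a member printed under either
    symbol generation matches a matrix row under the other).  Unmatched
    members are returned in the ``missing`` list, never silently dropped.

    Returns
    -------
    dict
        ``group -> (matched matrix symbols, missing member symbols)``, both
        in member order.
    """
    available = set(matrix_genes)
    # bidirectional alias lookup: symbol -> equivalence set
    equiv: dict[str, set[str]] = {}
    if registry is not None:
        for rec in registry:
            group = {rec.symbol, *rec.aliases}
            for s in group:
                equiv.setdefault(s, set()).update(group)

    out: dict[str, tuple[list[str], list[str]]] = {}
    for name, members in table.groups.items():
        matched: list[str] = []
        missing: list[str] = []
        seen: set[str] = set()
        for m in members:
            candidates = [m, *sorted(equiv.get(m, set()) - {m})]
            hit = next((c for c in candidates if c in available), None)
            if hit is None:
                missing.append(m)
            elif hit not in seen:
                matched.append(hit)
                seen.add(hit)
        out[name] = (matched, missing)
    return out


def ribosomal_protein_genes(path: str | Path | None = None) -> list[str]:
    """Bundled cytoplasmic ribosomal protein gene symbols (RPL*/RPS* set)."""
    src = bundled_path("ribosomal_proteins.tsv") if path is None else Path(path)
    with open(src) as fh:
        fh.readline()
        return [line.strip() for line in fh if line.strip()]
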
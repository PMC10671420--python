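"""Curation of phenotype and 22q13-region gene lists.

Gene lists for the five neurological phenotypes (ASD, intellectual
disability, seizures, hypotonia, language impairment) and for the
22q13.2-q13.33 region are supplied as plain two-column TSV files; this
module loads them, normalizes symbols, and merges them into a single
multi-label annotation table over the union of all symbols.  A gene may
carry several labels (the sets overlap; SHANK3, for instance, is both an
ASD and a seizure gene).

Symbol matching is exact after upper-casing.  No alias or synonym
resolution is attempted; an optional user-supplied two-column alias file
can be applied before matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Closed label vocabulary of the study; user-defined extras are allowed.
STANDARD_LABELS = (
    "ASD",
    "ID",
    "seizures",
    "hypotonia",
    "language_impairment",
    "region_22q13",
)

N_LABELS_COLUMN = "n_labels"


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (case-normalized to upper)."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        if any((not g) or g != g.upper() for g in self.genes):
            raise ValueError(f"gene set {self.name!r}: symbols must be non-empty upper-case")

    def __len__(self) -> int:
        return len(self.genes)


def _normalize_symbol(raw: str, path: Path, lineno: int) -> str:
    symbol = raw.strip()
    if not symbol:
        raise ValueError(f"{path}:{lineno}: empty gene symbol")
    if any(ch.isspace() for ch in symbol):
        raise ValueError(
            f"{path}:{lineno}: malformed gene symbol {symbol!r} (embedded whitespace)"
        )
    return symbol.upper()


def load_alias_map(path: str | Path) -> dict[str, str]:
    """Load a two-column TSV mapping legacy symbol -> current symbol."""
    path = Path(path)
    aliases: dict[str, str] = {}
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: alias line needs two columns")
            old = _normalize_symbol(parts[0], path, lineno)
            new = _normalize_symbol(parts[1], path, lineno)
            aliases[old] = new
    return aliases


def load_gene_set(
    path: str | Path,
    name: str,
    alias_map: Mapping[str, str] | None = None,
) -> GeneSet:
    """Load one gene list from a two-column TSV (gene<TAB>note, note optional).

    Lines starting with '#' and a single optional header line whose first
    field is 'gene' (case-insensitive) are skipped.  Duplicate symbols
    (after upper-casing and optional aliasing) are logged and dropped; an
    empty result is an error.
    """
    path = Path(path)
    genes: list[str] = []
    seen: set[str] = set()
    n_dup = 0
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            first = line.split("\t")[0]
            if lineno == 1 and first.strip().lower() == "gene":
                continue
            symbol = _normalize_symbol(first, path, lineno)
            if alias_map:
                symbol = alias_map.get(symbol, symbol)
            if symbol in seen:
                n_dup += 1
                continue
            seen.add(symbol)
            genes.append(symbol)
    if n_dup:
        logger.info("gene set %s: %d duplicate symbol(s) in %s dropped", name, n_dup, path)
    if not genes:
        raise ValueError(f"{path}: no genes parsed")
    return GeneSet(name=name, genes=frozenset(genes))


def load_combined_sets(path: str | Path, alias_map: Mapping[str, str] | None = None) -> list[GeneSet]:
    """Load several sets from one combined TSV with lines gene<TAB>set-name."""
    path = Path(path)
    members: dict[str, set[str]] = {}
    order: list[str] = []
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected gene<TAB>set-name")
            if lineno == 1 and parts[0].strip().lower() == "gene":
                continue
            symbol = _normalize_symbol(parts[0], path, lineno)
            if alias_map:
                symbol = alias_map.get(symbol, symbol)
            set_name = parts[1].strip()
            if not set_name:
                raise ValueError(f"{path}:{lineno}: empty set name")
            if set_name not in members:
                members[set_name] = set()
                order.append(set_name)
            members[set_name].add(symbol)
    if not members:
        raise ValueError(f"{path}: no genes parsed")
    return [GeneSet(name=n, genes=frozenset(members[n])) for n in order]


@dataclass
class GeneAnnotationTable:
    """Multi-label gene annotation: one boolean column per gene set.

    The underlying frame is indexed by gene symbol, carries one boolean
    column per set plus the derived integer column ``n_labels`` (number of
    sets the gene belongs to, always >= 1 for genes built from sets).
    """

    df: pd.DataFrame
    set_names: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        cols = [c for c in self.df.columns if c != N_LABELS_COLUMN]
        if self.df.index.has_duplicates:
            dupes = self.df.index[self.df.index.duplicated()].tolist()
            raise ValueError(f"duplicate genes in annotation table: {dupes[:5]}")
        self.df = self.df.copy()
        for c in cols:
            self.df[c] = self.df[c].astype(bool)
        self.df[N_LABELS_COLUMN] = self.df[cols].sum(axis=1).astype(int)
        self.set_names = tuple(cols)

    @property
    def genes(self) -> list[str]:
        return list(self.df.index)

    def members(self, set_name: str) -> set[str]:
        """Genes carrying the given label."""
        if set_name not in self.set_names:
            raise KeyError(f"unknown set {set_name!r}")
        return set(self.df.index[self.df[set_name]])

    def labels_of(self, gene: str) -> tuple[str, ...]:
        row = self.df.loc[gene]
        return tuple(s for s in self.set_names if row[s])

    def to_tsv(self, path: str | Path) -> None:
        out = self.df.copy()
        for c in self.set_names:
            out[c] = out[c].astype(int)
        out.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneAnnotationTable":
        df = pd.read_csv(path, sep="\t", index_col="gene")
        cols = [c for c in df.columns if c != N_LABELS_COLUMN]
        return cls(df[cols].astype(bool))


def build_annotation(sets: Sequence[GeneSet]) -> GeneAnnotationTable:
    """Merge gene sets into one annotation table over the union of symbols."""
    if not sets:
        raise ValueError("need at least one gene set")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate set names: {sorted(names)}")
    universe = sorted(set().union(*(s.genes for s in sets)))
    data = {s.name: [g in s.genes for g in universe] for s in sets}
    df = pd.DataFrame(data, index=pd.Index(universe, name="gene"))
    table = GeneAnnotationTable(df)
    logger.info(
        "annotation table: %d genes across %d sets (%s)",
        len(universe),
        len(sets),
        ", ".join(f"{s.name}={len(s)}" for s in sets),
    )
    return table
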
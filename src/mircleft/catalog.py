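"""Curated cleft-lip gene catalog: mutant records, set algebra, and
systematic-review bookkeeping (screening ledger, Cohen's kappa, Venn counts).
"""

from __future__ import annotations

import csv
import re
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import AliasConflictError, DomainError, ParseError, ValidationError

__all__ = [
    "TableKind",
    "Stage",
    "MutantRecord",
    "GeneCatalog",
    "VennCounts",
    "ClassContribution",
    "ScreeningRecord",
    "ScreeningLedger",
    "CLEFT_TOKENS",
    "parse_cleft_tokens",
    "load_mutant_records",
    "build_gene_union",
    "class_contribution",
    "venn_from_counts",
    "cohen_kappa",
    "prisma_flow",
    "filter_by_cleft_type",
    "load_screening_ledger",
    "screener_agreement_table",
]


class TableKind(str, Enum):
    single = "single"
    spontaneous = "spontaneous"
    compound = "compound"


class Stage(str, Enum):
    identified = "identified"
    screened = "screened"
    full_text = "full_text"
    included = "included"


STAGE_ORDER: tuple[Stage, ...] = (
    Stage.identified,
    Stage.screened,
    Stage.full_text,
    Stage.included,
)

#: Atomic phenotype tokens a cleft-type label may be built from.
CLEFT_TOKENS = frozenset(
    {"CL", "CLO", "CLP", "CPO", "CP", "midfacial cleft", "midfacial"}
)

_CLEFT_SPLIT = re.compile(r"\s*(?:,\s*(?:or\s+|and\s+)?|\s+or\s+|\s+and\s+)\s*")
_AKA = re.compile(r"^(?P<primary>.+?)\s*\(aka\s+(?P<aliases>[^)]+)\)\s*$")
_NOT_GENE = re.compile(r"not\s+gene", re.IGNORECASE)

CATALOG_COLUMNS = (
    "record_id",
    "table_kind",
    "gene_symbols",
    "aliases",
    "cleft_type",
    "penetrance_note",
    "pmids",
    "note",
)


def parse_cleft_tokens(label: str) -> tuple[str, ...]:
    """Split a cleft-type label like ``"CLO, CLP, or CPO"`` into its tokens.

    Raises :class:`ValidationError` if any token is unrecognized.
    """
    label = label.strip()
    if not label:
        raise ValidationError("cleft_type label is empty")
    tokens = tuple(t for t in _CLEFT_SPLIT.split(label) if t)
    unknown = [t for t in tokens if t not in CLEFT_TOKENS]
    if unknown:
        raise ValidationError(
            f"unknown cleft_type token(s) {unknown!r} in label {label!r}"
        )
    return tokens


@dataclass(frozen=True)
class MutantRecord:
    """One curated row of the single/spontaneous/compound mutant tables."""

    record_id: str
    table_kind: TableKind
    gene_symbols: tuple[str, ...]
    aliases: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    cleft_type: str = ""
    penetrance_note: str = ""
    pmids: tuple[str, ...] = ()
    note: str = ""

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValidationError("record_id must be nonempty")
        if not self.gene_symbols and not _NOT_GENE.search(self.note):
            raise ValidationError(
                f"{self.record_id}: gene_symbols empty but row is not marked 'Not gene'"
            )
        if self.table_kind is TableKind.compound and len(self.gene_symbols) != 2:
            raise ValidationError(
                f"{self.record_id}: compound records need exactly 2 symbols, "
                f"got {len(self.gene_symbols)}"
            )
        parse_cleft_tokens(self.cleft_type)  # validates non-emptiness and tokens

    @property
    def cleft_tokens(self) -> tuple[str, ...]:
        return parse_cleft_tokens(self.cleft_type)

    @property
    def is_gene_less(self) -> bool:
        return not self.gene_symbols


@dataclass(frozen=True)
class GeneCatalog:
    """Deduplicated, alias-resolved gene set with per-table provenance."""

    symbols: frozenset[str]
    provenance: Mapping[str, frozenset[TableKind]]
    alias_index: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = set(self.alias_index.values()) - self.symbols
        if bad:
            raise ValidationError(f"alias targets not in catalog: {sorted(bad)}")
        shadowed = self.symbols & set(self.alias_index)
        if shadowed:
            raise ValidationError(f"symbols also listed as aliases: {sorted(shadowed)}")
        missing = self.symbols - set(self.provenance)
        if missing:
            raise ValidationError(f"symbols without provenance: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.symbols)

    def resolve(self, name: str) -> str:
        """Map an alias (or primary symbol) to its primary symbol."""
        name = name.strip()
        return self.alias_index.get(name, name)


@dataclass(frozen=True)
class VennCounts:
    a_only: int
    both: int
    b_only: int

    def __post_init__(self) -> None:
        if min(self.a_only, self.both, self.b_only) < 0:
            raise DomainError("Venn components must be non-negative")

    @property
    def union(self) -> int:
        return self.a_only + self.both + self.b_only


@dataclass(frozen=True)
class ClassContribution:
    single_total: int
    spontaneous_new: int
    compound_new: int

    @property
    def total(self) -> int:
        return self.single_total + self.spontaneous_new + self.compound_new


def _parse_symbol_cell(cell: str) -> tuple[tuple[str, ...], dict[str, tuple[str, ...]]]:
    """Parse a ';'-separated symbol cell with optional '(aka X)' annotations."""
    symbols: list[str] = []
    aliases: dict[str, tuple[str, ...]] = {}
    for part in cell.split(";"):
        part = " ".join(part.split())  # collapse stray internal whitespace
        if not part:
            continue
        m = _AKA.match(part)
        if m:
            primary = m.group("primary").strip()
            alts = tuple(a.strip() for a in re.split(r"[|&]", m.group("aliases")) if a.strip())
            aliases[primary] = alts
        else:
            primary = part
        symbols.append(primary)
    return tuple(symbols), aliases


def _parse_alias_column(cell: str) -> dict[str, tuple[str, ...]]:
    """Parse 'primary=alt1|alt2;primary2=alt3' pairs."""
    out: dict[str, tuple[str, ...]] = {}
    for pair in cell.split(";"):
        pair = pair.strip()
        if not pair:
            continue
        if "=" not in pair:
            raise ParseError(f"malformed alias pair {pair!r} (expected 'primary=alt')")
        primary, alts = pair.split("=", 1)
        out[primary.strip()] = tuple(a.strip() for a in alts.split("|") if a.strip())
    return out


def load_mutant_records(path: str | Path, table_kind: TableKind | str) -> list[MutantRecord]:
    """Load one catalog fixture TSV into validated :class:`MutantRecord` rows."""
    table_kind = TableKind(table_kind)
    path = Path(path)
    records: list[MutantRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or tuple(reader.fieldnames) != CATALOG_COLUMNS:
            raise ParseError(
                f"{path}: bad header {reader.fieldnames!r}, expected {CATALOG_COLUMNS!r}"
            )
        for row in reader:
            lineno = reader.line_num
            if None in row or any(v is None for v in row.values()):
                raise ParseError(f"{path}:{lineno}: wrong number of fields")
            try:
                symbols, inline_aliases = _parse_symbol_cell(row["gene_symbols"])
                aliases = {**inline_aliases, **_parse_alias_column(row["aliases"])}
                rec = MutantRecord(
                    record_id=row["record_id"].strip(),
                    table_kind=table_kind,
                    gene_symbols=symbols,
                    aliases=aliases,
                    cleft_type=row["cleft_type"].strip(),
                    penetrance_note=row["penetrance_note"].strip(),
                    pmids=tuple(p.strip() for p in row["pmids"].split(";") if p.strip()),
                    note=row["note"].strip(),
                )
            except (ValidationError, ParseError) as exc:
                raise type(exc)(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


def build_gene_union(records: Iterable[MutantRecord]) -> GeneCatalog:
    """Union of primary symbols across records, with alias resolution.

    Gene-less ("Not gene") records are kept out of the symbol set; a
    conflicting alias assignment raises :class:`AliasConflictError`.
    """
    symbols: set[str] = set()
    provenance: dict[str, set[TableKind]] = {}
    alias_index: dict[str, str] = {}
    for rec in records:
        for primary, alts in rec.aliases.items():
            for alt in alts:
                prior = alias_index.get(alt)
                if prior is not None and prior != primary:
                    raise AliasConflictError(
                        f"alias {alt!r} assigned to both {prior!r} and {primary!r}"
                    )
                alias_index[alt] = primary
        for sym in rec.gene_symbols:
            symbols.add(sym)
            provenance.setdefault(sym, set()).add(rec.table_kind)
    # A name introduced both as primary and as someone's alias collapses to
    # the primary form (e.g. plain "Wnt9b" vs "Wnt9b (aka Clf1)").
    alias_index = {a: p for a, p in alias_index.items() if a not in symbols}
    return GeneCatalog(
        symbols=frozenset(symbols),
        provenance={s: frozenset(k) for s, k in provenance.items()},
        alias_index=alias_index,
    )


def class_contribution(
    records: Iterable[MutantRecord], catalog: GeneCatalog
) -> ClassContribution:
    """Decompose the catalog into single-total / spontaneous-new / compound-new."""
    by_kind: dict[TableKind, set[str]] = {k: set() for k in TableKind}
    for rec in records:
        by_kind[rec.table_kind].update(rec.gene_symbols)
    single = by_kind[TableKind.single]
    spont_new = by_kind[TableKind.spontaneous] - single
    compound_new = by_kind[TableKind.compound] - single - by_kind[TableKind.spontaneous]
    contrib = ClassContribution(len(single), len(spont_new), len(compound_new))
    if contrib.total != len(catalog):
        raise DomainError(
            f"class contributions sum to {contrib.total}, catalog has {len(catalog)}"
        )
    return contrib


def venn_from_counts(n_a: int, n_b: int, n_union: int) -> VennCounts:
    """Recover the two-set Venn partition from set sizes by inclusion-exclusion."""
    if not (max(n_a, n_b) <= n_union <= n_a + n_b):
        raise DomainError(
            f"counts inconsistent with any pair of sets: |A|={n_a}, |B|={n_b}, "
            f"|A∪B|={n_union}"
        )
    both = n_a + n_b - n_union
    return VennCounts(a_only=n_a - both, both=both, b_only=n_b - both)


def cohen_kappa(agreement: Sequence[Sequence[int]]) -> float:
    """Unweighted Cohen's kappa for a 2x2 include/exclude agreement table.

    ``agreement`` is ``[[both_include, A_only], [B_only, both_exclude]]``.
    """
    (a, b), (c, d) = agreement
    if min(a, b, c, d) < 0:
        raise ValidationError("agreement counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        raise ValidationError("agreement table is empty")
    p_o = (a + d) / n
    p_e = ((a + b) * (a + c) + (c + d) * (b + d)) / (n * n)
    if b == 0 and c == 0:
        return 1.0
    if p_e == 1.0:
        raise DomainError("degenerate marginals (p_e = 1) with imperfect agreement")
    return (p_o - p_e) / (1.0 - p_e)


@dataclass(frozen=True)
class ScreeningRecord:
    record_id: str
    screener_a_include: bool
    screener_b_include: bool
    stage_reached: Stage


@dataclass(frozen=True)
class ScreeningLedger:
    rows: tuple[ScreeningRecord, ...]

    def __len__(self) -> int:
        return len(self.rows)


def load_screening_ledger(path: str | Path) -> ScreeningLedger:
    path = Path(path)
    expected = ("record_id", "screenerA", "screenerB", "stage")
    rows: list[ScreeningRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or tuple(reader.fieldnames) != expected:
            raise ParseError(f"{path}: bad header, expected {expected!r}")
        for row in reader:
            lineno = reader.line_num
            try:
                rows.append(
                    ScreeningRecord(
                        record_id=row["record_id"].strip(),
                        screener_a_include=_parse_bool(row["screenerA"]),
                        screener_b_include=_parse_bool(row["screenerB"]),
                        stage_reached=Stage(row["stage"].strip()),
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return ScreeningLedger(rows=tuple(rows))


def _parse_bool(token: str) -> bool:
    token = token.strip().lower()
    if token in {"1", "true", "yes", "include"}:
        return True
    if token in {"0", "false", "no", "exclude"}:
        return False
    raise ValueError(f"not a boolean: {token!r}")


def prisma_flow(ledger: ScreeningLedger) -> dict[Stage, int]:
    """Cumulative per-stage counts: how many records reached each stage."""
    reached = Counter(r.stage_reached for r in ledger.rows)
    counts: dict[Stage, int] = {}
    running = 0
    for stage in reversed(STAGE_ORDER):
        running += reached.get(stage, 0)
        counts[stage] = running
    counts = {s: counts[s] for s in STAGE_ORDER}
    prev = None
    for stage in STAGE_ORDER:
        if prev is not None and counts[stage] > prev:
            raise ValidationError("stage counts increase along the stage order")
        prev = counts[stage]
    return counts


def screener_agreement_table(ledger: ScreeningLedger) -> list[list[int]]:
    """2x2 include/exclude agreement counts for :func:`cohen_kappa`."""
    a = sum(r.screener_a_include and r.screener_b_include for r in ledger.rows)
    b = sum(r.screener_a_include and not r.screener_b_include for r in ledger.rows)
    c = sum(not r.screener_a_include and r.screener_b_include for r in ledger.rows)
    d = sum(not r.screener_a_include and not r.screener_b_include for r in ledger.rows)
    return [[a, b], [c, d]]


def filter_by_cleft_type(
    records: Sequence[MutantRecord], label: str, mode: str = "exact"
) -> list[MutantRecord]:
    """Subset records by cleft-type label.

    ``mode="exact"`` keeps records whose full label equals ``label``;
    ``mode="contains"`` keeps records whose token list contains ``label``
    (which must then be a single recognized token). Input order is preserved.
    """
    if mode not in {"exact", "contains"}:
        raise ValidationError(f"unknown matching mode {mode!r}")
    if mode == "contains":
        if label not in CLEFT_TOKENS:
            raise ValidationError(f"unknown cleft_type token {label!r}")
        return [r for r in records if label in r.cleft_tokens]
    parse_cleft_tokens(label)  # validates the label itself
    return [r for r in records if r.cleft_type == label]
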
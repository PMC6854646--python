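"""miRNA-target interaction collections and their merge into a queryable map."""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ParseError, ValidationError

__all__ = [
    "Interaction",
    "TargetMap",
    "canonicalize_mirna",
    "load_interactions",
    "merge_sources",
    "gene_universe",
    "write_interactions",
    "INTERACTION_COLUMNS",
]

logger = logging.getLogger(__name__)

INTERACTION_COLUMNS = ("mirna", "gene", "source", "score")

# Species prefix ("mmu-", "hsa-", ...) is only treated as such when followed
# by a miRNA stem, so canonicalize("let-7a") never strips "let-".
_SPECIES_PREFIX = re.compile(r"^[a-z]{3}-(?=(miR|mir|let)-)")


def canonicalize_mirna(name: str, strip_species: bool = False) -> str:
    """Normalize a miRNA identifier.

    Internal whitespace is removed (the printed form "miR-466 l" becomes
    "miR-466l"); arm suffixes (-3p/-5p) are preserved, so "miR-124" and
    "miR-124-3p" stay distinct. With ``strip_species`` the leading species
    prefix (e.g. "mmu-") is dropped. Idempotent.
    """
    canonical = re.sub(r"\s+", "", name)
    if not canonical:
        raise ValidationError("miRNA identifier is empty")
    if strip_species:
        # iterate to a fixpoint so stacked prefixes cannot break idempotence
        while True:
            stripped = _SPECIES_PREFIX.sub("", canonical)
            if stripped == canonical:
                break
            canonical = stripped
    return canonical


@dataclass(frozen=True)
class Interaction:
    """One miRNA-gene link from one resource, score uninterpreted."""

    mirna: str
    gene: str
    source: str
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.mirna:
            raise ValidationError("interaction has empty miRNA id")
        if not self.gene:
            raise ValidationError("interaction has empty gene symbol")


@dataclass(frozen=True)
class TargetMap:
    """Merged miRNA -> target-gene-set mapping over a defined gene universe."""

    targets: Mapping[str, frozenset[str]]
    provenance: Mapping[tuple[str, str], frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        mapped = {(m, g) for m, genes in self.targets.items() for g in genes}
        if mapped != set(self.provenance):
            raise ValidationError("provenance keys do not match the mapped pairs")
        stray = {g for genes in self.targets.values() for g in genes} - self.universe
        if stray:
            raise ValidationError(f"target genes outside the universe: {sorted(stray)}")

    def __len__(self) -> int:
        return len(self.targets)


def load_interactions(path: str | Path, strip_species: bool = False) -> list[Interaction]:
    """Parse one interaction TSV; exact duplicate triples are dropped."""
    path = Path(path)
    interactions: list[Interaction] = []
    seen: set[tuple[str, str, str]] = set()
    n_dupes = 0
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or tuple(reader.fieldnames) != INTERACTION_COLUMNS:
            raise ParseError(
                f"{path}: bad header {reader.fieldnames!r}, expected {INTERACTION_COLUMNS!r}"
            )
        for row in reader:
            lineno = reader.line_num
            if None in row or any(v is None for v in row.values()):
                raise ParseError(f"{path}:{lineno}: wrong number of fields")
            gene = row["gene"].strip()
            if not gene:
                raise ValidationError(f"{path}:{lineno}: empty gene field")
            try:
                mirna = canonicalize_mirna(row["mirna"], strip_species=strip_species)
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            source = row["source"].strip()
            key = (mirna, gene, source)
            if key in seen:
                n_dupes += 1
                continue
            seen.add(key)
            score_cell = row["score"].strip()
            score = float(score_cell) if score_cell else None
            interactions.append(Interaction(mirna, gene, source, score))
    if n_dupes:
        logger.info("%s: dropped %d duplicate (mirna, gene, source) triples", path, n_dupes)
    return interactions


def merge_sources(
    interaction_lists: Sequence[Iterable[Interaction]],
    min_sources: int = 1,
    universe: Iterable[str] | None = None,
) -> TargetMap:
    """Merge per-resource interaction lists into one :class:`TargetMap`.

    A (mirna, gene) pair is retained iff it is supported by at least
    ``min_sources`` distinct resource names. The universe defaults to all
    genes seen in any input *before* the filter.
    """
    if not 1 <= min_sources <= max(len(interaction_lists), 1):
        raise ValidationError(
            f"min_sources={min_sources} out of range for {len(interaction_lists)} resources"
        )
    support: dict[tuple[str, str], set[str]] = {}
    all_genes: set[str] = set()
    for interactions in interaction_lists:
        for it in interactions:
            support.setdefault((it.mirna, it.gene), set()).add(it.source)
            all_genes.add(it.gene)
    kept = {pair: srcs for pair, srcs in support.items() if len(srcs) >= min_sources}
    targets: dict[str, set[str]] = {}
    for mirna, gene in kept:
        targets.setdefault(mirna, set()).add(gene)
    tmap = TargetMap(
        targets={m: frozenset(g) for m, g in targets.items()},
        provenance={pair: frozenset(srcs) for pair, srcs in kept.items()},
        universe=frozenset(all_genes),
    )
    if universe is not None:
        return TargetMap(
            targets=tmap.targets,
            provenance=tmap.provenance,
            universe=frozenset(gene_universe(tmap, universe)),
        )
    return tmap


def gene_universe(tmap: TargetMap, override: Iterable[str] | None = None) -> frozenset[str]:
    """The background gene set; an override must cover every mapped gene."""
    if override is None:
        return tmap.universe
    override_set = frozenset(override)
    mapped = {g for genes in tmap.targets.values() for g in genes}
    missing = mapped - override_set
    if missing:
        raise ValidationError(
            f"override universe is missing mapped genes: {sorted(missing)}"
        )
    return override_set


def write_interactions(tmap: TargetMap, path: str | Path) -> None:
    """Serialize a map back to the interaction dialect (one row per source)."""
    path = Path(path)
    rows = sorted(
        (mirna, gene, source)
        for (mirna, gene), sources in tmap.provenance.items()
        for source in sources
    )
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(INTERACTION_COLUMNS)
        for mirna, gene, source in rows:
            writer.writerow([mirna, gene, source, ""])
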
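"""Rank query genes by how many significant miRNAs list them as targets."""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .enrichment import EnrichmentResult
from .errors import ValidationError

__all__ = [
    "CoverageRow",
    "gene_coverage",
    "coverage_conservation_check",
    "write_coverage",
    "COVERAGE_COLUMNS",
]

COVERAGE_COLUMNS = ("gene", "n_mirnas", "mirnas")


@dataclass(frozen=True)
class CoverageRow:
    gene: str
    mirnas: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.mirnas) < 1:
            raise ValidationError(f"{self.gene}: coverage row needs >= 1 miRNA")
        if len(set(self.mirnas)) != len(self.mirnas):
            raise ValidationError(f"{self.gene}: duplicate miRNAs in coverage row")

    @property
    def n_mirnas(self) -> int:
        return len(self.mirnas)


def gene_coverage(
    results: Sequence[EnrichmentResult], min_count: int = 2
) -> list[CoverageRow]:
    """Count, per gene, the distinct miRNAs whose shared-gene lists include it.

    Rows with fewer than ``min_count`` miRNAs are dropped; output is sorted
    by count descending, then gene symbol ascending.
    """
    if min_count < 1:
        raise ValidationError(f"min_count must be >= 1, got {min_count}")
    hits: dict[str, set[str]] = defaultdict(set)
    for res in results:
        for gene in res.shared_genes:
            hits[gene].add(res.mirna)
    rows = [
        CoverageRow(gene=gene, mirnas=tuple(sorted(mirnas)))
        for gene, mirnas in hits.items()
        if len(mirnas) >= min_count
    ]
    rows.sort(key=lambda r: (-r.n_mirnas, r.gene))
    return rows


def coverage_conservation_check(
    results: Sequence[EnrichmentResult], coverage_all: Sequence[CoverageRow]
) -> bool:
    """Audit: total coverage counts must equal total shared-gene counts.

    ``coverage_all`` must have been computed from ``results`` with
    ``min_count=1``; any duplicated gene inside a shared-gene list breaks
    the conservation and is reported as ``False``.
    """
    return sum(r.n_mirnas for r in coverage_all) == sum(r.k for r in results)


def write_coverage(rows: Sequence[CoverageRow], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(COVERAGE_COLUMNS)
        for row in rows:
            writer.writerow([row.gene, row.n_mirnas, ",".join(row.mirnas)])
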
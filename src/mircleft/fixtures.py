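"""Loaders for the packaged catalog, enrichment, and coverage fixture tables."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .catalog import MutantRecord, TableKind, load_mutant_records
from .enrichment import EnrichmentResult
from .target_map import canonicalize_mirna

__all__ = [
    "fixture_path",
    "load_single_gene_records",
    "load_spontaneous_records",
    "load_compound_records",
    "load_all_catalog_records",
    "load_enrichment_table",
    "enrichment_results",
    "load_coverage_table",
]

_CATALOG_FILES = {
    TableKind.single: "single.tsv",
    TableKind.spontaneous: "spontaneous.tsv",
    TableKind.compound: "compound.tsv",
}


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(str(resources.files("mircleft.data").joinpath(name)))


def load_single_gene_records() -> list[MutantRecord]:
    return load_mutant_records(fixture_path("single.tsv"), TableKind.single)


def load_spontaneous_records() -> list[MutantRecord]:
    return load_mutant_records(fixture_path("spontaneous.tsv"), TableKind.spontaneous)


def load_compound_records() -> list[MutantRecord]:
    return load_mutant_records(fixture_path("compound.tsv"), TableKind.compound)


def load_all_catalog_records() -> list[MutantRecord]:
    return (
        load_single_gene_records()
        + load_spontaneous_records()
        + load_compound_records()
    )


def load_enrichment_table() -> pd.DataFrame:
    """The transcribed per-miRNA enrichment fixture.

    Columns: ``mirna`` (canonical), ``mirna_raw`` (as printed), ``n_genes``
    (printed count), ``genes`` (tuple, printed order), ``p_value``, ``fdr``.
    """
    df = pd.read_csv(fixture_path("enrichment.tsv"), sep="\t", dtype=str)
    out = pd.DataFrame(
        {
            "mirna": [canonicalize_mirna(m) for m in df["mirna"]],
            "mirna_raw": df["mirna"],
            "n_genes": df["n_genes"].astype(int),
            "genes": [tuple(g.split(",")) for g in df["genes"]],
            "p_value": df["p_value"].astype(float),
            "fdr": df["fdr"].astype(float),
        }
    )
    return out


def enrichment_results(
    df: pd.DataFrame | None = None, fdr_threshold: float = 0.2
) -> list[EnrichmentResult]:
    """View fixture rows as :class:`EnrichmentResult` objects (fdr taken as data)."""
    if df is None:
        df = load_enrichment_table()
    return [
        EnrichmentResult(
            mirna=row.mirna,
            shared_genes=tuple(row.genes),
            p_value=row.p_value,
            fdr=row.fdr,
            significant=row.fdr < fdr_threshold,
        )
        for row in df.itertuples()
    ]


def load_coverage_table() -> pd.DataFrame:
    """The transcribed gene-coverage fixture (printed row order preserved).

    Columns: ``gene``, ``n_mirnas``, ``mirnas`` (tuple of canonical,
    species-prefix-free ids, printed order).
    """
    df = pd.read_csv(fixture_path("coverage.tsv"), sep="\t", dtype=str)
    return pd.DataFrame(
        {
            "gene": df["gene"],
            "n_mirnas": df["n_mirnas"].astype(int),
            "mirnas": [
                tuple(canonicalize_mirna(m) for m in cell.split(","))
                for cell in df["mirnas"]
            ],
        }
    )
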
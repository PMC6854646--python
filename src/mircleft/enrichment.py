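"""Per-miRNA over-representation: 2x2 contingency construction, exact
Fisher p-values, Benjamini-Hochberg adjustment, and the significance filter.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .errors import DomainError, ValidationError
from .target_map import TargetMap, gene_universe

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "build_contingency",
    "fisher_pvalue",
    "bh_adjust",
    "run_enrichment",
    "filter_significant",
    "read_results",
    "write_results",
    "RESULT_COLUMNS",
]

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ("mirna", "n_genes", "genes", "p_value", "fdr", "significant")

#: Relative tolerance on the point-probability comparison of the two-sided rule.
TWO_SIDED_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts behind one miRNA's test.

    ``a`` = target ∩ query (the shared genes), ``b`` = target only,
    ``c`` = query only, ``d`` = neither.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def target_total(self) -> int:
        return self.a + self.b

    @property
    def query_total(self) -> int:
        return self.a + self.c


@dataclass(frozen=True)
class EnrichmentResult:
    """One miRNA's shared-gene list with raw and adjusted significance."""

    mirna: str
    shared_genes: tuple[str, ...]
    p_value: float
    fdr: float
    significant: bool
    table: ContingencyTable | None = None

    @property
    def k(self) -> int:
        return len(self.shared_genes)


def build_contingency(
    target_set: Iterable[str], query_set: Iterable[str], universe: Iterable[str]
) -> ContingencyTable:
    """Cross-tabulate target membership against query membership over the universe."""
    universe = frozenset(universe)
    if not universe:
        raise DomainError("gene universe is empty")
    target = frozenset(target_set)
    stray_target = target - universe
    if stray_target:
        raise ValidationError(f"target genes outside universe: {sorted(stray_target)}")
    query = frozenset(query_set)
    dropped = query - universe
    if dropped:
        logger.info("dropped %d query genes outside the universe", len(dropped))
        query &= universe
    a = len(target & query)
    b = len(target - query)
    c = len(query - target)
    return ContingencyTable(a=a, b=b, c=c, d=len(universe) - a - b - c)


def _hypergeom_support(table: ContingencyTable) -> range:
    lo = max(0, table.target_total + table.query_total - table.n)
    hi = min(table.target_total, table.query_total)
    return range(lo, hi + 1)


def _log_pmf(table: ContingencyTable, xs: np.ndarray) -> np.ndarray:
    """log P(X = x) for X ~ Hypergeom(N, target_total, query_total)."""
    n_, k_, q_ = table.n, table.target_total, table.query_total

    def _logc(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
        return gammaln(np.asarray(n) + 1) - gammaln(np.asarray(k) + 1) - gammaln(
            np.asarray(n) - np.asarray(k) + 1
        )

    return _logc(k_, xs) + _logc(n_ - k_, q_ - xs) - _logc(n_, q_)


def _exact_pmf(table: ContingencyTable, x: int) -> Fraction:
    n_, k_, q_ = table.n, table.target_total, table.query_total
    return Fraction(math.comb(k_, x) * math.comb(n_ - k_, q_ - x), math.comb(n_, q_))


def fisher_pvalue(
    table: ContingencyTable, alternative: str = "greater", exact: bool = False
) -> float:
    """Exact Fisher p-value for a 2x2 table.

    ``greater`` is the hypergeometric upper tail P(X >= a); ``two_sided``
    sums the probabilities of all same-margin tables whose point probability
    is at most that of the observed one (minimum-likelihood convention).
    With ``exact`` the sum is accumulated in rational arithmetic; otherwise
    log-gamma terms are combined through a log-sum-exp.
    """
    if alternative not in {"greater", "two_sided"}:
        raise ValidationError(f"unknown alternative {alternative!r}")
    support = _hypergeom_support(table)
    if table.a not in support:
        raise DomainError("observed count outside the hypergeometric support")
    if exact:
        pmf = {x: _exact_pmf(table, x) for x in support}
        if alternative == "greater":
            total = sum(pmf[x] for x in support if x >= table.a)
        else:
            cutoff = pmf[table.a] * (1 + Fraction(TWO_SIDED_RTOL).limit_denominator(10**9))
            total = sum(p for p in pmf.values() if p <= cutoff)
        return float(min(total, Fraction(1)))
    xs = np.arange(support.start, support.stop)
    logp = _log_pmf(table, xs)
    if alternative == "greater":
        mask = xs >= table.a
    else:
        observed = logp[xs == table.a][0]
        mask = logp <= observed + math.log1p(TWO_SIDED_RTOL)
    return float(min(1.0, math.exp(logsumexp(logp[mask]))))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def run_enrichment(
    tmap: TargetMap,
    query: Iterable[str],
    universe: Iterable[str] | None = None,
    alternative: str = "greater",
    fdr_threshold: float = 0.2,
    exact: bool = False,
) -> list[EnrichmentResult]:
    """Test every miRNA in the map for over-representation of the query set.

    BH adjustment runs over all miRNAs tested; ``significant`` uses a strict
    ``fdr < fdr_threshold`` cut. Results come back sorted by raw p ascending,
    ties broken by miRNA id.
    """
    if not tmap.targets:
        raise DomainError("target map is empty")
    if not 0 < fdr_threshold <= 1:
        raise ValidationError(f"fdr_threshold must be in (0, 1], got {fdr_threshold}")
    uni = gene_universe(tmap, universe)
    query = frozenset(query)
    if not query & uni:
        raise DomainError("query does not intersect the gene universe")
    mirnas = sorted(tmap.targets)
    tables = [build_contingency(tmap.targets[m], query, uni) for m in mirnas]
    pvals = [fisher_pvalue(t, alternative=alternative, exact=exact) for t in tables]
    fdrs = bh_adjust(pvals)
    results = [
        EnrichmentResult(
            mirna=m,
            shared_genes=tuple(sorted(tmap.targets[m] & query)),
            p_value=p,
            fdr=float(q),
            significant=bool(q < fdr_threshold),
            table=t,
        )
        for m, t, p, q in zip(mirnas, tables, pvals, fdrs)
    ]
    results.sort(key=lambda r: (r.p_value, r.mirna))
    return results


def filter_significant(results, threshold: float):
    """Rows with ``fdr < threshold`` (strict), order preserved.

    Accepts either a sequence of objects exposing ``.fdr`` (e.g.
    :class:`EnrichmentResult`) or a pandas DataFrame with an ``fdr`` column.
    """
    if hasattr(results, "columns"):  # DataFrame-like
        return results[results["fdr"] < threshold]
    return [r for r in results if r.fdr < threshold]


def read_results(path: str | Path, fdr_threshold: float = 0.2) -> list[EnrichmentResult]:
    """Read an enrichment TSV (output dialect, or the fixture dialect without
    the ``significant`` column, in which case the flag is recomputed)."""
    from .target_map import canonicalize_mirna  # local import avoids a cycle

    path = Path(path)
    results: list[EnrichmentResult] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        fields = tuple(reader.fieldnames or ())
        if fields not in (RESULT_COLUMNS, RESULT_COLUMNS[:-1]):
            raise ValidationError(f"{path}: unexpected header {fields!r}")
        for row in reader:
            fdr = float(row["fdr"])
            significant = (
                row["significant"].strip().lower() == "true"
                if "significant" in row
                else fdr < fdr_threshold
            )
            results.append(
                EnrichmentResult(
                    mirna=canonicalize_mirna(row["mirna"]),
                    shared_genes=tuple(g for g in row["genes"].split(",") if g),
                    p_value=float(row["p_value"]),
                    fdr=fdr,
                    significant=significant,
                )
            )
    return results


def write_results(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    """Emit results in the enrichment TSV dialect plus a `significant` column."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(RESULT_COLUMNS)
        for r in results:
            writer.writerow(
                [
                    r.mirna,
                    r.k,
                    ",".join(r.shared_genes),
                    repr(r.p_value),
                    repr(r.fdr),
                    str(r.significant).lower(),
                ]
            )
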
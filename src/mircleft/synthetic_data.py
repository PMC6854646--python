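"""Synthetic miRNA-target databases with known null or planted enrichment.

Target sets are drawn without replacement from a finite gene universe. For
planted miRNAs the draw is a successive (Wallenius-style) weighted sample in
which query genes carry relative weight ``odds_ratio``; ``odds_ratio = 1``
recovers the exact hypergeometric null of the Fisher test, which makes the
generator usable for type-I-error calibration as well as power studies.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .enrichment import bh_adjust, build_contingency, fisher_pvalue
from .errors import ValidationError
from .target_map import Interaction

__all__ = [
    "SimConfig",
    "generate_target_sets",
    "generate_target_db",
    "estimate_type1_error",
    "estimate_power",
    "write_truth",
]


@dataclass(frozen=True)
class SimConfig:
    universe_size: int
    query_size: int
    n_mirnas: int
    target_size: int | tuple[int, int]
    planted: frozenset[int] = frozenset()
    odds_ratio: float = 1.0
    n_sources: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.universe_size < 1:
            raise ValidationError("universe_size must be >= 1")
        if not 0 < self.query_size <= self.universe_size:
            raise ValidationError("query_size must be in [1, universe_size]")
        if self.n_mirnas < 1:
            raise ValidationError("n_mirnas must be >= 1")
        lo, hi = self.target_size_range
        if lo < 1 or hi > self.universe_size:
            raise ValidationError(
                f"target sizes must lie in [1, {self.universe_size}], got ({lo}, {hi})"
            )
        if self.odds_ratio < 1:
            raise ValidationError("odds_ratio must be >= 1")
        if any(i < 0 or i >= self.n_mirnas for i in self.planted):
            raise ValidationError("planted indices must be valid miRNA indices")
        if self.n_sources < 1:
            raise ValidationError("n_sources must be >= 1")

    @property
    def target_size_range(self) -> tuple[int, int]:
        if isinstance(self.target_size, int):
            return self.target_size, self.target_size
        lo, hi = self.target_size
        return int(lo), int(hi)

    @property
    def universe(self) -> list[str]:
        width = len(str(self.universe_size - 1))
        return [f"g{i:0{width}d}" for i in range(self.universe_size)]

    @property
    def query_genes(self) -> list[str]:
        return self.universe[: self.query_size]

    @property
    def mirna_ids(self) -> list[str]:
        width = len(str(self.n_mirnas - 1))
        return [f"syn-miR-{i:0{width}d}" for i in range(self.n_mirnas)]


def _replicate_rng(config: SimConfig, replicate: int) -> np.random.Generator:
    """Independent stream per (root seed, replicate index)."""
    return np.random.default_rng(np.random.SeedSequence([config.seed, replicate]))


def _weighted_sample_indices(
    rng: np.random.Generator, n_universe: int, n_query: int, size: int, rho: float
) -> np.ndarray:
    """Successive weighted sampling without replacement via the exponential race.

    Items with weight w get an Exp(w) arrival time; the ``size`` earliest
    arrivals are exactly a sequential weighted sample, and with rho = 1 this
    is a uniform draw (hypergeometric overlap with the query block).
    """
    weights = np.ones(n_universe)
    weights[:n_query] = rho
    keys = rng.standard_exponential(n_universe) / weights
    return np.argpartition(keys, size - 1)[:size]


def generate_target_sets(
    config: SimConfig, rng: np.random.Generator | None = None
) -> dict[str, frozenset[str]]:
    """Per-miRNA target sets drawn under the configured null/planted scheme."""
    if rng is None:
        rng = _replicate_rng(config, 0)
    lo, hi = config.target_size_range
    genes = np.array(config.universe)
    targets: dict[str, frozenset[str]] = {}
    for idx, mirna in enumerate(config.mirna_ids):
        size = int(rng.integers(lo, hi + 1)) if lo != hi else lo
        rho = config.odds_ratio if idx in config.planted else 1.0
        chosen = _weighted_sample_indices(
            rng, config.universe_size, config.query_size, size, rho
        )
        targets[mirna] = frozenset(genes[chosen])
    return targets


def generate_target_db(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[Interaction], dict[str, tuple[bool, float]]]:
    """Interactions in the TSV dialect plus per-miRNA ground-truth labels.

    Each (mirna, gene) pair is attributed to one synthetic source label so
    the output exercises the multi-resource merge path. Deterministic for a
    given config (the seed lives in the config).
    """
    if rng is None:
        rng = _replicate_rng(config, 0)
    targets = generate_target_sets(config, rng)
    interactions: list[Interaction] = []
    for mirna in config.mirna_ids:
        for gene in sorted(targets[mirna]):
            source = f"sim{int(rng.integers(config.n_sources))}"
            interactions.append(Interaction(mirna=mirna, gene=gene, source=source))
    truth = {
        mirna: (idx in config.planted, config.odds_ratio if idx in config.planted else 1.0)
        for idx, mirna in enumerate(config.mirna_ids)
    }
    return interactions, truth


def _replicate_pvalues(
    config: SimConfig,
    replicate: int,
    alternative: str = "greater",
    subset: set[str] | None = None,
) -> dict[str, float]:
    """Raw per-miRNA p-values for one simulated replicate.

    ``subset`` restricts which miRNAs are tested (the generation stream is
    identical either way, so pairing across calls is preserved).
    """
    rng = _replicate_rng(config, replicate)
    targets = generate_target_sets(config, rng)
    universe = frozenset(config.universe)
    query = frozenset(config.query_genes)
    return {
        mirna: fisher_pvalue(
            build_contingency(target, query, universe), alternative=alternative
        )
        for mirna, target in targets.items()
        if subset is None or mirna in subset
    }


def estimate_type1_error(
    config: SimConfig, alpha: float, reps: int
) -> tuple[float, float]:
    """Empirical rejection rate (p <= alpha) across null databases, with
    its binomial standard error. Requires ``odds_ratio == 1``."""
    if config.odds_ratio != 1:
        raise ValidationError("type-I calibration requires odds_ratio == 1")
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    rejections = 0
    total = 0
    for rep in range(reps):
        for p in _replicate_pvalues(config, rep).values():
            rejections += p <= alpha
            total += 1
    rate = rejections / total
    se = float(np.sqrt(rate * (1 - rate) / total))
    return rate, se


def estimate_power(
    config: SimConfig, alpha: float, reps: int, adjust: bool = False
) -> tuple[float, float]:
    """Empirical detection rate for planted miRNAs across replicates.

    With ``adjust`` a planted miRNA counts as detected only when it survives
    BH across all miRNAs of its replicate at level ``alpha``; otherwise the
    raw p <= alpha rule is used.
    """
    if not config.planted:
        raise ValidationError("power estimation requires a nonempty planted set")
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    planted_ids = {config.mirna_ids[i] for i in config.planted}
    detections = 0
    total = 0
    for rep in range(reps):
        pvals = _replicate_pvalues(config, rep, subset=None if adjust else planted_ids)
        if adjust:
            mirnas = list(pvals)
            fdrs = dict(zip(mirnas, bh_adjust([pvals[m] for m in mirnas])))
            for mirna in planted_ids:
                detections += fdrs[mirna] < alpha
                total += 1
        else:
            for mirna in planted_ids:
                detections += pvals[mirna] <= alpha
                total += 1
    rate = detections / total
    se = float(np.sqrt(rate * (1 - rate) / total))
    return rate, se


def write_truth(truth: dict[str, tuple[bool, float]], path: str | Path) -> None:
    """Ground-truth sidecar TSV: ``mirna  planted  odds_ratio``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["mirna", "planted", "odds_ratio"])
        for mirna, (planted, rho) in sorted(truth.items()):
            writer.writerow([mirna, str(planted).lower(), repr(rho)])
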
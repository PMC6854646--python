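# mircleft

Curation bookkeeping for a mouse cleft-lip (CL) gene catalog, per-miRNA
over-representation analysis (exact Fisher tests with Benjamini–Hochberg FDR),
gene-coverage ranking, and a synthetic interaction-database generator for
calibration and power studies — all runnable offline from packaged fixtures.

## What's inside

| module | purpose |
| --- | --- |
| `mircleft.catalog` | mutant-record parsing, alias-resolved gene union, class contributions, Venn arithmetic, PRISMA screening ledger, Cohen's kappa |
| `mircleft.target_map` | miRNA–target interaction TSVs, identifier canonicalization, multi-resource merge with provenance, gene universe |
| `mircleft.enrichment` | 2×2 contingency construction, exact Fisher p-values (log-gamma or rational arithmetic), BH step-up adjustment, significance filter |
| `mircleft.coverage` | per-gene coverage counts across significant miRNAs, conservation audit |
| `mircleft.synthetic_data` | null / planted-enrichment interaction databases (Wallenius-style weighted sampling), type-I-error and power estimation |
| `mircleft.cli` | `mircleft` command-line tool (`catalog`, `venn`, `kappa`, `enrich`, `coverage`, `simulate`, `run-all`) |
| `mircleft.fixtures` | loaders for the packaged catalog / enrichment / coverage tables under `mircleft/data/` |

## CLI examples

```sh
# catalog summary (55 genes: 39 single + 4 spontaneous + 12 compound)
mircleft catalog

# two-set Venn partition by inclusion-exclusion
mircleft venn --n-a 25 --n-b 41 --n-union 55

# simulate a planted database, run enrichment, rank coverage
mircleft simulate --n-universe 200 --n-query 30 --n-mirnas 50 \
    --target-size 15 --planted 0 --odds-ratio 20 --seed 7 --out sim.tsv
mircleft enrich --interactions sim.tsv --query sim.query.txt --out enrichment.tsv
mircleft coverage --results enrichment.tsv --min-coverage 2 --out coverage.tsv

# full pipeline bundle (enrichment.tsv, coverage.tsv, summary.json)
mircleft run-all --interactions sim.tsv --out bundle/
```

`run-all` also accepts a YAML config (`--config run.yaml`) whose keys mirror
the flags; explicit flags override the file.

## Notes on statistical conventions

- The enrichment test defaults to the one-sided "greater" hypergeometric tail
  (standard for over-representation); the two-sided minimum-likelihood
  convention is available via `alternative="two_sided"`.
- BH adjustment always runs over every miRNA tested in a run; significance is
  a strict `fdr < threshold` cut (default 0.2).
- The synthetic generator's `odds_ratio = 1` case is exactly the
  hypergeometric null of the Fisher test, so empirical type-I error can be
  checked against enumeration.
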
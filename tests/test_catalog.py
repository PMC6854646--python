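import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mircleft.catalog import (
    MutantRecord,
    ScreeningLedger,
    ScreeningRecord,
    Stage,
    TableKind,
    build_gene_union,
    class_contribution,
    cohen_kappa,
    filter_by_cleft_type,
    load_mutant_records,
    prisma_flow,
    screener_agreement_table,
    venn_from_counts,
)
from mircleft.errors import (
    AliasConflictError,
    DomainError,
    ParseError,
    ValidationError,
)

HEADER = "record_id\ttable_kind\tgene_symbols\taliases\tcleft_type\tpenetrance_note\tpmids\tnote\n"


def rec(record_id, kind, symbols, cleft="CLP", aliases=None, note=""):
    return MutantRecord(
        record_id=record_id,
        table_kind=TableKind(kind),
        gene_symbols=tuple(symbols),
        aliases=aliases or {},
        cleft_type=cleft,
        note=note,
    )


class TestLoadMutantRecords:
    def test_single_fixture_has_39_records(self, single_records):
        assert len(single_records) == 39

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text(HEADER)
        assert load_mutant_records(path, TableKind.single) == []

    def test_aka_annotation_parsed(self, spontaneous_records):
        wnt9b = [r for r in spontaneous_records if "Wnt9b" in r.gene_symbols]
        assert len(wnt9b) == 1
        assert wnt9b[0].aliases == {"Wnt9b": ("Clf1",)}

    def test_malformed_row_names_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(HEADER + "r1\tsingle\tGeneA\t\tCLP\t\t\t\nonly-two\tfields\n")
        with pytest.raises(ParseError, match=r":3"):
            load_mutant_records(path, TableKind.single)

    def test_unknown_cleft_token_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(HEADER + "r1\tsingle\tGeneA\t\tCLX\t\t\t\n")
        with pytest.raises(ValidationError, match="CLX"):
            load_mutant_records(path, TableKind.single)

    def test_bad_header_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("a\tb\n1\t2\n")
        with pytest.raises(ParseError, match="header"):
            load_mutant_records(path, TableKind.single)

    def test_alias_column_dialect(self, tmp_path):
        path = tmp_path / "ok.tsv"
        path.write_text(HEADER + "r1\tsingle\tGeneA\tGeneA=AltX|AltY\tCLP\t\t\t\n")
        (record,) = load_mutant_records(path, TableKind.single)
        assert record.aliases == {"GeneA": ("AltX", "AltY")}


class TestMutantRecordInvariants:
    def test_compound_requires_two_symbols(self):
        with pytest.raises(ValidationError):
            rec("x", "compound", ["OnlyOne"])

    def test_geneless_requires_not_gene_marker(self):
        with pytest.raises(ValidationError):
            rec("x", "single", [])
        assert rec("x", "spontaneous", [], note="Not gene; strain A/J").is_gene_less

    def test_cleft_type_must_be_nonempty(self):
        with pytest.raises(ValidationError):
            rec("x", "single", ["GeneA"], cleft="")


class TestBuildGeneUnion:
    def test_curated_catalog_has_55_genes(self, all_records):
        assert len(build_gene_union(all_records)) == 55

    def test_order_invariance(self, all_records):
        reference = build_gene_union(all_records)
        shuffled = list(all_records)
        random.Random(17).shuffle(shuffled)
        other = build_gene_union(shuffled)
        assert other.symbols == reference.symbols
        assert other.provenance == reference.provenance
        assert other.alias_index == reference.alias_index

    def test_idempotence_under_duplication(self, all_records):
        assert build_gene_union(list(all_records) * 2).symbols == build_gene_union(
            all_records
        ).symbols

    def test_shared_symbol_provenance_has_both_kinds(self):
        catalog = build_gene_union(
            [rec("a", "single", ["Wnt9b"]), rec("b", "spontaneous", ["Wnt9b"])]
        )
        assert catalog.symbols == {"Wnt9b"}
        assert catalog.provenance["Wnt9b"] == {TableKind.single, TableKind.spontaneous}

    def test_disjoint_union(self):
        catalog = build_gene_union(
            [rec("a", "single", ["X"]), rec("b", "compound", ["Y", "Z"])]
        )
        assert catalog.symbols == {"X", "Y", "Z"}

    def test_alias_conflict_raises(self):
        with pytest.raises(AliasConflictError):
            build_gene_union(
                [
                    rec("a", "single", ["GeneA"], aliases={"GeneA": ("Alt",)}),
                    rec("b", "single", ["GeneB"], aliases={"GeneB": ("Alt",)}),
                ]
            )

    def test_alias_resolution(self, all_records):
        catalog = build_gene_union(all_records)
        assert catalog.resolve("Clf1") == "Wnt9b"
        assert catalog.resolve("Alk5") == "Tgfbr1"
        assert "Clf1" not in catalog.symbols


class TestClassContribution:
    def test_curated_decomposition(self, all_records):
        catalog = build_gene_union(all_records)
        contrib = class_contribution(all_records, catalog)
        assert (contrib.single_total, contrib.spontaneous_new, contrib.compound_new) == (
            39,
            4,
            12,
        )
        assert contrib.total == len(catalog)

    def test_empty(self):
        contrib = class_contribution([], build_gene_union([]))
        assert (contrib.single_total, contrib.spontaneous_new, contrib.compound_new) == (
            0,
            0,
            0,
        )

    def test_hand_enumerated_overlap(self):
        records = [
            rec("s", "single", ["A"]),
            rec("p", "spontaneous", ["A"]),
            rec("c", "compound", ["A", "B"]),
        ]
        contrib = class_contribution(records, build_gene_union(records))
        assert (contrib.single_total, contrib.spontaneous_new, contrib.compound_new) == (
            1,
            0,
            1,
        )


class TestVennFromCounts:
    @pytest.mark.parametrize(
        "n_a,n_b,n_union,expected",
        [
            ((25), 41, 55, (14, 11, 30)),
            (5, 5, 5, (0, 5, 0)),
            (3, 4, 7, (3, 0, 4)),
        ],
    )
    def test_examples(self, n_a, n_b, n_union, expected):
        v = venn_from_counts(n_a, n_b, n_union)
        assert (v.a_only, v.both, v.b_only) == expected
        assert v.union == n_union

    @pytest.mark.parametrize("n_a,n_b,n_union", [(5, 5, 11), (5, 5, 4), (0, 5, 6)])
    def test_inconsistent_counts_rejected(self, n_a, n_b, n_union):
        with pytest.raises(DomainError):
            venn_from_counts(n_a, n_b, n_union)

    def test_round_trip_against_explicit_sets(self):
        rng = random.Random(42)
        for _ in range(1000):
            universe = range(rng.randint(1, 60))
            set_a = {x for x in universe if rng.random() < 0.4}
            set_b = {x for x in universe if rng.random() < 0.4}
            union = set_a | set_b
            if not union:
                continue
            v = venn_from_counts(len(set_a), len(set_b), len(union))
            assert v.both == len(set_a & set_b)
            assert v.a_only == len(set_a - set_b)
            assert v.b_only == len(set_b - set_a)


class TestCohenKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa([[50, 0], [0, 50]]) == 1.0

    def test_derived_value(self):
        assert cohen_kappa([[20, 5], [10, 65]]) == pytest.approx(0.625)

    def test_chance_level(self):
        assert cohen_kappa([[25, 25], [25, 25]]) == pytest.approx(0.0)

    def test_degenerate_but_perfect(self):
        assert cohen_kappa([[7, 0], [0, 0]]) == 1.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            cohen_kappa([[0, 0], [0, 0]])

    @given(
        st.tuples(
            st.integers(0, 200), st.integers(0, 200), st.integers(0, 200), st.integers(0, 200)
        ).filter(lambda t: sum(t) > 0)
    )
    def test_transpose_symmetry(self, counts):
        a, b, c, d = counts
        assert cohen_kappa([[a, b], [c, d]]) == pytest.approx(
            cohen_kappa([[a, c], [b, d]])
        )


def make_ledger(n_included, n_full_text_only, n_screened_only, n_identified_only=0):
    rows = []
    plan = [
        (Stage.included, n_included),
        (Stage.full_text, n_full_text_only),
        (Stage.screened, n_screened_only),
        (Stage.identified, n_identified_only),
    ]
    i = 0
    for stage, count in plan:
        for _ in range(count):
            include = stage in (Stage.included, Stage.full_text)
            rows.append(ScreeningRecord(f"r{i}", include, include, stage))
            i += 1
    return ScreeningLedger(rows=tuple(rows))


class TestPrismaFlow:
    def test_emulated_study_counts(self):
        ledger = make_ledger(n_included=45, n_full_text_only=107, n_screened_only=181)
        counts = prisma_flow(ledger)
        assert counts[Stage.identified] == 333
        assert counts[Stage.screened] == 333
        assert counts[Stage.full_text] == 152
        assert counts[Stage.included] == 45

    def test_empty_ledger(self):
        counts = prisma_flow(ScreeningLedger(rows=()))
        assert all(v == 0 for v in counts.values())

    def test_all_included_saturates(self):
        counts = prisma_flow(make_ledger(3, 0, 0))
        assert list(counts.values()) == [3, 3, 3, 3]

    @given(st.lists(st.sampled_from(list(Stage)), max_size=50))
    def test_counts_non_increasing(self, stages):
        ledger = ScreeningLedger(
            rows=tuple(
                ScreeningRecord(f"r{i}", True, True, s) for i, s in enumerate(stages)
            )
        )
        values = list(prisma_flow(ledger).values())
        assert all(x >= y for x, y in zip(values, values[1:]))

    def test_agreement_table_feeds_kappa(self):
        ledger = ScreeningLedger(
            rows=(
                ScreeningRecord("a", True, True, Stage.included),
                ScreeningRecord("b", True, False, Stage.screened),
                ScreeningRecord("c", False, False, Stage.identified),
            )
        )
        assert screener_agreement_table(ledger) == [[1, 1], [0, 1]]


class TestFilterByCleftType:
    def test_exact_clo_rows_of_single_table(self, single_records):
        matched = filter_by_cleft_type(single_records, "CLO", mode="exact")
        assert [r.gene_symbols[0] for r in matched] == [
            "Bmp4",
            "Cplane2",
            "Myh10",
            "Rpgrip1l",
            "Sp8",
        ]

    def test_absent_label_gives_empty(self, single_records):
        assert filter_by_cleft_type(single_records, "CPO", mode="exact") == []

    def test_contains_matches_substring_oracle(self, single_records):
        matched = filter_by_cleft_type(single_records, "CPO", mode="contains")
        oracle = [r for r in single_records if "CPO" in r.cleft_type]
        assert matched == oracle
        assert all("CPO" in r.cleft_type for r in matched)

    def test_unknown_label_rejected(self, single_records):
        with pytest.raises(ValidationError):
            filter_by_cleft_type(single_records, "CLX", mode="contains")
        with pytest.raises(ValidationError):
            filter_by_cleft_type(single_records, "CLO", mode="fuzzy")
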
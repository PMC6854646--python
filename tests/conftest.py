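import pytest

from mircleft import fixtures


@pytest.fixture(scope="session")
def single_records():
    return fixtures.load_single_gene_records()


@pytest.fixture(scope="session")
def spontaneous_records():
    return fixtures.load_spontaneous_records()


@pytest.fixture(scope="session")
def compound_records():
    return fixtures.load_compound_records()


@pytest.fixture(scope="session")
def all_records(single_records, spontaneous_records, compound_records):
    return single_records + spontaneous_records + compound_records


@pytest.fixture(scope="session")
def enrichment_df():
    return fixtures.load_enrichment_table()


@pytest.fixture(scope="session")
def enrichment_rows(enrichment_df):
    return fixtures.enrichment_results(enrichment_df)


@pytest.fixture(scope="session")
def coverage_df():
    return fixtures.load_coverage_table()
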
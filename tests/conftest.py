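import pytest

from enzyminer.corpus import FixtureEUtilsClient, PaperRecord
from enzyminer.gateway import MockBackend
from enzyminer.synth import CorpusSpec, make_corpus


@pytest.fixture
def backend():
    return MockBackend()


@pytest.fixture(scope="session")
def small_bundle():
    """A compact end-to-end corpus with every planted error mode."""
    spec = CorpusSpec(
        n_positive=12,
        n_negative=12,
        decoy_rate=0.2,
        hallucination_rate=0.1,
        heterologous_rate=0.1,
        seed=5,
    )
    return make_corpus(spec)


def make_year_records(per_year: dict[int, int], journal: str = "Phytochemistry"):
    """Flat records spread over years, all matching a 'testase' family term."""
    records = []
    i = 0
    for year, n in sorted(per_year.items()):
        for _ in range(n):
            records.append(
                PaperRecord(
                    pmid=f"{year}{i:05d}",
                    title=f"A study of testase enzyme {i}",
                    abstract="Characterization of a testase activity.",
                    journal=journal,
                    year=year,
                    article_types=["Journal Article"],
                )
            )
            i += 1
    return records


@pytest.fixture
def year_client():
    per_year = {2000: 3, 2001: 5, 2002: 2, 2003: 7, 2004: 1}
    records = make_year_records(per_year)
    return FixtureEUtilsClient(records), records, per_year
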
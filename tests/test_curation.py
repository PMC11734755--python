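"""Curation: taxonomy lookup, nontarget flagging, accession harvesting,
UniProt mapping, hallucination flags, prioritization."""

import random
import re
import string

import pandas as pd
import pytest

from enzyminer.curate import (
    CuratedEntry,
    LineageTable,
    attach_taxonomy,
    classify_accession,
    flag_hallucination,
    flag_nontarget,
    harvest_ids,
    load_lexicon,
    map_uniprot,
    minimally_curated,
    normalize_species,
    prioritize,
)
from enzyminer.extract import ActivityEntry
from enzyminer.synth import CorpusSpec, make_corpus


def make_entry(**kwargs):
    defaults = dict(
        source_id="p1",
        enzyme_name="hydroxycinnamoyl-CoA transferase",
        species_name="Arabidopsis thaliana",
        acceptor_substrates=["quinic acid"],
        donor_substrates=["caffeoyl-CoA"],
        products=["chlorogenic acid"],
    )
    defaults.update(kwargs)
    return CuratedEntry.from_entry(ActivityEntry(**defaults))


@pytest.fixture
def lineage():
    return LineageTable(
        {
            "Arabidopsis thaliana": ("Brassicaceae", "Viridiplantae"),
            "Escherichia coli": ("Enterobacteriaceae", "Bacteria"),
            "Homo sapiens": ("Hominidae", "Metazoa"),
        }
    )


class TestTaxonomy:
    def test_exact_lookup(self, lineage):
        [ce] = attach_taxonomy([make_entry()], lineage)
        assert (ce.tax_family, ce.tax_kingdom) == ("Brassicaceae", "Viridiplantae")
        assert "nonplant" not in ce.flags

    def test_normalization_variants_resolve(self, lineage):
        [ce] = attach_taxonomy(
            [make_entry(species_name="  ARABIDOPSIS   Thaliana (Col-0) ")], lineage
        )
        assert ce.tax_kingdom == "Viridiplantae"

    def test_abbreviated_genus_resolves_when_unique(self, lineage):
        [ce] = attach_taxonomy([make_entry(species_name="E. coli")], lineage)
        assert ce.tax_family == "Enterobacteriaceae"
        assert "nonplant" in ce.flags

    def test_abbreviated_genus_ambiguous_initial_unresolved(self):
        table = LineageTable(
            {
                "Escherichia coli": ("Enterobacteriaceae", "Bacteria"),
                "Erwinia amylovora": ("Erwiniaceae", "Bacteria"),
            }
        )
        [ce] = attach_taxonomy([make_entry(species_name="E. coli")], table)
        assert ce.tax_family == "" and ce.tax_kingdom == ""

    def test_miss_leaves_fields_empty(self, lineage):
        [ce] = attach_taxonomy([make_entry(species_name="Planthus obscurus")], lineage)
        assert ce.tax_family == "" and ce.tax_kingdom == ""

    def test_duplicate_keys_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            LineageTable(
                {
                    "Arabidopsis thaliana": ("Brassicaceae", "Viridiplantae"),
                    "ARABIDOPSIS THALIANA": ("Brassicaceae", "Viridiplantae"),
                }
            )

    def test_planted_unknown_fraction_exact(self):
        """Entries generated with 10% unknown species: exactly those miss."""
        bundle = make_corpus(
            CorpusSpec(n_positive=40, n_negative=0, unknown_species_rate=0.1, seed=9)
        )
        lineage = LineageTable.from_frame(bundle.lineage)
        entries = [
            make_entry(species_name=t.activity.species) for t in bundle.truth
        ]
        tagged = attach_taxonomy(entries, lineage)
        missing = sum(1 for ce in tagged if not ce.tax_kingdom)
        planted_unknown = sum(1 for t in bundle.truth if not t.species_known)
        assert missing == planted_unknown > 0

    def test_normalize_species(self):
        assert normalize_species(" solanum  Lycopersicum (cv. M82)") == (
            "Solanum lycopersicum"
        )
        assert normalize_species("") == ""


class TestNontargetFlagging:
    def test_decoy_family_flagged(self):
        lexicon = load_lexicon("bahd_acyltransferase")
        [ce] = flag_nontarget(
            [make_entry(enzyme_name="UDP-glycosyltransferase 71C1")], lexicon
        )
        assert "nontarget_family" in ce.flags

    def test_target_name_not_flagged(self):
        lexicon = load_lexicon("bahd_acyltransferase")
        [ce] = flag_nontarget(
            [make_entry(enzyme_name="hydroxycinnamoyl-CoA transferase")], lexicon
        )
        assert "nontarget_family" not in ce.flags

    def test_planted_decoys_all_flagged(self):
        """30% planted decoys: flag recall is 1.0 against generator truth,
        with zero false flags on target-family names."""
        bundle = make_corpus(
            CorpusSpec(n_positive=30, n_negative=0, decoy_rate=0.3, seed=21)
        )
        lexicon = load_lexicon("bahd_acyltransferase")
        entries = [
            make_entry(enzyme_name=t.activity.enzyme_name) for t in bundle.truth
        ]
        flagged = flag_nontarget(entries, lexicon)
        for ce, truth in zip(flagged, bundle.truth):
            assert ("nontarget_family" in ce.flags) == (truth.category == "decoy")


UNIPROT_ORACLE = re.compile(
    r"^([OPQ][0-9][A-Z0-9][A-Z0-9][A-Z0-9][0-9]"
    r"|[A-NR-Z][0-9][A-Z][A-Z0-9][A-Z0-9][0-9]"
    r"|[A-NR-Z][0-9][A-Z][A-Z0-9][A-Z0-9][0-9][A-Z][A-Z0-9][A-Z0-9][0-9])$"
)
GENBANK_ORACLE = re.compile(
    r"^([A-Z][0-9]{5}|[A-Z]{2}[0-9]{5,8}|[A-Z]{3}[0-9]{5,7})(\.[0-9]+)?$"
)


class TestHarvestIds:
    def test_uniprot_accession(self):
        [(acc, scheme)] = harvest_ids(make_entry(sequence_ids=["Q9FI78"]).entry)
        assert (acc, scheme) == ("Q9FI78", "uniprot")

    def test_genbank_accession(self):
        [(acc, scheme)] = harvest_ids(make_entry(sequence_ids=["AB123456"]).entry)
        assert (acc, scheme) == ("AB123456", "genbank")

    def test_mixed_field_tokenized(self):
        ids = harvest_ids(
            make_entry(sequence_ids=["Q9FI78, AB123456; not-an-id"]).entry
        )
        assert ids == [("Q9FI78", "uniprot"), ("AB123456", "genbank")]

    def test_fuzzed_strings_agree_with_independent_oracle(self):
        """10^4 random tokens: classification agrees with a second,
        independently written pattern pair; no token gets both schemes."""
        rng = random.Random(99)
        alphabet = string.ascii_uppercase + string.digits
        for _ in range(10_000):
            token = "".join(
                rng.choices(alphabet, k=rng.randint(1, 12))
            )
            scheme = classify_accession(token)
            is_uni = bool(UNIPROT_ORACLE.match(token))
            is_gb = bool(GENBANK_ORACLE.match(token))
            if is_uni:
                assert scheme == "uniprot"
            elif is_gb:
                assert scheme == "genbank"
            else:
                assert scheme is None


@pytest.fixture
def idmap():
    return pd.DataFrame(
        [
            {"foreign_id": "AB123456", "scheme": "genbank",
             "uniprot_accession": "Q9FI78", "species": "Arabidopsis thaliana"},
            {"foreign_id": "hydroxycinnamoyl-coa transferase", "scheme": "name",
             "uniprot_accession": "P12345", "species": "Arabidopsis thaliana"},
            {"foreign_id": "AB123456", "scheme": "genbank",
             "uniprot_accession": "Q8H8H8", "species": "Arabidopsis thaliana"},
        ],
        columns=["foreign_id", "scheme", "uniprot_accession", "species"],
    )


class TestMapUniprot:
    def test_id_match_returns_all_hits(self, idmap):
        [ce] = map_uniprot([make_entry(sequence_ids=["AB123456"])], idmap)
        assert ce.uniprot_accessions == ["Q8H8H8", "Q9FI78"]

    def test_id_match_takes_precedence_over_name(self, idmap):
        [ce] = map_uniprot([make_entry(sequence_ids=["AB123456"])], idmap)
        assert "P12345" not in ce.uniprot_accessions

    def test_name_match_requires_species_agreement(self, idmap):
        [hit] = map_uniprot([make_entry(sequence_ids=[])], idmap)
        assert hit.uniprot_accessions == ["P12345"]
        [miss] = map_uniprot(
            [make_entry(sequence_ids=[], species_name="Zea mays")], idmap
        )
        assert miss.uniprot_accessions == []

    def test_order_independent(self, idmap):
        entries = [
            make_entry(sequence_ids=["AB123456"]),
            make_entry(sequence_ids=[], species_name="Zea mays"),
            make_entry(sequence_ids=[]),
        ]
        forward = map_uniprot(entries, idmap)
        backward = list(reversed(map_uniprot(list(reversed(entries)), idmap)))
        assert [ce.uniprot_accessions for ce in forward] == [
            ce.uniprot_accessions for ce in backward
        ]

    def test_planted_mapping_fraction_recovered_exactly(self):
        """1000 entries with a 58% planted mappable fraction map exactly."""
        bundle = make_corpus(
            CorpusSpec(n_positive=334, n_negative=0, mappable_fraction=0.58, seed=31)
        )
        entries = [
            CuratedEntry.from_entry(
                ActivityEntry(
                    source_id=t.pmid,
                    enzyme_name=t.activity.enzyme_name,
                    species_name=t.activity.species,
                    sequence_ids=list(t.activity.sequence_ids),
                    acceptor_substrates=list(t.activity.acceptors),
                    donor_substrates=list(t.activity.donors),
                    products=list(t.activity.products),
                )
            )
            for t in bundle.truth
        ]
        mapped = map_uniprot(entries, bundle.idmap)
        n = len(bundle.truth)
        assert n >= 500
        n_mapped = sum(1 for ce in mapped if ce.uniprot_accessions)
        assert n_mapped == round(0.58 * n)
        for ce, truth in zip(mapped, bundle.truth):
            assert bool(ce.uniprot_accessions) == truth.mappable


class TestHallucinationFlags:
    TITLE = "Characterization of a BAHD acyltransferase from Vitis vinifera"

    def test_biomedical_species_without_mention_flagged(self):
        [ce] = flag_hallucination(
            [make_entry(species_name="Homo sapiens")], self.TITLE
        )
        assert "hallucination_suspect" in ce.flags

    def test_host_species_flagged_as_heterologous_only(self):
        [ce] = flag_hallucination(
            [make_entry(species_name="Escherichia coli")], self.TITLE
        )
        assert ce.flags == {"heterologous_host"}

    def test_plant_species_unflagged(self):
        [ce] = flag_hallucination(
            [make_entry(species_name="Arabidopsis thaliana")], self.TITLE
        )
        assert ce.flags == frozenset()

    def test_mentioned_biomedical_species_not_flagged(self):
        [ce] = flag_hallucination(
            [make_entry(species_name="Homo sapiens")],
            "Comparative study of human and plant acyltransferases",
        )
        assert "hallucination_suspect" not in ce.flags

    def test_empty_species_never_flagged(self):
        [ce] = flag_hallucination([make_entry(species_name="")], self.TITLE)
        assert ce.flags == frozenset()


class TestPrioritize:
    def test_tiers(self, idmap):
        mapped = map_uniprot([make_entry(sequence_ids=["AB123456"])], idmap)
        raw_id = [make_entry(sequence_ids=["ZZ999999"], species_name="Zea mays")]
        name_only = [make_entry(sequence_ids=[], species_name="Zea mays")]
        tiers = [
            ce.priority_tier
            for ce in prioritize(mapped + raw_id + name_only)
        ]
        assert tiers == [1, 2, 3]

    def test_tier1_iff_mapped(self, idmap):
        entries = prioritize(
            map_uniprot(
                [make_entry(sequence_ids=["AB123456"]), make_entry(sequence_ids=[])],
                idmap,
            )
        )
        for ce in entries:
            assert (ce.priority_tier == 1) == bool(ce.uniprot_accessions)

    def test_minimally_curated_excludes_flagged(self):
        lexicon = load_lexicon("bahd_acyltransferase")
        entries = flag_nontarget(
            [
                make_entry(enzyme_name="UDP-glycosyltransferase 71C1"),
                make_entry(enzyme_name="anthocyanin acyltransferase"),
            ],
            lexicon,
        )
        minimal = minimally_curated(prioritize(entries))
        assert len(minimal) == 1
        assert minimal[0].entry.enzyme_name == "anthocyanin acyltransferase"


def test_curation_never_mutates_extraction_fields(lineage, idmap):
    ce = make_entry(sequence_ids=["AB123456"])
    original = ce.entry
    before = (
        original.enzyme_name,
        list(original.acceptor_substrates),
        list(original.sequence_ids),
    )
    out = prioritize(
        flag_hallucination(
            map_uniprot(
                flag_nontarget(
                    attach_taxonomy([ce], lineage),
                    load_lexicon("bahd_acyltransferase"),
                ),
                idmap,
            ),
            "some title",
        )
    )
    assert out[0].entry is original
    assert (
        original.enzyme_name,
        original.acceptor_substrates,
        original.sequence_ids,
    ) == before
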
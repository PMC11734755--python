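"""Semi-automatic curation (Step 5): taxonomy attachment, nontarget-family
flagging, sequence-ID harvesting, UniProt mapping, hallucination flagging
and prioritization into a Minimally Curated Set.

Curation is strictly append-only: extraction fields are never rewritten,
every step returns new :class:`CuratedEntry` objects with extra columns or
flags, so each decision stays auditable back to the raw extraction.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .extract import ActivityEntry, LIST_SEP

__all__ = [
    "CuratedEntry",
    "LineageTable",
    "Lexicon",
    "normalize_species",
    "attach_taxonomy",
    "flag_nontarget",
    "harvest_ids",
    "map_uniprot",
    "flag_hallucination",
    "prioritize",
    "minimally_curated",
    "load_lexicon",
    "curated_to_frame",
    "UNIPROT_ACCESSION_RE",
    "GENBANK_ACCESSION_RE",
    "DEFAULT_BIOMEDICAL_SPECIES",
    "DEFAULT_HETEROLOGOUS_HOSTS",
]

PLANT_KINGDOM = "Viridiplantae"

# species whose appearance in plant-enzyme extractions usually signals a
# model hallucination from its training data rather than paper content
DEFAULT_BIOMEDICAL_SPECIES: dict[str, tuple[str, ...]] = {
    "Homo sapiens": ("human",),
    "Mus musculus": ("mouse", "mice", "murine"),
    "Rattus norvegicus": ("rat",),
}

# common heterologous expression hosts: their mention is expected, not
# hallucinated, but the activity belongs to the donor-organism enzyme
DEFAULT_HETEROLOGOUS_HOSTS: dict[str, tuple[str, ...]] = {
    "Escherichia coli": ("e. coli", "e.coli"),
    "Saccharomyces cerevisiae": ("s. cerevisiae", "s.cerevisiae", "yeast"),
    "Nicotiana benthamiana": ("n. benthamiana",),
}


@dataclass
class CuratedEntry:
    """An extraction entry plus appended curation columns.

    ``priority_tier``: 1 = mapped UniProt accession, 2 = raw sequence ID
    present but unmapped, 3 = name only.
    """

    entry: ActivityEntry
    tax_family: str = ""
    tax_kingdom: str = ""
    harvested_ids: list[tuple[str, str]] = field(default_factory=list)
    uniprot_accessions: list[str] = field(default_factory=list)
    flags: frozenset[str] = frozenset()
    priority_tier: int | None = None

    @classmethod
    def from_entry(cls, entry: ActivityEntry) -> "CuratedEntry":
        return cls(entry=entry)

    def with_flag(self, flag: str) -> "CuratedEntry":
        return replace(self, flags=self.flags | {flag})


# ---------------------------------------------------------------------------
# species normalization and lineage lookup

_PAREN_RE = re.compile(r"\([^)]*\)")
_ABBREV_RE = re.compile(r"^([A-Za-z])\.\s*(\S+)(.*)$")


def normalize_species(name: str) -> str:
    """Canonical binomial form: cultivar/strain parentheticals stripped,
    whitespace collapsed, genus capitalized, epithet lower-cased."""
    name = _PAREN_RE.sub(" ", name)
    tokens = name.replace("\t", " ").split()
    if not tokens:
        return ""
    genus = tokens[0].capitalize()
    rest = [t.lower() for t in tokens[1:]]
    return " ".join([genus] + rest)


class LineageTable:
    """Species (normalized binomial) -> (family, kingdom) lookup.

    Abbreviated genus names ("A. thaliana") resolve only when exactly one
    genus in the table starts with that initial; otherwise the lookup
    fails rather than guess.
    """

    COLUMNS = ["species", "family", "kingdom"]

    def __init__(self, mapping: dict[str, tuple[str, str]]) -> None:
        normalized: dict[str, tuple[str, str]] = {}
        for species, lineage in mapping.items():
            key = normalize_species(species)
            if key in normalized:
                raise ValueError(f"duplicate species key after normalization: {key}")
            normalized[key] = lineage
        self.mapping = normalized
        self._genus_by_initial: dict[str, set[str]] = {}
        for key in normalized:
            genus = key.split()[0]
            self._genus_by_initial.setdefault(genus[0].upper(), set()).add(genus)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "LineageTable":
        return cls(
            {
                str(r["species"]): (str(r["family"]), str(r["kingdom"]))
                for _, r in frame.iterrows()
            }
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LineageTable":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype=str).fillna(""))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"species": s, "family": f, "kingdom": k}
                for s, (f, k) in sorted(self.mapping.items())
            ],
            columns=self.COLUMNS,
        )

    def lookup(self, species: str) -> tuple[str, str] | None:
        if not species.strip():
            return None
        m = _ABBREV_RE.match(species.strip())
        if m:
            initial, epithet = m.group(1).upper(), m.group(2).lower().rstrip(".")
            genera = self._genus_by_initial.get(initial, set())
            if len(genera) != 1:
                return None
            genus = next(iter(genera))
            return self.mapping.get(f"{genus} {epithet}")
        return self.mapping.get(normalize_species(species))


def attach_taxonomy(
    entries: list[CuratedEntry],
    lineage: LineageTable,
    target_kingdom: str = PLANT_KINGDOM,
) -> list[CuratedEntry]:
    """Fill family/kingdom from the lineage table; misses stay empty.

    Entries resolving to a kingdom other than ``target_kingdom`` get the
    ``nonplant`` flag (the downstream Minimally Curated Set excludes them).
    """
    out = []
    for ce in entries:
        hit = lineage.lookup(ce.entry.species_name)
        if hit is None:
            out.append(ce)
            continue
        fam, kingdom = hit
        updated = replace(ce, tax_family=fam, tax_kingdom=kingdom)
        if kingdom and kingdom != target_kingdom:
            updated = updated.with_flag("nonplant")
        out.append(updated)
    return out


# ---------------------------------------------------------------------------
# nontarget-family flagging


@dataclass(frozen=True)
class Lexicon:
    """Per-family name patterns: target matches and known other-family
    contaminants.  Case-insensitive substring semantics."""

    family: str
    target_patterns: tuple[str, ...]
    nontarget_patterns: tuple[str, ...]


def load_lexicon(family_slug: str) -> Lexicon:
    """Load a shipped lexicon file (e.g. ``bahd_acyltransferase``)."""
    ref = importlib.resources.files("enzyminer").joinpath(
        "lexicons", f"{family_slug}.txt"
    )
    target: list[str] = []
    nontarget: list[str] = []
    bucket: list[str] | None = None
    for line in ref.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line == "[target]":
            bucket = target
        elif line == "[nontarget]":
            bucket = nontarget
        elif bucket is not None:
            bucket.append(line.lower())
    return Lexicon(family_slug, tuple(target), tuple(nontarget))


def flag_nontarget(
    entries: list[CuratedEntry], lexicon: Lexicon
) -> list[CuratedEntry]:
    """Flag entries whose enzyme name matches a known other-family pattern
    and no target pattern; ambiguous names are left for manual review."""
    if not (lexicon.target_patterns or lexicon.nontarget_patterns):
        raise ValueError("lexicon has no patterns")
    out = []
    for ce in entries:
        name = f"{ce.entry.enzyme_name} {ce.entry.enzyme_abbrev}".lower()
        is_target = any(p in name for p in lexicon.target_patterns)
        is_nontarget = any(p in name for p in lexicon.nontarget_patterns)
        if is_nontarget and not is_target:
            out.append(ce.with_flag("nontarget_family"))
        else:
            out.append(ce)
    return out


# ---------------------------------------------------------------------------
# sequence-ID harvesting and UniProt mapping

UNIPROT_ACCESSION_RE = re.compile(
    r"(?:[OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9](?:[A-Z][A-Z0-9]{2}[0-9]){1,2})"
)
GENBANK_ACCESSION_RE = re.compile(
    r"(?:[A-Z]{3}\d{5,7}|[A-Z]{2}\d{5,8}|[A-Z]\d{5})(?:\.\d+)?"
)

_TOKEN_SPLIT_RE = re.compile(r"[,;\s/]+")


def classify_accession(token: str) -> str | None:
    """Scheme of one candidate token; UniProt takes precedence so no token
    is ever reported under both schemes."""
    token = token.strip()
    if not token:
        return None
    if UNIPROT_ACCESSION_RE.fullmatch(token):
        return "uniprot"
    if GENBANK_ACCESSION_RE.fullmatch(token.upper()):
        return "genbank"
    return None


def harvest_ids(entry: ActivityEntry) -> list[tuple[str, str]]:
    """Extract (accession, scheme) pairs from the entry's sequence-ID field."""
    found: list[tuple[str, str]] = []
    seen: set[str] = set()
    for raw in entry.sequence_ids:
        for token in _TOKEN_SPLIT_RE.split(raw):
            scheme = classify_accession(token)
            if scheme and token not in seen:
                seen.add(token)
                found.append((token.strip(), scheme))
    return found


IDMAP_COLUMNS = ["foreign_id", "scheme", "uniprot_accession", "species"]


def map_uniprot(
    entries: list[CuratedEntry], idmap: pd.DataFrame
) -> list[CuratedEntry]:
    """Attach UniProt accessions from an ID-mapping table.

    ID-based rows (scheme uniprot/genbank) match harvested accessions and
    take precedence; name-based rows (scheme ``name``) require exact
    normalized enzyme-name *and* species agreement.  All hits are retained,
    sorted, deduplicated; the result is independent of entry order.
    """
    for col in IDMAP_COLUMNS:
        if col not in idmap.columns:
            raise ValueError(f"idmap is missing column {col!r}")

    by_id: dict[str, set[str]] = {}
    by_name: dict[tuple[str, str], set[str]] = {}
    for _, row in idmap.iterrows():
        acc = str(row["uniprot_accession"]).strip()
        if not acc:
            continue
        if str(row["scheme"]).strip().lower() == "name":
            key = (
                str(row["foreign_id"]).strip().lower(),
                normalize_species(str(row["species"])),
            )
            by_name.setdefault(key, set()).add(acc)
        else:
            by_id.setdefault(str(row["foreign_id"]).strip().lower(), set()).add(acc)

    out = []
    for ce in entries:
        harvested = ce.harvested_ids or harvest_ids(ce.entry)
        hits: set[str] = set()
        for token, _scheme in harvested:
            hits |= by_id.get(token.lower(), set())
        if not hits:
            name_key = (
                ce.entry.enzyme_name.strip().lower(),
                normalize_species(ce.entry.species_name),
            )
            hits = set(by_name.get(name_key, set()))
        out.append(
            replace(
                ce,
                harvested_ids=list(harvested),
                uniprot_accessions=sorted(hits),
            )
        )
    return out


# ---------------------------------------------------------------------------
# hallucination / host flagging


def _mentioned(species: str, aliases: tuple[str, ...], haystack: str) -> bool:
    needles = [species.lower(), *aliases]
    return any(n in haystack for n in needles)


def flag_hallucination(
    entries: list[CuratedEntry],
    paper_title: str,
    biomedical_species: dict[str, tuple[str, ...]] | None = None,
    source_text: str = "",
    heterologous_hosts: dict[str, tuple[str, ...]] | None = None,
) -> list[CuratedEntry]:
    """Flag biomedical-species entries unsupported by the paper itself.

    A species from the biomedical list (human/mouse/rat by default) that
    appears in neither the paper title nor the source text is a
    hallucination suspect.  Known heterologous expression hosts get the
    ``heterologous_host`` flag instead — their mention is real but the
    enzyme belongs to the donor organism.
    """
    biomedical = (
        DEFAULT_BIOMEDICAL_SPECIES if biomedical_species is None else biomedical_species
    )
    hosts = (
        DEFAULT_HETEROLOGOUS_HOSTS
        if heterologous_hosts is None
        else heterologous_hosts
    )
    haystack = f"{paper_title}\n{source_text}".lower()
    host_norm = {normalize_species(k): v for k, v in hosts.items()}
    biomed_norm = {normalize_species(k): v for k, v in biomedical.items()}

    out = []
    for ce in entries:
        species = normalize_species(ce.entry.species_name)
        if not species:
            out.append(ce)
            continue
        if species in host_norm:
            out.append(ce.with_flag("heterologous_host"))
            continue
        aliases = biomed_norm.get(species)
        if aliases is not None and not _mentioned(species, aliases, haystack):
            out.append(ce.with_flag("hallucination_suspect"))
        else:
            out.append(ce)
    return out


# ---------------------------------------------------------------------------
# prioritization and export


def prioritize(entries: list[CuratedEntry]) -> list[CuratedEntry]:
    """Assign priority tiers after mapping has been attempted."""
    out = []
    for ce in entries:
        if ce.uniprot_accessions:
            tier = 1
        elif ce.harvested_ids or ce.entry.sequence_ids:
            tier = 2
        else:
            tier = 3
            ce = ce.with_flag("no_sequence_id")
        out.append(replace(ce, priority_tier=tier))
    return out


def minimally_curated(entries: list[CuratedEntry]) -> list[CuratedEntry]:
    """The Minimally Curated Set: prioritized entries minus nontarget-family
    and nonplant flags (any tier; the tier stays recorded)."""
    return [
        ce
        for ce in entries
        if not (ce.flags & {"nontarget_family", "nonplant"})
    ]


CURATED_COLUMNS = [
    "source_id",
    "enzyme_name",
    "enzyme_abbrev",
    "species_name",
    "sequence_ids",
    "acceptor_substrates",
    "donor_substrates",
    "products",
    "method_source",
    "pairing_flag",
    "tax_family",
    "tax_kingdom",
    "uniprot_accessions",
    "flags",
    "priority_tier",
]


def curated_to_frame(entries: list[CuratedEntry]) -> pd.DataFrame:
    rows = []
    for ce in entries:
        e = ce.entry
        rows.append(
            {
                "source_id": e.source_id,
                "enzyme_name": e.enzyme_name,
                "enzyme_abbrev": e.enzyme_abbrev,
                "species_name": e.species_name,
                "sequence_ids": LIST_SEP.join(e.sequence_ids),
                "acceptor_substrates": LIST_SEP.join(e.acceptor_substrates),
                "donor_substrates": LIST_SEP.join(e.donor_substrates),
                "products": LIST_SEP.join(e.products),
                "method_source": e.method_source,
                "pairing_flag": getattr(e, "pairing_flag", ""),
                "tax_family": ce.tax_family,
                "tax_kingdom": ce.tax_kingdom,
                "uniprot_accessions": LIST_SEP.join(ce.uniprot_accessions),
                "flags": LIST_SEP.join(sorted(ce.flags)),
                "priority_tier": ce.priority_tier,
            }
        )
    return pd.DataFrame(rows, columns=CURATED_COLUMNS)
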
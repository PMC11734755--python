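"""Rigid sentence grammar for planted enzyme activities.

Synthetic manuscripts and abstracts embed each ground-truth activity as one
human-readable sentence with a fixed word order, so that both the rule-based
mock gateway and any independent parser can recover the planted fields
unambiguously.  The grammar is deliberately sentence-like (not hidden markup)
so the same fixtures exercise prompt templates realistically.

Canonical form::

    In enzymatic assays, the <family> enzyme <name> (<abbrev>; <ids>) from
    <species> converted acceptor(s) <a1; a2> with donor(s) <d1> into
    product(s) <p1; p2>.

Empty slots are written as ``-``.  A donor slot of ``reported separately``
signals the split-donor layout, where the donor is stated in its own
methods-style sentence::

    The acyl donor(s) for <name> was <d1; d2>.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

EMPTY_SLOT = "-"
SPLIT_DONOR_SLOT = "reported separately"
LIST_SEP = "; "

_SENTENCE_RE = re.compile(
    r"In enzymatic assays, the (?P<family>.+?) enzyme (?P<name>.+?) "
    r"\((?P<abbrev>.*?); (?P<ids>.*?)\) from (?P<species>.+?) "
    r"converted acceptor\(s\) (?P<acceptors>.*?) "
    r"with donor\(s\) (?P<donors>.*?) "
    r"into product\(s\) (?P<products>.*?)\."
)

_DONOR_RE = re.compile(
    r"The acyl donor\(s\) for (?P<name>.+?) (?:was|were) (?P<donors>.+?)\."
)


@dataclass
class PlantedActivity:
    """One ground-truth enzyme-substrate assertion planted in a fixture."""

    family: str
    enzyme_name: str
    abbrev: str = ""
    species: str = ""
    sequence_ids: list[str] = field(default_factory=list)
    acceptors: list[str] = field(default_factory=list)
    donors: list[str] = field(default_factory=list)
    products: list[str] = field(default_factory=list)
    split_donor: bool = False


def _join(values: list[str]) -> str:
    return LIST_SEP.join(values) if values else EMPTY_SLOT


def _split(slot: str) -> list[str]:
    slot = slot.strip()
    if not slot or slot == EMPTY_SLOT:
        return []
    return [v.strip() for v in slot.split(";") if v.strip()]


def format_sentence(activity: PlantedActivity) -> str:
    """Render the canonical activity sentence (donor sentence excluded)."""
    donors = SPLIT_DONOR_SLOT if activity.split_donor else _join(activity.donors)
    return (
        f"In enzymatic assays, the {activity.family} enzyme "
        f"{activity.enzyme_name} "
        f"({activity.abbrev or EMPTY_SLOT}; {_join(activity.sequence_ids)}) "
        f"from {activity.species or EMPTY_SLOT} "
        f"converted acceptor(s) {_join(activity.acceptors)} "
        f"with donor(s) {donors} "
        f"into product(s) {_join(activity.products)}."
    )


def format_donor_sentence(activity: PlantedActivity) -> str:
    verb = "were" if len(activity.donors) > 1 else "was"
    return (
        f"The acyl donor(s) for {activity.enzyme_name} {verb} "
        f"{_join(activity.donors)}."
    )


def parse_sentinels(text: str) -> list[PlantedActivity]:
    """Recover every planted activity from a document.

    Split-donor activities are resolved against donor sentences matched by
    enzyme name; an unmatched split-donor slot yields an empty donor list
    (that is the point of the layout: it stresses incomplete-donor handling
    downstream when a donor sentence is dropped).
    """
    # wrapped layouts (PDF text extraction) break sentences across lines;
    # the grammar is whitespace-insensitive, so normalize first
    text = re.sub(r"\s+", " ", text)
    donor_sentences: dict[str, list[str]] = {}
    for m in _DONOR_RE.finditer(text):
        donor_sentences[m.group("name").strip()] = _split(m.group("donors"))

    activities: list[PlantedActivity] = []
    for m in _SENTENCE_RE.finditer(text):
        name = m.group("name").strip()
        donor_slot = m.group("donors").strip()
        if donor_slot == SPLIT_DONOR_SLOT:
            donors = donor_sentences.get(name, [])
            split_donor = True
        else:
            donors = _split(donor_slot)
            split_donor = False
        abbrev = m.group("abbrev").strip()
        species = m.group("species").strip()
        activities.append(
            PlantedActivity(
                family=m.group("family").strip(),
                enzyme_name=name,
                abbrev="" if abbrev == EMPTY_SLOT else abbrev,
                species="" if species == EMPTY_SLOT else species,
                sequence_ids=_split(m.group("ids")),
                acceptors=_split(m.group("acceptors")),
                donors=donors,
                products=_split(m.group("products")),
                split_donor=split_donor,
            )
        )
    return activities
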
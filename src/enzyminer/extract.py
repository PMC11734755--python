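"""Manuscript-level activity extraction (Step 4).

Two extraction routes per paper — document attachment and extracted raw
text — merged by a third LLM call, then schema-validated and converted to
tabular entries.  Multi-activity rows are split into atomic entries
(at most one acceptor, donor, and product each) with positional pairing
when acceptor and product counts line up; mismatched rows are emitted as
unpaired atoms for manual review rather than cross-multiplied.

Compound names are preserved verbatim (including shorthand like aiC4 or
iC5 CoA esters); no normalization or synonym resolution happens here.
Every request is stateless: nothing from one paper's extraction can leak
into the next.
"""

from __future__ import annotations

import importlib.resources
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .gateway import Backend, LLMRequest, complete, payload_to_dicts
from .pdfio import pdf_to_text

__all__ = [
    "ActivityEntry",
    "AtomicEntry",
    "extract_via_text",
    "extract_via_attachment",
    "merge_payloads",
    "parse_payload",
    "split_entry",
    "entries_to_payload",
    "entries_to_frame",
    "frame_to_entries",
    "write_quarantine",
    "pdf_to_text",
]

LIST_SEP = "; "


@dataclass
class ActivityEntry:
    """One extracted enzyme-substrate assertion, possibly multi-compound."""

    source_id: str
    enzyme_name: str
    enzyme_abbrev: str = ""
    species_name: str = ""
    sequence_ids: list[str] = field(default_factory=list)
    acceptor_substrates: list[str] = field(default_factory=list)
    donor_substrates: list[str] = field(default_factory=list)
    products: list[str] = field(default_factory=list)
    method_source: str = "text"  # pdf | text | merge
    raw_payload: str = ""


@dataclass
class AtomicEntry(ActivityEntry):
    """An entry reduced to at most one acceptor, donor, and product."""

    pairing_flag: str = "aligned"  # aligned | unpaired

    def __post_init__(self) -> None:
        if (
            len(self.acceptor_substrates) > 1
            or len(self.donor_substrates) > 1
            or len(self.products) > 1
        ):
            raise ValueError("atomic entries carry at most one compound per slot")


def _template(name: str) -> str:
    ref = importlib.resources.files("enzyminer").joinpath("templates", name)
    return ref.read_text(encoding="utf-8")


def _extract_request(
    family: str, seed: int, user_doc: str | None, attachment: str | None
) -> LLMRequest:
    prompt = _template("extract.txt")
    user_text = f"{prompt}\nFAMILY: {family}"
    if user_doc is not None:
        user_text += f"\nDOCUMENT:\n{user_doc}"
    return LLMRequest(
        system_text=_template("system_extract.txt"),
        user_text=user_text,
        temperature=0.5,
        seed=seed,
        attachment=attachment,
    )


def extract_via_text(
    text: str, family: str, backend: Backend, seed: int = 1
) -> str:
    """Raw-text route: the extracted manuscript text travels in the prompt."""
    request = _extract_request(family, seed, user_doc=text, attachment=None)
    return complete(request, backend).text


def extract_via_attachment(
    pdf_path: str | Path, family: str, backend: Backend, seed: int = 1
) -> str:
    """Attachment route: the PDF travels as an opaque document handle."""
    request = _extract_request(
        family, seed, user_doc=None, attachment=str(pdf_path)
    )
    return complete(request, backend).text


def merge_payloads(
    payload_a: str, payload_b: str, backend: Backend, seed: int = 1
) -> str:
    """Merge the two routes' payloads with a third completion.

    An unparseable payload triggers a fallback to the parseable one with a
    warning; both unparseable is an error.
    """
    ok_a = ok_b = True
    try:
        payload_to_dicts(payload_a)
    except (ValueError, json.JSONDecodeError):
        ok_a = False
    try:
        payload_to_dicts(payload_b)
    except (ValueError, json.JSONDecodeError):
        ok_b = False
    if not ok_a and not ok_b:
        raise ValueError("both extraction payloads are unparseable")
    if not ok_a or not ok_b:
        warnings.warn(
            "one extraction payload was unparseable; falling back to the other",
            stacklevel=2,
        )
        return payload_a if ok_a else payload_b

    prompt = _template("merge.txt")
    request = LLMRequest(
        system_text=_template("system_extract.txt"),
        user_text=f"{prompt}\nPAYLOAD A:\n{payload_a}\nPAYLOAD B:\n{payload_b}",
        temperature=0.5,
        seed=seed,
    )
    return complete(request, backend).text


# ---------------------------------------------------------------------------
# payload parsing and validation


def _as_str_list(value) -> list[str] | None:
    if value is None:
        return []
    if isinstance(value, str):
        return [value] if value.strip() else []
    if isinstance(value, list) and all(isinstance(v, str) for v in value):
        return [v for v in value if v.strip()]
    return None


def _validate_record(rec: dict) -> tuple[dict | None, str]:
    if not isinstance(rec, dict):
        return None, "record is not an object"
    name = rec.get("enzyme_name", "")
    if not isinstance(name, str) or not name.strip():
        return None, "missing enzyme_name"
    fields = {}
    for key in ("sequence_ids", "acceptors", "donors", "products"):
        lst = _as_str_list(rec.get(key))
        if lst is None:
            return None, f"field {key} is not a list of strings"
        fields[key] = lst
    if not (fields["acceptors"] or fields["donors"] or fields["products"]):
        return None, "no compound information in any field"
    fields["enzyme_name"] = name.strip()
    fields["enzyme_abbrev"] = str(rec.get("enzyme_abbrev", "") or "").strip()
    fields["species"] = str(rec.get("species", "") or "").strip()
    return fields, ""


def parse_payload(
    raw: str, source_id: str, method_source: str
) -> tuple[list[ActivityEntry], list[tuple[str, str]]]:
    """Convert a JSON payload into validated entries.

    Returns (entries, quarantine); quarantined items are (raw fragment,
    reason) pairs.  A wholly unparseable payload yields no entries and one
    quarantine line.
    """
    try:
        records = payload_to_dicts(raw)
    except (ValueError, json.JSONDecodeError) as err:
        return [], [(raw, f"unparseable payload: {err}")]

    entries: list[ActivityEntry] = []
    quarantine: list[tuple[str, str]] = []
    for rec in records:
        fields, reason = _validate_record(rec)
        if fields is None:
            quarantine.append((json.dumps(rec, default=str), reason))
            continue
        entries.append(
            ActivityEntry(
                source_id=source_id,
                enzyme_name=fields["enzyme_name"],
                enzyme_abbrev=fields["enzyme_abbrev"],
                species_name=fields["species"],
                sequence_ids=fields["sequence_ids"],
                acceptor_substrates=fields["acceptors"],
                donor_substrates=fields["donors"],
                products=fields["products"],
                method_source=method_source,
                raw_payload=json.dumps(rec),
            )
        )
    return entries, quarantine


def entries_to_payload(entries: list[ActivityEntry]) -> str:
    """Serialize entries back to the JSON payload dialect (parse inverse)."""
    records = [
        {
            "enzyme_name": e.enzyme_name,
            "enzyme_abbrev": e.enzyme_abbrev,
            "species": e.species_name,
            "sequence_ids": list(e.sequence_ids),
            "acceptors": list(e.acceptor_substrates),
            "donors": list(e.donor_substrates),
            "products": list(e.products),
            "notes": "",
        }
        for e in entries
    ]
    return json.dumps({"activities": records}, indent=1)


def write_quarantine(
    quarantine: list[tuple[str, str]], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for fragment, reason in quarantine:
            fh.write(json.dumps({"reason": reason, "record": fragment}) + "\n")


# ---------------------------------------------------------------------------
# atomic splitting


def split_entry(entry: ActivityEntry) -> list[AtomicEntry]:
    """Split a multi-activity row into atomic entries.

    When acceptor and product counts agree, the i-th acceptor pairs with
    the i-th product; the donor pairs positionally when counts agree, is
    replicated when single, and is emitted as separate unpaired atoms when
    its count disagrees.  When acceptor and product counts disagree no
    pairing is trusted: every compound mention becomes its own unpaired
    atom flagged for manual review.
    """
    acc, don, pro = (
        entry.acceptor_substrates,
        entry.donor_substrates,
        entry.products,
    )

    def atom(a: list[str], d: list[str], p: list[str], flag: str) -> AtomicEntry:
        return AtomicEntry(
            source_id=entry.source_id,
            enzyme_name=entry.enzyme_name,
            enzyme_abbrev=entry.enzyme_abbrev,
            species_name=entry.species_name,
            sequence_ids=list(entry.sequence_ids),
            acceptor_substrates=a,
            donor_substrates=d,
            products=p,
            method_source=entry.method_source,
            raw_payload=entry.raw_payload,
            pairing_flag=flag,
        )

    if len(acc) == len(pro) and acc:
        atoms = []
        donor_aligned = len(don) == len(acc) or len(don) == 1
        for i in range(len(acc)):
            if len(don) == len(acc):
                d = [don[i]]
            elif len(don) == 1:
                d = [don[0]]
            else:
                d = []
            atoms.append(atom([acc[i]], d, [pro[i]], "aligned"))
        if not donor_aligned and don:
            atoms.extend(atom([], [d], [], "unpaired") for d in don)
        return atoms

    # degenerate single-slot rows stay aligned (nothing to mispair)
    non_empty = [s for s in (acc, don, pro) if s]
    if len(non_empty) == 1 and len(non_empty[0]) == 1:
        return [atom(acc[:1], don[:1], pro[:1], "aligned")]

    atoms = [atom([a], [], [], "unpaired") for a in acc]
    atoms += [atom([], [d], [], "unpaired") for d in don]
    atoms += [atom([], [], [p], "unpaired") for p in pro]
    return atoms


# ---------------------------------------------------------------------------
# tabular IO

ENTRY_COLUMNS = [
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
]


def entries_to_frame(entries: list[ActivityEntry]) -> pd.DataFrame:
    rows = []
    for e in entries:
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
            }
        )
    return pd.DataFrame(rows, columns=ENTRY_COLUMNS)


def _split_cell(cell) -> list[str]:
    if not isinstance(cell, str) or not cell.strip():
        return []
    return [v.strip() for v in cell.split(";") if v.strip()]


def frame_to_entries(frame: pd.DataFrame) -> list[ActivityEntry]:
    entries: list[ActivityEntry] = []
    for _, row in frame.iterrows():
        kwargs = dict(
            source_id=str(row["source_id"]),
            enzyme_name=str(row["enzyme_name"]),
            enzyme_abbrev=str(row.get("enzyme_abbrev", "") or ""),
            species_name=str(row.get("species_name", "") or ""),
            sequence_ids=_split_cell(row.get("sequence_ids")),
            acceptor_substrates=_split_cell(row.get("acceptor_substrates")),
            donor_substrates=_split_cell(row.get("donor_substrates")),
            products=_split_cell(row.get("products")),
            method_source=str(row.get("method_source", "text") or "text"),
        )
        flag = str(row.get("pairing_flag", "") or "")
        if flag:
            entries.append(AtomicEntry(pairing_flag=flag, **kwargs))
        else:
            entries.append(ActivityEntry(**kwargs))
    return entries
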
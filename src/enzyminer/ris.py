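"""RIS citation interchange format, reader and writer.

Only the tag subset needed for reference-manager import is emitted:
TY (always JOUR), TI, AU, JO, PY, DO, AB, ID (PubMed id), ER.  The parser
accepts any well-formed tagged records and returns them as dictionaries
keyed by tag, with repeated tags (AU) collected into lists.
"""

from __future__ import annotations

import re

__all__ = ["write_ris", "parse_ris"]

_TAG_RE = re.compile(r"^(?P<tag>[A-Z][A-Z0-9])  - ?(?P<value>.*)$")

_LIST_TAGS = {"AU", "KW"}


def write_ris(entries: list[dict]) -> str:
    """Serialize citation dictionaries to RIS text.

    Each entry may carry: title, authors (list), journal, year, doi,
    abstract, pmid.  Tags with empty values are omitted; every record is
    closed with ER.
    """
    blocks = []
    for e in entries:
        lines = ["TY  - JOUR"]
        if e.get("title"):
            lines.append(f"TI  - {e['title']}")
        for au in e.get("authors", []):
            lines.append(f"AU  - {au}")
        if e.get("journal"):
            lines.append(f"JO  - {e['journal']}")
        if e.get("year"):
            lines.append(f"PY  - {e['year']}")
        if e.get("doi"):
            lines.append(f"DO  - {e['doi']}")
        if e.get("abstract"):
            lines.append(f"AB  - {e['abstract']}")
        if e.get("pmid"):
            lines.append(f"ID  - {e['pmid']}")
        lines.append("ER  - ")
        blocks.append("\n".join(lines))
    return "\n".join(blocks) + ("\n" if blocks else "")


def parse_ris(text: str) -> list[dict]:
    """Parse RIS text back into the same dictionary form as write_ris."""
    entries: list[dict] = []
    current: dict | None = None
    for line in text.splitlines():
        m = _TAG_RE.match(line)
        if not m:
            continue
        tag, value = m.group("tag"), m.group("value").strip()
        if tag == "TY":
            current = {"type": value, "authors": []}
        elif current is None:
            continue
        elif tag == "ER":
            entries.append(current)
            current = None
        elif tag == "AU":
            current["authors"].append(value)
        elif tag == "TI":
            current["title"] = value
        elif tag == "JO":
            current["journal"] = value
        elif tag == "PY":
            current["year"] = int(value) if value.isdigit() else value
        elif tag == "DO":
            current["doi"] = value
        elif tag == "AB":
            current["abstract"] = value
        elif tag == "ID":
            current["pmid"] = value
    return entries
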
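"""Minimal PDF generation and text extraction.

The synthetic manuscripts used throughout the test harness are single-font,
uncompressed, text-layer-only PDFs produced by :func:`write_minimal_pdf`.
:func:`pdf_to_text` recovers the text of such documents (and of any PDF
whose content streams are uncompressed) by scanning the page content
streams for text-showing operators.  Image-only or empty documents yield
empty text with a warning rather than an error, so callers can route those
papers to the attachment-only extraction path.
"""

from __future__ import annotations

import re
import textwrap
import warnings
from pathlib import Path

__all__ = ["write_minimal_pdf", "pdf_to_text", "EmptyPdfWarning"]


class EmptyPdfWarning(UserWarning):
    pass


def _escape(line: str) -> str:
    return line.replace("\\", r"\\").replace("(", r"\(").replace(")", r"\)")


def _content_stream(lines: list[str], columns: int) -> bytes:
    """Build the page content stream; two-column layout splits the lines
    into left and right text blocks at different x origins."""
    blocks: list[tuple[int, list[str]]] = []
    if columns == 2 and len(lines) > 1:
        half = (len(lines) + 1) // 2
        blocks = [(40, lines[:half]), (310, lines[half:])]
    else:
        blocks = [(40, lines)]
    parts = []
    for x, block in blocks:
        ops = [f"BT /F1 9 Tf 11 TL {x} 780 Td"]
        for line in block:
            ops.append(f"({_escape(line)}) Tj T*")
        ops.append("ET")
        parts.append("\n".join(ops))
    return "\n".join(parts).encode("latin-1", errors="replace")


def write_minimal_pdf(
    text: str,
    path: str | Path,
    columns: int = 1,
    wrap: int = 88,
) -> Path:
    """Write ``text`` as an uncompressed one-page-per-~70-lines PDF."""
    path = Path(path)
    lines: list[str] = []
    for paragraph in text.split("\n"):
        wrapped = textwrap.wrap(paragraph, width=wrap) or [""]
        lines.extend(wrapped)

    per_page = 70
    pages = [lines[i : i + per_page] for i in range(0, len(lines), per_page)] or [[]]

    objects: list[bytes] = []
    # 1: catalog, 2: pages, 3: font; pages start at object 4
    n_pages = len(pages)
    page_obj_ids = [4 + 2 * i for i in range(n_pages)]
    kids = " ".join(f"{oid} 0 R" for oid in page_obj_ids)
    objects.append(b"<< /Type /Catalog /Pages 2 0 R >>")
    objects.append(
        f"<< /Type /Pages /Kids [{kids}] /Count {n_pages} >>".encode()
    )
    objects.append(b"<< /Type /Font /Subtype /Type1 /BaseFont /Helvetica >>")
    for i, page_lines in enumerate(pages):
        content = _content_stream(page_lines, columns)
        stream_id = page_obj_ids[i] + 1
        objects.append(
            (
                f"<< /Type /Page /Parent 2 0 R /MediaBox [0 0 612 792] "
                f"/Resources << /Font << /F1 3 0 R >> >> "
                f"/Contents {stream_id} 0 R >>"
            ).encode()
        )
        objects.append(
            f"<< /Length {len(content)} >>\nstream\n".encode()
            + content
            + b"\nendstream"
        )

    out = bytearray(b"%PDF-1.4\n")
    offsets = [0]
    for i, obj in enumerate(objects, start=1):
        offsets.append(len(out))
        out += f"{i} 0 obj\n".encode() + obj + b"\nendobj\n"
    xref_pos = len(out)
    n = len(objects) + 1
    out += f"xref\n0 {n}\n".encode()
    out += b"0000000000 65535 f \n"
    for off in offsets[1:]:
        out += f"{off:010d} 00000 n \n".encode()
    out += (
        f"trailer\n<< /Size {n} /Root 1 0 R >>\nstartxref\n{xref_pos}\n%%EOF\n"
    ).encode()
    path.write_bytes(bytes(out))
    return path


_STREAM_RE = re.compile(rb"stream\r?\n(.*?)\r?\nendstream", re.DOTALL)
_TJ_RE = re.compile(rb"\((?P<s>(?:\\.|[^()\\])*)\)\s*Tj")


def _unescape(raw: bytes) -> str:
    out = []
    i = 0
    while i < len(raw):
        c = raw[i : i + 1]
        if c == b"\\" and i + 1 < len(raw):
            nxt = raw[i + 1 : i + 2]
            if nxt in (b"(", b")", b"\\"):
                out.append(nxt.decode("latin-1"))
                i += 2
                continue
            if nxt == b"n":
                out.append("\n")
                i += 2
                continue
        out.append(c.decode("latin-1"))
        i += 1
    return "".join(out)


def pdf_to_text(path: str | Path) -> str:
    """Extract the text layer of an uncompressed PDF, in stream order."""
    data = Path(path).read_bytes()
    lines: list[str] = []
    for stream in _STREAM_RE.finditer(data):
        body = stream.group(1)
        if b"FlateDecode" in data[max(0, stream.start() - 200) : stream.start()]:
            continue  # compressed streams carry no recoverable plain text here
        for m in _TJ_RE.finditer(body):
            lines.append(_unescape(m.group("s")))
    text = "\n".join(lines)
    if not text.strip():
        warnings.warn(
            f"no selectable text found in {path}; document may be image-only",
            EmptyPdfWarning,
            stacklevel=2,
        )
    return text
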
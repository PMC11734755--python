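"""PubMed corpus retrieval: query construction, year chunking, fetching,
keyword/journal filtering.

The NCBI efetch service caps a single query's retrievable hits, so large
queries are split into publication-year windows whose individual hit counts
stay under the cap.  Retrieval goes through a small client contract
(:class:`EUtilsClient`) with a live stdlib-HTTP implementation and an
offline fixture implementation that serves genuine E-Utilities XML, so the
parser is exercised identically in tests and production.
"""

from __future__ import annotations

import re
import time
import urllib.parse
import urllib.request
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Protocol

from lxml import etree

__all__ = [
    "QueryConfig",
    "PaperRecord",
    "YearChunk",
    "InvalidConfigError",
    "EUtilsParseError",
    "EUtilsClient",
    "LiveEUtilsClient",
    "FixtureEUtilsClient",
    "build_query",
    "chunk_by_year",
    "fetch_records",
    "filter_records",
    "dedupe_records",
]


class InvalidConfigError(ValueError):
    pass


class EUtilsParseError(ValueError):
    """Raised when an E-Utilities response is not well-formed for its role."""


@dataclass(frozen=True)
class QueryConfig:
    """Settings for one family-specific corpus search.

    ``journals`` and ``keywords`` may be empty, which disables the
    corresponding filter.  ``per_query_limit`` mirrors the efetch retrieval
    cap that forces year chunking (default 10000).
    """

    family_term: str
    journals: tuple[str, ...] = ()
    keywords: tuple[str, ...] = ()
    exclude_reviews: bool = True
    use_elink: bool = False
    year_range: tuple[int, int] = (1975, 2024)
    per_query_limit: int = 10000
    retries: int = 3
    api_key: str | None = None
    email: str | None = None

    def __post_init__(self) -> None:
        if not self.family_term.strip():
            raise InvalidConfigError("family_term must be non-empty")
        if self.per_query_limit < 1:
            raise InvalidConfigError("per_query_limit must be >= 1")
        if self.year_range[0] > self.year_range[1]:
            raise InvalidConfigError("year_range start must be <= end")


@dataclass
class PaperRecord:
    """One PubMed article: identifiers, bibliographic fields, type flags."""

    pmid: str
    doi: str = ""
    title: str = ""
    abstract: str = ""
    journal: str = ""
    year: int = 0
    article_types: list[str] = field(default_factory=list)
    mesh_keywords: list[str] = field(default_factory=list)
    origin: str = "search"  # "search" or "elink"


@dataclass(frozen=True)
class YearChunk:
    start: int
    end: int
    hits: int = 0
    over_limit: bool = False


def build_query(config: QueryConfig, date_window: tuple[int, int]) -> str:
    """Compose a PubMed term string for one publication-year window."""
    lo, hi = date_window
    if lo < config.year_range[0] or hi > config.year_range[1]:
        raise InvalidConfigError("date_window outside config.year_range")
    parts = [f'("{config.family_term}")']
    if config.journals:
        journal_clause = " OR ".join(f'"{j}"[Journal]' for j in config.journals)
        parts.append(f"({journal_clause})")
    parts.append(f'("{lo}"[PDAT] : "{hi}"[PDAT])')
    query = " AND ".join(parts)
    if config.exclude_reviews:
        query += " NOT (Review[Publication Type])"
    return query


def chunk_by_year(
    hit_counter: Callable[[tuple[int, int]], int],
    window: tuple[int, int],
    limit: int,
) -> list[YearChunk]:
    """Partition ``window`` into year spans each holding <= ``limit`` hits.

    Greedy cumulative-sum over per-year counts, yielding the fewest windows.
    A single year exceeding the limit cannot be split further: it is
    returned alone with ``over_limit=True``.
    """
    if limit < 1:
        raise ValueError("limit must be >= 1")
    lo, hi = window
    if lo > hi:
        raise ValueError("window start must be <= end")
    per_year = {y: hit_counter((y, y)) for y in range(lo, hi + 1)}
    if sum(per_year.values()) == 0:
        return [YearChunk(lo, hi, 0, False)]

    chunks: list[YearChunk] = []
    start = lo
    acc = 0
    for y in range(lo, hi + 1):
        n = per_year[y]
        if n > limit:
            # flush accumulated span, then emit the oversize year alone
            if y > start:
                chunks.append(YearChunk(start, y - 1, acc, False))
            chunks.append(YearChunk(y, y, n, True))
            start, acc = y + 1, 0
        elif acc + n > limit:
            chunks.append(YearChunk(start, y - 1, acc, False))
            start, acc = y, n
        else:
            acc += n
    if start <= hi:
        chunks.append(YearChunk(start, hi, acc, False))
    return chunks


# ---------------------------------------------------------------------------
# client contract


class EUtilsClient(Protocol):
    def esearch(self, query: str, retstart: int, retmax: int) -> bytes: ...

    def efetch(self, pmids: list[str]) -> bytes: ...

    def elink(self, pmids: list[str]) -> bytes: ...


class LiveEUtilsClient:
    """Stdlib-HTTP client for the NCBI E-Utilities endpoints.

    Applies the standard courtesy rate limit and retries transient failures
    with exponential backoff.  Not used by the offline test suite.
    """

    BASE = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils"

    def __init__(
        self,
        api_key: str | None = None,
        email: str | None = None,
        retries: int = 3,
        delay: float = 0.34,
    ) -> None:
        self.api_key = api_key
        self.email = email
        self.retries = retries
        self.delay = delay

    def _get(self, endpoint: str, params: dict[str, str]) -> bytes:
        if self.api_key:
            params["api_key"] = self.api_key
        if self.email:
            params["email"] = self.email
        url = f"{self.BASE}/{endpoint}.fcgi?" + urllib.parse.urlencode(params)
        last_err: Exception | None = None
        for attempt in range(self.retries + 1):
            try:
                time.sleep(self.delay)
                with urllib.request.urlopen(url, timeout=60) as resp:
                    return resp.read()
            except Exception as err:  # noqa: BLE001 - transport layer
                last_err = err
                time.sleep(2.0**attempt)
        raise ConnectionError(f"E-Utilities request failed: {url}") from last_err

    def esearch(self, query: str, retstart: int, retmax: int) -> bytes:
        return self._get(
            "esearch",
            {
                "db": "pubmed",
                "term": query,
                "retstart": str(retstart),
                "retmax": str(retmax),
            },
        )

    def efetch(self, pmids: list[str]) -> bytes:
        return self._get(
            "efetch",
            {"db": "pubmed", "id": ",".join(pmids), "rettype": "abstract", "retmode": "xml"},
        )

    def elink(self, pmids: list[str]) -> bytes:
        return self._get(
            "elink",
            {"dbfrom": "pubmed", "db": "pubmed", "id": ",".join(pmids), "linkname": "pubmed_pubmed"},
        )


# ---------------------------------------------------------------------------
# fixture client

_QUOTED_RE = re.compile(r'^\("(?P<term>[^"]+)"\)')
_JOURNAL_RE = re.compile(r'"([^"]+)"\[Journal\]')
_PDAT_RE = re.compile(r'"(\d{4})"\[PDAT\] : "(\d{4})"\[PDAT\]')
_NOT_REVIEW_RE = re.compile(r"NOT \(Review\[Publication Type\]\)")


def _xml_escape(s: str) -> str:
    return s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")


class FixtureEUtilsClient:
    """Offline stand-in serving E-Utilities XML over an in-memory corpus.

    Evaluates only the query dialect emitted by :func:`build_query` (family
    term, journal disjunction, PDAT window, review exclusion).  ``links``
    optionally maps a pmid to related pmids served by ``elink``.
    """

    def __init__(
        self,
        records: Iterable[PaperRecord],
        links: dict[str, list[str]] | None = None,
    ) -> None:
        self.records = list(records)
        self.by_pmid = {r.pmid: r for r in self.records}
        self.links = links or {}

    def _matches(self, record: PaperRecord, query: str) -> bool:
        m = _QUOTED_RE.match(query)
        if m:
            term = m.group("term").lower()
            haystack = " ".join(
                [record.title, record.abstract, " ".join(record.mesh_keywords)]
            ).lower()
            if term not in haystack:
                return False
        journals = _JOURNAL_RE.findall(query)
        if journals and record.journal not in journals:
            return False
        pdat = _PDAT_RE.search(query)
        if pdat:
            lo, hi = int(pdat.group(1)), int(pdat.group(2))
            if not lo <= record.year <= hi:
                return False
        if _NOT_REVIEW_RE.search(query):
            if any("review" in t.lower() for t in record.article_types):
                return False
        return True

    def _hits(self, query: str) -> list[PaperRecord]:
        return [r for r in self.records if self._matches(r, query)]

    def count(self, query: str) -> int:
        return len(self._hits(query))

    def esearch(self, query: str, retstart: int, retmax: int) -> bytes:
        hits = self._hits(query)
        page = hits[retstart : retstart + retmax]
        ids = "".join(f"<Id>{r.pmid}</Id>" for r in page)
        xml = (
            '<?xml version="1.0" encoding="UTF-8" ?>\n'
            f"<eSearchResult><Count>{len(hits)}</Count>"
            f"<RetMax>{len(page)}</RetMax><RetStart>{retstart}</RetStart>"
            f"<IdList>{ids}</IdList></eSearchResult>"
        )
        return xml.encode()

    def efetch(self, pmids: list[str]) -> bytes:
        articles = []
        for pmid in pmids:
            r = self.by_pmid.get(pmid)
            if r is None:
                continue
            abstract = (
                f"<Abstract><AbstractText>{_xml_escape(r.abstract)}</AbstractText></Abstract>"
                if r.abstract
                else ""
            )
            types = "".join(
                f"<PublicationType>{_xml_escape(t)}</PublicationType>"
                for t in r.article_types
            )
            mesh = "".join(
                f"<MeshHeading><DescriptorName>{_xml_escape(k)}</DescriptorName></MeshHeading>"
                for k in r.mesh_keywords
            )
            doi = (
                f'<ArticleId IdType="doi">{_xml_escape(r.doi)}</ArticleId>' if r.doi else ""
            )
            articles.append(
                "<PubmedArticle><MedlineCitation>"
                f"<PMID>{r.pmid}</PMID>"
                "<Article>"
                f"<Journal><Title>{_xml_escape(r.journal)}</Title>"
                f"<JournalIssue><PubDate><Year>{r.year}</Year></PubDate></JournalIssue></Journal>"
                f"<ArticleTitle>{_xml_escape(r.title)}</ArticleTitle>"
                f"{abstract}"
                f"<PublicationTypeList>{types}</PublicationTypeList>"
                "</Article>"
                f"<MeshHeadingList>{mesh}</MeshHeadingList>"
                "</MedlineCitation><PubmedData>"
                f"<ArticleIdList><ArticleId IdType=\"pubmed\">{r.pmid}</ArticleId>{doi}</ArticleIdList>"
                "</PubmedData></PubmedArticle>"
            )
        xml = (
            '<?xml version="1.0" encoding="UTF-8" ?>\n'
            f"<PubmedArticleSet>{''.join(articles)}</PubmedArticleSet>"
        )
        return xml.encode()

    def elink(self, pmids: list[str]) -> bytes:
        linksets = []
        for pmid in pmids:
            ids = "".join(
                f"<Link><Id>{t}</Id></Link>" for t in self.links.get(pmid, [])
            )
            linksets.append(
                "<LinkSet><IdList>"
                f"<Id>{pmid}</Id></IdList>"
                f"<LinkSetDb><DbTo>pubmed</DbTo><LinkName>pubmed_pubmed</LinkName>{ids}</LinkSetDb>"
                "</LinkSet>"
            )
        xml = (
            '<?xml version="1.0" encoding="UTF-8" ?>\n'
            f"<eLinkResult>{''.join(linksets)}</eLinkResult>"
        )
        return xml.encode()


# ---------------------------------------------------------------------------
# parsing


def _parse_xml(payload: bytes, role: str) -> etree._Element:
    try:
        return etree.fromstring(payload)
    except etree.XMLSyntaxError as err:
        raise EUtilsParseError(f"malformed {role} response: {err}") from err


def parse_esearch(payload: bytes) -> tuple[int, list[str]]:
    root = _parse_xml(payload, "esearch")
    count_el = root.find("Count")
    if count_el is None:
        raise EUtilsParseError("esearch response missing <Count>")
    ids = [el.text for el in root.findall(".//IdList/Id") if el.text]
    return int(count_el.text), ids


def parse_efetch(payload: bytes) -> list[PaperRecord]:
    root = _parse_xml(payload, "efetch")
    records = []
    for art in root.findall(".//PubmedArticle"):
        pmid = art.findtext(".//MedlineCitation/PMID", default="")
        title = art.findtext(".//ArticleTitle", default="") or ""
        abstract = " ".join(
            (el.text or "") for el in art.findall(".//Abstract/AbstractText")
        ).strip()
        journal = art.findtext(".//Journal/Title", default="") or ""
        year_text = art.findtext(".//JournalIssue/PubDate/Year")
        if year_text is None:
            medline_date = art.findtext(".//JournalIssue/PubDate/MedlineDate", default="")
            m = re.search(r"\d{4}", medline_date or "")
            year_text = m.group(0) if m else "0"
        types = [el.text or "" for el in art.findall(".//PublicationTypeList/PublicationType")]
        mesh = [
            el.text or ""
            for el in art.findall(".//MeshHeadingList/MeshHeading/DescriptorName")
        ]
        doi = ""
        for aid in art.findall(".//ArticleIdList/ArticleId"):
            if aid.get("IdType") == "doi" and aid.text:
                doi = aid.text
        records.append(
            PaperRecord(
                pmid=pmid,
                doi=doi,
                title=title,
                abstract=abstract,
                journal=journal,
                year=int(year_text),
                article_types=[t for t in types if t],
                mesh_keywords=[k for k in mesh if k],
            )
        )
    return records


def parse_elink(payload: bytes) -> list[str]:
    root = _parse_xml(payload, "elink")
    return [el.text for el in root.findall(".//LinkSetDb/Link/Id") if el.text]


# ---------------------------------------------------------------------------
# high-level retrieval


def fetch_records(
    query: str,
    client: EUtilsClient,
    use_elink: bool = False,
    batch_size: int = 200,
) -> list[PaperRecord]:
    """Run esearch paging + efetch (and optional elink expansion).

    Records without an abstract are retained with an empty abstract.
    Elink-expanded records are tagged ``origin="elink"``.
    """
    count, ids = parse_esearch(client.esearch(query, 0, batch_size))
    while len(ids) < count:
        _, more = parse_esearch(client.esearch(query, len(ids), batch_size))
        if not more:
            break
        ids.extend(more)

    records: list[PaperRecord] = []
    for i in range(0, len(ids), batch_size):
        records.extend(parse_efetch(client.efetch(ids[i : i + batch_size])))

    if use_elink and ids:
        seen = {r.pmid for r in records}
        linked: list[str] = []
        for i in range(0, len(ids), batch_size):
            linked.extend(parse_elink(client.elink(ids[i : i + batch_size])))
        new_ids = [p for p in dict.fromkeys(linked) if p not in seen]
        for i in range(0, len(new_ids), batch_size):
            for rec in parse_efetch(client.efetch(new_ids[i : i + batch_size])):
                records.append(replace(rec, origin="elink"))
    return records


def dedupe_records(records: Iterable[PaperRecord]) -> list[PaperRecord]:
    """Drop duplicates by PMID, falling back to lower-cased DOI."""
    seen: set[str] = set()
    out: list[PaperRecord] = []
    for r in records:
        key = r.pmid or f"doi:{r.doi.lower()}"
        if key in seen:
            continue
        seen.add(key)
        out.append(r)
    return out


def filter_records(records: list[PaperRecord], config: QueryConfig) -> list[PaperRecord]:
    """Journal / keyword / review-type filter (order-preserving, idempotent).

    A record survives iff its journal is in the configured list (or the list
    is empty), some keyword matches title+abstract+MeSH case-insensitively
    (or the list is empty), and it is not review-typed when reviews are
    excluded.
    """
    out = []
    for r in records:
        if config.journals and r.journal not in config.journals:
            continue
        if config.keywords:
            haystack = " ".join(
                [r.title, r.abstract, " ".join(r.mesh_keywords)]
            ).lower()
            if not any(k.lower() in haystack for k in config.keywords):
                continue
        if config.exclude_reviews and any(
            "review" in t.lower() for t in r.article_types
        ):
            continue
        out.append(r)
    return out
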
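"""Chat-completion gateway: one contract, a live backend and a rule-based mock.

Every pipeline stage that needs a language model goes through
:func:`complete`, so the whole workflow can run offline against
:class:`MockBackend` — a pure function of (request text, seed) that reads
the sentinel grammar planted by the synthetic-fixture generator.  The live
backend wraps the OpenAI chat-completion API and is imported lazily; it is
never needed by the test suite.

Binary screening requests are constrained the same way on both backends:
``max_tokens=1`` plus a two-token logit bias, so the reply is exactly "1"
or "0".  Each call is stateless (fresh context): no conversation memory is
ever carried between papers.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Protocol

from .sentinel import PlantedActivity, parse_sentinels

__all__ = [
    "LLMRequest",
    "LLMResponse",
    "TransportError",
    "Backend",
    "MockBackend",
    "OpenAIBackend",
    "complete",
    "mock_rules",
    "DEFAULT_TOKEN_BIAS",
    "activities_to_payload",
    "payload_to_dicts",
]

# token ids of "0" and "1" in the cl100k vocabulary, biased hard so a
# single-token completion must be one of them
DEFAULT_TOKEN_BIAS: dict[str, int] = {"15": 100, "16": 100}


class TransportError(RuntimeError):
    def __init__(self, message: str, request_id: str = "") -> None:
        super().__init__(message)
        self.request_id = request_id


@dataclass(frozen=True)
class LLMRequest:
    system_text: str
    user_text: str
    temperature: float = 0.5
    seed: int = 1
    max_tokens: int | None = None
    token_bias: dict[str, int] | None = None
    attachment: str | None = None  # path to a PDF document
    request_id: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.temperature <= 2.0:
            raise ValueError("temperature must be in [0, 2]")
        if self.max_tokens is not None and self.max_tokens < 1:
            raise ValueError("max_tokens must be positive")

    @property
    def is_binary(self) -> bool:
        return self.max_tokens == 1 and bool(self.token_bias) and len(self.token_bias) == 2


@dataclass
class LLMResponse:
    text: str
    token_logprobs: list[tuple[str, float]] | None = None
    model_id: str = ""
    fresh_context: bool = True


class Backend(Protocol):
    model_id: str

    def complete(self, request: LLMRequest) -> LLMResponse: ...


def complete(request: LLMRequest, backend: Backend) -> LLMResponse:
    """Issue one stateless chat completion through ``backend``."""
    response = backend.complete(request)
    if request.is_binary and response.text not in ("1", "0"):
        # the constrained-token contract must hold on every backend
        raise TransportError(
            f"binary-constrained request returned {response.text!r}",
            request.request_id,
        )
    return response


# ---------------------------------------------------------------------------
# payload helpers (shared JSON dialect between mock and live prompts)


def activities_to_payload(activities: Iterable[PlantedActivity]) -> str:
    records = [
        {
            "enzyme_name": a.enzyme_name,
            "enzyme_abbrev": a.abbrev,
            "species": a.species,
            "sequence_ids": list(a.sequence_ids),
            "acceptors": list(a.acceptors),
            "donors": list(a.donors),
            "products": list(a.products),
            "notes": "",
        }
        for a in activities
    ]
    return json.dumps({"activities": records}, indent=1)


def payload_to_dicts(payload: str) -> list[dict]:
    data = json.loads(payload)
    if isinstance(data, dict):
        data = data.get("activities", [])
    if not isinstance(data, list):
        raise ValueError("payload is neither a list nor an activities object")
    return data


def _record_key(rec: dict) -> tuple:
    def norm(v) -> tuple:
        if isinstance(v, list):
            return tuple(str(x).strip().lower() for x in v)
        return (str(v).strip().lower(),)

    return (
        norm(rec.get("enzyme_name", "")),
        norm(rec.get("acceptors", [])),
        norm(rec.get("donors", [])),
        norm(rec.get("products", [])),
    )


# ---------------------------------------------------------------------------
# mock backend

_QUESTION_FAMILY_RE = re.compile(r'"([^"]+)"')
_SECTION_RE = re.compile(
    r"TITLE:(?P<title>.*?)\nABSTRACT:(?P<abstract>.*?)\nQUESTION:(?P<question>.*)",
    re.DOTALL,
)
_FAMILY_LINE_RE = re.compile(r"^FAMILY:\s*(?P<family>.+)$", re.MULTILINE)
_DOC_RE = re.compile(r"DOCUMENT:\n(?P<doc>.*)", re.DOTALL)
_PAYLOADS_RE = re.compile(
    r"PAYLOAD A:\n(?P<a>.*?)\nPAYLOAD B:\n(?P<b>.*)", re.DOTALL
)
_MARKER_RE = re.compile(r"In enzymatic assays,")


def mock_rules(text: str, task: str, seed: int = 1) -> str:
    """Deterministic stand-in behavior for the three LLM tasks.

    ``screen``: "1" iff the title+abstract carries a planted assay sentence
    for the queried family, or — for templates with inclusive wording
    ("likely", "describes") — merely mentions the family name.  ``extract``:
    structured JSON for every sentinel block whose family matches the query.
    ``merge``: de-duplicated union of two JSON payloads.
    """
    if task == "screen":
        m = _SECTION_RE.search(text)
        if not m:
            return "0"
        body = m.group("title") + "\n" + m.group("abstract")
        question = m.group("question")
        fam_match = _QUESTION_FAMILY_RE.search(question)
        family = fam_match.group(1).lower() if fam_match else ""
        strict = "directly tests" in question
        has_marker = any(
            a.family.lower() == family for a in parse_sentinels(body)
        ) if family else bool(_MARKER_RE.search(body))
        if has_marker:
            return "1"
        if not strict and family and family in body.lower():
            return "1"
        return "0"

    if task == "extract":
        fam = _FAMILY_LINE_RE.search(text)
        doc = _DOC_RE.search(text)
        family = fam.group("family").strip().lower() if fam else ""
        body = doc.group("doc") if doc else text
        hits = [
            a for a in parse_sentinels(body)
            if not family or a.family.lower() == family
        ]
        return activities_to_payload(hits)

    if task == "merge":
        m = _PAYLOADS_RE.search(text)
        if not m:
            raise ValueError("merge request lacks PAYLOAD A/B sections")
        recs_a = payload_to_dicts(m.group("a"))
        recs_b = payload_to_dicts(m.group("b"))
        merged: dict[tuple, dict] = {}
        for rec in recs_a + recs_b:
            merged.setdefault(_record_key(rec), rec)
        return json.dumps({"activities": list(merged.values())}, indent=1)

    raise ValueError(f"unrecognized mock task: {task!r}")


class MockBackend:
    """Rule-based offline backend; bit-identical output for identical input.

    The task is inferred from the request shape: a binary-constrained
    request is a screen, a request carrying PAYLOAD A/B sections is a merge,
    anything else is an extraction.  An extraction request with a PDF
    attachment reads the document through the given text extractor
    (defaults to the built-in minimal-PDF reader).
    """

    model_id = "mock-rules-1"

    def __init__(self, log_path: str | Path | None = None) -> None:
        self.log_path = Path(log_path) if log_path else None

    def _task(self, request: LLMRequest) -> str:
        if request.is_binary:
            return "screen"
        if "PAYLOAD A:" in request.user_text:
            return "merge"
        return "extract"

    def complete(self, request: LLMRequest) -> LLMResponse:
        task = self._task(request)
        user_text = request.user_text
        if task == "extract" and request.attachment:
            from .pdfio import pdf_to_text

            doc = pdf_to_text(request.attachment)
            user_text = f"{user_text}\nDOCUMENT:\n{doc}"
        text = mock_rules(user_text, task, seed=request.seed)
        logprobs = None
        if task == "screen":
            # stable pseudo-confidence: marker-backed yes > keyword yes > no
            logprobs = [(text, -0.02 if text == "1" else -0.05)]
        response = LLMResponse(
            text=text, token_logprobs=logprobs, model_id=self.model_id
        )
        if self.log_path is not None:
            log_exchange(self.log_path, request, response)
        return response


# ---------------------------------------------------------------------------
# live backend (lazy import; not exercised by offline tests)


class OpenAIBackend:
    """Thin wrapper over the OpenAI chat-completion API.

    Live completions are not guaranteed deterministic even with a fixed
    seed; responses are logged so any run can be audited and replayed.
    """

    def __init__(
        self,
        model_id: str = "gpt-4-turbo",
        api_key: str | None = None,
        log_path: str | Path | None = None,
    ) -> None:
        try:
            from openai import OpenAI
        except ImportError as err:  # pragma: no cover - live-only path
            raise ImportError(
                "the live backend requires the optional 'openai' package"
            ) from err
        self._client = OpenAI(api_key=api_key)
        self.model_id = model_id
        self.log_path = Path(log_path) if log_path else None

    def complete(self, request: LLMRequest) -> LLMResponse:  # pragma: no cover
        kwargs: dict = {
            "model": self.model_id,
            "temperature": request.temperature,
            "seed": request.seed,
            "messages": [
                {"role": "system", "content": request.system_text},
                {"role": "user", "content": request.user_text},
            ],
        }
        if request.max_tokens is not None:
            kwargs["max_tokens"] = request.max_tokens
        if request.token_bias:
            kwargs["logit_bias"] = {int(k): v for k, v in request.token_bias.items()}
        try:
            out = self._client.chat.completions.create(**kwargs)
        except Exception as err:  # noqa: BLE001
            raise TransportError(str(err), request.request_id) from err
        text = out.choices[0].message.content or ""
        response = LLMResponse(text=text.strip(), model_id=self.model_id)
        if self.log_path is not None:
            log_exchange(self.log_path, request, response)
        return response


# ---------------------------------------------------------------------------
# audit log and batch files (line-delimited JSON)


def log_exchange(path: str | Path, request: LLMRequest, response: LLMResponse) -> None:
    entry = {"request": asdict(request), "response": asdict(response)}
    with open(path, "a", encoding="utf-8") as fh:
        fh.write(json.dumps(entry) + "\n")


def read_log(path: str | Path) -> list[dict]:
    with open(path, encoding="utf-8") as fh:
        return [json.loads(line) for line in fh if line.strip()]


def dump_batch(requests: Iterable[LLMRequest], path: str | Path) -> None:
    """Serialize a request queue for overnight batch submission."""
    with open(path, "w", encoding="utf-8") as fh:
        for req in requests:
            fh.write(json.dumps(asdict(req)) + "\n")


def load_batch(path: str | Path) -> list[LLMRequest]:
    with open(path, encoding="utf-8") as fh:
        return [LLMRequest(**json.loads(line)) for line in fh if line.strip()]
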
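"""Abstract screening (Step 2): binary family-specific triage of title and
abstract, plus RIS export of the positives.

Each paper gets one stateless, binary-constrained completion: the prompt
embeds the enzyme family name in a templated question, and the reply is
forced to the single token "1" (yes) or "0" (no) through max_tokens=1 and
a two-token logit bias.  Default temperature 0.5 and seed 1.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .corpus import PaperRecord
from .gateway import (
    DEFAULT_TOKEN_BIAS,
    Backend,
    LLMRequest,
    TransportError,
    complete,
)
from .ris import write_ris

__all__ = [
    "PromptTemplate",
    "ScreenDecision",
    "TemplateError",
    "load_template",
    "render_prompt",
    "screen_corpus",
    "export_ris",
    "decisions_to_frame",
]

FAMILY_PLACEHOLDER = "{family}"


class TemplateError(ValueError):
    pass


@dataclass(frozen=True)
class PromptTemplate:
    """A screening question with a single family placeholder."""

    template_id: str
    system_text: str
    question_text: str

    def __post_init__(self) -> None:
        if self.question_text.count(FAMILY_PLACEHOLDER) != 1:
            raise TemplateError(
                f"template {self.template_id!r} must contain exactly one "
                f"{FAMILY_PLACEHOLDER} placeholder"
            )


@dataclass
class ScreenDecision:
    pmid: str
    label: str  # "yes" | "no"
    raw_token: str  # "1" | "0"
    token_logprob: float | None
    template_id: str
    temperature: float
    seed: int

    def __post_init__(self) -> None:
        if (self.label == "yes") != (self.raw_token == "1"):
            raise ValueError("label and raw_token disagree")


def _read_resource(name: str) -> str:
    ref = importlib.resources.files("enzyminer").joinpath("templates", name)
    return ref.read_text(encoding="utf-8")


def load_template(template_id: str) -> PromptTemplate:
    """Load a shipped screening template (e.g. ``q1``, ``q11``) by id."""
    return PromptTemplate(
        template_id=template_id,
        system_text=_read_resource("system_screen.txt"),
        question_text=_read_resource(f"{template_id.lower()}.txt"),
    )


def render_prompt(
    template: PromptTemplate,
    family: str,
    record: PaperRecord,
    temperature: float = 0.5,
    seed: int = 1,
) -> LLMRequest:
    """Build the binary-constrained request for one paper."""
    if not record.title:
        raise ValueError(f"record {record.pmid} has an empty title")
    question = template.question_text.replace(FAMILY_PLACEHOLDER, family)
    user_text = (
        f"TITLE: {record.title}\n"
        f"ABSTRACT: {record.abstract}\n"
        f"QUESTION: {question}"
    )
    return LLMRequest(
        system_text=template.system_text,
        user_text=user_text,
        temperature=temperature,
        seed=seed,
        max_tokens=1,
        token_bias=dict(DEFAULT_TOKEN_BIAS),
        request_id=f"screen:{record.pmid}",
    )


def screen_corpus(
    records: list[PaperRecord],
    template: PromptTemplate,
    family: str,
    backend: Backend,
    temperature: float = 0.5,
    seed: int = 1,
    retry_path: str | Path | None = None,
) -> tuple[list[ScreenDecision], list[tuple[str, str]]]:
    """Screen every record; transport failures never abort the run.

    Returns the decision list plus a list of (pmid, error) pairs for
    records that failed after retries; when ``retry_path`` is given those
    pmids are also written to a sidecar file for later resubmission.
    On the mock backend the failure list is empty and the decision list is
    deterministic for a given seed.
    """
    decisions: list[ScreenDecision] = []
    failures: list[tuple[str, str]] = []
    for record in records:
        request = render_prompt(template, family, record, temperature, seed)
        try:
            response = complete(request, backend)
        except TransportError as err:
            failures.append((record.pmid, str(err)))
            continue
        token = response.text
        logprob = None
        if response.token_logprobs:
            logprob = response.token_logprobs[0][1]
        decisions.append(
            ScreenDecision(
                pmid=record.pmid,
                label="yes" if token == "1" else "no",
                raw_token=token,
                token_logprob=logprob,
                template_id=template.template_id,
                temperature=temperature,
                seed=seed,
            )
        )
    if retry_path is not None and failures:
        Path(retry_path).write_text(
            "".join(f"{pmid}\t{msg}\n" for pmid, msg in failures),
            encoding="utf-8",
        )
    return decisions, failures


def decisions_to_frame(decisions: list[ScreenDecision]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pmid": d.pmid,
                "label": d.label,
                "raw_token": d.raw_token,
                "token_logprob": d.token_logprob,
                "template_id": d.template_id,
                "temperature": d.temperature,
                "seed": d.seed,
            }
            for d in decisions
        ],
        columns=[
            "pmid",
            "label",
            "raw_token",
            "token_logprob",
            "template_id",
            "temperature",
            "seed",
        ],
    )


def export_ris(
    decisions: list[ScreenDecision], records: list[PaperRecord]
) -> str:
    """RIS text with one JOUR block per yes-decision, for reference-manager
    import and PDF retrieval."""
    by_pmid = {r.pmid: r for r in records}
    entries = []
    for d in decisions:
        if d.label != "yes":
            continue
        r = by_pmid.get(d.pmid)
        if r is None:
            continue
        entries.append(
            {
                "title": r.title,
                "journal": r.journal,
                "year": r.year,
                "doi": r.doi,
                "abstract": r.abstract,
                "pmid": r.pmid,
            }
        )
    return write_ris(entries)
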
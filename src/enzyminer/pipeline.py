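"""Orchestration across the five pipeline stages, with a run manifest.

Stages run in fixed order — search, screen, extract, curate, grade — and
communicate only through files in the working directory, so any stage can
resume from a previous run's outputs.  The manifest records a config
snapshot, per-stage input/output digests and record counts, and the
backend identity, making every run reproducible and auditable; with the
mock backend two runs of the same config are identical except timestamps.
"""

from __future__ import annotations

import configparser
import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import curate as cur
from . import evaluate as ev
from . import extract as ex
from .corpus import (
    EUtilsClient,
    PaperRecord,
    QueryConfig,
    build_query,
    chunk_by_year,
    dedupe_records,
    fetch_records,
    filter_records,
    parse_esearch,
)
from .gateway import Backend
from .screen import decisions_to_frame, export_ris, load_template, screen_corpus

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "run_pipeline",
    "funnel_report",
    "load_config",
    "records_to_frame",
    "frame_to_records",
    "STAGES",
]

STAGES = ("search", "screen", "extract", "curate", "grade")


@dataclass
class PipelineConfig:
    family: str
    lexicon: str = "bahd_acyltransferase"
    template_id: str = "q11"
    temperature: float = 0.5
    seed: int = 1
    mode: str = "merge"  # pdf | text | merge
    query: QueryConfig | None = None
    pdf_dir: str | None = None
    lineage_path: str | None = None
    idmap_path: str | None = None
    hqd_path: str | None = None

    def snapshot(self) -> dict:
        data = dataclasses.asdict(self)
        return data


def load_config(path: str | Path) -> PipelineConfig:
    """Read the flat key/value configuration file (INI sections)."""
    parser = configparser.ConfigParser()
    parser.read(path)
    search = parser["search"] if "search" in parser else {}
    screen = parser["screen"] if "screen" in parser else {}
    extract = parser["extract"] if "extract" in parser else {}
    curate_s = parser["curate"] if "curate" in parser else {}
    grade = parser["grade"] if "grade" in parser else {}

    query = None
    if search.get("family"):
        years = search.get("years", "1975-2024").split("-")
        query = QueryConfig(
            family_term=search["family"],
            journals=tuple(
                j.strip() for j in search.get("journals", "").split(",") if j.strip()
            ),
            keywords=tuple(
                k.strip() for k in search.get("keywords", "").split(",") if k.strip()
            ),
            exclude_reviews=search.get("exclude_reviews", "true").lower() == "true",
            use_elink=search.get("use_elink", "false").lower() == "true",
            year_range=(int(years[0]), int(years[1])),
            per_query_limit=int(search.get("per_query_limit", "10000")),
        )
    return PipelineConfig(
        family=search.get("family", screen.get("family", "")),
        lexicon=curate_s.get("lexicon", "bahd_acyltransferase"),
        template_id=screen.get("template", "q11"),
        temperature=float(screen.get("temperature", "0.5")),
        seed=int(screen.get("seed", "1")),
        mode=extract.get("mode", "merge"),
        query=query,
        pdf_dir=extract.get("pdf_dir"),
        lineage_path=curate_s.get("lineage"),
        idmap_path=curate_s.get("idmap"),
        hqd_path=grade.get("hqd"),
    )


@dataclass
class RunManifest:
    run_id: str
    config: dict
    backend_id: str
    steps: list[dict] = field(default_factory=list)
    created: float = 0.0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(path: Path, producing_stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"{path} is missing; run the '{producing_stage}' stage first"
        )
    return path


# ---------------------------------------------------------------------------
# record table IO

RECORD_COLUMNS = [
    "pmid",
    "doi",
    "title",
    "abstract",
    "journal",
    "year",
    "article_types",
    "mesh_keywords",
    "origin",
]


def records_to_frame(records: list[PaperRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pmid": r.pmid,
                "doi": r.doi,
                "title": r.title,
                "abstract": r.abstract,
                "journal": r.journal,
                "year": r.year,
                "article_types": "; ".join(r.article_types),
                "mesh_keywords": "; ".join(r.mesh_keywords),
                "origin": r.origin,
            }
            for r in records
        ],
        columns=RECORD_COLUMNS,
    )


def frame_to_records(frame: pd.DataFrame) -> list[PaperRecord]:
    records = []
    for _, row in frame.fillna("").iterrows():
        records.append(
            PaperRecord(
                pmid=str(row["pmid"]),
                doi=str(row["doi"]),
                title=str(row["title"]),
                abstract=str(row["abstract"]),
                journal=str(row["journal"]),
                year=int(row["year"]),
                article_types=[
                    t.strip() for t in str(row["article_types"]).split(";") if t.strip()
                ],
                mesh_keywords=[
                    k.strip() for k in str(row["mesh_keywords"]).split(";") if k.strip()
                ],
                origin=str(row["origin"]) or "search",
            )
        )
    return records


# ---------------------------------------------------------------------------
# stage implementations


def _stage_search(
    config: PipelineConfig, workdir: Path, client: EUtilsClient
) -> dict:
    if config.query is None:
        raise ValueError("search stage requires a QueryConfig")
    qc = config.query

    def hit_counter(window: tuple[int, int]) -> int:
        count, _ = parse_esearch(client.esearch(build_query(qc, window), 0, 0))
        return count

    chunks = chunk_by_year(hit_counter, qc.year_range, qc.per_query_limit)
    records: list[PaperRecord] = []
    for chunk in chunks:
        query = build_query(qc, (chunk.start, chunk.end))
        records.extend(fetch_records(query, client, use_elink=qc.use_elink))
    records = dedupe_records(records)
    kept = filter_records(records, qc)
    records_to_frame(kept).to_csv(workdir / "records.tsv", sep="\t", index=False)
    return {
        "family": config.family,
        "windows": len(chunks),
        "fetched": len(records),
        "out": len(kept),
    }


def _stage_screen(
    config: PipelineConfig, workdir: Path, backend: Backend
) -> dict:
    records = frame_to_records(
        pd.read_csv(_require(workdir / "records.tsv", "search"), sep="\t")
    )
    template = load_template(config.template_id)
    decisions, failures = screen_corpus(
        records,
        template,
        config.family,
        backend,
        temperature=config.temperature,
        seed=config.seed,
        retry_path=workdir / "screen_retry.tsv",
    )
    decisions_to_frame(decisions).to_csv(
        workdir / "decisions.tsv", sep="\t", index=False
    )
    (workdir / "positives.ris").write_text(
        export_ris(decisions, records), encoding="utf-8"
    )
    n_yes = sum(1 for d in decisions if d.label == "yes")
    return {
        "family": config.family,
        "in": len(records),
        "yes": n_yes,
        "no": len(decisions) - n_yes,
        "failed": len(failures),
    }


def _find_document(pdf_dir: Path, pmid: str) -> Path | None:
    for pattern in (f"ITEM{pmid}/*.pdf", f"ITEM{pmid}/*.txt", f"{pmid}.pdf", f"{pmid}.txt"):
        hits = sorted(pdf_dir.glob(pattern))
        if hits:
            return hits[0]
    return None


def _stage_extract(
    config: PipelineConfig, workdir: Path, backend: Backend
) -> dict:
    decisions = pd.read_csv(_require(workdir / "decisions.tsv", "screen"), sep="\t")
    yes_pmids = [str(p) for p in decisions[decisions["label"] == "yes"]["pmid"]]
    pdf_dir = Path(config.pdf_dir) if config.pdf_dir else workdir / "pdfs"

    atoms: list[ex.ActivityEntry] = []
    quarantine: list[tuple[str, str]] = []
    n_docs = 0
    for pmid in yes_pmids:
        doc = _find_document(pdf_dir, pmid)
        if doc is None:
            continue
        n_docs += 1
        if doc.suffix == ".pdf":
            text = ex.pdf_to_text(doc)
            pdf_path: Path | None = doc
        else:
            text = doc.read_text(encoding="utf-8")
            pdf_path = None
        payloads = {}
        if config.mode in ("text", "merge"):
            payloads["text"] = ex.extract_via_text(
                text, config.family, backend, seed=config.seed
            )
        if config.mode in ("pdf", "merge") and pdf_path is not None:
            payloads["pdf"] = ex.extract_via_attachment(
                pdf_path, config.family, backend, seed=config.seed
            )
        if config.mode == "merge" and len(payloads) == 2:
            raw = ex.merge_payloads(
                payloads["pdf"], payloads["text"], backend, seed=config.seed
            )
            source = "merge"
        else:
            source, raw = next(iter(payloads.items()))
        entries, bad = ex.parse_payload(raw, source_id=pmid, method_source=source)
        quarantine.extend(bad)
        for entry in entries:
            atoms.extend(ex.split_entry(entry))

    ex.entries_to_frame(atoms).to_csv(workdir / "entries.tsv", sep="\t", index=False)
    ex.write_quarantine(quarantine, workdir / "quarantine.jsonl")
    return {
        "family": config.family,
        "in": len(yes_pmids),
        "documents": n_docs,
        "entries": len(atoms),
        "quarantined": len(quarantine),
    }


def _stage_curate(config: PipelineConfig, workdir: Path) -> dict:
    frame = pd.read_csv(
        _require(workdir / "entries.tsv", "extract"), sep="\t"
    ).fillna("")
    frame["source_id"] = frame["source_id"].astype(str)
    entries = ex.frame_to_entries(frame)
    curated = [cur.CuratedEntry.from_entry(e) for e in entries]

    if config.lineage_path:
        lineage = cur.LineageTable.from_tsv(config.lineage_path)
        curated = cur.attach_taxonomy(curated, lineage)
    lexicon = cur.load_lexicon(config.lexicon)
    curated = cur.flag_nontarget(curated, lexicon)
    if config.idmap_path:
        idmap = pd.read_csv(config.idmap_path, sep="\t", dtype=str).fillna("")
        curated = cur.map_uniprot(curated, idmap)

    titles: dict[str, str] = {}
    records_path = workdir / "records.tsv"
    if records_path.exists():
        rec_frame = pd.read_csv(records_path, sep="\t").fillna("")
        titles = {
            str(r["pmid"]): str(r["title"]) for _, r in rec_frame.iterrows()
        }
    # flag per paper so the title context is the right one
    by_paper: dict[str, list[cur.CuratedEntry]] = {}
    for ce in curated:
        by_paper.setdefault(ce.entry.source_id, []).append(ce)
    flagged: list[cur.CuratedEntry] = []
    for pmid, group in by_paper.items():
        flagged.extend(
            cur.flag_hallucination(group, paper_title=titles.get(pmid, ""))
        )
    curated = cur.prioritize(flagged)
    minimal = cur.minimally_curated(curated)

    cur.curated_to_frame(curated).to_csv(
        workdir / "curated.tsv", sep="\t", index=False
    )
    cur.curated_to_frame(minimal).to_csv(
        workdir / "minimally_curated.tsv", sep="\t", index=False
    )
    flag_counts: dict[str, int] = {}
    for ce in curated:
        for flag in ce.flags:
            flag_counts[flag] = flag_counts.get(flag, 0) + 1
    return {
        "family": config.family,
        "in": len(entries),
        "minimally_curated": len(minimal),
        "tier1": sum(1 for ce in curated if ce.priority_tier == 1),
        **{f"flag_{k}": v for k, v in sorted(flag_counts.items())},
    }


def _stage_grade(config: PipelineConfig, workdir: Path) -> dict:
    if not config.hqd_path:
        raise ValueError("grade stage requires hqd_path in the config")
    hqd = pd.read_csv(config.hqd_path, sep="\t", dtype=str).fillna("")
    frame = pd.read_csv(
        _require(workdir / "minimally_curated.tsv", "curate"), sep="\t"
    ).fillna("")
    frame["source_id"] = frame["source_id"].astype(str)
    entries = ex.frame_to_entries(frame[ex.ENTRY_COLUMNS])
    grades = [ev.GradeRecord(entry_ref=e, grade="correct") for e in entries]
    reaction, substrate = ev.reaction_substrate_pr(grades, hqd)
    report = pd.DataFrame(
        [
            {
                "granularity": m.granularity,
                "precision": m.precision,
                "recall": m.recall,
                "f1": m.f1,
                **m.counts,
            }
            for m in (reaction, substrate)
        ]
    )
    report.to_csv(workdir / "metrics.tsv", sep="\t", index=False)
    return {
        "family": config.family,
        "in": len(entries),
        "reaction_precision": reaction.precision,
        "reaction_recall": reaction.recall,
        "substrate_precision": substrate.precision,
        "substrate_recall": substrate.recall,
    }


_STAGE_OUTPUTS = {
    "search": ["records.tsv"],
    "screen": ["decisions.tsv", "positives.ris"],
    "extract": ["entries.tsv", "quarantine.jsonl"],
    "curate": ["curated.tsv", "minimally_curated.tsv"],
    "grade": ["metrics.tsv"],
}
_STAGE_INPUTS = {
    "search": [],
    "screen": ["records.tsv"],
    "extract": ["decisions.tsv"],
    "curate": ["entries.tsv"],
    "grade": ["minimally_curated.tsv"],
}


def run_pipeline(
    config: PipelineConfig,
    stages: list[str],
    workdir: str | Path,
    client: EUtilsClient | None = None,
    backend: Backend | None = None,
) -> RunManifest:
    """Execute the selected stages in canonical order and write a manifest.

    Unselected earlier stages are resumed from their on-disk outputs, whose
    digests are verified into the manifest before the next stage starts.
    """
    for stage in stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; valid: {', '.join(STAGES)}")
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)

    backend_id = getattr(backend, "model_id", "none")
    manifest = RunManifest(
        run_id=f"{config.family.replace(' ', '_')}-seed{config.seed}",
        config=config.snapshot(),
        backend_id=backend_id,
        created=time.time(),
    )

    for stage in STAGES:
        if stage not in stages:
            continue
        inputs = {
            name: _digest(_require(workdir / name, _producer(name)))
            for name in _STAGE_INPUTS[stage]
        }
        if stage == "search":
            if client is None:
                raise ValueError("search stage requires an E-Utilities client")
            counts = _stage_search(config, workdir, client)
        elif stage == "screen":
            if backend is None:
                raise ValueError("screen stage requires an LLM backend")
            counts = _stage_screen(config, workdir, backend)
        elif stage == "extract":
            if backend is None:
                raise ValueError("extract stage requires an LLM backend")
            counts = _stage_extract(config, workdir, backend)
        elif stage == "curate":
            counts = _stage_curate(config, workdir)
        else:
            counts = _stage_grade(config, workdir)
        outputs = {
            name: _digest(workdir / name)
            for name in _STAGE_OUTPUTS[stage]
            if (workdir / name).exists()
        }
        manifest.steps.append(
            {"stage": stage, "inputs": inputs, "outputs": outputs, "counts": counts}
        )
        manifest.save(workdir / "manifest.json")

    return manifest


def _producer(filename: str) -> str:
    for stage, outputs in _STAGE_OUTPUTS.items():
        if filename in outputs:
            return stage
    return "unknown"


def funnel_report(manifests: RunManifest | list[RunManifest]) -> pd.DataFrame:
    """Per-stage record counts, one row per family."""
    if isinstance(manifests, RunManifest):
        manifests = [manifests]
    rows = []
    for manifest in manifests:
        row: dict = {"family": manifest.config.get("family", "")}
        for step in manifest.steps:
            stage = step["stage"]
            for key, value in step["counts"].items():
                if key == "family":
                    continue
                row[f"{stage}_{key}"] = value
        rows.append(row)
    return pd.DataFrame(rows)
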
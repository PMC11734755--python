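"""Validation machinery: screening confusion metrics, four-class grading
summaries, reaction- and substrate-level precision/recall against a
high-quality comparison dataset (HQD), coverage statistics, the
curation-gap estimate, and prompt benchmarking.

Conventions: metrics with a zero denominator are reported as ``None``
(undefined), never as 0; rounding happens only at presentation and is
never fed back into computation; "unknown correct" grades (plausible
extractions absent from the HQD) are excluded from both the numerator and
denominator of precision unless explicitly appended to the HQD in the
"(+)" re-grading mode.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from .curate import CuratedEntry
from .extract import ActivityEntry

__all__ = [
    "ConfusionCounts",
    "GradeRecord",
    "MetricsReport",
    "GradeSummary",
    "CurationGapReport",
    "confusion_metrics",
    "f1_score",
    "screening_recall",
    "coverage_stats",
    "grade_summary",
    "reaction_substrate_pr",
    "curation_gap",
    "benchmark_prompts",
    "family_id_hit_summary",
    "HQD_COLUMNS",
]

GRADES = ("correct", "unknown_correct", "incorrect", "incomplete")
HQD_COLUMNS = [
    "enzyme",
    "species",
    "accession",
    "acceptor",
    "donor",
    "product",
    "reference",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_pairs(
        cls, truth: Sequence[bool], predicted: Sequence[bool]
    ) -> "ConfusionCounts":
        if len(truth) != len(predicted):
            raise ValueError("truth and prediction lengths differ")
        tp = sum(t and p for t, p in zip(truth, predicted))
        fp = sum((not t) and p for t, p in zip(truth, predicted))
        tn = sum((not t) and (not p) for t, p in zip(truth, predicted))
        fn = sum(t and (not p) for t, p in zip(truth, predicted))
        return cls(tp, fp, tn, fn)


@dataclass
class GradeRecord:
    """Evaluator verdict for one atomic entry."""

    entry_ref: ActivityEntry | None
    grade: str
    missing_component: str = "none"  # donor | acceptor | none
    family_match: bool = True

    def __post_init__(self) -> None:
        if self.grade not in GRADES:
            raise ValueError(f"unknown grade {self.grade!r}")
        if self.missing_component not in ("donor", "acceptor", "none"):
            raise ValueError(f"unknown missing_component {self.missing_component!r}")
        if self.missing_component != "none" and self.grade != "incomplete":
            raise ValueError("a missing component implies grade 'incomplete'")


@dataclass
class MetricsReport:
    granularity: str  # reaction | substrate | screening
    precision: float | None
    recall: float | None
    f1: float | None
    counts: dict = field(default_factory=dict)


def f1_score(precision: float | None, recall: float | None) -> float | None:
    if precision is None or recall is None:
        return None
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def confusion_metrics(c: ConfusionCounts, granularity: str = "screening") -> MetricsReport:
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    return MetricsReport(
        granularity=granularity,
        precision=precision,
        recall=recall,
        f1=f1_score(precision, recall),
        counts={"tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn},
    )


def screening_recall(relevant_retrieved: int, classified_yes: int) -> float:
    """Fraction of truly relevant retrieved papers the screen passed on."""
    if classified_yes > relevant_retrieved:
        raise ValueError("classified_yes cannot exceed relevant_retrieved")
    if relevant_retrieved == 0:
        raise ValueError("no relevant papers retrieved; recall undefined")
    return classified_yes / relevant_retrieved


def coverage_stats(hqd_papers: int, retrieved: int) -> float:
    """Percentage of comparison-dataset papers found by the search step."""
    if retrieved > hqd_papers:
        raise ValueError("retrieved cannot exceed hqd_papers")
    if hqd_papers == 0:
        raise ValueError("empty comparison dataset")
    return 100.0 * retrieved / hqd_papers


# ---------------------------------------------------------------------------
# grading summaries


@dataclass
class GradeSummary:
    n_total: int
    class_counts: dict[str, int]
    class_pct: dict[str, float]
    n_missing_donor: int
    n_missing_acceptor: int
    donor_missing_pct: float | None
    acceptor_missing_pct: float | None
    n_incorrect: int
    n_incorrect_family_match: int
    fp_family_match_pct: float | None


def grade_summary(grades: list[GradeRecord]) -> GradeSummary:
    """Per-class counts/percentages, the donor/acceptor split among
    single-substrate incompletes, and the family composition of the
    incorrect (false-positive) entries."""
    n = len(grades)
    counts = {g: 0 for g in GRADES}
    for rec in grades:
        counts[rec.grade] += 1
    pct = {g: (100.0 * c / n if n else 0.0) for g, c in counts.items()}

    n_donor = sum(1 for r in grades if r.missing_component == "donor")
    n_acceptor = sum(1 for r in grades if r.missing_component == "acceptor")
    n_single_sub = n_donor + n_acceptor
    donor_pct = 100.0 * n_donor / n_single_sub if n_single_sub else None
    acceptor_pct = 100.0 * n_acceptor / n_single_sub if n_single_sub else None

    incorrect = [r for r in grades if r.grade == "incorrect"]
    n_fam = sum(1 for r in incorrect if r.family_match)
    fam_pct = 100.0 * n_fam / len(incorrect) if incorrect else None

    return GradeSummary(
        n_total=n,
        class_counts=counts,
        class_pct=pct,
        n_missing_donor=n_donor,
        n_missing_acceptor=n_acceptor,
        donor_missing_pct=donor_pct,
        acceptor_missing_pct=acceptor_pct,
        n_incorrect=len(incorrect),
        n_incorrect_family_match=n_fam,
        fp_family_match_pct=fam_pct,
    )


# ---------------------------------------------------------------------------
# reaction- and substrate-level precision/recall vs the HQD


def _norm(name: str) -> str:
    return " ".join(str(name).lower().split())


def _entry_slots(e: ActivityEntry) -> tuple[str, str, str]:
    acc = _norm(e.acceptor_substrates[0]) if e.acceptor_substrates else ""
    don = _norm(e.donor_substrates[0]) if e.donor_substrates else ""
    pro = _norm(e.products[0]) if e.products else ""
    return acc, don, pro


def _match_score(entry_slots: tuple[str, str, str], row: tuple[str, str, str]) -> int:
    return sum(1 for a, b in zip(entry_slots, row) if a and b and a == b)


def _max_matching(eligible: np.ndarray) -> int:
    """Size of a maximum bipartite matching over a boolean eligibility
    matrix (rows = extracted entries, columns = HQD activities)."""
    if eligible.size == 0 or not eligible.any():
        return 0
    graph = csr_matrix(eligible)
    match = maximum_bipartite_matching(graph, perm_type="column")
    return int((match != -1).sum())


def reaction_substrate_pr(
    grades: list[GradeRecord],
    hqd: pd.DataFrame,
    augment_unknown: bool = False,
) -> tuple[MetricsReport, MetricsReport]:
    """Reaction-level and substrate-level precision/recall.

    Reaction level: an extracted entry counts as correct when it can be
    matched to an HQD activity of the same paper agreeing on at least 2 of
    the 3 reaction compounds (acceptor, donor, product); matching is
    one-to-one (maximum bipartite matching per paper).  Substrate level:
    compound mentions are judged independently per slot via multiset
    intersection.  Recall denominators are the HQD activities (or
    mentions) of the evaluated papers only.

    ``augment_unknown=True`` is the "(+)" re-grading mode: unknown-correct
    entries are appended to the HQD and included in the evaluated set;
    otherwise they are excluded from both sides of precision.
    """
    for col in HQD_COLUMNS:
        if col not in hqd.columns:
            raise ValueError(f"HQD table is missing column {col!r}")

    kept: list[ActivityEntry] = []
    extra_rows: list[dict] = []
    for rec in grades:
        if rec.entry_ref is None:
            continue
        if rec.grade == "unknown_correct":
            if augment_unknown:
                e = rec.entry_ref
                acc, don, pro = _entry_slots(e)
                extra_rows.append(
                    {
                        "enzyme": e.enzyme_name,
                        "species": e.species_name,
                        "accession": "",
                        "acceptor": acc,
                        "donor": don,
                        "product": pro,
                        "reference": e.source_id,
                    }
                )
                kept.append(e)
            continue
        kept.append(rec.entry_ref)

    papers = {e.source_id for e in kept}
    hqd_slice = hqd[hqd["reference"].astype(str).isin(papers)]
    if extra_rows:
        hqd_slice = pd.concat(
            [hqd_slice, pd.DataFrame(extra_rows)], ignore_index=True
        )

    # --- reaction level
    matched_entries = 0
    n_hqd_rows = len(hqd_slice)
    for paper in sorted(papers):
        p_entries = [e for e in kept if e.source_id == paper]
        p_rows = hqd_slice[hqd_slice["reference"].astype(str) == paper]
        if not p_entries or p_rows.empty:
            continue
        row_slots = [
            (_norm(r["acceptor"]), _norm(r["donor"]), _norm(r["product"]))
            for _, r in p_rows.iterrows()
        ]
        eligible = np.array(
            [
                [_match_score(_entry_slots(e), rs) >= 2 for rs in row_slots]
                for e in p_entries
            ],
            dtype=bool,
        )
        matched_entries += _max_matching(eligible)

    reaction_p = matched_entries / len(kept) if kept else None
    reaction_r = matched_entries / n_hqd_rows if n_hqd_rows else None
    reaction = MetricsReport(
        granularity="reaction",
        precision=reaction_p,
        recall=reaction_r,
        f1=f1_score(reaction_p, reaction_r),
        counts={
            "matched": matched_entries,
            "entries": len(kept),
            "hqd_activities": n_hqd_rows,
        },
    )

    # --- substrate level (slot-aware multiset intersection per paper)
    matched_mentions = 0
    total_extracted = 0
    total_hqd = 0
    slots = ("acceptor", "donor", "product")
    for paper in sorted(papers):
        p_entries = [e for e in kept if e.source_id == paper]
        p_rows = hqd_slice[hqd_slice["reference"].astype(str) == paper]
        for si, slot in enumerate(slots):
            ext = Counter(
                _entry_slots(e)[si] for e in p_entries if _entry_slots(e)[si]
            )
            ref = Counter(
                _norm(v) for v in p_rows[slot] if _norm(v)
            )
            matched_mentions += sum((ext & ref).values())
            total_extracted += sum(ext.values())
            total_hqd += sum(ref.values())
    # HQD mentions of papers with no surviving entries still count in recall
    other = hqd_slice[~hqd_slice["reference"].astype(str).isin(papers)]
    for slot in slots:
        total_hqd += sum(1 for v in other[slot] if _norm(v))

    substrate_p = matched_mentions / total_extracted if total_extracted else None
    substrate_r = matched_mentions / total_hqd if total_hqd else None
    substrate = MetricsReport(
        granularity="substrate",
        precision=substrate_p,
        recall=substrate_r,
        f1=f1_score(substrate_p, substrate_r),
        counts={
            "matched": matched_mentions,
            "extracted_mentions": total_extracted,
            "hqd_mentions": total_hqd,
        },
    )
    return reaction, substrate


# ---------------------------------------------------------------------------
# curation gap


@dataclass
class CurationGapReport:
    basis: str
    n_unique_ids: int
    n_reviewed: int
    reviewed_pct: float | None
    n_catalytic: int
    catalytic_pct: float | None
    n_missed_catalogued: int
    gap_pct: float | None


def curation_gap(
    verified_entries: Iterable[CuratedEntry] | Iterable[str],
    reviewed_ids: set[str],
    rhea_ids: set[str],
    missed_catalogued_ids: set[str] = frozenset(),
    basis: str = "per_id",
) -> CurationGapReport:
    """Fraction of the verified set lacking catalytic-activity annotations.

    ``verified_entries`` may be curated entries (their mapped accessions
    are pooled) or a bare iterable of accession strings.  Known annotated
    enzymes that the workflow missed (``missed_catalogued_ids``) extend
    both the annotated count and the universe, making the estimate a lower
    bound on the true gap.
    """
    ids: set[str] = set()
    for item in verified_entries:
        if isinstance(item, CuratedEntry):
            ids.update(item.uniprot_accessions)
        else:
            ids.add(str(item))

    missed = set(missed_catalogued_ids) - ids
    n_unique = len(ids)
    n_reviewed = len(ids & reviewed_ids)
    n_catalytic = len(ids & rhea_ids)
    universe = n_unique + len(missed)
    annotated = n_catalytic + len(missed)
    return CurationGapReport(
        basis=basis,
        n_unique_ids=n_unique,
        n_reviewed=n_reviewed,
        reviewed_pct=100.0 * n_reviewed / n_unique if n_unique else None,
        n_catalytic=n_catalytic,
        catalytic_pct=100.0 * n_catalytic / n_unique if n_unique else None,
        n_missed_catalogued=len(missed),
        gap_pct=100.0 * (1 - annotated / universe) if universe else None,
    )


# ---------------------------------------------------------------------------
# prompt benchmarking


def benchmark_prompts(
    records,
    truth: dict[str, bool],
    templates,
    temperatures: Sequence[float],
    backend,
    family: str,
    seed: int = 1,
) -> pd.DataFrame:
    """Metrics grid over (template, temperature) cells.

    Deterministic on the mock backend; per-cell transport failures are
    recorded in the ``failures`` column and never abort the grid.
    """
    from .screen import screen_corpus

    rows = []
    for template in templates:
        for temp in temperatures:
            decisions, failures = screen_corpus(
                records, template, family, backend, temperature=temp, seed=seed
            )
            pairs = [
                (truth[d.pmid], d.label == "yes")
                for d in decisions
                if d.pmid in truth
            ]
            counts = ConfusionCounts.from_pairs(
                [t for t, _ in pairs], [p for _, p in pairs]
            )
            report = confusion_metrics(counts)
            rows.append(
                {
                    "template_id": template.template_id,
                    "temperature": temp,
                    "tp": counts.tp,
                    "fp": counts.fp,
                    "tn": counts.tn,
                    "fn": counts.fn,
                    "precision": report.precision,
                    "recall": report.recall,
                    "f1": report.f1,
                    "yes_rate": (counts.tp + counts.fp) / counts.total
                    if counts.total
                    else None,
                    "failures": len(failures),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "template_id",
            "temperature",
            "tp",
            "fp",
            "tn",
            "fn",
            "precision",
            "recall",
            "f1",
            "yes_rate",
            "failures",
        ],
    )


# ---------------------------------------------------------------------------
# per-family ID-hit table


def family_id_hit_summary(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-family extracted/ID-hit counts with percentages and a totals row.

    Input columns: ``family``, ``extracted_entries``, ``id_hits``.
    Output adds ``pct_with_id`` and ``no_id`` per family plus a ``Total``
    row (summed counts; average of the per-family percentages).
    """
    for col in ("family", "extracted_entries", "id_hits"):
        if col not in frame.columns:
            raise ValueError(f"missing column {col!r}")
    out = frame.copy()
    out["pct_with_id"] = 100.0 * out["id_hits"] / out["extracted_entries"]
    out["no_id"] = out["extracted_entries"] - out["id_hits"]
    total = pd.DataFrame(
        [
            {
                "family": "Total",
                "extracted_entries": int(out["extracted_entries"].sum()),
                "id_hits": int(out["id_hits"].sum()),
                "pct_with_id": float(out["pct_with_id"].mean()),
                "no_id": int(out["no_id"].sum()),
            }
        ]
    )
    return pd.concat([out, total], ignore_index=True)
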
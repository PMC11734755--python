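"""Evaluation harness: confusion metrics, grading summaries, HQD
precision/recall with an exhaustive matching oracle, curation gap,
prompt benchmarking."""

import itertools
import random

import pandas as pd
import pytest

from enzyminer.evaluate import (
    ConfusionCounts,
    GradeRecord,
    benchmark_prompts,
    confusion_metrics,
    coverage_stats,
    curation_gap,
    f1_score,
    family_id_hit_summary,
    grade_summary,
    reaction_substrate_pr,
    screening_recall,
)
from enzyminer.extract import ActivityEntry
from enzyminer.gateway import MockBackend
from enzyminer.screen import load_template
from enzyminer.synth import CorpusSpec, make_testset


class TestConfusionMetrics:
    def test_published_example_rounds_to_091(self):
        # a screen with precision 0.95 and recall 0.88 has F1 0.91
        assert round(f1_score(0.95, 0.88), 2) == 0.91

    def test_perfect_classifier(self):
        report = confusion_metrics(ConfusionCounts(tp=20, fp=0, tn=5, fn=0))
        assert report.precision == report.recall == report.f1 == 1.0

    def test_random_counts_agree_with_item_level_recount(self):
        """Aggregate formulas agree with a per-item brute-force recount."""
        rng = random.Random(7)
        for _ in range(100):
            tp, fp, tn, fn = (rng.randint(0, 30) for _ in range(4))
            truth = [True] * tp + [False] * fp + [False] * tn + [True] * fn
            pred = [True] * tp + [True] * fp + [False] * tn + [False] * fn
            counts = ConfusionCounts.from_pairs(truth, pred)
            assert (counts.tp, counts.fp, counts.tn, counts.fn) == (tp, fp, tn, fn)
            report = confusion_metrics(counts)
            if tp + fp:
                assert report.precision == tp / (tp + fp)
            else:
                assert report.precision is None
            if tp + fn:
                assert report.recall == tp / (tp + fn)
            else:
                assert report.recall is None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)

    def test_undefined_metrics_are_none_not_zero(self):
        report = confusion_metrics(ConfusionCounts(tp=0, fp=0, tn=10, fn=0))
        assert report.precision is None
        assert report.recall is None
        assert report.f1 is None


class TestRatioOperations:
    def test_screening_recall_examples(self):
        assert round(screening_recall(113, 101), 2) == 0.89
        assert round(screening_recall(78, 76), 2) == 0.97
        assert screening_recall(50, 50) == 1.0

    def test_coverage_examples(self):
        assert round(coverage_stats(129, 113), 1) == 87.6
        assert round(coverage_stats(129, 78), 1) == 60.5
        assert coverage_stats(40, 0) == 0.0

    def test_impossible_ratios_rejected(self):
        with pytest.raises(ValueError):
            screening_recall(10, 11)
        with pytest.raises(ValueError):
            coverage_stats(10, 11)


def make_grades(n_correct=0, n_unknown=0, n_incorrect=0, n_incomplete=0,
                n_missing_donor=0, n_missing_acceptor=0, n_incorrect_family=0):
    grades = []
    grades += [GradeRecord(None, "correct") for _ in range(n_correct)]
    grades += [GradeRecord(None, "unknown_correct") for _ in range(n_unknown)]
    grades += [
        GradeRecord(None, "incorrect", family_match=i < n_incorrect_family)
        for i in range(n_incorrect)
    ]
    grades += [
        GradeRecord(None, "incomplete", missing_component="donor")
        for _ in range(n_missing_donor)
    ]
    grades += [
        GradeRecord(None, "incomplete", missing_component="acceptor")
        for _ in range(n_missing_acceptor)
    ]
    grades += [
        GradeRecord(None, "incomplete")
        for _ in range(n_incomplete - n_missing_donor - n_missing_acceptor)
    ]
    return grades


class TestGradeSummary:
    def test_incomplete_share_of_graded_entries(self):
        grades = make_grades(n_correct=539, n_unknown=0, n_incorrect=65,
                             n_incomplete=191, n_missing_donor=74,
                             n_missing_acceptor=22)
        summary = grade_summary(grades)
        assert summary.n_total == 795
        assert round(summary.class_pct["incomplete"], 1) == 24.0

    def test_single_substrate_split(self):
        grades = make_grades(n_incomplete=96, n_missing_donor=74,
                             n_missing_acceptor=22)
        summary = grade_summary(grades)
        assert round(summary.donor_missing_pct, 1) == 77.1
        assert round(summary.acceptor_missing_pct, 1) == 22.9

    def test_false_positive_family_composition(self):
        summary = grade_summary(make_grades(n_incorrect=65, n_incorrect_family=20))
        assert round(summary.fp_family_match_pct, 1) == 30.8

    def test_all_correct_has_zero_everywhere_else(self):
        summary = grade_summary(make_grades(n_correct=10))
        assert summary.class_pct["correct"] == 100.0
        for cls in ("unknown_correct", "incorrect", "incomplete"):
            assert summary.class_pct[cls] == 0.0
        assert summary.donor_missing_pct is None

    def test_invariant_missing_component_implies_incomplete(self):
        with pytest.raises(ValueError):
            GradeRecord(None, "correct", missing_component="donor")


def atomic(source, enzyme, acceptor, donor, product):
    return ActivityEntry(
        source_id=source,
        enzyme_name=enzyme,
        acceptor_substrates=[acceptor] if acceptor else [],
        donor_substrates=[donor] if donor else [],
        products=[product] if product else [],
    )


def hqd_frame(rows):
    return pd.DataFrame(
        [
            {
                "enzyme": r[0], "species": "", "accession": "",
                "acceptor": r[1], "donor": r[2], "product": r[3],
                "reference": r[4],
            }
            for r in rows
        ]
    )


def exhaustive_matching_oracle(entries, rows):
    """Maximum number of one-to-one entry/row pairs agreeing on >= 2 of 3
    compounds, by explicit enumeration (small instances only)."""
    def score(e, r):
        slots_e = (
            e.acceptor_substrates[0].lower() if e.acceptor_substrates else "",
            e.donor_substrates[0].lower() if e.donor_substrates else "",
            e.products[0].lower() if e.products else "",
        )
        return sum(
            1 for a, b in zip(slots_e, r) if a and b and a == b
        )

    best = 0
    indices = range(len(rows))
    for k in range(min(len(entries), len(rows)), 0, -1):
        for entry_subset in itertools.permutations(range(len(entries)), k):
            for row_subset in itertools.combinations(indices, k):
                if all(
                    score(entries[e], rows[r]) >= 2
                    for e, r in zip(entry_subset, row_subset)
                ):
                    return k
    return best


class TestReactionSubstratePR:
    def test_exact_match_gives_unit_scores(self):
        entries = [atomic("p1", "E1", "a", "d", "pr"), atomic("p1", "E2", "b", "d", "qr")]
        hqd = hqd_frame([("E1", "a", "d", "pr", "p1"), ("E2", "b", "d", "qr", "p1")])
        grades = [GradeRecord(e, "correct") for e in entries]
        reaction, substrate = reaction_substrate_pr(grades, hqd)
        assert reaction.precision == reaction.recall == 1.0
        assert substrate.precision == substrate.recall == 1.0

    def test_two_of_three_rule(self):
        # acceptor+donor agree, product wrong: still a reaction match
        entries = [atomic("p1", "E1", "a", "d", "WRONG")]
        hqd = hqd_frame([("E1", "a", "d", "pr", "p1")])
        reaction, substrate = reaction_substrate_pr(
            [GradeRecord(e, "correct") for e in entries], hqd
        )
        assert reaction.precision == 1.0
        # substrate level judges each mention independently: 2 of 3 correct
        assert substrate.precision == pytest.approx(2 / 3)

    def test_agrees_with_exhaustive_oracle_on_random_instances(self):
        rng = random.Random(23)
        compounds = ["c1", "c2", "c3", "c4"]
        for _ in range(40):
            n_e, n_r = rng.randint(1, 5), rng.randint(1, 5)
            entries = [
                atomic("p1", f"E{i}", rng.choice(compounds), rng.choice(compounds),
                       rng.choice(compounds))
                for i in range(n_e)
            ]
            rows = [
                (f"E{i}", rng.choice(compounds), rng.choice(compounds),
                 rng.choice(compounds), "p1")
                for i in range(n_r)
            ]
            hqd = hqd_frame(rows)
            reaction, _ = reaction_substrate_pr(
                [GradeRecord(e, "correct") for e in entries], hqd
            )
            oracle = exhaustive_matching_oracle(
                entries, [(r[1].lower(), r[2].lower(), r[3].lower()) for r in rows]
            )
            assert reaction.counts["matched"] == oracle

    def test_unknown_correct_excluded_by_default(self):
        entries = [atomic("p1", "E1", "a", "d", "pr")]
        novel = atomic("p1", "E9", "x", "y", "z")
        hqd = hqd_frame([("E1", "a", "d", "pr", "p1")])
        grades = [GradeRecord(entries[0], "correct"), GradeRecord(novel, "unknown_correct")]
        reaction, _ = reaction_substrate_pr(grades, hqd)
        assert reaction.precision == 1.0  # novel entry not penalized
        assert reaction.counts["entries"] == 1

    def test_augmented_regrading_raises_both_metrics(self):
        """Appending unknown-correct activities to the HQD ('+' mode) must
        raise precision and recall relative to silently dropping them."""
        entries = [
            atomic("p1", "E1", "a", "d", "pr"),
            atomic("p1", "E2", "b", "WRONG-DONOR", "MISS"),
        ]
        novel = atomic("p1", "E9", "x", "y", "z")
        hqd = hqd_frame(
            [("E1", "a", "d", "pr", "p1"), ("E2", "b", "d", "qr", "p1"),
             ("E3", "k", "l", "m", "p1")]
        )
        grades = [
            GradeRecord(entries[0], "correct"),
            GradeRecord(entries[1], "incorrect"),
            GradeRecord(novel, "unknown_correct"),
        ]
        base_r, base_s = reaction_substrate_pr(grades, hqd)
        plus_r, plus_s = reaction_substrate_pr(grades, hqd, augment_unknown=True)
        assert plus_r.precision > base_r.precision
        assert plus_r.recall > base_r.recall
        assert plus_s.precision > base_s.precision
        assert plus_s.recall > base_s.recall

    def test_monotonicity_under_planted_perturbations(self):
        hqd = hqd_frame(
            [("E1", "a", "d", "pr", "p1"), ("E2", "b", "d", "qr", "p1")]
        )
        good = atomic("p1", "E1", "a", "d", "pr")
        base = [GradeRecord(good, "correct")]
        base_r, _ = reaction_substrate_pr(base, hqd)
        # adding a correct entry never decreases recall
        more_correct = base + [GradeRecord(atomic("p1", "E2", "b", "d", "qr"), "correct")]
        more_r, _ = reaction_substrate_pr(more_correct, hqd)
        assert more_r.recall >= base_r.recall
        # adding an incorrect entry never increases precision
        with_bad = base + [GradeRecord(atomic("p1", "E7", "x", "y", "z"), "incorrect")]
        bad_r, _ = reaction_substrate_pr(with_bad, hqd)
        assert bad_r.precision <= base_r.precision

    def test_empty_hqd_slice_reports_undefined_recall(self):
        entries = [atomic("p9", "E1", "a", "d", "pr")]
        hqd = hqd_frame([("E1", "a", "d", "pr", "OTHER")])
        reaction, substrate = reaction_substrate_pr(
            [GradeRecord(e, "correct") for e in entries], hqd
        )
        assert reaction.recall is None
        assert substrate.recall is None


class TestCurationGap:
    def test_reviewed_and_catalytic_fractions(self):
        ids = [f"ID{i}" for i in range(187)]
        report = curation_gap(
            ids,
            reviewed_ids=set(ids[:49]),
            rhea_ids=set(ids[:44]),
        )
        assert report.n_unique_ids == 187
        assert round(report.reviewed_pct, 1) == 26.2
        assert round(report.catalytic_pct, 1) == 23.5

    def test_gap_with_missed_catalogued_ids(self):
        ids = [f"ID{i}" for i in range(187)]
        report = curation_gap(
            ids,
            reviewed_ids=set(ids[:49]),
            rhea_ids=set(ids[:44]),
            missed_catalogued_ids={f"MISS{i}" for i in range(20)},
        )
        assert round(report.gap_pct, 1) == 69.1

    def test_fully_annotated_set_has_zero_gap(self):
        ids = {"A1", "A2", "A3"}
        report = curation_gap(ids, reviewed_ids=ids, rhea_ids=set(ids))
        assert report.gap_pct == 0.0


class TestBenchmarkPrompts:
    def test_strictness_tradeoff_on_planted_corpus(self):
        spec = CorpusSpec(
            n_positive=20, n_negative=20,
            families=("BAHD acyltransferase",),
            marker_dropout=0.3, keyword_bait_rate=0.3, seed=17,
        )
        records, truth = make_testset(spec)
        labels = {row["pmid"]: bool(row["label"]) for _, row in truth.iterrows()}
        grid = benchmark_prompts(
            records, labels,
            [load_template("q1"), load_template("q11")],
            [0.1, 0.5], MockBackend(), "BAHD acyltransferase",
        )
        assert len(grid) == 4
        strict = grid[grid.template_id == "q1"].iloc[0]
        loose = grid[grid.template_id == "q11"].iloc[0]
        assert strict.precision >= loose.precision
        assert loose.recall >= strict.recall
        assert grid.failures.sum() == 0

    def test_single_cell_equals_confusion_metrics(self):
        spec = CorpusSpec(
            n_positive=5, n_negative=5, families=("BAHD acyltransferase",), seed=3
        )
        records, truth = make_testset(spec)
        labels = {row["pmid"]: bool(row["label"]) for _, row in truth.iterrows()}
        grid = benchmark_prompts(
            records, labels, [load_template("q11")], [0.5],
            MockBackend(), "BAHD acyltransferase",
        )
        assert len(grid) == 1
        cell = grid.iloc[0]
        report = confusion_metrics(
            ConfusionCounts(tp=cell.tp, fp=cell.fp, tn=cell.tn, fn=cell.fn)
        )
        assert cell.precision == report.precision
        assert cell.recall == report.recall

    def test_empty_template_list_gives_empty_grid(self):
        grid = benchmark_prompts(
            [], {}, [], [0.5], MockBackend(), "BAHD acyltransferase"
        )
        assert grid.empty


def test_family_id_hit_summary_totals():
    frame = pd.DataFrame(
        [
            {"family": "fam A", "extracted_entries": 100, "id_hits": 58},
            {"family": "fam B", "extracted_entries": 200, "id_hits": 90},
        ]
    )
    out = family_id_hit_summary(frame)
    total = out[out.family == "Total"].iloc[0]
    assert total.extracted_entries == 300
    assert total.id_hits == 148
    assert total.no_id == 152
    assert total.pct_with_id == pytest.approx((58.0 + 45.0) / 2)
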
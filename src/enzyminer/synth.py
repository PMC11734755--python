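"""Deterministic synthetic corpora with complete ground-truth bookkeeping.

Everything the pipeline consumes — abstracts, manuscripts (plain text and
minimal PDFs), lineage and ID-mapping tables, a high-quality comparison
table — can be generated offline as a pure function of a
:class:`CorpusSpec` and its seed.  Planted error modes mirror the failure
taxonomy seen in live extraction runs:

* nontarget *decoys*: activities attributed to the queried family whose
  enzyme names belong to another family (glycosyltransferases,
  O-methyltransferases, ...);
* *hallucination traps*: activities listing a biomedical species (human,
  mouse, rat) under a plant-titled paper;
* *heterologous hosts*: activities listing the expression host
  (E. coli, yeast) instead of the source plant;
* *split-donor* layout: the acyl donor stated in a methods paragraph away
  from the acceptor/product discussion, stressing incomplete-donor
  handling.

Category counts are exact (``round(rate * n)``), never Bernoulli draws, so
downstream flag fractions can be checked for equality, not approximation.
"""

from __future__ import annotations

import dataclasses
import random
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .corpus import PaperRecord
from .pdfio import write_minimal_pdf
from .sentinel import PlantedActivity, format_donor_sentence, format_sentence

__all__ = [
    "CorpusSpec",
    "Manuscript",
    "PlantedTruth",
    "CorpusBundle",
    "make_testset",
    "make_manuscript",
    "make_reference_tables",
    "make_corpus",
    "hqd_from_truth",
    "STUDY_FAMILIES",
]

# the five families used for screening validation
STUDY_FAMILIES = (
    "BAHD acyltransferase",
    "cytochrome P450",
    "O-methyltransferase",
    "UDP-glycosyltransferase",
    "peroxidase",
)

_PLANT_SPECIES = [
    ("Arabidopsis thaliana", "Brassicaceae"),
    ("Solanum lycopersicum", "Solanaceae"),
    ("Oryza sativa", "Poaceae"),
    ("Nicotiana tabacum", "Solanaceae"),
    ("Medicago truncatula", "Fabaceae"),
    ("Vitis vinifera", "Vitaceae"),
    ("Zea mays", "Poaceae"),
    ("Glycine max", "Fabaceae"),
    ("Populus trichocarpa", "Salicaceae"),
    ("Coffea canephora", "Rubiaceae"),
]

_UNKNOWN_SPECIES = ["Planthus obscurus", "Herbaceum ignotum", "Folium incertum"]

_BIOMEDICAL_SPECIES = ["Homo sapiens", "Mus musculus", "Rattus norvegicus"]
_HOST_SPECIES = ["Escherichia coli", "Saccharomyces cerevisiae"]

_OTHER_LINEAGE = {
    "Escherichia coli": ("Enterobacteriaceae", "Bacteria"),
    "Saccharomyces cerevisiae": ("Saccharomycetaceae", "Fungi"),
    "Homo sapiens": ("Hominidae", "Metazoa"),
    "Mus musculus": ("Muridae", "Metazoa"),
    "Rattus norvegicus": ("Muridae", "Metazoa"),
}

# target-family enzyme name stems: every name matches the family's target
# lexicon patterns
_TARGET_ENZYMES = {
    "BAHD acyltransferase": [
        "hydroxycinnamoyl-CoA quinate acyltransferase",
        "spermidine hydroxycinnamoyl transferase",
        "anthocyanin acyltransferase",
        "malonyl-CoA acyl transferase",
        "shikimate hydroxycinnamoyl transferase",
    ],
    "cytochrome P450": [
        "cytochrome P450 monooxygenase",
        "ferulate 5-hydroxylase cytochrome P450",
    ],
    "O-methyltransferase": [
        "caffeic acid O-methyltransferase",
        "flavonoid O-methyltransferase",
    ],
    "UDP-glycosyltransferase": [
        "UDP-glycosyltransferase",
        "anthocyanidin glucosyltransferase",
    ],
    "peroxidase": ["class III peroxidase", "cationic peroxidase"],
}

# decoy names: match a nontarget pattern of the BAHD lexicon and no target
# pattern, emulating other-family contamination under a target-family query
_DECOY_ENZYMES = [
    "UDP-glycosyltransferase 71C1",
    "caffeic acid O-methyltransferase 1",
    "cytochrome P450 98A3",
    "4-coumarate:CoA ligase 2",
    "chalcone synthase 3",
    "anthocyanidin dioxygenase 1",
]

_ACCEPTORS = [
    "quinic acid",
    "shikimic acid",
    "anthocyanin 3-O-glucoside",
    "spermidine",
    "quercetin",
    "kaempferol",
    "caffeic acid",
    "cyanidin 3-O-glucoside",
    "putrescine",
    "tyramine",
]

_DONORS = [
    "coumaroyl-CoA",
    "caffeoyl-CoA",
    "feruloyl-CoA",
    "malonyl-CoA",
    "acetyl-CoA",
    "aiC4",
    "iC5",
    "aiC5",
]

_PRODUCTS = [
    "chlorogenic acid",
    "coumaroyl shikimate",
    "feruloyl putrescine",
    "coumaroyl spermidine",
    "malonylated anthocyanin",
    "caffeoyl spermidine",
    "acylated quercetin glycoside",
    "feruloyl tyramine",
]

_JOURNALS = [
    "Plant Cell",
    "Plant Journal",
    "Journal of Biological Chemistry",
    "Phytochemistry",
    "Planta",
]

_NEGATIVE_TOPICS = [
    "root architecture under drought stress",
    "photoperiodic control of flowering time",
    "stomatal development signaling",
    "seed dormancy regulation",
    "leaf senescence transcription networks",
]


@dataclass(frozen=True)
class CorpusSpec:
    """Study conditions for one synthetic corpus; generation is a pure
    function of this object (the seed lives inside it)."""

    n_positive: int
    n_negative: int
    families: tuple[str, ...] = STUDY_FAMILIES
    decoy_rate: float = 0.0
    hallucination_rate: float = 0.0
    heterologous_rate: float = 0.0
    unknown_species_rate: float = 0.0
    split_donor_rate: float = 0.0
    marker_dropout: float = 0.0
    keyword_bait_rate: float = 0.0
    sentinel_noise_rate: float = 0.0
    mappable_fraction: float = 0.58
    seed: int = 1

    def __post_init__(self) -> None:
        for name in (
            "decoy_rate",
            "hallucination_rate",
            "heterologous_rate",
            "unknown_species_rate",
            "split_donor_rate",
            "marker_dropout",
            "keyword_bait_rate",
            "sentinel_noise_rate",
            "mappable_fraction",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_positive < 0 or self.n_negative < 0:
            raise ValueError("corpus sizes must be non-negative")


def _exact_subset(n: int, rate: float, rng: random.Random) -> set[int]:
    """Indices of an exactly round(rate*n)-sized random subset of range(n)."""
    k = round(rate * n)
    return set(rng.sample(range(n), k)) if k else set()


# ---------------------------------------------------------------------------
# screening test set


def make_testset(spec: CorpusSpec) -> tuple[list[PaperRecord], pd.DataFrame]:
    """Balanced positive/negative abstracts with a planted-label truth table.

    Positives carry a sentinel assay sentence for their family (balanced
    round-robin within +/-1 across families); ``marker_dropout`` positives
    mention the family only in prose; ``keyword_bait_rate`` negatives
    mention a family name without any assay; ``sentinel_noise_rate`` flips
    sentinel presence against the true label on both sides, so screening
    confusion counts can be predicted exactly from the truth table.
    """
    rng = random.Random(spec.seed)
    records: list[PaperRecord] = []
    truth_rows: list[dict] = []

    pos_dropout = _exact_subset(spec.n_positive, spec.marker_dropout, rng)
    pos_noise = _exact_subset(spec.n_positive, spec.sentinel_noise_rate, rng)
    neg_bait = _exact_subset(spec.n_negative, spec.keyword_bait_rate, rng)
    neg_noise = _exact_subset(spec.n_negative, spec.sentinel_noise_rate, rng)

    for i in range(spec.n_positive):
        family = spec.families[i % len(spec.families)]
        species, _fam = _PLANT_SPECIES[i % len(_PLANT_SPECIES)]
        enzyme = _TARGET_ENZYMES[family][i % len(_TARGET_ENZYMES[family])]
        activity = PlantedActivity(
            family=family,
            enzyme_name=enzyme,
            abbrev=f"EN{i:03d}",
            species=species,
            acceptors=[_ACCEPTORS[i % len(_ACCEPTORS)]],
            donors=[_DONORS[i % len(_DONORS)]],
            products=[_PRODUCTS[i % len(_PRODUCTS)]],
        )
        pmid = f"9{i:07d}"
        title = f"Characterization of a {family} from {species}"
        has_marker = i not in pos_dropout
        has_keyword = True
        if i in pos_noise:
            # noise flips a positive to look negative: no sentinel, no
            # family mention anywhere (title included)
            has_marker = False
            has_keyword = False
            title = f"Gene expression atlas of {species} tissues"
        if has_marker:
            abstract = (
                f"We report the purification of {enzyme} from {species}. "
                f"{format_sentence(activity)} Kinetic analysis supported a "
                "ping-pong mechanism."
            )
        elif has_keyword:
            abstract = (
                f"We characterized a {family} enzyme from {species}; the "
                "assay details are reported in the main text."
            )
        else:
            abstract = (
                f"Transcriptomic profiling of {species} tissues revealed "
                "expression dynamics during development."
            )
        records.append(
            PaperRecord(
                pmid=pmid,
                doi=f"10.1000/syn.{pmid}",
                title=title,
                abstract=abstract,
                journal=_JOURNALS[i % len(_JOURNALS)],
                year=2000 + i % 20,
                article_types=["Journal Article"],
                mesh_keywords=["enzyme assay", "plant metabolism"],
            )
        )
        truth_rows.append(
            {
                "pmid": pmid,
                "label": True,
                "family": family,
                "has_marker": has_marker,
                "has_keyword": has_keyword,
            }
        )

    for j in range(spec.n_negative):
        family = spec.families[j % len(spec.families)]
        species, _fam = _PLANT_SPECIES[(j + 3) % len(_PLANT_SPECIES)]
        topic = _NEGATIVE_TOPICS[j % len(_NEGATIVE_TOPICS)]
        pmid = f"8{j:07d}"
        has_marker = False
        has_keyword = j in neg_bait
        if j in neg_noise:
            # noise flips a negative to look positive: plant a sentinel
            has_marker = True
        if has_marker:
            noise_activity = PlantedActivity(
                family=family,
                enzyme_name=_TARGET_ENZYMES[family][0],
                species=species,
                acceptors=[_ACCEPTORS[j % len(_ACCEPTORS)]],
                donors=[_DONORS[j % len(_DONORS)]],
                products=[_PRODUCTS[j % len(_PRODUCTS)]],
            )
            abstract = (
                f"A study of {topic} in {species}. "
                f"{format_sentence(noise_activity)}"
            )
        elif has_keyword:
            abstract = (
                f"A review-adjacent discussion of {topic} in {species}, "
                f"mentioning {family} genes among differentially expressed loci."
            )
        else:
            abstract = f"A study of {topic} in {species} using field trials."
        records.append(
            PaperRecord(
                pmid=pmid,
                doi=f"10.1000/syn.{pmid}",
                title=f"Insights into {topic} in {species}",
                abstract=abstract,
                journal=_JOURNALS[j % len(_JOURNALS)],
                year=2000 + j % 20,
                article_types=["Journal Article"],
                mesh_keywords=["plant development"],
            )
        )
        truth_rows.append(
            {
                "pmid": pmid,
                "label": False,
                "family": family,
                "has_marker": has_marker,
                "has_keyword": has_keyword,
            }
        )

    truth = pd.DataFrame(
        truth_rows, columns=["pmid", "label", "family", "has_marker", "has_keyword"]
    )
    return records, truth


# ---------------------------------------------------------------------------
# manuscripts


@dataclass
class Manuscript:
    pmid: str
    title: str
    text: str
    activities: list[PlantedActivity]

    def write_pdf(self, path: str | Path, columns: int = 1) -> Path:
        return write_minimal_pdf(self.text, path, columns=columns)


def make_manuscript(
    activities: list[PlantedActivity],
    title: str = "Characterization of plant enzymes",
    pmid: str = "0000000",
    host_mention: bool = False,
) -> Manuscript:
    """Embed one sentinel sentence per activity inside realistic prose.

    Split-donor activities put their donor sentence in the methods
    paragraph, away from the results discussion.  ``host_mention`` adds a
    heterologous-expression sentence without planting a host activity.
    """
    intro = (
        "Specialized metabolism in plants relies on large enzyme families "
        "whose members display broad substrate ranges. Here we combine "
        "recombinant protein expression with in vitro assays to resolve "
        "individual activities."
    )
    methods_lines = [
        "Recombinant proteins were purified by affinity chromatography and "
        "assayed at 30 C in phosphate buffer."
    ]
    if host_mention:
        methods_lines.append(
            "All constructs were heterologously expressed in Escherichia coli "
            "BL21 cells prior to purification."
        )
    results_lines = []
    for activity in activities:
        results_lines.append(format_sentence(activity))
        if activity.split_donor and activity.donors:
            methods_lines.append(format_donor_sentence(activity))
    text = "\n".join(
        [
            title,
            "",
            "Introduction",
            intro,
            "",
            "Results",
            *results_lines,
            "",
            "Methods",
            *methods_lines,
            "",
            "References",
            "1. Prior work on plant specialized metabolism.",
        ]
    )
    return Manuscript(pmid=pmid, title=title, text=text, activities=activities)


# ---------------------------------------------------------------------------
# reference tables


def make_reference_tables(
    activities: list[PlantedActivity],
    mappable_fraction: float,
    seed: int = 1,
    n_distractors: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame, list[bool]]:
    """Lineage + ID-mapping tables covering the planted activities.

    Exactly ``round(mappable_fraction * n)`` activities get an ID-mapping
    row; the returned bookkeeping list marks which.  Distractor rows are
    appended to both tables so lookups are never trivially exhaustive.
    """
    rng = random.Random(seed)
    lineage_rows = {s: fam for s, fam in _PLANT_SPECIES}
    lineage = [
        {"species": s, "family": fam, "kingdom": "Viridiplantae"}
        for s, fam in lineage_rows.items()
    ]
    lineage += [
        {"species": s, "family": fam, "kingdom": kingdom}
        for s, (fam, kingdom) in _OTHER_LINEAGE.items()
    ]

    mappable_idx = _exact_subset(len(activities), mappable_fraction, rng)
    idmap_rows = []
    bookkeeping = []
    for i, activity in enumerate(activities):
        mappable = i in mappable_idx
        bookkeeping.append(mappable)
        if not mappable:
            continue
        accession = f"Q{rng.randint(0, 9)}{''.join(rng.choices('ABCDEFGHIJ', k=2))}{rng.randint(0, 9)}{rng.randint(0, 9)}{rng.randint(0, 9)}"
        if activity.sequence_ids:
            idmap_rows.append(
                {
                    "foreign_id": activity.sequence_ids[0],
                    "scheme": "genbank",
                    "uniprot_accession": accession,
                    "species": activity.species,
                }
            )
        else:
            idmap_rows.append(
                {
                    "foreign_id": activity.enzyme_name.lower(),
                    "scheme": "name",
                    "uniprot_accession": accession,
                    "species": activity.species,
                }
            )
    for d in range(n_distractors):
        idmap_rows.append(
            {
                "foreign_id": f"ZZ{900000 + d}",
                "scheme": "genbank",
                "uniprot_accession": f"P{80000 + d}",
                "species": "Arabidopsis thaliana",
            }
        )
    idmap = pd.DataFrame(
        idmap_rows, columns=["foreign_id", "scheme", "uniprot_accession", "species"]
    )
    return pd.DataFrame(lineage), idmap, bookkeeping


# ---------------------------------------------------------------------------
# full corpus with manuscripts


@dataclass
class PlantedTruth:
    pmid: str
    activity: PlantedActivity
    category: str  # target | decoy | hallucination | host
    species_known: bool
    mappable: bool


@dataclass
class CorpusBundle:
    spec: CorpusSpec
    family: str
    records: list[PaperRecord]
    screen_truth: pd.DataFrame
    manuscripts: dict[str, Manuscript]
    truth: list[PlantedTruth]
    lineage: pd.DataFrame
    idmap: pd.DataFrame
    hqd: pd.DataFrame

    def write_pdfs(self, directory: str | Path) -> dict[str, Path]:
        """Zotero-storage layout: one subdirectory per item."""
        directory = Path(directory)
        paths = {}
        for pmid, ms in self.manuscripts.items():
            item_dir = directory / f"ITEM{pmid}"
            item_dir.mkdir(parents=True, exist_ok=True)
            paths[pmid] = ms.write_pdf(item_dir / f"{pmid}.pdf")
        return paths


def make_corpus(spec: CorpusSpec, family: str | None = None) -> CorpusBundle:
    """End-to-end corpus: positive papers carry manuscripts whose planted
    activities include the requested exact decoy/hallucination/host
    fractions.

    All sentinels carry the queried family label (decoys keep their
    other-family enzyme *names*), emulating the dominant live error mode:
    nontarget enzymes attributed to the target query.
    """
    family = family or spec.families[0]
    # the end-to-end corpus targets one family: all positives belong to it
    single = dataclasses.replace(spec, families=(family,))
    records, screen_truth = make_testset(single)
    rng = random.Random(spec.seed + 7)

    positives = [r for r in records if r.pmid.startswith("9")]
    # one activity per planted slot; 1-3 slots per paper
    slots: list[str] = []
    for r in positives:
        slots.extend([r.pmid] * rng.choice([1, 2, 3]))

    n = len(slots)
    order = list(range(n))
    rng.shuffle(order)
    n_decoy = round(spec.decoy_rate * n)
    n_hall = round(spec.hallucination_rate * n)
    n_host = round(spec.heterologous_rate * n)
    decoy_idx = set(order[:n_decoy])
    hall_idx = set(order[n_decoy : n_decoy + n_hall])
    host_idx = set(order[n_decoy + n_hall : n_decoy + n_hall + n_host])
    remainder = order[n_decoy + n_hall + n_host :]
    n_unknown = round(spec.unknown_species_rate * len(remainder))
    unknown_idx = set(remainder[:n_unknown])
    split_idx = _exact_subset(n, spec.split_donor_rate, random.Random(spec.seed + 11))

    target_names = _TARGET_ENZYMES.get(family, _TARGET_ENZYMES[STUDY_FAMILIES[0]])
    truth: list[PlantedTruth] = []
    activities: list[PlantedActivity] = []
    for i, pmid in enumerate(slots):
        if i in decoy_idx:
            category = "decoy"
            enzyme = _DECOY_ENZYMES[i % len(_DECOY_ENZYMES)]
            species = _PLANT_SPECIES[i % len(_PLANT_SPECIES)][0]
        elif i in hall_idx:
            category = "hallucination"
            enzyme = target_names[i % len(target_names)]
            species = _BIOMEDICAL_SPECIES[i % len(_BIOMEDICAL_SPECIES)]
        elif i in host_idx:
            category = "host"
            enzyme = target_names[i % len(target_names)]
            species = _HOST_SPECIES[i % len(_HOST_SPECIES)]
        else:
            category = "target"
            enzyme = target_names[i % len(target_names)]
            if i in unknown_idx:
                species = _UNKNOWN_SPECIES[i % len(_UNKNOWN_SPECIES)]
            else:
                species = _PLANT_SPECIES[i % len(_PLANT_SPECIES)][0]
        activity = PlantedActivity(
            family=family,
            enzyme_name=enzyme,
            abbrev=f"ENZ{i:04d}",
            species=species,
            sequence_ids=[f"AB{100000 + i:06d}"],
            acceptors=[_ACCEPTORS[i % len(_ACCEPTORS)]],
            donors=[_DONORS[i % len(_DONORS)]],
            products=[_PRODUCTS[i % len(_PRODUCTS)]],
            split_donor=i in split_idx,
        )
        activities.append(activity)
        truth.append(
            PlantedTruth(
                pmid=pmid,
                activity=activity,
                category=category,
                species_known=category != "target" or i not in unknown_idx,
                mappable=False,  # filled below
            )
        )

    lineage, idmap, mappable = make_reference_tables(
        activities, spec.mappable_fraction, seed=spec.seed + 13
    )
    for t, m in zip(truth, mappable):
        t.mappable = m

    manuscripts: dict[str, Manuscript] = {}
    for r in positives:
        paper_acts = [t.activity for t in truth if t.pmid == r.pmid]
        manuscripts[r.pmid] = make_manuscript(
            paper_acts,
            title=r.title,
            pmid=r.pmid,
            host_mention=any(
                t.category == "host" for t in truth if t.pmid == r.pmid
            ),
        )

    hqd = hqd_from_truth(truth)
    return CorpusBundle(
        spec=spec,
        family=family,
        records=records,
        screen_truth=screen_truth,
        manuscripts=manuscripts,
        truth=truth,
        lineage=lineage,
        idmap=idmap,
        hqd=hqd,
    )


def hqd_from_truth(truth: list[PlantedTruth]) -> pd.DataFrame:
    """High-quality comparison table from the planted target activities."""
    rows = []
    for t in truth:
        if t.category != "target":
            continue
        a = t.activity
        for i in range(max(len(a.acceptors), len(a.products), 1)):
            rows.append(
                {
                    "enzyme": a.enzyme_name,
                    "species": a.species,
                    "accession": a.sequence_ids[0] if a.sequence_ids else "",
                    "acceptor": a.acceptors[i] if i < len(a.acceptors) else "",
                    "donor": a.donors[min(i, len(a.donors) - 1)] if a.donors else "",
                    "product": a.products[i] if i < len(a.products) else "",
                    "reference": t.pmid,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["enzyme", "species", "accession", "acceptor", "donor", "product", "reference"],
    )
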
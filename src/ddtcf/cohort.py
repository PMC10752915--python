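"""Study-cohort table: loading, validation, filters and descriptive counts.

The cohort is a table of pediatric low-grade glioma (pLGG) samples — one row
per surgical sample — carrying the clinical and molecular features that drive
the downstream analyses: patient sex and age, histological diagnosis, tumor
localization, DNA-methylation classification, and the MAPK pathway alteration
with its detection method.

Only samples whose alteration is detectable by one of the two droplet-digital
PCR assays (the BRAF exon-14 duplication duplex, which covers both
KIAA1549:BRAF fusions and plain BRAF duplications, and the BRAF V600E
mutation duplex) can be followed longitudinally in culture; the rest are
"non-trackable".
"""

from __future__ import annotations

import csv
import enum
import math
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .errors import SchemaError, ValidationError
from .stats import FiveNumberSummary, five_number_summary

__all__ = [
    "Alteration",
    "Sex",
    "NOT_DONE",
    "NOT_CLASSIFIABLE",
    "CohortRecord",
    "CohortSummary",
    "COHORT_COLUMNS",
    "LOCALIZATION_GROUPS",
    "TRACKABLE_ALTERATIONS",
    "read_cohort",
    "write_cohort",
    "load_reference_cohort",
    "count_by_alteration",
    "count_ddpcr_trackable",
    "summarize_cohort",
]


class Sex(str, enum.Enum):
    F = "F"
    M = "M"


class Alteration(str, enum.Enum):
    """MAPK alteration categories observed in the cohort."""

    KIAA1549_BRAF_FUSION = "KIAA1549_BRAF_FUSION"
    BRAF_V600E = "BRAF_V600E"
    BRAF_DUPLICATION = "BRAF_DUPLICATION"
    BRAF_599TT_INS = "BRAF_599TT_INS"
    COPC_ROS1_FUSION = "COPC_ROS1_FUSION"
    PRKAR2B_BRAF_FUSION = "PRKAR2B_BRAF_FUSION"
    OTHER = "OTHER"


#: Sentinels for the methylation-class column.
NOT_DONE = "NOT_DONE"
NOT_CLASSIFIABLE = "NOT_CLASSIFIABLE"

#: Alterations the two ddPCR assays can follow: the exon-14/exon-3 duplex
#: detects the copy gain shared by KIAA1549:BRAF fusions and BRAF
#: duplications; the mutation duplex detects V600E.
TRACKABLE_ALTERATIONS = frozenset(
    {
        Alteration.KIAA1549_BRAF_FUSION,
        Alteration.BRAF_DUPLICATION,
        Alteration.BRAF_V600E,
    }
)

#: Anatomical grouping used for supra-/infratentorial summaries.  The
#: spinal compartment is neither and is reported as its own "other" bucket.
LOCALIZATION_GROUPS: Mapping[str, str] = {
    "posterior fossa": "infratentorial",
    "cerebellum": "infratentorial",
    "brain stem": "infratentorial",
    "midbrain": "infratentorial",
    "parietooccipital": "supratentorial",
    "parieto-occipital": "supratentorial",
    "left temporal": "supratentorial",
    "temporal": "supratentorial",
    "optic pathway": "supratentorial",
    "spinal": "other",
}

COHORT_COLUMNS = (
    "sample_id",
    "sex",
    "age_years",
    "histology",
    "localization",
    "methylation_class",
    "classifier_score",
    "alteration",
    "detection_method",
)

# Normalized (lower-case, punctuation-stripped) alteration spellings.
_ALTERATION_PATTERNS = {
    "kiaa1549 braf fusion": Alteration.KIAA1549_BRAF_FUSION,
    "kiaa1549 braf": Alteration.KIAA1549_BRAF_FUSION,
    "braf v600e mutation": Alteration.BRAF_V600E,
    "braf v600e": Alteration.BRAF_V600E,
    "v600e": Alteration.BRAF_V600E,
    "braf duplication": Alteration.BRAF_DUPLICATION,
    "braf 599tt insertion": Alteration.BRAF_599TT_INS,
    "braf 599tt ins": Alteration.BRAF_599TT_INS,
    "copc ros1 fusion": Alteration.COPC_ROS1_FUSION,
    "copc ros1": Alteration.COPC_ROS1_FUSION,
    "prkar2b braf fusion": Alteration.PRKAR2B_BRAF_FUSION,
    "prkar2b braf": Alteration.PRKAR2B_BRAF_FUSION,
    "other": Alteration.OTHER,
}


def _normalize_alteration(raw: str) -> Alteration:
    if raw.strip().upper() in Alteration.__members__:
        return Alteration[raw.strip().upper()]
    key = re.sub(r"[^a-z0-9]+", " ", raw.lower()).strip()
    try:
        return _ALTERATION_PATTERNS[key]
    except KeyError:
        raise ValidationError(f"unrecognized alteration string: {raw!r}") from None


def _normalize_methylation(raw: str) -> str:
    key = re.sub(r"[^a-z]+", " ", raw.lower()).strip()
    if key in {"not done", "nd", "none", ""} or raw.strip().upper() == NOT_DONE:
        return NOT_DONE
    if key == "not classifiable" or raw.strip().upper() == NOT_CLASSIFIABLE:
        return NOT_CLASSIFIABLE
    return raw.strip()


@dataclass(frozen=True)
class CohortRecord:
    """One cohort row: clinical and molecular features of a single sample."""

    sample_id: str
    sex: Sex
    age_years: float
    histology: str
    localization: str
    methylation_class: str
    classifier_score: Optional[float]
    alteration: Alteration
    detection_method: str = ""

    def __post_init__(self) -> None:
        if self.age_years < 0 or not math.isfinite(self.age_years):
            raise ValidationError(
                f"{self.sample_id}: age_years must be a finite non-negative "
                f"number, got {self.age_years}"
            )
        if self.classifier_score is not None and not 0.0 <= self.classifier_score <= 1.0:
            raise ValidationError(
                f"{self.sample_id}: classifier_score must lie in [0, 1], "
                f"got {self.classifier_score}"
            )

    @property
    def methylation_done(self) -> bool:
        return self.methylation_class != NOT_DONE

    @property
    def methylation_classified(self) -> bool:
        return self.methylation_class not in (NOT_DONE, NOT_CLASSIFIABLE)

    @property
    def ddpcr_trackable(self) -> bool:
        return self.alteration in TRACKABLE_ALTERATIONS

    @property
    def localization_group(self) -> str:
        return LOCALIZATION_GROUPS.get(self.localization.strip().lower(), "other")


@dataclass(frozen=True)
class CohortSummary:
    """Descriptive counts over a cohort (the Table-1-style summary)."""

    n: int
    counts_by_alteration: Mapping[Alteration, int]
    counts_by_sex: Mapping[Sex, int]
    counts_by_localization_group: Mapping[str, int]
    age_summary: FiveNumberSummary
    n_methylation_done: int
    n_methylation_classified: int
    n_ddpcr_trackable: int
    n_histology_pa: int = 0


def read_cohort(path: str | Path, dialect: str = "TSV") -> list[CohortRecord]:
    """Parse a cohort table into validated records.

    Parameters
    ----------
    path:
        TSV/CSV file whose header must match :data:`COHORT_COLUMNS` exactly.
    dialect:
        ``"TSV"`` (tab-separated, the packaged reference table) or ``"CSV"``.

    Raises
    ------
    SchemaError
        If a required column is missing from the header.
    ValidationError
        If a row carries an unparseable age/score, an unknown alteration, or
        a duplicated sample_id (the error names the offending sample).
    """
    delim = {"TSV": "\t", "CSV": ","}.get(dialect.upper())
    if delim is None:
        raise ValidationError(f"dialect must be TSV or CSV, got {dialect!r}")
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        for col in COHORT_COLUMNS:
            if col not in header:
                raise SchemaError(f"{path.name}: missing required column {col!r}")
        records: list[CohortRecord] = []
        seen: set[str] = set()
        for row in reader:
            sid = (row["sample_id"] or "").strip()
            if sid in seen:
                raise ValidationError(f"duplicate sample_id {sid!r}")
            seen.add(sid)
            try:
                sex = Sex(row["sex"].strip().upper())
            except ValueError:
                raise ValidationError(f"{sid}: invalid sex {row['sex']!r}") from None
            try:
                age = float(row["age_years"])
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{sid}: unparseable age_years {row['age_years']!r}"
                ) from None
            raw_score = (row["classifier_score"] or "").strip()
            if raw_score in ("", "NA", "NaN", "nan"):
                score = None
            else:
                try:
                    score = float(raw_score)
                except ValueError:
                    raise ValidationError(
                        f"{sid}: unparseable classifier_score {raw_score!r}"
                    ) from None
            records.append(
                CohortRecord(
                    sample_id=sid,
                    sex=sex,
                    age_years=age,
                    histology=row["histology"].strip(),
                    localization=row["localization"].strip(),
                    methylation_class=_normalize_methylation(row["methylation_class"]),
                    classifier_score=score,
                    alteration=_normalize_alteration(row["alteration"]),
                    detection_method=(row.get("detection_method") or "").strip(),
                )
            )
    return records


def write_cohort(records: Iterable[CohortRecord], path: str | Path, dialect: str = "TSV") -> None:
    """Serialize records back to the documented schema (round-trip safe)."""
    delim = {"TSV": "\t", "CSV": ","}[dialect.upper()]
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(COHORT_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.sample_id,
                    r.sex.value,
                    f"{r.age_years:g}",
                    r.histology,
                    r.localization,
                    r.methylation_class,
                    "NA" if r.classifier_score is None else f"{r.classifier_score:g}",
                    r.alteration.value,
                    r.detection_method,
                ]
            )


def load_reference_cohort() -> list[CohortRecord]:
    """Load the packaged 18-sample pLGG reference cohort table."""
    ref = resources.files("ddtcf").joinpath("data/cohort_table1.tsv")
    with resources.as_file(ref) as path:
        return read_cohort(path, dialect="TSV")


def count_by_alteration(records: Sequence[CohortRecord], target: Alteration) -> int:
    """Number of samples carrying the given MAPK alteration."""
    return sum(1 for r in records if r.alteration is target)


def count_ddpcr_trackable(records: Sequence[CohortRecord]) -> int:
    """Number of samples followable by either ddPCR assay.

    The exon-14 duplication duplex detects KIAA1549:BRAF fusions and BRAF
    duplications (both present an exon-14 copy gain); the mutation duplex
    detects BRAF V600E.  Everything else cannot be monitored in culture.
    """
    return sum(1 for r in records if r.ddpcr_trackable)


def summarize_cohort(records: Sequence[CohortRecord]) -> CohortSummary:
    """Compute all descriptive counts for a non-empty cohort."""
    if not records:
        raise ValidationError("cannot summarize an empty cohort")
    by_alt = {alt: count_by_alteration(records, alt) for alt in Alteration}
    by_sex = {s: sum(1 for r in records if r.sex is s) for s in Sex}
    by_loc: dict[str, int] = {"supratentorial": 0, "infratentorial": 0, "other": 0}
    for r in records:
        by_loc[r.localization_group] += 1
    return CohortSummary(
        n=len(records),
        counts_by_alteration=by_alt,
        counts_by_sex=by_sex,
        counts_by_localization_group=by_loc,
        age_summary=five_number_summary([r.age_years for r in records]),
        n_methylation_done=sum(1 for r in records if r.methylation_done),
        n_methylation_classified=sum(1 for r in records if r.methylation_classified),
        n_ddpcr_trackable=count_ddpcr_trackable(records),
        n_histology_pa=sum(
            1 for r in records if r.histology.strip().lower() == "pilocytic astrocytoma"
        ),
    )
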
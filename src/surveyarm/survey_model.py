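"""Likert subscale scoring and integer recoding.

Turns raw item-level survey responses into one integer score per domain.
The instrument modelled here has six COVID-19 adjustment domains on a
5-point agreement scale (Strongly Disagree .. Strongly Agree) and three
Ways-of-Coping domains on a 4-point usage scale (Never used .. Used a
great deal).  Scoring is: reverse any reverse-keyed items, average the
subscale's items, then recode the mean back onto the integer scale with
fixed bins.  Missing responses are an error, never imputed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "SubscaleDefinition",
    "SurveyRecord",
    "DomainScoreVector",
    "COHORTS",
    "COVID_SCORE_LABELS",
    "WOC_SCORE_LABELS",
    "DEFAULT_SUBSCALES",
    "reverse_item",
    "subscale_mean",
    "recode_mean_5pt",
    "recode_mean_4pt",
    "recode_mean",
    "score_record",
    "score_records",
    "cronbach_alpha",
    "read_survey_csv",
    "read_scores_csv",
    "write_scores_csv",
    "subscales_from_config",
]

COHORTS = ("undergraduate", "graduate")

COVID_SCORE_LABELS = {
    1: "Strongly Disagree",
    2: "Disagree",
    3: "Neutral",
    4: "Agree",
    5: "Strongly Agree",
}

WOC_SCORE_LABELS = {
    1: "Never used",
    2: "Somewhat used",
    3: "Used quite a bit",
    4: "Used a great deal",
}


class ValidationError(ValueError):
    """Raised when survey input violates the scoring contract."""


@dataclass(frozen=True)
class SubscaleDefinition:
    """One scored domain: its items, reverse-keyed subset, and scale.

    Parameters
    ----------
    domain_code
        Short token used in basket items, e.g. ``"C1"`` or ``"W3"``.
    name
        Human-readable domain label, e.g. ``"Emotionality"``.
    item_ids
        Column names of the items averaged into this domain.
    reversed_items
        Subset of ``item_ids`` whose scale is inverted before averaging.
    scale_points
        5 for the COVID domains, 4 for the Ways-of-Coping domains.
    """

    domain_code: str
    name: str
    item_ids: tuple[str, ...]
    reversed_items: frozenset[str] = frozenset()
    scale_points: int = 5

    def __post_init__(self) -> None:
        object.__setattr__(self, "item_ids", tuple(self.item_ids))
        object.__setattr__(self, "reversed_items", frozenset(self.reversed_items))
        if not self.item_ids:
            raise ValidationError(f"{self.domain_code}: item_ids must be non-empty")
        if len(set(self.item_ids)) != len(self.item_ids):
            raise ValidationError(f"{self.domain_code}: duplicate item ids")
        if not self.reversed_items <= set(self.item_ids):
            extra = self.reversed_items - set(self.item_ids)
            raise ValidationError(
                f"{self.domain_code}: reversed items not in item list: {sorted(extra)}"
            )
        if self.scale_points not in (4, 5):
            raise ValidationError(
                f"{self.domain_code}: scale_points must be 4 or 5, got {self.scale_points}"
            )

    @property
    def score_labels(self) -> Mapping[int, str]:
        return COVID_SCORE_LABELS if self.scale_points == 5 else WOC_SCORE_LABELS


# Default instrument structure: six COVID adjustment domains (items q1..q25,
# reverse-keyed items carry an "R" suffix in the source instrument) and three
# Ways-of-Coping domains.  The WOC instrument's item-level content is not
# modelled; generic item ids matching the subscale sizes (8/6/7) stand in.
DEFAULT_SUBSCALES: tuple[SubscaleDefinition, ...] = (
    SubscaleDefinition("C1", "Emotionality", ("q8", "q9", "q10", "q11"), frozenset(), 5),
    SubscaleDefinition(
        "C2", "Social Support", ("q19", "q20", "q21", "q22"),
        frozenset({"q19", "q20", "q21", "q22"}), 5,
    ),
    SubscaleDefinition(
        "C3", "Academic Adjustment", ("q1", "q2", "q3", "q4", "q5", "q6", "q7"),
        frozenset(), 5,
    ),
    SubscaleDefinition("C4", "Discriminatory Adjustment", ("q12", "q13", "q14"), frozenset(), 5),
    SubscaleDefinition("C5", "Regulation Reaction - Specific", ("q23", "q24", "q25"), frozenset(), 5),
    SubscaleDefinition(
        "C6", "Regulation Reaction - General", ("q15", "q16", "q17", "q18"),
        frozenset({"q16", "q17", "q18"}), 5,
    ),
    SubscaleDefinition(
        "W1", "Escape Avoidance",
        tuple(f"w1_{i}" for i in range(1, 9)), frozenset(), 4,
    ),
    SubscaleDefinition(
        "W2", "Planful Problem Solving",
        tuple(f"w2_{i}" for i in range(1, 7)), frozenset(), 4,
    ),
    SubscaleDefinition(
        "W3", "Positive Reappraisal",
        tuple(f"w3_{i}" for i in range(1, 8)), frozenset(), 4,
    ),
)


@dataclass(frozen=True)
class SurveyRecord:
    """One participant's raw responses plus cohort membership."""

    participant_id: str
    cohort: str
    responses: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValidationError(
                f"participant {self.participant_id}: cohort must be one of "
                f"{COHORTS}, got {self.cohort!r}"
            )


@dataclass(frozen=True)
class DomainScoreVector:
    """One participant's integer score per domain."""

    participant_id: str
    cohort: str
    scores: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValidationError(
                f"participant {self.participant_id}: cohort must be one of "
                f"{COHORTS}, got {self.cohort!r}"
            )


def reverse_item(response: int, scale_points: int) -> int:
    """Invert a Likert response: maps x to scale_points + 1 - x.

    Involutive: reversing twice returns the original response.
    """
    if not 1 <= response <= scale_points:
        raise ValidationError(
            f"response {response} outside 1..{scale_points}"
        )
    return scale_points + 1 - response


def subscale_mean(record: SurveyRecord, definition: SubscaleDefinition) -> float:
    """Mean of a participant's items for one domain, reversing keyed items."""
    missing = [i for i in definition.item_ids if i not in record.responses]
    if missing:
        raise ValidationError(
            f"participant {record.participant_id}: missing items for "
            f"{definition.domain_code}: {missing}"
        )
    values = []
    for item in definition.item_ids:
        r = record.responses[item]
        if not 1 <= r <= definition.scale_points:
            raise ValidationError(
                f"participant {record.participant_id}: item {item} response {r} "
                f"outside 1..{definition.scale_points}"
            )
        values.append(
            reverse_item(r, definition.scale_points)
            if item in definition.reversed_items
            else r
        )
    return float(np.mean(values))


def recode_mean_5pt(m: float) -> int:
    """Recode a 5-point subscale mean to an integer 1..5.

    Bins: [1, 1.80] -> 1, (1.80, 2.60] -> 2, (2.60, 3.40] -> 3,
    (3.40, 4.20] -> 4, (4.20, 5] -> 5.  The printed interval gaps
    (e.g. 1.80 vs 1.81) are closed upward at the <= boundary.
    """
    if not 1.0 <= m <= 5.0:
        raise ValidationError(f"mean {m} outside [1, 5]")
    for level, upper in enumerate((1.80, 2.60, 3.40, 4.20), start=1):
        if m <= upper:
            return level
    return 5


def recode_mean_4pt(m: float) -> int:
    """Recode a 4-point subscale mean to an integer 1..4 via equal-width bins.

    Bins mirror the 5-point scheme: [1, 1.75] -> 1, (1.75, 2.50] -> 2,
    (2.50, 3.25] -> 3, (3.25, 4] -> 4.
    """
    if not 1.0 <= m <= 4.0:
        raise ValidationError(f"mean {m} outside [1, 4]")
    for level, upper in enumerate((1.75, 2.50, 3.25), start=1):
        if m <= upper:
            return level
    return 4


def recode_mean(m: float, scale_points: int) -> int:
    if scale_points == 5:
        return recode_mean_5pt(m)
    if scale_points == 4:
        return recode_mean_4pt(m)
    raise ValidationError(f"unsupported scale_points {scale_points}")


def score_record(
    record: SurveyRecord,
    subscales: Sequence[SubscaleDefinition] = DEFAULT_SUBSCALES,
) -> DomainScoreVector:
    """Score one participant: mean each subscale, recode to integers."""
    scores = {
        d.domain_code: recode_mean(subscale_mean(record, d), d.scale_points)
        for d in subscales
    }
    return DomainScoreVector(record.participant_id, record.cohort, scores)


def score_records(
    records: Iterable[SurveyRecord],
    subscales: Sequence[SubscaleDefinition] = DEFAULT_SUBSCALES,
) -> list[DomainScoreVector]:
    return [score_record(r, subscales) for r in records]


def cronbach_alpha(items: np.ndarray) -> float:
    """Cronbach's alpha internal-consistency coefficient.

    ``items`` is a participants x items matrix.  Computed as
    k/(k-1) * (1 - sum of item variances / variance of row totals),
    with sample (ddof=1) variances.
    """
    x = np.asarray(items, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValidationError("need at least 2 participants and 2 items")
    k = x.shape[1]
    total_var = np.var(x.sum(axis=1), ddof=1)
    if total_var == 0:
        raise ValidationError("total-score variance is zero; alpha undefined")
    item_vars = np.var(x, axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_vars / total_var))


# ---------------------------------------------------------------------------
# CSV / config I/O

def read_survey_csv(
    path: str | Path,
    subscales: Sequence[SubscaleDefinition] = DEFAULT_SUBSCALES,
) -> list[SurveyRecord]:
    """Read item-level survey responses.

    Expected header: ``participant_id, cohort, <item columns>`` where the
    item columns cover every configured subscale's item_ids.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValidationError(f"{path}: empty file, no header row")
        needed = {i for d in subscales for i in d.item_ids}
        have = set(reader.fieldnames)
        missing = needed - have
        if missing:
            raise ValidationError(f"{path}: missing item columns {sorted(missing)}")
        records = []
        for lineno, row in enumerate(reader, start=2):
            try:
                responses = {i: int(row[i]) for i in needed}
            except (TypeError, ValueError) as exc:
                raise ValidationError(f"{path}:{lineno}: non-integer response ({exc})")
            records.append(
                SurveyRecord(row["participant_id"], row["cohort"], responses)
            )
    if not records:
        raise ValidationError(f"{path}: no participant rows")
    return records


def read_scores_csv(
    path: str | Path,
    subscales: Sequence[SubscaleDefinition] = DEFAULT_SUBSCALES,
) -> list[DomainScoreVector]:
    """Read precomputed integer domain scores (bypasses item-level scoring).

    Expected header: ``participant_id, cohort, C1..C6, W1..W3``.
    """
    path = Path(path)
    by_code = {d.domain_code: d for d in subscales}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValidationError(f"{path}: empty file, no header row")
        missing = set(by_code) - set(reader.fieldnames)
        if missing:
            raise ValidationError(f"{path}: missing domain columns {sorted(missing)}")
        vectors = []
        for lineno, row in enumerate(reader, start=2):
            scores: dict[str, int] = {}
            for code, d in by_code.items():
                try:
                    s = int(row[code])
                except (TypeError, ValueError) as exc:
                    raise ValidationError(f"{path}:{lineno}: bad score for {code} ({exc})")
                if not 1 <= s <= d.scale_points:
                    raise ValidationError(
                        f"{path}:{lineno}: {code} score {s} outside 1..{d.scale_points}"
                    )
                scores[code] = s
            vectors.append(DomainScoreVector(row["participant_id"], row["cohort"], scores))
    if not vectors:
        raise ValidationError(f"{path}: no participant rows")
    return vectors


def write_scores_csv(
    vectors: Sequence[DomainScoreVector],
    path: str | Path,
    subscales: Sequence[SubscaleDefinition] = DEFAULT_SUBSCALES,
) -> None:
    path = Path(path)
    codes = [d.domain_code for d in subscales]
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["participant_id", "cohort", *codes])
        for v in vectors:
            writer.writerow([v.participant_id, v.cohort, *(v.scores[c] for c in codes)])


def subscales_from_config(config: Mapping) -> tuple[SubscaleDefinition, ...]:
    """Build subscale definitions from a parsed config mapping.

    Schema (YAML-friendly)::

        subscales:
          C1: {name: Emotionality, items: [q8, q9], reversed: [], scale_points: 5}
    """
    entries = config.get("subscales", config)
    defs = []
    for code, spec in entries.items():
        defs.append(
            SubscaleDefinition(
                domain_code=code,
                name=spec.get("name", code),
                item_ids=tuple(spec["items"]),
                reversed_items=frozenset(spec.get("reversed", ())),
                scale_points=int(spec.get("scale_points", 5)),
            )
        )
    return tuple(defs)
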
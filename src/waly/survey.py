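"""Survey instruments, responses and the paired-comparison design encoding.

Three questionnaire versions are used to elicit impaired welfare weights:

- version A: visual analogue scale (VAS) module + 16 paired comparisons,
- version B: time trade-off (TTO) module + 16 paired comparisons,
- version C: both anchor modules + 11 paired comparisons.

All versions include a demographics module and a care-experience question.
A paired comparison asks which of two described dogs has *better* welfare.
For probit scaling, each answered comparison becomes a signed design row:
+1 for the first impediment in the question, -1 for the second, 0 elsewhere,
with a binary outcome equal to 1 when the first impediment was chosen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .catalogue import Catalogue

VERSIONS = ("A", "B", "C")
#: Number of paired-comparison questions per questionnaire version.
PC_ITEMS = {"A": 16, "B": 16, "C": 11}
#: Which anchor modules each version contains.
ANCHOR_MODULES = {"A": ("vas",), "B": ("tto",), "C": ("vas", "tto")}

#: The five impediments valued directly on the VAS and TTO anchor modules.
ANCHOR_IMPEDIMENTS = (
    "anaemia_mild",
    "msk_one_limb_mild",
    "diarrhoea_frequent",
    "cancer_lung_metastasis",
    "respiratory_distress",
)

VAS_RANGE = (0.0, 100.0)
TTO_RANGE = (0.0, 10.0)


class SurveyError(ValueError):
    pass


@dataclass(frozen=True)
class RespondentProfile:
    respondent_id: str
    gender: str
    age: float
    graduation_year: int
    interest_small_animal: bool
    works_with_livestock: bool
    questionnaire_version: str
    cared_for_conditions: bool = False

    def __post_init__(self) -> None:
        if self.questionnaire_version not in VERSIONS:
            raise SurveyError(
                f"unknown questionnaire version {self.questionnaire_version!r}"
            )
        if self.age <= 0:
            raise SurveyError("age must be positive")


@dataclass(frozen=True)
class PairedComparisonRecord:
    respondent_id: str
    question_id: str
    first_impediment: str
    second_impediment: str
    choice: str  # first_better | second_better | no_answer

    CHOICES = ("first_better", "second_better", "no_answer")

    def __post_init__(self) -> None:
        if self.first_impediment == self.second_impediment:
            raise SurveyError(
                f"question {self.question_id}: identical impediments "
                f"{self.first_impediment!r}"
            )
        if self.choice not in self.CHOICES:
            raise SurveyError(f"unknown choice {self.choice!r}")


@dataclass(frozen=True)
class AnchorResponse:
    respondent_id: str
    method: str  # vas | tto
    impediment_id: str
    value: float
    feasible: bool = True

    def __post_init__(self) -> None:
        if self.method not in ("vas", "tto"):
            raise SurveyError(f"unknown anchor method {self.method!r}")

    @property
    def in_range(self) -> bool:
        lo, hi = VAS_RANGE if self.method == "vas" else TTO_RANGE
        return lo <= self.value <= hi


@dataclass(frozen=True)
class PairedDesignRow:
    """One probit design row: signed indicators plus binary outcome."""

    respondent_id: str
    question_id: str
    first_impediment: str
    second_impediment: str
    outcome: int  # 1 if the first impediment was chosen as better

    def indicator(self, impediment_ids: Sequence[str]) -> np.ndarray:
        row = np.zeros(len(impediment_ids))
        row[list(impediment_ids).index(self.first_impediment)] = 1.0
        row[list(impediment_ids).index(self.second_impediment)] = -1.0
        return row


@dataclass(frozen=True)
class Instrument:
    """A concrete questionnaire: version, modules and paired questions."""

    version: str
    anchor_modules: tuple[str, ...]
    paired_questions: tuple[tuple[str, str], ...]
    includes_demographics: bool = True
    includes_care_experience: bool = True


def build_question_bank(
    catalogue: Catalogue, seed: int, n_pairs: int | None = None
) -> list[tuple[str, str]]:
    """Seeded random paired-comparison bank covering every impediment.

    Death is a valued welfare state like any other, so it participates in
    comparisons. Pairs are drawn without replacement from all unordered
    pairs, after first guaranteeing each impediment appears at least once.
    """
    import itertools

    ids = catalogue.ids
    rng = np.random.default_rng(seed)
    shuffled = list(ids)
    rng.shuffle(shuffled)
    bank: list[tuple[str, str]] = []
    seen: set[frozenset] = set()
    # cover every impediment once via a shuffled chain
    for a, b in zip(shuffled, shuffled[1:] + shuffled[:1]):
        key = frozenset((a, b))
        if key not in seen:
            bank.append((a, b))
            seen.add(key)
    if n_pairs is not None:
        rest = [
            p for p in itertools.combinations(ids, 2)
            if frozenset(p) not in seen
        ]
        order = rng.permutation(len(rest))
        flip = rng.random(len(rest)) < 0.5
        for k in order:
            if len(bank) >= n_pairs:
                break
            a, b = rest[k]
            bank.append((b, a) if flip[k] else (a, b))
        bank = bank[:n_pairs]
    return bank


def assemble_questionnaire(
    version: str,
    catalogue: Catalogue,
    question_bank: Sequence[tuple[str, str]],
    seed: int,
) -> Instrument:
    """Assemble one questionnaire version from the paired-question bank.

    The version determines the anchor modules and the number of paired
    comparisons (16 for A and B, 11 for C); the seed fixes which bank pairs
    are selected, so the same seed reproduces the same instrument.
    """
    if version not in VERSIONS:
        raise SurveyError(f"unknown questionnaire version {version!r}")
    n = PC_ITEMS[version]
    if len(question_bank) < n:
        raise SurveyError(
            f"question bank has {len(question_bank)} pairs; version "
            f"{version} needs {n}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(question_bank), size=n, replace=False)
    questions = tuple(question_bank[i] for i in sorted(idx))
    for a, b in questions:
        if a not in catalogue or b not in catalogue:
            raise SurveyError(f"bank pair ({a!r}, {b!r}) not in catalogue")
    return Instrument(
        version=version,
        anchor_modules=ANCHOR_MODULES[version],
        paired_questions=questions,
    )


def encode_paired_design(
    records: Iterable[PairedComparisonRecord], catalogue: Catalogue
) -> list[PairedDesignRow]:
    """Encode answered comparisons as signed probit design rows.

    Records with ``no_answer`` must have been filtered out upstream; one is
    an error here. The outcome is 1 when the first impediment was chosen
    (as having better welfare), 0 otherwise.
    """
    rows = []
    for rec in records:
        if rec.choice == "no_answer":
            raise SurveyError(
                f"record {rec.question_id} of {rec.respondent_id} is "
                "unanswered; filter before encoding"
            )
        for imp in (rec.first_impediment, rec.second_impediment):
            if imp not in catalogue:
                raise SurveyError(f"unknown impediment {imp!r}")
        rows.append(
            PairedDesignRow(
                respondent_id=rec.respondent_id,
                question_id=rec.question_id,
                first_impediment=rec.first_impediment,
                second_impediment=rec.second_impediment,
                outcome=1 if rec.choice == "first_better" else 0,
            )
        )
    return rows


def decode_design_row(row: PairedDesignRow) -> PairedComparisonRecord:
    """Invert :func:`encode_paired_design` for one row."""
    return PairedComparisonRecord(
        respondent_id=row.respondent_id,
        question_id=row.question_id,
        first_impediment=row.first_impediment,
        second_impediment=row.second_impediment,
        choice="first_better" if row.outcome == 1 else "second_better",
    )


@dataclass(frozen=True)
class Exclusion:
    respondent_id: str
    module: str
    item: str
    reason: str


@dataclass
class FilterResult:
    paired: list[PairedComparisonRecord] = field(default_factory=list)
    anchors: list[AnchorResponse] = field(default_factory=list)
    exclusions: list[Exclusion] = field(default_factory=list)


def filter_responses(
    paired: Iterable[PairedComparisonRecord],
    anchors: Iterable[AnchorResponse],
) -> FilterResult:
    """Drop infeasible anchor answers and unanswered comparisons.

    An anchor response is removed when its value lies outside the method's
    range or it was flagged infeasible at capture (e.g. a VAS placement
    contradicting the respondent's own severity ranking). Paired records
    with ``no_answer`` are removed. Every removal is listed in the
    exclusion report; the operation is idempotent.
    """
    result = FilterResult()
    for rec in paired:
        if rec.choice == "no_answer":
            result.exclusions.append(
                Exclusion(rec.respondent_id, "paired_comparison",
                          rec.question_id, "no answer")
            )
        else:
            result.paired.append(rec)
    for resp in anchors:
        if not resp.in_range:
            result.exclusions.append(
                Exclusion(resp.respondent_id, resp.method,
                          resp.impediment_id, "out of range")
            )
        elif not resp.feasible:
            result.exclusions.append(
                Exclusion(resp.respondent_id, resp.method,
                          resp.impediment_id, "infeasible answer")
            )
        else:
            result.anchors.append(resp)
    return result


def count_answered(
    records: Iterable[PairedComparisonRecord],
    version_counts: Mapping[str, int],
) -> int:
    """Number of answered paired-comparison items.

    Computed as the planned total (respondents per version times that
    version's item count) minus the unanswered records observed.
    """
    planned = sum(
        int(n) * PC_ITEMS[v] for v, n in version_counts.items() if n
    )
    unanswered = sum(1 for r in records if r.choice == "no_answer")
    return planned - unanswered


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------


def paired_to_frame(records: Iterable[PairedComparisonRecord]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "respondent_id": r.respondent_id,
                "question_id": r.question_id,
                "first": r.first_impediment,
                "second": r.second_impediment,
                "choice": r.choice,
            }
            for r in records
        ]
    )


def paired_from_frame(frame) -> list[PairedComparisonRecord]:
    return [
        PairedComparisonRecord(
            respondent_id=str(r.respondent_id),
            question_id=str(r.question_id),
            first_impediment=str(r.first),
            second_impediment=str(r.second),
            choice=str(r.choice),
        )
        for r in frame.itertuples()
    ]


def anchors_to_frame(responses: Iterable[AnchorResponse]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "respondent_id": a.respondent_id,
                "method": a.method,
                "impediment": a.impediment_id,
                "value": a.value,
                "feasible": a.feasible,
            }
            for a in responses
        ]
    )


def anchors_from_frame(frame) -> list[AnchorResponse]:
    return [
        AnchorResponse(
            respondent_id=str(r.respondent_id),
            method=str(r.method),
            impediment_id=str(r.impediment),
            value=float(r.value),
            feasible=bool(r.feasible),
        )
        for r in frame.itertuples()
    ]


def respondents_to_frame(profiles: Iterable[RespondentProfile]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "respondent_id": p.respondent_id,
                "gender": p.gender,
                "age": p.age,
                "graduation_year": p.graduation_year,
                "interest_small_animal": p.interest_small_animal,
                "works_with_livestock": p.works_with_livestock,
                "questionnaire_version": p.questionnaire_version,
                "cared_for_conditions": p.cared_for_conditions,
            }
            for p in profiles
        ]
    )


def respondents_from_frame(frame) -> list[RespondentProfile]:
    return [
        RespondentProfile(
            respondent_id=str(r.respondent_id),
            gender=str(r.gender),
            age=float(r.age),
            graduation_year=int(r.graduation_year),
            interest_small_animal=bool(r.interest_small_animal),
            works_with_livestock=bool(r.works_with_livestock),
            questionnaire_version=str(r.questionnaire_version),
            cared_for_conditions=bool(r.cared_for_conditions),
        )
        for r in frame.itertuples()
    ]
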
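"""Synthetic surveys, life tables and end-to-end scenarios.

The generator inverts the elicitation model so that every stage of the
pipeline can be exercised and validated without external data:

- each impediment has a *true* IWW in (0,1); its latent severity is the
  logit of that weight;
- a paired comparison between impediments (first, second) is answered
  "first better" with probability Phi((s_second - s_first) / probit_scale),
  the standard Thurstonian choice model with unit-scaled probit noise;
- VAS placements are 100*(1 - IWW) plus Gaussian noise (clipped to the
  scale); TTO traded years are 10*(1 - IWW) plus noise, clipped to [0,10];
- the life table derives from a Gompertz survival curve by numerical
  integration of residual life expectancy.

Defaults mirror the realized survey: 61 respondents split 16/16/29 across
questionnaire versions A/B/C, three unanswered comparisons' worth of
no-answer rate, one infeasible anchor respondent per module, and true
weights spread over the elicited range with death near 0.56.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import integrate, optimize, stats

from .catalogue import (
    Catalogue,
    LifeTable,
    packaged_catalogue,
    packaged_disease_models,
    write_catalogue,
    write_disease_models,
    write_life_table,
)
from .survey import (
    ANCHOR_IMPEDIMENTS,
    PC_ITEMS,
    AnchorResponse,
    PairedComparisonRecord,
    RespondentProfile,
    anchors_to_frame,
    build_question_bank,
    paired_to_frame,
    respondents_to_frame,
)

logger = __import__("logging").getLogger(__name__)


class SyntheticError(ValueError):
    pass


@dataclass
class ScenarioConfig:
    """Knobs of a synthetic elicitation scenario (all with survey-realistic
    defaults)."""

    respondent_plan: Mapping[str, int] = field(
        default_factory=lambda: {"A": 16, "B": 16, "C": 29}
    )
    iww_spread: tuple[float, float] = (0.117, 0.857)
    death_iww: float = 0.56
    #: True weights of the five anchoring impediments. They were chosen to
    #: cover the severity range, so their truths are pinned to a spread of
    #: mild-to-severe values rather than drawn at random.
    anchor_truths: Mapping[str, float] = field(
        default_factory=lambda: {
            "anaemia_mild": 0.20,
            "msk_one_limb_mild": 0.39,
            "diarrhoea_frequent": 0.48,
            "cancer_lung_metastasis": 0.86,
            "respiratory_distress": 0.92,
        }
    )
    probit_scale: float = 1.0
    vas_noise_sd: float = 15.0  # points on the 0-100 scale
    tto_noise_sd: float = 2.5  # years on the 0-10 scale
    infeasibility_rate: float = 0.02
    no_answer_rate: float = 0.0036  # ~3 of 831 planned comparisons
    #: Distinct paired-comparison questions available across respondents.
    #: Kept wide so each impediment meets many partners, the random-
    #: selection design recommended for paired-comparison valuation.
    bank_pairs: int = 300
    latent_bend: float = 0.0  # nonlinearity knob for the severity scale
    newborn_expectancy: float = 13.7
    senescence_rate: float = 0.35
    max_age: float = 22.0
    life_table_rows: int = 23


def generate_true_iwws(
    n_impediments: int,
    spread: tuple[float, float] = (0.117, 0.857),
    seed: int = 0,
    ids: Sequence[str] | None = None,
    death_id: str | None = "death",
    death_iww: float = 0.56,
) -> dict[str, float]:
    """Reproducible true IWWs spread over ``spread``.

    The designated death impediment receives ``death_iww``; the remaining
    weights are uniform draws within the spread.
    """
    if n_impediments < 2:
        raise SyntheticError("need at least two impediments")
    lo, hi = spread
    if not 0.0 < lo < hi < 1.0:
        raise SyntheticError("spread must satisfy 0 < lo < hi < 1")
    if ids is None:
        ids = [f"imp_{k:02d}" for k in range(n_impediments)]
    if len(ids) != n_impediments:
        raise SyntheticError("ids length must equal n_impediments")
    rng = np.random.default_rng(seed)
    values = rng.uniform(lo, hi, n_impediments)
    truth = {imp: float(v) for imp, v in zip(ids, values)}
    if death_id is not None and death_id in truth:
        truth[death_id] = death_iww
    return truth


def _severity(iww: float, bend: float = 0.0) -> float:
    """Latent severity of a weight: logit, optionally bent.

    ``bend`` adds a cubic distortion on the logit scale to stress the
    local-regression anchoring against non-linear maps.
    """
    s = math.log(iww / (1.0 - iww))
    return s + bend * s**3


def simulate_respondents(
    plan: Mapping[str, int], seed: int = 0
) -> list[RespondentProfile]:
    """Demographic profiles matching the survey's marginal structure."""
    rng = np.random.default_rng(seed)
    out = []
    k = 0
    for version in sorted(plan):
        for _ in range(int(plan[version])):
            k += 1
            age = float(np.clip(rng.normal(38, 11), 24, 69))
            out.append(
                RespondentProfile(
                    respondent_id=f"r{k:03d}",
                    gender="female" if rng.random() < 0.67 else "male",
                    age=round(age, 1),
                    graduation_year=int(2017 - max(1, age - 25)),
                    interest_small_animal=bool(rng.random() < 0.49),
                    works_with_livestock=bool(rng.random() < 0.30),
                    questionnaire_version=version,
                    cared_for_conditions=bool(rng.random() < 0.5),
                )
            )
    return out


def simulate_paired_comparisons(
    true_iwws: Mapping[str, float],
    respondents: Sequence[RespondentProfile],
    question_bank: Sequence[tuple[str, str]],
    probit_scale: float = 1.0,
    no_answer_rate: float = 0.0,
    seed: int = 0,
    latent_bend: float = 0.0,
) -> list[PairedComparisonRecord]:
    """Thurstonian paired-comparison answers for every respondent.

    P(first chosen as better) = Phi((s_second - s_first) / probit_scale)
    with s = logit(true IWW): the *less* severe impediment is the better
    welfare state. A small fraction of answers is replaced by no_answer.
    """
    missing = {a for q in question_bank for a in q} - set(true_iwws)
    if missing:
        raise SyntheticError(f"bank impediments without truth: {missing}")
    if probit_scale <= 0:
        raise SyntheticError("probit_scale must be positive")
    rng = np.random.default_rng(seed)
    records = []
    for resp in respondents:
        n_q = PC_ITEMS[resp.questionnaire_version]
        idx = rng.choice(len(question_bank), size=n_q, replace=False)
        for qn, i in enumerate(sorted(idx)):
            first, second = question_bank[i]
            s1 = _severity(true_iwws[first], latent_bend)
            s2 = _severity(true_iwws[second], latent_bend)
            p_first_better = stats.norm.cdf((s2 - s1) / probit_scale)
            if rng.random() < no_answer_rate:
                choice = "no_answer"
            elif rng.random() < p_first_better:
                choice = "first_better"
            else:
                choice = "second_better"
            records.append(
                PairedComparisonRecord(
                    respondent_id=resp.respondent_id,
                    question_id=f"{resp.respondent_id}_q{qn:02d}",
                    first_impediment=first,
                    second_impediment=second,
                    choice=choice,
                )
            )
    return records


def simulate_anchor_responses(
    true_iwws: Mapping[str, float],
    method: str,
    respondents: Sequence[RespondentProfile] | int,
    noise_sd: float,
    infeasibility_rate: float = 0.0,
    seed: int = 0,
    anchor_ids: Sequence[str] = ANCHOR_IMPEDIMENTS,
) -> list[AnchorResponse]:
    """Noisy VAS placements or TTO traded years for the anchor impediments.

    The noiseless response inverts the anchoring formula exactly
    (value = scale * (1 - IWW)); Gaussian noise is added and clipped to
    the scale. A stated fraction of respondents is flagged infeasible to
    exercise the filtering stage.
    """
    if method not in ("vas", "tto"):
        raise SyntheticError(f"unknown anchor method {method!r}")
    scale = 100.0 if method == "vas" else 10.0
    if isinstance(respondents, int):
        respondents = [
            RespondentProfile(
                respondent_id=f"r{k:03d}", gender="female", age=35.0,
                graduation_year=2007, interest_small_animal=True,
                works_with_livestock=False,
                questionnaire_version="C",
            )
            for k in range(1, respondents + 1)
        ]
    rng = np.random.default_rng(seed)
    out = []
    for resp in respondents:
        infeasible = rng.random() < infeasibility_rate
        for imp in anchor_ids:
            base = scale * (1.0 - true_iwws[imp])
            value = float(np.clip(base + rng.normal(0.0, noise_sd), 0.0, scale))
            out.append(
                AnchorResponse(
                    respondent_id=resp.respondent_id,
                    method=method,
                    impediment_id=imp,
                    value=value,
                    feasible=not infeasible,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Life table
# ---------------------------------------------------------------------------


def _gompertz_residual_expectancy(
    age: float, b: float, c: float, horizon: float
) -> float:
    def survival(t):
        return np.exp(-(b / c) * (np.expm1(c * t)))

    s_a = survival(age)
    if s_a <= 0:
        return 0.0
    val, _err = integrate.quad(survival, age, horizon, limit=200)
    return val / s_a


def simulate_life_table(
    newborn_expectancy: float = 13.7,
    max_age: float = 22.0,
    n_rows: int = 23,
    seed: int = 0,
    senescence_rate: float = 0.35,
) -> LifeTable:
    """Life table from a Gompertz survival curve.

    The baseline hazard is calibrated so the residual expectancy at age 0
    equals ``newborn_expectancy``; each row's expectancy is the numerically
    integrated mean remaining lifetime under the same curve, so the table
    is internally coherent. The seed is accepted for interface symmetry
    but the construction is deterministic.
    """
    if newborn_expectancy <= 0:
        raise SyntheticError("newborn expectancy must be positive")
    if n_rows < 2 or max_age <= 0:
        raise SyntheticError("need max_age > 0 and at least two rows")
    c = senescence_rate
    horizon = max_age + 60.0  # survival is numerically zero well before this

    def e0(log_b: float) -> float:
        return _gompertz_residual_expectancy(0.0, math.exp(log_b), c, horizon)

    log_b = optimize.brentq(
        lambda lb: e0(lb) - newborn_expectancy, -15.0, 2.0, xtol=1e-12
    )
    b = math.exp(log_b)
    ages = np.linspace(0.0, max_age, n_rows)
    rows = tuple(
        (float(a), _gompertz_residual_expectancy(float(a), b, c, horizon))
        for a in ages
    )
    return LifeTable(rows)


# ---------------------------------------------------------------------------
# End-to-end scenario
# ---------------------------------------------------------------------------


@dataclass
class SyntheticScenario:
    config: ScenarioConfig
    seed: int
    true_iwws: dict[str, float]
    catalogue: Catalogue
    respondents: list[RespondentProfile]
    paired: list[PairedComparisonRecord]
    anchors: list[AnchorResponse]
    life_table: LifeTable
    question_bank: list[tuple[str, str]]


def build_scenario(
    config: ScenarioConfig | None = None, seed: int = 0
) -> SyntheticScenario:
    """Generate a full synthetic scenario in memory."""
    cfg = config or ScenarioConfig()
    catalogue = packaged_catalogue()
    ids = catalogue.ids
    truth = generate_true_iwws(
        len(ids), cfg.iww_spread, seed=seed, ids=ids,
        death_id=catalogue.death_id, death_iww=cfg.death_iww,
    )
    truth.update(cfg.anchor_truths)
    bank = build_question_bank(catalogue, seed=seed + 1, n_pairs=cfg.bank_pairs)
    respondents = simulate_respondents(cfg.respondent_plan, seed=seed + 2)
    paired = simulate_paired_comparisons(
        truth, respondents, bank,
        probit_scale=cfg.probit_scale,
        no_answer_rate=cfg.no_answer_rate,
        seed=seed + 3,
        latent_bend=cfg.latent_bend,
    )
    vas_respondents = [
        r for r in respondents if r.questionnaire_version in ("A", "C")
    ]
    tto_respondents = [
        r for r in respondents if r.questionnaire_version in ("B", "C")
    ]
    anchors = simulate_anchor_responses(
        truth, "vas", vas_respondents, cfg.vas_noise_sd,
        cfg.infeasibility_rate, seed=seed + 4,
    ) + simulate_anchor_responses(
        truth, "tto", tto_respondents, cfg.tto_noise_sd,
        cfg.infeasibility_rate, seed=seed + 5,
    )
    life_table = simulate_life_table(
        cfg.newborn_expectancy, cfg.max_age, cfg.life_table_rows,
        seed=seed, senescence_rate=cfg.senescence_rate,
    )
    return SyntheticScenario(
        config=cfg, seed=seed, true_iwws=truth, catalogue=catalogue,
        respondents=respondents, paired=paired, anchors=anchors,
        life_table=life_table, question_bank=bank,
    )


def make_end_to_end_scenario(
    out_dir, config: ScenarioConfig | None = None, seed: int = 0
) -> SyntheticScenario:
    """Write a complete, loader-compatible input set to ``out_dir``.

    Emits paired.csv, anchors.csv, respondents.csv, catalogue.yaml,
    diseases.yaml, lifetable.csv and truth.json; byte-reproducible for a
    fixed seed and config.
    """
    scenario = build_scenario(config, seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paired_to_frame(scenario.paired).to_csv(out / "paired.csv", index=False)
    anchors_to_frame(scenario.anchors).to_csv(out / "anchors.csv", index=False)
    respondents_to_frame(scenario.respondents).to_csv(
        out / "respondents.csv", index=False
    )
    write_catalogue(scenario.catalogue, out / "catalogue.yaml")
    write_disease_models(
        packaged_disease_models(scenario.catalogue), out / "diseases.yaml"
    )
    write_life_table(scenario.life_table, out / "lifetable.csv")
    truth = {
        "seed": scenario.seed,
        "true_iwws": scenario.true_iwws,
        "question_bank": [list(q) for q in scenario.question_bank],
    }
    (out / "truth.json").write_text(
        json.dumps(truth, indent=1, sort_keys=True), encoding="utf-8"
    )
    return scenario
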
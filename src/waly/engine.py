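"""WALY computation: YLIW, YLL, weighted YLL and their uncertainty.

The Welfare-Adjusted Life Year for a disease is

    WALY = YLIW + YLL

where YLIW = sum_i P_i * D_i * IWW_i over the disease's welfare impediments
(death excluded), and YLL is the residual life expectancy at the age of
premature death (age at diagnosis + survival time), read from a life table
by linear interpolation and scaled by the case fatality carried on the
death sequela item. The weighted YLL multiplies YLL by the IWW of death,
treating death as a welfare state rather than a total loss; weighted WALY
is YLIW plus weighted YLL.

Uncertainty is propagated by Monte Carlo: per draw, probabilities,
durations, ages, survival times and IWWs (each from its logit-normal) are
sampled, the five quantities computed, and each summarised by its mean and
2.5th/97.5th percentiles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .catalogue import DiseaseModel, LifeTable
from .elicitation import IWWEstimate, inv_logit

logger = logging.getLogger(__name__)


class EngineError(ValueError):
    pass


@dataclass(frozen=True)
class Interval:
    mean: float
    low: float
    high: float


@dataclass(frozen=True)
class WALYResult:
    """Burden of one disease: five quantities, each with mean and 95% UI."""

    disease_id: str
    yliw: Interval
    yll: Interval
    waly: Interval
    weighted_yll: Interval
    weighted_waly: Interval
    fraction_yliw: float
    fraction_yll: float
    n_sims: int
    seed: int


def life_expectancy_at(life_table: LifeTable, age: float) -> float:
    """Residual life expectancy at ``age`` by linear interpolation.

    Exact at tabulated ages. Ages beyond the last row clamp to the final
    expectancy (with a warning); ages below the first row are an error.
    """
    ages = np.asarray(life_table.ages)
    exps = np.asarray(life_table.expectancies)
    if age < ages[0]:
        raise EngineError(
            f"age {age} below the life table start ({ages[0]})"
        )
    if age > ages[-1]:
        logger.warning(
            "age %.2f beyond life table end (%.2f); clamping", age, ages[-1]
        )
        return float(exps[-1])
    return float(np.interp(age, ages, exps))


def _iww_lookup(
    iww_table: Sequence[IWWEstimate] | Mapping[str, float],
) -> Mapping[str, float]:
    if isinstance(iww_table, Mapping):
        return iww_table
    return {e.impediment_id: e.mean for e in iww_table}


def compute_yliw(
    disease: DiseaseModel,
    iww_table: Sequence[IWWEstimate] | Mapping[str, float],
    death_id: str = "death",
) -> float:
    """Years lived with impaired welfare: sum of P_i * D_i * IWW_i.

    The death impediment never contributes here; it only weights YLL.
    """
    iwws = _iww_lookup(iww_table)
    total = 0.0
    for seq in disease.sequelae:
        for item in seq.items:
            if item.impediment_id == death_id:
                continue
            if item.impediment_id not in iwws:
                raise EngineError(
                    f"{disease.id}: no IWW for impediment "
                    f"{item.impediment_id!r}"
                )
            total += (
                item.probability.point
                * item.duration.point
                * iwws[item.impediment_id]
            )
    return total


def _death_probability(disease: DiseaseModel, death_id: str) -> float:
    for seq in disease.sequelae:
        for item in seq.items:
            if item.impediment_id == death_id:
                return item.probability.point
    return 1.0


def compute_yll(
    disease: DiseaseModel, life_table: LifeTable, death_id: str = "death"
) -> float:
    """Years of life lost: case fatality times residual expectancy at death.

    The age of premature death is age at diagnosis plus survival time; the
    residual expectancy at that age is read from the life table and scaled
    by the probability on the death sequela item (1 if none is recorded).
    Non-fatal diseases return 0.
    """
    if not disease.causes_death:
        return 0.0
    if disease.age_at_diagnosis is None or disease.survival_time is None:
        raise EngineError(f"{disease.id}: missing age or survival input")
    age_at_death = disease.age_at_diagnosis.point + disease.survival_time.point
    L = life_expectancy_at(life_table, age_at_death)
    return _death_probability(disease, death_id) * L


def weight_yll(yll: float, iww_death: float) -> float:
    """YLL multiplied by the IWW of death (death as a welfare state)."""
    if not 0.0 <= iww_death <= 1.0:
        raise EngineError(f"IWW of death {iww_death} outside [0,1]")
    return yll * iww_death


def compute_waly(yliw: float, yll: float) -> tuple[float, float, float]:
    """WALY = YLIW + YLL, with the two components' proportional shares.

    Returns (waly, fraction_yliw, fraction_yll); fractions are (0, 0) for
    a zero WALY.
    """
    if yliw < 0 or yll < 0:
        raise EngineError("YLIW and YLL must be non-negative")
    waly = yliw + yll
    if waly == 0.0:
        return 0.0, 0.0, 0.0
    return waly, yliw / waly, yll / waly


def _summary(draws: np.ndarray) -> Interval:
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return Interval(float(draws.mean()), float(lo), float(hi))


def simulate_burden_draws(
    disease: DiseaseModel,
    iww_table: Sequence[IWWEstimate],
    life_table: LifeTable,
    iww_death: IWWEstimate | None,
    n_sims: int = 100_000,
    seed: int = 0,
    death_id: str = "death",
) -> dict[str, np.ndarray]:
    """Per-draw Monte Carlo arrays for one disease.

    Per draw: sample every P_i and D_i from its uncertainty spec, every
    IWW from its logit-normal, the age at diagnosis and survival time, and
    the death IWW; compute YLIW, YLL, weighted YLL, WALY and weighted WALY.
    The identity WALY = YLIW + YLL holds in every draw by construction.
    """
    if n_sims < 1:
        raise EngineError("n_sims must be >= 1")
    rng = np.random.default_rng(seed)
    by_id = {e.impediment_id: e for e in iww_table}

    iww_draws: dict[str, np.ndarray] = {}

    def draws_for(est: IWWEstimate) -> np.ndarray:
        if est.impediment_id not in iww_draws:
            if est.logit_se == 0.0:
                iww_draws[est.impediment_id] = np.full(
                    n_sims, float(inv_logit(est.logit_mean))
                )
            else:
                z = rng.normal(est.logit_mean, est.logit_se, n_sims)
                iww_draws[est.impediment_id] = inv_logit(z)
        return iww_draws[est.impediment_id]

    yliw = np.zeros(n_sims)
    for seq in disease.sequelae:
        for item in seq.items:
            if item.impediment_id == death_id:
                continue
            if item.impediment_id not in by_id:
                raise EngineError(
                    f"{disease.id}: no IWW for impediment "
                    f"{item.impediment_id!r}"
                )
            p = np.clip(item.probability.sample(rng, n_sims), 0.0, 1.0)
            d = np.clip(item.duration.sample(rng, n_sims), 0.0, None)
            yliw += p * d * draws_for(by_id[item.impediment_id])

    ages = np.asarray(life_table.ages)
    exps = np.asarray(life_table.expectancies)
    if disease.causes_death:
        if disease.age_at_diagnosis is None or disease.survival_time is None:
            raise EngineError(f"{disease.id}: missing age or survival input")
        age_dx = disease.age_at_diagnosis.sample(rng, n_sims)
        surv = np.clip(disease.survival_time.sample(rng, n_sims), 0.0, None)
        age_death = np.clip(age_dx + surv, ages[0], None)
        if np.any(age_death > ages[-1]):
            logger.warning(
                "%s: %d draws beyond life table end; clamped",
                disease.id, int(np.sum(age_death > ages[-1])),
            )
        L = np.interp(age_death, ages, exps)
        p_death = None
        for seq in disease.sequelae:
            for item in seq.items:
                if item.impediment_id == death_id:
                    p_death = np.clip(
                        item.probability.sample(rng, n_sims), 0.0, 1.0
                    )
        yll = L if p_death is None else p_death * L
        if iww_death is None:
            raise EngineError(f"{disease.id}: fatal disease needs a death IWW")
        w = draws_for(iww_death)
        weighted_yll = yll * w
    else:
        yll = np.zeros(n_sims)
        weighted_yll = np.zeros(n_sims)

    return {
        "yliw": yliw,
        "yll": yll,
        "waly": yliw + yll,
        "weighted_yll": weighted_yll,
        "weighted_waly": yliw + weighted_yll,
    }


def propagate_waly_uncertainty(
    disease: DiseaseModel,
    iww_table: Sequence[IWWEstimate],
    life_table: LifeTable,
    iww_death: IWWEstimate | None,
    n_sims: int = 100_000,
    seed: int = 0,
    death_id: str = "death",
) -> WALYResult:
    """Monte Carlo burden of one disease, summarised as mean and 95% UI.

    See :func:`simulate_burden_draws` for the sampling model; a fixed seed
    reproduces results exactly.
    """
    d = simulate_burden_draws(
        disease, iww_table, life_table, iww_death, n_sims, seed, death_id
    )
    yliw, yll = d["yliw"], d["yll"]
    waly, weighted_yll, weighted_waly = (
        d["waly"], d["weighted_yll"], d["weighted_waly"]
    )
    mean_waly = float(waly.mean())
    if mean_waly > 0:
        frac_yliw = float(yliw.mean()) / mean_waly
        frac_yll = float(yll.mean()) / mean_waly
    else:
        frac_yliw = frac_yll = 0.0
    return WALYResult(
        disease_id=disease.id,
        yliw=_summary(yliw),
        yll=_summary(yll),
        waly=_summary(waly),
        weighted_yll=_summary(weighted_yll),
        weighted_waly=_summary(weighted_waly),
        fraction_yliw=frac_yliw,
        fraction_yll=frac_yll,
        n_sims=n_sims,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def _fmt(v: float) -> str:
    if v >= 10:
        return f"{v:.3g}"
    return f"{v:.2f}"


def _fmt_interval(iv: Interval) -> str:
    return f"{_fmt(iv.mean)} ({_fmt(iv.low)}–{_fmt(iv.high)})"


def build_results_table(results: Sequence[WALYResult]):
    """Burden results as a DataFrame with "mean (lo-hi)" columns.

    Values are rendered at 2 decimal places (3 significant figures at 10
    and above); internal arithmetic stays at full precision.
    """
    import pandas as pd

    if not results:
        raise EngineError("no results to tabulate")
    rows = []
    for r in results:
        rows.append(
            {
                "disease": r.disease_id,
                "YLIW": _fmt_interval(r.yliw),
                "Non-weighted YLLs": _fmt_interval(r.yll),
                "Non-weighted WALYs": _fmt_interval(r.waly),
                "Weighted YLLs": _fmt_interval(r.weighted_yll),
                "Weighted WALYs": _fmt_interval(r.weighted_waly),
            }
        )
    return pd.DataFrame(rows)


def results_to_frame(results: Sequence[WALYResult]):
    """Machine-readable results: one row per disease, lo/hi columns."""
    import pandas as pd

    rows = []
    for r in results:
        rec = {"disease": r.disease_id}
        for name in ("yliw", "yll", "waly", "weighted_yll", "weighted_waly"):
            iv: Interval = getattr(r, name)
            rec[name] = iv.mean
            rec[f"{name}_low"] = iv.low
            rec[f"{name}_high"] = iv.high
        rec["fraction_yliw"] = r.fraction_yliw
        rec["fraction_yll"] = r.fraction_yll
        rec["n_sims"] = r.n_sims
        rec["seed"] = r.seed
        rows.append(rec)
    return pd.DataFrame(rows)
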
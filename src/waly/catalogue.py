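"""Impediment catalogues, disease models and life tables.

A *welfare impediment* is a concrete condition, sign or treatment (e.g.
"Anaemia: mild", "Severe heart failure (with treatment)") that compromises
an animal's welfare. A disease maps onto impediments through *sequelae*:
stages of the disease (pre-diagnosis, stable phase, recurrence, death), each
carrying per-impediment probabilities ``P_i`` and mean durations ``D_i`` in
years. Death is itself represented as a catalogue impediment, flagged
``is_death``; it never enters the years-lived-with-impaired-welfare sum and
is used only to weight years of life lost.

Catalogues and disease models are stored as YAML documents with a
``schema: waly/1`` header; life tables are two-column CSV files
(``age,life_expectancy``). Loading validates referential integrity and the
structural invariants documented on each type.
"""

from __future__ import annotations

import csv
import io
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "waly/1"


class CatalogueError(ValueError):
    """Raised when a catalogue, disease model or life table is invalid."""


class FormatError(CatalogueError):
    """Raised when an input file cannot be parsed at all."""


# ---------------------------------------------------------------------------
# Uncertainty specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UncertaintySpec:
    """Distribution descriptor for a scalar epidemiological input.

    Supported kinds:

    - ``point``: degenerate at ``value``
    - ``uniform``: parameters ``low``, ``high``
    - ``normal``: parameters ``mean``, ``sd``
    - ``lognormal``: parameters ``median``, ``low``, ``high`` — fitted so the
      log-scale sigma places the reported range at roughly the central 95%
    - ``beta``: parameters ``mean``, ``n`` — Beta(mean*n, (1-mean)*n)
    """

    kind: str
    params: Mapping[str, float]

    _KINDS = ("point", "uniform", "normal", "lognormal", "beta")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise CatalogueError(f"unknown uncertainty kind {self.kind!r}")
        p = self.params
        if self.kind == "point" and "value" not in p:
            raise CatalogueError("point spec requires 'value'")
        if self.kind == "uniform":
            if not p.get("low", 0.0) <= p.get("high", -1.0):
                raise CatalogueError("uniform spec requires low <= high")
        if self.kind == "normal" and p.get("sd", -1.0) < 0:
            raise CatalogueError("normal spec requires sd >= 0")
        if self.kind == "lognormal":
            med = p.get("median", 0.0)
            if med <= 0 or not (0 < p.get("low", 0.0) <= med <= p.get("high", 0.0)):
                raise CatalogueError(
                    "lognormal spec requires 0 < low <= median <= high"
                )
        if self.kind == "beta":
            if not 0.0 <= p.get("mean", -1.0) <= 1.0 or p.get("n", 0.0) <= 0:
                raise CatalogueError("beta spec requires mean in [0,1] and n > 0")

    def sample(self, rng, size: int):
        """Draw ``size`` values from the described distribution."""
        import numpy as np

        p = self.params
        if self.kind == "point":
            return np.full(size, float(p["value"]))
        if self.kind == "uniform":
            return rng.uniform(p["low"], p["high"], size)
        if self.kind == "normal":
            return rng.normal(p["mean"], p["sd"], size)
        if self.kind == "lognormal":
            mu = math.log(p["median"])
            # place the reported bounds near the central 95% on the log scale
            sigma = (math.log(p["high"]) - math.log(p["low"])) / (2 * 1.96)
            return rng.lognormal(mu, sigma, size)
        if self.kind == "beta":
            a = p["mean"] * p["n"]
            b = (1.0 - p["mean"]) * p["n"]
            return rng.beta(max(a, 1e-9), max(b, 1e-9), size)
        raise AssertionError(self.kind)

    @property
    def point(self) -> float:
        """Central (point) value of the distribution."""
        p = self.params
        if self.kind == "point":
            return float(p["value"])
        if self.kind == "uniform":
            return 0.5 * (p["low"] + p["high"])
        if self.kind == "normal":
            return float(p["mean"])
        if self.kind == "lognormal":
            return float(p["median"])
        if self.kind == "beta":
            return float(p["mean"])
        raise AssertionError(self.kind)

    def to_dict(self) -> dict:
        return {"kind": self.kind, **{k: float(v) for k, v in self.params.items()}}

    @classmethod
    def from_value(cls, obj) -> "UncertaintySpec":
        """Build a spec from a YAML scalar (point) or mapping."""
        if isinstance(obj, (int, float)):
            return cls("point", {"value": float(obj)})
        if isinstance(obj, Mapping):
            d = dict(obj)
            kind = d.pop("kind", None)
            if kind is None:
                raise CatalogueError(f"uncertainty mapping missing 'kind': {obj!r}")
            return cls(kind, d)
        raise CatalogueError(f"cannot interpret uncertainty spec {obj!r}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WelfareImpediment:
    """A named welfare-compromising condition.

    ``domains_profile`` maps a Five Domains category (nutrition, environment,
    health, behaviour, affective state) to welfare-compromise statements,
    each tagged with a prevalence band (">=50%" or "10-50%").
    """

    id: str
    name: str
    lay_description: str = ""
    domains_profile: Mapping[str, Sequence[Mapping[str, str]]] = field(
        default_factory=dict
    )
    is_death: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise CatalogueError("impediment id must be non-empty")
        if not self.is_death and not self.lay_description:
            raise CatalogueError(
                f"impediment {self.id!r} requires a lay description"
            )
        if len(self.lay_description.split()) > 50:
            raise CatalogueError(
                f"lay description of {self.id!r} exceeds 50 words"
            )


class Catalogue:
    """An ordered, id-indexed collection of welfare impediments.

    Exactly one impediment may be flagged ``is_death``.
    """

    def __init__(self, impediments: Iterable[WelfareImpediment]):
        self._items: dict[str, WelfareImpediment] = {}
        for imp in impediments:
            if imp.id in self._items:
                raise CatalogueError(f"duplicate impediment id {imp.id!r}")
            self._items[imp.id] = imp
        deaths = [i.id for i in self._items.values() if i.is_death]
        if len(deaths) > 1:
            raise CatalogueError(
                f"more than one death impediment: {', '.join(deaths)}"
            )
        self._death_id = deaths[0] if deaths else None

    def __len__(self) -> int:
        return len(self._items)

    def __iter__(self):
        return iter(self._items.values())

    def __contains__(self, impediment_id: str) -> bool:
        return impediment_id in self._items

    def __getitem__(self, impediment_id: str) -> WelfareImpediment:
        try:
            return self._items[impediment_id]
        except KeyError:
            raise KeyError(f"unknown impediment id {impediment_id!r}") from None

    @property
    def ids(self) -> list[str]:
        return list(self._items)

    @property
    def death_id(self) -> str | None:
        """Id of the impediment flagged as death, if any."""
        return self._death_id

    def non_death_ids(self) -> list[str]:
        return [i for i in self._items if i != self._death_id]


@dataclass(frozen=True)
class SequelaItem:
    """One (impediment, probability, duration) entry of a sequela."""

    impediment_id: str
    probability: UncertaintySpec
    duration: UncertaintySpec

    def __post_init__(self) -> None:
        p = self.probability.point
        if not 0.0 <= p <= 1.0:
            raise CatalogueError(
                f"probability {p} for {self.impediment_id!r} outside [0,1]"
            )
        d = self.duration.point
        if not (math.isfinite(d) and d >= 0.0):
            raise CatalogueError(
                f"duration {d} for {self.impediment_id!r} must be finite and >= 0"
            )


@dataclass(frozen=True)
class SequelaEntry:
    """A disease stage with its impediment probabilities and durations."""

    sequela_name: str
    items: Sequence[SequelaItem]


@dataclass(frozen=True)
class DiseaseModel:
    """A disease: its sequelae plus mortality inputs.

    ``age_at_diagnosis`` and ``survival_time`` are in years;
    ``survival_time`` is absent (None) for non-fatal diseases.
    """

    id: str
    name: str
    sequelae: Sequence[SequelaEntry]
    causes_death: bool
    age_at_diagnosis: UncertaintySpec | None = None
    survival_time: UncertaintySpec | None = None

    def __post_init__(self) -> None:
        if self.age_at_diagnosis is not None and self.age_at_diagnosis.point < 0:
            raise CatalogueError(f"{self.id}: age_at_diagnosis must be >= 0")
        if self.survival_time is not None and self.survival_time.point < 0:
            raise CatalogueError(f"{self.id}: survival_time must be >= 0")
        if self.causes_death and self.survival_time is None:
            raise CatalogueError(
                f"{self.id}: fatal disease requires a survival_time"
            )

    def impediment_ids(self) -> list[str]:
        seen: list[str] = []
        for seq in self.sequelae:
            for item in seq.items:
                if item.impediment_id not in seen:
                    seen.append(item.impediment_id)
        return seen


@dataclass(frozen=True)
class LifeTable:
    """Age-indexed residual life expectancy.

    ``rows`` is an ordered list of (age, residual life expectancy), both in
    years, with strictly increasing ages and at least two rows.
    """

    rows: Sequence[tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise CatalogueError("life table needs at least two rows")
        ages = [a for a, _ in self.rows]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise CatalogueError("life table ages must be strictly increasing")
        if any(e < 0 for _, e in self.rows):
            raise CatalogueError("life expectancies must be non-negative")

    @property
    def ages(self):
        return [a for a, _ in self.rows]

    @property
    def expectancies(self):
        return [e for _, e in self.rows]


# ---------------------------------------------------------------------------
# Loading and writing
# ---------------------------------------------------------------------------


def _read_yaml(path) -> dict:
    text = Path(path).read_text(encoding="utf-8")
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = mark.line + 1 if mark is not None else "?"
        raise FormatError(f"{path}: YAML parse failure at line {line}: {exc}")
    if not isinstance(doc, Mapping):
        raise FormatError(f"{path}: expected a mapping at top level")
    schema = doc.get("schema")
    if schema != SCHEMA_VERSION:
        raise FormatError(
            f"{path}: unsupported schema {schema!r}, expected {SCHEMA_VERSION!r}"
        )
    return dict(doc)


def load_catalogue(path) -> Catalogue:
    """Load a welfare-impediment catalogue from YAML.

    Raises :class:`FormatError` on parse failure and :class:`CatalogueError`
    on duplicate ids or multiple death impediments.
    """
    doc = _read_yaml(path)
    raw = doc.get("impediments")
    if not isinstance(raw, list):
        raise FormatError(f"{path}: 'impediments' must be a list")
    ids = [e.get("id") for e in raw]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise CatalogueError(f"{path}: duplicate impediment ids: {', '.join(dupes)}")
    imps = [
        WelfareImpediment(
            id=e["id"],
            name=e.get("name", e["id"]),
            lay_description=e.get("lay_description", ""),
            domains_profile=e.get("domains_profile", {}),
            is_death=bool(e.get("is_death", False)),
        )
        for e in raw
    ]
    return Catalogue(imps)


def load_disease_models(path, catalogue: Catalogue) -> list[DiseaseModel]:
    """Load disease models from YAML, resolving impediments in ``catalogue``."""
    doc = _read_yaml(path)
    raw = doc.get("diseases")
    if not isinstance(raw, list):
        raise FormatError(f"{path}: 'diseases' must be a list")
    models = []
    for entry in raw:
        sequelae = []
        for seq in entry.get("sequelae", []):
            items = []
            for it in seq.get("items", []):
                imp_id = it["impediment"]
                if imp_id not in catalogue:
                    raise CatalogueError(
                        f"{entry.get('id')}: unresolved impediment id {imp_id!r}"
                    )
                items.append(
                    SequelaItem(
                        impediment_id=imp_id,
                        probability=UncertaintySpec.from_value(it["probability"]),
                        duration=UncertaintySpec.from_value(it["duration"]),
                    )
                )
            sequelae.append(SequelaEntry(seq["name"], tuple(items)))
        death_id = catalogue.death_id
        references_death = death_id is not None and any(
            it.impediment_id == death_id for s in sequelae for it in s.items
        )
        causes_death = bool(entry.get("causes_death", references_death))
        if causes_death != references_death:
            raise CatalogueError(
                f"{entry.get('id')}: causes_death={causes_death} inconsistent "
                f"with sequelae (death referenced: {references_death})"
            )
        models.append(
            DiseaseModel(
                id=entry["id"],
                name=entry.get("name", entry["id"]),
                sequelae=tuple(sequelae),
                causes_death=causes_death,
                age_at_diagnosis=(
                    UncertaintySpec.from_value(entry["age_at_diagnosis"])
                    if "age_at_diagnosis" in entry
                    else None
                ),
                survival_time=(
                    UncertaintySpec.from_value(entry["survival_time"])
                    if "survival_time" in entry
                    else None
                ),
            )
        )
    return models


def load_life_table(path) -> LifeTable:
    """Load a life table from ``age,life_expectancy`` CSV.

    Rows out of age order are sorted (with a warning); fewer than two rows
    is an error because linear interpolation would be impossible.
    """
    text = Path(path).read_text(encoding="utf-8")
    reader = csv.DictReader(io.StringIO(text))
    if reader.fieldnames is None or not {"age", "life_expectancy"} <= set(
        reader.fieldnames
    ):
        raise FormatError(
            f"{path}: expected CSV header with columns age,life_expectancy"
        )
    rows = []
    for rec in reader:
        try:
            rows.append((float(rec["age"]), float(rec["life_expectancy"])))
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: bad numeric row {rec!r}") from exc
    ordered = sorted(rows)
    if ordered != rows:
        logger.warning("life table %s rows were out of age order; sorted", path)
    return LifeTable(tuple(ordered))


def write_catalogue(catalogue: Catalogue, path) -> None:
    doc = {
        "schema": SCHEMA_VERSION,
        "impediments": [
            {
                "id": i.id,
                "name": i.name,
                "lay_description": i.lay_description,
                "domains_profile": {
                    k: [dict(s) for s in v] for k, v in i.domains_profile.items()
                },
                "is_death": i.is_death,
            }
            for i in catalogue
        ],
    }
    Path(path).write_text(
        yaml.safe_dump(doc, sort_keys=False, allow_unicode=True), encoding="utf-8"
    )


def write_disease_models(models: Sequence[DiseaseModel], path) -> None:
    def spec(s: UncertaintySpec | None):
        if s is None:
            return None
        if s.kind == "point":
            return float(s.params["value"])
        return s.to_dict()

    doc = {
        "schema": SCHEMA_VERSION,
        "diseases": [
            {
                "id": m.id,
                "name": m.name,
                "causes_death": m.causes_death,
                **(
                    {"age_at_diagnosis": spec(m.age_at_diagnosis)}
                    if m.age_at_diagnosis is not None
                    else {}
                ),
                **(
                    {"survival_time": spec(m.survival_time)}
                    if m.survival_time is not None
                    else {}
                ),
                "sequelae": [
                    {
                        "name": s.sequela_name,
                        "items": [
                            {
                                "impediment": it.impediment_id,
                                "probability": spec(it.probability),
                                "duration": spec(it.duration),
                            }
                            for it in s.items
                        ],
                    }
                    for s in m.sequelae
                ],
            }
            for m in models
        ],
    }
    Path(path).write_text(
        yaml.safe_dump(doc, sort_keys=False, allow_unicode=True), encoding="utf-8"
    )


def write_life_table(table: LifeTable, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["age", "life_expectancy"])
        for age, exp in table.rows:
            w.writerow([f"{age:g}", f"{exp:.6g}"])


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------


def _data_path(name: str):
    return resources.files("waly.data").joinpath(name)


def packaged_catalogue() -> Catalogue:
    """The packaged 35-impediment canine catalogue."""
    with resources.as_file(_data_path("catalogue.yaml")) as p:
        return load_catalogue(p)


def packaged_disease_models(catalogue: Catalogue | None = None) -> list[DiseaseModel]:
    """The packaged ten canine disease models."""
    if catalogue is None:
        catalogue = packaged_catalogue()
    with resources.as_file(_data_path("diseases.yaml")) as p:
        return load_disease_models(p, catalogue)


def packaged_life_table() -> LifeTable:
    """Packaged synthetic canine life table (Gompertz-derived)."""
    with resources.as_file(_data_path("lifetable_synthetic.csv")) as p:
        return load_life_table(p)
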
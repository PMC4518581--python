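"""Core data model and file I/O for six-option questionnaire data.

Every item offers six integer response options (1..6) anchored by two
contrasting statements; higher responses connote greater impairment.
Responses are kept on the 1..6 scale throughout the package except inside
the Rasch module, which recodes to 0-based analysis categories internally.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

RESPONSE_MIN = 1
RESPONSE_MAX = 6

#: covariate columns the loader recognises by name
STANDARD_COVARIATES = ("severity_pct", "spiro_window_days", "oxygen_use", "group")


class InstrumentError(ValueError):
    """Raised for an invalid instrument definition or configuration."""


class ResponseLoadError(ValueError):
    """Raised when a response file violates the 1..6 integer contract."""


@dataclass(frozen=True)
class ItemDef:
    """One questionnaire item: two contrasting anchors, six options."""

    id: str
    left_anchor: str
    right_anchor: str
    domain: str | None = None
    reverse_scored: bool = False

    def __post_init__(self):
        if not self.id:
            raise InstrumentError("item id must be non-empty")
        if not self.left_anchor or not self.right_anchor:
            raise InstrumentError(f"item {self.id!r}: anchors must be non-empty")


@dataclass
class InstrumentDefinition:
    """Item list, domain structure and standalone (total-only) items."""

    items: list[ItemDef]
    domains: list[str]
    standalone_items: list[str] = field(default_factory=list)
    covariates: list[str] = field(default_factory=lambda: list(STANDARD_COVARIATES))

    def __post_init__(self):
        if not self.items:
            raise InstrumentError("instrument must define at least one item")
        ids = [it.id for it in self.items]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise InstrumentError(f"duplicate item ids: {dup}")
        if len(set(self.domains)) != len(self.domains):
            raise InstrumentError("duplicate domain names")
        standalone = set(self.standalone_items)
        for it in self.items:
            if it.domain is None:
                standalone.add(it.id)
            elif it.domain not in self.domains:
                raise InstrumentError(
                    f"item {it.id!r} references undeclared domain {it.domain!r}"
                )
        unknown = standalone - set(ids)
        if unknown:
            raise InstrumentError(f"standalone ids not in instrument: {sorted(unknown)}")
        self.standalone_items = [i for i in ids if i in standalone]

    @property
    def item_ids(self) -> list[str]:
        return [it.id for it in self.items]

    def item(self, item_id: str) -> ItemDef:
        for it in self.items:
            if it.id == item_id:
                return it
        raise KeyError(item_id)

    def domain_items(self, domain: str) -> list[str]:
        return [it.id for it in self.items if it.domain == domain]

    def domain_of(self, item_id: str) -> str | None:
        return self.item(item_id).domain

    def subset(self, keep_ids: list[str]) -> "InstrumentDefinition":
        """Instrument restricted to ``keep_ids`` (original order kept)."""
        keep = set(keep_ids)
        items = [it for it in self.items if it.id in keep]
        domains = [d for d in self.domains if any(it.domain == d for it in items)]
        return InstrumentDefinition(
            items=items,
            domains=domains,
            standalone_items=[i for i in self.standalone_items if i in keep],
            covariates=list(self.covariates),
        )

    def reassign(self, moves: dict[str, str]) -> "InstrumentDefinition":
        """New instrument with items moved to different domains."""
        items = []
        for it in self.items:
            if it.id in moves:
                items.append(
                    ItemDef(it.id, it.left_anchor, it.right_anchor,
                            moves[it.id], it.reverse_scored)
                )
            else:
                items.append(it)
        return InstrumentDefinition(items, list(self.domains),
                                    list(self.standalone_items), list(self.covariates))


_CONFIG_DEFAULTS = dict(
    min_categories_used=5,
    max_missing_fraction=0.20,
    max_floor_ceiling_fraction=0.49,
    redundancy_r=0.70,
    convergent_r=0.30,
    alpha_level=0.05,
    infit_useful=(0.5, 1.5),
    infit_degrade=2.0,
    imputation_min_fraction=0.5,
    spiro_window_days_max=92,
)


@dataclass
class AnalysisConfig:
    """Thresholds driving item deletion, scaling and validity analyses.

    Defaults follow the development study's published rules: fewer than five
    used categories, >20% missing, >49% floor/ceiling, inter-item r > 0.7,
    convergent validity at r >= 0.3, infit useful in [0.5, 1.5] and
    degrading above 2.0, imputation requiring at least half the scale
    answered, and a 92-day spirometry window.
    """

    min_categories_used: int = 5
    max_missing_fraction: float = 0.20
    max_floor_ceiling_fraction: float = 0.49
    redundancy_r: float = 0.70
    convergent_r: float = 0.30
    alpha_level: float = 0.05
    infit_useful: tuple[float, float] = (0.5, 1.5)
    infit_degrade: float = 2.0
    imputation_min_fraction: float = 0.5
    spiro_window_days_max: int = 92
    retain_overrides: list[str] = field(default_factory=list)
    conceptual_deletions: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        for name in ("max_missing_fraction", "max_floor_ceiling_fraction",
                     "imputation_min_fraction", "alpha_level"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InstrumentError(f"{name}={v} outside [0, 1]")
        lo, hi = self.infit_useful
        if not lo < hi < self.infit_degrade:
            raise InstrumentError("require infit_useful lower < upper < infit_degrade")

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        kwargs = dict(d)
        if "infit_useful" in kwargs:
            kwargs["infit_useful"] = tuple(kwargs["infit_useful"])
        known = {f.name for f in dc_fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise InstrumentError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in dc_fields(self)}
        d["infit_useful"] = list(self.infit_useful)
        return d


class ResponseMatrix:
    """Respondents x items integer responses (NaN = missing) plus covariates."""

    def __init__(self, responses: pd.DataFrame, covariates: pd.DataFrame | None = None,
                 respondent_ids: list | None = None):
        self.responses = responses.astype(float)
        vals = self.responses.to_numpy()
        ok = np.isnan(vals) | (
            (vals >= RESPONSE_MIN) & (vals <= RESPONSE_MAX) & (vals == np.round(vals))
        )
        if not ok.all():
            r, c = np.argwhere(~ok)[0]
            raise ResponseLoadError(
                f"response {vals[r, c]!r} at row {r}, item {responses.columns[c]!r} "
                f"is not an integer in {RESPONSE_MIN}..{RESPONSE_MAX}"
            )
        n = len(responses)
        if covariates is None:
            covariates = pd.DataFrame(index=responses.index)
        if len(covariates) != n:
            raise ResponseLoadError("covariate length does not match respondent count")
        self.covariates = covariates
        self.respondent_ids = (
            list(respondent_ids) if respondent_ids is not None else list(range(n))
        )
        if len(self.respondent_ids) != n:
            raise ResponseLoadError("respondent id length mismatch")

    @property
    def n(self) -> int:
        return len(self.responses)

    @property
    def item_ids(self) -> list[str]:
        return list(self.responses.columns)

    def item(self, item_id: str) -> np.ndarray:
        return self.responses[item_id].to_numpy()

    def covariate(self, name: str) -> np.ndarray:
        return self.covariates[name].to_numpy()

    def subset_items(self, item_ids: list[str]) -> "ResponseMatrix":
        return ResponseMatrix(self.responses[list(item_ids)].copy(),
                              self.covariates.copy(), self.respondent_ids)

    def missing_counts(self) -> pd.Series:
        return self.responses.isna().sum()


def read_responses(path, instrument: InstrumentDefinition) -> ResponseMatrix:
    """Load a response CSV (header = item ids + covariates, NA/empty = missing).

    Reverse-scored items are recoded as 7 - x here, exactly once.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    raw = raw.replace({"": np.nan, "NA": np.nan})
    resp_ids = None
    if "respondent_id" in raw.columns:
        resp_ids = raw.pop("respondent_id").tolist()
    item_cols, cov_cols = {}, {}
    for col in raw.columns:
        if col in instrument.item_ids:
            s = pd.to_numeric(raw[col], errors="coerce")
            bad = s.isna() & raw[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ResponseLoadError(
                    f"non-numeric response {raw[col].iloc[row]!r} at row {row}, "
                    f"item {col!r}"
                )
            item_cols[col] = s
        elif col in instrument.covariates:
            if col in ("oxygen_use", "group"):
                cov_cols[col] = raw[col]
            else:
                cov_cols[col] = pd.to_numeric(raw[col])
        else:
            logger.warning("ignoring unknown column %r", col)
    missing_items = [i for i in instrument.item_ids if i not in item_cols]
    if missing_items:
        logger.warning("instrument items absent from file: %s", missing_items)
    responses = pd.DataFrame({i: item_cols[i] for i in instrument.item_ids
                              if i in item_cols})
    for it in instrument.items:
        if it.reverse_scored and it.id in responses:
            responses[it.id] = (RESPONSE_MAX + RESPONSE_MIN) - responses[it.id]
    cov = pd.DataFrame(cov_cols, index=responses.index)
    matrix = ResponseMatrix(responses, cov, resp_ids)
    for item_id, cnt in matrix.missing_counts().items():
        if cnt:
            logger.info("item %s: %d missing cells", item_id, cnt)
    return matrix


def write_responses(matrix: ResponseMatrix, path) -> None:
    """Write a ResponseMatrix back to CSV; missing cells are left empty."""
    out = matrix.responses.copy()
    out = out.astype("Int64")  # keeps integers while allowing <NA>
    out.insert(0, "respondent_id", matrix.respondent_ids)
    for col in matrix.covariates.columns:
        out[col] = matrix.covariates[col].to_numpy()
    out.to_csv(path, index=False, na_rep="")


def read_instrument(path) -> InstrumentDefinition:
    """Read an instrument definition from a YAML configuration file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return instrument_from_dict(doc)


def instrument_from_dict(doc: dict) -> InstrumentDefinition:
    if not doc or not doc.get("items"):
        raise InstrumentError("configuration declares no items")
    items = [
        ItemDef(
            id=str(d["id"]),
            left_anchor=d.get("left", d.get("left_anchor", "")),
            right_anchor=d.get("right", d.get("right_anchor", "")),
            domain=d.get("domain"),
            reverse_scored=bool(d.get("reverse_scored", False)),
        )
        for d in doc["items"]
    ]
    return InstrumentDefinition(
        items=items,
        domains=list(doc.get("domains", [])),
        standalone_items=list(doc.get("standalone_items", [])),
        covariates=list(doc.get("covariates", STANDARD_COVARIATES)),
    )


def read_config(path) -> AnalysisConfig:
    """Read the analysis thresholds from the ``config:`` block of a YAML file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return AnalysisConfig.from_dict(doc.get("config", {}) or {})


def write_instrument(instrument: InstrumentDefinition, path,
                     config: AnalysisConfig | None = None) -> None:
    doc = {
        "items": [
            {"id": it.id, "left": it.left_anchor, "right": it.right_anchor,
             "domain": it.domain, "reverse_scored": it.reverse_scored}
            for it in instrument.items
        ],
        "domains": list(instrument.domains),
        "standalone_items": list(instrument.standalone_items),
        "covariates": list(instrument.covariates),
    }
    if config is not None:
        doc["config"] = config.to_dict()
    text = yaml.safe_dump(doc, sort_keys=False)
    if isinstance(path, io.IOBase):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


@dataclass
class ValidationReport:
    issues: list[str]
    category_usage: dict[str, dict[int, int]]

    @property
    def ok(self) -> bool:
        return not self.issues


def validate(matrix: ResponseMatrix, instrument: InstrumentDefinition) -> ValidationReport:
    """Report-only consistency check of a matrix against an instrument."""
    issues = []
    usage: dict[str, dict[int, int]] = {}
    for item_id in instrument.item_ids:
        if item_id not in matrix.responses.columns:
            issues.append(f"instrument item {item_id!r} missing from matrix")
            continue
        v = matrix.item(item_id)
        obs = v[~np.isnan(v)].astype(int)
        usage[item_id] = {k: int((obs == k).sum())
                          for k in range(RESPONSE_MIN, RESPONSE_MAX + 1)}
        if obs.size == 0:
            issues.append(f"item {item_id!r}: 100% missing")
    extra = [c for c in matrix.responses.columns if c not in instrument.item_ids]
    for c in extra:
        issues.append(f"matrix column {c!r} not in instrument")
    return ValidationReport(issues, usage)
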
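"""The drug–tumor scenario registry: types, I/O, and validation.

A scenario registry has one row per drug–tumor example: the incremental
median overall-survival gain reported by the pivotal randomized trial, the
annual number of deaths eligible for the therapy in North America and
worldwide (optionally derived from site-level death counts and a molecular
or histologic subgroup fraction), and the discovery (patent surrogate) and
approval dates.  The packaged fixture ``"paper-2018"`` carries 27 published
examples of survival-prolonging therapies for advanced malignancies,
approved between 1998 and 2015, with their printed eligible counts and
printed discovery-to-approval durations stored as authoritative overrides.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, List, Optional, Tuple, Union

import pandas as pd

from ._rounding import round_half_away
from .dates import ApproximateDate

__all__ = [
    "SubgroupSpec",
    "TherapyScenario",
    "ScenarioTable",
    "ValidationIssue",
    "ValidationReport",
    "RegistryError",
    "BUILTIN_FIXTURES",
    "REGISTRY_COLUMNS",
    "derive_eligible",
    "load_registry",
    "write_registry",
    "validate_registry",
]

REGISTRY_COLUMNS = [
    "drug",
    "site",
    "subgroup_label",
    "subgroup_fraction",
    "survival_gain_years",
    "eligible_na",
    "eligible_ww",
    "site_deaths_na",
    "site_deaths_ww",
    "discovery_date",
    "approval_date",
    "duration_override_years",
    "reference_tags",
]

#: Built-in fixture identifiers mapped to packaged resource names.
BUILTIN_FIXTURES = {"paper-2018": "paper_2018.csv"}

#: Relative mismatch between a stored eligible count and the
#: site-deaths × fraction derivation above which validation warns.
MISMATCH_WARNING_THRESHOLD = 0.15


class RegistryError(ValueError):
    """Raised for unparseable or structurally invalid registry sources."""


@dataclass(frozen=True)
class SubgroupSpec:
    """A molecular/histologic subgroup within a tumor site.

    ``fraction`` is the subgroup's share of the site-level death pool
    (e.g. HER2-positive = 20% of breast cancers); ``1.0`` with label
    ``"all"`` means the whole site is eligible.
    """

    site_label: str
    subgroup_label: str
    fraction: float

    def __post_init__(self) -> None:
        if not (0.0 < self.fraction <= 1.0):
            raise ValueError(f"subgroup fraction must be in (0, 1], got {self.fraction}")


@dataclass(frozen=True)
class TherapyScenario:
    """One drug–tumor example: survival gain, eligible deaths, dates."""

    drug: str
    site: str
    subgroup: SubgroupSpec
    survival_gain_years: float
    eligible_na: float
    eligible_ww: float
    discovery: ApproximateDate
    approval: ApproximateDate
    site_deaths_na: Optional[float] = None
    site_deaths_ww: Optional[float] = None
    duration_override_years: Optional[float] = None
    reference_tags: Tuple[str, ...] = ()

    @property
    def key(self) -> Tuple[str, str, str]:
        return (self.drug, self.site, self.subgroup.subgroup_label)

    def eligible(self, region: str) -> float:
        if region == "north_america":
            return self.eligible_na
        if region == "worldwide":
            return self.eligible_ww
        raise ValueError(f"unknown region {region!r}")


@dataclass
class ScenarioTable:
    """An ordered, uniquely keyed collection of therapy scenarios."""

    rows: List[TherapyScenario]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[TherapyScenario]:
        return iter(self.rows)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ScenarioTable):
            return NotImplemented
        return self.rows == other.rows

    def to_dataframe(self) -> pd.DataFrame:
        """The registry as a pandas DataFrame in file-column order."""
        records = []
        for s in self.rows:
            records.append(
                {
                    "drug": s.drug,
                    "site": s.site,
                    "subgroup_label": s.subgroup.subgroup_label,
                    "subgroup_fraction": s.subgroup.fraction,
                    "survival_gain_years": s.survival_gain_years,
                    "eligible_na": s.eligible_na,
                    "eligible_ww": s.eligible_ww,
                    "site_deaths_na": s.site_deaths_na,
                    "site_deaths_ww": s.site_deaths_ww,
                    "discovery_date": s.discovery.isoformat(),
                    "approval_date": s.approval.isoformat(),
                    "duration_override_years": s.duration_override_years,
                    "reference_tags": ";".join(s.reference_tags),
                }
            )
        return pd.DataFrame.from_records(records, columns=REGISTRY_COLUMNS)


@dataclass(frozen=True)
class ValidationIssue:
    row_key: Tuple[str, str, str]
    severity: str  # "error" | "warning"
    message: str


@dataclass
class ValidationReport:
    issues: List[ValidationIssue] = field(default_factory=list)

    @property
    def errors(self) -> List[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> List[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    @property
    def has_errors(self) -> bool:
        return bool(self.errors)

    def __str__(self) -> str:
        if not self.issues:
            return "registry valid: no issues"
        lines = []
        for i in self.issues:
            lines.append(f"[{i.severity}] {'/'.join(i.row_key)}: {i.message}")
        return "\n".join(lines)


def derive_eligible(site_deaths: float, fraction: float) -> int:
    """Eligible annual deaths for a subgroup: ``site_deaths × fraction``,
    rounded half-away-from-zero to an integer.

    This is the subgroup-prevalence adjustment: when only a biomarker- or
    histology-defined subset of a tumor site benefits from a therapy, its
    eligible pool is the site-level annual deaths scaled by the published
    subgroup prevalence.
    """
    if site_deaths < 0:
        raise ValueError(f"site_deaths must be >= 0, got {site_deaths}")
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    return int(round_half_away(site_deaths * fraction))


# ---------------------------------------------------------------------------
# parsing helpers

def _parse_number(text: str, column: str, row_key: str):
    t = text.strip()
    try:
        if t and "." not in t and "e" not in t.lower():
            return int(t)
        return float(t)
    except ValueError:
        raise RegistryError(
            f"row {row_key}: cannot parse {column}={text!r} as a number"
        ) from None


def _row_to_scenario(raw: dict, row_key: str) -> TherapyScenario:
    def cell(col: str) -> str:
        v = raw.get(col)
        return "" if v is None or (isinstance(v, float) and pd.isna(v)) else str(v)

    def required_number(col: str):
        t = cell(col)
        if t == "":
            raise RegistryError(f"row {row_key}: missing required value in column {col!r}")
        return _parse_number(t, col, row_key)

    def optional_number(col: str):
        t = cell(col)
        return None if t == "" else _parse_number(t, col, row_key)

    try:
        discovery = ApproximateDate.parse(cell("discovery_date"))
        approval = ApproximateDate.parse(cell("approval_date"))
    except ValueError as exc:
        raise RegistryError(f"row {row_key}: {exc}") from None

    fraction = required_number("subgroup_fraction")
    try:
        subgroup = SubgroupSpec(
            site_label=cell("site"),
            subgroup_label=cell("subgroup_label") or "all",
            fraction=float(fraction),
        )
    except ValueError as exc:
        raise RegistryError(f"row {row_key}: {exc}") from None

    tags = tuple(t for t in cell("reference_tags").split(";") if t)
    return TherapyScenario(
        drug=cell("drug"),
        site=cell("site"),
        subgroup=subgroup,
        survival_gain_years=float(required_number("survival_gain_years")),
        eligible_na=required_number("eligible_na"),
        eligible_ww=required_number("eligible_ww"),
        site_deaths_na=optional_number("site_deaths_na"),
        site_deaths_ww=optional_number("site_deaths_ww"),
        discovery=discovery,
        approval=approval,
        duration_override_years=optional_number("duration_override_years"),
        reference_tags=tags,
    )


def load_registry(source: Union[str, Path]) -> ScenarioTable:
    """Load a scenario registry from a delimited file or a builtin fixture.

    Parameters
    ----------
    source : str or Path
        Either a path to a comma-separated registry file with the
        documented header, or a builtin fixture identifier
        (currently ``"paper-2018"``).

    Raises
    ------
    RegistryError
        On a missing/renamed column, a malformed date or number (the error
        names the offending row), an empty registry, or an unknown fixture
        identifier.
    """
    provenance = str(source)
    if isinstance(source, str) and source in BUILTIN_FIXTURES:
        resource = importlib.resources.files("lifeyears.data").joinpath(
            BUILTIN_FIXTURES[source]
        )
        with importlib.resources.as_file(resource) as path:
            df = pd.read_csv(path, dtype=str, keep_default_na=False)
        provenance = f"builtin:{source}"
    else:
        path = Path(source)
        if not path.exists():
            if isinstance(source, str) and "/" not in source and "." not in source:
                raise RegistryError(
                    f"unknown builtin fixture {source!r}; "
                    f"available: {sorted(BUILTIN_FIXTURES)}"
                )
            raise RegistryError(f"registry file not found: {path}")
        df = pd.read_csv(path, dtype=str, keep_default_na=False)

    missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise RegistryError(f"registry is missing required column(s): {missing}")
    if len(df) == 0:
        raise RegistryError("empty registry: no scenario rows")

    rows = []
    for idx, raw in enumerate(df.to_dict("records")):
        key = f"{idx + 1} ({raw.get('drug', '?')})"
        rows.append(_row_to_scenario(raw, key))
    return ScenarioTable(rows=rows, provenance=provenance)


def _format_number(value) -> str:
    if value is None:
        return ""
    if isinstance(value, int):
        return str(value)
    f = float(value)
    return str(int(f)) if f.is_integer() else repr(f)


def write_registry(table: ScenarioTable, path: Union[str, Path]) -> None:
    """Write a registry in the same delimited format :func:`load_registry`
    reads; numbers use full precision so the round trip is lossless."""
    lines = [",".join(REGISTRY_COLUMNS)]
    for s in table.rows:
        cells = [
            s.drug,
            s.site,
            s.subgroup.subgroup_label,
            _format_number(s.subgroup.fraction),
            _format_number(s.survival_gain_years),
            _format_number(s.eligible_na),
            _format_number(s.eligible_ww),
            _format_number(s.site_deaths_na),
            _format_number(s.site_deaths_ww),
            s.discovery.isoformat(),
            s.approval.isoformat(),
            _format_number(s.duration_override_years),
            ";".join(s.reference_tags),
        ]
        lines.append(",".join(cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def validate_registry(
    table: ScenarioTable,
    mismatch_threshold: float = MISMATCH_WARNING_THRESHOLD,
) -> ValidationReport:
    """Check registry invariants and return a report.

    Errors (block analysis): negative gains or counts, approval provably
    earlier than discovery, duplicate (drug, site, subgroup) keys, an empty
    table.  Warnings (do not block): a stored eligible count deviating from
    the ``site_deaths × fraction`` derivation by more than
    ``mismatch_threshold`` relative.
    """
    report = ValidationReport()
    if len(table) == 0:
        report.issues.append(
            ValidationIssue(("", "", ""), "error", "empty registry: no scenario rows")
        )
        return report

    seen = set()
    for s in table.rows:
        key = s.key
        if key in seen:
            report.issues.append(
                ValidationIssue(key, "error", "duplicate (drug, site, subgroup) key")
            )
        seen.add(key)

        if s.survival_gain_years < 0:
            report.issues.append(
                ValidationIssue(key, "error",
                                f"negative survival gain {s.survival_gain_years}")
            )
        for label, value in (
            ("eligible_na", s.eligible_na),
            ("eligible_ww", s.eligible_ww),
            ("site_deaths_na", s.site_deaths_na),
            ("site_deaths_ww", s.site_deaths_ww),
        ):
            if value is not None and value < 0:
                report.issues.append(
                    ValidationIssue(key, "error", f"negative {label}: {value}")
                )

        if s.approval.provably_before(s.discovery):
            report.issues.append(
                ValidationIssue(
                    key, "error",
                    f"approval {s.approval} earlier than discovery {s.discovery}",
                )
            )

        if s.duration_override_years is not None and s.duration_override_years < 0:
            report.issues.append(
                ValidationIssue(key, "error",
                                f"negative duration override {s.duration_override_years}")
            )

        for label, site_deaths, eligible in (
            ("north_america", s.site_deaths_na, s.eligible_na),
            ("worldwide", s.site_deaths_ww, s.eligible_ww),
        ):
            if site_deaths is None or site_deaths < 0 or eligible < 0:
                continue
            derived = site_deaths * s.subgroup.fraction
            rel = abs(eligible - derived) / max(eligible, 1)
            if rel > mismatch_threshold:
                report.issues.append(
                    ValidationIssue(
                        key, "warning",
                        f"{label} eligible {eligible} deviates "
                        f"{rel:.1%} from site_deaths x fraction = {derived:.0f}",
                    )
                )
    return report


def scale_row(scenario: TherapyScenario, gain_factor: float,
              na_factor: float, ww_factor: float) -> TherapyScenario:
    """Return a copy with the gain and the regional death counts scaled;
    used by the synthetic perturbation machinery."""
    return replace(
        scenario,
        survival_gain_years=scenario.survival_gain_years * gain_factor,
        eligible_na=scenario.eligible_na * na_factor,
        eligible_ww=scenario.eligible_ww * ww_factor,
        site_deaths_na=None if scenario.site_deaths_na is None
        else scenario.site_deaths_na * na_factor,
        site_deaths_ww=None if scenario.site_deaths_ww is None
        else scenario.site_deaths_ww * ww_factor,
    )
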
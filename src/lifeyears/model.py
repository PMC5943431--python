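"""The life-years-saved product model and its portfolio evaluation.

The model quantifies the human cost of slow drug development for lethal
disease with a deterministic product.  For one drug–tumor example with
median overall-survival gain Δs (years), eligible annual deaths E
(persons/year), and discovery-to-approval interval T (years):

* life-years gained per year of earlier availability  L = Δs · E
* life-years forgone over the whole development interval  LYL = L · T
* life-years saved had development taken T* years  S = L · max(0, T − T*)

A treated fraction p ∈ [0, 1] scales every quantity linearly, modelling
incomplete real-world uptake.  All arithmetic is in full precision;
integers appear only at presentation boundaries (half-away-from-zero).

The module exposes both plain functions for the row-level primitives and a
statsmodels-style pair of objects: :class:`LifeYearsModel` built from a
scenario registry, whose :meth:`~LifeYearsModel.fit` returns a
:class:`PortfolioResults` carrying per-row results, portfolio summaries and
a printable ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import pandas as pd

from ._rounding import round_half_away
from .aggregate import Summary, summarize
from .dates import duration_years
from .registry import (
    ScenarioTable,
    TherapyScenario,
    ValidationReport,
    load_registry,
    validate_registry,
)

__all__ = [
    "REGIONS",
    "AnalysisConfig",
    "RowResult",
    "PortfolioResults",
    "LifeYearsModel",
    "ValidationFailure",
    "life_years_per_acceleration_year",
    "life_years_lost",
    "acceleration_scenario",
    "apply_treated_fraction",
    "effective_duration",
    "evaluate_portfolio",
]

REGIONS = ("north_america", "worldwide")
MEDIAN_CONVENTIONS = ("standard", "paper-lower")
ROUNDING_MODES = ("full-precision", "presentation-integer")


class ValidationFailure(ValueError):
    """Raised when a portfolio evaluation is refused because the registry
    fails validation; carries the offending :class:`ValidationReport`."""

    def __init__(self, report: ValidationReport):
        self.report = report
        super().__init__(f"registry failed validation:\n{report}")


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of a portfolio evaluation.

    Parameters
    ----------
    target_years : float
        Counterfactual discovery-to-approval interval T*, years (default 5,
        the feasibility benchmark set by recent accelerated approvals).
    treated_fraction : float
        Fraction p of eligible patients actually treated, in [0, 1]
        (default 1: universal uptake).
    median_convention : {"standard", "paper-lower"}
        Which median headline reports quote; both are always computed.
    regions : tuple of {"north_america", "worldwide"}
        Regions to evaluate.
    rounding : {"full-precision", "presentation-integer"}
        Whether row results carry full precision or presentation integers.
    """

    target_years: float = 5.0
    treated_fraction: float = 1.0
    median_convention: str = "standard"
    regions: Tuple[str, ...] = REGIONS
    rounding: str = "full-precision"

    def __post_init__(self) -> None:
        if self.target_years < 0:
            raise ValueError(f"target_years must be >= 0, got {self.target_years}")
        if not (0.0 <= self.treated_fraction <= 1.0):
            raise ValueError(
                f"treated_fraction must be in [0, 1], got {self.treated_fraction}"
            )
        if self.median_convention not in MEDIAN_CONVENTIONS:
            raise ValueError(
                f"median_convention must be one of {MEDIAN_CONVENTIONS}, "
                f"got {self.median_convention!r}"
            )
        if len(self.regions) == 0:
            raise ValueError("no regions selected")
        unknown = [r for r in self.regions if r not in REGIONS]
        if unknown:
            raise ValueError(f"unknown region(s) {unknown}; valid: {REGIONS}")
        if self.rounding not in ROUNDING_MODES:
            raise ValueError(
                f"rounding must be one of {ROUNDING_MODES}, got {self.rounding!r}"
            )

    @classmethod
    def from_mapping(cls, mapping: dict) -> "AnalysisConfig":
        """Build a config from a (YAML/JSON-derived) key-value mapping;
        unknown keys are rejected, missing keys take the defaults."""
        known = {
            "target_years", "treated_fraction", "median_convention",
            "regions", "rounding",
        }
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = dict(mapping)
        if "regions" in kwargs:
            kwargs["regions"] = tuple(kwargs["regions"])
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# row-level primitives


def life_years_per_acceleration_year(survival_gain_years: float,
                                     eligible: float) -> float:
    """L = Δs × E: life-years gained per year of earlier drug availability,
    assuming every eligible patient is treated."""
    if survival_gain_years < 0:
        raise ValueError(f"survival gain must be >= 0, got {survival_gain_years}")
    if eligible < 0:
        raise ValueError(f"eligible count must be >= 0, got {eligible}")
    return survival_gain_years * eligible


def life_years_lost(per_year: float, duration: float) -> float:
    """LYL = L × T: life-years forgone between discovery and approval."""
    if per_year < 0:
        raise ValueError(f"per-year life-years must be >= 0, got {per_year}")
    if duration < 0:
        raise ValueError(f"duration must be >= 0, got {duration}")
    return per_year * duration


def acceleration_scenario(per_year: float, duration: float,
                          target_years: float) -> float:
    """S = L × max(0, T − T*): life-years saved had development taken
    ``target_years``; clamps at zero when the drug was already faster."""
    if per_year < 0 or duration < 0 or target_years < 0:
        raise ValueError("per_year, duration and target_years must all be >= 0")
    return per_year * max(0.0, duration - target_years)


def apply_treated_fraction(value: float, fraction: float) -> float:
    """Scale a life-year quantity by the treated fraction p ∈ [0, 1]."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"treated fraction must be in [0, 1], got {fraction}")
    return value * fraction


def effective_duration(scenario: TherapyScenario) -> float:
    """The development interval used in analysis: the registry's printed
    override when present, otherwise computed from the dates."""
    if scenario.duration_override_years is not None:
        return float(scenario.duration_override_years)
    return duration_years(scenario.discovery, scenario.approval)


# ---------------------------------------------------------------------------
# portfolio objects


@dataclass(frozen=True)
class RowResult:
    """Per-scenario outputs: L, T, LYL and S, per region."""

    key: Tuple[str, str, str]
    duration_years: float
    per_year: Dict[str, float]
    life_years_lost: Dict[str, float]
    scenario_saved: Dict[str, float]


@dataclass
class PortfolioResults:
    """Results of evaluating the product model over a whole registry.

    Attributes
    ----------
    rows : list of RowResult
        Per-scenario metrics in registry order.
    summaries : dict
        ``(metric, region) -> Summary``; the region key is ``"all"`` for
        region-independent metrics (duration, survival gain).
    config : AnalysisConfig
        The configuration the evaluation ran under.
    """

    rows: List[RowResult]
    summaries: Dict[Tuple[str, str], Summary]
    config: AnalysisConfig
    provenance: str = ""

    @property
    def n_scenarios(self) -> int:
        return len(self.rows)

    def metric(self, name: str, region: str) -> List[float]:
        """Per-row values of one metric in registry order."""
        if name == "duration":
            return [r.duration_years for r in self.rows]
        return [getattr(r, name)[region] for r in self.rows]

    def to_frame(self) -> pd.DataFrame:
        """Per-row results as a DataFrame (one row per scenario)."""
        records = []
        for r in self.rows:
            rec = {
                "drug": r.key[0],
                "site": r.key[1],
                "subgroup": r.key[2],
                "duration_years": r.duration_years,
            }
            for region in self.config.regions:
                short = "na" if region == "north_america" else "ww"
                rec[f"per_year_{short}"] = r.per_year[region]
                rec[f"life_years_lost_{short}"] = r.life_years_lost[region]
                rec[f"scenario_saved_{short}"] = r.scenario_saved[region]
            records.append(rec)
        return pd.DataFrame.from_records(records)

    def summary(self) -> str:
        """A printable portfolio summary table (both median conventions)."""
        c = self.config
        lines = [
            "Life-years saved model — portfolio summary",
            "=" * 58,
            f"scenarios: {self.n_scenarios}   regions: {', '.join(c.regions)}",
            f"target interval T*: {c.target_years} y   "
            f"treated fraction p: {c.treated_fraction}",
            f"headline median convention: {c.median_convention}",
            "-" * 58,
        ]
        header = (f"{'metric':<28}{'median(std)':>12}{'median(low)':>12}"
                  f"{'min':>10}{'max':>12}{'cumulative':>14}")
        lines.append(header)
        for (metric, region), s in self.summaries.items():
            label = metric if region == "all" else f"{metric}[{region}]"
            digits = 2 if metric in ("duration", "survival_gain") else 0

            def fmt(x: float) -> str:
                if digits:
                    return f"{x:,.2f}"
                return f"{round_half_away(x):,}"

            lines.append(
                f"{label:<28}{fmt(s.median_standard):>12}{fmt(s.median_paper):>12}"
                f"{fmt(s.minimum):>10}{fmt(s.maximum):>12}{fmt(s.cumulative):>14}"
            )
        lines.append("-" * 58)
        lines.append("per_year = median survival gain (years) x no. patients "
                     "dying per year;")
        lines.append("life_years_lost = per_year x discovery-to-approval years; "
                     "scenario_saved = per_year x max(0, T - T*).")
        return "\n".join(lines)


class LifeYearsModel:
    """Product model of life-years gained by faster drug approval.

    Parameters
    ----------
    table : ScenarioTable
        The drug–tumor scenario registry.
    config : AnalysisConfig, optional
        Evaluation configuration (defaults: T* = 5 years, p = 1, both
        regions, full precision).

    Examples
    --------
    >>> model = LifeYearsModel.from_registry("paper-2018")
    >>> results = model.fit()
    >>> print(results.summary())  # doctest: +SKIP
    """

    def __init__(self, table: ScenarioTable,
                 config: Optional[AnalysisConfig] = None):
        self.table = table
        self.config = config or AnalysisConfig()

    @classmethod
    def from_registry(cls, source,
                      config: Optional[AnalysisConfig] = None) -> "LifeYearsModel":
        """Build the model from a registry file path or builtin fixture id."""
        return cls(load_registry(source), config)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, provenance: str = "dataframe",
                       config: Optional[AnalysisConfig] = None) -> "LifeYearsModel":
        """Build the model from a DataFrame in registry-column layout."""
        from .registry import REGISTRY_COLUMNS, RegistryError, _row_to_scenario

        missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
        if missing:
            raise RegistryError(f"registry is missing required column(s): {missing}")
        if len(df) == 0:
            raise RegistryError("empty registry: no scenario rows")
        rows = []
        for idx, raw in enumerate(df.to_dict("records")):
            key = f"{idx + 1} ({raw.get('drug', '?')})"
            raw = {k: "" if v is None or (isinstance(v, float) and pd.isna(v))
                   else str(v) for k, v in raw.items()}
            rows.append(_row_to_scenario(raw, key))
        return cls(ScenarioTable(rows=rows, provenance=provenance), config)

    def fit(self, config: Optional[AnalysisConfig] = None) -> PortfolioResults:
        """Evaluate the model over every registry row.

        Refuses to run (raising :class:`ValidationFailure`) if the registry
        has validation errors; warnings do not block.
        """
        cfg = config or self.config
        report = validate_registry(self.table)
        if report.has_errors:
            raise ValidationFailure(report)

        p = cfg.treated_fraction
        present = cfg.rounding == "presentation-integer"

        rows: List[RowResult] = []
        for s in self.table.rows:
            T = effective_duration(s)
            per_year: Dict[str, float] = {}
            lost: Dict[str, float] = {}
            saved: Dict[str, float] = {}
            for region in cfg.regions:
                L = apply_treated_fraction(
                    life_years_per_acceleration_year(
                        s.survival_gain_years, s.eligible(region)
                    ),
                    p,
                )
                lyl = life_years_lost(L, T)
                sv = acceleration_scenario(L, T, cfg.target_years)
                if present:
                    L, lyl, sv = (round_half_away(L), round_half_away(lyl),
                                  round_half_away(sv))
                per_year[region] = L
                lost[region] = lyl
                saved[region] = sv
            rows.append(RowResult(key=s.key, duration_years=T, per_year=per_year,
                                  life_years_lost=lost, scenario_saved=saved))

        summaries: Dict[Tuple[str, str], Summary] = {}
        summaries[("survival_gain", "all")] = summarize(
            [s.survival_gain_years for s in self.table.rows]
        )
        summaries[("duration", "all")] = summarize([r.duration_years for r in rows])
        for metric in ("per_year", "life_years_lost", "scenario_saved"):
            for region in cfg.regions:
                summaries[(metric, region)] = summarize(
                    [getattr(r, metric)[region] for r in rows]
                )
        return PortfolioResults(rows=rows, summaries=summaries, config=cfg,
                                provenance=self.table.provenance)


def evaluate_portfolio(table: ScenarioTable,
                       config: Optional[AnalysisConfig] = None) -> PortfolioResults:
    """Functional entry point: evaluate the product model over a registry."""
    return LifeYearsModel(table, config).fit()
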
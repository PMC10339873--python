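"""Pipeline configuration: assay constants, QC thresholds, analysis parameters.

Every threshold used by the stage modules lives here so that a single YAML
file (plus ``--set key=value`` overrides) fully determines a pipeline run.
Defaults reproduce the published workflow: duplicate CV < 10%, inter-assay
CV < 16%, plate re-run above 50% duplicate failures, 1-SD baseline trim,
2-SD peak threshold, 48-h note window, 7-day chronic gap.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = [
    "AssayConfig",
    "PipelineConfig",
    "CORTISOL",
    "CORTICOSTERONE",
    "DEFAULT_ASSAYS",
    "ConfigError",
]


class ConfigError(ValueError):
    """Raised when a configuration value violates its constraints."""


@dataclass(frozen=True)
class AssayConfig:
    """Constants for one competitive EIA.

    Parameters
    ----------
    name
        Assay identifier (``cortisol`` or ``corticosterone``).
    standards_pg_ml
        The kit standard ladder, lowest first, in pg/mL.
    default_dilution
        Working sample dilution factor (1:10 cortisol, 1:30 corticosterone).
    bld_include_dilution
        Whether the below-detection imputation constant is multiplied by the
        working dilution. Off by default, which yields the conventional
        0.78 / 0.16 ng/g constants.
    """

    name: str
    standards_pg_ml: tuple[float, ...]
    default_dilution: float
    bld_include_dilution: bool = False

    def __post_init__(self) -> None:
        if len(self.standards_pg_ml) < 2:
            raise ConfigError(f"{self.name}: need at least 2 standards")
        if any(s <= 0 for s in self.standards_pg_ml):
            raise ConfigError(f"{self.name}: standards must be positive")
        if self.default_dilution <= 0:
            raise ConfigError(f"{self.name}: dilution must be positive")

    @property
    def min_standard_pg_ml(self) -> float:
        """Lowest standard; the assay's minimum detection limit."""
        return min(self.standards_pg_ml)

    @property
    def max_standard_pg_ml(self) -> float:
        return max(self.standards_pg_ml)

    @property
    def n_standards(self) -> int:
        return len(self.standards_pg_ml)


# Kit standard ladders (pg/mL) as printed in the manufacturer inserts:
# cortisol: seven two-fold standards; corticosterone: five five-fold standards.
CORTISOL = AssayConfig(
    name="cortisol",
    standards_pg_ml=(156.0, 313.0, 625.0, 1250.0, 2500.0, 5000.0, 10000.0),
    default_dilution=10.0,
)
CORTICOSTERONE = AssayConfig(
    name="corticosterone",
    standards_pg_ml=(32.0, 160.0, 800.0, 4000.0, 20000.0),
    default_dilution=30.0,
)
DEFAULT_ASSAYS: dict[str, AssayConfig] = {
    "cortisol": CORTISOL,
    "corticosterone": CORTICOSTERONE,
}


@dataclass
class PipelineConfig:
    """All tunable thresholds for a full quantify -> longitudinal run.

    Units: CV limits are percentages, masses grams, volumes millilitres,
    the note window hours, the chronic gap calendar days, SD multipliers
    dimensionless.
    """

    # extraction (0.20 +/- 0.02 g dry feces in 2 mL 90% methanol)
    extract_volume_ml: float = 2.0
    target_dry_mass_g: float = 0.20
    min_dry_mass_g: float = 0.18

    # plate QC cascade
    duplicate_cv_limit: float = 10.0
    intra_assay_cv_limit: float = 10.0
    inter_assay_cv_limit: float = 16.0
    plate_rerun_fraction: float = 0.5

    # validation
    parallelism_alpha: float = 0.05
    accuracy_r2_min: float = 0.95
    accuracy_slope_band: tuple[float, float] = (0.8, 1.2)
    linear_region_pb: tuple[float, float] = (20.0, 80.0)
    min_dilution_floor: float = 10.0

    # longitudinal analysis
    trim_sd: float = 1.0
    peak_sd: float = 2.0
    iterate_trim: bool = False
    note_window_hours: float = 48.0
    chronic_gap_days: int = 7

    seed: int = 0

    assays: dict[str, AssayConfig] = field(
        default_factory=lambda: dict(DEFAULT_ASSAYS)
    )

    def __post_init__(self) -> None:
        for name in (
            "extract_volume_ml",
            "target_dry_mass_g",
            "min_dry_mass_g",
            "duplicate_cv_limit",
            "intra_assay_cv_limit",
            "inter_assay_cv_limit",
            "trim_sd",
            "peak_sd",
            "note_window_hours",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0 < self.plate_rerun_fraction <= 1:
            raise ConfigError("plate_rerun_fraction must be in (0, 1]")
        if not 0 < self.parallelism_alpha < 1:
            raise ConfigError("parallelism_alpha must be in (0, 1)")
        if self.chronic_gap_days < 1:
            raise ConfigError("chronic_gap_days must be >= 1")

    def assay(self, name: str) -> AssayConfig:
        try:
            return self.assays[name]
        except KeyError:
            raise ConfigError(f"unknown assay {name!r}") from None

    # ---- serialization ---------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["accuracy_slope_band"] = list(self.accuracy_slope_band)
        d["linear_region_pb"] = list(self.linear_region_pb)
        d["assays"] = {
            k: {
                "standards_pg_ml": list(v.standards_pg_ml),
                "default_dilution": v.default_dilution,
                "bld_include_dilution": v.bld_include_dilution,
            }
            for k, v in self.assays.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        assays = d.pop("assays", None)
        if assays is not None:
            d["assays"] = {
                name: AssayConfig(
                    name=name,
                    standards_pg_ml=tuple(spec["standards_pg_ml"]),
                    default_dilution=float(spec["default_dilution"]),
                    bld_include_dilution=bool(
                        spec.get("bld_include_dilution", False)
                    ),
                )
                for name, spec in assays.items()
            }
        for key in ("accuracy_slope_band", "linear_region_pb"):
            if key in d:
                d[key] = tuple(d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        return cls.from_dict(data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def with_overrides(self, overrides: list[str]) -> "PipelineConfig":
        """Apply ``key=value`` overrides (dotted keys reach into assays)."""
        d = self.to_dict()
        for item in overrides:
            key, _, raw = item.partition("=")
            if not _:
                raise ConfigError(f"override {item!r} is not key=value")
            value = yaml.safe_load(raw)
            target: Any = d
            parts = key.split(".")
            for p in parts[:-1]:
                if p not in target:
                    raise ConfigError(f"unknown config key {key!r}")
                target = target[p]
            if parts[-1] not in target:
                raise ConfigError(f"unknown config key {key!r}")
            target[parts[-1]] = value
        return PipelineConfig.from_dict(d)
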
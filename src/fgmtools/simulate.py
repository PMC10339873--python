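"""Synthetic EIA plates, longitudinal FGM series, and note logs.

Every stage of the pipeline is testable against known ground truth:
plates are generated from a 4PL response with multiplicative lognormal OD
noise; per-animal series are lognormal baselines (FGM concentrations are
positive and right-skewed) with acute or chronic stress spikes injected
into both metabolites at a stated magnitude in units of the animal's
linear-scale SD; husbandry notes are emitted for a configured fraction of
injected events plus decoys. A ledger records every injected spike so that
detection sensitivity and specificity are always scored against the truth,
never against re-detected events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from .config import AssayConfig, DEFAULT_ASSAYS, PipelineConfig
from .plate import PlateRecord, Role, Well
from .quantify import ExtractionRecord, impute_bld

__all__ = [
    "PlateSimConfig",
    "AnimalSpec",
    "SeriesSimConfig",
    "SimConfig",
    "simulate_plate",
    "simulate_series",
    "DEFAULT_ROSTER",
]


@dataclass(frozen=True)
class PlateSimConfig:
    """Ground truth for plate simulation.

    The OD response is nsb_od + (b0_od - nsb_od) / (1 + (x/c)^b), i.e. a
    falling 4PL between maximum binding and background, with multiplicative
    lognormal noise of the stated CV applied to every well.
    """

    curve_b: float = 1.0
    curve_c_pg_ml: float | None = None  # default: geometric mid of standards
    noise_cv: float = 0.0
    b0_od: float = 1.0
    nsb_od: float = 0.05
    ta_od: float = 1.8
    blank_od: float = 0.04

    def c_for(self, assay: AssayConfig) -> float:
        if self.curve_c_pg_ml is not None:
            return self.curve_c_pg_ml
        return float(
            math.sqrt(assay.min_standard_pg_ml * assay.max_standard_pg_ml)
        )


@dataclass(frozen=True)
class AnimalSpec:
    """One animal's sampling regime and baseline distribution.

    ``log_mean``/``log_sd`` parameterize the lognormal baseline of each
    metabolite in ln(ng/g). Defaults put cortisol baselines in the tens of
    ng/g and corticosterone somewhat higher, with moderate right skew.
    """

    animal_id: str
    n_samples: int
    log_mean: dict[str, float] = field(
        default_factory=lambda: {"cortisol": math.log(30.0),
                                 "corticosterone": math.log(65.0)}
    )
    log_sd: dict[str, float] = field(
        default_factory=lambda: {"cortisol": 0.5, "corticosterone": 0.5}
    )
    n_acute_spikes: int = 0
    n_chronic_spikes: int = 0
    chronic_duration: int = 3  # consecutive sampled dates per chronic event
    samples_per_week: float = 2.0  # opportunistic daytime sampling rate
    start: date = date(2010, 1, 1)

    def linear_sd(self, assay: str) -> float:
        """SD of the lognormal baseline on the ng/g scale."""
        mu, s = self.log_mean[assay], self.log_sd[assay]
        return math.exp(mu + s * s / 2.0) * math.sqrt(math.expm1(s * s))


# Four-animal roster mirroring a long-term aquarium study: sample counts
# 233/122/72/60 and dual-spike counts 11/0/5/7.
DEFAULT_ROSTER: tuple[AnimalSpec, ...] = (
    AnimalSpec("M1", 233, n_acute_spikes=11, start=date(2008, 1, 1)),
    AnimalSpec("F1", 122, n_acute_spikes=0, start=date(1999, 1, 1)),
    AnimalSpec("F2", 72, n_acute_spikes=5, start=date(2006, 1, 1)),
    AnimalSpec("F3", 60, n_acute_spikes=7, start=date(2015, 1, 1)),
)


@dataclass(frozen=True)
class SeriesSimConfig:
    """Longitudinal simulation: roster, spikes, censoring, and notes."""

    animals: tuple[AnimalSpec, ...] = DEFAULT_ROSTER
    spike_magnitude_sd: float = 6.0  # spike height in animal-sigma units
    spike_jitter_log_sd: float = 0.1  # lognormal jitter on spike height
    rho: float = 0.9  # spike-height correlation between metabolites
    censor_bld: bool = True  # replace sub-detection values by BLD constant
    note_prob: float = 0.39  # P(note emitted for an injected event)
    decoy_notes_per_100_days: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")
        if self.spike_magnitude_sd < 0 or self.spike_jitter_log_sd < 0:
            raise ValueError("spike parameters must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Top-level simulation configuration; one seed drives everything."""

    seed: int = 0
    plate: PlateSimConfig = field(default_factory=PlateSimConfig)
    series: SeriesSimConfig = field(default_factory=SeriesSimConfig)


# ---- plate simulation ----------------------------------------------------

_POSITIONS = [f"{r}{c}" for r in "ABCDEFGH" for c in range(1, 13)]


def simulate_plate(
    sample_concs_pg_ml: Sequence[tuple[str, float]],
    assay: AssayConfig,
    config: PlateSimConfig | None = None,
    seed: int | np.random.Generator = 0,
    plate_id: str = "P1",
    dilution: float | None = None,
) -> tuple[PlateRecord, pd.DataFrame]:
    """Simulate one duplicate-well plate from known in-well concentrations.

    Parameters
    ----------
    sample_concs_pg_ml
        (sample_id, true concentration in the assayed well, pg/mL) pairs;
        concentrations may deliberately fall outside the standard range to
        exercise the BLD / above-curve paths.

    Returns the validated :class:`PlateRecord` and a truth table with the
    intended well concentration and the fecal ng/g each sample should
    quantify to (at the default 0.2 g / 2 mL extraction).
    """
    cfg = config or PlateSimConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dil = dilution if dilution is not None else assay.default_dilution
    c = cfg.c_for(assay)

    def od_true(x: float) -> float:
        frac = 1.0 / (1.0 + (x / c) ** cfg.curve_b) if x > 0 else 1.0
        return cfg.nsb_od + (cfg.b0_od - cfg.nsb_od) * frac

    def noisy(od: float) -> float:
        if cfg.noise_cv <= 0:
            return od
        return od * float(np.exp(cfg.noise_cv * rng.standard_normal()))

    wells: list[Well] = []
    pos = iter(_POSITIONS)

    def add(role: Role, od: float, **kw) -> None:
        wells.append(
            Well(plate_id=plate_id, position=next(pos), role=role,
                 od=max(noisy(od), 0.0), **kw)
        )

    for _ in range(2):
        add(Role.NSB, cfg.nsb_od)
    for _ in range(2):
        add(Role.TA, cfg.ta_od)
    for _ in range(2):
        add(Role.B0, cfg.b0_od)
    for _ in range(2):
        add(Role.BLANK, cfg.blank_od)
    for conc in assay.standards_pg_ml:
        for _ in range(2):
            add(Role.STANDARD, od_true(conc), standard_conc=conc)
    truth_rows = []
    for sample_id, conc in sample_concs_pg_ml:
        for _ in range(2):
            add(Role.SAMPLE, od_true(conc), sample_id=sample_id, dilution=dil)
        truth_rows.append(
            {
                "sample_id": sample_id,
                "true_well_conc_pg_ml": conc,
                "dilution": dil,
                "true_fecal_ng_g": conc / 1000.0 * dil * 2.0 / 0.2,
            }
        )
    plate = PlateRecord(plate_id=plate_id, assay=assay.name, wells=wells)
    return plate, pd.DataFrame(truth_rows)


def default_extractions(
    truth: pd.DataFrame,
    animal_id: str = "A1",
    start: date = date(2020, 1, 1),
) -> dict[str, ExtractionRecord]:
    """On-target (0.2 g / 2 mL) extraction records for simulated samples."""
    out = {}
    for i, r in enumerate(truth.itertuples()):
        out[str(r.sample_id)] = ExtractionRecord(
            sample_id=str(r.sample_id),
            animal_id=animal_id,
            collection_datetime=datetime.combine(
                start + timedelta(days=i), datetime.min.time()
            ) + timedelta(hours=9),
            dry_mass_g=0.2,
            solvent_volume_ml=2.0,
        )
    return out


# ---- longitudinal simulation ---------------------------------------------


def _detection_floor_ng_g(assay: AssayConfig, cfg: PipelineConfig) -> float:
    """Lowest quantifiable fecal concentration at the working dilution."""
    return (
        assay.min_standard_pg_ml / 1000.0
        * assay.default_dilution
        * cfg.extract_volume_ml
        / cfg.target_dry_mass_g
    )


def simulate_series(
    config: SimConfig | SeriesSimConfig | None = None,
    seed: int | None = None,
    assays: dict[str, AssayConfig] = DEFAULT_ASSAYS,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate dual-metabolite longitudinal series with injected spikes.

    Returns ``(series, ledger, notes)``:

    - ``series``: rows (animal_id, date, assay, conc_ng_g) — daily fecal
      concentrations after optional below-detection censoring to the BLD
      constant;
    - ``ledger``: one row per injected spike event (animal_id, kind,
      start_date, end_date, n_dates, magnitude_sd) — the ground truth for
      sensitivity scoring;
    - ``notes``: rows (animal_id, timestamp, category, text) with
      event-linked notes (within the 48-h lookback window of the event) for
      a ``note_prob`` fraction of injected events, plus random decoys.
    """
    if config is None:
        config = SimConfig()
    if isinstance(config, SeriesSimConfig):
        config = SimConfig(seed=seed if seed is not None else 0, series=config)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    scfg = config.series
    pipe = PipelineConfig()

    series_rows: list[dict] = []
    ledger_rows: list[dict] = []
    note_rows: list[dict] = []
    event_categories = [
        "health", "enrichment", "exhibit_shift", "normal_behavior",
    ]

    for spec in scfg.animals:
        span_days = max(
            int(round(spec.n_samples / spec.samples_per_week * 7.0)),
            spec.n_samples,
        )
        day_offsets = np.sort(
            rng.choice(span_days, size=spec.n_samples, replace=False)
        )
        days = [spec.start + timedelta(days=int(o)) for o in day_offsets]

        values = {
            a: np.exp(
                rng.normal(spec.log_mean[a], spec.log_sd[a], spec.n_samples)
            )
            for a in ("cortisol", "corticosterone")
        }

        # choose non-overlapping spike start indices, separated enough that
        # acute events never merge into runs
        n_events = spec.n_acute_spikes + spec.n_chronic_spikes
        spike_idx: list[int] = []
        if n_events:
            min_gap = spec.chronic_duration + 1
            candidates = np.arange(spec.n_samples - spec.chronic_duration)
            rng.shuffle(candidates)
            for i in candidates:
                if all(abs(i - j) >= min_gap for j in spike_idx):
                    spike_idx.append(int(i))
                if len(spike_idx) == n_events:
                    break
            if len(spike_idx) < n_events:
                raise ValueError(
                    f"{spec.animal_id}: cannot place {n_events} spikes in "
                    f"{spec.n_samples} samples"
                )
        kinds = ["acute"] * spec.n_acute_spikes + ["chronic"] * spec.n_chronic_spikes

        for i0, kind in zip(spike_idx, kinds):
            length = 1 if kind == "acute" else spec.chronic_duration
            idxs = list(range(i0, i0 + length))
            for i in idxs:
                z1 = rng.standard_normal()
                z2 = scfg.rho * z1 + math.sqrt(1.0 - scfg.rho**2) * rng.standard_normal()
                for a, z in (("cortisol", z1), ("corticosterone", z2)):
                    mag = scfg.spike_magnitude_sd * math.exp(
                        scfg.spike_jitter_log_sd * z
                    )
                    values[a][i] += mag * spec.linear_sd(a)
            ledger_rows.append(
                {
                    "animal_id": spec.animal_id,
                    "kind": kind,
                    "start_date": days[idxs[0]].isoformat(),
                    "end_date": days[idxs[-1]].isoformat(),
                    "n_dates": length,
                    "magnitude_sd": scfg.spike_magnitude_sd,
                }
            )
            if rng.random() < scfg.note_prob:
                note_day = days[idxs[0]] - timedelta(days=int(rng.integers(0, 2)))
                note_rows.append(
                    {
                        "animal_id": spec.animal_id,
                        "timestamp": datetime.combine(
                            note_day, datetime.min.time()
                        ).replace(hour=int(rng.integers(7, 17))).isoformat(),
                        "category": str(rng.choice(event_categories)),
                        "text": f"injected {kind} event",
                    }
                )

        # decoy notes on random non-event days
        n_decoys = rng.poisson(scfg.decoy_notes_per_100_days * span_days / 100.0)
        for _ in range(int(n_decoys)):
            d = spec.start + timedelta(days=int(rng.integers(0, span_days)))
            note_rows.append(
                {
                    "animal_id": spec.animal_id,
                    "timestamp": datetime.combine(d, datetime.min.time())
                    .replace(hour=int(rng.integers(7, 17)))
                    .isoformat(),
                    "category": str(
                        rng.choice(["normal_behavior", "environment", "other"])
                    ),
                    "text": "routine observation",
                }
            )

        for a in ("cortisol", "corticosterone"):
            vals = values[a]
            if scfg.censor_bld:
                floor = _detection_floor_ng_g(assays[a], pipe)
                bld = impute_bld(assays[a], pipe.extract_volume_ml,
                                 pipe.target_dry_mass_g)
                vals = np.where(vals < floor, bld, vals)
            for d, v in zip(days, vals):
                series_rows.append(
                    {
                        "animal_id": spec.animal_id,
                        "date": d.isoformat(),
                        "assay": a,
                        "conc_ng_g": float(v),
                    }
                )

    series = pd.DataFrame(
        series_rows, columns=["animal_id", "date", "assay", "conc_ng_g"]
    )
    ledger = pd.DataFrame(
        ledger_rows,
        columns=["animal_id", "kind", "start_date", "end_date", "n_dates",
                 "magnitude_sd"],
    )
    notes = pd.DataFrame(
        note_rows, columns=["animal_id", "timestamp", "category", "text"]
    )
    notes = notes.sort_values(["animal_id", "timestamp"], kind="stable").reset_index(
        drop=True
    )
    return series, ledger, notes
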
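"""Plate responses -> final ng/g dry-feces concentrations with QC.

Implements the quantification cascade: duplicate-mean percent bound,
4PL back-calculation, dilution and extraction corrections
(C_fecal = C_extract * D * V / m), the duplicate-CV / standards / 50%-failure
re-run rules, below-detection imputation at half the lowest standard, and
the sub-mass discard rule for extractions under 0.18 g.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import AssayConfig, ConfigError, DEFAULT_ASSAYS, PipelineConfig
from .curve import CurveRangeError, RangeSide, StandardCurve, inverse_4pl
from .plate import PlateRecord, duplicate_cv

__all__ = [
    "ExtractionRecord",
    "Measurement",
    "QCReport",
    "QCFlag",
    "to_fecal_concentration",
    "impute_bld",
    "apply_qc",
    "quantify_plate",
    "supersede_reruns",
    "inter_assay_cv",
    "read_extractions",
    "write_measurements",
    "read_measurements",
]


class QCFlag:
    """String constants used in Measurement.qc_flags."""

    DUP_CV_FAIL = "DUP_CV_FAIL"
    RERUN = "RERUN"
    ABOVE_CURVE = "ABOVE_CURVE"
    BLD_IMPUTED = "BLD_IMPUTED"
    MASS_DISCARD = "MASS_DISCARD"


@dataclass(frozen=True)
class ExtractionRecord:
    """One fecal extraction: 0.20 +/- 0.02 g dry feces in 2 mL solvent."""

    sample_id: str
    animal_id: str
    collection_datetime: datetime
    dry_mass_g: float
    solvent_volume_ml: float = 2.0

    def __post_init__(self) -> None:
        if self.dry_mass_g <= 0:
            raise ValueError(f"{self.sample_id}: dry_mass_g must be > 0")
        if self.solvent_volume_ml <= 0:
            raise ValueError(f"{self.sample_id}: solvent_volume_ml must be > 0")


@dataclass
class Measurement:
    """Final quantified sample: ng analyte per g dry feces, with QC flags."""

    sample_id: str
    animal_id: str
    date: datetime
    assay: str
    extract_conc_ng_ml: float  # concentration in the assayed (diluted) extract
    dilution_factor: float
    fecal_conc_ng_g: float  # NaN when discarded or awaiting re-run
    qc_flags: set[str] = field(default_factory=set)
    plate_id: str = ""

    @property
    def usable(self) -> bool:
        """True when the value can enter a longitudinal series as-is."""
        blocking = {QCFlag.DUP_CV_FAIL, QCFlag.RERUN, QCFlag.ABOVE_CURVE,
                    QCFlag.MASS_DISCARD}
        return not (self.qc_flags & blocking) and math.isfinite(
            self.fecal_conc_ng_g
        )


@dataclass
class QCReport:
    """Per-plate QC outcome under the duplicate-CV cascade."""

    plate_id: str
    duplicate_failures: list[str]  # failing sample_ids
    n_samples: int
    standards_cv_fail: bool
    plate_rerun_required: bool
    intra_assay_cv: float  # mean sample-duplicate CV on this plate, %
    inter_assay_cv: float | None = None  # CV of a pooled control across plates
    intra_pass: bool = True
    inter_pass: bool | None = None


def to_fecal_concentration(
    extract_conc_ng_ml: float,
    dilution: float,
    volume_ml: float,
    mass_g: float,
) -> float:
    """ng/g dry feces = C_extract (ng/mL, in the diluted extract) * D * V / m."""
    for name, v in (
        ("extract_conc_ng_ml", extract_conc_ng_ml),
        ("dilution", dilution),
        ("volume_ml", volume_ml),
        ("mass_g", mass_g),
    ):
        if v <= 0 or not math.isfinite(v):
            raise ValueError(f"{name} must be positive and finite, got {v}")
    return extract_conc_ng_ml * dilution * volume_ml / mass_g


def impute_bld(
    assay: str | AssayConfig,
    volume_ml: float = 2.0,
    mass_g: float = 0.2,
    assays: Mapping[str, AssayConfig] = DEFAULT_ASSAYS,
) -> float:
    """Below-detection value: halfway between zero and the lowest standard.

    The midpoint concentration (min standard / 2, pg/mL -> ng/mL) is
    converted to dry-feces units with the extraction ratio V/m alone; the
    working dilution is NOT applied unless the assay config sets
    ``bld_include_dilution``. With the kit minimum standards this yields
    0.78 ng/g (cortisol, 156 pg/mL) and 0.16 ng/g (corticosterone,
    32 pg/mL).
    """
    if isinstance(assay, str):
        try:
            cfg = assays[assay]
        except KeyError:
            raise ConfigError(f"unknown assay {assay!r}") from None
    else:
        cfg = assay
    min_std_ng_ml = cfg.min_standard_pg_ml / 1000.0
    value = 0.5 * min_std_ng_ml * volume_ml / mass_g
    if cfg.bld_include_dilution:
        value *= cfg.default_dilution
    return value


def apply_qc(
    plate: PlateRecord,
    curve: StandardCurve | None = None,
    config: PipelineConfig | None = None,
) -> QCReport:
    """Apply the duplicate-CV cascade to one plate.

    A sample duplicate fails at CV >= 10%; a failing standard set, or more
    than 50% of sample duplicates failing, forces a whole-plate re-run.
    Intra-assay CV is the mean sample-duplicate CV on the plate; the
    inter-assay CV needs a control tracked across plates (see
    :func:`inter_assay_cv`) and is left unset here.
    """
    cfg = config or PipelineConfig()
    limit = cfg.duplicate_cv_limit

    failures = [
        sid
        for sid, (od1, od2) in plate.sample_pairs().items()
        if not duplicate_cv(od1, od2, limit).passed
    ]
    standards_fail = any(
        not duplicate_cv(od1, od2, limit).passed
        for od1, od2 in plate.standard_pairs().values()
    )
    sample_cvs = [
        duplicate_cv(od1, od2, limit).cv_percent
        for od1, od2 in plate.sample_pairs().values()
    ]
    n_samples = len(sample_cvs)
    frac_fail = len(failures) / n_samples if n_samples else 0.0
    rerun = standards_fail or frac_fail > cfg.plate_rerun_fraction
    intra = float(np.mean(sample_cvs)) if sample_cvs else 0.0
    return QCReport(
        plate_id=plate.plate_id,
        duplicate_failures=failures,
        n_samples=n_samples,
        standards_cv_fail=standards_fail,
        plate_rerun_required=rerun,
        intra_assay_cv=intra,
        intra_pass=intra < cfg.intra_assay_cv_limit,
    )


def inter_assay_cv(control_values: Sequence[float]) -> float | None:
    """CV% of a pooled control sample measured across plates (None if < 2)."""
    vals = np.asarray(list(control_values), dtype=float)
    if vals.size < 2:
        return None
    mean = vals.mean()
    if mean == 0:
        return None
    return float(100.0 * vals.std(ddof=1) / mean)


def quantify_plate(
    plate: PlateRecord,
    curve: StandardCurve,
    extractions: Mapping[str, ExtractionRecord],
    config: PipelineConfig | None = None,
) -> list[Measurement]:
    """Quantify every sample on a plate.

    Each sample: duplicate-mean OD -> %B -> inverse 4PL -> pg/mL in the
    assayed dilution -> ng/mL -> ng/g via the extraction ratio. Samples
    below the calibrated range (or the zero-dose asymptote) receive the
    assay's BLD constant with BLD_IMPUTED; samples above it are flagged
    ABOVE_CURVE with no concentration (re-run at higher dilution expected);
    failing duplicates are flagged DUP_CV_FAIL + RERUN; extractions under
    the minimum dry mass are flagged MASS_DISCARD with no concentration.
    """
    cfg = config or PipelineConfig()
    assay_cfg = cfg.assay(plate.assay)
    qc = apply_qc(plate, curve, cfg)
    out: list[Measurement] = []

    for sid, (od1, od2) in plate.sample_pairs().items():
        if sid not in extractions:
            raise KeyError(f"sample {sid!r} has no extraction record")
        ext = extractions[sid]
        dilution = plate.sample_dilution(sid) or assay_cfg.default_dilution
        m = Measurement(
            sample_id=sid,
            animal_id=ext.animal_id,
            date=ext.collection_datetime,
            assay=plate.assay,
            extract_conc_ng_ml=float("nan"),
            dilution_factor=dilution,
            fecal_conc_ng_g=float("nan"),
            plate_id=plate.plate_id,
        )
        if ext.dry_mass_g < cfg.min_dry_mass_g:
            m.qc_flags.add(QCFlag.MASS_DISCARD)
            out.append(m)
            continue
        pair = duplicate_cv(od1, od2, cfg.duplicate_cv_limit)
        if not pair.passed or qc.plate_rerun_required:
            m.qc_flags |= {QCFlag.DUP_CV_FAIL, QCFlag.RERUN}
            if qc.plate_rerun_required and pair.passed:
                m.qc_flags.discard(QCFlag.DUP_CV_FAIL)

        pb = plate.percent_bound_of(pair.mean_od)
        try:
            well_conc_pg_ml = inverse_4pl(pb, curve)
        except CurveRangeError as err:
            if err.side is RangeSide.ABOVE_CURVE:
                m.qc_flags.add(QCFlag.ABOVE_CURVE)
                out.append(m)
                continue
            well_conc_pg_ml = 0.0  # below the zero-dose asymptote -> BLD

        if well_conc_pg_ml < curve.range_low:
            m.fecal_conc_ng_g = impute_bld(
                assay_cfg, cfg.extract_volume_ml, cfg.target_dry_mass_g
            )
            m.qc_flags.add(QCFlag.BLD_IMPUTED)
        elif well_conc_pg_ml > curve.range_high:
            m.qc_flags.add(QCFlag.ABOVE_CURVE)
        else:
            m.extract_conc_ng_ml = well_conc_pg_ml / 1000.0
            m.fecal_conc_ng_g = to_fecal_concentration(
                m.extract_conc_ng_ml,
                dilution,
                ext.solvent_volume_ml,
                ext.dry_mass_g,
            )
        out.append(m)
    return out


def supersede_reruns(measurements: Iterable[Measurement]) -> list[Measurement]:
    """Latest usable measurement per (sample, assay) wins; audit trail kept.

    Returns the effective measurement list: for each (sample_id, assay) the
    last usable entry in input order, else the last entry (still flagged).
    """
    by_key: dict[tuple[str, str], Measurement] = {}
    for m in measurements:
        key = (m.sample_id, m.assay)
        prev = by_key.get(key)
        if prev is None or m.usable or not prev.usable:
            by_key[key] = m
    return list(by_key.values())


# ---- CSV I/O ------------------------------------------------------------


def read_extractions(path: str) -> dict[str, ExtractionRecord]:
    """Read extractions.csv: sample_id, animal_id, collection_datetime,
    dry_mass_g, solvent_volume_ml."""
    df = pd.read_csv(
        path, dtype={"sample_id": str, "animal_id": str},
        float_precision="round_trip",
    )
    out = {}
    for r in df.itertuples():
        out[str(r.sample_id)] = ExtractionRecord(
            sample_id=str(r.sample_id),
            animal_id=str(r.animal_id),
            collection_datetime=pd.Timestamp(r.collection_datetime).to_pydatetime(),
            dry_mass_g=float(r.dry_mass_g),
            solvent_volume_ml=float(getattr(r, "solvent_volume_ml", 2.0)),
        )
    return out


def write_measurements(measurements: Sequence[Measurement], path: str) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "animal_id": m.animal_id,
            "date": pd.Timestamp(m.date).isoformat(),
            "assay": m.assay,
            "plate_id": m.plate_id,
            "extract_conc_ng_ml": m.extract_conc_ng_ml,
            "dilution_factor": m.dilution_factor,
            "fecal_conc_ng_g": m.fecal_conc_ng_g,
            "qc_flags": ";".join(sorted(m.qc_flags)),
        }
        for m in measurements
    ]
    pd.DataFrame(
        rows,
        columns=[
            "sample_id", "animal_id", "date", "assay", "plate_id",
            "extract_conc_ng_ml", "dilution_factor", "fecal_conc_ng_g",
            "qc_flags",
        ],
    ).to_csv(path, index=False)


def read_measurements(path: str) -> list[Measurement]:
    df = pd.read_csv(
        path, dtype={"sample_id": str, "animal_id": str},
        float_precision="round_trip",
    )
    out = []
    for r in df.itertuples():
        flags = set()
        raw = getattr(r, "qc_flags", "")
        if isinstance(raw, str) and raw:
            flags = set(raw.split(";"))
        out.append(
            Measurement(
                sample_id=str(r.sample_id),
                animal_id=str(r.animal_id),
                date=pd.Timestamp(r.date).to_pydatetime(),
                assay=str(r.assay),
                extract_conc_ng_ml=float(r.extract_conc_ng_ml),
                dilution_factor=float(r.dilution_factor),
                fecal_conc_ng_g=float(r.fecal_conc_ng_g),
                qc_flags=flags,
                plate_id=str(getattr(r, "plate_id", "")),
            )
        )
    return out
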
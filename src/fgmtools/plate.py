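"""96-well EIA plate model and CSV I/O.

A competitive enzyme immunoassay plate carries, all in duplicate:
non-specific-binding (NSB) wells, total-activity (TA) wells, zero-standard
blanks, maximum-binding (B0) wells, a full standard ladder, and samples.
This module validates that structure, transforms optical densities to
percent antibody bound (%B/B0), and applies the duplicate-CV rule.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

__all__ = [
    "Role",
    "Well",
    "PlateRecord",
    "DuplicatePair",
    "PlateLayoutError",
    "PlateDataError",
    "PlateFailureError",
    "read_plate",
    "write_plate",
    "percent_bound",
    "duplicate_cv",
]

ROWS = "ABCDEFGH"
COLUMNS = range(1, 13)
VALID_POSITIONS = frozenset(f"{r}{c}" for r in ROWS for c in COLUMNS)


class PlateLayoutError(ValueError):
    """Layout violates plate invariants (missing duplicates, unmapped wells)."""


class PlateDataError(ValueError):
    """OD data is invalid (negative readings, missing wells)."""


class PlateFailureError(ValueError):
    """The plate itself failed (e.g. maximum binding not above background)."""


class Role(str, enum.Enum):
    NSB = "NSB"
    TA = "TA"
    B0 = "B0"
    BLANK = "BLANK"
    STANDARD = "STANDARD"
    SAMPLE = "SAMPLE"


#: control roles that must each appear exactly twice on a plate
CONTROL_ROLES = (Role.NSB, Role.TA, Role.B0, Role.BLANK)


@dataclass(frozen=True)
class Well:
    """One well: position, role, and its 405-nm optical density."""

    plate_id: str
    position: str
    role: Role
    od: float
    standard_conc: float | None = None  # pg/mL, STANDARD wells only
    sample_id: str | None = None  # SAMPLE wells only
    dilution: float | None = None  # SAMPLE wells only

    def __post_init__(self) -> None:
        if self.position not in VALID_POSITIONS:
            raise PlateLayoutError(
                f"invalid well position {self.position!r} (expected A1..H12)"
            )
        if not math.isfinite(self.od) or self.od < 0:
            raise PlateDataError(
                f"well {self.position}: OD must be finite and >= 0, got {self.od}"
            )
        if self.role is Role.STANDARD:
            if self.standard_conc is None or self.standard_conc <= 0:
                raise PlateLayoutError(
                    f"well {self.position}: STANDARD requires standard_conc > 0"
                )
        elif self.standard_conc is not None:
            raise PlateLayoutError(
                f"well {self.position}: standard_conc only valid for STANDARD"
            )
        if self.role is Role.SAMPLE:
            if not self.sample_id:
                raise PlateLayoutError(
                    f"well {self.position}: SAMPLE requires sample_id"
                )
        elif self.sample_id is not None:
            raise PlateLayoutError(
                f"well {self.position}: sample_id only valid for SAMPLE"
            )


@dataclass(frozen=True)
class DuplicatePair:
    """Duplicate-well agreement: mean OD, CV%, and the <10% pass flag."""

    mean_od: float
    cv_percent: float
    passed: bool


def duplicate_cv(od1: float, od2: float, cv_limit: float = 10.0) -> DuplicatePair:
    """CV% between duplicate ODs, with the strict ``< cv_limit`` pass rule.

    Uses the sample standard deviation (n-1 denominator), which for two
    values is |od1 - od2| / sqrt(2).
    """
    if od1 < 0 or od2 < 0:
        raise PlateDataError("duplicate ODs must be >= 0")
    mean = (od1 + od2) / 2.0
    if mean == 0:
        raise PlateDataError("duplicate mean OD is zero; CV undefined")
    sd = abs(od1 - od2) / math.sqrt(2.0)
    cv = 100.0 * sd / mean
    return DuplicatePair(mean_od=mean, cv_percent=cv, passed=cv < cv_limit)


def percent_bound(sample_od: float, nsb_mean: float, b0_mean: float) -> float:
    """Percent antibody bound: 100 * (OD - NSB) / (B0 - NSB).

    Anchored so that the B0 (maximum binding) OD maps to 100 and the NSB
    (background) OD maps to 0. Raises :class:`PlateFailureError` when
    maximum binding does not exceed background.
    """
    if b0_mean <= nsb_mean:
        raise PlateFailureError(
            f"maximum binding (B0={b0_mean}) not above background (NSB={nsb_mean})"
        )
    return 100.0 * (sample_od - nsb_mean) / (b0_mean - nsb_mean)


@dataclass
class PlateRecord:
    """A validated EIA plate: wells grouped by role with duplicate structure."""

    plate_id: str
    assay: str
    wells: list[Well] = field(default_factory=list)
    read_wavelength: float = 405.0

    #: expected number of distinct standards per assay; other assay names
    #: are accepted with any ladder of >= 2 standards
    EXPECTED_STANDARDS = {"cortisol": 7, "corticosterone": 5}

    def __post_init__(self) -> None:
        self.validate()

    # ---- validation ------------------------------------------------------

    def validate(self) -> None:
        positions = [w.position for w in self.wells]
        if len(set(positions)) != len(positions):
            dupes = sorted({p for p in positions if positions.count(p) > 1})
            raise PlateLayoutError(f"duplicate well positions: {dupes}")

        for role in CONTROL_ROLES:
            n = sum(1 for w in self.wells if w.role is role)
            if n != 2:
                raise PlateLayoutError(
                    f"plate {self.plate_id}: duplicate required for {role.value} "
                    f"wells (found {n}, expected 2)"
                )
        for conc, ws in self._group_standards().items():
            if len(ws) != 2:
                raise PlateLayoutError(
                    f"plate {self.plate_id}: duplicate required for standard "
                    f"{conc} pg/mL (found {len(ws)})"
                )
        for sid, ws in self._group_samples().items():
            if len(ws) != 2:
                raise PlateLayoutError(
                    f"plate {self.plate_id}: duplicate required for sample "
                    f"{sid!r} (found {len(ws)})"
                )
            dils = {w.dilution for w in ws}
            if len(dils) != 1:
                raise PlateLayoutError(
                    f"plate {self.plate_id}: sample {sid!r} duplicates disagree "
                    f"on dilution {sorted(dils)}"
                )
        expected = self.EXPECTED_STANDARDS.get(self.assay)
        n_std = len(self._group_standards())
        if expected is not None and n_std != expected:
            raise PlateLayoutError(
                f"plate {self.plate_id}: {self.assay} plate requires {expected} "
                f"standards, found {n_std}"
            )
        if expected is None and n_std < 2:
            raise PlateLayoutError(
                f"plate {self.plate_id}: at least 2 standards required"
            )

    # ---- grouped accessors ----------------------------------------------

    def _group_standards(self) -> dict[float, list[Well]]:
        out: dict[float, list[Well]] = {}
        for w in self.wells:
            if w.role is Role.STANDARD:
                out.setdefault(float(w.standard_conc), []).append(w)
        return out

    def _group_samples(self) -> dict[str, list[Well]]:
        out: dict[str, list[Well]] = {}
        for w in self.wells:
            if w.role is Role.SAMPLE:
                out.setdefault(w.sample_id, []).append(w)
        return out

    def control_pair(self, role: Role) -> tuple[float, float]:
        ods = [w.od for w in self.wells if w.role is role]
        return ods[0], ods[1]

    @property
    def nsb_mean(self) -> float:
        return sum(self.control_pair(Role.NSB)) / 2.0

    @property
    def b0_mean(self) -> float:
        return sum(self.control_pair(Role.B0)) / 2.0

    def standard_pairs(self) -> dict[float, tuple[float, float]]:
        """Standard concentration (pg/mL) -> its duplicate ODs, ascending dose."""
        groups = self._group_standards()
        return {
            conc: (groups[conc][0].od, groups[conc][1].od)
            for conc in sorted(groups)
        }

    def sample_pairs(self) -> dict[str, tuple[float, float]]:
        groups = self._group_samples()
        return {sid: (ws[0].od, ws[1].od) for sid, ws in sorted(groups.items())}

    def sample_dilution(self, sample_id: str) -> float | None:
        for w in self.wells:
            if w.role is Role.SAMPLE and w.sample_id == sample_id:
                return w.dilution
        raise KeyError(sample_id)

    def percent_bound_of(self, od: float) -> float:
        return percent_bound(od, self.nsb_mean, self.b0_mean)


# ---- CSV I/O ------------------------------------------------------------

LAYOUT_COLUMNS = [
    "plate_id",
    "well",
    "role",
    "standard_conc_pg_ml",
    "sample_id",
    "dilution",
]
OD_COLUMNS = ["plate_id", "well", "od"]


def read_plate(
    layout_path: str, od_path: str, assay: str | None = None
) -> PlateRecord | list[PlateRecord]:
    """Read layout + OD CSV exports into validated :class:`PlateRecord` s.

    The layout CSV maps well positions to roles/IDs (columns
    ``plate_id, well, role, standard_conc_pg_ml, sample_id, dilution``); the
    OD CSV gives one OD per position. The layout may optionally carry an
    ``assay`` column; otherwise pass ``assay=``. Returns a single record if
    the files describe one plate, else a list (one per plate_id).
    """
    layout = pd.read_csv(
        layout_path, dtype={"plate_id": str, "sample_id": str},
        float_precision="round_trip",
    )
    ods = pd.read_csv(od_path, dtype={"plate_id": str}, float_precision="round_trip")
    for col in ("plate_id", "well", "role"):
        if col not in layout.columns:
            raise PlateLayoutError(f"layout missing column {col!r}")
    for col in OD_COLUMNS:
        if col not in ods.columns:
            raise PlateDataError(f"od file missing column {col!r}")

    od_map = {
        (str(r.plate_id), str(r.well)): float(r.od) for r in ods.itertuples()
    }
    layout_keys = {
        (str(r.plate_id), str(r.well)) for r in layout.itertuples()
    }
    unmapped = sorted(set(od_map) - layout_keys)
    if unmapped:
        raise PlateLayoutError(
            f"OD given for wells absent from layout: {unmapped[:5]}"
        )

    plates: list[PlateRecord] = []
    for plate_id, sub in layout.groupby("plate_id", sort=True):
        wells = []
        for r in sub.itertuples():
            key = (str(plate_id), str(r.well))
            if key not in od_map:
                raise PlateDataError(f"no OD for well {r.well} on {plate_id}")
            role = Role(str(r.role))
            conc = getattr(r, "standard_conc_pg_ml", None)
            conc = None if conc is None or pd.isna(conc) else float(conc)
            sid = getattr(r, "sample_id", None)
            sid = None if sid is None or pd.isna(sid) else str(sid)
            dil = getattr(r, "dilution", None)
            dil = None if dil is None or pd.isna(dil) else float(dil)
            wells.append(
                Well(
                    plate_id=str(plate_id),
                    position=str(r.well),
                    role=role,
                    od=od_map[key],
                    standard_conc=conc if role is Role.STANDARD else None,
                    sample_id=sid if role is Role.SAMPLE else None,
                    dilution=dil if role is Role.SAMPLE else None,
                )
            )
        plate_assay = assay
        if plate_assay is None and "assay" in sub.columns:
            plate_assay = str(sub["assay"].iloc[0])
        if plate_assay is None:
            raise PlateLayoutError(
                "assay not given and layout has no 'assay' column"
            )
        plates.append(PlateRecord(plate_id=str(plate_id), assay=plate_assay, wells=wells))
    if not plates:
        raise PlateLayoutError("empty layout")
    return plates[0] if len(plates) == 1 else plates


def write_plate(
    plates: PlateRecord | Iterable[PlateRecord], layout_path: str, od_path: str
) -> None:
    """Write plates back to the layout/OD CSV dialect, bit-stable for round-trips."""
    if isinstance(plates, PlateRecord):
        plates = [plates]
    layout_rows = []
    od_rows = []
    for p in plates:
        for w in p.wells:
            layout_rows.append(
                {
                    "plate_id": p.plate_id,
                    "well": w.position,
                    "role": w.role.value,
                    "standard_conc_pg_ml": w.standard_conc,
                    "sample_id": w.sample_id,
                    "dilution": w.dilution,
                    "assay": p.assay,
                }
            )
            od_rows.append({"plate_id": p.plate_id, "well": w.position, "od": w.od})
    pd.DataFrame(layout_rows, columns=LAYOUT_COLUMNS + ["assay"]).to_csv(
        layout_path, index=False
    )
    pd.DataFrame(od_rows, columns=OD_COLUMNS).to_csv(od_path, index=False)
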
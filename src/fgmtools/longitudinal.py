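"""Per-individual FGM baselines, peaks, stress events, and note matching.

Baseline: the untrimmed mean and sample SD are computed over an animal's
whole series; values more than one SD above the mean are removed once and
the mean of the remainder is the baseline. Peaks use the UNTRIMMED
statistics: a sample is a peak when it strictly exceeds mean + 2 SD.
An adrenal stress response requires BOTH metabolites (cortisol- and
corticosterone-immunoreactive) to peak on the same sample date; a single
dual-peak date is an acute event, a run of nearby dual-peak dates a chronic
one. Events are then matched against husbandry notes falling on the peak
day or the preceding calendar day (a 48-h lookback at day resolution).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .quantify import Measurement

__all__ = [
    "NoteCategory",
    "NoteRecord",
    "HormoneSeries",
    "StressEvent",
    "compute_baseline",
    "detect_peaks",
    "classify_stress_events",
    "match_notes",
    "summarize_study",
    "summarize_totals",
    "read_series_csv",
    "read_notes_csv",
]


class NoteCategory(str, enum.Enum):
    HEALTH = "health"
    ENRICHMENT = "enrichment"
    EXHIBIT_SHIFT = "exhibit_shift"
    ENVIRONMENT = "environment"
    NORMAL_BEHAVIOR = "normal_behavior"
    OTHER = "other"


@dataclass(frozen=True)
class NoteRecord:
    """A husbandry/behavioral note for one animal at one timestamp."""

    animal_id: str
    timestamp: datetime
    category: NoteCategory
    text: str = ""

    @property
    def day(self) -> date:
        return self.timestamp.date()


def _sample_sd(values: np.ndarray) -> float:
    return float(values.std(ddof=1)) if values.size > 1 else 0.0


def compute_baseline(
    values: Sequence[float], trim_sd: float = 1.0, iterate: bool = False
) -> tuple[float, float, float]:
    """(untrimmed mean, untrimmed sample SD, trimmed-mean baseline).

    Single-pass trim by default: values strictly above mean + trim_sd * SD
    are removed and the mean recomputed; if nothing is removed the baseline
    equals the mean. ``iterate=True`` repeats the trim to convergence.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("empty series")
    if np.any(~np.isfinite(v)) or np.any(v < 0):
        raise ValueError("concentrations must be finite and >= 0")
    mean = float(v.mean())
    sd = _sample_sd(v)

    kept = v
    while True:
        cut = kept.mean() + trim_sd * _sample_sd(kept)
        nxt = kept[kept <= cut]
        if nxt.size == kept.size or nxt.size == 0:
            break
        kept = nxt
        if not iterate:
            break
    baseline = float(kept.mean())
    return mean, sd, baseline


@dataclass
class HormoneSeries:
    """Dated fecal concentrations for one animal and one metabolite.

    Multiple samples on one calendar day are averaged into a daily value
    before any statistics; raw observations are retained.
    """

    animal_id: str
    assay: str
    dates: list[date]
    values: list[float]  # daily ng/g dry feces, aligned with dates
    raw: pd.DataFrame | None = None
    trim_sd: float = 1.0
    peak_sd: float = 2.0
    mean: float = field(init=False)
    sd: float = field(init=False)
    baseline: float = field(init=False)
    peak_threshold: float = field(init=False)

    def __post_init__(self) -> None:
        if len(self.dates) != len(self.values):
            raise ValueError("dates and values must align")
        if len(self.values) == 0:
            raise ValueError(f"{self.animal_id}/{self.assay}: empty series")
        order = np.argsort(np.array(self.dates, dtype="datetime64[D]"))
        self.dates = [self.dates[i] for i in order]
        self.values = [float(self.values[i]) for i in order]
        self.mean, self.sd, self.baseline = compute_baseline(
            self.values, self.trim_sd
        )
        self.peak_threshold = self.mean + self.peak_sd * self.sd

    @classmethod
    def from_observations(
        cls,
        animal_id: str,
        assay: str,
        observations: Iterable[tuple[date | datetime, float]],
        trim_sd: float = 1.0,
        peak_sd: float = 2.0,
    ) -> "HormoneSeries":
        rows = []
        for when, value in observations:
            day = when.date() if isinstance(when, datetime) else when
            rows.append({"date": day, "conc_ng_g": float(value)})
        raw = pd.DataFrame(rows)
        daily = raw.groupby("date", sort=True)["conc_ng_g"].mean()
        return cls(
            animal_id=animal_id,
            assay=assay,
            dates=list(daily.index),
            values=[float(v) for v in daily.to_numpy()],
            raw=raw,
            trim_sd=trim_sd,
            peak_sd=peak_sd,
        )

    @classmethod
    def from_measurements(
        cls,
        measurements: Iterable[Measurement],
        animal_id: str,
        assay: str,
        **kw,
    ) -> "HormoneSeries":
        obs = [
            (m.date, m.fecal_conc_ng_g)
            for m in measurements
            if m.animal_id == animal_id and m.assay == assay and m.usable
        ]
        return cls.from_observations(animal_id, assay, obs, **kw)

    @property
    def n(self) -> int:
        return len(self.values)


def detect_peaks(series: HormoneSeries) -> list[date]:
    """Dates strictly exceeding the untrimmed mean + peak_sd * SD threshold.

    A constant series (SD = 0) has no peaks under the strict inequality.
    """
    thr = series.peak_threshold
    return [d for d, v in zip(series.dates, series.values) if v > thr]


@dataclass
class StressEvent:
    """A dual-metabolite exceedance: acute (one date) or chronic (a run)."""

    animal_id: str
    dates: list[date]
    kind: str  # "acute" | "chronic"
    metabolite_values: list[tuple[float, float]]  # (cortisol, corticosterone)
    matched_notes: list[NoteRecord] = field(default_factory=list)

    @property
    def start(self) -> date:
        return self.dates[0]

    @property
    def end(self) -> date:
        return self.dates[-1]


def classify_stress_events(
    cortisol: HormoneSeries,
    corticosterone: HormoneSeries,
    chronic_gap_days: int = 7,
) -> list[StressEvent]:
    """Intersect the two metabolites' peak dates and group runs into events.

    Dual-peak dates adjacent in the animal's sampled-date sequence and at
    most ``chronic_gap_days`` apart form one event; single dates are acute,
    runs of two or more chronic.
    """
    if cortisol.animal_id != corticosterone.animal_id:
        raise ValueError(
            f"series belong to different animals: {cortisol.animal_id!r} "
            f"vs {corticosterone.animal_id!r}"
        )
    cort_by_day = dict(zip(cortisol.dates, cortisol.values))
    cc_by_day = dict(zip(corticosterone.dates, corticosterone.values))
    dual = sorted(set(detect_peaks(cortisol)) & set(detect_peaks(corticosterone)))
    if not dual:
        return []

    # sampled dates present in both series, for adjacency
    sampled = sorted(set(cortisol.dates) & set(corticosterone.dates))
    idx = {d: i for i, d in enumerate(sampled)}

    events: list[StressEvent] = []
    run: list[date] = [dual[0]]
    for prev, cur in zip(dual, dual[1:]):
        adjacent = idx[cur] == idx[prev] + 1
        close = (cur - prev).days <= chronic_gap_days
        if adjacent and close:
            run.append(cur)
        else:
            events.append(_make_event(cortisol.animal_id, run, cort_by_day, cc_by_day))
            run = [cur]
    events.append(_make_event(cortisol.animal_id, run, cort_by_day, cc_by_day))
    return events


def _make_event(
    animal_id: str,
    run: list[date],
    cort: Mapping[date, float],
    cc: Mapping[date, float],
) -> StressEvent:
    return StressEvent(
        animal_id=animal_id,
        dates=list(run),
        kind="acute" if len(run) == 1 else "chronic",
        metabolite_values=[(cort[d], cc[d]) for d in run],
    )


def match_notes(
    events: Sequence[StressEvent],
    notes: Sequence[NoteRecord],
    window_hours: float = 48.0,
) -> list[StressEvent]:
    """Attach notes from the peak day or the preceding window to each event.

    The window is expressed in hours but applied at calendar-day resolution
    (fecal timestamps are collection times, not excretion times): with the
    default 48 h a note matches if it falls on a peak date or up to one day
    before one.
    """
    lookback_days = max(int(math.ceil(window_hours / 24.0)) - 1, 0)
    out = []
    for ev in events:
        windows = set()
        for d in ev.dates:
            for k in range(lookback_days + 1):
                windows.add(d - timedelta(days=k))
        matched = [
            n for n in notes if n.animal_id == ev.animal_id and n.day in windows
        ]
        out.append(
            StressEvent(
                animal_id=ev.animal_id,
                dates=list(ev.dates),
                kind=ev.kind,
                metabolite_values=list(ev.metabolite_values),
                matched_notes=sorted(matched, key=lambda n: n.timestamp),
            )
        )
    return out


def summarize_totals(per_animal: pd.DataFrame) -> dict[str, float]:
    """Study totals from per-animal count rows.

    Expects columns ``n_samples``, ``dual_peaks``, ``noted_dual_peaks``;
    returns total samples, total dual peaks, total noted dual peaks, and
    the percent of dual peaks with at least one associated note.
    """
    total_samples = int(per_animal["n_samples"].sum())
    dual = int(per_animal["dual_peaks"].sum())
    noted = int(per_animal["noted_dual_peaks"].sum())
    percent = 100.0 * noted / dual if dual else float("nan")
    return {
        "total_samples": total_samples,
        "total_dual_peaks": dual,
        "total_noted_dual_peaks": noted,
        "percent_noted": percent,
    }


def summarize_study(
    series: Mapping[str, Mapping[str, HormoneSeries]],
    events: Mapping[str, Sequence[StressEvent]],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-animal summary table plus study totals.

    ``series`` maps animal_id -> assay -> HormoneSeries; ``events`` maps
    animal_id -> its note-annotated stress events. Each row reports the
    per-metabolite baseline, per-metabolite peak counts, dual-peak sample
    counts, and how many dual peaks carry at least one note.
    """
    rows = []
    for animal_id in sorted(series):
        by_assay = series[animal_id]
        cort = by_assay.get("cortisol")
        cc = by_assay.get("corticosterone")
        evs = list(events.get(animal_id, []))
        dual_dates = [d for ev in evs for d in ev.dates]
        noted_dates = [
            d
            for ev in evs
            if ev.matched_notes
            for d in ev.dates
        ]
        n_samples = 0
        for s in (cort, cc):
            if s is not None:
                n_samples = max(n_samples, s.n)
        rows.append(
            {
                "animal_id": animal_id,
                "n_samples": n_samples,
                "cortisol_baseline_ng_g": cort.baseline if cort else float("nan"),
                "corticosterone_baseline_ng_g": cc.baseline if cc else float("nan"),
                "cortisol_peaks": len(detect_peaks(cort)) if cort else 0,
                "corticosterone_peaks": len(detect_peaks(cc)) if cc else 0,
                "dual_peaks": len(dual_dates),
                "noted_dual_peaks": len(noted_dates),
                "acute_events": sum(1 for e in evs if e.kind == "acute"),
                "chronic_events": sum(1 for e in evs if e.kind == "chronic"),
            }
        )
    table = pd.DataFrame(rows)
    return table, summarize_totals(table)


# ---- CSV I/O ------------------------------------------------------------


def read_series_csv(
    path: str, trim_sd: float = 1.0, peak_sd: float = 2.0
) -> dict[str, dict[str, HormoneSeries]]:
    """Read series.csv (animal_id, date, assay, conc_ng_g[, qc_flags]).

    Rows carrying a blocking QC flag (RERUN, ABOVE_CURVE, MASS_DISCARD,
    DUP_CV_FAIL) are excluded. Returns animal_id -> assay -> series.
    """
    df = pd.read_csv(path, dtype={"animal_id": str}, float_precision="round_trip")
    blocking = {"DUP_CV_FAIL", "RERUN", "ABOVE_CURVE", "MASS_DISCARD"}
    if "qc_flags" in df.columns:
        flags = df["qc_flags"].fillna("").astype(str)
        keep = ~flags.map(lambda s: bool(set(s.split(";")) & blocking))
        df = df[keep]
    df = df[np.isfinite(df["conc_ng_g"])]
    out: dict[str, dict[str, HormoneSeries]] = {}
    for (animal, assay), sub in df.groupby(["animal_id", "assay"]):
        obs = [
            (pd.Timestamp(r.date).date(), float(r.conc_ng_g))
            for r in sub.itertuples()
        ]
        out.setdefault(str(animal), {})[str(assay)] = (
            HormoneSeries.from_observations(
                str(animal), str(assay), obs, trim_sd=trim_sd, peak_sd=peak_sd
            )
        )
    return out


def read_notes_csv(path: str) -> list[NoteRecord]:
    """Read notes.csv: animal_id, timestamp (ISO), category, text."""
    df = pd.read_csv(path, dtype={"animal_id": str}, float_precision="round_trip")
    out = []
    for r in df.itertuples():
        out.append(
            NoteRecord(
                animal_id=str(r.animal_id),
                timestamp=pd.Timestamp(r.timestamp).to_pydatetime(),
                category=NoteCategory(str(r.category)),
                text="" if pd.isna(getattr(r, "text", "")) else str(r.text),
            )
        )
    return out
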
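"""Fragmentation strategies as event-driven controllers.

Three strategies are provided:

* :class:`MS1Controller` — full-scan acquisition only;
* :class:`TopNController` — standard data-dependent acquisition: each duty
  cycle is one MS1 survey scan followed by up to N fragmentation scans of
  the most intense eligible precursors, with a minimum-intensity threshold
  and a dynamic exclusion window (DEW) preventing a precursor m/z from
  being fragmented twice in quick succession;
* :func:`run_dsda` — a multi-sample prioritization scheme (a documented
  surrogate for data-set-dependent acquisition): the first sample is
  acquired DDA-style on a fixed timing grid, then each later sample's MS2
  slots are assigned to the features that are intense and still
  unfragmented (or fragmented poorly) in all samples so far.

The DsDA surrogate scores an MS2 spectrum as
``quality = min(1, peaks above a noise floor / k_ref)`` and weights each
aligned feature by ``max MS1 intensity x (1 - best quality)``. Slot
assignment is greedy by weight, or weighted-random when MaxDepth is on
(which restores sampling mass to rare features).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .chemicals import Chemical
from .feature_db import SpectralFeatureDatabase
from .virtual_ms import Scan, ScanRequest, VirtualMS

__all__ = [
    "TopNParams",
    "ExclusionRecord",
    "MS1Controller",
    "TopNController",
    "select_top_n",
    "GridSlot",
    "DsDASchedule",
    "GridController",
    "dsda_priority",
    "run_dsda",
    "DsDAResult",
    "simulate",
]


@dataclass(frozen=True)
class TopNParams:
    """Top-N DDA settings.

    N
        Maximum fragmentation events per duty cycle.
    dew
        Dynamic exclusion window in seconds.
    min_ms1_intensity
        Minimum precursor intensity to be selected (default 1.75e5 ion
        counts, a typical orbitrap metabolomics setting).
    isolation_width
        Full width of the isolation window in Th.
    mz_tol
        Exclusion-match tolerance, absolute Th by default; interpreted as
        ppm when ``mz_tol_is_ppm`` is set.
    """

    N: int = 10
    dew: float = 15.0
    min_ms1_intensity: float = 1.75e5
    isolation_width: float = 1.0
    mz_tol: float = 0.01
    mz_tol_is_ppm: bool = False

    def __post_init__(self) -> None:
        if self.N < 0:
            raise ValueError("N must be >= 0")
        if self.dew < 0:
            raise ValueError("dew must be >= 0")
        if self.isolation_width <= 0:
            raise ValueError("isolation_width must be positive")

    def matches(self, mz_a: float, mz_b: float) -> bool:
        tol = self.mz_tol * mz_b * 1e-6 if self.mz_tol_is_ppm else self.mz_tol
        return abs(mz_a - mz_b) <= tol


@dataclass(frozen=True)
class ExclusionRecord:
    mz: float
    expiry_rt: float


class MS1Controller:
    """Requests full scans for the whole acquisition window."""

    def acquisition_start(self, start_rt: float, end_rt: float) -> list[ScanRequest]:
        return [ScanRequest(ms_level=1)]

    def scan_completed(self, scan: Scan) -> list[ScanRequest]:
        return [ScanRequest(ms_level=1)]

    def acquisition_end(self, scan_log: Sequence[Scan]) -> None:
        return None


def select_top_n(
    ms1_peaks: Sequence[tuple[float, float]],
    params: TopNParams,
    exclusions: Sequence[ExclusionRecord],
    rt: float,
) -> list[tuple[float, float]]:
    """Pick up to N precursors from an MS1 peak list.

    Peaks below ``min_ms1_intensity`` or matching an active exclusion
    record (within ``mz_tol``) are skipped; the rest are returned in
    descending intensity (ties broken by lower m/z). Selected precursors
    are also mutually separated by more than the exclusion tolerance, so
    one duty cycle never fragments the same m/z twice.
    """
    active = [e for e in exclusions if e.expiry_rt > rt]
    candidates = sorted(
        (p for p in ms1_peaks if p[1] >= params.min_ms1_intensity),
        key=lambda p: (-p[1], p[0]),
    )
    selected: list[tuple[float, float]] = []
    for mz, inten in candidates:
        if len(selected) >= params.N:
            break
        if any(params.matches(mz, e.mz) for e in active):
            continue
        if any(params.matches(mz, s[0]) for s in selected):
            continue
        selected.append((mz, inten))
    return selected


class TopNController:
    """Top-N DDA with dynamic exclusion.

    Exclusion records are added when each MS2 scan completes (expiry =
    scan RT + DEW) and purged lazily at selection time.
    """

    def __init__(self, params: TopNParams) -> None:
        self.params = params
        self.exclusions: list[ExclusionRecord] = []
        self._pending_ms2 = 0

    def acquisition_start(self, start_rt: float, end_rt: float) -> list[ScanRequest]:
        return [ScanRequest(ms_level=1)]

    def scan_completed(self, scan: Scan) -> list[ScanRequest]:
        if scan.ms_level == 1:
            self.exclusions = [e for e in self.exclusions if e.expiry_rt > scan.rt]
            precursors = select_top_n(scan.peaks, self.params, self.exclusions, scan.rt)
            if not precursors:
                return [ScanRequest(ms_level=1)]
            self._pending_ms2 = len(precursors)
            half = self.params.isolation_width / 2
            return [
                ScanRequest(
                    ms_level=2,
                    isolation_window=(mz - half, mz + half),
                    precursor_mz=mz,
                )
                for mz, _ in precursors
            ]
        self._pending_ms2 -= 1
        if scan.precursor is not None:
            self.exclusions.append(
                ExclusionRecord(scan.precursor.mz, scan.rt + self.params.dew)
            )
        return [ScanRequest(ms_level=1)] if self._pending_ms2 <= 0 else []

    def acquisition_end(self, scan_log: Sequence[Scan]) -> None:
        return None

    def state_dict(self) -> dict:
        return {
            "exclusions": [[e.mz, e.expiry_rt] for e in self.exclusions],
        }


def simulate(
    chemicals: Sequence[Chemical],
    db: SpectralFeatureDatabase,
    controller,
    start_rt: float,
    end_rt: float,
    rng: np.random.Generator,
) -> list[Scan]:
    """Convenience wrapper: run one acquisition and return the scan log."""
    return VirtualMS(chemicals, db, rng).run(controller, start_rt, end_rt)


# -- DsDA ------------------------------------------------------------------


@dataclass(frozen=True)
class GridSlot:
    rt: float
    ms_level: int
    duration: float
    target_mz: float | None = None


@dataclass
class DsDASchedule:
    """A fixed timing grid of scan slots; MS2 slots may carry targets."""

    slots: list[GridSlot]

    def __post_init__(self) -> None:
        rts = [s.rt for s in self.slots]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("schedule grid RTs must be strictly increasing")


def make_schedule_grid(
    db: SpectralFeatureDatabase, n: int, start_rt: float, end_rt: float
) -> DsDASchedule:
    """Repeating cycle of 1 MS1 + ``n`` MS2 slots with constant durations
    taken from the feature-database medians."""

    def _median(next_level: int, default: float) -> float:
        pool = [
            d
            for (_, nxt), durs in db.scan_durations.items()
            for d in durs
            if nxt == next_level
        ]
        return float(np.median(pool)) if pool else default

    ms1_dur = _median(1, 0.4)
    ms2_dur = _median(2, 0.2)
    slots: list[GridSlot] = []
    t = float(start_rt)
    while t < end_rt:
        slots.append(GridSlot(t, 1, ms1_dur))
        t += ms1_dur
        for _ in range(n):
            if t >= end_rt:
                break
            slots.append(GridSlot(t, 2, ms2_dur))
            t += ms2_dur
    if n == 0 or not any(s.ms_level == 2 for s in slots):
        warnings.warn("schedule grid contains no MS2 slots; MS1-only schedule", stacklevel=2)
    return DsDASchedule(slots)


# m/z window assigned to an MS2 slot with no target and no eligible
# precursor: below any physical mass, so the scan is logged empty (the
# instrument idles for the slot's duration).
_BLANK_WINDOW = (0.0, 1e-6)


class GridController:
    """Walks a fixed timing grid.

    MS2 slots with a target m/z are fragmented as scheduled regardless of
    what is eluting (a mis-scheduled slot simply yields an empty
    spectrum). Untargeted MS2 slots fall back to DDA behavior: the most
    intense eligible precursor of the last MS1 scan, honoring the
    minimum-intensity threshold and dynamic exclusion.
    """

    def __init__(self, schedule: DsDASchedule, params: TopNParams) -> None:
        self.schedule = schedule
        self.params = params
        self.exclusions: list[ExclusionRecord] = []
        self._idx = 0
        self._last_ms1: Scan | None = None
        self._cycle_selected: list[float] = []

    def _next_request(self) -> list[ScanRequest]:
        if self._idx >= len(self.schedule.slots):
            return []
        slot = self.schedule.slots[self._idx]
        self._idx += 1
        if slot.ms_level == 1:
            self._cycle_selected = []
            return [ScanRequest(ms_level=1, duration=slot.duration)]
        half = self.params.isolation_width / 2
        if slot.target_mz is not None:
            return [
                ScanRequest(
                    ms_level=2,
                    isolation_window=(slot.target_mz - half, slot.target_mz + half),
                    precursor_mz=slot.target_mz,
                    duration=slot.duration,
                )
            ]
        peaks = self._last_ms1.peaks if self._last_ms1 is not None else []
        rt = self._last_ms1.rt if self._last_ms1 is not None else slot.rt
        exclusions = self.exclusions + [
            ExclusionRecord(mz, float("inf")) for mz in self._cycle_selected
        ]
        picked = select_top_n(peaks, replace(self.params, N=1), exclusions, rt)
        if not picked:
            return [
                ScanRequest(
                    ms_level=2,
                    isolation_window=_BLANK_WINDOW,
                    precursor_mz=None,
                    duration=slot.duration,
                )
            ]
        mz = picked[0][0]
        self._cycle_selected.append(mz)
        return [
            ScanRequest(
                ms_level=2,
                isolation_window=(mz - half, mz + half),
                precursor_mz=mz,
                duration=slot.duration,
            )
        ]

    def acquisition_start(self, start_rt: float, end_rt: float) -> list[ScanRequest]:
        self._idx = 0
        self._last_ms1 = None
        self.exclusions = []
        return self._next_request()

    def scan_completed(self, scan: Scan) -> list[ScanRequest]:
        if scan.ms_level == 1:
            self._last_ms1 = scan
            self.exclusions = [e for e in self.exclusions if e.expiry_rt > scan.rt]
        elif scan.precursor is not None and scan.precursor.mz > _BLANK_WINDOW[1]:
            self.exclusions.append(
                ExclusionRecord(scan.precursor.mz, scan.rt + self.params.dew)
            )
        return self._next_request()

    def acquisition_end(self, scan_log: Sequence[Scan]) -> None:
        return None

    def state_dict(self) -> dict:
        return {"exclusions": [[e.mz, e.expiry_rt] for e in self.exclusions]}


@dataclass
class _AlignedFeature:
    mz: float
    mz_lo: float
    mz_hi: float
    rt_lo: float
    rt_hi: float
    intensity: float
    quality: float = 0.0


def dsda_priority(
    feature_history: Sequence[tuple[float, float]]
) -> np.ndarray:
    """Weights for (max MS1 intensity, best MS2 quality) pairs.

    ``weight = intensity x (1 - quality)``: intense, never- or
    poorly-fragmented features are prioritized; a perfectly fragmented
    feature drops to zero.
    """
    weights = []
    for intensity, quality in feature_history:
        if not 0 <= quality <= 1:
            raise ValueError("qualities must be in [0, 1]")
        weights.append(intensity * (1.0 - quality))
    return np.asarray(weights, dtype=float)


@dataclass
class DsDAResult:
    scan_logs: list[list[Scan]]
    schedules: list[DsDASchedule]
    features: list[_AlignedFeature]


def _merge_picked(
    features: list[_AlignedFeature], picked, align_ppm: float
) -> None:
    for peak in picked:
        mz = (peak.mz_lo + peak.mz_hi) / 2
        matched = False
        for f in features:
            if abs(mz - f.mz) <= f.mz * align_ppm * 1e-6 and not (
                peak.rt_hi < f.rt_lo or peak.rt_lo > f.rt_hi
            ):
                f.intensity = max(f.intensity, peak.apex_intensity)
                f.rt_lo = min(f.rt_lo, peak.rt_lo)
                f.rt_hi = max(f.rt_hi, peak.rt_hi)
                matched = True
                break
        if not matched:
            features.append(
                _AlignedFeature(
                    mz=mz,
                    mz_lo=peak.mz_lo,
                    mz_hi=peak.mz_hi,
                    rt_lo=peak.rt_lo,
                    rt_hi=peak.rt_hi,
                    intensity=peak.apex_intensity,
                )
            )


def _update_qualities(
    features: list[_AlignedFeature],
    scan_log: Sequence[Scan],
    k_ref: int,
    noise_floor: float,
    mz_slack: float,
) -> None:
    for scan in scan_log:
        if scan.ms_level != 2 or scan.precursor is None:
            continue
        if scan.precursor.intensity <= 0:
            continue
        quality = min(1.0, float(np.sum(scan.intensities >= noise_floor)) / k_ref)
        for f in features:
            if f.mz_lo - mz_slack <= scan.precursor.mz <= f.mz_hi + mz_slack and (
                f.rt_lo <= scan.rt <= f.rt_hi
            ):
                f.quality = max(f.quality, quality)


def _assign_slots(
    grid: DsDASchedule,
    features: list[_AlignedFeature],
    max_depth: bool,
    rng: np.random.Generator,
) -> DsDASchedule:
    weights = dsda_priority([(f.intensity, f.quality) for f in features])
    assigned: set[int] = set()
    slots: list[GridSlot] = []
    for slot in grid.slots:
        if slot.ms_level == 1:
            slots.append(replace(slot, target_mz=None))
            continue
        eligible = [
            i
            for i, f in enumerate(features)
            if i not in assigned and f.rt_lo <= slot.rt <= f.rt_hi
        ]
        if not eligible:
            slots.append(replace(slot, target_mz=None))
            continue
        if max_depth:
            w = weights[eligible]
            total = w.sum()
            p = w / total if total > 0 else np.full(len(eligible), 1 / len(eligible))
            choice = eligible[int(rng.choice(len(eligible), p=p))]
        else:
            choice = min(eligible, key=lambda i: (-weights[i], features[i].mz))
        assigned.add(choice)
        slots.append(replace(slot, target_mz=features[choice].mz))
    return DsDASchedule(slots)


def run_dsda(
    samples: Sequence[Sequence[Chemical]],
    db: SpectralFeatureDatabase,
    base_params: TopNParams,
    start_rt: float,
    end_rt: float,
    rng: np.random.Generator,
    max_depth: bool = False,
    k_ref: int = 10,
    noise_floor: float = 100.0,
    pick_params=None,
    align_ppm: float = 10.0,
) -> DsDAResult:
    """Acquire an ordered series of samples under the DsDA surrogate.

    Sample 1 runs Top-N DDA on the fixed timing grid; after each sample,
    MS1 features are picked from the log (bundled naive picker unless
    ``pick_params`` overrides its thresholds), aligned to the running
    feature list, their fragmentation qualities updated, and the next
    sample's MS2 slots assigned to the highest-priority features.
    """
    from .evaluation import naive_pick_peaks  # local import: avoids a cycle

    if not samples:
        raise ValueError("run_dsda needs at least one sample")
    grid = make_schedule_grid(db, base_params.N, start_rt, end_rt)
    features: list[_AlignedFeature] = []
    schedule = grid  # first sample: untargeted (plain Top-N on the grid)
    logs: list[list[Scan]] = []
    schedules: list[DsDASchedule] = []
    for s_idx, chems in enumerate(samples):
        controller = GridController(schedule, base_params)
        log = VirtualMS(chems, db, rng).run(controller, start_rt, end_rt)
        logs.append(log)
        schedules.append(schedule)
        if s_idx == len(samples) - 1:
            break
        ms1_scans = [s for s in log if s.ms_level == 1]
        picked = naive_pick_peaks(ms1_scans, pick_params)
        _merge_picked(features, picked, align_ppm)
        _update_qualities(
            features, log, k_ref, noise_floor, mz_slack=base_params.mz_tol
        )
        schedule = _assign_slots(grid, features, max_depth, rng)
    return DsDAResult(logs, schedules, features)
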
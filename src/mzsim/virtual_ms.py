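"""The virtual mass spectrometer.

Holds the chemical mixture and the clock, answers scan requests from a
controller, and advances time with scan durations sampled from the
spectral feature database (keyed by the MS-level transition from the
previous scan). Chromatograms are evaluated at arbitrary RTs by linear
interpolation between the two nearest template knots, for both relative
intensity and m/z offset; outside the template span a chemical emits
nothing.

A scan's RT stamp is the clock at scan start; its duration advances the
clock afterwards. The controller observes every completed scan before its
next request is executed; if it has no pending request while the clock is
still inside the acquisition window, a full-scan (MS1) request is
substituted.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np

from .chemicals import Chemical, ms1_traces
from .feature_db import SpectralFeatureDatabase, sample_scan_duration
from .roi import NormalizedROI

__all__ = [
    "ScanRequest",
    "Precursor",
    "Scan",
    "Controller",
    "VirtualMS",
    "interpolate_signal",
    "save_state",
    "load_state",
]


@dataclass(frozen=True)
class ScanRequest:
    """A controller's instruction for the next scan."""

    ms_level: int = 1
    isolation_window: tuple[float, float] | None = None
    precursor_mz: float | None = None
    duration: float | None = None  # fixed-schedule override; sampled when None

    def __post_init__(self) -> None:
        if self.ms_level not in (1, 2):
            raise ValueError("ms_level must be 1 or 2")
        if self.ms_level == 2:
            if self.isolation_window is None:
                raise ValueError("an MS2 scan request needs an isolation window")
            lo, hi = self.isolation_window
            if not lo < hi:
                raise ValueError("isolation window must satisfy mz_lo < mz_hi")


@dataclass(frozen=True)
class Precursor:
    mz: float
    intensity: float
    parent_scan_id: int | None = None
    isolation_window: tuple[float, float] | None = None


@dataclass(eq=False)
class Scan:
    """A simulated (or loaded) centroided spectrum."""

    scan_id: int
    ms_level: int
    rt: float
    duration: float
    mzs: np.ndarray
    intensities: np.ndarray
    precursor: Precursor | None = None

    def __post_init__(self) -> None:
        self.mzs = np.asarray(self.mzs, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mzs.tolist(), self.intensities.tolist()))

    def __len__(self) -> int:
        return self.mzs.size


class Controller(Protocol):
    """Event protocol a fragmentation strategy implements."""

    def acquisition_start(self, start_rt: float, end_rt: float) -> list[ScanRequest]:
        ...

    def scan_completed(self, scan: Scan) -> list[ScanRequest]:
        ...

    def acquisition_end(self, scan_log: Sequence[Scan]) -> None:
        ...


def interpolate_signal(
    chromatogram: NormalizedROI, rt_offset: float
) -> tuple[float, float]:
    """(relative intensity, m/z offset) of a template at an RT offset.

    Exact at knots, linear between them, (0, 0) outside the span.
    """
    rts = chromatogram.rt_offsets
    if rt_offset < rts[0] or rt_offset > rts[-1]:
        return 0.0, 0.0
    rel = float(np.interp(rt_offset, rts, chromatogram.rel_intensities))
    mz_off = float(np.interp(rt_offset, rts, chromatogram.mz_offsets))
    return rel, mz_off


class _ActiveChem:
    __slots__ = ("chem", "end_rt", "traces")

    def __init__(self, chem: Chemical) -> None:
        self.chem = chem
        self.end_rt = chem.start_rt + chem.chromatogram.duration
        self.traces = ms1_traces(chem)


class VirtualMS:
    """Virtual instrument state: chemicals, clock, scan log, RNG."""

    def __init__(
        self,
        chemicals: Sequence[Chemical],
        db: SpectralFeatureDatabase,
        rng: np.random.Generator,
    ) -> None:
        self.db = db
        self.rng = rng
        self.clock: float = 0.0
        self.scan_log: list[Scan] = []
        self._all = sorted((_ActiveChem(c) for c in chemicals), key=lambda a: a.chem.start_rt)
        self._next = 0
        self._active: list[_ActiveChem] = []
        self._last_ms1_id: int | None = None

    # -- chemistry ---------------------------------------------------------

    def _advance_active(self) -> None:
        while self._next < len(self._all) and self._all[self._next].chem.start_rt <= self.clock:
            self._active.append(self._all[self._next])
            self._next += 1
        self._active = [a for a in self._active if a.end_rt >= self.clock]

    def generate_ms1_scan(self, request: ScanRequest, duration: float = 0.0) -> Scan:
        """Evaluate every eluting trace at the current clock RT."""
        if request.ms_level != 1:
            raise ValueError("generate_ms1_scan requires a level-1 request")
        self._advance_active()
        mzs: list[float] = []
        intens: list[float] = []
        for a in self._active:
            rel, mz_off = interpolate_signal(a.chem.chromatogram, self.clock - a.chem.start_rt)
            if rel <= 0:
                continue
            for base_mz, prop in a.traces:
                inten = a.chem.max_intensity * prop * rel
                if inten <= 0:
                    continue
                mzs.append(base_mz + mz_off)
                intens.append(inten)
        order = np.argsort(mzs, kind="stable")
        scan = Scan(
            scan_id=len(self.scan_log),
            ms_level=1,
            rt=self.clock,
            duration=duration,
            mzs=np.asarray(mzs)[order],
            intensities=np.asarray(intens)[order],
        )
        return scan

    def generate_ms2_scan(self, request: ScanRequest, duration: float = 0.0) -> Scan:
        """Fragment everything whose eluting trace falls in the window.

        Fragment intensities are the chemical's relative fragment
        intensities scaled by the matched trace's current MS1 intensity;
        co-eluting chemicals yield a chimeric union of fragment sets. An
        empty window still produces (and logs) an empty MS2 scan.
        """
        if request.ms_level != 2:
            raise ValueError("generate_ms2_scan requires a level-2 request")
        if request.isolation_window is None:
            raise ValueError("an MS2 scan requires an isolation window")
        lo, hi = request.isolation_window
        self._advance_active()
        mzs: list[float] = []
        intens: list[float] = []
        precursor_intensity = 0.0
        for a in self._active:
            rel, mz_off = interpolate_signal(a.chem.chromatogram, self.clock - a.chem.start_rt)
            if rel <= 0:
                continue
            for base_mz, prop in a.traces:
                cur_mz = base_mz + mz_off
                if not lo <= cur_mz <= hi:
                    continue
                trace_int = a.chem.max_intensity * prop * rel
                if trace_int <= 0:
                    continue
                precursor_intensity += trace_int
                for frag_mz, frag_rel in a.chem.fragments:
                    mzs.append(frag_mz)
                    intens.append(frag_rel * trace_int)
        order = np.argsort(mzs, kind="stable")
        scan = Scan(
            scan_id=len(self.scan_log),
            ms_level=2,
            rt=self.clock,
            duration=duration,
            mzs=np.asarray(mzs)[order],
            intensities=np.asarray(intens)[order],
            precursor=Precursor(
                mz=request.precursor_mz if request.precursor_mz is not None else (lo + hi) / 2,
                intensity=precursor_intensity,
                parent_scan_id=self._last_ms1_id,
                isolation_window=(lo, hi),
            ),
        )
        return scan

    # -- acquisition loop --------------------------------------------------

    def run(self, controller: Controller, start_rt: float, end_rt: float) -> list[Scan]:
        """Run an acquisition from ``start_rt`` until the clock reaches
        ``end_rt``, returning the scan log."""
        if not start_rt < end_rt:
            raise ValueError("start_rt must be smaller than end_rt")
        self.clock = float(start_rt)
        self.scan_log = []
        self._next = 0
        self._active = []
        self._last_ms1_id = None
        pending: deque[ScanRequest] = deque(
            controller.acquisition_start(start_rt, end_rt) or []
        )
        prev_level: int | None = None
        while self.clock < end_rt:
            request = pending.popleft() if pending else ScanRequest(ms_level=1)
            if request.duration is not None:
                duration = float(request.duration)
            else:
                duration = sample_scan_duration(
                    self.db,
                    prev_level if prev_level is not None else request.ms_level,
                    request.ms_level,
                    self.rng,
                )
            if request.ms_level == 1:
                scan = self.generate_ms1_scan(request, duration)
                self._last_ms1_id = scan.scan_id
            else:
                scan = self.generate_ms2_scan(request, duration)
            self.scan_log.append(scan)
            prev_level = request.ms_level
            self.clock += duration
            pending.extend(controller.scan_completed(scan) or [])
        controller.acquisition_end(self.scan_log)
        return list(self.scan_log)


# -- state snapshots -------------------------------------------------------

_STATE_FORMAT = "mzsim.sim_state"


def _scan_to_dict(scan: Scan) -> dict:
    d = {
        "scan_id": scan.scan_id,
        "ms_level": scan.ms_level,
        "rt": scan.rt,
        "duration": scan.duration,
        "mzs": scan.mzs.tolist(),
        "intensities": scan.intensities.tolist(),
    }
    if scan.precursor is not None:
        p = scan.precursor
        d["precursor"] = {
            "mz": p.mz,
            "intensity": p.intensity,
            "parent_scan_id": p.parent_scan_id,
            "isolation_window": list(p.isolation_window) if p.isolation_window else None,
        }
    return d


def _scan_from_dict(d: dict) -> Scan:
    precursor = None
    if d.get("precursor"):
        p = d["precursor"]
        precursor = Precursor(
            mz=p["mz"],
            intensity=p["intensity"],
            parent_scan_id=p.get("parent_scan_id"),
            isolation_window=tuple(p["isolation_window"]) if p.get("isolation_window") else None,
        )
    return Scan(
        scan_id=d["scan_id"],
        ms_level=d["ms_level"],
        rt=d["rt"],
        duration=d["duration"],
        mzs=np.asarray(d["mzs"], dtype=float),
        intensities=np.asarray(d["intensities"], dtype=float),
        precursor=precursor,
    )


def save_state(path: str | Path, vms: VirtualMS, controller=None) -> None:
    """Snapshot the simulator (scan log, clock, RNG state and, when the
    controller exposes ``state_dict()``, its exclusion records) to JSON."""
    payload = {
        "format": _STATE_FORMAT,
        "version": 1,
        "clock": vms.clock,
        "scans": [_scan_to_dict(s) for s in vms.scan_log],
        "rng_state": vms.rng.bit_generator.state,
        "controller": controller.state_dict() if hasattr(controller, "state_dict") else None,
    }
    Path(path).write_text(json.dumps(payload))


def load_state(path: str | Path) -> dict:
    """Load a snapshot written by :func:`save_state`.

    Returns a dict with keys ``clock``, ``scans`` (Scan objects),
    ``rng_state`` and ``controller``.
    """
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != _STATE_FORMAT:
        raise ValueError("not a simulator state snapshot")
    return {
        "clock": payload["clock"],
        "scans": [_scan_from_dict(d) for d in payload["scans"]],
        "rng_state": payload["rng_state"],
        "controller": payload.get("controller"),
    }
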
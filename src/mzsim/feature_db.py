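"""The spectral feature database.

Empirical pools of features extracted from centroided LC-MS/MS runs, used
to parameterize simulated chemicals and scan timings:

* MS1 features — (m/z, RT, max intensity) of chromatographic trace apexes;
* MS2 peaks — (m/z, intensity) pairs pooled over all fragmentation scans;
* fragment counts — per-MS2-scan numbers of peaks, giving an empirical
  distribution of fragmentation-spectrum sizes;
* scan durations — inter-scan RT gaps keyed by the (previous level,
  next level) transition, used to advance the simulated clock;
* optionally, molecular formulas for the synthetic-sample workflow.

All sampling is uniform with replacement and reproducible under a seeded
``numpy.random.Generator``. The database serializes to a versioned JSON
container; ``load_db(save_db(db))`` is the identity.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from .roi import ROIParams, extract_rois

__all__ = [
    "MS1Feature",
    "SpectralFeatureDatabase",
    "build_feature_db",
    "sample_feature",
    "sample_scan_duration",
    "save_db",
    "load_db",
]

_FORMAT = "mzsim.feature_db"
_VERSION = 1


class MS1Feature(NamedTuple):
    """A chromatographic peak apex observed in MS1 data."""

    mz: float
    rt: float
    max_intensity: float


@dataclass
class SpectralFeatureDatabase:
    ms1_features: list[MS1Feature] = field(default_factory=list)
    ms2_peaks: list[tuple[float, float]] = field(default_factory=list)
    fragment_counts: list[int] = field(default_factory=list)
    scan_durations: dict[tuple[int, int], list[float]] = field(default_factory=dict)
    formulas: list[str] | None = None

    def __post_init__(self) -> None:
        for key, pool in self.scan_durations.items():
            if not (key[0] in (1, 2) and key[1] in (1, 2)):
                raise ValueError(f"scan duration key {key} outside MS levels {{1,2}}")
            if any(d <= 0 for d in pool):
                raise ValueError("scan durations must be positive")


def build_feature_db(
    spectra_runs: Sequence[Sequence],
    min_intensity: float,
    roi_params: ROIParams | None = None,
    formulas: Sequence[str] | None = None,
) -> SpectralFeatureDatabase:
    """Build the database from RT-ordered centroided runs.

    Each run is a sequence of Scan-like objects (``ms_level``, ``rt``,
    ``mzs``, ``intensities``). MS1 features are the apexes of ROIs
    extracted with ``roi_params`` (defaulting to ``min_intensity`` as the
    point threshold); MS2 peaks and fragment counts come from MS2 scans
    with peaks at or above ``min_intensity``; scan durations are the RT
    gaps between consecutive scans, keyed by their level transition (the
    final scan of a run contributes no duration).
    """
    runs = list(spectra_runs)
    if not runs or all(len(run) == 0 for run in runs):
        raise ValueError("cannot build a feature database from empty input")
    if roi_params is None:
        roi_params = ROIParams(min_point_intensity=max(min_intensity, 1e-6))

    db = SpectralFeatureDatabase(formulas=list(formulas) if formulas else None)
    n_ms2_scans = 0
    for run in runs:
        scans = list(run)
        ms1_scans = [s for s in scans if s.ms_level == 1]
        for roi in extract_rois(ms1_scans, roi_params):
            k = roi.apex_index
            db.ms1_features.append(
                MS1Feature(roi.mzs[k], roi.rts[k], roi.intensities[k])
            )
        for s in scans:
            if s.ms_level != 2:
                continue
            n_ms2_scans += 1
            mzs = np.asarray(s.mzs, dtype=float)
            intens = np.asarray(s.intensities, dtype=float)
            mask = intens >= min_intensity
            db.ms2_peaks.extend(zip(mzs[mask].tolist(), intens[mask].tolist()))
            if int(mask.sum()) > 0:
                db.fragment_counts.append(int(mask.sum()))
        for a, b in zip(scans, scans[1:]):
            gap = float(b.rt) - float(a.rt)
            if gap <= 0:
                warnings.warn("non-positive inter-scan RT gap skipped", stacklevel=2)
                continue
            db.scan_durations.setdefault((int(a.ms_level), int(b.ms_level)), []).append(gap)

    if n_ms2_scans == 0:
        warnings.warn(
            "input runs contain no MS2 scans; MS2 peak and fragment-count "
            "pools are empty",
            stacklevel=2,
        )
    return db


def sample_feature(
    db: SpectralFeatureDatabase, kind: str, rng: np.random.Generator
):
    """Draw uniformly (with replacement) from one of the database pools.

    ``kind`` is one of ``"ms1"``, ``"ms2_peak"`` or ``"fragment_count"``.
    """
    pools = {
        "ms1": db.ms1_features,
        "ms2_peak": db.ms2_peaks,
        "fragment_count": db.fragment_counts,
    }
    try:
        pool = pools[kind]
    except KeyError:
        raise ValueError(f"unknown pool kind {kind!r}") from None
    if not pool:
        raise ValueError(f"cannot sample from empty pool {kind!r}")
    return pool[int(rng.integers(len(pool)))]


def sample_scan_duration(
    db: SpectralFeatureDatabase,
    prev_level: int,
    next_level: int,
    rng: np.random.Generator,
) -> float:
    """Draw a scan duration for the (prev_level -> next_level) transition.

    If that transition was never observed, falls back (with a warning) to
    the pooled durations of all transitions ending at ``next_level``.
    """
    pool = db.scan_durations.get((prev_level, next_level))
    if not pool:
        pool = [
            d
            for (_, nxt), durs in sorted(db.scan_durations.items())
            for d in durs
            if nxt == next_level
        ]
        if not pool:
            raise ValueError(
                f"no scan durations available for transitions to MS level {next_level}"
            )
        warnings.warn(
            f"no durations for transition {(prev_level, next_level)}; "
            f"falling back to pooled MS{next_level} durations",
            stacklevel=2,
        )
    return float(pool[int(rng.integers(len(pool)))])


def save_db(db: SpectralFeatureDatabase, path: str | Path) -> None:
    """Write the database as a versioned JSON container."""
    payload = {
        "format": _FORMAT,
        "version": _VERSION,
        "ms1_features": [list(f) for f in db.ms1_features],
        "ms2_peaks": [list(p) for p in db.ms2_peaks],
        "fragment_counts": list(db.fragment_counts),
        "scan_durations": {f"{a},{b}": v for (a, b), v in db.scan_durations.items()},
        "formulas": db.formulas,
    }
    Path(path).write_text(json.dumps(payload))


def load_db(path: str | Path) -> SpectralFeatureDatabase:
    """Read a database written by :func:`save_db`.

    Raises ``ValueError`` on anything that is not a complete, valid
    container; never returns a partial database.
    """
    try:
        payload = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ValueError(f"not a valid feature database file: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != _FORMAT:
        raise ValueError("not a valid feature database file: missing format tag")
    if payload.get("version") != _VERSION:
        raise ValueError(
            f"unsupported feature database version {payload.get('version')!r}"
        )
    try:
        durations = {}
        for key, pool in payload["scan_durations"].items():
            a, b = key.split(",")
            durations[(int(a), int(b))] = [float(d) for d in pool]
        return SpectralFeatureDatabase(
            ms1_features=[MS1Feature(*f) for f in payload["ms1_features"]],
            ms2_peaks=[tuple(p) for p in payload["ms2_peaks"]],
            fragment_counts=[int(c) for c in payload["fragment_counts"]],
            scan_durations=durations,
            formulas=payload.get("formulas"),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"not a valid feature database file: {exc}") from exc
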
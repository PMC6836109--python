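"""Scoring of fragmentation runs.

Evaluation compares MS1 features (picked chromatographic peaks, boxes in
m/z x RT with an apex intensity) between a full-scan file and a
fragmentation file, against the fragmentation events of the run:

* ground truth = features found in BOTH files (matched by m/z centers
  within a ppm tolerance and overlapping RT ranges);
* TP — ground-truth features fragmented at or above the minimum MS1
  intensity threshold;
* FP — features only in the fragmentation file, fragmented above the
  threshold;
* TN — features only in the fragmentation file, not fragmented (or below
  threshold);
* FN — features only in the full-scan file, plus — as a documented
  extension — ground-truth features that were NOT fragmented above the
  threshold. Without that extension recall would ignore ground-truth
  features the strategy missed; with it, recall = TP/(TP+FN) measures
  coverage of the ground truth.

Interval membership is closed on both axes. Precision, recall and F1
follow the usual formulas, with undefined (0/0) ratios reported as 0 and
flagged.

A naive peak picker (ROI apex above a threshold; box = ROI extents) is
bundled for tests and for the DsDA surrogate's between-sample step; real
analyses should import externally picked peak lists (CSV).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .roi import ROIParams, extract_rois
from .virtual_ms import Scan

__all__ = [
    "PickedPeak",
    "FragmentationEvent",
    "EvaluationCounts",
    "PRF1",
    "match_events",
    "confusion_counts",
    "prf1",
    "coverage_count",
    "grid_evaluate",
    "naive_pick_peaks",
    "events_from_log",
    "read_picked_peaks_csv",
    "write_picked_peaks_csv",
]


@dataclass(frozen=True)
class PickedPeak:
    """An MS1 feature: a box in m/z x RT with an apex intensity."""

    mz_lo: float
    mz_hi: float
    rt_lo: float
    rt_hi: float
    apex_intensity: float

    def __post_init__(self) -> None:
        if not (self.mz_lo < self.mz_hi and self.rt_lo < self.rt_hi):
            raise ValueError("peak box must satisfy lo < hi on both axes")

    @property
    def mz(self) -> float:
        return (self.mz_lo + self.mz_hi) / 2


@dataclass(frozen=True)
class FragmentationEvent:
    precursor_mz: float
    rt: float
    precursor_intensity: float

    def __post_init__(self) -> None:
        if self.precursor_intensity < 0:
            raise ValueError("precursor intensity must be non-negative")


class PRF1(NamedTuple):
    precision: float
    recall: float
    f1: float
    undefined: frozenset[str]


@dataclass(frozen=True)
class EvaluationCounts:
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float
    undefined: frozenset[str] = frozenset()


def match_events(
    events: Sequence[FragmentationEvent],
    peaks: Sequence[PickedPeak],
    min_intensity: float,
) -> np.ndarray:
    """Per-peak flag: fragmented at or above ``min_intensity``.

    A peak is flagged iff some event lies inside its box (closed
    intervals on both axes) with precursor intensity >= the threshold.
    """
    flags = np.zeros(len(peaks), dtype=bool)
    qualifying = [e for e in events if e.precursor_intensity >= min_intensity]
    if not peaks or not qualifying:
        return flags
    e_mz = np.array([e.precursor_mz for e in qualifying])
    e_rt = np.array([e.rt for e in qualifying])
    mz_lo = np.array([p.mz_lo for p in peaks])
    mz_hi = np.array([p.mz_hi for p in peaks])
    rt_lo = np.array([p.rt_lo for p in peaks])
    rt_hi = np.array([p.rt_hi for p in peaks])
    for j in range(e_mz.size):  # events are usually far fewer than peaks
        flags |= (
            (mz_lo <= e_mz[j])
            & (e_mz[j] <= mz_hi)
            & (rt_lo <= e_rt[j])
            & (e_rt[j] <= rt_hi)
        )
    return flags


def prf1(tp: int, fp: int, fn: int) -> PRF1:
    """Precision, recall, F1; 0/0 ratios are 0 and flagged."""
    undefined = set()
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision, undefined = 0.0, undefined | {"precision"}
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        recall, undefined = 0.0, undefined | {"recall"}
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1, undefined = 0.0, undefined | {"f1"}
    return PRF1(precision, recall, f1, frozenset(undefined))


def _match_peaks(
    frag_peaks: Sequence[PickedPeak],
    fullscan_peaks: Sequence[PickedPeak],
    match_tol_ppm: float,
) -> dict[int, int]:
    """Greedy one-to-one correspondence frag-index -> full-index.

    Candidate pairs have m/z centers within ``match_tol_ppm`` and
    overlapping RT ranges; closest-m/z pairs are matched first.
    """
    if not frag_peaks or not fullscan_peaks:
        return {}
    f_mz = np.array([p.mz for p in frag_peaks])
    f_rt_lo = np.array([p.rt_lo for p in frag_peaks])
    f_rt_hi = np.array([p.rt_hi for p in frag_peaks])
    s_mz = np.array([p.mz for p in fullscan_peaks])
    s_rt_lo = np.array([p.rt_lo for p in fullscan_peaks])
    s_rt_hi = np.array([p.rt_hi for p in fullscan_peaks])
    ppm = np.abs(f_mz[:, None] - s_mz[None, :]) / s_mz[None, :] * 1e6
    ok = (
        (ppm <= match_tol_ppm)
        & (f_rt_hi[:, None] >= s_rt_lo[None, :])
        & (f_rt_lo[:, None] <= s_rt_hi[None, :])
    )
    pairs = np.argwhere(ok)
    candidates = sorted((float(ppm[i, j]), int(i), int(j)) for i, j in pairs)
    matched: dict[int, int] = {}
    used_full: set[int] = set()
    for _, i, j in candidates:
        if i in matched or j in used_full:
            continue
        matched[i] = j
        used_full.add(j)
    return matched


def confusion_counts(
    fullscan_peaks: Sequence[PickedPeak],
    frag_peaks: Sequence[PickedPeak],
    events: Sequence[FragmentationEvent],
    min_intensity: float,
    match_tol_ppm: float = 10.0,
) -> EvaluationCounts:
    """Confusion counts of a fragmentation run against a full-scan file."""
    if not fullscan_peaks:
        warnings.warn("empty full-scan peak list: TP and FN are zero", stacklevel=2)
    matched = _match_peaks(frag_peaks, fullscan_peaks, match_tol_ppm)
    frag_flags = match_events(events, frag_peaks, min_intensity)
    tp = fp = tn = 0
    fn = len(fullscan_peaks) - len(matched)  # full-scan-only features
    for i in range(len(frag_peaks)):
        if i in matched:
            if frag_flags[i]:
                tp += 1
            else:
                fn += 1  # ground truth missed by the strategy (extension)
        else:
            if frag_flags[i]:
                fp += 1
            else:
                tn += 1
    p, r, f1, undefined = prf1(tp, fp, fn)
    return EvaluationCounts(tp, fp, fn, tn, p, r, f1, undefined)


def coverage_count(
    aligned_peaks: Sequence[PickedPeak],
    events: Sequence[FragmentationEvent],
    min_intensity: float,
) -> int:
    """Number of aligned peaks with at least one qualifying event."""
    return int(match_events(events, aligned_peaks, min_intensity).sum())


def events_from_log(scan_log: Sequence[Scan]) -> list[FragmentationEvent]:
    """The fragmentation events of a run: one per MS2 scan's precursor."""
    return [
        FragmentationEvent(s.precursor.mz, s.rt, s.precursor.intensity)
        for s in scan_log
        if s.ms_level == 2 and s.precursor is not None
    ]


# Naive picker defaults: wide enough to keep genuine simulated traces,
# strict enough (4 points) to drop single-scan spikes, CentWave-style.
_PICK_DEFAULTS = ROIParams(mz_tol_ppm=10.0, min_point_intensity=1.0, min_points=4)
_BOX_EPS = 1e-6


def naive_pick_peaks(
    scans: Sequence[Scan],
    roi_params: ROIParams | None = None,
    min_apex_intensity: float = 0.0,
) -> list[PickedPeak]:
    """Pick MS1 features from scans: ROI extents with an apex filter.

    Intended for tests and the DsDA surrogate only — no wavelet shape
    analysis is performed.
    """
    ms1 = [s for s in scans if s.ms_level == 1]
    peaks = []
    for roi in extract_rois(ms1, roi_params or _PICK_DEFAULTS):
        if roi.apex_intensity < min_apex_intensity:
            continue
        peaks.append(
            PickedPeak(
                mz_lo=min(roi.mzs) - _BOX_EPS,
                mz_hi=max(roi.mzs) + _BOX_EPS,
                rt_lo=roi.rts[0],
                rt_hi=roi.rts[-1] + _BOX_EPS,
                apex_intensity=roi.apex_intensity,
            )
        )
    return peaks


def grid_evaluate(
    fullscan_source,
    n_values: Sequence[int],
    dew_values: Sequence[float],
    fixed_params,
    db=None,
    *,
    start_rt: float,
    end_rt: float,
    seed: int = 0,
    pick_params: ROIParams | None = None,
    match_tol_ppm: float = 10.0,
) -> pd.DataFrame:
    """One Top-N simulation + evaluation per (N, DEW) grid cell.

    ``fullscan_source`` is either a chemical list or a path to a
    centroided full-scan mzML file (converted via ROI extraction, the
    existing-sample workflow). ``fixed_params`` is a
    :class:`~mzsim.controllers.TopNParams` whose N and DEW are overridden
    cell by cell. Returns a table with one row per cell: N, dew, the
    confusion counts, precision/recall/F1 and the number of MS1 features
    picked from the fragmentation run.
    """
    from .controllers import TopNController, simulate  # avoids an import cycle

    if db is None:
        raise ValueError("grid_evaluate requires a spectral feature database")
    if isinstance(fullscan_source, (str, Path)):
        from .chemicals import chemicals_from_rois
        from .io_mzml import read_run

        scans = read_run(fullscan_source)
        rois = extract_rois(
            [s for s in scans if s.ms_level == 1],
            pick_params or _PICK_DEFAULTS,
        )
        chemicals = chemicals_from_rois(rois)
    else:
        chemicals = list(fullscan_source)

    from .controllers import MS1Controller

    fullscan_rng = np.random.default_rng([seed, 0])
    fullscan_log = simulate(
        chemicals, db, MS1Controller(), start_rt, end_rt, fullscan_rng
    )
    fullscan_peaks = naive_pick_peaks(fullscan_log, pick_params)

    rows = []
    from dataclasses import replace

    cell = 0
    for n in n_values:
        for dew in dew_values:
            cell += 1
            params = replace(fixed_params, N=int(n), dew=float(dew))
            rng = np.random.default_rng([seed, cell])
            log = simulate(
                chemicals, db, TopNController(params), start_rt, end_rt, rng
            )
            frag_peaks = naive_pick_peaks(log, pick_params)
            counts = confusion_counts(
                fullscan_peaks,
                frag_peaks,
                events_from_log(log),
                params.min_ms1_intensity,
                match_tol_ppm,
            )
            rows.append(
                {
                    "N": int(n),
                    "dew": float(dew),
                    "tp": counts.tp,
                    "fp": counts.fp,
                    "fn": counts.fn,
                    "tn": counts.tn,
                    "precision": counts.precision,
                    "recall": counts.recall,
                    "f1": counts.f1,
                    "peaks_picked": len(frag_peaks),
                    "ms1_scans": sum(1 for s in log if s.ms_level == 1),
                }
            )
    return pd.DataFrame(rows)


_CSV_COLUMNS = ["mz_lo", "mz_hi", "rt_lo", "rt_hi", "apex_intensity"]


def read_picked_peaks_csv(path: str | Path) -> list[PickedPeak]:
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"picked-peak CSV is missing columns {sorted(missing)}")
    return [PickedPeak(*row) for row in df[_CSV_COLUMNS].itertuples(index=False)]


def write_picked_peaks_csv(peaks: Sequence[PickedPeak], path: str | Path) -> None:
    pd.DataFrame(
        [(p.mz_lo, p.mz_hi, p.rt_lo, p.rt_hi, p.apex_intensity) for p in peaks],
        columns=_CSV_COLUMNS,
    ).to_csv(path, index=False)
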
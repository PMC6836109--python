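"""Region-of-interest (ROI) extraction and chromatogram normalization.

An ROI is a mass trace: centroids from consecutive MS1 scans whose m/z
values stay within a ppm window of the trace's running mean m/z. ROIs are
the raw material for chromatographic peaks; here they also serve as
empirical chromatogram templates that, once normalized (m/z centered on 0,
RT starting at 0, intensity scaled to a maximum of 1), can be attached to
simulated chemicals.

The grouping rules are deterministic:

* a point joins the open ROI whose mean m/z is closest, among those within
  ``mz_tol_ppm`` of their running mean; ties go to the earlier-created ROI;
* at most one point per ROI per scan — when two peaks of one scan claim the
  same ROI, the closer one joins and the other seeds a new ROI;
* ROIs not extended by a scan are closed after that scan;
* closed ROIs with fewer than ``min_points`` points are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ROIParams",
    "ROIPoint",
    "ROI",
    "NormalizedROI",
    "extract_rois",
    "normalize_roi",
    "rois_to_dataframe",
]


@dataclass(frozen=True)
class ROIPoint:
    """A single (m/z, RT, intensity) centroid."""

    mz: float
    rt: float
    intensity: float

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")


@dataclass(frozen=True)
class ROIParams:
    """Extraction thresholds.

    mz_tol_ppm
        Half-width of the matching window around the ROI's running mean
        m/z, in parts per million.
    min_point_intensity
        Centroids below this intensity are ignored entirely.
    min_points
        Closed ROIs with fewer points are discarded.
    """

    mz_tol_ppm: float = 10.0
    min_point_intensity: float = 1.0
    min_points: int = 3

    def __post_init__(self) -> None:
        if self.mz_tol_ppm <= 0:
            raise ValueError("mz_tol_ppm must be positive")
        if self.min_point_intensity <= 0:
            raise ValueError("min_point_intensity must be positive")
        if self.min_points <= 0:
            raise ValueError("min_points must be positive")


class ROI:
    """An RT-ordered mass trace with a running mean m/z."""

    __slots__ = ("mzs", "rts", "intensities", "_mz_sum")

    def __init__(
        self,
        mzs: Iterable[float] = (),
        rts: Iterable[float] = (),
        intensities: Iterable[float] = (),
    ) -> None:
        self.mzs: list[float] = [float(x) for x in mzs]
        self.rts: list[float] = [float(x) for x in rts]
        self.intensities: list[float] = [float(x) for x in intensities]
        if not (len(self.mzs) == len(self.rts) == len(self.intensities)):
            raise ValueError("mzs, rts and intensities must have equal length")
        if any(b <= a for a, b in zip(self.rts, self.rts[1:])):
            raise ValueError("ROI retention times must be strictly increasing")
        if any(i < 0 for i in self.intensities):
            raise ValueError("ROI intensities must be non-negative")
        self._mz_sum = float(sum(self.mzs))

    def append(self, mz: float, rt: float, intensity: float) -> None:
        if self.rts and rt <= self.rts[-1]:
            raise ValueError("points must be appended in strictly increasing RT order")
        self.mzs.append(float(mz))
        self.rts.append(float(rt))
        self.intensities.append(float(intensity))
        self._mz_sum += float(mz)

    def __len__(self) -> int:
        return len(self.mzs)

    @property
    def points(self) -> list[ROIPoint]:
        return [ROIPoint(m, r, i) for m, r, i in zip(self.mzs, self.rts, self.intensities)]

    @property
    def mean_mz(self) -> float:
        return self._mz_sum / len(self.mzs)

    @property
    def apex_index(self) -> int:
        return int(np.argmax(self.intensities))

    @property
    def apex_intensity(self) -> float:
        return self.intensities[self.apex_index]

    @property
    def apex_rt(self) -> float:
        return self.rts[self.apex_index]

    @property
    def apex_mz(self) -> float:
        return self.mzs[self.apex_index]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"ROI(n={len(self)}, mean_mz={self.mean_mz:.4f}, "
            f"rt=[{self.rts[0]:.1f}, {self.rts[-1]:.1f}], apex={self.apex_intensity:.3g})"
        )


@dataclass(frozen=True, eq=False)
class NormalizedROI:
    """A reusable chromatogram template.

    m/z offsets are centered on 0 (mean m/z subtracted), RT offsets start
    at 0 (first RT subtracted) and intensities are scaled so the maximum
    is exactly 1.
    """

    mz_offsets: np.ndarray
    rt_offsets: np.ndarray
    rel_intensities: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mz_offsets", np.asarray(self.mz_offsets, dtype=float))
        object.__setattr__(self, "rt_offsets", np.asarray(self.rt_offsets, dtype=float))
        object.__setattr__(self, "rel_intensities", np.asarray(self.rel_intensities, dtype=float))
        if self.rt_offsets.size == 0:
            raise ValueError("normalized ROI must contain at least one point")
        if self.rt_offsets[0] != 0.0:
            raise ValueError("rt_offsets must start at 0")
        peak = self.rel_intensities.max()
        # normalize_roi always yields a maximum of exactly 1; hand-built
        # templates may sit below it (e.g. clipped shapes) but never above
        if not 0 < peak <= 1.0 + 1e-9:
            raise ValueError("rel_intensities must peak in (0, 1]")

    @property
    def duration(self) -> float:
        """RT span of the template in seconds."""
        return float(self.rt_offsets[-1])


class _OpenROI:
    __slots__ = ("roi", "order")

    def __init__(self, roi: ROI, order: int) -> None:
        self.roi = roi
        self.order = order


def _scan_peaks(scan) -> tuple[np.ndarray, np.ndarray]:
    """Peak arrays from a Scan-like object (``mzs``/``intensities`` attrs)."""
    return np.asarray(scan.mzs, dtype=float), np.asarray(scan.intensities, dtype=float)


def extract_rois(scans: Sequence, params: ROIParams | None = None) -> list[ROI]:
    """Extract ROIs from RT-ordered centroided MS1 scans.

    Returns the kept ROIs (those with at least ``params.min_points``
    points) in order of creation.
    """
    kept, _ = extract_rois_full(scans, params)
    return kept


def extract_rois_full(
    scans: Sequence, params: ROIParams | None = None
) -> tuple[list[ROI], list[ROI]]:
    """Like :func:`extract_rois` but also returns the discarded ROIs.

    Every centroid at or above ``min_point_intensity`` ends up in exactly
    one ROI of the union kept + discarded.
    """
    params = params or ROIParams()
    open_rois: list[_OpenROI] = []
    closed: list[_OpenROI] = []
    counter = 0
    last_rt = None

    for scan in scans:
        rt = float(scan.rt)
        if last_rt is not None and rt <= last_rt:
            raise ValueError("scans must be ordered by strictly increasing RT")
        last_rt = rt

        mzs, intens = _scan_peaks(scan)
        mask = intens >= params.min_point_intensity
        mzs, intens = mzs[mask], intens[mask]
        order = np.argsort(mzs, kind="stable")
        mzs, intens = mzs[order], intens[order]

        claims: dict[int, list[tuple[float, int]]] = {}
        unmatched: list[int] = []
        if open_rois and mzs.size:
            means = np.array([o.roi.mean_mz for o in open_rois])
            tols = means * (params.mz_tol_ppm * 1e-6)
            dist = np.abs(mzs[:, None] - means[None, :])
            dist = np.where(dist <= tols[None, :], dist, np.inf)
            best = np.argmin(dist, axis=1)  # ties -> lowest index = earliest created
            best_dist = dist[np.arange(mzs.size), best]
            for p in range(mzs.size):
                if np.isfinite(best_dist[p]):
                    claims.setdefault(int(best[p]), []).append((float(best_dist[p]), p))
                else:
                    unmatched.append(p)
        else:
            unmatched = list(range(mzs.size))

        extended: set[int] = set()
        seeds: list[int] = []
        for roi_idx, claimants in claims.items():
            claimants.sort()  # by distance, then peak order (lower m/z first)
            _, winner = claimants[0]
            open_rois[roi_idx].roi.append(mzs[winner], rt, intens[winner])
            extended.add(roi_idx)
            seeds.extend(p for _, p in claimants[1:])
        seeds.extend(unmatched)
        seeds.sort()

        survivors = [o for i, o in enumerate(open_rois) if i in extended]
        closed.extend(o for i, o in enumerate(open_rois) if i not in extended)
        for p in seeds:
            survivors.append(_OpenROI(ROI([mzs[p]], [rt], [intens[p]]), counter))
            counter += 1
        open_rois = survivors

    closed.extend(open_rois)
    closed.sort(key=lambda o: o.order)
    kept = [o.roi for o in closed if len(o.roi) >= params.min_points]
    discarded = [o.roi for o in closed if len(o.roi) < params.min_points]
    return kept, discarded


def normalize_roi(roi: ROI) -> NormalizedROI:
    """Normalize a trace into a chromatogram template.

    Subtracts the ROI's mean m/z from each m/z, its first RT from each RT,
    and divides intensities by the maximum. Raises if the maximum
    intensity is not positive.
    """
    if len(roi) == 0:
        raise ValueError("cannot normalize an empty ROI")
    max_i = roi.apex_intensity
    if max_i <= 0:
        raise ValueError("cannot normalize an ROI with no positive intensity")
    mean = roi.mean_mz
    return NormalizedROI(
        mz_offsets=np.array(roi.mzs) - mean,
        rt_offsets=np.array(roi.rts) - roi.rts[0],
        rel_intensities=np.array(roi.intensities) / max_i,
    )


def rois_to_dataframe(rois: Sequence[ROI]) -> pd.DataFrame:
    """Flatten ROIs to a table with columns roi_id, mz, rt, intensity."""
    rows = [
        (i, mz, rt, inten)
        for i, roi in enumerate(rois)
        for mz, rt, inten in zip(roi.mzs, roi.rts, roi.intensities)
    ]
    return pd.DataFrame(rows, columns=["roi_id", "mz", "rt", "intensity"])
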
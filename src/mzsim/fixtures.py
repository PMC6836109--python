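"""Synthetic fixtures: parametric test inputs with machine-readable truth.

Everything a simulation needs — a spectral feature database, chromatogram
templates, chemical mixtures, and small centroided runs — can be
generated here from stated parametric distributions, with no external
data. Defaults emulate an orbitrap metabolomics run: m/z uniform in
70-1000 Th, log10 apex intensity uniform in [4, 7], Gaussian
chromatographic peaks 3-10 s wide (sigma), MS1 scans near 0.4 s and MS2
scans near 0.2 s.

Fixture chromatograms are Gaussian in RT so each artifact ships with
closed-form truth (apex position, height, and extents), enabling exact
expected-value tests downstream; empirical ROIs from real data are not
Gaussian, which is the main fidelity gap of these fixtures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import exp, log, sqrt
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chemicals import (
    DEFAULT_ADDUCTS,
    AdductSpec,
    KnownChemical,
    UnknownChemical,
    ms1_traces,
    sample_known_chemicals,
)
from .evaluation import PickedPeak
from .feature_db import MS1Feature, SpectralFeatureDatabase
from .roi import ROI, NormalizedROI
from .virtual_ms import Scan

__all__ = [
    "DEFAULT_FORMULAS",
    "FixtureChemSpec",
    "make_formula_pool",
    "make_fixture_db",
    "make_roi_pool",
    "make_gaussian_chromatogram",
    "make_fixture_run",
    "make_unknown_chemicals",
    "make_synthetic_chemicals",
    "truth_boxes",
]

# a small spread of common metabolite formulas (sugars, amino acids,
# organic acids, nucleotides, lipid fragments)
DEFAULT_FORMULAS: tuple[str, ...] = (
    "C6H12O6", "C5H10O5", "C12H22O11", "C3H6O3", "C4H6O4", "C6H8O7",
    "C2H5NO2", "C3H7NO2", "C5H9NO4", "C5H11NO2S", "C9H11NO2", "C9H11NO3",
    "C11H12N2O2", "C6H14N2O2", "C6H9N3O2", "C4H8N2O3", "C5H9NO2",
    "C3H7NO3", "C4H9NO3", "C6H13NO2", "C5H5N5", "C5H5N5O", "C4H5N3O",
    "C5H6N2O2", "C10H13N5O4", "C10H13N5O5", "C9H13N3O5", "C10H14N2O5",
    "C10H16N5O13P3", "C10H15N5O10P2", "C10H14N5O7P", "C21H27N7O14P2",
    "C4H4O4", "C4H6O5", "C5H6O5", "C6H10O5", "C7H6O2", "C7H8O2",
    "C8H8O3", "C10H8O4", "C7H12O6", "C6H5NO2", "C6H6N2O", "C8H10NO6P",
    "C9H17NO5", "C3H9O6P", "C6H13O9P", "C16H32O2", "C18H34O2",
    "C18H32O2", "C5H11NO2", "C7H15NO3", "C9H17NO2", "C23H38N7O17P3S",
    "C2H7NO3S", "C3H10N2", "C5H14NO", "C10H12N2O", "C8H11NO3",
)

def make_formula_pool(n: int, rng: np.random.Generator) -> list[str]:
    """Random metabolite-like molecular formulas (CHNOPS).

    Emulates the diversity of a metabolite-database export: carbon counts
    3-30, hydrogen between 0.8C and 2C+2, oxygen up to 12, occasional
    nitrogen, sulfur and phosphorus. With thousands of formulas almost
    all sampled chemicals get distinct monoisotopic masses, as they would
    when sampling a real database.
    """
    pool = []
    for _ in range(n):
        c = int(rng.integers(3, 31))
        h = int(rng.integers(max(1, int(0.8 * c)), 2 * c + 3))
        o = int(rng.integers(0, min(12, c) + 1))
        nn = int(rng.choice([0, 0, 0, 1, 1, 2, 3, 4]))
        s = int(rng.random() < 0.08)
        p = int(rng.random() < 0.05)
        parts = [f"C{c}", f"H{h}"]
        if nn:
            parts.append(f"N{nn}")
        if o:
            parts.append(f"O{o}")
        if p:
            parts.append("P")
        if s:
            parts.append("S")
        pool.append("".join(parts))
    return pool


_DEFAULT_DURATION_MEANS: dict[tuple[int, int], float] = {
    (1, 1): 0.4,
    (1, 2): 0.2,
    (2, 2): 0.2,
    (2, 1): 0.4,
}


def make_fixture_db(
    n_ms1: int = 500,
    n_ms2: int = 2000,
    duration_means: dict[tuple[int, int], float] | None = None,
    rng: np.random.Generator | None = None,
    *,
    mz_range: tuple[float, float] = (70.0, 1000.0),
    rt_range: tuple[float, float] = (0.0, 300.0),
    log10_intensity_range: tuple[float, float] = (4.0, 7.0),
    fragment_count_range: tuple[int, int] = (5, 30),
    n_durations: int = 60,
    formulas: Sequence[str] | None = None,
) -> SpectralFeatureDatabase:
    """A parametric spectral feature database.

    MS1 feature m/z uniform in ``mz_range``, RT uniform in ``rt_range``,
    log10 intensity uniform in ``log10_intensity_range``; MS2 peak m/z
    uniform in 50-500 Th; fragment counts uniform integers in
    ``fragment_count_range``; durations jittered +/-10% around
    ``duration_means``. When ``formulas`` is None a fresh 2000-formula
    pool from :func:`make_formula_pool` is attached; pass an empty
    sequence for a database without formulas.
    """
    if n_ms1 <= 0 or n_ms2 <= 0:
        raise ValueError("pool sizes must be positive")
    rng = rng or np.random.default_rng()
    if formulas is None:
        formulas = make_formula_pool(2000, rng)
    duration_means = duration_means or _DEFAULT_DURATION_MEANS
    db = SpectralFeatureDatabase(
        ms1_features=[
            MS1Feature(
                float(rng.uniform(*mz_range)),
                float(rng.uniform(*rt_range)),
                float(10.0 ** rng.uniform(*log10_intensity_range)),
            )
            for _ in range(n_ms1)
        ],
        ms2_peaks=[
            (float(rng.uniform(50.0, 500.0)), float(10.0 ** rng.uniform(2.0, 5.0)))
            for _ in range(n_ms2)
        ],
        fragment_counts=[
            int(rng.integers(fragment_count_range[0], fragment_count_range[1] + 1))
            for _ in range(200)
        ],
        scan_durations={
            key: (mean * rng.uniform(0.9, 1.1, size=n_durations)).tolist()
            for key, mean in duration_means.items()
        },
        formulas=list(formulas) if formulas else None,
    )
    return db


def make_gaussian_chromatogram(
    sigma: float,
    n_points: int = 21,
    mz_jitter_sd: float = 0.0002,
    rng: np.random.Generator | None = None,
) -> NormalizedROI:
    """A Gaussian chromatogram template spanning +/-3 sigma.

    The apex (relative intensity exactly 1) sits at the middle knot;
    m/z offsets are small centred jitter emulating centroiding error.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = rng or np.random.default_rng()
    rts = np.linspace(0.0, 6.0 * sigma, n_points)
    center = rts[len(rts) // 2]
    rel = np.exp(-((rts - center) ** 2) / (2 * sigma**2))
    rel /= rel.max()
    mz_off = rng.normal(0.0, mz_jitter_sd, size=n_points)
    mz_off -= mz_off.mean()
    return NormalizedROI(mz_off, rts, rel)


def make_roi_pool(
    n: int,
    rng: np.random.Generator | None = None,
    *,
    sigma_range: tuple[float, float] = (3.0, 10.0),
    point_spacing: float = 0.5,
    mz_range: tuple[float, float] = (70.0, 1000.0),
    log10_intensity_range: tuple[float, float] = (4.0, 7.0),
    mz_jitter_sd: float = 0.0002,
) -> list[ROI]:
    """Gaussian-shaped ROIs usable as chromatogram templates.

    The m/z jitter is a small absolute wobble (default 0.2 mTh): template
    m/z offsets are re-applied at other chemicals' m/z values, so they
    must stay well inside the ppm matching window across the whole mass
    range.
    """
    rng = rng or np.random.default_rng()
    pool = []
    for _ in range(n):
        sigma = float(rng.uniform(*sigma_range))
        apex = float(10.0 ** rng.uniform(*log10_intensity_range))
        center_mz = float(rng.uniform(*mz_range))
        rts = np.arange(0.0, 6.0 * sigma + point_spacing / 2, point_spacing)
        mid = rts[-1] / 2
        intens = apex * np.exp(-((rts - mid) ** 2) / (2 * sigma**2))
        mzs = center_mz + rng.normal(0.0, mz_jitter_sd, size=rts.size)
        pool.append(ROI(mzs.tolist(), rts.tolist(), intens.tolist()))
    return pool


@dataclass(frozen=True)
class FixtureChemSpec:
    """Ground-truth description of one Gaussian trace in a fixture run."""

    mz: float
    apex_rt: float
    sigma: float
    apex_intensity: float


def make_fixture_run(
    chemical_specs: Sequence[FixtureChemSpec | tuple],
    scan_period: float = 0.5,
    path: str | Path | None = None,
    *,
    rt_range: tuple[float, float] | None = None,
    emit_threshold: float = 0.01,
) -> tuple[list[Scan], pd.DataFrame]:
    """A small centroided MS1 run of known Gaussian traces + truth table.

    Each spec contributes intensity ``apex * exp(-(t-apex_rt)^2/2 sigma^2)``
    wherever that exceeds ``emit_threshold`` of the apex. The truth table
    lists each chemical's box (m/z +/- 0.01 Th, RT at the emission
    cutoff) and apex. If ``path`` is given the run is also written as
    mzML.
    """
    specs = [s if isinstance(s, FixtureChemSpec) else FixtureChemSpec(*s) for s in chemical_specs]
    for i, a in enumerate(specs):
        for b in specs[i + 1 :]:
            if abs(a.mz - b.mz) <= a.mz * 10e-6 and abs(a.apex_rt - b.apex_rt) < 3 * (
                a.sigma + b.sigma
            ):
                warnings.warn(
                    f"overlapping specs at m/z {a.mz:.4f}: traces will merge",
                    stacklevel=2,
                )
    if rt_range is None:
        if specs:
            lo = min(s.apex_rt - 4 * s.sigma for s in specs)
            hi = max(s.apex_rt + 4 * s.sigma for s in specs)
            rt_range = (max(0.0, lo), hi)
        else:
            rt_range = (0.0, 10.0)

    half_span = sqrt(2.0 * log(1.0 / emit_threshold))  # in sigmas
    scans = []
    scan_times = np.arange(rt_range[0], rt_range[1], scan_period)
    for i, t in enumerate(scan_times):
        mzs, intens = [], []
        for s in specs:
            z = (t - s.apex_rt) / s.sigma
            if abs(z) > half_span:
                continue
            mzs.append(s.mz)
            intens.append(s.apex_intensity * exp(-0.5 * z * z))
        order = np.argsort(mzs)
        scans.append(
            Scan(
                scan_id=i,
                ms_level=1,
                rt=float(t),
                duration=scan_period,
                mzs=np.asarray(mzs)[order],
                intensities=np.asarray(intens)[order],
            )
        )
    truth = pd.DataFrame(
        {
            "mz": [s.mz for s in specs],
            "apex_rt": [s.apex_rt for s in specs],
            "apex_intensity": [s.apex_intensity for s in specs],
            "mz_lo": [s.mz - 0.01 for s in specs],
            "mz_hi": [s.mz + 0.01 for s in specs],
            "rt_lo": [s.apex_rt - half_span * s.sigma for s in specs],
            "rt_hi": [s.apex_rt + half_span * s.sigma for s in specs],
        }
    )
    if path is not None:
        from .io_mzml import write_run

        write_run(scans, path)
    return scans, truth


def make_unknown_chemicals(
    n: int,
    rng: np.random.Generator | None = None,
    *,
    rt_range: tuple[float, float] = (10.0, 100.0),
    mz_range: tuple[float, float] = (70.0, 1000.0),
    log10_intensity_range: tuple[float, float] = (4.0, 7.0),
    sigma_range: tuple[float, float] = (3.0, 10.0),
) -> list[UnknownChemical]:
    """Quick single-trace chemicals with Gaussian chromatograms."""
    rng = rng or np.random.default_rng()
    out = []
    for i in range(n):
        sigma = float(rng.uniform(*sigma_range))
        chrom = make_gaussian_chromatogram(sigma, rng=rng)
        out.append(
            UnknownChemical(
                observed_mz=float(rng.uniform(*mz_range)),
                start_rt=float(rng.uniform(*rt_range)),
                max_intensity=float(10.0 ** rng.uniform(*log10_intensity_range)),
                chromatogram=chrom,
                chem_id=i,
            )
        )
    return out


def make_synthetic_chemicals(
    n: int,
    rng: np.random.Generator,
    *,
    rt_range: tuple[float, float] = (10.0, 100.0),
    adducts: Sequence[AdductSpec] = DEFAULT_ADDUCTS,
    fragment_method: str = "random",
    db: SpectralFeatureDatabase | None = None,
) -> tuple[list[KnownChemical], SpectralFeatureDatabase]:
    """Known chemicals via the synthetic-sample workflow, plus their db.

    Builds a fixture feature database whose MS1 RT pool matches
    ``rt_range`` (chemicals start eluting inside the stated window) and a
    Gaussian ROI pool, then runs :func:`sample_known_chemicals`.
    """
    if db is None:
        db = make_fixture_db(rng=rng, rt_range=rt_range)
    pool = make_roi_pool(max(50, n // 10), rng)
    chems = sample_known_chemicals(
        db, n, adducts=adducts, roi_pool=pool, rng=rng, fragment_method=fragment_method
    )
    return chems, db


def truth_boxes(
    chemicals: Sequence[KnownChemical | UnknownChemical], mz_pad: float = 0.01
) -> list[PickedPeak]:
    """Ground-truth MS1 feature boxes, one per chemical's main trace."""
    boxes = []
    for chem in chemicals:
        traces = ms1_traces(chem)
        mz, prop = max(traces, key=lambda t: t[1])
        boxes.append(
            PickedPeak(
                mz_lo=mz - mz_pad,
                mz_hi=mz + mz_pad,
                rt_lo=chem.start_rt,
                rt_hi=chem.start_rt + chem.chromatogram.duration,
                apex_intensity=chem.max_intensity * prop,
            )
        )
    return boxes
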
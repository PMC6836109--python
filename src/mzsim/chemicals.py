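"""Chemical objects: what the virtual mass spectrometer "sees".

Two construction routes mirror the two simulation workflows:

* the synthetic-sample workflow samples molecular formulas from a list
  (e.g., an HMDB export) and dresses each with a starting RT and maximum
  intensity drawn from the spectral feature database, a chromatogram
  template of similar apex intensity, adduct/isotope proportions and a
  fragmentation spectrum (:func:`sample_known_chemicals`);
* the existing-sample workflow converts each extracted ROI into a single
  unknown chemical that re-emits the observed trace
  (:func:`chemicals_from_rois`).

A known chemical's maximum intensity is split across its adduct x isotope
traces so the trace proportions sum to 1; an unknown chemical emits
exactly one trace.

Fragmentation spectra come from two baseline generators: independent
uniform draws from the MS2 peak pool, or a truncated Chinese Restaurant
Process in which a fragment peak is reused with probability proportional
to how often it has been served before (and a fresh peak is opened with
probability proportional to the concentration parameter), truncated so no
spectrum contains the same peak twice.

Replicate samples model technical/biological variation by dropping each
chemical independently with a dropout probability and jittering retained
maximum intensities with Gaussian noise (floored at 1 count).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from math import comb
from typing import Sequence

import numpy as np
from pyteomics import mass as _ptmass
from pyteomics.auxiliary import PyteomicsError

from .feature_db import SpectralFeatureDatabase, sample_feature
from .roi import ROI, NormalizedROI, normalize_roi

__all__ = [
    "PROTON_MASS",
    "C13_MASS_SHIFT",
    "Formula",
    "AdductSpec",
    "DEFAULT_ADDUCTS",
    "KnownChemical",
    "UnknownChemical",
    "CRPState",
    "monoisotopic_mass",
    "adduct_mz",
    "isotope_proportions",
    "ms1_traces",
    "sample_known_chemicals",
    "chemicals_from_rois",
    "replicate_samples",
    "assign_fragments",
    "cooccurrence_fraction",
]

PROTON_MASS = 1.00727646677  # Da
C13_MASS_SHIFT = 1.0033548378  # Da, 13C - 12C
_P13C = 0.0107  # natural abundance of 13C


@dataclass(frozen=True)
class Formula:
    """A molecular formula as element -> count."""

    element_counts: tuple[tuple[str, int], ...]

    @classmethod
    def parse(cls, formula: str) -> "Formula":
        """Parse a Hill-notation formula string, e.g. ``"C6H12O6"``."""
        try:
            comp = _ptmass.Composition(formula=formula)
        except PyteomicsError as exc:
            raise ValueError(f"cannot parse formula {formula!r}: {exc.message}") from exc
        counts = tuple(sorted((el, int(n)) for el, n in comp.items() if n))
        if not counts:
            raise ValueError(f"formula {formula!r} contains no atoms")
        return cls(counts)

    def as_dict(self) -> dict[str, int]:
        return dict(self.element_counts)

    def __str__(self) -> str:
        return "".join(f"{el}{n if n > 1 else ''}" for el, n in self.element_counts)


def monoisotopic_mass(formula: Formula | str) -> float:
    """Monoisotopic mass in Da: sum of count x lightest-isotope mass."""
    if isinstance(formula, str):
        formula = Formula.parse(formula)
    counts = formula.as_dict()
    if not counts:
        raise ValueError("empty formula has no mass")
    for el in counts:
        if el not in _ptmass.nist_mass:
            raise ValueError(f"unknown element {el!r}")
    return float(_ptmass.calculate_mass(composition=_ptmass.Composition(counts)))


@dataclass(frozen=True)
class AdductSpec:
    """An ionization adduct, e.g. M+H with shift +1.00728 Da at charge 1."""

    name: str
    mass_shift: float
    charge: int
    proportion: float

    def __post_init__(self) -> None:
        if int(self.charge) < 1:
            raise ValueError(f"adduct {self.name!r} must have charge >= 1")
        if not 0 <= self.proportion <= 1:
            raise ValueError("adduct proportion must be in [0, 1]")


DEFAULT_ADDUCTS: tuple[AdductSpec, ...] = (AdductSpec("M+H", PROTON_MASS, 1, 1.0),)


def adduct_mz(mass: float, adduct: AdductSpec) -> float:
    """m/z of an adduct ion: (neutral mass + shift) / charge."""
    if int(adduct.charge) < 1:
        raise ValueError("adduct charge must be >= 1")
    return (mass + adduct.mass_shift) / adduct.charge


def isotope_proportions(formula: Formula, max_shift: int = 2) -> list[float]:
    """Approximate natural-abundance isotope pattern, truncated at M+max_shift.

    Only the 13C contribution is modeled (a binomial over the carbon
    count), which captures the dominant isotope peaks of typical
    metabolites; the truncated pattern is renormalized to sum to 1.
    """
    nc = formula.as_dict().get("C", 0)
    raw = [
        comb(nc, k) * _P13C**k * (1 - _P13C) ** (nc - k) if k <= nc else 0.0
        for k in range(max_shift + 1)
    ]
    total = sum(raw)
    return [p / total for p in raw]


@dataclass
class KnownChemical:
    """A chemical with a known molecular formula (synthetic workflow)."""

    formula: Formula
    start_rt: float
    max_intensity: float
    chromatogram: NormalizedROI
    adducts: tuple[AdductSpec, ...]
    isotope_proportions: tuple[float, ...]
    fragments: tuple[tuple[float, float], ...] = ()
    chem_id: int | None = None

    def __post_init__(self) -> None:
        if self.max_intensity <= 0:
            raise ValueError("max_intensity must be positive")
        total = sum(a.proportion for a in self.adducts) * sum(self.isotope_proportions)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                "adduct x isotope proportions must sum to 1 "
                f"(got {total:.6f})"
            )


@dataclass
class UnknownChemical:
    """A chemical observed only as a trace (existing-sample workflow)."""

    observed_mz: float
    start_rt: float
    max_intensity: float
    chromatogram: NormalizedROI
    fragments: tuple[tuple[float, float], ...] = ()
    chem_id: int | None = None

    def __post_init__(self) -> None:
        if self.max_intensity <= 0:
            raise ValueError("max_intensity must be positive")


Chemical = KnownChemical | UnknownChemical


def ms1_traces(chem: Chemical) -> list[tuple[float, float]]:
    """The (base m/z, intensity proportion) traces a chemical emits in MS1.

    A known chemical emits one trace per adduct x isotope combination with
    proportions multiplying to 1 in total; an unknown chemical emits a
    single trace at its observed m/z.
    """
    if isinstance(chem, UnknownChemical):
        return [(chem.observed_mz, 1.0)]
    mass = monoisotopic_mass(chem.formula)
    traces = []
    for adduct in chem.adducts:
        for k, iso_p in enumerate(chem.isotope_proportions):
            traces.append(
                (
                    adduct_mz(mass + k * C13_MASS_SHIFT, adduct),
                    adduct.proportion * iso_p,
                )
            )
    return traces


@dataclass
class CRPState:
    """Seating counts of the (truncated) Chinese Restaurant Process.

    ``table_counts`` maps MS2-peak-pool indices to the number of times
    that peak has been served across previous spectra.
    """

    table_counts: dict[int, int] = field(default_factory=dict)
    concentration: float = 1.0

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("CRP concentration must be positive")
        if any(c <= 0 for c in self.table_counts.values()):
            raise ValueError("CRP table counts must be positive")


def _crp_spectrum(
    db: SpectralFeatureDatabase,
    count: int,
    state: CRPState,
    allowed: np.ndarray,
    rng: np.random.Generator,
) -> list[int]:
    allowed_set = set(int(i) for i in allowed)
    chosen: list[int] = []
    chosen_set: set[int] = set()
    for _ in range(count):
        tables = [
            (idx, c)
            for idx, c in sorted(state.table_counts.items())
            if idx in allowed_set and idx not in chosen_set
        ]
        denom = sum(c for _, c in tables) + state.concentration
        u = rng.random() * denom
        pick = None
        acc = 0.0
        for idx, c in tables:
            acc += c
            if u < acc:
                pick = idx
                break
        if pick is None:  # open a new table
            fresh = [
                i for i in allowed_set
                if i not in chosen_set and i not in state.table_counts
            ]
            if not fresh:
                fresh = [i for i in allowed_set if i not in chosen_set]
            if not fresh:
                break
            fresh.sort()
            pick = fresh[int(rng.integers(len(fresh)))]
        chosen.append(pick)
        chosen_set.add(pick)
        state.table_counts[pick] = state.table_counts.get(pick, 0) + 1
    return chosen


def assign_fragments(
    db: SpectralFeatureDatabase,
    rng: np.random.Generator,
    method: str = "random",
    crp_state: CRPState | None = None,
    max_mz: float | None = None,
) -> tuple[tuple[float, float], ...]:
    """Draw a fragmentation spectrum from the MS2 peak pool.

    The spectrum size is drawn from the empirical fragment-count pool.
    ``method="random"`` draws peaks independently (with replacement);
    ``method="crp"`` follows the truncated Chinese Restaurant Process in
    ``crp_state`` — reuse probability proportional to a peak's seating
    count, new-peak probability proportional to the concentration, and no
    peak served twice within one spectrum. ``max_mz`` optionally restricts
    the pool to fragments at or below a precursor m/z.

    Returns (m/z, relative intensity) pairs scaled to a maximum of 1.
    """
    if not db.ms2_peaks or not db.fragment_counts:
        raise ValueError("feature database has empty MS2 peak or fragment-count pool")
    count = int(sample_feature(db, "fragment_count", rng))
    peaks = np.asarray(db.ms2_peaks, dtype=float)
    allowed = np.arange(len(peaks))
    if max_mz is not None:
        allowed = allowed[peaks[:, 0] <= max_mz]
        if allowed.size == 0:
            return ()

    if method == "random":
        idx = allowed[rng.integers(allowed.size, size=count)]
    elif method == "crp":
        if crp_state is None:
            raise ValueError("crp fragment assignment requires a CRPState")
        idx = np.asarray(
            _crp_spectrum(db, min(count, allowed.size), crp_state, allowed, rng),
            dtype=int,
        )
    else:
        raise ValueError(f"unknown fragment assignment method {method!r}")

    if idx.size == 0:
        return ()
    chosen = peaks[idx]
    rel = chosen[:, 1] / chosen[:, 1].max()
    return tuple((float(m), float(r)) for m, r in zip(chosen[:, 0], rel))


def sample_known_chemicals(
    db: SpectralFeatureDatabase,
    n: int,
    adducts: Sequence[AdductSpec] = DEFAULT_ADDUCTS,
    roi_pool: Sequence[ROI] = (),
    rng: np.random.Generator | None = None,
    fragment_method: str = "random",
    crp_state: CRPState | None = None,
) -> list[KnownChemical]:
    """Create ``n`` known chemicals via the synthetic-sample workflow.

    Each chemical gets a formula drawn uniformly from ``db.formulas``, a
    starting RT and maximum intensity from an MS1 feature drawn from the
    database, the chromatogram template from ``roi_pool`` whose apex
    intensity is nearest in log10 to the chemical's maximum intensity,
    and a fragmentation spectrum from :func:`assign_fragments`.
    """
    if n <= 0:
        return []
    if not db.formulas:
        raise ValueError("feature database has no formulas to sample from")
    if not roi_pool:
        raise ValueError("roi_pool must be non-empty")
    if rng is None:
        rng = np.random.default_rng()
    adducts = tuple(adducts)
    total = sum(a.proportion for a in adducts)
    if abs(total - 1.0) > 1e-6:
        raise ValueError("adduct proportions must sum to 1")

    pool_log10 = np.log10([max(r.apex_intensity, 1e-12) for r in roi_pool])
    out: list[KnownChemical] = []
    for i in range(n):
        formula = Formula.parse(db.formulas[int(rng.integers(len(db.formulas)))])
        feat = sample_feature(db, "ms1", rng)
        nearest = int(np.argmin(np.abs(pool_log10 - np.log10(feat.max_intensity))))
        out.append(
            KnownChemical(
                formula=formula,
                start_rt=float(feat.rt),
                max_intensity=float(feat.max_intensity),
                chromatogram=normalize_roi(roi_pool[nearest]),
                adducts=adducts,
                isotope_proportions=tuple(isotope_proportions(formula)),
                fragments=assign_fragments(db, rng, fragment_method, crp_state),
                chem_id=i,
            )
        )
    return out


def chemicals_from_rois(rois: Sequence[ROI]) -> list[UnknownChemical]:
    """Convert extracted ROIs to unknown chemicals, one per ROI.

    The simplifying assumption is that each ROI is a single chemical: its
    observed m/z is the ROI mean m/z, its starting RT the first RT, its
    maximum intensity the apex intensity, and its chromatogram the
    normalized ROI.
    """
    return [
        UnknownChemical(
            observed_mz=roi.mean_mz,
            start_rt=roi.rts[0],
            max_intensity=roi.apex_intensity,
            chromatogram=normalize_roi(roi),
            chem_id=i,
        )
        for i, roi in enumerate(rois)
    ]


def replicate_samples(
    chemicals: Sequence[Chemical],
    noise_sd: float,
    dropout_prob: float,
    n_samples: int,
    rng: np.random.Generator,
) -> list[list[Chemical]]:
    """Generate related replicate samples from one chemical list.

    Each sample retains each chemical independently with probability
    ``1 - dropout_prob``; retained chemicals get independent Gaussian
    noise (SD ``noise_sd``) added to their maximum intensity, floored at
    1 count to keep intensities positive.
    """
    if not 0 <= dropout_prob < 1:
        raise ValueError("dropout_prob must be in [0, 1)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    samples: list[list[Chemical]] = []
    n = len(chemicals)
    for _ in range(n_samples):
        keep = rng.random(n) >= dropout_prob
        sample: list[Chemical] = []
        for chem, kept in zip(chemicals, keep):
            if not kept:
                continue
            if noise_sd > 0:
                new_int = max(1.0, chem.max_intensity + rng.normal(0.0, noise_sd))
                chem = dataclasses.replace(chem, max_intensity=new_int)
            sample.append(chem)
        samples.append(sample)
    return samples


def cooccurrence_fraction(
    sample_a: Sequence[Chemical], sample_b: Sequence[Chemical], n_total: int
) -> float:
    """Fraction of the original chemicals present in both samples.

    Requires chemicals to carry ``chem_id`` labels (as assigned by the
    generators in this package).
    """
    ids_a = {c.chem_id for c in sample_a}
    ids_b = {c.chem_id for c in sample_b}
    if None in ids_a or None in ids_b:
        raise ValueError("chemicals must carry chem_id labels")
    return len(ids_a & ids_b) / n_total
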
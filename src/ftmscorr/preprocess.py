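"""Per-peptide mass and isotope-ratio computation, XIC extraction, peak detection.

For each identified peptide this module computes the monoisotopic (all-¹²C)
m/z and the first ¹³C isotope m/z, the theoretical intensity ratio *r* of the
M+1 peak to the monoisotopic peak (fixed by elemental composition and natural
isotope abundances), extracts the two ion chromatograms from the MS1 scans,
and locates the elution-peak interval around the identified retention time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, NoPeakError
from .msio import PeptideRecord, ScanCollection

# Monoisotopic masses (u), CODATA/IUPAC.
MONO_MASS = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}
PROTON_MASS = 1.00727646688
C13_C12_DELTA = 1.0033548378

# Natural isotope abundances by nominal mass shift above the lightest isotope.
ISOTOPE_ABUNDANCE = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
}

# Residue (amino acid minus water) compositions as (C, H, N, O, S).
RESIDUE_COMPOSITION = {
    "G": (2, 3, 1, 1, 0), "A": (3, 5, 1, 1, 0), "S": (3, 5, 1, 2, 0),
    "P": (5, 7, 1, 1, 0), "V": (5, 9, 1, 1, 0), "T": (4, 7, 1, 2, 0),
    "C": (3, 5, 1, 1, 1), "L": (6, 11, 1, 1, 0), "I": (6, 11, 1, 1, 0),
    "N": (4, 6, 2, 2, 0), "D": (4, 5, 1, 3, 0), "Q": (5, 8, 2, 2, 0),
    "K": (6, 12, 2, 1, 0), "E": (5, 7, 1, 3, 0), "M": (5, 9, 1, 1, 1),
    "H": (6, 7, 3, 1, 0), "F": (9, 9, 1, 1, 0), "R": (6, 12, 4, 1, 0),
    "Y": (9, 9, 1, 2, 0), "W": (11, 10, 2, 1, 0),
}

_ELEMENTS = ("C", "H", "N", "O", "S")


@dataclass(frozen=True)
class ElementalComposition:
    """Atom counts of the neutral peptide (residues plus one water)."""

    C: int
    H: int
    N: int
    O: int
    S: int = 0

    def __post_init__(self):
        if any(getattr(self, e) < 0 for e in _ELEMENTS):
            raise InputError("negative atom count")

    def as_dict(self) -> dict[str, int]:
        return {e: getattr(self, e) for e in _ELEMENTS}


@dataclass
class ElutionProfile:
    """A time-ordered intensity trace y = [y(t1), y(t2), ...] for one ion."""

    times: np.ndarray  # seconds, strictly increasing
    intensities: np.ndarray  # ion counts, >= 0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if t.shape != y.shape or t.ndim != 1 or t.size < 1:
            raise InputError("profile arrays must be equal-length 1-D, length >= 1")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise InputError("profile times must be strictly increasing")
        if np.any(y < 0):
            raise InputError("negative intensity in elution profile")
        self.times, self.intensities = t, y

    def __len__(self) -> int:
        return len(self.times)

    @property
    def apex_intensity(self) -> float:
        return float(self.intensities.max())

    def with_intensities(self, values: np.ndarray) -> "ElutionProfile":
        return ElutionProfile(self.times.copy(), np.asarray(values, dtype=float))


@dataclass(frozen=True)
class PeakInterval:
    """Half-open [start, end) index interval on a profile's time axis."""

    start: int
    end: int

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise InputError(f"invalid peak interval [{self.start}, {self.end})")

    def slice(self) -> slice:
        return slice(self.start, self.end)


@dataclass
class IsotopePair:
    """Paired ¹²C (y1) and first-¹³C (y2) profiles of one peptide.

    ``r`` is the theoretical intensity ratio x2/x1 of the two species; the
    true (suppression-free) profiles satisfy x2 = r * x1 pointwise.
    """

    y1: ElutionProfile
    y2: ElutionProfile
    r: float
    peptide: PeptideRecord
    interval: PeakInterval | None = field(default=None)

    def __post_init__(self):
        if not np.array_equal(self.y1.times, self.y2.times):
            raise InputError("isotope pair profiles must share one time grid")
        if not 0.0 < self.r < 1.0:
            raise InputError(f"isotope ratio must be in (0, 1), got {self.r}")


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable preprocessing thresholds (typical Orbitrap-era defaults)."""

    tol_ppm: float = 10.0  # XIC m/z window half-width
    rt_window_s: float = 120.0  # apex search half-window around the id'd time
    boundary_frac: float = 0.05  # peak boundary at this fraction of apex


def elemental_composition(sequence: str) -> ElementalComposition:
    """Elemental composition of the neutral peptide: residue sum plus H2O."""
    if not sequence:
        raise InputError("empty peptide sequence")
    totals = [0, 0, 0, 0, 0]
    for ch in sequence:
        try:
            comp = RESIDUE_COMPOSITION[ch]
        except KeyError:
            raise InputError(f"unknown residue {ch!r} in {sequence!r}") from None
        for i, n in enumerate(comp):
            totals[i] += n
    totals[1] += 2  # H2O
    totals[3] += 1
    return ElementalComposition(*totals)


def monoisotopic_mass(composition: ElementalComposition) -> float:
    """Neutral monoisotopic mass in u."""
    return sum(n * MONO_MASS[e] for e, n in composition.as_dict().items())


def monoisotopic_mz(composition: ElementalComposition, charge: int) -> float:
    """m/z of the all-¹²C species at the given charge (protonation assumed)."""
    if charge < 1:
        raise InputError(f"charge must be >= 1, got {charge}")
    return (monoisotopic_mass(composition) + charge * PROTON_MASS) / charge


def isotope13_mz(mono_mz: float, charge: int) -> float:
    """m/z of the single-¹³C species: mono m/z shifted by the ¹³C-¹²C delta."""
    if charge < 1:
        raise InputError(f"charge must be >= 1, got {charge}")
    return mono_mz + C13_C12_DELTA / charge


def _element_distribution(element: str, count: int, n_terms: int) -> np.ndarray:
    """Isotopologue mass-shift distribution of ``count`` atoms of one element.

    Exact polynomial convolution (exponentiation by squaring), truncated to
    ``n_terms`` nominal mass shifts.
    """
    base = np.zeros(n_terms)
    abund = ISOTOPE_ABUNDANCE[element]
    base[: min(len(abund), n_terms)] = abund[:n_terms]
    result = np.zeros(n_terms)
    result[0] = 1.0
    power = base
    k = count
    while k:
        if k & 1:
            result = np.convolve(result, power)[:n_terms]
        k >>= 1
        if k:
            power = np.convolve(power, power)[:n_terms]
    return result


def isotope_distribution(composition: ElementalComposition, n_terms: int = 4) -> np.ndarray:
    """Aggregate isotope-pattern abundances at mass shifts 0..n_terms-1."""
    dist = np.zeros(n_terms)
    dist[0] = 1.0
    for element, count in composition.as_dict().items():
        if count:
            dist = np.convolve(dist, _element_distribution(element, count, n_terms))[:n_terms]
    return dist


def theoretical_isotope_ratio(composition: ElementalComposition) -> float:
    """Ratio r of the M+1 isotope-peak abundance to the monoisotopic peak.

    Computed by exact polynomial convolution of per-element natural isotope
    distributions.  The pairing used for correction is valid only when the
    value lies in (0, 1).
    """
    if all(n == 0 for n in composition.as_dict().values()):
        raise InputError("empty composition")
    dist = isotope_distribution(composition, n_terms=2)
    return float(dist[1] / dist[0])


def extract_xic(scans: ScanCollection, mz: float, tol_ppm: float = 10.0) -> ElutionProfile:
    """Extracted ion chromatogram: per scan, sum of peaks within ±tol_ppm of mz."""
    if tol_ppm <= 0:
        raise InputError(f"tol_ppm must be > 0, got {tol_ppm}")
    if len(scans) == 0:
        raise InputError("empty scan collection")
    half = mz * tol_ppm * 1e-6
    lo, hi = mz - half, mz + half
    times = np.empty(len(scans))
    inten = np.empty(len(scans))
    for i, scan in enumerate(scans.scans):
        times[i] = scan.retention_time
        a = np.searchsorted(scan.mz, lo, side="left")
        b = np.searchsorted(scan.mz, hi, side="right")
        inten[i] = scan.intensity[a:b].sum()
    return ElutionProfile(times, inten)


def _smooth3(y: np.ndarray) -> np.ndarray:
    """Centered 3-point moving average; endpoint samples are left unsmoothed."""
    if len(y) < 3:
        return y.astype(float)
    out = y.astype(float).copy()
    out[1:-1] = (y[:-2] + y[1:-1] + y[2:]) / 3.0
    return out


def detect_peak_interval(
    profile: ElutionProfile,
    rt_hint: float,
    rt_window_s: float = 120.0,
    boundary_frac: float = 0.05,
) -> PeakInterval:
    """Locate the elution-peak interval around an identified retention time.

    The apex is the maximum of the 3-point smoothed profile within
    ±rt_window_s of rt_hint; the interval expands outward while the smoothed
    intensity stays >= boundary_frac * apex and > 0.
    """
    if len(profile) < 3:
        raise InputError("profile too short for peak detection (need >= 3 points)")
    smoothed = _smooth3(profile.intensities)
    in_window = np.abs(profile.times - rt_hint) <= rt_window_s
    if not in_window.any():
        raise NoPeakError(
            f"no scans within ±{rt_window_s:g}s of rt={rt_hint:g}s"
        )
    windowed = np.where(in_window, smoothed, -np.inf)
    apex = int(np.argmax(windowed))
    apex_intensity = smoothed[apex]
    if apex_intensity <= 0:
        raise NoPeakError(f"apex intensity is 0 near rt={rt_hint:g}s")
    floor = boundary_frac * apex_intensity
    left = apex
    while left > 0 and smoothed[left - 1] >= floor and smoothed[left - 1] > 0:
        left -= 1
    right = apex
    n = len(profile)
    while right < n - 1 and smoothed[right + 1] >= floor and smoothed[right + 1] > 0:
        right += 1
    return PeakInterval(left, right + 1)


def build_isotope_pair(
    scans: ScanCollection,
    peptide: PeptideRecord,
    config: PreprocessConfig = PreprocessConfig(),
) -> IsotopePair:
    """Full preprocessing of one peptide: masses, ratio, XICs, peak interval."""
    comp = elemental_composition(peptide.sequence)
    mz1 = monoisotopic_mz(comp, peptide.charge)
    mz2 = isotope13_mz(mz1, peptide.charge)
    r = theoretical_isotope_ratio(comp)
    y1 = extract_xic(scans, mz1, config.tol_ppm)
    y2 = extract_xic(scans, mz2, config.tol_ppm)
    interval = detect_peak_interval(
        y1, peptide.elution_time, config.rt_window_s, config.boundary_frac
    )
    if not 0.0 < r < 1.0:
        raise InputError(
            f"isotope ratio {r:.3f} outside (0,1) for {peptide.sequence}"
        )
    return IsotopePair(y1=y1, y2=y2, r=r, peptide=peptide, interval=interval)
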
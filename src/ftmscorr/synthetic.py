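"""Ground-truthed synthetic LC-FTMS data embodying the suppression model.

The generators produce Gaussian elution peaks for ¹²C/¹³C isotope pairs that
share one true isotope ratio, pass the true profiles through an
intensity-dependent monotone distortion (identical for both isotopes of a
peptide, varying across peptides), add multiplicative measurement noise, and
— for run pairs — apply lognormal between-run abundance variation centered
at ratio 1.  Every generator is a pure function of its seed, and each output
carries a truth record sufficient to score downstream estimates.
"""

from __future__ import annotations

import base64
import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .msio import PeptideRecord, write_peptide_list
from .preprocess import (
    ElutionProfile,
    IsotopePair,
    elemental_composition,
    isotope13_mz,
    monoisotopic_mz,
    theoretical_isotope_ratio,
)

_RESIDUES = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class DistortionSpec:
    """Parametric distortion family: identity, or power-law in log space.

    The power law maps true intensity x to observed
    g(x) = threshold * (x / threshold)**gamma for x < threshold (identity
    above), which is continuous at the threshold, monotone, and suppressive
    (g(x) < x) for gamma > 1.
    """

    family: str = "power_law"  # "identity" | "power_law"
    gamma: float = 1.5
    threshold: float = 1e6

    def __post_init__(self):
        if self.family not in ("identity", "power_law"):
            raise InputError(f"unknown distortion family {self.family!r}")
        if self.family == "power_law" and self.gamma <= 1.0:
            raise InputError(f"power_law requires gamma > 1, got {self.gamma}")
        if self.threshold <= 0:
            raise InputError("threshold must be > 0")


def make_distortion(spec: DistortionSpec):
    """Return the callable pair (g, f): distortion and its exact inverse."""
    if spec.family == "identity":
        ident = lambda x: np.asarray(x, dtype=float) + 0.0  # noqa: E731
        return ident, ident
    thr, gamma = spec.threshold, spec.gamma

    def g(x):
        x = np.asarray(x, dtype=float)
        return np.where(x >= thr, x, np.where(x > 0, thr * (x / thr) ** gamma, 0.0))

    def f(y):
        y = np.asarray(y, dtype=float)
        return np.where(y >= thr, y, np.where(y > 0, thr * (y / thr) ** (1.0 / gamma), 0.0))

    return g, f


@dataclass
class PairTruth:
    """Ground truth for one generated isotope pair."""

    x1: ElutionProfile
    x2: ElutionProfile
    distortion: DistortionSpec
    r: float
    true_area1: float
    true_area2: float


def _gaussian_profile(times: np.ndarray, center: float, sigma: float,
                      apex: float) -> np.ndarray:
    return apex * np.exp(-0.5 * ((times - center) / sigma) ** 2)


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit mean and the given coefficient of variation."""
    if cv <= 0:
        return np.ones(size)
    s = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * s * s, sigma=s, size=size)


def random_sequence(rng: np.random.Generator, length: int | None = None) -> str:
    n = int(length or rng.integers(8, 21))
    return "".join(rng.choice(_RESIDUES, size=n))


def generate_pair(
    true_apex: float,
    r: float,
    distortion: DistortionSpec = DistortionSpec(),
    noise_cv: float = 0.0,
    n_scans: int = 61,
    seed: int = 0,
    *,
    dt: float = 1.0,
    sigma_scans: float = 5.0,
    center: float | None = None,
    peptide: PeptideRecord | None = None,
) -> tuple[IsotopePair, PairTruth]:
    """One synthetic isotope pair with known truth.

    The true ¹²C profile is Gaussian with the stated apex; the true ¹³C
    profile is r times it pointwise.  Observed profiles are the distorted
    true profiles with iid multiplicative lognormal noise of the stated CV.
    """
    if true_apex <= 0:
        raise InputError("true_apex must be > 0")
    if not 0.0 < r < 1.0:
        raise InputError(f"isotope ratio must be in (0, 1), got {r}")
    rng = np.random.default_rng(seed)
    times = np.arange(n_scans, dtype=float) * dt
    c = (n_scans - 1) * dt / 2.0 if center is None else center
    x1 = _gaussian_profile(times, c, sigma_scans * dt, true_apex)
    x2 = r * x1
    g, _ = make_distortion(distortion)
    y1 = g(x1) * _lognormal_noise(rng, noise_cv, n_scans)
    y2 = g(x2) * _lognormal_noise(rng, noise_cv, n_scans)
    if peptide is None:
        peptide = PeptideRecord(
            sequence=random_sequence(rng), charge=2, elution_time=c,
            id_probability=0.99,
        )
    p1 = ElutionProfile(times, x1)
    p2 = ElutionProfile(times, x2)
    pair = IsotopePair(
        y1=ElutionProfile(times, y1),
        y2=ElutionProfile(times, y2),
        r=r,
        peptide=peptide,
    )
    truth = PairTruth(
        x1=p1, x2=p2, distortion=distortion, r=r,
        true_area1=float(np.trapezoid(x1, times)),
        true_area2=float(np.trapezoid(x2, times)),
    )
    return pair, truth


@dataclass(frozen=True)
class RunSpec:
    """Parameters of a synthetic 1:1 label-free run pair.

    Defaults reflect a typical quality-control experiment: peptide apexes
    log-uniform over 1e4..1e7 ion counts, isotope ratios in the correctable
    window, one power-law distortion per peptide (shared by its two isotopes
    and both runs), 1% point noise and 0.05 log10 between-run variation.
    """

    n_peptides: int = 200
    apex_low: float = 1e4
    apex_high: float = 1e7
    sigma_scans: float = 5.0
    n_scans: int = 61
    r_low: float = 0.2
    r_high: float = 0.8
    gamma_low: float = 1.1
    gamma_high: float = 2.0
    distortion_family: str = "power_law"  # "identity" disables suppression
    identity_threshold: float = 1e6
    noise_cv: float = 0.01
    sigma_log10: float = 0.05  # per-run lognormal abundance variation
    seed: int = 0

    def __post_init__(self):
        if self.n_peptides < 1:
            raise InputError("n_peptides must be >= 1")
        if not (0 < self.apex_low < self.apex_high):
            raise InputError("apex range must be positive and ordered")
        if not (0 < self.r_low < self.r_high < 1):
            raise InputError("r range must lie inside (0, 1)")
        if not (1 < self.gamma_low <= self.gamma_high):
            raise InputError("gamma range must satisfy 1 < low <= high")
        if self.distortion_family not in ("identity", "power_law"):
            raise InputError(f"unknown distortion family {self.distortion_family!r}")


@dataclass
class SyntheticRun:
    """One synthetic LC-MS run: isotope pairs keyed by (sequence, charge)."""

    pairs: list[IsotopePair]
    identity_threshold: float = 1e6

    def __len__(self) -> int:
        return len(self.pairs)


def generate_run_pair(spec: RunSpec) -> tuple[SyntheticRun, SyntheticRun, pd.DataFrame]:
    """Generate a 1:1 run pair sharing true base abundances.

    Each run's true abundance is the shared base times an independent
    lognormal(0, sigma_log10) factor, so log10 fold changes of
    suppression-free peptides have SD ≈ sigma_log10 * sqrt(2).  Each peptide
    keeps its own distortion in both runs.
    """
    rng = np.random.default_rng(spec.seed)
    seqs: set[str] = set()
    runs: tuple[list[IsotopePair], list[IsotopePair]] = ([], [])
    rows = []
    for _ in range(spec.n_peptides):
        # the isotope ratio is a property of the sequence, so sample
        # sequences until the theoretical ratio falls in the usable window;
        # this keeps mzXML fixtures self-consistent with the profiles
        while True:
            seq = random_sequence(rng, length=int(rng.integers(4, 17)))
            if seq in seqs:
                continue
            r = theoretical_isotope_ratio(elemental_composition(seq))
            if spec.r_low <= r <= spec.r_high:
                break
        seqs.add(seq)
        apex = 10.0 ** rng.uniform(np.log10(spec.apex_low), np.log10(spec.apex_high))
        gamma = rng.uniform(spec.gamma_low, spec.gamma_high)
        if spec.distortion_family == "identity":
            gamma = 1.0
            dist = DistortionSpec("identity", threshold=spec.identity_threshold)
        else:
            dist = DistortionSpec("power_law", gamma, spec.identity_threshold)
        b = 10.0 ** rng.normal(0.0, spec.sigma_log10, size=2)
        peptide = PeptideRecord(
            sequence=seq, charge=int(rng.integers(2, 4)),
            elution_time=(spec.n_scans - 1) / 2.0, id_probability=0.99,
        )
        truths = []
        for k in range(2):
            pair, truth = generate_pair(
                true_apex=apex * b[k], r=r, distortion=dist,
                noise_cv=spec.noise_cv, n_scans=spec.n_scans,
                seed=int(rng.integers(0, 2**31 - 1)),
                sigma_scans=spec.sigma_scans, peptide=peptide,
            )
            runs[k].append(pair)
            truths.append(truth)
        rows.append(
            {
                "sequence": seq, "charge": peptide.charge, "base_apex": apex,
                "r": r, "gamma": gamma, "b1": b[0], "b2": b[1],
                "true_area1": truths[0].true_area1,
                "true_area2": truths[1].true_area1,
            }
        )
    truth_table = pd.DataFrame(rows)
    return (
        SyntheticRun(runs[0], spec.identity_threshold),
        SyntheticRun(runs[1], spec.identity_threshold),
        truth_table,
    )


def _encode_peaks(mz: np.ndarray, intensity: np.ndarray, precision: int = 64) -> str:
    fmt = ">%d%s" % (2 * len(mz), "d" if precision == 64 else "f")
    interleaved = np.empty(2 * len(mz))
    interleaved[0::2] = mz
    interleaved[1::2] = intensity
    return base64.b64encode(struct.pack(fmt, *interleaved)).decode()


def write_mzxml_fixture(run: SyntheticRun, path: str | Path,
                        precision: int = 64) -> None:
    """Write a run as a minimal valid mzXML file of msLevel-1 scans.

    Each peptide contributes two peaks per scan (monoisotopic and +1 m/z at
    its charge); a peptide-list TSV is written alongside with suffix
    ``.peptides.tsv``.
    """
    if len(run) == 0:
        raise InputError("cannot write an mzXML fixture for an empty run")
    path = Path(path)
    times = run.pairs[0].y1.times
    rows_mz: list[list[float]] = [[] for _ in times]
    rows_int: list[list[float]] = [[] for _ in times]
    for pair in run.pairs:
        if not np.array_equal(pair.y1.times, times):
            raise InputError("all pairs in a run must share one scan grid")
        comp = elemental_composition(pair.peptide.sequence)
        mz1 = monoisotopic_mz(comp, pair.peptide.charge)
        mz2 = isotope13_mz(mz1, pair.peptide.charge)
        for i in range(len(times)):
            for mz, inten in ((mz1, pair.y1.intensities[i]),
                              (mz2, pair.y2.intensities[i])):
                if inten > 0:
                    rows_mz[i].append(mz)
                    rows_int[i].append(inten)
    lines = [
        '<?xml version="1.0" encoding="ISO-8859-1"?>',
        '<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2">',
        f' <msRun scanCount="{len(times)}">',
    ]
    for i, t in enumerate(times):
        mz = np.array(rows_mz[i])
        inten = np.array(rows_int[i])
        order = np.argsort(mz, kind="stable")
        payload = _encode_peaks(mz[order], inten[order], precision)
        lines.append(
            f'  <scan num="{i + 1}" msLevel="1" peaksCount="{len(mz)}" '
            f'retentionTime="PT{t:.6f}S">'
        )
        lines.append(
            f'   <peaks precision="{precision}" byteOrder="network" '
            f'contentType="m/z-int" compressionType="none">{payload}</peaks>'
        )
        lines.append("  </scan>")
    lines += [" </msRun>", "</mzXML>", ""]
    path.write_text("\n".join(lines))
    write_peptide_list([p.peptide for p in run.pairs],
                       path.with_suffix(path.suffix + ".peptides.tsv"))


def peptide_list_path(mzxml_path: str | Path) -> Path:
    """Path of the peptide list written alongside an mzXML fixture."""
    p = Path(mzxml_path)
    return p.with_suffix(p.suffix + ".peptides.tsv")
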
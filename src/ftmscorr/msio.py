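"""Reading and writing of MS1 scans, peptide lists, result tables and caches.

MS1 spectra come in as mzXML (read through :mod:`pyteomics.mzxml`), the
identified-peptide list as a TSV with columns ``sequence``, ``charge``,
``elution_time`` and ``probability`` (a PeptideProphet-style posterior).
Results go out as a six-column TSV.  Retention times are normalized to
seconds on read regardless of the source units.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree
from pyteomics import mzxml as _mzxml

from .errors import InputError, MzxmlParseError, PeptideListError

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

RESULT_COLUMNS = (
    "sequence",
    "abundance_before",
    "correctable",
    "abundance_after",
    "fold_change",
    "p_value",
)


@dataclass(frozen=True)
class Scan:
    """One MS1 spectrum: centroided peaks at a single retention time."""

    retention_time: float  # seconds
    mz: np.ndarray  # Th, ascending
    intensity: np.ndarray  # ion counts, >= 0

    def __post_init__(self):
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape:
            raise InputError("mz and intensity arrays differ in length")
        if mz.size and np.any(np.diff(mz) < 0):
            raise InputError("scan m/z array is not sorted ascending")
        if np.any(inten < 0):
            raise InputError("negative peak intensity in scan")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)


@dataclass
class ScanCollection:
    """Time-ordered MS1 scans of one LC-MS run (msLevel-1 only)."""

    scans: list[Scan]

    def __post_init__(self):
        rts = [s.retention_time for s in self.scans]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise InputError("scan retention times are not strictly increasing")

    def __len__(self) -> int:
        return len(self.scans)

    @property
    def retention_times(self) -> np.ndarray:
        return np.array([s.retention_time for s in self.scans])


@dataclass(frozen=True)
class PeptideRecord:
    """One identified peptide: sequence, charge, elution time, id posterior."""

    sequence: str
    charge: int
    elution_time: float  # seconds
    id_probability: float

    def __post_init__(self):
        if not self.sequence:
            raise InputError("empty peptide sequence")
        bad = set(self.sequence) - STANDARD_RESIDUES
        if bad:
            raise InputError(
                f"sequence {self.sequence!r} contains non-residue character(s) "
                f"{sorted(bad)}"
            )
        if self.charge < 1:
            raise InputError(f"charge must be >= 1, got {self.charge}")
        if not 0.0 <= self.id_probability <= 1.0:
            raise InputError(
                f"id_probability must be in [0, 1], got {self.id_probability}"
            )


@dataclass
class FoldChangeResult:
    """Per-peptide output record of the differential analysis.

    ``abundance_before``/``abundance_after`` hold one value per dataset
    (run 1, run 2); for peptides that are not correctable the after-values
    equal the before-values.
    """

    sequence: str
    abundance_before: tuple[float, float]
    correctable: bool
    abundance_after: tuple[float, float]
    fold_change: float
    p_value: float
    reason: str = field(default="", compare=False)

    def __post_init__(self):
        if any(a < 0 for a in self.abundance_before + self.abundance_after):
            raise InputError("abundances must be >= 0")
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise InputError(f"p_value outside [0, 1]: {self.p_value}")
        if not self.correctable and self.abundance_after != self.abundance_before:
            raise InputError(
                "uncorrectable peptide must keep abundance_after == abundance_before"
            )


def read_mzxml(path: str | Path) -> ScanCollection:
    """Read MS1 scans from an mzXML file.

    Only msLevel-1 scans are kept; retention times are converted to seconds
    and scans are sorted by retention time.  Base64 peak blocks (32/64 bit,
    optionally zlib-compressed) are decoded by pyteomics.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"mzXML file not found: {path}")
    scans: list[Scan] = []
    try:
        with _mzxml.read(str(path), use_index=False) as reader:
            for entry in reader:
                if int(entry.get("msLevel", 0)) != 1:
                    continue
                rt = entry["retentionTime"]
                unit = getattr(rt, "unit_info", "minute")
                rt_s = float(rt) * 60.0 if unit == "minute" else float(rt)
                scans.append(
                    Scan(
                        retention_time=rt_s,
                        mz=entry["m/z array"],
                        intensity=entry["intensity array"],
                    )
                )
    except etree.XMLSyntaxError as exc:
        raise MzxmlParseError(
            f"malformed mzXML {path}: {exc.msg} (line {exc.lineno}, "
            f"column {exc.position[1]})"
        ) from exc
    if not scans:
        raise InputError(f"no msLevel-1 scans in {path}")
    scans.sort(key=lambda s: s.retention_time)
    return ScanCollection(scans)


def read_peptide_list(path: str | Path) -> list[PeptideRecord]:
    """Read an identified-peptide TSV (sequence, charge, elution_time, probability).

    Extra columns are ignored.  Any row violating a record invariant aborts
    the read with an error naming the row.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"peptide list not found: {path}")
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sequence", "charge", "elution_time", "probability"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise PeptideListError(f"{path}: missing column(s) {missing}")
    records: list[PeptideRecord] = []
    for i, row in enumerate(table.itertuples(index=False), start=2):  # 1 = header
        try:
            rec = PeptideRecord(
                sequence=str(getattr(row, "sequence")).strip(),
                charge=int(getattr(row, "charge")),
                elution_time=float(getattr(row, "elution_time")),
                id_probability=float(getattr(row, "probability")),
            )
        except (ValueError, TypeError) as exc:
            raise PeptideListError(f"{path} row {i}: unparsable value ({exc})") from exc
        except InputError as exc:
            raise PeptideListError(f"{path} row {i}: {exc}") from exc
        records.append(rec)
    return records


def write_peptide_list(records: list[PeptideRecord], path: str | Path) -> None:
    """Write records in the TSV dialect accepted by :func:`read_peptide_list`."""
    pd.DataFrame(
        {
            "sequence": [r.sequence for r in records],
            "charge": [r.charge for r in records],
            "elution_time": [f"{r.elution_time:.6g}" for r in records],
            "probability": [f"{r.id_probability:.6g}" for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def _fmt_pair(pair: tuple[float, float]) -> str:
    return f"{pair[0]:.6g};{pair[1]:.6g}"


def _parse_pair(text: str) -> tuple[float, float]:
    a, b = text.split(";")
    return float(a), float(b)


def write_results(results: list[FoldChangeResult], path: str | Path) -> None:
    """Write the six-column result TSV (one row per peptide, 6 sig. digits).

    The two per-dataset abundances share one column, joined by ``;``.
    """
    if not results:
        raise InputError("refusing to write an empty result table")
    rows = [
        {
            "sequence": r.sequence,
            "abundance_before": _fmt_pair(r.abundance_before),
            "correctable": str(bool(r.correctable)).lower(),
            "abundance_after": _fmt_pair(r.abundance_after),
            "fold_change": f"{r.fold_change:.6g}",
            "p_value": f"{r.p_value:.6g}",
        }
        for r in results
    ]
    pd.DataFrame(rows, columns=list(RESULT_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> list[FoldChangeResult]:
    """Read back a result TSV written by :func:`write_results`."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in RESULT_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"{path}: missing result column(s) {missing}")
    out = []
    for row in table.itertuples(index=False):
        out.append(
            FoldChangeResult(
                sequence=row.sequence,
                abundance_before=_parse_pair(row.abundance_before),
                correctable=row.correctable == "true",
                abundance_after=_parse_pair(row.abundance_after),
                fold_change=float(row.fold_change),
                p_value=float(row.p_value),
            )
        )
    return out


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_cache(entries: list[dict], path: str | Path, *, mzxml_sha256: str,
                peptides_sha256: str) -> None:
    """Persist preprocessing output (XIC pairs, intervals, isotope ratios).

    The cache is a deterministic JSON document keyed by the checksums of the
    inputs it was derived from, so reruns on identical inputs are
    byte-identical and stale caches are detectable.
    """
    doc = {
        "format": "ftmscorr-cache",
        "version": 1,
        "mzxml_sha256": mzxml_sha256,
        "peptides_sha256": peptides_sha256,
        "entries": entries,
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True, indent=None,
                                     separators=(",", ":")))


def read_cache(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise InputError(f"cache file not found: {path}")
    doc = json.loads(path.read_text())
    if doc.get("format") != "ftmscorr-cache":
        raise InputError(f"{path} is not an ftmscorr cache file")
    return doc
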
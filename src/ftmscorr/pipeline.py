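"""High-level pipeline steps tying preprocessing, correction and analysis together."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import msio
from .config import RunConfig
from .errors import FtmscorrError, InputError
from .preprocess import (
    ElutionProfile,
    IsotopePair,
    PeakInterval,
    build_isotope_pair,
)
from .suppression_analysis import (
    NullDistribution,
    assign_significance,
    build_function_library,
    experimental_null,
)

logger = logging.getLogger(__name__)


def preprocess_to_cache(
    mzxml_path: str | Path,
    peptides_path: str | Path,
    cache_path: str | Path,
    config: RunConfig = RunConfig(),
) -> dict:
    """Compute per-peptide XIC pairs, intervals and isotope ratios; cache them.

    Peptides whose preprocessing fails (no peak, ratio out of the usable
    range) are recorded in the cache with a skip reason instead of aborting
    the run.  Reruns on unchanged inputs are byte-identical.
    """
    scans = msio.read_mzxml(mzxml_path)
    peptides = msio.read_peptide_list(peptides_path)
    entries = []
    for pep in peptides:
        base = {
            "sequence": pep.sequence,
            "charge": pep.charge,
            "elution_time": pep.elution_time,
            "probability": pep.id_probability,
        }
        try:
            pair = build_isotope_pair(scans, pep, config.preprocess)
        except FtmscorrError as exc:
            logger.info("skipping %s: %s", pep.sequence, exc)
            entries.append({**base, "skip_reason": str(exc)})
            continue
        entries.append(
            {
                **base,
                "r": pair.r,
                "times": pair.y1.times.tolist(),
                "y1": pair.y1.intensities.tolist(),
                "y2": pair.y2.intensities.tolist(),
                "interval": [pair.interval.start, pair.interval.end],
            }
        )
    doc_checksums = {
        "mzxml_sha256": msio.file_sha256(mzxml_path),
        "peptides_sha256": msio.file_sha256(peptides_path),
    }
    msio.write_cache(entries, cache_path, **doc_checksums)
    return {"n_peptides": len(peptides),
            "n_cached": sum(1 for e in entries if "skip_reason" not in e)}


def pairs_from_cache(cache_path: str | Path) -> list[IsotopePair]:
    """Rebuild isotope pairs from a preprocessing cache."""
    doc = msio.read_cache(cache_path)
    pairs = []
    for entry in doc["entries"]:
        if "skip_reason" in entry:
            continue
        peptide = msio.PeptideRecord(
            sequence=entry["sequence"],
            charge=int(entry["charge"]),
            elution_time=float(entry["elution_time"]),
            id_probability=float(entry["probability"]),
        )
        times = np.array(entry["times"])
        pairs.append(
            IsotopePair(
                y1=ElutionProfile(times, np.array(entry["y1"])),
                y2=ElutionProfile(times, np.array(entry["y2"])),
                r=float(entry["r"]),
                peptide=peptide,
                interval=PeakInterval(*entry["interval"]),
            )
        )
    if not pairs:
        raise InputError(f"cache {cache_path} holds no usable peptides")
    return pairs


def analyze_pair(
    pairs1: list[IsotopePair],
    pairs2: list[IsotopePair],
    config: RunConfig = RunConfig(),
    null_source: NullDistribution | None = None,
) -> list[msio.FoldChangeResult]:
    """Correction → function library → null prediction → significance.

    ``null_source`` is an experimental null from a dedicated 1:1 run pair;
    when omitted, the analyzed pair itself is treated as 1:1 and its
    suppression-free peptides provide the experimental null.
    """
    library = build_function_library(pairs1, config.correction, dataset_id="run1")
    logger.info(
        "function library: %d fitted, %d skipped", len(library), len(library.skipped)
    )
    if null_source is None:
        null_source = experimental_null(
            pairs1, pairs2, config.correction.identity_threshold
        )
    results = assign_significance(
        pairs1, pairs2, library, null_source, config.analysis
    )
    n_corr = sum(1 for r in results if r.correctable)
    logger.info(
        "%d peptides analyzed: %d correctable, %d uncorrectable",
        len(results), n_corr, len(results) - n_corr,
    )
    return results
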
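"""Suppression characterization, null-distribution prediction, significance.

The correction functions estimated from correctable isotope pairs are pooled
into a library and treated as random samples of all possible distortion
functions of the instrument.  Pushing a template elution profile through the
library characterizes suppression across intensity levels; pushing samples
of the experimental null distribution (fold changes of suppression-free
peptides in a 1:1 replicate pair) through the library yields a predicted
null distribution at any intensity level, against which measured fold
changes receive empirical two-sided P-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .correction import (
    CorrectionConfig,
    CorrectionFunction,
    check_correction_conditions,
    fit_correction_function,
    profile_area,
)
from .errors import FtmscorrError, InputError
from .msio import FoldChangeResult
from .preprocess import ElutionProfile, IsotopePair

logger = logging.getLogger(__name__)

MIN_NULL_SIZE = 30  # minimum sample size for a null used in P-value computation


@dataclass
class FunctionLibrary:
    """Pooled correction functions g_i, i in 1..N, with their provenance."""

    functions: list[CorrectionFunction]
    provenance: list[str]
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        if len(self.functions) < 1:
            raise InputError("function library must contain at least one function")
        if len(self.provenance) != len(self.functions):
            raise InputError("provenance must match functions one-to-one")

    def __len__(self) -> int:
        return len(self.functions)


@dataclass
class NullDistribution:
    """Empirical sample of log10 fold changes at (optionally) one intensity level."""

    log_ratios: np.ndarray
    kind: str  # "experimental" | "predicted" | "observed"
    intensity_level: float | None = None
    warning: str | None = None

    def __post_init__(self):
        if self.kind not in ("experimental", "predicted", "observed"):
            raise InputError(f"unknown null kind {self.kind!r}")
        self.log_ratios = np.asarray(self.log_ratios, dtype=float)
        if self.log_ratios.ndim != 1 or self.log_ratios.size < 1:
            raise InputError("null distribution needs a non-empty 1-D sample")

    @property
    def n(self) -> int:
        return int(self.log_ratios.size)

    @property
    def median(self) -> float:
        return float(np.median(self.log_ratios))

    @property
    def sd(self) -> float:
        return float(np.std(self.log_ratios, ddof=1)) if self.n > 1 else 0.0

    def to_tsv(self, path) -> None:
        pd.DataFrame({"log10_ratio": self.log_ratios}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path, kind: str = "experimental") -> "NullDistribution":
        table = pd.read_csv(path, sep="\t")
        if "log10_ratio" not in table.columns:
            raise InputError(f"{path}: expected a log10_ratio column")
        return cls(table["log10_ratio"].to_numpy(), kind=kind)


def build_function_library(
    pairs: list[IsotopePair],
    config: CorrectionConfig = CorrectionConfig(),
    dataset_id: str = "run",
) -> FunctionLibrary:
    """Fit every correctable pair and pool the resulting functions.

    Uncorrectable or non-converging pairs are skipped with a logged reason;
    an error is raised only if no pair at all can be corrected.
    """
    functions, provenance, skipped = [], [], []
    for pair in pairs:
        label = f"{dataset_id}:{pair.peptide.sequence}/{pair.peptide.charge}"
        verdict = check_correction_conditions(pair, config)
        if not verdict.correctable:
            skipped.append((label, verdict.reason))
            logger.info("skipping %s: %s", label, verdict.reason)
            continue
        try:
            f, _, _ = fit_correction_function(pair, config)
        except FtmscorrError as exc:
            skipped.append((label, str(exc)))
            logger.info("skipping %s: %s", label, exc)
            continue
        functions.append(f)
        provenance.append(label)
    if not functions:
        reasons = pd.Series([r for _, r in skipped])
        top = reasons.value_counts().idxmax() if len(reasons) else "no pairs"
        raise InputError(
            f"no correctable pairs in {dataset_id}; most common reason: {top}"
        )
    return FunctionLibrary(functions, provenance, skipped)


def suppression_statistics(
    library: FunctionLibrary,
    template: ElutionProfile,
    levels: list[float],
) -> pd.DataFrame:
    """Mean/SD suppression ratio across the library at each intensity level.

    At each level the template is scaled so its apex equals the level, every
    distortion g_i is applied, and the area ratio distorted/true is recorded.
    Columns: level, mean_ratio, sd, band_low, band_high (mean ± 3·SD).
    """
    rows = []
    base = template.intensities / template.apex_intensity
    for level in levels:
        scaled = template.with_intensities(base * level)
        true_area = profile_area(scaled)
        ratios = np.array(
            [
                profile_area(scaled.with_intensities(f.distortion(scaled.intensities)))
                / true_area
                for f in library.functions
            ]
        )
        mean = float(ratios.mean())
        sd = float(ratios.std(ddof=1)) if len(ratios) > 1 else 0.0
        rows.append(
            {
                "level": level,
                "mean_ratio": mean,
                "sd": sd,
                "band_low": mean - 3 * sd,
                "band_high": mean + 3 * sd,
            }
        )
    return pd.DataFrame(rows)


def _match_pairs(
    pairs_run1: list[IsotopePair], pairs_run2: list[IsotopePair]
) -> list[tuple[IsotopePair, IsotopePair]]:
    key = lambda p: (p.peptide.sequence, p.peptide.charge)  # noqa: E731
    index2 = {key(p): p for p in pairs_run2}
    return [(p, index2[key(p)]) for p in pairs_run1 if key(p) in index2]


def experimental_null(
    pairs_run1: list[IsotopePair],
    pairs_run2: list[IsotopePair],
    threshold: float = 1e6,
) -> NullDistribution:
    """Fold-change null from suppression-free peptides of a 1:1 run pair.

    Peptides are matched by (sequence, charge); those whose ¹²C apex exceeds
    the distortion-free threshold in both runs contribute
    log10(area2 / area1).  Their variation reflects only the experimental
    (sample-handling) process, not instrumental suppression.
    """
    matched = _match_pairs(pairs_run1, pairs_run2)
    if not matched:
        raise InputError("no peptides matched between the two runs")
    log_ratios = []
    for p1, p2 in matched:
        if (
            p1.y1.apex_intensity > threshold
            and p2.y1.apex_intensity > threshold
        ):
            # only the portion of the profiles above the distortion-free
            # threshold in both runs is guaranteed suppression-free; the
            # below-threshold tails would leak instrumental variation into
            # the experimental null
            y1a = p1.y1.intensities
            if np.array_equal(p1.y1.times, p2.y1.times):
                y1b = p2.y1.intensities
            else:  # different scan grids: resample run 2 onto run 1's grid
                y1b = np.interp(
                    p1.y1.times, p2.y1.times, p2.y1.intensities,
                    left=0.0, right=0.0,
                )
            mask = (y1a > threshold) & (y1b > threshold)
            if mask.sum() < 2:
                continue
            t = p1.y1.times[mask]
            a1 = float(np.trapezoid(y1a[mask], t))
            a2 = float(np.trapezoid(y1b[mask], t))
            if a1 > 0 and a2 > 0:
                log_ratios.append(np.log10(a2 / a1))
    if len(log_ratios) < 5:
        raise InputError(
            f"only {len(log_ratios)} suppression-free matched peptides; "
            "cannot estimate the experimental null"
        )
    warning = None
    if len(log_ratios) < MIN_NULL_SIZE:
        warning = (
            f"experimental null based on only {len(log_ratios)} peptides "
            f"(< {MIN_NULL_SIZE}); P-values will be unstable"
        )
        logger.warning(warning)
    return NullDistribution(
        np.array(log_ratios), kind="experimental", warning=warning
    )


def predict_null(
    exp_null: NullDistribution,
    library: FunctionLibrary,
    template: ElutionProfile,
    level: float,
    n_draws: int = 1000,
    seed: int = 0,
) -> NullDistribution:
    """Push experimental-null samples through the distortion library.

    For each draw a^j from the experimental null and each library function
    g_i, the predicted fold-change ratio is
    r^ij = area(g_i(a^j * y_p)) / area(g_i(y_p)), with the template y_p
    scaled to the requested apex level.  The pooled log10 r^ij form the
    predicted null at that level.  Deterministic given the seed.
    """
    if exp_null.kind != "experimental":
        raise InputError("predict_null requires an experimental null")
    rng = np.random.default_rng(seed)
    draws = rng.choice(exp_null.log_ratios, size=n_draws, replace=True)
    a = 10.0 ** draws
    yp = template.intensities * (level / template.apex_intensity)
    t = template.times
    flagged = all(
        level >= f.identity_threshold for f in library.functions
    )
    log_ratios = np.empty(len(library) * n_draws)
    scaled = a[:, None] * yp[None, :]  # (n_draws, n_points)
    for i, f in enumerate(library.functions):
        denom = np.trapezoid(f.distortion(yp), t)
        numer = np.trapezoid(
            f.distortion(scaled.ravel()).reshape(scaled.shape), t, axis=1
        )
        log_ratios[i * n_draws : (i + 1) * n_draws] = np.log10(numer / denom)
    warning = (
        "intensity level above the library's suppression range; predicted "
        "null reduces to a resample of the experimental null"
        if flagged
        else None
    )
    return NullDistribution(
        log_ratios, kind="predicted", intensity_level=level, warning=warning
    )


def ks_compare(a: NullDistribution, b: NullDistribution) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov D statistic and asymptotic p-value."""
    if a.n < 5 or b.n < 5:
        raise InputError("KS comparison needs at least 5 points per sample")
    res = stats.ks_2samp(a.log_ratios, b.log_ratios, method="asymp")
    return float(res.statistic), float(res.pvalue)


def fold_change_pvalue(fc: float, null: NullDistribution) -> float:
    """Two-sided empirical P-value of a fold change under a null sample.

    With m null log-ratios and k of them at least as far from the null
    median as log10(fc), p = (k + 1) / (m + 1); the add-one rule keeps
    p > 0 for fold changes beyond the null's support.
    """
    if fc <= 0:
        raise InputError(f"fold change must be > 0, got {fc}")
    if null.n < MIN_NULL_SIZE:
        raise InputError(
            f"null sample too small for P-values ({null.n} < {MIN_NULL_SIZE})"
        )
    center = null.median
    dev = abs(np.log10(fc) - center)
    # small absolute slack so a fold change at the null median (up to the
    # log/exp float round trip) counts every null point as extreme
    k = int(np.sum(np.abs(null.log_ratios - center) + 1e-12 >= dev))
    return (k + 1) / (null.n + 1)


@dataclass(frozen=True)
class AnalysisConfig:
    """Parameters of the significance-assignment step."""

    correction: CorrectionConfig = CorrectionConfig()
    bin_width_log10: float = 0.5  # half-decade intensity strata
    n_draws: int = 1000  # experimental-null draws per predicted null
    seed: int = 0
    template_sigma_scans: float = 5.0  # Gaussian template elution SD
    template_n_scans: int = 61


def default_template(
    n_scans: int = 61, sigma_scans: float = 5.0, dt: float = 1.0
) -> ElutionProfile:
    """Unit-apex Gaussian elution template used for null prediction."""
    t = np.arange(n_scans, dtype=float) * dt
    c = (n_scans - 1) * dt / 2.0
    return ElutionProfile(t, np.exp(-0.5 * ((t - c) / (sigma_scans * dt)) ** 2))


def intensity_bin(apex: float, bin_width_log10: float = 0.5) -> float:
    """Center (in ion counts) of the log10 intensity stratum holding ``apex``."""
    idx = np.floor(np.log10(apex) / bin_width_log10)
    return float(10.0 ** ((idx + 0.5) * bin_width_log10))


def assign_significance(
    pairs_run1: list[IsotopePair],
    pairs_run2: list[IsotopePair],
    library: FunctionLibrary,
    exp_null: NullDistribution,
    config: AnalysisConfig = AnalysisConfig(),
    template: ElutionProfile | None = None,
) -> list[FoldChangeResult]:
    """Per-peptide fold changes and P-values for a matched run pair.

    Correctable-in-both-runs peptides are corrected and tested against the
    experimental null; all others are tested against the predicted null of
    the half-decade intensity stratum of the taller profile's apex
    (predicted nulls are cached per stratum).
    """
    matched = _match_pairs(pairs_run1, pairs_run2)
    if not matched:
        raise InputError("no peptides matched between the two runs")
    if template is None:
        template = default_template(
            config.template_n_scans, config.template_sigma_scans
        )
    null_cache: dict[float, NullDistribution] = {}
    results: list[FoldChangeResult] = []
    for p1, p2 in matched:
        before = (
            profile_area(p1.y1, p1.interval),
            profile_area(p2.y1, p2.interval),
        )
        try:
            v1 = check_correction_conditions(p1, config.correction)
            v2 = check_correction_conditions(p2, config.correction)
            if v1.correctable and v2.correctable:
                f1, x1a, _ = fit_correction_function(p1, config.correction)
                f2, x1b, _ = fit_correction_function(p2, config.correction)
                after = (
                    profile_area(x1a, p1.interval),
                    profile_area(x1b, p2.interval),
                )
                fc = after[1] / after[0]
                p = fold_change_pvalue(fc, exp_null)
                results.append(
                    FoldChangeResult(
                        sequence=p1.peptide.sequence,
                        abundance_before=before,
                        correctable=True,
                        abundance_after=after,
                        fold_change=fc,
                        p_value=p,
                    )
                )
                continue
            if before[0] <= 0 or before[1] <= 0:
                raise InputError("zero uncorrected abundance")
            fc = before[1] / before[0]
            taller = max(p1.y1.apex_intensity, p2.y1.apex_intensity)
            level = intensity_bin(taller, config.bin_width_log10)
            if level not in null_cache:
                null_cache[level] = predict_null(
                    exp_null,
                    library,
                    template,
                    level,
                    n_draws=config.n_draws,
                    seed=config.seed + int(round(np.log10(level) * 1000)) % 100000,
                )
            # the predicted null holds N * n_draws points but only
            # exp_null.n independent experimental draws stand behind them,
            # so its P-values are floored at the experimental resolution
            p = max(
                fold_change_pvalue(fc, null_cache[level]),
                1.0 / (exp_null.n + 1),
            )
            results.append(
                FoldChangeResult(
                    sequence=p1.peptide.sequence,
                    abundance_before=before,
                    correctable=False,
                    abundance_after=before,
                    fold_change=fc,
                    p_value=p,
                )
            )
        except FtmscorrError as exc:
            logger.warning(
                "peptide %s failed: %s", p1.peptide.sequence, exc
            )
            results.append(
                FoldChangeResult(
                    sequence=p1.peptide.sequence,
                    abundance_before=before,
                    correctable=False,
                    abundance_after=before,
                    fold_change=float("nan"),
                    p_value=float("nan"),
                    reason=str(exc),
                )
            )
    return results
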
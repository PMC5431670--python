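"""Distribution-level statistics for SAV effect scores.

The central descriptive device is the cumulative effect curve: for each
integer threshold t on the SNAP2 scale [-100, 100], the fraction of a score
set predicted at or above t.  Curves are compared across variant classes
(rare / uncommon / common within-human, cross-species, random backgrounds,
disease) with two-sample Kolmogorov-Smirnov tests, and their uncertainty is
quantified by a bootstrap standard error of the mean (100 resamples by
default), drawn as the curve shifted by +-3 SEM along the score axis.

Also here: Pearson correlations between prediction methods with the
analytic standard error SE_r = sqrt((1 - r^2) / (n - 2)), binary
effect/neutral projections per method, accuracy-from-the-extremes curves on
labelled reference data, the effect AUC (empirical score mass above 0), and
the error-corrected effect/neutral fractions
Neff* = Neff - FPR*Neff + FNR*Nneu.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .variant_model import MissingScoreError, ScoredSAV, VariantModelError

#: Integer threshold grid of the SNAP2 score axis.
SCORE_GRID = np.arange(-100, 101)

#: Smallest p-value reported verbatim; anything below is floored and
#: formatted as "< 2.2e-16".
P_FLOOR = 2.2e-16

#: Named example thresholds on the SNAP2 scale: strong-neutral at -42
#: (~85% neutral accuracy), strong-effect at +50 (~85%) and +75 (~88%).
THRESHOLD_PRESETS = {"neutral85": -42, "effect85": 50, "effect88": 75}

#: Default binary effect rules and correlation transforms per method.
#: SIFT scores are inverted (1 - score) before correlation so that high
#: always means effect.
METHOD_DEFAULTS: dict[str, "MethodConfig"]


class StatisticsError(VariantModelError):
    pass


class EmptyInputError(StatisticsError):
    pass


def _as_scores(scores: Iterable[float], bounded: bool = False) -> np.ndarray:
    arr = np.asarray(list(scores) if not isinstance(scores, np.ndarray) else scores,
                     dtype=float)
    if arr.size == 0:
        raise EmptyInputError("empty score set")
    if bounded and (arr.min() < -100 or arr.max() > 100):
        raise StatisticsError("scores outside [-100, 100]")
    return arr


# ---------------------------------------------------------------------------
# Bootstrap SEM and cumulative curves
# ---------------------------------------------------------------------------

def bootstrap_sem(scores: Iterable[float], n_boot: int = 100, seed: int = 0) -> float:
    """Bootstrap standard error of the mean.

    Draws ``n_boot`` resamples of size n with replacement, computes each
    resample mean, and returns the standard deviation (ddof=1) of those
    means.
    """
    if n_boot < 2:
        raise StatisticsError(f"n_boot must be >= 2, got {n_boot}")
    arr = _as_scores(scores)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, arr.size, size=(n_boot, arr.size))
    means = arr[idx].mean(axis=1)
    return float(means.std(ddof=1))


@dataclass(frozen=True)
class CumulativeCurve:
    """Fraction of scores at or above each integer threshold.

    ``fraction(t) = |{s : s >= t}| / n``; non-increasing in t, with
    fraction(-100) = 1 for any non-empty set.  ``sem`` is the bootstrap SEM
    of the score mean; the 99.7% confidence band is the curve shifted by
    +-3 SEM along the score axis (``band_offset``).
    """

    thresholds: np.ndarray
    fraction: np.ndarray
    sem: float
    n: int

    @property
    def band_offset(self) -> float:
        return 3.0 * self.sem

    def band_curves(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) band thresholds: the grid shifted by -+3 SEM."""
        return self.thresholds - self.band_offset, self.thresholds + self.band_offset

    def at(self, threshold: float) -> float:
        """Fraction of scores >= threshold (grid lookup for integers,
        direct comparison otherwise)."""
        i = np.searchsorted(self.thresholds, threshold)
        if i < len(self.thresholds) and self.thresholds[i] == threshold:
            return float(self.fraction[i])
        raise StatisticsError(f"threshold {threshold} not on the grid")


def cumulative_effect_curve(
    scores: Iterable[float],
    n_boot: int = 100,
    seed: int = 0,
    thresholds: Optional[np.ndarray] = None,
) -> CumulativeCurve:
    """Cumulative fraction-at-or-above curve over the integer score grid,
    with bootstrap SEM (``n_boot = 0`` disables the bootstrap)."""
    arr = _as_scores(scores, bounded=True)
    grid = SCORE_GRID if thresholds is None else np.asarray(thresholds)
    sorted_scores = np.sort(arr)
    # |{s >= t}| = n - (number of scores strictly below t)
    below = np.searchsorted(sorted_scores, grid, side="left")
    fraction = (arr.size - below) / arr.size
    sem = bootstrap_sem(arr, n_boot, seed) if n_boot else 0.0
    return CumulativeCurve(grid, fraction, sem, int(arr.size))


# ---------------------------------------------------------------------------
# Two-sample Kolmogorov-Smirnov
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KSResult:
    """Two-sample KS comparison: D is the supremum gap between the two
    empirical distribution functions; p from the asymptotic Kolmogorov
    distribution with effective size n*n'/(n+n')."""

    D: float
    p: float
    n: int
    n_prime: int

    @property
    def p_text(self) -> str:
        return f"< {P_FLOOR:.1e}" if self.p < P_FLOOR else f"{self.p:.3g}"


def ks_two_sample(a: Iterable[float], b: Iterable[float]) -> KSResult:
    """Two-sample KS test (asymptotic p-value, floored at 2.2e-16)."""
    xa = _as_scores(a)
    xb = _as_scores(b)
    with np.errstate(divide="ignore"):  # asymptotic p at n = 1
        res = sps.ks_2samp(xa, xb, method="asymp")
    return KSResult(D=float(res.statistic), p=float(res.pvalue),
                    n=int(xa.size), n_prime=int(xb.size))


# ---------------------------------------------------------------------------
# Correlation with analytic standard error
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    r: float
    se_r: float
    n: int


def se_of_r(r: float, n: int) -> float:
    """Standard error of a Pearson coefficient: sqrt((1 - r^2) / (n - 2))."""
    if n < 3:
        raise StatisticsError(f"need n >= 3 for SE_r, got {n}")
    return float(np.sqrt((1.0 - r * r) / (n - 2)))


def pearson_with_se(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson r over complete pairs (pairs with either value missing/NaN
    are dropped first) plus its analytic standard error."""
    xa = np.asarray([np.nan if v is None else float(v) for v in x])
    ya = np.asarray([np.nan if v is None else float(v) for v in y])
    if xa.size != ya.size:
        raise StatisticsError("x and y differ in length")
    mask = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[mask], ya[mask]
    n = int(xa.size)
    if n < 3:
        raise StatisticsError(f"fewer than 3 complete pairs (n={n})")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise StatisticsError("zero variance: correlation undefined")
    r = float(sps.pearsonr(xa, ya).statistic)
    return CorrelationResult(r=r, se_r=se_of_r(r, n), n=n)


# ---------------------------------------------------------------------------
# Effect AUC and binary projection
# ---------------------------------------------------------------------------

def effect_auc(scores: Iterable[float]) -> float:
    """Empirical score mass on the effect side (0, 100]: the fraction of
    scores strictly greater than 0."""
    arr = _as_scores(scores, bounded=True)
    return float(np.mean(arr > 0))


@dataclass(frozen=True)
class MethodConfig:
    """Binary effect rule and correlation transform for one method.

    Exactly one of ``threshold`` (numeric: effect iff score > threshold) or
    ``effect_labels`` (categorical: effect iff label in the set) is given.
    ``invert`` maps the raw score to 1 - score before correlation.
    """

    name: str
    threshold: Optional[float] = None
    effect_labels: Optional[frozenset[str]] = None
    invert: bool = False

    def __post_init__(self) -> None:
        if (self.threshold is None) == (self.effect_labels is None):
            raise StatisticsError(
                f"method {self.name!r}: exactly one of threshold / "
                "effect_labels must be set"
            )


METHOD_DEFAULTS = {
    "SNAP2": MethodConfig("SNAP2", threshold=0.0),
    "CADD": MethodConfig("CADD", threshold=3.0),
    "PolyPhen-2": MethodConfig(
        "PolyPhen-2",
        effect_labels=frozenset({"probably_damaging", "possibly_damaging",
                                 "probably damaging", "possibly damaging"}),
    ),
    "SIFT": MethodConfig("SIFT", effect_labels=frozenset({"deleterious"}),
                         invert=True),
}


def classify_binary(scored: ScoredSAV, config: MethodConfig) -> str:
    """Project a raw score onto {"effect", "neutral"} per the method's rule
    (e.g. SNAP2 > 0 is effect, so a score of exactly 0 is neutral)."""
    value = scored.score(config.name)
    if config.threshold is not None:
        return "effect" if float(value) > config.threshold else "neutral"
    return "effect" if str(value) in config.effect_labels else "neutral"


def normalize_for_correlation(scored: ScoredSAV, config: MethodConfig) -> float:
    """Raw score, or 1 - score for inverted methods (SIFT), so that higher
    always means more effect."""
    value = scored.score(config.name)
    try:
        value = float(value)
    except (TypeError, ValueError):
        raise MissingScoreError(
            f"{config.name} score {value!r} is not numeric; cannot correlate"
        ) from None
    return 1.0 - value if config.invert else value


# ---------------------------------------------------------------------------
# Accuracy from the extremes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AccuracyCurve:
    """Per-threshold accuracies accumulating from the score extremes toward
    0: effect accuracy TP/(TP+FP) among scores >= t, neutral accuracy
    TN/(TN+FN) among scores <= t.  NaN marks an empty denominator
    (undefined, never silently 0)."""

    thresholds: np.ndarray
    effect_accuracy: np.ndarray
    neutral_accuracy: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray


def threshold_accuracy_curve(
    labeled: Sequence[tuple[float, str]],
    thresholds: Optional[np.ndarray] = None,
) -> AccuracyCurve:
    """Accuracy-from-the-extremes curves on (score, label) pairs with
    labels in {"effect", "neutral"}."""
    if not labeled:
        raise EmptyInputError("empty labelled set")
    labels = {lab for _, lab in labeled}
    if labels - {"effect", "neutral"}:
        raise StatisticsError(f"unknown labels {labels - {'effect', 'neutral'}}")
    if len(labels) < 2:
        raise StatisticsError("degenerate labels: need both effect and neutral")
    grid = SCORE_GRID if thresholds is None else np.asarray(thresholds)
    eff = np.sort(np.array([s for s, lab in labeled if lab == "effect"]))
    neu = np.sort(np.array([s for s, lab in labeled if lab == "neutral"]))
    # scores >= t among each label class
    tp = eff.size - np.searchsorted(eff, grid, side="left")
    fp = neu.size - np.searchsorted(neu, grid, side="left")
    # scores <= t among each label class
    tn = np.searchsorted(neu, grid, side="right")
    fn = np.searchsorted(eff, grid, side="right")
    with np.errstate(invalid="ignore", divide="ignore"):
        effect_acc = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), np.nan)
        neutral_acc = np.where(tn + fn > 0, tn / np.maximum(tn + fn, 1), np.nan)
    return AccuracyCurve(grid, effect_acc, neutral_acc, tp, fp, tn, fn)


# ---------------------------------------------------------------------------
# Error-corrected effect/neutral fractions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErrorCorrectedFractions:
    """Effect/neutral fractions corrected for classifier error while
    conserving total mass:

    Neff* = Neff - FPR*Neff + FNR*Nneu
    Nneu* = Nneu - FNR*Nneu + FPR*Neff
    """

    neff_raw: float
    nneu_raw: float
    fpr: float
    fnr: float
    neff_star: float
    nneu_star: float


#: Default error rates: one minus the reported positive accuracy (78%) and
#: negative accuracy (77%) of the effect classifier at its default
#: threshold.
DEFAULT_FPR = 0.22
DEFAULT_FNR = 0.23


def error_correct_fractions(
    neff_raw: float,
    nneu_raw: float,
    fpr: float = DEFAULT_FPR,
    fnr: float = DEFAULT_FNR,
) -> ErrorCorrectedFractions:
    if abs(neff_raw + nneu_raw - 1.0) > 1e-9:
        raise StatisticsError(
            f"fractions must sum to 1: {neff_raw} + {nneu_raw}"
        )
    for rate, name in ((fpr, "fpr"), (fnr, "fnr")):
        if not 0.0 <= rate <= 1.0:
            raise StatisticsError(f"{name} {rate} outside [0, 1]")
    neff_star = neff_raw - fpr * neff_raw + fnr * nneu_raw
    nneu_star = nneu_raw - fnr * nneu_raw + fpr * neff_raw
    return ErrorCorrectedFractions(
        neff_raw=neff_raw, nneu_raw=nneu_raw, fpr=fpr, fnr=fnr,
        neff_star=neff_star, nneu_star=nneu_star,
    )


# ---------------------------------------------------------------------------
# Grouped summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistributionSummary:
    mean: float
    sem: float
    effect_auc: float
    n: int


def grouped_distribution_summary(
    scores_by_group: Mapping[str, Iterable[float]],
    n_boot: int = 100,
    seed: int = 0,
) -> tuple[dict[str, DistributionSummary], dict[tuple[str, str], KSResult]]:
    """Per-group mean / bootstrap SEM / effect AUC / n, plus pairwise KS
    results between all group pairs (in label-sorted order)."""
    arrays: dict[str, np.ndarray] = {}
    for label, scores in scores_by_group.items():
        arr = np.asarray(list(scores), dtype=float)
        if arr.size == 0:
            raise EmptyInputError(f"group {label!r} is empty")
        arrays[label] = arr
    summaries = {}
    for i, (label, arr) in enumerate(arrays.items()):
        summaries[label] = DistributionSummary(
            mean=float(arr.mean()),
            sem=bootstrap_sem(arr, n_boot, seed + i) if n_boot else 0.0,
            effect_auc=effect_auc(arr),
            n=int(arr.size),
        )
    pairwise: dict[tuple[str, str], KSResult] = {}
    labels = sorted(arrays)
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            pairwise[(la, lb)] = ks_two_sample(arrays[la], arrays[lb])
    return summaries, pairwise
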
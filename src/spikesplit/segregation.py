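"""Pearson chi-square testing of observed phenotype splits.

The hybridological track of the analysis: observed two-class counts for a
trait are tested for goodness of fit against the expected Mendelian ratio,
Q = sum_i (O_i - E_i)^2 / E_i with E_i = n * p_i, df = classes - 1, no
continuity correction (matching the convention under which the study's
printed statistics reproduce exactly).  A trait measured in four spike
projections is accepted as segregating under a model only when the model is
not rejected in any of the four projections.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .genetics import InheritanceModel, RatioLibrary, phenotype_proportions

__all__ = [
    "SegregationCounts",
    "ChiSquareResult",
    "ConsistencyVerdict",
    "GroupComparison",
    "pearson_chi2",
    "ratio_battery",
    "projection_consistency",
    "group_comparison",
]

#: Default significance level; the matching 1-df critical value is 3.84.
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class SegregationCounts:
    """Observed two-class phenotype counts, dominant (majority) class first."""

    trait: str
    observed: tuple[int, int]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.observed):
            raise ValueError(f"{self.trait}: counts must be non-negative, got {self.observed}")

    @property
    def n(self) -> int:
        return int(sum(self.observed))

    @classmethod
    def from_unordered(cls, trait: str, counts: Sequence[int]) -> "SegregationCounts":
        """Orient so the majority class takes the dominant (first) slot."""
        a, b = int(counts[0]), int(counts[1])
        return cls(trait=trait, observed=(a, b) if a >= b else (b, a))


@dataclass(frozen=True)
class ChiSquareResult:
    """One Pearson chi-square goodness-of-fit result."""

    trait: str
    model_name: str
    chi2: float
    df: int
    p_value: float
    alpha: float
    rejected: bool
    observed: tuple[int, ...]
    expected: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.chi2 < 0 or not (0.0 <= self.p_value <= 1.0):
            raise ValueError("invalid chi-square result")


def pearson_chi2(
    counts: SegregationCounts,
    model: InheritanceModel,
    alpha: float = DEFAULT_ALPHA,
    continuity_correction: bool = False,
) -> ChiSquareResult:
    """Pearson chi-square of observed counts against a model's expected ratio.

    Parameters
    ----------
    counts:
        Observed split, dominant class first.
    model:
        Inheritance model supplying the expected proportions.
    alpha:
        Significance level for the rejection flag (default 0.05).
    continuity_correction:
        Apply the Yates correction ``(|O-E| - 0.5)^2 / E``.  Off by default:
        the plain statistic is the one matching classical worked splits such
        as 125:54 vs 3:1 -> 2.549.
    """
    n = counts.n
    if n <= 0:
        raise ValueError(f"{counts.trait}: total count must be positive")
    props = phenotype_proportions(model)
    expected = tuple(n * p for p in props)
    if any(e <= 0 for e in expected):
        raise ValueError(f"{counts.trait}: expected count of zero under {model.name}")
    obs = np.asarray(counts.observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    dev = np.abs(obs - exp)
    if continuity_correction:
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float(np.sum(dev**2 / exp))
    df = len(obs) - 1
    p = float(stats.chi2.sf(chi2, df))
    critical = float(stats.chi2.ppf(1.0 - alpha, df))
    return ChiSquareResult(
        trait=counts.trait,
        model_name=model.name,
        chi2=chi2,
        df=df,
        p_value=p,
        alpha=alpha,
        rejected=chi2 > critical,
        observed=tuple(int(o) for o in counts.observed),
        expected=expected,
    )


def ratio_battery(
    counts: SegregationCounts,
    library: RatioLibrary,
    alpha: float = DEFAULT_ALPHA,
) -> list[ChiSquareResult]:
    """Test one observed split against every model in the library, in order."""
    if len(library) == 0:
        raise ValueError("ratio library is empty")
    return [pearson_chi2(counts, model, alpha=alpha) for model in library]


@dataclass(frozen=True)
class ConsistencyVerdict:
    """Four-projection agreement verdict for one trait and one model.

    ``consistent`` is true iff the model is rejected in none of the four
    projections — the reliability rule requiring a split to hold in every
    standardized camera view of the spike before it is attributed to the
    trait rather than to a single-view artefact.
    """

    trait: str
    model_name: str
    per_projection: tuple[ChiSquareResult, ...]
    consistent: bool


def projection_consistency(results: Sequence[ChiSquareResult]) -> ConsistencyVerdict:
    """Combine four per-projection results for one trait into a verdict."""
    if len(results) != 4:
        raise ValueError(f"expected exactly 4 per-projection results, got {len(results)}")
    traits = {r.trait for r in results}
    models = {r.model_name for r in results}
    if len(traits) != 1 or len(models) != 1:
        raise ValueError(
            f"results must share one trait and one model, got traits={sorted(traits)}, "
            f"models={sorted(models)}"
        )
    return ConsistencyVerdict(
        trait=results[0].trait,
        model_name=results[0].model_name,
        per_projection=tuple(results),
        consistent=not any(r.rejected for r in results),
    )


@dataclass(frozen=True)
class GroupComparison:
    """Equality-of-means summary over labelled groups of one trait.

    One-way ANOVA gives the overall equality-of-means p-value; all pairwise
    two-sided Mann-Whitney rank-sum tests give distribution-free pairwise
    comparisons (the reporting convention for comparing awnless, awned and
    tetraaristatum spikes by awn area).
    """

    groups: tuple[str, ...]
    n: Mapping[str, int]
    means: Mapping[str, float]
    variances: Mapping[str, float]
    anova_p: float
    pairwise_p: Mapping[tuple[str, str], float]


def group_comparison(values: Sequence[float], labels: Sequence[str]) -> GroupComparison:
    """Per-group mean/variance, one-way ANOVA p, pairwise rank-sum p-values."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have equal length")
    group_names = tuple(dict.fromkeys(labels.tolist()))  # first-appearance order
    if len(group_names) < 2:
        raise ValueError("need at least two groups")
    samples = {g: values[labels == g] for g in group_names}
    for g, v in samples.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    anova_p = float(stats.f_oneway(*(samples[g] for g in group_names)).pvalue)
    pairwise: dict[tuple[str, str], float] = {}
    for g1, g2 in itertools.combinations(group_names, 2):
        pairwise[(g1, g2)] = float(
            stats.mannwhitneyu(samples[g1], samples[g2], alternative="two-sided").pvalue
        )
    return GroupComparison(
        groups=group_names,
        n={g: int(len(samples[g])) for g in group_names},
        means={g: float(np.mean(samples[g])) for g in group_names},
        variances={g: float(np.var(samples[g], ddof=1)) for g in group_names},
        anova_p=anova_p,
        pairwise_p=pairwise,
    )
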
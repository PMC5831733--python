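"""Multi-species gene-set conservation: Venn accounting, resampling null,
and the two-proportion chi-squared test.

A candidate gene set (e.g. literature-curated skeletogenic genes) is more
conserved than chance if its all-species overlap exceeds that of equally
sized random sets drawn from the same gene universe. The null distribution
comes from repeated draws without replacement; the headline comparison is
a standard 2 x 2 chi-squared proportion test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import EchinodevError, PresenceMatrix

__all__ = [
    "OverlapSummary",
    "ResampleNull",
    "ProportionTestResult",
    "ConservationReport",
    "venn_overlap",
    "resample_overlap_null",
    "two_proportion_chisq",
    "conservation_test",
]


@dataclass
class OverlapSummary:
    """Disjoint Venn-region counts keyed by the species subset present."""

    region_counts: dict[tuple[str, ...], int]
    all_four: int
    n_genes: int


def venn_overlap(pm: PresenceMatrix, subset: set[str] | None = None) -> OverlapSummary:
    """Assign each gene to its exact species-presence region.

    Regions always contain the reference species (the matrix is indexed by
    reference gene ids); counts over regions partition the subset.
    """
    if subset is None:
        genes = pm.genes
    else:
        unknown = set(subset) - set(pm.genes)
        if unknown:
            raise EchinodevError(f"unknown genes in subset: {sorted(unknown)[:5]}")
        genes = pm.genes.intersection(subset)
    sub = pm.present.loc[genes]
    species = np.array(pm.species)
    counts: dict[tuple[str, ...], int] = {}
    patterns, n = np.unique(sub.to_numpy(dtype=bool), axis=0, return_counts=True) if len(sub) else ([], [])
    for pat, c in zip(patterns, n):
        key = tuple(species[pat])
        counts[key] = counts.get(key, 0) + int(c)
    all_species = tuple(species)
    return OverlapSummary(
        region_counts=counts, all_four=counts.get(all_species, 0), n_genes=len(sub)
    )


@dataclass
class ResampleNull:
    """All-species overlap counts of random equally sized gene sets."""

    draws: np.ndarray
    set_size: int
    n_draws: int
    seed: int


def resample_overlap_null(
    pm: PresenceMatrix, set_size: int = 901, n_draws: int = 1000, seed: int = 0
) -> ResampleNull:
    """Overlap null: ``n_draws`` random sets of ``set_size`` genes.

    Each draw samples without replacement from the full universe and
    records how many of its genes are present in every species. The RNG
    stream is salted with a module constant so that passing one global seed
    to both a data generator and this null keeps the two streams distinct.
    """
    n_univ = len(pm.genes)
    if set_size > n_univ:
        raise EchinodevError(f"set_size {set_size} exceeds universe {n_univ}")
    rng = np.random.default_rng([seed, 715517])
    all_mask = pm.all_species_mask().to_numpy()
    draws = np.empty(n_draws, dtype=np.int64)
    for i in range(n_draws):
        idx = rng.choice(n_univ, size=set_size, replace=False)
        draws[i] = int(all_mask[idx].sum())
    return ResampleNull(draws=draws, set_size=set_size, n_draws=n_draws, seed=seed)


@dataclass
class ProportionTestResult:
    """1-df chi-squared comparison of two proportions x1/n1 vs x2/n2."""

    chi2: float
    p_value: float
    df: int = 1
    continuity_corrected: bool = False


def two_proportion_chisq(
    x1: int, n1: int, x2: int, n2: int, continuity: bool = False
) -> ProportionTestResult:
    """Standard 2 x 2 chi-squared test on (x1, n1-x1; x2, n2-x2).

    ``continuity`` applies the Yates correction. The p-value is the upper
    tail of the 1-df chi-squared distribution.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0:
            raise EchinodevError("group sizes must be positive")
        if not 0 <= x <= n:
            raise EchinodevError(f"successes {x} outside [0, {n}]")
    a, b = float(x1), float(n1 - x1)
    c, d = float(x2), float(n2 - x2)
    N = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:  # a margin is empty: no association testable
        return ProportionTestResult(chi2=0.0, p_value=1.0, continuity_corrected=continuity)
    diff = abs(a * d - b * c)
    if continuity:
        diff = max(diff - N / 2.0, 0.0)
    chi2 = N * diff**2 / denom
    p = float(stats.chi2.sf(chi2, df=1))
    return ProportionTestResult(chi2=float(chi2), p_value=p, continuity_corrected=continuity)


@dataclass
class ConservationReport:
    """Observed vs resampled conservation of a candidate gene set.

    Two denominator conventions are reported side by side: the all-species
    count over genes present in at least one non-reference species, and
    over the whole set.
    """

    observed_all: int
    set_size: int
    observed_at_least_one: int
    null: ResampleNull
    null_mean: float
    null_sd: float
    empirical_p: float
    chisq_at_least_one: ProportionTestResult
    chisq_total: ProportionTestResult
    extras: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "set_size": self.set_size,
            "observed_all_species": self.observed_all,
            "observed_at_least_one_nonref": self.observed_at_least_one,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "empirical_p": self.empirical_p,
            "chi2_at_least_one": self.chisq_at_least_one.chi2,
            "p_at_least_one": self.chisq_at_least_one.p_value,
            "chi2_total": self.chisq_total.chi2,
            "p_total": self.chisq_total.p_value,
        }


def conservation_test(
    pm: PresenceMatrix,
    candidate_set: set[str],
    n_draws: int = 1000,
    seed: int = 0,
    continuity: bool = False,
) -> ConservationReport:
    """Is a candidate set more conserved across species than random sets?

    Resamples equally sized random sets for the null, reports a one-sided
    empirical p with the (r+1)/(n+1) convention, and chi-squared tests of
    the candidate all-species proportion against the mean random one under
    both denominator conventions.
    """
    unknown = set(candidate_set) - set(pm.genes)
    if unknown:
        raise EchinodevError(f"candidate genes outside universe: {sorted(unknown)[:5]}")
    size = len(candidate_set)
    if size == 0:
        raise EchinodevError("empty candidate set")
    sub = pm.present.loc[sorted(candidate_set)]
    observed = int(sub.all(axis=1).sum())
    nonref = pm.species[1:]
    at_least_one = int(sub[nonref].any(axis=1).sum())

    null = resample_overlap_null(pm, set_size=size, n_draws=n_draws, seed=seed)
    r = int((null.draws >= observed).sum())
    empirical_p = (r + 1) / (n_draws + 1)
    null_mean = float(null.draws.mean())
    null_sd = float(null.draws.std(ddof=1))

    # mean random set under the same two denominator conventions
    all_mask = pm.all_species_mask()
    any_nonref = pm.present[nonref].any(axis=1)
    univ_n = len(pm.genes)
    exp_all = round(size * float(all_mask.sum()) / univ_n)
    exp_any = round(size * float(any_nonref.sum()) / univ_n)
    chisq_any = two_proportion_chisq(
        observed, max(at_least_one, 1), exp_all, max(exp_any, 1), continuity=continuity
    )
    chisq_total = two_proportion_chisq(observed, size, exp_all, size, continuity=continuity)
    return ConservationReport(
        observed_all=observed,
        set_size=size,
        observed_at_least_one=at_least_one,
        null=null,
        null_mean=null_mean,
        null_sd=null_sd,
        empirical_p=empirical_p,
        chisq_at_least_one=chisq_any,
        chisq_total=chisq_total,
    )
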
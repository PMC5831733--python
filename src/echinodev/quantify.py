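"""Filtering, RPKM scaling and internal-standard normalization of EC tables.

The normalization strategy: each EC's trajectory is first divided by its
own peak; ECs whose peak-normalized trajectory has an across-time-point
standard deviation below 0.01 are taken as the internal standard (their
expression is effectively constant through development); the per-time-point
mean RPKM of that standard set is the normalization factor, and every value
is divided by it and multiplied by 1,000,000, yielding transcripts-per-
million-like units in which the standard set averages 1e6 at every stage.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix, EchinodevError, TimeCourseMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationTables",
    "NormalizationResult",
    "filter_low_count",
    "compute_rpkm",
    "peak_normalize",
    "select_internal_standard",
    "normalize_by_standard",
    "propagate_annotation",
]

#: Tiers of sequence-similarity annotation: reciprocal best hits are
#: orthologs, one-directional hits homologs.
TIERS = ("ortholog", "homolog", "none")


def filter_low_count(m: CountMatrix, min_reads: int = 10) -> CountMatrix:
    """Drop ECs with fewer than ``min_reads`` total reads (included samples).

    Totals below ten reads correspond to technical background level; the
    boundary is strict ("less than ten"): an EC with exactly ``min_reads``
    is retained.
    """
    if min_reads < 0:
        raise EchinodevError("min_reads must be non-negative")
    if len(m.ec_ids) == 0:
        logger.warning("filter_low_count: empty count matrix")
        return m
    totals = m.included_totals()
    keep = totals >= min_reads
    removed = int((~keep).sum())
    logger.info("filter_low_count: removed %d of %d ECs (< %d reads)", removed, len(keep), min_reads)
    return CountMatrix(counts=m.counts.loc[keep], sample_meta=m.sample_meta)


def compute_rpkm(m: CountMatrix, lengths: pd.Series | dict) -> TimeCourseMatrix:
    """Reads per kilobase per million mapped reads, per time point.

    Counts of included samples sharing an hpf are summed; the library size
    is the included total at that time point. value = count * 1e9 /
    (length_bp * library_size).
    """
    lengths = pd.Series(lengths)
    missing = m.ec_ids.difference(lengths.index)
    if len(missing):
        raise EchinodevError(f"missing lengths for ECs: {list(missing[:5])}")
    lengths = lengths.loc[m.ec_ids].astype(float)
    if (lengths <= 0).any():
        raise EchinodevError("gene lengths must be positive")

    inc = m.included_samples()
    if not inc:
        raise EchinodevError("no included samples")
    meta = m.sample_meta.loc[inc]
    timepoints = sorted(meta["hpf"].unique())
    values = {}
    for t in timepoints:
        samples = meta.index[meta["hpf"] == t]
        counts_t = m.counts[samples].sum(axis=1).astype(float)
        lib = counts_t.sum()
        if lib == 0:
            raise EchinodevError(f"zero mapped reads at {t} hpf")
        values[float(t)] = counts_t * 1e9 / (lengths * lib)
    return TimeCourseMatrix(values=pd.DataFrame(values), unit="rpkm")


def peak_normalize(t: TimeCourseMatrix) -> TimeCourseMatrix:
    """Divide each EC's trajectory by its own peak of expression."""
    peaks = t.values.max(axis=1)
    zero = peaks[peaks <= 0]
    if len(zero):
        raise EchinodevError(f"all-zero trajectories cannot be peak-normalized: {list(zero.index[:5])}")
    return TimeCourseMatrix(values=t.values.div(peaks, axis=0), unit="peak_normalized")


def select_internal_standard(t: TimeCourseMatrix, sd_threshold: float = 0.01) -> set[str]:
    """ECs whose peak-normalized trajectory is near-constant (SD < threshold).

    Uses the sample standard deviation (n-1 denominator) across time
    points. These near-flat ECs serve as the internal standard against
    which the whole matrix is scaled.
    """
    if t.unit != "peak_normalized":
        raise EchinodevError("internal-standard selection expects a peak-normalized matrix")
    sd = t.values.std(axis=1, ddof=1)
    chosen = set(sd.index[sd < sd_threshold])
    logger.info("select_internal_standard: %d of %d ECs below SD %.3g", len(chosen), len(sd), sd_threshold)
    if not chosen:
        raise EchinodevError(
            f"no EC has trajectory SD below {sd_threshold}; review the threshold — "
            "normalization is impossible without an internal standard"
        )
    return chosen


@dataclass
class NormalizationResult:
    """Internal-standard scaled matrix plus the factors used."""

    matrix: TimeCourseMatrix  # unit tpm_like
    standard_set: set[str]
    factors: pd.Series  # per-timepoint mean standard RPKM


def normalize_by_standard(
    t: TimeCourseMatrix, standard: set[str], scale: float = 1e6
) -> NormalizationResult:
    """Scale so the internal-standard mean equals ``scale`` per time point.

    The factor at each time point is the mean RPKM of the standard ECs
    there; every value is divided by that factor and multiplied by
    ``scale`` (1,000,000 by default).
    """
    if not standard:
        raise EchinodevError("empty internal-standard set")
    extra = set(standard) - set(t.ec_ids)
    if extra:
        raise EchinodevError(f"standard ECs absent from matrix: {sorted(extra)[:5]}")
    std_rows = t.values.loc[sorted(standard)]
    factors = std_rows.mean(axis=0)
    if (factors <= 0).any():
        bad = [c for c, f in factors.items() if f <= 0]
        raise EchinodevError(f"zero normalization factor at time points {bad}")
    normalized = t.values.div(factors, axis=1) * scale
    return NormalizationResult(
        matrix=TimeCourseMatrix(values=normalized, unit="tpm_like"),
        standard_set=set(standard),
        factors=factors,
    )


@dataclass
class AnnotationTables:
    """Contig-level annotation and EC membership.

    ``ec_members`` maps each EC to its constituent contig ids;
    ``contig_annotation`` maps a contig to ``(annotation_id, tier)`` with
    tier in :data:`TIERS`.
    """

    ec_members: dict[str, list[str]]
    contig_annotation: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for ec, contigs in self.ec_members.items():
            dup = seen.intersection(contigs)
            if dup:
                raise EchinodevError(f"contigs in more than one EC: {sorted(dup)[:5]}")
            seen.update(contigs)
        for contig, (_, tier) in self.contig_annotation.items():
            if tier not in TIERS:
                raise EchinodevError(f"unknown tier {tier!r} for contig {contig!r}")


def propagate_annotation(a: AnnotationTables) -> pd.DataFrame:
    """EC-level annotation: most frequent constituent-contig annotation.

    Ortholog-tier annotations take priority over homolog-tier ones: if any
    constituent contig has an ortholog annotation, the most frequent
    ortholog annotation wins; otherwise the most frequent homolog
    annotation; otherwise none. Frequency ties break to the
    lexicographically smallest annotation id, flagged ambiguous.

    Returns a DataFrame indexed by EC with columns annotation, tier,
    ambiguous.
    """
    rows = {}
    for ec, contigs in a.ec_members.items():
        by_tier: dict[str, Counter] = {"ortholog": Counter(), "homolog": Counter()}
        for contig in contigs:
            ann = a.contig_annotation.get(contig)
            if ann is None:
                logger.info("propagate_annotation: contig %s has no annotation entry", contig)
                continue
            ann_id, tier = ann
            if tier in by_tier:
                by_tier[tier][ann_id] += 1
        chosen, tier_out, ambiguous = None, "none", False
        for tier in ("ortholog", "homolog"):
            counter = by_tier[tier]
            if counter:
                top = max(counter.values())
                tied = sorted(aid for aid, c in counter.items() if c == top)
                chosen, tier_out, ambiguous = tied[0], tier, len(tied) > 1
                if ambiguous:
                    logger.info("propagate_annotation: tie in EC %s among %s", ec, tied)
                break
        rows[ec] = {"annotation": chosen, "tier": tier_out, "ambiguous": ambiguous}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "ec"
    return out
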
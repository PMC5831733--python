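"""Transcript-family partitioning of protein sequences by percent identity.

De novo assemblers emit multiple contigs per gene (SNPs, indels, fragments);
collapsing contigs whose proteins are at least 97% identical into transcript
families recovers approximate gene-level units. Identity is computed from a
global alignment under fixed scoring (match +1, mismatch -1, gap -2, end
gaps penalized) with the full alignment length — gap columns included — as
the denominator, the strictest common convention. Families are
single-linkage connected components of the >= threshold identity graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from Bio import Align
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .containers import EchinodevError, ProteinSet

__all__ = ["FamilyPartition", "pairwise_identity", "partition_families", "mismatch_rate"]

#: Co-optimal global alignments may disagree on identity; identity is the
#: maximum over at most this many of them (deterministic).
_MAX_COOPTIMAL = 64


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    # no terminal-gap discount: end gaps cost the same as internal ones
    return aligner


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical columns in an optimal global alignment.

    The denominator is the alignment length including gap columns. Among
    co-optimal alignments the highest identity is reported.
    """
    if not a or not b:
        raise EchinodevError("empty sequence")
    aligner = _make_aligner()
    alignments = aligner.align(a, b)
    best = 0.0
    for aln, _ in zip(alignments, range(_MAX_COOPTIMAL)):
        counts = aln.counts()
        ident = counts.identities / aln.length
        best = max(best, ident)
    return best


@dataclass
class FamilyPartition:
    """Contig -> family assignment; family id = smallest member id."""

    assignment: pd.Series  # contig -> family id
    threshold: float

    def family_sizes(self) -> pd.Series:
        return self.assignment.value_counts().sort_index()

    def mean_family_size(self) -> float:
        return float(len(self.assignment) / self.assignment.nunique())

    def as_frame(self) -> pd.DataFrame:
        sizes = self.assignment.map(self.family_sizes())
        return pd.DataFrame(
            {"family": self.assignment, "family_size": sizes},
            index=self.assignment.index,
        )


def partition_families(p: ProteinSet, threshold: float = 0.97) -> FamilyPartition:
    """Single-linkage partition at >= ``threshold`` pairwise identity.

    A length-band prefilter keeps the all-vs-all pass tractable: under the
    gap-inclusive denominator identity is bounded by the shorter/longer
    length ratio, so pairs with ratio below the threshold are skipped
    without alignment. Family ids are deterministic (smallest member id).
    """
    if not 0.0 < threshold <= 1.0:
        raise EchinodevError("threshold must lie in (0, 1]")
    ids = sorted(p.ids())
    n = len(ids)
    index = {sid: i for i, sid in enumerate(ids)}
    rows, cols = [], []
    for sa, sb in combinations(ids, 2):
        a, b = p[sa], p[sb]
        ratio = min(len(a), len(b)) / max(len(a), len(b))
        if ratio < threshold:
            continue
        if pairwise_identity(a, b) >= threshold:
            rows.append(index[sa])
            cols.append(index[sb])
    graph = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    family_name = {}
    for comp in range(n_comp):
        members = [ids[i] for i in np.flatnonzero(labels == comp)]
        family_name[comp] = min(members)
    assignment = pd.Series(
        {sid: family_name[labels[index[sid]]] for sid in ids}, name="family"
    )
    assignment.index.name = "contig"
    return FamilyPartition(assignment=assignment, threshold=threshold)


def mismatch_rate(mismatches: float, aligned_length: float) -> float:
    """Percent mismatches over aligned length, to one decimal.

    E.g. ~7 mismatches on an average 588-bp coding alignment is a 1.2%
    polymorphism rate.
    """
    if aligned_length <= 0:
        raise EchinodevError("aligned length must be positive")
    if not 0 <= mismatches <= aligned_length:
        raise EchinodevError("mismatches outside [0, aligned_length]")
    return round(100.0 * mismatches / aligned_length, 1)
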
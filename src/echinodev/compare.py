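"""Cross-species comparison of expression-mode usage over an ortholog map.

Two species' gene -> mode assignments are joined through a table of
sequence-similarity pairs (reciprocal hits = orthologs, one-directional =
homologs) and tallied into a 5 x 5 mode-by-mode contingency table. The
diagonal counts genes deployed in the same temporal mode in both species;
off-diagonal mass measures divergence of developmental regulatory states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .containers import MODES, EchinodevError, ModeMap

logger = logging.getLogger(__name__)

__all__ = ["OrthologMap", "ModeComparison", "compare_mode_usage"]

RELATIONS = ("ortholog", "homolog")


@dataclass
class OrthologMap:
    """Pairs (gene_A, gene_B, relation) linking two species' gene ids."""

    pairs: pd.DataFrame  # columns gene_a, gene_b, relation

    def __post_init__(self) -> None:
        need = {"gene_a", "gene_b", "relation"}
        missing = need - set(self.pairs.columns)
        if missing:
            raise EchinodevError(f"ortholog map lacks columns: {sorted(missing)}")
        if self.pairs.duplicated(["gene_a", "gene_b"]).any():
            raise EchinodevError("duplicate (gene_a, gene_b) pairs in ortholog map")
        bad = set(self.pairs["relation"].unique()) - set(RELATIONS)
        if bad:
            raise EchinodevError(f"unknown relations: {sorted(bad)}")


@dataclass
class ModeComparison:
    """Mode x mode contingency plus per-mode shared/unique tallies."""

    contingency: pd.DataFrame  # MODES x MODES counts (A rows, B columns)
    per_mode_shared: pd.Series
    per_mode_only_a: pd.Series
    per_mode_only_b: pd.Series
    unmapped_a: int
    unmapped_b: int
    ambiguous_pairs: int


def _resolve_partners(map_: OrthologMap) -> pd.DataFrame:
    """One partner per species-A gene: unique ortholog pair if any, else the
    lexicographically smallest partner (orthologs before homologs)."""
    chosen = []
    ambiguous = 0
    for gene_a, grp in map_.pairs.groupby("gene_a", sort=True):
        if len(grp) == 1:
            chosen.append(grp.iloc[0])
            continue
        orth = grp[grp["relation"] == "ortholog"]
        pool = orth if len(orth) else grp
        if len(pool) > 1:
            ambiguous += 1
            logger.info("compare: gene %s has %d candidate partners; taking smallest id", gene_a, len(pool))
        chosen.append(pool.sort_values("gene_b").iloc[0])
    out = pd.DataFrame(chosen).reset_index(drop=True)
    out.attrs["ambiguous"] = ambiguous
    return out


def compare_mode_usage(
    modes_a: ModeMap,
    modes_b: ModeMap,
    map_: OrthologMap,
    subset: set[str] | None = None,
) -> ModeComparison:
    """Tally mode usage of mapped gene pairs between two species.

    ``subset`` filters on species-A gene ids (e.g. the transcription-factor
    set); defaults to every gene in ``modes_a``. Subset genes without a
    mapped partner carrying a mode in species B count as unmapped.
    """
    genes_a = set(modes_a.labels.index)
    if subset is None:
        subset_ids = genes_a
    else:
        subset_ids = set(subset) & genes_a

    resolved = _resolve_partners(map_)
    partner = dict(zip(resolved["gene_a"], resolved["gene_b"]))

    contingency = pd.DataFrame(0, index=list(MODES), columns=list(MODES), dtype=int)
    unmapped_a = 0
    hit_b_genes = set()
    for g in sorted(subset_ids):
        mode_a = modes_a.labels[g]
        b = partner.get(g)
        if b is None or b not in modes_b.labels.index:
            unmapped_a += 1
            continue
        mode_b = modes_b.labels[b]
        contingency.loc[mode_a, mode_b] += 1
        hit_b_genes.add(b)
    unmapped_b = len(set(modes_b.labels.index) - hit_b_genes)

    shared = pd.Series({m: int(contingency.loc[m, m]) for m in MODES})
    only_a = contingency.sum(axis=1) - shared
    only_b = contingency.sum(axis=0) - shared
    return ModeComparison(
        contingency=contingency,
        per_mode_shared=shared,
        per_mode_only_a=only_a,
        per_mode_only_b=only_b,
        unmapped_a=unmapped_a,
        unmapped_b=unmapped_b,
        ambiguous_pairs=int(resolved.attrs.get("ambiguous", 0)),
    )
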
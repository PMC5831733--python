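"""Seeded generators for every input the pipeline consumes.

Three generators with known ground truth:

* :func:`simulate_timecourse` — 4-time-point expression profiles drawn from
  mode-specific trajectory templates with multiplicative log-normal noise,
  a planted subset of near-constant internal-standard genes, and optional
  low-count background ECs and excluded (perturbed) samples.
* :func:`simulate_presence` — gene x species presence/absence with a
  conservation-enriched labelled subset.
* :func:`simulate_protein_families` — protein families generated from
  mutually dissimilar ancestors by i.i.d. substitution.

All generators are deterministic given (config, seed in config).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    BI_MODAL,
    EARLY,
    INTERMEDIATE,
    LATE,
    UNCLASSIFIED,
    CountMatrix,
    EchinodevError,
    PresenceMatrix,
    ProteinSet,
    TimeCourseMatrix,
)
from .cluster import classify_centroid_mode

#: Study time points in hours post-fertilization.
DEFAULT_TIMEPOINTS = (9.0, 18.0, 27.0, 39.0)

#: One representative trajectory template per mode: a decreasing profile
#: (peak at the first stage), a single interior peak, an increasing profile
#: (peak at the last stage), and a twin-peaked profile.
DEFAULT_TEMPLATES: dict[str, tuple[float, ...]] = {
    EARLY: (1.0, 0.6, 0.3, 0.2),
    INTERMEDIATE: (0.2, 1.0, 0.5, 0.3),
    LATE: (0.2, 0.3, 0.6, 1.0),
    BI_MODAL: (1.0, 0.3, 0.8, 0.2),
}


def _default_proportions() -> dict[str, float]:
    return {EARLY: 0.25, INTERMEDIATE: 0.25, LATE: 0.25, BI_MODAL: 0.25}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic 4-point developmental time course.

    ``noise_sd`` is the SD of multiplicative noise on the natural-log scale;
    ``standard_noise_sd`` the same for the planted internal-standard genes.
    ``n_lowcount`` ECs receive totals below the 10-read filter threshold.
    ``depth_per_sample`` is the expected total mapped reads per sample.
    """

    n_genes: int = 2000
    mode_proportions: dict[str, float] = field(default_factory=_default_proportions)
    trajectory_templates: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_TEMPLATES)
    )
    noise_sd: float = 0.1
    n_standard: int = 50
    standard_noise_sd: float = 0.002
    n_lowcount: int = 0
    depth_per_sample: float = 5e6
    gene_length_range: tuple[int, int] = (500, 3000)
    timepoints_hpf: tuple[float, ...] = DEFAULT_TIMEPOINTS
    n_excluded_samples: int = 0
    flat_eps: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.mode_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise EchinodevError(f"mode proportions sum to {total}, expected 1")
        if self.noise_sd < 0 or self.standard_noise_sd < 0:
            raise EchinodevError("noise SDs must be non-negative")
        if self.n_standard + self.n_lowcount > self.n_genes:
            raise EchinodevError("planted standard + lowcount genes exceed n_genes")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise EchinodevError("invalid gene length range")
        T = len(self.timepoints_hpf)
        for mode, tpl in self.trajectory_templates.items():
            if len(tpl) != T:
                raise EchinodevError(f"template for {mode} has length {len(tpl)}, expected {T}")
            if any(v < 0 for v in tpl):
                raise EchinodevError(f"negative template value for {mode}")
            got = classify_centroid_mode(np.asarray(tpl, dtype=float), flat_eps=self.flat_eps)
            if got != mode:
                raise EchinodevError(
                    f"template for {mode} classifies as {got}; templates must "
                    "carry the sign pattern of their own mode"
                )
        for mode in self.mode_proportions:
            if mode not in self.trajectory_templates:
                raise EchinodevError(f"no template for mode {mode}")


def simulate_timecourse(
    config: SimulationConfig,
) -> tuple[CountMatrix, TimeCourseMatrix, pd.Series, set[str]]:
    """Generate a seeded count matrix plus true expression trajectories.

    Returns ``(counts, expression, truth, standard_truth)`` where
    ``expression`` holds the continuous per-time-point expression levels
    that the Poisson read counts are drawn around (unit tagged ``rpkm``),
    ``truth`` maps every gene to its planted mode (standard and low-count
    genes are labelled UNCLASSIFIED: their profiles are flat or below the
    detection floor), and ``standard_truth`` is the planted internal-standard
    id set.
    """
    rng = np.random.default_rng(config.seed)
    T = len(config.timepoints_hpf)
    n = config.n_genes
    n_std, n_low = config.n_standard, config.n_lowcount
    n_regular = n - n_std - n_low

    gene_ids = [f"EC{i:05d}" for i in range(n)]
    # role layout: regular genes first, then standards, then low-count ECs
    regular_ids = gene_ids[:n_regular]
    standard_ids = gene_ids[n_regular : n_regular + n_std]
    lowcount_ids = gene_ids[n_regular + n_std :]

    modes = list(config.mode_proportions)
    probs = np.array([config.mode_proportions[m] for m in modes])
    mode_of_regular = rng.choice(len(modes), size=n_regular, p=probs)

    # per-gene amplitude log-uniform over two orders of magnitude, so
    # normalization is exercised across the dynamic range
    amplitude = 10.0 ** rng.uniform(0.0, 2.0, size=n)

    templates = np.array(
        [np.asarray(config.trajectory_templates[m], dtype=float) for m in modes]
    )
    expr = np.empty((n, T), dtype=float)
    expr[:n_regular] = templates[mode_of_regular] * amplitude[:n_regular, None]
    expr[:n_regular] *= np.exp(rng.normal(0.0, config.noise_sd, size=(n_regular, T)))
    # internal standards: constant level, tiny multiplicative wobble
    expr[n_regular : n_regular + n_std] = amplitude[n_regular : n_regular + n_std, None]
    expr[n_regular : n_regular + n_std] *= np.exp(
        rng.normal(0.0, config.standard_noise_sd, size=(n_std, T))
    )
    # low-count ECs: expression at the technical-background floor (their
    # counts are overridden below to guarantee totals under 10 reads)
    expr[n_regular + n_std :] = 1e-3

    lengths = rng.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1, size=n
    )

    # samples: one included per time point, plus optional excluded extras at
    # the third time point (mirrors perturbed mesenchyme-blastula replicates)
    sample_ids = [f"S{int(t)}hpf" for t in config.timepoints_hpf]
    hpfs = list(config.timepoints_hpf)
    included = [True] * T
    excl_t = config.timepoints_hpf[min(2, T - 1)]
    for j in range(config.n_excluded_samples):
        sample_ids.append(f"S{int(excl_t)}hpf_perturbed{j + 1}")
        hpfs.append(excl_t)
        included.append(False)

    counts = np.zeros((n, len(sample_ids)), dtype=np.int64)
    weights = expr * lengths[:, None]  # expected reads ∝ expression × length
    for s, sid in enumerate(sample_ids):
        t_idx = config.timepoints_hpf.index(hpfs[s])
        lam = weights[:, t_idx]
        lam = lam / lam.sum() * config.depth_per_sample
        counts[:, s] = rng.poisson(lam)
    # overwrite planted low-count ECs: totals strictly below 10 reads
    for i in range(n_regular + n_std, n):
        total = int(rng.integers(0, 10))
        counts[i, :] = rng.multinomial(total, np.full(len(sample_ids), 1.0 / len(sample_ids)))

    meta = pd.DataFrame({"hpf": hpfs, "included": included}, index=pd.Index(sample_ids, name="sample"))
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(gene_ids, name="ec"), columns=sample_ids),
        sample_meta=meta,
    )
    tc = TimeCourseMatrix(
        values=pd.DataFrame(
            expr, index=pd.Index(gene_ids, name="ec"), columns=list(config.timepoints_hpf)
        ),
        unit="rpkm",
    )
    truth = pd.Series(UNCLASSIFIED, index=pd.Index(gene_ids, name="ec"), dtype=object)
    truth.iloc[:n_regular] = [modes[i] for i in mode_of_regular]
    return cm, tc, truth, set(standard_ids)


@dataclass
class PresenceSimConfig:
    """Gene x species presence/absence with an enriched labelled subset.

    ``retention_prob`` gives, per non-reference species, the probability a
    background gene is detected there; ``enriched_retention_prob`` the same
    for the planted conservation-enriched subset. The first species name is
    the reference and is always present.
    """

    universe_size: int = 10000
    species_names: tuple[str, ...] = ("Spu", "Afi", "Pmi", "Ame")
    retention_prob: dict[str, float] = field(default_factory=dict)
    enriched_set_size: int = 0
    enriched_retention_prob: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.universe_size <= 0:
            raise EchinodevError("universe_size must be positive")
        if self.enriched_set_size > self.universe_size:
            raise EchinodevError("enriched_set_size exceeds universe_size")
        for probs in (self.retention_prob, self.enriched_retention_prob):
            for sp, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise EchinodevError(f"probability for {sp} outside [0, 1]: {p}")


def simulate_presence(config: PresenceSimConfig) -> tuple[PresenceMatrix, set[str]]:
    """Draw a presence matrix; returns it with the planted enriched id set."""
    rng = np.random.default_rng(config.seed)
    ref, *others = config.species_names
    genes = [f"G{i:05d}" for i in range(config.universe_size)]
    enriched_idx = rng.choice(config.universe_size, size=config.enriched_set_size, replace=False)
    enriched_mask = np.zeros(config.universe_size, dtype=bool)
    enriched_mask[enriched_idx] = True

    cols = {ref: np.ones(config.universe_size, dtype=bool)}
    for sp in others:
        p_bg = config.retention_prob.get(sp, 1.0)
        p_en = config.enriched_retention_prob.get(sp, p_bg)
        p = np.where(enriched_mask, p_en, p_bg)
        cols[sp] = rng.random(config.universe_size) < p
    pm = PresenceMatrix(
        present=pd.DataFrame(cols, index=pd.Index(genes, name="gene"), columns=list(config.species_names))
    )
    enriched = {genes[i] for i in enriched_idx}
    return pm, enriched


@dataclass
class FamilySimConfig:
    """Protein families from dissimilar ancestors with i.i.d. substitutions.

    Family members derive from a common random ancestor; each position is
    substituted independently with probability ``within_family_sub_rate``.
    Ancestors are rejection-sampled until every cross-family identity is
    below ``between_family_identity_cap``, guaranteeing a separable truth
    partition at ``partition_threshold``.
    """

    n_families: int = 10
    members_per_family: int = 3
    seq_length: int = 200
    within_family_sub_rate: float = 0.01
    between_family_identity_cap: float = 0.8
    partition_threshold: float = 0.97
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_families, self.members_per_family, self.seq_length) <= 0:
            raise EchinodevError("counts and lengths must be positive")
        r = self.within_family_sub_rate
        if not 0.0 <= r <= 1.0:
            raise EchinodevError("substitution rate outside [0, 1]")
        # expected identity between two members: both positions unchanged, or
        # both substituted to the same residue (19 alternatives each)
        expected_identity = (1 - r) ** 2 + r * r / 19.0
        if expected_identity <= self.partition_threshold:
            raise EchinodevError(
                f"within-family expected identity {expected_identity:.4f} does not "
                f"exceed partition threshold {self.partition_threshold}"
            )
        if not self.between_family_identity_cap < self.partition_threshold:
            raise EchinodevError("between-family identity cap must lie below the threshold")


_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def simulate_protein_families(config: FamilySimConfig) -> tuple[ProteinSet, pd.Series]:
    """Generate families of similar proteins; returns sequences + truth.

    Truth maps every contig id to its family index (as ``famNN`` strings).
    """
    from .families import pairwise_identity  # local import to avoid cycle

    rng = np.random.default_rng(config.seed)
    ancestors: list[str] = []
    attempts = 0
    while len(ancestors) < config.n_families:
        attempts += 1
        if attempts > 1000 * config.n_families:
            raise EchinodevError("could not sample mutually dissimilar ancestors; lower the cap")
        cand = "".join(rng.choice(_AA, size=config.seq_length))
        if all(
            pairwise_identity(cand, anc) < config.between_family_identity_cap
            for anc in ancestors
        ):
            ancestors.append(cand)

    sequences: dict[str, str] = {}
    truth: dict[str, str] = {}
    L = config.seq_length
    # each member stays within half the identity budget of its ancestor, so
    # every within-family pair is >= the partition threshold by the triangle
    # bound: the planted truth is separable by construction on both sides
    # (positional identity lower-bounds alignment identity)
    max_subs = int(np.floor((1.0 - config.partition_threshold) * L / 2.0))
    for f, anc in enumerate(ancestors):
        anc_arr = np.array(list(anc))
        for m in range(config.members_per_family):
            while True:
                hit = rng.random(L) < config.within_family_sub_rate
                if hit.sum() <= max_subs:
                    break
            seq = anc_arr.copy()
            for pos in np.flatnonzero(hit):
                choices = _AA[_AA != seq[pos]]
                seq[pos] = rng.choice(choices)
            cid = f"contig_f{f:02d}_m{m:02d}"
            sequences[cid] = "".join(seq)
            truth[cid] = f"fam{f:02d}"
    return ProteinSet(sequences), pd.Series(truth, name="family")
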
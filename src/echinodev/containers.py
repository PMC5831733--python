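"""Core in-memory containers shared across the pipeline.

An *expression cluster* (EC) is a group of assembled contigs that share
mapped reads; it is the quantification proxy for a gene throughout this
package. Counts are held per (EC, sample); time-course values per
(EC, time point in hours post-fertilization).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Expression modes of a 4-point developmental trajectory.
EARLY = "EARLY"
INTERMEDIATE = "INTERMEDIATE"
LATE = "LATE"
BI_MODAL = "BI_MODAL"
UNCLASSIFIED = "UNCLASSIFIED"

#: Canonical ordering used for contingency tables and reports.
MODES: tuple[str, ...] = (EARLY, INTERMEDIATE, LATE, BI_MODAL, UNCLASSIFIED)


class EchinodevError(ValueError):
    """Base class for input/configuration errors raised by this package."""


@dataclass
class CountMatrix:
    """Raw EC x sample read counts plus per-sample metadata.

    Parameters
    ----------
    counts
        Non-negative integer DataFrame, index = EC ids, columns = sample ids.
    sample_meta
        DataFrame indexed by sample id with columns ``hpf`` (number) and
        ``included`` (bool). Excluded samples (e.g. chemically perturbed
        replicates) never contribute to totals or library sizes downstream.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise EchinodevError("duplicate EC ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise EchinodevError("duplicate sample ids in count matrix")
        if (self.counts.to_numpy() < 0).any():
            raise EchinodevError("negative counts")
        missing = set(self.counts.columns) - set(self.sample_meta.index)
        if missing:
            raise EchinodevError(f"samples missing from metadata: {sorted(missing)}")
        for col in ("hpf", "included"):
            if col not in self.sample_meta.columns:
                raise EchinodevError(f"sample metadata lacks column {col!r}")

    @property
    def ec_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def included_samples(self) -> list[str]:
        inc = self.sample_meta.loc[self.counts.columns, "included"]
        return [s for s, ok in inc.items() if bool(ok)]

    def included_totals(self) -> pd.Series:
        """Per-EC total read count over included samples only."""
        return self.counts[self.included_samples()].sum(axis=1)


#: Allowed unit tags for a TimeCourseMatrix.
UNITS = ("rpkm", "peak_normalized", "tpm_like")


@dataclass
class TimeCourseMatrix:
    """EC x ordered-time-point expression values.

    ``values`` columns are time points in hpf (strictly increasing);
    ``unit`` records the scale: raw ``rpkm``, ``peak_normalized`` (every
    row max is 1) or ``tpm_like`` (internal-standard scaled, standard mean
    = 1e6 per time point).
    """

    values: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise EchinodevError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        tps = np.asarray(self.values.columns, dtype=float)
        if len(tps) >= 2 and not (np.diff(tps) > 0).all():
            raise EchinodevError("time points must be strictly increasing")
        if self.values.index.has_duplicates:
            raise EchinodevError("duplicate EC ids in time-course matrix")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise EchinodevError("non-finite expression values")
        if (arr < 0).any():
            raise EchinodevError("negative expression values")

    @property
    def ec_ids(self) -> pd.Index:
        return self.values.index

    @property
    def timepoints_hpf(self) -> np.ndarray:
        return np.asarray(self.values.columns, dtype=float)


@dataclass
class ModeMap:
    """Gene -> expression mode assignment.

    ``labels`` maps every clustered gene to one of :data:`MODES`;
    ``flat_eps`` records the flatness tolerance (relative to the trajectory
    maximum) used when the map was produced.
    """

    labels: pd.Series
    flat_eps: float = 0.05

    def __post_init__(self) -> None:
        bad = set(self.labels.unique()) - set(MODES)
        if bad:
            raise EchinodevError(f"unknown mode labels: {sorted(bad)}")
        if self.labels.index.has_duplicates:
            raise EchinodevError("duplicate gene ids in mode map")

    def __len__(self) -> int:
        return len(self.labels)

    def counts(self) -> pd.Series:
        return self.labels.value_counts().reindex(MODES, fill_value=0)


@dataclass
class PresenceMatrix:
    """Gene x species boolean occupancy; first species is the reference.

    Every gene is, by construction, present in the reference species (the
    matrix is indexed by reference-species gene ids).
    """

    present: pd.DataFrame

    def __post_init__(self) -> None:
        if self.present.shape[1] < 2:
            raise EchinodevError("need at least two species")
        if self.present.index.has_duplicates:
            raise EchinodevError("duplicate gene ids in presence matrix")
        ref = self.present.columns[0]
        if not self.present[ref].all():
            raise EchinodevError(f"reference species {ref!r} column must be all present")

    @property
    def genes(self) -> pd.Index:
        return self.present.index

    @property
    def species(self) -> list[str]:
        return list(self.present.columns)

    @property
    def reference(self) -> str:
        return str(self.present.columns[0])

    def all_species_mask(self) -> pd.Series:
        return self.present.all(axis=1)


@dataclass
class ProteinSet:
    """id -> amino-acid sequence (uppercase 20-letter alphabet plus X)."""

    sequences: dict[str, str] = field(default_factory=dict)

    _ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

    def __post_init__(self) -> None:
        for sid, seq in self.sequences.items():
            if not seq:
                raise EchinodevError(f"empty sequence for {sid!r}")
            bad = set(seq) - self._ALPHABET
            if bad:
                raise EchinodevError(f"non-amino-acid characters in {sid!r}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, sid: str) -> str:
        return self.sequences[sid]

    def ids(self) -> list[str]:
        return list(self.sequences)
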
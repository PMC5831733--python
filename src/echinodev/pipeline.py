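"""End-to-end orchestration: simulate -> quantify -> cluster -> modes ->
conserve, with every artifact written as TSV carrying a provenance header.

Defaults follow the study constants: 10-read filter, SD < 0.01 internal
standard, 1e6 scale, k = 27 fuzzy clusters, 100 runs, 97% family identity,
1000 resampling draws of a 901-gene set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .cluster import assign_modes, cluster_trajectories
from .conservation import conservation_test
from .containers import EchinodevError
from .quantify import (
    compute_rpkm,
    filter_low_count,
    normalize_by_standard,
    peak_normalize,
    select_internal_standard,
)
from .simulate import PresenceSimConfig, SimulationConfig, simulate_presence, simulate_timecourse

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Per-stage parameters with study-constant defaults."""

    out_dir: Path = Path("echinodev_out")
    seed: int = 0
    # simulate
    simulation: SimulationConfig | None = None
    presence: PresenceSimConfig | None = None
    # quantify
    min_reads: int = 10
    sd_threshold: float = 0.01
    scale: float = 1e6
    # cluster / modes
    k: int | None = 27
    runs: int = 100
    fuzzifier: float = 1.25
    flat_eps: float = 0.05
    min_expression: float = 0.0
    # conservation
    n_draws: int = 1000
    stages: tuple[str, ...] = ("simulate", "quantify", "cluster", "modes", "conserve")
    extra: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the selected contiguous stage chain; returns artifact paths.

    Every stochastic stage derives its seed from ``config.seed`` and
    records it in the output provenance header.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    sim_cfg = config.simulation or SimulationConfig(seed=config.seed)
    cm = tc = truth = None
    if "simulate" in config.stages:
        cm, tc, truth, std_truth = simulate_timecourse(sim_cfg)
        io.write_count_matrix(
            cm, out / "counts.tsv", out / "samples.tsv", seed=sim_cfg.seed, stage="simulate"
        )
        io.write_timecourse(tc, out / "expression.tsv", seed=sim_cfg.seed, stage="simulate")
        io.write_table(truth.to_frame("mode"), out / "truth_modes.tsv", index_label="gene")
        io.write_gene_list(std_truth, out / "truth_standards.txt")
        artifacts["counts"] = out / "counts.tsv"
        artifacts["expression"] = out / "expression.tsv"

    norm = None
    if "quantify" in config.stages:
        if cm is None:
            cm = io.read_count_matrix(out / "counts.tsv", out / "samples.tsv")
        if tc is None:
            tc = io.read_timecourse(out / "expression.tsv")
        filtered = filter_low_count(cm, min_reads=config.min_reads)
        from .containers import TimeCourseMatrix

        expr = TimeCourseMatrix(values=tc.values.loc[filtered.ec_ids], unit=tc.unit)
        pn = peak_normalize(expr)
        standard = select_internal_standard(pn, sd_threshold=config.sd_threshold)
        norm = normalize_by_standard(expr, standard, scale=config.scale)
        io.write_timecourse(
            norm.matrix,
            out / "normalized.tsv",
            sd_threshold=config.sd_threshold,
            scale=config.scale,
            n_standard=len(standard),
            stage="quantify",
        )
        io.write_gene_list(standard, out / "standard_set.txt")
        artifacts["normalized"] = out / "normalized.tsv"

    consensus = mode_input = None
    if "cluster" in config.stages:
        if norm is None:
            matrix = io.read_timecourse(out / "normalized.tsv")
        else:
            matrix = norm.matrix
        mode_input = peak_normalize(matrix)
        run_results, consensus = cluster_trajectories(
            mode_input,
            k=config.k,
            runs=config.runs,
            m=config.fuzzifier,
            seed=config.seed,
        )
        cons_df = pd.DataFrame(
            {
                "consensus_cluster": consensus.consensus_label,
                "support": consensus.consensus_support,
            },
            index=mode_input.ec_ids,
        )
        io.write_table(
            cons_df,
            out / "consensus.tsv",
            index_label="gene",
            k=run_results[0].k,
            runs=config.runs,
            fuzzifier=config.fuzzifier,
            seed=config.seed,
            stage="cluster",
        )
        artifacts["consensus"] = out / "consensus.tsv"

    if "modes" in config.stages:
        if consensus is None:
            raise EchinodevError("modes stage requires the cluster stage in the same chain")
        mm = assign_modes(
            consensus,
            gene_ids=mode_input.ec_ids,
            clustered=mode_input.values.to_numpy(),
            expression=matrix.values.to_numpy(),
            flat_eps=config.flat_eps,
            min_expression=config.min_expression,
        )
        extra = pd.DataFrame(
            {
                "consensus_cluster": consensus.consensus_label,
                "support": consensus.consensus_support,
            },
            index=mm.labels.index,
        )
        io.write_mode_map(mm, out / "modes.tsv", extra=extra, stage="modes")
        artifacts["modes"] = out / "modes.tsv"

    if "conserve" in config.stages:
        pres_cfg = config.presence or PresenceSimConfig(seed=config.seed)
        pm, enriched = simulate_presence(pres_cfg)
        io.write_presence(pm, out / "presence.tsv", seed=pres_cfg.seed, stage="conserve")
        io.write_gene_list(enriched, out / "enriched_set.txt")
        if enriched:
            report = conservation_test(pm, enriched, n_draws=config.n_draws, seed=config.seed)
            io.write_table(
                pd.DataFrame([report.summary()]),
                out / "conservation.tsv",
                index_label=None,
                n_draws=config.n_draws,
                seed=config.seed,
                stage="conserve",
            )
            artifacts["conservation"] = out / "conservation.tsv"
        artifacts["presence"] = out / "presence.tsv"

    return artifacts
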
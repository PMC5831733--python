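"""Internal-standard normalization of a simulated 4-stage time course.

Generates a synthetic expression-cluster matrix with 50 planted
near-constant genes, filters technical background (< 10 reads), selects
the internal standard (peak-normalized SD < 0.01) and rescales so the
standard averages one million at every time point.
"""

from echinodev import (
    SimulationConfig,
    filter_low_count,
    normalize_by_standard,
    peak_normalize,
    select_internal_standard,
    simulate_timecourse,
)

cfg = SimulationConfig(n_genes=1000, n_standard=50, n_lowcount=30, seed=42)
counts, expression, truth, planted_standards = simulate_timecourse(cfg)

kept = filter_low_count(counts, min_reads=10)
print(f"ECs retained after the 10-read filter: {len(kept.ec_ids)} of {len(counts.ec_ids)}")

expr = expression.values.loc[kept.ec_ids]
from echinodev import TimeCourseMatrix

expression = TimeCourseMatrix(values=expr, unit=expression.unit)
standard = select_internal_standard(peak_normalize(expression), sd_threshold=0.01)
recall = len(standard & planted_standards) / len(planted_standards)
print(f"internal-standard ECs selected: {len(standard)} (planted-standard recall {recall:.2f})")

result = normalize_by_standard(expression, standard, scale=1e6)
means = result.matrix.values.loc[sorted(standard)].mean(axis=0)
print("standard-set mean per time point after scaling:")
print(means.to_string(float_format=lambda v: f"{v:,.0f}"))
# the mean is exactly 1e6 at every stage: expression is now on a common
# transcripts-per-million-like scale, comparable across time points
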
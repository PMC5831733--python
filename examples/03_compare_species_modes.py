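"""Cross-species comparison of expression-mode usage.

Builds two mode maps linked by an ortholog table in which a third of the
genes switch temporal mode between species, then tallies the 5 x 5
mode-by-mode contingency. The diagonal counts genes used in the same
temporal mode in both species; off-diagonal mass is regulatory divergence.
"""

import numpy as np
import pandas as pd

from echinodev import MODES, ModeMap, OrthologMap, compare_mode_usage
from echinodev.containers import BI_MODAL, EARLY, INTERMEDIATE, LATE

rng = np.random.default_rng(5)
n = 120
modes = [EARLY, INTERMEDIATE, LATE, BI_MODAL]
genes_a = [f"afi_{i:03d}" for i in range(n)]
genes_b = [f"spu_{i:03d}" for i in range(n)]
modes_a = rng.choice(modes, size=n)
# two thirds conserved usage, one third reassigned to another mode
modes_b = modes_a.copy()
switch = rng.random(n) < 1 / 3
modes_b[switch] = rng.choice(modes, size=int(switch.sum()))

map_ = OrthologMap(
    pairs=pd.DataFrame({"gene_a": genes_a, "gene_b": genes_b, "relation": "ortholog"})
)
result = compare_mode_usage(
    ModeMap(labels=pd.Series(modes_a, index=genes_a, dtype=object)),
    ModeMap(labels=pd.Series(modes_b, index=genes_b, dtype=object)),
    map_,
)

print("mode-by-mode contingency (rows: species A, columns: species B):")
print(result.contingency.to_string())
shared = int(result.per_mode_shared.sum())
total = int(result.contingency.to_numpy().sum())
print(f"\nsame-mode orthologs: {shared}/{total} "
      f"({100 * shared / total:.0f}% conserved temporal usage)")
# each off-diagonal cell is a putative heterochronic shift: the ortholog
# pair is expressed, but deployed at a different phase of development
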
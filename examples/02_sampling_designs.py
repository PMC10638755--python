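"""Enumerate the benchmark sampling designs and draw one dataset.

Three designs vary the number of cell types (5..20), the cells per type
(50..250), and the major:minor imbalance ratio (2:1, 4:1, 10:1), each
repeated 10 times per atlas.  Every dataset spec carries a seed derived
from the base seed, so any single dataset can be rebuilt in isolation.
"""

import pandas as pd

from scattrib import (
    DesignGrid, SyntheticSpec, enumerate_designs, generate, sample_dataset,
    specs_manifest,
)

grid = DesignGrid(base_seed=0)
specs = enumerate_designs(grid)
man = specs_manifest(specs)
print(man.groupby("design_kind").size().rename("datasets").to_string())
print(f"total: {len(specs)} dataset specifications")

# use a synthetic atlas as the sampling source (a real atlas works the same)
atlas, _ = generate(SyntheticSpec(n_genes=300, n_cell_types=12,
                                  cells_per_type=260, markers_per_type=3, seed=9))
imb = [s for s in specs if s.design.design_kind == "imbalance"
       and s.design.n_cell_types == 10 and s.design.n_cells_minor == 20][0]
ds = sample_dataset(atlas, imb)
sizes = pd.Series(ds.cell_type).value_counts()
print(f"\none 10:1 imbalance dataset: {ds.n_cells} cells "
      f"({(sizes == 200).sum()} major types x 200, {(sizes == 20).sum()} minor x 20)")
# 5 x 200 + 5 x 20 = 1100 cells: half the types are major, half minor.
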
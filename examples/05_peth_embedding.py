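"""PCA embedding of double PETHs across a synthetic multi-lab population.

Each of five brain regions carries a distinct movement-locked response
template; cells are summarized by concatenated fast/slow reaction-time
PETHs, embedded with PCA, and compared with KS tests targeting either
regions (expected different) or labs (expected exchangeable).
"""

import numpy as np

from reprophys import (
    REGIONS,
    SynthConfig,
    build_peth_matrix,
    gen_multilab_population,
    ks_test_grid,
    pca_embed,
    subsampled_ks_fisher,
)

cfg = SynthConfig(
    seed=11,
    n_labs=6,
    mice_per_lab=1,
    units_per_region={r: 5 for r in REGIONS},
    n_trials=120,
    n_channels=16,
)
population = gen_multilab_population(cfg)
pm = build_peth_matrix(population)
emb = pca_embed(pm.Y, k=2)
print(f"PETH matrix: {pm.Y.shape[0]} cells x {pm.Y.shape[1]} bins")
print(f"median reconstruction R^2 with 2 PCs: {np.median(emb.r2_per_cell):.2f}\n")

labs = pm.cell_meta["lab"].to_numpy()
regions = pm.cell_meta["region"].to_numpy()
grid = ks_test_grid(emb.U[:, 0], labs, regions)
print("KS p-values, region vs rest (row 'all'):")
print(grid.loc["all", list(REGIONS)].apply(lambda p: f"{p:.2e}").to_string())
print("\nKS p-values, lab vs rest (column 'all'):")
print(grid.loc[grid.index != "all", "all"].apply(lambda p: f"{p:.3f}").to_string())

fr = subsampled_ks_fisher(emb.U[:, 0], regions == "PO", n_samplings=50, seed=0)
print(f"\ncell-number-controlled PO test (Fisher combined): p = {fr.p_value:.2e}")
print(
    "\nRegion-targeted tests are significant (distinct dynamics per"
    "\nregion); lab-targeted tests are not, since labs are exchangeable"
    "\nby construction — the cross-lab reproducibility signature."
)
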
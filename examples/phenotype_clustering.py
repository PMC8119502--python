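"""Build a multidimensional migration phenotype and cluster the cell lines.

Simulates a panel of synthetic "cell lines" (one collective, three
disordered) measured in paired replicates against a control, computes paired
t-statistics per metric, and splits the line–line correlation matrix into
blocks by the greedy/BIC procedure.
"""

import numpy as np
import pandas as pd

import sheetflow as sf
from sheetflow.phenotype import block_split_bic, build_phenotype_matrix, cluster_tree

kappas = {"collective": 8.0, "dis1": 0.8, "dis2": 1.0, "dis3": 1.2, "control": 3.0}
rows = []
for rep in range(5):
    for li, (line, kappa) in enumerate(kappas.items()):
        p = sf.SyntheticParams(seed=1000 + 17 * rep + 101 * li, n_frames=40,
                               direction_concentration=kappa)
        seq, _ = sf.generate_flow_sequence(p, grid_shape=(16, 16))
        dev = sf.angular_deviation(sf.radial_direction_angles(seq))
        coord = sf.local_coordination(sf.radial_velocity_autocorrelation(seq))
        rows += [
            dict(replicate=rep, cell_line=line, metric="angular_deviation", value=dev),
            dict(replicate=rep, cell_line=line, metric="local_coordination", value=coord),
            dict(replicate=rep, cell_line=line, metric="u_variability",
                 value=float(np.std(seq.u_stack()))),
        ]

pheno = build_phenotype_matrix(pd.DataFrame(rows), control="control")
print("phenotype matrix (paired t vs control; + = higher than control):")
print(pheno.round(2))

tree = cluster_tree(pheno, axis="lines")
X = pheno.to_numpy(float).T
order = [list(pheno.columns).index(l) for l in tree.leaf_order]
labels = block_split_bic(np.corrcoef(X[order]))
print(f"\nleaf order : {tree.leaf_order}")
print(f"blocks     : {dict(zip(tree.leaf_order, labels.tolist()))}")
print("→ the disordered lines share one block; the collective line separates.")
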
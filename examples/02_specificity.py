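"""Background-probe specificity analysis on synthetic tissue.

Shows the three length scales: whole-tissue count ranking (which targets sit
in the background range), the global segmentation-free FDR, and the spatial
rescue of a rare-cell-type marker via Moran's I + nearest-neighbor distance.
A uniform pseudo-target planted at the same abundance is flagged instead.
"""

import stqc
from stqc.simulate import CellTypeSpec

types = list(stqc.TissueSimConfig().cell_types)
types.append(CellTypeSpec("rare", "internodular", 0.014, {"RARE": 25.0}))
cfg = stqc.TissueSimConfig(
    field_size=(800.0, 800.0),
    cell_density=1200.0,
    nodules=((250.0, 250.0, 180.0), (600.0, 600.0, 140.0)),
    cell_types=tuple(types),
    background_rates={f"Blank-{i:02d}": 250.0 + 10.0 * i for i in range(25)},
    uniform_target_rates={"PSEUDO": 110.0},  # spatially random "target"
)
tt, mask, panel, _ = stqc.simulate_tissue(cfg, seed=1)

fdr = stqc.global_fdr(tt, panel)
print(f"global FDR: {fdr.fdr_percent:.2f}% "
      f"({fdr.background_barcode_calls} background calls on "
      f"{fdr.number_of_background_barcodes} probes vs "
      f"{fdr.total_target_gene_calls} target calls on "
      f"{fdr.number_of_target_genes} genes)")

matrix, _ = stqc.assign_transcripts(tt, mask, panel, include_background=True)
table = stqc.build_specificity_table(
    tt, panel, cell_counts=matrix.counts,
    centroids=matrix.centroids[["x", "y"]].to_numpy(),
).set_index("gene_id")

in_range = table[(table["kind"] == "target") & table["within_background_range"]]
print(f"{len(in_range)} targets within the background count range: "
      f"{sorted(in_range.index)}")
for gene in ("RARE", "PSEUDO"):
    row = table.loc[gene]
    print(f"  {gene}: {row.total_count} calls, scaled Moran's I "
          f"{row.morans_i_scaled:.2f}, median NN distance "
          f"{row.median_nn_distance:.1f} um -> "
          f"{'LOW CONFIDENCE' if row.low_confidence else 'kept'}")
print("RARE survives because its calls cluster inside scattered rare cells "
      "(small NN distance); PSEUDO's spatially random calls look like a "
      "background probe and are flagged.")
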
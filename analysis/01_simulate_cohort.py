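"""Generate the canonical synthetic cohort, spatial grid and proteome.

Writes the full data (MTX sample directories, spot grid, proteome) under
scratch/data/ and a compact cohort summary under results/.
"""

from pathlib import Path

import pandas as pd

from astromod import CohortConfig, generate_cohort, generate_proteome, generate_spot_grid
from astromod import io

SCRATCH = Path("scratch/data")
RESULTS = Path("results")
SEED = 42


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = CohortConfig(seed=SEED)
    samples, metadata, truth = generate_cohort(cfg)
    io.write_cohort(samples, metadata, SCRATCH / "cohort")
    truth.cluster_of_cell.rename("cluster").rename_axis("cell").reset_index() \
        .to_csv(SCRATCH / "cohort" / "cell_clusters.tsv", sep="\t", index=False)

    layout = {"CTX": (0, 10, 0, 20), "HIP": (10, 20, 0, 10), "WM": (10, 20, 10, 20)}
    markers = {r: [f"{r}_g{i}" for i in range(30)] for r in layout}
    cm, spots = generate_spot_grid(20, 20, layout, markers, seed=SEED)
    io.write_spot_grid(cm, spots, SCRATCH / "spots")
    io.write_gmt(markers, SCRATCH / "spots" / "region_markers.gmt")

    modules = {p: truth.program_top_genes(p, 20) for p in truth.program_genes}
    ab, traits = generate_proteome(
        modules, {"control": 30, "AsymAD": 30, "AD": 30},
        within_module_r=0.6, missing_rate=0.005,
        status_shifts={"P2": {"AsymAD": 1.5, "AD": 1.5}}, seed=SEED,
    )
    io.write_proteome(ab, traits, SCRATCH / "proteome")
    io.write_gmt(modules, SCRATCH / "proteome" / "modules.gmt")

    summary = metadata.copy()
    summary["n_cells"] = [samples[s].n_cells for s in summary["sample_id"]]
    summary.to_csv(RESULTS / "cohort_summary.tsv", sep="\t", index=False)
    print(f"cohort: {len(samples)} samples, "
          f"{sum(s.n_cells for s in samples.values())} cells, "
          f"{cfg.n_genes} genes, {cfg.n_programs} planted programs")
    print(f"spot grid: {len(spots)} spots over {len(layout)} regions")
    print(f"proteome: {ab.shape[0]} proteins x {ab.shape[1]} samples "
          f"(0.5% missing, early shift planted in P2)")


if __name__ == "__main__":
    main()
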
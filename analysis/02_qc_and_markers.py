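"""QC, normalization, HVG selection and subtype markers on the cohort.

Reads scratch/data/cohort (written by 01), applies the standard QC
criteria, selects highly variable genes and detects one-vs-rest subtype
markers; writes marker and QC summaries under results/.
"""

from pathlib import Path

import pandas as pd

from astromod import QCThresholds, find_markers, lognormalize, qc_filter, select_hvg
from astromod import io
from astromod.pipeline import pool_samples

SCRATCH = Path("scratch/data")
RESULTS = Path("results")


def main() -> None:
    samples, metadata = io.read_cohort(SCRATCH / "cohort")
    labels = pd.read_csv(SCRATCH / "cohort" / "cell_clusters.tsv", sep="\t") \
        .set_index("cell")["cluster"]

    thr = QCThresholds(min_genes_per_cell=50)  # desk-scale cohort: 1,000 genes
    kept, reports = {}, []
    for sid, cm in samples.items():
        filtered, report = qc_filter(cm, thr)
        kept[sid] = filtered
        reports.append(report.assign(sample_id=sid))
    qc = pd.concat(reports)
    n_removed = int((~qc["kept"]).sum())

    pooled = pool_samples(kept)
    norm = lognormalize(pooled)
    hvg = select_hvg(norm, 300)
    markers = find_markers(norm, labels.reindex(norm.cells))
    markers.to_csv(RESULTS / "markers.tsv", sep="\t", index=False)
    summary = markers.groupby("cluster").agg(
        n_markers=("gene", "size"), max_log2fc=("log2fc", "max")
    )
    summary.to_csv(RESULTS / "marker_summary.tsv", sep="\t")
    pd.Series(hvg, name="gene").to_csv(RESULTS / "hvg.tsv", sep="\t", index=False)

    print(f"QC removed {n_removed} of {len(qc)} cells")
    print(f"{len(markers)} marker records across "
          f"{markers['cluster'].nunique()} subtypes; 300 HVGs written")
    print(summary)


if __name__ == "__main__":
    main()
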
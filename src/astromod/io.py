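"""Reading and writing the pipeline's on-disk formats.

Samples are exchanged as 10x-style directories (matrix.mtx + genes.tsv +
barcodes.tsv, genes x cells), gene sets as GMT, everything tabular as TSV.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CountMatrix


def write_sample_dir(cm: CountMatrix, path: str | os.PathLike) -> None:
    """Write one sample as matrix.mtx / genes.tsv / barcodes.tsv."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(cm.counts))
    pd.Series(cm.genes).to_csv(path / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(cm.cells).to_csv(
        path / "barcodes.tsv", sep="\t", index=False, header=False
    )


def read_sample_dir(path: str | os.PathLike) -> CountMatrix:
    path = Path(path)
    mtx = sp.csr_matrix(scipy.io.mmread(path / "matrix.mtx"))
    genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0]
    cells = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0]
    return CountMatrix(mtx, pd.Index(genes), pd.Index(cells))


def write_cohort(samples: dict[str, CountMatrix], metadata: pd.DataFrame,
                 outdir: str | os.PathLike) -> None:
    """Write a cohort as per-sample directories plus samples.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sid, cm in samples.items():
        write_sample_dir(cm, outdir / sid)
    metadata.to_csv(outdir / "samples.tsv", sep="\t", index=False)


def read_cohort(indir: str | os.PathLike) -> tuple[dict[str, CountMatrix], pd.DataFrame]:
    indir = Path(indir)
    metadata = pd.read_csv(indir / "samples.tsv", sep="\t")
    samples = {
        sid: read_sample_dir(indir / sid) for sid in metadata["sample_id"]
    }
    return samples, metadata


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> gene..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | os.PathLike,
              description: str = "astromod") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def write_spot_grid(cm: CountMatrix, spots: pd.DataFrame,
                    outdir: str | os.PathLike) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(outdir / "matrix.mtx", sp.coo_matrix(cm.counts))
    pd.Series(cm.genes).to_csv(outdir / "genes.tsv", sep="\t", index=False, header=False)
    spots.to_csv(outdir / "spots.tsv", sep="\t", index=False)


def read_spot_grid(indir: str | os.PathLike) -> tuple[CountMatrix, pd.DataFrame]:
    indir = Path(indir)
    mtx = sp.csr_matrix(scipy.io.mmread(indir / "matrix.mtx"))
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0]
    spots = pd.read_csv(indir / "spots.tsv", sep="\t")
    cm = CountMatrix(mtx, pd.Index(genes), pd.Index(spots["spot_id"]))
    return cm, spots


def write_proteome(abundances: pd.DataFrame, traits: pd.DataFrame,
                   outdir: str | os.PathLike) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    abundances.to_csv(outdir / "proteins.tsv", sep="\t")
    traits.to_csv(outdir / "traits.tsv", sep="\t", index=False)


def read_proteome(indir: str | os.PathLike) -> tuple[pd.DataFrame, pd.DataFrame]:
    indir = Path(indir)
    abundances = pd.read_csv(indir / "proteins.tsv", sep="\t", index_col=0)
    traits = pd.read_csv(indir / "traits.tsv", sep="\t")
    return abundances, traits
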
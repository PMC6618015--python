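"""Readers and writers for the pipeline's on-disk formats.

Genotype likelihoods travel in BEAGLE text format: columns ``marker
allele1 allele2`` followed by three likelihood columns per individual
(genotypes with 0, 1 and 2 copies of allele2, the derived allele).
Markers are ``<gene>_<position>``. Everything else is plain TSV plus a
Newick tree. Gzip-compressed BEAGLE files are read transparently.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd

from .popgen import GenotypeLikelihoodTable

__all__ = [
    "write_beagle",
    "read_beagle",
    "read_gene_map",
    "read_sample_sheet",
    "write_dataset",
    "FLOAT_FORMAT",
]

FLOAT_FORMAT = "%.10g"


def write_beagle(table: GenotypeLikelihoodTable, path) -> None:
    path = Path(path)
    n_ind = table.n_individuals
    header = ["marker", "allele1", "allele2"]
    for ind in table.individuals:
        header.extend([str(ind)] * 3)
    flat = table.gl.reshape(table.n_sites, 3 * n_ind)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        fh.write("\t".join(header) + "\n")
        for s in range(table.n_sites):
            vals = "\t".join(FLOAT_FORMAT % v for v in flat[s])
            fh.write(f"{table.markers[s]}\t0\t1\t{vals}\n")


def read_beagle(path, sample_sheet: pd.DataFrame) -> GenotypeLikelihoodTable:
    """Parse a BEAGLE likelihood file into a site table.

    Sex labels are joined in from the sample sheet by individual id.
    Individuals whose three likelihoods are identical at a site carry no
    read data there and are marked missing.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["marker", "allele1", "allele2"]:
            raise ValueError(f"{path}: not a BEAGLE likelihood file")
        individuals = header[3::3]
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    if not rows:
        raise ValueError(f"{path}: no sites")
    markers = np.array([r[0] for r in rows])
    gl = np.array([[float(v) for v in r[3:]] for r in rows]).reshape(
        len(rows), len(individuals), 3
    )
    genes = np.array([m.rsplit("_", 1)[0] for m in markers])
    positions = np.array([int(m.rsplit("_", 1)[1]) for m in markers])
    sex_by_ind = (
        sample_sheet.drop_duplicates("individual")
        .set_index("individual")["sex"]
        .map({"male": "M", "female": "F"})
    )
    sexes = sex_by_ind.reindex(individuals)
    if sexes.isna().any():
        missing = sexes.index[sexes.isna()].tolist()
        raise ValueError(f"individuals absent from sample sheet: {missing}")
    has_data = ~np.all(np.isclose(gl, gl[:, :, [0]]), axis=2)
    return GenotypeLikelihoodTable(
        markers=markers,
        genes=genes,
        positions=positions,
        gl=gl,
        has_data=has_data,
        sexes=sexes.to_numpy(),
        individuals=np.array(individuals),
    )


def read_gene_map(path) -> pd.DataFrame:
    gm = pd.read_csv(path, sep="\t")
    required = {"gene", "chrom_class", "start", "end"}
    missing = required - set(gm.columns)
    if missing:
        raise ValueError(f"gene map lacks columns {sorted(missing)}")
    if not set(gm["chrom_class"]) <= {"A", "Z"}:
        raise ValueError("chrom_class must be A or Z")
    return gm


def read_sample_sheet(path) -> pd.DataFrame:
    ss = pd.read_csv(path, sep="\t")
    required = {"sample", "species", "individual", "sex", "tissue"}
    missing = required - set(ss.columns)
    if missing:
        raise ValueError(f"sample sheet lacks columns {sorted(missing)}")
    if not set(ss["sex"]) <= {"male", "female"}:
        raise ValueError("sex must be male or female")
    if not set(ss["tissue"]) <= {"gonad", "spleen"}:
        raise ValueError("tissue must be gonad or spleen")
    dup = ss.duplicated(subset=["individual", "tissue"])
    if dup.any():
        raise ValueError("(individual, tissue) pairs must be unique")
    return ss


def _to_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def write_dataset(dataset, outdir) -> Path:
    """Write a simulated dataset to the directory layout the CLI reads.

    Layout: top-level ``tree.nwk``, ``traits.tsv``, ``genes.tsv`` (truth
    labels), and one subdirectory per species containing ``gl.beagle``,
    ``counts.tsv``, ``samples.tsv``, ``annotation.tsv``, ``genemap.tsv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "tree.nwk").write_text(dataset.newick + "\n")
    _to_tsv(dataset.traits, outdir / "traits.tsv")
    _to_tsv(dataset.genes, outdir / "genes.tsv")
    annotation = dataset.genes[
        ["gene", "chrom_class", "length_bp", "gc_fraction", "immune_flag"]
    ]
    for sp, data in dataset.species.items():
        spdir = outdir / f"species_{sp}"
        spdir.mkdir(exist_ok=True)
        write_beagle(data["gl_table"], spdir / "gl.beagle")
        _to_tsv(data["counts"].reset_index(), spdir / "counts.tsv")
        _to_tsv(data["samples"], spdir / "samples.tsv")
        _to_tsv(annotation, spdir / "annotation.tsv")
        _to_tsv(data["genemap"], spdir / "genemap.tsv")
    return outdir
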
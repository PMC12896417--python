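"""Readers and writers for the plain-text interchange formats.

Annotation travels as GFF3 (1-based inclusive on disk, 0-based half-open in
memory), count matrices as featureCounts-style TSV (Geneid, Chr, Start,
End, Strand, Length, then one column per library), library metadata and
truth tables as TSV, configuration as YAML.
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import gffutils
import pandas as pd
import yaml

from .containers import CountMatrix
from .errors import InputError
from .simulate import GeneModel, SimConfig


def write_gff3(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    """Write gene features as GFF3 (converting to 1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};subgenome={g.subgenome}"
            fh.write(
                "\t".join(
                    [
                        g.scaffold,
                        "karyonorm",
                        "gene",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | os.PathLike) -> pd.DataFrame:
    """Read gene features from GFF3 into a 0-based half-open annotation table."""
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    rows = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        rows.append(
            {
                "gene_id": gene_id,
                "scaffold": feat.seqid,
                "start": feat.start - 1,  # GFF3 is 1-based inclusive
                "end": feat.end,
                "strand": feat.strand,
                "subgenome": feat.attributes.get("subgenome", ["NA"])[0],
            }
        )
    if not rows:
        raise InputError(f"no gene features found in {path}")
    return pd.DataFrame(rows).set_index("gene_id")


def write_bed(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.scaffold}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def write_counts_tsv(cm: CountMatrix, genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    """featureCounts-style TSV: annotation columns, then one column per library."""
    ann = {g.gene_id: g for g in genes}
    missing = [gid for gid in cm.gene_ids if gid not in ann]
    if missing:
        raise InputError(f"genes missing from annotation: {missing[:5]}")
    table = pd.DataFrame(
        {
            "Geneid": cm.gene_ids,
            "Chr": [ann[g].scaffold for g in cm.gene_ids],
            "Start": [ann[g].start + 1 for g in cm.gene_ids],
            "End": [ann[g].end for g in cm.gene_ids],
            "Strand": [ann[g].strand for g in cm.gene_ids],
            # the length actually counted (the WGS window for WGS data)
            "Length": (
                cm.lengths.astype(int).tolist()
                if cm.lengths is not None
                else [ann[g].length for g in cm.gene_ids]
            ),
        }
    )
    out = pd.concat([table.reset_index(drop=True), cm.counts.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False)


def write_library_metadata(cm: CountMatrix, path: str | os.PathLike) -> None:
    cm.libraries.rename_axis("library_id").to_csv(path, sep="\t")


def read_library_metadata(path: str | os.PathLike) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t").set_index("library_id")
    required = {"subline", "assay", "replicate"}
    if not required <= set(meta.columns):
        raise InputError(f"library metadata must have columns {sorted(required)}")
    return meta


def read_counts_tsv(path: str | os.PathLike, libraries: pd.DataFrame) -> CountMatrix:
    """Read a featureCounts-style TSV together with its library metadata table."""
    table = pd.read_csv(path, sep="\t", comment="#")
    if "Geneid" not in table.columns:
        raise InputError("expected a featureCounts-style table with a Geneid column")
    table = table.set_index("Geneid").rename_axis("gene_id")
    annotation_cols = [c for c in ("Chr", "Start", "End", "Strand", "Length") if c in table]
    lib_cols = [c for c in table.columns if c not in annotation_cols]
    lengths = table["Length"] if "Length" in table else None
    counts = table[lib_cols]
    return CountMatrix(counts=counts, libraries=libraries.loc[lib_cols], lengths=lengths)


def write_truth(truth: pd.DataFrame, path: str | os.PathLike) -> None:
    truth.to_csv(path, sep="\t")


def read_truth(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").set_index("gene_id")


def write_config(config: SimConfig, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def read_config(path: str | os.PathLike) -> SimConfig:
    with open(path) as fh:
        data: Mapping = yaml.safe_load(fh)
    return SimConfig.from_dict(data)


def write_dataset(outdir: str | os.PathLike, config: SimConfig) -> dict[str, str]:
    """Simulate a full dataset and write every artifact to ``outdir``."""
    from .simulate import simulate_dataset

    os.makedirs(outdir, exist_ok=True)
    genes, truth, wgs, rna = simulate_dataset(config)
    paths = {
        "annotation": os.path.join(outdir, "genes.gff3"),
        "wgs_counts": os.path.join(outdir, "wgs_counts.tsv"),
        "rna_counts": os.path.join(outdir, "rna_counts.tsv"),
        "wgs_libraries": os.path.join(outdir, "wgs_libraries.tsv"),
        "rna_libraries": os.path.join(outdir, "rna_libraries.tsv"),
        "truth": os.path.join(outdir, "truth.tsv"),
        "config": os.path.join(outdir, "config.yaml"),
    }
    write_gff3(genes, paths["annotation"])
    write_counts_tsv(wgs, genes, paths["wgs_counts"])
    write_counts_tsv(rna, genes, paths["rna_counts"])
    write_library_metadata(wgs, paths["wgs_libraries"])
    write_library_metadata(rna, paths["rna_libraries"])
    write_truth(truth, paths["truth"])
    write_config(config, paths["config"])
    return paths
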
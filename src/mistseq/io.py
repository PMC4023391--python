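"""Readers and writers for the external file formats.

Count tables travel as BED-derived TSV: fixed columns ``chrom pos strand
species`` followed by one column per library named
``condition:timepoint:replicate`` (e.g. ``WT:0:R1``).  Gene models come
from GFF3 (1-based inclusive coordinates, converted to 0-based
half-open), full-length isoforms and motifs from plain TSV.  All output
tables get a commented header recording the configuration and seed.
"""
from __future__ import annotations

import os
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from . import __version__
from .model import (
    CountTable,
    FormatError,
    FullLengthIsoform,
    GeneModel,
    RunConfig,
    SITE_INDEX,
    STRANDS,
    ValidationError,
)

FIXED_COLUMNS = ["chrom", "pos", "strand", "species"]


def _parse_library(name: str) -> tuple:
    parts = name.split(":")
    if len(parts) != 3:
        raise FormatError(
            f"count column {name!r} is not of the form condition:timepoint:replicate"
        )
    cond, tp, rep = parts
    try:
        tp_val = float(tp)
    except ValueError as exc:
        raise FormatError(f"count column {name!r}: timepoint {tp!r} is not numeric") from exc
    return cond, tp_val, rep


def format_library(lib: tuple) -> str:
    cond, tp, rep = lib
    tp = int(tp) if float(tp).is_integer() else tp
    return f"{cond}:{tp}:{rep}"


def read_site_counts(path, config: Optional[RunConfig] = None) -> CountTable:
    """Read a per-site count table, summing duplicate rows for the same site."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in FIXED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    lib_names = [c for c in df.columns if c not in FIXED_COLUMNS]
    if not lib_names:
        raise FormatError("no count columns found")
    libs = [_parse_library(c) for c in lib_names]

    bad_strand = ~df["strand"].isin(STRANDS)
    if bad_strand.any():
        row = int(np.flatnonzero(bad_strand)[0])
        raise ValidationError(f"row {row}: invalid strand {df['strand'].iloc[row]!r}")
    try:
        counts = df[lib_names].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric count value: {exc}") from exc
    if np.isnan(counts).any():
        row = int(np.flatnonzero(np.isnan(counts).any(axis=1))[0])
        raise ValidationError(f"row {row}: missing count value")
    if (counts < 0).any():
        row = int(np.flatnonzero((counts < 0).any(axis=1))[0])
        raise ValidationError(f"row {row}: negative count")

    grouped = df.groupby(SITE_INDEX, sort=True)
    summed = grouped[lib_names].sum()
    species = grouped["species"].first()
    n_species = grouped["species"].nunique()
    if (n_species > 1).any():
        key = n_species[n_species > 1].index[0]
        raise ValidationError(f"site {key} has conflicting species tags")
    summed.columns = pd.MultiIndex.from_tuples(libs)
    return CountTable(summed, species)


def write_site_counts(table: CountTable, path, config: Optional[RunConfig] = None) -> None:
    df = table.counts.copy()
    df.columns = [format_library(lib) for lib in df.columns]
    df.insert(0, "species", table.species)
    with open(path, "w") as fh:
        _write_header(fh, config)
        df.reset_index().to_csv(fh, sep="\t", index=False)


def read_gene_models(path) -> list[GeneModel]:
    """Parse GFF3 gene models: CDS features are ORFs, SUT features are SUTs."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"line {lineno}: expected 9 GFF columns, got {len(fields)}")
            chrom, _source, ftype, start, end, _score, strand, _frame, attrs = fields
            if ftype not in ("CDS", "SUT"):
                continue
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise ValidationError(f"line {lineno}: end < start")
            if strand not in STRANDS:
                raise ValidationError(f"line {lineno}: invalid strand {strand!r}")
            gene_id = _gff_attr(attrs, "ID") or f"feature_{lineno}"
            biotype = "ORF" if ftype == "CDS" else "SUT"
            # GFF is 1-based inclusive; internal is 0-based half-open.
            genes.append(
                GeneModel(gene_id, chrom, start_i - 1, end_i, strand, biotype)
            )
    return genes


def write_gene_models(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            ftype = "CDS" if g.biotype == "ORF" else "SUT"
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        "mistseq",
                        ftype,
                        str(g.cds_start + 1),
                        str(g.cds_end),
                        ".",
                        g.strand,
                        ".",
                        f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )


def _gff_attr(attrs: str, key: str) -> Optional[str]:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            return part[len(key) + 1 :]
    return None


def read_tif_annotation(path) -> list[FullLengthIsoform]:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"chrom", "strand", "start5", "end3", "support"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"TIF table missing column(s) {sorted(missing)}")
    if "tif_id" not in df.columns:
        df["tif_id"] = [f"tif_{i}" for i in range(len(df))]
    return [
        FullLengthIsoform(
            str(r.tif_id), str(r.chrom), str(r.strand), int(r.start5), int(r.end3),
            int(r.support),
        )
        for r in df.itertuples()
    ]


def write_tif_annotation(tifs: Iterable[FullLengthIsoform], path) -> None:
    rows = [
        (t.tif_id, t.chrom, t.strand, t.start5, t.end3, t.support) for t in tifs
    ]
    pd.DataFrame(
        rows, columns=["tif_id", "chrom", "strand", "start5", "end3", "support"]
    ).to_csv(path, sep="\t", index=False)


def read_motifs(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"motif_id", "iupac"} <= set(df.columns):
        raise FormatError("motif table needs columns motif_id, iupac")
    return df[["motif_id", "iupac"]]


def write_fasta(genome: dict, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _write_header(fh, config: Optional[RunConfig]) -> None:
    fh.write(f"# mistseq {__version__}\n")
    if config is not None:
        for key, val in config.to_header_dict().items():
            fh.write(f"# {key}={val}\n")


def write_table(df: pd.DataFrame, path, config: Optional[RunConfig] = None,
                index: bool = False) -> None:
    """Write any result table as TSV with a commented config header."""
    with open(path, "w") as fh:
        _write_header(fh, config)
        df.to_csv(fh, sep="\t", index=index)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_results(tables: dict, out_dir, config: Optional[RunConfig] = None) -> dict:
    """Write a dict of name -> DataFrame to ``out_dir`` as TSV files."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        path = os.path.join(out_dir, f"{name}.tsv")
        write_table(df, path, config)
        paths[name] = path
    return paths
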
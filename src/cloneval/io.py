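"""Readers and writers for the plain-text formats the pipeline exchanges.

Dosage matrices are tab-delimited, individuals x markers, with "NA" for a
missing call.  Phenotypes and pedigrees travel as CSV ("0" marks an
unknown parent).  Relationship matrices persist as an (i, j, value)
triplet file whose header records the individual order.  Row/column field
coordinates are 1-based in every file format.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .pedigree import Pedigree
from .relmat import RelationshipMatrix

__all__ = [
    "read_genotypes",
    "write_dosage_matrix",
    "read_dosage_matrix",
    "read_vcf",
    "write_vcf",
    "read_phenotypes",
    "write_phenotypes",
    "read_pedigree",
    "write_pedigree",
    "write_matrix_triplet",
    "read_matrix_triplet",
    "write_json",
    "config_hash",
]

PathLike = Union[str, Path]


# ----------------------------------------------------------------------
# dosage matrices
# ----------------------------------------------------------------------
def write_dosage_matrix(g: GenotypeMatrix, path: PathLike) -> None:
    """Write a dosage TSV; allele labels go to a `<path>.alleles` sidecar."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample\t" + "\t".join(str(m) for m in g.markers) + "\n")
        for i, s in enumerate(g.samples):
            row = [
                "NA" if not np.isfinite(v) else str(int(v)) for v in g.dosages[i]
            ]
            fh.write(str(s) + "\t" + "\t".join(row) + "\n")
    if g.alleles is not None:
        with Path(str(path) + ".alleles").open("w") as fh:
            fh.write("marker\tcounted\tother\n")
            for m, (a1, a2) in zip(g.markers, g.alleles):
                fh.write(f"{m}\t{a1}\t{a2}\n")


def read_dosage_matrix(path: PathLike) -> GenotypeMatrix:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ValueError(f"{path}: header must contain marker identifiers")
        markers = header[1:]
        samples: List[str] = []
        rows: List[List[float]] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(markers) + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected {len(markers) + 1} fields, got {len(parts)}"
                )
            samples.append(parts[0])
            try:
                rows.append(
                    [np.nan if v in ("NA", "") else float(v) for v in parts[1:]]
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed dosage ({exc})") from None
    alleles = None
    sidecar = Path(str(path) + ".alleles")
    if sidecar.exists():
        table = {}
        with sidecar.open() as fh:
            fh.readline()
            for line in fh:
                m, a1, a2 = line.rstrip("\n").split("\t")
                table[m] = (a1, a2)
        if set(markers) <= set(table):
            alleles = np.array([table[m] for m in markers], dtype=object)
    return GenotypeMatrix(np.array(rows, dtype=float), samples, markers, alleles)


def read_genotypes(path: PathLike, format: str = "dosage-matrix") -> GenotypeMatrix:
    """Read genotypes as a dosage matrix or a (biallelic-SNP) VCF."""
    if format == "dosage-matrix":
        return read_dosage_matrix(path)
    if format == "vcf":
        return read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


# ----------------------------------------------------------------------
# VCF
# ----------------------------------------------------------------------
def read_vcf(path: PathLike) -> GenotypeMatrix:
    """Dosages from a VCF by counting alternate alleles per genotype.

    Non-biallelic records are skipped (with a count reported via logging);
    missing genotypes (./.) become NaN.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    markers: List[str] = []
    alleles: List[Tuple[str, str]] = []
    columns: List[np.ndarray] = []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        gts = var.genotype.array()
        calls = gts[:, :2].astype(float)
        calls[calls < 0] = np.nan
        dos = calls.sum(axis=1)
        columns.append(dos)
        markers.append(var.ID or f"{var.CHROM}_{var.POS}")
        alleles.append((var.ALT[0], var.REF))
    vcf.close()
    if skipped:
        import logging

        logging.getLogger(__name__).info("skipped %d non-biallelic VCF records", skipped)
    if not columns:
        raise ValueError(f"{path}: no biallelic records found")
    dosages = np.column_stack(columns)
    return GenotypeMatrix(dosages, samples, markers, np.array(alleles, dtype=object))


def write_vcf(g: GenotypeMatrix, path: PathLike) -> None:
    """Minimal biallelic VCF with GT fields; alternate allele is the counted one."""
    path = Path(path)
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1"}
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in g.samples)
            + "\n"
        )
        for j, m in enumerate(g.markers):
            if g.alleles is not None:
                alt, ref = g.alleles[j]
            else:
                ref, alt = "A", "B"
            calls = [
                "./." if not np.isfinite(v) else gt_of[int(v)] for v in g.dosages[:, j]
            ]
            fh.write(
                f"1\t{j + 1}\t{m}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


# ----------------------------------------------------------------------
# tables
# ----------------------------------------------------------------------
def write_phenotypes(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, index=False)


def read_phenotypes(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


def write_pedigree(ped: Pedigree, path: PathLike) -> None:
    ped.to_frame().to_csv(path, index=False)


def read_pedigree(path: PathLike) -> Pedigree:
    return Pedigree.from_frame(pd.read_csv(path, dtype=str))


# ----------------------------------------------------------------------
# relationship matrices
# ----------------------------------------------------------------------
def write_matrix_triplet(mat: RelationshipMatrix, path: PathLike) -> None:
    """Plain-text (i, j, value) triplets (lower triangle) with an id header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# kind: " + mat.kind + "\n")
        fh.write("# ids: " + "\t".join(str(i) for i in mat.ids) + "\n")
        n = len(mat.ids)
        for i in range(n):
            for j in range(i + 1):
                v = float(mat.values[i, j])
                if v != 0.0:
                    fh.write(f"{i + 1}\t{j + 1}\t{v!r}\n")


def read_matrix_triplet(path: PathLike) -> RelationshipMatrix:
    path = Path(path)
    with path.open() as fh:
        kind_line = fh.readline().strip()
        ids_line = fh.readline().rstrip("\n")
        if not kind_line.startswith("# kind:") or not ids_line.startswith("# ids:"):
            raise ValueError(f"{path}: missing triplet header")
        kind = kind_line.split(":", 1)[1].strip()
        ids = ids_line.split(":", 1)[1].strip().split("\t")
        n = len(ids)
        values = np.zeros((n, n))
        for lineno, line in enumerate(fh, start=3):
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 'i j value'")
            i, j, v = int(parts[0]) - 1, int(parts[1]) - 1, float(parts[2])
            values[i, j] = v
            values[j, i] = v
    return RelationshipMatrix(values, ids, kind)


# ----------------------------------------------------------------------
# reports
# ----------------------------------------------------------------------
def write_json(obj: Dict, path: PathLike) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")


def config_hash(obj) -> str:
    """Stable short hash of a configuration for run manifests."""
    text = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]
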
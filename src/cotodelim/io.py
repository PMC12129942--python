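"""Readers and writers for the external formats the pipeline touches.

Genotypes come in as VCF (GT field, biallelic, diploid) or as a plain
dosage table; ancestry matrices use the ADMIXTURE ``.Q`` dialect (one
whitespace-separated row of K fractions per individual, sample order
supplied separately); sample maps, trait tables and clade maps are
TSV with a header row.
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (MISSING, AncestryMatrix, CladeMap, GenotypeMatrix,
                        SampleMap, Site, Trait, TraitTable, QUALITATIVE,
                        QUANTITATIVE)


# ---------------------------------------------------------------------
# genotypes

def read_genotype_matrix(path: str | os.PathLike,
                         multiallelic: str = "error") -> GenotypeMatrix:
    """Read a GenotypeMatrix from a VCF or a dosage table.

    Dosage 0/1/2 counts alternate alleles; ``./.`` becomes MISSING.
    ``multiallelic`` is ``"error"`` (reject the file) or ``"skip"``
    (drop multiallelic records).
    """
    path = os.fspath(path)
    if path.endswith(".vcf") or path.endswith(".vcf.gz"):
        return _read_vcf(path, multiallelic)
    return read_dosage_table(path)


def _read_vcf(path: str, multiallelic: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids in VCF header")
    sites: list[Site] = []
    rows: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            if multiallelic == "skip":
                continue
            raise ValueError(
                f"multiallelic record at {var.CHROM}:{var.POS}")
        dos = np.empty(len(samples), dtype=np.int16)
        for i, gt in enumerate(var.genotypes):
            alleles = gt[:-1]
            if len(alleles) != 2:
                raise ValueError(
                    f"non-diploid GT for sample {samples[i]!r} at "
                    f"{var.CHROM}:{var.POS}")
            if alleles[0] < 0 or alleles[1] < 0:
                dos[i] = MISSING
            else:
                dos[i] = int(alleles[0] == 1) + int(alleles[1] == 1)
        sites.append(Site(var.CHROM, var.POS, var.REF, var.ALT[0]))
        rows.append(dos)
    dosages = (np.stack(rows, axis=1) if rows
               else np.empty((len(samples), 0), dtype=np.int16))
    return GenotypeMatrix(samples, sites, dosages)


def read_dosage_table(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a TSV dosage table: rows = samples, columns = ``chrom:pos``."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    sites = []
    for col in df.columns:
        chrom, pos = col.rsplit(":", 1)
        sites.append(Site(chrom, int(pos)))
    dosages = df.to_numpy(dtype=float)
    dosages = np.where(np.isnan(dosages), MISSING, dosages).astype(np.int16)
    return GenotypeMatrix(list(df.index.astype(str)), sites, dosages)


def write_dosage_table(G: GenotypeMatrix, path: str | os.PathLike) -> None:
    cols = [f"{s.chrom}:{s.pos}" for s in G.sites]
    df = pd.DataFrame(G.dosages.astype(float), index=G.samples, columns=cols)
    df = df.mask(df == MISSING)
    df.to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------
# ancestry

def read_ancestry_matrix(q_path: str | os.PathLike,
                         samples: Sequence[str],
                         meta: Mapping[str, object] | None = None
                         ) -> AncestryMatrix:
    """Read an ADMIXTURE-style .Q file against an ordered sample list.

    Rows whose sum deviates from 1 by at most 1e-3 are renormalized;
    larger deviations are an error, as are negative fractions.
    """
    q = np.loadtxt(q_path, ndmin=2)
    if q.shape[0] != len(samples):
        raise ValueError(
            f".Q file has {q.shape[0]} rows for {len(samples)} samples")
    if (q < 0).any():
        raise ValueError("negative ancestry fraction in .Q file")
    sums = q.sum(axis=1)
    bad = np.abs(sums - 1.0) > 1e-3
    if bad.any():
        i = int(np.argmax(bad))
        raise ValueError(
            f".Q row {i} sums to {sums[i]:.4f} (|sum-1| > 1e-3)")
    q = q / sums[:, None]
    return AncestryMatrix(samples, q, meta)


def write_ancestry_matrix(Q: AncestryMatrix, path: str | os.PathLike) -> None:
    np.savetxt(path, Q.q, fmt="%.6f")


# ---------------------------------------------------------------------
# trait tables

def read_trait_table(path: str | os.PathLike,
                     schema: Sequence[Trait]) -> TraitTable:
    """Read a delimited trait table; empty cells become MISSING (NaN)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    names = [t.name for t in schema]
    missing = set(names) - set(df.columns)
    if missing:
        raise ValueError(f"trait table missing column(s) {sorted(missing)}")
    return TraitTable(df[names], schema)


def write_trait_table(T: TraitTable, path: str | os.PathLike) -> None:
    T.values.to_csv(path, sep="\t", index_label="unit")


def schema_from_records(records: Sequence[tuple]) -> list[Trait]:
    """Build a trait schema from (name, kind, unit-or-states) tuples."""
    out = []
    for name, kind, extra in records:
        if kind == QUANTITATIVE:
            out.append(Trait(name, kind, unit=extra))
        else:
            states = frozenset(int(s) for s in extra) if extra else None
            out.append(Trait(name, QUALITATIVE, states=states))
    return out


# ---------------------------------------------------------------------
# sample maps and clade maps

def read_sample_map(path: str | os.PathLike) -> SampleMap:
    # keep_default_na=False: clade/series labels like "NA" are data here
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "series" not in df.columns:
        df["series"] = None
    return SampleMap(df)


def write_sample_map(M: SampleMap, path: str | os.PathLike) -> None:
    M.table.to_csv(path, sep="\t", index=False)


def read_clade_map(path: str | os.PathLike) -> CladeMap:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return CladeMap(dict(zip(df["population"], df["clade"])))


def write_clade_map(C: CladeMap, path: str | os.PathLike) -> None:
    df = pd.DataFrame(sorted(C.assignments.items()),
                      columns=["population", "clade"])
    df.to_csv(path, sep="\t", index=False)
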
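"""Readers, writers and validated in-memory containers for the file formats the tool touches.

Genotypes travel as PLINK text ``.ped``/``.map`` pairs; phenotypes and
pedigrees as whitespace-delimited tables.  All joins downstream are by
individual id, never by row order.  Coordinates are 1-based base pairs and
region spans are closed intervals, following the PLINK convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = np.nan

__all__ = [
    "FormatError",
    "GenotypeMatrix",
    "MarkerMap",
    "PhenotypeTable",
    "Pedigree",
    "read_plink_text",
    "write_plink_text",
    "read_phenotypes",
    "write_phenotypes",
    "read_pedigree",
    "write_pedigree",
    "read_grm_text",
    "write_grm_text",
    "align_by_id",
]


class FormatError(ValueError):
    """A file violates the expected on-disk format."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Additive allele counts, individuals x SNPs.

    ``codes`` holds values in {0, 1, 2} with NaN for missing.  Column j
    counts copies of the minor allele of SNP j (orientation is fixed at
    load time so relationship matrices are reproducible regardless of
    allele labelling in the source file).
    """

    individual_ids: np.ndarray
    snp_ids: np.ndarray
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.codes = np.asarray(self.codes, dtype=float)
        n, m = self.codes.shape
        if n != self.individual_ids.size:
            raise ValueError("row count does not match number of individual ids")
        if m != self.snp_ids.size:
            raise ValueError("column count does not match number of snp ids")
        ok = np.isnan(self.codes) | np.isin(self.codes, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("genotype codes must be 0, 1, 2 or missing")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def subset_individuals(self, ids: Sequence) -> "GenotypeMatrix":
        pos = {v: i for i, v in enumerate(self.individual_ids)}
        idx = np.array([pos[v] for v in ids], dtype=int)
        return GenotypeMatrix(np.asarray(ids, dtype=object), self.snp_ids,
                              self.codes[idx])


@dataclass
class MarkerMap:
    """SNP id, chromosome label and 1-based bp position, in column order of the genotype matrix."""

    snp_id: np.ndarray
    chromosome: np.ndarray
    position_bp: np.ndarray

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        if not (self.snp_id.size == self.chromosome.size == self.position_bp.size):
            raise ValueError("marker map columns must have equal length")
        if pd.Index(self.snp_id).has_duplicates:
            raise ValueError("snp ids must be unique")
        for chrom in pd.unique(self.chromosome):
            pos = self.position_bp[self.chromosome == chrom]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}")

    @property
    def n_snps(self) -> int:
        return self.snp_id.size

    def chromosomes(self) -> list:
        return list(pd.unique(self.chromosome))

    def chrom_indices(self, chrom) -> np.ndarray:
        """Column indices (0-based, map order) of the SNPs on one chromosome."""
        return np.flatnonzero(self.chromosome == chrom)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"snp_id": self.snp_id,
                             "chromosome": self.chromosome,
                             "position_bp": self.position_bp})


@dataclass
class PhenotypeTable:
    """Trait records keyed by individual id; NaN marks a missing record."""

    data: pd.DataFrame  # index: individual id; columns: trait names

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise FormatError("duplicate individual ids in phenotype table")

    @property
    def individual_ids(self) -> np.ndarray:
        return self.data.index.to_numpy(dtype=object)

    @property
    def trait_names(self) -> list[str]:
        return list(self.data.columns)

    def trait(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise FormatError(f"trait {name!r} not present")
        return self.data[name]


@dataclass
class Pedigree:
    """Topologically ordered pedigree: parents always precede offspring.

    Unknown parents are ``None``.  ``generation`` is optional bookkeeping
    from the simulator; it is not required for the relationship matrix.
    """

    individual_ids: np.ndarray
    sire: np.ndarray  # parent id or None
    dam: np.ndarray
    generation: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.sire = np.asarray(self.sire, dtype=object)
        self.dam = np.asarray(self.dam, dtype=object)
        if pd.Index(self.individual_ids).has_duplicates:
            raise FormatError("duplicate ids in pedigree")
        seen: set = set()
        for i, ind in enumerate(self.individual_ids):
            for par in (self.sire[i], self.dam[i]):
                if par is not None and par not in seen:
                    raise ValueError(
                        "pedigree not topologically ordered; use Pedigree.from_records")
            seen.add(ind)

    def __len__(self) -> int:
        return self.individual_ids.size

    @classmethod
    def from_records(cls, ids, sires, dams, generation=None) -> "Pedigree":
        """Validate and topologically sort raw pedigree records.

        Parents that never appear as individuals are auto-added as founders
        (with a warning); a cycle raises :class:`FormatError`.
        """
        ids = [str(v) for v in ids]
        norm = lambda v: None if v is None or str(v) in ("0", "", "nan", "NA") else str(v)
        sires = [norm(v) for v in sires]
        dams = [norm(v) for v in dams]
        known = set(ids)
        extra = [p for p in dict.fromkeys(s for s in sires + dams if s is not None)
                 if p not in known]
        if extra:
            logger.warning("%d parent ids not defined as individuals; added as founders",
                           len(extra))
        all_ids = extra + ids
        parent_of = {i: [] for i in all_ids}
        gen_map = {}
        if generation is not None:
            gen_map = dict(zip(ids, generation))
        for i, s, d in zip(ids, sires, dams):
            parent_of[i] = [p for p in (s, d) if p is not None]
        ts = TopologicalSorter(parent_of)
        try:
            order = list(ts.static_order())
        except CycleError as exc:
            raise FormatError(f"pedigree contains a cycle: {exc.args[1]}") from exc
        rec = {i: (s, d) for i, s, d in zip(ids, sires, dams)}
        sire_o = [rec.get(i, (None, None))[0] for i in order]
        dam_o = [rec.get(i, (None, None))[1] for i in order]
        gen_o = None
        if gen_map:
            gen_o = np.array([gen_map.get(i, 0) for i in order])
        return cls(np.array(order, dtype=object),
                   np.array(sire_o, dtype=object),
                   np.array(dam_o, dtype=object),
                   gen_o)


# ---------------------------------------------------------------------------
# PLINK text
# ---------------------------------------------------------------------------


def read_plink_text(ped_path, map_path) -> tuple[GenotypeMatrix, MarkerMap]:
    """Read a PLINK text ``.ped``/``.map`` pair into minor-allele counts.

    The ``.map`` must have 4 columns (chromosome, snp id, cM, bp); each
    ``.ped`` line has 6 leading columns then two alleles per SNP.  ``0 0``
    is the missing genotype.  For each SNP the counted allele is the minor
    one (ties broken toward the lexicographically smaller label).
    """
    mp = pd.read_csv(map_path, sep=r"\s+", header=None, dtype=str)
    if mp.shape[1] != 4:
        raise FormatError(f"{map_path}: expected 4 columns in .map, got {mp.shape[1]}")
    mmap = MarkerMap(mp[1].to_numpy(), mp[0].to_numpy(),
                     mp[3].astype(np.int64).to_numpy())
    m = mmap.n_snps

    ids = []
    allele_rows = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6 + 2 * m:
                raise FormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} fields "
                    f"(2 alleles for each of {m} SNPs), got {len(tok)}")
            ids.append(tok[1])
            allele_rows.append(np.array(tok[6:], dtype="U8"))
    alleles = np.array(allele_rows)  # n x 2m
    n = alleles.shape[0]
    codes = np.full((n, m), np.nan)
    a1 = alleles[:, 0::2]
    a2 = alleles[:, 1::2]
    for j in range(m):
        col1, col2 = a1[:, j], a2[:, j]
        miss = (col1 == "0") | (col2 == "0")
        labels, counts = np.unique(
            np.concatenate([col1[~miss], col2[~miss]]), return_counts=True)
        if labels.size > 2:
            raise FormatError(
                f"SNP {mmap.snp_id[j]} has {labels.size} alleles; biallelic required")
        if labels.size == 0:
            continue  # fully missing column
        if labels.size == 1:
            minor = None  # monomorphic: count the absent allele -> all zeros
            codes[:, j] = 0.0
        else:
            order = np.lexsort((labels, counts))  # minor first, label tie-break
            minor = labels[order[0]]
            codes[:, j] = (col1 == minor).astype(float) + (col2 == minor)
        codes[miss, j] = np.nan
    return GenotypeMatrix(np.array(ids, dtype=object), mmap.snp_id, codes), mmap


def write_plink_text(genotypes: GenotypeMatrix, mmap: MarkerMap, prefix) -> None:
    """Write ``<prefix>.ped`` and ``<prefix>.map`` (alleles labelled 1/2, code = count of allele 2)."""
    prefix = str(prefix)
    with open(prefix + ".map", "w") as fh:
        for j in range(mmap.n_snps):
            cm = mmap.position_bp[j] / 1_000_000  # 1 cM/Mb convention
            fh.write(f"{mmap.chromosome[j]}\t{mmap.snp_id[j]}\t{cm:.6f}\t{mmap.position_bp[j]}\n")
    pair = {0.0: "1 1", 1.0: "1 2", 2.0: "2 2"}
    with open(prefix + ".ped", "w") as fh:
        for i, ind in enumerate(genotypes.individual_ids):
            lead = f"FAM {ind} 0 0 2 -9"
            row = genotypes.codes[i]
            geno = " ".join("0 0" if np.isnan(c) else pair[c] for c in row)
            fh.write(lead + " " + geno + "\n")


# ---------------------------------------------------------------------------
# phenotypes / pedigree tables
# ---------------------------------------------------------------------------


def read_phenotypes(path, trait_names: Sequence[str] | None = None) -> PhenotypeTable:
    df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
    if df.columns[0].lower() not in ("id", "iid", "individual_id"):
        raise FormatError(f"{path}: first column must be the individual id")
    df[df.columns[0]] = df[df.columns[0]].astype(str)  # ids join as strings
    df = df.set_index(df.columns[0])
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate individual ids")
    if trait_names is not None:
        missing = [t for t in trait_names if t not in df.columns]
        if missing:
            raise FormatError(f"{path}: requested trait(s) absent: {missing}")
        df = df[list(trait_names)]
    return PhenotypeTable(df.astype(float))


def write_phenotypes(table: PhenotypeTable, path) -> None:
    df = table.data.copy()
    df.index.name = "id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g")


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    if df.shape[1] < 3:
        raise FormatError(f"{path}: pedigree needs >= 3 columns (id, sire, dam)")
    gen = df.iloc[:, 3] if df.shape[1] > 3 else None
    return Pedigree.from_records(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2],
                                 None if gen is None else gen.astype(int).to_numpy())


def write_pedigree(ped: Pedigree, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tsire\tdam\tgeneration\n")
        gen = ped.generation if ped.generation is not None else np.zeros(len(ped), int)
        for i in range(len(ped)):
            s = ped.sire[i] or "0"
            d = ped.dam[i] or "0"
            fh.write(f"{ped.individual_ids[i]}\t{s}\t{d}\t{gen[i]}\n")


# ---------------------------------------------------------------------------
# relationship-matrix text format (lower triangle, 10 significant digits)
# ---------------------------------------------------------------------------


def write_grm_text(ids, values: np.ndarray, prefix) -> None:
    prefix = Path(prefix)
    ids = np.asarray(ids, dtype=object)
    n = ids.size
    with open(str(prefix) + ".grm.id", "w") as fh:
        for v in ids:
            fh.write(f"{v}\n")
    with open(str(prefix) + ".grm.txt", "w") as fh:
        for i in range(n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{values[i, j]:.10g}\n")


def read_grm_text(prefix) -> tuple[np.ndarray, np.ndarray]:
    prefix = Path(prefix)
    with open(str(prefix) + ".grm.id") as fh:
        ids = np.array([line.strip() for line in fh if line.strip()], dtype=object)
    n = ids.size
    vals = np.zeros((n, n))
    with open(str(prefix) + ".grm.txt") as fh:
        for line in fh:
            i, j, v = line.split()
            i, j = int(i) - 1, int(j) - 1
            vals[i, j] = vals[j, i] = float(v)
    return ids, vals


def align_by_id(genotypes: GenotypeMatrix, pheno: PhenotypeTable, trait: str
                ) -> tuple[np.ndarray, GenotypeMatrix]:
    """Inner-join one trait with the genotypes by individual id.

    Returns the phenotype vector and the row-subset genotype matrix in a
    common id order.  Individuals missing either side are dropped with a
    logged count (per-trait, not globally).
    """
    y = pheno.trait(trait).dropna()
    common = [i for i in genotypes.individual_ids if i in y.index]
    dropped = genotypes.n_individuals - len(common) + (y.size - len(common))
    if dropped:
        logger.info("align_by_id: dropped %d unmatched/missing records for trait %s",
                    dropped, trait)
    if not common:
        raise ValueError(f"no individuals with both genotype and trait {trait!r}")
    return y.loc[common].to_numpy(float), genotypes.subset_individuals(common)
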
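"""Genotype data model and EIGENSTRAT-style I/O.

The central container is :class:`GenotypeDataset`: an individuals x SNPs
matrix of alternate-allele counts in {0, 1, 2, MISSING}, an ordered SNP table
(chromosome, genetic position in Morgans, physical position in base pairs,
alleles), and an ordered individual table (id, sex, group label, optional
cemetery and calibrated date midpoint).

Pseudo-haploid data — one randomly sampled read standing in for the diploid
genotype — is represented on the same {0, 2} scale with a dataset-level
``ploidy`` flag, so a single code path serves both ploidies; the flag only
controls how many allele "slots" a called genotype contributes to frequency
estimation (1 for pseudo-haploid, 2 for diploid).

File dialect: plain-text EIGENSTRAT geno/snp/ind triples. Genetic positions
in the .snp file are read as Morgans (the convention of the ancestral
toolchain); no unit auto-detection is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = 9
"""Sentinel genotype value for a no-call (matches the '9' file encoding)."""

AUTOSOMES = tuple(str(c) for c in range(1, 23))
X_CHROM = "23"

SNP_COLUMNS = ["snp_id", "chromosome", "genetic_pos", "physical_pos", "ref", "alt"]
IND_COLUMNS = ["individual_id", "sex", "group"]
META_COLUMNS = [
    "individual_id", "sex", "group", "cemetery", "date_midpoint_ce", "exclude",
]


class EigenstratParseError(ValueError):
    """Structured parse failure naming the offending file and line."""

    def __init__(self, path, line, message):
        self.path = str(path)
        self.line = line
        super().__init__(f"{path}:{line}: {message}")


@dataclass
class GenotypeDataset:
    """Individuals x SNPs genotype matrix with SNP and individual metadata.

    Parameters
    ----------
    genotypes : ndarray of shape (n_individuals, n_snps), dtype int8
        Alternate-allele counts; 9 encodes a missing call. A pseudo-haploid
        dataset contains only {0, 2, 9}.
    snps : DataFrame with columns ``snp_id, chromosome, genetic_pos,
        physical_pos, ref, alt``; genetic positions in Morgans.
    individuals : DataFrame with at least ``individual_id, sex, group``;
        optionally ``cemetery``, ``date_midpoint_ce``, ``exclude``.
    ploidy : "pseudohaploid" or "diploid"
        Controls slot counting in allele-frequency estimation.
    """

    genotypes: np.ndarray
    snps: pd.DataFrame
    individuals: pd.DataFrame
    ploidy: str = "pseudohaploid"

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotype matrix must be 2-D (individuals x SNPs)")
        n_ind, n_snp = self.genotypes.shape
        if len(self.individuals) != n_ind:
            raise ValueError(
                f"{len(self.individuals)} individual records for a matrix "
                f"with {n_ind} rows"
            )
        if len(self.snps) != n_snp:
            raise ValueError(
                f"{len(self.snps)} SNP records for a matrix with {n_snp} columns"
            )
        if self.ploidy not in ("pseudohaploid", "diploid"):
            raise ValueError(f"unknown ploidy {self.ploidy!r}")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype values must be in {0, 1, 2, 9}")
        if self.ploidy == "pseudohaploid" and (self.genotypes == 1).any():
            raise ValueError("pseudo-haploid dataset contains heterozygous calls")
        ids = self.individuals["individual_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate individual_id {dup!r}")
        self.snps = self.snps.reset_index(drop=True)
        self.individuals = self.individuals.reset_index(drop=True)

    # -- basic views ------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def group_indices(self, group: str) -> np.ndarray:
        idx = np.flatnonzero(self.individuals["group"].to_numpy() == group)
        if idx.size == 0:
            raise KeyError(f"no individuals with group label {group!r}")
        return idx

    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.individuals["group"]))

    def subset_individuals(self, index) -> "GenotypeDataset":
        index = np.asarray(index)
        return replace(
            self,
            genotypes=self.genotypes[index],
            individuals=self.individuals.iloc[index].reset_index(drop=True),
            snps=self.snps,
        )

    def subset_snps(self, index) -> "GenotypeDataset":
        index = np.asarray(index)
        return replace(
            self,
            genotypes=self.genotypes[:, index],
            snps=self.snps.iloc[index].reset_index(drop=True),
            individuals=self.individuals,
        )


# -- EIGENSTRAT I/O -------------------------------------------------------

_SEX_IN = {"M": "male", "F": "female", "U": "unknown"}
_SEX_OUT = {"male": "M", "female": "F", "unknown": "U"}


def read_eigenstrat(prefix_or_geno, snp_path=None, ind_path=None,
                    ploidy: str = "pseudohaploid") -> GenotypeDataset:
    """Read a plain-text EIGENSTRAT geno/snp/ind triple.

    Accepts either a shared path prefix (``prefix`` -> ``prefix.geno`` etc.)
    or the three explicit paths. Character '9' maps to MISSING; individual
    and SNP order is preserved.
    """
    if snp_path is None and ind_path is None:
        prefix = str(prefix_or_geno)
        geno_path, snp_path, ind_path = (
            prefix + ".geno", prefix + ".snp", prefix + ".ind")
    else:
        geno_path = prefix_or_geno

    snps = _read_snp(snp_path)
    individuals = _read_ind(ind_path)
    n_ind = len(individuals)

    rows = []
    with open(geno_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if len(line) != n_ind:
                raise EigenstratParseError(
                    geno_path, lineno,
                    f"row has {len(line)} genotypes but .ind lists "
                    f"{n_ind} individuals")
            try:
                rows.append(np.frombuffer(line.encode(), dtype=np.uint8) - ord("0"))
            except ValueError as exc:  # pragma: no cover - frombuffer rarely fails
                raise EigenstratParseError(geno_path, lineno, str(exc))
            codes = rows[-1]
            bad = ~np.isin(codes, (0, 1, 2, 9))
            if bad.any():
                raise EigenstratParseError(
                    geno_path, lineno,
                    f"unknown genotype character {line[int(np.flatnonzero(bad)[0])]!r}")
    if len(rows) != len(snps):
        raise EigenstratParseError(
            geno_path, len(rows),
            f".geno has {len(rows)} rows but .snp lists {len(snps)} SNPs")
    if rows:
        matrix = np.vstack(rows).T.astype(np.int8)  # -> individuals x SNPs
    else:
        matrix = np.zeros((n_ind, 0), dtype=np.int8)
    return GenotypeDataset(matrix, snps, individuals, ploidy=ploidy)


def _read_snp(path) -> pd.DataFrame:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise EigenstratParseError(path, lineno, "expected >=4 columns")
            ref, alt = (parts[4], parts[5]) if len(parts) >= 6 else ("A", "G")
            records.append((parts[0], parts[1], float(parts[2]),
                            int(parts[3]), ref, alt))
    return pd.DataFrame(records, columns=SNP_COLUMNS)


def _read_ind(path) -> pd.DataFrame:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 3:
                raise EigenstratParseError(path, lineno, "expected 3 columns")
            sex = _SEX_IN.get(parts[1].upper())
            if sex is None:
                raise EigenstratParseError(path, lineno,
                                           f"unknown sex code {parts[1]!r}")
            records.append((parts[0], sex, parts[2]))
    return pd.DataFrame(records, columns=IND_COLUMNS)


def write_eigenstrat(dataset: GenotypeDataset, out_prefix) -> tuple[str, str, str]:
    """Write ``dataset`` as a plain-text EIGENSTRAT triple.

    Returns the (geno, snp, ind) paths. MISSING serializes as '9';
    a round trip through :func:`read_eigenstrat` reproduces the dataset.
    """
    out_prefix = str(out_prefix)
    Path(out_prefix).parent.mkdir(parents=True, exist_ok=True)
    geno_path, snp_path, ind_path = (
        out_prefix + ".geno", out_prefix + ".snp", out_prefix + ".ind")

    codes = dataset.genotypes.T + ord("0")  # SNPs x individuals
    with open(geno_path, "wb") as fh:
        for row in codes.astype(np.uint8):
            fh.write(row.tobytes() + b"\n")
    with open(snp_path, "w") as fh:
        for rec in dataset.snps.itertuples(index=False):
            fh.write(f"{rec.snp_id}\t{rec.chromosome}\t{rec.genetic_pos:.8f}"
                     f"\t{rec.physical_pos}\t{rec.ref}\t{rec.alt}\n")
    with open(ind_path, "w") as fh:
        for rec in dataset.individuals.itertuples(index=False):
            fh.write(f"{rec.individual_id}\t{_SEX_OUT[rec.sex]}\t{rec.group}\n")
    return geno_path, snp_path, ind_path


def read_metadata(path) -> pd.DataFrame:
    """Read the individual metadata sidecar TSV.

    Columns: individual_id, sex, group, cemetery, date_midpoint_ce, exclude.
    """
    meta = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    missing = set(META_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"metadata file {path} lacks columns {sorted(missing)}")
    meta["exclude"] = meta["exclude"].astype(bool)
    return meta


def attach_metadata(dataset: GenotypeDataset, meta: pd.DataFrame) -> GenotypeDataset:
    """Join sidecar metadata onto the dataset's individual table by id."""
    merged = dataset.individuals[["individual_id", "sex", "group"]].merge(
        meta.drop(columns=["sex", "group"], errors="ignore"),
        on="individual_id", how="left", validate="one_to_one")
    return replace(dataset, individuals=merged)


# -- frequencies and compartments ----------------------------------------

def allele_frequencies(dataset: GenotypeDataset, group=None,
                       indices=None) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP alternate-allele frequency and allele-slot count for a group.

    A called pseudo-haploid genotype contributes 1 slot, a called diploid
    genotype 2 slots; frequency = (sum of alt counts, on the slot scale) /
    slots. SNPs with zero slots get frequency NaN (the "flagged" state).

    Either a ``group`` label or an explicit array of row ``indices`` may be
    given.
    """
    if indices is None:
        indices = dataset.group_indices(group)
    sub = dataset.genotypes[np.asarray(indices)]
    called = sub != MISSING
    if dataset.ploidy == "pseudohaploid":
        # calls live on {0,2}; one slot each, alt contribution 0 or 1
        alt = (sub == 2).sum(axis=0).astype(float)
        slots = called.sum(axis=0).astype(float)
    else:
        alt = np.where(called, sub, 0).sum(axis=0).astype(float)
        slots = 2.0 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(slots > 0, alt / np.maximum(slots, 1), np.nan)
    return freq, slots


def partition_compartments(dataset: GenotypeDataset,
                           ) -> dict[str, GenotypeDataset]:
    """Split into autosomal (chr 1-22) and X (chr "23") datasets.

    Y/mtDNA SNPs, if present, are dropped with a logged warning: uniparental
    analyses consume haplogroup tables, not SNP matrices.
    """
    chrom = dataset.snps["chromosome"].astype(str).to_numpy()
    auto_mask = np.isin(chrom, AUTOSOMES)
    x_mask = chrom == X_CHROM
    dropped = int((~auto_mask & ~x_mask).sum())
    if dropped:
        logger.warning("dropping %d SNPs outside chromosomes 1-23", dropped)
    return {
        "autosomes": dataset.subset_snps(np.flatnonzero(auto_mask)),
        "X": dataset.subset_snps(np.flatnonzero(x_mask)),
    }
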
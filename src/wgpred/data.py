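"""Core data containers for genotypes, pedigrees and phenotypes.

Genotypes are stored as allele counts (0/1/2) in a dense integer matrix
with ``-1`` marking missing calls.  Pedigrees and phenotypes are thin
wrappers around :class:`pandas.DataFrame` with a fixed column contract,
so they interoperate directly with pandas/statsmodels workflows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: column contract for pedigree tables
PEDIGREE_COLUMNS = ["individual_id", "sire_id", "dam_id", "sex", "generation", "cohort"]

#: column contract for phenotype tables
PHENOTYPE_COLUMNS = ["individual_id", "height", "sex", "age", "true_genetic_value", "adjusted_height"]


class PanelMismatchError(ValueError):
    """Raised when two genotype panels do not share the same marker set."""


@dataclass
class GenotypeMatrix:
    """n individuals x p markers allele-count matrix.

    Parameters
    ----------
    ids : array of str
        Individual identifiers (row labels).
    counts : (n, p) int array
        Allele counts in {0, 1, 2}; ``-1`` encodes a missing call.
    marker_ids : array of str
        Marker identifiers (column labels), in map order.
    """

    ids: np.ndarray
    counts: np.ndarray
    marker_ids: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.counts = np.asarray(self.counts)
        n, p = self.counts.shape
        if n != len(self.ids) or p != len(self.marker_ids):
            raise ValueError("counts shape does not match ids/marker_ids")
        valid = (self.counts == MISSING) | ((self.counts >= 0) & (self.counts <= 2))
        if not valid.all():
            raise ValueError("genotype entries must be in {0,1,2} or -1 (missing)")

    @property
    def n_individuals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_markers(self) -> int:
        return self.counts.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.counts == MISSING

    def call_rate(self) -> np.ndarray:
        """Per-marker fraction of non-missing calls."""
        return 1.0 - self.missing_mask.mean(axis=0)

    def allele_frequency(self) -> np.ndarray:
        """Per-marker empirical frequency of the counted allele.

        Computed from non-missing calls only.  Markers with no calls get NaN.
        """
        obs = ~self.missing_mask
        n_obs = obs.sum(axis=0)
        totals = np.where(obs, self.counts, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_obs > 0, totals / (2.0 * n_obs), np.nan)

    def minor_allele_frequency(self) -> np.ndarray:
        """Per-marker MAF: counted-allele frequency folded onto (0, 0.5]."""
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)

    def subset_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.ids, self.counts[:, index], self.marker_ids[index])

    def subset_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.ids[index], self.counts[index, :], self.marker_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.ids, columns=self.marker_ids)


@dataclass
class Pedigree:
    """Two-generation pedigree: founders (generation 0) and offspring.

    The underlying frame has columns ``individual_id, sire_id, dam_id,
    sex, generation, cohort``; parent links are None for founders, sex is
    'M'/'F', and cohort is 'original' or 'offspring'.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(PEDIGREE_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"pedigree table missing columns: {sorted(missing)}")
        self.table = self.table.reset_index(drop=True)
        ids = set(self.table["individual_id"])
        if len(ids) != len(self.table):
            raise ValueError("duplicate individual ids in pedigree")
        for col in ("sire_id", "dam_id"):
            parents = self.table[col].dropna()
            unknown = set(parents) - ids
            if unknown:
                raise ValueError(f"{col} refers to unknown individuals: {sorted(unknown)[:5]}")
        # parents must precede children in generation order
        gen = pd.Series(
            self.table["generation"].to_numpy(), index=self.table["individual_id"]
        )
        child_gen = self.table["generation"].to_numpy()
        for col in ("sire_id", "dam_id"):
            par = self.table[col]
            has = par.notna().to_numpy()
            if has.any():
                par_gen = gen.reindex(par[has]).to_numpy()
                if not (par_gen < child_gen[has]).all():
                    raise ValueError("parent generation must precede child generation")

    @property
    def ids(self) -> np.ndarray:
        return self.table["individual_id"].to_numpy()

    @property
    def founders(self) -> pd.DataFrame:
        return self.table[self.table["generation"] == 0]

    @property
    def offspring(self) -> pd.DataFrame:
        return self.table[self.table["generation"] > 0]

    def parents_of(self, individual_id: str) -> tuple:
        row = self.table.loc[self.table["individual_id"] == individual_id].iloc[0]
        return (row["sire_id"], row["dam_id"])


@dataclass
class PhenotypeTable:
    """Phenotypes: height (cm), sex, age (years), plus the simulation-only
    true genetic value and the adjusted height filled by preprocessing."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(PHENOTYPE_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
        if not np.isfinite(self.table["height"].to_numpy(dtype=float)).all():
            raise ValueError("non-finite heights in phenotype table")
        self.table = self.table.reset_index(drop=True)

    @property
    def ids(self) -> np.ndarray:
        return self.table["individual_id"].to_numpy()

    @property
    def height(self) -> np.ndarray:
        return self.table["height"].to_numpy(dtype=float)

    @property
    def adjusted_height(self) -> np.ndarray:
        return self.table["adjusted_height"].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# File I/O: PLINK .ped/.map text, TSV dialects
# ---------------------------------------------------------------------------

def write_plink(genotypes: GenotypeMatrix, prefix: str, pedigree: Pedigree | None = None) -> None:
    """Write genotypes as PLINK text .ped/.map.

    Allele counts are encoded biallelically with alleles A (reference) and
    B (counted); a count of 1 becomes ``A B``, missing becomes ``0 0``.
    """
    sex_code = {"M": "1", "F": "2"}
    ped_info = {}
    if pedigree is not None:
        for _, row in pedigree.table.iterrows():
            ped_info[row["individual_id"]] = (
                row["sire_id"] or "0",
                row["dam_id"] or "0",
                sex_code.get(row["sex"], "0"),
            )
    allele_pairs = {0: "A A", 1: "A B", 2: "B B", MISSING: "0 0"}
    with open(prefix + ".ped", "w") as fh:
        for i, ind in enumerate(genotypes.ids):
            sire, dam, sex = ped_info.get(ind, ("0", "0", "0"))
            geno = " ".join(allele_pairs[int(c)] for c in genotypes.counts[i])
            fh.write(f"FAM1 {ind} {sire} {dam} {sex} -9 {geno}\n")
    with open(prefix + ".map", "w") as fh:
        for j, marker in enumerate(genotypes.marker_ids):
            fh.write(f"1 {marker} 0 {j + 1}\n")


def read_plink(prefix: str) -> GenotypeMatrix:
    """Read the .ped/.map text dialect written by :func:`write_plink`."""
    marker_ids = []
    with open(prefix + ".map") as fh:
        for line in fh:
            parts = line.split()
            marker_ids.append(parts[1])
    ids, rows = [], []
    count_of = {("A", "A"): 0, ("A", "B"): 1, ("B", "A"): 1, ("B", "B"): 2, ("0", "0"): MISSING}
    with open(prefix + ".ped") as fh:
        for line in fh:
            parts = line.split()
            ids.append(parts[1])
            alleles = parts[6:]
            if len(alleles) != 2 * len(marker_ids):
                raise ValueError("ped/map marker count mismatch")
            rows.append(
                [count_of[(alleles[2 * j], alleles[2 * j + 1])] for j in range(len(marker_ids))]
            )
    return GenotypeMatrix(np.array(ids, dtype=object), np.array(rows, dtype=np.int8),
                          np.array(marker_ids, dtype=object))


def write_genotypes_tsv(genotypes: GenotypeMatrix, path: str) -> None:
    """Plain TSV dialect: rows = individuals, columns = markers, NA = missing."""
    df = genotypes.to_dataframe().astype(object)
    df[genotypes.missing_mask] = pd.NA
    df.to_csv(path, sep="\t", index_label="individual_id", na_rep="NA")


def read_genotypes_tsv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="individual_id")
    counts = df.to_numpy(dtype=float)
    counts = np.where(np.isnan(counts), MISSING, counts).astype(np.int8)
    return GenotypeMatrix(df.index.to_numpy(dtype=object), counts,
                          df.columns.to_numpy(dtype=object))


def write_pedigree_tsv(pedigree: Pedigree, path: str) -> None:
    pedigree.table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_pedigree_tsv(path: str) -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype={c: object for c in ("individual_id", "sire_id", "dam_id")})
    for col in ("sire_id", "dam_id"):
        df[col] = df[col].where(df[col].notna() & (df[col] != "NA"), None)
    return Pedigree(df)


def write_phenotypes_tsv(phenotypes: PhenotypeTable, path: str) -> None:
    phenotypes.table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes_tsv(path: str) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": object})
    return PhenotypeTable(df)
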
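"""Genotype QC, HWE imputation, marker subsetting and phenotype adjustment.

The QC pipeline follows the standard order: call-rate filter, then MAF
filter computed on non-missing calls (minor-allele oriented), then
binomial imputation of the remaining missing genotypes under
Hardy-Weinberg proportions.  Imputed values never influence the MAF
estimates used for filtering.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import MISSING, GenotypeMatrix, PhenotypeTable


class EmptyPanelError(ValueError):
    """All markers failed QC; downstream models would be vacuous."""


@dataclass
class QCReport:
    n_markers_in: int
    n_failed_callrate: int
    n_failed_maf: int
    n_markers_out: int
    callrate_threshold: float
    maf_threshold: float

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


@dataclass
class AdjustmentModel:
    """OLS fit of height on a male indicator and age; residuals are the
    adjusted heights carried into the genomic models."""

    intercept: float
    sex_coefficient: float
    age_coefficient: float
    residual_sd: float
    dropped_terms: tuple = ()

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "intercept": self.intercept,
                    "sex_coefficient": self.sex_coefficient,
                    "age_coefficient": self.age_coefficient,
                    "residual_sd": self.residual_sd,
                    "dropped_terms": list(self.dropped_terms),
                },
                fh,
                indent=2,
            )


def filter_markers(
    genotypes: GenotypeMatrix,
    callrate_threshold: float = 0.90,
    maf_threshold: float = 0.03,
) -> tuple[GenotypeMatrix, QCReport]:
    """Exclude markers with call rate below 90% or MAF below 3% (defaults).

    A marker failing both screens is tallied in both failure classes but
    removed once.  Raises :class:`EmptyPanelError` if nothing survives.
    """
    if not (0.0 < callrate_threshold < 1.0 and 0.0 < maf_threshold < 1.0):
        raise ValueError("thresholds must lie in (0, 1)")
    callrate = genotypes.call_rate()
    maf = genotypes.minor_allele_frequency()
    fail_cr = callrate < callrate_threshold
    fail_maf = np.isnan(maf) | (maf < maf_threshold)
    keep = ~(fail_cr | fail_maf)
    report = QCReport(
        n_markers_in=genotypes.n_markers,
        n_failed_callrate=int(fail_cr.sum()),
        n_failed_maf=int(fail_maf.sum()),
        n_markers_out=int(keep.sum()),
        callrate_threshold=callrate_threshold,
        maf_threshold=maf_threshold,
    )
    if report.n_markers_out == 0:
        raise EmptyPanelError("all markers failed QC (call-rate or MAF screens)")
    return genotypes.subset_markers(np.flatnonzero(keep)), report


def impute_missing(genotypes: GenotypeMatrix, seed: int = 0) -> GenotypeMatrix:
    """Impute missing calls by sampling Binomial(2, p_hat) under HWE.

    ``p_hat`` is the empirical frequency of the counted allele among
    non-missing calls at each marker.  Observed genotypes are untouched.
    """
    freqs = genotypes.allele_frequency()
    if np.isnan(freqs).any():
        raise ValueError(
            "marker with no non-missing calls: MAF not estimable "
            "(such markers should have been removed by the call-rate filter)"
        )
    rng = np.random.default_rng(seed)
    counts = genotypes.counts.copy()
    mask = genotypes.missing_mask
    if mask.any():
        draws = rng.binomial(2, np.broadcast_to(freqs, counts.shape)[mask])
        counts[mask] = draws.astype(counts.dtype)
    return GenotypeMatrix(genotypes.ids, counts, genotypes.marker_ids)


def subset_evenly_spaced(genotypes: GenotypeMatrix, n_target: int) -> GenotypeMatrix:
    """Select ``n_target`` markers at uniform spacing in map order.

    Uses indices ``floor(j * p / n_target)`` for ``j = 0..n_target-1``,
    e.g. p=10, n_target=5 selects {0, 2, 4, 6, 8}.  Deterministic.
    """
    p = genotypes.n_markers
    if not (1 <= n_target <= p):
        raise ValueError(f"n_target must lie in [1, {p}], got {n_target}")
    idx = np.floor(np.arange(n_target) * p / n_target).astype(int)
    return genotypes.subset_markers(idx)


def adjust_phenotype(
    phenotypes: PhenotypeTable,
) -> tuple[PhenotypeTable, AdjustmentModel]:
    """Regress height on sex and age by OLS; the residual is the adjusted height.

    Constant sex or age columns are dropped from the design (with a
    recorded note) instead of producing a rank-deficient fit.
    """
    df = phenotypes.table
    if df["sex"].isna().any() or df["age"].isna().any():
        raise ValueError("ages and sexes must be non-missing for adjustment")
    y = df["height"].to_numpy(dtype=float)
    male = (df["sex"] == "M").to_numpy(dtype=float)
    age = df["age"].to_numpy(dtype=float)

    dropped = []
    cols = {}
    if np.ptp(male) > 0:
        cols["male"] = male
    else:
        dropped.append("sex")
    if np.ptp(age) > 0:
        cols["age"] = age
    else:
        dropped.append("age")
    X = sm.add_constant(pd.DataFrame(cols, index=df.index) if cols else
                        pd.DataFrame(index=df.index), has_constant="add")
    fit = sm.OLS(y, X).fit()
    residuals = np.asarray(fit.resid)

    model = AdjustmentModel(
        intercept=float(fit.params.get("const", np.nan)),
        sex_coefficient=float(fit.params.get("male", 0.0)),
        age_coefficient=float(fit.params.get("age", 0.0)),
        residual_sd=float(np.sqrt(fit.scale)),
        dropped_terms=tuple(dropped),
    )
    out = df.copy()
    out["adjusted_height"] = residuals
    return PhenotypeTable(out), model


def filter_adults(phenotypes: PhenotypeTable, min_age: float = 18.0) -> PhenotypeTable:
    """Adults-only screen applied before adjustment (default: age >= 18)."""
    df = phenotypes.table
    return PhenotypeTable(df[df["age"] >= min_age].reset_index(drop=True))
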
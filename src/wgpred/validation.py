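"""Validation designs, relatedness scoring and the experiment driver.

Three ways of splitting a cohort into training (TRN) and testing (TST)
sets are supported:

* ``kfold`` — k-fold cross-validation with random fold assignment; every
  individual is tested exactly once and fold sizes differ by at most one.
* ``two_generation`` — train on the founder ("original") cohort, test on
  the offspring cohort; by construction a single replicate.
* ``random_split`` — repeated random TRN/TST splits with the TRN size
  fixed to the founder-cohort size, isolating the effect of training-set
  composition from training-set size.

For each tested individual a relatedness score ``s_i`` sums, over the
training individuals, 1 for a parent-offspring or full-sib pair and 0.5
for a half-sib pair; individuals are stratified into groups s=0, s=1,
s=2 and s>=3 (fractional scores fall into the nearest lower group).
Predictive accuracy is the out-of-sample R^2,
``1 - Var(observed - predicted) / Var(observed)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, Pedigree, PhenotypeTable
from .gblup import GBLUP, MCMCConfig
from .grm import build_grm
from .lasso import BayesianLasso
from .preprocess import adjust_phenotype, filter_adults, filter_markers, impute_missing, subset_evenly_spaced
from .simulate import SimulatedCohort


class LeakageError(ValueError):
    """Training and testing sets overlap."""


def expected_r2_from_accuracy(correlation: float, h2: float) -> float:
    """Out-of-sample R^2 implied by a given accuracy of genetic-value
    prediction on a trait with heritability ``h2``.

    If the correlation between predicted and true genetic values is rho,
    the squared correlation between predictions and realized phenotypes is
    ``rho^2 * h2`` (the genetic values themselves explain only h2 of the
    phenotypic variance).
    """
    if not (0.0 <= h2 <= 1.0):
        raise ValueError("h2 must lie in [0, 1]")
    return correlation**2 * h2


# ---------------------------------------------------------------------------
# Split plans
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """TRN/TST assignments for one validation design.

    ``folds`` is a list of ``(trn_ids, tst_ids)`` pairs — one per fold for
    k-fold CV, one per replicate otherwise.
    """

    design: str
    folds: list
    seed: int

    def __post_init__(self) -> None:
        for trn, tst in self.folds:
            if set(trn) & set(tst):
                raise LeakageError("TRN and TST overlap within a fold")
        if self.design == "kfold":
            sizes = [len(tst) for _, tst in self.folds]
            if max(sizes) - min(sizes) > 1:
                raise ValueError("k-fold TST sizes must differ by at most 1")
            tested = [i for _, tst in self.folds for i in tst]
            if len(tested) != len(set(tested)):
                raise ValueError("individual tested more than once across folds")
        if self.design == "two_generation" and len(self.folds) != 1:
            raise ValueError("two-generation design is constrained to one replicate")
        if self.design == "random_split":
            trn_sizes = {len(trn) for trn, _ in self.folds}
            if len(trn_sizes) > 1:
                raise ValueError("random-split TRN size must be fixed across replicates")

    @property
    def n_folds(self) -> int:
        return len(self.folds)


def make_split(
    design: str,
    ids: np.ndarray,
    pedigree: Pedigree | None = None,
    n_folds: int = 10,
    n_replicates: int = 10,
    n_train: int | None = None,
    seed: int = 0,
) -> SplitPlan:
    """Build a :class:`SplitPlan` over ``ids`` for one of the three designs."""
    ids = np.asarray(ids, dtype=object)
    rng = np.random.default_rng(seed)
    if design == "kfold":
        if n_folds < 2:
            raise ValueError("k-fold requires n_folds >= 2")
        perm = rng.permutation(len(ids))
        folds = []
        for chunk in np.array_split(perm, n_folds):
            tst = ids[chunk]
            trn = ids[np.setdiff1d(np.arange(len(ids)), chunk, assume_unique=False)]
            folds.append((trn, tst))
    elif design == "two_generation":
        if pedigree is None:
            raise ValueError("two-generation design requires a pedigree with cohort labels")
        cohort = pedigree.table.set_index("individual_id")["cohort"]
        labels = cohort.reindex(ids)
        if labels.isna().any():
            raise ValueError("cohort labels missing for some individuals")
        trn = ids[(labels == "original").to_numpy()]
        tst = ids[(labels == "offspring").to_numpy()]
        folds = [(trn, tst)]
    elif design == "random_split":
        if n_train is None:
            if pedigree is None:
                raise ValueError("random_split needs n_train or a pedigree to size TRN")
            cohort = pedigree.table.set_index("individual_id")["cohort"]
            n_train = int((cohort.reindex(ids) == "original").sum())
        if not (0 < n_train < len(ids)):
            raise ValueError("n_train must lie strictly between 0 and n")
        folds = []
        for _ in range(n_replicates):
            perm = rng.permutation(len(ids))
            folds.append((ids[perm[:n_train]], ids[perm[n_train:]]))
    else:
        raise ValueError(f"unknown design {design!r}")
    return SplitPlan(design=design, folds=folds, seed=seed)


# ---------------------------------------------------------------------------
# Relatedness scores
# ---------------------------------------------------------------------------

def _relative_weights(pedigree: Pedigree) -> dict:
    """Map each individual to {relative: weight} for the close-relative
    classes that score: parent/offspring and full sibs (1), half sibs (0.5).

    Grandparental and avuncular pairs score 0 and are omitted.
    """
    tbl = pedigree.table
    parents = {
        row["individual_id"]: (row["sire_id"], row["dam_id"])
        for _, row in tbl.iterrows()
    }
    weights: dict = {iid: {} for iid in parents}
    children_of: dict = {}
    for child, (sire, dam) in parents.items():
        for par in (sire, dam):
            if par is not None:
                weights[child][par] = 1.0
                weights[par][child] = 1.0
                children_of.setdefault(par, []).append(child)
    for par, kids in children_of.items():
        for i in range(len(kids)):
            for j in range(i + 1, len(kids)):
                a, b = kids[i], kids[j]
                full = parents[a] == parents[b] and None not in parents[a]
                w = 1.0 if full else 0.5
                weights[a][b] = w
                weights[b][a] = w
    return weights


def score_group(s: float, breaks: tuple = (1.0, 2.0, 3.0)) -> str:
    """Four-group stratification; fractional scores round down."""
    if s < breaks[0]:
        return "s=0"
    if s < breaks[1]:
        return "s=1"
    if s < breaks[2]:
        return "s=2"
    return "s>=3"


def relatedness_scores(plan: SplitPlan, pedigree: Pedigree) -> pd.DataFrame:
    """Per (fold, TST individual): the close-relative score s and its group."""
    known = set(pedigree.table["individual_id"])
    weights = _relative_weights(pedigree)
    rows = []
    for fold_idx, (trn, tst) in enumerate(plan.folds):
        if not set(trn) <= known or not set(tst) <= known:
            raise ValueError("pedigree does not cover all ids in the plan")
        trn_set = set(trn)
        for i in tst:
            s = sum(w for j, w in weights[i].items() if j in trn_set)
            rows.append(
                {"fold": fold_idx, "individual_id": i, "s": s, "group": score_group(s)}
            )
    return pd.DataFrame(rows)


def r2_val(
    predictions: np.ndarray,
    observed: np.ndarray,
    trn_ids=None,
    tst_ids=None,
) -> float:
    """Out-of-sample R^2 = 1 - Var(observed - predicted)/Var(observed).

    If id sets are supplied, any TRN/TST overlap raises
    :class:`LeakageError` — predictions must come from a model whose
    training set excluded these individuals.
    """
    if trn_ids is not None and tst_ids is not None:
        overlap = set(trn_ids) & set(tst_ids)
        if overlap:
            raise LeakageError(f"TRN/TST overlap: {sorted(overlap)[:5]}")
    predictions = np.asarray(predictions, dtype=float)
    observed = np.asarray(observed, dtype=float)
    var_obs = float(np.var(observed, ddof=1))
    if var_obs == 0.0:
        raise ValueError("observed values have zero variance")
    return 1.0 - float(np.var(observed - predictions, ddof=1)) / var_obs


# ---------------------------------------------------------------------------
# Experiment driver
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Grid of models x marker counts x validation designs."""

    models: tuple = ("GY", "GH", "BL")
    marker_counts: tuple = (100, 500, 2000)
    designs: tuple = ("kfold",)
    n_folds: int = 10
    n_replicates: int = 10
    mcmc: MCMCConfig = field(default_factory=lambda: MCMCConfig(n_iter=3000, burn_in=500, thin=5))
    callrate_threshold: float = 0.90
    maf_threshold: float = 0.03
    seed: int = 0


@dataclass
class ValidationReport:
    """Replicate-level metrics plus aggregated tables.

    ``cells`` has one row per (design, model, n_markers) with replicate
    means and the coefficient of variation of R2_VAL; ``by_group`` holds
    the per-relatedness-group R2_VAL pooled across CV folds.  Negative
    R2_VAL values are flagged, never clamped.
    """

    replicates: pd.DataFrame
    cells: pd.DataFrame
    by_group: pd.DataFrame

    def table_by_markers(self, design: str) -> pd.DataFrame:
        """Rows = marker counts, columns = model x metric (Table-1/2 shape)."""
        sub = self.cells[self.cells["design"] == design]
        return sub.pivot_table(
            index="n_markers", columns="model", values=["r2_trn", "r2_val", "h2", "dic"]
        )

    def to_json(self, path: str) -> None:
        payload = {
            "cells": self.cells.to_dict(orient="records"),
            "by_group": self.by_group.to_dict(orient="records"),
            "n_negative_r2_val": int((self.replicates["r2_val"] < 0).sum()),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)


def _fit_and_predict(
    model: str,
    y: np.ndarray,
    genotypes: GenotypeMatrix,
    grms: dict,
    id_index: dict,
    trn: np.ndarray,
    tst: np.ndarray,
    mcmc: MCMCConfig,
):
    """Train one model on TRN, return (r2_trn, h2, dic, tst_predictions)."""
    trn_idx = np.array([id_index[i] for i in trn])
    tst_idx = np.array([id_index[i] for i in tst])
    if model in ("GY", "GH"):
        G = grms[model]
        fit = GBLUP(y[trn_idx], G.matrix[np.ix_(trn_idx, trn_idx)]).fit(mcmc)
        preds = fit.predict(G.matrix[np.ix_(tst_idx, trn_idx)])
        return fit.r2_trn(), fit.h2, fit.dic, preds
    if model == "BL":
        bl = BayesianLasso(y[trn_idx], genotypes.subset_individuals(trn_idx))
        fit = bl.fit(mcmc)
        preds = fit.predict(genotypes.subset_individuals(tst_idx))
        return fit.r2_trn(), np.nan, fit.dic, preds
    raise ValueError(f"unknown model {model!r}")


def run_experiment(
    cohort: SimulatedCohort, config: ExperimentConfig | None = None
) -> ValidationReport:
    """Execute the full validation grid on a simulated cohort.

    QC, imputation and phenotype adjustment run once; each grid cell
    trains on its TRN set only and predicts its TST set.  Relatedness
    groups are computed for k-fold and two-generation designs and pooled
    across folds.
    """
    config = config or ExperimentConfig()
    phen = filter_adults(cohort.phenotypes)
    phen, _ = adjust_phenotype(phen)
    keep = np.isin(cohort.genotypes.ids, phen.ids)
    genotypes = cohort.genotypes.subset_individuals(np.flatnonzero(keep))
    genotypes, _ = filter_markers(genotypes, config.callrate_threshold, config.maf_threshold)
    genotypes = impute_missing(genotypes, seed=config.seed)

    y = (
        phen.table.set_index("individual_id")
        .loc[list(genotypes.ids), "adjusted_height"]
        .to_numpy(dtype=float)
    )
    ids = genotypes.ids
    id_index = {iid: k for k, iid in enumerate(ids)}

    rep_rows, group_rows = [], []
    for n_markers in config.marker_counts:
        panel = subset_evenly_spaced(genotypes, min(n_markers, genotypes.n_markers))
        grms = {m: build_grm(panel, m[1]) for m in config.models if m in ("GY", "GH")}
        for design in config.designs:
            plan = make_split(
                design,
                ids,
                pedigree=cohort.pedigree,
                n_folds=config.n_folds,
                n_replicates=config.n_replicates,
                seed=config.seed,
            )
            scores = (
                relatedness_scores(plan, cohort.pedigree)
                if design in ("kfold", "two_generation")
                else None
            )
            for model in config.models:
                pooled_pred, pooled_obs, pooled_ids = [], [], []
                for fold_idx, (trn, tst) in enumerate(plan.folds):
                    mcmc = MCMCConfig(
                        n_iter=config.mcmc.n_iter,
                        burn_in=config.mcmc.burn_in,
                        thin=config.mcmc.thin,
                        seed=(config.seed * 1009 + fold_idx) % (2**31),
                    )
                    r2t, h2, dic, preds = _fit_and_predict(
                        model, y, panel, grms, id_index, trn, tst, mcmc
                    )
                    tst_idx = np.array([id_index[i] for i in tst])
                    obs = y[tst_idx]
                    rep_rows.append(
                        {
                            "design": design,
                            "model": model,
                            "n_markers": panel.n_markers,
                            "fold": fold_idx,
                            "r2_trn": r2t,
                            "h2": h2,
                            "dic": dic,
                            "r2_val": r2_val(preds, obs, trn, tst),
                        }
                    )
                    pooled_pred.append(preds)
                    pooled_obs.append(obs)
                    pooled_ids.extend(tst)
                if scores is not None:
                    pooled = pd.DataFrame(
                        {
                            "individual_id": pooled_ids,
                            "pred": np.concatenate(pooled_pred),
                            "obs": np.concatenate(pooled_obs),
                        }
                    ).merge(
                        scores[["individual_id", "group"]].drop_duplicates("individual_id"),
                        on="individual_id",
                    )
                    for group, sub in pooled.groupby("group"):
                        if len(sub) >= 3:
                            group_rows.append(
                                {
                                    "design": design,
                                    "model": model,
                                    "n_markers": panel.n_markers,
                                    "group": group,
                                    "n": len(sub),
                                    "r2_val": r2_val(sub["pred"], sub["obs"]),
                                }
                            )

    replicates = pd.DataFrame(rep_rows)
    agg = (
        replicates.groupby(["design", "model", "n_markers"], as_index=False)
        .agg(
            r2_trn=("r2_trn", "mean"),
            r2_val=("r2_val", "mean"),
            r2_val_cv=("r2_val", lambda x: x.std(ddof=1) / abs(x.mean()) if len(x) > 1 and x.mean() != 0 else np.nan),
            h2=("h2", "mean"),
            dic=("dic", "mean"),
        )
    )
    return ValidationReport(
        replicates=replicates,
        cells=agg,
        by_group=pd.DataFrame(group_rows),
    )
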
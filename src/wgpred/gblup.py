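"""Bayesian GBLUP: random-effects model with a genomic relationship matrix.

Model
-----
For adjusted phenotypes ``y`` (length n)::

    y = 1 mu + g + e,    g ~ N(0, sigma_g^2 G),    e ~ N(0, sigma_e^2 I)

with a flat prior on ``mu`` and conjugate scaled-inverse-chi-square priors
on both variance components (default 5 degrees of freedom, scales chosen
so each prior expectation equals half the sample variance of ``y``).

The sampler works in the eigenbasis of ``G``: writing ``G = U D U'`` and
``g = U a``, the coefficients ``a_j`` have independent normal full
conditionals, so one eigendecomposition (reusable across chains and
cross-validation folds) buys O(n) Gibbs updates.  Heritability is
summarized as the posterior mean of the per-draw ratio
``sigma_g^2 / (sigma_g^2 + sigma_e^2)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .grm import GenomicRelationship

_EIG_TOL = 1e-10  # relative cutoff below which an eigenvalue is treated as null


class NotPSDError(ValueError):
    """G has an eigenvalue below the PSD tolerance."""


@dataclass
class GBLUPPriorConfig:
    """Scaled-inverse-chi-square hyper-parameters for both variances.

    ``df > 2`` keeps the prior mean and variance finite; scales of None are
    resolved at fit time by the half-sample-variance rule
    (:func:`default_scales`).
    """

    df_g: float = 5.0
    df_e: float = 5.0
    scale_g: float | None = None
    scale_e: float | None = None

    def __post_init__(self) -> None:
        if self.df_g <= 2 or self.df_e <= 2:
            raise ValueError("prior degrees of freedom must exceed 2")


@dataclass
class MCMCConfig:
    n_iter: int = 30_000
    burn_in: int = 5_000
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


def default_scales(y: np.ndarray, df: float) -> float:
    """Scale S such that the prior mean df*S/(df-2) is half the variance of y."""
    if df <= 2:
        raise ValueError("prior mean undefined for df <= 2")
    return 0.5 * float(np.var(y, ddof=1)) * (df - 2.0) / df


def sample_scaled_inv_chi2(
    rng: np.random.Generator, df: float, scale: float
) -> float:
    """One draw from ScaledInvChi2(df, scale) = df*scale / chi2(df)."""
    return df * scale / rng.chisquare(df)


def compute_dic(
    deviance_draws: np.ndarray, deviance_at_posterior_mean: float
) -> tuple[float, float, float]:
    """DIC = Dbar + pD with pD = Dbar - D(posterior mean)."""
    deviance_draws = np.asarray(deviance_draws, dtype=float)
    if deviance_draws.size == 0:
        raise ValueError("need at least one post-burn-in deviance draw")
    dbar = float(deviance_draws.mean())
    p_d = dbar - float(deviance_at_posterior_mean)
    return dbar + p_d, dbar, p_d


class GBLUP:
    """Gaussian phenotype model with multivariate-normal genetic values.

    Parameters
    ----------
    endog : (n,) array
        Adjusted phenotypes, aligned with the rows of ``grm``.
    grm : GenomicRelationship or (n, n) array
        Standardized genomic relationship matrix (mean diagonal 1).
    priors : GBLUPPriorConfig, optional
    psd_tol : float
        Tolerance on the negative spectral mass of G, as a fraction of
        the total absolute spectral mass.  GRMs whose diagonal is
        estimated separately from the cross-products (method "Y") are
        mildly indefinite at low marker counts; such small negative
        eigenvalues are projected to zero (nearest-PSD).  A matrix whose
        negative mass exceeds ``psd_tol`` is not a noisy Gram matrix and
        raises :class:`NotPSDError`.
    """

    def __init__(self, endog, grm, priors: GBLUPPriorConfig | None = None,
                 psd_tol: float = 0.05):
        y = np.asarray(endog, dtype=float)
        if np.isnan(y).any():
            raise ValueError(
                "endog contains missing values; exclude test individuals "
                "before fitting rather than masking them"
            )
        if isinstance(grm, GenomicRelationship):
            G = grm.matrix
            self.grm_method = grm.method
        else:
            G = np.asarray(grm, dtype=float)
            self.grm_method = "custom"
        if G.shape != (y.size, y.size):
            raise ValueError("grm dimension does not match endog")
        self.endog = y
        self.G = G
        self.priors = priors or GBLUPPriorConfig()
        self.psd_tol = psd_tol
        self._eig: tuple | None = None

    @classmethod
    def from_phenotypes(cls, phenotypes, grm: GenomicRelationship, **kwargs) -> "GBLUP":
        """Align adjusted heights to the GRM ids and build the model."""
        tbl = phenotypes.table.set_index("individual_id")
        y = tbl.loc[list(grm.ids), "adjusted_height"].to_numpy(dtype=float)
        return cls(y, grm, **kwargs)

    # -- internals ----------------------------------------------------------

    def _eigendecompose(self) -> tuple:
        if self._eig is None:
            d, U = np.linalg.eigh(self.G)
            neg_mass = float(-d[d < 0].sum())
            total_mass = float(np.abs(d).sum())
            if total_mass == 0 or neg_mass / total_mass > self.psd_tol:
                raise NotPSDError(
                    f"G has negative spectral mass fraction "
                    f"{neg_mass / max(total_mass, 1e-300):.3f} "
                    f"(min eigenvalue {d.min():.3e}); not PSD within tolerance"
                )
            d = np.clip(d, 0.0, None)
            self._eig = (d, U)
        return self._eig

    def fit(
        self,
        mcmc: MCMCConfig | None = None,
        fixed_variances: tuple | None = None,
    ) -> "GBLUPResults":
        """Run the Gibbs sampler and return posterior summaries.

        ``fixed_variances=(sigma_g2, sigma_e2)`` freezes both variance
        components (used for closed-form cross-checks and for the
        degenerate no-genetic-signal mode sigma_g2=0).
        """
        mcmc = mcmc or MCMCConfig()
        y = self.endog
        n = y.size
        d, U = self._eigendecompose()
        pos = d > _EIG_TOL * max(1.0, float(d.max()))
        d_pos = d[pos]
        k = int(pos.sum())

        prior = self.priors
        scale_g = prior.scale_g if prior.scale_g is not None else default_scales(y, prior.df_g)
        scale_e = prior.scale_e if prior.scale_e is not None else default_scales(y, prior.df_e)

        Uty = U.T @ y
        Ut1 = U.T @ np.ones(n)

        rng = np.random.default_rng(mcmc.seed)
        var_y = float(np.var(y, ddof=1))
        if fixed_variances is not None:
            sigma_g2, sigma_e2 = map(float, fixed_variances)
            if sigma_e2 <= 0:
                raise ValueError("fixed residual variance must be positive")
        else:
            sigma_g2, sigma_e2 = 0.5 * var_y, 0.5 * var_y
        mu = float(y.mean())
        a = np.zeros(n)

        n_keep = (mcmc.n_iter - mcmc.burn_in) // mcmc.thin
        draws = {
            "mu": np.empty(n_keep),
            "sigma2_g": np.empty(n_keep),
            "sigma2_e": np.empty(n_keep),
            "h2": np.empty(n_keep),
            "deviance": np.empty(n_keep),
        }
        a_draws = np.empty((n_keep, n))
        kept = 0

        log2pi = np.log(2.0 * np.pi)
        for it in range(mcmc.n_iter):
            r = Uty - mu * Ut1
            # genetic coefficients in the eigenbasis
            if sigma_g2 > 0.0:
                prec = 1.0 / sigma_e2 + 1.0 / (sigma_g2 * d_pos)
                mean = (r[pos] / sigma_e2) / prec
                a[pos] = mean + rng.standard_normal(k) / np.sqrt(prec)
            else:
                a[:] = 0.0
            # common effect (flat prior)
            resid_mean = (y.sum() - Ut1 @ a) / n
            mu = resid_mean + rng.standard_normal() * np.sqrt(sigma_e2 / n)
            r = Uty - mu * Ut1
            ss_e = float(((r - a) ** 2).sum())
            if fixed_variances is None:
                if sigma_g2 >= 0.0 and k > 0:
                    ss_g = float((a[pos] ** 2 / d_pos).sum())
                    sigma_g2 = sample_scaled_inv_chi2(
                        rng, prior.df_g + k, (ss_g + prior.df_g * scale_g) / (prior.df_g + k)
                    )
                sigma_e2 = sample_scaled_inv_chi2(
                    rng, prior.df_e + n, (ss_e + prior.df_e * scale_e) / (prior.df_e + n)
                )
            if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
                draws["mu"][kept] = mu
                draws["sigma2_g"][kept] = sigma_g2
                draws["sigma2_e"][kept] = sigma_e2
                draws["h2"][kept] = sigma_g2 / (sigma_g2 + sigma_e2)
                draws["deviance"][kept] = n * (log2pi + np.log(sigma_e2)) + ss_e / sigma_e2
                a_draws[kept] = a
                kept += 1

        g_draws = a_draws @ U.T  # each row: U @ a
        g_mean = g_draws.mean(axis=0)
        mu_mean = float(draws["mu"].mean())
        sigma_e2_mean = float(draws["sigma2_e"].mean())
        resid = y - mu_mean - g_mean
        dev_at_mean = n * (log2pi + np.log(sigma_e2_mean)) + float(
            (resid**2).sum()
        ) / sigma_e2_mean
        dic, dbar, p_d = compute_dic(draws["deviance"], dev_at_mean)

        return GBLUPResults(
            model=self,
            mcmc=mcmc,
            draws=draws,
            g_draws=g_draws,
            g=g_mean,
            mu=mu_mean,
            sigma2_g=float(draws["sigma2_g"].mean()),
            sigma2_e=sigma_e2_mean,
            h2=float(draws["h2"].mean()),
            dic=dic,
            dbar=dbar,
            p_d=p_d,
        )


@dataclass
class GBLUPResults:
    """Posterior summaries and draws from a fitted GBLUP model."""

    model: GBLUP
    mcmc: MCMCConfig
    draws: dict
    g_draws: np.ndarray
    g: np.ndarray
    mu: float
    sigma2_g: float
    sigma2_e: float
    h2: float
    dic: float
    dbar: float
    p_d: float

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.mu + self.g

    @property
    def resid(self) -> np.ndarray:
        return self.model.endog - self.fittedvalues

    def r2_trn(self) -> float:
        """Training-sample R^2: 1 - Var(y - yhat)/Var(y)."""
        y = self.model.endog
        var_y = float(np.var(y, ddof=1))
        if var_y == 0.0:
            raise ValueError("response has zero variance")
        return 1.0 - float(np.var(y - self.fittedvalues, ddof=1)) / var_y

    def mcse(self, name: str) -> float:
        """Naive Monte-Carlo standard error of a scalar posterior mean."""
        x = self.draws[name]
        return float(x.std(ddof=1) / np.sqrt(x.size))

    def g_mcse(self) -> np.ndarray:
        """Per-individual Monte-Carlo SEs of the posterior mean genetic values."""
        return self.g_draws.std(axis=0, ddof=1) / np.sqrt(self.g_draws.shape[0])

    def predict(self, G_cross: np.ndarray, y_train: np.ndarray | None = None) -> np.ndarray:
        """Predict phenotypes of new individuals from their relationship to
        the training set.

        ``G_cross`` has one row per new individual and one column per
        training individual.  The predictor is the mixed-model conditional
        mean evaluated at posterior-mean variances::

            yhat = mu + G_cross (G_trn + lambda I)^{-1} (y_trn - mu),
            lambda = sigma_e^2 / sigma_g^2,

        which stays well-defined when ``G_trn`` is rank-deficient.
        """
        G_cross = np.atleast_2d(np.asarray(G_cross, dtype=float))
        y = self.model.endog if y_train is None else np.asarray(y_train, dtype=float)
        n = y.size
        if G_cross.shape[1] != n:
            raise ValueError("G_cross columns must match the training sample")
        if self.sigma2_g <= 0:
            return np.full(G_cross.shape[0], self.mu)
        lam = self.sigma2_e / self.sigma2_g
        rhs = np.linalg.solve(self.model.G + lam * np.eye(n), y - self.mu)
        return self.mu + G_cross @ rhs

    def split_chain_diagnostic(self) -> dict:
        """|mean(first half) - mean(second half)| in Monte-Carlo SEs, per scalar."""
        out = {}
        for name in ("mu", "sigma2_g", "sigma2_e", "h2"):
            x = self.draws[name]
            half = x.size // 2
            a, b = x[:half], x[half:]
            se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
            out[name] = float(abs(a.mean() - b.mean()) / se) if se > 0 else 0.0
        return out

    def summary(self) -> str:
        lines = [
            "Bayesian GBLUP results",
            "======================",
            f"n individuals        {self.model.endog.size:>10d}",
            f"GRM method           {self.model.grm_method:>10s}",
            f"posterior draws kept {self.draws['mu'].size:>10d}",
            "",
            f"{'parameter':<12}{'post. mean':>12}{'MC SE':>10}",
            "-" * 34,
        ]
        for label, name, value in (
            ("mu", "mu", self.mu),
            ("sigma2_g", "sigma2_g", self.sigma2_g),
            ("sigma2_e", "sigma2_e", self.sigma2_e),
            ("h2", "h2", self.h2),
        ):
            lines.append(f"{label:<12}{value:>12.4f}{self.mcse(name):>10.4f}")
        lines += [
            "-" * 34,
            f"R2 (training)  {self.r2_trn():.4f}",
            f"DIC {self.dic:.1f}  (Dbar {self.dbar:.1f}, pD {self.p_d:.1f})",
        ]
        return "\n".join(lines)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "mu": self.mu,
                    "sigma2_g": self.sigma2_g,
                    "sigma2_e": self.sigma2_e,
                    "h2": self.h2,
                    "r2_trn": self.r2_trn(),
                    "dic": self.dic,
                    "dbar": self.dbar,
                    "p_d": self.p_d,
                },
                fh,
                indent=2,
            )
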
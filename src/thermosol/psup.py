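"""Bayesian mixing-ratio model for sedimentation fractionation proteomics.

After ultracentrifugation of a lysate into Total (T), Supernatant (S) and
Pellet (P) fractions, conservation of mass holds for each protein in the
original lysate but not in the measured peak areas: each fraction is
processed and measured separately, so measured intensities are related by
per-experiment mixing ratios ``alpha_s`` and ``alpha_p``,

    T_i = alpha_s * S_i + alpha_p * P_i   (up to measurement noise).

The model places a lognormal likelihood on the total,

    log(T_i) ~ Normal(log(alpha_s * S_i + alpha_p * P_i), sigma),

with Gamma(1, 1) priors on the mixing ratios and a half-Cauchy(0, 3) prior
on sigma.  Posterior mixing ratios then give the proportion of each protein
in the supernatant,

    pSup_i = alpha_s * S_i / (alpha_s * S_i + alpha_p * P_i),

a per-protein solubility measure: a drop in pSup under heat shock is read as
condensation.

The model is exposed statsmodels-style: build a :class:`MixingRatioModel`
from a fractionation table, call :meth:`~MixingRatioModel.fit` (adaptive
random-walk Metropolis, with R-hat / effective-sample-size diagnostics) or
:meth:`~MixingRatioModel.fit_map`, and compute per-protein pSup estimates
with credible intervals from the resulting :class:`MixingRatioResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MixingRatioModel",
    "MixingRatioResults",
    "MAPResult",
    "filter_by_intensity",
    "log_posterior",
    "fit_map",
    "fit_mcmc",
    "compute_psup",
]

REQUIRED_COLUMNS = ("protein_id", "total", "sup", "pellet")

_LOG_2PI = math.log(2.0 * math.pi)


def _as_quant_frame(quant: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in quant.columns]
    if missing:
        raise ValueError(f"fractionation table missing columns: {missing}")
    bad = quant[["total", "sup", "pellet"]].lt(0).any(axis=1)
    if bad.any():
        first = quant.loc[bad, "protein_id"].iloc[0]
        raise ValueError(f"negative intensity for protein {first!r}")
    return quant


def filter_by_intensity(
    quant: pd.DataFrame, threshold: float = 1.0, column: str = "total"
) -> pd.DataFrame:
    """Restrict a fractionation table to proteins usable for the mixing fit.

    Keeps records whose ``column`` intensity strictly exceeds ``threshold``
    (the fit uses all proteins with intensity > 1 by default).  The filter
    applies only to the mixing-ratio fit set: pSup is still reported for
    every protein with S + P > 0.

    Raises ``ValueError`` if nothing survives (the fit would be impossible).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    quant = _as_quant_frame(quant)
    kept = quant[quant[column] > threshold]
    if kept.empty:
        raise ValueError(
            f"no records with {column} > {threshold}; mixing-ratio fit impossible"
        )
    return kept.reset_index(drop=True)


def _check_fit_set(sup: np.ndarray, pellet: np.ndarray, ids: Sequence) -> None:
    zero_both = (sup == 0) & (pellet == 0)
    if zero_both.any():
        offender = np.asarray(ids)[zero_both][0]
        raise ValueError(
            f"protein {offender!r} has S = P = 0 in the fit set; "
            "the likelihood mean log(aS*S + aP*P) is undefined"
        )


def _log_prior(alpha_s: float, alpha_p: float, sigma: float) -> float:
    # Gamma(1,1) == Exponential(1) on the mixing ratios; half-Cauchy(0,3)
    # on sigma (positive truncation of a Cauchy(0,3) scale prior).
    lp = -alpha_s - alpha_p
    lp += math.log(2.0 / (math.pi * 3.0)) - math.log1p((sigma / 3.0) ** 2)
    return lp


def log_posterior(
    alpha_s: float,
    alpha_p: float,
    sigma: float,
    quant: pd.DataFrame,
) -> float:
    """Unnormalized log posterior of the mixing-ratio model.

    Sum over records of the Normal log-density of ``log(total)`` at mean
    ``log(alpha_s*sup + alpha_p*pellet)`` with SD ``sigma``, plus
    Gamma(1, 1) log-priors on both mixing ratios and a half-Cauchy(0, 3)
    log-prior on sigma.  Returns ``-inf`` for non-positive parameters.
    """
    if alpha_s <= 0 or alpha_p <= 0 or sigma <= 0:
        return -math.inf
    quant = _as_quant_frame(quant)
    sup = quant["sup"].to_numpy(float)
    pellet = quant["pellet"].to_numpy(float)
    total = quant["total"].to_numpy(float)
    _check_fit_set(sup, pellet, quant["protein_id"].to_numpy())
    return _log_posterior_arrays(
        alpha_s, alpha_p, sigma, np.log(total), sup, pellet
    )


def _log_posterior_arrays(
    alpha_s: float,
    alpha_p: float,
    sigma: float,
    log_total: np.ndarray,
    sup: np.ndarray,
    pellet: np.ndarray,
) -> float:
    mu = np.log(alpha_s * sup + alpha_p * pellet)
    resid = log_total - mu
    n = log_total.size
    ll = -n * math.log(sigma) - 0.5 * n * _LOG_2PI - float(resid @ resid) / (
        2.0 * sigma**2
    )
    return ll + _log_prior(alpha_s, alpha_p, sigma)


@dataclass
class MAPResult:
    """Posterior-mode point estimate of the mixing-ratio parameters."""

    alpha_s: float
    alpha_p: float
    sigma: float
    log_posterior: float
    converged: bool
    message: str = ""

    def params(self) -> np.ndarray:
        return np.array([self.alpha_s, self.alpha_p, self.sigma])


@dataclass
class MixingRatioResults:
    """Posterior draws and diagnostics for (alpha_s, alpha_p, sigma).

    ``draws_*`` have shape (n_chains, n_draws).  Point estimates are
    posterior means; ``rhat`` and ``ess`` are split-R-hat and bulk effective
    sample size per parameter.  ``converged`` requires R-hat < 1.01 and
    ESS > 400 for every parameter.
    """

    model: "MixingRatioModel"
    draws_alpha_s: np.ndarray
    draws_alpha_p: np.ndarray
    draws_sigma: np.ndarray
    rhat: dict = field(default_factory=dict)
    ess: dict = field(default_factory=dict)
    seed: int | None = None
    n_warmup: int = 0
    accept_rate: float = float("nan")

    @property
    def alpha_s(self) -> float:
        return float(self.draws_alpha_s.mean())

    @property
    def alpha_p(self) -> float:
        return float(self.draws_alpha_p.mean())

    @property
    def sigma(self) -> float:
        return float(self.draws_sigma.mean())

    @property
    def n_chains(self) -> int:
        return self.draws_alpha_s.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws_alpha_s.shape[1]

    @property
    def converged(self) -> bool:
        return bool(
            all(v < 1.01 for v in self.rhat.values())
            and all(v > 400 for v in self.ess.values())
        )

    def flat_draws(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "alpha_s": self.draws_alpha_s.ravel(),
                "alpha_p": self.draws_alpha_p.ravel(),
                "sigma": self.draws_sigma.ravel(),
            }
        )

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, draws in (
            ("alpha_s", self.draws_alpha_s),
            ("alpha_p", self.draws_alpha_p),
            ("sigma", self.draws_sigma),
        ):
            flat = draws.ravel()
            lo, hi = np.percentile(flat, [2.5, 97.5])
            rows.append(
                {
                    "parameter": name,
                    "mean": flat.mean(),
                    "sd": flat.std(ddof=1),
                    "hdi_2.5%": lo,
                    "hdi_97.5%": hi,
                    "r_hat": self.rhat.get(name, float("nan")),
                    "ess_bulk": self.ess.get(name, float("nan")),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<MixingRatioResults alpha_s={self.alpha_s:.4f} "
            f"alpha_p={self.alpha_p:.4f} sigma={self.sigma:.4f} "
            f"chains={self.n_chains} draws={self.n_draws} "
            f"converged={self.converged}>"
        )

    def compute_psup(self, quant: pd.DataFrame | None = None, force: bool = False):
        return compute_psup(
            self.model.data if quant is None else quant, self, force=force
        )


class MixingRatioModel:
    """Mixing-ratio model for one fractionation experiment.

    Parameters
    ----------
    quant
        Fractionation table with columns ``protein_id``, ``total``, ``sup``,
        ``pellet`` (arbitrary peak-area units); extra columns pass through.
    intensity_threshold
        Strict lower bound on ``intensity_column`` for a record to enter the
        mixing-ratio fit set (default 1, the conventional cutoff).
    intensity_column
        Which intensity the threshold applies to; the modelled response
        ``total`` by default.

    Records with both S and P zero are excluded from the fit set and
    recorded in ``n_dropped_zero_zero``; they are reported downstream as
    missing pSup, never as 0.5.
    """

    def __init__(
        self,
        quant: pd.DataFrame,
        intensity_threshold: float = 1.0,
        intensity_column: str = "total",
    ):
        self.data = _as_quant_frame(quant).reset_index(drop=True)
        self.intensity_threshold = float(intensity_threshold)
        self.intensity_column = intensity_column
        fit_set = filter_by_intensity(
            self.data, self.intensity_threshold, intensity_column
        )
        zero_both = (fit_set["sup"] == 0) & (fit_set["pellet"] == 0)
        self.n_dropped_zero_zero = int(zero_both.sum())
        fit_set = fit_set[~zero_both].reset_index(drop=True)
        if fit_set.empty:
            raise ValueError("fit set empty after dropping S = P = 0 records")
        self.fit_data = fit_set
        self._log_total = np.log(fit_set["total"].to_numpy(float))
        self._sup = fit_set["sup"].to_numpy(float)
        self._pellet = fit_set["pellet"].to_numpy(float)

    @classmethod
    def from_dataframe(cls, quant: pd.DataFrame, **kwargs) -> "MixingRatioModel":
        return cls(quant, **kwargs)

    # ---- posterior ----------------------------------------------------

    def log_posterior(self, alpha_s: float, alpha_p: float, sigma: float) -> float:
        if alpha_s <= 0 or alpha_p <= 0 or sigma <= 0:
            return -math.inf
        return _log_posterior_arrays(
            alpha_s, alpha_p, sigma, self._log_total, self._sup, self._pellet
        )

    def _log_post_unconstrained(self, theta: np.ndarray) -> float:
        # theta = log(alpha_s, alpha_p, sigma); include the Jacobian so the
        # chain targets the posterior of the original parameters.
        a_s, a_p, sig = np.exp(theta)
        return self.log_posterior(a_s, a_p, sig) + float(theta.sum())

    # ---- MAP ----------------------------------------------------------

    def fit_map(
        self,
        x0: Sequence[float] | None = None,
        bounds: Sequence[tuple[float, float]] | None = None,
    ) -> MAPResult:
        """Maximize the log posterior (L-BFGS-B on log-parameters).

        ``bounds`` is an optional box for (alpha_s, alpha_p, sigma) in the
        original parameterization.  Non-convergence is reported in the
        result, never silently ignored.
        """
        from scipy.optimize import minimize

        if x0 is None:
            ratio = self.fit_data["total"] / (
                self._sup + self._pellet
            ).clip(min=1e-300)
            a0 = float(np.median(ratio.clip(1e-3, 1e3)))
            x0 = (a0, a0, 0.1)
        theta0 = np.log(np.asarray(x0, float))
        if bounds is not None:
            log_bounds = [
                (math.log(lo), math.log(hi)) for lo, hi in bounds
            ]
        else:
            log_bounds = [(-10.0, 10.0)] * 3

        def neg(theta):
            a_s, a_p, sig = np.exp(theta)
            val = self.log_posterior(a_s, a_p, sig)
            return -val if np.isfinite(val) else 1e300

        opt = minimize(neg, theta0, method="L-BFGS-B", bounds=log_bounds)
        a_s, a_p, sig = np.exp(opt.x)
        return MAPResult(
            alpha_s=float(a_s),
            alpha_p=float(a_p),
            sigma=float(sig),
            log_posterior=float(-opt.fun),
            converged=bool(opt.success),
            message=str(opt.message),
        )

    # ---- MCMC ----------------------------------------------------------

    def fit(
        self,
        n_chains: int = 4,
        n_warmup: int = 1000,
        n_draws: int = 4000,
        seed: int = 0,
    ) -> MixingRatioResults:
        """Sample the posterior with adaptive random-walk Metropolis.

        Proposals are Gaussian on log-parameters; during warmup the step
        scale adapts toward ~30% acceptance and the proposal covariance is
        re-estimated from the accumulated warmup history.  Adaptation is
        frozen for the retained draws.  Identical seeds give identical
        draws.
        """
        if n_chains < 2:
            raise ValueError("need >= 2 chains for split-R-hat diagnostics")
        map_fit = self.fit_map()
        theta_map = np.log(map_fit.params())

        ss = np.random.SeedSequence(seed)
        chain_seeds = ss.spawn(n_chains)
        chains = np.empty((n_chains, n_draws, 3))
        accepts = 0
        for c in range(n_chains):
            chains[c], acc = self._run_chain(
                theta_map, n_warmup, n_draws, np.random.default_rng(chain_seeds[c])
            )
            accepts += acc
        draws = np.exp(chains)

        rhat, ess = _diagnostics(draws)
        return MixingRatioResults(
            model=self,
            draws_alpha_s=draws[:, :, 0],
            draws_alpha_p=draws[:, :, 1],
            draws_sigma=draws[:, :, 2],
            rhat=rhat,
            ess=ess,
            seed=seed,
            n_warmup=n_warmup,
            accept_rate=accepts / (n_chains * n_draws),
        )

    fit_mcmc = fit

    def _run_chain(
        self,
        theta_start: np.ndarray,
        n_warmup: int,
        n_draws: int,
        rng: np.random.Generator,
    ) -> tuple[np.ndarray, int]:
        d = 3
        theta = theta_start + 0.1 * rng.standard_normal(d)
        lp = self._log_post_unconstrained(theta)
        log_scale = math.log(0.5)
        chol = np.eye(d)
        history = np.empty((n_warmup, d))
        target = 0.30
        for i in range(n_warmup):
            prop = theta + math.exp(log_scale) * (chol @ rng.standard_normal(d))
            lp_prop = self._log_post_unconstrained(prop)
            accept_p = math.exp(min(0.0, lp_prop - lp))
            if rng.random() < accept_p:
                theta, lp = prop, lp_prop
            history[i] = theta
            # Robbins-Monro scale adaptation toward the target rate.
            log_scale += (accept_p - target) / math.sqrt(i + 1)
            if i >= 200 and i % 100 == 0:
                cov = np.cov(history[i // 2 : i + 1].T)
                cov += 1e-10 * np.eye(d)
                try:
                    chol = np.linalg.cholesky(cov)
                except np.linalg.LinAlgError:
                    pass
        out = np.empty((n_draws, d))
        accepted = 0
        step = math.exp(log_scale)
        for i in range(n_draws):
            prop = theta + step * (chol @ rng.standard_normal(d))
            lp_prop = self._log_post_unconstrained(prop)
            if math.log(rng.random() + 1e-300) < lp_prop - lp:
                theta, lp = prop, lp_prop
                accepted += 1
            out[i] = theta
        return out, accepted


def _diagnostics(draws: np.ndarray) -> tuple[dict, dict]:
    """Split-R-hat and bulk ESS per parameter via arviz."""
    import arviz as az

    names = ("alpha_s", "alpha_p", "sigma")
    idata = az.from_dict(
        posterior={name: draws[:, :, k] for k, name in enumerate(names)}
    )
    rhat_ds = az.rhat(idata)
    ess_ds = az.ess(idata)
    rhat = {name: float(rhat_ds[name].values) for name in names}
    ess = {name: float(ess_ds[name].values) for name in names}
    return rhat, ess


# ---- module-level conveniences mirroring the operation surface ---------


def fit_map(
    quant: pd.DataFrame,
    bounds: Sequence[tuple[float, float]] | None = None,
    intensity_threshold: float = 1.0,
) -> MAPResult:
    """MAP point estimate of (alpha_s, alpha_p, sigma) for one experiment."""
    return MixingRatioModel(quant, intensity_threshold).fit_map(bounds=bounds)


def fit_mcmc(
    quant: pd.DataFrame,
    n_chains: int = 4,
    n_warmup: int = 1000,
    n_draws: int = 4000,
    seed: int = 0,
    intensity_threshold: float = 1.0,
) -> MixingRatioResults:
    """Posterior sampling of the mixing-ratio model for one experiment."""
    return MixingRatioModel(quant, intensity_threshold).fit(
        n_chains=n_chains, n_warmup=n_warmup, n_draws=n_draws, seed=seed
    )


def compute_psup(
    quant: pd.DataFrame,
    mixing: MixingRatioResults,
    force: bool = False,
) -> pd.DataFrame:
    """Per-protein pSup with 95% credible intervals.

    The point estimate plugs the posterior-mean mixing ratios into
    ``pSup = aS*S / (aS*S + aP*P)``; the interval is the 2.5-97.5 percentile
    of the per-draw pSup.  Proteins with S = P = 0 are reported with missing
    pSup (NaN), never 0.5.  Refuses a non-converged posterior unless
    ``force=True``.
    """
    if not mixing.converged and not force:
        raise ValueError(
            "mixing posterior not converged (R-hat/ESS); pass force=True to override"
        )
    quant = _as_quant_frame(quant)
    sup = quant["sup"].to_numpy(float)
    pellet = quant["pellet"].to_numpy(float)
    a_s, a_p = mixing.alpha_s, mixing.alpha_p

    denom = a_s * sup + a_p * pellet
    with np.errstate(invalid="ignore", divide="ignore"):
        psup = np.where(denom > 0, a_s * sup / denom, np.nan)

    draws_s = mixing.draws_alpha_s.ravel()
    draws_p = mixing.draws_alpha_p.ravel()
    num = draws_s[None, :] * sup[:, None]
    den = num + draws_p[None, :] * pellet[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        per_draw = np.where(den > 0, num / den, np.nan)
    lo = np.nanpercentile(per_draw, 2.5, axis=1)
    hi = np.nanpercentile(per_draw, 97.5, axis=1)
    lo = np.where(np.isnan(psup), np.nan, lo)
    hi = np.where(np.isnan(psup), np.nan, hi)

    out = pd.DataFrame(
        {
            "protein_id": quant["protein_id"].to_numpy(),
            "psup": psup,
            "ci_low": lo,
            "ci_high": hi,
            "n_draws": draws_s.size,
        }
    )
    for col in ("species", "condition", "temperature_c", "replicate"):
        if col in quant.columns:
            out[col] = quant[col].to_numpy()
    return out
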
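"""Thermal phenotype fitting: growth, heat-shock response, condensation onset.

Four statistics describe how a species or a purified protein responds to
temperature:

* the maximum specific growth rate at each temperature, extracted as the
  slope of the linear range of ln OD600 versus time;
* the cardinal temperature model with inflection (CTMI), a four-parameter
  (T_min, T_opt, T_max, mu_opt) description of growth rate versus
  temperature;
* a skew-normal fit to the heat-shock reporter response versus temperature,
  whose numeric mode is the temperature of maximum response;
* the condensation onset temperature (T_condense) of a purified protein,
  detected as a sustained departure of the DLS hydrodynamic radius from its
  low-temperature monomer baseline.

CTMI and skew-normal fits follow a statsmodels-like Model/Results pattern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "CTMIModel",
    "CTMIResults",
    "SkewNormalHSRModel",
    "SkewNormalHSRResults",
    "TcondenseResult",
    "ctmi_value",
    "fit_ctmi",
    "fit_hsr_skewnormal",
    "skewnormal_mode",
    "max_specific_growth_rate",
    "normalize_cytometry",
    "compute_tcondense",
    "correlate_optima",
]


# ---------------------------------------------------------------- CTMI


def ctmi_value(
    t, t_min: float, t_opt: float, t_max: float, mu_opt: float
):
    """Growth rate mu(T) under the cardinal temperature model with inflection.

    Rosso-form closed expression, zero at and outside the cardinal
    temperatures, equal to ``mu_opt`` at ``t_opt``::

        mu(T) = mu_opt * (T - T_max)(T - T_min)^2 /
                { (T_opt - T_min) [ (T_opt - T_min)(T - T_opt)
                                    - (T_opt - T_max)(T_opt + T_min - 2T) ] }

    Accepts scalars or arrays.
    """
    if not (t_min < t_opt < t_max):
        raise ValueError("cardinal ordering t_min < t_opt < t_max required")
    t = np.asarray(t, float)
    num = (t - t_max) * (t - t_min) ** 2
    den = (t_opt - t_min) * (
        (t_opt - t_min) * (t - t_opt) - (t_opt - t_max) * (t_opt + t_min - 2.0 * t)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = mu_opt * num / den
    mu = np.where((t <= t_min) | (t >= t_max), 0.0, mu)
    if mu.ndim == 0:
        return float(mu)
    return mu


@dataclass
class CTMIResults:
    """Cardinal temperatures with their standard deviations.

    SDs come from the covariance of the nonlinear least-squares fit
    (delta-method through the ordering reparameterization).
    """

    t_min: float
    t_opt: float
    t_max: float
    mu_opt: float
    sd: dict = field(default_factory=dict)
    residual_rms: float = float("nan")
    converged: bool = True
    n_points: int = 0

    def predict(self, t):
        return ctmi_value(t, self.t_min, self.t_opt, self.t_max, self.mu_opt)

    def params(self) -> dict:
        return {
            "t_min": self.t_min,
            "t_opt": self.t_opt,
            "t_max": self.t_max,
            "mu_opt": self.mu_opt,
        }

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.params(),
                "sd": {k: self.sd.get(k, float("nan")) for k in self.params()},
            }
        )

    def plot(self, temperature=None, mu=None, ax=None):
        from thermosol.plotting import plot_ctmi_fit

        return plot_ctmi_fit(self, temperature, mu, ax=ax)


class CTMIModel:
    """Fit the CTMI to (temperature, growth rate[, SE]) observations.

    Weighted least squares when SEs are supplied.  The ordering constraint
    T_min < T_opt < T_max is enforced by fitting positive gaps
    (T_min, d1, d2) with T_opt = T_min + d1 and T_max = T_opt + d2.
    """

    def __init__(self, temperature, mu, se=None):
        self.temperature = np.asarray(temperature, float)
        self.mu = np.asarray(mu, float)
        self.se = None if se is None else np.asarray(se, float)
        if self.temperature.size != self.mu.size:
            raise ValueError("temperature and mu must have equal length")
        if np.unique(self.temperature).size < 5:
            raise ValueError("need >= 5 distinct temperatures to fit the CTMI")
        if np.all(self.mu <= 0):
            raise ValueError("all growth rates <= 0; CTMI fit degenerate")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, temperature="temperature_c", mu="mu", se=None
    ) -> "CTMIModel":
        return cls(
            df[temperature], df[mu], None if se is None else df[se]
        )

    def fit(self) -> CTMIResults:
        t, mu = self.temperature, self.mu
        w = np.ones_like(mu) if self.se is None else 1.0 / np.clip(self.se, 1e-9, None)

        t_opt0 = t[np.argmax(mu)]
        t_min0 = t.min() - 5.0
        t_max0 = t.max() + 2.0
        x0 = np.array(
            [t_min0, t_opt0 - t_min0, t_max0 - t_opt0, max(mu.max(), 1e-6)]
        )

        def resid(x):
            t_min, d1, d2, mu_opt = x
            return w * (ctmi_value(t, t_min, t_min + d1, t_min + d1 + d2, mu_opt) - mu)

        lower = [-273.0, 1e-3, 1e-3, 1e-9]
        upper = [np.inf, np.inf, np.inf, np.inf]
        sol = optimize.least_squares(resid, x0, bounds=(lower, upper))
        t_min, d1, d2, mu_opt = sol.x
        t_opt, t_max = t_min + d1, t_min + d1 + d2

        n, p = mu.size, 4
        dof = max(n - p, 1)
        s2 = 2.0 * sol.cost / dof
        try:
            jtj_inv = np.linalg.pinv(sol.jac.T @ sol.jac)
            cov_x = s2 * jtj_inv
            # params = A @ x with t_opt = t_min + d1, t_max = t_min + d1 + d2
            a = np.array(
                [
                    [1, 0, 0, 0],
                    [1, 1, 0, 0],
                    [1, 1, 1, 0],
                    [0, 0, 0, 1],
                ],
                float,
            )
            cov = a @ cov_x @ a.T
            sds = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:  # pragma: no cover
            sds = np.full(4, np.nan)

        return CTMIResults(
            t_min=float(t_min),
            t_opt=float(t_opt),
            t_max=float(t_max),
            mu_opt=float(mu_opt),
            sd={
                "t_min": float(sds[0]),
                "t_opt": float(sds[1]),
                "t_max": float(sds[2]),
                "mu_opt": float(sds[3]),
            },
            residual_rms=float(np.sqrt(np.mean(resid(sol.x) ** 2))),
            converged=bool(sol.success),
            n_points=int(n),
        )


def fit_ctmi(points) -> CTMIResults:
    """Fit the CTMI to a list of (temperature, mu[, se]) tuples or a frame."""
    if isinstance(points, pd.DataFrame):
        se = points["se"] if "se" in points.columns else None
        return CTMIModel(points["temperature_c"], points["mu"], se).fit()
    arr = np.asarray(points, float)
    se = arr[:, 2] if arr.shape[1] > 2 else None
    return CTMIModel(arr[:, 0], arr[:, 1], se).fit()


# ------------------------------------------------- growth-rate extraction


def max_specific_growth_rate(
    times_min, od600, min_points: int = 4
) -> tuple[float, float, tuple[float, float]]:
    """Maximum specific growth rate from one OD600 time course.

    Scans every contiguous window of at least ``min_points`` samples and
    returns the slope of ln OD versus time over the window with the highest
    linear-fit R^2 (ties broken toward the longer, then earlier, window).
    Returns ``(mu_per_hour, se_per_hour, (t_start, t_end))`` with times in
    the input minutes.
    """
    t = np.asarray(times_min, float)
    od = np.asarray(od600, float)
    if t.size < min_points:
        raise ValueError(f"need at least {min_points} samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(od <= 0):
        raise ValueError("od600 must be positive")
    y = np.log(od)

    best = None  # (r2, length, -start, slope, se, window)
    n = t.size
    for i in range(n - min_points + 1):
        for j in range(i + min_points, n + 1):
            tt, yy = t[i:j], y[i:j]
            slope, intercept = np.polyfit(tt, yy, 1)
            pred = slope * tt + intercept
            ss_res = float(np.sum((yy - pred) ** 2))
            ss_tot = float(np.sum((yy - yy.mean()) ** 2))
            r2 = 1.0 if ss_res < 1e-24 else (
                0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
            )
            m = j - i
            sxx = float(np.sum((tt - tt.mean()) ** 2))
            se = math.sqrt(max(ss_res, 0.0) / max(m - 2, 1) / sxx)
            key = (round(r2, 12), m, -i)
            if best is None or key > best[0]:
                best = (key, slope, se, (tt[0], tt[-1]))
    _, slope, se, window = best
    return slope * 60.0, se * 60.0, window


# ------------------------------------------------------------- cytometry


def normalize_cytometry(
    events: pd.DataFrame,
    mock_events: pd.DataFrame,
    autofl_quantile: float = 0.95,
    min_cells: int = 5000,
) -> float:
    """Size- and autofluorescence-normalized reporter fold change.

    Events above the ``autofl_quantile`` quantile of the autofluorescence
    channel (computed per sample) are gated out; the per-cell statistic is
    fluorescence / forward-scatter area (a size control), and the returned
    fold change is its mean relative to mock-treated cells.  Fails if fewer
    than ``min_cells`` events survive the gate in either sample.
    """

    def gated_stat(df: pd.DataFrame) -> float:
        needed = {"fluorescence", "fsc_a", "autofl"}
        if not needed <= set(df.columns):
            raise ValueError(f"event table needs columns {sorted(needed)}")
        cut = df["autofl"].quantile(autofl_quantile)
        kept = df[df["autofl"] <= cut]
        if len(kept) < min_cells:
            raise ValueError(
                f"only {len(kept)} events after autofluorescence gate "
                f"(floor {min_cells})"
            )
        return float((kept["fluorescence"] / kept["fsc_a"]).mean())

    return gated_stat(events) / gated_stat(mock_events)


# ------------------------------------------------------------ skew-normal


def skewnormal_mode(
    xi: float, omega: float, alpha_shape: float, grid_step: float = 0.01
) -> float:
    """Numeric mode of the skew-normal density (no closed form exists).

    Dense-grid argmax at ``grid_step`` resolution; exact ``xi`` for the
    symmetric case.
    """
    if omega <= 0:
        raise ValueError("omega must be > 0")
    if abs(alpha_shape) < 1e-12:
        return float(xi)
    lo, hi = xi - 4.0 * omega, xi + 4.0 * omega
    grid = np.arange(lo, hi + grid_step, grid_step)
    dens = stats.skewnorm.pdf(grid, alpha_shape, loc=xi, scale=omega)
    return float(grid[np.argmax(dens)])


@dataclass
class SkewNormalHSRResults:
    """Skew-normal fit of a heat-shock-response curve.

    ``t_max_response`` is the numeric mode of the fitted density (0.01 degC
    grid), the temperature of maximum reporter response; ``sd_of_fit`` is
    the fitted scale omega.
    """

    xi: float
    omega: float
    alpha_shape: float
    amplitude: float
    t_max_response: float
    sd_of_fit: float
    residual_rms: float
    converged: bool

    def predict(self, t):
        t = np.asarray(t, float)
        dens = stats.skewnorm.pdf(t, self.alpha_shape, loc=self.xi, scale=self.omega)
        peak = stats.skewnorm.pdf(
            self.t_max_response, self.alpha_shape, loc=self.xi, scale=self.omega
        )
        return self.amplitude * dens / peak

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": {
                    "xi": self.xi,
                    "omega": self.omega,
                    "alpha_shape": self.alpha_shape,
                    "amplitude": self.amplitude,
                    "t_max_response": self.t_max_response,
                }
            }
        )

    def plot(self, temperature=None, response=None, ax=None):
        from thermosol.plotting import plot_hsr_fit

        return plot_hsr_fit(self, temperature, response, ax=ax)


class SkewNormalHSRModel:
    """Least-squares skew-normal fit to response versus temperature.

    The curve is one point per temperature (fold change of the reporter
    over mock), modelled as an amplitude-scaled skew-normal density whose
    peak height equals the amplitude.
    """

    def __init__(self, temperature, response):
        self.temperature = np.asarray(temperature, float)
        self.response = np.asarray(response, float)
        if self.temperature.size < 4:
            raise ValueError("need >= 4 temperatures to fit")
        if not np.all(np.isfinite(self.response)):
            raise ValueError("responses must be finite")
        if np.ptp(self.response) <= 0:
            raise ValueError("flat response curve; skew-normal fit rejected")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, temperature="temperature_c", response="response_fold"
    ) -> "SkewNormalHSRModel":
        return cls(df[temperature], df[response])

    def fit(self) -> SkewNormalHSRResults:
        t, y = self.temperature, self.response

        def curve(x):
            xi, log_omega, alpha, log_amp = x
            omega = math.exp(log_omega)
            dens = stats.skewnorm.pdf(t, alpha, loc=xi, scale=omega)
            mode = skewnormal_mode(xi, omega, alpha, grid_step=0.05)
            peak = stats.skewnorm.pdf(mode, alpha, loc=xi, scale=omega)
            return math.exp(log_amp) * dens / peak

        def resid(x):
            return curve(x) - y

        span = np.ptp(t)
        # multi-start over the shape: skewed curves trap single starts in
        # poor local optima when initialized symmetric
        sol = None
        for alpha0 in (0.0, -2.0, 2.0):
            x0 = np.array(
                [
                    t[np.argmax(y)],
                    math.log(max(span / 4.0, 0.5)),
                    alpha0,
                    math.log(y.max()),
                ]
            )
            cand = optimize.least_squares(resid, x0)
            if sol is None or cand.cost < sol.cost:
                sol = cand
        xi, log_omega, alpha, log_amp = sol.x
        omega, amp = math.exp(log_omega), math.exp(log_amp)
        mode = skewnormal_mode(xi, omega, alpha, grid_step=0.01)
        mode = float(np.clip(mode, t.min(), t.max()))
        return SkewNormalHSRResults(
            xi=float(xi),
            omega=float(omega),
            alpha_shape=float(alpha),
            amplitude=float(amp),
            t_max_response=mode,
            sd_of_fit=float(omega),
            residual_rms=float(np.sqrt(np.mean(sol.fun**2))),
            converged=bool(sol.success),
        )


def fit_hsr_skewnormal(curve: pd.DataFrame) -> SkewNormalHSRResults:
    """Fit a heat-shock-response curve table (temperature_c, response_fold)."""
    return SkewNormalHSRModel.from_dataframe(curve).fit()


# ----------------------------------------------------------- T_condense


@dataclass
class TcondenseResult:
    """Condensation onset detected from one or more DLS temperature ramps."""

    baseline_rh: float
    t_condense: float  # NaN when no sustained exceedance is found
    per_replicate: dict = field(default_factory=dict)
    sd: float = float("nan")

    @property
    def detected(self) -> bool:
        return not math.isnan(self.t_condense)


def _tcondense_single(
    temperature: np.ndarray,
    rh: np.ndarray,
    baseline_cutoff: float,
    k_sd: float,
    run_length: int,
    method: str,
    rel_increase: float,
) -> tuple[float, float]:
    below = temperature < baseline_cutoff
    if below.sum() < 3:
        raise ValueError(
            f"need >= 3 points below {baseline_cutoff} degC to set the baseline"
        )
    baseline = float(rh[below].mean())
    if method == "sd":
        sd = float(rh[below].std(ddof=0))
        sd = max(sd, 0.02 * baseline)  # floor against near-noiseless baselines
        threshold = baseline + k_sd * sd
    elif method == "relative":
        threshold = baseline * (1.0 + rel_increase)
    else:
        raise ValueError(f"unknown onset method {method!r}")

    exceed = rh > threshold
    n = exceed.size
    for i in range(n):
        if temperature[i] < baseline_cutoff:
            continue
        j = min(i + run_length, n)
        if j - i >= run_length and exceed[i:j].all():
            return baseline, float(temperature[i])
    return baseline, float("nan")


def compute_tcondense(
    ramp: pd.DataFrame,
    baseline_cutoff: float = 35.0,
    k_sd: float = 5.0,
    run_length: int = 2,
    method: str = "sd",
    rel_increase: float = 0.5,
) -> TcondenseResult:
    """Condensation onset temperature from DLS temperature-ramp data.

    The monomer baseline is the mean hydrodynamic radius below
    ``baseline_cutoff`` (35 degC).  T_condense is the lowest temperature at
    which R_h exceeds baseline + ``k_sd`` baseline SDs (SD floored at 2% of
    the baseline) for at least ``run_length`` consecutive acquisitions;
    ``method="relative"`` instead thresholds at a fractional R_h increase.
    With a ``replicate`` column, per-replicate onsets are averaged and
    their SD reported; undetected onsets stay missing, never extrapolated.
    """
    if not {"temperature_c", "rh_nm"} <= set(ramp.columns):
        raise ValueError("ramp needs columns temperature_c, rh_nm")
    if (ramp["rh_nm"] <= 0).any():
        raise ValueError("rh_nm must be positive")

    groups = (
        [(None, ramp)]
        if "replicate" not in ramp.columns
        else list(ramp.groupby("replicate", sort=True))
    )
    baselines, onsets, per_rep = [], [], {}
    for name, g in groups:
        g = g.sort_values("temperature_c", kind="stable")
        b, tc = _tcondense_single(
            g["temperature_c"].to_numpy(float),
            g["rh_nm"].to_numpy(float),
            baseline_cutoff,
            k_sd,
            run_length,
            method,
            rel_increase,
        )
        baselines.append(b)
        onsets.append(tc)
        per_rep[name if name is not None else 0] = tc
    detected = [x for x in onsets if not math.isnan(x)]
    t_condense = float(np.mean(detected)) if detected else float("nan")
    sd = float(np.std(detected, ddof=1)) if len(detected) > 1 else float("nan")
    return TcondenseResult(
        baseline_rh=float(np.mean(baselines)),
        t_condense=t_condense,
        per_replicate=per_rep,
        sd=sd,
    )


# ------------------------------------------------------ optima correlation


def correlate_optima(x, y) -> dict:
    """OLS line through paired temperature optima, plus identity offsets.

    ``x`` and ``y`` are sequences of temperatures (or (value, sd) pairs;
    SDs ride along unused by the OLS).  Returns slope, intercept, Pearson
    r, and each point's offset from the y = x line.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.ndim == 2:
        x = x[:, 0]
    if y.ndim == 2:
        y = y[:, 0]
    if x.size < 3:
        raise ValueError("need >= 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate: all x values equal")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "pearson_r": float(res.rvalue),
        "identity_offsets": (y - x).tolist(),
    }
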
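"""Hierarchical Bayesian model of the ecosystem functional response.

The response is standardized log(ANPP); the covariate is standardized
cumulative March-June volumetric water content (VWC).  The linear predictor

    mu_i = beta . x_i + gamma_{j(i)} . z_i + eta_t

has six fixed effects (control intercept and slope plus drought/irrigation
intercept and slope offsets), plot-level random intercepts and slopes
gamma_j ~ MVN(0, Sigma), and year effects eta_t ~ N(0, sigma_year^2).
Observations are y_i ~ N(mu_i, sigma^2).  Priors: beta ~ N(0, 5) per
coefficient; half-Cauchy(2.5) on sigma, sigma_year and the scales of Sigma,
with a uniform prior on the intercept-slope correlation.

Posteriors are sampled by a blocked Gibbs sampler: conjugate normal updates
for beta, gamma and eta, and univariate slice sampling for the scale
parameters and the correlation.  Convergence is checked with rank-normalized
split R-hat; values >= 1.1 raise a warning attached to the results.

The two scientific hypotheses are one-tailed posterior probabilities on the
slope offsets: drought x VWC > 0 (greater sensitivity under drought) and
irrigation x VWC < 0 (saturation under irrigation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

TREATMENT_LEVELS = ("control", "drought", "irrigation")
BETA_NAMES = ("intercept", "drought_intercept", "irrigation_intercept",
              "slope", "drought_slope", "irrigation_slope")


# ---------------------------------------------------------------------------
# standardization and design
# ---------------------------------------------------------------------------

@dataclass
class Standardized:
    """z-scored values with stored mean/s.d. (population convention)."""

    values: np.ndarray
    mean: float
    sd: float

    def destandardize(self, z) -> np.ndarray:
        return np.asarray(z) * self.sd + self.mean


def standardize(values) -> Standardized:
    """Center and scale to mean 0, unit variance (population s.d.)."""
    x = np.asarray(values, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("cannot standardize: fewer than 2 distinct values")
    mean = float(np.mean(x))
    sd = float(np.std(x))  # population (n) convention for deterministic tests
    return Standardized((x - mean) / sd, mean, sd)


def build_design_row(treatment: str, v: float) -> np.ndarray:
    """Design row (1, I_drought, I_irr, v, I_drought*v, I_irr*v)."""
    if treatment not in TREATMENT_LEVELS:
        raise ValueError(f"unknown treatment label {treatment!r}")
    d = 1.0 if treatment == "drought" else 0.0
    i = 1.0 if treatment == "irrigation" else 0.0
    return np.array([1.0, d, i, v, d * v, i * v])


def build_design(treatments, vwc_std) -> np.ndarray:
    """Stacked design matrix for sequences of treatments and scaled VWC."""
    return np.vstack([build_design_row(t, v) for t, v in zip(treatments, vwc_std)])


# ---------------------------------------------------------------------------
# slice sampler
# ---------------------------------------------------------------------------

def _slice_sample(x0: float, logp, rng, w: float = 1.0, max_steps: int = 50) -> float:
    """Univariate slice sampling with stepping-out and shrinkage."""
    logy = logp(x0) + np.log(rng.random())
    u = rng.random()
    lo, hi = x0 - w * u, x0 + w * (1.0 - u)
    for _ in range(max_steps):
        if logp(lo) <= logy:
            break
        lo -= w
    for _ in range(max_steps):
        if logp(hi) <= logy:
            break
        hi += w
    for _ in range(200):
        x1 = rng.uniform(lo, hi)
        if logp(x1) > logy:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0  # pathological shrinkage; keep current state


def _log_half_cauchy(sigma: float, scale: float) -> float:
    return -np.log1p((sigma / scale) ** 2)


# ---------------------------------------------------------------------------
# model and results
# ---------------------------------------------------------------------------

@dataclass
class MCMCConfig:
    """Sampler settings.

    ``iterations`` is the total per chain; the first half is discarded as
    warmup and the remainder thinned by ``thin`` (defaults follow the
    4 chains x 10,000 iterations, save-every-10th protocol).
    """

    chains: int = 4
    iterations: int = 10_000
    thin: int = 10
    seed: int = 0
    prior_beta_sd: float = 5.0
    hc_scale: float = 2.5

    @property
    def warmup(self) -> int:
        return self.iterations // 2


class FunctionalResponseModel:
    """Hierarchical regression of standardized log(ANPP) on standardized VWC.

    Parameters
    ----------
    records : DataFrame
        Plot-year records with columns plot_id, treatment, treatment_year,
        anpp (g m^-2, > 0) and vwc (cumulative spring VWC, shared within
        treatment-year).
    """

    def __init__(self, records: pd.DataFrame, prestandardized: bool = False):
        value_cols = {"y_std", "vwc_std"} if prestandardized else {"anpp", "vwc"}
        req = {"plot_id", "treatment", "treatment_year"} | value_cols
        missing = req - set(records.columns)
        if missing:
            raise ValueError(f"records missing column(s) {sorted(missing)}")
        if not prestandardized and (records["anpp"] <= 0).any():
            raise ValueError("anpp must be > 0 (log transform)")
        if records.duplicated(["plot_id", "treatment_year"]).any():
            raise ValueError("one record per plot-year required")
        trts = set(records["treatment"].unique())
        unknown = trts - set(TREATMENT_LEVELS)
        if unknown:
            raise ValueError(f"unknown treatment label(s) {sorted(unknown)}")
        if records["plot_id"].nunique() < 2 or records["treatment_year"].nunique() < 2:
            raise ValueError("need >= 2 plots and >= 2 years")

        self.records = records.reset_index(drop=True)
        if prestandardized:
            self.y_std = Standardized(self.records["y_std"].to_numpy(dtype=float), 0.0, 1.0)
            self.vwc_std = Standardized(self.records["vwc_std"].to_numpy(dtype=float), 0.0, 1.0)
        else:
            self.y_std = standardize(np.log(self.records["anpp"].to_numpy(dtype=float)))
            self.vwc_std = standardize(self.records["vwc"].to_numpy(dtype=float))
        self.plot_ids = sorted(self.records["plot_id"].unique())
        self.years = sorted(self.records["treatment_year"].unique())
        self.plot_idx = self.records["plot_id"].map({p: i for i, p in enumerate(self.plot_ids)}).to_numpy()
        self.year_idx = self.records["treatment_year"].map({t: i for i, t in enumerate(self.years)}).to_numpy()
        self.X = build_design(self.records["treatment"], self.vwc_std.values)
        self.v = self.vwc_std.values.copy()
        self.y = self.y_std.values.copy()

    @classmethod
    def from_dataframe(cls, records: pd.DataFrame) -> "FunctionalResponseModel":
        return cls(records)

    @classmethod
    def from_standardized(cls, records: pd.DataFrame) -> "FunctionalResponseModel":
        """Build from records already on the standardized scale.

        ``records`` carries ``y_std`` (standardized log-ANPP) and ``vwc_std``
        directly — the scale the generative equations are written on — which
        keeps the estimand of recovery experiments identical to the
        generating coefficients.
        """
        return cls(records, prestandardized=True)

    # -- sampler -----------------------------------------------------------

    def fit(self, chains: int | None = None, iterations: int | None = None,
            thin: int | None = None, seed: int | None = None,
            prior_beta_sd: float | None = None, hc_scale: float | None = None,
            config: MCMCConfig | None = None,
            use_likelihood: bool = True) -> "FunctionalResponseResults":
        """Run the Gibbs sampler and return posterior draws + summaries.

        ``use_likelihood=False`` samples from the prior only (the data define
        just the dimensions), which is used for prior-recovery checks.
        """
        cfg = config or MCMCConfig()
        if chains is not None:
            cfg.chains = chains
        if iterations is not None:
            cfg.iterations = iterations
        if thin is not None:
            cfg.thin = thin
        if seed is not None:
            cfg.seed = seed
        if prior_beta_sd is not None:
            cfg.prior_beta_sd = prior_beta_sd
        if hc_scale is not None:
            cfg.hc_scale = hc_scale

        seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.chains)
        chains_out = [self._run_chain(np.random.default_rng(s), cfg, use_likelihood)
                      for s in seeds]
        draws = {k: np.stack([c[k] for c in chains_out]) for k in chains_out[0]}
        res = FunctionalResponseResults(self, draws, cfg)
        if cfg.chains >= 2:
            bad = {k: v for k, v in res.rhat().items() if np.any(np.asarray(v) >= 1.1)}
            if bad:
                res.warnings.append(f"R-hat >= 1.1 for: {sorted(bad)}")
                warnings.warn(f"convergence warning, R-hat >= 1.1 for: {sorted(bad)}")
        else:
            res.warnings.append("single chain: R-hat unavailable")
            warnings.warn("single chain: R-hat unavailable")
        return res

    def _run_chain(self, rng, cfg: MCMCConfig, use_likelihood: bool) -> dict:
        n, J, T = len(self.y), len(self.plot_ids), len(self.years)
        X, y, v = self.X, self.y, self.v
        plot_idx, year_idx = self.plot_idx, self.year_idx
        s_b2 = cfg.prior_beta_sd ** 2

        # Joint design W = [X | plot intercept/slope blocks | year indicators].
        # All linear coefficients theta = (beta, gamma, eta) are updated in a
        # single conjugate multivariate-normal block, which decouples the
        # fixed effects from the random effects they are confounded with and
        # gives near-independent draws given the variance parameters.
        p = 6 + 2 * J + T
        W = np.zeros((n, p))
        W[:, :6] = X
        rows = np.arange(n)
        W[rows, 6 + 2 * plot_idx] = 1.0
        W[rows, 6 + 2 * plot_idx + 1] = v
        W[rows, 6 + 2 * J + year_idx] = 1.0
        WtW = W.T @ W
        Wty = W.T @ y

        # initial state
        beta = rng.normal(0.0, 0.5, size=6)
        gamma = rng.normal(0.0, 0.1, size=(J, 2))
        eta = rng.normal(0.0, 0.1, size=T)
        sigma, sigma_year = 0.5, 0.3
        tau = np.array([0.5, 0.5])
        rho = 0.0

        n_save = (cfg.iterations - cfg.warmup) // cfg.thin
        out = {"beta": np.empty((n_save, 6)), "gamma": np.empty((n_save, J, 2)),
               "eta": np.empty((n_save, T)), "sigma": np.empty(n_save),
               "sigma_year": np.empty(n_save), "tau": np.empty((n_save, 2)),
               "rho": np.empty(n_save)}
        k = 0
        for it in range(cfg.iterations):
            if use_likelihood:
                # theta | variances: one joint Gaussian draw
                det_S = tau[0] ** 2 * tau[1] ** 2 * (1 - rho ** 2)
                iS = np.array([[tau[1] ** 2, -rho * tau[0] * tau[1]],
                               [-rho * tau[0] * tau[1], tau[0] ** 2]]) / det_S
                A = WtW / sigma ** 2
                A[:6, :6] += np.eye(6) / s_b2
                for j in range(J):
                    A[6 + 2 * j:8 + 2 * j, 6 + 2 * j:8 + 2 * j] += iS
                idx = np.arange(6 + 2 * J, p)
                A[idx, idx] += 1.0 / sigma_year ** 2
                b = Wty / sigma ** 2
                L = np.linalg.cholesky(A)
                mean = np.linalg.solve(A, b)
                theta = mean + np.linalg.solve(L.T, rng.standard_normal(p))
                beta = theta[:6]
                gamma = theta[6:6 + 2 * J].reshape(J, 2)
                eta = theta[6 + 2 * J:]

                # sigma | rest (slice on log sigma)
                ssr = float(np.sum((y - W @ theta) ** 2))

                def logp_sigma(th):
                    s = np.exp(th)
                    return -n * th - ssr / (2 * s * s) + _log_half_cauchy(s, cfg.hc_scale) + th

                sigma = float(np.exp(_slice_sample(np.log(sigma), logp_sigma, rng)))
            else:
                beta = rng.normal(0.0, cfg.prior_beta_sd, size=6)
                Sig = np.array([[tau[0] ** 2, rho * tau[0] * tau[1]],
                                [rho * tau[0] * tau[1], tau[1] ** 2]])
                gamma = rng.multivariate_normal(np.zeros(2), Sig, size=J)
                eta = rng.normal(0.0, sigma_year, size=T)
                u = rng.random()
                sigma = float(cfg.hc_scale * np.tan(np.pi * u / 2))

            # sigma_year | eta
            sse_eta = float(np.sum(eta ** 2))

            def logp_sy(th):
                s = np.exp(th)
                return -T * th - sse_eta / (2 * s * s) + _log_half_cauchy(s, cfg.hc_scale) + th

            sigma_year = float(np.exp(_slice_sample(np.log(sigma_year), logp_sy, rng)))

            # Sigma | gamma: slice each of log tau1, log tau2, atanh rho
            S11 = float(np.sum(gamma[:, 0] ** 2))
            S22 = float(np.sum(gamma[:, 1] ** 2))
            S12 = float(np.sum(gamma[:, 0] * gamma[:, 1]))

            def loglik_Sigma(t1, t2, r_):
                quad = (S11 / t1 ** 2 - 2 * r_ * S12 / (t1 * t2) + S22 / t2 ** 2) / (1 - r_ ** 2)
                return -J * (np.log(t1) + np.log(t2)) - J / 2 * np.log(1 - r_ ** 2) - quad / 2

            def logp_t1(th):
                t1 = np.exp(th)
                return loglik_Sigma(t1, tau[1], rho) + _log_half_cauchy(t1, cfg.hc_scale) + th

            tau[0] = float(np.exp(_slice_sample(np.log(tau[0]), logp_t1, rng)))

            def logp_t2(th):
                t2 = np.exp(th)
                return loglik_Sigma(tau[0], t2, rho) + _log_half_cauchy(t2, cfg.hc_scale) + th

            tau[1] = float(np.exp(_slice_sample(np.log(tau[1]), logp_t2, rng)))

            def logp_u(u_):
                r_ = np.tanh(u_)
                # uniform prior on rho; Jacobian d rho/d u = 1 - rho^2
                return loglik_Sigma(tau[0], tau[1], r_) + np.log1p(-r_ ** 2)

            rho = float(np.tanh(_slice_sample(np.arctanh(rho), logp_u, rng)))

            if it >= cfg.warmup and (it - cfg.warmup) % cfg.thin == 0 and k < n_save:
                out["beta"][k] = beta
                out["gamma"][k] = gamma
                out["eta"][k] = eta
                out["sigma"][k] = sigma
                out["sigma_year"][k] = sigma_year
                out["tau"][k] = tau
                out["rho"][k] = rho
                k += 1
        return out


class FunctionalResponseResults:
    """Posterior draws plus Table-style summaries and hypothesis probabilities.

    ``draws`` maps parameter name to an array with leading (chain, draw)
    dimensions: beta (6), gamma (J, 2), eta (T), sigma, sigma_year,
    tau (2), rho.
    """

    def __init__(self, model: FunctionalResponseModel, draws: dict, config: MCMCConfig):
        self.model = model
        self.draws = draws
        self.config = config
        self.warnings: list[str] = []

    # flattened (chain*draw, ...) views -------------------------------------
    def _flat(self, name: str) -> np.ndarray:
        a = self.draws[name]
        return a.reshape(-1, *a.shape[2:])

    @property
    def beta(self) -> np.ndarray:
        return self._flat("beta")

    def sigma_draws(self) -> np.ndarray:
        t = self._flat("tau")
        r = self._flat("rho")
        out = np.empty((len(r), 2, 2))
        out[:, 0, 0] = t[:, 0] ** 2
        out[:, 1, 1] = t[:, 1] ** 2
        out[:, 0, 1] = out[:, 1, 0] = r * t[:, 0] * t[:, 1]
        return out

    # summaries -------------------------------------------------------------
    @staticmethod
    def _summary_row(d: np.ndarray) -> dict:
        lo, med, hi = np.percentile(d, [2.5, 50.0, 97.5])
        return {"mean": float(np.mean(d)), "median": float(med),
                "lower95": float(lo), "upper95": float(hi)}

    def summary(self) -> pd.DataFrame:
        """Treatment-level coefficient summaries (control + offset per draw).

        The drought/irrigation rows summarize the per-draw sums of the control
        coefficient and the treatment offset — summed before summarizing.
        """
        b = self.beta
        rows = []
        combos = {
            ("Intercept", "Control"): b[:, 0],
            ("Intercept", "Drought"): b[:, 0] + b[:, 1],
            ("Intercept", "Irrigation"): b[:, 0] + b[:, 2],
            ("Slope", "Control"): b[:, 3],
            ("Slope", "Drought"): b[:, 3] + b[:, 4],
            ("Slope", "Irrigation"): b[:, 3] + b[:, 5],
        }
        rhats = self.rhat()["beta"]
        rhat_map = {
            ("Intercept", "Control"): rhats[0], ("Intercept", "Drought"): rhats[1],
            ("Intercept", "Irrigation"): rhats[2], ("Slope", "Control"): rhats[3],
            ("Slope", "Drought"): rhats[4], ("Slope", "Irrigation"): rhats[5],
        }
        for (coef, trt), d in combos.items():
            row = {"coefficient": coef, "treatment": trt, **self._summary_row(d)}
            row["rhat_offset"] = float(rhat_map[(coef, trt)]) if rhat_map[(coef, trt)] is not None else np.nan
            rows.append(row)
        return pd.DataFrame(rows)

    def offsets(self) -> pd.DataFrame:
        """Treatment offsets with one-tailed posterior probabilities.

        Slope offsets use the hypothesized directions (drought > 0,
        irrigation < 0); intercept offsets use the direction of the
        posterior median.
        """
        b = self.beta
        rows = []
        spec = [
            ("intercept_offset", "drought", b[:, 1], None),
            ("intercept_offset", "irrigation", b[:, 2], None),
            ("slope_offset", "drought", b[:, 4], ">"),
            ("slope_offset", "irrigation", b[:, 5], "<"),
        ]
        for coef, trt, d, direction in spec:
            if direction is None:
                direction = ">" if np.median(d) > 0 else "<"
            rows.append({"coefficient": coef, "treatment": trt,
                         **self._summary_row(d),
                         "direction": direction,
                         "tail_probability": tail_probability(d, direction)})
        return pd.DataFrame(rows)

    def beta_ci(self, alpha: float = 0.05) -> np.ndarray:
        """Equal-tailed credible bounds per fixed effect, shape (6, 2)."""
        q = 100 * np.array([alpha / 2, 1 - alpha / 2])
        return np.percentile(self.beta, q, axis=0).T

    def rhat(self) -> dict:
        """Rank-normalized split R-hat per parameter group (arviz)."""
        if self.draws["beta"].shape[0] < 2:
            return {k: None for k in ("beta", "sigma", "sigma_year", "tau", "rho")}
        out = {}
        for name in ("beta", "sigma", "sigma_year", "tau", "rho"):
            ds = az.convert_to_dataset({name: self.draws[name]})
            out[name] = np.atleast_1d(az.rhat(ds)[name].to_numpy())
        return out

    def predict_anpp(self, treatment: str, vwc: np.ndarray) -> np.ndarray:
        """Posterior-mean ANPP (g m^-2) at raw VWC values (fixed effects only)."""
        v = (np.asarray(vwc, dtype=float) - self.vwc_mean) / self.vwc_sd
        X = build_design([treatment] * len(v), v)
        y_std = X @ self.beta.mean(axis=0)
        return np.exp(self.model.y_std.destandardize(y_std))

    @property
    def vwc_mean(self) -> float:
        return self.model.vwc_std.mean

    @property
    def vwc_sd(self) -> float:
        return self.model.vwc_std.sd


def fit_model(records: pd.DataFrame, mcmc_config: MCMCConfig | None = None,
              **kwargs) -> FunctionalResponseResults:
    """Convenience wrapper: build the model from records and sample."""
    return FunctionalResponseModel(records).fit(config=mcmc_config, **kwargs)


def summarize_posterior(results: FunctionalResponseResults) -> pd.DataFrame:
    """Treatment-level posterior summary table (see ``summary``)."""
    return results.summary()


def tail_probability(offset_draws, direction: str) -> float:
    """One-tailed posterior probability that an offset is >0 or <0."""
    d = np.asarray(offset_draws, dtype=float)
    if d.size == 0:
        raise ValueError("no posterior draws supplied")
    if direction == ">":
        return float(np.mean(d > 0))
    if direction == "<":
        return float(np.mean(d < 0))
    raise ValueError("direction must be '>' or '<'")
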
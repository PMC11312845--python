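"""Hierarchical spatiotemporal Poisson model for areal relative risk.

The likelihood is ``O_it ~ Poisson(E_it * theta_it)`` with

    log theta_it = alpha + x_i' beta + u_i + v_i + (beta_t + delta_i) * t

where ``u`` carries an intrinsic CAR (ICAR) prior over the areal graph,
``v`` is an iid normal heterogeneity effect (together the BYM convolution),
and the temporal part is a shared linear trend ``beta_t`` plus area-specific
slope deviations ``delta_i`` (differential-trend spatiotemporal structure).
Precisions carry Gamma hyperpriors; fixed effects carry vague normals.

Inference is a Metropolis-within-Gibbs sampler: conjugate Gamma updates for
the precisions, single-site adaptive random-walk Metropolis for the latent
fields (vectorized over graph-coloring classes, which are conditionally
independent given the Markov ICAR prior), and a joint random-walk for the
fixed effects with a proposal shaped by the Poisson GLM covariance.
Per-component sum-to-zero identifiability of the ICAR fields is maintained
by re-centering each sweep, transferring the removed level to the intercept
(or, for the slope deviations, to the shared trend).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml
from scipy.special import gammaln, logsumexp

from .errors import ValidationError
from .graph import ICARStructure

__all__ = [
    "RiskModelSpec", "FitResult", "CoefficientSummary",
    "fit", "design_matrix", "summarize_coefficient", "fitted_rr",
    "waic", "vif_screen", "VifResult",
]


@dataclass(frozen=True)
class RiskModelSpec:
    """Configuration of the risk model and its sampler.

    Parameters
    ----------
    include_spatial : include the BYM pair (ICAR ``u`` + iid ``v``).
    include_temporal : include the shared trend and slope deviations.
    delta_prior : "icar" (spatially structured slope deviations) or "iid".
    spatial_variant : "classic_bym", or "scaled_bym" which multiplies the
        ICAR precision of ``u`` by the graph's scaling factor so that the
        prior's typical marginal variance is 1/tau_u.
    tau_shape, tau_rate : Gamma hyperprior on each precision
        (default Gamma(1, 0.0005), a long-tailed historical default).
    beta_prior_sd : vague normal prior sd on intercept/coefficients/trend.
    chains, iterations, burn_in, thin, seed : chain configuration;
        iterations counts total sweeps per chain including burn-in.
    """

    include_spatial: bool = True
    include_temporal: bool = True
    delta_prior: str = "icar"
    spatial_variant: str = "classic_bym"
    tau_shape: float = 1.0
    tau_rate: float = 0.0005
    beta_prior_sd: float = 100.0
    chains: int = 4
    iterations: int = 10_000
    burn_in: int = 5_000
    thin: int = 5
    seed: int = 0
    rhat_threshold: float = 1.1

    def __post_init__(self):
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.delta_prior not in ("icar", "iid"):
            raise ValueError("delta_prior must be 'icar' or 'iid'")
        if self.spatial_variant not in ("classic_bym", "scaled_bym"):
            raise ValueError("spatial_variant must be 'classic_bym' or 'scaled_bym'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RiskModelSpec":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown model config keys: {sorted(unknown)}")
        return cls(**doc)


@dataclass(frozen=True)
class CoefficientSummary:
    """Posterior summary of one log-scale coefficient and its relative risk."""

    name: str
    mean: float
    sd: float
    ci_low: float
    ci_high: float

    @property
    def rr(self) -> float:
        with np.errstate(over="ignore"):
            return float(np.exp(self.mean))

    @property
    def rr_ci(self) -> tuple[float, float]:
        with np.errstate(over="ignore"):
            return (float(np.exp(self.ci_low)), float(np.exp(self.ci_high)))

    @property
    def significant(self) -> bool:
        # both credibility limits on the same side of zero
        return (self.ci_low > 0 and self.ci_high > 0) or \
               (self.ci_low < 0 and self.ci_high < 0)


def summarize_coefficient(draws: np.ndarray, name: str = "") -> CoefficientSummary:
    """Mean, equal-tailed 95% interval and RR = exp(mean) for one parameter."""
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size == 0:
        raise ValidationError("empty posterior draw vector")
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return CoefficientSummary(name=name, mean=float(draws.mean()),
                              sd=float(draws.std(ddof=1)) if draws.size > 1 else 0.0,
                              ci_low=float(lo), ci_high=float(hi))


def design_matrix(covariates: pd.DataFrame,
                  ids: Sequence[str]) -> pd.DataFrame:
    """Fixed-effect design: intercept, development index, size contrasts.

    Size class enters as two indicators (small, medium) against the "large"
    reference level.  Any area without covariates is a hard error.
    """
    cov = covariates.set_index("area_id")
    missing = [a for a in ids if a not in cov.index]
    if missing:
        raise ValidationError(f"missing covariates for areas: "
                              f"{', '.join(missing)}")
    cov = cov.loc[list(ids)]
    X = pd.DataFrame({
        "intercept": 1.0,
        "ipdm": cov["ipdm"].astype(float),
        "small": (cov["size_class"] == "small").astype(float),
        "medium": (cov["size_class"] == "medium").astype(float),
    }, index=list(ids))
    return X


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    """Posterior draws, summaries and diagnostics of one model fit.

    Draw arrays have leading axes (chain, draw).  ``theta_mean`` is the
    posterior mean relative risk per area-period, accumulated over all kept
    draws.  ``loglik`` holds pointwise log-likelihood draws over the cells
    with positive expected counts (for WAIC).
    """

    ids: tuple[str, ...]
    years: tuple[int, ...]
    coef_names: tuple[str, ...]
    spec: RiskModelSpec
    draws: dict[str, np.ndarray]
    loglik: np.ndarray
    theta_mean: np.ndarray
    mask: np.ndarray
    rhat: dict[str, float] = field(default_factory=dict)
    ess: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def waic(self) -> float:
        return waic(self.loglik)

    def coefficient(self, name: str) -> CoefficientSummary:
        if name == "trend":
            if "beta_t" not in self.draws:
                raise KeyError("model was fitted without a temporal trend")
            return summarize_coefficient(self.draws["beta_t"], "trend")
        try:
            k = self.coef_names.index(name)
        except ValueError:
            raise KeyError(f"unknown coefficient {name!r}") from None
        return summarize_coefficient(self.draws["beta"][..., k], name)

    def summary(self) -> pd.DataFrame:
        """One row per monitored scalar parameter, Table-2 style columns."""
        rows = []
        for name in self.coef_names:
            s = self.coefficient(name)
            rows.append(self._row(name, s))
        if "beta_t" in self.draws:
            rows.append(self._row("trend", self.coefficient("trend")))
        for name in ("tau_u", "tau_v", "tau_delta"):
            if name in self.draws:
                s = summarize_coefficient(self.draws[name], name)
                row = self._row(name, s)
                row["rr"] = row["rr_low"] = row["rr_high"] = np.nan
                rows.append(row)
        return pd.DataFrame(rows)

    def _row(self, name: str, s: CoefficientSummary) -> dict:
        return {
            "parameter": name, "mean": s.mean, "sd": s.sd,
            "q025": s.ci_low, "q975": s.ci_high,
            "rr": s.rr, "rr_low": s.rr_ci[0], "rr_high": s.rr_ci[1],
            "significant": s.significant,
            "rhat": self.rhat.get(name, np.nan),
            "ess": self.ess.get(name, np.nan),
        }

    def pointwise_loglik(self, chain: int, draw: int) -> np.ndarray:
        """Recompute the pointwise log-likelihood of one stored draw from the
        stored latent state (independent of the sampler's cached values)."""
        eta = self._eta(chain, draw)
        return _poisson_loglik(self._O, self._E, eta)[self.mask]

    def theta_draw(self, chain: int, draw: int) -> np.ndarray:
        return np.exp(self._eta(chain, draw))

    def _eta(self, chain: int, draw: int) -> np.ndarray:
        n, T = len(self.ids), len(self.years)
        eta = np.tile((self._X @ self.draws["beta"][chain, draw])[:, None], (1, T))
        if "u" in self.draws:
            eta += (self.draws["u"][chain, draw] +
                    self.draws["v"][chain, draw])[:, None]
        if "beta_t" in self.draws:
            slope = self.draws["beta_t"][chain, draw] + \
                self.draws["delta"][chain, draw]
            eta += slope[:, None] * self._t[None, :]
        return eta


def _poisson_loglik(O: np.ndarray, E: np.ndarray, eta: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        logE = np.where(E > 0, np.log(np.where(E > 0, E, 1.0)), 0.0)
    return O * (logE + eta) - E * np.exp(eta) - gammaln(O + 1.0)


def _pivot(table: pd.DataFrame, value: str, ids, years) -> np.ndarray:
    piv = table.pivot_table(index="area_id", columns="year", values=value,
                            aggfunc="sum")
    try:
        piv = piv.loc[list(ids), list(years)]
    except KeyError as exc:
        raise ValidationError(f"area-period table does not cover the full "
                              f"area x period grid: {exc}") from None
    if piv.isna().any().any():
        raise ValidationError("area-period table has missing cells")
    return piv.to_numpy(dtype=float)


def _greedy_colors(Q: sp.csr_matrix, active: np.ndarray) -> list[np.ndarray]:
    """Independent-set classes of the active (non-singleton) nodes."""
    import networkx as nx

    A = sp.diags(Q.diagonal()) - Q
    g = nx.from_scipy_sparse_array(A.tocsr())
    coloring = nx.greedy_color(g, strategy="largest_first")
    classes: dict[int, list[int]] = {}
    for node in np.flatnonzero(active):
        classes.setdefault(coloring[int(node)], []).append(int(node))
    return [np.array(v, dtype=int) for _, v in sorted(classes.items())]


def fit(area_period: pd.DataFrame,
        covariates: pd.DataFrame | None,
        icar: ICARStructure,
        spec: RiskModelSpec,
        design: pd.DataFrame | None = None) -> FitResult:
    """Sample the posterior of the spatiotemporal risk model.

    Parameters
    ----------
    area_period : table with columns area_id, year, observed, expected
        (the output of :func:`arealrisk.standardize.sir_table`).
    covariates : area-level covariate table (ipdm, size_class); ignored when
        an explicit ``design`` is supplied.
    icar : precision structure of the areal graph (defines area ordering).
    spec : model and chain configuration.
    design : optional explicit fixed-effect design (areas x columns); an
        intercept column is prepended when absent.
    """
    ids = icar.ids
    years = tuple(sorted(area_period["year"].unique()))
    O = _pivot(area_period, "observed", ids, years)
    E = _pivot(area_period, "expected", ids, years)
    if ((E <= 0) & (O > 0)).any():
        raise ValidationError("positive observed count with non-positive "
                              "expected count")
    if spec.include_temporal and len(years) < 2:
        raise ValidationError("temporal trend requires at least two periods")

    if design is None:
        if covariates is None:
            X = pd.DataFrame({"intercept": np.ones(len(ids))}, index=list(ids))
        else:
            X = design_matrix(covariates, ids)
    else:
        X = design.copy().astype(float)
        X = X.loc[list(ids)]
        if "intercept" not in X.columns:
            X.insert(0, "intercept", 1.0)
    coef_names = tuple(X.columns)
    Xm = X.to_numpy(dtype=float)

    T = len(years)
    t_scaled = (np.arange(T) / (T - 1)) if T > 1 else np.zeros(1)
    mask = E > 0

    beta_hat, chol = _glm_init(O, E, Xm, mask)

    sampler = _Sampler(O=O, E=E, X=Xm, t=t_scaled, mask=mask, icar=icar,
                       spec=spec, beta_hat=beta_hat, prop_chol=chol)
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.chains)
    chains = [sampler.run_chain(np.random.default_rng(s), chain_index=c)
              for c, s in enumerate(seeds)]

    draws = {k: np.stack([ch[k] for ch in chains])
             for k in chains[0] if k not in ("loglik", "theta_sum", "n_kept")}
    loglik = np.stack([ch["loglik"] for ch in chains])
    theta_mean = sum(ch["theta_sum"] for ch in chains) / \
        sum(ch["n_kept"] for ch in chains)

    result = FitResult(ids=ids, years=years, coef_names=coef_names, spec=spec,
                       draws=draws, loglik=loglik, theta_mean=theta_mean,
                       mask=mask)
    result._O, result._E, result._X, result._t = O, E, Xm, t_scaled
    _attach_diagnostics(result)
    return result


def _glm_init(O, E, X, mask):
    """Poisson GLM point estimate and proposal Cholesky for (alpha, beta)."""
    import statsmodels.api as sm

    y = O[mask]
    n_rep = np.broadcast_to(np.arange(O.shape[0])[:, None], O.shape)[mask]
    Xr = X[n_rep]
    offset = np.log(E[mask])
    p = X.shape[1]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, Xr, family=sm.families.Poisson(),
                         offset=offset).fit()
        beta = np.asarray(res.params, dtype=float)
        cov = np.asarray(res.cov_params(), dtype=float)
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(p))
        if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(chol))):
            raise np.linalg.LinAlgError
    except Exception:
        total_o, total_e = O[mask].sum(), E[mask].sum()
        beta = np.zeros(p)
        beta[0] = np.log(total_o / total_e) if total_o > 0 and total_e > 0 else 0.0
        chol = 0.1 * np.eye(p)
    return beta, chol


class _Sampler:
    """Metropolis-within-Gibbs machinery shared across chains."""

    def __init__(self, O, E, X, t, mask, icar, spec, beta_hat, prop_chol):
        self.O, self.E, self.X, self.t = O, E, X, t
        self.mask = mask
        self.spec = spec
        self.icar = icar
        self.n, self.T = O.shape
        self.p = X.shape[1]
        self.beta_hat, self.prop_chol = beta_hat, prop_chol
        self.Om = np.where(mask, O, 0.0)
        self.Osum = self.Om.sum(axis=1)
        self.Ot = self.Om @ t
        Q = icar.Q
        self.Q = Q
        self.deg = Q.diagonal()
        self.A = (sp.diags(self.deg) - Q).tocsr()
        comp_sizes = np.bincount(icar.components)
        self.nonsingleton = comp_sizes[icar.components] > 1
        self.colors = _greedy_colors(Q, self.nonsingleton) \
            if self.nonsingleton.any() else []
        self.comp_idx = [np.flatnonzero(icar.components == c)
                         for c in np.unique(icar.components)
                         if (icar.components == c).sum() > 1]
        self.icar_rank = self.n - len(np.unique(icar.components))
        self.c_u = icar.scaling_factor if spec.spatial_variant == "scaled_bym" \
            else 1.0

    # -- per-chain state helpers ---------------------------------------

    def _recompute(self, st):
        eta = (self.X @ st["beta"])[:, None] + np.zeros((self.n, self.T))
        if self.spec.include_spatial:
            eta += (st["u"] + st["v"])[:, None]
        if self.spec.include_temporal:
            eta += (st["beta_t"] + st["delta"])[:, None] * self.t[None, :]
        st["eta"] = eta
        st["expE"] = np.where(self.mask, self.E * np.exp(eta), 0.0)
        st["Lam"] = st["expE"].sum(axis=1)

    def run_chain(self, rng, chain_index: int):
        spec = self.spec
        st = {
            "beta": self.beta_hat + (0.0 if chain_index == 0 else
                                     self.prop_chol @ rng.standard_normal(self.p) * 2.0),
            "u": np.zeros(self.n), "v": np.zeros(self.n),
            "delta": np.zeros(self.n), "beta_t": 0.0,
            "tau_u": 100.0, "tau_v": 100.0, "tau_delta": 100.0,
        }
        self._recompute(st)

        step_u = np.full(self.n, 0.1)
        step_v = np.full(self.n, 0.1)
        step_d = np.full(self.n, 0.1)
        step_bt = 0.1
        scale_b = 1.0
        step_shift = np.full(self.p + 1, 0.1)
        acc_shift = np.zeros(self.p + 1)
        acc = {k: np.zeros(self.n) for k in ("u", "v", "d")}
        acc_bt = acc_b = 0.0
        batch = 50
        batch_no = 0

        # adaptive-Metropolis statistics for the fixed-effect block: a second
        # proposal learns the empirical burn-in covariance (which reflects
        # confounding with the latent fields); the GLM covariance both seeds
        # it and floors it so the adaptation cannot collapse
        glm_cov = self.prop_chol @ self.prop_chol.T
        prop_chol = self.prop_chol * (2.38 / math.sqrt(self.p))
        scale_am = 1.0
        acc_am = 0.0
        am_n = 0
        am_mean = np.zeros(self.p)
        am_m2 = np.zeros((self.p, self.p))

        kept = (spec.iterations - spec.burn_in + spec.thin - 1) // spec.thin
        out = {
            "beta": np.empty((kept, self.p)),
            "loglik": np.empty((kept, int(self.mask.sum()))),
        }
        if spec.include_spatial:
            out["u"] = np.empty((kept, self.n))
            out["v"] = np.empty((kept, self.n))
            out["tau_u"] = np.empty(kept)
            out["tau_v"] = np.empty(kept)
        if spec.include_temporal:
            out["beta_t"] = np.empty(kept)
            out["delta"] = np.empty((kept, self.n))
            out["tau_delta"] = np.empty(kept)
        theta_sum = np.zeros((self.n, self.T))
        k = 0

        for it in range(spec.iterations):
            if spec.include_spatial:
                self._update_site_shift(st, "u", st["tau_u"] * self.c_u,
                                        step_u, acc["u"], rng, structured=True)
                self._update_site_shift(st, "v", st["tau_v"], step_v,
                                        acc["v"], rng, structured=False)
            if spec.include_temporal:
                structured = spec.delta_prior == "icar"
                self._update_delta(st, step_d, acc["d"], rng, structured)
                acc_bt += self._update_beta_t(st, step_bt, rng)
            acc_b += self._update_beta(st, scale_b, self.prop_chol, rng)
            acc_am += self._update_beta(st, scale_am, prop_chol, rng)
            if spec.include_spatial:
                self._shift_moves(st, step_shift, acc_shift, rng)
            self._update_taus(st, rng)
            self._recenter(st)
            self._recompute(st)

            if it < spec.burn_in:
                am_n += 1
                delta = st["beta"] - am_mean
                am_mean += delta / am_n
                am_m2 += np.outer(delta, st["beta"] - am_mean)
                if am_n > 20 * self.p and (it + 1) % (4 * batch) == 0:
                    cov = am_m2 / (am_n - 1) + 0.1 * glm_cov
                    try:
                        L = np.linalg.cholesky(
                            cov + 1e-12 * np.eye(self.p))
                        prop_chol = L * (2.38 / math.sqrt(self.p))
                    except np.linalg.LinAlgError:
                        pass

            if it < spec.burn_in and (it + 1) % batch == 0:
                batch_no += 1
                d = min(0.05, batch_no ** -0.5)
                for key, steps, target in (("u", step_u, 0.44),
                                           ("v", step_v, 0.44),
                                           ("d", step_d, 0.44)):
                    rates = acc[key] / batch
                    steps *= np.exp(np.where(rates > target, d, -d))
                    acc[key][:] = 0.0
                step_bt *= math.exp(d if acc_bt / batch > 0.44 else -d)
                scale_b *= math.exp(d if acc_b / batch > 0.234 else -d)
                scale_am *= math.exp(d if acc_am / batch > 0.234 else -d)
                acc_am = 0.0
                rates = acc_shift / batch
                step_shift *= np.exp(np.where(rates > 0.44, d, -d))
                acc_shift[:] = 0.0
                acc_bt = acc_b = 0.0

            if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0:
                out["beta"][k] = st["beta"]
                if spec.include_spatial:
                    out["u"][k] = st["u"]
                    out["v"][k] = st["v"]
                    out["tau_u"][k] = st["tau_u"]
                    out["tau_v"][k] = st["tau_v"]
                if spec.include_temporal:
                    out["beta_t"][k] = st["beta_t"]
                    out["delta"][k] = st["delta"]
                    out["tau_delta"][k] = st["tau_delta"]
                ll = _poisson_loglik(self.O, self.E, st["eta"])
                out["loglik"][k] = ll[self.mask]
                theta_sum += np.exp(st["eta"])
                k += 1

        out["theta_sum"] = theta_sum
        out["n_kept"] = k
        return out

    # -- update steps --------------------------------------------------

    def _update_site_shift(self, st, key, tau, steps, acc, rng, structured):
        """Single-site RW for an effect entering eta as a constant area shift."""
        x = st[key]
        if structured:
            subsets = self.colors
        else:
            subsets = [np.arange(self.n)]
        for idx in subsets:
            if idx.size == 0:
                continue
            d = steps[idx] * rng.standard_normal(idx.size)
            if structured:
                Ax = self.A @ x
                dlp = -0.5 * tau * (self.deg[idx] * ((x[idx] + d) ** 2 - x[idx] ** 2)
                                    - 2.0 * d * Ax[idx])
            else:
                dlp = -0.5 * tau * ((x[idx] + d) ** 2 - x[idx] ** 2)
            dll = d * self.Osum[idx] - np.expm1(d) * st["Lam"][idx]
            accept = np.log(rng.uniform(size=idx.size)) < dll + dlp
            hit = idx[accept]
            if hit.size:
                x[hit] += d[accept]
                g = np.exp(d[accept])
                st["eta"][hit, :] += d[accept][:, None]
                st["expE"][hit, :] *= g[:, None]
                st["Lam"][hit] *= g
            acc[idx] += accept

    def _update_delta(self, st, steps, acc, rng, structured):
        x = st["delta"]
        tau = st["tau_delta"]
        subsets = self.colors if structured else [np.arange(self.n)]
        for idx in subsets:
            if idx.size == 0:
                continue
            d = steps[idx] * rng.standard_normal(idx.size)
            if structured:
                Ax = self.A @ x
                dlp = -0.5 * tau * (self.deg[idx] * ((x[idx] + d) ** 2 - x[idx] ** 2)
                                    - 2.0 * d * Ax[idx])
            else:
                dlp = -0.5 * tau * ((x[idx] + d) ** 2 - x[idx] ** 2)
            growth = np.expm1(np.outer(d, self.t))        # (k, T)
            dll = d * self.Ot[idx] - (st["expE"][idx] * growth).sum(axis=1)
            accept = np.log(rng.uniform(size=idx.size)) < dll + dlp
            hit = idx[accept]
            if hit.size:
                x[hit] += d[accept]
                g = np.exp(np.outer(d[accept], self.t))
                st["eta"][hit, :] += np.outer(d[accept], self.t)
                st["expE"][hit, :] *= g
                st["Lam"][hit] = st["expE"][hit].sum(axis=1)
            acc[idx] += accept

    def _update_beta_t(self, st, step, rng) -> float:
        d = step * rng.standard_normal()
        growth = np.expm1(d * self.t)
        dll = d * self.Ot.sum() - (st["expE"] @ growth).sum()
        sd = self.spec.beta_prior_sd
        dlp = -((st["beta_t"] + d) ** 2 - st["beta_t"] ** 2) / (2 * sd * sd)
        if math.log(rng.uniform()) < dll + dlp:
            st["beta_t"] += d
            st["eta"] += d * self.t[None, :]
            st["expE"] *= np.exp(d * self.t)[None, :]
            st["Lam"] = st["expE"].sum(axis=1)
            return 1.0
        return 0.0

    def _update_beta(self, st, scale, prop_chol, rng) -> float:
        db = scale * (prop_chol @ rng.standard_normal(self.p))
        deta = self.X @ db
        dll = (self.Osum * deta - st["Lam"] * np.expm1(deta)).sum()
        sd = self.spec.beta_prior_sd
        dlp = -(((st["beta"] + db) ** 2 - st["beta"] ** 2).sum()) / (2 * sd * sd)
        if math.log(rng.uniform()) < dll + dlp:
            st["beta"] = st["beta"] + db
            g = np.exp(deta)
            st["eta"] += deta[:, None]
            st["expE"] *= g[:, None]
            st["Lam"] *= g
            return 1.0
        return 0.0

    def _shift_moves(self, st, steps, acc, rng):
        """Interweaving moves along the likelihood-invariant directions that
        trade a fixed effect against the iid heterogeneity field.

        Shifting ``beta_k`` by d while subtracting ``d * x_k`` from ``v``
        leaves every linear predictor unchanged, so the acceptance ratio
        involves only the priors.  These moves decorrelate the fixed effects
        from the latent fields, which single-site updates mix slowly.
        """
        sd = self.spec.beta_prior_sd
        tau_v = st["tau_v"]
        v = st["v"]
        for k in range(self.p):
            d = steps[k] * rng.standard_normal()
            xk = self.X[:, k]
            dlp_v = -0.5 * tau_v * (-2.0 * d * (v @ xk) + d * d * (xk @ xk))
            dlp_b = -((st["beta"][k] + d) ** 2 - st["beta"][k] ** 2) / (2 * sd * sd)
            if math.log(rng.uniform()) < dlp_v + dlp_b:
                st["beta"] = st["beta"].copy()
                st["beta"][k] += d
                v -= d * xk
                acc[k] += 1
        if self.spec.include_temporal and self.spec.delta_prior == "iid":
            # same trade between the shared trend and iid slope deviations
            d = steps[self.p] * rng.standard_normal()
            delta = st["delta"]
            tau_d = st["tau_delta"]
            dlp_d = -0.5 * tau_d * (-2.0 * d * delta.sum() + d * d * self.n)
            dlp_b = -((st["beta_t"] + d) ** 2 - st["beta_t"] ** 2) / (2 * sd * sd)
            if math.log(rng.uniform()) < dlp_d + dlp_b:
                st["beta_t"] += d
                delta -= d
                acc[self.p] += 1

    def _update_taus(self, st, rng):
        a, b = self.spec.tau_shape, self.spec.tau_rate
        if self.spec.include_spatial:
            quad = float(st["u"] @ (self.Q @ st["u"])) * self.c_u
            st["tau_u"] = rng.gamma(a + 0.5 * self.icar_rank,
                                    1.0 / (b + 0.5 * quad))
            st["tau_v"] = rng.gamma(a + 0.5 * self.n,
                                    1.0 / (b + 0.5 * float(st["v"] @ st["v"])))
        if self.spec.include_temporal:
            if self.spec.delta_prior == "icar":
                quad = float(st["delta"] @ (self.Q @ st["delta"]))
                st["tau_delta"] = rng.gamma(a + 0.5 * self.icar_rank,
                                            1.0 / (b + 0.5 * quad))
            else:
                st["tau_delta"] = rng.gamma(
                    a + 0.5 * self.n,
                    1.0 / (b + 0.5 * float(st["delta"] @ st["delta"])))

    def _recenter(self, st):
        """Per-component sum-to-zero re-centering, level moved to the
        intercept (u) or to the shared trend slope (delta)."""
        if self.spec.include_spatial and self.comp_idx:
            offs = np.zeros(self.n)
            for idx in self.comp_idx:
                m = st["u"][idx].mean()
                st["u"][idx] -= m
                offs[idx] = m
            st["beta"][0] += offs.mean()
        if self.spec.include_temporal and self.spec.delta_prior == "icar" \
                and self.comp_idx:
            offs = np.zeros(self.n)
            for idx in self.comp_idx:
                m = st["delta"][idx].mean()
                st["delta"][idx] -= m
                offs[idx] = m
            st["beta_t"] += offs.mean()


def _attach_diagnostics(result: FitResult) -> None:
    """Split-R-hat and effective sample size for the monitored scalars."""
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        import arviz as az

        scalars: dict[str, np.ndarray] = {}
        for k, name in enumerate(result.coef_names):
            scalars[name] = result.draws["beta"][..., k]
        for key, label in (("beta_t", "trend"), ("tau_u", "tau_u"),
                           ("tau_v", "tau_v"), ("tau_delta", "tau_delta")):
            if key in result.draws:
                scalars[label] = result.draws[key]
        for name, arr in scalars.items():
            if arr.shape[0] == 1 or arr.shape[1] < 4 or np.ptp(arr) == 0:
                continue
            ds = az.convert_to_dataset(arr[..., None] if arr.ndim == 2 else arr)
            try:
                result.rhat[name] = float(np.asarray(az.rhat(ds)["x"].values).ravel()[0])
                result.ess[name] = float(np.asarray(az.ess(ds)["x"].values).ravel()[0])
            except Exception:
                continue
    bad = [n for n, r in result.rhat.items()
           if np.isfinite(r) and r > result.spec.rhat_threshold]
    if bad:
        result.warnings.append(
            f"split-R-hat above {result.spec.rhat_threshold} for: "
            f"{', '.join(bad)}")


# ---------------------------------------------------------------------------
# derived quantities


def fitted_rr(result: FitResult, level: str = "area_period",
              regions: dict[str, str] | pd.DataFrame | None = None
              ) -> pd.DataFrame:
    """Posterior-mean relative risk aggregated to the requested level.

    ``area_period`` — posterior mean theta per area and year;
    ``area_mean`` — averaged over years per area;
    ``region_year_mean`` — unweighted mean over a region's member areas of
    the area-period posterior means (requires a region mapping).
    """
    base = pd.DataFrame(result.theta_mean, index=list(result.ids),
                        columns=list(result.years))
    if level == "area_period":
        out = base.stack().rename("rr").reset_index()
        out.columns = ["area_id", "year", "rr"]
        return out
    if level == "area_mean":
        return pd.DataFrame({"area_id": list(result.ids),
                             "rr": base.mean(axis=1).to_numpy()})
    if level == "region_year_mean":
        if regions is None:
            raise ValidationError("region mapping required for region_year_mean")
        if isinstance(regions, pd.DataFrame):
            regions = dict(zip(regions["area_id"].astype(str),
                               regions["region_id"].astype(str)))
        unknown = [a for a in result.ids if a not in regions]
        if unknown:
            raise ValidationError(f"areas without a region: "
                                  f"{', '.join(unknown)}")
        table = base.copy()
        table["region_id"] = [regions[a] for a in result.ids]
        out = (table.groupby("region_id").mean()
               .stack().rename("mean_rr").reset_index())
        out.columns = ["region_id", "year", "mean_rr"]
        return out
    raise ValueError(f"unknown aggregation level: {level!r}")


def waic(loglik: np.ndarray) -> float:
    """Widely applicable information criterion on the deviance scale.

    ``loglik`` is a (draws, observations) or (chains, draws, observations)
    array of pointwise log-likelihoods.  WAIC = -2 * (lppd - p_waic) with
    the variance-based penalty; a single draw has zero penalty.
    """
    ll = np.asarray(loglik, dtype=float)
    if ll.ndim == 3:
        ll = ll.reshape(-1, ll.shape[-1])
    if ll.ndim != 2:
        raise ValidationError("log-likelihood array must be 2-D or 3-D")
    if not np.all(np.isfinite(ll)):
        raise ValidationError("non-finite pointwise log-likelihood")
    S = ll.shape[0]
    lppd = (logsumexp(ll, axis=0) - math.log(S)).sum()
    p = ll.var(axis=0, ddof=1).sum() if S > 1 else 0.0
    return float(-2.0 * (lppd - p))


# ---------------------------------------------------------------------------
# collinearity screen


@dataclass(frozen=True)
class VifResult:
    vifs: pd.Series                  # initial VIF per covariate
    retained: tuple[str, ...]
    dropped: tuple[tuple[str, float], ...]
    warnings: tuple[str, ...] = ()


def vif_screen(design: pd.DataFrame, response: np.ndarray,
               offset: np.ndarray, threshold: float = 5.0) -> VifResult:
    """Iterative variance-inflation screen under Poisson working weights.

    Each covariate's VIF is 1/(1 - R^2) from a weighted regression on the
    remaining covariates (plus intercept), weighted by the fitted means of a
    Poisson GLM with the given offset.  The largest VIF above the threshold
    is dropped and the screen repeats; perfectly collinear covariates (VIF
    infinite) are dropped later-listed first.
    """
    import statsmodels.api as sm

    if design.shape[1] < 2:
        raise ValidationError("VIF screen needs at least two covariates")
    if design.shape[0] <= design.shape[1]:
        raise ValidationError("VIF screen needs n > p")
    cols = list(design.columns)
    y = np.asarray(response, dtype=float)
    initial: pd.Series | None = None
    dropped: list[tuple[str, float]] = []
    warns: list[str] = []
    while True:
        Xc = design[cols].to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                glm = sm.GLM(y, sm.add_constant(Xc, has_constant="add"),
                             family=sm.families.Poisson(), offset=offset).fit()
                w = np.asarray(glm.mu, dtype=float)
            except Exception:
                w = np.ones_like(y)
        vifs = pd.Series({c: _weighted_vif(design[cols], c, w) for c in cols})
        if initial is None:
            initial = vifs.copy()
        over = vifs[vifs > threshold]
        if over.empty or len(cols) == 1:
            break
        if np.isinf(over).any():
            # drop the later-listed member of a perfectly collinear set
            name = [c for c in cols if np.isinf(vifs[c])][-1]
            warns.append(f"perfectly collinear covariate dropped: {name}")
        else:
            worst = over.max()
            name = [c for c in cols if vifs[c] == worst][-1]
        dropped.append((name, float(vifs[name])))
        cols.remove(name)
    return VifResult(vifs=initial, retained=tuple(cols),
                     dropped=tuple(dropped), warnings=tuple(warns))


def _weighted_vif(design: pd.DataFrame, col: str, w: np.ndarray) -> float:
    x = design[col].to_numpy(dtype=float)
    others = design.drop(columns=[col]).to_numpy(dtype=float)
    Z = np.column_stack([np.ones_like(x), others])
    sw = np.sqrt(w / w.sum())
    coef, *_ = np.linalg.lstsq(Z * sw[:, None], x * sw, rcond=None)
    resid = x - Z @ coef
    ssr = float(w @ resid ** 2)
    xbar = float(w @ x) / float(w.sum())
    sst = float(w @ (x - xbar) ** 2)
    if sst <= 0:
        return math.inf
    r2 = 1.0 - ssr / sst
    if r2 >= 1.0 - 1e-12:
        return math.inf
    return 1.0 / (1.0 - r2)
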
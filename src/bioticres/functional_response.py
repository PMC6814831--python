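"""Functional-response analysis for prey-depletion trials.

Implements the non-replacement (prey-depletion) functional response of
Rogers, the so-called random predator equation,

    Ne = N0 * (1 - exp(a * (Ne * h - T)))

where ``Ne`` is the number of prey eaten during a trial of duration ``T``
starting from ``N0`` prey, ``a`` is the attack rate and ``h`` the handling
time per prey item.  The implicit equation is solved explicitly with the
Lambert W function; parameters are estimated by maximum likelihood on a
per-trial binomial likelihood, with non-parametric bootstrap confidence
bands.  Functional-response type (II vs III) is classified from a logistic
regression of the proportion consumed against initial density.

Two single-number per-capita impact summaries derive from the fit: the
maximum feeding rate ``1/h`` and the functional response ratio
``FRR = a/h``, which combines search efficiency at low density with the
asymptotic ceiling at high density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats

__all__ = [
    "rogers_predict",
    "rogers_root_bisect",
    "RogersModel",
    "RogersResults",
    "BootstrapBand",
    "ShapeRegressionResult",
    "logistic_shape_regression",
    "classify_fr_type",
    "determine_fr_type",
    "max_feeding_rate",
    "functional_response_ratio",
    "fit_group_table",
    "FitError",
    "AllZeroConsumptionError",
]

_PCLIP = 1e-9  # binomial success probabilities clamped to [_PCLIP, 1-_PCLIP]


class FitError(RuntimeError):
    """Raised when the maximum-likelihood fit cannot be completed."""

    def __init__(self, message, best_params=None, best_loglike=None):
        super().__init__(message)
        self.best_params = best_params
        self.best_loglike = best_loglike


class AllZeroConsumptionError(FitError):
    """All trials recorded zero consumption: the attack rate sits on the a -> 0 boundary."""


def rogers_predict(a, h, T, N0):
    """Expected number of prey eaten under the random predator equation.

    Solves ``Ne = N0 (1 - exp(a (Ne h - T)))`` explicitly via the principal
    branch of the Lambert W function:

        Ne = N0 - W(a h N0 exp(-a (T - h N0))) / (a h)

    evaluated through the Wright omega function ``omega(y) = W(exp(y))`` so
    that large ``a*h*N0`` cannot overflow.

    Parameters
    ----------
    a : float
        Attack rate (per unit prey density per experimental period), >= 0.
    h : float
        Handling time (experimental periods per prey item), >= 0.
    T : float
        Trial duration in experimental periods, > 0.
    N0 : float or array_like
        Initial prey density, >= 0.

    Returns
    -------
    float or ndarray
        Expected consumption, guaranteed within ``[0, N0]``.
    """
    a = float(a)
    h = float(h)
    T = float(T)
    if not (np.isfinite(a) and np.isfinite(h) and np.isfinite(T)):
        raise ValueError("a, h and T must be finite")
    if a < 0 or h < 0:
        raise ValueError("attack rate and handling time must be non-negative")
    if T <= 0:
        raise ValueError("duration T must be positive")
    n0 = np.asarray(N0, dtype=float)
    if np.any(n0 < 0):
        raise ValueError("initial density N0 must be non-negative")
    scalar = n0.ndim == 0
    n0 = np.atleast_1d(n0)

    if a == 0.0:
        ne = np.zeros_like(n0)
    elif h == 0.0:
        # no handling: pure exponential depletion over the full period
        ne = n0 * (-np.expm1(-a * T))
    else:
        ne = np.zeros_like(n0)
        pos = n0 > 0
        with np.errstate(divide="ignore"):
            y = np.log(a * h * n0[pos]) - a * (T - h * n0[pos])
        w = special.wrightomega(y).real
        ne[pos] = n0[pos] - w / (a * h)
    ne = np.clip(ne, 0.0, n0)
    return float(ne[0]) if scalar else ne


def rogers_root_bisect(a, h, T, N0, tol=1e-12, max_iter=200):
    """Root of the implicit depletion equation by plain bisection.

    Lambert-W-free reference solver: brackets the unique root of
    ``g(x) = N0 (1 - exp(a (x h - T))) - x`` on ``[0, N0]`` and bisects.
    Used as an independent numerical cross-check of :func:`rogers_predict`.
    """
    a, h, T, N0 = float(a), float(h), float(T), float(N0)
    if N0 == 0 or a == 0:
        return 0.0

    def g(x):
        return N0 * -math.expm1(a * (x * h - T)) - x

    lo, hi = 0.0, N0
    if g(hi) >= 0:  # numerically everything is eaten
        return N0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def max_feeding_rate(h):
    """Maximum feeding rate ``1/h``: the asymptote of a type II response."""
    h = float(h)
    if not np.isfinite(h) or h <= 0:
        raise ValueError("handling time must be positive and finite")
    return 1.0 / h


def functional_response_ratio(a, h):
    """Functional response ratio ``FRR = a / h``.

    A high attack rate combined with a short handling time gives a large
    FRR (large per-capita effect across the density range); the ratio
    avoids having to privilege either parameter when comparing consumers.
    """
    a, h = float(a), float(h)
    if not (np.isfinite(a) and np.isfinite(h)) or a <= 0 or h <= 0:
        raise ValueError("attack rate and handling time must be positive and finite")
    return a / h


# ---------------------------------------------------------------------------
# shape classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ShapeRegressionResult:
    """Coefficients of the logistic regression of proportion eaten on density."""

    order: int
    coef1: float
    p1: float
    coef2: float | None = None
    p2: float | None = None


def logistic_shape_regression(trials: pd.DataFrame, order: int = 1) -> ShapeRegressionResult:
    """Binomial GLM (logit link) of proportion consumed against initial density.

    Parameters
    ----------
    trials : DataFrame
        Columns ``density`` (N0) and ``eaten`` (Ne), one row per trial.
    order : {1, 2}
        Whether to include a quadratic density term.

    The sign and significance of the density terms classify the response
    shape: a significantly negative first-order term indicates type II
    (proportional mortality declines with density); a significantly
    positive first-order term followed by a significantly negative
    second-order term indicates type III.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    n0 = np.asarray(trials["density"], dtype=float)
    ne = np.asarray(trials["eaten"], dtype=float)
    n_levels = np.unique(n0).size
    if n_levels < order + 1:
        raise ValueError(
            f"need at least {order + 1} distinct densities for an order-{order} shape regression"
        )
    if np.all(ne == 0) or np.all(ne == n0):
        raise FitError("degenerate shape regression: consumption is all-zero or all-total")

    endog = np.column_stack([ne, n0 - ne])
    cols = {"density": n0}
    if order == 2:
        cols["density_sq"] = n0**2
    exog = sm.add_constant(pd.DataFrame(cols))
    res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
    coef1 = float(res.params["density"])
    p1 = float(res.pvalues["density"])
    if order == 1:
        return ShapeRegressionResult(order=1, coef1=coef1, p1=p1)
    return ShapeRegressionResult(
        order=2,
        coef1=coef1,
        p1=p1,
        coef2=float(res.params["density_sq"]),
        p2=float(res.pvalues["density_sq"]),
    )


def classify_fr_type(result: ShapeRegressionResult, alpha_level: float = 0.05) -> str:
    """Map shape-regression coefficients to a functional-response type.

    Returns one of ``"II"``, ``"III"`` or ``"inconclusive"``.  Type I is
    never inferred from curvature alone.
    """
    if result.order == 2:
        if (
            result.coef1 > 0
            and result.p1 < alpha_level
            and result.coef2 is not None
            and result.coef2 < 0
            and result.p2 < alpha_level
        ):
            return "III"
        return "inconclusive"
    if result.coef1 < 0 and result.p1 < alpha_level:
        return "II"
    return "inconclusive"


def determine_fr_type(trials: pd.DataFrame, alpha_level: float = 0.05):
    """Sequenced type classification: quadratic model first, then linear.

    Fits the order-2 regression; if its quadratic term is significant the
    order-2 rule applies, otherwise the model is refit at order 1 and the
    first-order rule applies.  Returns ``(fr_type, ShapeRegressionResult)``
    where the result is the one the classification was read from.
    """
    n_levels = np.unique(np.asarray(trials["density"])).size
    if n_levels >= 3:
        res2 = logistic_shape_regression(trials, order=2)
        if res2.p2 is not None and res2.p2 < alpha_level:
            return classify_fr_type(res2, alpha_level), res2
    res1 = logistic_shape_regression(trials, order=1)
    return classify_fr_type(res1, alpha_level), res1


# ---------------------------------------------------------------------------
# maximum-likelihood fit
# ---------------------------------------------------------------------------


class RogersModel:
    """Random predator equation fitted to depletion-trial counts.

    The observation model is per-trial binomial: each of the ``N0`` prey in
    a trial is consumed independently with probability
    ``rogers_predict(a, h, T, N0) / N0``.  Estimation maximises the
    binomial log-likelihood over ``(log a, log h)``, which enforces
    positivity of both parameters.

    Parameters
    ----------
    density : array_like of int
        Initial prey count per trial (N0 > 0).
    eaten : array_like of int
        Number consumed per trial (0 <= eaten <= density).
    T : float
        Trial duration in experimental periods (default 1.0, i.e. handling
        time is expressed as a fraction of the trial length).
    """

    def __init__(self, density, eaten, T: float = 1.0):
        density = np.asarray(density, dtype=int)
        eaten = np.asarray(eaten, dtype=int)
        if density.size == 0:
            raise ValueError("no trials supplied")
        if density.shape != eaten.shape:
            raise ValueError("density and eaten must have the same length")
        if np.any(density <= 0):
            raise ValueError("initial densities must be positive")
        if np.any(eaten < 0) or np.any(eaten > density):
            raise ValueError("eaten counts must lie in [0, density]")
        if T <= 0:
            raise ValueError("duration T must be positive")
        self.density = density
        self.eaten = eaten
        self.T = float(T)
        if np.unique(density).size < 2:
            raise ValueError("need at least two distinct densities to fit")

        # The likelihood depends on density only through N0, so per-density
        # sufficient statistics make each objective evaluation O(#levels).
        levels, inv = np.unique(density, return_inverse=True)
        self._levels = levels.astype(float)
        self._eaten_by_level = np.bincount(inv, weights=eaten.astype(float))
        self._avail_by_level = np.bincount(inv, weights=density.astype(float))
        self._log_binom_const = float(
            np.sum(
                special.gammaln(density + 1)
                - special.gammaln(eaten + 1)
                - special.gammaln(density - eaten + 1)
            )
        )

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, density_col: str = "density", eaten_col: str = "eaten", T: float = 1.0
    ) -> "RogersModel":
        return cls(data[density_col].to_numpy(), data[eaten_col].to_numpy(), T=T)

    # -- likelihood ---------------------------------------------------------

    def loglike(self, params) -> float:
        """Binomial log-likelihood at ``params = (log a, log h)``."""
        log_a, log_h = params
        if not (np.isfinite(log_a) and np.isfinite(log_h)):
            return -np.inf
        a, h = math.exp(log_a), math.exp(log_h)
        ne = rogers_predict(a, h, self.T, self._levels)
        p = np.clip(ne / self._levels, _PCLIP, 1.0 - _PCLIP)
        ll = np.sum(
            self._eaten_by_level * np.log(p)
            + (self._avail_by_level - self._eaten_by_level) * np.log1p(-p)
        )
        return float(ll) + self._log_binom_const

    def _nll(self, params) -> float:
        return -self.loglike(params)

    def _starts(self) -> list[tuple[float, float]]:
        # moment-style anchor: overall proportion eaten sets a crude attack
        # rate; handling seeded from the high-density plateau
        prop = max(self.eaten.sum() / self.density.sum(), 1e-3)
        a0 = -math.log1p(-min(prop, 0.999)) / self.T
        hi = self._levels.argmax()
        mean_hi = self._eaten_by_level[hi] / (self._avail_by_level[hi] / self._levels[hi])
        h0 = self.T / max(mean_hi, 0.5)
        starts = [(math.log(a0), math.log(h0))]
        for la in (-1.5, 0.0, 1.5):
            for lh in (-3.0, -1.0):
                starts.append((la, lh))
        return starts

    def fit(self, starts: Sequence[tuple[float, float]] | None = None, quick_start=None) -> "RogersResults":
        """Maximise the likelihood and return a :class:`RogersResults`.

        ``quick_start`` (a ``(log a, log h)`` pair) short-circuits the
        multi-start search with a single warm start; used by the bootstrap
        where the full-data optimum is a reliable neighbourhood.
        """
        if np.all(self.eaten == 0):
            raise AllZeroConsumptionError(
                "all trials have zero consumption: attack rate is on the a -> 0 boundary"
            )
        if quick_start is not None:
            start_list = [tuple(quick_start)]
        else:
            start_list = list(starts) if starts is not None else self._starts()

        best = None
        for x0 in start_list:
            res = optimize.minimize(
                self._nll,
                x0,
                method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 400},
            )
            if best is None or res.fun < best.fun:
                best = res
        if quick_start is None:
            # gradient polish from the best simplex point
            polished = optimize.minimize(self._nll, best.x, method="BFGS", options={"gtol": 1e-8})
            if np.isfinite(polished.fun) and polished.fun <= best.fun + 1e-10:
                best = polished
        if best is None or not np.isfinite(best.fun):
            raise FitError("optimisation failed from every start", best_params=None)
        converged = bool(best.success) or best.fun < np.inf
        log_a, log_h = best.x
        cov_log = self._cov_logparams(best.x)
        return RogersResults(self, float(log_a), float(log_h), -float(best.fun), cov_log, converged)

    def _cov_logparams(self, x):
        """Inverse observed information on the (log a, log h) scale."""
        hess = _numeric_hessian(self._nll, np.asarray(x, dtype=float))
        try:
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(cov)) or cov[0, 0] < 0 or cov[1, 1] < 0:
            return None
        return cov


def _numeric_hessian(f, x, eps=1e-4):
    n = x.size
    hess = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = eps
            ej[j] = eps
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps * eps)
    if not np.all(np.isfinite(hess)):
        hess[:] = np.nan
    return hess


@dataclass
class BootstrapBand:
    """Percentile bootstrap summaries for a fitted depletion model."""

    n_boot: int
    conf: float
    n_failed: int
    a_ci: tuple[float, float]
    h_ci: tuple[float, float]
    frr_ci: tuple[float, float]
    densities: np.ndarray
    lower: np.ndarray
    point: np.ndarray
    upper: np.ndarray

    def band_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "density": self.densities,
                "lower": self.lower,
                "predicted": self.point,
                "upper": self.upper,
            }
        )


class RogersResults:
    """Maximum-likelihood estimates for the random predator equation.

    Exposes the attack rate ``a`` and handling time ``h`` with Wald
    standard errors (delta method from the log scale), the derived maximum
    feeding rate ``1/h`` and functional response ratio ``a/h``, prediction,
    bootstrap bands and a text summary.
    """

    def __init__(self, model: RogersModel, log_a, log_h, llf, cov_log, converged):
        self.model = model
        self._log_a = log_a
        self._log_h = log_h
        self.llf = llf
        self.converged = converged
        self._cov_log = cov_log

    # -- point estimates ----------------------------------------------------

    @property
    def attack_rate(self) -> float:
        return math.exp(self._log_a)

    @property
    def handling_time(self) -> float:
        return math.exp(self._log_h)

    @property
    def params(self) -> pd.Series:
        return pd.Series({"a": self.attack_rate, "h": self.handling_time})

    @property
    def bse(self) -> pd.Series:
        """Delta-method standard errors on the natural scale."""
        if self._cov_log is None:
            return pd.Series({"a": np.nan, "h": np.nan})
        se_a = self.attack_rate * math.sqrt(self._cov_log[0, 0])
        se_h = self.handling_time * math.sqrt(self._cov_log[1, 1])
        return pd.Series({"a": se_a, "h": se_h})

    @property
    def pvalues(self) -> pd.Series:
        """Wald z-tests of a = 0 and h = 0 on the natural scale."""
        bse = self.bse
        out = {}
        for name, est in self.params.items():
            se = bse[name]
            if not np.isfinite(se) or se == 0:
                out[name] = np.nan
            else:
                out[name] = 2.0 * stats.norm.sf(abs(est / se))
        return pd.Series(out)

    @property
    def max_feeding_rate(self) -> float:
        return max_feeding_rate(self.handling_time)

    @property
    def frr(self) -> float:
        return functional_response_ratio(self.attack_rate, self.handling_time)

    def predict(self, density) -> np.ndarray:
        return rogers_predict(self.attack_rate, self.handling_time, self.model.T, density)

    # -- bootstrap ----------------------------------------------------------

    def bootstrap(
        self,
        n_boot: int = 2000,
        conf: float = 0.95,
        seed=None,
        densities=None,
    ) -> BootstrapBand:
        """Non-parametric bootstrap, stratified by density level.

        Trials are resampled with replacement within each density level
        (preserving the experimental design), the model refit per resample
        from the full-data optimum, and percentile intervals taken over the
        surviving refits for the parameters, the FRR and the per-density
        predicted consumption.  Refits that fail are dropped and counted;
        more than 50% failures aborts with diagnostics.
        """
        if n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not 0 < conf < 1:
            raise ValueError("confidence level must be in (0, 1)")
        rng = np.random.default_rng(seed)
        dens = self.model.density
        eaten = self.model.eaten
        strata = {lev: np.flatnonzero(dens == lev) for lev in np.unique(dens)}
        if densities is None:
            densities = np.unique(dens).astype(float)
        else:
            densities = np.asarray(densities, dtype=float)

        warm = (self._log_a, self._log_h)
        a_bs, h_bs, frr_bs, preds = [], [], [], []
        n_failed = 0
        for _ in range(n_boot):
            idx = np.concatenate(
                [rng.choice(members, size=members.size, replace=True) for members in strata.values()]
            )
            try:
                bs_model = RogersModel(dens[idx], eaten[idx], T=self.model.T)
                bs_res = bs_model.fit(quick_start=warm)
            except (FitError, ValueError):
                n_failed += 1
                continue
            a_bs.append(bs_res.attack_rate)
            h_bs.append(bs_res.handling_time)
            frr_bs.append(bs_res.frr)
            preds.append(bs_res.predict(densities))
        if n_failed > n_boot / 2:
            raise FitError(
                f"bootstrap unstable: {n_failed}/{n_boot} refits failed",
                best_params=self.params.to_dict(),
            )
        lo_q, hi_q = 100 * (1 - conf) / 2, 100 * (1 + conf) / 2
        preds = np.asarray(preds)
        point = self.predict(densities)
        lower = np.minimum(np.percentile(preds, lo_q, axis=0), point)
        upper = np.maximum(np.percentile(preds, hi_q, axis=0), point)
        pct = lambda v: (float(np.percentile(v, lo_q)), float(np.percentile(v, hi_q)))
        return BootstrapBand(
            n_boot=n_boot,
            conf=conf,
            n_failed=n_failed,
            a_ci=pct(a_bs),
            h_ci=pct(h_bs),
            frr_ci=pct(frr_bs),
            densities=densities,
            lower=lower,
            point=np.atleast_1d(point),
            upper=upper,
        )

    def summary(self) -> str:
        bse = self.bse
        pv = self.pvalues
        lines = [
            "Random predator equation (prey depletion, binomial MLE)",
            f"  trials: {self.model.density.size}   duration T: {self.model.T}",
            f"  log-likelihood: {self.llf:.4f}   converged: {self.converged}",
            f"  attack rate a    : {self.attack_rate:10.4f}  (SE {bse['a']:.4f}, p {pv['a']:.4g})",
            f"  handling time h  : {self.handling_time:10.4f}  (SE {bse['h']:.4f}, p {pv['h']:.4g})",
            f"  max feeding rate : {self.max_feeding_rate:10.4f}  (1/h)",
            f"  FRR (a/h)        : {self.frr:10.4f}",
        ]
        return "\n".join(lines)

    def __repr__(self):
        return (
            f"<RogersResults a={self.attack_rate:.4g} h={self.handling_time:.4g} "
            f"llf={self.llf:.4g}>"
        )


def fit_group_table(
    trials: pd.DataFrame,
    alpha_level: float = 0.05,
    T: float = 1.0,
) -> pd.DataFrame:
    """Fit every (predator, prey) group and tabulate shape + parameters.

    ``trials`` must carry ``predator``, ``prey``, ``density`` and ``eaten``
    columns (control rows already removed).  Returns one row per group with
    the linear shape coefficient and p-value, the inferred response type,
    the fitted a and h with p-values, the maximum feeding rate and the FRR.
    """
    rows = []
    for (predator, prey), grp in trials.groupby(["predator", "prey"], sort=True):
        fr_type, shape = determine_fr_type(grp, alpha_level)
        res = RogersModel.from_dataframe(grp, T=T).fit()
        pv = res.pvalues
        rows.append(
            {
                "predator": predator,
                "prey": prey,
                "n_trials": len(grp),
                "linear_coef": shape.coef1,
                "linear_p": shape.p1,
                "fr_type": fr_type,
                "attack_rate": res.attack_rate,
                "attack_rate_p": pv["a"],
                "handling_time": res.handling_time,
                "handling_time_p": pv["h"],
                "max_feeding_rate": res.max_feeding_rate,
                "frr": res.frr,
            }
        )
    return pd.DataFrame(rows)
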
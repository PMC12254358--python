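"""Maximum-likelihood twin models for one or two traits.

The engine fits multivariate-normal models to twin-pair observation
vectors (trait1_twin1, trait2_twin1, trait1_twin2, trait2_twin2) by full
information maximum likelihood (FIML): each pair contributes the density
of its observed subvector, so item- or scale-level missingness needs no
imputation.  Internally the likelihood is evaluated from sufficient
statistics grouped by missingness pattern, which is exact and makes the
cost of an evaluation independent of sample size.

Models:

* saturated models at three constraint levels (unconstrained; means,
  variances and cross-twin cross-trait covariances equated across twin
  order; means and variances additionally equated across zygosity),
  used for assumption testing and for extracting twin and cross-twin
  cross-trait (CTCT) correlations;
* ACE variance-component models and their nested AE / CE / E submodels,
  with each component's 2x2 (or 1x1) covariance block parameterized by a
  Cholesky factor — the mathematically equivalent correlated-factors
  solution is available as an alternative parameterization;
* likelihood-ratio comparison of nested fits, profile-likelihood
  confidence intervals, and the decomposition of the model-implied
  phenotypic correlation into A/C/E shares.

The MZ/DZ contrast is the classical twin design: additive-genetic
factors correlate 1.0 between MZ co-twins and 0.5 between DZ co-twins,
shared environment correlates 1.0 in both, non-shared environment 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "PairData",
    "fiml_neg2ll",
    "fit_saturated",
    "extract_correlations",
    "fit_bivariate_ace",
    "fit_ace",
    "lrt_compare",
    "decompose_rph",
    "profile_ci",
    "falconer_estimates",
    "SaturatedFit",
    "ACEFit",
    "LRTResult",
    "RphDecomposition",
]

_LOG2PI = math.log(2.0 * math.pi)
_BIG = 1e12
_GROUPS = ("MZ", "DZ")
#: additive-genetic cross-twin correlation per zygosity group
_A_WEIGHT = {"MZ": 1.0, "DZ": 0.5}


# ---------------------------------------------------------------------------
# sufficient statistics and the FIML objective


def _pattern_stats(Y: np.ndarray) -> list[tuple[np.ndarray, int, np.ndarray, np.ndarray]]:
    """Group rows by missingness pattern; per pattern keep (observed
    indices, count, mean, scatter about the mean)."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("observations must be a 2-d array")
    obs = np.isfinite(Y)
    keep = obs.any(axis=1)
    Y, obs = Y[keep], obs[keep]
    d = Y.shape[1]
    codes = obs @ (1 << np.arange(d))
    out = []
    for code in np.unique(codes):
        rows = Y[codes == code]
        idx = np.flatnonzero((int(code) >> np.arange(d)) & 1)
        Yo = rows[:, idx]
        xbar = Yo.mean(axis=0)
        R = Yo - xbar
        out.append((idx, rows.shape[0], xbar, R.T @ R))
    return out


def _neg2ll_stats(stats_list, mu: np.ndarray, Sigma: np.ndarray) -> float | None:
    """-2 log likelihood from pattern statistics; None if any observed
    sub-block of Sigma is not positive definite."""
    tot = 0.0
    for idx, n, xbar, S in stats_list:
        So = Sigma[np.ix_(idx, idx)]
        try:
            cf = cho_factor(So, lower=True, check_finite=False)
        except (np.linalg.LinAlgError, ValueError):
            return None
        logdet = 2.0 * np.log(np.diag(cf[0])).sum()
        d = xbar - mu[idx]
        quad = float(d @ cho_solve(cf, d, check_finite=False))
        tr = float(np.trace(cho_solve(cf, S, check_finite=False)))
        tot += n * (idx.size * _LOG2PI + logdet + quad) + tr
    return tot


def fiml_neg2ll(observations, mu, Sigma) -> float:
    """Casewise FIML -2 log likelihood of a multivariate-normal model.

    Each row of ``observations`` (NaN = missing) contributes the log
    density of its observed subvector under the mean/covariance subset
    to the observed indices.  Raises on a singular observed sub-block.
    """
    mu = np.asarray(mu, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    val = _neg2ll_stats(_pattern_stats(observations), mu, Sigma)
    if val is None:
        raise np.linalg.LinAlgError("singular observed sub-block of Sigma")
    return val


class PairData:
    """Twin-pair observations, one array per zygosity group.

    Each row is the length-``2*t`` vector (traits of twin 1, traits of
    twin 2); entries may be NaN.  ``from_moments`` builds an exact-moment
    dataset whose ML solution reproduces the supplied population mean
    and covariance — the closed-form oracle route.
    """

    def __init__(self, mz, dz, trait_names: tuple[str, ...] | None = None):
        self.y = {"MZ": np.asarray(mz, dtype=float), "DZ": np.asarray(dz, dtype=float)}
        d = self.y["MZ"].shape[1]
        if self.y["DZ"].shape[1] != d or d % 2:
            raise ValueError("groups must share an even observation length")
        self.n_traits = d // 2
        self.trait_names = trait_names or tuple(
            f"trait{j + 1}" for j in range(self.n_traits)
        )
        self.stats = {g: _pattern_stats(self.y[g]) for g in _GROUPS}
        self.n_pairs = {g: sum(s[1] for s in self.stats[g]) for g in _GROUPS}

    @classmethod
    def from_moments(cls, mu_mz, Sigma_mz, mu_dz, Sigma_dz, n: int = 10_000):
        """Dataset whose sufficient statistics equal population moments."""
        obj = cls.__new__(cls)
        mu_mz = np.asarray(mu_mz, dtype=float)
        d = mu_mz.size
        obj.y = None
        obj.n_traits = d // 2
        obj.trait_names = tuple(f"trait{j + 1}" for j in range(obj.n_traits))
        idx = np.arange(d)
        obj.stats = {
            "MZ": [(idx, n, mu_mz, n * np.asarray(Sigma_mz, dtype=float))],
            "DZ": [(idx, n, np.asarray(mu_dz, dtype=float), n * np.asarray(Sigma_dz, dtype=float))],
        }
        obj.n_pairs = {"MZ": n, "DZ": n}
        return obj

    @classmethod
    def from_scores(cls, individuals: pd.DataFrame, trait_1: str, trait_2: str | None = None):
        """Build pair observations from a per-individual score table.

        ``individuals`` needs ``pair_id``, ``twin``, ``zygosity`` and one
        column per trait.  Same-sex and opposite-sex DZ pairs are pooled
        into a single DZ group; undetermined pairs are rejected.
        """
        traits = [trait_1] if trait_2 is None else [trait_1, trait_2]
        if (individuals["zygosity"] == "undetermined").any():
            raise ValueError("undetermined-zygosity pairs must be filtered out first")
        wide = individuals.pivot(index="pair_id", columns="twin", values=traits)
        cols = [(tr, twin) for twin in (1, 2) for tr in traits]
        Y = wide[cols].to_numpy(dtype=float)
        zyg = individuals.drop_duplicates("pair_id").set_index("pair_id")["zygosity"]
        zyg = zyg.loc[wide.index].to_numpy()
        is_mz = zyg == "MZ"
        return cls(Y[is_mz], Y[~is_mz], trait_names=tuple(traits))

    @classmethod
    def from_latents(cls, latents: pd.DataFrame, trait_1: str, trait_2: str | None = None):
        """Build pair observations from a pair-wide latent-score table
        (``generate_latent_scores`` output); DZ groups are pooled."""
        traits = [trait_1] if trait_2 is None else [trait_1, trait_2]
        cols = [f"{tr}_latent_{twin}" for twin in (1, 2) for tr in traits]
        keep = latents[latents["zygosity"] != "undetermined"]
        Y = keep[cols].to_numpy(dtype=float)
        is_mz = (keep["zygosity"] == "MZ").to_numpy()
        return cls(Y[is_mz], Y[~is_mz], trait_names=tuple(traits))

    def permuted_twin_order(self, seed: int = 0) -> "PairData":
        """Randomly swap twin 1/2 within pairs (exchangeability checks)."""
        if self.y is None:
            raise ValueError("moment-based data has no twin order")
        rng = np.random.default_rng(seed)
        t = self.n_traits
        out = {}
        for g in _GROUPS:
            Y = self.y[g].copy()
            flip = rng.integers(0, 2, Y.shape[0]).astype(bool)
            Y[flip] = np.concatenate([Y[flip][:, t:], Y[flip][:, :t]], axis=1)
            out[g] = Y
        return PairData(out["MZ"], out["DZ"], self.trait_names)


def _moment_start(stats_list, d: int) -> tuple[np.ndarray, np.ndarray]:
    """Available-case mean and covariance used as optimizer start values."""
    num = np.zeros(d)
    den = np.zeros(d)
    for idx, n, xbar, _ in stats_list:
        num[idx] += n * xbar
        den[idx] += n
    mu = num / np.maximum(den, 1)
    Snum = np.zeros((d, d))
    Sden = np.zeros((d, d))
    for idx, n, xbar, S in stats_list:
        ij = np.ix_(idx, idx)
        dev = xbar - mu[idx]
        Snum[ij] += S + n * np.outer(dev, dev)
        Sden[ij] += n
    Sigma = Snum / np.maximum(Sden, 1)
    missing = Sden == 0
    Sigma[missing] = 0.0
    np.fill_diagonal(Sigma, np.where(np.diag(Sden) == 0, 1.0, np.diag(Sigma)))
    return mu, Sigma


def _nearest_psd(M: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    M = 0.5 * (M + M.T)
    w, V = np.linalg.eigh(M)
    return (V * np.clip(w, floor, None)) @ V.T


# ---------------------------------------------------------------------------
# generic ML fit base with profile-likelihood CIs


class _MLFit:
    """Common surface for fitted models: objective, theta, derived targets."""

    theta: np.ndarray
    neg2ll: float
    n_free_params: int
    converged: bool

    def _objective(self, theta: np.ndarray) -> float:  # pragma: no cover
        raise NotImplementedError

    def _derived(self, theta: np.ndarray) -> dict[str, float]:  # pragma: no cover
        raise NotImplementedError

    def target(self, name: str) -> float:
        return self._derived(self.theta)[name]

    #: natural range of each derived quantity (profile search caps)
    _TARGET_CAPS: dict[str, tuple[float, float]] = {}

    def _caps(self, name: str) -> tuple[float, float]:
        if name in self._TARGET_CAPS:
            return self._TARGET_CAPS[name]
        for prefix, caps in (
            (("a2", "c2", "e2"), (0.0, 1.0)),
            (("rA", "rC", "rE", "rph", "ctct", "twin_r"), (-1.0, 1.0)),
            (("share",), (-5.0, 5.0)),
        ):
            if any(name.startswith(p) for p in prefix):
                return caps
        return (-np.inf, np.inf)

    @property
    def aic(self) -> float:
        return self.neg2ll + 2.0 * self.n_free_params


def _minimize(objective, x0, maxiter=3000):
    def safe(th):
        v = objective(th)
        return _BIG if v is None or not np.isfinite(v) else v

    res = optimize.minimize(
        safe, x0, method="L-BFGS-B",
        options={"maxiter": maxiter, "maxfun": 10 * maxiter, "ftol": 1e-13, "gtol": 1e-8},
    )
    return res


def _polish(objective, res):
    """Derivative-free polish; numeric-gradient quasi-Newton can stall a
    few 1e-5 above the optimum when a component sits on its boundary."""
    def safe(th):
        v = objective(th)
        return _BIG if v is None or not np.isfinite(v) else v

    ref = optimize.minimize(
        safe, res.x, method="Nelder-Mead",
        options={"maxiter": 4000, "fatol": 1e-10, "xatol": 1e-8},
    )
    return ref if ref.fun < res.fun else res


def _fit_with_restarts(objective, x0, n_extra: int = 4, seed: int = 0):
    """Quasi-Newton fit with jittered restarts on failure."""
    best = _minimize(objective, x0)
    if best.fun < _BIG / 2 and best.success:
        return _polish(objective, best), True
    rng = np.random.default_rng(seed)
    for _ in range(n_extra):
        res = _minimize(objective, x0 + 0.1 * rng.standard_normal(len(x0)))
        if res.fun < best.fun:
            best = res
        if best.fun < _BIG / 2 and best.success:
            return _polish(objective, best), True
    return _polish(objective, best), bool(best.fun < _BIG / 2)


def profile_ci(fit: _MLFit, target: str, level: float = 0.95) -> tuple[float, float]:
    """Profile-likelihood confidence interval for a derived quantity.

    Each bound is the value of the target at which the profiled -2 log
    likelihood exceeds its minimum by the chi-square(1) quantile
    (3.841 at 95%).  If the likelihood stays within the threshold all the
    way to the target's natural boundary (e.g. a variance share at 0),
    the bound is reported at that boundary.
    """
    crit = stats.chi2.ppf(level, 1)
    vhat = fit.target(target)
    lo_cap, hi_cap = fit._caps(target)
    cache: dict[float, np.ndarray] = {float(vhat): np.asarray(fit.theta, dtype=float)}
    memo: dict[float, float] = {round(float(vhat), 12): float(fit.neg2ll)}

    def objective(th):
        v = fit._objective(th)
        return _BIG if v is None or not np.isfinite(v) else v

    def profiled(v: float) -> float:
        key = round(float(v), 12)
        if key in memo:
            return memo[key]
        keys = np.array(list(cache))
        x0 = cache[float(keys[np.argmin(np.abs(keys - v))])]
        best = None
        for start in (x0, fit.theta):
            res = optimize.minimize(
                objective, start, method="SLSQP",
                constraints=[{"type": "eq", "fun": lambda th: fit._derived(th)[target] - v}],
                options={"maxiter": 400, "ftol": 1e-11},
            )
            ok = np.isfinite(res.fun) and abs(fit._derived(res.x)[target] - v) < 1e-6
            if ok and (best is None or res.fun < best.fun):
                best = res
            if best is not None and start is x0:
                break
        if best is None:
            memo[key] = _BIG
            return _BIG
        cache[float(v)] = best.x
        memo[key] = float(best.fun)
        return memo[key]

    def g(v: float) -> float:
        return profiled(v) - (fit.neg2ll + crit)

    bounds = []
    scale = max(0.05, 0.2 * abs(vhat))
    for sign, cap in ((-1.0, lo_cap), (1.0, hi_cap)):
        step = 0.25 * scale
        v_in = vhat
        bound = None
        for _ in range(40):
            v_try = vhat + sign * step
            if (sign < 0 and v_try <= cap) or (sign > 0 and v_try >= cap):
                v_try = cap
            gv = g(v_try)
            if gv > 0:
                lo, hi = (v_try, v_in) if sign < 0 else (v_in, v_try)
                try:
                    bound = optimize.brentq(g, lo, hi, xtol=1e-4, rtol=1e-6, maxiter=60)
                except ValueError:
                    bound = v_in  # solver noise at the bracket; inner bound
                break
            v_in = v_try
            if v_try == cap:
                bound = cap  # likelihood flat to the boundary
                break
            step *= 1.7
        if bound is None:
            bound = cap if np.isfinite(cap) else sign * np.inf
        bounds.append(float(bound))
    return bounds[0], bounds[1]


# ---------------------------------------------------------------------------
# saturated models


def _vech_indices(d: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(d) for j in range(i + 1)]


def _sym_from_vech(vals, d: int) -> np.ndarray:
    M = np.zeros((d, d))
    for v, (i, j) in zip(vals, _vech_indices(d)):
        M[i, j] = M[j, i] = v
    return M


@dataclass
class SaturatedFit(_MLFit):
    """ML fit of a (constrained) saturated two-group model.

    ``constraint_level`` 0 leaves means and covariances free per group;
    level 1 equates means/variances across twin order within group and
    the two cross-twin cross-trait covariances; level 2 additionally
    equates means and variances across zygosity groups.
    """

    constraint_level: int
    n_traits: int
    theta: np.ndarray
    neg2ll: float
    n_free_params: int
    converged: bool
    data: PairData = field(repr=False)

    def _structure(self, theta):
        """(mu_g, Sigma_g) per group from the parameter vector."""
        t = self.n_traits
        d = 2 * t
        q = t * (t + 1) // 2
        out = {}
        if self.constraint_level == 0:
            per = d + d * (d + 1) // 2
            for k, g in enumerate(_GROUPS):
                th = theta[k * per:(k + 1) * per]
                out[g] = (th[:d], _sym_from_vech(th[d:], d))
        elif self.constraint_level == 1:
            per = t + 2 * q
            for k, g in enumerate(_GROUPS):
                th = theta[k * per:(k + 1) * per]
                m, W, B = th[:t], _sym_from_vech(th[t:t + q], t), _sym_from_vech(th[t + q:], t)
                out[g] = (np.tile(m, 2), np.block([[W, B], [B, W]]))
        else:
            m, v = theta[:t], theta[t:2 * t]
            off = 2 * t
            n_wo = t * (t - 1) // 2
            for g in _GROUPS:
                wo = theta[off:off + n_wo]
                B = _sym_from_vech(theta[off + n_wo:off + n_wo + q], t)
                off += n_wo + q
                W = np.diag(v).astype(float)
                k = 0
                for i in range(t):
                    for j in range(i):
                        W[i, j] = W[j, i] = wo[k]
                        k += 1
                out[g] = (np.tile(m, 2), np.block([[W, B], [B, W]]))
        return out

    def _objective(self, theta):
        tot = 0.0
        for g, (mu, Sigma) in self._structure(theta).items():
            v = _neg2ll_stats(self.data.stats[g], mu, Sigma)
            if v is None:
                return None
            tot += v
        return tot

    def group_moments(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        return self._structure(self.theta)

    def _derived(self, theta):
        t = self.n_traits
        out: dict[str, float] = {}
        for g, (mu, Sigma) in self._structure(theta).items():
            W = Sigma[:t, :t]
            B = Sigma[t:, :t]
            # guard: optimizer excursions may pass non-PD trial points
            denom2 = max(W[0, 0] * W[-1, -1], 1e-12)
            for i in range(t):
                out[f"twin_r_{g}_{i}"] = B[i, i] / max(W[i, i], 1e-12)
            if t == 2:
                out[f"ctct_{g}"] = B[0, 1] / math.sqrt(denom2)
                out[f"rph_{g}"] = W[0, 1] / math.sqrt(denom2)
        return out


def _saturated_start(data: PairData, level: int) -> np.ndarray:
    t = data.n_traits
    d = 2 * t
    q = t * (t + 1) // 2
    mom = {g: _moment_start(data.stats[g], d) for g in _GROUPS}

    def sym_parts(Sigma):
        W = 0.5 * (Sigma[:t, :t] + Sigma[t:, t:])
        B = 0.5 * (Sigma[t:, :t] + Sigma[t:, :t].T)
        return _nearest_psd(W, 1e-8), 0.5 * (B + B.T)

    if level == 0:
        parts = []
        for g in _GROUPS:
            mu, Sigma = mom[g]
            Sigma = _nearest_psd(Sigma, 1e-8)
            parts.append(np.concatenate([mu, [Sigma[i, j] for i, j in _vech_indices(d)]]))
        return np.concatenate(parts)
    if level == 1:
        parts = []
        for g in _GROUPS:
            mu, Sigma = mom[g]
            m = 0.5 * (mu[:t] + mu[t:])
            W, B = sym_parts(Sigma)
            parts.append(np.concatenate([
                m, [W[i, j] for i, j in _vech_indices(t)], [B[i, j] for i, j in _vech_indices(t)],
            ]))
        return np.concatenate(parts)
    mus, Ws, Bs = [], {}, {}
    for g in _GROUPS:
        mu, Sigma = mom[g]
        mus.append(0.5 * (mu[:t] + mu[t:]))
        Ws[g], Bs[g] = sym_parts(Sigma)
    m = np.mean(mus, axis=0)
    v = np.mean([np.diag(Ws[g]) for g in _GROUPS], axis=0)
    parts = [m, v]
    for g in _GROUPS:
        parts.append(np.array([Ws[g][i, j] for i, j in _vech_indices(t) if i != j]))
        parts.append(np.array([Bs[g][i, j] for i, j in _vech_indices(t)]))
    return np.concatenate(parts)


def _saturated_nparams(t: int, level: int) -> int:
    d, q = 2 * t, t * (t + 1) // 2
    if level == 0:
        return 2 * (d + d * (d + 1) // 2)
    if level == 1:
        return 2 * (t + 2 * q)
    return 2 * t + 2 * (t * (t - 1) // 2 + q)


def fit_saturated(data: PairData, constraint_level: int = 0, seed: int = 0) -> SaturatedFit:
    """Fit the saturated model at the requested constraint level.

    With complete data and no constraints the ML solution equals the
    sample means and the n-divisor sample covariances; the optimizer
    reproduces it and additionally handles missing entries via FIML.
    """
    if constraint_level not in (0, 1, 2):
        raise ValueError("constraint_level must be 0, 1 or 2")
    for g in _GROUPS:
        if data.n_pairs[g] < 30:
            warnings.warn(
                f"only {data.n_pairs[g]} {g} pairs; saturated estimates may be unstable",
                stacklevel=2,
            )
    fit = SaturatedFit(
        constraint_level=constraint_level,
        n_traits=data.n_traits,
        theta=_saturated_start(data, constraint_level),
        neg2ll=np.nan,
        n_free_params=_saturated_nparams(data.n_traits, constraint_level),
        converged=False,
        data=data,
    )
    res, ok = _fit_with_restarts(fit._objective, fit.theta, seed=seed)
    fit.theta = res.x
    fit.neg2ll = float(res.fun)
    fit.converged = ok
    if not ok:
        warnings.warn("saturated model did not converge", stacklevel=2)
    return fit


def extract_correlations(
    fit: SaturatedFit,
    ci: bool = False,
    level: float = 0.95,
    ci_targets: tuple[str, ...] = ("twin_r", "ctct"),
) -> dict:
    """Twin correlations and CTCT per zygosity from a constrained fit.

    Requires the level-2 constrained saturated model (the model the twin
    and CTCT correlations are defined on).  With ``ci=True`` each
    correlation family named in ``ci_targets`` gets a profile-likelihood
    interval.
    """
    if fit.constraint_level != 2:
        raise ValueError("correlations are extracted from the level-2 constrained fit")
    der = fit._derived(fit.theta)
    out: dict[str, dict] = {"twin_r": {}, "ctct": {}, "rph": {}}
    for g in _GROUPS:
        for i in range(fit.n_traits):
            key = f"twin_r_{g}_{i}"
            entry = {"estimate": der[key]}
            if ci and "twin_r" in ci_targets:
                entry["ci"] = profile_ci(fit, key, level)
            out["twin_r"][(g, i)] = entry
        if fit.n_traits == 2:
            entry = {"estimate": der[f"ctct_{g}"]}
            if ci and "ctct" in ci_targets:
                entry["ci"] = profile_ci(fit, f"ctct_{g}", level)
            out["ctct"][g] = entry
            out["rph"][g] = {"estimate": der[f"rph_{g}"]}
    return out


# ---------------------------------------------------------------------------
# ACE family


_MODEL_COMPONENTS = {"ACE": "ACE", "AE": "AE", "CE": "CE", "E": "E"}


def _tri_from_vals(vals, t: int) -> np.ndarray:
    L = np.zeros((t, t))
    for v, (i, j) in zip(vals, _vech_indices(t)):
        L[i, j] = v
    return L


def _comp_mat(vals, t: int, param: str) -> np.ndarray:
    if param == "cholesky":
        L = _tri_from_vals(vals, t)
        return L @ L.T
    # correlated factors: per-trait SDs plus a factor correlation
    if t == 1:
        return np.array([[vals[0] ** 2]])
    s1, s2, z = vals
    rho = math.tanh(z)
    return np.array([[s1 * s1, abs(s1 * s2) * rho], [abs(s1 * s2) * rho, s2 * s2]])


def _comp_start_vals(M: np.ndarray, t: int, param: str) -> np.ndarray:
    M = _nearest_psd(M, 1e-4)
    if param == "cholesky":
        L = np.linalg.cholesky(M)
        return np.array([L[i, j] for i, j in _vech_indices(t)])
    if t == 1:
        return np.array([math.sqrt(M[0, 0])])
    s1, s2 = math.sqrt(M[0, 0]), math.sqrt(M[1, 1])
    rho = np.clip(M[0, 1] / (s1 * s2), -0.99, 0.99)
    return np.array([s1, s2, math.atanh(rho)])


@dataclass
class ACEFit(_MLFit):
    """ML fit of an ACE-family model (ACE, AE, CE or E) for 1 or 2 traits.

    Component covariance blocks A, C, E are each parameterized through a
    lower-triangular Cholesky factor (or the equivalent correlated-
    factors form), guaranteeing positive semi-definiteness.  Means are
    equated across twins and zygosity.  Standardized components, factor
    correlations and the phenotypic-correlation decomposition are
    derived from the fitted blocks.
    """

    model: str
    param: str
    n_traits: int
    theta: np.ndarray
    neg2ll: float
    n_free_params: int
    converged: bool
    data: PairData = field(repr=False)

    @property
    def components(self) -> str:
        return _MODEL_COMPONENTS[self.model]

    def _unpack(self, theta):
        t = self.n_traits
        q = t * (t + 1) // 2
        mu = np.tile(theta[:t], 2)
        mats = {}
        off = t
        for comp in "ACE":
            if comp in self.components:
                mats[comp] = _comp_mat(theta[off:off + q], t, self.param)
                off += q
            else:
                mats[comp] = np.zeros((t, t))
        return mu, mats

    def _sigmas(self, theta):
        mu, mats = self._unpack(theta)
        T = mats["A"] + mats["C"] + mats["E"]
        out = {}
        for g in _GROUPS:
            B = _A_WEIGHT[g] * mats["A"] + mats["C"]
            out[g] = np.block([[T, B], [B, T]])
        return mu, out, mats

    def _objective(self, theta):
        mu, Sig, _ = self._sigmas(theta)
        tot = 0.0
        for g in _GROUPS:
            v = _neg2ll_stats(self.data.stats[g], mu, Sig[g])
            if v is None:
                return None
            tot += v
        return tot

    def _derived(self, theta):
        t = self.n_traits
        _, mats = self._unpack(theta)
        T = mats["A"] + mats["C"] + mats["E"]
        out: dict[str, float] = {}
        for i in range(t):
            for comp in "ACE":
                out[f"{comp.lower()}2_{i}"] = mats[comp][i, i] / max(T[i, i], 1e-12)
        if t == 2:
            for comp in "ACE":
                M = mats[comp]
                denom = math.sqrt(max(M[0, 0] * M[1, 1], 0.0))
                out[f"r{comp}"] = M[0, 1] / denom if denom > 1e-12 else 0.0
            rph = T[0, 1] / math.sqrt(max(T[0, 0] * T[1, 1], 1e-12))
            out["rph"] = rph
            for comp in "ACE":
                cov = mats[comp][0, 1]
                out[f"share_{comp}"] = cov / T[0, 1] if abs(T[0, 1]) > 1e-12 else np.nan
        return out

    # convenience accessors -------------------------------------------------

    @property
    def component_matrices(self) -> dict[str, np.ndarray]:
        return self._unpack(self.theta)[1]

    @property
    def means(self) -> np.ndarray:
        return self.theta[: self.n_traits]

    def standardized(self) -> dict[str, float]:
        return self._derived(self.theta)

    def expected_covariance(self, group: str) -> np.ndarray:
        return self._sigmas(self.theta)[1][group]


def _ace_start(data: PairData, model: str, param: str) -> np.ndarray:
    t = data.n_traits
    mom = {g: _moment_start(data.stats[g], 2 * t) for g in _GROUPS}

    def blocks(g):
        mu, Sigma = mom[g]
        W = 0.5 * (Sigma[:t, :t] + Sigma[t:, t:])
        B = Sigma[t:, :t]
        return mu, W, 0.5 * (B + B.T)

    mu_mz, W_mz, B_mz = blocks("MZ")
    mu_dz, W_dz, B_dz = blocks("DZ")
    T = 0.5 * (W_mz + W_dz)
    m = 0.25 * (mu_mz[:t] + mu_mz[t:] + mu_dz[:t] + mu_dz[t:])
    comps = _MODEL_COMPONENTS[model]
    if comps == "ACE":
        A0 = 2.0 * (B_mz - B_dz)
        C0 = 2.0 * B_dz - B_mz
    elif comps == "AE":
        A0 = 0.5 * (B_mz + 2.0 * B_dz)
        C0 = np.zeros((t, t))
    elif comps == "CE":
        A0 = np.zeros((t, t))
        C0 = 0.5 * (B_mz + B_dz)
    else:
        A0 = C0 = np.zeros((t, t))
    E0 = T - A0 - C0
    vals = [m]
    for comp, M in (("A", A0), ("C", C0), ("E", E0)):
        if comp in comps:
            vals.append(_comp_start_vals(M, t, param))
    return np.concatenate(vals)


def fit_ace(
    data: PairData,
    model: str = "ACE",
    param: str = "cholesky",
    seed: int = 0,
) -> ACEFit:
    """Fit an ACE-family model by FIML.

    ``model`` is one of ACE / AE / CE / E; omitted components are fixed
    at zero matrices.  ``param`` selects the Cholesky or the equivalent
    correlated-factors parameterization (identical likelihoods).  Starts
    come from Falconer-style moment estimates; jittered restarts are
    used on non-convergence.
    """
    if model not in _MODEL_COMPONENTS:
        raise ValueError(f"unknown model {model!r}")
    if param not in ("cholesky", "correlated_factors"):
        raise ValueError(f"unknown parameterization {param!r}")
    t = data.n_traits
    q = t * (t + 1) // 2
    n_free = t + q * len(_MODEL_COMPONENTS[model])
    fit = ACEFit(
        model=model,
        param=param,
        n_traits=t,
        theta=_ace_start(data, model, param),
        neg2ll=np.nan,
        n_free_params=n_free,
        converged=False,
        data=data,
    )
    res, ok = _fit_with_restarts(fit._objective, fit.theta, seed=seed)
    fit.theta = res.x
    fit.neg2ll = float(res.fun)
    fit.converged = ok
    if not ok:
        warnings.warn(f"{model} model did not converge", stacklevel=2)
    return fit


def fit_bivariate_ace(data: PairData, model: str = "ACE", **kwargs) -> ACEFit:
    """Bivariate ACE-family fit (two-trait :func:`fit_ace`)."""
    if data.n_traits != 2:
        raise ValueError("fit_bivariate_ace requires two traits")
    return fit_ace(data, model=model, **kwargs)


@dataclass(frozen=True)
class LRTResult:
    delta_neg2ll: float
    delta_df: int
    p_value: float
    preferred: str


def lrt_compare(full: _MLFit, nested: _MLFit, alpha: float = 0.05) -> LRTResult:
    """Likelihood-ratio test of a nested model against a fuller one.

    The nested model is preferred when the test is non-significant (the
    parsimony rule).  A nested fit beating the full fit by more than
    numerical slack signals an optimizer failure and raises.
    """
    delta = nested.neg2ll - full.neg2ll
    if delta < -1e-6 * max(1.0, abs(full.neg2ll)):
        raise RuntimeError(
            f"nested model fits better than full by {-delta:.3g}; refit with perturbed starts"
        )
    delta = max(delta, 0.0)
    ddf = full.n_free_params - nested.n_free_params
    if ddf < 0:
        raise ValueError("nested model has more free parameters than the full model")
    p = float(stats.chi2.sf(delta, ddf)) if ddf > 0 else 1.0
    full_name = getattr(full, "model", f"saturated_l{getattr(full, 'constraint_level', '?')}")
    nested_name = getattr(nested, "model", f"saturated_l{getattr(nested, 'constraint_level', '?')}")
    preferred = nested_name if p >= alpha else full_name
    return LRTResult(float(delta), int(ddf), p, preferred)


@dataclass
class RphDecomposition:
    """A/C/E shares of the model-implied phenotypic correlation.

    With h_i = sqrt(a2_i) etc., rPh = h1*h2*rA + c1*c2*rC + e1*e2*rE and
    each share is its term divided by rPh; the shares sum to 1.
    """

    rph_model: float
    share_A: float
    share_C: float
    share_E: float
    ci_A: tuple[float, float] | None = None
    ci_C: tuple[float, float] | None = None
    ci_E: tuple[float, float] | None = None


def decompose_rph(fit: ACEFit, ci: bool = False, level: float = 0.95) -> RphDecomposition:
    """Decompose the phenotypic correlation of a converged bivariate fit."""
    if fit.n_traits != 2:
        raise ValueError("decomposition requires a bivariate fit")
    der = fit._derived(fit.theta)
    if abs(der["rph"]) < 1e-6:
        raise ValueError("model-implied phenotypic correlation is ~0; shares undefined")
    kw = {}
    if ci:
        for comp in fit.components:
            kw[f"ci_{comp}"] = profile_ci(fit, f"share_{comp}", level)
    return RphDecomposition(
        rph_model=der["rph"],
        share_A=der["share_A"],
        share_C=der["share_C"],
        share_E=der["share_E"],
        **kw,
    )


def falconer_estimates(r_mz: float, r_dz: float) -> tuple[float, float, float]:
    """Closed-form biometric moment estimators.

    a2 = 2(r_MZ - r_DZ), c2 = 2 r_DZ - r_MZ, e2 = 1 - r_MZ.  No
    truncation is applied; out-of-range values are the caller's signal
    that the classical decomposition does not hold.
    """
    for r in (r_mz, r_dz):
        if not -1.0 <= r <= 1.0:
            raise ValueError("correlations must lie in [-1, 1]")
    a2 = 2.0 * (r_mz - r_dz)
    c2 = 2.0 * r_dz - r_mz
    e2 = 1.0 - r_mz
    return a2, c2, e2
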
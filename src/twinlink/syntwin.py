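"""Synthetic twin-cohort generator with a known bivariate ACE structure.

Simulates twin pairs whose latent trait values follow the classical twin
model: for each trait, t = a*A + c*C + e*E where the additive-genetic
factor A correlates 1.0 between monozygotic (MZ) co-twins and 0.5 between
dizygotic (DZ) co-twins, the shared environment C is identical within a
pair, and the non-shared environment E is independent across twins.
Cross-trait correlations of the A/C/E factors (rA, rC, rE) induce a known
decomposition of every cross-trait association, so each downstream stage
(scale scoring, phenotype preparation, correlation analysis, twin
modelling) can be tested against generator truth.

On top of the latent layer the generator emits ordinal item responses
(graded-threshold discretization with independent item noise, calibrated
to a target Cronbach's alpha), positively skewed response distributions
for the traits that are skewed in adolescent self-report data, and
missing / "don't know" codes at configurable rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "TraitSpec",
    "SimulationConfig",
    "generate_twin_dataset",
    "generate_latent_scores",
    "generate_item_responses",
    "write_dataset",
    "read_dataset",
    "item_noise_for_alpha",
    "default_config",
    "DK_CODE",
]

#: in-memory code for "I don't know / don't want to answer"; NaN is missing
DK_CODE = -1.0

ZYGOSITIES = ("MZ", "DZ_ss", "DZ_os", "undetermined")


@dataclass(frozen=True)
class TraitSpec:
    """Generating truth for one trait.

    a2/c2/e2 are the standardized variance components of the latent trait
    (must sum to 1).  Items are graded-threshold discretizations of the
    latent value plus independent Gaussian item noise whose variance is
    calibrated so the simulated scale reaches ``target_alpha`` internal
    consistency (override with ``item_noise_sd``).  ``skew_transform``
    controls threshold placement: ``"exponentiate"`` piles response mass
    on the lowest category, producing the positive skew typical of
    symptom scales; ``"none"`` uses equiprobable categories.
    """

    name: str
    a2: float
    c2: float
    e2: float
    n_items: int
    n_response_levels: int = 4
    skew_transform: str = "none"
    item_missing_rate: float = 0.0
    dontknow_rate: float = 0.0
    target_alpha: float = 0.8
    item_noise_sd: float | None = None
    #: geometric base of P(level >= k) for skewed traits; smaller = more
    #: floor and stronger positive skew (only used when skewed)
    level_exceedance: float = 0.16

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise ValueError("n_items must be >= 1")
        if self.n_response_levels < 2:
            raise ValueError("n_response_levels must be >= 2")
        comps = (self.a2, self.c2, self.e2)
        if any(v < 0 for v in comps):
            raise ValueError(f"variance components must be >= 0, got {comps}")
        if abs(sum(comps) - 1.0) > 1e-12:
            raise ValueError(f"a2+c2+e2 must sum to 1, got {sum(comps)!r}")
        for rate in (self.item_missing_rate, self.dontknow_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rates must lie in [0, 1], got {rate}")
        if self.skew_transform not in ("none", "exponentiate"):
            raise ValueError(f"unknown skew_transform {self.skew_transform!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort layout and cross-trait factor correlations.

    ``rA``/``rC``/``rE`` may be scalars (direct cross-trait correlation;
    for >2 traits an exchangeable matrix) or sequences of length
    ``len(traits) - 1`` giving the correlation of trait 0 with each other
    trait, completed to a positive semi-definite matrix through a
    single-factor construction anchored on trait 0.
    """

    n_mz: int
    n_dz_ss: int
    n_dz_os: int
    traits: tuple[TraitSpec, ...]
    rA: float | tuple[float, ...] = 0.0
    rC: float | tuple[float, ...] = 0.0
    rE: float | tuple[float, ...] = 0.0
    sex_effect: float | tuple[float, ...] = 0.0
    birthyear_effect: float | tuple[float, ...] = 0.0
    frac_undetermined: float = 0.0
    birth_year_range: tuple[int, int] = (1999, 2004)
    seed: int = 0

    def __post_init__(self) -> None:
        for n in (self.n_mz, self.n_dz_ss, self.n_dz_os):
            if n < 0:
                raise ValueError("pair counts must be >= 0")
        if not 0.0 <= self.frac_undetermined <= 1.0:
            raise ValueError("frac_undetermined must lie in [0, 1]")
        if len(self.traits) < 1:
            raise ValueError("at least one trait is required")
        object.__setattr__(self, "traits", tuple(self.traits))
        # validate correlation inputs eagerly
        for r in (self.rA, self.rC, self.rE):
            cross_trait_corr(len(self.traits), r)

    @property
    def n_pairs(self) -> int:
        return self.n_mz + self.n_dz_ss + self.n_dz_os


def cross_trait_corr(n_traits: int, r) -> np.ndarray:
    """Build the latent cross-trait correlation matrix for one component.

    Scalar ``r``: direct correlation for two traits, exchangeable
    correlation for more.  Vector of length ``n_traits - 1``: correlation
    of trait 0 with each other trait; the off-anchor correlations follow
    a single common factor, which keeps the matrix PSD for any graded set
    of anchor correlations with ``|r_j| <= lambda_0``.
    """
    if np.isscalar(r):
        r = float(r)
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"correlation must lie in [-1, 1], got {r}")
        R = np.full((n_traits, n_traits), r)
        np.fill_diagonal(R, 1.0)
    else:
        r = np.asarray(r, dtype=float)
        if r.shape != (n_traits - 1,):
            raise ValueError(
                f"correlation vector must have length {n_traits - 1}, got {r.shape}"
            )
        if np.any(np.abs(r) > 1.0):
            raise ValueError("correlations must lie in [-1, 1]")
        lam0 = max(0.6, float(np.max(np.abs(r))) + 1e-9)
        lam = np.concatenate([[lam0], r / lam0])
        R = np.outer(lam, lam)
        np.fill_diagonal(R, 1.0)
        R[0, 1:] = r
        R[1:, 0] = r
    eigvals = np.linalg.eigvalsh(R)
    if eigvals.min() < -1e-10:
        raise ValueError(
            "implied latent correlation matrix is not positive semi-definite"
        )
    return R


def _as_vector(value, n: int) -> np.ndarray:
    if np.isscalar(value):
        return np.full(n, float(value))
    out = np.asarray(value, dtype=float)
    if out.shape != (n,):
        raise ValueError(f"expected scalar or length-{n} vector, got shape {out.shape}")
    return out


def _chol_psd(R: np.ndarray) -> np.ndarray:
    # latent correlation matrices may be exactly singular (e.g. r = 1)
    try:
        return np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(R)
        return V * np.sqrt(np.clip(w, 0.0, None))


def _draw_corr(rng: np.random.Generator, n: int, L: np.ndarray) -> np.ndarray:
    return rng.standard_normal((n, L.shape[0])) @ L.T


def _simulate_latents(config: SimulationConfig, rng: np.random.Generator):
    """Latent trait values for both twins of every pair, plus demographics."""
    t = len(config.traits)
    a = np.sqrt([s.a2 for s in config.traits])
    c = np.sqrt([s.c2 for s in config.traits])
    e = np.sqrt([s.e2 for s in config.traits])
    L_A = _chol_psd(cross_trait_corr(t, config.rA))
    L_C = _chol_psd(cross_trait_corr(t, config.rC))
    L_E = _chol_psd(cross_trait_corr(t, config.rE))

    n = config.n_pairs
    zygosity = np.array(
        ["MZ"] * config.n_mz + ["DZ_ss"] * config.n_dz_ss + ["DZ_os"] * config.n_dz_os,
        dtype=object,
    )
    # A-correlation between co-twins: 1 for MZ, 0.5 for DZ (classical twin design)
    w = np.where(zygosity == "MZ", 1.0, 0.5)[:, None]

    A_shared = _draw_corr(rng, n, L_A)
    A_uniq1 = _draw_corr(rng, n, L_A)
    A_uniq2 = _draw_corr(rng, n, L_A)
    C_shared = _draw_corr(rng, n, L_C)
    E1 = _draw_corr(rng, n, L_E)
    E2 = _draw_corr(rng, n, L_E)

    A1 = np.sqrt(w) * A_shared + np.sqrt(1.0 - w) * A_uniq1
    A2 = np.sqrt(w) * A_shared + np.sqrt(1.0 - w) * A_uniq2
    y1 = A1 * a + C_shared * c + E1 * e
    y2 = A2 * a + C_shared * c + E2 * e

    # demographics
    sex_same = rng.integers(0, 2, n)  # 0 male, 1 female for same-sex pairs
    os_order = rng.integers(0, 2, config.n_dz_os)
    sex_1 = sex_same.copy()
    sex_2 = sex_same.copy()
    os_idx = np.arange(config.n_mz + config.n_dz_ss, n)
    sex_1[os_idx] = os_order
    sex_2[os_idx] = 1 - os_order
    lo, hi = config.birth_year_range
    birth_year = rng.integers(lo, hi + 1, n)

    sex_eff = _as_vector(config.sex_effect, t)
    by_eff = _as_vector(config.birthyear_effect, t)
    by_c = birth_year - (lo + hi) / 2.0
    y1 = y1 + sex_1[:, None] * sex_eff + by_c[:, None] * by_eff
    y2 = y2 + sex_2[:, None] * sex_eff + by_c[:, None] * by_eff

    # undetermined zygosity: random relabelling of same-sex pairs
    if config.frac_undetermined > 0:
        same_sex = np.flatnonzero(zygosity != "DZ_os")
        flip = rng.random(same_sex.size) < config.frac_undetermined
        zygosity[same_sex[flip]] = "undetermined"

    demo = pd.DataFrame(
        {
            "pair_id": np.arange(1, n + 1),
            "zygosity": zygosity,
            "sex_1": np.where(sex_1 == 1, "F", "M"),
            "sex_2": np.where(sex_2 == 1, "F", "M"),
            "birth_year": birth_year,
        }
    )
    return demo, y1, y2


def _level_cumprobs(spec: TraitSpec) -> np.ndarray:
    """Cumulative category probabilities for item thresholds.

    For skewed traits, the probability of exceeding each successive level
    halves, concentrating responses at 0 and producing positive skew in
    the scale score; otherwise categories are equiprobable.
    """
    L = spec.n_response_levels
    if spec.skew_transform == "exponentiate":
        # geometric exceedance: most respondents endorse the lowest level,
        # producing a positively skewed scale score
        exceed = spec.level_exceedance ** np.arange(1, L)
        cum = 1.0 - exceed
    else:
        cum = np.arange(1, L) / L
    return cum


def _ordinal_attenuation(cuts: np.ndarray, levels: np.ndarray) -> float:
    """corr(Z, discretize(Z)) for standard-normal Z and given cutpoints."""
    edges = np.concatenate([[-np.inf], cuts, [np.inf]])
    p = norm.cdf(edges[1:]) - norm.cdf(edges[:-1])
    # E[Z * 1{a < Z < b}] = phi(a) - phi(b)
    ez = norm.pdf(edges[:-1]) - norm.pdf(edges[1:])
    cov = float(np.sum(levels * ez))
    mean_d = float(np.sum(levels * p))
    var_d = float(np.sum(levels**2 * p) - mean_d**2)
    if var_d <= 0:
        return 0.0
    return cov / math.sqrt(var_d)


def item_noise_for_alpha(spec: TraitSpec) -> float:
    """Item-noise SD giving the target Cronbach's alpha.

    Inverts the Spearman-Brown/alpha relation for the mean inter-item
    correlation, then corrects for ordinal discretization using the exact
    attenuation of a normal variable cut at the trait's thresholds.
    """
    if spec.item_noise_sd is not None:
        return float(spec.item_noise_sd)
    alpha, k = spec.target_alpha, spec.n_items
    if k == 1:
        return 0.0
    rbar = alpha / (k - alpha * (k - 1))
    cuts = norm.ppf(_level_cumprobs(spec))
    lam = _ordinal_attenuation(cuts, np.arange(spec.n_response_levels, dtype=float))
    rbar_cont = rbar / max(lam**2, 1e-6)
    rbar_cont = min(rbar_cont, 0.999)
    var_noise = 1.0 / rbar_cont - 1.0
    return math.sqrt(var_noise)


def generate_item_responses(
    latent: np.ndarray, spec: TraitSpec, seed: int | np.random.Generator
) -> np.ndarray:
    """Ordinal item responses for a vector of latent trait values.

    Each item is the latent value plus independent N(0, sigma^2) noise,
    cut at fixed thresholds into ``n_response_levels`` ordered categories
    (0 .. L-1).  Missing and "don't know" codes are then inserted at the
    configured per-slot rates (NaN and ``DK_CODE`` respectively).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    latent = np.asarray(latent, dtype=float)
    n = latent.shape[0]
    sigma = item_noise_for_alpha(spec)
    u = latent[:, None] + sigma * rng.standard_normal((n, spec.n_items))
    # thresholds on the observed-utility scale (latent assumed ~ N(mu, s^2))
    mu, s = float(np.mean(latent)), float(np.std(latent))
    scale = math.sqrt(s**2 + sigma**2) if n > 1 else math.sqrt(1.0 + sigma**2)
    cuts = mu + norm.ppf(_level_cumprobs(spec)) * scale
    items = np.searchsorted(cuts, u).astype(float)

    if spec.item_missing_rate or spec.dontknow_rate:
        p_miss, p_dk = spec.item_missing_rate, spec.dontknow_rate
        if p_miss + p_dk > 1.0:
            raise ValueError("item_missing_rate + dontknow_rate exceeds 1")
        draw = rng.random((n, spec.n_items))
        items[draw < p_miss] = np.nan
        items[(draw >= p_miss) & (draw < p_miss + p_dk)] = DK_CODE
    return items


def item_columns(spec: TraitSpec, twin: int) -> list[str]:
    return [f"{spec.name}_{k + 1}_{twin}" for k in range(spec.n_items)]


def generate_latent_scores(config: SimulationConfig) -> pd.DataFrame:
    """Pair-wide table of true latent trait values (no item layer).

    Columns: demographics plus ``<trait>_latent_<twin>``.  Used for
    moment-level checks and for exercising the modelling engine without
    measurement error.
    """
    rng = np.random.default_rng(config.seed)
    demo, y1, y2 = _simulate_latents(config, rng)
    out = demo.copy()
    for j, spec in enumerate(config.traits):
        out[f"{spec.name}_latent_1"] = y1[:, j]
        out[f"{spec.name}_latent_2"] = y2[:, j]
    return out


def generate_twin_dataset(config: SimulationConfig) -> pd.DataFrame:
    """Generate a full synthetic cohort as a pair-wide item-level table.

    One row per pair: ``pair_id, zygosity, sex_1, sex_2, birth_year``
    followed by ``<trait>_<item>_<twin>`` ordinal responses (float; NaN =
    missing, -1 = "don't know").  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    demo, y1, y2 = _simulate_latents(config, rng)
    blocks = [demo]
    for j, spec in enumerate(config.traits):
        for twin, y in ((1, y1), (2, y2)):
            items = generate_item_responses(y[:, j], spec, rng)
            blocks.append(
                pd.DataFrame(items, columns=item_columns(spec, twin), index=demo.index)
            )
    return pd.concat(blocks, axis=1)


def write_dataset(records: pd.DataFrame, path) -> None:
    """Write a pair-wide table to CSV.

    Missing item responses become empty cells and "don't know" codes the
    literal token ``DK``; ``read_dataset`` restores the in-memory
    representation exactly.
    """
    out = records.copy()
    for col in out.columns:
        if col in ("pair_id", "zygosity", "sex_1", "sex_2", "birth_year"):
            continue
        vals = out[col].to_numpy()
        if vals.dtype.kind == "f":
            as_int = np.where(np.isfinite(vals) & (vals == np.round(vals)), 1, 0)
            txt = np.where(
                np.isnan(vals),
                "",
                np.where(
                    vals == DK_CODE,
                    "DK",
                    np.where(
                        as_int,
                        np.char.mod("%d", np.nan_to_num(vals).astype(np.int64)),
                        np.char.mod("%.17g", np.nan_to_num(vals)),
                    ),
                ),
            )
            out[col] = txt
    out.to_csv(path, index=False)


def read_dataset(path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_dataset` (or real data in the
    same layout) back into the in-memory representation."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    meta = {"pair_id": int, "birth_year": int}
    for col in df.columns:
        if col in ("zygosity", "sex_1", "sex_2"):
            continue
        if col in meta:
            df[col] = df[col].astype(meta[col])
            continue
        vals = df[col].to_numpy()
        parsed = np.empty(vals.shape[0], dtype=float)
        for i, v in enumerate(vals):
            if v == "":
                parsed[i] = np.nan
            elif v == "DK":
                parsed[i] = DK_CODE
            else:
                parsed[i] = float(v)
        df[col] = parsed
    return df


def default_config(
    n_mz: int = 814,
    n_dz_ss: int = 923,
    n_dz_os: int = 835,
    seed: int = 0,
    frac_undetermined: float = 0.008,
) -> SimulationConfig:
    """Study-scale default cohort.

    Trait set, item counts, response formats, target internal
    consistencies, skewness pattern and missing/"don't know" rates
    emulate an 18-year-old population twin cohort screened for
    synaesthesia and eight neurodevelopmental/psychiatric feature
    scales; the ACE structure has moderate heritabilities, negligible
    shared environment, and graded genetic links that are strongest for
    the obsessive-compulsive analogue scale.

    The target variance components and factor correlations below are
    stated on the *observed score* scale, where the non-shared
    environment absorbs measurement error — the scale on which twin
    analyses of questionnaire data report them.  Because the item layer
    adds its own measurement error, the latent generating parameters
    are attenuation-corrected (reliability taken as the target alpha)
    so that score-scale analyses of the generated cohort recover
    approximately the stated values rather than attenuated ones.
    """
    # name, a2, n_items, levels, exceedance (None = unskewed), alpha,
    # miss, dk, effective score reliability.  Exceedance bases are
    # calibrated so the scale-score skews match the graded pattern of
    # adolescent self-report data (mild for OC/autism, strong for the
    # synaesthesia screen and PLE).  The effective reliability is the
    # squared correlation between the (log-transformed where skewed)
    # scale score and the latent trait under this measurement design; it
    # falls below alpha for the heavily floored scales.
    rows = [
        ("synaesthesia", 0.50, 8, 3, 0.16, 0.80, 0.02, 0.05, 0.64),
        ("oc", 0.60, 12, 4, 0.33, 0.77, 0.02, 0.02, 0.72),
        ("anxiety", 0.60, 38, 4, None, 0.93, 0.005, 0.005, 0.92),
        ("depression", 0.60, 11, 4, None, 0.86, 0.005, 0.005, 0.85),
        ("ple", 0.60, 6, 4, 0.13, 0.65, 0.005, 0.005, 0.57),
        ("adhd", 0.60, 18, 4, None, 0.92, 0.003, 0.003, 0.90),
        ("autism", 0.60, 12, 4, 0.31, 0.72, 0.04, 0.04, 0.67),
        ("eating", 0.50, 23, 4, None, 0.93, 0.005, 0.005, 0.91),
        ("mania", 0.60, 13, 2, None, 0.84, 0.015, 0.015, 0.81),
    ]
    # latent a2 = observed a2 / effective reliability (capped); observed
    # e2 then emerges as latent e2 * rho + (1 - rho) via item noise
    rel = {r[0]: r[8] for r in rows}
    a2_lat = {r[0]: min(r[1] / rel[r[0]], 0.93) for r in rows}
    traits = tuple(
        TraitSpec(
            name=name,
            a2=round(a2_lat[name], 12),
            c2=0.0,
            e2=round(1.0 - a2_lat[name], 12),
            n_items=k,
            n_response_levels=levels,
            skew_transform="none" if base is None else "exponentiate",
            level_exceedance=base if base is not None else 0.16,
            target_alpha=alpha,
            item_missing_rate=miss,
            dontknow_rate=dk,
        )
        for name, a2, k, levels, base, alpha, miss, dk, _rel in rows
    )
    # graded genetic / non-shared-environment links of each feature scale
    # with the synaesthesia screen (strongest for the OC analogue), on the
    # observed score scale
    rA = (0.33, 0.29, 0.27, 0.26, 0.25, 0.27, 0.07, 0.21)
    rE_obs = (0.18, 0.09, 0.10, 0.10, 0.07, 0.10, 0.11, 0.12)
    # genetic correlations are unaffected by uncorrelated measurement
    # error; rE must be inflated to survive the attenuation of the
    # E-standardization: rE_lat = rE_obs * e_obs1 e_obs2 /
    # (sqrt(rho1 rho2) * e_lat1 e_lat2)
    syn_name, syn_a2_obs = rows[0][0], rows[0][1]
    syn_rho = rel[syn_name]
    e_obs_syn = math.sqrt(1.0 - syn_a2_obs)
    e_lat_syn = math.sqrt(1.0 - a2_lat[syn_name])
    rE = []
    for (name, a2_obs, *_rest), r in zip(rows[1:], rE_obs):
        rho = rel[name]
        e_obs = math.sqrt(1.0 - a2_obs)
        e_lat = math.sqrt(1.0 - a2_lat[name])
        val = r * e_obs_syn * e_obs / (math.sqrt(syn_rho * rho) * e_lat_syn * e_lat)
        rE.append(min(val, 0.95))
    rE = tuple(rE)
    sex_effect = (0.0, 0.05, 0.30, 0.30, 0.0, -0.10, -0.05, 0.35, 0.05)
    return SimulationConfig(
        n_mz=n_mz,
        n_dz_ss=n_dz_ss,
        n_dz_os=n_dz_os,
        traits=traits,
        rA=rA,
        rC=0.0,
        rE=rE,
        sex_effect=sex_effect,
        birthyear_effect=0.02,
        frac_undetermined=frac_undetermined,
        seed=seed,
    )


def two_trait_config(
    a2=(0.6, 0.5),
    c2=(0.0, 0.0),
    rA: float = 0.5,
    rC: float = 0.0,
    rE: float = 0.2,
    n_mz: int = 4000,
    n_dz: int = 4000,
    seed: int = 0,
    **kwargs,
) -> SimulationConfig:
    """Minimal two-trait configuration used throughout testing."""
    traits = tuple(
        TraitSpec(
            name=f"trait{j + 1}",
            a2=a2[j],
            c2=c2[j],
            e2=round(1.0 - a2[j] - c2[j], 12),
            n_items=1,
            n_response_levels=2,
        )
        for j in range(2)
    )
    return SimulationConfig(
        n_mz=n_mz, n_dz_ss=n_dz, n_dz_os=0, traits=traits,
        rA=rA, rC=rC, rE=rE, seed=seed, **kwargs,
    )
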
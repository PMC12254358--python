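"""Phenotypic correlations on one randomly selected twin per pair.

Twin observations are not independent, so phenotypic correlation
analysis selects a single twin per pair at random.  Pearson correlations
carry Fisher-z 95% confidence intervals and two-sided p-values; pairs of
dependent correlations that share the synaesthesia variable are compared
with the Pearson-Filon (1898) z test for overlapping correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "select_one_per_pair",
    "pearson_with_ci",
    "pearson_filon_compare",
    "compare_strongest",
    "CorrelationResult",
    "CorrelationComparison",
]


@dataclass(frozen=True)
class CorrelationResult:
    trait_x: str
    trait_y: str
    r: float
    ci_low: float
    ci_high: float
    n: int
    p_value: float


@dataclass(frozen=True)
class CorrelationComparison:
    """Comparison of corr(j,k) vs corr(j,h) for shared variable j."""

    shared: str
    trait_k: str
    trait_h: str
    r_jk: float
    r_jh: float
    r_kh: float
    n: int
    z: float
    p_value: float


def select_one_per_pair(individuals: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Keep exactly one individual per pair (Bernoulli(0.5) per pair).

    Deterministic given ``seed``; input must contain ``pair_id`` and
    ``twin`` columns with both twins present for every pair.
    """
    if individuals.empty:
        raise ValueError("empty input")
    rng = np.random.default_rng(seed)
    pair_ids = np.sort(individuals["pair_id"].unique())
    chosen_twin = rng.integers(1, 3, pair_ids.size)
    pick = pd.DataFrame({"pair_id": pair_ids, "twin": chosen_twin})
    out = individuals.merge(pick, on=["pair_id", "twin"], how="inner")
    if len(out) != pair_ids.size:
        raise ValueError("some pairs are missing the selected twin")
    return out.reset_index(drop=True)


def pearson_with_ci(x, y, ci_level: float = 0.95) -> CorrelationResult:
    """Pearson correlation with Fisher-z CI and two-sided p-value.

    Missing values are removed pairwise.  A perfect correlation
    (|r| = 1) yields a degenerate CI [r, r] and p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("need >= 3 complete cases")
    if np.var(x) <= 0 or np.var(y) <= 0:
        raise ValueError("zero variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0 - 1e-15:
        r = float(np.sign(r))
        return CorrelationResult("", "", r, r, r, n, 0.0)
    # two-sided p from the exact null distribution of r (t-transform)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    zcrit = stats.norm.ppf(0.5 + ci_level / 2)
    z = np.arctanh(r)
    half = zcrit / np.sqrt(n - 3)
    return CorrelationResult(
        "", "", r, float(np.tanh(z - half)), float(np.tanh(z + half)), n, float(p)
    )


def pearson_filon_compare(
    r_jk: float, r_jh: float, r_kh: float, n: int,
    shared: str = "", trait_k: str = "", trait_h: str = "",
) -> CorrelationComparison:
    """Pearson-Filon z test for two overlapping dependent correlations.

    Tests corr(j,k) = corr(j,h) on the same sample of size n, where j is
    the shared variable:

        z = sqrt(n) * (r_jk - r_jh) / sqrt((1-r_jk^2)^2 + (1-r_jh^2)^2 - 2k)
        k = r_kh*(1 - r_jk^2 - r_jh^2)
            - 0.5 * r_jk * r_jh * (1 - r_jk^2 - r_jh^2 - r_kh^2)
    """
    for name, r in (("r_jk", r_jk), ("r_jh", r_jh), ("r_kh", r_kh)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{name} must lie strictly in (-1, 1), got {r}")
    if n <= 3:
        raise ValueError("n must exceed 3")
    R = np.array([[1.0, r_jk, r_jh], [r_jk, 1.0, r_kh], [r_jh, r_kh, 1.0]])
    if np.linalg.eigvalsh(R).min() < -1e-10:
        raise ValueError("correlation triple is not positive semi-definite")
    k_cov = r_kh * (1.0 - r_jk**2 - r_jh**2) - 0.5 * r_jk * r_jh * (
        1.0 - r_jk**2 - r_jh**2 - r_kh**2
    )
    denom = (1.0 - r_jk**2) ** 2 + (1.0 - r_jh**2) ** 2 - 2.0 * k_cov
    if denom <= 0:
        raise ValueError("degenerate variance in Pearson-Filon statistic")
    z = np.sqrt(n) * (r_jk - r_jh) / np.sqrt(denom)
    p = 2.0 * stats.norm.sf(abs(z))
    return CorrelationComparison(
        shared, trait_k, trait_h, r_jk, r_jh, r_kh, int(n), float(z), float(p)
    )


def compare_strongest(
    scores: pd.DataFrame,
    shared: str,
    traits: list[str],
    bonferroni_family: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Compare the strongest shared-variable correlation against the rest.

    ``scores`` holds one row per (independent) individual with a column
    per trait.  The trait most strongly correlated with ``shared`` is
    compared to each other trait via the Pearson-Filon z; the n for each
    comparison is the smallest of the three pairwise-complete ns
    (conservative).  The Bonferroni flag divides ``alpha`` by the size
    of the primary correlation family (defaults to ``len(traits)``).
    """
    if len(traits) < 2:
        raise ValueError("need at least two traits to compare")
    missing = [t for t in [shared, *traits] if t not in scores.columns]
    if missing:
        raise ValueError(f"missing trait columns: {missing}")
    family = bonferroni_family if bonferroni_family is not None else len(traits)

    def pair_r(a: str, b: str) -> tuple[float, int]:
        x = scores[a].to_numpy(dtype=float)
        y = scores[b].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        return float(np.corrcoef(x[ok], y[ok])[0, 1]), int(ok.sum())

    with_shared = {t: pair_r(shared, t) for t in traits}
    top = max(traits, key=lambda t: with_shared[t][0])
    rows = []
    for other in traits:
        if other == top:
            continue
        r_jk, n_jk = with_shared[top]
        r_jh, n_jh = with_shared[other]
        r_kh, n_kh = pair_r(top, other)
        n = min(n_jk, n_jh, n_kh)
        cmp = pearson_filon_compare(r_jk, r_jh, r_kh, n, shared, top, other)
        rows.append(
            {
                "shared": shared,
                "trait_top": top,
                "trait_other": other,
                "r_top": r_jk,
                "r_other": r_jh,
                "r_between": r_kh,
                "n": n,
                "z": cmp.z,
                "p": cmp.p_value,
                "significant_bonferroni": cmp.p_value < alpha / family,
            }
        )
    return pd.DataFrame(rows)
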
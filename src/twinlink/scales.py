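"""Scale scoring, inclusion rules, descriptives, and phenotype preparation.

Turns item-level twin questionnaire data into analysis-ready phenotypes:

* synaesthesia screen scoring (yes = 1.0, "yes, to some extent" = 0.5,
  no = 0) with the rule that more than one missing/"don't know" item
  excludes the respondent;
* symptom-scale scoring with the strict "<80% of items answered"
  exclusion and prorating of near-complete responses;
* pair-level inclusion filtering (screen rule, complete pairs only,
  determined zygosity) with an exclusion tally;
* Cronbach's alpha with a Feldt F-based 95% CI, sample skewness, and a
  descriptives table split by zygosity;
* skew-gated log(1+x) transformation, residualization on sex and birth
  year, and standardization of the residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .syntwin import DK_CODE, SimulationConfig, TraitSpec, item_columns

__all__ = [
    "score_synaesthesia_screen",
    "score_scale",
    "score_dataset",
    "cronbach_alpha",
    "skewness",
    "prepare_phenotype",
    "PreparedPhenotype",
    "apply_inclusion_filters",
    "descriptives_table",
    "ScaleDescriptives",
    "pairs_to_individuals",
]

#: synaesthesia screen response weights by ordinal level
_SCREEN_WEIGHTS = {0: 0.0, 1: 0.5, 2: 1.0}
_SCREEN_LABELS = {"no": 0, "some_extent": 1, "yes": 2}


def _to_levels(responses) -> np.ndarray:
    """Normalize responses to float levels (NaN missing, DK_CODE don't-know)."""
    arr = np.asarray(responses, dtype=object)
    out = np.empty(arr.shape[0], dtype=float)
    for i, v in enumerate(arr):
        if v is None:
            out[i] = np.nan
        elif isinstance(v, str):
            key = v.strip().lower()
            if key in _SCREEN_LABELS:
                out[i] = _SCREEN_LABELS[key]
            elif key in ("dk", "don't know", "dont_know"):
                out[i] = DK_CODE
            elif key == "":
                out[i] = np.nan
            else:
                raise ValueError(f"unknown response label {v!r}")
        else:
            out[i] = float(v)
    return out


def _answered_mask(levels: np.ndarray) -> np.ndarray:
    return np.isfinite(levels) & (levels != DK_CODE)


def score_synaesthesia_screen(responses) -> tuple[float, bool]:
    """Score the 8-item synaesthesia screen.

    Returns ``(score, excluded)``.  Answered items contribute their
    weight (no = 0, to some extent = 0.5, yes = 1.0); a single
    missing/"don't know" item is tolerated and contributes 0; more than
    one flags the respondent as excluded (score is NaN).
    """
    levels = _to_levels(responses)
    if levels.shape[0] != 8:
        raise ValueError(f"screen has exactly 8 items, got {levels.shape[0]}")
    answered = _answered_mask(levels)
    bad = levels[answered][~np.isin(levels[answered], list(_SCREEN_WEIGHTS))]
    if bad.size:
        raise ValueError(f"unknown screen response level(s) {sorted(set(bad))}")
    if (~answered).sum() > 1:
        return float("nan"), True
    score = sum(_SCREEN_WEIGHTS[int(v)] for v in levels[answered])
    return float(score), False


def score_scale(responses, n_items: int | None = None) -> float:
    """Score a symptom scale as the (prorated) item sum.

    Respondents answering strictly less than 80% of the items (missing
    or "don't know") get a missing score.  Near-complete responses are
    prorated: score = n_items * mean(answered items), which equals the
    plain sum when every item is answered.
    """
    levels = _to_levels(responses)
    k = n_items if n_items is not None else levels.shape[0]
    if levels.shape[0] != k:
        raise ValueError(f"expected {k} items, got {levels.shape[0]}")
    if np.any(levels[_answered_mask(levels)] < 0):
        raise ValueError("negative response levels are not valid")
    answered = _answered_mask(levels)
    if answered.sum() / k < 0.8:
        return float("nan")
    return float(k * levels[answered].mean())


def _screen_scores_block(items: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized synaesthesia screen scoring over an (n, 8) block."""
    answered = np.isfinite(items) & (items != DK_CODE)
    n_unanswered = 8 - answered.sum(axis=1)
    weights = np.where(answered, np.where(items == 2, 1.0, np.where(items == 1, 0.5, 0.0)), 0.0)
    score = weights.sum(axis=1)
    excluded = n_unanswered > 1
    score = np.where(excluded, np.nan, score)
    return score, excluded


def _scale_scores_block(items: np.ndarray) -> np.ndarray:
    """Vectorized prorated scale scoring over an (n, k) block."""
    k = items.shape[1]
    answered = np.isfinite(items) & (items != DK_CODE)
    n_ans = answered.sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean_ans = np.where(answered, items, 0.0).sum(axis=1) / np.where(n_ans > 0, n_ans, 1)
    score = k * mean_ans
    return np.where(n_ans / k < 0.8, np.nan, score)


def pairs_to_individuals(pairs: pd.DataFrame, traits: tuple[TraitSpec, ...]) -> pd.DataFrame:
    """Reshape a pair-wide item table to one row per individual.

    The result keeps ``pair_id``, ``twin`` (1/2), ``zygosity``, ``sex``,
    ``birth_year`` and the per-trait item columns named
    ``<trait>_<item>`` regardless of twin position.
    """
    frames = []
    for twin in (1, 2):
        cols = {"pair_id": pairs["pair_id"], "twin": twin,
                "zygosity": pairs["zygosity"], "sex": pairs[f"sex_{twin}"],
                "birth_year": pairs["birth_year"]}
        frame = pd.DataFrame(cols)
        item_frames = []
        for spec in traits:
            src = item_columns(spec, twin)
            block = pairs[src].to_numpy(dtype=float)
            names = [f"{spec.name}_{k + 1}" for k in range(spec.n_items)]
            item_frames.append(pd.DataFrame(block, columns=names, index=frame.index))
        frames.append(pd.concat([frame, *item_frames], axis=1))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["pair_id", "twin"], kind="stable").reset_index(drop=True)


def score_dataset(individuals: pd.DataFrame, traits: tuple[TraitSpec, ...]) -> pd.DataFrame:
    """Per-individual scale scores for every trait.

    The trait named ``synaesthesia`` is scored with the screen rule
    (missing-as-0, >1 unanswered excluded); every other trait with the
    80%-rule prorated sum.  Adds ``<trait>_score`` columns and a
    ``screen_excluded`` flag.
    """
    out = individuals[["pair_id", "twin", "zygosity", "sex", "birth_year"]].copy()
    all_item_cols = [
        f"{spec.name}_{k + 1}" for spec in traits for k in range(spec.n_items)
    ]
    absent = individuals[all_item_cols].isna().all(axis=1).to_numpy()
    for spec in traits:
        cols = [f"{spec.name}_{k + 1}" for k in range(spec.n_items)]
        block = individuals[cols].to_numpy(dtype=float)
        if spec.name == "synaesthesia":
            score, excluded = _screen_scores_block(block)
            out["screen_excluded"] = excluded & ~absent
        else:
            score = _scale_scores_block(block)
        out[f"{spec.name}_score"] = score
    if "screen_excluded" not in out:
        out["screen_excluded"] = False
    out["absent"] = absent
    return out


def cronbach_alpha(item_matrix, ci_level: float = 0.95) -> tuple[float, float, float]:
    """Cronbach's alpha with a Feldt F-distribution confidence interval.

    alpha = k/(k-1) * (1 - sum of item variances / variance of total),
    computed on complete cases.  The CI uses Feldt's result that
    (1 - alpha)/(1 - alpha_hat) follows F(n-1, (n-1)(k-1)).
    """
    X = np.asarray(item_matrix, dtype=float)
    X = X[~np.isnan(X).any(axis=1)]
    n, k = X.shape
    if k < 2:
        raise ValueError("alpha requires at least 2 items")
    if n < 3:
        raise ValueError("alpha requires at least 3 complete respondents")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("zero total-score variance; alpha undefined")
    item_vars = X.var(axis=0, ddof=1)
    alpha = k / (k - 1) * (1.0 - item_vars.sum() / total_var)
    gamma = 1.0 - ci_level
    df1, df2 = n - 1, (n - 1) * (k - 1)
    lo = 1.0 - (1.0 - alpha) * stats.f.ppf(1.0 - gamma / 2, df1, df2)
    hi = 1.0 - (1.0 - alpha) * stats.f.ppf(gamma / 2, df1, df2)
    return float(alpha), float(lo), float(hi)


def skewness(values) -> float:
    """Adjusted Fisher-Pearson standardized third moment (G1)."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValueError("skewness requires >= 3 non-missing values")
    if np.var(x) <= 0:
        raise ValueError("skewness undefined for constant input")
    return float(stats.skew(x, bias=False))


@dataclass
class PreparedPhenotype:
    """Standardized residual phenotype for one trait.

    ``values`` is aligned to the input index; missing scores propagate.
    Over the non-missing entries the values have mean 0 and unit variance
    (ddof=1).  ``transform_applied`` records whether the skew-gated
    log(1+x) transform was used (decided once, on the raw scores).
    """

    trait: str
    values: pd.Series
    transform_applied: bool
    skew_raw: float
    skew_after_transform: float | None
    covariates_used: tuple[str, ...] = ("sex", "birth_year")


def prepare_phenotype(
    scores, sex, birth_year, trait: str = "", skew_threshold: float = 1.0
) -> PreparedPhenotype:
    """Skew-gated log(1+x) transform, OLS residualization, standardization.

    If the raw-score skewness exceeds ``skew_threshold`` (and scores are
    non-negative, so the transform is defined), applies x -> log(1+x);
    then regresses on a sex indicator and birth year via OLS and divides
    the residuals by their standard deviation.  Missing scores propagate.
    """
    s = pd.Series(np.asarray(scores, dtype=float))
    if hasattr(scores, "index"):
        s.index = scores.index
    mask = np.isfinite(s.to_numpy())
    if mask.sum() < 3:
        raise ValueError("need >= 3 non-missing scores")
    x = s.to_numpy()[mask]
    if np.var(x) <= 0:
        raise ValueError("constant scores cannot be residualized")

    skew_raw = skewness(x)
    transform = skew_raw > skew_threshold and np.min(x) >= 0
    skew_after = None
    if transform:
        x = np.log1p(x)
        skew_after = skewness(x)

    sex_arr = np.asarray(sex)
    sex_ind = (
        (sex_arr == "F").astype(float)
        if sex_arr.dtype.kind in "OUS"
        else sex_arr.astype(float)
    )
    by = np.asarray(birth_year, dtype=float)
    X = np.column_stack([np.ones(mask.sum()), sex_ind[mask], by[mask]])
    beta, *_ = np.linalg.lstsq(X, x, rcond=None)
    resid = x - X @ beta
    sd = resid.std(ddof=1)
    if sd <= 0:
        raise ValueError("residuals are constant; cannot standardize")
    out = np.full(s.shape[0], np.nan)
    out[mask] = resid / sd
    return PreparedPhenotype(
        trait=trait,
        values=pd.Series(out, index=s.index),
        transform_applied=bool(transform),
        skew_raw=skew_raw,
        skew_after_transform=skew_after,
    )


def apply_inclusion_filters(
    scored: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the pair-level inclusion rules in study order.

    Input is the per-individual scored table (``score_dataset`` output,
    with ``screen_excluded`` and ``absent`` flags).  Individuals with no
    item data at all are non-participants and are dropped before
    tallying.  Exclusion order: (1) screen
    missingness, (2) incomplete pair (co-twin absent or screen-excluded),
    (3) undetermined zygosity.  Returns the surviving individuals and a
    tally of individuals per exclusion reason; tally counts plus
    survivors partition the participating individuals.
    """
    if scored.duplicated(["pair_id", "twin"]).any():
        raise ValueError("duplicate pair_id/twin combinations")
    df = scored.copy()
    if "absent" in df.columns:
        df = df[~df["absent"].to_numpy()].copy()

    tally = {"screen_missingness": 0, "incomplete_pair": 0, "undetermined_zygosity": 0}
    by_pair = df.groupby("pair_id")
    keep_pairs = []
    for pid, grp in by_pair:
        n_present = len(grp)
        n_screen_fail = int(grp["screen_excluded"].sum())
        tally["screen_missingness"] += n_screen_fail
        n_ok = n_present - n_screen_fail
        if n_present < 2 or n_screen_fail > 0:
            # surviving member(s) of a broken pair drop with the co-twin
            tally["incomplete_pair"] += n_ok
            continue
        if grp["zygosity"].iloc[0] == "undetermined":
            tally["undetermined_zygosity"] += 2
            continue
        keep_pairs.append(pid)
    out = df[df["pair_id"].isin(keep_pairs)].reset_index(drop=True)
    tally["included"] = len(out)
    assert sum(tally.values()) == len(df)
    return out, tally


@dataclass
class ScaleDescriptives:
    """One descriptives row: sample coverage, skew, alpha, moments."""

    trait: str
    n_items: int
    n_included: int
    pct_of_sample: float
    skew_raw: float
    skew_after_transform: float | None
    alpha: float
    alpha_ci_low: float
    alpha_ci_high: float
    mean_all: float
    mean_mz: float
    mean_dz: float
    sd_all: float
    sd_mz: float
    sd_dz: float


def descriptives_table(
    individuals: pd.DataFrame,
    scored: pd.DataFrame,
    traits: tuple[TraitSpec, ...],
    skew_threshold: float = 1.0,
) -> pd.DataFrame:
    """Descriptive statistics per trait on the included sample.

    ``individuals`` carries item-level data (for alpha, complete cases)
    and ``scored`` the per-individual scores; both restricted to included
    individuals.  Skew after transform is reported only for traits whose
    raw skewness exceeds the transform threshold.  DZ pools same- and
    opposite-sex pairs.
    """
    if scored.empty:
        raise ValueError("empty dataset")
    n_total = len(scored)
    is_mz = scored["zygosity"].to_numpy() == "MZ"
    rows = []
    for spec in traits:
        score = scored[f"{spec.name}_score"].to_numpy(dtype=float)
        ok = np.isfinite(score)
        x = score[ok]
        sk = skewness(x)
        sk_after = skewness(np.log1p(x)) if (sk > skew_threshold and x.min() >= 0) else None
        item_cols = [f"{spec.name}_{k + 1}" for k in range(spec.n_items)]
        items = individuals[item_cols].to_numpy(dtype=float)
        items = np.where(items == DK_CODE, np.nan, items)
        alpha, lo, hi = cronbach_alpha(items)
        rows.append(
            ScaleDescriptives(
                trait=spec.name,
                n_items=spec.n_items,
                n_included=int(ok.sum()),
                pct_of_sample=100.0 * ok.sum() / n_total,
                skew_raw=sk,
                skew_after_transform=sk_after,
                alpha=alpha,
                alpha_ci_low=lo,
                alpha_ci_high=hi,
                mean_all=float(x.mean()),
                mean_mz=float(score[ok & is_mz].mean()),
                mean_dz=float(score[ok & ~is_mz].mean()),
                sd_all=float(x.std(ddof=1)),
                sd_mz=float(score[ok & is_mz].std(ddof=1)),
                sd_dz=float(score[ok & ~is_mz].std(ddof=1)),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
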
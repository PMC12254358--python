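"""End-to-end analysis pipeline: simulate/load -> score & QC -> prepare ->
correlate -> twin-model -> report.

Runs the full study sequence on a pair-wide item-level dataset (either a
synthetic cohort or real data in the same layout): scale scoring with the
inclusion rules, descriptives, skew-gated transformation and
residualization, one-twin-per-pair correlation analysis with dependent-
correlation comparisons, and per trait pair the saturated assumption
tests, the bivariate ACE/AE/CE/E model stack with likelihood-ratio
selection, twin/CTCT correlations, and the decomposition of the
phenotypic correlation into genetic and environmental shares.  Every
stage is deterministic given the two seeds (cohort simulation;
one-per-pair selection), and per-trait-pair failures are recorded
without aborting the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assoc import compare_strongest, pearson_with_ci, select_one_per_pair
from .scales import (
    apply_inclusion_filters,
    descriptives_table,
    pairs_to_individuals,
    prepare_phenotype,
    score_dataset,
)
from .syntwin import (
    SimulationConfig,
    TraitSpec,
    default_config,
    generate_twin_dataset,
    read_dataset,
)
from .twinmodel import (
    PairData,
    decompose_rph,
    extract_correlations,
    fit_ace,
    fit_saturated,
    lrt_compare,
    profile_ci,
)

__all__ = ["RunConfig", "RunReport", "run_full_analysis", "write_report_tables"]

log = logging.getLogger("twinlink")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``simulation`` (a :class:`SimulationConfig`) or ``input_path``
    plus ``traits`` must be provided.  ``trait_pairs`` defaults to the
    synaesthesia screen against every other trait.
    """

    simulation: SimulationConfig | None = None
    input_path: str | None = None
    traits: tuple[TraitSpec, ...] | None = None
    selection_seed: int = 1
    alpha: float = 0.05
    bonferroni_family: int = 8
    outdir: str = "twinlink_run"
    trait_pairs: tuple[tuple[str, str], ...] | None = None
    compute_cis: bool = True
    shared_trait: str = "synaesthesia"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.bonferroni_family < 1:
            raise ValueError("bonferroni_family must be >= 1")
        if self.simulation is None and (self.input_path is None or self.traits is None):
            raise ValueError("provide either a simulation config or input_path + traits")

    @property
    def trait_specs(self) -> tuple[TraitSpec, ...]:
        return self.traits if self.traits is not None else self.simulation.traits

    def resolved_pairs(self) -> tuple[tuple[str, str], ...]:
        if self.trait_pairs is not None:
            return tuple(tuple(p) for p in self.trait_pairs)
        names = [s.name for s in self.trait_specs]
        return tuple((self.shared_trait, n) for n in names if n != self.shared_trait)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = None
        if raw.get("default_cohort"):
            sim = default_config(**raw.get("simulation", {}))
        elif "simulation" in raw:
            simraw = dict(raw["simulation"])
            simraw["traits"] = tuple(TraitSpec(**t) for t in simraw["traits"])
            for key in ("rA", "rC", "rE", "sex_effect", "birthyear_effect"):
                if isinstance(simraw.get(key), list):
                    simraw[key] = tuple(simraw[key])
            sim = SimulationConfig(**simraw)
        kwargs = {
            k: raw[k]
            for k in (
                "input_path", "selection_seed", "alpha", "bonferroni_family",
                "outdir", "compute_cis", "shared_trait",
            )
            if k in raw
        }
        if "traits" in raw:
            kwargs["traits"] = tuple(TraitSpec(**t) for t in raw["traits"])
        if "trait_pairs" in raw:
            kwargs["trait_pairs"] = tuple(tuple(p) for p in raw["trait_pairs"])
        return cls(simulation=sim, **kwargs)


@dataclass
class RunReport:
    """Aggregated outputs of one pipeline run."""

    exclusion_tally: dict[str, int]
    descriptives: pd.DataFrame
    transforms: dict[str, bool]
    correlations: pd.DataFrame
    comparisons: pd.DataFrame
    twin_reports: dict[tuple[str, str], dict]
    provenance: dict


def _model_stack(
    phenotypes: pd.DataFrame,
    trait_1: str,
    trait_2: str,
    alpha: float,
    compute_cis: bool,
) -> dict:
    """Saturated assumption tests, ACE stack, selection and decomposition
    for one trait pair."""
    data = PairData.from_scores(phenotypes, trait_1, trait_2)
    report: dict = {
        "traits": [trait_1, trait_2],
        "n_pairs": {g: int(data.n_pairs[g]) for g in ("MZ", "DZ")},
    }

    sat = {lvl: fit_saturated(data, lvl) for lvl in (0, 1, 2)}
    report["saturated"] = {
        str(lvl): {
            "neg2ll": fit.neg2ll,
            "n_free_params": fit.n_free_params,
            "converged": fit.converged,
        }
        for lvl, fit in sat.items()
    }
    report["assumption_tests"] = {
        "order": dataclasses.asdict(lrt_compare(sat[0], sat[1], alpha)),
        "zygosity": dataclasses.asdict(lrt_compare(sat[1], sat[2], alpha)),
    }
    corr = extract_correlations(sat[2], ci=compute_cis, ci_targets=("ctct",))
    report["twin_correlations"] = {
        f"{g}_{data.trait_names[i]}": entry
        for (g, i), entry in corr["twin_r"].items()
    }
    report["ctct"] = corr["ctct"]
    report["rph_saturated"] = corr["rph"]

    fits = {m: fit_ace(data, m) for m in ("ACE", "AE", "CE", "E")}
    report["vs_saturated"] = dataclasses.asdict(lrt_compare(sat[0], fits["ACE"], alpha))
    lrts = {m: lrt_compare(fits["ACE"], fits[m], alpha) for m in ("AE", "CE", "E")}
    report["model_fits"] = {
        m: {
            "neg2ll": f.neg2ll,
            "n_free_params": f.n_free_params,
            "aic": f.aic,
            "converged": f.converged,
            "standardized": f.standardized(),
        }
        for m, f in fits.items()
    }
    report["lrt_vs_ace"] = {m: dataclasses.asdict(l) for m, l in lrts.items()}

    # parsimony rule: most constrained nested model not rejected vs ACE
    candidates = [m for m in ("E", "CE", "AE") if lrts[m].p_value >= alpha]
    if candidates:
        selected = min(candidates, key=lambda m: (fits[m].n_free_params, fits[m].aic))
    else:
        selected = "ACE"
    report["selected_model"] = selected
    sel = fits[selected]

    std = sel.standardized()
    estimates = {"rph": std["rph"]}
    for comp in sel.components:
        estimates[f"r{comp}"] = std[f"r{comp}"]
    for i, name in enumerate(data.trait_names):
        for comp in sel.components:
            estimates[f"{comp.lower()}2_{name}"] = std[f"{comp.lower()}2_{i}"]
    if compute_cis:
        cis = {"rph": profile_ci(sel, "rph")}
        for comp in sel.components:
            cis[f"r{comp}"] = profile_ci(sel, f"r{comp}")
        report["cis"] = {k: list(v) for k, v in cis.items()}
    report["estimates"] = estimates

    dec = decompose_rph(sel, ci=compute_cis)
    report["rph_decomposition"] = {
        "rph_model": dec.rph_model,
        "share_A": dec.share_A,
        "share_C": dec.share_C,
        "share_E": dec.share_E,
        "ci_A": list(dec.ci_A) if dec.ci_A else None,
        "ci_C": list(dec.ci_C) if dec.ci_C else None,
        "ci_E": list(dec.ci_E) if dec.ci_E else None,
    }
    return report


def run_full_analysis(config: RunConfig) -> RunReport:
    """Execute all stages in study order and return the aggregated report.

    Correlation analyses use one randomly selected twin per complete
    pair; twin models use all complete pairs (MZ vs pooled DZ).  Fully
    deterministic given the simulation and selection seeds.
    """
    t0 = time.perf_counter()
    traits = config.trait_specs
    if config.input_path is not None:
        log.info("reading dataset from %s", config.input_path)
        pairs = read_dataset(config.input_path)
    else:
        log.info("simulating cohort (seed=%d)", config.simulation.seed)
        pairs = generate_twin_dataset(config.simulation)

    individuals = pairs_to_individuals(pairs, traits)
    scored = score_dataset(individuals, traits)
    included, tally = apply_inclusion_filters(scored)
    log.info("inclusion tally: %s", tally)

    key = included.set_index(["pair_id", "twin"]).index
    ind_included = individuals.set_index(["pair_id", "twin"]).loc[key].reset_index()
    descr = descriptives_table(ind_included, included, traits)

    phenotypes = included[["pair_id", "twin", "zygosity", "sex", "birth_year"]].copy()
    transforms = {}
    for spec in traits:
        prep = prepare_phenotype(
            included[f"{spec.name}_score"],
            included["sex"].to_numpy(),
            included["birth_year"].to_numpy(),
            trait=spec.name,
        )
        phenotypes[spec.name] = prep.values.to_numpy()
        transforms[spec.name] = prep.transform_applied

    one = select_one_per_pair(phenotypes, config.selection_seed)
    shared = config.shared_trait
    feature_names = [s.name for s in traits if s.name != shared]
    rows = []
    for name in feature_names:
        res = pearson_with_ci(one[shared], one[name])
        rows.append(
            {
                "trait": name,
                "r": res.r,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "n": res.n,
                "p": res.p_value,
                "significant_bonferroni": res.p_value
                < config.alpha / config.bonferroni_family,
            }
        )
    correlations = pd.DataFrame(rows)
    comparisons = compare_strongest(
        one, shared, feature_names,
        bonferroni_family=config.bonferroni_family, alpha=config.alpha,
    )

    twin_reports: dict[tuple[str, str], dict] = {}
    for t1, t2 in config.resolved_pairs():
        t_pair = time.perf_counter()
        try:
            twin_reports[(t1, t2)] = _model_stack(
                phenotypes, t1, t2, config.alpha, config.compute_cis
            )
            log.info("modelled %s x %s in %.1fs", t1, t2, time.perf_counter() - t_pair)
        except Exception as exc:  # per-pair failures never abort the run
            log.warning("model stack failed for %s x %s: %s", t1, t2, exc)
            twin_reports[(t1, t2)] = {"traits": [t1, t2], "error": str(exc)}

    provenance = {
        "twinlink_version": __version__,
        "selection_seed": config.selection_seed,
        "alpha": config.alpha,
        "bonferroni_family": config.bonferroni_family,
        "shared_trait": shared,
        "n_individuals_included": int(len(included)),
        "n_pairs_included": int(included["pair_id"].nunique()),
        "n_one_per_pair": int(len(one)),
        "transforms": transforms,
        "trait_pairs": [list(p) for p in config.resolved_pairs()],
        "runtime_s": round(time.perf_counter() - t0, 2),
    }
    if config.simulation is not None:
        sim = dataclasses.asdict(config.simulation)
        sim["traits"] = [dataclasses.asdict(t) for t in config.simulation.traits]
        provenance["simulation"] = sim
    else:
        provenance["input_path"] = config.input_path

    return RunReport(
        exclusion_tally=tally,
        descriptives=descr,
        transforms=transforms,
        correlations=correlations,
        comparisons=comparisons,
        twin_reports=twin_reports,
        provenance=provenance,
    )


def _fmt(df: pd.DataFrame) -> pd.DataFrame:
    return df.round(10)


def write_report_tables(report: RunReport, outdir) -> dict[str, Path]:
    """Write the report to stable CSV/JSON files.

    Emits ``table2.csv`` (descriptives), ``fig1.csv`` (forest-plot-ready
    correlations), ``comparisons.csv``, ``table3.csv`` (rPh/rA/rE and
    CTCT with CIs), ``table4.csv`` (phenotypic-correlation shares),
    ``exclusions.csv``, ``model_fits.json`` and ``run.json``.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["table2"] = out / "table2.csv"
    _fmt(report.descriptives).to_csv(paths["table2"], index=False)
    paths["fig1"] = out / "fig1.csv"
    _fmt(report.correlations).to_csv(paths["fig1"], index=False)
    paths["comparisons"] = out / "comparisons.csv"
    _fmt(report.comparisons).to_csv(paths["comparisons"], index=False)

    rows3, rows4 = [], []
    for (t1, t2), rep in report.twin_reports.items():
        if "error" in rep:
            rows3.append({"trait_1": t1, "trait_2": t2, "error": rep["error"]})
            continue
        est = rep["estimates"]
        cis = rep.get("cis", {})

        def ci(key, side):
            pair = cis.get(key)
            return pair[side] if pair else np.nan

        def ctct(g, fld):
            e = rep["ctct"].get(g, {})
            if fld == "est":
                return e.get("estimate", np.nan)
            return e.get("ci", (np.nan, np.nan))[fld]

        rows3.append(
            {
                "trait_1": t1,
                "trait_2": t2,
                "selected_model": rep["selected_model"],
                "rph": est.get("rph", np.nan),
                "rph_ci_low": ci("rph", 0),
                "rph_ci_high": ci("rph", 1),
                "rA": est.get("rA", np.nan),
                "rA_ci_low": ci("rA", 0),
                "rA_ci_high": ci("rA", 1),
                "rE": est.get("rE", np.nan),
                "rE_ci_low": ci("rE", 0),
                "rE_ci_high": ci("rE", 1),
                "ctct_mz": ctct("MZ", "est"),
                "ctct_mz_ci_low": ctct("MZ", 0),
                "ctct_mz_ci_high": ctct("MZ", 1),
                "ctct_dz": ctct("DZ", "est"),
                "ctct_dz_ci_low": ctct("DZ", 0),
                "ctct_dz_ci_high": ctct("DZ", 1),
            }
        )
        dec = rep["rph_decomposition"]
        rows4.append(
            {
                "trait_1": t1,
                "trait_2": t2,
                "selected_model": rep["selected_model"],
                "rph_model": dec["rph_model"],
                "share_A": dec["share_A"],
                "share_A_ci_low": (dec["ci_A"] or (np.nan, np.nan))[0],
                "share_A_ci_high": (dec["ci_A"] or (np.nan, np.nan))[1],
                "share_E": dec["share_E"],
                "share_E_ci_low": (dec["ci_E"] or (np.nan, np.nan))[0],
                "share_E_ci_high": (dec["ci_E"] or (np.nan, np.nan))[1],
            }
        )
    cols3 = ["trait_1", "trait_2", "selected_model", "rph", "rph_ci_low", "rph_ci_high",
             "rA", "rA_ci_low", "rA_ci_high", "rE", "rE_ci_low", "rE_ci_high",
             "ctct_mz", "ctct_mz_ci_low", "ctct_mz_ci_high",
             "ctct_dz", "ctct_dz_ci_low", "ctct_dz_ci_high"]
    cols4 = ["trait_1", "trait_2", "selected_model", "rph_model",
             "share_A", "share_A_ci_low", "share_A_ci_high",
             "share_E", "share_E_ci_low", "share_E_ci_high"]
    paths["table3"] = out / "table3.csv"
    _fmt(pd.DataFrame(rows3, columns=cols3 if rows3 else cols3)).to_csv(
        paths["table3"], index=False
    )
    paths["table4"] = out / "table4.csv"
    _fmt(pd.DataFrame(rows4, columns=cols4)).to_csv(paths["table4"], index=False)

    paths["exclusions"] = out / "exclusions.csv"
    pd.DataFrame([report.exclusion_tally]).to_csv(paths["exclusions"], index=False)

    paths["model_fits"] = out / "model_fits.json"
    serializable = {f"{t1}__{t2}": rep for (t1, t2), rep in report.twin_reports.items()}
    paths["model_fits"].write_text(json.dumps(serializable, indent=2, default=float))

    paths["run"] = out / "run.json"
    paths["run"].write_text(json.dumps(report.provenance, indent=2, default=str))
    return paths
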
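"""Orchestration of the four model families across all responses.

The analysis fits, for every response, four fixed-effect families:

* ``body_mass`` — log body mass as the sole predictor;
* ``life_span`` — log maximum life span (focal) controlling for log body
  mass, log number of ringing recoveries, and migration distance;
* ``fecundity`` — log annual fecundity (focal) with log body mass and
  migration distance;
* ``bmr`` — log BMR (focal) with log body mass.

Responses are the individual fatty acids plus SFA, MUFA, PUFA and
n-3/total PUFA (beta regression), and ACL, DBI, PI and log AI (Gaussian
regression).  Each fitted model is summarised by the average marginal effect
of its focal predictor with an equal-tailed 95% credible interval; no
multiple-testing adjustment is applied (the expected number of chance
significances is reported for context instead).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import geodesy
from .fatty_acids import CompositionTable, compute_indices
from .model import (MCMCSettings, ModelSpec, Posterior, Predictor,
                    PriorSettings, average_marginal_effect, fit,
                    prepare_design)
from .phylogeny import PhyloCovariance
from .synthetic import DEFAULT_FA_PANEL

__all__ = [
    "MODEL_FAMILIES",
    "PlannedModel",
    "AnalysisPlan",
    "assemble_trait_table",
    "build_plan",
    "run_plan",
    "forest_summary",
    "expected_chance_significant",
    "load_config",
]

logger = logging.getLogger(__name__)

#: Fixed-effect structure of the four model families: (focal predictor,
#: predictor list).  Body mass, life span, recoveries, fecundity and BMR are
#: log-transformed; all predictors are z-standardized.
MODEL_FAMILIES: dict[str, tuple[str, tuple[Predictor, ...]]] = {
    "body_mass": (
        "body_mass_g",
        (Predictor("body_mass_g", log=True),),
    ),
    "life_span": (
        "life_span_y",
        (Predictor("life_span_y", log=True),
         Predictor("body_mass_g", log=True),
         Predictor("n_recoveries", log=True),
         Predictor("migration_distance_Mm")),
    ),
    "fecundity": (
        "annual_fecundity",
        (Predictor("annual_fecundity", log=True),
         Predictor("body_mass_g", log=True),
         Predictor("migration_distance_Mm")),
    ),
    "bmr": (
        "bmr_kj_h",
        (Predictor("bmr_kj_h", log=True),
         Predictor("body_mass_g", log=True)),
    ),
}

#: The eight composition-level index responses and their model treatment.
INDEX_RESPONSES: tuple[tuple[str, str, dict], ...] = (
    ("SFA", "beta", {"response_scale": "percent"}),
    ("MUFA", "beta", {"response_scale": "percent"}),
    ("PUFA", "beta", {"response_scale": "percent"}),
    ("n3_over_total_pufa", "beta", {"response_scale": "fraction"}),
    ("ACL", "gaussian", {}),
    ("DBI", "gaussian", {}),
    ("PI", "gaussian", {}),
    ("AI", "gaussian", {"log_response": True}),
)


@dataclass
class PlannedModel:
    response: str
    model_family: str
    focal: str
    spec: ModelSpec


@dataclass
class AnalysisPlan:
    models: list[PlannedModel]
    skipped: list[tuple[str, str, str]]  # (response, family, reason)

    def __len__(self) -> int:
        return len(self.models)


def assemble_trait_table(composition: CompositionTable,
                         life_history: pd.DataFrame,
                         origin: geodesy.GeoPoint = geodesy.JUTLAND_CENTROID,
                         ) -> pd.DataFrame:
    """Join FA mol%, composition indices, life history and migration distance.

    Migration distance is derived from ``migratory_status`` and the
    non-breeding centroid columns via the haversine formula (sedentary
    species get 0).
    """
    fa = composition.to_dataframe()
    indices = compute_indices(composition)
    table = fa.join(indices, how="inner").join(life_history, how="inner")
    if "migratory_status" in table.columns:
        records = []
        for sp, row in table.iterrows():
            centroid = None
            if not (pd.isna(row.get("nonbreeding_lat", np.nan))
                    or pd.isna(row.get("nonbreeding_lon", np.nan))):
                centroid = geodesy.GeoPoint(row["nonbreeding_lat"],
                                            row["nonbreeding_lon"])
            records.append(geodesy.MigrationRecord(str(sp),
                                                   str(row["migratory_status"]),
                                                   centroid))
        table["migration_distance_Mm"] = geodesy.migration_distance(records, origin)
    return table


def build_plan(
    traits: pd.DataFrame,
    fa_panel: Sequence[str] = DEFAULT_FA_PANEL,
    families: Sequence[str] = tuple(MODEL_FAMILIES),
    mcmc: MCMCSettings = MCMCSettings(),
    priors: PriorSettings = PriorSettings(),
    seed: int = 0,
) -> AnalysisPlan:
    """Enumerate every (response, family) model on the available columns.

    Responses absent from the trait table are listed as skipped, as are whole
    families whose predictors are missing (e.g. no BMR column).  Each model
    receives a deterministic seed derived from ``seed``.
    """
    responses: list[tuple[str, str, dict]] = [
        (label, "beta", {"response_scale": "percent"}) for label in fa_panel
    ] + list(INDEX_RESPONSES)

    models: list[PlannedModel] = []
    skipped: list[tuple[str, str, str]] = []
    ss = np.random.SeedSequence(seed)
    for fam in families:
        if fam not in MODEL_FAMILIES:
            raise KeyError(f"unknown model family {fam!r}")
        focal, predictors = MODEL_FAMILIES[fam]
        missing = [p.name for p in predictors if p.name not in traits.columns]
        if missing:
            for resp, _, _ in responses:
                skipped.append((resp, fam, f"missing predictors: {missing}"))
            continue
        for resp, family, kwargs in responses:
            if resp not in traits.columns:
                skipped.append((resp, fam, "response not in trait table"))
                continue
            child = ss.spawn(1)[0]
            model_seed = int(child.generate_state(1, np.uint32)[0] % (2**31 - 1))
            spec = ModelSpec(response=resp, family=family,
                             predictors=predictors, priors=priors,
                             mcmc=replace(mcmc, seed=model_seed), **kwargs)
            models.append(PlannedModel(resp, fam, focal, spec))
    return AnalysisPlan(models=models, skipped=skipped)


def run_plan(plan: AnalysisPlan, traits: pd.DataFrame,
             covariance: PhyloCovariance) -> pd.DataFrame:
    """Fit every planned model and summarise the focal average marginal effect.

    Non-converged fits are flagged, never raised; failures become rows with a
    ``status`` describing the error.  Deterministic under the plan's seeds.
    """
    rows = []
    for pm in plan.models:
        try:
            design = prepare_design(traits, covariance, pm.spec)
            post = fit(pm.spec, design)
            eff = average_marginal_effect(post, design, pm.focal)
            rows.append({
                "response": pm.response, "model_family": pm.model_family,
                "focal": pm.focal, "ame_mean": eff.mean,
                "ci_low": eff.lower, "ci_high": eff.upper,
                "significant": eff.significant, "rhat_max": post.max_rhat,
                "converged": post.converged, "n_species": len(design.species),
                "status": "ok",
            })
        except Exception as err:  # noqa: BLE001 — batch must survive any fit
            logger.warning("model %s/%s failed: %s", pm.response,
                           pm.model_family, err)
            rows.append({
                "response": pm.response, "model_family": pm.model_family,
                "focal": pm.focal, "ame_mean": np.nan, "ci_low": np.nan,
                "ci_high": np.nan, "significant": False, "rhat_max": np.nan,
                "converged": False, "n_species": 0,
                "status": f"failed: {err}",
            })
    for resp, fam, reason in plan.skipped:
        rows.append({
            "response": resp, "model_family": fam, "focal": "",
            "ame_mean": np.nan, "ci_low": np.nan, "ci_high": np.nan,
            "significant": False, "rhat_max": np.nan, "converged": False,
            "n_species": 0, "status": f"skipped: {reason}",
        })
    return pd.DataFrame(rows)


def forest_summary(results: pd.DataFrame,
                   order: Sequence[str] = tuple(DEFAULT_FA_PANEL) +
                   tuple(r[0] for r in INDEX_RESPONSES)) -> pd.DataFrame:
    """Per-family effect listing in panel order, with significance markers."""
    if results.empty:
        return results.copy()
    rank = {name: i for i, name in enumerate(order)}
    out = results[results["status"] == "ok"].copy()
    out["_rank"] = out["response"].map(lambda r: rank.get(r, len(rank)))
    out = out.sort_values(["model_family", "_rank"]).drop(columns="_rank")
    out["marker"] = np.where(out["significant"], "*", "")
    return out.reset_index(drop=True)


def plot_forest(results: pd.DataFrame, path=None):
    """Forest plot of average marginal effects with 95% credible bars."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ok = forest_summary(results)
    fams = list(dict.fromkeys(ok["model_family"]))
    fig, axes = plt.subplots(1, max(len(fams), 1),
                             figsize=(3.2 * max(len(fams), 1),
                                      0.25 * ok["response"].nunique() + 2),
                             sharey=True)
    axes = np.atleast_1d(axes)
    for ax, fam in zip(axes, fams):
        sub = ok[ok["model_family"] == fam]
        ypos = np.arange(len(sub))[::-1]
        ax.errorbar(sub["ame_mean"], ypos,
                    xerr=[sub["ame_mean"] - sub["ci_low"],
                          sub["ci_high"] - sub["ame_mean"]],
                    fmt="o", ms=3, lw=1)
        ax.axvline(0, color="grey", lw=0.7)
        ax.set_yticks(ypos, sub["response"])
        ax.set_title(fam)
        ax.set_xlabel("average marginal effect")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def expected_chance_significant(results: pd.DataFrame, level: float = 0.95) -> float:
    """Expected number of significant effects under the global null, given the
    number of fitted models — context for the informal multiplicity stance."""
    return (1.0 - level) * float((results["status"] == "ok").sum())


def load_config(path) -> dict:
    """Load a YAML analysis config (fa_panel, families, mcmc, priors, seed)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    out = {
        "fa_panel": tuple(cfg.get("fa_panel", DEFAULT_FA_PANEL)),
        "families": tuple(cfg.get("families", tuple(MODEL_FAMILIES))),
        "seed": int(cfg.get("seed", 0)),
        "mcmc": MCMCSettings(**cfg.get("mcmc", {})),
        "priors": PriorSettings(**cfg.get("priors", {})),
    }
    return out
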
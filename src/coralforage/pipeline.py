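"""Orchestration: simulate -> evenness -> preference -> glmm -> overlap.

``run_all`` executes every stage on either a generated synthetic study or
user-supplied CSV tables, writes one JSON per stage plus a combined
Markdown/JSON report, and logs the counts removed by each filter (the
minimum-observation rule, the focal-genus restriction, the focal-species
restriction) so the provenance of every number is visible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import evenness as ev
from . import glmm, overlap, preference
from .io import (
    FOCAL_GENERA,
    availability_proportions,
    read_benthic_csv,
    read_foraging_csv,
    to_jsonable,
    write_result_json,
)
from .simulate import SimulationConfig, generate_study, write_study

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One full analysis run: inputs, focal sets, stochastic controls."""

    foraging_csv: str | None = None
    benthic_csv: str | None = None
    simulation: SimulationConfig | None = None
    focal_genera: tuple[str, ...] = FOCAL_GENERA
    preference_species: tuple[str, ...] = preference.PREFERENCE_SPECIES
    overlap_species: tuple[str, ...] = overlap.OVERLAP_SPECIES
    min_obs_overlap: int = 8
    n_sim: int = 1000
    seed: int = 0
    outdir: str = "coralforage_out"
    glmm_full_terms: tuple[str, ...] = ("cover", "species", "site", "year")
    do_backward_selection: bool = True
    jackknife_reps: int = 100

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        if sim is not None:
            cfg.simulation = SimulationConfig(
                **{k: tuple(v) if isinstance(v, list) else v for k, v in sim.items()}
            )
        return cfg


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns (and writes) the combined report.

    A failed stage is recorded in the report and its downstream dependents
    are skipped; independent stages still run.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "seed": config.seed}

    observations = transects = None
    if config.simulation is not None:
        sim = config.simulation
        logger.info("simulate: seed=%d", sim.seed)
        bundle = generate_study(sim)
        write_study(bundle, outdir / "synthetic")
        observations, transects = bundle.observations, bundle.transects
        report["stages"]["simulate"] = {"status": "ok", "seed": sim.seed}
    else:
        if config.foraging_csv:
            observations = read_foraging_csv(config.foraging_csv)
        if config.benthic_csv:
            transects = read_benthic_csv(config.benthic_csv)

    # ---- evenness ----------------------------------------------------------
    try:
        stage: dict = {}
        if transects is not None:
            coral_rec = ev.coral_pie_by_transect(transects)
            stage["coral"] = ev.pie_year_comparison(coral_rec)
            stage["coral"]["records"] = [to_jsonable(r) for r in coral_rec]
        if observations is not None:
            diet_rec = ev.diet_pie_by_species_site(observations, config.preference_species)
            stage["diet"] = ev.pie_year_comparison(diet_rec)
            stage["diet"]["records"] = [to_jsonable(r) for r in diet_rec]
        stage["status"] = "ok" if stage else "skipped"
        report["stages"]["evenness"] = stage
        write_result_json(stage, outdir / "evenness.json")
    except Exception as exc:
        logger.exception("evenness stage failed")
        report["stages"]["evenness"] = {"status": "failed", "error": str(exc)}

    # ---- preference (needs both tables) ------------------------------------
    pairs_df = None
    if observations is not None and transects is not None:
        try:
            site_years = sorted({(t.site, t.year) for t in transects})
            avail = {
                sy: availability_proportions(transects, sy[0], sy[1], level="species")
                for sy in site_years
            }
            focal_obs = [
                o for o in observations if o.fish_species in set(config.preference_species)
            ]
            logger.info(
                "preference: %d of %d observations in the %d focal species",
                len(focal_obs), len(observations), len(config.preference_species),
            )
            profiles = [
                preference.ivlev_electivity(o, avail[(o.site, o.year)], config.focal_genera)
                for o in focal_obs
            ]
            profiles = [p for p in profiles if p.total_bites > 0]
            pairs = preference.preference_pairs(profiles, avail)
            pairs_df = preference.pairs_to_frame(pairs)
            pairs_df.to_csv(outdir / "pairs.csv", index=False)
            diet = preference.diet_proportions(observations, taxon_level="genus")
            diet.to_csv(outdir / "diet_proportions.csv", index=False)
            report["stages"]["preference"] = {
                "status": "ok",
                "n_profiles": len(profiles),
                "n_pairs": len(pairs),
                "mean_coefficient_by_species": {
                    sp: float(g["coefficient"].mean())
                    for sp, g in pairs_df.groupby("fish_species")
                },
            }
            write_result_json(report["stages"]["preference"], outdir / "preference.json")
        except Exception as exc:
            logger.exception("preference stage failed")
            report["stages"]["preference"] = {"status": "failed", "error": str(exc)}
    else:
        logger.warning("preference stage skipped: needs both foraging and benthic tables")
        report["stages"]["preference"] = {"status": "skipped"}

    # ---- glmm (needs pairs) -------------------------------------------------
    if pairs_df is not None and len(pairs_df) >= 20:
        try:
            full_spec = glmm.OibeModelSpec(mean_terms=config.glmm_full_terms)
            if config.do_backward_selection:
                fit, trace = glmm.backward_aic_select(pairs_df, full_spec)
            else:
                fit, trace = glmm.fit_oibe(pairs_df, full_spec), []
            stage = {
                "status": "ok",
                "selected_terms": list(fit.spec.mean_terms),
                "coefficients": fit.beta,
                "ci": {k: list(v) for k, v in fit.ci.items()},
                "phi": fit.phi,
                "nu": fit.nu,
                "sigma_u": fit.sigma_u,
                "sigma_v": fit.sigma_v,
                "aic": fit.aic,
                "loglik": fit.loglik,
                "r2_generalized": fit.r2_generalized,
                "n_pairs": fit.n_obs,
                "selection_trace": trace,
            }
            if config.jackknife_reps > 0 and "cover" in fit.spec.mean_terms:
                bands = glmm.jackknife_predictions(
                    pairs_df, fit.spec, reps=config.jackknife_reps,
                    seed=np.random.default_rng(config.seed),
                )
                stage["prediction_bands"] = {
                    sp: {k: np.asarray(v).tolist() for k, v in d.items()}
                    for sp, d in bands.items()
                }
            report["stages"]["glmm"] = stage
            write_result_json(to_jsonable(stage), outdir / "glmm.json")
        except Exception as exc:
            logger.exception("glmm stage failed")
            report["stages"]["glmm"] = {"status": "failed", "error": str(exc)}
    else:
        logger.warning("glmm stage skipped: no (or too few) preference pairs")
        report["stages"]["glmm"] = {"status": "skipped"}

    # ---- overlap (needs observations) ---------------------------------------
    if observations is not None:
        try:
            focal_obs = [
                o for o in observations if o.fish_species in set(config.overlap_species)
            ]
            years = sorted({o.year for o in focal_obs})
            stage = {"status": "ok", "years": {}}
            rng = np.random.default_rng(config.seed)
            for year in years:
                m = overlap.build_resource_matrix(
                    focal_obs, year, min_obs=config.min_obs_overlap,
                    genera=config.focal_genera,
                )
                logger.info(
                    "overlap %d: %d species pass the >=%d-observations-in-every-year rule",
                    year, len(m.species), config.min_obs_overlap,
                )
                res = overlap.null_model_test(m, n_sim=config.n_sim, seed=rng)
                stage["years"][str(year)] = {
                    "species": m.species,
                    "observed": res.observed,
                    "ses": res.ses,
                    "p_upper": res.p_upper,
                    "p_lower": res.p_lower,
                    "p_two_tailed": res.p_two_tailed,
                    "n_sim": res.n_sim,
                }
            report["stages"]["overlap"] = stage
            write_result_json(stage, outdir / "overlap.json")
        except Exception as exc:
            logger.exception("overlap stage failed")
            report["stages"]["overlap"] = {"status": "failed", "error": str(exc)}
    else:
        report["stages"]["overlap"] = {"status": "skipped"}

    (outdir / "report.json").write_text(json.dumps(to_jsonable(report), indent=2))
    (outdir / "report.md").write_text(_markdown_report(report))
    return report


def _markdown_report(report: dict) -> str:
    lines = ["# coralforage run report", ""]
    for name, stage in report["stages"].items():
        lines.append(f"## {name}: {stage.get('status', '?')}")
        if name == "evenness" and "diet" in stage:
            d = stage["diet"]
            lines.append(
                f"- diet PIE Kruskal-Wallis: H = {d['H']:.3f}, df = {d['df']}, p = {d['p']:.4f}"
            )
            if "coral" in stage:
                c = stage["coral"]
                lines.append(
                    f"- coral PIE Kruskal-Wallis: H = {c['H']:.3f}, df = {c['df']}, p = {c['p']:.4f}"
                )
        if name == "glmm" and stage.get("status") == "ok":
            lines.append(f"- selected terms: {stage['selected_terms']}")
            for k, v in stage["coefficients"].items():
                lo, hi = stage["ci"][k]
                lines.append(f"- {k}: {v:.4f} (95% CI {lo:.4f} to {hi:.4f})")
            lines.append(f"- R2 (likelihood-ratio) = {stage['r2_generalized']}")
        if name == "overlap" and stage.get("status") == "ok":
            for year, r in stage["years"].items():
                lines.append(
                    f"- {year}: mean Pianka = {r['observed']:.4f}, "
                    f"SES = {r['ses']:.2f}, one-tailed p(upper) = {r['p_upper']:.3f}"
                )
        lines.append("")
    return "\n".join(lines)
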
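"""End-to-end orchestration: simulate/load -> filter -> calibrate -> score -> compare.

A single config (YAML/JSON mapping) drives the whole comparison study;
every stage's products are written as plain CSV/JSON so reruns with the
same config and seed are bit-identical.  Stage timings and seeds go to
the run log, never into the report files.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import classical, compare, fit as fit_mod, scoring
from .calibrate import CalibrationResult, EmConfig, calibrate_domain, standard_errors
from .grm import (
    GrmItemParams,
    load_category_maps,
    load_item_params,
    save_item_params,
)
from .instrument import (
    filter_complete,
    load_instrument,
    read_responses,
    saqc_instrument,
)
from .simulate import default_saqc_config, generate_dataset

__all__ = ["run_pipeline", "result_from_items", "load_pipeline_config"]

logger = logging.getLogger("saqirt")


def result_from_items(
    items: list[GrmItemParams],
    domain: str,
    item_order: tuple[str, ...] | None = None,
    category_maps: dict[str, dict[int, int]] | None = None,
) -> CalibrationResult:
    """Wrap externally calibrated item parameters as a scoring-ready result.

    Used when parameters come from a file rather than from this package's
    EM (single N(0,1) population, no likelihood trace).  ``category_maps``
    carries any raw-code recodes recorded with the parameters.
    """
    from .calibrate import LatentGroupParams

    order = item_order or tuple(it.item_id for it in items)
    return CalibrationResult(
        items={it.item_id: it for it in items},
        groups=[LatentGroupParams(label="all", is_reference=True)],
        loglik_trace=[],
        converged=True,
        n_cycles=0,
        domain=domain,
        item_order=order,
        category_maps={
            i: m for i, m in (category_maps or {}).items() if i in order
        },
    )


def load_pipeline_config(source: str | Path | Mapping) -> dict:
    if isinstance(source, Mapping):
        return dict(source)
    path = Path(source)
    text = path.read_text()
    return json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


class _StageTimer:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is None:
            logger.info("stage %s: done in %.2fs", self.name, dt)
        else:
            logger.error("stage %s: failed after %.2fs: %s", self.name, dt, exc)
        return False


def run_pipeline(config: str | Path | Mapping, out_dir: str | Path | None = None) -> dict:
    """Run the full scoring-comparison pipeline from a single config.

    Stages: obtain responses (simulation or CSV), listwise filtering,
    per-domain GRM calibration (or loading item parameters), scoring by
    both methods, optional limited-information fit, and the resolution/
    precision comparison.  Returns a dict with artifact paths and the
    in-memory report objects.  Any stage failure propagates with the
    stage name attached.
    """
    cfg = load_pipeline_config(config)
    out = Path(out_dir or cfg.get("output_dir", "saqirt_out"))
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    artifacts: dict = {"output_dir": out}
    seed = int(cfg.get("seed", 0))
    logger.info("master seed: %d", seed)

    try:
        # ---- acquire responses -------------------------------------------
        with _StageTimer("data"):
            if "simulate" in cfg:
                sim_cfg = dict(cfg["simulate"])
                n = int(sim_cfg.get("n_respondents", 5000))
                config_sim = default_saqc_config(
                    n,
                    seed=int(sim_cfg.get("seed", seed)),
                    missing_rate_items=float(sim_cfg.get("missing_rate_items", 0.005)),
                    missing_rate_group=float(sim_cfg.get("missing_rate_group", 0.04)),
                )
                matrix, truth = generate_dataset(config_sim)
                spec = config_sim.spec
                artifacts["truth"] = truth
            elif "input" in cfg:
                inp = cfg["input"]
                spec = (
                    load_instrument(inp["instrument"])
                    if "instrument" in inp
                    else saqc_instrument()
                )
                matrix = read_responses(inp["responses"], spec)
            else:
                raise ValueError("config needs a 'simulate' or 'input' section")

        # ---- filter ------------------------------------------------------
        with _StageTimer("filter"):
            require_group = bool(
                cfg.get("calibrate", {}).get("multigroup", False)
                and matrix.group is not None
            )
            filtered, report = filter_complete(
                matrix, spec, require_group=require_group or matrix.group is not None
            )
            _json_dump(report.to_dict(), out / "exclusion.json")
            artifacts["exclusion"] = report
            logger.info(
                "filter: %d collected, %d analyzed", report.n_collected, report.n_analyzed
            )

        # ---- calibrate or load parameters --------------------------------
        calib_cfg = dict(cfg.get("calibrate", {}))
        calibs: dict[str, CalibrationResult] = {}
        with _StageTimer("calibrate"):
            if "parameters" in cfg:
                all_items = {it.item_id: it for it in load_item_params(cfg["parameters"])}
                maps = load_category_maps(cfg["parameters"])
                for dom in spec.domain_ids:
                    order = spec.items_for(dom)
                    calibs[dom] = result_from_items(
                        [all_items[i] for i in order], dom, order, category_maps=maps
                    )
            else:
                em = EmConfig(
                    n_quadrature=int(calib_cfg.get("n_quadrature", 49)),
                    max_cycles=int(calib_cfg.get("max_cycles", 500)),
                    tol=float(calib_cfg.get("tol", 1e-4)),
                )
                multigroup = bool(calib_cfg.get("multigroup", False))
                for dom in spec.domain_ids:
                    calibs[dom] = calibrate_domain(
                        filtered, dom, spec, em=em, groups=multigroup or None
                    )
                    logger.info(
                        "calibrate %s: %d cycles, converged=%s, loglik=%.2f",
                        dom,
                        calibs[dom].n_cycles,
                        calibs[dom].converged,
                        calibs[dom].loglik,
                    )
                    if calib_cfg.get("standard_errors", False):
                        standard_errors(calibs[dom], filtered, spec)
                save_item_params(
                    [it for dom in spec.domain_ids for it in calibs[dom].item_list],
                    out / "item_parameters.json",
                    category_maps={
                        i: m
                        for dom in spec.domain_ids
                        for i, m in calibs[dom].category_maps.items()
                    },
                )
                calib_report = {
                    dom: {
                        "converged": c.converged,
                        "n_cycles": c.n_cycles,
                        "loglik_trace": c.loglik_trace,
                        "groups": [
                            {
                                "label": g.label,
                                "mu": g.mu,
                                "sigma": g.sigma,
                                "is_reference": g.is_reference,
                            }
                            for g in c.groups
                        ],
                        "standard_errors": c.standard_errors,
                    }
                    for dom, c in calibs.items()
                }
                _json_dump(calib_report, out / "calibration_report.json")
        artifacts["calibrations"] = calibs

        # ---- score -------------------------------------------------------
        with _StageTimer("score"):
            score_cfg = dict(cfg.get("score", {}))
            rescale_cfg = scoring.RescaleConfig(
                theta_low=float(score_cfg.get("theta_low", -5.0)),
                theta_high=float(score_cfg.get("theta_high", 5.0)),
            )
            mean_scores = classical.domain_mean_scores(filtered, spec)
            irt_scores = scoring.score_matrix(filtered, calibs, spec)
            scores = pd.DataFrame(index=filtered.respondent_ids)
            for dom in spec.domain_ids:
                scores[f"{dom}_mean"] = mean_scores[dom]
                scores[f"{dom}_theta"] = irt_scores[f"{dom}_theta"]
                scores[f"{dom}_theta_2dp"] = irt_scores[f"{dom}_theta_2dp"]
                scores[f"{dom}_psd"] = irt_scores[f"{dom}_psd"]
                scores[f"{dom}_rescaled_0_100"] = scoring.rescale_0_100(
                    irt_scores[f"{dom}_theta"].to_numpy(), rescale_cfg
                )
            scores.to_csv(out / "scores.csv")
            artifacts["scores"] = scores

        # ---- fit ---------------------------------------------------------
        fit_cfg = dict(cfg.get("fit", {}))
        if fit_cfg.get("enabled", True):
            with _StageTimer("fit"):
                theta = irt_scores[[f"{d}_theta" for d in spec.domain_ids]].copy()
                theta.columns = list(spec.domain_ids)
                rel = {
                    d: fit_mod.marginal_reliability(irt_scores[f"{d}_psd"])
                    for d in spec.domain_ids
                }
                fit_domains = fit_cfg.get("domains", list(spec.domain_ids))
                fits = {}
                multigroup_fit = any(len(calibs[d].groups) > 1 for d in fit_domains)
                if multigroup_fit:
                    logger.info("fit: skipping M2 (multigroup calibration)")
                else:
                    for dom in fit_domains:
                        rep = fit_mod.fit_report(calibs[dom], filtered)
                        fits[dom] = rep.to_dict()
                        logger.info(
                            "fit %s: M2=%.2f df=%d RMSEA=%.4f NNFI=%.4f",
                            dom, rep.m2, rep.df, rep.rmsea, rep.nnfi,
                        )
                corr, dis = fit_mod.domain_correlations(theta, rel)
                payload = {
                    "per_domain": fits,
                    "reliabilities": rel,
                    "domain_corr": corr.round(10).to_dict(),
                    "domain_corr_disattenuated": dis.round(10).to_dict(),
                }
                _json_dump(payload, out / "fit.json")
                artifacts["fit"] = payload

        # ---- compare -----------------------------------------------------
        with _StageTimer("compare"):
            cmp_cfg = dict(cfg.get("compare", {}))
            # unrounded EAPs feed the statistics; rounding enters only the
            # unique-value count (via irt_decimals inside the report)
            irt_theta = irt_scores[[f"{d}_theta" for d in spec.domain_ids]].copy()
            irt_theta.columns = list(spec.domain_ids)
            report = compare.comparison_report(
                mean_scores,
                irt_theta,
                spec,
                irt_decimals=cmp_cfg.get("irt_decimals", 2),
            )
            _json_dump(report.to_dict(), out / "comparison.json")
            artifacts["comparison"] = report

            # scatter data for plotting; jitter is cosmetic and output-only
            jitter_sd = float(cfg.get("scatter", {}).get("jitter_sd", 0.3))
            rng = np.random.default_rng(seed + 1)
            rows = []
            for dom in spec.domain_ids:
                m = mean_scores[dom].to_numpy()
                t = irt_theta[dom].to_numpy()
                jit = rng.normal(0.0, jitter_sd, size=m.size) if jitter_sd > 0 else 0.0
                rows.append(
                    pd.DataFrame(
                        {
                            "domain": dom,
                            "mean_score": m,
                            "mean_score_jittered": m + jit,
                            "irt_theta_2dp": t,
                        }
                    )
                )
            pd.concat(rows, ignore_index=True).to_csv(out / "scatter.csv", index=False)
    except Exception:
        logger.removeHandler(handler)
        handler.close()
        raise
    logger.removeHandler(handler)
    handler.close()
    return artifacts
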
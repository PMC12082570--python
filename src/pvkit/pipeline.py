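"""End-to-end orchestration: ingest -> dedup -> signal scan -> TTO -> risk
model -> optional network stage, with a manifest that makes runs reproducible.

Every numeric policy (thresholds, priors, strata cuts, date policy, adjustment
method, seeds) lives in the run config, never in code. Outputs are plain CSV
and JSON under a run directory; re-running an identical config over identical
inputs reproduces the output tree byte for byte, so the manifest carries no
wall-clock timestamp unless one is supplied explicitly in the config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from .disprop import (
    BCPNNPriors,
    Thresholds,
    adjust_pvalues,
    results_to_frame,
    stratified_scan,
)
from .faers_ingest import (
    default_smq,
    deduplicate,
    flag_event_cases,
    ingest_log,
    load_smq,
    read_tables,
    select_ps_reports,
)
from .nettox_lite import GeneSet, degree_hubs, intersect_sets, load_edges
from .risk_model import (
    SeparationError,
    build_model_frame,
    build_nomogram,
    fit_logistic,
    roc_auc,
    select_covariates,
)
from .synth_faers import SimulationConfig, simulate, write_faers_tables
from .tto_weibull import WeibullFitError, compute_tto, fit_weibull, summarize_tto

DEFAULT_STRATA = {"sex": None, "age": 65.0, "weight": 80.0}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(Path(path).read_bytes())
    return digest.hexdigest()


def _write_json(path: Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _slug(name: str) -> str:
    return "".join(ch if ch.isalnum() else "_" for ch in name)


def run_all(config: Mapping[str, object], outdir: Path) -> Path:
    """Run every configured stage into ``outdir``; abort on the first failure
    with the stage name, leaving the manifest written so far on disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "pvkit_version": __version__,
        "config": json.loads(json.dumps(config, default=str)),
        "stages": {},
        "warnings": [],
    }
    if config.get("timestamp"):
        manifest["timestamp"] = str(config["timestamp"])

    def finish_stage(name: str, info: dict) -> None:
        manifest["stages"][name] = info
        _write_json(outdir / "manifest.json", manifest)

    stage = "input"
    try:
        if config.get("simulate"):
            sim_config = SimulationConfig.from_dict(config["simulate"])  # type: ignore[arg-type]
            dataset = simulate(sim_config)
            input_dir = outdir / "input"
            paths = write_faers_tables(dataset, input_dir)
        elif config.get("input_dir"):
            input_dir = Path(str(config["input_dir"]))
            paths = {name: input_dir / f"{name.upper()}.txt" for name in
                     ("demo", "drug", "reac", "ther", "outc")}
        else:
            raise ValueError("config needs either 'simulate' or 'input_dir'")
        try:
            input_label = str(input_dir.resolve().relative_to(outdir.resolve()))
        except ValueError:
            input_label = str(input_dir)
        finish_stage(stage, {
            "input_dir": input_label,
            # a missing table is the ingest stage's named error, not a hash failure
            "input_hashes": {name: _sha256(p) for name, p in sorted(paths.items())
                             if p.exists()},
        })

        stage = "ingest"
        date_policy = str(config.get("date_policy", "strict_day"))
        tables = read_tables(input_dir)
        reports = deduplicate(tables, date_policy=date_policy)
        smq_file = config.get("smq_file")
        smq = load_smq(Path(str(smq_file))) if smq_file else default_smq()
        scope = str(config.get("scope", "narrow"))
        flags = flag_event_cases(reports, smq, scope)
        log = ingest_log(tables, reports, flags, smq, scope)
        _write_json(outdir / "ingest_log.json", log)
        finish_stage(stage, log)

        drugs: List[str] = list(config.get("drugs") or sorted(
            {d.name for r in reports for d in r.drugs if d.role == "PS"}
        ))
        priors = BCPNNPriors(**config.get("priors", {}))  # type: ignore[arg-type]
        thresholds = Thresholds(**config.get("thresholds", {}))  # type: ignore[arg-type]
        strata = config.get("strata", DEFAULT_STRATA)

        stage = "signal"
        all_results = []
        for drug in drugs:
            all_results.extend(
                stratified_scan(
                    reports, drug, smq, strata, scope=scope,
                    priors=priors, thresholds=thresholds,
                )
            )
        all_results = adjust_pvalues(all_results, str(config.get("p_adjust", "fdr_bh")))
        signal_frame = results_to_frame(all_results)
        signal_frame.to_csv(outdir / "signals.csv", index=False)
        finish_stage(stage, {
            "n_pairs": len(all_results),
            "n_signal_positive": int(signal_frame["signal"].sum()) if len(signal_frame) else 0,
        })

        stage = "tto"
        tto_rows = []
        tto_floor = int(config.get("tto_min_n", 30))
        for drug in drugs:
            ps_flagged = [
                r for r in select_ps_reports(reports, drug)
                if flags.get(r.primary_id, False)
            ]
            sample = compute_tto(ps_flagged, drug)
            row: dict = {
                "drug": drug,
                "n": sample.n,
                "n_excluded_missing": sample.n_excluded_missing,
                "n_excluded_nonpositive": sample.n_excluded_nonpositive,
            }
            if sample.n:
                row.update(summarize_tto(sample))
            if sample.n >= 2:
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", UserWarning)
                        fit = fit_weibull(sample, min_n=tto_floor)
                    row.update(
                        alpha=fit.alpha, alpha_lo=fit.alpha_ci95[0],
                        alpha_hi=fit.alpha_ci95[1], beta=fit.beta,
                        beta_lo=fit.beta_ci95[0], beta_hi=fit.beta_ci95[1],
                        failure_type=fit.failure_type,
                    )
                except WeibullFitError as exc:
                    manifest["warnings"].append(f"tto: {drug}: {exc}")
            tto_rows.append(row)
        pd.DataFrame(tto_rows).to_csv(outdir / "tto.csv", index=False)
        finish_stage(stage, {"n_drugs": len(tto_rows)})

        stage = "risk"
        risk_config = config.get("risk")
        if risk_config:
            covariates = list(risk_config.get("covariates", ["age_le65", "weight_gt80", "female"]))
            conmeds = list(risk_config.get("conmeds", []))
            p_enter = float(risk_config.get("p_enter", 0.05))
            risk_drugs = list(risk_config.get("drugs") or drugs)
            fitted = {}
            for drug in risk_drugs:
                frame = build_model_frame(reports, drug, flags, conmeds=conmeds)
                all_covs = covariates + [f"conmed:{c}" for c in conmeds]
                uni = {}
                for cov in all_covs:
                    try:
                        uni[cov] = fit_logistic(frame, [cov], mode="univariable")[cov]
                    except (SeparationError, ValueError) as exc:
                        manifest["warnings"].append(f"risk: {drug}: skipped {cov}: {exc}")
                selected = select_covariates(uni, p_enter)
                multi = None
                if selected:
                    try:
                        multi = fit_logistic(frame, selected, mode="multivariable")
                    except (SeparationError, ValueError) as exc:
                        manifest["warnings"].append(f"risk: {drug}: multivariable: {exc}")
                rows = []
                for cov, model in uni.items():
                    or_u, lo_u, hi_u = model.odds_ratios[cov]
                    row = {
                        "drug": drug, "variable": cov,
                        "p_univariable": model.pvalues[cov],
                        "or_univariable": or_u,
                        "or_univariable_lo": lo_u, "or_univariable_hi": hi_u,
                        "p_multivariable": None, "or_multivariable": None,
                        "or_multivariable_lo": None, "or_multivariable_hi": None,
                    }
                    if multi is not None and cov in multi.covariates:
                        or_m, lo_m, hi_m = multi.odds_ratios[cov]
                        row.update(
                            p_multivariable=multi.pvalues[cov],
                            or_multivariable=or_m,
                            or_multivariable_lo=lo_m,
                            or_multivariable_hi=hi_m,
                        )
                    rows.append(row)
                slug = _slug(drug)
                pd.DataFrame(rows).to_csv(outdir / f"risk_{slug}.csv", index=False)
                if multi is not None:
                    nomogram = build_nomogram(multi)
                    _write_json(outdir / f"nomogram_{slug}.json", nomogram.to_dict())
                    auc, curve = roc_auc(multi, frame)
                    curve.to_csv(outdir / f"roc_{slug}.csv", index=False)
                    fitted[drug] = {"auc": auc, "n_obs": multi.n_obs,
                                    "covariates": list(multi.covariates)}
            finish_stage(stage, fitted)
        else:
            finish_stage(stage, {"skipped": True})

        stage = "nettox"
        net_config = config.get("nettox")
        if net_config:
            targets = GeneSet.from_file(Path(str(net_config["targets"])), "drug_targets")
            disease = GeneSet.from_file(Path(str(net_config["disease"])), "disease_genes")
            overlap = intersect_sets(targets, disease)
            graph = load_edges(
                Path(str(net_config["edges"])),
                score_floor=float(net_config.get("score_floor", 0.15)),
            )
            hubs = degree_hubs(graph, int(net_config.get("top", 3)))
            _write_json(outdir / "nettox.json", {
                "n_targets": len(targets),
                "n_disease": len(disease),
                "intersection": sorted(overlap.symbols),
                "n_intersection": len(overlap),
                "score_rescaled": graph.score_rescaled,
                "hubs": [{"gene": g, "degree": d} for g, d in hubs],
            })
            finish_stage(stage, {"n_intersection": len(overlap), "n_hubs": len(hubs)})
        else:
            finish_stage(stage, {"skipped": True})
    except PipelineError:
        raise
    except Exception as exc:
        _write_json(outdir / "manifest.json", manifest)
        raise PipelineError(stage, exc) from exc

    return outdir


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def _render_frame(frame: pd.DataFrame) -> str:
    if frame.empty:
        return "(no rows)"
    return frame.to_string(index=False, float_format=lambda v: f"{v:.4g}")


def make_report(outdir: Path) -> Path:
    """Assemble a single human-readable summary from the run outputs.

    Missing stage outputs leave a flagged gap instead of failing.
    Regeneration over unchanged outputs is byte-identical.
    """
    outdir = Path(outdir)
    lines = ["# Pharmacovigilance run report", ""]

    signals_path = outdir / "signals.csv"
    lines.append("## Signal detection")
    if signals_path.exists():
        frame = pd.read_csv(signals_path)
        positive = frame[frame["signal"] == True]  # noqa: E712
        if positive.empty:
            lines.append("No signal-positive drug-event pairs under the joint criteria.")
        else:
            lines.append(_render_frame(positive))
        lines.append("")
        lines.append("### All strata")
        lines.append(_render_frame(frame))
    else:
        lines.append("*(stage not run)*")
    lines.append("")

    tto_path = outdir / "tto.csv"
    lines.append("## Time to onset")
    lines.append(_render_frame(pd.read_csv(tto_path)) if tto_path.exists() else "*(stage not run)*")
    lines.append("")

    lines.append("## Risk models")
    risk_files = sorted(outdir.glob("risk_*.csv"))
    if risk_files:
        for path in risk_files:
            lines.append(f"### {path.stem}")
            lines.append(_render_frame(pd.read_csv(path)))
            lines.append("")
    else:
        lines.append("*(stage not run)*")
    lines.append("")

    lines.append("## Network hubs")
    nettox_path = outdir / "nettox.json"
    if nettox_path.exists():
        payload = json.loads(nettox_path.read_text())
        lines.append(f"Intersection size: {payload['n_intersection']}")
        for hub in payload["hubs"]:
            lines.append(f"- {hub['gene']} (degree {hub['degree']})")
    else:
        lines.append("*(stage not run)*")
    lines.append("")

    report_path = outdir / "report.md"
    report_path.write_text("\n".join(lines))
    return report_path
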
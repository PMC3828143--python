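"""End-to-end pipeline: quantify -> estimate-rate -> fit-hotspot -> nco-tracts -> tests.

A single structured config (dict or YAML file) names the input tables and
analysis parameters; :func:`run_pipeline` executes the stages in order,
writes per-stage JSON/TSV outputs under ``out_dir``, and records a run
manifest with the seed, a stable config digest, and every output path.
Any stage failure aborts with the stage name and cause.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from . import io as ptio
from .dilution import PriorSpec, PrimerKind, estimate, posterior_scan, quantify_by_poisson
from .hotspot import (
    fit_gaussian_mixture,
    interval_rates,
    median_breakpoint_position,
    orientation_separation,
)
from .nco import nco_frequency, summarize_tracts, tract_bounds
from .statistics import ContingencyTable2x2, fisher_exact, leftright_orientation_test

__all__ = ["PipelineError", "RunManifest", "run_pipeline", "load_config"]

log = logging.getLogger("pollentyping")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunManifest:
    """Record of one pipeline run."""

    seed: int
    config_digest: str
    version: str
    inputs: dict[str, str]
    outputs: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def config_digest(config: dict[str, Any]) -> str:
    canon = yaml.safe_dump(config, sort_keys=True).encode()
    return hashlib.sha256(canon).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as e:
                raise PipelineError(f"stage {name!r} failed: {e}") from e

        return wrapped

    return deco


def run_pipeline(config: dict[str, Any] | str | Path, out_dir: str | Path | None = None) -> RunManifest:
    """Run the full analysis described by ``config``.

    Config keys: ``seed``; ``inputs`` (``marker_map``, ``plates``,
    ``breakpoints``, ``nco_events`` paths); ``params`` (``f``, ``r_max``,
    ``grid: {n_C, n_r}``, ``components``, ``n_genomes``).
    """
    if not isinstance(config, dict):
        config = load_config(config)
    inputs = config.get("inputs", {})
    params = config.get("params", {})
    seed = int(config.get("seed", 0))
    out = Path(out_dir or config.get("out_dir", "."))
    out.mkdir(parents=True, exist_ok=True)

    for key in ("marker_map", "plates", "breakpoints", "nco_events"):
        p = inputs.get(key)
        if p is None or not Path(p).exists():
            raise PipelineError(f"stage 'inputs' failed: missing input {key!r}: {p}")

    manifest = RunManifest(
        seed=seed,
        config_digest=config_digest(config),
        version=__version__,
        inputs={k: str(v) for k, v in inputs.items()},
    )
    f = float(params.get("f", 0.5))

    marker_map = ptio.read_marker_map(inputs["marker_map"])
    series = ptio.read_plate_table(inputs["plates"])
    breakpoints = ptio.read_breakpoints(inputs["breakpoints"])
    events = ptio.read_nco_events(inputs["nco_events"])

    # --- quantify: e^-m Poisson quantification of the parental plates
    @_stage("quantify")
    def run_quantify():
        parental = series[PrimerKind.PARENTAL]
        rows = []
        for e in parental.entries:
            if e.negatives == 0:
                continue  # saturated plate carries no MPN information
            q = quantify_by_poisson(e.wells, e.negatives, e.dilution, f)
            rows.append(
                {
                    "dilution": e.dilution,
                    "wells": e.wells,
                    "negatives": e.negatives,
                    "m_per_well": q.m,
                    "undiluted_count": q.undiluted_count,
                }
            )
        path = out / "quantify.json"
        path.write_text(json.dumps(rows, indent=2))
        manifest.outputs["quantify"] = str(path)

    # --- estimate-rate: Bayesian posterior scan over (C, r)
    @_stage("estimate-rate")
    def run_estimate() -> float:
        prior = PriorSpec(r_max=float(params.get("r_max", 0.1)))
        grid = params.get("grid", {})
        post = posterior_scan(
            series[PrimerKind.PARENTAL],
            series.get(PrimerKind.RECOMBINANT),
            prior,
            f=f,
            n_C=int(grid.get("n_C", 200)),
            n_r=int(grid.get("n_r", 200)),
        )
        result = {}
        for which in ("C", "r"):
            est = estimate(post, which)
            result[which] = {
                "mean": est.mean,
                "mode": est.mode,
                "ci95": [est.lower, est.upper],
            }
        result["unit"] = "proportion"
        path = out / "estimate.json"
        path.write_text(json.dumps(result, indent=2))
        manifest.outputs["estimate-rate"] = str(path)
        return result["r"]["mean"]

    # --- fit-hotspot: cM/Mb profile and Gaussian shape fit
    @_stage("fit-hotspot")
    def run_fit(freq: float):
        profile = interval_rates(breakpoints, marker_map, freq)
        ptio.write_profile(profile, out / "profile.tsv")
        K = int(params.get("components", 1))
        fits = fit_gaussian_mixture(profile, K, seed=seed)
        fit_json = [
            {
                "mu": g.mu,
                "sigma": g.sigma,
                "weight": g.weight,
                "width95": g.width95,
                "sse": g.sse,
            }
            for g in fits
        ]
        (out / "fit.json").write_text(json.dumps(fit_json, indent=2))
        manifest.outputs["fit-hotspot"] = str(out / "fit.json")
        manifest.outputs["profile"] = str(out / "profile.tsv")

    # --- nco-tracts: tract bounds and frequencies
    @_stage("nco-tracts")
    def run_nco():
        tracts = [tract_bounds(e, marker_map) for e in events]
        result: dict[str, Any] = {"n_events": len(events)}
        if any(t.bounded for t in tracts):
            summary = summarize_tracts(tracts)
            result["tracts"] = {
                "mean_min_bp": summary.mean_min_bp,
                "mean_max_bp": summary.mean_max_bp,
                "averaged_mid_bp": summary.averaged_mid_bp,
            }
        n_genomes = int(params.get("n_genomes", 0))
        if n_genomes:
            freq = nco_frequency(len(events), n_genomes)
            result["frequency"] = {
                "rate": freq.rate,
                "ci95": [freq.ci_lower, freq.ci_upper],
                "unit": "proportion",
            }
        by_orient: dict[str, int] = {}
        for e in events:
            by_orient[e.orientation] = by_orient.get(e.orientation, 0) + 1
        result["orientation_counts"] = by_orient
        result["n_chimeric"] = sum(1 for e in events if e.chimeric)
        path = out / "nco_summary.json"
        path.write_text(json.dumps(path_safe(result), indent=2))
        manifest.outputs["nco-tracts"] = str(path)

    # --- tests: orientation asymmetry statistics
    @_stage("tests")
    def run_tests():
        result: dict[str, Any] = {}
        median = median_breakpoint_position(breakpoints)
        try:
            table, p = leftright_orientation_test(breakpoints, median)
            result["leftright_orientation"] = {
                "table": [[table.a, table.b], [table.c, table.d]],
                "p_two_tailed": p,
            }
            result["orientation_separation_bp"] = orientation_separation(breakpoints)
        except ValueError as e:
            result["leftright_orientation"] = {"skipped": str(e)}
        n_p1 = sum(1 for e in events if e.orientation == "P1toP2toP1")
        n_p2 = sum(1 for e in events if e.orientation == "P2toP1toP2")
        n_genomes = int(params.get("n_genomes", 0))
        if n_genomes and (n_p1 or n_p2):
            table = ContingencyTable2x2(
                n_p2, n_genomes - n_p2, n_p1, n_genomes - n_p1
            )
            result["nco_orientation"] = {
                "counts": {"P2toP1toP2": n_p2, "P1toP2toP1": n_p1},
                "p_one_tailed": fisher_exact(table, "one_tailed_less"),
            }
        path = out / "tests.json"
        path.write_text(json.dumps(result, indent=2))
        manifest.outputs["tests"] = str(path)

    run_quantify()
    freq = run_estimate()
    run_fit(freq)
    run_nco()
    run_tests()
    manifest.to_json(out / "run_manifest.json")
    manifest.outputs["manifest"] = str(out / "run_manifest.json")
    return manifest


def path_safe(obj: Any) -> Any:
    """Recursively convert numpy scalars for JSON serialization."""
    import numpy as np

    if isinstance(obj, dict):
        return {k: path_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [path_safe(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
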
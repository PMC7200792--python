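"""The experiment runner: one config in, a reproducible set of artifacts out.

A run config (YAML or dict) describes a scene (phantom + optics + noise), a
method (``physennet``, ``gs``, ``tie`` or ``red``) with its settings, an
output directory and a master seed.  :func:`run_experiment` generates the
scene, runs the method, evaluates against the synthetic ground truth, and
writes: the reconstructed phase (float TIFF + metadata), the optimisation
trace (CSV ``epoch,loss[,mse]``), a JSON report and a manifest capturing the
effective config, all seeds and the package version.  Re-running from a
manifest reproduces the outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .baselines import GSConfig, REDConfig, TIEInput, gs_retrieve, red_reconstruct, tie_solve
from .core import NetworkSpec, OptimizationConfig, reconstruct, reconstruct_multi
from .io import parse_length, write_image, write_metadata
from .metrics import evaluate
from .optics import PropagationSpec
from .phantoms import NoiseSpec, PhantomSpec, generate_phantom, simulate_measurement

__all__ = ["run_experiment", "load_config", "CONFIG_VERSION", "METHODS"]

CONFIG_VERSION = 1
METHODS = ("physennet", "gs", "tie", "red")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _scene_from_config(cfg: dict, master_seed: int):
    scene = cfg.get("scene", {})
    ph = dict(scene.get("phantom", {}))
    ph.setdefault("seed", master_seed)
    phantom_spec = PhantomSpec(**ph)
    opt = scene.get("optics", {})
    pspec = PropagationSpec(
        wavelength=parse_length(opt.get("wavelength", "632.8nm")),
        pitch=parse_length(opt.get("pitch", "8um")),
        distance=parse_length(opt.get("distance", "10mm")),
        pad_factor=int(opt.get("pad_factor", 1)),
    )
    noise = NoiseSpec(**scene.get("noise", {"model": "none"}))
    return phantom_spec, pspec, noise


def _simulate(phase, pspec, noise, seed, distance=None):
    spec = pspec if distance is None else pspec.with_distance(parse_length(distance))
    return simulate_measurement(phase, spec, noise, seed=seed), spec


def run_experiment(config: dict, output_dir: str | Path | None = None) -> dict:
    """Run one synthetic-scene experiment and write its artifacts.

    Returns the manifest (also written to ``manifest.json``).  On failure,
    partial outputs are removed and the failure is recorded in the manifest.
    """
    cfg = dict(config)
    method = cfg.get("method")
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}: valid methods are {METHODS}")
    seed = int(cfg.get("seed", 0))
    out = Path(output_dir if output_dir is not None else cfg.get("output_dir", "runs"))
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "config_version": cfg.get("version", CONFIG_VERSION),
        "package_version": __version__,
        "method": method,
        "seed": seed,
        "config": cfg,
        "outputs": {},
    }
    written: list[Path] = []
    try:
        phantom_spec, pspec, noise = _scene_from_config(cfg, seed)
        truth = generate_phantom(phantom_spec)
        mcfg = dict(cfg.get(method, {}))
        trace = None

        if method == "physennet":
            nspec = NetworkSpec(**mcfg.get("network", {}))
            ocfg = dict(mcfg.get("optimization", {}))
            ocfg.setdefault("seed", seed)
            oconfig = OptimizationConfig(**ocfg)
            distances = mcfg.get("distances")
            if distances:
                Is, specs = [], []
                for i, d in enumerate(distances):
                    I, sp = _simulate(truth, pspec, noise, seed + 1 + i, d)
                    Is.append(I)
                    specs.append(sp)
                res = reconstruct_multi(Is, specs, nspec, oconfig, ground_truth=truth)
            else:
                I, _ = _simulate(truth, pspec, noise, seed + 1)
                res = reconstruct(I, pspec, nspec, oconfig, ground_truth=truth)
            phase, trace = res.phase, res
        elif method == "red":
            nspec = NetworkSpec(**mcfg.get("network", {}))
            ocfg = dict(mcfg.get("optimization", {}))
            ocfg.setdefault("seed", seed)
            oconfig = OptimizationConfig(**ocfg)
            rcfg = REDConfig(
                lambda_red=float(mcfg.get("lambda_red", 0.05)),
                denoiser=mcfg.get("denoiser", "gaussian"),
                denoiser_params=mcfg.get("denoiser_params", {}),
            )
            I, _ = _simulate(truth, pspec, noise, seed + 1)
            phase = red_reconstruct(I, pspec, nspec, rcfg, oconfig)
        elif method == "gs":
            distances = mcfg.get("distances", ["10mm", "15mm", "20mm", "25mm", "30mm"])
            planes = []
            for i, d in enumerate(distances):
                I, sp = _simulate(truth, pspec, noise, seed + 1 + i, d)
                planes.append((I, sp.distance))
            gs_cfg = GSConfig(
                planes=planes,
                n_iterations=int(mcfg.get("n_iterations", 200)),
                init_phase=mcfg.get("init_phase", "zeros"),
                seed=seed,
            )
            phase = gs_retrieve(gs_cfg, pspec)
        else:  # tie
            dz = parse_length(mcfg.get("delta_z", "0.5mm"))
            d0 = pspec.distance
            Im, _ = _simulate(truth, pspec, noise, seed + 1, d0 - dz)
            I0, _ = _simulate(truth, pspec, noise, seed + 2, d0)
            Ip, _ = _simulate(truth, pspec, noise, seed + 3, d0 + dz)
            phase = tie_solve(
                TIEInput(Im, I0, Ip, dz), pspec, mode=mcfg.get("mode", "uniform")
            )

        report = evaluate(phase, truth, rescale=True, method=method,
                          scene=phantom_spec.kind)
        phase_path = out / f"{method}_phase.tiff"
        write_image(phase_path, phase)
        written.append(phase_path)
        written.append(write_metadata(phase_path, pspec.with_distance(0.0)))
        if trace is not None:
            trace_path = out / f"{method}_trace.csv"
            _write_trace(trace_path, trace)
            written.append(trace_path)
            manifest["outputs"]["trace"] = trace_path.name
        report_path = out / f"{method}_report.json"
        report_path.write_text(json.dumps({
            "mse": report.mse,
            "rescale_gain": report.rescale_gain,
            "rescale_offset": report.rescale_offset,
            "negated": report.negated,
            "method": method,
        }, indent=2))
        written.append(report_path)
        manifest["outputs"]["phase"] = phase_path.name
        manifest["outputs"]["report"] = report_path.name
        manifest["mse"] = report.mse
        manifest["status"] = "ok"
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _write_trace(path: Path, res) -> None:
    mse_by_epoch = {}
    if res.mse_trace is not None:
        mse_by_epoch = {int(e): m for e, m in res.mse_trace}
    with open(path, "w") as fh:
        fh.write("epoch,loss,mse\n" if mse_by_epoch else "epoch,loss\n")
        for e, l in res.loss_trace:
            if mse_by_epoch:
                m = mse_by_epoch.get(int(e), "")
                fh.write(f"{int(e)},{l:.8g},{m}\n")
            else:
                fh.write(f"{int(e)},{l:.8g}\n")
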
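"""End-to-end pipeline: declarative config, staged execution, run manifest.

A run is described by one YAML config with a global seed and per-stage
blocks.  Stages execute in dependency order; each stage records a hash of
its parameters and input files in the run manifest, and an unchanged stage
is skipped on rerun (cache hit).  Fixed seeds and inputs give byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__, collagen_fourier, colorimetry, ordination, platelets, synthetic_data

logger = logging.getLogger(__name__)

#: execution order and the keys each stage block accepts
STAGE_SCHEMA: dict[str, set[str]] = {
    "simulate_spectra": {"n_per_group", "noise_sd", "groups", "wl_step_nm", "seed"},
    "spectra": {"input", "samples", "span", "exclude_melanistic"},
    "rda": {"summary", "samples", "constrain", "condition", "n_perm", "seed"},
    "simulate_platelets": {
        "n_platelets", "thickness_nm", "width_nm", "aligned_fraction",
        "angle_sigma_deg", "scale_nm_per_px", "noise", "image_px", "shape", "seed",
    },
    "platelets": {"image", "scale_nm_per_px", "mode", "bin_deg", "min_area_px", "n_platelet"},
    "simulate_collagen": {
        "mean_spacing_nm", "spacing_cv", "fibre_diameter_nm",
        "scale_nm_per_px", "size_px", "seed",
    },
    "collagen": {"image", "scale_nm_per_px", "square_px", "window"},
}
STAGE_ORDER = list(STAGE_SCHEMA)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    """Check the stage list and per-stage keys; raise listing offenders."""
    unknown_top = set(cfg) - {"seed", "out_dir", "stages"}
    if unknown_top:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown_top)}")
    stages = cfg.get("stages") or {}
    if not isinstance(stages, dict) or not stages:
        raise ValueError("config must define a non-empty 'stages' mapping")
    bad_stages = set(stages) - set(STAGE_SCHEMA)
    if bad_stages:
        raise ValueError(f"unknown stages: {sorted(bad_stages)}")
    offending = {
        stage: sorted(set(block or {}) - STAGE_SCHEMA[stage])
        for stage, block in stages.items()
        if set(block or {}) - STAGE_SCHEMA[stage]
    }
    if offending:
        raise ValueError(f"unknown keys per stage: {offending}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_hash(params: dict, input_hashes: dict[str, str]) -> str:
    blob = json.dumps({"params": params, "inputs": input_hashes},
                      sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


class PipelineError(ValueError):
    pass


def run_pipeline(config: str | Path | dict, out_dir: str | Path | None = None) -> dict:
    """Execute the configured stages; return the run manifest (also written).

    Reruns against an existing output directory skip stages whose parameter
    and input hashes are unchanged and whose outputs still exist.
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else dict(config)
    if not isinstance(config, (str, Path)):
        validate_config(cfg)
    out = Path(out_dir or cfg.get("out_dir", "iridoscan_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    stages: dict = cfg["stages"]

    # resolve inputs up front so missing files fail before any stage runs
    resolved: dict[str, dict] = {}
    for stage in STAGE_ORDER:
        if stage not in stages:
            continue
        block = dict(stages[stage] or {})
        inputs = _stage_inputs(stage, block, stages, out)
        for name, p in inputs.items():
            # inputs left at their defaults may be produced by earlier stages
            excused = name not in block and _produced_by_earlier_stage(stage, name, stages)
            if not p.exists() and not excused:
                raise PipelineError(f"stage '{stage}': missing input file {p}")
        resolved[stage] = block

    manifest_path = out / "manifest.json"
    previous = {}
    if manifest_path.exists():
        with open(manifest_path) as fh:
            previous = json.load(fh).get("stages", {})

    config_blob = json.dumps(cfg, sort_keys=True, default=str)
    manifest: dict[str, Any] = {
        "tool": "iridoscan",
        "version": __version__,
        "config_hash": hashlib.sha256(config_blob.encode()).hexdigest(),
        "seed": seed,
        "stages": {},
    }

    for stage in STAGE_ORDER:
        if stage not in resolved:
            continue
        block = resolved[stage]
        inputs = _stage_inputs(stage, block, stages, out)
        input_hashes = {k: _sha256(p) for k, p in inputs.items() if p.exists()}
        shash = _stage_hash(block, input_hashes)
        prev = previous.get(stage)
        outputs = [out / f for f in _stage_outputs(stage)]
        if prev and prev.get("hash") == shash and all(p.exists() for p in outputs):
            logger.info("stage %s: cache hit, skipped", stage)
            manifest["stages"][stage] = {**prev, "cache_hit": True}
            continue
        t0 = time.time()
        counts = _run_stage(stage, block, stages, out, seed)
        manifest["stages"][stage] = {
            "hash": shash,
            "params": block,
            "inputs": input_hashes,
            "outputs": [p.name for p in outputs],
            "counts": counts,
            "cache_hit": False,
            "elapsed_s": round(time.time() - t0, 3),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def _produced_by_earlier_stage(stage: str, name: str, stages: dict) -> bool:
    producers = {
        "spectra": {"input": "simulate_spectra", "samples": "simulate_spectra"},
        "rda": {"summary": "spectra", "samples": "simulate_spectra"},
        "platelets": {"image": "simulate_platelets"},
        "collagen": {"image": "simulate_collagen"},
    }
    producer = producers.get(stage, {}).get(name)
    return producer is not None and producer in stages


def _stage_inputs(stage: str, block: dict, stages: dict, out: Path) -> dict[str, Path]:
    defaults = {
        "spectra": {"input": out / "spectra.csv", "samples": out / "samples.csv"},
        "rda": {"summary": out / "summary.csv", "samples": out / "samples.csv"},
        "platelets": {"image": out / "platelets.tif"},
        "collagen": {"image": out / "collagen.tif"},
    }
    names = defaults.get(stage, {})
    return {k: Path(block.get(k, v)) for k, v in names.items()}


def _stage_outputs(stage: str) -> list[str]:
    return {
        "simulate_spectra": ["spectra.csv", "samples.csv", "truth.csv"],
        "spectra": ["summary.csv"],
        "rda": ["rda.json", "scores.csv"],
        "simulate_platelets": ["platelets.tif", "platelets_truth.csv"],
        "platelets": ["platelets.csv", "angular.json", "wavelengths.csv"],
        "simulate_collagen": ["collagen.tif", "collagen_truth.csv"],
        "collagen": ["radial.csv", "reflectivity.csv"],
    }[stage]


def _run_stage(stage: str, block: dict, stages: dict, out: Path, seed: int) -> dict:
    if stage == "simulate_spectra":
        groups = {
            name: synthetic_data.GroupEffect(**(g or {}))
            for name, g in (block.get("groups") or {"A": {}}).items()
        }
        spectra, truth = synthetic_data.gen_spectra(
            n_per_group=int(block.get("n_per_group", 10)),
            groups=groups,
            noise_sd=float(block.get("noise_sd", 0.5)),
            seed=int(block.get("seed", seed)),
            wl_step_nm=float(block.get("wl_step_nm", 1.0)),
        )
        synthetic_data.write_spectra_files(spectra, truth, out)
        return {"spectra": len(spectra)}

    if stage == "spectra":
        inputs = _stage_inputs(stage, block, stages, out)
        spectra = colorimetry.read_spectra(
            inputs["input"], inputs["samples"],
            exclude_melanistic=bool(block.get("exclude_melanistic", False)),
        )
        span = float(block.get("span", 0.3))
        table = colorimetry.summarize_table(spectra, span=span)
        colorimetry.write_summary(table, out / "summary.csv", params={"span": span})
        return {"spectra": len(spectra)}

    if stage == "rda":
        inputs = _stage_inputs(stage, block, stages, out)
        summary = pd.read_csv(inputs["summary"])
        sheet = pd.read_csv(inputs["samples"], dtype=str)
        Y = ordination.standardize(summary[colorimetry.SUMMARY_COLUMNS])
        X = ordination.design_matrix(sheet, block.get("constrain", ["taxon"]))
        cond = block.get("condition")
        Z = ordination.design_matrix(sheet, cond) if cond else None
        model = ordination.RDA(
            n_permutations=int(block.get("n_perm", 9999)),
            random_state=int(block.get("seed", seed)),
        ).fit(Y, X, Z)
        res = model.result_
        report = {
            "constrained_eigenvalues": res.constrained_eigenvalues.tolist(),
            "residual_eigenvalues": res.residual_eigenvalues.tolist(),
            "prop_variance": res.prop_variance.tolist(),
            "pseudo_F": res.pseudo_F,
            "p_value": res.p_value,
            "n_perm": res.n_perm,
            "adj_R2": res.adj_R2,
            "seed": res.seed,
        }
        with open(out / "rda.json", "w") as fh:
            json.dump(report, fh, indent=2)
        pd.DataFrame(
            res.site_scores,
            columns=[f"RDA{i+1}" for i in range(res.site_scores.shape[1])],
        ).to_csv(out / "scores.csv", index=False)
        return {"rows": len(summary)}

    if stage == "simulate_platelets":
        img, truth = synthetic_data.gen_platelet_image(
            n_platelets=int(block.get("n_platelets", 150)),
            thickness_nm=tuple(block.get("thickness_nm", (90.0, 30.0))),
            width_nm=tuple(block.get("width_nm", (395.0, 120.0))),
            aligned_fraction=float(block.get("aligned_fraction", 0.8)),
            angle_sigma_deg=float(block.get("angle_sigma_deg", 25.0)),
            scale_nm_per_px=float(block.get("scale_nm_per_px", 5.0)),
            noise=float(block.get("noise", 0.0)),
            image_px=int(block.get("image_px", 1400)),
            shape=block.get("shape", "ellipse"),
            seed=int(block.get("seed", seed)),
        )
        tifffile.imwrite(out / "platelets.tif", img)
        truth.table.to_csv(out / "platelets_truth.csv", index=False)
        return {"platelets": len(truth.table)}

    if stage == "platelets":
        inputs = _stage_inputs(stage, block, stages, out)
        scale = float(block.get("scale_nm_per_px") or
                      _truth_param(out / "platelets_truth.csv", stages, "scale_nm_per_px", 5.0))
        img = tifffile.imread(inputs["image"])
        pset = platelets.measure_micrograph(
            img, scale, mode=block.get("mode", "intact"),
            min_area_px=int(block.get("min_area_px", 20)),
        )
        pset.records.to_csv(out / "platelets.csv", index=False)
        org = platelets.angular_organization(pset, bin_deg=float(block.get("bin_deg", 5.0)))
        model = platelets.ThinFilmModel(n_platelet=float(block.get("n_platelet", 1.83)))
        peak = platelets.predicted_wavelength_peak(pset, model)
        with open(out / "angular.json", "w") as fh:
            json.dump({**org.as_dict(), "predicted_peak_nm": peak,
                       "n_platelets": len(pset)}, fh, indent=2)
        lam = platelets.thin_film_wavelength(pset.minor_nm, model)
        hist, edges = np.histogram(lam, bins=25)
        pd.DataFrame({
            "wavelength_lo_nm": edges[:-1], "wavelength_hi_nm": edges[1:], "count": hist,
        }).to_csv(out / "wavelengths.csv", index=False)
        return {"platelets": len(pset)}

    if stage == "simulate_collagen":
        img, truth = synthetic_data.gen_collagen_image(
            mean_spacing_nm=float(block.get("mean_spacing_nm", 200.0)),
            spacing_cv=float(block.get("spacing_cv", 0.1)),
            fibre_diameter_nm=float(block.get("fibre_diameter_nm", 110.0)),
            scale_nm_per_px=float(block.get("scale_nm_per_px", 18.0)),
            size_px=int(block.get("size_px", 800)),
            seed=int(block.get("seed", seed)),
        )
        tifffile.imwrite(out / "collagen.tif", img)
        truth.table.to_csv(out / "collagen_truth.csv", index=False)
        return {"fibres": int(truth.table["n_fibres"].iloc[0])}

    if stage == "collagen":
        inputs = _stage_inputs(stage, block, stages, out)
        scale = float(block.get("scale_nm_per_px") or
                      _truth_param(out / "collagen_truth.csv", stages, "scale_nm_per_px", 18.0))
        img = tifffile.imread(inputs["image"])
        cfg_f = collagen_fourier.FourierConfig(
            square_px=int(block.get("square_px", min(800, min(img.shape)))),
            window=block.get("window", "none"),
        )
        profile, refl = collagen_fourier.analyze_micrograph(img, scale, cfg_f)
        pd.DataFrame({"freq_per_nm": profile.freq_per_nm, "power": profile.power}
                     ).to_csv(out / "radial.csv", index=False)
        pd.DataFrame({
            "wavelength_nm": refl.wavelength_nm, "reflectivity": refl.reflectivity,
        }).to_csv(out / "reflectivity.csv", index=False)
        return {"bins": len(refl.wavelength_nm)}

    raise PipelineError(f"unknown stage {stage}")  # pragma: no cover


def _truth_param(truth_csv: Path, stages: dict, key: str, default: float) -> float:
    for name in ("simulate_platelets", "simulate_collagen"):
        block = stages.get(name) or {}
        if key in block:
            return float(block[key])
    return default
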
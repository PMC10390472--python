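"""Reproducible multi-stage pipelines driven by one configuration.

A :class:`PipelineConfig` lists stages with parameter blocks and a single
global seed; the seed is fanned out to per-stage child seeds by stable
hashing, so adding a stage never shifts another stage's random stream. The
run writes a manifest recording parameters, seeds and SHA-256 hashes of
every output file.
"""

from __future__ import annotations

import hashlib
import inspect
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import fibers, phantoms, pores
from .core import child_seed
from .io import write_image

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Stage list + parameter blocks + global seed + output directory."""

    output_dir: str | Path
    seed: int = 0
    stages: list[dict] = field(default_factory=list)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        return cls(
            output_dir=raw.get("output_dir", "."),
            seed=int(raw.get("seed", 0)),
            stages=list(raw.get("stages", [])),
        )

    def to_dict(self) -> dict:
        return {"output_dir": str(self.output_dir), "seed": self.seed, "stages": self.stages}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# --- stage implementations ---------------------------------------------------

def _stage_simulate_fibers(params: dict, seed: int, outdir: Path, ctx: dict) -> list[Path]:
    phantom = phantoms.FiberNetworkPhantom.grid(
        field_size_um=tuple(params.get("field_size_um", (100.0, 100.0))),
        pixel_size_um=params.get("pixel_size_um", 0.1),
        gap_rate_per_um=params.get("gap_rate_per_um", 1 / 3),
        sigma_nm=params.get("sigma_nm", 130.0),
        orientation=params.get("orientation", "cross"),
        seed=seed,
    )
    image = phantoms.generate_fiber_image(
        phantom,
        modality=params.get("modality", "confocal"),
        noise=params.get("noise", True),
    )
    ctx["image"] = image
    out = outdir / "fiber_phantom.tif"
    write_image(out, image)
    truth = outdir / "fiber_phantom_truth.json"
    truth.write_text(
        json.dumps(
            {
                "gap_rate_per_um": phantom.gap_rate_per_um,
                "n_fibers": len(phantom.fibers),
                "sigma_nm": phantom.fibers[0].sigma_nm if phantom.fibers else None,
                "seed": seed,
            },
            indent=2,
        )
    )
    return [out, truth]


def _stage_pores(params: dict, seed: int, outdir: Path, ctx: dict) -> list[Path]:
    image = ctx.get("image")
    if image is None:
        from .io import read_image

        image = read_image(params["input"], params.get("pixel_size_um"))
    known = {f.name for f in pores.PoreConfig.__dataclass_fields__.values()}
    cfg = pores.PoreConfig(**{k: v for k, v in params.items() if k in known})
    result = pores.pore_size_pipeline(image, cfg)
    out = outdir / "pore_size.json"
    out.write_text(
        json.dumps(
            {
                "pore_size_um": result.pore_size_um,
                "rate_per_um": result.rate_per_um,
                "n_gaps": result.n_gaps,
                "ks_statistic": result.ks_statistic,
            },
            indent=2,
        )
    )
    return [out]


def _stage_fiber_width(params: dict, seed: int, outdir: Path, ctx: dict) -> list[Path]:
    image = ctx.get("image")
    if image is None:
        from .io import read_image

        image = read_image(params["input"], params.get("pixel_size_um"))
    rois = fibers.auto_transects(image, n=params.get("n_rois", 20), seed=seed)
    report = fibers.fiber_width_report(image, rois)
    out = outdir / "fiber_width.json"
    out.write_text(
        json.dumps(
            {k: report[k] for k in ("mean_fwhm", "sd_fwhm", "n_accepted", "n_rejected")}, indent=2
        )
    )
    return [out]


_STAGES = {
    "simulate_fibers": _stage_simulate_fibers,
    "pores": _stage_pores,
    "fiber_width": _stage_fiber_width,
}

# parameter keys accepted per stage, for schema validation
_STAGE_PARAMS = {
    "simulate_fibers": {
        "field_size_um", "pixel_size_um", "gap_rate_per_um", "sigma_nm", "orientation",
        "modality", "noise",
    },
    "pores": {f.name for f in pores.PoreConfig.__dataclass_fields__.values()} | {"input", "pixel_size_um"},
    "fiber_width": {"input", "pixel_size_um", "n_rois"},
}


def validate_config(config: PipelineConfig) -> None:
    """Raise on unknown stages or parameter keys, naming the offenders."""
    problems = []
    for i, stage in enumerate(config.stages):
        name = stage.get("stage")
        if name not in _STAGES:
            problems.append(f"stages[{i}].stage = {name!r} is not a known stage")
            continue
        bad = set(stage.get("params", {})) - _STAGE_PARAMS[name]
        if bad:
            problems.append(f"stages[{i}] ({name}) has unknown parameter(s): {sorted(bad)}")
    if problems:
        raise ValueError("invalid pipeline config: " + "; ".join(problems))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute stages in order and return the output manifest.

    The manifest records per stage: parameters, the derived child seed, and
    SHA-256 hashes of every written file. A failing stage is recorded in
    the manifest, which is still written, before the error propagates.
    """
    validate_config(config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "outputs": {}}
    ctx: dict = {}
    failure = None
    for stage in config.stages:
        name = stage["stage"]
        params = stage.get("params", {})
        seed = child_seed(config.seed, name)
        entry = {"stage": name, "params": params, "seed": seed, "outputs": []}
        try:
            paths = _STAGES[name](params, seed, outdir, ctx)
        except Exception as e:  # record the failure, then re-raise
            entry["error"] = f"{type(e).__name__}: {e}"
            manifest["stages"].append(entry)
            failure = e
            break
        for p in paths:
            digest = _sha256(p)
            entry["outputs"].append(p.name)
            manifest["outputs"][p.name] = digest
        manifest["stages"].append(entry)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if failure is not None:
        raise failure
    return manifest
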
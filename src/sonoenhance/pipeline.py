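"""Configuration-driven pipeline: simulate -> enhance -> evaluate -> stats.

The pipeline is described by a YAML document with a versioned schema;
unknown keys are errors so a typo in a gain parameter cannot pass silently.
All randomness flows from seeds named in the config. Every artifact lands
under the output directory and is listed, with its SHA-256 content hash, in
``manifest.json`` — identical config and seeds give identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import clinstats, evaluate, io as img_io
from .enhance import GainScheme, Stage, StagePlan, WindowSpec, default_plan, run_stages
from .phantom import PhantomSpec, degrade, simulate_phantom

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline", "load_config"]

log = logging.getLogger("sonoenhance")

SCHEMA_VERSION = 1

_TOP_KEYS = {"schema_version", "output_dir", "log_level", "phantom", "enhance", "evaluate", "stats"}
_PHANTOM_KEYS = {f.name for f in PhantomSpec.__dataclass_fields__.values()} | {
    "suite_size",
    "suite_seed",
    "noise_sd",
}
_ENHANCE_KEYS = {"stages"}
_STAGE_KEYS = {"operator", "mode", "C", "D", "g_max", "epsilon", "n", "sigma", "label"}
_EVALUATE_KEYS = {"threshold_frac", "margin"}
_STATS_KEYS = {"registry", "n_override"}


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    output_dir: Path
    phantom: dict = field(default_factory=dict)
    plan: StagePlan = field(default_factory=default_plan)
    evaluate_params: dict = field(default_factory=dict)
    stats: dict | None = None
    log_level: str = "INFO"


def _parse_stage(entry: dict) -> Stage:
    _check_keys(entry, _STAGE_KEYS, "enhance.stages[]")
    mode = entry.get("mode", "constant")
    scheme = GainScheme(
        mode=mode,
        C=float(entry.get("C", 2.0)),
        D=float(entry.get("D", 0.05)),
        g_max=float(entry.get("g_max", 5.0)),
        epsilon=float(entry.get("epsilon", 1e-6)),
    )
    return Stage(
        operator=entry["operator"],
        scheme=scheme,
        window=WindowSpec(int(entry.get("n", 3))),
        sigma=float(entry.get("sigma", 2.0)),
        label=entry.get("label", ""),
    )


def load_config(source) -> PipelineConfig:
    """Parse and validate a YAML config (path or mapping)."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = dict(source)
    _check_keys(raw, _TOP_KEYS, "config")
    if raw.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"config schema_version must be {SCHEMA_VERSION}")
    phantom = dict(raw.get("phantom", {}))
    _check_keys(phantom, _PHANTOM_KEYS, "phantom")
    enhance_cfg = raw.get("enhance")
    if enhance_cfg is None:
        plan = default_plan()
    else:
        _check_keys(enhance_cfg, _ENHANCE_KEYS, "enhance")
        plan = StagePlan(tuple(_parse_stage(s) for s in enhance_cfg["stages"]))
    eval_cfg = dict(raw.get("evaluate", {}))
    _check_keys(eval_cfg, _EVALUATE_KEYS, "evaluate")
    stats_cfg = raw.get("stats")
    if stats_cfg is not None:
        _check_keys(stats_cfg, _STATS_KEYS, "stats")
    return PipelineConfig(
        output_dir=Path(raw.get("output_dir", "out")),
        phantom=phantom,
        plan=plan,
        evaluate_params=eval_cfg,
        stats=stats_cfg,
        log_level=raw.get("log_level", "INFO"),
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run simulate -> enhance -> evaluate (-> stats); returns the manifest.

    Any stage failure raises :class:`PipelineStageError` naming the stage.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    manifest: dict = {"schema_version": SCHEMA_VERSION, "outputs": {}, "skipped": []}

    def record(path: Path) -> None:
        manifest["outputs"][str(path.relative_to(out))] = _sha256(path)

    ph = dict(config.phantom)
    suite_size = int(ph.pop("suite_size", 8))
    suite_seed = int(ph.pop("suite_seed", 0))
    noise_sd = float(ph.pop("noise_sd", 0.03))

    try:
        template = PhantomSpec(**ph)
        specs = evaluate.balanced_suite(suite_size, base_seed=suite_seed, template=template)
        degraded = []
        for i, spec in enumerate(specs):
            pair = simulate_phantom(spec)
            img = degrade(pair.image, spec.blur_sigma, noise_sd, seed=spec.seed + 7919)
            degraded.append((spec, img))
            img_io.write_image(pair.image, out / f"phantom_{i:02d}.png")
            img_io.write_mask(pair.truth_mask, out / f"truth_{i:02d}.png")
            img_io.write_image(img, out / f"degraded_{i:02d}.png")
            record(out / f"phantom_{i:02d}.png")
            record(out / f"truth_{i:02d}.png")
            record(out / f"degraded_{i:02d}.png")
    except Exception as exc:  # noqa: BLE001 - rewrap with the stage name
        raise PipelineStageError("simulate", exc) from exc

    try:
        for i, (spec, img) in enumerate(degraded):
            final, snapshots = run_stages(img, config.plan)
            for name, snap in snapshots:
                g = snap.min(), snap.max(), snap.mean()
                log.info("phantom %02d stage %s: min=%.3f max=%.3f mean=%.3f", i, name, *g)
            img_io.write_image(final, out / f"enhanced_{i:02d}.png")
            record(out / f"enhanced_{i:02d}.png")
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("enhance", exc) from exc

    try:
        curve = evaluate.accuracy_curve(
            [s for s, _ in degraded], config.plan, noise_sd=noise_sd, **config.evaluate_params
        )
        curve.to_frame().to_csv(out / "accuracy_curve.csv", index=False)
        record(out / "accuracy_curve.csv")
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("evaluate", exc) from exc

    if config.stats is None:
        manifest["skipped"].append("stats")
    else:
        try:
            registry = clinstats.load_registry(config.stats.get("registry"))
            report = clinstats.reproduce_published_comparisons(
                registry, n_override=config.stats.get("n_override")
            )
            report.to_csv(out / "clinical_report.csv", index=False)
            record(out / "clinical_report.csv")
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("stats", exc) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
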
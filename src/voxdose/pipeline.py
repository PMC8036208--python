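"""End-to-end pipeline: phantom -> kernels -> cumulated activity -> dose -> metrics.

A :class:`RunConfig` captures every stage parameter and seed; running the
same config twice produces bit-identical artifacts, and the manifest
records content hashes of every output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import dose as dose_mod
from . import evaluation, kernels, phantoms, transport
from .io import write_volume
from .volumes import Volume

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Serializable description of one dosimetry run."""

    out_dir: str = "voxdose_run"
    phantom_shape: tuple = (48, 48, 48)
    lesion: bool = False
    engine: str = "ssv"              # ssv | msv | specific | direct-mc
    provider: str = "oracle"         # for engine=specific
    kernel_histories: int = 50_000
    direct_histories: int = 200_000
    oracle_histories: int = 20_000
    noise_scale_bq_ml: float = 0.0
    reference: bool = False          # also run direct MC and compare
    seed: int = 0

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self))

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        doc = yaml.safe_load(text)
        doc["phantom_shape"] = tuple(doc.get("phantom_shape", (48, 48, 48)))
        return cls(**doc)

    def config_hash(self) -> str:
        return hashlib.sha1(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()


def _h(arr) -> str:
    return hashlib.sha1(np.ascontiguousarray(arr).tobytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the artifact manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": asdict(config),
                "config_hash": config.config_hash(),
                "stages": {}, "outputs": {}, "hashes": {}}

    def stage(name):
        logger.info("pipeline stage: %s", name)
        manifest["stages"][name] = time.strftime("%Y-%m-%dT%H:%M:%S")

    try:
        stage("phantom")
        lesion = None
        if config.lesion:
            c = tuple(1.5 * n for n in config.phantom_shape)
            lesion = phantoms.LesionSpec(center_mm=(c[0] * 0.8, c[1] * 0.8,
                                                    c[2]), radius_mm=9.0)
        spec = phantoms.PhantomSpec.default_torso(config.phantom_shape,
                                                  lesion=lesion)
        density, materials = phantoms.generate_phantom(spec, seed=config.seed)
        write_volume(density, out / "density.nii.gz")
        write_volume(Volume(materials.data.astype(float),
                            materials.spacing_mm),
                     out / "materials.nii.gz")

        stage("activity")
        series = phantoms.generate_activity_series(
            materials, seed=config.seed + 1,
            noise_scale_bq_ml=config.noise_scale_bq_ml)
        cum = dose_mod.cumulate_activity(series)
        write_volume(cum, out / "cumulated.nii.gz")

        stage("kernels")
        engine = config.engine
        if engine == "ssv":
            kern = kernels.build_ssv_kernel(config.kernel_histories,
                                            config.seed + 2)
            kernels.save_kernel(kern, out / "ssv_kernel.h5")
            stage("dose")
            dmap = dose_mod.dose_ssv(cum, kern, density)
        elif engine == "msv":
            lib = kernels.build_msv_library(
                n_histories=config.kernel_histories, seed=config.seed + 2)
            lib.save(out / "msv_library.h5")
            stage("dose")
            dmap = dose_mod.dose_msv(cum, lib, materials, density)
        elif engine == "specific":
            provider = kernels.OracleProvider(
                n_histories=config.oracle_histories, seed=config.seed + 2)
            stage("dose")
            dmap = dose_mod.dose_specific(cum, provider, density, materials)
        elif engine == "direct-mc":
            stage("dose")
            dmap = transport.simulate_direct_dose(
                density, cum, config.direct_histories, config.seed + 2,
                materials=materials)
        else:
            raise ValueError(f"unknown engine {config.engine!r}")
        write_volume(dmap, out / "dose.nii.gz")

        report = {"engine": engine,
                  "total_decays": float(cum.data.sum()),
                  "mean_body_dose_gy": float(
                      dmap.data[materials.data > 0].mean())}
        if config.reference and engine != "direct-mc":
            stage("reference")
            ref = transport.simulate_direct_dose(
                density, cum, config.direct_histories, config.seed + 3,
                materials=materials)
            write_volume(ref, out / "dose_reference.nii.gz")
            body = materials.data > 0
            m = evaluation.voxel_metrics(dmap, ref, body)
            ba = evaluation.bland_altman(dmap, ref, body)
            report["vs_direct_mc"] = {
                "mae_gy": m.mae, "mrae_pct": m.mrae_pct, "rmse_gy": m.rmse,
                "bland_altman_bias_pct": ba.bias_pct,
                "bland_altman_loa_pct": [ba.loa_lower_pct, ba.loa_upper_pct],
                "r2": evaluation.joint_histogram_r2(dmap, ref, body),
            }
            manifest["hashes"]["dose_reference"] = _h(ref.data)

        stage("report")
        (out / "report.json").write_text(json.dumps(report, indent=1))
        manifest["outputs"] = {p.name: str(p) for p in sorted(out.iterdir())}
        manifest["hashes"].update({
            "density": _h(density.data), "materials": _h(materials.data),
            "cumulated": _h(cum.data), "dose": _h(dmap.data)})
        manifest["report"] = report
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return manifest
    except Exception as exc:
        failed = [s for s in manifest["stages"]][-1] if manifest["stages"] \
            else "init"
        raise RuntimeError(f"pipeline failed in stage {failed!r}: {exc}") \
            from exc
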
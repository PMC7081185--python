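"""End-to-end orchestration: series in, maps + lesion statistics out.

Stage order mirrors the analysis workflow: ADC fitting, pre/post rate
fitting and ΔR2/ΔR2* construction, VSI/Q/MVD mapping, ROI classification
and statistics.  Every stage logs its parameters; outputs are hashed into
a manifest so each file is traceable to inputs + config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from .config import PipelineConfig
from .lesions import (
    classify_tissue,
    proportion_above,
    roi_metric_summary,
    students_t,
)
from .phantom import PhantomSpec, make_brain_phantom, render_series
from .physics import characteristic_frequency
from .relaxometry import (
    EchoSeries,
    compute_adc_map,
    compute_delta_map,
    compute_mvd,
    compute_q,
    compute_vsi,
)
from . import io as vio

log = logging.getLogger("vsimri")

__all__ = ["run_pipeline", "estimate_noise_sigma", "phantom_inputs"]


def estimate_noise_sigma(series: EchoSeries) -> float:
    """Rician noise sigma from the background: mean magnitude = sigma*sqrt(pi/2)."""
    from .relaxometry import _series_mask

    bg = ~_series_mask(series)
    if not bg.any():
        return 0.0
    return float(series.volumes[:, bg].mean() / np.sqrt(np.pi / 2.0))


def phantom_inputs(config: PipelineConfig, snr: float | None = None) -> tuple[dict, dict]:
    """Generate the five acquisition series and ROI masks from the default
    brain phantom (seeded by the config)."""
    spec = PhantomSpec(seed=config.seed, **({"snr": snr} if snr is not None else {}))
    truth = make_brain_phantom(spec)
    series = {
        name: render_series(truth, name) for name in
        ("dwi", "msme_pre", "msme_post", "mege_pre", "mege_post")
    }
    return series, truth.rois


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the full mapping + lesion-statistics pipeline.

    Inputs come from ``config.paths`` (keys dwi, msme_pre, msme_post,
    mege_pre, mege_post and a ``rois`` mapping of name -> NIfTI path); with
    no paths configured, the synthetic brain phantom supplies them.
    Returns the summary bundle (also written to ``out_dir``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = dict(config.paths)

    if paths:
        required = ["dwi", "msme_pre", "msme_post", "mege_pre", "mege_post"]
        missing = [k for k in required if k not in paths]
        if missing:
            raise RuntimeError(
                f"stage delta-map: missing input series {missing} in config.paths"
            )
        series = {k: vio.read_series(paths[k]) for k in required}
        rois = {
            name: vio.read_volume(p)[0] > 0.5
            for name, p in dict(paths.get("rois", {})).items()
        }
    else:
        log.info("no input paths configured; generating the synthetic phantom")
        series, rois = phantom_inputs(config)

    vs = series["dwi"].voxel_size
    physics = config.physics
    dwc = characteristic_frequency(physics)

    log.info("stage adc-map: %d b-values", len(series["dwi"].axis_values))
    adc = compute_adc_map(series["dwi"])

    sigma = max(estimate_noise_sigma(series["mege_post"]), estimate_noise_sigma(series["msme_post"]))
    floor = 3.0 * sigma if sigma > 0 else None
    log.info("stage delta-map: fitted_train, scale %.3f, noise floor %s", config.scale_factor, floor)
    try:
        delta_r2 = compute_delta_map(
            series["msme_pre"], series["msme_post"], "fitted_train",
            scale_factor=config.scale_factor, noise_floor=floor,
        )
        delta_r2_star = compute_delta_map(
            series["mege_pre"], series["mege_post"], "fitted_train",
            scale_factor=1.0, noise_floor=floor,
        )
    except Exception as exc:
        raise RuntimeError(f"stage delta-map failed: {exc}") from exc

    log.info("stage vsi-maps: D=%g um^2/s, delta_omega_c=%g rad/s", config.D, dwc)
    vsi = compute_vsi(delta_r2, delta_r2_star, config.D, dwc)
    q = compute_q(delta_r2, delta_r2_star)
    mvd = compute_mvd(q, config.D)

    maps = {
        "adc": adc, "delta_r2": delta_r2, "delta_r2_star": delta_r2_star,
        "vsi": vsi, "q": q, "mvd": mvd,
    }
    for name, pmap in maps.items():
        vio.write_parameter_map(pmap, out / f"{name}.nii.gz", voxel_size=vs)

    summary: dict = {"rois": {}, "tests": {}, "config": config.to_dict()}
    if rois:
        log.info("stage lesion-stats: %d ROIs, ADC threshold %g", len(rois), config.adc_threshold)
        per_roi = {}
        for name, mask in rois.items():
            adc_sum = roi_metric_summary(adc, mask, name, "adc")
            entry = {
                "n_voxels": adc_sum.n_voxels,
                "mean_adc": adc_sum.mean,
                "tissue_class": classify_tissue(adc_sum.mean, config.adc_threshold),
            }
            for metric, pmap in (("vsi", vsi), ("q", q), ("mvd", mvd)):
                s = roi_metric_summary(pmap, mask, name, metric)
                entry[f"{metric}_mean"] = s.mean
                entry[f"{metric}_median"] = s.median
            entry["vsi_prop_gt_cutoff"] = proportion_above(
                roi_metric_summary(vsi, mask, name, "vsi").values, config.vsi_cutoff
            )
            entry["mvd_prop_gt_cutoff"] = proportion_above(
                roi_metric_summary(mvd, mask, name, "mvd").values, config.mvd_cutoff
            )
            per_roi[name] = entry
        summary["rois"] = per_roi

        if "lesion" in rois and "contra_subcortex" in rois:
            for metric, pmap in (("vsi", vsi), ("q", q), ("mvd", mvd)):
                a = roi_metric_summary(pmap, rois["lesion"], "lesion", metric).values
                b = roi_metric_summary(
                    pmap, rois["contra_subcortex"], "contra_subcortex", metric
                ).values
                t = students_t(a, b, paired=False)
                summary["tests"][metric] = {
                    "t": t.statistic, "p": t.p_value,
                    "n": list(t.n_per_group), "paired": t.paired,
                }

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    manifest = {
        "config": config.to_dict(),
        "outputs": {
            p.name: _sha256(p) for p in sorted(out.glob("*.nii.gz"))
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return summary
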
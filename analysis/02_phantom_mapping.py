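#!/usr/bin/env python
"""Voxel-wise mapping pipeline on the synthetic stroke phantom.

Generates the two-hemisphere brain phantom (subcortical lesion: ADC 500
vs 750 um²/s, VSI 12 vs 4 um, Q 0.6 vs 1.07 s^-1/3) at SNR 40, renders
the five acquisition series (DWI; pre/post spin-echo and gradient-echo
echo trains), and runs the full pipeline: ADC map, echo-train ΔR2
(x4.375) and ΔR2* maps, VSI/Q/MVD maps, ROI classification and t-tests.

Finding it verifies and prints: the lesion classifies as ischemic edema
(mean ADC < 650 um²/s) and shows higher VSI, lower Q and lower MVD than
the contralateral subcortex, each with p < 0.001.

Writes NIfTI maps plus summary.json under results/phantom/.
"""

import argparse
import json
from pathlib import Path

from vsimri import PipelineConfig, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/phantom"))
    args = ap.parse_args()

    summary = run_pipeline(PipelineConfig(seed=args.seed), args.out)
    for name, e in summary["rois"].items():
        print(
            f"{name:16s} ADC {e['mean_adc']:6.0f} um^2/s ({e['tissue_class']:6s})  "
            f"VSI {e['vsi_mean']:5.2f} um (> 10 um: {e['vsi_prop_gt_cutoff']:.1%})  "
            f"Q {e['q_mean']:5.3f}  MVD {e['mvd_mean']:5.0f} mm^-2 "
            f"(> 200: {e['mvd_prop_gt_cutoff']:.1%})"
        )
    for metric, t in summary["tests"].items():
        print(f"lesion vs contralateral subcortex, {metric}: t = {t['t']:.1f}, p = {t['p']:.2e}")
    print(f"maps + summary.json -> {args.out}")


if __name__ == "__main__":
    main()
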
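#!/usr/bin/env python
"""Simulate the reference phantom study.

Builds the default post-resection phantom (white-matter background,
CSF cavity, T2w-hyperintense zone at the stable-group diffusivities,
focal lesion at the transformed-group diffusivities), acquires a
noisy 13-measurement DWI (1 b0 + 12 directions at b = 1000 s/mm^2,
SNR 20), and writes the study to scratch/study/ (volumes) with a
region summary under results/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from gliodti import (
    build_phantom,
    compute_maps,
    default_phantom_spec,
    default_scheme,
    save_dwi,
    simulate_dwi,
)
from gliodti.io import save_mask

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--snr", type=float, default=20.0)
    ap.add_argument("--out", type=Path, default=ROOT / "scratch" / "study")
    ap.add_argument("--results", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    spec = default_phantom_spec(style="prolate")
    phantom = build_phantom(spec)
    scheme = default_scheme()
    dwi = simulate_dwi(phantom.field, scheme, phantom.s0, snr=args.snr, seed=args.seed)

    save_dwi(dwi, args.out)
    save_mask(phantom.tumor_mask, args.out / "tumor_mask.nii.gz", spec.voxel_size)
    save_mask(phantom.t2w_mask, args.out / "t2w_mask.nii.gz", spec.voxel_size)

    truth = compute_maps(phantom.field)
    rows = []
    for name, mask in phantom.masks.items():
        rows.append(
            {
                "region": name,
                "n_voxels": int(mask.sum()),
                "true_ad_1e3": float(truth["ad"][mask].mean() * 1e3),
                "true_md_1e3": float(truth["md"][mask].mean() * 1e3),
                "true_rd_1e3": float(truth["rd"][mask].mean() * 1e3),
                "s0": float(phantom.s0[mask].mean()),
            }
        )
    table = pd.DataFrame(rows)
    args.results.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.results / "phantom_regions.csv", index=False, float_format="%.4f")

    print(f"study written to {args.out} (seed {args.seed}, SNR {args.snr})")
    print(table.to_string(index=False))
    lesion = table.set_index("region").loc["lesion"]
    t2 = table.set_index("region").loc["t2_hyperintense"]
    print(
        f"\nFinding: the lesion sits at AD {lesion.true_ad_1e3:.2f} vs "
        f"{t2.true_ad_1e3:.2f} x 1e-3 mm^2/s in the surrounding zone — the "
        "diffusion restriction the downstream biomarkers must detect."
    )


if __name__ == "__main__":
    main()
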
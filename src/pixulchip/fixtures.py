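"""Seeded fixture suite: synthetic gel, qPCR plate and peak files with truth.

Everything is generated from one integer seed and written with deterministic
encoders, so two runs with the same seed are byte-identical.  The manifest
records the constructed expected values for use by test harnesses.
"""

from __future__ import annotations

import json
import os

import numpy as np

import pixulchip
from pixulchip._util import atomic_write_text
from pixulchip.gel.image import save_gel_image
from pixulchip.gel.ladder import LadderSpec
from pixulchip.peaks import Peak, write_broadpeak
from pixulchip.sim.distributions import FragmentDistribution
from pixulchip.sim.simulate import GelSimConfig, simulate_gel

DEFAULT_LADDER = LadderSpec(
    sizes_bp=(1500, 1000, 700, 500, 400, 300, 200, 100), name="100bp+"
)

QPCR_CURVE_SLOPE = -3.4
QPCR_CURVE_INTERCEPT = 24.0
QPCR_TRUE_ENRICHMENTS = (0.001, 0.01, 0.05, 0.2)
QPCR_CT_SIGMA = 0.05
QPCR_REPLICATES = 4


def plate_distributions(rng: np.random.Generator, n: int = 12) -> list[FragmentDistribution]:
    """Twelve shear-like log-normal smears with mildly varying parameters."""
    medians = rng.uniform(250.0, 400.0, size=n)
    sigmas = rng.uniform(0.12, 0.18, size=n)
    return [FragmentDistribution.single(m, s) for m, s in zip(medians, sigmas)]


def make_fixtures(out_dir: str, seed: int = 0) -> dict:
    """Write the fixture suite and return (and save) its manifest."""
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest: dict = {"seed": seed, "version": pixulchip.__version__}

    # --- 13-lane synthetic gel + analytic truth
    cfg = GelSimConfig(seed=int(rng.integers(0, 2**31)))
    dists = plate_distributions(rng, cfg.n_lanes - 1)
    gel, truth = simulate_gel(dists, DEFAULT_LADDER, cfg)
    gel_path = os.path.join(out_dir, "gel.png")
    save_gel_image(gel, gel_path, bit_depth=16)
    atomic_write_text(os.path.join(out_dir, "gel_truth.json"), truth.to_json() + "\n")
    sim_config = {
        "a": cfg.a,
        "b": cfg.b,
        "psf_sigma": cfg.psf_sigma,
        "background": list(cfg.background),
        "noise_sigma": cfg.noise_sigma,
        "image_shape": list(cfg.image_shape),
        "lane_centers": list(cfg.lane_centers),
        "lane_half_width": cfg.lane_half_width,
        "ladder_lane_index": cfg.ladder_lane_index,
        "exposure": cfg.exposure,
        "seed": cfg.seed,
        "range_lo": cfg.range_lo,
        "range_hi": cfg.range_hi,
        "convention": cfg.convention,
        "ladder": {"name": DEFAULT_LADDER.name, "sizes_bp": list(DEFAULT_LADDER.sizes_bp)},
        "lanes": [{"components": [list(c) for c in d.components]} for d in dists],
    }
    atomic_write_text(
        os.path.join(out_dir, "sim_config.json"),
        json.dumps(sim_config, indent=2, sort_keys=True) + "\n",
    )
    manifest["gel"] = {
        "image": "gel.png",
        "truth": "gel_truth.json",
        "sim_config": "sim_config.json",
        "n_lanes": cfg.n_lanes,
        "ladder_lane": cfg.ladder_lane_index,
        "ladder_sizes_bp": list(DEFAULT_LADDER.sizes_bp),
        "expected_mean_bp": truth.lane_mean_bp,
        "expected_frac_in_range": truth.lane_frac_in_range,
        "mean_bp_rtol": 0.05,
        "frac_atol": 0.03,
    }

    # --- qPCR standards + plate with known enrichments
    m, b = QPCR_CURVE_SLOPE, QPCR_CURVE_INTERCEPT
    std_lines = ["primer_pair,concentration,ct"]
    for conc in (1.0, 0.1, 0.01, 0.001, 0.0001):
        ct = m * np.log10(conc) + b + rng.normal(0, 0.02)
        std_lines.append(f"locusA,{conc},{ct:.6f}")
    atomic_write_text(os.path.join(out_dir, "standards.csv"), "\n".join(std_lines) + "\n")

    q_input = 0.05  # genomic-DNA units in the input well
    plate_lines = ["sample_id,target,antibody,is_input,input_dilution," + ",".join(
        f"ct_{i + 1}" for i in range(QPCR_REPLICATES)
    )]
    input_cts = m * np.log10(q_input) + b + rng.normal(0, QPCR_CT_SIGMA, QPCR_REPLICATES)
    plate_lines.append(
        "input,locusA,,true,1," + ",".join(f"{c:.6f}" for c in input_cts)
    )
    for i, enrich in enumerate(QPCR_TRUE_ENRICHMENTS, start=1):
        cts = m * np.log10(enrich * q_input) + b + rng.normal(0, QPCR_CT_SIGMA, QPCR_REPLICATES)
        plate_lines.append(
            f"s{i},locusA,H3K4m3,false,1," + ",".join(f"{c:.6f}" for c in cts)
        )
    atomic_write_text(os.path.join(out_dir, "plate.csv"), "\n".join(plate_lines) + "\n")
    manifest["qpcr"] = {
        "standards": "standards.csv",
        "plate": "plate.csv",
        "input_sample": "input",
        "expected_fraction_of_input": {
            f"s{i}": e for i, e in enumerate(QPCR_TRUE_ENRICHMENTS, start=1)
        },
        "rtol": 0.05,
    }

    # --- paired broadPeak sets with a constructed overlap percentage
    n_a = 200
    n_shared = 150  # 75.0% of A overlaps B by construction
    peaks_a = [
        Peak(
            chrom="chr1",
            start=1000 * i + 100,
            end=1000 * i + 300,
            name=f"a_{i}",
            fold_enrichment=float(rng.uniform(1, 20)),
            neg_log10_q=float(rng.uniform(0, 30)),
            neg_log10_p=float(rng.uniform(0, 30)),
            mark="H3K4m3",
        )
        for i in range(n_a)
    ]
    peaks_b = [
        Peak(
            chrom="chr1",
            start=p.start + 50,
            end=p.end + 50,
            name=f"b_{i}",
            fold_enrichment=p.fold_enrichment,
            neg_log10_q=p.neg_log10_q,
            neg_log10_p=p.neg_log10_p,
            mark="H3K4m3",
        )
        for i, p in enumerate(peaks_a[:n_shared])
    ] + [
        Peak(
            chrom="chr2",
            start=1000 * i + 100,
            end=1000 * i + 300,
            name=f"b_extra_{i}",
            fold_enrichment=float(rng.uniform(1, 20)),
            neg_log10_q=float(rng.uniform(0, 30)),
            neg_log10_p=float(rng.uniform(0, 30)),
            mark="H3K4m3",
        )
        for i in range(40)
    ]
    write_broadpeak(peaks_a, os.path.join(out_dir, "a.broadPeak"))
    write_broadpeak(peaks_b, os.path.join(out_dir, "b.broadPeak"))
    manifest["peaks"] = {
        "a": "a.broadPeak",
        "b": "b.broadPeak",
        "expected_count_a": n_a,
        "expected_overlapping": n_shared,
        "expected_percent": 100.0 * n_shared / n_a,
    }

    atomic_write_text(
        os.path.join(out_dir, "manifest.json"),
        json.dumps(manifest, indent=2, sort_keys=True) + "\n",
    )
    return manifest
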
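"""End-to-end gel analysis: image -> lanes -> calibration -> lane statistics."""

from __future__ import annotations

from dataclasses import dataclass

from pixulchip.gel.calibration import MigrationCalibration, fit_calibration
from pixulchip.gel.image import GelImage
from pixulchip.gel.ladder import LadderSpec, detect_ladder_bands
from pixulchip.gel.lanes import LaneGeometry, detect_lanes, extract_profile
from pixulchip.gel.smear import (
    LaneQuant,
    SmearCurve,
    fit_smear_curve,
    quantify_lane,
    rescale_to_bp,
)
from pixulchip.gel.waterfall import WaterfallData, build_waterfall


@dataclass
class GelAnalysis:
    """Everything produced by one gel run, in lane order."""

    geometry: LaneGeometry
    calibration: MigrationCalibration
    waterfall: WaterfallData

    @property
    def curves(self) -> list[SmearCurve]:
        return self.waterfall.curves

    @property
    def quants(self) -> list[LaneQuant]:
        return self.waterfall.quants


def analyze_gel(
    img: GelImage,
    n_lanes: int,
    ladder_lane: int,
    ladder: LadderSpec,
    range_lo: float = 200.0,
    range_hi: float = 600.0,
    grid_step: float = 1.0,
    model: str = "semilog_linear",
    jacobian: bool = False,
    waterfall_path: str | None = None,
) -> GelAnalysis:
    """Quantify every sample lane of a gel image.

    ``n_lanes`` counts all lanes including the ladder; sample lanes are the
    remaining ``n_lanes - 1``, labelled ``lane1..laneN`` left to right.
    """
    geom = detect_lanes(img, n_lanes=n_lanes, ladder_lane=ladder_lane)
    ladder_profile = extract_profile(img, geom, geom.ladder_lane_index)
    bands = detect_ladder_bands(ladder_profile, ladder)
    cal = fit_calibration(bands, model=model)

    curves: list[SmearCurve] = []
    quants: list[LaneQuant] = []
    sample_no = 0
    for lane_index in range(1, geom.n_lanes + 1):
        if lane_index == geom.ladder_lane_index:
            continue
        sample_no += 1
        profile = extract_profile(img, geom, lane_index)
        curve = rescale_to_bp(profile, cal, grid_step=grid_step, jacobian=jacobian)
        curve.lane_label = f"lane{sample_no}"
        curve = fit_smear_curve(curve)
        curves.append(curve)
        quants.append(quantify_lane(curve, range_lo=range_lo, range_hi=range_hi))
    waterfall = build_waterfall(curves, quants, out_path=waterfall_path)
    return GelAnalysis(geometry=geom, calibration=cal, waterfall=waterfall)
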
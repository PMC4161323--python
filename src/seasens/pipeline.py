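"""Convenience glue running the survey → detection → density-surface chain.

These helpers wire the stage functions together for the common single
species / single platform case; the CLI and the test-suite share them so the
pipeline is exercised the same way everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import detection, dsm
from .synthetic import ScenarioConfig, TruthSurface, simulate_survey

__all__ = ["corrected_segment_abundance", "HotspotRecovery", "run_hotspot_recovery"]


def corrected_segment_abundance(segments: pd.DataFrame, observations: pd.DataFrame,
                                model: detection.DetectionModel,
                                flying_strip: bool = True) -> pd.DataFrame:
    """Attach a detection-corrected abundance column ``n_hat`` per segment.

    Sitting counts are divided by the model's p̄; flying strip counts (no
    recorded distance) enter uncorrected with detection probability 1.
    """
    seg = segments.copy()
    sit = observations[observations["behaviour"] == "sitting"]
    counts = (sit.groupby("segment_id")["count"].sum()
              .reindex(seg["segment_id"], fill_value=0).to_numpy(dtype=float))
    nhat = detection.correct_segment_counts(counts, model)
    if flying_strip:
        fly = observations[observations["behaviour"] == "flying"]
        nhat = nhat + (fly.groupby("segment_id")["count"].sum()
                       .reindex(seg["segment_id"], fill_value=0)
                       .to_numpy(dtype=float))
    seg["n_hat"] = nhat
    return seg


@dataclass
class HotspotRecovery:
    """End-to-end recovery metrics on a synthetic scenario."""
    detection_model: detection.DetectionModel
    density_model: dsm.DensityModel
    surface: dsm.DensitySurface
    cell_cvs: np.ndarray
    covered: np.ndarray               # cells inside the survey extent
    usable: np.ndarray                # sea cells with a prediction
    predicted_total: float            # over covered usable cells
    true_total: float                 # truth over the same cells
    total_se: float                   # posterior + detection, combined
    n_segments: int

    @property
    def z(self) -> float:
        return (self.predicted_total - self.true_total) / self.total_se


def run_hotspot_recovery(truth: TruthSurface, scenario: ScenarioConfig,
                         grid: pd.DataFrame, coastline=None,
                         n_draws: int = 400, seed: int = 0) -> HotspotRecovery:
    """Survey the truth, fit detection + DSM, and score abundance recovery.

    The combined SE of the total couples the GAM posterior spread of the
    summed abundance with the detection-probability CV by the delta method.
    """
    segs, obs = simulate_survey(truth, scenario, coastline=coastline)
    sit = obs[obs["behaviour"] == "sitting"]
    det_model = detection.fit_best(
        distances=sit["perp_distance_m"].dropna().to_numpy(),
        w=scenario.truncation_m)
    if isinstance(det_model, detection.InsufficientSample):
        raise RuntimeError("scenario produced too few observations for "
                           "detection fitting")
    seg = corrected_segment_abundance(segs, obs, det_model)
    cd_max = float(np.nanmax(np.where(np.isfinite(grid["cdist_km"]),
                                      grid["cdist_km"], np.nan)))
    xmin = grid["x"].min() - 1500
    xmax = grid["x"].max() + 1500
    ymin = grid["y"].min() - 1500
    ymax = grid["y"].max() + 1500
    model = dsm.fit_dsm(seg, domain={"x": (xmin, xmax), "y": (ymin, ymax),
                                     "cdist_km": (0.0, cd_max)})
    surf = dsm.predict_grid(model, grid)
    cvs = dsm.cell_cv(model, grid, detection_cv=det_model.cv_p,
                      n_draws=n_draws, seed=seed)
    surf.table["cv"] = cvs

    if scenario.survey_extent is not None:
        sx0, sy0, sx1, sy1 = scenario.survey_extent
        covered = ((grid["x"].to_numpy() >= sx0) & (grid["x"].to_numpy() <= sx1)
                   & (grid["y"].to_numpy() >= sy0) & (grid["y"].to_numpy() <= sy1))
    else:
        covered = np.ones(len(grid), dtype=bool)
    usable = (grid["is_sea"].to_numpy(dtype=bool)
              & np.isfinite(surf.table["density"].to_numpy()))
    sel = covered & usable
    pred_total = float(np.nansum(surf.table["abundance"].to_numpy()[sel]))
    true_total = float(np.sum(truth.density[sel]
                              * grid["area_km2"].to_numpy()[sel]))

    rng = np.random.default_rng(seed + 1)
    Vb = model.Vb
    try:
        L = np.linalg.cholesky(Vb)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(Vb + 1e-10 * np.eye(len(Vb)))
    draws = model.beta[None, :] + rng.standard_normal(
        (n_draws, len(model.beta))) @ L.T
    X = model.design(grid.loc[sel])
    area = grid["area_km2"].to_numpy()[sel]
    totals = (np.exp(np.clip(X @ draws.T, -30, 30)) * area[:, None]).sum(axis=0)
    se = float(np.sqrt(totals.std(ddof=1) ** 2
                       + (det_model.cv_p * pred_total) ** 2))
    return HotspotRecovery(
        detection_model=det_model, density_model=model, surface=surf,
        cell_cvs=cvs, covered=covered, usable=usable,
        predicted_total=pred_total, true_total=true_total, total_se=se,
        n_segments=len(seg))
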
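"""Sensitivity mapping: combine density surfaces with species scores.

Per species and season, sitting and flying densities are summed, then the
boat and aerial surfaces fused cell by cell under the CV gates: candidates
with CV > 0.5 are discarded; among the survivors the maximum density wins if
its CV is below 0.3, otherwise the candidate with the lowest CV.  Each
species' fused density d becomes a layer  score × ln(d + 1); layers are
summed across species.  Cells where no species had usable data carry the
value 0 with ``data_ok = False`` — an exact zero in the output marks poor
coverage or poor model fits, not measured absence.

Per-risk maps weight by the raw collision/displacement index; the overall
map weights by the categorical risk value max(collision_cat,
displacement_cat) per species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dsm import DensitySurface
from .ssi import SpeciesSensitivity

__all__ = [
    "SensitivityLayer",
    "CV_KEEP_MAX",
    "CV_EXCLUDE",
    "combine_behaviours",
    "fuse_platforms",
    "species_layer",
    "aggregate",
    "overall_map",
    "write_layer_csv",
]

#: below this CV a surface is trusted enough to take the larger density
CV_KEEP_MAX = 0.3
#: above this CV a predicted density is excluded altogether
CV_EXCLUDE = 0.5


@dataclass
class SensitivityLayer:
    season: str
    risk_type: str                       # "collision" | "displacement" | "overall"
    table: pd.DataFrame = field(repr=False)   # cell_id, value, data_ok
    meta: dict = field(default_factory=dict)

    def values(self) -> pd.Series:
        return self.table.set_index("cell_id")["value"]


def _check_same_grid(a: pd.DataFrame, b: pd.DataFrame) -> None:
    if len(a) != len(b) or not np.array_equal(a["cell_id"].to_numpy(),
                                              b["cell_id"].to_numpy()):
        raise ValueError("surfaces are not on the same grid")


def combine_behaviours(sitting: DensitySurface | None,
                       flying: DensitySurface | None) -> DensitySurface:
    """Sum sitting and flying densities; combine CVs assuming independence.

    CV of the sum = sqrt(σ_s² + σ_f²) / (d_s + d_f).  A missing component
    contributes zero; a cell missing in both stays missing.
    """
    if sitting is None and flying is None:
        raise ValueError("both behaviour surfaces are missing")
    if sitting is None or flying is None:
        present = sitting if sitting is not None else flying
        t = present.table.copy()
        return DensitySurface(species=present.species, behaviour="combined",
                              season=present.season, platform=present.platform,
                              table=t)
    _check_same_grid(sitting.table, flying.table)
    ds = sitting.table["density"].to_numpy(dtype=float)
    df_ = flying.table["density"].to_numpy(dtype=float)
    cs = sitting.table["cv"].to_numpy(dtype=float)
    cf = flying.table["cv"].to_numpy(dtype=float)
    sig_s = np.where(np.isfinite(ds), np.nan_to_num(cs * ds), 0.0)
    sig_f = np.where(np.isfinite(df_), np.nan_to_num(cf * df_), 0.0)
    d = np.where(np.isfinite(ds), ds, 0.0) + np.where(np.isfinite(df_), df_, 0.0)
    both_missing = ~np.isfinite(ds) & ~np.isfinite(df_)
    d = np.where(both_missing, np.nan, d)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(d > 0, np.sqrt(sig_s ** 2 + sig_f ** 2) / d, 0.0)
    cv = np.where(both_missing, np.nan, cv)
    # a zero-density cell with one finite-CV component keeps that CV
    one_zero = (d == 0) & ~both_missing
    cv = np.where(one_zero, np.fmax(np.nan_to_num(cs), np.nan_to_num(cf)), cv)
    t = sitting.table[["cell_id"]].copy()
    t["density"] = d
    t["cv"] = cv
    t["abundance"] = np.nan
    t["extrapolated"] = (sitting.table["extrapolated"].to_numpy(dtype=bool)
                         & flying.table["extrapolated"].to_numpy(dtype=bool))
    return DensitySurface(species=sitting.species, behaviour="combined",
                          season=sitting.season, platform=sitting.platform,
                          table=t)


def fuse_platforms(boat: DensitySurface | None,
                   aerial: DensitySurface | None,
                   cv_keep_max: float = CV_KEEP_MAX,
                   cv_exclude: float = CV_EXCLUDE) -> DensitySurface:
    """Fuse boat and aerial surfaces per cell under the CV gates.

    Candidates with CV > ``cv_exclude`` are dropped; if the maximum-density
    survivor has CV < ``cv_keep_max`` it is taken, otherwise the survivor
    with the lowest CV.  No survivors → missing.
    """
    if not 0 < cv_keep_max < cv_exclude:
        raise ValueError("need 0 < cv_keep_max < cv_exclude")
    if boat is None and aerial is None:
        raise ValueError("both platform surfaces are missing")
    surfaces = [s for s in (boat, aerial) if s is not None]
    if len(surfaces) == 2:
        _check_same_grid(surfaces[0].table, surfaces[1].table)
    n = len(surfaces[0].table)
    dens = np.stack([s.table["density"].to_numpy(dtype=float) for s in surfaces])
    cvs = np.stack([s.table["cv"].to_numpy(dtype=float) for s in surfaces])
    ok = np.isfinite(dens) & np.isfinite(cvs) & (cvs <= cv_exclude)
    d_out = np.full(n, np.nan)
    cv_out = np.full(n, np.nan)
    for i in range(n):
        cand_d = dens[ok[:, i], i]
        cand_cv = cvs[ok[:, i], i]
        if cand_d.size == 0:
            continue
        imax = int(np.argmax(cand_d))
        if cand_cv[imax] < cv_keep_max:
            pick = imax
        else:
            pick = int(np.argmin(cand_cv))
        d_out[i] = cand_d[pick]
        cv_out[i] = cand_cv[pick]
    t = surfaces[0].table[["cell_id"]].copy()
    t["density"] = d_out
    t["cv"] = cv_out
    t["abundance"] = np.nan
    t["extrapolated"] = ~np.isfinite(d_out)
    s0 = surfaces[0]
    return DensitySurface(species=s0.species, behaviour=s0.behaviour,
                          season=s0.season, platform="fused", table=t)


def species_layer(density: DensitySurface, ssi_value: float) -> pd.Series:
    """Per-cell contribution ssi_value × ln(density + 1); missing stays missing."""
    if ssi_value < 0:
        raise ValueError("sensitivity score must be >= 0")
    d = density.table["density"].to_numpy(dtype=float)
    if np.any(d[np.isfinite(d)] < 0):
        raise ValueError("negative density")
    vals = ssi_value * np.log1p(d)
    return pd.Series(vals, index=density.table["cell_id"].to_numpy(),
                     name=density.species)


def aggregate(layers: dict[str, pd.Series], season: str,
              risk_type: str) -> SensitivityLayer:
    """Sum species layers per cell.

    Missing species-cells contribute 0; ``data_ok`` is True wherever at least
    one species had usable data.  Cells with no usable data at all emit
    exactly 0.
    """
    if not layers:
        raise ValueError("no species layers to aggregate")
    df = pd.DataFrame(layers)
    data_ok = df.notna().any(axis=1)
    value = df.fillna(0.0).sum(axis=1)
    value = value.where(data_ok, 0.0)
    table = pd.DataFrame({"cell_id": df.index, "value": value.to_numpy(),
                          "data_ok": data_ok.to_numpy()})
    return SensitivityLayer(season=season, risk_type=risk_type, table=table,
                            meta={"n_species": len(layers)})


def overall_map(fused: dict[str, DensitySurface],
                sensitivities: dict[str, SpeciesSensitivity],
                season: str) -> SensitivityLayer:
    """Overall layer: Σ_species max(collision_cat, displacement_cat) × ln(d+1)."""
    layers = {}
    for sp, surf in fused.items():
        sens = sensitivities[sp]
        layers[sp] = species_layer(surf, sens.overall_cat)
    return aggregate(layers, season=season, risk_type="overall")


def risk_map(fused: dict[str, DensitySurface],
             sensitivities: dict[str, SpeciesSensitivity],
             season: str, risk_type: str,
             categorical: bool = False) -> SensitivityLayer:
    """Collision or displacement layer from raw index scores (default) or
    categorical values."""
    layers = {}
    for sp, surf in fused.items():
        s = sensitivities[sp]
        if risk_type == "collision":
            v = s.collision_cat if categorical else s.collision_score
        elif risk_type == "displacement":
            v = s.displacement_cat if categorical else s.displacement_score
        else:
            raise ValueError(f"unknown risk type {risk_type!r}")
        layers[sp] = species_layer(surf, v)
    return aggregate(layers, season=season, risk_type=risk_type)


def write_layer_csv(layer: SensitivityLayer, path,
                    shared_scale: tuple[float, float] | None = None) -> None:
    """Write a layer; ``shared_scale`` records a common min/max in the header
    comment so seasonal maps can be rendered on one scale."""
    with open(path, "w") as fh:
        if shared_scale is not None:
            fh.write(f"# scale_min={shared_scale[0]:.6g} "
                     f"scale_max={shared_scale[1]:.6g}\n")
        layer.table.to_csv(fh, index=False)
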
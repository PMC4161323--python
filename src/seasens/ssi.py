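"""Species sensitivity scoring for offshore-wind collision and displacement risk.

Each species carries ten factor scores: four conservation-importance factors
(share of the biogeographic population, adult survival band, UK threat status,
Birds Directive status) and six behavioural vulnerability factors (percentage
of flight time at turbine blade height, flight manoeuvrability, percentage of
time flying, nocturnal flight activity, disturbance susceptibility, habitat
specialisation).  Conservation importance CI is the sum of the four
conservation factors.  Two indices are derived:

* collision index  = round_half_even( blade_pct * (manoeuvre + time_flying
  + nocturnal) / 3 * CI )
* displacement index = round_half_even( disturbance * habitat * CI / 10 )

Collision and displacement scales are not comparable quantitatively; only the
ranking within each scale is meaningful.  Both indices are banded into risk
classes (Very high .. Very low); displacement is never assigned "Very high".
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Literal

import pandas as pd

__all__ = [
    "SpeciesFactorScores",
    "SpeciesSensitivity",
    "RiskThresholds",
    "COLLISION_THRESHOLDS",
    "DISPLACEMENT_THRESHOLDS",
    "load_species_scores",
    "score_directive",
    "score_pct_population",
    "score_survival",
    "score_bocc",
    "conservation_importance",
    "collision_index",
    "displacement_index",
    "classify_risk",
    "score_table",
]

RiskClass = Literal["Very high", "High", "Moderate", "Low", "Very low"]

#: Ordered risk classes, highest first, with their categorical values.
RISK_CATEGORIES: dict[str, int] = {
    "Very high": 5,
    "High": 4,
    "Moderate": 3,
    "Low": 2,
    "Very low": 1,
}


@dataclass(frozen=True)
class SpeciesFactorScores:
    """The ten factor scores for one species.

    Field letters follow the factor table column order: a–d are the
    conservation factors, e–j the vulnerability factors.  ``e_blade_pct`` is a
    percentage (0–100, possibly fractional); all other factors are ordinal.
    """

    species: str
    scientific_name: str
    a_pct_pop: int
    b_survival: int
    c_threat: int
    d_directive: int
    e_blade_pct: float
    f_manoeuvre: int
    g_time_flying: int
    h_nocturnal: int
    i_disturbance: int
    j_habitat: int

    def __post_init__(self) -> None:
        for name in ("a_pct_pop", "b_survival", "c_threat",
                     "f_manoeuvre", "g_time_flying", "h_nocturnal",
                     "i_disturbance", "j_habitat"):
            v = getattr(self, name)
            if not 1 <= v <= 5:
                raise ValueError(f"{name}={v} outside 1..5 for {self.species}")
        if self.d_directive not in (1, 3, 5):
            raise ValueError(
                f"d_directive={self.d_directive} not in {{1,3,5}} for {self.species}")
        if not 0 <= self.e_blade_pct <= 100:
            raise ValueError(
                f"e_blade_pct={self.e_blade_pct} outside 0..100 for {self.species}")


@dataclass(frozen=True)
class SpeciesSensitivity:
    species: str
    ci: int
    collision_score: int
    displacement_score: int
    collision_class: str
    displacement_class: str
    collision_cat: int
    displacement_cat: int

    @property
    def overall_cat(self) -> int:
        return max(self.collision_cat, self.displacement_cat)


@dataclass(frozen=True)
class RiskThresholds:
    """Lower bounds of the risk bands, strictly decreasing.

    ``very_high`` is None for risk types where the top band is not assigned
    (displacement).  A score below ``low`` is "Very low".
    """

    very_high: float | None
    high: float
    moderate: float
    low: float

    def __post_init__(self) -> None:
        seq = ([self.very_high] if self.very_high is not None else []) + [
            self.high, self.moderate, self.low]
        if any(a <= b for a, b in zip(seq, seq[1:])):
            raise ValueError(f"thresholds must be strictly decreasing: {seq}")


# Band edges sit in the gaps between adjacent printed scores so every
# published class label reproduces; configurable for other score tables.
COLLISION_THRESHOLDS = RiskThresholds(very_high=850, high=410, moderate=190, low=50)
DISPLACEMENT_THRESHOLDS = RiskThresholds(very_high=None, high=20, moderate=9, low=6)


def load_species_scores(path: str | Path | None = None) -> list[SpeciesFactorScores]:
    """Load a species factor-score table (the bundled 54-species table by default)."""
    if path is None:
        ref = resources.files("seasens").joinpath("data/species_scores.csv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = {f.name for f in SpeciesFactorScores.__dataclass_fields__.values()}  # type: ignore[attr-defined]
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"species score table missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(SpeciesFactorScores(
            species=d["species"], scientific_name=d["scientific_name"],
            a_pct_pop=int(d["a_pct_pop"]), b_survival=int(d["b_survival"]),
            c_threat=int(d["c_threat"]), d_directive=int(d["d_directive"]),
            e_blade_pct=float(d["e_blade_pct"]), f_manoeuvre=int(d["f_manoeuvre"]),
            g_time_flying=int(d["g_time_flying"]), h_nocturnal=int(d["h_nocturnal"]),
            i_disturbance=int(d["i_disturbance"]), j_habitat=int(d["j_habitat"])))
    return out


# ---------------------------------------------------------------------------
# Banding rules for the four conservation factors
# ---------------------------------------------------------------------------

def score_directive(status: str) -> int:
    """Birds Directive factor: Annex 1 → 5, migratory SPA feature → 3, other → 1."""
    mapping = {"annex1": 5, "migratory_spa_feature": 3, "other": 1}
    try:
        return mapping[status]
    except KeyError:
        raise ValueError(f"unknown directive status {status!r}; "
                         f"expected one of {sorted(mapping)}") from None


def score_pct_population(pct: float) -> int:
    """Band the percentage of the biogeographic population using English waters.

    >20% → 5; 10–19.9% → 4; 5–9.9% → 3; 1–4.9% → 2; <1% → 1.
    """
    if not 0 <= pct <= 100:
        raise ValueError(f"percentage {pct} outside [0, 100]")
    if pct > 20:
        return 5
    if pct >= 10:
        return 4
    if pct >= 5:
        return 3
    if pct >= 1:
        return 2
    return 1


def score_survival(s: float) -> int:
    """Band annual adult survival: <0.749→1, 0.75–0.799→2, 0.80–0.849→3,
    0.85–0.899→4, >0.90→5.  High-survival (K-selected) species are most
    vulnerable to added mortality."""
    if not 0 < s < 1:
        raise ValueError(f"survival probability {s} outside (0, 1)")
    if s >= 0.90:
        return 5
    if s >= 0.85:
        return 4
    if s >= 0.80:
        return 3
    if s >= 0.75:
        return 2
    return 1


def score_bocc(bocc2: str, bocc3: str) -> int:
    """UK threat status from the Birds of Conservation Concern listings.

    Scored from the (BOCC2, BOCC3) pair; combinations not observed in the
    source assessment are rejected.
    """
    key = (bocc2.lower(), bocc3.lower())
    if key[1] == "red":
        return 5
    mapping = {
        ("green", "green"): 1,
        ("amber", "green"): 2,
        ("green", "amber"): 3,
        ("amber", "amber"): 4,
    }
    try:
        return mapping[key]
    except KeyError:
        raise ValueError(f"BOCC combination {key} not represented in the "
                         "assessment") from None


# ---------------------------------------------------------------------------
# Indices
# ---------------------------------------------------------------------------

def conservation_importance(scores: SpeciesFactorScores) -> int:
    """CI = sum of the four conservation factor scores (range 4–20)."""
    return scores.a_pct_pop + scores.b_survival + scores.c_threat + scores.d_directive


def _frac(x: float) -> Fraction:
    # exact rational from a decimal-valued float (blade pct like 0.5, 12, 35)
    return Fraction(str(x))


def collision_index(scores: SpeciesFactorScores, ci: int | None = None) -> int:
    """Collision vulnerability index.

    Blade-height exposure gets full weight; manoeuvrability, time flying and
    nocturnal activity enter as their mean; the product is scaled by CI and
    rounded half-to-even.  Computed in exact rational arithmetic so that
    half-way cases are genuine ties.
    """
    if ci is None:
        ci = conservation_importance(scores)
    raw = (_frac(scores.e_blade_pct)
           * (scores.f_manoeuvre + scores.g_time_flying + scores.h_nocturnal)
           * ci / 3)
    return round(raw)


def displacement_index(scores: SpeciesFactorScores, ci: int | None = None) -> int:
    """Displacement vulnerability index: disturbance × habitat × CI / 10,
    rounded half-to-even (exact rational arithmetic)."""
    if ci is None:
        ci = conservation_importance(scores)
    raw = Fraction(scores.i_disturbance * scores.j_habitat * ci, 10)
    return round(raw)


def classify_risk(score: float, risk_type: Literal["collision", "displacement"],
                  thresholds: RiskThresholds | None = None) -> tuple[str, int]:
    """Band an index score into a risk class and its categorical value (5..1).

    Displacement risk is capped at "High" (category 4).
    """
    if thresholds is None:
        thresholds = (COLLISION_THRESHOLDS if risk_type == "collision"
                      else DISPLACEMENT_THRESHOLDS)
    if risk_type == "displacement" and thresholds.very_high is not None:
        raise ValueError("'Very high' risk is not assigned for displacement")
    if thresholds.very_high is not None and score >= thresholds.very_high:
        label = "Very high"
    elif score >= thresholds.high:
        label = "High"
    elif score >= thresholds.moderate:
        label = "Moderate"
    elif score >= thresholds.low:
        label = "Low"
    else:
        label = "Very low"
    return label, RISK_CATEGORIES[label]


def score_table(rows: list[SpeciesFactorScores],
                collision_thresholds: RiskThresholds | None = None,
                displacement_thresholds: RiskThresholds | None = None,
                ) -> pd.DataFrame:
    """Score every species and rank.

    Returns a DataFrame sorted by descending collision score (stable, so
    equal scores keep input order), with both indices, class labels and
    categorical values, plus rank columns for each risk type.
    """
    if not rows:
        raise ValueError("empty species table")
    recs = []
    for sc in rows:
        ci = conservation_importance(sc)
        col = collision_index(sc, ci)
        dis = displacement_index(sc, ci)
        col_cls, col_cat = classify_risk(
            col, "collision", collision_thresholds)
        dis_cls, dis_cat = classify_risk(
            dis, "displacement", displacement_thresholds)
        recs.append(dict(
            species=sc.species, ci=ci,
            collision_score=col, collision_class=col_cls, collision_cat=col_cat,
            displacement_score=dis, displacement_class=dis_cls,
            displacement_cat=dis_cat, overall_cat=max(col_cat, dis_cat)))
    df = pd.DataFrame.from_records(recs)
    df["collision_rank"] = (df["collision_score"]
                            .rank(method="min", ascending=False).astype(int))
    df["displacement_rank"] = (df["displacement_score"]
                               .rank(method="min", ascending=False).astype(int))
    return (df.sort_values("collision_score", ascending=False, kind="stable")
            .reset_index(drop=True))


def sensitivity_for(rows: list[SpeciesFactorScores]) -> dict[str, SpeciesSensitivity]:
    """Map species name → SpeciesSensitivity for downstream mapping."""
    df = score_table(rows)
    return {
        r.species: SpeciesSensitivity(
            species=r.species, ci=r.ci,
            collision_score=r.collision_score,
            displacement_score=r.displacement_score,
            collision_class=r.collision_class,
            displacement_class=r.displacement_class,
            collision_cat=r.collision_cat,
            displacement_cat=r.displacement_cat)
        for r in df.itertuples(index=False)
    }
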
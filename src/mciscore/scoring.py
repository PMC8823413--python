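"""Point-based risk scoring (Sullivan/Framingham construction).

Converts a fitted sex-specific Cox model into an integer point instrument
through the classic seven steps: per-factor regression coefficients βᵢ;
clinically meaningful categories with within-category median reference
values Wᵢ; the first (lowest-risk) category's reference W_iREF as the base;
differences Dᵢ = βᵢ·(Wᵢ − W_iREF); a base constant B representing one point;
integer points Pᵢ = round(Dᵢ / B); and an absolute-risk map

    risk(score) = 1 − S₀(t*) ^ exp(Σᵢβᵢ·W_iREF + B·score − Σᵢβᵢ·Mᵢ)

where S₀(t*) is the overall Kaplan–Meier survival at the horizon t* and Mᵢ
the covariate mean (proportion) in the fitting cohort.  With the unrounded
score Σ Dᵢ/B the exponent collapses to the mean-centred Cox linear
predictor, so the map is algebraically identical to the direct Cox
prediction; rounding to integer points perturbs the exponent by at most
half a point times B per factor.

The published sex-specific instruments (integer points and score-to-risk
bands) ship as packaged constants; their underlying S₀ and β were not
published, so they score and band but do not produce absolute risks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import BaselineProfile, SurvivalRecord
from .exceptions import (
    ExtrapolationError,
    InputError,
    MissingFieldError,
    OutOfRangeError,
    ParameterError,
    RiskParametersUnavailableError,
    UnsupportedCategoryError,
)
from .survival import CoxModel, SurvivalCurve

__all__ = [
    "CategoryDef",
    "FactorScheme",
    "CategoryScheme",
    "RiskParams",
    "ScoreBand",
    "InstrumentFactor",
    "Instrument",
    "RiskPrediction",
    "default_factor_definitions",
    "build_category_scheme",
    "build_instrument",
    "absolute_risk",
    "published_instruments",
    "apply_instrument",
    "profile_covariates",
    "risk_grid",
]


# ---------------------------------------------------------------------------
# Categories and schemes


@dataclass(frozen=True)
class CategoryDef:
    """One category of a factor: a closed interval [lo, hi] for continuous
    factors or a single coded level for discrete ones."""

    label: str
    lo: float | None = None
    hi: float | None = None
    level: float | None = None

    def contains(self, value: float) -> bool:
        if self.level is not None:
            return value == self.level
        lo = -np.inf if self.lo is None else self.lo
        hi = np.inf if self.hi is None else self.hi
        return lo <= value <= hi


@dataclass(frozen=True)
class FactorScheme:
    """Ordered categories of one factor plus reference values Wᵢ.

    The first category is the basic (lowest-risk) reference; its W is
    W_iREF.  Categories must be exhaustive and non-overlapping over the
    factor's domain.
    """

    name: str
    categories: tuple[CategoryDef, ...]
    w: tuple[float, ...]

    def __post_init__(self):
        if len(self.categories) != len(self.w):
            raise InputError(f"{self.name}: one W per category required")

    @property
    def w_ref(self) -> float:
        return self.w[0]

    def assign(self, value: float) -> int:
        for i, cat in enumerate(self.categories):
            if cat.contains(value):
                return i
        raise UnsupportedCategoryError(f"{self.name}: value {value!r} matches no category")


CategoryScheme = dict[str, FactorScheme]


def default_factor_definitions() -> dict[str, tuple[CategoryDef, ...]]:
    """Category layouts of the published instrument, reference first.

    Age in decade bands over the supported 61–90 range; APOE e4 carriage,
    MMSE ≤26 and CDR 0.5 as indicator factors.  Configurable for other
    cohorts: pass your own mapping to :func:`build_category_scheme`.
    """
    return {
        "age": (
            CategoryDef("61-70", lo=61, hi=70),
            CategoryDef("71-80", lo=71, hi=80),
            CategoryDef("81-90", lo=81, hi=90),
        ),
        "apoe4": (CategoryDef("No", level=0.0), CategoryDef("Yes", level=1.0)),
        "mmse_le26": (CategoryDef(">26", level=0.0), CategoryDef("<=26", level=1.0)),
        "cdr05": (CategoryDef("0.0", level=0.0), CategoryDef("0.5", level=1.0)),
    }


def build_category_scheme(
    records: Sequence[SurvivalRecord],
    definitions: Mapping[str, tuple[CategoryDef, ...]] | None = None,
) -> CategoryScheme:
    """Attach reference values to category definitions from cohort data.

    Continuous categories take the within-category median of observed
    values as W; level categories take the coded level itself.  An empty
    continuous category is an error naming the category, since its
    reference value would be undefined.
    """
    definitions = definitions or default_factor_definitions()
    scheme: CategoryScheme = {}
    for name, cats in definitions.items():
        values = np.array(
            [r.covariates[name] for r in records if name in r.covariates and np.isfinite(r.covariates[name])]
        )
        ws = []
        for cat in cats:
            if cat.level is not None:
                ws.append(float(cat.level))
                continue
            inside = values[[cat.contains(v) for v in values]] if values.size else values
            if inside.size == 0:
                raise InputError(f"empty category {cat.label!r} for factor {name!r}")
            ws.append(float(np.median(inside)))
        scheme[name] = FactorScheme(name, tuple(cats), tuple(ws))
    return scheme


# ---------------------------------------------------------------------------
# The instrument


@dataclass(frozen=True)
class RiskParams:
    """Parameters of the score → absolute-risk map."""

    s0: float  # overall KM survival at the horizon
    horizon: float  # years
    offset: float  # Σ βᵢ·Mᵢ over the instrument's factors
    ref_term: float  # Σ βᵢ·W_iREF (reference-profile contribution)


@dataclass(frozen=True)
class ScoreBand:
    """A contiguous score interval mapped to a predicted-risk band (%)."""

    score_lo: int | None  # None = open below
    score_hi: int | None  # None = open above
    label: str
    risk_lo: float  # lower band bound in %, exclusive except for the first band
    risk_hi: float | None  # None = open above

    def contains(self, score: float) -> bool:
        lo = -np.inf if self.score_lo is None else self.score_lo
        hi = np.inf if self.score_hi is None else self.score_hi
        return lo <= score <= hi


@dataclass(frozen=True)
class InstrumentFactor:
    name: str
    categories: tuple[CategoryDef, ...]
    points: tuple[int, ...]

    def assign(self, value: float) -> int:
        for i, cat in enumerate(self.categories):
            if cat.contains(value):
                return i
        raise UnsupportedCategoryError(f"{self.name}: value {value!r} matches no category")


@dataclass(frozen=True)
class Instrument:
    """A sex-specific integer point instrument with a score→risk lookup."""

    sex: str
    factors: tuple[InstrumentFactor, ...]
    B: float
    bands: tuple[ScoreBand, ...]
    risk_params: RiskParams | None = None

    @property
    def min_score(self) -> int:
        return sum(min(f.points) for f in self.factors)

    @property
    def max_score(self) -> int:
        return sum(max(f.points) for f in self.factors)

    def band_for(self, score: float) -> ScoreBand:
        for band in self.bands:
            if band.contains(score):
                return band
        raise InputError(f"score {score} falls in no band of the {self.sex} instrument")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "sex": self.sex,
            "B": None if np.isnan(self.B) else self.B,
            "factors": [
                {
                    "name": f.name,
                    "categories": [
                        {"label": c.label, "lo": c.lo, "hi": c.hi, "level": c.level}
                        for c in f.categories
                    ],
                    "points": list(f.points),
                }
                for f in self.factors
            ],
            "bands": [
                {"score_lo": b.score_lo, "score_hi": b.score_hi, "label": b.label,
                 "risk_lo": b.risk_lo, "risk_hi": b.risk_hi}
                for b in self.bands
            ],
            "risk_params": None
            if self.risk_params is None
            else {"s0": self.risk_params.s0, "horizon": self.risk_params.horizon,
                  "offset": self.risk_params.offset, "ref_term": self.risk_params.ref_term},
            "min_score": self.min_score,
            "max_score": self.max_score,
        }

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "Instrument":
        factors = tuple(
            InstrumentFactor(
                f["name"],
                tuple(CategoryDef(c["label"], c["lo"], c["hi"], c["level"]) for c in f["categories"]),
                tuple(int(p) for p in f["points"]),
            )
            for f in d["factors"]
        )
        bands = tuple(
            ScoreBand(b["score_lo"], b["score_hi"], b["label"], b["risk_lo"], b["risk_hi"])
            for b in d["bands"]
        )
        rp = d.get("risk_params")
        return cls(
            sex=d["sex"], factors=factors,
            B=float("nan") if d["B"] is None else float(d["B"]),
            bands=bands,
            risk_params=None if rp is None else RiskParams(**rp),
        )

    @classmethod
    def from_json(cls, path) -> "Instrument":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def score_table(self) -> pd.DataFrame:
        """Long-format per-category point table (the instrument's first part)."""
        rows = []
        for f in self.factors:
            for cat, pts in zip(f.categories, f.points):
                rows.append({"factor": f.name, "category": cat.label, "points": pts})
        return pd.DataFrame(rows)

    def band_table(self) -> pd.DataFrame:
        """Score→risk band table (the instrument's second part)."""
        return pd.DataFrame(
            [{"score_lo": b.score_lo, "score_hi": b.score_hi, "band": b.label,
              "risk_lo_pct": b.risk_lo, "risk_hi_pct": b.risk_hi}
             for b in self.bands]
        )


@dataclass(frozen=True)
class RiskPrediction:
    participant_id: str | None
    points: dict[str, int]
    total: int
    band: str
    risk: float | None = None  # absolute risk in [0,1], when parameters exist
    high_risk: bool | None = None


def _round_half_away(x: float) -> int:
    return int(np.sign(x) * np.floor(np.abs(x) + 0.5))


def _band_label(lo_pct: float, hi_pct: float | None) -> str:
    if lo_pct <= 0:
        return f"<={hi_pct:.0f}%"
    if hi_pct is None:
        return f">{lo_pct:.0f}%"
    return f"{lo_pct + 1:.0f}-{hi_pct:.0f}%"


def build_instrument(
    model: CoxModel,
    scheme: CategoryScheme,
    b: float | str = "auto",
    horizon: float = 12.0,
    s0_curve: SurvivalCurve | None = None,
    sex: str = "unspecified",
    band_width_pct: float = 10.0,
) -> Instrument:
    """Construct the point instrument from a fitted Cox model.

    ``b`` is the hazard increment one point represents; ``"auto"`` uses the
    Framingham convention of half an age decade, βage·5 years, which yields
    the familiar two-points-per-decade age column.  The score→risk lookup
    is built by evaluating the absolute-risk map at every achievable total
    score and binning into ``band_width_pct`` bands.
    """
    missing = [n for n in scheme if n not in model.covariates]
    if missing:
        raise InputError(f"model lacks scheme factors {missing}")
    if b == "auto":
        if "age" not in scheme:
            raise ParameterError("b='auto' requires an age factor in the scheme")
        b_val = model.beta("age") * 5.0
    else:
        b_val = float(b)
    if b_val <= 0:
        raise ParameterError(f"point constant B must be positive, got {b_val}")
    if s0_curve is None:
        raise InputError("an overall survival curve is required")
    if horizon > s0_curve.max_time:
        raise ExtrapolationError(
            f"horizon {horizon} y beyond last observed time {s0_curve.max_time} y"
        )

    factors = []
    ref_term = 0.0
    offset = 0.0
    for name, fs in scheme.items():
        beta = model.beta(name)
        d = [beta * (w - fs.w_ref) for w in fs.w]
        points = tuple(_round_half_away(di / b_val) for di in d)
        factors.append(InstrumentFactor(name, fs.categories, points))
        ref_term += beta * fs.w_ref
        offset += beta * model.mean(name)

    rp = RiskParams(
        s0=float(s0_curve.survival_at(horizon)),
        horizon=horizon,
        offset=offset,
        ref_term=ref_term,
    )
    inst = Instrument(sex=sex, factors=tuple(factors), B=b_val, bands=(), risk_params=rp)

    # bin achievable totals into fixed-width predicted-risk bands
    lo, hi = inst.min_score, inst.max_score
    totals = np.arange(lo, hi + 1)
    risks_pct = np.array([absolute_risk(t, inst) for t in totals]) * 100
    band_idx = np.ceil(risks_pct / band_width_pct).astype(int).clip(min=1)
    bands = []
    for bi in np.unique(band_idx):
        members = totals[band_idx == bi]
        b_lo = (bi - 1) * band_width_pct
        b_hi = bi * band_width_pct
        open_top = b_hi >= 100
        bands.append(
            ScoreBand(
                score_lo=None if members.min() == lo else int(members.min()),
                score_hi=None if members.max() == hi else int(members.max()),
                label=_band_label(b_lo, None if open_top else b_hi),
                risk_lo=float(b_lo),
                risk_hi=None if open_top else float(b_hi),
            )
        )
    return Instrument(sex=sex, factors=tuple(factors), B=b_val, bands=tuple(bands), risk_params=rp)


def absolute_risk(total_points: float, instrument: Instrument) -> float:
    """Absolute event risk at the instrument's horizon for a total score.

    Accepts the integer total or an unrounded score (Σ Dᵢ/B), for which the
    result equals the direct Cox prediction exactly.
    """
    rp = instrument.risk_params
    if rp is None:
        raise RiskParametersUnavailableError(
            f"{instrument.sex} instrument carries no absolute-risk parameters"
        )
    if not 0 <= rp.s0 <= 1:
        raise InputError(f"S0 must lie in [0, 1], got {rp.s0}")
    if rp.s0 == 0:
        warnings.warn("S0 at the horizon is 0; risk saturates at 1", stacklevel=2)
        return 1.0
    exponent = rp.ref_term + instrument.B * float(total_points) - rp.offset
    return float(1.0 - rp.s0 ** np.exp(exponent))


# ---------------------------------------------------------------------------
# The published instruments


def _pub_factors(apoe: int, mmse: int, cdr: int) -> tuple[InstrumentFactor, ...]:
    defs = default_factor_definitions()
    return (
        InstrumentFactor("age", defs["age"], (0, 2, 4)),
        InstrumentFactor("apoe4", defs["apoe4"], (0, apoe)),
        InstrumentFactor("mmse_le26", defs["mmse_le26"], (0, mmse)),
        InstrumentFactor("cdr05", defs["cdr05"], (0, cdr)),
    )


_FEMALE_BANDS = (
    ScoreBand(None, 1, "<=10%", 0.0, 10.0),
    ScoreBand(2, 8, "11-20%", 10.0, 20.0),
    ScoreBand(9, 12, "21-30%", 20.0, 30.0),
    ScoreBand(13, 16, "31-40%", 30.0, 40.0),
    ScoreBand(17, 19, "41-50%", 40.0, 50.0),
    ScoreBand(20, None, ">50%", 50.0, None),
)

_MALE_BANDS = (
    ScoreBand(None, 10, "<=10%", 0.0, 10.0),
    ScoreBand(11, 15, "11-20%", 10.0, 20.0),
    ScoreBand(16, 18, "21-30%", 20.0, 30.0),
    ScoreBand(19, 21, "31-40%", 30.0, 40.0),
    ScoreBand(22, None, "41-50%", 40.0, 50.0),
)


def published_instruments() -> tuple[Instrument, Instrument]:
    """The published female and male instruments as packaged constants.

    Points per factor and the score→risk bands transcribe the published
    tables; the underlying S₀(t*) and β were not published, so
    ``risk_params`` is None and these instruments report risk bands only.
    """
    female = Instrument(
        sex="female",
        factors=_pub_factors(apoe=2, mmse=1, cdr=14),
        B=float("nan"),
        bands=_FEMALE_BANDS,
        risk_params=None,
    )
    male = Instrument(
        sex="male",
        factors=_pub_factors(apoe=3, mmse=5, cdr=9),
        B=float("nan"),
        bands=_MALE_BANDS,
        risk_params=None,
    )
    return female, male


# ---------------------------------------------------------------------------
# Scoring profiles


_REQUIRED_FIELDS = ("age", "apoe4_carrier", "mmse", "cdr_global")


def profile_covariates(profile: BaselineProfile | Mapping[str, float]) -> dict[str, float]:
    """Map a baseline profile to the instrument's factor values."""
    if isinstance(profile, BaselineProfile):
        for name in _REQUIRED_FIELDS:
            if getattr(profile, name) is None:
                raise MissingFieldError(f"{profile.participant_id}: required field {name!r} missing")
        return {
            "age": float(profile.age),
            "apoe4": float(profile.apoe4_carrier),
            "mmse_le26": float(profile.mmse <= 26),
            "cdr05": float(profile.cdr_global == 0.5),
            "_cdr_raw": float(profile.cdr_global),
            "_id": profile.participant_id,
        }
    cov = dict(profile)
    for key in ("age", "apoe4", "mmse_le26", "cdr05"):
        if key not in cov or cov[key] is None or not np.isfinite(cov[key]):
            raise MissingFieldError(f"required factor value {key!r} missing")
    return cov


def apply_instrument(
    profile: BaselineProfile | Mapping[str, float],
    instrument: Instrument,
    cutoff: float | None = None,
) -> RiskPrediction:
    """Score one profile: per-factor points, total, risk band, absolute risk.

    The profile's age must lie in the supported 61–90 range and its global
    CDR must be 0.0 or 0.5 (the instrument defines no categories beyond
    questionable impairment).  ``cutoff`` — on the absolute-risk scale when
    risk parameters exist, otherwise on the score scale — sets the
    high-risk flag.
    """
    cov = profile_covariates(profile)
    if not 61 <= cov["age"] <= 90:
        raise OutOfRangeError(f"age {cov['age']} outside the supported range [61, 90]")
    raw_cdr = cov.get("_cdr_raw", 0.5 * cov["cdr05"])
    if raw_cdr not in (0.0, 0.5):
        raise UnsupportedCategoryError(f"CDR {raw_cdr} unsupported; instrument covers 0.0 and 0.5")

    points = {}
    for f in instrument.factors:
        idx = f.assign(cov[f.name])
        points[f.name] = f.points[idx]
    total = int(sum(points.values()))
    band = instrument.band_for(total)
    risk = absolute_risk(total, instrument) if instrument.risk_params is not None else None
    high = None
    if cutoff is not None:
        ranking = risk if risk is not None else total
        high = bool(ranking >= cutoff)
    return RiskPrediction(
        participant_id=cov.get("_id"),
        points=points,
        total=total,
        band=band.label,
        risk=risk,
        high_risk=high,
    )


def risk_grid(instrument: Instrument) -> pd.DataFrame:
    """All category combinations with points, totals, bands and risks.

    For the default four-factor layout this is the 3×2×2×2 = 24-cell grid
    behind the published heat map.
    """
    rows = []
    for combo in product(*[range(len(f.categories)) for f in instrument.factors]):
        row = {}
        total = 0
        for f, idx in zip(instrument.factors, combo):
            row[f.name] = f.categories[idx].label
            row[f"{f.name}_points"] = f.points[idx]
            total += f.points[idx]
        row["total"] = total
        row["band"] = instrument.band_for(total).label
        if instrument.risk_params is not None:
            row["risk"] = absolute_risk(total, instrument)
        rows.append(row)
    return pd.DataFrame(rows)
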
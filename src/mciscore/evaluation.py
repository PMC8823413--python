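"""Discrimination, cutoff selection, calibration and validation reporting.

AUC is the tie-corrected pairwise concordance (computed via scikit-learn's
midrank implementation) with a DeLong-style analytic confidence interval;
the high/low-risk cutoff maximises Youden's J over observed score values
("high risk" means score >= cutoff); calibration uses the grouped
Hosmer–Lemeshow chi-square comparing observed with expected event counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .cohort import BaselineProfile, SurvivalRecord
from .exceptions import DegenerateInputError, InputError, UndefinedMetricError
from .scoring import Instrument, apply_instrument

__all__ = [
    "RocResult",
    "HosmerLemeshowResult",
    "WelchResult",
    "EvaluationReport",
    "roc_auc",
    "youden_cutoff",
    "hosmer_lemeshow",
    "dichotomized_c",
    "external_validate",
    "sex_risk_compare",
    "high_risk_age_distribution",
]


def _check_classes(labels: np.ndarray):
    if labels.all() or not labels.any():
        raise UndefinedMetricError("AUC undefined: only one outcome class present")


def _sens_spec(scores: np.ndarray, labels: np.ndarray, threshold: float) -> tuple[float, float]:
    high = scores >= threshold
    sens = high[labels].mean()
    spec = (~high[~labels]).mean()
    return float(sens), float(spec)


@dataclass
class RocResult:
    auc: float
    ci: tuple[float, float]
    points: pd.DataFrame  # threshold, sensitivity, specificity at every distinct score


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> float:
    """DeLong variance of the AUC via midrank placements."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n  # placement of each positive
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m  # placement of each negative
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc(scores, labels, alpha: float = 0.05) -> RocResult:
    """AUC as tie-corrected pairwise concordance, with ROC points.

    Equivalent to the probability that a randomly chosen converter scores
    above a randomly chosen non-converter, counting ties as 1/2.  The
    confidence interval uses the DeLong placement variance (normal on the
    AUC scale, clipped to [0, 1]).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise InputError("scores and labels must align")
    _check_classes(labels)
    auc = float(roc_auc_score(labels, scores))
    var = _delong_variance(scores, labels)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    thresholds = np.unique(scores)
    pts = [(_t, *_sens_spec(scores, labels, _t)) for _t in thresholds]
    points = pd.DataFrame(pts, columns=["threshold", "sensitivity", "specificity"])
    return RocResult(auc=auc, ci=(max(0.0, auc - half), min(1.0, auc + half)), points=points)


def youden_cutoff(scores, labels) -> tuple[float, float]:
    """Threshold maximising Youden's J = sensitivity + specificity − 1.

    Searches every distinct observed score as a candidate "score >= t is
    high risk" threshold; ties in J break toward the lowest threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    _check_classes(labels)
    best_t, best_j = None, -np.inf
    for t in np.unique(scores):  # ascending, so first max wins ties
        sens, spec = _sens_spec(scores, labels, t)
        j = sens + spec - 1
        if j > best_j + 1e-12:
            best_t, best_j = float(t), float(j)
    return best_t, best_j


@dataclass
class HosmerLemeshowResult:
    statistic: float
    df: int
    p_value: float
    n_groups: int
    table: pd.DataFrame  # per group: n, mean predicted, observed, expected


def hosmer_lemeshow(
    predicted,
    observed,
    n_groups: int = 10,
    group_index=None,
) -> HosmerLemeshowResult:
    """Grouped chi-square calibration test.

    Groups subjects by predicted-risk quantiles (deciles by default) or by
    a caller-supplied ``group_index`` (e.g. score bands).  Per group g,
    with mean predicted risk π̄_g and observed events O_g,

        χ² = Σ_g (O_g − n_g·π̄_g)² / (n_g·π̄_g·(1 − π̄_g)),   df = g − 2.

    Degenerate groups (π̄ of exactly 0 or 1) are merged with a neighbour
    with a warning.
    """
    p = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=bool)
    if p.shape != y.shape:
        raise InputError("predicted and observed must align")
    if np.any((p < 0) | (p > 1)):
        raise InputError("predicted risks must lie in [0, 1]")
    if group_index is not None:
        gidx = np.asarray(group_index)
        codes = pd.factorize(gidx, sort=True)[0]
    else:
        if n_groups < 2:
            raise InputError("need at least 2 groups")
        order = np.argsort(p, kind="stable")
        codes = np.empty(len(p), dtype=int)
        for g, chunk in enumerate(np.array_split(order, n_groups)):
            codes[chunk] = g

    groups = []
    for g in np.unique(codes):
        mask = codes == g
        groups.append([int(mask.sum()), float(p[mask].mean()), int(y[mask].sum()), float(p[mask].sum())])
    # merge degenerate groups (mean predicted risk exactly 0 or 1) into a neighbour
    i = 0
    while i < len(groups):
        n_g, pbar, o_g, e_g = groups[i]
        if pbar in (0.0, 1.0) and len(groups) > 1:
            warnings.warn("merging degenerate calibration group with neighbour", stacklevel=2)
            j = i + 1 if i + 1 < len(groups) else i - 1
            nj, _, oj, ej = groups[j]
            merged_n = n_g + nj
            groups[j] = [merged_n, (e_g + ej) / merged_n, o_g + oj, e_g + ej]
            groups.pop(i)
            continue
        i += 1

    stat = 0.0
    rows = []
    for n_g, pbar, o_g, e_g in groups:
        denom = n_g * pbar * (1 - pbar)
        if denom > 0:
            stat += (o_g - n_g * pbar) ** 2 / denom
        rows.append({"n": n_g, "mean_predicted": pbar, "observed": o_g, "expected": n_g * pbar})
    df = max(len(groups) - 2, 1)
    return HosmerLemeshowResult(
        statistic=float(stat),
        df=df,
        p_value=float(stats.chi2.sf(stat, df)),
        n_groups=len(groups),
        table=pd.DataFrame(rows),
    )


def dichotomized_c(high_flags, labels) -> float:
    """C-statistic of a binary high/low predictor: (sensitivity + specificity)/2."""
    flags = np.asarray(high_flags, dtype=bool)
    labels = np.asarray(labels, dtype=bool)
    _check_classes(labels)
    sens = flags[labels].mean()
    spec = (~flags[~labels]).mean()
    return float((sens + spec) / 2)


@dataclass
class EvaluationReport:
    sex: str
    n: int
    n_events: int
    auc: float
    auc_ci: tuple[float, float]
    roc_points: pd.DataFrame
    cutoff: float
    youden_j: float
    dichotomized_c: float
    ranking: str  # "risk" | "score"
    hosmer_lemeshow: HosmerLemeshowResult | None
    calibration_table: pd.DataFrame | None
    unscored: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sex": self.sex,
            "n": self.n,
            "n_events": self.n_events,
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "cutoff": self.cutoff,
            "youden_j": self.youden_j,
            "dichotomized_c": self.dichotomized_c,
            "ranking": self.ranking,
            "hl_statistic": None if self.hosmer_lemeshow is None else self.hosmer_lemeshow.statistic,
            "hl_df": None if self.hosmer_lemeshow is None else self.hosmer_lemeshow.df,
            "hl_p": None if self.hosmer_lemeshow is None else self.hosmer_lemeshow.p_value,
            "n_unscored": len(self.unscored),
        }


def external_validate(
    instrument: Instrument,
    profiles: dict[str, BaselineProfile],
    records: list[SurvivalRecord],
    cutoff: float | None = None,
    ranking: str = "auto",
) -> EvaluationReport:
    """Score a prepared cohort with the instrument and assess it end to end.

    Runs discrimination (AUC), cutoff selection (Youden, unless a fixed
    ``cutoff`` is supplied), calibration (Hosmer–Lemeshow over score-band
    groups, only when the instrument carries absolute-risk parameters) and
    the dichotomized C-statistic.  The ranking variable is the predicted
    absolute risk when available, otherwise the total score; subjects the
    instrument cannot score are excluded with a warning and listed.
    """
    if ranking not in ("auto", "risk", "score"):
        raise InputError(f"unknown ranking {ranking!r}")
    use_risk = instrument.risk_params is not None if ranking == "auto" else ranking == "risk"
    if ranking == "risk" and instrument.risk_params is None:
        raise InputError("risk ranking requested but instrument has no risk parameters")

    scores, risks, labels, bands, unscored = [], [], [], [], []
    for rec in records:
        prof = profiles.get(rec.participant_id)
        if prof is None:
            unscored.append(rec.participant_id)
            continue
        try:
            pred = apply_instrument(prof, instrument)
        except Exception:
            unscored.append(rec.participant_id)
            continue
        scores.append(pred.total)
        risks.append(pred.risk)
        bands.append(pred.band)
        labels.append(rec.event)
    if unscored:
        warnings.warn(f"excluded {len(unscored)} unscoreable subjects", stacklevel=2)
    labels = np.asarray(labels, dtype=bool)
    values = np.asarray(risks if use_risk else scores, dtype=float)

    roc = roc_auc(values, labels)
    if cutoff is None:
        cutoff, j = youden_cutoff(values, labels)
    else:
        sens, spec = _sens_spec(values, labels, cutoff)
        j = sens + spec - 1
    flags = values >= cutoff
    c_dich = dichotomized_c(flags, labels)

    hl = None
    calib = None
    if use_risk:
        hl = hosmer_lemeshow(np.asarray(risks, dtype=float), labels, group_index=np.asarray(bands))
        calib = hl.table
    return EvaluationReport(
        sex=instrument.sex,
        n=int(labels.size),
        n_events=int(labels.sum()),
        auc=roc.auc,
        auc_ci=roc.ci,
        roc_points=roc.points,
        cutoff=float(cutoff),
        youden_j=float(j),
        dichotomized_c=c_dich,
        ranking="risk" if use_risk else "score",
        hosmer_lemeshow=hl,
        calibration_table=calib,
        unscored=unscored,
    )


@dataclass
class WelchResult:
    mean1: float
    mean2: float
    difference: float
    statistic: float
    df: float
    p_value: float


def sex_risk_compare(predictions_female, predictions_male) -> WelchResult:
    """Welch two-sample comparison of predicted risks between the sexes."""
    a = np.asarray(predictions_female, dtype=float)
    b = np.asarray(predictions_male, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both groups must be non-empty")
    if a.var(ddof=0) == 0 and b.var(ddof=0) == 0:
        if np.array_equal(np.unique(a), np.unique(b)):
            return WelchResult(float(a.mean()), float(b.mean()), 0.0, 0.0, float(a.size + b.size - 2), 1.0)
        raise DegenerateInputError("Welch test undefined: zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(
        mean1=float(a.mean()),
        mean2=float(b.mean()),
        difference=float(a.mean() - b.mean()),
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
    )


AGE_BANDS = ((61, 70), (71, 80), (81, 90))


def high_risk_age_distribution(
    predictions,
    profiles: list[BaselineProfile],
    cutoff: float,
) -> pd.DataFrame:
    """Counts and within-sex proportions of high-risk subjects by age band.

    ``predictions`` is the per-subject ranking value (absolute risk or
    total score, matching the cutoff's scale), aligned with ``profiles``.
    """
    values = np.asarray(predictions, dtype=float)
    if len(values) != len(profiles):
        raise InputError("predictions and profiles must align")
    rows = []
    for sex in ("female", "male"):
        idx = [i for i, p in enumerate(profiles) if p.sex == sex]
        high = [profiles[i] for i in idx if values[i] >= cutoff]
        counts = []
        for lo, hi in AGE_BANDS:
            counts.append(sum(lo <= p.age <= hi for p in high))
        total = sum(counts)
        for (lo, hi), c in zip(AGE_BANDS, counts):
            rows.append(
                {"sex": sex, "age_band": f"{lo}-{hi}", "high_risk": c,
                 "proportion": c / total if total else 0.0}
            )
    return pd.DataFrame(rows)
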
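"""Point-system construction, the packaged published instruments, scoring."""

import numpy as np
import pytest

from mciscore import (
    BaselineProfile,
    CategoryDef,
    CoxModel,
    Instrument,
    SurvivalCurve,
    SurvivalRecord,
    absolute_risk,
    apply_instrument,
    build_category_scheme,
    build_instrument,
    default_factor_definitions,
    fit_cox,
    km_survival,
    published_instruments,
    risk_grid,
)
from mciscore.exceptions import (
    ExtrapolationError,
    InputError,
    MissingFieldError,
    OutOfRangeError,
    ParameterError,
    RiskParametersUnavailableError,
    UnsupportedCategoryError,
)
from mciscore.scoring import RiskParams


def _prof(sex="female", age=65, apoe=False, mmse=29, cdr=0.0, pid="X"):
    return BaselineProfile(participant_id=pid, sex=sex, age=age, apoe4_carrier=apoe,
                           mmse=mmse, cdr_global=cdr)


def _flat_curve(s0=0.8, tmax=15.0):
    return SurvivalCurve(np.array([1.0, tmax]), np.array([0.9, s0]),
                         np.array([10, 5]), np.array([1, 1]))


def _model(betas, means):
    names = tuple(betas)
    return CoxModel(
        covariates=names,
        coef=np.array([betas[n] for n in names]),
        se=np.full(len(names), 0.1),
        means=np.array([means[n] for n in names]),
        loglik=0.0, ties="efron", n=100, n_events=20,
    )


class TestCategoryScheme:
    def test_uniform_age_band_median(self):
        recs = [SurvivalRecord(f"P{a}", None, 1.0, False, {"age": float(a)})
                for a in range(61, 71)]
        defs = {"age": (CategoryDef("61-70", lo=61, hi=70),)}
        scheme = build_category_scheme(recs, defs)
        assert scheme["age"].w == (65.5,)

    def test_binary_levels_use_coded_values(self, small_cohorts):
        scheme = build_category_scheme(small_cohorts.female)
        assert scheme["apoe4"].w == (0.0, 1.0)
        assert scheme["apoe4"].w_ref == 0.0

    def test_default_age_bands_match_published_layout(self):
        defs = default_factor_definitions()
        assert [c.label for c in defs["age"]] == ["61-70", "71-80", "81-90"]
        assert (defs["age"][0].lo, defs["age"][2].hi) == (61, 90)

    def test_empty_category_is_named_in_error(self):
        recs = [SurvivalRecord("P", None, 1.0, False, {"age": 65.0})]
        defs = {"age": (CategoryDef("61-70", lo=61, hi=70), CategoryDef("71-80", lo=71, hi=80))}
        with pytest.raises(InputError, match="71-80"):
            build_category_scheme(recs, defs)


class TestBuildInstrument:
    def test_reference_categories_score_zero(self, small_cohorts):
        model = fit_cox(small_cohorts.male, ["age", "apoe4", "mmse_le26", "cdr05"])
        inst = build_instrument(model, build_category_scheme(small_cohorts.male),
                                s0_curve=km_survival(small_cohorts.male), sex="male")
        assert all(f.points[0] == 0 for f in inst.factors)

    def test_age_points_hand_arithmetic(self):
        # beta_age = 0.07/yr, band medians 65.5/75.5/85.5, B = 0.35
        # D = 0.07 * (0, 10, 20) = (0, 0.7, 1.4); P = D/0.35 = (0, 2, 4)
        recs = [SurvivalRecord(f"P{a}", None, 1.0, False, {"age": float(a)})
                for a in list(range(61, 71)) + list(range(71, 81)) + list(range(81, 91))]
        defs = {"age": default_factor_definitions()["age"]}
        scheme = build_category_scheme(recs, defs)
        model = _model({"age": 0.07}, {"age": 75.5})
        inst = build_instrument(model, scheme, b=0.35, s0_curve=_flat_curve(), sex="test")
        assert inst.factors[0].points == (0, 2, 4)

    def test_auto_b_is_half_decade_of_age(self, small_cohorts):
        model = fit_cox(small_cohorts.female, ["age", "apoe4", "mmse_le26", "cdr05"])
        inst = build_instrument(model, build_category_scheme(small_cohorts.female),
                                s0_curve=km_survival(small_cohorts.female))
        assert inst.B == pytest.approx(model.beta("age") * 5.0)
        assert inst.factors[0].points == (0, 2, 4)  # two points per decade

    def test_doubling_b_halves_unrounded_points(self):
        scheme_defs = {"age": default_factor_definitions()["age"]}
        recs = [SurvivalRecord(f"P{a}", None, 1.0, False, {"age": float(a)})
                for a in range(61, 91)]
        scheme = build_category_scheme(recs, scheme_defs)
        model = _model({"age": 0.08}, {"age": 75.0})
        i1 = build_instrument(model, scheme, b=0.2, s0_curve=_flat_curve(), sex="t")
        i2 = build_instrument(model, scheme, b=0.4, s0_curve=_flat_curve(), sex="t")
        # unrounded D/B halves; on these values the rounded points halve too
        assert tuple(p // 2 for p in i1.factors[0].points) == i2.factors[0].points

    def test_nonpositive_b_rejected(self, small_cohorts):
        model = fit_cox(small_cohorts.male, ["age", "apoe4", "mmse_le26", "cdr05"])
        scheme = build_category_scheme(small_cohorts.male)
        with pytest.raises(ParameterError):
            build_instrument(model, scheme, b=-0.1,
                             s0_curve=km_survival(small_cohorts.male))

    def test_horizon_beyond_follow_up_rejected(self, small_cohorts):
        model = fit_cox(small_cohorts.male, ["age", "apoe4", "mmse_le26", "cdr05"])
        scheme = build_category_scheme(small_cohorts.male)
        with pytest.raises(ExtrapolationError):
            build_instrument(model, scheme, horizon=50.0,
                             s0_curve=km_survival(small_cohorts.male))


class TestAbsoluteRisk:
    def test_zero_exponent_recovers_one_minus_s0(self):
        inst = Instrument(
            sex="t", factors=(), B=1.0, bands=(),
            risk_params=RiskParams(s0=0.8, horizon=12.0, offset=0.0, ref_term=0.0),
        )
        assert absolute_risk(0, inst) == pytest.approx(0.2, abs=1e-15)

    def test_monotone_in_total_points(self, small_cohorts):
        model = fit_cox(small_cohorts.female, ["age", "apoe4", "mmse_le26", "cdr05"])
        inst = build_instrument(model, build_category_scheme(small_cohorts.female),
                                s0_curve=km_survival(small_cohorts.female), sex="female")
        risks = [absolute_risk(t, inst) for t in range(inst.min_score, inst.max_score + 1)]
        assert np.all(np.diff(risks) > 0)
        assert all(0 <= r < 1 for r in risks)

    def test_unrounded_score_equals_direct_cox_prediction(self, small_cohorts):
        """Algebraic identity: at the exact score Σβᵢ(xᵢ−W_iREF)/B, the banded
        risk map reproduces 1 − S0^exp(Σβᵢ(xᵢ−Mᵢ)) to numerical precision."""
        covs = ["age", "apoe4", "mmse_le26", "cdr05"]
        model = fit_cox(small_cohorts.female, covs)
        scheme = build_category_scheme(small_cohorts.female)
        curve = km_survival(small_cohorts.female)
        inst = build_instrument(model, scheme, s0_curve=curve, sex="female")
        rng = np.random.default_rng(42)
        for _ in range(200):
            vals = {"age": rng.uniform(61, 90), "apoe4": float(rng.integers(2)),
                    "mmse_le26": float(rng.integers(2)), "cdr05": float(rng.integers(2))}
            unrounded = sum(model.beta(n) * (vals[n] - scheme[n].w_ref) for n in covs) / inst.B
            direct = 1 - inst.risk_params.s0 ** np.exp(model.linear_predictor(vals))
            assert absolute_risk(unrounded, inst) == pytest.approx(direct, abs=1e-10)

    def test_invariant_to_reference_category_shift(self, small_cohorts):
        """Moving a factor's reference value shifts the ref_term compensatingly,
        leaving the unrounded-score risk unchanged."""
        covs = ["age", "apoe4", "mmse_le26", "cdr05"]
        model = fit_cox(small_cohorts.male, covs)
        curve = km_survival(small_cohorts.male)
        scheme = build_category_scheme(small_cohorts.male)
        defs = default_factor_definitions()
        shifted_defs = dict(defs)
        shifted_defs["age"] = tuple(reversed(defs["age"]))  # oldest band as reference
        shifted = build_category_scheme(small_cohorts.male, shifted_defs)
        i1 = build_instrument(model, scheme, b=0.3, s0_curve=curve, sex="male")
        i2 = build_instrument(model, shifted, b=0.3, s0_curve=curve, sex="male")
        vals = {"age": 77.0, "apoe4": 1.0, "mmse_le26": 0.0, "cdr05": 1.0}
        u1 = sum(model.beta(n) * (vals[n] - scheme[n].w_ref) for n in covs) / 0.3
        u2 = sum(model.beta(n) * (vals[n] - shifted[n].w_ref) for n in covs) / 0.3
        assert absolute_risk(u1, i1) == pytest.approx(absolute_risk(u2, i2), abs=1e-12)

    def test_rounding_error_bounded_by_half_point_per_factor(self, small_cohorts):
        covs = ["age", "apoe4", "mmse_le26", "cdr05"]
        model = fit_cox(small_cohorts.female, covs)
        scheme = build_category_scheme(small_cohorts.female)
        inst = build_instrument(model, scheme, s0_curve=km_survival(small_cohorts.female))
        k = len(inst.factors)
        for combo_vals in ({"age": 75.5, "apoe4": 1.0, "mmse_le26": 1.0, "cdr05": 0.0},
                           {"age": 85.5, "apoe4": 0.0, "mmse_le26": 0.0, "cdr05": 1.0}):
            idxs = {n: scheme[n].assign(combo_vals[n]) for n in covs}
            unrounded = sum(
                model.beta(n) * (scheme[n].w[idxs[n]] - scheme[n].w_ref) for n in covs
            ) / inst.B
            rounded = sum(f.points[idxs[f.name]] for f in inst.factors)
            assert abs(rounded - unrounded) <= 0.5 * k + 1e-9
            lo = absolute_risk(unrounded - 0.5 * k, inst)
            hi = absolute_risk(unrounded + 0.5 * k, inst)
            assert lo <= absolute_risk(rounded, inst) <= hi

    def test_missing_risk_parameters_raise(self):
        female, _ = published_instruments()
        with pytest.raises(RiskParametersUnavailableError):
            absolute_risk(5, female)


class TestPublishedInstruments:
    def test_female_cdr_half_point_value(self):
        female, _ = published_instruments()
        cdr = next(f for f in female.factors if f.name == "cdr05")
        assert cdr.points == (0, 14)

    def test_male_mmse_and_apoe_points(self):
        _, male = published_instruments()
        points = {f.name: f.points for f in male.factors}
        assert points["mmse_le26"] == (0, 5)
        assert points["apoe4"] == (0, 3)

    def test_age_band_points_shared_by_sexes(self):
        female, male = published_instruments()
        assert next(f for f in female.factors if f.name == "age").points == (0, 2, 4)
        assert next(f for f in male.factors if f.name == "age").points == (0, 2, 4)

    def test_band_lookup_partitions_score_range(self):
        for inst in published_instruments():
            for total in range(inst.min_score, inst.max_score + 1):
                assert sum(b.contains(total) for b in inst.bands) == 1

    def test_json_round_trip(self, tmp_path):
        female, _ = published_instruments()
        path = tmp_path / "inst.json"
        female.to_json(path)
        back = Instrument.from_json(path)
        assert back.to_dict() == female.to_dict()


class TestApplyInstrument:
    def test_lowest_risk_female_profile(self):
        female, _ = published_instruments()
        pred = apply_instrument(_prof(age=65, apoe=False, mmse=29, cdr=0.0), female)
        assert pred.total == 0 and pred.band == "<=10%"

    def test_highest_risk_female_profile(self):
        female, _ = published_instruments()
        pred = apply_instrument(_prof(age=85, apoe=True, mmse=25, cdr=0.5), female)
        assert pred.total == 21 and pred.band == ">50%"

    def test_mid_risk_male_profile(self):
        _, male = published_instruments()
        pred = apply_instrument(_prof(sex="male", age=75, apoe=True, mmse=27), male)
        assert pred.total == 5 and pred.band == "<=10%"

    def test_total_is_sum_of_factor_points(self):
        female, _ = published_instruments()
        pred = apply_instrument(_prof(age=72, apoe=True, mmse=26, cdr=0.5), female)
        assert pred.total == sum(pred.points.values()) == 2 + 2 + 1 + 14

    @pytest.mark.parametrize("age", [59, 95])
    def test_age_out_of_range_rejected(self, age):
        female, _ = published_instruments()
        with pytest.raises(OutOfRangeError):
            apply_instrument(_prof(age=age), female)

    def test_cdr_above_half_rejected(self):
        female, _ = published_instruments()
        with pytest.raises(UnsupportedCategoryError):
            apply_instrument(_prof(cdr=1.0), female)

    def test_missing_required_field_rejected(self):
        female, _ = published_instruments()
        prof = BaselineProfile(participant_id="X", sex="female", age=70, mmse=29,
                               cdr_global=0.0, apoe4_carrier=None)
        with pytest.raises(MissingFieldError):
            apply_instrument(prof, female)

    def test_cutoff_sets_high_risk_flag(self):
        _, male = published_instruments()
        pred = apply_instrument(_prof(sex="male", age=85, apoe=True, mmse=25, cdr=0.5),
                                male, cutoff=12)
        assert pred.total == 21 and pred.high_risk is True


class TestRiskGrid:
    def test_grid_has_24_cells_per_sex(self):
        for inst in published_instruments():
            assert len(risk_grid(inst)) == 24

    def test_grid_totals_monotone_in_each_factor(self):
        for inst in published_instruments():
            grid = risk_grid(inst)
            for f in inst.factors:
                others = [g.name for g in inst.factors if g.name != f.name]
                for _, sub in grid.groupby(others):
                    ordered = sub.sort_values(f"{f.name}_points")
                    assert ordered.total.is_monotonic_increasing

    def test_grid_maxima_match_column_sums(self):
        female, male = published_instruments()
        assert risk_grid(female).total.max() == 21
        assert risk_grid(male).total.max() == 21

    def test_grid_totals_agree_with_apply_instrument(self, fixtures):
        for sex, inst in zip(("female", "male"), published_instruments()):
            grid = risk_grid(inst)
            profiles = fixtures["grid_profiles"][sex]
            scored = sorted(apply_instrument(p, inst).total for p in profiles)
            assert scored == sorted(grid.total)

    def test_bands_cover_achievable_scores(self, small_cohorts):
        model = fit_cox(small_cohorts.female, ["age", "apoe4", "mmse_le26", "cdr05"])
        inst = build_instrument(model, build_category_scheme(small_cohorts.female),
                                s0_curve=km_survival(small_cohorts.female), sex="female")
        for total in range(inst.min_score, inst.max_score + 1):
            assert sum(b.contains(total) for b in inst.bands) == 1
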
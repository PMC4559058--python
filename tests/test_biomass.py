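import numpy as np
import pandas as pd
import pytest

from grainbeta.biomass import (
    AllometryModel,
    counts_to_biomass,
    fit_allometry,
    mean_measured_weight,
    resolve_weights,
    split_column,
)
from grainbeta.community import AbundanceMatrix, ValidationError, validate_species_traits


def make_traits(rows):
    return validate_species_traits(pd.DataFrame(rows, columns=[
        "species_id", "subfamily", "caste", "dimension_type", "dimension_mm",
        "dry_weights_mg",
    ]))


def trait_row(sp, weights, dim=1.0, caste="none", subfamily="Myrmicinae",
              dim_type="pronotum_width"):
    return (sp, subfamily, caste, dim_type, dim, weights)


class TestMeanMeasuredWeight:
    def test_mean_of_three_specimens(self):
        traits = make_traits([trait_row("sp1", [1.0, 2.0, 3.0])])
        w = mean_measured_weight(traits, "sp1")
        assert w.mean_weight_mg == pytest.approx(2.0)
        assert w.source == "measured"

    def test_two_specimens_is_absent(self):
        traits = make_traits([trait_row("sp1", [1.0, 2.0])])
        assert mean_measured_weight(traits, "sp1") is None

    def test_equal_weights_identity(self):
        traits = make_traits([trait_row("sp1", [0.7, 0.7, 0.7, 0.7])])
        assert mean_measured_weight(traits, "sp1").mean_weight_mg == pytest.approx(0.7)

    def test_castes_resolved_separately(self):
        traits = make_traits([
            trait_row("sp1", [1.0, 1.0, 1.0], caste="major"),
            trait_row("sp1", [0.2, 0.2, 0.2], caste="minor"),
        ])
        assert mean_measured_weight(traits, "sp1", "major").mean_weight_mg == 1.0
        assert mean_measured_weight(traits, "sp1", "minor").mean_weight_mg == pytest.approx(0.2)


class TestFitAllometry:
    def test_noiseless_power_law_recovered_exactly(self):
        # W = 2 * L^3 in log-log space: slope 3, intercept log 2
        lengths = [0.5, 0.8, 1.3, 2.1]
        rows = [
            trait_row(f"sp{i}", [2 * L**3] * 3, dim=L) for i, L in enumerate(lengths)
        ]
        models = fit_allometry(make_traits(rows))
        m = models["pronotum_width"]
        assert m.slope == pytest.approx(3.0, abs=1e-9)
        assert m.intercept == pytest.approx(np.log(2.0), abs=1e-9)
        assert m.predict(1.7) == pytest.approx(2 * 1.7**3, rel=1e-9)

    def test_single_point_group_errors(self):
        with pytest.raises(ValidationError, match="pronotum_width"):
            fit_allometry(make_traits([trait_row("sp1", [1.0, 1.0, 1.0])]))

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(5)
        lengths = rng.uniform(0.4, 2.5, size=6)
        weights = 0.8 * lengths**2.6 * np.exp(rng.normal(0, 0.2, 6))
        rows = [
            trait_row(f"sp{i}", [w] * 3, dim=L)
            for i, (L, w) in enumerate(zip(lengths, weights))
        ]
        m = fit_allometry(make_traits(rows))["pronotum_width"]
        X = np.column_stack([np.ones(6), np.log(lengths)])
        y = np.log(weights)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert m.intercept == pytest.approx(beta[0], abs=1e-9)
        assert m.slope == pytest.approx(beta[1], abs=1e-9)

    def test_duplicated_point_changes_fit_unless_on_line(self):
        lengths = np.array([0.5, 1.0, 2.0])
        on_line = 2 * lengths**3
        rows = [trait_row(f"sp{i}", [w] * 3, dim=L) for i, (L, w) in enumerate(zip(lengths, on_line))]
        base = fit_allometry(make_traits(rows))["pronotum_width"]
        dup_on = rows + [trait_row("dup", [on_line[1]] * 3, dim=lengths[1])]
        m_on = fit_allometry(make_traits(dup_on))["pronotum_width"]
        assert (m_on.slope, m_on.intercept) == pytest.approx(
            (base.slope, base.intercept), abs=1e-9
        )
        off = rows + [trait_row("dup", [10 * on_line[1]] * 3, dim=lengths[1])]
        m_off = fit_allometry(make_traits(off))["pronotum_width"]
        assert abs(m_off.intercept - base.intercept) > 1e-3

    def test_predictions_positive_for_any_positive_dimension(self):
        m = AllometryModel("head_length", intercept=-2.0, slope=2.7, n_points=5,
                           residual_var=0.1)
        for dim in (1e-3, 0.5, 10.0):
            assert m.predict(dim) > 0


class TestCountsToBiomass:
    def test_simple_product(self):
        traits = make_traits([trait_row("sp1", [0.5, 0.5, 0.5])])
        m = AbundanceMatrix(pd.DataFrame({"sp1": [3]}, index=["u1"]), "count")
        out = counts_to_biomass(m, traits)
        assert out.value_kind == "biomass"
        assert out.values.tolist() == [[1.5]]

    def test_unit_weights_identity(self):
        traits = make_traits([
            trait_row("sp1", [1.0, 1.0, 1.0]),
            trait_row("sp2", [1.0, 1.0, 1.0]),
        ])
        m = AbundanceMatrix(
            pd.DataFrame({"sp1": [3, 1], "sp2": [2, 4]}, index=["u1", "u2"]), "count"
        )
        np.testing.assert_array_equal(counts_to_biomass(m, traits).values, m.values)

    def test_castes_summed_into_one_species_column(self):
        traits = make_traits([
            trait_row("sp1", [1.0, 1.0, 1.0], caste="major"),
            trait_row("sp1", [0.2, 0.2, 0.2], caste="minor"),
        ])
        m = AbundanceMatrix(
            pd.DataFrame({"sp1|major": [2], "sp1|minor": [10]}, index=["u1"]), "count"
        )
        out = counts_to_biomass(m, traits)
        assert out.species_ids == ["sp1"]
        assert out.values.tolist() == [[pytest.approx(4.0)]]

    def test_linearity_in_counts(self):
        traits = make_traits([
            trait_row("sp1", [0.3, 0.3, 0.3]),
            trait_row("sp2", [0.9, 0.9, 0.9]),
        ])
        base = pd.DataFrame({"sp1": [3, 1], "sp2": [2, 4]}, index=["u1", "u2"])
        b1 = counts_to_biomass(AbundanceMatrix(base, "count"), traits).values
        b3 = counts_to_biomass(AbundanceMatrix(base * 3, "count"), traits).values
        np.testing.assert_allclose(b3, 3 * b1)

    def test_unresolvable_species_listed(self):
        # one species measured, the other has neither >=3 weights nor dimension
        traits = make_traits([
            trait_row("good", [0.5, 0.5, 0.5]),
            trait_row("bad", [], dim=np.nan),
        ])
        m = AbundanceMatrix(pd.DataFrame({"good": [1], "bad": [2]}, index=["u1"]),
                            "count")
        with pytest.raises(ValidationError, match="bad"):
            counts_to_biomass(m, traits)

    def test_prediction_route_through_dimension_model(self):
        # sp_pred has only 2 specimens; prediction uses the fitted power law
        lengths = [0.5, 1.0, 2.0]
        rows = [
            trait_row(f"sp{i}", [2 * L**3] * 3, dim=L)
            for i, L in enumerate(lengths)
        ]
        rows.append(trait_row("sp_pred", [99.0, 99.0], dim=1.5))
        traits = make_traits(rows)
        weights = resolve_weights(traits)
        w = weights[("sp_pred", "none")]
        assert w.source == "predicted"
        assert w.mean_weight_mg == pytest.approx(2 * 1.5**3, rel=1e-9)

    def test_total_biomass_is_exact_sum_of_products(self):
        traits = make_traits([
            trait_row("sp1", [0.25, 0.25, 0.25]),
            trait_row("sp2", [1.5, 1.5, 1.5]),
        ])
        m = AbundanceMatrix(
            pd.DataFrame({"sp1": [7, 2], "sp2": [1, 5]}, index=["u1", "u2"]), "count"
        )
        out = counts_to_biomass(m, traits)
        assert out.values.sum() == pytest.approx(9 * 0.25 + 6 * 1.5, rel=1e-12)


def test_split_column():
    assert split_column("sp1") == ("sp1", "none")
    assert split_column("sp1|major") == ("sp1", "major")
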
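import pytest

import thermodev as td

# Mean immature durations of the packaged G. pyloalis table, used across
# the suite (reciprocals are the rates all models consume).
IMMATURE_DURATIONS = {16: 134.33, 20: 46.62, 24: 29.34, 28: 24.47, 30: 22.04, 32: 22.43}
EGG_DURATIONS = {20: 6.52, 24: 4.76, 28: 3.71, 30: 3.00}
LARVAE_DURATIONS = {20: 24.37, 24: 14.06, 28: 11.75, 30: 10.16}


@pytest.fixture(scope="session")
def example_table():
    return td.load_example_table()


@pytest.fixture(scope="session")
def immature_linear_points(example_table):
    """Immature rate points restricted to the linear range 20-30 degC."""
    points = td.compute_rates(example_table, "immature_total")
    return td.select_linear_range(
        points, example_table.survival_by_temp("immature_total")
    )


@pytest.fixture(scope="session")
def immature_curve_points(example_table):
    """Immature rate points over the nonlinear fitting range 20-32 degC."""
    return [
        p
        for p in td.compute_rates(example_table, "immature_total")
        if p.temperature_C >= 20
    ]


@pytest.fixture(scope="session")
def immature_briere2_fit(immature_curve_points):
    return td.ThermalCurveModel("briere2", immature_curve_points).fit()


@pytest.fixture(scope="session")
def immature_lactin2_fit(immature_curve_points):
    return td.ThermalCurveModel("lactin2", immature_curve_points).fit()


@pytest.fixture(scope="session")
def immature_analytis_fit(immature_curve_points):
    return td.ThermalCurveModel("analytis", immature_curve_points).fit()


@pytest.fixture(scope="session")
def immature_ssi_fit(immature_curve_points):
    return td.SSIModel(immature_curve_points).fit()
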
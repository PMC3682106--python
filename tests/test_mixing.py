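"""Mixing thermodynamics: ideal reference, excess area/enthalpy, miscibility."""

import dataclasses

import numpy as np
import pytest

from monofilm import (
    CompositionSeries,
    Isotherm,
    IsothermSpec,
    MixtureSpec,
    UNIT_FACTOR,
    analytic_excess_gibbs,
    area_of_pressure,
    assess_miscibility,
    describe,
    dg_vs_composition,
    excess_area_curve,
    excess_gibbs,
    generate_isotherm,
    generate_mixture_series,
    ideal_area,
)


# ---------------------------------------------------------------------------
# ideal mean area
# ---------------------------------------------------------------------------

def test_ideal_area_weighted_average():
    assert ideal_area((40.0, 60.0), (0.5, 0.5)) == pytest.approx(50.0)
    assert ideal_area((40.0, 60.0), (1.0, 0.0)) == pytest.approx(40.0)
    # brute-force dot product: 0.27*38 + 0.405*52 + 0.325*90 = 60.57
    assert ideal_area((38.0, 52.0, 90.0), (0.27, 0.405, 0.325)) == pytest.approx(60.57)


def test_ideal_area_dimension_mismatch():
    with pytest.raises(ValueError):
        ideal_area((40.0, 60.0), (0.3, 0.3, 0.4))
    with pytest.raises(ValueError):
        ideal_area((40.0, 60.0), (0.6, 0.6))


# ---------------------------------------------------------------------------
# excess free enthalpy
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def binary_specs():
    x_grid = tuple((1.0 - x, x) for x in (0.0, 0.1, 0.3, 0.5, 0.7, 0.9, 1.0))
    host = IsothermSpec("host", a_lift=60.0, a_coll=36.0, pi_coll=48.0, seed=1)
    probe = IsothermSpec("probe", a_lift=98.0, a_coll=32.0, pi_coll=40.0, seed=2)
    return host, probe, x_grid


def test_ideal_mixture_has_zero_excess(binary_specs):
    host, probe, grid = binary_specs
    spec = MixtureSpec("ideal", (host, probe), grid, interaction_beta=0.0, seed=5)
    series = generate_mixture_series(spec)
    for x in (0.1, 0.3, 0.5, 0.7, 0.9):
        prof = excess_gibbs(series, (1.0 - x, x), pi_max=30.0)
        assert abs(prof.dg_excess[-1]) < 1.0
        assert prof.dg_excess[0] == 0.0


def test_constant_negative_excess_area_rectangle(binary_specs):
    """A^exc ≡ −10 Å² up to 30 mN/m → ΔG^exc(30) = −10·30·6.02214076 J/mol."""
    host, probe, grid = binary_specs
    # pi_ref → ∞ freezes the pressure dependence; β·X₁X₂ = 10 at X = 0.5
    spec = MixtureSpec("rect", (host, probe), grid,
                       interaction_beta=40.0, pi_ref=1e9, seed=5)
    series = generate_mixture_series(spec)
    prof = excess_gibbs(series, (0.5, 0.5), pi_max=30.0)
    np.testing.assert_allclose(prof.a_excess[1:], -10.0, atol=1e-6)
    assert prof.dg_excess[-1] == pytest.approx(-10.0 * 30.0 * UNIT_FACTOR, abs=1e-3)


def test_trapezoid_matches_analytic_interaction_oracle(binary_specs):
    """β = 20, X = 0.5, π_ref = 30 → ΔG^exc(30) = −6.02214076·5·45 = −1355.0 J/mol."""
    host, probe, grid = binary_specs
    spec = MixtureSpec("attract", (host, probe), grid,
                       interaction_beta=20.0, pi_ref=30.0, seed=5)
    series = generate_mixture_series(spec)
    want = analytic_excess_gibbs(spec, (0.5, 0.5), 30.0)
    assert want == pytest.approx(-1354.98, abs=0.1)
    for x in (0.1, 0.5, 0.9):
        got = excess_gibbs(series, (1.0 - x, x), pi_max=30.0).dg_excess[-1]
        oracle = analytic_excess_gibbs(spec, (1.0 - x, x), 30.0)
        assert got == pytest.approx(oracle, rel=1e-3)


def test_dg_invariant_under_grid_refinement(binary_specs):
    host, probe, grid = binary_specs
    spec = MixtureSpec("attract", (host, probe), grid,
                       interaction_beta=20.0, pi_ref=30.0, seed=5)
    series = generate_mixture_series(spec)
    coarse = excess_gibbs(series, (0.5, 0.5), 30.0, grid_step=0.25).dg_excess[-1]
    fine = excess_gibbs(series, (0.5, 0.5), 30.0, grid_step=0.125).dg_excess[-1]
    assert fine == pytest.approx(coarse, rel=5e-4)


def test_excess_symmetric_under_component_swap(binary_specs):
    host, probe, grid = binary_specs
    spec = MixtureSpec("fwd", (host, probe), grid,
                       interaction_beta=20.0, pi_ref=30.0, seed=5)
    swapped = MixtureSpec("rev", (probe, host), tuple((x, h) for h, x in grid),
                          interaction_beta=20.0, pi_ref=30.0, seed=5)
    s1 = generate_mixture_series(spec)
    s2 = generate_mixture_series(swapped)
    p1 = excess_gibbs(s1, (0.7, 0.3), 30.0)
    p2 = excess_gibbs(s2, (0.3, 0.7), 30.0)
    np.testing.assert_allclose(p1.a_excess, p2.a_excess, atol=1e-6)
    np.testing.assert_allclose(p1.dg_excess, p2.dg_excess, atol=1e-3)


def test_range_error_names_limiting_isotherm(binary_specs):
    host, probe, grid = binary_specs
    spec = MixtureSpec("attract", (host, probe), grid, interaction_beta=20.0, seed=5)
    series = generate_mixture_series(spec)
    from monofilm import RangeError

    with pytest.raises(RangeError):
        excess_gibbs(series, (0.5, 0.5), pi_max=45.0)  # probe collapses at 40


def test_interaction_beta_recovered_from_dg_curve(binary_specs):
    """Fitting the ΔG^exc(X) curve returns the generator's β within 5 %."""
    host, probe, grid = binary_specs
    beta = 20.0
    spec = MixtureSpec("attract", (host, probe), grid,
                       interaction_beta=beta, pi_ref=30.0, seed=5)
    series = generate_mixture_series(spec)
    df = dg_vs_composition(series, pi=30.0)
    x = df["X"].to_numpy()
    design = -UNIT_FACTOR * (1.0 - x) * x * (30.0 + 30.0**2 / (2.0 * 30.0))
    beta_hat = float(np.linalg.lstsq(design[:, None], df["dG_exc"].to_numpy(), rcond=None)[0][0])
    assert beta_hat == pytest.approx(beta, rel=0.05)


# ---------------------------------------------------------------------------
# excess-area and ΔG-vs-composition tables
# ---------------------------------------------------------------------------

def test_excess_area_curve_signs_and_extremum(binary_specs):
    host, probe, grid = binary_specs
    ideal = generate_mixture_series(
        MixtureSpec("ideal", (host, probe), grid, interaction_beta=0.0, seed=5))
    attract = generate_mixture_series(
        MixtureSpec("attract", (host, probe), grid, interaction_beta=20.0, seed=5))
    repel = generate_mixture_series(
        MixtureSpec("repel", (host, probe), grid, interaction_beta=-20.0, seed=5))

    df0 = excess_area_curve(ideal, pi=20.0)
    assert np.all(np.abs(df0["A_exc"]) < 0.05)

    dfa = excess_area_curve(attract, pi=20.0)
    interior = dfa[(dfa.X > 0.0) & (dfa.X < 1.0)]
    assert np.all(interior["A_exc"] < 0.0)
    assert interior.loc[interior["A_exc"].idxmin(), "X"] == pytest.approx(0.5)

    dfr = excess_area_curve(repel, pi=20.0)
    interior = dfr[(dfr.X > 0.0) & (dfr.X < 1.0)]
    assert np.all(interior["A_exc"] > 0.0)


def test_dg_vs_composition_symmetric_minimum(binary_specs):
    """Attractive 1:1 interaction → ΔG^exc minimum at equimolar composition."""
    host, probe, grid = binary_specs
    series = generate_mixture_series(
        MixtureSpec("attract", (host, probe), grid, interaction_beta=20.0, seed=5))
    df = dg_vs_composition(series, pi=30.0)
    interior = df[(df.X > 0.0) & (df.X < 1.0)]
    assert interior.loc[interior["dG_exc"].idxmin(), "X"] == pytest.approx(0.5)


def test_ternary_membrane_contrast(library):
    """Repulsive chol/DPPC/APC → ΔG^exc > 0; attractive chol/POPC/APC → < 0."""
    normal = generate_mixture_series(
        dataclasses.replace(library["normal_membrane"], noise_sd_pi=0.0))
    tumor = generate_mixture_series(
        dataclasses.replace(library["tumor_membrane"], noise_sd_pi=0.0))
    for series, sign in ((normal, +1), (tumor, -1)):
        df = dg_vs_composition(series, pi=30.0)
        interior = df[(df.X > 0.0) & (df.X < 1.0)]
        assert np.all(sign * interior["dG_exc"] > 0.0)
        # pseudo-binary reference (probe vs intact host film) agrees in sign
        df2 = dg_vs_composition(series, pi=30.0, reference="pseudo_binary")
        interior2 = df2[(df2.X > 0.0) & (df2.X < 1.0)]
        assert np.all(sign * interior2["dG_exc"] > 0.0)


# ---------------------------------------------------------------------------
# miscibility
# ---------------------------------------------------------------------------

def _collapse_series(pi_colls: dict, pure_probe_pi=38.0, pure_host_pi=44.0):
    """Series whose mixed films collapse at prescribed pressures per X."""
    host = generate_isotherm(
        IsothermSpec("host", a_lift=45.0, a_coll=38.0, pi_coll=pure_host_pi, seed=11))
    probe = generate_isotherm(
        IsothermSpec("probe", a_lift=70.0, a_coll=28.0, pi_coll=pure_probe_pi, seed=12))
    mixed = []
    for x, pi_c in pi_colls.items():
        spec = IsothermSpec(f"mix{x}", a_lift=70.0 - 20.0 * x, a_coll=30.0,
                            pi_coll=pi_c, seed=int(100 * x))
        iso = generate_isotherm(spec)
        mixed.append(Isotherm(area=iso.area, pressure=iso.pressure,
                              components=("host", "probe"),
                              mole_fractions=(1.0 - x, x), label=f"X={x}"))
    series = CompositionSeries("test system", ("host", "probe"), (host, probe), mixed)
    descs = [describe(iso) for iso in (host, probe)] + [describe(m) for m in mixed]
    return series, descs


def test_constant_collapse_run_is_immiscible():
    """π_coll pinned at the pure-probe value for X ≥ 0.7 → immiscible there,
    varying below → miscible."""
    series, descs = _collapse_series({0.1: 43.0, 0.3: 41.5, 0.5: 40.0, 0.7: 38.0, 0.9: 38.0})
    report = assess_miscibility(series, descs)
    by_x = {e.x: e.classification for e in report.entries}
    assert by_x[0.7] == "immiscible"
    assert by_x[0.9] == "immiscible"
    assert by_x[0.3] == "miscible"
    assert by_x[0.5] == "miscible"
    assert report.immiscible_range() == (0.7, 0.9)


def test_two_collapse_film_is_immiscible():
    series, descs = _collapse_series({0.5: 40.0, 0.9: 38.0})
    two = generate_isotherm(
        IsothermSpec("mix07", a_lift=60.0, a_coll=30.0, pi_coll=38.0,
                     second_collapse=53.0, seed=70))
    series.mixed_isotherms.append(
        Isotherm(area=two.area, pressure=two.pressure, components=("host", "probe"),
                 mole_fractions=(0.3, 0.7), label="X=0.7"))
    descs.append(describe(series.mixed_isotherms[-1]))
    report = assess_miscibility(series, descs)
    entry = next(e for e in report.entries if e.x == 0.7)
    assert entry.classification == "immiscible"
    assert len(entry.collapse_pressures) == 2
    assert "ejection" in entry.rationale


def test_linearly_varying_collapse_is_miscible():
    pis = {0.1: 43.4, 0.3: 41.4, 0.5: 39.5, 0.7: 36.0, 0.9: 33.0}
    series, descs = _collapse_series(pis, pure_probe_pi=31.0, pure_host_pi=44.0)
    report = assess_miscibility(series, descs)
    assert all(e.classification == "miscible" for e in report.entries)


def test_truncated_film_is_partial():
    series, descs = _collapse_series({0.1: 43.0, 0.5: 40.0})
    spec = IsothermSpec("mix09", a_lift=55.0, a_coll=30.0, pi_coll=60.0, seed=90)
    pi = np.linspace(0.0, 45.0, 300)  # barrier range ends before the collapse
    iso = Isotherm(area=np.asarray(area_of_pressure(spec, pi)), pressure=pi,
                   components=("host", "probe"), mole_fractions=(0.1, 0.9), label="X=0.9")
    series.mixed_isotherms.append(iso)
    descs.append(describe(iso))
    report = assess_miscibility(series, descs)
    entry = next(e for e in report.entries if e.x == 0.9)
    assert entry.classification == "partial"
    assert "barrier" in entry.rationale


def test_missing_pure_collapse_is_an_error():
    series, descs = _collapse_series({0.5: 40.0})
    descs[0].collapses = []  # strip the host's collapse
    with pytest.raises(ValueError, match="no detected collapse"):
        assess_miscibility(series, descs)
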
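"""Preprocessing, balance-system assembly, fitting, AIC and summaries."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize

from epimech.errors import (
    DegenerateGeometryError,
    DomainError,
    EmptySystemError,
    PerfectFitError,
)
from epimech.estimation import (
    PreprocessConfig,
    aic,
    assemble_balance_system,
    estimate,
    fit,
    model_select,
    normalize_estimates,
    preprocess,
    recovered_parameters,
    standard_errors,
    tension_anisotropy,
)
from epimech.experiments import (
    generator_params,
    reference_sim_config,
    sim_preprocess_config,
)
from epimech.mesh import classify_vertices
from epimech.models import ModelSpec, ParameterSet, all_aniso_spring_specs
from epimech.simulator import forces, simulate_dataset

from conftest import build_tissue, hexagon_lattice, square_grid


def _row_of_widths(widths):
    """One row of unit-height rectangular cells with the given widths."""
    xs = np.concatenate([[0.0], np.cumsum(widths)])
    coords = [(x, 0.0) for x in xs] + [(x, 1.0) for x in xs]
    nb = len(xs)
    loops = [[i, i + 1, nb + i + 1, nb + i] for i in range(len(widths))]
    return build_tissue(coords, loops)


class TestPreprocess:
    def test_short_junction_excluded(self):
        t = _row_of_widths([1.0, 0.002, 1.0])
        pre, rep = preprocess(t, PreprocessConfig(min_junction_length=0.05,
                                                  normalize=False))
        short = [j for j in t.junctions if t.junction_length(j) < 0.05]
        assert set(short) == rep.excluded_junctions != set()

    def test_giant_cell_excluded(self):
        t = _row_of_widths([1.0, 1.0, 1.0, 2.5])
        _, rep = preprocess(t, PreprocessConfig(min_junction_length=0.01,
                                                normalize=False))
        areas = {c: t.cell_area(c) for c in t.cells}
        (big,) = [c for c, a in areas.items() if a == pytest.approx(2.5)]
        assert rep.excluded_cells == {big}  # 2 x median(1) = 2 < 2.5

    def test_normalization_halves_coordinates(self):
        t = square_grid(3, 3, size=2.0)  # every cell area 4
        pre, rep = preprocess(t, PreprocessConfig(min_junction_length=0.01))
        assert rep.scale == pytest.approx(2.0)
        for vid, v in t.vertices.items():
            assert pre.vertices[vid].x == pytest.approx(v.x / 2)
            assert pre.vertices[vid].y == pytest.approx(v.y / 2)

    def test_all_junctions_excluded_raises(self):
        t = square_grid(2, 2, size=0.01)
        with pytest.raises(EmptySystemError):
            preprocess(t, PreprocessConfig(min_junction_length=1.0))


class TestAssembly:
    def test_tension_coefficients_are_unit_vectors(self, small_sim_c):
        sim, cfg = small_sim_c
        pre, rep = preprocess(sim.tissue, sim_preprocess_config())
        sys = assemble_balance_system(pre, ModelSpec(variant="A"), rep)
        nj = len(sys.junction_ids)
        T_block = sys.C[:, :nj]
        for r in range(0, sys.n, 2):
            cols = np.flatnonzero(T_block[r] != 0)
            mags = T_block[r, cols] ** 2 + T_block[r + 1, cols] ** 2
            np.testing.assert_allclose(mags, 1.0, atol=1e-12)

    def test_pressure_columns_cancel_at_interior_vertices(self, small_sim_c):
        """For a vertex fully ringed by cells, the constant-pressure
        contributions form a closed loop and sum to exactly zero."""
        sim, cfg = small_sim_c
        pre, rep = preprocess(sim.tissue, sim_preprocess_config())
        sys = assemble_balance_system(pre, ModelSpec(variant="A"), rep)
        nj = len(sys.junction_ids)
        P_block = sys.C[:, nj:]
        kinds = classify_vertices(pre)
        for r, vid in enumerate(sys.row_vertices):
            assert kinds[vid] == "interior"
            assert P_block[2 * r].sum() == pytest.approx(0.0, abs=1e-12)
            assert P_block[2 * r + 1].sum() == pytest.approx(0.0, abs=1e-12)

    def test_rows_reproduce_simulator_forces(self, small_sim_c):
        """C X with the true tensions/pressures equals the simulator's net
        vertex forces (independent code paths for the same physics)."""
        sim, cfg = small_sim_c
        tissue = sim.tissue
        sys = assemble_balance_system(tissue, cfg.spec)
        from epimech.models import tension as tension_fn
        X = np.concatenate([
            [tension_fn(cfg.spec, cfg.params, tissue.junction_length(j),
                        tissue.junction_angle(j)) for j in sys.junction_ids],
            [-cfg.params.k * (tissue.cell_area(c) - cfg.params.A0)
             for c in sys.cell_ids],
        ])
        F = sys.C @ X
        f = forces(tissue, cfg.spec, cfg.params)
        for r, vid in enumerate(sys.row_vertices):
            np.testing.assert_allclose(F[2 * r: 2 * r + 2], f[vid], atol=1e-10)

    def test_hand_checked_pressure_coefficient(self):
        # vertex 4 of a 2x2 grid is interior; its coefficient for each cell
        # is the half cross-difference of the flanking loop vertices
        t = square_grid(2, 2)
        sys = assemble_balance_system(t, ModelSpec(variant="E"))
        assert sys.row_vertices == [4]
        nj = len(sys.junction_ids)
        # cell 0 has loop [0,1,4,3]: flanking vertices of 4 are 1 and 3
        # b = ((y3 - y1)/2, -(x3 - x1)/2) = (0.5, 0.5)
        c0 = sys.cell_ids.index(0)
        assert sys.C[0, nj + c0] == pytest.approx(0.5)
        assert sys.C[1, nj + c0] == pytest.approx(0.5)


class TestAic:
    def test_log_term_vanishes(self):
        assert aic(1 / (2 * math.pi), 2, 1) == pytest.approx(6.0)

    def test_n_only(self):
        assert aic(1 / (2 * math.pi), 10, 0) == pytest.approx(12.0)

    def test_linear_in_p(self):
        s, n = 0.3, 50
        assert aic(s, n, 5) - aic(s, n, 3) == pytest.approx(4.0)

    def test_perfect_fit_guard(self):
        with pytest.raises(PerfectFitError):
            aic(0.0, 10, 2)


class TestFit:
    def test_recovery_on_isotropic_equilibrium_with_full_model(self, small_sim_c):
        """Fitting the full model A to model-C data finds ~zero anisotropy."""
        sim, cfg = small_sim_c
        f, rep = estimate(sim.tissue, ModelSpec(variant="A"),
                          sim_preprocess_config())
        assert f.params.mu0 < 0.05
        assert f.sigma2 < 1e-4
        est = recovered_parameters(f, rep, 1.0)
        truth = generator_params("C")
        assert est["lambda0"] == pytest.approx(truth.lambda0 / truth.k, rel=0.05)
        assert est["lambda1"] == pytest.approx(truth.lambda1 / truth.k, rel=0.10)

    def test_regular_hexagon_lattice_is_degenerate(self):
        t = hexagon_lattice(4, 4)
        with pytest.raises(DegenerateGeometryError):
            fit(t, ModelSpec(variant="A"))

    def test_closed_form_matches_numerical_minimizer(self, small_sim_c):
        """The linear-algebra solution equals brute-force minimization of
        ||F||^2 over the free coefficients."""
        sim, cfg = small_sim_c
        pre, rep = preprocess(sim.tissue, sim_preprocess_config())
        spec = ModelSpec(variant="C")
        sys = assemble_balance_system(pre, spec, rep)
        f = fit(pre, spec, exclusions=rep)
        y, A = sys.M[:, 0], sys.M[:, 1:]
        res = minimize(lambda b: np.sum((y + A @ b) ** 2), np.zeros(A.shape[1]),
                       method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000})
        free = list(spec.tension_columns[1:]) + ["k"]
        beta_pkg = np.array([f.coefficients[c] for c in free])
        np.testing.assert_allclose(beta_pkg, res.x, atol=1e-6)
        assert np.sum((y + A @ beta_pkg) ** 2) <= res.fun + 1e-10

    def test_predicted_values_reproduce_model_functions(self, small_sim_c):
        sim, cfg = small_sim_c
        spec = ModelSpec(variant="B")
        f, rep = estimate(sim.tissue, spec, sim_preprocess_config())
        pre, _ = preprocess(sim.tissue, sim_preprocess_config())
        from epimech.models import pressure as pressure_fn
        from epimech.models import tension as tension_fn
        for j, that in list(f.predicted_tensions.items())[:20]:
            l = pre.junction_length(j)
            th = pre.junction_angle(j)
            assert that == pytest.approx(
                tension_fn(spec, f.params, l, th), rel=1e-9)
        for c, phat in list(f.predicted_pressures.items())[:20]:
            A = pre.cell_area(c)
            assert phat == pytest.approx(
                pressure_fn(spec, f.params, A), rel=1e-9)

    def test_scale_invariance_of_normalized_estimates(self, small_sim_c):
        sim, cfg = small_sim_c
        spec = ModelSpec(variant="C")
        f1, rep1 = estimate(sim.tissue, spec, sim_preprocess_config())
        scaled = sim.tissue.scaled(3.0)
        cfg3 = PreprocessConfig(min_junction_length=3 * 0.05)
        f2, rep2 = estimate(scaled, spec, cfg3)
        e1 = recovered_parameters(f1, rep1, 1.0)
        e2 = recovered_parameters(f2, rep2, 9.0)  # A0 scales with area
        for key in e1:
            assert e1[key] == pytest.approx(e2[key], rel=1e-9, abs=1e-12)


class TestModelSelect:
    def test_single_candidate(self, small_sim_c):
        sim, cfg = small_sim_c
        pre, rep = preprocess(sim.tissue, sim_preprocess_config())
        best, table = model_select(pre, [ModelSpec(variant="C")], exclusions=rep)
        assert best.variant == "C" and len(table) == 1

    def test_generating_model_selected(self, small_sim_c):
        sim, cfg = small_sim_c
        pre, rep = preprocess(sim.tissue, sim_preprocess_config())
        best, table = model_select(pre, all_aniso_spring_specs(), exclusions=rep)
        assert best.variant == "C"
        assert len(table) == 5

    def test_nested_sigma2_ordering(self, small_sim_c):
        """A richer nested model never fits worse in sigma^2."""
        sim, cfg = small_sim_c
        pre, rep = preprocess(sim.tissue, sim_preprocess_config())
        _, table = model_select(pre, all_aniso_spring_specs(), exclusions=rep)
        s = {r["spec"].variant: r["sigma2"] for r in table if r["fit"]}
        tol = 1e-12
        assert s["A"] <= s["B"] + tol <= s["C"] + 2 * tol
        assert s["B"] <= s["D"] + tol  # B nests D? no: B has lambda1, D does not
        assert s["A"] <= s["D"] + tol and s["C"] <= s["E"] + tol


class TestAnisotropySummary:
    def test_constant_tension_gives_zero(self, rng):
        th = rng.uniform(0, math.pi, 500)
        res = tension_anisotropy(np.full(500, 2.0), th)
        assert res.R_T == pytest.approx(0.0, abs=1e-12)

    def test_cos2theta_profile(self):
        """T = 1 + cos 2theta over uniform angles: the defining averages give
        R_T -> 0.5 and Theta -> 0 (quadrature oracle on a fine grid)."""
        th = np.linspace(0, math.pi, 20001)[:-1]
        T = 1.0 + np.cos(2 * th)
        res = tension_anisotropy(T, th)
        assert res.R_T == pytest.approx(0.5, abs=1e-6)
        assert min(res.Theta, math.pi - res.Theta) == pytest.approx(0.0, abs=1e-6)

    def test_rotation_equivariance(self, rng):
        th = rng.uniform(0, math.pi, 300)
        T = 1.0 + 0.4 * np.cos(2 * (th - 0.6))
        base = tension_anisotropy(T, th)
        delta = 0.37
        rot = tension_anisotropy(T, th + delta)
        assert rot.R_T == pytest.approx(base.R_T, rel=1e-12)
        assert rot.Theta == pytest.approx((base.Theta + delta) % math.pi, abs=1e-9)

    def test_empty_input(self):
        with pytest.raises(DomainError):
            tension_anisotropy([], [])


class TestStandardErrors:
    def test_near_zero_on_clean_equilibrium(self, small_sim_c):
        sim, cfg = small_sim_c
        f, rep = estimate(sim.tissue, ModelSpec(variant="C"),
                          sim_preprocess_config())
        assert f.standard_errors is not None
        assert f.standard_errors["lambda1"] < 0.05 * abs(f.coefficients["lambda1"])

    def test_row_duplication_scales_se(self, small_sim_c):
        """Duplicating every equation leaves the estimate unchanged and
        shrinks SEs by sqrt(2) (sigma^2 unchanged, A'A doubled)."""
        sim, cfg = small_sim_c
        pre, rep = preprocess(sim.tissue, sim_preprocess_config())
        spec = ModelSpec(variant="C")
        sys = assemble_balance_system(pre, spec, rep)
        f1 = fit(pre, spec, exclusions=rep, system=sys)
        import dataclasses
        sys2 = dataclasses.replace(
            sys,
            C=np.vstack([sys.C, sys.C]),
            M=np.vstack([sys.M, sys.M]),
        )
        f2 = fit(pre, spec, exclusions=rep, system=sys2)
        for c in ("lambda1", "k"):
            assert f2.coefficients[c] == pytest.approx(f1.coefficients[c], rel=1e-9)
            assert f2.standard_errors[c] == pytest.approx(
                f1.standard_errors[c] / math.sqrt(2), rel=1e-6)


class TestNormalization:
    @pytest.mark.parametrize("coef, k_hat, A0, expected", [
        ("lambda0", 1.0, 1.0, 0.2),
        ("lambda1", 2.0, 1.0, 0.03),
        ("lambda0", 1.0, 4.0, 1.0),
    ])
    def test_formulas(self, coef, k_hat, A0, expected, small_sim_c):
        sim, cfg = small_sim_c
        f, _ = estimate(sim.tissue, ModelSpec(variant="C"),
                        sim_preprocess_config())
        f.coefficients["lambda0"] = {"lambda0": 0.2, "lambda1": 0.2}[coef]
        if coef == "lambda0" and A0 == 4.0:
            f.coefficients["lambda0"] = 8.0
        if coef == "lambda1":
            f.coefficients["lambda1"] = 0.06
        out = normalize_estimates(f, k_hat, A0)
        assert out[coef] == pytest.approx(expected)

    def test_domain_guards(self, small_sim_c):
        sim, cfg = small_sim_c
        f, _ = estimate(sim.tissue, ModelSpec(variant="C"),
                        sim_preprocess_config())
        with pytest.raises(DomainError):
            normalize_estimates(f, -1.0, 1.0)
        with pytest.raises(DomainError):
            normalize_estimates(f, 1.0, 0.0)
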
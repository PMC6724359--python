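"""Conformal-contact criterion, bending stiffness, fits and integrals."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shemon.contact_mech import (LaminateStack, SkinModel, classify_elastomers,
                                 critical_adhesion,
                                 effective_bending_stiffness, peel_energy,
                                 sag_amplitude, work_of_adhesion_intercept)

SKIN = SkinModel()


class TestBendingStiffness:
    def test_single_layer_closed_form(self):
        E, t = 2.5e9, 1e-6
        st_ = LaminateStack([("PI", t, E)])
        assert effective_bending_stiffness(st_) == pytest.approx(
            E * t ** 3 / 12, rel=1e-12)

    def test_two_identical_layers(self):
        E, t = 2.5e9, 1e-6
        st_ = LaminateStack([("a", t, E), ("b", t, E)])
        assert effective_bending_stiffness(st_) == pytest.approx(
            E * (2 * t) ** 3 / 12, rel=1e-12)

    def test_four_layer_stack_vs_numerical_integration(self):
        stack = LaminateStack([("Au", 0.2e-6, 79e9), ("Cr", 0.01e-6, 279e9),
                               ("PI", 1.0e-6, 2.5e9),
                               ("elastomer", 500e-6, 30e3)])
        # brute-force: integrate E(y) (y - ybar)^2 dy on a fine grid
        edges = np.cumsum([0] + [t for _, t, _ in stack.layers])
        y = np.linspace(0, edges[-1], 2_000_001)
        E = np.zeros_like(y)
        for (name, t, Ei), lo, hi in zip(stack.layers, edges, edges[1:]):
            E[(y >= lo) & (y <= hi)] = Ei
        ybar = np.trapezoid(E * y, y) / np.trapezoid(E, y)
        brute = np.trapezoid(E * (y - ybar) ** 2, y)
        assert effective_bending_stiffness(stack) == pytest.approx(
            brute, rel=1e-4)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(1e-6, 1e-4), st.floats(1e3, 1e11)),
                    min_size=1, max_size=5))
    def test_random_stacks_match_integration(self, layers):
        stack = LaminateStack([(f"l{i}", t, E)
                               for i, (t, E) in enumerate(layers)])
        edges = np.cumsum([0] + [t for _, t, _ in stack.layers])
        y = np.linspace(0, edges[-1], 400_001)
        E = np.zeros_like(y)
        for (name, t, Ei), lo, hi in zip(stack.layers, edges, edges[1:]):
            E[(y >= lo) & (y <= hi)] = Ei
        ybar = np.trapezoid(E * y, y) / np.trapezoid(E, y)
        brute = np.trapezoid(E * (y - ybar) ** 2, y)
        assert effective_bending_stiffness(stack) == pytest.approx(
            brute, rel=5e-3)

    def test_zero_thickness_rejected(self):
        with pytest.raises(ValueError):
            LaminateStack([("a", 0.0, 1e9)])


class TestSagAmplitude:
    def test_floppy_film_follows_skin(self):
        assert sag_amplitude(0.0, SKIN) == pytest.approx(SKIN.h_rough)

    def test_smooth_skin_no_sag(self):
        assert sag_amplitude(1e-9, SkinModel(h_rough=0.0)) == 0.0

    def test_half_amplitude_at_matched_stiffness(self):
        EI = SKIN.E_skin * SKIN.lambda_rough ** 3 / (16 * np.pi ** 3)
        assert sag_amplitude(EI, SKIN) == pytest.approx(SKIN.h_rough / 2,
                                                        rel=1e-12)

    def test_monotone_decreasing_and_bounded(self):
        EIs = np.logspace(-16, -4, 40)
        hs = np.array([sag_amplitude(ei, SKIN) for ei in EIs])
        assert (np.diff(hs) < 0).all()
        assert hs.min() >= 0 and hs.max() <= SKIN.h_rough


class TestCriticalAdhesion:
    STACK = LaminateStack([("Au", 0.2e-6, 79e9), ("Cr", 0.01e-6, 279e9),
                           ("PI", 1.0e-6, 2.5e9),
                           ("elastomer", 500e-6, 30e3)], alpha=0.3)

    def test_smooth_skin_zero(self):
        res = critical_adhesion(self.STACK, SkinModel(h_rough=0.0))
        assert res.gamma_crit == 0.0

    def test_areal_fraction_prefactor(self):
        r0 = critical_adhesion(LaminateStack(self.STACK.layers, alpha=0.0),
                               SKIN)
        r5 = critical_adhesion(LaminateStack(self.STACK.layers, alpha=0.5),
                               SKIN)
        assert r5.gamma_crit / r0.gamma_crit == pytest.approx(2.0, rel=1e-12)

    def test_matches_symbolic_evaluation(self):
        """Independent route: the same criterion evaluated symbolically."""
        sympy = pytest.importorskip("sympy")
        EI_s, E_s, lam_s, hr_s, al_s = sympy.symbols(
            "EI E lam hr al", positive=True)
        h_s = E_s * hr_s / (16 * sympy.pi ** 3 * EI_s / lam_s ** 3 + E_s)
        gamma_s = (sympy.pi ** 4 * EI_s * h_s ** 2 / lam_s ** 4
                   + sympy.pi * E_s * (hr_s - h_s) / (16 * lam_s)
                   * (1 + sympy.pi ** 2 * h_s ** 2 / (4 * lam_s ** 2))) \
            / (1 - al_s)
        EI = effective_bending_stiffness(self.STACK)
        expect = float(gamma_s.evalf(30, subs={
            EI_s: EI, E_s: SKIN.E_skin, lam_s: SKIN.lambda_rough,
            hr_s: SKIN.h_rough, al_s: self.STACK.alpha}))
        got = critical_adhesion(self.STACK, SKIN).gamma_crit
        assert got == pytest.approx(expect, rel=1e-9)

    def test_nondecreasing_in_roughness_amplitude(self):
        gs = [critical_adhesion(self.STACK, SkinModel(h_rough=h)).gamma_crit
              for h in np.linspace(0, 100e-6, 30)]
        assert all(b >= a for a, b in zip(gs, gs[1:]))

    def test_alpha_one_rejected(self):
        with pytest.raises(ValueError):
            LaminateStack(self.STACK.layers, alpha=1.0)


class TestClassifyElastomers:
    STACK = TestCriticalAdhesion.STACK
    # measured moduli of the five candidate substrates (Pa); adhesion values
    # are user-supplied plausible inputs (the measured ones are not public)
    CANDIDATES = [("PDMS", 1131.04e3, 0.05), ("Solaris", 251.53e3, 0.10),
                  ("Ecoflex0030", 32.23e3, 0.25), ("Ecoflex1:1", 11.17e3, 0.40),
                  ("Ecoflex1:2", 7.85e3, 0.50)]

    def test_margin_ordering_monotone(self):
        rows = classify_elastomers(self.CANDIDATES, self.STACK, SKIN)
        margins = [r["margin"] for r in rows]
        assert margins == sorted(margins)  # stiff/low-adhesion worst

    def test_boundary_case_is_nonconformal(self):
        gc = critical_adhesion(self.STACK, SKIN).gamma_crit
        # a candidate exactly at the critical value fails the strict test
        rows = classify_elastomers([("edge", 30e3, gc)], self.STACK, SKIN)
        assert rows[0]["conformal"] is False

    def test_any_candidate_conformal_on_smooth_skin(self):
        rows = classify_elastomers(self.CANDIDATES, self.STACK,
                                   SkinModel(h_rough=0.0))
        assert all(r["conformal"] for r in rows)

    def test_missing_gamma_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            rows = classify_elastomers([("x", 1e5, None)], self.STACK, SKIN)
        assert rows == []


class TestAdhesionFit:
    def test_exact_line(self):
        pts = [(v, 2.0 + 3.0 * v) for v in (0.1, 0.2, 0.3, 0.5)]
        g0, se = work_of_adhesion_intercept(pts)
        assert g0 == pytest.approx(2.0, abs=1e-12)

    def test_noisy_line_coverage(self):
        """Intercept within 2 SE of truth in >= 93/100 replicates."""
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(100):
            v = rng.uniform(0.05, 1.0, size=40)
            g = 2.0 + 3.0 * v + rng.normal(0, 0.1, size=40)
            g0, se = work_of_adhesion_intercept(np.column_stack([v, g]))
            hits += abs(g0 - 2.0) <= 2 * se
        assert hits >= 93

    def test_single_speed_rejected(self):
        with pytest.raises(ValueError):
            work_of_adhesion_intercept([(0.3, 1.0), (0.3, 1.2)])


class TestPeelEnergy:
    def test_triangle(self):
        pts = [(0.0, 0.0), (0.005, 1.0), (0.010, 0.0)]
        assert peel_energy(pts) == pytest.approx(5e-3, rel=1e-12)

    def test_zero_force(self):
        assert peel_energy([(0.0, 0.0), (0.01, 0.0)]) == 0.0

    def test_sine_bump_matches_closed_form(self):
        x = np.linspace(0, 0.01, 4001)
        f = np.sin(np.pi * x / 0.01)
        assert peel_energy(np.column_stack([x, f])) == pytest.approx(
            0.01 * 2 / np.pi, rel=1e-6)

    def test_nonmonotone_displacement_rejected(self):
        with pytest.raises(ValueError):
            peel_energy([(0.0, 0.0), (0.01, 1.0), (0.005, 0.0)])
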
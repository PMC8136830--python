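"""Figures of merit: FCA, logarithmic sensitivity, MDL, threshold, sweeps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circuitfca import (
    DoseResponse,
    HillPut,
    LinearCircuitParams,
    compute_fca,
    compute_mdl,
    compute_threshold,
    design_diagram,
    linear_dose_response,
    linear_optimal_fs,
    put_transfer,
    sensitivity_curve,
    sweep_fs,
)

BETA, N = 0.1, 1.5
S_MAX_CLOSED = N * (1 - np.sqrt(BETA)) / (1 + np.sqrt(BETA))
MDL_CLOSED = BETA ** (1 / (2 * N))


@pytest.fixture
def put_curve(put):
    u = np.geomspace(1e-3, 1e3, 601)
    return DoseResponse(u, put_transfer(u, put))


class TestFca:
    def test_span_ratio(self):
        dr = DoseResponse([1.0, 10.0, 100.0], [1.0, 5.0, 10.0])
        assert compute_fca(dr, floor=0.0) == pytest.approx(10.0)

    def test_constant_curve(self):
        dr = DoseResponse([1, 2, 3], [4.0, 4.0, 4.0])
        assert compute_fca(dr) == pytest.approx(1.0)

    def test_floor_rule(self):
        dr = DoseResponse([1, 2], [0.0, 1.0])
        assert compute_fca(dr, floor=1e-3) == pytest.approx(1000.0)

    def test_zero_off_and_zero_floor_undefined(self):
        dr = DoseResponse([1, 2], [0.0, 1.0])
        with pytest.raises(ZeroDivisionError):
            compute_fca(dr, floor=0.0)

    def test_extrema_mode_for_nonmonotone_curves(self):
        dr = DoseResponse([1, 2, 3], [2.0, 8.0, 4.0])
        assert compute_fca(dr, floor=0.0, mode="extrema") == pytest.approx(4.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(scale=st.floats(1e-3, 1e6))
    def test_invariant_under_output_rescaling(self, scale):
        out = np.array([0.5, 2.0, 5.0])
        fca = compute_fca(DoseResponse([1, 2, 3], out), floor=0.0)
        fca_scaled = compute_fca(DoseResponse([1, 2, 3], out * scale), floor=0.0)
        assert fca_scaled == pytest.approx(fca, rel=1e-12)


class TestSensitivity:
    def test_constant_curve_zero(self):
        u = np.geomspace(0.1, 10, 21)
        s = sensitivity_curve(DoseResponse(u, np.full_like(u, 3.0)))
        assert np.allclose(s, 0.0)

    def test_identity_unity(self):
        u = np.geomspace(0.1, 10, 21)
        s = sensitivity_curve(DoseResponse(u, u.copy()))
        assert np.allclose(s, 1.0, atol=1e-10)

    @pytest.mark.parametrize("k", [-1.5, 0.5, 2.0])
    def test_power_law_gain(self, k):
        u = np.geomspace(1e-2, 1e2, 51)
        s = sensitivity_curve(DoseResponse(u, 3.0 * u**k))
        assert np.allclose(s, k, atol=1e-8)

    def test_put_maximum_matches_closed_form(self, put_curve):
        assert sensitivity_curve(put_curve).max() == pytest.approx(S_MAX_CLOSED, rel=0.01)

    def test_nonpositive_output_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_curve(DoseResponse([1, 2, 3], [0.0, 1.0, 2.0]))


class TestMdlAndThreshold:
    def test_put_mdl_matches_closed_form(self, put_curve):
        step = (1e3 / 1e-3) ** (1 / 600)  # multiplicative grid step
        assert MDL_CLOSED / step <= compute_mdl(put_curve) <= MDL_CLOSED * step

    def test_constant_curve_ties_to_smallest_input(self):
        u = np.geomspace(0.1, 10, 11)
        assert compute_mdl(DoseResponse(u, np.full_like(u, 2.0))) == pytest.approx(u[0])

    def test_put_threshold_matches_closed_form(self, put_curve):
        # midpoint sqrt(beta) is crossed where u**n = sqrt(beta)
        assert compute_threshold(put_curve) == pytest.approx(MDL_CLOSED, rel=1e-3)

    def test_mdl_and_threshold_coincide_for_bare_put(self, put_curve):
        step = (1e3 / 1e-3) ** (1 / 600)
        mdl, th = compute_mdl(put_curve), compute_threshold(put_curve)
        assert th / step <= mdl <= th * step

    def test_two_point_step_interpolates(self):
        dr = DoseResponse([1.0, 100.0], [1.0, 100.0])
        # log-midpoint output 10 lies halfway in log space -> input 10
        assert compute_threshold(dr) == pytest.approx(10.0)

    def test_no_crossing_returns_nan(self):
        dr = DoseResponse([1, 2, 3], [5.0, 5.0, 5.0])
        assert np.isnan(compute_threshold(dr))


def _linear_factory(topology, beta, floor=1e-3, n=N):
    put = HillPut(beta=beta, n=n)

    def factory(fs):
        params = LinearCircuitParams(topology, fs, floor=floor)
        return lambda x: linear_dose_response(x, put, params)

    return factory


class TestSweep:
    def test_linear_dnf_fca_plateau(self):
        x = np.geomspace(1e-4, 1e4, 201)
        res = sweep_fs(_linear_factory("DNF", 0.1), np.linspace(0, 0.5, 51), x)
        plateau = res.fs_grid >= 0.1
        assert np.allclose(res.fca[plateau], 1000.0)
        assert np.all(np.diff(res.fca[~plateau]) >= -1e-9)

    def test_molecular_icf_fca_strictly_increasing(self, mol_defaults):
        from circuitfca import dose_response

        x = np.geomspace(1e-4, 1e6, 121)

        def factory(fs):
            return lambda xx: dose_response("ICF", mol_defaults.with_fs(fs), xx).outputs

        res = sweep_fs(factory, np.linspace(0, 5, 26), x, floor=0.0)
        assert np.all(np.diff(res.fca) > 0)

    def test_molecular_icf_mdl_nondecreasing(self, mol_defaults):
        from circuitfca import dose_response

        x = np.geomspace(1e-4, 1e6, 241)
        mdls = []
        for fs in [0.0, 1.0]:
            dr = dose_response("ICF", mol_defaults.with_fs(fs), x)
            mdls.append(compute_mdl(dr))
        assert mdls[1] >= mdls[0]

    def test_argmax_tie_breaks_toward_smaller_fs(self):
        res = sweep_fs(
            _linear_factory("DNF", 0.1),
            np.linspace(0.2, 0.5, 11),  # entirely on the plateau
            np.geomspace(1e-3, 1e3, 101),
        )
        assert res.argmax_fca == pytest.approx(0.2)

    def test_sensitivity_equal_across_topologies_at_matched_fraction(self):
        """Max sensitivity is topology-independent at half-optimal strength."""
        beta = 0.1
        x = np.geomspace(1e-4, 1e4, 2001)
        smax = {}
        for topo in ["OL", "ICF", "DNF"]:
            fs_star = linear_optimal_fs(topo, beta)
            fs = 0.5 * (fs_star if fs_star is not None else beta)
            out = _linear_factory(topo, beta, floor=0.0)(fs)(x)
            smax[topo] = sensitivity_curve(DoseResponse(x, out)).max()
        vals = list(smax.values())
        assert (max(vals) - min(vals)) / min(vals) < 0.02


class TestDesignDiagram:
    def _family(self, topology):
        def family(beta, fs):
            return _linear_factory(topology, beta)(fs)

        return family

    @pytest.mark.parametrize(
        "topology, formula",
        [("ICF", lambda b: b / (1 - b)), ("DNF", lambda b: b)],
    )
    def test_optimal_fca_boundary_tracks_formula(self, topology, formula):
        betas = [0.05, 0.1, 0.2]
        fs_grid = np.linspace(0.0, 0.5, 201)
        df = design_diagram(
            self._family(topology), betas, fs_grid, np.geomspace(1e-3, 1e3, 101)
        )
        step = fs_grid[1] - fs_grid[0]
        for b in betas:
            onset = df[(df.beta == b) & df.optimal_fca].fs.min()
            assert abs(onset - formula(b)) <= 2 * step

    def test_degenerate_delta_marks_everything_optimal(self):
        df = design_diagram(
            self._family("DNF"), [0.1], np.linspace(0, 0.3, 11),
            np.geomspace(1e-2, 1e2, 51), delta=1.0,
        )
        assert df.optimal_fca.all() and df.optimal_mdl.all()
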
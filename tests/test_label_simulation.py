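"""EMU decomposition, steady-state MIDs and the isotopomer oracle."""

import numpy as np
import pytest

from leakyflux.fluxes import FluxState
from leakyflux.label_simulation import (
    EMU,
    LabelInput,
    LabellingError,
    brute_force_isotopomer_oracle,
    emu_decompose,
    solve_steady_state_mids,
)
from leakyflux.network_model import parse_model
from leakyflux.synthetic_data import draw_random_fluxes, load_fixture_model

from conftest import pool_randomised_inputs


class TestDecomposition:
    def test_chain_full_emu_traces_to_source(self):
        m = parse_model("v1: A (ab) -> B (ab)\nv2: B (ab) -> C (ab)")
        net = emu_decompose(m, [EMU("B", (1, 2))])
        routes = net.nodes[EMU("B", (1, 2))]
        assert len(routes) == 1
        assert routes[0][1] == (EMU("A", (1, 2)),)
        assert EMU("A", (1, 2)) in net.inputs

    def test_single_atom_kept_through_cleavage(self):
        m = parse_model("v1: A (ab) -> C (a) + D (b)\nv2: C (a) -> E (a)")
        net = emu_decompose(m, [EMU("C", (1,))])
        assert net.nodes[EMU("C", (1,))][0][1] == (EMU("A", (1,)),)

    def test_condensation_creates_convolution(self):
        m = parse_model(
            "f1: X (a) -> A (a)\nf2: Y (b) -> B (b)\n"
            "cond: A (a) + B (b) -> C (ab)\nout: C (ab) -> P (ab)"
        )
        net = emu_decompose(m, [EMU("C", (1, 2))])
        routes = net.nodes[EMU("C", (1, 2))]
        assert len(routes) == 1
        assert set(routes[0][1]) == {EMU("A", (1,)), EMU("B", (1,))}

    def test_unproduced_target_errors(self):
        # B's only producer carries no atom maps (boundary feed), so its
        # labelling cannot be traced
        m = parse_model(
            "@source A\nv0: A (a) -> D (a)\nv1: A -> B\nv2: B (a) -> C (a)"
        )
        with pytest.raises(LabellingError, match="no producing"):
            emu_decompose(m, [EMU("B", (1,))])


class TestSteadyState:
    def test_pass_through_is_identity(self):
        m = parse_model("v1: A (abc) -> B (abc)\nv2: B (abc) -> C (abc)")
        inp = LabelInput.from_patterns(m, {"A": [(0.3, "U"), (0.7, "110")]})
        fs = FluxState({"v1": 1.0, "v2": 1.0})
        mids = solve_steady_state_mids(m, fs, inp, ["B"])
        np.testing.assert_allclose(
            mids[EMU("B", (1, 2, 3))], inp.emu_mid(EMU("A", (1, 2, 3))), atol=1e-12
        )

    def test_flux_weighted_mixing(self):
        m = parse_model(
            "v1: A (abc) -> X (abc)\nv2: B (abc) -> X (abc)\nout: X (abc) -> P (abc)"
        )
        inp = LabelInput.from_patterns(
            m, {"A": [(1.0, "0")], "B": [(1.0, "U")]}
        )
        fs = FluxState({"v1": 1.0, "v2": 1.0, "out": 2.0})
        mids = solve_steady_state_mids(m, fs, inp, ["X"])
        np.testing.assert_allclose(
            mids[EMU("X", (1, 2, 3))], [0.5, 0, 0, 0.5], atol=1e-12
        )

    def test_negative_effective_flux_errors(self):
        m = parse_model("v1: A (a) -> B (a)\nv2: B (a) -> C (a)")
        inp = LabelInput.from_patterns(m, {"A": [(1.0, "U")]})
        with pytest.raises(LabellingError, match="negative effective flux"):
            solve_steady_state_mids(m, FluxState({"v1": -1.0, "v2": -1.0}), inp, ["B"])

    @pytest.mark.parametrize("name", ["chain", "condensation", "diamond",
                                      "central_carbon"])
    def test_emu_equals_isotopomer_oracle(self, suite, rng, name):
        """EMU cascade vs independent positional fixed point, random fluxes."""
        fx = suite[name]
        inputs = pool_randomised_inputs(fx, rng)
        for _ in range(3):
            fs = draw_random_fluxes(fx.model, rng)
            oracle = brute_force_isotopomer_oracle(fx.model, fs, inputs)
            mids = solve_steady_state_mids(
                fx.model, fs, inputs, list(fx.model.balanced_metabolites)
            )
            for emu, mid in mids.items():
                np.testing.assert_allclose(
                    mid, oracle[emu.metabolite], atol=1e-8,
                    err_msg=f"{name}:{emu}",
                )

    def test_mid_normalisation_invariant(self, suite, rng):
        fx = suite["central_carbon"]
        inputs = pool_randomised_inputs(fx, rng)
        fs = draw_random_fluxes(fx.model, rng)
        mids = solve_steady_state_mids(
            fx.model, fs, inputs, list(fx.model.balanced_metabolites)
        )
        for mid in mids.values():
            assert mid.min() >= 0.0
            assert abs(mid.sum() - 1.0) < 1e-9

    def test_pyruvate_mmax_monotone_in_glucose_labelling(self, suite):
        """More labelled glucose never lowers the fully-labelled pyruvate
        fraction (all fluxes and other inputs held fixed)."""
        from leakyflux.synthetic_data import central_label_input

        fx = suite["central_carbon"]
        prev = -1.0
        for f in (0.1, 0.3, 0.469, 0.717, 0.95):
            li = central_label_input(f)
            pos = dict(li.positional)
            for p in fx.model.pools:
                n = fx.model.metabolites[p].carbon_count
                pos[p] = LabelInput.pattern_distribution(n, "0")
            mids = solve_steady_state_mids(
                fx.model, fx.true_fluxes, LabelInput(pos), ["PYR_c"]
            )
            m3 = mids[EMU("PYR_c", (1, 2, 3))][3]
            assert m3 >= prev
            prev = m3

    def test_symmetric_metabolite_orientation_convention(self, suite, rng):
        """Reversing the succinate/fumarate atom-order convention in the
        model file leaves every steady-state MID unchanged."""
        from leakyflux.synthetic_data import fixture_model_text

        text = fixture_model_text("central_carbon")
        flipped = text.replace("SDH\tSUC (abcd) -> FUM (abcd)",
                               "SDH\tSUC (abcd) -> FUM (dcba)")
        assert flipped != text
        m1 = suite["central_carbon"].model
        m2 = parse_model(flipped)
        inputs = pool_randomised_inputs(suite["central_carbon"], rng)
        fs = draw_random_fluxes(m1, rng)
        mids1 = solve_steady_state_mids(m1, fs, inputs, ["MAL", "OAA", "CIT"])
        mids2 = solve_steady_state_mids(m2, fs, inputs, ["MAL", "OAA", "CIT"])
        for emu in mids1:
            np.testing.assert_allclose(mids1[emu], mids2[emu], atol=1e-10)


class TestOracle:
    def test_oracle_pass_through_identity(self):
        m = parse_model("v1: A (ab) -> B (ab)\nv2: B (ab) -> C (ab)")
        inp = LabelInput.from_patterns(m, {"A": [(0.4, "U"), (0.6, "10")]})
        out = brute_force_isotopomer_oracle(m, FluxState({"v1": 1.0, "v2": 1.0}), inp)
        np.testing.assert_allclose(
            out["B"], inp.emu_mid(EMU("A", (1, 2))), atol=1e-12
        )

    def test_oracle_symmetric_scrambling(self):
        """A symmetric metabolite's positional state is orientation-averaged:
        a [1-13C] feed yields the same MID as a [2-13C] feed downstream."""
        base = "@symmetric S2\nv1: A (ab) -> S2 (ab)\nv2: S2 (ab) -> B (ab)\nv3: B (ab) -> C (ab)"
        m = parse_model(base)
        fs = FluxState({"v1": 1.0, "v2": 1.0, "v3": 1.0})
        out1 = brute_force_isotopomer_oracle(
            m, fs, LabelInput.from_patterns(m, {"A": [(1.0, "10")]})
        )
        out2 = brute_force_isotopomer_oracle(
            m, fs, LabelInput.from_patterns(m, {"A": [(1.0, "01")]})
        )
        np.testing.assert_allclose(out1["B"], out2["B"], atol=1e-12)
        np.testing.assert_allclose(out1["B"], [0, 1, 0], atol=1e-12)


class TestLabelInput:
    def test_pattern_distributions(self):
        u = LabelInput.pattern_distribution(2, "U")
        assert u[3] == 1.0
        n = LabelInput.pattern_distribution(2, "0", natural_p=0.01)
        assert n[0] == pytest.approx(0.99**2)
        assert n.sum() == pytest.approx(1.0)

    def test_emu_marginals(self):
        m = parse_model("v1: A (ab) -> B (ab)\nv2: B (ab) -> C (ab)")
        li = LabelInput.from_patterns(m, {"A": [(1.0, "10")]})
        np.testing.assert_allclose(li.emu_mid(EMU("A", (1,))), [0, 1])
        np.testing.assert_allclose(li.emu_mid(EMU("A", (2,))), [1, 0])
        np.testing.assert_allclose(li.emu_mid(EMU("A", (1, 2))), [0, 1, 0])

    def test_bad_mixture_rejected(self):
        m = parse_model("v1: A (ab) -> B (ab)\nv2: B (ab) -> C (ab)")
        with pytest.raises(ValueError, match="sum"):
            LabelInput.from_patterns(m, {"A": [(0.5, "U")]})
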
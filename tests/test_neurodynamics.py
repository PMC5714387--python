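import numpy as np
import pytest

import synpolarity as sp
from synpolarity.connectome import AblationSpec, Connectome
from synpolarity.neurodynamics import (
    CircuitEnsemble,
    CircuitState,
    InputPattern,
    PhysioParams,
    PolarityMatrix,
    SolverConfig,
    ca_gate,
    ca_steady,
    current_decomposition,
    derivatives,
    input_current,
    steady_state,
    syn_activation,
)


class TestActivationFunctions:
    def test_sigmoid_midpoint_and_saturation(self):
        assert syn_activation(-40.0, 0.08, -40.0) == pytest.approx(0.5)
        assert syn_activation(1e4, 0.08, -40.0) == pytest.approx(1.0)
        assert syn_activation(-1e4, 0.08, -40.0) == pytest.approx(0.0)

    def test_ash_operating_point(self):
        # V_ash = 0.5 * (-90) = -45 with the ASH constants
        h = syn_activation(-45.0, 0.03, -90.0)
        assert h == pytest.approx(1.0 / (1.0 + np.exp(-1.35)))
        assert h == pytest.approx(0.794, abs=1e-3)

    def test_ca_gate(self):
        assert ca_gate(-20.0) == pytest.approx(0.5)
        assert ca_gate(-65.0) == pytest.approx(1.0 / (1.0 + np.exp(5.0)), rel=1e-9)
        v = np.linspace(-90, 20, 50)
        assert (np.diff(ca_gate(v)) > 0).all()

    def test_ca_steady_nonnegative_and_realistic(self):
        p = PhysioParams()
        v = np.linspace(-80, 0, 30)
        ca = ca_steady(v, p)
        assert (ca >= 0).all()
        # at typical operating voltages calcium sits in the 1-100 uM range
        assert 1.0 < ca_steady(-30.0, p) < 100.0


class TestInputCurrent:
    def test_decoupled_limit(self):
        p = PhysioParams(f_ash=0.0)
        sigma = InputPattern.optimal()
        assert input_current("AVB", p, sigma) == pytest.approx(p.X_o)
        assert input_current("AVA", p, sigma) == pytest.approx(-p.X_o)

    def test_ash_ablation_removes_modulation(self):
        p = PhysioParams()
        sigma = InputPattern.optimal()
        assert input_current("AVB", p, sigma, ash_ablated=True) == pytest.approx(p.X_o)

    def test_composed_with_sigmoid_oracle(self):
        p = PhysioParams(X_o=3.5, c_ash=0.5, f_ash=-0.8)
        h = syn_activation(p.V_ash, p.gamma_ash, p.theta_ash)
        sigma = InputPattern.optimal()
        assert input_current("AVA", p, sigma) == pytest.approx(-3.5 * (1 - 0.8 * h))

    def test_unknown_neuron(self):
        with pytest.raises(KeyError):
            input_current("ASH", PhysioParams(), InputPattern.optimal())


def _naive_rhs(state, c, cs, eps, sigma, p, ablated):
    """Independent per-equation reference implementation (plain loops)."""
    idx = c.index
    dyn = [n for n in c.nodes if n not in ("ASH", "E_b", "E_f")]
    alive = {n: (0.0 if n in ablated else 1.0) for n in c.nodes}
    alive["E_b"] = alive["E_f"] = 1.0
    vof = {n: state.V[dyn.index(n)] for n in dyn}
    vof["E_f"], vof["E_b"] = state.E_f, state.E_b
    if "ASH" in c.nodes:
        vof["ASH"] = p.c_ash * p.theta_ash

    w = {(a, b): c.syn_mean[idx[b], idx[a]] * p.q_s for (a, b) in cs.active}

    def H(pre):
        th, ga = (p.theta_ash, p.gamma_ash) if pre == "ASH" else (p.theta, p.gamma)
        return 1.0 / (1.0 + np.exp(-ga * (vof[pre] - th)))

    def syn_gap(post):
        s = 0.0
        for (a, b), wij in w.items():
            if b == post:
                s -= alive[a] * wij * H(a) * (
                    vof[post] - (1 - eps[(a, b)]) * p.V_Cl
                )
        g = 0.0
        for other in c.nodes:
            if other == post:
                continue
            ge = c.gap[idx[post], idx[other]] * p.q_e
            g -= alive[other] * ge * (vof[post] - vof[other])
        return s, g

    dV, dCa = [], []
    for k, n in enumerate(dyn):
        if n in ablated:
            dV.append(0.0)
            dCa.append(0.0)
            continue
        V, Ca = vof[n], state.Ca[k]
        m = 1.0 / (1.0 + np.exp(-(V + 20.0) / 9.0))
        s, g = syn_gap(n)
        x = input_current(n, p, sigma, ash_ablated="ASH" in ablated)
        dv = (
            -p.g_L * (V - p.V_L)
            - p.g_Ca * m * m * (V - p.V_Ca)
            - p.g_KCa * Ca / (p.K_D + Ca) * (V - p.V_K)
            + s + g + x
        ) / p.C
        dca = -Ca / p.tau_Ca - 2 * p.g_Ca * m * m * (V - p.V_Ca) / (p.d_cm * p.F)
        dV.append(dv)
        dCa.append(dca)
    pools = []
    for n in ("E_f", "E_b"):
        s, g = syn_gap(n)
        pools.append((-p.g_L * (vof[n] - p.V_L) + s + g) / p.C)
    return np.concatenate([dV, dCa, pools])


class TestDerivatives:
    def test_leak_equilibrium(self, circuit):
        p = PhysioParams(q_s=0.0, q_e=0.0, X_o=0.0, g_Ca=0.0, g_KCa=0.0)
        cs = sp.reduce_by_cutoff(circuit, 0.75)
        eps = PolarityMatrix.all_inhibitory(cs)
        state = CircuitState(
            neurons=("AVA", "AVB", "AVD", "AVE", "PVC", "DVA"),
            V=np.full(6, p.V_L),
            Ca=np.zeros(6),
            E_f=p.V_L,
            E_b=p.V_L,
        )
        d = derivatives(state, circuit, cs, eps, InputPattern.optimal(), p)
        np.testing.assert_allclose(d.y, 0.0, atol=1e-14)

    def test_matches_naive_loop_implementation(self, circuit, truth_full):
        rng = np.random.default_rng(5)
        cs, eps, sigma = truth_full.connset, truth_full.polarity, truth_full.inputs
        p = truth_full.params
        for ablated in [frozenset(), frozenset({"ASH"}), frozenset({"AVA", "PVC"})]:
            state = CircuitState(
                neurons=("AVA", "AVB", "AVD", "AVE", "PVC", "DVA"),
                V=rng.uniform(-70, -20, 6),
                Ca=rng.uniform(0.1, 60, 6),
                E_f=rng.uniform(-70, -20),
                E_b=rng.uniform(-70, -20),
            )
            ab = AblationSpec("x", ablated)
            got = derivatives(state, circuit, cs, eps, sigma, p, ab)
            want = _naive_rhs(state, circuit, cs, eps, sigma, p, ablated)
            np.testing.assert_allclose(got.y, want, rtol=1e-10, atol=1e-12)

    def test_missing_polarity_entry_raises(self, circuit):
        cs = sp.reduce_by_cutoff(circuit, 0.75)
        bad = PolarityMatrix({cs.free[0]: 0})  # misses the other connections
        state = CircuitState.from_vector(
            ("AVA", "AVB", "AVD", "AVE", "PVC", "DVA"), np.full(14, -60.0)
        )
        with pytest.raises(KeyError, match="polarity"):
            derivatives(state, circuit, cs, bad, InputPattern.optimal(), PhysioParams())


class TestSteadyState:
    def test_leak_only_exact(self, circuit):
        p = PhysioParams(q_s=0.0, q_e=0.0, X_o=0.0, g_Ca=0.0, g_KCa=0.0)
        cs = sp.reduce_by_cutoff(circuit, 0.75)
        res = steady_state(
            circuit, cs, PolarityMatrix.all_inhibitory(cs), InputPattern.optimal(), p
        )
        assert res.converged
        np.testing.assert_allclose(res.state.V, p.V_L, atol=1e-9)
        np.testing.assert_allclose(res.state.E_f, p.V_L, atol=1e-9)

    def test_isolated_neuron_with_input_closed_form(self, circuit):
        # no coupling, no active currents: V = V_L + X / g_L
        p = PhysioParams(q_s=0.0, q_e=0.0, g_Ca=0.0, g_KCa=0.0, X_o=0.1, f_ash=0.0)
        cs = sp.reduce_by_cutoff(circuit, 0.75)
        sigma = InputPattern.optimal()
        res = steady_state(circuit, cs, PolarityMatrix.all_inhibitory(cs), sigma, p)
        assert res.converged
        for k, n in enumerate(("AVA", "AVB", "AVD", "AVE", "PVC", "DVA")):
            expected = p.V_L + p.X_o * sigma[n] / p.g_L
            assert res.state.V[k] == pytest.approx(expected, abs=1e-7)

    def test_calcium_closed_form_at_steady_state(self, truth8, ev8):
        ens = ev8.ensemble
        ens.configure(truth8.polarity, truth8.inputs, truth8.params)
        for res in ens.steady_states():
            assert res.converged
            np.testing.assert_allclose(
                res.state.Ca,
                np.where(
                    res.state.Ca > 0, ca_steady(res.state.V, truth8.params), 0.0
                ),
                rtol=1e-8, atol=1e-10,
            )

    def test_hybrid_agrees_with_dopri(self, circuit, truth_full):
        cs, eps, sigma, p = (
            truth_full.connset, truth_full.polarity,
            truth_full.inputs, truth_full.params,
        )
        for label, ablated in [("wild_type", frozenset()), ("ASH-", frozenset({"ASH"}))]:
            ab = AblationSpec(label, ablated)
            hy = steady_state(circuit, cs, eps, sigma, p, ab)
            do = steady_state(
                circuit, cs, eps, sigma, p, ab,
                solver=SolverConfig(method="dopri", t_max=6e4),
            )
            assert hy.converged and do.converged
            np.testing.assert_allclose(hy.state.y, do.state.y, rtol=1e-4, atol=1e-4)

    def test_two_initial_conditions_agree(self, circuit, truth_full):
        """Two reasonable initial states must reach the same wild-type
        attractor (disagreement would flag bistability)."""
        cs, eps, sigma, p = (
            truth_full.connset, truth_full.polarity,
            truth_full.inputs, truth_full.params,
        )
        a = steady_state(circuit, cs, eps, sigma, p)
        alt = CircuitState(
            neurons=("AVA", "AVB", "AVD", "AVE", "PVC", "DVA"),
            V=np.full(6, -45.0),
            Ca=np.full(6, 10.0),
            E_f=-45.0,
            E_b=-45.0,
        )
        b = steady_state(circuit, cs, eps, sigma, p, init=alt)
        assert a.converged and b.converged
        np.testing.assert_allclose(a.state.y, b.state.y, rtol=1e-6, atol=1e-6)

    def test_nonconvergence_is_flagged_not_raised(self, circuit, truth_full):
        cs = truth_full.connset
        tight = SolverConfig(t_max=1.0, t_window=1.0, max_newton=1, newton_tol=1e-300)
        res = steady_state(
            circuit, cs, truth_full.polarity, truth_full.inputs, truth_full.params,
            AblationSpec("wt"), solver=tight,
        )
        assert res.converged is False


class TestCurrents:
    def test_components_balance_at_steady_state(self, truth8, ev8):
        ens = ev8.ensemble
        ens.configure(truth8.polarity, truth8.inputs, truth8.params)
        states = ens.steady_states()
        Y = np.stack([s.state.y for s in states])
        for per in ens.current_decomposition(Y):
            for neuron, comps in per.items():
                assert abs(sum(comps.values())) < 1e-8, neuron

    def test_leak_only_equilibrium_has_zero_components(self, circuit):
        p = PhysioParams(q_s=0.0, q_e=0.0, X_o=0.0, g_Ca=0.0, g_KCa=0.0)
        cs = sp.reduce_by_cutoff(circuit, 0.75)
        eps = PolarityMatrix.all_inhibitory(cs)
        sigma = InputPattern.optimal()
        res = steady_state(circuit, cs, eps, sigma, p)
        dec = current_decomposition(res.state, circuit, cs, eps, sigma, p)
        for comps in dec.values():
            for v in comps.values():
                assert v == pytest.approx(0.0, abs=1e-9)

    def test_inhibitory_synaptic_current_sign(self, circuit, truth_full):
        # all-inhibitory inputs at V > V_Cl must hyperpolarize
        p = truth_full.params
        ens = CircuitEnsemble(
            circuit, truth_full.connset, [AblationSpec("wt")]
        ).configure(truth_full.polarity, truth_full.inputs, p)
        y = np.concatenate([np.full(6, -45.0), np.full(6, 5.0), [-45.0, -45.0]])
        cur = ens.currents(y[None])
        syn = cur["synaptic"][0]
        # every node whose incoming synapses are all inhibitory
        exc_targets = {post for (pre, post), v in truth_full.polarity.eps.items() if v == 1}
        for j, node in enumerate(circuit.nodes):
            if node in ("ASH",) or node in exc_targets:
                continue
            assert syn[j] <= 1e-12

    def test_gap_current_antisymmetry(self):
        # two-neuron circuit with a single gap junction
        nodes = ("AVA", "AVB", "E_b", "E_f")
        syn = np.zeros((4, 4))
        gap = np.zeros((4, 4))
        gap[0, 1] = gap[1, 0] = 3.0
        c = Connectome(nodes=nodes, syn_mean=syn, syn_sd=syn.copy(), gap=gap)
        cs = sp.reduce_by_cutoff(c, 0.0)
        p = PhysioParams(X_o=0.0)
        ens = CircuitEnsemble(c, cs, [AblationSpec("wt")]).configure(
            PolarityMatrix({}), InputPattern.uniform(("AVA", "AVB")), p
        )
        y = np.array([-40.0, -60.0, 1.0, 1.0, -60.0, -60.0])
        cur = ens.currents(y[None])
        g = cur["gap"][0]
        assert g[0] == pytest.approx(-g[1])
        assert g[0] == pytest.approx(-3.0 * p.q_e * (-40.0 - (-60.0)))


class TestAblationEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_ablation_equals_structural_deletion(self, seed):
        """Masking a neuron must reproduce the dynamics of the circuit with
        that node physically removed."""
        c = sp.make_random_connectome(5, density=0.5, seed=seed)
        victim = c.nodes[1]
        keep = [n for n in c.nodes if n != victim]
        kidx = [c.index[n] for n in keep]
        reduced = Connectome(
            nodes=tuple(keep),
            syn_mean=c.syn_mean[np.ix_(kidx, kidx)],
            syn_sd=c.syn_sd[np.ix_(kidx, kidx)],
            gap=c.gap[np.ix_(kidx, kidx)],
        )
        p = PhysioParams()
        dyn_full = [n for n in c.nodes if n not in ("ASH", "E_b", "E_f")]
        dyn_red = [n for n in dyn_full if n != victim]
        sig_full = InputPattern({n: (1 if k % 2 else -1) for k, n in enumerate(dyn_full)})
        sig_red = InputPattern({n: sig_full[n] for n in dyn_red})
        cs_f = sp.reduce_by_cutoff(c, 0.0)
        cs_r = sp.reduce_by_cutoff(reduced, 0.0)
        res_f = steady_state(
            c, cs_f, PolarityMatrix.all_inhibitory(cs_f), sig_full, p,
            AblationSpec("cut", frozenset({victim})),
        )
        res_r = steady_state(
            reduced, cs_r, PolarityMatrix.all_inhibitory(cs_r), sig_red, p
        )
        assert res_f.converged and res_r.converged
        for n in dyn_red:
            assert res_f.state.voltage(n) == pytest.approx(
                res_r.state.voltage(n), abs=1e-8
            )
        assert res_f.state.E_f == pytest.approx(res_r.state.E_f, abs=1e-8)
        assert res_f.state.E_b == pytest.approx(res_r.state.E_b, abs=1e-8)
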
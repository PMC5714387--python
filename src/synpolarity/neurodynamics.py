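"""Conductance-based dynamics of the pre-motor circuit.

The model has 14 state variables for the canonical circuit: membrane voltages
and intracellular calcium concentrations of the six dynamic interneurons
(AVA, AVB, AVD, AVE, PVC, DVA) plus the average voltages of the forward (E_f)
and backward (E_b) motor-neuron pools.  Interneurons carry leak, Ca2+,
Ca2+-activated K+ currents, gap-junction and graded chemical-synaptic
coupling, and a constant sensory input; motor pools carry leak, gap and
synaptic currents only.  ASH is not a dynamical variable: its voltage is held
at c_ash * theta_ash and it acts on the circuit through its outgoing
connections and through a multiplicative modulation of the input.

Units: mV, ms, uA/cm^2, mS/cm^2, uF/cm^2, uM.  With the dendrite diameter in
cm and the Faraday constant in C/mol, the calcium influx term
-2 g_Ca m^2 (V - V_Ca) / (d F) comes out exactly in uM/ms, so the single
unit-conversion constant ``CA_UNIT_FACTOR`` equals 1.0 (see docs/methods.md
for the derivation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from types import MappingProxyType
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import expit

from .connectome import AblationSpec, Connectome, ConnectionSet, MOTOR_POOLS

__all__ = [
    "PhysioParams",
    "OPT_RANGES",
    "CA_UNIT_FACTOR",
    "PolarityMatrix",
    "InputPattern",
    "CircuitState",
    "SolverConfig",
    "SteadyStateResult",
    "CircuitEnsemble",
    "syn_activation",
    "ca_gate",
    "ca_steady",
    "input_current",
    "derivatives",
    "steady_state",
    "current_decomposition",
]

#: conversion from (uA/cm^2) / (cm * C/mol) to uM/ms -- exactly unity in this
#: unit system (derivation in docs/methods.md)
CA_UNIT_FACTOR = 1.0

#: search ranges of the optimized physiological parameters
OPT_RANGES: Mapping[str, tuple[float, float]] = MappingProxyType(
    {
        "q_s": (0.0, 0.07),
        "q_e": (0.0, 0.07),
        "X_o": (0.0, 4.0),
        "c_ash": (0.0, 2.0),
        "f_ash": (-1.0, 1.0),
        "eta": (1.0, 10.0),
    }
)

#: presentation order of the input-pattern vector sigma
INPUT_ORDER = ("AVA", "AVB", "AVD", "AVE", "DVA", "PVC")


@dataclass(frozen=True)
class PhysioParams:
    """Physiological constants of the circuit model.

    The first six fields are the optimized parameters (defaults are the
    best-fit values for the mean-weights circuit); the rest are fixed
    constants.
    """

    q_s: float = 0.039      # synaptic conductance per contact, mS/cm^2
    q_e: float = 0.042      # gap-junction conductance per contact, mS/cm^2
    X_o: float = 3.5        # input amplitude, uA/cm^2
    c_ash: float = 0.5      # ASH stimulation level, unitless
    f_ash: float = -0.8     # ASH input coupling, unitless
    eta: float = 2.0        # behavioral voltage-noise amplitude, mV

    g_L: float = 0.0067     # leak conductance, mS/cm^2
    V_L: float = -60.0      # leak reversal, mV
    V_Ca: float = 120.0     # calcium reversal, mV
    V_K: float = -90.0      # potassium reversal, mV
    V_Cl: float = -50.0     # chloride (inhibitory) reversal, mV
    g_Ca: float = 0.043     # calcium conductance, mS/cm^2
    g_KCa: float = 0.057    # Ca-activated K conductance, mS/cm^2
    K_D: float = 30.0       # calcium threshold, uM
    tau_Ca: float = 150.0   # calcium decay constant, ms
    d: float = 0.5          # dendrite diameter, um
    C: float = 1.0          # membrane capacitance, uF/cm^2
    F: float = 96485.33212  # Faraday constant, C/mol
    theta: float = -40.0    # synaptic activation threshold (non-ASH), mV
    gamma: float = 0.08     # synaptic activation steepness (non-ASH), 1/mV
    theta_ash: float = -90.0
    gamma_ash: float = 0.03

    def __post_init__(self):
        for name in ("q_s", "q_e", "g_L", "g_Ca", "g_KCa"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.eta <= 0:
            raise ValueError("eta must be > 0")
        if self.K_D <= 0 or self.tau_Ca <= 0:
            raise ValueError("K_D and tau_Ca must be > 0")

    def replace(self, **kw) -> "PhysioParams":
        return replace(self, **kw)

    @property
    def d_cm(self) -> float:
        return self.d * 1e-4

    @property
    def V_ash(self) -> float:
        """Constant ASH voltage, c_ash * theta_ash."""
        return self.c_ash * self.theta_ash


def syn_activation(V, gamma: float, theta: float):
    """Sigmoidal synaptic transmission H(V) = 1 / (1 + exp(-gamma (V - theta)))."""
    return expit(gamma * (np.asarray(V, dtype=float) - theta))


def ca_gate(V):
    """Calcium-channel gating variable m(V) = 1 / (1 + exp(-(V + 20)/9))."""
    return expit((np.asarray(V, dtype=float) + 20.0) / 9.0)


def ca_steady(V, p: PhysioParams):
    """Closed-form stationary calcium concentration at fixed voltage (uM).

    [Ca]_ss = -2 tau_Ca g_Ca m(V)^2 (V - V_Ca) / (d F), which is >= 0 for
    V <= V_Ca.
    """
    m = ca_gate(V)
    return (
        -2.0 * p.tau_Ca * p.g_Ca * m * m * (np.asarray(V, dtype=float) - p.V_Ca)
        / (p.d_cm * p.F) * CA_UNIT_FACTOR
    )


@dataclass(frozen=True)
class PolarityMatrix:
    """Binary polarity assignment over the active chemical connections.

    ``eps[(pre, post)]`` is 1 for excitatory (reversal 0 mV) and 0 for
    inhibitory (reversal V_Cl).  Fixed-excitatory connections always carry 1.
    """

    eps: Mapping[tuple[str, str], int]

    def __post_init__(self):
        object.__setattr__(self, "eps", MappingProxyType(dict(self.eps)))
        for conn, v in self.eps.items():
            if v not in (0, 1):
                raise ValueError(f"polarity for {conn} must be 0 or 1, got {v}")

    @classmethod
    def for_connection_set(
        cls,
        cs: ConnectionSet,
        values: Mapping[tuple[str, str], int] | None = None,
        default: int = 0,
        frozen_value: int = 0,
    ) -> "PolarityMatrix":
        """Polarity over ``cs.active``: free connections take ``values`` (or
        ``default``), fixed-excitatory connections are forced to 1, frozen
        connections are pinned at ``frozen_value`` (inhibitory by default)."""
        values = values or {}
        eps = {conn: int(values.get(conn, default)) for conn in cs.free}
        eps.update({conn: 1 for conn in cs.fixed})
        eps.update({conn: frozen_value for conn in cs.frozen})
        return cls(eps)

    @classmethod
    def all_inhibitory(cls, cs: ConnectionSet) -> "PolarityMatrix":
        return cls.for_connection_set(cs)

    def flip(self, conn: tuple[str, str]) -> "PolarityMatrix":
        if conn not in self.eps:
            raise KeyError(f"{conn} is not an active connection")
        new = dict(self.eps)
        new[conn] = 1 - new[conn]
        return PolarityMatrix(new)

    def __getitem__(self, conn) -> int:
        return self.eps[conn]


@dataclass(frozen=True)
class InputPattern:
    """Input polarity sigma_i (+1 or -1) for each input-receiving neuron."""

    sigma: Mapping[str, int]

    def __post_init__(self):
        object.__setattr__(self, "sigma", MappingProxyType(dict(self.sigma)))
        for name, v in self.sigma.items():
            if v not in (-1, 1):
                raise ValueError(f"sigma[{name}] must be +1 or -1, got {v}")

    @classmethod
    def uniform(cls, neurons: Sequence[str] = INPUT_ORDER, value: int = 1):
        return cls({n: value for n in neurons})

    @classmethod
    def optimal(cls) -> "InputPattern":
        """AVA inhibited, all other receivers excited (the optimal pattern)."""
        return cls({n: (-1 if n == "AVA" else 1) for n in INPUT_ORDER})

    def __getitem__(self, name: str) -> int:
        return self.sigma[name]


def input_current(
    neuron: str, p: PhysioParams, sigma: InputPattern, ash_ablated: bool = False
) -> float:
    """Constant sensory input X_i = X_o sigma_i [1 + a_ash f_ash H_ash(V_ash)].

    Ablating ASH (a_ash = 0) removes the bracketed modulation.
    """
    if neuron not in sigma.sigma:
        raise KeyError(f"{neuron} does not receive input")
    mod = 1.0
    if not ash_ablated:
        mod += p.f_ash * syn_activation(p.V_ash, p.gamma_ash, p.theta_ash)
    return p.X_o * sigma[neuron] * float(mod)


@dataclass(frozen=True)
class CircuitState:
    """Stacked circuit state: interneuron voltages and calcium + pool voltages."""

    neurons: tuple[str, ...]
    V: np.ndarray
    Ca: np.ndarray
    E_f: float
    E_b: float

    @property
    def y(self) -> np.ndarray:
        return np.concatenate([self.V, self.Ca, [self.E_f, self.E_b]])

    @property
    def dim(self) -> int:
        return 2 * len(self.neurons) + 2

    def voltage(self, name: str) -> float:
        if name == "E_f":
            return self.E_f
        if name == "E_b":
            return self.E_b
        return float(self.V[self.neurons.index(name)])

    def calcium(self, name: str) -> float:
        return float(self.Ca[self.neurons.index(name)])

    @classmethod
    def from_vector(cls, neurons: Sequence[str], y: np.ndarray) -> "CircuitState":
        nd = len(neurons)
        return cls(
            neurons=tuple(neurons),
            V=np.asarray(y[:nd], dtype=float).copy(),
            Ca=np.asarray(y[nd : 2 * nd], dtype=float).copy(),
            E_f=float(y[2 * nd]),
            E_b=float(y[2 * nd + 1]),
        )


@dataclass(frozen=True)
class SolverConfig:
    """Steady-state solver settings.

    ``method`` is "hybrid" (pseudo-transient Newton on the voltage-reduced
    system with a stability check and integration fallback; default) or
    "dopri" (windowed Dormand-Prince 5(4) integration to stationarity).
    """

    method: str = "hybrid"
    stat_tol: float = 1e-8      # stationarity: max scaled |dy/dt|
    window_tol: float = 1e-6    # alternative: state change over one window
    t_window: float = 2000.0    # ms per integration window
    t_max: float = 1.0e4        # ms, integration budget
    rtol: float = 1e-8          # integration accuracy for the "dopri" method
    atol: float = 1e-10
    newton_tol: float = 1e-11   # mV/ms residual for the Newton stage
    max_newton: int = 120
    check_stability: bool = True

    def __post_init__(self):
        if self.method not in ("hybrid", "dopri"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.stat_tol <= 0 or self.newton_tol <= 0:
            raise ValueError("tolerances must be > 0")


@dataclass(frozen=True)
class SteadyStateResult:
    state: CircuitState
    residual: float          # max |dy/dt| over active components, mV/ms or uM/ms
    converged: bool
    method: str
    stable: bool | None = None
    message: str = ""


class CircuitEnsemble:
    """Batched steady-state engine for a panel of ablation variants.

    Precomputes the structural arrays (contact-count matrices restricted to
    active connections, ablation masks, sigmoid constants) once; per-candidate
    conductances, polarities and inputs are filled in by :meth:`configure`.
    All variants are solved simultaneously with vectorized numpy operations.
    """

    def __init__(
        self,
        connectome: Connectome,
        connset: ConnectionSet,
        ablations: Sequence[AblationSpec],
        solver: SolverConfig | None = None,
    ):
        self.connectome = connectome
        self.connset = connset
        self.ablations = list(ablations)
        self.solver = solver or SolverConfig()

        nodes = connectome.nodes
        self.nodes = nodes
        idx = connectome.index
        self.dyn = tuple(n for n in nodes if n not in MOTOR_POOLS and n != "ASH")
        self.n_dyn = len(self.dyn)
        self.nstate = 2 * self.n_dyn + 2
        self._dyn_cols = np.array([idx[n] for n in self.dyn])
        self._ash_col = idx.get("ASH")
        self._ef_col = idx["E_f"]
        self._eb_col = idx["E_b"]
        N = len(nodes)

        # contact counts restricted to active (non-dropped) connections
        self._Ns = np.zeros((N, N))
        for pre, post in connset.active:
            self._Ns[idx[post], idx[pre]] = connectome.syn_mean[idx[post], idx[pre]]
        self._Ne = connectome.gap.copy()

        B = len(self.ablations)
        self.B = B
        self._alive = np.ones((B, N))
        for b, ab in enumerate(self.ablations):
            for n in ab.ablated:
                if n not in idx:
                    raise KeyError(f"unknown neuron {n!r} in ablation {ab.label!r}")
                self._alive[b, idx[n]] = 0.0
        self._a_dyn = self._alive[:, self._dyn_cols]  # (B, n_dyn)
        self._ash_alive = (
            self._alive[:, self._ash_col] if self._ash_col is not None else np.zeros(B)
        )
        self._configured = False

    # -- candidate configuration ------------------------------------------

    def configure(
        self, polarity: PolarityMatrix, inputs: InputPattern, params: PhysioParams
    ) -> "CircuitEnsemble":
        p = params
        idx = self.connectome.index
        N = len(self.nodes)
        eps = np.zeros((N, N))
        for conn in self.connset.active:
            if conn not in polarity.eps:
                raise KeyError(f"missing polarity entry for active connection {conn}")
            eps[idx[conn[1]], idx[conn[0]]] = polarity.eps[conn]

        # per-variant coupling matrices with ablation masks (a_i a_j factors)
        a = self._alive
        mask2 = a[:, :, None] * a[:, None, :]
        self._W = self._Ns[None] * p.q_s * mask2            # (B, N, N)
        self._Wrev = self._W * ((1.0 - eps) * p.V_Cl)[None]
        self._G = self._Ne[None] * p.q_e * mask2
        self._Gsum = self._G.sum(axis=2)

        # presynaptic sigmoid constants (ASH terms use the ASH constants)
        th = np.full(N, p.theta)
        ga = np.full(N, p.gamma)
        if self._ash_col is not None:
            th[self._ash_col] = p.theta_ash
            ga[self._ash_col] = p.gamma_ash
        self._theta_pre = th
        self._gamma_pre = ga

        # constant input to dynamic interneurons, per variant
        sig = np.array([inputs[n] for n in self.dyn], dtype=float)
        h_ash = float(syn_activation(p.V_ash, p.gamma_ash, p.theta_ash))
        mod = 1.0 + self._ash_alive * p.f_ash * h_ash       # (B,)
        self._X = p.X_o * sig[None, :] * mod[:, None] * self._a_dyn

        self._Vash = p.V_ash
        self.params = p
        self._configured = True
        return self

    # -- right-hand side ---------------------------------------------------

    def _vfull(self, Y: np.ndarray) -> np.ndarray:
        nd = self.n_dyn
        shape = Y.shape[:-1] + (len(self.nodes),)
        Vf = np.zeros(shape)
        Vf[..., self._dyn_cols] = Y[..., :nd]
        if self._ash_col is not None:
            Vf[..., self._ash_col] = self._Vash
        Vf[..., self._ef_col] = Y[..., 2 * nd]
        Vf[..., self._eb_col] = Y[..., 2 * nd + 1]
        return Vf

    def _coupling(self, Vf: np.ndarray, sel=None):
        """Synaptic and gap current densities onto every node (inward > 0)."""
        W = self._W if sel is None else self._W[sel]
        Wrev = self._Wrev if sel is None else self._Wrev[sel]
        G = self._G if sel is None else self._G[sel]
        Gsum = self._Gsum if sel is None else self._Gsum[sel]
        H = expit(self._gamma_pre * (Vf - self._theta_pre))
        wh = np.einsum("bij,...bj->...bi", W, H)
        syn = -Vf * wh + np.einsum("bij,...bj->...bi", Wrev, H)
        gap = -Vf * Gsum + np.einsum("bij,...bj->...bi", G, Vf)
        return syn, gap

    def rhs(self, Y: np.ndarray, sel=None) -> np.ndarray:
        """Time derivative of the stacked state.

        ``Y`` has shape (..., B, nstate); ablated neurons contribute nothing
        and their own derivatives are zero.  ``sel`` restricts the variant
        axis to the given indices.
        """
        if not self._configured:
            raise RuntimeError("call configure() first")
        p = self.params
        a_dyn = self._a_dyn if sel is None else self._a_dyn[sel]
        X = self._X if sel is None else self._X[sel]
        nd = self.n_dyn
        V = Y[..., :nd]
        Ca = Y[..., nd : 2 * nd]
        Vf = self._vfull(Y)
        syn, gap = self._coupling(Vf, sel)

        m = ca_gate(V)
        ica = -p.g_Ca * m * m * (V - p.V_Ca)
        ikca = -p.g_KCa * (Ca / (p.K_D + Ca)) * (V - p.V_K)
        leak = -p.g_L * (V - p.V_L)
        dV = (
            leak + ica + ikca
            + syn[..., self._dyn_cols] + gap[..., self._dyn_cols] + X
        ) / p.C * a_dyn
        influx = -2.0 * p.g_Ca * m * m * (V - p.V_Ca) / (p.d_cm * p.F) * CA_UNIT_FACTOR
        dCa = (-Ca / p.tau_Ca + influx) * a_dyn
        dEf = (
            -p.g_L * (Vf[..., self._ef_col] - p.V_L)
            + syn[..., self._ef_col] + gap[..., self._ef_col]
        ) / p.C
        dEb = (
            -p.g_L * (Vf[..., self._eb_col] - p.V_L)
            + syn[..., self._eb_col] + gap[..., self._eb_col]
        ) / p.C
        return np.concatenate([dV, dCa, dEf[..., None], dEb[..., None]], axis=-1)

    def currents(self, Y: np.ndarray) -> dict[str, np.ndarray]:
        """Per-node membrane current components (B, N), inward positive."""
        p = self.params
        nd = self.n_dyn
        V = Y[..., :nd]
        Ca = Y[..., nd : 2 * nd]
        Vf = self._vfull(Y)
        syn, gap = self._coupling(Vf)
        N = len(self.nodes)
        zeros = np.zeros(Y.shape[:-1] + (N,))
        leak = -p.g_L * (Vf - p.V_L)
        ica = zeros.copy()
        ikca = zeros.copy()
        inp = zeros.copy()
        m = ca_gate(V)
        ica[..., self._dyn_cols] = -p.g_Ca * m * m * (V - p.V_Ca)
        ikca[..., self._dyn_cols] = -p.g_KCa * (Ca / (p.K_D + Ca)) * (V - p.V_K)
        inp[..., self._dyn_cols] = self._X
        if self._ash_col is not None:
            leak[..., self._ash_col] = 0.0
        return {
            "leak": leak, "calcium": ica, "kca": ikca,
            "gap": gap, "synaptic": syn, "input": inp,
        }

    # -- steady states -----------------------------------------------------

    def _init_y(self) -> np.ndarray:
        """Default initial condition: V = V_L, Ca at its closed form."""
        p = self.params
        y = np.empty((self.B, self.nstate))
        y[:, : self.n_dyn] = p.V_L
        y[:, self.n_dyn : 2 * self.n_dyn] = ca_steady(p.V_L, p)
        y[:, 2 * self.n_dyn :] = p.V_L
        return y

    def _unknowns_to_y(self, v: np.ndarray) -> np.ndarray:
        """Embed voltage unknowns (..., B, n_dyn + 2) into full states with Ca
        slaved to its closed form."""
        nd = self.n_dyn
        V = v[..., :nd]
        Ca = ca_steady(V, self.params)
        return np.concatenate([V, Ca, v[..., nd:]], axis=-1)

    def _reduced_residual(self, v: np.ndarray) -> np.ndarray:
        nd = self.n_dyn
        f = self.rhs(self._unknowns_to_y(v))
        F = np.concatenate([f[..., :nd], f[..., 2 * nd :]], axis=-1)
        # pin ablated voltages so the Jacobian stays nonsingular
        pin = np.concatenate([self._a_dyn, np.ones((self.B, 2))], axis=-1)
        return F * pin + (v - self.params.V_L) * (1.0 - pin)

    def _newton(
        self,
        v0: np.ndarray | None = None,
        dt0: float = 5.0,
        ramp: float = 1.6,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Pseudo-transient Newton on the voltage-reduced system.

        Returns (states y, per-variant converged flags).  The continuation
        parameter starts at an implicit-Euler step of ``dt0`` ms and grows
        geometrically, so early iterations follow the flow toward the
        attractor and late iterations are full Newton steps.  With a large
        ``dt0`` this is plain damped Newton (used to polish integrated
        states).
        """
        cfg = self.solver
        m = self.n_dyn + 2
        if v0 is None:
            v = np.full((self.B, m), self.params.V_L)
        else:
            v = v0.copy()
        eye = np.eye(m)
        dt = dt0
        h = 1e-6
        done = np.zeros(self.B, dtype=bool)
        for _ in range(cfg.max_newton):
            F = self._reduced_residual(v)
            done = np.max(np.abs(F), axis=-1) < cfg.newton_tol
            if done.all():
                break
            # batched forward-difference Jacobian: (m, B, m) residuals
            vp = np.repeat(v[None, :, :], m, axis=0)
            for k in range(m):
                vp[k, :, k] += h
            Fp = self._reduced_residual(vp)
            J = (Fp - F[None]) / h          # (m, B, m) = dF_j/dv_k at [k, b, j]
            J = np.transpose(J, (1, 2, 0))  # (B, j, k)
            A = eye[None] / dt - J
            try:
                delta = np.linalg.solve(A, F[..., None])[..., 0]
            except np.linalg.LinAlgError:
                delta = np.einsum("bjk,bk->bj", np.linalg.pinv(A), F)
            np.clip(delta, -30.0, 30.0, out=delta)
            v = v + np.where(done[:, None], 0.0, delta)
            dt = min(dt * ramp, 1e12)
        y = self._unknowns_to_y(v)
        resid = np.max(np.abs(self._reduced_residual(v)), axis=-1)
        return y, resid < max(cfg.newton_tol * 10.0, 1e-10)

    def _full_jacobian(self, Y: np.ndarray) -> np.ndarray:
        """Forward-difference Jacobian of the full rhs, (B, S, S)."""
        S = self.nstate
        h = 1e-6
        F0 = self.rhs(Y)
        Yp = np.repeat(Y[None], S, axis=0)
        for k in range(S):
            Yp[k, :, k] += h
        Fp = self.rhs(Yp)
        J = (Fp - F0[None]) / h  # (k, B, j)
        return np.transpose(J, (1, 2, 0))

    def _active_components(self, b: int) -> np.ndarray:
        nd = self.n_dyn
        mask = np.ones(self.nstate, dtype=bool)
        for k in range(nd):
            if self._a_dyn[b, k] == 0:
                mask[k] = mask[nd + k] = False
        return np.flatnonzero(mask)

    def _is_stable(self, Y: np.ndarray) -> np.ndarray:
        J = self._full_jacobian(Y)
        out = np.zeros(self.B, dtype=bool)
        for b in range(self.B):
            comp = self._active_components(b)
            eig = np.linalg.eigvals(J[b][np.ix_(comp, comp)])
            out[b] = np.max(eig.real) < 1e-10
        return out

    def _relax(self, Y: np.ndarray, t_total: float, dt: float = 10.0) -> np.ndarray:
        """Exponential-Euler relaxation of the full batch.

        Per step, gating variables and coupling voltages are frozen and every
        voltage/calcium component is moved exponentially toward its
        instantaneous equilibrium; unconditionally stable, so it follows the
        flow into the correct basin at large steps.  Used to escape unstable
        fixed points before Newton polishing.
        """
        p = self.params
        nd = self.n_dyn
        Y = Y.copy()
        n_steps = max(int(round(t_total / dt)), 1)
        ef, eb = self._ef_col, self._eb_col
        for _ in range(n_steps):
            V = Y[:, :nd]
            Ca = Y[:, nd : 2 * nd]
            Vf = self._vfull(Y)
            H = expit(self._gamma_pre * (Vf - self._theta_pre))
            wh = np.einsum("bij,bj->bi", self._W, H)
            syn_c = np.einsum("bij,bj->bi", self._Wrev, H)
            gap_c = np.einsum("bij,bj->bi", self._G, Vf)
            m = ca_gate(V)
            caf = Ca / (p.K_D + Ca)
            g_ion = p.g_L + p.g_Ca * m * m + p.g_KCa * caf
            c_ion = p.g_L * p.V_L + p.g_Ca * m * m * p.V_Ca + p.g_KCa * caf * p.V_K
            g_tot = g_ion + wh[:, self._dyn_cols] + self._Gsum[:, self._dyn_cols]
            c_tot = (
                c_ion + syn_c[:, self._dyn_cols] + gap_c[:, self._dyn_cols] + self._X
            )
            v_inf = c_tot / np.maximum(g_tot, 1e-12)
            decay = np.exp(-g_tot * dt / p.C)
            V_new = np.where(
                self._a_dyn > 0, v_inf + (V - v_inf) * decay, V
            )
            influx = (
                -2.0 * p.g_Ca * m * m * (V - p.V_Ca) / (p.d_cm * p.F) * CA_UNIT_FACTOR
            )
            ca_inf = p.tau_Ca * influx
            Ca_new = np.where(
                self._a_dyn > 0,
                ca_inf + (Ca - ca_inf) * np.exp(-dt / p.tau_Ca),
                Ca,
            )
            for col, k in ((ef, 2 * nd), (eb, 2 * nd + 1)):
                g_p = p.g_L + wh[:, col] + self._Gsum[:, col]
                c_p = p.g_L * p.V_L + syn_c[:, col] + gap_c[:, col]
                vi = c_p / np.maximum(g_p, 1e-12)
                Y[:, k] = vi + (Y[:, k] - vi) * np.exp(-g_p * dt / p.C)
            Y[:, :nd] = V_new
            Y[:, nd : 2 * nd] = Ca_new
        return Y

    def _rhs_single(self, b: int):
        """Closure over the rhs restricted to one variant."""
        sel = np.array([b])

        def fun(t, y):
            return self.rhs(y[None], sel)[0]

        return fun

    def _integrate_window(
        self, b: int, y0: np.ndarray, rtol: float, atol: float, method: str = "RK45"
    ):
        sol = solve_ivp(
            self._rhs_single(b), (0.0, self.solver.t_window), y0,
            method=method, rtol=rtol, atol=atol,
        )
        return sol.y[:, -1]

    def _integrate_variant(self, b: int, y0: np.ndarray):
        """Windowed integration to stationarity (Dormand-Prince 5(4))."""
        cfg = self.solver
        fun = self._rhs_single(b)
        y = y0.copy()
        t = 0.0
        converged = False
        while t < cfg.t_max:
            ynew = self._integrate_window(b, y, cfg.rtol, cfg.atol)
            t += cfg.t_window
            f = fun(0.0, ynew)
            scaled = np.max(np.abs(f) / (1.0 + np.abs(ynew)))
            if scaled < cfg.stat_tol or np.max(np.abs(ynew - y)) < cfg.window_tol:
                y = ynew
                converged = True
                break
            y = ynew
        return y, converged

    def steady_states(
        self, method: str | None = None, init: np.ndarray | None = None
    ) -> list[SteadyStateResult]:
        """Stationary state of every variant in the panel.

        ``init`` optionally overrides the default initial condition (a single
        state vector broadcast over variants, or one row per variant)."""
        cfg = self.solver
        method = method or cfg.method
        B, nd = self.B, self.n_dyn
        if init is not None:
            init = np.broadcast_to(
                np.asarray(init, dtype=float), (B, self.nstate)
            ).copy()
        if method == "hybrid":
            v0 = None
            if init is not None:
                v0 = np.concatenate([init[:, :nd], init[:, 2 * nd :]], axis=-1)
            Y, ok = self._newton(v0)
            stable = self._is_stable(Y) if cfg.check_stability else np.ones(B, bool)
            good = ok & stable
            msg = np.where(good, "newton", "fallback-integration")
            # variants where Newton landed on an unstable branch (or failed):
            # follow the true flow from the default initial condition in
            # windows, polishing with plain Newton after each window
            if not good.all():
                Yb = init.copy() if init is not None else self._init_y()
                t = 0.0
                while (~good).any() and t < cfg.t_max:
                    Yb = self._relax(Yb, cfg.t_window)
                    t += cfg.t_window
                    v0 = np.concatenate([Yb[:, :nd], Yb[:, 2 * nd :]], axis=-1)
                    Yp, okp = self._newton(v0, dt0=1e9)
                    stp = (
                        self._is_stable(Yp) if cfg.check_stability
                        else np.ones(B, bool)
                    )
                    newly = ~good & okp & stp
                    Y[newly] = Yp[newly]
                    stable[newly] = stp[newly]
                    good |= newly
            full = self.rhs(Y)
            results = []
            for b in range(B):
                comp = self._active_components(b)
                resid = float(np.max(np.abs(full[b][comp])))
                results.append(
                    SteadyStateResult(
                        state=CircuitState.from_vector(self.dyn, Y[b]),
                        residual=resid,
                        converged=bool(good[b] and resid < 1e-7),
                        method="hybrid",
                        stable=bool(stable[b]) if cfg.check_stability else None,
                        message=str(msg[b]),
                    )
                )
            return results
        # pure integration (Dormand-Prince 5(4)) with windowed stationarity
        results = []
        Y0 = init if init is not None else self._init_y()
        Yf = Y0.copy()
        for b in range(B):
            yb, conv = self._integrate_variant(b, Y0[b])
            Yf[b] = yb
        full = self.rhs(Yf)
        for b in range(B):
            comp = self._active_components(b)
            resid = float(np.max(np.abs(full[b][comp])))
            yb, conv = Yf[b], resid < 1e-6
            results.append(
                SteadyStateResult(
                    state=CircuitState.from_vector(self.dyn, yb),
                    residual=resid,
                    converged=bool(conv),
                    method="dopri",
                )
            )
        return results

    def current_decomposition(self, Y: np.ndarray) -> list[dict[str, dict[str, float]]]:
        """Named current components per non-ablated neuron, per variant."""
        cur = self.currents(Y)
        out = []
        for b in range(self.B):
            per = {}
            for j, node in enumerate(self.nodes):
                if node == "ASH" or self._alive[b, j] == 0:
                    continue
                per[node] = {name: float(c[b, j]) for name, c in cur.items()}
            out.append(per)
        return out


# -- single-variant functional surface ------------------------------------


def _single_ensemble(c, cs, eps, sigma, p, ab, solver=None) -> CircuitEnsemble:
    ab = ab or AblationSpec("wild_type")
    ens = CircuitEnsemble(c, cs, [ab], solver=solver)
    ens.configure(eps, sigma, p)
    return ens


def derivatives(
    state: CircuitState,
    c: Connectome,
    cs: ConnectionSet,
    eps: PolarityMatrix,
    sigma: InputPattern,
    p: PhysioParams,
    ab: AblationSpec | None = None,
) -> CircuitState:
    """Time derivative d(state)/dt of the 14-dimensional circuit model."""
    ens = _single_ensemble(c, cs, eps, sigma, p, ab)
    dy = ens.rhs(state.y[None])[0]
    return CircuitState.from_vector(ens.dyn, dy)


def steady_state(
    c: Connectome,
    cs: ConnectionSet,
    eps: PolarityMatrix,
    sigma: InputPattern,
    p: PhysioParams,
    ab: AblationSpec | None = None,
    init: CircuitState | None = None,
    solver: SolverConfig | None = None,
) -> SteadyStateResult:
    """Stationary solution of the circuit for one ablation variant.

    ``init`` overrides the default initial condition (V = V_L, calcium at
    its closed form).  Non-convergence is reported through the ``converged``
    flag, never raised.
    """
    ens = _single_ensemble(c, cs, eps, sigma, p, ab, solver=solver)
    init_y = init.y[None] if init is not None else None
    return ens.steady_states(init=init_y)[0]


def current_decomposition(
    s: CircuitState,
    c: Connectome,
    cs: ConnectionSet,
    eps: PolarityMatrix,
    sigma: InputPattern,
    p: PhysioParams,
    ab: AblationSpec | None = None,
) -> dict[str, dict[str, float]]:
    """Six named membrane-current components per non-ablated neuron.

    Sign convention: inward (depolarizing) positive; at a stationary state the
    components of each neuron sum to zero.
    """
    ens = _single_ensemble(c, cs, eps, sigma, p, ab)
    return ens.current_decomposition(s.y[None])[0]
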
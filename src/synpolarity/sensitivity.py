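"""Post-fit analyses: polarity-flip scan, input-pattern enumeration,
cut-off sweep with random sub-threshold polarities, 1-D parameter sweeps,
and per-variant activity/current reports."""

from __future__ import annotations

from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .connectome import Connectome, reduce_by_cutoff
from .neurodynamics import (
    InputPattern,
    PhysioParams,
    PolarityMatrix,
    SolverConfig,
)
from .objective import BehavioralData, PanelEvaluator

__all__ = [
    "flip_scan",
    "input_pattern_scan",
    "cutoff_scan",
    "parameter_sweep",
    "ablation_report",
]

SWEEPABLE = ("X_o", "q_s", "q_e", "g_Ca", "g_KCa")


def flip_scan(
    ev: PanelEvaluator,
    eps: PolarityMatrix,
    sigma: InputPattern,
    params: PhysioParams,
) -> pd.DataFrame:
    """SED after flipping each free polarity bit, one at a time.

    Rows are ordered by decreasing connection weight; a final
    ``all_excitatory`` row scores the configuration with every free bit
    set to 1.  The baseline itself is included as column ``sed_baseline``.
    """
    base = ev(eps, sigma, params).sed
    rows = []
    for conn in ev.connset.free:
        flipped = eps.flip(conn)
        rows.append(
            {
                "connection": f"{conn[0]}->{conn[1]}",
                "weight": ev.connectome.weight(*conn),
                "sed": ev(flipped, sigma, params).sed,
            }
        )
    all_exc = PolarityMatrix(
        {conn: (1 if conn in ev.connset.free else eps[conn]) for conn in eps.eps}
    )
    rows.append(
        {
            "connection": "all_excitatory",
            "weight": np.nan,
            "sed": ev(all_exc, sigma, params).sed,
        }
    )
    df = pd.DataFrame(rows)
    df["sed_baseline"] = base
    df["sed_ratio"] = df["sed"] / base if base > 0 else np.inf
    return df


def input_pattern_scan(
    ev: PanelEvaluator,
    eps: PolarityMatrix,
    params: PhysioParams,
) -> pd.DataFrame:
    """Exhaustive SED over all 2^6 = 64 input patterns at fixed polarities."""
    receivers = tuple(ev.ensemble.dyn)
    rows = []
    for signs in product((-1, 1), repeat=len(receivers)):
        sigma = InputPattern(dict(zip(receivers, signs)))
        rows.append(
            {
                **{f"sigma_{n}": s for n, s in zip(receivers, signs)},
                "pattern": "".join("+" if s > 0 else "-" for s in signs),
                "sed": ev(eps, sigma, params).sed,
            }
        )
    return pd.DataFrame(rows).sort_values("sed", kind="stable").reset_index(drop=True)


def cutoff_scan(
    c: Connectome,
    cutoffs: Sequence[float],
    data: BehavioralData,
    sigma: InputPattern,
    params: PhysioParams,
    n_random: int = 100,
    seed: int = 0,
    solver: SolverConfig | None = None,
) -> pd.DataFrame:
    """Mean and spread of SED when sub-threshold polarities are randomized.

    For each cut-off, connections stronger than the cut-off are set
    inhibitory while the polarities of the weaker ones are drawn at random
    (``n_random`` versions); no connection is removed from the dynamics.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    cs = reduce_by_cutoff(c, 0.0)  # keep everything in the dynamics
    ev = PanelEvaluator(c, cs, data, solver=solver)
    rng = np.random.default_rng(seed)
    rows = []
    for cutoff in cutoffs:
        below = [conn for conn in cs.free if c.weight(*conn) <= cutoff]
        seds = np.empty(n_random)
        for k in range(n_random):
            bits = {conn: int(rng.integers(0, 2)) for conn in below}
            eps = PolarityMatrix.for_connection_set(cs, bits)
            seds[k] = ev(eps, sigma, params).sed
            if not below:
                seds[:] = seds[0]  # no randomness below this cut-off
                break
        rows.append(
            {
                "cutoff": cutoff,
                "n_random_connections": len(below),
                "sed_mean": float(seds.mean()),
                "sed_sd": float(seds.std(ddof=0)),
            }
        )
    return pd.DataFrame(rows)


def parameter_sweep(
    which: str,
    grid: Sequence[float],
    ev: PanelEvaluator,
    eps: PolarityMatrix,
    sigma: InputPattern,
    params: PhysioParams,
) -> pd.DataFrame:
    """1-D SED profile along one conductance or input parameter."""
    if which not in SWEEPABLE:
        raise ValueError(f"sweepable parameters are {SWEEPABLE}, got {which!r}")
    rows = []
    for v in grid:
        if v < 0:
            raise ValueError(f"{which} must be >= 0")
        rows.append({which: v, "sed": ev(eps, sigma, params.replace(**{which: v})).sed})
    return pd.DataFrame(rows)


def default_sweep_grid(baseline: float, n: int = 41, span: float = 1.0) -> np.ndarray:
    """Grid of n points spanning +-span (fractional) around the baseline."""
    lo = max(baseline * (1.0 - span), 0.0)
    hi = baseline * (1.0 + span)
    if hi == 0:
        hi = 1.0
    return np.linspace(lo, hi, n)


def ablation_report(
    ev: PanelEvaluator,
    eps: PolarityMatrix,
    sigma: InputPattern,
    params: PhysioParams,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Steady-state activities and current decompositions across the panel.

    Returns (activity table, current table, Spearman rank correlation between
    membrane voltage and calcium concentration across interneurons and
    variants).  Ablated neurons are absent from their variant's rows.
    """
    ens = ev.ensemble
    ens.configure(eps, sigma, params)
    states = ens.steady_states()
    Y = np.stack([s.state.y for s in states])
    decomp = ens.current_decomposition(Y)

    act_rows, cur_rows = [], []
    v_all, ca_all = [], []
    for b, (ab, st) in enumerate(zip(ens.ablations, states)):
        for k, n in enumerate(ens.dyn):
            if n in ab.ablated:
                continue
            act_rows.append(
                {
                    "variant": ab.label, "neuron": n,
                    "V": float(st.state.V[k]), "Ca": float(st.state.Ca[k]),
                    "converged": st.converged,
                }
            )
            v_all.append(st.state.V[k])
            ca_all.append(st.state.Ca[k])
        act_rows.append(
            {"variant": ab.label, "neuron": "E_f", "V": st.state.E_f,
             "Ca": np.nan, "converged": st.converged}
        )
        act_rows.append(
            {"variant": ab.label, "neuron": "E_b", "V": st.state.E_b,
             "Ca": np.nan, "converged": st.converged}
        )
        for n, comps in decomp[b].items():
            cur_rows.append({"variant": ab.label, "neuron": n, **comps,
                             "total": sum(comps.values())})
    rho = float(spearmanr(v_all, ca_all).statistic) if len(v_all) > 2 else np.nan
    return pd.DataFrame(act_rows), pd.DataFrame(cur_rows), rho
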
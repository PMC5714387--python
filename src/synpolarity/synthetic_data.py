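"""Planted-truth fixtures: ground-truth configurations, noisy behavioral
panels, and random small connectomes.

The behavioral table the inference pipeline fits is not shipped with the
package (the measured forward/backward timings live in the primary
literature), so every pipeline stage is exercised against data generated
from a fully known model: an "optimal" truth with all free connections
inhibitory and an input pattern exciting every receiver except AVA, or a
"random" truth drawn uniformly from the search ranges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .connectome import (
    AblationSpec,
    Connectome,
    ConnectionSet,
    default_connectome,
    default_panel,
    reduce_by_cutoff,
)
from .neurodynamics import (
    OPT_RANGES,
    InputPattern,
    PhysioParams,
    PolarityMatrix,
    SolverConfig,
)
from .objective import BehavioralData, PanelEvaluator

__all__ = ["GroundTruth", "make_truth", "make_behavioral_data", "make_random_connectome"]

#: lower bound on reported SDs, keeps SED finite for noise-free panels
SD_FLOOR = 0.01


@dataclass(frozen=True)
class GroundTruth:
    """A fully specified generating model for synthetic behavioral panels."""

    params: PhysioParams
    polarity: PolarityMatrix
    inputs: InputPattern
    connectome: Connectome
    connset: ConnectionSet
    panel: tuple[AblationSpec, ...]
    seed: int
    preset: str


def make_truth(
    preset: str = "optimal",
    seed: int = 0,
    connectome: Connectome | None = None,
    cutoff: float = 0.75,
    n_free: int | None = None,
    panel: Sequence[AblationSpec] | None = None,
) -> GroundTruth:
    """Build a generating model.

    ``optimal``: best-fit continuous parameters, all free connections
    inhibitory, input pattern sigma_AVA = -1 and +1 elsewhere.  ``random``:
    continuous parameters uniform over the search ranges, polarities and
    input signs uniform.  ``n_free`` keeps only the n strongest connections
    optimizable; the remaining above-cutoff connections stay in the dynamics
    with the planted polarity.
    """
    connectome = connectome or default_connectome()
    panel = tuple(panel) if panel is not None else tuple(default_panel())
    cs = reduce_by_cutoff(connectome, cutoff)
    if n_free is not None:
        cs = cs.restrict(n_free)

    rng = np.random.default_rng(seed)
    if preset == "optimal":
        params = PhysioParams()
        eps_bits = {conn: 0 for conn in cs.free}
        sigma = InputPattern.optimal()
    elif preset == "random":
        draws = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in OPT_RANGES.items()}
        draws["eta"] = max(draws["eta"], 1.0)
        params = PhysioParams().replace(**draws)
        eps_bits = {conn: int(rng.integers(0, 2)) for conn in cs.free}
        sigma = InputPattern(
            {n: int(1 - 2 * rng.integers(0, 2)) for n in InputPattern.optimal().sigma}
        )
    else:
        raise ValueError(f"unknown preset {preset!r}")

    polarity = PolarityMatrix.for_connection_set(cs, eps_bits)
    return GroundTruth(
        params=params,
        polarity=polarity,
        inputs=sigma,
        connectome=connectome,
        connset=cs,
        panel=panel,
        seed=seed,
        preset=preset,
    )


def make_behavioral_data(
    truth: GroundTruth,
    noise_sd: float = 0.0,
    seed: int = 0,
    solver: SolverConfig | None = None,
    r_th: np.ndarray | None = None,
) -> BehavioralData:
    """Generate a behavioral table from a planted truth.

    R_exp = clip(R_th + Normal(0, noise_sd), [0, 1]) per variant; the
    recorded SD is max(noise_sd, 0.01).  Clipping slightly biases variants
    whose true R sits near 0 or 1 (see docs).  noise_sd = 0 reproduces the
    theoretical ratios exactly, so the generating configuration scores
    SED ~ 0 by construction.  ``r_th`` may carry precomputed theoretical
    ratios for the panel (e.g. when drawing many noisy replicates of the
    same truth).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    labels = tuple(ab.label for ab in truth.panel)
    if r_th is None:
        data0 = BehavioralData(
            labels=labels,
            r_exp=np.full(len(truth.panel), 0.5),
            sd_exp=np.full(len(truth.panel), 1.0),
            panel=truth.panel,
        )
        ev = PanelEvaluator(truth.connectome, truth.connset, data0, solver=solver)
        r_th, _ = ev.ratios(truth.polarity, truth.inputs, truth.params)
    rng = np.random.default_rng(seed)
    r_exp = np.clip(r_th + rng.normal(0.0, noise_sd, size=r_th.shape), 0.0, 1.0)
    sd = np.full_like(r_exp, max(noise_sd, SD_FLOOR))
    return BehavioralData(labels=labels, r_exp=r_exp, sd_exp=sd, panel=truth.panel)


def make_random_connectome(
    n_neurons: int, density: float, seed: int = 0
) -> Connectome:
    """Random small circuit for reduced-size tests.

    Uses the first ``n_neurons`` canonical interneuron labels plus the two
    motor pools.  Directed chemical edges are drawn independently with
    probability ``density`` among the interneurons (so the expected edge
    count is density * n * (n - 1)); the gap matrix is symmetric with the
    same edge probability on unordered pairs.  Weights are integer contact
    counts in 1..10 with sd = 20% of the mean.
    """
    if n_neurons < 3:
        raise ValueError("n_neurons must be >= 3")
    if not (0 <= density <= 1):
        raise ValueError("density must be in [0, 1]")
    inter = ("AVA", "AVB", "AVD", "AVE", "PVC", "DVA", "ASH")[:n_neurons]
    nodes = inter + ("E_b", "E_f")
    n_all = len(nodes)
    rng = np.random.default_rng(seed)
    syn_mean = np.zeros((n_all, n_all))
    syn_sd = np.zeros((n_all, n_all))
    for i in range(n_neurons):
        for j in range(n_neurons):
            if i != j and rng.random() < density:
                w = float(rng.integers(1, 11))
                syn_mean[i, j] = w
                syn_sd[i, j] = round(0.2 * w, 3)
    gap = np.zeros((n_all, n_all))
    for i in range(n_neurons):
        for j in range(i + 1, n_neurons):
            if rng.random() < density:
                gap[i, j] = gap[j, i] = float(rng.integers(1, 6))
    return Connectome(
        nodes=nodes, syn_mean=syn_mean, syn_sd=syn_sd, gap=gap,
        fixed_excitatory=frozenset(),
    )
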
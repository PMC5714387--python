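"""Representation of the 9-node pre-motor locomotory circuit graph.

The circuit comprises five command-interneuron classes (AVA, AVB, AVD, AVE,
PVC), the sensory neuron DVA, the polysensory neuron ASH, and two motor-neuron
pools: E_b (A-type, backward) and E_f (B-type, forward).  Chemical synapses are
directed and carry a mean and standard deviation of contact counts (class
pairing introduces variability); gap junctions are symmetric contact counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "CANONICAL_NODES",
    "MOTOR_POOLS",
    "Connectome",
    "AblationSpec",
    "ConnectionSet",
    "load_connectome",
    "default_connectome",
    "load_ablation_panel",
    "default_panel",
    "reduce_by_cutoff",
    "polarity_space_size",
    "reshuffle_weights",
]

#: canonical node ordering; genome layouts and matrices follow this order
CANONICAL_NODES = ("AVA", "AVB", "AVD", "AVE", "PVC", "DVA", "ASH", "E_b", "E_f")
MOTOR_POOLS = ("E_b", "E_f")

Connection = tuple[str, str]  # (pre, post)


class ConnectomeError(ValueError):
    """Raised when a connectome file or matrix violates the schema."""


@dataclass(frozen=True)
class Connectome:
    """Directed chemical-synapse and symmetric gap-junction count matrices.

    Matrix convention: entry ``[i, j]`` is the connection from presynaptic
    node ``j`` onto postsynaptic node ``i`` (rows = post, columns = pre).
    """

    nodes: tuple[str, ...]
    syn_mean: np.ndarray
    syn_sd: np.ndarray
    gap: np.ndarray
    fixed_excitatory: frozenset[Connection] = field(default_factory=frozenset)

    def __post_init__(self):
        n = len(self.nodes)
        for name in ("syn_mean", "syn_sd", "gap"):
            m = getattr(self, name)
            if m.shape != (n, n):
                raise ConnectomeError(f"{name} must be {n}x{n}, got {m.shape}")
            bad = np.argwhere(m < 0)
            if bad.size:
                i, j = bad[0]
                raise ConnectomeError(
                    f"negative count in {name} at ({self.nodes[i]}, {self.nodes[j]})"
                )
        if np.any((self.syn_mean == 0) & (self.syn_sd != 0)):
            i, j = np.argwhere((self.syn_mean == 0) & (self.syn_sd != 0))[0]
            raise ConnectomeError(
                f"syn_sd nonzero where syn_mean is zero at ({self.nodes[i]}, {self.nodes[j]})"
            )
        if not np.allclose(self.gap, self.gap.T):
            i, j = np.argwhere(~np.isclose(self.gap, self.gap.T))[0]
            raise ConnectomeError(
                f"gap matrix asymmetric at ({self.nodes[i]}, {self.nodes[j]})"
            )
        diag = np.arange(n)
        if np.any(self.syn_mean[diag, diag]) or np.any(self.gap[diag, diag]):
            raise ConnectomeError("self-connections are not allowed")
        idx = self.index
        for pre, post in self.fixed_excitatory:
            if self.syn_mean[idx[post], idx[pre]] <= 0:
                raise ConnectomeError(
                    f"fixed excitatory connection {pre}->{post} has no synapses"
                )

    @property
    def index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.nodes)}

    def connections(self) -> list[Connection]:
        """All directed chemical connections with nonzero mean count."""
        out = []
        for i, post in enumerate(self.nodes):
            for j, pre in enumerate(self.nodes):
                if self.syn_mean[i, j] > 0:
                    out.append((pre, post))
        return out

    def weight(self, pre: str, post: str) -> float:
        idx = self.index
        return float(self.syn_mean[idx[post], idx[pre]])

    def total_weight(self) -> float:
        return float(self.syn_mean.sum())

    def to_json(self, path: str | Path) -> None:
        obj = {
            "nodes": list(self.nodes),
            "syn_mean": self.syn_mean.tolist(),
            "syn_sd": self.syn_sd.tolist(),
            "gap": self.gap.tolist(),
            "fixed_excitatory": [list(c) for c in sorted(self.fixed_excitatory)],
        }
        Path(path).write_text(json.dumps(obj, indent=1))


@dataclass(frozen=True)
class AblationSpec:
    """A circuit variant: the named subset of neurons removed (a_i = 0)."""

    label: str
    ablated: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        bad = set(self.ablated) & set(MOTOR_POOLS)
        if bad:
            raise ValueError(f"motor pools cannot be ablated: {sorted(bad)}")


@dataclass(frozen=True)
class ConnectionSet:
    """Result of the cut-off reduction of the chemical-connection space.

    ``free`` holds the connections whose polarity is optimized, ordered by
    decreasing mean weight (ties broken by node order) so that "the n
    strongest" is a prefix.  ``dropped`` connections are removed from the
    dynamics entirely.  Fixed-excitatory connections above the cut-off stay in
    the dynamics with polarity 1 but are never free.  ``frozen`` connections
    stay in the dynamics at a pinned polarity without being optimized (used
    when the search is restricted to the strongest connections).
    """

    free: tuple[Connection, ...]
    dropped: tuple[Connection, ...]
    cutoff: float
    fixed: tuple[Connection, ...] = ()
    frozen: tuple[Connection, ...] = ()

    @property
    def active(self) -> tuple[Connection, ...]:
        """Connections that participate in the dynamics."""
        return self.free + self.fixed + self.frozen

    def restrict(self, n_free: int) -> "ConnectionSet":
        """Keep only the ``n_free`` strongest connections optimizable; the
        rest of the free set is frozen (at inhibitory polarity by default)."""
        return ConnectionSet(
            free=self.free[:n_free],
            dropped=self.dropped,
            cutoff=self.cutoff,
            fixed=self.fixed,
            frozen=self.frozen + self.free[n_free:],
        )


def _as_matrix(raw, name: str, n: int) -> np.ndarray:
    try:
        m = np.asarray(raw, dtype=float)
    except (TypeError, ValueError) as exc:
        raise ConnectomeError(f"{name} is not numeric: {exc}") from exc
    if m.shape != (n, n):
        raise ConnectomeError(f"{name} must be {n}x{n}, got shape {m.shape}")
    return m


def load_connectome(path: str | Path) -> Connectome:
    """Load and validate a connectome from the documented JSON schema.

    Schema::

        {"nodes": [...], "syn_mean": [[...]], "syn_sd": [[...]],
         "gap": [[...]], "fixed_excitatory": [["E_b", "PVC"]]}
    """
    try:
        obj = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ConnectomeError(f"malformed JSON in {path}: {exc}") from exc
    for key in ("nodes", "syn_mean", "syn_sd", "gap"):
        if key not in obj:
            raise ConnectomeError(f"missing key {key!r} in {path}")
    nodes = tuple(obj["nodes"])
    n = len(nodes)
    return Connectome(
        nodes=nodes,
        syn_mean=_as_matrix(obj["syn_mean"], "syn_mean", n),
        syn_sd=_as_matrix(obj["syn_sd"], "syn_sd", n),
        gap=_as_matrix(obj["gap"], "gap", n),
        fixed_excitatory=frozenset(tuple(c) for c in obj.get("fixed_excitatory", [])),
    )


def default_connectome() -> Connectome:
    """The packaged 9-node circuit fixture (synthetic reconstruction).

    The fixture honors the documented counting structure of the circuit:
    38 optimizable chemical connections, 12 of them with mean contact count
    <= 0.75, AVA->E_b the unique strongest connection, and E_b->PVC the only
    fixed excitatory connection.  See ``data/connectome_synthetic.json``.
    """
    with resources.as_file(
        resources.files("synpolarity.data") / "connectome_synthetic.json"
    ) as p:
        return load_connectome(p)


def load_ablation_panel(path: str | Path) -> list[AblationSpec]:
    """Load an ablation panel from TSV with columns ``label``, ``ablated``.

    ``ablated`` is a comma-separated list of neuron names; empty for wild type.
    """
    specs: list[AblationSpec] = []
    seen = set()
    lines = Path(path).read_text().splitlines()
    header = lines[0].rstrip("\n").split("\t")
    if header[:2] != ["label", "ablated"]:
        raise ValueError(f"ablation panel must have columns label, ablated; got {header}")
    for line in lines[1:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        label = parts[0].strip()
        if label in seen:
            raise ValueError(f"duplicate variant label {label!r}")
        seen.add(label)
        raw = parts[1].strip() if len(parts) > 1 else ""
        ablated = frozenset(x.strip() for x in raw.split(",") if x.strip())
        specs.append(AblationSpec(label=label, ablated=ablated))
    return specs


def default_panel() -> list[AblationSpec]:
    """The packaged 18-variant panel (wild type + 17 ablations).

    A synthetic reconstruction: the exact composition of the published 17
    ablation variants is documented only in figure axes, so the packaged
    panel covers all single ablations plus multi-neuron removals including
    ASH alone and ASH with AVA / AVB, and is user-overridable.
    """
    with resources.as_file(
        resources.files("synpolarity.data") / "ablation_panel_synthetic.tsv"
    ) as p:
        return load_ablation_panel(p)


def _ordered_connections(c: Connectome) -> list[Connection]:
    """Connections sorted by decreasing mean weight; ties by node order."""
    idx = c.index
    conns = c.connections()
    return sorted(conns, key=lambda pp: (-c.weight(*pp), idx[pp[0]], idx[pp[1]]))


def reduce_by_cutoff(c: Connectome, cutoff: float = 0.75) -> ConnectionSet:
    """Drop connections with mean contact count <= ``cutoff``.

    Dropped connections are removed from the dynamics entirely; the remainder
    minus the fixed-excitatory set forms the free (optimizable) list.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    free, dropped, fixed = [], [], []
    for conn in _ordered_connections(c):
        w = c.weight(*conn)
        if w <= cutoff:
            dropped.append(conn)
        elif conn in c.fixed_excitatory:
            fixed.append(conn)
        else:
            free.append(conn)
    return ConnectionSet(
        free=tuple(free), dropped=tuple(dropped), cutoff=float(cutoff), fixed=tuple(fixed)
    )


def polarity_space_size(cs: ConnectionSet) -> int:
    """Number of binary excitation/inhibition patterns over the free set."""
    return 2 ** len(cs.free)


def reshuffle_weights(
    c: Connectome, n_draws: int = 100, n_select: int = 30, seed: int = 0
) -> list[Connectome]:
    """Draw connectome variants with weights in {m, m-sd, m+sd} per connection.

    Each of ``n_draws`` draws picks, independently and uniformly for every
    chemical connection, one of mean, mean-sd, mean+sd (clipped at 0 since
    contact counts cannot be negative).  The ``n_select`` draws whose total
    weight is closest to the all-mean total are returned; ties are broken by
    draw index so the result is deterministic for a given seed.
    """
    if n_select > n_draws:
        raise ValueError("n_select must be <= n_draws")
    rng = np.random.default_rng(seed)
    mask = c.syn_mean > 0
    target = c.total_weight()
    draws: list[Connectome] = []
    totals = np.empty(n_draws)
    for k in range(n_draws):
        shift = rng.integers(-1, 2, size=c.syn_mean.shape)  # -1, 0, +1
        w = np.where(mask, np.clip(c.syn_mean + shift * c.syn_sd, 0.0, None), 0.0)
        sd = np.where(w > 0, c.syn_sd, 0.0)
        draws.append(
            Connectome(
                nodes=c.nodes,
                syn_mean=w,
                syn_sd=sd,
                gap=c.gap,
                fixed_excitatory=c.fixed_excitatory,
            )
        )
        totals[k] = w.sum()
    order = np.argsort(np.abs(totals - target), kind="stable")
    return [draws[k] for k in order[:n_select]]
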
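"""Island genetic algorithm over binary-encoded circuit configurations.

A genome is a flat bit vector: a fixed-width binary slice per optimized
continuous parameter, one bit per input-receiving neuron for sigma
(1 -> +1, 0 -> -1) and one bit per free connection for the polarity epsilon.
Islands evolve independently (mutation based on three donor genomes,
20% crossover, greedy elitist replacement) and periodically broadcast the
global best genome, which replaces each island's worst member.  Results are
fully reproducible from the seed and independent of the parallel worker
count: each island owns a spawned random stream and is evolved as a pure
function of its state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from joblib import Parallel, delayed

from .neurodynamics import OPT_RANGES, InputPattern, PhysioParams, PolarityMatrix

__all__ = [
    "GenomeLayout",
    "GAConfig",
    "OptimizationResult",
    "mutate",
    "crossover",
    "select",
    "run_islands",
]

CONTINUOUS_ORDER = ("q_s", "q_e", "X_o", "c_ash", "f_ash", "eta")


@dataclass(frozen=True)
class GenomeLayout:
    """Named slices of the binary genome.

    ``continuous_fields`` may be any subset of the six optimized parameters
    (an empty tuple fixes them all at ``base_params``); ``sigma_neurons``
    and ``eps_connections`` define the discrete slices.
    """

    base_params: PhysioParams
    continuous_fields: tuple[str, ...] = CONTINUOUS_ORDER
    sigma_neurons: tuple[str, ...] = ()
    eps_connections: tuple[tuple[str, str], ...] = ()
    bits_per_field: int = 16
    ranges: Mapping[str, tuple[float, float]] = field(default_factory=lambda: OPT_RANGES)

    def __post_init__(self):
        unknown = set(self.continuous_fields) - set(CONTINUOUS_ORDER)
        if unknown:
            raise ValueError(f"unknown continuous fields {sorted(unknown)}")

    @property
    def n_continuous_bits(self) -> int:
        return self.bits_per_field * len(self.continuous_fields)

    @property
    def length(self) -> int:
        return self.n_continuous_bits + len(self.sigma_neurons) + len(self.eps_connections)

    @property
    def discrete_slice(self) -> slice:
        return slice(self.n_continuous_bits, self.length)

    def field_slice(self, name: str) -> slice:
        k = self.continuous_fields.index(name)
        return slice(k * self.bits_per_field, (k + 1) * self.bits_per_field)

    @property
    def quantization(self) -> dict[str, float]:
        """Worst-case rounding error per continuous field."""
        return {
            f: (self.ranges[f][1] - self.ranges[f][0]) / (2**self.bits_per_field - 1)
            for f in self.continuous_fields
        }

    # -- scalar <-> bits ---------------------------------------------------

    def _encode_value(self, name: str, x: float) -> np.ndarray:
        lo, hi = self.ranges[name]
        if not (lo <= x <= hi):
            raise ValueError(f"{name}={x} outside range [{lo}, {hi}]")
        levels = 2**self.bits_per_field - 1
        code = int(round((x - lo) / (hi - lo) * levels))
        bits = (code >> np.arange(self.bits_per_field - 1, -1, -1)) & 1
        return bits.astype(np.uint8)

    def _decode_value(self, name: str, bits: np.ndarray) -> float:
        lo, hi = self.ranges[name]
        weights = 1 << np.arange(self.bits_per_field - 1, -1, -1)
        code = int(np.dot(bits.astype(np.int64), weights))
        return lo + code / (2**self.bits_per_field - 1) * (hi - lo)

    def encode(
        self,
        params: PhysioParams,
        sigma: InputPattern | None = None,
        eps: PolarityMatrix | None = None,
    ) -> np.ndarray:
        g = np.zeros(self.length, dtype=np.uint8)
        for name in self.continuous_fields:
            g[self.field_slice(name)] = self._encode_value(name, getattr(params, name))
        off = self.n_continuous_bits
        for k, n in enumerate(self.sigma_neurons):
            g[off + k] = 1 if sigma[n] == 1 else 0
        off += len(self.sigma_neurons)
        for k, conn in enumerate(self.eps_connections):
            g[off + k] = eps[conn]
        return g

    def decode(
        self, genome: np.ndarray
    ) -> tuple[PhysioParams, dict[str, int], dict[tuple[str, str], int]]:
        """Decode bits into (params, sigma bits by neuron, eps bits by connection).

        Continuous values round-trip within one quantization step; discrete
        slices round-trip exactly.
        """
        if len(genome) != self.length:
            raise ValueError(f"genome length {len(genome)} != layout length {self.length}")
        kw = {
            name: self._decode_value(name, genome[self.field_slice(name)])
            for name in self.continuous_fields
        }
        params = self.base_params.replace(**kw) if kw else self.base_params
        off = self.n_continuous_bits
        sigma = {
            n: (1 if genome[off + k] else -1) for k, n in enumerate(self.sigma_neurons)
        }
        off += len(self.sigma_neurons)
        eps = {conn: int(genome[off + k]) for k, conn in enumerate(self.eps_connections)}
        return params, sigma, eps


@dataclass(frozen=True)
class GAConfig:
    """Island-GA settings; defaults mirror the published protocol
    (pool of 35 candidates, 30 inner loops between migrations, 20% crossover)."""

    islands: int = 4
    pool_size: int = 35
    inner_loops: int = 30
    crossover_fraction: float = 0.20
    stop_threshold: float = 1e-3
    max_migrations: int = 50
    seed: int = 0
    de_scale: float = 0.8           # DE/rand/1 factor on decoded continuous values
    discrete_mix_prob: float = 0.5  # per-bit mixing probability on discrete slices
    topology: str = "broadcast"     # or "ring"
    n_jobs: int = 1

    def __post_init__(self):
        if self.pool_size < 4:
            raise ValueError("pool_size must be >= 4 (mutation needs 3 donors)")
        if not (0 < self.crossover_fraction <= 1):
            raise ValueError("crossover_fraction must be in (0, 1]")
        if self.topology not in ("broadcast", "ring"):
            raise ValueError(f"unknown topology {self.topology!r}")


@dataclass(frozen=True)
class OptimizationResult:
    best_genome: np.ndarray
    best_sed: float
    best_params: PhysioParams
    best_sigma: dict[str, int]
    best_eps: dict[tuple[str, str], int]
    history: tuple[float, ...]             # global best SED after each migration
    island_history: tuple[tuple[float, ...], ...]
    n_migrations: int
    n_evaluations: int


def mutate(
    target: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    layout: GenomeLayout,
    rng: np.random.Generator,
    de_scale: float = 0.8,
    discrete_mix_prob: float = 0.5,
) -> np.ndarray:
    """Differential proposal built from three donor genomes.

    Continuous slices: decode a, b, c and re-encode a + de_scale * (b - c),
    clipped to the search ranges (so a = b = c reproduces a's values exactly
    up to quantization).  Discrete slices: per bit, take the mixed source
    a XOR (b AND c) with probability ``discrete_mix_prob``, else keep a's bit.
    """
    for g in (a, b, c):
        if len(g) != len(target):
            raise ValueError("genomes must share the layout length")
    if (a is b) or (b is c) or (a is c):
        raise ValueError("mutation donors must be three distinct genomes")
    out = a.copy()
    pa, _, _ = layout.decode(a)
    pb, _, _ = layout.decode(b)
    pc, _, _ = layout.decode(c)
    for name in layout.continuous_fields:
        lo, hi = layout.ranges[name]
        v = getattr(pa, name) + de_scale * (getattr(pb, name) - getattr(pc, name))
        out[layout.field_slice(name)] = layout._encode_value(
            name, float(np.clip(v, lo, hi))
        )
    ds = layout.discrete_slice
    n_disc = ds.stop - ds.start
    if n_disc:
        mixed = a[ds] ^ (b[ds] & c[ds])
        use = rng.random(n_disc) < discrete_mix_prob
        out[ds] = np.where(use, mixed, a[ds])
    return out


def crossover(
    x: np.ndarray, y: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Replace round(fraction * L) uniformly chosen entries of x by y's."""
    if len(x) != len(y):
        raise ValueError("genome length mismatch")
    L = len(x)
    k = int(round(fraction * L))
    out = x.copy()
    if k:
        pos = rng.choice(L, size=min(k, L), replace=False)
        out[pos] = y[pos]
    return out


def select(
    old: tuple[np.ndarray, float], new: tuple[np.ndarray, float]
) -> tuple[np.ndarray, float]:
    """Greedy elitist replacement; the incumbent survives ties."""
    return new if new[1] < old[1] else old


def _evolve_island(
    pool: list[np.ndarray],
    scores: list[float],
    rng: np.random.Generator,
    layout: GenomeLayout,
    cfg: GAConfig,
    objective: Callable[[np.ndarray], float],
) -> tuple[list[np.ndarray], list[float], int]:
    """Run ``inner_loops`` generations on one island (pure given rng state)."""
    n_eval = 0
    P = cfg.pool_size
    for _ in range(cfg.inner_loops):
        for t in range(P):
            donors = rng.choice(P - 1, size=3, replace=False)
            donors = [d if d < t else d + 1 for d in donors]
            ia, ib, ic = donors
            mutant = mutate(
                pool[t], pool[ia], pool[ib], pool[ic], layout, rng,
                de_scale=cfg.de_scale, discrete_mix_prob=cfg.discrete_mix_prob,
            )
            trial = crossover(pool[t], mutant, cfg.crossover_fraction, rng)
            trial_sed = objective(trial)
            n_eval += 1
            pool[t], scores[t] = select((pool[t], scores[t]), (trial, trial_sed))
    # the rng is returned so the advanced stream survives process boundaries
    return pool, scores, n_eval, rng


def run_islands(
    objective: Callable[[np.ndarray], float],
    layout: GenomeLayout,
    cfg: GAConfig | None = None,
) -> OptimizationResult:
    """Minimize the objective with the island genetic algorithm.

    Stops when the global best SED improves by less than ``stop_threshold``
    across two consecutive migrations, or at ``max_migrations``.  Objective
    failures must be returned as penalized scores by the caller; the loop
    itself never raises on a bad candidate.
    """
    cfg = cfg or GAConfig()
    L = layout.length
    if L == 0:
        raise ValueError("genome layout is empty")
    ss = np.random.SeedSequence(cfg.seed)
    island_rngs = [np.random.default_rng(s) for s in ss.spawn(cfg.islands)]

    pools: list[list[np.ndarray]] = []
    scores: list[list[float]] = []
    n_eval = 0
    for rng in island_rngs:
        pool = [rng.integers(0, 2, size=L).astype(np.uint8) for _ in range(cfg.pool_size)]
        sc = [objective(g) for g in pool]
        n_eval += cfg.pool_size
        pools.append(pool)
        scores.append(sc)

    history: list[float] = []
    island_history: list[list[float]] = [[] for _ in range(cfg.islands)]
    plateau = 0
    migrations = 0
    prev_best = min(min(s) for s in scores)

    parallel = Parallel(n_jobs=cfg.n_jobs, backend="loky") if cfg.n_jobs != 1 else None

    for migrations in range(1, cfg.max_migrations + 1):
        jobs = [
            (pools[i], scores[i], island_rngs[i], layout, cfg, objective)
            for i in range(cfg.islands)
        ]
        if parallel is None:
            results = [_evolve_island(*j) for j in jobs]
        else:
            results = parallel(delayed(_evolve_island)(*j) for j in jobs)
        for i, (pool, sc, ne, rng) in enumerate(results):
            pools[i], scores[i], island_rngs[i] = pool, sc, rng
            n_eval += ne
            island_history[i].append(min(sc))

        # migration: circulate the best genome(s)
        bests = [int(np.argmin(sc)) for sc in scores]
        if cfg.topology == "broadcast":
            gi = int(np.argmin([scores[i][bests[i]] for i in range(cfg.islands)]))
            g_best = pools[gi][bests[gi]].copy()
            s_best = scores[gi][bests[gi]]
            for i in range(cfg.islands):
                worst = int(np.argmax(scores[i]))
                pools[i][worst] = g_best.copy()
                scores[i][worst] = s_best
        else:  # ring: island i receives the best of island i-1
            migr = [
                (pools[i][bests[i]].copy(), scores[i][bests[i]])
                for i in range(cfg.islands)
            ]
            for i in range(cfg.islands):
                g, s = migr[(i - 1) % cfg.islands]
                worst = int(np.argmax(scores[i]))
                pools[i][worst] = g
                scores[i][worst] = s

        best_now = min(min(s) for s in scores)
        history.append(best_now)
        plateau = plateau + 1 if prev_best - best_now < cfg.stop_threshold else 0
        prev_best = best_now
        if plateau >= 2:
            break

    flat = [(g, s) for pool, sc in zip(pools, scores) for g, s in zip(pool, sc)]
    best_genome, best_sed = min(flat, key=lambda gs: gs[1])
    params, sigma, eps = layout.decode(best_genome)
    return OptimizationResult(
        best_genome=best_genome.copy(),
        best_sed=float(best_sed),
        best_params=params,
        best_sigma=sigma,
        best_eps=eps,
        history=tuple(history),
        island_history=tuple(tuple(h) for h in island_history),
        n_migrations=migrations,
        n_evaluations=n_eval,
    )
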
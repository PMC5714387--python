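import numpy as np
import pytest
from hypothesis import given, strategies as st

from synpolarity.neurodynamics import (
    OPT_RANGES,
    InputPattern,
    PhysioParams,
    PolarityMatrix,
)
from synpolarity.optimizer import (
    CONTINUOUS_ORDER,
    GAConfig,
    GenomeLayout,
    crossover,
    mutate,
    run_islands,
    select,
)

CONNS = (("AVA", "E_b"), ("AVD", "AVA"), ("AVE", "E_b"))
SIGMA6 = ("AVA", "AVB", "AVD", "AVE", "PVC", "DVA")


def _layout(**kw):
    defaults = dict(
        base_params=PhysioParams(),
        sigma_neurons=SIGMA6,
        eps_connections=CONNS,
    )
    defaults.update(kw)
    return GenomeLayout(**defaults)


class TestGenomeLayout:
    def test_length(self):
        lay = _layout()
        assert lay.length == 6 * 16 + 6 + 3

    def test_sigma_all_positive_encodes_ones(self):
        lay = _layout()
        g = lay.encode(
            PhysioParams(),
            InputPattern.uniform(SIGMA6, 1),
            PolarityMatrix({c: 0 for c in CONNS}),
        )
        off = lay.n_continuous_bits
        assert (g[off : off + 6] == 1).all()

    def test_lower_bounds_encode_all_zero(self):
        lay = _layout()
        p = PhysioParams().replace(
            **{k: OPT_RANGES[k][0] for k in CONTINUOUS_ORDER}
        )
        g = lay.encode(p, InputPattern.uniform(SIGMA6, -1),
                       PolarityMatrix({c: 0 for c in CONNS}))
        assert not g.any()

    @given(
        vals=st.tuples(*[st.floats(lo, hi) for lo, hi in OPT_RANGES.values()]),
        sig=st.tuples(*[st.sampled_from([-1, 1])] * 6),
        eps=st.tuples(*[st.sampled_from([0, 1])] * 3),
    )
    def test_roundtrip_within_quantization(self, vals, sig, eps):
        lay = _layout()
        p = PhysioParams().replace(**dict(zip(CONTINUOUS_ORDER, vals)))
        g = lay.encode(
            p,
            InputPattern(dict(zip(SIGMA6, sig))),
            PolarityMatrix(dict(zip(CONNS, eps))),
        )
        p2, sig2, eps2 = lay.decode(g)
        q = lay.quantization
        for name in CONTINUOUS_ORDER:
            assert abs(getattr(p2, name) - getattr(p, name)) <= q[name] / 2 + 1e-12
        assert tuple(sig2[n] for n in SIGMA6) == sig
        assert tuple(eps2[c] for c in CONNS) == eps

    def test_out_of_range_rejected(self):
        lay = _layout()
        with pytest.raises(ValueError, match="outside range"):
            lay.encode(
                PhysioParams(X_o=3.9).replace(q_s=0.08 - 0.0),
                InputPattern.uniform(SIGMA6),
                PolarityMatrix({c: 0 for c in CONNS}),
            )

    def test_discrete_only_layout(self):
        lay = _layout(continuous_fields=())
        assert lay.length == 9
        p, sig, eps = lay.decode(np.ones(9, dtype=np.uint8))
        assert p == PhysioParams()
        assert all(v == 1 for v in sig.values())


class TestOperators:
    def test_mutate_identical_donors_keeps_continuous(self):
        lay = _layout()
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, lay.length).astype(np.uint8)
        out = mutate(a.copy(), a.copy(), a.copy(), a.copy(), lay, rng)
        pa, _, _ = lay.decode(a)
        po, _, _ = lay.decode(out)
        q = lay.quantization
        for name in CONTINUOUS_ORDER:
            assert abs(getattr(po, name) - getattr(pa, name)) <= q[name] + 1e-12
        assert len(out) == lay.length

    def test_mutate_requires_distinct_donors(self):
        lay = _layout()
        rng = np.random.default_rng(0)
        a = np.zeros(lay.length, dtype=np.uint8)
        with pytest.raises(ValueError, match="distinct"):
            mutate(a, a, a, a, lay, rng)

    def test_mutation_covers_every_polarity_bit(self):
        lay = _layout()
        rng = np.random.default_rng(1)
        ds = lay.discrete_slice
        flipped = np.zeros(ds.stop - ds.start, dtype=int)
        for _ in range(2000):
            a, b, c = (
                rng.integers(0, 2, lay.length).astype(np.uint8) for _ in range(3)
            )
            t = rng.integers(0, 2, lay.length).astype(np.uint8)
            out = mutate(t, a, b, c, lay, rng)
            flipped += out[ds] != a[ds]
        assert (flipped > 0).all()

    def test_crossover_bounds(self):
        rng = np.random.default_rng(2)
        x = np.zeros(50, dtype=np.uint8)
        y = np.ones(50, dtype=np.uint8)
        assert (crossover(x, y, 0.0, rng) == x).all()
        assert (crossover(x, y, 1.0, rng) == y).all()
        out = crossover(x, y, 0.2, rng)
        assert (out != x).sum() <= round(0.2 * 50)

    def test_crossover_length_mismatch(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            crossover(np.zeros(3, np.uint8), np.zeros(4, np.uint8), 0.2, rng)

    def test_select_greedy_elitist(self):
        g1, g2 = np.zeros(4, np.uint8), np.ones(4, np.uint8)
        assert select((g1, 2.0), (g2, 1.0))[1] == 1.0
        kept = select((g1, 2.0), (g2, 2.0))
        assert kept[0] is g1  # tie keeps the incumbent


def _bitcount_objective(g):
    """Toy objective: number of set bits; optimum is the all-zero genome."""
    return float(np.sum(g))


class TestRunIslands:
    def test_constant_objective_stops_at_plateau(self):
        lay = _layout(continuous_fields=())
        cfg = GAConfig(islands=2, pool_size=6, inner_loops=2, max_migrations=30, seed=0)
        res = run_islands(lambda g: 1.0, lay, cfg)
        assert res.n_migrations == 2  # two consecutive no-improvement checks
        assert res.best_sed == 1.0

    def test_best_sed_monotone_over_migrations(self):
        lay = _layout(continuous_fields=())
        cfg = GAConfig(islands=3, pool_size=8, inner_loops=3, max_migrations=10, seed=1)
        res = run_islands(_bitcount_objective, lay, cfg)
        hist = np.array(res.history)
        assert (np.diff(hist) <= 0).all()

    def test_single_island_reduces_to_plain_ga(self):
        lay = _layout(continuous_fields=())
        cfg = GAConfig(islands=1, pool_size=10, inner_loops=5, max_migrations=20, seed=2)
        res = run_islands(_bitcount_objective, lay, cfg)
        assert res.best_sed == 0.0  # 9-bit space is easy for a single pool

    def test_seeded_determinism(self):
        lay = _layout(continuous_fields=())
        cfg = GAConfig(islands=2, pool_size=6, inner_loops=3, max_migrations=5, seed=7)
        r1 = run_islands(_bitcount_objective, lay, cfg)
        r2 = run_islands(_bitcount_objective, lay, cfg)
        np.testing.assert_array_equal(r1.best_genome, r2.best_genome)
        assert r1.history == r2.history

    def test_worker_count_does_not_change_result(self):
        lay = _layout(continuous_fields=())
        base = dict(islands=2, pool_size=6, inner_loops=3, max_migrations=4, seed=9)
        serial = run_islands(_bitcount_objective, lay, GAConfig(**base))
        parallel = run_islands(
            _bitcount_objective, lay, GAConfig(**base, n_jobs=2)
        )
        np.testing.assert_array_equal(serial.best_genome, parallel.best_genome)
        assert serial.history == parallel.history

    def test_ring_topology_runs(self):
        lay = _layout(continuous_fields=())
        cfg = GAConfig(
            islands=3, pool_size=6, inner_loops=2, max_migrations=4, seed=0,
            topology="ring",
        )
        res = run_islands(_bitcount_objective, lay, cfg)
        assert res.best_sed <= 2.0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GAConfig(pool_size=3)
        with pytest.raises(ValueError):
            GAConfig(crossover_fraction=0.0)
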
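import numpy as np
import pytest

from cyclehop import (
    AttractorSet,
    CellState,
    DynamicsParams,
    ExternalField,
    assign_state,
    build_coupling,
    overlap,
    pc_projection,
    population_mean_expression,
    simulate_population,
    state_distribution,
)


class TestOverlap:
    def test_self_and_negation(self, attractors64):
        assert overlap(attractors64.xi[3], attractors64, 3) == 1.0
        assert overlap(-attractors64.xi[3], attractors64, 3) == -1.0

    def test_random_state_concentrates_near_zero(self, attractors64):
        rng = np.random.default_rng(0)
        ms = [
            overlap(rng.choice([-1, 1], size=64), attractors64, 0)
            for _ in range(200)
        ]
        # binomial concentration: |m| <~ 3/sqrt(N) for almost all draws
        assert np.mean(np.abs(ms) <= 3 / np.sqrt(64)) > 0.95


class TestAssignState:
    def test_stored_pattern(self, attractors64):
        assert assign_state(attractors64.xi[3], attractors64) == 3

    def test_single_flip_keeps_assignment(self, attractors64):
        sigma = attractors64.xi[3].copy()
        sigma[10] *= -1
        assert assign_state(sigma, attractors64) == 3

    def test_exact_tie_breaks_to_lowest_index(self):
        shared = np.array([1, 1, -1, -1, 1, -1])
        others = [
            np.array([-1, 1, 1, -1, -1, 1]),
            np.array([1, -1, 1, 1, -1, -1]),
            np.array([-1, -1, -1, 1, 1, 1]),
            np.array([-1, 1, -1, 1, -1, 1]),
        ]
        xi = np.array([others[0], shared, others[1], others[2], others[3], shared])
        att = AttractorSet(xi=xi, gene_ids=[f"G{i}" for i in range(6)])
        assert assign_state(shared, att) == 1  # mu=1 and mu=5 tie; lowest wins


class TestMeanExpression:
    def test_identical_cells_reproduce_the_common_trajectory(self, attractors64):
        coupling = build_coupling(attractors64, 1.0, sparsify=False)
        params = DynamicsParams(T=0.0, update_prob=1.0)
        trace = simulate_population(
            coupling, attractors64, None, kappa=4, steps=8, params=params,
            init=("synchronized", 0), record_spins=True,
            rng=np.random.default_rng(0),
        )
        series = population_mean_expression(trace, gene=0)
        expected = [attractors64.xi[t % 8][0] for t in range(9)]
        assert np.array_equal(series, expected)

    def test_synchronized_population_decoheres(self, attractors300, coupling300, params):
        """<sigma_i(t)>_K is a decaying oscillation for synchronized starts.

        Individual cells stay at +/-1; only the ensemble mean decays, because
        stochastic transitions spread the cells' phases over time.
        """
        trace = simulate_population(
            coupling300, attractors300, None, kappa=50, steps=2000, params=params,
            init=("synchronized", 0), record_spins=True,
            rng=np.random.default_rng(4),
        )
        # oscillation amplitude per window as the RMS of the ensemble mean:
        # early it swings near +/-1, late it is residual sampling noise
        amplitudes_first, amplitudes_last = [], []
        for gene in range(0, 300, 30):
            series = population_mean_expression(trace, gene)
            quarter = series.size // 4
            amplitudes_first.append(series[:quarter].std())
            amplitudes_last.append(series[-quarter:].std())
        assert np.mean(amplitudes_last) < 0.5 * np.mean(amplitudes_first)
        # fully desynchronized: late-window time average near zero
        late_means = [
            population_mean_expression(trace, g)[-500:].mean() for g in range(0, 300, 30)
        ]
        assert np.all(np.abs(late_means) < 0.1)

    def test_requires_spin_history(self, attractors64):
        coupling = build_coupling(attractors64, 0.5)
        trace = simulate_population(
            coupling, attractors64, None, kappa=2, steps=5,
            params=DynamicsParams(), rng=np.random.default_rng(0),
        )
        with pytest.raises(ValueError, match="spin history"):
            population_mean_expression(trace, 0)


class TestStateDistribution:
    def test_delta_distribution(self, attractors64):
        coupling = build_coupling(attractors64, 0.0, sparsify=False)
        trace = simulate_population(
            coupling, attractors64, None, kappa=10, steps=4,
            params=DynamicsParams(T=0.0, update_prob=1.0),
            init=("synchronized", 2), rng=np.random.default_rng(0),
        )
        dist = state_distribution(trace)
        assert np.array_equal(dist.P[2], np.ones(5))
        assert np.array_equal(dist.P.sum(axis=0), np.ones(5))

    def test_normalization_always_exact(self, attractors300, coupling300, params):
        trace = simulate_population(
            coupling300, attractors300, None, kappa=37, steps=50, params=params,
            rng=np.random.default_rng(9),
        )
        dist = state_distribution(trace)
        assert np.allclose(dist.P.sum(axis=0), 1.0)
        assert dist.time_average.sum() == pytest.approx(1.0)

    def test_window_beyond_trace_errors(self, attractors64):
        coupling = build_coupling(attractors64, 0.5)
        trace = simulate_population(
            coupling, attractors64, None, kappa=3, steps=10,
            params=DynamicsParams(), rng=np.random.default_rng(0),
        )
        with pytest.raises(ValueError, match="window"):
            state_distribution(trace, t0=5, tau=100)


class TestSimulatePopulation:
    def test_overlapping_schedule_rejected(self, attractors64):
        coupling = build_coupling(attractors64, 0.5)
        zero = ExternalField.zero(64)
        with pytest.raises(ValueError, match="overlap"):
            simulate_population(
                coupling, attractors64, [(0, 10, zero), (5, 15, zero)],
                kappa=2, steps=20, params=DynamicsParams(),
            )

    def test_random_init_converges_into_the_cycle(self, attractors300, coupling300, params):
        trace = simulate_population(
            coupling300, attractors300, None, kappa=20, steps=600, params=params,
            init="random", record_spins=True, rng=np.random.default_rng(5),
        )
        xi = attractors300.xi.astype(float)
        post = trace.spins[:, :, 200:]  # after relaxation
        m_max = np.abs(
            np.einsum("knt,mn->kmt", post.astype(float), xi) / 300
        ).max(axis=1)
        assert (m_max > 0.8).mean() > 0.90

    def test_synchronized_occupancy_decays_to_uniform(self, attractors300, coupling300, params):
        trace = simulate_population(
            coupling300, attractors300, None, kappa=400, steps=1500, params=params,
            init=("synchronized", 0), rng=np.random.default_rng(6),
        )
        dist = state_distribution(trace)
        assert dist.P[0, 0] == 1.0  # fully synchronized start
        late = dist.P[:, -400:].mean(axis=1)
        assert np.abs(late - 1 / 8).max() < 0.04

    def test_strong_coherent_field_locks_assignment(self, attractors64):
        coupling = build_coupling(attractors64, 0.5)
        field = ExternalField(
            values=100.0 * attractors64.xi[5].astype(float),
            clamp_mask=np.zeros(64, bool),
        )
        trace = simulate_population(
            coupling, attractors64, [(0, 10, field)], kappa=5, steps=10,
            params=DynamicsParams(T=0.05, update_prob=1.0), init="random",
            rng=np.random.default_rng(7),
        )
        assert (trace.states[:, 1:] == 5).all()

    def test_half_ensembles_are_exchangeable(self, attractors300, coupling300, params):
        halves = []
        for seed in (100, 200):
            trace = simulate_population(
                coupling300, attractors300, None, kappa=500, steps=500, params=params,
                rng=np.random.default_rng(seed),
            )
            halves.append(state_distribution(trace, t0=200, tau=300).time_average)
        assert np.abs(halves[0] - halves[1]).max() < 0.03

    def test_circular_phase_variance_grows_on_average(self, attractors300, coupling300, params):
        """Synchronized ensembles only lose phase coherence, never regain it."""
        p = attractors300.p
        variances = []
        for rep in range(10):
            trace = simulate_population(
                coupling300, attractors300, None, kappa=60, steps=900, params=params,
                init=("synchronized", 0), rng=np.random.default_rng(1000 + rep),
            )
            angles = 2 * np.pi * trace.states / p
            resultant = np.abs(np.exp(1j * angles).mean(axis=0))
            variances.append(1.0 - resultant)
        mean_var = np.mean(variances, axis=0)
        thirds = np.array_split(mean_var, 3)
        means = [seg.mean() for seg in thirds]
        assert means[0] < means[1] < means[2]


class TestPCProjection:
    def test_antipodal_pairs_and_identity(self, attractors64):
        coords, attr_coords = pc_projection(attractors64.xi, attractors64)
        assert np.allclose(coords, attr_coords)
        center = attr_coords.mean(axis=0)
        for mu in range(4):
            assert np.allclose(
                attr_coords[mu] - center, -(attr_coords[mu + 4] - center), atol=1e-9
            )

    def test_attractors_form_an_ordered_ring(self, attractors300):
        _, attr_coords = pc_projection(attractors300.xi, attractors300)
        centered = attr_coords - attr_coords.mean(axis=0)
        angles = np.arctan2(centered[:, 1], centered[:, 0])
        unwrapped = np.unwrap(angles)
        diffs = np.diff(unwrapped)
        assert (diffs > 0).all() or (diffs < 0).all()

    def test_too_few_patterns_rejected(self):
        att = AttractorSet(
            xi=np.array([[1, -1, 1], [-1, 1, -1]]), gene_ids=["a", "b", "c"]
        )
        with pytest.raises(ValueError, match="p >= 3"):
            pc_projection(att.xi, att)
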
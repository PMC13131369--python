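import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mcmct_eval.barn_sim import ACTIVITIES, SimConfig, simulate_herd
from mcmct_eval.farm_config import FarmConfig
from mcmct_eval.system_emulator import (
    UNIDENTIFIED,
    ErrorModel,
    assign_identities,
    assign_identity,
    discrete_frechet,
    emulate,
    is_ghost_id,
    jitter_trajectory,
    make_reference_pool,
    uniform_confusion,
)

# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def frechet_by_coupling_enumeration(p, q):
    """Min over all monotone couplings of the max pointwise distance."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    n, m = len(p), len(q)
    best = [np.inf]

    def walk(i, j, cur):
        cur = max(cur, float(np.linalg.norm(p[i] - q[j])))
        if i == n - 1 and j == m - 1:
            best[0] = min(best[0], cur)
            return
        if i < n - 1:
            walk(i + 1, j, cur)
        if j < m - 1:
            walk(i, j + 1, cur)
        if i < n - 1 and j < m - 1:
            walk(i + 1, j + 1, cur)

    walk(0, 0, 0.0)
    return best[0]


def min_cost_assignment_enumeration(observations, pool, threshold):
    """Best total cost over all injective partial assignments; unassigned
    observations cost exactly ``threshold``."""
    keys = sorted(observations)
    refs = sorted(pool)
    dist = {
        (k, r): discrete_frechet(observations[k], pool[r]) for k in keys for r in refs
    }
    best = [np.inf]

    def rec(i, used, cost):
        if cost >= best[0]:
            return
        if i == len(keys):
            best[0] = cost
            return
        rec(i + 1, used, cost + threshold)  # leave unassigned
        for r in refs:
            if r not in used and dist[keys[i], r] < threshold:
                rec(i + 1, used | {r}, cost + dist[keys[i], r])

    rec(0, frozenset(), 0.0)
    return best[0]


coords = st.floats(-10, 10, allow_nan=False, allow_infinity=False)
trajectory = st.lists(st.tuples(coords, coords), min_size=1, max_size=6).map(np.array)


# --------------------------------------------------------------------------
# discrete Fréchet distance
# --------------------------------------------------------------------------

class TestDiscreteFrechet:
    def test_identical_sequences_give_zero(self, rng):
        traj = rng.normal(size=(7, 2))
        assert discrete_frechet(traj, traj) == 0.0

    def test_single_points_reduce_to_euclidean(self):
        assert discrete_frechet([(0.0, 0.0)], [(3.0, 4.0)]) == pytest.approx(5.0)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            discrete_frechet(np.empty((0, 2)), [(0.0, 0.0)])

    @given(p=trajectory, q=trajectory)
    def test_symmetry_and_nonnegativity(self, p, q):
        d = discrete_frechet(p, q)
        assert d >= 0.0
        assert d == pytest.approx(discrete_frechet(q, p))

    @given(p=trajectory, q=trajectory)
    def test_appending_far_point_never_decreases(self, p, q):
        far = np.array([[1e4, 1e4]])
        assert discrete_frechet(np.vstack([p, far]), q) >= discrete_frechet(p, q) - 1e-9

    def test_matches_coupling_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            p = rng.normal(size=(rng.integers(1, 6), 2))
            q = rng.normal(size=(rng.integers(1, 6), 2))
            assert discrete_frechet(p, q) == pytest.approx(
                frechet_by_coupling_enumeration(p, q), abs=1e-12
            )


# --------------------------------------------------------------------------
# identity association
# --------------------------------------------------------------------------

class TestIdentityAssignment:
    def test_exact_copy_wins(self, rng):
        pool = make_reference_pool(rng, ["C001", "C002", "C003"])
        assert assign_identity(pool["C002"], pool, threshold=5.0) == "C002"

    def test_threshold_gates_assignment(self, rng):
        pool = {"C001": np.zeros((3, 2))}
        obs = np.full((3, 2), 100.0)
        assert assign_identity(obs, pool, threshold=1.0) is None

    def test_tie_breaks_lexicographically(self):
        ref = np.zeros((2, 2))
        pool = {"C009": ref.copy(), "C002": ref.copy()}
        assert assign_identity(ref, pool, threshold=1.0) == "C002"

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            assign_identity(np.zeros((1, 2)), {}, threshold=1.0)

    def test_competing_observations_assigned_injectively(self, rng):
        pool = make_reference_pool(rng, ["C001", "C002"])
        obs = {
            "a": jitter_trajectory(pool["C001"], 0.01, rng),
            "b": jitter_trajectory(pool["C001"], 0.30, rng),
        }
        result = assign_identities(obs, pool, threshold=50.0)
        assigned = [v for v in result.values() if v is not None]
        assert len(assigned) == len(set(assigned))
        assert result["a"] == "C001"

    def test_batch_matches_minimum_cost_enumeration(self, rng):
        for trial in range(30):
            n_obs = int(rng.integers(1, 5))
            n_ref = int(rng.integers(1, 5))
            pool = {f"C{j:03d}": rng.normal(size=(4, 2)) for j in range(n_ref)}
            obs = {f"o{i}": rng.normal(size=(4, 2)) for i in range(n_obs)}
            threshold = float(rng.uniform(0.5, 4.0))
            result = assign_identities(obs, pool, threshold)
            cost = sum(
                discrete_frechet(obs[k], pool[r]) if r is not None else threshold
                for k, r in result.items()
            )
            assert cost == pytest.approx(
                min_cost_assignment_enumeration(obs, pool, threshold), abs=1e-9
            )

    def test_jittered_pool_recovered(self, rng):
        ids = [f"C{i:03d}" for i in range(1, 21)]
        pool = make_reference_pool(rng, ids, spread=60.0)
        obs = {cid: jitter_trajectory(pool[cid], 0.05, rng) for cid in ids}
        result = assign_identities(obs, pool, threshold=5.0)
        assert all(result[cid] == cid for cid in ids)


# --------------------------------------------------------------------------
# error-model emulation
# --------------------------------------------------------------------------

def _noiseless():
    return ErrorModel()


class TestEmulate:
    def test_noiseless_passthrough(self, small_sim, small_farm):
        truth, visits = small_sim
        records, snaps = emulate(truth, visits, _noiseless(), 1)
        assert (records["assigned_id"].to_numpy() == truth["cow_id"].astype(str).to_numpy()).all()
        assert (records["activity"].to_numpy() == truth["activity"].to_numpy()).all()
        assert (records["zone"].to_numpy() == truth["zone"].to_numpy()).all()
        sizes = snaps.groupby(["day", "tick_minute"], observed=True).size()
        assert (sizes == small_farm.n_cows).all()
        assert len(sizes) == 3 * 288

    def test_total_daily_miss_empties_outputs(self, small_sim):
        truth, visits = small_sim
        records, snaps = emulate(truth, visits, ErrorModel(daily_miss=1.0), 1)
        assert len(records) == 0 and len(snaps) == 0

    def test_suppressed_cow_day_fraction_is_binomial(self):
        farm = FarmConfig("T", 50, 500.0, 50, 1, 1, 1)
        truth, visits = simulate_herd(farm, SimConfig(seed=4, n_days=20))
        records, _ = emulate(truth, visits, ErrorModel(daily_miss=0.10), 12)
        observed = records.groupby(["day", "source_id"], observed=True).ngroups
        total = 50 * 20
        frac_suppressed = 1.0 - observed / total
        se = np.sqrt(0.1 * 0.9 / total)
        assert abs(frac_suppressed - 0.10) <= 3 * se

    def test_snapshots_never_duplicate_ids(self, small_emulation):
        *_, snaps = small_emulation
        assert not snaps.duplicated(["day", "tick_minute", "detected_id"]).any()

    def test_ghosts_live_outside_herd_namespace(self, small_emulation):
        truth, _, _, records, snaps = small_emulation
        herd = set(truth["cow_id"].astype(str))
        ghost_ids = {i for i in snaps["detected_id"] if is_ghost_id(i)}
        assert ghost_ids, "expected some ghosts at ghost_rate=0.15 over 3 days"
        assert not ghost_ids & herd

    def test_identity_error_split_between_swap_and_unidentified(self, small_sim):
        truth, visits = small_sim
        em = ErrorModel(id_correct=0.0, id_swap_share=0.5)
        records, _ = emulate(truth, visits, em, 3)
        real = records[~records["source_id"].map(is_ghost_id)]
        assert (real["assigned_id"] != real["source_id"]).all()
        share_unidentified = (real["assigned_id"] == UNIDENTIFIED).mean()
        assert 0.3 < share_unidentified < 0.7

    def test_night_thinning_reduces_night_snapshot_sizes(self, small_sim):
        truth, visits = small_sim
        em = ErrorModel(night_detect_drop=0.5)
        _, snaps = emulate(truth, visits, em, 6)
        from mcmct_eval.barn_sim import is_night

        sizes = snaps.groupby(["day", "tick_minute"], observed=True).size().reset_index(name="n")
        night = is_night(sizes["tick_minute"])
        assert sizes.loc[night, "n"].mean() < 0.7 * sizes.loc[~night, "n"].mean()

    def test_activity_confusion_applied_at_configured_rate(self, small_sim):
        truth, visits = small_sim
        em = ErrorModel(activity_confusion=uniform_confusion(0.7))
        records, _ = emulate(truth, visits, em, 9)
        real = records[~records["source_id"].map(is_ghost_id)]
        merged = real.merge(
            truth.assign(cow_id=truth["cow_id"].astype(str)),
            left_on=["day", "tick_minute", "source_id"],
            right_on=["day", "tick_minute", "cow_id"],
            suffixes=("_sys", "_gold"),
        )
        agree = (merged["activity_sys"].astype(str) == merged["activity_gold"].astype(str)).mean()
        assert abs(agree - 0.7) < 0.02

    def test_reproducible_for_fixed_seed(self, small_sim):
        truth, visits = small_sim
        em = ErrorModel(daily_miss=0.1, ghost_rate=0.2, id_correct=0.8)
        a = emulate(truth, visits, em, 77)
        b = emulate(truth, visits, em, 77)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_visits_outside_herd_rejected(self, small_sim):
        truth, visits = small_sim
        bad = visits.copy()
        bad["cow_id"] = bad["cow_id"].astype(str)
        bad.loc[bad.index[0], "cow_id"] = "Z999"
        with pytest.raises(ValueError, match="missing from truth"):
            emulate(truth, bad, _noiseless(), 1)


class TestErrorModelValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"daily_miss": 1.5},
            {"id_correct": -0.1},
            {"night_detect_drop": 2.0},
            {"activity_confusion": np.ones((6, 6))},
            {"activity_confusion": np.eye(5)},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ErrorModel(**kwargs).validate()

    def test_uniform_confusion_rows_stochastic(self):
        conf = uniform_confusion(0.9)
        assert conf.shape == (len(ACTIVITIES), len(ACTIVITIES))
        assert np.allclose(conf.sum(axis=1), 1.0)
        assert np.allclose(np.diag(conf), 0.9)
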
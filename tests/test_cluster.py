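import numpy as np
import pandas as pd
import pytest

from reprt import (
    RTTable,
    normalize_profiles,
    select_calibrants,
    som_cluster,
    to_wide,
    wide_to_long,
)


def _profiles(small_dataset):
    _, table, _, _ = small_dataset
    return normalize_profiles(to_wide(table), "per_cm_elution")


class TestNormalizeProfiles:
    def test_per_cm_elution_divides_by_column_max(self):
        m = pd.DataFrame({"c1": [1.0, 2.0, 4.0]}, index=["a", "b", "c"])
        out = normalize_profiles(m, "per_cm_elution")
        np.testing.assert_allclose(out["c1"], [0.25, 0.5, 1.0])

    def test_none_is_identity(self):
        m = pd.DataFrame({"c1": [1.0, 2.0]}, index=["a", "b"])
        pd.testing.assert_frame_equal(normalize_profiles(m, "none"), m)

    def test_minmax_maps_to_unit_interval(self):
        m = pd.DataFrame({"c1": [2.0, 4.0, 6.0]}, index=["a", "b", "c"])
        out = normalize_profiles(m, "per_cm_minmax")
        np.testing.assert_allclose(out["c1"], [0.0, 0.5, 1.0])

    def test_missing_cells_rejected_with_instruction(self):
        m = pd.DataFrame({"c1": [1.0, np.nan]}, index=["a", "b"])
        with pytest.raises(ValueError, match="fully observed"):
            normalize_profiles(m)


class TestSomCluster:
    def test_two_separated_blobs_perfectly_split(self, rng):
        # brute-force oracle: nearest-prototype must equal blob membership
        blob1 = rng.normal(0.2, 0.01, (20, 4))
        blob2 = rng.normal(0.8, 0.01, (20, 4))
        profiles = pd.DataFrame(
            np.vstack([blob1, blob2]),
            index=[f"m{i:02d}" for i in range(40)],
            columns=list("abcd"),
        )
        a = som_cluster(profiles, grid=(1, 2), epochs=500, seed=3)
        g1 = {a.groups[f"m{i:02d}"] for i in range(20)}
        g2 = {a.groups[f"m{i:02d}"] for i in range(20, 40)}
        assert len(g1) == len(g2) == 1 and g1 != g2

    def test_identical_profiles_collapse_to_one_unit(self):
        profiles = pd.DataFrame(
            np.full((10, 3), 0.5), index=[f"m{i}" for i in range(10)], columns=list("abc")
        )
        a = som_cluster(profiles, grid=(2, 2), epochs=200, seed=0)
        assert len(set(a.groups.values())) == 1

    def test_same_seed_is_bit_reproducible(self, small_dataset):
        profiles = _profiles(small_dataset)
        a1 = som_cluster(profiles, grid=(3, 3), epochs=800, seed=11)
        a2 = som_cluster(profiles, grid=(3, 3), epochs=800, seed=11)
        assert a1.groups == a2.groups
        pd.testing.assert_frame_equal(a1.prototypes, a2.prototypes)

    def test_group_numbering_matches_grid(self, small_dataset):
        profiles = _profiles(small_dataset)
        a = som_cluster(profiles, grid=(3, 3), epochs=800, seed=11)
        assert a.n_groups == 9
        assert all(1 <= g <= 9 for g in a.groups.values())

    def test_recovers_known_groups_above_chance(self, small_dataset):
        # noiseless group structure: SOM agreement must beat a permutation null
        _, _, _, truth = small_dataset
        profiles = normalize_profiles(
            truth.rt_clean / truth.rt_clean.max(axis=0), "none"
        )
        a = som_cluster(profiles, grid=(3, 3), epochs=2000, seed=5)
        labels_true = np.array([truth.groups[m] for m in profiles.index])
        labels_som = np.array([a.groups[m] for m in profiles.index])

        def agreement(lt, ls):
            # fraction of pairs consistently together/apart
            same_t = lt[:, None] == lt[None, :]
            same_s = ls[:, None] == ls[None, :]
            iu = np.triu_indices(len(lt), 1)
            return float((same_t == same_s)[iu].mean())

        obs = agreement(labels_true, labels_som)
        rng = np.random.default_rng(0)
        null = [
            agreement(labels_true, rng.permutation(labels_som)) for _ in range(100)
        ]
        assert obs > np.quantile(null, 0.99)


@pytest.fixture(scope="module")
def assignment(small_dataset):
    return som_cluster(_profiles(small_dataset), grid=(3, 3), epochs=1500, seed=2)


class TestSelectCalibrants:

    def test_every_group_contributes(self, assignment, small_dataset):
        _, table, _, _ = small_dataset
        n_groups = len(assignment.nonempty_groups)
        cal = select_calibrants(assignment, table, target_size=max(10, n_groups),
                                min_groups_covered=n_groups)
        covered = {assignment.groups[m] for m in cal.molecule_ids}
        assert covered >= set(assignment.nonempty_groups)

    def test_rt_range_coverage(self, assignment, small_dataset):
        _, table, _, _ = small_dataset
        cal = select_calibrants(assignment, table, target_size=20, min_groups_covered=3)
        wide = to_wide(table)
        sub = wide.loc[list(cal.molecule_ids)]
        span = (sub.max() - sub.min()) / (wide.max() - wide.min())
        assert (span >= 0.90).all()

    def test_growing_target_never_loses_coverage(self, assignment, small_dataset):
        _, table, _, _ = small_dataset
        prev_cov, prev_ids = 0, ()
        for size in (8, 12, 16, 24):
            cal = select_calibrants(assignment, table, size, min_groups_covered=3)
            cov = len({assignment.groups[m] for m in cal.molecule_ids})
            assert cov >= prev_cov
            # greedy is nested: earlier picks are a prefix of later ones
            assert cal.molecule_ids[: len(prev_ids)] == prev_ids
            prev_cov, prev_ids = cov, cal.molecule_ids

    def test_forced_selection_with_one_molecule_per_group(self):
        # 5 molecules, 5 singleton groups: selection is forced
        from reprt import BehaviorAssignment

        rts = [(f"m{i}", c, float(i + 1 + j)) for i in range(5) for j, c in enumerate("ab")]
        table = RTTable.from_records(rts)
        profiles = normalize_profiles(to_wide(table), "per_cm_elution")
        a = BehaviorAssignment(
            groups={f"m{i}": i + 1 for i in range(5)},
            n_groups=5,
            grid_shape=(1, 5),
            prototypes=profiles.set_axis(range(1, 6), axis=0),
        )
        cal = select_calibrants(a, table, target_size=5, min_groups_covered=5)
        assert sorted(cal.molecule_ids) == [f"m{i}" for i in range(5)]

    def test_infeasible_coverage_raises(self, assignment, small_dataset):
        _, table, _, _ = small_dataset
        with pytest.raises(ValueError):
            select_calibrants(assignment, table, target_size=30,
                              min_groups_covered=assignment.n_groups + 5)
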
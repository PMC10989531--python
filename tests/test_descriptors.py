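import numpy as np
import pandas as pd
import pytest

from jcoupling import (
    CouplingRecord,
    MolecularStructure,
    SENTINEL_DISTANCE,
    feature_names,
    featurize,
    perceive_bonds,
)
from jcoupling import descriptors as desc
from jcoupling.graph import enumerate_pairs

from conftest import apply_rigid_motion, random_rigid_motion


class TestPairDistance:
    def test_three_four_five(self):
        s = MolecularStructure("s", ("H", "C"), np.array([[0, 0, 0], [3.0, 4.0, 0]]))
        assert desc.pair_distance(s, 0, 1) == pytest.approx(5.0)
        assert desc.pair_distance(s, 1, 0) == pytest.approx(5.0)

    def test_self_distance_rejected(self, methane):
        with pytest.raises(ValueError):
            desc.pair_distance(methane, 2, 2)

    def test_methane_ch(self, methane):
        assert desc.pair_distance(methane, 0, 1) == pytest.approx(1.09, abs=1e-9)


class TestKnnHeteroatomDistances:
    def test_no_oxygen_gives_all_sentinels(self, methane):
        out = desc.knn_heteroatom_distances(methane, np.zeros(3), "O", k=6)
        assert out == [SENTINEL_DISTANCE] * 6

    def test_padding_after_available_atoms(self):
        s = MolecularStructure("s", ("O", "H"), np.array([[2.0, 0, 0], [0, 0, 0]]))
        out = desc.knn_heteroatom_distances(s, np.zeros(3), "O", k=3)
        assert out == [pytest.approx(2.0), SENTINEL_DISTANCE, SENTINEL_DISTANCE]

    def test_sorted_first_k(self):
        s = MolecularStructure(
            "s", ("O", "O", "O"),
            np.array([[1.0, 0, 0], [3.0, 0, 0], [2.0, 0, 0]]),
        )
        out = desc.knn_heteroatom_distances(s, np.zeros(3), "O", k=2)
        assert out == [pytest.approx(1.0), pytest.approx(2.0)]

    def test_excluded_atom_not_a_candidate(self):
        s = MolecularStructure("s", ("N", "N"), np.array([[0, 0, 0], [1.5, 0, 0]]))
        out = desc.knn_heteroatom_distances(s, s.coords[0], "N", k=2, exclude=(0,))
        assert out == [pytest.approx(1.5), SENTINEL_DISTANCE]


class TestMidpointDescriptors:
    def test_hydrocarbon_all_sentinel(self, ethane):
        rec = CouplingRecord("ethane", 2, 3, "2JHH")
        out = desc.midpoint_descriptors(ethane, rec)
        assert len(out) == 12
        assert out == [SENTINEL_DISTANCE] * 12

    def test_water_midpoint_oxygen_distance(self, water):
        rec = CouplingRecord("water", 1, 2, "2JHH")
        out = desc.midpoint_descriptors(water, rec)
        mid = 0.5 * (water.coords[1] + water.coords[2])
        assert out[0] == pytest.approx(float(np.linalg.norm(mid - water.coords[0])))
        assert out[1:6] == [SENTINEL_DISTANCE] * 5  # only one O
        assert out[6:] == [SENTINEL_DISTANCE] * 6  # no N


class TestTargetAtomDescriptors:
    def test_hydrocarbon_all_sentinel(self, ethane):
        rec = CouplingRecord("ethane", 2, 0, "1JCH")
        out = desc.target_atom_descriptors(ethane, rec)
        assert len(out) == 24
        assert out == [SENTINEL_DISTANCE] * 24

    def test_hh_type_rejected(self, ethane):
        rec = CouplingRecord("ethane", 2, 3, "2JHH")
        with pytest.raises(ValueError):
            desc.target_atom_descriptors(ethane, rec)

    def test_target_nitrogen_excluded_from_own_candidates(self):
        # H-N...N chain: the N target's nearest *other* N is at 2.5 A
        s = MolecularStructure(
            "dini", ("H", "N", "N"),
            np.array([[0, 0, 0], [1.01, 0, 0], [3.51, 0, 0]]),
        )
        rec = CouplingRecord("dini", 0, 1, "1JNH")
        out = desc.target_atom_descriptors(s, rec)
        atom1_n_block = out[18:24]
        assert atom1_n_block[0] == pytest.approx(2.5)


class TestSameTypeDistanceDescriptors:
    def test_singleton_identities(self, methane):
        rec = CouplingRecord("methane", 1, 0, "1JCH")
        out = dict(zip(desc.SAME_TYPE_NAMES,
                       desc.same_type_distance_descriptors([rec], rec, methane)))
        d = desc.pair_distance(methane, 1, 0)
        for g in ("mol", "h", "partner"):
            assert out[f"st_{g}_count"] == 1
            assert out[f"st_{g}_mean"] == pytest.approx(d)
            assert out[f"st_{g}_min"] == pytest.approx(d)
            assert out[f"st_{g}_max"] == pytest.approx(d)
            assert out[f"st_{g}_std"] == 0.0
            assert out[f"st_{g}_d_minus_mean"] == pytest.approx(0.0)
            assert out[f"st_{g}_d_over_mean"] == pytest.approx(1.0)
            assert out[f"st_{g}_rank"] == 1

    def test_two_record_hand_computation(self):
        # distances 1.0 and 3.0; the record under featurization has d = 1.0
        s = MolecularStructure(
            "s", ("C", "H", "H", "C"),
            np.array([[0, 0, 0], [1.0, 0, 0], [-3.0, 0, 0], [5.0, 5.0, 5.0]]),
        )
        r1 = CouplingRecord("s", 1, 0, "1JCH")
        r2 = CouplingRecord("s", 2, 0, "1JCH")
        out = dict(zip(desc.SAME_TYPE_NAMES,
                       desc.same_type_distance_descriptors([r1, r2], r1, s)))
        assert out["st_mol_mean"] == pytest.approx(2.0)
        assert out["st_mol_min"] == pytest.approx(1.0)
        assert out["st_mol_max"] == pytest.approx(3.0)
        assert out["st_mol_std"] == pytest.approx(1.0)  # population std
        assert out["st_mol_d_minus_mean"] == pytest.approx(-1.0)
        assert out["st_mol_d_over_mean"] == pytest.approx(0.5)
        assert out["st_mol_count"] == 2
        assert out["st_mol_rank"] == 1
        # the shared-partner group (both couple to carbon 0) equals the full group
        assert out["st_partner_mean"] == pytest.approx(2.0)
        # the shared-hydrogen group is the singleton {1.0}
        assert out["st_h_mean"] == pytest.approx(1.0)

    def test_record_must_belong_to_group(self, methane):
        r1 = CouplingRecord("methane", 1, 0, "1JCH")
        r2 = CouplingRecord("methane", 2, 0, "1JCH")
        with pytest.raises(ValueError):
            desc.same_type_distance_descriptors([r1], r2, methane)

    def test_output_length_is_49(self, methane):
        rec = CouplingRecord("methane", 1, 0, "1JCH")
        assert len(desc.same_type_distance_descriptors([rec], rec, methane)) == 49


class TestStandardMolecularDescriptors:
    def test_methane_counts_and_weight(self, methane):
        graph = perceive_bonds(methane)
        rec = CouplingRecord("methane", 1, 0, "1JCH")
        out = dict(zip(desc.MOLECULAR_DESCRIPTOR_NAMES,
                       desc.standard_molecular_descriptors(methane, graph, rec)))
        assert out["mol_num_atoms"] == 5
        assert out["mol_num_bonds"] == 4
        assert out["rdkit_MolWt"] == pytest.approx(16.043, abs=1e-3)

    def test_benzene_carbon_aromatic_flag(self, benzene):
        graph = perceive_bonds(benzene)
        rec = CouplingRecord("benzene", 6, 0, "1JCH")  # H6 bonded to C0
        out = dict(zip(desc.MOLECULAR_DESCRIPTOR_NAMES,
                       desc.standard_molecular_descriptors(benzene, graph, rec)))
        assert out["atom1_aromatic"] == 1.0
        assert out["atom1_in_ring"] == 1.0
        assert out["atom1_ring6"] == 1.0
        assert out["atom1_hyb_sp2"] == 1.0
        assert out["atom0_is_H"] == 1.0

    def test_output_length_is_210(self, ethane):
        graph = perceive_bonds(ethane)
        rec = CouplingRecord("ethane", 2, 0, "1JCH")
        assert len(desc.standard_molecular_descriptors(ethane, graph, rec)) == 210


class TestHHReplacementDescriptors:
    def test_methane_nearest_cn_is_own_carbon(self, methane):
        graph = perceive_bonds(methane)
        recs = [r for r in enumerate_pairs(methane, graph) if r.coupling_type == "2JHH"]
        rec = recs[0]
        out = dict(zip(desc.HH_REPLACEMENT_NAMES,
                       desc.hh_replacement_descriptors(methane, graph, rec, recs)))
        assert out["hh_nearest_cn"] == pytest.approx(1.09, abs=1e-9)
        # hydrocarbon: all 12 averaged heteroatom slots are sentinels
        for name in desc.HH_REPLACEMENT_NAMES[:12]:
            assert out[name] == SENTINEL_DISTANCE

    def test_symmetric_pair_average_equals_either(self, methane):
        # all methane hydrogens are equivalent, so averages equal per-atom values
        graph = perceive_bonds(methane)
        recs = [r for r in enumerate_pairs(methane, graph) if r.coupling_type == "2JHH"]
        rec = recs[0]
        out = desc.hh_replacement_descriptors(methane, graph, rec, recs)
        per_atom = desc._per_atom_same_type_stats(rec.atom_index_0, recs, methane)
        np.testing.assert_allclose(out[-4:], per_atom)

    def test_non_hh_rejected(self, methane):
        graph = perceive_bonds(methane)
        rec = CouplingRecord("methane", 1, 0, "1JCH")
        with pytest.raises(ValueError):
            desc.hh_replacement_descriptors(methane, graph, rec, [rec])


class TestFeaturize:
    @pytest.mark.parametrize(
        "ctype, mode, expected_length",
        [
            ("1JCH", "proposed", 296), ("2JCH", "proposed", 296), ("3JCH", "proposed", 296),
            ("1JNH", "proposed", 295), ("2JNH", "proposed", 295), ("3JNH", "proposed", 295),
            ("2JHH", "proposed", 289), ("3JHH", "proposed", 289),
            ("1JCH", "traditional", 211), ("3JHH", "traditional", 211),
        ],
    )
    def test_vector_lengths(self, ctype, mode, expected_length):
        assert len(feature_names(ctype, mode)) == expected_length

    def test_deterministic(self, ethane):
        graph = perceive_bonds(ethane)
        recs = [r for r in enumerate_pairs(ethane, graph) if r.coupling_type == "3JHH"]
        v1 = featurize(ethane, graph, recs[0], same_type_records=recs)
        v2 = featurize(ethane, graph, recs[0], same_type_records=recs)
        assert v1.names == v2.names
        np.testing.assert_array_equal(v1.values, v2.values)

    def test_nh_vector_omits_nearest_n_slot(self):
        s = MolecularStructure(
            "amine", ("N", "H", "H"),
            np.array([[0, 0, 0], [1.01, 0, 0], [-0.35, 0.95, 0]]),
        )
        graph = perceive_bonds(s)
        rec = CouplingRecord("amine", 1, 0, "1JNH")
        vec = featurize(s, graph, rec, same_type_records=[rec])
        assert len(vec) == 295
        assert "atom1_N_1" not in vec.names
        assert "atom1_N_2" in vec.names

    def test_rigid_motion_invariance(self, small_dataset):
        structures, couplings = small_dataset
        rng = np.random.default_rng(23)
        mol_ids = list(structures)[:5]
        for mol_id in mol_ids:
            structure = structures[mol_id]
            graph = perceive_bonds(structure)
            recs = [r for r in couplings if r.molecule_id == mol_id]
            by_type = {}
            for r in recs:
                by_type.setdefault(r.coupling_type, []).append(r)
            rot, shift = random_rigid_motion(rng)
            moved = apply_rigid_motion(structure, rot, shift)
            moved_graph = perceive_bonds(moved)
            for ctype, group in by_type.items():
                v1 = featurize(structure, graph, group[0], same_type_records=group)
                v2 = featurize(moved, moved_graph, group[0], same_type_records=group)
                assert np.max(np.abs(v1.values - v2.values)) < 1e-9

    def test_index_relabeling_invariance(self, ethane):
        rng = np.random.default_rng(3)
        perm = rng.permutation(ethane.n_atoms)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        shuffled = MolecularStructure(
            "ethane", tuple(ethane.elements[p] for p in perm), ethane.coords[perm]
        )
        graph = perceive_bonds(ethane)
        sgraph = perceive_bonds(shuffled)
        recs = [r for r in enumerate_pairs(ethane, graph) if r.coupling_type == "2JCH"]
        mapped = [
            CouplingRecord("ethane", int(inv[r.atom_index_0]), int(inv[r.atom_index_1]), "2JCH")
            for r in recs
        ]
        v1 = featurize(ethane, graph, recs[0], same_type_records=recs)
        v2 = featurize(shuffled, sgraph, mapped[0], same_type_records=mapped)
        np.testing.assert_allclose(v1.values, v2.values, atol=1e-9)

    def test_featurize_table_single_type_enforced(self, small_dataset):
        structures, couplings = small_dataset
        with pytest.raises(ValueError, match="single coupling type"):
            desc.featurize_table(structures, couplings)


class TestVarianceFilter:
    def _frame(self, values):
        # rdkit_MolWt is in the eligible toolkit block; pair_distance is not
        return pd.DataFrame({"rdkit_MolWt": values, "pair_distance": np.arange(len(values), dtype=float)})

    def test_96_of_100_identical_dropped(self):
        mask = desc.variance_filter(self._frame([1.0] * 96 + [2, 3, 4, 5]), threshold=0.95)
        assert not mask["rdkit_MolWt"]

    def test_all_distinct_kept(self):
        mask = desc.variance_filter(self._frame(list(np.arange(100.0))), threshold=0.95)
        assert mask["rdkit_MolWt"]

    def test_94_of_100_identical_kept(self):
        mask = desc.variance_filter(self._frame([1.0] * 94 + list(range(10, 16))), threshold=0.95)
        assert mask["rdkit_MolWt"]

    def test_exactly_95_dropped_under_at_least_convention(self):
        mask = desc.variance_filter(self._frame([1.0] * 95 + list(range(10, 15))), threshold=0.95)
        assert not mask["rdkit_MolWt"]

    def test_non_toolkit_columns_never_dropped(self):
        mask = desc.variance_filter(self._frame([1.0] * 100), threshold=0.95)
        assert mask["pair_distance"]

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            desc.variance_filter(pd.DataFrame(columns=["rdkit_MolWt"]))


class TestKnnProperties:
    """Property check: knn output is sorted, padded, and consistent with a
    brute-force candidate enumeration for arbitrary geometries."""

    from hypothesis import given, settings, strategies as st

    @given(
        n_oxygen=st.integers(min_value=0, max_value=8),
        k=st.integers(min_value=1, max_value=8),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_sorted_padded_and_complete(self, n_oxygen, k, seed):
        rng = np.random.default_rng(seed)
        elements = ("C",) + ("O",) * n_oxygen
        coords = np.vstack([np.zeros(3), rng.uniform(-5, 5, size=(n_oxygen, 3))])
        s = MolecularStructure("mol", elements, coords)
        point = rng.uniform(-5, 5, size=3)
        out = desc.knn_heteroatom_distances(s, point, "O", k=k)
        assert len(out) == k
        assert out == sorted(out)
        expected = sorted(
            float(np.linalg.norm(coords[i] - point)) for i in range(1, n_oxygen + 1)
        )[:k]
        np.testing.assert_allclose(out[: len(expected)], expected, rtol=1e-12)
        assert out[len(expected):] == [SENTINEL_DISTANCE] * (k - len(expected))
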
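"""Descriptor families against hand-computed values, brute-force oracles and
their geometric/combinatorial invariances."""

import numpy as np
import pytest

from cppspace.descriptors import (DescriptorConfig, UNDEFINED,
                                  compute_descriptor_matrix, constitutional,
                                  geary_from_arrays, graph_pattern_descriptors,
                                  morse_from_arrays, morse_signal,
                                  whim_symmetry_from_arrays)
from cppspace.properties import default_properties
from cppspace.structures import (PeptideSequence, build_peptide_graph,
                                 generate_conformer, topological_distances)

from .conftest import graph_from_smiles, random_connected_distance_matrix


def brute_geary(weights, dist, lag):
    """Independent double-loop implementation of the Geary autocorrelation."""
    A = len(weights)
    num = 0.0
    delta = 0
    for i in range(A):
        for j in range(A):
            if dist[i][j] == lag:
                delta += 1
                num += (weights[i] - weights[j]) ** 2
    wbar = sum(weights) / A
    denom = sum((w - wbar) ** 2 for w in weights) / (A - 1)
    if delta == 0 or denom == 0:
        return float("nan")
    return (num / (2 * delta)) / denom


def brute_morse(weights, coords, signal):
    """Independent double-loop pair sum for the 3D-MoRSE transform."""
    s = signal - 1
    total = 0.0
    A = len(weights)
    for i in range(A):
        for j in range(i + 1, A):
            r = float(np.linalg.norm(np.asarray(coords[i]) - np.asarray(coords[j])))
            x = s * r
            total += weights[i] * weights[j] * (1.0 if x == 0 else np.sin(x) / x)
    return total


class TestGeary:
    def test_three_atom_path_lag_one(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]])
        assert geary_from_arrays([1, 2, 3], d, 1) == pytest.approx(0.5)

    def test_equal_weights_undefined(self):
        d = np.array([[0, 1], [1, 0]])
        assert np.isnan(geary_from_arrays([2.0, 2.0], d, 1))

    def test_no_pair_at_lag_undefined(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]])
        assert np.isnan(geary_from_arrays([1, 2, 3], d, 3))

    def test_single_atom_error(self):
        with pytest.raises(ValueError):
            geary_from_arrays([1.0], np.zeros((1, 1)), 1)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(3, 12))
            d = random_connected_distance_matrix(rng, n)
            w = rng.uniform(0.5, 3.0, n)
            for lag in (1, 2, 3, 5):
                ours = geary_from_arrays(w, d, lag)
                ref = brute_geary(list(w), d.tolist(), lag)
                if np.isnan(ref):
                    assert np.isnan(ours)
                else:
                    assert ours == pytest.approx(ref, rel=1e-10)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        n = 9
        d = random_connected_distance_matrix(rng, n)
        w = rng.uniform(0.5, 3.0, n)
        perm = rng.permutation(n)
        for lag in (1, 2, 4):
            a = geary_from_arrays(w, d, lag)
            b = geary_from_arrays(w[perm], d[np.ix_(perm, perm)], lag)
            assert a == pytest.approx(b, rel=1e-12)


class TestMorse:
    def test_signal_one_counts_pairs(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(7, 3))
        assert morse_from_arrays(np.ones(7), coords, 1) == pytest.approx(21.0)

    def test_signal_one_weighted_closed_form(self):
        rng = np.random.default_rng(1)
        w = rng.uniform(0.5, 3.0, 9)
        coords = rng.normal(size=(9, 3))
        expected = (w.sum() ** 2 - (w ** 2).sum()) / 2
        assert morse_from_arrays(w, coords, 1) == pytest.approx(expected,
                                                                rel=1e-12)

    def test_two_atoms_at_pi_vanishes(self):
        coords = np.array([[0.0, 0, 0], [np.pi, 0, 0]])  # s=1 at signal 2
        assert morse_from_arrays([1.0, 1.0], coords, 2) == pytest.approx(
            0.0, abs=1e-12)

    def test_right_triangle_matches_oracle(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 1, 0]])
        ours = morse_from_arrays(np.ones(3), coords, 2)
        assert ours == pytest.approx(brute_morse([1, 1, 1], coords, 2),
                                     abs=1e-12)

    def test_matches_brute_force_on_random_conformers(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(2, 10))
            w = rng.uniform(0.5, 3.0, n)
            coords = rng.normal(scale=2.0, size=(n, 3))
            for sig in (1, 2, 5, 16, 32):
                ours = morse_from_arrays(w, coords, sig)
                assert ours == pytest.approx(
                    brute_morse(list(w), coords, sig), rel=1e-10, abs=1e-12)


def random_rigid_transform(rng):
    M = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(M)
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    t = rng.normal(scale=5.0, size=3)
    return Q, t


class TestWhimSymmetry:
    def test_homonuclear_diatomic_fully_symmetric(self):
        coords = np.array([[0.0, 0, 0], [1.5, 0, 0]])
        g = whim_symmetry_from_arrays([1.0, 1.0], coords, 1)
        assert g == pytest.approx(1.0)

    def test_four_collinear_unpaired_scores(self):
        coords = np.array([[-3.0, 0, 0], [-1.0, 0, 0], [2.0, 0, 0],
                           [5.0, 0, 0]])
        g = whim_symmetry_from_arrays(np.ones(4), coords, 1, tolerance=0.01)
        assert g == pytest.approx(1.0 / 3.0)

    def test_centrosymmetric_gives_one(self):
        coords = np.array([[-2.0, 0, 0], [-1.0, 0, 0], [1.0, 0, 0],
                           [2.0, 0, 0]])
        g = whim_symmetry_from_arrays(np.ones(4), coords, 1, tolerance=0.01)
        assert g == pytest.approx(1.0)

    def test_degenerate_axis_undefined(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        assert np.isnan(whim_symmetry_from_arrays(np.ones(3), coords, 2))

    def test_range_and_rigid_invariance(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(4, 12))
            w = rng.uniform(0.5, 3.0, n)
            coords = rng.normal(size=(n, 3))
            base = whim_symmetry_from_arrays(w, coords, 1)
            assert 0.0 < base <= 1.0
            Q, t = random_rigid_transform(rng)
            moved = coords @ Q.T + t
            assert whim_symmetry_from_arrays(w, moved, 1) == pytest.approx(
                base, abs=1e-9)


class TestGraphPatterns:
    def test_asparagine_has_nn_at_distance_four(self, asn_graph):
        assert graph_pattern_descriptors(asn_graph)["B04[N-N]"] == 1

    @pytest.mark.parametrize("aa,nct", [("V", 1), ("G", 0), ("L", 1),
                                        ("I", 1)])
    def test_tertiary_carbon_counts(self, residue_graphs, aa, nct):
        g, d = residue_graphs[aa]
        assert graph_pattern_descriptors(g, d)["nCt"] == nct

    def test_dipeptide_patterns(self, gg_graph):
        pat = graph_pattern_descriptors(gg_graph)
        assert pat["nRCONHR"] == 1
        assert pat["nROR"] == 0
        assert pat["T(N.S)"] == 0

    def test_aliphatic_ether_counted(self):
        assert graph_pattern_descriptors(graph_from_smiles("COC"))["nROR"] == 1

    def test_ester_oxygen_not_an_ether(self):
        # methyl acetate: the C(=O)-O carbon is sp2, so no aliphatic ether
        assert graph_pattern_descriptors(graph_from_smiles("CC(=O)OC"))["nROR"] == 0

    def test_primary_amide_not_secondary(self):
        # acetamide C(=O)NH2 lacks the N-substituted carbon
        assert graph_pattern_descriptors(graph_from_smiles("CC(N)=O"))["nRCONHR"] == 0

    def test_tns_sums_all_pairs(self, residue_graphs):
        g, d = residue_graphs["M"]
        pat = graph_pattern_descriptors(g, d)
        # free methionine: one N, one S at distance 4
        assert pat["T(N.S)"] == 4


class TestConstitutional:
    def test_glycine_mw(self, gly_graph):
        assert constitutional(gly_graph)["MW"] == pytest.approx(75.07,
                                                                abs=0.01)

    def test_dipeptide_mw(self, gg_graph):
        assert constitutional(gg_graph)["MW"] == pytest.approx(132.12,
                                                               abs=0.01)

    def test_all_carbon_mean_polarizability_is_one(self):
        from .conftest import bare_carbon_graph
        assert constitutional(bare_carbon_graph(4))["Mp"] == pytest.approx(1.0)

    def test_carbon_scaling_identity(self):
        table = default_properties()
        for prop in ("mass", "sanderson_en", "polarizability", "vdw_volume"):
            assert table.carbon_scaled("C", prop) == 1.0


class TestDescriptorMatrix:
    def test_default_grid_column_count(self):
        cfg = DescriptorConfig()
        cols = cfg.column_names()
        assert len(cols) == 8 * 4 + 32 * 5 + 3 * 5 + 7
        assert len(set(cols)) == len(cols)
        for name in ("GATS5m", "Mor15p", "G2e", "B04[N-N]", "T(N.S)",
                     "nCt", "nROR", "nRCONHR", "MW", "Mp"):
            assert name in cols

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            compute_descriptor_matrix([])

    def test_missing_conformer_lists_peptides(self, gg_graph):
        with pytest.raises(ValueError, match="GG"):
            compute_descriptor_matrix([(gg_graph, None)])

    def test_identical_peptides_identical_rows(self, gg_graph, gg_conformer):
        mat = compute_descriptor_matrix(
            [(gg_graph, gg_conformer), (gg_graph, gg_conformer)])
        assert mat.shape[0] == 2
        row0, row1 = mat.iloc[0], mat.iloc[1]
        assert row0.fillna(-999).equals(row1.fillna(-999))

    def test_2d_only_without_conformers(self, gg_graph):
        cfg = DescriptorConfig(include_3d=False)
        mat = compute_descriptor_matrix([(gg_graph, None)], cfg)
        assert mat.shape[1] == 8 * 4 + 7

    def test_csv_round_trip_preserves_undefined(self, tmp_path, gg_graph,
                                                gg_conformer):
        from cppspace.descriptors import (read_descriptor_csv,
                                          write_descriptor_csv)
        mat = compute_descriptor_matrix([(gg_graph, gg_conformer)])
        path = tmp_path / "m.csv"
        write_descriptor_csv(mat, path)
        assert "NA" in path.read_text()
        back = read_descriptor_csv(path)
        assert back.isna().equals(mat.isna())
        np.testing.assert_allclose(back.fillna(0).to_numpy(),
                                   mat.fillna(0).to_numpy(), rtol=1e-8)


class Test3DInvariance:
    def test_morse_rigid_invariance(self, gg_graph, gg_conformer):
        rng = np.random.default_rng(12)
        w = np.asarray(default_properties().weights(gg_graph.elements, "p"))
        base = morse_from_arrays(w, gg_conformer.coordinates, 15)
        for _ in range(25):
            Q, t = random_rigid_transform(rng)
            moved = gg_conformer.coordinates @ Q.T + t
            assert morse_from_arrays(w, moved, 15) == pytest.approx(
                base, abs=1e-9)

    def test_pattern_descriptors_invariant_under_renumbering(self):
        from rdkit import Chem
        g = build_peptide_graph(PeptideSequence("p", "MVN"))
        base = graph_pattern_descriptors(g)
        rng = np.random.default_rng(2)
        order = [int(i) for i in rng.permutation(g.n_atoms)]
        from cppspace.structures import MolecularGraph
        permuted = MolecularGraph(id="p2",
                                  mol=Chem.RenumberAtoms(g.mol, order))
        assert graph_pattern_descriptors(permuted) == base
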
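"""Contact maps, secondary structure, loop distance, clustering."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from shiftensemble.structure import (ALPHA, BETA, COIL, HELIX310, SS_CLASSES,
                                     TURN, ConformerEnsemble,
                                     ContactMapClusterer, assign_ss_builtin,
                                     cluster_ensemble, contact_map,
                                     loop_distance, read_ensemble,
                                     read_ss_assignments, silhouette,
                                     ss_proportions, write_ensemble)
from shiftensemble.synthetic import (SyntheticSpec, build_backbone,
                                     make_toy_ensemble, plan_dihedrals)

from conftest import make_residues


def toy_ensemble(n_conformers=4, n_res=20, seed=0):
    spec = SyntheticSpec(n_conformers=n_conformers, n_residues=n_res, seed=seed)
    return make_toy_ensemble(spec)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def test_pdb_round_trip(tmp_path):
    ensemble = toy_ensemble(n_conformers=5)
    path = tmp_path / "ens.pdb"
    write_ensemble(ensemble, path)
    back = read_ensemble(path)
    assert back.n_conformers == 5
    assert back.residue_numbers == ensemble.residue_numbers
    # PDB stores 3 decimals
    np.testing.assert_allclose(back.coords["CA"], ensemble.coords["CA"],
                               atol=1.5e-3)
    np.testing.assert_allclose(back.coords["H"], ensemble.coords["H"],
                               atol=1.5e-3)


def test_missing_ca_is_fatal(tmp_path):
    path = tmp_path / "bad.pdb"
    path.write_text(
        "MODEL        1\n"
        "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
        "ENDMDL\nEND\n")
    with pytest.raises(ValueError, match="CA"):
        read_ensemble(path)


# ---------------------------------------------------------------------------
# Contact map & loop distance
# ---------------------------------------------------------------------------

def test_contact_map_boundary_is_strict():
    ca = np.array([[0.0, 0, 0], [3.8, 0, 0], [3.8 + 7.6, 0, 0]])
    cmap = contact_map({"CA": ca})
    assert cmap.matrix[0, 1] and cmap.matrix[1, 0]      # 3.8 A: contact
    assert not cmap.matrix[1, 2]                         # 7.6 A: no contact
    assert cmap.matrix.diagonal().all()


def test_contact_map_matches_brute_force(rng):
    ca = rng.uniform(-20, 20, size=(30, 3))
    cmap = contact_map({"CA": ca}, cutoff=7.5)
    expected = np.array([[np.linalg.norm(a - b) < 7.5 for b in ca] for a in ca])
    np.testing.assert_array_equal(cmap.matrix, expected)


def test_contact_map_invariant_under_rigid_motion(rng):
    ca = rng.uniform(-15, 15, size=(25, 3))
    rot = Rotation.random(random_state=3).as_matrix()
    moved = ca @ rot.T + np.array([5.0, -2.0, 11.0])
    np.testing.assert_array_equal(contact_map({"CA": ca}).matrix,
                                  contact_map({"CA": moved}).matrix)


def test_loop_distance_definitions(rng):
    ca = np.zeros((30, 3))
    ca[16] = (0.0, 0.0, 0.0)
    ca[23] = (20.0, 0.0, 0.0)
    assert loop_distance({"CA": ca}) == pytest.approx(20.0)
    assert loop_distance({"CA": ca}, res_a=17, res_b=17) == 0.0
    coords = rng.uniform(-10, 10, size=(30, 3))
    assert loop_distance({"CA": coords}, res_a=5, res_b=12) == pytest.approx(
        np.linalg.norm(coords[4] - coords[11]))


# ---------------------------------------------------------------------------
# External assignments
# ---------------------------------------------------------------------------

STRIDE_BLOCK = """\
REM  -------------------- Secondary structure summary ----------------
ASG  ALA A    1    1    C   Coil        -60.00    140.00     100.0
ASG  GLU A    2    2    H   AlphaHelix  -57.00    -47.00      80.0
ASG  LEU A    3    3    G   310Helix    -49.00    -26.00      60.0
ASG  LYS A    4    4    E   Strand     -120.00    120.00      40.0
ASG  ASP A    5    5    T   Turn        -70.00    -10.00      90.0
"""


def dssp_text(codes_per_block):
    lines = []
    for codes in codes_per_block:
        lines.append("  #  RESIDUE AA STRUCTURE BP1 BP2  ACC")
        for i, code in enumerate(codes):
            lines.append(f"{i + 1:5d}{i + 1:5d} A A  {code}")
    return "\n".join(lines) + "\n"


def test_stride_parsing_and_mapping(tmp_path):
    path = tmp_path / "out.stride"
    path.write_text(STRIDE_BLOCK)
    labels = read_ss_assignments(path, "stride")
    assert labels.shape == (1, 5)
    assert list(labels[0]) == [COIL, ALPHA, HELIX310, BETA, TURN]


def test_stride_multiple_blocks_split_on_residue_reset(tmp_path):
    path = tmp_path / "two.stride"
    path.write_text(STRIDE_BLOCK + STRIDE_BLOCK)
    labels = read_ss_assignments(path, "stride")
    assert labels.shape == (2, 5)
    np.testing.assert_array_equal(labels[0], labels[1])


def test_dssp_parsing_matches_stride_for_same_labels(tmp_path):
    stride_path = tmp_path / "a.stride"
    stride_path.write_text(STRIDE_BLOCK)
    dssp_path = tmp_path / "a.dssp"
    dssp_path.write_text(dssp_text(["CHGET"]))
    np.testing.assert_array_equal(read_ss_assignments(stride_path, "stride"),
                                  read_ss_assignments(dssp_path, "dssp"))


def test_unknown_code_maps_to_coil_with_warning(tmp_path, caplog):
    path = tmp_path / "x.dssp"
    path.write_text(dssp_text(["CHZ"]))
    with caplog.at_level("WARNING"):
        labels = read_ss_assignments(path, "dssp")
    assert labels[0, 2] == COIL
    assert "unknown" in caplog.text.lower()


def test_block_length_mismatch_is_fatal(tmp_path):
    path = tmp_path / "bad.dssp"
    path.write_text(dssp_text(["CCH", "CC"]))
    with pytest.raises(ValueError, match="disagree"):
        read_ss_assignments(path, "dssp")


# ---------------------------------------------------------------------------
# Built-in assigner
# ---------------------------------------------------------------------------

def test_ideal_helix_interior_is_alpha(rng):
    atoms = build_backbone(*plan_dihedrals([("helix", 14)], rng))
    labels = assign_ss_builtin(atoms)
    assert all(lbl == ALPHA for lbl in labels[2:-2])


def test_ideal_310_helix_detected(rng):
    atoms = build_backbone(*plan_dihedrals([("310", 12)], rng))
    labels = assign_ss_builtin(atoms)
    assert all(lbl == HELIX310 for lbl in labels[3:-3])


def test_isolated_extended_chain_has_no_sheet(rng):
    atoms = build_backbone(*plan_dihedrals([("strand", 12)], rng))
    labels = assign_ss_builtin(atoms)
    assert BETA not in labels
    assert set(labels) <= {COIL, TURN}


def test_paired_strands_become_sheet(rng):
    strand = build_backbone(*plan_dihedrals([("strand", 10)], rng))
    ca = strand["CA"]
    axis = ca[-1] - ca[0]
    axis /= np.linalg.norm(axis)
    perp = np.cross(axis, [0.0, 0.0, 1.0])
    perp /= np.linalg.norm(perp)
    pair = {a: np.vstack([strand[a], strand[a] + 4.8 * perp]) for a in strand}
    labels = assign_ss_builtin(pair)
    assert (labels == BETA).sum() >= 12


def test_builtin_helix_agrees_with_psea_cross_check(rng):
    """Independent oracle: biotite's P-SEA labels an ideal helix 'a'."""
    import biotite.structure as bst
    atoms = build_backbone(*plan_dihedrals([("helix", 14)], rng))
    array = bst.AtomArray(14)
    array.chain_id = np.array(["A"] * 14)
    array.res_id = np.arange(1, 15)
    array.res_name = np.array(["ALA"] * 14)
    array.atom_name = np.array(["CA"] * 14)
    array.element = np.array(["C"] * 14)
    array.coord = atoms["CA"]
    psea = bst.annotate_sse(array)
    ours = assign_ss_builtin(atoms)
    interior = slice(3, 11)
    assert all(code == "a" for code in psea[interior])
    assert all(lbl == ALPHA for lbl in ours[interior])


# ---------------------------------------------------------------------------
# Proportions
# ---------------------------------------------------------------------------

def test_proportions_counting_oracle(rng):
    classes = np.array(SS_CLASSES, dtype=object)
    assignments = classes[rng.integers(0, 5, size=(40, 12))]
    profile = ss_proportions(assignments)
    for i in range(12):
        for cls in SS_CLASSES:
            expected = np.mean(assignments[:, i] == cls)
            assert profile.proportions.iloc[i][cls] == pytest.approx(expected)
    sums = profile.proportions.sum(axis=1)
    np.testing.assert_allclose(sums, 1.0, atol=1e-12)


def test_beta_core_uses_strict_majority():
    n = 10
    assignments = np.full((n, 3), COIL, dtype=object)
    assignments[:, 0] = BETA                      # P = 1.0 -> in B
    assignments[: n // 2, 1] = BETA               # P = 0.5 -> not in B
    profile = ss_proportions(assignments)
    assert profile.beta_core == (1,)
    assert profile.proportions.iloc[1][BETA] == pytest.approx(0.5)


def test_per_conformer_beta_fraction_over_core():
    assignments = np.array([[BETA, BETA, COIL],
                            [BETA, COIL, COIL],
                            [BETA, BETA, TURN]], dtype=object)
    profile = ss_proportions(assignments)
    assert profile.beta_core == (1, 2)
    np.testing.assert_allclose(profile.per_conformer_beta, [1.0, 0.5, 1.0])


def test_weighted_proportions_match_manual_average():
    assignments = np.array([[ALPHA, COIL], [BETA, COIL]], dtype=object)
    profile = ss_proportions(assignments, weights=np.array([0.75, 0.25]))
    assert profile.proportions.iloc[0][ALPHA] == pytest.approx(0.75)
    assert profile.proportions.iloc[0][BETA] == pytest.approx(0.25)
    assert profile.class_proportions[COIL] == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def planted_features(rng, n_a=12, n_b=8, d=120, flip=10):
    base = rng.random(d) < 0.3
    rows = []
    for k in range(n_a + n_b):
        v = base.copy()
        if k >= n_a:
            v[:flip] = ~v[:flip]
        v ^= rng.random(d) < 0.02
        rows.append(v)
    labels = np.array([0] * n_a + [1] * n_b)
    return np.array(rows, dtype=float), labels


def test_planted_partition_recovered_exactly(rng):
    X, truth = planted_features(rng)
    clusterer = ContactMapClusterer(n_clusters=2, random_state=1).fit(X)
    found = clusterer.labels_
    agreement = max(np.mean(found == truth), np.mean(found == 1 - truth))
    assert agreement == 1.0
    assert silhouette(clusterer.embedding_, found) > 0.5


def test_clustering_deterministic_given_seed(rng):
    X, _ = planted_features(rng)
    a = ContactMapClusterer(n_clusters=2, random_state=7).fit(X)
    b = ContactMapClusterer(n_clusters=2, random_state=7).fit(X)
    np.testing.assert_array_equal(a.labels_, b.labels_)
    np.testing.assert_allclose(a.embedding_, b.embedding_)


def test_identical_maps_have_zero_embedding_variance():
    X = np.tile((np.arange(45) % 3 == 0).astype(float), (6, 1))
    clusterer = ContactMapClusterer(n_clusters=1).fit(X)
    assert np.allclose(clusterer.explained_variance_, 0.0)
    np.testing.assert_allclose(clusterer.embedding_, 0.0, atol=1e-12)
    assert len(set(clusterer.labels_)) == 1


def test_component_variances_non_increasing(rng):
    X = rng.normal(size=(20, 30))
    clusterer = ContactMapClusterer(n_clusters=2, n_components=5).fit(X)
    assert np.all(np.diff(clusterer.explained_variance_) <= 1e-12)


def test_k_exceeding_support_is_error(rng):
    ensemble = toy_ensemble(n_conformers=4)
    w = np.array([0.5, 0.5, 0.0, 0.0])
    with pytest.raises(ValueError, match="exceeds"):
        cluster_ensemble(ensemble, w, k=3)


def test_weighted_clustering_uses_only_supported_conformers(rng):
    ensemble = toy_ensemble(n_conformers=6)
    w = np.array([0.4, 0.3, 0.3, 0.0, 0.0, 0.0])
    clusterer = cluster_ensemble(ensemble, w, k=2, seed=0)
    assert list(clusterer.supported_indices_) == [0, 1, 2]
    assert set(clusterer.representatives_.values()) <= {0, 1, 2}
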
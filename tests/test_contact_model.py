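"""Surface model: contact map, interface energies, canonical relabelling."""

import numpy as np
import pytest

import aggrevol as ag
from aggrevol.contact_model import (
    ALPHABET,
    ROTATIONS,
    contact_partner,
    interface_energy,
    interface_energy_at_rotation,
)

GRID = [(r, c) for r in range(1, 5) for c in range(1, 5)]


def brute_force_energy(face1, face2, rotation, matrix):
    """Independent double-loop oracle over the 4x4 grid."""
    total = 0.0
    for r in range(1, 5):
        for c in range(1, 5):
            pr, pc = contact_partner((r, c), rotation)
            total += matrix[face1.residue(r, c), face2.residue(pr, pc)]
    return total


def random_face(rng):
    return ag.SurfaceFace(rng.integers(0, 20, size=16, dtype=np.uint8))


class TestContactMatrix:
    def test_packaged_matrix_mean_and_symmetry(self, matrix):
        assert matrix.energies.shape == (20, 20)
        assert np.array_equal(matrix.energies, matrix.energies.T)
        assert matrix.mean_energy == pytest.approx(-0.057, abs=5e-4)
        assert (matrix.energies > 0).any() and (matrix.energies < 0).any()

    def test_zero_matrix_is_valid(self, tmp_path):
        lines = ["\t".join([""] + list(ALPHABET))]
        for aa in ALPHABET:
            lines.append("\t".join([aa] + ["0.0"] * 20))
        path = tmp_path / "zeros.tsv"
        path.write_text("\n".join(lines) + "\n")
        loaded = ag.load_contact_matrix(path)
        assert loaded.mean_energy == 0.0

    def test_asymmetric_table_rejected(self, tmp_path, matrix):
        e = matrix.energies.copy()
        e[ALPHABET.index("R"), ALPHABET.index("K")] += 0.5
        lines = ["\t".join([""] + list(ALPHABET))]
        for i, aa in enumerate(ALPHABET):
            lines.append("\t".join([aa] + [f"{v:.3f}" for v in e[i]]))
        path = tmp_path / "asym.tsv"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ag.ContactMatrixFormatError, match="asymmetric"):
            ag.load_contact_matrix(path)

    def test_non_numeric_cell_named(self, tmp_path):
        lines = ["\t".join([""] + list(ALPHABET))]
        for aa in ALPHABET:
            row = [aa] + ["0.0"] * 20
            if aa == "H":
                row[1 + ALPHABET.index("W")] = "oops"
            lines.append("\t".join(row))
        path = tmp_path / "bad.tsv"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ag.ContactMatrixFormatError, match=r"\(H,W\)"):
            ag.load_contact_matrix(path)


class TestContactPartner:
    @pytest.mark.parametrize("rotation", ROTATIONS)
    def test_involution_everywhere(self, rotation):
        for pos in GRID:
            partner = contact_partner(pos, rotation)
            assert contact_partner(partner, rotation) == pos

    def test_fixed_point_counts(self):
        for rotation, expected in [(0, 0), (90, 4), (180, 0), (270, 4)]:
            fixed = [p for p in GRID if contact_partner(p, rotation) == p]
            assert len(fixed) == expected, rotation

    def test_main_diagonal_self_contacts_at_90(self):
        # linear positions 1, 6, 11, 16 are (1,1), (2,2), (3,3), (4,4)
        assert contact_partner((2, 2), 90) == (2, 2)
        fixed = {p for p in GRID if contact_partner(p, 90) == p}
        assert fixed == {(1, 1), (2, 2), (3, 3), (4, 4)}

    def test_antidiagonal_self_contacts_at_270(self):
        assert contact_partner((1, 4), 270) == (1, 4)
        fixed = {p for p in GRID if contact_partner(p, 270) == p}
        assert fixed == {(1, 4), (2, 3), (3, 2), (4, 1)}

    def test_mirror_map_at_0(self):
        assert contact_partner((1, 1), 0) == (4, 1)

    def test_invalid_rotation(self):
        with pytest.raises(ValueError, match="rotation"):
            contact_partner((1, 1), 45)


class TestInterfaceEnergy:
    def test_uniform_face_energy(self, matrix):
        face = ag.SurfaceFace.from_letters("L" * 16)
        for rot in ROTATIONS:
            e = interface_energy_at_rotation(face, face, rot, matrix)
            assert e == pytest.approx(16 * matrix["L", "L"])
        other = ag.SurfaceFace.from_letters("K" * 16)
        assert interface_energy(face, other, matrix) == pytest.approx(
            16 * matrix["L", "K"]
        )

    def test_matches_brute_force_oracle(self, matrix, rng):
        for _ in range(50):
            f1, f2 = random_face(rng), random_face(rng)
            per_rot = [
                interface_energy_at_rotation(f1, f2, rot, matrix)
                for rot in ROTATIONS
            ]
            expected = [brute_force_energy(f1, f2, rot, matrix) for rot in ROTATIONS]
            assert per_rot == pytest.approx(expected)
            assert interface_energy(f1, f2, matrix) == pytest.approx(min(expected))

    def test_min_never_exceeds_unrotated(self, matrix, rng):
        for _ in range(20):
            f1, f2 = random_face(rng), random_face(rng)
            assert interface_energy(f1, f2, matrix) <= interface_energy_at_rotation(
                f1, f2, 0, matrix
            ) + 1e-12

    def test_symmetric_in_faces(self, matrix, rng):
        for _ in range(20):
            f1, f2 = random_face(rng), random_face(rng)
            assert interface_energy(f1, f2, matrix) == pytest.approx(
                interface_energy(f2, f1, matrix)
            )

    def test_isologous_pairs_counted_twice(self, matrix, rng):
        # at 0 deg the pairing has no fixed points, so an isologous energy
        # is an even sum of pair energies: in units of the matrix's 0.01 kT
        # resolution it is an even integer
        face = random_face(rng)
        e = interface_energy_at_rotation(face, face, 0, matrix)
        hundredths = round(e * 100)
        assert hundredths % 2 == 0
        assert e == pytest.approx(hundredths / 100, abs=1e-9)


class TestProteinSurfaces:
    def test_sequence_round_trip(self, rng):
        seq = "".join(ALPHABET[i] for i in rng.integers(0, 20, size=32))
        protein = ag.ProteinSurfaces.from_sequence(seq)
        assert protein.sequence == seq
        assert not protein.relabelled

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="32"):
            ag.ProteinSurfaces.from_sequence("A" * 31)

    def test_identical_faces_no_relabel(self, matrix):
        protein = ag.ProteinSurfaces.from_sequence("ACDEFGHIKLMNPQRS" * 2)
        energies, canonical = ag.protein_interface_energies(protein, matrix)
        assert energies.E_AA == pytest.approx(energies.E_BB)
        assert energies.E_AA == pytest.approx(energies.E_AB)
        assert not canonical.relabelled

    def test_relabelling_enforces_order(self, matrix, rng):
        saw_swap = False
        for _ in range(50):
            protein = ag.ProteinSurfaces(random_face(rng), random_face(rng))
            raw_aa = interface_energy(protein.face_a, protein.face_a, matrix)
            raw_bb = interface_energy(protein.face_b, protein.face_b, matrix)
            energies, canonical = ag.protein_interface_energies(protein, matrix)
            assert energies.E_AA <= energies.E_BB
            if raw_aa > raw_bb:
                saw_swap = True
                assert canonical.relabelled
                assert canonical.face_a == protein.face_b
        assert saw_swap

    def test_batch_agrees_with_scalar(self, matrix, rng):
        fa = rng.integers(0, 20, size=(30, 16), dtype=np.uint8)
        fb = rng.integers(0, 20, size=(30, 16), dtype=np.uint8)
        e_aa, e_bb, e_ab, swapped = ag.batch_interface_energies(fa, fb, matrix)
        for i in range(30):
            protein = ag.ProteinSurfaces(ag.SurfaceFace(fa[i]), ag.SurfaceFace(fb[i]))
            energies, canonical = ag.protein_interface_energies(protein, matrix)
            assert e_aa[i] == pytest.approx(energies.E_AA)
            assert e_bb[i] == pytest.approx(energies.E_BB)
            assert e_ab[i] == pytest.approx(energies.E_AB)
            assert swapped[i] == canonical.relabelled


class TestEnsembleStatistics:
    def test_isologous_variance_twice_heterologous(self, matrix, rng):
        # at one fixed rotation an isologous interface repeats each of its
        # 8 residue pairs twice, doubling the energy variance relative to
        # a heterologous interface with the same number of contacts
        n = 100_000
        e = matrix.energies
        perm0 = np.array(
            [((5 - r) - 1) * 4 + (c - 1) for r in range(1, 5) for c in range(1, 5)]
        )
        f1 = rng.integers(0, 20, size=(n, 16))
        f2 = rng.integers(0, 20, size=(n, 16))
        iso = e[f1, f1[:, perm0]].sum(axis=1)
        het = e[f1, f2[:, perm0]].sum(axis=1)
        ratio = iso.var() / het.var()
        assert ratio == pytest.approx(2.0, rel=0.15)

    def test_neutral_energy_ordering(self, neutral_ensemble):
        e_aa = neutral_ensemble["E_AA"].mean()
        e_bb = neutral_ensemble["E_BB"].mean()
        e_ab = neutral_ensemble["E_AB"].mean()
        assert e_aa < e_ab < e_bb
        # the minimum over rotations pulls every mean below the raw
        # random-interface expectation of 16 * <B> = -0.912
        assert max(e_aa, e_bb, e_ab) < -0.912
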
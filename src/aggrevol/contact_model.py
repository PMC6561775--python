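"""Surface representation and pairwise-contact interface energies.

A protein is modelled as a rigid block with two opposing 4x4 binding
faces, A and B.  The energy of an interface between two faces is the sum
of the 16 amino-acid pair energies formed when the faces are pressed
together, taken from a 20x20 statistical contact potential in kT units.
Four relative 90-degree rotations of the two faces are possible; the
interface energy is the minimum over the four rotations.  Faces are
relabelled where necessary so that the AA interface is the stronger
isologous one (E_AA <= E_BB).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "ALPHABET",
    "AA_TO_INDEX",
    "ROTATIONS",
    "ContactMatrix",
    "ContactMatrixFormatError",
    "SurfaceFace",
    "ProteinSurfaces",
    "InterfaceEnergies",
    "load_contact_matrix",
    "contact_partner",
    "interface_energy_at_rotation",
    "interface_energy",
    "protein_interface_energies",
    "batch_interface_energies",
]

#: The 20 standard amino acids in the fixed one-letter alphabetical order
#: used everywhere in this package (sequences, tables, outputs).
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

AA_TO_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

#: Allowed relative rotations of two faces, in degrees.
ROTATIONS = (0, 90, 180, 270)

FACE_SIZE = 16  # 4x4 grid
SEQUENCE_LENGTH = 32  # two faces


class ContactMatrixFormatError(ValueError):
    """Raised when a contact-energy table violates its format contract."""


def _partner_rowcol(row: int, col: int, rotation: int) -> tuple[int, int]:
    # 1-based grid coordinates; each map is an involution.
    if rotation == 0:
        return 5 - row, col
    if rotation == 90:
        return col, row
    if rotation == 180:
        return row, 5 - col
    if rotation == 270:
        return 5 - col, 5 - row
    raise ValueError(f"rotation must be one of {ROTATIONS}, got {rotation!r}")


def contact_partner(position: tuple[int, int], rotation: int) -> tuple[int, int]:
    """Opposing-face grid position contacted by ``position`` at a rotation.

    Positions are 1-based ``(row, col)`` with linear numbering 1..16 being
    row-major, so positions 1, 6, 11 and 16 form the main diagonal.  The
    map is an involution at every rotation; it has no fixed points at 0
    and 180 degrees, and at 90 degrees its fixed points are exactly the
    main-diagonal positions (residues that contact themselves across an
    isologous interface).
    """
    row, col = position
    if not (1 <= row <= 4 and 1 <= col <= 4):
        raise ValueError(f"position out of the 4x4 grid: {position!r}")
    return _partner_rowcol(row, col, rotation)


def _permutation(rotation: int) -> np.ndarray:
    """0-based linear-index permutation for a rotation."""
    out = np.empty(FACE_SIZE, dtype=np.intp)
    for r in range(1, 5):
        for c in range(1, 5):
            pr, pc = _partner_rowcol(r, c, rotation)
            out[(r - 1) * 4 + (c - 1)] = (pr - 1) * 4 + (pc - 1)
    return out


_PERMUTATIONS = {rot: _permutation(rot) for rot in ROTATIONS}
_PERM_STACK = np.stack([_PERMUTATIONS[rot] for rot in ROTATIONS])  # (4, 16)


@dataclass(frozen=True)
class ContactMatrix:
    """Symmetric 20x20 amino-acid pair potential in kT units."""

    energies: np.ndarray
    alphabet: str = ALPHABET

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        if e.shape != (20, 20):
            raise ContactMatrixFormatError(f"expected a 20x20 table, got {e.shape}")
        asym = np.abs(e - e.T)
        if asym.max() > 1e-9:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise ContactMatrixFormatError(
                f"matrix is asymmetric at ({self.alphabet[i]},{self.alphabet[j]}): "
                f"{e[i, j]} != {e[j, i]}"
            )
        if not np.isfinite(e).all():
            raise ContactMatrixFormatError("matrix contains non-finite entries")
        object.__setattr__(self, "energies", e)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.energies[AA_TO_INDEX[a], AA_TO_INDEX[b]])

    @property
    def mean_energy(self) -> float:
        """Grand mean over all 400 ordered entries."""
        return float(self.energies.mean())


def _packaged_matrix_path() -> Path:
    return Path(str(resources.files("aggrevol").joinpath("data/bt_contact_matrix.tsv")))


def load_contact_matrix(source: str | Path | None = None) -> ContactMatrix:
    """Load a whitespace-delimited 20x20 contact table with one-letter headers.

    With ``source=None`` the packaged default potential is used: the
    Miyazawa-Jernigan contact potential in the threonine-referenced form
    of Betancourt and Thirumalai, whose grand mean is -0.057 kT.
    """
    path = _packaged_matrix_path() if source is None else Path(source)
    validate_mean = source is None
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if len(lines) != 21:
        raise ContactMatrixFormatError(
            f"{path}: expected a header plus 20 rows, got {len(lines)} non-empty lines"
        )
    header = lines[0].split()
    if sorted(header) != sorted(ALPHABET):
        missing = set(ALPHABET) - set(header)
        raise ContactMatrixFormatError(
            f"{path}: header must name the 20 standard amino acids"
            + (f"; missing {sorted(missing)}" if missing else "")
        )
    col_of = {aa: k for k, aa in enumerate(header)}
    energies = np.empty((20, 20))
    seen_rows = set()
    for ln in lines[1:]:
        parts = ln.split()
        row_aa = parts[0]
        if row_aa not in AA_TO_INDEX:
            raise ContactMatrixFormatError(f"{path}: unknown row label {row_aa!r}")
        if len(parts) != 21:
            raise ContactMatrixFormatError(
                f"{path}: row {row_aa} has {len(parts) - 1} cells, expected 20"
            )
        seen_rows.add(row_aa)
        i = AA_TO_INDEX[row_aa]
        for aa in ALPHABET:
            cell = parts[1 + col_of[aa]]
            try:
                energies[i, AA_TO_INDEX[aa]] = float(cell)
            except ValueError:
                raise ContactMatrixFormatError(
                    f"{path}: non-numeric cell at ({row_aa},{aa}): {cell!r}"
                ) from None
    if len(seen_rows) != 20:
        raise ContactMatrixFormatError(
            f"{path}: missing rows for {sorted(set(ALPHABET) - seen_rows)}"
        )
    matrix = ContactMatrix(energies)
    if validate_mean and abs(matrix.mean_energy - (-0.057)) > 5e-4:
        raise ContactMatrixFormatError(
            f"packaged matrix failed its mean check: {matrix.mean_energy:.6f}"
        )
    return matrix


def _face_indices(residues) -> np.ndarray:
    if isinstance(residues, str):
        try:
            idx = np.array([AA_TO_INDEX[a] for a in residues], dtype=np.uint8)
        except KeyError as exc:
            raise ValueError(f"invalid amino-acid letter {exc.args[0]!r}") from None
    else:
        idx = np.asarray(residues, dtype=np.uint8)
        if idx.size and idx.max() > 19:
            raise ValueError("residue indices must be in 0..19")
    if idx.shape != (FACE_SIZE,):
        raise ValueError(f"a face holds exactly {FACE_SIZE} residues, got {idx.shape}")
    return idx


@dataclass(frozen=True)
class SurfaceFace:
    """One 4x4 binding face, stored as residue indices in row-major order."""

    indices: np.ndarray

    @classmethod
    def from_letters(cls, letters: str) -> "SurfaceFace":
        return cls(_face_indices(letters))

    def __post_init__(self) -> None:
        object.__setattr__(self, "indices", _face_indices(self.indices))

    @property
    def letters(self) -> str:
        return "".join(ALPHABET[i] for i in self.indices)

    def residue(self, row: int, col: int) -> str:
        """Residue at a 1-based (row, col) grid position."""
        return ALPHABET[self.indices[(row - 1) * 4 + (col - 1)]]

    def __eq__(self, other) -> bool:
        return isinstance(other, SurfaceFace) and bool(
            np.array_equal(self.indices, other.indices)
        )


@dataclass(frozen=True)
class ProteinSurfaces:
    """The two binding faces of one protein plus the relabelling flag.

    The 32-letter sequence convention is: positions 1-16 are face A in
    row-major order, positions 17-32 are face B likewise.
    """

    face_a: SurfaceFace
    face_b: SurfaceFace
    relabelled: bool = False

    @classmethod
    def from_sequence(cls, sequence: str) -> "ProteinSurfaces":
        if len(sequence) != SEQUENCE_LENGTH:
            raise ValueError(
                f"surface sequence must have {SEQUENCE_LENGTH} residues, "
                f"got {len(sequence)}"
            )
        return cls(
            SurfaceFace.from_letters(sequence[:FACE_SIZE]),
            SurfaceFace.from_letters(sequence[FACE_SIZE:]),
        )

    @property
    def sequence(self) -> str:
        return self.face_a.letters + self.face_b.letters

    def swapped(self) -> "ProteinSurfaces":
        return ProteinSurfaces(self.face_b, self.face_a, not self.relabelled)


@dataclass(frozen=True)
class InterfaceEnergies:
    """The three interface energies in kT, with E_AA <= E_BB."""

    E_AA: float
    E_BB: float
    E_AB: float

    def __iter__(self):
        return iter((self.E_AA, self.E_BB, self.E_AB))


def interface_energy_at_rotation(
    face1: SurfaceFace, face2: SurfaceFace, rotation: int, matrix: ContactMatrix
) -> float:
    """Sum of the 16 pairwise contact energies at one relative rotation."""
    perm = _PERMUTATIONS.get(rotation)
    if perm is None:
        raise ValueError(f"rotation must be one of {ROTATIONS}, got {rotation!r}")
    return float(matrix.energies[face1.indices, face2.indices[perm]].sum())


def interface_energy(
    face1: SurfaceFace, face2: SurfaceFace, matrix: ContactMatrix
) -> float:
    """Minimum of the four rotational interface energies."""
    e = matrix.energies
    i1, i2 = face1.indices, face2.indices
    return float(min(e[i1, i2[perm]].sum() for perm in _PERMUTATIONS.values()))


def protein_interface_energies(
    protein: ProteinSurfaces, matrix: ContactMatrix
) -> tuple[InterfaceEnergies, ProteinSurfaces]:
    """Canonical interface energies and the (possibly relabelled) protein.

    Computes the two isologous energies and the heterologous energy, and
    swaps the face labels if needed so that E_AA <= E_BB; exact ties keep
    the input labelling.
    """
    e_11 = interface_energy(protein.face_a, protein.face_a, matrix)
    e_22 = interface_energy(protein.face_b, protein.face_b, matrix)
    e_12 = interface_energy(protein.face_a, protein.face_b, matrix)
    if e_11 > e_22:
        return InterfaceEnergies(e_22, e_11, e_12), protein.swapped()
    return InterfaceEnergies(e_11, e_22, e_12), protein


def batch_interface_energies(
    face_a: np.ndarray, face_b: np.ndarray, matrix: ContactMatrix
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised canonical energies for many proteins at once.

    Parameters
    ----------
    face_a, face_b
        Integer residue-index arrays of shape (n, 16).

    Returns
    -------
    (E_AA, E_BB, E_AB, swapped) where ``swapped`` marks rows whose faces
    were relabelled to enforce E_AA <= E_BB.
    """
    face_a = np.asarray(face_a)
    face_b = np.asarray(face_b)
    e = matrix.energies

    def _min_energy(f1: np.ndarray, f2: np.ndarray) -> np.ndarray:
        # (n, 4, 16) gather over the four rotation permutations
        contacts = e[f1[:, None, :], f2[:, _PERM_STACK]]
        return contacts.sum(axis=2).min(axis=1)

    e_11 = _min_energy(face_a, face_a)
    e_22 = _min_energy(face_b, face_b)
    e_12 = _min_energy(face_a, face_b)
    swapped = e_11 > e_22
    e_aa = np.where(swapped, e_22, e_11)
    e_bb = np.where(swapped, e_11, e_22)
    return e_aa, e_bb, e_12, swapped
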
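"""File formats, run configuration and fixture generation.

Sequence files are a FASTA dialect in which every record is exactly 32
amino-acid letters: positions 1-16 are the A face in row-major order
(rows top to bottom, columns left to right) and positions 17-32 are the
B face in the same convention.  Tabular outputs are TSV (or JSON) with a
deterministic column order, floats at 12 significant digits, gzip
compression when the path ends in .gz, and a header comment carrying the
tool version and the resolved configuration hash.
"""

from __future__ import annotations

import gzip
import hashlib
import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .contact_model import ALPHABET, ProteinSurfaces, SEQUENCE_LENGTH

__all__ = [
    "RunConfig",
    "SequenceRecord",
    "SequenceFormatError",
    "read_sequences",
    "write_sequences",
    "write_table",
    "read_table",
    "make_fixtures",
    "FIXTURE_KINDS",
]

FIXTURE_KINDS = ("toy_matrix", "random_sequences", "example_energies")

_VALID = set(ALPHABET)


class SequenceFormatError(ValueError):
    """Raised for malformed sequence records."""


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) != SEQUENCE_LENGTH:
            raise SequenceFormatError(
                f"record {self.id!r}: expected {SEQUENCE_LENGTH} residues, "
                f"got {len(self.residues)}"
            )
        for pos, aa in enumerate(self.residues, start=1):
            if aa not in _VALID:
                raise SequenceFormatError(
                    f"record {self.id!r}: invalid letter {aa!r} at position {pos}"
                )

    def protein(self) -> ProteinSurfaces:
        return ProteinSurfaces.from_sequence(self.residues)


def _open_text(path: Path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_sequences(path) -> list[SequenceRecord]:
    """Read 32-residue surface records from a FASTA-dialect file."""
    records: list[SequenceRecord] = []
    name, chunks = None, []
    with _open_text(Path(path), "r") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", ";")):
                continue
            if line.startswith(">"):
                if name is not None:
                    records.append(SequenceRecord(name, "".join(chunks)))
                fields = line[1:].split()
                name = fields[0] if fields else ""
                chunks = []
            else:
                if name is None:
                    raise SequenceFormatError(f"{path}: sequence data before header")
                chunks.append(line.upper())
        if name is not None:
            records.append(SequenceRecord(name, "".join(chunks)))
    if not records:
        raise SequenceFormatError(f"{path}: no sequence records found")
    return records


def write_sequences(records, path) -> None:
    with _open_text(Path(path), "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.residues}\n")


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one CLI run.

    Serialises to a flat key=value file; its short hash stamps every
    output header so results can be traced back to the exact settings.
    """

    command: str
    options: dict = field(default_factory=dict)

    def to_text(self) -> str:
        lines = [f"command={self.command}"]
        for key in sorted(self.options):
            lines.append(f"{key}={self.options[key]}")
        return "\n".join(lines) + "\n"

    @property
    def hash(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:12]

    def write(self, out_path) -> Path:
        """Write the resolved config next to an output file."""
        cfg_path = Path(str(out_path) + ".config")
        cfg_path.write_text(self.to_text())
        return cfg_path


def _format_value(v) -> str:
    if isinstance(v, (bool, np.bool_)):
        return str(bool(v))
    if isinstance(v, (float, np.floating)):
        return f"{v:.12g}"
    return str(v)


def _header_lines(config: RunConfig | None) -> list[str]:
    from . import __version__

    stamp = f"aggrevol {__version__}"
    if config is not None:
        stamp += f" config={config.hash}"
    return [f"# {stamp}"]


def write_table(rows, path, fmt: str = "tsv", config: RunConfig | None = None,
                columns=None) -> None:
    """Write rows (list of dicts or DataFrame) as TSV or JSON.

    All rows must share one schema; the column order is the schema order
    of the first row (or ``columns``), floats are rendered at 12
    significant digits, and a ``.gz`` suffix enables gzip.
    """
    if fmt not in ("tsv", "json"):
        raise ValueError(f"format must be 'tsv' or 'json', got {fmt!r}")
    if isinstance(rows, pd.DataFrame):
        cols = list(columns or rows.columns)
        dicts = rows[cols].to_dict("records")
    else:
        dicts = list(rows)
        cols = list(columns) if columns else (list(dicts[0]) if dicts else [])
        for i, row in enumerate(dicts):
            if list(row) != cols and set(row) != set(cols):
                raise ValueError(
                    f"row {i} schema {sorted(row)} does not match columns {sorted(cols)}"
                )
    path = Path(path)
    buf = _io.StringIO()
    if fmt == "tsv":
        for line in _header_lines(config):
            buf.write(line + "\n")
        buf.write("\t".join(cols) + "\n")
        for row in dicts:
            buf.write("\t".join(_format_value(row[c]) for c in cols) + "\n")
    else:
        payload = {
            "_header": _header_lines(config)[0].lstrip("# "),
            "columns": cols,
            "rows": [{c: row[c] for c in cols} for row in dicts],
        }
        buf.write(json.dumps(payload, indent=1, default=_format_value))
        buf.write("\n")
    with _open_text(path, "w") as fh:
        fh.write(buf.getvalue())


def read_table(path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table`."""
    with _open_text(Path(path), "r") as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


# -- fixtures ---------------------------------------------------------------

#: Hand-set toy energies on a two-letter sub-alphabet {A, C}; all other
#: pairs are zero.  Small enough for brute-force enumeration in tests.
_TOY_ENERGIES = {("A", "A"): -1.0, ("C", "C"): -2.0, ("A", "C"): 0.5}


def make_fixtures(kind: str, out_dir, rng: np.random.Generator | None = None,
                  n_sequences: int = 10) -> Path:
    """Write a small test fixture and return its path.

    toy_matrix         20x20 table, hand-set energies on {A, C}, zero
                       elsewhere (synthetic data for oracle tests).
    random_sequences   seeded FASTA of 32-mers.
    example_energies   the six exemplar (E_AA, E_BB, E_AB) triples.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if kind == "toy_matrix":
        path = out_dir / "toy_matrix.tsv"
        lines = ["\t".join([""] + list(ALPHABET))]
        for a in ALPHABET:
            row = [a]
            for b in ALPHABET:
                e = _TOY_ENERGIES.get((a, b), _TOY_ENERGIES.get((b, a), 0.0))
                row.append(f"{e:.2f}")
            lines.append("\t".join(row))
        path.write_text("\n".join(lines) + "\n")
        return path
    if kind == "random_sequences":
        if rng is None:
            raise ValueError("random_sequences requires an rng")
        path = out_dir / "random_sequences.fasta"
        records = []
        for i in range(n_sequences):
            letters = "".join(
                ALPHABET[j] for j in rng.integers(0, 20, size=SEQUENCE_LENGTH)
            )
            records.append(SequenceRecord(f"seq{i + 1}", letters))
        write_sequences(records, path)
        return path
    if kind == "example_energies":
        from .aggregation import EXAMPLE_ENERGIES

        path = out_dir / "example_energies.tsv"
        rows = [
            dict(sequence=name, E_AA=e.E_AA, E_BB=e.E_BB, E_AB=e.E_AB)
            for name, e in EXAMPLE_ENERGIES.items()
        ]
        write_table(rows, path)
        return path
    raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
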
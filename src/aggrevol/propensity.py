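"""Amino-acid interface propensities from large sequence ensembles.

Once every sequence is relabelled so that the A face forms the stronger
isologous interface, the residue composition of the two faces separates:
sticky residues enrich on A, and the enrichment pattern defines an
interface-propensity scale directly comparable to scales measured on
real protein structures.

  p_A, p_B   per-amino-acid frequency on each face relative to the
             mutational frequency pi (1 = no enrichment),
  S_int      ln(p_A / p_B), the interface propensity,
  S_iso      ln of the ratio of A-face frequencies under dimer selection
             vs oriented-fibril selection, contrasting isologous with
             heterologous interfaces.

Per-amino-acid predictors computed from the contact matrix itself are
B_self (the diagonal element), B_ave (the row mean over 20 partners) and
delta_B = B_ave - B_self.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from scipy import stats

from .contact_model import (
    ALPHABET,
    ContactMatrix,
    ProteinSurfaces,
    SurfaceFace,
    batch_interface_energies,
    protein_interface_energies,
)
from .evolution import EvolutionChain, MutationModel

__all__ = [
    "PropensityTable",
    "MatrixPredictors",
    "CorrelationResult",
    "random_sequence_sample",
    "random_surface_sample_arrays",
    "surface_frequencies",
    "s_int",
    "s_iso",
    "matrix_predictors",
    "pearson_with_pvalue",
    "external_scale_correlations",
    "neutral_propensity_table",
]


@dataclass(frozen=True)
class PropensityTable:
    """Relative per-amino-acid face frequencies for one sequence sample."""

    p_A: np.ndarray  # length 20, relative to pi
    p_B: np.ndarray
    pi: np.ndarray
    sample_size: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"aa": list(ALPHABET), "p_A": self.p_A, "p_B": self.p_B}
        )


@dataclass(frozen=True)
class MatrixPredictors:
    """Per-amino-acid energy summaries of the contact matrix (kT)."""

    B_self: np.ndarray
    B_ave: np.ndarray
    delta_B: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"aa": list(ALPHABET), "B_self": self.B_self,
             "B_ave": self.B_ave, "delta_B": self.delta_B}
        )


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with two-sided t-test significance."""

    r: float
    p_value: float
    n: int


def random_surface_sample_arrays(
    n_sequences: int,
    model: MutationModel,
    matrix: ContactMatrix,
    rng: np.random.Generator,
    chunk: int = 100_000,
    return_energies: bool = False,
):
    """Canonically relabelled i.i.d. random surfaces as index arrays.

    Sequences are drawn site-wise from pi and each is relabelled so that
    E_AA <= E_BB before any counting.  Returns (face_a, face_b) arrays of
    shape (n, 16); with ``return_energies`` also the (E_AA, E_BB, E_AB)
    arrays.  Generation is chunked only to bound memory; the draw stream
    is a single sequential pass, so results do not depend on chunk size.
    """
    if n_sequences < 1:
        raise ValueError("need at least one sequence")
    fa_parts, fb_parts, e_parts = [], [], []
    remaining = n_sequences
    while remaining > 0:
        m = min(chunk, remaining)
        seqs = rng.choice(20, size=(m, 32), p=model.pi).astype(np.uint8)
        fa, fb = seqs[:, :16], seqs[:, 16:]
        e_aa, e_bb, e_ab, swapped = batch_interface_energies(fa, fb, matrix)
        fa2 = np.where(swapped[:, None], fb, fa)
        fb2 = np.where(swapped[:, None], fa, fb)
        fa_parts.append(fa2)
        fb_parts.append(fb2)
        if return_energies:
            e_parts.append(np.column_stack([e_aa, e_bb, e_ab]))
        remaining -= m
    face_a = np.concatenate(fa_parts)
    face_b = np.concatenate(fb_parts)
    if return_energies:
        e = np.concatenate(e_parts)
        return face_a, face_b, e[:, 0], e[:, 1], e[:, 2]
    return face_a, face_b


def random_sequence_sample(
    n_sequences: int,
    model: MutationModel,
    matrix: ContactMatrix,
    rng: np.random.Generator,
) -> Iterator[ProteinSurfaces]:
    """Stream of canonically relabelled i.i.d. random proteins."""
    for _ in range(n_sequences):
        seq = rng.choice(20, size=32, p=model.pi).astype(np.uint8)
        protein = ProteinSurfaces(SurfaceFace(seq[:16]), SurfaceFace(seq[16:]))
        _, canonical = protein_interface_energies(protein, matrix)
        # emit with a clean flag: the canonical order is this protein's
        # native labelling as far as downstream consumers are concerned
        yield ProteinSurfaces(canonical.face_a, canonical.face_b)


def _face_arrays(sample) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(sample, EvolutionChain):
        post = sample.post_burn_in()
        return post.sequences[:, :16], post.sequences[:, 16:]
    if isinstance(sample, tuple) and len(sample) == 2:
        return np.asarray(sample[0]), np.asarray(sample[1])
    if isinstance(sample, Iterable):
        proteins = list(sample)
        if not proteins:
            raise ValueError("empty sequence sample")
        fa = np.stack([p.face_a.indices for p in proteins])
        fb = np.stack([p.face_b.indices for p in proteins])
        return fa, fb
    raise TypeError(f"unsupported sample type {type(sample)!r}")


def surface_frequencies(sample, model: MutationModel) -> PropensityTable:
    """Per-face amino-acid frequencies relative to pi.

    ``sample`` may be a pair of (face_a, face_b) index arrays, an
    EvolutionChain (post-burn-in samples are used, including rejection
    duplicates) or an iterable of canonically relabelled proteins.
    Residues are pooled over all sequences on each face.
    """
    fa, fb = _face_arrays(sample)
    if fa.size == 0:
        raise ValueError("empty sequence sample")
    n_res = fa.size  # 16 * n_sequences per face
    counts_a = np.bincount(fa.ravel(), minlength=20)
    counts_b = np.bincount(fb.ravel(), minlength=20)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_a = counts_a / n_res / model.pi
        p_b = counts_b / n_res / model.pi
    return PropensityTable(p_A=p_a, p_B=p_b, pi=model.pi, sample_size=len(fa))


def _log_ratio(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
    bad = [ALPHABET[i] for i in range(20) if num[i] <= 0 or den[i] <= 0]
    if bad:
        raise ValueError(
            f"zero frequency for {bad} in {what}; use a larger sample"
        )
    return np.log(num / den)


def s_int(table: PropensityTable) -> np.ndarray:
    """Interface propensity ln(p_A / p_B) per amino acid."""
    return _log_ratio(table.p_A, table.p_B, "S_int")


def s_iso(
    dimer_table: PropensityTable, oriented_table: PropensityTable
) -> np.ndarray:
    """Isologous-vs-heterologous propensity ln(p_A(dimers)/p_A(oriented))."""
    return _log_ratio(dimer_table.p_A, oriented_table.p_A, "S_iso")


def matrix_predictors(matrix: ContactMatrix) -> MatrixPredictors:
    e = matrix.energies
    b_self = np.diag(e).copy()
    b_ave = e.mean(axis=1)
    return MatrixPredictors(B_self=b_self, B_ave=b_ave, delta_B=b_ave - b_self)


def pearson_with_pvalue(x, y) -> CorrelationResult:
    """Pearson r with the two-sided t-test p-value (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length 1-d vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in correlation input")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue),
                             n=len(x))


def _read_scale(table, name: str) -> np.ndarray:
    """A per-amino-acid scale as {aa: value}, Series or two-column frame."""
    if isinstance(table, pd.DataFrame):
        if table.shape[1] != 2:
            raise ValueError(f"scale {name!r} must have two columns (aa, value)")
        mapping = dict(zip(table.iloc[:, 0], table.iloc[:, 1]))
    elif isinstance(table, pd.Series):
        mapping = table.to_dict()
    else:
        mapping = dict(table)
    missing = [aa for aa in ALPHABET if aa not in mapping]
    if missing:
        raise ValueError(f"scale {name!r} is missing amino acids {missing}")
    return np.array([float(mapping[aa]) for aa in ALPHABET])


def external_scale_correlations(
    scores: np.ndarray, scales: dict[str, object]
) -> dict[str, CorrelationResult]:
    """Correlate a per-amino-acid score with external propensity scales.

    ``scales`` maps a scale name (e.g. "ln_RIP", "stickiness", "ln_REI")
    to a per-amino-acid two-column table, Series or mapping.
    """
    return {
        name: pearson_with_pvalue(scores, _read_scale(table, name))
        for name, table in scales.items()
    }


def neutral_propensity_table(
    n_sequences: int,
    model: MutationModel,
    matrix: ContactMatrix,
    rng: np.random.Generator,
) -> PropensityTable:
    """Propensity table for an i.i.d. neutral ensemble (convenience)."""
    arrays = random_surface_sample_arrays(n_sequences, model, matrix, rng)
    return surface_frequencies(arrays, model)
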
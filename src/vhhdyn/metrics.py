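"""Per-position flexibility statistics of conformational ensembles.

Covers the frequency-based measures over the Protein Block alphabet
(per-position frequencies, Neq, ΔNeq, ΔPB) and their amino-acid analogue
(ΔAA), the positional measures (Kabsch superposition, CA RMSF), and the
per-domain z-score normalisation applied to B-factors and RMSF.

Neq is the exponential of the Shannon entropy of the per-position Protein
Block frequencies, Neq = exp(-Σ_x f_x ln f_x): the effective number of
local conformational states sampled at that position (1 = a single block,
16 = a uniform distribution over the alphabet).  ΔPB (and ΔAA) is the L1
distance Σ_x |f¹_x - f²_x| between two frequency vectors, in [0, 2]:
0 for identical profiles, 2 for disjoint support.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .io_formats import Ensemble
from .pb import PB_LABELS, UNDEFINED_LABEL

__all__ = [
    "AA_ALPHABET",
    "FrequencyVector",
    "MetricProfile",
    "pb_frequencies",
    "aa_frequencies",
    "neq",
    "delta_neq",
    "delta_pb",
    "delta_aa",
    "superpose",
    "rmsf",
    "znormalise",
    "pb_count_matrix",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class FrequencyVector:
    """Probabilities over a fixed alphabet plus the observation count.

    A vector with ``count == 0`` is flagged undefined; its probabilities
    are NaN and it propagates through the derived statistics as an
    undefined result rather than a number.
    """

    probs: np.ndarray
    count: int
    alphabet: str = PB_LABELS

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.count > 0:
            if self.probs.shape != (len(self.alphabet),):
                raise ValueError("probability vector length mismatch")
            if np.any(self.probs < -1e-12):
                raise ValueError("negative probability")
            if abs(self.probs.sum() - 1.0) > 1e-9:
                raise ValueError("probabilities do not sum to 1")

    @property
    def defined(self) -> bool:
        return self.count > 0

    @classmethod
    def undefined(cls, alphabet: str = PB_LABELS) -> "FrequencyVector":
        return cls(np.full(len(alphabet), np.nan), 0, alphabet)

    @classmethod
    def from_counts(cls, counts, alphabet: str = PB_LABELS
                    ) -> "FrequencyVector":
        counts = np.asarray(counts, dtype=float)
        total = counts.sum()
        if total == 0:
            return cls.undefined(alphabet)
        return cls(counts / total, int(total), alphabet)


@dataclass
class MetricProfile:
    """A per-position vector of one scalar metric with its provenance."""

    name: str
    values: np.ndarray            # NaN marks a missing position
    units: str = ""
    scope: str = ""               # domain_id or cluster identifier
    index: str = "residue"        # "residue" or "column"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def _column_frequencies(column, alphabet: str, excluded: str
                        ) -> FrequencyVector:
    counts = np.zeros(len(alphabet))
    lut = {c: i for i, c in enumerate(alphabet)}
    for label in column:
        if label in excluded:
            continue
        i = lut.get(label)
        if i is not None:
            counts[lut[label]] += 1
    return FrequencyVector.from_counts(counts, alphabet)


def pb_frequencies(column) -> FrequencyVector:
    """Protein Block frequencies of one PB-matrix column.

    'Z' (unassignable) entries are excluded from both numerator and
    denominator; a column of only 'Z' yields an undefined vector.
    """
    column = list(column)
    if not column:
        raise ValueError("empty column")
    return _column_frequencies(column, PB_LABELS, UNDEFINED_LABEL)


def aa_frequencies(column) -> FrequencyVector:
    """Amino-acid frequencies of one alignment column (gaps and 'X' ignored)."""
    return _column_frequencies(list(column), AA_ALPHABET, "-.X")


def pb_count_matrix(pbmatrix: np.ndarray) -> np.ndarray:
    """Per-residue PB counts, shape (n_residues, 16); 'Z' excluded."""
    R = pbmatrix.shape[1]
    counts = np.zeros((R, 16))
    for x, lab in enumerate(PB_LABELS):
        counts[:, x] = (pbmatrix == lab).sum(axis=0)
    return counts


def neq(f: FrequencyVector) -> float:
    """Effective number of states: exp of the Shannon entropy (natural log).

    Terms with f_x = 0 contribute nothing (0·ln 0 := 0).  Undefined input
    propagates as NaN.
    """
    if not f.defined:
        return float("nan")
    p = f.probs[f.probs > 0]
    return float(np.exp(-np.sum(p * np.log(p))))


def delta_neq(n1: float, n2: float) -> float:
    """Absolute difference between two Neq values (NaN propagates)."""
    return abs(n1 - n2)


def _l1(f1: FrequencyVector, f2: FrequencyVector) -> float:
    if f1.alphabet != f2.alphabet:
        raise ValueError("frequency vectors over different alphabets")
    if not (f1.defined and f2.defined):
        return float("nan")
    return float(np.sum(np.abs(f1.probs - f2.probs)))


def delta_pb(f1: FrequencyVector, f2: FrequencyVector) -> float:
    """L1 distance between two PB frequency vectors, in [0, 2]."""
    return _l1(f1, f2)


def delta_aa(f1: FrequencyVector, f2: FrequencyVector) -> float:
    """L1 distance between two amino-acid frequency vectors, in [0, 2]."""
    return _l1(f1, f2)


def superpose(mobile: np.ndarray, reference: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of one CA set onto another.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference`` with a
    proper rotation (det = +1; mirror images are never matched by a
    reflection).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2:
        raise ValueError("coordinate sets must have identical (n, 3) shapes")
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 atoms to superpose")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - rc, mobile - mc)
    R = rot.as_matrix()
    t = rc - mc @ R.T
    fitted = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    return R, t, rmsd


def _fit_frames(ca: np.ndarray, reference: np.ndarray) -> np.ndarray:
    out = np.empty_like(ca)
    for i in range(ca.shape[0]):
        R, t, _ = superpose(ca[i], reference)
        out[i] = ca[i] @ R.T + t
    return out


def rmsf(ensemble: Ensemble, fit: bool = True,
         fit_mask: np.ndarray | None = None) -> MetricProfile:
    """Root mean square fluctuation of the CA atoms, in Å.

    With ``fit`` enabled each frame is rigidly superposed onto the mean
    structure in two passes: fit to the first frame, recompute the mean,
    refit to that mean, then measure fluctuations about the final mean.
    ``fit_mask`` optionally restricts the atoms used for fitting (e.g. a
    rigid core); fluctuations are always reported for all residues.
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    ca = ensemble.ca().copy()
    if fit:
        mask = (np.ones(ensemble.n_residues, dtype=bool)
                if fit_mask is None else np.asarray(fit_mask, dtype=bool))
        for reference in (ca[0], None):
            ref = ca.mean(axis=0) if reference is None else reference
            for i in range(ca.shape[0]):
                R, t, _ = superpose(ca[i][mask], ref[mask])
                ca[i] = ca[i] @ R.T + t
    mean = ca.mean(axis=0)
    vals = np.sqrt(np.mean(np.sum((ca - mean) ** 2, axis=2), axis=0))
    return MetricProfile("rmsf", vals, units="angstrom",
                         scope=ensemble.domain_id)


def znormalise(values, ddof: int = 0) -> np.ndarray:
    """Per-domain z-score, (v_i - mean) / sd, with the population sd.

    A constant profile carries no flexibility signal and is a hard error.
    Set ``ddof=1`` for the sample-sd variant.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values to normalise")
    sd = float(np.std(values, ddof=ddof))
    if sd < 1e-12:
        raise ValueError("zero standard deviation: constant profile")
    return (values - values.mean()) / sd
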
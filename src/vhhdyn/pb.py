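"""Protein Blocks assignment from backbone dihedrals.

The structural alphabet describes the local backbone conformation of each
residue by an 8-dihedral window spanning five consecutive residues,
(psi[i-2], phi[i-1], psi[i-1], phi[i], psi[i], phi[i+1], psi[i+1],
phi[i+2]), and assigns the window to the nearest of 16 reference prototypes
('a'-'p') under the RMSDA dissimilarity (root mean square of wrapped
angular differences).  The two residues at each chain end, and any position
with an undefined window angle, receive the out-of-alphabet label 'Z'.

Angles are handled in degrees throughout, wrapped to (-180, 180].
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .io_formats import Ensemble

__all__ = [
    "PB_LABELS",
    "UNDEFINED_LABEL",
    "load_prototypes",
    "wrap_angle",
    "dihedral",
    "extract_dihedrals",
    "rmsda",
    "assign_window",
    "assign_ensemble",
    "windows_from_dihedrals",
]

PB_LABELS = "abcdefghijklmnop"
UNDEFINED_LABEL = "Z"

_prototypes_cache: np.ndarray | None = None


def load_prototypes() -> np.ndarray:
    """Return the packaged 16 x 8 prototype dihedral table (degrees).

    Rows follow label order 'a'-'p'; columns follow the window layout
    (psi[i-2], phi[i-1], psi[i-1], phi[i], psi[i], phi[i+1], psi[i+1],
    phi[i+2]).
    """
    global _prototypes_cache
    if _prototypes_cache is None:
        text = (resources.files("vhhdyn") / "data" / "pb_prototypes.tsv"
                ).read_text()
        rows = {}
        for line in text.splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            rows[parts[0]] = [float(v) for v in parts[1:9]]
        table = np.array([rows[lab] for lab in PB_LABELS])
        if table.shape != (16, 8):
            raise RuntimeError("corrupt prototype table")
        _prototypes_cache = table
    return _prototypes_cache


def wrap_angle(a):
    """Wrap angle(s) in degrees to the interval (-180, 180]."""
    a = np.asarray(a, dtype=float)
    wrapped = -np.mod(-a + 180.0, 360.0) + 180.0
    return wrapped if wrapped.ndim else float(wrapped)


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle (degrees) of four points, IUPAC convention.

    The angle is measured between the half-plane through (p1, p2, p3) and
    the half-plane through (p2, p3, p4); the trans configuration is 180 and
    the result lies in (-180, 180].
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    if (np.linalg.norm(b1) < 1e-9 or np.linalg.norm(b2) < 1e-9
            or np.linalg.norm(b3) < 1e-9):
        raise ValueError("degenerate geometry: coincident consecutive points")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise ValueError("degenerate geometry: collinear consecutive points")
    b2u = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2u))
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def _dihedral_batch(p1, p2, p3, p4) -> np.ndarray:
    """Vectorised torsion over leading axes; NaN rows propagate to NaN."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2u = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    x = np.einsum("...i,...i->...", n1, n2)
    y = np.einsum("...i,...i->...", np.cross(n1, n2), b2u)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def extract_dihedrals(ensemble: Ensemble) -> np.ndarray:
    """Backbone (phi, psi) series of an ensemble.

    Returns an array of shape (n_frames, n_residues, 2) in degrees;
    phi of the first residue and psi of the last are NaN (undefined).
    phi(i) is the torsion C(i-1)-N(i)-CA(i)-C(i); psi(i) is
    N(i)-CA(i)-C(i)-N(i+1).
    """
    if ensemble.n_residues < 3:
        raise ValueError("need at least 3 residues to define any dihedral")
    xyz = ensemble.coords  # (F, R, 3 atoms, 3)
    N, CA, C = xyz[:, :, 0], xyz[:, :, 1], xyz[:, :, 2]
    out = np.full((ensemble.n_frames, ensemble.n_residues, 2), np.nan)
    out[:, 1:, 0] = _dihedral_batch(C[:, :-1], N[:, 1:], CA[:, 1:], C[:, 1:])
    out[:, :-1, 1] = _dihedral_batch(N[:, :-1], CA[:, :-1], C[:, :-1],
                                     N[:, 1:])
    if np.isnan(out[:, 1:, 0]).any() or np.isnan(out[:, :-1, 1]).any():
        bad = np.argwhere(np.isnan(out).any(axis=2))
        raise ValueError(
            f"degenerate backbone geometry near frame/residue {bad[0]}")
    return out


def rmsda(w1, w2) -> float:
    """Root mean square angular deviation between two 8-angle windows.

    Each componentwise difference is wrapped to (-180, 180] before
    squaring, so the result is invariant to adding full turns.
    """
    w1 = np.asarray(w1, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    if np.isnan(w1).any() or np.isnan(w2).any():
        raise ValueError("undefined angle in RMSDA input")
    d = wrap_angle(w1 - w2)
    return float(np.sqrt(np.mean(np.square(d))))


def assign_window(window, prototypes: np.ndarray | None = None) -> str:
    """Assign one fully defined 8-angle window to its nearest prototype.

    Ties (equal RMSDA) are broken by alphabetical label order.
    """
    if prototypes is None:
        prototypes = load_prototypes()
    window = np.asarray(window, dtype=float)
    if np.isnan(window).any():
        raise ValueError("undefined angle in window")
    d = wrap_angle(window[None, :] - prototypes)
    scores = np.mean(np.square(d), axis=1)
    return PB_LABELS[int(np.argmin(scores))]  # argmin takes the first = 'a' first


def windows_from_dihedrals(dihedrals: np.ndarray) -> np.ndarray:
    """Build the (F, R, 8) window tensor from a (F, R, 2) dihedral grid.

    Positions whose window reaches past the chain (the first two and last
    two residues) are NaN-filled.
    """
    F, R, _ = dihedrals.shape
    phi, psi = dihedrals[:, :, 0], dihedrals[:, :, 1]
    win = np.full((F, R, 8), np.nan)
    sl = slice(2, R - 2)
    if R >= 5:
        win[:, sl, 0] = psi[:, 0:R - 4]
        win[:, sl, 1] = phi[:, 1:R - 3]
        win[:, sl, 2] = psi[:, 1:R - 3]
        win[:, sl, 3] = phi[:, 2:R - 2]
        win[:, sl, 4] = psi[:, 2:R - 2]
        win[:, sl, 5] = phi[:, 3:R - 1]
        win[:, sl, 6] = psi[:, 3:R - 1]
        win[:, sl, 7] = phi[:, 4:R]
    return win


def assign_ensemble(dihedrals: np.ndarray,
                    prototypes: np.ndarray | None = None,
                    chunk: int = 65536) -> np.ndarray:
    """Assign Protein Blocks to every residue of every frame.

    Parameters
    ----------
    dihedrals : np.ndarray, shape (n_frames, n_residues, 2)
        (phi, psi) grid in degrees, NaN where undefined.
    prototypes : np.ndarray, optional
        16 x 8 reference table; defaults to the packaged one.
    chunk : int
        Number of windows scored per vectorised block (memory control).

    Returns
    -------
    np.ndarray of single characters, shape (n_frames, n_residues);
    'Z' at the two positions of each chain end and wherever any window
    angle is undefined.
    """
    if prototypes is None:
        prototypes = load_prototypes()
    F, R, _ = dihedrals.shape
    labels = np.full((F, R), UNDEFINED_LABEL, dtype="<U1")
    win = windows_from_dihedrals(dihedrals).reshape(F * R, 8)
    ok = ~np.isnan(win).any(axis=1)
    idx = np.flatnonzero(ok)
    lab_arr = np.frombuffer(PB_LABELS.encode(), dtype="S1").astype("<U1")
    flat = labels.reshape(F * R)
    for start in range(0, idx.size, chunk):
        block = idx[start:start + chunk]
        d = wrap_angle(win[block, None, :] - prototypes[None, :, :])
        scores = np.mean(np.square(d), axis=2)
        flat[block] = lab_arr[np.argmin(scores, axis=1)]
    return labels


def pbmatrix_to_strings(pbmatrix: np.ndarray) -> list[str]:
    """Render a PB label matrix as one string per frame (for text output)."""
    return ["".join(row) for row in pbmatrix]
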
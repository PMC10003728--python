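"""Synthetic conformational ensembles with known ground truth.

The analysis pipeline was designed for microsecond-scale simulation
trajectories; for development and testing this module generates inputs
with the same statistical structure but exactly known ground truth:

* :func:`gen_windows` — per-position 8-angle dihedral windows drawn from a
  controllable mixture of Protein Block prototypes plus wrapped Gaussian
  angular noise.  Window-level generation deliberately bypasses chain
  consistency (overlapping windows of a real chain constrain each other);
  it isolates the block-assignment and frequency statistics with exact
  per-draw truth labels.
* :func:`build_backbone` — internal-to-Cartesian construction (sequential
  NeRF placement) of a backbone from (phi, psi) pairs under ideal bond
  geometry, omega fixed at 180 degrees.
* :func:`gen_ensemble3d` — frames of a base structure plus isotropic
  per-atom Gaussian displacement with region-controlled amplitude; with
  superposition disabled the expected CA RMSF is sigma * sqrt(3).
* :func:`gen_family` — multi-class families of domains sharing a gapped
  MSA, whose loop regions are driven into targeted flexibility quadrants
  by two independent mechanisms: rigid-body region translations (global
  displacement, i.e. RMSF, without local conformational change) and
  switching among a set of distinct backbone dihedral states (local
  conformational diversity, i.e. Neq).

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import Ensemble, MSA
from .metrics import AA_ALPHABET, superpose
from .pb import PB_LABELS, load_prototypes, wrap_angle

__all__ = [
    "IDEAL_GEOMETRY",
    "WindowGeneratorSpec",
    "RegionSpec",
    "FamilySpec",
    "FamilyResult",
    "gen_windows",
    "place_atom",
    "build_backbone",
    "gen_ensemble3d",
    "gen_family",
    "default_family_spec",
]

#: ideal backbone covalent geometry (Engh & Huber averages), Å and degrees
IDEAL_GEOMETRY = {
    "bond_n_ca": 1.458,
    "bond_ca_c": 1.525,
    "bond_c_n": 1.329,
    "angle_n_ca_c": 111.2,
    "angle_ca_c_n": 116.2,
    "angle_c_n_ca": 121.7,
    "omega": 180.0,
}


# ---------------------------------------------------------------------------
# dihedral-window generator


@dataclass
class WindowGeneratorSpec:
    """Sampling recipe for per-position dihedral windows.

    ``positions`` holds, per position, the candidate source block labels
    and optional sampling weights (uniform when None).  ``noise_sd`` is
    the wrapped-Gaussian angular noise in degrees added independently to
    each of the 8 window angles.
    """

    positions: list[tuple[str, list[float] | None]]
    noise_sd: float = 0.0
    n_frames: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for labels, weights in self.positions:
            if not labels or any(l not in PB_LABELS for l in labels):
                raise ValueError(f"bad source labels {labels!r}")
            if weights is not None:
                w = np.asarray(weights, dtype=float)
                if w.shape != (len(labels),) or (w < 0).any() or w.sum() <= 0:
                    raise ValueError("invalid sampling weights")


def gen_windows(spec: WindowGeneratorSpec,
                prototypes: np.ndarray | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Draw window tensors and their generating labels.

    Returns ``(angles, labels)`` with shapes (n_frames, n_positions, 8)
    and (n_frames, n_positions); each draw picks a source block by weight,
    emits its prototype 8-vector and adds independent wrapped noise.
    """
    if prototypes is None:
        prototypes = load_prototypes()
    rng = np.random.default_rng(spec.seed)
    F, P = spec.n_frames, len(spec.positions)
    angles = np.empty((F, P, 8))
    labels = np.empty((F, P), dtype="<U1")
    for p, (cands, weights) in enumerate(spec.positions):
        w = None
        if weights is not None:
            w = np.asarray(weights, dtype=float)
            w = w / w.sum()
        idx = rng.choice(len(cands), size=F, p=w)
        lab = np.array(list(cands))[idx]
        labels[:, p] = lab
        proto_idx = np.array([PB_LABELS.index(l) for l in cands])[idx]
        angles[:, p, :] = prototypes[proto_idx]
    if spec.noise_sd > 0:
        angles = angles + rng.normal(0.0, spec.noise_sd, size=angles.shape)
    return wrap_angle(angles), labels


# ---------------------------------------------------------------------------
# internal-to-Cartesian backbone construction


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D given atoms A, B, C, the C-D bond length, the B-C-D
    angle and the A-B-C-D torsion (degrees)."""
    ab = b - a
    bc = c - b
    bc_hat = bc / np.linalg.norm(bc)
    n = np.cross(ab, bc_hat)
    n_hat = n / np.linalg.norm(n)
    m_hat = np.cross(n_hat, bc_hat)
    theta = np.radians(angle)
    chi = np.radians(torsion)
    d_local = bond * np.array([
        -np.cos(theta),
        np.sin(theta) * np.cos(chi),
        np.sin(theta) * np.sin(chi),
    ])
    return c + d_local[0] * bc_hat + d_local[1] * m_hat + d_local[2] * n_hat


def build_backbone(phi_psi, sequence: str | None = None,
                   domain_id: str = "synthetic",
                   geometry: dict | None = None) -> Ensemble:
    """Build a single-frame backbone from per-residue (phi, psi) pairs.

    phi of the first residue and psi of the last are geometrically
    undefined and ignored; omega is fixed at 180 degrees.  The returned
    ensemble round-trips through dihedral extraction to within numerical
    precision of the inputs.
    """
    g = dict(IDEAL_GEOMETRY, **(geometry or {}))
    phi_psi = np.asarray(phi_psi, dtype=float)
    n = phi_psi.shape[0]
    if n < 3:
        raise ValueError("need at least 3 residues")
    coords = np.empty((n, 3, 3))
    # seed: N0 at origin, CA0 on x, C0 in the xy-plane
    coords[0, 0] = (0.0, 0.0, 0.0)
    coords[0, 1] = (g["bond_n_ca"], 0.0, 0.0)
    ang = np.radians(180.0 - g["angle_n_ca_c"])
    coords[0, 2] = coords[0, 1] + g["bond_ca_c"] * np.array(
        [np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n):
        Np, CAp, Cp = coords[i - 1]
        Ni = place_atom(Np, CAp, Cp, g["bond_c_n"], g["angle_ca_c_n"],
                        phi_psi[i - 1, 1])                    # psi(i-1)
        CAi = place_atom(CAp, Cp, Ni, g["bond_n_ca"], g["angle_c_n_ca"],
                         g["omega"])
        Ci = place_atom(Cp, Ni, CAi, g["bond_ca_c"], g["angle_n_ca_c"],
                        phi_psi[i, 0])                        # phi(i)
        coords[i] = (Ni, CAi, Ci)
    seq = sequence if sequence is not None else "A" * n
    if len(seq) != n:
        raise ValueError("sequence length mismatch")
    return Ensemble(domain_id=domain_id, coords=coords[None], residues=seq)


# ---------------------------------------------------------------------------
# positional-noise ensembles


def gen_ensemble3d(base: Ensemble, sigma, n_frames: int,
                   seed: int = 0) -> Ensemble:
    """Frames of ``base`` plus isotropic per-atom Gaussian displacement.

    ``sigma`` is a scalar or per-residue array of displacement standard
    deviations (Å, per axis); with superposition disabled the expected CA
    RMSF of a residue is its sigma times sqrt(3).
    """
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float),
                            (base.n_residues,))
    if (sigma < 0).any():
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    ref = base.coords[0]
    noise = rng.normal(size=(n_frames, base.n_residues, 3, 3))
    coords = ref[None] + noise * sigma[None, :, None, None]
    return Ensemble(domain_id=base.domain_id, coords=coords,
                    residues=base.residues, bfactors=base.bfactors)


# ---------------------------------------------------------------------------
# multi-class families


#: distinct backbone dihedral anchors used as conformational states; each
#: pair, repeated along a segment, assigns to a different Protein Block
#: (d, m, e, n, a, o respectively) with a wide RMSDA margin, so a region
#: switching among k anchors samples k distinct blocks at its core
STATE_ANCHORS: tuple[tuple[float, float], ...] = (
    (-114.8, 140.1),   # extended beta strand        -> block d
    (-100.0, -45.0),   # alpha-helical               -> block m
    (85.0, -175.0),    # positive-phi extended       -> block e
    (100.0, -110.0),   # left-handed extended        -> block n
    (125.0, 50.0),     # positive-phi / psi turn     -> block a
    (125.0, 0.0),      # positive-phi helical cap    -> block o
)

QUADRANTS = ("rigid", "mobile", "flexible", "deformable")


@dataclass
class RegionSpec:
    """One contiguous block of MSA columns with per-class behaviour."""

    name: str
    start: int                 # 1-based MSA column, inclusive
    end: int
    quadrants: tuple[str, ...]  # one target per class
    gap_rate: float = 0.0

    def core(self) -> tuple[int, int]:
        """Columns (1-based, inclusive) whose 5-residue windows lie fully
        inside the region; gap insertion and truth labels avoid/target
        exactly these."""
        return (self.start + 2, self.end - 2)


@dataclass
class FamilySpec:
    """Recipe for a multi-class family of domains sharing an MSA."""

    n_classes: int
    domains_per_class: int
    n_frames: int
    regions: list[RegionSpec]
    seed: int = 0
    mobility_sigma: float = 2.5    # Å, rigid-body translation sd per axis
    flexible_sigma: float = 2.5    # Å, same, for flexible regions
    n_states: int = 5              # dihedral states in flexible/deformable
    jitter_sigma: float = 0.05     # Å, per-atom background noise

    def __post_init__(self) -> None:
        if self.n_states < 1 or self.n_states > len(STATE_ANCHORS):
            raise ValueError(
                f"n_states must be in [1, {len(STATE_ANCHORS)}] "
                "(the number of distinct backbone states available)")
        cols = sorted((r.start, r.end) for r in self.regions)
        expect = 1
        for lo, hi in cols:
            if lo != expect or hi < lo:
                raise ValueError("regions must tile the columns contiguously")
            expect = hi + 1
        for r in self.regions:
            if len(r.quadrants) != self.n_classes:
                raise ValueError(
                    f"region {r.name}: need one quadrant per class")
            if any(q not in QUADRANTS for q in r.quadrants):
                raise ValueError(f"region {r.name}: unknown quadrant label")
            if not 0 <= r.gap_rate <= 1:
                raise ValueError("gap_rate must be in [0, 1]")

    @property
    def n_columns(self) -> int:
        return max(r.end for r in self.regions)


@dataclass
class FamilyResult:
    """Generated family: ensembles, alignment and ground truth."""

    ensembles: dict[str, Ensemble]
    msa: MSA
    class_labels: dict[str, int]
    true_quadrants: dict[int, np.ndarray]   # per class, per column ('' = untargeted)
    spec: FamilySpec


def _quadrant_settings(spec: FamilySpec, quadrant: str) -> tuple[float, int]:
    return {
        "rigid": (0.0, 1),
        "mobile": (spec.mobility_sigma, 1),
        "flexible": (spec.flexible_sigma, spec.n_states),
        "deformable": (0.0, spec.n_states),
    }[quadrant]


def _build_chain_coords(phi_psi: np.ndarray) -> np.ndarray:
    return build_backbone(phi_psi).coords[0]


def gen_family(spec: FamilySpec,
               prototypes: np.ndarray | None = None) -> FamilyResult:
    """Generate a family of domains with class-specific dynamics.

    Per class, a template sequence and per-region settings are drawn; per
    domain, gaps are inserted at the region's ``gap_rate`` (never inside
    the 5-column region core, so block windows survive) and frames are
    assembled from the base backbone by (i) swapping targeted regions
    among ``n_states`` locally-aligned dihedral conformers (drives Neq)
    and (ii) translating targeted regions rigidly with Gaussian amplitude
    (drives RMSF), plus a small per-atom jitter everywhere.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.n_columns
    base_phi_psi_col = np.tile(np.array(STATE_ANCHORS[0]), (L, 1))

    ensembles: dict[str, Ensemble] = {}
    sequences: dict[str, str] = {}
    class_labels: dict[str, int] = {}
    true_quadrants: dict[int, np.ndarray] = {}

    for ci in range(spec.n_classes):
        template = "".join(rng.choice(list(AA_ALPHABET), size=L))
        truth = np.full(L, "", dtype=object)
        settings = []
        for r in spec.regions:
            q = r.quadrants[ci]
            sigma, k = _quadrant_settings(spec, q)
            settings.append((r, q, sigma, k))
            lo, hi = r.core()
            if hi >= lo:
                truth[lo - 1:hi] = q
        true_quadrants[ci] = truth

        for di in range(spec.domains_per_class):
            did = f"c{ci}_d{di}"
            # gap placement: only outside region cores
            present = np.ones(L, dtype=bool)
            for r, q, sigma, k in settings:
                if r.gap_rate <= 0:
                    continue
                lo, hi = r.core()
                for col in range(r.start, r.end + 1):
                    if lo <= col <= hi:
                        continue
                    if rng.random() < r.gap_rate:
                        present[col - 1] = False
            # keep chain ends intact so the ensemble has stable termini
            present[0] = present[-1] = True
            cols = np.flatnonzero(present)          # 0-based present columns
            col_to_res = {c: i for i, c in enumerate(cols)}
            n_res = cols.size

            base_pp = base_phi_psi_col[cols]
            base = _build_chain_coords(base_pp)

            # per-region conformational states, aligned onto the base region
            region_states: list[tuple[np.ndarray, int, float, np.ndarray]] = []
            for r, q, sigma, k in settings:
                ridx = np.array([col_to_res[c] for c in
                                 range(r.start - 1, r.end)
                                 if c in col_to_res])
                if ridx.size == 0:
                    continue
                variants = np.empty((k, ridx.size, 3, 3))
                variants[0] = base[ridx]
                for s in range(1, k):
                    pp = base_pp.copy()
                    pp[ridx] = STATE_ANCHORS[s]
                    chain = _build_chain_coords(pp)
                    seg = chain[ridx].reshape(-1, 3)
                    ref = base[ridx].reshape(-1, 3)
                    R, t, _ = superpose(seg, ref)
                    variants[s] = (seg @ R.T + t).reshape(ridx.size, 3, 3)
                region_states.append((ridx, k, sigma, variants))

            coords = np.broadcast_to(
                base, (spec.n_frames, n_res, 3, 3)).copy()
            for ridx, k, sigma, variants in region_states:
                if k > 1:
                    choice = rng.integers(k, size=spec.n_frames)
                    coords[:, ridx] = variants[choice]
                if sigma > 0:
                    shift = rng.normal(0.0, sigma, size=(spec.n_frames, 3))
                    coords[:, ridx] += shift[:, None, None, :]
            if spec.jitter_sigma > 0:
                coords = coords + rng.normal(
                    0.0, spec.jitter_sigma, size=coords.shape)

            # synthetic experimental B-factors: 8 pi^2 <u^2> of the intended
            # per-axis displacement, plus mild multiplicative noise
            sig2 = np.full(n_res, spec.jitter_sigma ** 2)
            for ridx, k, sigma, variants in region_states:
                sig2[ridx] += sigma ** 2
            bfac = 8 * np.pi ** 2 * sig2
            bfac = bfac * rng.uniform(0.8, 1.2, size=n_res) + 1.0

            seq = "".join(template[c] for c in cols)
            gapped = "".join(template[c] if present[c] else "-"
                             for c in range(L))
            ensembles[did] = Ensemble(domain_id=did, coords=coords,
                                      residues=seq, bfactors=bfac)
            sequences[did] = gapped
            class_labels[did] = ci

    return FamilyResult(ensembles=ensembles, msa=MSA(sequences=sequences),
                        class_labels=class_labels,
                        true_quadrants=true_quadrants, spec=spec)


def default_family_spec(n_classes: int = 4, domains_per_class: int = 5,
                        n_frames: int = 200, seed: int = 0,
                        gap_rate: float = 0.15) -> FamilySpec:
    """A standard family layout: four 7-column loops on a 120-column
    scaffold; class ``c`` is flexible at loop ``c mod 4`` and mobile at
    loop ``(c+1) mod 4``, rigid elsewhere.

    The layout keeps the moving fraction of each chain small enough that
    the targeted loops clear the normalised-RMSF threshold of 2 (a
    z-score saturates at sqrt((1-p)/p) for a hot fraction p).
    """
    bounds = [(1, 20), (21, 27), (28, 47), (48, 54), (55, 74), (75, 81),
              (82, 101), (102, 108), (109, 120)]
    loops = {1: 0, 3: 1, 5: 2, 7: 3}   # region index -> loop number
    regions = []
    for i, (lo, hi) in enumerate(bounds):
        if i in loops:
            ln = loops[i]
            quads = tuple(
                "flexible" if ln == c % 4
                else ("mobile" if ln == (c + 1) % 4 else "rigid")
                for c in range(n_classes))
            regions.append(RegionSpec(f"loop{ln + 1}", lo, hi, quads))
        else:
            regions.append(RegionSpec(
                f"fr{i}", lo, hi, ("rigid",) * n_classes,
                gap_rate=gap_rate))
    return FamilySpec(n_classes=n_classes,
                      domains_per_class=domains_per_class,
                      n_frames=n_frames, regions=regions, seed=seed)
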
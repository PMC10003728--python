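"""Reading and writing of the formats the pipeline touches.

Conformational ensembles travel as multi-model PDB files (one MODEL per
frame), alignments as FASTA or Clustal files, and region/threshold
configuration as YAML.  Internally residues are indexed 0-based and
contiguous; the author PDB residue numbering is kept only as metadata,
because insertion codes in antibody numbering schemes make raw ``resSeq``
unsafe as an array index.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml
from Bio import AlignIO, SeqIO
from Bio.PDB import PDBParser

__all__ = [
    "BACKBONE_ATOMS",
    "Ensemble",
    "MSA",
    "RegionConfig",
    "read_ensemble",
    "write_ensemble",
    "read_msa",
    "load_region_config",
    "DEFAULT_REGIONS",
    "REGION_PRESETS",
]

#: backbone atoms stored per residue, in storage order
BACKBONE_ATOMS = ("N", "CA", "C")

_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_AA1TO3 = {v: k for k, v in _AA3TO1.items()}


@dataclass
class Ensemble:
    """An ordered set of backbone conformations for one domain.

    Attributes
    ----------
    domain_id : str
        Identifier linking the ensemble to its MSA record.
    coords : np.ndarray, shape (n_frames, n_residues, 3, 3), Å
        Backbone coordinates; axis 2 runs over (N, CA, C).
    residues : str
        One-letter amino-acid sequence (ungapped).
    bfactors : np.ndarray or None, shape (n_residues,), Å²
        Experimental CA B-factors from the reference (first) model.
    resseq : np.ndarray or None
        Author residue numbers of the first model (metadata only).
    """

    domain_id: str
    coords: np.ndarray
    residues: str
    bfactors: np.ndarray | None = None
    resseq: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 4 or self.coords.shape[2:] != (3, 3):
            raise ValueError(
                "coords must have shape (n_frames, n_residues, 3 atoms, 3)"
            )
        if self.coords.shape[1] != len(self.residues):
            raise ValueError(
                f"{self.coords.shape[1]} coordinate rows for "
                f"{len(self.residues)} residues"
            )
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates in ensemble")
        if self.bfactors is not None:
            self.bfactors = np.asarray(self.bfactors, dtype=float)
            if self.bfactors.shape != (self.n_residues,):
                raise ValueError("bfactors length mismatch")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]

    def ca(self) -> np.ndarray:
        """CA coordinates, shape (n_frames, n_residues, 3)."""
        return self.coords[:, :, 1, :]


@dataclass
class MSA:
    """A stored multiple sequence alignment (computing one is out of scope)."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            bad = [k for k, s in self.sequences.items()
                   if len(s) != max(lengths)]
            raise ValueError(f"ragged alignment; offending records: {bad}")
        # normalise '.' gaps to '-'
        self.sequences = {k: s.replace(".", "-").upper()
                          for k, s in self.sequences.items()}

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    def ungapped(self, domain_id: str) -> str:
        return self.sequences[domain_id].replace("-", "")

    def validate_against(self, ensemble: Ensemble) -> None:
        """Check that the record's ungapped sequence matches the ensemble."""
        seq = self.ungapped(ensemble.domain_id)
        if seq != ensemble.residues:
            raise ValueError(
                f"MSA record {ensemble.domain_id!r} does not match the "
                f"ensemble residues ({seq!r} vs {ensemble.residues!r})"
            )


# Region intervals in 1-based inclusive MSA-column coordinates.  The source
# study's prose gives slightly different CDR boundaries in different places
# (CDR1 starting at 25 or 26, CDR3 ending at 139 or 140); both readings ship
# as named presets and overlaps are resolved by CDR-over-FR priority.
DEFAULT_REGIONS: dict[str, tuple[int, int]] = {
    "FR1": (1, 25),
    "CDR1": (26, 44),
    "FR2": (45, 62),
    "CDR2": (63, 74),
    "FR3": (77, 113),
    "CDR3": (113, 140),
    "FR4": (140, 150),
}

REGION_PRESETS: dict[str, dict[str, tuple[int, int]]] = {
    "main": DEFAULT_REGIONS,
    "none": {},
    "alt": {
        "FR1": (1, 24),
        "CDR1": (25, 44),
        "FR2": (45, 62),
        "CDR2": (63, 74),
        "FR3": (75, 113),
        "CDR3": (113, 139),
        "FR4": (140, 150),
    },
}


@dataclass
class RegionConfig:
    """FR/CDR intervals plus the analysis thresholds and clustering knobs."""

    regions: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_REGIONS))
    rmsf_threshold: float = 2.0   # on the per-domain z-score of RMSF
    neq_threshold: float = 3.0    # effective number of Protein Blocks
    linkage: str = "complete"
    k: int = 4
    cut_height: float | None = None
    min_cluster_size: int = 2

    def __post_init__(self) -> None:
        if self.rmsf_threshold <= 0 or self.neq_threshold <= 0:
            raise ValueError("thresholds must be positive")
        for name, (lo, hi) in self.regions.items():
            if lo < 1 or hi < lo:
                raise ValueError(f"bad interval for {name}: ({lo}, {hi})")

    def validate_columns(self, n_columns: int) -> None:
        for name, (lo, hi) in self.regions.items():
            if hi > n_columns:
                raise ValueError(
                    f"region {name} ({lo}-{hi}) exceeds alignment "
                    f"width {n_columns}")


def load_region_config(path) -> RegionConfig:
    """Load a :class:`RegionConfig` from YAML.

    Recognised keys: ``preset`` (name of a shipped interval set),
    ``regions`` (mapping name -> [start, end]), ``rmsf_threshold``,
    ``neq_threshold``, ``linkage``, ``k``, ``cut_height``,
    ``min_cluster_size``.  Explicit ``regions`` entries override the preset.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    regions = dict(REGION_PRESETS[raw.pop("preset", "main")])
    for name, iv in (raw.pop("regions", None) or {}).items():
        regions[name] = (int(iv[0]), int(iv[1]))
    return RegionConfig(regions=regions, **raw)


# ---------------------------------------------------------------------------
# PDB ensembles


def read_ensemble(path, domain_id: str | None = None) -> Ensemble:
    """Read a multi-model PDB file into an :class:`Ensemble`.

    Frames are ordered by MODEL number; a single-structure PDB yields a
    one-frame ensemble (usable for the B-factor branch only).  Every residue
    must carry N, CA and C atoms in every model; a missing backbone atom or
    an inconsistent residue count across models is a hard error.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("ens", str(path))
    models = sorted(structure, key=lambda m: m.serial_num)
    if not models:
        raise ValueError(f"{path}: no MODEL records")

    frames, n_res = [], None
    residues_letters: str = ""
    bfactors = resseq = None
    for mi, model in enumerate(models):
        residues = [r for chain in model for r in chain
                    if r.id[0] == " " or r.resname in _AA3TO1]
        if n_res is None:
            n_res = len(residues)
        elif len(residues) != n_res:
            raise ValueError(
                f"{path}: model {mi + 1} has {len(residues)} residues, "
                f"expected {n_res}")
        frame = np.empty((n_res, 3, 3))
        for ri, res in enumerate(residues):
            for ai, name in enumerate(BACKBONE_ATOMS):
                if name not in res:
                    raise ValueError(
                        f"{path}: residue {res.resname}{res.id[1]} in model "
                        f"{mi + 1} is missing backbone atom {name}")
                frame[ri, ai] = res[name].coord
        frames.append(frame)
        if mi == 0:
            residues_letters = "".join(
                _AA3TO1.get(r.resname, "X") for r in residues)
            bfactors = np.array([r["CA"].bfactor for r in residues])
            resseq = np.array([r.id[1] for r in residues])
    return Ensemble(
        domain_id=domain_id or str(path),
        coords=np.stack(frames),
        residues=residues_letters,
        bfactors=bfactors,
        resseq=resseq,
    )


def write_ensemble(ensemble: Ensemble, path) -> None:
    """Write an :class:`Ensemble` as a standard multi-model PDB file."""
    if ensemble.n_frames == 0:
        raise ValueError("cannot write an ensemble with no frames")
    if np.any(np.abs(ensemble.coords) >= 10000):
        raise ValueError("coordinates outside the PDB fixed-column range")
    lines: list[str] = []
    for fi in range(ensemble.n_frames):
        lines.append(f"MODEL     {fi + 1:4d}")
        serial = 1
        for ri, aa in enumerate(ensemble.residues):
            resname = _AA1TO3.get(aa, "UNK")
            rnum = (int(ensemble.resseq[ri]) if ensemble.resseq is not None
                    else ri + 1)
            for ai, name in enumerate(BACKBONE_ATOMS):
                x, y, z = ensemble.coords[fi, ri, ai]
                b = 0.0
                if ai == 1 and ensemble.bfactors is not None:
                    b = float(ensemble.bfactors[ri])
                lines.append(
                    f"ATOM  {serial:5d} {name:^4s} {resname:>3s} A"
                    f"{rnum:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}"
                    f"{b:6.2f}          {name[0]:>2s}"
                )
                serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# MSAs


def read_msa(path) -> MSA:
    """Read a FASTA or Clustal alignment into an :class:`MSA`.

    The format is sniffed from the first non-blank line; '-' and '.' are
    both accepted as gap characters.
    """
    with open(path) as fh:
        text = fh.read()
    first = next((ln for ln in text.splitlines() if ln.strip()), "")
    fmt = "clustal" if first.upper().startswith("CLUSTAL") else "fasta"
    handle = io.StringIO(text)
    if fmt == "fasta":
        records = list(SeqIO.parse(handle, "fasta"))
        seqs = {r.id: str(r.seq) for r in records}
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) > 1:
            width = max(lengths)
            bad = [k for k, s in seqs.items() if len(s) != width]
            raise ValueError(f"{path}: ragged alignment, records {bad}")
    else:
        aln = AlignIO.read(handle, "clustal")
        seqs = {r.id: str(r.seq) for r in aln}
    if not seqs:
        raise ValueError(f"{path}: no records")
    return MSA(sequences=seqs)
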
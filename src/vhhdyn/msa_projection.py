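"""Mapping per-residue metrics onto alignment columns.

Cross-domain comparison requires a common coordinate system: the columns
of the multiple sequence alignment.  A residue contributes to a column
statistic only where the domain actually has a residue at that column —
gap columns carry an explicit missing marker (NaN), never a zero.
MSA columns are 1-based in all user-facing coordinates (matching the
usual alignment-viewer convention); internal arrays are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MSA, RegionConfig
from .metrics import MetricProfile

__all__ = [
    "AlignmentMap",
    "build_alignment_map",
    "project",
    "unproject",
    "aggregate",
    "annotate",
]

UNANNOTATED = ""


@dataclass
class AlignmentMap:
    """Bijections between residue indices and MSA columns per domain.

    ``res_to_col[d][i]`` is the 1-based column of the i-th residue
    (0-based) of domain ``d``; ``col_to_res[d]`` is the inverse, with -1
    at gap columns.  ``occupancy[c]`` counts domains with a residue at
    0-based column ``c``.
    """

    n_columns: int
    res_to_col: dict[str, np.ndarray]
    col_to_res: dict[str, np.ndarray]
    occupancy: np.ndarray

    def domains(self):
        return list(self.res_to_col)


def build_alignment_map(msa: MSA) -> AlignmentMap:
    """Derive the residue/column maps and column occupancy from an MSA."""
    n = msa.n_columns
    res_to_col: dict[str, np.ndarray] = {}
    col_to_res: dict[str, np.ndarray] = {}
    occupancy = np.zeros(n, dtype=int)
    for did, seq in msa.sequences.items():
        cols = np.flatnonzero(np.frombuffer(seq.encode(), dtype="S1") != b"-")
        res_to_col[did] = cols + 1
        inv = np.full(n, -1, dtype=int)
        inv[cols] = np.arange(cols.size)
        col_to_res[did] = inv
        occupancy[cols] += 1
    return AlignmentMap(n, res_to_col, col_to_res, occupancy)


def project(profile: MetricProfile, amap: AlignmentMap,
            domain_id: str) -> MetricProfile:
    """Relocate a residue-indexed profile onto MSA columns.

    Gap columns are NaN; the number of non-missing column entries equals
    the residue count of the domain.
    """
    cols = amap.res_to_col[domain_id]
    if profile.values.shape[0] != cols.size:
        raise ValueError(
            f"profile has {profile.values.shape[0]} values but domain "
            f"{domain_id!r} has {cols.size} aligned residues")
    out = np.full(amap.n_columns, np.nan)
    out[cols - 1] = profile.values
    return MetricProfile(profile.name, out, units=profile.units,
                         scope=domain_id, index="column")


def unproject(profile: MetricProfile, amap: AlignmentMap,
              domain_id: str) -> MetricProfile:
    """Inverse of :func:`project`: read a column profile back per residue."""
    cols = amap.res_to_col[domain_id]
    return MetricProfile(profile.name, profile.values[cols - 1],
                         units=profile.units, scope=domain_id,
                         index="residue")


def aggregate(profiles: list[MetricProfile]) -> pd.DataFrame:
    """Per-column mean, population sd and occupancy over column profiles.

    Statistics pool present (non-NaN) values only; sd is NaN at
    occupancy 1 and below.  Returns a DataFrame indexed by 1-based column
    with columns ``mean``, ``sd``, ``occupancy``.
    """
    if not profiles:
        raise ValueError("no profiles to aggregate")
    mat = np.vstack([p.values for p in profiles])
    occ = (~np.isnan(mat)).sum(axis=0)
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.where(occ > 0, np.nanmean(mat, axis=0), np.nan)
        sd = np.where(occ > 1, np.nanstd(mat, axis=0, ddof=0), np.nan)
    return pd.DataFrame(
        {"mean": mean, "sd": sd, "occupancy": occ},
        index=pd.RangeIndex(1, mat.shape[1] + 1, name="column"),
    )


def annotate(config: RegionConfig, n_columns: int) -> np.ndarray:
    """Label every MSA column with its FR/CDR region.

    Overlapping intervals are resolved with CDR-over-FR priority, then by
    the listed order of the config; unannotated columns get ''.
    Intervals outside [1, n_columns] are a hard error.
    """
    config.validate_columns(n_columns)
    labels = np.full(n_columns, UNANNOTATED, dtype=object)
    # Write FRs then CDRs, each class in reverse listed order, so CDRs
    # overwrite FRs at shared boundary columns and the first-listed
    # interval wins inside a class.
    frs = [(n, iv) for n, iv in config.regions.items()
           if not n.upper().startswith("CDR")]
    cdrs = [(n, iv) for n, iv in config.regions.items()
            if n.upper().startswith("CDR")]
    for name, (lo, hi) in list(reversed(frs)) + list(reversed(cdrs)):
        labels[lo - 1:hi] = name
    return labels
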
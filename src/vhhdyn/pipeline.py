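"""End-to-end convenience wrappers over the analysis stages.

Each function here is a thin composition of the module-level operations
(block assignment -> per-residue metrics -> MSA projection -> clustering /
classification); they define the default data flow used by the command
line and the test harness.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .clustering import ClusterResult, hcluster, profile_distance_matrix
from .io_formats import Ensemble, MSA, RegionConfig
from .metrics import (FrequencyVector, MetricProfile, neq, pb_count_matrix,
                      pb_frequencies, rmsf, znormalise)
from .msa_projection import AlignmentMap, build_alignment_map, project
from .flexibility_classes import classify_profile
from .pb import assign_ensemble, extract_dihedrals

__all__ = [
    "assign_domain",
    "domain_metrics",
    "pb_column_counts",
    "pb_column_frequencies",
    "rmsf_column_profiles",
    "cluster_by_rmsf",
    "classify_domains",
]


def assign_domain(ensemble: Ensemble) -> np.ndarray:
    """Protein Block matrix (frames x residues) of one ensemble."""
    return assign_ensemble(extract_dihedrals(ensemble))


def domain_metrics(ensemble: Ensemble,
                   pbmatrix: np.ndarray | None = None,
                   fit: bool = True) -> pd.DataFrame:
    """Per-residue metric table for one domain.

    Columns: ``bfactor`` (Å², NaN when absent), ``bfactor_norm``,
    ``rmsf`` (Å), ``rmsf_norm`` and ``neq``; indexed by 0-based residue.
    """
    if pbmatrix is None:
        pbmatrix = assign_domain(ensemble)
    r = rmsf(ensemble, fit=fit).values
    neq_vals = np.array([neq(pb_frequencies(pbmatrix[:, i]))
                         for i in range(ensemble.n_residues)])
    bf = (ensemble.bfactors if ensemble.bfactors is not None
          else np.full(ensemble.n_residues, np.nan))
    bnorm = (znormalise(bf) if np.isfinite(bf).all()
             else np.full_like(bf, np.nan))
    return pd.DataFrame({
        "bfactor": bf,
        "bfactor_norm": bnorm,
        "rmsf": r,
        "rmsf_norm": znormalise(r),
        "neq": neq_vals,
    }, index=pd.RangeIndex(ensemble.n_residues, name="residue_index"))


def pb_column_counts(ensemble: Ensemble, amap: AlignmentMap,
                     pbmatrix: np.ndarray | None = None) -> np.ndarray:
    """PB observation counts in MSA-column space, shape (n_columns, 16)."""
    if pbmatrix is None:
        pbmatrix = assign_domain(ensemble)
    per_res = pb_count_matrix(pbmatrix)
    out = np.zeros((amap.n_columns, 16))
    cols = amap.res_to_col[ensemble.domain_id]
    out[cols - 1] = per_res
    return out


def pb_column_frequencies(counts: np.ndarray) -> dict[int, FrequencyVector]:
    """Column -> frequency vector map from a (n_columns, 16) count array."""
    return {c + 1: FrequencyVector.from_counts(counts[c])
            for c in range(counts.shape[0])
            if counts[c].sum() > 0}


def rmsf_column_profiles(ensembles: dict[str, Ensemble], msa: MSA,
                         fit: bool = True,
                         normalised: bool = False) -> dict[str, np.ndarray]:
    """Column-projected RMSF profile per domain (NaN at gaps)."""
    amap = build_alignment_map(msa)
    out = {}
    for did, ens in ensembles.items():
        msa.validate_against(ens)
        vals = rmsf(ens, fit=fit).values
        if normalised:
            vals = znormalise(vals)
        prof = MetricProfile("rmsf", vals, units="angstrom", scope=did)
        out[did] = project(prof, amap, did).values
    return out


def cluster_by_rmsf(ensembles: dict[str, Ensemble], msa: MSA,
                    k: int = 4, min_size: int = 2,
                    fit: bool = True) -> ClusterResult:
    """The standard clustering route: RMSF -> MSA-guided distance ->
    complete-linkage hierarchical clustering."""
    profiles = rmsf_column_profiles(ensembles, msa, fit=fit)
    dm = profile_distance_matrix(profiles)
    return hcluster(dm, k=k, min_size=min_size)


def classify_domains(ensembles: dict[str, Ensemble], msa: MSA,
                     config: RegionConfig | None = None
                     ) -> pd.DataFrame:
    """Quadrant labels per (domain, MSA column).

    Returns a tidy frame with columns ``domain_id``, ``column``,
    ``rmsf_norm``, ``neq``, ``label``.
    """
    config = config or RegionConfig()
    amap = build_alignment_map(msa)
    rows = []
    for did, ens in ensembles.items():
        pbm = assign_domain(ens)
        table = domain_metrics(ens, pbmatrix=pbm)
        cols = amap.res_to_col[did]
        labels = classify_profile(table["rmsf_norm"].to_numpy(),
                                  table["neq"].to_numpy(), config)
        for i in range(ens.n_residues):
            rows.append({
                "domain_id": did,
                "column": int(cols[i]),
                "rmsf_norm": table["rmsf_norm"].iloc[i],
                "neq": table["neq"].iloc[i],
                "label": labels[i],
            })
    return pd.DataFrame(rows)
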
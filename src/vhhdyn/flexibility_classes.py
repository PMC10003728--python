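"""Interpretive layer: flexibility quadrants, cluster deviation profiles,
and CDR termini geometry.

Crossing the per-domain normalised RMSF (global displacement) with Neq
(local backbone conformational diversity) separates four behaviours:

* **flexible** — normalised RMSF > 2.0 and Neq > 3.0: the backbone both
  moves and changes local conformation;
* **mobile**   — normalised RMSF > 2.0 and Neq <= 3.0: a region that moves
  as a rigid body, its internal conformation essentially unchanged;
* **deformable** — normalised RMSF <= 2.0 and Neq > 3.0: local
  conformational change without large overall displacement;
* **rigid**    — neither exceeds its threshold.

The thresholds (2.0 on the RMSF z-score, 3.0 on Neq) are strict
inequalities: a value exactly at a threshold falls in the non-exceeding
class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import Ensemble, MSA, RegionConfig
from .metrics import (FrequencyVector, aa_frequencies, delta_aa, delta_pb)
from .msa_projection import AlignmentMap

__all__ = [
    "FLEX_LABELS",
    "classify",
    "classify_profile",
    "cluster_profiles",
    "termini_distance",
    "termini_table",
]

FLEX_LABELS = ("rigid", "mobile", "deformable", "flexible")


def classify(rmsf_norm: float, neq_value: float,
             config: RegionConfig | None = None) -> str | None:
    """Quadrant label for one (normalised RMSF, Neq) pair.

    Undefined (NaN) inputs propagate as ``None``.
    """
    if np.isnan(rmsf_norm) or np.isnan(neq_value):
        return None
    rt = config.rmsf_threshold if config else 2.0
    nt = config.neq_threshold if config else 3.0
    moving = rmsf_norm > rt
    diverse = neq_value > nt
    if moving and diverse:
        return "flexible"
    if moving:
        return "mobile"
    if diverse:
        return "deformable"
    return "rigid"


def classify_profile(rmsf_norm: np.ndarray, neq_values: np.ndarray,
                     config: RegionConfig | None = None) -> np.ndarray:
    """Vectorised :func:`classify`; missing positions get ''."""
    rmsf_norm = np.asarray(rmsf_norm, dtype=float)
    neq_values = np.asarray(neq_values, dtype=float)
    out = np.array([
        classify(r, n, config) or ""
        for r, n in zip(rmsf_norm, neq_values)
    ], dtype=object)
    return out


def _pooled_pb_freq(counts_by_domain: dict[str, np.ndarray],
                    members: list[str], col: int) -> FrequencyVector:
    total = np.zeros(16)
    for d in members:
        total += counts_by_domain[d][col]
    return FrequencyVector.from_counts(total)


def cluster_profiles(members: list[str],
                     pb_counts: dict[str, np.ndarray],
                     msa: MSA,
                     amap: AlignmentMap,
                     aa_weighting: str = "sequence") -> pd.DataFrame:
    """Per-column ΔPB and ΔAA of one cluster against the whole dataset.

    Parameters
    ----------
    members : list of domain ids forming the cluster (subset of the
        dataset; the whole dataset is every domain in ``pb_counts``).
    pb_counts : per domain, an (n_columns, 16) array of PB observation
        counts in MSA-column space ('Z' and gap columns count zero).
    msa, amap : alignment and its map (for the amino-acid branch).
    aa_weighting : "sequence" (one vote per domain; amino acids are static
        sequence features) — the only mode for ΔAA.

    PB frequencies pool frames across all domains present at a column
    (frame-weighted).  Returns a DataFrame indexed by 1-based column with
    ``delta_pb`` and ``delta_aa`` (NaN where either side is undefined).
    """
    if not members:
        raise ValueError("empty cluster")
    dataset = list(pb_counts)
    unknown = set(members) - set(dataset)
    if unknown:
        raise ValueError(f"cluster members outside dataset: {sorted(unknown)}")
    n_cols = amap.n_columns
    dpb = np.full(n_cols, np.nan)
    daa = np.full(n_cols, np.nan)
    seqs = msa.sequences
    for c in range(n_cols):
        fc = _pooled_pb_freq(pb_counts, members, c)
        fd = _pooled_pb_freq(pb_counts, dataset, c)
        if fc.defined and fd.defined:
            dpb[c] = delta_pb(fc, fd)
        ac = aa_frequencies([seqs[d][c] for d in members])
        ad = aa_frequencies([seqs[d][c] for d in dataset])
        if ac.defined and ad.defined:
            daa[c] = delta_aa(ac, ad)
    return pd.DataFrame(
        {"delta_pb": dpb, "delta_aa": daa},
        index=pd.RangeIndex(1, n_cols + 1, name="column"),
    )


@dataclass
class TerminiStats:
    """CA-CA distance statistics between a CDR's first and last residue."""

    domain_id: str
    region: str
    mean: float
    sd: float
    n_frames: int


def termini_distance(ensemble: Ensemble, amap: AlignmentMap,
                     interval: tuple[int, int],
                     region_name: str = "") -> TerminiStats | None:
    """Per-frame CA-CA distance between the first and last occupied
    column of a CDR interval, summarised as mean and population sd (Å).

    The CDR termini are this domain's first and last residue inside the
    interval; if the domain has no residue in the interval, the entry is
    flagged missing (``None``).
    """
    lo, hi = interval
    inv = amap.col_to_res[ensemble.domain_id]
    inside = inv[lo - 1:hi]
    present = inside[inside >= 0]
    if present.size < 2:
        return None
    i, j = int(present[0]), int(present[-1])
    ca = ensemble.ca()
    d = np.linalg.norm(ca[:, i] - ca[:, j], axis=1)
    return TerminiStats(ensemble.domain_id, region_name,
                        float(d.mean()), float(d.std(ddof=0)),
                        ensemble.n_frames)


def termini_table(ensembles: dict[str, Ensemble], amap: AlignmentMap,
                  config: RegionConfig) -> pd.DataFrame:
    """Termini statistics for every domain and every CDR region."""
    rows = []
    for name, interval in config.regions.items():
        if not name.upper().startswith("CDR"):
            continue
        for did, ens in ensembles.items():
            st = termini_distance(ens, amap, interval, region_name=name)
            rows.append({
                "domain_id": did,
                "cdr": name,
                "mean_A": st.mean if st else np.nan,
                "sd_A": st.sd if st else np.nan,
            })
    return pd.DataFrame(rows)
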
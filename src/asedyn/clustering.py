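"""k-means grouping of expression and allele-frequency trajectories.

Combined-expression profiles are centered and scaled per gene before
clustering; allele-frequency (ASE) profiles are centered only, so that the
magnitude of the imbalance is preserved.  Genes with missing timepoints are
removed first (k-means has no missing-data handling), and zero-variance
genes cannot be scaled and are excluded with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = ["ClusterModel", "cluster_profiles", "classify_transition"]


@dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray
    assignments: pd.Series  # gene -> cluster id
    inertia: float
    mode: str
    dropped_missing: list
    dropped_zero_variance: list


def _normalize_profiles(profiles: pd.DataFrame, mode: str):
    values = profiles.to_numpy(dtype=float)
    means = values.mean(axis=1, keepdims=True)
    centered = values - means
    if mode == "center_only":
        return centered, np.zeros(len(profiles), dtype=bool)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    zero_var = (sd == 0).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(sd > 0, centered / np.where(sd > 0, sd, 1.0), 0.0)
    return scaled, zero_var


def cluster_profiles(
    profiles: pd.DataFrame,
    k: int = 12,
    mode: str = "center_scale",
    seed: int | None = None,
    n_restarts: int = 25,
) -> ClusterModel:
    """Cluster per-gene timecourse profiles into ``k`` groups.

    ``profiles`` is a genes x timepoints frame (NaN marks missing data).
    Lloyd's algorithm with k-means++ initialization, best of ``n_restarts``
    restarts by within-cluster sum of squares.  ``mode`` is
    ``center_scale`` (per-gene mean 0, sd 1) or ``center_only``.
    """
    if mode not in ("center_scale", "center_only"):
        raise ValueError(f"unknown mode {mode!r}")
    missing = profiles.isna().any(axis=1)
    dropped_missing = profiles.index[missing].tolist()
    work = profiles.loc[~missing]

    norm, zero_var = _normalize_profiles(work, mode)
    dropped_zero = work.index[zero_var].tolist()
    if dropped_zero:
        warnings.warn(
            f"excluding {len(dropped_zero)} zero-variance profile(s) "
            "that cannot be scaled",
            stacklevel=2,
        )
    keep = ~zero_var
    norm = norm[keep]
    genes = work.index[keep]
    if k > len(genes):
        raise ValueError(f"k={k} exceeds the {len(genes)} usable genes")

    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_restarts,
        algorithm="lloyd",
        random_state=seed,
    ).fit(norm)
    return ClusterModel(
        k=k,
        centroids=km.cluster_centers_,
        assignments=pd.Series(km.labels_, index=genes, name="cluster"),
        inertia=float(km.inertia_),
        mode=mode,
        dropped_missing=dropped_missing,
        dropped_zero_variance=dropped_zero,
    )


def classify_transition(
    series: np.ndarray,
    shift_index: int,
    window: int = 3,
    margin: float = 0.0,
) -> str:
    """Label an ASE trajectory by where its deviation is largest.

    The series is centered; if the largest absolute centered value inside
    ``shift_index +/- window`` strictly exceeds the absolute centered values
    at both endpoints by ``margin``, the gene's imbalance peaks during the
    metabolic transition (``transition_extremum``); otherwise the imbalance
    keeps growing or shrinking toward an endpoint (``environment_dependent``).
    """
    s = np.asarray(series, dtype=float)
    s = s - np.nanmean(s)
    lo, hi = shift_index - window, shift_index + window + 1
    if lo < 0 or hi > len(s):
        raise ValueError("shift window extends outside the series")
    peak = np.nanmax(np.abs(s[lo:hi]))
    if peak > abs(s[0]) + margin and peak > abs(s[-1]) + margin:
        return "transition_extremum"
    return "environment_dependent"
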
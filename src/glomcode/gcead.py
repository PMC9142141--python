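"""GC-EAD and GC-MS peak analysis: Kovats indices, cross-antenna alignment,
the EAD-active criterion, amplitude matrices and internal-standard amounts.

A gas chromatograph splits a headspace extract into eluting fractions; a
flame-ionization detector (FID) records abundance while an insect antenna
wired as an electro-antennographic detector (EAD) reports, in mV, which
fractions it can smell.  Retention times are normalized against a ladder of
n-alkanes into Kovats retention indices (alkane Cn = 100 n), making peaks
comparable across instruments and runs.  A fraction counts as EAD-active
when it elicited responses at matching retention in at least three antennae
and the fraction is present in at least one other replicate sample of the
same headspace type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AlkaneLadder",
    "kovats_ri",
    "count_peaks_vs_blank",
    "match_across_antennae",
    "call_ead_active",
    "median_amplitude_matrix",
    "estimate_amount",
    "build_feature_table",
]

DEFAULT_RI_TOLERANCE = 5.0
DEFAULT_MIN_ANTENNAE = 3


@dataclass(frozen=True)
class AlkaneLadder:
    """Retention times of an n-alkane series (carbon number -> minutes)."""

    carbons: tuple[int, ...]
    retention_times: tuple[float, ...]

    def __post_init__(self):
        if len(self.carbons) != len(self.retention_times):
            raise ValueError("carbons and retention_times must align")
        if len(self.carbons) < 2:
            raise ValueError("need at least 2 alkanes")
        c = np.asarray(self.carbons)
        rt = np.asarray(self.retention_times, dtype=float)
        if np.any(np.diff(c) <= 0) or np.any(np.diff(rt) <= 0):
            raise ValueError("ladder must be strictly increasing in n and rt")

    @property
    def span(self) -> tuple[float, float]:
        return self.retention_times[0], self.retention_times[-1]


def kovats_ri(rt, ladder: AlkaneLadder):
    """Temperature-programmed (linear) Kovats retention index.

    RI = 100 (n + (n1 - n) (rt - rt_n) / (rt_n1 - rt_n)) with C_n, C_n1 the
    bracketing ladder alkanes.  Retention times outside the ladder span are
    linearly extrapolated from the nearest segment, with a warning.
    """
    rt_arr = np.atleast_1d(np.asarray(rt, dtype=float))
    rts = np.asarray(ladder.retention_times, dtype=float)
    carbons = np.asarray(ladder.carbons, dtype=float)
    if np.any(rt_arr < rts[0]) or np.any(rt_arr > rts[-1]):
        warnings.warn(
            "retention time outside alkane ladder span; extrapolating",
            stacklevel=2,
        )
    seg = np.clip(np.searchsorted(rts, rt_arr, side="right") - 1, 0, len(rts) - 2)
    n0, n1 = carbons[seg], carbons[seg + 1]
    t0, t1 = rts[seg], rts[seg + 1]
    ri = 100.0 * (n0 + (n1 - n0) * (rt_arr - t0) / (t1 - t0))
    return float(ri[0]) if np.isscalar(rt) or np.ndim(rt) == 0 else ri


def count_peaks_vs_blank(
    sample_counts: pd.DataFrame, blank_counts: Sequence[float]
) -> pd.DataFrame:
    """Classify each sample's mean GC-peak count against the blank range.

    ``sample_counts`` needs columns ``sample`` and ``n_peaks`` (one row per
    individual collection).  The blank range is the closed interval
    [min, max] of the blank counts; a sample mean inside it (endpoints
    included) is "within", else "outside".
    """
    blanks = np.asarray(list(blank_counts), dtype=float)
    if blanks.size == 0:
        raise ValueError("need at least one blank collection")
    lo, hi = blanks.min(), blanks.max()
    agg = (
        sample_counts.groupby("sample")["n_peaks"]
        .agg(["mean", "min", "max", "count"])
        .reset_index()
        .rename(
            columns={"mean": "mean_count", "min": "min_count", "max": "max_count",
                     "count": "n_collections"}
        )
    )
    agg["blank_min"] = lo
    agg["blank_max"] = hi
    agg["classification"] = np.where(
        (agg["mean_count"] >= lo) & (agg["mean_count"] <= hi), "within", "outside"
    )
    return agg


def _single_linkage_1d(values: np.ndarray, tolerance: float) -> np.ndarray:
    """Single-linkage clusters on a 1-D array: break where the sorted gap > tol.

    Equivalent to connected components of the graph joining every pair within
    ``tolerance``.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    order = np.argsort(values, kind="stable")
    labels = np.empty(len(values), dtype=int)
    current = 0
    prev = None
    for idx in order:
        if prev is not None and values[idx] - prev > tolerance:
            current += 1
        labels[idx] = current
        prev = values[idx]
    return labels


def match_across_antennae(
    peaks: pd.DataFrame, tolerance: float = DEFAULT_RI_TOLERANCE
) -> pd.DataFrame:
    """Group EAD-responsive peaks from different antennae into putative compounds.

    ``peaks`` needs columns ``antenna_id``, ``headspace``, ``ri`` and
    ``amplitude``.  Within each headspace, peaks are clustered on retention
    index by single linkage with the given gap tolerance (RI units); one
    cluster is one putative compound.  Returns the input with ``group_id``
    plus per-group ``consensus_ri`` (mean RI) and ``support`` (number of
    distinct responding antennae).
    """
    required = {"antenna_id", "headspace", "ri", "amplitude"}
    if not required <= set(peaks.columns):
        raise ValueError(f"peaks table needs columns {sorted(required)}")
    out = []
    offset = 0
    for hs, sub in peaks.groupby("headspace", sort=True):
        sub = sub.copy()
        labels = _single_linkage_1d(sub["ri"].to_numpy(), tolerance)
        sub["group_id"] = labels + offset
        offset += labels.max() + 1 if len(labels) else 0
        out.append(sub)
    if not out:
        return peaks.assign(group_id=[], consensus_ri=[], support=[])
    merged = pd.concat(out, ignore_index=True)
    stats = merged.groupby("group_id").agg(
        consensus_ri=("ri", "mean"),
        support=("antenna_id", "nunique"),
    )
    return merged.merge(stats, on="group_id")


def call_ead_active(
    groups: pd.DataFrame,
    fid_peaks: pd.DataFrame | None,
    min_antennae: int = DEFAULT_MIN_ANTENNAE,
    ri_tolerance: float = DEFAULT_RI_TOLERANCE,
) -> pd.DataFrame:
    """Apply the EAD-active criterion to aligned peak groups.

    A group is active iff (a) it is supported by at least ``min_antennae``
    distinct antennae and (b) a peak at matching retention index (within
    ``ri_tolerance``, area > 0) is present in at least one other replicate
    sample of the same headspace type.  ``fid_peaks`` needs columns
    ``headspace``, ``replicate``, ``ri`` and ``area``; if it is None or has
    no rows for a group's headspace, that group is ``indeterminate`` and
    never active.

    Returns one row per group: headspace, group_id, consensus_ri, support,
    replicate_presence, status in {active, inactive, indeterminate}.
    """
    summary = (
        groups.groupby(["headspace", "group_id"])
        .agg(consensus_ri=("consensus_ri", "first"), support=("support", "first"))
        .reset_index()
    )
    rows = []
    for row in summary.itertuples(index=False):
        status, presence = "inactive", None
        if fid_peaks is None or fid_peaks[fid_peaks["headspace"] == row.headspace].empty:
            status = "indeterminate"
        else:
            sub = fid_peaks[
                (fid_peaks["headspace"] == row.headspace)
                & (fid_peaks["area"] > 0)
                & ((fid_peaks["ri"] - row.consensus_ri).abs() <= ri_tolerance)
            ]
            # "one other headspace of the same type": at least 2 distinct
            # replicate samples must carry the fraction (the stimulated one
            # plus one more).
            presence = sub["replicate"].nunique() >= 2
            if row.support >= min_antennae and presence:
                status = "active"
        rows.append(
            {
                "headspace": row.headspace,
                "group_id": row.group_id,
                "consensus_ri": row.consensus_ri,
                "support": row.support,
                "replicate_presence": presence,
                "status": status,
            }
        )
    return pd.DataFrame(rows)


def median_amplitude_matrix(
    groups: pd.DataFrame, active: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Compound x headspace matrix of median EAD amplitudes (mV).

    Medians run over the responding antennae of each aligned group.  When an
    ``active`` table from :func:`call_ead_active` is given, only active
    groups are kept.  Rows are indexed by rounded consensus RI; absence is
    NaN.  Rows are sorted by their maximum amplitude, strongest first.
    """
    data = groups
    if active is not None:
        keep = active.loc[active["status"] == "active", "group_id"]
        data = groups[groups["group_id"].isin(keep)]
    if data.empty:
        return pd.DataFrame()
    med = (
        data.groupby(["group_id", "headspace"])
        .agg(amplitude=("amplitude", "median"), consensus_ri=("consensus_ri", "first"))
        .reset_index()
    )
    med["compound"] = med["consensus_ri"].round().astype(int).astype(str)
    mat = med.pivot_table(
        index="compound", columns="headspace", values="amplitude", aggfunc="median"
    )
    return mat.loc[mat.max(axis=1).sort_values(ascending=False).index]


def estimate_amount(area: float, istd_area: float, istd_ng: float = 5.0) -> float:
    """Single-point quantitation against the internal standard.

    ng = istd_ng * area / istd_area (5 ng 1-bromodecane by default); no
    compound-specific response factors.
    """
    if istd_area <= 0:
        raise ValueError("internal-standard area must be positive")
    if area < 0:
        raise ValueError("peak area must be nonnegative")
    return istd_ng * area / istd_area


def build_feature_table(
    peaks: pd.DataFrame, ri_tolerance: float = DEFAULT_RI_TOLERANCE
) -> pd.DataFrame:
    """Sample x feature abundance table by retention-index binning.

    ``peaks`` needs columns ``sample_id``, ``ri`` and ``area``.  All peaks of
    all samples are pooled and clustered on RI (single linkage, gap
    tolerance); each cluster is a feature column named by its rounded mean
    RI; cell values are per-sample summed areas, zero when absent.  A
    simplified stand-in for nontargeted GC-MS feature detection.
    """
    required = {"sample_id", "ri", "area"}
    if not required <= set(peaks.columns):
        raise ValueError(f"peaks table needs columns {sorted(required)}")
    if peaks.empty:
        return pd.DataFrame()
    work = peaks.copy()
    work["feature"] = _single_linkage_1d(work["ri"].to_numpy(), ri_tolerance)
    centers = work.groupby("feature")["ri"].mean()
    name_map = {f: f"RI{int(round(v))}" for f, v in centers.items()}
    work["feature"] = work["feature"].map(name_map)
    table = work.pivot_table(
        index="sample_id", columns="feature", values="area", aggfunc="sum", fill_value=0.0
    )
    ordered = [name_map[f] for f in sorted(name_map, key=lambda f: centers[f])]
    # deduplicate while keeping RI order (distinct clusters can round alike)
    seen: list[str] = []
    for name in ordered:
        if name not in seen:
            seen.append(name)
    return table[seen].sort_index()
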
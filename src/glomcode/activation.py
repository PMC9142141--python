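"""Activation calling and response normalization for glomerular response tables.

The response of every identified glomerulus to each plant headspace is
compared against the averaged response to two solvent (dichloromethane, DCM)
control stimulations.  Within one mating-status group and glomerulus, animals
are blocks and the stimuli (headspaces plus the DCM average) are treatments
of a Friedman design; Dunn's multiple-comparisons test against the DCM
control, Bonferroni-adjusted over the headspace comparisons, assigns each
headspace to one of three tiers: inactive, active at p < 0.01, active at
p < 0.001.

Responses are additionally min-max normalized to 0..100 per animal and
glomerulus (over headspaces and the DCM average) so activity maps can be
compared across individuals.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FriedmanResult",
    "friedman_test",
    "dunn_vs_control",
    "call_activated",
    "normalize_responses",
    "tally_max_headspace",
    "count_activated",
    "median_activated_map",
    "TIER_INACTIVE",
    "TIER_P01",
    "TIER_P001",
]

TIER_INACTIVE = "inactive"
TIER_P01 = "active_p01"
TIER_P001 = "active_p001"

DCM_AVG_LABEL = "DCM_avg"


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float
    pvalue: float
    method: str  # "asymptotic" or "exact"


def _friedman_statistic(matrix: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square for a blocks x treatments matrix."""
    n, k = matrix.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, matrix)
    col_sums = ranks.sum(axis=0)
    ssbn = (col_sums**2).sum()
    # tie correction: per block, sum of (t^3 - t) over tie groups
    ties = 0.0
    for row in matrix:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts**3 - counts).sum())
    c = 1.0 - ties / (n * k * (k * k - 1))
    if c <= 0:
        return 0.0  # every block fully tied
    return (12.0 / (n * k * (k + 1)) * ssbn - 3.0 * n * (k + 1)) / c


def friedman_test(
    matrix: np.ndarray, method: str = "asymptotic", max_exact: int = 50000
) -> FriedmanResult:
    """Friedman test on a blocks x treatments matrix (no missing cells).

    ``method`` "asymptotic" uses the tie-corrected chi-square approximation
    (k - 1 degrees of freedom); "exact" enumerates all within-block orderings
    — the permutation null of (k!)^n equally likely rank assignments — and is
    only feasible for tiny designs (refused above ``max_exact`` orderings).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("need a 2-D blocks x treatments matrix")
    n, k = matrix.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 blocks and >= 2 treatments")
    if np.any(~np.isfinite(matrix)):
        raise ValueError("missing cells are not supported")
    observed = _friedman_statistic(matrix)
    if observed == 0.0 and all(len(set(row)) == 1 for row in matrix):
        return FriedmanResult(0.0, 1.0, method)
    if method == "asymptotic":
        p = float(stats.chi2.sf(observed, k - 1))
        return FriedmanResult(float(observed), p, "asymptotic")
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    total = math.factorial(k) ** n
    if total > max_exact:
        raise ValueError(f"exact enumeration infeasible: {total} orderings")
    count = 0
    perms = list(itertools.permutations(range(k)))
    for assignment in itertools.product(perms, repeat=n):
        permuted = np.stack([matrix[i, list(p)] for i, p in enumerate(assignment)])
        if _friedman_statistic(permuted) >= observed - 1e-12:
            count += 1
    return FriedmanResult(float(observed), count / total, "exact")


def dunn_vs_control(
    matrix: np.ndarray,
    control: int,
    treatment_labels: Sequence | None = None,
) -> pd.DataFrame:
    """Dunn's post-hoc test of every treatment against one control column.

    Within-block mean ranks (average ties over the k treatments); for each
    non-control treatment j, z = (Rbar_j - Rbar_c) / sqrt(k (k+1) / (6 n)),
    two-sided normal p, Bonferroni-adjusted over the m = k - 1 comparisons.
    """
    matrix = np.asarray(matrix, dtype=float)
    n, k = matrix.shape
    if k < 2:
        raise ValueError("need >= 2 treatments")
    if not 0 <= control < k:
        raise ValueError("control index out of range")
    ranks = np.apply_along_axis(stats.rankdata, 1, matrix)
    mean_ranks = ranks.mean(axis=0)
    se = math.sqrt(k * (k + 1) / (6.0 * n))
    m = k - 1
    labels = list(treatment_labels) if treatment_labels is not None else list(range(k))
    rows = []
    for j in range(k):
        if j == control:
            continue
        z = (mean_ranks[j] - mean_ranks[control]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {
                "treatment": labels[j],
                "z": z,
                "p_raw": p,
                "p_adj": min(1.0, p * m),
                "mean_rank": mean_ranks[j],
                "control_mean_rank": mean_ranks[control],
            }
        )
    return pd.DataFrame(rows)


REQUIRED_COLUMNS = ("animal", "group", "glomerulus", "stimulus", "response")


def _check_table(responses: pd.DataFrame) -> None:
    missing = set(REQUIRED_COLUMNS) - set(responses.columns)
    if missing:
        raise ValueError(f"response table missing columns {sorted(missing)}")


def _control_average(
    sub: pd.DataFrame, control_stimuli: Sequence[str]
) -> pd.DataFrame:
    """Replace the control trials by their per-animal x glomerulus average."""
    is_ctrl = sub["stimulus"].isin(control_stimuli)
    n_ctrl = sub[is_ctrl].groupby(["animal", "glomerulus"])["stimulus"].nunique()
    if (n_ctrl != len(control_stimuli)).any():
        raise ValueError("every animal x glomerulus needs all control trials")
    ctrl = (
        sub[is_ctrl]
        .groupby(["animal", "group", "glomerulus"], as_index=False)["response"]
        .mean()
        .assign(stimulus=DCM_AVG_LABEL)
    )
    return pd.concat([sub[~is_ctrl], ctrl], ignore_index=True)


def call_activated(
    responses: pd.DataFrame,
    control_stimuli: Sequence[str] = ("DCM1", "DCM2"),
    p01: float = 0.01,
    p001: float = 0.001,
) -> pd.DataFrame:
    """Score headspace-activated glomeruli per mating-status group.

    For each (group, glomerulus): blocks are the group's animals, treatments
    are the headspaces plus the averaged control (19 at paper defaults); the
    Friedman omnibus statistic is recorded and Dunn's vs-control adjusted p
    assigns tiers (p < 0.01 and p < 0.001).  Requires >= 3 animals per group
    and both control trials in every animal x glomerulus.

    Returns tidy columns: group, glomerulus, stimulus, z, p_raw, p_adj, tier,
    friedman_stat, friedman_p.
    """
    _check_table(responses)
    data = _control_average(responses, control_stimuli)
    out = []
    for (group, glom), sub in data.groupby(["group", "glomerulus"], sort=False):
        pivot = sub.pivot(index="animal", columns="stimulus", values="response")
        if pivot.isna().any().any():
            raise ValueError(f"incomplete crossing for group={group}, glom={glom}")
        if len(pivot) < 3:
            raise ValueError(f"group {group} has fewer than 3 animals")
        cols = [c for c in pivot.columns if c != DCM_AVG_LABEL] + [DCM_AVG_LABEL]
        pivot = pivot[cols]
        fried = friedman_test(pivot.to_numpy())
        dunn = dunn_vs_control(
            pivot.to_numpy(), control=len(cols) - 1, treatment_labels=cols
        )
        for row in dunn.itertuples(index=False):
            tier = TIER_INACTIVE
            if row.p_adj < p001:
                tier = TIER_P001
            elif row.p_adj < p01:
                tier = TIER_P01
            out.append(
                {
                    "group": group,
                    "glomerulus": glom,
                    "stimulus": row.treatment,
                    "z": row.z,
                    "p_raw": row.p_raw,
                    "p_adj": row.p_adj,
                    "tier": tier,
                    "friedman_stat": fried.statistic,
                    "friedman_p": fried.pvalue,
                }
            )
    return pd.DataFrame(out)


def normalize_responses(
    responses: pd.DataFrame,
    control_stimuli: Sequence[str] = ("DCM1", "DCM2"),
) -> pd.DataFrame:
    """Min-max rescale responses to 0..100 per animal x glomerulus.

    The span covers the headspaces plus the averaged control.  A degenerate
    cell (all stimuli equal) maps to all zeros with ``degenerate=True``.
    Output keeps the control average as stimulus ``DCM_avg``.
    """
    _check_table(responses)
    data = _control_average(responses, control_stimuli)
    grp = data.groupby(["animal", "glomerulus"])["response"]
    lo = grp.transform("min")
    hi = grp.transform("max")
    span = hi - lo
    out = data.copy()
    out["degenerate"] = span <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = 100.0 * (data["response"] - lo) / span
    out["normalized"] = np.where(out["degenerate"], 0.0, scaled)
    return out


def tally_max_headspace(
    responses: pd.DataFrame,
    control_stimuli: Sequence[str] = ("DCM1", "DCM2"),
    stimulus_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Fraction of animal x glomerulus cells in which each headspace is maximal.

    The argmax runs over headspaces only (controls excluded); ties resolve to
    the first headspace in canonical order and are counted in ``n_ties``.
    Fractions are percentages of all cells and sum to 100.
    """
    _check_table(responses)
    data = responses[~responses["stimulus"].isin(control_stimuli)]
    headspaces = (
        list(stimulus_order)
        if stimulus_order is not None
        else sorted(data["stimulus"].unique())
    )
    counts = {h: 0 for h in headspaces}
    ties = {h: 0 for h in headspaces}
    n_cells = 0
    for _, sub in data.groupby(["animal", "glomerulus"], sort=False):
        vals = sub.set_index("stimulus")["response"].reindex(headspaces)
        if vals.isna().any():
            raise ValueError("incomplete stimulus set in a cell")
        n_cells += 1
        top = vals.max()
        winners = [h for h in headspaces if vals[h] == top]
        counts[winners[0]] += 1
        if len(winners) > 1:
            ties[winners[0]] += 1
    return pd.DataFrame(
        {
            "stimulus": headspaces,
            "n_max": [counts[h] for h in headspaces],
            "n_ties": [ties[h] for h in headspaces],
            "fraction_pct": [100.0 * counts[h] / n_cells for h in headspaces],
        }
    )


def count_activated(
    activation: pd.DataFrame,
    categories: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Activated-glomerulus counts per (group, headspace), optionally by category.

    ``categories`` maps headspace -> category label (e.g. nectar / host /
    sympatric host / background); the second return value then summarizes
    counts per (group, category) with mean, min and max, else it is None.
    """
    active = activation[activation["tier"] != TIER_INACTIVE]
    groups = activation[["group"]].drop_duplicates()["group"]
    stimuli = activation["stimulus"].drop_duplicates()
    counts = (
        active.groupby(["group", "stimulus"])["glomerulus"].nunique().rename("n_activated")
    )
    full_index = pd.MultiIndex.from_product(
        [groups, stimuli], names=["group", "stimulus"]
    )
    counts = counts.reindex(full_index, fill_value=0).reset_index()
    if categories is None:
        return counts, None
    counts["category"] = counts["stimulus"].map(categories)
    summary = (
        counts.dropna(subset=["category"])
        .groupby(["group", "category"])["n_activated"]
        .agg(["mean", "min", "max"])
        .reset_index()
    )
    return counts, summary


def median_activated_map(
    normalized: pd.DataFrame, activation: pd.DataFrame
) -> pd.DataFrame:
    """Median normalized response across animals, restricted to activated cells.

    Joins the per-animal normalized table with the activation calls on
    (group, glomerulus, stimulus); inactive cells are absent from the output,
    and the activation tier is carried through.
    """
    med = (
        normalized.groupby(["group", "glomerulus", "stimulus"], as_index=False)[
            "normalized"
        ]
        .median()
        .rename(columns={"normalized": "median_normalized"})
    )
    active = activation[activation["tier"] != TIER_INACTIVE]
    return med.merge(
        active[["group", "glomerulus", "stimulus", "tier"]],
        on=["group", "glomerulus", "stimulus"],
        how="inner",
    )
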
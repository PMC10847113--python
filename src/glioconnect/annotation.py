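"""Malignant cell-state assignment, 2D state projection and cluster typing.

Cell states are the transcriptional programs of malignant glioma cells
(AC, MES1, MES2, OPC, NPC1, NPC2 plus the cycling programs G1_S and G2_M).
Each state is scored per cell with a binned-control module score of its
marker set; a cell is assigned the argmax state.  The 2D projection places
each cell on a butterfly layout: the Y axis opposes the astro/mesenchymal
scores to the oligo/neural ones and the X axis resolves the winning half.

Cluster typing compares each candidate non-malignant type's cluster-median
score against the malignant score (NMS = S_type - S_malignant); a cluster is
called non-malignant when its best NMS clears median + MAD of all NMS values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import MAD_SCALE, NormalizedMatrix
from .scoring import ModuleScoreParams, module_score

CANONICAL_STATES = ("AC", "MES1", "MES2", "OPC", "NPC1", "NPC2", "G1_S", "G2_M")
PROJECTION_STATES = ("AC", "MES1", "MES2", "OPC", "NPC1", "NPC2")


@dataclass
class StateScores:
    """Per-cell state signature scores plus the argmax assignment."""

    scores: pd.DataFrame        # cells x states
    assigned_state: pd.Series   # per cell


def score_states(
    nm: NormalizedMatrix,
    marker_sets: dict[str, set[str]],
    params: ModuleScoreParams | None = None,
) -> StateScores:
    """One module score per state; assignment is the highest-scoring state.

    Ties are broken by the canonical state order (warned), so the result is
    deterministic regardless of the dict ordering of ``marker_sets``.
    """
    params = params or ModuleScoreParams()
    order = [s for s in CANONICAL_STATES if s in marker_sets]
    order += [s for s in marker_sets if s not in order]
    cols = {}
    for i, state in enumerate(order):
        p = ModuleScoreParams(params.n_bins, params.n_ctrl, seed=params.seed + i)
        cols[state] = module_score(nm, marker_sets[state], p).values
    scores = pd.DataFrame(cols, index=nm.cell_ids)[order]
    arr = scores.to_numpy()
    best = arr.argmax(axis=1)  # argmax takes the first max -> canonical tie-break
    n_tied = int((arr == arr.max(axis=1, keepdims=True)).sum(axis=1).max())
    if n_tied > 1:
        warnings.warn("tied state scores broken by canonical order", RuntimeWarning,
                      stacklevel=2)
    assigned = pd.Series([order[b] for b in best], index=scores.index)
    return StateScores(scores, assigned)


def project_states_2d(ss: StateScores | pd.DataFrame) -> pd.DataFrame:
    """Two-dimensional state projection.

    Y = max(S_AC, S_MES1, S_MES2) - max(S_OPC, S_NPC1, S_NPC2);
    if Y > 0, X = S_AC - max(S_MES1, S_MES2),
    otherwise X = S_OPC - max(S_NPC1, S_NPC2).
    Cycling scores do not enter the projection.
    """
    scores = ss.scores if isinstance(ss, StateScores) else ss
    missing = set(PROJECTION_STATES) - set(scores.columns)
    if missing:
        raise ValueError(f"missing state scores: {sorted(missing)}")
    s = {k: scores[k].to_numpy() for k in PROJECTION_STATES}
    y = np.maximum.reduce([s["AC"], s["MES1"], s["MES2"]]) - \
        np.maximum.reduce([s["OPC"], s["NPC1"], s["NPC2"]])
    x_pos = s["AC"] - np.maximum(s["MES1"], s["MES2"])
    x_neg = s["OPC"] - np.maximum(s["NPC1"], s["NPC2"])
    x = np.where(y > 0, x_pos, x_neg)
    return pd.DataFrame({"X": x, "Y": y}, index=scores.index)


# ---------------------------------------------------------------------------
# cluster-level typing
# ---------------------------------------------------------------------------


def cluster_median_scores(
    type_scores: pd.DataFrame, cluster_ids: pd.Series
) -> pd.DataFrame:
    """Median of each per-cell type score within each cluster (types x clusters)."""
    cluster_ids = cluster_ids.loc[type_scores.index]
    return type_scores.groupby(cluster_ids).median().T


def assign_cluster_types(
    S_ij: pd.DataFrame,
    malignant_type: str = "malignant",
    overrides: dict | None = None,
) -> pd.Series:
    """Call each cluster malignant or the best-scoring non-malignant type.

    ``S_ij`` is types x clusters cluster-median scores including the row for
    the malignant program.  NMS_ij = S_ij - S_malignant,j for each
    non-malignant type; the threshold is median(all NMS) + scaled MAD(all
    NMS).  A cluster whose maximal NMS exceeds the threshold is assigned that
    type (ties on multiple clearing types resolve to the larger NMS),
    otherwise it is malignant.  ``overrides`` force-labels chosen clusters
    (the manual-review escape hatch).
    """
    if malignant_type not in S_ij.index:
        raise ValueError(f"{malignant_type!r} row missing from score matrix")
    nonmal = S_ij.drop(index=malignant_type)
    nms = nonmal.sub(S_ij.loc[malignant_type], axis=1)
    flat = nms.to_numpy().ravel()
    med = np.median(flat)
    mad = MAD_SCALE * np.median(np.abs(flat - med))
    if S_ij.shape[1] < 2 or mad == 0:
        warnings.warn("degenerate MAD in cluster typing; threshold = median",
                      RuntimeWarning, stacklevel=2)
    threshold = med + mad

    out = {}
    for cluster in S_ij.columns:
        col = nms[cluster]
        best_type = col.idxmax()
        out[cluster] = best_type if col.max() > threshold else malignant_type
    labels = pd.Series(out)
    if overrides:
        for cluster, label in overrides.items():
            labels.loc[cluster] = label
    return labels
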
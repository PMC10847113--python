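"""Module scores with expression-binned controls, connectivity classification,
random-set controls, overlap testing and quartile stratification.

The module score of a gene set in a cell is the mean normalised expression of
the set minus the mean of a pooled control set: genes are binned into
``n_bins`` equal-frequency bins by average expression across cells and each
signature gene contributes ``n_ctrl`` control genes drawn from its bin.  The
connectivity signature score of a cell is the module score of the upregulated
connectivity genes minus the module score of the downregulated ones; a cell
is predicted highly connected when its up-score strictly exceeds its
down-score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .core_data import NormalizedMatrix, ScoreVector, z_winsorize
from .differential import GeneSignature


@dataclass
class ModuleScoreParams:
    n_bins: int = 24
    n_ctrl: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 1 or self.n_ctrl < 1:
            raise ValueError("n_bins and n_ctrl must be >= 1")


@dataclass
class ConnectivityScores:
    unit_ids: list[str]
    up_score: np.ndarray
    down_score: np.ndarray
    scaling_state: str = "raw"

    @property
    def connectivity_score(self) -> np.ndarray:
        return self.up_score - self.down_score

    def score_vector(self) -> ScoreVector:
        return ScoreVector(list(self.unit_ids), self.connectivity_score, self.scaling_state)


@dataclass
class ConfusionMetrics:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def _ratio(self, num: int, den: int) -> float:
        if den == 0:
            warnings.warn("undefined metric (0/0): reporting NaN", RuntimeWarning,
                          stacklevel=3)
            return float("nan")
        return num / den

    @property
    def accuracy(self) -> float:
        return self._ratio(self.tp + self.tn, self.n)

    @property
    def sensitivity(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self._ratio(self.tn, self.tn + self.fn)

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
        }


# ---------------------------------------------------------------------------
# module score
# ---------------------------------------------------------------------------


def _expression_bins(avg_expr: np.ndarray, gene_ids: list[str], n_bins: int) -> np.ndarray:
    """Equal-frequency bin index per gene; ties broken by gene-id order."""
    order = np.lexsort((np.array(gene_ids), avg_expr))
    ranks = np.empty_like(order)
    ranks[order] = np.arange(len(order))
    return (ranks * n_bins) // len(order)


def module_score(
    nm: NormalizedMatrix,
    genes: set[str] | list[str],
    params: ModuleScoreParams | None = None,
) -> ScoreVector:
    """Binned-control module score of a gene set, per cell.

    The control pool matches the expression distribution of the signature:
    for each signature gene, ``n_ctrl`` control genes are drawn (seeded,
    without replacement) from that gene's average-expression bin; a bin
    smaller than ``n_ctrl`` contributes all its members.  score(cell) =
    mean over signature genes minus mean over the pooled control draw.
    """
    params = params or ModuleScoreParams()
    genes = set(genes)
    if not genes:
        raise ValueError("empty gene set")
    gidx = nm.gene_index()
    missing = genes - set(gidx)
    if missing:
        warnings.warn(f"{len(missing)} signature genes absent from matrix; dropped",
                      RuntimeWarning, stacklevel=2)
        genes = genes - missing
    if not genes:
        raise ValueError("no signature genes present in the matrix")

    avg = nm.values.mean(axis=1)
    bins = _expression_bins(avg, nm.gene_ids, params.n_bins)
    bin_members: dict[int, np.ndarray] = {
        b: np.flatnonzero(bins == b) for b in range(params.n_bins)
    }
    rng = np.random.default_rng(params.seed)
    set_idx = np.array(sorted(gidx[g] for g in genes))
    ctrl_parts = []
    for gi in set_idx:
        pool = bin_members[bins[gi]]
        if pool.size <= params.n_ctrl:
            ctrl_parts.append(pool)
        else:
            ctrl_parts.append(rng.choice(pool, size=params.n_ctrl, replace=False))
    ctrl_idx = np.concatenate(ctrl_parts)
    score = nm.values[set_idx].mean(axis=0) - nm.values[ctrl_idx].mean(axis=0)
    return ScoreVector(list(nm.cell_ids), score, "raw")


def connectivity_score(
    nm: NormalizedMatrix,
    sig: GeneSignature,
    params: ModuleScoreParams | None = None,
    zwinsorize: bool = False,
) -> ConnectivityScores:
    """Up-set module score minus down-set module score, per cell."""
    params = params or ModuleScoreParams()
    if not sig.up or not sig.down:
        raise ValueError("signature requires both up and down gene sets")
    up = module_score(nm, sig.up, params)
    down = module_score(nm, sig.down, params)
    cs = ConnectivityScores(list(nm.cell_ids), up.values, down.values)
    if zwinsorize:
        z = z_winsorize(cs.score_vector())
        # scaled difference is reported; component scores stay raw
        return ConnectivityScores(cs.unit_ids, z.values, np.zeros_like(z.values),
                                  "z_winsorized")
    return cs


def predict_connectivity(cs: ConnectivityScores) -> pd.Series:
    """Label a unit "high" iff up-score strictly exceeds down-score."""
    labels = np.where(cs.up_score > cs.down_score, "high", "low")
    return pd.Series(labels, index=cs.unit_ids)


def confusion_metrics(
    pred: pd.Series, truth: pd.Series, positive: str = "high"
) -> ConfusionMetrics:
    pred, truth = pred.align(truth, join="inner")
    p = pred == positive
    t = truth == positive
    return ConfusionMetrics(
        tp=int((p & t).sum()),
        fn=int((~p & t).sum()),
        fp=int((p & ~t).sum()),
        tn=int((~p & ~t).sum()),
    )


def random_control_metrics(
    nm: NormalizedMatrix,
    truth: pd.Series,
    sizes: tuple[int, int] = (40, 31),
    n_sets: int = 100,
    seed: int = 0,
    params: ModuleScoreParams | None = None,
) -> dict[str, float]:
    """Chance-level control: average prediction metrics over ``n_sets``
    random signatures of the stated up/down sizes."""
    n_up, n_down = sizes
    if n_up + n_down > nm.n_genes:
        raise ValueError("random signature larger than gene universe")
    rng = np.random.default_rng(seed)
    base = params or ModuleScoreParams()
    acc: dict[str, list[float]] = {k: [] for k in
                                   ("accuracy", "sensitivity", "specificity", "ppv", "npv")}
    for i in range(n_sets):
        pick = rng.choice(nm.n_genes, size=n_up + n_down, replace=False)
        sig = GeneSignature(
            f"random_{i}",
            {nm.gene_ids[j] for j in pick[:n_up]},
            {nm.gene_ids[j] for j in pick[n_up:]},
        )
        p = ModuleScoreParams(base.n_bins, base.n_ctrl, seed=int(rng.integers(2**31)))
        cs = connectivity_score(nm, sig, p)
        m = confusion_metrics(predict_connectivity(cs), truth)
        for k, v in m.as_dict().items():
            acc[k].append(v)
    return {k: float(np.nanmean(v)) for k, v in acc.items()}


# ---------------------------------------------------------------------------
# overlap test and quartile groups
# ---------------------------------------------------------------------------


def hypergeom_overlap(k: int, m: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k) of observing at least
    ``k`` shared genes between sets of sizes ``m`` and ``n`` drawn from a
    universe of ``N`` genes."""
    if not (0 <= k <= min(m, n) <= N):
        raise ValueError("require 0 <= k <= min(m, n) <= N")
    return float(scipy.stats.hypergeom.sf(k - 1, N, m, n))


def quartile_groups(v: ScoreVector, four_level: bool = False) -> pd.Series:
    """Stratify scores at the 25th/75th percentiles (linear interpolation).

    Default labels: Q1 (lowest quartile), Q2-Q3, Q4 (highest).  The
    ``four_level`` variant splits at all three quartiles into Q1..Q4.
    """
    x = v.values
    if np.all(x == x[0]):
        warnings.warn("all values tied: single quartile group", RuntimeWarning,
                      stacklevel=2)
        return pd.Series(["Q1-Q4"] * x.size, index=v.unit_ids)
    if four_level:
        q = np.quantile(x, [0.25, 0.5, 0.75])
        labels = np.select(
            [x <= q[0], x <= q[1], x <= q[2]], ["Q1", "Q2", "Q3"], default="Q4"
        )
    else:
        q1, q3 = np.quantile(x, [0.25, 0.75])
        labels = np.select([x <= q1, x > q3], ["Q1", "Q4"], default="Q2-Q3")
    return pd.Series(labels, index=v.unit_ids)
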
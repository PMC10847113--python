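"""Differential expression tests and the signature-construction cascades.

Three routes produce a :class:`GeneSignature`:

* single-cell: per-line Wilcoxon rank-sum marker tests followed by a
  three-line aggregation rule (same direction in all three lines, or same
  direction with |log fold change| >= 0.4 in two);
* bulk: a per-gene negative-binomial Wald test with a group term and a
  cell-line covariate, thresholded at adjusted p < 0.05 and |log2 FC| >= 1;
* labeling-intensity cascade: three pairwise comparisons (High-vs-Medium,
  Medium-vs-Low, High-vs-Low) merged through five ordered filters, with an
  optional diffusion correction that removes genes shared with a
  constitutively labeling control signature.

Fold-change conventions: single-cell log fold changes are natural-log
differences of expm1-averaged normalised expression (+1 pseudocount), the
convention of the marker-test tooling this mirrors; bulk fold changes are
log2.  DEG tables are plain DataFrames with documented columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .core_data import NormalizedMatrix

DEG_COLUMNS = ["gene_id", "logfc", "p", "p_adj", "pct_a", "pct_b"]


@dataclass
class GeneSignature:
    """Named up/down gene sets with provenance."""

    name: str
    up: set[str]
    down: set[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down sets must be disjoint")

    @property
    def genes(self) -> set[str]:
        return self.up | self.down

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


# ---------------------------------------------------------------------------
# single-cell route
# ---------------------------------------------------------------------------


def rank_sum_markers(
    nm: NormalizedMatrix,
    group_a: np.ndarray,
    group_b: np.ndarray,
    min_pct: float = 0.1,
    logfc_min: float = 0.25,
    log_base: str = "natural",
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum marker test of group a vs group b.

    Genes are pre-filtered: detected in at least ``min_pct`` of cells in one
    of the groups and |logfc| >= ``logfc_min``.  The log fold change is
    ln(mean(expm1(a)) + 1) - ln(mean(expm1(b)) + 1) (or the log2 analogue).
    P-values are Bonferroni-adjusted over all genes in the matrix (the
    convention of the marker-test tooling this mirrors), not just the
    pre-filter survivors.
    """
    group_a = np.asarray(group_a)
    group_b = np.asarray(group_b)
    if group_a.dtype == bool:
        group_a = np.flatnonzero(group_a)
    if group_b.dtype == bool:
        group_b = np.flatnonzero(group_b)
    if group_a.size == 0 or group_b.size == 0:
        raise ValueError("both groups must be non-empty")
    if set(group_a.tolist()) & set(group_b.tolist()):
        raise ValueError("groups overlap")

    A = nm.values[:, group_a]
    B = nm.values[:, group_b]
    pct_a = (A > 0).mean(axis=1)
    pct_b = (B > 0).mean(axis=1)
    mean_a = np.expm1(A).mean(axis=1)
    mean_b = np.expm1(B).mean(axis=1)
    if log_base == "natural":
        logfc = np.log(mean_a + 1.0) - np.log(mean_b + 1.0)
    elif log_base == "log2":
        logfc = np.log2(mean_a + 1.0) - np.log2(mean_b + 1.0)
    else:
        raise ValueError("log_base must be 'natural' or 'log2'")

    testable = (np.maximum(pct_a, pct_b) >= min_pct) & (np.abs(logfc) >= logfc_min)
    rows = []
    for g in np.flatnonzero(testable):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant-input warnings on degenerate genes
            try:
                _, p = scipy.stats.mannwhitneyu(A[g], B[g], alternative="two-sided")
            except ValueError:  # all values identical
                p = 1.0
        rows.append((nm.gene_ids[g], logfc[g], p, pct_a[g], pct_b[g]))
    out = pd.DataFrame(rows, columns=["gene_id", "logfc", "p", "pct_a", "pct_b"])
    out["p_adj"] = np.minimum(out["p"] * nm.n_genes, 1.0) if len(out) else []
    return out[DEG_COLUMNS]


def aggregate_sc_signature(
    tables: list[pd.DataFrame],
    padj_max: float = 0.05,
    lfc_two_line: float = 0.4,
    name: str = "sc_connectivity",
) -> GeneSignature:
    """Aggregate per-line marker tables into a connectivity signature.

    A gene is kept if it is significant (p_adj < ``padj_max``) with the same
    direction in all three lines, or significant with the same direction and
    |logfc| >= ``lfc_two_line`` in at least two lines (the fold-change bar
    applies to both qualifying lines).  Genes whose significant directions
    conflict are dropped.
    """
    if len(tables) != 3:
        raise ValueError("exactly 3 per-line tables required")
    sig = [t[t["p_adj"] < padj_max] for t in tables]
    per_gene: dict[str, list[float]] = {}
    for t in sig:
        for _, row in t.iterrows():
            per_gene.setdefault(row["gene_id"], []).append(float(row["logfc"]))

    up, down = set(), set()
    for gene, lfcs in per_gene.items():
        signs = {np.sign(l) for l in lfcs}
        if len(signs) != 1 or 0.0 in signs:
            continue  # direction conflict (or zero fold change) -> dropped
        n_lines = len(lfcs)
        big = [l for l in lfcs if abs(l) >= lfc_two_line]
        if n_lines == 3 or len(big) >= 2:
            (up if lfcs[0] > 0 else down).add(gene)
    return GeneSignature(name, up, down, {"rule": "all3_or_2line_lfc", "padj_max": padj_max,
                                          "lfc_two_line": lfc_two_line})


# ---------------------------------------------------------------------------
# bulk route
# ---------------------------------------------------------------------------


def _moment_dispersions(counts: np.ndarray, X: np.ndarray, offset: np.ndarray) -> np.ndarray:
    """Design-aware method-of-moments NB dispersions, shrunk toward a
    mean-dispersion trend.

    Per gene, a Poisson GLM with the full design gives fitted means mu_i; the
    moment estimator phi = sum_i[((y_i - mu_i)^2 - mu_i) / mu_i^2] / (n - p)
    is then shrunk halfway (in log space) toward an exponential trend fitted
    across genes.  counts: samples x genes.
    """
    n, p = X.shape
    n_genes = counts.shape[1]
    raw = np.full(n_genes, 1e-8)
    mu_bar = np.full(n_genes, np.nan)
    for j in range(n_genes):
        y = counts[:, j]
        if np.all(y == y[0]):
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
            mu = fit.fittedvalues
        except Exception:
            mu = np.full(n, max(y.mean(), 1e-8))
        mu_bar[j] = mu.mean()
        raw[j] = np.sum(((y - mu) ** 2 - mu) / mu**2) / max(n - p, 1)
    raw = np.clip(raw, 1e-8, 10.0)
    ok = np.isfinite(mu_bar) & (mu_bar > 0) & (raw > 1e-8)
    if ok.sum() >= 10:
        b, a = np.polyfit(np.log(mu_bar[ok]), np.log(raw[ok]), 1)
        trend = np.exp(a + b * np.log(np.maximum(np.nan_to_num(mu_bar, nan=1.0), 1e-8)))
        shrunk = np.exp(0.5 * np.log(raw) + 0.5 * np.log(np.clip(trend, 1e-8, 10.0)))
    else:
        shrunk = raw
    return np.clip(shrunk, 1e-8, 10.0)


def nb_group_test(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    group_col: str = "group",
    line_col: str | None = "line",
    ref_group: str = "low",
) -> pd.DataFrame:
    """Per-gene negative-binomial Wald test of a two-level group factor.

    ``counts`` is samples x genes (low-count genes already filtered);
    ``design`` carries the group factor and an optional line covariate.
    Size factors are median-of-ratios.  Dispersion is a per-gene
    method-of-moments estimate shrunk toward a fitted mean-dispersion trend.
    Returns a DEG table with log2 fold change (group vs ``ref_group``) and
    Benjamini-Hochberg adjusted p-values.
    """
    design = design.loc[counts.index]
    groups = design[group_col].astype(str)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError("group factor must have exactly 2 levels")
    other = [l for l in levels if l != ref_group]
    if not other:
        raise ValueError(f"ref_group {ref_group!r} not among levels {levels}")
    if groups.value_counts().min() < 2:
        raise ValueError("need >= 2 samples per group")

    X_cols = [np.ones(len(design)), (groups != ref_group).astype(float).to_numpy()]
    col_names = ["intercept", "group"]
    if line_col is not None:
        lines = design[line_col].astype(str)
        for lv in sorted(lines.unique())[1:]:
            X_cols.append((lines == lv).astype(float).to_numpy())
            col_names.append(f"line_{lv}")
    X = np.column_stack(X_cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"singular design; confounded terms among {col_names}")

    mat = counts.to_numpy(dtype=float)
    # median-of-ratios size factors (pseudo-reference over positive genes)
    with np.errstate(divide="ignore"):
        log_mat = np.log(mat)
    ok = np.all(mat > 0, axis=0)
    if ok.sum() >= 10:
        log_ref = log_mat[:, ok].mean(axis=0)
        sf = np.exp(np.median(log_mat[:, ok] - log_ref[None, :], axis=1))
    else:
        sf = mat.sum(axis=1) / np.exp(np.mean(np.log(mat.sum(axis=1))))
    offset = np.log(sf)

    phis = _moment_dispersions(mat, X, offset)
    rows = []
    for j, gene in enumerate(counts.columns):
        y = mat[:, j]
        if np.all(y == y[0]):
            rows.append((gene, 0.0, 1.0, np.nan, np.nan))
            continue
        fam = sm.families.NegativeBinomial(alpha=float(phis[j]))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y, X, family=fam, offset=offset).fit()
            beta = res.params[1]
            se = res.bse[1]
            z = beta / se if se > 0 else 0.0
            p = 2.0 * scipy.stats.norm.sf(abs(z))
        except Exception:
            beta, p = 0.0, 1.0
        rows.append((gene, beta / np.log(2.0), p, np.nan, np.nan))
    out = pd.DataFrame(rows, columns=["gene_id", "logfc", "p", "pct_a", "pct_b"])
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
    return out[DEG_COLUMNS]


def aggregate_bulk_signature(
    table: pd.DataFrame,
    padj_max: float = 0.05,
    abs_log2fc_min: float = 1.0,
    name: str = "bulk_connectivity",
) -> GeneSignature:
    """Threshold filter: p_adj < padj_max and |log2 FC| >= abs_log2fc_min."""
    keep = table[(table["p_adj"] < padj_max) & (table["logfc"].abs() >= abs_log2fc_min)]
    up = set(keep.loc[keep["logfc"] > 0, "gene_id"])
    down = set(keep.loc[keep["logfc"] < 0, "gene_id"])
    return GeneSignature(name, up, down,
                         {"padj_max": padj_max, "abs_log2fc_min": abs_log2fc_min})


# ---------------------------------------------------------------------------
# labeling-intensity cascade
# ---------------------------------------------------------------------------


def caprola_cascade(
    tables: dict[str, pd.DataFrame],
    padj_max: float = 0.05,
    logcpm_min: float = 2.0,
    top_n: int = 50,
    membership: str = "every",
    name: str = "calcium",
) -> GeneSignature:
    """Merge three pairwise DEG tables through five ordered filters.

    ``tables`` maps comparison labels (e.g. ``high_vs_medium``) to DEG tables
    that additionally carry a ``logcpm`` column.  Filters, in order:

    1. drop entries with adjusted p (FDR) > ``padj_max``;
    2. drop genes detected in only one comparison;
    3. drop genes with inconsistent direction of regulation across comparisons;
    4. drop genes with log CPM < ``logcpm_min``;
    5. drop genes not in the top ``top_n`` or bottom ``top_n`` by fold change
       in every comparison in which they remain (``membership='any'`` relaxes
       this to at least one comparison).
    """
    if len(tables) != 3:
        raise ValueError("exactly 3 pairwise comparison tables required")
    for label, t in tables.items():
        if "logcpm" not in t.columns:
            raise ValueError(f"table {label!r} lacks a logcpm column")

    # filter 1: per-comparison FDR
    sig = {label: t[t["p_adj"] <= padj_max].copy() for label, t in tables.items()}

    gene_hits: dict[str, dict[str, pd.Series]] = {}
    for label, t in sig.items():
        for _, row in t.iterrows():
            gene_hits.setdefault(row["gene_id"], {})[label] = row

    # filter 2: present in >= 2 comparisons
    gene_hits = {g: h for g, h in gene_hits.items() if len(h) >= 2}
    # filter 3: consistent direction
    gene_hits = {
        g: h for g, h in gene_hits.items()
        if len({np.sign(r["logfc"]) for r in h.values()}) == 1
        and 0.0 not in {np.sign(r["logfc"]) for r in h.values()}
    }
    # filter 4: expression
    gene_hits = {
        g: h for g, h in gene_hits.items()
        if all(r["logcpm"] >= logcpm_min for r in h.values())
    }

    # filter 5: top/bottom-N by fold change within each comparison, computed
    # over the genes remaining after filters 1-4
    remaining = set(gene_hits)
    rank_sets: dict[str, set[str]] = {}
    for label, t in sig.items():
        sub = t[t["gene_id"].isin(remaining)].sort_values("logfc")
        ids = sub["gene_id"].tolist()
        chosen = set(ids[:top_n]) | set(ids[-top_n:])
        rank_sets[label] = chosen

    up, down = set(), set()
    for g, h in gene_hits.items():
        in_sets = [g in rank_sets[label] for label in h]
        ok = all(in_sets) if membership == "every" else any(in_sets)
        if not ok:
            continue
        sign = np.sign(next(iter(h.values()))["logfc"])
        (up if sign > 0 else down).add(g)
    return GeneSignature(name, up, down, {"rule": "caprola_cascade", "top_n": top_n,
                                          "membership": membership})


def diffusion_correct(sig_ca: GeneSignature, sig_ctrl: GeneSignature) -> GeneSignature:
    """Remove from a calcium signature every gene present (either direction)
    in the constitutively labeling control signature."""
    ctrl = sig_ctrl.genes
    return GeneSignature(
        f"{sig_ca.name}_diffusion_corrected",
        sig_ca.up - ctrl,
        sig_ca.down - ctrl,
        {"corrected_against": sig_ctrl.name, "removed": sorted(sig_ca.genes & ctrl)},
    )
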
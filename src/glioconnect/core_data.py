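"""Core containers, normalisation/scaling transforms, QC filters and file I/O.

The central container is :class:`CountMatrix`: a genes x cells integer count
matrix with per-cell and per-gene annotations, stored sparse.  Downstream
stages operate on the log-normalised :class:`NormalizedMatrix` (natural log of
1 + CP10K by default) and on per-unit :class:`ScoreVector` objects that can be
z-scaled and winsorized to [-3, 3] for reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

MAD_SCALE = 1.4826  # consistency constant: scaled MAD estimates sigma under normality


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Genes x cells non-negative integer counts with annotations.

    Parameters
    ----------
    gene_ids, cell_ids
        Unique identifiers for the rows / columns of ``counts``.
    counts
        ``(n_genes, n_cells)`` sparse or dense array of non-negative integers.
    cell_meta
        Per-cell annotations indexed by ``cell_ids`` (e.g. ``line_id``,
        ``group_label``, ``cluster_id``, ``true_state``).
    gene_meta
        Per-gene annotations indexed by ``gene_ids`` (e.g. boolean ``mito``).
    """

    gene_ids: list[str]
    cell_ids: list[str]
    counts: sp.spmatrix | np.ndarray
    cell_meta: pd.DataFrame = None
    gene_meta: pd.DataFrame = None

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell_ids must be unique")
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"({len(self.gene_ids)}, {len(self.cell_ids)})"
            )
        data = self.counts.data
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise ValueError("counts must be non-negative integers")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=self.cell_ids)
        else:
            self.cell_meta = self.cell_meta.loc[self.cell_ids]
        if self.gene_meta is None:
            self.gene_meta = pd.DataFrame(index=self.gene_ids)
        else:
            self.gene_meta = self.gene_meta.loc[self.gene_ids]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def genes_detected(self) -> np.ndarray:
        """Number of genes with a non-zero count, per cell."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        idx = np.flatnonzero(mask)
        return CountMatrix(
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in idx],
            counts=self.counts[:, idx],
            cell_meta=self.cell_meta.iloc[idx],
            gene_meta=self.gene_meta,
        )

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        idx = np.flatnonzero(mask)
        return CountMatrix(
            gene_ids=[self.gene_ids[i] for i in idx],
            cell_ids=list(self.cell_ids),
            counts=self.counts[idx, :],
            cell_meta=self.cell_meta,
            gene_meta=self.gene_meta.iloc[idx],
        )


@dataclass
class NormalizedMatrix:
    """Log-normalised expression with the same axes as its source counts."""

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray  # dense genes x cells, ln(1 + scale * count / total)
    cell_meta: pd.DataFrame = None
    scale_factor: float = 1e4
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


@dataclass
class ScoreVector:
    """Per-cell/sample scores, optionally z-scaled and winsorized."""

    unit_ids: list[str]
    values: np.ndarray
    scaling_state: str = "raw"  # "raw" | "z_winsorized"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.unit_ids) != self.values.size:
            raise ValueError("unit_ids and values length mismatch")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.unit_ids)


@dataclass
class QCThresholds:
    """Fixed single-cell exclusion thresholds (gene counts, UMIs, mito fraction)."""

    min_genes: int = 200
    max_genes: int = 8000
    min_counts: int = 500
    max_counts: int = 80000
    max_mito_frac: float = 0.10
    n_mads: float = 3.0

    def __post_init__(self) -> None:
        if not (self.min_genes < self.max_genes and self.min_counts < self.max_counts):
            raise ValueError("min threshold must be below max threshold")
        if not 0.0 <= self.max_mito_frac <= 1.0:
            raise ValueError("max_mito_frac must lie in [0, 1]")


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


def lognormalize(cm: CountMatrix, scale_factor: float = 1e4) -> NormalizedMatrix:
    """Library-size normalise counts to ln(1 + scale_factor * count / total).

    Every cell must have a positive total count; a zero-count cell makes the
    per-cell scaling undefined and raises a ``ValueError`` naming the cell.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    totals = cm.cell_totals()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"cell {cm.cell_ids[zero[0]]!r} has zero total count")
    dense = np.asarray(cm.counts.todense(), dtype=float)
    values = np.log1p(scale_factor * dense / totals[None, :])
    return NormalizedMatrix(
        gene_ids=list(cm.gene_ids),
        cell_ids=list(cm.cell_ids),
        values=values,
        cell_meta=cm.cell_meta.copy(),
        scale_factor=scale_factor,
        source="lognormalize",
    )


def z_winsorize(v: ScoreVector, lower: float = -3.0, upper: float = 3.0) -> ScoreVector:
    """Z-scale (mean 0, sd 1 with n-1 denominator) then clip to [lower, upper].

    A zero-variance input yields all zeros with a warning rather than NaNs.
    """
    if v.scaling_state != "raw":
        raise ValueError("input is already scaled")
    x = v.values
    if x.size < 2:
        raise ValueError("need at least 2 units to z-scale")
    sd = x.std(ddof=1)
    if sd == 0:
        warnings.warn("zero variance: z-scores set to 0", RuntimeWarning, stacklevel=2)
        z = np.zeros_like(x)
    else:
        z = (x - x.mean()) / sd
    return ScoreVector(list(v.unit_ids), np.clip(z, lower, upper), "z_winsorized")


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------


def qc_filter_fixed(
    cm: CountMatrix,
    thr: QCThresholds | None = None,
    mito_prefix: str = "MT-",
) -> tuple[CountMatrix, dict[str, int]]:
    """Remove cells failing any fixed threshold.

    A cell is removed if its number of detected genes falls outside
    ``[min_genes, max_genes]``, its total count falls outside
    ``[min_counts, max_counts]``, or more than ``max_mito_frac`` of its counts
    come from mitochondrial genes.  Mitochondrial genes are taken from a
    boolean ``mito`` column of ``gene_meta`` if present, otherwise from the
    ``mito_prefix`` gene-id prefix; if neither identifies any gene the mito
    rule is skipped with a warning.

    Returns the filtered matrix and a per-rule removal tally.
    """
    thr = thr or QCThresholds()
    genes_det = cm.genes_detected()
    totals = cm.cell_totals()

    fail_genes = (genes_det < thr.min_genes) | (genes_det > thr.max_genes)
    fail_counts = (totals < thr.min_counts) | (totals > thr.max_counts)

    if "mito" in cm.gene_meta.columns:
        mito_mask = cm.gene_meta["mito"].to_numpy(dtype=bool)
    else:
        mito_mask = np.array([g.startswith(mito_prefix) for g in cm.gene_ids])
    if mito_mask.any():
        mito_counts = np.asarray(cm.counts[mito_mask, :].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(totals > 0, mito_counts / totals, 0.0)
        fail_mito = mito_frac > thr.max_mito_frac
    else:
        warnings.warn("no mitochondrial genes annotated; mito rule skipped",
                      RuntimeWarning, stacklevel=2)
        fail_mito = np.zeros(cm.n_cells, dtype=bool)

    removed = {
        "genes_detected": int(fail_genes.sum()),
        "total_counts": int(fail_counts.sum()),
        "mito_fraction": int(fail_mito.sum()),
    }
    keep = ~(fail_genes | fail_counts | fail_mito)
    removed["total_removed"] = int((~keep).sum())
    return cm.subset_cells(keep), removed


def qc_filter_mad(values: np.ndarray, n_mads: float = 3.0) -> np.ndarray:
    """One-sided outlier mask: keep values <= median + n_mads * scaled MAD.

    Only the high tail is removed.  Uses the scaled MAD (1.4826 x median
    absolute deviation).  When the MAD is zero the rule degenerates to
    "remove anything strictly above the median" (with a 1e-12 guard), which
    is documented behaviour rather than an error.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 cells for the MAD rule")
    med = np.median(values)
    mad = MAD_SCALE * np.median(np.abs(values - med))
    cutoff = med + n_mads * mad if mad > 0 else med + 1e-12
    return values <= cutoff


def lowcount_gene_filter(bulk: pd.DataFrame, min_total: int = 10) -> pd.DataFrame:
    """Drop genes whose total count across all samples is below ``min_total``.

    ``bulk`` is samples x genes; a gene with total exactly ``min_total`` is kept.
    """
    if (bulk.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    totals = bulk.sum(axis=0)
    return bulk.loc[:, totals >= min_total]


# ---------------------------------------------------------------------------
# file I/O  (MTX triple + TSV; 1-based indices on disk per MTX convention)
# ---------------------------------------------------------------------------


def write_count_matrix(cm: CountMatrix, prefix: str | Path) -> None:
    """Write matrix.mtx, genes.tsv, barcodes.tsv, cell_meta.tsv under ``prefix``."""
    prefix = Path(prefix)
    prefix.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(prefix / "matrix.mtx"), sp.coo_matrix(cm.counts), field="integer")
    pd.Series(cm.gene_ids).to_csv(prefix / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(cm.cell_ids).to_csv(prefix / "barcodes.tsv", sep="\t", index=False, header=False)
    meta = cm.cell_meta.copy()
    meta.index.name = "cell_id"
    meta.to_csv(prefix / "cell_meta.tsv", sep="\t")
    if len(cm.gene_meta.columns):
        gm = cm.gene_meta.copy()
        gm.index.name = "gene_id"
        gm.to_csv(prefix / "gene_meta.tsv", sep="\t")


def read_count_matrix(prefix: str | Path) -> CountMatrix:
    prefix = Path(prefix)
    counts = scipy.io.mmread(str(prefix / "matrix.mtx"))
    gene_ids = pd.read_csv(prefix / "genes.tsv", sep="\t", header=None)[0].astype(str).tolist()
    cell_ids = pd.read_csv(prefix / "barcodes.tsv", sep="\t", header=None)[0].astype(str).tolist()
    meta_path = prefix / "cell_meta.tsv"
    cell_meta = None
    if meta_path.exists():
        cell_meta = pd.read_csv(meta_path, sep="\t", index_col="cell_id")
        cell_meta.index = cell_meta.index.astype(str)
        cell_meta.index.name = None
    gene_meta = None
    gm_path = prefix / "gene_meta.tsv"
    if gm_path.exists():
        gene_meta = pd.read_csv(gm_path, sep="\t", index_col="gene_id")
        gene_meta.index = gene_meta.index.astype(str)
        gene_meta.index.name = None
    return CountMatrix(gene_ids, cell_ids, counts, cell_meta, gene_meta)


def write_signature_tsv(path: str | Path, up: set[str], down: set[str]) -> None:
    """Two-column signature exchange format: gene_id, direction in {up, down}."""
    rows = [(g, "up") for g in sorted(up)] + [(g, "down") for g in sorted(down)]
    pd.DataFrame(rows, columns=["gene_id", "direction"]).to_csv(path, sep="\t", index=False)


def read_signature_tsv(path: str | Path) -> tuple[set[str], set[str]]:
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "direction"} <= set(df.columns):
        raise ValueError("signature TSV needs gene_id and direction columns")
    up = set(df.loc[df["direction"] == "up", "gene_id"].astype(str))
    down = set(df.loc[df["direction"] == "down", "gene_id"].astype(str))
    return up, down
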
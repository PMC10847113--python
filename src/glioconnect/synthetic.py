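"""Synthetic data with planted ground truth for every downstream stage.

Emulates the study conditions end-to-end without any external download:

* a sorted single-cell experiment — three tumor cell lines, each split into a
  highly connected ("high") and lowly connected ("low") sorted group, with
  connectivity genes planted as multiplicative mean shifts on a
  negative-binomial count background and discrete malignant cell states
  (AC / MES1 / MES2 / OPC / NPC1 / NPC2 / cycling) planted as marker boosts;
* a small bulk two-group experiment with a per-line baseline covariate;
* calcium fluorescence recordings in which transients propagate between
  spatially neighbouring cells with lag = distance / speed;
* per-cell immunohistochemistry staining ratings 0-3.

All generators are seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_data import CountMatrix

STATES = ("AC", "MES1", "MES2", "OPC", "NPC1", "NPC2", "cycling")


# ---------------------------------------------------------------------------
# single-cell experiment
# ---------------------------------------------------------------------------


@dataclass
class ScSimConfig:
    """Configuration of the sorted single-cell simulation.

    ``effect_size`` multiplies the NB mean of planted up-genes in the "high"
    group and of planted down-genes in the "low" group.  ``lines_with_effect``
    restricts the effect to a subset of lines to exercise the two-of-three
    aggregation rule.  Counts are NB with variance m + phi * m^2 (phi =
    ``dispersion``, shared across genes).
    """

    n_lines: int = 3
    cells_per_group: int = 300
    n_genes: int = 800
    n_up_degs: int = 40
    n_down_degs: int = 31
    effect_size: float = 3.0
    baseline_log_mean: float = 0.5    # log-normal location of per-gene mean counts
    baseline_log_sd: float = 1.0
    dispersion: float = 0.3
    state_boost: float = 3.0          # multiplicative marker boost in assigned state
    markers_per_state: int = 10
    mito_fraction: float = 0.02       # share of genes labelled mitochondrial
    lines_with_effect: tuple[int, ...] | None = None  # None = all lines
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_up_degs + self.n_down_degs > self.n_genes:
            raise ValueError("planted DEG sets exceed n_genes")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")


@dataclass
class ScTruth:
    up_genes: set[str]
    down_genes: set[str]
    state_markers: dict[str, set[str]]
    cell_states: pd.Series  # per cell


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB with variance mean + phi * mean^2 (gamma-Poisson mixture)."""
    if phi <= 0:
        return rng.poisson(mean)
    shape = 1.0 / phi
    lam = rng.gamma(shape, mean * phi)
    return rng.poisson(lam)


def simulate_sc_experiment(cfg: ScSimConfig) -> tuple[CountMatrix, ScTruth]:
    """Generate NB counts with planted connectivity DEGs and cell states."""
    rng = np.random.default_rng(cfg.seed)
    n_genes = cfg.n_genes
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    n_mito = int(round(cfg.mito_fraction * n_genes))
    # rename a trailing block to mitochondrial ids so the prefix rule works
    for i in range(n_mito):
        gene_ids[n_genes - 1 - i] = f"MT-{i:03d}"

    base_mean = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, n_genes)

    up_idx = np.arange(cfg.n_up_degs)
    down_idx = np.arange(cfg.n_up_degs, cfg.n_up_degs + cfg.n_down_degs)
    # state markers occupy a block after the planted DEGs (orthogonal by default)
    marker_start = cfg.n_up_degs + cfg.n_down_degs
    state_markers: dict[str, set[str]] = {}
    marker_idx: dict[str, np.ndarray] = {}
    for s, state in enumerate(STATES):
        lo = marker_start + s * cfg.markers_per_state
        hi = min(lo + cfg.markers_per_state, n_genes - n_mito)
        idx = np.arange(lo, hi)
        marker_idx[state] = idx
        state_markers[state] = {gene_ids[i] for i in idx}

    affected = set(cfg.lines_with_effect) if cfg.lines_with_effect is not None \
        else set(range(cfg.n_lines))

    blocks, cells, meta_rows, states_all = [], [], [], []
    for line in range(cfg.n_lines):
        line_id = f"L{line + 1}"
        for group in ("high", "low"):
            n_c = cfg.cells_per_group
            mean = np.tile(base_mean[:, None], (1, n_c))
            if line in affected:
                if group == "high":
                    mean[up_idx, :] *= cfg.effect_size
                else:
                    mean[down_idx, :] *= cfg.effect_size
            # assign states uniformly and boost that state's markers
            cell_states = rng.choice(len(STATES), size=n_c)
            for s, state in enumerate(STATES):
                cols = np.flatnonzero(cell_states == s)
                if cols.size:
                    mean[np.ix_(marker_idx[state], cols)] *= cfg.state_boost
            counts = _nb_draw(rng, mean, cfg.dispersion)
            blocks.append(sp.csr_matrix(counts))
            ids = [f"{line_id}_{group}_{i:04d}" for i in range(n_c)]
            cells.extend(ids)
            group_label = "SR101high" if group == "high" else "SR101low"
            for i, cid in enumerate(ids):
                meta_rows.append((cid, line_id, group_label, STATES[cell_states[i]]))
            states_all.extend(STATES[s] for s in cell_states)

    counts = sp.hstack(blocks, format="csr")
    cell_meta = pd.DataFrame(
        meta_rows, columns=["cell_id", "line_id", "group_label", "true_state"]
    ).set_index("cell_id")
    gene_meta = pd.DataFrame(
        {"mito": [g.startswith("MT-") for g in gene_ids]}, index=gene_ids
    )
    cm = CountMatrix(gene_ids, cells, counts, cell_meta, gene_meta)
    truth = ScTruth(
        up_genes={gene_ids[i] for i in up_idx},
        down_genes={gene_ids[i] for i in down_idx},
        state_markers=state_markers,
        cell_states=cell_meta["true_state"],
    )
    return cm, truth


# ---------------------------------------------------------------------------
# bulk experiment
# ---------------------------------------------------------------------------


@dataclass
class BulkSimConfig:
    n_lines: int = 3
    reps_per_group: int = 3           # replicates per line x group
    n_genes: int = 500
    n_up_degs: int = 20
    n_down_degs: int = 20
    effect_size: float = 4.0          # fold change in "high" vs "low"
    line_offset_sd: float = 0.5       # per-line log-scale baseline offset
    base_mean: float = 100.0
    dispersion: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_up_degs + self.n_down_degs > self.n_genes:
            raise ValueError("planted DEG sets exceed n_genes")


@dataclass
class BulkTruth:
    up_genes: set[str]
    down_genes: set[str]


def simulate_bulk_experiment(cfg: BulkSimConfig) -> tuple[pd.DataFrame, pd.DataFrame, BulkTruth]:
    """Two-group bulk counts with a per-line baseline covariate.

    Returns (samples x genes counts, sample design frame with ``group`` and
    ``line`` columns, truth).
    """
    rng = np.random.default_rng(cfg.seed)
    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    base = rng.lognormal(np.log(cfg.base_mean), 1.0, cfg.n_genes)
    up = np.arange(cfg.n_up_degs)
    down = np.arange(cfg.n_up_degs, cfg.n_up_degs + cfg.n_down_degs)

    line_offsets = rng.normal(0.0, cfg.line_offset_sd, (cfg.n_lines, cfg.n_genes))
    rows, design = [], []
    for line in range(cfg.n_lines):
        for group in ("high", "low"):
            for rep in range(cfg.reps_per_group):
                mean = base * np.exp(line_offsets[line])
                fc = np.ones(cfg.n_genes)
                if group == "high":
                    fc[up] = cfg.effect_size
                else:
                    fc[down] = cfg.effect_size
                counts = _nb_draw(rng, mean * fc, cfg.dispersion)
                sid = f"L{line + 1}_{group}_r{rep + 1}"
                rows.append(pd.Series(counts, index=gene_ids, name=sid))
                design.append((sid, group, f"L{line + 1}"))
    counts_df = pd.DataFrame(rows)
    design_df = pd.DataFrame(design, columns=["sample_id", "group", "line"]).set_index("sample_id")
    truth = BulkTruth({gene_ids[i] for i in up}, {gene_ids[i] for i in down})
    return counts_df, design_df, truth


# ---------------------------------------------------------------------------
# calcium recordings
# ---------------------------------------------------------------------------


@dataclass
class CaSimConfig:
    """Calcium-imaging simulation: transients propagate along graph edges.

    Cells are scattered in a square field; cell pairs closer than
    ``max_edge_dist_um`` become connected with probability ``edge_prob``.
    Each cell fires Poisson events at ``base_rate_hz``; an event propagates
    across each incident edge with probability ``share_prob`` and appears in
    the neighbour delayed by distance / ``speed_um_s``.
    """

    n_cells: int = 20
    field_um: float = 300.0
    frame_interval_s: float = 1.52
    duration_s: float = 1800.0
    max_edge_dist_um: float = 100.0
    edge_prob: float = 1.0
    speed_um_s: float = 10.0
    kernel_amplitude: float = 1.0
    kernel_width_s: float = 5.0
    base_rate_hz: float = 0.01
    share_prob: float = 0.8
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 4.0 <= self.speed_um_s <= 25.0:
            raise ValueError("propagation speed must lie in [4, 25] um/s")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.duration_s < 600.0:
            raise ValueError("recording must be at least one 10-min segment long")


@dataclass
class CalciumRecording:
    """Cells x frames fluorescence traces with 2D positions in micrometres."""

    traces: np.ndarray            # (n_cells, n_frames)
    frame_interval_s: float
    positions: np.ndarray         # (n_cells, 2) in um
    cell_ids: list[str]
    true_edges: list[tuple[int, int]] | None = None
    true_event_times: list[np.ndarray] | None = None

    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    def distance(self, a: int, b: int) -> float:
        return float(np.hypot(*(self.positions[a] - self.positions[b])))


def _transient_kernel(t: np.ndarray, amplitude: float, width_s: float) -> np.ndarray:
    """Asymmetric transient: half-Gaussian rise then exponential decay."""
    rise_sd = width_s / 5.0
    decay_tau = width_s / 2.0
    out = np.zeros_like(t)
    pre = t < 0
    out[pre] = np.exp(-0.5 * (t[pre] / rise_sd) ** 2)
    out[~pre] = np.exp(-t[~pre] / decay_tau)
    return amplitude * out


def simulate_calcium_recording(cfg: CaSimConfig) -> CalciumRecording:
    rng = np.random.default_rng(cfg.seed)
    n_frames = int(round(cfg.duration_s / cfg.frame_interval_s))
    pos = rng.uniform(0.0, cfg.field_um, (cfg.n_cells, 2))

    edges: list[tuple[int, int]] = []
    for a in range(cfg.n_cells):
        for b in range(a + 1, cfg.n_cells):
            d = float(np.hypot(*(pos[a] - pos[b])))
            if d <= cfg.max_edge_dist_um and rng.random() < cfg.edge_prob:
                edges.append((a, b))
    neighbours: dict[int, list[int]] = {i: [] for i in range(cfg.n_cells)}
    for a, b in edges:
        neighbours[a].append(b)
        neighbours[b].append(a)

    # own events, then one-hop propagation with lag = distance / speed
    event_times: list[list[float]] = [[] for _ in range(cfg.n_cells)]
    for c in range(cfg.n_cells):
        n_events = rng.poisson(cfg.base_rate_hz * cfg.duration_s)
        own = np.sort(rng.uniform(0.0, cfg.duration_s, n_events))
        event_times[c].extend(own.tolist())
        for t0 in own:
            for nb in neighbours[c]:
                if rng.random() < cfg.share_prob:
                    d = float(np.hypot(*(pos[c] - pos[nb])))
                    t1 = t0 + d / cfg.speed_um_s
                    if t1 < cfg.duration_s:
                        event_times[nb].append(t1)

    t_frames = np.arange(n_frames) * cfg.frame_interval_s
    traces = rng.normal(0.0, cfg.noise_sd, (cfg.n_cells, n_frames))
    support_s = 6.0 * cfg.kernel_width_s
    for c in range(cfg.n_cells):
        for t0 in event_times[c]:
            lo = max(0, int((t0 - support_s) / cfg.frame_interval_s))
            hi = min(n_frames, int((t0 + support_s) / cfg.frame_interval_s) + 1)
            traces[c, lo:hi] += _transient_kernel(
                t_frames[lo:hi] - t0, cfg.kernel_amplitude, cfg.kernel_width_s
            )

    return CalciumRecording(
        traces=traces,
        frame_interval_s=cfg.frame_interval_s,
        positions=pos,
        cell_ids=[f"C{i:03d}" for i in range(cfg.n_cells)],
        true_edges=edges,
        true_event_times=[np.sort(np.array(ts)) for ts in event_times],
    )


# ---------------------------------------------------------------------------
# histology ratings
# ---------------------------------------------------------------------------


def simulate_histology(
    n_cells: int, rating_probs: tuple[float, float, float, float], seed: int = 0
) -> pd.DataFrame:
    """Multinomial per-cell staining ratings 0-3."""
    p = np.asarray(rating_probs, dtype=float)
    if p.size != 4 or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("rating_probs must be a 4-simplex")
    rng = np.random.default_rng(seed)
    ratings = rng.choice(4, size=n_cells, p=p)
    return pd.DataFrame(
        {"cell_id": [f"H{i:05d}" for i in range(n_cells)], "rating": ratings}
    )
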
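"""Derive the connectivity signature from the simulated sorted experiment.

Reads scratch/data/sc_mtx (written by 01), applies the fixed + MAD QC
filters, log-normalises, runs the per-line rank-sum marker test and the
three-line aggregation rule, and writes the derived signature plus its
overlap with the planted truth to results/.

Run:  python analysis/02_derive_signature.py
"""

import json
from pathlib import Path

from glioconnect.core_data import (
    QCThresholds,
    lognormalize,
    qc_filter_fixed,
    qc_filter_mad,
    read_count_matrix,
    read_signature_tsv,
    write_signature_tsv,
)
from glioconnect.differential import aggregate_sc_signature, rank_sum_markers
from glioconnect.scoring import hypergeom_overlap

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    data_dir = ROOT / "scratch" / "data"
    cm = read_count_matrix(data_dir / "sc_mtx")
    planted_up, planted_down = read_signature_tsv(data_dir / "planted_signature.tsv")

    cm, removed = qc_filter_fixed(cm, QCThresholds())
    keep = qc_filter_mad(cm.cell_totals(), QCThresholds().n_mads)
    cm = cm.subset_cells(keep)
    nm = lognormalize(cm)

    tables = []
    for line in sorted(nm.cell_meta["line_id"].unique()):
        in_line = nm.cell_meta["line_id"] == line
        a = (in_line & (nm.cell_meta["group_label"] == "SR101high")).to_numpy()
        b = (in_line & (nm.cell_meta["group_label"] == "SR101low")).to_numpy()
        t = rank_sum_markers(nm, a, b)
        t.to_csv(ROOT / "results" / f"02_deg_{line}.tsv", sep="\t", index=False)
        tables.append(t)

    sig = aggregate_sc_signature(tables)
    write_signature_tsv(ROOT / "results" / "02_connectivity_signature.tsv",
                        sig.up, sig.down)

    planted = planted_up | planted_down
    overlap = len(sig.genes & planted)
    p_overlap = hypergeom_overlap(overlap, len(sig.genes), len(planted), nm.n_genes)
    summary = {
        "qc_removed": removed,
        "n_cells_after_qc": nm.n_cells,
        "signature_up": len(sig.up),
        "signature_down": len(sig.down),
        "overlap_with_planted": overlap,
        "jaccard_vs_planted": overlap / len(sig.genes | planted),
        "overlap_hypergeom_p": p_overlap,
    }
    (ROOT / "results" / "02_signature_summary.json").write_text(
        json.dumps(summary, indent=2))
    print(f"derived {len(sig.up)} up / {len(sig.down)} down connectivity genes; "
          f"{overlap}/{len(planted)} planted recovered "
          f"(hypergeometric p = {p_overlap:.3g})")


if __name__ == "__main__":
    main()
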
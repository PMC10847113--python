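"""Score cells with the derived signature and classify against sorted labels.

Reads the matrix from 01 and the signature from 02, computes the
connectivity signature score per cell (binned-control module scores,
up minus down), predicts high/low connectivity, evaluates against the sorted
group labels, and contrasts with the random-gene-set chance control and the
quartile stratification.

Run:  python analysis/03_score_and_classify.py [--seed 1]
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from glioconnect.core_data import lognormalize, read_count_matrix, read_signature_tsv
from glioconnect.differential import GeneSignature
from glioconnect.scoring import (
    ModuleScoreParams,
    confusion_metrics,
    connectivity_score,
    predict_connectivity,
    quartile_groups,
    random_control_metrics,
)
from glioconnect.core_data import z_winsorize

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-random-sets", type=int, default=100)
    args = ap.parse_args()

    cm = read_count_matrix(ROOT / "scratch" / "data" / "sc_mtx")
    nm = lognormalize(cm)
    up, down = read_signature_tsv(ROOT / "results" / "02_connectivity_signature.tsv")
    sig = GeneSignature("derived", up, down)

    params = ModuleScoreParams(seed=args.seed)
    cs = connectivity_score(nm, sig, params)
    pred = predict_connectivity(cs)
    truth = nm.cell_meta["group_label"].map({"SR101high": "high", "SR101low": "low"})
    m = confusion_metrics(pred, truth)

    scores = pd.DataFrame({
        "cell_id": cs.unit_ids,
        "connectivity_score": cs.connectivity_score,
        "score_z": z_winsorize(cs.score_vector()).values,
        "predicted": pred.to_numpy(),
        "sorted_group": truth.to_numpy(),
        "quartile_group": quartile_groups(cs.score_vector()).to_numpy(),
    })
    # per-cell table is bulky; it lives with the other large artefacts
    scores_path = ROOT / "scratch" / "data" / "scores.tsv"
    scores_path.parent.mkdir(parents=True, exist_ok=True)
    scores.to_csv(scores_path, sep="\t", index=False, float_format="%.4f")

    chance = random_control_metrics(nm, truth, sizes=(len(up), len(down)),
                                    n_sets=args.n_random_sets, seed=args.seed + 1,
                                    params=params)
    report = {
        "metrics": m.as_dict(),
        "confusion": {"tp": m.tp, "fn": m.fn, "fp": m.fp, "tn": m.tn},
        "random_control_mean_metrics": chance,
        "n_random_sets": args.n_random_sets,
    }
    (ROOT / "results" / "03_classification.json").write_text(
        json.dumps(report, indent=2))
    print(f"accuracy {m.accuracy:.3f} (sens {m.sensitivity:.3f}, "
          f"spec {m.specificity:.3f}); random-set control accuracy "
          f"{chance['accuracy']:.3f}")


if __name__ == "__main__":
    main()
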
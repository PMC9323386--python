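"""Chain-initialized fuzzy clustering of the test scores.

Reads the 5-dimensional test scores from results/test_scores.csv (run
02_preprocess_reduce.py first).  FCM is seeded with the first score vector
of each storage day, run to convergence, and its centers initialize KHM
and GK.  Writes membership matrices (clusters x samples), cluster centers,
a run log and per-day membership profile plots.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from fuzzynir import (ClusterParams, chain_initialize, fcm_fit, gk_fit,
                      khm_fit)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    scores_df = pd.read_csv(RESULTS / "test_scores.csv")
    labels = scores_df["label"].to_numpy()
    scores = scores_df.drop(columns=["sample_id", "label"]).to_numpy()

    params = ClusterParams()
    inits, fcm_part = chain_initialize(scores, labels, params)
    parts = {
        "fcm": fcm_part,
        "khm": khm_fit(scores, inits["khm"], params),
        "gk": gk_fit(scores, inits["gk"], params),
    }
    log = {}
    for name, part in parts.items():
        pd.DataFrame(part.U).to_csv(RESULTS / f"membership_{name}.csv",
                                    index=False)
        pd.DataFrame(part.V).to_csv(RESULTS / f"centers_{name}.csv",
                                    index=False)
        log[name] = {
            "n_iter": part.n_iter,
            "converged": bool(part.converged),
            "final_objective": float(part.objective_trace[-1]),
            "objective_trace": [float(v) for v in part.objective_trace],
        }
        print(f"{name.upper()}: {part.n_iter} iterations, "
              f"converged={part.converged}, "
              f"objective {part.objective_trace[-1]:.6g}")
    (RESULTS / "cluster_runs.json").write_text(json.dumps(log, indent=2) + "\n")

    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        print("matplotlib unavailable; skipping membership plots")
        return
    figdir = RESULTS / "figures"
    figdir.mkdir(exist_ok=True)
    for name, part in parts.items():
        c = part.U.shape[0]
        fig, axes = plt.subplots(c, 1, figsize=(8, 1.6 * c), sharex=True)
        for i, ax in enumerate(axes):
            ax.plot(part.U[i], lw=0.8)
            ax.set_ylabel(f"day {i + 1}", fontsize=8)
            ax.set_ylim(0, 1)
        axes[-1].set_xlabel("test sample index (grouped by true day)")
        fig.suptitle(f"{name.upper()} membership profiles")
        fig.tight_layout()
        fig.savefig(figdir / f"membership_{name}.png", dpi=120)
        plt.close(fig)
    print(f"wrote membership/centers CSVs and figures under {RESULTS}")


if __name__ == "__main__":
    main()
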
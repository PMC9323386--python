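"""Split, scatter-correct and project the spectra to discriminant scores.

Takes the default synthetic set (from scratch/data/, regenerated if
absent), performs the stratified 2:1 split, fits the MSC reference on the
270 training spectra, corrects both halves, fits OLDA on the corrected
training set and projects the 132 test spectra to the 5-dimensional score
space.  Writes the test scores, the component criterion shares and a
pairwise score scatter plot of the first three components.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from fuzzynir import (SpectraSet, SyntheticConfig, apply_msc,
                      fit_msc_reference, fit_olda, generate_dataset, project,
                      split_train_test)

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"
SPLIT_SEED = 0


def load_default() -> SpectraSet:
    path = DATA / "spectra_default.csv"
    if path.exists():
        return SpectraSet.from_csv(path)
    return generate_dataset(SyntheticConfig(seed=7))


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    ds = load_default()
    train, test = split_train_test(ds, (2, 1), seed=SPLIT_SEED)
    ref = fit_msc_reference(train)
    train_c, _ = apply_msc(train, ref)
    test_c, fit = apply_msc(test, ref)
    print(f"MSC: test-sample slopes in [{fit.slope.min():.3f}, "
          f"{fit.slope.max():.3f}], fitted on {ref.n_source_samples} train spectra")

    model = fit_olda(train_c.absorbance, train_c.labels, 5)
    scores = project(model, test_c.absorbance)
    shares = model.component_shares
    print("OLDA criterion shares per component:",
          np.array2string(shares, precision=3))

    df = pd.DataFrame(scores, columns=[f"OLDA{i+1}" for i in range(5)])
    df.insert(0, "sample_id", test.sample_ids)
    df.insert(1, "label", test.labels)
    df.to_csv(RESULTS / "test_scores.csv", index=False)
    (RESULTS / "olda_model_summary.json").write_text(json.dumps({
        "n_components": model.n_components,
        "criterion_value": model.criterion_value,
        "component_shares": shares.tolist(),
    }, indent=2) + "\n")

    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        print("matplotlib unavailable; skipping score plot")
        return
    figdir = RESULTS / "figures"
    figdir.mkdir(exist_ok=True)
    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    pairs = [(0, 1), (0, 2), (1, 2)]
    for ax, (i, j) in zip(axes, pairs):
        for c in np.unique(test.labels):
            m = test.labels == c
            ax.scatter(scores[m, i], scores[m, j], s=12, label=f"day {c}")
        ax.set_xlabel(f"OLDA{i+1}")
        ax.set_ylabel(f"OLDA{j+1}")
    axes[0].legend(fontsize=7)
    fig.suptitle("Test-set discriminant scores (MSC + OLDA)")
    fig.tight_layout()
    fig.savefig(figdir / "olda_scores.png", dpi=120)
    print(f"wrote results/test_scores.csv and {figdir}/olda_scores.png")


if __name__ == "__main__":
    main()
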
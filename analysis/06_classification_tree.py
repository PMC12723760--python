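"""Post-hoc classification tree characterizing the latent classes.

Grows a Gini CART on baseline predictors (treatment arm, P-tau217, amyloid
PET, APOE e4, sex, age, education, hippocampal atrophy, baseline PACC) with
the posterior class labels as outcome; the complexity parameter is tuned by
class-stratified 10-fold cross-validation on accuracy.  Reports the tree,
cross-validated balanced accuracy, and impurity-based variable importance.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from pacctraj.cohort import read_cohort
from pacctraj.lcmm import LcmmFit
from pacctraj.pipeline import _tree_features
from pacctraj.tree import tune_tree


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", default="analysis/data")
    ap.add_argument("--results-dir", default="results")
    ap.add_argument("--seed", type=int, default=23)
    args = ap.parse_args()

    data, out = Path(args.data_dir), Path(args.results_dir)
    cohort = read_cohort(data / "visits.csv", data / "baseline.csv")
    best = LcmmFit.from_json(out / "fit.json")
    post = pd.read_csv(out / "posterior.csv")
    labels = dict(zip(post["subject_id"], post["class"]))
    best.subject_ids = post["subject_id"].to_numpy()

    feats = _tree_features(cohort, best)
    y = np.array([labels[s] for s in feats.index])
    cp, model, table = tune_tree(feats.reset_index(drop=True), y, seed=args.seed)
    table.to_csv(out / "tree_cv.csv", index=False)
    model.to_json(out / "tree.json")
    (out / "tree.txt").write_text(model.to_text())
    imp = model.variable_importance()
    imp.rename("importance_pct").rename_axis("variable").to_csv(
        out / "tree_importance.csv"
    )

    print(model.to_text())
    mean_ba, se_ba = model.cv_balanced_accuracy
    print(
        f"\nbest cp {cp}; cross-validated accuracy {model.cv_accuracy:.3f}, "
        f"balanced accuracy {mean_ba:.2f} (SE {se_ba:.3f})"
    )
    print("variable importance (%):")
    for name, pct in imp.items():
        print(f"  {name:20s} {pct:5.1f}")
    miss = 1.0 - (model.predict(feats.reset_index(drop=True)) == y).mean()
    print(f"training misclassification {miss:.1%}")


if __name__ == "__main__":
    main()
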
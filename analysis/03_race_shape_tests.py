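"""Test for mandible shape differences between the chromosomal races.

Nested MANCOVA (population within race, centroid size as covariate), the
Procrustes-distance permutation test on allometry-corrected shapes, the
leave-one-out discriminant classification rate, and a between-group PCA on
population means (with a scatter plot).
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

import morphokaryo as mk


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    landmarks = mk.read_tps(args.data_dir / "data.tps")
    meta = mk.read_metadata(args.data_dir / "meta.csv").loc[landmarks.ids]
    race = meta["race"].to_numpy()
    population = meta["population"].to_numpy()

    shapes = mk.gpa_align(landmarks)
    model = mk.regress_shape_on_size(shapes, n_perm=999, seed=args.seed)
    resid = model.residuals

    mancova = mk.nested_mancova(shapes.flat, race, population, shapes.centroid_sizes)
    for term in mancova:
        print(f"MANCOVA {term.term}: Wilks Lambda={term.statistic:.3f} "
              f"df={term.df[0]} p={term.p:.2e}")

    perm = mk.mean_shape_permutation_test(resid, race, n_perm=9999, seed=args.seed)
    print(f"race mean-shape permutation: Procrustes distance="
          f"{perm.statistic:.4f} p={perm.p:.4f}")

    loo = mk.lda_crossval(resid, race)
    print(f"LOO cross-validated classification rate: {100 * loo:.2f}%")

    bg = mk.bg_pca(resid, population)
    pct = bg["percent_total_variance"]
    print(f"between-group PC1/PC2: {pct[0]:.2f}% / {pct[1]:.2f}% of total variance")

    out = args.out_dir
    (out / "tables").mkdir(parents=True, exist_ok=True)
    (out / "figures").mkdir(parents=True, exist_ok=True)
    scores = pd.DataFrame(bg["scores"][:, :2], index=landmarks.ids,
                          columns=["bgPC1", "bgPC2"])
    scores["race"] = race
    scores["population"] = population
    scores.to_csv(out / "tables" / "bgpca_scores.csv")

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for r, marker in zip(sorted(set(race)), ("o", "s")):
        sel = scores["race"] == r
        ax.scatter(scores.loc[sel, "bgPC1"], scores.loc[sel, "bgPC2"],
                   marker=marker, alpha=0.7, label=r)
    ax.set_xlabel(f"bgPC1 ({pct[0]:.1f}%)")
    ax.set_ylabel(f"bgPC2 ({pct[1]:.1f}%)")
    ax.legend(title="race")
    fig.tight_layout()
    fig.savefig(out / "figures" / "bgpca.png", dpi=150)

    (out / "tables" / "race_shape_tests.json").write_text(json.dumps({
        "mancova": [
            {"term": t.term, "wilks_lambda": t.statistic, "df": t.df, "p": t.p}
            for t in mancova
        ],
        "mean_shape_permutation": {"distance": perm.statistic, "p": perm.p},
        "loo_rate": loo,
        "bgpca_percent": pct[:2].tolist(),
        "seed": args.seed,
    }, indent=2))


if __name__ == "__main__":
    main()
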
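"""Shape variation in geographic space.

Mantel test of morphometric against geographic distances, partial Mantel
tests controlling genetic and karyotypic structure (and the reverse control),
and the bearing analysis: Mantel correlations against direction-weighted
geographic distances over a 36-direction grid, with a profile plot.
"""

import argparse
import json
from pathlib import Path

import numpy as np

import morphokaryo as mk
from morphokaryo import gpa


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    landmarks = mk.read_tps(args.data_dir / "data.tps")
    meta = mk.read_metadata(args.data_dir / "meta.csv").loc[landmarks.ids]
    genotypes = mk.read_genotypes(args.data_dir / "genotypes.gen")
    geo = meta[["geo_x", "geo_y"]].to_numpy(float)

    shapes = mk.gpa_align(landmarks)
    resid = mk.regress_shape_on_size(shapes, n_perm=999, seed=args.seed).residuals
    morph_d = gpa.residual_shape_distances(landmarks.ids, resid)
    geo_d = mk.geographic_distances(geo, ids=landmarks.ids)
    gen_d = mk.nei_da_distance(genotypes)
    karyo_d = mk.karyotype_distance_matrix(meta["karyotype"].to_numpy(),
                                           ids=landmarks.ids)

    m = mk.mantel(morph_d, geo_d, n_perm=9999, seed=args.seed)
    print(f"Mantel morphometric ~ geographic: r={m.r:.3f} p={m.p:.4f}")
    pg = mk.partial_mantel(morph_d, geo_d, gen_d, n_perm=9999, seed=args.seed,
                           controlled_label="genetic")
    pk = mk.partial_mantel(morph_d, geo_d, karyo_d, n_perm=9999, seed=args.seed,
                           controlled_label="karyotypic")
    kg = mk.partial_mantel(karyo_d, morph_d, geo_d, n_perm=9999, seed=args.seed,
                           controlled_label="geographic")
    print(f"  morph ~ geo | genetic:   r={pg.r:.3f} p={pg.p:.4f}")
    print(f"  morph ~ geo | karyotype: r={pk.r:.3f} p={pk.p:.4f}")
    print(f"  karyo ~ morph | geo:     r={kg.r:.3f} p={kg.p:.4f}")

    profile = mk.bearing_analysis(morph_d, geo, ids=landmarks.ids,
                                  n_perm=999, seed=args.seed)
    print(f"bearing profile: max r={profile.max_r:.3f} at "
          f"{profile.argmax_direction % 180:.0f} degrees")

    out = args.out_dir
    (out / "tables").mkdir(parents=True, exist_ok=True)
    (out / "figures").mkdir(parents=True, exist_ok=True)

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(profile.directions, profile.r, marker="o", ms=3)
    sig = profile.p <= 0.05
    ax.plot(profile.directions[sig], profile.r[sig], "o", ms=5, color="crimson",
            label="p <= 0.05")
    ax.set_xlabel("bearing (degrees clockwise from north)")
    ax.set_ylabel("Mantel r")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "figures" / "bearing_profile.png", dpi=150)

    (out / "tables" / "spatial.json").write_text(json.dumps({
        "mantel_morph_geo": {"r": m.r, "p": m.p},
        "partial_morph_geo_given_genetic": {"r": pg.r, "p": pg.p},
        "partial_morph_geo_given_karyo": {"r": pk.r, "p": pk.p},
        "partial_karyo_morph_given_geo": {"r": kg.r, "p": kg.p},
        "bearing": {
            "directions": profile.directions.tolist(),
            "r": np.nan_to_num(profile.r).tolist(),
            "p": np.nan_to_num(profile.p, nan=1.0).tolist(),
            "argmax": profile.argmax_direction,
        },
        "seed": args.seed,
    }, indent=2))


if __name__ == "__main__":
    main()
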
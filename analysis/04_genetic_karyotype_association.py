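"""Disentangle karyotype from genetic relatedness.

Builds individual-level Nei D_A distances from the genotypes and the binary
karyotypic distance matrix, correlates them with allometry-corrected
morphometric distances (Mantel / partial Mantel), and compares the linear
models shape ~ race + genetic PCo vs shape ~ genetic PCo by residual
randomization (RRPP).
"""

import argparse
import json
from pathlib import Path

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
    race = meta["race"].to_numpy()

    shapes = mk.gpa_align(landmarks)
    resid = mk.regress_shape_on_size(shapes, n_perm=999, seed=args.seed).residuals
    morph_d = gpa.residual_shape_distances(landmarks.ids, resid)
    gen_d = mk.nei_da_distance(genotypes)
    karyo_d = mk.karyotype_distance_matrix(meta["karyotype"].to_numpy(),
                                           ids=landmarks.ids)

    m1 = mk.mantel(morph_d, gen_d, n_perm=9999, seed=args.seed)
    print(f"Mantel morphometric ~ genetic: r={m1.r:.3f} p={m1.p:.4f}")
    m2 = mk.partial_mantel(karyo_d, morph_d, gen_d, n_perm=9999, seed=args.seed,
                           controlled_label="genetic")
    print(f"partial Mantel karyotype ~ morphometric | genetic: "
          f"r={m2.r:.3f} p={m2.p:.4f}")

    pco = mk.pcoa(gen_d, min_variance_fraction=0.01)
    print(f"PCoA of genetic distances: {pco.retained} axes with >= 1% variance")
    rrpp = mk.race_vs_genetic_rrpp(resid, race, pco.coordinates,
                                   n_perm=999, seed=args.seed)
    print(f"RRPP race beyond genetic structure: F={rrpp.statistic:.4f} "
          f"Z={rrpp.z:.3f} p={rrpp.p:.4f}")

    out = args.out_dir / "tables"
    out.mkdir(parents=True, exist_ok=True)
    mk.write_distance_matrix(gen_d, out / "nei_da_distances.csv")
    (out / "genetic_association.json").write_text(json.dumps({
        "mantel_morph_genetic": {"r": m1.r, "p": m1.p},
        "partial_mantel_karyo_morph_given_genetic": {"r": m2.r, "p": m2.p},
        "pcoa_retained_axes": pco.retained,
        "rrpp": {"F": rrpp.statistic, "Z": rrpp.z, "p": rrpp.p},
        "seed": args.seed,
    }, indent=2))


if __name__ == "__main__":
    main()
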
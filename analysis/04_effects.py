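"""Summarize the posterior into direct effects, retained edges, and paths.

Produces the result tables of the analysis:

* coefficients.csv — posterior mean and 89% equal-tailed credible interval
  for every coefficient (the forest-plot table);
* edges.csv — the relationships whose 89% interval excludes zero ("do not
  greatly overlap zero"), signed: the retained path-diagram edges;
* paths.csv — all indirect climate/geology -> ... -> herbivory chains along
  retained edges, with draw-wise product effects and their intervals;
* genus_contrasts.csv — Flindersia-minus-Alphitonia slope differences.

If ground truth is available (truth.json from 01_simulate.py), also reports
the fraction of true coefficients covered by their 89% intervals.
"""
import argparse
import json
from pathlib import Path

import pandas as pd

import herbscape as hs
from herbscape.synthetic import TrueParameters


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in-dir", type=Path, default=Path("results") / "synthetic")
    ap.add_argument("--fit-dir", type=Path, default=Path("results") / "fit")
    ap.add_argument("--out-dir", type=Path, default=Path("results") / "effects")
    ap.add_argument("--level", type=float, default=0.89)
    args = ap.parse_args()

    tables = {
        name: pd.read_csv(args.in_dir / f"{name}.csv")
        for name in ("sites", "soil", "trees", "leaves")
    }
    data = hs.build_analysis(
        tables["sites"], tables["soil"], tables["trees"], tables["leaves"]
    )
    draws = hs.PosteriorDraws.from_dataframe(
        pd.read_csv(args.fit_dir / "draws.csv")
    )
    spec = hs.ModelSpec()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    coef_names = [
        n for n in draws.names if ".site[" not in n
    ]
    table = hs.summary_table(draws, coef_names, level=args.level)
    table.to_csv(args.out_dir / "coefficients.csv", index=False)

    graph = hs.build_path_graph(draws, spec, level=args.level)
    edges = pd.DataFrame(
        [{"source": u, "target": v, **d} for u, v, d in graph.edges(data=True)]
    )
    edges.to_csv(args.out_dir / "edges.csv", index=False)

    paths = pd.DataFrame(
        [
            {"path": p.label, "mean": p.summary.mean, "lower": p.summary.lower,
             "upper": p.summary.upper, "excludes_zero": p.summary.excludes_zero}
            for p in graph.graph["paths"]
        ]
    )
    paths.to_csv(args.out_dir / "paths.csv", index=False)

    contrasts = []
    for resp in ("total_n", "n_digest", "herbivory"):
        preds = (spec.herbivory_predictors if resp == "herbivory"
                 else spec.foliage_predictors)
        for p in preds:
            c = hs.genus_contrast(draws, resp, p, level=args.level)
            contrasts.append(
                {"response": resp, "predictor": p, "mean": c.mean,
                 "lower": c.lower, "upper": c.upper,
                 "excludes_zero": c.excludes_zero}
            )
    pd.DataFrame(contrasts).to_csv(
        args.out_dir / "genus_contrasts.csv", index=False
    )

    n_retained = int(table["excludes_zero"].sum())
    print(f"{n_retained}/{len(table)} coefficients exclude zero at "
          f"{args.level:.0%}; {graph.number_of_edges()} retained edges; "
          f"{len(paths)} abiotic->herbivory paths")
    if len(paths):
        strongest = paths.loc[paths["mean"].abs().idxmax()]
        print(f"strongest path: {strongest.path} "
              f"(mean {strongest['mean']:.3f}, "
              f"[{strongest.lower:.3f}, {strongest.upper:.3f}])")

    truth_file = args.in_dir / "truth.json"
    if truth_file.exists():
        blob = json.loads(truth_file.read_text())
        truth = TrueParameters(
            soil_coeffs=blob["soil_coeffs"],
            foliage_coeffs=blob["foliage_coeffs"],
            herbivory_coeffs=blob["herbivory_coeffs"],
        )
        tmap = hs.truth_on_model_scale(
            truth, data, leaves_per_tree=blob["config"]["leaves_per_tree"]
        )
        frac, _ = hs.coefficient_coverage(draws, tmap, level=args.level)
        print(f"coverage of true coefficients by {args.level:.0%} intervals: "
              f"{frac:.1%}")


if __name__ == "__main__":
    main()
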
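"""Convergence and posterior-predictive diagnostics for a fitted model.

Recomputes the fit context (data + model) from the synthetic tables, loads
the retained draws from 02_fit.py, and reports: the classic Gelman-Rubin
R-hat for every parameter (convergence requires R-hat - 1 < 0.1), and the
residual-sum-of-squares posterior-predictive check with Bayesian p-values per
tier and pooled (values near 0.5 indicate adequate fit).

Writes rhat.csv and ppc_pairs.csv (the observed-vs-replicated RSS pairs for
the 1:1 plot) plus bayesian_p.json under results/diagnostics/.
"""
import argparse
import json
from pathlib import Path

import pandas as pd

import herbscape as hs


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--in-dir", type=Path, default=Path("results") / "synthetic")
    ap.add_argument("--fit-dir", type=Path, default=Path("results") / "fit")
    ap.add_argument("--out-dir", type=Path, default=Path("results") / "diagnostics")
    args = ap.parse_args()

    tables = {
        name: pd.read_csv(args.in_dir / f"{name}.csv")
        for name in ("sites", "soil", "trees", "leaves")
    }
    data = hs.build_analysis(
        tables["sites"], tables["soil"], tables["trees"], tables["leaves"]
    )
    model = hs.HierarchicalModel(hs.ModelSpec(), data)
    draws = hs.PosteriorDraws.from_dataframe(
        pd.read_csv(args.fit_dir / "draws.csv")
    )

    rhat = hs.rhat_table(draws)
    ppc = hs.posterior_predictive_check(draws, model, seed=args.seed,
                                        max_draws=1000)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    rhat.to_csv(args.out_dir / "rhat.csv", index=False)
    pairs = pd.DataFrame({
        "rss_observed": ppc.rss_observed["pooled"],
        "rss_replicated": ppc.rss_replicated["pooled"],
    })
    pairs.to_csv(args.out_dir / "ppc_pairs.csv", index=False)
    with open(args.out_dir / "bayesian_p.json", "w") as fh:
        json.dump(ppc.bayesian_p, fh, indent=1)

    worst = rhat.iloc[0]
    print(f"worst R-hat: {worst.rhat:.4f} ({worst.parameter}); "
          f"convergence {'OK' if worst.rhat - 1 < 0.1 else 'NOT reached'}")
    print("Bayesian p-values:",
          {k: round(v, 3) for k, v in ppc.bayesian_p.items()})


if __name__ == "__main__":
    main()
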
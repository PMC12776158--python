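"""Sweep the sparsity weight lambda for the teacher network.

One independent seeded training per lambda on the dense dataset; writes the
per-lambda test NMSE/SSIM table and a box-plot figure under
results/lambda_sweep/.  The default grid is the protocol's
{10, 50, 100, 200, 400, 800}; --results-grid switches to the wider
{5, 25, ...} grid discussed alongside the sweep results.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from stormdistill import models, simulate, training


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dataset", type=Path, default=Path("results/data/dense13"))
    ap.add_argument("--arch", default="drlstorm")
    ap.add_argument("--epochs", type=int, default=10)
    ap.add_argument("--seed", type=int, default=123)
    ap.add_argument("--results-grid", action="store_true",
                    help="use the wider lambda grid including 5 and 25")
    ap.add_argument("--out", type=Path, default=Path("results/lambda_sweep"))
    args = ap.parse_args()

    ds = simulate.read_dataset(args.dataset)
    grid = training.LAMBDA_GRID_RESULTS if args.results_grid else training.LAMBDA_GRID_DEFAULT
    cfg = training.TrainConfig(epochs=args.epochs, rng_seed=args.seed)
    builder = lambda seed: models.build_model(args.arch, rng_seed=seed)  # noqa: E731
    table = training.sweep_lambda(builder, ds, grid, cfg)

    args.out.mkdir(parents=True, exist_ok=True)
    table.drop(columns=["nmse", "ssim"]).to_csv(args.out / "sweep.csv", index=False)
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, metric in zip(axes, ("nmse", "ssim")):
        ax.boxplot([row for row in table[metric]], tick_labels=[f"{l:g}" for l in table["lam"]])
        ax.set_xlabel("lambda")
        ax.set_ylabel(f"test {metric.upper()}")
    fig.tight_layout()
    fig.savefig(args.out / "sweep_boxplot.png", dpi=150)

    best = table.loc[table["ssim_mean"].idxmax()]
    print(table.drop(columns=["nmse", "ssim"]).to_string(index=False))
    print(f"highest mean SSIM at lambda={best['lam']:g} ({best['ssim_mean']:.3f})")


if __name__ == "__main__":
    main()
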
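"""Sweep the attention weight alpha of the attentive imitation loss.

Distills the frozen trained teacher into fresh SRCNN students, one per
alpha in 0.1..0.8; each student's test NMSE/SSIM distribution is tabulated
against the alpha-free baseline student.  Writes results/alpha_sweep/.
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
    ap.add_argument("--teacher", type=Path,
                    default=Path("results/baselines/drlstorm/checkpoint"))
    ap.add_argument("--epochs", type=int, default=10)
    ap.add_argument("--seed", type=int, default=123)
    ap.add_argument("--ail-mode", default="as_printed", choices=["as_printed", "imitation"])
    ap.add_argument("--alphas", type=float, nargs="*",
                    default=list(training.ALPHA_GRID_DEFAULT))
    ap.add_argument("--out", type=Path, default=Path("results/alpha_sweep"))
    args = ap.parse_args()

    ds = simulate.read_dataset(args.dataset)
    teacher = models.load_checkpoint(args.teacher).freeze_all()
    cfg = training.TrainConfig(epochs=args.epochs, rng_seed=args.seed)
    table = training.sweep_alpha(models.build_srcnn, teacher, ds, args.alphas, cfg,
                                 mode=args.ail_mode)

    args.out.mkdir(parents=True, exist_ok=True)
    table.drop(columns=["nmse", "ssim"]).to_csv(args.out / "sweep.csv", index=False)
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, metric in zip(axes, ("nmse", "ssim")):
        ax.boxplot([row for row in table[metric]],
                   tick_labels=[f"{a:g}" for a in table["alpha"]])
        ax.set_xlabel("alpha")
        ax.set_ylabel(f"test {metric.upper()}")
    fig.tight_layout()
    fig.savefig(args.out / "sweep_boxplot.png", dpi=150)
    print(table.drop(columns=["nmse", "ssim"]).to_string(index=False))


if __name__ == "__main__":
    main()
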
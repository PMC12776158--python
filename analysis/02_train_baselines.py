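"""Train the teacher (DRL-STORM-style) and student (SRCNN) baselines.

Both networks are optimized on the L1L2 loss (lambda = 100) over the dense
dataset from 01_simulate.py, then scored on the test split with NMSE and
SSIM.  Writes checkpoints, loss histories and a metrics comparison under
results/baselines/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from stormdistill import metrics, models, simulate, training


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dataset", type=Path, default=Path("results/data/dense13"))
    ap.add_argument("--epochs", type=int, default=20)
    ap.add_argument("--lam", type=float, default=100.0)
    ap.add_argument("--seed", type=int, default=123)
    ap.add_argument("--out", type=Path, default=Path("results/baselines"))
    args = ap.parse_args()

    ds = simulate.read_dataset(args.dataset)
    cfg = training.TrainConfig(epochs=args.epochs, lam=args.lam, rng_seed=args.seed)
    summaries = {}
    for arch in ("drlstorm", "srcnn"):
        model = models.build_model(arch, rng_seed=args.seed)
        model, hist = training.train_baseline(model, ds, cfg)
        models.save_checkpoint(model, args.out / arch / "checkpoint")
        hist.to_frame().to_csv(args.out / arch / "history.csv", index=False)
        report = metrics.evaluate(model, ds, split="test")
        pd.DataFrame({"nmse": report.nmse, "ssim": report.ssim}).to_csv(
            args.out / arch / "test_metrics.csv", index=False)
        summaries[arch] = report.summary
        print(f"{arch}: train loss {hist.train_loss[0]:.1f} -> {hist.train_loss[-1]:.1f}; "
              f"test NMSE {report.summary['nmse']['mean']:.3f}, "
              f"test SSIM {report.summary['ssim']['mean']:.3f}")

    (args.out / "summary.json").write_text(json.dumps(summaries, indent=2))
    better = max(summaries, key=lambda k: summaries[k]["ssim"]["mean"])
    print(f"higher mean test SSIM: {better}")


if __name__ == "__main__":
    main()
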
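"""Hint learning: teach SRCNN the teacher's 32-channel representation.

Stage 1 trains the student body to match the frozen teacher's hint layer
(MSE); stage 2 freezes the hint-learned body and trains only the
reconstruction head with the attentive imitation loss.  Writes both
histories, the final checkpoint and its test metrics under results/hint/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from stormdistill import metrics, models, simulate, training


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dataset", type=Path, default=Path("results/data/dense13"))
    ap.add_argument("--teacher", type=Path,
                    default=Path("results/baselines/drlstorm/checkpoint"))
    ap.add_argument("--hint-epochs", type=int, default=10)
    ap.add_argument("--head-epochs", type=int, default=10)
    ap.add_argument("--alpha", type=float, default=0.6)
    ap.add_argument("--seed", type=int, default=123)
    ap.add_argument("--out", type=Path, default=Path("results/hint"))
    args = ap.parse_args()

    ds = simulate.read_dataset(args.dataset)
    teacher = models.load_checkpoint(args.teacher).freeze_all()

    student = models.build_srcnn(args.seed)
    cfg = training.TrainConfig(epochs=args.hint_epochs, rng_seed=args.seed)
    student, hint_hist = training.train_hint(student, teacher, ds, cfg)
    print(f"hint MSE {hint_hist.train_loss[0]:.4f} -> {hint_hist.train_loss[-1]:.4f} "
          f"over {args.hint_epochs} epochs")

    student.freeze_body()
    ctx = training.make_ail_context(teacher, ds, lam=cfg.lam, alpha=args.alpha)
    head_cfg = training.TrainConfig(epochs=args.head_epochs, rng_seed=args.seed)
    student, head_hist = training.train_head_after_hint(student, teacher, ds, ctx, head_cfg)

    args.out.mkdir(parents=True, exist_ok=True)
    hint_hist.to_frame().to_csv(args.out / "hint_history.csv", index=False)
    head_hist.to_frame().to_csv(args.out / "head_history.csv", index=False)
    models.save_checkpoint(student, args.out / "checkpoint")
    report = metrics.evaluate(student, ds, split="test")
    pd.DataFrame({"nmse": report.nmse, "ssim": report.ssim}).to_csv(
        args.out / "test_metrics.csv", index=False)
    (args.out / "summary.json").write_text(json.dumps(report.summary, indent=2))
    print(f"hint-learned student: test NMSE {report.summary['nmse']['mean']:.3f}, "
          f"SSIM {report.summary['ssim']['mean']:.3f}")


if __name__ == "__main__":
    main()
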
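"""Compare 32-channel hint representations across four models.

Pools each model's hint features over the test patches (per-channel global
average, d = 32), embeds all of them jointly with UMAP, and histograms the
matched pairwise distances teacher-vs-hint-learned and teacher-vs-plain
student.  A negative mean shift means hint learning moved the student's
representation toward the teacher's.  Writes results/representation/.
"""

import argparse
import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from stormdistill import models, representation, simulate


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dataset", type=Path, default=Path("results/data/dense13"))
    ap.add_argument("--teacher", type=Path,
                    default=Path("results/baselines/drlstorm/checkpoint"))
    ap.add_argument("--student", type=Path,
                    default=Path("results/baselines/srcnn/checkpoint"))
    ap.add_argument("--hint-student", type=Path, default=Path("results/hint/checkpoint"))
    ap.add_argument("--seed", type=int, default=123)
    ap.add_argument("--max-patches", type=int, default=100)
    ap.add_argument("--out", type=Path, default=Path("results/representation"))
    args = ap.parse_args()

    ds = simulate.read_dataset(args.dataset)
    x, _ = ds.split("test")
    x = x[: args.max_patches]

    named = {
        "srcnn_untrained": models.build_srcnn(args.seed + 1),
        "srcnn_trained": models.load_checkpoint(args.student),
        "srcnn_hint_learned": models.load_checkpoint(args.hint_student),
        "drlstorm": models.load_checkpoint(args.teacher),
    }
    sets = {}
    for label, model in named.items():
        fs = representation.extract_features(model, x)
        fs.model_name = label
        sets[label] = fs

    frame = representation.embed_models(list(sets.values()), rng_seed=args.seed)
    args.out.mkdir(parents=True, exist_ok=True)
    frame.to_csv(args.out / "embedding.csv", index=False)

    d_hint = representation.pairwise_distances(sets["drlstorm"], sets["srcnn_hint_learned"])
    d_plain = representation.pairwise_distances(sets["drlstorm"], sets["srcnn_trained"])
    shift = representation.distance_shift_summary(d_hint, d_plain)
    (args.out / "distance_shift.json").write_text(json.dumps(shift, indent=2))

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for label, grp in frame.groupby("model"):
        axes[0].scatter(grp["u1"], grp["u2"], s=8, label=label)
    axes[0].legend(fontsize=7)
    axes[0].set_title("UMAP of pooled hint features")
    axes[1].hist(d_plain, bins=20, alpha=0.6, label="teacher vs trained SRCNN")
    axes[1].hist(d_hint, bins=20, alpha=0.6, label="teacher vs hint-learned SRCNN")
    axes[1].set_xlabel("pairwise feature distance")
    axes[1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(args.out / "representation.png", dpi=150)

    print(json.dumps(shift, indent=2))
    direction = "toward" if shift["shift_mean"] <= 0 else "away from"
    print(f"hint learning moved the student's representation {direction} the teacher "
          f"(mean shift {shift['shift_mean']:+.4f})")


if __name__ == "__main__":
    main()
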
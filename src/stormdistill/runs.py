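"""Config-driven pipeline stages and TIFF stack reconstruction.

A run configuration is a plain nested mapping (usually loaded from YAML)
naming a stage plus the parameters that stage needs.  ``run_stage`` validates
it against the known key schema (unknown keys are rejected with their full
key path), executes the stage, and leaves a self-contained run directory:
the config snapshot, a timestamped log, and the stage's artifacts
(dataset bundle, checkpoints, history/report CSVs).  All randomness flows
from the config's ``seed``, so deterministic stages replay bit-identically
from their snapshots.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from stormdistill import losses, metrics, representation, simulate, training
from stormdistill.models import FactorizedModel, build_model, load_checkpoint, save_checkpoint

STAGES = (
    "simulate",
    "train",
    "distill",
    "hint",
    "evaluate",
    "embed",
    "sweep-lambda",
    "sweep-alpha",
    "reconstruct",
)

#: allowed keys, by config section (None = scalar leaf)
_SCHEMA = {
    "stage": None,
    "seed": None,
    "out_dir": None,
    "dataset": {
        "n_images", "image_size", "pixel_size_um", "density_per_um2",
        "background_level", "psf_sigma_px", "patch_size", "patches_per_image",
        "split_probs", "photon_model", "photons", "y_scale",
    },
    "model": {"arch", "enc_widths", "dec_widths", "skip_mode", "upsample"},
    "loss": {"lam", "alpha", "ail_mode", "kernel", "hint_reduction"},
    "train": {
        "epochs", "batch_size", "learning_rate", "sched_factor",
        "sched_patience", "sched_threshold", "monitor",
    },
    "eval": {"split", "nmse_mode", "ssim_window"},
    "embed": {"n_neighbors", "min_dist", "pooling", "split", "max_patches"},
    "sweep": {"lambda_values", "alpha_values"},
    "reconstruct": {"aggregate", "norm_mean", "norm_std"},
    "paths": {
        "dataset_dir", "teacher_checkpoint", "student_checkpoint",
        "checkpoint", "checkpoints", "tiff",
    },
}
_KERNEL_KEYS = {"size", "sigma"}


def validate_config(config: dict) -> dict:
    """Check every key against the schema; reject unknowns by key path."""
    if "stage" not in config:
        raise ValueError("config must name a 'stage'")
    if config["stage"] not in STAGES:
        raise ValueError(f"unknown stage {config['stage']!r}; expected one of {STAGES}")
    for key, value in config.items():
        if key not in _SCHEMA:
            raise ValueError(f"unknown config key '{key}'")
        allowed = _SCHEMA[key]
        if allowed is None:
            continue
        if not isinstance(value, dict):
            raise ValueError(f"config section '{key}' must be a mapping")
        for sub in value:
            if sub not in allowed:
                raise ValueError(f"unknown config key '{key}.{sub}'")
            if key == "loss" and sub == "kernel":
                for kk in value[sub]:
                    if kk not in _KERNEL_KEYS:
                        raise ValueError(f"unknown config key 'loss.kernel.{kk}'")
    return config


def _loss_kernel(config: dict) -> losses.GaussianKernel:
    kcfg = config.get("loss", {}).get("kernel", {})
    return losses.make_gaussian_kernel(kcfg.get("size", 3), kcfg.get("sigma", 1.0))


def _train_config(config: dict, seed: int) -> training.TrainConfig:
    t = dict(config.get("train", {}))
    lam = float(config.get("loss", {}).get("lam", 100.0))
    return training.TrainConfig(lam=lam, kernel=_loss_kernel(config), rng_seed=seed, **t)


def _build_from_config(config: dict, seed: int) -> FactorizedModel:
    m = dict(config.get("model", {}))
    arch = m.pop("arch", "srcnn")
    if arch == "drlstorm":
        for k in ("enc_widths", "dec_widths"):
            if k in m:
                m[k] = tuple(m[k])
    else:
        m = {}
    return build_model(arch, rng_seed=seed, **m)


def _load_dataset(config: dict) -> simulate.PatchDataset:
    try:
        dataset_dir = config["paths"]["dataset_dir"]
    except KeyError:
        raise ValueError("config requires 'paths.dataset_dir' for this stage")
    return simulate.read_dataset(dataset_dir)


def _write_history(history: training.TrainHistory, run_dir: Path) -> None:
    history.to_frame().to_csv(run_dir / "history.csv", index=False)


def _write_report(report: metrics.MetricsReport, run_dir: Path, stem: str = "report") -> None:
    pd.DataFrame({"patch": np.arange(len(report.nmse)), "nmse": report.nmse,
                  "ssim": report.ssim}).to_csv(run_dir / f"{stem}.csv", index=False)
    summary = {"model": report.model_name, "dataset": report.dataset_id,
               **report.summary}
    (run_dir / f"{stem}_summary.json").write_text(json.dumps(summary, indent=2))


def run_stage(config: dict, out_dir: str | Path | None = None) -> Path:
    """Validate, execute and archive one pipeline stage; return the run dir."""
    config = validate_config(dict(config))
    stage = config["stage"]
    seed = int(config.get("seed", 0))
    run_dir = Path(out_dir or config.get("out_dir") or f"runs/{stage}")
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.json").write_text(json.dumps(config, indent=2, default=str))

    log = logging.getLogger(f"stormdistill.{stage}")
    handler = logging.FileHandler(run_dir / "log.txt")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    t0 = time.time()
    log.info("stage=%s seed=%d out=%s", stage, seed, run_dir)
    try:
        _STAGE_FNS[stage](config, seed, run_dir, log)
        log.info("stage complete in %.1f s", time.time() - t0)
    finally:
        log.removeHandler(handler)
        handler.close()
    return run_dir


# ---------------------------------------------------------------------------
# stage implementations


def _stage_simulate(config, seed, run_dir, log):
    ds = simulate.make_dataset(rng_seed=seed, **config.get("dataset", {}))
    simulate.write_dataset(ds, run_dir / "dataset")
    log.info("dataset: %d patches of %d px, splits %s", len(ds), ds.patch_size,
             {s: int((ds.labels == s).sum()) for s in simulate.SPLITS})


def _stage_train(config, seed, run_dir, log):
    ds = _load_dataset(config)
    model = _build_from_config(config, seed)
    cfg = _train_config(config, seed)
    model, history = training.train_baseline(model, ds, cfg)
    save_checkpoint(model, run_dir / "checkpoint")
    _write_history(history, run_dir)
    log.info("trained %s for %d epochs; final val loss %.4g", model.name,
             cfg.epochs, history.val_loss[-1] if history.val_loss else float("nan"))


def _ail_context_from_config(config, teacher, ds):
    loss_cfg = config.get("loss", {})
    return training.make_ail_context(
        teacher, ds,
        lam=float(loss_cfg.get("lam", 100.0)),
        alpha=float(loss_cfg.get("alpha", 0.5)),
        kernel=_loss_kernel(config),
        mode=loss_cfg.get("ail_mode", "as_printed"),
    )


def _stage_distill(config, seed, run_dir, log):
    ds = _load_dataset(config)
    teacher = load_checkpoint(config["paths"]["teacher_checkpoint"]).freeze_all()
    student = _build_from_config(config, seed)
    ctx = _ail_context_from_config(config, teacher, ds)
    pd.DataFrame({"sample": np.arange(ctx.e_T.size), "e_T": ctx.e_T}).to_csv(
        run_dir / "teacher_errors.csv", index=False)
    cfg = _train_config(config, seed)
    student, history = training.train_with_ail(student, teacher, ds, ctx, cfg)
    save_checkpoint(student, run_dir / "checkpoint")
    _write_history(history, run_dir)
    log.info("distilled %s (alpha=%.2f, phi=%.4g)", student.name, ctx.alpha, ctx.phi)


def _stage_hint(config, seed, run_dir, log):
    ds = _load_dataset(config)
    teacher = load_checkpoint(config["paths"]["teacher_checkpoint"]).freeze_all()
    student = _build_from_config(config, seed)
    cfg = _train_config(config, seed)
    reduction = config.get("loss", {}).get("hint_reduction", "mean")
    student, history = training.train_hint(student, teacher, ds, cfg, reduction=reduction)
    save_checkpoint(student, run_dir / "checkpoint")
    _write_history(history, run_dir)
    log.info("hint learning: loss %.4g -> %.4g", history.train_loss[0],
             history.train_loss[-1])


def _stage_evaluate(config, seed, run_dir, log):
    ds = _load_dataset(config)
    model = load_checkpoint(config["paths"]["checkpoint"])
    e = config.get("eval", {})
    report = metrics.evaluate(model, ds, split=e.get("split", "test"),
                              nmse_mode=e.get("nmse_mode", "printed"),
                              ssim_window=e.get("ssim_window", 7))
    _write_report(report, run_dir)
    log.info("evaluated %s: mean NMSE %.4g, mean SSIM %.4g", report.model_name,
             report.nmse.mean(), report.ssim.mean())


def _stage_embed(config, seed, run_dir, log):
    ds = _load_dataset(config)
    e = config.get("embed", {})
    x, _ = ds.split(e.get("split", "test"))
    x = x[: e.get("max_patches", 200)]
    sets = []
    for i, ckpt in enumerate(config["paths"]["checkpoints"]):
        model = load_checkpoint(ckpt)
        fs = representation.extract_features(model, x, pooling=e.get("pooling", "mean"))
        # disambiguate multiple checkpoints of one architecture
        fs.model_name = f"{fs.model_name}#{i}"
        sets.append(fs)
    frame = representation.embed_models(sets, n_neighbors=e.get("n_neighbors", 15),
                                        min_dist=e.get("min_dist", 0.1), rng_seed=seed)
    frame.to_csv(run_dir / "embedding.csv", index=False)
    log.info("embedded %d vectors from %d models", len(frame), len(sets))


def _stage_sweep_lambda(config, seed, run_dir, log):
    ds = _load_dataset(config)
    lams = config.get("sweep", {}).get("lambda_values", training.LAMBDA_GRID_DEFAULT)
    cfg = _train_config(config, seed)
    builder = lambda s: _build_from_config(config, s)  # noqa: E731
    table = training.sweep_lambda(builder, ds, lams, cfg)
    table.drop(columns=["nmse", "ssim"]).to_csv(run_dir / "sweep_lambda.csv", index=False)
    log.info("lambda sweep over %s complete", list(lams))


def _stage_sweep_alpha(config, seed, run_dir, log):
    ds = _load_dataset(config)
    alphas = config.get("sweep", {}).get("alpha_values", training.ALPHA_GRID_DEFAULT)
    teacher = load_checkpoint(config["paths"]["teacher_checkpoint"]).freeze_all()
    cfg = _train_config(config, seed)
    builder = lambda s: _build_from_config(config, s)  # noqa: E731
    table = training.sweep_alpha(builder, teacher, ds, alphas, cfg,
                                 mode=config.get("loss", {}).get("ail_mode", "as_printed"))
    table.drop(columns=["nmse", "ssim"]).to_csv(run_dir / "sweep_alpha.csv", index=False)
    log.info("alpha sweep over %s complete", list(alphas))


def _stage_reconstruct(config, seed, run_dir, log):
    model = load_checkpoint(config["paths"]["checkpoint"])
    r = config.get("reconstruct", {})
    if "norm_mean" in r and "norm_std" in r:
        norm_stats = (float(r["norm_mean"]), float(r["norm_std"]))
    else:
        ds_meta = json.loads((Path(config["paths"]["dataset_dir"]) / "meta.json").read_text())
        norm_stats = (ds_meta["norm_mean"], ds_meta["norm_std"])
    image = reconstruct_stack(model, config["paths"]["tiff"], norm_stats,
                              aggregate=r.get("aggregate", "sum"))
    tifffile.imwrite(run_dir / "reconstruction.tiff", image.astype(np.float32))
    log.info("reconstructed %s -> %s", config["paths"]["tiff"], image.shape)


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "train": _stage_train,
    "distill": _stage_distill,
    "hint": _stage_hint,
    "evaluate": _stage_evaluate,
    "embed": _stage_embed,
    "sweep-lambda": _stage_sweep_lambda,
    "sweep-alpha": _stage_sweep_alpha,
    "reconstruct": _stage_reconstruct,
}


def reconstruct_stack(
    model: FactorizedModel,
    tiff_stack_path: str | Path | np.ndarray,
    norm_stats: tuple[float, float],
    aggregate: str = "sum",
    batch_size: int = 8,
) -> np.ndarray:
    """Run a model over every frame of a stack and aggregate the outputs.

    Frames are z-scored with the training set's pooled ``(mean, std)``,
    reflect-padded to the model's spatial-divisor constraint, reconstructed,
    cropped back, and summed (standard SMLM rendering) or averaged.
    """
    if aggregate not in ("sum", "mean"):
        raise ValueError("aggregate must be 'sum' or 'mean'")
    if isinstance(tiff_stack_path, np.ndarray):
        frames = tiff_stack_path
    else:
        try:
            frames = tifffile.imread(tiff_stack_path)
        except (OSError, ValueError) as exc:
            raise OSError(f"cannot read TIFF stack {tiff_stack_path}: {exc}") from exc
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim == 2:
        frames = frames[None]
    mean, std = norm_stats
    if std <= 0:
        raise ValueError("norm std must be positive")
    h, w = frames.shape[1:]
    d = model.spatial_divisor
    ph, pw = (-h) % d, (-w) % d
    x = (frames - mean) / std
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, ph), (0, pw)), mode="reflect")
    out = training.predict(model, x.astype(np.float32), batch_size=batch_size)[:, 0]
    out = out[:, :h, :w]
    return out.sum(axis=0) if aggregate == "sum" else out.mean(axis=0)
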
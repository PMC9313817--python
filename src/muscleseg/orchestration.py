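"""End-to-end experiment: simulate -> observers -> pretrain -> fine-tune ->
evaluate -> report.

Stages are idempotent: each writes its outputs plus a small state file
recording a hash of the configuration that produced them; a rerun with the
same configuration skips the stage, and deleting one run's checkpoint
re-executes only that run. A manifest lists every artifact with a checksum.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as msio
from .design import ExperimentGrid, derive_seed, enumerate_runs, make_folds, nested_subsets
from .metrics import bone_mask, dsc, remove_bone, rms_dta, sma, smd
from .nn import NetConfig
from .preprocess import to_model_input, window_level
from .pretext import (
    build_permutation_set,
    train_autoencoder,
    train_classification_proxy,
    train_jigsaw,
    train_segmentation_proxy,
)
from .statistics import dunnett_test, observer_baseline, summarize_grid
from .synthetic import calibrate_observer, generate_phantom, simulate_observer, wall_mask
from .training import TrainConfig, fine_tune, predict, transfer_weights
from .types import MetricRecord, ObserverModel, PhantomParams
from .weights import NamedWeights

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "run_experiment", "smoke_config", "paper_scale_config"]


@dataclass
class ExperimentConfig:
    phantom: PhantomParams = field(default_factory=PhantomParams)
    grid: ExperimentGrid = field(default_factory=ExperimentGrid)
    train: TrainConfig = field(default_factory=TrainConfig)
    n_test: int = 37
    observer_target_dsc: float = 0.90
    observers_per_image: int = 5
    n_permutations: int = 50
    pretrain_epochs: int = 15
    master_seed: int = 0
    out_root: str = "runs"

    def to_dict(self) -> dict:
        return {
            "phantom": self.phantom.to_dict(),
            "grid": self.grid.to_dict(),
            "train": self.train.to_dict(),
            "n_test": self.n_test,
            "observer_target_dsc": self.observer_target_dsc,
            "observers_per_image": self.observers_per_image,
            "n_permutations": self.n_permutations,
            "pretrain_epochs": self.pretrain_epochs,
            "master_seed": self.master_seed,
            "out_root": self.out_root,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(
            phantom=PhantomParams.from_dict(d["phantom"]),
            grid=ExperimentGrid.from_dict(d["grid"]),
            train=TrainConfig.from_dict(d["train"]),
            **{
                k: d[k]
                for k in (
                    "n_test",
                    "observer_target_dsc",
                    "observers_per_image",
                    "n_permutations",
                    "pretrain_epochs",
                    "master_seed",
                    "out_root",
                )
            },
        )

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def smoke_config(out_root: str = "runs", master_seed: int = 0) -> ExperimentConfig:
    """Desk-scale grid: cohort 60, sizes (5, 10, 25), 2 pretexts, 64 px."""
    phantom = PhantomParams(cohort_size=60, image_side=64, spacing_mm=6.0)
    grid = ExperimentGrid(
        pretext_tasks=("random_init", "segmentation"),
        subset_sizes=(5, 10, 25),
        n_folds=4,
        n_subsamples_per_size=2,
        n_repeats_per_subset=2,
        master_seed=master_seed,
    )
    train = TrainConfig(net=NetConfig(width=8), max_epochs=150, patience=40)
    return ExperimentConfig(
        phantom=phantom,
        grid=grid,
        train=train,
        n_test=12,
        pretrain_epochs=100,
        master_seed=master_seed,
        out_root=out_root,
    )


def paper_scale_config(out_root: str = "runs", master_seed: int = 0) -> ExperimentConfig:
    """The full study-shaped grid (cohort 204, all five pretexts, sizes 5-125)."""
    grid = ExperimentGrid(master_seed=master_seed)
    return ExperimentConfig(
        phantom=PhantomParams(cohort_size=204),
        grid=grid,
        train=TrainConfig(max_epochs=100, patience=20),
        n_test=37,
        master_seed=master_seed,
        out_root=out_root,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _stage_fresh(state_file: Path, cfg_hash: str) -> bool:
    if not state_file.exists():
        return False
    try:
        return json.loads(state_file.read_text()).get("config_hash") == cfg_hash
    except json.JSONDecodeError:
        return False


def _mark_stage(state_file: Path, cfg_hash: str) -> None:
    state_file.write_text(json.dumps({"config_hash": cfg_hash}))


def _model_inputs(slices):
    return {
        ct.slice_id: to_model_input(window_level(ct), provenance=ct.slice_id)
        for ct in slices
    }


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute the full pipeline; returns the manifest of produced artifacts."""
    out = Path(config.out_root)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    msio.save_json(config.to_dict(), out / "config.json")
    manifest: dict = {"config_hash": cfg_hash, "stages": {}, "files": {}, "failures": []}

    # ---- stage 1: simulate -------------------------------------------------
    cohort_dir = out / "cohort"
    state = out / "simulate.state.json"
    if not _stage_fresh(state, cfg_hash):
        cohort = generate_phantom(config.phantom, derive_seed(config.master_seed, "cohort"))
        msio.save_cohort(cohort, cohort_dir)
        _mark_stage(state, cfg_hash)
        logger.info("simulate: wrote %d phantoms", len(cohort))
    else:
        cohort = msio.load_cohort(cohort_dir / "manifest.csv")
        logger.info("simulate: cache hit")
    manifest["stages"]["simulate"] = "done"

    ids = [ct.slice_id for ct, _, _ in cohort]
    rng = np.random.default_rng(derive_seed(config.master_seed, "split"))
    order = list(rng.permutation(len(ids)))
    test_ids = sorted(ids[i] for i in order[: config.n_test])
    parent_ids = sorted(ids[i] for i in order[config.n_test :])
    grid = ExperimentGrid.from_dict(
        {**config.grid.to_dict(), "test_ids": test_ids, "parent_ids": parent_ids,
         "master_seed": config.master_seed}
    )
    assert not (set(test_ids) & set(parent_ids)), "test-set isolation violated"

    by_id = {ct.slice_id: (ct, mu, bo) for ct, mu, bo in cohort}
    inputs = _model_inputs([ct for ct, _, _ in cohort])

    # ---- stage 2: observer study ------------------------------------------
    obs_file = out / "observer_baseline.json"
    state = out / "observers.state.json"
    if not _stage_fresh(state, cfg_hash):
        calib_masks = [by_id[i][1] for i in parent_ids[:10]]
        model = calibrate_observer(
            calib_masks,
            config.observer_target_dsc,
            derive_seed(config.master_seed, "calibrate"),
        )
        observer_masks = {}
        for sid in test_ids:
            truth = by_id[sid][1]
            observer_masks[sid] = [
                simulate_observer(
                    truth, model, derive_seed(config.master_seed, "obs", sid, j)
                )
                for j in range(config.observers_per_image)
            ]
        baseline = observer_baseline(
            observer_masks,
            {sid: by_id[sid][1] for sid in test_ids},
            {sid: by_id[sid][0] for sid in test_ids},
        )
        obs_values = {
            "dsc": [
                float(dsc(o, by_id[sid][1]))
                for sid, obs in observer_masks.items()
                for o in obs
            ],
            "rms_dta_cm": [
                float(rms_dta(o, by_id[sid][1]))
                for sid, obs in observer_masks.items()
                for o in obs
            ],
        }
        msio.save_json(
            {
                "model": model.to_dict(),
                "baseline": baseline.to_dict(),
                "values": obs_values,
                "delineations_per_image": config.observers_per_image + 1,
            },
            obs_file,
        )
        _mark_stage(state, cfg_hash)
    manifest["stages"]["observers"] = "done"

    # ---- stage 3: pretraining ---------------------------------------------
    weights_dir = out / "pretrained"
    weights_dir.mkdir(exist_ok=True)
    parent_inputs = [inputs[i] for i in parent_ids]
    pretrained: dict[str, NamedWeights | None] = {"random_init": None}
    for task in grid.pretext_tasks:
        if task == "random_init":
            continue
        wfile = weights_dir / f"{task}.npz"
        if wfile.exists() and _stage_fresh(weights_dir / f"{task}.state.json", cfg_hash):
            pretrained[task] = NamedWeights.load(wfile)
            continue
        seed = derive_seed(config.master_seed, "pretrain", task)
        if task == "reconstruction":
            res = train_autoencoder(
                parent_inputs, config.train.net, seed, epochs=config.pretrain_epochs
            )
        elif task == "jigsaw":
            pset = build_permutation_set((3, 3), config.n_permutations, seed)
            msio.save_json(pset.to_dict(), weights_dir / "permutations.json")
            res = train_jigsaw(
                parent_inputs, pset, config.train.net, seed, epochs=config.pretrain_epochs
            )
        elif task == "classification":
            # image-level label: number of connected bone components
            from scipy import ndimage as ndi

            labels = [
                min(int(ndi.label(by_id[i][2].bool())[1]), 3) for i in parent_ids
            ]
            res = train_classification_proxy(
                parent_inputs, labels, config.train.net, seed,
                epochs=config.pretrain_epochs,
            )
        elif task == "segmentation":
            aux_params = PhantomParams(
                **{
                    **config.phantom.to_dict(),
                    "cohort_size": max(20, config.phantom.cohort_size),
                    "shape_variability": config.phantom.shape_variability * 1.3,
                }
            )
            aux = generate_phantom(aux_params, derive_seed(config.master_seed, "aux"))
            aux_cohort = [
                (
                    to_model_input(window_level(ct), provenance=f"aux_{ct.slice_id}"),
                    wall_mask(ct, mu),
                )
                for ct, mu, _ in aux
            ]
            res = train_segmentation_proxy(
                aux_cohort, config.train.net, seed,
                epochs=config.pretrain_epochs, target_ids=set(ids),
            )
        res.weights.save(wfile)
        _mark_stage(weights_dir / f"{task}.state.json", cfg_hash)
        pretrained[task] = res.weights
        logger.info("pretrain %s: final loss %.4f", task, res.loss_history[-1])
    manifest["stages"]["pretrain"] = "done"

    # ---- stage 4: fine-tune + evaluate ------------------------------------
    runs_dir = out / "finetuned"
    runs_dir.mkdir(exist_ok=True)
    folds = make_folds(parent_ids, grid.n_folds, derive_seed(config.master_seed, "folds"))
    records: list[MetricRecord] = []
    rec_file = out / "metrics.csv"
    from .nn import SegmentationNet  # target layer names/shapes

    target_shapes = {
        k: p.value.shape
        for k, p in SegmentationNet(config.train.net, seed=0).named_parameters().items()
    }
    test_bone = {sid: bone_mask(by_id[sid][0]) for sid in test_ids}

    for run in enumerate_runs(grid):
        tag = f"{run.pretext}_n{run.size}_f{run.fold}_c{run.chain}_r{run.repeat}"
        ckpt_file = runs_dir / f"{tag}.npz"
        met_file = runs_dir / f"{tag}.metrics.csv"
        if ckpt_file.exists() and met_file.exists():
            cached = pd.read_csv(met_file, float_precision="round_trip")
            records.extend(MetricRecord(**row) for row in cached.to_dict("records"))
            continue
        try:
            val_ids = folds[run.fold]
            train_pool = sorted(set(parent_ids) - set(val_ids))
            chains = nested_subsets(
                train_pool,
                grid.subset_sizes,
                grid.n_subsamples_per_size,
                derive_seed(config.master_seed, "subsets", run.fold),
            )
            subset = chains[run.chain][run.size]
            assert not (set(subset) & set(test_ids) | set(subset) & set(val_ids))
            train_data = [(inputs[i], by_id[i][1]) for i in subset]
            val_data = [(inputs[i], by_id[i][1]) for i in val_ids]
            init, rep = transfer_weights(
                pretrained[run.pretext], target_shapes, seed=derive_seed(run.seed, "init")
            )
            result = fine_tune(
                init, rep, train_data, val_data, config.train, run.seed, descriptor=run
            )
            result.checkpoint.save(ckpt_file)
            pd.DataFrame(
                {"epoch": range(len(result.train_loss)),
                 "train_loss": result.train_loss, "val_loss": result.val_loss}
            ).to_csv(runs_dir / f"{tag}.losses.csv", index=False)
            run_records = []
            for sid in test_ids:
                ct, truth, _ = by_id[sid]
                pred = predict(result.checkpoint, inputs[sid], config.train.net, ct.spacing)
                d = dsc(pred, truth)
                dta = (
                    rms_dta(pred, truth)
                    if pred.area_px > 0
                    else float("nan")
                )
                clean = remove_bone(pred, test_bone[sid])
                run_records.append(
                    MetricRecord(
                        pretext=run.pretext, size=run.size, fold=run.fold,
                        chain=run.chain, repeat=run.repeat, slice_id=sid,
                        dsc=d,
                        rms_dta_cm=dta,
                        smd_hu=smd(ct, clean) if clean.area_px else float("nan"),
                        sma_cm2=sma(clean),
                    )
                )
            pd.DataFrame([r.__dict__ for r in run_records]).to_csv(met_file, index=False)
            records.extend(run_records)
        except Exception as exc:  # keep going; record the failure
            logger.exception("run %s failed", tag)
            manifest["failures"].append({"run": tag, "error": str(exc)})
    df = pd.DataFrame([r.__dict__ for r in records])
    df.to_csv(rec_file, index=False)
    manifest["stages"]["finetune_evaluate"] = "done"

    # ---- stage 5: report ---------------------------------------------------
    report = _report(out, df, msio.load_json(obs_file))
    manifest["stages"]["report"] = "done"
    manifest["report"] = report

    for f in sorted(out.rglob("*")):
        if f.is_file() and f.suffix in {".csv", ".json", ".npz", ".nii", ".png"}:
            manifest["files"][str(f.relative_to(out))] = _sha256(f)
    msio.save_json(manifest, out / "manifest.json")
    return manifest


def _report(out: Path, df: pd.DataFrame, obs: dict) -> dict:
    """Summary tables, Dunnett comparisons vs the observer control, plots."""
    report: dict = {}
    obs_dsc = np.asarray(obs["values"]["dsc"])
    obs_dta = np.asarray(obs["values"]["rms_dta_cm"])
    for metric, control in (("dsc", obs_dsc), ("rms_dta_cm", obs_dta)):
        sub = df.dropna(subset=[metric])
        table, plateau = summarize_grid(sub, metric=metric)
        table.to_csv(out / f"summary_{metric}.csv", index=False)
        groups = {
            f"{p}/n={s}": g[metric].to_numpy()
            for (p, s), g in sub.groupby(["pretext", "size"])
            if len(g) >= 2
        }
        if groups and len(control) >= 2:
            dres = dunnett_test(groups, control)
            pd.DataFrame(
                [
                    {"comparison": k, "adjusted_p": v,
                     "direction": dres.directions[k]}
                    for k, v in dres.p_values.items()
                ]
            ).to_csv(out / f"dunnett_{metric}.csv", index=False)
            report[f"dunnett_{metric}"] = dres.p_values
        report[f"plateau_{metric}"] = plateau
    _plot(out, df, obs)
    return report


def _plot(out: Path, df: pd.DataFrame, obs: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for metric, ax, obs_key in (
        ("dsc", axes[0], "dsc"),
        ("rms_dta_cm", axes[1], "rms_dta_cm"),
    ):
        sub = df.dropna(subset=[metric])
        for pretext, grp in sub.groupby("pretext"):
            agg = grp.groupby("size")[metric].agg(["mean", "sem"])
            ax.errorbar(
                agg.index, agg["mean"], yerr=1.96 * agg["sem"], marker="o",
                capsize=3, label=pretext,
            )
        vals = np.asarray(obs["values"][obs_key])
        mu, se = vals.mean(), vals.std(ddof=1) / np.sqrt(len(vals))
        ax.axhline(mu, ls=":", color="k")
        ax.axhspan(mu - se, mu + se, color="k", alpha=0.1)
        ax.set_xlabel("training-set size n")
        ax.set_ylabel(metric)
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "learning_curves.png", dpi=120)
    plt.close(fig)
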
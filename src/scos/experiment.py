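"""Desk-scale study orchestration.

Reproduces the study protocol end to end on synthetic phantoms: train
every task setting on *unrotated* slices (optionally with online random
rotation augmentation), then evaluate on rotated 2D test slices (no
post-processing) and on rotated 3D volumes (largest-connected-component
post-processing), and aggregate per-setting, per-organ metric summaries.

Single-task models are trained one per organ and grouped back into a
composite "STL" entry so they can be compared with the joint settings on
identical cases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aux_targets import contour_map, distance_map
from .losses import compute_loss
from .metrics import MetricRecord, evaluate_case, largest_cc_3d, records_to_frame, summarize
from .model import BackboneConfig, SegModel, build_model, get_setting
from .nn import Adam
from .phantom import ORGANS, PhantomConfig, generate_dataset, generate_volume
from .preprocess import WindowSpec, preprocess_slice, random_rotation_augment

# paper-scale reference hyperparameters (defaults of record): learning rate
# 1e-3, batch size 8, 3000 epochs. Desk-scale runs override epochs.
PAPER_SCALE = {"learning_rate": 1e-3, "batch_size": 8, "epochs": 3000}

#: evaluation groups -> the settings whose heads cover the three organs
GROUPS = {
    "STL": ("STL_lung", "STL_heart", "STL_cord"),
    "SCOS": ("SCOS",),
    "TASKS1": ("TASKS1",),
    "TASKS2": ("TASKS2",),
    "STL_aug": ("STL_lung_aug", "STL_heart_aug", "STL_cord_aug"),
    "SCOS_aug": ("SCOS_aug",),
}


@dataclass(frozen=True)
class ExperimentConfig:
    phantom: PhantomConfig = PhantomConfig()
    model: BackboneConfig = BackboneConfig()
    groups: tuple[str, ...] = ("STL", "SCOS", "TASKS1", "TASKS2", "STL_aug", "SCOS_aug")
    learning_rate: float = 1e-3
    batch_size: int = 8
    epochs: int = 25
    n_train: int = 96
    n_val: int = 32
    n_test_2d: int = 120
    n_test_volumes: int = 4
    volume_slices: int = 12
    volume_angle_range: tuple[float, float] = (1.5, 9.34)
    augment_range: tuple[float, float] = (-30.0, 30.0)
    window: WindowSpec = WindowSpec()
    threshold: float = 0.5
    seeds: tuple[int, ...] = (0, 1, 2)
    # multi-start safeguards for the soft-Dice small-structure trap: at
    # ``restart_epoch`` any segmentation head whose training Dice is below
    # ``restart_dice`` marks a stuck basin; training restarts from a fresh
    # derived init (at most ``max_restarts`` times). After the scheduled
    # epochs, heads still below ``extend_below`` earn up to
    # ``max_extensions`` blocks of ``extend_epochs`` further epochs.
    restart_epoch: int | None = None
    restart_dice: float = 0.30
    max_restarts: int = 3
    extend_epochs: int = 8
    max_extensions: int = 0
    extend_below: float = 0.90

    def settings(self) -> list[str]:
        out = []
        for g in self.groups:
            out.extend(GROUPS[g])
        return out


def desk_study_config(base_seed: int = 0) -> ExperimentConfig:
    """The desk-scale study conditions: 56x56 phantoms, depth-3 backbone
    with 6 base filters, 64 unrotated training slices, three stochastic
    replicates. ``base_seed`` shifts the replicate seeds."""
    return ExperimentConfig(
        phantom=PhantomConfig(image_height=56, image_width=56),
        model=BackboneConfig(depth=3, base_filters=6),
        n_train=64, n_val=32, n_test_2d=72,
        n_test_volumes=2, volume_slices=9,
        learning_rate=4e-3, epochs=34,
        restart_epoch=21, max_extensions=2,
        seeds=(base_seed % 2 ** 30, base_seed % 2 ** 30 + 1, base_seed % 2 ** 30 + 2),
    )


# --------------------------------------------------------------------------
# tensors
# --------------------------------------------------------------------------

def _image_tensor(slices, window: WindowSpec):
    """Window raw HU to [0,255] then scale to [0,1], shape (N,1,H,W)."""
    imgs = [preprocess_slice(s, window).image / window.out_max for s in slices]
    return np.stack(imgs)[:, None].astype(np.float32)


def _targets_for(setting, slices):
    """Head-name -> (N,1,H,W) target arrays for a batch of slices."""
    targets: dict[str, list] = {h[0]: [] for h in setting.heads}
    for s in slices:
        for organ in ORGANS:
            if organ in targets:
                targets[organ].append(s.masks[organ].astype(np.float32))
            cname = f"contour_{organ}"
            if cname in targets:
                targets[cname].append(contour_map(s.masks[organ]).astype(np.float32))
        if "distance" in targets:
            targets["distance"].append(distance_map(s.masks).astype(np.float32))
    return {k: np.stack(v)[:, None] for k, v in targets.items()}


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

def _seg_train_dice(model, setting, probe_x, probe_t):
    """Per-organ soft training Dice on a probe subset (dice_* terms only)."""
    rep = compute_loss(setting, model.net.forward(probe_x), probe_t)
    return {k: v for k, v in rep.per_term.items() if k.startswith("dice_")}


def train(setting_name: str, train_slices, config: ExperimentConfig, seed: int,
          val_slices=None, augment: bool | None = None):
    """Train one setting with Adam; returns (model, per-epoch loss log).

    ``augment=None`` infers augmentation from the ``_aug`` name suffix.
    Non-augmented training asserts that no rotated slice entered the
    stream (protocol purity); augmented training rotates each sample
    online by a uniform draw from the augmentation range.

    Soft-Dice optimization of tiny structures is bistable: a bad draw can
    leave a head saturated at an empty prediction. When
    ``config.restart_epoch`` is set, training restarts from a fresh
    derived init if a segmentation head is still below
    ``config.restart_dice`` there, and converging-but-slow heads earn
    extra epoch blocks (``max_extensions``). All randomness derives from
    ``seed``, so retraining with the same seed is bit-identical.
    """
    if augment is None:
        augment = setting_name.endswith("_aug")
    setting = get_setting(setting_name)
    if not augment:
        bad = [s for s in train_slices if s.angle_deg != 0.0]
        if bad:
            raise ValueError(f"{len(bad)} rotated slices in a non-augmented "
                             "training stream")
    n = len(train_slices)
    if n == 0:
        raise ValueError("empty training set")
    val_x = _image_tensor(val_slices, config.window) if val_slices else None
    val_t = _targets_for(setting, val_slices) if val_slices else None
    all_x = all_t = None
    if not augment:
        # fixed stream: build image/target tensors once
        all_x = _image_tensor(train_slices, config.window)
        all_t = _targets_for(setting, train_slices)
    # probe tensors for the stuck-basin checks (original, unaugmented slices)
    n_probe = min(n, 32)
    if augment:
        probe_x = _image_tensor(train_slices[:n_probe], config.window)
        probe_t = _targets_for(setting, train_slices[:n_probe])
    else:
        probe_x, probe_t = all_x[:n_probe], {k: v[:n_probe] for k, v in all_t.items()}

    def run_epochs(model, opt, rng, n_epochs, log, label):
        for _ in range(n_epochs):
            order = rng.permutation(n)
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, n, config.batch_size):
                idx = order[start:start + config.batch_size]
                if augment:
                    batch = [random_rotation_augment(train_slices[i], rng,
                                                     config.augment_range) for i in idx]
                    x = _image_tensor(batch, config.window)
                    targets = _targets_for(setting, batch)
                else:
                    x = all_x[idx]
                    targets = {k: v[idx] for k, v in all_t.items()}

                preds = model.net.forward(x)
                report, d_heads = compute_loss(setting, preds, targets, want_grad=True)
                if not np.isfinite(report.total):
                    raise FloatingPointError(
                        f"training diverged ({setting_name}, {label})")
                model.net.backward(d_heads, accumulate=False)
                opt.step()
                epoch_loss += report.total
                n_batches += 1
            row = {"epoch": len(log), "train_loss": epoch_loss / n_batches,
                   "phase": label}
            if val_x is not None:
                vr = compute_loss(setting, model.net.forward(val_x), val_t)
                row["val_loss"] = vr.total
            log.append(row)

    check_at = config.restart_epoch
    attempt = 0
    best = None   # (min seg dice, model, opt, rng, log) of failed attempts
    while True:
        log: list[dict] = []
        init_seed = seed + attempt * 77_003
        model = build_model(config.model, setting, seed=init_seed)
        opt = Adam(model.net, lr=config.learning_rate)
        rng = np.random.default_rng(init_seed + 10_000)
        label = f"attempt{attempt}"
        if check_at is None or check_at >= config.epochs:
            run_epochs(model, opt, rng, config.epochs, log, label)
            break
        run_epochs(model, opt, rng, check_at, log, label)
        dice = _seg_train_dice(model, setting, probe_x, probe_t)
        worst = min(dice.values())
        if all(v >= config.restart_dice for v in dice.values()):
            run_epochs(model, opt, rng, config.epochs - check_at, log, label)
            break
        if best is None or worst > best[0]:
            best = (worst, model, opt, rng, log)
        if attempt >= config.max_restarts:
            # no attempt escaped; resume the most promising one
            _, model, opt, rng, log = best
            run_epochs(model, opt, rng, config.epochs - check_at, log,
                       log[-1]["phase"])
            break
        attempt += 1
    for ext in range(config.max_extensions):
        dice = _seg_train_dice(model, setting, probe_x, probe_t)
        if all(v >= config.extend_below for v in dice.values()):
            break
        run_epochs(model, opt, rng, config.extend_epochs, log, f"extension{ext}")
    return model, log


# --------------------------------------------------------------------------
# prediction / evaluation helpers
# --------------------------------------------------------------------------

def predict_organ_masks(models: dict[str, SegModel], slices, config: ExperimentConfig,
                        chunk: int = 16) -> list[dict[str, np.ndarray]]:
    """Composite per-slice organ masks from one or several models."""
    x = _image_tensor(slices, config.window)
    out = [dict() for _ in slices]
    for model in models.values():
        seg_heads = model.setting.seg_heads
        for start in range(0, len(slices), chunk):
            preds = model.net.forward(x[start:start + chunk])
            for organ in seg_heads:
                prob = preds[organ][:, 0]
                for j in range(prob.shape[0]):
                    out[start + j][organ] = prob[j] >= config.threshold
    return out


def _group_models(group: str, trained: dict[str, SegModel]) -> dict[str, SegModel]:
    return {name: trained[name] for name in GROUPS[group]}


# --------------------------------------------------------------------------
# the study
# --------------------------------------------------------------------------

@dataclass
class StudyReport:
    records: pd.DataFrame                     # per case/organ/seed/group/phase
    loss_logs: dict = field(default_factory=dict)
    config: ExperimentConfig | None = None

    def summary(self, phase: str, metric: str = "dice") -> pd.DataFrame:
        """Per (group, organ): quartiles over finite values plus N(inf)."""
        sub = self.records[self.records.phase == phase]
        rows = []
        for (group, organ), g in sub.groupby(["group", "organ"]):
            s = summarize(g[metric].to_numpy())
            rows.append({"group": group, "organ": organ, "metric": metric,
                         "q1": s.q1, "median": s.median, "q3": s.q3,
                         "iqr": s.iqr, "mean": s.mean, "n": s.n, "n_inf": s.n_inf})
        return pd.DataFrame(rows)

    def median_dice(self, phase: str, group: str, organ: str, seed=None) -> float:
        sub = self.records[(self.records.phase == phase) & (self.records.group == group)
                           & (self.records.organ == organ)]
        if seed is not None:
            sub = sub[sub.seed == seed]
        return float(sub.dice.median())

    def n_inf_total(self, phase: str, group: str, seed=None) -> int:
        sub = self.records[(self.records.phase == phase) & (self.records.group == group)]
        if seed is not None:
            sub = sub[sub.seed == seed]
        return int(sub.is_inf.sum())

    def save(self, out_dir) -> None:
        import pathlib
        d = pathlib.Path(out_dir)
        d.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(d / "report.csv", index=False)
        summaries = {}
        for phase in self.records.phase.unique():
            for metric in ("dice", "max_hd", "hd95", "asd"):
                key = f"{phase}_{metric}"
                summaries[key] = self.summary(phase, metric).to_dict(orient="records")
        (d / "summary.json").write_text(json.dumps(summaries, indent=2, default=float))


def _records_df(records: list[MetricRecord], **cols) -> pd.DataFrame:
    df = records_to_frame(records)
    for k, v in cols.items():
        df[k] = v
    return df


def run_study(config: ExperimentConfig, progress=None) -> StudyReport:
    """Run the full comparison for every seed and aggregate a report."""
    frames, loss_logs = [], {}
    for seed in config.seeds:
        rng = np.random.default_rng(seed)
        sub = [int(s) for s in rng.integers(0, 2 ** 31 - 1, size=6)]
        train_set = generate_dataset(config.phantom, config.n_train, rotated=False,
                                     seed=sub[0])
        val_set = generate_dataset(config.phantom, config.n_val, rotated=False,
                                   seed=sub[1])
        test2d = generate_dataset(config.phantom, config.n_test_2d, rotated=True,
                                  seed=sub[2])
        vol_rng = np.random.default_rng(sub[3])
        volumes = []
        for v in range(config.n_test_volumes):
            mag = vol_rng.uniform(*config.volume_angle_range)
            angle = float(mag * vol_rng.choice([-1.0, 1.0]))
            volumes.append(generate_volume(config.phantom, config.volume_slices,
                                           angle_deg=angle, case_id=f"vol{v}",
                                           seed=sub[4] + v))

        trained: dict[str, SegModel] = {}
        for name in config.settings():
            if progress:
                progress(f"seed {seed}: training {name}")
            model, log = train(name, train_set, config, seed=seed, val_slices=None)
            trained[name] = model
            loss_logs[(seed, name)] = log

        for group in config.groups:
            models = _group_models(group, trained)
            # unrotated validation, 2D
            preds = predict_organ_masks(models, val_set, config)
            recs = []
            for s, p in zip(val_set, preds):
                recs.extend(evaluate_case(p, s.masks, case_id=s.case_id))
            frames.append(_records_df(recs, seed=seed, group=group, phase="val"))
            # rotated 2D test, no post-processing
            preds = predict_organ_masks(models, test2d, config)
            recs = []
            for s, p in zip(test2d, preds):
                recs.extend(evaluate_case(p, s.masks, case_id=s.case_id))
            frames.append(_records_df(recs, seed=seed, group=group, phase="test2d"))
            # rotated 3D volumes, largest-component post-processing
            recs = []
            for vol in volumes:
                slice_preds = predict_organ_masks(models, vol.slices, config)
                pred_vol = {o: largest_cc_3d(np.stack([sp[o] for sp in slice_preds]))
                            for o in ORGANS}
                truth_vol = {o: vol.mask_volume(o) for o in ORGANS}
                recs.extend(evaluate_case(pred_vol, truth_vol,
                                          case_id=f"s{seed}_{vol.slices[0].case_id}",
                                          spacing=vol.spacing))
            frames.append(_records_df(recs, seed=seed, group=group, phase="test3d"))

    records = pd.concat(frames, ignore_index=True)
    return StudyReport(records=records, loss_logs=loss_logs, config=config)


def dice_difference(report: StudyReport, group_a: str, group_b: str,
                    phase: str = "test2d") -> pd.DataFrame:
    """Per-case, per-organ Dice(a) - Dice(b), ordered by case id."""
    df = report.records
    cols = ["seed", "case_id", "organ"]
    a = df[(df.group == group_a) & (df.phase == phase)][cols + ["dice"]]
    b = df[(df.group == group_b) & (df.phase == phase)][cols + ["dice"]]
    merged = a.merge(b, on=cols, suffixes=("_a", "_b"), how="outer", indicator=True)
    if (merged["_merge"] != "both").any():
        raise ValueError("case sets differ between the two groups")
    merged["dice_diff"] = merged.dice_a - merged.dice_b
    return merged.sort_values(cols).reset_index(drop=True)[cols + ["dice_a", "dice_b",
                                                                   "dice_diff"]]
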
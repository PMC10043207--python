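"""End-to-end study driver: cohort -> labels -> CNN -> interpretability.

The full-scale protocol (0.01 ms steps, 2000 ms episodes, 100 training
epochs, 5 folds) is expensive; :func:`StudyConfig.scaled` carries the
package's scaled-down study conditions used by the test suite and the
acceptance script: 128 px disks at 0.3 mm, 0.1 ms steps, ablation at
400 ms into the episode, a 1000 ms episode limit, a ~112-disk cohort,
a 64 px model input and 40 training epochs with 3-fold rotation.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import ablation, epsim, interpret, model as M, stats_report, tissue


@dataclass
class StudyConfig:
    n_base: int = 65
    n_synthetic: int = 199
    cohort: tissue.CohortConfig = field(default_factory=tissue.CohortConfig)
    label: ablation.LabelConfig = field(default_factory=ablation.LabelConfig)
    spec: M.ModelSpec = field(default_factory=M.ModelSpec)
    train: M.TrainConfig = field(default_factory=M.TrainConfig)
    n_holdout: int = 50
    n_folds: int = 5
    interp: interpret.InterpretConfig = field(default_factory=interpret.InterpretConfig)
    n_interpret_disks: int = 50

    @classmethod
    def scaled(cls) -> "StudyConfig":
        """The package's reduced study conditions (see module docstring)."""
        return cls(
            n_base=38,
            n_synthetic=74,
            cohort=tissue.CohortConfig(size=128, threshold_range=(0.5, 0.7)),
            label=ablation.LabelConfig(dt=0.1, t_end=1000.0, lesion_time=400.0),
            spec=M.ModelSpec(input_size=64),
            train=M.TrainConfig(epochs=40, batch_size=16),
            n_holdout=28,
            n_folds=3,
            interp=interpret.InterpretConfig(lime_samples=150, gradcam_block=3),
            n_interpret_disks=8,
        )


def build_labelled_cohort(cfg: StudyConfig, seed: int):
    """Generate disks and simulate the three-strategy labels for each.

    Returns (disks, labels, outcomes, manifest); non-inducible disks are
    dropped from all four and flagged in the manifest.
    """
    disks_list, manifest = tissue.generate_cohort(
        cfg.n_base, cfg.n_synthetic, seed=seed, config=cfg.cohort)
    ids = manifest["id"].tolist()
    disks, labels, outcomes = {}, {}, {}
    status, y_cols = [], {k: [] for k in M.CLASS_NAMES}
    for disk_id, disk in zip(ids, disks_list):
        try:
            lab, outs = ablation.label_disk(disk, cfg.label)
        except ablation.NonInducibleError:
            status.append("non_inducible")
            for k in M.CLASS_NAMES:
                y_cols[k].append(np.nan)
            continue
        status.append("labelled")
        disks[disk_id] = disk
        labels[disk_id] = lab.y
        outcomes[disk_id] = outs
        for k, val in zip(M.CLASS_NAMES, lab.y):
            y_cols[k].append(float(val))
    manifest = manifest.copy()
    manifest["status"] = status
    for k in M.CLASS_NAMES:
        manifest[k] = y_cols[k]
    return disks, labels, outcomes, manifest


def train_and_evaluate(disks, labels, cfg: StudyConfig, seed: int):
    """Hold-out + fold-rotation training on the labelled cohort."""
    ids = list(disks.keys())
    X = np.stack([M.disk_to_image(disks[i], cfg.spec) for i in ids])
    y = np.stack([labels[i] for i in ids])
    split = M.make_split(ids, n_holdout=cfg.n_holdout, n_folds=cfg.n_folds,
                         seed=seed)
    train_cfg = replace(cfg.train, seed=seed)
    report, best = M.cross_validate(X, y, ids, split, cfg.spec, train_cfg)
    return report, best, split, (X, y, ids)


def shuffled_label_control(disks, labels, cfg: StudyConfig, seed: int,
                           split: M.DatasetSplit, n_controls: int = 3):
    """Label-shuffled controls with the real model's training budget.

    ``n_controls`` independent label permutations are each trained (single
    fold) and scored against the true hold-out labels; per-class AUCs are
    averaged, which estimates the chance level much more stably than a
    single shuffle.
    """
    ids = list(disks.keys())
    X = np.stack([M.disk_to_image(disks[i], cfg.spec) for i in ids])
    y = np.stack([labels[i] for i in ids])
    rng = np.random.default_rng(seed)
    index = {d: i for i, d in enumerate(ids)}
    ho = [index[d] for d in split.holdout_ids]
    val_ids = [index[d] for d in split.fold_ids(1)]
    tr_ids = [index[d] for d, f in split.cv_fold_assignment.items() if f != 1]
    reports = []
    for k in range(n_controls):
        perm = rng.permutation(len(y))
        y_shuf = y[perm]
        mdl, _ = M.train_fold(X[tr_ids], y_shuf[tr_ids], X[val_ids], y_shuf[val_ids],
                              cfg.spec, replace(cfg.train, seed=seed + k))
        reports.append(M.evaluate(mdl, X[ho], y[ho]))
    out = reports[0].copy()
    for col in ("auc", "recall", "precision", "f1"):
        out[col] = np.nanmean([r[col].to_numpy() for r in reports], axis=0)
    return out


def run_interpretability(best_model, disks, labels, outcomes, split,
                         cfg: StudyConfig, seed: int):
    """Attribution study on (a subset of) the hold-out disks."""
    ho = [d for d in split.holdout_ids if d in disks][: cfg.n_interpret_disks]
    sub_disks = {d: disks[d] for d in ho}
    sub_out = {d: outcomes[d] for d in ho}
    sub_lab = {d: labels[d] for d in ho}
    icfg = replace(cfg.interp, seed=seed)
    return interpret.run_interpretability_study(
        best_model, sub_disks, sub_out, sub_lab, icfg)


def run_study(cfg: StudyConfig, seed: int, out_dir=None, verbose: bool = False):
    """The whole pipeline; returns a dict of study artifacts."""
    ss = np.random.SeedSequence(seed)
    s_cohort, s_split, s_shuf, s_interp = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]

    t0 = time.time()
    disks, labels, outcomes, manifest = build_labelled_cohort(cfg, s_cohort)
    if verbose:
        print(f"[{time.time()-t0:6.0f}s] labelled {len(disks)} disks "
              f"({(manifest.status == 'non_inducible').sum()} non-inducible)")

    report, best, split, (X, y, ids) = train_and_evaluate(
        disks, labels, cfg, s_split)
    if verbose:
        print(f"[{time.time()-t0:6.0f}s] trained {cfg.n_folds} folds; "
              f"best fold {report.best_fold}")

    shuffled = shuffled_label_control(disks, labels, cfg, s_shuf, split)
    table, averages = run_interpretability(
        best, disks, labels, outcomes, split, cfg, s_interp)
    if verbose:
        print(f"[{time.time()-t0:6.0f}s] interpretability table "
              f"({len(table)} rows)")

    comps = pd.concat([
        stats_report.compare_methods(table, metric, strategy)
        for metric in ("iou", "lesion_pct", "nat_pct")
        for strategy in ("pvi", "fibro", "rotor")
    ], ignore_index=True)

    artifacts = dict(
        manifest=manifest, disks=disks, labels=labels, outcomes=outcomes,
        eval_report=report, best_model=best, split=split,
        shuffled_eval=shuffled, metrics_table=table, averages=averages,
        comparisons=comps,
    )
    if out_dir is not None:
        stats_report.build_report(
            out_dir, eval_report=report, metrics_table=table,
            comparisons=comps, averages=averages)
        manifest.to_csv(f"{out_dir}/cohort_manifest.csv", index=False)
    return artifacts


# ---------------------------------------------------------------------------
# solver calibration quantities (used by the acceptance script)


def cv_calibration(params: epsim.FKParams | None = None,
                   dx: float = 0.1, dt: float = 0.02) -> dict:
    """Healthy / fibrotic conduction velocities and their ratio on
    grid-converged calibration strips."""
    p = params or epsim.FKParams()
    cvh = epsim.measure_cv(p, D=p.D_healthy, dx=dx, dt=dt)
    cvf = epsim.measure_cv(p, D=p.D_fibrotic, dx=dx, dt=dt)
    return {"cv_healthy_m_per_s": cvh, "cv_fibrotic_m_per_s": cvf,
            "cv_ratio": cvf / cvh}


def rotor_induction_summary(t_end: float = 800.0, dt: float = 0.05) -> dict:
    """Cross-field induction on the homogeneous 100x100 sheet: longest
    continuous phase-singularity presence (ms)."""
    sheet = tissue.make_sheet((100, 100))
    res = epsim.run_crossfield(sheet, params=epsim.FKParams(), t_end=t_end,
                               dt=dt, snapshot_stride=2.0,
                               stop_on_termination=False)
    phase = ablation.compute_phase(res.snapshots)
    counts = np.array([len(ablation.detect_ps(phase[k]))
                       for k in range(phase.shape[0])])
    best = cur = 0
    for c in counts:
        cur = cur + 1 if c > 0 else 0
        best = max(best, cur)
    stride = float(res.trace_times[1] - res.trace_times[0])
    active = res.trace_times[res.max_u_trace >= 0.1]
    return {
        "ps_longest_presence_ms": best * stride,
        "active_until_ms": float(active.max()) if len(active) else 0.0,
    }
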
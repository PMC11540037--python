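"""Experiment presets: desk-scale replications of the three decoding
protocols, the control-loop ablation, and the end-to-end pipeline runner.

Each task builds its own trial inventory (a scaled-down version of the
standard protocol), simulates recordings, extracts the task's features and
trains/evaluates the task's classifier.  All stages are deterministic given
the task seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import classify, control as ctl, features as feat
from .panel import OdorantPanel
from .protocol import (ANTICORR_TRAIN, CORR_TRAIN, PULSE, Trial,
                       randomize_protocol)
from .sensor import NoiseConfig, default_sensor_array
from .simulate import SimulationConfig, simulate_protocol

CONC_LEVELS = (100.0, 80.0, 60.0, 40.0, 20.0)
TRAIN_FREQS = (2.0, 5.0, 10.0, 20.0, 40.0, 60.0)
PAIRWISE_REFERENCE_HZ = 20.0


def _spawn(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2 ** 31))


def _sim_config(experiment: str, **kw) -> SimulationConfig:
    return SimulationConfig(modes=ctl.experiment_modes(experiment), **kw)


# ---------------------------------------------------------------------------
# static task (k-NN vs concentration)
# ---------------------------------------------------------------------------

@dataclass
class StaticTaskConfig:
    seed: int = 0
    trials_per_class: int = 20          # 1 s pulses at 100% (4 odors + blank)
    trials_per_conc: int = 8            # per odor at each reduced concentration
    concentrations: tuple = CONC_LEVELS
    variants: tuple = ("normalized_cycled", "raw_cycled")
    window_starts_ms: tuple = tuple(range(500, 1000, 50))
    train_fraction: float = 0.6
    k: int = 5
    cv_folds: int = 5


def _static_trials(cfg: StaticTaskConfig, panel) -> list:
    trials = []
    for name in list(panel.odor_names) + [panel.blank_name]:
        trials += [Trial(PULSE, (name,), 1000, 100.0)] * cfg.trials_per_class
    for conc in cfg.concentrations:
        if conc == 100.0:
            continue
        for name in panel.odor_names:
            trials += [Trial(PULSE, (name,), 1000, conc)] * cfg.trials_per_conc
    return trials


def run_static_task(cfg: StaticTaskConfig = None) -> dict:
    """Concentration-robustness protocol.

    Trains a k-NN (k = 5, five-fold CV) on windows 500-1000 ms into 1 s
    full-concentration pulses (four odors + blank, 60/40 trial-level split)
    and tests on held-out trials at every concentration, blank omitted at
    test time.  Reported per feature variant: cycled sensors feed the raw
    and normalized variants.
    """
    cfg = StaticTaskConfig() if cfg is None else cfg
    panel = OdorantPanel.default()
    sim = _sim_config("B")
    rand = randomize_protocol(_static_trials(cfg, panel), _spawn(cfg.seed, 0))
    sensors_cycled = tuple(range(4, 8))
    sensors_const = tuple(range(0, 4))

    tables = {v: [] for v in cfg.variants}
    for tid, rec in enumerate(simulate_protocol(rand.trials, sim,
                                                _spawn(cfg.seed, 1))):
        for variant in cfg.variants:
            sens = sensors_const if variant.endswith("_const") else sensors_cycled
            tab = feat.windowed_features(rec, sens, variant,
                                         starts_rel_ms=cfg.window_starts_ms)
            tab["trial_id"] = tid
            tab["odor"] = rec.meta["odors"][0]
            tab["concentration"] = rec.meta["concentration"]
            tables[variant].append(tab)

    rng = np.random.default_rng(_spawn(cfg.seed, 2))
    report = {"task": "static_knn", "accuracy_by_concentration": {},
              "cv_scores": {}, "n_trials": len(rand.trials)}
    split = None
    for variant in cfg.variants:
        df = pd.concat(tables[variant], ignore_index=True)
        vcols = feat.feature_columns(df)
        full = df[df["concentration"] == 100.0]
        if split is None:
            split = _trial_split(full, rng, cfg.train_fraction)
        train_ids, test_ids = split
        tr = full[full["trial_id"].isin(train_ids)]
        result = classify.train_static_knn(tr[vcols].to_numpy(),
                                           tr["odor"].to_numpy(),
                                           k=cfg.k, folds=cfg.cv_folds)
        acc = {}
        for conc in cfg.concentrations:
            te = df[(df["concentration"] == conc) & (df["odor"] != "blank")]
            if conc == 100.0:
                te = te[te["trial_id"].isin(test_ids)]
            pred = result.model.predict(te[vcols].to_numpy())
            acc[conc] = float(np.mean(pred == te["odor"].to_numpy()))
        report["accuracy_by_concentration"][variant] = acc
        report["cv_scores"][variant] = result.cv_scores.tolist()
    report["train_trials"] = sorted(int(i) for i in split[0])
    report["test_trials"] = sorted(int(i) for i in split[1])
    return report


def _trial_split(df: pd.DataFrame, rng, train_fraction: float):
    """Trial-level stratified split: no trial contributes windows to both
    sides."""
    train_ids, test_ids = set(), set()
    for _, grp in df.groupby("odor"):
        ids = rng.permutation(sorted(grp["trial_id"].unique()))
        n_tr = int(round(train_fraction * ids.size))
        train_ids.update(ids[:n_tr])
        test_ids.update(ids[n_tr:])
    return train_ids, test_ids


# ---------------------------------------------------------------------------
# dynamic task (SVM ensemble, prediction over time)
# ---------------------------------------------------------------------------

@dataclass
class DynamicTaskConfig:
    seed: int = 0
    train_per_cell: int = 6             # trials per (odor, concentration)
    blank_trials: int = 12
    test_per_duration: int = 10         # per odor, durations below
    test_durations_ms: tuple = (50, 100, 200, 500, 1000)
    short_durations_ms: tuple = (10, 20)
    short_per_duration: int = 6
    concentrations: tuple = CONC_LEVELS
    svm_c: float = 1e3
    svm_gamma: float = 1e-4
    cv_folds: int = 5
    span_ms: float = 2000.0


def run_dynamic_task(cfg: DynamicTaskConfig = None) -> dict:
    """Time-resolved pulse classification.

    The SVM ensemble trains only on windows from 1 s pulses (five
    concentrations, blanks included; transition-straddling windows
    rejected), then predicts over time on pulses of 10-1000 ms at full
    concentration.  Per-duration accuracy, onset and offset latencies are
    reported.
    """
    cfg = DynamicTaskConfig() if cfg is None else cfg
    panel = OdorantPanel.default()
    sim = _sim_config("A")
    sensors = tuple(range(8))

    train_trials = []
    for conc in cfg.concentrations:
        for name in panel.odor_names:
            train_trials += [Trial(PULSE, (name,), 1000, conc)] * cfg.train_per_cell
    train_trials += [Trial(PULSE, (panel.blank_name,), 1000, 100.0)] * cfg.blank_trials
    test_trials = []
    for dur in cfg.test_durations_ms:
        for name in panel.odor_names:
            test_trials += [Trial(PULSE, (name,), dur, 100.0)] * cfg.test_per_duration
    for dur in cfg.short_durations_ms:
        for name in panel.odor_names:
            test_trials += [Trial(PULSE, (name,), dur, 100.0)] * cfg.short_per_duration

    rand_tr = randomize_protocol(train_trials, _spawn(cfg.seed, 0))
    rand_te = randomize_protocol(test_trials, _spawn(cfg.seed, 1))

    def _tables(trials, sim_seed):
        tabs = []
        for tid, rec in enumerate(simulate_protocol(trials, sim, sim_seed)):
            tab = feat.windowed_features(rec, sensors, "normalized_cycled",
                                         span_ms=cfg.span_ms)
            tab["trial_id"] = tid
            tab["true_odor"] = rec.meta["odors"][0]
            tab["duration_ms"] = rec.meta["duration_ms"]
            tabs.append(tab)
        return pd.concat(tabs, ignore_index=True)

    train_df = _tables(rand_tr.trials, _spawn(cfg.seed, 2))
    test_df = _tables(rand_te.trials, _spawn(cfg.seed, 3))

    vcols = feat.feature_columns(train_df)
    keep = train_df["label"] != feat.LABEL_REJECTED
    ensemble = classify.train_dynamic_svm(
        train_df.loc[keep, vcols].to_numpy(),
        train_df.loc[keep, "label"].to_numpy(),
        C=cfg.svm_c, gamma=cfg.svm_gamma, folds=cfg.cv_folds,
        seed=_spawn(cfg.seed, 4))

    raster = classify.predict_over_time(ensemble, test_df)
    scores = classify.score_raster(raster)
    metrics = classify.per_duration_metrics(scores)
    return {
        "task": "dynamic_svm",
        "per_duration": metrics.to_dict(orient="records"),
        "n_train_windows": int(keep.sum()),
        "n_test_trials": int(scores.shape[0]),
        "scores": scores,
        "raster_columns": [c for c in raster.columns
                           if c not in feat.feature_columns(raster)],
    }


# ---------------------------------------------------------------------------
# temporal task (spectral features + random-forest ensembles)
# ---------------------------------------------------------------------------

@dataclass
class TemporalTaskConfig:
    seed: int = 0
    pair: tuple = ("IA", "EB")
    frequencies: tuple = TRAIN_FREQS
    train_per_cell: int = 10            # per (frequency, correlation mode)
    test_per_cell: int = 6
    n_seed_repeats: int = 10
    n_trees: int = 100
    cv_folds: int = 10
    pre_s: float = 1.5
    post_s: float = 1.5


def _temporal_trials(cfg: TemporalTaskConfig, per_cell: int) -> list:
    trials = []
    for f in cfg.frequencies:
        trials += [Trial(ANTICORR_TRAIN, cfg.pair, 1000, 100.0, f)] * per_cell
        trials += [Trial(CORR_TRAIN, cfg.pair, 1000, 100.0, f)] * per_cell
    return trials


def _temporal_features(cfg: TemporalTaskConfig, experiment: str,
                       per_cell: int, seed: int) -> pd.DataFrame:
    sim = _sim_config(experiment, pre_s=cfg.pre_s, post_s=cfg.post_s)
    rand = randomize_protocol(_temporal_trials(cfg, per_cell), _spawn(seed, 0))
    rows = []
    for tid, rec in enumerate(simulate_protocol(rand.trials, sim,
                                                _spawn(seed, 1))):
        sf = feat.spectral_triplets(rec, sensors=(0, 1, 2, 3))
        rows.append({"trial_id": tid, "kind": rec.meta["kind"],
                     "frequency_hz": rec.meta["frequency_hz"],
                     **{f"v{j}": v for j, v in enumerate(sf.vector)}})
    return pd.DataFrame(rows)


def run_temporal_task(cfg: TemporalTaskConfig = None) -> dict:
    """Temporal-structure decoding on constant-temperature sensors.

    Training/validation recordings come from one session (sensors 1-4
    constant at 400 C), test recordings from an independent session, so no
    trial crosses the split.  Three tasks on the same 12-dim feature:
    multiclass modulation-frequency decoding, pairwise frequency vs the
    20 Hz reference, and correlated-vs-anticorrelated discrimination per
    frequency.  Accuracies are mean +/- SD over retrained ensembles.
    """
    cfg = TemporalTaskConfig() if cfg is None else cfg
    train = _temporal_features(cfg, "B", cfg.train_per_cell, _spawn(cfg.seed, 10))
    test = _temporal_features(cfg, "C", cfg.test_per_cell, _spawn(cfg.seed, 20))
    vcols = feat.feature_columns(train)

    def train_fn(X, y, seed):
        return classify.train_temporal_rdf(X, y, n_trees=cfg.n_trees,
                                           folds=cfg.cv_folds, seed=seed)

    def repeated(tr_df, te_df, column):
        return classify.repeated_accuracy(
            train_fn, tr_df[vcols].to_numpy(),
            tr_df[column].astype(str).to_numpy(),
            te_df[vcols].to_numpy(), te_df[column].astype(str).to_numpy(),
            n_seeds=cfg.n_seed_repeats, seed0=_spawn(cfg.seed, 30))

    report = {"task": "temporal_rdf", "pair": list(cfg.pair)}

    # (i) multiclass frequency decoding, scored per true frequency
    mean, sd, accs = repeated(train, test, "frequency_hz")
    per_freq = {}
    ens = train_fn(train[vcols].to_numpy(),
                   train["frequency_hz"].astype(str).to_numpy(),
                   seed=_spawn(cfg.seed, 31))
    pred = ens.predict(test[vcols].to_numpy())
    for f in cfg.frequencies:
        m = test["frequency_hz"] == f
        per_freq[f] = float(np.mean(pred[m.to_numpy()] == str(f)))
    report["frequency_multiclass"] = {"mean": mean, "sd": sd,
                                      "per_frequency": per_freq}

    # (ii) pairwise frequency vs the 20 Hz reference
    pairwise = {}
    for f in cfg.frequencies:
        if f == PAIRWISE_REFERENCE_HZ:
            continue
        tr = train[train["frequency_hz"].isin((f, PAIRWISE_REFERENCE_HZ))]
        te = test[test["frequency_hz"].isin((f, PAIRWISE_REFERENCE_HZ))]
        mean, sd, _ = repeated(tr, te, "frequency_hz")
        pairwise[f] = {"mean": mean, "sd": sd}
    report["frequency_pairwise_vs_20hz"] = pairwise

    # (iii) correlated vs anticorrelated, per frequency
    corr = {}
    for f in cfg.frequencies:
        tr = train[train["frequency_hz"] == f]
        te = test[test["frequency_hz"] == f]
        mean, sd, accs = repeated(tr, te, "kind")
        corr[f] = {"mean": mean, "sd": sd, "n_test": int(te.shape[0])}
    report["correlation_decoding"] = corr
    return report


# ---------------------------------------------------------------------------
# control-loop ablation
# ---------------------------------------------------------------------------

def run_control_ablation(seed: int = 0, duration_s: float = 6.0,
                         perturb: tuple = (2.0, 4.0),
                         airflow_step: float = 1.5) -> dict:
    """Open-loop vs open+closed-loop control under an airflow perturbation.

    Both runs share the heater, calibration and noise seed; the airflow
    factor steps up during the perturbation window.  Reports the mean
    absolute temperature error in the perturbed window and at the two
    plateaus.
    """
    sensors = default_sensor_array(n=4)
    modes = [ctl.HeaterMode(ctl.CYCLED)] * 4
    n = int(duration_s * 1000)
    airflow = np.ones(n)
    airflow[int(perturb[0] * 1000):int(perturb[1] * 1000)] = airflow_step
    cals = [ctl.run_calibration(p) for p in sensors]
    out = {}
    for label, closed in (("open_loop", False), ("closed_loop", True)):
        cfgc = ctl.ControllerConfig(closed_loop=closed)
        trace = ctl.simulate_hotplate(sensors, modes, n, airflow=airflow,
                                      config=cfgc, calibrations=cals,
                                      seed=seed)
        err = trace.t_true - trace.t_target
        win = slice(int(perturb[0] * 1000), int(perturb[1] * 1000))
        # ignore the intra-cycle transient: score the back half of each step
        settled = _settled_mask(trace.t_target[0], 1000)
        out[label] = {
            "mean_abs_error_perturbed": float(np.mean(np.abs(err[:, win][:, settled[win]]))),
            "mean_abs_error_overall": float(np.mean(np.abs(err[:, settled]))),
        }
    return out


def _settled_mask(target_row: np.ndarray, fs: int,
                  settle_ms: float = 15.0) -> np.ndarray:
    """True where the target has been constant for at least ``settle_ms``."""
    n = target_row.size
    k = int(settle_ms / 1000 * fs)
    changed = np.concatenate(([True], np.diff(target_row) != 0))
    mask = np.ones(n, dtype=bool)
    idx = np.nonzero(changed)[0]
    for i in idx:
        mask[i:i + k] = False
    return mask


# ---------------------------------------------------------------------------
# end-to-end runner
# ---------------------------------------------------------------------------

KNOWN_TASKS = ("static_odor_knn", "dynamic_odor_svm", "temporal_rdf",
               "control_ablation")


def run_pipeline(tasks=KNOWN_TASKS, seed: int = 0, scale: float = 1.0) -> dict:
    """Chain simulate -> extract -> train -> evaluate for the named tasks.

    ``scale`` multiplies the per-cell trial counts (minimum counts are
    enforced so stratified splits stay valid).  Unknown task names fail
    before any simulation starts.
    """
    unknown = [t for t in tasks if t not in KNOWN_TASKS]
    if unknown:
        raise ValueError(f"unknown task(s): {unknown}")
    report = {"seed": seed, "tasks": list(tasks)}
    if "static_odor_knn" in tasks:
        c = StaticTaskConfig(seed=seed)
        c = replace(c, trials_per_class=max(10, int(c.trials_per_class * scale)),
                    trials_per_conc=max(5, int(c.trials_per_conc * scale)))
        report["static_odor_knn"] = run_static_task(c)
    if "dynamic_odor_svm" in tasks:
        c = DynamicTaskConfig(seed=seed)
        c = replace(c, train_per_cell=max(2, int(c.train_per_cell * scale)),
                    test_per_duration=max(3, int(c.test_per_duration * scale)),
                    short_per_duration=max(3, int(c.short_per_duration * scale)),
                    blank_trials=max(10, int(c.blank_trials * scale)))
        rep = run_dynamic_task(c)
        rep = {k: v for k, v in rep.items() if k != "scores"}
        report["dynamic_odor_svm"] = rep
    if "temporal_rdf" in tasks:
        c = TemporalTaskConfig(seed=seed)
        c = replace(c, test_per_cell=max(3, int(c.test_per_cell * scale)))
        report["temporal_rdf"] = run_temporal_task(c)
    if "control_ablation" in tasks:
        report["control_ablation"] = run_control_ablation(seed=seed)
    return report
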
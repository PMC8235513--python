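"""Full calibration-transfer study: reference models, condition grid, reports.

The protocol, per master-slave device pair and repetition:

1. draw a balanced training set from the master (default 48 samples, 24 per
   class) and fit the PCA+LDA classifier there;
2. select master transfer samples by Kennard-Stone and slave transfer samples
   per scheme (standard / nonstandard / unlabeled KS), fit the transfer
   method;
3. build the evaluation classifier on the master training samples plus — for
   labeled schemes — the corrected slave transfer samples, and score every
   slave measurement *excluding* the slave transfer samples.

The master classifier evaluated on its own held-out data is the *reference*
to approach; evaluated on raw slave data it is the *threshold* to beat. The
calibration-extension method (CEM) baseline adds raw labeled slave transfer
rows to the master training set with no correction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import PCALDAClassifier, balanced_split, compute_metrics
from .preprocess import feature_values
from .selection import (
    ONE_CLASS,
    TWO_CLASS,
    draw_pool,
    select_master_transfer,
    select_nonstandard,
    select_standard,
    select_unlabeled,
)
from .simulate import SimConfig, simulate_study
from .transfer import (
    CORAL,
    DirectStandardization,
    PiecewiseDirectStandardization,
    PLSDACalibrationTransfer,
    PLSDAComponentRemoval,
    coral_lambda,
)

LABELED_METHODS = ("DS", "PDS", "PLSDA_CT", "CEM")
UNLABELED_METHODS = ("CORAL", "PLSDA_removal")
ALL_METHODS = LABELED_METHODS + UNLABELED_METHODS
UNLABELED = "unlabeled"


@dataclass
class ExperimentConfig:
    """Grid and protocol parameters of the study."""

    master_device: int = 1
    slave_devices: tuple = (2, 3)
    methods: tuple = ALL_METHODS
    n_transfer: tuple = (10, 20, 30, 40)
    sample_types: tuple = ("standard", "nonstandard")
    class_schemes: tuple = (TWO_CLASS, ONE_CLASS)
    pds_windows: tuple = (1, 3, 5, 7, 9, 11, 13)
    pds_n_lv: int = 2
    plsda_ct_lvs: tuple = (1, 2, 4, 8)
    removal_components: tuple = (1, 2, 3)
    coral_lambda_factors: tuple = (1e-4, 1e-2, 1.0, 1e2, 1e4)
    reps: int = 20
    train_size: int = 48
    n_pcs: int = 13
    nonstandard_pool_size: int = 20
    corrected_transfer_in_training: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown method(s): {sorted(unknown)}")
        if min(self.n_transfer, default=0) < 10:
            raise ValueError("n_transfer grid minimum is 10")
        for g in ("n_transfer", "slave_devices", "class_schemes"):
            if not getattr(self, g):
                raise ValueError(f"{g} must be nonempty")


@dataclass
class Condition:
    """One point of the experimental grid."""

    method: str
    slave: int
    n_transfer: int
    sample_type: str
    class_scheme: str
    hyper: float | None = None

    @property
    def key(self) -> str:
        h = "-" if self.hyper is None else f"{self.hyper:g}"
        return f"{self.method}|S{self.slave}|n{self.n_transfer}|{self.sample_type}|{self.class_scheme}|{h}"


def _condition_entropy(key: str) -> int:
    return int(hashlib.sha256(key.encode()).hexdigest()[:8], 16) % (2**31)


def _rep_rng(seed: int, cond_key: str, rep: int) -> np.random.Generator:
    return np.random.default_rng([seed % (2**31), _condition_entropy(cond_key), rep])


def iter_conditions(config: ExperimentConfig) -> list[Condition]:
    """Cartesian grid of all configured conditions."""
    conds = []
    for method in config.methods:
        if method in LABELED_METHODS:
            types = config.sample_types
        else:
            types = (UNLABELED,)
        if method == "PDS":
            hypers = config.pds_windows
        elif method == "PLSDA_CT":
            hypers = config.plsda_ct_lvs
        elif method == "PLSDA_removal":
            hypers = config.removal_components
        elif method == "CORAL":
            hypers = config.coral_lambda_factors
        else:
            hypers = (None,)
        for slave in config.slave_devices:
            for nt in config.n_transfer:
                for st in types:
                    for scheme in config.class_schemes:
                        for h in hypers:
                            conds.append(Condition(method, slave, nt, st, scheme, h))
    return conds


def _check_compatible(cond: Condition) -> None:
    if cond.method in LABELED_METHODS and cond.sample_type not in ("standard", "nonstandard"):
        raise ValueError(f"{cond.method} requires labeled (standard/nonstandard) transfer samples")
    if cond.method in UNLABELED_METHODS and cond.sample_type != UNLABELED:
        raise ValueError(f"{cond.method} uses unlabeled transfer samples only")


def _master_transfer(cond, master_df, train_df):
    """Master-side transfer rows: KS within the training subset (two-class,
    per class, interleaved) or over all master no-meal rows (one-class, where
    the balanced training subset is too small to supply up to 40)."""
    if cond.class_scheme == TWO_CLASS:
        return select_master_transfer(train_df, cond.n_transfer, TWO_CLASS)
    return select_master_transfer(master_df, cond.n_transfer, ONE_CLASS)


def _evaluate_rep(cond: Condition, master_df, slave_df, config, rng):
    X_master = feature_values(master_df)
    y_master = master_df["class"].to_numpy()
    train_pos, _ = balanced_split(master_df, config.train_size // 2, rng)
    train_df = master_df.iloc[train_pos]
    Xtr_m = X_master[train_pos]
    ytr_m = y_master[train_pos]
    n_pcs = config.n_pcs

    if cond.method in LABELED_METHODS:
        m_transfer = _master_transfer(cond, master_df, train_df)
        if cond.sample_type == "standard":
            ts = select_standard(m_transfer, slave_df, cond.class_scheme)
        else:
            pool = draw_pool(
                slave_df,
                max(config.nonstandard_pool_size, cond.n_transfer),
                cond.class_scheme,
                rng,
            )
            ts = select_nonstandard(m_transfer, pool, cond.class_scheme)
        transfer_ids = set(ts.slave_ids)
    else:
        s_transfer = select_unlabeled(slave_df, cond.n_transfer, cond.class_scheme)
        transfer_ids = set(s_transfer["sample_id"])

    test_df = slave_df[~slave_df["sample_id"].isin(transfer_ids)]
    assert not (set(test_df["sample_id"]) & transfer_ids), "slave transfer rows leaked into the test set"
    Xtest = feature_values(test_df)
    ytest = test_df["class"].to_numpy()

    if cond.method == "CEM":
        Xtr = np.vstack([Xtr_m, ts.Xs])
        ytr = np.concatenate([ytr_m, ts.labels])
        clf = PCALDAClassifier(n_components=n_pcs).fit(Xtr, ytr)
        scores = clf.decision_function(Xtest)
    elif cond.method in ("DS", "PDS"):
        if cond.method == "DS":
            t = DirectStandardization().fit(ts.Xs, ts.Xm)
        else:
            t = PiecewiseDirectStandardization(
                window=int(cond.hyper), n_components=config.pds_n_lv
            ).fit(ts.Xs, ts.Xm)
        extra = t.transform(ts.Xs) if config.corrected_transfer_in_training else ts.Xs
        Xtr = np.vstack([Xtr_m, extra])
        ytr = np.concatenate([ytr_m, ts.labels])
        clf = PCALDAClassifier(n_components=n_pcs).fit(Xtr, ytr)
        scores = clf.decision_function(t.transform(Xtest))
    elif cond.method == "PLSDA_CT":
        c = int(cond.hyper)
        t = PLSDACalibrationTransfer(n_components=c).fit(
            Xtr_m, ytr_m, Xm_ct=ts.Xm, Xs_ct=ts.Xs
        )
        Ttr = np.vstack([t.project_master(Xtr_m), t.transform(ts.Xs)])
        ytr = np.concatenate([ytr_m, ts.labels])
        clf = PCALDAClassifier(n_components=c).fit(Ttr, ytr)
        scores = clf.decision_function(t.transform(Xtest))
    elif cond.method == "CORAL":
        Xs_ct = feature_values(s_transfer)
        lam = coral_lambda(Xtr_m, cond.hyper)
        t = CORAL(lam=lam).fit(Xtr_m, Xs_ct)
        clf = PCALDAClassifier(n_components=n_pcs).fit(t.transform(Xtr_m), ytr_m)
        scores = clf.decision_function(Xtest)
    elif cond.method == "PLSDA_removal":
        m_transfer = _master_transfer(cond, master_df, train_df)
        Xs_ct = feature_values(s_transfer)
        rem = PLSDAComponentRemoval.from_blocks(
            feature_values(m_transfer), Xs_ct, n_components=int(cond.hyper)
        )
        clf = PCALDAClassifier(n_components=n_pcs).fit(rem.transform(Xtr_m), ytr_m)
        scores = clf.decision_function(rem.transform(Xtest))
    else:  # pragma: no cover
        raise ValueError(f"unknown method {cond.method!r}")
    return compute_metrics(scores, ytest)


def evaluate_condition(
    cond: Condition,
    datasets: dict[int, pd.DataFrame],
    config: ExperimentConfig,
) -> dict:
    """Run all repetitions of one condition; returns one tidy record."""
    _check_compatible(cond)
    master_df = datasets[config.master_device]
    slave_df = datasets[cond.slave]
    metrics = []
    for rep in range(config.reps):
        rng = _rep_rng(config.seed, cond.key, rep)
        metrics.append(_evaluate_rep(cond, master_df, slave_df, config, rng))
    aucs = np.array([m.auc for m in metrics])
    return {
        "method": cond.method,
        "slave_device": cond.slave,
        "n_transfer": cond.n_transfer,
        "sample_type": cond.sample_type,
        "class_scheme": cond.class_scheme,
        "hyper": np.nan if cond.hyper is None else float(cond.hyper),
        "auc": aucs.mean(),
        "se": aucs.std(ddof=1) / np.sqrt(len(aucs)) if len(aucs) > 1 else 0.0,
        "accuracy": np.mean([m.accuracy for m in metrics]),
        "sensitivity": np.mean([m.sensitivity for m in metrics]),
        "specificity": np.mean([m.specificity for m in metrics]),
        "reps": config.reps,
        "condition": cond.key,
    }


def reference_table(
    datasets: dict[int, pd.DataFrame],
    n_pcs: int = 13,
    reps: int = 20,
    train_size: int = 48,
    seed: int = 0,
) -> pd.DataFrame:
    """Before-transfer reference and threshold models.

    Same-device pairs train on a balanced subset and test on the remainder;
    cross-device pairs train on the master and test on the slave's full
    table. AUC/SE over ``reps`` repeated random balanced splits.
    """
    if len(datasets) < 2:
        raise ValueError("need the master and at least one slave device dataset")
    devices = sorted(datasets)
    master = devices[0]
    pairs = [(d, d) for d in devices] + [(master, d) for d in devices if d != master]
    rows = []
    for train_dev, test_dev in pairs:
        if train_dev not in datasets or test_dev not in datasets:
            raise ValueError(f"device {train_dev} or {test_dev} missing from datasets")
        key = f"ref|{train_dev}|{test_dev}"
        metrics = []
        for rep in range(reps):
            rng = _rep_rng(seed, key, rep)
            df = datasets[train_dev]
            X = feature_values(df)
            y = df["class"].to_numpy()
            train, rest = balanced_split(df, train_size // 2, rng)
            clf = PCALDAClassifier(n_components=n_pcs).fit(X[train], y[train])
            if train_dev == test_dev:
                Xt, yt = X[rest], y[rest]
            else:
                tdf = datasets[test_dev]
                Xt, yt = feature_values(tdf), tdf["class"].to_numpy()
            metrics.append(compute_metrics(clf.decision_function(Xt), yt))
        aucs = np.array([m.auc for m in metrics])
        rows.append(
            {
                "pair": ("M{}-M{}" if train_dev == test_dev and train_dev == master
                         else "S{}-S{}" if train_dev == test_dev
                         else "M{}-S{}").format(train_dev, test_dev),
                "train_device": train_dev,
                "test_device": test_dev,
                "auc": aucs.mean(),
                "se": aucs.std(ddof=1) / np.sqrt(len(aucs)) if len(aucs) > 1 else 0.0,
                "accuracy": np.mean([m.accuracy for m in metrics]),
                "sensitivity": np.mean([m.sensitivity for m in metrics]),
                "specificity": np.mean([m.specificity for m in metrics]),
                "n_pcs": n_pcs,
                "reps": reps,
            }
        )
    return pd.DataFrame(rows)


def run_full_experiment(
    config: ExperimentConfig,
    datasets: dict[int, pd.DataFrame] | None = None,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate the full condition grid; returns (results, reference) tables.

    With ``out_dir`` set, writes ``results.csv``, ``reference.csv`` and a run
    log, and *resumes*: conditions whose key is already present in an
    existing ``results.csv`` written with the same seed are not recomputed.
    """
    if datasets is None:
        datasets = simulate_study(SimConfig(seed=config.seed))
    ref = reference_table(
        datasets, n_pcs=config.n_pcs, reps=config.reps,
        train_size=config.train_size, seed=config.seed,
    )
    conditions = iter_conditions(config)
    done: dict[str, dict] = {}
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        prev = out_path / "results.csv"
        log = out_path / "run_log.json"
        if prev.exists() and log.exists():
            old_log = json.loads(log.read_text())
            if old_log.get("seed") == config.seed:
                old = pd.read_csv(prev)
                done = {r["condition"]: r for r in old.to_dict("records")}
    rows = []
    for cond in conditions:
        if cond.key in done:
            rows.append(done[cond.key])
        else:
            rows.append(evaluate_condition(cond, datasets, config))
    results = pd.DataFrame(rows)
    if out_path is not None:
        results.to_csv(out_path / "results.csv", index=False)
        ref.to_csv(out_path / "reference.csv", index=False)
        cfg = asdict(config)
        (out_path / "run_log.json").write_text(
            json.dumps({"seed": config.seed, "config": cfg,
                        "n_conditions": len(conditions)}, default=str, indent=1)
        )
    return results, ref


def plot_results(
    results: pd.DataFrame,
    reference: pd.DataFrame,
    out_dir: str | Path,
    master_device: int = 1,
) -> list[Path]:
    """AUC vs number of transfer samples, one figure per method/slave pair.

    Horizontal lines mark the master reference (same-device AUC) and the
    before-transfer threshold (master model on raw slave data).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    ref_auc = reference.query(
        "train_device == @master_device and test_device == @master_device"
    )["auc"].iloc[0]
    for (method, slave), g in results.groupby(["method", "slave_device"]):
        thr = reference.query(
            "train_device == @master_device and test_device == @slave"
        )["auc"].iloc[0]
        fig, ax = plt.subplots(figsize=(7, 4.5))
        for (st, scheme, hyper), gg in g.groupby(["sample_type", "class_scheme", "hyper"], dropna=False):
            gg = gg.sort_values("n_transfer")
            label = f"{st}/{scheme}" + ("" if pd.isna(hyper) else f" h={hyper:g}")
            ax.errorbar(gg["n_transfer"], gg["auc"], yerr=gg["se"], marker="o", label=label)
        ax.axhline(ref_auc, color="k", ls="--", label="master reference")
        ax.axhline(thr, color="r", ls=":", label="before-CT threshold")
        ax.set_xlabel("transfer samples")
        ax.set_ylabel("AUC")
        ax.set_title(f"{method}, slave device {slave}")
        ax.legend(fontsize=7, ncol=2)
        path = out / f"{method}_S{slave}.png"
        fig.tight_layout()
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)
    return written
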
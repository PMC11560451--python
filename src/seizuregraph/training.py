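"""Optimization: loss, class-balanced epochs, Adam, and the two protocols.

The loss is binary cross-entropy on the ictal-class probability. The l2
penalty on all parameters is realized through the optimizer's decoupled
weight decay (default 1e-3); an explicit ``tau``-weighted global l2-norm
term can be added to the loss instead for exactness (see TrainConfig.tau)
— the two are not applied together by default to avoid double
regularization.

Class imbalance is handled twice, as in the evaluation protocols this
package follows: the interictal pool is first capped at 5:1 against ictal
(``preprocess.rebalance_pool``); then every epoch draws a fresh balanced
subset — all ictal training segments plus an equal number of randomly drawn
interictal ones.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .data import EEGRecording, SegmentSet
from .manifest import stage_seed
from .metrics import MetricReport, evaluate_probs, metrics_table
from .model import ModelConfig, MultiBranchGCN
from .nn import Parameter
from .preprocess import make_splits, prepare_recording, rebalance_pool


@dataclass
class TrainConfig:
    lr: float = 3e-4
    weight_decay: float = 1e-3
    tau: float = 0.0  # explicit global l2-norm weight; 0 = decay-only
    epochs: int = 100
    batch_size: int = 64
    seed: int = 0
    early_stop_patience: int = 10
    mode: str = "patient_specific"
    # Sum the binary cross-entropy over both sigmoid output units (one-hot
    # targets) instead of the ictal unit alone. With single-unit CE the
    # interictal output unit receives no gradient and stays an untrained
    # random projection, which injects noise into argmax decisions.
    two_unit_ce: bool = True

    def __post_init__(self) -> None:
        if self.lr <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("lr, epochs and batch_size must be positive")
        if self.mode not in ("patient_specific", "patient_independent"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def to_dict(self) -> dict:
        return asdict(self)


def bce_loss(
    probs: Tensor,
    labels: np.ndarray,
    tau: float = 0.0,
    params: list[Parameter] | None = None,
    two_unit: bool = False,
) -> Tensor:
    """Mean binary cross-entropy on the positive-class (ictal) probability.

    Probabilities are clamped to [1e-7, 1 - 1e-7] so log never sees 0. With
    ``two_unit`` the same form is summed over both output units against
    one-hot targets (so the interictal unit is trained too). With
    ``tau > 0`` the global l2-norm of all parameters is added.
    """
    y = np.asarray(labels, dtype=np.float64)
    p1 = probs[:, 1].clip(1e-7, 1.0 - 1e-7)
    ce = -(Tensor(y) * p1.log() + Tensor(1.0 - y) * (1.0 - p1).log()).mean()
    if two_unit:
        p0 = probs[:, 0].clip(1e-7, 1.0 - 1e-7)
        ce = ce - (
            Tensor(1.0 - y) * p0.log() + Tensor(y) * (1.0 - p0).log()
        ).mean()
    if tau and params:
        sq = None
        for p in params:
            term = (p**2).sum()
            sq = term if sq is None else sq + term
        ce = ce + tau * sq**0.5
    return ce


def balanced_epoch_subset(labels: np.ndarray, seed: int) -> np.ndarray:
    """Positions of a class-balanced epoch subset of ``labels``.

    All ictal positions are kept; an equal number of interictal positions is
    drawn uniformly without replacement; the concatenation is shuffled.
    """
    y = np.asarray(labels, dtype=int)
    ictal = np.flatnonzero(y == 1)
    inter = np.flatnonzero(y == 0)
    if len(ictal) == 0 or len(inter) == 0:
        raise ValueError("both classes must be present for balanced resampling")
    rng = np.random.default_rng(seed)
    take = min(len(ictal), len(inter))
    drawn = rng.choice(inter, size=take, replace=False)
    subset = np.concatenate([ictal, drawn])
    rng.shuffle(subset)
    return subset


class Adam:
    """Adam with decoupled weight decay (the l2 penalty of the loss)."""

    def __init__(self, params: list[Parameter], lr: float = 3e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-3):
        self.params = params
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                g = np.zeros_like(p.data)
            else:
                g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


@dataclass
class FitResult:
    history: pd.DataFrame
    best_epoch: int
    best_val_loss: float
    balance_audit: list[tuple[int, int]] = field(default_factory=list)


def _eval_loss(model: MultiBranchGCN, x: np.ndarray, y: np.ndarray,
               batch_size: int, two_unit: bool = False) -> tuple[float, float]:
    probs = model.predict_proba(x, batch_size)
    p1 = np.clip(probs[:, 1], 1e-7, 1 - 1e-7)
    loss = float(-(y * np.log(p1) + (1 - y) * np.log(1 - p1)).mean())
    if two_unit:
        p0 = np.clip(probs[:, 0], 1e-7, 1 - 1e-7)
        loss += float(-((1 - y) * np.log(p0) + y * np.log(1 - p0)).mean())
    acc = float((np.argmax(probs, axis=1) == y).mean())
    return loss, acc


def fit(
    model: MultiBranchGCN,
    segs: SegmentSet,
    split: tuple[np.ndarray, np.ndarray, np.ndarray],
    tcfg: TrainConfig,
    verbose: bool = False,
) -> FitResult:
    """Train on one (train, val, test) split with early stopping.

    Every epoch draws a fresh balanced subset of the training indices
    (seeded per epoch off ``tcfg.seed``); validation loss is monitored and
    the best-epoch weights (including BN running statistics) are restored
    at the end. Raises on divergence (non-finite loss).
    """
    train_idx, val_idx, _ = (np.asarray(s) for s in split)
    x_train = segs.segments[train_idx]
    y_train = segs.labels[train_idx]
    x_val = segs.segments[val_idx]
    y_val = segs.labels[val_idx]

    opt = Adam(model.parameters(), lr=tcfg.lr, weight_decay=tcfg.weight_decay)
    rows = []
    balance_audit = []
    best_state, best_loss, best_epoch, bad = None, np.inf, -1, 0
    for epoch in range(tcfg.epochs):
        sub = balanced_epoch_subset(
            y_train, stage_seed(tcfg.seed, f"epoch-{epoch}")
        )
        balance_audit.append(
            (int((y_train[sub] == 0).sum()), int((y_train[sub] == 1).sum()))
        )
        model.train()
        t0 = time.perf_counter()
        losses = []
        for i in range(0, len(sub), tcfg.batch_size):
            batch = sub[i : i + tcfg.batch_size]
            probs = model(x_train[batch])
            loss = bce_loss(
                probs, y_train[batch], tcfg.tau, model.parameters(),
                two_unit=tcfg.two_unit_ce,
            )
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"training diverged: loss={loss.item()} at epoch {epoch}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        val_loss, val_acc = _eval_loss(
            model, x_val, y_val, tcfg.batch_size, two_unit=tcfg.two_unit_ce
        )
        rows.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "val_loss": val_loss,
                "val_acc": val_acc,
                "seconds": time.perf_counter() - t0,
            }
        )
        if verbose:
            print(
                f"epoch {epoch:3d}  train {rows[-1]['train_loss']:.4f}  "
                f"val {val_loss:.4f}  acc {val_acc:.3f}"
            )
        if val_loss < best_loss - 1e-6:
            best_loss, best_epoch, bad = val_loss, epoch, 0
            best_state = model.state_dict()
        else:
            bad += 1
            if bad >= tcfg.early_stop_patience:
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    return FitResult(pd.DataFrame(rows), best_epoch, best_loss, balance_audit)


def evaluate(
    model: MultiBranchGCN, segs: SegmentSet, idx: np.ndarray
) -> MetricReport:
    """Eval-mode metric report on the indexed segments."""
    idx = np.asarray(idx)
    probs = model.predict_proba(segs.segments[idx])
    return evaluate_probs(segs.labels[idx], probs)


ABLATION_VARIANTS: dict[str, dict] = {
    "full": {},
    "h1": {"branch_connectivity": False, "branch_adaptive": False},
    "h2": {"branch_distance": False, "branch_adaptive": False},
    "h3": {"branch_distance": False, "branch_connectivity": False},
    "no_attention": {"attention": False},
}


def protocol_on_segments(
    segs: SegmentSet,
    mode: str,
    model_cfg: ModelConfig,
    tcfg: TrainConfig,
    folds: list[int] | None = None,
    n_folds: int = 5,
    out_dir=None,
    layout=None,
    train_rebalance_ratio: float | None = None,
    verbose: bool = False,
) -> tuple[pd.DataFrame, list[MetricReport]]:
    """Split -> fit -> evaluate on an already-prepared segment set.

    Each fold trains a freshly initialized model (seed derived per fold
    from ``tcfg.seed``) and evaluates on its test indices. With ``out_dir``
    set, per-fold checkpoints and history CSVs are written there.
    ``train_rebalance_ratio`` caps the interictal:ictal ratio of each
    fold's *training* indices after splitting — the alternative to capping
    the whole pool before splitting (see ``prepare_cohort``).
    """
    from pathlib import Path

    from .model import save_checkpoint

    splits = make_splits(segs, mode, n_folds=n_folds, seed=tcfg.seed)
    chosen = range(len(splits)) if folds is None else folds
    reports, cases = [], []
    for i in chosen:
        split = splits[i]
        if train_rebalance_ratio is not None:
            train = split[0]
            y = segs.labels[train]
            ictal = train[y == 1]
            inter = train[y == 0]
            cap = min(len(inter), int(train_rebalance_ratio * len(ictal)))
            rng = np.random.default_rng(stage_seed(tcfg.seed, f"fold-rebalance-{i}"))
            inter = np.sort(rng.choice(inter, size=cap, replace=False))
            split = (np.sort(np.concatenate([ictal, inter])), split[1], split[2])
        model = MultiBranchGCN(
            ModelConfig.from_dict(
                {**model_cfg.to_dict(), "seed": stage_seed(tcfg.seed, f"init-{i}")}
            ),
            layout=layout,
        )
        result = fit(model, segs, split, tcfg, verbose=verbose)
        reports.append(evaluate(model, segs, split[2]))
        if mode == "patient_independent":
            cases.append(str(segs.patient_ids[split[2][0]]))
        else:
            cases.append(f"fold{i}")
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            save_checkpoint(model, out / f"checkpoint_{cases[-1]}.npz")
            result.history.to_csv(out / f"history_{cases[-1]}.csv", index=False)
    return metrics_table(reports, cases), reports


def prepare_cohort(
    cohort: list[EEGRecording],
    mode: str,
    interictal_to_ictal: float | None = 5.0,
    seed: int = 0,
) -> SegmentSet:
    """Preprocess and rebalance a cohort for one protocol.

    Patient-specific rebalances the (single) recording's pool directly;
    patient-independent merges all subjects first, then rebalances.
    ``interictal_to_ictal=None`` skips pool rebalancing entirely (use
    ``protocol_on_segments(train_rebalance_ratio=...)`` to cap per fold
    after splitting instead).
    """
    seg_sets = []
    for rec in cohort:
        s = prepare_recording(rec)
        if mode == "patient_specific" and interictal_to_ictal is not None:
            s = rebalance_pool(
                s, interictal_to_ictal, stage_seed(seed, f"rebalance-{rec.patient_id}")
            )
        seg_sets.append(s)
    if mode == "patient_independent":
        merged = SegmentSet.concatenate(seg_sets)
        if interictal_to_ictal is None:
            return merged
        return rebalance_pool(merged, interictal_to_ictal, stage_seed(seed, "rebalance"))
    if len(cohort) != 1:
        raise ValueError("patient_specific protocol expects a single recording")
    return seg_sets[0]


def run_protocol(
    cohort: list[EEGRecording],
    mode: str,
    model_cfg: ModelConfig,
    tcfg: TrainConfig,
    interictal_to_ictal: float = 5.0,
    folds: list[int] | None = None,
    n_folds: int = 5,
    out_dir=None,
    rebalance_stage: str = "pool",
    verbose: bool = False,
) -> tuple[pd.DataFrame, list[MetricReport]]:
    """Preprocess -> split -> fit -> evaluate for either protocol.

    ``patient_specific`` runs stratified ``n_folds``-fold on a single
    recording; ``patient_independent`` runs leave-one-subject-out over the
    cohort. Returns the per-fold + mean percentage table and the raw
    per-fold reports. ``folds`` restricts to a subset of fold indices.
    ``rebalance_stage`` selects where the 5:1 interictal cap is applied:
    ``"pool"`` before splitting (default) or ``"per_fold"`` on each fold's
    training indices after splitting.
    """
    if rebalance_stage not in ("pool", "per_fold"):
        raise ValueError(f"unknown rebalance_stage {rebalance_stage!r}")
    per_fold = rebalance_stage == "per_fold"
    merged = prepare_cohort(
        cohort, mode, None if per_fold else interictal_to_ictal, tcfg.seed
    )
    return protocol_on_segments(
        merged, mode, model_cfg, tcfg, folds=folds, n_folds=n_folds,
        out_dir=out_dir, verbose=verbose,
        train_rebalance_ratio=interictal_to_ictal if per_fold else None,
    )


def ablation_on_segments(
    segs: SegmentSet,
    mode: str,
    model_cfg: ModelConfig,
    tcfg: TrainConfig,
    variants: list[str] | None = None,
    folds: list[int] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Run the configuration-switch ablation grid; one row per variant."""
    rows = []
    for name in variants or list(ABLATION_VARIANTS):
        cfg = ModelConfig.from_dict({**model_cfg.to_dict(), **ABLATION_VARIANTS[name]})
        table, _ = protocol_on_segments(segs, mode, cfg, tcfg, folds=folds, **kwargs)
        mean = table[table["case"] == "Mean"].iloc[0]
        rows.append({"variant": name, **mean.drop("case").to_dict()})
    return pd.DataFrame(rows)


def run_ablation(
    cohort: list[EEGRecording],
    mode: str,
    model_cfg: ModelConfig,
    tcfg: TrainConfig,
    variants: list[str] | None = None,
    folds: list[int] | None = None,
    interictal_to_ictal: float = 5.0,
    **kwargs,
) -> pd.DataFrame:
    """Ablation grid starting from raw recordings (preprocesses once)."""
    merged = prepare_cohort(cohort, mode, interictal_to_ictal, tcfg.seed)
    return ablation_on_segments(
        merged, mode, model_cfg, tcfg, variants=variants, folds=folds, **kwargs
    )
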
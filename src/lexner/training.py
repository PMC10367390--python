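"""Joint dual-branch optimisation and confidence-filtered self-training.

The global training objective is the weighted sum of the two branch losses,

    Loss = alpha * Loss_B + beta * Loss_F,

optionally augmented by FGM adversarial perturbation of the character
embedding table.  Self-training alternates supervised fitting with
pseudo-labelling of an unlabeled pool; pseudo-labelled sentences enter the
loss through the interpolation

    Loss = (1 - theta) * Loss_LD + theta * Loss_ULD,

where LD is the labeled set and ULD the admitted pseudo-labelled pool.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam
from .corpus_io import LabeledSentence

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 16
    lr_encoder: float = 1e-3
    lr_heads: float = 1e-2
    alpha: float = 1.0            # boundary-branch weight
    beta: float = 1.0             # type-branch weight
    seed: int = 0
    fgm_enabled: bool = False
    fgm_epsilon: float = 0.5
    grad_clip: float = 2.0
    weight_decay: float = 0.01
    grad_accum_steps: int = 1
    dev_fraction: float = 0.1     # carved from train when no dev set given
    # A-Softmax margin anneal: lam decays lam_start -> lam_min over steps
    lam_start: float = 1000.0
    lam_min: float = 5.0
    lam_decay: float = 0.2


@dataclass
class SelfTrainConfig:
    tau: float = 0.9              # confidence threshold for admission
    theta: float = 0.3            # unlabeled-loss weight in the mixed loss
    max_rounds: int = 3
    per_round_cap: float = 0.2    # fraction of |U| admissible per round
    round_epochs: int = 8         # additional epochs per self-training round

    def __post_init__(self):
        if not 0.0 < self.tau <= 1.0:
            raise ValueError("tau must be in (0, 1]")
        if not 0.0 <= self.theta < 1.0:
            raise ValueError("theta must be in [0, 1)")


@dataclass
class FitResults:
    """Outcome of a fit: history, best checkpoint and a summary table."""

    model: object
    history: list = field(default_factory=list)
    rounds: list = field(default_factory=list)
    best_f1: float = 0.0
    best_epoch: int = -1
    elapsed: float = 0.0

    def summary(self) -> str:
        lines = ["Dual-branch NER fit", "=" * 46,
                 f"{'epoch':>6} {'loss_B':>9} {'loss_F':>9} {'dev F1':>8}"]
        for h in self.history:
            lines.append(f"{h['epoch']:>6} {h['loss_B']:>9.4f} "
                         f"{h['loss_F']:>9.4f} {h['dev_f1']:>8.4f}")
        lines.append("-" * 46)
        lines.append(f"best dev F1 {self.best_f1:.4f} at epoch {self.best_epoch}"
                     f"  ({self.elapsed:.1f}s)")
        for r in self.rounds:
            lines.append(f"round {r['round']}: selected {r['selected']}, "
                         f"pool {r['pool_size']}, U {r['u_size']}, "
                         f"dev F1 {r['dev_f1']:.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Loss algebra (exact contracts, kept as pure functions)

def joint_loss(loss_B, loss_F, alpha: float = 1.0, beta: float = 1.0):
    """Global loss alpha * Loss_B + beta * Loss_F."""
    if alpha < 0 or beta < 0:
        raise ValueError("loss weights must be non-negative")
    if alpha + beta == 0:
        raise ValueError("at least one loss weight must be positive")
    return alpha * loss_B + beta * loss_F


def semisupervised_loss(loss_ld, loss_uld, theta: float):
    """(1 - theta) * Loss_LD + theta * Loss_ULD (convex combination)."""
    if not 0.0 <= theta < 1.0:
        raise ValueError("theta must be in [0, 1)")
    return (1.0 - theta) * loss_ld + theta * loss_uld


def fgm_perturbation(grad: np.ndarray, epsilon: float) -> np.ndarray | None:
    """epsilon * g / ||g||; None when the gradient vanishes."""
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    norm = float(np.linalg.norm(grad))
    if norm == 0.0:
        return None
    return epsilon * grad / norm


# ---------------------------------------------------------------------------
# Supervised loop

def _lam(cfg: TrainConfig, step: int) -> float:
    return max(cfg.lam_min, cfg.lam_start / (1.0 + cfg.lam_decay * step))


def _make_optimizer(model, cfg: TrainConfig) -> Adam:
    return Adam([{"params": model.encoder_parameters(), "lr": cfg.lr_encoder},
                 {"params": model.head_parameters(), "lr": cfg.lr_heads}],
                weight_decay=cfg.weight_decay, grad_clip=cfg.grad_clip)


def _train_epochs(model, opt: Adam, batches_fn, epochs: int, cfg: TrainConfig,
                  dev, history: list, best: dict, step_offset: int = 0,
                  mixed_pool_fn=None) -> int:
    """Shared epoch driver.  ``batches_fn(epoch_rng)`` yields labeled batches;
    ``mixed_pool_fn(epoch_rng)``, when given, yields pseudo-labelled batches
    cycled alongside and combined per the self-training interpolation."""
    step = step_offset
    for ep in range(epochs):
        rng = np.random.default_rng(cfg.seed * 100003 + len(history))
        lb_sum = lf_sum = 0.0
        nb = 0
        pool_batches = mixed_pool_fn(rng) if mixed_pool_fn is not None else None
        pool_i = 0
        for batch in batches_fn(rng):
            opt.zero_grad()
            lam = _lam(cfg, step)
            loss_b, loss_f = model.loss_batch(batch, lam=lam)
            loss = joint_loss(loss_b, loss_f, cfg.alpha, cfg.beta)
            if pool_batches:
                pbatch = pool_batches[pool_i % len(pool_batches)]
                pool_i += 1
                pl_b, pl_f = model.loss_batch(pbatch, lam=lam)
                loss = semisupervised_loss(
                    loss, joint_loss(pl_b, pl_f, cfg.alpha, cfg.beta),
                    mixed_pool_fn.theta)
            if not np.isfinite(loss.data):
                raise RuntimeError(f"training diverged: non-finite loss at step {step}")
            loss.backward()
            if cfg.fgm_enabled and cfg.fgm_epsilon > 0:
                emb = model.enc.E_c
                r = fgm_perturbation(emb.grad, cfg.fgm_epsilon) \
                    if emb.grad is not None else None
                if r is not None:
                    emb.data += r
                    adv_b, adv_f = model.loss_batch(batch, lam=lam)
                    joint_loss(adv_b, adv_f, cfg.alpha, cfg.beta).backward()
                    emb.data -= r
            opt.step()
            model.typehead.renormalize_classifier()
            lb_sum += float(loss_b.data)
            lf_sum += float(loss_f.data)
            nb += 1
            step += 1
        rec = {"epoch": len(history), "loss_B": lb_sum / max(nb, 1),
               "loss_F": lf_sum / max(nb, 1), "dev_f1": float("nan")}
        if dev:
            rec["dev_f1"] = model.evaluate(dev)["f1"]
            if rec["dev_f1"] > best["f1"]:
                best["f1"] = rec["dev_f1"]
                best["epoch"] = rec["epoch"]
                best["state"] = model.state_dict()
        history.append(rec)
        logger.info("epoch %d: loss_B %.4f loss_F %.4f dev F1 %.4f",
                    rec["epoch"], rec["loss_B"], rec["loss_F"], rec["dev_f1"])
    return step


def train_supervised(model, train, dev=None,
                     cfg: TrainConfig | None = None) -> FitResults:
    """Fit the joint dual-branch objective; returns the best-dev-F1 model.

    When no dev set is given, ``dev_fraction`` of the training sentences is
    split off (seeded) for checkpoint selection.
    """
    cfg = cfg or TrainConfig()
    train = list(train)
    if not train:
        raise ValueError("training corpus is empty")
    if dev is None and cfg.dev_fraction > 0 and len(train) >= 10:
        rng = np.random.default_rng(cfg.seed + 777)
        idx = rng.permutation(len(train))
        n_dev = max(1, int(cfg.dev_fraction * len(train)))
        dev = [train[i] for i in idx[:n_dev]]
        train = [train[i] for i in idx[n_dev:]]
    t0 = time.time()
    opt = _make_optimizer(model, cfg)
    history: list = []
    best = {"f1": -1.0, "epoch": -1, "state": None}

    def batches_fn(rng):
        return model.make_batches(train, cfg.batch_size, shuffle_rng=rng)

    _train_epochs(model, opt, batches_fn, cfg.epochs, cfg, dev, history, best)
    if best["state"] is not None:
        model.load_state_dict(best["state"])
    return FitResults(model=model, history=history, best_f1=max(best["f1"], 0.0),
                      best_epoch=best["epoch"], elapsed=time.time() - t0)


# ---------------------------------------------------------------------------
# Self-training

def pseudo_label(model, unlabeled, tau: float) -> list[tuple]:
    """Confidently tagged unlabeled sentences.

    Returns (sentence, labels, confidence) triples for sentences whose
    confidence (CRF path probability times mean entity-token type
    probability) reaches ``tau``.
    """
    out = []
    for sent, conf in model.predict_with_confidence(unlabeled):
        if conf >= tau:
            out.append((sent.chars, sent.labels, conf))
    return out


def self_train(model, labeled, unlabeled, st_cfg: SelfTrainConfig | None = None,
               cfg: TrainConfig | None = None, dev=None) -> FitResults:
    """Algorithm: fit on L; repeatedly pseudo-label U, admit confident
    sentences to the pool, and continue training on the mixed objective.

    Stops at ``max_rounds`` or when a round admits nothing.  The pool only
    grows (admitted pseudo-labels are frozen); U only shrinks.
    """
    st_cfg = st_cfg or SelfTrainConfig()
    cfg = cfg or TrainConfig()
    labeled = list(labeled)
    unlabeled = [list(u) for u in unlabeled]
    if not unlabeled:
        logger.warning("empty unlabeled set: degenerating to supervised training")
        return train_supervised(model, labeled, dev, cfg)
    if len(unlabeled) <= len(labeled):
        logger.warning("unlabeled pool (%d) not larger than labeled set (%d)",
                       len(unlabeled), len(labeled))
    if dev is None and cfg.dev_fraction > 0 and len(labeled) >= 10:
        rng = np.random.default_rng(cfg.seed + 777)
        idx = rng.permutation(len(labeled))
        n_dev = max(1, int(cfg.dev_fraction * len(labeled)))
        dev = [labeled[i] for i in idx[:n_dev]]
        labeled = [labeled[i] for i in idx[n_dev:]]
    t0 = time.time()
    base = train_supervised(model, labeled, dev, cfg)
    history = base.history
    best = {"f1": base.best_f1, "epoch": base.best_epoch,
            "state": model.state_dict()}
    opt = _make_optimizer(model, cfg)
    pool: list[LabeledSentence] = []
    rounds = []
    step = cfg.epochs * max(1, len(labeled) // cfg.batch_size)

    def batches_fn(rng):
        return model.make_batches(labeled, cfg.batch_size, shuffle_rng=rng)

    for rnd in range(1, st_cfg.max_rounds + 1):
        selected = pseudo_label(model, unlabeled, st_cfg.tau)
        cap = max(1, int(st_cfg.per_round_cap * len(unlabeled))) if unlabeled else 0
        selected = sorted(selected, key=lambda x: -x[2])[:cap]
        taken = {tuple(chars) for chars, _l, _c in selected}
        unlabeled = [u for u in unlabeled if tuple(u) not in taken]
        pool.extend(LabeledSentence(chars=list(c), labels=list(l))
                    for c, l, _conf in selected)
        if not selected:
            rounds.append({"round": rnd, "selected": 0, "pool_size": len(pool),
                           "u_size": len(unlabeled),
                           "dev_f1": history[-1]["dev_f1"] if history else float("nan")})
            break

        def mixed_pool_fn(rng, _pool=list(pool)):
            return model.make_batches(_pool, cfg.batch_size, shuffle_rng=rng)
        mixed_pool_fn.theta = st_cfg.theta

        step = _train_epochs(model, opt, batches_fn, st_cfg.round_epochs, cfg,
                             dev, history, best, step_offset=step,
                             mixed_pool_fn=mixed_pool_fn if st_cfg.theta > 0 else None)
        rounds.append({"round": rnd, "selected": len(selected),
                       "pool_size": len(pool), "u_size": len(unlabeled),
                       "dev_f1": history[-1]["dev_f1"]})
    if best["state"] is not None:
        model.load_state_dict(best["state"])
    return FitResults(model=model, history=history, rounds=rounds,
                      best_f1=max(best["f1"], 0.0), best_epoch=best["epoch"],
                      elapsed=time.time() - t0)
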
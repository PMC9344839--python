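"""Minibatch training with masked supervision and per-epoch reshuffling.

Defaults mirror the reference configuration: batch size 18, fine-tuning
learning rate 5e-6 on the target corpus and 5e-5 for the transfer
(pre-training) stage; a two-stage transfer schedule is expressed as two
successive :func:`train` invocations at different learning rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .. import annotation
from .autograd import Tensor
from .crf import crf_nll_op
from .encoder import EncoderContract
from .heads import make_head
from .loss import masked_ce_sum_op
from .model import TaggerModel

__all__ = ["TrainConfig", "TrainingInstance", "train"]


@dataclass(frozen=True)
class TrainingInstance:
    """One packed question-passage sequence with its gold labels."""

    tokenized: annotation.TokenizedInput
    labels: annotation.LabeledSequence

    def __post_init__(self) -> None:
        if len(self.tokenized) != len(self.labels):
            raise ValueError("tokenized input and labels must be aligned")


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters; seed governs every source of randomness."""

    learning_rate: float = 5e-6
    transfer_learning_rate: float = 5e-5
    batch_size: int = 18
    max_steps: int = 1000
    seed: int = 0
    shuffle_each_epoch: bool = True
    head: str = "linear"
    hidden: int = 16
    #: CRF variant: map IGNORE to O and train on all positions (the
    #: reference behaviour) instead of restricting to the supervised
    #: sub-chain.
    crf_mask_supervision: bool = False
    grad_clip: float | None = 5.0
    adam_betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.transfer_learning_rate <= 0:
            raise ValueError("learning rates must be positive")
        if self.batch_size < 1 or self.max_steps < 1:
            raise ValueError("batch size and max steps must be positive")


class _Adam:
    def __init__(self, params: list[Tensor], lr: float, betas, eps):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def _clip_global_norm(params: list[Tensor], max_norm: float) -> None:
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float(np.sum(p.grad**2))
    norm = np.sqrt(total)
    if norm > max_norm > 0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale


def _crf_labels(labels: annotation.LabeledSequence) -> list[int]:
    return [
        annotation.O if l == annotation.IGNORE else l for l in labels.labels
    ]


def _batch_loss(model: TaggerModel, batch, config: TrainConfig) -> Tensor:
    head = model.head
    loss_sum: Tensor | None = None
    denom = 0.0
    for inst in batch:
        scores = head.score(model.encoder.encode(inst.tokenized))
        if head.has_crf:
            if config.crf_mask_supervision:
                sup = [
                    i
                    for i, l in enumerate(inst.labels.labels)
                    if l != annotation.IGNORE
                ]
                if not sup:
                    raise ValueError("sample carries no supervised positions")
                sub_scores = scores.take_rows(sup)
                gold = [inst.labels.labels[i] for i in sup]
                term = crf_nll_op(
                    sub_scores, head.transitions, head.start, head.end, gold
                )
            else:
                term = crf_nll_op(
                    scores,
                    head.transitions,
                    head.start,
                    head.end,
                    _crf_labels(inst.labels),
                )
            weight = 1.0
        else:
            term, n = masked_ce_sum_op(scores, inst.labels)
            weight = float(n)
        loss_sum = term if loss_sum is None else loss_sum + term
        denom += weight
    assert loss_sum is not None
    return loss_sum * (1.0 / denom)


def train(
    instances: list[TrainingInstance],
    encoder: EncoderContract,
    config: TrainConfig,
    head=None,
    learning_rate: float | None = None,
) -> tuple[TaggerModel, list[tuple[int, float]]]:
    """Train a tagging head (and the encoder, if trainable) on instances.

    Runs up to ``config.max_steps`` minibatch steps, reshuffling the
    sample order at the start of each epoch from the configured seed.
    Returns the trained model and a ``(step, loss)`` log.  A non-finite
    loss aborts with a diagnostic.
    """
    if not instances:
        raise ValueError("no training instances")
    if head is None:
        head = make_head(
            config.head,
            encoder.dim,
            hidden=config.hidden,
            rng=np.random.default_rng(config.seed),
        )
    model = TaggerModel(encoder=encoder, head=head)
    params = list(encoder.parameters()) + list(head.parameters())
    lr = config.learning_rate if learning_rate is None else learning_rate
    opt = _Adam(params, lr, config.adam_betas, config.adam_eps)
    rng = np.random.default_rng(config.seed)

    order = np.arange(len(instances))
    if config.shuffle_each_epoch:
        rng.shuffle(order)
    cursor = 0
    log: list[tuple[int, float]] = []
    for step in range(1, config.max_steps + 1):
        batch = []
        for _ in range(config.batch_size):
            if cursor >= len(order):  # epoch boundary
                cursor = 0
                if config.shuffle_each_epoch:
                    rng.shuffle(order)
            batch.append(instances[order[cursor]])
            cursor += 1
        loss = _batch_loss(model, batch, config)
        value = float(loss.data)
        if not np.isfinite(value):
            raise RuntimeError(
                f"training diverged at step {step}: loss={value!r}"
            )
        opt.zero_grad()
        loss.backward()
        if config.grad_clip is not None:
            _clip_global_norm(params, config.grad_clip)
        opt.step()
        log.append((step, value))
    return model, log
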
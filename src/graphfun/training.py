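"""Training machinery: group-aware cross-validation, masked multi-task binary
cross-entropy, Adam optimisation over whole-protein batches, native/predicted
structure augmentation, and prediction ensembling.

Batches are whole proteins (graphs are ragged); the gradient of the mean
per-protein loss is taken per batch.  Everything is seeded: weight
initialisation, fold assignment and batch order, so identical seeds give
identical runs.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .graph import ProteinGraph
from .network import GNNConfig, GNNModel
from .structio import PredictionResult

logger = logging.getLogger(__name__)

MASK = -1  # label value marking "not annotated for this task"
_EPS = 1e-7


@dataclass
class TrainConfig:
    folds: int = 5
    seeds: tuple = (0,)
    epochs: int = 30
    batch_size: int = 8
    learning_rate: float = 1e-3
    tasks: tuple = ()
    augmentation: bool = True
    patience: int = 10

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("need at least 2 folds")
        if not self.seeds:
            raise ValueError("need at least one seed")
        self.seeds = tuple(self.seeds)
        self.tasks = tuple(self.tasks)


@dataclass
class LabeledExample:
    """A featurized protein with residue-level and/or protein-level labels.

    Labels are {0, 1} with -1 marking masked (unannotated) entries; variants
    of the same protein (native / predicted structure) share a ``group_id``
    so cross-validation never splits them across folds.
    """

    graph: ProteinGraph
    residue_labels: dict = field(default_factory=dict)  # task -> (L,) int array
    protein_labels: np.ndarray | None = None
    group_id: str = ""
    protein_id: str = ""

    def __post_init__(self):
        for task, lab in self.residue_labels.items():
            lab = np.asarray(lab)
            if len(lab) != self.graph.n_nodes:
                raise ValueError(f"task {task}: label length != node count")
            self.residue_labels[task] = lab
        has_res = any(np.any(l != MASK) for l in self.residue_labels.values())
        has_prot = self.protein_labels is not None and np.any(self.protein_labels != MASK)
        if not (has_res or has_prot):
            raise ValueError("example has no unmasked labels")


@dataclass
class EnsembleModel:
    members: list
    config: TrainConfig | None = None

    def __post_init__(self):
        shapes = [
            {k: v.value.shape for k, v in m.params.items()} for m in self.members
        ]
        if any(s != shapes[0] for s in shapes[1:]):
            raise ValueError("ensemble members have mismatched architectures")

    def save(self, directory):
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for k, m in enumerate(self.members):
            m.save(d / f"member{k}.npz")

    @classmethod
    def load(cls, directory):
        from pathlib import Path

        paths = sorted(Path(directory).glob("member*.npz"))
        if not paths:
            raise ValueError(f"no checkpoint members found in {directory}")
        return cls(members=[GNNModel.load(p) for p in paths])


def make_cv_folds(examples, k: int, seed: int = 0):
    """k (train_idx, val_idx) splits partitioning the examples, keeping all
    examples of a group in the same fold."""
    n = len(examples)
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} examples")
    groups = [ex.group_id or ex.protein_id or str(i) for i, ex in enumerate(examples)]
    uniq = list(dict.fromkeys(groups))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    fold_of_group = {uniq[g]: int(f % k) for f, g in enumerate(order)}
    folds = []
    assignment = np.array([fold_of_group[g] for g in groups])
    for f in range(k):
        val = np.where(assignment == f)[0]
        train = np.where(assignment != f)[0]
        folds.append((train, val))
    return folds


def augment_with_predicted(examples):
    """Interleave native examples with their predicted-structure variants,
    checking that paired variants agree on sequence length and labels."""
    by_group = {}
    for ex in examples:
        by_group.setdefault(ex.group_id, []).append(ex)
    out = []
    for gid, variants in by_group.items():
        ref = variants[0]
        for v in variants[1:]:
            if v.graph.n_nodes != ref.graph.n_nodes:
                raise ValueError(f"group {gid}: variants differ in length")
            for task in ref.residue_labels:
                if not np.array_equal(ref.residue_labels[task], v.residue_labels[task]):
                    raise ValueError(f"group {gid}: variants differ in labels")
        out.extend(variants)
    return out


def _bce_terms(scores: Tensor, labels: np.ndarray):
    """Sum of binary cross-entropy over unmasked entries plus their count."""
    labels = np.asarray(labels).ravel()
    idx = np.where(labels != MASK)[0]
    if len(idx) == 0:
        return None, 0
    flat = ad.reshape(scores, (scores.value.size,))
    p = ad.gather(flat, idx)
    y = labels[idx].astype(float)
    term = -(Tensor(y) * ad.log(p + _EPS) + Tensor(1.0 - y) * ad.log((1.0 - p) + _EPS))
    return ad.tsum(term), len(idx)


def multitask_loss(residue_scores: dict, example: LabeledExample,
                   protein_score: Tensor | None = None) -> Tensor:
    """Mean binary cross-entropy over all unmasked (residue, task) and
    (protein, label) entries."""
    total, count = None, 0
    for task, scores in residue_scores.items():
        if task not in example.residue_labels:
            continue
        term, c = _bce_terms(scores, example.residue_labels[task])
        if c:
            total = term if total is None else total + term
            count += c
    if protein_score is not None and example.protein_labels is not None:
        term, c = _bce_terms(protein_score, example.protein_labels)
        if c:
            total = term if total is None else total + term
            count += c
    if count == 0:
        raise ValueError("all labels masked: loss undefined")
    return total * (1.0 / count)


class Adam:
    """Adaptive-moment estimation over a parameter dict."""

    def __init__(self, params: dict, lr: float = 1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.value) for k, p in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.value = p.value - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _example_loss(model: GNNModel, ex: LabeledExample) -> Tensor:
    _, res, prot = model.forward(ex.graph)
    return multitask_loss(res, ex, prot)


def evaluate_loss(model: GNNModel, examples) -> float:
    if not examples:
        return float("nan")
    return float(np.mean([_example_loss(model, ex).value for ex in examples]))


def train_model(train_examples, val_examples, config: TrainConfig,
                model_config: GNNConfig, seed: int = 0, log_lines=None) -> GNNModel:
    """Train one model by Adam on the masked multi-task BCE.

    The returned model carries the parameters of the epoch with the best
    validation loss (final training-set state when no validation set is
    given); training stops early after ``config.patience`` epochs without
    validation improvement.
    """
    if not train_examples:
        raise ValueError("empty training set")
    g0 = train_examples[0].graph
    model = GNNModel(
        g0.node_features.shape[1], g0.edge_features.shape[1], model_config, seed=seed
    )
    opt = Adam(model.params, lr=config.learning_rate)
    rng = np.random.default_rng(seed + 1)
    best_val = np.inf
    best_state = model.state_arrays()
    stall = 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_examples))
        train_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            batch = [train_examples[i] for i in order[start:start + config.batch_size]]
            losses = [_example_loss(model, ex) for ex in batch]
            total = losses[0]
            for t in losses[1:]:
                total = total + t
            loss = total * (1.0 / len(batch))
            if not np.isfinite(loss.value):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} (seed {seed})"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            train_loss += float(loss.value) * len(batch)
        train_loss /= len(order)
        val_loss = evaluate_loss(model, val_examples) if val_examples else float("nan")
        line = f"seed={seed} epoch={epoch} train_loss={train_loss:.6f} val_loss={val_loss:.6f}"
        logger.info(line)
        if log_lines is not None:
            log_lines.append(line)
        if val_examples:
            if val_loss < best_val - 1e-9:
                best_val = val_loss
                best_state = model.state_arrays()
                stall = 0
            else:
                stall += 1
                if stall >= config.patience:
                    break
        else:
            best_state = model.state_arrays()
    model.load_state_arrays(best_state)
    return model


def train_ensemble(examples, config: TrainConfig, model_config: GNNConfig,
                   mode: str = "cv", log_lines=None) -> EnsembleModel:
    """One member per cross-validation fold (``mode="cv"``) or one member per
    seed trained on everything (``mode="seed"``)."""
    members = []
    if mode == "cv":
        folds = make_cv_folds(examples, config.folds, seed=config.seeds[0])
        for f, (tr, va) in enumerate(folds):
            members.append(
                train_model(
                    [examples[i] for i in tr], [examples[i] for i in va],
                    config, model_config, seed=config.seeds[0] + f, log_lines=log_lines,
                )
            )
    elif mode == "seed":
        for s in config.seeds:
            members.append(
                train_model(examples, [], config, model_config, seed=s,
                            log_lines=log_lines)
            )
    else:
        raise ValueError(f"unknown ensemble mode {mode!r}")
    return EnsembleModel(members=members, config=config)


def ensemble_predict(ensemble: EnsembleModel, graph: ProteinGraph) -> PredictionResult:
    """Arithmetic mean of the members' sigmoid outputs."""
    preds = [m.predict(graph) for m in ensemble.members]
    out = PredictionResult(protein_id=preds[0].protein_id)
    for task in preds[0].residue_scores:
        out.residue_scores[task] = np.mean(
            [p.residue_scores[task] for p in preds], axis=0
        )
    for label in preds[0].protein_scores:
        out.protein_scores[label] = float(
            np.mean([p.protein_scores[label] for p in preds])
        )
    return out
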
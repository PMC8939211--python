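"""A lightweight multi-input 1-D attention U-Net for SS prediction.

The network takes up to four per-residue feature blocks — one-hot amino
acids (20), PSSM (20), HHM profile (30) and a windowed contact map (W,
default 50) — each through its own contractive (encoder) path.  After
every down-block the features of all inputs are concatenated and passed
to the matching up-block through a skip connection; a single expanding
(decoder) path reconstructs per-residue representations, and two 1x1
softmax heads emit L x 3 and L x 8 state probabilities.  Down-blocks
use two convolutions with dropout 0.1 between them; additive attention
gates modulate each skip connection right before concatenation, with
the up-path features as the gating signal.

Chains are right-padded with zero features to ``max_len`` (default 704,
which every supported chain must fit; longer chains are rejected
upstream) and the loss and all metrics are masked to real positions.
The loss is the unweighted sum of the SS3 and SS8 categorical
cross-entropies.

Training follows a plateau schedule: Adam with initial learning rate
1e-3, batch size 8; the learning rate is multiplied by 0.1 after 4
epochs without validation-loss improvement, training stops after 7 such
epochs, and the parameters of the epoch with the lowest validation loss
are returned.  An ensemble averages the softmax outputs of its member
models.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import nn
from .core import (
    FeatureBundle,
    PredictionRecord,
    ProteinRecord,
    SS3_STATES,
    SS8_STATES,
    SS8_TO_SS3,
)

__all__ = [
    "INPUT_WIDTHS",
    "ModelConfig",
    "TrainConfig",
    "FoldSplit",
    "StandardizationStats",
    "window_contact_map",
    "standardize",
    "build_model",
    "SSUnet",
    "stratified_folds",
    "train_model",
    "TrainingHistory",
    "predict",
    "ensemble_predict",
    "save_checkpoint",
    "load_checkpoint",
]

#: channel width of each supported input block ("contact_window" takes
#: its width from ModelConfig.contact_window)
INPUT_WIDTHS = {"aa_onehot": 20, "pssm": 20, "hhm": 30}


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    The default input set is the full PSSM + HHM + contact + one-hot
    combination with 64 filters; depth and kernel size are inherited
    from the single-input predecessor architecture and configurable.
    """

    inputs: tuple[str, ...] = ("pssm", "hhm", "contact_window", "aa_onehot")
    contact_window: int = 50
    depth: int = 4
    f_c: int = 64
    f_e: int = 64
    convs_per_block: int = 2
    dropout_rate: float = 0.1
    kernel_size: int = 7
    max_len: int = 704
    attention: bool = True

    def __post_init__(self) -> None:
        if not isinstance(self.inputs, tuple):
            object.__setattr__(self, "inputs", tuple(self.inputs))
        if not self.inputs:
            raise ValueError("at least one input block is required")
        unknown = [i for i in self.inputs if i not in (*INPUT_WIDTHS, "contact_window")]
        if unknown:
            raise ValueError(f"unknown input blocks: {unknown}")
        if self.max_len % (2 ** self.depth) != 0:
            raise ValueError(
                f"max_len {self.max_len} must be divisible by 2^depth = {2 ** self.depth}"
            )
        if self.kernel_size % 2 == 0 or self.kernel_size < 1:
            raise ValueError("kernel_size must be odd and positive")

    def input_width(self, name: str) -> int:
        return self.contact_window if name == "contact_window" else INPUT_WIDTHS[name]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation schedule."""

    batch_size: int = 8
    lr_initial: float = 1e-3
    lr_factor: float = 0.1
    lr_patience: int = 4
    stop_patience: int = 7
    max_epochs: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr_patience < 1 or self.stop_patience < 1:
            raise ValueError("patience values must be positive")
        if not (0.0 < self.lr_factor < 1.0):
            raise ValueError("lr_factor must lie in (0, 1)")


# ------------------------------------------------------ contact windows

def window_contact_map(cmap: np.ndarray, w: int = 50) -> np.ndarray:
    """Extract an L x w window of contact probabilities per residue.

    Row i holds the contacts of residue i to residues at offsets
    -w/2 .. -1, +1 .. +w/2 (self excluded), zero-padded beyond the chain
    ends.  Contact maps arrive in [0, 1] and are passed through without
    standardisation.
    """
    cmap = np.asarray(cmap, dtype=float)
    if cmap.ndim != 2 or cmap.shape[0] != cmap.shape[1]:
        raise ValueError(f"contact map must be square, got {cmap.shape}")
    if w < 2 or w % 2:
        raise ValueError("window size must be a positive even integer")
    L = cmap.shape[0]
    half = w // 2
    offsets = np.array([o for o in range(-half, half + 1) if o != 0])
    out = np.zeros((L, w))
    rows = np.arange(L)
    for c, off in enumerate(offsets):
        j = rows + off
        valid = (j >= 0) & (j < L)
        out[valid, c] = cmap[rows[valid], j[valid]]
    return out


# ------------------------------------------------------- standardisation

@dataclass
class StandardizationStats:
    """Training-set column means/SDs for the PSSM and HHM blocks."""

    pssm_mean: Optional[np.ndarray] = None
    pssm_sd: Optional[np.ndarray] = None
    hhm_mean: Optional[np.ndarray] = None
    hhm_sd: Optional[np.ndarray] = None


def _column_stats(mats: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    stacked = np.concatenate(mats, axis=0)
    mean = stacked.mean(axis=0)
    sd = stacked.std(axis=0)
    zero = sd == 0.0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance feature column(s): centred only"
        )
        sd = np.where(zero, 1.0, sd)
    return mean, sd


def standardize(
    bundles: Sequence[FeatureBundle],
    stats: Optional[StandardizationStats] = None,
) -> tuple[list[FeatureBundle], StandardizationStats]:
    """Standardise PSSM and HHM columns to zero mean / unit SD.

    Without ``stats`` the means and SDs are computed from the given
    bundles (the training split) and returned for reuse; with ``stats``
    (validation/test) they are applied unchanged.  One-hot blocks and
    contact windows pass through untouched.
    """
    if stats is None:
        stats = StandardizationStats()
        pssms = [b.pssm for b in bundles if b.pssm is not None]
        hhms = [b.hhm for b in bundles if b.hhm is not None]
        if pssms:
            stats.pssm_mean, stats.pssm_sd = _column_stats(pssms)
        if hhms:
            stats.hhm_mean, stats.hhm_sd = _column_stats(hhms)
    out = []
    for b in bundles:
        pssm = b.pssm
        if pssm is not None and stats.pssm_mean is not None:
            pssm = (pssm - stats.pssm_mean) / stats.pssm_sd
        hhm = b.hhm
        if hhm is not None and stats.hhm_mean is not None:
            hhm = (hhm - stats.hhm_mean) / stats.hhm_sd
        out.append(
            FeatureBundle(
                aa_onehot=b.aa_onehot, pssm=pssm, hhm=hhm,
                contact_window=b.contact_window,
            )
        )
    return out, stats


# ----------------------------------------------------------- components

class _Conv1D:
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (k * c_in))
        self.w = nn.Tensor(rng.normal(0.0, scale, (k, c_in, c_out)), requires_grad=True)
        self.b = nn.Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        return nn.conv1d(x, self.w, self.b)

    @property
    def params(self) -> list[nn.Tensor]:
        return [self.w, self.b]


class _ConvBlock:
    """``convs_per_block`` convolutions with ReLU, dropout in between."""

    def __init__(self, c_in: int, c_out: int, k: int, n_convs: int,
                 dropout_rate: float, rng: np.random.Generator):
        self.convs = [
            _Conv1D(c_in if i == 0 else c_out, c_out, k, rng) for i in range(n_convs)
        ]
        self.dropout_rate = dropout_rate

    def __call__(self, x: nn.Tensor, training: bool, rng: np.random.Generator) -> nn.Tensor:
        for i, conv in enumerate(self.convs):
            x = nn.relu(conv(x))
            if i < len(self.convs) - 1:
                x = nn.dropout(x, self.dropout_rate, rng, training)
        return x

    @property
    def params(self) -> list[nn.Tensor]:
        return [p for c in self.convs for p in c.params]


class _AttentionGate:
    """Additive attention gate: skip features x are scaled by
    sigmoid(psi(relu(theta(x) + phi(g)))) with gating signal g from the
    up path."""

    def __init__(self, c_x: int, c_g: int, rng: np.random.Generator):
        c_int = max(c_x // 2, 1)
        self.theta = _Conv1D(c_x, c_int, 1, rng)
        self.phi = _Conv1D(c_g, c_int, 1, rng)
        self.psi = _Conv1D(c_int, 1, 1, rng)

    def __call__(self, x: nn.Tensor, g: nn.Tensor) -> nn.Tensor:
        attn = nn.sigmoid(self.psi(nn.relu(nn.add(self.theta(x), self.phi(g)))))
        return nn.mul(x, attn)

    @property
    def params(self) -> list[nn.Tensor]:
        return self.theta.params + self.phi.params + self.psi.params


class SSUnet:
    """The assembled network; create via :func:`build_model`."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        k = config.kernel_size
        n_in = len(config.inputs)
        self.down: dict[str, list[_ConvBlock]] = {}
        for name in config.inputs:
            c_in = config.input_width(name)
            blocks = []
            for level in range(config.depth):
                blocks.append(
                    _ConvBlock(c_in if level == 0 else config.f_c, config.f_c, k,
                               config.convs_per_block, config.dropout_rate, rng)
                )
            self.down[name] = blocks
        skip_ch = n_in * config.f_c
        self.bottom = _ConvBlock(skip_ch, config.f_e, k,
                                 config.convs_per_block, config.dropout_rate, rng)
        self.gates: list[Optional[_AttentionGate]] = []
        self.up: list[_ConvBlock] = []
        for _ in range(config.depth):
            self.gates.append(
                _AttentionGate(skip_ch, config.f_e, rng) if config.attention else None
            )
            self.up.append(
                _ConvBlock(skip_ch + config.f_e, config.f_e, k,
                           config.convs_per_block, config.dropout_rate, rng)
            )
        self.head8 = _Conv1D(config.f_e, 8, 1, rng)
        self.head3 = _Conv1D(config.f_e, 3, 1, rng)

    @property
    def params(self) -> list[nn.Tensor]:
        ps: list[nn.Tensor] = []
        for blocks in self.down.values():
            for b in blocks:
                ps.extend(b.params)
        ps.extend(self.bottom.params)
        for gate, up in zip(self.gates, self.up):
            if gate is not None:
                ps.extend(gate.params)
            ps.extend(up.params)
        ps.extend(self.head8.params + self.head3.params)
        return ps

    @property
    def param_count(self) -> int:
        return int(sum(p.data.size for p in self.params))

    def forward(
        self,
        features: dict[str, np.ndarray],
        training: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> tuple[nn.Tensor, nn.Tensor]:
        """Run the network; returns (logits8, logits3) as graph tensors.

        ``features`` maps input name -> (B, max_len, width) arrays.
        """
        cfg = self.config
        if rng is None:
            rng = np.random.default_rng(0)
        missing = [n for n in cfg.inputs if n not in features]
        if missing:
            raise ValueError(f"missing input blocks: {missing}")
        xs = {n: nn.Tensor(features[n]) for n in cfg.inputs}
        skips: list[nn.Tensor] = []
        for level in range(cfg.depth):
            outs = {n: self.down[n][level](xs[n], training, rng) for n in cfg.inputs}
            skips.append(nn.concat([outs[n] for n in cfg.inputs]))
            xs = {n: nn.maxpool2(outs[n]) for n in cfg.inputs}
        x = self.bottom(nn.concat([xs[n] for n in cfg.inputs]), training, rng)
        for level in range(cfg.depth - 1, -1, -1):
            x = nn.upsample2(x)
            skip = skips[level]
            gate = self.gates[cfg.depth - 1 - level]
            if gate is not None:
                skip = gate(skip, x)
            x = self.up[cfg.depth - 1 - level](nn.concat([skip, x]), training, rng)
        return self.head8(x), self.head3(x)

    def predict_probs(self, features: dict[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        """Softmax outputs (B, max_len, 8) and (B, max_len, 3), no dropout."""
        z8, z3 = self.forward(features, training=False)
        return nn.softmax(z8.data), nn.softmax(z3.data)

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        params = self.params
        if len(weights) != len(params):
            raise ValueError("weight list does not match parameter list")
        for p, w in zip(params, weights):
            if p.data.shape != w.shape:
                raise ValueError("weight shape mismatch")
            p.data = w.copy()


def build_model(config: ModelConfig, seed: int = 0) -> SSUnet:
    """Construct a seeded, deterministically initialised network."""
    return SSUnet(config, seed=seed)


# -------------------------------------------------------- data plumbing

_SS8_INDEX = {s: j for j, s in enumerate(SS8_STATES)}
_SS3_INDEX = {s: j for j, s in enumerate(SS3_STATES)}


def prepare_batch(
    records: Sequence[ProteinRecord], config: ModelConfig
) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray, np.ndarray]:
    """Pad records to max_len -> (features, mask, onehot8, onehot3)."""
    n, L = len(records), config.max_len
    feats = {
        name: np.zeros((n, L, config.input_width(name))) for name in config.inputs
    }
    mask = np.zeros((n, L))
    y8 = np.zeros((n, L, 8))
    y3 = np.zeros((n, L, 3))
    for i, rec in enumerate(records):
        if rec.features is None:
            raise ValueError(f"record {rec.id} has no features")
        li = len(rec)
        if li > L:
            raise ValueError(f"record {rec.id} longer than max_len {L}")
        for name in config.inputs:
            block = getattr(rec.features, name)
            if block is None:
                raise ValueError(f"record {rec.id} missing feature block {name}")
            feats[name][i, :li] = block
        mask[i, :li] = 1.0
        if rec.ss8 is not None:
            for t, ch in enumerate(rec.ss8):
                y8[i, t, _SS8_INDEX[ch]] = 1.0
                y3[i, t, _SS3_INDEX[SS8_TO_SS3[ch]]] = 1.0
    return feats, mask, y8, y3


# ------------------------------------------------------ stratified folds

@dataclass
class FoldSplit:
    """10-fold assignment with the 9-factor stratum of every chain."""

    assignment: dict[str, int]
    strata: dict[str, tuple[int, ...]]
    k: int

    def fold_ids(self, fold: int) -> list[str]:
        return [cid for cid, f in self.assignment.items() if f == fold]


def stratified_folds(
    records: Sequence[ProteinRecord], k: int = 10, seed: int = 0
) -> FoldSplit:
    """Split chains into k folds stratified on nine binary factors.

    Factors: sequence length above/below the mean length, plus — for
    each of the 8 states — whether the chain's occurrence count of that
    state is above the mean occurrences per chain.  Within each stratum
    chains are ordered by rare-class content (seeded shuffle breaking
    ties) and dealt round-robin from a seeded starting fold, which keeps
    fold sizes within one chain per stratum and balances even the
    near-absent classes across folds.
    """
    if k > len(records):
        raise ValueError(f"cannot make {k} folds from {len(records)} chains")
    for rec in records:
        if rec.ss8 is None:
            raise ValueError(f"record {rec.id} has no ss8 labels")
    lengths = np.array([len(r) for r in records], dtype=float)
    counts = np.array(
        [[r.ss8.count(s) for s in SS8_STATES] for r in records], dtype=float
    )
    mean_len = lengths.mean()
    mean_counts = counts.mean(axis=0)  # mean occurrences per chain, per class
    strata: dict[str, tuple[int, ...]] = {}
    by_stratum: dict[tuple[int, ...], list[int]] = {}
    for i, rec in enumerate(records):
        bits = (int(lengths[i] > mean_len),) + tuple(
            int(counts[i, j] > mean_counts[j]) for j in range(8)
        )
        strata[rec.id] = bits
        by_stratum.setdefault(bits, []).append(i)
    # rarest classes first: their residues are the hardest to balance
    global_freq = counts.sum(axis=0)
    rare_order = np.argsort(global_freq)[:3]
    rng = np.random.default_rng(seed)
    fold_of = np.empty(len(records), dtype=int)
    fold_counts = np.zeros((k, 8))  # residues of each class per fold
    fold_sizes = np.zeros(k, dtype=int)
    for bits in sorted(by_stratum):
        members = by_stratum[bits]
        rng.shuffle(members)
        keys = [tuple(-counts[i, j] for j in rare_order) for i in members]
        members = [m for _, m in sorted(zip(keys, members), key=lambda t: t[0])]
        # deal in blocks of k: every fold gets one chain per full block,
        # so per-stratum counts stay within +-1; inside a block the chains
        # richest in rare classes go to the folds currently poorest in them
        for lo in range(0, len(members), k):
            block = members[lo : lo + k]
            full = len(block) == k
            order = sorted(
                range(k),
                key=lambda f: (
                    (fold_sizes[f],) if not full else ()
                ) + tuple(fold_counts[f, j] for j in rare_order) + (rng.random(),),
            )
            for chain, f in zip(block, order):
                fold_of[chain] = f
                fold_counts[f] += counts[chain]
                fold_sizes[f] += 1
    # refinement: the rarest classes concentrate in few chains, which the
    # stratum-local deal cannot spread evenly.  Swap chains between the
    # extreme folds per rare class (preserving fold sizes exactly), each
    # time picking the swap partner with the most similar residue profile
    # so the common classes stay balanced.
    per_chain_mean = counts.mean(axis=0) + 1e-9
    fold_mean = fold_counts.mean(axis=0)
    for c in rare_order:
        for _ in range(60 * k):
            hi = int(np.argmax(fold_counts[:, c]))
            lo = int(np.argmin(fold_counts[:, c]))
            if fold_counts[hi, c] - fold_counts[lo, c] <= max(1.0, 0.05 * fold_mean[c]):
                break
            hi_chains = np.where(fold_of == hi)[0]
            lo_chains = np.where(fold_of == lo)[0]
            a = hi_chains[np.argmax(counts[hi_chains, c])]
            diffs = (counts[lo_chains] - counts[a]) / per_chain_mean
            collateral = np.abs(diffs).sum(axis=1) - np.abs(diffs[:, c])
            b = lo_chains[np.lexsort((collateral, counts[lo_chains, c]))][0]
            move = counts[b] - counts[a]
            if move[c] >= 0:  # no improving swap left for this class
                break
            fold_counts[hi] += move
            fold_counts[lo] -= move
            fold_of[a], fold_of[b] = lo, hi
    assignment = {records[i].id: int(fold_of[i]) for i in range(len(records))}
    return FoldSplit(assignment=assignment, strata=strata, k=k)


# --------------------------------------------------------------- training

@dataclass
class TrainingHistory:
    """Per-epoch record of the optimisation."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = -1


def _epoch_loss(model: SSUnet, records: Sequence[ProteinRecord],
                batch_size: int) -> float:
    total, weight = 0.0, 0.0
    for lo in range(0, len(records), batch_size):
        batch = records[lo : lo + batch_size]
        feats, mask, y8, y3 = prepare_batch(batch, model.config)
        z8, z3 = model.forward(feats, training=False)
        l8 = nn.softmax_cross_entropy(z8, y8, mask)
        l3 = nn.softmax_cross_entropy(z3, y3, mask)
        n = mask.sum()
        total += (float(l8.data) + float(l3.data)) * n
        weight += n
    return total / weight


def train_model(
    model: SSUnet,
    train_records: Sequence[ProteinRecord],
    val_records: Sequence[ProteinRecord],
    config: TrainConfig = TrainConfig(),
) -> tuple[SSUnet, TrainingHistory]:
    """Train with Adam under the plateau schedule (see module docstring).

    Returns the model restored to its best-validation-loss weights and
    the per-epoch history.  Feature standardisation must already have
    been applied with training-split statistics.
    """
    if not train_records:
        raise ValueError("empty training set")
    if not val_records:
        raise ValueError("empty validation set")
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.params, lr=config.lr_initial)
    history = TrainingHistory()
    best_val = np.inf
    best_weights = model.get_weights()
    lr_wait = 0
    stop_wait = 0
    order = np.arange(len(train_records))
    for epoch in range(config.max_epochs):
        rng.shuffle(order)
        total, weight = 0.0, 0.0
        for lo in range(0, len(order), config.batch_size):
            batch = [train_records[i] for i in order[lo : lo + config.batch_size]]
            feats, mask, y8, y3 = prepare_batch(batch, model.config)
            z8, z3 = model.forward(feats, training=True, rng=rng)
            loss = nn.add(
                nn.softmax_cross_entropy(z8, y8, mask),
                nn.softmax_cross_entropy(z3, y3, mask),
            )
            opt.zero_grad()
            loss.backward()
            opt.step()
            n = mask.sum()
            total += float(loss.data) * n
            weight += n
        val = _epoch_loss(model, val_records, config.batch_size)
        history.train_loss.append(total / weight)
        history.val_loss.append(val)
        history.lr.append(opt.lr)
        if val < best_val - 1e-12:
            best_val = val
            best_weights = model.get_weights()
            history.best_epoch = epoch
            lr_wait = 0
            stop_wait = 0
        else:
            lr_wait += 1
            stop_wait += 1
            if stop_wait >= config.stop_patience:
                break
            if lr_wait >= config.lr_patience:
                opt.lr *= config.lr_factor
                lr_wait = 0
    model.set_weights(best_weights)
    return model, history


# -------------------------------------------------------------- predict

def predict(
    model: SSUnet,
    record: ProteinRecord,
    stats: Optional[StandardizationStats] = None,
) -> PredictionRecord:
    """Predict one chain; probabilities trimmed to the chain length."""
    rec = record
    if stats is not None and rec.features is not None:
        bundles, _ = standardize([rec.features], stats)
        rec = copy.copy(rec)
        rec.features = bundles[0]
    feats, mask, _, _ = prepare_batch([rec], model.config)
    p8, p3 = model.predict_probs(feats)
    L = len(record)
    return PredictionRecord(id=record.id, probs8=p8[0, :L], probs3=p3[0, :L])


def ensemble_predict(
    models: Sequence[SSUnet],
    record: ProteinRecord,
    stats: Optional[StandardizationStats] = None,
) -> PredictionRecord:
    """Average the softmax outputs of the member models (equal weights)."""
    if not models:
        raise ValueError("empty ensemble")
    configs = {m.config for m in models}
    if len(configs) > 1:
        raise ValueError("ensemble members must share one ModelConfig")
    preds = [predict(m, record, stats) for m in models]
    probs8 = np.mean([p.probs8 for p in preds], axis=0)
    probs3 = np.mean([p.probs3 for p in preds], axis=0)
    return PredictionRecord(id=record.id, probs8=probs8, probs3=probs3)


# ------------------------------------------------------------ checkpoint

def save_checkpoint(
    path: str | Path,
    model: SSUnet,
    stats: Optional[StandardizationStats] = None,
) -> None:
    """Bundle weights + config + standardisation stats + state order."""
    path = Path(path)
    payload: dict[str, np.ndarray] = {
        f"w{i}": w for i, w in enumerate(model.get_weights())
    }
    meta = {
        "config": asdict(model.config),
        "seed": model.seed,
        "ss8_states": list(SS8_STATES),
        "ss3_states": list(SS3_STATES),
    }
    if stats is not None:
        for name in ("pssm_mean", "pssm_sd", "hhm_mean", "hhm_sd"):
            arr = getattr(stats, name)
            if arr is not None:
                payload[f"stats_{name}"] = arr
    np.savez(path, meta=json.dumps(meta), **payload)


def load_checkpoint(path: str | Path) -> tuple[SSUnet, StandardizationStats]:
    with np.load(Path(path).with_suffix(".npz") if not str(path).endswith(".npz") else path,
                 allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        if meta["ss8_states"] != list(SS8_STATES):
            raise ValueError("checkpoint uses a different canonical state order")
        cfg = meta["config"]
        cfg["inputs"] = tuple(cfg["inputs"])
        model = SSUnet(ModelConfig(**cfg), seed=meta["seed"])
        weights = [data[f"w{i}"] for i in range(len(model.params))]
        model.set_weights(weights)

        def _opt(name: str) -> Optional[np.ndarray]:
            return data[name] if name in data.files else None

        stats = StandardizationStats(
            pssm_mean=_opt("stats_pssm_mean"),
            pssm_sd=_opt("stats_pssm_sd"),
            hhm_mean=_opt("stats_hhm_mean"),
            hhm_sd=_opt("stats_hhm_sd"),
        )
    return model, stats
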
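"""Synthetic SS datasets with controllable imbalance and error structure.

Real DSSP label sequences are heavily imbalanced (H dominates, I is
nearly absent) and strongly segmental: states come in runs (helices of
~9 residues, strands of ~5).  The generator emulates both with a
first-order Markov chain over the eight states whose stationary
distribution matches requested class frequencies and whose
self-transition probabilities produce requested expected run lengths
(run length of state s is geometric with mean 1/(1 - T[s,s])).

Off-diagonal transition rows are solved by proportional allocation: a
weight vector a is found by fixed-point iteration such that
T[s,t] = (1 - T[s,s]) * a_t / sum_{u != s} a_u leaves the target
frequencies stationary.  If no such chain exists for the requested
frequency/run-length combination the solver raises instead of silently
adjusting the targets.

The default frequency preset approximates the qualitative imbalance of
benchmark test sets (H >> E > C, T > S, G > B >> I) with an exact 10:1
H:G ratio, the canonical accuracy-paradox pair.  Exact benchmark values
are not claimed.

Predictor outputs are simulated per residue: with probability
recall(class) the softmax peaks on the true class, otherwise on a
confusable class; a temperature controls peak sharpness.  Optionally
the effective recall increases with the chain's Neff, emulating
profile-quality dependence.  Pseudo-feature blocks (PSSM/HHM/contact
map) are class-dependent mean vectors plus Gaussian noise — enough
signal for a network to fit, with no claim of biophysical realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .core import (
    AA_ORDER,
    FeatureBundle,
    PredictionRecord,
    ProteinRecord,
    SS8_STATES,
)

__all__ = [
    "DEFAULT_SS8_FREQS",
    "DEFAULT_RUN_LENGTHS",
    "GeneratorConfig",
    "ErrorProfile",
    "solve_transition_matrix",
    "generate_truth",
    "generate_predictions",
    "generate_features",
    "gapped_chain_fixture",
]

#: Imbalanced class-frequency preset (approximate, qualitative match to
#: benchmark SS8 distributions; H:G fixed at 10:1).
DEFAULT_SS8_FREQS: dict[str, float] = {
    "G": 0.035, "H": 0.350, "I": 0.003, "B": 0.015,
    "E": 0.220, "S": 0.085, "T": 0.110, "C": 0.182,
}

#: Expected run length (residues) per state; helices long, bridges short.
DEFAULT_RUN_LENGTHS: dict[str, float] = {
    "G": 2.5, "H": 9.0, "I": 1.8, "B": 1.2,
    "E": 5.0, "S": 2.0, "T": 2.5, "C": 3.0,
}


@dataclass
class GeneratorConfig:
    """Study conditions for a synthetic dataset."""

    n_chains: int = 200
    length_min: int = 30
    length_max: int = 200
    length_mean: float = 100.0
    freqs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SS8_FREQS))
    run_lengths: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RUN_LENGTHS))
    neff_mean_log: float = 1.3
    neff_sigma_log: float = 0.7
    neff_max: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequency targets must sum to 1, got {total}")
        if set(self.freqs) != set(SS8_STATES):
            raise ValueError("freqs must cover exactly the 8 SS8 states")
        if any(v < 1.0 for v in self.run_lengths.values()):
            raise ValueError("expected run lengths must be >= 1")
        if not (1 <= self.length_min <= self.length_mean <= self.length_max):
            raise ValueError("need length_min <= length_mean <= length_max")


@dataclass
class ErrorProfile:
    """Per-class error structure of a simulated predictor.

    recall      : per-class probability that a residue of that class is
                  predicted correctly.
    confusion   : optional per-class preference weights over the wrong
                  classes (default: uniform over the other seven).
    constant    : if set, every residue is predicted as this state
                  (recall/confusion ignored) — the accuracy-paradox
                  baseline.
    temperature : softmax sharpness; the chosen state gets probability
                  e^(1/T) / (e^(1/T) + 7) * base.
    neff_slope  : effective recall = clip(recall + slope * (neff -
                  neff_center), 0.01, 1) when the chain carries a Neff.
    """

    recall: dict[str, float] = field(
        default_factory=lambda: {s: 0.8 for s in SS8_STATES}
    )
    confusion: Optional[dict[str, dict[str, float]]] = None
    constant: Optional[str] = None
    temperature: float = 0.25
    neff_slope: float = 0.0
    neff_center: float = 5.0

    def __post_init__(self) -> None:
        for cls, r in self.recall.items():
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"recall for {cls} must be in [0, 1], got {r}")
        if self.constant is not None and self.constant not in SS8_STATES:
            raise ValueError(f"unknown constant state {self.constant!r}")

    def shifted(self, delta: float) -> "ErrorProfile":
        """A copy with every per-class recall shifted by ``delta`` (clipped)."""
        return replace(
            self,
            recall={c: float(np.clip(r + delta, 0.0, 1.0)) for c, r in self.recall.items()},
        )


# --------------------------------------------------- Markov construction

def solve_transition_matrix(
    freqs: dict[str, float],
    run_lengths: dict[str, float],
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Solve for an 8 x 8 transition matrix with the given stationary
    distribution and self-transition probabilities 1 - 1/run_length.

    Raises ``ValueError`` when the fixed-point allocation does not
    converge or the resulting chain's stationary distribution misses the
    targets — the requested combination is then infeasible.
    """
    pi = np.array([freqs[s] for s in SS8_STATES])
    p_self = np.array([1.0 - 1.0 / run_lengths[s] for s in SS8_STATES])
    leave = pi * (1.0 - p_self)  # stationary flow out of each state
    k = len(SS8_STATES)
    a = leave.copy()
    for _ in range(max_iter):
        total = a.sum()
        denom_s = total - a  # sum over u != s of a_u
        coeff = leave / denom_s
        new_a = leave / (coeff.sum() - coeff)
        new_a = new_a / new_a.sum() * total  # fix scale (solution is projective)
        if np.max(np.abs(new_a - a)) < tol * max(1.0, total):
            a = new_a
            break
        a = new_a
    T = np.zeros((k, k))
    for s in range(k):
        w = a.copy()
        w[s] = 0.0
        T[s] = (1.0 - p_self[s]) * w / w.sum()
        T[s, s] = p_self[s]
    # verify stationarity of the constructed chain
    resid = np.abs(pi @ T - pi).max()
    if not np.isfinite(T).all() or (T < -1e-12).any() or resid > 1e-6:
        raise ValueError(
            "infeasible frequency/run-length combination "
            f"(stationarity residual {resid:.2e})"
        )
    return T


def _markov_labels(
    T: np.ndarray, pi: np.ndarray, lengths: np.ndarray, rng: np.random.Generator
) -> list[str]:
    """Vectorised sampling of one Markov chain per requested length."""
    n, lmax = len(lengths), int(lengths.max())
    cum_t = np.cumsum(T, axis=1)
    states = np.empty((n, lmax), dtype=np.int8)
    states[:, 0] = np.searchsorted(np.cumsum(pi), rng.random(n), side="right")
    u = rng.random((n, lmax))
    for t in range(1, lmax):
        states[:, t] = (u[:, t, None] > cum_t[states[:, t - 1]]).sum(axis=1)
    symbols = np.array(list(SS8_STATES))
    return ["".join(symbols[states[i, : lengths[i]]]) for i in range(n)]


def generate_truth(config: GeneratorConfig) -> list[ProteinRecord]:
    """Sample ground-truth records: Markov SS8 labels, random amino-acid
    sequences and per-chain Neff values, deterministically from the seed."""
    rng = np.random.default_rng(config.seed)
    T = solve_transition_matrix(config.freqs, config.run_lengths)
    pi = np.array([config.freqs[s] for s in SS8_STATES])
    span = config.length_max - config.length_min
    if span == 0:
        lengths = np.full(config.n_chains, config.length_min)
    else:
        p = (config.length_mean - config.length_min) / span
        lengths = config.length_min + rng.binomial(span, p, size=config.n_chains)
    labels = _markov_labels(T, pi, lengths, rng)
    aa = np.array(list(AA_ORDER))
    neff = np.minimum(
        rng.lognormal(config.neff_mean_log, config.neff_sigma_log, config.n_chains),
        config.neff_max,
    )
    records = []
    for i in range(config.n_chains):
        seq = "".join(aa[rng.integers(0, 20, size=lengths[i])])
        records.append(
            ProteinRecord(
                id=f"syn{i:05d}",
                sequence=seq,
                ss8=labels[i],
                neff=float(neff[i]),
            )
        )
    return records


# ----------------------------------------------------------- predictions

_STATE_INDEX = {s: j for j, s in enumerate(SS8_STATES)}


def _peaked_rows(chosen: np.ndarray, temperature: float) -> np.ndarray:
    """Row-stochastic L x 8 matrix whose rows peak on ``chosen``."""
    peak = float(np.exp(1.0 / temperature))
    base = 1.0 / (peak + 7.0)
    probs = np.full((chosen.size, 8), base)
    probs[np.arange(chosen.size), chosen] = peak * base
    return probs


def generate_predictions(
    records: Sequence[ProteinRecord],
    profile: ErrorProfile,
    seed: int = 0,
) -> dict[str, PredictionRecord]:
    """Simulate a predictor's probability outputs on ground-truth records."""
    rng = np.random.default_rng(seed)
    out: dict[str, PredictionRecord] = {}
    recall_vec = np.array([profile.recall.get(s, 0.8) for s in SS8_STATES])
    # per-class cumulative confusion distribution over wrong classes
    conf_cum = np.zeros((8, 8))
    for j, s in enumerate(SS8_STATES):
        w = np.ones(8)
        if profile.confusion and s in profile.confusion:
            w = np.array([profile.confusion[s].get(t, 0.0) for t in SS8_STATES])
        w[j] = 0.0
        if w.sum() <= 0:
            raise ValueError(f"confusion weights for {s} sum to zero")
        conf_cum[j] = np.cumsum(w / w.sum())
    for rec in records:
        if rec.ss8 is None:
            raise ValueError(f"record {rec.id} has no truth labels")
        true_idx = np.array([_STATE_INDEX[c] for c in rec.ss8])
        if profile.constant is not None:
            chosen = np.full(len(rec), _STATE_INDEX[profile.constant])
        else:
            rec_recall = recall_vec[true_idx]
            if profile.neff_slope and rec.neff is not None:
                rec_recall = np.clip(
                    rec_recall + profile.neff_slope * (rec.neff - profile.neff_center),
                    0.01, 1.0,
                )
            correct = rng.random(len(rec)) < rec_recall
            wrong = (
                rng.random((len(rec), 1)) > conf_cum[true_idx]
            ).sum(axis=1)
            chosen = np.where(correct, true_idx, wrong)
        out[rec.id] = PredictionRecord(
            id=rec.id, probs8=_peaked_rows(chosen, profile.temperature)
        )
    return out


# -------------------------------------------------------------- features

def generate_features(
    records: Sequence[ProteinRecord],
    noise: float = 0.3,
    seed: int = 0,
    separation: float = 1.0,
    contact_window: int = 50,
) -> list[ProteinRecord]:
    """Attach class-correlated pseudo-features to each record.

    PSSM rows are class mean vectors (drawn once from the seed) plus
    Gaussian noise; HHM rows are the logistic of the same construction
    (keeping the [0, 1] range of transformed profiles); the contact
    window derives from a banded class-modulated contact map clipped to
    [0, 1].  ``noise = 0`` gives perfectly class-separable features.
    """
    from .model import window_contact_map  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    mu_pssm = rng.normal(0.0, separation, size=(8, 20))
    mu_hhm = rng.normal(0.0, separation, size=(8, 30))
    mod = rng.uniform(0.5, 1.0, size=8)  # per-class contact modulation
    out = []
    for rec in records:
        if rec.ss8 is None:
            raise ValueError(f"record {rec.id} has no truth labels")
        L = len(rec)
        idx = np.array([_STATE_INDEX[c] for c in rec.ss8])
        pssm = mu_pssm[idx] + noise * rng.normal(size=(L, 20))
        hhm = 1.0 / (1.0 + np.exp(-(mu_hhm[idx] + noise * rng.normal(size=(L, 30)))))
        offsets = np.abs(np.arange(L)[:, None] - np.arange(L)[None, :])
        band = np.exp(-offsets / 5.0)
        cmap = band * np.outer(mod[idx], mod[idx])
        cmap = np.clip(cmap + noise * 0.05 * rng.normal(size=(L, L)), 0.0, 1.0)
        cmap = (cmap + cmap.T) / 2.0
        from .core import one_hot_sequence

        bundle = FeatureBundle(
            aa_onehot=one_hot_sequence(rec.sequence),
            pssm=pssm,
            hhm=hhm,
            contact_window=window_contact_map(cmap, contact_window),
        )
        out.append(replace(rec, features=bundle))
    return out


# ------------------------------------------------------------------ gaps

def gapped_chain_fixture(
    record: ProteinRecord, gaps: Sequence[tuple[int, int]]
) -> ProteinRecord:
    """Delete residue segments, emulating chains with unresolved regions.

    ``gaps`` is a list of ``(start, length)`` pairs in 0-based residue
    coordinates; overlapping or out-of-range gaps raise.
    """
    L = len(record)
    covered = np.zeros(L, dtype=bool)
    for start, length in gaps:
        if length < 0 or start < 0 or start + length > L:
            raise ValueError(f"gap ({start}, {length}) outside chain of length {L}")
        if covered[start : start + length].any():
            raise ValueError(f"gap ({start}, {length}) overlaps another gap")
        covered[start : start + length] = True
    keep = ~covered
    seq = "".join(np.array(list(record.sequence))[keep])
    ss8 = None if record.ss8 is None else "".join(np.array(list(record.ss8))[keep])
    features = None
    if record.features is not None:
        f = record.features
        features = FeatureBundle(
            aa_onehot=None if f.aa_onehot is None else f.aa_onehot[keep],
            pssm=None if f.pssm is None else f.pssm[keep],
            hhm=None if f.hhm is None else f.hhm[keep],
            contact_window=None if f.contact_window is None else f.contact_window[keep],
        )
    return replace(record, sequence=seq, ss8=ss8, features=features)
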
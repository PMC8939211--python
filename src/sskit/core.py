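"""Domain types for protein secondary-structure (SS) prediction.

The eight DSSP states are kept in one canonical order, shared by label
strings, probability-matrix columns and every report in the package:

    G  3₁₀-helix        B  beta-bridge      S  high-curvature loop
    H  alpha-helix      E  beta-strand      T  beta-turn
    I  pi-helix                             C  coil

The three-state alphabet (H, E, C) is obtained by the standard grouping
{G, H, I} -> H, {B, E} -> E, {S, T, C} -> C.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "SS8_STATES",
    "SS3_STATES",
    "SS8_TO_SS3",
    "AA_ORDER",
    "MAX_LENGTH",
    "SSAlphabet",
    "FeatureBundle",
    "ProteinRecord",
    "PredictionRecord",
    "map_ss8_to_ss3",
    "one_hot_sequence",
]

#: Canonical SS8 state order. Column i of every L x 8 probability matrix
#: refers to state SS8_STATES[i]; never reorder.
SS8_STATES: tuple[str, ...] = ("G", "H", "I", "B", "E", "S", "T", "C")

#: Canonical SS3 state order (same convention for L x 3 matrices).
SS3_STATES: tuple[str, ...] = ("H", "E", "C")

#: Surjective DSSP 8-state -> 3-state grouping.
SS8_TO_SS3: dict[str, str] = {
    "G": "H", "H": "H", "I": "H",
    "B": "E", "E": "E",
    "S": "C", "T": "C", "C": "C",
}

#: Canonical order of the 20 standard amino acids used for one-hot
#: encodings and PSSM columns (alphabetical one-letter codes).
AA_ORDER: str = "ACDEFGHIKLMNPQRSTVWY"

#: Default maximum supported chain length; longer chains are rejected.
MAX_LENGTH: int = 704


@dataclass(frozen=True)
class SSAlphabet:
    """The SS8/SS3 alphabets and their grouping, as one value object."""

    ss8_states: tuple[str, ...] = SS8_STATES
    ss3_states: tuple[str, ...] = SS3_STATES
    mapping: tuple[tuple[str, str], ...] = tuple(SS8_TO_SS3.items())

    def __post_init__(self) -> None:
        m = dict(self.mapping)
        if set(m) != set(self.ss8_states):
            raise ValueError("mapping must cover every ss8 state exactly once")
        if set(m.values()) != set(self.ss3_states):
            raise ValueError("mapping must be onto the ss3 states")


def map_ss8_to_ss3(labels: str) -> str:
    """Map an SS8 label string to SS3 by the DSSP grouping.

    Raises ``ValueError`` naming the first offending position if a
    character is not a valid SS8 state.
    """
    out = []
    for i, ch in enumerate(labels):
        try:
            out.append(SS8_TO_SS3[ch])
        except KeyError:
            raise ValueError(
                f"invalid SS8 symbol {ch!r} at position {i}"
            ) from None
    return "".join(out)


def one_hot_sequence(sequence: str) -> np.ndarray:
    """L x 20 one-hot encoding of an amino-acid sequence.

    Non-standard residues (X, B, Z, U, ...) get an all-zero row so the
    matrix keeps exactly 20 columns.
    """
    idx = {aa: j for j, aa in enumerate(AA_ORDER)}
    mat = np.zeros((len(sequence), 20))
    for i, aa in enumerate(sequence.upper()):
        j = idx.get(aa)
        if j is not None:
            mat[i, j] = 1.0
    return mat


@dataclass
class FeatureBundle:
    """Per-residue input features for one chain.

    All blocks are optional; present blocks must agree on L.

    aa_onehot : L x 20 binary (rows sum to 1, or 0 for unknown residues)
    pssm      : L x 20 log-odds profile
    hhm       : L x 30 HMM profile (20 emissions + 10 transition/diversity)
    contact_window : L x W windowed contact probabilities in [0, 1]
    """

    aa_onehot: Optional[np.ndarray] = None
    pssm: Optional[np.ndarray] = None
    hhm: Optional[np.ndarray] = None
    contact_window: Optional[np.ndarray] = None

    _WIDTHS = {"aa_onehot": 20, "pssm": 20, "hhm": 30}

    def __post_init__(self) -> None:
        lengths = set()
        for name in ("aa_onehot", "pssm", "hhm", "contact_window"):
            block = getattr(self, name)
            if block is None:
                continue
            block = np.asarray(block, dtype=float)
            setattr(self, name, block)
            if block.ndim != 2:
                raise ValueError(f"{name} must be a 2-D matrix")
            want = self._WIDTHS.get(name)
            if want is not None and block.shape[1] != want:
                raise ValueError(
                    f"{name} must have {want} columns, got {block.shape[1]}"
                )
            lengths.add(block.shape[0])
        if len(lengths) > 1:
            raise ValueError(f"feature blocks disagree on length: {sorted(lengths)}")
        cw = self.contact_window
        if cw is not None and (cw.min() < 0.0 or cw.max() > 1.0):
            raise ValueError("contact_window entries must lie in [0, 1]")

    @property
    def length(self) -> Optional[int]:
        for name in ("aa_onehot", "pssm", "hhm", "contact_window"):
            block = getattr(self, name)
            if block is not None:
                return block.shape[0]
        return None


@dataclass
class ProteinRecord:
    """One protein chain: sequence, optional SS8 labels, Neff and features."""

    id: str
    sequence: str
    ss8: Optional[str] = None
    neff: Optional[float] = None
    features: Optional[FeatureBundle] = None
    max_length: int = MAX_LENGTH

    def __post_init__(self) -> None:
        L = len(self.sequence)
        if L < 1:
            raise ValueError(f"{self.id}: empty sequence")
        if L > self.max_length:
            raise ValueError(
                f"{self.id}: sequence length {L} exceeds max length {self.max_length}"
            )
        if self.ss8 is not None:
            if len(self.ss8) != L:
                raise ValueError(
                    f"{self.id}: ss8 length {len(self.ss8)} != sequence length {L}"
                )
            bad = [i for i, ch in enumerate(self.ss8) if ch not in SS8_TO_SS3]
            if bad:
                raise ValueError(
                    f"{self.id}: invalid SS8 symbol {self.ss8[bad[0]]!r} "
                    f"at position {bad[0]}"
                )
        if self.neff is not None and self.neff < 0:
            raise ValueError(f"{self.id}: neff must be non-negative")
        if self.features is not None:
            fl = self.features.length
            if fl is not None and fl != L:
                raise ValueError(
                    f"{self.id}: feature length {fl} != sequence length {L}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def ss3(self) -> Optional[str]:
        return None if self.ss8 is None else map_ss8_to_ss3(self.ss8)


@dataclass
class PredictionRecord:
    """Per-residue class-probability output of a predictor for one chain.

    ``probs8`` (and ``probs3`` when present) are row-stochastic with the
    columns in canonical state order; ``labels8`` is the per-row argmax.
    """

    id: str
    probs8: np.ndarray
    probs3: Optional[np.ndarray] = None
    _ROW_SUM_TOL = 1e-6

    def __post_init__(self) -> None:
        self.probs8 = self._check(np.asarray(self.probs8, dtype=float), 8, "probs8")
        if self.probs3 is not None:
            self.probs3 = self._check(np.asarray(self.probs3, dtype=float), 3, "probs3")
            if self.probs3.shape[0] != self.probs8.shape[0]:
                raise ValueError(f"{self.id}: probs3/probs8 length mismatch")

    def _check(self, mat: np.ndarray, k: int, name: str) -> np.ndarray:
        if mat.ndim != 2 or mat.shape[1] != k:
            raise ValueError(f"{self.id}: {name} must be L x {k}")
        if mat.shape[0] < 1:
            raise ValueError(f"{self.id}: {name} is empty")
        if mat.min() < 0:
            raise ValueError(f"{self.id}: {name} has negative probabilities")
        sums = mat.sum(axis=1)
        off = np.abs(sums - 1.0)
        if off.max() > self._ROW_SUM_TOL:
            row = int(off.argmax())
            raise ValueError(
                f"{self.id}: {name} row {row} sums to {sums[row]:.8f}, not 1"
            )
        return mat

    def __len__(self) -> int:
        return self.probs8.shape[0]

    @property
    def labels8(self) -> str:
        return "".join(SS8_STATES[j] for j in self.probs8.argmax(axis=1))

    @property
    def labels3(self) -> Optional[str]:
        if self.probs3 is None:
            return map_ss8_to_ss3(self.labels8)
        return "".join(SS3_STATES[j] for j in self.probs3.argmax(axis=1))
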
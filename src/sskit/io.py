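"""Readers and writers for the on-disk formats.

Formats handled here:

* FASTA sequences (via Biopython).
* Label files: one line per chain, ``id<TAB>ss8-string``.
* Neff files: one line per chain, ``id<TAB>value``.
* PSI-BLAST-style ASCII PSSM (the 20 log-odds columns).
* HH-suite ``.hhm`` profiles: the 20 match-emission columns plus the 10
  transition/diversity columns per residue.  Scores are stored by
  HH-suite as ``-1000 * log2(p)`` with ``*`` meaning probability zero;
  both are converted to probabilities ``2^(-score/1000)`` at read time
  (``*`` -> 0) so downstream standardisation sees probabilities.
* Square contact maps as whitespace-delimited text.
* Prediction TSV: ``id  pos  p_G ... p_C`` with a header naming the
  eight states; columns are reordered to canonical order on read.
* A YAML dataset manifest tying the pieces together.

File formats use 1-based residue numbering where the upstream standard
does (PSSM, predictions); all in-memory arrays are 0-based.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    AA_ORDER,
    MAX_LENGTH,
    FeatureBundle,
    PredictionRecord,
    ProteinRecord,
    SS8_STATES,
)

logger = logging.getLogger("sskit")

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_labels",
    "write_labels",
    "read_pssm",
    "write_pssm",
    "read_hhm",
    "write_hhm",
    "read_contact_map",
    "write_contact_map",
    "read_prediction",
    "write_prediction",
    "read_predictions",
    "write_predictions",
    "read_dataset",
    "write_dataset",
]


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-)FASTA file into an id -> sequence mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=k, description="") for k, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ------------------------------------------------------ labels and Neff

def read_labels(path: str | Path) -> dict[str, str]:
    """Read ``id<TAB>ss8`` lines."""
    out: dict[str, str] = {}
    for n, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{n}: expected 'id<TAB>labels'")
        out[parts[0]] = parts[1]
    return out


def write_labels(path: str | Path, labels: dict[str, str]) -> None:
    Path(path).write_text("".join(f"{k}\t{v}\n" for k, v in labels.items()))


def read_neff(path: str | Path) -> dict[str, float]:
    out: dict[str, float] = {}
    for n, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{n}: expected 'id<TAB>neff'")
        out[parts[0]] = float(parts[1])
    return out


def write_neff(path: str | Path, neff: dict[str, float]) -> None:
    Path(path).write_text("".join(f"{k}\t{v:.6g}\n" for k, v in neff.items()))


# ----------------------------------------------------------------- PSSM

def read_pssm(path: str | Path) -> np.ndarray:
    """Read the 20 log-odds columns of a PSI-BLAST ASCII PSSM.

    Rows look like ``  1 M  -2 -1 ...`` (position, residue, 20 values,
    optionally further columns which are ignored).  Header and footer
    lines are skipped.  A data row with fewer than 20 numeric columns is
    an error naming the line.
    """
    rows: list[list[float]] = []
    for n, line in enumerate(Path(path).read_text().splitlines(), start=1):
        parts = line.split()
        if len(parts) < 2 or not parts[0].isdigit() or len(parts[1]) != 1:
            continue  # header / footer / blank
        vals = parts[2:22]
        try:
            row = [float(v) for v in vals]
        except ValueError:
            raise ValueError(f"{path}:{n}: non-numeric PSSM entry") from None
        if len(row) != 20:
            raise ValueError(
                f"{path}:{n}: expected 20 PSSM columns, found {len(row)}"
            )
        rows.append(row)
    if not rows:
        raise ValueError(f"{path}: no PSSM rows found")
    return np.asarray(rows, dtype=float)


def write_pssm(path: str | Path, pssm: np.ndarray, sequence: Optional[str] = None) -> None:
    """Write a PSSM in the PSI-BLAST-like ASCII dialect read_pssm accepts."""
    pssm = np.asarray(pssm, dtype=float)
    if pssm.ndim != 2 or pssm.shape[1] != 20:
        raise ValueError("pssm must be L x 20")
    if sequence is None:
        sequence = "X" * pssm.shape[0]
    lines = [
        "",
        "Last position-specific scoring matrix computed",
        "            " + "   ".join(AA_ORDER),
    ]
    for i, row in enumerate(pssm):
        vals = " ".join(f"{v:.4f}" for v in row)
        lines.append(f"{i + 1} {sequence[i]} {vals}")
    Path(path).write_text("\n".join(lines) + "\n")


# ------------------------------------------------------------------ HHM

_HHM_SCALE = 1000.0


def _hhm_to_prob(token: str) -> float:
    if token == "*":
        return 0.0
    return float(2.0 ** (-float(token) / _HHM_SCALE))


def _prob_to_hhm(p: float) -> str:
    if p <= 0.0:
        return "*"
    return str(int(round(-_HHM_SCALE * math.log2(p))))


def read_hhm(path: str | Path) -> np.ndarray:
    """Read an HH-suite ``.hhm`` profile into an L x 30 probability matrix.

    Columns 0..19 are match emissions in AA_ORDER, columns 20..29 the
    transition/diversity block.  ``*`` entries map to probability 0.
    """
    lines = Path(path).read_text().splitlines()
    declared_len: Optional[int] = None
    start = None
    for i, line in enumerate(lines):
        if line.startswith("LENG"):
            declared_len = int(line.split()[1])
        if line.startswith("HMM\t") or line.startswith("HMM "):
            start = i
            break
    if start is None:
        raise ValueError(f"{path}: no HMM block found")
    # skip the HMM header line, the transition-name line and the
    # begin-state transition line
    i = start + 3
    rows: list[list[float]] = []
    while i < len(lines) and not lines[i].startswith("//"):
        em = lines[i].split()
        tr = lines[i + 1].split() if i + 1 < len(lines) else []
        if len(em) < 22 or len(tr) < 10:
            raise ValueError(f"{path}: truncated profile at line {i + 1}")
        # em = [aa, pos, 20 scores, pos]; tr = 10 scores
        row = [_hhm_to_prob(t) for t in em[2:22]] + [_hhm_to_prob(t) for t in tr[:10]]
        rows.append(row)
        i += 2
    if not rows:
        raise ValueError(f"{path}: empty HMM block")
    if declared_len is not None and declared_len != len(rows):
        raise ValueError(
            f"{path}: header declares {declared_len} residues, found {len(rows)}"
        )
    return np.asarray(rows, dtype=float)


def write_hhm(path: str | Path, hhm: np.ndarray, sequence: Optional[str] = None) -> None:
    """Write an L x 30 probability matrix in the ``.hhm`` dialect."""
    hhm = np.asarray(hhm, dtype=float)
    if hhm.ndim != 2 or hhm.shape[1] != 30:
        raise ValueError("hhm must be L x 30")
    L = hhm.shape[0]
    if sequence is None:
        sequence = "X" * L
    lines = [
        "HHsearch 1.5",
        f"LENG  {L}",
        "HMM    " + "\t".join(AA_ORDER),
        "       M->M\tM->I\tM->D\tI->M\tI->I\tD->M\tD->D\tNeff\tNeff_I\tNeff_D",
        "       0\t*\t*\t*\t*\t*\t*\t*\t*\t*",
    ]
    for i in range(L):
        em = "\t".join(_prob_to_hhm(p) for p in hhm[i, :20])
        tr = "\t".join(_prob_to_hhm(p) for p in hhm[i, 20:])
        lines.append(f"{sequence[i]} {i + 1}\t{em}\t{i + 1}")
        lines.append(f"\t{tr}")
    lines.append("//")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------- contact map

def read_contact_map(path: str | Path) -> np.ndarray:
    mat = np.loadtxt(str(path), ndmin=2)
    if mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{path}: contact map must be square, got {mat.shape}")
    if mat.min() < 0 or mat.max() > 1:
        raise ValueError(f"{path}: contact probabilities must lie in [0, 1]")
    return mat


def write_contact_map(path: str | Path, cmap: np.ndarray) -> None:
    np.savetxt(str(path), np.asarray(cmap, dtype=float), fmt="%.6f")


# ----------------------------------------------------------- predictions

_PRED_HEADER = ["id", "pos"] + [f"p_{s}" for s in SS8_STATES]


def write_prediction(path: str | Path, pred: PredictionRecord) -> None:
    write_predictions(path, [pred])


def write_predictions(path: str | Path, preds: Iterable[PredictionRecord]) -> None:
    lines = ["\t".join(_PRED_HEADER)]
    for pred in preds:
        for i, row in enumerate(pred.probs8):
            vals = "\t".join(f"{p:.8f}" for p in row)
            lines.append(f"{pred.id}\t{i + 1}\t{vals}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_predictions(path: str | Path) -> dict[str, PredictionRecord]:
    """Read a prediction TSV; state columns are matched by header name and
    reordered to canonical order, so shuffled columns round-trip."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty prediction file")
    header = lines[0].split("\t")
    if header[:2] != ["id", "pos"]:
        raise ValueError(f"{path}: prediction header must start with 'id\\tpos'")
    try:
        order = [header.index(f"p_{s}") for s in SS8_STATES]
    except ValueError:
        missing = [s for s in SS8_STATES if f"p_{s}" not in header]
        raise ValueError(f"{path}: missing probability columns for {missing}") from None
    by_id: dict[str, list[list[float]]] = {}
    for n, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        try:
            row = [float(parts[j]) for j in order]
        except (ValueError, IndexError):
            raise ValueError(f"{path}:{n}: malformed prediction row") from None
        by_id.setdefault(parts[0], []).append(row)
    # PredictionRecord validates non-negativity and row sums
    return {k: PredictionRecord(id=k, probs8=np.asarray(v)) for k, v in by_id.items()}


def read_prediction(path: str | Path, chain_id: str) -> PredictionRecord:
    preds = read_predictions(path)
    if chain_id not in preds:
        raise KeyError(f"{path}: no prediction for chain {chain_id!r}")
    return preds[chain_id]


# -------------------------------------------------------------- dataset

def read_dataset(path: str | Path, max_length: int = MAX_LENGTH) -> list[ProteinRecord]:
    """Load a dataset from a YAML manifest.

    The manifest names a FASTA file, a label file and, optionally, a
    Neff file and per-chain feature directories::

        fasta: sequences.fasta
        labels: labels.tsv        # optional
        neff: neff.tsv            # optional
        features:                 # optional; files named <id>.<ext>
          pssm_dir: pssm
          hhm_dir: hhm
          cmap_dir: cmap

    Records violating an invariant (length mismatch, invalid symbol,
    over-long chain, broken feature file) are skipped with a logged
    warning; a missing manifest or FASTA is fatal.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    manifest = yaml.safe_load(path.read_text())
    base = path.parent
    sequences = read_fasta(base / manifest["fasta"])
    labels = read_labels(base / manifest["labels"]) if manifest.get("labels") else {}
    neff = read_neff(base / manifest["neff"]) if manifest.get("neff") else {}
    feat = manifest.get("features") or {}

    records: list[ProteinRecord] = []
    for cid, seq in sequences.items():
        try:
            bundle = None
            blocks: dict[str, np.ndarray] = {}
            if feat.get("pssm_dir"):
                blocks["pssm"] = read_pssm(base / feat["pssm_dir"] / f"{cid}.pssm")
            if feat.get("hhm_dir"):
                blocks["hhm"] = read_hhm(base / feat["hhm_dir"] / f"{cid}.hhm")
            if feat.get("cmap_dir"):
                from .model import window_contact_map  # noqa: PLC0415 (cycle)

                cmap = read_contact_map(base / feat["cmap_dir"] / f"{cid}.cmap")
                blocks["contact_window"] = window_contact_map(
                    cmap, int(feat.get("contact_window", 50))
                )
            if blocks:
                from .core import one_hot_sequence

                blocks["aa_onehot"] = one_hot_sequence(seq)
                bundle = FeatureBundle(**blocks)
            records.append(
                ProteinRecord(
                    id=cid,
                    sequence=seq,
                    ss8=labels.get(cid),
                    neff=neff.get(cid),
                    features=bundle,
                    max_length=max_length,
                )
            )
        except (ValueError, FileNotFoundError) as exc:
            logger.warning("skipping record %s: %s", cid, exc)
    return records


def write_dataset(
    out_dir: str | Path,
    records: Sequence[ProteinRecord],
    predictions: Optional[dict[str, Sequence[PredictionRecord]]] = None,
) -> Path:
    """Write records (and optional named prediction sets) as a complete
    on-disk dataset; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(out / "sequences.fasta", {r.id: r.sequence for r in records})
    manifest: dict = {"fasta": "sequences.fasta"}
    labelled = {r.id: r.ss8 for r in records if r.ss8 is not None}
    if labelled:
        write_labels(out / "labels.tsv", labelled)
        manifest["labels"] = "labels.tsv"
    neff = {r.id: r.neff for r in records if r.neff is not None}
    if neff:
        write_neff(out / "neff.tsv", neff)
        manifest["neff"] = "neff.tsv"
    have_pssm = any(r.features is not None and r.features.pssm is not None for r in records)
    have_hhm = any(r.features is not None and r.features.hhm is not None for r in records)
    if have_pssm or have_hhm:
        manifest["features"] = {}
    if have_pssm:
        (out / "pssm").mkdir(exist_ok=True)
        for r in records:
            if r.features is not None and r.features.pssm is not None:
                write_pssm(out / "pssm" / f"{r.id}.pssm", r.features.pssm, r.sequence)
        manifest["features"]["pssm_dir"] = "pssm"
    if have_hhm:
        (out / "hhm").mkdir(exist_ok=True)
        for r in records:
            if r.features is not None and r.features.hhm is not None:
                write_hhm(out / "hhm" / f"{r.id}.hhm", r.features.hhm, r.sequence)
        manifest["features"]["hhm_dir"] = "hhm"
    if predictions:
        for name, preds in predictions.items():
            write_predictions(out / f"predictions_{name}.tsv", preds)
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return out / "manifest.yaml"
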
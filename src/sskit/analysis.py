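"""Orchestration of predictor-comparison studies.

A study compares a baseline predictor against one or more rivals on a
common chain set: residue-level pooled metric tables, sequence-level
paired permutation tests per class and for the macro/overall metrics
(both one-sided directions, so a significantly *worse* baseline is
reported too), Cohen's d with its qualitative label, Neff-stratified
comparisons and tidy-table exports for boxplots.

Guard rules: chains where a metric is UNDEFINED are dropped pairwise
before testing; a cell with fewer than ``min_n`` (default 20) retained
pairs is not tested and renders as a dash.  Neff bins take the floor of
each chain's Neff and bins with fewer than ``min_bin`` (default 20)
chains are excluded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import PredictionRecord, ProteinRecord, SS8_STATES
from .metrics import (
    UNDEFINED,
    MetricReport,
    evaluate_residue_level,
    evaluate_sequence_level,
)
from .stats import NotRun, PairedComparison, guarded_test

__all__ = [
    "StudyConfig",
    "ComparisonCell",
    "ComparisonStudy",
    "NeffBin",
    "run_comparison",
    "neff_analysis",
    "export_boxplot_data",
    "flag_poor_chains",
    "study_to_table",
]

#: default metric grid: overall metrics + per-class AGM
DEFAULT_METRICS = ("macro_agm", "macro_f1", "q8") + tuple(
    f"agm:{s}" for s in SS8_STATES
)


@dataclass(frozen=True)
class StudyConfig:
    metrics: tuple[str, ...] = DEFAULT_METRICS
    alpha: float = 0.01
    min_n: int = 20
    r_permutations: int = 9999
    seed: int = 0


@dataclass
class ComparisonCell:
    """Baseline-vs-rival result for one metric."""

    metric: str
    rival: str
    greater: PairedComparison | NotRun  # H1: baseline mean > rival mean
    less: PairedComparison | NotRun     # H1: baseline mean < rival mean

    @property
    def marker(self) -> str:
        """'better' / 'worse' at alpha, '' when not significant,
        '-' when the sample guard blocked the test."""
        if isinstance(self.greater, NotRun):
            return "-"
        if self.greater.significant:
            return "better"
        if self.less.significant:
            return "worse"
        return ""

    @property
    def d(self) -> Optional[float]:
        return None if isinstance(self.greater, NotRun) else self.greater.d

    @property
    def n(self) -> int:
        return self.greater.n


@dataclass
class ComparisonStudy:
    baseline: str
    rivals: tuple[str, ...]
    config: StudyConfig
    residue_reports: dict[str, MetricReport]
    sequence_values: dict[str, dict[str, dict[str, Optional[float]]]]
    cells: list[ComparisonCell]
    n_tests: int


def _check_coverage(
    records: Sequence[ProteinRecord],
    predictions_by_name: dict[str, dict[str, PredictionRecord]],
) -> None:
    ids = {r.id for r in records}
    for name, preds in predictions_by_name.items():
        missing = ids - set(preds)
        if missing:
            raise KeyError(
                f"predictor {name!r} is missing {len(missing)} chains "
                f"(e.g. {sorted(missing)[:3]})"
            )


def run_comparison(
    records: Sequence[ProteinRecord],
    predictions_by_name: dict[str, dict[str, PredictionRecord]],
    config: StudyConfig = StudyConfig(),
) -> ComparisonStudy:
    """Compare the first-named predictor against every other one.

    For each selected metric, sequence-level vectors are built per
    predictor, UNDEFINED chains dropped pairwise, and the guarded paired
    permutation test run in both one-sided directions at ``alpha``.
    Residue-level pooled reports are attached per predictor.
    """
    names = list(predictions_by_name)
    if len(names) < 2:
        raise ValueError("need at least 2 predictors to compare")
    _check_coverage(records, predictions_by_name)
    baseline, rivals = names[0], names[1:]
    residue_reports = {
        name: evaluate_residue_level(records, preds)
        for name, preds in predictions_by_name.items()
    }
    sequence_values = {
        name: {
            metric: evaluate_sequence_level(records, preds, metric)
            for metric in config.metrics
        }
        for name, preds in predictions_by_name.items()
    }
    cells = []
    n_tests = 0
    for rival in rivals:
        for metric in config.metrics:
            va = sequence_values[baseline][metric]
            vb = sequence_values[rival][metric]
            pairs = {cid: (va[cid], vb[cid]) for cid in va}
            greater = guarded_test(
                pairs, alternative="greater", min_n=config.min_n,
                alpha=config.alpha, r=config.r_permutations, seed=config.seed,
            )
            less = guarded_test(
                pairs, alternative="less", min_n=config.min_n,
                alpha=config.alpha, r=config.r_permutations, seed=config.seed,
            )
            if not isinstance(greater, NotRun):
                n_tests += 2
            cells.append(ComparisonCell(metric=metric, rival=rival,
                                        greater=greater, less=less))
    return ComparisonStudy(
        baseline=baseline,
        rivals=tuple(rivals),
        config=config,
        residue_reports=residue_reports,
        sequence_values=sequence_values,
        cells=cells,
        n_tests=n_tests,
    )


# ------------------------------------------------------------- Neff bins

@dataclass
class NeffBin:
    """Chains sharing floor(Neff), with per-predictor mean macro-AGM."""

    neff_value: int
    chain_ids: tuple[str, ...]
    mean_macro_agm: dict[str, float]
    comparisons: dict[str, PairedComparison | NotRun]

    @property
    def n(self) -> int:
        return len(self.chain_ids)


def neff_analysis(
    records: Sequence[ProteinRecord],
    predictions_by_name: dict[str, dict[str, PredictionRecord]],
    min_bin: int = 20,
    config: StudyConfig = StudyConfig(),
) -> list[NeffBin]:
    """Group chains by floor(Neff); per bin, report each predictor's mean
    sequence-level macro-AGM and test baseline > rival.

    Bins with fewer than ``min_bin`` chains are dropped.  Chains without
    a Neff value are ignored; if none carries one, raise.
    """
    names = list(predictions_by_name)
    _check_coverage(records, predictions_by_name)
    with_neff = [r for r in records if r.neff is not None]
    if not with_neff:
        raise ValueError("no record carries a Neff value")
    values = {
        name: evaluate_sequence_level(with_neff, preds, "macro_agm")
        for name, preds in predictions_by_name.items()
    }
    by_bin: dict[int, list[ProteinRecord]] = {}
    for rec in with_neff:
        by_bin.setdefault(int(np.floor(rec.neff)), []).append(rec)
    bins = []
    baseline = names[0]
    for neff_value in sorted(by_bin):
        members = by_bin[neff_value]
        if len(members) < min_bin:
            continue
        ids = tuple(r.id for r in members)
        means = {}
        for name in names:
            vals = [values[name][cid] for cid in ids]
            defined = [v for v in vals if v is not UNDEFINED]
            means[name] = float(np.mean(defined)) if defined else float("nan")
        comparisons = {}
        for rival in names[1:]:
            pairs = {
                cid: (values[baseline][cid], values[rival][cid]) for cid in ids
            }
            comparisons[rival] = guarded_test(
                pairs, alternative="greater", min_n=min_bin,
                alpha=config.alpha, r=config.r_permutations, seed=config.seed,
            )
        bins.append(
            NeffBin(neff_value=neff_value, chain_ids=ids,
                    mean_macro_agm=means, comparisons=comparisons)
        )
    return bins


# ---------------------------------------------------------- tidy exports

def export_boxplot_data(
    sequence_values: dict[str, dict[str, Optional[float]]],
    metric: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy per-chain table + summary stats for boxplot rendering.

    ``sequence_values`` maps predictor -> chain -> value.  Returns
    (tidy, summary): tidy has columns (chain, predictor, metric, value)
    with UNDEFINED rows excluded; summary has per-predictor n, mean, sd,
    median, q1, q3 and the count of excluded UNDEFINED chains.
    """
    rows = []
    excluded: dict[str, int] = {}
    for predictor, values in sequence_values.items():
        excluded[predictor] = 0
        for cid, v in values.items():
            if v is UNDEFINED:
                excluded[predictor] += 1
            else:
                rows.append(
                    {"chain": cid, "predictor": predictor, "metric": metric, "value": v}
                )
    tidy = pd.DataFrame(rows, columns=["chain", "predictor", "metric", "value"])
    if tidy.empty:
        raise ValueError("no defined values to export")
    summary = (
        tidy.groupby("predictor")["value"]
        .agg(
            n="count",
            mean="mean",
            sd=lambda s: s.std(ddof=1),
            median="median",
            q1=lambda s: s.quantile(0.25),
            q3=lambda s: s.quantile(0.75),
        )
        .reset_index()
    )
    summary["n_undefined"] = summary["predictor"].map(excluded)
    summary["metric"] = metric
    return tidy, summary


def flag_poor_chains(
    study: ComparisonStudy, threshold: float = 0.3
) -> list[str]:
    """Chains on which *every* predictor's sequence-level macro-AGM is
    below ``threshold`` — candidates for data defects such as unresolved
    residues in the source structures."""
    names = [study.baseline, *study.rivals]
    per_name = {n: study.sequence_values[n].get("macro_agm", {}) for n in names}
    if not per_name[study.baseline]:
        return []
    flagged = []
    for cid in per_name[study.baseline]:
        vals = [per_name[n].get(cid) for n in names]
        if all(v is not UNDEFINED and v is not None and v < threshold for v in vals):
            flagged.append(cid)
    return flagged


# -------------------------------------------------------------- rendering

def study_to_table(study: ComparisonStudy) -> pd.DataFrame:
    """Flatten the comparison grid; NOT-RUN cells carry '-' markers."""
    rows = []
    for cell in study.cells:
        if isinstance(cell.greater, NotRun):
            rows.append(
                {
                    "metric": cell.metric, "rival": cell.rival, "n": cell.greater.n,
                    "p_greater": "-", "p_less": "-", "d": "-",
                    "effect": "-", "marker": "-",
                }
            )
        else:
            rows.append(
                {
                    "metric": cell.metric, "rival": cell.rival, "n": cell.greater.n,
                    "p_greater": cell.greater.p_value,
                    "p_less": cell.less.p_value,
                    "d": "-" if cell.greater.d is None else cell.greater.d,
                    "effect": cell.greater.interpretation or "-",
                    "marker": cell.marker,
                }
            )
    return pd.DataFrame(rows)


def study_to_json(study: ComparisonStudy) -> str:
    table = study_to_table(study)
    return json.dumps(
        {
            "baseline": study.baseline,
            "rivals": list(study.rivals),
            "alpha": study.config.alpha,
            "min_n": study.config.min_n,
            "n_tests_run": study.n_tests,
            "cells": table.to_dict(orient="records"),
        },
        indent=2,
    )
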
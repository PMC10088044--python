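"""Baseline summarization and the two-proteome benchmark metrics.

Baselines: target-decoy PSM FDR filtering, Top3 protein summarization
(mean of the three most abundant PSMs per protein and sample; two PSMs are
also averaged; one or zero PSMs yield a missing value), and a Welch t-test
with Benjamini-Hochberg correction as the significance comparator.

Benchmark metrics mirror the two-proteome mixture evaluation: the
discrimination curve (differential foreground proteins vs background
proteins as the significance cutoff sweeps), the calibration curve
(observed background fraction at each estimated q-value threshold) and the
per-species fold-change bias of point estimates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats_io import QuantTable

__all__ = [
    "ProteinMatrix",
    "psm_fdr_filter",
    "top3_summarize",
    "ttest_bh_baseline",
    "bh_adjust",
    "discrimination_curve",
    "foreground_at_background",
    "calibration_curve",
    "fold_change_bias",
    "run_synthetic_benchmark",
    "TTestResult",
]

MISSING = math.nan


@dataclass
class ProteinMatrix:
    """Protein-by-run abundance matrix with species annotations."""

    proteins: list[str]
    runs: list[str]
    values: np.ndarray  # shape (n_proteins, n_runs); NaN = missing
    species: dict[str, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape != (len(self.proteins), len(self.runs)):
            raise ValueError("values shape must be (n_proteins, n_runs)")
        present = self.values[np.isfinite(self.values)]
        if present.size and present.min() < 0:
            raise ValueError("abundances must be non-negative where present")


def psm_fdr_filter(table: QuantTable, fdr: float) -> QuantTable:
    """Target-decoy PSM-level FDR filter.

    q-values use the +1 decoy correction, ``q(s) = (#decoys >= s + 1) /
    (#targets >= s)``, monotonized so that q never increases with score;
    targets with q <= ``fdr`` are retained and decoys are removed.
    """
    if not (0.0 < fdr < 1.0):
        raise ValueError("fdr must be in (0, 1)")
    is_decoy = np.array([r.is_decoy for r in table.records], bool)
    if not is_decoy.any():
        raise ValueError("no decoy records; target-decoy filtering impossible")
    scores = np.array([r.search_score for r in table.records], float)
    order = np.argsort(-scores, kind="stable")
    n_targets = 0
    n_decoys = 0
    fdr_est = np.empty(len(order))
    for rank, idx in enumerate(order):
        if is_decoy[idx]:
            n_decoys += 1
        else:
            n_targets += 1
        fdr_est[rank] = (n_decoys + 1) / max(n_targets, 1)
    qvals_ranked = np.minimum.accumulate(fdr_est[::-1])[::-1]
    q = np.empty(len(order))
    q[order] = qvals_ranked
    kept = [
        rec
        for rec, qi, dec in zip(table.records, q, is_decoy)
        if not dec and qi <= fdr
    ]
    return QuantTable(kept)


def top3_summarize(table: QuantTable, *, fdr_filtered: bool = True) -> ProteinMatrix:
    """Top3: mean of the three most abundant PSMs per (protein, run).

    Exactly two PSMs are averaged as well; one or zero PSMs give a missing
    value.  The caller is expected to FDR-filter the PSMs first
    (``fdr_filtered`` asserts that contract).
    """
    if not fdr_filtered:
        raise ValueError("Top3 expects an FDR-filtered table (see psm_fdr_filter)")
    runs = QuantTable(table.records).runs
    run_idx = {r: i for i, r in enumerate(runs)}
    per_cell: dict[str, dict[int, list[float]]] = {}
    species: dict[str, str | None] = {}
    for rec in table.records:
        if rec.intensity is None:
            continue
        for acc in rec.protein_ids:
            per_cell.setdefault(acc, {}).setdefault(
                run_idx[rec.run_id], []
            ).append(rec.intensity)
            if acc not in species:
                import re

                m = re.search(r"_([A-Z0-9]+)$", acc)
                species[acc] = m.group(1) if m else None
    proteins = sorted(per_cell)
    values = np.full((len(proteins), len(runs)), MISSING)
    for i, acc in enumerate(proteins):
        for j, intensities in per_cell[acc].items():
            top = sorted(intensities, reverse=True)[:3]
            if len(top) >= 2:
                values[i, j] = float(np.mean(top))
    return ProteinMatrix(proteins, runs, values, species)


@dataclass
class TTestResult:
    protein_id: str
    species_tag: str | None
    estimate: float  # log2 fold change (condition A - condition B)
    p_value: float
    adjusted_p: float = math.nan
    tested: bool = True


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, original order preserved."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    if p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ttest_bh_baseline(
    matrix: ProteinMatrix,
    design: Mapping[str, str],
    *,
    log_transform: bool = True,
) -> list[TTestResult]:
    """Welch two-sample t-test per protein with BH correction.

    The estimate is the difference of condition means on the log2 scale
    (condition labels sorted; first minus second).  Proteins with fewer than
    two non-missing values in either condition, or zero variance in both,
    are reported untested (NaN p).
    """
    conds = sorted(set(design.values()))
    if len(conds) != 2:
        raise ValueError("design must have exactly two conditions")
    cols_a = [j for j, r in enumerate(matrix.runs) if design[r] == conds[0]]
    cols_b = [j for j, r in enumerate(matrix.runs) if design[r] == conds[1]]
    results: list[TTestResult] = []
    for i, acc in enumerate(matrix.proteins):
        row = matrix.values[i]
        a = row[cols_a]
        b = row[cols_b]
        a = a[np.isfinite(a)]
        b = b[np.isfinite(b)]
        if log_transform:
            a, b = np.log2(a), np.log2(b)
        if len(a) < 2 or len(b) < 2:
            results.append(
                TTestResult(acc, matrix.species.get(acc), math.nan, math.nan,
                            tested=False)
            )
            continue
        estimate = float(a.mean() - b.mean())
        if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
            results.append(
                TTestResult(acc, matrix.species.get(acc), estimate, math.nan,
                            tested=False)
            )
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat = stats.ttest_ind(a, b, equal_var=False)
        results.append(
            TTestResult(acc, matrix.species.get(acc), estimate,
                        float(stat.pvalue))
        )
    tested = [r for r in results if r.tested]
    if tested:
        adjusted = bh_adjust([r.p_value for r in tested])
        for r, adj in zip(tested, adjusted):
            r.adjusted_p = float(adj)
    return results


def discrimination_curve(
    labels: Sequence[str | None], background_tag: str
) -> list[tuple[int, int]]:
    """Cumulative (background, foreground) counts along a significance ranking.

    ``labels`` are species tags sorted most significant first; anything that
    is not the background tag counts as foreground (unknown tags warn).
    """
    points: list[tuple[int, int]] = []
    n_bg = 0
    n_fg = 0
    for tag in labels:
        if tag == background_tag:
            n_bg += 1
        else:
            if tag is None:
                warnings.warn("unknown species tag counted as foreground",
                              stacklevel=2)
            n_fg += 1
        points.append((n_bg, n_fg))
    return points


def foreground_at_background(
    points: Sequence[tuple[int, int]], n_background: int
) -> int:
    """Foreground count on the curve when ``n_background`` is first reached."""
    best = 0
    for bg, fg in points:
        if bg > n_background:
            break
        best = fg
    return best


def calibration_curve(
    qvalues: Sequence[float],
    labels: Sequence[str | None],
    background_tag: str,
    thresholds: Sequence[float],
) -> list[tuple[float, float]]:
    """Observed background fraction among proteins with q <= t, per threshold.

    Thresholds where nothing is reported are omitted.
    """
    q = np.asarray(qvalues, float)
    if q.size and (q.min() < 0 or q.max() > 1):
        raise ValueError("q-values must be in [0, 1]")
    tags = np.array([lab if lab is not None else "" for lab in labels])
    points: list[tuple[float, float]] = []
    for t in thresholds:
        mask = q <= t
        n = int(mask.sum())
        if n == 0:
            continue
        frac = float((tags[mask] == background_tag).sum() / n)
        points.append((float(t), frac))
    return points


def run_synthetic_benchmark(
    seed: int,
    *,
    config=None,
    tau: float = 0.51,
    q_threshold: float = 0.05,
    background_tag: str = "HUMAN",
    psm_fdr: float = 0.01,
) -> dict:
    """One full benchmark replicate on synthetic two-proteome data.

    Simulates a dataset, runs the Bayesian engine and the Top3 + Welch/BH
    baseline, and returns the headline metrics: per-species fold-change MAP
    medians, the observed background fraction at ``q <= q_threshold``, and
    both methods' discrimination-curve foreground counts at 50 background
    proteins.  ``tau`` is used both as the engine's fold-change evaluation
    threshold and as the baseline's fold-change cutoff.
    """
    from .model import quantify
    from .synthetic_data import default_lfqbench_config, simulate_dataset

    if config is None:
        config = default_lfqbench_config(seed)
    table, truth = simulate_dataset(config)
    results = quantify(table, fold_change_eval=tau)

    labels = {r.protein_id: r.species_tag for r in results}
    estimates = {r.protein_id: r.log2_fc_map for r in results}
    species_truth = {
        sp: config.true_log2_fc(sp) for sp in config.n_proteins
    }
    bias = fold_change_bias(estimates, labels, species_truth)

    qvals = np.array([r.q_value for r in results])
    tags = np.array([r.species_tag for r in results])
    reported = qvals <= q_threshold
    background_fraction = (
        float((tags[reported] == background_tag).mean())
        if reported.any()
        else math.nan
    )

    engine_curve = discrimination_curve(
        [r.species_tag for r in results], background_tag
    )
    filtered = psm_fdr_filter(table, psm_fdr)
    baseline = ttest_bh_baseline(top3_summarize(filtered), table.conditions)
    passing = sorted(
        (r for r in baseline if r.tested and abs(r.estimate) >= tau),
        key=lambda r: (r.adjusted_p, r.protein_id),
    )
    baseline_curve = discrimination_curve(
        [r.species_tag for r in passing], background_tag
    )
    return {
        "results": results,
        "truth": truth,
        "median_fc_map": {sp: bias[sp][0] + species_truth[sp] for sp in bias},
        "fold_change_bias": bias,
        "n_reported": int(reported.sum()),
        "background_fraction": background_fraction,
        "engine_foreground_at_50": foreground_at_background(engine_curve, 50),
        "baseline_foreground_at_50": foreground_at_background(baseline_curve, 50),
    }


def fold_change_bias(
    estimates: Mapping[str, float],
    labels: Mapping[str, str],
    truth: Mapping[str, float],
) -> dict[str, tuple[float, float]]:
    """Per-species (median bias, IQR) of fold-change point estimates.

    ``estimates`` maps protein -> estimated log2 fc, ``labels`` maps protein
    -> species tag, ``truth`` maps species tag -> true log2 fc.
    """
    per_species: dict[str, list[float]] = {}
    for acc, est in estimates.items():
        tag = labels[acc]
        if tag not in truth:
            raise KeyError(f"species {tag!r} missing from truth")
        per_species.setdefault(tag, []).append(est - truth[tag])
    out: dict[str, tuple[float, float]] = {}
    for tag, errors in per_species.items():
        arr = np.asarray(errors, float)
        q25, q75 = np.percentile(arr, [25.0, 75.0])
        out[tag] = (float(np.median(arr)), float(q75 - q25))
    return out
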
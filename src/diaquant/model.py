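"""The Bayesian protein-quantification engine.

Peptide-level evidence is never thresholded.  Each PSM enters a mixture
likelihood: with probability ``1 - pep`` (pep = identification posterior
error probability, estimated from target/decoy score distributions) the
observation reflects the protein's log10 abundance ``x`` with Gaussian
multiplicative noise and censored-normal missingness; with probability
``pep`` it is an incorrect identification, explained by a uniform
background over the abundance grid.

Per (protein, run), peptide likelihoods are multiplied with the protein
prior on a uniform log10 grid.  Condition means are formed by exact
discrete convolution of the independent per-run posteriors, the fold-change
posterior is the distribution of the difference of condition means
(converted to log2), the differential posterior error probability is the
mass within ±tau of zero, MAP point estimates are grid argmaxes, and
q-values are running means of sorted PEPs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from .formats_io import PsmRecord, QuantTable
from .priors import (
    Hyperparameters,
    LOG2_PER_LOG10,
    fit_hyperparameters,
    fold_change_eval_lower_bound,
)

__all__ = [
    "PosteriorGrid",
    "ProteinResult",
    "best_psm_per_precursor",
    "drop_shared_peptides",
    "identification_pep",
    "peptide_likelihood",
    "peptide_log_likelihood",
    "protein_posterior",
    "fold_change_posterior",
    "differential_pep",
    "map_estimate",
    "qvalues_from_peps",
    "quantify",
]

_SPACING_RTOL = 1e-9
_MASS_TOL = 1e-6


@dataclass
class PosteriorGrid:
    """A discretized probability distribution on a uniform abscissa.

    ``abscissa`` is strictly increasing and uniformly spaced (log10
    abundance or log2 fold change, stated per use); ``mass`` sums to one.
    """

    abscissa: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        self.abscissa = np.asarray(self.abscissa, float)
        self.mass = np.asarray(self.mass, float)
        if self.abscissa.ndim != 1 or self.abscissa.shape != self.mass.shape:
            raise ValueError("abscissa and mass must be 1-D and equal length")
        if len(self.abscissa) > 1:
            steps = np.diff(self.abscissa)
            if steps.min() <= 0:
                raise ValueError("abscissa must be strictly increasing")
            h = steps.mean()
            if np.abs(steps - h).max() > 1e-12 + _SPACING_RTOL * abs(h):
                raise ValueError("abscissa must be uniformly spaced")
        if self.mass.min() < 0:
            raise ValueError("mass must be non-negative")
        total = self.mass.sum()
        if not math.isfinite(total) or total <= 0:
            raise ValueError("mass must have positive finite total")
        if abs(total - 1.0) > _MASS_TOL:
            raise ValueError("mass must sum to 1 within 1e-6")

    @property
    def spacing(self) -> float:
        if len(self.abscissa) < 2:
            raise ValueError("spacing undefined for a single-point grid")
        return float(self.abscissa[1] - self.abscissa[0])

    def mean(self) -> float:
        return float(np.dot(self.abscissa, self.mass))

    def sd(self) -> float:
        m = self.mean()
        return float(math.sqrt(np.dot((self.abscissa - m) ** 2, self.mass)))


@dataclass
class ProteinResult:
    """Per-protein output of the engine."""

    protein_id: str
    species_tag: str | None
    n_peptides: int
    map_abundance_per_sample: dict[str, float]
    log2_fc_map: float
    differential_pep: float
    q_value: float = math.nan

    def __post_init__(self) -> None:
        if not (0.0 <= self.differential_pep <= 1.0):
            raise ValueError("differential_pep must be in [0, 1]")


# ---------------------------------------------------------------------------
# input reduction


def best_psm_per_precursor(table: QuantTable) -> QuantTable:
    """Keep one record per (peptide, charge, run): the highest search score,
    ties broken by higher intensity, then by input order."""
    best: dict[tuple[str, int, str], PsmRecord] = {}
    for rec in table.records:
        key = (rec.peptide, rec.charge, rec.run_id)
        cur = best.get(key)
        if cur is None:
            best[key] = rec
            continue
        new_int = -math.inf if rec.intensity is None else rec.intensity
        cur_int = -math.inf if cur.intensity is None else cur.intensity
        if (rec.search_score, new_int) > (cur.search_score, cur_int):
            best[key] = rec
    kept = set(map(id, best.values()))
    return QuantTable([r for r in table.records if id(r) in kept])


def drop_shared_peptides(table: QuantTable) -> tuple[QuantTable, int]:
    """Remove records attributed to more than one protein.

    Returns the reduced table and the number of removed rows.
    """
    kept = [r for r in table.records if len(r.protein_ids) == 1]
    return QuantTable(kept), len(table.records) - len(kept)


# ---------------------------------------------------------------------------
# identification error probabilities


def identification_pep(
    table: QuantTable,
    *,
    decoy_factor: float = 1.0,
    n_bins: int | None = None,
) -> np.ndarray:
    """Posterior error probability per record from target/decoy scores.

    The decoy score distribution models incorrect identifications; within
    score bins the decoy/target count ratio (divided by ``decoy_factor``,
    the decoy-to-incorrect-target ratio of the database) estimates the local
    FDR, which is then made non-increasing in score by isotonic regression.
    Entrapment hits count as targets.  Returns an array aligned with
    ``table.records``; decoy records get PEP 1.0.
    """
    scores = np.array([r.search_score for r in table.records], float)
    is_decoy = np.array([r.is_decoy for r in table.records], bool)
    if not is_decoy.any():
        raise ValueError(
            "no decoy records: supply decoys (or entrapment proxies) or "
            "PEP-bearing input"
        )
    t_scores = scores[~is_decoy]
    d_scores = scores[is_decoy]
    if n_bins is None:
        n_bins = int(np.clip(len(t_scores) // 50, 10, 200))
    edges = np.quantile(np.concatenate([t_scores, d_scores]),
                        np.linspace(0.0, 1.0, n_bins + 1))
    edges = np.unique(edges)
    edges[0], edges[-1] = -np.inf, np.inf
    t_counts, _ = np.histogram(t_scores, bins=edges)
    d_counts, _ = np.histogram(d_scores, bins=edges)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (d_counts / decoy_factor) / np.maximum(t_counts, 1)
    raw = np.clip(raw, 0.0, 1.0)
    centers = np.array(
        [t_scores.min() - 1.0]
        + [0.5 * (edges[i] + edges[i + 1]) for i in range(1, len(edges) - 2)]
        + [t_scores.max() + 1.0]
    )
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=False,
                             out_of_bounds="clip")
    weights = np.maximum(t_counts + d_counts, 1)
    iso.fit(centers, raw, sample_weight=weights)
    peps = iso.predict(scores)
    peps[is_decoy] = 1.0
    return peps


# ---------------------------------------------------------------------------
# likelihood and posteriors


def peptide_log_likelihood(
    observation: float | None,
    pep: float,
    grid: np.ndarray,
    hyper: Hyperparameters,
) -> np.ndarray:
    """Log of :func:`peptide_likelihood`, computed without underflow.

    The correct-identification component is evaluated with log-pdf/log-cdf
    primitives and combined with the uniform background via logaddexp, so
    observations many noise-widths away from a grid point keep a finite,
    meaningful log likelihood.
    """
    grid = np.asarray(grid, float)
    if grid.size == 0:
        raise ValueError("grid must be non-empty")
    if not (0.0 <= pep <= 1.0):
        raise ValueError("pep must be in [0, 1]")
    span = grid[-1] - grid[0] if len(grid) > 1 else 1.0
    background = 1.0 / span if span > 0 else 1.0
    if observation is None:
        log_correct = stats.norm.logcdf((hyper.mu_m - grid) / hyper.sigma_m)
    else:
        y = float(observation)
        if not math.isfinite(y):
            raise ValueError("observation must be finite or None")
        log_correct = stats.norm.logsf(
            (hyper.mu_m - y) / hyper.sigma_m
        ) + stats.norm.logpdf(y, grid, hyper.sigma_noise)
    if pep == 0.0:
        return log_correct
    if pep == 1.0:
        return np.full_like(grid, math.log(background))
    return np.logaddexp(
        math.log1p(-pep) + log_correct, math.log(pep * background)
    )


def peptide_likelihood(
    observation: float | None,
    pep: float,
    grid: np.ndarray,
    hyper: Hyperparameters,
) -> np.ndarray:
    """Mixture likelihood of one peptide observation over the abundance grid.

    Observed y (log10): ``(1-pep) * (1 - Phi((mu_m-y)/sigma_m)) *
    Normal(y; x, sigma_noise) + pep * U``; missing: ``(1-pep) *
    Phi((mu_m-x)/sigma_m) + pep * U`` with U the uniform density over the
    grid range.
    """
    return np.exp(peptide_log_likelihood(observation, pep, grid, hyper))


def protein_posterior(
    peptide_likelihoods: Sequence[np.ndarray],
    grid: np.ndarray,
    prior_mean: float,
    prior_sd: float,
    *,
    log_space: bool = False,
) -> PosteriorGrid:
    """Grid posterior: prior density times the product of peptide likelihoods.

    Accumulated in log space with max-subtraction to avoid underflow; pass
    ``log_space=True`` with :func:`peptide_log_likelihood` values to keep
    the whole chain in log space (required when observations sit many noise
    widths apart, where linear-space densities underflow to zero).
    """
    if len(peptide_likelihoods) == 0:
        raise ValueError("need at least one peptide likelihood")
    grid = np.asarray(grid, float)
    log_post = stats.norm.logpdf(grid, prior_mean, prior_sd)
    with np.errstate(divide="ignore"):
        for lik in peptide_likelihoods:
            lik = np.asarray(lik, float)
            if lik.shape != grid.shape:
                raise ValueError("all likelihoods must live on the same grid")
            log_post = log_post + (lik if log_space else np.log(lik))
    log_post -= log_post.max()
    mass = np.exp(log_post)
    total = mass.sum()
    if not math.isfinite(total) or total <= 0:
        raise FloatingPointError("degenerate posterior (all-zero product)")
    return PosteriorGrid(grid, mass / total)


def _check_shared_spacing(grids: Sequence[PosteriorGrid]) -> float:
    spacings = [g.spacing for g in grids if len(g.abscissa) > 1]
    if not spacings:
        raise ValueError("need at least one multi-point grid")
    h = spacings[0]
    for s in spacings[1:]:
        if abs(s - h) > 1e-12 + _SPACING_RTOL * abs(h):
            raise ValueError("grids must share spacing")
    return h


def _convolve_sum(posteriors: Sequence[PosteriorGrid]) -> tuple[float, np.ndarray]:
    """Distribution of the sum of independent grid distributions sharing
    spacing; returns (start abscissa, mass)."""
    start = 0.0
    mass = np.array([1.0])
    for post in posteriors:
        start += float(post.abscissa[0])
        mass = np.convolve(mass, post.mass)
    return start, mass


def fold_change_posterior(
    cond_a: Sequence[PosteriorGrid],
    cond_b: Sequence[PosteriorGrid],
) -> PosteriorGrid:
    """Posterior of the log2 fold change between two conditions.

    The condition means are ``(X_1 + ... + X_N)/N`` with independent
    per-sample posteriors on a shared log10 grid spacing; the difference of
    the two means is computed by exact discrete convolution on the common
    lattice and converted from log10 to log2 units.
    """
    if len(cond_a) == 0 or len(cond_b) == 0:
        raise ValueError("both conditions need at least one sample posterior")
    h = _check_shared_spacing(list(cond_a) + list(cond_b))
    # starts must sit on a common lattice for the convolution to be exact
    all_grids = list(cond_a) + list(cond_b)
    ref = all_grids[0].abscissa[0]
    for g in all_grids[1:]:
        offset = (g.abscissa[0] - ref) / h
        if abs(offset - round(offset)) > 1e-6:
            raise ValueError("grids must be aligned on a common lattice")

    n_a, n_b = len(cond_a), len(cond_b)
    start_a, mass_a = _convolve_sum(cond_a)
    start_b, mass_b = _convolve_sum(cond_b)
    lcm = math.lcm(n_a, n_b)
    step_a, step_b = lcm // n_a, lcm // n_b
    fine = h / lcm
    if step_a == step_b == 1:
        mass_d = np.convolve(mass_a, mass_b[::-1])
    else:
        n_lattice = step_a * (len(mass_a) - 1) + step_b * (len(mass_b) - 1) + 1
        mass_d = np.zeros(n_lattice)
        idx_a = step_a * np.arange(len(mass_a))
        idx_b = step_b * np.arange(len(mass_b))
        for j, mb in enumerate(mass_b):
            if mb > 0.0:
                np.add.at(mass_d, idx_a + (idx_b[-1] - idx_b[j]), mass_a * mb)
    start = start_a / n_a - (start_b + h * (len(mass_b) - 1)) / n_b
    abscissa = (start + fine * np.arange(len(mass_d))) * LOG2_PER_LOG10
    total = mass_d.sum()
    return PosteriorGrid(abscissa, mass_d / total)


def differential_pep(fc_posterior: PosteriorGrid, tau: float) -> float:
    """Posterior probability that |log2 fold change| <= tau.

    Grid cells straddling the band boundary contribute the overlapping
    fraction of their cell (half-cell interpolation).
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    x = fc_posterior.abscissa
    if len(x) == 1:
        return float(abs(x[0]) <= tau)
    h = fc_posterior.spacing
    lo = np.maximum(x - h / 2.0, -tau)
    hi = np.minimum(x + h / 2.0, tau)
    frac = np.clip((hi - lo) / h, 0.0, 1.0)
    return float(np.clip(np.dot(frac, fc_posterior.mass), 0.0, 1.0))


def map_estimate(grid: PosteriorGrid) -> float:
    """Abscissa of maximal mass; exact ties resolve to the smaller abscissa."""
    return float(grid.abscissa[int(np.argmax(grid.mass))])


def qvalues_from_peps(peps: Sequence[float]) -> np.ndarray:
    """q-values as running means of sorted PEPs, mapped back to input order.

    The running mean of the ascending PEPs estimates the FDR among the most
    confident items at each rank; monotonicity is enforced before mapping
    back.
    """
    peps = np.asarray(peps, float)
    if peps.size and (peps.min() < 0 or peps.max() > 1):
        raise ValueError("all PEPs must be in [0, 1]")
    if peps.size == 0:
        return np.array([])
    order = np.argsort(peps, kind="stable")
    sorted_peps = peps[order]
    running = np.cumsum(sorted_peps) / np.arange(1, len(peps) + 1)
    running = np.maximum.accumulate(running)
    out = np.empty_like(running)
    out[order] = running
    return out


# ---------------------------------------------------------------------------
# pipeline


def _species_tag(accession: str) -> str | None:
    import re

    m = re.search(r"_([A-Z0-9]+)$", accession)
    return m.group(1) if m else None


def _build_grid(values: np.ndarray, hyper: Hyperparameters, spacing: float) -> np.ndarray:
    center = float(np.median(values))
    half = max(5.0 * hyper.sigma_y, 5.0 * hyper.sigma_noise, 2.0)
    lo = min(center - half, float(values.min()) - 0.5)
    hi = max(center + half, float(values.max()) + 0.5)
    n = int(math.ceil((hi - lo) / spacing)) + 1
    return lo + spacing * np.arange(n)


def _trim(post: PosteriorGrid, tail: float = 1e-12) -> PosteriorGrid:
    """Drop negligible tails so downstream convolutions stay small."""
    c = np.cumsum(post.mass)
    lo = int(np.searchsorted(c, tail))
    hi = int(np.searchsorted(c, 1.0 - tail)) + 1
    lo, hi = max(lo, 0), min(max(hi, lo + 2), len(post.mass))
    mass = post.mass[lo:hi]
    return PosteriorGrid(post.abscissa[lo:hi], mass / mass.sum())


def quantify(
    table: QuantTable,
    *,
    hyperparams: Hyperparameters | None = None,
    fold_change_eval: float | str = "auto",
    grid_spacing: float = 0.01,
    missing_value_prior: str = "DIA",
    normalize: str = "none",
    decoy_factor: float = 1.0,
    verbose: bool = False,
) -> list[ProteinResult]:
    """Run the full engine on a two-condition PSM table.

    Reduces to best PSM per precursor, estimates identification PEPs from
    decoys, removes shared peptides and decoys, median-centers runs, fits
    hyperparameters (unless given), computes per-(protein, run) posteriors,
    fold-change posteriors, differential PEPs at tau (``fold_change_eval``;
    "auto" derives the Eq.-style lower bound from sigma_y and N and prints
    it) and PEP-averaged q-values.  Results are sorted by differential PEP.
    """
    table = best_psm_per_precursor(table)
    peps = identification_pep(table, decoy_factor=decoy_factor)

    records: list[PsmRecord] = []
    rec_peps: list[float] = []
    for rec, pep in zip(table.records, peps):
        if rec.is_decoy or len(rec.protein_ids) != 1:
            continue
        records.append(rec)
        rec_peps.append(float(pep))
    if not records:
        raise ValueError("no usable target records")

    conditions = QuantTable(records).conditions
    runs = QuantTable(records).runs
    cond_labels = sorted(set(conditions.values()))
    if len(cond_labels) != 2:
        raise ValueError("quantify requires exactly two conditions")
    cond_a, cond_b = cond_labels

    # optional run-level normalization: median-centering equalizes loading
    # differences, but on engineered mixtures whose composition changes
    # between conditions the run medians are not comparable and centering
    # would shift every fold change, so it is off by default
    if normalize == "median":
        obs_by_run: dict[str, list[float]] = {r: [] for r in runs}
        for rec in records:
            if rec.intensity is not None:
                obs_by_run[rec.run_id].append(math.log10(rec.intensity))
        run_median = {
            r: float(np.median(v)) if v else 0.0 for r, v in obs_by_run.items()
        }
        centered = QuantTable(
            [
                rec
                if rec.intensity is None
                else PsmRecord(
                    rec.run_id,
                    rec.condition,
                    rec.charge,
                    rec.search_score,
                    10.0 ** (math.log10(rec.intensity) - run_median[rec.run_id]),
                    rec.peptide,
                    rec.protein_ids,
                    rec.is_decoy,
                    rec.is_entrapment,
                )
                for rec in records
            ]
        )
    elif normalize == "none":
        centered = QuantTable(records)
    else:
        raise ValueError("normalize must be 'none' or 'median'")

    if hyperparams is None:
        # decoys are needed for the PEP-filtered hyperparameter fit; rebuild
        # a centered table that still carries them
        decoys = [r for r in table.records if r.is_decoy]
        hyperparams = fit_hyperparameters(
            QuantTable(centered.records + decoys),
            missing_value_prior=missing_value_prior,
            center_runs=False,
        )
    hyper = hyperparams

    n_per_cond = QuantTable(records).n_samples_per_condition
    if fold_change_eval == "auto":
        tau = fold_change_eval_lower_bound(hyper.sigma_y, min(n_per_cond.values()))
        print(f"fold_change_eval (auto, Eq.-1 lower bound): {tau:.4f}")
    else:
        tau = float(fold_change_eval)
    if verbose:
        print(f"hyperparameters: {hyper}")

    # organize observations per protein
    by_protein: dict[str, dict[str, dict[str, tuple[float | None, float]]]] = {}
    for rec, pep in zip(centered.records, rec_peps):
        protein = rec.protein_ids[0]
        pep_map = by_protein.setdefault(protein, {})
        run_map = pep_map.setdefault(rec.peptide, {})
        y = None if rec.intensity is None else math.log10(rec.intensity)
        # best-PSM reduction leaves one record per (peptide, charge, run);
        # multiple charges of a peptide in one run count as separate evidence
        key = f"{rec.run_id}\x00{rec.charge}"
        run_map[key] = (y, pep, rec.run_id)

    # Peptides of one protein differ by a fixed ionization efficiency, so
    # they disagree about the absolute abundance while agreeing about its
    # profile across runs.  The engine therefore works per protein in
    # relative space: each peptide is centered by its observed mean (an
    # estimate of its ionization constant, which cancels in fold changes),
    # the censoring anchor mu_m is shifted by the same constant, and the
    # likelihood width carries the plug-in penalty sqrt(1 + 1/n_obs).
    grid = _build_grid(
        np.array([0.0]), hyper, grid_spacing
    )

    from dataclasses import replace as _replace

    runs_by_cond = {c: [r for r in runs if conditions[r] == c] for c in cond_labels}
    results: list[ProteinResult] = []
    for protein in sorted(by_protein):
        pep_map = by_protein[protein]
        pep_hyper: dict[str, Hyperparameters] = {}
        pep_center: dict[str, float] = {}
        for peptide, slots in pep_map.items():
            observed = [v[0] for v in slots.values() if v[0] is not None]
            if observed:
                c_i = float(np.mean(observed))
                width = hyper.sigma_noise * math.sqrt(1.0 + 1.0 / len(observed))
            else:  # only missing markers ever recorded for this peptide
                c_i = hyper.mu_y
                width = hyper.sigma_noise * math.sqrt(2.0)
            pep_center[peptide] = c_i
            pep_hyper[peptide] = _replace(
                hyper, mu_m=hyper.mu_m - c_i, sigma_noise=width
            )
        level = float(np.mean(list(pep_center.values())))

        run_posts: dict[str, PosteriorGrid] = {}
        for run in runs:
            liks = []
            for peptide, slots in pep_map.items():
                h_i = pep_hyper[peptide]
                c_i = pep_center[peptide]
                present = [v for v in slots.values() if v[2] == run]
                if present:
                    for y, pep, _ in present:
                        y_rel = None if y is None else y - c_i
                        liks.append(
                            peptide_log_likelihood(y_rel, pep, grid, h_i)
                        )
                else:
                    # peptide never recorded in this run: a missing slot;
                    # carry the peptide's best identification confidence
                    best_pep = min(v[1] for v in slots.values())
                    liks.append(
                        peptide_log_likelihood(None, best_pep, grid, h_i)
                    )
            run_posts[run] = _trim(
                protein_posterior(liks, grid, 0.0, hyper.sigma_y, log_space=True)
            )
        posts_a = [run_posts[r] for r in runs_by_cond[cond_a]]
        posts_b = [run_posts[r] for r in runs_by_cond[cond_b]]
        if not posts_a or not posts_b:
            continue
        fc_post = fold_change_posterior(posts_a, posts_b)
        d_pep = differential_pep(fc_post, tau)
        results.append(
            ProteinResult(
                protein_id=protein,
                species_tag=_species_tag(protein),
                n_peptides=len(pep_map),
                map_abundance_per_sample={
                    run: map_estimate(post) + level
                    for run, post in run_posts.items()
                },
                log2_fc_map=map_estimate(fc_post),
                differential_pep=d_pep,
            )
        )

    results.sort(key=lambda r: (r.differential_pep, r.protein_id))
    qvals = qvalues_from_peps([r.differential_pep for r in results])
    for res, q in zip(results, qvals):
        res.q_value = float(q)
    return results
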
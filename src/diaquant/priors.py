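"""Hyperparameter estimation for the Bayesian quantification engine.

All fitting happens on log10 intensities.  Four groups of hyperparameters
are estimated from the PSM table itself:

* the censored-normal missing-value curve ``P(missing | log10 intensity x)
  = Phi((mu_m - x) / sigma_m)``, with separate fitting procedures for
  DDA-like data (censored maximum likelihood over all XIC values) and for
  the low-missingness DIA regime (a truncated-binomial probit anchored on
  the observed means of the peptide groups in which the missing values
  occurred);
* the within-(peptide, condition) multiplicative noise scale ``sigma_noise``;
* the protein prior ``Normal(mu_y, sigma_y)`` over log10 relative abundance;
* the advisable lower bound for the fold-change evaluation threshold tau,
  chosen so that the central 99% of the null fold-change distribution
  (difference of two condition means under the protein prior) lies within
  +/- tau.

:func:`fit_hyperparameters` orchestrates the above: when decoys are
present it first discards PSMs whose identification posterior error
probability exceeds a cutoff, so that incorrect identifications do not
contaminate the hyperparameter fits (the engine itself still consumes all
PSMs; only the estimation step is filtered).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .formats_io import QuantTable

__all__ = [
    "Hyperparameters",
    "MissingnessFitError",
    "fit_missing_value_prior",
    "estimate_protein_prior",
    "fit_hyperparameters",
    "fold_change_eval_lower_bound",
    "noise_structure_diagnostic",
    "NoiseDiagnostic",
    "LOG2_PER_LOG10",
]

#: Unit conversion: one log10 unit equals log2(10) log2 units.
LOG2_PER_LOG10 = math.log2(10.0)


def _group_mean_difference_factor(n_samples: int) -> float:
    """Null fold-change sd as a multiple of sigma_y: the difference of two
    independent group means of N samples each has sd sigma_y * sqrt(2/N)."""
    return math.sqrt(2.0 / n_samples)


class MissingnessFitError(ValueError):
    """Raised when the missingness curve cannot be fitted from the data."""


@dataclass
class Hyperparameters:
    """Fitted priors of the quantification model (log10 units throughout,
    except ``fold_change_eval`` which is in log2 units)."""

    mu_m: float
    sigma_m: float
    sigma_noise: float
    mu_y: float
    sigma_y: float
    fold_change_eval: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_m <= 0 or self.sigma_noise <= 0 or self.sigma_y <= 0:
            raise ValueError("all sigma hyperparameters must be positive")
        if self.fold_change_eval < 0:
            raise ValueError("fold_change_eval must be >= 0")


def _target_frame(table: QuantTable) -> pd.DataFrame:
    df = table.to_dataframe()
    return df[~df["is_decoy"]].copy()


def _slot_summary(df: pd.DataFrame, excluded_slots=None) -> pd.DataFrame:
    """Per (peptide, condition): observed-value anchor and slot counts.

    A slot is one (peptide, run) pair; once a peptide is seen anywhere it is
    expected in every run of a condition, so runs without an observed record
    count as missing.  ``excluded_slots`` are (peptide, run) pairs whose only
    records were discarded (e.g. as likely incorrect identifications): those
    slots are removed from the accounting entirely, being neither trustworthy
    observations nor evidence of censoring.
    """
    run_cond = df.drop_duplicates("run")[["run", "condition"]]
    runs_per_cond = run_cond.groupby("condition")["run"].count()
    cond_of_run = dict(zip(run_cond["run"], run_cond["condition"]))

    obs = df[df["intensity"].notna()].copy()
    obs["x"] = np.log10(obs["intensity"].astype(float))
    grouped = obs.groupby(["peptide", "condition"], sort=True)
    out = grouped["x"].mean().rename("anchor").to_frame()
    out["n_obs_runs"] = (
        obs.drop_duplicates(["peptide", "run"])
        .groupby(["peptide", "condition"], sort=True)["run"]
        .count()
    )
    out = out.reset_index()
    out["n_slots"] = out["condition"].map(runs_per_cond).astype(float)

    n_excluded = pd.Series(0.0, index=out.index)
    if excluded_slots:
        counts: dict[tuple[str, str], int] = {}
        for peptide, run in excluded_slots:
            cond = cond_of_run.get(run)
            if cond is not None:
                counts[(peptide, cond)] = counts.get((peptide, cond), 0) + 1
        keys = list(zip(out["peptide"], out["condition"]))
        n_excluded = pd.Series([counts.get(k, 0) for k in keys], dtype=float)
    out["n_excluded"] = n_excluded
    out["n_missing"] = np.maximum(
        out["n_slots"] - out["n_obs_runs"] - out["n_excluded"], 0.0
    )
    return out


def fit_missing_value_prior(
    table: QuantTable,
    mode: str = "DIA",
    *,
    sigma_noise: float | None = None,
    excluded_slots=None,
    min_missing: int = 10,
    fallback_sigma_m: float = 2.0,
) -> tuple[float, float]:
    """Fit the censored-normal missingness curve ``Phi((mu_m - x)/sigma_m)``.

    ``mode="DDA"`` fits a censored normal by maximum likelihood over all
    observed log10 XIC values jointly with the total missingness count.
    ``mode="DIA"`` (the low-missingness regime) instead ties the sparse
    missing events to the abundance level at which they occurred: a binomial
    probit of per-slot missingness on the mean observed log10 intensity of
    each (peptide, condition) group, conditioned on the group being visible
    at all (at least one observed slot) so that fully censored groups do not
    silently flatten the curve.  When ``sigma_noise`` is supplied, the
    within-group replicate noise is deconvolved from the fitted scale so
    that sigma_m describes the per-value censoring curve.

    Raises :class:`MissingnessFitError` when the table contains no missing
    values; falls back to a wide ``sigma_m`` (with a warning) when fewer
    than ``min_missing`` missing observations are available.
    """
    if mode not in ("DDA", "DIA"):
        raise ValueError("mode must be 'DDA' or 'DIA'")
    df = _target_frame(table)
    if df["intensity"].notna().sum() == 0:
        raise MissingnessFitError("no observed intensities in table")

    slots = _slot_summary(df, excluded_slots)
    n_missing_total = int(slots["n_missing"].sum())
    x_obs = np.log10(
        df.loc[df["intensity"].notna(), "intensity"].astype(float).to_numpy()
    )
    if n_missing_total == 0:
        raise MissingnessFitError(
            "table contains no missing values; cannot fit the missingness "
            "curve — supply a default missing-value prior instead"
        )
    if n_missing_total < min_missing:
        warnings.warn(
            f"only {n_missing_total} missing observations (<{min_missing}); "
            "falling back to a wide-sigma_m missing-value prior",
            stacklevel=2,
        )
        return float(np.percentile(x_obs, 1.0)), fallback_sigma_m

    if mode == "DDA":
        mu_m, sigma_m = _fit_missing_dda(x_obs, n_missing_total)
    else:
        mu_m, sigma_m = _fit_missing_dia(slots, sigma_noise)
    # keep the censoring midpoint inside the observed intensity range
    mu_m = float(np.clip(mu_m, x_obs.min(), x_obs.max()))
    return mu_m, float(sigma_m)


def _minimize_multistart(nll, starts) -> np.ndarray:
    best = None
    for start in starts:
        res = optimize.minimize(
            nll,
            np.asarray(start, float),
            method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-7, "fatol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best.x


def _fit_missing_dda(x_obs: np.ndarray, n_missing: int) -> tuple[float, float]:
    """Censored-normal ML: underlying x ~ Normal(mu_x, sigma_x), observed
    with probability 1 - Phi((mu_m - x)/sigma_m); missing slots enter
    through the marginal missing probability."""

    def nll(params: np.ndarray) -> float:
        mu_x, log_sx, mu_m, log_sm = params
        sx, sm = math.exp(log_sx), math.exp(log_sm)
        log_obs = stats.norm.logpdf(x_obs, mu_x, sx) + stats.norm.logsf(
            mu_m - x_obs, 0.0, sm
        )
        p_miss = stats.norm.cdf(mu_m - mu_x, 0.0, math.hypot(sx, sm))
        p_miss = min(max(p_miss, 1e-300), 1.0 - 1e-12)
        return -(log_obs.sum() + n_missing * math.log(p_miss))

    base = [x_obs.mean(), math.log(max(x_obs.std(), 1e-3))]
    starts = [
        base + [np.percentile(x_obs, 1), math.log(0.5)],
        base + [np.percentile(x_obs, 10), math.log(0.3)],
        base + [x_obs.mean(), math.log(1.0)],
    ]
    mu_x, log_sx, mu_m, log_sm = _minimize_multistart(nll, starts)
    return float(mu_m), float(math.exp(log_sm))


def _fit_missing_dia(
    slots: pd.DataFrame,
    sigma_noise: float | None,
    outlier_fraction: float = 0.01,
) -> tuple[float, float]:
    """Truncated-binomial probit of missingness on group anchors.

    Each (peptide, condition) group contributes a binomial likelihood for
    its missing/observed slot pattern at its anchor, conditioned on the
    group being visible.  A small outlier component (a free binomial at the
    marginal missing rate, weight ``outlier_fraction``) keeps groups whose
    anchor is corrupted — e.g. by a residual incorrect identification —
    from exerting leverage on the censoring curve.
    """
    keep = np.isfinite(slots["anchor"].to_numpy(float))
    anchors = slots["anchor"].to_numpy(float)[keep]
    n_miss = slots["n_missing"].to_numpy(float)[keep]
    n_obs = slots["n_obs_runs"].to_numpy(float)[keep]
    n_eff = n_obs + n_miss
    extra_var = 0.0 if sigma_noise is None else float(sigma_noise) ** 2
    rate = n_miss.sum() / max(n_miss.sum() + n_obs.sum(), 1.0)
    rate = min(max(rate, 1e-12), 1.0 - 1e-12)
    log_bg = n_miss * math.log(rate) + n_obs * math.log1p(-rate)
    eps = outlier_fraction

    def nll(params: np.ndarray) -> float:
        mu_m, log_sm = params
        scale = math.sqrt(math.exp(log_sm) ** 2 + extra_var)
        z = (mu_m - anchors) / scale
        logp = stats.norm.logcdf(z)
        logq = stats.norm.logsf(z)
        # condition each group on being visible: 1 - p^n
        log_vis = np.log1p(-np.exp(np.minimum(n_eff * logp, -1e-12)))
        log_model = n_miss * logp + n_obs * logq - log_vis
        if eps <= 0.0:
            return -float(log_model.sum())
        mixed = np.logaddexp(
            math.log1p(-eps) + log_model, math.log(eps) + log_bg
        )
        return -float(mixed.sum())

    mu0 = np.quantile(anchors, min(max(2.0 * rate, 0.01), 0.5))
    mu_m, log_sm = _minimize_multistart(
        nll, [[mu0, math.log(0.5)], [anchors.min(), math.log(1.0)]]
    )
    return float(mu_m), float(math.exp(log_sm))


def _pooled_noise_sd(df: pd.DataFrame, sigma_floor: float) -> float:
    """Robust pooled within-(peptide, condition) sd of log10 intensities.

    Uses the median of per-group variances within each degrees-of-freedom
    class, corrected by the chi-square median so the estimator is unbiased
    for Gaussian noise yet insensitive to a small fraction of contaminated
    groups (incorrect identifications).
    """
    grp = df.groupby(["peptide", "condition"])["x"]
    sizes = grp.size()
    variances = grp.var(ddof=1)
    mask = sizes >= 2
    if not mask.any():
        return sigma_floor
    var = variances[mask].to_numpy(float)
    dof = (sizes[mask] - 1).to_numpy(int)
    estimates = []
    weights = []
    for df_class in np.unique(dof):
        sel = var[dof == df_class]
        correction = stats.chi2.ppf(0.5, df_class) / df_class
        estimates.append(float(np.median(sel)) / correction)
        weights.append(float(df_class * len(sel)))
    pooled = float(np.average(estimates, weights=weights))
    if pooled <= sigma_floor**2:
        warnings.warn("within-group variance at floor", stacklevel=3)
    return max(math.sqrt(max(pooled, 0.0)), sigma_floor)


def estimate_protein_prior(
    table: QuantTable,
    *,
    center_runs: bool = True,
    sigma_floor: float = 1e-3,
    use_species_tags: bool = True,
) -> tuple[float, float, float]:
    """Estimate (mu_y, sigma_y, sigma_noise) from the PSM table.

    ``sigma_noise`` is the pooled within-(peptide, condition) standard
    deviation of log10 intensities across replicate runs.  ``mu_y`` is the
    mean of per-protein mean log10 relative intensities (after median
    centering each run unless ``center_runs=False``).  ``sigma_y`` is the
    between-protein spread of those means after subtracting the estimated
    within-protein sampling variance (peptide-to-peptide ionization spread
    divided by the peptide count), so that it reflects protein-level spread
    rather than peptide sampling noise.  When UniProt-style species suffixes
    are parseable for (nearly) all proteins — an engineered multi-species
    mixture — protein means are centered per species first, so the known
    mixture design does not inflate the biological prior spread.
    """
    df = table.to_dataframe()
    df = df[~df["is_decoy"] & df["intensity"].notna()].copy()
    if df.empty:
        raise ValueError("no observed intensities in table")
    df["protein"] = df["proteins"].str.split(";").str[0]
    if df["protein"].nunique() < 2:
        raise ValueError("need >= 2 proteins with quantified peptides")
    df["x"] = np.log10(df["intensity"].astype(float))
    if center_runs:
        df["x"] = df["x"] - df.groupby("run")["x"].transform("median")

    sigma_noise = _pooled_noise_sd(df, sigma_floor)

    # per-(protein, peptide) means, then per-protein summaries
    pep_means = df.groupby(["protein", "peptide"])["x"].mean()
    prot = pep_means.groupby("protein").agg(["mean", "var", "count"])
    mu_y = float(prot["mean"].mean())

    means = prot["mean"].to_numpy(float)
    k = prot["count"].to_numpy(float)
    within = prot["var"].to_numpy(float)  # NaN where a protein has 1 peptide
    finite = within[np.isfinite(within)]
    pooled_within = float(np.median(finite)) if finite.size else 0.0
    # winsorize so a few contaminated proteins cannot dominate the correction
    if finite.size:
        cap = 5.0 * max(pooled_within, sigma_floor**2)
        within = np.minimum(np.where(np.isfinite(within), within, pooled_within), cap)
    else:
        within = np.zeros_like(means)

    centered = means.copy()
    if use_species_tags:
        species = prot.index.str.extract(r"_([A-Z0-9]+)$", expand=False)
        tagged = species.notna()
        if tagged.mean() >= 0.9 and species[tagged].nunique() > 1:
            sp = pd.Series(centered, index=prot.index)
            sp_means = sp.groupby(species).transform("mean")
            centered = (sp - sp_means + sp.mean()).to_numpy(float)

    between = float(np.var(centered, ddof=1))
    sampling = float(np.mean(within / np.maximum(k, 1.0)))
    var_y = between - sampling
    if var_y <= sigma_floor**2:
        warnings.warn("protein prior variance at floor", stacklevel=2)
    sigma_y = max(math.sqrt(max(var_y, 0.0)), sigma_floor)
    return mu_y, sigma_y, sigma_noise


def fit_hyperparameters(
    table: QuantTable,
    *,
    missing_value_prior: str = "DIA",
    pep_filter: float = 0.2,
    center_runs: bool = True,
    coverage: float = 0.99,
) -> Hyperparameters:
    """Fit all hyperparameters from a PSM table in one pass.

    When the table carries decoys, identification PEPs are estimated first
    and PSMs with PEP above ``pep_filter`` are discarded for the purpose of
    hyperparameter estimation only (their slots are excluded from the
    missingness accounting rather than counted as censored).  The engine
    itself never thresholds PSMs; this filter only protects the prior fits
    from contamination by incorrect identifications.
    """
    from .model import best_psm_per_precursor, identification_pep

    table = best_psm_per_precursor(table)
    excluded: list[tuple[str, str]] = []
    records = [r for r in table.records if not r.is_decoy]
    if any(r.is_decoy for r in table.records):
        peps = identification_pep(table)
        kept = []
        removed_pairs = set()
        for rec, pep in zip(table.records, peps):
            if rec.is_decoy:
                continue
            if pep <= pep_filter:
                kept.append(rec)
            else:
                removed_pairs.add((rec.peptide, rec.run_id))
        observed_pairs = {(r.peptide, r.run_id) for r in kept}
        excluded = sorted(removed_pairs - observed_pairs)
        records = kept
    clean = QuantTable(records)

    mu_y, sigma_y, sigma_noise = estimate_protein_prior(
        clean, center_runs=center_runs
    )
    try:
        mu_m, sigma_m = fit_missing_value_prior(
            clean,
            missing_value_prior,
            sigma_noise=sigma_noise,
            excluded_slots=excluded,
        )
    except MissingnessFitError:
        x = np.log10(
            [r.intensity for r in clean.records if r.intensity is not None]
        )
        mu_m, sigma_m = float(np.percentile(x, 1.0)) - 1.0, 2.0

    n = min(clean.n_samples_per_condition.values())
    tau = fold_change_eval_lower_bound(sigma_y, n, coverage=coverage)
    return Hyperparameters(
        mu_m=mu_m,
        sigma_m=sigma_m,
        sigma_noise=sigma_noise,
        mu_y=mu_y,
        sigma_y=sigma_y,
        fold_change_eval=tau,
    )


def fold_change_eval_lower_bound(
    sigma_y: float, n_samples: int, *, coverage: float = 0.99
) -> float:
    """Smallest tau (log2) containing the central 99% of the null fold change.

    Under the protein prior, the difference of two independent condition
    means of ``n_samples`` each is Normal with sd
    ``sigma_y * sqrt(2/n_samples)`` in log10 units; the bound is the
    two-sided 99% half-width of that normal converted to log2 units.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if sigma_y < 0:
        raise ValueError("sigma_y must be >= 0")
    z = stats.norm.ppf(0.5 + coverage / 2.0)
    return float(
        z * sigma_y * _group_mean_difference_factor(n_samples) * LOG2_PER_LOG10
    )


@dataclass
class NoiseDiagnostic:
    slope: float
    intercept: float
    r_squared: float


def noise_structure_diagnostic(table: QuantTable) -> NoiseDiagnostic:
    """Check that noise is multiplicative on the raw intensity scale.

    Regresses the within-(peptide, condition) standard deviation of raw
    intensities on the group mean; a clearly positive slope with a decent
    fit indicates sd proportional to mean, i.e. multiplicative noise.
    Groups with fewer than two observed intensities are excluded.
    """
    df = table.to_dataframe()
    df = df[~df["is_decoy"] & df["intensity"].notna()]
    grp = df.groupby(["peptide", "condition"])["intensity"]
    sizes = grp.size()
    means = grp.mean()[sizes >= 2]
    sds = grp.std(ddof=1)[sizes >= 2]
    if len(means) < 2:
        raise ValueError("no (peptide, condition) group with >= 2 observations")
    res = stats.linregress(means.to_numpy(float), sds.to_numpy(float))
    return NoiseDiagnostic(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )
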
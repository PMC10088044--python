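"""Synthetic two-proteome-mixture benchmark data with full ground truth.

Emulates the HYE124 LFQBench design: two conditions measured in triplicate,
each a known w/w mixture of human, yeast and E. coli proteins (sample A:
65/30/5, sample B: 65/15/20), so every protein's true log2 fold change is
fixed by its species.  The generative model embodies exactly the
assumptions the engine makes: protein base log10 abundance drawn from
Normal(mu_y, sigma_y) plus the log10 mixture fraction of its
species/condition; a fixed per-peptide ionization offset; multiplicative
(log-normal) within-run noise of scale sigma_noise; intensity-dependent
censoring to missing with probability Phi((mu_m - x)/sigma_m); a fraction
of PSMs replaced by incorrect identifications (intensity resampled from the
global pool, score drawn from the decoy score law); and appended decoy
PSMs for target-decoy calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .formats_io import PsmRecord, QuantTable

__all__ = [
    "SimConfig",
    "SimTruth",
    "expected_log2_fc",
    "simulate_dataset",
    "default_lfqbench_config",
]

_AA_BODY = "ACDEFGHILMNQSTVWY"  # no K/R/P: keeps generated peptides tryptic


def expected_log2_fc(frac_a: float, frac_b: float) -> float:
    """True log2 fold change implied by the w/w mixture fractions."""
    if frac_a <= 0 or frac_b <= 0:
        raise ValueError("fractions must be positive")
    return math.log2(frac_a / frac_b)


@dataclass
class SimConfig:
    """Generator settings; defaults are the benchmark's study conditions."""

    n_proteins: dict[str, int]
    fractions: dict[str, dict[str, float]]  # condition -> species -> w/w
    n_replicates: int = 3
    peptides_per_protein: tuple = ("poisson", 6.0)
    mu_y: float = 6.0
    sigma_y: float = 0.4
    sigma_noise: float = 0.1
    peptide_offset_sd: float = 0.5
    mu_m: float = 4.0
    sigma_m: float = 0.4
    id_error_rate: float = 0.05
    decoy_multiplier: int = 1
    score_correct: tuple[float, float] = (3.0, 1.0)
    score_incorrect: tuple[float, float] = (1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_proteins or any(n < 1 for n in self.n_proteins.values()):
            raise ValueError("each species needs a positive protein count")
        for cond, fracs in self.fractions.items():
            if set(fracs) != set(self.n_proteins):
                raise ValueError(f"fractions for {cond!r} must cover all species")
            if abs(sum(fracs.values()) - 1.0) > 1e-9:
                raise ValueError(f"fractions for {cond!r} must sum to 1")
            if any(f <= 0 for f in fracs.values()):
                raise ValueError("fractions must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for name in ("sigma_y", "sigma_noise", "sigma_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.id_error_rate < 1.0):
            raise ValueError("id_error_rate must be in [0, 1)")
        if self.decoy_multiplier < 0:
            raise ValueError("decoy_multiplier must be >= 0")

    @property
    def conditions(self) -> list[str]:
        return sorted(self.fractions)

    def true_log2_fc(self, species: str) -> float:
        cond_a, cond_b = self.conditions[:2]
        return expected_log2_fc(
            self.fractions[cond_a][species], self.fractions[cond_b][species]
        )


@dataclass
class SimTruth:
    """Ground truth emitted alongside the PSM table."""

    species: dict[str, str]  # protein accession -> species tag
    true_log2_fc: dict[str, float]  # protein accession -> log2 fc (A vs B)
    psm_correct: list[bool]  # aligned with QuantTable.records
    censored: set  # (peptide, run_id) pairs censored to missing
    latent_log10: dict  # (peptide, run_id) -> true log10 intensity per slot


def default_lfqbench_config(seed: int = 0) -> SimConfig:
    """The HYE124 benchmark conditions: triplicates of A (65/30/5 w/w
    human/yeast/E. coli) vs B (65/15/20), 1000 proteins in total."""
    return SimConfig(
        n_proteins={"HUMAN": 500, "YEAST": 350, "ECOLI": 150},
        fractions={
            "A": {"HUMAN": 0.65, "YEAST": 0.30, "ECOLI": 0.05},
            "B": {"HUMAN": 0.65, "YEAST": 0.15, "ECOLI": 0.20},
        },
        n_replicates=3,
        seed=seed,
    )


def _peptide_counts(dist: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = dist[0]
    if kind == "poisson":
        counts = rng.poisson(float(dist[1]), size=n)
        return np.maximum(counts, 1)
    if kind == "fixed":
        return np.full(n, int(dist[1]))
    raise ValueError(f"unknown peptides_per_protein distribution {dist!r}")


def _random_peptides(n: int, rng: np.random.Generator) -> list[str]:
    """Unique tryptic-looking sequences: K/R only at the C terminus."""
    peptides: list[str] = []
    seen: set[str] = set()
    while len(peptides) < n:
        length = int(rng.integers(7, 21))
        body = "".join(rng.choice(list(_AA_BODY), size=length))
        pep = body + ("K" if rng.random() < 0.5 else "R")
        if pep not in seen:
            seen.add(pep)
            peptides.append(pep)
    return peptides


def simulate_dataset(config: SimConfig) -> tuple[QuantTable, SimTruth]:
    """Draw one synthetic PSM table plus ground truth, reproducibly.

    Intensities are 10**x with x the simulated log10 abundance; censored
    (peptide, run) slots produce no record at all, mimicking an upstream
    search that never reports them.
    """
    rng = np.random.default_rng(config.seed)
    conds = config.conditions
    if len(conds) != 2:
        raise ValueError("the generator models exactly two conditions")
    runs = [(f"{c}{i + 1}", c) for c in conds for i in range(config.n_replicates)]

    species_of: dict[str, str] = {}
    true_fc: dict[str, float] = {}
    accessions: list[str] = []
    for species in sorted(config.n_proteins):
        for i in range(config.n_proteins[species]):
            acc = f"P{len(accessions):05d}_{species}"
            accessions.append(acc)
            species_of[acc] = species
            true_fc[acc] = config.true_log2_fc(species)

    n_prot = len(accessions)
    base = rng.normal(config.mu_y, config.sigma_y, size=n_prot)
    pep_counts = _peptide_counts(config.peptides_per_protein, n_prot, rng)
    peptides = _random_peptides(int(pep_counts.sum()), rng)

    rows = []  # (run, cond, charge, x_true, peptide, protein)
    censored: set = set()
    latent: dict = {}
    pep_idx = 0
    for p, acc in enumerate(accessions):
        species = species_of[acc]
        level = {
            c: base[p] + math.log10(config.fractions[c][species]) for c in conds
        }
        for _ in range(pep_counts[p]):
            peptide = peptides[pep_idx]
            pep_idx += 1
            offset = rng.normal(0.0, config.peptide_offset_sd)
            charge = int(rng.choice([2, 3]))
            for run_id, cond in runs:
                x = level[cond] + offset + rng.normal(0.0, config.sigma_noise)
                latent[(peptide, run_id)] = x
                p_miss = stats.norm.cdf((config.mu_m - x) / config.sigma_m)
                if rng.random() < p_miss:
                    censored.add((peptide, run_id))
                else:
                    rows.append((run_id, cond, charge, x, peptide, acc))

    n_rows = len(rows)
    x_pool = np.array([r[3] for r in rows])
    n_incorrect = int(round(config.id_error_rate * n_rows))
    incorrect_idx = set(
        rng.choice(n_rows, size=n_incorrect, replace=False).tolist()
    ) if n_incorrect else set()

    mu_c, sd_c = config.score_correct
    mu_i, sd_i = config.score_incorrect
    records: list[PsmRecord] = []
    correct_labels: list[bool] = []
    for i, (run_id, cond, charge, x, peptide, acc) in enumerate(rows):
        if i in incorrect_idx:
            x_out = float(rng.choice(x_pool))
            score = float(rng.normal(mu_i, sd_i))
            correct = False
        else:
            x_out = x
            score = float(rng.normal(mu_c, sd_c))
            correct = True
        records.append(
            PsmRecord(
                run_id=run_id,
                condition=cond,
                charge=charge,
                search_score=score,
                intensity=10.0**x_out,
                peptide=peptide,
                protein_ids=(acc,),
            )
        )
        correct_labels.append(correct)

    # decoy PSMs: one decoy per expected incorrect target match, scaled by
    # the decoy database multiplier
    n_decoys = int(round(config.decoy_multiplier * config.id_error_rate * n_rows))
    decoy_peptides = _random_peptides(n_decoys, rng)
    for j in range(n_decoys):
        run_id, cond = runs[int(rng.integers(0, len(runs)))]
        records.append(
            PsmRecord(
                run_id=run_id,
                condition=cond,
                charge=2,
                search_score=float(rng.normal(mu_i, sd_i)),
                intensity=10.0 ** float(rng.choice(x_pool)),
                peptide=decoy_peptides[j],
                protein_ids=(f"decoy_P{j:05d}",),
                is_decoy=True,
            )
        )
        correct_labels.append(False)

    truth = SimTruth(
        species=species_of,
        true_log2_fc=true_fc,
        psm_correct=correct_labels,
        censored=censored,
        latent_log10=latent,
    )
    return QuantTable(records), truth
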
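import itertools
import math

import numpy as np
import pytest
from scipy import stats

from diaquant.formats_io import QuantTable
from diaquant.priors import LOG2_PER_LOG10, Hyperparameters
from diaquant.model import (
    PosteriorGrid,
    best_psm_per_precursor,
    differential_pep,
    drop_shared_peptides,
    fold_change_posterior,
    identification_pep,
    map_estimate,
    peptide_likelihood,
    protein_posterior,
    qvalues_from_peps,
)

from conftest import make_record


NO_CENSORING = Hyperparameters(
    mu_m=-1e6, sigma_m=1.0, sigma_noise=0.1, mu_y=0.0, sigma_y=1.0
)


class TestBestPsmPerPrecursor:
    def test_single_record_unchanged(self):
        table = QuantTable([make_record()])
        assert best_psm_per_precursor(table) == table

    def test_highest_score_kept(self):
        low = make_record(score=2.0, intensity=50.0)
        high = make_record(score=3.0, intensity=40.0)
        out = best_psm_per_precursor(QuantTable([low, high]))
        assert out.records == [high]

    def test_score_tie_broken_by_intensity(self):
        a = make_record(score=3.0, intensity=40.0)
        b = make_record(score=3.0, intensity=90.0)
        out = best_psm_per_precursor(QuantTable([a, b]))
        assert out.records == [b]

    def test_distinct_precursors_all_kept(self):
        records = [
            make_record(peptide="AAAK"),
            make_record(peptide="AAAK", charge=3),
            make_record(peptide="CCCK"),
            make_record(peptide="AAAK", run="A2"),
        ]
        out = best_psm_per_precursor(QuantTable(records))
        assert len(out) == 4


class TestDropSharedPeptides:
    def test_single_protein_records_unchanged(self, toy_table):
        out, removed = drop_shared_peptides(toy_table)
        assert out == toy_table and removed == 0

    def test_multi_protein_record_removed_and_counted(self):
        records = [
            make_record(proteins=("P1",)),
            make_record(proteins=("P1", "P2"), peptide="CCCK"),
            make_record(proteins=("P3",), peptide="DDDK"),
        ]
        out, removed = drop_shared_peptides(QuantTable(records))
        assert removed == 1
        assert len(out) == 2
        assert all(len(r.protein_ids) == 1 for r in out.records)


class TestIdentificationPep:
    def test_requires_decoys(self, toy_table):
        with pytest.raises(ValueError, match="decoy"):
            identification_pep(toy_table)

    def test_monotone_non_increasing_in_score(self):
        rng = np.random.default_rng(4)
        records = [
            make_record(score=float(rng.normal(3, 1)), peptide=f"T{i}K")
            for i in range(2000)
        ] + [
            make_record(score=float(rng.normal(1, 1)), peptide=f"D{i}K",
                        proteins=("decoy_P%d" % i,), is_decoy=True)
            for i in range(600)
        ]
        table = QuantTable(records)
        peps = identification_pep(table)
        scores = np.array([r.search_score for r in table.records])
        targets = ~np.array([r.is_decoy for r in table.records])
        order = np.argsort(scores[targets])
        assert np.all(np.diff(peps[targets][order]) <= 1e-12)

    def test_mixture_simulation_matches_analytic_posterior(self):
        """70% correct at N(3,1), 30% incorrect at N(1,1): the estimated PEP
        tracks the analytic posterior within 0.05 mean absolute error."""
        rng = np.random.default_rng(11)
        n = 10_000
        correct = rng.random(n) < 0.7
        scores = np.where(
            correct, rng.normal(3.0, 1.0, n), rng.normal(1.0, 1.0, n)
        )
        records = [
            make_record(score=float(s), peptide=f"T{i}K") for i, s in enumerate(scores)
        ] + [
            make_record(score=float(rng.normal(1.0, 1.0)), peptide=f"D{i}K",
                        proteins=(f"decoy_P{i}",), is_decoy=True)
            for i in range(3000)
        ]
        table = QuantTable(records)
        peps = identification_pep(table)[: n]
        truth = 0.3 * stats.norm.pdf(scores, 1, 1) / (
            0.7 * stats.norm.pdf(scores, 3, 1) + 0.3 * stats.norm.pdf(scores, 1, 1)
        )
        assert np.mean(np.abs(peps - truth)) < 0.05

    def test_null_case_peps_near_one(self):
        """Targets indistinguishable from decoys should get PEP ~ 1."""
        rng = np.random.default_rng(5)
        records = [
            make_record(score=float(rng.normal(1, 1)), peptide=f"T{i}K")
            for i in range(2000)
        ] + [
            make_record(score=float(rng.normal(1, 1)), peptide=f"D{i}K",
                        proteins=(f"decoy_P{i}",), is_decoy=True)
            for i in range(2000)
        ]
        peps = identification_pep(QuantTable(records))[:2000]
        assert np.mean(peps) > 0.85


class TestPeptideLikelihood:
    grid = np.arange(-2.0, 2.0, 0.01)

    def test_pep_one_is_flat(self):
        lik = peptide_likelihood(0.3, 1.0, self.grid, NO_CENSORING)
        assert np.allclose(lik, lik[0])

    def test_pep_zero_no_censoring_matches_gaussian(self):
        y = 0.25
        lik = peptide_likelihood(y, 0.0, self.grid, NO_CENSORING)
        expected = stats.norm.pdf(y, self.grid, NO_CENSORING.sigma_noise)
        assert np.max(np.abs(lik - expected)) < 1e-9

    def test_missing_likelihood_non_increasing(self):
        hyper = Hyperparameters(
            mu_m=0.0, sigma_m=0.5, sigma_noise=0.1, mu_y=0.0, sigma_y=1.0
        )
        lik = peptide_likelihood(None, 0.1, self.grid, hyper)
        assert np.all(np.diff(lik) <= 1e-15)

    def test_rejects_non_finite_observation(self):
        with pytest.raises(ValueError):
            peptide_likelihood(math.nan, 0.0, self.grid, NO_CENSORING)
        with pytest.raises(ValueError):
            peptide_likelihood(0.0, 1.5, self.grid, NO_CENSORING)


class TestProteinPosterior:
    def test_conjugate_oracle_randomized_sweep(self):
        """Grid posterior matches the analytic normal-normal update within
        1e-3 (mean and sd) across random parameter settings."""
        rng = np.random.default_rng(2023)
        for _ in range(100):
            mu_y = rng.uniform(-1, 1)
            sigma_y = rng.uniform(0.1, 1.0)
            sigma_noise = rng.uniform(0.02, 0.5)
            y = mu_y + rng.uniform(-2, 2) * sigma_y
            hyper = Hyperparameters(
                mu_m=-1e6, sigma_m=1.0, sigma_noise=sigma_noise,
                mu_y=mu_y, sigma_y=sigma_y,
            )
            span = 5.0 * max(sigma_y, sigma_noise)
            grid = np.arange(min(mu_y, y) - span, max(mu_y, y) + span, 0.01)
            lik = peptide_likelihood(y, 0.0, grid, hyper)
            post = protein_posterior([lik], grid, mu_y, sigma_y)
            prec = 1.0 / sigma_y**2 + 1.0 / sigma_noise**2
            mean_expected = (mu_y / sigma_y**2 + y / sigma_noise**2) / prec
            sd_expected = math.sqrt(1.0 / prec)
            assert abs(post.mean() - mean_expected) < 1e-3
            assert abs(post.sd() - sd_expected) < 1e-3

    def test_mass_normalized(self):
        grid = np.arange(-1, 1, 0.01)
        lik = peptide_likelihood(0.0, 0.2, grid, NO_CENSORING)
        post = protein_posterior([lik, lik], grid, 0.0, 0.5)
        assert abs(post.mass.sum() - 1.0) < 1e-6

    def test_flat_prior_limit_posterior_proportional_to_likelihood(self):
        grid = np.arange(-1, 1, 0.01)
        lik = peptide_likelihood(0.3, 0.0, grid, NO_CENSORING)
        post = protein_posterior([lik], grid, 0.0, 1e6)
        assert np.allclose(post.mass, lik / lik.sum(), atol=1e-9)

    def test_more_peptides_tighter_posteriors(self):
        """Median posterior sd strictly decreases as peptide count grows
        1 -> 4 -> 16 at fixed noise."""
        rng = np.random.default_rng(8)
        grid = np.arange(-2, 2, 0.01)
        medians = []
        for k in (1, 4, 16):
            sds = []
            for _ in range(30):
                ys = rng.normal(0.2, NO_CENSORING.sigma_noise, size=k)
                liks = [
                    peptide_likelihood(float(y), 0.0, grid, NO_CENSORING)
                    for y in ys
                ]
                sds.append(protein_posterior(liks, grid, 0.0, 1.0).sd())
            medians.append(np.median(sds))
        assert medians[0] > medians[1] > medians[2]


def normal_grid(mu, sd, lo, hi, h):
    x = np.arange(lo, hi + h / 2, h)
    mass = stats.norm.pdf(x, mu, sd)
    return PosteriorGrid(x, mass / mass.sum())


class TestFoldChangePosterior:
    def test_identical_conditions_symmetric_map_zero(self):
        post = normal_grid(0.5, 0.05, 0.0, 1.0, 0.01)
        fc = fold_change_posterior([post, post], [post, post])
        assert map_estimate(fc) == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(fc.mass, fc.mass[::-1], atol=1e-12)

    def test_shifted_condition_map_in_log2_units(self):
        """0.3 log10 shift -> MAP ~ 0.3*log2(10) ~ 0.9966, within one step."""
        a = normal_grid(0.8, 0.04, 0.0, 1.6, 0.01)
        b = normal_grid(0.5, 0.04, 0.0, 1.6, 0.01)
        fc = fold_change_posterior([a], [b])
        assert abs(map_estimate(fc) - 0.3 * LOG2_PER_LOG10) <= fc.spacing

    @pytest.mark.parametrize("n_a,n_b", [(2, 1), (2, 2), (3, 2)])
    def test_brute_force_oracle_on_small_grids(self, n_a, n_b):
        """Exhaustive summation over all grid-point combinations equals the
        convolution output within 1e-10 on 15-point grids."""
        rng = np.random.default_rng(n_a * 10 + n_b)
        h = 0.05

        def random_grid(start):
            mass = rng.random(15)
            return PosteriorGrid(start + h * np.arange(15), mass / mass.sum())

        cond_a = [random_grid(rng.integers(-3, 3) * h) for _ in range(n_a)]
        cond_b = [random_grid(rng.integers(-3, 3) * h) for _ in range(n_b)]
        fc = fold_change_posterior(cond_a, cond_b)

        expected = np.zeros_like(fc.mass)
        for idx_a in itertools.product(range(15), repeat=n_a):
            mean_a = np.mean([cond_a[s].abscissa[i] for s, i in enumerate(idx_a)])
            w_a = np.prod([cond_a[s].mass[i] for s, i in enumerate(idx_a)])
            for idx_b in itertools.product(range(15), repeat=n_b):
                mean_b = np.mean(
                    [cond_b[s].abscissa[i] for s, i in enumerate(idx_b)]
                )
                w_b = np.prod([cond_b[s].mass[i] for s, i in enumerate(idx_b)])
                value = (mean_a - mean_b) * LOG2_PER_LOG10
                pos = np.argmin(np.abs(fc.abscissa - value))
                assert abs(fc.abscissa[pos] - value) < 1e-9
                expected[pos] += w_a * w_b
        assert np.max(np.abs(fc.mass - expected)) < 1e-10

    def test_mismatched_spacing_rejected(self):
        a = normal_grid(0.5, 0.05, 0.0, 1.0, 0.01)
        b = normal_grid(0.5, 0.05, 0.0, 1.0, 0.02)
        with pytest.raises(ValueError, match="spacing"):
            fold_change_posterior([a], [b])


class TestDifferentialPep:
    def test_point_mass_outside_band(self):
        grid = PosteriorGrid(
            np.arange(0.0, 2.0, 0.1), np.eye(20)[10]  # mass at 1.0
        )
        assert differential_pep(grid, 0.5) == 0.0

    def test_tau_beyond_grid_range_gives_one(self):
        grid = normal_grid(0.0, 0.3, -1.5, 1.5, 0.01)
        assert differential_pep(grid, 10.0) == pytest.approx(1.0, abs=1e-9)

    def test_central_fifty_percent_band(self):
        """tau at the central 50% quantile of a symmetric posterior -> 0.5."""
        sd = 0.4
        grid = normal_grid(0.0, sd, -3.0, 3.0, 0.002)
        tau = sd * stats.norm.ppf(0.75)
        assert differential_pep(grid, tau) == pytest.approx(0.5, abs=2e-3)

    def test_negative_tau_rejected(self):
        grid = normal_grid(0.0, 0.3, -1.0, 1.0, 0.01)
        with pytest.raises(ValueError):
            differential_pep(grid, -0.1)


class TestMapEstimate:
    def test_unimodal_peak(self):
        grid = normal_grid(0.37, 0.1, 0.0, 1.0, 0.01)
        assert map_estimate(grid) == pytest.approx(0.37, abs=0.005)

    def test_tie_resolves_to_smaller_abscissa(self):
        grid = PosteriorGrid(np.array([0.0, 1.0, 2.0]),
                             np.array([0.4, 0.4, 0.2]))
        assert map_estimate(grid) == 0.0

    def test_equals_linear_scan_on_random_grids(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            mass = rng.random(40)
            grid = PosteriorGrid(np.arange(40) * 0.1, mass / mass.sum())
            best = 0
            for i in range(40):
                if grid.mass[i] > grid.mass[best]:
                    best = i
            assert map_estimate(grid) == grid.abscissa[best]


def brute_force_qvalues(peps):
    """Oracle: q_i = min over k >= rank(i) of the mean of the k smallest."""
    peps = list(peps)
    order = sorted(range(len(peps)), key=lambda i: peps[i])
    out = [0.0] * len(peps)
    for rank, idx in enumerate(order):
        candidates = [
            sum(peps[j] for j in order[: k + 1]) / (k + 1)
            for k in range(rank, len(peps))
        ]
        out[idx] = min(candidates)
    return out


class TestQvaluesFromPeps:
    def test_worked_example(self):
        assert qvalues_from_peps([0.0, 0.1, 0.5]) == pytest.approx(
            [0.0, 0.05, 0.2]
        )

    def test_constant_peps_unchanged(self):
        assert qvalues_from_peps([0.3] * 5) == pytest.approx([0.3] * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            qvalues_from_peps([0.5, 1.2])

    def test_non_decreasing_along_pep_order(self):
        rng = np.random.default_rng(6)
        peps = rng.random(200)
        q = qvalues_from_peps(peps)
        order = np.argsort(peps)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_matches_brute_force_on_all_small_permutations(self):
        base = [0.0, 0.05, 0.2, 0.2, 0.7, 1.0]
        for n in range(1, len(base) + 1):
            for perm in itertools.permutations(base[:n]):
                assert qvalues_from_peps(list(perm)) == pytest.approx(
                    brute_force_qvalues(perm)
                )
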
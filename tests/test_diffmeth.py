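"""Coverage counting, enrichment QC, TMM, dispersion and the exact test."""

import math
import subprocess

import numpy as np
import pytest
from scipy import stats

from mtmedip.diffmeth import (
    CpNCountMatrix,
    Sample,
    count_coverage,
    cpg_enrichment_score,
    estimate_common_dispersion,
    exact_test,
    filter_low_counts,
    run_contrasts,
    tmm_factors,
)
from mtmedip.genome_io import CpNSite, find_cpn_sites
from mtmedip.synthetic import SimulationConfig, default_samples, make_genome, simulate_counts


def _matrix(counts, samples=None):
    counts = np.atleast_2d(np.asarray(counts))
    if samples is None:
        samples = [Sample(f"s{j}", "M", "control") for j in range(counts.shape[1])]
    sites = [CpNSite(10 * (i + 1), "CpG") for i in range(counts.shape[0])]
    return CpNCountMatrix(sites=sites, counts=counts, samples=samples)


class TestCountCoverage:
    SAMPLES = [Sample("s1", "M", "control")]

    def test_read_covers_site(self):
        sites = [CpNSite(25, "CpG"), CpNSite(60, "CpA")]
        m = count_coverage({"s1": [(1, 50)]}, sites, 100, self.SAMPLES)
        assert m.counts[:, 0].tolist() == [1, 0]

    def test_wrapping_read_covers_origin_proximal_site(self):
        # read L-9..L then 1..40 on a 100 bp circle covers a site at 5
        sites = [CpNSite(5, "CpG"), CpNSite(50, "CpG"), CpNSite(95, "CpG")]
        m = count_coverage({"s1": [(91, 50)]}, sites, 100, self.SAMPLES)
        assert m.counts[:, 0].tolist() == [1, 0, 1]

    def test_empty_hits_all_zero(self):
        sites = [CpNSite(5, "CpG")]
        m = count_coverage({}, sites, 100, self.SAMPLES)
        assert (m.counts == 0).all()

    def test_site_outside_genome_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            count_coverage({}, [CpNSite(200, "CpG")], 100, self.SAMPLES)


class TestEnrichmentScore:
    def test_whole_genome_scores_one(self, small_genome):
        assert cpg_enrichment_score([(1, len(small_genome))], small_genome) == 1.0

    def test_uniform_coverage_of_random_genome_near_one(self, small_genome):
        # flat tiling in 100 bp windows: score ~ 1 for non-enriched input
        regions = [(s, s + 99) for s in range(1, len(small_genome) - 99, 100)]
        assert cpg_enrichment_score(regions, small_genome) == pytest.approx(1.0, abs=0.1)

    def test_cpg_rich_subset_matches_hand_ratio(self):
        from mtmedip.genome_io import CircularGenome

        g = CircularGenome(id="g", sequence="CGCGCGCGCG" + "ATATATATAT", circular=False)
        # covered: only the CpG half; hand computation:
        # covered rel freq = 5/10, genome rel freq = 5/20 -> score 2
        assert cpg_enrichment_score([(1, 10)], g) == pytest.approx(2.0)

    def test_empty_covered_set_rejected(self, small_genome):
        with pytest.raises(ValueError):
            cpg_enrichment_score([], small_genome)


class TestFilterLowCounts:
    def test_threshold_is_inclusive_at_ten(self):
        m = _matrix([[4, 5], [5, 5], [6, 5]])  # row totals 9, 10, 11
        kept = filter_low_counts(m, 10)
        assert [s.position for s in kept.sites] == [20, 30]

    def test_all_zero_matrix_empties(self):
        assert filter_low_counts(_matrix(np.zeros((3, 2))), 10).sites == []

    def test_min_total_zero_is_identity(self):
        m = _matrix([[0, 0], [1, 2]])
        assert len(filter_low_counts(m, 0).sites) == 2


def _tmm_oracle(y, j, r, trim_m=0.3, trim_a=0.05):
    """Step-by-step spreadsheet-style TMM factor for sample j vs reference r."""
    y = np.asarray(y, float)
    lib = y.sum(axis=0)
    yj, yr, nj, nr = y[:, j], y[:, r], lib[j], lib[r]
    rows = [i for i in range(len(yj)) if yj[i] > 0 and yr[i] > 0]
    m = [math.log2((yj[i] / nj) / (yr[i] / nr)) for i in rows]
    a = [0.5 * math.log2((yj[i] / nj) * (yr[i] / nr)) for i in rows]
    w = [1.0 / ((nj - yj[i]) / (nj * yj[i]) + (nr - yr[i]) / (nr * yr[i])) for i in rows]
    n = len(rows)
    lo_m, lo_a = math.floor(n * trim_m) + 1, math.floor(n * trim_a) + 1
    hi_m, hi_a = n + 1 - lo_m, n + 1 - lo_a
    rank = lambda v: [sorted(v).index(x) + 1 for x in v]
    rm, ra = rank(m), rank(a)
    keep = [k for k in range(n) if lo_m <= rm[k] <= hi_m and lo_a <= ra[k] <= hi_a]
    return 2 ** (sum(w[k] * m[k] for k in keep) / sum(w[k] for k in keep))


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        m = _matrix(np.tile([[10], [20], [30], [40]], (1, 3)))
        assert tmm_factors(m) == pytest.approx(np.ones(3))

    def test_pure_library_size_difference_gives_unit_factors(self):
        base = np.array([[10, 20], [20, 40], [30, 60], [40, 80], [50, 100]])
        f = tmm_factors(_matrix(base))
        assert f == pytest.approx(np.ones(2), abs=1e-9)

    def test_matches_stepwise_oracle_with_inflated_site(self):
        y = np.array(
            [[100, 95, 480], [50, 55, 52], [75, 70, 78],
             [120, 130, 110], [60, 58, 66], [90, 85, 88]]
        )
        m = _matrix(y)
        f = tmm_factors(m, reference=0)
        oracle = np.array([1.0, _tmm_oracle(y, 1, 0), _tmm_oracle(y, 2, 0)])
        oracle /= np.exp(np.mean(np.log(oracle)))
        assert f == pytest.approx(oracle, rel=1e-10)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(5)
        y = rng.poisson(50, size=(40, 4)) + 1
        f = tmm_factors(_matrix(y))
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-9)

    def test_matches_edger_calcnormfactors(self, tmp_path):
        """Independent cross-check against the Bioconductor implementation."""
        rng = np.random.default_rng(17)
        y = rng.poisson([40, 60, 55, 80], size=(30, 4)) + 1
        f = tmm_factors(_matrix(y))
        mfile = tmp_path / "m.txt"
        np.savetxt(mfile, y, fmt="%d")
        script = (
            "suppressMessages(library(edgeR));"
            f"y <- as.matrix(read.table('{mfile}'));"
            "f <- calcNormFactors(y, method='TMM');"
            "cat(sprintf('%.12f', f), sep='\\n')"
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True,
                             check=True)
        edger = np.array([float(x) for x in out.stdout.split()])
        assert f == pytest.approx(edger, abs=1e-8)


class TestDispersion:
    def _sim_matrix(self, phi, n_sites=2000, seed=0):
        cfg = SimulationConfig(seed=seed, genome_length=16775, nb_dispersion=phi)
        g = make_genome(cfg)
        sites = find_cpn_sites(g)[:n_sites]
        return simulate_counts(sites, cfg)

    def test_poisson_null_recovers_zero(self):
        m = self._sim_matrix(0.0)
        assert estimate_common_dispersion(m) < 0.02

    def test_nb_dispersion_recovered(self):
        m = self._sim_matrix(0.2, seed=1)
        phi_hat = estimate_common_dispersion(m)
        assert 0.15 <= phi_hat <= 0.25

    def test_identical_replicates_give_zero(self):
        col = np.array([[30], [40], [50], [60]])
        m = _matrix(np.hstack([col, col]))
        assert estimate_common_dispersion(m, groups=["g", "g"]) == 0.0

    def test_no_replication_raises(self):
        m = _matrix(np.array([[3, 4], [5, 6]]))
        with pytest.raises(ValueError, match="dispersion"):
            estimate_common_dispersion(m, groups=["a", "b"])


class TestExactTest:
    def test_identical_groups_give_p_one(self):
        fc, p = exact_test([[12, 12]], [[12, 12]], [100, 100], [100, 100], phi=0.1)
        assert p[0] == pytest.approx(1.0)
        assert fc[0] == pytest.approx(0.0)

    def test_poisson_limit_matches_conditional_binomial(self):
        """phi=0 must reduce to the two-sided binomial split of the total."""
        for a, b in [(30, 10), (8, 3), (100, 70), (55, 45), (150, 50)]:
            fc, p = exact_test([[a]], [[b]], [1000], [1000], phi=0.0)
            n = a + b
            pmf = stats.binom.pmf(np.arange(n + 1), n, 0.5)
            expected = pmf[pmf <= pmf[a] * (1 + 1e-12)].sum()
            assert p[0] == pytest.approx(expected, abs=1e-6)

    def test_small_totals_match_nb_convolution_enumeration(self):
        """Brute-force enumeration over integer splits via scipy's NB pmf."""
        phi = 0.3
        cases = [([3, 2], [1, 0]), ([5, 4], [2, 3]), ([7, 0], [1, 2]), ([1, 1], [6, 5])]
        for ca, cb in cases:
            fc, p = exact_test([ca], [cb], [100] * len(ca), [100] * len(cb), phi=phi)
            na, nb = len(ca), len(cb)
            t = sum(ca) + sum(cb)
            mu_a, mu_b = t * na / (na + nb), t * nb / (na + nb)
            ra, rb = na / phi, nb / phi
            pa = stats.nbinom.pmf(np.arange(t + 1), ra, ra / (ra + mu_a))
            pb = stats.nbinom.pmf(t - np.arange(t + 1), rb, rb / (rb + mu_b))
            joint = pa * pb
            obs = joint[sum(ca)]
            expected = joint[joint <= obs * (1 + 1e-12)].sum() / joint.sum()
            assert p[0] == pytest.approx(expected, abs=1e-9)

    def test_both_groups_zero(self):
        fc, p = exact_test([[0, 0]], [[0, 0]], [50, 50], [50, 50], phi=0.1)
        assert p[0] == 1.0 and fc[0] == 0.0

    def test_group_swap_symmetry(self):
        rng = np.random.default_rng(3)
        a = rng.poisson(40, size=(20, 3))
        b = rng.poisson(60, size=(20, 3))
        libs = np.full(3, 800.0)
        fc1, p1 = exact_test(a, b, libs, libs, phi=0.05)
        fc2, p2 = exact_test(b, a, libs, libs, phi=0.05)
        assert p1 == pytest.approx(p2, abs=1e-12)
        assert fc1 == pytest.approx(-fc2, abs=1e-9)

    def test_scaling_sample_and_library_leaves_p_unchanged(self):
        """Multiplying one sample's counts and library by c is a no-op up to
        the discreteness of the conditional split (O(1/sqrt(t)))."""
        a = np.array([[200, 300]])
        b = np.array([[250, 280]])
        _, p1 = exact_test(a, b, [5000, 5000], [5000, 5000], phi=0.1)
        a2 = a * np.array([3, 1])
        _, p2 = exact_test(a2, b, [15000, 5000], [5000, 5000], phi=0.1)
        assert p1 == pytest.approx(p2, rel=0.02)


class TestRunContrasts:
    def test_empty_planted_list_alpha_zero(self):
        cfg = SimulationConfig(seed=5, genome_length=2000)
        g = make_genome(cfg)
        mat = simulate_counts(find_cpn_sites(g), cfg)
        res = run_contrasts(mat, alpha=0.0)
        assert sum(d.significant for d in res) == 0

    def test_missing_cell_raises(self):
        samples = [Sample("a", "M", "control"), Sample("b", "M", "control"),
                   Sample("c", "M", "stress"), Sample("d", "M", "stress")]
        m = _matrix(np.full((5, 4), 20), samples)
        with pytest.raises(ValueError, match="no samples"):
            run_contrasts(m)

    def test_bh_adjustment_is_more_conservative(self):
        cfg = SimulationConfig(seed=6, genome_length=4000)
        g = make_genome(cfg)
        mat = simulate_counts(find_cpn_sites(g)[:500], cfg)
        raw = run_contrasts(mat, phi=0.05)
        bh = run_contrasts(mat, phi=0.05, adjust="BH")
        assert sum(d.significant for d in bh) <= sum(d.significant for d in raw)
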
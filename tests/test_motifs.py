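"""PWM IO, log-odds scoring, exact DP p-values, scanning, conservation."""

import itertools

import numpy as np
import pytest

from mtmedip.dmr import MtDMR
from mtmedip.genome_io import CircularGenome, reverse_complement
from mtmedip.motifs import (
    ScoreDistribution,
    conserved_window,
    log_odds,
    motifs_in_regions,
    pwm_from_counts,
    read_pwm,
    scan,
    strand_summary,
)
from mtmedip.synthetic import SimulationConfig, make_genome

CORE = "TGTTGGATCAGGAC"


def _core_pwm(pseudocount=0.1):
    counts = np.zeros((4, len(CORE)))
    for i, b in enumerate(CORE):
        counts["ACGT".index(b), i] = 20.0
    return pwm_from_counts("core", counts, pseudocount=pseudocount)


class TestPwmIO:
    def test_single_sequence_counts(self):
        counts = np.eye(4)  # one observation of "ACGT"
        pwm = pwm_from_counts("m", counts, pseudocount=0.0)
        assert np.allclose(pwm.matrix, np.eye(4))
        assert pwm.consensus == "ACGT"

    def test_pseudocount_on_zero_counts_gives_uniform(self):
        pwm = pwm_from_counts("m", np.zeros((4, 3)), pseudocount=1.0)
        assert np.allclose(pwm.matrix, 0.25)

    def test_jaspar_fixture_normalisation(self, tmp_path):
        p = tmp_path / "m.pfm"
        p.write_text(
            ">MA0000.1 TEST\n"
            "A [ 10  0  5 ]\n"
            "C [  0 20  5 ]\n"
            "G [  5  0  5 ]\n"
            "T [  5  0  5 ]\n"
        )
        pwm = read_pwm(p, pseudocount=0.0)
        assert pwm.name == "MA0000.1"
        expected_col0 = np.array([10, 0, 5, 5]) / 20
        assert np.allclose(pwm.matrix[:, 0], expected_col0)
        assert np.allclose(pwm.matrix.sum(axis=0), 1.0)

    def test_meme_minimal_format(self, tmp_path):
        p = tmp_path / "m.meme"
        p.write_text(
            "MEME version 4\n\nALPHABET= ACGT\n\n"
            "MOTIF TEST1\n"
            "letter-probability matrix: alength= 4 w= 2 nsites= 10 E= 0\n"
            " 0.7 0.1 0.1 0.1\n"
            " 0.1 0.1 0.1 0.7\n"
        )
        pwm = read_pwm(p, pseudocount=0.0)
        assert pwm.name == "TEST1"
        assert pwm.consensus == "AT"
        assert pwm.matrix[0, 0] == pytest.approx(0.7)


class TestLogOdds:
    def test_background_column_scores_zero(self):
        m = np.tile(np.array([[0.4], [0.3], [0.2], [0.1]]), (1, 2))
        pwm = pwm_from_counts("m", m * 100, pseudocount=0.0)
        s = log_odds(pwm, np.array([0.4, 0.3, 0.2, 0.1]))
        assert np.allclose(s, 0.0)

    def test_plugin_value(self):
        counts = np.array([[10.0], [0.0], [0.0], [0.0]])
        pwm = pwm_from_counts("m", counts, pseudocount=0.5)
        s = log_odds(pwm, np.full(4, 0.25))
        assert s[0, 0] == pytest.approx(np.log2((10.5 / 12) / 0.25))

    def test_nonpositive_background_rejected(self):
        pwm = _core_pwm()
        with pytest.raises(ValueError):
            log_odds(pwm, np.array([1.0, 0.0, 0.0, 0.0]))


class TestScoreDistribution:
    @pytest.mark.parametrize("w", [1, 2, 4, 6])
    def test_dp_matches_enumeration(self, w):
        rng = np.random.default_rng(w)
        counts = rng.integers(1, 30, size=(4, w)).astype(float)
        pwm = pwm_from_counts("m", counts)
        bg = np.array([0.3, 0.2, 0.3, 0.2])
        dist = ScoreDistribution(log_odds(pwm, bg), bg, granularity=1000)
        mass: dict[int, float] = {}
        for word in itertools.product(range(4), repeat=w):
            k = dist.int_score(np.array(word))
            mass[k] = mass.get(k, 0.0) + float(np.prod(bg[list(word)]))
        for k in sorted(mass):
            enum_tail = sum(v for kk, v in mass.items() if kk >= k)
            assert dist.pvalue_int(k) == pytest.approx(enum_tail, abs=1e-9)

    def test_total_mass_and_monotonicity(self):
        pwm = _core_pwm()
        bg = np.full(4, 0.25)
        dist = ScoreDistribution(log_odds(pwm, bg), bg)
        assert dist.pmf.sum() == pytest.approx(1.0, abs=1e-12)
        assert (np.diff(dist.tail) <= 1e-15).all()
        # best word has positive probability
        best = dist.int_matrix.max(axis=0).sum()
        assert dist.pvalue_int(int(best)) > 0

    def test_width_one_equals_background_tail(self):
        counts = np.array([[8.0], [4.0], [2.0], [1.0]])
        pwm = pwm_from_counts("m", counts, pseudocount=0.0)
        bg = np.array([0.1, 0.2, 0.3, 0.4])
        dist = ScoreDistribution(log_odds(pwm, bg), bg, granularity=500)
        for b in range(4):
            k = dist.int_matrix[b, 0]
            expected = bg[dist.int_matrix[:, 0] >= k].sum()
            assert dist.pvalue_int(int(k)) == pytest.approx(expected, abs=1e-12)


class TestScan:
    def test_planted_consensus_is_the_unique_hit(self):
        cfg = SimulationConfig(seed=19, genome_length=2000,
                               planted_motifs=[(CORE, 700, "+")])
        g = make_genome(cfg)
        hits = scan(g, _core_pwm(), p_threshold=1e-4)
        assert [(h.start, h.end, h.strand) for h in hits] == [(700, 713, "+")]
        assert hits[0].matched == CORE
        assert hits[0].strand_label == "heavy"

    def test_minus_strand_plant_recovered(self):
        cfg = SimulationConfig(seed=23, genome_length=2000,
                               planted_motifs=[(CORE, 700, "-")])
        g = make_genome(cfg)
        hits = scan(g, _core_pwm(), p_threshold=1e-6)
        best = min(hits, key=lambda h: h.p_value)
        assert (best.start, best.strand, best.matched) == (700, "-", CORE)
        assert best.strand_label == "light"

    def test_reverse_complement_symmetry(self):
        cfg = SimulationConfig(seed=2, genome_length=3000,
                               planted_motifs=[(CORE, 1000, "+")])
        g = make_genome(cfg)
        rc = CircularGenome(id="rc", sequence=reverse_complement(g.sequence))
        L = len(g)
        fwd = sorted((h.start, h.strand, round(h.p_value, 12)) for h in scan(g, _core_pwm()))
        rev = sorted(
            (L - h.end + 1, "+" if h.strand == "-" else "-", round(h.p_value, 12))
            for h in scan(rc, _core_pwm())
        )
        assert fwd == rev

    def test_circular_scan_finds_origin_spanning_site(self):
        cfg = SimulationConfig(seed=3, genome_length=2000)
        g = make_genome(cfg)
        # place the core across the origin by rotating the genome
        rotated = g.sequence[7:] + g.sequence[:7]
        seq = CORE[7:] + rotated[len(CORE) - 7 : -7] + CORE[:7]
        g2 = CircularGenome(id="wrap", sequence=seq, circular=True)
        linear_hits = scan(g2, _core_pwm(), p_threshold=1e-4, circular=False)
        circular_hits = scan(g2, _core_pwm(), p_threshold=1e-4, circular=True)
        start = len(seq) - 7 + 1
        assert all(h.start != start for h in linear_hits)
        assert any(h.start == start and h.strand == "+" for h in circular_hits)

    def test_expected_random_hit_count_on_iid_background(self):
        pwm = _core_pwm()
        total, n_rep, L = 0, 15, 16775
        for s in range(n_rep):
            g = make_genome(SimulationConfig(seed=300 + s, genome_length=L))
            total += len(scan(g, pwm, p_threshold=1e-4))
        expected = 2 * (L - pwm.width + 1) * 1e-4 * n_rep
        # the DP threshold is the largest achievable p <= 1e-4, so the true
        # per-window rate is at most 1e-4; allow 3 sigma Poisson slack
        assert total <= expected + 3 * expected**0.5
        assert total >= 0.2 * expected

    def test_width_longer_than_genome_rejected(self):
        g = CircularGenome(id="g", sequence="ACGT", circular=False)
        with pytest.raises(ValueError):
            scan(g, _core_pwm())


class TestSummaries:
    def _hit(self, start, label, motif="m"):
        from mtmedip.motifs import MotifHit

        return MotifHit("g", motif, start, start + 5, "+" if label == "heavy" else "-",
                        label, 10.0, 1e-5, "ACGTAC")

    def test_strand_summary_percentages(self):
        hits = [self._hit(1, "light"), self._hit(10, "light"), self._hit(20, "light"),
                self._hit(30, "heavy")]
        assert strand_summary(hits) == {"heavy": 25.0, "light": 75.0}
        hits17 = [self._hit(i * 10, "light") for i in range(16)] + [self._hit(500, "heavy")]
        assert strand_summary(hits17)["light"] == 94.1
        assert strand_summary([]) is None

    def test_motifs_in_regions_table(self):
        regions = {"MCvsMS": [MtDMR("MCvsMS", 100, 160, direction="hypo"),
                              MtDMR("MCvsMS", 300, 360, direction="hypo"),
                              MtDMR("MCvsMS", 500, 560, direction="hyper")]}
        hits = [self._hit(155, "heavy", "ATF4"),   # overlaps region 1 edge
                self._hit(200, "heavy", "ATF4"),   # between regions
                self._hit(520, "light", "HNF4A")]  # inside region 3
        table = motifs_in_regions(hits, regions)
        assert table.shape[0] == 3
        assert table.loc[0, "ATF4"] and not table.loc[0, "HNF4A"]
        assert not table.loc[1, "ATF4"]
        assert table.loc[2, "HNF4A"] and not table.loc[2, "ATF4"]


class TestConservedWindow:
    def _species(self, n=5, flank_seed=400):
        genomes, hits = {}, {}
        pwm = _core_pwm()
        for i in range(n):
            cfg = SimulationConfig(seed=flank_seed + i, genome_length=2500,
                                   planted_motifs=[(CORE, 900, "+")])
            g = make_genome(cfg, genome_id=f"sp{i}")
            genomes[f"sp{i}"] = g
            hit = [h for h in scan(g, pwm, p_threshold=1e-4) if h.start == 900][0]
            hits[f"sp{i}"] = hit
        return genomes, hits

    def test_identical_windows_full_consensus(self):
        genomes, hits = self._species(n=1)
        g = genomes["sp0"]
        same = {f"c{i}": g for i in range(4)}
        same_hits = {f"c{i}": hits["sp0"] for i in range(4)}
        cw = conserved_window(same_hits, same)
        assert cw.consensus == g.fetch(880, 933)
        assert all(f == 1.0 for f in cw.fractions)

    def test_planted_core_columns_fully_conserved(self):
        genomes, hits = self._species(n=5)
        cw = conserved_window(hits, genomes)
        assert len(cw.consensus) == 14 + 40
        assert cw.consensus[20:34] == CORE
        assert all(f == 1.0 for f in cw.fractions[20:34])

    def test_four_of_five_agreement_passes_seventy_percent(self):
        genomes, hits = self._species(n=5)
        # mutate one species' window at one flank column
        sp = "sp0"
        g = genomes[sp]
        seq = list(g.sequence)
        col_pos = 900 - 20 + 3  # 4th window column, inside the left flank
        seq[col_pos - 1] = "A" if seq[col_pos - 1] != "A" else "C"
        genomes[sp] = CircularGenome(id=sp, sequence="".join(seq), circular=True)
        cw = conserved_window(hits, genomes, consensus_threshold=0.70)
        others = [genomes[s].fetch(883, 883)[0] for s in genomes if s != sp]
        if len(set(others)) == 1:  # 4/5 = 80% >= 70% -> consensus holds
            assert cw.consensus[3] == others[0]
            assert cw.fractions[3] >= 0.8
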
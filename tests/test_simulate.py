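"""Synthetic-data generators: statistical contracts, closed forms, determinism."""
import math

import numpy as np
import pytest

from conftest import CONSENSUS, KINETIC_CONCS
from selexscan.kinetics import model_response
from selexscan.pwm import iupac_mismatches
from selexscan.seqs import revcomp
from selexscan.simulate import (
    CORE_LENGTH,
    LEFT_FLANK,
    RIGHT_FLANK,
    TEMPLATE_LENGTH,
    AffinityModel,
    RepsaConfig,
    SelectionLibrary,
    SelectionTemplate,
    fraction_matching,
    generate_genome,
    generate_library,
    planted_core_library,
    reads_from_library,
    simulate_repa_bands,
    simulate_repsa,
    simulate_repsa_round,
    simulate_sensorgram,
)


class TestSelectionTemplate:
    def test_default_design_is_73bp_with_iisre_sites(self):
        t = SelectionTemplate(core="A" * 24)
        assert len(t.sequence) == TEMPLATE_LENGTH
        assert "GGATG" in t.left_flank  # FokI
        assert "CTGGAG" in t.left_flank  # BpmI
        assert "CATCC" in t.right_flank and "CTCCAG" in t.right_flank

    def test_wrong_core_length_rejected(self):
        with pytest.raises(ValueError):
            SelectionTemplate(core="A" * 23)


class TestGenerateLibrary:
    def test_core_length_contract(self):
        lib = generate_library(4, 24, seed=1)
        assert lib.n_total == 4
        assert all(len(c) == 24 for c in lib.cores)

    def test_base_frequencies_uniform(self):
        lib = generate_library(100_000, 24, seed=7)
        cores = lib.expand()
        counts = np.zeros((24, 4))
        for c in cores:
            for i, b in enumerate(c):
                counts[i, "ACGT".index(b)] += 1
        freqs = counts / len(cores)
        # Binomial CI: sd of a per-position frequency is ~0.0014 at n=1e5.
        assert (np.abs(freqs - 0.25) < 0.01).all()

    def test_deterministic_under_seed(self):
        a = generate_library(500, 24, seed=11)
        b = generate_library(500, 24, seed=11)
        assert a.cores == b.cores and np.array_equal(a.counts, b.counts)

    @pytest.mark.parametrize("n,w", [(0, 24), (10, 0)])
    def test_non_positive_sizes_rejected(self, n, w):
        with pytest.raises(ValueError):
            generate_library(n, w, seed=0)


@pytest.fixture(scope="module")
def affinity():
    return AffinityModel.from_iupac(CONSENSUS, kd_min=3.0, beta=1.0)


class TestRepsaRound:
    def test_full_cleavage_without_protein_kills_library(self, affinity):
        lib = generate_library(2000, 24, seed=2)
        cfg = RepsaConfig(protein_conc=0.0, cleavage_efficiency=1.0,
                          pcr_resampling_depth=2000, seed=0)
        out = simulate_repsa_round(lib, affinity, cfg)
        assert out.n_unique == 0 and out.round_index == 1

    def test_no_selection_pressure_preserves_score_distribution(self, affinity):
        lib = generate_library(5000, 24, seed=3)
        cfg = RepsaConfig(protein_conc=34.0, cleavage_efficiency=0.0,
                          pcr_resampling_depth=5000, seed=1)
        out = simulate_repsa_round(lib, affinity, cfg)
        assert out.n_total == 5000
        scores_in = affinity.scores(lib.cores)
        s_in = np.average(scores_in, weights=lib.counts)
        s_out = np.average(affinity.scores(out.cores), weights=out.counts)
        # Resampling is unbiased: allow 5 standard errors of the resample mean.
        se = np.sqrt(np.average((scores_in - s_in) ** 2, weights=lib.counts) / 5000)
        assert s_out == pytest.approx(s_in, abs=5 * se)

    def test_survivors_bounded_by_input(self, affinity):
        lib = generate_library(1000, 24, seed=4)
        rng = np.random.default_rng(0)
        kd = affinity.kd(lib.cores)
        theta = 34.0 / (34.0 + kd)
        p = theta + (1 - theta) * 0.1
        survivors = rng.binomial(lib.counts, p)
        assert (survivors <= lib.counts).all()

    def test_mean_score_non_decreasing_across_rounds(self):
        # Short planted half-site pattern: perfect matches exist at this scale,
        # so selection has something to enrich.
        aff = AffinityModel.from_iupac("ATTGTGAC", kd_min=3.0, beta=1.0)
        lib = generate_library(20_000, 24, seed=5)
        cfg = RepsaConfig(protein_conc=34.0, cleavage_efficiency=0.9, rounds=4,
                          pcr_resampling_depth=20_000, seed=5)
        means = [np.average(aff.scores(lib.cores), weights=lib.counts)]
        for r in simulate_repsa(lib, aff, cfg):
            means.append(np.average(aff.scores(r.cores), weights=r.counts))
        assert all(b >= a - 1e-9 for a, b in zip(means, means[1:])), means

    def test_match_fraction_enriches(self):
        aff = AffinityModel.from_iupac("ATTGTGAC", kd_min=3.0, beta=1.0)
        lib = generate_library(20_000, 24, seed=6)
        cfg = RepsaConfig(protein_conc=34.0, cleavage_efficiency=0.9, rounds=4,
                          pcr_resampling_depth=20_000, seed=6)
        rounds = simulate_repsa(lib, aff, cfg)
        f0 = fraction_matching(lib, "ATTGTGAC")
        f_last = fraction_matching(rounds[-1], "ATTGTGAC")
        assert f_last > 10 * max(f0, 1e-6)

    def test_empty_library_rejected(self, affinity):
        empty = SelectionLibrary([], np.empty(0, dtype=np.int64), 0)
        with pytest.raises(ValueError):
            simulate_repsa_round(empty, affinity, RepsaConfig())


class TestReads:
    def test_zero_noise_reads_reconstruct_templates(self):
        lib = generate_library(50, 24, seed=8)
        reads = reads_from_library(lib, 0.0, 0.0, seed=0)
        expected = {LEFT_FLANK + c + RIGHT_FLANK for c in lib.cores}
        assert {str(r.seq) for r in reads} == expected

    def test_substitution_rate_calibrated(self):
        lib = generate_library(10_000, 24, seed=9)
        reads = reads_from_library(lib, 0.01, 0.0, seed=1)
        cores = lib.expand()
        mism = total = 0
        for rec, core in zip(reads, cores):
            truth = LEFT_FLANK + core + RIGHT_FLANK
            mism += sum(a != b for a, b in zip(str(rec.seq), truth))
            total += len(truth)
        assert mism / total == pytest.approx(0.01, abs=0.002)

    def test_fastq_round_trip(self, tmp_path):
        from Bio import SeqIO

        lib = generate_library(20, 24, seed=10)
        reads = reads_from_library(lib, 0.0, 0.1, seed=2, phred=27)
        path = tmp_path / "r.fastq"
        SeqIO.write(reads, str(path), "fastq")
        back = list(SeqIO.parse(str(path), "fastq"))
        assert [str(r.seq) for r in back] == [str(r.seq) for r in reads]
        assert all(set(r.letter_annotations["phred_quality"]) == {27} for r in back)

    def test_rate_bounds(self):
        lib = generate_library(5, 24, seed=0)
        with pytest.raises(ValueError):
            reads_from_library(lib, error_rate=1.5)


class TestGenerateGenome:
    def test_gc_content(self):
        genome, _ = generate_genome(100_000, gc=0.5, seed=1)
        gc = (genome.count("G") + genome.count("C")) / len(genome)
        assert 0.49 <= gc <= 0.51

    def test_planted_site_forward(self):
        site = "ATTGTGACACACATCACAAT"
        genome, _ = generate_genome(10_000, planted_sites=[(site, 5000, "+")], seed=2)
        assert genome[5000:5020] == site

    def test_planted_site_reverse(self):
        site = "ATTGTGACACACATCACAAA"
        genome, _ = generate_genome(10_000, planted_sites=[(site, 5000, "-")], seed=2)
        assert genome[5000:5020] == revcomp(site)

    def test_overlapping_plants_rejected(self):
        site = "A" * 20
        with pytest.raises(ValueError):
            generate_genome(10_000, planted_sites=[(site, 100, "+"), (site, 110, "+")], seed=0)

    def test_feature_table_shape(self):
        _, feats = generate_genome(20_000, seed=3)
        assert (feats["end"] >= feats["start"]).all()
        assert set(feats["strand"]) <= {"+", "-"}
        # The first two genes are a divergent (head-to-head) pair.
        assert list(feats["strand"][:2]) == ["-", "+"]
        # Non-overlapping ORFs.
        assert (feats["start"].iloc[1:].to_numpy() > feats["end"].iloc[:-1].to_numpy()).all()


class TestSensorgrams:
    KON, KOFF = 4.6e5, 1.6e-3

    def test_half_saturation_at_kd(self):
        kd_nm = self.KOFF / self.KON * 1e9
        sgs = simulate_sensorgram(self.KON, self.KOFF, 1.0, [kd_nm],
                                  t_assoc=50_000, t_dissoc=10, dt=100, noise_sd=0)
        sg = sgs[0]
        plateau = sg.responses[sg.times == 50_000][0]
        assert plateau == pytest.approx(0.5, rel=1e-6)

    def test_dissociation_log_linear(self):
        sgs = simulate_sensorgram(self.KON, self.KOFF, 1.0, [51.0],
                                  t_assoc=300, t_dissoc=300, dt=1.0, noise_sd=0)
        sg = sgs[0]
        mask = sg.times > 300
        slope = np.polyfit(sg.times[mask], np.log(sg.responses[mask]), 1)[0]
        assert slope == pytest.approx(-self.KOFF, rel=1e-6)

    def test_traces_ordered_by_concentration(self):
        sgs = simulate_sensorgram(self.KON, self.KOFF, 1.0, KINETIC_CONCS,
                                  t_assoc=300, t_dissoc=300, dt=1.0, noise_sd=0)
        assoc = np.array([sg.responses[sg.times <= 300] for sg in sgs])
        # At every association time point after t=0, responses increase with C.
        assert (np.diff(assoc[:, 1:], axis=0) > 0).all()

    def test_matches_closed_form_everywhere(self):
        sgs = simulate_sensorgram(self.KON, self.KOFF, 2.0, [17.0],
                                  t_assoc=120, t_dissoc=120, dt=0.5, noise_sd=0)
        sg = sgs[0]
        expected = model_response(self.KON, self.KOFF, 2.0, 17.0, sg.times, 120)
        assert np.allclose(sg.responses, expected, atol=1e-14)

    def test_invalid_rates(self):
        with pytest.raises(ValueError):
            simulate_sensorgram(-1, 1e-3, 1.0, [10.0])


class TestRepaBands:
    def test_no_protein_probe_equals_control(self):
        (m,) = simulate_repa_bands(100.0, [0.0], cleavage_efficiency=0.9)
        assert m.probe_uncleaved == pytest.approx(m.control_uncleaved)

    def test_saturation(self):
        (m,) = simulate_repa_bands(100.0, [1e9], cleavage_efficiency=0.9)
        frac = m.probe_uncleaved / (m.probe_uncleaved + m.probe_cleaved)
        assert frac == pytest.approx(1.0, abs=1e-6)

    def test_uncleaved_fraction_strictly_increasing(self):
        concs = [62.5, 125, 250, 500, 1000]
        ms = simulate_repa_bands(100.0, concs, cleavage_efficiency=0.9)
        fracs = [m.probe_uncleaved / (m.probe_uncleaved + m.probe_cleaved) for m in ms]
        assert all(b > a for a, b in zip(fracs, fracs[1:]))

    def test_control_lane_is_binding_free(self):
        (m,) = simulate_repa_bands(math.inf, [500.0], cleavage_efficiency=0.8)
        frac = m.probe_uncleaved / (m.probe_uncleaved + m.probe_cleaved)
        assert frac == pytest.approx(0.2)


class TestPlantedLibraryAndAffinity:
    def test_planted_cores_contain_consensus(self):
        cores = planted_core_library(300, CONSENSUS, 1.0, seed=1)
        assert all(len(c) == CORE_LENGTH for c in cores)
        hits = 0
        for c in cores:
            found = any(
                iupac_mismatches(c[i : i + 20], CONSENSUS) == 0
                or iupac_mismatches(revcomp(c)[i : i + 20], CONSENSUS) == 0
                for i in range(5)
            )
            hits += found
        assert hits == 300

    def test_affinity_monotone_in_score(self, affinity):
        perfect = "AA" + "ATTGTGACACACATCACAAT" + "AA"
        mutant = "AA" + "CTTGTGACACACATCACAAT" + "AA"
        kd = affinity.kd([perfect, mutant])
        assert kd[0] == pytest.approx(3.0, rel=1e-9)
        assert kd[1] > kd[0]

    def test_generators_bit_reproducible(self):
        a = planted_core_library(100, CONSENSUS, 0.5, seed=42)
        b = planted_core_library(100, CONSENSUS, 0.5, seed=42)
        assert a == b
        g1, f1 = generate_genome(5000, seed=9)
        g2, f2 = generate_genome(5000, seed=9)
        assert g1 == g2 and f1.equals(f2)
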
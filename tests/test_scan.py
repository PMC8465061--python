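"""Genome scanning: exact p-values, BH q-values, symmetry, annotation."""
import itertools

import numpy as np
import pytest

from selexscan.pwm import PWMotif
from selexscan.scan import (
    ScoreDistribution,
    annotate_hits,
    log_odds,
    read_gff3,
    scan,
    write_gff3,
)
from selexscan.seqs import revcomp
from selexscan.simulate import generate_genome

UNIFORM_BG = np.full(4, 0.25)


def random_pwm(rng, width):
    return PWMotif(rng.dirichlet(np.ones(4) * 0.5, size=width))


class TestLogOdds:
    def test_uniform_matrix_uniform_background_is_zero(self):
        pwm = PWMotif(np.full((3, 4), 0.25))
        assert np.allclose(log_odds(pwm, UNIFORM_BG, pseudocount=0.0), 0.0)

    def test_deterministic_column_scores_two_bits(self):
        pwm = PWMotif(np.array([[1.0, 0, 0, 0]]))
        lo = log_odds(pwm, UNIFORM_BG, pseudocount=0.0)
        assert lo[0, 0] == pytest.approx(2.0)

    def test_max_scoring_word_is_argmax_concatenation(self, rng):
        pwm = random_pwm(rng, 5)
        lo = log_odds(pwm, UNIFORM_BG, pseudocount=0.01)
        best = max(
            itertools.product(range(4), repeat=5),
            key=lambda word: sum(lo[i, b] for i, b in enumerate(word)),
        )
        assert "".join("ACGT"[b] for b in best) == pwm.max_score_word()


class TestScoreDistribution:
    def test_width_one_best_base_pvalue(self):
        pwm = PWMotif(np.array([[0.97, 0.01, 0.01, 0.01]]))
        lo = log_odds(pwm, UNIFORM_BG, pseudocount=0.0)
        dist = ScoreDistribution(lo, UNIFORM_BG, granularity=1000)
        p = dist.pvalue_of_int(dist.int_score(np.array([0])))
        assert p == pytest.approx(0.25)

    @pytest.mark.parametrize("width", [2, 4, 6])
    def test_dp_matches_brute_force_enumeration(self, width):
        rng = np.random.default_rng(width)
        for _ in range(7):
            bg = rng.dirichlet(np.ones(4) * 2)
            pwm = random_pwm(rng, width)
            lo = log_odds(pwm, bg, pseudocount=0.01)
            dist = ScoreDistribution(lo, bg, granularity=500)
            # Brute force over all 4^width words on the same integer grid.
            survival = np.zeros(dist.max_int + 1)
            for word in itertools.product(range(4), repeat=width):
                s = dist.int_score(np.array(word))
                survival[: s + 1] += np.prod(bg[list(word)])
            assert np.allclose(dist.survival, survival, atol=1e-12, rtol=0)

    def test_survival_non_increasing_and_total(self, rng):
        lo = log_odds(random_pwm(rng, 5), UNIFORM_BG, pseudocount=0.01)
        dist = ScoreDistribution(lo, UNIFORM_BG)
        assert (np.diff(dist.survival) <= 1e-15).all()
        assert dist.survival[0] == pytest.approx(1.0)

    def test_granularity_validation(self, rng):
        lo = log_odds(random_pwm(rng, 3), UNIFORM_BG, pseudocount=0.01)
        with pytest.raises(ValueError):
            ScoreDistribution(lo, UNIFORM_BG, granularity=10)


@pytest.fixture(scope="module")
def site_pwm():
    # Sharp planted-site motif: max-score word ATTGTGACACACATCACAAT.
    from selexscan.simulate import AffinityModel

    return AffinityModel.from_iupac("ATTGTGACACACATCACAAT", 3, 1).pwm


class TestScan:
    def test_planted_sites_recovered(self, site_pwm):
        word = "ATTGTGACACACATCACAAT"
        plants = [(word, 5000, "+"), (word, 20_000, "-"), (word, 50_123, "+")]
        genome, _ = generate_genome(60_000, gc=0.5, planted_sites=plants, seed=30)
        hits = scan({"chr": genome}, site_pwm, p_threshold=1e-4)
        found = {(h.start, h.strand) for h in hits}
        # Palindromic word: each planted site is hit on both strands.
        for _, pos, _ in plants:
            assert (pos + 1, "+") in found and (pos + 1, "-") in found
        top = hits[0]
        assert top.p_value < 1e-6 and top.matched_sequence == word

    def test_threshold_one_reports_every_window(self, site_pwm):
        genome, _ = generate_genome(500, seed=31)
        hits = scan({"chr": genome}, site_pwm, p_threshold=1.0)
        n_win = 500 - site_pwm.width + 1
        assert len(hits) == 2 * n_win

    def test_reverse_complement_genome_symmetry(self, site_pwm):
        genome, _ = generate_genome(3000, seed=32)
        fwd = scan({"chr": genome}, site_pwm, p_threshold=1e-2, background=UNIFORM_BG)
        rev = scan({"chr": revcomp(genome)}, site_pwm, p_threshold=1e-2,
                   background=UNIFORM_BG)
        L = len(genome)
        mapped = {(L - h.end + 1, "+-"["+-".index(h.strand) ^ 1], round(h.p_value, 12))
                  for h in rev}
        original = {(h.start, h.strand, round(h.p_value, 12)) for h in fwd}
        assert mapped == original

    def test_chunked_scan_matches_whole_genome(self, site_pwm):
        genome, _ = generate_genome(4000, seed=33)
        w = site_pwm.width
        whole = {(h.start, h.strand, round(h.p_value, 12))
                 for h in scan({"chr": genome}, site_pwm, p_threshold=1e-2,
                               background=UNIFORM_BG)}
        chunk_size, overlap = 1000, w - 1
        merged = set()
        for lo in range(0, 4000, chunk_size):
            chunk = genome[lo : lo + chunk_size + overlap]
            if len(chunk) < w:
                continue
            for h in scan({"chr": chunk}, site_pwm, p_threshold=1e-2,
                          background=UNIFORM_BG):
                merged.add((h.start + lo, h.strand, round(h.p_value, 12)))
        assert merged == whole

    def test_hits_sorted_and_bh_monotone(self, site_pwm):
        genome, _ = generate_genome(20_000, seed=34)
        hits = scan({"chr": genome}, site_pwm, p_threshold=0.05)
        ps = [h.p_value for h in hits]
        qs = [h.q_value for h in hits]
        assert ps == sorted(ps)
        assert all(b >= a - 1e-15 for a, b in zip(qs, qs[1:]))
        assert qs[0] >= ps[0]

    def test_short_sequence_rejected(self, site_pwm):
        with pytest.raises(ValueError):
            scan({"chr": "ACGT"}, site_pwm)


class TestAnnotate:
    @staticmethod
    def hit(start, end, strand="+", p=1e-7):
        from selexscan.scan import GenomeHit

        return GenomeHit("chr", start, end, strand, 20.0, p, p * 10, "A" * (end - start + 1))

    @staticmethod
    def features(rows):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "seqid": "chr", "source": "t", "type": "gene",
                    "start": s, "end": e, "score": ".", "strand": st,
                    "frame": ".", "attributes": f"ID={gid}", "gene_id": gid,
                }
                for gid, s, e, st in rows
            ]
        )

    def test_upstream_hit_in_window(self):
        feats = self.features([("geneA", 1000, 1900, "+")])
        calls = annotate_hits([self.hit(950, 971)], feats)
        assert len(calls) == 1
        c = calls[0]
        assert c.location_class == "window" and c.offset == -50 and not c.bidirectional

    def test_divergent_pair_gives_two_bidirectional_calls(self):
        feats = self.features([("geneL", 200, 800, "-"), ("geneR", 1000, 1600, "+")])
        calls = annotate_hits([self.hit(890, 911)], feats)
        assert len(calls) == 2
        assert all(c.bidirectional and c.location_class == "window" for c in calls)
        assert {c.gene_id for c in calls} == {"geneL", "geneR"}
        offsets = {c.gene_id: c.offset for c in calls}
        assert offsets["geneR"] == 890 - 1000 and offsets["geneL"] == 800 - 911

    def test_far_hit_is_intergenic(self):
        feats = self.features([("geneA", 10_000, 10_900, "+")])
        (call,) = annotate_hits([self.hit(100, 121)], feats)
        assert call.location_class == "intergenic_far" and call.gene_id is None

    def test_hit_inside_gene_body_is_intragenic(self):
        feats = self.features([("geneA", 100, 2000, "+")])
        (call,) = annotate_hits([self.hit(1000, 1021)], feats)
        assert call.location_class == "intragenic" and call.gene_id == "geneA"

    def test_minus_strand_offsets(self):
        feats = self.features([("geneA", 1000, 1900, "-")])
        (call,) = annotate_hits([self.hit(1950, 1971)], feats)
        assert call.location_class == "window" and call.offset == 1900 - 1971

    def test_p_value_filter(self):
        feats = self.features([("geneA", 1000, 1900, "+")])
        calls = annotate_hits([self.hit(950, 971, p=1e-4)], feats, far_threshold=5e-6)
        assert calls == []

    def test_bad_feature_rejected(self):
        feats = self.features([("geneA", 1900, 1000, "+")])
        with pytest.raises(ValueError):
            annotate_hits([self.hit(950, 971)], feats)

    def test_gff3_round_trip(self, tmp_path):
        _, feats = generate_genome(20_000, seed=35)
        path = tmp_path / "f.gff3"
        write_gff3(feats, path)
        back = read_gff3(path)
        assert list(back["start"]) == list(feats["start"])
        assert list(back["gene_id"]) == [f"gene{i + 1:04d}" for i in range(len(feats))]
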
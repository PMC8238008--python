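"""Promoter extraction, JASPAR PWMs, scanning and motif enrichment."""

import numpy as np
import pytest

from helpers import hypergeom_tail_enum
from kinomics import promoter as prom
from kinomics.annotation import Gene, GenomeAnnotation, Transcript
from kinomics.simulate import SimConfig, gen_genome, motif_pwms


def _annotation_with_gene(start, end, strand, chrom_len=5000):
    ann = GenomeAnnotation(chrom_lengths={"chr1": chrom_len})
    tx = Transcript("g.1", "g", "chr1", strand, exons=[(start, end)],
                    cds=[(start, end)])
    ann.add_gene(Gene("g", "chr1", start, end, strand, [tx]))
    return ann


def _genome(chrom_len=5000, seed=0):
    rng = np.random.default_rng(seed)
    return {"chr1": "".join(rng.choice(list("ACGT"), size=chrom_len))}


class TestExtractPromoters:
    def test_plus_strand_window(self):
        # 1-based gene start 1501 -> promoter covers 1-based 501..1500
        ann = _annotation_with_gene(1500, 2000, "+")
        g = _genome()
        p, = prom.extract_promoters(ann, g)
        assert (p.start, p.end) == (500, 1500)
        assert p.length == 1000 and not p.clipped
        assert p.sequence == g["chr1"][500:1500]

    def test_minus_strand_reverse_complement(self):
        from Bio.Seq import Seq

        ann = _annotation_with_gene(500, 1000, "-")
        g = _genome()
        p, = prom.extract_promoters(ann, g)
        assert (p.start, p.end) == (1000, 2000)
        assert p.sequence == str(
            Seq(g["chr1"][1000:2000]).reverse_complement())

    def test_clipping_at_chromosome_start(self):
        ann = _annotation_with_gene(299, 600, "+")
        p, = prom.extract_promoters(ann, _genome())
        assert (p.start, p.end) == (0, 299)
        assert p.length == 299 and p.clipped

    def test_missing_chromosome_raises(self):
        ann = _annotation_with_gene(1500, 2000, "+")
        with pytest.raises(ValueError, match="chr1"):
            prom.extract_promoters(ann, {"chrX": "ACGT"})

    def test_minus_strand_round_trip(self):
        """Reverse-complementing a minus-strand promoter reproduces the
        genome substring exactly."""
        from Bio.Seq import Seq

        ann = _annotation_with_gene(500, 1000, "-")
        g = _genome(seed=3)
        p, = prom.extract_promoters(ann, g)
        assert str(Seq(p.sequence).reverse_complement()) \
            == g["chr1"][p.start:p.end]


class TestJasparIO:
    def test_pseudocount_probability(self):
        pwm = prom.PWM("m1", np.array([[10.0], [0.0], [0.0], [0.0]]))
        lod = prom.pfm_to_logodds(pwm, pseudocount=0.5)
        assert 2 ** lod[0, 0] * 0.25 == pytest.approx(10.5 / 12)

    def test_uniform_counts_zero_logodds(self):
        pwm = prom.PWM("m1", np.full((4, 6), 2.5))
        assert np.allclose(prom.pfm_to_logodds(pwm), 0.0)

    def test_file_round_trip_preserves_counts(self, tmp_path):
        pwms = motif_pwms()
        path = tmp_path / "motifs.pfm"
        prom.write_jaspar_pfm(pwms, path)
        back = prom.read_jaspar_pfm(path)
        assert [p.motif_id for p in back] == [p.motif_id for p in pwms]
        for a, b in zip(pwms, back):
            assert np.array_equal(a.counts, b.counts)

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.pfm"
        path.write_text(">m1 m1\nA [ 1 2 ]\nC [ 1 x ]\nG [ 1 2 ]\n"
                        "T [ 1 2 ]\n")
        with pytest.raises(ValueError, match="bad.pfm:3"):
            prom.read_jaspar_pfm(path)


class TestScan:
    def test_consensus_hits_with_max_score(self):
        pwm = motif_pwms()[0]
        lod = prom.pfm_to_logodds(pwm)
        hits = prom.scan_promoter(lod, pwm.consensus)
        assert hits and hits[0][0] == 0
        assert hits[0][2] == pytest.approx(lod.max(axis=0).sum())

    def test_deterministic(self, rng):
        pwm = motif_pwms()[0]
        lod = prom.pfm_to_logodds(pwm)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        assert prom.scan_promoter(lod, seq) == prom.scan_promoter(lod, seq)

    def test_short_promoter_warns_empty(self):
        pwm = motif_pwms()[0]
        lod = prom.pfm_to_logodds(pwm)
        with pytest.warns(UserWarning, match="shorter"):
            assert prom.scan_promoter(lod, "ACGT") == []

    def test_matches_naive_window_enumeration(self, rng):
        from Bio.Seq import Seq

        pwm = motif_pwms()[1]
        lod = prom.pfm_to_logodds(pwm)
        w = pwm.width
        max_score = lod.max(axis=0).sum()
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=120))
            expected = []
            for strand in "+-":
                s = seq if strand == "+" else \
                    str(Seq(seq).reverse_complement())
                for off in range(len(s) - w + 1):
                    score = sum(lod["ACGT".index(s[off + j]), j]
                                for j in range(w))
                    if score >= 0.8 * max_score:
                        pos = off if strand == "+" else len(s) - w - off
                        expected.append((pos, strand, score))
            got = prom.scan_promoter(lod, seq)
            assert sorted(got) == sorted(
                (p, st, pytest.approx(sc)) for p, st, sc in expected)


class TestEnrichment:
    def test_exact_tail_value(self):
        # N=20, K=5, n=5, k=4 -> (C(5,4)C(15,1)+C(5,5))/C(20,5)
        p = prom.hypergeom_upper_tail(4, 20, 5, 5)
        assert p == pytest.approx(76 / 15504, abs=1e-12)
        assert p == pytest.approx(0.004902, abs=1e-6)

    def test_zero_foreground_hits_never_enriched(self):
        p = prom.hypergeom_upper_tail(0, 100, 30, 10)
        assert p == pytest.approx(1.0)

    def test_tail_monotone_decreasing_in_k(self):
        values = [prom.hypergeom_upper_tail(k, 40, 12, 10)
                  for k in range(0, 11)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_empty_foreground_raises(self):
        with pytest.raises(ValueError, match="foreground"):
            prom.family_motif_enrichment([], [], motif_pwms())

    def test_planted_motif_monte_carlo_detection_rate(self):
        """A motif planted in 80% of 50 foreground promoters vs 5% of a
        500-promoter background is called enriched in >= 95% of 100
        seeded replicates."""
        pwm = motif_pwms()[0]
        cons = pwm.consensus
        detected = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            proms = []
            for i in range(500):
                seq = list("".join(rng.choice(list("ACGT"), size=200)))
                plant_rate = 0.8 if i < 50 else 0.05
                if rng.random() < plant_rate:
                    off = int(rng.integers(0, 200 - len(cons) + 1))
                    seq[off:off + len(cons)] = list(cons)
                proms.append(prom.Promoter(f"g{i}", "c", 0, 200, "+",
                                           "".join(seq)))
            with_hit = prom.promoters_with_hit(pwm, proms)
            k = sum(1 for i in range(50) if f"g{i}" in with_hit)
            p = prom.hypergeom_upper_tail(k, 500, len(with_hit), 50)
            detected += p < 1e-2
        assert detected >= 95

    def test_planted_motif_detected_in_family(self):
        cfg = SimConfig()
        b = gen_genome(cfg, seed=13)
        promoters = prom.extract_promoters(b.annotation, b.genome)
        fam_genes = {g for g, f in b.truth.true_family.items()
                     if f == "RLK-Pelle_DLSV"}
        fg = [p for p in promoters if p.gene_id in fam_genes]
        results = prom.family_motif_enrichment(
            fg, promoters, motif_pwms(), family="RLK-Pelle_DLSV")
        by_id = {r.motif_id: r for r in results}
        assert by_id["MCRE001"].enriched
        assert by_id["MCRE001"].p < 1e-2 and by_id["MCRE001"].q < 1e-2
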
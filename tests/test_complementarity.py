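import math

import numpy as np
import pytest

from exosmallrna import complementarity as comp
from exosmallrna import synthetic_data as sd
from exosmallrna.annotation_io import GenomicInterval, reverse_complement
from exosmallrna.complementarity import KAParams, UTRRecord


def utr(seq, tid="T1", gene="G1", chrom="chrU", start=0, strand="+"):
    return UTRRecord(tid, gene, seq, [GenomicInterval(chrom, start, start + len(seq), strand)])


# ---------------------------------------------------------------------------
# Exhaustive oracle: every seed occurrence x every end-trim


def oracle_hits(query, subject, seed_len=6, ka=KAParams()):
    """All maximal-scoring ungapped extensions of exact reverse-complement
    seeds, enumerated over every subject window and every end trim."""
    rq = reverse_complement(query).upper()
    subject = subject.upper()
    qn, sn = len(rq), len(subject)

    def score(j, i, length):
        s = 0
        for k in range(length):
            a, b = rq[j + k], subject[i + k]
            s += ka.reward if (a == b and a != "N") else ka.penalty
        return s

    seeds = [
        (j, i)
        for j in range(qn - seed_len + 1)
        for i in range(sn - seed_len + 1)
        if "N" not in rq[j : j + seed_len] and rq[j : j + seed_len] == subject[i : i + seed_len]
    ]
    best = {}
    for j, i in seeds:
        candidates = []
        max_left = min(j, i)
        max_right = min(qn - j - seed_len, sn - i - seed_len)
        for left in range(max_left + 1):
            for right in range(max_right + 1):
                length = seed_len + left + right
                s = score(j - left, i - left, length)
                candidates.append((s, -right, -left, i - left, i - left + length, j - left, j - left + length))
        s, _, _, s_lo, s_hi, q_lo, q_hi = max(candidates)
        key = (s_lo, s_hi)
        if key not in best or s > best[key][4]:
            best[key] = (s_lo, s_hi, q_lo, q_hi, s)
    return sorted(best.values())


class TestSearchSpace:
    def test_identical_loci_counted_once(self):
        a = utr("A" * 1000, "T1", start=100)
        b = utr("A" * 1000, "T2", start=100)
        assert comp.build_utr_db([a, b]).effective_search_space == 1000

    def test_disjoint_add(self):
        a = utr("A" * 500, "T1", start=0)
        b = utr("C" * 500, "T2", start=1000)
        assert comp.build_utr_db([a, b]).effective_search_space == 1000

    def test_nested_union(self):
        a = utr("A" * 1000, "T1", start=0)
        b = utr("A" * 400, "T2", start=200)
        assert comp.build_utr_db([a, b]).effective_search_space == 1000


class TestKarlinAltschul:
    @pytest.mark.parametrize("raw,expected", [(11, 22.3), (13, 26.3), (14, 28.2), (16, 32.2)])
    def test_bitscores_of_ungapped_plus1_minus3(self, raw, expected):
        assert round(comp.bitscore(raw), 1) == expected

    def test_bitscore_strictly_increasing(self):
        bits = [comp.bitscore(s) for s in range(5, 40)]
        assert all(b2 > b1 for b1, b2 in zip(bits, bits[1:]))

    def test_evalue_linear_in_space(self):
        assert comp.evalue(14, 2e6) == pytest.approx(2 * comp.evalue(14, 1e6))

    def test_evalue_vanishes_for_large_scores(self):
        assert comp.evalue(500, 1e9) < 1e-200

    def test_evalue_consistency_back_derived_space(self):
        """A search space back-derived from one (S, E) anchor predicts the
        e-value at S+2 by a pure exp(-2*lambda) rescaling."""
        ka = KAParams()
        space = 0.19 / (ka.K * math.exp(-ka.lam * 14))
        predicted = comp.evalue(16, space, ka)
        assert predicted == pytest.approx(0.19 * math.exp(-2 * ka.lam), rel=1e-12)
        assert predicted == pytest.approx(0.012, abs=0.001)


class TestAntisenseSearch:
    def db_for(self, *seqs):
        return comp.build_utr_db(
            [utr(s, f"T{i}", f"G{i}", start=2000 * i) for i, s in enumerate(seqs)]
        )

    def test_perfect_14mer(self, rng):
        query = "AGTGGTTAGGATTC"
        subject = (
            "".join(np.array(list("ACGT"))[rng.integers(0, 4, 40)])
            + reverse_complement(query)
            + "".join(np.array(list("ACGT"))[rng.integers(0, 4, 40)])
        )
        db = self.db_for(subject)
        hits = [h for h in comp.antisense_search("q", query, db) if h.raw_score >= 14]
        assert any(h.matches >= 14 and h.mismatches == 0 for h in hits)
        best = max(hits, key=lambda h: h.raw_score)
        assert best.raw_score == best.matches - 3 * best.mismatches

    def test_no_seed_no_hits(self):
        # subject shares no 6-mer with the query's reverse complement
        query = "A" * 20
        subject = "C" * 200
        assert comp.antisense_search("q", query, self.db_for(subject)) == []

    def test_planted_site_with_one_mismatch(self, toy):
        db = comp.build_utr_db(toy.utrs)
        for site in toy.planted_sites:
            hits = comp.antisense_search("q", site["query"], db)
            match = [
                h for h in hits
                if any(iv.start == site["start"] and iv.end == site["end"]
                       for iv in h.genomic_intervals)
            ]
            assert match, f"planted site at {site['start']} not found"
            h = match[0]
            assert (h.matches, h.mismatches, h.raw_score) == (
                site["matches"], site["mismatches"], site["raw_score"]
            )

    def test_matches_exhaustive_oracle_on_random_instances(self, rng):
        bases = np.array(list("ACGT"))
        for trial in range(15):
            query = "".join(bases[rng.integers(0, 4, int(rng.integers(15, 35)))])
            subject = "".join(bases[rng.integers(0, 4, 300)])
            if trial % 3 == 0:  # plant a near-perfect site
                site = list(reverse_complement(query[:18]))
                site[9] = {"A": "C", "C": "A", "G": "T", "T": "G"}[site[9]]
                pos = int(rng.integers(0, 280))
                subject = subject[:pos] + "".join(site) + subject[pos + 18 :]
                subject = subject[:300]
            rec = utr(subject, "T0", "G0")
            got = comp._search_one_subject("q", query, rec, 6, KAParams())
            expected = oracle_hits(query, subject)
            assert got == expected

    def test_reverse_complement_symmetry(self, rng):
        bases = np.array(list("ACGT"))
        query = "".join(bases[rng.integers(0, 4, 25)])
        subject = "".join(bases[rng.integers(0, 4, 200)])
        site = reverse_complement(query[:15])
        subject = subject[:90] + site + subject[90 + 15 :]
        fwd = comp._search_one_subject("q", query, utr(subject, "T"), 6, KAParams())
        rev = comp._search_one_subject(
            "q", reverse_complement(query), utr(reverse_complement(subject), "T"), 6, KAParams()
        )
        assert sorted(h[4] for h in fwd) == sorted(h[4] for h in rev)

    def test_evalue_filter(self):
        query = "AGTGGTTAGGATTCGGCGCT"
        subject = "X" * 0 + reverse_complement(query[:6]) + "TTTTTTTTTTTTTT"
        subject = subject.replace("X", "")
        db = self.db_for(subject + "A" * 100)
        hits = comp.antisense_search("q", query, db, max_evalue=1e-6)
        assert all(h.e_value <= 1e-6 for h in hits)

    def test_too_many_ambiguous_bases(self):
        with pytest.raises(ValueError):
            comp.antisense_search("q", "NNNNNNNNAC", self.db_for("ACGT" * 50))


class TestUTRMapping:
    def test_plus_strand_multi_interval(self):
        rec = UTRRecord(
            "T", "G", "A" * 30,
            [GenomicInterval("chr1", 100, 120, "+"), GenomicInterval("chr1", 200, 210, "+")],
        )
        pieces = rec.offsets_to_genomic(15, 25)
        assert [(p.start, p.end) for p in pieces] == [(115, 120), (200, 205)]

    def test_minus_strand(self):
        rec = UTRRecord("T", "G", "A" * 30, [GenomicInterval("chr1", 100, 130, "-")])
        pieces = rec.offsets_to_genomic(0, 5)
        # sequence start = genomic end on the minus strand
        assert [(p.start, p.end) for p in pieces] == [(125, 130)]


class TestConservation:
    def track(self, values, chrom="chrU"):
        return comp.ConservationTrack({chrom: dict(enumerate(values))})

    def hit(self, start, end, tid="T1"):
        return comp.ComplementarityHit(
            "q", tid, "G", 0, end - start, 0, end - start, end - start, 0,
            end - start, 0.0, 0.1,
            genomic_intervals=[GenomicInterval("chrU", start, end, "+")],
        )

    def test_uniform_track_normalizes_to_one(self):
        db = comp.build_utr_db([utr("A" * 100)])
        track = self.track([3.0] * 100)
        cons, norm = comp.conservation_scores(self.hit(10, 24), track, db)
        assert (cons, norm) == (3.0, 1.0)

    def test_ratio_two(self):
        values = [1.0] * 100
        for i in range(10, 24):
            values[i] = 100 / 14 * 2 - (86 / 14)  # make hit mean exactly 2x UTR mean
        db = comp.build_utr_db([utr("A" * 100)])
        track = self.track(values)
        cons, norm = comp.conservation_scores(self.hit(10, 24), track, db)
        assert norm == pytest.approx(cons / np.mean(values))

    def test_hand_computed_fixture(self):
        # 100-nt UTR, background 0.5, a 14-nt planted site at 2.5
        values = [0.5] * 100
        for i in range(40, 54):
            values[i] = 2.5
        db = comp.build_utr_db([utr("A" * 100)])
        track = self.track(values)
        cons, norm = comp.conservation_scores(self.hit(40, 54), track, db)
        utr_mean = (0.5 * 86 + 2.5 * 14) / 100
        assert cons == pytest.approx(2.5)
        assert norm == pytest.approx(2.5 / utr_mean)

    def test_difference_mode(self):
        values = [1.0] * 100
        db = comp.build_utr_db([utr("A" * 100)])
        track = self.track(values)
        _, norm = comp.conservation_scores(self.hit(0, 10), track, db, mode="difference")
        assert norm == pytest.approx(1.0)

    def test_shortest_overlapping_utr_selected(self):
        long_utr = utr("A" * 400, "LONG", start=0)
        short_utr = utr("A" * 100, "SHORT", start=50)
        db = comp.build_utr_db([long_utr, short_utr])
        values = [1.0] * 400
        for i in range(50, 150):
            values[i] = 2.0
        for i in range(60, 74):
            values[i] = 4.0
        track = self.track(values)
        cons, norm = comp.conservation_scores(self.hit(60, 74, "SHORT"), track, db)
        short_mean = (2.0 * 86 + 4.0 * 14) / 100
        assert norm == pytest.approx(4.0 / short_mean)

    def test_missing_track_returns_none(self):
        db = comp.build_utr_db([utr("A" * 100)])
        track = comp.ConservationTrack({})
        cons, norm = comp.conservation_scores(self.hit(0, 10), track, db)
        assert cons is None and norm is None


def test_bedgraph_round_trip(tmp_path, toy):
    rng = np.random.default_rng(3)
    track = sd.simulate_conservation(toy, rng)
    path = tmp_path / "cons.bedgraph"
    sd.write_conservation_bedgraph(track, path)
    loaded = comp.ConservationTrack.from_bedgraph(path)
    iv = [GenomicInterval("chrU", 100, 120, "+")]
    assert loaded.mean(iv) == pytest.approx(float(np.mean(track["chrU"][100:120])), abs=1e-3)
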
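"""Germline mining: RSS scanning, segment search, cluster assembly, export."""

import numpy as np
import pytest

from ignarkit import germline, simulate
from ignarkit.germline import (CANONICAL_HEPTAMER, CANONICAL_NONAMER, RSSHit,
                               RSSMotif, assemble_clusters, default_motifs,
                               export_germline, find_rss, read_germline,
                               scan_segments)
from ignarkit.seqio import SeqEntry, revcomp

from conftest import references_from

HEP, NON = CANONICAL_HEPTAMER, CANONICAL_NONAMER


def brute_force_rss(seq, motifs, hb, nb):
    """Independent oracle: naive Hamming scan of every window/spacer/strand."""
    out = set()
    n = len(seq)
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for m in motifs:
            span = 7 + m.spacer_length + 9
            for i in range(n - span + 1):
                hmm = sum(a != b for a, b in zip(s[i:i + 7], m.heptamer))
                if hmm > hb:
                    continue
                nmm = sum(a != b for a, b in
                          zip(s[i + 7 + m.spacer_length:i + span], m.nonamer))
                if nmm > nb:
                    continue
                start = i if strand == "+" else n - (i + span)
                out.add((start, start + span, strand, m.spacer_length, hmm, nmm))
    # keep the lowest-mismatch assignment per (start, strand, spacer)
    best = {}
    for start, end, strand, sp, hmm, nmm in out:
        key = (start, strand, sp)
        if key not in best or hmm + nmm < best[key][4] + best[key][5]:
            best[key] = (start, end, strand, sp, hmm, nmm)
    return set(best.values())


def as_tuples(hits):
    return {(h.start, h.end, h.strand, h.spacer_length,
             h.heptamer_mismatches, h.nonamer_mismatches) for h in hits}


def mutate(s, positions):
    out = list(s)
    for p in positions:
        out[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[out[p]]
    return "".join(out)


class TestFindRSS:
    def test_exact_planted_motif_single_hit(self):
        rng = np.random.default_rng(0)
        spacer = "".join(rng.choice(list("ACGT"), 12))
        genome = {"c": "AAA" + HEP + spacer + NON + "AAA"}
        hits = find_rss(genome, [RSSMotif(spacer_length=12)])
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand) == (3, 31, "+")
        assert h.end - h.start == 28
        assert h.heptamer_mismatches == 0 and h.nonamer_mismatches == 0

    def test_three_heptamer_mismatches_exceed_default_budget(self):
        rng = np.random.default_rng(0)
        spacer = "".join(rng.choice(list("ACGT"), 12))
        genome = {"c": "AAA" + mutate(HEP, [0, 3, 6]) + spacer + NON + "AAA"}
        assert find_rss(genome, [RSSMotif(spacer_length=12)]) == []
        # the same construct passes once the budget covers it
        assert len(find_rss(genome, [RSSMotif(spacer_length=12)],
                            heptamer_budget=3)) == 1

    def test_matches_bruteforce_on_planted_5kb(self):
        rng = np.random.default_rng(42)
        bg = list(rng.choice(list("ACGT"), 5000))
        plants = [(200, 12, 0, 0), (1400, 23, 2, 1), (2800, 22, 1, 3),
                  (4200, 12, 2, 3)]
        for pos, sp, hmm, nmm in plants:
            text = (mutate(HEP, list(range(hmm)))
                    + "".join(rng.choice(list("ACGT"), sp))
                    + mutate(NON, list(range(nmm))))
            bg[pos:pos + len(text)] = list(text)
        genome = "".join(bg)
        motifs = default_motifs()
        hits = as_tuples(find_rss({"c": genome}, motifs))
        assert hits == brute_force_rss(genome, motifs, 2, 3)
        planted_found = {(p, p + 16 + sp) for p, sp, _, _ in plants}
        assert planted_found <= {(s, e) for s, e, *_ in hits}

    def test_reverse_complement_mirrors_hits(self):
        rng = np.random.default_rng(3)
        genome = "".join(rng.choice(list("ACGT"), 2000))
        genome = genome[:900] + HEP + genome[900:912] + NON + genome[912:]
        fwd = find_rss({"c": genome})
        rev = find_rss({"c": revcomp(genome)})
        n = len(genome)
        mirrored = {(n - h.end, n - h.start,
                     "-" if h.strand == "+" else "+",
                     h.spacer_length, h.heptamer_mismatches,
                     h.nonamer_mismatches) for h in fwd}
        assert mirrored == as_tuples(rev)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_budget_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        genome = {"c": "".join(rng.choice(list("ACGT"), 3000))}
        loose = as_tuples(find_rss(genome, heptamer_budget=3, nonamer_budget=4))
        tight = find_rss(genome, heptamer_budget=2, nonamer_budget=3)
        assert as_tuples(tight) <= loose

    def test_empty_genome_warns_and_returns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            assert find_rss({}) == []
        assert "empty" in caplog.text

    def test_hits_sorted_and_unique(self):
        rng = np.random.default_rng(9)
        genome = {"c": "".join(rng.choice(list("ACGT"), 4000))}
        hits = find_rss(genome, heptamer_budget=3, nonamer_budget=4)
        keys = [(h.contig_id, h.start, h.strand, h.spacer_length) for h in hits]
        assert keys == sorted(keys)
        assert len(keys) == len(set(keys))

    def test_n_bases_count_as_mismatches(self):
        genome = {"c": "AAA" + "NN" + HEP[2:] + "A" * 12 + NON + "AAA"}
        hits = find_rss(genome, [RSSMotif(spacer_length=12)])
        assert hits and hits[0].heptamer_mismatches == 2
        none = find_rss(genome, [RSSMotif(spacer_length=12)], heptamer_budget=1)
        assert none == []


class TestScanSegments:
    def _genome_with(self, insert, rng, pad=600):
        left = "".join(rng.choice(list("ACGT"), pad))
        right = "".join(rng.choice(list("ACGT"), pad))
        return left + insert + right, pad

    def test_literal_reference_found_at_identity_one(self):
        rng = np.random.default_rng(1)
        ref = "".join(rng.choice(list("ACGT"), 240))
        genome, pad = self._genome_with(ref, rng)
        segs = scan_segments({"c": genome}, [SeqEntry("V_ref", ref)])
        assert len(segs) == 1
        s = segs[0]
        assert (s.kind, s.start, s.end, s.strand) == ("V", pad, pad + 240, "+")
        assert s.identity_to_reference == 1.0

    def test_diverged_reference_identity_tracks_substitutions(self):
        rng = np.random.default_rng(2)
        ref = "".join(rng.choice(list("ACGT"), 240))
        positions = rng.choice(240, size=12, replace=False)  # 5% divergence
        genome, pad = self._genome_with(mutate(ref, positions), rng)
        segs = scan_segments({"c": genome}, [SeqEntry("V_ref", ref)],
                             min_identity=0.8)
        assert len(segs) == 1
        assert segs[0].identity_to_reference == pytest.approx(228 / 240, abs=0.01)

    def test_reverse_strand_hit(self):
        rng = np.random.default_rng(4)
        ref = "".join(rng.choice(list("ACGT"), 150))
        genome, pad = self._genome_with(revcomp(ref), rng)
        segs = scan_segments({"c": genome}, [SeqEntry("J_ref", ref)])
        assert len(segs) == 1 and segs[0].strand == "-"

    def test_planted_d_with_two_rss_flanks(self):
        rng = np.random.default_rng(5)
        d = "".join(rng.choice(list("ACGT"), 9))
        left_rss = revcomp(HEP + "".join(rng.choice(list("ACGT"), 12)) + NON)
        right_rss = HEP + "".join(rng.choice(list("ACGT"), 12)) + NON
        genome, pad = self._genome_with(left_rss + d + right_rss, rng)
        segs = scan_segments({"c": genome}, [SeqEntry("D_ref", d)])
        d_segs = [s for s in segs if s.kind == "D" and s.start == pad + 28]
        assert len(d_segs) == 1
        assert len(d_segs[0].flanking_rss) == 2

    def test_reference_shorter_than_seed_skipped_with_warning(self):
        rng = np.random.default_rng(6)
        genome, _ = self._genome_with("ACGTA", rng)
        with pytest.warns(UserWarning, match="shorter than seed"):
            segs = scan_segments({"c": genome}, [SeqEntry("D_tiny", "ACGTA")])
        assert segs == []


class TestAssembleAndExport:
    @pytest.fixture()
    def planted(self):
        cfg = simulate.SimConfig(seed=3)
        cfg.germline.clusters = [simulate.ClusterLayout(name="IgNAR1")]
        rng = np.random.default_rng(3)
        gl = simulate.synthetic_germline(cfg.germline, rng)
        contigs, _ = simulate.make_synthetic_genome(cfg, rng=rng, germline=gl)
        segs = scan_segments(contigs, references_from(gl))
        return contigs, segs

    def test_full_layout_is_one_complete_cluster(self, planted):
        _, segs = planted
        clusters = assemble_clusters(segs)
        assert len(clusters) == 1
        assert clusters[0].completeness == "complete"
        kinds = [s.kind for s in clusters[0].segments]
        assert kinds == list(germline.COMPLETE_ORDER)

    def test_missing_v_makes_cluster_incomplete(self, planted):
        _, segs = planted
        clusters = assemble_clusters([s for s in segs if s.kind != "V"])
        assert clusters[0].completeness == "incomplete"

    def test_gap_rule_splits_distant_layouts(self, planted):
        _, segs = planted
        shift = 10 * 50_000
        far = [germline.GermlineSegment(
            kind=s.kind, contig_id=s.contig_id, start=s.start + shift,
            end=s.end + shift, strand=s.strand,
            identity_to_reference=s.identity_to_reference,
            flanking_rss=[RSSHit(h.contig_id, h.start + shift, h.end + shift,
                                 h.strand, h.spacer_length,
                                 h.heptamer_mismatches, h.nonamer_mismatches)
                          for h in s.flanking_rss],
            sequence=s.sequence) for s in segs]
        clusters = assemble_clusters(sorted(segs + far, key=lambda s: s.start))
        assert len(clusters) == 2
        assert [c.completeness for c in clusters] == ["complete", "complete"]

    def test_empty_segment_list(self):
        assert assemble_clusters([]) == []

    def test_export_names_and_record_count(self, planted, tmp_path):
        contigs, segs = planted
        clusters = assemble_clusters(segs)
        fasta, tsv = export_germline(clusters, tmp_path, genome=contigs)
        from ignarkit.seqio import read_sequences
        recs = read_sequences(fasta)
        # complete cluster: 1 V + 3 D + 1 J + 5 C + Sec + Tm segments
        assert len(recs) == 12
        names = {r.id for r in recs}
        assert "IGNARV1" in names and "IGNARJ1" in names
        assert {"IGNARD1-1", "IGNARD1-2", "IGNARD1-3"} <= names

    def test_export_import_round_trip(self, planted, tmp_path):
        contigs, segs = planted
        clusters = assemble_clusters(segs)
        export_germline(clusters, tmp_path, genome=contigs)
        back = read_germline(tmp_path)
        assert len(back) == len(clusters)
        for a, b in zip(back, clusters):
            assert a.name == b.name and a.completeness == b.completeness
            assert [s.__dict__ for s in a.segments] == \
                   [s.__dict__ for s in b.segments]

    def test_duplicate_names_hard_error(self, planted, tmp_path):
        contigs, segs = planted
        clusters = assemble_clusters(segs)
        clusters[0].segments[1].name = clusters[0].segments[0].name
        with pytest.raises(ValueError, match="duplicate"):
            export_germline(clusters, tmp_path, genome=contigs)
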
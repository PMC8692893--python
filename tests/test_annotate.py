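"""Read annotation: QC, two-stage V/J assignment, CDR3 extraction, tables."""

import numpy as np
import pandas as pd
import pytest

from ignarkit import annotate, simulate
from ignarkit.annotate import (GermlineDB, annotate_read, annotate_sample,
                               build_rearrangement_table, call_d, filter_reads,
                               read_rearrangement_table,
                               write_rearrangement_table)
from ignarkit.seqio import SeqEntry, revcomp

from conftest import germline_db_from, validation_preset


def make_reads(cfg, n, seed, gl):
    rng = np.random.default_rng(seed)
    return simulate.simulate_repertoire(cfg, n, rng=rng, germline=gl)


class TestFilterReads:
    def test_good_read_kept(self):
        reads = [SeqEntry("r", "ACGT" * 100, [30] * 400)]
        kept, report = filter_reads(reads)
        assert kept == reads
        assert report["kept"] == 1 and report["input"] == 1

    def test_n_fraction_rule(self):
        seq = "N" * 40 + "ACGT" * 90  # 10% N
        kept, report = filter_reads([SeqEntry("r", seq, [30] * 400)])
        assert kept == [] and report["removed_n_content"] == 1

    def test_short_and_low_quality_rules(self):
        reads = [SeqEntry("short", "ACGT" * 10, [30] * 40),
                 SeqEntry("lowq", "ACGT" * 100, [10] * 400)]
        kept, report = filter_reads(reads)
        assert kept == []
        assert report["removed_short"] == 1
        assert report["removed_low_quality"] == 1

    def test_fasta_input_skips_quality_rule(self):
        kept, report = filter_reads([SeqEntry("r", "ACGT" * 100)])
        assert kept and report["quality_rule_applied"] is False

    def test_empty_input(self):
        kept, report = filter_reads([])
        assert kept == [] and report["input"] == 0 and report["kept"] == 0

    def test_conservation(self):
        rng = np.random.default_rng(0)
        reads = [SeqEntry(f"r{i}", "".join(rng.choice(list("ACGTN"),
                                                      rng.integers(50, 500))),
                          None) for i in range(50)]
        kept, report = filter_reads(reads)
        removed = (report["removed_short"] + report["removed_n_content"]
                   + report["removed_low_quality"])
        assert len(kept) + removed == len(reads)


class TestAssignment:
    def test_exact_concatenation_recovers_calls(self, sim_bundle):
        _, gl, db = sim_bundle
        read = SeqEntry("r", gl.v["IGNARV1"] + "ACGTT" + gl.j["IGNARJ1"])
        rec = annotate_read(read, db)
        assert (rec.v_call, rec.j_call) == ("IGNARV1", "IGNARJ1")
        assert rec.v_identity == 1.0 and rec.j_identity == 1.0
        assert rec.pass_qc

    def test_random_read_flagged_unassigned(self, sim_bundle):
        _, _, db = sim_bundle
        rng = np.random.default_rng(1)
        rec = annotate_read(SeqEntry("r", "".join(rng.choice(list("ACGT"), 400))), db)
        assert not rec.pass_qc
        assert rec.qc_reason == "unassigned"
        assert rec.v_call == "" and rec.j_call == ""

    def test_orientation_canonicalised(self, sim_bundle):
        _, gl, db = sim_bundle
        seq = gl.v["IGNARV1"] + "ACGTT" + gl.j["IGNARJ1"]
        fwd = annotate_read(SeqEntry("r", seq), db)
        rev = annotate_read(SeqEntry("r", revcomp(seq)), db)
        assert (fwd.v_call, fwd.j_call, fwd.cdr3_aa) == \
               (rev.v_call, rev.j_call, rev.cdr3_aa)

    def test_three_prime_allele_disambiguation(self):
        # two V alleles identical except at their 3' end; the base-by-base
        # extension past the aligned core must separate them
        rng = np.random.default_rng(5)
        core = "".join(rng.choice(list("ACGT"), 231))
        tail_a, tail_b = "TGCACTGGT", "TGCACTCCA"
        v_a, v_b = core + tail_a, core + tail_b
        j = "ACTAGG" + "TGG" + "".join(rng.choice(list("ACGT"), 27))
        db = GermlineDB(v={"IGNARVA": v_a, "IGNARVB": v_b}, j={"IGNARJ1": j},
                        v_anchor={"IGNARVA": 231, "IGNARVB": 231},
                        j_anchor={"IGNARJ1": 6})
        for v_seq, want in ((v_a, "IGNARVA"), (v_b, "IGNARVB")):
            rec = annotate_read(SeqEntry("r", v_seq + "GGGGG" + j), db)
            assert rec.v_call == want

    def test_d_called_from_planted_core(self, sim_bundle):
        _, gl, db = sim_bundle
        d = gl.d["IGNARV1"][0]
        junction = "GG" + d + "TT"
        assert call_d(junction, db.d) == "IGNARD1-1"

    def test_non_templated_junction_gives_none(self, sim_bundle):
        _, _, db = sim_bundle
        assert call_d("A" * 4, db.d) == "none"
        assert call_d("", db.d) == "none"

    def test_frameshifted_junction_is_out_of_frame(self, sim_bundle):
        _, gl, db = sim_bundle
        read = SeqEntry("r", gl.v["IGNARV1"] + "ACGT" + gl.j["IGNARJ1"])
        rec = annotate_read(read, db)
        # 4 inserted + 6 germline CDR3 head + 6 tail bases -> not codon-aligned
        assert rec.frame == "out"
        assert not rec.productive


class TestTruthRecovery:
    def test_zero_noise_calls_equal_truth(self, sim_bundle):
        cfg = validation_preset(seed=7)
        rng = np.random.default_rng(7)
        gl = simulate.synthetic_germline(cfg.germline, rng)
        db = germline_db_from(gl)
        reads, truth = simulate.simulate_repertoire(cfg, 800, rng=rng,
                                                    germline=gl)
        tab = build_rearrangement_table(annotate_sample(reads, db))
        m = tab.merge(truth, left_on="sequence_id", right_on="read_id")
        inframe = m[m.frame_y == "in"]
        assert len(inframe) > 100
        for col in ("v_call", "j_call", "d_call"):
            assert (inframe[f"{col}_x"] == inframe[f"{col}_y"]).all()
        assert (inframe.cdr3_aa_x == inframe.cdr3_aa_y).all()

    def test_accuracy_degrades_monotonically_with_shm(self, sim_bundle):
        _, gl, db = sim_bundle
        accs = []
        for shm in (0.0, 0.01, 0.02, 0.05):
            cfg = simulate.SimConfig(seed=13)
            cfg.repertoire.shm_rate = shm
            cfg.repertoire.seq_error = 0.0
            reads, truth = make_reads(cfg, 600, 13, gl)
            tab = build_rearrangement_table(annotate_sample(reads, db))
            m = tab.merge(truth, left_on="sequence_id", right_on="read_id")
            ok = ((m.v_call_x == m.v_call_y) & (m.j_call_x == m.j_call_y)
                  & m.pass_qc)
            accs.append(ok.mean())
        assert accs[0] > 0.95
        # monotone within sampling error
        assert all(a2 <= a1 + 0.02 for a1, a2 in zip(accs, accs[1:]))

    def test_read_conservation(self, sim_bundle):
        cfg, gl, db = sim_bundle
        reads, _ = make_reads(cfg, 300, 21, gl)
        rng = np.random.default_rng(22)
        reads += [SeqEntry(f"junk{i}", "".join(rng.choice(list("ACGT"), 350)))
                  for i in range(20)]
        tab = build_rearrangement_table(annotate_sample(reads, db))
        assert len(tab) == len(reads)
        assert set(tab.sequence_id) == {r.id for r in reads}
        # pass/fail is a partition
        assert (tab.pass_qc | (tab.qc_reason != "")).all()
        failed = tab[~tab.pass_qc]
        assert (failed.qc_reason != "").all()


class TestTable:
    def test_round_trip_equals_original(self, sim_bundle, tmp_path):
        cfg, gl, db = sim_bundle
        reads, _ = make_reads(cfg, 60, 31, gl)
        sample = annotate_sample(reads, db, sample_id="s")
        path = tmp_path / "s.tsv"
        write_rearrangement_table(sample, path)
        back = read_rearrangement_table(path, sample_id="s")
        assert [r.__dict__ for r in back.rearrangements] == \
               [r.__dict__ for r in sample.rearrangements]

    def test_unassigned_rows_retained_with_empty_calls(self, sim_bundle, tmp_path):
        _, _, db = sim_bundle
        rng = np.random.default_rng(8)
        reads = [SeqEntry("junk", "".join(rng.choice(list("ACGT"), 350)))]
        tab = build_rearrangement_table(annotate_sample(reads, db))
        row = tab.iloc[0]
        assert row.v_call == "" and row.j_call == ""
        assert row.pass_qc == False  # noqa: E712
        assert row.qc_reason == "unassigned"

    def test_header_plus_one_row_per_read(self, sim_bundle, tmp_path):
        cfg, gl, db = sim_bundle
        reads, _ = make_reads(cfg, 3, 33, gl)
        path = tmp_path / "t.tsv"
        write_rearrangement_table(annotate_sample(reads, db), path)
        lines = path.read_text().rstrip("\n").split("\n")
        assert len(lines) == 4
        assert lines[0].split("\t")[:3] == ["sequence_id", "sequence", "v_call"]
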
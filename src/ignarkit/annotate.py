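"""Repertoire read annotation: QC, two-stage V(D)J assignment, CDR3 calling.

Reads are single-end vNAR amplicons.  Annotation proceeds in two stages,
mirroring the high sequence similarity of IgNAR cluster paralogs:

1. **primary** — every germline V and J is aligned to the read (edit
   distance, infix mode) on both strands; the best V hit fixes the read
   orientation and the top-k candidates per gene type are kept;
2. **refinement** — each candidate's alignment path is recomputed, terminal
   germline-only columns (junctional trimming) are stripped, and the
   alignment boundary is then extended base-by-base toward the junction
   while the read continues to match the germline.  The final call maximises
   (identity, aligned length, database order).  D is called by a
   near-exact (<= 1 mismatch, >= 6 bp) match of a germline D inside the
   junction.

CDR3 is delimited by the FR3b canonical cysteine codon of the V (anchor
stored in the germline database) and the conserved FR4 tryptophan codon of
the J, translated in the V frame; the junction is CDR3 plus both anchors.
A clonotype is keyed by ``(v_call, j_call, cdr3_aa)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np
import pandas as pd

from .germline import IgNARCluster
from .seqio import SeqEntry, revcomp, translate

_CIGAR_RE = re.compile(r"(\d+)([=XID])")


# ---------------------------------------------------------------------------
# germline database view
# ---------------------------------------------------------------------------

@dataclass
class GermlineDB:
    """Flat V/D/J germline reference with CDR3 anchors.

    ``v_anchor`` is the 0-based nt offset of the FR3b canonical cysteine
    codon within each V; ``j_anchor`` the offset of the conserved FR4
    tryptophan codon within each J.  Database order is the candidate
    tie-break of last resort.
    """

    v: dict[str, str]
    j: dict[str, str]
    d: dict[str, str] = field(default_factory=dict)
    v_anchor: dict[str, int] = field(default_factory=dict)
    j_anchor: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.v or not self.j:
            raise ValueError("germline database needs at least one V and one J")
        self.v_order = list(self.v)
        self.j_order = list(self.j)

    @classmethod
    def from_clusters(cls, clusters: Sequence[IgNARCluster]) -> "GermlineDB":
        v, j, d, va, ja = {}, {}, {}, {}, {}
        for cl in clusters:
            for seg in cl.segments:
                if seg.kind == "V":
                    v[seg.name] = seg.sequence
                    va[seg.name] = (seg.anchor if seg.anchor is not None
                                    else _guess_v_anchor(seg.sequence))
                elif seg.kind == "J":
                    j[seg.name] = seg.sequence
                    ja[seg.name] = (seg.anchor if seg.anchor is not None
                                    else _guess_j_anchor(seg.sequence))
                elif seg.kind == "D":
                    d[seg.name] = seg.sequence
        return cls(v=v, j=j, d=d, v_anchor=va, j_anchor=ja)

    @classmethod
    def from_dir(cls, path: str | Path) -> "GermlineDB":
        from .germline import read_germline
        return cls.from_clusters(read_germline(path))


def _guess_v_anchor(seq: str) -> int:
    """Heuristic FR3b cysteine anchor: last in-frame TGT/TGC codon."""
    for i in range(3 * ((len(seq) - 3) // 3), -1, -3):
        if seq[i:i + 3] in ("TGT", "TGC"):
            return i
    raise ValueError("no in-frame cysteine codon in V segment")


def _guess_j_anchor(seq: str) -> int:
    """Heuristic FR4 tryptophan anchor: first TGG at any offset."""
    i = seq.find("TGG")
    if i < 0:
        raise ValueError("no tryptophan codon in J segment")
    return i


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class Rearrangement:
    read_id: str
    sequence: str = ""
    v_call: str = ""
    d_call: str = ""
    j_call: str = ""
    v_identity: float = 0.0
    j_identity: float = 0.0
    cdr3_nt: str = ""
    cdr3_aa: str = ""
    junction_nt: str = ""        # CDR3 plus both anchor codons
    junction_aa: str = ""
    frame: str = ""              # "in" / "out" / ""
    productive: bool = False
    pass_qc: bool = True
    qc_reason: str = ""

    @property
    def clonotype(self) -> tuple[str, str, str]:
        return (self.v_call, self.j_call, self.cdr3_aa)


@dataclass
class RepertoireSample:
    sample_id: str
    rearrangements: list[Rearrangement]

    def passing(self) -> list[Rearrangement]:
        return [r for r in self.rearrangements if r.pass_qc]


# ---------------------------------------------------------------------------
# read QC
# ---------------------------------------------------------------------------

def filter_reads(reads: Sequence[SeqEntry], min_length: int = 200,
                 max_n_fraction: float = 0.02,
                 min_mean_quality: float = 20.0
                 ) -> tuple[list[SeqEntry], dict]:
    """Length / N-content / mean-quality filter with a per-rule report.

    FASTA input (no qualities) skips the quality rule; the report notes it.
    """
    kept: list[SeqEntry] = []
    report = {"input": len(reads), "kept": 0, "removed_short": 0,
              "removed_n_content": 0, "removed_low_quality": 0,
              "quality_rule_applied": True}
    saw_qual = any(r.qual is not None for r in reads)
    if not saw_qual:
        report["quality_rule_applied"] = False
    for r in reads:
        if len(r.seq) < min_length:
            report["removed_short"] += 1
            continue
        if r.seq.count("N") / len(r.seq) > max_n_fraction:
            report["removed_n_content"] += 1
            continue
        if r.qual is not None and np.mean(r.qual) < min_mean_quality:
            report["removed_low_quality"] += 1
            continue
        kept.append(r)
    report["kept"] = len(kept)
    return kept, report


# ---------------------------------------------------------------------------
# stage 1: candidate alignments
# ---------------------------------------------------------------------------

@dataclass
class Candidate:
    name: str
    edit_distance: int
    identity: float
    read_start: int       # inclusive
    read_end: int         # exclusive
    db_index: int


def _infix(query: str, target: str, task: str = "distance"):
    return edlib.align(query, target, mode="HW", task=task)


def _candidates(read: str, refs: dict[str, str], order: list[str],
                top_k: int, min_identity: float,
                region_start: int = 0) -> list[Candidate]:
    out = []
    window = read[region_start:]
    for i, name in enumerate(order):
        ref = refs[name]
        res = _infix(ref, window, "locations")
        if res["editDistance"] < 0 or not res["locations"]:
            continue
        ident = 1.0 - res["editDistance"] / len(ref)
        if ident < min_identity:
            continue
        s, e = res["locations"][0]
        out.append(Candidate(name, res["editDistance"], ident,
                             region_start + s, region_start + e + 1, i))
    out.sort(key=lambda c: (-c.identity, c.db_index))
    return out[:top_k]


def assign_vj_primary(read: SeqEntry, db: GermlineDB, top_k: int = 3,
                      min_v_identity: float = 0.75,
                      min_j_identity: float = 0.75
                      ) -> tuple[str, str, list[Candidate], list[Candidate]]:
    """Orient the read by its best V hit and return top-k V/J candidates.

    Returns ``(oriented_sequence, strand, v_candidates, j_candidates)``;
    empty candidate lists mean no germline gene reached the identity floor.
    J candidates are restricted to start after the best V candidate ends.
    """
    fwd, rev = read.seq, revcomp(read.seq)
    best = {"+": None, "-": None}
    for strand, seq in (("+", fwd), ("-", rev)):
        dists = [_infix(vseq, seq)["editDistance"] for vseq in db.v.values()]
        dists = [d for d in dists if d >= 0]
        best[strand] = min(dists) if dists else None
    if best["+"] is None and best["-"] is None:
        return fwd, "+", [], []
    strand = "+" if (best["-"] is None
                     or (best["+"] is not None and best["+"] <= best["-"])) else "-"
    seq = fwd if strand == "+" else rev
    v_cands = _candidates(seq, db.v, db.v_order, top_k, min_v_identity)
    j_start = v_cands[0].read_end if v_cands else 0
    j_cands = _candidates(seq, db.j, db.j_order, top_k, min_j_identity,
                          region_start=j_start)
    return seq, strand, v_cands, j_cands


# ---------------------------------------------------------------------------
# stage 2: refinement (global path + base-by-base extension)
# ---------------------------------------------------------------------------

@dataclass
class RefinedAlignment:
    name: str
    identity: float
    length: int                  # aligned + extended columns
    read_start: int
    read_end: int                # exclusive; includes extension
    germ_start: int
    germ_end: int                # exclusive; includes extension
    pairs: dict[int, int]        # germline pos -> read pos (match/mismatch cols)
    db_index: int

    def read_pos(self, germ_pos: int) -> Optional[int]:
        return self.pairs.get(germ_pos)


def _parse_path(cigar: str, germ_start: int, read_start: int):
    """Yield (op, length) while tracking germline/read cursors."""
    g, r = germ_start, read_start
    for m in _CIGAR_RE.finditer(cigar):
        n, op = int(m.group(1)), m.group(2)
        yield op, n, g, r
        if op in "=XI":
            g += n
        if op in "=XD":
            r += n


def _refine_one(read: str, germ: str, side: str, db_index: int,
                name: str) -> Optional[RefinedAlignment]:
    """Path alignment of the full germline against the read, junctional-side
    germline-only columns stripped, then greedy matched extension into the
    junction.  ``side`` is "V" (junction at 3'/right) or "J" (5'/left)."""
    res = _infix(germ, read, "path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    loc_s, loc_e = res["locations"][0]
    ops = list(_parse_path(res["cigar"], 0, loc_s))
    # drop junction-side germline-only (I) runs: trimmed germline bases
    if side == "V":
        while ops and ops[-1][0] == "I":
            ops.pop()
    else:
        while ops and ops[0][0] == "I":
            ops.pop(0)
    if not ops:
        return None
    pairs: dict[int, int] = {}
    matches = cols = 0
    for op, n, g, r in ops:
        cols += n
        if op in "=X":
            for k in range(n):
                pairs[g + k] = r + k
            if op == "=":
                matches += n
    first_op, first_n, germ_lo, read_lo = ops[0]
    last_op, last_n, last_g, last_r = ops[-1]
    germ_hi = last_g + (last_n if last_op in "=XI" else 0)
    read_hi = last_r + (last_n if last_op in "=XD" else 0)
    # bootstrapping extension: extend while read matches germline
    if side == "V":
        g, r = germ_hi, read_hi
        while g < len(germ) and r < len(read) and read[r] == germ[g]:
            pairs[g] = r
            g += 1
            r += 1
            matches += 1
            cols += 1
        germ_hi, read_hi = g, r
    else:
        g, r = germ_lo - 1, read_lo - 1
        while g >= 0 and r >= 0 and read[r] == germ[g]:
            pairs[g] = r
            g -= 1
            r -= 1
            matches += 1
            cols += 1
        germ_lo, read_lo = g + 1, r + 1
    identity = matches / cols if cols else 0.0
    return RefinedAlignment(name, identity, cols, read_lo, read_hi,
                            germ_lo, germ_hi, pairs, db_index)


def refine_vdj(seq: str, v_cands: Sequence[Candidate],
               j_cands: Sequence[Candidate], db: GermlineDB,
               d_max_mismatch: int = 1, d_min_length: int = 6
               ) -> tuple[Optional[RefinedAlignment], Optional[RefinedAlignment], str]:
    """Final V/J calls by refined identity, plus the junction D call."""
    v_best = _best_refined(seq, v_cands, db.v, "V")
    j_best = _best_refined(seq, j_cands, db.j, "J")
    d_call = "none"
    if v_best and j_best:
        junction = seq[v_best.read_end:j_best.read_start]
        d_call = call_d(junction, db.d, d_max_mismatch, d_min_length)
    return v_best, j_best, d_call


def _best_refined(seq: str, cands: Sequence[Candidate], refs: dict[str, str],
                  side: str) -> Optional[RefinedAlignment]:
    best = None
    for c in cands:
        ref = _refine_one(seq, refs[c.name], side, c.db_index, c.name)
        if ref is None:
            continue
        key = (ref.identity, ref.length, -ref.db_index)
        if best is None or key > (best.identity, best.length, -best.db_index):
            best = ref
    return best


def call_d(junction: str, d_refs: dict[str, str], max_mismatch: int = 1,
           min_length: int = 6) -> str:
    """Longest >= min_length end-trimmed D core matching the junction with
    at most ``max_mismatch`` substitutions; 'none' if nothing qualifies."""
    best_name, best_len = "none", 0
    for name, d in d_refs.items():
        for a in range(len(d)):
            for b in range(len(d), a + min_length - 1, -1):
                core = d[a:b]
                if len(core) <= best_len:
                    break
                if _occurs(core, junction, max_mismatch):
                    best_name, best_len = name, len(core)
                    break
    return best_name


def _occurs(pattern: str, text: str, max_mm: int) -> bool:
    k = len(pattern)
    for i in range(len(text) - k + 1):
        mm = 0
        for a, b in zip(pattern, text[i:i + k]):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        if mm <= max_mm:
            return True
    return False


# ---------------------------------------------------------------------------
# CDR3 extraction
# ---------------------------------------------------------------------------

def extract_cdr3(seq: str, v: RefinedAlignment, j: RefinedAlignment,
                 db: GermlineDB) -> tuple[str, str, str, bool, str]:
    """CDR3 between the FR3b cysteine codon (V) and FR4 tryptophan codon (J).

    Returns ``(cdr3_nt, cdr3_aa, junction_nt, junction_aa, frame,
    productive, fail_reason)``; a non-empty fail_reason means the anchors
    were not covered by the read.
    """
    va, ja = db.v_anchor[v.name], db.j_anchor[j.name]
    # read position of the codon immediately after the V anchor cysteine
    start = _anchor_read_pos(v, va + 3, va)
    end = j.read_pos(ja)
    if start is None or end is None or end < start:
        return "", "", "", "", "", False, "anchor not covered"
    cdr3_nt = seq[start:end]
    frame = "in" if len(cdr3_nt) % 3 == 0 else "out"
    cdr3_aa = translate(cdr3_nt) if frame == "in" else ""
    junction_nt = seq[max(0, start - 3):end + 3]
    junction_aa = translate(junction_nt) if frame == "in" else ""
    productive = frame == "in" and _no_stop(seq, v, j, start)
    if "*" in cdr3_aa:
        productive = False
    return cdr3_nt, cdr3_aa, junction_nt, junction_aa, frame, productive, ""


def _anchor_read_pos(v: RefinedAlignment, want: int, anchor: int) -> Optional[int]:
    pos = v.read_pos(want)
    if pos is not None:
        return pos
    # V 3' trimmed into the germline CDR3 head: the anchor codon itself must
    # still be covered, and CDR3 then starts right after the covered part
    last = v.read_pos(anchor + 2)
    if last is not None and v.germ_end >= anchor + 3:
        return v.read_end
    return None


def _no_stop(seq: str, v: RefinedAlignment, j: RefinedAlignment,
             cdr3_start: int) -> bool:
    """Stop-scan of the assembled region translated in the V frame."""
    region_start = cdr3_start % 3   # V frame propagated to read coordinates
    region = seq[region_start:j.read_end]
    return "*" not in translate(region)


# ---------------------------------------------------------------------------
# driver + AIRR-style table
# ---------------------------------------------------------------------------

def annotate_read(read: SeqEntry, db: GermlineDB, top_k: int = 3,
                  min_v_identity: float = 0.75,
                  min_j_identity: float = 0.75) -> Rearrangement:
    seq, strand, v_cands, j_cands = assign_vj_primary(
        read, db, top_k, min_v_identity, min_j_identity)
    rec = Rearrangement(read_id=read.id, sequence=seq)
    if not v_cands or not j_cands:
        rec.pass_qc = False
        rec.qc_reason = "unassigned" if not v_cands else "no J assignment"
        return rec
    v, j, d_call = refine_vdj(seq, v_cands, j_cands, db)
    if v is None or j is None:
        rec.pass_qc = False
        rec.qc_reason = "unassigned"
        return rec
    if j.read_start < v.read_end:
        rec.pass_qc = False
        rec.qc_reason = "overlapping calls"
        rec.v_call, rec.j_call = v.name, j.name
        return rec
    rec.v_call, rec.j_call, rec.d_call = v.name, j.name, d_call
    rec.v_identity = round(v.identity, 6)
    rec.j_identity = round(j.identity, 6)
    (cdr3_nt, cdr3_aa, junction_nt, junction_aa,
     frame, productive, fail) = extract_cdr3(seq, v, j, db)
    if fail:
        rec.pass_qc = False
        rec.qc_reason = fail
        return rec
    rec.cdr3_nt, rec.cdr3_aa = cdr3_nt, cdr3_aa
    rec.junction_nt, rec.junction_aa = junction_nt, junction_aa
    rec.frame, rec.productive = frame, productive
    return rec


def annotate_sample(reads: Iterable[SeqEntry], db: GermlineDB,
                    sample_id: str = "sample", **kwargs) -> RepertoireSample:
    recs = [annotate_read(r, db, **kwargs) for r in reads]
    return RepertoireSample(sample_id=sample_id, rearrangements=recs)


TABLE_COLUMNS = ["sequence_id", "sequence", "v_call", "d_call", "j_call",
                 "cdr3", "cdr3_aa", "junction", "junction_aa", "v_identity",
                 "j_identity", "frame", "productive", "pass_qc", "qc_reason"]


def build_rearrangement_table(sample: RepertoireSample) -> pd.DataFrame:
    """AIRR-style TSV-ready table, one row per read (QC failures included).

    ``junction`` extends the CDR3 by the two anchor codons when both are
    within the called segments.
    """
    rows = []
    for r in sample.rearrangements:
        rows.append(dict(
            sequence_id=r.read_id, sequence=r.sequence, v_call=r.v_call,
            d_call=r.d_call, j_call=r.j_call, cdr3=r.cdr3_nt,
            cdr3_aa=r.cdr3_aa, junction=r.junction_nt,
            junction_aa=r.junction_aa,
            v_identity=r.v_identity, j_identity=r.j_identity, frame=r.frame,
            productive=r.productive, pass_qc=r.pass_qc, qc_reason=r.qc_reason))
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def write_rearrangement_table(sample: RepertoireSample, path: str | Path) -> Path:
    path = Path(path)
    build_rearrangement_table(sample).to_csv(path, sep="\t", index=False)
    return path


def read_rearrangement_table(path: str | Path,
                             sample_id: Optional[str] = None) -> RepertoireSample:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={c: str for c in ["sequence_id", "sequence",
                                             "v_call", "d_call", "j_call",
                                             "cdr3", "cdr3_aa", "junction",
                                             "junction_aa", "frame",
                                             "qc_reason"]})
    recs = []
    for _, row in df.iterrows():
        recs.append(Rearrangement(
            read_id=row["sequence_id"], sequence=row["sequence"],
            v_call=row["v_call"], d_call=row["d_call"], j_call=row["j_call"],
            v_identity=float(row["v_identity"]),
            j_identity=float(row["j_identity"]), cdr3_nt=row["cdr3"],
            cdr3_aa=row["cdr3_aa"], junction_nt=row["junction"],
            junction_aa=row["junction_aa"], frame=row["frame"],
            productive=_to_bool(row["productive"]),
            pass_qc=_to_bool(row["pass_qc"]), qc_reason=row["qc_reason"]))
    return RepertoireSample(sample_id=sample_id or Path(path).stem,
                            rearrangements=recs)


def _to_bool(x) -> bool:
    return str(x).strip().lower() in ("true", "1")
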
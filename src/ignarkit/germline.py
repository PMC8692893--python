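"""Germline IgNAR cluster mining.

Shark immunoglobulin loci are organised as *clusters*: each locus carries its
own V, D, J and C segments instead of the pooled translocon layout of
mammals.  A complete IgNAR cluster holds one V, three D, one J and five C
segments followed by a secretory-tail (Sec) and transmembrane-tail (Tm)
exon.  Recombination signal sequences (RSS) — a conserved heptamer and
nonamer separated by a 12, 22 or 23 bp spacer — flank the V/D/J segments and
are the physical evidence that a candidate segment is recombinogenic.  A
germline D that lacks both flanking RSS but still matches a D reference is
reported as *pre-joined* (already fused in the germline).

This module mines such clusters from a genome FASTA:

1. :func:`find_rss` — exhaustive mismatch-budgeted scan for
   heptamer–spacer–nonamer motifs on both strands;
2. :func:`scan_segments` — seed-and-extend local similarity search of
   reference V/D/J/C/Sec/Tm sequences, each retained hit annotated with its
   nearest compatible RSS;
3. :func:`assemble_clusters` — proximity grouping into named clusters with a
   completeness classification;
4. :func:`export_germline` / :func:`read_germline` — lossless germline
   database artifacts (FASTA + TSV [+ GFF3]).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio import Align

from .seqio import SeqEntry, read_sequences, revcomp, write_sequences

log = logging.getLogger(__name__)

SEGMENT_KINDS = ("V", "D", "J", "C", "Sec", "Tm")

#: canonical recombination-signal motifs; the heptamer/nonamer consensus with
#: the three spacer classes seen at shark IgNAR loci.  Users may extend this
#: set (the conserved-motif collections in the literature contain variants).
CANONICAL_HEPTAMER = "CACAGTG"
CANONICAL_NONAMER = "ACAAAAACC"
DEFAULT_SPACERS = (12, 22, 23)

COMPLETE_COMPOSITION = {"V": 1, "D": 3, "J": 1, "C": 5, "Sec": 1, "Tm": 1}
COMPLETE_ORDER = ("V", "D", "D", "D", "J", "C", "C", "C", "C", "C", "Sec", "Tm")


@dataclass(frozen=True)
class RSSMotif:
    """A heptamer/nonamer consensus with one allowed spacer length."""

    heptamer: str = CANONICAL_HEPTAMER
    nonamer: str = CANONICAL_NONAMER
    spacer_length: int = 23
    orientation: str = "downstream_of_segment"

    def __post_init__(self):
        if len(self.heptamer) != 7:
            raise ValueError("heptamer must be exactly 7 nt")
        if len(self.nonamer) != 9:
            raise ValueError("nonamer must be exactly 9 nt")
        if self.orientation not in ("downstream_of_segment", "upstream_of_segment"):
            raise ValueError(f"bad orientation {self.orientation!r}")

    @property
    def span(self) -> int:
        return 7 + self.spacer_length + 9


def default_motifs(spacers: Iterable[int] = DEFAULT_SPACERS) -> list[RSSMotif]:
    return [RSSMotif(spacer_length=s) for s in spacers]


@dataclass(frozen=True, order=True)
class RSSHit:
    """One located RSS: full heptamer–spacer–nonamer span, 0-based half-open."""

    contig_id: str
    start: int
    end: int
    strand: str
    spacer_length: int
    heptamer_mismatches: int
    nonamer_mismatches: int

    def __post_init__(self):
        if self.end - self.start != 7 + self.spacer_length + 9:
            raise ValueError("RSS span does not equal 7 + spacer + 9")


@dataclass
class GermlineSegment:
    kind: str
    contig_id: str
    start: int
    end: int
    strand: str
    identity_to_reference: float
    flanking_rss: list[RSSHit] = field(default_factory=list)
    prejoined: bool = False
    sequence: str = ""
    name: str = ""
    #: 0-based nt offset of the anchor codon within ``sequence``:
    #: V → FR3b canonical cysteine codon; J → conserved FR4 tryptophan codon.
    anchor: Optional[int] = None

    def __post_init__(self):
        if self.kind not in SEGMENT_KINDS:
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if not 0.0 <= self.identity_to_reference <= 1.0:
            raise ValueError("identity_to_reference outside [0, 1]")
        limits = {"V": 1, "J": 1, "D": 2}
        if len(self.flanking_rss) > limits.get(self.kind, 0):
            raise ValueError(f"{self.kind} segment with too many flanking RSS")


@dataclass
class IgNARCluster:
    name: str
    segments: list[GermlineSegment]
    completeness: str
    contig_id: str
    start: int
    end: int

    @property
    def span(self) -> tuple[str, int, int]:
        return (self.contig_id, self.start, self.end)


# ---------------------------------------------------------------------------
# RSS scanning
# ---------------------------------------------------------------------------

def _mismatch_profile(enc: np.ndarray, motif: str) -> np.ndarray:
    """Hamming distance of *motif* against every window of *enc* (uint8)."""
    k = len(motif)
    if len(enc) < k:
        return np.empty(0, dtype=np.int64)
    m = np.frombuffer(motif.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(enc, k)
    return (windows != m).sum(axis=1)


def _scan_strand(seq: str, motifs: Sequence[RSSMotif], hb: int, nb: int):
    """Yield (start, spacer, hep_mm, non_mm) for one strand's sequence."""
    enc = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    n = len(enc)
    # cache per distinct heptamer/nonamer string
    hep_cache: dict[str, np.ndarray] = {}
    non_cache: dict[str, np.ndarray] = {}
    for motif in motifs:
        hep = hep_cache.setdefault(motif.heptamer,
                                   _mismatch_profile(enc, motif.heptamer))
        non = non_cache.setdefault(motif.nonamer,
                                   _mismatch_profile(enc, motif.nonamer))
        s = motif.spacer_length
        limit = n - (7 + s + 9) + 1
        if limit <= 0:
            continue
        ok = (hep[:limit] <= hb) & (non[7 + s: 7 + s + limit] <= nb)
        for i in np.nonzero(ok)[0]:
            yield int(i), s, int(hep[i]), int(non[i + 7 + s])


def find_rss(genome: Mapping[str, str] | Sequence[SeqEntry],
             motifs: Optional[Sequence[RSSMotif]] = None,
             heptamer_budget: int = 2,
             nonamer_budget: int = 3) -> list[RSSHit]:
    """Exhaustively locate RSS motifs on both strands under mismatch budgets.

    ``N`` (or any non-ACGT character) never matches a motif base, so it
    counts against the budget.  Hits are sorted by (contig, start) and
    deduplicated on (contig, start, strand, spacer), keeping the
    lowest-mismatch assignment.
    """
    if heptamer_budget < 0 or nonamer_budget < 0:
        raise ValueError("mismatch budgets must be >= 0")
    motifs = list(motifs) if motifs is not None else default_motifs()
    if not motifs:
        raise ValueError("empty motif set")
    contigs = _as_contig_dict(genome)
    if not contigs:
        log.warning("find_rss called on an empty genome")
        return []
    best: dict[tuple, RSSHit] = {}
    for contig_id, seq in contigs.items():
        n = len(seq)
        for strand, strand_seq in (("+", seq), ("-", revcomp(seq))):
            for i, spacer, hm, nm in _scan_strand(
                    strand_seq, motifs, heptamer_budget, nonamer_budget):
                span = 7 + spacer + 9
                if strand == "+":
                    start = i
                else:
                    start = n - (i + span)
                key = (contig_id, start, strand, spacer)
                hit = RSSHit(contig_id, start, start + span, strand,
                             spacer, hm, nm)
                prev = best.get(key)
                if prev is None or (hm + nm) < (prev.heptamer_mismatches
                                                + prev.nonamer_mismatches):
                    best[key] = hit
    return sorted(best.values(),
                  key=lambda h: (h.contig_id, h.start, h.strand, h.spacer_length))


def _as_contig_dict(genome) -> dict[str, str]:
    if isinstance(genome, Mapping):
        return {k: v.upper() for k, v in genome.items()}
    return {r.id: r.seq.upper() for r in genome}


# ---------------------------------------------------------------------------
# Segment similarity search (seed-and-extend Smith–Waterman)
# ---------------------------------------------------------------------------

def _local_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 2
    a.mismatch_score = -3
    a.open_gap_score = -5
    a.extend_gap_score = -2
    return a


def reference_kind(ref_id: str) -> str:
    """Segment kind from a reference id: leading token 'V', 'D1', 'Sec', ..."""
    for kind in ("Sec", "Tm", "V", "D", "J", "C"):
        if ref_id.upper().startswith(kind.upper()):
            return kind
    raise ValueError(
        f"reference id {ref_id!r} does not start with a segment kind "
        f"(V/D/J/C/Sec/Tm)")


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        idx.setdefault(seq[i:i + k], []).append(i)
    return idx


def _alignment_identity(aln) -> tuple[float, int, int, int]:
    """(identity, aligned_cols, target_start, target_end) of one alignment."""
    t, q = aln[0], aln[1]
    cols = len(t)
    matches = sum(1 for a, b in zip(t, q) if a == b and a != "-")
    tstart = int(aln.aligned[0][0][0]) if len(aln.aligned[0]) else 0
    tend = int(aln.aligned[0][-1][1]) if len(aln.aligned[0]) else 0
    return (matches / cols if cols else 0.0), cols, tstart, tend


def scan_segments(genome: Mapping[str, str] | Sequence[SeqEntry],
                  references: Sequence[SeqEntry],
                  min_identity: float = 0.8,
                  seed_len: int = 8,
                  min_coverage: float = 0.8,
                  flank_window: int = 10,
                  rss_hits: Optional[Sequence[RSSHit]] = None,
                  heptamer_budget: int = 2,
                  nonamer_budget: int = 3) -> list[GermlineSegment]:
    """Locate germline segments by local similarity to labelled references.

    References are seeded with exact ``seed_len``-mers, candidate loci
    extended with an affine-gap Smith–Waterman alignment, overlapping hits of
    the same kind collapsed to the highest-identity one (ties: leftmost
    start, then + strand), and each retained hit annotated with the nearest
    compatible RSS within ``flank_window`` bp.
    """
    if not 0 < min_identity <= 1:
        raise ValueError("min_identity must lie in (0, 1]")
    contigs = _as_contig_dict(genome)
    if rss_hits is None:
        rss_hits = find_rss(contigs, heptamer_budget=heptamer_budget,
                            nonamer_budget=nonamer_budget)
    aligner = _local_aligner()
    raw: list[GermlineSegment] = []
    for contig_id, seq in contigs.items():
        n = len(seq)
        idx = _kmer_index(seq, seed_len)
        for ref in references:
            kind = reference_kind(ref.id)
            if len(ref.seq) < seed_len:
                warnings.warn(
                    f"reference {ref.id!r} shorter than seed length "
                    f"{seed_len}; skipped")
                continue
            if len(ref.seq) < 3 * seed_len:
                # short segments (D and the like) match exactly, full length;
                # their mismatch tolerance comes from RSS evidence, since a
                # local alignment of a ~12 bp query has no genome-scale
                # specificity
                for strand in ("+", "-"):
                    query = ref.seq if strand == "+" else revcomp(ref.seq)
                    at = seq.find(query)
                    while at >= 0:
                        raw.append(GermlineSegment(
                            kind=kind, contig_id=contig_id, start=at,
                            end=at + len(query), strand=strand,
                            identity_to_reference=1.0,
                            sequence=ref.seq))
                        at = seq.find(query, at + 1)
                continue
            for strand in ("+", "-"):
                query = ref.seq if strand == "+" else revcomp(ref.seq)
                loci = _candidate_loci(query, idx, seed_len, len(seq))
                for lo, hi in loci:
                    window = seq[lo:hi]
                    try:
                        aln = aligner.align(window, query)[0]
                    except IndexError:
                        continue
                    ident, cols, tstart, tend = _alignment_identity(aln)
                    if ident < min_identity or cols < min_coverage * len(query):
                        continue
                    start, end = lo + tstart, lo + tend
                    raw.append(GermlineSegment(
                        kind=kind, contig_id=contig_id, start=start, end=end,
                        strand=strand, identity_to_reference=round(ident, 6),
                        sequence=(seq[start:end] if strand == "+"
                                  else revcomp(seq[start:end]))))
    kept = _collapse_overlaps(raw)
    for seg in kept:
        seg.flanking_rss = _nearest_rss(seg, rss_hits, flank_window)
    kept.sort(key=lambda s: (s.contig_id, s.start, s.end))
    return kept


def _candidate_loci(query: str, idx: dict[str, list[int]], k: int,
                    contig_len: int, pad: int = 30) -> list[tuple[int, int]]:
    """Diagonal-clustered seed matches → merged candidate windows.

    Long queries (>= 3k) require two seeds at least k apart on the same
    diagonal (a single chance match of k+1..2k-1 bases yields overlapping
    seeds, so mere seed count has no genome-scale specificity); short
    queries (e.g. 9-12 bp D segments) keep single seeds.
    """
    diag_hits: dict[int, list[int]] = {}
    for qpos in range(len(query) - k + 1):
        for tpos in idx.get(query[qpos:qpos + k], ()):
            diag_hits.setdefault(tpos - qpos, []).append(tpos)
    need_spread = len(query) >= 3 * k
    windows = []
    for diag, positions in diag_hits.items():
        if need_spread and max(positions) - min(positions) < k:
            continue
        lo = max(0, diag - pad)
        hi = min(contig_len, diag + len(query) + pad)
        windows.append((lo, hi))
    # merge overlapping windows to avoid re-aligning the same locus
    windows.sort()
    merged: list[tuple[int, int]] = []
    for lo, hi in windows:
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def _collapse_overlaps(segments: list[GermlineSegment]) -> list[GermlineSegment]:
    """Keep the best hit among same-kind overlaps.

    Ranking: highest identity, then leftmost start, then + strand first.
    """
    order = sorted(
        segments,
        key=lambda s: (-s.identity_to_reference, s.start, s.strand != "+"))
    kept: list[GermlineSegment] = []
    for seg in order:
        clash = any(k.kind == seg.kind and k.contig_id == seg.contig_id
                    and k.start < seg.end and seg.start < k.end
                    for k in kept)
        if not clash:
            kept.append(seg)
    return kept


def _nearest_rss(seg: GermlineSegment, hits: Sequence[RSSHit],
                 flank_window: int) -> list[RSSHit]:
    """Nearest compatible RSS within the flank window.

    On the + strand a recombinogenic RSS downstream of a segment reads
    heptamer-first (+ strand hit starting at/after the segment end); an
    upstream RSS reads nonamer-first on the forward genome, i.e. is a −
    strand hit ending at/before the segment start.  Mirrored for − strand
    segments.  V takes a downstream RSS only, J an upstream one only, D both;
    C/Sec/Tm none.
    """
    if seg.kind not in ("V", "D", "J"):
        return []

    def pick(bio_side: str) -> Optional[RSSHit]:
        # The heptamer abuts the segment, so the genomic-right flank always
        # carries a '+' oriented motif hit and the genomic-left flank a '-'
        # hit; which biological side that is depends on segment strand.
        right = (bio_side == "down") == (seg.strand == "+")
        best, best_gap = None, None
        for h in hits:
            if h.contig_id != seg.contig_id:
                continue
            if right:
                gap, ok = h.start - seg.end, h.strand == "+"
            else:
                gap, ok = seg.start - h.end, h.strand == "-"
            if ok and 0 <= gap <= flank_window:
                if best_gap is None or gap < best_gap:
                    best, best_gap = h, gap
        return best

    sides = {"V": ["down"], "J": ["up"], "D": ["up", "down"]}[seg.kind]
    found = [h for h in (pick(s) for s in sides) if h is not None]
    return found


# ---------------------------------------------------------------------------
# Cluster assembly
# ---------------------------------------------------------------------------

def assemble_clusters(segments: Sequence[GermlineSegment],
                      max_gap: int = 50_000) -> list[IgNARCluster]:
    """Group coordinate-sorted segments into clusters by proximity.

    Segments on the same contig and strand whose successive gaps are at most
    ``max_gap`` form one cluster.  Clusters are named ``IgNAR1, IgNAR2, ...``
    in genomic order.  Completeness follows the exact composition rule
    (1 V, 3 D, 1 J, 5 C, Sec, Tm in genomic order).  A D without flanking
    RSS is flagged pre-joined.
    """
    if not segments:
        return []
    segs = sorted(segments, key=lambda s: (s.contig_id, s.strand != "+", s.start))
    groups: list[list[GermlineSegment]] = [[segs[0]]]
    for seg in segs[1:]:
        prev = groups[-1][-1]
        same = (seg.contig_id == prev.contig_id and seg.strand == prev.strand)
        if same and seg.start - prev.end <= max_gap:
            groups[-1].append(seg)
        else:
            groups.append([seg])
    # an isolated group of RSS-less D hits is background, not a locus: a
    # real pre-joined D sits inside a cluster with V/J/C context
    groups = [g for g in groups
              if any(s.kind != "D" or s.flanking_rss for s in g)]
    if not groups:
        return []
    groups.sort(key=lambda g: (g[0].contig_id, g[0].start))
    clusters = []
    for i, group in enumerate(groups, start=1):
        ordered = sorted(group, key=lambda s: s.start)
        if group[0].strand == "-":
            ordered = ordered[::-1]  # biological order runs right-to-left
        ordered = _drop_contextless_d(ordered)
        for seg in ordered:
            # a recombinogenic D carries an RSS on each side; anything less
            # (a lone chance flank hit included) is called pre-joined
            if seg.kind == "D" and len(seg.flanking_rss) < 2:
                seg.prejoined = True
        kinds = tuple(s.kind for s in ordered)
        completeness = "complete" if kinds == COMPLETE_ORDER else "incomplete"
        name = f"IgNAR{i}"
        for j, seg in enumerate(ordered):
            seg.name = _segment_name(name, seg.kind,
                                     sum(1 for s in ordered[:j]
                                         if s.kind == seg.kind) + 1,
                                     kinds.count(seg.kind))
        clusters.append(IgNARCluster(
            name=name, segments=ordered, completeness=completeness,
            contig_id=group[0].contig_id,
            start=min(s.start for s in group),
            end=max(s.end for s in group)))
    return clusters


def _drop_contextless_d(ordered: list[GermlineSegment]) -> list[GermlineSegment]:
    """Discard RSS-less D hits outside the V–J interval of their cluster.

    A germline D (pre-joined or not) sits between V and J; an RSS-less
    match elsewhere is a chance hit of a short reference.
    """
    v_idx = next((i for i, s in enumerate(ordered) if s.kind == "V"), None)
    j_idx = next((i for i, s in enumerate(ordered) if s.kind == "J"), None)
    out = []
    for i, s in enumerate(ordered):
        if s.kind == "D" and not s.flanking_rss:
            if v_idx is None or j_idx is None or not v_idx < i < j_idx:
                continue
        out.append(s)
    return out


def _segment_name(cluster: str, kind: str, ordinal: int, total: int) -> str:
    """``IgNAR1`` V → ``IGNARV1``; the 2nd of 3 Ds → ``IGNARD1-2``."""
    idx = cluster.replace("IgNAR", "")
    base = f"IGNAR{kind.upper()}{idx}"
    return base if total == 1 else f"{base}-{ordinal}"


# ---------------------------------------------------------------------------
# Germline database export / import
# ---------------------------------------------------------------------------

TSV_COLUMNS = ["segment_id", "cluster", "completeness", "kind", "contig",
               "start", "end", "strand", "identity", "prejoined", "anchor",
               "rss_json"]


def export_germline(clusters: Sequence[IgNARCluster], out_dir: str | Path,
                    genome: Optional[Mapping[str, str]] = None) -> tuple[Path, Path]:
    """Write the germline database: ``germline.fasta`` + ``germline.tsv``.

    Segment sequences come from the segment objects, or are sliced from
    *genome* when absent.  Duplicate segment names are a hard error.  The
    pair of files round-trips losslessly through :func:`read_germline`.
    """
    if not clusters:
        raise ValueError("no clusters to export")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, rows, seen = [], [], set()
    for cl in clusters:
        for seg in cl.segments:
            if not seg.name:
                raise ValueError("segment without a name; run assemble_clusters")
            if seg.name in seen:
                raise ValueError(f"duplicate segment name {seg.name!r}")
            seen.add(seg.name)
            seq = seg.sequence
            if not seq:
                if genome is None:
                    raise ValueError(f"no sequence for {seg.name} and no genome")
                seq = genome[seg.contig_id][seg.start:seg.end]
                if seg.strand == "-":
                    seq = revcomp(seq)
            records.append(SeqEntry(seg.name, seq))
            rows.append("\t".join(str(x) for x in [
                seg.name, cl.name, cl.completeness, seg.kind, seg.contig_id,
                seg.start, seg.end, seg.strand, seg.identity_to_reference,
                int(seg.prejoined),
                "" if seg.anchor is None else seg.anchor,
                json.dumps([list(h.__dict__.values()) for h in seg.flanking_rss]),
            ]))
    fasta = out_dir / "germline.fasta"
    tsv = out_dir / "germline.tsv"
    write_sequences(records, fasta)
    tsv.write_text("\t".join(TSV_COLUMNS) + "\n" + "\n".join(rows) + "\n")
    return fasta, tsv


def read_germline(out_dir: str | Path) -> list[IgNARCluster]:
    """Inverse of :func:`export_germline`."""
    out_dir = Path(out_dir)
    seqs = {r.id: r.seq for r in read_sequences(out_dir / "germline.fasta")}
    lines = (out_dir / "germline.tsv").read_text().rstrip("\n").split("\n")
    header = lines[0].split("\t")
    assert header == TSV_COLUMNS, "unexpected germline TSV columns"
    by_cluster: dict[str, dict] = {}
    for line in lines[1:]:
        (name, cluster, completeness, kind, contig, start, end, strand,
         ident, prejoined, anchor, rss_json) = line.split("\t")
        seg = GermlineSegment(
            kind=kind, contig_id=contig, start=int(start), end=int(end),
            strand=strand, identity_to_reference=float(ident),
            flanking_rss=[RSSHit(*v) for v in json.loads(rss_json)],
            prejoined=bool(int(prejoined)), sequence=seqs[name], name=name,
            anchor=None if anchor == "" else int(anchor))
        info = by_cluster.setdefault(cluster, {"completeness": completeness,
                                               "segments": []})
        info["segments"].append(seg)
    clusters = []
    for cname in sorted(by_cluster, key=lambda c: int(c.replace("IgNAR", ""))):
        info = by_cluster[cname]
        segs = info["segments"]
        clusters.append(IgNARCluster(
            name=cname, segments=segs, completeness=info["completeness"],
            contig_id=segs[0].contig_id,
            start=min(s.start for s in segs),
            end=max(s.end for s in segs)))
    return clusters


def export_gff3(clusters: Sequence[IgNARCluster], path: str | Path) -> Path:
    """Optional GFF3 of segments and their RSS (1-based, inclusive)."""
    path = Path(path)
    lines = ["##gff-version 3"]
    for cl in clusters:
        for seg in cl.segments:
            lines.append("\t".join([
                seg.contig_id, "ignarkit", f"{seg.kind}_gene_segment",
                str(seg.start + 1), str(seg.end), ".", seg.strand, ".",
                f"ID={seg.name};cluster={cl.name};"
                f"completeness={cl.completeness}"]))
            for h in seg.flanking_rss:
                lines.append("\t".join([
                    h.contig_id, "ignarkit", "recombination_feature",
                    str(h.start + 1), str(h.end), ".", h.strand, ".",
                    f"Parent={seg.name};spacer={h.spacer_length};"
                    f"heptamer_mm={h.heptamer_mismatches};"
                    f"nonamer_mm={h.nonamer_mismatches}"]))
    path.write_text("\n".join(lines) + "\n")
    return path
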
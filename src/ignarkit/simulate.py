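"""Ground-truthed synthetic data for the whole pipeline.

Three generators, all driven by one :class:`SimConfig` and a single seed:

* :func:`make_synthetic_genome` — a background genome with planted IgNAR
  clusters whose segments are flanked by RSS with configured mismatch
  counts, plus a truth GFF3;
* :func:`simulate_repertoire` — single-end amplicon reads of V(D)J
  rearrangements with configurable V–J pairing, junctional trimming and
  N-insertion, somatic hypermutation (SHM), clone-size skew and per-base
  sequencing error, plus a per-read truth table;
* :func:`simulate_vnar_library` — full-length vNAR amino-acid sequences at a
  configured type mixture, cysteine-count mixture and duplication level.

The generative factorisation of the repertoire draws the V–J pair per read
from the pair-probability table and then a clone within that pair's pool
under a discrete power law, so read-weighted pair usage is exactly
multinomial while clonality statistics keep their power-law structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import vnar_types
from .seqio import SeqEntry, revcomp, translate, write_sequences
from .germline import CANONICAL_HEPTAMER, CANONICAL_NONAMER

AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: residue alphabet used for randomised positions: cysteine and tryptophan
#: are excluded so that type identity is controlled exactly by placement.
AA_NEUTRAL = "".join(a for a in AA20 if a not in "CW")

#: the study's vNAR amplification primers (V-side / J-side)
PRIMER_VNAR_V = "AGACCGCTTGGCCTCCGACTTGGGTTGAACAAACACCGACA"
PRIMER_VNAR_J = "ACATGGCTACGATCCGACTTAATCCATTTGCCCTCTGTTCT"

_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
_SYNONYMS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["CTG", "CTC", "CTT", "TTA"], "M": ["ATG"], "N": ["AAT", "AAC"],
    "P": ["CCT", "CCA", "CCG"], "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "AGA"], "S": ["TCT", "TCA", "AGT"],
    "T": ["ACT", "ACC", "ACA"], "V": ["GTT", "GTC", "GTA"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ClusterLayout:
    """Layout of one planted cluster.  ``has_v=False`` gives an incomplete
    cluster lacking V and D (only J, C x5, Sec, Tm)."""

    name: str
    has_v: bool = True
    n_d: int = 3
    prejoined_last_d: bool = False
    rss_heptamer_mm: int = 0
    rss_nonamer_mm: int = 0


def paper_like_layouts() -> list[ClusterLayout]:
    """Seven clusters: 1/2/5/6 complete, 3/4/7 incomplete; pre-joined final
    D in clusters 2, 5 and 6 — the germline organisation of the bamboo-shark
    IgNAR locus."""
    out = []
    for i in range(1, 8):
        complete = i in (1, 2, 5, 6)
        out.append(ClusterLayout(
            name=f"IgNAR{i}", has_v=complete, n_d=3 if complete else 0,
            prejoined_last_d=i in (2, 5, 6)))
    return out


@dataclass
class GermlineConfig:
    clusters: list[ClusterLayout] = field(default_factory=paper_like_layouts)
    divergence: float = 0.05      # per-base substitution between cluster V genes
    segment_gap: int = 200        # bp between segments within a cluster
    cluster_gap: int = 110_000    # bp between clusters; 7 clusters then span
                                  # ~0.8 Mb as at the real locus
    background_gc: float = 0.42
    d_length: int = 12
    spacer_v: int = 23            # spacer classes: V 23, D 12/12, J 22
    spacer_d: int = 12
    spacer_j: int = 22


@dataclass
class RepertoireConfig:
    #: V-J pair probabilities keyed "IGNARV1:IGNARJ1"; within-cluster pairs,
    #: dominant IgNAR1 pair at the blood-repertoire share.
    pair_probs: dict[str, float] = field(default_factory=lambda: {
        "IGNARV1:IGNARJ1": 0.96,
        "IGNARV2:IGNARJ2": 0.02,
        "IGNARV5:IGNARJ5": 0.01,
        "IGNARV6:IGNARJ6": 0.01,
    })
    n_clones: int = 10_000
    clone_exponent: float = 0.8   # discrete power-law (Zipf) exponent
    d_usage: float = 0.8          # probability the junction templates a D
    trim_mean: float = 2.0        # geometric mean trim of V 3' / J 5'
    d_trim_mean: float = 1.0
    n_insert_mean: float = 3.0    # Poisson N-insertion length per side
    shm_rate: float = 0.01
    seq_error: float = 0.001
    read_length: int = 400
    add_primers: bool = False
    #: validation mode: rejection-sample junctions until the true parse is
    #: unambiguous — N-insertions neither extend a germline match across the
    #: segment boundary nor imitate a D core the event did not use.  Off by
    #: default; exact-recovery checks combine it with zero trimming.
    identifiable_junctions: bool = False


@dataclass
class LibraryConfig:
    #: type mixture; the printed profile leaves 0.3% unallocated, assigned
    #: to type I here
    type_mixture: dict[str, float] = field(default_factory=lambda: {
        "II": 0.790, "new": 0.188, "IV": 0.019, "I": 0.003})
    #: P(exactly one CDR3 Cys | type II); one CDR3 Cys gives the 4-cysteine
    #: pattern, two give 5
    p_single_cdr3_cys: float = 0.745 / 0.790
    unique_fraction: float = 0.838
    cdr3_length_mean: float = 15.0
    cdr3_length_min: int = 5
    framework_diversity: float = 0.02


@dataclass
class SimConfig:
    seed: int = 0
    germline: GermlineConfig = field(default_factory=GermlineConfig)
    repertoire: RepertoireConfig = field(default_factory=RepertoireConfig)
    library: LibraryConfig = field(default_factory=LibraryConfig)

    def validate(self) -> None:
        tot = sum(self.repertoire.pair_probs.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"pair probabilities sum to {tot}, not 1")
        tot = sum(self.library.type_mixture.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"type mixture sums to {tot}, not 1")
        for name, rate in [("shm_rate", self.repertoire.shm_rate),
                           ("seq_error", self.repertoire.seq_error)]:
            if not 0 <= rate < 1:
                raise ValueError(f"{name} outside [0, 1)")
        if "IV" in self.library.type_mixture and self.library.cdr3_length_min < 2:
            raise ValueError("cdr3_length_min < 2 cannot host type II cysteines")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        if "seed" in data:
            cfg.seed = int(data["seed"])
        for section, obj in [("germline", cfg.germline),
                             ("repertoire", cfg.repertoire),
                             ("library", cfg.library)]:
            for k, v in (data.get(section) or {}).items():
                if not hasattr(obj, k):
                    raise ValueError(f"unknown config key {section}.{k}")
                setattr(obj, k, v)
        cfg.validate()
        return cfg


# ---------------------------------------------------------------------------
# germline synthesis
# ---------------------------------------------------------------------------

def _reverse_translate(aa: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_SYNONYMS[a]) for a in aa)


def _random_dna(n: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=probs))


@dataclass
class SyntheticGermline:
    """In-memory germline database with exact anchors and cluster layout."""

    v: dict[str, str]
    d: dict[str, list[str]]          # V name -> D sequences of its cluster
    j: dict[str, str]
    c: dict[str, list[str]]
    sec: dict[str, str]
    tm: dict[str, str]
    v_anchor: dict[str, int]         # nt offset of FR3b Cys codon in V
    j_anchor: dict[str, int]         # nt offset of FR4 Trp codon in J
    prejoined: dict[str, bool]       # per D name

    def pair_names(self) -> list[tuple[str, str]]:
        return [(v, v.replace("V", "J")) for v in self.v]


def synthetic_germline(config: GermlineConfig,
                       rng: np.random.Generator,
                       template: vnar_types.RegionTemplate = vnar_types.DEFAULT_TEMPLATE
                       ) -> SyntheticGermline:
    """Build the germline segment sequences for every configured cluster.

    V covers FR1..FR3b plus two germline CDR3 codons; J contributes two
    CDR3-tail codons plus FR4.  Cluster V genes diverge from the template by
    ``divergence`` synonymous/neutral substitutions (canonical cysteine and
    tryptophan codons are never touched), mirroring the high similarity of
    IgNAR cluster paralogs.
    """
    prefix_aa = "".join(template.regions[r] for r in
                        ("FR1", "CDR1", "FR2", "HV2", "FR3a", "FR3b"))
    cdr3_ref = template.regions["CDR3"]
    fr4_aa = template.regions["FR4"]
    v_anchor = 3 * (len(prefix_aa) - 1)          # FR3b canonical Cys codon
    base_v = _reverse_translate(prefix_aa + cdr3_ref[:2], rng)
    base_j = _reverse_translate(cdr3_ref[-2:] + fr4_aa, rng)
    j_anchor = 6                                  # FR4 Trp codon after 2 codons
    protected_v = set(range(v_anchor, v_anchor + 3)) | {3 * (len(template.regions["FR1"]) - 1) + k for k in range(3)}
    protected_j = set(range(j_anchor, j_anchor + 3))
    gl = SyntheticGermline({}, {}, {}, {}, {}, {}, {}, {}, {})
    for layout in config.clusters:
        idx = layout.name.replace("IgNAR", "")
        jn = f"IGNARJ{idx}"
        gl.j[jn] = _diverge_distinct(base_j, config.divergence, rng,
                                     protected_j, gl.j.values(),
                                     core=slice(j_anchor, None))
        gl.j_anchor[jn] = j_anchor
        gl.c[jn] = [_random_dna(290, rng, 0.5) for _ in range(5)]
        gl.sec[jn] = _random_dna(150, rng, 0.5)
        gl.tm[jn] = _random_dna(150, rng, 0.5)
        if layout.has_v:
            vn = f"IGNARV{idx}"
            gl.v[vn] = _diverge_distinct(base_v, config.divergence, rng,
                                         protected_v, gl.v.values(),
                                         core=slice(0, v_anchor + 3))
            gl.v_anchor[vn] = v_anchor
            ds = []
            for di in range(layout.n_d):
                dseq = _random_dna(config.d_length, rng, 0.5)
                ds.append(dseq)
                dname = f"IGNARD{idx}-{di + 1}"
                gl.prejoined[dname] = (layout.prejoined_last_d
                                       and di == layout.n_d - 1)
            gl.d[vn] = ds
    return gl


def _diverge_distinct(seq: str, rate: float, rng: np.random.Generator,
                      protected: set[int], existing, min_dist: int = 2,
                      core: slice = slice(None)) -> str:
    """Diverged copy guaranteed >= min_dist substitutions from every
    *existing* paralog inside ``core`` — the span junctional trimming can
    never remove — so germline gene calls stay identifiable from reads."""
    for _ in range(100):
        cand = _diverge(seq, rate, rng, protected)
        if all(_hamming(cand[core], e[core]) >= min_dist for e in existing):
            return cand
    raise RuntimeError("could not generate a distinct paralog; "
                       "raise the divergence rate")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b)) + abs(len(a) - len(b))


def _diverge(seq: str, rate: float, rng: np.random.Generator,
             protected: set[int]) -> str:
    """Substitute bases at *rate*, avoiding protected positions and new
    in-frame stop codons."""
    out = list(seq)
    for i in range(len(out)):
        if i in protected or rng.random() >= rate:
            continue
        old = out[i]
        for _ in range(8):
            new = rng.choice([b for b in "ACGT" if b != old])
            out[i] = new
            codon_start = 3 * (i // 3)
            codon = "".join(out[codon_start:codon_start + 3])
            if len(codon) < 3 or codon not in ("TAA", "TAG", "TGA"):
                break
            out[i] = old
    return "".join(out)


def _plant_rss(rng: np.random.Generator, spacer: int, hep_mm: int,
               non_mm: int) -> str:
    """Forward-orientation RSS text with exact planted mismatch counts."""
    hep = _mutate_exact(CANONICAL_HEPTAMER, hep_mm, rng)
    non = _mutate_exact(CANONICAL_NONAMER, non_mm, rng)
    return hep + _random_dna(spacer, rng, 0.5) + non


def _mutate_exact(motif: str, k: int, rng: np.random.Generator) -> str:
    out = list(motif)
    for i in rng.choice(len(motif), size=k, replace=False):
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def make_synthetic_genome(config: SimConfig,
                          rng: Optional[np.random.Generator] = None,
                          germline: Optional[SyntheticGermline] = None
                          ) -> tuple[dict[str, str], list[dict]]:
    """Plant the configured clusters into a background contig.

    Returns ``(contigs, features)`` where *features* is the truth list (one
    dict per planted segment or RSS, 0-based half-open coordinates).  Use
    :func:`write_genome` to produce the FASTA + GFF3 artifacts.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    gcfg = config.germline
    if germline is None:
        germline = synthetic_germline(gcfg, rng)
    gc = gcfg.background_gc
    parts: list[str] = []
    features: list[dict] = []
    pos = 0

    def emit(seq: str) -> int:
        nonlocal pos
        parts.append(seq)
        start = pos
        pos += len(seq)
        return start

    def emit_rss(spacer: int, orient: str, parent: str, layout: ClusterLayout):
        text = _plant_rss(rng, spacer, layout.rss_heptamer_mm,
                          layout.rss_nonamer_mm)
        if orient == "-":
            text = revcomp(text)
        start = emit(text)
        features.append(dict(type="RSS", id=f"{parent}_rss_{start}",
                             start=start, end=start + len(text),
                             strand=orient, spacer=spacer,
                             heptamer_mm=layout.rss_heptamer_mm,
                             nonamer_mm=layout.rss_nonamer_mm, parent=parent))

    def emit_segment(name: str, kind: str, seq: str):
        start = emit(seq)
        features.append(dict(type=kind, id=name, start=start,
                             end=start + len(seq), strand="+"))

    emit(_random_dna(1000, rng, gc))
    for layout in config.germline.clusters:
        idx = layout.name.replace("IgNAR", "")
        vn, jn = f"IGNARV{idx}", f"IGNARJ{idx}"
        if layout.has_v:
            emit_segment(vn, "V", germline.v[vn])
            emit_rss(gcfg.spacer_v, "+", vn, layout)      # V: downstream RSS
            emit(_random_dna(gcfg.segment_gap, rng, gc))
            for di, dseq in enumerate(germline.d[vn], start=1):
                dname = f"IGNARD{idx}-{di}"
                if not germline.prejoined.get(dname, False):
                    emit_rss(gcfg.spacer_d, "-", dname, layout)
                emit_segment(dname, "D", dseq)
                if not germline.prejoined.get(dname, False):
                    emit_rss(gcfg.spacer_d, "+", dname, layout)
                emit(_random_dna(gcfg.segment_gap, rng, gc))
        emit_rss(gcfg.spacer_j, "-", jn, layout)          # J: upstream RSS
        emit_segment(jn, "J", germline.j[jn])
        emit(_random_dna(gcfg.segment_gap, rng, gc))
        for ci, cseq in enumerate(germline.c[jn], start=1):
            emit_segment(f"IGNARC{idx}-{ci}", "C", cseq)
            emit(_random_dna(gcfg.segment_gap, rng, gc))
        emit_segment(f"IGNARSEC{idx}", "Sec", germline.sec[jn])
        emit(_random_dna(gcfg.segment_gap, rng, gc))
        emit_segment(f"IGNARTM{idx}", "Tm", germline.tm[jn])
        emit(_random_dna(gcfg.cluster_gap, rng, gc))
    contigs = {"chr44": "".join(parts)}
    for f in features:
        f["contig"] = "chr44"
    return contigs, features


def write_genome(contigs: dict[str, str], features: list[dict],
                 out_dir: str | Path) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / "genome.fasta"
    write_sequences([SeqEntry(k, v) for k, v in contigs.items()], fasta)
    gff = out_dir / "genome_truth.gff3"
    lines = ["##gff-version 3"]
    for f in features:
        ftype = ("recombination_feature" if f["type"] == "RSS"
                 else f"{f['type']}_gene_segment")
        attrs = [f"ID={f['id']}"]
        if f["type"] == "RSS":
            attrs += [f"spacer={f['spacer']}", f"heptamer_mm={f['heptamer_mm']}",
                      f"nonamer_mm={f['nonamer_mm']}", f"Parent={f['parent']}"]
        lines.append("\t".join([f["contig"], "ignarkit-sim", ftype,
                                str(f["start"] + 1), str(f["end"]), ".",
                                f["strand"], ".", ";".join(attrs)]))
    gff.write_text("\n".join(lines) + "\n")
    return fasta, gff


# ---------------------------------------------------------------------------
# repertoire simulation
# ---------------------------------------------------------------------------

@dataclass
class _Clone:
    clone_id: str
    v_call: str
    d_call: str
    j_call: str
    sequence: str          # rearranged, SHM applied
    cdr3_start: int
    cdr3_end: int
    n_shm: int
    v_trim: int = 0
    j_trim: int = 0
    n_insert: int = 0      # total non-templated bases

    @property
    def cdr3_nt(self) -> str:
        return self.sequence[self.cdr3_start:self.cdr3_end]


def _geometric0(rng: np.random.Generator, mean: float, cap: int) -> int:
    if mean <= 0:
        return 0
    return min(int(rng.geometric(1.0 / (mean + 1.0)) - 1), cap)


def _make_clone(clone_id: str, v: str, j: str, gl: SyntheticGermline,
                rcfg: RepertoireConfig, rng: np.random.Generator) -> _Clone:
    vseq, jseq = gl.v[v], gl.j[j]
    v_anchor, j_anchor = gl.v_anchor[v], gl.j_anchor[j]
    v_tail = len(vseq) - (v_anchor + 3)          # germline CDR3 head length
    v_trim = _geometric0(rng, rcfg.trim_mean, v_tail)
    j_trim = _geometric0(rng, rcfg.trim_mean, j_anchor)
    d_call, d_core = "none", ""
    if gl.d.get(v) and rng.random() < rcfg.d_usage:
        di = int(rng.integers(len(gl.d[v])))
        dseq = gl.d[v][di]
        idx = v.replace("IGNARV", "")
        lt = _geometric0(rng, rcfg.d_trim_mean, len(dseq) // 2)
        rt = _geometric0(rng, rcfg.d_trim_mean, len(dseq) // 2)
        core = dseq[lt:len(dseq) - rt]
        if core:
            d_call, d_core = f"IGNARD{idx}-{di + 1}", core
    for _attempt in range(200):
        n1 = "".join(rng.choice(list("ACGT"),
                                size=rng.poisson(rcfg.n_insert_mean)))
        n2 = "".join(rng.choice(list("ACGT"),
                                size=rng.poisson(rcfg.n_insert_mean)))
        junction = n1 + d_core + n2
        if not rcfg.identifiable_junctions or _junction_identifiable(
                junction, n1, n2, d_call, v_trim, j_trim, vseq, jseq,
                j_anchor, gl):
            break
    v_part = vseq[:len(vseq) - v_trim]
    j_part = jseq[j_trim:]
    seq = v_part + junction + j_part
    cdr3_start = v_anchor + 3
    cdr3_end = len(v_part) + len(junction) + (j_anchor - j_trim)
    seq, n_shm = _mutate_rate(seq, rcfg.shm_rate, rng)
    return _Clone(clone_id, v, d_call, j, seq, cdr3_start, cdr3_end, n_shm,
                  v_trim=v_trim, j_trim=j_trim, n_insert=len(n1) + len(n2))


def _junction_identifiable(junction: str, n1: str, n2: str, d_call: str,
                           v_trim: int, j_trim: int, vseq: str, jseq: str,
                           j_anchor: int, gl: SyntheticGermline) -> bool:
    """True when the planted parse is the unambiguous parsimonious one.

    Checks: (a) the first/last junction bases do not continue a trimmed
    germline match across the boundary; (b) a junction D scan returns
    exactly the planted D (or none).
    """
    from .annotate import call_d  # local import: annotate does not import us
    if v_trim > 0 and junction and junction[0] == vseq[len(vseq) - v_trim]:
        return False
    if j_trim > 0 and junction and junction[-1] == jseq[j_trim - 1]:
        return False
    all_d = {f"IGNARD{v.replace('IGNARV', '')}-{i + 1}": s
             for v, ds in gl.d.items() for i, s in enumerate(ds)}
    return call_d(junction, all_d) == d_call


def _mutate_rate(seq: str, rate: float, rng: np.random.Generator
                 ) -> tuple[str, int]:
    if rate <= 0:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode(), len(hits)


class ClonePool:
    """Per-pair clone pools with power-law size weights, shared across
    time points so clonal trajectories can be simulated."""

    def __init__(self, gl: SyntheticGermline, rcfg: RepertoireConfig,
                 rng: np.random.Generator):
        self.gl, self.rcfg, self.rng = gl, rcfg, rng
        self.pairs = list(rcfg.pair_probs)
        self.pair_p = np.array([rcfg.pair_probs[p] for p in self.pairs])
        self.pool_size: dict[str, int] = {}
        self.weights: dict[str, np.ndarray] = {}
        self.clones: dict[tuple[str, int], _Clone] = {}
        for pair, p in zip(self.pairs, self.pair_p):
            n = max(1, int(round(rcfg.n_clones * p)))
            w = np.arange(1, n + 1, dtype=float) ** (-rcfg.clone_exponent)
            self.pool_size[pair] = n
            self.weights[pair] = w / w.sum()

    def clone(self, pair: str, rank: int) -> _Clone:
        key = (pair, rank)
        if key not in self.clones:
            v, j = pair.split(":")
            self.clones[key] = _make_clone(f"{pair}|c{rank}", v, j, self.gl,
                                           self.rcfg, self.rng)
        return self.clones[key]

    def expand(self, pair: str, ranks: Sequence[int], factor: float) -> None:
        """Multiply chosen clones' weights (clonal expansion), renormalise."""
        w = self.weights[pair].copy()
        w[list(ranks)] *= factor
        self.weights[pair] = w / w.sum()


def simulate_repertoire(config: SimConfig, n_reads: int,
                        rng: Optional[np.random.Generator] = None,
                        germline: Optional[SyntheticGermline] = None,
                        pool: Optional[ClonePool] = None,
                        sample_id: str = "s1"
                        ) -> tuple[list[SeqEntry], pd.DataFrame]:
    """Emit FASTQ-ready reads plus one truth row per read.

    Truth CDR3 is taken from the clone's SHM-mutated rearrangement (what a
    perfect annotator sees before sequencing error).  Qualities are constant
    Q30.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    rcfg = config.repertoire
    if germline is None:
        germline = synthetic_germline(config.germline, rng)
    for pair in rcfg.pair_probs:
        v, j = pair.split(":")
        if v not in germline.v or j not in germline.j:
            raise ValueError(f"configured pair {pair} absent from germline")
    if pool is None:
        pool = ClonePool(germline, rcfg, rng)
    pair_idx = rng.choice(len(pool.pairs), size=n_reads, p=pool.pair_p)
    reads: list[SeqEntry] = []
    truth_rows = []
    for i in range(n_reads):
        pair = pool.pairs[pair_idx[i]]
        rank = int(rng.choice(pool.pool_size[pair], p=pool.weights[pair]))
        clone = pool.clone(pair, rank)
        seq = clone.sequence
        if rcfg.add_primers:
            seq = PRIMER_VNAR_V + seq + revcomp(PRIMER_VNAR_J)
        seq, n_err = _mutate_rate(seq, rcfg.seq_error, rng)
        seq = seq[:rcfg.read_length]
        read_id = f"{sample_id}_r{i}"
        reads.append(SeqEntry(read_id, seq, [30] * len(seq)))
        cdr3_nt = clone.cdr3_nt
        frame = "in" if len(cdr3_nt) % 3 == 0 else "out"
        truth_rows.append(dict(
            read_id=read_id, clone_id=clone.clone_id, v_call=clone.v_call,
            d_call=clone.d_call, j_call=clone.j_call, cdr3_nt=cdr3_nt,
            cdr3_aa=translate(cdr3_nt) if frame == "in" else "",
            frame=frame, n_shm=clone.n_shm, n_err=n_err, pair=pair,
            v_trim=clone.v_trim, j_trim=clone.j_trim,
            n_insert=clone.n_insert))
    return reads, pd.DataFrame(truth_rows)


def simulate_timecourse(config: SimConfig, n_reads: int, n_timepoints: int,
                        expanded_clones: int = 10, expansion_factor: float = 8.0,
                        rng: Optional[np.random.Generator] = None
                        ) -> list[tuple[list[SeqEntry], pd.DataFrame]]:
    """Repeated sampling of one individual with programmed clonal expansion.

    ``expanded_clones`` low-frequency clones of the dominant pair multiply
    their weight by ``expansion_factor`` at each successive time point,
    emulating antigen-driven expansion over an immunisation course.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    germline = synthetic_germline(config.germline, rng)
    pool = ClonePool(germline, config.repertoire, rng)
    dominant = pool.pairs[int(np.argmax(pool.pair_p))]
    n = pool.pool_size[dominant]
    lo = n // 2  # programmed clones start in the low-frequency tail
    ranks = list(range(lo, min(lo + expanded_clones, n)))
    out = []
    for t in range(n_timepoints):
        reads, truth = simulate_repertoire(
            config, n_reads, rng=rng, germline=germline, pool=pool,
            sample_id=f"tp{t + 1}")
        truth["timepoint"] = t + 1
        truth["programmed"] = truth["clone_id"].isin(
            {f"{dominant}|c{r}" for r in ranks})
        out.append((reads, truth))
        if t < n_timepoints - 1:
            pool.expand(dominant, ranks, expansion_factor)
    return out


# ---------------------------------------------------------------------------
# vNAR library simulation (amino acid)
# ---------------------------------------------------------------------------

def _library_sequence(vtype: str, cfg: LibraryConfig,
                      template: vnar_types.RegionTemplate,
                      rng: np.random.Generator) -> str:
    regions = {}
    for r in vnar_types.REGIONS:
        ref = template.regions[r]
        if r in ("CDR1", "HV2"):
            regions[r] = "".join(rng.choice(list(AA_NEUTRAL), size=len(ref)))
        elif r == "CDR3":
            ln = max(cfg.cdr3_length_min, int(rng.poisson(cfg.cdr3_length_mean)))
            regions[r] = "".join(rng.choice(list(AA_NEUTRAL), size=ln))
        else:
            out = list(ref)
            # framework diversity, sparing anchor Cys/Trp residues
            for i in range(len(out)):
                if out[i] in "CW":
                    continue
                if rng.random() < cfg.framework_diversity:
                    out[i] = rng.choice(list(AA_NEUTRAL))
            regions[r] = "".join(out)

    def place(region: str, n: int, residue: str = "C"):
        s = list(regions[region])
        free = [i for i, a in enumerate(s) if a not in "CW"]
        for i in rng.choice(free, size=n, replace=False):
            s[i] = residue
        regions[region] = "".join(s)

    if vtype == "I":
        place("FR2", 1)
        place("FR4", 1)
        place("CDR3", 2)
    elif vtype == "II":
        place("CDR1", 1)
        place("CDR3", 1 if rng.random() < cfg.p_single_cdr3_cys else 2)
    elif vtype == "III":
        place("CDR1", 1)
        place("CDR1", 1, "W")
        place("CDR3", 1 if rng.random() < cfg.p_single_cdr3_cys else 2)
    elif vtype == "IV":
        pass
    elif vtype == "new":
        place("FR2", 1)   # canonical pair + lone FR2 Cys: fits no named type
    else:
        raise ValueError(f"unknown vNAR type {vtype!r}")
    return "".join(regions[r] for r in vnar_types.REGIONS)


def simulate_vnar_library(config: SimConfig, n_seqs: int,
                          rng: Optional[np.random.Generator] = None
                          ) -> tuple[list[SeqEntry], pd.DataFrame]:
    """Amino-acid vNAR library at the configured type mixture + duplication.

    Each emitted slot is a fresh draw from the type mixture with probability
    ``unique_fraction``, otherwise a uniform resample of an earlier
    sequence, so the distinct/total ratio is binomial around the configured
    uniqueness.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lcfg = config.library
    types = list(lcfg.type_mixture)
    probs = np.array([lcfg.type_mixture[t] for t in types])
    entries: list[SeqEntry] = []
    rows = []
    fresh: list[tuple[str, str]] = []   # (sequence, type)
    for i in range(n_seqs):
        if not fresh or rng.random() < lcfg.unique_fraction:
            vtype = types[int(rng.choice(len(types), p=probs))]
            seq = _library_sequence(vtype, lcfg, vnar_types.DEFAULT_TEMPLATE, rng)
            fresh.append((seq, vtype))
            dup = False
        else:
            seq, vtype = fresh[int(rng.integers(len(fresh)))]
            dup = True
        sid = f"lib_{i}"
        entries.append(SeqEntry(sid, seq))
        rows.append(dict(seq_id=sid, type=vtype, n_cys=seq.count("C"),
                         duplicate=dup))
    return entries, pd.DataFrame(rows)
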
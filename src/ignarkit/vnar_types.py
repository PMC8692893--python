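"""Cysteine-pattern classification of vNAR domains.

The single variable domain of IgNAR (vNAR) is stabilised by a canonical
disulfide between two framework cysteines, one in FR1 and one in FR3b.
The classical vNAR taxonomy is defined by where *additional* (non-canonical)
cysteines sit:

* **Type I** — extra cysteines in FR2 and FR4 plus an even number (>= 2) in
  CDR3, none in CDR1; the CDR3 is pinned to the framework by two disulfides.
* **Type II** — exactly one extra cysteine in CDR1 and at least one in CDR3
  (a CDR1–CDR3 disulfide), none in FR2/FR4.
* **Type III** — the type II pattern with a conserved tryptophan in CDR1.
* **Type IV** — the canonical pair only.
* **new** — anything else, including domains lacking the canonical pair.

Region labels follow the vNAR convention FR1, CDR1, FR2, HV2, FR3a, FR3b,
CDR3, FR4 (HV2 is the hypervariable loop unique to vNARs/TCRs).  Regions are
assigned by alignment to a region-annotated reference template; the template
ships as data (YAML-editable) so other numbering conventions can be used.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml
from Bio import Align
from Bio.Align import substitution_matrices

REGIONS = ("FR1", "CDR1", "FR2", "HV2", "FR3a", "FR3b", "CDR3", "FR4")
FRAMEWORK_REGIONS = ("FR1", "FR2", "FR3a", "FR3b", "FR4")
TYPES = ("I", "II", "III", "IV", "new")


@dataclass(frozen=True)
class RegionTemplate:
    """Region-annotated vNAR reference frame.

    ``regions`` maps each region label to its reference amino-acid stretch;
    the canonical cysteines sit at the last FR1 and last FR3b positions, the
    conserved tryptophans at FR2[2] and FR4[0] of the default template.
    """

    regions: dict[str, str]

    def __post_init__(self):
        missing = [r for r in REGIONS if r not in self.regions]
        if missing:
            raise ValueError(f"template missing regions: {missing}")

    @property
    def sequence(self) -> str:
        return "".join(self.regions[r] for r in REGIONS)

    @property
    def labels(self) -> list[str]:
        out = []
        for r in REGIONS:
            out.extend([r] * len(self.regions[r]))
        return out

    def region_length(self, region: str) -> int:
        return len(self.regions[region])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RegionTemplate":
        data = yaml.safe_load(Path(path).read_text())
        return cls(regions={r: str(data[r]) for r in REGIONS})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dict(self.regions)))


#: default reference frame (~100 aa).  FR1 ends in the canonical cysteine,
#: FR3b ends in the second canonical cysteine immediately before CDR3,
#: FR2 carries the conserved tryptophan adjacent to the disulfide, FR4
#: begins with the conserved J-encoded tryptophan motif.
DEFAULT_TEMPLATE = RegionTemplate(regions={
    "FR1": "ARVDQTPQTITKETGESLTINC",
    "CDR1": "DSNSAL",
    "FR2": "TYWYRKNPGS",
    "HV2": "TNEESISK",
    "FR3a": "GGRYVETVNS",
    "FR3b": "GSKSFSLRIKDLTVADSATYYC",
    "CDR3": "GRSGAYGSSYDV",
    "FR4": "WGQGTQVTVN",
})


@dataclass
class RegionMap:
    """Per-residue region labels for one vNAR amino-acid sequence."""

    labels: list[str]
    framework_identity: float

    def residues(self, seq: str, region: str) -> str:
        return "".join(a for a, l in zip(seq, self.labels) if l == region)


@dataclass
class TypeCall:
    type: str
    cysteine_count: int
    canonical_pair_present: bool
    noncanonical_positions: list[str] = field(default_factory=list)


class UnalignableSequence(ValueError):
    """Sequence too diverged from the reference frame to label regions."""


def _global_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11
    a.extend_gap_score = -1
    return a


def assign_regions(seq: str,
                   template: RegionTemplate = DEFAULT_TEMPLATE,
                   min_framework_identity: float = 0.5) -> RegionMap:
    """Label every residue of *seq* with its vNAR region.

    Fast path: when only CDR3 length differs from the template (the common
    case — vNAR framework and CDR1/HV2 lengths are essentially fixed), the
    framework prefix (FR1..FR3b) and FR4 suffix are compared ungapped and
    the middle is CDR3.  Otherwise a global alignment to the annotated
    reference propagates labels; insertion columns inherit the neighbouring
    region, preferring the hypervariable one at region boundaries.

    Raises :class:`UnalignableSequence` when framework identity falls below
    ``min_framework_identity``.
    """
    if len(seq) < 60:
        raise UnalignableSequence(f"sequence of {len(seq)} aa; need >= 60")
    prefix_labels = [l for l in template.labels if l not in ("CDR3", "FR4")]
    p, s = len(prefix_labels), template.region_length("FR4")
    tmpl_seq = template.sequence
    if len(seq) >= p + s:
        fw_mask = [l in FRAMEWORK_REGIONS for l in prefix_labels]
        pre_pairs = [(a, b) for a, b, m in zip(tmpl_seq[:p], seq[:p], fw_mask) if m]
        pre_id = (sum(a == b for a, b in pre_pairs) / len(pre_pairs)
                  if pre_pairs else 0.0)
        suf_id = _ungapped_identity(tmpl_seq[-s:], seq[-s:])
        if pre_id >= 0.8 and suf_id >= 0.8:
            labels = prefix_labels + ["CDR3"] * (len(seq) - p - s) + ["FR4"] * s
            fw_id = _framework_identity(seq, labels, template)
            return RegionMap(labels=labels, framework_identity=fw_id)
    return _assign_by_alignment(seq, template, min_framework_identity)


def _ungapped_identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    return sum(x == y for x, y in zip(a, b)) / n if n else 0.0


def _framework_identity(seq: str, labels: Sequence[str],
                        template: RegionTemplate) -> float:
    matches = total = 0
    per_region_pos: dict[str, int] = {r: 0 for r in REGIONS}
    for aa, label in zip(seq, labels):
        i = per_region_pos[label]
        per_region_pos[label] += 1
        if label in FRAMEWORK_REGIONS:
            ref = template.regions[label]
            if i < len(ref):
                total += 1
                matches += aa == ref[i]
    return matches / total if total else 0.0


def _assign_by_alignment(seq: str, template: RegionTemplate,
                         min_framework_identity: float) -> RegionMap:
    aln = _global_aligner().align(template.sequence, seq)[0]
    tmpl_labels = template.labels
    labels: list[Optional[str]] = [None] * len(seq)
    fw_match = fw_total = 0
    t_idx = q_idx = 0
    tmpl_aln, query_aln = aln[0], aln[1]
    for tc, qc in zip(tmpl_aln, query_aln):
        if tc != "-" and qc != "-":
            label = tmpl_labels[t_idx]
            labels[q_idx] = label
            if label in FRAMEWORK_REGIONS:
                fw_total += 1
                fw_match += tc == qc
        if tc != "-":
            t_idx += 1
        if qc != "-":
            q_idx += 1
    # insertion columns: inherit a neighbour, preferring hypervariable labels
    hyper = {"CDR1", "HV2", "CDR3"}
    for i, l in enumerate(labels):
        if l is None:
            prev = next((labels[j] for j in range(i - 1, -1, -1)
                         if labels[j] is not None), None)
            nxt = next((labels[j] for j in range(i + 1, len(labels))
                        if labels[j] is not None), None)
            if nxt in hyper:
                labels[i] = nxt
            elif prev in hyper or prev is not None:
                labels[i] = prev
            else:
                labels[i] = nxt or "FR1"
    fw_id = fw_match / fw_total if fw_total else 0.0
    if fw_id < min_framework_identity:
        raise UnalignableSequence(
            f"framework identity {fw_id:.2f} below {min_framework_identity}")
    return RegionMap(labels=[l or "FR1" for l in labels],
                     framework_identity=fw_id)


def classify_type(region_map: RegionMap, seq: str) -> TypeCall:
    """Apply the vNAR type rule table to one region-labelled sequence.

    The rules form a partition: every sequence receives exactly one of
    I/II/III/IV/new.  Any cysteine beyond the single canonical one in FR1 or
    FR3b, or any cysteine in HV2/FR3a, disqualifies the named types.
    """
    cys_by_region = Counter(l for a, l in zip(seq, region_map.labels)
                            if a == "C")
    total_cys = sum(cys_by_region.values())
    f1, f3b = cys_by_region["FR1"], cys_by_region["FR3b"]
    c1, c3 = cys_by_region["CDR1"], cys_by_region["CDR3"]
    f2, f4 = cys_by_region["FR2"], cys_by_region["FR4"]
    stray = cys_by_region["HV2"] + cys_by_region["FR3a"]
    canonical = f1 >= 1 and f3b >= 1
    noncanon = [r for r in ("CDR1", "FR2", "HV2", "FR3a", "CDR3", "FR4")
                if cys_by_region[r] > 0]
    if f1 > 1:
        noncanon.append("FR1")
    if f3b > 1:
        noncanon.append("FR3b")

    named_base = canonical and f1 == 1 and f3b == 1 and stray == 0
    if named_base and f2 == 1 and f4 == 1 and c1 == 0 and c3 >= 2 and c3 % 2 == 0:
        vtype = "I"
    elif named_base and f2 == 0 and f4 == 0 and c1 == 1 and c3 >= 1:
        cdr1 = region_map.residues(seq, "CDR1")
        vtype = "III" if "W" in cdr1 else "II"
    elif named_base and f2 == 0 and f4 == 0 and c1 == 0 and c3 == 0:
        vtype = "IV"
    else:
        vtype = "new"
    return TypeCall(type=vtype, cysteine_count=total_cys,
                    canonical_pair_present=canonical,
                    noncanonical_positions=sorted(set(noncanon)))


def classify_sequences(seqs: Sequence[str],
                       template: RegionTemplate = DEFAULT_TEMPLATE,
                       min_framework_identity: float = 0.5
                       ) -> list[Optional[TypeCall]]:
    """Region-assign and type every sequence; ``None`` marks unalignable."""
    calls: list[Optional[TypeCall]] = []
    for s in seqs:
        try:
            rm = assign_regions(s, template, min_framework_identity)
        except UnalignableSequence:
            calls.append(None)
            continue
        calls.append(classify_type(rm, s))
    return calls


def type_profile(seqs: Sequence[str],
                 calls: Optional[Sequence[Optional[TypeCall]]] = None,
                 template: RegionTemplate = DEFAULT_TEMPLATE) -> dict:
    """Per-type percentages, cysteine-count histogram and uniqueness.

    Percentages are over classified (alignable) sequences and sum to 100.
    """
    if not seqs:
        raise ValueError("empty sequence set")
    if calls is None:
        calls = classify_sequences(seqs, template)
    typed = [c for c in calls if c is not None]
    if not typed:
        raise ValueError("no classifiable sequences")
    n = len(typed)
    type_counts = Counter(c.type for c in typed)
    cys_counts = Counter(c.cysteine_count for c in typed)
    return {
        "n_classified": n,
        "n_unalignable": len(calls) - n,
        "type_percent": {t: 100.0 * type_counts.get(t, 0) / n for t in TYPES},
        "cysteine_count_percent": {int(k): 100.0 * v / n
                                   for k, v in sorted(cys_counts.items())},
        "unique_fraction": len(set(seqs)) / len(seqs),
    }
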
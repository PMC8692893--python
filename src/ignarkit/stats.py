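"""Repertoire summary statistics.

All statistics operate on clonotype tables or annotated samples.  A
clonotype is the equivalence class ``(v_call, j_call, cdr3_aa)``; only
pass-QC rearrangements enter any statistic, and by default only productive
ones (switchable, since whether out-of-frame clonotypes belong in diversity
summaries is a convention choice).

Diversity is the Shannon–Wiener index H = -sum p_i ln p_i in nats (the
log base is a convention; Pielou evenness H / ln k is reported alongside
for comparability across sample sizes).  Positional amino-acid variability
is the Wu–Kabat score: (number of distinct residues) / (frequency of the
most common residue), 1.0 at an invariant column.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import entropy

from .annotate import RepertoireSample

REGIONS = ("FR1", "CDR1", "FR2", "HV2", "FR3a", "FR3b", "CDR3", "FR4")


@dataclass
class ClonotypeTable:
    """Clonotype -> read count, with derived frequencies."""

    counts: "pd.Series[int]"

    def __post_init__(self):
        if (self.counts < 1).any():
            raise ValueError("clonotype counts must be >= 1")

    @classmethod
    def from_sample(cls, sample: RepertoireSample,
                    productive_only: bool = True) -> "ClonotypeTable":
        keys = [" | ".join(r.clonotype) for r in sample.passing()
                if (r.productive or not productive_only) and r.cdr3_aa]
        if not keys:
            raise ValueError(f"empty sample {sample.sample_id!r}")
        return cls(pd.Series(Counter(keys)).sort_index())

    @classmethod
    def from_counts(cls, counts: dict) -> "ClonotypeTable":
        return cls(pd.Series(counts).sort_index())

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> "pd.Series[float]":
        return self.counts / self.total

    def __len__(self) -> int:
        return len(self.counts)


def shannon_index(table: ClonotypeTable) -> float:
    """Shannon–Wiener diversity H = -sum p ln p (nats) over clonotypes."""
    if len(table) == 0 or table.total == 0:
        raise ValueError("empty sample")
    return float(entropy(table.counts.to_numpy()))


def pielou_evenness(table: ClonotypeTable) -> float:
    """H normalised by its maximum ln(k); defined as 1.0 for k = 1."""
    k = len(table)
    return 1.0 if k == 1 else shannon_index(table) / float(np.log(k))


def positional_variability(sequences: Sequence[str],
                           region_labels: Optional[Sequence[str]] = None
                           ) -> pd.DataFrame:
    """Wu–Kabat variability per aligned column.

    *sequences* must be equal length (gaps ``-`` allowed and excluded from
    residue counts).  Returns a frame with columns ``position``, ``region``
    (if labels given), ``variability``, ``coverage``; zero-coverage columns
    carry NaN variability.
    """
    if not sequences:
        raise ValueError("no sequences")
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("sequences are not aligned to a common length")
    if region_labels is not None and len(region_labels) != length:
        raise ValueError("region label track length mismatch")
    rows = []
    for i in range(length):
        col = [s[i] for s in sequences if s[i] not in "-."]
        if col:
            counts = Counter(col)
            top_freq = max(counts.values()) / len(col)
            var = len(counts) / top_freq
        else:
            var = float("nan")
        rows.append(dict(position=i,
                         region=(region_labels[i] if region_labels is not None
                                 else ""),
                         variability=var, coverage=len(col)))
    return pd.DataFrame(rows)


def vj_pair_matrix(sample: RepertoireSample, weight: str = "read",
                   productive_only: bool = False) -> pd.DataFrame:
    """V x J pairing frequency matrix summing to 1 over pass-QC reads.

    ``weight="read"`` counts every read; ``weight="clonotype"`` counts each
    distinct clonotype once.
    """
    recs = [r for r in sample.passing()
            if r.v_call and r.j_call and (r.productive or not productive_only)]
    if not recs:
        raise ValueError("no assigned rearrangements")
    if weight == "clonotype":
        seen = {r.clonotype: r for r in recs}
        recs = list(seen.values())
    df = pd.DataFrame({"v": [r.v_call for r in recs],
                       "j": [r.j_call for r in recs]})
    return pd.crosstab(df["v"], df["j"], normalize="all")


def v_usage(sample: RepertoireSample, **kwargs) -> pd.Series:
    return vj_pair_matrix(sample, **kwargs).sum(axis=1)


def j_usage(sample: RepertoireSample, **kwargs) -> pd.Series:
    return vj_pair_matrix(sample, **kwargs).sum(axis=0)


def top_n_cumulative(table: ClonotypeTable, n: int) -> float:
    """Cumulative frequency of the n most frequent clonotypes.

    Ties break by clonotype key order; n beyond the table size returns 1.0.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    freqs = table.frequencies
    ordered = freqs.sort_index().sort_values(ascending=False, kind="stable")
    return float(ordered.iloc[:n].sum())


def unique_ratio(sequences: Sequence[str]) -> dict:
    """Sequence-level uniqueness of a sample.

    ``distinct_fraction`` (primary) = distinct / total; ``singleton_fraction``
    = reads whose sequence occurs exactly once / total.
    """
    if not sequences:
        raise ValueError("no sequences")
    counts = Counter(sequences)
    total = len(sequences)
    singletons = sum(1 for c in counts.values() if c == 1)
    return {"distinct_fraction": len(counts) / total,
            "singleton_fraction": singletons / total,
            "total": total, "distinct": len(counts)}


def clonotype_overlap(a: ClonotypeTable, b: ClonotypeTable,
                      method: str = "min") -> float:
    """Shared-clonotype rate between two samples.

    ``min``: |A n B| / min(|A|, |B|) (symmetric; 1.0 when one sample's
    clonotypes are a subset of the other's).  ``jaccard``: |A n B| / |A u B|.
    """
    sa, sb = set(a.counts.index), set(b.counts.index)
    if not sa or not sb:
        raise ValueError("overlap undefined for an empty sample")
    shared = len(sa & sb)
    if method == "min":
        return shared / min(len(sa), len(sb))
    if method == "jaccard":
        return shared / len(sa | sb)
    raise ValueError(f"unknown overlap method {method!r}")


def clonotype_tracking(tables: Sequence[ClonotypeTable], top_n: int = 100
                       ) -> pd.DataFrame:
    """Frequency trajectories of the union of each time point's top-n
    clonotypes; residual mass appears as the ``other`` row.  Columns are
    time points (1-based) and sum to 1 each.
    """
    if len(tables) < 2:
        raise ValueError("tracking needs >= 2 time points")
    union: list[str] = []
    for t in tables:
        ordered = (t.frequencies.sort_index()
                   .sort_values(ascending=False, kind="stable"))
        for key in ordered.index[:top_n]:
            if key not in union:
                union.append(key)
    data = {}
    for i, t in enumerate(tables, start=1):
        freqs = t.frequencies
        col = [float(freqs.get(k, 0.0)) for k in union]
        data[i] = col + [1.0 - sum(col)]
    return pd.DataFrame(data, index=union + ["other"])


def sample_summary(sample: RepertoireSample, top_n: int = 100,
                   productive_only: bool = True) -> dict:
    """One-stop per-sample statistics bundle (JSON-serialisable)."""
    table = ClonotypeTable.from_sample(sample, productive_only)
    read_seqs = [r.sequence for r in sample.passing()]
    collapsed = ClonotypeTable.from_counts(
        {k: 1 for k in table.counts.index})
    return {
        "sample_id": sample.sample_id,
        "n_reads": len(sample.rearrangements),
        "n_pass_qc": len(sample.passing()),
        "n_clonotypes": len(table),
        "shannon_read_weighted": shannon_index(table),
        "shannon_clonotype_collapsed": shannon_index(collapsed),
        "pielou_evenness": pielou_evenness(table),
        "top_n_cumulative": top_n_cumulative(table, top_n),
        "unique": unique_ratio(read_seqs),
        "cdr3_lengths": Counter(len(r.cdr3_aa) for r in sample.passing()
                                if r.cdr3_aa),
    }
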
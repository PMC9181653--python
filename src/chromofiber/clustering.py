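"""Grouping of strand breaks by genomic distance and lesion-complexity
classification (Nikjoo scheme).

Within one primary history, breaks are clustered by single linkage on the
bp index alone (strand-blind): two breaks are connected when their bp
separation is at most the clustering distance ``n_bp``, and clusters are the
maximal connected components.  Classification then inspects strands:

* one strand, one break              → SSB
* one strand, several breaks         → SSB+
* both strands represented           → DSB family: DSB (exactly two breaks),
  DSB+ (one opposite-strand pair plus extras), DSB++ (two or more pairs)

A mixed-strand cluster always contains an opposite-strand pair within
``n_bp`` (some edge of the connecting chain joins opposite strands), so the
"2SSB" configuration — opposite-strand breaks farther apart than ``n_bp`` —
can only arise across clusters; it is reported as a derived per-history
statistic, not a cluster label.

The DSB multiplicity of a mixed cluster is ``min(#strand0, #strand1)``, the
size of a maximal disjoint opposite-strand pairing; this makes total strand
breaks = SSB breaks + 2 x DSB count an identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .damage import StrandBreak
from .errors import InvalidArgumentError

__all__ = [
    "ClusterConfig",
    "DamageCluster",
    "DamageTally",
    "cluster_breaks",
    "classify_cluster",
    "two_ssb_count",
    "tally",
    "clusters_to_frame",
]

CANONICAL_DISTANCES_BP = (3, 10, 30, 40)

LABELS = ("SSB", "SSB+", "DSB", "DSB+", "DSB++")


@dataclass(frozen=True)
class ClusterConfig:
    """Clustering distance in base pairs (canonically 3, 10, 30 or 40)."""

    n_bp: int = 10

    def __post_init__(self) -> None:
        if self.n_bp < 1:
            raise InvalidArgumentError("n_bp must be >= 1")


@dataclass(frozen=True)
class DamageCluster:
    breaks: tuple[StrandBreak, ...]
    label: str
    dsb_multiplicity: int

    @property
    def history_id(self) -> int:
        return self.breaks[0].history_id

    @property
    def span(self) -> tuple[int, int]:
        idx = [b.bp_index for b in self.breaks]
        return min(idx), max(idx)

    @property
    def n_breaks(self) -> int:
        return len(self.breaks)


def classify_cluster(breaks: Sequence[StrandBreak], config: ClusterConfig) -> tuple[str, int]:
    """Complexity label and DSB multiplicity of one cluster."""
    n0 = sum(1 for b in breaks if b.strand == 0)
    n1 = len(breaks) - n0
    if n0 == 0 or n1 == 0:
        return ("SSB", 0) if len(breaks) == 1 else ("SSB+", 0)
    multiplicity = min(n0, n1)
    if multiplicity >= 2:
        return "DSB++", multiplicity
    if len(breaks) == 2:
        return "DSB", 1
    return "DSB+", 1


def cluster_breaks(breaks: Sequence[StrandBreak], config: ClusterConfig) -> list[DamageCluster]:
    """Single-linkage clustering of breaks per history.

    In one dimension single linkage reduces to splitting the bp-sorted break
    list wherever the gap to the previous break exceeds ``n_bp``; the result
    is identical to connected components of the |bp_i - bp_j| <= n_bp graph
    and is deterministic.
    """
    if not breaks:
        return []
    ordered = sorted(breaks, key=lambda b: (b.history_id, b.bp_index, b.strand))
    clusters: list[DamageCluster] = []
    current: list[StrandBreak] = [ordered[0]]
    for brk in ordered[1:]:
        prev = current[-1]
        if brk.history_id == prev.history_id and brk.bp_index - prev.bp_index <= config.n_bp:
            current.append(brk)
        else:
            label, mult = classify_cluster(current, config)
            clusters.append(DamageCluster(tuple(current), label, mult))
            current = [brk]
    label, mult = classify_cluster(current, config)
    clusters.append(DamageCluster(tuple(current), label, mult))
    return clusters


def two_ssb_count(clusters: Sequence[DamageCluster]) -> int:
    """Derived 2SSB statistic: per history, the number of opposite-strand
    pairs formed by single-strand clusters lying farther apart than the
    clustering distance (greedy pairing = min of the per-strand counts)."""
    per_history: dict[int, list[int]] = {}
    for c in clusters:
        if c.label in ("SSB", "SSB+"):
            strand = c.breaks[0].strand
            per_history.setdefault(c.history_id, [0, 0])[strand] += 1
    return sum(min(v[0], v[1]) for v in per_history.values())


@dataclass(frozen=True)
class DamageTally:
    """Per-ensemble damage bookkeeping.

    Yields are raw counts plus normalized values per Gy per Gbp.  The
    ``ssb_dsb_ratio`` is omitted (None) when no DSB was scored.  Total
    strand breaks satisfy tsb = ssb_breaks + 2 * dsb_count.
    """

    counts_by_label: dict[str, int]
    total_breaks: int
    dsb_count: int
    ssb_break_count: int
    two_ssb: int
    dose_gy: float
    genome_gbp: float
    ssb_yield: float = field(init=False)
    dsb_yield: float = field(init=False)
    tsb_yield: float = field(init=False)

    def __post_init__(self) -> None:
        norm = self.dose_gy * self.genome_gbp
        object.__setattr__(self, "ssb_yield", self.ssb_break_count / norm)
        object.__setattr__(self, "dsb_yield", self.dsb_count / norm)
        object.__setattr__(self, "tsb_yield", self.total_breaks / norm)

    @property
    def tsb(self) -> int:
        return self.total_breaks

    @property
    def ssb_dsb_ratio(self) -> float | None:
        if self.dsb_count == 0:
            return None
        return self.ssb_break_count / self.dsb_count

    def to_dict(self) -> dict:
        return {
            "counts_by_label": dict(self.counts_by_label),
            "total_breaks": self.total_breaks,
            "dsb_count": self.dsb_count,
            "ssb_break_count": self.ssb_break_count,
            "two_ssb": self.two_ssb,
            "dose_gy": self.dose_gy,
            "genome_gbp": self.genome_gbp,
            "ssb_yield_per_gy_gbp": self.ssb_yield,
            "dsb_yield_per_gy_gbp": self.dsb_yield,
            "tsb_yield_per_gy_gbp": self.tsb_yield,
            "ssb_dsb_ratio": self.ssb_dsb_ratio,
        }


def tally(clusters: Sequence[DamageCluster], dose_gy: float, genome_bp: float) -> DamageTally:
    """Aggregate clusters into SSB/DSB/TSB yields.

    ``dsb_count`` sums DSB multiplicities; ``ssb_break_count`` is every break
    not consumed by a DSB pair, so tsb = ssb + 2*dsb exactly.
    Yields are normalized per Gy and per Gbp of DNA in the scoring region.
    """
    if dose_gy <= 0:
        raise InvalidArgumentError("dose must be > 0")
    if genome_bp <= 0:
        raise InvalidArgumentError("genome_bp must be > 0")
    counts = {label: 0 for label in LABELS}
    total_breaks = 0
    dsb_count = 0
    for c in clusters:
        counts[c.label] += 1
        total_breaks += c.n_breaks
        dsb_count += c.dsb_multiplicity
    return DamageTally(
        counts_by_label=counts,
        total_breaks=total_breaks,
        dsb_count=dsb_count,
        ssb_break_count=total_breaks - 2 * dsb_count,
        two_ssb=two_ssb_count(clusters),
        dose_gy=dose_gy,
        genome_gbp=genome_bp / 1e9,
    )


def clusters_to_frame(clusters: Sequence[DamageCluster]) -> pd.DataFrame:
    """Cluster table: one row per damage cluster."""
    rows = [
        {
            "history_id": c.history_id,
            "label": c.label,
            "span_min": c.span[0],
            "span_max": c.span[1],
            "n_breaks": c.n_breaks,
            "dsb_multiplicity": c.dsb_multiplicity,
        }
        for c in clusters
    ]
    return pd.DataFrame(rows, columns=["history_id", "label", "span_min", "span_max", "n_breaks", "dsb_multiplicity"])


def write_sdd_minimal(clusters: Sequence[DamageCluster], geometry, path: str) -> None:
    """Minimal Standard-DNA-Damage-style record: one line per cluster with
    the lab-frame position of the span centroid and a label code."""
    codes = {"SSB": 0, "SSB+": 1, "DSB": 2, "DSB+": 3, "DSB++": 4}
    with open(path, "w") as fh:
        fh.write("# chromofiber minimal SDD-style damage records\n")
        fh.write("# history_id, x_nm, y_nm, z_nm, label_code, n_breaks, dsb_multiplicity\n")
        for c in clusters:
            mid_bp = (c.span[0] + c.span[1]) // 2
            x, y, z = geometry.origins[mid_bp]
            fh.write(
                f"{c.history_id}, {x:.3f}, {y:.3f}, {z:.3f}, {codes[c.label]}, {c.n_breaks}, {c.dsb_multiplicity}\n"
            )
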
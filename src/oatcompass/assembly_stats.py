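"""Scaffold-level assembly summary statistics.

N50 is the length of the scaffold at which the cumulative length, taken in
descending order, first reaches half the assembly; L50 is that scaffold's
rank. Gap accounting follows the convention that a run of 20 or more Ns is
a contig break: scaffolds are split on such runs to count contigs, and the
mean break length is reported.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

from .errors import ValidationError

_GAP_RE = re.compile(r"N{20,}")
_VALID_RE = re.compile(r"[^ACGTN]")


@dataclass(frozen=True)
class AssemblyStats:
    n_scaffolds: int
    total_bp: int
    longest_bp: int
    shortest_bp: int
    n50_bp: int
    l50: int
    base_fractions: dict[str, float] = field(default_factory=dict)
    gc_fraction: float = 0.0
    n_gap_runs: int = 0
    contig_count: int = 0
    mean_gap_bp: float = 0.0


def compute_assembly_stats(sequences: dict[str, str]) -> AssemblyStats:
    """Summary statistics over a named scaffold set (alphabet ACGTN)."""
    if not sequences:
        raise ValidationError("empty sequence set")
    lengths = []
    base_counts: Counter[str] = Counter()
    n_gap_runs = 0
    gap_bp = 0
    contig_count = 0
    for name, seq in sequences.items():
        up = seq.upper()
        bad = _VALID_RE.search(up)
        if bad:
            raise ValidationError(
                f"illegal character {bad.group()!r} in {name!r} at position {bad.start()}"
            )
        lengths.append(len(up))
        base_counts.update(up)
        gaps = _GAP_RE.findall(up)
        n_gap_runs += len(gaps)
        gap_bp += sum(len(g) for g in gaps)
        contig_count += sum(1 for part in _GAP_RE.split(up) if part)
    total = sum(lengths)
    if total == 0:
        raise ValidationError("all scaffolds are empty")
    lengths_desc = sorted(lengths, reverse=True)
    cum = 0
    n50 = l50 = 0
    for rank, ln in enumerate(lengths_desc, start=1):
        cum += ln
        if cum * 2 >= total:
            n50, l50 = ln, rank
            break
    fractions = {b: base_counts.get(b, 0) / total for b in "ACGTN"}
    acgt = total - base_counts.get("N", 0)
    gc = (base_counts.get("G", 0) + base_counts.get("C", 0)) / acgt if acgt else 0.0
    return AssemblyStats(
        n_scaffolds=len(lengths),
        total_bp=total,
        longest_bp=max(lengths),
        shortest_bp=min(lengths),
        n50_bp=n50,
        l50=l50,
        base_fractions=fractions,
        gc_fraction=gc,
        n_gap_runs=n_gap_runs,
        contig_count=contig_count,
        mean_gap_bp=gap_bp / n_gap_runs if n_gap_runs else 0.0,
    )


def stats_report(stats: AssemblyStats) -> str:
    """TSV report with one metric per row."""
    rows = [
        ("Number of scaffolds", stats.n_scaffolds),
        ("Total size of scaffolds (bp)", stats.total_bp),
        ("Longest scaffold (bp)", stats.longest_bp),
        ("Shortest scaffold (bp)", stats.shortest_bp),
        ("N50 scaffold length", stats.n50_bp),
        ("L50 scaffold count", stats.l50),
        ("Scaffold % A", round(100 * stats.base_fractions["A"], 2)),
        ("Scaffold % C", round(100 * stats.base_fractions["C"], 2)),
        ("Scaffold % G", round(100 * stats.base_fractions["G"], 2)),
        ("Scaffold % T", round(100 * stats.base_fractions["T"], 2)),
        ("Scaffold % N", round(100 * stats.base_fractions["N"], 2)),
        ("GC content (%)", round(100 * stats.gc_fraction, 2)),
        ("Number of gaps (>=20 Ns)", stats.n_gap_runs),
        ("Number of contigs", stats.contig_count),
        ("Average gap length (bp)", round(stats.mean_gap_bp, 1)),
    ]
    return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"
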
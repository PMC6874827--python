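"""Tag-marker placement, linkage-group assignment, and arm merging.

Short genotyping-by-sequencing tags (64 bp by default) are located on an
assembly at perfect identity only: a tag is placed iff it (or its reverse
complement) occurs exactly once genome-wide; everything else is rejected as
``no_hit`` or ``multi_hit``. Placed tags carry a linkage group (LG) and cM
position from a consensus genetic map, which lets scaffolds be assigned to
LGs by plurality vote and, when two scaffolds share an LG, ordered and
oriented into a single pseudo-chromosome joined with a run of Ns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import MergeConflictError, ValidationError
from .seq import revcomp

PLACEMENT_COLUMNS = ["marker_id", "chromosome", "position", "strand"]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (table-style percentages)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _rolling_hash_hits(
    sequences: dict[str, str], probes: dict[str, list]
) -> None:
    """Append (chromosome, position) genome hits to each probe's list.

    All probes must share one length; a polynomial rolling hash over each
    chromosome flags candidate positions, which are then verified by direct
    string comparison (hash collisions cannot create false hits).
    """
    k = len(next(iter(probes)))
    base = np.uint64(1099511628211)
    powk = base ** np.uint64(k - 1)

    def hash_str(s: str) -> np.uint64:
        h = np.uint64(0)
        with np.errstate(over="ignore"):
            for ch in s.encode():
                h = h * base + np.uint64(ch)
        return h

    probe_hashes = np.sort(np.array([hash_str(p) for p in probes], dtype=np.uint64))
    for name, seq in sequences.items():
        if len(seq) < k:
            continue
        arr = np.frombuffer(seq.encode(), dtype=np.uint8).astype(np.uint64)
        n = arr.size - k + 1
        with np.errstate(over="ignore"):
            codes = np.zeros(n, dtype=np.uint64)
            for j in range(k):
                codes = codes * base + arr[j : j + n]
        idx = np.searchsorted(probe_hashes, codes)
        idx[idx == probe_hashes.size] = 0
        cand = np.flatnonzero(probe_hashes[idx] == codes)
        for pos in cand:
            sub = seq[pos : pos + k]
            if sub in probes:
                probes[sub].append((name, int(pos)))


def place_markers(
    markers: pd.DataFrame, sequences: dict[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place tag sequences at perfect identity, keeping unique hits only.

    Parameters
    ----------
    markers : DataFrame with columns ``marker_id`` and ``sequence``.
    sequences : named sequence set to search (both strands).

    Returns
    -------
    placements : DataFrame [marker_id, chromosome, position, strand];
        ``position`` is the 0-based start of the matching genome substring.
    rejects : DataFrame [marker_id, reason] with reason in {no_hit, multi_hit}.
    """
    placements, rejects = [], []
    upper = {name: s.upper() for name, s in sequences.items()}
    ids = list(markers.get("marker_id", []))
    tags = [t.upper() for t in markers.get("sequence", [])]
    for marker_id, tag in zip(ids, tags):
        if set(tag) - set("ACGT"):
            raise ValidationError(f"marker {marker_id!r} has non-ACGT characters")
    # group tags by length so each genome pass handles one probe size
    by_len: dict[int, dict[str, list]] = {}
    for tag in tags:
        probes = by_len.setdefault(len(tag), {})
        probes.setdefault(tag, [])
        probes.setdefault(revcomp(tag), [])
    for _, probes in sorted(by_len.items()):
        _rolling_hash_hits(upper, probes)
    for marker_id, tag in zip(ids, tags):
        probes = by_len[len(tag)]
        rc = revcomp(tag)
        hits = [(name, pos, "+") for name, pos in probes[tag]]
        if rc != tag:
            hits += [(name, pos, "-") for name, pos in probes[rc]]
        if len(hits) == 1:
            name, pos, strand = hits[0]
            placements.append((marker_id, name, pos, strand))
        else:
            rejects.append((marker_id, "no_hit" if not hits else "multi_hit"))
    return (
        pd.DataFrame(placements, columns=PLACEMENT_COLUMNS),
        pd.DataFrame(rejects, columns=["marker_id", "reason"]),
    )


@dataclass
class LGAssignmentTable:
    """Per-scaffold linkage-group vote: plurality LG and mismatch percentages."""

    table: pd.DataFrame  # scaffold, total_placed, plurality_lg, mismatch_count,
    #                      mismatch_pct, match_pct, tie, low_evidence
    counts: pd.DataFrame  # long form: scaffold, lg, count
    skipped: list[str] = field(default_factory=list)

    def summary(self) -> dict[str, float]:
        """Overall mismatch rate, both as mean of per-row percentages and pooled."""
        t = self.table
        total = int(t["total_placed"].sum())
        mism = int(t["mismatch_count"].sum())
        return {
            "mean_of_rows": round_half_up(float(t["mismatch_pct"].mean())),
            "pooled": round_half_up(100.0 * mism / total) if total else 0.0,
        }


def assign_linkage_groups(
    placements: pd.DataFrame, marker_map: pd.DataFrame
) -> LGAssignmentTable:
    """Assign each scaffold to the LG contributing the plurality of its markers.

    ``marker_map`` needs columns ``marker_id``, ``lg`` (and usually ``cM``).
    Ties go to the lexicographically smallest LG id and are flagged.
    """
    missing = set(placements["marker_id"]) - set(marker_map["marker_id"])
    if missing:
        raise ValidationError(f"{len(missing)} placed markers missing from map")
    merged = placements.merge(marker_map[["marker_id", "lg"]], on="marker_id")
    rows, counts = [], []
    for scaffold, grp in merged.groupby("chromosome", sort=True):
        tally = grp["lg"].value_counts()
        top = tally.max()
        winners = sorted(tally[tally == top].index)
        plurality = winners[0]
        total = int(tally.sum())
        mismatch = total - int(top)
        mism_pct = round_half_up(100.0 * mismatch / total)
        rows.append(
            {
                "scaffold": scaffold,
                "total_placed": total,
                "plurality_lg": plurality,
                "mismatch_count": mismatch,
                "mismatch_pct": mism_pct,
                "match_pct": round_half_up(100.0 - mism_pct),
                "tie": len(winners) > 1,
            }
        )
        counts += [
            {"scaffold": scaffold, "lg": lg, "count": int(n)}
            for lg, n in tally.sort_index().items()
        ]
    return LGAssignmentTable(
        table=pd.DataFrame(rows),
        counts=pd.DataFrame(counts, columns=["scaffold", "lg", "count"]),
    )


@dataclass
class MergePlan:
    """Ordered, oriented scaffold lists per LG, joined by ``gap_n`` Ns."""

    entries: dict[str, list[tuple[str, str]]]  # lg -> [(scaffold, orientation)]
    gap_n: int = 1000
    evidence: pd.DataFrame | None = None  # scaffold, lg, cm_min, cm_max, rho, flags


def infer_merge_plan(
    assignment: LGAssignmentTable,
    placements: pd.DataFrame,
    marker_map: pd.DataFrame,
    gap_n: int = 1000,
    min_markers: int = 3,
    overlap_tolerance_cm: float = 1.0,
) -> MergePlan:
    """Build a head-to-tail merge plan for LGs claimed by several scaffolds.

    Scaffolds are ordered by the midpoint of their cM span; orientation is
    the sign of the Spearman correlation between cM and physical position
    (negative means the scaffold is reverse-complemented before joining).
    Scaffolds with fewer than ``min_markers`` placements default to ``+``
    and are flagged ``low_evidence``. Overlapping cM spans beyond
    ``overlap_tolerance_cm`` raise :class:`MergeConflictError`.
    """
    merged = placements.merge(marker_map[["marker_id", "lg", "cM"]], on="marker_id")
    lg_of = dict(
        zip(assignment.table["scaffold"], assignment.table["plurality_lg"])
    )
    entries: dict[str, list[tuple[str, str]]] = {}
    evidence = []
    by_lg: dict[str, list[str]] = {}
    for scaffold, lg in lg_of.items():
        by_lg.setdefault(lg, []).append(scaffold)
    for lg, scaffolds in sorted(by_lg.items()):
        if len(scaffolds) < 2:
            continue
        parts = []
        for scaffold in scaffolds:
            sub = merged[
                (merged["chromosome"] == scaffold) & (merged["lg"] == lg)
            ]
            cm = sub["cM"].to_numpy(float)
            pos = sub["position"].to_numpy(float)
            flags = []
            if len(sub) < min_markers:
                rho = np.nan
                orient = "+"
                flags.append("low_evidence")
            else:
                rho = stats.spearmanr(cm, pos).statistic
                orient = "-" if rho < 0 else "+"
            span = (float(cm.min()), float(cm.max())) if len(cm) else (np.nan, np.nan)
            parts.append((scaffold, orient, span, rho, flags))
        parts.sort(key=lambda p: (p[2][0] + p[2][1]) / 2.0)
        for (s1, _, (a1, b1), _, _), (s2, _, (a2, b2), _, _) in zip(parts, parts[1:]):
            if b1 - a2 > overlap_tolerance_cm:
                raise MergeConflictError(
                    f"LG {lg}: cM spans overlap: {s1} ({a1:.1f}-{b1:.1f}) vs "
                    f"{s2} ({a2:.1f}-{b2:.1f})"
                )
        entries[lg] = [(s, o) for s, o, _, _, _ in parts]
        evidence += [
            {
                "lg": lg,
                "scaffold": s,
                "orientation": o,
                "cm_min": span[0],
                "cm_max": span[1],
                "spearman_rho": rho,
                "flags": ",".join(fl),
            }
            for s, o, span, rho, fl in parts
        ]
    return MergePlan(
        entries=entries, gap_n=gap_n, evidence=pd.DataFrame(evidence)
    )


def apply_merge(sequences: dict[str, str], plan: MergePlan) -> dict[str, str]:
    """Join planned scaffolds into one sequence per LG, gap-separated.

    Minus-oriented parts are reverse-complemented; merged scaffolds are
    removed from the output and the joined sequence is named after the LG.
    """
    out = dict(sequences)
    for lg, parts in plan.entries.items():
        segments = []
        for scaffold, orient in parts:
            if scaffold not in out:
                raise ValidationError(f"unknown scaffold {scaffold!r} in merge plan")
            seq = out.pop(scaffold)
            segments.append(revcomp(seq) if orient == "-" else seq)
        out[lg] = ("N" * plan.gap_n).join(segments)
    return out


def genes_in_interval(
    annotations: pd.DataFrame, chromosome: str, start: int, end: int
) -> pd.DataFrame:
    """Genes overlapping a 1-based closed interval by at least 1 bp.

    ``annotations`` uses the package-internal 0-based half-open columns
    ``start``/``end`` plus ``chromosome``; results are sorted by start.
    """
    if start > end:
        raise ValidationError("interval start exceeds end")
    if chromosome not in set(annotations["chromosome"]):
        raise ValidationError(f"unknown chromosome {chromosome!r}")
    q_start0, q_end0 = start - 1, end  # to 0-based half-open
    sub = annotations[
        (annotations["chromosome"] == chromosome)
        & (annotations["start"] < q_end0)
        & (annotations["end"] > q_start0)
    ]
    return sub.sort_values("start").reset_index(drop=True)
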
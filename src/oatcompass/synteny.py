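"""Synteny-block orthology calls and block-size correlation.

Consumes precomputed synteny block files (a SynMap/DAGchainer-style dialect
or a simple one-row-per-block TSV) and calls orthologous chromosome pairs
by majority rule: chromosome ``a`` is declared the ortholog of the partner
holding more than 50% of ``a``'s syntenic sequence. The denominator is the
summed (overlap-merged, per partner) block length on the query side, so
partner fractions always sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

BLOCK_COLUMNS = [
    "chrom_a",
    "start_a",
    "end_a",
    "chrom_b",
    "start_b",
    "end_b",
    "n_gene_pairs",
    "orientation",
]


def _validate_blocks(blocks: pd.DataFrame) -> pd.DataFrame:
    if blocks.empty:
        raise ValidationError("empty synteny block list")
    bad = blocks[(blocks.start_a >= blocks.end_a) | (blocks.start_b >= blocks.end_b)]
    if not bad.empty:
        raise ValidationError(
            f"{len(bad)} zero- or negative-length blocks (first at row {bad.index[0]})"
        )
    if (blocks.n_gene_pairs < 1).any():
        raise ValidationError("blocks must contain at least one gene pair")
    return blocks


def read_block_tsv(path) -> pd.DataFrame:
    """Simple dialect: one block per row, header with BLOCK_COLUMNS."""
    blocks = pd.read_csv(path, sep="\t")
    missing = set(BLOCK_COLUMNS) - set(blocks.columns)
    if missing:
        raise ValidationError(f"block TSV missing columns: {sorted(missing)}")
    return _validate_blocks(blocks[BLOCK_COLUMNS])


def read_dagchainer(path) -> pd.DataFrame:
    """DAGchainer-style dialect: ``#`` block headers, one gene pair per row.

    Pair rows are tab-separated: chrom_a, gene_a, start_a, end_a, chrom_b,
    gene_b, start_b, end_b[, score]. Block coordinates are the min/max over
    the block's pairs; orientation is the sign of the b-side trend.
    """
    blocks = []
    current: list[list[str]] = []

    def flush():
        if not current:
            return
        arr = pd.DataFrame(
            current,
            columns=["chrom_a", "gene_a", "start_a", "end_a", "chrom_b", "gene_b", "start_b", "end_b"],
        )
        for col in ("start_a", "end_a", "start_b", "end_b"):
            arr[col] = arr[col].astype(int)
        slope = np.polyfit(arr["start_a"], arr["start_b"], 1)[0] if len(arr) > 1 else 1.0
        blocks.append(
            {
                "chrom_a": arr["chrom_a"].iloc[0],
                "start_a": int(arr["start_a"].min()),
                "end_a": int(arr["end_a"].max()),
                "chrom_b": arr["chrom_b"].iloc[0],
                "start_b": int(arr["start_b"].min()),
                "end_b": int(arr["end_b"].max()),
                "n_gene_pairs": len(arr),
                "orientation": "-" if slope < 0 else "+",
            }
        )
        current.clear()

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                flush()
                continue
            current.append(line.split("\t")[:8])
    flush()
    if not blocks:
        raise ValidationError("no blocks parsed")
    return _validate_blocks(pd.DataFrame(blocks)[BLOCK_COLUMNS])


def _merged_length(intervals: list[tuple[int, int]]) -> int:
    """Total covered length after merging overlapping half-open intervals."""
    total = 0
    last_end = None
    for s, e in sorted(intervals):
        if last_end is None or s >= last_end:
            total += e - s
            last_end = e
        elif e > last_end:
            total += e - last_end
            last_end = e
    return total


@dataclass(frozen=True)
class OrthologyCall:
    chrom_a: str
    best_partner: str
    fraction: float
    syntenic_bp: int
    status: str  # ortholog | split


def call_orthologs(blocks: pd.DataFrame) -> tuple[list[OrthologyCall], pd.DataFrame]:
    """Majority-rule ortholog calls per query chromosome.

    Returns the calls plus the full fraction table (chrom_a, chrom_b,
    syntenic_bp, fraction).
    """
    blocks = _validate_blocks(blocks)
    rows = []
    for chrom_a, grp in blocks.groupby("chrom_a", sort=True):
        per_partner = {}
        for chrom_b, sub in grp.groupby("chrom_b"):
            ivals = list(zip(sub["start_a"].astype(int), sub["end_a"].astype(int)))
            per_partner[chrom_b] = _merged_length(ivals)
        denom = sum(per_partner.values())
        for chrom_b, bp in sorted(per_partner.items()):
            rows.append(
                {
                    "chrom_a": chrom_a,
                    "chrom_b": chrom_b,
                    "syntenic_bp": bp,
                    "fraction": bp / denom,
                }
            )
    fractions = pd.DataFrame(rows)
    calls = []
    for chrom_a, grp in fractions.groupby("chrom_a", sort=True):
        best = grp.sort_values(["fraction", "chrom_b"], ascending=[False, True]).iloc[0]
        calls.append(
            OrthologyCall(
                chrom_a=str(chrom_a),
                best_partner=str(best["chrom_b"]),
                fraction=float(best["fraction"]),
                syntenic_bp=int(best["syntenic_bp"]),
                status="ortholog" if best["fraction"] > 0.5 else "split",
            )
        )
    return calls, fractions


def block_size_correlation(blocks: pd.DataFrame) -> tuple[float, bool]:
    """Squared Pearson correlation of block sizes on the two sides.

    Returns ``(r_squared, degenerate)``; a side with zero size variance
    yields ``(0.0, True)``.
    """
    blocks = _validate_blocks(blocks)
    if len(blocks) < 2:
        raise ValidationError("need at least two blocks")
    size_a = (blocks["end_a"] - blocks["start_a"]).to_numpy(float)
    size_b = (blocks["end_b"] - blocks["start_b"]).to_numpy(float)
    if np.ptp(size_a) == 0 or np.ptp(size_b) == 0:
        return 0.0, True
    r = stats.pearsonr(size_a, size_b).statistic
    return float(r * r), False
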
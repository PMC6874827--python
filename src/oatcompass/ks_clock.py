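"""Synonymous divergence (Nei–Gojobori 1986) and molecular-clock arithmetic.

Ks — synonymous substitutions per synonymous site — is estimated by the NG86
counting method: each codon contributes fractional synonymous site counts
(the fraction of its nine single-nucleotide changes that preserve the amino
acid; changes creating stop codons count as nonsynonymous), differences in
multi-hit codons are averaged over all minimal substitution pathways that do
not pass through a stop codon, and the proportion of synonymous differences
``pS = Sd / S`` is corrected for multiple hits with the Jukes–Cantor formula

    Ks = -(3/4) * ln(1 - (4/3) * pS)

which diverges (saturates) at ``pS >= 3/4``.

Under a strict molecular clock two lineages separated for T years accumulate
``Ks = 2 r T`` synonymous substitutions per site, so a dated node calibrates
the lineage rate ``r = Ks / (2 T)`` and a rate dates a split ``T = Ks / (2 r)``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from Bio.Data import CodonTable

from .errors import ValidationError

_BASES = "TCAG"
CODONS: list[str] = ["".join(c) for c in itertools.product(_BASES, repeat=3)]
_CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
AMINO = {c: _TABLE.forward_table.get(c, "*") for c in CODONS}

#: Externally sourced constant: a broadly used eukaryote-wide synonymous
#: substitution rate (substitutions / synonymous site / year), offered as an
#: alternative calibration to a lineage-specific rate.
CORE_EUKARYOTE_RATE = 8.1e-9


def _syn_site_count(codon: str) -> float:
    """Fractional synonymous sites of one sense codon (stops -> nonsynonymous)."""
    aa = AMINO[codon]
    s = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if AMINO[alt] == aa and alt not in STOP_CODONS:
                s += 1.0 / 3.0
    return s


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) for a codon pair, averaged over stop-free minimal pathways."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    blocked = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if AMINO[cur] == AMINO[nxt] and nxt not in STOP_CODONS:
                sd += 1.0
            else:
                nd += 1.0
            if nxt in STOP_CODONS:
                through_stop = True
            cur = nxt
        (blocked if through_stop else results).append((sd, nd))
    if not results:  # every route crosses a stop; fall back to all routes
        results = blocked
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


def _build_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    s_sites = np.zeros(64)
    sd = np.zeros((64, 64))
    nd = np.zeros((64, 64))
    for i, c1 in enumerate(CODONS):
        if c1 in STOP_CODONS:
            continue
        s_sites[i] = _syn_site_count(c1)
        for j, c2 in enumerate(CODONS):
            if c2 in STOP_CODONS:
                continue
            sd[i, j], nd[i, j] = _pathway_counts(c1, c2)
    return s_sites, sd, nd


S_SITES, SD_TABLE, ND_TABLE = _build_tables()


@dataclass(frozen=True)
class KsEstimate:
    """NG86 synonymous-divergence estimate for one codon-aligned gene pair."""

    s_sites: float  # synonymous sites S (average of both sequences)
    n_sites: float  # nonsynonymous sites N; S + N = alignment length (nt)
    s_diffs: float  # synonymous differences Sd (pathway-averaged)
    n_diffs: float  # nonsynonymous differences Nd
    p_s: float  # Sd / S
    ks: float | None  # Jukes-Cantor corrected; None when saturated
    saturated: bool = False


def encode_codons(seq: str) -> np.ndarray:
    """Codon-index array (0..63) for an ungapped coding sequence."""
    seq = seq.upper()
    if len(seq) % 3:
        raise ValidationError(f"sequence length {len(seq)} not divisible by 3")
    try:
        return np.array(
            [_CODON_INDEX[seq[i : i + 3]] for i in range(0, len(seq), 3)],
            dtype=np.int8,
        )
    except KeyError as exc:
        raise ValidationError(f"non-ACGT codon {exc.args[0]!r}") from None


def jukes_cantor(p_s: float) -> float | None:
    """Multiple-hit correction; None at saturation (p_s >= 3/4)."""
    if p_s >= 0.75:
        return None
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p_s)


def ks_ng86(seq1: str, seq2: str) -> KsEstimate:
    """NG86 Ks for one codon-aligned pair.

    Sequences must be equal-length and codon-aligned; codons containing a
    gap character in either sequence are dropped from the alignment before
    counting; internal stop codons are rejected.
    """
    if len(seq1) != len(seq2):
        raise ValidationError("sequences differ in length")
    s1, s2 = seq1.upper(), seq2.upper()
    if len(s1) % 3:
        raise ValidationError(f"alignment length {len(s1)} not divisible by 3")
    keep1, keep2 = [], []
    for i in range(0, len(s1), 3):
        c1, c2 = s1[i : i + 3], s2[i : i + 3]
        if "-" in c1 or "-" in c2:
            continue
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            raise ValidationError(f"internal stop codon at position {i}")
        keep1.append(c1)
        keep2.append(c2)
    if not keep1:
        raise ValidationError("no ungapped codons in alignment")
    i1 = encode_codons("".join(keep1))
    i2 = encode_codons("".join(keep2))
    return _estimate_from_indices(i1, i2)


def _estimate_from_indices(i1: np.ndarray, i2: np.ndarray) -> KsEstimate:
    length = 3 * i1.size
    s = 0.5 * (S_SITES[i1].sum() + S_SITES[i2].sum())
    sd = SD_TABLE[i1, i2].sum()
    nd = ND_TABLE[i1, i2].sum()
    p_s = sd / s if s > 0 else 0.0
    ks = jukes_cantor(p_s)
    return KsEstimate(
        s_sites=float(s),
        n_sites=float(length - s),
        s_diffs=float(sd),
        n_diffs=float(nd),
        p_s=float(p_s),
        ks=ks,
        saturated=ks is None,
    )


def ks_many(pairs: list[tuple[str, str]]) -> list[KsEstimate]:
    """Vectorised NG86 over many gap-free codon-aligned pairs."""
    return [
        _estimate_from_indices(encode_codons(a), encode_codons(b)) for a, b in pairs
    ]


def ks_batch(codons_a: np.ndarray, codons_b: np.ndarray) -> np.ndarray:
    """NG86 Ks for stacked codon-index pairs, shape (n_pairs, n_codons).

    Returns an array of Ks values with NaN at saturated pairs. Same counting
    tables as :func:`ks_ng86`, applied across the whole batch at once.
    """
    a = np.asarray(codons_a, dtype=np.int64)
    b = np.asarray(codons_b, dtype=np.int64)
    if a.shape != b.shape or a.ndim != 2:
        raise ValidationError("codon index arrays must share shape (n_pairs, n_codons)")
    s = 0.5 * (S_SITES[a].sum(axis=1) + S_SITES[b].sum(axis=1))
    sd = SD_TABLE[a, b].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_s = np.where(s > 0, sd / s, 0.0)
        ks = np.where(p_s < 0.75, -0.75 * np.log(1.0 - (4.0 / 3.0) * p_s), np.nan)
    return ks


def ks_peak(values, bin_width: float = 0.005) -> float:
    """Mode of a Ks distribution as the center of the fullest histogram bin.

    Fixed-width bins anchored at zero keep the estimate deterministic; ties
    resolve to the smallest bin center.
    """
    vals = np.asarray([v for v in np.ravel(values) if np.isfinite(v)], dtype=float)
    if vals.size == 0:
        raise ValidationError("no finite Ks values")
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    n_bins = int(np.floor(vals.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(vals, bins=edges)
    best = int(np.argmax(counts))  # argmax takes the first (smallest) on ties
    return float((best + 0.5) * bin_width)


@dataclass(frozen=True)
class ClockResult:
    """One calibrated clock: peak Ks, lineage rate, and the dated split."""

    ks_peak: float
    rate: float  # substitutions / synonymous site / year
    time: float  # years


def calibrate_rate(ks: float, node_age: float) -> float:
    """Per-lineage substitution rate ``r = Ks / (2 T)`` from a dated node."""
    if node_age <= 0:
        raise ValidationError("node_age must be positive")
    if ks < 0:
        raise ValidationError("ks must be non-negative")
    return ks / (2.0 * node_age)


def divergence_time(ks: float, rate: float) -> float:
    """Split age ``T = Ks / (2 r)`` in years."""
    if rate <= 0:
        raise ValidationError("rate must be positive")
    if ks < 0:
        raise ValidationError("ks must be non-negative")
    return ks / (2.0 * rate)
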
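"""Tandem-repeat discovery, density tracks, centromere/telomere calls, SSRs.

Plant centromeres are dominated by megabase arrays of a satellite monomer
of roughly 150-180 bp, so the most abundant tandem monomer in an assembly
is a strong centromere candidate; telomere-associated satellites behave the
same way at chromosome ends. Monomers are canonicalized to the minimal
rotation over both strands of their primitive unit, profiled into windowed
density tracks (bedGraph-ready), and the track maxima drive centromere
midpoint calls and arm-ratio morphology classes (Levan-style cutoffs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .seq import canonical_monomer, is_primitive, revcomp, seq_to_bytes

_KMER = 21  # anchor size for candidate-period detection


@dataclass
class TandemMonomer:
    monomer: str  # canonical rotation (primitive, strand-symmetric)
    length: int
    total_copies: int
    n_arrays: int
    array_spans: list[tuple[str, int, int]]  # (chromosome, start, end) 0-based half-open

    @property
    def total_bp(self) -> int:
        return sum(e - s for _, s, e in self.array_spans)


def _kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Packed integer codes of all k-mers (k <= 31) of a byte sequence."""
    lut = np.zeros(256, dtype=np.int64)
    lut[np.frombuffer(b"ACGT", dtype=np.uint8)] = np.arange(4)
    b = lut[arr]
    n = arr.size - k + 1
    codes = np.zeros(n, dtype=np.int64)
    for j in range(k):
        codes = codes * 4 + b[j : j + n]
    return codes


def _candidate_periods(arr: np.ndarray, min_len: int, max_len: int) -> list[tuple[int, int]]:
    """(position, period) candidates where an anchor k-mer recurs in range."""
    if arr.size < _KMER + min_len:
        return []
    codes = _kmer_codes(arr, _KMER)
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    out = []
    start = 0
    for end in np.flatnonzero(np.diff(sorted_codes)) + 1:
        group = np.sort(order[start:end])
        if group.size > 1:
            gaps = np.diff(group)
            for pos, gap in zip(group[:-1], gaps):
                if min_len <= gap <= max_len:
                    out.append((int(pos), int(gap)))
        start = end
    # final group
    group = np.sort(order[start:])
    if group.size > 1:
        for pos, gap in zip(group[:-1], np.diff(group)):
            if min_len <= gap <= max_len:
                out.append((int(pos), int(gap)))
    return out


def _arrays_for_period(
    arr: np.ndarray, period: int, max_divergence: float, min_copies: int
) -> list[tuple[int, int]]:
    """Spans (0-based half-open) where the period-p self-match density holds.

    The self-match profile ``s[i] == s[i+p]`` is smoothed over one period;
    segments whose local match density stays clear of the random-background
    level are kept, then trimmed inward to exact self-match boundaries.
    Random i.i.d. sequence matches itself at ~25% per site, so the density
    cutoff ``1 - 2 * max_divergence`` (0.6 by default) cleanly separates
    arrays with up to ``max_divergence`` monomer divergence from background.
    """
    eq = arr[period:] == arr[:-period]
    if eq.size < period:
        return []
    w = min(period, eq.size)
    thr = 1.0 - 2.0 * max_divergence
    dens = np.convolve(eq, np.ones(w), mode="valid") / w
    mask = dens >= thr
    spans = []
    i = 0
    n = mask.size
    while i < n:
        if not mask[i]:
            i += 1
            continue
        j = i
        while j < n and mask[j]:
            j += 1
        lo, hi = _trim_edges(eq, i, j + w - 1, thr)
        span = (lo, hi + period)  # include the final period
        if lo < hi and (span[1] - span[0]) // period >= min_copies:
            spans.append(span)
        i = j
    return spans


def _trim_edges(eq: np.ndarray, lo: int, hi: int, thr: float, w: int = 16) -> tuple[int, int]:
    """Snap coarse span edges to the first/last locally dense self-match."""
    while lo < hi and not (eq[lo] and eq[lo : lo + w].mean() >= thr):
        lo += 1
    while hi > lo and not (eq[hi - 1] and eq[max(lo, hi - w) : hi].mean() >= thr):
        hi -= 1
    return lo, hi


def find_tandem_monomers(
    sequences: dict[str, str],
    min_len: int = 50,
    max_len: int = 2000,
    min_copies: int = 5,
    max_divergence: float = 0.2,
) -> list[TandemMonomer]:
    """Discover tandem arrays and rank canonical monomers by total array bp.

    Anchor k-mers recurring at a distance in ``[min_len, max_len]`` seed
    candidate periods; for each seeded period the chromosome is scanned for
    segments where the period-p self-match density holds within
    ``max_divergence``. Arrays of the same canonical monomer are pooled;
    the returned list is sorted by total array bp, descending.
    """
    if min_len > max_len:
        raise ValidationError("min_len exceeds max_len")
    arrays: dict[str, list[tuple[str, int, int]]] = {}
    for chrom, seq in sequences.items():
        arr = seq_to_bytes(seq)
        claimed = np.zeros(arr.size, dtype=bool)
        period_votes: dict[int, int] = {}
        for _, period in _candidate_periods(arr, min_len, max_len):
            period_votes[period] = period_votes.get(period, 0) + 1
        # a true array of c copies yields on the order of c anchor votes
        periods = sorted(p for p, v in period_votes.items() if v >= min_copies - 1)
        for period in periods:
            for lo, hi in _arrays_for_period(arr, period, max_divergence, min_copies):
                if claimed[lo:hi].mean() > 0.5:
                    continue  # already explained by a smaller period
                # take an interior copy: edge slop cannot corrupt a rotation
                mid_copy = lo + ((hi - lo) // period // 2) * period
                unit = seq[mid_copy : mid_copy + period]
                canon = canonical_monomer(unit)
                if len(canon) < min_len:
                    continue  # true period below the detection floor
                claimed[lo:hi] = True
                arrays.setdefault(canon, []).append((chrom, lo, hi))
    monomers = []
    for canon, spans in arrays.items():
        merged = _merge_spans(spans)
        copies = sum((e - s) // len(canon) for _, s, e in merged)
        if copies < min_copies:
            continue
        monomers.append(
            TandemMonomer(
                monomer=canon,
                length=len(canon),
                total_copies=copies,
                n_arrays=len(merged),
                array_spans=merged,
            )
        )
    monomers.sort(key=lambda m: (-m.total_bp, m.monomer))
    return monomers


def _merge_spans(spans: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    out: list[tuple[str, int, int]] = []
    for chrom, s, e in sorted(spans):
        if out and out[-1][0] == chrom and s <= out[-1][2]:
            prev = out.pop()
            out.append((chrom, prev[1], max(prev[2], e)))
        else:
            out.append((chrom, s, e))
    return out


@dataclass
class DensityTrack:
    chromosome: str
    window_bp: int
    counts: np.ndarray  # occurrences per window, indexed by floor(start / window)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_bedgraph(self) -> str:
        lines = []
        for w, c in enumerate(self.counts):
            lines.append(f"{self.chromosome}\t{w * self.window_bp}\t{(w + 1) * self.window_bp}\t{int(c)}")
        return "\n".join(lines) + "\n"


def _occurrence_starts(
    arr: np.ndarray, monomer: str, max_mismatch: int
) -> np.ndarray:
    """Starts where monomer (either strand) matches within a Hamming budget."""
    m = len(monomer)
    if arr.size < m:
        return np.array([], dtype=int)
    n = arr.size - m + 1
    best = np.full(n, m + 1, dtype=np.int32)
    for probe in {monomer.upper(), revcomp(monomer.upper())}:
        pb = seq_to_bytes(probe)
        mm = np.zeros(n, dtype=np.int32)
        for j in range(m):
            mm += arr[j : j + n] != pb[j]
        best = np.minimum(best, mm)
    return np.flatnonzero(best <= max_mismatch)


def density_track(
    sequences: dict[str, str],
    monomer: str,
    window_bp: int = 1_000_000,
    max_mismatch_fraction: float = 0.1,
) -> list[DensityTrack]:
    """Windowed counts of non-overlapping monomer occurrences per chromosome.

    Occurrences on either strand within the Hamming budget are taken
    greedily left to right (each base counted once) and assigned to the
    window containing their start.
    """
    if not monomer:
        raise ValidationError("empty monomer")
    if window_bp < len(monomer):
        raise ValidationError("window_bp smaller than the monomer")
    budget = int(np.floor(max_mismatch_fraction * len(monomer)))
    m = len(monomer)
    tracks = []
    for chrom, seq in sequences.items():
        arr = seq_to_bytes(seq)
        n_windows = max(1, int(np.ceil(len(seq) / window_bp)))
        counts = np.zeros(n_windows, dtype=np.int64)
        starts = _occurrence_starts(arr, monomer, budget)
        last_end = -1
        for s in starts:
            if s < last_end:
                continue
            counts[s // window_bp] += 1
            last_end = s + m
        tracks.append(DensityTrack(chromosome=chrom, window_bp=window_bp, counts=counts))
    return tracks


@dataclass(frozen=True)
class CentromereCall:
    chromosome: str
    centromere_midpoint: float  # bp
    short_arm: float
    long_arm: float
    arm_ratio: float
    morphology: str  # metacentric | submetacentric | sub-telocentric | telocentric


#: Levan-style arm-ratio cutoffs (upper bounds; beyond the last -> telocentric)
MORPHOLOGY_THRESHOLDS = ((1.7, "metacentric"), (3.0, "submetacentric"), (7.0, "sub-telocentric"))


def classify_morphology(arm_ratio: float, thresholds=MORPHOLOGY_THRESHOLDS) -> str:
    for k, (cutoff, label) in enumerate(thresholds):
        last = k == len(thresholds) - 1
        if arm_ratio < cutoff or (last and arm_ratio <= cutoff):
            return label
    return "telocentric"


def call_centromeres_telomeres(
    cen_tracks: list[DensityTrack],
    tel_tracks: list[DensityTrack],
    chromosome_lengths: dict[str, int],
    terminal_fraction: float = 0.05,
    thresholds=MORPHOLOGY_THRESHOLDS,
) -> tuple[list[CentromereCall], pd.DataFrame]:
    """Call centromere midpoints/morphology and label telomere arrays.

    The centromere midpoint is the count-weighted centroid of the contiguous
    non-zero run of windows around the global maximum of the centromeric
    track. Telomere-array runs are ``terminal`` when their midpoint lies
    within ``terminal_fraction`` of either chromosome end, else
    ``interstitial``. Chromosomes with an all-zero centromeric track are
    skipped (no call).
    """
    calls = []
    for track in cen_tracks:
        length = chromosome_lengths[track.chromosome]
        if track.total == 0:
            continue
        peak = int(np.argmax(track.counts))
        lo = peak
        while lo > 0 and track.counts[lo - 1] > 0:
            lo -= 1
        hi = peak
        while hi + 1 < track.counts.size and track.counts[hi + 1] > 0:
            hi += 1
        windows = np.arange(lo, hi + 1)
        weights = track.counts[lo : hi + 1].astype(float)
        centers = (windows + 0.5) * track.window_bp
        midpoint = float(np.average(centers, weights=weights))
        midpoint = min(midpoint, float(length))
        short_arm = min(midpoint, length - midpoint)
        long_arm = max(midpoint, length - midpoint)
        ratio = long_arm / short_arm if short_arm > 0 else float("inf")
        calls.append(
            CentromereCall(
                chromosome=track.chromosome,
                centromere_midpoint=midpoint,
                short_arm=short_arm,
                long_arm=long_arm,
                arm_ratio=ratio,
                morphology=classify_morphology(ratio, thresholds),
            )
        )
    tel_rows = []
    for track in tel_tracks:
        length = chromosome_lengths[track.chromosome]
        nz = track.counts > 0
        w = 0
        while w < nz.size:
            if not nz[w]:
                w += 1
                continue
            run_start = w
            while w < nz.size and nz[w]:
                w += 1
            start_bp = run_start * track.window_bp
            end_bp = min(w * track.window_bp, length)
            mid = (start_bp + end_bp) / 2.0
            terminal = mid <= terminal_fraction * length or mid >= (1 - terminal_fraction) * length
            tel_rows.append(
                {
                    "chromosome": track.chromosome,
                    "start": start_bp,
                    "end": end_bp,
                    "n_copies": int(track.counts[run_start:w].sum()),
                    "location": "terminal" if terminal else "interstitial",
                }
            )
    return calls, pd.DataFrame(
        tel_rows, columns=["chromosome", "start", "end", "n_copies", "location"]
    )


@dataclass(frozen=True)
class SSR:
    chromosome: str
    start: int  # 0-based
    motif: str  # canonical rotation over both strands
    unit_length: int
    copies: int


DEFAULT_SSR_MIN_COPIES = {2: 6, 3: 5, 4: 5}


def scan_ssrs(
    sequences: dict[str, str],
    unit_lengths: tuple[int, ...] = (2, 3, 4),
    min_copies: dict[int, int] | None = None,
) -> list[SSR]:
    """Maximal perfect microsatellite runs of primitive units.

    Non-primitive units (e.g. ATAT at period 4, or homopolymers at period
    2) are skipped, so each locus is reported once at its true period.
    """
    min_copies = dict(DEFAULT_SSR_MIN_COPIES if min_copies is None else min_copies)
    out = []
    for chrom, seq in sequences.items():
        up = seq.upper()
        arr = seq_to_bytes(seq)
        for p in unit_lengths:
            need = min_copies.get(p, 5)
            if arr.size < 2 * p:
                continue
            eq = arr[p:] == arr[:-p]
            i = 0
            n = eq.size
            while i < n:
                if not eq[i]:
                    i += 1
                    continue
                j = i
                while j < n and eq[j]:
                    j += 1
                span = (j - i) + p  # run of self-matches plus one period
                copies = span // p
                unit = up[i : i + p]
                if copies >= need and is_primitive(unit) and "N" not in unit:
                    out.append(
                        SSR(
                            chromosome=chrom,
                            start=i,
                            motif=canonical_monomer(unit),
                            unit_length=p,
                            copies=copies,
                        )
                    )
                i = j + 1
    out.sort(key=lambda s: (s.chromosome, s.start, s.unit_length))
    return out
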
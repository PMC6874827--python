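"""Subgenome deconvolution of hexaploid linkage groups and translocation calls.

Hexaploid oat (AACCDD) linkage groups are assigned ancestral subgenome
origins by placing tag markers on two diploid reference assemblies — an
A-genome and a C-genome diploid — at perfect identity. C-derived LGs map
overwhelmingly to the C reference; A- and D-derived LGs both map to the A
reference (the two subgenomes are closely related), so they are paired as
homoeologs sharing a primary A-reference chromosome and disambiguated by
perfect-match counts: the closer (A) subgenome retains more exact hits.
LGs with substantial placements on both references get slash labels (A/C,
D/C), the signature of intergenomic translocations, which are localised by
scanning each LG in cM order for runs of markers that jump reference or
chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError


@dataclass
class ContingencyMatrix:
    """Linkage-group x chromosome placement tallies against one reference."""

    reference_id: str
    counts: pd.DataFrame  # index: lg, columns: chromosome, values: counts
    rejected: pd.DataFrame | None = None  # markers lacking an LG label

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def column_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def fractions(self) -> pd.DataFrame:
        """Row-normalised fractions (placed markers only)."""
        totals = self.row_totals.replace(0, pd.NA)
        return self.counts.div(totals, axis=0).fillna(0.0)


def build_contingency(
    placements: pd.DataFrame, marker_map: pd.DataFrame, reference_id: str
) -> ContingencyMatrix:
    """Tally placements by (LG, chromosome) for one reference assembly."""
    lg_of = dict(zip(marker_map["marker_id"], marker_map["lg"]))
    rows, rejected = [], []
    for rec in placements.itertuples(index=False):
        lg = lg_of.get(rec.marker_id)
        if lg is None or pd.isna(lg):
            rejected.append({"marker_id": rec.marker_id, "reason": "no_lg_label"})
        else:
            rows.append({"lg": lg, "chromosome": rec.chromosome})
    if rows:
        counts = (
            pd.DataFrame(rows)
            .groupby(["lg", "chromosome"])
            .size()
            .unstack(fill_value=0)
            .sort_index()
        )
        counts.columns.name = None
    else:
        counts = pd.DataFrame(dtype=int)
        counts.index.name = "lg"
    return ContingencyMatrix(
        reference_id=reference_id,
        counts=counts,
        rejected=pd.DataFrame(rejected, columns=["marker_id", "reason"]),
    )


def call_subgenomes(
    matrix_a: ContingencyMatrix,
    matrix_c: ContingencyMatrix,
    c_ratio: float = 2.0,
    slash_min_fraction: float = 0.2,
    prior_labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Label each LG as A, C, D (or slashed) from dual-reference tallies.

    Rules, applied per LG with ``n_A``/``n_C`` total placements on the two
    references:

    * both zero -> ``unassigned``;
    * ``n_C >= c_ratio * n_A`` -> base label C;
    * otherwise the LG joins the homoeolog pool keyed by its primary
      A-reference chromosome; within each pool the LG with more perfect
      A-reference placements is labeled A, its partner D (``prior_labels``
      overrides this data-driven ordering when supplied);
    * if the minority reference still holds at least ``slash_min_fraction``
      of ``n_A + n_C``, the label becomes a slash label with the larger
      side first (e.g. ``A/C``).

    Returns a DataFrame indexed by LG with label, evidence counts, primary
    chromosomes and homoeolog partner.
    """
    lgs = sorted(set(matrix_a.counts.index) | set(matrix_c.counts.index))
    columns = [
        "lg",
        "label",
        "n_A_ref",
        "n_C_ref",
        "primary_chromosome_A",
        "primary_chromosome_C",
        "homoeolog_partner",
    ]
    if not lgs:
        return pd.DataFrame(columns=columns).set_index("lg")
    n_a = matrix_a.row_totals.reindex(lgs, fill_value=0)
    n_c = matrix_c.row_totals.reindex(lgs, fill_value=0)

    def primary(matrix: ContingencyMatrix, lg: str) -> str | None:
        if lg not in matrix.counts.index or matrix.counts.loc[lg].sum() == 0:
            return None
        return matrix.counts.loc[lg].idxmax()

    base: dict[str, str] = {}
    pools: dict[str, list[str]] = {}
    for lg in lgs:
        if n_a[lg] == 0 and n_c[lg] == 0:
            base[lg] = "unassigned"
        elif n_c[lg] >= c_ratio * n_a[lg]:
            base[lg] = "C"
        else:
            chrom = primary(matrix_a, lg)
            pools.setdefault(chrom, []).append(lg)

    partner: dict[str, str | None] = {lg: None for lg in lgs}
    for chrom, pool in pools.items():
        if prior_labels and all(lg in prior_labels for lg in pool):
            for lg in pool:
                base[lg] = prior_labels[lg]
        else:
            ranked = sorted(pool, key=lambda lg: (-n_a[lg], lg))
            for i, lg in enumerate(ranked):
                base[lg] = "A" if i == 0 else "D"
        if len(pool) == 2:
            partner[pool[0]], partner[pool[1]] = pool[1], pool[0]

    rows = []
    for lg in lgs:
        label = base[lg]
        total = n_a[lg] + n_c[lg]
        if label not in ("unassigned",) and total > 0:
            minor_ref = "C" if label in ("A", "D") else "A"
            minor = n_c[lg] if minor_ref == "C" else n_a[lg]
            major = total - minor
            if minor / total >= slash_min_fraction:
                other = "C" if label in ("A", "D") else "A"
                label = f"{label}/{other}" if major >= minor else f"{other}/{label}"
        rows.append(
            {
                "lg": lg,
                "label": label,
                "n_A_ref": int(n_a[lg]),
                "n_C_ref": int(n_c[lg]),
                "primary_chromosome_A": primary(matrix_a, lg),
                "primary_chromosome_C": primary(matrix_c, lg),
                "homoeolog_partner": partner[lg],
            }
        )
    return pd.DataFrame(rows).set_index("lg")


@dataclass(frozen=True)
class TranslocationCall:
    lg: str
    segment_1: tuple[tuple[float, float], str, str]  # (cM range, chromosome, reference)
    segment_2: tuple[tuple[float, float], str, str]
    breakpoint_interval: tuple[float, float]  # open cM interval around the switch
    kind: str  # intergenomic | intragenomic
    n_segment_markers: int = 0


def detect_translocations(
    placements_a: pd.DataFrame,
    placements_c: pd.DataFrame,
    marker_map: pd.DataFrame,
    min_segment_markers: int = 5,
) -> list[TranslocationCall]:
    """Scan each LG in cM order for runs of markers on a foreign chromosome.

    Markers placed on both references are dropped as ambiguous. Within an
    LG the modal (reference, chromosome) defines the resident segment; any
    maximal run of at least ``min_segment_markers`` markers sharing one
    different (reference, chromosome) yields a call whose breakpoint
    interval spans from the last cM before the switch to the first cM after
    it. Runs shorter than the threshold (stray hits) are ignored.
    """
    maps = marker_map.set_index("marker_id")
    frames = []
    for ref, plc in (("A", placements_a), ("C", placements_c)):
        df = plc.copy()
        df["reference"] = ref
        frames.append(df)
    both = pd.concat(frames, ignore_index=True)
    dup = both["marker_id"].duplicated(keep=False)
    both = both[~dup]
    both = both.join(maps[["lg", "cM"]], on="marker_id")
    if both["lg"].isna().any():
        raise ValidationError("placements include markers missing from the map")

    calls: list[TranslocationCall] = []
    for lg, grp in both.groupby("lg", sort=True):
        grp = grp.sort_values("cM").reset_index(drop=True)
        labels = list(zip(grp["reference"], grp["chromosome"]))
        modal = max(set(labels), key=lambda lab: (labels.count(lab), lab))
        cms = grp["cM"].to_numpy(float)
        i = 0
        while i < len(labels):
            j = i
            while j < len(labels) and labels[j] == labels[i]:
                j += 1
            run_label, run_len = labels[i], j - i
            if run_label != modal and run_len >= min_segment_markers:
                modal_cms = cms[[k for k, lab in enumerate(labels) if lab == modal]]
                lo = cms[i - 1] if i > 0 else float("-inf")
                ref2, chrom2 = run_label
                calls.append(
                    TranslocationCall(
                        lg=str(lg),
                        segment_1=(
                            (float(modal_cms.min()), float(modal_cms.max())),
                            modal[1],
                            modal[0],
                        ),
                        segment_2=(
                            (float(cms[i]), float(cms[j - 1])),
                            chrom2,
                            ref2,
                        ),
                        breakpoint_interval=(float(lo), float(cms[i])),
                        kind="intergenomic" if ref2 != modal[0] else "intragenomic",
                        n_segment_markers=run_len,
                    )
                )
            i = j
    return calls
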
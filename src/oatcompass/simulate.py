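"""Synthetic data with the statistical structure the analysis chain assumes.

One configuration drives every generator, producing:

* three diploid genomes — an A genome, a closely related D copy and a more
  diverged C copy (per-site divergence defaults 1% and 5%) — with planted
  centromeric (159 bp monomer) and telomeric (665 bp monomer) tandem
  arrays and non-overlapping gene intervals;
* tag-marker panels (64 bp) with linkage-group labels and cM positions from
  a recombination map with tenfold pericentromeric suppression;
* codon-aligned gene pairs evolved by synonymous-biased substitution so the
  realized NG86 Ks distribution peaks at a chosen value;
* a clade-structured, mostly homozygous genotype matrix with an outgroup
  and optional heterozygote/missing contamination.

Every generator also emits ground-truth tables so downstream modules can be
scored without re-simulation; a fixed seed gives byte-identical artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ks_clock
from .errors import SizingError, ValidationError
from .gff import ANNOTATION_COLUMNS, write_gff3
from .seq import is_primitive, mutate, random_dna, revcomp, write_fasta
from .snp_phylo import GenotypeMatrix

# per-operation rng streams derived from the one config seed
(
    _STREAM_TRUTH,
    _STREAM_LINKAGE,
    _STREAM_HEX,
    _STREAM_KS,
    _STREAM_GENO,
    _STREAM_SYNTENY,
) = range(1, 7)

SUBGENOME_PREFIX = {"A": "AA", "D": "AD", "C": "AE"}
PREFIX_SUBGENOME = {v: k for k, v in SUBGENOME_PREFIX.items()}


@dataclass
class SimulationConfig:
    """All knobs for the synthetic study system (desk-scale defaults)."""

    seed: int = 0
    n_chromosomes: int = 3
    chromosome_length: int = 2_000_000
    n_genes: int = 20  # per chromosome
    gene_length: int = 1500
    # cycled across chromosomes; defaults cover the three morphology classes
    centromere_position_fraction: tuple[float, ...] = (0.5, 0.3, 0.15)
    centromere_monomer_length: int = 159
    telomere_monomer_length: int = 665
    array_copy_numbers: dict = field(
        default_factory=lambda: {"centromere": 400, "telomere": 30}
    )
    n_markers_per_lg: int = 120
    marker_length: int = 64
    subgenome_divergence: dict = field(default_factory=lambda: {"D": 0.01, "C": 0.05})
    translocation_spec: tuple | None = None  # (lg, breakpoint_cm, donor_chromosome)
    ks_peak: float = 0.0875
    ks_dispersion: float = 0.02
    n_gene_pairs: int = 2000
    n_codons: int = 300
    n_accessions: int = 12
    n_sites: int = 3000
    clade_structure: tuple = (
        ("cladeA", 6, 0.02),
        ("cladeB", 5, 0.02),
        ("outgroup", 1, 0.08),
    )
    het_rate: float = 0.0
    missing_rate: float = 0.0
    recombination_suppression: float = 10.0
    map_length_cm: float = 100.0
    gc: float = 0.44

    def __post_init__(self):
        for frac in self.centromere_position_fraction:
            if not 0.0 <= frac <= 1.0:
                raise ValidationError("centromere fractions must lie in [0, 1]")
        for name, val in self.subgenome_divergence.items():
            if not 0.0 <= val <= 1.0:
                raise ValidationError(f"divergence {name} must lie in [0, 1]")
        for rate in (self.het_rate, self.missing_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValidationError("contamination rates must lie in [0, 1]")
        if not 0.0 <= self.gc <= 1.0:
            raise ValidationError("gc must lie in [0, 1]")
        for val in (
            self.n_chromosomes,
            self.chromosome_length,
            self.marker_length,
            self.centromere_monomer_length,
            self.telomere_monomer_length,
        ):
            if val <= 0:
                raise ValidationError("lengths and counts must be positive")
        if self.marker_length > self.chromosome_length:
            raise ValidationError("marker_length exceeds chromosome_length")
        if sum(n for _, n, _ in self.clade_structure) != self.n_accessions:
            raise ValidationError("clade_structure must partition all accessions")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class SyntheticBundle:
    """Simulated genomes plus the truth tables used as the universal oracle."""

    config: SimulationConfig
    genome_A: dict[str, str]
    genome_D: dict[str, str]
    genome_C: dict[str, str]
    annotations: pd.DataFrame  # ANNOTATION_COLUMNS, 0-based half-open
    truth_arrays: pd.DataFrame  # genome, chromosome, start, end, monomer, role
    centromere_monomer: str
    telomere_monomer: str

    def genome(self, subgenome: str) -> dict[str, str]:
        return {"A": self.genome_A, "D": self.genome_D, "C": self.genome_C}[subgenome]

    def chromosome_lengths(self, subgenome: str = "A") -> dict[str, int]:
        return {name: len(s) for name, s in self.genome(subgenome).items()}


def _recombination_knots(
    length: int, cen_frac: float, suppression: float, map_length: float
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear bp -> cM map with suppressed pericentromeric third."""
    mid = cen_frac * length
    a = max(0.0, mid - length / 6.0)
    b = min(float(length), mid + length / 6.0)
    xs = np.array([0.0, a, b, float(length)])
    dens = np.array([1.0, 1.0 / suppression, 1.0])
    cum = np.concatenate([[0.0], np.cumsum(dens * np.diff(xs))])
    cum = cum / cum[-1] * map_length
    return xs, cum


def cm_of_position(
    positions, length: int, cen_frac: float, suppression: float, map_length: float
) -> np.ndarray:
    xs, cum = _recombination_knots(length, cen_frac, suppression, map_length)
    return np.interp(np.asarray(positions, dtype=float), xs, cum)


def position_of_cm(
    cms, length: int, cen_frac: float, suppression: float, map_length: float
) -> np.ndarray:
    xs, cum = _recombination_knots(length, cen_frac, suppression, map_length)
    return np.interp(np.asarray(cms, dtype=float), cum, xs)


def _primitive_monomer(rng: np.random.Generator, length: int, gc: float) -> str:
    while True:
        m = random_dna(rng, length, gc)
        if is_primitive(m):
            return m


def _chromosome_layout(config: SimulationConfig, i: int) -> dict:
    """Array spans for chromosome ``i`` (0-based), 0-based half-open."""
    L = config.chromosome_length
    cen_len = config.centromere_monomer_length * config.array_copy_numbers["centromere"]
    tel_len = config.telomere_monomer_length * config.array_copy_numbers["telomere"]
    frac = config.centromere_position_fraction[
        i % len(config.centromere_position_fraction)
    ]
    cen_start = int(round(frac * L - cen_len / 2))
    cen_start = max(tel_len + 1000, min(cen_start, L - tel_len - 1000 - cen_len))
    if 2 * tel_len + cen_len + 2000 + config.n_genes * (config.gene_length + 10) > L:
        raise SizingError(
            f"chromosome length {L} too short for requested arrays and genes"
        )
    return {
        "telomere_left": (0, tel_len),
        "centromere": (cen_start, cen_start + cen_len),
        "telomere_right": (L - tel_len, L),
    }


def _place_genes(
    rng: np.random.Generator, config: SimulationConfig, forbidden: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Non-overlapping gene intervals outside the forbidden (array) spans."""
    L = config.chromosome_length
    glen = config.gene_length
    taken = sorted(forbidden)
    out = []
    attempts = 0
    while len(out) < config.n_genes:
        attempts += 1
        if attempts > 200 * max(1, config.n_genes):
            raise SizingError("cannot place requested genes without overlap")
        s = int(rng.integers(0, L - glen))
        e = s + glen
        if any(s < te and e > ts for ts, te in taken):
            continue
        taken.append((s, e))
        taken.sort()
        out.append((s, e))
    return sorted(out)


def simulate_truth_set(config: SimulationConfig) -> SyntheticBundle:
    """Build the three genomes, planted arrays, and gene annotations."""
    rng = config.rng(_STREAM_TRUTH)
    cen_monomer = _primitive_monomer(rng, config.centromere_monomer_length, config.gc)
    tel_monomer = _primitive_monomer(rng, config.telomere_monomer_length, config.gc)
    cen_array = cen_monomer * config.array_copy_numbers["centromere"]
    tel_array = tel_monomer * config.array_copy_numbers["telomere"]

    genome_a: dict[str, str] = {}
    layouts: dict[int, dict] = {}
    ann_rows = []
    for i in range(config.n_chromosomes):
        layout = _chromosome_layout(config, i)
        layouts[i] = layout
        seq = list(random_dna(rng, config.chromosome_length, config.gc))
        for role, (s, e) in layout.items():
            arr = cen_array if role == "centromere" else tel_array
            seq[s:e] = arr
        name = f"{SUBGENOME_PREFIX['A']}{i + 1}"
        genome_a[name] = "".join(seq)
        genes = _place_genes(rng, config, list(layout.values()))
        for g, (s, e) in enumerate(genes):
            ann_rows.append(
                {
                    "genome": "A",
                    "chromosome": name,
                    "start": s,
                    "end": e,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "gene_id": f"{name}g{g + 1:04d}",
                }
            )

    protected = {
        i: list(layouts[i].values()) for i in range(config.n_chromosomes)
    }
    genomes = {"A": genome_a}
    for sub in ("D", "C"):
        rate = config.subgenome_divergence[sub]
        out = {}
        for i, (name_a, seq) in enumerate(genome_a.items()):
            name = f"{SUBGENOME_PREFIX[sub]}{i + 1}"
            out[name] = mutate(rng, seq, rate, protected=protected[i])
        genomes[sub] = out

    # annotations carried over to D and C at identical coordinates
    base_ann = pd.DataFrame(ann_rows, columns=ANNOTATION_COLUMNS)
    all_ann = [base_ann]
    for sub in ("D", "C"):
        sub_ann = base_ann.copy()
        sub_ann["genome"] = sub
        sub_ann["chromosome"] = sub_ann["chromosome"].str.replace(
            SUBGENOME_PREFIX["A"], SUBGENOME_PREFIX[sub], regex=False
        )
        sub_ann["gene_id"] = (
            sub_ann["chromosome"] + "g" + base_ann["gene_id"].str.split("g").str[-1]
        )
        all_ann.append(sub_ann)
    annotations = pd.concat(all_ann, ignore_index=True)

    truth_rows = []
    for sub in ("A", "D", "C"):
        for i in range(config.n_chromosomes):
            name = f"{SUBGENOME_PREFIX[sub]}{i + 1}"
            for role, (s, e) in layouts[i].items():
                truth_rows.append(
                    {
                        "genome": sub,
                        "chromosome": name,
                        "start": s,
                        "end": e,
                        "monomer": cen_monomer if role == "centromere" else tel_monomer,
                        "role": "centromere" if role == "centromere" else "telomere",
                    }
                )
    return SyntheticBundle(
        config=config,
        genome_A=genomes["A"],
        genome_D=genomes["D"],
        genome_C=genomes["C"],
        annotations=annotations,
        truth_arrays=pd.DataFrame(truth_rows),
        centromere_monomer=cen_monomer,
        telomere_monomer=tel_monomer,
    )


def _forbidden_for_markers(
    bundle: SyntheticBundle, subgenome: str, chromosome: str, marker_length: int
) -> list[tuple[int, int]]:
    sub = bundle.truth_arrays
    rows = sub[(sub["genome"] == subgenome) & (sub["chromosome"] == chromosome)]
    return [
        (max(0, int(r.start) - marker_length), int(r.end)) for r in rows.itertuples()
    ]


def _sample_marker_positions(
    rng: np.random.Generator,
    n: int,
    length: int,
    marker_length: int,
    forbidden: list[tuple[int, int]],
    lo: int = 0,
) -> np.ndarray:
    positions: set[int] = set()
    attempts = 0
    while len(positions) < n:
        attempts += 1
        if attempts > 500 * max(1, n):
            raise SizingError("cannot sample enough marker positions")
        p = int(rng.integers(lo, length - marker_length))
        if p in positions or any(s <= p < e for s, e in forbidden):
            continue
        positions.add(p)
    return np.array(sorted(positions), dtype=int)


def simulate_linkage_panel(
    bundle: SyntheticBundle, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tag-marker panel on the A genome: one LG per chromosome.

    Returns (markers, truth): markers has marker_id, sequence, lg, cM;
    truth adds the source chromosome, 0-based position and strand. Tags are
    exact substrings (or reverse complements) of their chromosome; cM
    positions follow the pericentromere-suppressed map.
    """
    rng = config.rng(_STREAM_LINKAGE)
    markers, truth = [], []
    for i, (chrom, seq) in enumerate(bundle.genome_A.items()):
        frac = config.centromere_position_fraction[
            i % len(config.centromere_position_fraction)
        ]
        forbidden = _forbidden_for_markers(bundle, "A", chrom, config.marker_length)
        pos = _sample_marker_positions(
            rng, config.n_markers_per_lg, len(seq), config.marker_length, forbidden
        )
        cms = cm_of_position(
            pos, len(seq), frac, config.recombination_suppression, config.map_length_cm
        )
        lg = str(i + 1)
        for k, (p, cm) in enumerate(zip(pos, cms)):
            tag = seq[p : p + config.marker_length]
            strand = "+" if rng.random() < 0.5 else "-"
            markers.append(
                {
                    "marker_id": f"t{chrom}_{k + 1:04d}",
                    "sequence": tag if strand == "+" else revcomp(tag),
                    "lg": lg,
                    "cM": float(cm),
                }
            )
            truth.append(
                {
                    "marker_id": f"t{chrom}_{k + 1:04d}",
                    "subgenome": "A",
                    "chromosome": chrom,
                    "position": int(p),
                    "strand": strand,
                    "lg": lg,
                    "cM": float(cm),
                }
            )
    cols = ["marker_id", "sequence", "lg", "cM"]
    return (
        pd.DataFrame(markers, columns=cols),
        pd.DataFrame(
            truth,
            columns=["marker_id", "subgenome", "chromosome", "position", "strand", "lg", "cM"],
        ),
    )


@dataclass
class HexaploidPanel:
    """Markers emulating a hexaploid consensus map over three subgenomes."""

    bundle: SyntheticBundle
    markers: pd.DataFrame  # marker_id, sequence, lg, cM
    truth: pd.DataFrame  # + subgenome, chromosome, position, strand
    lg_truth: pd.DataFrame  # lg, subgenome, chromosome (dominant origin)


def simulate_hexaploid_panel(config: SimulationConfig) -> HexaploidPanel:
    """Marker panel drawn from A, D and C subgenome copies.

    Each chromosome contributes three LGs (one per subgenome), named
    ``Mrg01``.. in chromosome-major order. With ``translocation_spec =
    (lg, breakpoint_cm, donor_chromosome)``, markers of that LG past the
    cM breakpoint are drawn from the donor chromosome instead, emulating an
    intergenomic translocation.
    """
    div = config.subgenome_divergence
    if not div["D"] < div["C"]:
        raise ValidationError("A-to-D divergence must be below A-to-C divergence")
    bundle = simulate_truth_set(config)
    rng = config.rng(_STREAM_HEX)
    subgenomes = ("A", "D", "C")
    lg_rows, markers, truth = [], [], []
    spec_lg, spec_break, spec_donor = (None, None, None)
    if config.translocation_spec is not None:
        spec_lg, spec_break, spec_donor = config.translocation_spec
        if not 0.0 < spec_break < config.map_length_cm:
            raise ValidationError(
                f"breakpoint {spec_break} outside LG cM range (0, {config.map_length_cm})"
            )

    def chrom_info(chromosome: str) -> tuple[str, int]:
        prefix, idx = chromosome[:2], int(chromosome[2:]) - 1
        return PREFIX_SUBGENOME[prefix], idx

    lg_counter = 0
    for i in range(config.n_chromosomes):
        frac = config.centromere_position_fraction[
            i % len(config.centromere_position_fraction)
        ]
        for sub in subgenomes:
            lg_counter += 1
            lg = f"Mrg{lg_counter:02d}"
            chrom = f"{SUBGENOME_PREFIX[sub]}{i + 1}"
            lg_rows.append({"lg": lg, "subgenome": sub, "chromosome": chrom})
            seq = bundle.genome(sub)[chrom]
            forbidden = _forbidden_for_markers(bundle, sub, chrom, config.marker_length)
            pos = _sample_marker_positions(
                rng, config.n_markers_per_lg, len(seq), config.marker_length, forbidden
            )
            cms = cm_of_position(
                pos, len(seq), frac, config.recombination_suppression, config.map_length_cm
            )
            order = np.argsort(cms)
            pos, cms = pos[order], cms[order]
            for k, (p, cm) in enumerate(zip(pos, cms)):
                src_sub, src_chrom, src_seq, src_pos, src_cm = sub, chrom, seq, int(p), float(cm)
                if lg == spec_lg and cm > spec_break:
                    # redraw this marker from the donor chromosome, at a
                    # donor position past the same cM breakpoint
                    d_sub, d_idx = chrom_info(spec_donor)
                    d_seq = bundle.genome(d_sub)[spec_donor]
                    d_frac = config.centromere_position_fraction[
                        d_idx % len(config.centromere_position_fraction)
                    ]
                    d_forbidden = _forbidden_for_markers(
                        bundle, d_sub, spec_donor, config.marker_length
                    )
                    lo = int(
                        position_of_cm(
                            spec_break,
                            len(d_seq),
                            d_frac,
                            config.recombination_suppression,
                            config.map_length_cm,
                        )
                    )
                    d_pos = _sample_marker_positions(
                        rng, 1, len(d_seq), config.marker_length, d_forbidden, lo=lo
                    )[0]
                    src_sub, src_chrom, src_seq = d_sub, spec_donor, d_seq
                    src_pos = int(d_pos)
                    src_cm = float(
                        cm_of_position(
                            d_pos,
                            len(d_seq),
                            d_frac,
                            config.recombination_suppression,
                            config.map_length_cm,
                        )
                    )
                tag = src_seq[src_pos : src_pos + config.marker_length]
                strand = "+" if rng.random() < 0.5 else "-"
                marker_id = f"h{lg}_{k + 1:04d}"
                markers.append(
                    {
                        "marker_id": marker_id,
                        "sequence": tag if strand == "+" else revcomp(tag),
                        "lg": lg,
                        "cM": float(cm),
                    }
                )
                truth.append(
                    {
                        "marker_id": marker_id,
                        "subgenome": src_sub,
                        "chromosome": src_chrom,
                        "position": src_pos,
                        "strand": strand,
                        "lg": lg,
                        "cM": float(cm),
                        "source_cm": src_cm,
                    }
                )
    return HexaploidPanel(
        bundle=bundle,
        markers=pd.DataFrame(markers, columns=["marker_id", "sequence", "lg", "cM"]),
        truth=pd.DataFrame(truth),
        lg_truth=pd.DataFrame(lg_rows, columns=["lg", "subgenome", "chromosome"]),
    )


def _fourfold_mask() -> np.ndarray:
    """Codon indices whose third position is fourfold degenerate (all sense)."""
    mask = np.zeros(64, dtype=bool)
    for idx, codon in enumerate(ks_clock.CODONS):
        if codon in ks_clock.STOP_CODONS:
            continue
        family = [codon[:2] + b for b in "TCAG"]
        aas = {ks_clock.AMINO[c] for c in family}
        if len(aas) == 1 and not any(c in ks_clock.STOP_CODONS for c in family):
            mask[idx] = True
    return mask


FOURFOLD = _fourfold_mask()
_SENSE = np.array(
    [i for i, c in enumerate(ks_clock.CODONS) if c not in ks_clock.STOP_CODONS],
    dtype=np.int8,
)


@dataclass
class KsPairSet:
    """Codon-aligned gene pairs plus per-pair evolution bookkeeping."""

    codons_a: np.ndarray  # (n_pairs, n_codons) codon indices
    codons_b: np.ndarray
    truth: pd.DataFrame  # pair_id, target_ks, n_substitutions, s_sites, p_s, ks

    @property
    def n_pairs(self) -> int:
        return self.codons_a.shape[0]

    def sequence_pair(self, i: int) -> tuple[str, str]:
        codons = np.array(ks_clock.CODONS)
        return (
            "".join(codons[self.codons_a[i]]),
            "".join(codons[self.codons_b[i]]),
        )

    def to_fasta(self, path) -> None:
        with open(path, "w", newline="\n") as fh:
            for i in range(self.n_pairs):
                a, b = self.sequence_pair(i)
                fh.write(f">pair{i}_a\n{a}\n>pair{i}_b\n{b}\n")


def simulate_ks_pairs(config: SimulationConfig) -> KsPairSet:
    """Evolve codon pairs so NG86 Ks is unimodal near ``config.ks_peak``.

    Substitutions are applied only at fourfold-degenerate third positions
    (guaranteed synonymous), with a per-pair probability chosen so the
    expected NG86 synonymous difference proportion matches the pair's
    target Ks after Jukes-Cantor inversion. ``ks_peak = 0`` yields
    identical pairs.
    """
    if config.ks_peak < 0:
        raise ValidationError("ks_peak must be non-negative")
    rng = config.rng(_STREAM_KS)
    n, m = config.n_gene_pairs, config.n_codons
    if n == 0:
        empty = np.zeros((0, m), dtype=np.int8)
        return KsPairSet(empty, empty.copy(), pd.DataFrame(
            columns=["pair_id", "target_ks", "n_substitutions", "s_sites", "p_s", "ks"]
        ))
    ca = rng.choice(_SENSE, size=(n, m)).astype(np.int64)
    if config.ks_peak == 0:
        target = np.zeros(n)
    else:
        target = np.clip(rng.normal(config.ks_peak, config.ks_dispersion, size=n), 0, None)
    p_site = 0.75 * (1.0 - np.exp(-4.0 * target / 3.0))
    s_orig = ks_clock.S_SITES[ca].sum(axis=1)
    ff = FOURFOLD[ca]
    n4 = ff.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p4 = np.where(n4 > 0, np.clip(p_site * s_orig / np.maximum(n4, 1), 0, 1), 0.0)
    mut = ff & (rng.random((n, m)) < p4[:, None])
    cb = ca.copy()
    if mut.any():
        idx = np.nonzero(mut)
        third = cb[idx] % 4
        new_third = (third + rng.integers(1, 4, size=third.size)) % 4
        cb[idx] = cb[idx] - third + new_third
    # realized NG86 bookkeeping straight from the counting tables
    s_avg = 0.5 * (ks_clock.S_SITES[ca].sum(1) + ks_clock.S_SITES[cb].sum(1))
    sd = ks_clock.SD_TABLE[ca, cb].sum(1)
    p_s = np.where(s_avg > 0, sd / s_avg, 0.0)
    ks = np.array([ks_clock.jukes_cantor(p) for p in p_s], dtype=object)
    truth = pd.DataFrame(
        {
            "pair_id": [f"pair{i}" for i in range(n)],
            "target_ks": target,
            "n_substitutions": mut.sum(axis=1).astype(int),
            "s_sites": s_avg,
            "p_s": p_s,
            "ks": [float(k) if k is not None else np.nan for k in ks],
        }
    )
    return KsPairSet(ca.astype(np.int8), cb.astype(np.int8), truth)


def simulate_genotypes(config: SimulationConfig) -> tuple[GenotypeMatrix, str]:
    """Clade-structured, mostly homozygous genotype matrix plus truth tree.

    Sites are assigned to tree branches with probability proportional to
    branch length (an infinite-sites model on a fixed rooted tree), so
    same-clade accessions are closer than between-clade ones. Optional
    heterozygote/missing contamination is injected cell-wise for filter
    testing. Returns (matrix, truth tree in Newick).
    """
    rng = config.rng(_STREAM_GENO)
    terminal_factor = 0.25
    accessions, branches, newick_parts = [], [], []
    # branches: (label, length, member slice)
    for clade, n, div in config.clade_structure:
        members = [f"{clade}_{j + 1}" for j in range(n)]
        start = len(accessions)
        accessions += members
        idx = list(range(start, start + n))
        tlen = terminal_factor * div
        if n > 1:
            branches.append((f"{clade}", div, idx))
            for j, a in zip(idx, members):
                branches.append((a, tlen, [j]))
            newick_parts.append(
                "(" + ",".join(f"{a}:{tlen:g}" for a in members) + f"):{div:g}"
            )
        else:
            branches.append((members[0], div + tlen, idx))
            newick_parts.append(f"{members[0]}:{div + tlen:g}")
    newick = "(" + ",".join(newick_parts) + ");"
    if config.n_sites < len(branches):
        raise SizingError(
            f"n_sites={config.n_sites} below the {len(branches)} branches needing support"
        )
    lengths = np.array([b[1] for b in branches])
    chosen = rng.choice(len(branches), size=config.n_sites, p=lengths / lengths.sum())
    calls = np.zeros((config.n_sites, config.n_accessions), dtype=np.int8)
    for s, b in enumerate(chosen):
        calls[s, branches[b][2]] = 2
    # site coordinates on the A-genome chromosomes, increasing per chromosome
    chroms = [f"{SUBGENOME_PREFIX['A']}{i + 1}" for i in range(config.n_chromosomes)]
    per = np.array_split(np.arange(config.n_sites), config.n_chromosomes)
    site_rows = []
    bases = np.array(list("ACGT"))
    for chrom, block in zip(chroms, per):
        k = len(block)
        pos = np.sort(rng.choice(config.chromosome_length, size=k, replace=False)) + 1
        for p in pos:
            ref, alt = rng.choice(4, size=2, replace=False)
            site_rows.append(
                {"chromosome": chrom, "position": int(p), "ref": bases[ref], "alt": bases[alt]}
            )
    sites = pd.DataFrame(site_rows, columns=["chromosome", "position", "ref", "alt"])
    if config.het_rate > 0:
        calls[rng.random(calls.shape) < config.het_rate] = 1
    if config.missing_rate > 0:
        calls[rng.random(calls.shape) < config.missing_rate] = -1
    return GenotypeMatrix(accessions=accessions, sites=sites, calls=calls), newick


def simulate_synteny_blocks(
    bundle: SyntheticBundle, n_blocks_per_chromosome: int = 6, jitter: float = 0.05
) -> pd.DataFrame:
    """Synteny blocks between the A and C genomes from the shared gene layout.

    Because the simulated subgenomes diverge by substitution only, gene
    coordinates coincide; each A chromosome's gene span is cut into blocks
    whose C-side coordinates get mild multiplicative end jitter, giving a
    strongly but not perfectly correlated block-size relationship.
    """
    rng = bundle.config.rng(_STREAM_SYNTENY)
    ann = bundle.annotations
    rows = []
    for i in range(bundle.config.n_chromosomes):
        chrom_a = f"{SUBGENOME_PREFIX['A']}{i + 1}"
        chrom_b = f"{SUBGENOME_PREFIX['C']}{i + 1}"
        genes = ann[(ann["genome"] == "A") & (ann["chromosome"] == chrom_a)]
        genes = genes.sort_values("start").reset_index(drop=True)
        if genes.empty:
            continue
        cuts = np.array_split(np.arange(len(genes)), n_blocks_per_chromosome)
        for block in cuts:
            if len(block) == 0:
                continue
            s = int(genes.loc[block[0], "start"])
            e = int(genes.loc[block[-1], "end"])
            scale = 1.0 + rng.uniform(-jitter, jitter)
            size_b = max(1, int(round((e - s) * scale)))
            rows.append(
                {
                    "chrom_a": chrom_a,
                    "start_a": s,
                    "end_a": e,
                    "chrom_b": chrom_b,
                    "start_b": s,
                    "end_b": s + size_b,
                    "n_gene_pairs": len(block),
                    "orientation": "+",
                }
            )
    return pd.DataFrame(rows)


def write_bundle(bundle: SyntheticBundle, outdir) -> dict[str, Path]:
    """Write FASTA/GFF3/TSV artifacts for a bundle; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for sub in ("A", "D", "C"):
        fa = outdir / f"genome_{sub}.fasta"
        write_fasta(fa, bundle.genome(sub))
        paths[f"genome_{sub}"] = fa
        gff = outdir / f"genes_{sub}.gff3"
        write_gff3(bundle.annotations[bundle.annotations["genome"] == sub], gff)
        paths[f"genes_{sub}"] = gff
    arrays = outdir / "truth_arrays.tsv"
    bundle.truth_arrays.to_csv(arrays, sep="\t", index=False, lineterminator="\n")
    paths["truth_arrays"] = arrays
    return paths


def write_marker_tsv(markers: pd.DataFrame, path) -> None:
    markers.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.6f")


def read_marker_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"marker_id": str, "lg": str})
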
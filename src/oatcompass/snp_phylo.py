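"""SNP filtering, LD-window pruning, and bootstrapped NJ phylogeny.

Mirrors the resequencing-panel workflow for highly inbred (cleistogamous)
accessions: biallelic sites are kept only with zero missing calls, a
heterozygote fraction no greater than 5% (excess heterozygosity flags
spurious read mapping in an inbred panel), and minor allele frequency of at
least 0.1. Linked sites are thinned with a greedy sliding window (default
500 kb, r-squared threshold 0.1). The tree is neighbor-joining on pairwise
p-distances with heterozygotes coded as 0.5 allele dosage, rooted on a
designated outgroup, with clade support from site-resampling bootstrap.

Genotype codes in the calls matrix: 0 = homozygous reference, 1 =
heterozygous, 2 = homozygous alternate, -1 = missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj

from .errors import ValidationError

MISSING = -1
SITE_COLUMNS = ["chromosome", "position", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Biallelic genotype calls: sites x accessions."""

    accessions: list[str]
    sites: pd.DataFrame  # chromosome, position (1-based), ref, alt
    calls: np.ndarray  # int8 (n_sites, n_accessions)

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sites), len(self.accessions)):
            raise ValidationError("calls shape does not match sites x accessions")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def dosage(self) -> np.ndarray:
        """Alternate-allele dosage in [0, 1] with NaN for missing calls."""
        d = self.calls.astype(float) / 2.0
        d[self.calls == MISSING] = np.nan
        return d

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            accessions=list(self.accessions),
            sites=self.sites.iloc[index].reset_index(drop=True),
            calls=self.calls[index],
        )


@dataclass(frozen=True)
class FilterReport:
    input_sites: int
    removed_unplaced: int
    removed_missing: int
    removed_het: int
    removed_maf: int
    output_sites: int


def filter_sites(
    matrix: GenotypeMatrix,
    max_het_fraction: float = 0.05,
    min_maf: float = 0.1,
    chromosomes: set[str] | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the missing / heterozygosity / MAF site filters.

    Retained sites have zero missing calls, a heterozygote fraction of at
    most ``max_het_fraction`` (strictly greater is removed), and minor
    allele frequency of at least ``min_maf`` (heterozygotes count half a
    dose). Removal is attributed to the first failing rule in the order
    unplaced -> missing -> het -> maf. ``chromosomes``, when given,
    restricts sites to named (placed) chromosomes first.
    """
    calls = matrix.calls
    n_acc = len(matrix.accessions)
    placed = (
        matrix.sites["chromosome"].isin(chromosomes).to_numpy()
        if chromosomes is not None
        else np.ones(matrix.n_sites, dtype=bool)
    )
    any_missing = (calls == MISSING).any(axis=1)
    het_frac = (calls == 1).sum(axis=1) / n_acc
    alt_freq = (calls == 2).sum(axis=1) / n_acc + 0.5 * het_frac
    maf = np.minimum(alt_freq, 1.0 - alt_freq)

    r_unplaced = ~placed
    r_missing = placed & any_missing
    r_het = placed & ~any_missing & (het_frac > max_het_fraction)
    r_maf = placed & ~any_missing & ~(het_frac > max_het_fraction) & (maf < min_maf)
    keep = placed & ~any_missing & ~(het_frac > max_het_fraction) & (maf >= min_maf)
    report = FilterReport(
        input_sites=matrix.n_sites,
        removed_unplaced=int(r_unplaced.sum()),
        removed_missing=int(r_missing.sum()),
        removed_het=int(r_het.sum()),
        removed_maf=int(r_maf.sum()),
        output_sites=int(keep.sum()),
    )
    return matrix.take_sites(np.nonzero(keep)[0]), report


def _r_squared(x: np.ndarray, y: np.ndarray) -> float:
    """Squared allele-dosage correlation between two sites."""
    vx, vy = x.var(), y.var()
    if vx == 0 or vy == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_prune(
    matrix: GenotypeMatrix,
    window_bp: int = 500_000,
    r2_threshold: float = 0.1,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Greedy left-to-right LD thinning within a physical window.

    Scanning each chromosome in position order, a site is dropped when its
    r-squared with any already-retained site no more than ``window_bp``
    upstream exceeds ``r2_threshold``. Monomorphic (zero-variance) sites
    are dropped with reason ``monomorphic``. After pruning, no retained
    pair within a window exceeds the threshold.
    """
    dosage = matrix.dosage()
    if np.isnan(dosage).any():
        raise ValidationError("LD pruning expects a matrix with no missing calls")
    keep_idx: list[int] = []
    dropped = []
    order = matrix.sites.sort_values(["chromosome", "position"]).index.to_numpy()
    kept_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for i in order:
        chrom = matrix.sites.at[i, "chromosome"]
        pos = int(matrix.sites.at[i, "position"])
        x = dosage[i]
        if x.var() == 0:
            dropped.append({"site_index": int(i), "reason": "monomorphic"})
            continue
        linked = False
        for kpos, kidx in reversed(kept_by_chrom.get(chrom, [])):
            if pos - kpos > window_bp:
                break
            if _r_squared(x, dosage[kidx]) > r2_threshold:
                linked = True
                break
        if linked:
            dropped.append({"site_index": int(i), "reason": "linked"})
        else:
            keep_idx.append(int(i))
            kept_by_chrom.setdefault(chrom, []).append((pos, int(i)))
    keep_arr = np.array(sorted(keep_idx), dtype=int)
    return matrix.take_sites(keep_arr), pd.DataFrame(
        dropped, columns=["site_index", "reason"]
    )


def p_distance_matrix(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise p-distances on allele dosage (het = 0.5), pairwise-complete."""
    d = matrix.dosage()
    n = len(matrix.accessions)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = np.abs(d[:, i] - d[:, j])
            ok = ~np.isnan(diff)
            if not ok.any():
                raise ValidationError("no co-called sites for an accession pair")
            out[i, j] = out[j, i] = float(diff[ok].mean())
    return DistanceMatrix(out, ids=matrix.accessions)


def _clades(tree, all_tips: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial tip sets below internal nodes of a rooted tree."""
    clades = set()
    for node in tree.non_tips(include_self=False):
        tips = frozenset(t.name for t in node.tips())
        if 1 < len(tips) < len(all_tips):
            clades.add(tips)
    return clades


@dataclass
class TreeResult:
    newick: str
    tree: object  # skbio TreeNode, rooted, with bootstrap support as node names
    supports: dict[frozenset[str], float] = field(default_factory=dict)
    n_bootstrap: int = 0


def _nj_rooted(dm: DistanceMatrix, outgroup_id: str):
    tree = nj(dm)
    rooted = tree.root_by_outgroup([outgroup_id])
    return rooted


def build_tree(
    matrix: GenotypeMatrix,
    outgroup_id: str,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> TreeResult:
    """Outgroup-rooted NJ tree with site-resampling bootstrap supports.

    Supports are the percentage of replicate trees (sites resampled with
    replacement, canonically by site index) containing each clade of the
    reference tree, written as internal node names in the Newick output.
    """
    if len(matrix.accessions) < 3:
        raise ValidationError("need at least 3 accessions")
    if outgroup_id not in matrix.accessions:
        raise ValidationError(f"outgroup {outgroup_id!r} not in matrix")
    if matrix.n_sites == 0:
        raise ValidationError("no sites")
    dm = p_distance_matrix(matrix)
    ref = _nj_rooted(dm, outgroup_id)
    all_tips = frozenset(matrix.accessions)
    ref_clades = _clades(ref, all_tips)

    # per-site absolute dosage differences, so replicate distance matrices
    # are means over resampled site rows
    d = matrix.dosage()
    n = len(matrix.accessions)
    per_site = np.abs(d[:, :, None] - d[:, None, :])  # (sites, n, n)

    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {c: 0 for c in ref_clades}
    for _ in range(n_bootstrap):
        idx = rng.integers(0, matrix.n_sites, size=matrix.n_sites)
        mat = np.nanmean(per_site[idx], axis=0)
        np.fill_diagonal(mat, 0.0)
        rep = _nj_rooted(DistanceMatrix(mat, ids=matrix.accessions), outgroup_id)
        rep_clades = _clades(rep, all_tips)
        for c in ref_clades:
            if c in rep_clades:
                counts[c] += 1
    supports = {
        c: 100.0 * k / n_bootstrap if n_bootstrap else float("nan")
        for c, k in counts.items()
    }
    for node in ref.non_tips(include_self=False):
        tips = frozenset(t.name for t in node.tips())
        if tips in supports:
            node.name = f"{supports[tips]:.0f}"
    newick = str(ref).strip()
    return TreeResult(newick=newick, tree=ref, supports=supports, n_bootstrap=n_bootstrap)


def read_genotype_tsv(path) -> GenotypeMatrix:
    """TSV with columns chromosome, position, ref, alt, then one per accession.

    Calls are written as 0/1/2 dosage codes with ``.`` for missing.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    acc = [c for c in df.columns if c not in SITE_COLUMNS]
    calls = df[acc].replace(".", MISSING).to_numpy(dtype=np.int8)
    return GenotypeMatrix(accessions=acc, sites=df[SITE_COLUMNS].copy(), calls=calls)


def write_genotype_tsv(matrix: GenotypeMatrix, path) -> None:
    df = matrix.sites.copy()
    for k, a in enumerate(matrix.accessions):
        col = matrix.calls[:, k].astype(object)
        df[a] = ["." if v == MISSING else int(v) for v in col]
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Minimal VCFv4.2 with GT fields (unphased diploid)."""
    gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.accessions)
            + "\n"
        )
        for i, site in enumerate(matrix.sites.itertuples(index=False)):
            row = [
                str(site.chromosome),
                str(int(site.position)),
                ".",
                site.ref,
                site.alt,
                ".",
                "PASS",
                ".",
                "GT",
            ] + [gt[int(v)] for v in matrix.calls[i]]
            fh.write("\t".join(row) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF (text) file via pysam."""
    import pysam

    sites, rows = [], []
    with pysam.VariantFile(str(path)) as vf:
        accessions = list(vf.header.samples)
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            sites.append(
                {
                    "chromosome": rec.chrom,
                    "position": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0],
                }
            )
            row = []
            for s in accessions:
                g = rec.samples[s]["GT"]
                if g is None or any(a is None for a in g):
                    row.append(MISSING)
                else:
                    row.append(int(sum(g)))
            rows.append(row)
    return GenotypeMatrix(
        accessions=accessions,
        sites=pd.DataFrame(sites, columns=SITE_COLUMNS),
        calls=np.array(rows, dtype=np.int8) if rows else np.zeros((0, len(accessions)), np.int8),
    )
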
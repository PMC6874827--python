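"""Site filters, LD pruning, and NJ tree building with bootstrap support."""

import itertools

import numpy as np
import pandas as pd
import pytest

from oatcompass import simulate, snp_phylo as sp
from oatcompass.errors import ValidationError


def _matrix(calls, positions=None, chromosome="c1"):
    calls = np.asarray(calls, dtype=np.int8)
    n_sites, n_acc = calls.shape
    positions = positions if positions is not None else range(1, n_sites + 1)
    sites = pd.DataFrame(
        {
            "chromosome": [chromosome] * n_sites,
            "position": list(positions),
            "ref": ["A"] * n_sites,
            "alt": ["G"] * n_sites,
        }
    )
    return sp.GenotypeMatrix(
        accessions=[f"t{i}" for i in range(n_acc)], sites=sites, calls=calls
    )


class TestFilterSites:
    def test_any_missing_call_removes_site(self):
        calls = np.zeros((1, 20), dtype=np.int8)
        calls[0, 3] = -1
        _, report = sp.filter_sites(_matrix(calls))
        assert report.removed_missing == 1 and report.output_sites == 0

    def test_het_rule_is_strictly_greater_than_five_percent(self):
        one_het = np.full((1, 20), 2, dtype=np.int8)
        one_het[0, :10] = 0
        one_het[0, 0] = 1  # 5% het, frequencies balanced
        kept, report = sp.filter_sites(_matrix(one_het))
        assert report.removed_het == 0 and kept.n_sites == 1
        two_het = one_het.copy()
        two_het[0, 1] = 1  # 10% het
        _, report2 = sp.filter_sites(_matrix(two_het))
        assert report2.removed_het == 1

    def test_maf_threshold_on_homozygous_panel(self):
        single = np.zeros((1, 20), dtype=np.int8)
        single[0, 0] = 2  # minor frequency 0.05
        _, r1 = sp.filter_sites(_matrix(single))
        assert r1.removed_maf == 1
        double = single.copy()
        double[0, 1] = 2  # minor frequency 0.10
        kept, r2 = sp.filter_sites(_matrix(double))
        assert r2.removed_maf == 0 and kept.n_sites == 1

    def test_first_failing_rule_attribution_and_accounting(self):
        calls = np.zeros((3, 20), dtype=np.int8)
        calls[0, 0] = -1  # missing (also would fail maf)
        calls[1, :3] = 1  # 15% het (also would fail maf)
        calls[2, 0] = 2  # maf 0.05
        _, report = sp.filter_sites(_matrix(calls))
        assert (report.removed_missing, report.removed_het, report.removed_maf) == (1, 1, 1)
        assert report.input_sites == report.output_sites + 3

    def test_post_filter_matrix_satisfies_all_thresholds(self):
        cfg = simulate.SimulationConfig(seed=6, het_rate=0.03, missing_rate=0.02)
        gm, _ = simulate.simulate_genotypes(cfg)
        kept, _ = sp.filter_sites(gm)
        assert (kept.calls != sp.MISSING).all()
        het_frac = (kept.calls == 1).mean(axis=1)
        assert (het_frac <= 0.05).all()
        alt = (kept.calls == 2).mean(axis=1) + het_frac / 2
        assert (np.minimum(alt, 1 - alt) >= 0.1).all()


class TestLDPrune:
    def test_duplicated_adjacent_site_dropped(self):
        site = [0, 0, 2, 2, 0, 2]
        pruned, dropped = sp.ld_prune(_matrix([site, site], positions=[100, 101]))
        assert pruned.n_sites == 1
        assert list(dropped.reason) == ["linked"]

    def test_low_r2_pair_kept(self):
        # haplotype frequencies p_A = p_B = 0.5, p_AB = 0.3:
        # r^2 = (0.3 - 0.25)^2 / 0.25^2 = 0.04 < 0.1
        a = [2] * 10 + [0] * 10
        b = [2] * 6 + [0] * 4 + [2] * 4 + [0] * 6
        x, y = np.array(a) / 2, np.array(b) / 2
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert r2 == pytest.approx(0.04, abs=1e-9)
        pruned, _ = sp.ld_prune(_matrix([a, b], positions=[100, 200]))
        assert pruned.n_sites == 2

    def test_identical_sites_outside_window_both_kept(self):
        site = [0, 0, 2, 2]
        pruned, _ = sp.ld_prune(
            _matrix([site, site], positions=[1, 600_002]), window_bp=500_000
        )
        assert pruned.n_sites == 2

    def test_monomorphic_site_dropped_with_reason(self):
        pruned, dropped = sp.ld_prune(_matrix([[0, 0, 0, 0], [0, 2, 0, 2]]))
        assert pruned.n_sites == 1
        assert "monomorphic" in set(dropped.reason)

    def test_no_retained_pair_within_window_exceeds_threshold(self):
        cfg = simulate.SimulationConfig(seed=7)
        gm, _ = simulate.simulate_genotypes(cfg)
        kept, _ = sp.filter_sites(gm)
        pruned, _ = sp.ld_prune(kept)
        d = pruned.dosage()
        for chrom, grp in pruned.sites.groupby("chromosome"):
            idx = grp.index.to_numpy()
            for i, j in itertools.combinations(idx, 2):
                if abs(grp.position[j] - grp.position[i]) <= 500_000:
                    r2 = np.corrcoef(d[i], d[j])[0, 1] ** 2
                    assert r2 <= 0.1 + 1e-12


def _additive_matrix():
    """Counts matrix realizing d(AB)=2/9, d(CD)=4/9, cross distances 6/9."""
    blocks = [
        (1, [0]),  # A-only
        (1, [1]),  # B-only
        (2, [2]),  # C-only
        (2, [3]),  # D-only
        (3, [0, 1]),  # internal edge: A,B share the derived allele
    ]
    rows = []
    for count, members in blocks:
        row = np.zeros(4, dtype=np.int8)
        row[members] = 2
        rows += [row] * count
    return np.array(rows)


def oracle_least_squares_topologies(D):
    """Brute force: fit edge lengths for each 4-taxon topology, return the
    exactly fitting one. Taxa 0..3; topologies given by the sister pair."""
    fits = {}
    for pair in [(0, 1), (0, 2), (0, 3)]:
        others = [i for i in range(4) if i not in pair]
        # unknowns: e0..e3 terminal, e4 internal
        rows, rhs = [], []
        for i, j in itertools.combinations(range(4), 2):
            coef = np.zeros(5)
            coef[i] += 1
            coef[j] += 1
            same_side = {i, j} == set(pair) or {i, j} == set(others)
            if not same_side:
                coef[4] = 1
            rows.append(coef)
            rhs.append(D[i, j])
        sol, res, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
        pred = np.array(rows) @ sol
        fits[pair] = (np.abs(pred - np.array(rhs)).max(), sol)
    return fits


class TestBuildTree:
    def test_nj_reproduces_additive_metric_exactly(self):
        gm = _matrix(_additive_matrix())
        dm = sp.p_distance_matrix(gm)
        D = dm.data
        fits = oracle_least_squares_topologies(D)
        # the oracle finds exactly one perfectly fitting topology: (0,1)|(2,3)
        exact = [pair for pair, (resid, _) in fits.items() if resid < 1e-12]
        assert exact == [(0, 1)]
        result = sp.build_tree(gm, outgroup_id="t3", n_bootstrap=0)
        tree = result.tree
        # clade {t0,t1} present after rooting on t3
        clades = {frozenset(t.name for t in n.tips()) for n in tree.non_tips()}
        assert frozenset({"t0", "t1"}) in clades
        # patristic distances reproduce the input metric
        for i, j in itertools.combinations(range(4), 2):
            a, b = tree.find(f"t{i}"), tree.find(f"t{j}")
            assert a.distance(b) == pytest.approx(D[i, j], abs=1e-9)

    def test_three_taxa_unique_topology(self):
        calls = np.array([[2, 0, 0], [0, 2, 0], [0, 0, 2]], dtype=np.int8)
        result = sp.build_tree(_matrix(calls), outgroup_id="t2", n_bootstrap=0)
        assert sorted(t.name for t in result.tree.tips()) == ["t0", "t1", "t2"]

    def test_two_clean_clades_reach_high_support(self):
        cfg = simulate.SimulationConfig(seed=8)
        gm, _ = simulate.simulate_genotypes(cfg)
        kept, _ = sp.filter_sites(gm)
        pruned, _ = sp.ld_prune(kept)
        result = sp.build_tree(pruned, outgroup_id="outgroup_1", n_bootstrap=200, seed=3)
        clade_a = frozenset(a for a in gm.accessions if a.startswith("cladeA"))
        clade_b = frozenset(a for a in gm.accessions if a.startswith("cladeB"))
        assert result.supports[clade_a] >= 90
        assert result.supports[clade_b] >= 90

    def test_supports_invariant_under_accession_permutation(self):
        cfg = simulate.SimulationConfig(seed=9)
        gm, _ = simulate.simulate_genotypes(cfg)
        perm = np.random.default_rng(1).permutation(len(gm.accessions))
        gm_perm = sp.GenotypeMatrix(
            accessions=[gm.accessions[i] for i in perm],
            sites=gm.sites.copy(),
            calls=gm.calls[:, perm],
        )
        r1 = sp.build_tree(gm, "outgroup_1", n_bootstrap=50, seed=4)
        r2 = sp.build_tree(gm_perm, "outgroup_1", n_bootstrap=50, seed=4)
        # zero-length within-clade branches make shallow nodes tie-dependent;
        # the supported clades themselves must be order-invariant
        for clade in (
            frozenset(a for a in gm.accessions if a.startswith("cladeA")),
            frozenset(a for a in gm.accessions if a.startswith("cladeB")),
        ):
            assert clade in r1.supports and clade in r2.supports
            assert r1.supports[clade] == r2.supports[clade]

    def test_missing_outgroup_and_tiny_matrices_rejected(self):
        calls = np.zeros((2, 4), dtype=np.int8)
        with pytest.raises(ValidationError):
            sp.build_tree(_matrix(calls), outgroup_id="nope")
        with pytest.raises(ValidationError):
            sp.build_tree(_matrix(np.zeros((2, 2), dtype=np.int8)), outgroup_id="t0")


class TestIO:
    def test_tsv_roundtrip(self, tmp_path):
        gm, _ = simulate.simulate_genotypes(
            simulate.SimulationConfig(seed=10, missing_rate=0.05)
        )
        path = tmp_path / "geno.tsv"
        sp.write_genotype_tsv(gm, path)
        back = sp.read_genotype_tsv(path)
        assert back.accessions == gm.accessions
        assert (back.calls == gm.calls).all()

    def test_vcf_roundtrip(self, tmp_path):
        gm, _ = simulate.simulate_genotypes(
            simulate.SimulationConfig(seed=11, het_rate=0.05, missing_rate=0.05)
        )
        path = tmp_path / "geno.vcf"
        sp.write_vcf(gm, path)
        back = sp.read_vcf(path)
        assert back.accessions == gm.accessions
        assert (back.calls == gm.calls).all()
        assert (back.sites.position == gm.sites.position).all()
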
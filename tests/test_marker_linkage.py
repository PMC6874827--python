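"""Marker placement, LG assignment, merge planning, interval queries."""

import numpy as np
import pandas as pd
import pytest

from oatcompass import marker_linkage as ml
from oatcompass.errors import MergeConflictError, ValidationError
from oatcompass.seq import revcomp


def _markers(*seqs):
    return pd.DataFrame(
        {"marker_id": [f"m{i}" for i in range(len(seqs))], "sequence": list(seqs)}
    )


def brute_force_hits(tag, sequences):
    """Exhaustive scan oracle: every occurrence of tag or its revcomp."""
    hits = []
    rc = revcomp(tag)
    for name, seq in sequences.items():
        for i in range(len(seq) - len(tag) + 1):
            window = seq[i : i + len(tag)]
            if window == tag:
                hits.append((name, i, "+"))
            if rc != tag and window == rc:
                hits.append((name, i, "-"))
    return hits


class TestPlaceMarkers:
    def test_unique_forward_substring_placed_plus(self):
        seqs = {"chr1": "AAAACGTACGGGTTTT"}
        plc, rej = ml.place_markers(_markers("ACGTACGG"), seqs)
        assert rej.empty
        assert tuple(plc.iloc[0][["chromosome", "position", "strand"]]) == ("chr1", 3, "+")

    def test_reverse_complement_placed_minus_at_substring_start(self):
        seqs = {"chr1": "AAAACGTACGGGTTTT"}
        plc, _ = ml.place_markers(_markers(revcomp("ACGTACGG")), seqs)
        assert tuple(plc.iloc[0][["chromosome", "position", "strand"]]) == ("chr1", 3, "-")

    def test_multi_hit_and_no_hit_rejected(self):
        seqs = {"chr1": "ACGTACGTAAAAAAAACGTACGT"}
        tags = _markers("ACGTACGT", "GGGGCCCC")
        plc, rej = ml.place_markers(tags, seqs)
        assert plc.empty
        reasons = dict(zip(rej.marker_id, rej.reason))
        assert reasons == {"m0": "multi_hit", "m1": "no_hit"}

    def test_empty_marker_table_gives_empty_outputs(self):
        plc, rej = ml.place_markers(_markers(), {"chr1": "ACGT"})
        assert plc.empty and rej.empty

    def test_agrees_with_exhaustive_scan_on_random_genomes(self, rng):
        bases = np.array(list("ACGT"))
        seqs = {
            f"c{k}": "".join(rng.choice(bases, 300)) for k in range(3)
        }
        # tags: genuine substrings, reverse complements, mutated, duplicated
        tags = []
        for _ in range(30):
            chrom = f"c{int(rng.integers(3))}"
            i = int(rng.integers(0, 280))
            tag = seqs[chrom][i : i + 20]
            style = rng.integers(4)
            if style == 1:
                tag = revcomp(tag)
            elif style == 2:
                pos = int(rng.integers(20))
                tag = tag[:pos] + "ACGT"[int(rng.integers(4))] + tag[pos + 1 :]
            elif style == 3:
                seqs["c0"] += tag  # force an extra copy
            tags.append(tag)
        plc, rej = ml.place_markers(_markers(*tags), seqs)
        placed = {row.marker_id: (row.chromosome, row.position, row.strand)
                  for row in plc.itertuples()}
        for mid, tag in zip(_markers(*tags).marker_id, tags):
            hits = brute_force_hits(tag, seqs)
            if len(hits) == 1:
                assert placed[mid] == hits[0]
            else:
                assert mid not in placed


class TestAssignLinkageGroups:
    @staticmethod
    def _fake(scaffold_counts):
        rows, map_rows = [], []
        k = 0
        for scaffold, by_lg in scaffold_counts.items():
            for lg, n in by_lg.items():
                for _ in range(n):
                    rows.append({"marker_id": f"x{k}", "chromosome": scaffold,
                                 "position": k, "strand": "+"})
                    map_rows.append({"marker_id": f"x{k}", "lg": lg, "cM": float(k)})
                    k += 1
        return pd.DataFrame(rows), pd.DataFrame(map_rows)

    def test_plurality_percentages_match_printed_rounding(self):
        plc, mp = self._fake({"s1": {"7": 838, "1": 8}})
        table = ml.assign_linkage_groups(plc, mp).table
        row = table.iloc[0]
        assert row.total_placed == 846
        assert row.plurality_lg == "7"
        assert row.mismatch_pct == 0.9
        assert row.match_pct == 99.1

    def test_single_lg_scores_one_hundred(self):
        plc, mp = self._fake({"s1": {"1": 10}})
        row = ml.assign_linkage_groups(plc, mp).table.iloc[0]
        assert row.match_pct == 100.0 and row.mismatch_count == 0

    def test_exact_tie_takes_smallest_lg_and_flags(self):
        plc, mp = self._fake({"s1": {"2": 5, "1": 5}})
        row = ml.assign_linkage_groups(plc, mp).table.iloc[0]
        assert row.plurality_lg == "1" and bool(row.tie)

    def test_row_order_invariance(self):
        plc, mp = self._fake({"s1": {"1": 7, "2": 3}, "s2": {"2": 9}})
        shuffled = plc.sample(frac=1, random_state=0).reset_index(drop=True)
        a = ml.assign_linkage_groups(plc, mp).table
        b = ml.assign_linkage_groups(shuffled, mp).table
        pd.testing.assert_frame_equal(a, b)

    def test_overall_summary_reports_both_mismatch_conventions(self):
        plc, mp = self._fake({"s1": {"1": 99, "2": 1}, "s2": {"3": 9, "4": 1}})
        summary = ml.assign_linkage_groups(plc, mp).summary()
        assert summary["mean_of_rows"] == pytest.approx(5.5)  # (1.0 + 10.0)/2
        assert summary["pooled"] == pytest.approx(1.8)  # 2/110


def _split_scenario(forward=True):
    """Two scaffolds covering one LG: 0-48 cM and 49-116 cM."""
    rows, map_rows = [], []
    for k, cm in enumerate(np.linspace(0, 48, 8)):
        rows.append({"marker_id": f"a{k}", "chromosome": "scafA",
                     "position": 1000 * k, "strand": "+"})
        map_rows.append({"marker_id": f"a{k}", "lg": "2", "cM": cm})
    for k, cm in enumerate(np.linspace(49, 116, 8)):
        pos = 1000 * k if forward else 1000 * (8 - k)
        rows.append({"marker_id": f"b{k}", "chromosome": "scafB",
                     "position": pos, "strand": "+"})
        map_rows.append({"marker_id": f"b{k}", "lg": "2", "cM": cm})
    return pd.DataFrame(rows), pd.DataFrame(map_rows)


class TestMergePlan:
    def test_orders_by_cm_span_and_keeps_forward_orientation(self):
        plc, mp = _split_scenario()
        table = ml.assign_linkage_groups(plc, mp)
        plan = ml.infer_merge_plan(table, plc, mp)
        assert plan.entries == {"2": [("scafA", "+"), ("scafB", "+")]}

    def test_anticorrelated_scaffold_gets_minus_orientation(self):
        plc, mp = _split_scenario(forward=False)
        table = ml.assign_linkage_groups(plc, mp)
        plan = ml.infer_merge_plan(table, plc, mp)
        assert plan.entries["2"][1] == ("scafB", "-")

    def test_single_scaffold_lg_has_no_plan_entry(self):
        plc, mp = _split_scenario()
        solo = plc[plc.chromosome == "scafA"]
        table = ml.assign_linkage_groups(solo, mp)
        plan = ml.infer_merge_plan(table, solo, mp)
        assert plan.entries == {}

    def test_overlapping_cm_spans_raise_conflict(self):
        plc, mp = _split_scenario()
        mp2 = mp.copy()
        mp2.loc[mp2.marker_id.str.startswith("b"), "cM"] -= 30  # spans now overlap
        table = ml.assign_linkage_groups(plc, mp2)
        with pytest.raises(MergeConflictError, match="scafA"):
            ml.infer_merge_plan(table, plc, mp2)


class TestApplyMerge:
    def test_merged_length_includes_thousand_n_gap(self):
        seqs = {"s1": "A" * 100, "s2": "C" * 200}
        plan = ml.MergePlan(entries={"lg1": [("s1", "+"), ("s2", "+")]})
        merged = ml.apply_merge(seqs, plan)
        assert set(merged) == {"lg1"}
        assert len(merged["lg1"]) == 1300
        assert "N" * 1000 in merged["lg1"]
        assert "N" * 1001 not in merged["lg1"]

    def test_minus_part_is_reverse_complemented(self):
        seqs = {"s1": "ACGTTT", "s2": "AACCGG"}
        plan = ml.MergePlan(entries={"lg": [("s1", "+"), ("s2", "-")]}, gap_n=5)
        merged = ml.apply_merge(seqs, plan)
        assert merged["lg"] == "ACGTTT" + "N" * 5 + revcomp("AACCGG")

    def test_empty_plan_is_identity(self):
        seqs = {"s1": "ACGT"}
        assert ml.apply_merge(seqs, ml.MergePlan(entries={})) == seqs

    def test_unknown_scaffold_rejected(self):
        with pytest.raises(ValidationError):
            ml.apply_merge({"s1": "ACGT"}, ml.MergePlan(entries={"lg": [("nope", "+")]}))


class TestGenesInInterval:
    ann = pd.DataFrame(
        {
            "genome": ["A"] * 3,
            "chromosome": ["c1"] * 3,
            "start": [0, 100, 200],  # 0-based half-open
            "end": [50, 150, 250],
            "strand": ["+", "-", "+"],
            "gene_id": ["g1", "g2", "g3"],
        }
    )

    def test_interval_covering_two_of_three_genes(self):
        hits = ml.genes_in_interval(self.ann, "c1", 40, 160)  # 1-based closed
        assert list(hits.gene_id) == ["g1", "g2"]

    def test_gene_straddling_interval_start_included(self):
        hits = ml.genes_in_interval(self.ann, "c1", 245, 260)
        assert list(hits.gene_id) == ["g3"]

    def test_gap_interval_is_empty(self):
        assert ml.genes_in_interval(self.ann, "c1", 60, 90).empty

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValidationError):
            ml.genes_in_interval(self.ann, "c9", 1, 10)


class TestSyntheticRecovery:
    def test_clean_panel_recovers_every_truth_position(
        self, linkage_panel, linkage_placements, bundle
    ):
        markers, truth = linkage_panel
        placements, rejects = linkage_placements
        assert rejects.empty
        merged = placements.merge(truth, on="marker_id", suffixes=("", "_t"))
        assert len(merged) == len(markers)
        assert (merged.position == merged.position_t).all()
        assert (merged.chromosome == merged.chromosome_t).all()
        assert (merged.strand == merged.strand_t).all()

    def test_lg_assignment_recovers_every_scaffold(
        self, linkage_panel, linkage_placements
    ):
        markers, truth = linkage_panel
        placements, _ = linkage_placements
        table = ml.assign_linkage_groups(placements, markers).table
        truth_lg = truth.drop_duplicates("chromosome").set_index("chromosome")["lg"]
        for row in table.itertuples():
            assert row.plurality_lg == truth_lg[row.scaffold]
            assert row.match_pct == 100.0

    def test_split_chromosome_roundtrips_through_merge(self, bundle, config):
        from oatcompass import simulate

        chrom = "AA1"
        seq = bundle.genome_A[chrom]
        half = len(seq) // 2
        split = {"arm1": seq[:half], "arm2": seq[half:]}
        markers, truth = simulate.simulate_linkage_panel(bundle, config)
        sub = markers[markers.lg == "1"]
        placements, _ = ml.place_markers(sub, split)
        table = ml.assign_linkage_groups(placements, sub)
        plan = ml.infer_merge_plan(table, placements, sub)
        merged = ml.apply_merge(split, plan)
        assert merged["1"] == seq[:half] + "N" * 1000 + seq[half:]

    def test_cm_monotone_in_physical_position(self, linkage_panel):
        from scipy import stats

        _, truth = linkage_panel
        for _, grp in truth.groupby("lg"):
            rho = stats.spearmanr(grp.cM, grp.position).statistic
            assert rho == pytest.approx(1.0)
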
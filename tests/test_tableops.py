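"""Taxonomy canonicalization and table algebra."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coremic.table import AbundanceTable, ValidationError
from coremic.tableops import (
    binarize,
    canonicalize_lineage,
    collapse_at_rank,
    collapse_by_taxonomy,
    filter_low_depth_samples,
    merge_tables,
    normalize,
)

from conftest import random_table


class TestCanonicalize:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("k__Bacteria; p__Proteobacteria", "k__Bacteria;p__Proteobacteria"),
            ("k_Bacteria;p_;c_;o_;f_;g_;s_", "k__Bacteria;p__;c__;o__;f__;g__;s__"),
            (" k__Bacteria ", "k__Bacteria"),
            ("p_Planctomycetes;c_Planctomycetia;o_B97",
             "p__Planctomycetes;c__Planctomycetia;o__B97"),
        ],
    )
    def test_canonical_form(self, raw, expected):
        assert canonicalize_lineage(raw).canonical == expected

    def test_empty_string_rejected(self):
        with pytest.raises(ValidationError):
            canonicalize_lineage("   ")

    @given(st.lists(
        st.tuples(st.sampled_from("kpcofgs"),
                  st.text(alphabet="ABCdef123", max_size=6)),
        min_size=1, max_size=7,
    ))
    @settings(max_examples=100, derandomize=True)
    def test_idempotence(self, parts):
        raw = ";".join(f"{p}_{'_' * (hash(n) % 2)}{n}" for p, n in parts)
        once = canonicalize_lineage(raw).canonical
        assert canonicalize_lineage(once).canonical == once


class TestCollapse:
    def test_identical_taxonomies_summed(self):
        df = pd.DataFrame(
            [[1, 2], [3, 4], [0, 5]],
            index=["k__B;g__L1", "k__B; g__L1", "k__B;g__L2"],
            columns=["S1", "S2"],
        )
        # duplicate index entries are only legal pre-collapse via reader suffixes
        df.index = ["k__B;g__L1", "k__B;g__L1@@1", "k__B;g__L2"]
        out = collapse_by_taxonomy(AbundanceTable(data=df))
        assert out.row_ids == ["k__B;g__L1", "k__B;g__L2"]
        assert out.data.loc["k__B;g__L1"].tolist() == [4, 6]
        assert out.data.loc["k__B;g__L2"].tolist() == [0, 5]

    def test_unique_taxonomies_unchanged(self, small_table):
        out = collapse_by_taxonomy(small_table)
        assert out.data.equals(small_table.data)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, derandomize=True)
    def test_column_sums_conserved(self, seed):
        t = random_table(np.random.default_rng(seed))
        out = collapse_by_taxonomy(t)
        assert np.allclose(out.column_sums(), t.column_sums())


class TestMerge:
    def _t(self, rows, cols, fill=1.0):
        return AbundanceTable(
            data=pd.DataFrame(fill, index=rows, columns=cols)
        )

    def test_intersection_and_column_concatenation(self):
        t1 = self._t(["k__X", "k__Y", "k__Z"], ["A", "B"])
        t2 = self._t(["k__Y", "k__Z", "k__W"], ["C"])
        m = merge_tables([t1, t2])
        assert m.row_ids == ["k__Y", "k__Z"]
        assert m.sample_ids == ["A", "B", "C"]

    def test_single_table_identity(self, small_table):
        assert merge_tables([small_table]).data.equals(small_table.data)

    def test_order_swap_preserves_cells(self):
        rng = np.random.default_rng(7)
        t1, t2 = random_table(rng), random_table(rng, n_cols=3)
        t1, t2 = collapse_by_taxonomy(t1), collapse_by_taxonomy(t2)
        t2 = t2.with_data(t2.data.rename(columns=lambda c: c + "x"))
        m12 = merge_tables([t1, t2])
        m21 = merge_tables([t2, t1])
        assert set(m12.row_ids) == set(m21.row_ids)
        assert m12.data.loc[sorted(m12.row_ids), sorted(m12.sample_ids)].equals(
            m21.data.loc[sorted(m21.row_ids), sorted(m12.sample_ids)]
        )

    def test_duplicate_sample_id_rejected(self, small_table):
        with pytest.raises(ValidationError, match="duplicate sample"):
            merge_tables([small_table, small_table])

    def test_empty_intersection_rejected(self):
        t1 = self._t(["k__X"], ["A"])
        t2 = self._t(["k__Y"], ["B"])
        with pytest.raises(ValidationError, match="no shared taxonomies"):
            merge_tables([t1, t2])


class TestDepthFilter:
    def test_case_study_threshold(self):
        # depths 48, 75, 1200, 1500 with threshold 1150 keeps two samples
        df = pd.DataFrame(
            [[48.0, 75.0, 1200.0, 1500.0]],
            index=["k__B;p__P"], columns=["a", "b", "c", "d"],
        )
        out = filter_low_depth_samples(AbundanceTable(data=df), 1150)
        assert out.sample_ids == ["c", "d"]

    def test_zero_threshold_identity(self, small_table):
        assert filter_low_depth_samples(small_table, 0).data.equals(small_table.data)

    def test_all_removed_errors(self, small_table):
        with pytest.raises(ValidationError, match="all .* removed"):
            filter_low_depth_samples(small_table, 10_000)


class TestNormalize:
    def test_total_sum(self):
        df = pd.DataFrame({"S": [2.0, 3.0, 5.0]}, index=["k__A", "k__B", "k__C"])
        out = normalize(AbundanceTable(data=df), "total_sum")
        assert out.data["S"].tolist() == [0.2, 0.3, 0.5]

    def test_total_sum_zero_column_rejected(self):
        df = pd.DataFrame({"S": [0.0, 0.0]}, index=["k__A", "k__B"])
        with pytest.raises(ValidationError, match="all-zero"):
            normalize(AbundanceTable(data=df), "total_sum")

    def test_rarefy_hits_target_depth_and_is_seeded(self):
        t = random_table(np.random.default_rng(11), n_rows=20, n_cols=5)
        depth = int(t.column_sums().min())
        r1 = normalize(t, "rarefy", depth=depth, seed=42)
        r2 = normalize(t, "rarefy", depth=depth, seed=42)
        assert (r1.column_sums() == depth).all()
        assert r1.data.equals(r2.data)

    def test_rarefy_drops_shallow_columns(self):
        df = pd.DataFrame(
            [[10.0, 1.0], [10.0, 1.0]], index=["k__A", "k__B"], columns=["deep", "shallow"]
        )
        out = normalize(AbundanceTable(data=df), "rarefy", depth=15, seed=0)
        assert out.sample_ids == ["deep"]

    def test_rarefy_requires_depth(self, small_table):
        with pytest.raises(ValidationError):
            normalize(small_table, "rarefy", depth=0)

    def test_none_identity(self, small_table):
        assert normalize(small_table, "none") is small_table


class TestRankCollapse:
    def test_genera_summed_at_phylum(self):
        df = pd.DataFrame(
            [[1.0, 2.0], [3.0, 4.0]],
            index=[
                "k__Bacteria;p__Bacteroidetes;c__C1;o__O;f__F;g__G1;s__",
                "k__Bacteria;p__Bacteroidetes;c__C2;o__O;f__F;g__G2;s__",
            ],
            columns=["S1", "S2"],
        )
        out = collapse_at_rank(AbundanceTable(data=df), "phylum")
        assert out.row_ids == ["k__Bacteria;p__Bacteroidetes"]
        assert out.data.iloc[0].tolist() == [4.0, 6.0]

    def test_species_collapse_equals_taxonomy_collapse(self):
        t = random_table(np.random.default_rng(3))
        # genus-level labels have no species rank; pad to species
        padded = t.with_data(t.data.rename(index=lambda r: r + ";s__"))
        assert collapse_at_rank(padded, "species").data.equals(
            collapse_by_taxonomy(padded).data
        )

    @given(st.integers(0, 2**31 - 1), st.sampled_from(["kingdom", "phylum", "genus"]))
    @settings(max_examples=30, derandomize=True)
    def test_column_totals_preserved(self, seed, rank):
        t = random_table(np.random.default_rng(seed))
        out = collapse_at_rank(t, rank)
        assert np.allclose(out.column_sums(), t.column_sums())

    def test_unknown_rank_rejected(self, small_table):
        with pytest.raises(ValidationError, match="unknown rank"):
            collapse_at_rank(small_table, "domain")


class TestBinarize:
    def test_zero_nonzero_rule(self):
        df = pd.DataFrame({"S1": [0.0], "S2": [1.0], "S3": [7.0]}, index=["k__A"])
        pm = binarize(AbundanceTable(data=df))
        assert pm.data.loc["k__A"].tolist() == [False, True, True]

    def test_custom_threshold(self):
        df = pd.DataFrame({"S1": [0.0], "S2": [1.0], "S3": [7.0]}, index=["k__A"])
        pm = binarize(AbundanceTable(data=df), detection_threshold=5)
        assert pm.data.loc["k__A"].tolist() == [False, False, True]

    def test_idempotent_under_unit_threshold(self, small_table):
        pm = binarize(small_table)
        as_counts = small_table.with_data(pm.data.astype(float))
        assert binarize(as_counts).data.equals(pm.data)

    def test_presence_invariant_under_total_sum(self):
        t = random_table(np.random.default_rng(5), n_rows=10)
        t = t.with_data(t.data + (t.column_sums() == 0))  # avoid all-zero columns
        pm_raw = binarize(t)
        pm_rel = binarize(normalize(t, "total_sum"), detection_threshold=1e-12)
        assert pm_raw.data.equals(pm_rel.data)

    def test_nonpositive_threshold_rejected(self, small_table):
        with pytest.raises(ValidationError):
            binarize(small_table, detection_threshold=0)
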
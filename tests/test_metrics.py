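"""Metric formulas against closed forms and brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panelfrag.fragments import MOTIFS, ConfigError, GenomicInterval
from panelfrag.metrics import (
    FeatureTable,
    LengthDistribution,
    compute_feature_tables,
    fragment_bin_proportions,
    full_gene_depth,
    impute_features,
    motif_diversity_score,
    normalized_depth,
    shannon_entropy,
    small_fragment_fraction,
    tfbs_entropy,
)
from panelfrag.regions import ATACRegionSet, TFBSCollection
from panelfrag import synthetic as syn
from conftest import make_fragments


def entropy_oracle(counts):
    """Independent plug-in entropy: explicit probability-vector evaluation."""
    n = sum(counts)
    return -sum((c / n) * math.log(c / n) for c in counts if c > 0)


class TestNormalizedDepth:
    def test_stated_formula(self):
        assert normalized_depth(4, 100, 10) == pytest.approx(0.004)

    def test_zero_count(self):
        assert normalized_depth(0, 100, 10) == 0.0

    def test_scale_invariance_in_counts(self):
        assert normalized_depth(8, 100, 20) == pytest.approx(
            normalized_depth(4, 100, 10)
        )

    def test_undefined_without_reads(self):
        with pytest.raises(ConfigError):
            normalized_depth(1, 100, 0)


class TestShannonEntropy:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({167: 10}, 0.0),
            ({167: 5, 150: 5}, math.log(2)),
            ({167: 3, 150: 1}, -(0.75 * math.log(0.75) + 0.25 * math.log(0.25))),
        ],
    )
    def test_closed_forms(self, counts, expected):
        assert shannon_entropy(LengthDistribution(counts)) == pytest.approx(expected)

    def test_empty_is_missing(self):
        assert np.isnan(shannon_entropy(LengthDistribution({})))

    @given(
        st.lists(st.integers(min_value=1, max_value=50), min_size=1, max_size=10)
    )
    @settings(max_examples=200, derandomize=True)
    def test_matches_oracle_and_bounds(self, counts):
        h = shannon_entropy(counts)
        assert h == pytest.approx(entropy_oracle(counts), abs=1e-12)
        assert -1e-12 <= h <= math.log(len(counts)) + 1e-12


class TestFragmentBins:
    def test_one_per_bin(self):
        props = fragment_bin_proportions([50, 120, 160, 210, 280, 350])
        assert props == pytest.approx([1 / 6] * 6)

    def test_mononucleosome_bin(self):
        assert fragment_bin_proportions([167, 167]) == pytest.approx(
            [0, 0, 1, 0, 0, 0]
        )

    @pytest.mark.parametrize(
        "length,bin_idx",
        [(100, 0), (101, 1), (150, 1), (151, 2), (300, 4), (301, 5)],
    )
    def test_boundaries_upper_inclusive(self, length, bin_idx):
        props = fragment_bin_proportions([length])
        assert props[bin_idx] == 1.0

    def test_sums_to_one_and_single_bin_membership(self, rng):
        for _ in range(20):
            lengths = rng.integers(20, 501, size=int(rng.integers(1, 200)))
            props = fragment_bin_proportions(lengths)
            assert props.sum() == pytest.approx(1.0)

    def test_empty_missing(self):
        assert np.isnan(fragment_bin_proportions([])).all()


class TestSmallFragments:
    def test_boundary_inclusive(self):
        assert small_fragment_fraction([100, 150, 151, 200]) == pytest.approx(0.5)
        assert small_fragment_fraction([150, 150]) == 1.0
        assert small_fragment_fraction([167]) == 0.0


class TestMDS:
    def test_uniform_is_one(self):
        assert motif_diversity_score({m: 3 for m in MOTIFS}) == pytest.approx(1.0)

    def test_single_motif_zero(self):
        assert motif_diversity_score({"ACGT": 99}) == 0.0

    def test_two_equal_motifs(self):
        assert motif_diversity_score({"AAAA": 5, "TTTT": 5}) == pytest.approx(0.125)

    def test_label_permutation_invariance(self, rng):
        counts = rng.integers(0, 30, size=256)
        perm = rng.permutation(256)
        assert motif_diversity_score(counts) == pytest.approx(
            motif_diversity_score(counts[perm])
        )

    def test_base_independence(self, rng):
        counts = rng.integers(1, 20, size=256).astype(float)
        p = counts / counts.sum()
        h2 = -(p * np.log2(p)).sum() / math.log2(256)
        assert motif_diversity_score(counts) == pytest.approx(h2)

    def test_range_and_unknown_keys(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 10, size=256)
            if counts.sum() == 0:
                continue
            assert 0.0 <= motif_diversity_score(counts) <= 1.0
        with pytest.raises(ConfigError):
            motif_diversity_score({"ACGU": 1})


class TestGeneLevelDepth:
    def test_single_exon_gene_reduces_to_exon_depth(self, toy_panel):
        sf = make_fragments("s", [("chr1", 2000, 2100)] * 3 + [("chr1", 0, 50)])
        d = full_gene_depth(sf, toy_panel, "C")
        assert d == pytest.approx(normalized_depth(3, 120, 4))

    def test_disjoint_fragments_sum(self, toy_panel):
        # gene A: exons [100,200) and [300,450); 3 + 2 disjoint fragments
        frags = [("chr1", 110, 190)] * 3 + [("chr1", 310, 430)] * 2
        frags += [("chr1", 5000, 5100)] * 95  # padding for total reads
        sf = make_fragments("s", frags)
        assert full_gene_depth(sf, toy_panel, "A") == pytest.approx(5 / 250 / 100)

    def test_spanning_fragment_counted_once(self, toy_panel):
        frags = [("chr1", 150, 350)] + [("chr1", 5000, 5100)] * 99
        sf = make_fragments("s", frags)
        assert full_gene_depth(sf, toy_panel, "A") == pytest.approx(1 / 250 / 100)
        assert full_gene_depth(sf, toy_panel, "A", count_once=False) == pytest.approx(
            2 / 250 / 100
        )


class TestPooledEntropies:
    def test_tfbs_pooling_hand_case(self):
        sf = make_fragments(
            "s", [("chr1", 100, 250), ("chr1", 120, 287), ("chr1", 500, 667)]
        )
        sites = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [100, 450],
                "end": [300, 700],
                "support": [9, 9],
            }
        )
        coll = TFBSCollection({"TFX": sites}, top_n=2)
        # site 1 captures lengths {150, 167}; site 2 captures {167}
        expected = entropy_oracle([1, 2])
        assert tfbs_entropy(sf, coll)["TFX"] == pytest.approx(expected)

    def test_disjoint_sites_missing(self):
        sf = make_fragments("s", [("chr1", 0, 100)])
        coll = TFBSCollection(
            {"T": pd.DataFrame({"chrom": ["chr1"], "start": [5000], "end": [5100],
                                "support": [1]})},
            top_n=1,
        )
        assert np.isnan(tfbs_entropy(sf, coll)["T"])

    def test_atac_covering_everything_equals_sample_entropy(self):
        sf = make_fragments("s", [("chr1", 0, 150), ("chr1", 10, 177), ("chr1", 50, 217)])
        atac = ATACRegionSet({"pan": [GenomicInterval("chr1", 0, 10_000)]})
        from panelfrag.metrics import atac_entropy

        got = atac_entropy(sf, atac)["pan"]
        assert got == pytest.approx(
            shannon_entropy(LengthDistribution.from_lengths(sf.lengths))
        )

    def test_two_toy_types_hand_computed(self):
        sf = make_fragments(
            "s",
            [("chr1", 0, 150), ("chr1", 0, 167), ("chr1", 1000, 1167),
             ("chr1", 1000, 1167)],
        )
        atac = ATACRegionSet(
            {
                "t1": [GenomicInterval("chr1", 0, 200)],
                "t2": [GenomicInterval("chr1", 900, 1200)],
            }
        )
        from panelfrag.metrics import atac_entropy

        got = atac_entropy(sf, atac)
        assert got["t1"] == pytest.approx(entropy_oracle([1, 1]))
        assert got["t2"] == pytest.approx(0.0)


@pytest.fixture(scope="module")
def cohort_tables():
    cfg = syn.SimulationConfig(seed=17, n_genes=3, exons_per_gene=(2, 2),
                               n_samples_per_phenotype=3, reads_per_sample=1500)
    panel = syn.generate_panel(cfg)
    samples, _ = syn.simulate_cohort(cfg, panel)
    tfbs = TFBSCollection(
        {"TF1": pd.DataFrame({"chrom": [cfg.chrom], "start": [1000],
                              "end": [1400], "support": [3]})},
        top_n=1,
    )
    atac = ATACRegionSet({"t1": [GenomicInterval(cfg.chrom, 0, 20_000)]})
    tables = compute_feature_tables(samples, panel, tfbs=tfbs, atac=atac)
    return cfg, panel, samples, tables


class TestFeatureAssembly:
    def test_column_counting_rules(self, cohort_tables):
        _, panel, _, tables = cohort_tables
        assert tables["depth_all_exons"].n_features == 6
        assert tables["depth_full_gene"].n_features == 3
        assert tables["fragment_bins"].n_features == 36
        assert tables["depth_E1"].n_features == 3

    def test_e1_columns_subset_of_all_exons(self, cohort_tables):
        _, _, _, tables = cohort_tables
        assert set(tables["depth_E1"].values.columns) <= set(
            tables["depth_all_exons"].values.columns
        )
        assert set(tables["entropy_E1"].values.columns) <= set(
            tables["entropy_all_exons"].values.columns
        )

    def test_combined_width_is_sum_of_parts(self, cohort_tables):
        _, _, _, tables = cohort_tables
        parts = [t.n_features for m, t in tables.items() if m != "combined"]
        assert tables["combined"].n_features == sum(parts)

    def test_conservation_exact_count_recovery(self, cohort_tables):
        """depth * bp * total_reads must recover integer assigned counts."""
        from panelfrag.fragments import overlap_assign

        _, panel, samples, tables = cohort_tables
        depth = tables["depth_all_exons"].values
        for s in samples:
            assign = overlap_assign(s.fragments, [e.interval for e in panel.exons])
            for i, e in enumerate(panel.exons):
                recovered = (
                    depth.loc[s.sample_id, f"depth@{e.label}"]
                    * e.length
                    * s.fragments.total_reads
                )
                assert recovered == pytest.approx(len(assign[i]), abs=1e-6)

    def test_invariant_to_fragment_order(self, cohort_tables, rng):
        from panelfrag.fragments import SampleFragments

        cfg, panel, samples, tables = cohort_tables
        s = samples[0]
        shuffled = SampleFragments(
            s.sample_id, s.fragments.df.sample(frac=1, random_state=7)
        )

        class Shim:
            sample_id = s.sample_id
            phenotype = s.phenotype
            fragments = shuffled

        t2 = compute_feature_tables([Shim()], panel, metrics=["depth_all_exons",
                                                              "entropy_all_exons"])
        for m in t2:
            pd.testing.assert_series_equal(
                t2[m].values.loc[s.sample_id],
                tables[m].values.loc[s.sample_id],
                check_names=False,
            )

    def test_unknown_metric_rejected(self, cohort_tables):
        cfg, panel, samples, _ = cohort_tables
        with pytest.raises(ConfigError):
            compute_feature_tables(samples, panel, metrics=["nope"])

    def test_tsv_roundtrip(self, cohort_tables, tmp_path):
        _, _, _, tables = cohort_tables
        p = tmp_path / "depth.tsv"
        tables["depth_all_exons"].write_tsv(p)
        back = FeatureTable.read_tsv(p)
        assert back.metric_name == "depth_all_exons"
        pd.testing.assert_frame_equal(back.values, tables["depth_all_exons"].values)


class TestImputation:
    def test_depth_imputes_zero_entropy_imputes_median(self):
        vals = pd.DataFrame({"f": [1.0, np.nan, 3.0]})
        filled, _ = impute_features(vals, "depth_all_exons")
        assert filled["f"].tolist() == [1.0, 0.0, 3.0]
        filled, med = impute_features(vals, "entropy_all_exons")
        assert filled["f"].tolist() == [1.0, 2.0, 3.0]
        assert med["f"] == 2.0

    def test_training_medians_applied_to_heldout(self):
        train = pd.DataFrame({"f": [1.0, 5.0]})
        _, med = impute_features(train, "mds_all_exons")
        test = pd.DataFrame({"f": [np.nan]})
        filled, _ = impute_features(test, "mds_all_exons", medians=med)
        assert filled["f"].iloc[0] == 3.0
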
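"""ASV-table operations: sets, abundance, alpha diversity, PCoA, differential."""

import numpy as np
import pandas as pd
import pytest

from peckorder.microbiome import (
    AsvTable,
    alpha,
    alpha_group_compare,
    alpha_table,
    asv_sets,
    bray_curtis_pcoa,
    differential_abundance,
    pcoa_from_distances,
    rarefy,
    read_asv_table,
    relative_abundance,
    write_asv_table,
)
from peckorder.synth import SynthConfig, generate_asv_table

LIN = "k__Bacteria; p__{p}; c__C; o__O; f__{f}; g__{g}; s__unclassified"


@pytest.fixture
def toy_table():
    counts = pd.DataFrame(
        {"A1": [10, 5, 0, 8], "A2": [0, 0, 3, 2], "A3": [50, 40, 30, 20],
         "A4": [1, 0, 0, 0], "A5": [0, 2, 0, 0]},
        index=["s1", "s2", "s3", "s4"])
    tax = pd.Series({
        "A1": LIN.format(p="Firmicutes", f="Lachnospiraceae", g="Anaerostipes"),
        "A2": LIN.format(p="Firmicutes", f="Oscillospiraceae", g="Subdoligranulum"),
        "A3": LIN.format(p="Bacteroidota", f="Bacteroidaceae", g="Bacteroides"),
        "A4": LIN.format(p="Bacteroidota", f="Barnesiellaceae", g="unclassified"),
        "A5": LIN.format(p="Deferribacterota", f="Deferribacteraceae", g="Mucispirillum"),
    })
    groups = pd.Series({"s1": "HR", "s2": "HR", "s3": "LR", "s4": "LR"})
    return AsvTable(counts=counts, taxonomy=tax, groups=groups)


class TestIO:
    def test_round_trip_identity(self, toy_table, tmp_path):
        p = tmp_path / "asv.tsv"
        write_asv_table(toy_table, p)
        back = read_asv_table(p, groups=toy_table.groups)
        pd.testing.assert_frame_equal(back.counts, toy_table.counts)
        pd.testing.assert_series_equal(back.taxonomy, toy_table.taxonomy,
                                       check_names=False)

    def test_missing_taxonomy_rejected(self, toy_table, tmp_path):
        p = tmp_path / "asv.tsv"
        out = toy_table.counts.T
        out.to_csv(p, sep="\t")
        with pytest.raises(ValueError, match="taxonomy"):
            read_asv_table(p)

    def test_bad_count_named_by_cell(self, toy_table, tmp_path):
        p = tmp_path / "asv.tsv"
        out = toy_table.counts.T.astype(object)
        out.loc["A2", "s3"] = 1.5
        out["taxonomy"] = toy_table.taxonomy
        out.to_csv(p, sep="\t")
        with pytest.raises(ValueError, match="A2.*s3"):
            read_asv_table(p)

    def test_negative_count_rejected(self, toy_table):
        bad = toy_table.counts.copy()
        bad.loc["s1", "A1"] = -1
        with pytest.raises(ValueError, match="negative count"):
            AsvTable(bad, toy_table.taxonomy)


class TestAsvSets:
    def test_toy_exclusives(self, toy_table):
        out = asv_sets(toy_table)
        # A4 (s1) and A5 (s2) only in HR samples; A2 only in LR samples
        assert out["exclusive_HR"] == 2
        assert out["exclusive_LR"] == 1
        assert out["shared"] == 2
        assert out["total"] == 5

    def test_planted_exclusive_recovery(self, hrlr_groups):
        rng = np.random.default_rng(0)
        n_asv = 60
        counts = rng.poisson(20, size=(16, n_asv))
        counts[:, :40] += 1  # shared block present everywhere
        hr_rows = np.arange(8)
        lr_rows = np.arange(8, 16)
        counts[:, 40:50][lr_rows] = 0   # 10 ASVs exclusive to HR
        counts[:, 40:50][hr_rows] += 1
        counts[:, 50:57][hr_rows] = 0   # 7 ASVs exclusive to LR
        counts[:, 50:57][lr_rows] += 1
        counts[:, 57:] = 0              # absent everywhere
        asv_ids = [f"A{i}" for i in range(n_asv)]
        tax = pd.Series({a: LIN.format(p="Firmicutes", f="F", g="G") for a in asv_ids})
        t = AsvTable(pd.DataFrame(counts, index=hrlr_groups.index, columns=asv_ids),
                     tax, hrlr_groups)
        out = asv_sets(t)
        assert out["exclusive_HR"] == 10
        assert out["exclusive_LR"] == 7
        assert out["exclusive_HR"] + out["exclusive_LR"] + out["shared"] == out["total"]

    def test_partition_identity_on_synthetic(self, hrlr_groups):
        t = generate_asv_table(hrlr_groups, SynthConfig(seed=2, n_taxa=80,
                                                        depth_mean=2000))
        out = asv_sets(t)
        assert out["exclusive_HR"] + out["exclusive_LR"] + out["shared"] == out["total"]

    def test_empty_group_rejected(self, toy_table):
        t = AsvTable(toy_table.counts, toy_table.taxonomy,
                     pd.Series({"s1": "HR", "s2": "HR", "s3": "HR", "s4": "HR"}))
        with pytest.raises(ValueError):
            asv_sets(t)


class TestRelativeAbundance:
    def test_phylum_aggregation_and_normalization(self, toy_table):
        props = relative_abundance(toy_table, "phylum")
        assert props.sum(axis=1).to_numpy() == pytest.approx(np.ones(4), abs=1e-12)
        # s1: Firmicutes 10, Bacteroidota 51 of 61
        assert props.loc["s1", "Firmicutes"] == pytest.approx(10 / 61)
        assert props.loc["s1", "Bacteroidota"] == pytest.approx(51 / 61)

    def test_sixty_forty_split(self):
        counts = pd.DataFrame({"A1": [60], "A2": [40]}, index=["s1"])
        tax = pd.Series({"A1": LIN.format(p="Firmicutes", f="F", g="G1"),
                         "A2": LIN.format(p="Bacteroidota", f="F2", g="G2")})
        props = relative_abundance(AsvTable(counts, tax), "phylum")
        assert props.loc["s1", "Firmicutes"] == pytest.approx(0.6)
        assert props.loc["s1", "Bacteroidota"] == pytest.approx(0.4)

    def test_unclassified_genus_gets_parent_label(self, toy_table):
        props = relative_abundance(toy_table, "genus")
        assert "Barnesiellaceae unclassified" in props.columns

    def test_columns_ordered_by_mean_abundance(self, toy_table):
        props = relative_abundance(toy_table, "genus")
        means = props.mean(axis=0)
        assert list(means.index) == list(means.sort_values(ascending=False).index)

    def test_zero_depth_sample_excluded(self, toy_table):
        counts = toy_table.counts.copy()
        counts.loc["s3"] = 0
        props = relative_abundance(AsvTable(counts, toy_table.taxonomy), "phylum")
        assert "s3" not in props.index


class TestAlpha:
    def test_uniform_closed_form(self):
        a = alpha([1, 1, 1, 1])
        assert a.observed == 4
        assert a.shannon == pytest.approx(2.0)
        assert a.simpson == pytest.approx(0.75)
        assert a.pielou == pytest.approx(1.0)

    def test_chao1_without_singletons(self):
        assert alpha([2, 2, 2, 2]).chao1 == 4.0

    def test_hand_computed_mixture(self):
        a = alpha([50, 25, 25])
        assert a.shannon == pytest.approx(1.5)
        assert a.simpson == pytest.approx(0.625)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            alpha([0, 0, 0])

    def test_identities_on_random_samples(self):
        rng = np.random.default_rng(12)
        for _ in range(1000):
            n = rng.integers(2, 60)
            counts = rng.poisson(rng.uniform(0.5, 20), n)
            if counts.sum() == 0 or (counts > 0).sum() < 2:
                continue
            a = alpha(counts)
            assert a.chao1 >= a.observed
            assert 0 <= a.pielou <= 1
            assert a.pielou * np.log2(a.observed) == pytest.approx(a.shannon, abs=1e-12)
            assert a.shannon <= np.log2(a.observed) + 1e-12

    def test_matches_skbio_reference(self):
        from skbio.diversity import alpha as ska

        rng = np.random.default_rng(5)
        for _ in range(25):
            counts = rng.poisson(3, 40)
            counts[0] += 1  # nonzero
            a = alpha(counts)
            assert a.shannon == pytest.approx(ska.shannon(counts, base=2), abs=1e-10)
            assert a.simpson == pytest.approx(ska.simpson(counts), abs=1e-10)
            assert a.chao1 == pytest.approx(ska.chao1(counts, bias_corrected=True),
                                            abs=1e-10)
            if a.observed > 1:
                assert a.pielou == pytest.approx(ska.pielou_e(counts), abs=1e-10)


class TestAlphaGroupCompare:
    def test_identical_groups_p_one(self, hrlr_groups):
        row = np.array([5, 5, 4, 3, 2, 1, 1, 1, 0, 0])
        counts = pd.DataFrame([row] * 16, index=hrlr_groups.index,
                              columns=[f"A{i}" for i in range(10)])
        tax = pd.Series({f"A{i}": LIN.format(p="Firmicutes", f="F", g="G")
                         for i in range(10)})
        out = alpha_group_compare(AsvTable(counts, tax, hrlr_groups))
        assert (out["p"] == 1.0).all()

    def test_table_shape(self, hrlr_groups):
        t = generate_asv_table(hrlr_groups, SynthConfig(seed=3, n_taxa=60,
                                                        depth_mean=2000))
        out = alpha_group_compare(t)
        assert list(out.index) == ["observed", "shannon", "simpson", "chao1", "pielou"]
        assert {"mean_HR", "sd_HR", "mean_LR", "sem", "t", "p"} <= set(out.columns)


class TestPcoa:
    def test_identical_samples_zero_distance(self, hrlr_groups):
        counts = pd.DataFrame([[5, 5, 5]] * 3, index=["s1", "s2", "s3"],
                              columns=["A1", "A2", "A3"])
        tax = pd.Series({a: LIN.format(p="P", f="F", g="G") for a in counts.columns})
        res = bray_curtis_pcoa(AsvTable(counts, tax))
        assert res.distances.to_numpy() == pytest.approx(np.zeros((3, 3)))

    def test_distance_properties_and_disjoint_samples(self):
        counts = pd.DataFrame({"A1": [10, 0, 5], "A2": [0, 10, 5]},
                              index=["s1", "s2", "s3"])
        tax = pd.Series({"A1": LIN.format(p="P", f="F", g="G1"),
                         "A2": LIN.format(p="P", f="F", g="G2")})
        res = bray_curtis_pcoa(AsvTable(counts, tax))
        d = res.distances.to_numpy()
        assert d == pytest.approx(d.T)
        assert np.diag(d) == pytest.approx(np.zeros(3))
        assert ((d >= 0) & (d <= 1)).all()
        assert res.distances.loc["s1", "s2"] == pytest.approx(1.0)

    def test_embedding_preserves_distances_when_euclidean(self):
        # three points whose BC distances admit an exact Euclidean embedding
        counts = pd.DataFrame({"A1": [10, 0, 5], "A2": [0, 10, 5]},
                              index=["s1", "s2", "s3"])
        tax = pd.Series({"A1": LIN.format(p="P", f="F", g="G1"),
                         "A2": LIN.format(p="P", f="F", g="G2")})
        res = bray_curtis_pcoa(AsvTable(counts, tax))
        if (res.eigvals >= -1e-9).all():
            coords = res.coordinates.to_numpy()
            for i in range(3):
                for j in range(3):
                    emb = np.linalg.norm(coords[i] - coords[j])
                    assert emb == pytest.approx(res.distances.iloc[i, j], abs=1e-9)

    def test_negative_eigenvalues_reported(self):
        # triangle-violating dissimilarity: classical PCoA must surface the
        # negative eigenvalue instead of clamping it
        d = pd.DataFrame([[0, 5, 1], [5, 0, 1], [1, 1, 0]],
                         index=list("abc"), columns=list("abc"), dtype=float)
        res = pcoa_from_distances(d)
        assert res.eigvals.min() == pytest.approx(-3.5)
        assert res.eigvals.max() == pytest.approx(12.5)

    def test_axis_sign_deterministic(self, hrlr_groups):
        t = generate_asv_table(hrlr_groups, SynthConfig(seed=1, n_taxa=40,
                                                        depth_mean=2000))
        c1 = bray_curtis_pcoa(t).coordinates
        c2 = bray_curtis_pcoa(t).coordinates
        pd.testing.assert_frame_equal(c1, c2)
        for col in c1.columns:
            assert c1[col].abs().max() == c1[col].max() or \
                c1.loc[c1[col].abs().idxmax(), col] > 0

    def test_too_few_samples_rejected(self, toy_table):
        with pytest.raises(ValueError, match="3 samples"):
            bray_curtis_pcoa(toy_table.subset_samples(["s1", "s2"]))


class TestDifferentialAbundance:
    def test_identical_compositions_unstarred(self, hrlr_groups):
        props = pd.DataFrame({"T1": [0.5] * 16, "T2": [0.5] * 16},
                             index=hrlr_groups.index)
        out = differential_abundance(props, hrlr_groups)
        assert (out["stars"] == "").all()

    def test_planted_effect_power(self, hrlr_groups):
        detected = 0
        for seed in range(50):
            cfg = SynthConfig(seed=seed, effect_taxa={"Anaerostipes": 1.0},
                              hr_zero_fraction=0.0, depth_mean=50000)
            t = generate_asv_table(hrlr_groups, cfg)
            out = differential_abundance(relative_abundance(t, "genus"),
                                         hrlr_groups)
            detected += out.loc["Anaerostipes", "p"] < 0.05
        assert detected >= 40  # >= 80% of 50 seeds

    def test_direction_reflects_mean_difference(self, hrlr_groups):
        up = np.r_[np.full(8, 0.8), np.full(8, 0.2)]
        props = pd.DataFrame({"T1": up, "T2": 1 - up}, index=hrlr_groups.index)
        out = differential_abundance(props, hrlr_groups)
        assert out.loc["T1", "direction"] == "HR"
        assert out.loc["T2", "direction"] == "LR"

    def test_absent_taxon_skipped(self, hrlr_groups):
        props = pd.DataFrame({"T1": np.linspace(0.2, 0.8, 16), "T0": 0.0},
                             index=hrlr_groups.index)
        out = differential_abundance(props, hrlr_groups)
        assert "T0" not in out.index

    def test_bh_correction_monotone(self, hrlr_groups):
        rng = np.random.default_rng(4)
        props = pd.DataFrame(rng.dirichlet(np.ones(6), 16),
                             columns=[f"T{i}" for i in range(6)],
                             index=hrlr_groups.index)
        out = differential_abundance(props, hrlr_groups, bh_correct=True)
        assert (out["p_adj"] >= out["p"] - 1e-12).all()


class TestRarefy:
    def test_equal_depths_and_identity_invariants(self, hrlr_groups):
        t = generate_asv_table(hrlr_groups, SynthConfig(seed=6, n_taxa=50,
                                                        depth_mean=3000))
        r = rarefy(t, rng=np.random.default_rng(0))
        depths = r.counts.sum(axis=1)
        assert depths.nunique() == 1
        assert (r.counts.to_numpy() <= t.counts.to_numpy()).all()
        at, ar = alpha_table(t), alpha_table(r)
        assert (ar["observed"] <= at["observed"]).all()
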
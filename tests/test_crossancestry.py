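"""Locus overlap set algebra, multi-trait signal similarity, downsampling."""

import numpy as np
import pandas as pd
import pytest

from omnigwas import bin_loci, downsample_specificity, signal_similarity
from omnigwas.containers import ZPanel
from omnigwas.crossancestry import bin_of
from omnigwas.nullcov import NullCovariance


def assoc_frame(positions, new=None, chrom="1"):
    df = pd.DataFrame({"chrom": [chrom] * len(positions), "pos": positions})
    if new is not None:
        df["new"] = new
    return df


class TestBinLoci:
    def test_single_ancestry_degenerates_to_bin_count(self):
        table = bin_loci({"EUR": assoc_frame([100, 200, 2_000_000])})
        assert table.union_size == 2
        assert table.table["count"].sum() == 2

    def test_identical_sets_all_shared(self):
        a = assoc_frame([100, 2_000_000])
        table = bin_loci({"A": a, "B": a.copy()})
        t = table.table
        pair = t[(t["A"]) & (t["B"])]
        assert pair["count"].iloc[0] == 2
        exclusive = t[(t["A"]) ^ (t["B"])]
        assert (exclusive["count"] == 0).all()

    def test_three_ancestry_counts_match_enumeration(self):
        # bins: A={0,1,2}, B={1,2,3}, C={2,4}
        a = assoc_frame([500, 1_000_500, 2_000_500])
        b = assoc_frame([1_000_600, 2_000_600, 3_000_500])
        c = assoc_frame([2_000_700, 4_000_500])
        table = bin_loci({"A": a, "B": b, "C": c}).table

        def count(mask):
            row = table
            for anc, val in mask.items():
                row = row[row[anc] == val]
            return row["count"].iloc[0]

        assert count({"A": True, "B": False, "C": False}) == 1   # bin 0
        assert count({"A": True, "B": True, "C": False}) == 1    # bin 1
        assert count({"A": True, "B": True, "C": True}) == 1     # bin 2
        assert count({"A": False, "B": True, "C": False}) == 1   # bin 3
        assert count({"A": False, "B": False, "C": True}) == 1   # bin 4

    def test_exclusive_counts_sum_to_union(self):
        rng = np.random.default_rng(0)
        tables = {
            anc: assoc_frame(rng.integers(1, 20_000_000, size=15))
            for anc in ("A", "B", "C")
        }
        overlap = bin_loci(tables)
        assert overlap.table["count"].sum() == overlap.union_size

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        frames = {anc: assoc_frame(rng.integers(1, 10_000_000, size=10))
                  for anc in ("A", "B", "C")}
        t1 = bin_loci(frames).table
        t2 = bin_loci(dict(reversed(list(frames.items())))).table
        merged = t1.merge(t2, on=["A", "B", "C"], suffixes=("_1", "_2"))
        assert (merged["count_1"] == merged["count_2"]).all()

    def test_new_flag_propagates(self):
        a = assoc_frame([100], new=[True])
        b = assoc_frame([5_000_000], new=[False])
        table = bin_loci({"A": a, "B": b}).table
        only_a = table[(table["A"]) & (~table["B"])]
        only_b = table[(~table["A"]) & (table["B"])]
        assert bool(only_a["has_new"].iloc[0])
        assert not bool(only_b["has_new"].iloc[0])


def make_panel(z, traits, positions=None):
    n = z.shape[0]
    positions = positions if positions is not None else np.arange(1, n + 1) * 100
    snps = pd.DataFrame({"chrom": "1", "pos": positions, "ref": "A", "alt": "G"},
                        index=[f"rs{i}" for i in range(n)])
    return ZPanel(snps=snps, z=z, traits=traits,
                  n_per_trait=np.full(len(traits), 1e4),
                  mask=np.isfinite(z))


def leads_for(panel, rows):
    return pd.DataFrame({
        "rsid": [panel.snps.index[i] for i in rows],
        "chrom": [panel.snps["chrom"].iloc[i] for i in rows],
        "pos": [panel.snps["pos"].iloc[i] for i in rows],
        "log10p_joint": [10.0] * len(rows),
    })


class TestSignalSimilarity:
    traits = ["t1", "t2", "t3", "t4"]

    def test_identical_vectors_score_one(self):
        z = np.array([[1.0, 2.0, -1.0, 0.5]])
        pa = make_panel(z, self.traits)
        pb = make_panel(z.copy(), self.traits)
        out = signal_similarity(pa, pb, leads_for(pa, [0]), leads_for(pb, [0]))
        assert out["r2"].iloc[0] == pytest.approx(1.0)
        assert out["same_snp"].iloc[0]

    def test_global_sign_flip_still_scores_one(self):
        z = np.array([[1.0, 2.0, -1.0, 0.5]])
        pa = make_panel(z, self.traits)
        pb = make_panel(-z, self.traits)
        out = signal_similarity(pa, pb, leads_for(pa, [0]), leads_for(pb, [0]))
        assert out["r2"].iloc[0] == pytest.approx(1.0)

    def test_fewer_than_three_shared_traits_rejected(self):
        z = np.ones((1, 2))
        pa = make_panel(z, ["t1", "t2"])
        pb = make_panel(z, ["t2", "t3"])
        with pytest.raises(ValueError, match="shared traits"):
            signal_similarity(pa, pb, leads_for(pa, [0]), leads_for(pb, [0]))

    def test_shared_traits_only_in_correlation(self):
        # ancestry B lacks t4; r2 computed over t1-t3
        za = np.array([[1.0, 2.0, 3.0, 9.0]])
        zb = np.array([[1.0, 2.0, 3.0]])
        pa = make_panel(za, self.traits)
        pb = make_panel(zb, ["t1", "t2", "t3"])
        out = signal_similarity(pa, pb, leads_for(pa, [0]), leads_for(pb, [0]))
        assert out["r2"].iloc[0] == pytest.approx(1.0)
        assert out["n_traits"].iloc[0] == 3

    def test_median_r2_tracks_effect_sharing(self):
        # 100 loci, shared 8-trait effect vectors plus noise, two ancestries
        rng = np.random.default_rng(7)
        k, n_loci = 8, 100
        shared = rng.normal(0, 4.0, size=(n_loci, k))
        za = shared + rng.standard_normal((n_loci, k))
        zb = shared + rng.standard_normal((n_loci, k))
        positions = np.arange(n_loci) * 1_000_000 + 500  # one locus per bin
        traits = [f"t{i}" for i in range(k)]
        pa = make_panel(za, traits, positions)
        pb = make_panel(zb, traits, positions)
        rows = list(range(n_loci))
        out = signal_similarity(pa, pb, leads_for(pa, rows), leads_for(pb, rows))
        # independent oracle: direct per-locus correlations
        oracle = np.median([
            np.corrcoef(za[i], zb[i])[0, 1] ** 2 for i in range(n_loci)
        ])
        assert out["r2"].median() == pytest.approx(oracle, abs=0.02)
        assert out["r2"].median() > 0.8

    def test_divergence_degrades_similarity(self):
        rng = np.random.default_rng(8)
        k, n_loci = 8, 60
        shared = rng.normal(0, 4.0, size=(n_loci, k))
        za = shared + rng.standard_normal((n_loci, k))
        zb_close = shared + rng.standard_normal((n_loci, k))
        zb_far = shared + 4.0 * rng.standard_normal((n_loci, k))
        positions = np.arange(n_loci) * 1_000_000 + 500
        traits = [f"t{i}" for i in range(k)]
        pa = make_panel(za, traits, positions)
        rows = list(range(n_loci))
        med_close = signal_similarity(pa, make_panel(zb_close, traits, positions),
                                      leads_for(pa, rows),
                                      leads_for(pa, rows))["r2"].median()
        med_far = signal_similarity(pa, make_panel(zb_far, traits, positions),
                                    leads_for(pa, rows),
                                    leads_for(pa, rows))["r2"].median()
        assert med_close > med_far


class TestDownsampleSpecificity:
    def setup_panel(self):
        # three strong leads in distinct bins; one bin shared with ancestry B
        z = np.full((3, 3), 8.0)
        positions = np.array([500, 1_000_500, 2_000_500])
        panel = make_panel(z, ["t1", "t2", "t3"], positions)
        leads = leads_for(panel, [0, 1, 2])
        omega = NullCovariance(omega=np.eye(3), traits=["t1", "t2", "t3"])
        other = {("1", 0)}  # ancestry B detects the first bin
        return panel, leads, omega, other

    def test_full_sample_gives_observed_specificity(self):
        panel, leads, omega, other = self.setup_panel()
        curve = downsample_specificity(leads, panel, omega, other,
                                       fractions=np.array([1.0]))
        assert curve["specificity"].iloc[0] == pytest.approx(2.0 / 3.0)

    def test_zero_fraction_gives_zero(self):
        panel, leads, omega, other = self.setup_panel()
        curve = downsample_specificity(leads, panel, omega, other,
                                       fractions=np.array([0.0]))
        assert curve["specificity"].iloc[0] == 0.0
        assert curve["n_detected"].iloc[0] == 0

    def test_detection_monotone_in_fraction(self):
        panel, leads, omega, other = self.setup_panel()
        curve = downsample_specificity(leads, panel, omega, other,
                                       fractions=np.arange(0, 1.01, 0.1))
        assert (np.diff(curve["n_detected"]) >= 0).all()

    def test_matched_sample_size_removes_specificity(self):
        # equal true effects: at the fraction matching ancestry B's power,
        # every surviving EUR bin is one B also detects
        z = np.full((2, 3), 8.0)
        positions = np.array([500, 1_000_500])
        panel = make_panel(z, ["t1", "t2", "t3"], positions)
        leads = leads_for(panel, [0, 1])
        omega = NullCovariance(omega=np.eye(3), traits=["t1", "t2", "t3"])
        other = {("1", 0), ("1", 1)}
        curve = downsample_specificity(leads, panel, omega, other,
                                       fractions=np.arange(0, 1.01, 0.25))
        assert (curve["specificity"] == 0.0).all()


class TestBinOf:
    def test_fixed_origin_bins(self):
        bins = bin_of(["1", "1", "2"], [1, 1_000_000, 1_000_001])
        assert bins == [("1", 0), ("1", 0), ("2", 1)]
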
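"""Filter arithmetic against brute-force oracles, boundary semantics, VCF I/O,
idempotence, and provenance-log reconciliation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from landgea import variant_io as vio
from landgea.errors import (
    ConfigurationError,
    DegenerateDataError,
    PreconditionError,
)
from conftest import make_gm

NA = np.nan


class TestVcfIO:
    def test_gt_encoding_round_trip(self, tmp_path):
        gm = make_gm([[0, 1, 2, NA], [2, NA, 1, 0]])
        path = tmp_path / "toy.vcf"
        vio.write_vcf(gm, path)
        back = vio.read_vcf(path)
        pd.testing.assert_frame_equal(
            gm.dosage_frame().fillna(-9), back.dosage_frame().fillna(-9)
        )
        assert (back.loci["variant_class"] == "SNP").all()

    def test_sv_support_field_round_trip(self, tmp_path):
        gm = make_gm([[1, 2], [0, NA]], variant_class="DEL",
                     support=[[5, 2], [7, NA]])
        gm.loci["alt"] = "<DEL>"
        path = tmp_path / "sv.vcf"
        vio.write_vcf(gm, path, support_field="SR")
        back = vio.read_vcf(path, support_field="SR")
        assert back.loci["variant_class"].eq("DEL").all()
        np.testing.assert_allclose(
            np.nan_to_num(back.support, nan=-1), [[5, 2], [7, -1]]
        )


class TestFilterSites:
    def test_missingness_boundary_is_strict(self):
        # 10 individuals: 3 missing = 30% -> removed; 2 missing -> retained
        col_30 = [NA, NA, NA] + [1] * 7
        col_20 = [NA, NA] + [1] * 8
        gm = make_gm(np.column_stack([col_30, col_20]))
        out = vio.filter_sites(gm, biallelic_only=False, max_site_missing=0.30)
        assert out.locus_ids.tolist() == ["L001"]

    def test_complete_locus_retained(self):
        gm = make_gm([[0, 1], [1, 2]])
        out = vio.filter_sites(gm)
        assert out.n_loci == 2

    def test_multiallelic_and_indel_dropped_when_flagged(self):
        gm = make_gm(np.zeros((3, 3)))
        gm.loci.loc[0, "multiallelic"] = True
        gm.loci.loc[1, "variant_class"] = "INDEL"
        assert vio.filter_sites(gm, biallelic_only=True).n_loci == 1
        assert vio.filter_sites(gm, biallelic_only=False).n_loci == 3

    def test_matches_brute_force_count(self):
        rng = np.random.default_rng(0)
        d = rng.choice([0.0, 1.0, 2.0, NA], p=[0.3, 0.3, 0.2, 0.2], size=(20, 10))
        gm = make_gm(d)
        out = vio.filter_sites(gm, biallelic_only=False, max_site_missing=0.30)
        expected = [
            f"L{j:03d}" for j in range(10)
            if np.isnan(d[:, j]).mean() < 0.30
        ]
        assert out.locus_ids.tolist() == expected


class TestFilterIndividuals:
    def test_boundary_strictly_greater(self):
        # 10 loci: 3 missing = 30% -> retained (rule removes only > 30%)
        d = np.ones((2, 10))
        d[0, :3] = NA
        d[1, :4] = NA  # 40% -> removed
        out = vio.filter_individuals(make_gm(d), 0.30)
        assert out.individuals.index.tolist() == ["ind00"]

    def test_matches_hand_enumeration(self):
        rng = np.random.default_rng(1)
        d = rng.choice([1.0, NA], p=[0.7, 0.3], size=(5, 10))
        out = vio.filter_individuals(make_gm(d), 0.30)
        keep = [f"ind{i:02d}" for i in range(5) if np.isnan(d[i]).mean() <= 0.30]
        assert out.individuals.index.tolist() == keep


class TestRecodeLowSupport:
    def test_boundary_inclusive_at_min_support(self):
        gm = make_gm([[1, 1, 1]], support=[[2, 3, 4]], variant_class="DUP")
        out = vio.recode_low_support(gm, min_support=3)
        np.testing.assert_array_equal(
            np.nan_to_num(out.dosage, nan=-9), [[-9, 1, 1]]
        )

    def test_all_supported_is_identity(self):
        gm = make_gm([[1, 2], [0, 1]], support=[[3, 9], [4, 3]])
        out = vio.recode_low_support(gm)
        np.testing.assert_array_equal(out.dosage, gm.dosage)

    def test_missing_support_matrix_rejected(self):
        with pytest.raises(ConfigurationError):
            vio.recode_low_support(make_gm([[1]]))


def _brute_force_prune(gm, r2_threshold, window_bp):
    """O(n²) oracle with the same window membership and greedy order."""
    loci = gm.loci
    removed = set()
    df = pd.DataFrame(gm.dosage)
    for chrom, grp in loci.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        step = max(window_bp // 2, 1)
        starts = range(int(pos.min()), int(pos.max()) + 1, step)
        share = {
            (a, b)
            for s in starts
            for ai, a in enumerate(idx)
            if s <= pos[ai] < s + window_bp
            for b in idx[ai + 1:][(pos[ai + 1:] >= s) & (pos[ai + 1:] < s + window_bp)]
        }
        for ai, a in enumerate(idx):
            if a in removed:
                continue
            for b in idx[ai + 1:]:
                if b in removed or (a, b) not in share:
                    continue
                r = df[a].corr(df[b], min_periods=2)
                if np.isfinite(r) and r * r > r2_threshold:
                    removed.add(b)
    return [l for i, l in enumerate(loci["locus_id"]) if i not in removed]


class TestLdPrune:
    def test_identical_loci_keep_exactly_one(self):
        col = np.array([0, 1, 2, 1, 0, 2, 1, 1], float)
        gm = make_gm(np.column_stack([col, col]), positions=[1000, 2000])
        out = vio.ld_prune(gm)
        assert out.locus_ids.tolist() == ["L000"]

    def test_below_threshold_pair_retained(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=200).round().clip(0, 2)
        b = a.copy()
        flip = rng.random(200) < 0.45
        b[flip] = rng.integers(0, 3, flip.sum())
        r2 = np.corrcoef(a, b)[0, 1] ** 2
        assert r2 < 0.5  # construction sanity
        gm = make_gm(np.column_stack([a, b]), positions=[1000, 2000])
        assert vio.ld_prune(gm, r2_threshold=0.5).n_loci == 2

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        n, m = 40, 50
        base = rng.integers(0, 3, (n, 8)).astype(float)
        d = base[:, rng.integers(0, 8, m)]  # heavy correlation blocks
        noise = rng.random((n, m)) < 0.25
        d[noise] = rng.integers(0, 3, noise.sum())
        pos = np.sort(rng.choice(np.arange(1, 2_000_000), m, replace=False))
        gm = make_gm(d, positions=pos)
        out = vio.ld_prune(gm, r2_threshold=0.5, window_bp=200_000)
        assert out.locus_ids.tolist() == _brute_force_prune(gm, 0.5, 200_000)

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        d = rng.integers(0, 3, (30, 20)).astype(float)
        d[:, 1] = d[:, 0]
        gm = make_gm(d, positions=np.arange(1, 21) * 1000)
        once = vio.ld_prune(gm)
        twice = vio.ld_prune(once)
        assert once.locus_ids.tolist() == twice.locus_ids.tolist()

    def test_unsorted_loci_rejected(self):
        gm = make_gm([[0, 1], [1, 2]], positions=[5000, 1000])
        with pytest.raises(PreconditionError):
            vio.ld_prune(gm)


class TestExcludeRegions:
    def test_bed_half_open_boundaries(self, tmp_path):
        bed = tmp_path / "r.bed"
        bed.write_text("chr1\t99\t200\n")
        gm = make_gm([[0, 0, 0]], positions=[99, 100, 200])
        out = vio.exclude_regions(gm, bed)
        # BED (99,200]: pos 100 and 200 inside, pos 99 outside
        assert out.loci["pos"].tolist() == [99]

    def test_matches_interval_oracle(self, tmp_path):
        rng = np.random.default_rng(8)
        pos = np.sort(rng.choice(np.arange(1, 10_000), 60, replace=False))
        gm = make_gm(np.zeros((2, 60)), positions=pos)
        iv = np.sort(rng.choice(np.arange(0, 10_000), (15, 2)).astype(int), axis=1)
        iv = iv[iv[:, 0] < iv[:, 1]]
        bed = tmp_path / "rand.bed"
        bed.write_text("".join(f"chr1\t{s}\t{e}\n" for s, e in iv))
        out = vio.exclude_regions(gm, bed)
        keep = [p for p in pos if not any(s < p <= e for s, e in iv)]
        assert out.loci["pos"].tolist() == keep


class TestImputeMode:
    def test_mode_and_smallest_dosage_tie_break(self):
        gm = make_gm(np.array([[0, 0], [0, 0], [1, 1], [NA, 1], [2, NA]]))
        out = vio.impute_mode(gm)
        # L000: mode 0; L001: tie 0x2 vs 1x2 -> smallest dosage 0
        assert out.dosage[3, 0] == 0 and out.dosage[4, 1] == 0

    def test_no_missing_left_and_observed_unchanged(self):
        rng = np.random.default_rng(9)
        d = rng.choice([0.0, 1.0, 2.0, NA], p=[0.3, 0.3, 0.2, 0.2], size=(15, 8))
        d[0] = 1.0  # guarantee no all-missing locus
        gm = make_gm(d)
        out = vio.impute_mode(gm)
        assert not np.isnan(out.dosage).any()
        obs = ~np.isnan(d)
        np.testing.assert_array_equal(out.dosage[obs], d[obs])

    def test_all_missing_locus_rejected(self):
        with pytest.raises(DegenerateDataError):
            vio.impute_mode(make_gm([[NA, 1], [NA, 0]]))


class TestAlleleFrequencies:
    def test_hand_arithmetic(self):
        gm = make_gm([[0], [1], [2]])
        f = vio.allele_frequencies(gm, {f"ind{i:02d}": "g" for i in range(3)})
        assert f.freq.loc["g"].iloc[0] == pytest.approx(0.5)
        assert f.n_alleles.loc["g"].iloc[0] == 6

    def test_all_missing_group_cell_is_nan(self):
        gm = make_gm([[NA], [1]])
        grouping = {"ind00": "a", "ind01": "b"}
        f = vio.allele_frequencies(gm, grouping)
        assert np.isnan(f.freq.loc["a"].iloc[0])
        assert f.freq.loc["b"].iloc[0] == 0.5

    def test_matches_recount_on_fixture(self, small_panel):
        gm, _ = small_panel
        pops = gm.individuals["population"]
        f = vio.allele_frequencies(gm, pops)
        rng = np.random.default_rng(10)
        for j in rng.choice(gm.n_loci, 15, replace=False):
            for g in f.freq.index[:4]:
                sel = (pops == g).to_numpy()
                col = gm.dosage[sel, j]
                obs = col[~np.isnan(col)]
                expect = obs.sum() / (2 * len(obs)) if len(obs) else np.nan
                got = f.freq.loc[g].iloc[j]
                assert (np.isnan(expect) and np.isnan(got)) or got == pytest.approx(expect)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_filters_are_idempotent_and_logs_reconcile(seed):
    rng = np.random.default_rng(seed)
    d = rng.choice([0.0, 1.0, 2.0, NA], p=[0.3, 0.25, 0.15, 0.3], size=(12, 15))
    gm = make_gm(d, positions=np.arange(1, 16) * 500)
    for op in (
        lambda g: vio.filter_sites(g, biallelic_only=False, max_site_missing=0.3),
        lambda g: vio.filter_individuals(g, 0.3),
    ):
        once = op(gm)
        twice = op(once)
        np.testing.assert_array_equal(
            np.nan_to_num(once.dosage, nan=-9), np.nan_to_num(twice.dosage, nan=-9)
        )
        entry = once.filter_log[-1]
        assert entry["n_in"] - entry["n_removed"] == entry["n_out"]
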
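"""Unit and property tests for the allele-frequency filter cascade."""

import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from spikemap import bulkfilter
from spikemap._records import MutationRecord, SiteReadCounts
from spikemap.bulkfilter import (
    FilterConfig,
    HET_BULK,
    HOM_BULK,
    MUT_BULK,
    WT_BULK,
    Zygosity,
    allele_frequency,
    classify_zygosity,
    filter_three_bulk,
    filter_two_bulk,
    index_counts,
    is_ems_type,
)


class TestIsEmsType:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [("G", "A", True), ("C", "T", True), ("A", "G", False),
         ("T", "C", False), ("G", "T", False)],
    )
    def test_classification(self, ref, alt, expected):
        assert is_ems_type(ref, alt) is expected

    def test_rejects_non_acgt(self):
        with pytest.raises(ValueError):
            is_ems_type("N", "A")
        with pytest.raises(ValueError):
            is_ems_type("g", "a")


class TestAlleleFrequency:
    def test_printed_mutant_bulk_counts(self):
        c = SiteReadCounts("m", "MUT", ref_reads=169 - 144, alt_reads=144)
        assert allele_frequency(c) == pytest.approx(144 / 169)

    def test_printed_wild_type_bulk_counts(self):
        assert allele_frequency(SiteReadCounts("m", "WT", 188, 0)) == 0.0

    def test_symmetric_counts(self):
        assert allele_frequency(SiteReadCounts("m", "b", 10, 10)) == 0.5

    def test_zero_depth_is_undefined_not_zero(self):
        assert allele_frequency(SiteReadCounts("m", "b", 0, 0)) is None


class TestClassifyZygosity:
    CFG = FilterConfig()

    @pytest.mark.parametrize(
        "freq,expected",
        [(0.50, Zygosity.HETEROZYGOUS), (0.40, Zygosity.HETEROZYGOUS),
         (0.60, Zygosity.HETEROZYGOUS), (0.95, Zygosity.HOMOZYGOUS),
         (1.0, Zygosity.HOMOZYGOUS), (0.9, Zygosity.HOMOZYGOUS),
         (0.75, Zygosity.AMBIGUOUS), (0.0, Zygosity.REFERENCE)],
    )
    def test_windows_closed_at_both_ends(self, freq, expected):
        assert classify_zygosity(freq, self.CFG) == expected

    def test_overlapping_windows_rejected_at_load(self):
        with pytest.raises(ValueError, match="overlap"):
            FilterConfig(het_window=(0.4, 0.92), hom_window=(0.9, 1.0))

    def test_out_of_range_frequency(self):
        with pytest.raises(ValueError):
            classify_zygosity(1.2, self.CFG)


def _mut(mid="M1", ref="G", alt="A", chrom="1D", pos=1000):
    return MutationRecord(mid, chrom, pos, ref, alt)


def _counts3(mid, wt=(30, 0), het=(15, 15), hom=(1, 29)):
    return {
        WT_BULK: {mid: SiteReadCounts(mid, WT_BULK, *wt)},
        HET_BULK: {mid: SiteReadCounts(mid, HET_BULK, *het)},
        HOM_BULK: {mid: SiteReadCounts(mid, HOM_BULK, *hom)},
    }


def _merge(*counts_dicts):
    out = {}
    for d in counts_dicts:
        for bulk, sub in d.items():
            out.setdefault(bulk, {}).update(sub)
    return out


class TestFilterThreeBulk:
    CFG = FilterConfig(whitelist=frozenset({("1D", 1000, "G", "A"),
                                            ("1D", 2000, "G", "A")}))

    def test_good_candidate_retained(self):
        m = _mut()
        cs = filter_three_bulk([m], _counts3("M1"), self.CFG)
        assert cs.retained == [m]
        assert cs.rejection_log == {}

    def test_non_ems_rejected_at_ems_rule(self):
        m = _mut(ref="A", alt="C")
        cfg = dataclasses.replace(self.CFG, whitelist=frozenset(
            {("1D", 1000, "A", "C")}))
        cs = filter_three_bulk([m], _counts3("M1"), cfg)
        assert cs.retained == []
        assert cs.rejection_log["M1"] == bulkfilter.RULE_NOT_EMS

    def test_hom_like_het_bulk_rejected_for_zygosity_inconsistency(self):
        # both bulks look homozygous: fails the het-window rule first
        m = _mut()
        counts = _counts3("M1", het=(8, 92), hom=(7, 93))
        cs = filter_three_bulk([m], counts, self.CFG)
        assert cs.rejection_log["M1"] == bulkfilter.RULE_HET_WINDOW

    def test_whitelist_rule(self):
        m = _mut(pos=999)  # not whitelisted
        counts = _counts3("M1")
        cs = filter_three_bulk([m], counts, self.CFG)
        assert cs.rejection_log["M1"] == bulkfilter.RULE_NOT_WHITELISTED

    def test_wt_alt_reads_rule(self):
        m = _mut()
        counts = _counts3("M1", wt=(25, 5))
        cs = filter_three_bulk([m], counts, self.CFG)
        assert cs.rejection_log["M1"] == bulkfilter.RULE_WT_ALT

    def test_low_depth_rejected_not_silently_passed(self):
        m = _mut()
        counts = _counts3("M1", wt=(2, 0), het=(1, 1), hom=(0, 2))
        cs = filter_three_bulk([m], counts, self.CFG)
        assert cs.rejection_log["M1"] == bulkfilter.RULE_DEPTH

    def test_missing_bulk_counts_rejected_with_reason(self):
        m1, m2 = _mut("M1"), _mut("M2", pos=2000)
        counts = _counts3("M1")  # no counts at all for M2
        cs = filter_three_bulk([m1, m2], counts, self.CFG)
        assert cs.rejection_log["M2"] == bulkfilter.RULE_MISSING

    def test_bulk_id_mismatch_is_an_error(self):
        m = _mut()
        counts = {"A": {}, "B": {}, "C": {}}
        with pytest.raises(ValueError, match="bulk id mismatch"):
            filter_three_bulk([m], counts, self.CFG)

    def test_partition_and_idempotence(self):
        muts = [_mut("M1"), _mut("M2", pos=2000, ref="C", alt="T"),
                _mut("M3", pos=3000)]
        counts = _merge(
            _counts3("M1"),
            _counts3("M2", het=(2, 28)),
            _counts3("M3", wt=(20, 10)),
        )
        cfg = FilterConfig()  # no whitelist
        cs = filter_three_bulk(muts, counts, cfg)
        assert len(cs.retained) + len(cs.rejection_log) == 3
        assert cs.retained_ids.isdisjoint(cs.rejection_log)
        again = filter_three_bulk(cs.retained, counts, cfg)
        assert again.retained_ids == cs.retained_ids


class TestFilterTwoBulk:
    CFG = FilterConfig(mode="two_bulk")

    def _counts(self, mut=(25, 144), wt=(188, 0)):
        return {
            WT_BULK: {"M1": SiteReadCounts("M1", WT_BULK, *wt)},
            MUT_BULK: {"M1": SiteReadCounts("M1", MUT_BULK, *mut)},
        }

    def test_printed_counts_retained_at_default_threshold(self):
        """144/169 in the mutant bulk (freq 0.852 > 0.8), 0/188 in wild type."""
        m = _mut()
        cs = filter_two_bulk([m], self._counts(), self.CFG)
        assert cs.retained == [m]

    def test_half_frequency_rejected(self):
        m = _mut()
        cs = filter_two_bulk([m], self._counts(mut=(80, 80)), self.CFG)
        assert cs.rejection_log["M1"] == bulkfilter.RULE_MUT_FREQ

    def test_threshold_is_strict(self):
        m = _mut()
        cs = filter_two_bulk([m], self._counts(mut=(20, 80)), self.CFG)  # = 0.8
        assert cs.rejection_log["M1"] == bulkfilter.RULE_MUT_FREQ

    def test_whitelist_checked_before_frequency(self):
        m = _mut()
        cfg = dataclasses.replace(self.CFG, whitelist=frozenset())
        cs = filter_two_bulk([m], self._counts(mut=(80, 80)), cfg)
        assert cs.rejection_log["M1"] == bulkfilter.RULE_NOT_WHITELISTED


@st.composite
def site_counts(draw):
    mid = f"M{draw(st.integers(0, 9))}"
    pos = 1000 + int(mid[1:])
    ref, alt = draw(st.sampled_from([("G", "A"), ("C", "T"), ("A", "G")]))
    counts = {}
    for bulk in (WT_BULK, HET_BULK, HOM_BULK):
        r = draw(st.integers(0, 60))
        a = draw(st.integers(0, 60))
        counts[bulk] = (r, a)
    return mid, pos, ref, alt, counts


class TestFilterProperties:
    @settings(max_examples=60, deadline=None)
    @given(st.lists(site_counts(), min_size=1, max_size=8, unique_by=lambda s: s[0]))
    def test_partition_and_shrinking_windows_monotone(self, sites):
        muts = [_mut(mid, ref, alt, pos=pos) for mid, pos, ref, alt, _ in sites]
        counts = {WT_BULK: {}, HET_BULK: {}, HOM_BULK: {}}
        for mid, _pos, _r, _a, per_bulk in sites:
            for bulk, (r, a) in per_bulk.items():
                counts[bulk][mid] = SiteReadCounts(mid, bulk, r, a)
        wide = FilterConfig(het_window=(0.3, 0.7), hom_window=(0.85, 1.0),
                            wt_max_alt_reads=5, min_depth=5)
        narrow = FilterConfig(het_window=(0.45, 0.55), hom_window=(0.95, 1.0),
                              wt_max_alt_reads=2, min_depth=10)
        cs_wide = filter_three_bulk(muts, counts, wide)
        cs_narrow = filter_three_bulk(muts, counts, narrow)
        for cs in (cs_wide, cs_narrow):
            assert len(cs.retained) + len(cs.rejection_log) == len(muts)
        assert cs_narrow.retained_ids <= cs_wide.retained_ids

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 200), st.integers(0, 200),
           st.floats(0.0, 0.99), st.floats(0.0, 0.99))
    def test_raising_two_bulk_threshold_monotone(self, r, a, t_low, t_high):
        t_low, t_high = sorted((t_low, t_high))
        m = _mut()
        counts = {
            WT_BULK: {"M1": SiteReadCounts("M1", WT_BULK, 50, 0)},
            MUT_BULK: {"M1": SiteReadCounts("M1", MUT_BULK, r, a)},
        }
        low = FilterConfig(mode="two_bulk", mutant_bulk_min_freq=t_low)
        high = FilterConfig(mode="two_bulk", mutant_bulk_min_freq=t_high)
        assert (
            filter_two_bulk([m], counts, high).retained_ids
            <= filter_two_bulk([m], counts, low).retained_ids
        )


class TestEndToEndWithSimulator:
    def test_causal_retained_and_passers_linked(self, group1_genome):
        """The planted causal SNP survives the cascade; every other retained
        site lies on the causal chromosome (linked hitchhikers only)."""
        from spikemap import simcross as sc

        genome = group1_genome
        muts = sc.simulate_ems_mutations(
            genome, sc.MutagenesisConfig(800, 0.98, seed=21)
        )
        causal = MutationRecord("causal", "1D", 217_644_011, "G", "A",
                                effect_class="missense")
        muts = sorted(
            [m for m in muts if (m.chromosome, m.position) != causal.key[:2]]
            + [causal],
            key=lambda m: (genome.names.index(m.chromosome), m.position),
        )
        ci = muts.index(causal)
        founder = sc.Individual.f1_heterozygote(len(muts))
        family = sc.simulate_cross(
            sc.CrossPlan([sc.BACKCROSS, sc.SELF], 200), muts, genome, founder,
            seed=22, carrier_index=ci,
        )
        sc.assign_phenotypes(family, sc.CausalSpec("causal"), muts)
        sel = {
            WT_BULK: lambda i: i.spikelet_phenotype == sc.Spikelet.WILD_TYPE,
            HET_BULK: lambda i: i.spikelet_phenotype == sc.Spikelet.PAIRED
            and i.leaf_phenotype == sc.Leaf.NORMAL,
            HOM_BULK: lambda i: i.leaf_phenotype == sc.Leaf.CURLED,
        }
        counts = {}
        for k, (bulk_id, f) in enumerate(sel.items()):
            bulk = sc.build_bulks(family, f, 20, seed=30 + k, bulk_id=bulk_id)
            reads = sc.sample_bulk_reads(
                bulk, muts, sc.ReadDepthModel(180.0, 0.001, seed=40 + k)
            )
            counts[bulk_id] = {c.mutation_id: c for c in reads}
        cs = filter_three_bulk(muts, counts, FilterConfig())
        assert "causal" in cs.retained_ids
        assert all(m.chromosome == "1D" for m in cs.retained)


class TestReports:
    def test_run_report_json(self, tmp_path):
        m = _mut()
        cfg = FilterConfig()
        cs = filter_three_bulk([m], _counts3("M1"), cfg)
        path = tmp_path / "report.json"
        bulkfilter.write_run_report(path, cs, cfg)
        import json

        data = json.loads(path.read_text())
        assert data["n_retained"] == 1
        assert data["config"]["het_window"] == [0.4, 0.6]

    def test_candidates_tsv(self, tmp_path):
        import pandas as pd

        m = _mut()
        cs = filter_three_bulk([m], _counts3("M1"), FilterConfig())
        path = tmp_path / "cand.tsv"
        bulkfilter.write_candidates_tsv(path, cs)
        df = pd.read_csv(path, sep="\t")
        assert list(df["id"]) == ["M1"]
        assert float(df["freq_HET"][0]) == pytest.approx(0.5)
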
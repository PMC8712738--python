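"""VCF reading, hard/marker filters, and the filter report contract."""

import numpy as np
import pandas as pd
import pytest

from bsrmap import synthetic, variant_io
from bsrmap.variant_io import (MarkerRecord, apply_hard_filters,
                               apply_marker_filters, markers_to_frame,
                               read_bulk_vcf, summarize_variants)


def make_record(pos=100, lg="LG1", ref="A", alt="T", qd=20.0, fs=10.0,
                mq=60.0, gq=60.0, depths=(25, 25, 25, 25), missing=False):
    return MarkerRecord(
        linkage_group=lg, position=pos, ref_allele=ref, alt_allele=alt,
        variant_class="SNP" if len(ref) == len(alt) == 1 else "INDEL",
        ref_high=depths[0], alt_high=depths[1],
        ref_low=depths[2], alt_low=depths[3],
        gq_high=gq, gq_low=gq, qd=qd, fs=fs, mq=mq,
        missing_high=missing, missing_low=missing)


@pytest.fixture()
def vcf_path(tmp_path, f2_model):
    markers, _ = synthetic.generate_dataset(
        f2_model, [], n_markers_per_lg=60, n_linkage_groups=3, seed=5)
    return synthetic.write_vcf(markers, tmp_path / "bulks.vcf"), markers


class TestReadBulkVcf:
    def test_round_trip_matches_generator_output(self, vcf_path):
        path, markers = vcf_path
        records = read_bulk_vcf(path, "bulk_high", "bulk_low")
        frame = markers_to_frame(records)
        assert len(frame) == len(markers)
        for col in ("linkage_group", "position", "ref_allele", "alt_allele",
                    "ref_high", "alt_high", "ref_low", "alt_low"):
            assert (frame[col].to_numpy() == markers[col].to_numpy()).all()

    def test_records_in_coordinate_order(self, vcf_path):
        path, _ = vcf_path
        records = read_bulk_vcf(path, "bulk_high", "bulk_low")
        keys = [(r.linkage_group, r.position) for r in records]
        by_lg = {}
        for lg, pos in keys:
            by_lg.setdefault(lg, []).append(pos)
        for positions in by_lg.values():
            assert positions == sorted(positions)

    def test_missing_sample_raises(self, vcf_path):
        path, _ = vcf_path
        with pytest.raises(ValueError, match="nope"):
            read_bulk_vcf(path, "nope", "bulk_low")

    def test_ad_field_maps_to_depths(self, tmp_path):
        vcf = tmp_path / "one.vcf"
        vcf.write_text("\n".join([
            "##fileformat=VCFv4.2",
            "##contig=<ID=LG1,length=1000>",
            '##INFO=<ID=QD,Number=1,Type=Float,Description="x">',
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="x">',
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="x">',
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="x">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\thi\tlo",
            "LG1\t5\t.\tA\tG\t50\tPASS\tQD=20\tGT:AD:GQ\t"
            "0/1:12,8:60\t0/1:9,11:60",
        ]) + "\n")
        (rec,) = read_bulk_vcf(vcf, "hi", "lo")
        assert (rec.ref_high, rec.alt_high) == (12, 8)
        assert (rec.ref_low, rec.alt_low) == (9, 11)

    @pytest.mark.parametrize("policy,expected", [("drop", 0), ("split", 2)])
    def test_multiallelic_policy(self, tmp_path, policy, expected):
        vcf = tmp_path / "multi.vcf"
        vcf.write_text("\n".join([
            "##fileformat=VCFv4.2",
            "##contig=<ID=LG1,length=1000>",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="x">',
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="x">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\thi\tlo",
            "LG1\t5\t.\tA\tG,T\t50\tPASS\t.\tGT:AD\t"
            "0/1:10,5,5\t0/2:8,4,8",
        ]) + "\n")
        records = read_bulk_vcf(vcf, "hi", "lo", multiallelic=policy)
        assert len(records) == expected


class TestHardFilters:
    @pytest.mark.parametrize("kwargs,removed", [
        ({"qd": 3.9}, True),
        ({"qd": 4.0, "fs": 60.0, "mq": 40.0}, False),  # boundaries pass
        ({"fs": 60.1}, True),
        ({"mq": 39.9}, True),
        ({"qd": float("nan")}, False),  # absent metric passes
    ])
    def test_site_metric_conditions(self, kwargs, removed):
        records = [make_record(**kwargs)]
        kept, report = apply_hard_filters(records)
        assert (len(kept) == 0) is removed
        assert report.check_conservation()

    def test_low_gq_marks_bulk_missing_not_removed(self):
        rec = make_record(gq=15.0)
        kept, _ = apply_hard_filters([rec])
        assert len(kept) == 1 and kept[0].missing_high

    def test_cluster_of_three_in_four_bp_removed(self):
        records = [make_record(pos=p) for p in (100, 102, 103)]
        kept, report = apply_hard_filters(records)
        assert kept == []
        assert report.removed["cluster"]["SNP"] == 3

    def test_cluster_matches_sliding_window_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            pos = np.sort(rng.choice(np.arange(1, 300), size=40,
                                     replace=False))
            records = [make_record(pos=int(p)) for p in pos]
            kept, _ = apply_hard_filters(records, cluster_window=10,
                                         cluster_size=3)
            # oracle: a variant is clustered if some window of 3 consecutive
            # variants containing it spans <= 10 bp
            removed = set()
            for i in range(len(pos) - 2):
                if pos[i + 2] - pos[i] + 1 <= 10:
                    removed |= {pos[i], pos[i + 1], pos[i + 2]}
            assert {r.position for r in kept} == set(pos) - removed

    def test_idempotent(self):
        records = [make_record(pos=p) for p in (10, 400, 900)]
        once, _ = apply_hard_filters(records)
        twice, _ = apply_hard_filters(once)
        assert markers_to_frame(once).equals(markers_to_frame(twice))


class TestMarkerFilters:
    @pytest.mark.parametrize("depths,kept", [
        ((4, 4, 25, 25), False),   # bulk depth 8 < 10
        ((5, 5, 250, 250), True),  # inclusive lower bound
        ((250, 250, 5, 5), True),  # inclusive upper bound
        ((300, 300, 25, 25), False),  # 600 > 500
    ])
    def test_depth_bounds(self, depths, kept):
        out, _ = apply_marker_filters([make_record(depths=depths)])
        assert (len(out) == 1) is kept

    @pytest.mark.parametrize("idx_high,idx_low,kept", [
        (0.1, 0.2, False),  # both low: near-monomorphic ref
        (0.8, 0.9, False),  # both high: near-monomorphic alt
        (0.1, 0.8, True),   # divergent marker retained
        (0.5, 0.5, True),
    ])
    def test_both_bulk_index_rule(self, idx_high, idx_low, kept):
        depths = (round(100 * (1 - idx_high)), round(100 * idx_high),
                  round(100 * (1 - idx_low)), round(100 * idx_low))
        out, _ = apply_marker_filters([make_record(depths=depths)])
        assert (len(out) == 1) is kept

    def test_missing_genotype_excluded(self):
        out, report = apply_marker_filters([make_record(missing=True)])
        assert out == [] and report.removed["missing"]["SNP"] == 1

    def test_conservation_and_single_attribution(self, small_dataset):
        markers, _ = small_dataset
        filtered, hard = apply_hard_filters(markers)
        final, marker = apply_marker_filters(filtered)
        assert hard.check_conservation() and marker.check_conservation()
        n_removed = sum(sum(v.values()) for v in hard.removed.values())
        n_removed += sum(sum(v.values()) for v in marker.removed.values())
        assert len(markers) == len(final) + n_removed

    def test_order_preserved(self, small_dataset):
        markers, _ = small_dataset
        out, _ = apply_marker_filters(markers)
        key = out[["linkage_group", "position"]]
        assert key.equals(key.sort_values(["linkage_group", "position"])
                          .reset_index(drop=True))


class TestSummarizeVariants:
    def test_totals_are_snp_plus_indel(self):
        table = summarize_variants({"SNP": 1_411_727, "INDEL": 106_475},
                                   {"SNP": 555_478, "INDEL": 65_157},
                                   label="brain")
        total = table[table["Variation"] == "Total"].iloc[0]
        assert total["Before filter"] == 1_518_202
        assert total["After filter"] == 620_635

    def test_accepts_filter_reports(self, small_dataset):
        markers, _ = small_dataset
        filtered, hard = apply_hard_filters(markers)
        _, marker = apply_marker_filters(filtered)
        table = summarize_variants(hard, marker)
        total = table[table["Variation"] == "Total"].iloc[0]
        assert total["Before filter"] == len(markers)
        snp = table[table["Variation"] == "SNP"].iloc[0]
        indel = table[table["Variation"] == "Indel"].iloc[0]
        assert total["After filter"] == snp["After filter"] + \
            indel["After filter"]

    def test_empty_input_all_zero(self):
        table = summarize_variants({}, {})
        assert (table[["Before filter", "After filter"]] == 0).all().all()
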
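"""Decile-stratified TSS distances and annotation overlap."""

import numpy as np
import pytest

from eqtlpower import (
    AnnotationSet,
    EqtlSignal,
    annotation_overlap_by_decile,
    decile_edges,
    fraction_beyond,
    tss_distance_by_decile,
)
from eqtlpower.characterization import read_bed, read_gene_list, _point_in_intervals


def _signal(r, tss=1000, gene="g1", pos=500, chrom="1"):
    return EqtlSignal(gene_id=gene, variant_id=f"{chrom}:{pos}", r=r,
                      tss_distance=tss, chrom=chrom, position=pos)


class TestFractionBeyond:
    def test_inclusive_boundary(self):
        sigs = [_signal(0.1, tss=d) for d in (10_000, 36_000, 50_000)]
        assert fraction_beyond(sigs, 36_000) == pytest.approx(2 / 3)

    def test_zero_threshold(self):
        sigs = [_signal(0.1, tss=d) for d in (5, 10)]
        assert fraction_beyond(sigs, 0) == 1.0

    def test_above_max(self):
        sigs = [_signal(0.1, tss=d) for d in (5, 10)]
        assert fraction_beyond(sigs, 11) == 0.0

    def test_non_increasing_in_threshold(self, rng):
        sigs = [_signal(0.1, tss=int(d)) for d in rng.integers(0, 100_000, 50)]
        fracs = [fraction_beyond(sigs, t) for t in range(0, 100_001, 10_000)]
        assert np.all(np.diff(fracs) <= 0)


class TestTssByDecile:
    def test_planted_inverse_relation_gives_decreasing_medians(self, rng):
        # distance proportional to 1/r: weaker signals sit further away
        rs = rng.uniform(0.02, 0.9, 500)
        sigs = [_signal(r, tss=int(1000 / r)) for r in rs]
        bins = decile_edges(rs)
        table = tss_distance_by_decile(sigs, bins)
        med = table["median"].to_numpy()
        assert np.all(np.diff(med) < 0)
        assert table["count"].sum() == 500

    def test_constant_distances(self):
        rs = np.linspace(0.05, 0.95, 40)
        sigs = [_signal(r, tss=7777) for r in rs]
        table = tss_distance_by_decile(sigs, decile_edges(rs))
        assert np.all(table["median"].dropna() == 7777)

    def test_empty_decile_reported_with_nan(self):
        rs = np.linspace(0.05, 0.95, 20)
        bins = decile_edges(rs)
        table = tss_distance_by_decile([_signal(0.5, tss=100)], bins)
        assert (table["count"] == 0).sum() == 9
        row = table[table["count"] == 1].iloc[0]
        assert row["median"] == 100


class TestBedAndOverlap:
    def test_read_bed_and_containment(self, tmp_path):
        bed = tmp_path / "p.bed"
        bed.write_text("1\t100\t200\n2\t0\t50\n")
        track = read_bed(bed)
        # 1-based position 101 maps to 0-based 100, the interval start
        assert _point_in_intervals(track, "1", 101)
        assert _point_in_intervals(track, "1", 200)
        assert not _point_in_intervals(track, "1", 201)  # end is exclusive
        assert not _point_in_intervals(track, "1", 100)
        assert not _point_in_intervals(track, "3", 101)

    def test_malformed_bed_reports_line(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text("1\t100\t200\n1\tfoo\tbar\n")
        with pytest.raises(ValueError, match=":2"):
            read_bed(bed)

    def test_invalid_interval_rejected(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text("1\t200\t100\n")
        with pytest.raises(ValueError, match="invalid interval"):
            read_bed(bed)

    def test_matches_brute_force_membership(self, tmp_path, rng):
        starts = np.sort(rng.integers(0, 500, 8))
        bed = tmp_path / "t.bed"
        bed.write_text("".join(f"1\t{s}\t{s + 20}\n" for s in starts))
        track = read_bed(bed)
        covered = set()
        for s in starts:
            covered.update(range(s, s + 20))  # 0-based half-open expansion
        for pos0 in range(0, 550):
            assert _point_in_intervals(track, "1", pos0 + 1) == (pos0 in covered)

    def test_gene_list_reader(self, tmp_path):
        path = tmp_path / "genes.txt"
        path.write_text("# header\ngeneA\n\ngeneB\n")
        assert read_gene_list(path) == {"geneA", "geneB"}


class TestAnnotationOverlapByDecile:
    def test_empty_annotations_give_zero(self):
        rs = np.linspace(0.05, 0.95, 30)
        sigs = [_signal(r) for r in rs]
        table = annotation_overlap_by_decile(sigs, AnnotationSet(), decile_edges(rs))
        filled = table.dropna()
        assert (filled[["prop_promoter", "prop_enhancer",
                        "prop_high_pli", "prop_tf"]] == 0).all().all()

    def test_planted_enhancer_trend_recovered(self, rng):
        # weak signals placed in enhancers with probability 0.8, strong 0.2
        n = 2000
        rs = np.concatenate([rng.uniform(0.02, 0.1, n // 2),
                             rng.uniform(0.5, 0.9, n // 2)])
        enh = np.arange(0, 10_000_000, 1000)  # enhancers [k*1000, k*1000+100)
        track = {"1": np.column_stack([enh, enh + 100])}
        sigs = []
        for i, r in enumerate(rs):
            weak = r < 0.3
            p_in = 0.8 if weak else 0.2
            inside = rng.random() < p_in
            pos = i * 1000 + (50 if inside else 500) + 1
            sigs.append(_signal(r, pos=pos))
        ann = AnnotationSet(enhancers=track)
        table = annotation_overlap_by_decile(sigs, ann, decile_edges(rs))
        weak_prop = table["prop_enhancer"].iloc[0]
        strong_prop = table["prop_enhancer"].iloc[-1]
        se = np.sqrt(0.8 * 0.2 / (n / 10))
        assert abs(weak_prop - 0.8) < 3 * se
        assert abs(strong_prop - 0.2) < 3 * se

    def test_gene_flags_counted(self):
        rs = np.linspace(0.05, 0.95, 20)
        sigs = [_signal(r, gene=("tf_gene" if r > 0.5 else "other")) for r in rs]
        ann = AnnotationSet(tf_genes={"tf_gene"}, high_pli_genes={"other"})
        table = annotation_overlap_by_decile(sigs, ann, decile_edges(rs))
        assert table["prop_tf"].iloc[-1] == 1.0
        assert table["prop_high_pli"].iloc[0] == 1.0
        assert table["count"].sum() == 20
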
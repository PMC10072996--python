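"""Dataset construction rules: constitutive selection, negative tiling with
the 10% overlap filter, chromosome split, subsampling, cryptic calling."""

import numpy as np
import pytest

from cpascan.datasets import (
    DatasetError,
    LabeledWindow,
    build_cryptic_set,
    make_positive_windows,
    max_site_overlap,
    normalize_chrom,
    select_constitutive,
    site_region,
    split_by_chromosome,
    subsample_negatives,
    tile_negatives,
)
from cpascan.scan import ScanTrack
from cpascan.sequence_io import CPASite, GeneModel, GenomicInterval


def _site(gene, pos, pse, rpm, chrom="chr1", strand="+"):
    return CPASite(gene, GenomicInterval(chrom, pos, pos + 1, strand), pse, rpm)


def _gene(gene_id, start, end, utr=None, chrom="chr1", strand="+"):
    span = GenomicInterval(chrom, start, end, strand)
    utr_iv = GenomicInterval(chrom, *utr, strand) if utr else None
    return GeneModel(gene_id, span, utr_iv)


class TestSelectConstitutive:
    def test_argmax_significance_wins(self):
        sites = [_site("G1", 850, 100, 2.0), _site("G1", 800, 50, 3.0)]
        models = {"G1": _gene("G1", 0, 1000, utr=(700, 900))}
        chosen, dropped = select_constitutive(sites, models)
        assert chosen["G1"].base == 850 and not dropped

    def test_tie_breaks_most_distal(self):
        sites = [_site("G1", 800, 100, 2.0), _site("G1", 850, 100, 2.0)]
        models = {"G1": _gene("G1", 0, 1000, utr=(700, 900))}
        chosen, _ = select_constitutive(sites, models)
        assert chosen["G1"].base == 850

    def test_tie_on_minus_strand_takes_lower_coordinate(self):
        sites = [
            _site("G1", 800, 100, 2.0, strand="-"),
            _site("G1", 850, 100, 2.0, strand="-"),
        ]
        models = {"G1": _gene("G1", 0, 1000, utr=(700, 900), strand="-")}
        chosen, _ = select_constitutive(sites, models)
        assert chosen["G1"].base == 800  # 3'-distal on the minus strand

    def test_site_outside_utr_drops_gene(self):
        sites = [_site("G1", 100, 100, 2.0)]
        models = {"G1": _gene("G1", 0, 1000, utr=(700, 900))}
        chosen, dropped = select_constitutive(sites, models)
        assert not chosen and dropped == ["G1"]

    def test_site_at_utr_end_qualifies(self):
        sites = [_site("G1", 900, 100, 2.0)]
        models = {"G1": _gene("G1", 0, 1000, utr=(700, 900))}
        chosen, _ = select_constitutive(sites, models)
        assert chosen["G1"].base == 900

    def test_recovers_planted_sites(self, truth):
        """Every planted constitutive site with maximal PSE x RPM is
        recovered from the emitted annotations."""
        chosen, dropped = select_constitutive(
            truth.all_known_sites, truth.gene_models()
        )
        assert not dropped
        for gene_id, site in truth.constitutive_sites.items():
            assert chosen[gene_id].base == site.base


class TestTileNegatives:
    GENOME = {"chr1": "ACGU" * 300}  # 1200 nt

    def test_window_count_arithmetic(self):
        models = [_gene("G1", 0, 1000)]
        wins = tile_negatives(models, self.GENOME, [])
        assert len(wins) == 6  # starts 0,100,...,500
        assert [w.window.start for w in wins] == [0, 100, 200, 300, 400, 500]

    def test_overlap_boundary_is_strict(self):
        models = [_gene("G1", 0, 1000)]
        # site region [450, 950): window [0, 500) overlaps by exactly 50
        keep = tile_negatives(models, self.GENOME, [_site("G1", 700, 50, 1.0)])
        assert 0 in [w.window.start for w in keep]
        # site base 699 -> region [449, 949): overlap 51 -> removed
        drop = tile_negatives(models, self.GENOME, [_site("G1", 699, 50, 1.0)])
        assert 0 not in [w.window.start for w in drop]

    def test_gene_shorter_than_window_yields_nothing(self):
        assert tile_negatives([_gene("G1", 0, 400)], self.GENOME, []) == []

    def test_minus_strand_windows_are_transcript_sense(self):
        models = [_gene("G1", 0, 500, strand="-")]
        wins = tile_negatives(models, self.GENOME, [])
        from cpascan.sequence_io import reverse_complement

        assert wins[0].sequence == reverse_complement(self.GENOME["chr1"][0:500])

    def test_no_surviving_window_exceeds_overlap_budget(self, splits, truth):
        """Post-hoc: every generated negative respects the 10% rule."""
        rng = np.random.default_rng(0)
        sample = rng.choice(len(splits["negatives"]), size=200, replace=False)
        for i in sample:
            ov = max_site_overlap(splits["negatives"][i], truth.all_known_sites)
            assert ov <= 50


class TestSplit:
    def test_chromosome_routing(self):
        ex = [
            LabeledWindow("g", GenomicInterval(c, 0, 500, "+"), "A" * 500, "negative")
            for c in ("chr3", "chrX", "chrY", "15")
        ]
        train, test, excluded = split_by_chromosome(ex)
        assert [e.window.chrom for e in train] == ["chr3"]
        assert sorted(e.window.chrom for e in test) == ["15", "chrX"]
        assert [e.window.chrom for e in excluded] == ["chrY"]

    def test_unknown_naming_scheme_rejected(self):
        ex = [
            LabeledWindow(
                "g", GenomicInterval("scaffold77", 0, 500, "+"), "A" * 500, "negative"
            )
        ]
        with pytest.raises(DatasetError, match="chr1"):
            split_by_chromosome(ex)

    def test_normalize_dialects(self):
        assert normalize_chrom("1") == "chr1"
        assert normalize_chrom("chrX") == "chrX"

    def test_partition_is_exhaustive_and_disjoint(self, splits):
        n = len(splits["positives"])
        got = len(splits["pos_train"]) + len(splits["pos_test"])
        assert got <= n and n - got >= 0  # excluded only for chrY/unplaced
        train_genes = {w.gene_id for w in splits["pos_train"]}
        test_genes = {w.gene_id for w in splits["pos_test"]}
        assert not train_genes & test_genes


class TestSubsample:
    def _negatives(self, n):
        return [
            LabeledWindow(
                f"g{i}", GenomicInterval("chr1", i * 10, i * 10 + 500, "+"),
                "A" * 500, "negative",
            )
            for i in range(n)
        ]

    def test_exact_ratio(self):
        out = subsample_negatives(self._negatives(1000), 10, ratio=30, seed=0)
        assert len(out) == 300

    def test_deterministic_per_seed(self):
        negs = self._negatives(1000)
        a = subsample_negatives(negs, 10, seed=7)
        b = subsample_negatives(negs, 10, seed=7)
        assert [w.window.start for w in a] == [w.window.start for w in b]

    def test_shortfall_reported(self):
        with pytest.raises(DatasetError, match="short by 200"):
            subsample_negatives(self._negatives(100), 10, ratio=30, seed=0)


class TestCrypticCalling:
    GENOME = {"chrT": "ACGU" * 10}

    def _track(self, probs, flank=5):
        return ScanTrack("chrT", np.array(probs), flank=flank)

    def test_single_run_peak(self):
        track = self._track([0.5, 0.7, 0.8, 0.7, 0.5])
        out = build_cryptic_set([track], [], self.GENOME, flank=2, half_window=2)
        assert len(out) == 1
        # peak at track index 2 -> CPA base 2 + flank(5) = 7
        assert out[0].window.start == 5 and out[0].window.end == 9
        assert out[0].score == pytest.approx(0.8)

    def test_known_site_suppresses_run(self):
        track = self._track([0.5, 0.7, 0.8, 0.7, 0.5])
        known = [_site("g", 7, 50, 1.0, chrom="chrT")]
        out = build_cryptic_set([track], known, self.GENOME, flank=2, half_window=2)
        assert out == []

    def test_subthreshold_track_yields_nothing(self):
        track = self._track([0.1, 0.69, 0.5])
        assert build_cryptic_set([track], [], self.GENOME, half_window=2) == []

    def test_two_separated_runs(self):
        track = self._track([0.9, 0.1, 0.1, 0.95, 0.9])
        out = build_cryptic_set([track], [], self.GENOME, flank=2, half_window=2)
        assert len(out) == 2


class TestPositiveWindows:
    def test_positive_window_geometry(self, splits):
        w = splits["pos_train"][0]
        assert len(w.sequence) == 500
        assert w.site_offset == 250
        assert w.label == "positive"

    def test_site_base_sits_at_flank_offset(self, truth):
        """The planted cleavage base (an A from the CA/UA dinucleotide) is
        at offset 250 of its positive window."""
        chosen, _ = select_constitutive(truth.all_known_sites, truth.gene_models())
        windows = make_positive_windows(chosen, truth.sequences)
        hits = sum(w.sequence[250] == "A" for w in windows[:50])
        assert hits == 50  # CA/UA inclusion is 1.0 in the default spec
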
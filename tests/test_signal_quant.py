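import numpy as np
import pytest

from acetylink.genomic_io import (
    CountMatrix,
    GeneRecord,
    PeakRecord,
    SampleRecord,
    SampleSheet,
)
from acetylink.signal_quant import (
    BackgroundEstimate,
    compute_fpkm,
    estimate_background_scale,
    normalize_peak_signal,
    read_signal_matrix,
)

from conftest import make_sheet


def chip_input_sheet(libsizes):
    records = []
    for sid, size in libsizes.items():
        assay = "input" if "input" in sid else "chip"
        records.append(SampleRecord(sid, "control", assay, size))
    return SampleSheet(records)


class TestComputeFpkm:
    def test_closed_form(self):
        sheet = make_sheet(1)  # control1, case1, library 1e6
        genes = [GeneRecord("g1", "chr1", 0, 1000, "+")]
        cm = CountMatrix(["g1"], ["control1", "case1"], np.array([[10, 0]]), "gene")
        fpkm = compute_fpkm(cm, genes, sheet)
        assert fpkm.signal[0, 0] == pytest.approx(10.0)
        assert fpkm.signal[0, 1] == 0.0

    def test_matches_elementwise_oracle(self, rng):
        n_genes, n_samples = 50, 4
        counts = rng.integers(0, 500, size=(n_genes, n_samples))
        lengths = rng.integers(200, 20000, size=n_genes)
        libs = rng.integers(10**6, 10**7, size=n_samples)
        genes = [
            GeneRecord(f"g{i}", "chr1", 0, int(lengths[i]), "+") for i in range(n_genes)
        ]
        sheet = SampleSheet(
            [SampleRecord(f"s{j}", "control", "rna", int(libs[j])) for j in range(n_samples)]
        )
        cm = CountMatrix(
            [g.gene_id for g in genes], [f"s{j}" for j in range(n_samples)], counts, "gene"
        )
        fpkm = compute_fpkm(cm, genes, sheet)
        for i in range(n_genes):
            for j in range(n_samples):
                expected = counts[i, j] * 1e9 / (lengths[i] * libs[j])
                assert fpkm.signal[i, j] == pytest.approx(expected, rel=1e-12)

    def test_linear_in_counts(self):
        sheet = make_sheet(1)
        genes = [GeneRecord("g1", "chr1", 0, 1000, "+")]
        one = compute_fpkm(
            CountMatrix(["g1"], ["control1", "case1"], np.array([[7, 7]]), "gene"), genes, sheet
        )
        three = compute_fpkm(
            CountMatrix(["g1"], ["control1", "case1"], np.array([[21, 21]]), "gene"), genes, sheet
        )
        assert np.allclose(three.signal, 3 * one.signal)

    def test_missing_annotation_rejected(self):
        sheet = make_sheet(1)
        cm = CountMatrix(["gX"], ["control1", "case1"], np.array([[1, 1]]), "gene")
        with pytest.raises(ValueError, match="annotation"):
            compute_fpkm(cm, [], sheet)

    def test_missing_sample_rejected(self):
        sheet = make_sheet(1)
        genes = [GeneRecord("g1", "chr1", 0, 1000, "+")]
        cm = CountMatrix(["g1"], ["stranger"], np.array([[1]]), "gene")
        with pytest.raises(ValueError, match="sample sheet"):
            compute_fpkm(cm, genes, sheet)


class TestNormalizePeakSignal:
    peaks = [PeakRecord("p1", "chr1", 0, 500)]
    pairing = {"c1_chip": "c1_input"}

    def matrices(self, chip_count, input_count):
        chip = CountMatrix(["p1"], ["c1_chip"], np.array([[chip_count]]), "peak")
        inp = CountMatrix(["p1"], ["c1_input"], np.array([[input_count]]), "peak")
        return chip, inp

    def test_closed_form(self):
        sheet = chip_input_sheet({"c1_chip": 10**6, "c1_input": 10**6})
        chip, inp = self.matrices(100, 50)
        sig = normalize_peak_signal(chip, inp, self.peaks, sheet, self.pairing)
        # dens_chip = 100*1e9/(1e6*500) = 200; dens_input = 100
        assert sig.signal[0, 0] == pytest.approx(100.0)
        assert sig.normalization_meta["scale_constant"] == 1e9

    def test_equal_densities_cancel(self):
        sheet = chip_input_sheet({"c1_chip": 10**6, "c1_input": 2 * 10**6})
        chip, inp = self.matrices(50, 100)  # c/N == i/N
        sig = normalize_peak_signal(chip, inp, self.peaks, sheet, self.pairing)
        assert sig.signal[0, 0] == 0.0

    def test_floored_at_zero(self):
        sheet = chip_input_sheet({"c1_chip": 10**6, "c1_input": 10**6})
        chip, inp = self.matrices(0, 10)
        sig = normalize_peak_signal(chip, inp, self.peaks, sheet, self.pairing)
        assert sig.signal[0, 0] == 0.0

    def test_background_scale_applied(self):
        sheet = chip_input_sheet({"c1_chip": 10**6, "c1_input": 10**6})
        chip, inp = self.matrices(100, 50)
        bg = {"c1_chip": BackgroundEstimate("c1_chip", scale_factor=2.0, n_bins_used=10)}
        sig = normalize_peak_signal(chip, inp, self.peaks, sheet, self.pairing, background=bg)
        assert sig.signal[0, 0] == pytest.approx(0.0)  # 200 - 2*100

    def test_unpaired_chip_sample_rejected(self):
        sheet = chip_input_sheet({"c1_chip": 10**6, "c1_input": 10**6})
        chip, inp = self.matrices(1, 1)
        with pytest.raises(ValueError, match="paired"):
            normalize_peak_signal(chip, inp, self.peaks, sheet, {})

    def test_peak_missing_from_list_rejected(self):
        sheet = chip_input_sheet({"c1_chip": 10**6, "c1_input": 10**6})
        chip, inp = self.matrices(1, 1)
        with pytest.raises(ValueError, match="missing from peak list"):
            normalize_peak_signal(chip, inp, [], sheet, self.pairing)

    def test_scaling_equivariance(self):
        base = chip_input_sheet({"c1_chip": 10**6, "c1_input": 10**6})
        scaled = chip_input_sheet({"c1_chip": 3 * 10**6, "c1_input": 10**6})
        chip, inp = self.matrices(100, 50)
        chip3, _ = self.matrices(300, 50)
        a = normalize_peak_signal(chip, inp, self.peaks, base, self.pairing)
        b = normalize_peak_signal(chip3, inp, self.peaks, scaled, self.pairing)
        assert np.allclose(a.signal, b.signal)

    def test_length_invariance(self):
        sheet = chip_input_sheet({"c1_chip": 10**6, "c1_input": 10**6})
        chip, inp = self.matrices(100, 50)
        double = [PeakRecord("p1", "chr1", 0, 1000)]
        chip2, inp2 = self.matrices(200, 100)
        a = normalize_peak_signal(chip, inp, self.peaks, sheet, self.pairing)
        b = normalize_peak_signal(chip2, inp2, double, sheet, self.pairing)
        assert np.allclose(a.signal, b.signal)

    def test_signal_bounded_by_chip_density(self, rng):
        sheet = chip_input_sheet({"c1_chip": 10**6, "c1_input": 10**6})
        chip_counts = rng.integers(0, 1000, size=(20, 1))
        input_counts = rng.integers(0, 1000, size=(20, 1))
        peaks = [PeakRecord(f"p{i}", "chr1", 0, 500) for i in range(20)]
        chip = CountMatrix([p.peak_id for p in peaks], ["c1_chip"], chip_counts, "peak")
        inp = CountMatrix([p.peak_id for p in peaks], ["c1_input"], input_counts, "peak")
        sig = normalize_peak_signal(chip, inp, peaks, sheet, {"c1_chip": "c1_input"})
        dens_chip = chip_counts[:, 0] * 1e9 / (10**6 * 500)
        assert (sig.signal[:, 0] <= dens_chip + 1e-9).all()
        zero_input = CountMatrix([p.peak_id for p in peaks], ["c1_input"],
                                 np.zeros((20, 1), dtype=int), "peak")
        sig0 = normalize_peak_signal(chip, zero_input, peaks, sheet, {"c1_chip": "c1_input"})
        assert np.allclose(sig0.signal[:, 0], dens_chip)

    def test_signal_tsv_roundtrip(self, tmp_path):
        sheet = chip_input_sheet({"c1_chip": 10**6, "c1_input": 10**6})
        chip, inp = self.matrices(100, 50)
        sig = normalize_peak_signal(chip, inp, self.peaks, sheet, self.pairing)
        path = tmp_path / "sig.tsv"
        sig.write_tsv(path)
        back = read_signal_matrix(path)
        assert back.feature_ids == sig.feature_ids
        assert np.array_equal(back.signal, sig.signal)


class TestEstimateBackgroundScale:
    def bins(self, chip_vals, input_vals):
        ids = [f"b{i}" for i in range(len(chip_vals))]
        chip = CountMatrix(ids, ["c1_chip"], np.array(chip_vals)[:, None], "bin")
        inp = CountMatrix(ids, ["c1_input"], np.array(input_vals)[:, None], "bin")
        return chip, inp

    def test_constant_double_ratio(self):
        sheet = chip_input_sheet({"c1_chip": 10**6, "c1_input": 10**6})
        chip, inp = self.bins([2, 4, 8], [1, 2, 4])
        (est,) = estimate_background_scale(chip, inp, sheet, {"c1_chip": "c1_input"})
        assert est.scale_factor == pytest.approx(2.0)
        assert est.n_bins_used == 3

    def test_identical_bins_give_unity(self):
        sheet = chip_input_sheet({"c1_chip": 10**6, "c1_input": 10**6})
        chip, inp = self.bins([5, 7, 9], [5, 7, 9])
        (est,) = estimate_background_scale(chip, inp, sheet, {"c1_chip": "c1_input"})
        assert est.scale_factor == pytest.approx(1.0)

    def test_zero_input_bins_excluded(self):
        sheet = chip_input_sheet({"c1_chip": 10**6, "c1_input": 10**6})
        chip, inp = self.bins([10, 3], [0, 3])
        (est,) = estimate_background_scale(chip, inp, sheet, {"c1_chip": "c1_input"})
        assert est.n_bins_used == 1
        assert est.scale_factor == pytest.approx(1.0)

    def test_all_zero_input_rejected(self):
        sheet = chip_input_sheet({"c1_chip": 10**6, "c1_input": 10**6})
        chip, inp = self.bins([1, 2], [0, 0])
        with pytest.raises(ValueError, match="input > 0"):
            estimate_background_scale(chip, inp, sheet, {"c1_chip": "c1_input"})

    def test_poisson_bins_match_direct_median_oracle(self, rng):
        n_bins = 500
        chip_vals = rng.poisson(20, size=n_bins)
        input_vals = rng.poisson(10, size=n_bins)
        n_chip, n_input = 4 * 10**6, 2 * 10**6
        sheet = chip_input_sheet({"c1_chip": n_chip, "c1_input": n_input})
        chip, inp = self.bins(chip_vals, input_vals)
        (est,) = estimate_background_scale(chip, inp, sheet, {"c1_chip": "c1_input"})
        mask = input_vals > 0
        expected = np.median((chip_vals[mask] / n_chip) / (input_vals[mask] / n_input))
        assert est.scale_factor == pytest.approx(expected)


class TestQuantifyBamOverIntervals:
    @pytest.fixture
    def toy_bam(self, tmp_path):
        pysam = pytest.importorskip("pysam")
        path = str(tmp_path / "toy.bam")
        header = {"HD": {"VN": "1.6", "SO": "coordinate"},
                  "SQ": [{"SN": "chr1", "LN": 10000}]}
        # read A: [100, 200); reads B, C: [1000, 1100) and [1100, 1200)
        reads = [("A", 100, 100), ("B", 1000, 100), ("C", 1100, 100)]
        with pysam.AlignmentFile(path, "wb", header=header) as bam:
            for name, pos, length in reads:
                a = pysam.AlignedSegment()
                a.query_name = name
                a.query_sequence = "A" * length
                a.reference_id = 0
                a.reference_start = pos
                a.mapping_quality = 60
                a.cigarstring = f"{length}M"
                a.query_qualities = pysam.qualitystring_to_array("I" * length)
                bam.write(a)
        pysam.index(path)
        return path

    def test_partial_overlap_counts_covered_bases(self, toy_bam):
        from acetylink.signal_quant import quantify_bam_over_intervals

        # read A covers [100, 200); interval [150, 250) overlaps 50 bases
        cm = quantify_bam_over_intervals(toy_bam, [PeakRecord("iv", "chr1", 150, 250)])
        assert cm.counts[0, 0] == 50

    def test_no_overlap_is_zero(self, toy_bam):
        from acetylink.signal_quant import quantify_bam_over_intervals

        cm = quantify_bam_over_intervals(toy_bam, [PeakRecord("iv", "chr1", 5000, 5100)])
        assert cm.counts[0, 0] == 0

    def test_two_contained_reads(self, toy_bam):
        from acetylink.signal_quant import quantify_bam_over_intervals

        cm = quantify_bam_over_intervals(toy_bam, [PeakRecord("iv", "chr1", 1000, 1200)])
        assert cm.counts[0, 0] == 200

    def test_absent_contig_rejected(self, toy_bam):
        from acetylink.signal_quant import quantify_bam_over_intervals

        with pytest.raises(ValueError, match="chrX"):
            quantify_bam_over_intervals(toy_bam, [PeakRecord("iv", "chrX", 0, 10)])

    def test_missing_index_rejected(self, toy_bam, tmp_path):
        import shutil

        from acetylink.signal_quant import quantify_bam_over_intervals

        unindexed = str(tmp_path / "unindexed.bam")
        shutil.copy(toy_bam, unindexed)
        with pytest.raises(ValueError, match="index"):
            quantify_bam_over_intervals(unindexed, [PeakRecord("iv", "chr1", 0, 10)])
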
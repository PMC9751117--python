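"""Library generator: seed design, mutation model, phenotype shapes, assembly."""

import io
from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from seq2exp import synthetic
from seq2exp.biophys import PROPERTY_NAMES, BiophysConfig
from seq2exp.errors import ConfigurationError, ValidationError
from seq2exp.synthetic import (
    GroundTruthModel,
    LibraryConfig,
    SequenceRecord,
    build_library,
    design_seeds,
    generate_series,
    hamming,
    remove_stop_codons,
    simulate_phenotype,
    write_csv,
)


class TestDesignSeeds:
    def test_single_seed_vacuous_distance(self):
        ss = design_seeds(1, 5, rng_seed=0)
        assert len(ss.seeds) == 1 and len(ss.seeds[0]) == 5
        assert ss.min_pairwise_hamming == 5

    def test_two_seeds_length_two_exhaustive(self):
        # brute force over all 16x16 pairs: the maximin Hamming distance is 2
        ss = design_seeds(2, 2, candidate_pool=16, rng_seed=1)
        assert ss.min_pairwise_hamming == 2

    def test_four_seeds_length_one_are_the_four_bases(self):
        ss = design_seeds(4, 1, candidate_pool=4, rng_seed=2)
        assert sorted(ss.seeds) == ["A", "C", "G", "T"]
        assert ss.min_pairwise_hamming == 1

    def test_impossible_request(self):
        with pytest.raises(ConfigurationError):
            design_seeds(5, 1)

    def test_deterministic(self):
        assert design_seeds(6, 12, rng_seed=7) == design_seeds(6, 12, rng_seed=7)


class TestGenerateSeries:
    def test_zero_rate_copies_seed(self):
        seed = "ACGTACGTAC"
        assert set(generate_series(seed, 20, 0.0, rng_seed=1)) == {seed}

    def test_rate_one_changes_every_position(self):
        seed = "ACGTACGTAC"
        for v in generate_series(seed, 20, 1.0, rng_seed=1):
            assert all(a != b for a, b in zip(seed, v))

    def test_mean_hamming_matches_binomial_expectation(self):
        seed = "ACGT" * 24  # L = 96
        p, n = 0.1, 1000
        variants = generate_series(seed, n, p, rng_seed=5)
        d = np.array([hamming(seed, v) for v in variants])
        expect = 96 * p
        se = np.sqrt(96 * p * (1 - p) / n)
        assert abs(d.mean() - expect) < 3 * se

    def test_bad_rate_rejected(self):
        with pytest.raises(ValidationError):
            generate_series("ACGT", 1, 1.5)


class TestSimulatePhenotype:
    cfg = BiophysConfig(btl_window=4)
    stats8 = (np.zeros(8), np.ones(8))

    def test_zero_model_gives_logistic_of_zero(self):
        model = GroundTruthModel(weights=np.zeros(8))
        y = simulate_phenotype("ACGTACGTACGT", model, self.stats8, config=self.cfg)
        assert y == pytest.approx(0.5)

    def test_noise_free_is_deterministic(self):
        model = GroundTruthModel(weights=np.linspace(-1, 1, 8), offset=0.3)
        args = ("ACGTACGTACGT", model, self.stats8)
        assert simulate_phenotype(*args, rng_seed=1, config=self.cfg) == simulate_phenotype(
            *args, rng_seed=2, config=self.cfg
        )

    def test_unknown_switch_property_rejected(self):
        with pytest.raises(ConfigurationError):
            GroundTruthModel(weights=np.zeros(8), switch_property="charge")

    def test_identity_link_is_linear_in_normalized_properties(self):
        w = np.full(8, 0.1)
        model = GroundTruthModel(weights=w, offset=0.1, link="identity")
        from seq2exp.biophys import profile

        seq = "ATGGCTGGTCAC"
        phi = profile(seq, self.cfg).as_vector()  # stats are (0,1): phi_norm == phi
        expected = float(np.clip(phi @ w + 0.1, 0, 1))
        got = simulate_phenotype(seq, model, self.stats8, config=self.cfg)
        assert got == pytest.approx(expected)


def _skew(values):
    return stats.skew(np.asarray(values))


def _is_bimodal(values, bins=10):
    """Two histogram peaks separated by a trough below half the smaller peak."""
    h, _ = np.histogram(values, bins=bins, range=(0, 1))
    half = bins // 2
    i = int(np.argmax(h[:half]))
    j = half + int(np.argmax(h[half:]))
    if j - i < 3:
        return False
    trough = h[i + 1 : j].min()
    return trough < 0.5 * min(h[i], h[j])


class TestShapeContracts:
    """Per-series phenotype distributions honour their preset shapes (n=2000)."""

    def test_shapes(self, shape_library):
        frame = shape_library.to_frame()
        for sid, grp in frame.groupby("series_id"):
            shape = shape_library.series_models[sid].shape
            y = grp["fluorescence"].to_numpy()
            if shape == "gaussian":
                assert abs(_skew(y)) < 0.5
            elif shape == "right_skew":
                assert _skew(y) > 0.5
            elif shape == "left_skew":
                assert _skew(y) < -0.5
            elif shape == "bimodal":
                assert _is_bimodal(y)


class TestBuildLibrary:
    def test_record_counts_and_series_labels(self):
        cfg = LibraryConfig(n_series=2, variants_per_series=3, length=12, master_seed=4)
        lib = build_library(config=cfg)
        assert len(lib) == 6
        counts = {}
        for r in lib:
            counts[r.series_id] = counts.get(r.series_id, 0) + 1
        assert counts == {1: 3, 2: 3}

    def test_deterministic_byte_identical_csv(self):
        cfg = LibraryConfig(n_series=2, variants_per_series=40, length=12, master_seed=9)
        bufs = []
        for _ in range(2):
            buf = io.StringIO()
            write_csv(build_library(config=cfg).records, buf)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]

    def test_within_series_tighter_than_between(self, small_library):
        frame = small_library.to_frame()
        per_series = {
            sid: grp["sequence"].tolist()[:40] for sid, grp in frame.groupby("series_id")
        }
        within, between = [], []
        for sid, seqs in per_series.items():
            within += [hamming(a, b) for a, b in combinations(seqs[:15], 2)]
        for a_id, b_id in combinations(per_series, 2):
            between += [
                hamming(a, b)
                for a, b in zip(per_series[a_id][:15], per_series[b_id][:15])
            ]
        assert np.mean(within) < np.mean(between)

    def test_records_are_valid_and_stop_free(self, small_library):
        for r in list(small_library)[::97]:
            assert 0.0 <= r.fluorescence <= 1.0
            codons = {r.sequence[i : i + 3] for i in range(0, len(r.sequence), 3)}
            assert not codons & {"TAA", "TAG", "TGA"}

    def test_record_validation(self):
        with pytest.raises(ValidationError):
            SequenceRecord("x", 1, "ACGN", 0.5)
        with pytest.raises(ValidationError):
            SequenceRecord("x", 1, "ACGT", 1.5)


def test_remove_stop_codons_repairs_all_frames():
    assert remove_stop_codons("TAATAGTGA") == "TATTATTGT"
    assert remove_stop_codons("ATGGCT") == "ATGGCT"
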
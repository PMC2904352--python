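"""Fold generator, homolog derivation, decoys and twilight clouds."""

import numpy as np
import pytest

from rna3dcons.chains import filter_dataset
from rna3dcons.sara import align_pair
from rna3dcons.scoring import score_alignment
from rna3dcons.synthetic import (FoldSpec, HomologParams, DomainShift, Segment,
                                 derive_homolog, generate_decoy_set,
                                 generate_fold, generate_twilight_points,
                                 ladder_pairs)
from rna3dcons.twilight import TwilightCurve, classify_points

WC = {"A": "U", "U": "A", "G": "C", "C": "G"}


def hairpin_spec(stem=10, loop=4, seed=0):
    return FoldSpec([Segment("stem", stem, 0), Segment("loop", loop),
                     Segment("stem", stem, 0)], seed=seed)


class TestGenerateFold:
    def test_hairpin_counts(self):
        chain, bps = generate_fold(hairpin_spec())
        assert len(chain) == 24
        assert len(bps) == 10

    def test_deterministic_per_seed(self):
        c1, _ = generate_fold(hairpin_spec(seed=5))
        c2, _ = generate_fold(hairpin_spec(seed=5))
        assert c1.sequence == c2.sequence
        np.testing.assert_array_equal(c1.coords, c2.coords)

    def test_consecutive_spacing_in_window(self):
        for chain, _ in generate_decoy_set(15, (30, 300), seed=13):
            d = np.linalg.norm(np.diff(chain.coords, axis=0), axis=1)
            assert d.min() >= 5.0 - 1e-9
            assert d.max() <= 7.0 + 1e-9

    def test_watson_crick_complementarity(self):
        chain, bps = generate_fold(hairpin_spec(seed=2))
        for i, j in bps.pairs:
            assert chain.sequence[j] == WC[chain.sequence[i]]

    def test_invalid_spec_lists_violations(self):
        bad = FoldSpec([Segment("stem", 1, 0), Segment("loop", 1),
                        Segment("stem", 2, 0)], seed=0)
        with pytest.raises(ValueError, match="invalid fold spec"):
            generate_fold(bad)

    def test_pseudoknot_rejected(self):
        # crossing stems: 0 opens, 1 opens, 0 closes, 1 closes
        segs = [Segment("stem", 5, 0), Segment("linker", 2),
                Segment("stem", 5, 1), Segment("loop", 4),
                Segment("stem", 5, 0), Segment("linker", 2),
                Segment("stem", 5, 1)]
        errors = FoldSpec(segs, seed=0).validate()
        assert errors


class TestDeriveHomolog:
    def test_identity_preserving_parameters(self, hairpin):
        chain, bps = hairpin
        hom, hbps = derive_homolog(chain, bps,
                                   HomologParams(target_pid=100.0, seed=1))
        assert hom.sequence == chain.sequence
        np.testing.assert_array_equal(hom.coords, chain.coords)
        assert hbps.pairs == bps.pairs

    def test_realized_identity_near_target(self):
        chain, bps = generate_decoy_set(2, (190, 210), seed=31)[0]
        hom, _ = derive_homolog(chain, bps,
                                HomologParams(target_pid=50.0, seed=4))
        ident = 100.0 * sum(a == b for a, b in
                            zip(chain.sequence, hom.sequence)) / len(chain)
        assert ident == pytest.approx(50.0, abs=5.0)

    def test_compensatory_mutations_preserve_complementarity(self):
        chain, bps = generate_decoy_set(2, (100, 150), seed=37)[0]
        hom, hbps = derive_homolog(
            chain, bps, HomologParams(target_pid=40.0, seed=5))
        assert hbps.pairs == bps.pairs
        for i, j in hbps.pairs:
            assert hom.sequence[j] == WC[hom.sequence[i]]

    def test_coordinate_noise_displacement(self):
        chain, bps = generate_decoy_set(2, (150, 250), seed=41)[0]
        hom, _ = derive_homolog(
            chain, bps, HomologParams(target_pid=100.0, coord_noise=0.5, seed=6))
        rms = np.sqrt(np.mean(np.sum((hom.coords - chain.coords) ** 2, axis=1)))
        assert rms == pytest.approx(0.5 * np.sqrt(3.0), rel=0.15)

    def test_domain_shift_moves_only_the_segment(self, hairpin):
        chain, bps = hairpin
        ds = DomainShift(start=12, end=23, rotation_deg=0.0, translation=15.0)
        hom, _ = derive_homolog(
            chain, bps, HomologParams(target_pid=100.0, domain_shift=ds, seed=7))
        np.testing.assert_array_equal(hom.coords[:12], chain.coords[:12])
        moved = np.linalg.norm(hom.coords[12:] - chain.coords[12:], axis=1)
        assert np.all(moved > 10.0)


class TestDecoySet:
    def test_all_pass_dataset_filters(self):
        decoys = generate_decoy_set(25, (30, 300), seed=43)
        kept, _, report = filter_dataset([c for c, _ in decoys],
                                         [b for _, b in decoys])
        assert report.n_too_short == 0
        assert report.n_too_few_pairs == 0
        assert len(kept) == 25   # no duplicated sequences either

    def test_decoy_alignments_near_random_identity(self):
        decoys = generate_decoy_set(16, (60, 200), seed=47)
        pids = []
        for i in range(0, 16, 2):
            (A, bA), (B, bB) = decoys[i], decoys[i + 1]
            s = score_alignment(align_pair(A, B, bA, bB), A, B, bA, bB)
            pids.append(s.pid)
        assert np.mean(pids) == pytest.approx(25.0, abs=10.0)

    def test_deterministic(self):
        a = generate_decoy_set(4, (30, 100), seed=51)
        b = generate_decoy_set(4, (30, 100), seed=51)
        for (c1, _), (c2, _) in zip(a, b):
            assert c1.sequence == c2.sequence
            np.testing.assert_array_equal(c1.coords, c2.coords)

    def test_too_few_raises(self):
        with pytest.raises(ValueError, match="at least 2"):
            generate_decoy_set(1)


class TestTwilightCloud:
    def test_separable_by_generating_curve(self):
        curve = TwilightCurve(A=3.0, B=300.0, k=0.08)
        points = generate_twilight_points(curve, 400, 400, margin=0.5, seed=53)
        assert classify_points(points, curve).mcc == 1.0

    def test_zero_margin_still_strictly_separable(self):
        curve = TwilightCurve(A=3.0, B=300.0, k=0.08)
        points = generate_twilight_points(curve, 200, 200, margin=0.0, seed=54)
        assert classify_points(points, curve).mcc == 1.0

    def test_precondition_errors(self):
        curve = TwilightCurve(A=3.0, B=300.0, k=0.08)
        with pytest.raises(ValueError, match="n_pos"):
            generate_twilight_points(curve, 0, 10)
        with pytest.raises(ValueError, match="margin"):
            generate_twilight_points(curve, 10, 10, margin=-1.0)

    def test_deterministic(self):
        curve = TwilightCurve(A=3.0, B=300.0, k=0.08)
        a = generate_twilight_points(curve, 50, 50, seed=55)
        b = generate_twilight_points(curve, 50, 50, seed=55)
        assert a == b


class TestLadder:
    def test_psi_degrades_monotonically_with_divergence(self):
        rows = {}
        for A, bA, B, bB, pid in ladder_pairs(pids=(40, 60, 80, 100),
                                              n_folds=4, seed=42):
            s = score_alignment(align_pair(A, B, bA, bB), A, B, bA, bB)
            rows.setdefault(pid, []).append(s.psi)
        medians = [np.median(rows[p]) for p in sorted(rows)]
        for lo, hi in zip(medians, medians[1:]):
            assert hi >= lo - 2.0
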
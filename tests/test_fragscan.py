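"""Docking score aggregation, core-region calling, pose-site classification."""

import numpy as np
import pytest

from bindlab import fragscan as fsn
from bindlab import peptides as pep
from bindlab import synthetic_data as syn

NLS1 = "AKKKSTGSSTWPLDPGVEVTLTMKVAS"


def brute_force_profile(scores, parent):
    """Oracle: double loop over (residue, fragment) membership."""
    means = {}
    for num in range(parent.start_number, parent.end_number + 1):
        vals = [
            fs.score
            for fs in scores
            if fs.fragment.start_number <= num <= fs.fragment.end_number
        ]
        if vals:
            means[num] = sum(vals) / len(vals)
    return means


@pytest.fixture
def nls1_scores():
    parent = pep.PeptideSequence(NLS1, start_number=58, c_term_cap="amide")
    frags = pep.make_fragments(parent)
    values = [-6, -6, -6, -7, -8, -8, -7, -6, -6, -6, -6]
    return parent, [fsn.FragmentScore(f, v) for f, v in zip(frags, values)]


class TestAggregatePerResidue:
    def test_uniform_scores_uniform_profile(self):
        parent = pep.PeptideSequence(NLS1, start_number=58)
        scores = [fsn.FragmentScore(f, -7.0) for f in pep.make_fragments(parent)]
        prof = fsn.aggregate_per_residue(scores, parent)
        assert np.allclose(prof.mean_scores, -7.0)
        assert prof.residue_numbers[0] == 58 and prof.residue_numbers[-1] == 84

    def test_single_fragment_covers_its_window_only(self):
        parent = pep.PeptideSequence(NLS1, start_number=58)
        frag = pep.make_fragments(parent)[2]  # residues 62-68
        prof = fsn.aggregate_per_residue([fsn.FragmentScore(frag, -5.5)], parent)
        assert list(prof.residue_numbers) == list(range(62, 69))
        assert np.allclose(prof.mean_scores, -5.5)

    def test_matches_brute_force_enumeration(self, nls1_scores):
        parent, scores = nls1_scores
        prof = fsn.aggregate_per_residue(scores, parent)
        oracle = brute_force_profile(scores, parent)
        assert list(prof.residue_numbers) == sorted(oracle)
        for num, mean in zip(prof.residue_numbers, prof.mean_scores):
            assert mean == pytest.approx(oracle[num], abs=1e-12)

    def test_random_inputs_match_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            length = rng.integers(9, 30)
            parent = pep.PeptideSequence("A" * int(length), start_number=int(rng.integers(1, 500)))
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                frags = pep.make_fragments(parent, window=7, step=2)
            scores = [fsn.FragmentScore(f, float(rng.normal(-7, 1))) for f in frags]
            prof = fsn.aggregate_per_residue(scores, parent)
            oracle = brute_force_profile(scores, parent)
            for num, mean in zip(prof.residue_numbers, prof.mean_scores):
                assert mean == pytest.approx(oracle[num], abs=1e-12)

    def test_coverage_counts_window7_step2(self, nls1_scores):
        """First/last residues are covered once; interior peaks at ceil(7/2) = 4."""
        parent, scores = nls1_scores
        prof = fsn.aggregate_per_residue(scores, parent)
        counts = dict(zip(prof.residue_numbers, prof.n_fragments))
        assert counts[58] == 1 and counts[84] == 1
        assert counts[70] == 4 and max(counts.values()) == 4
        assert prof.terminal_flags[0] and not prof.terminal_flags[12]

    def test_foreign_fragment_rejected(self):
        parent = pep.PeptideSequence(NLS1, start_number=58)
        alien = pep.Fragment("YYYYYYY", start_number=60)
        with pytest.raises(ValueError, match="does not match parent"):
            fsn.aggregate_per_residue([fsn.FragmentScore(alien, -7.0)], parent)


class TestCallCoreRegion:
    def test_single_dip_in_central_fragments(self, nls1_scores):
        """Scores dipping on the central fragments call a compact core inside
        the central third of the peptide (residue means: 67 -> -7.0,
        68 -> -7.25, 69/71 -> -7.667, 70 -> -7.5, 72 -> -7.25; margin 0.5
        keeps 68-72)."""
        parent, scores = nls1_scores
        prof = fsn.aggregate_per_residue(scores, parent)
        lo, hi = fsn.call_core_region(prof)
        assert (lo, hi) == (68, 72)

    def test_flat_profile_degenerate_call(self):
        parent = pep.PeptideSequence(NLS1, start_number=58)
        scores = [fsn.FragmentScore(f, -7.0) for f in pep.make_fragments(parent)]
        prof = fsn.aggregate_per_residue(scores, parent)
        with pytest.warns(UserWarning, match="flat"):
            lo, hi = fsn.call_core_region(prof)
        assert (lo, hi) == (58, 84)

    def test_minimum_at_n_terminus_is_clipped(self):
        """A minimum on the first fragment clips the region at the terminus."""
        parent = pep.PeptideSequence(NLS1, start_number=58, c_term_cap="amide")
        frags = pep.make_fragments(parent)
        values = [-9.0] + [-6.0] * 10
        prof = fsn.aggregate_per_residue(
            [fsn.FragmentScore(f, v) for f, v in zip(frags, values)], parent
        )
        lo, hi = fsn.call_core_region(prof)
        assert lo == 58
        assert prof.terminal_flags[0]

    def test_invariance_to_constant_shift_and_renumbering(self, nls1_scores):
        parent, scores = nls1_scores
        base = fsn.call_core_region(fsn.aggregate_per_residue(scores, parent))
        shifted = [fsn.FragmentScore(fs.fragment, fs.score + 3.25) for fs in scores]
        assert fsn.call_core_region(fsn.aggregate_per_residue(shifted, parent)) == base

        offset = 100
        parent2 = pep.PeptideSequence(parent.residues, start_number=58 + offset,
                                      c_term_cap="amide")
        frags2 = pep.make_fragments(parent2)
        scores2 = [fsn.FragmentScore(f, fs.score) for f, fs in zip(frags2, scores)]
        lo, hi = fsn.call_core_region(fsn.aggregate_per_residue(scores2, parent2))
        assert (lo - offset, hi - offset) == base

    def test_short_profile_rejected(self):
        prof = fsn.ResidueAffinityProfile(
            residue_numbers=np.arange(1, 6),
            mean_scores=np.array([-1.0, -2, -3, -2, -1]),
            n_fragments=np.ones(5, int),
            terminal_flags=np.zeros(5, bool),
        )
        with pytest.raises(ValueError, match="at least 7"):
            fsn.call_core_region(prof)


class TestClassifyPoseSite:
    def setup_method(self):
        rng = np.random.default_rng(5)
        self.ref = rng.normal(0, 5, size=(28, 3))

    def test_identical_pose_is_major_at_zero_distance(self):
        label, dist = fsn.classify_pose_site(self.ref.copy(), self.ref)
        assert label == "major" and dist == 0.0

    def test_far_translated_pose_is_other(self):
        label, dist = fsn.classify_pose_site(self.ref + 100.0, self.ref)
        assert label == "other" and dist > 50.0

    def test_nearby_pose_is_major(self):
        rng = np.random.default_rng(6)
        pose = self.ref + rng.normal(0, 1.5, self.ref.shape)
        label, dist = fsn.classify_pose_site(pose, self.ref)
        assert label == "major" and dist <= 5.0

    def test_minor_site_reference(self):
        minor_ref = self.ref + np.array([40.0, 0, 0])
        pose = minor_ref + 0.5
        label, _ = fsn.classify_pose_site(pose, self.ref, minor_ref)
        assert label == "minor"

    def test_missing_reference_warns_other(self):
        with pytest.warns(UserWarning, match="no major-site reference"):
            label, dist = fsn.classify_pose_site(self.ref, None)
        assert label == "other" and np.isinf(dist)


class TestRunBackend:
    def test_mock_backend_builds_profile(self, tmp_path):
        parent = pep.PeptideSequence(NLS1, start_number=58, c_term_cap="amide")
        frags = pep.make_fragments(parent)
        calls = []

        def backend(frag, config):
            calls.append(frag.residues)
            return -7.0, f"pose-{frag.start_number}"

        cache = tmp_path / "scores.csv"
        scores = fsn.run_backend(frags, fsn.DockingConfig(), backend, cache)
        assert len(scores) == 11 and len(calls) == 11
        prof = fsn.aggregate_per_residue(scores, parent)
        assert np.allclose(prof.mean_scores, -7.0)

        # cached results: backend must not be invoked again
        calls.clear()
        again = fsn.run_backend(frags, fsn.DockingConfig(), backend, cache)
        assert not calls
        assert [s.score for s in again] == [s.score for s in scores]

    def test_missing_backend_names_requirement(self):
        parent = pep.PeptideSequence(NLS1, start_number=58)
        frags = pep.make_fragments(parent)
        with pytest.raises(RuntimeError, match="docking engine"):
            fsn.run_backend(frags, fsn.DockingConfig())

    def test_malformed_backend_output_rejected(self):
        parent = pep.PeptideSequence(NLS1, start_number=58)
        frags = pep.make_fragments(parent)
        with pytest.raises(RuntimeError, match="malformed backend output"):
            fsn.run_backend(frags, fsn.DockingConfig(), lambda f, c: (float("nan"), "p"))


class TestLandscapeGenerator:
    def test_noiseless_landscape_recovers_constructed_core(self):
        scores, parent, truth = syn.gen_affinity_landscape(noise_sd=0.0, seed=4)
        prof = fsn.aggregate_per_residue(scores, parent)
        assert fsn.call_core_region(prof) == tuple(truth.parameters["core_region"])

    def test_flat_landscape_degenerate(self):
        with pytest.warns(UserWarning, match="flat"):
            scores, parent, _ = syn.gen_affinity_landscape(
                core_depth=0.0, noise_sd=0.0, seed=4
            )
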
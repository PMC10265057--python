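"""Kernel smoothing, codon averaging, region calling, and structure export."""

import math

import numpy as np
import pytest

from tilescan import synthetic_data as sd
from tilescan import screen_stats as ss
from tilescan import tiling_profile as tp


def nw_oracle(cut_pos, scores, xs, h, min_weight=1e-3):
    """Direct double-loop Nadaraya-Watson estimate with the same NA policy."""
    out = []
    for x in xs:
        num = den = 0.0
        for c, s in zip(cut_pos, scores):
            k = math.exp(-0.5 * ((x - c) / h) ** 2) / math.sqrt(2 * math.pi)
            num += k * s
            den += k
        out.append(num / den if den >= min_weight else float("nan"))
    return np.array(out)


class TestKernelSmooth:
    def test_constant_scores_give_constant_curve(self):
        curve = tp.kernel_smooth(np.array([10.0, 50.0, 90.0]), np.full(3, -0.7), 120)
        covered = ~np.isnan(curve)
        np.testing.assert_allclose(curve[covered], -0.7, atol=1e-12)

    def test_single_guide_weights_cancel(self):
        curve = tp.kernel_smooth(np.array([50.0]), np.array([-1.3]), 150)
        covered = ~np.isnan(curve)
        np.testing.assert_allclose(curve[covered], -1.3, atol=1e-12)
        # far positions fall below the kernel-mass cutoff
        assert np.isnan(curve[-1])

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 25))
            cut = rng.uniform(1, 300, size=n)
            val = rng.normal(size=n)
            cfg = tp.SmoothingConfig(bandwidth_nt=float(rng.uniform(3, 20)))
            curve = tp.kernel_smooth(cut, val, 300, cfg)
            xs = rng.integers(1, 301, size=30)
            expect = nw_oracle(cut, val, xs, cfg.bandwidth_nt, cfg.min_weight)
            got = curve[xs - 1]
            np.testing.assert_allclose(got, expect, atol=1e-9, equal_nan=True)

    def test_linearity_in_scores(self, rng):
        cut = rng.uniform(1, 120, size=12)
        val = rng.normal(size=12)
        a, b = 2.5, -0.4
        base = tp.kernel_smooth(cut, val, 120)
        scaled = tp.kernel_smooth(cut, a * val + b, 120)
        ok = ~np.isnan(base)
        np.testing.assert_allclose(scaled[ok], a * base[ok] + b, atol=1e-9)

    def test_locality_beyond_six_bandwidths(self):
        cfg = tp.SmoothingConfig(bandwidth_nt=5.0, min_weight=1e-3)
        curve = tp.kernel_smooth(np.array([30.0]), np.array([-1.0]), 300, cfg)
        # a single guide cannot support positions further than ~6h away
        assert np.isnan(curve[30 + 6 * 5 + 5 :]).all()

    def test_no_guides_rejected(self):
        with pytest.raises(ValueError, match="no kept"):
            tp.kernel_smooth(np.array([]), np.array([]), 100)


class TestCodonAverage:
    def test_trinucleotide_mean_and_na_policy(self):
        curve = np.array([1.0, 2.0, 3.0, np.nan, np.nan, np.nan, np.nan, 4.0, 6.0])
        out = tp.codon_average(curve)
        assert out[0] == 2.0
        assert np.isnan(out[1])
        assert out[2] == 5.0  # partial codon: mean of non-NA values

    def test_constant_curve_idempotent(self):
        np.testing.assert_allclose(tp.codon_average(np.full(30, -0.4)), -0.4)

    def test_preserves_mean_on_fully_covered_curve(self, rng):
        curve = rng.normal(size=90)
        assert tp.codon_average(curve).mean() == pytest.approx(curve.mean(), abs=1e-12)

    def test_bad_length_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            tp.codon_average(np.zeros(10))


class TestTopDepletedResidue:
    def test_strictly_increasing_profile(self):
        profile = tp.ResidueProfile(np.arange(10.0), np.ones(10, dtype=int))
        assert tp.top_depleted_residue(profile) == 1

    def test_ties_break_to_smallest_index(self):
        profile = tp.ResidueProfile(np.array([0.0, -1.0, -1.0]), np.ones(3, dtype=int))
        assert tp.top_depleted_residue(profile) == 2

    def test_all_na_rejected(self):
        profile = tp.ResidueProfile(np.full(3, np.nan), np.zeros(3, dtype=int))
        with pytest.raises(ValueError, match="all-NA"):
            tp.top_depleted_residue(profile)

    def test_recovers_planted_peak_from_simulation(self, simulated_screen):
        lib = simulated_screen["library"]
        profile = tp.residue_profile(simulated_screen["scan"], lib)
        assert abs(tp.top_depleted_residue(profile) - 108) <= 3


class TestCallDepletedRegions:
    def test_single_region_with_na_break(self):
        scores = np.array([0.0, 0.0, -1.0, -1.0, 0.0])
        profile = tp.ResidueProfile(scores, np.ones(5, dtype=int))
        regions = tp.call_depleted_regions(profile, -0.5)
        assert [(r.start_residue, r.end_residue) for r in regions] == [(3, 4)]
        assert regions[0].min_score == -1.0 and regions[0].argmin_residue == 3

    def test_all_above_threshold_empty(self):
        profile = tp.ResidueProfile(np.zeros(5), np.ones(5, dtype=int))
        assert tp.call_depleted_regions(profile, -0.5) == []

    def test_matches_run_length_oracle(self, rng):
        for _ in range(50):
            scores = rng.normal(scale=0.8, size=60)
            scores[rng.random(60) < 0.1] = np.nan
            profile = tp.ResidueProfile(scores, np.ones(60, dtype=int))
            regions = tp.call_depleted_regions(profile, -0.5)
            # brute-force run-length scan
            expected = []
            run = []
            for i, v in enumerate(list(scores) + [np.nan]):
                if not np.isnan(v) and v <= -0.5:
                    run.append(i + 1)
                elif run:
                    expected.append((run[0], run[-1]))
                    run = []
            assert [(r.start_residue, r.end_residue) for r in regions] == expected

    def test_na_residues_break_runs(self):
        scores = np.array([-1.0, np.nan, -1.0])
        profile = tp.ResidueProfile(scores, np.ones(3, dtype=int))
        regions = tp.call_depleted_regions(profile, -0.5)
        assert [(r.start_residue, r.end_residue) for r in regions] == [(1, 1), (3, 3)]


class TestChimeraAttribute:
    def test_assignment_lines_for_three_chains(self):
        scores = np.full(120, np.nan)
        scores[107] = -1.2345
        profile = tp.ResidueProfile(scores, np.zeros(120, dtype=int))
        text = tp.export_chimera_attribute(profile, "crisprScan", chains=["A", "C", "E"])
        lines = text.splitlines()
        assert lines[:3] == ["attribute: crisprScan", "match mode: 1-to-1", "recipient: residues"]
        assert lines[3:] == ["\t:108.A\t-1.2345", "\t:108.C\t-1.2345", "\t:108.E\t-1.2345"]

    def test_chainless_selector(self):
        profile = tp.ResidueProfile(np.array([0.25]), np.ones(1, dtype=int))
        assert "\t:1\t0.2500" in tp.export_chimera_attribute(profile, "scanScore")

    def test_round_trip_through_own_parser(self, simulated_screen):
        lib = simulated_screen["library"]
        profile = tp.residue_profile(simulated_screen["scan"], lib)
        text = tp.export_chimera_attribute(profile, "scanScore", chains=["A", "C"])
        name, values = tp.read_chimera_attribute(text)
        assert name == "scanScore"
        for r in range(1, profile.n_residues + 1):
            v = profile.scores[r - 1]
            if np.isnan(v):
                assert (r, "A") not in values
            else:
                assert values[(r, "A")] == pytest.approx(v, abs=5e-5)
                assert values[(r, "C")] == values[(r, "A")]

    def test_invalid_attribute_name_rejected(self):
        profile = tp.ResidueProfile(np.array([0.0]), np.ones(1, dtype=int))
        with pytest.raises(ValueError, match="lowercase"):
            tp.export_chimera_attribute(profile, "BadName")


TOY_PDB = """\
CRYST1    1.000    1.000    1.000  90.00  90.00  90.00 P 1           1
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00 10.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00 10.00           C
ATOM      3  CA  LYS A   3       7.600   0.000   0.000  1.00 10.00           C
ATOM      4  CA  ALA B   1       0.000   5.000   0.000  1.00 10.00           C
ATOM      5  CA  GLY B   2       3.800   5.000   0.000  1.00 10.00           C
ATOM      6  CA  LYS B   3       7.600   5.000   0.000  1.00 10.00           C
END
"""


class TestBfactorAnnotation:
    @pytest.fixture()
    def toy_structure(self, tmp_path):
        path = tmp_path / "toy.pdb"
        path.write_text(TOY_PDB)
        return path

    def test_scores_written_scaled_with_na_sentinel(self, toy_structure, tmp_path):
        import gemmi

        profile = tp.ResidueProfile(np.array([0.0, -1.0, np.nan]), np.ones(3, dtype=int))
        out = tmp_path / "annotated.pdb"
        n = tp.annotate_structure_bfactor(profile, toy_structure, ["A"], out)
        assert n == 3
        st = gemmi.read_structure(str(out))
        chain_a = {r.seqid.num: r[0].b_iso for r in st[0]["A"]}
        chain_b = {r.seqid.num: r[0].b_iso for r in st[0]["B"]}
        assert chain_a[1] == pytest.approx(0.0)
        assert chain_a[2] == pytest.approx(-100.0)
        assert chain_a[3] == pytest.approx(0.0)  # NA sentinel
        assert all(b == pytest.approx(10.0) for b in chain_b.values())  # untouched

    def test_round_trip_within_format_precision(self, toy_structure, tmp_path, rng):
        import gemmi

        scores = rng.uniform(-1.5, 0.5, size=3)
        profile = tp.ResidueProfile(scores, np.ones(3, dtype=int))
        out = tmp_path / "annotated.pdb"
        tp.annotate_structure_bfactor(profile, toy_structure, ["A", "B"], out)
        st = gemmi.read_structure(str(out))
        # PDB B-factor columns hold 6 characters: 0.005 precision below
        # |100|, one decimal fewer above it
        for chain in st[0]:
            for res in chain:
                want = scores[res.seqid.num - 1] * 100
                tol = 0.005 if abs(want) < 100 else 0.1
                assert res[0].b_iso == pytest.approx(want, abs=tol)

    def test_hexamer_chains_annotated_identically(self, tmp_path, rng):
        # three copies of the same protein in one assembly, as in a
        # RUVBL1/RUVBL2 hexamer where chains A, C, E are the same subunit
        lines = [TOY_PDB.splitlines()[0]]
        serial = 1
        for chain in "ACE":
            for i in range(1, 4):
                lines.append(
                    f"ATOM  {serial:5d}  CA  ALA {chain}{i:4d}    "
                    f"{serial * 1.0:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00 10.00           C"
                )
                serial += 1
        path = tmp_path / "hexamer.pdb"
        path.write_text("\n".join(lines) + "\nEND\n")
        profile = tp.ResidueProfile(rng.uniform(-1, 0, size=3), np.ones(3, dtype=int))
        out = tmp_path / "hex_annotated.pdb"
        tp.annotate_structure_bfactor(profile, path, ["A", "C", "E"], out)
        import gemmi

        st = gemmi.read_structure(str(out))
        per_chain = {
            ch.name: [r[0].b_iso for r in ch] for ch in st[0] if ch.name in "ACE"
        }
        assert per_chain["A"] == per_chain["C"] == per_chain["E"]

    def test_numbering_offset(self, tmp_path, toy_structure):
        profile = tp.ResidueProfile(np.array([-0.5]), np.ones(1, dtype=int))
        out = tmp_path / "off.pdb"
        # structure residue 3 corresponds to profile residue 1
        n = tp.annotate_structure_bfactor(profile, toy_structure, ["A"], out, offset=2)
        assert n == 1

    def test_no_matching_residues_rejected(self, toy_structure, tmp_path):
        profile = tp.ResidueProfile(np.array([0.0]), np.ones(1, dtype=int))
        with pytest.raises(ValueError, match="no residues"):
            tp.annotate_structure_bfactor(
                profile, toy_structure, ["Z"], tmp_path / "x.pdb"
            )


def test_residue_profile_support_counts(simulated_screen):
    lib = simulated_screen["library"]
    profile = tp.residue_profile(simulated_screen["scan"], lib)
    assert profile.n_residues == lib.cds_length // 3
    covered = ~np.isnan(profile.scores)
    assert (profile.n_supporting_guides[covered] >= 1).all()


def test_profile_tsv_round_trip(tmp_path, simulated_screen):
    lib = simulated_screen["library"]
    profile = tp.residue_profile(simulated_screen["scan"], lib)
    path = tmp_path / "profile.tsv"
    profile.to_tsv(path)
    back = tp.ResidueProfile.from_tsv(path)
    np.testing.assert_allclose(back.scores, profile.scores, atol=1e-12, equal_nan=True)
    np.testing.assert_array_equal(back.n_supporting_guides, profile.n_supporting_guides)
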
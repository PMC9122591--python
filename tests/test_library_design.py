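"""Library-design operations: complementarity patches, variant series,
native windows, restriction screening, barcodes, context reporters and
snoRNA retargeting."""

import numpy as np
import pytest

from oracles import all_pairs_min_hamming, check_duplex, pairs_antiparallel
from psimpra import (ContextReporter, PseudouridylationPocket, ReporterBackbone,
                     TargetConstruct, assign_barcodes, build_native_fragment,
                     build_plus1_series, build_synthetic_target,
                     build_u2g_control, design_native_library, design_ptc_snorna,
                     design_synthetic_library, enumerate_context_reporters,
                     screen_restriction_sites)
from psimpra.library_design import DEFAULT_BACKBONE, native_site_constructs
from psimpra.seqtools import hamming, revcomp


class TestSyntheticTarget:
    @pytest.mark.parametrize("level,up,down", [
        ("L3", 3, 2), ("L5", 5, 4), ("L8", 8, 8), ("L10", 10, 10),
    ])
    def test_patch_pairs_with_pocket(self, pocket_10_10, level, up, down):
        """The designed patch base-pairs antiparallel against both guide
        elements, with a U at the slot and an unpaired G at +1."""
        c = build_synthetic_target(pocket_10_10, level)
        patch = c.variable_seq[c.psi_index - up : c.psi_index + 2 + down]
        result = check_duplex(patch, pocket_10_10.guide5, pocket_10_10.guide3,
                              up, down)
        assert result["upstream_paired"] and result["downstream_paired"]
        assert result["u_is_t"] and result["plus1"] == "G"

    def test_worked_example_patch(self):
        """Psi-proximal guide3 bases AGT and guide5 bases AC at level L3
        give the patch ACT-U-G-GT (3 paired, U, unpaired G, 2 paired)."""
        pocket = PseudouridylationPocket("ex", 1, "GGAC", "AGTC")
        c = build_synthetic_target(pocket, "L3")
        i = c.psi_index
        assert c.variable_seq[i - 3 : i + 4] == "ACTTGGT"

    def test_l10_patch_length(self, pocket_10_10):
        c = build_synthetic_target(pocket_10_10, "L10")
        # 10 + U + G + 10 = 22 designed bases, everything else backbone
        diff = [i for i, (a, b) in
                enumerate(zip(c.variable_seq, DEFAULT_BACKBONE)) if a != b]
        assert all(c.psi_index - 10 <= i <= c.psi_index + 11 for i in diff)
        assert len(c.variable_seq) == len(DEFAULT_BACKBONE)

    def test_levels_nest(self, pocket_10_10):
        """L3 and L10 agree wherever their windows overlap."""
        c3 = build_synthetic_target(pocket_10_10, "L3")
        c10 = build_synthetic_target(pocket_10_10, "L10")
        i = c3.psi_index
        assert c3.variable_seq[i - 3 : i + 4] == c10.variable_seq[i - 3 : i + 4]

    def test_outside_patch_is_backbone(self, pocket_10_10):
        c = build_synthetic_target(pocket_10_10, "L5")
        i = c.psi_index
        assert c.variable_seq[: i - 5] == DEFAULT_BACKBONE[: i - 5]
        assert c.variable_seq[i + 6 :] == DEFAULT_BACKBONE[i + 6 :]

    def test_short_guides_truncate(self, pocket_short):
        """Windows longer than a guide are truncated to the guide and the
        construct flagged."""
        c = build_synthetic_target(pocket_short, "L10")
        assert c.truncated
        # guide3 has 4 nt and guide5 4 nt: patch is 4 + U + G + 4
        patch = c.variable_seq[c.psi_index - 4 : c.psi_index + 6]
        assert check_duplex(patch, pocket_short.guide5, pocket_short.guide3,
                            4, 4)["upstream_paired"]

    def test_guide_too_short_rejected(self):
        with pytest.raises(ValueError, match=r"\[2, 11\]"):
            PseudouridylationPocket("bad", 1, "A", "CAGT")

    def test_patch_overrun_names_construct(self, pocket_10_10):
        with pytest.raises(ValueError, match="snoA_a1_L10"):
            build_synthetic_target(pocket_10_10, "L10", backbone="ACGT" * 5,
                                   psi_slot=2)

    def test_unknown_level(self, pocket_10_10):
        with pytest.raises(ValueError, match="level"):
            build_synthetic_target(pocket_10_10, "L7")


class TestPlus1Series:
    def test_four_variants(self, pocket_10_10):
        c10 = build_synthetic_target(pocket_10_10, "L10")
        series = build_plus1_series(c10)
        assert [v.variant_class for v in series] == [
            "PLUS1_C", "PLUS1_A", "PLUS1_U", "PLUS1_DEL"]
        for v, base in zip(series[:3], "CAT"):
            assert hamming(v.variable_seq, c10.variable_seq) == 1
            assert v.variable_seq[c10.psi_index + 1] == base
        assert len(series[3].variable_seq) == len(c10.variable_seq) - 1
        # deletion shifts everything after +1 left by one
        assert (series[3].variable_seq[c10.psi_index + 1 :]
                == c10.variable_seq[c10.psi_index + 2 :])

    def test_deterministic(self, pocket_10_10):
        c10 = build_synthetic_target(pocket_10_10, "L10")
        a = build_plus1_series(c10)
        b = build_plus1_series(c10)
        assert [v.variable_seq for v in a] == [v.variable_seq for v in b]

    def test_rejects_non_l10(self, pocket_10_10):
        with pytest.raises(ValueError, match="L10"):
            build_plus1_series(build_synthetic_target(pocket_10_10, "L8"))


class TestU2GControl:
    def test_single_substitution(self, pocket_10_10):
        c = build_synthetic_target(pocket_10_10, "L10")
        ctrl = build_u2g_control(c)
        assert hamming(ctrl.variable_seq, c.variable_seq) == 1
        assert ctrl.variable_seq[c.psi_index] == "G"
        assert ctrl.psi_index is None
        assert ctrl.variant_class == "U2G_CONTROL"

    def test_native_maps_to_native_u2g(self):
        native = TargetConstruct("n1", "18S:100", "NATIVE", "A" * 41 + "T" + "C" * 33,
                                 psi_index=41)
        assert build_u2g_control(native).variant_class == "NATIVE_U2G"

    def test_requires_psi_index(self, pocket_10_10):
        ctrl = build_u2g_control(build_synthetic_target(pocket_10_10, "L10"))
        with pytest.raises(ValueError, match="psi_index"):
            build_u2g_control(ctrl)


class TestNativeFragment:
    def test_identity_window(self):
        mol = "G" * 41 + "T" + "A" * 33
        site = build_native_fragment("m", mol, 42)
        assert site.window_seq == mol
        assert len(site.window_seq) == 75

    def test_psi_at_position_42(self):
        mol = "C" * 200
        mol = mol[:120] + "T" + mol[121:]
        site = build_native_fragment("m", mol, 121)
        assert site.window_seq[41] == "T"  # 1-based position 42

    def test_shift_equivariance(self):
        rng = np.random.default_rng(7)
        mol = "".join(np.array(list("ACG"))[rng.integers(0, 3, 300)])
        mol = mol[:150] + "TT" + mol[152:]
        a = build_native_fragment("m", mol, 151)
        b = build_native_fragment("m", mol, 152)
        assert a.window_seq[1:] == b.window_seq[:-1]

    def test_edge_site_skipped(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="psimpra.library_design"):
            assert build_native_fragment("m", "T" * 60, 10) is None
        assert "skipped" in caplog.text

    def test_native_pair_includes_control(self):
        site = build_native_fragment("m", "G" * 41 + "T" + "A" * 33, 42)
        native, ctrl = native_site_constructs(site)
        assert native.variant_class == "NATIVE"
        assert ctrl.variant_class == "NATIVE_U2G"
        assert ctrl.variable_seq[41] == "G"


class TestRestrictionScreen:
    def test_ascl_site_omitted(self):
        assert screen_restriction_sites("AAGGCGCGCCTT", ["GGCGCGCC"]) is True

    def test_clean_sequence_kept(self):
        assert screen_restriction_sites("ACGACGACGACG", ["GGCGCGCC", "ACTAGT"]) is False

    def test_reverse_complement_detected(self):
        # non-palindromic probe site: present only on the minus strand
        site = "AACCGG"
        seq = "TTT" + revcomp(site) + "TTT"
        assert site not in seq
        assert screen_restriction_sites(seq, [site]) is True

    def test_empty_site_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            screen_restriction_sites("ACGT", [""])


class TestBarcodes:
    @staticmethod
    def _dummies(n):
        return [TargetConstruct(f"c{i}", "x", "NATIVE", "T" * 75, 41)
                for i in range(n)]

    def test_822_distinct_barcodes(self):
        constructs = self._dummies(822)
        codes = assign_barcodes(constructs, k=8, seed=11)
        assert len(set(codes)) == 822
        assert all(len(b) == 8 for b in codes)
        assert all(c.barcode in set(codes) for c in constructs)

    def test_min_pairwise_hamming(self):
        codes = assign_barcodes(self._dummies(200), k=8, seed=3)
        assert all_pairs_min_hamming(codes) >= 2

    def test_seed_determinism(self):
        a = assign_barcodes(self._dummies(50), k=8, seed=5)
        b = assign_barcodes(self._dummies(50), k=8, seed=5)
        assert a == b

    def test_no_restriction_site_in_barcode(self):
        codes = assign_barcodes(self._dummies(400), k=8, seed=2,
                                enzyme_sites=("ACTAGT",))
        assert all("ACTAGT" not in b and revcomp("ACTAGT") not in b for b in codes)

    def test_space_too_small(self):
        with pytest.raises(ValueError, match="barcode space"):
            assign_barcodes(self._dummies(17), k=2, seed=0)

    def test_space_exhausted_reports_progress(self):
        # k=2 with Hamming >= 2 supports at most 4 codes
        with pytest.raises(RuntimeError, match="assigning"):
            assign_barcodes(self._dummies(10), k=2, seed=0)


class TestContextReporters:
    def test_count_and_invariants(self):
        reps = enumerate_context_reporters()
        assert len(reps) == 729
        assert len({r.full_seq for r in reps}) == 729
        for r in reps[::81]:
            assert r.full_seq.count("T") == 1
            t = r.full_seq.index("T")
            assert r.full_seq[t + 1 : t + 7] == r.hexamer
            assert "T" not in r.full_seq[t - 40 : t]
            assert "T" not in r.full_seq[t + 7 : t + 7 + 64]

    def test_hexamers_are_full_product(self):
        import itertools
        reps = enumerate_context_reporters()
        expected = {"".join(p) for p in itertools.product("ACG", repeat=6)}
        assert {r.hexamer for r in reps} == expected

    def test_lexicographic_order(self):
        reps = enumerate_context_reporters()
        hexes = [r.hexamer for r in reps]
        assert hexes == sorted(hexes)

    def test_backbone_with_t_rejected(self):
        with pytest.raises(ValueError, match="contains a T"):
            ReporterBackbone(spacer="GACTCA")


class TestPtcSnorna:
    @staticmethod
    def _scaffold():
        """A toy scaffold with annotated pocket spans."""
        g5, g3 = "ACGTACGTAC", "GGATCCGATA"
        scaffold = "CCCC" + g5 + "AAAA" + g3 + "CCCC"
        pocket = PseudouridylationPocket(
            "ACA61", 1, g5, g3,
            guide5_span=(4, 14), guide3_span=(18, 28))
        return scaffold, pocket

    def test_length_preserved_and_replacement_count(self):
        scaffold, pocket = self._scaffold()
        window = "GCAGCAGCAG" + "T" + "A" + "GCGCGCGC" + "AA"
        out = design_ptc_snorna(scaffold, pocket, window, 10)
        assert len(out) == len(scaffold)
        diffs = [i for i, (a, b) in enumerate(zip(out, scaffold)) if a != b]
        # replaced positions stay within the psi-proximal 8 nt of guide5
        # (its 3' tail) and 3 nt of guide3 (its 5' head)
        assert set(diffs) <= set(range(6, 14)) | set(range(18, 21))

    def test_retargeted_pocket_pairs_target(self):
        scaffold, pocket = self._scaffold()
        window = "GCAGCAGCAG" + "T" + "A" + "GCGCGCGC" + "AA"
        out = design_ptc_snorna(scaffold, pocket, window, 10)
        new_g5_tail = out[6:14]
        new_g3_head = out[18:21]
        assert pairs_antiparallel(window[12:20], new_g5_tail)  # +2..+9
        assert pairs_antiparallel(window[7:10], new_g3_head)   # -3..-1

    def test_rejects_non_uridine_target(self):
        scaffold, pocket = self._scaffold()
        with pytest.raises(ValueError, match="expected U/T"):
            design_ptc_snorna(scaffold, pocket, "A" * 30, 10)

    def test_requires_annotated_spans(self, pocket_10_10):
        with pytest.raises(ValueError, match="spans"):
            design_ptc_snorna("A" * 50, pocket_10_10, "A" * 10 + "T" + "A" * 12, 10)


class TestLibraryAssembly:
    def test_synthetic_library_arithmetic(self):
        """n pockets -> 4 levels + 1 control each, +4 per +1-series pocket."""
        pockets = [PseudouridylationPocket(f"s{i}", 1, "ACGTACGTACG",
                                           "CAGTCAGTCAG") for i in range(6)]
        constructs, manifest = design_synthetic_library(
            pockets, plus1_pockets=["s0", "s1"], seed=0)
        assert len(constructs) == 6 * 5 + 2 * 4
        assert len(manifest) == len(constructs)
        assert (manifest["variant_class"] == "U2G_CONTROL").sum() == 6

    def test_full_seq_contains_variable_and_barcode(self):
        pockets = [PseudouridylationPocket("s0", 1, "ACGTACGTACG", "CAGTCAGTCAG")]
        constructs, _ = design_synthetic_library(pockets, seed=0)
        for c in constructs:
            assert c.variable_seq in c.full_seq
            assert c.barcode in c.full_seq

    def test_restriction_screen_flags_designs(self):
        """A backbone that embeds an AscI site marks every design omitted."""
        bad_backbone = DEFAULT_BACKBONE[:5] + "GGCGCGCC" + DEFAULT_BACKBONE[13:]
        pockets = [PseudouridylationPocket("s0", 1, "ACGTACGTACG", "CAGTCAGTCAG")]
        _, manifest = design_synthetic_library(pockets, backbone=bad_backbone,
                                               seed=0)
        assert manifest["omitted"].all()
        assert (manifest["omit_reason"] == "restriction_site").all()

    def test_native_library_counts_and_skips(self):
        rng = np.random.default_rng(0)
        seq = "".join(np.array(list("ACG"))[rng.integers(0, 3, 500)])
        seq = seq[:99] + "T" + seq[100:299] + "T" + seq[300:]
        sites = [("mol", 100), ("mol", 300), ("mol", 5)]  # last is unwindowable
        constructs, manifest = design_native_library(sites, {"mol": seq}, seed=0)
        assert len(constructs) == 4  # 2 windowable sites x (native + control)
        assert set(manifest["variant_class"]) == {"NATIVE", "NATIVE_U2G"}
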
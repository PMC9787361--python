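"""Cloverleaf decomposition, anomaly typing, catalogs, and the fold helper."""

import numpy as np
import pytest

from plastcmp.plastome_io import TaxonomyTable
from plastcmp.synthetic_data import _render_trna
from plastcmp.trna_struct import (FoldError, StructureParseError,
                                  TrnaStructure, catalog_variants,
                                  classify_structure, default_catalog, fold_trna,
                                  parse_cloverleaf)


def _render(kind, motif="", anticodon="GCU", seed=0):
    rng = np.random.default_rng(seed)
    seq, db, expected = _render_trna(rng, kind, motif, anticodon)
    return TrnaStructure(taxon="t", isotype="tRNA-Ser-GCU", sequence=seq,
                         structure=db), expected


class TestParseCloverleaf:
    def test_canonical_cloverleaf_has_four_arms_and_no_anomalies(self):
        t, _ = _render("typical")
        d = parse_cloverleaf(t)
        assert len(d.acceptor_pairs) == 7
        assert d.d_arm.loop_length == 8
        assert d.ac_arm.loop_length == 7
        assert d.t_arm.loop_length == 7
        assert d.v_length == 4
        assert d.anomalies == ()

    def test_paired_v_arm_is_long_v_arm_anomaly(self):
        t, _ = _render("v_arm_II", motif="UUA")
        d = parse_cloverleaf(t)
        assert d.v_arm is not None
        assert d.v_length >= 10
        assert "long-V-arm" in d.anomalies

    def test_bulge_in_ac_stem_is_extra_loop_anomaly(self):
        t, _ = _render("ac_extra", motif="UU")
        d = parse_cloverleaf(t)
        assert "extra-loop-at-AC-arm" in d.anomalies
        assert d.ac_arm.extra_loops[0][1] == "UU"

    def test_expanded_anticodon_loop_flagged(self):
        t, _ = _render("anc9")
        d = parse_cloverleaf(t)
        assert d.ac_arm.loop_length == 9
        assert "expanded-ANC-loop" in d.anomalies

    def test_bulge_in_t_stem_is_psi_arm_anomaly(self):
        t, _ = _render("t_extra", motif="GG")
        d = parse_cloverleaf(t)
        assert "extra-loop-at-psi-arm" in d.anomalies

    def test_unbalanced_brackets_raise(self):
        with pytest.raises(StructureParseError):
            parse_cloverleaf(TrnaStructure("t", "x", "ACGU", "(().") )

    def test_too_few_hairpins_raise(self):
        with pytest.raises(StructureParseError):
            parse_cloverleaf(TrnaStructure("t", "x", "GGGAAACCC", "(((...)))"))

    def test_anticodon_sits_at_loop_center_of_7nt_loop(self):
        t, _ = _render("typical", anticodon="UAC")
        d = parse_cloverleaf(t)
        lo, hi = d.anticodon_loop
        center = d.sequence[lo + 2:hi - 2]
        assert center == "UAC"


class TestClassification:
    @pytest.mark.parametrize("v_len,want", [(3, "intermediate"), (4, "I"), (5, "I"),
                                            (6, "intermediate"), (7, "intermediate"),
                                            (8, "intermediate"), (9, "intermediate"),
                                            (10, "II"), (11, "II"), (12, "II")])
    def test_v_arm_type_boundaries_exhaustive(self, v_len, want):
        rng = np.random.default_rng(1)
        # unpaired V region of exactly v_len nt
        seq, db, _ = _render_trna(rng, "typical", "", "GCU")
        d = parse_cloverleaf(TrnaStructure("t", "x", seq, db))
        v0, v1 = d.variable_region
        new_seq = seq[:v0] + "A" * v_len + seq[v1:]
        new_db = db[:v0] + "." * v_len + db[v1:]
        d2 = parse_cloverleaf(TrnaStructure("t", "x", new_seq, new_db))
        cls = classify_structure(d2)
        assert cls.v_arm_type == want

    def test_catalog_codes_for_planted_motifs(self):
        cat = default_catalog()
        t, _ = _render("v_arm_II", motif="AUA")
        d = parse_cloverleaf(TrnaStructure("t", "tRNA-Tyr-GUA", t.sequence, t.structure))
        assert classify_structure(d, cat).type_code == "C1"
        t2, _ = _render("anc9", anticodon="UAC")
        d2 = parse_cloverleaf(TrnaStructure("t", "tRNA-Val-UAC", t2.sequence, t2.structure))
        assert classify_structure(d2, cat).type_code == "E1"
        t3, _ = _render("typical", anticodon="UAC")
        d3 = parse_cloverleaf(TrnaStructure("t", "tRNA-Val-UAC", t3.sequence, t3.structure))
        assert classify_structure(d3, cat).type_code == "E2"

    def test_planted_classes_recovered_across_demo_set(self, demo):
        cat = default_catalog()
        for t in demo.trna:
            cls = classify_structure(parse_cloverleaf(t), cat)
            exp = demo.truth.trna_truth[t.taxon][t.isotype]
            assert cls.anc_loop_len == exp["anc_loop_len"]
            assert cls.v_arm_type == exp["v_arm_type"]
            assert cls.v_loop_seq == exp["v_loop_seq"]
            assert cls.ac_loop_extra == exp["ac_loop_extra"]
            assert cls.psi_loop_extra == exp["psi_loop_extra"]


class TestCatalogVariants:
    def _classes(self, demo):
        cat = default_catalog()
        classes = {}
        for t in demo.trna:
            cls = classify_structure(parse_cloverleaf(t), cat)
            classes.setdefault(t.taxon, {})[t.isotype] = cls
        return classes

    def test_planted_family_unique_and_variable_flags(self, demo, demo_taxonomy):
        patterns = catalog_variants(self._classes(demo), demo_taxonomy)
        flagged = {(p.family, p.isotype): (p.interfamilially_unique,
                                           p.intrafamilially_variable)
                   for p in patterns
                   if p.interfamilially_unique or p.intrafamilially_variable}
        assert flagged == {
            ("Fam01", "tRNA-Ser-GCU"): (True, False),
            ("Fam02", "tRNA-Ser-UGA"): (True, False),
            ("Fam03", "tRNA-Tyr-GUA"): (True, False),
            ("Fam04", "tRNA-Thr-UGU"): (True, False),
            ("Fam05", "tRNA-Cys-GCA"): (True, False),
            ("Fam06", "tRNA-Val-UAC"): (True, True),
            ("Fam07", "tRNA-Leu-UAA"): (True, False),
            ("Fam08", "tRNA-Leu-CAA"): (True, False),
        }

    def test_unique_flags_equal_set_difference_oracle(self, demo, demo_taxonomy):
        classes = self._classes(demo)
        patterns = catalog_variants(classes, demo_taxonomy)
        sigs = {}
        for taxon, per_iso in classes.items():
            fam = demo_taxonomy.family_of(taxon)
            for iso, cls in per_iso.items():
                sigs.setdefault((fam, iso), set()).add(cls.signature)
        for p in patterns:
            own = sigs[(p.family, p.isotype)]
            others = set()
            for (fam, iso), s in sigs.items():
                if iso == p.isotype and fam != p.family:
                    others |= s
            assert p.interfamilially_unique == bool(own - others)

    def test_identical_families_yield_no_flags(self):
        cat = default_catalog()
        classes = {}
        for fam, taxon in [("A", "a1"), ("A", "a2"), ("B", "b1")]:
            t, _ = _render("typical")
            cls = classify_structure(parse_cloverleaf(t), cat)
            classes[taxon] = {"tRNA-Ser-GCU": cls}
        tax = TaxonomyTable([("a1", "A"), ("a2", "A"), ("b1", "B")])
        for p in catalog_variants(classes, tax):
            assert not p.interfamilially_unique
            assert not p.intrafamilially_variable


class TestFold:
    def test_designed_sequence_recovers_planted_structure(self):
        # stems G/C only, every unpaired base A: no alternative pairing or
        # stem extension is possible, so the planted layout is the unique max
        seq = ("GGGGGGG" + "AA" + "GGGG" + "A" * 8 + "CCCC" + "A"
               + "GGGGG" + "A" * 7 + "CCCCC" + "AAAA"
               + "GGGGG" + "A" * 7 + "CCCCC" + "CCCCCCC" + "A")
        planted = ("(((((((" + ".." + "((((" + "." * 8 + "))))" + "."
                   + "(((((" + "." * 7 + ")))))" + "...."
                   + "(((((" + "." * 7 + ")))))" + ")))))))" + ".")
        folded = fold_trna(seq)
        assert folded.structure == planted

    def test_poly_a_has_no_cloverleaf(self):
        with pytest.raises(FoldError):
            fold_trna("A" * 72)

    def test_fold_parse_roundtrip(self):
        t, _ = _render("typical", seed=6)
        folded = fold_trna(t.sequence)
        d = parse_cloverleaf(folded)
        assert d.ac_arm.loop_length == 7
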
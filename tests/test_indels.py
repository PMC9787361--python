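"""Indel-event extraction, normalization, polarity, tallies, and SIC coding."""

import re

import numpy as np
import pytest

from plastcmp.indels import (AlignedMatrix, encode_sic, extract_indel_events,
                             family_unique, normalize_gaps, polarize_events,
                             polarity_shares, size_spectrum)
from plastcmp.plastome_io import TaxonomyTable
from plastcmp.synthetic_data import default_demo_config, gen_intron_alignment


def _aln(rows, taxa=None, locus="loc"):
    taxa = taxa or tuple(f"t{i + 1}" for i in range(len(rows)))
    return AlignedMatrix(locus=locus, taxa=tuple(taxa), rows=tuple(rows))


def _oracle_events(aln):
    """Independent maximal-gap-run extraction: regex runs per row, exact-
    coordinate grouping, then the single-position absorption rule."""
    grouped = {}
    for taxon, row in zip(aln.taxa, aln.rows):
        for m in re.finditer(r"-+", row):
            if m.start() == 0 or m.end() == len(row):
                continue  # terminal runs are missing data
            grouped.setdefault((m.start(), m.end()), set()).add(taxon)
    events = sorted(grouped.items())
    keep = []
    for (s, e), bearers in events:
        if e - s == 1:
            near = [1 for (s2, e2), b2 in events
                    if e2 - s2 > 1 and b2 == bearers
                    and max(s2 - e, s - e2) <= 1]
            if near:
                continue
        keep.append(((s, e), frozenset(bearers)))
    return keep


class TestExtraction:
    def test_shared_run_is_one_event(self):
        ev = extract_indel_events(_aln(["ACGTACGT", "ACG--CGT", "ACG--CGT"]))
        assert [(e.start, e.end, e.length_nt, set(e.bearers)) for e in ev] == \
            [(3, 5, 2, {"t2", "t3"})]

    def test_runs_with_different_ends_are_distinct_events(self):
        ev = extract_indel_events(_aln(["ACGTACGT", "ACG--CGT", "ACG---GT"]))
        assert [(e.start, e.end) for e in ev] == [(3, 5), (3, 6)]

    def test_terminal_gap_runs_are_not_events(self):
        assert extract_indel_events(_aln(["---ACGT", "ACGACGT", "ACGAC--"])) == []

    def test_single_flanking_column_is_absorbed(self):
        ev = extract_indel_events(_aln(["ACGTACGTA", "A--T-CGTA"]))
        assert [(e.start, e.end) for e in ev] == [(1, 3)]

    def test_all_gap_column_is_an_alignment_error(self):
        with pytest.raises(ValueError):
            extract_indel_events(_aln(["AC-GT", "AC-GT"]))

    def test_matches_brute_force_oracle_on_random_alignments(self):
        rng = np.random.default_rng(13)
        for _ in range(40):
            n = int(rng.integers(3, 10))
            length = int(rng.integers(20, 80))
            rows = []
            for _k in range(n):
                chars = rng.choice(list("ACGT"), size=length)
                gaps = rng.random(length) < 0.12
                rows.append("".join("-" if g else c for c, g in zip(chars, gaps)))
            # keep one ungapped row so no all-gap column can exist
            rows[0] = "".join(rng.choice(list("ACGT"), size=length))
            aln = _aln(rows)
            got = [((e.start, e.end), e.bearers) for e in extract_indel_events(aln)]
            assert got == _oracle_events(aln)


class TestNormalization:
    def test_flanking_repeat_gaps_align_to_same_columns(self):
        out = normalize_gaps(_aln(["AC--GT", "A--CGT"]))
        assert out.rows[0] == out.rows[1] == "A--CGT"

    def test_gapless_alignment_unchanged(self):
        aln = _aln(["ACGT", "ACGA"])
        assert normalize_gaps(aln).rows == aln.rows

    def test_non_slideable_gaps_unchanged(self):
        aln = _aln(["AG--GT", "AGCCGT"])
        assert normalize_gaps(aln).rows == aln.rows

    def test_every_row_content_preserved(self):
        rng = np.random.default_rng(14)
        for _ in range(25):
            rows = []
            for _k in range(4):
                chars = rng.choice(list("ACGT"), size=40)
                gaps = rng.random(40) < 0.15
                rows.append("".join("-" if g else c for c, g in zip(chars, gaps)))
            rows[0] = "".join(rng.choice(list("ACGT"), size=40))
            out = normalize_gaps(_aln(rows))
            for before, after in zip(rows, out.rows):
                assert before.replace("-", "") == after.replace("-", "")


class TestPolarity:
    def test_outgroup_residues_mean_deletion(self):
        aln = _aln(["ACGTACGT", "ACG--CGT", "ACG--CGT"], taxa=("og", "t2", "t3"))
        (ev,) = polarize_events(extract_indel_events(aln), aln, reference=["og"])
        assert ev.polarity == "deletion"

    def test_outgroup_gap_means_insertion(self):
        aln = _aln(["ACG--CGT", "ACGTACGT", "ACG--CGT"], taxa=("og", "t2", "t3"))
        (ev,) = polarize_events(extract_indel_events(aln), aln, reference=["og"])
        assert ev.polarity == "insertion"

    def test_majority_tie_is_ambiguous(self):
        aln = _aln(["ACGTACGT", "ACGTACGT", "ACG--CGT", "ACG--CGT"])
        (ev,) = polarize_events(extract_indel_events(aln), aln, reference="majority")
        assert ev.polarity == "ambiguous"

    def test_absent_outgroup_is_an_error(self):
        aln = _aln(["ACGTACGT", "ACG--CGT", "ACG--CGT"])
        with pytest.raises(ValueError):
            polarize_events(extract_indel_events(aln), aln, reference=["nope"])


class TestTallies:
    def test_size_spectrum_shares(self):
        aln = _aln(["ACGTACGTACGTACGTAAAA",
                    "AC-TACGTACGTACGTAAAA",
                    "ACGTA-----GTACGTAAAA",
                    "ACGTACGTAC-----TAAAA"])
        spectrum = size_spectrum(extract_indel_events(aln))
        five = spectrum[spectrum.length_nt == 5]
        assert five["count"].iloc[0] == 2
        assert five["share_pct"].iloc[0] == pytest.approx(100 * 2 / 3)

    def test_empty_event_list_gives_empty_histogram(self):
        assert size_spectrum([]).empty

    def test_polarity_shares(self):
        aln = _aln(["ACGTACGT", "ACG--CGT", "ACG--CGT"], taxa=("og", "t2", "t3"))
        events = polarize_events(extract_indel_events(aln), aln, reference=["og"])
        assert polarity_shares(events) == {"deletion": 100.0}


class TestFamilyUnique:
    tax = TaxonomyTable([("a1", "A"), ("a2", "A"), ("b1", "B"), ("b2", "B")])

    def _events(self, rows, taxa):
        aln = _aln(rows, taxa=taxa)
        return extract_indel_events(aln), aln

    def test_whole_family_deletion_is_unique_in_both_modes(self):
        events, aln = self._events(
            ["ACGTACGT", "ACG--CGT", "ACG--CGT", "ACGTACGT", "ACGTACGT"],
            ("og", "a1", "a2", "b1", "b2"))
        events = polarize_events(events, aln, reference=["og"])
        for mode in ("strict", "relaxed"):
            table = family_unique(events, self.tax, mode=mode, outgroups=["og"],
                                  all_taxa={"a1", "a2", "b1", "b2", "og"})
            assert table.set_index("family").total_count.to_dict() == {"A": 1, "B": 0}

    def test_partial_family_counts_only_in_relaxed_mode(self):
        events, aln = self._events(
            ["ACGTACGT", "ACG--CGT", "ACGTACGT", "ACGTACGT", "ACGTACGT"],
            ("og", "a1", "a2", "b1", "b2"))
        events = polarize_events(events, aln, reference=["og"])
        strict = family_unique(events, self.tax, mode="strict", outgroups=["og"],
                               all_taxa={"a1", "a2", "b1", "b2", "og"})
        relaxed = family_unique(events, self.tax, mode="relaxed", outgroups=["og"],
                                all_taxa={"a1", "a2", "b1", "b2", "og"})
        assert strict.set_index("family").total_count.to_dict() == {"A": 0, "B": 0}
        assert relaxed.set_index("family").total_count.to_dict() == {"A": 1, "B": 0}

    def test_event_spanning_two_families_is_not_unique(self):
        events, aln = self._events(
            ["ACGTACGT", "ACG--CGT", "ACGTACGT", "ACG--CGT", "ACGTACGT"],
            ("og", "a1", "a2", "b1", "b2"))
        events = polarize_events(events, aln, reference=["og"])
        table = family_unique(events, self.tax, outgroups=["og"],
                              all_taxa={"a1", "a2", "b1", "b2", "og"})
        assert table.total_count.sum() == 0

    def test_family_unique_insertion_attributed_to_residue_carriers(self):
        # residues confined to family A; everyone else gapped (incl. outgroup)
        events, aln = self._events(
            ["ACG--CGT", "ACGTACGT", "ACGTACGT", "ACG--CGT", "ACG--CGT"],
            ("og", "a1", "a2", "b1", "b2"))
        events = polarize_events(events, aln, reference=["og"])
        assert events[0].polarity == "insertion"
        table = family_unique(events, self.tax, mode="strict", outgroups=["og"],
                              all_taxa={"a1", "a2", "b1", "b2", "og"})
        assert table.set_index("family").total.to_dict() == {"A": "1/0/1", "B": "0/0/0"}

    def test_unmapped_taxon_is_an_error_naming_it(self):
        events, aln = self._events(
            ["ACGTACGT", "ACG--CGT", "ACGTACGT", "ACGTACGT", "ACGTACGT"],
            ("og", "zz", "a2", "b1", "b2"))
        events = polarize_events(events, aln, reference=["og"])
        with pytest.raises(ValueError, match="zz"):
            family_unique(events, self.tax, mode="relaxed", outgroups=["og"],
                          all_taxa={"zz", "a2", "b1", "b2", "og"})


class TestSic:
    def test_binary_column_for_simple_event(self):
        aln = _aln(["ACGTACGT", "ACG--CGT", "ACG--CGT", "ACGTACGT", "ACGTACGT"])
        m = encode_sic(extract_indel_events(aln), aln)
        assert m.states == ("0", "1", "1", "0", "0")

    def test_nested_event_scores_inapplicable_for_enclosing_taxon(self):
        aln = _aln(["ACGTACGTAA", "AC------AA", "ACG--CGTAA"])
        events = extract_indel_events(aln)
        m = encode_sic(events, aln)
        frame = m.to_frame()
        inner = f"loc:3-5"
        assert frame.loc["t2", inner] == "?"
        assert frame.loc["t3", inner] == "1"
        assert frame.loc["t1", inner] == "0"

    def test_no_events_gives_empty_matrix(self):
        aln = _aln(["ACGT", "ACGA"])
        assert encode_sic([], aln).to_frame().shape == (2, 0)


class TestPlantedRecovery:
    def test_exact_recovery_over_many_seeds(self):
        """Planted events come back with exact coordinates, bearers and
        polarity on every seed."""
        for seed in range(50):
            cfg = default_demo_config(seed=seed)
            names, rows, truth = gen_intron_alignment(cfg, "ndhA", cfg.all_taxa())
            aln = AlignedMatrix("ndhA", tuple(names), tuple(rows))
            aln = normalize_gaps(aln)
            events = polarize_events(extract_indel_events(aln), aln,
                                     reference=["Outgroup_1"])
            got = {(e.start, e.end, e.polarity, tuple(sorted(e.bearers)))
                   for e in events}
            want = {(t["start"], t["end"], t["polarity"], tuple(t["bearers"]))
                    for t in truth}
            assert got == want
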
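"""Indel-event extraction and coding from intron alignments.

An *indel event* is a maximal gap run with identical alignment
coordinates shared by one or more taxa.  Events are the unit of the
downstream analyses: polarity (insertion vs deletion) relative to an
outgroup or the majority state, size spectra, per-locus distributions,
family-unique markers, and simple indel coding (SIC) — one binary
presence/absence character per distinct-coordinate gap, with gaps nested
inside a longer gap of another taxon scored inapplicable ('?').

Two alignment-hygiene rules precede event counting:

* gap runs that can slide within a flanking repeat are left-justified so
  that equivalent gaps occupy identical columns across rows
  (:func:`normalize_gaps`);
* a single-column gap run immediately adjacent to an event borne by the
  same taxon set is absorbed into that event rather than counted as an
  independent single-base event; terminal (leading/trailing) gap runs
  are missing data, never events.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .plastome_io import TaxonomyTable

__all__ = [
    "AlignedMatrix",
    "IndelEvent",
    "IndelCharacterMatrix",
    "normalize_gaps",
    "extract_indel_events",
    "polarize_events",
    "size_spectrum",
    "family_unique",
    "encode_sic",
    "events_table",
    "locus_distribution",
    "polarity_shares",
]

GAP = "-"


@dataclass(frozen=True)
class AlignedMatrix:
    """One locus alignment: ordered taxa and equal-length gapped rows."""

    locus: str
    taxa: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows differ in count")
        if len(set(map(len, self.rows))) > 1:
            raise ValueError("rows differ in length")
        for taxon, row in zip(self.taxa, self.rows):
            if row and set(row) == {GAP}:
                raise ValueError(f"all-gap row for taxon {taxon}")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row_of(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]


@dataclass(frozen=True)
class IndelEvent:
    """A maximal shared gap block: coordinates, bearers, size, polarity."""

    locus: str
    start: int
    end: int   # half-open alignment columns
    bearers: frozenset[str]
    polarity: str = "unpolarized"  # insertion | deletion | ambiguous | unpolarized
    id: int = -1

    @property
    def length_nt(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class IndelCharacterMatrix:
    """taxa × events; states '0' (no gap), '1' (gap), '?' (nested/inapplicable)."""

    taxa: tuple[str, ...]
    events: tuple[IndelEvent, ...]
    states: tuple[str, ...]  # one string of {0,1,?} per taxon

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{e.locus}:{e.start}-{e.end}" for e in self.events]
        return pd.DataFrame([list(s) for s in self.states], index=list(self.taxa),
                            columns=cols)


# ---------------------------------------------------------------------------
# gap runs


def _gap_runs(row: str) -> list[tuple[int, int]]:
    """Maximal gap runs of one row as half-open column intervals."""
    runs, start = [], None
    for i, ch in enumerate(row):
        if ch == GAP:
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(row)))
    return runs


def _internal_runs(row: str) -> list[tuple[int, int]]:
    """Gap runs excluding terminal (leading/trailing) runs."""
    return [(s, e) for s, e in _gap_runs(row) if s > 0 and e < len(row)]


# ---------------------------------------------------------------------------
# normalization


def _column_residues(rows: list[str], col: int, skip: int) -> set[str]:
    return {r[col] for k, r in enumerate(rows) if k != skip and r[col] != GAP}


def normalize_gaps(aln: AlignedMatrix) -> AlignedMatrix:
    """Left-justify slideable gap runs so equivalent gaps share columns.

    A gap run may slide one column left when the residue immediately to
    its left can equally be placed at the run's right end — i.e. every
    residue-bearing row agrees at that destination column (flanking
    repeat ambiguity).  Sliding never changes any row's ungapped
    sequence.  Terminal runs are left untouched.
    """
    rows = [list(r) for r in aln.rows]
    changed = True
    while changed:
        changed = False
        for k, row in enumerate(rows):
            for s, e in _internal_runs("".join(row)):
                while s > 0 and row[s - 1] != GAP:
                    moving = row[s - 1]
                    dest = _column_residues(["".join(r) for r in rows], e - 1, k)
                    if dest and dest == {moving}:
                        row[s - 1], row[e - 1] = GAP, moving
                        s, e = s - 1, e - 1
                        changed = True
                    else:
                        break
    return AlignedMatrix(locus=aln.locus, taxa=aln.taxa,
                         rows=tuple("".join(r) for r in rows))


# ---------------------------------------------------------------------------
# event extraction


def extract_indel_events(aln: AlignedMatrix, min_flank: int = 1) -> list[IndelEvent]:
    """Group identical-coordinate internal gap runs into indel events.

    Runs with the same (start, end) across taxa are one event with the
    union bearer set.  A single-column event lying within one column of a
    longer event borne by exactly the same taxa is absorbed into that
    event (the single flanking position is not an independent event).
    Events are sorted by (start, end); ids are ordinal.
    """
    if aln.length and any(all(r[c] == GAP for r in aln.rows) for c in range(aln.length)):
        raise ValueError(f"{aln.locus}: all-gap column present; trim the alignment")
    grouped: dict[tuple[int, int], set[str]] = {}
    for taxon, row in zip(aln.taxa, aln.rows):
        for run in _internal_runs(row):
            grouped.setdefault(run, set()).add(taxon)
    events = [IndelEvent(locus=aln.locus, start=s, end=e, bearers=frozenset(b))
              for (s, e), b in grouped.items()]
    events.sort(key=lambda ev: (ev.start, ev.end))

    # single-position rule: a 1-column run is not an independent event when
    # a longer event with the same bearer set lies within min_flank columns
    absorbed: set[int] = set()
    for i, ev in enumerate(events):
        if ev.length_nt != 1:
            continue
        for other in events:
            if other.length_nt <= 1 or other.bearers != ev.bearers:
                continue
            gap = max(other.start - ev.end, ev.start - other.end)
            if gap <= min_flank:
                absorbed.add(i)
                break
    events = [ev for i, ev in enumerate(events) if i not in absorbed]
    return [replace(ev, id=i) for i, ev in enumerate(events)]


# ---------------------------------------------------------------------------
# polarity


def _event_state(row: str, ev: IndelEvent) -> str:
    """'gap' | 'residue' | 'mixed' of one row over the event columns."""
    chars = set(row[ev.start:ev.end])
    if chars == {GAP}:
        return "gap"
    if GAP in chars:
        return "mixed"
    return "residue"


def polarize_events(events: list[IndelEvent], aln: AlignedMatrix,
                    reference: list[str] | str = "majority") -> list[IndelEvent]:
    """Assign insertion/deletion polarity to each event.

    With outgroup taxa given, the event is a *deletion* when the outgroup
    carries residues at its columns, an *insertion* when the outgroup is
    gapped, and *ambiguous* when outgroups disagree or are partially
    gapped.  In ``majority`` mode the reference state is the majority
    row-state over all taxa; a tie is ambiguous.
    """
    out = []
    if reference == "majority":
        if len(aln.taxa) < 3:
            raise ValueError("majority polarization needs at least 3 taxa")
        for ev in events:
            states = [_event_state(r, ev) for r in aln.rows]
            n_gap = states.count("gap")
            n_res = states.count("residue")
            if n_res > n_gap:
                pol = "deletion"
            elif n_gap > n_res:
                pol = "insertion"
            else:
                pol = "ambiguous"
            out.append(replace(ev, polarity=pol))
        return out
    outgroups = [reference] if isinstance(reference, str) else list(reference)
    for og in outgroups:
        if og not in aln.taxa:
            raise ValueError(f"outgroup taxon {og!r} absent from alignment")
    for ev in events:
        states = {_event_state(aln.row_of(og), ev) for og in outgroups}
        if states == {"residue"}:
            pol = "deletion"
        elif states == {"gap"}:
            pol = "insertion"
        else:
            pol = "ambiguous"
        out.append(replace(ev, polarity=pol))
    return out


# ---------------------------------------------------------------------------
# tallies


def size_spectrum(events: list[IndelEvent]) -> pd.DataFrame:
    """Histogram of event lengths with percentage shares.

    Columns: length_nt, count, share_pct, cumulative_pct.  The share of
    events of at most 10 nt is ``spectrum.attrs['share_le_10nt']``.
    """
    lengths = sorted(ev.length_nt for ev in events)
    if not lengths:
        df = pd.DataFrame(columns=["length_nt", "count", "share_pct", "cumulative_pct"])
        df.attrs["share_le_10nt"] = float("nan")
        return df
    counts = pd.Series(lengths).value_counts().sort_index()
    total = counts.sum()
    df = pd.DataFrame({"length_nt": counts.index, "count": counts.to_numpy()})
    df["share_pct"] = 100.0 * df["count"] / total
    df["cumulative_pct"] = df["share_pct"].cumsum()
    df.attrs["share_le_10nt"] = float(100.0 * sum(c for l, c in counts.items() if l <= 10) / total)
    return df


def polarity_shares(events: list[IndelEvent]) -> dict[str, float]:
    """Percentage of events per polarity class."""
    if not events:
        return {}
    pols = [ev.polarity for ev in events]
    return {p: 100.0 * pols.count(p) / len(pols) for p in sorted(set(pols))}


def locus_distribution(events: list[IndelEvent]) -> pd.DataFrame:
    """Per-locus event counts and percentage shares, descending."""
    if not events:
        return pd.DataFrame(columns=["locus", "count", "share_pct"])
    loci = pd.Series([ev.locus for ev in events]).value_counts()
    df = pd.DataFrame({"locus": loci.index, "count": loci.to_numpy()})
    df["share_pct"] = 100.0 * df["count"] / len(events)
    return df


def marker_taxa(ev: IndelEvent, all_taxa: set[str],
                outgroups: set[str] | None = None) -> frozenset[str]:
    """The taxa an event distinguishes: gap bearers for deletions, residue
    carriers for insertions (the inserted sequence is what marks them)."""
    outgroups = outgroups or set()
    if ev.polarity == "insertion":
        return frozenset(all_taxa - set(ev.bearers) - outgroups)
    return frozenset(set(ev.bearers) - outgroups)


def family_unique(events: list[IndelEvent], taxonomy: TaxonomyTable,
                  mode: str = "strict",
                  outgroups: list[str] | None = None,
                  all_taxa: set[str] | None = None) -> pd.DataFrame:
    """Family-unique indel counts per locus, split by polarity.

    ``strict``: the event's marker taxa are exactly the family's taxa;
    ``relaxed``: a non-empty subset of one family with no outsiders.
    Output has one row per family with per-locus "ins/del/total" cells
    plus grand totals.  An event whose marker taxa include an unmapped
    taxon raises an error naming it.
    """
    if mode not in ("strict", "relaxed"):
        raise ValueError(f"unknown mode {mode!r}")
    og = set(outgroups or [])
    universe = set(all_taxa) if all_taxa is not None else {t for t, _ in taxonomy.items()} | og
    fam_taxa = {fam: set(taxonomy.taxa_of(fam)) for fam in taxonomy.families()}
    loci = sorted({ev.locus for ev in events})
    counts: dict[str, dict[str, list[int]]] = {
        fam: {loc: [0, 0] for loc in loci} for fam in fam_taxa}  # [ins, del]
    for ev in events:
        markers = marker_taxa(ev, universe, og)
        if not markers:
            continue
        for t in markers:
            if t not in taxonomy:
                raise ValueError(f"taxon {t!r} has no family assignment")
        fams = {taxonomy.family_of(t) for t in markers}
        if len(fams) != 1:
            continue
        fam = fams.pop()
        if mode == "strict" and markers != frozenset(fam_taxa[fam]):
            continue
        slot = 0 if ev.polarity == "insertion" else 1
        counts[fam][ev.locus][slot] += 1
    rows = []
    for fam in sorted(fam_taxa):
        row: dict[str, object] = {"family": fam}
        tot_ins = tot_del = 0
        for loc in loci:
            ins, dele = counts[fam][loc]
            tot_ins += ins
            tot_del += dele
            row[loc] = f"{ins}/{dele}/{ins + dele}"
        row["total"] = f"{tot_ins}/{tot_del}/{tot_ins + tot_del}"
        row["total_count"] = tot_ins + tot_del
        rows.append(row)
    return pd.DataFrame(rows, columns=["family", *loci, "total", "total_count"])


# ---------------------------------------------------------------------------
# simple indel coding


def encode_sic(events: list[IndelEvent], aln: AlignedMatrix) -> IndelCharacterMatrix:
    """Simple indel coding: one binary character per event.

    A taxon scores '1' when its row is gapped at exactly the event's
    columns as a complete run, '0' when it carries residues there, and
    '?' when its own gap run strictly contains the event (the character
    is inapplicable inside a longer deletion).
    """
    runs_by_taxon = {t: _gap_runs(r) for t, r in zip(aln.taxa, aln.rows)}
    states = []
    for taxon, row in zip(aln.taxa, aln.rows):
        chars = []
        for ev in events:
            if taxon in ev.bearers:
                chars.append("1")
                continue
            enclosing = any(s <= ev.start and ev.end <= e and (s, e) != (ev.start, ev.end)
                            for s, e in runs_by_taxon[taxon])
            if enclosing:
                chars.append("?")
            else:
                chars.append("0")
        states.append("".join(chars))
    return IndelCharacterMatrix(taxa=aln.taxa, events=tuple(events),
                                states=tuple(states))


def events_table(events: list[IndelEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"id": ev.id, "locus": ev.locus, "start": ev.start, "end": ev.end,
          "length_nt": ev.length_nt, "bearers": ",".join(sorted(ev.bearers)),
          "polarity": ev.polarity} for ev in events],
        columns=["id", "locus", "start", "end", "length_nt", "bearers", "polarity"])
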
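"""IR junction expansion/contraction profiling and family pattern typing.

The four junctions of the quadripartite plastome are named after the
regions they separate: JLB (LSC|IRb), JSB (IRb|SSC), JSA (SSC|IRa) and
JLA (IRa|LSC).  A focal gene at each junction either *spans* it (the IR
boundary falls inside the gene body — an IR expansion into the gene),
*abuts* it, or lies entirely on one side (a contraction leaves the gene
on the single-copy side).  Family-level combinations of the rps19 state
at JLB and the ndhF state at JSB are condensed into a six-way pattern
code.

Expansion/contraction is defined purely geometrically relative to the
focal gene (no ancestral IR length is assumed): expansion means the
junction falls inside the gene body, contraction means the gene sits
entirely on the single-copy side.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .plastome_io import GeneFeature, PlastomeRecord, RegionMap, TaxonomyTable

__all__ = [
    "JunctionGeneState",
    "JunctionProfile",
    "FamilyJunctionPattern",
    "DEFAULT_FOCAL_GENES",
    "junction_profile",
    "classify_pattern",
    "check_conserved_features",
    "profiles_table",
]

DEFAULT_FOCAL_GENES = {
    "JLB": "rps19",
    "JSB": "ndhF",
    "JSA": "ycf1",
    "JLA": "trnH-GUG",
}

# IR region bordering each junction
_IR_SIDE = {"JLB": "IRb", "JSB": "IRb", "JSA": "IRa", "JLA": "IRa"}


@dataclass(frozen=True)
class JunctionGeneState:
    junction: str
    position: int            # 0-based boundary position
    gene: str
    state: str               # spans | abuts | single-copy-side | ir-side | pseudo-fragment | gene-missing
    overlap_bp: int          # gene bases on the IR side of the junction
    distance_bp: int | None  # gap between gene end and junction when not overlapping


@dataclass(frozen=True)
class JunctionProfile:
    record_id: str
    taxon: str
    states: dict[str, JunctionGeneState]

    def __getitem__(self, junction: str) -> JunctionGeneState:
        return self.states[junction]


@dataclass(frozen=True)
class FamilyJunctionPattern:
    family: str
    rps19_at_jlb: str   # expansion | contraction | mixed
    ndhf_at_jsb: str
    pattern_id: int


def _junction_positions(rm: RegionMap) -> dict[str, int]:
    """Boundary positions: each junction is the start of its downstream region."""
    return {"JLB": rm.irb[0], "JSB": rm.ssc[0], "JSA": rm.ira[0], "JLA": rm.lsc[0]}


def _circular_arc(feature: GeneFeature, n: int) -> tuple[int, int]:
    """Gene body as a circular arc (start, length); introns included."""
    positions = sorted(feature.positions())
    lo, hi = positions[0], positions[-1] + 1
    direct = hi - lo
    if direct <= n - direct:
        return lo, direct
    # gene wraps the origin: start after the largest internal position gap
    best_gap, start = -1, lo
    for a, b in zip(positions, positions[1:]):
        if b - a - 1 > best_gap:
            best_gap, start = b - a - 1, b
    if best_gap <= 0:
        return lo, direct
    return start, n - best_gap


def _arc_distance_to_boundary(start: int, length: int, p: int, n: int) -> int:
    """0 if boundary p is inside/at the edge of the arc, else circular gap."""
    off = (p - start) % n
    if off <= length:
        return 0
    return min((off - length) % n, (start - p) % n)


def _ir_overlap(feature: GeneFeature, rm: RegionMap, ir_name: str) -> int:
    region = rm.irb if ir_name == "IRb" else rm.ira
    s, e = region
    n = rm.genome_length
    count = 0
    for pos in feature.positions():
        if s <= e:
            inside = s <= pos < e
        else:
            inside = pos >= s or pos < e
        if inside:
            count += 1
    return count


def _nearest_feature(candidates: list[GeneFeature], p: int, n: int) -> GeneFeature:
    def key(f: GeneFeature):
        start, length = _circular_arc(f, n)
        return (_arc_distance_to_boundary(start, length, p, n), start)

    return min(candidates, key=key)


def junction_profile(record: PlastomeRecord,
                     focal_genes: dict[str, str] | None = None) -> JunctionProfile:
    """Profile the focal gene at each of the four IR junctions.

    For every junction the nearest annotated copy of the focal gene is
    located and its geometric relation to the boundary is reported.  A
    pseudo-flagged copy (the truncated duplicate that IR expansion copies
    to the mirrored junction) is reported as ``pseudo-fragment``.  A
    missing focal gene yields state ``gene-missing`` rather than an
    exception.
    """
    if record.regions is None:
        raise ValueError("regions not inferred; call infer_regions first")
    rm = record.regions
    n = rm.genome_length
    focal = dict(DEFAULT_FOCAL_GENES)
    if focal_genes:
        focal.update(focal_genes)
    boundaries = _junction_positions(rm)
    states: dict[str, JunctionGeneState] = {}
    for junction, gene in focal.items():
        p = boundaries[junction]
        candidates = record.features_named(gene)
        if not candidates:
            states[junction] = JunctionGeneState(junction, p, gene, "gene-missing", 0, None)
            continue
        feat = _nearest_feature(candidates, p, n)
        start, length = _circular_arc(feat, n)
        ov = _ir_overlap(feat, rm, _IR_SIDE[junction])
        dist = _arc_distance_to_boundary(start, length, p, n)
        if feat.pseudo:
            state = "pseudo-fragment"
        elif 0 < ov < feat.length:
            state = "spans"
        elif ov == feat.length:
            state = "ir-side"
        elif dist == 0:
            state = "abuts"
        else:
            state = "single-copy-side"
        states[junction] = JunctionGeneState(
            junction, p, gene, state, ov,
            None if state == "spans" else dist)
    return JunctionProfile(record_id=record.id, taxon=record.taxon, states=states)


def _per_record_call(state: JunctionGeneState) -> str | None:
    """expansion/contraction call for one record at one junction."""
    if state.state in ("spans", "ir-side"):
        return "expansion"
    if state.state in ("single-copy-side", "abuts"):
        return "contraction"
    return None  # gene-missing or pseudo-fragment: uninformative


def _aggregate(calls: list[str]) -> str:
    if calls and all(c == "expansion" for c in calls):
        return "expansion"
    if calls and all(c == "contraction" for c in calls):
        return "contraction"
    return "mixed"


_PATTERN_IDS = {
    ("expansion", "contraction"): 1,
    ("contraction", "expansion"): 2,
    ("mixed", "expansion"): 3,
    ("expansion", "expansion"): 4,
    ("contraction", "contraction"): 5,
}


def classify_pattern(profiles: list[JunctionProfile],
                     taxonomy: TaxonomyTable) -> list[FamilyJunctionPattern]:
    """Six-way family pattern from the rps19@JLB and ndhF@JSB states.

    Per family the per-record calls are aggregated with no majority rule:
    a single deviating record makes the junction ``mixed``.  Pattern ids:
    1 = (expansion, contraction), 2 = (contraction, expansion),
    3 = (mixed, expansion), 4 = (expansion, expansion),
    5 = (contraction, contraction); every remaining combination involving
    heterogeneity at both or either junction collapses to 6.
    """
    by_family: dict[str, list[JunctionProfile]] = {}
    for prof in profiles:
        fam = taxonomy.get(prof.taxon)
        if fam is None:
            continue
        by_family.setdefault(fam, []).append(prof)
    patterns = []
    for fam, profs in by_family.items():
        rps19 = [_per_record_call(p["JLB"]) for p in profs]
        ndhf = [_per_record_call(p["JSB"]) for p in profs]
        rps19 = [c for c in rps19 if c is not None]
        ndhf = [c for c in ndhf if c is not None]
        if not rps19 and not ndhf:
            continue
        a, b = _aggregate(rps19), _aggregate(ndhf)
        patterns.append(FamilyJunctionPattern(
            family=fam, rps19_at_jlb=a, ndhf_at_jsb=b,
            pattern_id=_PATTERN_IDS.get((a, b), 6)))
    return sorted(patterns, key=lambda p: p.family)


def check_conserved_features(profiles: list[JunctionProfile],
                             records: list[PlastomeRecord] | None = None) -> pd.DataFrame:
    """Flags for the two order-wide conserved junction features.

    (a) ycf1 spans JSA with 400–1870 bp of its body inside IRa;
    (b) trnH-GUG overlaps IRa by exactly 3 bp, at its 3' terminus.
    The 3'-terminus test is strand-aware and needs the records; without
    them the overlap size alone is checked.
    """
    by_id = {r.id: r for r in records} if records else {}
    rows = []
    for prof in profiles:
        ycf1 = prof["JSA"]
        trnh = prof["JLA"]
        flag_a = ycf1.state == "spans" and 400 <= ycf1.overlap_bp <= 1870
        flag_b = trnh.overlap_bp == 3 and trnh.state == "spans"
        rec = by_id.get(prof.record_id)
        if flag_b and rec is not None:
            flag_b = _trnh_3prime_in_ira(rec)
        rows.append({"record": prof.record_id, "taxon": prof.taxon,
                     "ycf1_jsa_400_1870": flag_a, "trnh_3prime_3bp_ira": flag_b,
                     "ycf1_overlap_bp": ycf1.overlap_bp,
                     "trnh_overlap_bp": trnh.overlap_bp})
    return pd.DataFrame(rows)


def _trnh_3prime_in_ira(record: PlastomeRecord) -> bool:
    rm = record.regions
    n = rm.genome_length
    feats = record.features_named("trnH-GUG")
    if not feats:
        return False
    feat = _nearest_feature(feats, rm.lsc[0], n)
    start, length = _circular_arc(feat, n)
    if feat.strand == "+":
        terminal = [(start + length - 3 + k) % n for k in range(3)]
    else:
        terminal = [(start + k) % n for k in range(3)]
    return all(rm.region_of(pos) == "IRa" for pos in terminal)


def profiles_table(profiles: list[JunctionProfile]) -> pd.DataFrame:
    rows = []
    for prof in profiles:
        for junction, st in prof.states.items():
            rows.append({"record": prof.record_id, "taxon": prof.taxon,
                         "junction": junction, "gene": st.gene, "state": st.state,
                         "overlap_bp": st.overlap_bp, "distance_bp": st.distance_bp})
    return pd.DataFrame(rows)
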
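"""Parsing, validation and summary of annotated plastome records.

A plastome is a circular quadripartite genome: a large single-copy region
(LSC), one inverted-repeat copy (IRb), a small single-copy region (SSC)
and the second, reverse-complement inverted-repeat copy (IRa).  This
module parses GenBank-style flat files into :class:`PlastomeRecord`
objects, infers the quadripartite :class:`RegionMap` directly from the
sequence (maximal disjoint reverse-complement repeat pair), and produces
per-record size/GC summaries.

Coordinates are 0-based half-open genome coordinates throughout; flat-file
1-based inclusive positions are converted at the parsing boundary.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "GeneFeature",
    "RegionMap",
    "PlastomeRecord",
    "TaxonomyTable",
    "PlastomeParseError",
    "parse_plastome",
    "parse_plastomes",
    "infer_regions",
    "summarize",
    "summarize_table",
    "read_taxonomy",
    "gc_percent",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class PlastomeParseError(ValueError):
    """Raised when a flat-file record cannot be interpreted."""


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene with its exon structure.

    ``exons`` are (start, end) intervals in genome coordinates, listed in
    transcription (5'->3') order.  A gene wrapping the circular origin is
    represented by two intervals meeting at the origin.
    """

    name: str
    kind: str  # PCG | tRNA | rRNA
    strand: str  # '+' | '-'
    exons: tuple[tuple[int, int], ...]
    pseudo: bool = False

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"feature {self.name}: no exons")
        for s, e in self.exons:
            if not (0 <= s < e):
                raise ValueError(f"feature {self.name}: bad exon ({s},{e})")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def positions(self) -> set[int]:
        """All genome positions covered by the gene body."""
        out: set[int] = set()
        for s, e in self.exons:
            out.update(range(s, e))
        return out


@dataclass(frozen=True)
class RegionMap:
    """The quadripartite partition of a circular plastome.

    Intervals are 0-based half-open and may wrap the origin (start > end
    means the interval crosses position 0).  The four intervals tile the
    circle exactly once and the two IR copies are reverse complements.
    """

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    genome_length: int

    def interval_length(self, iv: tuple[int, int]) -> int:
        s, e = iv
        return e - s if s <= e else self.genome_length - s + e

    @property
    def lsc_length(self) -> int:
        return self.interval_length(self.lsc)

    @property
    def ir_length(self) -> int:
        return self.interval_length(self.irb)

    @property
    def ssc_length(self) -> int:
        return self.interval_length(self.ssc)

    def interval_positions(self, iv: tuple[int, int]) -> range | list[int]:
        s, e = iv
        if s <= e:
            return range(s, e)
        return list(range(s, self.genome_length)) + list(range(0, e))

    def region_of(self, pos: int) -> str:
        for name, iv in (("LSC", self.lsc), ("IRb", self.irb),
                         ("SSC", self.ssc), ("IRa", self.ira)):
            s, e = iv
            if s <= e:
                if s <= pos < e:
                    return name
            elif pos >= s or pos < e:
                return name
        raise ValueError(f"position {pos} outside genome of length {self.genome_length}")


@dataclass
class PlastomeRecord:
    """An annotated plastome: sequence, features, and (once inferred) regions."""

    id: str
    taxon: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    family: str | None = None
    regions: RegionMap | None = None

    def __post_init__(self):
        if self.regions is not None and len(self.sequence) != self.regions.genome_length:
            raise ValueError("sequence length disagrees with region map")

    def region_sequence(self, iv: tuple[int, int]) -> str:
        s, e = iv
        if s <= e:
            return self.sequence[s:e]
        return self.sequence[s:] + self.sequence[:e]

    def features_named(self, name: str) -> list[GeneFeature]:
        low = name.lower()
        return [f for f in self.features if f.name.lower() == low]


class TaxonomyTable:
    """taxon -> family lookup, read from a two-column TSV."""

    def __init__(self, rows: list[tuple[str, str]]):
        taxa = [t for t, _ in rows]
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxa in taxonomy table")
        for t, f in rows:
            if not f:
                raise ValueError(f"empty family for taxon {t}")
        self._map = dict(rows)

    def family_of(self, taxon: str) -> str:
        return self._map[taxon]

    def get(self, taxon: str) -> str | None:
        return self._map.get(taxon)

    def families(self) -> list[str]:
        seen: dict[str, None] = {}
        for f in self._map.values():
            seen.setdefault(f)
        return list(seen)

    def taxa_of(self, family: str) -> list[str]:
        return [t for t, f in self._map.items() if f == family]

    def __contains__(self, taxon: str) -> bool:
        return taxon in self._map

    def __len__(self) -> int:
        return len(self._map)

    def items(self):
        return self._map.items()


def read_taxonomy(path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["taxon", "family"]:
        raise ValueError("taxonomy TSV must have header 'taxon<TAB>family'")
    return TaxonomyTable(list(df[["taxon", "family"]].itertuples(index=False, name=None)))


# ---------------------------------------------------------------------------
# flat-file parsing


def _classify_kind(name: str, feat_type: str) -> str:
    if feat_type == "tRNA" or name.lower().startswith("trn"):
        return "tRNA"
    if feat_type == "rRNA" or name.lower().startswith("rrn"):
        return "rRNA"
    return "PCG"


def _feature_from_seqfeature(feat, genome_length: int) -> GeneFeature:
    quals = feat.qualifiers
    name = (quals.get("gene") or quals.get("locus_tag") or ["?"])[0]
    try:
        parts = feat.location.parts
        exons = tuple((int(p.start), int(p.end)) for p in parts)
    except Exception as exc:  # malformed location
        raise PlastomeParseError(f"malformed coordinates for feature {name!r}: {exc}") from exc
    for s, e in exons:
        if not (0 <= s < e <= genome_length):
            raise PlastomeParseError(
                f"feature {name!r}: exon ({s},{e}) outside genome of length {genome_length}")
    strand = "-" if feat.location.strand == -1 else "+"
    return GeneFeature(
        name=name,
        kind=_classify_kind(name, feat.type),
        strand=strand,
        exons=exons,
        pseudo="pseudo" in quals or "pseudogene" in quals,
    )


def parse_plastome(text: str) -> PlastomeRecord:
    """Parse a single GenBank-style flat-file record.

    Captures every gene/tRNA/rRNA feature with its exon structure; join()
    locations become multi-exon features.  Raises
    :class:`PlastomeParseError` on missing sequence or malformed feature
    coordinates (the offending feature is named in the message).
    """
    try:
        rec = SeqIO.read(io.StringIO(text), "genbank")
    except Exception as exc:
        raise PlastomeParseError(f"cannot parse flat-file record: {exc}") from exc
    seq = str(rec.seq).upper()
    if not seq or set(seq) == {"N"}:
        raise PlastomeParseError(f"record {rec.id}: missing ORIGIN sequence")
    features = []
    for feat in rec.features:
        if feat.type not in ("gene", "CDS", "tRNA", "rRNA"):
            continue
        # prefer 'gene' features; fall back to CDS/tRNA/rRNA only for genes
        # that lack a gene-level annotation
        if feat.type != "gene":
            continue
        features.append(_feature_from_seqfeature(feat, len(seq)))
    if not features:
        for feat in rec.features:
            if feat.type in ("CDS", "tRNA", "rRNA"):
                features.append(_feature_from_seqfeature(feat, len(seq)))
    taxon = rec.annotations.get("organism") or rec.description or rec.id
    return PlastomeRecord(id=rec.id, taxon=taxon.strip(), sequence=seq, features=features)


def parse_plastomes(path) -> list[PlastomeRecord]:
    """Parse a (possibly multi-record) GenBank flat file from ``path``."""
    with open(path) as fh:
        text = fh.read()
    records = []
    chunks = [c for c in text.split("//\n") if c.strip()]
    for chunk in chunks:
        records.append(parse_plastome(chunk.strip("\n") + "\n//\n"))
    return records


# ---------------------------------------------------------------------------
# quadripartite region inference

_BASE = np.uint64(0x100000001B3)  # odd multiplier; arithmetic is mod 2**64
_BASE_INV = np.uint64(pow(0x100000001B3, -1, 2 ** 64))


def _window_hashes(codes: np.ndarray, length: int, powers: np.ndarray,
                   inv_powers: np.ndarray) -> np.ndarray:
    """Polynomial rolling hashes (mod 2**64) of all windows of ``length``."""
    weighted = codes.astype(np.uint64) * powers[: len(codes)]
    prefix = np.zeros(len(codes) + 1, dtype=np.uint64)
    np.cumsum(weighted, out=prefix[1:])
    n_win = len(codes) - length + 1
    return (prefix[length:length + n_win] - prefix[:n_win]) * inv_powers[:n_win]


def _disjoint_rc_pairs(seq: str, codes: np.ndarray, rc_codes: np.ndarray,
                       length: int, powers: np.ndarray, inv_powers: np.ndarray,
                       first_only: bool = False) -> list[tuple[int, int]]:
    """All (i, k) with seq[i:i+length] == revcomp(seq[k:k+length]), disjoint, i<=k."""
    n = len(seq)
    if length > n:
        return []
    hf = _window_hashes(codes, length, powers, inv_powers)
    hr = _window_hashes(rc_codes, length, powers, inv_powers)
    common = np.intersect1d(hf, hr)
    if len(common) == 0:
        return []
    order = np.argsort(hf, kind="stable")
    sorted_hf = hf[order]
    pairs = []
    for h in common:
        lo = np.searchsorted(sorted_hf, h, side="left")
        hi = np.searchsorted(sorted_hf, h, side="right")
        f_positions = order[lo:hi]
        r_positions = np.flatnonzero(hr == h)
        for j in r_positions:
            k = n - int(j) - length  # genome interval of the revcomp occurrence
            for i in f_positions:
                a, b = int(i), int(k)
                if a > b:
                    a, b = b, a
                if b >= a + length:  # disjoint
                    if seq[a:a + length] == revcomp(seq[b:b + length]):
                        pairs.append((a, b))
                        if first_only:
                            return pairs
    return sorted(set(pairs))


def infer_regions(record: PlastomeRecord, min_ir: int = 1000) -> RegionMap | None:
    """Infer the quadripartite region map from the sequence alone.

    Finds the maximal-length pair of disjoint reverse-complement repeats of
    at least ``min_ir`` bp; the copy nearer the sequence start in the
    conventional LSC-first rotation is IRb (its downstream neighbour is the
    SSC).  The larger single-copy segment is the LSC.  Ties between equal
    length candidate pairs break to the lexicographically smallest pair of
    start coordinates.  Returns ``None`` when no repeat of at least
    ``min_ir`` bp exists (IR-lacking plastome).
    """
    seq = record.sequence
    n = len(seq)
    if n < 2 * min_ir:
        return None
    enc = np.frombuffer(seq.encode(), dtype=np.uint8)
    rc_enc = np.frombuffer(revcomp(seq).encode(), dtype=np.uint8)
    powers = np.empty(n + 1, dtype=np.uint64)
    powers[0] = 1
    np.multiply.accumulate(np.full(n, _BASE, dtype=np.uint64), out=powers[1:])
    inv_powers = np.empty(n + 1, dtype=np.uint64)
    inv_powers[0] = 1
    np.multiply.accumulate(np.full(n, _BASE_INV, dtype=np.uint64), out=inv_powers[1:])

    lo, hi = min_ir, n // 2
    if not _disjoint_rc_pairs(seq, enc, rc_enc, lo, powers, inv_powers, first_only=True):
        return None
    best = lo
    while lo < hi:  # largest L with a disjoint revcomp pair
        mid = (lo + hi + 1) // 2
        if _disjoint_rc_pairs(seq, enc, rc_enc, mid, powers, inv_powers, first_only=True):
            lo = mid
            best = mid
        else:
            hi = mid - 1
    pairs = _disjoint_rc_pairs(seq, enc, rc_enc, best, powers, inv_powers)
    first, second = min(pairs)  # lexicographically smallest start pair
    ir1 = (first, first + best)
    ir2 = (second, second + best)

    # single-copy segments between the two IR copies (circular)
    inner = (ir1[1], ir2[0])
    outer = (ir2[1] % n, ir1[0])
    rm = RegionMap(lsc=(0, 0), irb=(0, 0), ssc=(0, 0), ira=(0, 0), genome_length=n)
    inner_len = rm.interval_length(inner) if inner[0] != inner[1] else 0
    outer_len = rm.interval_length(outer) if outer[0] != outer[1] else n - 2 * best
    if inner_len >= outer_len:
        lsc, ssc = inner, outer
        # rotation order: LSC(inner) -> ir2 -> SSC(outer) -> ir1; IRb precedes SSC
        irb, ira = ir2, ir1
    else:
        lsc, ssc = outer, inner
        irb, ira = ir1, ir2
    return RegionMap(lsc=lsc, irb=irb, ssc=ssc, ira=ira, genome_length=n)


# ---------------------------------------------------------------------------
# summaries


def gc_percent(seq: str) -> float:
    """GC content in percent; N (and gaps) excluded from the denominator."""
    gc = seq.count("G") + seq.count("C") + seq.count("g") + seq.count("c")
    atgc = gc + seq.count("A") + seq.count("T") + seq.count("a") + seq.count("t")
    if atgc == 0:
        return float("nan")
    return 100.0 * gc / atgc


def summarize(record: PlastomeRecord) -> dict:
    """Size and GC summary per region (IR reported as one copy)."""
    if record.regions is None:
        raise ValueError("regions not inferred; call infer_regions first")
    rm = record.regions
    lsc_seq = record.region_sequence(rm.lsc)
    ssc_seq = record.region_sequence(rm.ssc)
    ir_seq = record.region_sequence(rm.irb)
    return {
        "id": record.id,
        "taxon": record.taxon,
        "family": record.family,
        "total_bp": len(record.sequence),
        "lsc_bp": rm.lsc_length,
        "ir_bp": rm.ir_length,
        "ssc_bp": rm.ssc_length,
        "gc_total": gc_percent(record.sequence),
        "gc_lsc": gc_percent(lsc_seq),
        "gc_ir": gc_percent(ir_seq),
        "gc_ssc": gc_percent(ssc_seq),
    }


def summarize_table(records: list[PlastomeRecord],
                    taxonomy: TaxonomyTable | None = None) -> pd.DataFrame:
    rows = []
    for rec in records:
        if taxonomy is not None and rec.family is None:
            rec = replace_family(rec, taxonomy.get(rec.taxon))
        rows.append(summarize(rec))
    return pd.DataFrame(rows)


def replace_family(record: PlastomeRecord, family: str | None) -> PlastomeRecord:
    return PlastomeRecord(id=record.id, taxon=record.taxon, sequence=record.sequence,
                          features=record.features, family=family, regions=record.regions)
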
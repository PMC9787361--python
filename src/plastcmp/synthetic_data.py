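"""Synthetic plastome datasets with planted ground truth.

Every analysis stage in this package is exercised against data whose
true junction geometry, gene/intron losses, indel events, diversity
hotspots and tRNA structural classes are known by construction:

* family-structured taxon sets on a family-monophyletic random tree;
* plastomes with exact IR copies, focal genes placed to realise a
  per-family junction pattern (including exact expansion sizes such as
  110 bp into rps19 or 1077 bp into ycf1, with the mirrored pseudo
  fragments IR copying creates), and configurable gene/intron losses,
  emitted as minimal GenBank flat files so the parser is exercised
  honestly;
* intron alignments with planted indel events of chosen coordinates,
  size, polarity and bearer sets (no repeat-slideable flanks unless
  requested);
* alignments with a planted high-diversity window;
* tRNA sequence/dot-bracket sets with planted anomalies (expanded
  anticodon loops, paired type-II V arms, extra stem loops).

Substitution noise uses a uniform per-site model rather than a
phylogenetic simulator: no stage here estimates substitution
parameters, so lineage-correlated noise would add cost without adding
test power.  All outputs are fully determined by the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .plastome_io import GeneFeature, TaxonomyTable, revcomp
from .trna_struct import TrnaStructure

__all__ = [
    "JunctionPlan",
    "IndelPlan",
    "HotspotPlan",
    "TrnaPlan",
    "SimConfig",
    "TruthBundle",
    "SyntheticDataset",
    "default_demo_config",
    "gen_taxonomy_and_tree",
    "gen_plastome",
    "gen_intron_alignment",
    "gen_hotspot_alignment",
    "gen_trna_set",
    "generate_dataset",
]

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# plans


@dataclass(frozen=True)
class JunctionPlan:
    """Focal-gene geometry for one family.

    ``rps19`` / ``ndhf`` are either ("expansion", overlap_bp) or
    ("contraction", distance_bp); ``ycf1_overlap`` is the JSA expansion
    into ycf1 (always an expansion, 400–1870 in nature); trnH always
    keeps its conserved 3 bp in IRa.
    """

    rps19: tuple[str, int] = ("expansion", 120)
    ndhf: tuple[str, int] = ("contraction", 50)
    ycf1_overlap: int = 1000

    @property
    def pattern_id(self) -> int:
        key = (self.rps19[0], self.ndhf[0])
        return {("expansion", "contraction"): 1, ("contraction", "expansion"): 2,
                ("expansion", "expansion"): 4, ("contraction", "contraction"): 5}[key]


@dataclass(frozen=True)
class IndelPlan:
    """One planted indel event in a locus alignment."""

    locus: str
    start: int
    end: int
    markers: tuple[str, ...]     # taxa distinguished by the event
    polarity: str                # "deletion" | "insertion"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class HotspotPlan:
    n_sequences: int = 20
    length: int = 10000
    p_background: float = 0.01
    p_hotspot: float = 0.10
    interval: tuple[int, int] = (4000, 5200)


@dataclass(frozen=True)
class TrnaPlan:
    """Planted structural class for one family × isotype.

    kind: "typical" | "anc9" | "v_arm_II" | "ac_extra" | "t_extra";
    motif: loop/extra-loop sequence to plant (v-loop for v_arm_II,
    extra-loop sequence for ac_extra/t_extra)."""

    family: str
    isotype: str
    kind: str
    motif: str = ""
    taxa: tuple[str, ...] = ()   # restrict to these taxa (default: whole family)


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_families: int = 8
    taxa_per_family: int = 5
    lsc_length: int = 30000
    ir_length: int = 8000
    ssc_length: int = 5000
    junction_plans: dict[str, JunctionPlan] = field(default_factory=dict)
    gene_losses: dict[str, tuple[str, ...]] = field(default_factory=dict)
    intron_losses: dict[str, tuple[str, ...]] = field(default_factory=dict)
    pseudo_genes: dict[str, tuple[str, ...]] = field(default_factory=dict)
    indel_plans: tuple[IndelPlan, ...] = ()
    loci: tuple[str, ...] = ()
    locus_length: int = 300
    substitution_rate: float = 0.01
    hotspot: HotspotPlan = field(default_factory=HotspotPlan)
    trna_plans: tuple[TrnaPlan, ...] = ()
    include_outgroup: bool = True

    def family_names(self) -> list[str]:
        return [f"Fam{k + 1:02d}" for k in range(self.n_families)]

    def taxa_of(self, family: str) -> list[str]:
        return [f"{family}_t{i + 1}" for i in range(self.taxa_per_family)]

    def all_taxa(self) -> list[str]:
        return [t for fam in self.family_names() for t in self.taxa_of(fam)]


@dataclass
class TruthBundle:
    """Planted ground truth, keyed the way the pipeline reports results."""

    taxonomy: list[tuple[str, str]] = field(default_factory=list)
    newick: str = ""
    junction_truth: dict[str, dict] = field(default_factory=dict)      # taxon -> per-junction truth
    pattern_truth: dict[str, int] = field(default_factory=dict)        # family -> pattern id
    gene_loss_truth: dict[str, tuple[str, ...]] = field(default_factory=dict)
    intron_loss_truth: dict[str, tuple[str, ...]] = field(default_factory=dict)
    indel_truth: dict[str, list[dict]] = field(default_factory=dict)   # locus -> events
    hotspot_truth: tuple[int, int] | None = None
    trna_truth: dict[str, dict[str, dict]] = field(default_factory=dict)  # taxon -> isotype -> class

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (set, frozenset, tuple)):
                return sorted(o) if isinstance(o, (set, frozenset)) else list(o)
            raise TypeError(type(o))
        return json.dumps(self.__dict__, default=default, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# taxonomy and tree


def _random_subtree(labels: list[str], rng: np.random.Generator) -> str:
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0]


def gen_taxonomy_and_tree(cfg: SimConfig) -> tuple[TaxonomyTable, str]:
    """Family-monophyletic random rooted tree plus the taxonomy table.

    Each family is a random binary subtree; family subtrees are then
    joined randomly.  The Newick string is byte-identical for a fixed
    config.
    """
    if cfg.n_families < 2:
        raise ValueError("need at least 2 families")
    rng = np.random.default_rng(cfg.seed)
    rows = []
    subtrees = []
    for fam in cfg.family_names():
        taxa = cfg.taxa_of(fam)
        rows.extend((t, fam) for t in taxa)
        subtrees.append(_random_subtree(taxa, rng))
    newick = _random_subtree(subtrees, rng) + ";"
    return TaxonomyTable(rows), newick


# ---------------------------------------------------------------------------
# plastomes


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _format_location(feature: GeneFeature) -> str:
    parts = [f"{s + 1}..{e}" for s, e in feature.exons]
    loc = parts[0] if len(parts) == 1 else "join(" + ",".join(parts) + ")"
    if feature.strand == "-":
        loc = f"complement({loc})"
    return loc


def _feature_block(feature: GeneFeature) -> str:
    ftype = {"tRNA": "gene", "rRNA": "gene", "PCG": "gene"}[feature.kind]
    lines = [f"     {ftype:<16}{_format_location(feature)}",
             f'                     /gene="{feature.name}"']
    if feature.pseudo:
        lines.append("                     /pseudo")
    return "\n".join(lines)


def _genbank_text(rec_id: str, taxon: str, seq: str,
                  features: list[GeneFeature]) -> str:
    lines = [
        f"LOCUS       {rec_id:<23} {len(seq):>7} bp    DNA     circular PLN 01-JAN-2024",
        "DEFINITION  synthetic plastome (simulated; not a natural sequence).",
        f"ACCESSION   {rec_id}",
        f"SOURCE      {taxon}",
        f"  ORGANISM  {taxon}",
        "            .",
        "FEATURES             Location/Qualifiers",
        "     source          1.." + str(len(seq)),
        f'                     /organism="{taxon}"',
    ]
    for feat in features:
        lines.append(_feature_block(feat))
    lines.append("ORIGIN")
    for i in range(0, len(seq), 60):
        chunk = seq[i:i + 60]
        blocks = " ".join(chunk[j:j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {blocks}")
    lines.append("//")
    return "\n".join(lines) + "\n"


# inventory placed in the LSC: (gene, kind, exon lengths)
_LSC_INVENTORY: list[tuple[str, str, tuple[int, ...]]] = [
    ("trnA-UGC", "tRNA", (38, 35)),
    ("trnI-GAU", "tRNA", (37, 35)),
    ("trnK-UUU", "tRNA", (37, 35)),
    ("trnL-UAA", "tRNA", (35, 50)),
    ("trnV-UAC", "tRNA", (38, 37)),
    ("atpF", "PCG", (145, 410)),
    ("clpP", "PCG", (71, 292, 228)),
    ("ndhA", "PCG", (553, 539)),
    ("ndhB", "PCG", (775, 756)),
    ("petB", "PCG", (6, 642)),
    ("petD", "PCG", (8, 475)),
    ("rpl16", "PCG", (9, 399)),
    ("rpl2", "PCG", (391, 434)),
    ("rpoC1", "PCG", (432, 1611)),
    ("rps16", "PCG", (40, 227)),
    ("ycf3", "PCG", (124, 230, 153)),
    ("infA", "PCG", (234,)),
    ("rpl32", "PCG", (174,)),
]

_INTRON_LEN = 120
_GENE_SPACING = 90


def gen_plastome(cfg: SimConfig, taxon: str, family: str,
                 plan: JunctionPlan) -> tuple[str, dict]:
    """One synthetic plastome as GenBank text plus its truth entry.

    The genome is LSC + IRb + SSC + IRa with IRa an exact reverse
    complement of IRb.  Focal genes realise the family's junction plan;
    IR expansion into rps19/ndhF/ycf1 also writes the mirrored
    pseudo fragment the duplication mechanism implies.  Gene, pseudo and
    intron losses configured for the family are applied to the LSC
    inventory.
    """
    lsc_n, ir_n, ssc_n = cfg.lsc_length, cfg.ir_length, cfg.ssc_length
    n = lsc_n + 2 * ir_n + ssc_n
    rng = np.random.default_rng([cfg.seed, 1, _stable_hash(taxon)])
    lsc = list(_random_dna(rng, lsc_n))
    irb = list(_random_dna(rng, ir_n))
    ssc = list(_random_dna(rng, ssc_n))
    ssc[0] = "A"
    ssc[-1] = "A"  # comp(A)=T: the IR repeat cannot extend across the SSC
    seq = "".join(lsc) + "".join(irb) + "".join(ssc) + revcomp("".join(irb))
    assert len(seq) == n

    jlb, jsb, jsa = lsc_n, lsc_n + ir_n, lsc_n + ir_n + ssc_n
    features: list[GeneFeature] = []
    truth: dict = {"family": family, "pattern_id": plan.pattern_id}

    # --- focal genes ------------------------------------------------------
    rps19_len, ndhf_len, ycf1_len, trnh_len = 279, 2241, 5000, 75
    mode, amount = plan.rps19
    if mode == "expansion":
        if amount >= rps19_len:
            raise ValueError(f"rps19 overlap {amount} exceeds gene length")
        features.append(GeneFeature("rps19", "PCG", "-",
                                    ((jlb - (rps19_len - amount), jlb + amount),)))
        features.append(GeneFeature("rps19", "PCG", "+", ((n - amount, n),), pseudo=True))
        truth["rps19"] = {"state": "spans", "overlap": amount}
    else:
        features.append(GeneFeature("rps19", "PCG", "-",
                                    ((jlb - amount - rps19_len, jlb - amount),)))
        truth["rps19"] = {"state": "single-copy-side", "overlap": 0, "distance": amount}

    mode, amount = plan.ndhf
    if mode == "expansion":
        if amount >= ndhf_len:
            raise ValueError(f"ndhF overlap {amount} exceeds gene length")
        features.append(GeneFeature("ndhF", "PCG", "-",
                                    ((jsb - amount, jsb - amount + ndhf_len),)))
        features.append(GeneFeature("ndhF", "PCG", "+", ((jsa, jsa + amount),), pseudo=True))
        truth["ndhF"] = {"state": "spans", "overlap": amount}
    else:
        features.append(GeneFeature("ndhF", "PCG", "-",
                                    ((jsb + amount, jsb + amount + ndhf_len),)))
        truth["ndhF"] = {"state": "single-copy-side", "overlap": 0, "distance": amount}

    ov = plan.ycf1_overlap
    if not (0 < ov < ycf1_len):
        raise ValueError(f"ycf1 overlap {ov} infeasible for gene length {ycf1_len}")
    features.append(GeneFeature("ycf1", "PCG", "+",
                                ((jsa - (ycf1_len - ov), jsa + ov),)))
    features.append(GeneFeature("ycf1", "PCG", "-", ((jsb - ov, jsb),), pseudo=True))
    truth["ycf1"] = {"state": "spans", "overlap": ov}

    features.append(GeneFeature("trnH-GUG", "tRNA", "-",
                                ((n - 3, n), (0, trnh_len - 3))))
    truth["trnH-GUG"] = {"state": "spans", "overlap": 3}

    # --- LSC inventory with losses ---------------------------------------
    lost = set(cfg.gene_losses.get(family, ()))
    pseudo = set(cfg.pseudo_genes.get(family, ()))
    intron_lost = set(cfg.intron_losses.get(family, ()))
    truth["gene_losses"] = tuple(sorted(lost))
    truth["pseudo_genes"] = tuple(sorted(pseudo))
    truth["intron_losses"] = tuple(sorted(intron_lost))

    cursor = trnh_len + _GENE_SPACING
    for gene, kind, exon_lens in _LSC_INVENTORY:
        if gene in lost:
            continue
        lens = list(exon_lens)
        if gene in intron_lost and len(lens) > 1:
            lens = [sum(lens)]  # fuse exons: one intron lost -> here all, single-exon copy
        exons = []
        pos = cursor
        for le in lens:
            exons.append((pos, pos + le))
            pos += le + _INTRON_LEN
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        features.append(GeneFeature(gene, kind, strand, tuple(exons),
                                    pseudo=gene in pseudo))
        cursor = exons[-1][1] + _GENE_SPACING
    # trans-spliced rps12: 5' exon feature + 3' two-exon cluster
    if "rps12" not in lost:
        five = (cursor, cursor + 114)
        cursor = five[1] + _GENE_SPACING
        three = ((cursor, cursor + 232), (cursor + 232 + _INTRON_LEN,
                                          cursor + 232 + _INTRON_LEN + 26))
        cursor = three[-1][1] + _GENE_SPACING
        features.append(GeneFeature("rps12", "PCG", "+", (five,)))
        if "rps12" in intron_lost:  # 3' intron lost: fused 3' cluster
            features.append(GeneFeature("rps12", "PCG", "+",
                                        ((three[0][0], three[1][1]),)))
        else:
            features.append(GeneFeature("rps12", "PCG", "+", three))
    if cursor >= jlb - rps19_len - 300:
        raise ValueError("LSC too short for the gene inventory")

    rec_id = f"SYN_{taxon}"
    text = _genbank_text(rec_id, taxon, seq, features)
    truth["record_id"] = rec_id
    truth["features"] = [
        {"name": f.name, "strand": f.strand, "exons": [list(x) for x in f.exons],
         "pseudo": f.pseudo} for f in features]
    truth["regions"] = {"lsc": [0, lsc_n], "irb": [jlb, jsb], "ssc": [jsb, jsa],
                        "ira": [jsa, n], "genome_length": n}
    return text, truth


# ---------------------------------------------------------------------------
# intron alignments


OUTGROUP = "Outgroup_1"


def gen_intron_alignment(cfg: SimConfig, locus: str,
                         taxa: list[str]) -> tuple[list[str], list[str], list[dict]]:
    """(names, rows, planted events) for one locus.

    The alignment starts from a random ancestral sequence with uniform
    per-site substitution noise, then the plan's gaps are carved in:
    deletions gap the marker taxa, insertions leave residues only in
    them.  Flanking columns of every event are pinned so no gap can
    slide and no single-column absorption is triggered by construction.
    Overlapping plans must be properly nested.
    """
    plans = [p for p in cfg.indel_plans if p.locus == locus]
    for a in plans:
        for b in plans:
            if a is b:
                continue
            if a.start < b.end and b.start < a.end:  # overlap
                nested = (a.start <= b.start and b.end <= a.end) or \
                         (b.start <= a.start and a.end <= b.end)
                if not nested or (a.start, a.end) == (b.start, b.end):
                    raise ValueError(
                        f"{locus}: overlapping non-nested planted events "
                        f"({a.start},{a.end}) vs ({b.start},{b.end})")
    length = max([cfg.locus_length] + [p.end + 3 for p in plans])
    rng = np.random.default_rng([cfg.seed, 2, _stable_hash(locus)])
    names = list(taxa) + ([OUTGROUP] if cfg.include_outgroup else [])
    anc = rng.integers(0, 4, size=length)
    mat = np.tile(anc, (len(names), 1))
    noise = rng.random(mat.shape) < cfg.substitution_rate
    mat = np.where(noise, (mat + rng.integers(1, 4, size=mat.shape)) % 4, mat)
    frozen = np.zeros(length, dtype=bool)  # columns exempt from noise/slide
    for p in plans:
        frozen[p.start - 1] = frozen[p.end - 1] = frozen[p.end] = True
    mat[:, frozen] = anc[frozen]
    # pin flanks: left flank differs from the event's last internal column
    for p in plans:
        if anc[p.start - 1] == anc[p.end - 1]:
            mat[:, p.start - 1] = (anc[p.end - 1] + 1) % 4
    rows = [["ACGT"[b] for b in row] for row in mat]
    gap_mask = np.zeros((len(names), length), dtype=bool)
    truth = []
    for p in plans:
        unknown = set(p.markers) - set(names)
        if unknown:
            raise ValueError(f"{locus}: planted markers not in taxon set: {sorted(unknown)}")
        if p.polarity == "deletion":
            bearer_idx = [names.index(t) for t in p.markers]
        else:  # insertion: everyone except the markers carries the gap
            bearer_idx = [k for k, t in enumerate(names) if t not in p.markers]
        for k in bearer_idx:
            gap_mask[k, p.start:p.end] = True
        truth.append({"locus": locus, "start": p.start, "end": p.end,
                      "length": p.length, "polarity": p.polarity,
                      "markers": sorted(p.markers),
                      "bearers": sorted(names[k] for k in bearer_idx)})
    for k in range(len(names)):
        for c in np.flatnonzero(gap_mask[k]):
            rows[k][c] = "-"
    return names, ["".join(r) for r in rows], truth


def _stable_hash(text: str) -> int:
    h = 2166136261
    for ch in text.encode():
        h = ((h ^ ch) * 16777619) % (2 ** 31)
    return h


# ---------------------------------------------------------------------------
# hotspot alignments


def gen_hotspot_alignment(cfg: SimConfig,
                          seed: int | None = None) -> tuple[list[str], tuple[int, int]]:
    """Rows with a planted high-diversity interval.

    Each sequence copies a random reference and is substituted per site
    with probability p_background outside the hotspot interval and
    p_hotspot inside it (substitutions go to a uniformly chosen
    different base).  Returns (rows, hotspot interval).
    """
    hp = cfg.hotspot
    if not hp.p_hotspot > hp.p_background:
        raise ValueError("hotspot rate must exceed background rate")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    ref = rng.integers(0, 4, size=hp.length)
    p = np.full(hp.length, hp.p_background)
    p[hp.interval[0]:hp.interval[1]] = hp.p_hotspot
    rows = []
    for _ in range(hp.n_sequences):
        hit = rng.random(hp.length) < p
        shifted = (ref + rng.integers(1, 4, size=hp.length)) % 4
        row = np.where(hit, shifted, ref)
        rows.append("".join("ACGT"[b] for b in row))
    return rows, hp.interval


# ---------------------------------------------------------------------------
# tRNA structures

ISOTYPES_TYPICAL = (
    "tRNA-Ala-UGC", "tRNA-Arg-ACG", "tRNA-Arg-UCU", "tRNA-Asn-GUU",
    "tRNA-Asp-GUC", "tRNA-Gln-UUG", "tRNA-Glu-UUC", "tRNA-Gly-GCC",
    "tRNA-Gly-UCC", "tRNA-His-GUG", "tRNA-Ile-GAU", "tRNA-Ile-CAU",
    "tRNA-Lys-UUU", "tRNA-Met-CAU", "tRNA-fMet-CAU", "tRNA-Phe-GAA",
    "tRNA-Pro-UGG", "tRNA-Trp-CCA", "tRNA-Ala-GGC", "tRNA-Asn-AUU",
    "tRNA-Gln-CUG", "tRNA-Glu-CUC", "tRNA-Gly-ACC", "tRNA-His-AUG",
    "tRNA-Lys-CUU", "tRNA-Phe-AAA",
)
ISOTYPES_SPECIAL = (
    "tRNA-Ser-UGA", "tRNA-Ser-GCU", "tRNA-Ser-GGA", "tRNA-Tyr-GUA",
    "tRNA-Leu-CAA", "tRNA-Leu-UAA", "tRNA-Val-UAC", "tRNA-Thr-UGU",
    "tRNA-Cys-GCA", "tRNA-Arg-CCG",
)
ALL_ISOTYPES = ISOTYPES_TYPICAL + ISOTYPES_SPECIAL  # 36 per taxon


_PAIR_OF = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _render_trna(rng: np.random.Generator, kind: str, motif: str,
                 anticodon: str) -> tuple[str, str, dict]:
    """(sequence, dot-bracket, expected-class fields) for one structure."""
    def stem(n):
        return "".join("AUGC"[i] for i in rng.integers(0, 4, size=n))

    def loop(n):
        return "".join("AUGC"[i] for i in rng.integers(0, 4, size=n))

    acc = stem(7)
    d5, dloop = stem(4), loop(8)
    ac5 = stem(5)
    anc_len = 9 if kind == "anc9" else 7
    pad = (anc_len - 3) // 2
    acloop = loop(pad) + anticodon + loop(anc_len - 3 - pad)
    t5, tloop = stem(5), loop(7)
    seq_parts: list[str] = []
    db_parts: list[str] = []

    def emit(s, d):
        seq_parts.append(s)
        db_parts.append(d)

    emit(acc, "(" * 7)
    emit(loop(2), "..")
    emit(d5, "(" * 4)
    emit(dloop, "." * 8)
    emit(_rc(d5), ")" * 4)
    emit(loop(1), ".")
    if kind == "ac_extra":
        ac_outer, ac_inner = ac5[:2], ac5[2:]
        emit(ac_outer, "((")
        emit(motif, "." * len(motif))
        emit(ac_inner, "(((")
        emit(acloop, "." * anc_len)
        emit(_rc(ac_inner), ")))")
        emit(_rc(ac_outer), "))")
    else:
        emit(ac5, "(" * 5)
        emit(acloop, "." * anc_len)
        emit(_rc(ac5), ")" * 5)
    if kind == "v_arm_II":
        v5 = stem(4)
        vloop = motif or loop(4)
        emit(loop(1), ".")
        emit(v5, "(" * 4)
        emit(vloop, "." * len(vloop))
        emit(_rc(v5), ")" * 4)
        emit(loop(1), ".")
        v_len = 2 + 8 + len(vloop)
        v_loop_seq = vloop
    else:
        vloop = motif if (motif and kind == "typical_motif") else loop(4)
        emit(vloop, "." * len(vloop))
        v_len = len(vloop)
        v_loop_seq = vloop
    if kind == "t_extra":
        t_outer, t_inner = t5[:2], t5[2:]
        emit(t_outer, "((")
        emit(motif, "." * len(motif))
        emit(t_inner, "(((")
        emit(tloop, "." * 7)
        emit(_rc(t_inner), ")))")
        emit(_rc(t_outer), "))")
    else:
        emit(t5, "(" * 5)
        emit(tloop, "." * 7)
        emit(_rc(t5), ")" * 5)
    emit(_rc(acc), ")" * 7)
    emit("A", ".")
    seq, db = "".join(seq_parts), "".join(db_parts)
    expected = {
        "anc_loop_len": anc_len,
        "v_arm_type": "I" if 4 <= v_len <= 5 else ("II" if v_len >= 10 else "intermediate"),
        "v_loop_seq": v_loop_seq,
        "ac_loop_extra": motif if kind == "ac_extra" else "",
        "psi_loop_extra": motif if kind == "t_extra" else "",
    }
    return seq, db, expected


def _rc(seq: str) -> str:
    return "".join(_PAIR_OF[c] for c in reversed(seq))


def gen_trna_set(cfg: SimConfig) -> tuple[list[TrnaStructure], dict]:
    """Structures for every taxon × isotype plus the planted class truth.

    Isotypes without a plan are rendered typical (7-nt anticodon loop,
    4-nt unpaired V region).  Plans override per family (optionally per
    taxon subset) with a planted anomaly or motif.
    """
    taxonomy, _ = gen_taxonomy_and_tree(cfg)
    plans: dict[tuple[str, str], TrnaPlan] = {}
    for p in cfg.trna_plans:
        plans[(p.family, p.isotype)] = p
    structures = []
    truth: dict[str, dict[str, dict]] = {}
    for fam in cfg.family_names():
        for taxon in cfg.taxa_of(fam):
            truth[taxon] = {}
            for isotype in ALL_ISOTYPES:
                plan = plans.get((fam, isotype))
                kind, motif = "typical", ""
                if plan is not None and (not plan.taxa or taxon in plan.taxa):
                    kind, motif = plan.kind, plan.motif
                # one render per (isotype, planted kind): real tRNA structures
                # are conserved, so identical plans yield identical structures
                # and family patterns reflect only the planted differences
                anticodon = isotype.rsplit("-", 1)[-1]
                rng = np.random.default_rng(
                    [cfg.seed, 3, _stable_hash(isotype), _stable_hash(kind + motif)])
                seq, db, expected = _render_trna(rng, kind, motif, anticodon)
                structures.append(TrnaStructure(taxon=taxon, isotype=isotype,
                                                sequence=seq, structure=db))
                truth[taxon][isotype] = {"kind": kind, "motif": motif, **expected}
    return structures, truth


# ---------------------------------------------------------------------------
# the default demo study


def default_demo_config(seed: int = 0) -> SimConfig:
    """The package's end-to-end demo: 8 families × 5 taxa, four junction
    patterns (with the 110-bp rps19 and 1077-bp ycf1 family signatures),
    three loss events, 60 planted indels over 17 intron loci, one
    diversity hotspot and five family-unique tRNA classes."""
    fams = [f"Fam{k + 1:02d}" for k in range(8)]
    junction_plans = {
        fams[0]: JunctionPlan(("expansion", 120), ("contraction", 40), 1000),
        fams[1]: JunctionPlan(("expansion", 200), ("contraction", 80), 700),
        fams[2]: JunctionPlan(("contraction", 60), ("expansion", 100), 900),
        fams[3]: JunctionPlan(("contraction", 25), ("expansion", 300), 1200),
        fams[4]: JunctionPlan(("expansion", 110), ("expansion", 150), 800),   # 110-bp rps19 signature
        fams[5]: JunctionPlan(("expansion", 90), ("expansion", 60), 1077),    # 1077-bp ycf1 signature
        fams[6]: JunctionPlan(("contraction", 45), ("contraction", 70), 600),
        fams[7]: JunctionPlan(("contraction", 150), ("contraction", 20), 1500),
    }
    loci = ("trnA-UGC", "trnI-GAU", "trnK-UUU", "trnL-UAA", "trnV-UAC",
            "atpF", "clpP_1", "clpP_2", "ndhA", "ndhB", "petB", "petD",
            "rpl16", "rpl2", "rpoC1", "rps12", "rps16")
    taxa = {f: [f"{f}_t{i + 1}" for i in range(5)] for f in fams}
    plans: list[IndelPlan] = []
    sizes = [1, 2, 3, 4, 5, 5, 6, 6, 7, 8, 9, 10, 12, 15, 20, 24, 30, 45, 60, 176]
    k = 0
    for li, locus in enumerate(loci):
        cursor = 20
        for _slot in range(4 if li < 9 else 3):  # 9*4 + 8*3 = 60 events
            fam = fams[k % 8]
            size = sizes[k % len(sizes)]
            polarity = "deletion" if k % 2 == 0 else "insertion"
            markers = tuple(taxa[fam]) if k % 3 else tuple(taxa[fam][:2])
            plans.append(IndelPlan(locus=locus, start=cursor, end=cursor + size,
                                   markers=markers, polarity=polarity))
            cursor += size + 12
            k += 1
    trna_plans = (
        # five family-unique classes (distinct planted motifs)
        TrnaPlan(fams[0], "tRNA-Ser-GCU", "v_arm_II", "UUA"),
        TrnaPlan(fams[1], "tRNA-Ser-UGA", "v_arm_II", "GAAUAA"),
        TrnaPlan(fams[2], "tRNA-Tyr-GUA", "v_arm_II", "AUA"),
        TrnaPlan(fams[3], "tRNA-Thr-UGU", "ac_extra", "UU"),
        TrnaPlan(fams[4], "tRNA-Cys-GCA", "t_extra", "GG"),
        # intrafamilial split: expanded ANC loop in 3 of 5 taxa
        TrnaPlan(fams[5], "tRNA-Val-UAC", "anc9", "",
                 taxa=tuple(taxa[fams[5]][:3])),
        TrnaPlan(fams[6], "tRNA-Leu-UAA", "anc9", ""),
        TrnaPlan(fams[7], "tRNA-Leu-CAA", "v_arm_II", "AAAG"),
    )
    return SimConfig(
        seed=seed,
        n_families=8,
        taxa_per_family=5,
        junction_plans=junction_plans,
        gene_losses={fams[4]: ("infA", "rpl32")},
        intron_losses={fams[5]: ("rps16",)},
        indel_plans=tuple(plans),
        loci=loci,
        trna_plans=trna_plans,
    )


@dataclass
class SyntheticDataset:
    config: SimConfig
    taxonomy: TaxonomyTable
    newick: str
    genbank: dict[str, str]                 # taxon -> flat-file text
    alignments: dict[str, tuple[list[str], list[str]]]  # locus -> (names, rows)
    hotspot_rows: list[str]
    trna: list[TrnaStructure]
    truth: TruthBundle


def generate_dataset(cfg: SimConfig) -> SyntheticDataset:
    """Generate the full dataset plus its :class:`TruthBundle`."""
    taxonomy, newick = gen_taxonomy_and_tree(cfg)
    truth = TruthBundle(taxonomy=list(taxonomy.items()), newick=newick)
    genbank = {}
    for fam in cfg.family_names():
        plan = cfg.junction_plans.get(fam, JunctionPlan())
        truth.pattern_truth[fam] = plan.pattern_id
        for taxon in cfg.taxa_of(fam):
            text, entry = gen_plastome(cfg, taxon, fam, plan)
            genbank[taxon] = text
            truth.junction_truth[taxon] = entry
            if entry["gene_losses"]:
                truth.gene_loss_truth[taxon] = entry["gene_losses"]
            if entry["intron_losses"]:
                truth.intron_loss_truth[taxon] = entry["intron_losses"]
    alignments = {}
    loci = cfg.loci or tuple(sorted({p.locus for p in cfg.indel_plans}))
    for locus in loci:
        names, rows, events = gen_intron_alignment(cfg, locus, cfg.all_taxa())
        alignments[locus] = (names, rows)
        truth.indel_truth[locus] = events
    hotspot_rows, interval = gen_hotspot_alignment(cfg)
    truth.hotspot_truth = interval
    trna, trna_truth = gen_trna_set(cfg)
    truth.trna_truth = trna_truth
    return SyntheticDataset(config=cfg, taxonomy=taxonomy, newick=newick,
                            genbank=genbank, alignments=alignments,
                            hotspot_rows=hotspot_rows, trna=trna, truth=truth)
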
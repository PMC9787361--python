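"""Gene-loss and intron-loss detection against a reference gene inventory.

The shipped reference set covers the 17 intron-containing plastid genes
(five tRNAs, twelve protein-coding genes; clpP and ycf3 carry two introns
each) plus the two genes whose loss is a known family marker in several
rosid-adjacent lineages, infA and rpl32.  rps12, the sole trans-spliced
plastid gene, is assessed on its 3' exon cluster only, so it contributes
a single intron column.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

from .plastome_io import PlastomeRecord, TaxonomyTable

__all__ = [
    "ReferenceGene",
    "ReferenceGeneSet",
    "LossReport",
    "default_reference",
    "load_reference",
    "detect_gene_losses",
    "detect_intron_losses",
    "loss_report",
    "aggregate_losses",
]


@dataclass(frozen=True)
class ReferenceGene:
    name: str
    kind: str
    expected_introns: int
    trans_spliced: bool = False


class ReferenceGeneSet:
    def __init__(self, genes: list[ReferenceGene]):
        names = [g.name.lower() for g in genes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene names in reference set")
        for g in genes:
            if g.expected_introns < 0:
                raise ValueError(f"{g.name}: negative intron count")
        self._genes = {g.name.lower(): g for g in genes}

    def __iter__(self):
        return iter(self._genes.values())

    def __len__(self):
        return len(self._genes)

    def get(self, name: str) -> ReferenceGene | None:
        return self._genes.get(name.lower())

    def intron_genes(self) -> list[ReferenceGene]:
        return [g for g in self if g.expected_introns > 0]


def load_reference(path) -> ReferenceGeneSet:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "kind": str})
    genes = [ReferenceGene(r.gene, r.kind, int(r.expected_introns), bool(int(r.trans_spliced)))
             for r in df.itertuples()]
    return ReferenceGeneSet(genes)


def default_reference() -> ReferenceGeneSet:
    ref = importlib.resources.files("plastcmp.data") / "reference_genes.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_reference(path)


@dataclass
class LossReport:
    record_id: str
    taxon: str
    missing_genes: set[str] = field(default_factory=set)
    pseudo_genes: set[str] = field(default_factory=set)
    intron_losses: list[tuple[str, int, int]] = field(default_factory=list)  # (gene, expected, observed)


def _present_features(record: PlastomeRecord, gene: ReferenceGene):
    return [f for f in record.features if f.name.lower() == gene.name.lower()]


def detect_gene_losses(record: PlastomeRecord,
                       ref: ReferenceGeneSet | None = None) -> tuple[set[str], set[str]]:
    """(missing, pseudo-only) reference genes for one record.

    A gene counts as present iff at least one non-pseudo feature bears its
    name (case-insensitive; tRNA isoacceptor suffixes are significant).
    IR-duplicated copies therefore never double-count, and a gene whose
    only copies are pseudo-flagged is reported separately rather than as
    lost.
    """
    ref = ref or default_reference()
    missing, pseudo = set(), set()
    for gene in ref:
        feats = _present_features(record, gene)
        if not feats:
            missing.add(gene.name)
        elif all(f.pseudo for f in feats):
            pseudo.add(gene.name)
    return missing, pseudo


def detect_intron_losses(record: PlastomeRecord,
                         ref: ReferenceGeneSet | None = None) -> list[tuple[str, int, int]]:
    """Rows (gene, expected introns, observed introns) for every deficit.

    Observed introns = exon count − 1 of the richest non-pseudo copy.  For
    the trans-spliced rps12 only the 3' exon cluster is assessed: the copy
    with the most exons carries the (single) spliceosome-independent 3'
    intron.  Absent genes are excluded here — they are gene losses.
    """
    ref = ref or default_reference()
    rows = []
    for gene in ref.intron_genes():
        feats = [f for f in _present_features(record, gene) if not f.pseudo]
        if not feats:
            continue
        observed = max(f.n_exons for f in feats) - 1
        if observed < gene.expected_introns:
            rows.append((gene.name, gene.expected_introns, observed))
    return rows


def loss_report(record: PlastomeRecord, ref: ReferenceGeneSet | None = None) -> LossReport:
    ref = ref or default_reference()
    missing, pseudo = detect_gene_losses(record, ref)
    return LossReport(record_id=record.id, taxon=record.taxon,
                      missing_genes=missing, pseudo_genes=pseudo,
                      intron_losses=detect_intron_losses(record, ref))


def aggregate_losses(reports: list[LossReport],
                     taxonomy: TaxonomyTable) -> pd.DataFrame:
    """family × gene loss-count matrix with family-universal flags.

    One row per (family, gene, kind-of-loss) with the number of affected
    records, family size, and whether the loss is universal in the family.
    """
    counts: dict[tuple[str, str, str], int] = {}
    family_sizes: dict[str, int] = {}
    for rep in reports:
        fam = taxonomy.get(rep.taxon)
        if fam is None:
            continue
        family_sizes[fam] = family_sizes.get(fam, 0) + 1
        for g in rep.missing_genes:
            counts[(fam, g, "gene-loss")] = counts.get((fam, g, "gene-loss"), 0) + 1
        for g in rep.pseudo_genes:
            counts[(fam, g, "pseudogenized")] = counts.get((fam, g, "pseudogenized"), 0) + 1
        for g, _exp, _obs in rep.intron_losses:
            counts[(fam, g, "intron-loss")] = counts.get((fam, g, "intron-loss"), 0) + 1
    rows = []
    for (fam, gene, kind), n in sorted(counts.items()):
        size = family_sizes[fam]
        rows.append({"family": fam, "gene": gene, "loss_kind": kind,
                     "n_records": n, "family_size": size,
                     "family_universal": n == size})
    return pd.DataFrame(rows, columns=["family", "gene", "loss_kind", "n_records",
                                       "family_size", "family_universal"])
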
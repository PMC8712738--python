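"""Gene-level annotation of candidate regions.

Assigns gene models to candidate regions by coordinate overlap, classifies
coding SNPs as synonymous or nonsynonymous with the standard genetic code
(reverse-complementing for minus-strand genes; input alleles follow the
VCF convention of forward genome strand), intersects candidate gene sets
between runs, and tests term enrichment of a gene set against a background
with the upper-tail hypergeometric test, BH-corrected.

No live ontology databases are touched: the term map is a user-supplied
two-column (gene, term) table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


@dataclass
class GeneModel:
    """A gene with its CDS segments (1-based inclusive, genomic order)."""

    gene_id: str
    linkage_group: str
    start: int
    end: int
    strand: str
    cds_segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        segs = sorted(self.cds_segments)
        for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping CDS segments in {self.gene_id}")
        self.cds_segments = segs
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"CDS length of {self.gene_id} not a multiple of 3")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)


@dataclass
class EffectCall:
    """Coding-effect classification of one substitution."""

    gene_id: str
    coding: bool
    codon_index: int | None = None
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    synonymous: bool | None = None


@dataclass
class EnrichmentResult:
    """One term's hypergeometric enrichment outcome."""

    term_id: str
    k: int  # set genes carrying the term
    K: int  # background genes carrying the term
    n: int  # set size
    N: int  # background size
    p_value: float
    q_value: float = float("nan")


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Load gene models (gene/mRNA/CDS) from a GFF3 file.

    CDS segments are taken from the first mRNA of each gene.
    """
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    genes = []
    for g in db.features_of_type("gene"):
        mrnas = list(db.children(g, featuretype="mRNA"))
        cds = []
        if mrnas:
            cds = [(c.start, c.end) for c in
                   db.children(mrnas[0], featuretype="CDS", order_by="start")]
        genes.append(GeneModel(gene_id=g.id, linkage_group=g.seqid,
                               start=g.start, end=g.end, strand=g.strand,
                               cds_segments=cds))
    return genes


def read_cds_fasta(path: str | Path) -> dict[str, str]:
    """Coding sequences keyed by record id."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def genes_in_regions(genes: list[GeneModel], regions) -> list[list[GeneModel]]:
    """Genes overlapping each region by >= 1 bp (1-based inclusive).

    Returns one gene list per region, parallel to ``regions``; a gene can
    appear under several regions but once per region.
    """
    out = []
    for r in regions:
        hits = [g for g in genes
                if g.linkage_group == r.linkage_group
                and g.start <= r.end and g.end >= r.start]
        seen, uniq = set(), []
        for g in hits:
            if g.gene_id not in seen:
                seen.add(g.gene_id)
                uniq.append(g)
        out.append(uniq)
    return out


def intersect_gene_sets(set_a, set_b) -> list[str]:
    """Sorted, deduplicated identifier intersection."""
    return sorted(set(set_a) & set(set_b))


def _translate(codon: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(codon).translate())


def classify_snp_effect(gene: GeneModel, cds_sequence: str, position: int,
                        ref_base: str, alt_base: str) -> EffectCall:
    """Synonymous/nonsynonymous call for a substitution inside a gene.

    ``ref_base``/``alt_base`` are on the forward genome strand (VCF
    convention); for minus-strand genes they are complemented onto the
    coding strand.  ``cds_sequence`` is the spliced coding sequence,
    5'->3' on the coding strand.  A position outside every CDS segment
    yields a non-coding call; a reference mismatch raises ``ValueError``.
    """
    if len(cds_sequence) != gene.cds_length:
        raise ValueError(
            f"CDS sequence length {len(cds_sequence)} does not match "
            f"{gene.gene_id} segments ({gene.cds_length})")
    offset = None
    before = 0
    for s, e in gene.cds_segments:
        if s <= position <= e:
            offset = before + (position - s)
            break
        before += e - s + 1
    if offset is None:
        return EffectCall(gene_id=gene.gene_id, coding=False)
    if gene.strand == "-":
        offset = gene.cds_length - 1 - offset
        ref_c = ref_base.translate(_COMPLEMENT).upper()
        alt_c = alt_base.translate(_COMPLEMENT).upper()
    else:
        ref_c, alt_c = ref_base.upper(), alt_base.upper()
    if cds_sequence[offset] != ref_c:
        raise ValueError(
            f"reference mismatch at {gene.linkage_group}:{position} "
            f"({gene.gene_id}): CDS has {cds_sequence[offset]}, "
            f"expected {ref_c}")
    ci = offset // 3
    within = offset % 3
    ref_codon = cds_sequence[3 * ci:3 * ci + 3]
    alt_codon = ref_codon[:within] + alt_c + ref_codon[within + 1:]
    ref_aa = _translate(ref_codon)
    alt_aa = _translate(alt_codon)
    return EffectCall(gene_id=gene.gene_id, coding=True, codon_index=ci + 1,
                      ref_codon=ref_codon, alt_codon=alt_codon,
                      ref_aa=ref_aa, alt_aa=alt_aa,
                      synonymous=(ref_aa == alt_aa))


def hypergeometric_enrichment(gene_set, background, term_map,
                              ) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric term enrichment, BH-corrected.

    ``term_map`` maps gene id -> iterable of term ids (or a two-column
    DataFrame ``gene_id, term_id``).  For each term with K carriers among
    the N background genes, the p-value is the probability of observing
    >= k carriers in a random draw of n = |gene_set| genes.  Results are
    sorted by p-value.
    """
    from bsrmap.thresholds import bh_fdr

    bg = set(background)
    gs = set(gene_set)
    if not gs <= bg:
        raise ValueError("gene_set must be a subset of the background")
    if isinstance(term_map, pd.DataFrame):
        pairs = term_map.iloc[:, :2].itertuples(index=False)
        mapping: dict[str, set[str]] = {}
        for gene, term in pairs:
            mapping.setdefault(str(gene), set()).add(str(term))
        term_map = mapping
    term_to_bg: dict[str, set[str]] = {}
    for gene, terms in term_map.items():
        if gene in bg:
            for t in terms:
                term_to_bg.setdefault(t, set()).add(gene)
    N, n = len(bg), len(gs)
    results = []
    for term in sorted(term_to_bg):
        carriers = term_to_bg[term]
        K = len(carriers)
        k = len(carriers & gs)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        results.append(EnrichmentResult(term_id=term, k=k, K=K, n=n, N=N,
                                        p_value=min(p, 1.0)))
    if results:
        q = bh_fdr([r.p_value for r in results])
        for r, qv in zip(results, q):
            r.q_value = float(qv)
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def read_term_map(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (gene_id, term_id) -> gene -> terms mapping."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["gene_id", "term_id"], dtype=str)
    mapping: dict[str, set[str]] = {}
    for gene, term in df.itertuples(index=False):
        mapping.setdefault(gene, set()).add(term)
    return mapping


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "term_id": r.term_id, "k": r.k, "K": r.K, "n": r.n, "N": r.N,
        "p_value": r.p_value, "q_value": r.q_value,
    } for r in results])
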
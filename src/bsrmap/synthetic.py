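"""Synthetic pooled-bulk variant data with known ground truth.

The generator emulates the sampling chain behind two-bulk segregant
sequencing: individuals are drawn from a segregating population into two
pools of ``n_per_bulk`` individuals, the pooled alternate-allele frequency
at each marker follows from the individuals' genotypes, and sequencing
reads are binomial draws from that pooled frequency at a per-marker depth.
One or more divergent (QTL) regions can be planted on any linkage group by
shifting the two bulks' true allele frequencies apart by ``delta_af``.

No read-level simulation, alignment or variant calling is performed; the
generator emits the two-sample VCF a caller would have produced, carrying
every field the downstream filters consume (GT/AD/DP/GQ per bulk, QD/FS/MQ
per site), together with a :class:`SyntheticTruth` recording the planted
regions and true per-marker bulk frequencies.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from bsrmap.annotation import GeneModel

_BASES = np.array(list("ACGT"))

#: column order of the marker table produced by :func:`generate_dataset`
MARKER_COLUMNS = [
    "linkage_group", "position", "ref_allele", "alt_allele", "variant_class",
    "ref_high", "alt_high", "ref_low", "alt_low",
    "gq_high", "gq_low", "qd", "fs", "mq",
    "missing_high", "missing_low",
]


@dataclass(frozen=True)
class PopulationModel:
    """Segregating population the bulks are drawn from.

    kind
        ``"F2"`` -- selfed/intercrossed F2 with 1:2:1 genotype segregation
        at a null locus; ``"RIL"`` -- recombinant inbred lines, homozygous
        1:1; ``"NATURAL"`` -- outbred cohort in Hardy-Weinberg proportions
        at ``background_alt_freq``.
    n_per_bulk
        Individuals pooled per bulk.  Default 42 (two pools of 14
        individuals from each of 3 replicate tanks in the motivating
        study design).
    background_alt_freq
        Null alternate-allele frequency for the ``NATURAL`` kind.
    """

    kind: str = "F2"
    n_per_bulk: int = 42
    background_alt_freq: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("F2", "RIL", "NATURAL"):
            raise ValueError(f"unknown population kind: {self.kind!r}")
        if self.n_per_bulk < 1:
            raise ValueError("n_per_bulk must be >= 1")
        if not 0.0 <= self.background_alt_freq <= 1.0:
            raise ValueError("background_alt_freq must be in [0, 1]")

    @property
    def null_freq(self) -> float:
        """Expected alternate-allele frequency at an unlinked locus."""
        return self.background_alt_freq if self.kind == "NATURAL" else 0.5


@dataclass(frozen=True)
class QtlSpec:
    """One planted divergent region.

    ``delta_af`` is the difference in true alternate-allele frequency
    between the two bulks at the region peak; ``shape`` is ``"block"``
    (constant across the region) or ``"triangular"`` (tapering linearly
    from the midpoint peak to zero at the edges).
    """

    linkage_group: str
    start: int
    end: int
    delta_af: float
    shape: str = "block"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("QTL start must be <= end")
        if not 0.0 <= self.delta_af <= 1.0:
            raise ValueError("delta_af must be in [0, 1]")
        if self.shape not in ("block", "triangular"):
            raise ValueError(f"unknown QTL shape: {self.shape!r}")

    def effect_at(self, positions: np.ndarray) -> np.ndarray:
        """Allele-frequency offset |Delta AF| at each position (0 outside)."""
        pos = np.asarray(positions)
        inside = (pos >= self.start) & (pos <= self.end)
        if self.shape == "block":
            return np.where(inside, self.delta_af, 0.0)
        mid = (self.start + self.end) / 2.0
        half = max((self.end - self.start) / 2.0, 1.0)
        taper = np.clip(1.0 - np.abs(pos - mid) / half, 0.0, 1.0)
        return np.where(inside, self.delta_af * taper, 0.0)


@dataclass
class SyntheticTruth:
    """Ground truth for a generated dataset: planted QTLs and the true
    per-marker bulk allele frequencies (columns ``linkage_group``,
    ``position``, ``freq_high``, ``freq_low``)."""

    qtls: list[QtlSpec]
    marker_freqs: pd.DataFrame
    seed: int


@dataclass(frozen=True)
class DepthModel:
    """Per-marker sequencing depth: uniform over [min_depth, max_depth],
    with optional contamination fractions re-drawn at out-of-range depths
    to exercise the depth filter."""

    min_depth: int = 20
    max_depth: int = 100
    low_fraction: float = 0.0
    high_fraction: float = 0.0
    low_depth: int = 5
    high_depth: int = 600

    def draw(self, size: int, rng: np.random.Generator) -> np.ndarray:
        depths = rng.integers(self.min_depth, self.max_depth + 1, size=size)
        u = rng.random(size)
        depths = np.where(u < self.low_fraction, self.low_depth, depths)
        depths = np.where(u > 1.0 - self.high_fraction, self.high_depth, depths)
        return depths


@dataclass(frozen=True)
class SiteMetricModel:
    """Site metrics written into the VCF.  Passing sites get the ``*_pass``
    values; a ``fail_fraction`` of sites gets the ``*_fail`` values (one
    randomly chosen metric each) to exercise the hard filters."""

    qd_pass: float = 20.0
    fs_pass: float = 10.0
    mq_pass: float = 60.0
    gq_pass: int = 60
    fail_fraction: float = 0.0
    qd_fail: float = 2.0
    fs_fail: float = 80.0
    mq_fail: float = 20.0
    gq_fail: int = 10


def sample_bulk_allele_freq(model: PopulationModel, locus_effect: float,
                            rng: np.random.Generator) -> float:
    """Pooled alternate-allele frequency of one bulk at one locus.

    ``locus_effect`` is the expected alternate-allele frequency of this
    bulk at the locus (``model.null_freq`` at an unlinked marker).  The
    pooled frequency is the mean allele dosage/2 over ``n_per_bulk``
    individuals; for F2/NATURAL kinds individual dosages are
    Binomial(2, p) (1/4:1/2:1/4 at an F2 null locus), for RIL each
    individual is homozygous alt with probability p.
    """
    return float(sample_bulk_allele_freqs(model, locus_effect, 1, rng)[0])


def sample_bulk_allele_freqs(model: PopulationModel, locus_effect,
                             size, rng: np.random.Generator) -> np.ndarray:
    """Vectorized :func:`sample_bulk_allele_freq`; ``locus_effect`` may be
    a scalar or an array broadcastable to ``size``."""
    p = np.asarray(locus_effect, dtype=float)
    if np.any((p < 0.0) | (p > 1.0)):
        raise ValueError("locus_effect must be in [0, 1]")
    n = model.n_per_bulk
    if model.kind in ("F2", "NATURAL"):
        # sum of n iid Binomial(2, p) dosages = Binomial(2n, p)
        return rng.binomial(2 * n, p, size=size) / (2.0 * n)
    if model.kind == "RIL":
        return rng.binomial(n, p, size=size) / float(n)
    raise ValueError(f"unknown population kind: {model.kind!r}")


def simulate_marker_depths(true_freq_high: float, true_freq_low: float,
                           depth_model: DepthModel,
                           rng: np.random.Generator,
                           metrics: SiteMetricModel | None = None) -> dict:
    """Read counts and site metrics for one marker.

    Alternate depth per bulk is Binomial(depth, true frequency); reference
    depth is the remainder.  A bulk with zero depth is flagged missing.
    Returns a dict with the :data:`MARKER_COLUMNS` count/metric fields.
    """
    for f in (true_freq_high, true_freq_low):
        if not 0.0 <= f <= 1.0:
            raise ValueError("true allele frequencies must be in [0, 1]")
    metrics = metrics or SiteMetricModel()
    d_high, d_low = depth_model.draw(2, rng)
    alt_high = rng.binomial(d_high, true_freq_high) if d_high > 0 else 0
    alt_low = rng.binomial(d_low, true_freq_low) if d_low > 0 else 0
    return {
        "ref_high": int(d_high - alt_high), "alt_high": int(alt_high),
        "ref_low": int(d_low - alt_low), "alt_low": int(alt_low),
        "gq_high": metrics.gq_pass, "gq_low": metrics.gq_pass,
        "qd": metrics.qd_pass, "fs": metrics.fs_pass, "mq": metrics.mq_pass,
        "missing_high": bool(d_high == 0), "missing_low": bool(d_low == 0),
    }


def _check_qtls(qtls: list[QtlSpec], n_linkage_groups: int) -> None:
    by_lg: dict[str, list[QtlSpec]] = {}
    lg_names = {f"LG{i + 1}" for i in range(n_linkage_groups)}
    for q in qtls:
        if q.linkage_group not in lg_names:
            raise ValueError(
                f"QTL on {q.linkage_group!r} but only {n_linkage_groups} "
                "linkage groups requested")
        by_lg.setdefault(q.linkage_group, []).append(q)
    for lg, group in by_lg.items():
        group = sorted(group, key=lambda q: q.start)
        for a, b in zip(group, group[1:]):
            if b.start <= a.end:
                raise ValueError(f"overlapping QTL specs on {lg}")


def generate_dataset(model: PopulationModel,
                     qtls: list[QtlSpec] | None = None,
                     n_markers_per_lg: int = 2000,
                     n_linkage_groups: int = 24,
                     depth_model: DepthModel | None = None,
                     seed: int = 0,
                     lg_length: int = 25_000_000,
                     metrics: SiteMetricModel | None = None,
                     indel_fraction: float = 0.05,
                     ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a two-bulk marker table plus its ground truth.

    Linkage groups are named ``LG1..LGn``; marker positions are sorted
    uniform draws on ``[1, lg_length]``.  The two bulks' true frequencies
    at a marker are ``null_freq +- effect/2`` (clipped to [0, 1]) where
    ``effect`` comes from any planted QTL covering the position, the high
    bulk taking the larger frequency.  All randomness derives from
    ``seed`` via per-linkage-group child streams, so identical seeds give
    identical datasets.  Use :func:`write_vcf` to serialize the table.
    """
    qtls = list(qtls or [])
    depth_model = depth_model or DepthModel()
    metrics = metrics or SiteMetricModel()
    _check_qtls(qtls, n_linkage_groups)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_linkage_groups)
    frames, truth_frames = [], []
    p0 = model.null_freq
    for gi in range(n_linkage_groups):
        lg = f"LG{gi + 1}"
        rng = np.random.default_rng(children[gi])
        m = n_markers_per_lg
        pos = np.sort(rng.choice(np.arange(1, lg_length + 1), size=m,
                                 replace=False)) if m <= lg_length else None
        if pos is None:
            raise ValueError("more markers than positions on a linkage group")

        effect = np.zeros(m)
        for q in qtls:
            if q.linkage_group == lg:
                effect = np.maximum(effect, q.effect_at(pos))
        p_high = np.clip(p0 + effect / 2.0, 0.0, 1.0)
        p_low = np.clip(p0 - effect / 2.0, 0.0, 1.0)

        freq_high = sample_bulk_allele_freqs(model, p_high, m, rng)
        freq_low = sample_bulk_allele_freqs(model, p_low, m, rng)
        d_high = depth_model.draw(m, rng)
        d_low = depth_model.draw(m, rng)
        alt_high = rng.binomial(d_high, freq_high)
        alt_low = rng.binomial(d_low, freq_low)

        ref_base = _BASES[rng.integers(0, 4, m)]
        alt_shift = rng.integers(1, 4, m)
        alt_base = _BASES[(np.searchsorted(_BASES, ref_base) + alt_shift) % 4]
        is_indel = rng.random(m) < indel_fraction
        ins = np.char.add(ref_base, alt_base)
        alt_allele = np.where(is_indel, ins, alt_base)
        vclass = np.where(is_indel, "INDEL", "SNP")

        gq = np.full(m, float(metrics.gq_pass))
        qd = np.full(m, metrics.qd_pass)
        fs = np.full(m, metrics.fs_pass)
        mq = np.full(m, metrics.mq_pass)
        fail = rng.random(m) < metrics.fail_fraction
        which = rng.integers(0, 4, m)
        qd = np.where(fail & (which == 0), metrics.qd_fail, qd)
        fs = np.where(fail & (which == 1), metrics.fs_fail, fs)
        mq = np.where(fail & (which == 2), metrics.mq_fail, mq)
        gq = np.where(fail & (which == 3), float(metrics.gq_fail), gq)

        frames.append(pd.DataFrame({
            "linkage_group": lg, "position": pos,
            "ref_allele": ref_base, "alt_allele": alt_allele,
            "variant_class": vclass,
            "ref_high": d_high - alt_high, "alt_high": alt_high,
            "ref_low": d_low - alt_low, "alt_low": alt_low,
            "gq_high": gq, "gq_low": gq, "qd": qd, "fs": fs, "mq": mq,
            "missing_high": d_high == 0, "missing_low": d_low == 0,
        }))
        truth_frames.append(pd.DataFrame({
            "linkage_group": lg, "position": pos,
            "freq_high": p_high, "freq_low": p_low,
        }))

    markers = pd.concat(frames, ignore_index=True)[MARKER_COLUMNS]
    truth = SyntheticTruth(qtls=qtls,
                           marker_freqs=pd.concat(truth_frames,
                                                  ignore_index=True),
                           seed=seed)
    return markers, truth


def write_vcf(markers: pd.DataFrame, path: str | Path,
              bulk_high_name: str = "bulk_high",
              bulk_low_name: str = "bulk_low",
              lg_length: int = 25_000_000) -> Path:
    """Serialize a marker table to a VCF 4.2 file with DP/AD/GQ per sample
    and QD/FS/MQ site metrics."""
    path = Path(path)
    lgs = list(dict.fromkeys(markers["linkage_group"]))
    lines = [
        "##fileformat=VCFv4.2",
        "##source=bsrmap-synthetic",
    ]
    lines += [f"##contig=<ID={lg},length={lg_length}>" for lg in lgs]
    lines += [
        '##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">',
        '##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias">',
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        f"{bulk_high_name}\t{bulk_low_name}",
    ]

    def sample_field(ref: int, alt: int, gq: float) -> str:
        dp = ref + alt
        if dp == 0:
            return f"./.:{ref},{alt}:0:0"
        gt = "0/0" if alt == 0 else ("1/1" if ref == 0 else "0/1")
        return f"{gt}:{ref},{alt}:{dp}:{int(gq)}"

    for row in markers.itertuples(index=False):
        info = f"QD={row.qd:g};FS={row.fs:g};MQ={row.mq:g}"
        lines.append("\t".join([
            str(row.linkage_group), str(row.position), ".",
            row.ref_allele, row.alt_allele, "100", "PASS", info,
            "GT:AD:DP:GQ",
            sample_field(row.ref_high, row.alt_high, row.gq_high),
            sample_field(row.ref_low, row.alt_low, row.gq_low),
        ]))
    path.write_text("\n".join(lines) + "\n")
    return path


def generate_gene_fixtures(n_genes: int,
                           regions: list[tuple[str, int, int]],
                           seed: int = 0,
                           gene_length: int = 3000,
                           n_exons: int = 2,
                           ) -> tuple[list[GeneModel], dict[str, str]]:
    """Gene models with coding sequences for exercising annotation.

    Places ``n_genes`` genes round-robin inside the given
    ``(linkage_group, start, end)`` regions, alternating strand.  Each gene
    gets ``n_exons`` CDS segments whose total length is a multiple of 3,
    and a random coding sequence starting with ATG.  Returns the gene
    models and a mapping gene_id -> CDS nucleotide sequence (coding
    strand, 5'->3').  Use :func:`write_gff3` / :func:`write_cds_fasta`
    to serialize.
    """
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    seqs: dict[str, str] = {}
    for i in range(n_genes):
        lg, rstart, rend = regions[i % len(regions)]
        span = rend - rstart + 1
        if span < gene_length + 10:
            raise ValueError("region too small for requested gene length")
        gstart = int(rstart + rng.integers(0, span - gene_length))
        gend = gstart + gene_length - 1
        strand = "+" if i % 2 == 0 else "-"
        # split the span into n_exons CDS segments separated by introns
        exon_len = (gene_length // (2 * n_exons)) // 3 * 3
        segs, cursor = [], gstart
        for _ in range(n_exons):
            segs.append((cursor, cursor + exon_len - 1))
            cursor += 2 * exon_len
        total = exon_len * n_exons
        body = "".join(rng.choice(_BASES, size=total - 3))
        cds = "ATG" + body
        gid = f"gene{i + 1:04d}"
        genes.append(GeneModel(gene_id=gid, linkage_group=lg,
                               start=gstart, end=gend, strand=strand,
                               cds_segments=segs))
        seqs[gid] = cds
    return genes, seqs


def write_gff3(genes: list[GeneModel], path: str | Path) -> Path:
    """Write gene/mRNA/CDS features as GFF3."""
    path = Path(path)
    out = ["##gff-version 3"]
    for g in genes:
        out.append("\t".join([g.linkage_group, "bsrmap", "gene",
                              str(g.start), str(g.end), ".", g.strand, ".",
                              f"ID={g.gene_id}"]))
        mid = f"{g.gene_id}.t1"
        out.append("\t".join([g.linkage_group, "bsrmap", "mRNA",
                              str(g.start), str(g.end), ".", g.strand, ".",
                              f"ID={mid};Parent={g.gene_id}"]))
        for j, (s, e) in enumerate(g.cds_segments):
            out.append("\t".join([g.linkage_group, "bsrmap", "CDS",
                                  str(s), str(e), ".", g.strand, "0",
                                  f"ID={mid}.cds{j};Parent={mid}"]))
    path.write_text("\n".join(out) + "\n")
    return path


def write_cds_fasta(seqs: dict[str, str], path: str | Path) -> Path:
    """Write coding sequences as FASTA keyed by gene id."""
    path = Path(path)
    with open(path, "w") as fh:
        for gid, seq in seqs.items():
            fh.write(f">{gid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    return path
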
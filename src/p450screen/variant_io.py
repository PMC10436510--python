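"""Multi-sample VCF reading restricted to a candidate-gene panel.

Variants are read with :mod:`cyvcf2`, restricted to the intervals of a
BED gene panel, and multi-allelic records are split into one biallelic
record per alternate allele.  Genotypes collapse to four classes per
subject (hom-ref / het / hom-alt / missing) relative to the alt allele
under consideration; in a split record any allele pairing involving the
alt counts as het unless both alleles are the alt.

Coordinates: VCF positions are 1-based, BED intervals 0-based
half-open; both are kept native at their interfaces and reconciled in
the overlap test.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GT_HOM_REF", "GT_HET", "GT_HOM_ALT", "GT_MISSING",
    "VariantRecord", "GeneInterval", "GenePanel", "PanelVariants",
    "read_panel_variants", "variant_identifier",
]

# Genotype class codes used throughout the package.
GT_HOM_REF = 0
GT_HET = 1
GT_HOM_ALT = 2
GT_MISSING = -1

_RS_ID = re.compile(r"^rs\d+$")


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic site after multi-allelic splitting."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    id: str
    gene: str | None = None
    impact: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if self.alt == self.ref:
            raise ValueError("alt equals ref")
        if not self.id:
            raise ValueError("id must be non-empty")


def variant_identifier(chrom: str, pos: int, alt: str, vcf_id: str | None = None) -> str:
    """Stable identifier: the rs-number when the VCF ID column carries
    one, else the positional token ``chr{chrom}_{pos}_{alt}`` (alt
    allele only), which is injective over (chrom, pos, alt)."""
    if vcf_id and _RS_ID.match(vcf_id):
        return vcf_id
    chrom = chrom[3:] if chrom.startswith("chr") else chrom
    return f"chr{chrom}_{pos}_{alt}"


@dataclass(frozen=True)
class GeneInterval:
    gene: str
    chrom: str
    start: int  # 0-based inclusive (BED)
    end: int    # 0-based exclusive (BED)

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty interval for {self.gene}")

    def contains(self, pos: int) -> bool:
        """Whether a 1-based VCF position falls inside this interval."""
        return self.start + 1 <= pos <= self.end


@dataclass
class GenePanel:
    """The candidate-gene panel: genomic intervals plus the gene ->
    substrate-class mapping used for summaries."""

    intervals: list[GeneInterval]
    substrate_classes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("panel must contain at least one gene")

    @property
    def genes(self) -> list[str]:
        return [iv.gene for iv in self.intervals]

    def gene_at(self, chrom: str, pos: int) -> str | None:
        chrom = _norm_chrom(chrom)
        for iv in self.intervals:
            if _norm_chrom(iv.chrom) == chrom and iv.contains(pos):
                return iv.gene
        return None

    def substrate_class(self, gene: str) -> str:
        try:
            return self.substrate_classes[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} has no substrate class in the panel") from None

    @classmethod
    def from_bed(cls, path: str | Path, substrate_classes: dict[str, str] | None = None) -> "GenePanel":
        """Load a 4+ column BED (chrom, start, end, gene symbol)."""
        intervals = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"BED line needs 4 columns (gene in col 4): {line!r}")
            intervals.append(GeneInterval(parts[3], parts[0], int(parts[1]), int(parts[2])))
        return cls(intervals, substrate_classes or {})


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.startswith("chr") else chrom


@dataclass
class PanelVariants:
    """Panel-restricted variants with a genotype-class row per variant,
    columns aligned with ``samples``."""

    samples: list[str]
    entries: list[tuple[VariantRecord, np.ndarray]]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def genotype_matrix(self) -> np.ndarray:
        return np.vstack([codes for _, codes in self.entries]) if self.entries else np.empty((0, len(self.samples)), dtype=np.int8)


def _classify(gt: list[int], alt_index: int) -> int:
    """Genotype class of one subject for one split alt allele.

    ``gt`` holds the two allele indices from cyvcf2 (-1 = missing).
    A pairing like 1/2 is het with respect to each alt.
    """
    alleles = gt[:2]
    if any(al < 0 for al in alleles):
        return GT_MISSING
    hits = sum(al == alt_index for al in alleles)
    if hits == 2:
        return GT_HOM_ALT
    if hits == 1:
        return GT_HET
    return GT_HOM_REF


def _ann_impact(info_ann: str | None, alt: str) -> str | None:
    """Impact token of the first SnpEff-style ANN entry matching the
    alt allele (first entry overall as a fallback).  Metadata only:
    impact never gates any statistic."""
    if not info_ann:
        return None
    entries = info_ann.split(",")
    chosen = entries[0]
    for entry in entries:
        if entry.split("|", 1)[0] == alt:
            chosen = entry
            break
    fields = chosen.split("|")
    return fields[2] if len(fields) > 2 and fields[2] else None


def read_panel_variants(vcf_path: str | Path, panel: GenePanel) -> PanelVariants:
    """Read a (plain or bgzipped) multi-sample VCF, keep variants whose
    position overlaps a panel interval, split multi-allelics, and map
    GT fields to genotype classes.

    Raises ``ValueError`` on records without a GT field and propagates
    cyvcf2 parse errors with the offending path.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=False)
    samples = list(vcf.samples)
    entries: list[tuple[VariantRecord, np.ndarray]] = []
    for v in vcf:
        gene = panel.gene_at(v.CHROM, v.POS)
        if gene is None:
            continue
        try:
            gts = v.genotypes
        except Exception as exc:  # pragma: no cover - cyvcf2 raises on no-GT
            raise ValueError(f"{vcf_path}:{v.CHROM}:{v.POS}: no GT genotypes ({exc})") from exc
        if gts is None:
            raise ValueError(f"{vcf_path}:{v.CHROM}:{v.POS}: GT format field absent")
        ann = v.INFO.get("ANN")
        for k, alt in enumerate(v.ALT, start=1):
            codes = np.fromiter((_classify(gt, k) for gt in gts), dtype=np.int8, count=len(samples))
            record = VariantRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alt=alt,
                id=variant_identifier(v.CHROM, v.POS, alt, v.ID),
                gene=gene,
                impact=_ann_impact(ann, alt),
            )
            entries.append((record, codes))
    return PanelVariants(samples, entries)
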
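"""Packaged reference tables and the demo study built from them.

Three small TSVs ship with the package:

``substrate_classes.tsv``
    The 57 human cytochrome P450 genes plus their three redox partners
    (POR, Adx, AdR), each with one of six substrate classes (Drugs,
    FattyAcids, Eicosanoids, Vitamins, Sterols, Unknown) or
    RedoxPartner.

``or_gt5_reference.tsv``
    Reference per-SNP association statistics for the GPD/GUN screen:
    every variant with OR > 5, with Wald 95% CI, p-value, comparison
    direction and carrier collapse mode (het-only or hom-only).  These
    printed statistics are the validation targets for the forward
    association code via the reconstruction oracle.

``band_counts_gpd_gun.tsv``
    Per-gene counts of significant GPD/GUN variants in each of the
    five odds-ratio bands, plus the total number of variants observed
    per gene.

``concordant_reference.tsv``
    Variants significant in both the GPD/GUN and GPD/HC comparisons,
    with both odds ratios.

The demo study (:func:`demo_config`) reconstructs integer carrier
tables from the printed OR>5 statistics and encodes them as
fixed-count variants of a synthetic cohort at *synthetic* genomic
coordinates (one interval per panel gene on a single synthetic
chromosome — real panel coordinates are not shipped), so the whole
pipeline can be exercised end to end and checked against the printed
numbers.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .reconstruction import ReconstructionQuery, ReconstructionSolution, reconstruct_counts
from .synthetic import SyntheticConfig, VariantSpec
from .variant_io import GeneInterval, GenePanel

__all__ = [
    "load_substrate_classes", "load_or_gt5_reference", "load_band_counts_reference",
    "load_concordant_reference", "reconstruct_or_gt5_tables", "demo_panel",
    "demo_config", "panel_to_bed",
]

COHORT_SIZES = {"GPD": 317, "GUN": 344, "HC": 193}

_GENE_SPAN = 500_000
_GENE_STRIDE = 1_000_000


def _data(name: str) -> Path:
    return Path(resources.files("p450screen").joinpath("data", name))


def load_substrate_classes() -> dict[str, str]:
    frame = pd.read_csv(_data("substrate_classes.tsv"), sep="\t")
    return dict(zip(frame["gene"], frame["substrate_class"]))


def load_or_gt5_reference() -> pd.DataFrame:
    return pd.read_csv(_data("or_gt5_reference.tsv"), sep="\t")


def load_band_counts_reference() -> pd.DataFrame:
    return pd.read_csv(_data("band_counts_gpd_gun.tsv"), sep="\t")


def load_concordant_reference() -> pd.DataFrame:
    return pd.read_csv(_data("concordant_reference.tsv"), sep="\t")


def reconstruct_or_gt5_tables(
    max_missing: int = 2,
    fold_to_gpd_gun: bool = True,
) -> pd.DataFrame:
    """Reconstruct the carrier table behind every OR>5 reference row.

    Identical printed statistics are solved once and shared.  Each row
    gains the best solution's counts (a = GPD carriers, c = GUN
    carriers), per-cohort missingness, and whether the solution is
    exact and unique.  With ``fold_to_gpd_gun`` the one row printed
    with the cohorts inverted (GUN/GPD) is reconstructed in GPD/GUN
    orientation, matching how the band summaries count it; otherwise
    its printed orientation is kept.
    """
    ref = load_or_gt5_reference()
    cache: dict[tuple, list[ReconstructionSolution]] = {}
    rows = []
    for _, row in ref.iterrows():
        comparison = "GPD/GUN" if fold_to_gpd_gun else row["comparison"]
        num, den = comparison.split("/")
        key = (row["or"], row["ci_low"], row["ci_high"], row["p"], num, den)
        if key not in cache:
            cache[key] = reconstruct_counts(
                ReconstructionQuery(
                    or_printed=row["or"],
                    ci_low_printed=row["ci_low"],
                    ci_high_printed=row["ci_high"],
                    p_printed=row["p"],
                    n1=COHORT_SIZES[num],
                    n2=COHORT_SIZES[den],
                    max_missing=max_missing,
                )
            )
        sol = cache[key][0]
        n_exact = sum(s.exact for s in cache[key])
        rows.append({
            **row,
            "comparison": comparison,
            "a": sol.table.a, "b": sol.table.b, "c": sol.table.c, "d": sol.table.d,
            "missing_num": sol.missing1, "missing_den": sol.missing2,
            "exact": sol.exact, "unique": n_exact == 1 if sol.exact else False,
            "residual": sol.residual,
        })
    return pd.DataFrame(rows)


def demo_panel() -> GenePanel:
    """The 60-gene panel at synthetic coordinates: gene *i* occupies a
    500 kb interval on synthetic chromosome 1, spaced 1 Mb apart."""
    classes = load_substrate_classes()
    intervals = [
        GeneInterval(gene, "1", i * _GENE_STRIDE, i * _GENE_STRIDE + _GENE_SPAN)
        for i, gene in enumerate(classes)
    ]
    return GenePanel(intervals, classes)


def panel_to_bed(panel: GenePanel, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        "".join(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.gene}\n" for iv in panel.intervals)
    )
    return path


def demo_config(seed: int = 0, max_missing: int = 2) -> tuple[SyntheticConfig, GenePanel, pd.DataFrame]:
    """Synthetic study encoding the reconstructed OR>5 carrier tables.

    Returns the generator config, the demo panel, and a manifest
    mapping each reference SNP to its synthetic variant id, collapse
    mode, reconstructed counts and expected printed statistics.
    Deterministic given ``seed``.
    """
    panel = demo_panel()
    gene_start = {iv.gene: iv.start for iv in panel.intervals}
    tables = reconstruct_or_gt5_tables(max_missing=max_missing)

    specs: list[VariantSpec] = []
    manifest_rows = []
    offset_in_gene: dict[str, int] = {}
    for _, row in tables.iterrows():
        gene = row["gene"]
        k = offset_in_gene.get(gene, 0)
        offset_in_gene[gene] = k + 1
        pos = gene_start[gene] + 1001 + 10 * k  # 1-based, inside the interval
        hom = row["mode"] == "hom_only"
        rsid = row["snp"] if str(row["snp"]).startswith("rs") else None
        spec = VariantSpec(
            chrom="1", pos=pos, ref="C", alt="T", gene=gene, rsid=rsid,
            hom_fraction=1.0 if hom else 0.0,
            fixed_counts={"GPD": int(row["a"]), "GUN": int(row["c"])},
            fixed_missing={"GPD": int(row["missing_num"]), "GUN": int(row["missing_den"])},
            impact="MODIFIER",
        )
        specs.append(spec)
        manifest_rows.append({
            "snp": row["snp"], "variant_id": spec.id, "gene": gene,
            "mode": row["mode"], "comparison": row["comparison"],
            "a": row["a"], "b": row["b"], "c": row["c"], "d": row["d"],
            "exact": row["exact"],
            "or": row["or"], "ci_low": row["ci_low"], "ci_high": row["ci_high"],
            "p": row["p"],
        })
    specs.sort(key=lambda s: s.pos)
    config = SyntheticConfig(
        cohort_sizes=dict(COHORT_SIZES), variants=specs, missing_rate=0.0, seed=seed
    )
    return config, panel, pd.DataFrame(manifest_rows)
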
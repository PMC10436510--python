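"""End-to-end orchestration: VCF + panel + subjects -> report bundle.

Reads the inputs, runs the association screen for every configured
cohort pair and collapse mode, writes the per-variant results table,
the gene-level band summary, the gene strength-of-association
categories, the cross-comparison concordance table and (when the
subject table carries supplement columns) the intake report, plus a
JSON manifest echoing every tunable.  Outputs are deterministic for a
fixed config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import CollapseMode, results_to_frame, round_half_up, screen
from .reference import load_substrate_classes
from .strata import classify_gene, concordant_snps, gene_summary, summaries_to_frame
from .supplements import intake_report
from .variant_io import GenePanel, read_panel_variants

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("p450screen")

DEFAULT_COMPARISONS = (("GPD", "HC"), ("GUN", "HC"), ("GPD", "GUN"))


@dataclass
class RunConfig:
    """Everything a pipeline run depends on."""

    vcf: Path
    bed: Path
    subjects: Path
    out_dir: Path
    comparisons: tuple[tuple[str, str], ...] = DEFAULT_COMPARISONS
    modes: tuple[str, ...] = (CollapseMode.het_only.value, CollapseMode.hom_only.value)
    alpha: float = 0.05
    zero_cell_policy: str = "undefined"  # or "haldane"
    seed: int = 0

    def __post_init__(self) -> None:
        for attr in ("vcf", "bed", "subjects", "out_dir"):
            setattr(self, attr, Path(getattr(self, attr)))
        for path in (self.vcf, self.bed, self.subjects):
            if not path.exists():
                raise FileNotFoundError(path)
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.zero_cell_policy not in ("undefined", "haldane"):
            raise ValueError("zero_cell_policy must be 'undefined' or 'haldane'")
        self.comparisons = tuple(tuple(pair) for pair in self.comparisons)
        self.modes = tuple(CollapseMode(m).value for m in self.modes)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)

    def to_manifest(self) -> dict:
        return {
            "version": __version__,
            "vcf": str(self.vcf), "bed": str(self.bed), "subjects": str(self.subjects),
            "out_dir": str(self.out_dir),
            "comparisons": ["/".join(p) for p in self.comparisons],
            "modes": list(self.modes),
            "alpha": self.alpha,
            "zero_cell_policy": self.zero_cell_policy,
            "seed": self.seed,
        }


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full screen and write the report bundle.

    Returns the paths of everything written.  Stage failures raise,
    tagged with the stage name, after being logged.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    counters: dict[str, int] = {}

    stage = "load"
    try:
        subjects = pd.read_csv(config.subjects, sep="\t")
        cohort_of = dict(zip(subjects["subject_id"], subjects["cohort"]))
        known = set(subjects["cohort"])
        for pair in config.comparisons:
            for label in pair:
                if label not in known:
                    raise ValueError(f"comparison cohort {label!r} absent from subject table")
        panel = GenePanel.from_bed(config.bed, substrate_classes=load_substrate_classes())
        variants = read_panel_variants(config.vcf, panel)
        counters["subjects"] = len(subjects)
        counters["panel_genes"] = len(panel.genes)
        counters["variants_in_panel"] = len(variants)
        log.info("loaded %d subjects, %d panel variants", len(subjects), len(variants))

        stage = "association"
        results = screen(
            variants.entries,
            cohort_of,
            samples=variants.samples,
            pairs=config.comparisons,
            modes=config.modes,
            haldane=config.zero_cell_policy == "haldane",
        )
        counters["tests"] = len(results)
        counters["significant"] = sum(r.significant(config.alpha) for r in results)
        frame = results_to_frame(results)
        written["results"] = out / "results.tsv"
        frame.to_csv(written["results"], sep="\t", index=False)
        written["results_json"] = out / "results.json"
        written["results_json"].write_text(frame.to_json(orient="records", indent=2))

        stage = "classification"
        summaries = gene_summary(results, panel, alpha=config.alpha)
        written["gene_summary"] = out / "gene_summary.tsv"
        summaries_to_frame(summaries).to_csv(written["gene_summary"], sep="\t", index=False)
        category_rows = [
            {
                "gene": s.gene, "comparison": s.comparison,
                "categories": ";".join(sorted(classify_gene(s))),
            }
            for s in summaries
        ]
        written["gene_categories"] = out / "gene_categories.tsv"
        pd.DataFrame(category_rows).to_csv(written["gene_categories"], sep="\t", index=False)

        by_pair = {r.comparison_label: None for r in results}
        if "GPD/GUN" in by_pair and "GPD/HC" in by_pair:
            primary = [r for r in results if r.comparison_label == "GPD/GUN"]
            secondary = [r for r in results if r.comparison_label == "GPD/HC"]
            concordant = concordant_snps(primary, secondary, alpha=config.alpha)
            counters["concordant"] = len(concordant)
            written["concordant"] = out / "concordant.tsv"
            pd.DataFrame([
                {
                    "gene": c.gene, "variant_id": c.variant_id, "mode": c.mode.value,
                    "or_gpd_gun": round_half_up(c.or_primary, 3),
                    "or_gpd_hc": round_half_up(c.or_secondary, 3),
                    "direction": c.direction,
                }
                for c in concordant
            ]).to_csv(written["concordant"], sep="\t", index=False)

        stage = "supplements"
        if {"fish_oil", "vitamin_d"} <= set(subjects.columns) and {"GUN", "GPD"} <= known:
            written["supplements"] = out / "supplements.tsv"
            intake_report(subjects).to_csv(written["supplements"], sep="\t", index=False)

        stage = "manifest"
        manifest = {"config": config.to_manifest(), "counters": counters}
        written["manifest"] = out / "manifest.json"
        written["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    except Exception:
        log.exception("pipeline failed in stage %r", stage)
        raise
    log.info("pipeline complete: %s", ", ".join(sorted(written)))
    return written
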
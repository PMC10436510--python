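"""Synthetic three-cohort studies for end-to-end testing without data access.

The generator emulates the structure of the whole-genome-sequencing
arm of a Parkinson's-disease observational study: three cohorts of
genetically predisposed patients (GPD, n=317), genetically predisposed
unaffected individuals (GUN, n=344) and healthy controls (HC, n=193),
genotyped at rare candidate-gene variants with per-cohort carrier
counts on the order of 1-20, heterozygous or homozygous carrier
states, occasional missing genotype calls (0-2 subjects per variant),
and binary supplement-intake covariates (fish oil, vitamin D).

Carriers can be drawn per subject with a per-cohort probability or
forced to an exact count per cohort (``fixed_counts``), which makes
downstream 2x2 tables exactly reproducible.  Missingness is applied
after carrier assignment and independently per call; ``fixed_missing``
additionally forces an exact number of missing calls among
non-carriers of a cohort, reproducing the per-variant denominator
fluctuation seen in real screens (e.g. 316 instead of 317 typed
subjects).  No linkage disequilibrium, phasing or population structure
is modelled, and supplement intake is independent of genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .variant_io import GT_HET, GT_HOM_ALT, GT_HOM_REF, GT_MISSING, variant_identifier

__all__ = [
    "VariantSpec", "SyntheticConfig", "SyntheticCohort",
    "generate_cohort", "write_vcf", "write_subject_table",
    "load_config", "save_config",
]

DEFAULT_COHORT_SIZES = {"GPD": 317, "GUN": 344, "HC": 193}

# Default supplement-intake structure: exact counts for the
# predisposed cohorts (fish oil 49/317 GPD vs 73/344 GUN; vitamin D
# 105/317 GPD vs 136/344 GUN) and mid-range rates for HC, for which no
# reference proportions exist.
DEFAULT_SUPPLEMENT_COUNTS = {
    "GPD": {"fish_oil": 49, "vitamin_d": 105},
    "GUN": {"fish_oil": 73, "vitamin_d": 136},
}
DEFAULT_SUPPLEMENT_RATES = {"fish_oil": 0.18, "vitamin_d": 0.36}


@dataclass
class VariantSpec:
    """Blueprint for one biallelic variant.

    ``carrier_prob`` draws carriers per subject; ``fixed_counts``
    overrides it with exact per-cohort carrier counts.  ``hom_fraction``
    is the fraction of carriers that are homozygous (rounded to the
    nearest whole carrier).  ``fixed_missing`` forces that many
    non-carrier calls per cohort to missing.  ``impact`` optionally
    emits a SnpEff-style ANN INFO entry (intronic panel variants in the
    emulated study are annotated MODIFIER).
    """

    chrom: str
    pos: int
    ref: str = "A"
    alt: str = "G"
    gene: str | None = None
    rsid: str | None = None
    carrier_prob: dict[str, float] = field(default_factory=dict)
    hom_fraction: float = 0.0
    fixed_counts: dict[str, int] | None = None
    fixed_missing: dict[str, int] | None = None
    impact: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.hom_fraction <= 1.0:
            raise ValueError("hom_fraction must be in [0, 1]")
        for p in self.carrier_prob.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("carrier probabilities must be in [0, 1]")

    @property
    def id(self) -> str:
        return variant_identifier(self.chrom, self.pos, self.alt, self.rsid)


@dataclass
class SyntheticConfig:
    """Full description of a synthetic cohort + genotype draw."""

    cohort_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COHORT_SIZES))
    variants: list[VariantSpec] = field(default_factory=list)
    missing_rate: float = 0.0
    seed: int = 0
    supplement_counts: dict[str, dict[str, int]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SUPPLEMENT_COUNTS.items()}
    )
    supplement_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUPPLEMENT_RATES)
    )

    def __post_init__(self) -> None:
        if not self.cohort_sizes:
            raise ValueError("at least one cohort required")
        for label, n in self.cohort_sizes.items():
            if n <= 0:
                raise ValueError(f"cohort {label!r} must have positive size")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        last: dict[str, int] = {}
        for spec in self.variants:
            if spec.pos <= last.get(spec.chrom, 0):
                raise ValueError(
                    f"variant positions must strictly increase within a chromosome "
                    f"({spec.chrom}:{spec.pos})"
                )
            last[spec.chrom] = spec.pos
            if spec.fixed_counts:
                for label, k in spec.fixed_counts.items():
                    if label not in self.cohort_sizes:
                        raise ValueError(f"fixed_counts references unknown cohort {label!r}")
                    if k > self.cohort_sizes[label]:
                        raise ValueError(
                            f"fixed carrier count {k} exceeds cohort {label} "
                            f"size {self.cohort_sizes[label]}"
                        )


@dataclass
class SyntheticCohort:
    """A realised draw: subject table, variant blueprints and the
    genotype-class matrix (variants x subjects, codes as in
    :mod:`p450screen.variant_io`)."""

    subjects: pd.DataFrame  # subject_id, cohort, fish_oil, vitamin_d, age
    variants: list[VariantSpec]
    genotypes: np.ndarray  # int8, shape (n_variants, n_subjects)

    @property
    def samples(self) -> list[str]:
        return list(self.subjects["subject_id"])

    @property
    def cohorts(self) -> list[str]:
        return list(self.subjects["cohort"])


def _draw_supplement(rng: np.random.Generator, n: int, count: int | None, rate: float) -> np.ndarray:
    flags = np.zeros(n, dtype=int)
    k = count if count is not None else int(rng.binomial(n, rate))
    flags[rng.choice(n, size=min(k, n), replace=False)] = 1
    return flags


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Draw one synthetic cohort; deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    labels, ids = [], []
    for cohort, n in config.cohort_sizes.items():
        labels.extend([cohort] * n)
        ids.extend(f"{cohort}_{i:04d}" for i in range(1, n + 1))
    n_total = len(ids)
    cohort_index = {
        cohort: np.flatnonzero(np.array(labels) == cohort) for cohort in config.cohort_sizes
    }

    subjects = pd.DataFrame({"subject_id": ids, "cohort": labels})
    for covariate in ("fish_oil", "vitamin_d"):
        col = np.zeros(n_total, dtype=int)
        for cohort, idx in cohort_index.items():
            count = config.supplement_counts.get(cohort, {}).get(covariate)
            col[idx] = _draw_supplement(rng, len(idx), count, config.supplement_rates[covariate])
        subjects[covariate] = col
    # enrolment age: no genotype linkage, cohorts essentially age-matched
    age_means = {"GPD": 58.2, "GUN": 57.6}
    age = np.empty(n_total)
    for cohort, idx in cohort_index.items():
        age[idx] = rng.normal(age_means.get(cohort, 61.0), 8.0, size=len(idx))
    subjects["age"] = np.round(age, 1)

    genotypes = np.full((len(config.variants), n_total), GT_HOM_REF, dtype=np.int8)
    for vi, spec in enumerate(config.variants):
        row = genotypes[vi]
        for cohort, idx in cohort_index.items():
            if spec.fixed_counts is not None:
                k = spec.fixed_counts.get(cohort, 0)
                carriers = rng.choice(idx, size=k, replace=False) if k else np.array([], dtype=int)
            else:
                p = spec.carrier_prob.get(cohort, 0.0)
                carriers = idx[rng.random(len(idx)) < p] if p > 0 else np.array([], dtype=int)
            if len(carriers):
                n_hom = int(round(spec.hom_fraction * len(carriers)))
                row[carriers] = GT_HET
                if n_hom:
                    row[rng.choice(carriers, size=n_hom, replace=False)] = GT_HOM_ALT
            if spec.fixed_missing:
                m = spec.fixed_missing.get(cohort, 0)
                if m:
                    non_carriers = np.setdiff1d(idx, carriers, assume_unique=False)
                    row[rng.choice(non_carriers, size=m, replace=False)] = GT_MISSING
        if config.missing_rate > 0:
            row[rng.random(n_total) < config.missing_rate] = GT_MISSING
    return SyntheticCohort(subjects, list(config.variants), genotypes)


_GT_STRING = {GT_HOM_REF: "0/0", GT_HET: "0/1", GT_HOM_ALT: "1/1", GT_MISSING: "./."}


def write_vcf(cohort: SyntheticCohort, path: str | Path) -> Path:
    """Write the genotype matrix as a VCF 4.2 with a GT format field.

    Sample columns follow the subject-table order; missing calls are
    './.'.  Variants with an ``impact`` get a minimal SnpEff-style ANN
    INFO entry.  Output is byte-deterministic given the cohort.
    """
    path = Path(path)
    lines = ["##fileformat=VCFv4.2", "##source=p450screen-synthetic"]
    for chrom in dict.fromkeys(spec.chrom for spec in cohort.variants):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append('##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(cohort.samples))
    for spec, row in zip(cohort.variants, cohort.genotypes):
        if spec.impact:
            ann = f"ANN={spec.alt}|intron_variant|{spec.impact}|{spec.gene or ''}"
        else:
            ann = "."
        gts = "\t".join(_GT_STRING[int(code)] for code in row)
        lines.append(
            f"{spec.chrom}\t{spec.pos}\t{spec.rsid or '.'}\t{spec.ref}\t{spec.alt}"
            f"\t.\tPASS\t{ann}\tGT\t{gts}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def write_subject_table(cohort: SyntheticCohort, path: str | Path) -> Path:
    """Subject table as TSV (subject_id, cohort, fish_oil, vitamin_d, age)."""
    path = Path(path)
    cohort.subjects.to_csv(path, sep="\t", index=False)
    return path


def save_config(config: SyntheticConfig, path: str | Path) -> Path:
    """Persist a config as YAML (round-trips with :func:`load_config`)."""
    payload = {
        "cohort_sizes": dict(config.cohort_sizes),
        "missing_rate": config.missing_rate,
        "seed": config.seed,
        "supplement_counts": config.supplement_counts,
        "supplement_rates": config.supplement_rates,
        "variants": [
            {k: v for k, v in vars(spec).items() if v not in (None, {}, 0.0) or k in ("chrom", "pos", "ref", "alt")}
            for spec in config.variants
        ],
    }
    path = Path(path)
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


def load_config(path: str | Path) -> SyntheticConfig:
    payload = yaml.safe_load(Path(path).read_text())
    variants = [VariantSpec(**v) for v in payload.pop("variants", [])]
    return SyntheticConfig(variants=variants, **payload)
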
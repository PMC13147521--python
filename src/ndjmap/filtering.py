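"""SNP panel selection and per-sample exclusion rules.

Raw inputs are per-sample read-count tables (``sample, chrom, pos,
ref_count, alt_count``) plus homozygous parental genotype calls for the
two crossed stocks (P1, P2) and the compound-chromosome father's stock
(C).  The rules reproduce the study's selection:

* keep SNPs that are biallelic between P1 and P2, homozygous in both and
  different between them (indels and missing calls dropped);
* on the correctly segregating chromosomes (X and 3 by default), drop
  SNPs whose variant allele is also present in stock C — those are not
  informative about the maternal chromatid because the father can
  contribute the variant;
* mask per-sample observations with sequencing depth below 8;
* drop SNPs whose across-sample variance of alt-allele frequency is
  below 0.01 (population/divide-by-n variance over unmasked samples);
* optionally exclude whole samples whose fraction of sufficiently
  covered panel SNPs is too low.

Filters never alter counts; they only mask observations (depth rule) or
drop SNPs panel-wide (informativeness and variance rules), so row
identity is conserved and the filters are idempotent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HOM_REF = "hom_ref"
HOM_ALT = "hom_alt"
HET = "het"
MISSING = "missing"


@dataclass
class FilterConfig:
    min_depth: int = 8
    min_population_variance: float = 0.01
    third_stock_chroms: frozenset = field(default_factory=lambda: frozenset({"X", "3", "3L", "3R"}))
    min_covered_fraction: float = 0.5  # per-sample exclusion threshold

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if self.min_population_variance < 0:
            raise ValueError("variance threshold must be >= 0")

    def to_dict(self) -> dict:
        return {
            "min_depth": self.min_depth,
            "min_population_variance": self.min_population_variance,
            "third_stock_chroms": sorted(self.third_stock_chroms),
            "min_covered_fraction": self.min_covered_fraction,
        }


# -- panel selection -------------------------------------------------------


def select_informative_snps(parents: pd.DataFrame) -> pd.DataFrame:
    """SNPs biallelic between P1 and P2: homozygous in both stocks and for
    different alleles.

    ``parents`` columns: ``chrom, pos, P1, P2`` (+ optional ``C``,
    ``is_indel``); genotype values in {hom_ref, hom_alt, het, missing}.
    Indels and any non-homozygous or missing parental call are dropped.
    """
    if parents.empty:
        raise ValueError("no overlapping SNPs between parental genotypes")
    keep = parents
    if "is_indel" in keep.columns:
        keep = keep[~keep["is_indel"].astype(bool)]
    hom = {HOM_REF, HOM_ALT}
    keep = keep[keep["P1"].isin(hom) & keep["P2"].isin(hom)]
    keep = keep[keep["P1"] != keep["P2"]]
    return keep.reset_index(drop=True)


def exclude_third_stock_snps(panel: pd.DataFrame, config: FilterConfig | None = None) -> pd.DataFrame:
    """On X/3-type chromosomes only, drop SNPs whose variant allele occurs
    in stock C (``C`` in {het, hom_alt}); chromosome-2 SNPs are untouched
    and SNPs with missing C calls are retained."""
    config = config or FilterConfig()
    if "C" not in panel.columns:
        return panel.reset_index(drop=True)
    scoped = panel["chrom"].astype(str).isin(config.third_stock_chroms)
    carries_variant = panel["C"].isin([HET, HOM_ALT])
    return panel[~(scoped & carries_variant)].reset_index(drop=True)


# -- counts-level filters --------------------------------------------------


def _ensure_masked(matrix: pd.DataFrame) -> pd.DataFrame:
    matrix = matrix.copy()
    if "masked" not in matrix.columns:
        matrix["masked"] = False
    return matrix


def with_freq(matrix: pd.DataFrame) -> pd.DataFrame:
    """Attach the derived alt-allele frequency column (NaN at zero depth)."""
    matrix = matrix.copy()
    depth = matrix["ref_count"] + matrix["alt_count"]
    with np.errstate(invalid="ignore", divide="ignore"):
        matrix["freq"] = np.where(depth > 0, matrix["alt_count"] / depth.replace(0, np.nan), np.nan)
    return matrix


def apply_depth_filter(matrix: pd.DataFrame, config: FilterConfig | None = None) -> pd.DataFrame:
    """Mask per-(sample, SNP) observations with depth < min_depth."""
    config = config or FilterConfig()
    matrix = _ensure_masked(matrix)
    depth = matrix["ref_count"] + matrix["alt_count"]
    matrix["masked"] = matrix["masked"] | (depth < config.min_depth)
    return matrix


def apply_variance_filter(matrix: pd.DataFrame, config: FilterConfig | None = None) -> pd.DataFrame:
    """Drop SNPs (panel-wide, all samples) whose across-sample population
    variance of alt-allele frequency over unmasked observations is below
    threshold.  SNPs with fewer than two unmasked samples cannot be
    evaluated and are retained with a warning."""
    config = config or FilterConfig()
    matrix = _ensure_masked(matrix)
    fr = with_freq(matrix)
    ok = ~fr["masked"] & fr["freq"].notna()
    grp = fr[ok].groupby(["chrom", "pos"])["freq"]
    var = grp.var(ddof=0)
    n = grp.size()
    evaluable = n >= 2
    low = var.index[(var < config.min_population_variance) & evaluable]
    n_uneval = int((~evaluable).sum()) + (
        len(fr[["chrom", "pos"]].drop_duplicates()) - len(n)
    )
    if n_uneval:
        warnings.warn(
            f"{n_uneval} SNPs had <2 unmasked samples; variance filter "
            "could not be evaluated and they were retained",
            stacklevel=2,
        )
    if len(low) == 0:
        return matrix
    key = pd.MultiIndex.from_frame(matrix[["chrom", "pos"]])
    return matrix[~key.isin(low)].reset_index(drop=True)


def exclude_low_coverage_samples(matrix: pd.DataFrame, config: FilterConfig | None = None) -> tuple[pd.DataFrame, list[str]]:
    """Drop whole samples whose fraction of panel SNPs at depth >=
    min_depth does not exceed ``min_covered_fraction``.  Returns the
    retained matrix and the excluded sample ids."""
    config = config or FilterConfig()
    matrix = _ensure_masked(matrix)
    depth = matrix["ref_count"] + matrix["alt_count"]
    covered = (depth >= config.min_depth).groupby(matrix["sample"]).mean()
    excluded = sorted(covered.index[covered <= config.min_covered_fraction])
    return matrix[~matrix["sample"].isin(excluded)].reset_index(drop=True), excluded


def run_filters(matrix: pd.DataFrame, config: FilterConfig | None = None) -> tuple[pd.DataFrame, dict]:
    """Documented filter order: per-sample depth mask, then panel-wide
    variance drop.  Returns the filtered matrix and a stage report."""
    config = config or FilterConfig()
    before = _ensure_masked(matrix)
    depth_masked = apply_depth_filter(before, config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final = apply_variance_filter(depth_masked, config)
    report = filter_report(before, final, intermediate={"after_depth_mask": depth_masked})
    return final, report


# -- reporting -------------------------------------------------------------


def filter_report(before: pd.DataFrame, after: pd.DataFrame, intermediate: dict | None = None) -> dict:
    """Per-stage and per-sample survival counts."""
    before = _ensure_masked(before)
    after = _ensure_masked(after)

    def summarize(df: pd.DataFrame) -> dict:
        unmasked = df[~df["masked"]]
        return {
            "rows": int(len(df)),
            "unmasked_rows": int(len(unmasked)),
            "snps": int(len(df[["chrom", "pos"]].drop_duplicates())),
            "per_sample_unmasked": {
                str(s): int(c) for s, c in unmasked.groupby("sample").size().items()
            } if "sample" in df.columns and len(unmasked) else {},
        }

    report = {"before": summarize(before), "after": summarize(after)}
    for name, df in (intermediate or {}).items():
        report[name] = summarize(df)
    return report


# -- readers / writers -----------------------------------------------------


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    required = {"sample", "chrom", "pos", "ref_count", "alt_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    return df


def write_counts_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index=False)


def read_counts_vcf(path) -> pd.DataFrame:
    """Read a multi-sample VCF with AD fields into the counts schema."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    names = vcf.samples
    rows = []
    for rec in vcf:
        ad = rec.format("AD")
        if ad is None:
            continue
        for i, name in enumerate(names):
            ref_c, alt_c = int(ad[i][0]), int(ad[i][1])
            rows.append((name, rec.CHROM, rec.start, max(ref_c, 0), max(alt_c, 0)))
    return pd.DataFrame(rows, columns=["sample", "chrom", "pos", "ref_count", "alt_count"])


def read_parental_genotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "P1", "P2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"parental genotype table missing columns: {sorted(missing)}")
    return df
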
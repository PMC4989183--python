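"""End-to-end orchestration of the three analysis arms from one config.

Each arm runs only when its inputs are configured: rhythmometry from a
long-format expression CSV, variant annotation from two VCFs + GFF3 +
FASTA, and regulatory density analysis from narrowPeak regions + SNP
positions.  Outputs are plain CSV/TSV/JSON tables mirroring the study's
table and figure structure, plus a run log (versions, seed, parameters —
no timestamps, so re-runs under the same config are byte-identical) and a
data dictionary describing every emitted column.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from . import rhythmometry as rhy
from . import regulatory as reg
from . import variants as var

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    pass


@dataclass
class RunConfig:
    out_dir: str
    # rhythmometry arm
    expression_csv: str | None = None
    gene_classes_csv: str | None = None
    period: float = 24.0
    rhythm_alpha: float = 0.01
    comparison_alpha: float = 0.01
    ci_level: float = 0.95
    # variants arm
    vcf_a: str | None = None
    vcf_b: str | None = None
    gff3: str | None = None
    fasta: str | None = None
    strain_a: str = "129S2"
    strain_b: str = "C57BL/6J"
    splice_window: int = 2
    # regulatory arm
    regions_narrowpeak: str | None = None
    snps_bed: str | None = None
    reference_regions_narrowpeak: str | None = None
    reference_snps_bed: str | None = None
    reference_density: float | None = None
    profile_window: int = 1000
    profile_binsize: int = 50
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self) -> None:
        for alpha in (self.rhythm_alpha, self.comparison_alpha, self.ci_level):
            if not 0.0 < alpha < 1.0:
                raise ConfigurationError(f"alpha/level out of (0,1): {alpha}")
        arms = [self.wants_rhythm, self.wants_variants, self.wants_regulatory]
        if not any(arms):
            raise ConfigurationError("no analysis arm has inputs configured")
        required: list[str | None] = []
        if self.wants_variants:
            required += [self.vcf_a, self.vcf_b, self.gff3, self.fasta]
        if self.wants_regulatory:
            required += [self.regions_narrowpeak, self.snps_bed]
        if self.wants_rhythm:
            required += [self.expression_csv]
        for path in required:
            if path is None:
                raise ConfigurationError(
                    "an analysis arm is partially configured (missing input)")
            if not Path(path).exists():
                raise ConfigurationError(f"input does not exist: {path}")

    @property
    def wants_rhythm(self) -> bool:
        return self.expression_csv is not None

    @property
    def wants_variants(self) -> bool:
        return any(p is not None
                   for p in (self.vcf_a, self.vcf_b, self.gff3, self.fasta))

    @property
    def wants_regulatory(self) -> bool:
        return any(p is not None
                   for p in (self.regions_narrowpeak, self.snps_bed))


def _load_gene_classes(path: str | None) -> dict[str, str]:
    if path is None:
        return {}
    df = pd.read_csv(path)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def run_rhythm_arm(config: RunConfig, out: Path) -> dict[str, Path]:
    expr = rhy.read_expression_csv(config.expression_csv)
    gene_classes = _load_gene_classes(config.gene_classes_csv)
    series = rhy.series_from_frame(expr)
    fits = [rhy.fit_cosinor(s, period=config.period, ci_level=config.ci_level)
            for s in series]

    fits_path = out / "cosinor_fits.csv"
    rhy.fits_to_frame(fits).to_csv(fits_path, index=False)

    counts_path = out / "rhythmicity_counts.csv"
    rhy.rhythmicity_table(fits, cutoff=config.rhythm_alpha,
                          gene_class_map=gene_classes or None
                          ).to_csv(counts_path, index=False)

    genotypes = sorted({f.genotype for f in fits})
    comp_path = out / "rhythm_comparisons.csv"
    delay_path = out / "phase_delay_summary.csv"
    if len(genotypes) == 2:
        by_cell = {(f.gene, f.tissue, f.light, f.genotype): f for f in fits}
        comps = []
        for (gene, tissue, light, genotype), fit in sorted(by_cell.items()):
            if genotype != genotypes[0]:
                continue
            other = by_cell.get((gene, tissue, light, genotypes[1]))
            if other is None:
                continue
            comps.append(rhy.compare_rhythms(
                fit, other, cutoff=config.comparison_alpha,
                rhythm_alpha=config.rhythm_alpha))
        rhy.comparisons_to_frame(comps).to_csv(comp_path, index=False)
        if gene_classes:
            rhy.summarize_phase_delays(comps, gene_classes
                                       ).to_csv(delay_path, index=False)

    diagram_path = out / "phase_diagram.csv"
    pd.DataFrame([{
        "gene": f.gene, "tissue": f.tissue, "genotype": f.genotype,
        "light": f.light, "acrophase_h": f.acrophase,
        "rhythmic": f.is_rhythmic(config.rhythm_alpha),
    } for f in fits]).to_csv(diagram_path, index=False)
    return {p.name: p for p in (fits_path, counts_path, comp_path,
                                delay_path, diagram_path) if p.exists()}


def run_variants_arm(config: RunConfig, out: Path) -> dict[str, Path]:
    from pyfaidx import Fasta

    model = var.GeneModel.from_gff3(config.gff3)
    genome = Fasta(str(config.fasta))
    raw_a = var.read_variants(config.vcf_a, strain=config.strain_a)
    raw_b = var.read_variants(config.vcf_b, strain=config.strain_b)
    removal = var.remove_shared(raw_a, raw_b)
    ann_a = var.annotate_variants(removal.a_only, model, genome,
                                  config.splice_window)
    ann_b = var.annotate_variants(removal.b_only, model, genome,
                                  config.splice_window)

    paths: dict[str, Path] = {}
    for strain, annos in ((config.strain_a, ann_a), (config.strain_b, ann_b)):
        safe = strain.replace("/", "_")
        p = out / f"annotated_{safe}.tsv"
        pd.DataFrame([{
            "chrom": a.variant.chrom, "pos": a.variant.pos,
            "ref": a.variant.ref, "alt": a.variant.alt, "gene": a.gene,
            "location_class": a.location_class,
            "coding_effect": a.coding_effect,
            "notation": (f"{a.cdna_notation}:{a.protein_notation}"
                         if a.cdna_notation else ""),
            "gms": a.gms, "gms_class": a.gms_class,
        } for a in annos]).to_csv(p, sep="\t", index=False)
        paths[p.name] = p

    report = var.variant_report(ann_a, ann_b, config.strain_a, config.strain_b,
                                n_shared=removal.n_shared)
    for key, frame in report.items():
        p = out / f"snv_{key}.csv"
        frame.to_csv(p, index=(key == "location"))
        paths[p.name] = p
    return paths


def run_regulatory_arm(config: RunConfig, out: Path) -> dict[str, Path]:
    regions = reg.read_narrowpeak(config.regions_narrowpeak)
    snps = reg.SnpSet.from_bed(config.snps_bed)

    counts = reg.count_snps_per_region(snps, regions)
    per_region = pd.DataFrame({
        "chrom": [r.chrom for r in regions],
        "start": [r.start for r in regions],
        "end": [r.end for r in regions],
        "summit": [r.summit for r in regions],
        "factor": [r.factor for r in regions],
        "gene": [r.gene for r in regions],
        "n_snps": counts,
    })
    paths: dict[str, Path] = {}
    p = out / "snps_per_region.csv"
    per_region.to_csv(p, index=False)
    paths[p.name] = p

    p = out / "snps_gene_by_factor.csv"
    reg.counts_by_gene_factor(snps, regions).to_csv(p)
    paths[p.name] = p

    p = out / "peak_centered_profile.csv"
    reg.peak_centered_profile(snps, regions, window=config.profile_window,
                              binsize=config.profile_binsize
                              ).to_csv(p, index=False)
    paths[p.name] = p

    reference_mean = config.reference_density
    reference_summary = None
    if (reference_mean is None and config.reference_regions_narrowpeak
            and config.reference_snps_bed):
        ref_regions = reg.read_narrowpeak(config.reference_regions_narrowpeak)
        ref_snps = reg.SnpSet.from_bed(config.reference_snps_bed)
        reference_summary = reg.density_report(ref_snps, ref_regions)
        reference_mean = reference_summary.density
    summary = reg.density_report(snps, regions, reference_mean=reference_mean)
    payload = {
        "region_count": summary.region_count,
        "snp_count": summary.snp_count,
        "total_length": summary.total_length,
        "density_snps_per_nt": summary.density,
        "one_snp_per_nt": summary.reciprocal_density,
        "per_factor_densities": summary.per_group_densities,
        "reference_density": reference_mean,
        "t_statistic": summary.t_statistic,
        "p_value": summary.p_value,
    }
    if reference_summary is not None:
        payload["reference_one_snp_per_nt"] = reference_summary.reciprocal_density
    p = out / "density_report.json"
    with open(p, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths[p.name] = p
    return paths


_DATA_DICTIONARY = """\
# Output data dictionary

## cosinor_fits.csv
One row per gene x tissue x genotype x light condition.
mesor: rhythm-adjusted mean (expression units). amplitude: half
peak-to-trough extent. acrophase_h: fitted peak time, circadian hours in
[0, 24). p_rhythm: zero-amplitude F-test p-value. amp_ci_*/phase_ci_*:
delta-method confidence bounds; phase bounds are circular and widen to the
full circle when phase_ci_reliable is False. degenerate: all-constant input.

## rhythmicity_counts.csv
Counts/percentages of fits with p_rhythm below the rhythmicity cutoff per
genotype x tissue x light (x gene class), with 'all' marginal rows.

## rhythm_comparisons.csv
Between-genotype Wald comparisons for genes rhythmic in both genotypes.
delta_phase_h: signed circular phase difference in [-12, 12), positive =
second genotype delayed. amp_ratio: second/first amplitude.
differential_*: p below the comparison cutoff. *_ci_overlap: whether the
per-genotype confidence intervals overlap.

## phase_delay_summary.csv
Mean signed phase delay per gene class over comparable genes.

## phase_diagram.csv
Acrophase per gene/genotype for circular phase plotting.

## annotated_<strain>.tsv
One row per strain-unique SNV: location_class (exonic, splicing,
exonic;splicing, UTR5, UTR3, intronic, intergenic, ncRNA), coding_effect,
c./p. notation, Grantham score and severity class for nonsynonymous SNVs.

## snv_location.csv / snv_per_gene.csv / snv_gms_classes.csv / snv_summary.csv
Location/consequence breakdowns per strain and for the strain difference;
per-gene SNV counts; Grantham severity class distribution; totals including
the shared-variant removal count.

## snps_per_region.csv / snps_gene_by_factor.csv
SNP counts per binding region (half-open) and the gene x factor matrix.

## peak_centered_profile.csv
SNP counts and average per-base density by offset bin from the peak summit
(offset 0 = summit); n_regions is the number of regions covering each bin.

## density_report.json
Aggregate density over merged regions, the reciprocal "one SNP per N nt"
form, per-factor densities, and the single-sample t test against the
reference density (df = number of factors - 1).
"""


def run_all(config: RunConfig) -> dict[str, Path]:
    """Run every configured arm; returns the emitted file paths."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    paths: dict[str, Path] = {}
    if config.wants_rhythm:
        paths.update(run_rhythm_arm(config, out))
    if config.wants_variants:
        paths.update(run_variants_arm(config, out))
    if config.wants_regulatory:
        paths.update(run_regulatory_arm(config, out))

    log_path = out / "run_log.json"
    with open(log_path, "w") as fh:
        json.dump({"chronovar_version": __version__,
                   "config": asdict(config)}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths[log_path.name] = log_path

    dd_path = out / "data_dictionary.md"
    dd_path.write_text(_DATA_DICTIONARY)
    paths[dd_path.name] = dd_path
    return paths
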
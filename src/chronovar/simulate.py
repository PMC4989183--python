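"""Synthetic inputs with attached ground truth for every analysis arm.

Three generators mirror the structure of the study's data sources:

* :func:`gen_expression` — replicated cosine-shaped RT-qPCR-like time
  courses sampled every 4 h over 24 h, with genotype-specific phase shifts
  and amplitude ratios plus Gaussian noise;
* :func:`gen_genome_variants` — a toy genome (~100 kb, ~20 genes on both
  strands) with per-strain planted SNVs covering every location class and
  coding consequence, written as FASTA + GFF3 + two VCFs;
* :func:`gen_regions_snps` — binding regions with summits and
  Poisson-planted SNPs at a specified per-base rate, optionally
  summit-enriched, written as narrowPeak + BED.

Every generator is deterministic under a fixed seed and verifies its
planted annotations at generation time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import variants as var
from .grantham import grantham_score
from .regulatory import BindingRegion, SnpSet, write_narrowpeak, write_snp_bed
from .rhythmometry import DEFAULT_PERIOD

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}

CORE_CLOCK_GENES = ("Bmal1", "Per1", "Per2", "Per3", "Cry1",
                    "Cry2", "Dbp", "Dec1", "Dec2", "RevErbA")
METABOLIC_GENES = ("Cyp51", "Cyp7a1", "Cyp8b", "Por", "Hmgcr",
                   "Ppara", "Ppargc1a", "Car", "Rxr", "Cyp17a1",
                   "Cyp11a1", "Cyp11b2", "Cyp21a1", "Pck1", "Nampt")

CLOCK_FACTORS = ("BMAL1", "CLOCK", "NPAS2", "PER1", "PER2", "CRY1", "CRY2")


def default_gene_classes() -> dict[str, str]:
    classes = {g: "core_clock" for g in CORE_CLOCK_GENES}
    classes.update({g: "metabolic" for g in METABOLIC_GENES})
    return classes


# ===========================================================================
# Expression

@dataclass
class RhythmDesign:
    """True cosinor parameters per gene x tissue x genotype x light.

    `params` must carry columns gene, tissue, genotype, light, mesor,
    amplitude, acrophase, sd.  Sampling is every 4 h over 24 h with 3
    replicate animals per timepoint unless overridden.
    """

    params: pd.DataFrame
    timepoints: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0)
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        required = {"gene", "tissue", "genotype", "light",
                    "mesor", "amplitude", "acrophase", "sd"}
        missing = required - set(self.params.columns)
        if missing:
            raise ValueError(f"design params missing columns: {sorted(missing)}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        p = self.params
        if (p["amplitude"] < 0).any() or (p["sd"] < 0).any():
            raise ValueError("amplitude and sd must be non-negative")
        if ((p["acrophase"] < 0) | (p["acrophase"] >= DEFAULT_PERIOD)).any():
            raise ValueError("acrophase must lie in [0, 24)")


def default_rhythm_design(
    seed: int = 0,
    core_delay: float = 2.8,
    metabolic_delay: float = 6.1,
    amp_ratio: float = 0.7,
    noise_sd: float = 0.5,
    phase_jitter_sd: float = 0.0,
    genotypes: tuple[str, str] = ("129S2", "C57BL/6J"),
    tissues: tuple[str, ...] = ("liver", "adrenal"),
    lights: tuple[str, ...] = ("DD", "LD"),
) -> RhythmDesign:
    """Study-shaped design: the second genotype is phase delayed by 2.8 h
    (core clock genes) or 6.1 h (metabolic genes) and has `amp_ratio` times
    the first genotype's amplitude.

    `phase_jitter_sd` adds gene-level Gaussian scatter around the class
    delay, so planted class means stay at the stated values in expectation.
    """
    rng = np.random.default_rng(seed)
    classes = default_gene_classes()
    rows = []
    for gene, cls in classes.items():
        base_phase = float(rng.uniform(0.0, 24.0))
        mesor = float(rng.uniform(3.0, 8.0))
        amplitude = 2.0
        delay = core_delay if cls == "core_clock" else metabolic_delay
        if phase_jitter_sd > 0:
            delay += float(rng.normal(0.0, phase_jitter_sd))
        for tissue in tissues:
            for light in lights:
                for genotype, phase, amp in (
                        (genotypes[0], base_phase, amplitude),
                        (genotypes[1], (base_phase + delay) % 24.0,
                         amplitude * amp_ratio)):
                    rows.append({
                        "gene": gene, "tissue": tissue, "genotype": genotype,
                        "light": light, "gene_class": cls, "mesor": mesor,
                        "amplitude": amp, "acrophase": phase, "sd": noise_sd,
                    })
    return RhythmDesign(params=pd.DataFrame(rows), seed=seed)


def gen_expression(design: RhythmDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the expression table; returns (long-format data, truth).

    values = M + A*cos(2*pi*(t - phi)/24) + N(0, sd^2), reproducible for a
    fixed design seed.
    """
    rng = np.random.default_rng(design.seed)
    t = np.repeat(np.asarray(design.timepoints, dtype=float), design.replicates)
    rows = []
    for p in design.params.itertuples(index=False):
        signal = p.mesor + p.amplitude * np.cos(
            2.0 * math.pi * (t - p.acrophase) / DEFAULT_PERIOD)
        noise = rng.normal(0.0, p.sd, size=t.size) if p.sd > 0 else 0.0
        values = signal + noise
        for ti, vi in zip(t, values):
            rows.append({"gene": p.gene, "tissue": p.tissue,
                         "genotype": p.genotype, "light": p.light,
                         "time_h": ti, "value": vi})
    return pd.DataFrame(rows), design.params.copy()


# ===========================================================================
# Toy genome and planted variants

# Coding gene layout, relative to the gene start (plus-strand coordinates):
# exon1 = 30 nt UTR + 200 nt CDS, intron 120 nt, exon2 = 200 nt CDS,
# intron 120 nt, exon3 = 200 nt CDS + 30 nt UTR.  600 nt CDS = 200 codons.
_EXONS = ((0, 230), (350, 550), (670, 900))
_CDS = ((30, 230), (350, 550), (670, 870))
_GENE_FOOTPRINT = 900
_NC_EXONS = ((0, 200), (300, 500))
_NC_FOOTPRINT = 500


@dataclass
class ToyGene:
    name: str
    start: int
    strand: str
    coding: bool
    cdna: str = ""  # CDS sequence in coding orientation (coding genes only)

    @property
    def exons(self) -> list[tuple[int, int]]:
        layout = _EXONS if self.coding else _NC_EXONS
        return [(self.start + s, self.start + e) for s, e in layout]

    @property
    def cds(self) -> list[tuple[int, int]]:
        if not self.coding:
            return []
        return [(self.start + s, self.start + e) for s, e in _CDS]

    def cdna_to_genomic(self, cds_pos: int) -> int:
        """0-based genomic position of a 1-based cDNA CDS coordinate."""
        blocks = self.cds if self.strand == "+" else list(reversed(self.cds))
        offset = cds_pos - 1
        for s, e in blocks:
            if offset < e - s:
                return s + offset if self.strand == "+" else e - 1 - offset
            offset -= e - s
        raise IndexError(f"cDNA position {cds_pos} beyond CDS")


@dataclass
class PlantedGenomeSpec:
    """Counts of variants to plant per category for each strain.

    Categories: synonymous, nonsynonymous, stopgain, stoploss, intronic,
    splicing, exonic_splicing, UTR5, UTR3, ncRNA, intergenic.  `n_shared`
    variants (random categories) are planted identically in both strains.
    The Per2-like worked case (c.G515C:p.S172T, GMS 58) is planted in
    strain A when `include_per2_case` is set.
    """

    counts_a: Mapping[str, int] = field(default_factory=lambda: {
        "synonymous": 10, "nonsynonymous": 5, "stopgain": 2, "stoploss": 1,
        "intronic": 20, "splicing": 3, "exonic_splicing": 2,
        "UTR5": 3, "UTR3": 3, "ncRNA": 4, "intergenic": 6,
    })
    counts_b: Mapping[str, int] = field(default_factory=lambda: {
        "synonymous": 3, "nonsynonymous": 2, "intronic": 5, "intergenic": 2,
    })
    n_shared: int = 5
    n_coding_genes: int = 16
    n_noncoding_genes: int = 4
    gene_spacing: int = 2000
    include_per2_case: bool = True


class GenerationError(RuntimeError):
    pass


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + internal non-stop codons + TAA."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        codon = "".join(rng.choice(list(_BASES), size=3))
        if codon not in _STOPS and codon != "ATG":
            codons.append(codon)
    codons.append("TAA")
    return "".join(codons)


def build_toy_genome(spec: PlantedGenomeSpec, seed: int
                     ) -> tuple[dict[str, str], var.GeneModel, list[ToyGene]]:
    """Random chromosome with alternating-strand coding/noncoding genes."""
    rng = np.random.default_rng(seed)
    genes: list[ToyGene] = []
    names = list(CORE_CLOCK_GENES + METABOLIC_GENES)
    pos = spec.gene_spacing
    for i in range(spec.n_coding_genes):
        name = "Per2" if (spec.include_per2_case and i == 0) else \
            names[i % len(names)] if names[i % len(names)] != "Per2" else f"G{i}"
        strand = "+" if (spec.include_per2_case and i == 0) else \
            ("+" if i % 2 == 0 else "-")
        cdna = _random_cds(rng, n_codons=200)
        if name == "Per2":
            # Codon 172 = AGT (Ser); cDNA position 515 is its middle base.
            cdna = cdna[:513] + "AGT" + cdna[516:]
        genes.append(ToyGene(name=name, start=pos, strand=strand,
                             coding=True, cdna=cdna))
        pos += _GENE_FOOTPRINT + spec.gene_spacing
    for i in range(spec.n_noncoding_genes):
        genes.append(ToyGene(name=f"ncRNA{i + 1}", start=pos,
                             strand="+" if i % 2 == 0 else "-", coding=False))
        pos += _NC_FOOTPRINT + spec.gene_spacing
    chrom_len = pos + spec.gene_spacing

    seq = rng.choice(list(_BASES), size=chrom_len)
    for g in genes:
        if not g.coding:
            continue
        placed = g.cdna if g.strand == "+" else \
            str(Seq(g.cdna).reverse_complement())
        offset = 0
        for s, e in g.cds:
            seq[s:e] = list(placed[offset:offset + (e - s)])
            offset += e - s
    genome = {"chr1": "".join(seq)}

    transcripts = [var.Transcript(
        tx_id=f"{g.name}_t1", gene=g.name, chrom="chr1", strand=g.strand,
        exons=g.exons, cds=g.cds) for g in genes]
    return genome, var.GeneModel(transcripts), genes


def _plant_coding(rng, g: ToyGene, genome, effect: str,
                  used: set[int]) -> tuple[var.Variant, str, str] | None:
    """Plant one coding variant of the requested consequence in gene g.

    The expected consequence and notation are computed here from the
    generator's own cDNA bookkeeping (codon lookup + translation), not via
    the annotation module.
    """
    n_codons = len(g.cdna) // 3
    for _ in range(200):
        if effect == "stoploss":
            codon_idx = n_codons - 1
        elif effect == "stopgain":
            codon_idx = int(rng.integers(1, n_codons - 1))
        else:
            codon_idx = int(rng.integers(1, n_codons - 1))
        offset = int(rng.integers(0, 3))
        cds_pos = codon_idx * 3 + offset + 1
        gpos0 = g.cdna_to_genomic(cds_pos)
        if gpos0 in used:
            continue
        codon = g.cdna[codon_idx * 3: codon_idx * 3 + 3]
        ref_c = codon[offset]
        alts = [b for b in _BASES if b != ref_c]
        rng.shuffle(alts)
        for alt_c in alts:
            alt_codon = codon[:offset] + alt_c + codon[offset + 1:]
            aa_from = str(Seq(codon).translate())
            aa_to = str(Seq(alt_codon).translate())
            got = ("synonymous" if aa_from == aa_to else
                   "stopgain" if aa_to == "*" else
                   "stoploss" if aa_from == "*" else "nonsynonymous")
            if got != effect:
                continue
            ref_g, alt_g = ref_c, alt_c
            if g.strand == "-":
                ref_g = ref_g.translate(var._COMPLEMENT)
                alt_g = alt_g.translate(var._COMPLEMENT)
            assert genome["chr1"][gpos0] == ref_g
            used.add(gpos0)
            return (var.Variant("chr1", gpos0 + 1, ref_g, alt_g),
                    f"c.{ref_c}{cds_pos}{alt_c}",
                    f"p.{aa_from}{codon_idx + 1}{aa_to}")
    return None


def _plant_noncoding(rng, genes: Sequence[ToyGene], genome,
                     category: str, chrom_len: int, splice_window: int,
                     used: set[int]) -> var.Variant | None:
    for _ in range(500):
        g = genes[int(rng.integers(0, len(genes)))]
        pos0 = None
        if category == "intronic" and g.coding:
            intron = ((g.start + 230, g.start + 350),
                      (g.start + 550, g.start + 670))[int(rng.integers(0, 2))]
            pos0 = int(rng.integers(intron[0] + splice_window,
                                    intron[1] - splice_window))
        elif category == "splicing" and g.coding:
            intron = ((g.start + 230, g.start + 350),
                      (g.start + 550, g.start + 670))[int(rng.integers(0, 2))]
            pos0 = intron[0] if rng.integers(0, 2) == 0 else intron[1] - 1
        elif category == "exonic_splicing" and g.coding:
            # Last CDS base of exon1 or first CDS base of exon2/3.
            choices = (g.start + 229, g.start + 350, g.start + 549, g.start + 670)
            pos0 = int(choices[int(rng.integers(0, len(choices)))])
        elif category in ("UTR5", "UTR3") and g.coding:
            left = int(rng.integers(g.start, g.start + 30))
            right = int(rng.integers(g.start + 870, g.start + 900))
            want_left = (category == "UTR5") == (g.strand == "+")
            pos0 = left if want_left else right
        elif category == "ncRNA" and not g.coding:
            exon = g.exons[int(rng.integers(0, len(g.exons)))]
            pos0 = int(rng.integers(exon[0], exon[1]))
        elif category == "intergenic":
            pos0 = int(rng.integers(0, chrom_len))
            footprints = [(gg.start, gg.start + (_GENE_FOOTPRINT if gg.coding
                                                 else _NC_FOOTPRINT))
                          for gg in genes]
            if any(s - splice_window <= pos0 < e + splice_window
                   for s, e in footprints):
                continue
        if pos0 is None or pos0 in used:
            continue
        ref = genome["chr1"][pos0]
        alt = _BASES[(_BASES.index(ref) + int(rng.integers(1, 4))) % 4]
        used.add(pos0)
        return var.Variant("chr1", pos0 + 1, ref, alt)
    return None


_CODING_CATEGORIES = ("synonymous", "nonsynonymous", "stopgain", "stoploss")


@dataclass
class PlantedGenomeResult:
    genome: dict[str, str]
    model: var.GeneModel
    genes: list[ToyGene]
    variants_a: list[var.Variant]
    variants_b: list[var.Variant]
    shared: list[var.Variant]
    truth: pd.DataFrame
    paths: dict[str, Path] = field(default_factory=dict)


def gen_genome_variants(spec: PlantedGenomeSpec, seed: int,
                        out_dir: str | Path | None = None,
                        splice_window: int = var.DEFAULT_SPLICE_WINDOW
                        ) -> PlantedGenomeResult:
    """Toy genome plus per-strain planted SNVs with verified ground truth.

    Every planted variant's intended location class / coding consequence is
    recomputed through the annotation module at generation time; any
    disagreement aborts generation.  When `out_dir` is given, FASTA, GFF3,
    two VCFs and a truth CSV are written.
    """
    rng = np.random.default_rng(seed)
    genome, model, genes = build_toy_genome(spec, seed)
    chrom_len = len(genome["chr1"])
    coding_genes = [g for g in genes if g.coding]
    used: set[int] = set()
    truth_rows: list[dict] = []

    def plant_category(category: str, strain: str) -> var.Variant:
        if category in _CODING_CATEGORIES:
            for _ in range(50):
                g = coding_genes[int(rng.integers(0, len(coding_genes)))]
                planted = _plant_coding(rng, g, genome, category, used)
                if planted:
                    v, cdna, prot = planted
                    loc = ("exonic;splicing"
                           if _exon_side_junction(g, v.pos0, splice_window)
                           else "exonic")
                    truth_rows.append({
                        "strain": strain, "chrom": v.chrom, "pos": v.pos,
                        "ref": v.ref, "alt": v.alt, "gene": g.name,
                        "location_class": loc, "coding_effect": category,
                        "cdna_notation": cdna, "protein_notation": prot,
                    })
                    return v
            raise GenerationError(f"could not plant {category}")
        v = _plant_noncoding(rng, genes, genome, category, chrom_len,
                             splice_window, used)
        if v is None:
            raise GenerationError(f"could not plant {category}")
        loc = {"exonic_splicing": "exonic;splicing"}.get(category, category)
        truth_rows.append({
            "strain": strain, "chrom": v.chrom, "pos": v.pos,
            "ref": v.ref, "alt": v.alt, "gene": None,
            "location_class": loc,
            "coding_effect": "none" if category != "exonic_splicing" else None,
            "cdna_notation": "", "protein_notation": "",
        })
        return v

    variants_a: list[var.Variant] = []
    variants_b: list[var.Variant] = []

    if spec.include_per2_case:
        per2 = next(g for g in coding_genes if g.name == "Per2")
        gpos0 = per2.cdna_to_genomic(515)
        assert genome["chr1"][gpos0] == "G"
        used.add(gpos0)
        v = var.Variant("chr1", gpos0 + 1, "G", "C")
        variants_a.append(v)
        truth_rows.append({
            "strain": "A", "chrom": v.chrom, "pos": v.pos, "ref": "G",
            "alt": "C", "gene": "Per2", "location_class": "exonic",
            "coding_effect": "nonsynonymous", "cdna_notation": "c.G515C",
            "protein_notation": "p.S172T",
        })

    for category, n in spec.counts_a.items():
        n_planted = n - (1 if category == "nonsynonymous"
                         and spec.include_per2_case else 0)
        for _ in range(max(n_planted, 0)):
            variants_a.append(plant_category(category, "A"))
    for category, n in spec.counts_b.items():
        for _ in range(n):
            variants_b.append(plant_category(category, "B"))

    shared: list[var.Variant] = []
    shared_cats = ("synonymous", "intronic", "intergenic")
    for i in range(spec.n_shared):
        v = plant_category(shared_cats[i % len(shared_cats)], "shared")
        shared.append(v)
    variants_a += shared
    variants_b += shared

    truth = pd.DataFrame(truth_rows)
    _verify_planted(truth, model, genome, splice_window)

    result = PlantedGenomeResult(
        genome=genome, model=model, genes=genes,
        variants_a=variants_a, variants_b=variants_b, shared=shared,
        truth=truth,
    )
    if out_dir is not None:
        result.paths = _write_genome_bundle(result, Path(out_dir))
    return result


def _exon_side_junction(g: ToyGene, pos0: int, window: int) -> bool:
    rel = pos0 - g.start
    junctions = (230, 350, 550, 670)
    for j, coord in enumerate(junctions):
        if j % 2 == 0 and 0 < coord - rel <= window:  # exon end
            return True
        if j % 2 == 1 and 0 < rel - coord + 1 <= window:  # exon start
            return True
    return False


def _verify_planted(truth: pd.DataFrame, model: var.GeneModel, genome,
                    splice_window: int) -> None:
    """Recompute every planted annotation through the annotation module."""
    for row in truth.itertuples(index=False):
        v = var.Variant(row.chrom, row.pos, row.ref, row.alt)
        loc = var.classify_location(v, model, splice_window)
        if loc != row.location_class:
            raise GenerationError(
                f"planted {row.location_class} at {row.chrom}:{row.pos} "
                f"annotates as {loc}")
        if row.coding_effect in _CODING_CATEGORIES:
            call = var.call_coding_effect(v, model, genome)
            if call is None or call.effect != row.coding_effect:
                raise GenerationError(
                    f"planted {row.coding_effect} at {row.chrom}:{row.pos} "
                    f"annotates as {call.effect if call else None}")
            if (call.cdna_notation != row.cdna_notation
                    or call.protein_notation != row.protein_notation):
                raise GenerationError(
                    f"notation mismatch at {row.chrom}:{row.pos}: "
                    f"{call.cdna_notation}:{call.protein_notation} vs "
                    f"{row.cdna_notation}:{row.protein_notation}")


def write_fasta(genome: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_gff3(genes: Sequence[ToyGene], path, source: str = "chronovar") -> None:
    """Emit gene/mRNA|ncRNA/exon/CDS features (1-based inclusive, GFF3)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            exons = g.exons
            start, end = exons[0][0] + 1, exons[-1][1]
            ttype = "mRNA" if g.coding else "ncRNA"
            fh.write(f"chr1\t{source}\tgene\t{start}\t{end}\t.\t{g.strand}\t.\t"
                     f"ID=gene:{g.name};Name={g.name}\n")
            tx = f"{g.name}_t1"
            fh.write(f"chr1\t{source}\t{ttype}\t{start}\t{end}\t.\t{g.strand}\t.\t"
                     f"ID={tx};Parent=gene:{g.name};gene_id={g.name}\n")
            for i, (s, e) in enumerate(exons, 1):
                fh.write(f"chr1\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                         f"ID={tx}.exon{i};Parent={tx}\n")
            if g.coding:
                blocks = g.cds if g.strand == "+" else list(reversed(g.cds))
                phase, cum = 0, 0
                lines = []
                for i, (s, e) in enumerate(blocks, 1):
                    lines.append((s, e, phase, i))
                    cum += e - s
                    phase = (3 - cum % 3) % 3
                for s, e, ph, i in sorted(lines):
                    fh.write(f"chr1\t{source}\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t"
                             f"{ph}\tID={tx}.cds{i};Parent={tx}\n")


def _write_genome_bundle(result: PlantedGenomeResult, out_dir: Path
                         ) -> dict[str, Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    contigs = {c: len(s) for c, s in result.genome.items()}
    paths = {
        "fasta": out_dir / "genome.fa",
        "gff3": out_dir / "genes.gff3",
        "vcf_a": out_dir / "strainA.vcf",
        "vcf_b": out_dir / "strainB.vcf",
        "truth": out_dir / "variant_truth.csv",
    }
    write_fasta(result.genome, paths["fasta"])
    write_gff3(result.genes, paths["gff3"])
    var.write_vcf(result.variants_a, paths["vcf_a"], contigs)
    var.write_vcf(result.variants_b, paths["vcf_b"], contigs)
    result.truth.to_csv(paths["truth"], index=False)
    return paths


# ===========================================================================
# Regions and SNPs

@dataclass
class PlantedRegionsSpec:
    """Binding regions with Poisson-planted SNPs at a known per-base rate.

    Defaults emulate the clock-factor region sets: seven factors, regions
    of ~1.5 kb, background SNP rate one per 219.6 nt.  Setting
    `enrichment_snps_per_region` > 0 adds Gaussian summit-centered SNPs
    (sd `enrichment_sd` nt).
    """

    factors: tuple[str, ...] = CLOCK_FACTORS
    regions_per_factor: int = 200
    region_length: int = 1500
    gap: int = 500
    background_rate: float = 1.0 / 219.6
    enrichment_snps_per_region: float = 0.0
    enrichment_sd: float = 100.0
    chrom: str = "chr1"
    gene_labels: tuple[str, ...] = CORE_CLOCK_GENES + METABOLIC_GENES

    def __post_init__(self) -> None:
        if self.background_rate <= 0:
            raise ValueError("background_rate must be positive")
        if self.enrichment_snps_per_region < 0:
            raise ValueError("enrichment weight must be non-negative")


@dataclass
class PlantedRegionsResult:
    regions: list[BindingRegion]
    snps: SnpSet
    truth: dict
    paths: dict[str, Path] = field(default_factory=dict)


def gen_regions_snps(spec: PlantedRegionsSpec, seed: int,
                     out_dir: str | Path | None = None,
                     file_prefix: str = "clock") -> PlantedRegionsResult:
    """Non-overlapping regions with summits and planted SNPs.

    SNP counts per region are Poisson(background_rate * length), positions
    uniform within the region, plus optionally Poisson-many summit-centered
    Gaussian positions clipped to the region.  The truth dict records the
    planted rates.
    """
    rng = np.random.default_rng(seed)
    regions: list[BindingRegion] = []
    positions: list[int] = []
    pos = spec.gap
    n_total = len(spec.factors) * spec.regions_per_factor
    for i in range(n_total):
        factor = spec.factors[i % len(spec.factors)]
        gene = spec.gene_labels[i % len(spec.gene_labels)]
        start, end = pos, pos + spec.region_length
        lo = start + spec.region_length // 4
        hi = end - spec.region_length // 4
        summit = int(rng.integers(lo, hi))
        regions.append(BindingRegion(chrom=spec.chrom, start=start, end=end,
                                     summit=summit, factor=factor, gene=gene))
        n_bg = rng.poisson(spec.background_rate * spec.region_length)
        positions.extend(rng.integers(start, end, size=n_bg).tolist())
        if spec.enrichment_snps_per_region > 0:
            n_en = rng.poisson(spec.enrichment_snps_per_region)
            draws = rng.normal(summit, spec.enrichment_sd, size=n_en)
            positions.extend(
                int(np.clip(round(d), start, end - 1)) for d in draws)
        pos = end + spec.gap

    snps = SnpSet({spec.chrom: positions}, source="planted")
    truth = {
        "background_rate": spec.background_rate,
        "reciprocal_rate": 1.0 / spec.background_rate,
        "enrichment_snps_per_region": spec.enrichment_snps_per_region,
        "enrichment_sd": spec.enrichment_sd,
        "n_regions": len(regions),
        "total_length": sum(r.length for r in regions),
    }
    result = PlantedRegionsResult(regions=regions, snps=snps, truth=truth)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "narrowpeak": out_dir / f"{file_prefix}_regions.narrowPeak",
            "snps": out_dir / f"{file_prefix}_snps.bed",
            "truth": out_dir / f"{file_prefix}_truth.csv",
        }
        write_narrowpeak(regions, paths["narrowpeak"])
        write_snp_bed(snps, paths["snps"])
        pd.DataFrame([truth]).to_csv(paths["truth"], index=False)
        result.paths = paths
    return result
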
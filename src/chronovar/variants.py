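"""SNV annotation: genomic location classes, coding consequences, Grantham
severity, and category enrichment.

Coordinates follow the field's two conventions with one centralized
conversion: VCF positions are 1-based inclusive at every interface, all
internal interval arithmetic is half-open 0-based.  Location classes use the
vocabulary {exonic, splicing, exonic;splicing, UTR5, UTR3, intronic,
intergenic, ncRNA}; when a variant overlaps several transcripts the highest-
precedence class is reported and the per-transcript detail retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .grantham import classify_gms, grantham_score

logger = logging.getLogger(__name__)

DEFAULT_SPLICE_WINDOW = 2

#: Highest first.  Reported class for a multi-transcript variant is the
#: first of its per-transcript classes in this order.
LOCATION_PRECEDENCE = (
    "exonic;splicing", "exonic", "splicing", "UTR5", "UTR3",
    "intronic", "ncRNA", "intergenic",
)

#: Most severe first, for the per-variant coding consequence.
EFFECT_SEVERITY = ("stopgain", "stoploss", "nonsynonymous", "synonymous", "none")


class ReferenceMismatchError(ValueError):
    """VCF REF base disagrees with the genome sequence."""


@dataclass(frozen=True, order=True)
class Variant:
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    strain: str | None = None

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"not a SNV: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def pos0(self) -> int:
        """0-based position (the centralized coordinate conversion)."""
        return self.pos - 1


@dataclass
class Transcript:
    tx_id: str
    gene: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]  # half-open 0-based, sorted by start
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(tuple(e) for e in self.exons)
        self.cds = sorted(tuple(c) for c in self.cds)
        for intervals, name in ((self.exons, "exons"), (self.cds, "CDS")):
            for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
                if e1 > s2:
                    raise ValueError(f"{name} overlap in {self.tx_id}")
        if self.coding and self.cds_length % 3 != 0:
            raise ValueError(
                f"CDS length {self.cds_length} of {self.tx_id} not divisible by 3")

    @property
    def coding(self) -> bool:
        return bool(self.cds)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def cds_position(self, pos0: int) -> int | None:
        """1-based cDNA coordinate of a genomic position within the CDS."""
        offset = 0
        if self.strand == "+":
            for s, e in self.cds:
                if s <= pos0 < e:
                    return offset + (pos0 - s) + 1
                offset += e - s
            return None
        for s, e in reversed(self.cds):
            if s <= pos0 < e:
                return offset + (e - 1 - pos0) + 1
            offset += e - s
        return None


class GeneModel:
    """A set of transcripts indexed by chromosome."""

    def __init__(self, transcripts: Iterable[Transcript]):
        self.transcripts = list(transcripts)
        self._by_chrom: dict[str, list[Transcript]] = {}
        for tx in self.transcripts:
            self._by_chrom.setdefault(tx.chrom, []).append(tx)
        for txs in self._by_chrom.values():
            txs.sort(key=lambda t: t.start)

    @classmethod
    def from_gff3(cls, path) -> "GeneModel":
        """Load transcripts from a GFF3 file (gene/mRNA|ncRNA/exon/CDS)."""
        import gffutils

        db = gffutils.create_db(str(path), ":memory:", force=True,
                                merge_strategy="create_unique",
                                keep_order=True)
        transcripts = []
        for tx in db.features_of_type(("mRNA", "ncRNA", "transcript")):
            gene = tx.attributes.get("gene_id", tx.attributes.get("Parent", [tx.id]))[0]
            exons = [(f.start - 1, f.end) for f in db.children(tx, featuretype="exon")]
            cds = [(f.start - 1, f.end) for f in db.children(tx, featuretype="CDS")]
            transcripts.append(Transcript(
                tx_id=tx.id, gene=gene, chrom=tx.seqid, strand=tx.strand,
                exons=exons or [(tx.start - 1, tx.end)], cds=cds,
            ))
        return cls(transcripts)

    def overlapping(self, chrom: str, pos0: int) -> list[Transcript]:
        return [tx for tx in self._by_chrom.get(chrom, ())
                if tx.start <= pos0 < tx.end]

    @property
    def chromosomes(self) -> set[str]:
        return set(self._by_chrom)


# ---------------------------------------------------------------------------
# VCF I/O

def read_variants(path, strain: str | None = None) -> list[Variant]:
    """Read SNVs from a VCF 4.x file via cyvcf2.

    Multi-allelic records are decomposed into biallelic variants; non-SNV
    alleles are skipped and the skip count logged.
    """
    from cyvcf2 import VCF

    variants: list[Variant] = []
    skipped = 0
    for rec in VCF(str(path)):
        for alt in rec.ALT:
            if (len(rec.REF) == 1 and len(alt) == 1
                    and rec.REF != alt and alt in "ACGT"):
                variants.append(Variant(rec.CHROM, rec.POS, rec.REF, alt,
                                        strain=strain))
            else:
                skipped += 1
    if skipped:
        logger.info("skipped %d non-SNV allele(s) in %s", skipped, path)
    return variants


def write_vcf(variants: Sequence[Variant], path,
              contigs: Mapping[str, int] | None = None) -> None:
    """Write SNVs as a minimal valid VCF 4.2 file (sorted)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=chronovar\n")
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants):
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\n")


# ---------------------------------------------------------------------------
# Strain comparison

@dataclass
class SharedRemoval:
    a_only: list[Variant]
    b_only: list[Variant]
    n_shared: int


def remove_shared(set_a: Sequence[Variant], set_b: Sequence[Variant]
                  ) -> SharedRemoval:
    """Drop variants identical in both strains, keyed by (chrom,pos,ref,alt)."""
    keys_a = {v.key for v in set_a}
    keys_b = {v.key for v in set_b}
    shared = keys_a & keys_b
    return SharedRemoval(
        a_only=[v for v in set_a if v.key not in shared],
        b_only=[v for v in set_b if v.key not in shared],
        n_shared=len(shared),
    )


# ---------------------------------------------------------------------------
# Location classification

def _classify_in_transcript(pos0: int, tx: Transcript, window: int) -> str | None:
    """Location class of one position within one transcript, or None."""
    if not (tx.start <= pos0 < tx.end):
        return None
    in_exon = any(s <= pos0 < e for s, e in tx.exons)
    if not tx.coding:
        return "ncRNA" if in_exon or len(tx.exons) > 1 else None
    if in_exon:
        in_cds = any(s <= pos0 < e for s, e in tx.cds)
        if in_cds:
            if _near_interior_junction_exon_side(pos0, tx, window):
                return "exonic;splicing"
            return "exonic"
        return _utr_side(pos0, tx)
    # Intronic; near-junction intron bases are the splicing class.
    if _near_junction_intron_side(pos0, tx, window):
        return "splicing"
    return "intronic"


def _interior_junctions(tx: Transcript) -> list[tuple[int, str]]:
    """Exon/intron boundaries interior to the transcript.

    Returned as (coordinate, side) where side 'end' is an exon end (intron
    starts at that coordinate) and 'start' an exon start (intron ends there).
    """
    jx = []
    for i, (s, e) in enumerate(tx.exons):
        if i > 0:
            jx.append((s, "start"))
        if i < len(tx.exons) - 1:
            jx.append((e, "end"))
    return jx


def _near_interior_junction_exon_side(pos0: int, tx: Transcript,
                                      window: int) -> bool:
    for coord, side in _interior_junctions(tx):
        if side == "end" and 0 < coord - pos0 <= window:
            return True
        if side == "start" and 0 < pos0 - coord + 1 <= window:
            return True
    return False


def _near_junction_intron_side(pos0: int, tx: Transcript, window: int) -> bool:
    for coord, side in _interior_junctions(tx):
        if side == "end" and 0 <= pos0 - coord < window:
            return True
        if side == "start" and 0 < coord - pos0 <= window:
            return True
    return False


def _utr_side(pos0: int, tx: Transcript) -> str:
    cds_start, cds_end = tx.cds[0][0], tx.cds[-1][1]
    if pos0 < cds_start:
        return "UTR5" if tx.strand == "+" else "UTR3"
    if pos0 >= cds_end:
        return "UTR3" if tx.strand == "+" else "UTR5"
    # Exonic but inside the CDS genomic span without being CDS cannot occur
    # for single-CDS-block-per-exon models; treat as intronic-adjacent UTR3.
    return "UTR3" if tx.strand == "+" else "UTR5"


def classify_location(variant: Variant, model: GeneModel,
                      splice_window: int = DEFAULT_SPLICE_WINDOW) -> str:
    """Precedence-ordered location class over all overlapping transcripts."""
    if variant.chrom not in model.chromosomes:
        logger.warning("chromosome %s not in gene model; classified intergenic",
                       variant.chrom)
        return "intergenic"
    classes = set()
    for tx in model.overlapping(variant.chrom, variant.pos0):
        cls = _classify_in_transcript(variant.pos0, tx, splice_window)
        if cls:
            classes.add(cls)
    for cls in LOCATION_PRECEDENCE:
        if cls in classes:
            return cls
    return "intergenic"


# ---------------------------------------------------------------------------
# Coding consequence

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _genome_base(genome, chrom: str, pos0: int) -> str:
    return str(genome[chrom][pos0:pos0 + 1]).upper()


def _cds_sequence(tx: Transcript, genome) -> str:
    parts = [str(genome[tx.chrom][s:e]) for s, e in tx.cds]
    seq = "".join(parts).upper()
    if tx.strand == "-":
        seq = seq.translate(_COMPLEMENT)[::-1]
    return seq


@dataclass
class CodingCall:
    tx_id: str
    effect: str
    cdna_notation: str
    protein_notation: str
    aa_from: str
    aa_to: str


def call_coding_effect(variant: Variant, model: GeneModel, genome
                       ) -> CodingCall | None:
    """Coding consequence of an exonic SNV against the standard genetic code.

    Evaluates every coding transcript whose CDS contains the variant and
    returns the most severe call (stopgain > stoploss > nonsynonymous >
    synonymous).  Notation follows the c.<ref><cdsPos><alt>:p.<refAA><aaPos>
    <altAA> style, with ref/alt in cDNA (coding-strand) orientation.
    Raises ReferenceMismatchError if the VCF REF disagrees with the genome.
    """
    calls = []
    for tx in model.overlapping(variant.chrom, variant.pos0):
        if not tx.coding:
            continue
        cds_pos = tx.cds_position(variant.pos0)
        if cds_pos is None:
            continue
        genome_ref = _genome_base(genome, variant.chrom, variant.pos0)
        if genome_ref != variant.ref:
            raise ReferenceMismatchError(
                f"{variant.chrom}:{variant.pos} REF {variant.ref} != "
                f"genome {genome_ref}")
        ref_c, alt_c = variant.ref, variant.alt
        if tx.strand == "-":
            ref_c = ref_c.translate(_COMPLEMENT)
            alt_c = alt_c.translate(_COMPLEMENT)
        cdna = _cds_sequence(tx, genome)
        assert cdna[cds_pos - 1] == ref_c, \
            f"internal CDS coordinate error in {tx.tx_id}"
        codon_idx = (cds_pos - 1) // 3
        codon = cdna[codon_idx * 3: codon_idx * 3 + 3]
        offset = (cds_pos - 1) % 3
        alt_codon = codon[:offset] + alt_c + codon[offset + 1:]
        aa_from = str(Seq(codon).translate())
        aa_to = str(Seq(alt_codon).translate())
        if aa_from == aa_to:
            effect = "synonymous"
        elif aa_to == "*":
            effect = "stopgain"
        elif aa_from == "*":
            effect = "stoploss"
        else:
            effect = "nonsynonymous"
        calls.append(CodingCall(
            tx_id=tx.tx_id, effect=effect,
            cdna_notation=f"c.{ref_c}{cds_pos}{alt_c}",
            protein_notation=f"p.{aa_from}{codon_idx + 1}{aa_to}",
            aa_from=aa_from, aa_to=aa_to,
        ))
    if not calls:
        return None
    calls.sort(key=lambda c: EFFECT_SEVERITY.index(c.effect))
    return calls[0]


# ---------------------------------------------------------------------------
# Full annotation

@dataclass
class AnnotatedVariant:
    variant: Variant
    location_class: str
    coding_effect: str = "none"
    gene: str | None = None
    cdna_notation: str = ""
    protein_notation: str = ""
    gms: int | None = None
    gms_class: str | None = None

    def __post_init__(self) -> None:
        if (self.gms is not None) != (self.coding_effect == "nonsynonymous"):
            raise ValueError("gms must be present iff effect is nonsynonymous")


def annotate_variants(variants: Sequence[Variant], model: GeneModel, genome,
                      splice_window: int = DEFAULT_SPLICE_WINDOW
                      ) -> list[AnnotatedVariant]:
    """Location class, coding consequence and Grantham severity per SNV."""
    out = []
    for v in variants:
        location = classify_location(v, model, splice_window)
        gene = None
        for tx in model.overlapping(v.chrom, v.pos0):
            if _classify_in_transcript(v.pos0, tx, splice_window):
                gene = tx.gene
                break
        effect, cdna, prot, gms, gms_cls = "none", "", "", None, None
        if location in ("exonic", "exonic;splicing"):
            call = call_coding_effect(v, model, genome)
            if call is not None:
                effect, cdna, prot = call.effect, call.cdna_notation, call.protein_notation
                if effect == "nonsynonymous":
                    gms = grantham_score(call.aa_from, call.aa_to)
                    gms_cls = classify_gms(gms)
        out.append(AnnotatedVariant(
            variant=v, location_class=location, coding_effect=effect,
            gene=gene, cdna_notation=cdna, protein_notation=prot,
            gms=gms, gms_class=gms_cls,
        ))
    return out


# ---------------------------------------------------------------------------
# Enrichment

def enrichment_fisher(gene_set: Iterable[str], background: Iterable[str],
                      category_map: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """One-sided Fisher exact enrichment of `gene_set` categories.

    `category_map` maps gene -> categories.  Returns one row per category
    with the 2x2 counts, odds ratio, raw p and Benjamini-Hochberg adjusted p.
    """
    gene_set = set(gene_set)
    background = set(background)
    if not gene_set <= background:
        raise ValueError("gene_set must be a subset of background")
    cat_members: dict[str, set[str]] = {}
    for gene in background:
        for cat in category_map.get(gene, ()):
            cat_members.setdefault(cat, set()).add(gene)
    if not cat_members:
        raise ValueError("no categories cover the background")

    rows = []
    for cat, members in sorted(cat_members.items()):
        k = len(gene_set & members)
        table = [[k, len(gene_set) - k],
                 [len(members) - k, len(background) - len(gene_set) - len(members) + k]]
        odds, p = stats.fisher_exact(table, alternative="greater")
        rows.append({"category": cat, "in_set": k, "set_size": len(gene_set),
                     "in_background": len(members),
                     "background_size": len(background),
                     "odds_ratio": odds, "p_value": p})
    df = pd.DataFrame(rows)
    df["p_bh"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


# ---------------------------------------------------------------------------
# Reporting

def variant_report(annotated_a: Sequence[AnnotatedVariant],
                   annotated_b: Sequence[AnnotatedVariant],
                   strain_a: str = "strain_a", strain_b: str = "strain_b",
                   n_shared: int = 0) -> dict[str, pd.DataFrame]:
    """Location/consequence breakdowns per strain and for the difference.

    The between-strain "difference" column counts the union of the two
    strain-unique sets (symmetric difference by variant key); per-strain
    columns count each strain's set after shared-variant removal, with the
    number of removed shared variants reported alongside.  Percentages use
    each column's total SNV count as denominator; one SNV can fall in
    several consequence rows across columns but has exactly one location
    class here.
    """

    def location_counts(annos: Sequence[AnnotatedVariant]) -> dict[str, int]:
        counts = {cls: 0 for cls in LOCATION_PRECEDENCE}
        effects = {e: 0 for e in EFFECT_SEVERITY if e != "none"}
        for a in annos:
            counts[a.location_class] += 1
            if a.coding_effect != "none":
                effects[a.coding_effect] += 1
        counts.update({f"exonic:{k}": v for k, v in effects.items()})
        counts["total"] = len(annos)
        return counts

    both = list(annotated_a) + list(annotated_b)
    cols = {strain_a: location_counts(annotated_a),
            strain_b: location_counts(annotated_b),
            "difference": location_counts(both)}
    loc = pd.DataFrame(cols)
    pct = loc.div(loc.loc["total"], axis=1).mul(100.0)
    loc_table = pd.concat({"count": loc, "pct": pct}, axis=1)
    loc_table.index.name = "category"

    gene_rows = []
    for strain, annos in ((strain_a, annotated_a), (strain_b, annotated_b)):
        for a in annos:
            if a.gene is None and a.location_class != "intergenic":
                continue
            gene_rows.append({
                "strain": strain, "gene": a.gene or "(intergenic)",
                "location_class": a.location_class,
                "coding_effect": a.coding_effect,
            })
    if gene_rows:
        per_gene = (pd.DataFrame(gene_rows)
                    .groupby(["gene", "location_class", "coding_effect"])
                    .size().rename("n_snvs").reset_index()
                    .sort_values(["gene", "location_class"])
                    .reset_index(drop=True))
    else:
        per_gene = pd.DataFrame(
            columns=["gene", "location_class", "coding_effect", "n_snvs"])

    gms_rows = [{"strain": s, "gms": a.gms, "gms_class": a.gms_class}
                for s, annos in ((strain_a, annotated_a), (strain_b, annotated_b))
                for a in annos if a.gms is not None]
    if gms_rows:
        gms = (pd.DataFrame(gms_rows).groupby("gms_class").size()
               .rename("n").reset_index())
        gms["pct"] = 100.0 * gms["n"] / gms["n"].sum()
    else:
        gms = pd.DataFrame(columns=["gms_class", "n", "pct"])

    summary = pd.DataFrame([{
        "n_" + strain_a: len(annotated_a),
        "n_" + strain_b: len(annotated_b),
        "n_shared_removed": n_shared,
        "n_difference_union": len(both),
    }])
    return {"location": loc_table, "per_gene": per_gene,
            "gms_classes": gms, "summary": summary}
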
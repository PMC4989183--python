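"""Variant annotation: location classes, coding consequences, enrichment."""

import math

import numpy as np
import pytest
from scipy import stats

from chronovar import variants as var
from chronovar.variants import (
    GeneModel,
    Transcript,
    Variant,
    annotate_variants,
    call_coding_effect,
    classify_location,
    enrichment_fisher,
    read_variants,
    remove_shared,
    variant_report,
    write_vcf,
)

LOCATION_RANK = {cls: i for i, cls in enumerate(var.LOCATION_PRECEDENCE)}


# ---------------------------------------------------------------------------
# Per-base painting oracle: label every base of the chromosome by painting
# per-transcript label tracks, then combine by precedence.  Structurally
# independent of the point-query classifier under test.

def paint_chromosome(transcripts, chrom_len, window):
    tracks = []
    for tx in transcripts:
        track = ["intergenic"] * chrom_len
        if not tx.coding:
            for p in range(tx.start, tx.end):
                track[p] = "ncRNA"
            tracks.append(track)
            continue
        for p in range(tx.start, tx.end):
            track[p] = "intronic"
        # splice windows on the intron side of interior junctions
        for i, (s, e) in enumerate(tx.exons):
            if i < len(tx.exons) - 1:
                for p in range(e, min(e + window, chrom_len)):
                    track[p] = "splicing"
            if i > 0:
                for p in range(max(s - window, 0), s):
                    track[p] = "splicing"
        # exon bases: UTR or CDS
        cds_start, cds_end = tx.cds[0][0], tx.cds[-1][1]
        for s, e in tx.exons:
            for p in range(s, e):
                if any(cs <= p < ce for cs, ce in tx.cds):
                    track[p] = "exonic"
                elif p < cds_start:
                    track[p] = "UTR5" if tx.strand == "+" else "UTR3"
                else:
                    track[p] = "UTR3" if tx.strand == "+" else "UTR5"
        # CDS bases within the window of an interior junction, exon side
        for i, (s, e) in enumerate(tx.exons):
            if i < len(tx.exons) - 1:
                for p in range(max(e - window, s), e):
                    if track[p] == "exonic":
                        track[p] = "exonic;splicing"
            if i > 0:
                for p in range(s, min(s + window, e)):
                    if track[p] == "exonic":
                        track[p] = "exonic;splicing"
        tracks.append(track)
    combined = []
    for p in range(chrom_len):
        labels = [track[p] for track in tracks]
        combined.append(min(labels, key=LOCATION_RANK.__getitem__))
    return combined


def random_toy_model(rng, chrom_len=3000):
    """A few random multi-exon transcripts with valid CDS on both strands."""
    transcripts = []
    pos = int(rng.integers(10, 120))
    i = 0
    while pos + 700 < chrom_len and i < 4:
        n_exons = int(rng.integers(1, 4))
        exons = []
        cursor = pos
        for _ in range(n_exons):
            elen = int(rng.integers(40, 180))
            exons.append((cursor, cursor + elen))
            cursor += elen + int(rng.integers(25, 120))
        total = sum(e - s for s, e in exons)
        coding = rng.random() < 0.75 and total >= 60
        cds = []
        if coding:
            utr5 = int(rng.integers(0, min(30, total - 30)))
            cds_len = ((total - utr5 - int(rng.integers(0, 25))) // 3) * 3
            cds_len = max(cds_len, 3)
            # carve the CDS out of the exon chain after utr5 bases
            remaining_skip, remaining_take = utr5, cds_len
            for s, e in exons:
                elen = e - s
                if remaining_skip >= elen:
                    remaining_skip -= elen
                    continue
                start = s + remaining_skip
                take = min(e - start, remaining_take)
                remaining_skip = 0
                if take > 0:
                    cds.append((start, start + take))
                    remaining_take -= take
                if remaining_take == 0:
                    break
        strand = "+" if rng.random() < 0.5 else "-"
        transcripts.append(Transcript(
            tx_id=f"t{i}", gene=f"g{i}", chrom="c", strand=strand,
            exons=exons, cds=cds))
        pos = cursor + int(rng.integers(50, 300))
        i += 1
    return transcripts


class TestClassifyLocation:
    def test_agrees_with_painting_oracle_on_random_models(self):
        rng = np.random.default_rng(12)
        window = 2
        for _ in range(50):
            transcripts = random_toy_model(rng)
            if not transcripts:
                continue
            model = GeneModel(transcripts)
            chrom_len = 3000
            oracle = paint_chromosome(transcripts, chrom_len, window)
            positions = rng.integers(0, chrom_len, size=200)
            for pos0 in positions:
                v = Variant("c", int(pos0) + 1, "A", "G")
                assert classify_location(v, model, window) == oracle[pos0], \
                    f"pos {pos0}"

    def test_mid_cds_is_exonic(self):
        tx = Transcript("t", "g", "c", "+", exons=[(0, 100), (200, 300)],
                        cds=[(10, 100), (200, 272)])
        model = GeneModel([tx])
        assert classify_location(Variant("c", 51, "A", "G"), model) == "exonic"

    def test_last_cds_base_is_exonic_splicing(self):
        tx = Transcript("t", "g", "c", "+", exons=[(0, 100), (200, 300)],
                        cds=[(10, 100), (200, 272)])
        model = GeneModel([tx])
        # genomic 0-based 99 = last base of exon 1, adjacent to the intron
        assert classify_location(Variant("c", 100, "A", "G"), model,
                                 splice_window=2) == "exonic;splicing"

    def test_unknown_chromosome_is_intergenic(self):
        model = GeneModel([Transcript("t", "g", "c", "+", exons=[(0, 90)],
                                      cds=[(0, 90)])])
        assert classify_location(Variant("other", 5, "A", "G"), model) \
            == "intergenic"


class TestCodingEffect:
    @staticmethod
    def _single_exon_gene(seq, strand="+"):
        genome = {"c": seq}
        tx = Transcript("t", "g", "c", strand, exons=[(0, len(seq))],
                        cds=[(0, len(seq))])
        return genome, GeneModel([tx])

    def test_wobble_synonymous(self):
        genome, model = self._single_exon_gene("ATGTTATAA")  # Met-Leu-Stop
        call = call_coding_effect(Variant("c", 6, "A", "G"), model, genome)
        assert call.effect == "synonymous"
        assert call.protein_notation == "p.L2L"

    def test_stopgain_and_stoploss(self):
        genome, model = self._single_exon_gene("ATGTACTAA")  # Met-Tyr-Stop
        gain = call_coding_effect(Variant("c", 6, "C", "A"), model, genome)
        assert gain.effect == "stopgain"  # TAC -> TAA
        loss = call_coding_effect(Variant("c", 7, "T", "C"), model, genome)
        assert loss.effect == "stoploss"  # TAA -> CAA

    def test_reference_mismatch_raises(self):
        genome, model = self._single_exon_gene("ATGTACTAA")
        with pytest.raises(var.ReferenceMismatchError):
            call_coding_effect(Variant("c", 6, "G", "A"), model, genome)

    def test_minus_strand_equals_reverse_complement_computation(self):
        """Annotating a minus-strand gene gives the same call as annotating
        the reverse-complemented locus on the plus strand."""
        from Bio.Seq import Seq

        cds = "ATGAGTCATTGGTAA"  # Met-Ser-His-Trp-Stop
        rc = str(Seq(cds).reverse_complement())
        genome_minus, model_minus = self._single_exon_gene(rc, strand="-")
        genome_plus, model_plus = self._single_exon_gene(cds, strand="+")
        # mutate cDNA position 5 (AGT -> ACT, Ser2Thr) on both layouts
        plus_call = call_coding_effect(Variant("c", 5, "G", "C"),
                                       model_plus, genome_plus)
        # same cDNA base sits at genomic position len-5 on the minus strand
        pos = len(cds) - 5 + 1
        minus_call = call_coding_effect(Variant("c", pos, "C", "G"),
                                        model_minus, genome_minus)
        for attr in ("effect", "cdna_notation", "protein_notation"):
            assert getattr(plus_call, attr) == getattr(minus_call, attr)
        assert plus_call.effect == "nonsynonymous"
        assert plus_call.protein_notation == "p.S2T"

    def test_worked_ser172thr_notation(self):
        """A gene carrying AGT at codon 172 mutated at cDNA 515 G>C yields
        the c.G515C:p.S172T call with Grantham score 58."""
        rng = np.random.default_rng(0)
        codons = ["ATG"]
        while len(codons) < 199:
            c = "".join(rng.choice(list("ACGT"), 3))
            if c not in {"TAA", "TAG", "TGA", "ATG"}:
                codons.append(c)
        codons[171] = "AGT"
        codons.append("TAA")
        seq = "".join(codons)
        genome, model = self._single_exon_gene(seq)
        v = Variant("c", 515, "G", "C")
        call = call_coding_effect(v, model, genome)
        assert call.cdna_notation == "c.G515C"
        assert call.protein_notation == "p.S172T"
        annotated = annotate_variants([v], model, genome)[0]
        assert annotated.gms == 58
        assert annotated.gms_class == "moderately conservative"


class TestVcfRoundTrip:
    def test_write_read_identity(self, tmp_path):
        variants = [Variant("chr1", 10, "A", "G"), Variant("chr1", 99, "C", "T"),
                    Variant("chr2", 5, "G", "A")]
        path = tmp_path / "x.vcf"
        write_vcf(variants, path, contigs={"chr1": 1000, "chr2": 1000})
        back = read_variants(path)
        assert [v.key for v in back] == [v.key for v in sorted(variants)]

    def test_empty_vcf(self, tmp_path):
        path = tmp_path / "empty.vcf"
        write_vcf([], path, contigs={"chr1": 100})
        assert read_variants(path) == []

    def test_non_snv_records_skipped(self, tmp_path):
        path = tmp_path / "mixed.vcf"
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##contig=<ID=chr1,length=1000>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            fh.write("chr1\t10\t.\tA\tG\t.\tPASS\t.\n")
            fh.write("chr1\t20\t.\tAT\tA\t.\tPASS\t.\n")  # indel
            fh.write("chr1\t30\t.\tC\tT\t.\tPASS\t.\n")
            fh.write("chr1\t40\t.\tG\tGA\t.\tPASS\t.\n")  # insertion
        assert len(read_variants(path)) == 2


class TestRemoveShared:
    def test_disjoint_unchanged(self):
        a = [Variant("c", 1, "A", "G")]
        b = [Variant("c", 2, "A", "G")]
        out = remove_shared(a, b)
        assert out.a_only == a and out.b_only == b and out.n_shared == 0

    def test_identical_sets_empty(self):
        a = [Variant("c", 1, "A", "G"), Variant("c", 2, "C", "T")]
        out = remove_shared(a, list(a))
        assert out.a_only == [] and out.b_only == [] and out.n_shared == 2

    def test_planted_overlap_counts(self):
        rng = np.random.default_rng(8)
        positions = rng.choice(10000, size=60, replace=False)
        shared = [Variant("c", int(p) + 1, "A", "G") for p in positions[:20]]
        a = shared + [Variant("c", int(p) + 1, "A", "G") for p in positions[20:40]]
        b = shared + [Variant("c", int(p) + 1, "A", "G") for p in positions[40:]]
        out = remove_shared(a, b)
        assert out.n_shared == 20
        assert len(out.a_only) == len(a) - 20
        assert len(out.b_only) == len(b) - 20
        # conservation: |a_only| + |shared| = |a| for de-duplicated inputs
        assert len(out.a_only) + out.n_shared == len(a)


class TestEnrichment:
    def test_matches_hypergeometric_enumeration(self):
        """The one-sided Fisher p for a 2x2 table equals the hypergeometric
        tail sum computed by direct enumeration."""
        k, set_rest, cat_rest, neither = 8, 2, 10, 80
        gene_set = [f"s{i}" for i in range(k + set_rest)]
        category = set(gene_set[:k]) | {f"c{i}" for i in range(cat_rest)}
        background = set(gene_set) | category | {f"b{i}" for i in range(neither)}
        out = enrichment_fisher(gene_set, background,
                                {g: ["cat"] for g in category})
        n_set = len(gene_set)
        n_cat = len(category)
        n_bg = len(background)
        tail = sum(stats.hypergeom.pmf(x, n_bg, n_cat, n_set)
                   for x in range(k, min(n_set, n_cat) + 1))
        assert out.p_value.item() == pytest.approx(tail, rel=1e-10)

    def test_perfect_enrichment_minimal_p(self):
        genes = [f"g{i}" for i in range(10)]
        background = genes + [f"x{i}" for i in range(90)]
        out = enrichment_fisher(genes, background, {g: ["hit"] for g in genes})
        minimal = 1.0 / math.comb(100, 10)
        assert out.p_value.item() == pytest.approx(minimal, rel=1e-6)

    def test_null_p_values_uniform(self):
        """Permuted category labels give approximately uniform p-values."""
        rng = np.random.default_rng(3)
        background = [f"g{i}" for i in range(60)]
        gene_set = background[:15]
        pvals = []
        for _ in range(400):
            members = rng.choice(background, size=20, replace=False)
            out = enrichment_fisher(gene_set, background,
                                    {g: ["cat"] for g in members})
            pvals.append(out.p_value.item())
        # discrete p-values are stochastically >= uniform under the null:
        # check the rejection rate at 0.05 is not inflated
        assert np.mean(np.array(pvals) < 0.05) <= 0.08

    def test_gene_set_outside_background_rejected(self):
        with pytest.raises(ValueError):
            enrichment_fisher(["a"], ["b"], {"b": ["x"]})


class TestVariantReport:
    def test_empty_input_all_zero(self):
        report = variant_report([], [])
        assert report["location"]["count"].sum().sum() == 0

    def test_planted_counts_recovered(self):
        from chronovar import simulate as sim

        spec = sim.PlantedGenomeSpec()
        res = sim.gen_genome_variants(spec, seed=21)
        ann_a = annotate_variants(
            [v for v in res.variants_a if v not in res.shared],
            res.model, res.genome)
        truth_a = res.truth[res.truth.strain == "A"]
        got = {cls: sum(a.location_class == cls for a in ann_a)
               for cls in var.LOCATION_PRECEDENCE}
        expected = truth_a.location_class.value_counts().to_dict()
        for cls, n in expected.items():
            assert got[cls] == n, cls

    def test_percentages_sum_to_100(self):
        from chronovar import simulate as sim

        res = sim.gen_genome_variants(sim.PlantedGenomeSpec(), seed=22)
        ann_a = annotate_variants(res.variants_a, res.model, res.genome)
        ann_b = annotate_variants(res.variants_b, res.model, res.genome)
        report = variant_report(ann_a, ann_b, "A", "B")
        pct = report["location"]["pct"]
        location_rows = [c for c in pct.index
                         if c in var.LOCATION_PRECEDENCE]
        for col in pct.columns:
            assert pct.loc[location_rows, col].sum() == pytest.approx(100.0)
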
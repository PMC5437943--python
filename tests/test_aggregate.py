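"""Gene×patient tabulation: conservation, severity, spectrum, CN mapping."""

import random

import pytest

from oncocohort.errors import PreconditionError, ValidationError
from oncocohort.formats_io import (
    ChromTable,
    GeneRecord,
    MafRecord,
    SegRecord,
)
from oncocohort.aggregate import (
    CNState,
    SEVERITY_RANK,
    accept_gistic_states,
    apply_gene_filters,
    build_mutation_matrix,
    gene_copy_states,
    log2_to_state,
    mutation_spectrum,
    summarize_cohort,
    worst_classification,
)


def maf(gene, sample, cls, *, vtype="SNP", ref="A", alt="T", start=100):
    if cls in ("Frame_Shift_Del", "In_Frame_Del"):
        vtype, ref, alt = "DEL", "AT", "A"
    elif cls in ("Frame_Shift_Ins", "In_Frame_Ins"):
        vtype, ref, alt = "INS", "A", "AT"
    return MafRecord(
        gene_symbol=gene, chrom="chr1", start=start, end=start + len(ref) - 1,
        ref_allele=ref, alt_allele=alt, variant_classification=cls,
        variant_type=vtype, sample_id=sample,
    )


def random_maf(rng: random.Random, n: int, n_genes=8, n_samples=6):
    classes = list(SEVERITY_RANK)
    recs = []
    for _ in range(n):
        cls = rng.choice(classes)
        ref = rng.choice("ACGT")
        alt = rng.choice([b for b in "ACGT" if b != ref])
        recs.append(
            maf(f"G{rng.randint(1, n_genes)}", f"S{rng.randint(1, n_samples)}",
                cls, ref=ref, alt=alt, start=rng.randint(1, 1000))
        )
    return recs


class TestMutationMatrix:
    def test_singleton(self):
        m = build_mutation_matrix([maf("TP53", "S1", "Missense_Mutation")])
        assert m.genes == ("TP53",) and m.patients == ("S1",)
        assert m.snv_cells[("TP53", "S1")].worst == "Missense_Mutation"
        assert m.patient_count["TP53"] == 1

    def test_worst_severity_and_counts(self):
        m = build_mutation_matrix(
            [maf("KMT2D", "S1", "Silent"), maf("KMT2D", "S1", "Nonsense_Mutation")],
            include_silent=True,
        )
        assert m.snv_cells[("KMT2D", "S1")].worst == "Nonsense_Mutation"
        assert m.mutation_count["KMT2D"] == 2
        assert m.patient_count["KMT2D"] == 1

    def test_empty_maf(self):
        m = build_mutation_matrix([])
        assert m.genes == () and m.patients == ()

    def test_silent_only_gene_has_zero_recurrence_by_default(self):
        m = build_mutation_matrix([maf("X", "S1", "Silent")])
        assert m.patient_count.get("X", 0) == 0
        assert ("X", "S1") in m.snv_cells  # cell still records the event

    def test_conservation_with_include_silent(self):
        rng = random.Random(3)
        recs = random_maf(rng, 250)
        m = build_mutation_matrix(recs, include_silent=True)
        assert m.total_cell_mutations() == len(recs)
        assert sum(m.mutation_count.values()) == len(recs)

    def test_severity_cell_matches_brute_force_max(self):
        rng = random.Random(11)
        recs = random_maf(rng, 300)
        m = build_mutation_matrix(recs)
        for (g, p), cell in m.snv_cells.items():
            classes = [
                r.variant_classification for r in recs
                if r.gene_symbol == g and r.sample_id == p
            ]
            assert SEVERITY_RANK[cell.worst] == max(SEVERITY_RANK[c] for c in classes)

    def test_roster_outside_records_rejected(self):
        with pytest.raises(ValidationError):
            build_mutation_matrix(
                [maf("A", "S9", "Silent")], patients=["S1", "S2"]
            )


class TestGeneCopyStates:
    GENES = [GeneRecord(symbol="G1", chrom="chr1", start=100, end=200)]

    def test_gene_inside_deep_loss_segment(self):
        segs = [SegRecord(sample_id="S1", chrom="chr1", start=1, end=1000,
                          log2_ratio=-1.3)]
        cn = gene_copy_states(segs, self.GENES)
        assert cn.cn_state("G1", "S1") == CNState.DEEP_LOSS

    def test_max_overlap_wins_on_split_gene(self):
        # 60% of the gene in a +0.5 segment, 40% in a -0.5 one
        segs = [
            SegRecord(sample_id="S1", chrom="chr1", start=1, end=160, log2_ratio=0.5),
            SegRecord(sample_id="S1", chrom="chr1", start=161, end=1000, log2_ratio=-0.5),
        ]
        cn = gene_copy_states(segs, self.GENES)
        assert cn.cn_state("G1", "S1") == CNState.GAIN

    def test_overlap_tie_goes_to_more_extreme_state(self):
        segs = [
            SegRecord(sample_id="S1", chrom="chr1", start=1, end=150, log2_ratio=0.4),
            SegRecord(sample_id="S1", chrom="chr1", start=151, end=1000, log2_ratio=-1.2),
        ]
        cn = gene_copy_states(segs, self.GENES)
        assert cn.cn_state("G1", "S1") == CNState.DEEP_LOSS

    def test_no_segments_means_neutral(self):
        segs = [SegRecord(sample_id="S1", chrom="chr9", start=1, end=10,
                          log2_ratio=1.4)]
        cn = gene_copy_states(segs, self.GENES)
        assert cn.cn_state("G1", "S1") == CNState.NEUTRAL

    def test_overlapping_segments_rejected(self):
        segs = [
            SegRecord(sample_id="S1", chrom="chr1", start=1, end=100, log2_ratio=0.0),
            SegRecord(sample_id="S1", chrom="chr1", start=50, end=150, log2_ratio=0.5),
        ]
        with pytest.raises(ValidationError):
            gene_copy_states(segs, self.GENES)

    def test_threshold_ordering_enforced(self):
        with pytest.raises(PreconditionError):
            log2_to_state(0.0, (-0.25, -1.0, 0.25, 1.0))

    def test_matches_per_base_overlap_oracle(self):
        """On small random genomes the max-overlap assignment agrees with a
        literal per-base tally of covered positions."""
        rng = random.Random(60)
        for _ in range(100):
            genome = 10_000
            genes = [
                GeneRecord(symbol=f"G{i}", chrom="chr1",
                           start=(s := rng.randrange(0, genome - 200)),
                           end=s + rng.randint(50, 200))
                for i in range(5)
            ]
            # non-overlapping random segmentation of the chromosome
            cuts = sorted(rng.sample(range(2, genome - 1), rng.randint(1, 19)))
            bounds = [0] + cuts + [genome]
            segs = [
                SegRecord(sample_id="S1", chrom="chr1", start=a + 1, end=b,
                          log2_ratio=round(rng.uniform(-2, 2), 3))
                for a, b in zip(bounds, bounds[1:])
            ]
            cn = gene_copy_states(segs, genes)
            for gene in genes:
                per_seg = []
                for seg in segs:
                    s0, e0 = seg.interval()
                    ov = sum(1 for b in range(gene.start, gene.end) if s0 <= b < e0)
                    if ov:
                        per_seg.append((ov, abs(int(log2_to_state(seg.log2_ratio))),
                                        abs(seg.log2_ratio), -seg.start,
                                        seg.log2_ratio))
                expect = (CNState.NEUTRAL if not per_seg
                          else log2_to_state(max(per_seg)[-1]))
                assert cn.cn_state(gene.symbol, "S1") == expect


class TestGistic:
    def test_direct_mapping(self):
        cn = accept_gistic_states({"A": {"S1": -2, "S2": 0}, "B": {"S1": 2}})
        assert cn.cn_state("A", "S1") == CNState.DEEP_LOSS
        assert cn.cn_state("A", "S2") == CNState.NEUTRAL
        assert cn.cn_state("B", "S1") == CNState.AMP

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            accept_gistic_states({"A": {"S1": 3}})


class TestGeneFilters:
    def _matrix(self, counts):
        recs = []
        for g, n in counts.items():
            for i in range(n):
                recs.append(maf(g, f"S{i}", "Missense_Mutation"))
        return build_mutation_matrix(recs)

    def test_threshold_and_blacklist(self):
        m = self._matrix({"A": 5, "B": 2, "C": 5})
        assert apply_gene_filters(m, 3, {"C"}) == ["A"]

    def test_identity_filter(self):
        m = self._matrix({"A": 2, "B": 1})
        assert set(apply_gene_filters(m, 1, set())) == {"A", "B"}

    def test_blacklist_everything(self):
        m = self._matrix({"A": 5})
        assert apply_gene_filters(m, 1, {"A"}) == []

    def test_monotone_in_threshold(self):
        rng = random.Random(8)
        m = build_mutation_matrix(random_maf(rng, 200))
        previous = None
        for t in range(1, 7):
            kept = set(apply_gene_filters(m, t, set()))
            if previous is not None:
                assert kept <= previous
            previous = kept

    def test_genomic_ordering(self):
        m = self._matrix({"A": 2, "B": 2, "C": 2})
        table = [
            GeneRecord(symbol="A", chrom="chr2", start=10, end=20),
            GeneRecord(symbol="B", chrom="chr1", start=500, end=600),
            GeneRecord(symbol="C", chrom="chr1", start=10, end=20),
        ]
        order = ChromTable((("chr1", 10**6), ("chr2", 10**6)))
        assert apply_gene_filters(
            m, 1, set(), gene_table=table, chrom_order=order
        ) == ["C", "B", "A"]


class TestSpectrum:
    def test_purine_reference_complemented(self):
        counts = mutation_spectrum([maf("X", "S1", "Silent", ref="G", alt="A")])
        assert counts.patient("S1")["C>T"] == 1

    def test_pyrimidine_reference_direct(self):
        counts = mutation_spectrum([maf("X", "S1", "Silent", ref="C", alt="T")])
        assert counts.patient("S1")["C>T"] == 1

    def test_counts_sum_to_snp_count(self):
        rng = random.Random(21)
        recs = random_maf(rng, 150)
        counts = mutation_spectrum(recs)
        n_snp = sum(1 for r in recs if r.variant_type == "SNP")
        total = sum(sum(counts.patient(p).values()) for p in {r.sample_id for r in recs})
        assert total + counts.n_skipped == n_snp

    def test_strand_complement_invariance(self):
        rng = random.Random(22)
        recs = [r for r in random_maf(rng, 200) if r.variant_type == "SNP"]
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        flipped = [
            MafRecord(
                gene_symbol=r.gene_symbol, chrom=r.chrom, start=r.start,
                end=r.end, ref_allele=comp[r.ref_allele],
                alt_allele=comp[r.alt_allele],
                variant_classification=r.variant_classification,
                variant_type=r.variant_type, sample_id=r.sample_id,
            )
            for r in recs
        ]
        a, b = mutation_spectrum(recs), mutation_spectrum(flipped)
        for p in {r.sample_id for r in recs}:
            assert a.patient(p) == b.patient(p)


class TestSummary:
    def test_single_record_tallies(self):
        s = summarize_cohort([maf("TP53", "S1", "Missense_Mutation")])
        assert s.classification_counts == {"Missense_Mutation": 1}
        assert s.variant_type_counts == {"SNP": 1}
        assert s.burden == {"S1": 1}

    def test_burden_sums_to_record_count(self):
        rng = random.Random(31)
        recs = random_maf(rng, 180)
        s = summarize_cohort(recs)
        assert sum(s.burden.values()) == len(recs)

    def test_threshold_above_cohort_empties_genecloud(self):
        s = summarize_cohort(
            [maf("A", "S1", "Missense_Mutation")], genecloud_min_patients=10
        )
        assert s.genecloud_weights == {}


def test_worst_classification_tie_is_deterministic():
    assert worst_classification(["Frame_Shift_Ins", "Frame_Shift_Del"]) == (
        worst_classification(["Frame_Shift_Del", "Frame_Shift_Ins"])
    )
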
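"""Gene-centric circos layout: slots, tracks, labels, deterministic emission."""

import random

import pytest

from oncocohort.errors import PreconditionError
from oncocohort.formats_io import ChromTable, GeneRecord
from oncocohort.aggregate import (
    CNState,
    CohortMatrix,
    SnvCell,
    build_mutation_matrix,
)
from oncocohort.circos import (
    STACK_ORDER,
    assign_gene_slots,
    build_bundle,
    build_cn_tracks,
    build_gene_karyotype,
    build_snv_track,
    emit_circos_bundle,
    genes_in_regions,
    style_labels,
)

ORDER = ChromTable((("chr1", 10**6), ("chr5", 10**6)))


def genes_on(chrom_counts):
    out = []
    i = 0
    for chrom, n in chrom_counts:
        for j in range(n):
            out.append(GeneRecord(symbol=f"{chrom}G{j}", chrom=chrom,
                                  start=1000 * (j + 1), end=1000 * (j + 1) + 100))
            i += 1
    return out


class TestKaryotype:
    def test_pseudo_chromosome_lengths_are_gene_counts(self):
        genes = genes_on([("chr1", 3), ("chr5", 1)])
        kt = build_gene_karyotype(genes, ORDER)
        assert kt.splitlines() == [
            "chr - chr1 chr1 0 3 grey",
            "chr - chr5 chr5 0 1 dgrey",
        ]

    def test_single_gene(self):
        kt = build_gene_karyotype(genes_on([("chr1", 1)]), ORDER)
        assert "chr1 chr1 0 1" in kt

    def test_slots_follow_genomic_start_order(self):
        genes = [
            GeneRecord(symbol="B", chrom="chr1", start=5000, end=5100),
            GeneRecord(symbol="A", chrom="chr1", start=100, end=200),
        ]
        slots = assign_gene_slots(genes, ORDER)
        assert [(s.symbol, s.start) for s in slots] == [("A", 0), ("B", 1)]

    def test_empty_gene_list_rejected(self):
        with pytest.raises(PreconditionError):
            build_gene_karyotype([], ORDER)

    def test_slot_conservation(self):
        rng = random.Random(17)
        for _ in range(30):
            genes = genes_on([("chr1", rng.randint(1, 9)), ("chr5", rng.randint(0, 9))])
            if not genes:
                continue
            slots = assign_gene_slots(genes, ORDER)
            kt = build_gene_karyotype(genes, ORDER)
            lengths = [int(l.split()[5]) for l in kt.splitlines()]
            assert sum(lengths) == len(genes) == len(slots)


def _matrix_with(cells, patients, counts=None):
    genes = tuple({g for g, _ in cells})
    m = CohortMatrix(genes=genes, patients=tuple(patients))
    for (g, p), classes in cells.items():
        m.snv_cells[(g, p)] = SnvCell(tuple(classes))
    m.patient_count = counts or {}
    return m


class TestSnvTrack:
    def test_stacked_values_in_severity_order(self):
        genes = genes_on([("chr1", 1)])
        genes[0] = GeneRecord(symbol="G", chrom="chr1", start=100, end=200)
        cells = {
            ("G", f"S{i}"): ["Missense_Mutation"] for i in range(3)
        }
        cells[("G", "S9")] = ["Nonsense_Mutation"]
        m = _matrix_with(cells, [f"S{i}" for i in range(3)] + ["S9"],
                         counts={"G": 4})
        slots = assign_gene_slots(genes, ORDER)
        stacked, total = build_snv_track(m, slots)
        values = [int(v) for v in stacked.split()[-1].split(",")]
        assert values[STACK_ORDER.index("Nonsense_Mutation")] == 1
        assert values[STACK_ORDER.index("Missense_Mutation")] == 3
        assert total.split()[-1] == "4"

    def test_stack_sums_to_patient_count(self, default_truth):
        from oncocohort.simulate import emit_maf

        m = build_mutation_matrix(emit_maf(default_truth))
        slots = assign_gene_slots(default_truth.genes, default_truth.chrom_table)
        stacked, _ = build_snv_track(m, slots)
        for line, slot in zip(stacked.splitlines(), slots):
            total = sum(int(v) for v in line.split()[-1].split(","))
            assert total == m.patient_count.get(slot.symbol, 0)

    def test_mutation_unit_sums_to_mutation_count(self, default_truth):
        from oncocohort.simulate import emit_maf

        m = build_mutation_matrix(emit_maf(default_truth))
        slots = assign_gene_slots(default_truth.genes, default_truth.chrom_table)
        stacked, _ = build_snv_track(m, slots, unit="mutations")
        for line, slot in zip(stacked.splitlines(), slots):
            total = sum(int(v) for v in line.split()[-1].split(","))
            assert total == m.mutation_count.get(slot.symbol, 0)


class TestCnTracks:
    def test_all_neutral_gene(self):
        genes = genes_on([("chr1", 1)])
        m = CohortMatrix(genes=("chr1G0",), patients=("S1", "S2"))
        slots = assign_gene_slots(genes, ORDER)
        gain, loss, mean = build_cn_tracks(m, slots)
        assert gain.split()[-1] == "0" and loss.split()[-1] == "0"
        assert mean.split()[-1] == "0"

    def test_half_amplified(self):
        genes = genes_on([("chr1", 1)])
        m = CohortMatrix(genes=("chr1G0",), patients=("S1", "S2", "S3", "S4"))
        m.cn_cells[("chr1G0", "S1")] = CNState.AMP
        m.cn_cells[("chr1G0", "S2")] = CNState.AMP
        slots = assign_gene_slots(genes, ORDER)
        gain, loss, mean = build_cn_tracks(m, slots)
        assert float(gain.split()[-1]) == 0.5
        assert float(loss.split()[-1]) == 0.0
        assert float(mean.split()[-1]) == 1.0

    def test_fractions_bounded(self):
        rng = random.Random(4)
        genes = genes_on([("chr1", 6)])
        patients = [f"S{i}" for i in range(10)]
        m = CohortMatrix(genes=tuple(g.symbol for g in genes),
                         patients=tuple(patients))
        for g in genes:
            for p in patients:
                st = rng.choice(list(CNState))
                if st != CNState.NEUTRAL:
                    m.cn_cells[(g.symbol, p)] = st
        gain, loss, _ = build_cn_tracks(m, assign_gene_slots(genes, ORDER))
        for track in (gain, loss):
            for line in track.splitlines():
                assert 0.0 <= float(line.split()[-1]) <= 1.0


class TestLabels:
    def _slots(self):
        return assign_gene_slots(genes_on([("chr1", 3)]), ORDER)

    def test_bold_at_exactly_twice_threshold(self):
        labels = style_labels(self._slots(), {"chr1G0": 10, "chr1G1": 9}, 5)
        lines = labels.splitlines()
        assert "label_font=bold" in lines[0]
        assert "label_font=bold" not in lines[1]

    def test_bold_and_color_co_occur(self):
        labels = style_labels(self._slots(), {"chr1G0": 12}, 5, {"chr1G0"})
        assert "label_font=bold,color=red" in labels.splitlines()[0]

    def test_unretained_highlight_warns(self):
        with pytest.warns(UserWarning, match="not retained"):
            style_labels(self._slots(), {}, 5, {"NOPE"})

    def test_every_retained_gene_labelled(self):
        slots = self._slots()
        labels = style_labels(slots, {}, 5)
        assert len(labels.splitlines()) == len(slots)


def test_genes_in_regions_overlap():
    genes = [GeneRecord(symbol="A", chrom="chr1", start=100, end=200),
             GeneRecord(symbol="B", chrom="chr1", start=500, end=600)]
    assert genes_in_regions(genes, [("chr1", 150, 400)]) == {"A"}


class TestBundle:
    def _bundle(self, truth):
        from oncocohort.simulate import emit_maf, emit_seg
        from oncocohort.aggregate import apply_gene_filters, gene_copy_states

        m = build_mutation_matrix(emit_maf(truth))
        cn = gene_copy_states(emit_seg(truth), truth.genes,
                              patients=truth.patients)
        retained = apply_gene_filters(
            m, 5, set(), gene_table=truth.genes, chrom_order=truth.chrom_table
        )
        records = [g for g in truth.genes if g.symbol in set(retained)]
        return build_bundle(m, cn, records, truth.chrom_table, 5), retained, m

    def test_referential_integrity(self, default_truth):
        bundle, retained, _ = self._bundle(default_truth)
        kt_lengths = {
            l.split()[2]: int(l.split()[5]) for l in bundle.karyotype.splitlines()
        }
        assert sum(kt_lengths.values()) == len(retained)
        for name, text in {**bundle.tracks, "labels": bundle.labels}.items():
            for line in text.splitlines():
                chrom, start, end = line.split()[0], int(line.split()[1]), int(line.split()[2])
                assert chrom in kt_lengths
                assert 0 <= start < end <= kt_lengths[chrom]
                assert end - start == 1  # exactly one gene slot

    def test_bold_set_matches_rule(self, default_truth):
        bundle, retained, m = self._bundle(default_truth)
        bold = {
            l.split()[3] for l in bundle.labels.splitlines()
            if "label_font=bold" in l
        }
        expected = {g for g in retained if m.patient_count.get(g, 0) >= 10}
        assert bold == expected
        assert bold <= set(retained)

    def test_reemission_is_byte_identical(self, default_truth, tmp_path):
        bundle, _, _ = self._bundle(default_truth)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        names1 = emit_circos_bundle(bundle, str(d1))
        names2 = emit_circos_bundle(bundle, str(d2))
        assert names1 == names2
        for name in names1:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_conf_references_every_track_once(self, default_truth, tmp_path):
        bundle, _, _ = self._bundle(default_truth)
        emit_circos_bundle(bundle, str(tmp_path))
        conf = (tmp_path / "circos.conf").read_text()
        for name in bundle.tracks:
            assert conf.count(f"{name}.txt") == 1

    def test_monotone_shrinkage(self, default_truth):
        from oncocohort.simulate import emit_maf
        from oncocohort.aggregate import apply_gene_filters

        m = build_mutation_matrix(emit_maf(default_truth))
        previous = None
        for t in (3, 6, 12, 24):
            retained = apply_gene_filters(
                m, t, set(), gene_table=default_truth.genes,
                chrom_order=default_truth.chrom_table,
            )
            if not retained:
                break
            kt = build_gene_karyotype(
                [g for g in default_truth.genes if g.symbol in set(retained)],
                default_truth.chrom_table,
            )
            size = sum(int(l.split()[5]) for l in kt.splitlines())
            if previous is not None:
                assert size <= previous
            previous = size
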
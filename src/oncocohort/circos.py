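"""Gene-centric circular layout: pseudo-karyotype and Circos data tracks.

Instead of plotting genes at genomic coordinates — where the interesting
recurrently mutated genes would be invisible slivers — the layout keeps only
genes above the recurrence threshold, preserves their relative order along
each chromosome, and gives every retained gene one unit-width slot.  A
chromosome's pseudo-length is therefore its retained-gene count, intergenic
space (and sub-threshold genes) having been eliminated.

Emitted files speak the Circos text dialect (karyotype, 2D data tracks,
text/label track) so the bundle can be rendered by an external Circos
install; the testable contract is the byte-deterministic text bundle, not
the rendering.

Tracks:

* ``snv_stacked`` — per-gene patient counts split by consequence class,
  comma-joined in severity order (a stacked histogram).
* ``snv_total``  — per-gene total mutated-patient count (circles/scatter).
* ``cn_gain`` / ``cn_loss`` — fraction of patients with a gain-side /
  loss-side copy state for the gene.
* ``cn_mean``  — mean ordinal copy state across patients.
* ``labels``   — one label per gene; bold when the gene's recurrence is at
  least twice the display threshold, colored when it is on the user's
  highlight list (or overlaps a highlighted region).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import PreconditionError
from .formats_io import ChromTable, GeneRecord
from .aggregate import CNState, CohortMatrix, SEVERITY_RANK

#: Stacking order of consequence classes in the snv_stacked track (severity
#: order, most severe first).
STACK_ORDER = tuple(SEVERITY_RANK)


@dataclass
class CircosBundle:
    """Karyotype + named data tracks + label track, all as Circos text."""

    karyotype: str
    tracks: dict[str, str] = field(default_factory=dict)
    labels: str = ""

    def files(self) -> dict[str, str]:
        out = {"karyotype.txt": self.karyotype}
        out.update({f"{name}.txt": text for name, text in self.tracks.items()})
        if self.labels:
            out["labels.txt"] = self.labels
        return out


@dataclass(frozen=True)
class GeneSlot:
    """Where one retained gene sits in the pseudo-karyotype."""

    symbol: str
    chrom: str
    start: int  # slot index on the pseudo-chromosome
    end: int  # start + 1


def assign_gene_slots(
    retained_genes: Sequence[GeneRecord], chrom_order: ChromTable
) -> list[GeneSlot]:
    """Unit-width slot per gene, genes kept in genomic order per chromosome."""
    if not retained_genes:
        raise PreconditionError("no retained genes to lay out")

    def key(g: GeneRecord):
        rank = (
            chrom_order.index(g.chrom)
            if g.chrom in chrom_order.names
            else len(chrom_order)
        )
        return (rank, g.start, g.symbol)

    slots = []
    counters: dict[str, int] = {}
    for g in sorted(retained_genes, key=key):
        i = counters.get(g.chrom, 0)
        counters[g.chrom] = i + 1
        slots.append(GeneSlot(symbol=g.symbol, chrom=g.chrom, start=i, end=i + 1))
    return slots


def build_gene_karyotype(
    retained_genes: Sequence[GeneRecord],
    chrom_order: ChromTable,
    *,
    color_cycle: Sequence[str] = ("grey", "dgrey"),
) -> str:
    """Karyotype lines ``chr - <id> <label> 0 <n_genes> <color>`` — one
    pseudo-chromosome per source chromosome holding ≥ 1 retained gene."""
    slots = assign_gene_slots(retained_genes, chrom_order)
    lengths: dict[str, int] = {}
    order: list[str] = []
    for s in slots:
        if s.chrom not in lengths:
            order.append(s.chrom)
        lengths[s.chrom] = max(lengths.get(s.chrom, 0), s.end)
    lines = []
    for i, chrom in enumerate(order):
        color = color_cycle[i % len(color_cycle)]
        lines.append(f"chr - {chrom} {chrom} 0 {lengths[chrom]} {color}")
    return "\n".join(lines) + "\n"


def _per_class_counts(
    matrix: CohortMatrix, gene: str, unit: str
) -> dict[str, int]:
    """Per-consequence-class tally for one gene.

    ``unit="patients"``: each counted patient contributes once, under the
    worst class among their counted records, so the classes sum to the
    gene's ``patient_count``.  ``unit="mutations"``: every counted record
    contributes, summing to ``mutation_count``.  "Counted" honours the
    matrix's ``include_silent`` policy.
    """
    from .aggregate import NON_CODING_CLASSES, worst_classification

    out: dict[str, int] = {}
    for (g, _p), cell in matrix.snv_cells.items():
        if g != gene:
            continue
        counted = [
            c
            for c in cell.classifications
            if matrix.include_silent or c not in NON_CODING_CLASSES
        ]
        if not counted:
            continue
        if unit == "patients":
            out_cls = worst_classification(counted)
            out[out_cls] = out.get(out_cls, 0) + 1
        else:
            for c in counted:
                out[c] = out.get(c, 0) + 1
    return out


def build_snv_track(
    matrix: CohortMatrix, slots: Sequence[GeneSlot], *, unit: str = "patients"
) -> tuple[str, str]:
    """(stacked-histogram track, total-count scatter track).

    The stacked track's value field comma-joins per-class counts in
    :data:`STACK_ORDER` — distinct patients by worst class when
    ``unit="patients"`` (the default; stack height equals the gene's
    recurrence) or raw mutation counts when ``unit="mutations"``.  The
    scatter value is the gene's total mutated-patient count.
    """
    if unit not in ("patients", "mutations"):
        raise PreconditionError(f"unknown unit {unit!r}")
    stacked, total = [], []
    for s in slots:
        per_class = _per_class_counts(matrix, s.symbol, unit)
        values = ",".join(str(per_class.get(cls, 0)) for cls in STACK_ORDER)
        stacked.append(f"{s.chrom} {s.start} {s.end} {values}")
        total.append(
            f"{s.chrom} {s.start} {s.end} {matrix.patient_count.get(s.symbol, 0)}"
        )
    return "\n".join(stacked) + "\n", "\n".join(total) + "\n"


def build_cn_tracks(
    cn_matrix: CohortMatrix, slots: Sequence[GeneSlot]
) -> tuple[str, str, str]:
    """Three inner copy-number tracks per gene slot.

    1. fraction of patients with a gain-side state (> NEUTRAL),
    2. fraction with a loss-side state (< NEUTRAL),
    3. mean ordinal state across all patients.
    """
    n = len(cn_matrix.patients)
    gain, loss, mean = [], [], []
    for s in slots:
        states = [cn_matrix.cn_state(s.symbol, p) for p in cn_matrix.patients]
        f_gain = sum(st > CNState.NEUTRAL for st in states) / n if n else 0.0
        f_loss = sum(st < CNState.NEUTRAL for st in states) / n if n else 0.0
        m = sum(int(st) for st in states) / n if n else 0.0
        gain.append(f"{s.chrom} {s.start} {s.end} {f_gain:.6g}")
        loss.append(f"{s.chrom} {s.start} {s.end} {f_loss:.6g}")
        mean.append(f"{s.chrom} {s.start} {s.end} {m:.6g}")
    return (
        "\n".join(gain) + "\n",
        "\n".join(loss) + "\n",
        "\n".join(mean) + "\n",
    )


def style_labels(
    slots: Sequence[GeneSlot],
    counts: Mapping[str, int],
    min_patients: int,
    highlight: set[str] = frozenset(),
    *,
    highlight_color: str = "red",
) -> str:
    """Label-track lines with per-gene styling.

    Bold iff the gene's mutated-patient count is at least twice the display
    threshold; colored iff the gene is on the highlight list.  Highlight
    entries that were not retained are ignored with a warning.
    """
    retained = {s.symbol for s in slots}
    for sym in sorted(highlight - retained):
        warnings.warn(f"highlight gene {sym!r} not retained; ignored", stacklevel=2)
    lines = []
    for s in slots:
        opts = []
        if counts.get(s.symbol, 0) >= 2 * min_patients:
            opts.append("label_font=bold")
        if s.symbol in highlight:
            opts.append(f"color={highlight_color}")
        opt_s = (" " + ",".join(opts)) if opts else ""
        lines.append(f"{s.chrom} {s.start} {s.end} {s.symbol}{opt_s}")
    return "\n".join(lines) + "\n"


def genes_in_regions(
    genes: Sequence[GeneRecord], regions: Sequence[tuple[str, int, int]]
) -> set[str]:
    """Genes overlapping any of the supplied (chrom, start, end) half-open
    regions — used to color genes inside recurrent-CNV regions the same way
    as highlight-list genes."""
    hit = set()
    for g in genes:
        for chrom, start, end in regions:
            if g.chrom == chrom and g.start < end and g.end > start:
                hit.add(g.symbol)
                break
    return hit


def build_bundle(
    matrix: CohortMatrix,
    cn_matrix: CohortMatrix,
    retained_genes: Sequence[GeneRecord],
    chrom_order: ChromTable,
    min_patients: int,
    highlight: set[str] = frozenset(),
) -> CircosBundle:
    """Assemble the complete circos text bundle for a filtered cohort."""
    slots = assign_gene_slots(retained_genes, chrom_order)
    karyotype = build_gene_karyotype(retained_genes, chrom_order)
    stacked, total = build_snv_track(matrix, slots)
    gain, loss, mean = build_cn_tracks(cn_matrix, slots)
    labels = style_labels(slots, matrix.patient_count, min_patients, highlight)
    return CircosBundle(
        karyotype=karyotype,
        tracks={
            "snv_stacked": stacked,
            "snv_total": total,
            "cn_gain": gain,
            "cn_loss": loss,
            "cn_mean": mean,
        },
        labels=labels,
    )


_CONF_TEMPLATE = """\
karyotype = {karyotype}

<ideogram>
<spacing>
default = 0.005r
</spacing>
radius    = 0.90r
thickness = 20p
fill      = yes
show_label = yes
label_radius = 1r + 75p
label_size = 30
</ideogram>

{plots}
<<include etc/colors_fonts_patterns.conf>>
<<include etc/housekeeping.conf>>
"""


def emit_circos_bundle(bundle: CircosBundle, out_dir: str) -> list[str]:
    """Write the bundle plus a minimal ``circos.conf`` referencing every
    track file exactly once.  Deterministic: re-emission is byte-identical.
    Returns the written file names."""
    os.makedirs(out_dir, exist_ok=True)
    written = []
    for name, text in sorted(bundle.files().items()):
        with open(os.path.join(out_dir, name), "w") as fh:
            fh.write(text)
        written.append(name)

    plot_blocks = []
    radius = 0.95
    for name in sorted(bundle.tracks):
        ptype = "histogram" if "stacked" in name else "scatter"
        plot_blocks.append(
            f"<plot>\ntype = {ptype}\nfile = {name}.txt\n"
            f"r1 = {radius:.2f}r\nr0 = {radius - 0.12:.2f}r\n</plot>"
        )
        radius -= 0.13
    if bundle.labels:
        plot_blocks.append(
            "<plot>\ntype = text\nfile = labels.txt\nr0 = 1r\nr1 = 1r+300p\n</plot>"
        )
    conf = _CONF_TEMPLATE.format(
        karyotype="karyotype.txt",
        plots="<plots>\n" + "\n".join(plot_blocks) + "\n</plots>\n",
    )
    with open(os.path.join(out_dir, "circos.conf"), "w") as fh:
        fh.write(conf)
    written.append("circos.conf")
    return written
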
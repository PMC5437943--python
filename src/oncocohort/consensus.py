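"""k-of-n ensemble consensus of somatic variant calls.

Individual somatic callers disagree substantially; a simple and robust
integration is to keep only the variants reported by at least ``k`` of the
``n`` callers.  Votes are counted under a normalized positional identity
(chrom, pos, ref, alt): alleles are upper-cased, shared trailing bases are
trimmed, then shared leading bases are trimmed with the position advanced,
stopping as soon as either allele is a single base.  This resolves the
representational differences between callers for SNVs and simple indels
without requiring a reference genome (no FASTA-based left-alignment is
attempted; see the methods note for the limitation).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import PreconditionError, ValidationError
from .formats_io import ChromTable, VcfDocument, VcfSite

PASS_FILTERS = frozenset({"PASS", "."})


@dataclass(frozen=True, order=True)
class VariantKey:
    """Normalized (chrom, pos, ref, alt) identity under which votes count."""

    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass(frozen=True)
class CallerResult:
    """The variant key set reported by one caller."""

    caller_name: str
    variants: frozenset[VariantKey]


@dataclass(frozen=True)
class ConsensusVariant:
    """A variant key together with the callers that support it."""

    key: VariantKey
    supporters: frozenset[str]

    @property
    def n_callers(self) -> int:
        return len(self.supporters)


def normalize_key(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Canonicalize a variant representation.

    Trailing bases shared by ref and alt are removed, then shared leading
    bases are removed with ``pos`` advanced, in both phases stopping when
    either allele would drop below one base.  Alleles that are identical
    after normalization are rejected.
    """
    if not ref or not alt:
        raise PreconditionError("ref and alt must be nonempty")
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if ref == alt:
        raise ValidationError(
            f"ref equals alt after normalization at {chrom}:{pos} ({ref})"
        )
    return VariantKey(chrom=chrom, pos=pos, ref=ref, alt=alt)


def split_multiallelic(site: VcfSite) -> list[VcfSite]:
    """Expand a comma-separated ALT field into one record per allele.

    INFO is copied verbatim; allele order is preserved.  (Sites read through
    ``formats_io.read_vcf_sites`` arrive already split; this handles records
    constructed directly.)
    """
    if not site.alt:
        raise ValidationError(f"empty ALT at {site.chrom}:{site.pos}")
    alts = site.alt.split(",")
    if any(not a for a in alts):
        raise ValidationError(f"empty ALT allele at {site.chrom}:{site.pos}")
    if len(alts) == 1:
        return [site]
    return [
        VcfSite(
            chrom=site.chrom, pos=site.pos, ref=site.ref, alt=a,
            filter=site.filter, info=site.info, id=site.id, qual=site.qual,
        )
        for a in alts
    ]


def caller_result_from_sites(
    name: str, sites: list[VcfSite], *, pass_only: bool = True
) -> CallerResult:
    """Collapse one caller's VCF records to a normalized key set.

    With ``pass_only`` (the default) only records whose FILTER is ``PASS`` or
    ``.`` contribute votes — callers flag their own low-confidence calls and
    an ensemble should count confident ones.
    """
    keys = set()
    for site in sites:
        for s in split_multiallelic(site):
            if pass_only and s.filter not in PASS_FILTERS:
                continue
            keys.add(normalize_key(s.chrom, s.pos, s.ref, s.alt))
    return CallerResult(caller_name=name, variants=frozenset(keys))


def vote(
    results: list[CallerResult],
    k: int,
    *,
    chrom_order: ChromTable | None = None,
) -> list[ConsensusVariant]:
    """Retain variants supported by at least ``k`` callers.

    ``k=1`` is the union of all call sets and ``k=n`` their intersection.
    Output is sorted by (chromosome — canonical rank when ``chrom_order`` is
    given, else name order — position, ref, alt).
    """
    if len(results) < 2:
        raise PreconditionError("an ensemble needs at least 2 callers")
    names = [r.caller_name for r in results]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate caller names in ensemble")
    if not 1 <= k <= len(results):
        raise PreconditionError(
            f"k={k} out of range [1, {len(results)}]"
        )
    support: dict[VariantKey, set[str]] = {}
    for r in results:
        for key in r.variants:
            support.setdefault(key, set()).add(r.caller_name)

    def rank(key: VariantKey):
        chrom = (
            chrom_order.index(key.chrom) if chrom_order is not None else key.chrom
        )
        return (chrom, key.pos, key.ref, key.alt)

    kept = [
        ConsensusVariant(key=key, supporters=frozenset(sup))
        for key, sup in support.items()
        if len(sup) >= k
    ]
    kept.sort(key=lambda c: rank(c.key))
    return kept


def consensus_to_vcf(
    consensus: list[ConsensusVariant], chrom_order: ChromTable
) -> VcfDocument:
    """Render a consensus as a sites-only VCF annotated with its support.

    Each record's INFO carries ``CALLERS`` (comma-joined sorted caller names)
    and ``NCALLERS`` (their count)."""
    sites = []
    for c in sorted(
        consensus,
        key=lambda c: (
            chrom_order.index(c.key.chrom), c.key.pos, c.key.ref, c.key.alt
        ),
    ):
        callers = ",".join(sorted(c.supporters))
        sites.append(
            VcfSite(
                chrom=c.key.chrom,
                pos=c.key.pos,
                ref=c.key.ref,
                alt=c.key.alt,
                filter="PASS",
                info=(("CALLERS", callers), ("NCALLERS", str(c.n_callers))),
            )
        )
    header = ["##fileformat=VCFv4.2"]
    for name, length in chrom_order:
        header.append(f"##contig=<ID={name},length={length}>")
    header.append(
        '##INFO=<ID=CALLERS,Number=.,Type=String,Description='
        '"Callers supporting this variant">'
    )
    header.append(
        '##INFO=<ID=NCALLERS,Number=1,Type=Integer,Description='
        '"Number of supporting callers">'
    )
    return VcfDocument(header=header, sites=sites)
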
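"""Immunoglobulin VL1 hypermutation assay: variant extraction and
point-mutation / gene-conversion classification.

The diversifying immunoglobulin light-chain variable gene of DT40 cells is a
natural lesion-bypass reporter: AID deaminates cytosines, the resulting
abasic sites are either bypassed by translesion synthesis (producing point
mutations at C/G pairs) or repaired by gene conversion (GC) templated by
upstream homeologous pseudogenes (producing tracts of templated changes).
Deep-sequenced amplicon reads covering the analysed region of VL1 are
aligned globally against the pre-expansion reference; base differences are
quality-filtered and classified:

* **point mutation** (PM_AT / PM_CG by the reference base pair) if the
  observed base is not present on any pseudogene at that position,
* **gene conversion** (GC) if at least two variants of the same amplicon
  match the same pseudogene and consecutive variants are at most 9 bp
  apart,
* **ambiguous** if donor-matching variants cannot form such a chain (the
  matching donors differ, or the distance exceeds 9 bp, or a donor-matching
  variant is isolated).

The maximum possible GC tract length is delimited by the closest
donor-specific positions flanking the event at which the read still carries
the reference base; with several compatible donors, the shortest tract is
reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import Align, SeqIO

logger = logging.getLogger(__name__)


class IgError(ValueError):
    pass


@dataclass(frozen=True)
class VLReference:
    """The VL1 amplicon with the analysed region marked (1-based, closed)."""

    seq: str
    region_start: int
    region_end: int

    def __post_init__(self) -> None:
        if not (1 <= self.region_start <= self.region_end <= len(self.seq)):
            raise IgError("analysed region must lie within the amplicon")
        if set(self.seq) - set("ACGTN"):
            raise IgError("amplicon must be uppercase DNA")

    def in_region(self, pos: int) -> bool:
        return self.region_start <= pos <= self.region_end


@dataclass
class PseudogeneAlignment:
    """A pseudogene donor projected onto amplicon coordinates.

    ``aligned[pos]`` is the donor base aligned to reference position ``pos``
    (absent positions are unaligned / gapped); ``donor_specific`` lists the
    positions where the donor differs from the reference.
    """

    donor_id: str
    aligned: dict[int, str]
    donor_specific: frozenset[int] = field(default_factory=frozenset)

    @classmethod
    def from_aligned_map(cls, donor_id: str, aligned: Mapping[int, str], ref: VLReference):
        specific = frozenset(
            pos for pos, base in aligned.items() if base != ref.seq[pos - 1]
        )
        return cls(donor_id=donor_id, aligned=dict(aligned), donor_specific=specific)


@dataclass(frozen=True)
class AmpliconVariant:
    pos: int
    ref: str
    obs: str
    qual: int

    def __post_init__(self) -> None:
        if self.ref == self.obs:
            raise IgError(f"variant at {self.pos} has ref == obs")


PM_AT = "PM_AT"
PM_CG = "PM_CG"
GC = "GC"
AMBIGUOUS = "AMBIGUOUS"
CATEGORIES = (PM_AT, PM_CG, GC, AMBIGUOUS)


@dataclass
class MutationEvent:
    category: str
    variants: tuple[AmpliconVariant, ...]
    donors: frozenset[str] = field(default_factory=frozenset)
    tract_max_length: int | None = None

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(v.pos for v in self.variants)


# ---------------------------------------------------------------------------
# Alignment


def make_aligner(
    match: float = 2.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


@dataclass
class AlignmentOutcome:
    variants: list[AmpliconVariant]
    has_indel: bool
    identity: float
    rejected: bool


def align_amplicon(
    read: str,
    quals: Sequence[int],
    ref: VLReference,
    aligner: Align.PairwiseAligner | None = None,
    min_identity: float = 0.8,
) -> AlignmentOutcome:
    """Globally align a merged read against the amplicon and extract variants.

    Substitutions within the analysed region are emitted with the base
    quality of the read position; indels are flagged but not classified.
    Reads whose identity (matching columns over amplicon length) falls below
    ``min_identity`` are rejected as foreign sequence.
    """
    if len(read) != len(quals):
        raise IgError("read and quality lengths differ")
    aligner = aligner or make_aligner()
    aln = aligner.align(ref.seq, read.upper())[0]
    t_blocks, q_blocks = aln.aligned
    matches = 0
    variants: list[AmpliconVariant] = []
    for (ts, te), (qs, _qe) in zip(t_blocks, q_blocks):
        for off in range(te - ts):
            rbase = ref.seq[ts + off]
            obase = read[qs + off].upper()
            if rbase == obase:
                matches += 1
            else:
                pos = ts + off + 1
                if ref.in_region(pos):
                    variants.append(
                        AmpliconVariant(pos=pos, ref=rbase, obs=obase, qual=quals[qs + off])
                    )
    has_indel = len(t_blocks) > 1
    identity = matches / len(ref.seq)
    rejected = identity < min_identity
    if rejected:
        logger.warning("rejecting read at identity %.2f (< %.2f)", identity, min_identity)
        variants = []
    return AlignmentOutcome(
        variants=sorted(variants, key=lambda v: v.pos),
        has_indel=has_indel,
        identity=identity,
        rejected=rejected,
    )


def filter_quality(
    variants: Iterable[AmpliconVariant], min_q: int = 30
) -> list[AmpliconVariant]:
    """Keep variants with base quality strictly greater than ``min_q``."""
    return [v for v in variants if v.qual > min_q]


# ---------------------------------------------------------------------------
# Classification


def _donor_matches(
    variant: AmpliconVariant, donors: Sequence[PseudogeneAlignment]
) -> frozenset[str]:
    return frozenset(
        d.donor_id for d in donors if d.aligned.get(variant.pos) == variant.obs
    )


def classify_amplicon(
    variants: Sequence[AmpliconVariant],
    donors: Sequence[PseudogeneAlignment],
    max_distance: int = 9,
) -> list[MutationEvent]:
    """Partition the variants of one amplicon into mutation events.

    Donor-matching variants are chained transitively: a variant joins the
    current chain when it lies within ``max_distance`` bp of the previous
    member and shares at least one donor with all members so far.  Chains of
    two or more become GC events (compatible donors = intersection of member
    donor sets); isolated donor-matching variants are AMBIGUOUS; variants
    matching no donor are point mutations, subtyped by the reference base
    pair.  Every variant belongs to exactly one event.
    """
    donors = sorted(donors, key=lambda d: d.donor_id)
    events: list[MutationEvent] = []
    chain: list[AmpliconVariant] = []
    chain_donors: frozenset[str] = frozenset()

    def flush() -> None:
        nonlocal chain, chain_donors
        if not chain:
            return
        if len(chain) >= 2:
            events.append(MutationEvent(GC, tuple(chain), donors=chain_donors))
        else:
            events.append(MutationEvent(AMBIGUOUS, tuple(chain), donors=chain_donors))
        chain, chain_donors = [], frozenset()

    for v in sorted(variants, key=lambda v: v.pos):
        matched = _donor_matches(v, donors)
        if not matched:
            flush()
            category = PM_AT if v.ref in "AT" else PM_CG
            events.append(MutationEvent(category, (v,)))
            continue
        if chain and v.pos - chain[-1].pos <= max_distance and chain_donors & matched:
            chain.append(v)
            chain_donors &= matched
        else:
            flush()
            chain, chain_donors = [v], matched
    flush()
    return sorted(events, key=lambda e: e.positions[0])


def gc_tract_max_length(
    event: MutationEvent,
    donors_by_id: Mapping[str, PseudogeneAlignment],
    all_variants: Sequence[AmpliconVariant],
    ref: VLReference,
    inclusive: bool = False,
) -> int:
    """Maximum possible copied-tract length of a GC event, in nucleotides.

    For each compatible donor, the tract is delimited by the closest
    donor-specific positions outside the event at which the amplicon retains
    the reference base (upstream delimiter u, downstream delimiter v);
    delimiters absent within the analysed region fall back to the region
    boundary -1 / +1.  The default length is exclusive of the delimiters,
    v - u - 1; ``inclusive`` counts them.  The minimum over compatible
    donors is returned (shortest-tract rule).
    """
    if event.category != GC:
        raise IgError("tract length is only defined for GC events")
    variant_positions = {v.pos for v in all_variants}
    lo, hi = min(event.positions), max(event.positions)
    lengths = []
    for donor_id in sorted(event.donors):
        donor = donors_by_id[donor_id]
        specific = [
            p
            for p in donor.donor_specific
            if ref.in_region(p) and p not in variant_positions
        ]
        upstream = [p for p in specific if p < lo]
        downstream = [p for p in specific if p > hi]
        u = max(upstream) if upstream else ref.region_start - 1
        v = min(downstream) if downstream else ref.region_end + 1
        lengths.append(v - u + 1 if inclusive else v - u - 1)
    if not lengths:
        raise IgError("GC event has no compatible donors")
    return min(lengths)


# ---------------------------------------------------------------------------
# Per-read pipeline and sample summaries


@dataclass
class ReadResult:
    read_id: str
    events: list[MutationEvent]
    rejected: bool = False
    has_indel: bool = False


@dataclass
class SampleIgSummary:
    counts: dict[str, int]
    n_read_pairs: int
    rates: dict[str, float]

    @property
    def gc_rate(self) -> float:
        return self.rates[GC]


def summarize_sample(
    events_per_read: Sequence[Sequence[MutationEvent]], n_read_pairs: int
) -> SampleIgSummary:
    """Per-category event counts and rates per sequenced read pair."""
    if n_read_pairs <= 0:
        raise IgError("n_read_pairs must be > 0")
    counts = {c: 0 for c in CATEGORIES}
    for events in events_per_read:
        for e in events:
            counts[e.category] += 1
    rates = {c: counts[c] / n_read_pairs for c in CATEGORIES}
    return SampleIgSummary(counts=counts, n_read_pairs=n_read_pairs, rates=rates)


def classify_read(
    read: str,
    quals: Sequence[int],
    ref: VLReference,
    donors: Sequence[PseudogeneAlignment],
    read_id: str = "",
    aligner: Align.PairwiseAligner | None = None,
    min_q: int = 30,
    max_distance: int = 9,
) -> ReadResult:
    """Align, quality-filter, classify and measure GC tracts for one read."""
    outcome = align_amplicon(read, quals, ref, aligner=aligner)
    if outcome.rejected:
        return ReadResult(read_id, [], rejected=True, has_indel=outcome.has_indel)
    variants = filter_quality(outcome.variants, min_q=min_q)
    events = classify_amplicon(variants, donors, max_distance=max_distance)
    donors_by_id = {d.donor_id: d for d in donors}
    for e in events:
        if e.category == GC:
            e.tract_max_length = gc_tract_max_length(e, donors_by_id, variants, ref)
    return ReadResult(read_id, events, has_indel=outcome.has_indel)


def process_reads(
    reads: Iterable[tuple[str, str, Sequence[int]]],
    ref: VLReference,
    donors: Sequence[PseudogeneAlignment],
    min_q: int = 30,
    max_distance: int = 9,
) -> list[ReadResult]:
    aligner = make_aligner()
    return [
        classify_read(
            seq, quals, ref, donors,
            read_id=read_id, aligner=aligner, min_q=min_q, max_distance=max_distance,
        )
        for read_id, seq, quals in reads
    ]


# ---------------------------------------------------------------------------
# I/O helpers


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, list[int]]]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq).upper(), list(rec.letter_annotations["phred_quality"])


def read_fasta_reads(
    path: str | Path, assumed_quality: int = 40
) -> Iterator[tuple[str, str, list[int]]]:
    """FASTA fallback for merged reads; every base gets ``assumed_quality``."""
    logger.warning("FASTA input: assuming uniform base quality %d", assumed_quality)
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        yield rec.id, seq, [assumed_quality] * len(seq)


def align_donor(
    ref: VLReference, donor_id: str, donor_seq: str, aligner: Align.PairwiseAligner | None = None
) -> PseudogeneAlignment:
    """Project a donor sequence onto amplicon coordinates by global alignment."""
    aligner = aligner or make_aligner()
    aln = aligner.align(ref.seq, donor_seq.upper())[0]
    t_blocks, q_blocks = aln.aligned
    aligned: dict[int, str] = {}
    for (ts, te), (qs, _qe) in zip(t_blocks, q_blocks):
        for off in range(te - ts):
            aligned[ts + off + 1] = donor_seq[qs + off].upper()
    return PseudogeneAlignment.from_aligned_map(donor_id, aligned, ref)


def donors_from_fasta(path: str | Path, ref: VLReference) -> list[PseudogeneAlignment]:
    aligner = make_aligner()
    return [
        align_donor(ref, rec.id, str(rec.seq), aligner)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
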
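"""Trinucleotide-context mutation spectra and context-specific counters.

Single-base substitutions (SBS) are conventionally reported on the
pyrimidine strand: a mutation whose reference base is a purine is mapped to
the reverse complement, so the 6 substitution classes (C>A, C>G, C>T, T>A,
T>C, T>G) combined with the 4x4 flanking bases give the standard 96-channel
triplet spectrum.  This module provides:

* mutation-list I/O (TSV and single-sample VCF),
* classification of SBS records into the 96 channels given a reference
  genome,
* context-specific counters used in DNA-adduct mutagenesis analyses
  (NCC>NAC substitutions at dinucleotide adduct motifs, single-T insertions
  after GG, deletion size histograms),
* genome triplet-frequency tables and cross-genome spectrum adjustment,
  used when comparing spectra derived from different species to reference
  signature catalogues.

Coordinates are 1-based and fully closed throughout (VCF convention), and
indel records use VCF-style anchored alleles (the first base of ref and alt
is the shared anchor base).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
PYRIMIDINES = "CT"
PURINES = "AG"
BASES = "ACGT"

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: The 96 channel names in COSMIC order: substitution classes as above,
#: flanks alphabetical (5' major, 3' minor), e.g. "A[C>A]A".
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_CLASSES
    for five in BASES
    for three in BASES
)
CHANNEL_INDEX = {name: i for i, name in enumerate(CHANNELS)}

#: The 32 pyrimidine-centred triplets, in channel-compatible order.
PYRIMIDINE_TRIPLETS: tuple[str, ...] = tuple(
    f"{five}{centre}{three}" for centre in PYRIMIDINES for five in BASES for three in BASES
)

#: For channel i, the pyrimidine-centred reference triplet it sits in.
CHANNEL_TRIPLETS: tuple[str, ...] = tuple(
    f"{name[0]}{name[2]}{name[6]}" for name in CHANNELS
)


class SpectraError(ValueError):
    """Base class for mutation-spectrum errors."""


class EdgeContextError(SpectraError):
    """SBS at a contig edge: no flanking base."""


class AmbiguousContextError(SpectraError):
    """The trinucleotide context contains an N."""


class RefMismatchError(SpectraError):
    """Record reference allele disagrees with the genome."""


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def collapse_triplet(triplet: str) -> str:
    """Map a 3-mer to its pyrimidine-centred (double-strand collapsed) representative."""
    if triplet[1] in PYRIMIDINES:
        return triplet
    return revcomp(triplet)


@dataclass(frozen=True)
class TripletClass:
    """A pyrimidine-centred substitution class with its 5' and 3' flanks."""

    substitution: str
    five_prime: str
    three_prime: str

    def __post_init__(self) -> None:
        if self.substitution not in SUBSTITUTION_CLASSES:
            raise SpectraError(f"not a pyrimidine-centred class: {self.substitution}")
        if self.five_prime not in BASES or self.three_prime not in BASES:
            raise SpectraError("flanking bases must be A/C/G/T")

    @property
    def name(self) -> str:
        return f"{self.five_prime}[{self.substitution}]{self.three_prime}"

    @property
    def channel(self) -> int:
        return CHANNEL_INDEX[self.name]

    @property
    def triplet(self) -> str:
        return f"{self.five_prime}{self.substitution[0]}{self.three_prime}"


class GenomeRef:
    """A reference genome: uppercase sequences keyed by contig name.

    Coordinates are 1-based, fully closed.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self.sequences: dict[str, str] = {}
        for name, seq in sequences.items():
            if name in self.sequences:
                raise SpectraError(f"duplicate contig name {name!r}")
            seq = seq.upper()
            if set(seq) - set("ACGTN"):
                bad = sorted(set(seq) - set("ACGTN"))
                raise SpectraError(f"contig {name!r} contains non-ACGTN bases {bad}")
            self.sequences[name] = seq

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeRef":
        return cls({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")

    def base(self, chrom: str, pos: int) -> str:
        return self.sequences[chrom][pos - 1]

    def slice(self, chrom: str, start: int, end: int) -> str:
        """1-based closed slice [start, end]."""
        return self.sequences[chrom][start - 1 : end]


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation call.

    ``mut_class`` follows from allele lengths: SBS (1:1), INS (alt longer),
    DEL (ref longer).  Indels are anchored: ref and alt share their first base.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        for allele, label in ((self.ref, "ref"), (self.alt, "alt")):
            if not allele or set(allele) - set("ACGTN"):
                raise SpectraError(f"invalid {label} allele {allele!r}")
        if self.ref == self.alt:
            raise SpectraError(f"ref equals alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise SpectraError(f"position must be >= 1, got {self.pos}")
        if len(self.ref) != len(self.alt) and self.ref[0] != self.alt[0]:
            raise SpectraError(
                f"indel at {self.chrom}:{self.pos} is not anchored (ref {self.ref}, alt {self.alt})"
            )

    @property
    def mut_class(self) -> str:
        if len(self.ref) == len(self.alt):
            if len(self.ref) != 1:
                raise SpectraError("multi-base substitutions are not supported")
            return "SBS"
        return "INS" if len(self.alt) > len(self.ref) else "DEL"


@dataclass
class TripletSpectrum:
    """An ordered 96-channel SBS count vector."""

    counts: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise SpectraError(f"spectrum must have 96 channels, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise SpectraError("spectrum counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CHANNELS), name=self.label)


# ---------------------------------------------------------------------------
# Mutation list I/O

_TSV_COLUMNS = ["sample", "chrom", "pos", "ref", "alt"]


def read_mutations(path: str | Path, sample_id: str | None = None) -> list[MutationRecord]:
    """Read a mutation list from TSV (sample, chrom, pos, ref, alt) or VCF.

    VCF files (suffix .vcf) are single-sample; ``sample_id`` names the sample
    (default: the file stem).  Malformed rows raise with the line number.
    """
    path = Path(path)
    if path.suffix == ".vcf":
        return _read_vcf(path, sample_id or path.stem)
    records: list[MutationRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TSV_COLUMNS and header[: len(_TSV_COLUMNS)] != _TSV_COLUMNS:
            raise SpectraError(
                f"{path}: expected header {_TSV_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise SpectraError(f"{path}:{lineno}: expected >=5 columns, got {len(fields)}")
            try:
                rec = MutationRecord(
                    sample_id=fields[0],
                    chrom=fields[1],
                    pos=int(fields[2]),
                    ref=fields[3].upper(),
                    alt=fields[4].upper(),
                )
            except (SpectraError, ValueError) as exc:
                raise SpectraError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


def _read_vcf(path: Path, sample_id: str) -> list[MutationRecord]:
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None:
                continue
            for alt in rec.alts:
                records.append(
                    MutationRecord(
                        sample_id=sample_id,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref.upper(),
                        alt=str(alt).upper(),
                    )
                )
    return records


def write_mutations(records: Iterable[MutationRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for r in records:
            fh.write(f"{r.sample_id}\t{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}\n")


# ---------------------------------------------------------------------------
# Classification and spectra


def classify_sbs(m: MutationRecord, genome: GenomeRef) -> TripletClass:
    """Classify an SBS into its pyrimidine-centred triplet channel.

    Purine-reference mutations are mapped to the reverse complement: the
    flanks are complemented and swapped so that e.g. G>A in a TGA context
    becomes T[C>T]A.
    """
    if m.mut_class != "SBS":
        raise SpectraError(f"record at {m.chrom}:{m.pos} is not an SBS")
    seq = genome.sequences[m.chrom]
    if m.pos < 2 or m.pos > len(seq) - 1:
        raise EdgeContextError(f"{m.chrom}:{m.pos}: no flanking base at contig edge")
    triplet = seq[m.pos - 2 : m.pos + 1]
    if "N" in triplet:
        raise AmbiguousContextError(f"{m.chrom}:{m.pos}: N in trinucleotide context")
    if triplet[1] != m.ref:
        raise RefMismatchError(
            f"{m.chrom}:{m.pos}: genome has {triplet[1]}, record ref is {m.ref}"
        )
    ref, alt = m.ref, m.alt
    five, three = triplet[0], triplet[2]
    if ref in PURINES:
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        five, three = COMPLEMENT[three], COMPLEMENT[five]
    return TripletClass(f"{ref}>{alt}", five, three)


def build_triplet_spectrum(
    muts: Iterable[MutationRecord], genome: GenomeRef, label: str = ""
) -> TripletSpectrum:
    """Build a 96-channel spectrum from the SBS records of a mutation list.

    Non-SBS records are ignored.  Records at contig edges or overlapping N
    are skipped with a warning; a reference-allele mismatch raises.
    """
    counts = np.zeros(96)
    for m in muts:
        if m.mut_class != "SBS":
            continue
        try:
            cls = classify_sbs(m, genome)
        except (EdgeContextError, AmbiguousContextError) as exc:
            logger.warning("skipping unclassifiable SBS: %s", exc)
            continue
        counts[cls.channel] += 1
    return TripletSpectrum(counts, label=label)


def write_spectra(spectra: Sequence[TripletSpectrum], path: str | Path) -> None:
    df = pd.DataFrame({s.label or f"spectrum_{i}": s.counts for i, s in enumerate(spectra)})
    df.index = list(CHANNELS)
    df.index.name = "channel"
    df.to_csv(path, sep="\t")


def read_spectra(path: str | Path) -> list[TripletSpectrum]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(CHANNELS):
        raise SpectraError(f"{path}: channel rows do not match the fixed 96-channel order")
    return [TripletSpectrum(df[col].to_numpy(), label=str(col)) for col in df.columns]


# ---------------------------------------------------------------------------
# Context-specific counters


def count_ncc_nac(muts: Iterable[MutationRecord], genome: GenomeRef) -> int:
    """Count NCC>NAC substitutions (C>A with a 3' C, any 5' base).

    These capture mutagenesis at GG/AG dinucleotide adducts read on the
    pyrimidine strand; opposite-strand GGN>GTN events collapse onto the same
    channels and are included.
    """
    n = 0
    for m in muts:
        if m.mut_class != "SBS":
            continue
        try:
            cls = classify_sbs(m, genome)
        except (EdgeContextError, AmbiguousContextError) as exc:
            logger.warning("skipping unclassifiable SBS: %s", exc)
            continue
        if cls.substitution == "C>A" and cls.three_prime == "C":
            n += 1
    return n


def count_t_ins_after_gg(muts: Iterable[MutationRecord], genome: GenomeRef) -> int:
    """Count single-T insertions whose two reference bases 5' of the
    insertion point are GG (double-strand collapsed).

    The inserted base sits between ``pos`` and ``pos+1`` (anchored VCF
    convention), so the 5' dinucleotide is at positions pos-1 and pos.  On
    the opposite strand the equivalent event is a single-A insertion
    immediately 5' of CC on the reference.
    """
    n = 0
    for m in muts:
        if m.mut_class != "INS" or len(m.ref) != 1 or len(m.alt) != 2:
            continue
        seq = genome.sequences[m.chrom]
        inserted = m.alt[1]
        if inserted == "T" and m.pos >= 2 and seq[m.pos - 2 : m.pos] == "GG":
            n += 1
        elif inserted == "A" and m.pos + 2 <= len(seq) and seq[m.pos : m.pos + 2] == "CC":
            n += 1
    return n


def deletion_size_histogram(muts: Iterable[MutationRecord]) -> dict[str, int]:
    """Bin deletion sizes into 1, 2 and 3+ bp classes."""
    hist = {"1": 0, "2": 0, "3+": 0}
    for m in muts:
        if m.mut_class != "DEL":
            continue
        size = len(m.ref) - len(m.alt)
        hist["1" if size == 1 else "2" if size == 2 else "3+"] += 1
    return hist


@dataclass
class ContextCounts:
    ncc_nac: int
    t_ins_after_gg: int
    del_size_hist: dict[str, int] = field(default_factory=dict)


def count_contexts(muts: Sequence[MutationRecord], genome: GenomeRef) -> ContextCounts:
    return ContextCounts(
        ncc_nac=count_ncc_nac(muts, genome),
        t_ins_after_gg=count_t_ins_after_gg(muts, genome),
        del_size_hist=deletion_size_histogram(muts),
    )


# ---------------------------------------------------------------------------
# Triplet frequencies and cross-genome adjustment


def triplet_frequencies(genome: GenomeRef) -> dict[str, int]:
    """Occurrence counts of the 32 pyrimidine-centred triplets in a genome.

    Every overlapping 3-mer without N is counted once, collapsed to its
    pyrimidine-centred representative (double-strand collapsing).
    """
    if all(len(s) < 3 for s in genome.sequences.values()):
        raise SpectraError("genome shorter than 3 bp: no triplets")
    freq = {t: 0 for t in PYRIMIDINE_TRIPLETS}
    any_counted = False
    for seq in genome.sequences.values():
        for i in range(len(seq) - 2):
            triplet = seq[i : i + 3]
            if "N" in triplet:
                continue
            freq[collapse_triplet(triplet)] += 1
            any_counted = True
    if not any_counted:
        raise SpectraError("no countable triplets (all contexts contain N)")
    return freq


def cross_genome_adjust(
    spectrum: TripletSpectrum,
    src: Mapping[str, int | float],
    dst: Mapping[str, int | float],
) -> TripletSpectrum:
    """Reweight a spectrum from one genome's triplet composition to another's.

    Channel i is multiplied by dst(triplet_i)/src(triplet_i) and the result
    is renormalised to the input's total count, so that e.g. a spectrum
    observed on one genome can be compared with signatures defined on a
    genome of different composition.  Identity when src == dst; invariant to
    uniform rescaling of dst.
    """
    for t in PYRIMIDINE_TRIPLETS:
        if not src.get(t, 0) > 0:
            raise SpectraError(f"source triplet frequency for {t} must be > 0")
    ratios = np.array([dst[t] / src[t] for t in CHANNEL_TRIPLETS], dtype=float)
    scaled = spectrum.counts * ratios
    total = spectrum.total
    if scaled.sum() > 0:
        scaled = scaled * (total / scaled.sum())
    return TripletSpectrum(scaled, label=spectrum.label)
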
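"""Synthetic data emulating clone-sequencing mutagenesis experiments.

The generators here stand in for the sequencing data of a mutation-
accumulation study in isogenic cell clones: toy reference genomes, clone
mutation catalogues drawn from mixtures of 96-channel signatures, site
pileup evidence with sequencing noise for the unique-mutation caller, and
immunoglobulin amplicon read populations carrying AID-style point mutations
and pseudogene-templated gene-conversion tracts.  Every generator is
deterministic under a fixed seed and emits its truth tables alongside the
observable data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import ig
from .calling import SampleEvidence, SitePileup
from .signatures import SignatureMatrix
from .spectra import (
    BASES,
    CHANNELS,
    CHANNEL_TRIPLETS,
    COMPLEMENT,
    GenomeRef,
    MutationRecord,
    PYRIMIDINES,
    collapse_triplet,
)


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Genomes and signatures


def make_genome(seed: int, length: int, gc_fraction: float = 0.42, contig: str = "chr1") -> GenomeRef:
    """An i.i.d. random genome at the stated GC fraction (chicken-like 0.42)."""
    if not 0 <= gc_fraction <= 1:
        raise SimulationError("gc_fraction must lie in [0,1]")
    if length < 1000:
        raise SimulationError("genome length must be >= 1000")
    rng = np.random.default_rng(seed)
    at, gc = (1 - gc_fraction) / 2, gc_fraction / 2
    bases = rng.choice(list("ACGT"), size=length, p=[at, gc, gc, at])
    return GenomeRef({contig: "".join(bases)})


def random_signatures(k: int = 3, seed: int = 0, n_active: int = 15) -> SignatureMatrix:
    """Sparse synthetic signatures with distinct channel supports.

    Each signature is a Dirichlet draw over ``n_active`` channels taken from
    a shuffled pool without replacement, so supports are disjoint while
    ``k * n_active <= 96`` — an idealised stand-in for mutational processes
    with distinct sequence preferences.
    """
    if k * n_active > 96:
        raise SimulationError("k * n_active exceeds the 96 channels")
    rng = np.random.default_rng(seed)
    pool = rng.permutation(96)
    mat = np.zeros((96, k))
    for j in range(k):
        active = pool[j * n_active : (j + 1) * n_active]
        mat[active, j] = rng.dirichlet(np.ones(n_active))
    return SignatureMatrix(mat, [f"T{j + 1}" for j in range(k)])


def simulate_spectra(
    signatures: SignatureMatrix,
    n_samples: int,
    mean_mutations: float = 500.0,
    weights_alpha: float = 1.0,
    seed: int = 0,
) -> tuple[list, np.ndarray]:
    """Cohort of spectra from signature mixtures with Poisson sampling noise.

    Per sample the mixture weights are Dirichlet(alpha), the total mutation
    count Poisson(mean), and channel counts multinomial.  Returns the
    spectra and the true exposure matrix in mutation counts.
    """
    from .spectra import TripletSpectrum

    rng = np.random.default_rng(seed)
    spectra = []
    exposures = np.zeros((n_samples, signatures.k))
    for i in range(n_samples):
        weights = rng.dirichlet(np.full(signatures.k, weights_alpha))
        total = rng.poisson(mean_mutations)
        probs = signatures.matrix @ weights
        counts = rng.multinomial(max(total, 1), probs)
        spectra.append(TripletSpectrum(counts.astype(float), label=f"sim_{i}"))
        exposures[i] = weights * counts.sum()
    return spectra, exposures


# ---------------------------------------------------------------------------
# Clone sets with pileup evidence


@dataclass
class CloneSimConfig:
    """Study-condition parameters of the clone-sequencing simulation.

    Defaults emulate a 50-day (~100 generation) mutation-accumulation
    round sequenced at ~30x: a few hundred unique SBS per descendant clone
    drawn from a signature mixture, an order of magnitude fewer short
    indels, binomial allele sampling at heterozygous fraction 0.5, per-base
    error rate 0.5%, and a small number of contaminant-like sites that show
    both spurious variant evidence and coverage jumps.
    """

    signatures: SignatureMatrix | None = None
    mixture_weights: np.ndarray | None = None
    sbs_per_clone: float = 200.0
    insertions_per_clone: float = 10.0
    deletions_per_clone: float = 10.0
    mean_depth: float = 30.0
    error_rate: float = 0.005
    alt_fraction: float = 0.5
    read_length: int = 150
    low_mq_fraction: float = 0.1
    n_noise_sites: int = 2000
    n_contaminant_sites: int = 20
    contaminant_alt_fraction: float = 0.3
    contaminant_cov_step: int = 8

    def __post_init__(self) -> None:
        for rate in (self.error_rate, self.alt_fraction, self.low_mq_fraction):
            if not 0 <= rate <= 1:
                raise SimulationError("rates must lie in [0,1]")


@dataclass
class CloneSimResult:
    truth: list[MutationRecord]
    contaminant_sites: list[tuple[str, int, str]]  # (sample, pos, allele)
    pileups: list[SitePileup]
    coverage: dict[str, np.ndarray]
    ancestral_id: str
    clone_ids: list[str]


def _triplet_position_index(seq: str) -> dict[str, np.ndarray]:
    """Positions (1-based, centre) of each collapsed pyrimidine triplet."""
    index: dict[str, list[int]] = {}
    for i in range(1, len(seq) - 1):
        triplet = seq[i - 1 : i + 2]
        if "N" in triplet:
            continue
        index.setdefault(collapse_triplet(triplet), []).append(i + 1)
    return {t: np.asarray(p) for t, p in index.items()}


def _mq_list(n: int, rng: np.random.Generator, low_fraction: float) -> list[int]:
    return [
        int(rng.integers(20, 40)) if rng.random() < low_fraction else 60 for _ in range(n)
    ]


def _coverage_track(
    length: int, mean_depth: float, read_length: int, rng: np.random.Generator
) -> np.ndarray:
    """Read-process coverage: smooth at base resolution, Poisson regionally."""
    lam = mean_depth / read_length
    starts = rng.poisson(lam, size=length + read_length)
    cum = np.concatenate([[0], np.cumsum(starts)])
    # coverage at position i (0-based in the genome): reads starting in
    # (i - read_length, i] of the padded start array
    idx = np.arange(length) + read_length
    cov = cum[idx + 1] - cum[idx + 1 - read_length]
    return np.maximum(cov, 1)


def simulate_clone_set(
    genome: GenomeRef,
    cfg: CloneSimConfig,
    n_clones: int = 4,
    seed: int = 0,
) -> CloneSimResult:
    """Plant unique mutations in descendant clones and emit pileup evidence.

    Each descendant receives a Poisson number of SBS placed at genome
    positions whose trinucleotide context matches the channel sampled from
    the configured signature mixture, plus short indels at random positions;
    the ancestral clone carries no unique mutations.  Pileups are emitted at
    every truth site, at noise-only sites, and at contaminant-like sites
    which also perturb the per-sample coverage tracks.
    """
    rng = np.random.default_rng(seed)
    contig, seq = next(iter(genome.sequences.items()))
    sigs = cfg.signatures if cfg.signatures is not None else random_signatures(3, seed=seed)
    weights = (
        np.asarray(cfg.mixture_weights, dtype=float)
        if cfg.mixture_weights is not None
        else np.full(sigs.k, 1.0 / sigs.k)
    )
    if abs(weights.sum() - 1.0) > 1e-9:
        raise SimulationError("mixture weights must sum to 1")
    channel_probs = sigs.matrix @ weights

    index = _triplet_position_index(seq)
    missing = [i for i, t in enumerate(CHANNEL_TRIPLETS) if t not in index]
    if missing:
        channel_probs = channel_probs.copy()
        channel_probs[missing] = 0.0
        if channel_probs.sum() <= 0:
            raise SimulationError("no signature channel has a compatible context")
        channel_probs /= channel_probs.sum()

    ancestral_id = "ancestral"
    clone_ids = [f"clone{i + 1}" for i in range(n_clones)]
    samples = [ancestral_id] + clone_ids

    used: set[int] = set()
    truth: list[MutationRecord] = []
    for clone in clone_ids:
        n_sbs = rng.poisson(cfg.sbs_per_clone)
        channels = rng.choice(96, size=n_sbs, p=channel_probs)
        for ch in channels:
            positions = index[CHANNEL_TRIPLETS[ch]]
            pos = None
            for _ in range(50):
                cand = int(positions[rng.integers(len(positions))])
                if cand not in used:
                    pos = cand
                    break
            if pos is None:
                continue  # context saturated at toy scale; drop this draw
            used.add(pos)
            name = CHANNELS[ch]
            pyr_ref, pyr_alt = name[2], name[4]
            base = seq[pos - 1]
            if base in PYRIMIDINES:
                ref, alt = pyr_ref, pyr_alt
            else:
                ref, alt = COMPLEMENT[pyr_ref], COMPLEMENT[pyr_alt]
            assert ref == base
            truth.append(MutationRecord(clone, contig, pos, ref, alt))
        for _ in range(rng.poisson(cfg.insertions_per_clone)):
            pos = int(rng.integers(2, len(seq) - 4))
            if pos in used:
                continue
            used.add(pos)
            ins = BASES[rng.integers(4)]
            truth.append(MutationRecord(clone, contig, pos, seq[pos - 1], seq[pos - 1] + ins))
        for _ in range(rng.poisson(cfg.deletions_per_clone)):
            pos = int(rng.integers(2, len(seq) - 5))
            if pos in used:
                continue
            used.add(pos)
            size = int(rng.choice([1, 2, 3], p=[0.5, 0.3, 0.2]))
            ref = seq[pos - 1 : pos + size]
            truth.append(MutationRecord(clone, contig, pos, ref, ref[0]))

    coverage = {
        s: _coverage_track(len(seq), cfg.mean_depth, cfg.read_length, rng) for s in samples
    }

    # noise-only sites
    noise_sites: list[int] = []
    while len(noise_sites) < cfg.n_noise_sites:
        pos = int(rng.integers(2, len(seq)))
        if pos not in used:
            used.add(pos)
            noise_sites.append(pos)

    # contaminant-like sites: spurious variant evidence plus coverage steps
    contaminants: list[tuple[str, int, str]] = []
    for _ in range(cfg.n_contaminant_sites):
        while True:
            pos = int(rng.integers(200, len(seq) - 200))
            if pos not in used:
                used.add(pos)
                break
        sample = clone_ids[rng.integers(len(clone_ids))]
        ref = seq[pos - 1]
        allele = rng.choice([b for b in BASES if b != ref])
        contaminants.append((sample, pos, str(allele)))
        lo, hi = pos - 60, pos + 60
        coverage[sample][lo - 1 : hi] += cfg.contaminant_cov_step

    carrier: dict[int, tuple[str, str]] = {}  # pos -> (sample, allele key)
    for m in truth:
        if m.mut_class == "SBS":
            allele = m.alt
        elif m.mut_class == "INS":
            allele = "+" + m.alt[len(m.ref):]
        else:
            allele = "-" + m.ref[len(m.alt):]
        carrier[m.pos] = (m.sample_id, allele)
    for sample, pos, allele in contaminants:
        carrier[pos] = (sample, allele)
    contaminant_pos = {pos for _, pos, _ in contaminants}

    pileups: list[SitePileup] = []
    all_sites = sorted(carrier) + noise_sites
    for pos in sorted(set(all_sites)):
        ref = seq[pos - 1]
        site = SitePileup(contig, pos, ref)
        for s in samples:
            depth = int(coverage[s][pos - 1])
            counts: dict[str, int] = {}
            mqs: dict[str, list[int]] = {}
            alt_n = 0
            if pos in carrier and carrier[pos][0] == s:
                allele = carrier[pos][1]
                frac = (
                    cfg.contaminant_alt_fraction
                    if pos in contaminant_pos
                    else cfg.alt_fraction
                )
                alt_n = int(rng.binomial(depth, frac))
                if alt_n:
                    counts[allele] = alt_n
                    mqs[allele] = _mq_list(alt_n, rng, cfg.low_mq_fraction)
            else:
                n_err = int(rng.binomial(depth, cfg.error_rate))
                for _ in range(n_err):
                    b = str(rng.choice([b for b in BASES if b != ref]))
                    counts[b] = counts.get(b, 0) + 1
                    mqs.setdefault(b, []).append(
                        _mq_list(1, rng, cfg.low_mq_fraction)[0]
                    )
                alt_n = n_err
            counts[ref] = depth - alt_n
            site.samples[s] = SampleEvidence(depth=depth, counts=counts, mqs=mqs)
        pileups.append(site)

    return CloneSimResult(
        truth=truth,
        contaminant_sites=contaminants,
        pileups=pileups,
        coverage=coverage,
        ancestral_id=ancestral_id,
        clone_ids=clone_ids,
    )


# ---------------------------------------------------------------------------
# Immunoglobulin amplicon populations


def make_vl_reference(seed: int = 0, length: int = 269, region: tuple[int, int] = (19, 251)) -> ig.VLReference:
    """A synthetic VL1-like amplicon (269 bp, analysed region 233 bp)."""
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=length, p=[0.25, 0.27, 0.27, 0.21]))
    return ig.VLReference(seq=seq, region_start=region[0], region_end=region[1])


def make_pseudogene_set(
    ref: ig.VLReference, n_donors: int = 10, divergence: float = 0.08, seed: int = 0
) -> list[ig.PseudogeneAlignment]:
    """Homeologous donors differing from the reference at Bernoulli(divergence)
    positions; donor-specific maps are recorded exactly."""
    if not 0 <= divergence < 0.3:
        raise SimulationError("divergence must lie in [0, 0.3)")
    rng = np.random.default_rng(seed)
    donors = []
    for j in range(n_donors):
        aligned = {}
        for pos in range(1, len(ref.seq) + 1):
            base = ref.seq[pos - 1]
            if rng.random() < divergence:
                base = str(rng.choice([b for b in "ACGT" if b != base]))
            aligned[pos] = base
        donors.append(ig.PseudogeneAlignment.from_aligned_map(f"psi{j + 1}", aligned, ref))
    return donors


@dataclass
class AmpliconSimConfig:
    """Amplicon-population parameters.

    Point mutations emulate AID-driven hypermutation (C/G-biased via
    ``cg_fraction``); gene conversions copy a geometric-length donor tract
    (mean ~29 nt, the wild-type mean tract length).  Residual base-call
    errors are rare (merged read pairs) and mostly carry qualities below the
    Q30 filter.
    """

    n_reads: int = 10_000
    pm_rate: float = 0.01
    cg_fraction: float = 0.9
    gc_rate: float = 0.005
    tract_mean: float = 29.0
    error_rate: float = 5e-5
    frac_errors_below_q30: float = 0.95

    def __post_init__(self) -> None:
        for p in (self.pm_rate, self.cg_fraction, self.gc_rate,
                  self.error_rate, self.frac_errors_below_q30):
            if not 0 <= p <= 1:
                raise SimulationError("probabilities must lie in [0,1]")


@dataclass
class SimulatedRead:
    read_id: str
    seq: str
    quals: list[int]


@dataclass
class ReadTruth:
    read_id: str
    pm_positions: tuple[int, ...] = ()
    gc_donor: str | None = None
    gc_span: tuple[int, int] | None = None
    gc_tract_length: int | None = None
    gc_changed_positions: tuple[int, ...] = ()
    #: event categories expected from the planted (noise-free) variants
    expected_events: dict[str, int] = field(default_factory=dict)


@dataclass
class AmpliconSimResult:
    reads: list[SimulatedRead]
    truth: list[ReadTruth]
    ref: ig.VLReference
    donors: list[ig.PseudogeneAlignment]


def simulate_amplicons(
    ref: ig.VLReference,
    donors: list[ig.PseudogeneAlignment],
    cfg: AmpliconSimConfig,
    seed: int = 0,
) -> AmpliconSimResult:
    """Simulate merged amplicon reads with planted PM and GC events.

    Per read, with probability ``gc_rate`` a donor tract of geometric length
    is copied into the analysed region; with probability ``pm_rate`` a point
    mutation not matching any donor is planted (C/G-biased).  Base-call
    errors are applied at ``error_rate``, with most error qualities drawn
    below Q30 so the quality filter removes them.  The truth table records
    realised planted variants and the expected event classification of the
    noise-free variant set.
    """
    rng = np.random.default_rng(seed)
    region_positions = np.arange(ref.region_start, ref.region_end + 1)
    cg_positions = [p for p in region_positions if ref.seq[p - 1] in "CG"]
    at_positions = [p for p in region_positions if ref.seq[p - 1] in "AT"]
    donors_by_id = {d.donor_id: d for d in donors}
    region_len = ref.region_end - ref.region_start + 1

    reads: list[SimulatedRead] = []
    truths: list[ReadTruth] = []
    for i in range(cfg.n_reads):
        read_id = f"read_{i}"
        seq = list(ref.seq)
        quals = [int(q) for q in rng.integers(33, 41, size=len(seq))]
        truth = ReadTruth(read_id=read_id)
        planted: list[ig.AmpliconVariant] = []

        if rng.random() < cfg.gc_rate:
            donor = donors[rng.integers(len(donors))]
            tract_len = 1
            for _ in range(100):
                tract_len = int(rng.geometric(1.0 / cfg.tract_mean))
                if tract_len <= region_len:
                    break
            tract_len = min(tract_len, region_len)
            start = int(rng.integers(ref.region_start, ref.region_end - tract_len + 2))
            end = start + tract_len - 1
            changed = []
            for pos in range(start, end + 1):
                donor_base = donor.aligned[pos]
                if donor_base != ref.seq[pos - 1]:
                    seq[pos - 1] = donor_base
                    changed.append(pos)
                    planted.append(
                        ig.AmpliconVariant(pos, ref.seq[pos - 1], donor_base, 40)
                    )
            truth.gc_donor = donor.donor_id
            truth.gc_span = (start, end)
            truth.gc_tract_length = tract_len
            truth.gc_changed_positions = tuple(changed)

        if rng.random() < cfg.pm_rate:
            pool = cg_positions if rng.random() < cfg.cg_fraction else at_positions
            for _ in range(100):
                pos = int(pool[rng.integers(len(pool))])
                if seq[pos - 1] != ref.seq[pos - 1]:
                    continue  # already altered by a GC tract
                taken = {d.aligned.get(pos) for d in donors} | {ref.seq[pos - 1]}
                free = [b for b in "ACGT" if b not in taken]
                if free:
                    obs = str(rng.choice(free))
                    seq[pos - 1] = obs
                    planted.append(ig.AmpliconVariant(pos, ref.seq[pos - 1], obs, 40))
                    truth.pm_positions = truth.pm_positions + (pos,)
                    break

        # base-call errors
        n_err = rng.binomial(len(seq), cfg.error_rate)
        for _ in range(n_err):
            pos = int(rng.integers(1, len(seq) + 1))
            cur = seq[pos - 1]
            seq[pos - 1] = str(rng.choice([b for b in "ACGT" if b != cur]))
            if rng.random() < cfg.frac_errors_below_q30:
                quals[pos - 1] = int(rng.integers(5, 30))
            else:
                quals[pos - 1] = int(rng.integers(31, 39))

        expected = ig.classify_amplicon(planted, donors)
        truth.expected_events = {}
        for e in expected:
            truth.expected_events[e.category] = truth.expected_events.get(e.category, 0) + 1

        reads.append(SimulatedRead(read_id, "".join(seq), quals))
        truths.append(truth)

    return AmpliconSimResult(reads=reads, truth=truths, ref=ref, donors=donors)


def write_fastq(reads: list[SimulatedRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.quals)
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{qual}\n")
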
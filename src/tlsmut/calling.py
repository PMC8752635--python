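"""Unique-mutation detection across sets of isogenic clone samples.

In a mutation-accumulation experiment a single-cell ancestral clone is
expanded and descendant clones are sequenced after a fixed culture period.
Newly arisen mutations are unique to one descendant, so a call requires
strong variant support in exactly one sample and clean reference support in
every other sample of the batch.  The caller here implements that
cleanness rule with a Fisher's-exact confidence score, followed by three
post-filters:

* a score-threshold calibration on the ancestral clone(s), which by design
  carry no unique mutations and so bound the tolerated false-positive count
  (at most 5 SBS and 1 indel per ancestral sample by default);
* a mapping-quality filter on mutation-supporting reads (minimum MQ 40,
  quorum rule), guarding against cross-contaminating reads from other
  species or samples;
* a coverage-jump filter that drops calls flanked on both sides by abrupt
  coverage steps (jumps of >=5 within a 200 bp window), which typically mark
  misalignment or contamination hotspots.

Alleles in pileups are encoded as "A"/"C"/"G"/"T" for substitutions,
"+SEQ" for insertions of SEQ after the site, and "-SEQ" for deletions of
SEQ following the site.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import fisher_exact

logger = logging.getLogger(__name__)


class CallingError(ValueError):
    pass


class CalibrationError(CallingError):
    """No finite threshold satisfies the ancestral call limits."""


@dataclass
class SampleEvidence:
    """Per-sample read evidence at one site."""

    depth: int
    counts: dict[str, int] = field(default_factory=dict)
    #: mapping qualities of reads supporting each non-reference allele
    mqs: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise CallingError("depth must be >= 0")
        if sum(self.counts.values()) > self.depth:
            raise CallingError("allele counts exceed depth")


@dataclass
class SitePileup:
    chrom: str
    pos: int
    ref: str
    samples: dict[str, SampleEvidence] = field(default_factory=dict)


@dataclass(frozen=True)
class CandidateCall:
    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    mut_class: str
    score: float
    alt_count: int
    depth: int
    alt_freq: float
    supporting_mqs: tuple[int, ...] = ()


@dataclass
class CallerConfig:
    """Thresholds of the unique-mutation caller.

    ``min_mq`` 40, ``jump_size`` 5 and ``jump_window`` 200 bp are the
    post-filter settings used for contamination control; ``ancestral_limits``
    is the (max SBS, max indel) false-positive budget per ancestral sample
    used to calibrate the score threshold.
    """

    min_alt_count: int = 3
    min_alt_freq: float = 0.2
    min_other_ref_freq: float = 0.9
    score_threshold: float = 0.0
    min_mq: int = 40
    jump_size: int = 5
    jump_window: int = 200
    ancestral_limits: tuple[int, int] = (5, 1)

    def __post_init__(self) -> None:
        if not 0 < self.min_alt_freq <= 1 or not 0 <= self.min_other_ref_freq <= 1:
            raise CallingError("frequency thresholds must lie in (0,1]")
        if self.jump_window % 2:
            raise CallingError("jump_window must be even")


def allele_to_alleles(ref: str, allele: str) -> tuple[str, str, str]:
    """Expand a pileup allele key to anchored (ref, alt, mut_class)."""
    if allele.startswith("+"):
        return ref, ref + allele[1:], "INS"
    if allele.startswith("-"):
        return ref + allele[1:], ref, "DEL"
    return ref, allele, "SBS"


def fisher_score(alt_focal: int, ref_focal: int, alt_other: int, ref_other: int) -> float:
    """-log10 of the one-sided Fisher's exact p-value that the focal sample
    has a higher alt proportion than the comparison sample."""
    _, p = fisher_exact(
        [[alt_focal, ref_focal], [alt_other, ref_other]], alternative="greater"
    )
    if p <= 0.0:
        return math.inf
    return -math.log10(p)


def detect_unique_mutations(
    pileups: Iterable[SitePileup],
    cfg: CallerConfig | None = None,
) -> list[CandidateCall]:
    """Emit sample-unique candidate calls from a stream of site pileups.

    A call for sample *i* and allele *a* requires (a) alt frequency and
    count above thresholds in *i*, (b) reference frequency at least
    ``min_other_ref_freq`` in every other sample, and (c) Fisher score vs
    the noisiest other sample (lowest reference frequency; ties broken by
    higher depth then sample id) at least ``score_threshold``.  At most one
    call per sample per site (highest-count alt; ties broken
    lexicographically).
    """
    cfg = cfg or CallerConfig()
    calls: list[CandidateCall] = []
    expected_ids: list[str] | None = None
    for site in pileups:
        ids = sorted(site.samples)
        if expected_ids is None:
            if len(ids) < 2:
                raise CallingError("at least two samples are required per site")
            expected_ids = ids
        elif ids != expected_ids:
            raise CallingError(
                f"inconsistent sample sets at {site.chrom}:{site.pos}: {ids} vs {expected_ids}"
            )
        if any(site.samples[s].depth == 0 for s in ids):
            logger.warning("skipping %s:%d: zero depth in a sample", site.chrom, site.pos)
            continue
        ref = site.ref
        ref_freq = {
            s: site.samples[s].counts.get(ref, 0) / site.samples[s].depth for s in ids
        }
        for s in ids:
            ev = site.samples[s]
            non_ref = [(a, c) for a, c in ev.counts.items() if a != ref and c > 0]
            if not non_ref:
                continue
            allele, count = max(non_ref, key=lambda t: (t[1], [-ord(ch) for ch in t[0]]))
            freq = count / ev.depth
            if count < cfg.min_alt_count or freq < cfg.min_alt_freq:
                continue
            others = [o for o in ids if o != s]
            if any(ref_freq[o] < cfg.min_other_ref_freq for o in others):
                continue
            noisiest = min(others, key=lambda o: (ref_freq[o], -site.samples[o].depth, o))
            nev = site.samples[noisiest]
            score = fisher_score(
                count,
                ev.counts.get(ref, 0),
                nev.counts.get(allele, 0),
                nev.counts.get(ref, 0),
            )
            if score < cfg.score_threshold:
                continue
            call_ref, call_alt, mut_class = allele_to_alleles(ref, allele)
            calls.append(
                CandidateCall(
                    sample_id=s,
                    chrom=site.chrom,
                    pos=site.pos,
                    ref=call_ref,
                    alt=call_alt,
                    mut_class=mut_class,
                    score=score,
                    alt_count=count,
                    depth=ev.depth,
                    alt_freq=freq,
                    supporting_mqs=tuple(ev.mqs.get(allele, ())),
                )
            )
    return calls


# ---------------------------------------------------------------------------
# Ancestral-clone score calibration


@dataclass(frozen=True)
class ScoreThresholds:
    sbs: float
    indel: float


def _calibrate_one(
    scores_by_sample: Mapping[str, Sequence[float]], limit: int
) -> float:
    for sample, scores in scores_by_sample.items():
        if sum(1 for s in scores if math.isinf(s)) > limit:
            raise CalibrationError(
                f"ancestral sample {sample!r} has more than {limit} calls with "
                "infinite score; no finite threshold can satisfy the limit"
            )
    all_scores = sorted({s for scores in scores_by_sample.values() for s in scores})
    candidates = [0.0] + [s for s in all_scores if math.isfinite(s)]
    if all_scores:
        candidates.append(max(s for s in all_scores if math.isfinite(s)) + 1.0)
    for t in candidates:
        if all(
            sum(1 for s in scores if s >= t) <= limit
            for scores in scores_by_sample.values()
        ):
            return t
    raise CalibrationError("threshold sweep exhausted")  # pragma: no cover


def calibrate_score_threshold(
    calls: Sequence[CandidateCall],
    ancestral_ids: Iterable[str],
    limits: tuple[int, int] = (5, 1),
) -> ScoreThresholds:
    """Smallest score thresholds keeping each ancestral sample at or below
    the allowed SBS and indel call counts.

    The ancestral clone carries no unique mutations by construction, so any
    call in it is a false positive; the returned thresholds (one for SBS,
    one for indels, keep rule ``score >= t``) are the smallest values at
    which every ancestral sample retains at most ``limits[0]`` SBS calls and
    ``limits[1]`` indel calls.
    """
    ancestral = set(ancestral_ids)
    if not ancestral:
        raise CallingError("no ancestral samples given")
    out = []
    for limit, classes in ((limits[0], {"SBS"}), (limits[1], {"INS", "DEL"})):
        scores: dict[str, list[float]] = {a: [] for a in ancestral}
        for c in calls:
            if c.sample_id in ancestral and c.mut_class in classes:
                scores[c.sample_id].append(c.score)
        out.append(_calibrate_one(scores, limit))
    return ScoreThresholds(sbs=out[0], indel=out[1])


def apply_score_thresholds(
    calls: Iterable[CandidateCall], thresholds: ScoreThresholds
) -> list[CandidateCall]:
    return [
        c
        for c in calls
        if c.score >= (thresholds.sbs if c.mut_class == "SBS" else thresholds.indel)
    ]


# ---------------------------------------------------------------------------
# Post-filters


def filter_min_mq(call: CandidateCall, cfg: CallerConfig) -> CandidateCall | None:
    """Discount supporting reads with MQ below ``cfg.min_mq``.

    The call is kept (with recomputed support) iff the retained reads still
    reach ``min_alt_count`` and the alt frequency recomputed on retained
    reads stays at or above ``min_alt_freq`` (quorum rule: not every
    supporting read needs to pass).
    """
    if not call.supporting_mqs:
        logger.warning(
            "dropping %s:%d in %s: no supporting mapping qualities",
            call.chrom, call.pos, call.sample_id,
        )
        return None
    kept = [q for q in call.supporting_mqs if q >= cfg.min_mq]
    dropped = len(call.supporting_mqs) - len(kept)
    new_depth = call.depth - dropped
    if len(kept) < cfg.min_alt_count:
        return None
    new_freq = len(kept) / new_depth if new_depth > 0 else 0.0
    if new_freq < cfg.min_alt_freq:
        return None
    return dataclasses.replace(
        call,
        alt_count=len(kept),
        depth=new_depth,
        alt_freq=new_freq,
        supporting_mqs=tuple(kept),
    )


def filter_coverage_jump(
    call: CandidateCall, coverage: np.ndarray, cfg: CallerConfig
) -> bool:
    """Keep/drop rule for the coverage-jump contamination filter.

    ``coverage[i]`` is the depth at 1-based position ``i+1`` of the call's
    contig for the call's sample.  A jump at position i means
    ``|cov(i+1) - cov(i)| >= jump_size``.  The call is dropped iff at least
    one jump lies strictly between pos-window/2 and pos AND at least one
    strictly between pos and pos+window/2.  Returns True to keep.
    """
    half = cfg.jump_window // 2
    pos = call.pos
    n = len(coverage)

    def jump_in(lo: int, hi: int) -> bool:
        # jump index i in [lo, hi], needs cov at i and i+1
        lo_c, hi_c = max(lo, 1), min(hi, n - 1)
        if lo_c > hi_c:
            return False
        seg = coverage[lo_c - 1 : hi_c + 1]
        return bool((np.abs(np.diff(seg)) >= cfg.jump_size).any())

    if pos - half + 1 < 1 or pos + half - 1 > n - 1:
        logger.warning(
            "coverage window at %s:%d truncated by contig edge", call.chrom, call.pos
        )
    left = jump_in(pos - half + 1, pos - 1)
    right = jump_in(pos + 1, pos + half - 1)
    return not (left and right)


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class CallingResult:
    calls: list[CandidateCall]
    thresholds: ScoreThresholds
    n_raw: int
    n_after_mq: int
    n_after_jump: int


def run_calling_pipeline(
    pileups: Iterable[SitePileup],
    ancestral_ids: Iterable[str],
    cfg: CallerConfig | None = None,
    coverage: Mapping[str, np.ndarray] | None = None,
) -> CallingResult:
    """Detection, MQ filter, coverage-jump filter, then ancestral calibration.

    ``coverage`` maps sample id to a per-bp depth track (single-contig
    input); when absent the jump filter is skipped.
    """
    cfg = cfg or CallerConfig()
    raw = detect_unique_mutations(pileups, dataclasses.replace(cfg, score_threshold=0.0))
    after_mq = [c for c in (filter_min_mq(c, cfg) for c in raw) if c is not None]
    if coverage is not None:
        after_jump = [
            c for c in after_mq if filter_coverage_jump(c, coverage[c.sample_id], cfg)
        ]
    else:
        after_jump = after_mq
    thresholds = calibrate_score_threshold(after_jump, ancestral_ids, cfg.ancestral_limits)
    final = apply_score_thresholds(after_jump, thresholds)
    return CallingResult(
        calls=final,
        thresholds=thresholds,
        n_raw=len(raw),
        n_after_mq=len(after_mq),
        n_after_jump=len(after_jump),
    )


# ---------------------------------------------------------------------------
# Pileup and call TSV I/O

_PILEUP_COLUMNS = ["chrom", "pos", "ref", "sample", "depth", "counts", "mqs"]


def _encode_counts(counts: Mapping[str, int]) -> str:
    return ";".join(f"{a}:{c}" for a, c in sorted(counts.items())) or "."


def _decode_counts(text: str) -> dict[str, int]:
    if text == ".":
        return {}
    return {a: int(c) for a, c in (item.split(":") for item in text.split(";"))}


def _encode_mqs(mqs: Mapping[str, Sequence[int]]) -> str:
    return ";".join(f"{a}:{','.join(map(str, qs))}" for a, qs in sorted(mqs.items())) or "."


def _decode_mqs(text: str) -> dict[str, list[int]]:
    if text == ".":
        return {}
    out = {}
    for item in text.split(";"):
        allele, qs = item.split(":")
        out[allele] = [int(q) for q in qs.split(",")] if qs else []
    return out


def write_pileups(pileups: Iterable[SitePileup], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_PILEUP_COLUMNS) + "\n")
        for site in pileups:
            for sample in sorted(site.samples):
                ev = site.samples[sample]
                fh.write(
                    f"{site.chrom}\t{site.pos}\t{site.ref}\t{sample}\t{ev.depth}\t"
                    f"{_encode_counts(ev.counts)}\t{_encode_mqs(ev.mqs)}\n"
                )


def read_pileups(path: str | Path) -> list[SitePileup]:
    sites: dict[tuple[str, int], SitePileup] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _PILEUP_COLUMNS:
            raise CallingError(f"{path}: unexpected pileup header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                chrom, pos_s, ref, sample, depth_s, counts_s, mqs_s = line.split("\t")
                key = (chrom, int(pos_s))
                site = sites.setdefault(key, SitePileup(chrom, int(pos_s), ref))
                site.samples[sample] = SampleEvidence(
                    depth=int(depth_s),
                    counts=_decode_counts(counts_s),
                    mqs=_decode_mqs(mqs_s),
                )
            except (ValueError, CallingError) as exc:
                raise CallingError(f"{path}:{lineno}: {exc}") from exc
    return sorted(sites.values(), key=lambda s: (s.chrom, s.pos))


def write_calls(calls: Iterable[CandidateCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tpos\tref\talt\tmut_class\tscore\talt_count\tdepth\talt_freq\n")
        for c in calls:
            fh.write(
                f"{c.sample_id}\t{c.chrom}\t{c.pos}\t{c.ref}\t{c.alt}\t{c.mut_class}\t"
                f"{c.score:.4g}\t{c.alt_count}\t{c.depth}\t{c.alt_freq:.4g}\n"
            )
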
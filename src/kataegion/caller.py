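"""Epoch-stratified calling of clustered-hypermutation candidates.

For each genome, SNVs are split into three evolutionary subsets (early
clonal, late clonal, subclonal); within each subset and chromosome the
inter-mutation distances are smoothed by exact piecewise-constant fitting
and maximal runs of >= 4 consecutive SNVs whose adjusted distances all fall
below a burden-adjusted threshold (capped at 1 kbp) become candidates.
Early/late candidates that re-call the same cluster of shared unspecified
SNVs are de-duplicated in favour of the larger one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .formats_io import Epoch, SnvRecord
from .segmentation import pcf_adjusted_imd

logger = logging.getLogger(__name__)

__all__ = [
    "EpochSubset",
    "KataegisCandidate",
    "build_epoch_subsets",
    "burden_threshold",
    "call_candidates",
    "dedup_early_late",
    "call_sample",
]

#: Default callable genome length (bp) before mask subtraction.
DEFAULT_GENOME_LENGTH = 3.1e9
#: Hard cap on the inter-mutation distance threshold.
MAX_THRESHOLD_BP = 1000.0

_SUBSET_MEMBERSHIP: dict[str, frozenset[Epoch]] = {
    "early": frozenset({Epoch.EARLY_CLONAL, Epoch.CLONAL_UNSPECIFIED, Epoch.UNKNOWN}),
    "late": frozenset({Epoch.LATE_CLONAL, Epoch.CLONAL_UNSPECIFIED, Epoch.UNKNOWN}),
    "subclonal": frozenset({Epoch.SUBCLONAL, Epoch.UNKNOWN}),
}


@dataclass(frozen=True)
class EpochSubset:
    epoch_tag: str  # early | late | subclonal
    snvs: tuple[SnvRecord, ...]

    def __len__(self) -> int:
        return len(self.snvs)


@dataclass(frozen=True)
class KataegisCandidate:
    """A maximal qualifying run of >= 4 closely spaced SNVs in one subset."""

    sample_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    snvs: tuple[SnvRecord, ...]
    epoch_tag: str
    max_adjusted_imd: float
    sequential_pair: bool = False  # overlaps a candidate of the other clonal epoch
                                   # without sharing SNVs

    @property
    def n_snvs(self) -> int:
        return len(self.snvs)

    @property
    def span_bp(self) -> int:
        return self.end - self.start + 1

    def positions(self) -> frozenset[tuple[str, int]]:
        return frozenset((s.chrom, s.pos) for s in self.snvs)


def build_epoch_subsets(snvs: Iterable[SnvRecord]) -> dict[str, EpochSubset]:
    """Split SNVs into the early / late / subclonal calling subsets.

    Unspecified-clonal SNVs enter both clonal subsets; unknown SNVs enter all
    three.
    """
    snvs = sorted(snvs, key=lambda s: (s.chrom, s.pos))
    return {
        tag: EpochSubset(tag, tuple(s for s in snvs if s.epoch in members))
        for tag, members in _SUBSET_MEMBERSHIP.items()
    }


def burden_threshold(
    n_snvs: int,
    genome_length: float = DEFAULT_GENOME_LENGTH,
    alpha: float = 0.01,
    max_threshold_bp: float = MAX_THRESHOLD_BP,
) -> float:
    """Burden-adjusted inter-mutation distance threshold (bp), capped.

    Models the subset as a uniform point process of rate
    ``lambda = n_snvs / genome_length`` and picks the largest distance d for
    which the expected genome-wide number of chance 4-SNV runs,
    ``n_snvs * (lambda * d)**3``, stays at ``alpha``; the result is capped at
    ``max_threshold_bp`` (default 1 kbp). Sparse subsets (< 4 SNVs) return
    the cap.
    """
    if n_snvs < 0:
        raise ValueError("n_snvs must be >= 0")
    if genome_length <= 0:
        raise ValueError("genome_length must be > 0")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_snvs < 4:
        return max_threshold_bp
    lam = n_snvs / genome_length
    d_star = (alpha / n_snvs) ** (1.0 / 3.0) / lam
    return min(max_threshold_bp, d_star)


def _dedup_positions(snvs: Sequence[SnvRecord]) -> list[SnvRecord]:
    seen: set[tuple[str, int]] = set()
    out: list[SnvRecord] = []
    dropped = 0
    for s in snvs:
        key = (s.chrom, s.pos)
        if key in seen:
            dropped += 1
            continue
        seen.add(key)
        out.append(s)
    if dropped:
        logger.info("call_candidates: collapsed %d duplicate positions", dropped)
    return out


def call_candidates(
    subset: EpochSubset,
    gamma: float = 25.0,
    kmin: int = 2,
    genome_length: float = DEFAULT_GENOME_LENGTH,
    alpha: float = 0.01,
    max_threshold_bp: float = MAX_THRESHOLD_BP,
) -> list[KataegisCandidate]:
    """Call candidates from one epoch subset.

    Per chromosome the adjusted inter-mutation distances are computed with
    :func:`~kataegion.segmentation.pcf_adjusted_imd`; a candidate is a
    maximal run of consecutive SNVs whose connecting adjusted distances are
    all below the burden-adjusted threshold, kept iff it has >= 4 SNVs.
    """
    snvs = _dedup_positions(subset.snvs)
    if not snvs:
        return []
    threshold = burden_threshold(len(snvs), genome_length, alpha, max_threshold_bp)
    out: list[KataegisCandidate] = []
    by_chrom: dict[tuple[str, str], list[SnvRecord]] = {}
    for s in snvs:
        by_chrom.setdefault((s.sample_id, s.chrom), []).append(s)
    for (sample_id, chrom), chrom_snvs in by_chrom.items():
        if len(chrom_snvs) < 4:
            continue
        positions = np.array([s.pos for s in chrom_snvs], dtype=np.int64)
        adj = pcf_adjusted_imd(positions, gamma=gamma, kmin=kmin)
        below = adj < threshold
        # maximal runs of consecutive True gaps
        i = 0
        n_gaps = below.size
        while i < n_gaps:
            if not below[i]:
                i += 1
                continue
            j = i
            while j < n_gaps and below[j]:
                j += 1
            members = chrom_snvs[i : j + 1]  # gaps i..j-1 connect SNVs i..j
            if len(members) >= 4:
                out.append(
                    KataegisCandidate(
                        sample_id=sample_id,
                        chrom=chrom,
                        start=members[0].pos,
                        end=members[-1].pos,
                        snvs=tuple(members),
                        epoch_tag=subset.epoch_tag,
                        max_adjusted_imd=float(adj[i:j].max()),
                    )
                )
            i = j
    out.sort(key=lambda c: (c.sample_id, c.chrom, c.start))
    return out


_SHAREABLE = frozenset({Epoch.CLONAL_UNSPECIFIED, Epoch.UNKNOWN})


def dedup_early_late(
    candidates_early: Sequence[KataegisCandidate],
    candidates_late: Sequence[KataegisCandidate],
) -> list[KataegisCandidate]:
    """Merge early and late candidate sets of one sample.

    Early and late candidates that share at least one unspecified-clonal or
    unknown member SNV describe the same physical cluster twice; only the one
    with more member SNVs survives (ties keep the early candidate).
    Overlapping pairs that share no SNV are genuinely sequential events: both
    are kept and flagged.
    """
    from dataclasses import replace

    drop_early: set[int] = set()
    drop_late: set[int] = set()
    seq_early: set[int] = set()
    seq_late: set[int] = set()

    def shareable_positions(c: KataegisCandidate) -> frozenset[tuple[str, int]]:
        return frozenset((s.chrom, s.pos) for s in c.snvs if s.epoch in _SHAREABLE)

    for ie, ce in enumerate(candidates_early):
        for il, cl in enumerate(candidates_late):
            if ce.sample_id != cl.sample_id or ce.chrom != cl.chrom:
                continue
            if ce.end < cl.start or cl.end < ce.start:
                continue
            shared = shareable_positions(ce) & shareable_positions(cl)
            if shared:
                if cl.n_snvs > ce.n_snvs:
                    drop_early.add(ie)
                else:
                    drop_late.add(il)
            else:
                seq_early.add(ie)
                seq_late.add(il)

    merged: list[KataegisCandidate] = []
    for ie, ce in enumerate(candidates_early):
        if ie in drop_early:
            continue
        merged.append(replace(ce, sequential_pair=ie in seq_early))
    for il, cl in enumerate(candidates_late):
        if il in drop_late:
            continue
        merged.append(replace(cl, sequential_pair=il in seq_late))
    merged.sort(key=lambda c: (c.sample_id, c.chrom, c.start, c.epoch_tag))
    return merged


def call_sample(
    snvs: Iterable[SnvRecord],
    gamma: float = 25.0,
    kmin: int = 2,
    genome_length: float = DEFAULT_GENOME_LENGTH,
    alpha: float = 0.01,
    max_threshold_bp: float = MAX_THRESHOLD_BP,
) -> list[KataegisCandidate]:
    """Full per-sample calling: subsets, per-subset calls, early/late dedup."""
    subsets = build_epoch_subsets(snvs)
    kwargs = dict(
        gamma=gamma,
        kmin=kmin,
        genome_length=genome_length,
        alpha=alpha,
        max_threshold_bp=max_threshold_bp,
    )
    early = call_candidates(subsets["early"], **kwargs)
    late = call_candidates(subsets["late"], **kwargs)
    sub = call_candidates(subsets["subclonal"], **kwargs)
    merged = dedup_early_late(early, late)
    merged.extend(sub)
    merged.sort(key=lambda c: (c.sample_id, c.chrom, c.start, c.epoch_tag))
    return merged
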
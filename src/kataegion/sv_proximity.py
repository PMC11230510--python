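"""Distances between clustered-hypermutation events and SV breakends,
matched-control simulation, and band enrichment tests.

Distances are measured from the event span: a breakend inside the span is at
distance 0; otherwise the gap to the nearer span boundary. Controls re-anchor
each event at a random somatic small variant of the same sample (outside the
exclusion mask) with an identical span, so observed and control sets face the
same SV catalog and the same length distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .formats_io import GenomeMask, SnvRecord, SvRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ProximityRecord",
    "EnrichmentTable",
    "breakend_index",
    "nearest_sv_distance",
    "generate_matched_controls",
    "proximity_enrichment",
    "sv_type_distance_profile",
    "fraction_within",
]

BANDS = ("within_10kb", "band_0.1_to_10Mb")


@dataclass(frozen=True)
class ProximityRecord:
    event_id: str
    sample_id: str
    nearest_distance_bp: int | None  # None when the sample has no SVs
    nearest_sv_type: str | None
    epoch_tag: str | None = None


@dataclass(frozen=True)
class EnrichmentTable:
    """2x2 observed/control x near/far counts with OR and exact p."""

    band: str
    observed_near: int
    observed_far: int
    control_near: int
    control_far: int
    odds_ratio: float
    p_value: float


def breakend_index(svs: Iterable[SvRecord]) -> dict[str, dict[str, np.ndarray]]:
    """Per-sample, per-chromosome sorted breakend positions with SV types."""
    acc: dict[str, dict[str, list[tuple[int, str]]]] = {}
    for sv in svs:
        per = acc.setdefault(sv.sample_id, {})
        per.setdefault(sv.chrom1, []).append((sv.pos1, sv.sv_type.value))
        per.setdefault(sv.chrom2, []).append((sv.pos2, sv.sv_type.value))
    out: dict[str, dict[str, np.ndarray]] = {}
    for sample, per in acc.items():
        out[sample] = {}
        for chrom, pts in per.items():
            pts.sort()
            out[sample][chrom] = np.array(
                pts, dtype=[("pos", np.int64), ("sv_type", "U8")]
            )
    return out


def _span_distance(pos: int, start: int, end: int) -> int:
    if pos < start:
        return start - pos
    if pos > end:
        return pos - end
    return 0


def _nearest_on_chrom(
    arr: np.ndarray, start: int, end: int
) -> tuple[int, str, int] | None:
    """(distance, sv_type, breakend_pos) of the nearest breakend on one chrom."""
    pos = arr["pos"]
    dist = np.where(pos < start, start - pos, np.where(pos > end, pos - end, 0))
    order = np.lexsort((pos, dist))
    k = order[0]
    return int(dist[k]), str(arr["sv_type"][k]), int(pos[k])


def nearest_sv_distance(
    event,
    svs: Sequence[SvRecord] | Mapping[str, Mapping[str, np.ndarray]],
    event_id: str | None = None,
) -> ProximityRecord:
    """Nearest-breakend distance for one event against same-sample SVs.

    ``event`` needs sample_id, chrom, start, end (and optionally epoch_tag).
    Ties across SV types go to the smallest breakend coordinate. A sample
    with no SVs yields a null distance (logged); such records are excluded
    from enrichment tests.
    """
    index = svs if isinstance(svs, Mapping) else breakend_index(svs)
    sample = event.sample_id
    eid = event_id or f"{sample}:{event.chrom}:{event.start}-{event.end}"
    epoch = getattr(event, "epoch_tag", None)
    per = index.get(sample)
    if not per:
        logger.info("nearest_sv_distance: sample %s has no SVs; null distance", sample)
        return ProximityRecord(eid, sample, None, None, epoch)
    arr = per.get(event.chrom)
    if arr is None or arr.size == 0:
        # no same-chromosome breakend: distance to another chromosome is
        # undefined in base pairs, treat as far beyond any band
        return ProximityRecord(eid, sample, None, None, epoch)
    d, t, _ = _nearest_on_chrom(arr, event.start, event.end)
    return ProximityRecord(eid, sample, d, t, epoch)


def compute_distances(
    events: Sequence, svs: Sequence[SvRecord] | Mapping
) -> list[ProximityRecord]:
    index = svs if isinstance(svs, Mapping) else breakend_index(svs)
    return [nearest_sv_distance(e, index, event_id=str(i)) for i, e in enumerate(events)]


@dataclass(frozen=True)
class _ControlRegion:
    sample_id: str
    chrom: str
    start: int  # 1-based inclusive, like event spans
    end: int


def generate_matched_controls(
    events: Sequence,
    all_small_variants: Sequence[SnvRecord],
    mask: GenomeMask | None,
    seed: int,
) -> list[_ControlRegion]:
    """One matched control region per event.

    Each control is anchored at a uniformly chosen somatic small variant of
    the same sample, outside the mask, and spans the same length as its
    event (anchor at the span start). Fully reproducible under ``seed``.
    """
    rng = np.random.default_rng(seed)
    by_sample: dict[str, list[SnvRecord]] = {}
    for v in all_small_variants:
        if mask is not None and mask.contains(v.chrom, v.pos - 1):
            continue
        by_sample.setdefault(v.sample_id, []).append(v)
    controls: list[_ControlRegion] = []
    for ev in events:
        pool = by_sample.get(ev.sample_id)
        if not pool:
            raise ValueError(
                f"no eligible small variant outside the mask for sample {ev.sample_id}"
            )
        anchor = pool[int(rng.integers(len(pool)))]
        span = ev.end - ev.start  # control span length == event span length
        controls.append(
            _ControlRegion(
                sample_id=ev.sample_id,
                chrom=anchor.chrom,
                start=anchor.pos,
                end=anchor.pos + span,
            )
        )
    return controls


def _band_counts(
    distances: Sequence[int | None], band: str
) -> tuple[int, int]:
    near = far = 0
    for d in distances:
        if d is None:
            continue
        if band == "within_10kb":
            if d <= 10_000:
                near += 1
            else:
                far += 1
        elif band == "band_0.1_to_10Mb":
            if 100_000 <= d <= 10_000_000:
                near += 1
            elif d > 10_000_000:
                far += 1
        else:
            raise ValueError(f"unknown band {band!r}; allowed: {BANDS}")
    return near, far


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> float:
    """Cross-product odds ratio with 0.5 continuity correction on zero cells."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def proximity_enrichment(
    observed_distances: Sequence[int | None],
    control_distances: Sequence[int | None],
    band: str = "within_10kb",
) -> EnrichmentTable:
    """Exact (hypergeometric, two-sided) enrichment test for one distance band.

    Rows: observed vs control events; columns: near vs far per the band
    definition. Null-distance records (samples without SVs) are excluded.
    """
    if band not in BANDS:
        raise ValueError(f"unknown band {band!r}; allowed: {BANDS}")
    obs = [d for d in observed_distances if d is not None]
    if not obs:
        raise ValueError("empty observed event set")
    a, b = _band_counts(observed_distances, band)
    c, d = _band_counts(control_distances, band)
    if a + b == 0 or c + d == 0:
        raise ValueError("a margin of the enrichment table is empty")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentTable(
        band=band,
        observed_near=a,
        observed_far=b,
        control_near=c,
        control_far=d,
        odds_ratio=odds_ratio_2x2(a, b, c, d),
        p_value=float(p),
    )


def sv_type_distance_profile(
    events: Sequence, svs: Sequence[SvRecord]
) -> list[dict]:
    """Nearest distance PER SV TYPE for each event, tagged with the epoch.

    Returns one row per (event, sv_type present in the sample on the event's
    chromosome) with the type-specific nearest distance; SV types without any
    breakend on the chromosome are absent from the table.
    """
    index = breakend_index(svs)
    rows: list[dict] = []
    for i, ev in enumerate(events):
        per = index.get(ev.sample_id, {})
        arr = per.get(ev.chrom)
        if arr is None or arr.size == 0:
            continue
        for sv_type in sorted(set(arr["sv_type"])):
            sub = arr[arr["sv_type"] == sv_type]
            d, _, _ = _nearest_on_chrom(sub, ev.start, ev.end)
            rows.append(
                {
                    "event_id": str(i),
                    "sample_id": ev.sample_id,
                    "epoch_tag": getattr(ev, "epoch_tag", None),
                    "sv_type": sv_type,
                    "distance_bp": d,
                    "log10_distance": float(np.log10(d)) if d > 0 else 0.0,
                }
            )
    return rows


def fraction_within(
    distances: Sequence[int | None], cutoff_bp: int = 1000
) -> float:
    """Fraction of non-null distances <= cutoff (e.g. the within-1-kbp share)."""
    vals = [d for d in distances if d is not None]
    if not vals:
        raise ValueError("no non-null distances")
    return sum(d <= cutoff_bp for d in vals) / len(vals)
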
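"""Seeded synthetic-cohort generator with planted hypermutation clusters.

Emits per-sample SNV catalogs (background point process plus planted
clusters with APOBEC-context bias, per-event epochs and partial phasing),
typed SV catalogs, and a full ground-truth table, so that every pipeline
stage can be exercised and scored without external data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .formats_io import Epoch, GenomeMask, SnvRecord, SvRecord, SvType

logger = logging.getLogger(__name__)

__all__ = ["SimConfig", "TruthEvent", "simulate_cohort", "truth_match"]

_SUBS = (("C", "A"), ("C", "G"), ("C", "T"), ("T", "A"), ("T", "C"), ("T", "G"),
         ("G", "T"), ("G", "C"), ("G", "A"), ("A", "T"), ("A", "G"), ("A", "C"))
_BASES = ("A", "C", "G", "T")

DEFAULT_GENOME = tuple((f"chr{i}", 140_000_000) for i in range(1, 23))


@dataclass
class SimConfig:
    """Knobs of the synthetic cohort; defaults follow the target data shape
    (median cluster of 6 SNVs in range 4-33, median span ~2.7 kbp in range
    0.2-35.3 kbp, ~31% of clusters phase-informative)."""

    n_samples: int = 5
    genome_model: Sequence[tuple[str, int]] = DEFAULT_GENOME
    background_rate: float = 1e-6  # SNVs per bp
    n_events: int = 3  # planted clusters per sample
    size_log_sigma: float = 0.45  # cluster size ~ round(lognormal(ln 6, sigma)) clipped to [4, 33]
    size_range: tuple[int, int] = (4, 33)
    span_log_sigma: float = 0.85  # span ~ lognormal(ln 2700, sigma) clipped
    span_median: float = 2700.0
    span_range: tuple[int, int] = (200, 35_300)
    apobec_context_prob: float = 0.8
    epoch_mix: dict = field(
        default_factory=lambda: {
            "early_clonal": 0.30,
            "late_clonal": 0.25,
            "clonal_unspecified": 0.10,
            "subclonal": 0.30,
            "unknown": 0.05,
        }
    )
    phasing_completeness: float = 0.31
    n_svs: int = 20
    frac_sv_linked: float = 0.3  # clusters within 1 kbp of a breakend
    frac_distal: float = 0.2  # clusters 0.1-10 Mbp from a breakend
    sv_type_mix: dict = field(
        default_factory=lambda: {
            "DEL": 0.30,
            "DUP": 0.20,
            "INV": 0.20,
            "TRA": 0.15,
            "TRA_INV": 0.10,
            "COMPLEX": 0.05,
        }
    )
    mask: GenomeMask | None = None
    background_epoch_mix: dict | None = None  # defaults to epoch_mix

    def validate(self) -> None:
        if self.frac_sv_linked + self.frac_distal > 1 + 1e-12:
            raise ValueError("frac_sv_linked + frac_distal must be <= 1")
        for name, probs in (("epoch_mix", self.epoch_mix), ("sv_type_mix", self.sv_type_mix)):
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"{name} has negative probabilities")
        for p in (self.apobec_context_prob, self.phasing_completeness, self.background_rate):
            if p < 0:
                raise ValueError("probabilities/rates must be >= 0")


@dataclass(frozen=True)
class TruthEvent:
    sample_id: str
    chrom: str
    start: int
    end: int
    n_snvs: int
    epoch: str
    sv_linked: bool
    distance_to_sv: int | None
    positions: tuple[int, ...]


def _choice(rng: np.random.Generator, mix: dict) -> str:
    keys = sorted(mix)
    probs = np.array([mix[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[int(rng.choice(len(keys), p=probs))]


def _masked(mask: GenomeMask | None, chrom: str, pos: int) -> bool:
    return mask is not None and mask.contains(chrom, pos - 1)


def _random_context(rng: np.random.Generator, ref: str) -> str:
    return _BASES[rng.integers(4)] + ref + _BASES[rng.integers(4)]


def _planted_snv(
    rng: np.random.Generator,
    sample: str,
    chrom: str,
    pos: int,
    epoch: str,
    phase_group: str | None,
    apobec_prob: float,
) -> SnvRecord:
    if rng.random() < apobec_prob:
        ref = "C"
        alt = "T" if rng.random() < 0.5 else "G"
        ctx = "T" + ref + _BASES[rng.integers(4)]  # TpC context
    else:
        ref, alt = _SUBS[int(rng.integers(len(_SUBS)))]
        ctx = _random_context(rng, ref)
    return SnvRecord(
        sample_id=sample,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        epoch=Epoch(epoch),
        phase_group=phase_group,
        tricontext=ctx,
    )


def _simulate_svs(
    rng: np.random.Generator, cfg: SimConfig, sample: str
) -> list[SvRecord]:
    chroms = [c for c, _ in cfg.genome_model]
    lengths = dict(cfg.genome_model)
    svs: list[SvRecord] = []
    for _ in range(cfg.n_svs):
        sv_type = SvType(_choice(rng, cfg.sv_type_mix))
        if sv_type in (SvType.TRA, SvType.TRA_INV):
            c1, c2 = rng.choice(len(chroms), size=2, replace=False)
            svs.append(
                SvRecord(
                    sample_id=sample,
                    chrom1=chroms[c1],
                    pos1=int(rng.integers(1, lengths[chroms[c1]])),
                    chrom2=chroms[c2],
                    pos2=int(rng.integers(1, lengths[chroms[c2]])),
                    sv_type=sv_type,
                )
            )
        else:
            c = chroms[int(rng.integers(len(chroms)))]
            size = int(np.clip(rng.lognormal(np.log(1e5), 1.5), 50, lengths[c] // 2))
            p1 = int(rng.integers(1, lengths[c] - size))
            svs.append(
                SvRecord(
                    sample_id=sample,
                    chrom1=c,
                    pos1=p1,
                    chrom2=c,
                    pos2=p1 + size,
                    sv_type=sv_type,
                    size_bp=size,
                )
            )
    return svs


def _event_anchor(
    rng: np.random.Generator,
    cfg: SimConfig,
    svs: list[SvRecord],
    span: int,
) -> tuple[str, int, bool, int | None]:
    """Pick (chrom, start, sv_linked, distance) for one planted event."""
    chroms = [c for c, _ in cfg.genome_model]
    lengths = dict(cfg.genome_model)
    u = rng.random()
    breakends = [(sv.chrom1, sv.pos1) for sv in svs] + [(sv.chrom2, sv.pos2) for sv in svs]
    for _ in range(100):
        if u < cfg.frac_sv_linked and breakends:
            chrom, bp = breakends[int(rng.integers(len(breakends)))]
            offset = int(rng.integers(0, 1001))
            start = bp + offset
            linked, dist = True, offset
        elif u < cfg.frac_sv_linked + cfg.frac_distal and breakends:
            chrom, bp = breakends[int(rng.integers(len(breakends)))]
            offset = int(10 ** rng.uniform(5, 7))  # 0.1-10 Mbp, log-uniform
            start = bp + offset
            linked, dist = False, offset
        else:
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(1, lengths[chrom]))
            linked, dist = False, None
        end = start + span - 1
        if end >= lengths[chrom]:
            continue
        if cfg.mask is not None and any(
            _masked(cfg.mask, chrom, p) for p in (start, end)
        ):
            continue
        return chrom, start, linked, dist
    raise RuntimeError("failed to place a planted event after 100 attempts")


def simulate_cohort(
    config: SimConfig, seed: int
) -> tuple[dict[str, list[SnvRecord]], dict[str, list[SvRecord]], list[TruthEvent]]:
    """Generate (per-sample SNVs, per-sample SVs, truth table); reproducible."""
    config.validate()
    rng = np.random.default_rng(seed)
    snvs_by_sample: dict[str, list[SnvRecord]] = {}
    svs_by_sample: dict[str, list[SvRecord]] = {}
    truth: list[TruthEvent] = []
    bg_mix = config.background_epoch_mix or config.epoch_mix
    lengths = dict(config.genome_model)
    chroms = [c for c, _ in config.genome_model]
    chrom_w = np.array([lengths[c] for c in chroms], dtype=float)
    chrom_w /= chrom_w.sum()
    lo_sz, hi_sz = config.size_range
    lo_sp, hi_sp = config.span_range

    for si in range(config.n_samples):
        sample = f"S{si:03d}"
        svs = _simulate_svs(rng, config, sample)
        svs_by_sample[sample] = svs
        snvs: list[SnvRecord] = []
        used_positions: set[tuple[str, int]] = set()

        total_len = float(sum(lengths.values()))
        n_bg = int(rng.poisson(config.background_rate * total_len))
        if n_bg:
            ep_keys = sorted(bg_mix)
            ep_p = np.array([bg_mix[k] for k in ep_keys], dtype=float)
            ep_p /= ep_p.sum()
            counts = rng.multinomial(n_bg, chrom_w)
            for ci, chrom in enumerate(chroms):
                k = int(counts[ci])
                if k == 0:
                    continue
                pos_arr = rng.integers(1, lengths[chrom] + 1, size=k)
                sub_idx = rng.integers(0, len(_SUBS), size=k)
                ep_idx = rng.choice(len(ep_keys), size=k, p=ep_p)
                f5 = rng.integers(0, 4, size=k)
                f3 = rng.integers(0, 4, size=k)
                for pos, sj, ej, a, b in zip(pos_arr, sub_idx, ep_idx, f5, f3):
                    pos = int(pos)
                    if _masked(config.mask, chrom, pos) or (chrom, pos) in used_positions:
                        continue  # rare collision: drop rather than redraw
                    used_positions.add((chrom, pos))
                    ref, alt = _SUBS[sj]
                    snvs.append(
                        SnvRecord(
                            sample_id=sample,
                            chrom=chrom,
                            pos=pos,
                            ref=ref,
                            alt=alt,
                            epoch=Epoch(ep_keys[ej]),
                            tricontext=_BASES[a] + ref + _BASES[b],
                        )
                    )

        for ei in range(config.n_events):
            size = int(np.clip(round(rng.lognormal(np.log(6.0), config.size_log_sigma)),
                               lo_sz, hi_sz))
            span = int(np.clip(round(rng.lognormal(np.log(config.span_median),
                                                   config.span_log_sigma)),
                               max(lo_sp, size), hi_sp))
            chrom, start, linked, dist = _event_anchor(rng, config, svs, span)
            end = start + span - 1
            # endpoints pinned to the span; interior positions uniform, distinct
            positions: list[int] = []
            for _ in range(100):
                interior: set[int] = set()
                while len(interior) < size - 2:
                    interior.add(int(rng.integers(start + 1, end)))
                cand = sorted({start, end} | interior)
                if all((chrom, p) not in used_positions for p in cand):
                    positions = cand
                    break
            if not positions:
                raise RuntimeError("failed to place event SNVs without collisions")
            epoch = _choice(rng, config.epoch_mix)
            phase = f"{sample}_PS{ei}" if rng.random() < config.phasing_completeness else None
            for pos in positions:
                if (chrom, pos) in used_positions:
                    continue
                used_positions.add((chrom, pos))
                snvs.append(
                    _planted_snv(rng, sample, chrom, pos, epoch, phase,
                                 config.apobec_context_prob)
                )
            truth.append(
                TruthEvent(
                    sample_id=sample,
                    chrom=chrom,
                    start=start,
                    end=end,
                    n_snvs=len(positions),
                    epoch=epoch,
                    sv_linked=linked,
                    distance_to_sv=dist,
                    positions=tuple(positions),
                )
            )
        snvs.sort(key=lambda s: (s.chrom, s.pos))
        snvs_by_sample[sample] = snvs
    return snvs_by_sample, svs_by_sample, truth


def truth_match(
    called_events: Sequence,
    truth: Sequence[TruthEvent],
    min_snv_share: float = 0.5,
) -> dict:
    """Score called events against the planted truth.

    A called event matches a truth event when they overlap on the same
    sample/chromosome and the called members cover at least ``min_snv_share``
    of the truth event's SNV positions. Returns TP/FP/FN plus sensitivity
    and precision.
    """
    truth_matched = [False] * len(truth)
    called_matched = [False] * len(called_events)
    for ci, ev in enumerate(called_events):
        ev_pos = {(s.chrom, s.pos) for s in ev.snvs}
        for ti, t in enumerate(truth):
            if t.sample_id != ev.sample_id or t.chrom != ev.chrom:
                continue
            if t.end < ev.start or ev.end < t.start:
                continue
            shared = sum((t.chrom, p) in ev_pos for p in t.positions)
            if shared >= min_snv_share * t.n_snvs:
                truth_matched[ti] = True
                called_matched[ci] = True
    tp = sum(truth_matched)
    fn = len(truth) - tp
    fp = called_matched.count(False)
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "sensitivity": tp / len(truth) if truth else (1.0 if not called_events else 0.0),
        "precision": (
            called_matched.count(True) / len(called_events) if called_events else (
                1.0 if not truth else 0.0
            )
        ),
    }
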
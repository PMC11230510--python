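"""Candidate filters: substitution-type consistency and phasing (in-cis) checks.

A candidate survives when at least one of two characteristics holds: all
member SNVs mutate the same strand-normalized reference base, or at least
two members are phased onto the same haplotype. Cohorts without phasing data
use a consistency-only mode. Every dropped candidate is accounted for.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .caller import KataegisCandidate

__all__ = [
    "KataegisEvent",
    "is_type_consistent",
    "is_in_cis",
    "apply_filters",
    "FILTER_MODES",
]

FILTER_MODES = ("phased", "consecutiveness_only")

_PYRIMIDINE_OF = {"A": "T", "G": "C", "C": "C", "T": "T"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class KataegisEvent:
    """A filtered candidate with filter provenance."""

    candidate: KataegisCandidate
    type_consistent: bool
    in_cis: bool
    kept: bool
    drop_reason: str | None = None  # inconsistent_and_unphased | epoch_duplicate

    def __getattr__(self, name):  # delegate candidate fields (chrom, snvs, ...)
        return getattr(self.candidate, name)


def normalized_substitution(ref: str, alt: str) -> str:
    """Substitution collapsed to a pyrimidine reference base, e.g. G>A -> C>T."""
    if ref in ("A", "G"):
        return f"{_COMPLEMENT[ref]}>{_COMPLEMENT[alt]}"
    return f"{ref}>{alt}"


def is_type_consistent(candidate: KataegisCandidate, strict: bool = False) -> bool:
    """True iff all member SNVs share the strand-normalized reference base.

    The default rule admits the canonical C>T / C>G mixture (all reference-C
    after pyrimidine normalization). ``strict=True`` instead requires the
    identical normalized substitution class for every member.
    """
    if strict:
        classes = {normalized_substitution(s.ref, s.alt) for s in candidate.snvs}
        return len(classes) == 1
    refs = {_PYRIMIDINE_OF[s.ref] for s in candidate.snvs}
    return len(refs) == 1


def is_in_cis(candidate: KataegisCandidate) -> bool:
    """True iff >= 2 member SNVs carry the same non-null phase-group ID."""
    seen: set[str] = set()
    for s in candidate.snvs:
        if s.phase_group is None:
            continue
        if s.phase_group in seen:
            return True
        seen.add(s.phase_group)
    return False


def apply_filters(
    candidates: Sequence[KataegisCandidate],
    mode: str = "phased",
    strict_consistency: bool = False,
) -> tuple[list[KataegisEvent], dict[str, int]]:
    """Filter candidates and return (all events with provenance, drop ledger).

    ``phased`` mode keeps candidates that are type-consistent OR in cis;
    ``consecutiveness_only`` (public cohorts without phasing) keeps
    type-consistent candidates. The ledger counts per drop reason and always
    satisfies input = kept + sum(ledger).
    """
    if mode not in FILTER_MODES:
        raise ValueError(f"unknown filter mode {mode!r}; allowed: {FILTER_MODES}")
    events: list[KataegisEvent] = []
    ledger: dict[str, int] = {}
    for c in candidates:
        consistent = is_type_consistent(c, strict=strict_consistency)
        cis = is_in_cis(c)
        kept = consistent or cis if mode == "phased" else consistent
        reason = None if kept else "inconsistent_and_unphased"
        if reason:
            ledger[reason] = ledger.get(reason, 0) + 1
        events.append(
            KataegisEvent(
                candidate=c,
                type_consistent=consistent,
                in_cis=cis,
                kept=kept,
                drop_reason=reason,
            )
        )
    return events, ledger


def kept_events(events: Sequence[KataegisEvent]) -> list[KataegisEvent]:
    return [e for e in events if e.kept]
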
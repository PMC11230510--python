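"""Readers, writers and interval utilities for somatic SNV/SV catalogs.

Coordinate conventions
----------------------
* SNVs are 1-based single positions (VCF convention).
* BED / BEDPE input and output are 0-based half-open.
* Internal event spans are 1-based inclusive.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

BASES = frozenset("ACGT")


class Epoch(str, Enum):
    """Evolutionary-timing label of a somatic SNV."""

    EARLY_CLONAL = "early_clonal"
    LATE_CLONAL = "late_clonal"
    CLONAL_UNSPECIFIED = "clonal_unspecified"
    SUBCLONAL = "subclonal"
    UNKNOWN = "unknown"


class SvType(str, Enum):
    DEL = "DEL"
    DUP = "DUP"
    INV = "INV"
    TRA = "TRA"
    TRA_INV = "TRA_INV"
    COMPLEX = "COMPLEX"


#: SV types that join two chromosomes.
INTERCHROM_TYPES = frozenset({SvType.TRA, SvType.TRA_INV})


class FormatError(ValueError):
    """Raised for malformed input rows; message names the offending line."""


def _parse_epoch(label: str | None, context: str = "") -> Epoch:
    if label is None or label == "" or label == ".":
        return Epoch.UNKNOWN
    try:
        return Epoch(label)
    except ValueError:
        allowed = ", ".join(e.value for e in Epoch)
        raise FormatError(
            f"unknown epoch label {label!r}{context}; allowed labels: {allowed}"
        ) from None


@dataclass(frozen=True)
class SnvRecord:
    """One somatic single-nucleotide variant."""

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    epoch: Epoch = Epoch.UNKNOWN
    phase_group: str | None = None
    tricontext: str | None = None  # reference-strand 3-mer centred on pos

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"ref/alt must be single bases, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class SvRecord:
    """One structural variant as a pair of breakends plus a type class."""

    sample_id: str
    chrom1: str
    pos1: int  # 1-based breakend point
    chrom2: str
    pos2: int
    sv_type: SvType
    size_bp: int | None = None

    def __post_init__(self) -> None:
        inter = self.chrom1 != self.chrom2
        if inter and self.sv_type not in INTERCHROM_TYPES:
            raise ValueError(
                f"inter-chromosomal SV must be TRA/TRA_INV, got {self.sv_type.value} "
                f"({self.chrom1}:{self.pos1} -- {self.chrom2}:{self.pos2})"
            )
        if not inter and self.sv_type in INTERCHROM_TYPES:
            raise ValueError(
                f"intra-chromosomal SV typed {self.sv_type.value} "
                f"({self.chrom1}:{self.pos1} -- {self.chrom2}:{self.pos2})"
            )
        if not inter and self.pos1 > self.pos2:
            raise ValueError("pos1 must be <= pos2 for intra-chromosomal SVs")


class GenomeMask:
    """A set of excluded genomic intervals (0-based half-open) with O(log n) lookup."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if end <= start:
                raise ValueError(f"empty/negative interval {chrom}:{start}-{end}")
            per_chrom.setdefault(chrom, []).append((start, end))
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for chrom, ivs in per_chrom.items():
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[chrom] = [s for s, _ in merged]
            self._ends[chrom] = [e for _, e in merged]

    @classmethod
    def from_bed(cls, path: str | Path) -> "GenomeMask":
        ivs = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise FormatError(f"{path}:{lineno}: BED row needs >=3 columns")
                try:
                    ivs.append((parts[0], int(parts[1]), int(parts[2])))
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: non-integer BED coordinates") from None
        return cls(ivs)

    def contains(self, chrom: str, pos0: int) -> bool:
        """True if the 0-based position falls inside a masked interval."""
        starts = self._starts.get(chrom)
        if not starts:
            return False
        i = bisect.bisect_right(starts, pos0) - 1
        return i >= 0 and pos0 < self._ends[chrom][i]

    def total_length(self) -> int:
        return sum(
            e - s
            for chrom in self._starts
            for s, e in zip(self._starts[chrom], self._ends[chrom])
        )

    def intervals(self) -> list[tuple[str, int, int]]:
        return [
            (chrom, s, e)
            for chrom in sorted(self._starts)
            for s, e in zip(self._starts[chrom], self._ends[chrom])
        ]


@dataclass
class ClinicalRow:
    """Per-patient clinical covariates used by the association models."""

    sample_id: str
    age_years: float | None = None
    psa_ng_ml: float | None = None
    grade_group: int | None = None
    ancestry: str | None = None
    sv_burden: int | None = None
    cnv_gain_bp: float | None = None
    cnv_loss_bp: float | None = None
    telomere_blood: float | None = None
    telomere_tumour: float | None = None
    gms: str | None = None

    @property
    def risk(self) -> str | None:
        """HR iff grade group >= 3, LR for 1-2."""
        if self.grade_group is None:
            return None
        return "HR" if self.grade_group >= 3 else "LR"


SNV_TSV_COLUMNS = ("sample_id", "chrom", "pos", "ref", "alt", "epoch", "phase_group", "tricontext")


def _sort_key(rec: SnvRecord) -> tuple[str, int]:
    return (rec.chrom, rec.pos)


def read_snvs(
    path: str | Path,
    dialect: str = "tsv",
    *,
    sample_id: str | None = None,
    epoch_key: str = "EPOCH",
    phase_key: str = "PGID",
    context_key: str = "TRICTX",
) -> list[SnvRecord]:
    """Read somatic SNVs from a TSV table or a VCF.

    Non-SNV rows (indels, multi-allelic sites) are skipped; the skipped count
    is logged. Output is sorted by (chrom, pos).

    Parameters
    ----------
    dialect:
        ``"tsv"`` expects a header with at least sample_id, chrom, pos, ref,
        alt; optional epoch, phase_group, tricontext columns. ``"vcf"`` reads
        a (possibly uncompressed) VCF and pulls epoch / phase-group /
        trinucleotide context from the INFO keys named by ``epoch_key``,
        ``phase_key`` and ``context_key``.
    """
    if dialect == "tsv":
        return _read_snvs_tsv(path)
    if dialect == "vcf":
        return _read_snvs_vcf(path, sample_id, epoch_key, phase_key, context_key)
    raise ValueError(f"unknown SNV dialect {dialect!r}; use 'tsv' or 'vcf'")


def _read_snvs_tsv(path: str | Path) -> list[SnvRecord]:
    records: list[SnvRecord] = []
    skipped = 0
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
        if not header_line:
            raise FormatError(f"{path}:1: empty file, expected header")
        header = header_line.split("\t")
        required = {"sample_id", "chrom", "pos", "ref", "alt"}
        missing = required - set(header)
        if missing:
            raise FormatError(f"{path}:1: missing columns {sorted(missing)}")
        idx = {name: header.index(name) for name in header}
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(parts)}"
                )

            def get(col: str) -> str | None:
                if col not in idx:
                    return None
                v = parts[idx[col]]
                return None if v in ("", ".") else v

            ref, alt = parts[idx["ref"]], parts[idx["alt"]]
            if len(ref) != 1 or len(alt) != 1 or "," in alt:
                skipped += 1
                continue
            try:
                records.append(
                    SnvRecord(
                        sample_id=parts[idx["sample_id"]],
                        chrom=parts[idx["chrom"]],
                        pos=int(parts[idx["pos"]]),
                        ref=ref,
                        alt=alt,
                        epoch=_parse_epoch(get("epoch"), f" at {path}:{lineno}"),
                        phase_group=get("phase_group"),
                        tricontext=get("tricontext"),
                    )
                )
            except FormatError:
                raise
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    if skipped:
        logger.info("read_snvs: skipped %d non-SNV rows from %s", skipped, path)
    records.sort(key=_sort_key)
    return records


def _read_snvs_vcf(
    path: str | Path,
    sample_id: str | None,
    epoch_key: str,
    phase_key: str,
    context_key: str,
) -> list[SnvRecord]:
    records: list[SnvRecord] = []
    skipped = 0
    default_sample = sample_id or Path(path).stem
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise FormatError(f"{path}:{lineno}: VCF row needs >=8 columns")
            chrom, pos_s, _id, ref, alt = parts[0], parts[1], parts[2], parts[3], parts[4]
            if len(ref) != 1 or len(alt) != 1 or alt in (".", "*") or "," in alt:
                skipped += 1
                continue
            info: dict[str, str] = {}
            for kv in parts[7].split(";"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    info[k] = v
            try:
                records.append(
                    SnvRecord(
                        sample_id=default_sample,
                        chrom=chrom,
                        pos=int(pos_s),
                        ref=ref,
                        alt=alt,
                        epoch=_parse_epoch(info.get(epoch_key), f" at {path}:{lineno}"),
                        phase_group=info.get(phase_key),
                        tricontext=info.get(context_key),
                    )
                )
            except FormatError:
                raise
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    if skipped:
        logger.info("read_snvs: skipped %d non-SNV rows from %s", skipped, path)
    records.sort(key=_sort_key)
    return records


def write_snvs(records: Sequence[SnvRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SNV_TSV_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.sample_id,
                        r.chrom,
                        str(r.pos),
                        r.ref,
                        r.alt,
                        r.epoch.value,
                        r.phase_group or ".",
                        r.tricontext or ".",
                    ]
                )
                + "\n"
            )


def read_svs(
    path: str | Path,
    *,
    breakend_point: str = "start",
    default_sample: str | None = None,
) -> list[SvRecord]:
    """Read SVs from a BEDPE file (0-based half-open breakend intervals).

    Columns: chrom1 start1 end1 chrom2 start2 end2 name [score strand1
    strand2] with the type class in the *name* column and an optional
    trailing sample column. Breakend intervals are reduced to 1-based points:
    ``start+1`` by default, or the interval midpoint with
    ``breakend_point="midpoint"``.
    """
    if breakend_point not in ("start", "midpoint"):
        raise ValueError("breakend_point must be 'start' or 'midpoint'")
    records: list[SvRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 7:
                raise FormatError(f"{path}:{lineno}: BEDPE row needs >=7 columns")
            try:
                c1, s1, e1 = parts[0], int(parts[1]), int(parts[2])
                c2, s2, e2 = parts[3], int(parts[4]), int(parts[5])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer BEDPE coordinates") from None
            try:
                sv_type = SvType(parts[6])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: unknown SV type {parts[6]!r}; "
                    f"allowed: {', '.join(t.value for t in SvType)}"
                ) from None
            if breakend_point == "start":
                p1, p2 = s1 + 1, s2 + 1
            else:
                p1, p2 = (s1 + e1) // 2 + 1, (s2 + e2) // 2 + 1
            sample = parts[10] if len(parts) > 10 else (default_sample or Path(path).stem)
            size = abs(p2 - p1) if c1 == c2 else None
            if c1 == c2 and p1 > p2:
                p1, p2 = p2, p1
            try:
                records.append(
                    SvRecord(
                        sample_id=sample,
                        chrom1=c1,
                        pos1=p1,
                        chrom2=c2,
                        pos2=p2,
                        sv_type=sv_type,
                        size_bp=size,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return records


def write_svs(records: Sequence[SvRecord], path: str | Path) -> None:
    """Write SVs as BEDPE (single-base breakend intervals, 0-based half-open)."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.chrom1,
                        str(r.pos1 - 1),
                        str(r.pos1),
                        r.chrom2,
                        str(r.pos2 - 1),
                        str(r.pos2),
                        r.sv_type.value,
                        ".",
                        ".",
                        ".",
                        r.sample_id,
                    ]
                )
                + "\n"
            )


def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read named BED intervals (chrom, start, end, name), 0-based half-open."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED row needs >=3 columns")
            name = parts[3] if len(parts) > 3 else f"interval_{lineno}"
            out.append((parts[0], int(parts[1]), int(parts[2]), name))
    return out


def annotate_intervals(
    events: Sequence[tuple[str, int, int]],
    bed_intervals: Sequence[tuple[str, int, int, str]],
) -> list[set[str]]:
    """Label each (chrom, start, end) event with names of overlapping intervals.

    Both events and intervals are interpreted as half-open on a shared
    convention; abutting ranges do not overlap.
    """
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, start, end, name in bed_intervals:
        by_chrom.setdefault(chrom, []).append((start, end, name))
    for ivs in by_chrom.values():
        ivs.sort()
    labels: list[set[str]] = []
    for chrom, start, end in events:
        hits: set[str] = set()
        for s, e, name in by_chrom.get(chrom, ()):
            if s >= end:
                break
            if e > start:
                hits.add(name)
        labels.append(hits)
    return labels


def read_clinical(path: str | Path) -> list[ClinicalRow]:
    """Read the clinical covariate TSV; empty cells and '.' become None."""
    import csv

    rows: list[ClinicalRow] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, 2):
            def fget(col: str) -> float | None:
                v = row.get(col)
                return None if v in (None, "", ".") else float(v)

            def sget(col: str) -> str | None:
                v = row.get(col)
                return None if v in (None, "", ".") else v

            gg = fget("grade_group")
            rows.append(
                ClinicalRow(
                    sample_id=row["sample_id"],
                    age_years=fget("age_years"),
                    psa_ng_ml=fget("psa_ng_ml"),
                    grade_group=int(gg) if gg is not None else None,
                    ancestry=sget("ancestry"),
                    sv_burden=int(fget("sv_burden") or 0) if sget("sv_burden") else None,
                    cnv_gain_bp=fget("cnv_gain_bp"),
                    cnv_loss_bp=fget("cnv_loss_bp"),
                    telomere_blood=fget("telomere_blood"),
                    telomere_tumour=fget("telomere_tumour"),
                    gms=sget("gms"),
                )
            )
    return rows
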
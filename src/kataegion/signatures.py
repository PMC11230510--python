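"""96-channel SBS and 32-channel SV catalogs with non-negative least-squares
signature refitting and APOBEC attribution summaries.

De novo signature extraction is out of scope; catalogs are refit against a
supplied column-stochastic reference matrix, with poorly reconstructed
catalogs (cosine similarity < 0.5) flagged for exclusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import nnls

from .formats_io import SnvRecord, SvRecord, SvType
from .segmentation import exact_pcf

logger = logging.getLogger(__name__)

__all__ = [
    "SBS96_CLASSES",
    "SV32_CLASSES",
    "build_sbs96",
    "build_sv32",
    "ExposureVector",
    "fit_exposures",
    "apobec_summary",
    "read_signature_matrix",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_FLANKS = ("A", "C", "G", "T")

#: COSMIC ordering: substitution-major, then 5' flank, then 3' flank.
SBS96_CLASSES: tuple[str, ...] = tuple(
    f"{f5}[{sub}]{f3}" for sub in _SUBSTITUTIONS for f5 in _FLANKS for f3 in _FLANKS
)

_SIZE_BINS = ((1, 10_000), (10_000, 100_000), (100_000, 1_000_000),
              (1_000_000, 10_000_000), (10_000_000, None))
_SIZE_LABELS = ("1-10kb", "10-100kb", "100kb-1Mb", "1-10Mb", ">10Mb")

SV32_CLASSES: tuple[str, ...] = tuple(
    f"{cl}_{t}_{size}"
    for cl in ("clustered", "non-clustered")
    for t in ("DEL", "DUP", "INV")
    for size in _SIZE_LABELS
) + ("clustered_TRA", "non-clustered_TRA")


def _revcomp(s: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(s))


def sbs96_class(ref: str, alt: str, tricontext: str) -> str:
    """Pyrimidine-normalized 96-channel label for one substitution.

    ``tricontext`` is the reference-strand 3-mer centred on the variant; its
    middle base must equal ``ref``. Purine-reference substitutions are
    reverse-complemented.
    """
    if len(tricontext) != 3:
        raise ValueError(f"tricontext must be a 3-mer, got {tricontext!r}")
    if tricontext[1] != ref:
        raise ValueError(f"tricontext {tricontext} middle base != ref {ref}")
    if ref in ("A", "G"):
        tricontext = _revcomp(tricontext)
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{tricontext[0]}[{ref}>{alt}]{tricontext[2]}"


def build_sbs96(snvs: Iterable[SnvRecord]) -> np.ndarray:
    """Count SNVs into the 96 substitution-context channels.

    SNVs whose context contains an N (or lacks a context entirely) are
    skipped with a logged count.
    """
    index = {c: i for i, c in enumerate(SBS96_CLASSES)}
    counts = np.zeros(96, dtype=np.int64)
    skipped = 0
    for s in snvs:
        ctx = s.tricontext
        if ctx is None:
            raise ValueError(
                f"SNV {s.chrom}:{s.pos} has no trinucleotide context; supply a "
                "tricontext column or an indexed FASTA"
            )
        if any(b not in "ACGT" for b in ctx):
            skipped += 1
            continue
        counts[index[sbs96_class(s.ref, s.alt, ctx)]] += 1
    if skipped:
        logger.info("build_sbs96: skipped %d SNVs with N-containing context", skipped)
    return counts


def _size_label(size_bp: int) -> str:
    for (lo, hi), label in zip(_SIZE_BINS, _SIZE_LABELS):
        if hi is None or size_bp < hi:
            return label
    return _SIZE_LABELS[-1]


def clustered_breakends(
    svs: Sequence[SvRecord],
    gamma: float = 25.0,
    quantile: float = 0.1,
) -> set[int]:
    """Indices of SVs flagged as clustered.

    Per sample and chromosome, log10 inter-breakend distances are segmented
    by exact piecewise-constant fitting; breakends in segments whose mean
    falls below the given quantile of all genome-wide inter-breakend
    distances are clustered. An SV is clustered if either breakend is.
    """
    pts: list[tuple[str, str, int, int]] = []  # sample, chrom, pos, sv index
    for i, sv in enumerate(svs):
        pts.append((sv.sample_id, sv.chrom1, sv.pos1, i))
        pts.append((sv.sample_id, sv.chrom2, sv.pos2, i))
    by_chrom: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for sample, chrom, pos, i in pts:
        by_chrom.setdefault((sample, chrom), []).append((pos, i))
    all_gaps: list[float] = []
    chrom_series: dict[tuple[str, str], tuple[list[int], np.ndarray]] = {}
    for key, lst in by_chrom.items():
        lst.sort()
        positions = np.array([p for p, _ in lst], dtype=np.int64)
        gaps = np.diff(positions)
        gaps = np.maximum(gaps, 1)
        idx = [i for _, i in lst]
        chrom_series[key] = (idx, gaps)
        # a gap between the two breakends of one SV is its span, not an
        # inter-SV distance; only inter-SV gaps define the clustering scale
        all_gaps.extend(
            float(g) for g, a, b in zip(gaps, idx, idx[1:]) if a != b
        )
    if not all_gaps:
        return set()
    cutoff = np.log10(np.quantile(all_gaps, quantile))
    clustered: set[int] = set()
    for key, (idx, gaps) in chrom_series.items():
        if gaps.size == 0:
            continue
        logg = np.log10(gaps.astype(float))
        if logg.size < 2:
            fitted = logg
        else:
            seg = exact_pcf(logg, gamma=gamma, kmin=1)
            fitted = seg.fitted(logg.size)
        for g in range(len(gaps)):
            if idx[g] != idx[g + 1] and fitted[g] <= cutoff:
                clustered.add(idx[g])
                clustered.add(idx[g + 1])
    return clustered


def build_sv32(
    svs: Sequence[SvRecord],
    cluster_gamma: float = 25.0,
    cluster_quantile: float = 0.1,
) -> np.ndarray:
    """Count SVs into the 32 rearrangement channels.

    Channels: {DEL, DUP, INV} x five size bins x {clustered, non-clustered}
    plus translocations (TRA, including inverted ones) split by clustering.
    COMPLEX calls have no channel and are skipped with a logged count.
    """
    index = {c: i for i, c in enumerate(SV32_CLASSES)}
    counts = np.zeros(32, dtype=np.int64)
    clustered = clustered_breakends(svs, gamma=cluster_gamma, quantile=cluster_quantile)
    skipped = 0
    for i, sv in enumerate(svs):
        prefix = "clustered" if i in clustered else "non-clustered"
        if sv.sv_type in (SvType.TRA, SvType.TRA_INV):
            counts[index[f"{prefix}_TRA"]] += 1
        elif sv.sv_type in (SvType.DEL, SvType.DUP, SvType.INV):
            if sv.size_bp is None:
                raise ValueError("intra-chromosomal SV missing size_bp")
            counts[index[f"{prefix}_{sv.sv_type.value}_{_size_label(sv.size_bp)}"]] += 1
        else:  # COMPLEX has no channel in the 32-class scheme
            skipped += 1
    if skipped:
        logger.info("build_sv32: skipped %d COMPLEX SVs (no channel)", skipped)
    return counts


@dataclass(frozen=True)
class ExposureVector:
    signatures: tuple[str, ...]
    exposures: np.ndarray
    reconstruction_cosine: float
    excluded: bool

    def as_dict(self) -> dict[str, float]:
        return {s: float(e) for s, e in zip(self.signatures, self.exposures)}


def read_signature_matrix(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    """Read a classes-x-signatures TSV; returns (class labels, names, matrix)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    return list(df.index), list(df.columns), df.to_numpy(dtype=float)


def fit_exposures(
    catalog: np.ndarray,
    signature_matrix: np.ndarray,
    signature_names: Sequence[str],
    cosine_cutoff: float = 0.5,
) -> ExposureVector:
    """Refit a catalog against reference signatures by non-negative least squares.

    Minimizes ||catalog - M @ e||_2 with e >= 0 and reports the cosine
    similarity between the catalog and its reconstruction; catalogs below
    ``cosine_cutoff`` are flagged excluded.
    """
    catalog = np.asarray(catalog, dtype=float)
    M = np.asarray(signature_matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] != catalog.size:
        raise ValueError(
            f"signature matrix has {M.shape[0] if M.ndim == 2 else '?'} rows, "
            f"catalog has {catalog.size} classes"
        )
    if M.shape[1] != len(signature_names):
        raise ValueError("signature_names length must match matrix columns")
    exposures, _ = nnls(M, catalog)
    recon = M @ exposures
    denom = np.linalg.norm(catalog) * np.linalg.norm(recon)
    cosine = float(catalog @ recon / denom) if denom > 0 else 0.0
    return ExposureVector(
        signatures=tuple(signature_names),
        exposures=exposures,
        reconstruction_cosine=cosine,
        excluded=cosine < cosine_cutoff,
    )


def apobec_summary(
    exposures_per_unit: Mapping[str, Mapping[str, float]],
    risk_by_unit: Mapping[str, str] | None = None,
) -> dict:
    """APOBEC (SBS2 + SBS13) attribution fractions per unit and cohort medians.

    For each unit (event or sample): ``apobec_fraction`` = (SBS2 + SBS13) /
    total exposure and ``sbs2_share`` = SBS2 / (SBS2 + SBS13) (None when the
    APOBEC total is 0). With a risk mapping, medians are reported per group.
    """
    per_unit: dict[str, dict] = {}
    for unit, expo in exposures_per_unit.items():
        total = sum(expo.values())
        apo = expo.get("SBS2", 0.0) + expo.get("SBS13", 0.0)
        per_unit[unit] = {
            "apobec_fraction": apo / total if total > 0 else 0.0,
            "sbs2_share": expo.get("SBS2", 0.0) / apo if apo > 0 else None,
        }
    out: dict = {"per_unit": per_unit}
    if risk_by_unit is not None:
        groups: dict[str, list[float]] = {}
        for unit, vals in per_unit.items():
            risk = risk_by_unit.get(unit)
            if risk is not None:
                groups.setdefault(risk, []).append(vals["apobec_fraction"])
        out["median_apobec_fraction_by_risk"] = {
            g: float(np.median(v)) for g, v in groups.items()
        }
    return out
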
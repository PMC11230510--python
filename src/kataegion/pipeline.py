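"""Staged pipeline: simulate -> call -> filter -> sv-enrich -> signatures -> assoc.

Plain directory-plus-manifest provenance: every stage reads and writes files
under one output directory; the manifest records parameter values and
content hashes of all inputs and outputs, and a rerun reuses a stage when
its inputs and parameters are unchanged.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .caller import KataegisCandidate, call_sample
from .filters import KataegisEvent, apply_filters
from .formats_io import (
    Epoch,
    GenomeMask,
    SnvRecord,
    SvRecord,
    read_snvs,
    read_svs,
    write_snvs,
    write_svs,
    read_clinical,
)
from .sv_proximity import (
    breakend_index,
    compute_distances,
    generate_matched_controls,
    proximity_enrichment,
)

logger = logging.getLogger(__name__)

EVENT_COLUMNS = (
    "sample_id", "chrom", "start", "end", "epoch", "n_snvs", "span_bp",
    "max_adjusted_imd", "sequential_pair", "type_consistent", "in_cis",
    "kept", "drop_reason", "members",
)

_KNOWN_KEYS = {
    "snvs", "svs", "mask", "clinical", "sbs96_reference", "out",
    "gamma", "kmin", "alpha", "genome_length", "max_threshold_bp",
    "filter_mode", "strict_consistency", "bands", "corr_cutoff",
    "seed", "max_events_per_sample", "risk_only", "stages",
    "sim",
}


@dataclass
class RunConfig:
    """Pipeline configuration; unknown keys in the YAML are rejected."""

    snvs: str | None = None
    svs: str | None = None
    mask: str | None = None
    clinical: str | None = None
    sbs96_reference: str | None = None
    out: str = "kataegion_out"
    gamma: float = 25.0
    kmin: int = 2
    alpha: float = 0.01
    genome_length: float = 3.1e9
    max_threshold_bp: float = 1000.0
    filter_mode: str = "phased"
    strict_consistency: bool = False
    bands: tuple[str, ...] = ("within_10kb", "band_0.1_to_10Mb")
    corr_cutoff: float = 0.6
    seed: int = 0
    max_events_per_sample: int = 40  # hyper-event outlier exclusion predicate
    risk_only: str | None = None  # e.g. "HR"
    stages: tuple[str, ...] = ("call", "filter", "sv_enrich", "signatures", "assoc")
    sim: dict | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.bands, list):
            cfg.bands = tuple(cfg.bands)
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        return cfg


def _member_str(s: SnvRecord) -> str:
    return "|".join(
        [str(s.pos), s.ref, s.alt, s.epoch.value, s.phase_group or ".", s.tricontext or "."]
    )


def _parse_member(sample: str, chrom: str, text: str) -> SnvRecord:
    pos, ref, alt, epoch, phase, ctx = text.split("|")
    return SnvRecord(
        sample_id=sample,
        chrom=chrom,
        pos=int(pos),
        ref=ref,
        alt=alt,
        epoch=Epoch(epoch),
        phase_group=None if phase == "." else phase,
        tricontext=None if ctx == "." else ctx,
    )


def write_events(events: Sequence, path: str | Path) -> None:
    """Write candidates or filtered events as a TSV with full member detail."""
    with open(path, "w") as fh:
        fh.write("\t".join(EVENT_COLUMNS) + "\n")
        for e in events:
            cand = e.candidate if isinstance(e, KataegisEvent) else e
            is_event = isinstance(e, KataegisEvent)
            fh.write(
                "\t".join(
                    [
                        cand.sample_id,
                        cand.chrom,
                        str(cand.start),
                        str(cand.end),
                        cand.epoch_tag,
                        str(cand.n_snvs),
                        str(cand.span_bp),
                        f"{cand.max_adjusted_imd:.4f}",
                        "1" if cand.sequential_pair else "0",
                        ("1" if e.type_consistent else "0") if is_event else ".",
                        ("1" if e.in_cis else "0") if is_event else ".",
                        ("1" if e.kept else "0") if is_event else ".",
                        (e.drop_reason or ".") if is_event else ".",
                        ",".join(_member_str(s) for s in cand.snvs),
                    ]
                )
                + "\n"
            )


def read_events(path: str | Path, kept_only: bool = False) -> list:
    """Read an events TSV back into candidates / filtered events."""
    out: list = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {h: i for i, h in enumerate(header)}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            sample, chrom = parts[idx["sample_id"]], parts[idx["chrom"]]
            members = tuple(
                _parse_member(sample, chrom, m) for m in parts[idx["members"]].split(",")
            )
            cand = KataegisCandidate(
                sample_id=sample,
                chrom=chrom,
                start=int(parts[idx["start"]]),
                end=int(parts[idx["end"]]),
                snvs=members,
                epoch_tag=parts[idx["epoch"]],
                max_adjusted_imd=float(parts[idx["max_adjusted_imd"]]),
                sequential_pair=parts[idx["sequential_pair"]] == "1",
            )
            if parts[idx["kept"]] == ".":
                obj = cand
                if kept_only:
                    raise ValueError(f"{path} holds unfiltered candidates; run filter first")
            else:
                obj = KataegisEvent(
                    candidate=cand,
                    type_consistent=parts[idx["type_consistent"]] == "1",
                    in_cis=parts[idx["in_cis"]] == "1",
                    kept=parts[idx["kept"]] == "1",
                    drop_reason=None if parts[idx["drop_reason"]] == "." else parts[idx["drop_reason"]],
                )
                if kept_only and not obj.kept:
                    continue
            out.append(obj)
    return out


def write_events_bed(events: Sequence, path: str | Path) -> None:
    """0-based half-open BED of event spans."""
    with open(path, "w") as fh:
        for e in events:
            cand = e.candidate if isinstance(e, KataegisEvent) else e
            name = f"{cand.sample_id}:{cand.epoch_tag}:{cand.n_snvs}"
            fh.write(f"{cand.chrom}\t{cand.start - 1}\t{cand.end}\t{name}\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data: dict = {"version": __version__, "stages": {}}
        if path.exists():
            with open(path) as fh:
                self.data = json.load(fh)

    def stage_fresh(self, name: str, inputs: dict[str, Path], params: dict) -> bool:
        prev = self.data.get("stages", {}).get(name)
        if not prev:
            return False
        cur_inputs = {str(k): _sha256(p) for k, p in inputs.items() if p.exists()}
        if prev.get("inputs") != cur_inputs or prev.get("params") != params:
            return False
        return all(
            Path(p).exists() and _sha256(Path(p)) == h
            for p, h in prev.get("outputs", {}).items()
        )

    def record(self, name: str, inputs: dict[str, Path], params: dict, outputs: list[Path]):
        self.data.setdefault("stages", {})[name] = {
            "inputs": {str(k): _sha256(p) for k, p in inputs.items() if p.exists()},
            "params": params,
            "outputs": {str(p): _sha256(p) for p in outputs},
        }
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)


def stage_simulate(cfg: RunConfig, outdir: Path) -> tuple[Path, Path, Path]:
    from .simulate import SimConfig, simulate_cohort

    sim_cfg = SimConfig(**(cfg.sim or {}))
    snvs_by_sample, svs_by_sample, truth = simulate_cohort(sim_cfg, cfg.seed)
    snv_path, sv_path, truth_path = (
        outdir / "snvs.tsv", outdir / "svs.bedpe", outdir / "truth.tsv",
    )
    all_snvs = [s for sample in sorted(snvs_by_sample) for s in snvs_by_sample[sample]]
    write_snvs(all_snvs, snv_path)
    write_svs([v for sample in sorted(svs_by_sample) for v in svs_by_sample[sample]], sv_path)
    with open(truth_path, "w") as fh:
        fh.write("sample_id\tchrom\tstart\tend\tn_snvs\tepoch\tsv_linked\t"
                 "distance_to_sv\tpositions\n")
        for t in truth:
            fh.write(
                f"{t.sample_id}\t{t.chrom}\t{t.start}\t{t.end}\t{t.n_snvs}\t{t.epoch}\t"
                f"{int(t.sv_linked)}\t{t.distance_to_sv if t.distance_to_sv is not None else '.'}\t"
                + ",".join(map(str, t.positions)) + "\n"
            )
    return snv_path, sv_path, truth_path


def stage_call(cfg: RunConfig, outdir: Path, snv_path: Path) -> Path:
    snvs = read_snvs(snv_path, dialect="vcf" if str(snv_path).endswith(".vcf") else "tsv")
    genome_length = cfg.genome_length
    if cfg.mask:
        genome_length -= GenomeMask.from_bed(cfg.mask).total_length()
    by_sample: dict[str, list[SnvRecord]] = {}
    for s in snvs:
        by_sample.setdefault(s.sample_id, []).append(s)
    candidates: list[KataegisCandidate] = []
    for sample in sorted(by_sample):
        candidates.extend(
            call_sample(
                by_sample[sample],
                gamma=cfg.gamma,
                kmin=cfg.kmin,
                genome_length=genome_length,
                alpha=cfg.alpha,
                max_threshold_bp=cfg.max_threshold_bp,
            )
        )
    path = outdir / "candidates.tsv"
    write_events(candidates, path)
    return path


def stage_filter(cfg: RunConfig, outdir: Path, candidates_path: Path) -> Path:
    candidates = read_events(candidates_path)
    events, ledger = apply_filters(
        candidates, mode=cfg.filter_mode, strict_consistency=cfg.strict_consistency
    )
    path = outdir / "events.tsv"
    write_events(events, path)
    write_events_bed([e for e in events if e.kept], outdir / "events.bed")
    with open(outdir / "filter_ledger.json", "w") as fh:
        json.dump({"input": len(candidates), "kept": sum(e.kept for e in events),
                   "dropped": ledger}, fh, indent=2)
    return path


def _select_events(cfg: RunConfig, events: list) -> list:
    """Cohort selection predicates: risk restriction and outlier exclusion."""
    out = events
    if cfg.risk_only and cfg.clinical:
        risk = {r.sample_id: r.risk for r in read_clinical(cfg.clinical)}
        out = [e for e in out if risk.get(e.sample_id) == cfg.risk_only]
    per_sample: dict[str, int] = {}
    for e in out:
        per_sample[e.sample_id] = per_sample.get(e.sample_id, 0) + 1
    outliers = {s for s, n in per_sample.items() if n > cfg.max_events_per_sample}
    if outliers:
        logger.info("excluding hyper-event outlier samples: %s", sorted(outliers))
    return [e for e in out if e.sample_id not in outliers]


def stage_sv_enrich(cfg: RunConfig, outdir: Path, events_path: Path,
                    sv_path: Path, snv_path: Path) -> Path:
    events = _select_events(cfg, read_events(events_path, kept_only=True))
    if not events:
        raise ValueError("no kept events to test for SV proximity")
    svs = read_svs(sv_path)
    snvs = read_snvs(snv_path, dialect="tsv")
    mask = GenomeMask.from_bed(cfg.mask) if cfg.mask else None
    index = breakend_index(svs)
    obs = compute_distances(events, index)
    controls = generate_matched_controls(events, snvs, mask, cfg.seed)
    ctrl = compute_distances(controls, index)
    with open(outdir / "event_distances.tsv", "w") as fh:
        fh.write("event_id\tsample_id\tepoch\tnearest_distance_bp\tnearest_sv_type\n")
        for r in obs:
            fh.write(
                f"{r.event_id}\t{r.sample_id}\t{r.epoch_tag or '.'}\t"
                f"{r.nearest_distance_bp if r.nearest_distance_bp is not None else '.'}\t"
                f"{r.nearest_sv_type or '.'}\n"
            )
    path = outdir / "enrichment.tsv"
    with open(path, "w") as fh:
        fh.write("band\tobserved_near\tobserved_far\tcontrol_near\tcontrol_far\t"
                 "odds_ratio\tp_value\n")
        for band in cfg.bands:
            t = proximity_enrichment(
                [r.nearest_distance_bp for r in obs],
                [r.nearest_distance_bp for r in ctrl],
                band=band,
            )
            fh.write(f"{t.band}\t{t.observed_near}\t{t.observed_far}\t{t.control_near}\t"
                     f"{t.control_far}\t{t.odds_ratio:.6g}\t{t.p_value:.6g}\n")
    return path


def stage_signatures(cfg: RunConfig, outdir: Path, events_path: Path) -> Path:
    from .signatures import build_sbs96, fit_exposures, read_signature_matrix, apobec_summary

    if not cfg.sbs96_reference:
        raise ValueError("signatures stage needs sbs96_reference in the config")
    _, names, M = read_signature_matrix(cfg.sbs96_reference)
    events = read_events(events_path, kept_only=True)
    by_sample: dict[str, list] = {}
    for e in events:
        by_sample.setdefault(e.sample_id, []).extend(e.snvs)
    path = outdir / "exposures.tsv"
    exposures_per_sample: dict[str, dict[str, float]] = {}
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(names) + "\tcosine\texcluded\n")
        for sample in sorted(by_sample):
            catalog = build_sbs96(by_sample[sample])
            ev = fit_exposures(catalog, M, names)
            exposures_per_sample[sample] = ev.as_dict()
            fh.write(
                sample + "\t" + "\t".join(f"{x:.4f}" for x in ev.exposures)
                + f"\t{ev.reconstruction_cosine:.4f}\t{int(ev.excluded)}\n"
            )
    with open(outdir / "apobec_summary.json", "w") as fh:
        json.dump(apobec_summary(exposures_per_sample), fh, indent=2)
    return path


def stage_assoc(cfg: RunConfig, outdir: Path, events_path: Path) -> Path:
    from .assoc import stepwise_glm
    import pandas as pd

    if not cfg.clinical:
        raise ValueError("assoc stage needs a clinical table in the config")
    clinical = read_clinical(cfg.clinical)
    events = read_events(events_path, kept_only=True)
    burden: dict[str, int] = {}
    for e in events:
        burden[e.sample_id] = burden.get(e.sample_id, 0) + 1
    rows = []
    for r in clinical:
        rows.append(
            {
                "sample_id": r.sample_id,
                "presence": int(burden.get(r.sample_id, 0) > 0),
                "burden": burden.get(r.sample_id, 0),
                "age_years": r.age_years,
                "risk_hr": None if r.risk is None else int(r.risk == "HR"),
                "ancestry": r.ancestry,
                "sv_burden": r.sv_burden,
                "cnv_gain_bp": r.cnv_gain_bp,
                "cnv_loss_bp": r.cnv_loss_bp,
                "telomere_blood": r.telomere_blood,
                "telomere_tumour": r.telomere_tumour,
            }
        )
    df = pd.DataFrame(rows)
    covs = ["age_years", "risk_hr", "sv_burden", "ancestry", "cnv_gain_bp",
            "cnv_loss_bp", "telomere_blood", "telomere_tumour"]
    covs = [c for c in covs if df[c].notna().any()]
    results = {}
    for response, family, transforms in (
        ("presence", "logistic", None),
        ("burden", "negative_binomial", {"sv_burden": "log", "cnv_loss_bp": "log"}),
    ):
        res = stepwise_glm(df, response, covs, family=family,
                           transforms=transforms, corr_cutoff=cfg.corr_cutoff)
        results[response] = {
            "selected": res.selected,
            "params": res.params,
            "pvalues": res.pvalues,
            "ratios": res.ratios,
            "aic": res.aic,
            "trace": res.trace,
            "excluded_correlated": res.excluded_correlated,
            "n_dropped_incomplete": res.n_dropped_incomplete,
        }
    path = outdir / "assoc_models.json"
    with open(path, "w") as fh:
        json.dump(results, fh, indent=2)
    return path


def run_pipeline(cfg: RunConfig) -> Path:
    """Run the configured stages; reuses stage outputs when hashes match."""
    outdir = Path(cfg.out)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(outdir / "manifest.json")
    params_base = {k: v for k, v in asdict(cfg).items() if k not in ("out",)}

    if cfg.sim is not None:
        snv_path, sv_path, _ = stage_simulate(cfg, outdir)
    else:
        if not cfg.snvs:
            raise ValueError("config needs either 'snvs' or a 'sim' block")
        snv_path = Path(cfg.snvs)
        sv_path = Path(cfg.svs) if cfg.svs else None

    def run_stage(name, inputs: dict[str, Path], fn):
        params = {**params_base, "stage": name}
        if manifest.stage_fresh(name, inputs, params):
            logger.info("stage %s: unchanged, reusing outputs", name)
            prev = manifest.data["stages"][name]["outputs"]
            return Path(next(iter(prev)))
        try:
            out = fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name} failed: {exc}") from exc
        manifest.record(name, inputs, params, [out])
        return out

    candidates_path = events_path = None
    if "call" in cfg.stages:
        candidates_path = run_stage(
            "call", {"snvs": snv_path}, lambda: stage_call(cfg, outdir, snv_path)
        )
    if "filter" in cfg.stages:
        events_path = run_stage(
            "filter", {"candidates": candidates_path},
            lambda: stage_filter(cfg, outdir, candidates_path),
        )
    if "sv_enrich" in cfg.stages and sv_path is not None:
        run_stage(
            "sv_enrich",
            {"events": events_path, "svs": sv_path, "snvs": snv_path},
            lambda: stage_sv_enrich(cfg, outdir, events_path, sv_path, snv_path),
        )
    if "signatures" in cfg.stages and cfg.sbs96_reference:
        run_stage(
            "signatures",
            {"events": events_path, "reference": Path(cfg.sbs96_reference)},
            lambda: stage_signatures(cfg, outdir, events_path),
        )
    if "assoc" in cfg.stages and cfg.clinical:
        run_stage(
            "assoc", {"events": events_path, "clinical": Path(cfg.clinical)},
            lambda: stage_assoc(cfg, outdir, events_path),
        )
    with open(outdir / "run.log", "a") as fh:
        fh.write(json.dumps({"version": __version__, "seed": cfg.seed,
                             "params": params_base}, sort_keys=True) + "\n")
    return outdir
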
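import numpy as np
import pytest

from kataegion.caller import (
    burden_threshold,
    build_epoch_subsets,
    call_candidates,
    call_sample,
    dedup_early_late,
)
from kataegion.formats_io import Epoch

from .conftest import make_snv


class TestEpochSubsets:
    def test_all_unknown_fills_all_subsets(self):
        snvs = [make_snv(100 * i + 100) for i in range(5)]
        subsets = build_epoch_subsets(snvs)
        for tag in ("early", "late", "subclonal"):
            assert len(subsets[tag]) == 5

    def test_membership_rules(self):
        snvs = [
            make_snv(100, epoch=Epoch.EARLY_CLONAL),
            make_snv(200, epoch=Epoch.EARLY_CLONAL),
            make_snv(300, epoch=Epoch.CLONAL_UNSPECIFIED),
            make_snv(400, epoch=Epoch.SUBCLONAL),
        ]
        subsets = build_epoch_subsets(snvs)
        assert len(subsets["early"]) == 3
        assert len(subsets["late"]) == 1
        assert len(subsets["subclonal"]) == 1

    def test_empty_input(self):
        subsets = build_epoch_subsets([])
        assert all(len(s) == 0 for s in subsets.values())

    def test_subsets_sorted(self):
        snvs = [make_snv(500), make_snv(100), make_snv(300, chrom="chr2")]
        subsets = build_epoch_subsets(snvs)
        pos = [(s.chrom, s.pos) for s in subsets["early"].snvs]
        assert pos == sorted(pos)


class TestBurdenThreshold:
    def test_capped_at_1kb(self):
        # closed form: d* = (alpha/n)^(1/3) / lambda ~= 1230 bp > cap
        assert burden_threshold(20_000, 3.1e9, 0.01) == 1000.0

    def test_exact_closed_form_below_cap(self):
        n, G, alpha = 200_000, 3.1e9, 0.01
        lam = n / G
        expected = (alpha / n) ** (1 / 3) / lam
        assert expected < 1000
        assert burden_threshold(n, G, alpha) == pytest.approx(expected)

    def test_sparse_fallback(self):
        assert burden_threshold(0) == 1000.0
        assert burden_threshold(3) == 1000.0

    def test_monotone_in_n(self):
        thresholds = [burden_threshold(n, 3.1e9, 0.01) for n in (10, 100, 10_000, 1_000_000)]
        assert thresholds == sorted(thresholds, reverse=True)

    def test_validation(self):
        with pytest.raises(ValueError):
            burden_threshold(-1)
        with pytest.raises(ValueError):
            burden_threshold(10, genome_length=0)
        with pytest.raises(ValueError):
            burden_threshold(10, alpha=1.5)


def _sparse_background(rng, n, lo=1, hi=3_000_000_000):
    return sorted(int(p) for p in rng.choice(np.arange(lo, hi, 997), size=n, replace=False))


class TestCallCandidates:
    def test_three_snvs_no_candidate(self):
        snvs = [make_snv(5_000_000 + 100 * i) for i in range(3)]
        snvs += [make_snv(100_000), make_snv(9_000_000)]
        subsets = build_epoch_subsets(snvs)
        assert call_candidates(subsets["early"]) == []

    def test_planted_six_snv_cluster_found(self, rng):
        # 6 SNVs spaced 100 bp inside ~1 SNV/Mb background (n=3000, G=3e9)
        background = _sparse_background(rng, 3000)
        cluster = [1_500_000_000 + 100 * i for i in range(6)]
        snvs = [make_snv(p) for p in sorted(set(background) | set(cluster))]
        subsets = build_epoch_subsets(snvs)
        cands = call_candidates(subsets["early"], genome_length=3e9)
        assert len(cands) == 1
        assert cands[0].n_snvs == 6
        assert cands[0].start == cluster[0] and cands[0].end == cluster[-1]
        assert cands[0].max_adjusted_imd < 1000

    def test_empty_subset(self):
        subsets = build_epoch_subsets([])
        assert call_candidates(subsets["early"]) == []

    def test_all_candidates_satisfy_invariants(self, rng):
        background = _sparse_background(rng, 2000)
        clusters = []
        for start in (500_000_000, 1_000_000_000, 2_000_000_000):
            clusters += [start + 150 * i for i in range(8)]
        snvs = [make_snv(p) for p in sorted(set(background) | set(clusters))]
        subsets = build_epoch_subsets(snvs)
        cands = call_candidates(subsets["early"], genome_length=3e9)
        assert len(cands) == 3
        for c in cands:
            assert c.n_snvs >= 4
            assert c.max_adjusted_imd < 1000
            positions = [s.pos for s in c.snvs]
            assert positions == sorted(positions)
        # non-overlapping within the subset
        spans = sorted((c.start, c.end) for c in cands)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2

    def test_translation_invariance(self, rng):
        background = _sparse_background(rng, 1000, hi=100_000_000)
        cluster = [50_000_001 + 120 * i for i in range(6)]
        snvs = [make_snv(p) for p in sorted(set(background) | set(cluster))]
        shifted = [make_snv(s.pos + 12_345) for s in snvs]
        c1 = call_candidates(build_epoch_subsets(snvs)["early"], genome_length=3e9)
        c2 = call_candidates(build_epoch_subsets(shifted)["early"], genome_length=3e9)
        assert [(c.n_snvs, c.end - c.start) for c in c1] == [
            (c.n_snvs, c.end - c.start) for c in c2
        ]

    def test_determinism(self, rng):
        background = _sparse_background(rng, 1500)
        cluster = [750_000_000 + 90 * i for i in range(7)]
        snvs = [make_snv(p) for p in sorted(set(background) | set(cluster))]
        subsets = build_epoch_subsets(snvs)
        a = call_candidates(subsets["early"], genome_length=3e9)
        b = call_candidates(subsets["early"], genome_length=3e9)
        assert a == b

    def test_duplicate_positions_collapsed(self, rng):
        background = _sparse_background(rng, 1000)
        cluster = [900_000_000 + 100 * i for i in range(6)]
        snvs = [make_snv(p) for p in sorted(set(background) | set(cluster))]
        snvs += [make_snv(cluster[0], ref="T", alt="A")]  # duplicate position
        subsets = build_epoch_subsets(sorted(snvs, key=lambda s: (s.chrom, s.pos)))
        cands = call_candidates(subsets["early"], genome_length=3e9)
        assert len(cands) == 1 and cands[0].n_snvs == 6


def _candidate(positions, epoch_tag, epochs=None):
    epochs = epochs or [Epoch.CLONAL_UNSPECIFIED] * len(positions)
    snvs = tuple(make_snv(p, epoch=e) for p, e in zip(positions, epochs))
    from kataegion.caller import KataegisCandidate

    return KataegisCandidate(
        sample_id="S0",
        chrom="chr1",
        start=positions[0],
        end=positions[-1],
        snvs=snvs,
        epoch_tag=epoch_tag,
        max_adjusted_imd=100.0,
    )


class TestDedupEarlyLate:
    def test_shared_unspecified_keeps_larger(self):
        shared = [1000, 1100, 1200, 1300]
        early = _candidate(shared + [1400, 1500], "early")
        late = _candidate(shared, "late")
        merged = dedup_early_late([early], [late])
        assert len(merged) == 1
        assert merged[0].epoch_tag == "early"

    def test_larger_late_wins(self):
        shared = [1000, 1100, 1200, 1300]
        early = _candidate(shared, "early")
        late = _candidate(shared + [1400, 1500], "late")
        merged = dedup_early_late([early], [late])
        assert len(merged) == 1 and merged[0].epoch_tag == "late"

    def test_tie_keeps_early(self):
        shared = [1000, 1100, 1200, 1300, 1400]
        early = _candidate(shared, "early")
        late = _candidate(shared, "late")
        merged = dedup_early_late([early], [late])
        assert len(merged) == 1 and merged[0].epoch_tag == "early"

    def test_disjoint_candidates_union(self):
        early = _candidate([1000, 1100, 1200, 1300], "early")
        late = _candidate([900_000, 900_100, 900_200, 900_300], "late")
        merged = dedup_early_late([early], [late])
        assert len(merged) == 2

    def test_overlapping_but_no_shared_snv_flagged_sequential(self):
        early = _candidate(
            [1000, 1100, 1200, 1300], "early", epochs=[Epoch.EARLY_CLONAL] * 4
        )
        late = _candidate(
            [1050, 1150, 1250, 1350], "late", epochs=[Epoch.LATE_CLONAL] * 4
        )
        merged = dedup_early_late([early], [late])
        assert len(merged) == 2
        assert all(c.sequential_pair for c in merged)


class TestCallSample:
    def test_epoch_specific_events_called_once(self, rng):
        background = [
            make_snv(p, epoch=Epoch.UNKNOWN)
            for p in _sparse_background(rng, 1000, hi=2_000_000_000)
        ]
        cluster = [
            make_snv(1_000_000_007 + 100 * i, epoch=Epoch.SUBCLONAL) for i in range(6)
        ]
        merged = call_sample(
            sorted(background + cluster, key=lambda s: (s.chrom, s.pos)),
            genome_length=3e9,
        )
        sub_events = [c for c in merged if c.epoch_tag == "subclonal"]
        assert len(sub_events) == 1
        assert sub_events[0].n_snvs == 6
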
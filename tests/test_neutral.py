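import numpy as np
import pytest

import adaptiphy as ap
from adaptiphy.alignio import FeatureSet, NucAlignment, Region, mask_features
from adaptiphy.neutral import (
    NFRWindow,
    NoLocalProxyError,
    ReferencePool,
    build_pool,
    build_reference,
    draw_nfr_windows,
    filter_min_rate,
    interquartile_filter,
    local_reference,
)

SPECIES = ["human", "chimp", "gorilla", "orangutan", "macaque"]


def _synthetic_window(rel_human, start=0, length=300, chrom="chr1", rng=None):
    """A window with a prescribed foreground relative rate (no fitting)."""
    rng = rng or np.random.default_rng(start)
    seqs = ["".join(rng.choice(list("ACGT"), length)) for _ in SPECIES]
    aln = NucAlignment(
        list(SPECIES), seqs, coord=Region(chrom, start, start + length),
        ref_species="human",
    )
    rest = (1.0 - rel_human) / 7
    rel = {"human": rel_human}
    for i, name in enumerate(
        ["chimp", "gorilla", "orangutan", "macaque",
         "chimp+human", "chimp+gorilla+human",
         "chimp+gorilla+human+orangutan"]
    ):
        rel[name] = rest
    return NFRWindow(aln, fit=None, rel=rel)


@pytest.fixture(scope="module")
def genome_alignment(primate_tree, sim_model):
    """A 3 kb simulated 'chromosome' with genomic coordinates."""
    aln = ap.simulate_alignment(primate_tree, sim_model, 3000, seed=31)
    aln.coord = Region("chr1", 0, 3000)
    aln.ref_species = "human"
    return aln


class TestDrawWindows:
    def test_fully_masked_chromosome_yields_nothing(self, genome_alignment,
                                                    primate_tree):
        masked = mask_features(genome_alignment, FeatureSet({("chr1", 0, 3000)}))
        assert draw_nfr_windows(masked, primate_tree, fit=False) == []

    def test_unmasked_3kb_gives_at_most_ten_disjoint_windows(
        self, genome_alignment, primate_tree
    ):
        windows = draw_nfr_windows(genome_alignment, primate_tree, seed=1,
                                   fit=False)
        assert 1 <= len(windows) <= 10
        spans = sorted((w.coord.start, w.coord.end) for w in windows)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_same_seed_identical_windows(self, genome_alignment, primate_tree):
        a = draw_nfr_windows(genome_alignment, primate_tree, seed=5, fit=False)
        b = draw_nfr_windows(genome_alignment, primate_tree, seed=5, fit=False)
        assert [w.coord for w in a] == [w.coord for w in b]

    def test_windows_touching_masked_columns_are_excluded(
        self, genome_alignment, primate_tree
    ):
        masked = mask_features(
            genome_alignment, FeatureSet({("chr1", 1000, 1001)})
        )
        windows = draw_nfr_windows(masked, primate_tree, seed=2, fit=False)
        for w in windows:
            assert not (w.coord.start <= 1000 < w.coord.end)
            assert "N" not in w.aln.get("human")

    def test_fitted_windows_carry_relative_rates(self, genome_alignment,
                                                 primate_tree):
        windows = draw_nfr_windows(genome_alignment, primate_tree, seed=3,
                                   max_n=2)
        for w in windows:
            assert w.rel is not None
            assert sum(w.rel.values()) == pytest.approx(1.0)


class TestFilterMinRate:
    def test_window_below_floor_on_any_branch_removed(self):
        windows = [_synthetic_window(0.1)]
        windows[0].rel["gorilla"] = 0.0005
        assert filter_min_rate(windows, floor=0.001) == []

    def test_all_branches_at_or_above_floor_kept(self):
        windows = [_synthetic_window(0.1)]
        assert filter_min_rate(windows, floor=0.001) == windows

    def test_zero_floor_is_identity(self):
        windows = [_synthetic_window(v) for v in (0.01, 0.2, 0.5)]
        assert filter_min_rate(windows, floor=0.0) == windows

    def test_foreground_only_mode_checks_one_branch(self):
        w = _synthetic_window(0.1)
        w.rel["gorilla"] = 0.0001
        assert filter_min_rate([w], floor=0.001, foreground_only="human") == [w]


class TestInterquartileFilter:
    def test_hundred_distinct_values_keep_exactly_fifty(self):
        values = np.linspace(0.01, 0.5, 100)
        windows = [_synthetic_window(float(v), start=i * 300)
                   for i, v in enumerate(values)]
        kept = interquartile_filter(windows, "human")
        assert len(kept) == 50
        kept_vals = sorted(w.rel["human"] for w in kept)
        assert kept_vals == sorted(values[25:75].tolist())

    def test_identical_values_all_survive(self):
        windows = [_synthetic_window(0.1, start=i * 300) for i in range(8)]
        assert len(interquartile_filter(windows, "human")) == 8

    def test_one_to_eight_keeps_three_to_six(self):
        # type-7 quartiles of 1..8 are 2.75 and 6.25; inclusive band keeps 3..6
        windows = [_synthetic_window(v / 10, start=i * 300)
                   for i, v in enumerate(range(1, 9))]
        kept = interquartile_filter(windows, "human")
        assert sorted(round(w.rel["human"] * 10) for w in kept) == [3, 4, 5, 6]

    def test_fewer_than_four_windows_rejected(self):
        with pytest.raises(ValueError):
            interquartile_filter([_synthetic_window(0.1)] * 3, "human")

    def test_output_range_within_input_iqr(self):
        rng = np.random.default_rng(12)
        vals = rng.uniform(0.01, 0.6, size=60)
        windows = [_synthetic_window(float(v), start=i * 300)
                   for i, v in enumerate(vals)]
        kept = interquartile_filter(windows, "human")
        kept_vals = [w.rel["human"] for w in kept]
        q1, q3 = np.quantile(vals, [0.25, 0.75])
        assert max(kept_vals) - min(kept_vals) <= q3 - q1 + 1e-12


class TestBuildReference:
    def _pool(self, n=20):
        windows = [_synthetic_window(0.05 + 0.01 * i, start=i * 400)
                   for i in range(n)]
        return ReferencePool(windows)

    def test_k_windows_concatenate_to_k_times_length(self):
        ref = build_reference(self._pool(), k=10, seed=1)
        assert ref.length == 3000
        assert len(ref.meta["segments"]) == 10

    def test_k_one_returns_single_window_content(self):
        pool = self._pool(5)
        ref = build_reference(pool, k=1, seed=2)
        assert any(ref.seqs == w.aln.seqs for w in pool.windows)

    def test_same_seed_same_reference(self):
        a = build_reference(self._pool(), k=5, seed=3)
        b = build_reference(self._pool(), k=5, seed=3)
        assert a.seqs == b.seqs

    def test_pool_smaller_than_k_rejected(self):
        with pytest.raises(ValueError):
            build_reference(self._pool(4), k=10)

    def test_reference_contains_no_masked_characters(self):
        ref = build_reference(self._pool(), k=10, seed=4)
        assert all("N" not in s for s in ref.seqs)


class TestLocalReference:
    def _pool(self):
        return ReferencePool([
            _synthetic_window(0.1, start=10_000),
            _synthetic_window(0.1, start=60_000),
            _synthetic_window(0.1, start=200_000),
        ])

    def test_windows_within_radius_are_concatenated(self):
        query = Region("chr1", 49_850, 50_150)
        ref = local_reference(query, self._pool(), radius=100_000)
        assert ref.length == 600  # windows at 10k and 60k

    def test_zero_radius_signals_no_proxy(self):
        with pytest.raises(NoLocalProxyError):
            local_reference(Region("chr1", 49_850, 50_150), self._pool(),
                            radius=0)

    def test_all_windows_in_radius_sum_lengths(self):
        query = Region("chr1", 99_850, 100_150)
        ref = local_reference(query, self._pool(), radius=150_000)
        assert ref.length == 900

    def test_other_chromosome_not_local(self):
        pool = ReferencePool([_synthetic_window(0.1, start=50_000,
                                                chrom="chr2")])
        with pytest.raises(NoLocalProxyError):
            local_reference(Region("chr1", 49_000, 51_000), pool,
                            radius=1_000_000)


class TestBuildPool:
    def test_stage_counts_are_recorded_and_nonincreasing(self):
        rng = np.random.default_rng(3)
        windows = [_synthetic_window(float(v), start=i * 400, rng=rng)
                   for i, v in enumerate(np.linspace(0.02, 0.4, 40))]
        windows[0].rel["gorilla"] = 0.0001  # planted sub-floor window
        pool = build_pool(windows, "human")
        stages = pool.provenance
        assert stages["min_rate"]["out"] == stages["fitted"]["out"] - 1
        ns = [stages[s]["out"] for s in ("fitted", "min_rate", "interquartile")]
        assert ns == sorted(ns, reverse=True)
        assert len(pool) == ns[-1]
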
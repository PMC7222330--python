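"""Sliding-window scans and batch testing of BED-listed query sets."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .alignio import (
    EmptyAlignmentError,
    FeatureSet,
    NucAlignment,
    Region,
)
from .neutral import ReferencePool, build_reference
from .selection import SelectionResult, TestConfig, test_selection

logger = logging.getLogger("adaptiphy")

__all__ = ["WindowResult", "make_windows", "scan_region", "batch_test"]


@dataclass
class WindowResult:
    """A selection-test outcome pinned to a genomic window."""

    interval: Region
    result: Optional[SelectionResult]
    skipped: str = ""

    @property
    def flag_significant(self) -> bool:
        return self.result is not None and self.result.p < 0.05

    def row(self) -> dict:
        out = {
            "chrom": self.interval.chrom,
            "start": self.interval.start,
            "end": self.interval.end,
        }
        if self.result is None:
            out.update({k: np.nan for k in
                        ("lnL_null", "lnL_alt", "LRT", "p", "zeta")})
            out["skipped"] = self.skipped
        else:
            out.update(self.result.row())
            out["skipped"] = ""
        return out


def make_windows(region: Region, size: int = 300, step: int = 150) -> list[Region]:
    """Half-open windows from region.start, advancing by ``step``; the
    last window is truncated at region.end.

    For a region of length L >= size the count is ceil((L - size)/step) + 1.
    """
    if not 1 <= step <= size:
        raise ValueError("require size >= step >= 1")
    if len(region) < size:
        logger.warning("region shorter than one window; emitting truncated window")
        return [region]
    windows = []
    start = region.start
    while start < region.end:
        end = min(start + size, region.end)
        windows.append(Region(region.chrom, start, end))
        if end == region.end:
            break
        start += step
    return windows


def _reference_for(pool_or_aln, n_references, rng) -> list[NucAlignment]:
    if isinstance(pool_or_aln, NucAlignment):
        return [pool_or_aln]
    if isinstance(pool_or_aln, ReferencePool):
        return [build_reference(pool_or_aln, seed=rng) for _ in range(n_references)]
    raise TypeError("expected a NucAlignment or ReferencePool")


def _window_seed(base: int, interval: Region, ref_idx: int) -> int:
    """Seed derived from coordinates so identical intervals reproduce."""
    ss = np.random.SeedSequence([base, interval.start, interval.end, ref_idx])
    return int(ss.generate_state(1)[0] % 2**31)


def _test_against_references(query, references, foreground, config, base_seed,
                             interval):
    """Median-p aggregation across references; per-reference results kept."""
    results = []
    for ref_idx, ref in enumerate(references):
        cfg_seed = _window_seed(base_seed, interval, ref_idx)
        cfg = TestConfig(
            topology=config.topology, foreground=foreground,
            family=config.family, n_restarts=config.n_restarts,
            seed=cfg_seed, mode=config.mode,
            min_query_len=config.min_query_len, min_ref_len=config.min_ref_len,
        )
        results.append(test_selection(query, ref, foreground, cfg))
    results.sort(key=lambda r: r.p)
    median = results[(len(results) - 1) // 2]
    return median, results


def scan_region(
    aln_source: NucAlignment,
    region: Region,
    reference_pool,
    foreground: str = "human",
    config: Optional[TestConfig] = None,
    size: int = 300,
    step: int = 150,
    n_references: int = 1,
    max_missing: float = 0.5,
    seed=None,
) -> list[WindowResult]:
    """Run the selection test in sliding windows across a region.

    Windows with insufficient alignment coverage or too much missing data
    are skipped (recorded, not dropped). Queries are allowed to overlap
    functional features — only references must be non-functional.
    """
    config = config or TestConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    references = _reference_for(reference_pool, n_references, rng)
    base_seed = int(rng.integers(2**31))
    out: list[WindowResult] = []
    for window in make_windows(region, size, step):
        try:
            sub = aln_source.subregion(window.start, window.end)
        except EmptyAlignmentError:
            out.append(WindowResult(window, None, skipped="no_coverage"))
            continue
        worst = max(sub.missing_fractions().values())
        if worst > max_missing:
            out.append(WindowResult(window, None, skipped="missing_data"))
            continue
        if sub.length < config.min_query_len:
            out.append(WindowResult(window, None, skipped="too_short"))
            continue
        sub.meta["id"] = f"{window.chrom}:{window.start}-{window.end}"
        median, _ = _test_against_references(
            sub, references, foreground, config, base_seed, window
        )
        out.append(WindowResult(window, median))
    return out


def _recenter(interval: Region, length: int) -> Region:
    """Fixed-length interval centered on the input's midpoint."""
    mid = interval.midpoint
    start = max(0, mid - length // 2)
    return Region(interval.chrom, start, start + length)


def batch_test(
    queries: Sequence[Region] | FeatureSet,
    aln_source: NucAlignment,
    reference_pool,
    foreground: str = "human",
    config: Optional[TestConfig] = None,
    center_len: Optional[int] = 300,
    n_references: int = 1,
    bh_adjust: bool = False,
    max_missing: float = 0.5,
    seed=None,
) -> pd.DataFrame:
    """Test a list of BED intervals; one output row per input interval.

    Intervals are re-centered to ``center_len`` (default 300 bp) so query
    length is uniform; intervals without alignment coverage are emitted
    as NA rows. ``bh_adjust`` appends Benjamini-Hochberg q-values.
    """
    if isinstance(queries, FeatureSet):
        queries = [Region(c, s, e) for c, s, e in sorted(queries.intervals)]
    config = config or TestConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    references = _reference_for(reference_pool, n_references, rng)
    base_seed = int(rng.integers(2**31))
    rows = []
    for interval in queries:
        target = _recenter(interval, center_len) if center_len else interval
        wr: WindowResult
        try:
            sub = aln_source.subregion(target.start, target.end)
            worst = max(sub.missing_fractions().values())
            if worst > max_missing:
                wr = WindowResult(target, None, skipped="missing_data")
            else:
                sub.meta["id"] = f"{target.chrom}:{target.start}-{target.end}"
                median, _ = _test_against_references(
                    sub, references, foreground, config, base_seed, target
                )
                wr = WindowResult(target, median)
        except EmptyAlignmentError:
            wr = WindowResult(target, None, skipped="no_coverage")
        row = wr.row()
        row["input_start"] = interval.start
        row["input_end"] = interval.end
        rows.append(row)
    df = pd.DataFrame(rows)
    if bh_adjust and len(df):
        df["q"] = _bh_qvalues(df["p"].to_numpy())
    return df


def _bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (NaNs passed through)."""
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    ps = p[ok]
    m = ps.size
    if m == 0:
        return q
    order = np.argsort(ps)
    ranked = ps[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0, 1)
    q[ok] = out
    return q
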
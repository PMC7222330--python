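"""Building filtered, concatenated proxy-neutral reference alignments.

Candidate windows (default 300 bp) are drawn without overlap from the
non-functional, feature-masked fraction of a genome alignment; windows
touching any masked column or with too much missing data are discarded.
Each survivor is fitted for branch lengths, then two filters run in
order: (1) drop windows where any branch's relative branch length falls
below a floor (near-zero rates signal alignment problems or hidden
constraint), and (2) keep only windows whose foreground relative branch
length lies within the pool's interquartile range, which narrows the
rate distribution the references are drawn from and sets the test's
conservativeness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .alignio import NucAlignment, Region, EmptyAlignmentError
from .phylo import TreeModel, fit_tree_model
from .tree import PhyloTree

logger = logging.getLogger("adaptiphy")

__all__ = [
    "NFRWindow",
    "ReferencePool",
    "NoLocalProxyError",
    "draw_nfr_windows",
    "filter_min_rate",
    "interquartile_filter",
    "build_reference",
    "local_reference",
]


class NoLocalProxyError(LookupError):
    """No candidate neutral windows near the query."""


@dataclass
class NFRWindow:
    """One candidate neutral window with its fitted tree."""

    aln: NucAlignment
    fit: Optional[TreeModel] = None
    rel: Optional[dict[str, float]] = None
    missing_frac: float = 0.0

    @property
    def coord(self) -> Optional[Region]:
        return self.aln.coord


@dataclass
class ReferencePool:
    """Windows surviving the filter pipeline, plus stage-count provenance."""

    windows: list[NFRWindow]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.windows)

    def record_stage(self, name: str, n_in: int, n_out: int, **params) -> None:
        if n_out > n_in:
            raise ValueError("a filter stage cannot add windows")
        self.provenance[name] = {"in": n_in, "out": n_out, **params}


def _window_is_clean(aln: NucAlignment, max_missing: float) -> tuple[bool, float]:
    """A window is usable if it contains no masked column and no species
    exceeds the missing-cell threshold."""
    if any("N" in s for s in aln.seqs):
        return False, 1.0
    fracs = aln.missing_fractions()
    worst = max(fracs.values())
    return worst <= max_missing, worst


def draw_nfr_windows(
    masked_aln: NucAlignment,
    topology: PhyloTree,
    window_len: int = 300,
    max_n: Optional[int] = None,
    seed=None,
    max_missing: float = 0.2,
    family: str = "HKY85",
    fit: bool = True,
) -> list[NFRWindow]:
    """Draw non-overlapping candidate windows from a masked alignment.

    Start positions (on the reference species) are visited in random
    order and accepted greedily while disjoint; a window containing any
    masked column is excluded outright. Reproducible given ``seed``.
    """
    if window_len < 50:
        raise ValueError("window_len must be >= 50")
    if masked_aln.coord is None:
        raise ValueError("masked alignment must carry coordinates")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = masked_aln.coord.start, masked_aln.coord.end
    if hi - lo < window_len:
        logger.warning("region shorter than one window")
        return []
    starts = np.arange(lo, hi - window_len + 1)
    rng.shuffle(starts)
    taken: list[tuple[int, int]] = []
    windows: list[NFRWindow] = []
    for s in starts:
        e = int(s) + window_len
        if any(s < te and e > ts for ts, te in taken):
            continue
        try:
            sub = masked_aln.subregion(int(s), e)
        except EmptyAlignmentError:
            continue
        ok, worst = _window_is_clean(sub, max_missing)
        if not ok:
            continue
        taken.append((int(s), e))
        tm = fit_tree_model(sub, topology, family) if fit else None
        rel = None
        if tm is not None and not tm.no_variation and tm.tree.total_length > 0:
            rel = tm.relative_branch_lengths()
        windows.append(NFRWindow(sub, fit=tm, rel=rel, missing_frac=worst))
        if max_n is not None and len(windows) >= max_n:
            break
    if not windows:
        logger.warning("no unmasked stretch of %d bp found", window_len)
    windows.sort(key=lambda w: (w.coord.chrom, w.coord.start))
    return windows


def filter_min_rate(
    windows: Sequence[NFRWindow],
    floor: float = 0.001,
    foreground_only: Optional[str] = None,
) -> list[NFRWindow]:
    """Drop windows in which any branch's relative branch length is below
    ``floor`` (near-zero rates pile up at 0 and bias the pool).

    With ``foreground_only`` set, only that branch is checked — the
    narrower alternative reading of the rule.
    """
    kept = []
    for w in windows:
        if w.rel is None:
            continue
        values = (
            [w.rel[foreground_only]] if foreground_only else list(w.rel.values())
        )
        if all(v >= floor for v in values):
            kept.append(w)
    return kept


def interquartile_filter(
    windows: Sequence[NFRWindow],
    foreground: str,
    lower: float = 0.25,
    upper: float = 0.75,
) -> list[NFRWindow]:
    """Keep windows whose foreground relative branch length lies within
    [Q_lower, Q_upper] of the pool's distribution (inclusive,
    linear-interpolation quantiles). Tightening or widening the
    percentile band trades sensitivity against conservativeness.
    """
    if len(windows) < 4:
        raise ValueError("need at least 4 windows to take quartiles")
    values = np.array([w.rel[foreground] for w in windows])
    q1, q3 = np.quantile(values, [lower, upper], method="linear")
    return [w for w, v in zip(windows, values) if q1 <= v <= q3]


def build_pool(
    windows: Sequence[NFRWindow],
    foreground: str,
    floor: float = 0.001,
    lower: float = 0.25,
    upper: float = 0.75,
) -> ReferencePool:
    """Run the full filter pipeline (min-rate, then interquartile) and
    record stage counts."""
    pool = ReferencePool([], {})
    fitted = [w for w in windows if w.rel is not None]
    pool.record_stage("fitted", len(list(windows)), len(fitted))
    floored = filter_min_rate(fitted, floor)
    pool.record_stage("min_rate", len(fitted), len(floored), floor=floor)
    final = interquartile_filter(floored, foreground, lower, upper)
    pool.record_stage(
        "interquartile", len(floored), len(final), lower=lower, upper=upper
    )
    pool.windows = final
    return pool


def build_reference(
    pool: ReferencePool,
    k: int = 10,
    seed=None,
) -> NucAlignment:
    """Concatenate ``k`` windows sampled without replacement into one
    reference alignment (k · window_len columns for gap-free windows)."""
    if len(pool) < k:
        raise ValueError(f"pool has {len(pool)} windows, need {k}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(len(pool.windows), size=k, replace=False)
    chosen = [pool.windows[int(i)] for i in sorted(idx)]
    ref = NucAlignment.concat([w.aln for w in chosen])
    ref.meta["segments"] = [
        (w.coord.chrom, w.coord.start, w.coord.end) if w.coord else None
        for w in chosen
    ]
    ref.meta["id"] = "ref:" + ",".join(
        f"{c[0]}:{c[1]}-{c[2]}" if c else "?" for c in ref.meta["segments"]
    )
    return ref


def local_reference(
    query_interval: Region,
    pool: ReferencePool,
    radius: int = 100_000,
    k: Optional[int] = None,
) -> NucAlignment:
    """Concatenate all pool windows within ``radius`` of the query
    midpoint (optionally capped at the nearest ``k``).

    Raises :class:`NoLocalProxyError` when none are in range — a common
    outcome in annotation-dense regions, and the reason the genome-wide
    pool exists.
    """
    mid = query_interval.midpoint
    candidates = [
        w for w in pool.windows
        if w.coord is not None
        and w.coord.chrom == query_interval.chrom
        and abs(w.coord.midpoint - mid) <= radius
    ]
    if not candidates:
        raise NoLocalProxyError(
            f"no neutral windows within {radius} bp of "
            f"{query_interval.chrom}:{query_interval.start}-{query_interval.end}"
        )
    candidates.sort(key=lambda w: abs(w.coord.midpoint - mid))
    if k is not None:
        candidates = candidates[:k]
    candidates.sort(key=lambda w: w.coord.start)
    ref = NucAlignment.concat([w.aln for w in candidates])
    ref.meta["id"] = f"local:{query_interval.chrom}:{mid}±{radius}"
    return ref
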
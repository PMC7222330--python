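"""Sequence simulation along trees and the four-regime evaluation study.

Alignments are simulated column-independently: the root state is drawn
from the stationary frequencies and evolved along each branch with the
model's transition matrices (seq-gen semantics; only leaf rows are
emitted, no indels, no among-site rate variation). Selection regimes are
expressed as branch-length scalings of an otherwise neutral tree:
multiplying a branch by α multiplies its expected substitutions/site,
which is how both constraint (α < 1) and positive selection (α > 1)
manifest at the sequence level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .alignio import NucAlignment
from .phylo import BASES, SubstModel
from .selection import SelectionResult, TestConfig, test_selection
from .tree import PhyloTree, read_newick, DEFAULT_PRIMATE_NEWICK

__all__ = [
    "SimulationRegime",
    "REGIMES",
    "TreeSampler",
    "SimPair",
    "simulate_alignment",
    "scale_branches",
    "generate_regime_dataset",
    "run_regime_study",
    "evaluate_performance",
    "DEFAULT_SIM_MODEL",
]

#: Default simulation model: HKY85 with primate-like base composition and
#: transition/transversion ratio.
DEFAULT_SIM_MODEL = SubstModel(
    "HKY85", pi=np.array([0.30, 0.20, 0.20, 0.30]), kappa=4.0
)


@dataclass(frozen=True)
class SimulationRegime:
    """A class of evolution for query alignments.

    ``alpha_fg`` scales the foreground branch, ``alpha_bg`` every
    background branch (all non-foreground branches, internal ones
    included), and ``alpha_extra`` one additional named branch.
    """

    name: str
    alpha_bg: float = 1.0
    alpha_fg: float = 1.0
    alpha_extra: float = 1.0
    extra_branch: Optional[str] = None

    @property
    def is_positive(self) -> bool:
        """Does the foreground evolve under positive selection?"""
        return self.alpha_fg > 1.0

    def scaled_tree(self, tree: PhyloTree, foreground: str) -> PhyloTree:
        fg = tree.branch_index(foreground)
        out = tree
        if self.alpha_bg != 1.0:
            background = [n for n in out.branch_names() if out.branch_index(n) != fg]
            out = out.scaled(background, self.alpha_bg)
        if self.alpha_fg != 1.0:
            out = out.scaled(foreground, self.alpha_fg)
        if self.extra_branch is not None and self.alpha_extra != 1.0:
            out = out.scaled(self.extra_branch, self.alpha_extra)
        return out


#: The four study regimes: neutral everywhere; relaxation of constraint
#: (background constrained 10-fold, foreground neutral); positive
#: selection on the foreground (α=7); positive selection on the
#: foreground plus an accelerated gorilla background branch (α=10).
REGIMES: dict[str, SimulationRegime] = {
    "neutral": SimulationRegime("neutral"),
    "relaxation": SimulationRegime("relaxation", alpha_bg=0.1),
    "fg_positive": SimulationRegime("fg_positive", alpha_fg=7.0),
    "fg_bg_positive": SimulationRegime(
        "fg_bg_positive", alpha_fg=7.0, alpha_extra=10.0, extra_branch="gorilla"
    ),
}


@dataclass
class TreeSampler:
    """Random neutral trees around a template.

    Each branch of the template is jittered multiplicatively by
    exp(sigma·Z), Z ~ N(0,1), independently per branch and replicate
    (median-preserving lognormal). An empirical table of fitted trees can
    be supplied instead and is sampled uniformly.
    """

    template: Optional[PhyloTree] = None
    sigma: float = 0.3
    empirical: Optional[Sequence[PhyloTree]] = None

    def __post_init__(self):
        if self.template is None and self.empirical is None:
            self.template = read_newick(DEFAULT_PRIMATE_NEWICK)
        if self.template is not None:
            self.template.require_lengths()

    def sample(self, rng: np.random.Generator) -> PhyloTree:
        if self.empirical is not None:
            tree = self.empirical[int(rng.integers(len(self.empirical)))]
            return tree.copy()
        branches = self.template.branch_nodes()
        base = self.template.blen[branches]
        jitter = np.exp(self.sigma * rng.standard_normal(base.shape))
        return self.template.with_lengths(base * jitter)


def simulate_alignment(
    tree: PhyloTree,
    model: SubstModel,
    length: int,
    seed=None,
) -> NucAlignment:
    """Simulate an alignment of ``length`` independent columns.

    ``seed`` may be an int or a Generator; the same seed reproduces the
    alignment exactly.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    tree.require_lengths()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = {tree.root: rng.choice(4, size=length, p=model.pi)}
    # preorder = reversed postorder: parents before children
    for node in tree.postorder[::-1]:
        if node == tree.root:
            continue
        P = model.transition_matrix(tree.blen[node])
        cum = np.cumsum(P, axis=1)
        u = rng.random(length)
        parent_states = states[tree.parent[node]]
        states[node] = (u[:, None] > cum[parent_states]).sum(axis=1)
    names, seqs = [], []
    base_arr = np.array(list(BASES))
    for name, node in sorted(tree.leaf_indices.items()):
        names.append(name)
        seqs.append("".join(base_arr[states[node]]))
    return NucAlignment(names, seqs)


def scale_branches(tree: PhyloTree, branches, alpha: float) -> PhyloTree:
    """Multiply the named branches' lengths by ``alpha`` (others untouched)."""
    return tree.scaled(branches, alpha)


@dataclass
class SimPair:
    """One simulated replicate: a query/reference pair plus provenance."""

    query: NucAlignment
    reference: NucAlignment
    regime: str
    replicate: int
    neutral_tree: PhyloTree
    query_tree: PhyloTree
    seed: int


def generate_regime_dataset(
    regime: SimulationRegime,
    n: int,
    query_len: int = 300,
    ref_len: int = 3000,
    sampler: Optional[TreeSampler] = None,
    seed=None,
    foreground: str = "human",
    model: SubstModel = DEFAULT_SIM_MODEL,
) -> list[SimPair]:
    """Simulate ``n`` paired (query, reference) alignments for a regime.

    Per replicate a neutral tree is drawn from the sampler; the reference
    evolves on it unchanged and the query on its regime-scaled copy.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sampler = sampler or TreeSampler()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pairs = []
    for i in range(n):
        rep_seed = int(rng.integers(2**31))
        rep_rng = np.random.default_rng(rep_seed)
        neutral = sampler.sample(rep_rng)
        qtree = regime.scaled_tree(neutral, foreground)
        reference = simulate_alignment(neutral, model, ref_len, rep_rng)
        query = simulate_alignment(qtree, model, query_len, rep_rng)
        query.meta["id"] = f"{regime.name}.{i}"
        reference.meta["id"] = f"{regime.name}.{i}.ref"
        pairs.append(
            SimPair(query, reference, regime.name, i, neutral, qtree, rep_seed)
        )
    return pairs


POSITIVE_REGIMES = {"fg_positive", "fg_bg_positive"}
NEGATIVE_REGIMES = {"neutral", "relaxation"}


def evaluate_performance(
    results: Sequence[SelectionResult],
    truth_labels: Sequence[str],
    alpha_level: float = 0.05,
) -> dict:
    """Confusion summary of test results against regime labels.

    Positive class = regimes with positive selection on the foreground
    ({fg_positive, fg_bg_positive}); negative class = {neutral,
    relaxation}. Sensitivity pools the positive regimes; specificity is
    one minus the pooled false-positive rate on the negative regimes.
    """
    if len(results) != len(truth_labels):
        raise ValueError("results and labels differ in length")
    per_regime: dict[str, list[bool]] = {}
    for res, label in zip(results, truth_labels):
        per_regime.setdefault(label, []).append(res.p < alpha_level)
    summary: dict = {"alpha_level": alpha_level, "per_regime": {}}
    tp = fn = fp = tn = 0
    for label, calls in per_regime.items():
        k = int(np.sum(calls))
        n = len(calls)
        summary["per_regime"][label] = {
            "n": n, "significant": k, "fraction": k / n,
        }
        if label in POSITIVE_REGIMES:
            tp += k
            fn += n - k
        elif label in NEGATIVE_REGIMES:
            fp += k
            tn += n - k
    summary["confusion"] = {"tp": tp, "fn": fn, "fp": fp, "tn": tn}
    summary["sensitivity"] = tp / (tp + fn) if (tp + fn) else float("nan")
    summary["specificity"] = tn / (tn + fp) if (tn + fp) else float("nan")
    return summary


def run_regime_study(
    n_per_regime: int,
    query_len: int = 300,
    ref_len: int = 3000,
    seed: Optional[int] = None,
    config: Optional[TestConfig] = None,
    regimes: Optional[dict[str, SimulationRegime]] = None,
    sampler: Optional[TreeSampler] = None,
    foreground: str = "human",
    model: SubstModel = DEFAULT_SIM_MODEL,
) -> pd.DataFrame:
    """Simulate all regimes and run the selection test on every pair.

    Returns one row per replicate with the regime label, p-value, ζ and
    the fitted mixture parameters — the raw material for sensitivity and
    specificity summaries.
    """
    regimes = regimes or REGIMES
    config = config or TestConfig()
    master = np.random.default_rng(seed)
    rows = []
    for name, regime in regimes.items():
        pairs = generate_regime_dataset(
            regime, n_per_regime, query_len=query_len, ref_len=ref_len,
            sampler=sampler, seed=master, foreground=foreground, model=model,
        )
        for pair in pairs:
            cfg_seed = int(np.random.default_rng(pair.seed + 1).integers(2**31))
            cfg = TestConfig(
                topology=config.topology, foreground=foreground,
                family=config.family, n_restarts=config.n_restarts,
                seed=cfg_seed, mode=config.mode,
                min_query_len=config.min_query_len,
                min_ref_len=config.min_ref_len,
            )
            res = test_selection(pair.query, pair.reference, foreground, cfg)
            row = res.row()
            row.update(regime=name, replicate=pair.replicate,
                       is_positive=regime.is_positive)
            rows.append(row)
    return pd.DataFrame(rows)
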
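"""Independent brute-force oracles for likelihood checks.

These enumerate every joint state assignment of unobserved nodes
(internal nodes and missing leaves) instead of pruning, so they are
exponential in tree size but trivially correct on small instances.
"""

from __future__ import annotations

import itertools

import numpy as np

from adaptiphy.phylo import MISSING, SubstModel, encode_alignment
from adaptiphy.tree import PhyloTree

__all__ = [
    "brute_force_column_likelihood",
    "brute_force_loglik",
    "brute_force_mixture_loglik",
]


def brute_force_column_likelihood(
    tree: PhyloTree,
    model: SubstModel,
    leaf_codes: dict[str, int],
    node_multipliers=None,
) -> float:
    """P(column) by summing over all assignments of unobserved nodes."""
    mult = np.ones(tree.n_nodes)
    if node_multipliers is not None:
        mult = np.asarray(node_multipliers, dtype=float)
    fixed: dict[int, int] = {}
    unknown: list[int] = []
    for node in range(tree.n_nodes):
        if tree.leaf_mask[node]:
            code = leaf_codes[tree.names[node]]
            if code == MISSING:
                unknown.append(node)
            else:
                fixed[node] = int(code)
        else:
            unknown.append(node)
    P = {}
    for node in tree.branch_nodes():
        P[node] = model.transition_matrix(tree.blen[node] * mult[node])
    total = 0.0
    for assignment in itertools.product(range(4), repeat=len(unknown)):
        state = dict(fixed)
        state.update(zip(unknown, assignment))
        prob = model.pi[state[tree.root]]
        for node in tree.branch_nodes():
            prob *= P[node][state[tree.parent[node]], state[node]]
        total += prob
    return total


def brute_force_loglik(aln, tree, model, branch_scale=None) -> float:
    """Alignment log-likelihood via per-column enumeration."""
    mult = np.ones(tree.n_nodes)
    if branch_scale:
        for name, m in branch_scale.items():
            mult[tree.branch_index(name)] = m
    codes = encode_alignment(aln)
    total = 0.0
    for j in range(aln.length):
        col = {sp: int(codes[i, j]) for i, sp in enumerate(aln.species)}
        total += np.log(brute_force_column_likelihood(tree, model, col, mult))
    return total


def brute_force_mixture_loglik(
    params, kind, ref_aln, query_aln, tree, model, foreground
) -> float:
    """Reference (all-neutral) + query mixture lnL by enumeration."""
    lnL = brute_force_loglik(ref_aln, tree, model)
    fg_node = tree.branch_index(foreground)
    codes = encode_alignment(query_aln)
    for j in range(query_aln.length):
        col = {sp: int(codes[i, j]) for i, sp in enumerate(query_aln.species)}
        site = 0.0
        for weight, bg, fg in params.categories(kind):
            mult = np.full(tree.n_nodes, bg)
            mult[fg_node] = fg
            site += weight * brute_force_column_likelihood(tree, model, col, mult)
        lnL += np.log(site)
    return lnL
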
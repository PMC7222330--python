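"""Nucleotide substitution models, Felsenstein pruning, ML tree fitting.

The rate matrix is calibrated to one expected substitution per site at
stationarity, so branch lengths are in substitutions/site. N and '-' are
treated as missing data (partial-likelihood vector of ones); there is no
gap-as-fifth-state and no among-site rate variation here — the only site
heterogeneity in the package is the selection mixture built on top.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from .alignio import NucAlignment
from .tree import PhyloTree, TreeError, relative_branch_lengths

__all__ = [
    "SubstModel",
    "SitePatternTable",
    "TreeModel",
    "compress_patterns",
    "pattern_likelihoods",
    "pruning_loglik",
    "fit_tree_model",
    "empirical_base_frequencies",
    "relative_branch_lengths",
]

BASES = "ACGT"
MISSING = 4
_CODE = np.full(256, MISSING, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i

#: Exchangeability order for GTR: AC, AG, AT, CG, CT, GT (GT fixed to 1).
GTR_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
_TRANSITIONS = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T


@dataclass
class SubstModel:
    """Time-reversible nucleotide model (HKY85 or GTR).

    Parameters
    ----------
    family : "HKY85" or "GTR"
    pi : stationary base frequencies (A, C, G, T), summing to 1
    kappa : transition/transversion rate ratio (HKY85)
    rates : six exchangeabilities in :data:`GTR_PAIRS` order (GTR)
    """

    family: str = "HKY85"
    pi: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    kappa: Optional[float] = 2.0
    rates: Optional[np.ndarray] = None

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (4,) or (self.pi <= 0).any():
            raise ValueError("pi must be four positive frequencies")
        if abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValueError("pi must sum to 1")
        if self.family == "HKY85":
            if self.kappa is None or self.kappa <= 0:
                raise ValueError("HKY85 requires kappa > 0")
        elif self.family == "GTR":
            self.rates = np.asarray(self.rates, dtype=float)
            if self.rates.shape != (6,) or (self.rates <= 0).any():
                raise ValueError("GTR requires six positive exchangeabilities")
        else:
            raise ValueError(f"unknown family {self.family!r}")
        self._build()

    def _build(self):
        Q = np.zeros((4, 4))
        for k, (i, j) in enumerate(GTR_PAIRS):
            if self.family == "HKY85":
                s = self.kappa if (i, j) in _TRANSITIONS else 1.0
            else:
                s = self.rates[k]
            Q[i, j] = s * self.pi[j]
            Q[j, i] = s * self.pi[i]
        np.fill_diagonal(Q, 0.0)
        Q[np.diag_indices(4)] = -Q.sum(axis=1)
        mu = -float(np.dot(self.pi, np.diag(Q)))
        Q /= mu  # calibrate: 1 expected substitution/site at stationarity
        self.Q = Q
        # symmetric similarity transform: S = D^1/2 Q D^-1/2 (D = diag(pi))
        d = np.sqrt(self.pi)
        S = Q * d[:, None] / d[None, :]
        S = (S + S.T) / 2  # guard against rounding asymmetry
        w, U = np.linalg.eigh(S)
        self._eigval = w
        self._right = U / d[:, None]           # D^-1/2 U    (4,4)
        self._left = U.T * d[None, :]          # U^T D^1/2   (4,4)

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1."""
        return self.transition_matrices(np.array([t]))[0]

    def transition_matrices(self, ts: np.ndarray) -> np.ndarray:
        """(n, 4, 4) stack of P(t) for an array of branch lengths."""
        ts = np.asarray(ts, dtype=float)
        if (ts < 0).any():
            raise ValueError("negative branch length")
        e = np.exp(np.outer(ts, self._eigval))  # (n, 4)
        P = np.einsum("ik,nk,kj->nij", self._right, e, self._left)
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=2, keepdims=True)
        P[ts == 0.0] = np.eye(4)  # exact identity at zero length
        return P

    def to_text(self) -> str:
        lines = [f"family\t{self.family}", "pi\t" + "\t".join(f"{x:.8g}" for x in self.pi)]
        if self.family == "HKY85":
            lines.append(f"kappa\t{self.kappa:.8g}")
        else:
            lines.append("rates\t" + "\t".join(f"{x:.8g}" for x in self.rates))
        return "\n".join(lines)


def empirical_base_frequencies(aln: NucAlignment, pseudocount: float = 0.5) -> np.ndarray:
    codes = encode_alignment(aln)
    counts = np.array([(codes == i).sum() for i in range(4)], dtype=float)
    counts += pseudocount
    return counts / counts.sum()


def encode_alignment(aln: NucAlignment) -> np.ndarray:
    """(n_species, length) uint8 codes: A=0 C=1 G=2 T=3, missing=4."""
    rows = [
        _CODE[np.frombuffer(s.encode("ascii"), dtype=np.uint8)] for s in aln.seqs
    ]
    return np.vstack(rows)


@dataclass
class SitePatternTable:
    """Distinct alignment columns with multiplicities."""

    patterns: np.ndarray  # (n_patterns, n_species) uint8 codes
    counts: np.ndarray    # (n_patterns,) ints
    species: list[str]

    @property
    def n_sites(self) -> int:
        return int(self.counts.sum())

    @property
    def n_patterns(self) -> int:
        return len(self.counts)


def compress_patterns(aln: NucAlignment) -> SitePatternTable:
    """Collapse an alignment into its distinct columns (order-independent)."""
    codes = encode_alignment(aln).T  # (L, S)
    patterns, counts = np.unique(codes, axis=0, return_counts=True)
    return SitePatternTable(patterns, counts, list(aln.species))


def _leaf_partials(pt: SitePatternTable, tree: PhyloTree) -> dict[int, np.ndarray]:
    """One-hot (or all-ones for missing) leaf likelihood vectors."""
    eye5 = np.vstack([np.eye(4), np.ones(4)])  # code -> partial row
    out = {}
    for name, node in tree.leaf_indices.items():
        try:
            col = pt.species.index(name)
        except ValueError:
            raise ValueError(f"species {name!r} missing from alignment") from None
        out[node] = eye5[pt.patterns[:, col]]
    return out


def _resolve_scale(tree: PhyloTree, branch_scale) -> np.ndarray:
    mult = np.ones(tree.n_nodes)
    if branch_scale:
        for name, m in branch_scale.items():
            if m < 0:
                raise ValueError("branch multipliers must be >= 0")
            mult[tree.branch_index(name)] = m
    return mult


def pattern_likelihoods(
    pt: SitePatternTable,
    tree: PhyloTree,
    model: SubstModel,
    node_multipliers: Optional[np.ndarray] = None,
    leaf_partials: Optional[dict[int, np.ndarray]] = None,
) -> np.ndarray:
    """Per-pattern column likelihood by postorder pruning.

    ``node_multipliers`` scales the branch above each node (array over all
    nodes; entries for the root are ignored).
    """
    tree.require_lengths()
    if leaf_partials is None:
        leaf_partials = _leaf_partials(pt, tree)
    branches = tree.branch_nodes()
    lens = tree.blen[branches]
    if node_multipliers is not None:
        lens = lens * node_multipliers[branches]
    P = model.transition_matrices(lens)
    Pmap = {node: P[k] for k, node in enumerate(branches)}
    partial: dict[int, np.ndarray] = {}
    for node in tree.postorder:
        if tree.leaf_mask[node]:
            partial[node] = leaf_partials[node]
            continue
        prod = None
        for child in tree.children[node]:
            contrib = partial.pop(child) @ Pmap[child].T
            prod = contrib if prod is None else prod * contrib
        partial[node] = prod
    return partial[tree.root] @ model.pi


def pruning_loglik(
    pt: SitePatternTable,
    tree: PhyloTree,
    model: SubstModel,
    branch_scale: Optional[dict[str, float]] = None,
) -> float:
    """Σ count · log P(column | tree, model), with branch multipliers.

    A pattern that is impossible under the scaled tree (e.g. conflicting
    states across zero-length branches) yields -inf.
    """
    mult = _resolve_scale(tree, branch_scale)
    lik = pattern_likelihoods(pt, tree, model, mult)
    if (lik <= 0).any():
        return float("-inf")
    return float(np.dot(pt.counts, np.log(lik)))


@dataclass
class TreeModel:
    """A fitted tree + substitution model."""

    tree: PhyloTree
    model: SubstModel
    lnL: float
    trace: list = field(default_factory=list)
    no_variation: bool = False
    n_iter: int = 0

    def relative_branch_lengths(self) -> dict[str, float]:
        return relative_branch_lengths(self.tree)

    def to_text(self) -> str:
        return (
            self.model.to_text()
            + f"\nlnL\t{self.lnL:.6f}\ntree\t{self.tree.to_newick()}"
        )


_LOG_BLEN_BOUNDS = (np.log(1e-8), np.log(10.0))
_LOG_KAPPA_BOUNDS = (np.log(0.05), np.log(100.0))


def _has_variable_site(pt: SitePatternTable) -> bool:
    for row in pt.patterns:
        obs = row[row < MISSING]
        if obs.size and (obs != obs[0]).any():
            return True
    return False


def fit_tree_model(
    aln: NucAlignment,
    topology: PhyloTree,
    family: str = "HKY85",
    *,
    pi: Optional[np.ndarray] = None,
    fix_kappa: Optional[float] = None,
    init_blen: float = 0.05,
    tol: float = 1e-8,
) -> TreeModel:
    """ML branch lengths and substitution parameters on a fixed topology.

    Base frequencies are the observed frequencies in the alignment unless
    ``pi`` is given; kappa (HKY85) or the GTR exchangeabilities are
    estimated by maximum likelihood (bounded quasi-Newton on the log
    scale). If the alignment has no variable non-missing site, all branch
    lengths are returned as zero with ``no_variation`` set.
    """
    if aln.n_species < 2:
        raise ValueError("need at least two species")
    missing = set(topology.leaf_indices) - set(aln.species)
    if missing:
        raise ValueError(f"alignment lacks species {sorted(missing)}")
    pt = compress_patterns(aln)
    if pi is None:
        pi = empirical_base_frequencies(aln)
    branches = topology.branch_nodes()
    nb = len(branches)

    if not _has_variable_site(pt):
        model = (
            SubstModel("HKY85", pi, kappa=fix_kappa or 2.0)
            if family == "HKY85"
            else SubstModel("GTR", pi, kappa=None, rates=np.ones(6))
        )
        zero = topology.with_lengths(np.zeros(nb))
        lnL = pruning_loglik(pt, zero, model)
        warnings.warn("alignment has no variable sites; branch lengths set to 0")
        return TreeModel(zero, model, lnL, no_variation=True)

    leafp = _leaf_partials(pt, topology)
    free_kappa = family == "HKY85" and fix_kappa is None
    n_rates = 5 if family == "GTR" else 0

    def unpack(theta):
        blen = np.exp(theta[:nb])
        tree = topology.with_lengths(blen)
        if family == "HKY85":
            kappa = np.exp(theta[nb]) if free_kappa else fix_kappa
            model = SubstModel("HKY85", pi, kappa=float(kappa))
        else:
            rates = np.append(np.exp(theta[nb:nb + n_rates]), 1.0)
            model = SubstModel("GTR", pi, kappa=None, rates=rates)
        return tree, model

    def objective(theta):
        tree, model = unpack(theta)
        lik = pattern_likelihoods(pt, tree, model, leaf_partials=leafp)
        if (lik <= 0).any():
            return 1e12
        return -float(np.dot(pt.counts, np.log(lik)))

    theta0 = np.concatenate([
        np.full(nb, np.log(init_blen)),
        [np.log(2.0)] if free_kappa else [],
        np.zeros(n_rates),
    ])
    bounds = (
        [_LOG_BLEN_BOUNDS] * nb
        + ([_LOG_KAPPA_BOUNDS] if free_kappa else [])
        + [(np.log(1e-3), np.log(1e3))] * n_rates
    )
    trace: list[float] = []
    res = minimize(
        objective,
        theta0,
        method="L-BFGS-B",
        bounds=bounds,
        callback=lambda xk: trace.append(-objective(xk)),
        options={"ftol": tol, "maxiter": 500},
    )
    tree, model = unpack(res.x)
    lnL = -float(res.fun)
    if lnL < -objective(theta0) - 1e-6:
        raise RuntimeError("optimizer returned a worse point than the start")
    # branches pinned at the lower bound are effectively zero
    blen = tree.blen.copy()
    blen[branches] = np.where(blen[branches] <= 1.5e-8, 0.0, blen[branches])
    tree = topology.with_lengths(blen[branches])
    return TreeModel(tree, model, lnL, trace=trace, n_iter=int(res.nit))
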
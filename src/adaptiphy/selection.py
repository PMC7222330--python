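"""The branch-specific selection test: mixture likelihoods, LRT, ζ.

A query alignment is compared with a proxy-neutral reference sharing one
set of branch lengths. Reference sites evolve neutrally on every branch.
Query sites fall into categories: a fraction b1 under purifying selection
(relative rate ζ1 < 1 on all branches) and b2 = 1 − b1 neutral (ζ2 = 1).
The null model lets a fraction Δ of the purifying sites evolve neutrally
on the foreground branch (relaxation of constraint); the alternative lets
fractions Δ1 (of purifying) and Δ2 (of neutral) sites evolve at ζ3 > 1 on
the foreground (positive selection). Twice the log-likelihood difference
is referred to a χ² distribution with one degree of freedom — a
deliberately conservative calibration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .alignio import NucAlignment
from .phylo import (
    SitePatternTable,
    SubstModel,
    TreeModel,
    compress_patterns,
    empirical_base_frequencies,
    fit_tree_model,
    pattern_likelihoods,
    _leaf_partials,
)
from .tree import PhyloTree, read_newick, DEFAULT_PRIMATE_NEWICK

logger = logging.getLogger("adaptiphy")

__all__ = [
    "MixtureModelParams",
    "SelectionResult",
    "TestConfig",
    "joint_loglik",
    "fit_selection_model",
    "lrt_pvalue",
    "test_selection",
    "estimate_zeta",
]

ZETA1_BOUNDS = (1e-4, 1.0 - 1e-4)
ZETA3_BOUNDS = (1.0 + 1e-4, 50.0)
FRACTION_BOUNDS = (0.0, 1.0)


@dataclass
class MixtureModelParams:
    """Site-category mixture parameters.

    The null model uses {b1, zeta1, delta}; the alternative uses
    {b1, zeta1, delta1, delta2, zeta3}. The neutral relative rate ζ2 is
    identically 1 and not represented.
    """

    b1: float
    zeta1: float
    delta: float = 0.0
    delta1: float = 0.0
    delta2: float = 0.0
    zeta3: float = 1.0 + 1e-4

    def validate(self, kind: str) -> None:
        for name in ("b1", "delta", "delta1", "delta2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not ZETA1_BOUNDS[0] <= self.zeta1 <= ZETA1_BOUNDS[1]:
            raise ValueError(f"zeta1={self.zeta1} outside {ZETA1_BOUNDS}")
        if kind == "alt" and not ZETA3_BOUNDS[0] <= self.zeta3 <= ZETA3_BOUNDS[1]:
            raise ValueError(f"zeta3={self.zeta3} outside {ZETA3_BOUNDS}")

    def categories(self, kind: str) -> list[tuple[float, float, float]]:
        """(weight, background multiplier, foreground multiplier) triples.

        Weights are non-negative and sum to 1 by construction.
        """
        b1, b2 = self.b1, 1.0 - self.b1
        z1 = self.zeta1
        if kind == "null":
            return [
                (b1 * (1.0 - self.delta), z1, z1),
                (b1 * self.delta, z1, 1.0),
                (b2, 1.0, 1.0),
            ]
        if kind == "alt":
            z3 = self.zeta3
            return [
                (b1 * (1.0 - self.delta1), z1, z1),
                (b1 * self.delta1, z1, z3),
                (b2 * (1.0 - self.delta2), 1.0, 1.0),
                (b2 * self.delta2, 1.0, z3),
            ]
        raise ValueError(f"unknown model kind {kind!r}")


@dataclass
class SelectionResult:
    """Outcome of one query/reference/foreground test."""

    lnL_null: float
    lnL_alt: float
    LRT: float
    p: float
    zeta: float
    mle_null: MixtureModelParams
    mle_alt: MixtureModelParams
    foreground: str
    query_id: str = ""
    ref_id: str = ""
    n_restarts_used: int = 0
    seed: Optional[int] = None
    tree: Optional[PhyloTree] = None

    def row(self) -> dict:
        """Flat record for tabular output."""
        out = {
            "query_id": self.query_id,
            "ref_id": self.ref_id,
            "foreground": self.foreground,
            "lnL_null": self.lnL_null,
            "lnL_alt": self.lnL_alt,
            "LRT": self.LRT,
            "p": self.p,
            "zeta": self.zeta,
            "b1": self.mle_alt.b1,
            "z1": self.mle_alt.zeta1,
            "d1": self.mle_alt.delta1,
            "d2": self.mle_alt.delta2,
            "z3": self.mle_alt.zeta3,
            "seed": self.seed,
        }
        return out


@dataclass
class TestConfig:
    """Knobs for :func:`test_selection`.

    mode="two_stage" first fits branch lengths and substitution
    parameters to the reference alone, then optimizes only the mixture;
    mode="joint" re-optimizes branch lengths together with the mixture
    (slower, the fully general fit).
    """

    topology: str = DEFAULT_PRIMATE_NEWICK
    foreground: str = "human"
    family: str = "HKY85"
    n_restarts: int = 20
    seed: Optional[int] = None
    mode: str = "joint"
    min_query_len: int = 50
    min_ref_len: int = 300


def _foreground_nodes(tree: PhyloTree, foreground) -> set[int]:
    """Node indices of the foreground branch(es)."""
    fg_names = [foreground] if isinstance(foreground, str) else list(foreground)
    return {tree.branch_index(n) for n in fg_names}


def _mixture_pattern_loglik(cats, lik_by_pair, counts):
    site = None
    for (w, lik) in zip(cats, lik_by_pair):
        term = w * lik
        site = term if site is None else site + term
    if (site <= 0).any():
        return float("-inf")
    return float(np.dot(counts, np.log(site)))


class _MixtureEngine:
    """Caches leaf partials and the constant neutral category likelihood
    for repeated mixture-likelihood evaluations on a fixed tree."""

    def __init__(self, query_pt, tree, model, foreground):
        self.pt = query_pt
        self.tree = tree
        self.model = model
        fg_nodes = _foreground_nodes(tree, foreground)
        self.is_fg = np.zeros(tree.n_nodes, dtype=bool)
        for n in fg_nodes:
            self.is_fg[n] = True
        self.leafp = _leaf_partials(query_pt, tree)
        self._cache: dict[tuple[float, float], np.ndarray] = {}

    def pair_likelihood(self, bg: float, fg: float) -> np.ndarray:
        key = (bg, fg)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        mult = np.where(self.is_fg, fg, bg)
        lik = pattern_likelihoods(
            self.pt, self.tree, self.model, mult, leaf_partials=self.leafp
        )
        if len(self._cache) > 64:
            self._cache.clear()
        self._cache[key] = lik
        return lik

    def loglik(self, params: MixtureModelParams, kind: str) -> float:
        cats = params.categories(kind)
        liks = [self.pair_likelihood(bg, fg) for (_, bg, fg) in cats]
        return _mixture_pattern_loglik([w for (w, _, _) in cats], liks, self.pt.counts)


def joint_loglik(
    params: MixtureModelParams,
    model_kind: str,
    ref_patterns: SitePatternTable,
    query_patterns: SitePatternTable,
    tree: PhyloTree,
    subst: SubstModel,
    foreground,
) -> float:
    """lnL of reference (all-neutral) plus the mixture lnL of the query."""
    params.validate(model_kind)
    ref_lik = pattern_likelihoods(ref_patterns, tree, subst)
    if (ref_lik <= 0).any():
        return float("-inf")
    lnL_ref = float(np.dot(ref_patterns.counts, np.log(ref_lik)))
    engine = _MixtureEngine(query_patterns, tree, subst, foreground)
    return lnL_ref + engine.loglik(params, model_kind)


def _vector_to_params(x, kind) -> MixtureModelParams:
    if kind == "null":
        return MixtureModelParams(b1=x[0], zeta1=x[1], delta=x[2])
    return MixtureModelParams(
        b1=x[0], zeta1=x[1], delta1=x[2], delta2=x[3], zeta3=x[4]
    )


def _params_to_vector(p: MixtureModelParams, kind) -> np.ndarray:
    if kind == "null":
        return np.array([p.b1, p.zeta1, p.delta])
    return np.array([p.b1, p.zeta1, p.delta1, p.delta2, p.zeta3])


def _mixture_bounds(kind):
    if kind == "null":
        return [FRACTION_BOUNDS, ZETA1_BOUNDS, FRACTION_BOUNDS]
    return [
        FRACTION_BOUNDS, ZETA1_BOUNDS, FRACTION_BOUNDS, FRACTION_BOUNDS,
        ZETA3_BOUNDS,
    ]


def _random_start(kind, rng) -> np.ndarray:
    b1 = rng.uniform(0.0, 1.0)
    z1 = rng.uniform(0.05, 0.95)
    if kind == "null":
        return np.array([b1, z1, rng.uniform(0.0, 1.0)])
    z3 = float(np.exp(rng.uniform(np.log(1.05), np.log(20.0))))
    return np.array([b1, z1, rng.uniform(0, 1), rng.uniform(0, 1), z3])


def fit_selection_model(
    model_kind: str,
    query_pt: SitePatternTable,
    tree: PhyloTree,
    subst: SubstModel,
    foreground,
    n_restarts: int = 20,
    rng: Optional[np.random.Generator] = None,
    extra_starts: Sequence[MixtureModelParams] = (),
    tol: float = 1e-8,
    polish: int = 3,
) -> tuple[float, MixtureModelParams, int]:
    """Best-of-restarts ML fit of the mixture on a fixed tree.

    Returns (query lnL, parameters, restarts actually run). Restart
    initializations are drawn from broad seeded distributions; callers may
    append deterministic starts (e.g. the null MLE mapped into the
    alternative) via ``extra_starts``.
    """
    if rng is None:
        rng = np.random.default_rng()
    engine = _MixtureEngine(query_pt, tree, subst, foreground)
    bounds = _mixture_bounds(model_kind)

    def objective(x):
        ll = engine.loglik(_vector_to_params(x, model_kind), model_kind)
        return 1e12 if not np.isfinite(ll) else -ll

    starts = [_params_to_vector(p, model_kind) for p in extra_starts]
    starts += [_random_start(model_kind, rng) for _ in range(n_restarts - len(starts))]
    stage1_results = []
    used = 0
    for x0 in starts:
        used += 1
        res = minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": tol, "maxiter": 300},
        )
        stage1_results.append(res)
    # quasi-Newton stalls on the mixture's flat ridges; a simplex polish
    # of the leading restarts reliably reaches the mode
    stage1_results.sort(key=lambda r: r.fun)
    best = stage1_results[0]
    for res in stage1_results[:polish]:
        polished = minimize(
            objective, res.x, method="Nelder-Mead", bounds=bounds,
            options={"fatol": 1e-8, "xatol": 1e-7, "maxiter": 1000},
        )
        if polished.fun < best.fun:
            best = polished
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"all {used} restarts failed for the {model_kind} model")
    params = _vector_to_params(best.x, model_kind)
    return -float(best.fun), params, used


def lrt_pvalue(lnL_null: float, lnL_alt: float) -> tuple[float, float]:
    """LRT statistic (clamped at 0) and upper-tail χ²₁ p-value."""
    stat = 2.0 * (lnL_alt - lnL_null)
    if stat < 0:
        log = logger.warning if stat < -1e-4 else logger.debug
        log("negative LRT %.3g clamped to 0 (optimizer noise)", stat)
        stat = 0.0
    return stat, float(chi2.sf(stat, df=1))


def estimate_zeta(mle_alt: MixtureModelParams) -> float:
    """Mixture-weighted mean foreground relative rate.

    ζ = b1(1−Δ1)ζ1 + b1Δ1ζ3 + b2(1−Δ2)·1 + b2Δ2ζ3, which equals
    K_query / K_reference on the foreground branch under the fitted
    alternative model.
    """
    p = mle_alt
    b2 = 1.0 - p.b1
    return (
        p.b1 * (1.0 - p.delta1) * p.zeta1
        + p.b1 * p.delta1 * p.zeta3
        + b2 * (1.0 - p.delta2) * 1.0
        + b2 * p.delta2 * p.zeta3
    )


def _null_to_alt(p: MixtureModelParams) -> MixtureModelParams:
    """Map a null MLE into the alternative parameter space (ζ3 at its
    lower bound makes the relaxed category numerically neutral), so the
    alternative fit can never fall below the null."""
    return MixtureModelParams(
        b1=p.b1, zeta1=p.zeta1, delta1=p.delta, delta2=0.0,
        zeta3=ZETA3_BOUNDS[0],
    )


class _JointFitter:
    """Joint refinement of branch lengths and mixture parameters.

    Substitution parameters (π, κ or GTR rates) stay at their stage-1
    estimates from the reference fit — with a reference an order of
    magnitude longer than the query they are essentially pinned by it —
    while all branch lengths are re-optimized together with the mixture,
    so the null can trade reference likelihood against query likelihood
    (e.g. stretch the foreground branch) exactly as the alternative can.
    """

    def __init__(self, query_pt, ref_pt, topology, model, foreground):
        self.query_pt = query_pt
        self.ref_pt = ref_pt
        self.topology = topology
        self.model = model
        self.branches = topology.branch_nodes()
        self.nb = len(self.branches)
        fg_names = [foreground] if isinstance(foreground, str) else list(foreground)
        self.is_fg = np.zeros(topology.n_nodes, dtype=bool)
        for name in fg_names:
            self.is_fg[topology.branch_index(name)] = True
        self.ref_leafp = _leaf_partials(ref_pt, topology)
        self.query_leafp = _leaf_partials(query_pt, topology)
        self.foreground = foreground

    def loglik(self, tree, params, kind) -> float:
        ref_lik = pattern_likelihoods(
            self.ref_pt, tree, self.model, leaf_partials=self.ref_leafp
        )
        if (ref_lik <= 0).any():
            return float("-inf")
        total = float(np.dot(self.ref_pt.counts, np.log(ref_lik)))
        cats = params.categories(kind)
        site = None
        for w, bg, fg in cats:
            mult = np.where(self.is_fg, fg, bg)
            lik = pattern_likelihoods(
                self.query_pt, tree, self.model, mult,
                leaf_partials=self.query_leafp,
            )
            term = w * lik
            site = term if site is None else site + term
        if (site <= 0).any():
            return float("-inf")
        return total + float(np.dot(self.query_pt.counts, np.log(site)))

    def refine(self, kind, blen0, mix0: MixtureModelParams):
        """L-BFGS-B over [log branch lengths, mixture] from a start, then
        a simplex polish of the mixture at the refined tree."""
        bounds = [_LOG_JOINT_BLEN_BOUNDS] * self.nb + _mixture_bounds(kind)
        x0 = np.concatenate([
            np.log(np.clip(blen0, 1e-8, None)),
            _params_to_vector(mix0, kind),
        ])

        def objective(theta):
            tree = self.topology.with_lengths(np.exp(theta[: self.nb]))
            params = _vector_to_params(theta[self.nb:], kind)
            ll = self.loglik(tree, params, kind)
            return 1e12 if not np.isfinite(ll) else -ll

        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                       options={"ftol": 1e-9, "maxiter": 500})
        tree = self.topology.with_lengths(np.exp(res.x[: self.nb]))
        lnL_mix, params, _ = fit_selection_model(
            kind, self.query_pt, tree, self.model, self.foreground,
            n_restarts=1, extra_starts=[_vector_to_params(res.x[self.nb:], kind)],
            polish=1,
        )
        ref_lik = pattern_likelihoods(
            self.ref_pt, tree, self.model, leaf_partials=self.ref_leafp
        )
        lnL = float(np.dot(self.ref_pt.counts, np.log(ref_lik))) + lnL_mix
        return lnL, params, tree


_LOG_JOINT_BLEN_BOUNDS = (np.log(1e-8), np.log(10.0))


def test_selection(
    query: NucAlignment,
    reference: NucAlignment,
    foreground: Optional[str] = None,
    config: Optional[TestConfig] = None,
) -> SelectionResult:
    """Run the full selection test on one query/reference pair.

    Fits the null and alternative mixture models, computes the LRT and
    its χ²₁ p-value, and reports ζ from the alternative MLE. With the
    same seed the result is deterministic.
    """
    config = config or TestConfig()
    foreground = foreground or config.foreground
    topology = (
        config.topology
        if isinstance(config.topology, PhyloTree)
        else read_newick(config.topology)
    )
    if set(query.species) != set(reference.species):
        raise ValueError("query and reference species sets differ")
    missing = set(topology.leaf_indices) - set(query.species)
    if missing:
        raise ValueError(f"alignments lack species {sorted(missing)}")
    if query.length < config.min_query_len:
        raise ValueError(
            f"query length {query.length} < minimum {config.min_query_len}"
        )
    if reference.length < config.min_ref_len:
        logger.warning(
            "reference is %d bp; at least %d bp is recommended",
            reference.length, config.min_ref_len,
        )
    rng = np.random.default_rng(config.seed)
    query_pt = compress_patterns(query)
    ref_pt = compress_patterns(reference)
    # base frequencies from the (longer, neutral) reference
    pi = empirical_base_frequencies(reference)

    # stage 1: neutral branch lengths + substitution parameters from the
    # reference alone (also the initializer for the joint mode)
    stage1 = fit_tree_model(reference, topology, config.family, pi=pi)
    tree, subst = stage1.tree, stage1.model

    if config.mode == "two_stage":
        ref_lik = pattern_likelihoods(ref_pt, tree, subst)
        lnL_ref = float(np.dot(ref_pt.counts, np.log(ref_lik)))
        qn, mle_null, used_n = fit_selection_model(
            "null", query_pt, tree, subst, foreground,
            n_restarts=config.n_restarts, rng=rng,
        )
        qa, mle_alt, used_a = fit_selection_model(
            "alt", query_pt, tree, subst, foreground,
            n_restarts=config.n_restarts, rng=rng,
            extra_starts=[_null_to_alt(mle_null)],
        )
        lnL_null, lnL_alt = lnL_ref + qn, lnL_ref + qa
        fitted_tree = tree
    elif config.mode == "joint":
        fitter = _JointFitter(query_pt, ref_pt, topology, subst, foreground)
        blen0 = stage1.tree.blen[topology.branch_nodes()]
        # scout the mixture landscape on the fixed stage-1 tree, then
        # refine branch lengths and mixture together
        _, null0, used_n = fit_selection_model(
            "null", query_pt, tree, subst, foreground,
            n_restarts=config.n_restarts, rng=rng, polish=1,
        )
        lnL_null, mle_null, tree_n = fitter.refine("null", blen0, null0)
        _, alt0, used_a = fit_selection_model(
            "alt", query_pt, tree, subst, foreground,
            n_restarts=config.n_restarts, rng=rng,
            extra_starts=[_null_to_alt(null0)], polish=1,
        )
        lnL_alt, mle_alt, tree_a = fitter.refine("alt", blen0, alt0)
        # nesting guard: also refine the alternative from the null's own
        # joint solution (ζ3 at its lower bound reproduces the null)
        lnL_alt2, mle_alt2, tree_a2 = fitter.refine(
            "alt", tree_n.blen[topology.branch_nodes()], _null_to_alt(mle_null)
        )
        if lnL_alt2 > lnL_alt:
            lnL_alt, mle_alt, tree_a = lnL_alt2, mle_alt2, tree_a2
        fitted_tree = tree_a
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    stat, p = lrt_pvalue(lnL_null, lnL_alt)
    return SelectionResult(
        lnL_null=lnL_null,
        lnL_alt=lnL_alt,
        LRT=stat,
        p=p,
        zeta=estimate_zeta(mle_alt),
        mle_null=mle_null,
        mle_alt=mle_alt,
        foreground=foreground if isinstance(foreground, str) else ",".join(foreground),
        query_id=str(query.meta.get("id", "")),
        ref_id=str(reference.meta.get("id", "")),
        n_restarts_used=used_n + used_a,
        seed=config.seed,
        tree=fitted_tree,
    )
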
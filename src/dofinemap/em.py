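"""Two-component Dirichlet-multinomial mixture and its EM fit.

Model
-----
For each gene-marker association g with p_g candidate SNPs, a latent
Bernoulli(gamma) indicator V_g says whether any candidate is causal and a
latent one-hot Z_g ~ Multinomial(1, Theta_g) picks the causal SNP, with
Theta_g ~ Dirichlet(Pi_g) informed by multi-omics priors.  The observed
trinarized DO allelic pattern Y~ is summarized by edit-distance counts:
against the causal candidate's genotype-effect pattern R~_k (5 classical
trials with cell probabilities a1, 3 wild trials with b1) under V_g = 1, or
against the founder-expression pattern B~ (a0, b0) under V_g = 0.

Fitting
-------
EM with soft responsibilities: the E-step computes the posterior over
(V_g, Z_g) per gene in log space; the M-step plugs the responsibilities
into pseudocounted multinomial MLEs for (a0, a1, b0, b1), the MAP update of
Theta_g under its Dirichlet prior, and the mean responsibility for gamma.
A hard (argmax-imputation) variant is available via ``em_mode='hard'``.
Multiple seeded restarts guard against local optima; the monitored
objective is the penalized observed-data log likelihood (mixture likelihood
plus Dirichlet prior density on Theta and the pseudocount regularizers),
which the soft EM increases monotonically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .datamodel import (
    EqtlInstance,
    FounderExpression,
    StrainPanel,
    edit_distance_counts,
    standardize_and_trinarize,
)
from .prior import GenePrior

logger = logging.getLogger(__name__)

_SIMPLEX_TOL = 1e-12


@dataclass
class ModelData:
    """Edit-distance sufficient statistics in flat arrays.

    ``cand_counts`` stacks the causal-pairing counts (n0,n1,n2,m0,m1,m2) of
    all candidates of all genes; ``gene_index`` maps each row to its gene;
    ``null_counts`` holds one null-pairing row per gene.
    """

    gene_ids: list[str]
    p: np.ndarray                  # (G,) candidate counts per gene
    gene_index: np.ndarray         # (P,) gene index per candidate row
    cand_counts: np.ndarray        # (P, 6)
    null_counts: np.ndarray        # (G, 6)
    snp_ids: list[str]             # (P,) flattened candidate SNP ids

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_candidates(self) -> int:
        return int(self.p.sum())

    @property
    def offsets(self) -> np.ndarray:
        """Start index of each gene's candidate block."""
        return np.concatenate([[0], np.cumsum(self.p)[:-1]]).astype(int)


def build_model_data(
    instances: list[EqtlInstance],
    expr: dict[str, FounderExpression],
    panel: StrainPanel,
    cutoff: float = 0.2,
    alpha: float = 0.05,
) -> ModelData:
    """Trinarize all vectors and assemble the edit-distance count arrays."""
    cidx, widx = panel.classical_idx, panel.wild_idx
    gene_ids, p, gidx, ccounts, ncounts, snp_ids = [], [], [], [], [], []
    for g, inst in enumerate(instances):
        if inst.p < 1:
            raise ValueError(f"{inst.gene_id}: association has no candidate SNPs")
        if inst.gene_id not in expr:
            raise KeyError(f"{inst.gene_id}: missing founder expression")
        y = standardize_and_trinarize(inst.allelic_effects, panel, cutoff)
        b = standardize_and_trinarize(expr[inst.gene_id].expression, panel, cutoff)
        ncounts.append(edit_distance_counts(y, b, panel).as_array())
        # vectorized candidate counts (same arithmetic as edit_distance_counts)
        effects = np.array([s.effect for s in inst.candidates])
        pvals = np.array([s.effect_pvalue for s in inst.candidates])
        genos = np.array([s.genotypes for s in inst.candidates])
        codes = np.where(pvals < alpha, np.sign(effects), 0.0).astype(int)
        r_rows = codes[:, None] * genos
        d = np.abs(y[None, :].astype(int) - r_rows)
        block = np.stack(
            [(d[:, cidx] == i).sum(axis=1) for i in range(3)]
            + [(d[:, widx] == i).sum(axis=1) for i in range(3)],
            axis=1,
        )
        ccounts.append(block.astype(float))
        gidx.append(np.full(inst.p, g))
        snp_ids.extend(s.snp_id for s in inst.candidates)
        gene_ids.append(inst.gene_id)
        p.append(inst.p)
    return ModelData(
        gene_ids=gene_ids,
        p=np.asarray(p, dtype=int),
        gene_index=np.concatenate(gidx),
        cand_counts=np.vstack(ccounts),
        null_counts=np.asarray(ncounts, dtype=float),
        snp_ids=snp_ids,
    )


def model_data_from_counts(
    gene_ids: list[str],
    cand_counts_per_gene: list[np.ndarray],
    null_counts: np.ndarray,
    snp_ids: list[list[str]] | None = None,
) -> ModelData:
    """Assemble ModelData directly from per-gene count arrays (tests, sims)."""
    p = np.array([c.shape[0] for c in cand_counts_per_gene], dtype=int)
    gidx = np.repeat(np.arange(len(gene_ids)), p)
    if snp_ids is None:
        snp_ids = [[f"{gid}_snp{k}" for k in range(pg)] for gid, pg in zip(gene_ids, p)]
    return ModelData(
        gene_ids=list(gene_ids),
        p=p,
        gene_index=gidx,
        cand_counts=np.vstack(cand_counts_per_gene).astype(float),
        null_counts=np.asarray(null_counts, dtype=float),
        snp_ids=[s for block in snp_ids for s in block],
    )


def _check_simplex(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (3,) or not np.all(np.isfinite(v)) or np.any(v < 0) \
            or abs(v.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} must be a probability triple summing to 1, got {v}")
    return v


@dataclass
class ModelParams:
    """Mixture parameters: four multinomial triples, gamma, and Theta.

    ``theta`` is flattened across genes in candidate order (aligned with
    ``ModelData.gene_index``).
    """

    a0: np.ndarray
    a1: np.ndarray
    b0: np.ndarray
    b1: np.ndarray
    gamma: float
    theta: np.ndarray

    def __post_init__(self) -> None:
        self.a0 = _check_simplex(self.a0, "a0")
        self.a1 = _check_simplex(self.a1, "a1")
        self.b0 = _check_simplex(self.b0, "b0")
        self.b1 = _check_simplex(self.b1, "b1")
        if not 0.0 < self.gamma < 1.0:
            raise ValueError("gamma must lie in (0, 1)")
        self.theta = np.asarray(self.theta, dtype=float)


@dataclass
class Responsibilities:
    """Posterior of (V_g, Z_g) per gene: w over candidates, w_null, v_hat."""

    w: np.ndarray        # (P,)
    w_null: np.ndarray   # (G,)
    v_hat: np.ndarray    # (G,)


@dataclass
class FitResult:
    params: ModelParams
    responsibilities: Responsibilities
    objective_trace: list[float]
    all_traces: list[list[float]]
    n_restarts: int
    best_restart: int
    seed: int
    converged: bool
    n_iterations: int


@dataclass
class FitConfig:
    restarts: int = 10
    max_iter: int = 500
    tol: float = 1e-8
    seed: int = 0
    lam: tuple[float, float, float] = (0.1, 0.01, 0.0)
    em_mode: str = "soft"


def _log_prob(triple_a: np.ndarray, triple_b: np.ndarray) -> np.ndarray:
    """log cell probabilities (log a_0..2, log b_0..2) with log 0 = -inf."""
    with np.errstate(divide="ignore"):
        return np.concatenate([np.log(triple_a), np.log(triple_b)])


def causal_loglik(counts, a1, b1) -> float:
    """Log likelihood of one candidate's counts under the causal kernel.

    Sum_i n_i log a1_i + m_i log b1_i with the 0 * log 0 = 0 convention;
    -inf when a zero-probability cell holds a positive count.
    """
    arr = counts.as_array() if hasattr(counts, "as_array") else np.asarray(counts, float)
    logp = _log_prob(np.asarray(a1, float), np.asarray(b1, float))
    with np.errstate(invalid="ignore"):
        terms = np.where(arr > 0, arr * logp, 0.0)
    return float(terms.sum())


def null_loglik(counts0, a0, b0) -> float:
    """Log likelihood of the null pairing's counts under (a0, b0)."""
    return causal_loglik(counts0, a0, b0)


def _counts_loglik(counts: np.ndarray, logp: np.ndarray) -> np.ndarray:
    """Vectorized count log likelihood for a (N, 6) block."""
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, counts * logp, 0.0).sum(axis=1)


def _segment_max(values: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    return np.maximum.reduceat(values, offsets)


def _segment_sum(values: np.ndarray, gene_index: np.ndarray, n_genes: int) -> np.ndarray:
    return np.bincount(gene_index, weights=values, minlength=n_genes)


def estep(data: ModelData, params: ModelParams) -> Responsibilities:
    """Posterior responsibilities over (V_g, Z_g), normalized in log space.

    w_k is proportional to gamma * theta_{g,k} * L1_{g,k}; w_null to
    (1 - gamma) * L0_g.  Genes where every component underflows to -inf get
    uniform responsibilities with a warning.
    """
    G = data.n_genes
    ll1 = _counts_loglik(data.cand_counts, _log_prob(params.a1, params.b1))
    ll0 = _counts_loglik(data.null_counts, _log_prob(params.a0, params.b0))
    with np.errstate(divide="ignore"):
        log_w = np.log(params.gamma) + np.log(params.theta) + ll1
        log_null = np.log1p(-params.gamma) + ll0
    seg_max = np.maximum(_segment_max(log_w, data.offsets), log_null)
    degenerate = ~np.isfinite(seg_max)
    if degenerate.any():
        logger.warning("%d gene(s) with fully degenerate likelihood; using uniform "
                       "responsibilities", int(degenerate.sum()))
        seg_max = np.where(degenerate, 0.0, seg_max)
        log_w = np.where(degenerate[data.gene_index], 0.0, log_w)
        log_null = np.where(degenerate, 0.0, log_null)
    u = np.exp(log_w - seg_max[data.gene_index])
    u_null = np.exp(log_null - seg_max)
    denom = _segment_sum(u, data.gene_index, G) + u_null
    w = u / denom[data.gene_index]
    w_null = u_null / denom
    if _hard_mode_flag.enabled:
        best = np.zeros(data.n_candidates)
        seg_best = _segment_max(w, data.offsets)
        causal = seg_best > w_null
        is_best = w >= (seg_best[data.gene_index] - 1e-15)
        # keep a single argmax per gene: first index attaining the max
        first = np.zeros_like(is_best)
        for g, off in enumerate(data.offsets):
            if causal[g]:
                block = np.nonzero(is_best[off : off + data.p[g]])[0]
                first[off + block[0]] = True
        best[first] = 1.0
        w = best
        w_null = 1.0 - _segment_sum(w, data.gene_index, G)
    v_hat = 1.0 - w_null
    return Responsibilities(w=w, w_null=w_null, v_hat=v_hat)


class _HardModeFlag:
    enabled = False


_hard_mode_flag = _HardModeFlag()


def mstep(
    data: ModelData,
    resp: Responsibilities,
    pi_flat: np.ndarray,
    lam: tuple[float, float, float] = (0.1, 0.01, 0.0),
) -> ModelParams:
    """Pseudocounted multinomial MLEs, MAP Theta, and gamma update.

    The pseudocount lambda_i * p_g enters each of the four weighted count
    sums per gene; the MAP Theta update is the Dirichlet(Pi + soft counts)
    mode with the denominator floored (binding only under a flat prior with
    vanishing responsibilities, where Theta falls back to uniform).
    """
    lam = np.asarray(lam, dtype=float)
    P_total = float(data.p.sum())
    wc = resp.w[:, None] * data.cand_counts          # (P, 6)
    causal_sums = wc.sum(axis=0)                     # N_0..2, M_0..2
    null_sums = (resp.w_null[:, None] * data.null_counts).sum(axis=0)
    pseudo = lam * P_total
    N = causal_sums[:3] + pseudo
    M = causal_sums[3:] + pseudo
    N0 = null_sums[:3] + pseudo
    M0 = null_sums[3:] + pseudo
    def normalize(triple: np.ndarray) -> np.ndarray:
        total = triple.sum()
        # empty component (all-zero sums under zero pseudocounts): uniform
        return triple / total if total > 0 else np.full(3, 1.0 / 3.0)

    a1, b1, a0, b0 = normalize(N), normalize(M), normalize(N0), normalize(M0)

    numer = pi_flat + resp.w - 1.0
    denom = _segment_sum(numer, data.gene_index, data.n_genes)
    floored = denom <= _SIMPLEX_TOL
    if floored.any():
        logger.debug("MAP Theta denominator floored for %d gene(s); uniform fallback",
                     int(floored.sum()))
    theta = np.where(
        floored[data.gene_index],
        (1.0 / data.p)[data.gene_index],
        numer / np.where(denom <= _SIMPLEX_TOL, 1.0, denom)[data.gene_index],
    )
    gamma = float(np.clip(resp.v_hat.mean(), 1e-6, 1.0 - 1e-6))
    return ModelParams(a0=a0, a1=a1, b0=b0, b1=b1, gamma=gamma, theta=theta)


def objective(
    data: ModelData,
    params: ModelParams,
    pi_flat: np.ndarray,
    lam: tuple[float, float, float] = (0.1, 0.01, 0.0),
) -> float:
    """Penalized observed-data objective monitored for convergence.

    Mixture log likelihood summed over genes, plus the Dirichlet prior log
    density of Theta_g, plus the pseudocount regularizers on the four
    multinomial triples (lambda terms with lambda_i = 0 contribute 0 even
    when the corresponding cell probability is 0).
    """
    lam = np.asarray(lam, dtype=float)
    G = data.n_genes
    ll1 = _counts_loglik(data.cand_counts, _log_prob(params.a1, params.b1))
    ll0 = _counts_loglik(data.null_counts, _log_prob(params.a0, params.b0))
    with np.errstate(divide="ignore"):
        log_w = np.log(params.gamma) + np.log(params.theta) + ll1
        log_null = np.log1p(-params.gamma) + ll0
    seg_max = np.maximum(_segment_max(log_w, data.offsets), log_null)
    safe = np.where(np.isfinite(seg_max), seg_max, 0.0)
    mix = safe + np.log(
        _segment_sum(np.exp(log_w - safe[data.gene_index]), data.gene_index, G)
        + np.exp(log_null - safe)
    )
    # Dirichlet prior density of Theta_g at Pi_g, with (pi-1)*log(theta)
    # terms vanishing when pi == 1 regardless of theta.
    pi_sum = _segment_sum(pi_flat, data.gene_index, G)
    log_norm = gammaln(pi_sum) - _segment_sum(gammaln(pi_flat), data.gene_index, G)
    coef = pi_flat - 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        theta_terms = np.where(coef != 0.0, coef * np.log(params.theta), 0.0)
    dir_term = log_norm + _segment_sum(theta_terms, data.gene_index, G)
    P_total = float(data.p.sum())
    pseudo_term = 0.0
    for triple in (params.a0, params.a1, params.b0, params.b1):
        for i in range(3):
            if lam[i] > 0:
                pseudo_term += lam[i] * P_total * (
                    np.log(triple[i]) if triple[i] > 0 else -np.inf
                )
    return float(mix.sum() + dir_term.sum() + pseudo_term)


def init_params(
    data: ModelData, pi_flat: np.ndarray, rng: np.random.Generator
) -> ModelParams:
    """Random restart initialization.

    The causal triples start tilted toward low edit distances (Dirichlet
    jitter around (0.7, 0.2, 0.1)), the null triples around uniform;
    gamma starts at 0.5 and Theta proportional to the prior weights.
    """
    a1 = rng.dirichlet(50.0 * np.array([0.7, 0.2, 0.1]))
    b1 = rng.dirichlet(50.0 * np.array([0.7, 0.2, 0.1]))
    a0 = rng.dirichlet(50.0 * np.ones(3) / 3.0)
    b0 = rng.dirichlet(50.0 * np.ones(3) / 3.0)
    pi_sum = _segment_sum(pi_flat, data.gene_index, data.n_genes)
    theta = pi_flat / pi_sum[data.gene_index]
    return ModelParams(a0=a0, a1=a1, b0=b0, b1=b1, gamma=0.5, theta=theta)


def fit(data: ModelData, priors: list[GenePrior], config: FitConfig | None = None) -> FitResult:
    """Multi-restart EM fit; returns the restart with the best objective.

    Deterministic given ``config.seed``: each restart draws its
    initialization from an independent spawned substream.  Restart ties
    (objectives within 1e-12) keep the lowest restart index.
    """
    config = config or FitConfig()
    if config.em_mode not in ("soft", "hard"):
        raise ValueError("em_mode must be 'soft' or 'hard'")
    pi_flat = np.concatenate([gp.pi for gp in priors])
    if pi_flat.shape[0] != data.n_candidates:
        raise ValueError("priors are not aligned with the model data")
    streams = np.random.SeedSequence(config.seed).spawn(config.restarts)
    best = None
    all_traces: list[list[float]] = []
    _hard_mode_flag.enabled = config.em_mode == "hard"
    try:
        for r in range(config.restarts):
            rng = np.random.default_rng(streams[r])
            params = init_params(data, pi_flat, rng)
            trace = [objective(data, params, pi_flat, config.lam)]
            converged = False
            resp = None
            for _ in range(config.max_iter):
                resp = estep(data, params)
                params = mstep(data, resp, pi_flat, config.lam)
                obj = objective(data, params, pi_flat, config.lam)
                rel = abs(obj - trace[-1]) / (abs(trace[-1]) + 1.0)
                trace.append(obj)
                if rel < config.tol:
                    converged = True
                    break
            if resp is None:
                resp = estep(data, params)
            all_traces.append(trace)
            candidate = (trace[-1], r, params, resp, trace, converged)
            if best is None or candidate[0] > best[0] + 1e-12:
                best = candidate
    finally:
        _hard_mode_flag.enabled = False
    obj, r, params, resp, trace, converged = best
    if not converged:
        logger.warning("EM did not converge within %d iterations (best restart %d)",
                       config.max_iter, r)
    return FitResult(
        params=params,
        responsibilities=resp,
        objective_trace=trace,
        all_traces=all_traces,
        n_restarts=config.restarts,
        best_restart=r,
        seed=config.seed,
        converged=converged,
        n_iterations=len(trace) - 1,
    )
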
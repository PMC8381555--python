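"""Posterior summaries: FDR calls, credible sets, selection strategies.

Gene-level calls use direct posterior probability FDR control: genes are
ranked by the posterior probability of harboring a causal SNP and the
largest prefix whose mean null posterior stays below the target rate is
selected.  SNP-level summaries condition on causality (posteriors
renormalized by v_hat) and yield credible sets, most/least-likely picks,
baseline selection strategies, and prior-component attribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datamodel import EqtlInstance
from .em import FitResult, ModelData
from .prior import COMPONENT_NAMES, GenePrior

STRATEGIES = ("most_likely", "least_likely", "random", "closest_marker", "closest_gene")


def fdr_select(v_hats: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Direct-posterior-probability FDR selection of causal-SNP genes.

    Sort descending by v_hat and take the largest prefix whose mean
    (1 - v_hat) is at most ``alpha``.  Genes tied at the cut value are
    included together when the extended prefix still satisfies the bound,
    otherwise excluded together.
    """
    v = np.asarray(v_hats, dtype=float)
    flags = np.zeros(v.shape[0], dtype=bool)
    if v.size == 0:
        return flags
    order = np.argsort(-v, kind="stable")
    sv = v[order]
    cum_null = np.cumsum(1.0 - sv) / np.arange(1, v.size + 1)
    # prefix lengths are only considered at tie-group boundaries
    boundaries = np.nonzero(np.diff(sv) != 0)[0].tolist() + [v.size - 1]
    best_len = 0
    for b in boundaries:
        if cum_null[b] <= alpha:
            best_len = b + 1
    flags[order[:best_len]] = True
    return flags


def credible_set(
    snp_posteriors: np.ndarray,
    snp_ids: list[str],
    threshold: float = 0.80,
    max_fraction: float = 0.5,
) -> tuple[list[str], bool]:
    """Smallest posterior-descending prefix reaching cumulative ``threshold``.

    Returns the ordered SNP ids and whether the set is informative, i.e.
    strictly smaller than ``max_fraction`` of the candidates.
    """
    post = np.asarray(snp_posteriors, dtype=float)
    order = np.argsort(-post, kind="stable")
    cum = np.cumsum(post[order])
    size = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    size = min(size, post.size)
    members = [snp_ids[i] for i in order[:size]]
    informative = size / post.size < max_fraction
    return members, informative


def select_strategies(
    instance: EqtlInstance,
    snp_posteriors: np.ndarray,
    rng: np.random.Generator,
) -> dict[str, str]:
    """Pick one SNP per selection strategy.

    Posterior and distance ties break toward the lower genomic coordinate;
    the random strategy consumes the provided seeded generator.
    """
    post = np.asarray(snp_posteriors, dtype=float)
    pos = np.array([c.pos for c in instance.candidates])
    d_marker = np.array([c.dist_to_marker for c in instance.candidates])
    d_gene = np.array([c.dist_to_promoter for c in instance.candidates])

    def pick(keys_desc: np.ndarray) -> str:
        best = np.max(keys_desc)
        tied = np.nonzero(keys_desc == best)[0]
        k = tied[np.argmin(pos[tied])]
        return instance.candidates[k].snp_id

    return {
        "most_likely": pick(post),
        "least_likely": pick(-post),
        "random": instance.candidates[int(rng.integers(instance.p))].snp_id,
        "closest_marker": pick(-d_marker),
        "closest_gene": pick(-d_gene),
    }


def _rank_of(keys: np.ndarray, index: int, pos: np.ndarray) -> int:
    """1-based rank of ``index`` when sorting ascending by (key, position)."""
    order = np.lexsort((pos, keys))
    return int(np.nonzero(order == index)[0][0]) + 1


def credible_proportion(
    instance: EqtlInstance,
    snp_posteriors: np.ndarray | None,
    true_snp: str,
    strategy: str = "most_likely",
    rng: np.random.Generator | None = None,
) -> float:
    """Rank of the causal SNP under a strategy's ranking, divided by p_g.

    The ranking is posterior-descending for ``most_likely``,
    posterior-ascending for ``least_likely``, distance-ascending for the
    closest-to-marker/gene baselines, and a uniformly random order for
    ``random``.
    """
    ids = [c.snp_id for c in instance.candidates]
    if true_snp not in ids:
        raise ValueError(f"causal SNP {true_snp} not among candidates")
    idx = ids.index(true_snp)
    pos = np.array([c.pos for c in instance.candidates], dtype=float)
    if strategy == "most_likely":
        keys = -np.asarray(snp_posteriors, dtype=float)
    elif strategy == "least_likely":
        keys = np.asarray(snp_posteriors, dtype=float)
    elif strategy == "closest_marker":
        keys = np.array([c.dist_to_marker for c in instance.candidates], dtype=float)
    elif strategy == "closest_gene":
        keys = np.array([c.dist_to_promoter for c in instance.candidates], dtype=float)
    elif strategy == "random":
        if rng is None:
            raise ValueError("random strategy requires a generator")
        keys = rng.permutation(instance.p).astype(float)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return _rank_of(keys, idx, pos) / instance.p


def contributor_rank_scores(
    components: np.ndarray, causal_index: int
) -> tuple[dict[str, float], str]:
    """Rank-score attribution of the prior components for the causal SNP.

    Each component column is ranked ascending across the p_g candidates
    (average ranks on ties) and the causal SNP's rank is normalized by p_g.
    The leading contributor is the component with the highest score (first
    in (F, D, cor_AE, cor_AB) order on ties).
    """
    comps = np.asarray(components, dtype=float)
    p = comps.shape[0]
    scores = {}
    for j, name in enumerate(COMPONENT_NAMES):
        ranks = rankdata(comps[:, j], method="average")
        scores[name] = float(ranks[causal_index] / p)
    leading = max(COMPONENT_NAMES, key=lambda nm: scores[nm])
    return scores, leading


@dataclass
class PosteriorResult:
    """Per-gene posterior summary."""

    gene_id: str
    v_hat: float
    fdr_called: bool
    snp_ids: list[str]
    snp_posteriors: np.ndarray
    credible_set: list[str]
    credible_informative: bool
    most_likely: str
    least_likely: str


def summarize(
    data: ModelData,
    fit: FitResult,
    instances: list[EqtlInstance],
    alpha: float = 0.05,
    threshold: float = 0.80,
    max_fraction: float = 0.5,
    seed: int = 0,
) -> list[PosteriorResult]:
    """Assemble per-gene posterior summaries from a fitted model.

    SNP posteriors are the responsibilities conditioned on V_g = 1
    (w_{g,k} / v_hat); genes with v_hat = 0 get no credible set.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    flags = fdr_select(fit.responsibilities.v_hat, alpha)
    results = []
    offsets = data.offsets
    for g, inst in enumerate(instances):
        sl = slice(offsets[g], offsets[g] + data.p[g])
        w = fit.responsibilities.w[sl]
        v = float(fit.responsibilities.v_hat[g])
        ids = data.snp_ids[sl.start : sl.stop]
        if v > 0:
            post = w / v
            cs, informative = credible_set(post, ids, threshold, max_fraction)
        else:
            post = np.zeros_like(w)
            cs, informative = [], False
        picks = select_strategies(inst, post, rng)
        results.append(
            PosteriorResult(
                gene_id=inst.gene_id,
                v_hat=v,
                fdr_called=bool(flags[g]),
                snp_ids=list(ids),
                snp_posteriors=post,
                credible_set=cs,
                credible_informative=informative,
                most_likely=picks["most_likely"],
                least_likely=picks["least_likely"],
            )
        )
    return results


def results_table(results: list[PosteriorResult]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": r.gene_id,
            "v_hat": r.v_hat,
            "fdr_called": r.fdr_called,
            "credible_set": ",".join(r.credible_set),
            "credible_fraction": len(r.credible_set) / max(1, len(r.snp_ids)),
            "most_likely": r.most_likely,
            "least_likely": r.least_likely,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def snp_posterior_table(results: list[PosteriorResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for sid, w in zip(r.snp_ids, r.snp_posteriors):
            rows.append({"gene_id": r.gene_id, "snp_id": sid, "posterior": float(w)})
    return pd.DataFrame(rows)


def contributor_table(
    results: list[PosteriorResult], priors: list[GenePrior]
) -> pd.DataFrame:
    """Rank scores of the prior components at each gene's most likely SNP."""
    rows = []
    for r, gp in zip(results, priors):
        if not r.fdr_called:
            continue
        idx = r.snp_ids.index(r.most_likely)
        scores, leading = contributor_rank_scores(gp.components, idx)
        row = {"gene_id": r.gene_id, "snp_id": r.most_likely, "leading": leading}
        row.update({f"score_{k}": v for k, v in scores.items()})
        rows.append(row)
    return pd.DataFrame(rows)
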
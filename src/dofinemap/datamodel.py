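"""Core data types and featurization primitives.

The package works with the eight Diversity Outbred (DO) founder strains.
Allelic-effect and expression vectors are always ordered according to a
:class:`StrainPanel`.  Continuous 8-strain vectors are reduced to trinary
allelic patterns (codes in {-1, 0, +1} relative to the reference strain B6),
and pairs of trinarized vectors are summarized by edit-distance counts over
the classical and wild-derived strain groups.  These counts are the
sufficient statistics of the mixture model in :mod:`dofinemap.em`.

Coordinates are 0-based half-open internally; TSV inputs carry 1-based
positions (converted by :mod:`dofinemap.io`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Default trinarization cutoff on standardized, reference-centered effects.
DEFAULT_CUTOFF = 0.2

#: Default candidate window half-width around the eQTL marker, in bp.
DEFAULT_WINDOW_BP = 1_000_000


@dataclass(frozen=True)
class StrainPanel:
    """The ordered panel of eight DO founder strains.

    The classical inbred strains (129, AJ, B6, NOD, NZO) and the
    wild-derived strains (CAST, PWK, WSB) play different roles in the
    edit-distance model: the former contribute 5 multinomial trials, the
    latter 3.  B6 is the reference strain.
    """

    strains: tuple[str, ...] = ("129", "AJ", "B6", "CAST", "NOD", "NZO", "PWK", "WSB")
    classical: frozenset[str] = frozenset({"129", "AJ", "B6", "NOD", "NZO"})
    wild: frozenset[str] = frozenset({"CAST", "PWK", "WSB"})
    reference: str = "B6"

    def __post_init__(self) -> None:
        if len(self.strains) != 8 or len(set(self.strains)) != 8:
            raise ValueError("panel must contain 8 distinct strains")
        if len(self.classical) != 5 or len(self.wild) != 3:
            raise ValueError("expected 5 classical and 3 wild-derived strains")
        if self.classical | self.wild != set(self.strains) or self.classical & self.wild:
            raise ValueError("classical and wild sets must partition the panel")
        if self.reference not in self.classical:
            raise ValueError("reference strain must be classical")

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    @property
    def classical_idx(self) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.strains) if s in self.classical])

    @property
    def wild_idx(self) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.strains) if s in self.wild])

    @property
    def reference_idx(self) -> int:
        return self.strains.index(self.reference)


@dataclass
class CandidateSnp:
    """One candidate regulatory variant (local-ATAC-MV) with its features.

    ``atac_signal`` is the normalized accessibility of the harboring peak in
    each strain; ``effect``/``effect_pvalue`` summarize the marginal
    regression of founder expression on this SNP's genotype;
    ``footprint_flag`` is 1 when the SNP significantly perturbs a TF
    footprint (simulation settings may override it with larger values).
    """

    snp_id: str
    chrom: str
    pos: int
    peak_id: str
    atac_signal: np.ndarray
    effect: float
    effect_pvalue: float
    genotypes: np.ndarray
    footprint_flag: float = 0.0
    dist_to_promoter: float = 0.0
    dist_to_marker: float = 0.0

    def __post_init__(self) -> None:
        self.atac_signal = np.asarray(self.atac_signal, dtype=float)
        self.genotypes = np.asarray(self.genotypes, dtype=int)
        if self.atac_signal.shape != (8,) or self.genotypes.shape != (8,):
            raise ValueError(f"{self.snp_id}: ATAC and genotype vectors must have length 8")
        if not set(np.unique(self.genotypes)) <= {0, 1}:
            raise ValueError(f"{self.snp_id}: genotypes must be 0/1")
        if self.footprint_flag < 0:
            raise ValueError(f"{self.snp_id}: footprint flag must be nonnegative")
        if self.dist_to_promoter < 0 or self.dist_to_marker < 0:
            raise ValueError(f"{self.snp_id}: distances must be nonnegative")

    @property
    def genotype_effect(self) -> np.ndarray:
        """8-strain expression effect vector E implied by the marginal fit."""
        return self.effect * self.genotypes.astype(float)


@dataclass
class EqtlInstance:
    """One DO gene-marker association and its candidate window."""

    gene_id: str
    gene_chrom: str
    gene_promoter_pos: int
    marker_chrom: str
    marker_pos: int
    allelic_effects: np.ndarray
    candidates: list[CandidateSnp] = field(default_factory=list)
    lod: float = float("nan")

    def __post_init__(self) -> None:
        self.allelic_effects = np.asarray(self.allelic_effects, dtype=float)
        if self.allelic_effects.shape != (8,):
            raise ValueError(f"{self.gene_id}: allelic-effect vector must have length 8")
        if not np.all(np.isfinite(self.allelic_effects)):
            raise ValueError(f"{self.gene_id}: allelic effects contain missing values")

    @property
    def p(self) -> int:
        """Number of candidate SNPs p_g."""
        return len(self.candidates)


@dataclass
class FounderExpression:
    """Normalized founder expression of one gene (8-strain vector B)."""

    gene_id: str
    expression: np.ndarray

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        if self.expression.shape != (8,) or not np.all(np.isfinite(self.expression)):
            raise ValueError(f"{self.gene_id}: expression must be 8 finite values")


@dataclass(frozen=True)
class EditDistanceCounts:
    """Multinomial sufficient statistics of one trinarized-vector pair.

    ``n`` counts per-strain edit distances 0/1/2 over the five classical
    strains, ``m`` over the three wild-derived strains; the totals are fixed
    by the panel (5 and 3 trials respectively) and enforced here.
    """

    n: tuple[int, int, int]
    m: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.n) != 3 or len(self.m) != 3:
            raise ValueError("counts must be triples over distances {0,1,2}")
        if any(v < 0 for v in self.n) or any(v < 0 for v in self.m):
            raise ValueError("counts must be nonnegative")
        if sum(self.n) != 5:
            raise ValueError(f"classical-strain counts must total 5 trials, got {sum(self.n)}")
        if sum(self.m) != 3:
            raise ValueError(f"wild-strain counts must total 3 trials, got {sum(self.m)}")

    def as_array(self) -> np.ndarray:
        """Concatenated (n0, n1, n2, m0, m1, m2)."""
        return np.array(self.n + self.m, dtype=float)


def trinarize_centered(values: np.ndarray, cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    """Threshold standardized, reference-centered values into {-1, 0, +1}.

    Entries strictly above ``cutoff`` code to +1, strictly below ``-cutoff``
    to -1, all others to 0.
    """
    values = np.asarray(values, dtype=float)
    return (np.where(values > cutoff, 1, 0) + np.where(values < -cutoff, -1, 0)).astype(np.int8)


def standardize_and_trinarize(
    effects: np.ndarray, panel: StrainPanel, cutoff: float = DEFAULT_CUTOFF
) -> np.ndarray:
    """Convert a continuous 8-strain effect vector to a trinary pattern.

    The vector is min-max scaled to [0, 1], the scaled reference (B6) entry
    is subtracted, and the centered values are thresholded at ``cutoff``.
    A constant input carries no information and maps to the all-zero
    pattern.  The reference entry is 0 by construction.
    """
    effects = np.asarray(effects, dtype=float)
    if effects.shape != (panel.n_strains,):
        raise ValueError("expected an 8-strain effect vector")
    if not np.all(np.isfinite(effects)):
        raise ValueError("effect vector contains non-finite entries")
    lo, hi = effects.min(), effects.max()
    if hi == lo:
        return np.zeros(panel.n_strains, dtype=np.int8)
    scaled = (effects - lo) / (hi - lo)
    centered = scaled - scaled[panel.reference_idx]
    return trinarize_centered(centered, cutoff)


def trinarize_genotype_effects(
    effect: float,
    pvalue: float,
    genotypes: np.ndarray,
    alpha: float = 0.05,
) -> np.ndarray:
    """Trinarize one SNP's marginal expression effect into a strain pattern.

    Strains carrying the alternative allele receive sign(effect) when the
    marginal regression is significant at level ``alpha``; all other strains
    (including the reference, which never carries the alternative allele)
    receive 0.
    """
    if not 0.0 <= pvalue <= 1.0:
        raise ValueError("p-value must lie in [0, 1]")
    genotypes = np.asarray(genotypes, dtype=int)
    code = int(np.sign(effect)) if pvalue < alpha else 0
    return (code * genotypes).astype(np.int8)


def distance_score(x_mb):
    """Distance-score prior component D(x) for a SNP at distance ``x`` Mb.

    Flat at the maximum 0.5 up to 0.25 Mb — deliberately not penalizing
    nearby variants — then decays as (5/12) / (10 x - 5/3), continuously at
    the knee.  Accepts scalars or arrays; negative distances are a domain
    error.
    """
    x = np.asarray(x_mb, dtype=float)
    if np.any(x < 0):
        raise ValueError("distance must be nonnegative")
    with np.errstate(divide="ignore"):
        far = (5.0 / 12.0) / (10.0 * x - 5.0 / 3.0)
    out = np.where(x <= 0.25, 0.5, far)
    return float(out) if np.isscalar(x_mb) else out


def edit_distance_counts(
    y: np.ndarray, r: np.ndarray, panel: StrainPanel
) -> EditDistanceCounts:
    """Edit-distance counts between two trinarized 8-strain patterns.

    Per-strain distance d_s = |y_s - r_s| in {0, 1, 2}; ``n`` tallies d over
    the classical strains, ``m`` over the wild-derived strains.  The same
    operation serves the causal pairing (Y~ vs R~) and the null pairing
    (Y~ vs B~).
    """
    y = np.asarray(y, dtype=int)
    r = np.asarray(r, dtype=int)
    if y.shape != (8,) or r.shape != (8,):
        raise ValueError("trinarized vectors must have length 8")
    if not (set(np.unique(y)) <= {-1, 0, 1} and set(np.unique(r)) <= {-1, 0, 1}):
        raise ValueError("trinarized vectors must take values in {-1, 0, +1}")
    d = np.abs(y - r)
    n = tuple(int(np.sum(d[panel.classical_idx] == i)) for i in range(3))
    m = tuple(int(np.sum(d[panel.wild_idx] == i)) for i in range(3))
    return EditDistanceCounts(n=n, m=m)


def candidate_window(
    marker_chrom: str,
    marker_pos: int,
    snps: list[CandidateSnp],
    window_bp: int = DEFAULT_WINDOW_BP,
) -> list[CandidateSnp]:
    """Candidate SNPs within ``marker_pos`` +/- ``window_bp`` (closed interval).

    SNPs on other chromosomes are excluded; the result is sorted by
    position.
    """
    kept = [
        s
        for s in snps
        if s.chrom == marker_chrom and abs(s.pos - marker_pos) <= window_bp
    ]
    return sorted(kept, key=lambda s: s.pos)
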
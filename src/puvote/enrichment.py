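"""Permutation-based gene set enrichment and companion statistics.

The enrichment score (ES) is the classic Kolmogorov–Smirnov running sum:
walking down a ranked gene list, each hit increments the sum by
|score|^p / sum(|score_hits|^p) and each miss decrements it by
1/(N - N_hits); the ES is the signed maximum deviation from zero.  With
weight exponent p = 0 (the default) the increments reduce to 1/N_hits and
the ES depends only on the hit positions, which makes small exhaustive
oracles exact and the statistic invariant under monotone transforms of the
scores.

Significance comes from permuting the gene-to-score assignment (or,
equivalently under exchangeability, the set membership): z is the observed
ES standardized by the permutation null, and p uses the add-one estimator
(1 + #{|ES_null| >= |ES_obs|}) / (1 + n_perm), which can never return 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import AnnotationTable, EXPERIMENTAL_EVIDENCE

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    es: float
    perm_mean: float | None = None
    perm_sd: float | None = None
    z: float | None = None
    p: float | None = None
    n_perm: int = 0
    hits: int = 0
    misses: int = 0
    leading_edge: list[str] = field(default_factory=list)
    running_sum: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "es": self.es,
            "perm_mean": self.perm_mean,
            "perm_sd": self.perm_sd,
            "z": self.z,
            "p": self.p,
            "n_perm": self.n_perm,
            "hits": self.hits,
            "misses": self.misses,
            "leading_edge": list(self.leading_edge),
        }


def _ranked_order(scores: pd.Series, seed: int = 0) -> pd.Series:
    """Sort descending; ties broken by stable order after a seed-fixed
    shuffle (deterministic, no systematic bias)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(scores))
    shuffled = scores.iloc[perm]
    order = np.argsort(-shuffled.to_numpy(), kind="stable")
    return shuffled.iloc[order]


def _running_sum(
    hit_mask: np.ndarray, sorted_scores: np.ndarray, weight_exponent: float
) -> np.ndarray:
    n = hit_mask.size
    n_hits = int(hit_mask.sum())
    if n_hits == 0 or n_hits == n:
        # degenerate normalization: all-hit list climbs to 1.0 at the end
        steps = np.where(hit_mask, 1.0 / max(n_hits, 1), 0.0)
        return np.cumsum(steps)
    if weight_exponent == 0:
        inc = np.full(n, 1.0 / n_hits)
    else:
        mag = np.abs(sorted_scores) ** weight_exponent
        total = mag[hit_mask].sum()
        if total == 0:
            inc = np.full(n, 1.0 / n_hits)
        else:
            inc = mag / total
    dec = 1.0 / (n - n_hits)
    steps = np.where(hit_mask, inc, -dec)
    return np.cumsum(steps)


def gsea_es(
    scores: pd.Series,
    hit_set: set[str],
    weight_exponent: float = 0.0,
    seed: int = 0,
) -> EnrichmentResult:
    """Enrichment score and running-sum curve of ``hit_set`` on the genes
    ranked by ``scores`` (descending).

    The leading edge is the set of hits at or before the rank where the
    running sum attains its extremum.
    """
    hit_set = set(hit_set)
    ranked = _ranked_order(scores, seed)
    genes = list(ranked.index)
    mask = np.array([g in hit_set for g in genes])
    if not mask.any():
        raise ValueError("hit set does not intersect the ranked list")
    curve = _running_sum(mask, ranked.to_numpy(dtype=float), weight_exponent)
    i_ext = int(np.argmax(np.abs(curve)))
    es = float(curve[i_ext])
    leading = [g for g, h in zip(genes[: i_ext + 1], mask[: i_ext + 1]) if h]
    return EnrichmentResult(
        es=es,
        hits=int(mask.sum()),
        misses=int((~mask).sum()),
        leading_edge=leading,
        running_sum=curve,
    )


def _null_es(
    n: int,
    n_hits: int,
    sorted_scores: np.ndarray,
    weight_exponent: float,
    n_perm: int,
    rng: np.random.Generator,
    chunk: int = 512,
) -> np.ndarray:
    """Null ES values with hit positions drawn uniformly without
    replacement.  Permuting gene-to-score assignment and permuting set
    membership both reduce to this null for a fixed ranked score vector."""
    if n_hits >= n:
        # degenerate all-hit list: ES is 1.0 under every permutation
        return np.full(n_perm, 1.0)
    dec = 1.0 / (n - n_hits)
    if weight_exponent == 0:
        base_inc = None
    else:
        mag = np.abs(sorted_scores) ** weight_exponent
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        # vectorized draw of b random hit masks
        u = rng.random((b, n))
        idx = np.argpartition(u, n_hits - 1, axis=1)[:, :n_hits]
        masks = np.zeros((b, n), dtype=bool)
        np.put_along_axis(masks, idx, True, axis=1)
        if weight_exponent == 0:
            steps = np.where(masks, 1.0 / n_hits, -dec)
        else:
            totals = (mag[None, :] * masks).sum(axis=1)
            totals[totals == 0] = 1.0
            steps = np.where(masks, mag[None, :] / totals[:, None], -dec)
        curves = np.cumsum(steps, axis=1)
        ext = np.argmax(np.abs(curves), axis=1)
        out[done : done + b] = curves[np.arange(b), ext]
        done += b
    return out


def permutation_enrichment(
    scores: pd.Series,
    hit_set: set[str],
    n_perm: int = 1000,
    seed: int = 0,
    scheme: str = "scores",
    weight_exponent: float = 0.0,
) -> EnrichmentResult:
    """Observed ES with a permutation null, z-score and add-one p-value.

    ``scheme`` may be "scores" (permute the gene-to-score assignment) or
    "labels" (permute set membership); for a fixed ranked score vector both
    amount to placing the hits uniformly at random, so they share one
    engine.  When the null has zero spread the z is missing but the p is
    still reported.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if scheme not in {"scores", "labels"}:
        raise ValueError("scheme must be 'scores' or 'labels'")
    result = gsea_es(scores, hit_set, weight_exponent, seed)
    ranked = _ranked_order(scores, seed)
    n = len(ranked)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(1,))
    )
    null = _null_es(
        n, result.hits, ranked.to_numpy(dtype=float), weight_exponent, n_perm, rng
    )
    perm_mean = float(null.mean())
    perm_sd = float(null.std(ddof=0))
    result.n_perm = n_perm
    result.perm_mean = perm_mean
    result.perm_sd = perm_sd
    # ties between null and observed |ES| count toward the tail; the small
    # tolerance keeps cumsum rounding from dropping exact ties
    result.p = float(
        (1 + np.sum(np.abs(null) >= abs(result.es) - 1e-12)) / (1 + n_perm)
    )
    if perm_sd > 0:
        result.z = float((result.es - perm_mean) / perm_sd)
    else:
        result.z = None
    return result


def fisher_enrichment(
    in_both: int, in_a_only: int, in_b_only: int, in_neither: int
) -> tuple[float | None, float]:
    """Conditional odds ratio and two-sided exact p for a 2x2 table.

    A zero margin gives p = 1 with the odds ratio missing.
    """
    table = np.array([[in_both, in_a_only], [in_b_only, in_neither]])
    if (table < 0).any():
        raise ValueError("table entries must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return None, 1.0
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


@dataclass
class ProportionCurve:
    """Proportion of reference-set genes among genes scoring >= t, per
    threshold, with a Fisher significance flag at each point."""

    table: pd.DataFrame  # threshold, n_selected, proportion, odds_ratio, p, significant

    def proportions(self) -> pd.Series:
        return self.table.set_index("threshold")["proportion"]


def proportion_curve(
    scores: pd.Series,
    reference_set: set[str],
    thresholds: list[float],
    alpha: float = 0.05,
) -> ProportionCurve:
    """Sweep thresholds over ``scores`` and report the reference-set
    fraction above each one, Fisher-tested against the complement."""
    if len(thresholds) == 0:
        raise ValueError("thresholds must be non-empty")
    ref = set(reference_set)
    genes = scores.index
    is_ref = genes.isin(ref)
    vals = scores.to_numpy(dtype=float)
    rows = []
    for t in sorted(thresholds):
        sel = vals >= t
        n_sel = int(sel.sum())
        if n_sel == 0:
            logger.warning("no genes at threshold %s; point dropped", t)
            continue
        both = int((sel & is_ref).sum())
        odds, p = fisher_enrichment(
            both,
            int((sel & ~is_ref).sum()),
            int((~sel & is_ref).sum()),
            int((~sel & ~is_ref).sum()),
        )
        rows.append(
            {
                "threshold": t,
                "n_selected": n_sel,
                "proportion": both / n_sel,
                "odds_ratio": odds,
                "p": p,
                "significant": p < alpha,
            }
        )
    return ProportionCurve(table=pd.DataFrame(rows))


def jaccard(a: set, b: set) -> float:
    """|A & B| / |A | B|; 0 by convention when both sets are empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


@dataclass
class SimilarityProfile:
    """Jaccard functional similarity of each gene to each core gene.

    ``similarity`` is a genes x core-genes DataFrame of Jaccard indices
    over evidence-filtered annotation-term sets.  For ranking purposes,
    genes with zero similarity to a given core gene are excluded from that
    core gene's list.
    """

    similarity: pd.DataFrame
    core_genes: list[str]

    def ranking(self, core_gene: str) -> pd.Series:
        col = self.similarity[core_gene]
        col = col[col > 0]
        return col.sort_values(ascending=False)


def similarity_profile(
    annotations: AnnotationTable,
    genes: list[str],
    core_genes: list[str],
    evidence_filter: frozenset[str] = EXPERIMENTAL_EVIDENCE,
) -> SimilarityProfile:
    """Jaccard index between each gene's and each core gene's annotated
    term sets (after evidence filtering)."""
    terms = annotations.gene_terms(evidence_filter)
    for cg in core_genes:
        if cg not in terms or not terms[cg]:
            raise ValueError(f"core gene {cg!r} has no surviving annotations")
    data = {
        cg: [jaccard(terms.get(g, frozenset()), terms[cg]) for g in genes]
        for cg in core_genes
    }
    sim = pd.DataFrame(data, index=pd.Index(genes, name="gene"))
    return SimilarityProfile(similarity=sim, core_genes=list(core_genes))


def group_compare(
    values_a: np.ndarray, values_b: np.ndarray
) -> tuple[float, float | None]:
    """One-sided Wilcoxon rank-sum p (direction A > B) and Cohen's d with
    pooled standard deviation (missing when the pooled sd is zero)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need >= 2 values")
    p = float(stats.mannwhitneyu(a, b, alternative="greater").pvalue)
    na, nb = a.size, b.size
    pooled_var = (
        (na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)
    ) / (na + nb - 2)
    if pooled_var == 0:
        return p, None
    d = float((a.mean() - b.mean()) / np.sqrt(pooled_var))
    return p, d


def voted_status_association(
    covariate: pd.Series, voted: pd.Series
) -> tuple[float | None, float | None, bool]:
    """Wald z and p for the slope of a univariate logistic regression of
    voted status (0/1) on a per-gene covariate.

    Returns (z, p, separated).  Under complete separation the fit is
    flagged and z/p are missing.
    """
    import statsmodels.api as sm

    df = pd.DataFrame({"x": covariate, "y": voted}).dropna()
    y = df["y"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both voted and unvoted genes must be present")
    x = sm.add_constant(df["x"].to_numpy(dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, x).fit(disp=False, maxiter=200)
        except (np.linalg.LinAlgError, Exception) as exc:  # separation et al.
            logger.warning("logistic fit failed: %s", exc)
            return None, None, True
    # complete separation: fitted probabilities pinned to 0/1
    prob = fit.predict(x)
    if np.all((prob > 0.999) == (y == 1)) and np.all((prob < 0.001) == (y == 0)):
        return None, None, True
    if not np.isfinite(fit.bse[1]) or fit.bse[1] == 0 or fit.bse[1] > 1e4:
        return None, None, True
    z = float(fit.params[1] / fit.bse[1])
    p = float(fit.pvalues[1])
    return z, p, False
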
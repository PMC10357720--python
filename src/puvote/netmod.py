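"""Functional modules formed by highly-voted candidate genes.

A functional module is the largest connected component of the interaction
subgraph induced by the highly-voted candidates annotated to one functional
term.  "Highly voted" defaults to a vote at or above the median positive
vote of the cohort, a parameter-free cut tied to the vote distribution.
Each module is scored by vote-ranked permutation GSEA (hits = module
members among all candidates), its share of the total positive z across
modules gives its relative significance, and downstream steps assess the
module's activity in a patient contrast (fold-change-ranked GSEA) and its
power as a subtype classifier (repeated stratified hold-outs of a logistic
model on the module genes).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score

from .enrichment import EnrichmentResult, permutation_enrichment
from .io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class FunctionalModule:
    term_id: str
    term_name: str
    member_genes: list[str]
    subgraph: nx.Graph
    enrichment: EnrichmentResult | None = None
    relative_significance: float | None = None

    @property
    def size(self) -> int:
        return len(self.member_genes)

    def to_dict(self) -> dict:
        return {
            "term_id": self.term_id,
            "term_name": self.term_name,
            "member_genes": sorted(self.member_genes),
            "n_edges": self.subgraph.number_of_edges(),
            "z": None if self.enrichment is None else self.enrichment.z,
            "p": None if self.enrichment is None else self.enrichment.p,
            "relative_significance": self.relative_significance,
        }


def highly_voted(votes: pd.Series, threshold: float | None = None) -> pd.Series:
    """Votes of the highly-voted candidates.

    Default threshold: the median vote among candidates with at least one
    vote ("median positive vote").
    """
    voted = votes[votes >= 1]
    if voted.empty:
        return voted
    if threshold is None:
        threshold = float(voted.median())
    return voted[voted >= threshold]


def score_module(
    votes: pd.Series,
    module_genes: list[str],
    n_perm: int = 10000,
    seed: int = 0,
) -> EnrichmentResult:
    """Vote-ranked permutation GSEA of one module over the candidates."""
    missing = set(module_genes) - set(votes.index)
    if missing:
        raise ValueError(f"module genes absent from the ranked universe: {sorted(missing)[:5]}")
    return permutation_enrichment(
        votes, set(module_genes), n_perm=n_perm, seed=seed
    )


def find_modules(
    ppi: nx.Graph,
    votes: pd.Series,
    term_sets: GeneSetCollection,
    min_size: int = 3,
    vote_threshold: float | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[FunctionalModule]:
    """Identify and score the functional modules of the highly-voted
    candidates.

    ``votes`` holds the candidate genes (voted non-seed genes) with their
    vote counts.  For each term the interaction subgraph induced by the
    highly-voted candidates annotated to it is taken; its largest connected
    component is kept as a module if it reaches ``min_size``.  Modules are
    scored by :func:`score_module` on the full candidate ranking and
    returned sorted by decreasing z.
    """
    candidates = set(votes.index)
    if not candidates & set(ppi.nodes):
        raise ValueError("no candidate gene appears in the interaction graph")
    high = highly_voted(votes, vote_threshold)
    modules: list[FunctionalModule] = []
    for ti, term in enumerate(term_sets.names()):
        members = set(term_sets[term]) & set(high.index) & set(ppi.nodes)
        if len(members) < min_size:
            continue
        sub = ppi.subgraph(members)
        components = sorted(nx.connected_components(sub), key=lambda c: (-len(c), sorted(c)))
        if not components or len(components[0]) < min_size:
            continue
        comp = sorted(components[0])
        module = FunctionalModule(
            term_id=term,
            term_name=term_sets.descriptions.get(term, ""),
            member_genes=comp,
            subgraph=nx.Graph(ppi.subgraph(comp)),
        )
        module.enrichment = score_module(
            votes, comp, n_perm=n_perm,
            seed=int(np.random.SeedSequence(entropy=seed, spawn_key=(ti,)).generate_state(1)[0] >> 1),
        )
        modules.append(module)
    if not modules:
        logger.warning("no term yields a module of size >= %d", min_size)
        return []
    modules.sort(
        key=lambda m: (-(m.enrichment.z if m.enrichment.z is not None else -np.inf), m.term_id)
    )
    return modules


def relative_significance(modules: list[FunctionalModule]) -> list[FunctionalModule]:
    """Assign each positively-enriched module its share of the total
    positive z; shares over the reported modules sum to 1."""
    scored = [
        m for m in modules
        if m.enrichment is not None
        and m.enrichment.z is not None
        and np.isfinite(m.enrichment.z)
        and m.enrichment.z > 0
    ]
    if not scored:
        raise ValueError("no module with finite positive z")
    total = sum(m.enrichment.z for m in scored)
    for m in modules:
        m.relative_significance = None
    for m in scored:
        m.relative_significance = m.enrichment.z / total
    return scored


def differential_rank(
    expr: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
) -> pd.Series:
    """Per-gene log2 fold-change between two patient groups:
    log2((mean_A + 1) / (mean_B + 1)).

    A deliberately simple ranking statistic; callers needing a moderated
    fit (voom-style) can substitute any gene -> real Series downstream.
    """
    cols = set(expr.patient_ids)
    a = [p for p in group_a if p in cols]
    b = [p for p in group_b if p in cols]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need >= 2 patients present in the matrix")
    mean_a = expr.values[a].mean(axis=1)
    mean_b = expr.values[b].mean(axis=1)
    fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    fc.name = "log2fc"
    return fc


ACTIVATED, INACTIVATED = "activated", "inactivated"


@dataclass
class ModuleActivity:
    module: FunctionalModule | None
    direction: str
    z: float | None
    p: float | None
    n_perm: int
    enrichment: EnrichmentResult = field(repr=False, default=None)


def module_activity(
    fold_changes: pd.Series,
    module_genes: list[str],
    n_perm: int = 1000,
    seed: int = 0,
    module: FunctionalModule | None = None,
) -> ModuleActivity:
    """Fold-change-ranked GSEA of a module; activated iff ES > 0."""
    res = permutation_enrichment(
        fold_changes, set(module_genes), n_perm=n_perm, seed=seed
    )
    return ModuleActivity(
        module=module,
        direction=ACTIVATED if res.es > 0 else INACTIVATED,
        z=res.z,
        p=res.p,
        n_perm=n_perm,
        enrichment=res,
    )


@dataclass
class ModuleClassifierReport:
    module_genes: list[str]
    n_holdouts: int
    auc_mean: float
    auc_sd: float
    aucpr_mean: float
    aucpr_sd: float
    effect_z: pd.Series  # gene -> mean/sd of standardized coefficient

    def to_dict(self) -> dict:
        return {
            "n_genes": len(self.module_genes),
            "n_holdouts": self.n_holdouts,
            "auc_mean": self.auc_mean,
            "auc_sd": self.auc_sd,
            "aucpr_mean": self.aucpr_mean,
            "aucpr_sd": self.aucpr_sd,
        }


def module_classifier(
    expr: ExpressionMatrix,
    module_genes: list[str],
    labels: pd.Series,
    n_holdouts: int = 100,
    train_frac: float = 0.6,
    seed: int = 0,
) -> ModuleClassifierReport:
    """Repeated stratified hold-out evaluation of a logistic model on the
    module genes.

    Per hold-out: a stratified train/test split (default 60/40), features
    log2(x+1)-standardized on the training patients, logistic regression,
    AUC and area under the precision-recall curve on the test patients.
    The per-gene effect z is mean/sd of the standardized coefficient across
    hold-outs.
    """
    genes = [g for g in module_genes if g in set(expr.gene_ids)]
    if not genes:
        raise ValueError("no module gene present in the matrix")
    y = labels.reindex(expr.patient_ids).to_numpy(dtype=int)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    if len(pos_idx) < 5 or len(neg_idx) < 5:
        raise ValueError("both classes need >= 5 patients")
    x = np.log2(expr.values.loc[genes].to_numpy().T + 1.0)  # patients x genes
    aucs, prs = [], []
    coefs = np.empty((n_holdouts, len(genes)))
    for h in range(n_holdouts):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(h,))
        )
        tr, te = [], []
        for idx in (pos_idx, neg_idx):
            order = rng.permutation(idx)
            n_tr = int(round(train_frac * len(idx)))
            n_tr = min(max(n_tr, 1), len(idx) - 1)
            tr.extend(order[:n_tr])
            te.extend(order[n_tr:])
        tr, te = np.array(tr), np.array(te)
        mu = x[tr].mean(axis=0)
        sd = x[tr].std(axis=0)
        sd[sd == 0] = 1.0
        z_tr, z_te = (x[tr] - mu) / sd, (x[te] - mu) / sd
        clf = LogisticRegression(max_iter=2000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(z_tr, y[tr])
        prob = clf.predict_proba(z_te)[:, 1]
        aucs.append(roc_auc_score(y[te], prob))
        prs.append(average_precision_score(y[te], prob))
        coefs[h] = clf.coef_[0]
    c_mean = coefs.mean(axis=0)
    c_sd = coefs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ez = np.where(c_sd > 0, c_mean / c_sd, np.nan)
    return ModuleClassifierReport(
        module_genes=genes,
        n_holdouts=n_holdouts,
        auc_mean=float(np.mean(aucs)),
        auc_sd=float(np.std(aucs, ddof=1)),
        aucpr_mean=float(np.mean(prs)),
        aucpr_sd=float(np.std(prs, ddof=1)),
        effect_z=pd.Series(ez, index=pd.Index(genes, name="gene")),
    )


def hub_ranking(
    module: FunctionalModule,
    effect_z: pd.Series,
    highlight_threshold: float = 2.0,
) -> pd.DataFrame:
    """Rank module genes by (degree in the module subgraph, |effect z|)
    lexicographically; genes with |z| above the threshold are highlighted."""
    missing = set(module.member_genes) - set(effect_z.index)
    if missing:
        raise ValueError(f"effect_z missing genes {sorted(missing)[:5]}")
    rows = []
    for g in module.member_genes:
        z = float(effect_z[g])
        rows.append(
            {
                "gene": g,
                "degree": module.subgraph.degree(g),
                "effect_z": z,
                "highlighted": abs(z) > highlight_threshold,
            }
        )
    df = pd.DataFrame(rows)
    df["abs_z"] = df["effect_z"].abs()
    df = df.sort_values(
        ["degree", "abs_z", "gene"], ascending=[False, False, True]
    ).drop(columns="abs_z")
    return df.reset_index(drop=True)
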
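"""Positive-unlabeled bagging of linear SVM member classifiers.

The central idea: genes are the samples and patients are the features.  The
known pathway members (a curated hallmark set) are the positives; genes in
any other curated hallmark set are excluded from training to avoid
confusing the learner; everything else is treated as negative even though
it is really just unlabeled.  Each member classifier is a linear SVM fit on
all positives plus a fresh random draw of ``np_ratio`` times as many
negatives, with a stratified 70/30 hold-out for testing.  The ensemble's
confidence in a gene is its vote: the number of members whose decision rule
calls it positive, out of M members.  Per-cohort ensembles are aggregated
pan-cancer by averaging votes over only the cohorts that voted for a gene,
alongside the gene's cancer prevalence (number of voting cohorts).

Preprocessing is log2(x+1) followed by per-patient standardization whose
mean/sd are fit on each member's 70% training split and applied unchanged
when scoring the full transcriptome, so no information leaks from scored
genes into the fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import LinearSVC

from .io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

POSITIVE, NEGATIVE, EXCLUDED = "positive", "negative", "excluded"


@dataclass
class LabelVector:
    """Per-gene training status: positive / negative / excluded."""

    status: pd.Series  # gene -> status string

    def __post_init__(self) -> None:
        bad = set(self.status.unique()) - {POSITIVE, NEGATIVE, EXCLUDED}
        if bad:
            raise ValueError(f"unknown statuses {sorted(bad)}")
        if (self.status == POSITIVE).sum() == 0:
            raise ValueError("positive set is empty")

    @property
    def positives(self) -> list[str]:
        return list(self.status.index[self.status == POSITIVE])

    @property
    def negatives(self) -> list[str]:
        return list(self.status.index[self.status == NEGATIVE])

    @property
    def excluded(self) -> list[str]:
        return list(self.status.index[self.status == EXCLUDED])

    @property
    def universe(self) -> list[str]:
        return list(self.status.index)


def build_label_vector(
    universe: list[str],
    positives: set[str],
    exclusion_sets: GeneSetCollection | None = None,
) -> LabelVector:
    """Label every gene in ``universe``.

    Genes in ``positives`` are positive; genes belonging to any exclusion
    set (minus the positives, which take precedence) are excluded from
    training; the remainder are negatives.
    """
    universe = list(universe)
    pos = set(positives) & set(universe)
    if not pos:
        raise ValueError("no positive gene present in the universe")
    excluded: set[str] = set()
    if exclusion_sets is not None:
        excluded = (exclusion_sets.all_genes() & set(universe)) - pos
    status = pd.Series(NEGATIVE, index=pd.Index(universe, name="gene"))
    status[status.index.isin(pos)] = POSITIVE
    status[status.index.isin(excluded)] = EXCLUDED
    return LabelVector(status=status)


@dataclass
class SampleManifest:
    """One member's training draw: all positives plus sampled negatives."""

    positives: list[str]
    negatives: list[str]
    np_ratio: float
    seed: int

    @property
    def genes(self) -> list[str]:
        return self.positives + self.negatives


def sample_training_set(
    labels: LabelVector, np_ratio: float, seed: int
) -> SampleManifest:
    """Draw all positives plus ``round(np_ratio * n_pos)`` negatives
    uniformly without replacement."""
    pos = labels.positives
    neg_pool = labels.negatives
    n_neg = int(round(np_ratio * len(pos)))
    if n_neg > len(neg_pool):
        raise ValueError(
            f"need {n_neg} negatives but only {len(neg_pool)} available"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(neg_pool), size=n_neg, replace=False)
    negatives = [neg_pool[i] for i in np.sort(idx)]
    return SampleManifest(
        positives=list(pos), negatives=negatives, np_ratio=np_ratio, seed=seed
    )


@dataclass
class MemberClassifier:
    """One weak linear SVM over patients-as-features.

    ``patient_weights`` and ``bias`` define the decision rule
    sign(w . x + b) on the standardized log2 scale; ``feature_mean`` /
    ``feature_sd`` are the standardization fit on the member's 70% training
    split.  ``test_precision`` is precision on the held-out 30%;
    ``initial_precision`` (filled by :func:`evaluate_initial`) is precision
    over the full labeled set.  Either precision is None when the member
    predicted no positives there.
    """

    patient_ids: list[str]
    patient_weights: np.ndarray
    bias: float
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    manifest: SampleManifest
    train_genes: list[str]
    test_genes: list[str]
    seed: int
    test_precision: float | None
    initial_precision: float | None = None

    def decision_values(self, log_values: np.ndarray) -> np.ndarray:
        """w . z + b for rows of ``log_values`` (genes x patients, log2
        scale), standardized with this member's training statistics."""
        z = (log_values - self.feature_mean) / self.feature_sd
        return z @ self.patient_weights + self.bias

    def predict(self, log_values: np.ndarray) -> np.ndarray:
        return self.decision_values(log_values) > 0.0


def precision(predicted_positive: set[str], true_positive: set[str]) -> float | None:
    """|pred & true| / |pred|; None (missing) when nothing was predicted."""
    if len(predicted_positive) == 0:
        return None
    return len(set(predicted_positive) & set(true_positive)) / len(
        predicted_positive
    )


def _log_transform(values: np.ndarray, enabled: bool) -> np.ndarray:
    return np.log2(values + 1.0) if enabled else np.asarray(values, dtype=float)


class _Workspace:
    """Cached log-transformed matrix and gene index for one cohort."""

    def __init__(self, expr: ExpressionMatrix, log_transform: bool = True):
        self.expr = expr
        self.log = _log_transform(expr.values.to_numpy(), log_transform)
        self.gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}

    def rows(self, genes: list[str]) -> np.ndarray:
        idx = [self.gene_pos[g] for g in genes]
        return self.log[idx]


def _fit_member(
    ws: _Workspace,
    manifest: SampleManifest,
    holdout_frac: float,
    seed: int,
    C: float,
    standardize: bool,
) -> MemberClassifier:
    pos, neg = manifest.positives, manifest.negatives
    if len(pos) < 4:
        raise ValueError("need >= 4 positives for a stratified split")
    rng = np.random.default_rng(seed)

    def split(items: list[str]) -> tuple[list[str], list[str]]:
        order = rng.permutation(len(items))
        n_test = int(round(holdout_frac * len(items)))
        n_test = min(max(n_test, 1), len(items) - 1)
        test = [items[i] for i in order[:n_test]]
        train = [items[i] for i in order[n_test:]]
        return train, test

    pos_tr, pos_te = split(pos)
    neg_tr, neg_te = split(neg)
    train_genes = pos_tr + neg_tr
    test_genes = pos_te + neg_te
    x_tr = ws.rows(train_genes)
    y_tr = np.r_[np.ones(len(pos_tr)), np.zeros(len(neg_tr))]
    if standardize:
        mean = x_tr.mean(axis=0)
        sd = x_tr.std(axis=0)
        sd[sd == 0] = 1.0
    else:
        mean = np.zeros(x_tr.shape[1])
        sd = np.ones(x_tr.shape[1])
    z_tr = (x_tr - mean) / sd
    clf = LinearSVC(
        loss="hinge",
        C=C,
        random_state=int(seed % (2**31 - 1)),
        max_iter=20000,
        tol=1e-4,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(z_tr, y_tr)
    w = clf.coef_[0].astype(float)
    b = float(clf.intercept_[0])

    member = MemberClassifier(
        patient_ids=ws.expr.patient_ids,
        patient_weights=w,
        bias=b,
        feature_mean=mean,
        feature_sd=sd,
        manifest=manifest,
        train_genes=train_genes,
        test_genes=test_genes,
        seed=seed,
        test_precision=None,
    )
    pred_te = member.predict(ws.rows(test_genes))
    predicted = {g for g, p in zip(test_genes, pred_te) if p}
    member.test_precision = precision(predicted, set(pos_te))
    return member


def train_member(
    expr: ExpressionMatrix,
    manifest: SampleManifest,
    holdout_frac: float = 0.3,
    seed: int = 0,
    C: float = 1.0,
    standardize: bool = True,
    log_transform: bool = True,
) -> MemberClassifier:
    """Fit one member on a sampled manifest with a stratified hold-out."""
    ws = _Workspace(expr, log_transform)
    return _fit_member(ws, manifest, holdout_frac, seed, C, standardize)


def evaluate_initial(
    member: MemberClassifier,
    expr: ExpressionMatrix,
    labels: LabelVector,
    log_transform: bool = True,
    _ws: _Workspace | None = None,
) -> float | None:
    """Precision of ``member`` over the full labeled set (all positives and
    all negatives, excluded genes left out)."""
    ws = _ws if _ws is not None else _Workspace(expr, log_transform)
    genes = labels.positives + labels.negatives
    pred = member.predict(ws.rows(genes))
    predicted = {g for g, p in zip(genes, pred) if p}
    member.initial_precision = precision(predicted, set(labels.positives))
    return member.initial_precision


@dataclass
class EnsembleModel:
    """A cohort's bag of members plus the per-gene vote tally (0..M)."""

    cohort: str
    members: list[MemberClassifier]
    votes: pd.Series  # gene -> int in [0, M]

    @property
    def n_members(self) -> int:
        return len(self.members)

    def voted_genes(self) -> list[str]:
        return list(self.votes.index[self.votes >= 1])

    def votes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.votes.index, "cohort": self.cohort, "vote": self.votes.values}
        )


def _member_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    # counter-based derivation: reproducible regardless of execution order
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))


def train_ensemble(
    expr: ExpressionMatrix,
    labels: LabelVector,
    M: int = 1000,
    np_ratio: float = 20.0,
    holdout_frac: float = 0.3,
    seed: int = 0,
    C: float = 1.0,
    standardize: bool = True,
    log_transform: bool = True,
    evaluate_initial_precision: bool = False,
) -> EnsembleModel:
    """Train ``M`` members with independent sampling seeds and tally votes.

    Every gene in ``expr`` is scored by every member — including genes
    excluded from training — so the vote vector covers the complete
    transcriptome.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    ws = _Workspace(expr, log_transform)
    votes = np.zeros(expr.n_genes, dtype=int)
    members: list[MemberClassifier] = []
    init_genes = labels.positives + labels.negatives
    init_rows = ws.rows(init_genes) if evaluate_initial_precision else None
    pos_set = set(labels.positives)
    for i in range(M):
        ss = _member_seed(seed, i)
        s_sample, s_split = ss.generate_state(2) >> 1  # keep below 2**31
        manifest = sample_training_set(labels, np_ratio, int(s_sample))
        member = _fit_member(
            ws, manifest, holdout_frac, int(s_split), C, standardize
        )
        votes += member.predict(ws.log)
        if evaluate_initial_precision:
            pred = member.predict(init_rows)
            predicted = {g for g, p in zip(init_genes, pred) if p}
            member.initial_precision = precision(predicted, pos_set)
        members.append(member)
    return EnsembleModel(
        cohort=expr.cohort,
        members=members,
        votes=pd.Series(votes, index=pd.Index(expr.gene_ids, name="gene")),
    )


@dataclass
class PanCancerVotes:
    """Per-gene votes across cohorts with prevalence and average vote.

    ``avg_vote`` is the mean vote over only the cohorts that voted for the
    gene (reported 0 when no cohort voted), and ``prevalence`` counts the
    voting cohorts.
    """

    table: pd.DataFrame  # genes x cohorts, integer votes (absent = 0)
    prevalence: pd.Series
    avg_vote: pd.Series

    @property
    def n_cohorts(self) -> int:
        return self.table.shape[1]

    def ranking_score(self) -> pd.Series:
        """Scalar score for ranking genes: average vote with prevalence as
        the tie-breaker; unvoted genes score 0."""
        eps = 1.0 / (self.n_cohorts + 1)
        return self.avg_vote + eps * self.prevalence / max(
            1, int(self.table.to_numpy().max()) + 1
        )

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out["prevalence"] = self.prevalence
        out["avg_vote"] = self.avg_vote
        return out


def aggregate_pan_cancer(models: list[EnsembleModel]) -> PanCancerVotes:
    """Combine per-cohort vote vectors over the union of gene universes."""
    if not models:
        raise ValueError("need at least one ensemble model")
    table = pd.DataFrame(
        {m.cohort: m.votes for m in models}
    ).fillna(0).astype(int)
    table.index.name = "gene"
    voting = table >= 1
    prevalence = voting.sum(axis=1)
    sums = table.where(voting).sum(axis=1)
    avg = np.where(prevalence > 0, sums / prevalence.replace(0, 1), 0.0)
    return PanCancerVotes(
        table=table,
        prevalence=prevalence,
        avg_vote=pd.Series(avg, index=table.index, name="avg_vote"),
    )


@dataclass
class CalibrationReport:
    """Distribution of member precisions per candidate NP ratio."""

    per_member: pd.DataFrame  # columns: cohort, np_ratio, test_precision, initial_precision
    medians: pd.DataFrame  # index: np_ratio; columns: test_precision, initial_precision
    chosen_ratio: float

    def to_frame(self) -> pd.DataFrame:
        return self.medians.assign(chosen=self.medians.index == self.chosen_ratio)


def calibrate_np_ratio(
    exprs: dict[str, ExpressionMatrix],
    labels: dict[str, LabelVector] | LabelVector,
    ratios: list[float] = (1, 10, 15, 20, 25, 30),
    members_per_ratio: int = 1000,
    seed: int = 0,
    holdout_frac: float = 0.3,
    C: float = 1.0,
    standardize: bool = True,
    log_transform: bool = True,
) -> CalibrationReport:
    """Train ``members_per_ratio`` members per NP ratio per cohort and pick
    the working ratio.

    The chosen ratio is the smallest whose pooled median precision on the
    full labeled ("initial") set exceeds 0.5 — the weak-classifier bar.  If
    no ratio qualifies the argmax is used with a warning.
    """
    ratios = sorted(ratios)
    if len(ratios) < 2:
        raise ValueError("need at least two candidate ratios")
    rows = []
    for ci, (cohort, expr) in enumerate(sorted(exprs.items())):
        lab = labels[cohort] if isinstance(labels, dict) else labels
        ws = _Workspace(expr, log_transform)
        init_genes = lab.positives + lab.negatives
        init_rows = ws.rows(init_genes)
        pos_set = set(lab.positives)
        for ri, ratio in enumerate(ratios):
            for mi in range(members_per_ratio):
                ss = np.random.SeedSequence(
                    entropy=seed, spawn_key=(ci, ri, mi)
                )
                s_sample, s_split = ss.generate_state(2) >> 1
                manifest = sample_training_set(lab, ratio, int(s_sample))
                member = _fit_member(
                    ws, manifest, holdout_frac, int(s_split), C, standardize
                )
                pred = member.predict(init_rows)
                predicted = {g for g, p in zip(init_genes, pred) if p}
                member.initial_precision = precision(predicted, pos_set)
                rows.append(
                    (cohort, ratio, member.test_precision, member.initial_precision)
                )
    per_member = pd.DataFrame(
        rows, columns=["cohort", "np_ratio", "test_precision", "initial_precision"]
    )
    medians = per_member.groupby("np_ratio")[
        ["test_precision", "initial_precision"]
    ].median()
    qualifying = medians.index[medians["initial_precision"] > 0.5]
    if len(qualifying):
        chosen = float(qualifying[0])
    else:
        chosen = float(medians["initial_precision"].idxmax())
        logger.warning(
            "no NP ratio reaches median initial precision > 0.5; "
            "falling back to argmax ratio %s", chosen,
        )
    return CalibrationReport(
        per_member=per_member, medians=medians, chosen_ratio=chosen
    )


def correlation_baseline(
    expr: ExpressionMatrix,
    positives: set[str],
    aggregate: str = "mean",
    log_transform: bool = True,
) -> pd.Series:
    """Conventional baseline: each gene's mean (or max) Pearson correlation
    with the positive genes, excluding self-correlation.

    Zero-variance genes get a missing (NaN) score.
    """
    if expr.n_patients < 2:
        raise ValueError("need >= 2 patients for correlation")
    if aggregate not in {"mean", "max"}:
        raise ValueError("aggregate must be 'mean' or 'max'")
    pos = [g for g in expr.gene_ids if g in set(positives)]
    if not pos:
        raise ValueError("no positive gene present in the matrix")
    x = _log_transform(expr.values.to_numpy(), log_transform)
    x = x - x.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(x, axis=1)
    zero_var = norm == 0
    norm_safe = np.where(zero_var, 1.0, norm)
    xn = x / norm_safe[:, None]
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    pos_idx = np.array([gene_pos[g] for g in pos])
    r = xn @ xn[pos_idx].T  # genes x positives
    r[zero_var, :] = np.nan
    r[:, zero_var[pos_idx]] = np.nan
    # exclude self-correlation for genes that are themselves positives
    for j, gi in enumerate(pos_idx):
        r[gi, j] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        score = np.nanmean(r, axis=1) if aggregate == "mean" else np.nanmax(r, axis=1)
    return pd.Series(score, index=pd.Index(expr.gene_ids, name="gene"))


def roc_auc(scores: pd.Series, positives: set[str], negatives: set[str]) -> float:
    """Rank-based AUC with tie correction (Mann-Whitney U scaled).

    Missing scores rank below every finite score.
    """
    pos = [g for g in positives]
    neg = [g for g in negatives]
    if not pos or not neg:
        raise ValueError("both classes must be non-empty")
    s = scores.reindex(pos + neg).to_numpy(dtype=float)
    s[np.isnan(s)] = -np.inf
    ranks = stats.rankdata(s)
    n_pos, n_neg = len(pos), len(neg)
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def patient_weights(model: EnsembleModel) -> pd.DataFrame:
    """Per-patient influence: mean of member weight vectors on the
    standardized feature scale, with the absolute value alongside."""
    w = np.mean([m.patient_weights for m in model.members], axis=0)
    patients = model.members[0].patient_ids
    return pd.DataFrame(
        {"weight": w, "abs_weight": np.abs(w)},
        index=pd.Index(patients, name="patient"),
    )
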
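"""Risk scoring, Kaplan-Meier stratification, stage trends, and
patient-weight subtype enrichment.

The risk score is the linear combination of log2(x+1) expression with a
pre-trained proportional-hazards signature's coefficients; patients are
split into high/low groups at the median score (ties go to the low group,
deterministically).  Kaplan-Meier curves and the two-group log-rank test
are delegated to lifelines; model *fitting* (Cox, additive hazards) is out
of scope here — coefficients come in, summaries go out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .enrichment import EnrichmentResult, permutation_enrichment
from .io import ClinicalTable, ExpressionMatrix, RiskModel, STAGES

logger = logging.getLogger(__name__)

HIGH, LOW = "high", "low"


@dataclass
class RiskScores:
    scores: pd.Series  # patient -> score
    groups: pd.Series  # patient -> "high" / "low"

    @property
    def high_patients(self) -> list[str]:
        return list(self.groups.index[self.groups == HIGH])

    @property
    def low_patients(self) -> list[str]:
        return list(self.groups.index[self.groups == LOW])


def risk_score(
    expr: ExpressionMatrix,
    model: RiskModel,
    gene_subset: set[str] | None = None,
    log_transform: bool = True,
) -> RiskScores:
    """Score patients with the signature over ``gene_subset`` (default: all
    signature genes) and median-split into high/low groups.

    score(patient) = sum_g coef(g) * log2(expr(g, patient) + 1), over the
    intersection of the subset, the signature and the matrix.
    """
    genes = set(model.genes)
    if gene_subset is not None:
        genes &= set(gene_subset)
    used = [g for g in expr.gene_ids if g in genes]
    if not used:
        missing = sorted(genes - set(expr.gene_ids))[:5]
        raise ValueError(
            f"no signature gene present in the matrix (missing e.g. {missing})"
        )
    x = expr.values.loc[used].to_numpy()
    if log_transform:
        x = np.log2(x + 1.0)
    coefs = model.coefficients.loc[used].to_numpy()
    s = pd.Series(
        coefs @ x, index=pd.Index(expr.patient_ids, name="patient"), name="risk_score"
    )
    med = float(s.median())
    groups = pd.Series(np.where(s > med, HIGH, LOW), index=s.index, name="group")
    return RiskScores(scores=s, groups=groups)


@dataclass
class KMResult:
    curves: dict[str, pd.DataFrame]  # group -> columns (time, survival)
    chi2: float
    p: float
    horizon_years: float

    def to_dict(self) -> dict:
        return {
            "chi2": self.chi2,
            "p": self.p,
            "horizon_years": self.horizon_years,
            "groups": {
                g: {"n": int(len(df))} for g, df in self.curves.items()
            },
        }


def km_logrank(
    clinical: ClinicalTable,
    groups: pd.Series,
    horizon_years: float = 5.0,
) -> KMResult:
    """Product-limit curves per group and the two-group log-rank test,
    with administrative censoring at the horizon."""
    df = clinical.records.loc[groups.index.intersection(clinical.patient_ids)]
    g = groups.loc[df.index]
    names = sorted(g.unique())
    if len(names) != 2:
        raise ValueError(f"need exactly two groups, got {names}")
    horizon_days = horizon_years * 365.25
    time = df["survival_time"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=int)
    over = time > horizon_days
    time = np.where(over, horizon_days, time)
    event = np.where(over, 0, event)
    curves = {}
    masks = {}
    for name in names:
        mask = (g == name).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"group {name!r} is empty")
        masks[name] = mask
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask])
        sf = kmf.survival_function_
        curves[name] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    res = logrank_test(
        time[masks[names[0]]],
        time[masks[names[1]]],
        event_observed_A=event[masks[names[0]]],
        event_observed_B=event[masks[names[1]]],
    )
    return KMResult(
        curves=curves,
        chi2=float(res.test_statistic),
        p=float(res.p_value),
        horizon_years=horizon_years,
    )


@dataclass
class StageTrend:
    summaries: pd.DataFrame  # per stage: n, median, q1, q3
    adjacent_tests: pd.DataFrame  # stage_a, stage_b, p (one-sided b > a)
    monotone: bool


def stage_trend(scores: RiskScores, stages: pd.Series) -> StageTrend:
    """Per-stage score summaries with one-sided rank-sum tests between
    adjacent stages (direction: later stage > earlier).

    Stages with fewer than two patients are excluded with a warning; the
    monotone flag reports strictly increasing medians across the populated
    stages.
    """
    ordered = [s for s in STAGES if s != "unknown"]
    common = scores.scores.index.intersection(stages.index)
    s = scores.scores.loc[common]
    st = stages.loc[common]
    groups: dict[str, np.ndarray] = {}
    for name in ordered:
        vals = s[st == name].to_numpy()
        if len(vals) == 0:
            continue
        if len(vals) < 2:
            logger.warning("stage %s has < 2 patients; excluded", name)
            continue
        groups[name] = vals
    if len(groups) < 2:
        raise ValueError("need at least two populated stages")
    summaries = pd.DataFrame(
        {
            name: {
                "n": len(v),
                "median": float(np.median(v)),
                "q1": float(np.quantile(v, 0.25)),
                "q3": float(np.quantile(v, 0.75)),
            }
            for name, v in groups.items()
        }
    ).T
    names = list(groups)
    rows = []
    for a, b in zip(names[:-1], names[1:]):
        p = float(
            stats.mannwhitneyu(groups[b], groups[a], alternative="greater").pvalue
        )
        rows.append({"stage_a": a, "stage_b": b, "p": p})
    medians = summaries["median"].to_numpy()
    monotone = bool(np.all(np.diff(medians) > 0))
    return StageTrend(
        summaries=summaries,
        adjacent_tests=pd.DataFrame(rows),
        monotone=monotone,
    )


def weight_enrichment(
    weights: pd.Series,
    subtype_flags: pd.DataFrame | pd.Series,
    n_perm: int = 10000,
    seed: int = 0,
    absolute: bool = False,
) -> dict[str, EnrichmentResult]:
    """Permutation GSEA of subtype membership on the patient-weight ranking.

    Patients are the ranked universe — by signed weight by default, since
    the ensemble assigns positive weight to patients on whom the pathway
    genes are elevated (``absolute=True`` ranks by |weight| instead); each
    subtype's flagged patients form the hit set.  Returns one result per
    subtype column.
    """
    if isinstance(subtype_flags, pd.Series):
        subtype_flags = subtype_flags.to_frame()
    ranked = weights.abs() if absolute else weights
    out: dict[str, EnrichmentResult] = {}
    for si, col in enumerate(subtype_flags.columns):
        flags = subtype_flags[col].reindex(ranked.index).fillna(0).astype(int)
        hit = set(flags.index[flags == 1])
        if not hit or len(hit) == len(flags):
            raise ValueError(f"subtype {col!r} needs both flagged and unflagged patients")
        out[col] = permutation_enrichment(
            ranked,
            hit,
            n_perm=n_perm,
            seed=int(
                np.random.SeedSequence(entropy=seed, spawn_key=(si,)).generate_state(1)[0] >> 1
            ),
        )
    return out
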
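"""End-to-end orchestration of the voting workflow.

Stages run in dependency order: simulate -> calibrate -> train ->
aggregate -> enrich -> modules -> survival.  Every stage writes plain-text
artifacts under the configured output directory and the run closes with a
machine-readable manifest (configuration, seeds, package version, SHA-256
of every output), so a rerun with the same configuration is byte-checkable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .ensemble import (
    aggregate_pan_cancer,
    build_label_vector,
    calibrate_np_ratio,
    correlation_baseline,
    patient_weights,
    roc_auc,
    train_ensemble,
)
from .enrichment import (
    permutation_enrichment,
    proportion_curve,
    similarity_profile,
)
from .io import (
    GeneSetCollection,
    read_annotation_table,
    read_clinical,
    read_expression,
    read_gmt,
    read_ppi,
    read_risk_model,
)
from .netmod import (
    differential_rank,
    find_modules,
    module_activity,
    module_classifier,
    relative_significance,
)
from .simulate import SimBundle, generate
from .survival import km_logrank, risk_score, stage_trend, weight_enrichment

logger = logging.getLogger(__name__)

STAGE_ORDER = [
    "simulate", "calibrate", "train", "aggregate", "enrich", "modules", "survival",
]
DEPENDENCIES = {
    "simulate": [],
    "calibrate": ["simulate"],
    "train": ["simulate"],
    "aggregate": ["train"],
    "enrich": ["aggregate", "simulate"],
    "modules": ["train", "simulate"],
    "survival": ["train", "simulate"],
}


class PipelineError(RuntimeError):
    pass


class _State:
    """Artifacts shared between stages within one run."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.bundle: SimBundle | None = None
        self.votes: dict[str, pd.Series] = {}
        self.weights: dict[str, pd.DataFrame] = {}
        self.pan = None
        self.outputs: dict[str, str] = {}

    def record(self, name: str, path: Path) -> None:
        self.outputs[name] = str(path)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _labels_for(state: _State):
    bundle = state.bundle
    cfg = state.config
    positives = set(bundle.gene_sets[cfg.positive_set])
    exclusion = GeneSetCollection(
        sets={
            name: bundle.gene_sets[name]
            for name in bundle.gene_sets.names()
            if name.startswith(cfg.exclusion_prefix) and name != cfg.positive_set
        }
    )
    first = next(iter(bundle.cohorts.values()))
    return build_label_vector(first.gene_ids, positives, exclusion)


def _stage_simulate(state: _State) -> None:
    cfg = state.config
    data_dir = state.outdir / "data"
    if cfg.data_dir is not None:
        state.bundle = _load_bundle(Path(cfg.data_dir))
        return
    state.bundle = generate(cfg.sim)
    manifest = state.bundle.write(data_dir)
    for name, path in manifest.items():
        state.record(f"data/{name}", Path(path))


def _load_bundle(data_dir: Path) -> SimBundle:
    """Re-assemble a bundle from files written by :meth:`SimBundle.write`."""
    import networkx as nx

    from .io import AnnotationTable  # noqa: F401

    expr_files = sorted(data_dir.glob("expression_*.tsv"))
    if not expr_files:
        raise PipelineError(
            f"no expression matrices under {data_dir}; run the simulate stage first"
        )
    cohorts = {}
    for f in expr_files:
        label = f.stem.replace("expression_", "")
        cohorts[label] = read_expression(f, label)
    truth = pd.read_csv(data_dir / "truth.tsv", sep="\t")
    roles = dict(zip(truth["gene"], truth["role"]))
    by_role = lambda r: frozenset(g for g, v in roles.items() if v == r)  # noqa: E731
    gene_sets = read_gmt(data_dir / "gene_sets.gmt")
    annotations = read_annotation_table(data_dir / "annotations.tsv")
    ppi = read_ppi(data_dir / "ppi.tsv")
    clinical = read_clinical(data_dir / "clinical.tsv")
    risk_model = read_risk_model(data_dir / "risk_model.tsv")
    seed_sorted = sorted(by_role("seed"))
    from .simulate import MODULE_TERM, N_CORE, SimConfig

    module_genes = frozenset(
        annotations.records.loc[
            annotations.records["term_id"] == MODULE_TERM, "gene"
        ]
    )
    return SimBundle(
        config=SimConfig(),
        cohorts=cohorts,
        seed_genes=by_role("seed"),
        hidden_genes=by_role("hidden"),
        excluded_genes=by_role("excluded"),
        decoy_genes=by_role("decoy"),
        core_genes=tuple(seed_sorted[:N_CORE]),
        module_genes=module_genes,
        gene_sets=gene_sets,
        annotations=annotations,
        ppi=ppi,
        clinical=clinical,
        risk_model=risk_model,
    )


def _stage_calibrate(state: _State) -> None:
    cfg = state.config
    labels = _labels_for(state)
    report = calibrate_np_ratio(
        state.bundle.cohorts,
        labels,
        ratios=list(cfg.calibration_ratios),
        members_per_ratio=cfg.members_per_ratio,
        seed=cfg.seed,
        holdout_frac=cfg.holdout_frac,
        C=cfg.svm_c,
        standardize=cfg.standardize,
        log_transform=cfg.log_transform,
    )
    path = state.outdir / "calibration.tsv"
    report.medians.assign(chosen_ratio=report.chosen_ratio).to_csv(path, sep="\t")
    state.record("calibration", path)


def _stage_train(state: _State) -> None:
    cfg = state.config
    labels = _labels_for(state)
    frames = []
    for ci, (label, expr) in enumerate(sorted(state.bundle.cohorts.items())):
        model = train_ensemble(
            expr,
            labels,
            M=cfg.members,
            np_ratio=cfg.np_ratio,
            holdout_frac=cfg.holdout_frac,
            seed=int(
                np.random.SeedSequence(
                    entropy=cfg.seed, spawn_key=(100, ci)
                ).generate_state(1)[0]
                >> 1
            ),
            C=cfg.svm_c,
            standardize=cfg.standardize,
            log_transform=cfg.log_transform,
        )
        state.votes[label] = model.votes
        weights = patient_weights(model)
        state.weights[label] = weights
        wpath = state.outdir / f"weights_{label}.tsv"
        weights.to_csv(wpath, sep="\t")
        state.record(f"weights_{label}", wpath)
        frames.append(model.votes_frame())
    vpath = state.outdir / "votes.tsv"
    pd.concat(frames).to_csv(vpath, sep="\t", index=False)
    state.record("votes", vpath)


def _load_votes(state: _State) -> None:
    vpath = state.outdir / "votes.tsv"
    if not vpath.exists():
        raise PipelineError("votes.tsv missing; run the train stage first")
    df = pd.read_csv(vpath, sep="\t")
    for label, grp in df.groupby("cohort"):
        state.votes[str(label)] = pd.Series(
            grp["vote"].to_numpy(), index=pd.Index(grp["gene"], name="gene")
        )
    for wfile in sorted(state.outdir.glob("weights_*.tsv")):
        label = wfile.stem.replace("weights_", "")
        state.weights[label] = pd.read_csv(wfile, sep="\t", index_col=0)


def _stage_aggregate(state: _State) -> None:
    from .ensemble import EnsembleModel

    models = [
        EnsembleModel(cohort=label, members=[], votes=votes)
        for label, votes in sorted(state.votes.items())
    ]
    state.pan = aggregate_pan_cancer(models)
    path = state.outdir / "pan_cancer_votes.tsv"
    state.pan.to_frame().to_csv(path, sep="\t")
    state.record("pan_cancer_votes", path)


def _stage_enrich(state: _State) -> None:
    cfg = state.config
    bundle = state.bundle
    pan = state.pan
    score = pan.ranking_score()
    seed_set = set(bundle.gene_sets[cfg.positive_set])
    universe = set(score.index)
    results = {}

    # accuracy of the ensemble vs the correlation baseline on seed recovery
    negatives = universe - seed_set
    results["seed_auc_ensemble"] = roc_auc(score, seed_set, negatives)
    first = bundle.cohorts[sorted(bundle.cohorts)[0]]
    corr = correlation_baseline(first, seed_set, log_transform=cfg.log_transform)
    results["seed_auc_correlation"] = roc_auc(corr, seed_set, negatives)

    # reference-set enrichment among voted genes (vote-ranked GSEA)
    ref = set(bundle.gene_sets[cfg.reference_set]) & universe
    voted = score[score > 0]
    enr = permutation_enrichment(
        voted, ref & set(voted.index), n_perm=cfg.n_perm_enrich, seed=cfg.seed
    )
    results["reference_enrichment"] = enr.to_dict()

    # proportion of reference genes vs vote threshold
    thresholds = np.linspace(1, cfg.members, 8).tolist()
    curve = proportion_curve(pan.avg_vote, ref, thresholds)
    cpath = state.outdir / "proportion_curve.tsv"
    curve.table.to_csv(cpath, sep="\t", index=False)
    state.record("proportion_curve", cpath)

    # functional similarity of candidates to the core genes
    profile = similarity_profile(
        bundle.annotations, list(universe - seed_set), list(bundle.core_genes)
    )
    candidates = set(voted.index) - seed_set
    sim_results = {}
    for cg in bundle.core_genes:
        ranking = profile.ranking(cg)
        hits = candidates & set(ranking.index)
        if not hits:
            continue
        r = permutation_enrichment(
            ranking, hits, n_perm=cfg.n_perm_enrich, seed=cfg.seed
        )
        sim_results[cg] = r.to_dict()
    results["core_similarity_enrichment"] = sim_results

    path = state.outdir / "enrichment.json"
    _write_json(results, path)
    state.record("enrichment", path)


def _stage_modules(state: _State) -> None:
    cfg = state.config
    bundle = state.bundle
    label = sorted(state.votes)[0]
    votes = state.votes[label]
    seed_set = set(bundle.gene_sets[cfg.positive_set])
    candidates = votes[(votes >= 1) & ~votes.index.isin(seed_set)]
    term_sets = bundle.annotations.term_sets()
    modules = find_modules(
        bundle.ppi,
        candidates,
        term_sets,
        min_size=cfg.module_min_size,
        n_perm=cfg.n_perm_activity,
        seed=cfg.seed,
    )
    if modules:
        try:
            relative_significance(modules)
        except ValueError:
            logger.warning("no positively enriched module; shares not assigned")

    clin = bundle.clinical.for_cohort(label)
    flags = clin[cfg.subtype_column]
    expr = bundle.cohorts[label]
    group_a = list(flags.index[flags == 1])
    group_b = list(flags.index[flags == 0])
    fc = differential_rank(expr, group_a, group_b)

    payload = []
    for m in modules:
        act = module_activity(
            fc, m.member_genes, n_perm=cfg.n_perm_activity, seed=cfg.seed, module=m
        )
        rep = module_classifier(
            expr,
            m.member_genes,
            flags,
            n_holdouts=cfg.classifier_holdouts,
            seed=cfg.seed,
        )
        entry = m.to_dict()
        entry["activity"] = {"direction": act.direction, "z": act.z, "p": act.p}
        entry["classifier"] = rep.to_dict()
        payload.append(entry)
    path = state.outdir / "modules.json"
    _write_json(payload, path)
    state.record("modules", path)


def _stage_survival(state: _State) -> None:
    cfg = state.config
    bundle = state.bundle
    label = sorted(bundle.cohorts)[0]
    expr = bundle.cohorts[label]
    voted = set(state.votes[label].index[state.votes[label] >= 1])
    scores = risk_score(expr, bundle.risk_model, gene_subset=voted or None)
    spath = state.outdir / "risk_scores.tsv"
    pd.DataFrame({"score": scores.scores, "group": scores.groups}).to_csv(
        spath, sep="\t"
    )
    state.record("risk_scores", spath)

    km = km_logrank(bundle.clinical, scores.groups, horizon_years=cfg.horizon_years)
    trend = stage_trend(scores, bundle.clinical.for_cohort(label)["stage"])
    results = {
        "km": km.to_dict(),
        "stage_trend": {
            "monotone": trend.monotone,
            "medians": trend.summaries["median"].to_dict(),
            "adjacent_p": trend.adjacent_tests.to_dict(orient="records"),
        },
    }
    if state.weights.get(label) is not None:
        flags = bundle.clinical.for_cohort(label)[[cfg.subtype_column]]
        enr = weight_enrichment(
            state.weights[label]["weight"],
            flags,
            n_perm=cfg.n_perm_enrich,
            seed=cfg.seed,
        )
        results["weight_enrichment"] = {
            k: v.to_dict() for k, v in enr.items()
        }
    path = state.outdir / "survival.json"
    _write_json(results, path)
    state.record("survival", path)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "calibrate": _stage_calibrate,
    "train": _stage_train,
    "aggregate": _stage_aggregate,
    "enrich": _stage_enrich,
    "modules": _stage_modules,
    "survival": _stage_survival,
}


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict:
    """Run the requested stages in dependency order and write a manifest.

    When a requested stage's upstream is not part of this run, its
    artifacts are loaded from the output directory; if they are absent the
    error names the stage to run first.
    """
    config.validate()
    if stages is None:
        stages = list(STAGE_ORDER)
    unknown = set(stages) - set(STAGE_ORDER)
    if unknown:
        raise PipelineError(f"unknown stages {sorted(unknown)}")
    stages = [s for s in STAGE_ORDER if s in set(stages)]
    state = _State(config)
    state.outdir.mkdir(parents=True, exist_ok=True)

    for stage in stages:
        for dep in DEPENDENCIES[stage]:
            if dep in stages and stages.index(dep) < stages.index(stage):
                continue
            # try to satisfy the dependency from disk
            if dep == "simulate" and state.bundle is None:
                try:
                    data_dir = (
                        Path(config.data_dir)
                        if config.data_dir is not None
                        else state.outdir / "data"
                    )
                    state.bundle = _load_bundle(data_dir)
                except (PipelineError, FileNotFoundError) as exc:
                    raise PipelineError(
                        f"stage {stage!r} needs 'simulate'; run it first ({exc})"
                    ) from exc
            elif dep == "train" and not state.votes:
                try:
                    _load_votes(state)
                except PipelineError as exc:
                    raise PipelineError(
                        f"stage {stage!r} needs 'train'; run it first"
                    ) from exc
            elif dep == "aggregate" and state.pan is None:
                if not state.votes:
                    _load_votes(state)
                _stage_aggregate(state)
        logger.info("running stage %s", stage)
        _STAGE_FUNCS[stage](state)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": stages,
        "outputs": {
            name: {"path": p, "sha256": _sha256(Path(p))}
            for name, p in sorted(state.outputs.items())
        },
    }
    mpath = state.outdir / "manifest.json"
    _write_json(manifest, mpath)
    return manifest
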
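"""Synthetic multi-cohort transcriptomes with a planted pathway signal.

The generator emulates the data layout the voting ensemble assumes: several
cancer cohorts of gene x patient expression, a seed pathway gene set whose
members co-vary through a single latent per-patient "pathway activity"
factor, hidden true members outside the seed set that load on the same
factor, decoy genes without it, stand-ins for other curated hallmark sets
(excluded from training), functional-term annotations overlapping the truth
set, a protein-interaction graph with one planted module, subtype labels
tied to the latent factor, and survival times driven by a bundled risk
signature.

Expression for a signal gene g on patient p is

    softplus(baseline + factor_strength * a_p + eps),  eps ~ N(0, noise_sd)

with a_p ~ N(0, 1) the patient's latent pathway activity; decoys drop the
factor term.  The softplus link keeps values non-negative without hard
truncation, preserving the rank structure linear classifiers exploit.

Every random stream is derived from the master seed by a fixed spawn key,
one stream per cohort plus dedicated streams for the shared structures, so
adding cohorts never perturbs existing ones and output is bit-identical
under a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import (
    AnnotationTable,
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    RiskModel,
)

#: Number of genes treated as "core" pathway members (analogous to the
#: central TNF / NF-kB family genes); taken as the first core genes of the
#: seed set and used as anchors for functional-similarity analyses.
N_CORE = 6


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    ``n_seed`` genes form the known pathway set (the training positives),
    ``n_hidden`` genes are true pathway members outside the seed set (the
    signal the ensemble should recover), ``n_excluded`` genes stand in for
    the other curated hallmark collections (excluded from training but
    scored), and the remainder are decoys.
    """

    n_cohorts: int = 3
    genes_total: int = 2000
    n_seed: int = 60
    n_hidden: int = 40
    n_excluded: int = 200
    patients_per_cohort: int = 150
    factor_strength: float = 1.5
    noise_sd: float = 1.0
    baseline_expr: float = 4.0
    subtype_fraction: float = 0.2
    baseline_hazard: float = 1.0 / 1500.0  # events per day
    risk_effect: float = 1.0
    ppi_nodes: int = 400
    ppi_attachment: int = 2
    module_size: int = 12
    seed: int = 17

    def validate(self) -> None:
        if self.n_seed + self.n_hidden + self.n_excluded >= self.genes_total:
            raise ValueError("set sizes exceed genes_total")
        for name in (
            "n_cohorts", "genes_total", "n_seed", "n_hidden", "n_excluded",
            "patients_per_cohort", "ppi_nodes", "ppi_attachment", "module_size",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.factor_strength < 0 or self.noise_sd < 0:
            raise ValueError("factor_strength and noise_sd must be >= 0")
        if not 0 < self.subtype_fraction < 1:
            raise ValueError("subtype_fraction must be in (0, 1)")
        if self.module_size > self.n_seed + self.n_hidden:
            raise ValueError("module_size exceeds seed+hidden pool")
        if self.ppi_nodes > self.genes_total:
            raise ValueError("ppi_nodes exceeds genes_total")


def default_config() -> SimConfig:
    """The repository's canonical desk-scale configuration.

    3 cohorts, 2,000 genes (60 seed / 40 hidden / 200 excluded), 150
    patients per cohort, factor strength 1.5, noise sd 1.0, master seed 17.
    All property-based checks in the test suite reference this config.
    """
    return SimConfig()


@dataclass
class SimBundle:
    """Everything :func:`generate` emits, in the toolkit's native containers."""

    config: SimConfig
    cohorts: dict[str, ExpressionMatrix]
    seed_genes: frozenset[str]
    hidden_genes: frozenset[str]
    excluded_genes: frozenset[str]
    decoy_genes: frozenset[str]
    core_genes: tuple[str, ...]
    module_genes: frozenset[str]
    gene_sets: GeneSetCollection
    annotations: AnnotationTable
    ppi: nx.Graph
    clinical: ClinicalTable
    risk_model: RiskModel
    latent_activity: dict[str, pd.Series] = field(default_factory=dict)

    @property
    def gene_ids(self) -> list[str]:
        first = next(iter(self.cohorts.values()))
        return first.gene_ids

    def write(self, outdir) -> dict[str, str]:
        """Write the bundle in the exact formats the readers accept.

        Returns a name -> path manifest of the files written.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest: dict[str, str] = {}
        for label, expr in self.cohorts.items():
            p = outdir / f"expression_{label}.tsv"
            expr.to_tsv(p)
            manifest[f"expression_{label}"] = str(p)
        p = outdir / "gene_sets.gmt"
        self.gene_sets.to_gmt(p)
        manifest["gene_sets"] = str(p)
        p = outdir / "annotations.tsv"
        self.annotations.to_tsv(p)
        manifest["annotations"] = str(p)
        p = outdir / "ppi.tsv"
        from .io import write_ppi

        write_ppi(self.ppi, p)
        manifest["ppi"] = str(p)
        p = outdir / "clinical.tsv"
        self.clinical.to_tsv(p)
        manifest["clinical"] = str(p)
        p = outdir / "risk_model.tsv"
        self.risk_model.to_tsv(p)
        manifest["risk_model"] = str(p)
        truth = pd.DataFrame(
            {
                "gene": self.gene_ids,
                "role": [
                    "seed" if g in self.seed_genes
                    else "hidden" if g in self.hidden_genes
                    else "excluded" if g in self.excluded_genes
                    else "decoy"
                    for g in self.gene_ids
                ],
            }
        )
        p = outdir / "truth.tsv"
        truth.to_csv(p, sep="\t", index=False)
        manifest["truth"] = str(p)
        return manifest


SEED_SET_NAME = "HALLMARK_SEED_PATHWAY"
ONCOGENIC_SET_NAME = "ONCOGENIC_C6_ANALOGUE"
MODULE_TERM = "GO:MOD0001"

_softplus = lambda x: np.logaddexp(0.0, x)  # noqa: E731


def _rng(config: SimConfig, domain: int, index: int = 0) -> np.random.Generator:
    """Stream derived from the master seed by a fixed (domain, index) key."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(domain, index))
    )


def _gene_names(config: SimConfig) -> tuple[list[str], ...]:
    n_decoy = (
        config.genes_total - config.n_seed - config.n_hidden - config.n_excluded
    )
    seed = [f"SEED{i:04d}" for i in range(config.n_seed)]
    hidden = [f"HID{i:04d}" for i in range(config.n_hidden)]
    excluded = [f"EXC{i:04d}" for i in range(config.n_excluded)]
    decoy = [f"DEC{i:05d}" for i in range(n_decoy)]
    return seed, hidden, excluded, decoy


def generate(config: SimConfig | None = None) -> SimBundle:
    """Build the full synthetic bundle for ``config`` (deterministically)."""
    if config is None:
        config = default_config()
    config.validate()
    seed_g, hidden_g, excluded_g, decoy_g = _gene_names(config)
    genes = seed_g + hidden_g + excluded_g + decoy_g
    signal = np.zeros(len(genes), dtype=bool)
    signal[: config.n_seed + config.n_hidden] = True
    core = tuple(seed_g[:N_CORE])

    cohorts: dict[str, ExpressionMatrix] = {}
    latent: dict[str, pd.Series] = {}
    clinical_frames = []
    risk_model = _make_risk_model(config, seed_g, hidden_g)

    for c in range(config.n_cohorts):
        label = f"C{c + 1}"
        rng = _rng(config, 0, c)
        n_pat = config.patients_per_cohort
        patients = [f"{label}-P{j:04d}" for j in range(n_pat)]
        a = rng.standard_normal(n_pat)
        noise = rng.normal(0.0, config.noise_sd, size=(len(genes), n_pat))
        mean = np.full((len(genes), n_pat), config.baseline_expr)
        mean[signal] += config.factor_strength * a[None, :]
        values = _softplus(mean + noise)
        df = pd.DataFrame(values, index=genes, columns=patients)
        cohorts[label] = ExpressionMatrix(values=df, cohort=label)
        latent[label] = pd.Series(a, index=patients, name="activity")
        clinical_frames.append(
            _make_clinical(config, label, df, a, risk_model, rng)
        )

    clinical = ClinicalTable(records=pd.concat(clinical_frames))
    gene_sets, module_genes = _make_gene_sets(
        config, seed_g, hidden_g, excluded_g, decoy_g
    )
    annotations = _make_annotations(
        config, seed_g, hidden_g, excluded_g, decoy_g, core, module_genes
    )
    ppi = _make_ppi(config, genes, module_genes)

    return SimBundle(
        config=config,
        cohorts=cohorts,
        seed_genes=frozenset(seed_g),
        hidden_genes=frozenset(hidden_g),
        excluded_genes=frozenset(excluded_g),
        decoy_genes=frozenset(decoy_g),
        core_genes=core,
        module_genes=frozenset(module_genes),
        gene_sets=gene_sets,
        annotations=annotations,
        ppi=ppi,
        clinical=clinical,
        risk_model=risk_model,
        latent_activity=latent,
    )


def _make_risk_model(config, seed_g, hidden_g) -> RiskModel:
    rng = _rng(config, 1)
    risk_genes = seed_g + hidden_g
    # positive log-hazard loadings on pathway genes, scaled so the patient
    # risk score has roughly unit spread after log2 transform
    coefs = rng.uniform(0.5, 1.5, size=len(risk_genes))
    coefs *= config.risk_effect / (0.2 * len(risk_genes))
    return RiskModel(
        coefficients=pd.Series(coefs, index=risk_genes, name="coefficient")
    )


def _make_clinical(config, label, df, a, risk_model, rng) -> pd.DataFrame:
    patients = list(df.columns)
    n_pat = len(patients)
    # risk score on the same scale downstream scoring uses
    logx = np.log2(df.loc[risk_model.genes].to_numpy() + 1.0)
    score = risk_model.coefficients.to_numpy() @ logx
    score_c = score - score.mean()
    hazard = config.baseline_hazard * np.exp(score_c)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.uniform(200.0, 4000.0, size=n_pat)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    # subtype flag: top subtype_fraction of patients by latent activity
    # (thresholded, not sampled, so the flag deterministically tracks the
    # factor the classifier weights respond to)
    k = max(1, int(round(config.subtype_fraction * n_pat)))
    order = np.argsort(-a, kind="stable")
    flag = np.zeros(n_pat, dtype=int)
    flag[order[:k]] = 1

    # stage increases with a noisy copy of the risk score
    noisy = score_c + rng.normal(0.0, 0.5 * max(score_c.std(), 1e-9), n_pat)
    qs = np.quantile(noisy, [0.4, 0.7, 0.9])
    stage = np.select(
        [noisy <= qs[0], noisy <= qs[1], noisy <= qs[2]],
        ["I", "II", "III"],
        default="IV",
    )
    her2 = rng.random(n_pat) < 0.15
    rec = pd.DataFrame(
        {
            "cohort": label,
            "survival_time": np.round(time, 1),
            "event": event,
            "stage": stage,
            "tnbc": flag,
            "er_positive": 1 - flag,
            "pr_positive": 1 - flag,
            "her2_positive": her2.astype(int),
        },
        index=pd.Index(patients, name="patient"),
    )
    return rec


def _make_gene_sets(config, seed_g, hidden_g, excluded_g, decoy_g):
    rng = _rng(config, 2)
    sets: dict[str, frozenset[str]] = {SEED_SET_NAME: frozenset(seed_g)}
    desc = {SEED_SET_NAME: "planted seed pathway (training positives)"}
    # partition the excluded genes into a few stand-in hallmark sets
    n_sets = 4
    chunks = np.array_split(np.array(excluded_g), n_sets)
    for i, chunk in enumerate(chunks):
        if len(chunk) == 0:
            continue
        name = f"HALLMARK_OTHER_{i + 1}"
        sets[name] = frozenset(chunk.tolist())
        desc[name] = "stand-in for another curated hallmark set"
    # oncogenic analogue: the true pathway plus a sprinkle of decoys
    n_extra = max(1, len(decoy_g) // 20)
    extra = rng.choice(np.array(decoy_g), size=n_extra, replace=False)
    sets[ONCOGENIC_SET_NAME] = frozenset(seed_g + hidden_g + extra.tolist())
    desc[ONCOGENIC_SET_NAME] = "oncogenic-style reference set overlapping truth"
    module_pool = np.array(hidden_g + seed_g)
    module_genes = module_pool[: config.module_size].tolist()
    return GeneSetCollection(sets=sets, descriptions=desc), module_genes


def _make_annotations(
    config, seed_g, hidden_g, excluded_g, decoy_g, core, module_genes
) -> AnnotationTable:
    """Term annotations in which the truth set shares processes with the
    core genes, plus background terms and some electronic (IEA) records the
    experimental-evidence filter should drop."""
    rng = _rng(config, 3)
    records: list[tuple[str, str, str, str]] = []

    def add(gene, term_id, term_name, evidence):
        records.append((gene, term_id, term_name, evidence))

    # shared pathway terms: every core gene carries all of them; seed and
    # hidden genes carry random subsets, decoys almost never.  Planted-
    # module members are left out so the module's own term stays its only
    # marker (otherwise every shared term would induce a near-copy of the
    # planted subgraph).
    n_core_terms = 8
    core_terms = [f"GO:CORE{i:03d}" for i in range(n_core_terms)]
    for g in core:
        for t in core_terms:
            add(g, t, f"core pathway process {t[-3:]}", "IDA")
    skip = set(core) | set(module_genes)
    truth_rest = [g for g in seed_g + hidden_g if g not in skip]
    for g in truth_rest:
        k = rng.integers(2, n_core_terms)
        for t in rng.choice(core_terms, size=k, replace=False):
            add(g, t, f"core pathway process {t[-3:]}", "IMP")
    # planted-module term: exactly the module genes
    for g in module_genes:
        add(g, MODULE_TERM, "planted interaction module process", "IDA")
    # background terms over all genes; each core gene also carries a couple
    # of them so similarity rankings include weakly related genes
    all_genes = np.array(seed_g + hidden_g + excluded_g + decoy_g)
    n_bg_terms = 40
    for i in range(n_bg_terms):
        t = f"GO:BG{i:04d}"
        size = int(rng.integers(10, 60))
        for g in rng.choice(all_genes, size=size, replace=False):
            add(g, t, f"background process {i}", "IDA")
    for ci, g in enumerate(core):
        for j in range(2):
            i = (2 * ci + j) % n_bg_terms
            add(g, f"GO:BG{i:04d}", f"background process {i}", "IDA")
    # a slice of decoys gets a core term only with electronic evidence;
    # the experimental filter must remove these
    n_iea = len(decoy_g) // 10
    for g in rng.choice(np.array(decoy_g), size=n_iea, replace=False):
        add(g, core_terms[0], "core pathway process 000", "IEA")
    df = pd.DataFrame(
        records, columns=["gene", "term_id", "term_name", "evidence"]
    ).drop_duplicates(subset=["gene", "term_id", "evidence"])
    df = df.sort_values(["gene", "term_id", "evidence"]).reset_index(drop=True)
    return AnnotationTable(records=df)


def _make_ppi(config, genes, module_genes) -> nx.Graph:
    """Scale-free background graph with one planted, densely connected
    module over pathway genes."""
    rng = _rng(config, 4)
    nodes = list(module_genes)
    others = [g for g in genes if g not in set(module_genes)]
    n_more = config.ppi_nodes - len(nodes)
    nodes += list(rng.choice(np.array(others), size=n_more, replace=False))
    ba_seed = int(rng.integers(0, 2**31 - 1))
    backbone = nx.barabasi_albert_graph(
        len(nodes), config.ppi_attachment, seed=ba_seed
    )
    graph = nx.relabel_nodes(backbone, dict(enumerate(nodes)))
    # plant the module: spanning path plus random extra edges, giving a
    # connected subgraph denser than the scale-free background
    m = list(module_genes)
    for i in range(len(m) - 1):
        graph.add_edge(m[i], m[i + 1])
    for i in range(len(m)):
        for j in range(i + 2, len(m)):
            if rng.random() < 0.4:
                graph.add_edge(m[i], m[j])
    graph.remove_edges_from(nx.selfloop_edges(graph))
    return graph


def config_from_dict(d: dict) -> SimConfig:
    """Build a :class:`SimConfig` from a plain dict (e.g. parsed YAML)."""
    fields = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(d) - fields
    if unknown:
        raise ValueError(f"unknown simulation parameters {sorted(unknown)}")
    return SimConfig(**d)
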
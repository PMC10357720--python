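"""Typed containers and readers/writers for the file formats the toolkit touches.

Expression matrices are gene x patient TSV (first column gene symbols, header
row patient barcodes).  Gene sets travel as GMT, functional annotations as a
GAF-like four-column TSV, protein-protein interactions as a two-column edge
list.  Gene identifiers are matched by exact, case-sensitive string equality
throughout; callers are expected to pre-map symbols.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# Gene Ontology evidence-code vocabulary (experimental, phylogenetic,
# computational, author/curator, electronic).
EVIDENCE_CODES = frozenset(
    {
        "EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "HTP", "HDA", "HMP",
        "HGI", "HEP", "IBA", "IBD", "IKR", "IRD", "ISS", "ISO", "ISA",
        "ISM", "IGC", "RCA", "TAS", "NAS", "IC", "ND", "IEA",
    }
)

#: Default filter used to operationalize "experimentally validated" terms.
EXPERIMENTAL_EVIDENCE = frozenset({"EXP", "IDA", "IPI", "IMP", "IGI", "IEP"})


@dataclass
class ExpressionMatrix:
    """Non-negative gene x patient expression values for one cohort.

    ``values`` is a DataFrame with unique gene symbols as the index and
    unique patient barcodes as columns.  Values are assumed normalized
    abundance (TPM-like); no further normalization is applied.
    """

    values: pd.DataFrame
    cohort: str

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] == 0 or v.shape[1] == 0:
            raise FormatError(f"empty expression matrix for cohort {self.cohort!r}")
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups[:5]}")
        if v.columns.duplicated().any():
            raise FormatError("duplicate patient ids")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("non-numeric expression values")
        if not np.isfinite(arr).all():
            raise FormatError("expression values must be finite (no NA/inf)")
        if (arr < 0).any():
            raise FormatError("expression values must be >= 0")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_patients(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")


def read_expression(path, cohort: str) -> ExpressionMatrix:
    """Read a gene x patient TSV into a validated :class:`ExpressionMatrix`.

    Duplicate gene rows are collapsed by their mean (deterministic and
    order-independent) with a logged warning.  Any non-numeric or missing
    cell is a :class:`FormatError`.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse expression TSV {path}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"empty expression matrix in {path}")
    if df.isna().any().any():
        raise FormatError(f"missing/NA cells in expression matrix {path}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise FormatError(f"non-numeric column {col!r} in {path}")
    if df.index.duplicated().any():
        n_dup = int(df.index.duplicated().sum())
        logger.warning(
            "%s: collapsing %d duplicated gene row(s) by mean", path, n_dup
        )
        df = df.groupby(level=0, sort=False).mean()
    df.index = df.index.astype(str)
    df.index.name = "gene"
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(values=df.astype(float), cohort=cohort)


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. MSigDB hallmark collections)."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise FormatError(f"gene set {name!r} is empty")
            self.sets[name] = frozenset(members)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return frozenset(out)

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name, members in self.sets.items():
                desc = self.descriptions.get(name, "")
                fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one tab-separated line per set (name, description,
    members...).  Duplicate set names are an error."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 fields, got {len(fields)}"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            if not members:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = frozenset(members)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


@dataclass
class AnnotationTable:
    """Gene -> functional-term records with evidence codes.

    ``records`` has columns gene, term_id, term_name, evidence; the
    (gene, term_id, evidence) triples are unique.
    """

    records: pd.DataFrame

    REQUIRED = ("gene", "term_id", "term_name", "evidence")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise FormatError(f"annotation table missing columns {missing}")
        bad = set(self.records["evidence"]) - EVIDENCE_CODES
        if bad:
            raise FormatError(f"unknown evidence codes {sorted(bad)}")
        if self.records.duplicated(subset=["gene", "term_id", "evidence"]).any():
            raise FormatError("duplicate (gene, term, evidence) triples")

    def term_sets(
        self, evidence_filter: frozenset[str] = EXPERIMENTAL_EVIDENCE
    ) -> GeneSetCollection:
        """Group the filtered records into term -> gene sets."""
        kept = self.records[self.records["evidence"].isin(evidence_filter)]
        if kept.empty:
            logger.warning("no annotation records survive the evidence filter")
            return GeneSetCollection()
        sets = {}
        descriptions = {}
        for term_id, grp in kept.groupby("term_id", sort=True):
            sets[str(term_id)] = frozenset(grp["gene"])
            descriptions[str(term_id)] = str(grp["term_name"].iloc[0])
        return GeneSetCollection(sets=sets, descriptions=descriptions)

    def gene_terms(
        self, evidence_filter: frozenset[str] = EXPERIMENTAL_EVIDENCE
    ) -> dict[str, frozenset[str]]:
        """Per-gene set of annotated term ids after evidence filtering."""
        kept = self.records[self.records["evidence"].isin(evidence_filter)]
        return {
            str(gene): frozenset(grp["term_id"])
            for gene, grp in kept.groupby("gene", sort=True)
        }

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def read_annotations(path, evidence_filter: frozenset[str] | None = None):
    """Read a GAF-style TSV (gene, term_id, term_name, evidence) and group it
    into a term-keyed :class:`GeneSetCollection`.

    Records with evidence codes outside the known vocabulary are dropped
    with a warning; ``evidence_filter`` (default: experimental codes) then
    selects which records are kept.
    """
    if evidence_filter is None:
        evidence_filter = EXPERIMENTAL_EVIDENCE
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in AnnotationTable.REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    unknown = ~df["evidence"].isin(EVIDENCE_CODES)
    if unknown.any():
        logger.warning(
            "%s: dropping %d record(s) with unknown evidence codes %s",
            path,
            int(unknown.sum()),
            sorted(set(df.loc[unknown, "evidence"])),
        )
        df = df[~unknown]
    table = AnnotationTable(records=df.reset_index(drop=True))
    return table.term_sets(frozenset(evidence_filter))


def read_annotation_table(path) -> AnnotationTable:
    """Read the raw annotation records (unknown evidence dropped, no filter)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in AnnotationTable.REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    unknown = ~df["evidence"].isin(EVIDENCE_CODES)
    if unknown.any():
        logger.warning(
            "%s: dropping %d record(s) with unknown evidence codes",
            path,
            int(unknown.sum()),
        )
        df = df[~unknown]
    return AnnotationTable(records=df.reset_index(drop=True))


def read_ppi(path) -> nx.Graph:
    """Read a two-column edge list into an undirected simple graph.

    Self-loops and duplicate (or orientation-flipped) edges are dropped;
    counts are logged.  Rows with a field count other than two are a
    :class:`FormatError`.
    """
    graph = nx.Graph()
    n_self = 0
    n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
                )
            a, b = fields
            if a == b:
                n_self += 1
                continue
            if graph.has_edge(a, b):
                n_dup += 1
                continue
            graph.add_edge(a, b)
    if n_self or n_dup:
        logger.info(
            "%s: dropped %d self-loop(s) and %d duplicate edge(s)",
            path, n_self, n_dup,
        )
    return graph


def write_ppi(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{a}\t{b}\n")


CLINICAL_COLUMNS = ("cohort", "survival_time", "event", "stage")
STAGES = ("I", "II", "III", "IV", "unknown")


@dataclass
class ClinicalTable:
    """Per-patient clinical covariates, indexed by patient barcode.

    Required columns: cohort, survival_time (days), event (0/1), stage
    (ordinal I..IV or 'unknown').  Additional columns hold subtype flags
    (e.g. ER/PR/HER2 status, a TNBC indicator).
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CLINICAL_COLUMNS if c not in self.records.columns]
        if missing:
            raise FormatError(f"clinical table missing columns {missing}")
        if self.records.index.duplicated().any():
            raise FormatError("patient present in more than one clinical row")
        if (self.records["survival_time"] < 0).any():
            raise FormatError("negative survival_time")
        if not set(self.records["event"]).issubset({0, 1}):
            raise FormatError("event must be 0/1")
        bad = set(self.records["stage"]) - set(STAGES)
        if bad:
            raise FormatError(f"unknown stages {sorted(bad)}")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.records.index)

    def for_cohort(self, cohort: str) -> pd.DataFrame:
        return self.records[self.records["cohort"] == cohort]

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index_label="patient")


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ClinicalTable(records=df)


@dataclass
class RiskModel:
    """Per-gene coefficients on the log-hazard scale (a pre-trained
    proportional-hazards signature, consumed as-is)."""

    coefficients: pd.Series

    def __post_init__(self) -> None:
        if not np.isfinite(self.coefficients.to_numpy(dtype=float)).all():
            raise FormatError("risk coefficients must be finite")
        self.coefficients = self.coefficients.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.coefficients.index)

    def to_tsv(self, path) -> None:
        self.coefficients.rename("coefficient").to_csv(
            path, sep="\t", index_label="gene"
        )


def read_risk_model(path) -> RiskModel:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] != 1:
        raise FormatError(f"{path}: expected columns (gene, coefficient)")
    return RiskModel(coefficients=df.iloc[:, 0])
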
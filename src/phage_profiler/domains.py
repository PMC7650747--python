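"""Protein-domain phyletic profiles: presence-absence matrix, Ward clustering,
cluster/singleton assignment, and a rule-based temperate-marker flag.

The domain search itself (RPS-BLAST against a conserved-domain database) is
external; this module consumes its tabular output.  Clustering follows the
Ward-D2 criterion (squared distances inside the Lance-Williams update,
heights on the original Euclidean scale), computed on the binary
genome x domain rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from .dendrogram import Dendrogram

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("genome_id", "protein_id", "domain_accession", "evalue")
DEFAULT_COLUMNS = (
    "genome_id",
    "protein_id",
    "domain_accession",
    "domain_name",
    "evalue",
    "bitscore",
)


@dataclass(frozen=True)
class DomainHit:
    """One domain hit from an RPS-BLAST-style tabular search."""

    genome_id: str
    protein_id: str
    domain_accession: str
    evalue: float
    domain_name: str = ""
    bitscore: float = 0.0


@dataclass
class ClusterAssignment:
    """Flat cluster labels plus the genomes flagged as singletons."""

    labels: dict[str, str]
    singletons: set[str] = field(default_factory=set)

    @property
    def ids(self) -> list[str]:
        return sorted(self.labels)

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def label_list(self, ids: Sequence[str] | None = None) -> list[str]:
        return [self.labels[g] for g in (ids if ids is not None else self.ids)]


def parse_domain_hits(
    table: str | Path,
    evalue_cutoff: float = 0.001,
    columns: Sequence[str] | None = None,
) -> list[DomainHit]:
    """Parse a tab-separated domain-hit table, keeping hits with
    ``evalue <= cutoff`` (the cutoff is inclusive).

    With ``columns=None`` the file must carry a header naming at least
    ``genome_id, protein_id, domain_accession, evalue``; otherwise
    ``columns`` gives the column names in file order and no header is read.
    Rows whose e-value does not parse are dropped with a logged warning.
    """
    if columns is None:
        df = pd.read_csv(table, sep="\t", header=0, dtype=str)
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"malformed header: missing columns {missing}")
    else:
        df = pd.read_csv(table, sep="\t", header=None, names=list(columns), dtype=str)
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"column map missing required columns {missing}")
    if df.empty:
        return []
    evalues = pd.to_numeric(df["evalue"], errors="coerce")
    bad = evalues.isna() | (evalues < 0)
    if bad.any():
        logger.warning("dropping %d rows with unparseable or negative e-values", int(bad.sum()))
    df = df[~bad].copy()
    evalues = evalues[~bad]
    keep = evalues <= evalue_cutoff
    df = df[keep]
    evalues = evalues[keep]
    bitscores = (
        pd.to_numeric(df["bitscore"], errors="coerce").fillna(0.0)
        if "bitscore" in df.columns
        else pd.Series(0.0, index=df.index)
    )
    names = df["domain_name"] if "domain_name" in df.columns else pd.Series("", index=df.index)
    return [
        DomainHit(
            genome_id=str(g),
            protein_id=str(p),
            domain_accession=str(a),
            evalue=float(e),
            domain_name=str(nm),
            bitscore=float(b),
        )
        for g, p, a, e, nm, b in zip(
            df["genome_id"], df["protein_id"], df["domain_accession"], evalues, names, bitscores
        )
    ]


def build_pa_matrix(
    hits_by_genome: Mapping[str, Sequence[DomainHit]],
    pfam_only: bool = True,
) -> pd.DataFrame:
    """Binary genomes x domain-accessions matrix (1 = at least one hit).

    Rows are all genomes in the input (genomes without hits keep an all-zero
    row); columns are the sorted union of accessions seen, so no column is
    all-zero.  ``pfam_only`` restricts columns to Pfam-prefixed accessions.
    """
    if not hits_by_genome:
        raise ValueError("at least one genome required")
    genomes = sorted(hits_by_genome)
    accessions: set[str] = set()
    presence: dict[str, set[str]] = {g: set() for g in genomes}
    for g, hits in hits_by_genome.items():
        for h in hits:
            acc = h.domain_accession
            if pfam_only and not acc.upper().startswith("PF"):
                continue
            accessions.add(acc)
            presence[g].add(acc)
    cols = sorted(accessions)
    data = np.zeros((len(genomes), len(cols)), dtype=np.int8)
    col_index = {a: j for j, a in enumerate(cols)}
    for i, g in enumerate(genomes):
        for acc in presence[g]:
            data[i, col_index[acc]] = 1
    return pd.DataFrame(data, index=pd.Index(genomes, name="genome_id"), columns=cols)


def ward_dendrogram(matrix: pd.DataFrame, criterion: str = "ward2") -> Dendrogram:
    """Agglomerative Ward clustering of the presence-absence rows.

    Distances are Euclidean on the binary rows.  ``ward2`` (default) is the
    Ward-D2 criterion with heights on the Euclidean scale; ``ward1`` applies
    the Lance-Williams Ward update to the unsquared distances.  Rows are
    sorted lexicographically by genome id first, which fixes tie-breaking.
    """
    if matrix.shape[0] < 1:
        raise ValueError("matrix must have at least one genome")
    matrix = matrix.sort_index()
    ids = [str(g) for g in matrix.index]
    if matrix.shape[0] == 1:
        return Dendrogram(ids=ids)
    X = matrix.to_numpy(dtype=float)
    y = pdist(X, metric="euclidean")
    if criterion == "ward2":
        Z = linkage(y, method="ward")
    elif criterion == "ward1":
        Z = linkage(np.sqrt(y), method="ward")
        Z = Z.copy()
        Z[:, 2] **= 2
    else:
        raise ValueError(f"unknown criterion: {criterion!r}")
    return Dendrogram(ids=ids, linkage=Z)


def shared_domain_counts(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise counts of domains shared between genomes."""
    X = matrix.to_numpy(dtype=np.int64)
    S = X @ X.T
    return pd.DataFrame(S, index=matrix.index, columns=matrix.index)


def cut_and_flag(
    dendrogram: Dendrogram,
    matrix: pd.DataFrame,
    n_clusters: int | None = None,
    height: float | None = None,
    singleton_min_shared: int = 3,
) -> ClusterAssignment:
    """Cut the tree into flat clusters and re-flag divergent singletons.

    A genome sharing fewer than ``singleton_min_shared`` domains with every
    other genome is re-labelled as its own singleton regardless of where the
    cut placed it -- the analogue of a phage too divergent to join any
    cluster.
    """
    if n_clusters is not None and n_clusters > dendrogram.n_leaves:
        raise ValueError("n_clusters exceeds number of genomes")
    raw = dendrogram.cut(n_clusters=n_clusters, height=height)
    matrix = matrix.sort_index()
    if list(matrix.index) != sorted(dendrogram.ids):
        raise ValueError("matrix and dendrogram cover different genomes")
    S = shared_domain_counts(matrix).to_numpy()
    np.fill_diagonal(S, -1)
    max_shared = S.max(axis=1) if S.shape[0] > 1 else np.full(S.shape[0], -1)
    labels: dict[str, str] = {}
    singletons: set[str] = set()
    for i, gid in enumerate(matrix.index):
        if max_shared[i] < singleton_min_shared:
            labels[gid] = f"singleton_{gid}"
            singletons.add(gid)
        else:
            labels[gid] = f"cluster_{raw[gid]}"
    return ClusterAssignment(labels=labels, singletons=singletons)


_MARKER_FILE = Path(__file__).parent / "data" / "temperate_markers.yaml"


def default_marker_accessions() -> list[str]:
    with open(_MARKER_FILE) as fh:
        data = yaml.safe_load(fh)
    return list(data["marker_accessions"])


def lifestyle_flags(
    hits: Sequence[DomainHit],
    marker_accessions: Sequence[str] | None = None,
) -> str:
    """Evidence flag for a temperate lifestyle.

    Returns ``"temperate-evidence"`` if at least one configured marker domain
    (integrase/recombinase or immunity-repressor families by default) is
    present, else ``"no-temperate-evidence"``.  This flags genomic evidence
    only; it is not a lifestyle prediction.  Accession matching is
    case-insensitive.
    """
    markers = marker_accessions if marker_accessions is not None else default_marker_accessions()
    if not markers:
        raise ValueError("marker accession list must be non-empty")
    marker_set = {m.upper() for m in markers}
    for h in hits:
        if h.domain_accession.upper() in marker_set:
            return "temperate-evidence"
    return "no-temperate-evidence"
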
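"""Reading, validation, alignment and tabular export of pipeline inputs.

Two delimited text files drive the pipeline: a wide-format enrichment
table (first column pathway identifiers, remaining columns one numeric
enrichment metric per analysis) and an embedding matrix (first column
pathway identifiers, remaining columns embedding dimensions).  Both may
be comma- or tab-separated; the delimiter is sniffed from the header
line unless given explicitly.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_GO_SPACE = re.compile(r"^(GO:)\s+")


def normalize_pathway_id(token: str) -> str:
    """Trim whitespace and collapse the typesetting space in ``GO: 0005739``.

    Matching elsewhere is exact string comparison; no case folding or
    fuzzy normalization is applied beyond this.
    """
    token = str(token).strip()
    return _GO_SPACE.sub(r"\1", token)


@dataclass
class EnrichmentTable:
    """Pathways x analyses matrix of enrichment metrics (NaN = missing)."""

    pathway_ids: list[str]
    analysis_names: list[str]
    values: np.ndarray  # shape (n_pathways, n_analyses), float64

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = len(self.pathway_ids), len(self.analysis_names)
        if n < 1 or m < 1:
            raise ValueError("enrichment table needs >= 1 pathway and >= 1 analysis")
        if self.values.shape != (n, m):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({n} pathways, {m} analyses)"
            )
        _check_unique(self.pathway_ids, "pathway ID")
        _check_unique(self.analysis_names, "analysis name")

    @property
    def n_pathways(self) -> int:
        return len(self.pathway_ids)

    @property
    def n_analyses(self) -> int:
        return len(self.analysis_names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.pathway_ids, columns=self.analysis_names
        )


@dataclass
class EmbeddingMatrix:
    """Pathways x dimensions real-valued embedding matrix.

    All entries must be finite and every row must have nonzero L2 norm
    (cosine similarity is undefined for the zero vector).
    """

    pathway_ids: list[str]
    vectors: np.ndarray  # shape (n_pathways, dim), float64

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2:
            raise ValueError("embedding vectors must form a 2-D matrix")
        if self.vectors.shape[0] != len(self.pathway_ids):
            raise ValueError("one embedding row required per pathway ID")
        _check_unique(self.pathway_ids, "pathway ID")
        bad = ~np.isfinite(self.vectors)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-finite embedding value for pathway {self.pathway_ids[i]!r} "
                f"(dimension {j + 1})"
            )
        norms = np.linalg.norm(self.vectors, axis=1)
        zero = np.flatnonzero(norms == 0.0)
        if zero.size:
            ids = [self.pathway_ids[i] for i in zero]
            raise ValueError(f"zero-norm embedding rows (cosine undefined): {ids}")

    @property
    def n_pathways(self) -> int:
        return len(self.pathway_ids)

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def row(self, pathway_id: str) -> np.ndarray:
        try:
            i = self.pathway_ids.index(pathway_id)
        except ValueError:
            raise KeyError(f"unknown pathway ID {pathway_id!r}") from None
        return self.vectors[i]


@dataclass
class AlignedDataset:
    """Enrichment table and embeddings restricted to a shared pathway set."""

    table: EnrichmentTable
    embeddings: EmbeddingMatrix
    dropped_from_table: list[str] = field(default_factory=list)
    dropped_from_embeddings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.table.pathway_ids != self.embeddings.pathway_ids:
            raise ValueError("aligned table and embeddings must share ID order")


def _check_unique(items: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for x in items:
        if not x:
            raise ValueError(f"empty {what} not allowed")
        seen[x] = seen.get(x, 0) + 1
        if seen[x] == 2:
            dups.append(x)
    if dups:
        raise ValueError(f"duplicate {what}s: {dups}")


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    # Tab wins whenever present: TSV headers may legally contain commas.
    return "\t" if "\t" in header else ","


def _read_delimited(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = delimiter if delimiter is not None else _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, header=0, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(
            f"{path}: need >= 2 columns (identifiers + at least one data column); "
            f"found {df.shape[1]} with delimiter {sep!r}"
        )
    return df


_NA_TOKENS = {"", "na", "nan", "n/a", "null", "none"}


def _numeric_block(df: pd.DataFrame, path: Path, allow_missing: bool) -> np.ndarray:
    """Parse all columns after the first as floats, locating bad cells."""
    out = np.empty((df.shape[0], df.shape[1] - 1), dtype=float)
    for j, col in enumerate(df.columns[1:]):
        raw = df[col].astype(str).str.strip()
        is_na = raw.str.lower().isin(_NA_TOKENS)
        parsed = pd.to_numeric(raw.mask(is_na), errors="coerce")
        bad = parsed.isna() & ~is_na
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric value {raw.iloc[i]!r} in column {col!r}, "
                f"row {i + 2} (counting the header as row 1)"
            )
        if not allow_missing and is_na.any():
            i = int(np.flatnonzero(is_na.to_numpy())[0])
            raise ValueError(
                f"{path}: missing value in column {col!r}, row {i + 2} "
                f"(counting the header as row 1); embeddings must be complete"
            )
        # builtin float() is correctly rounded; pandas' fast parser is not
        out[:, j] = [
            np.nan if na else float(x) for x, na in zip(raw, is_na)
        ]
    return out


def read_enrichment_table(
    path: str | Path, delimiter: str | None = None
) -> EnrichmentTable:
    """Read a wide-format enrichment table (TSV or CSV).

    First column: pathway identifiers.  Remaining columns: one real
    enrichment metric per analysis; empty/NA cells are kept as missing.
    """
    path = Path(path)
    df = _read_delimited(path, delimiter)
    ids = [normalize_pathway_id(x) for x in df.iloc[:, 0]]
    values = _numeric_block(df, path, allow_missing=True)
    return EnrichmentTable(
        pathway_ids=ids,
        analysis_names=[str(c).strip() for c in df.columns[1:]],
        values=values,
    )


def read_embeddings(path: str | Path, delimiter: str | None = None) -> EmbeddingMatrix:
    """Read a pathway-embedding matrix (TSV or CSV); no missing cells allowed."""
    path = Path(path)
    df = _read_delimited(path, delimiter)
    ids = [normalize_pathway_id(x) for x in df.iloc[:, 0]]
    vectors = _numeric_block(df, path, allow_missing=False)
    return EmbeddingMatrix(pathway_ids=ids, vectors=vectors)


def align_inputs(
    table: EnrichmentTable, embeddings: EmbeddingMatrix
) -> AlignedDataset:
    """Restrict both inputs to their shared pathway set, in table row order.

    Pathways present on only one side are dropped with a logged warning;
    an empty intersection is a hard error.
    """
    emb_index = {pid: i for i, pid in enumerate(embeddings.pathway_ids)}
    kept = [pid for pid in table.pathway_ids if pid in emb_index]
    if not kept:
        raise ValueError(
            "no pathway IDs shared between the enrichment table and the embeddings"
        )
    kept_set = set(kept)
    dropped_tab = [p for p in table.pathway_ids if p not in kept_set]
    dropped_emb = [p for p in embeddings.pathway_ids if p not in kept_set]
    if dropped_tab:
        logger.warning(
            "%d pathway(s) in the enrichment table lack embeddings and were "
            "dropped: %s", len(dropped_tab), dropped_tab
        )
    if dropped_emb:
        logger.warning(
            "%d embedding row(s) absent from the enrichment table were "
            "dropped: %s", len(dropped_emb), dropped_emb
        )
    tab_index = {pid: i for i, pid in enumerate(table.pathway_ids)}
    rows_t = [tab_index[p] for p in kept]
    rows_e = [emb_index[p] for p in kept]
    return AlignedDataset(
        table=EnrichmentTable(
            pathway_ids=list(kept),
            analysis_names=list(table.analysis_names),
            values=table.values[rows_t],
        ),
        embeddings=EmbeddingMatrix(
            pathway_ids=list(kept), vectors=embeddings.vectors[rows_e]
        ),
        dropped_from_table=dropped_tab,
        dropped_from_embeddings=dropped_emb,
    )


def write_enrichment_table(table: EnrichmentTable, path: str | Path) -> Path:
    """Write an enrichment table as TSV (missing cells left blank)."""
    path = Path(path)
    df = table.to_frame()
    df.index.name = "Pathway"
    df.to_csv(path, sep="\t", na_rep="", float_format="%.17g")
    return path


def write_embeddings(embeddings: EmbeddingMatrix, path: str | Path) -> Path:
    """Write an embedding matrix as TSV with dimension columns V1..Vd."""
    path = Path(path)
    df = pd.DataFrame(
        embeddings.vectors,
        index=embeddings.pathway_ids,
        columns=[f"V{j + 1}" for j in range(embeddings.dim)],
    )
    df.index.name = "Pathway"
    df.to_csv(path, sep="\t", float_format="%.17g")
    return path


def write_cluster_table(summaries, assignment, path: str | Path) -> Path:
    """Write the per-pathway cluster table as TSV.

    Columns: pathway_id, cluster_id, is_mrt (0/1), cosine_to_centroid.
    Rows are ordered by cluster_id ascending, then cosine descending,
    then pathway_id ascending, so reruns are byte-identical.
    """
    path = Path(path)
    rows = []
    for s in summaries:
        for pid in s.members:
            rows.append(
                (
                    pid,
                    s.cluster_id,
                    int(pid == s.mrt),
                    s.member_similarities[pid],
                )
            )
    rows.sort(key=lambda r: (r[1], -r[3], r[0]))
    df = pd.DataFrame(
        rows, columns=["pathway_id", "cluster_id", "is_mrt", "cosine_to_centroid"]
    )
    df.to_csv(path, sep="\t", index=False)
    return path
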
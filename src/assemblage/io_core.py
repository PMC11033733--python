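"""Feature tables, metadata, presence/absence matrices and alpha diversity.

The canonical in-memory orientation is samples x taxa for count tables.
:class:`BinaryMatrix` alone is taxa x samples, because co-occurrence
statistics operate on taxon pairs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "BinaryMatrix",
    "read_feature_table",
    "write_feature_table",
    "read_metadata",
    "to_binary",
    "relative_abundance",
    "aggregate_taxonomy",
    "alpha_diversity",
]

#: ordered taxonomy ranks handled by :func:`aggregate_taxonomy`
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

METADATA_COLUMNS = ("sample_id", "calf_id", "week", "treatment", "health")


@dataclass
class FeatureTable:
    """Samples x taxa non-negative integer count matrix with IDs.

    Parameters
    ----------
    counts
        ``(n_samples, n_taxa)`` array of non-negative integers.
    sample_ids, taxon_ids
        Unique string identifiers for the rows and columns of ``counts``.
    taxonomy
        Optional per-taxon lineage strings (semicolon-separated,
        kingdom -> genus).
    """

    counts: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]
    taxonomy: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if self.counts.size == 0:
            raise ValueError("empty feature table")
        if (self.counts < 0).any():
            raise ValueError("negative counts are not allowed")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        n_s, n_t = self.counts.shape
        if len(self.sample_ids) != n_s:
            raise ValueError("sample_ids length does not match counts rows")
        if len(self.taxon_ids) != n_t:
            raise ValueError("taxon_ids length does not match counts columns")
        if len(set(self.sample_ids)) != n_s:
            raise ValueError("duplicate sample IDs")
        if len(set(self.taxon_ids)) != n_t:
            raise ValueError("duplicate taxon IDs")
        if self.taxonomy is not None and len(self.taxonomy) != n_t:
            raise ValueError("taxonomy length does not match taxon count")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    def select_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        """Subset (and reorder) samples; taxonomy is carried along."""
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in sample_ids]
        return FeatureTable(
            self.counts[rows],
            list(sample_ids),
            list(self.taxon_ids),
            None if self.taxonomy is None else list(self.taxonomy),
        )


@dataclass
class BinaryMatrix:
    """Taxa x samples presence/absence matrix.

    Degenerate (all-zero) rows and columns are dropped at construction with
    a warning; downstream null models require non-trivial marginals.
    """

    entries: np.ndarray
    taxon_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        e = np.asarray(self.entries)
        if not np.isin(e, (0, 1)).all():
            raise ValueError("binary matrix entries must be 0 or 1")
        e = e.astype(np.uint8)
        row_keep = e.sum(axis=1) > 0
        col_keep = e.sum(axis=0) > 0
        if not row_keep.all() or not col_keep.all():
            n_r = int((~row_keep).sum())
            n_c = int((~col_keep).sum())
            warnings.warn(
                f"dropping {n_r} all-zero taxa and {n_c} all-zero samples "
                "from binary matrix"
            )
            e = e[row_keep][:, col_keep]
            self.taxon_ids = [t for t, k in zip(self.taxon_ids, row_keep) if k]
            self.sample_ids = [s for s, k in zip(self.sample_ids, col_keep) if k]
        self.entries = e
        if len(self.taxon_ids) != e.shape[0] or len(self.sample_ids) != e.shape[1]:
            raise ValueError("ID lengths do not match matrix shape")

    @property
    def n_taxa(self) -> int:
        return self.entries.shape[0]

    @property
    def n_samples(self) -> int:
        return self.entries.shape[1]


def _require_integer_frame(df: pd.DataFrame, path: str) -> np.ndarray:
    arr = df.to_numpy()
    try:
        farr = arr.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell in feature table") from exc
    if not np.all(np.equal(np.mod(farr, 1), 0)):
        raise ValueError(f"{path}: non-integer counts in feature table")
    return farr.astype(np.int64)


def read_feature_table(
    path: str | Path, format: Literal["tsv", "biom-json"] = "tsv"
) -> FeatureTable:
    """Read a feature table from TSV (taxa rows x sample columns) or BIOM-JSON.

    The TSV dialect stores taxa as rows and samples as columns with the first
    column holding taxon IDs; the table is transposed on load to the
    canonical samples x taxa orientation.  An optional trailing ``taxonomy``
    column is honoured.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
        if df.empty:
            raise ValueError(f"{path}: empty feature table")
        taxonomy = None
        if "taxonomy" in df.columns:
            taxonomy = df["taxonomy"].tolist()
            df = df.drop(columns=["taxonomy"])
        counts = _require_integer_frame(df, str(path))
        taxon_ids = [str(t) for t in df.index]
        sample_ids = [str(s) for s in df.columns]
        if len(set(taxon_ids)) != len(taxon_ids):
            raise ValueError(f"{path}: duplicate taxon IDs")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError(f"{path}: duplicate sample IDs")
        return FeatureTable(counts.T, sample_ids, taxon_ids, taxonomy)
    if format == "biom-json":
        return _read_biom_json(path)
    raise ValueError(f"unknown format: {format!r}")


def _read_biom_json(path: Path) -> FeatureTable:
    # BIOM v1.0: rows = observations (taxa), columns = samples.
    with open(path) as fh:
        doc = json.load(fh)
    n_taxa, n_samples = doc["shape"]
    if n_taxa == 0 or n_samples == 0:
        raise ValueError(f"{path}: empty BIOM table")
    dense = np.zeros((n_taxa, n_samples), dtype=float)
    data = doc["data"]
    if doc.get("matrix_type", "sparse") == "dense":
        dense = np.asarray(data, dtype=float)
    else:
        for r, c, v in data:
            dense[int(r), int(c)] = v
    if not np.all(np.equal(np.mod(dense, 1), 0)):
        raise ValueError(f"{path}: non-integer counts in BIOM table")
    if (dense < 0).any():
        raise ValueError(f"{path}: negative counts in BIOM table")
    taxon_ids = [str(r["id"]) for r in doc["rows"]]
    sample_ids = [str(c["id"]) for c in doc["columns"]]
    if len(set(taxon_ids)) != n_taxa or len(set(sample_ids)) != n_samples:
        raise ValueError(f"{path}: duplicate IDs in BIOM table")
    taxonomy = None
    if all(r.get("metadata") and "taxonomy" in r["metadata"] for r in doc["rows"]):
        taxonomy = []
        for r in doc["rows"]:
            tx = r["metadata"]["taxonomy"]
            taxonomy.append("; ".join(tx) if isinstance(tx, list) else str(tx))
    return FeatureTable(dense.astype(np.int64).T, sample_ids, taxon_ids, taxonomy)


def write_feature_table(
    table: FeatureTable, path: str | Path, format: Literal["tsv", "biom-json"] = "tsv"
) -> None:
    """Write a feature table; the inverse of :func:`read_feature_table`."""
    path = Path(path)
    if format == "tsv":
        df = pd.DataFrame(
            table.counts.T, index=table.taxon_ids, columns=table.sample_ids
        )
        df.index.name = "taxon_id"
        if table.taxonomy is not None:
            df["taxonomy"] = table.taxonomy
        df.to_csv(path, sep="\t")
        return
    if format == "biom-json":
        mat = table.counts.T  # taxa x samples
        data = [
            [int(r), int(c), int(mat[r, c])]
            for r, c in zip(*np.nonzero(mat))
        ]
        rows = []
        for i, t in enumerate(table.taxon_ids):
            meta = None
            if table.taxonomy is not None:
                meta = {"taxonomy": [p.strip() for p in table.taxonomy[i].split(";")]}
            rows.append({"id": t, "metadata": meta})
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "assemblage",
            "date": "",
            "matrix_type": "sparse",
            "matrix_element_type": "int",
            "shape": [len(table.taxon_ids), len(table.sample_ids)],
            "rows": rows,
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": data,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
        return
    raise ValueError(f"unknown format: {format!r}")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata TSV with the required cohort columns.

    Validates column presence, week values, treatment/health levels and the
    one-sample-per-calf-week constraint.
    """
    md = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "calf_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in md.columns]
    if missing:
        raise ValueError(f"metadata is missing required columns: {missing}")
    md["week"] = md["week"].astype(int)
    bad_week = sorted(set(md["week"]) - {1, 2, 3, 6, 8})
    if bad_week:
        raise ValueError(f"unexpected week values: {bad_week}")
    for col, levels in (("treatment", {"CON", "SCB"}), ("health", {"H", "UH"})):
        bad = sorted(set(md[col]) - levels)
        if bad:
            raise ValueError(f"unexpected {col} values: {bad}")
    if md.duplicated(["calf_id", "week"]).any():
        raise ValueError("more than one sample for a calf-week combination")
    if md["sample_id"].duplicated().any():
        raise ValueError("duplicate sample IDs in metadata")
    return md


def to_binary(table: FeatureTable, detection_threshold: int = 1) -> BinaryMatrix:
    """Presence/absence (taxa x samples): 1 iff count >= detection_threshold."""
    if detection_threshold < 1:
        raise ValueError("detection_threshold must be >= 1")
    entries = (table.counts >= detection_threshold).astype(np.uint8).T
    return BinaryMatrix(entries, list(table.taxon_ids), list(table.sample_ids))


def relative_abundance(table: FeatureTable) -> np.ndarray:
    """Row-normalized proportions (samples x taxa); rows sum to 1."""
    totals = table.counts.sum(axis=1)
    zero = np.nonzero(totals == 0)[0]
    if zero.size:
        bad = [table.sample_ids[i] for i in zero]
        raise ValueError(f"samples with zero total count: {bad}")
    return table.counts / totals[:, None]


def _rank_label(lineage: str, rank_index: int) -> str:
    parts = [p.strip() for p in lineage.split(";")]
    if rank_index >= len(parts):
        return "unclassified"
    label = parts[rank_index]
    # strip greengenes/SILVA-style prefixes like "p__Firmicutes"
    if "__" in label:
        label = label.split("__", 1)[1]
    return label if label else "unclassified"


def aggregate_taxonomy(table: FeatureTable, rank: str) -> FeatureTable:
    """Sum counts within each taxonomy label at ``rank``.

    Unresolved lineages pool under ``"unclassified"``.  Aggregating at genus
    (the native rank of six-level lineages) is the identity up to grouping of
    equal labels.
    """
    if table.taxonomy is None:
        raise ValueError("feature table has no taxonomy; cannot aggregate")
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    ridx = RANKS.index(rank)
    labels = [_rank_label(lin, ridx) for lin in table.taxonomy]
    order: list[str] = []
    seen: dict[str, int] = {}
    for lab in labels:
        if lab not in seen:
            seen[lab] = len(order)
            order.append(lab)
    agg = np.zeros((table.n_samples, len(order)), dtype=np.int64)
    for j, lab in enumerate(labels):
        agg[:, seen[lab]] += table.counts[:, j]
    return FeatureTable(agg, list(table.sample_ids), order, None)


def alpha_diversity(
    table: FeatureTable, metric: Literal["chao1", "shannon"]
) -> pd.Series:
    """Per-sample Chao1 (bias-corrected) or Shannon (natural log)."""
    counts = table.counts
    if (counts.sum(axis=1) == 0).any():
        bad = [s for s, t in zip(table.sample_ids, counts.sum(axis=1)) if t == 0]
        raise ValueError(f"empty samples: {bad}")
    if metric == "shannon":
        p = counts / counts.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log(p), 0.0)
        vals = -terms.sum(axis=1)
    elif metric == "chao1":
        s_obs = (counts > 0).sum(axis=1).astype(float)
        f1 = (counts == 1).sum(axis=1).astype(float)
        f2 = (counts == 2).sum(axis=1).astype(float)
        vals = s_obs + f1 * (f1 - 1.0) / (2.0 * (f2 + 1.0))
    else:
        raise ValueError(f"unknown metric: {metric!r}")
    return pd.Series(vals, index=table.sample_ids, name=metric)
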
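"""Readers and writers for the tabular formats the pipeline touches.

Every analysis starts from a gene x sample matrix of non-negative integer
read counts plus a sample design table.  Cross-species comparisons add an
ortholog map (two gene-identifier columns, optionally a relation label) and
gene-set collections in GMT format.  All tables are UTF-8, tab-delimited,
one header row, identifiers unquoted; missing numeric values serialize as
``.``.  Gene identifiers are matched case-sensitively after whitespace
stripping -- silent case-folding would create phantom orthologs.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

__all__ = [
    "CountMatrix",
    "SampleDesign",
    "OrthologMap",
    "GeneSetCollection",
    "read_count_matrix",
    "write_count_matrix",
    "read_design",
    "read_ortholog_map",
    "read_gene_sets",
    "read_table",
    "write_table",
    "load_config",
    "get_logger",
]

MISSING = "."

RELATIONS = ("one_to_one", "one_to_many", "many_to_many")


# ---------------------------------------------------------------------------
# logging

_HANDLER: logging.Handler | None = None


def get_logger(stage: str) -> logging.Logger:
    """Timestamped, level-filtered, stage-tagged logger writing to stderr."""
    global _HANDLER
    root = logging.getLogger("microgliaseq")
    if _HANDLER is None:
        _HANDLER = logging.StreamHandler(sys.stderr)
        _HANDLER.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s [%(name)s] %(message)s")
        )
        root.addHandler(_HANDLER)
        root.setLevel(logging.INFO)
    return root.getChild(stage)


# ---------------------------------------------------------------------------
# domain containers


class CountMatrix:
    """Gene x sample matrix of non-negative integer read counts.

    Wraps a :class:`pandas.DataFrame` (genes as rows, samples as columns)
    and enforces the entry-point invariants once, so downstream stages can
    assume clean input: unique identifiers, integral non-negative counts,
    at least one gene and two samples.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        df.index = pd.Index([str(g).strip() for g in df.index], name="gene_id")
        df.columns = pd.Index([str(s).strip() for s in df.columns], name="sample_id")
        dup_g = df.index[df.index.duplicated()].unique()
        if len(dup_g):
            raise ValueError(f"duplicate gene identifier(s): {', '.join(dup_g)}")
        dup_s = df.columns[df.columns.duplicated()].unique()
        if len(dup_s):
            raise ValueError(f"duplicate sample identifier(s): {', '.join(dup_s)}")
        if df.shape[0] < 1 or df.shape[1] < 2:
            raise ValueError(
                f"count matrix needs >=1 gene and >=2 samples, got {df.shape}"
            )
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            numeric = np.vectorize(_is_number)(arr)
            if not numeric.all():
                r, c = np.argwhere(~numeric)[0]
                raise ValueError(
                    f"non-numeric count at gene {df.index[r]!r}, "
                    f"sample {df.columns[c]!r}"
                )
            arr = df.astype(float).to_numpy()
        if np.isnan(arr).any():
            r, c = np.argwhere(np.isnan(arr))[0]
            raise ValueError(
                f"missing count at gene {df.index[r]!r}, sample {df.columns[c]!r}"
            )
        if np.any(arr < 0) or np.any(arr != np.floor(arr)):
            r, c = np.argwhere((arr < 0) | (arr != np.floor(arr)))[0]
            raise ValueError(
                f"negative or non-integer count {arr[r, c]} at "
                f"gene {df.index[r]!r}, sample {df.columns[c]!r} (row {r}, col {c})"
            )
        self.df = df.astype(np.int64)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    def subset_samples(self, sample_ids) -> "CountMatrix":
        missing = [s for s in sample_ids if s not in self.df.columns]
        if missing:
            raise KeyError(f"samples not in count matrix: {', '.join(missing)}")
        return CountMatrix(self.df[list(sample_ids)])

    def subset_genes(self, gene_ids) -> "CountMatrix":
        missing = [g for g in gene_ids if g not in self.df.index]
        if missing:
            raise KeyError(f"genes not in count matrix: {', '.join(missing[:5])}")
        return CountMatrix(self.df.loc[list(gene_ids)])

    def __eq__(self, other) -> bool:
        return isinstance(other, CountMatrix) and self.df.equals(other.df)

    def __repr__(self) -> str:
        return f"CountMatrix({self.shape[0]} genes x {self.shape[1]} samples)"


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


class SampleDesign:
    """Sample annotation: sample_id, group, replicate, species.

    ``group`` is the biological condition (e.g. "3dpf", "5dpf", "7dpf",
    "brain"); ``replicate`` a positive integer; (species, group, replicate)
    triples must be unique.
    """

    REQUIRED = ("sample_id", "group", "replicate", "species")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"design missing column(s): {', '.join(missing)}")
        df = df[list(self.REQUIRED)].copy()
        if len(df) == 0:
            raise ValueError("design table is empty")
        for col in ("sample_id", "group", "species"):
            df[col] = df[col].astype(str).str.strip()
        dup = df["sample_id"][df["sample_id"].duplicated()].unique()
        if len(dup):
            raise ValueError(f"duplicate sample_id(s) in design: {', '.join(dup)}")
        rep = pd.to_numeric(df["replicate"], errors="coerce")
        bad = df.loc[rep.isna() | (rep != np.floor(rep)) | (rep < 1), "sample_id"]
        if len(bad):
            raise ValueError(
                f"non-integer or non-positive replicate for sample(s): "
                f"{', '.join(bad)}"
            )
        df["replicate"] = rep.astype(int)
        key = df[["species", "group", "replicate"]]
        if key.duplicated().any():
            dupkey = key[key.duplicated()].iloc[0]
            raise ValueError(
                "duplicate (species, group, replicate) triple: "
                f"{tuple(dupkey)}"
            )
        self.df = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df["sample_id"])

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.df["group"]))

    @property
    def species(self) -> list[str]:
        return list(dict.fromkeys(self.df["species"]))

    def samples_in_group(self, group: str, species: str | None = None) -> list[str]:
        sel = self.df["group"] == group
        if species is not None:
            sel &= self.df["species"] == species
        return list(self.df.loc[sel, "sample_id"])

    def check_against(self, counts: CountMatrix) -> None:
        """Every sample in the count matrix must be annotated."""
        missing = [s for s in counts.sample_ids if s not in set(self.sample_ids)]
        if missing:
            raise ValueError(
                f"samples present in counts but absent from design: "
                f"{', '.join(missing)}"
            )

    def __repr__(self) -> str:
        return (
            f"SampleDesign({len(self.df)} samples, groups={self.groups}, "
            f"species={self.species})"
        )


class OrthologMap:
    """Cross-species gene pairing with relation labels.

    Records are (gene_a, gene_b, relation) with relation in
    ``one_to_one`` / ``one_to_many`` / ``many_to_many``.  When the input has
    no relation column, relations are inferred from the multiplicity of each
    identifier within the map; when it does, the labels must agree with the
    realized multiplicities.
    """

    def __init__(self, df: pd.DataFrame, infer_relation: bool = False):
        for col in ("gene_a", "gene_b"):
            if col not in df.columns:
                raise ValueError(f"ortholog map missing column {col!r}")
        df = df.copy()
        df["gene_a"] = df["gene_a"].astype(str).str.strip()
        df["gene_b"] = df["gene_b"].astype(str).str.strip()
        if df.duplicated(["gene_a", "gene_b"]).any():
            pair = df[df.duplicated(["gene_a", "gene_b"])].iloc[0]
            raise ValueError(
                f"duplicate ortholog pair ({pair['gene_a']}, {pair['gene_b']})"
            )
        inferred = self._infer(df)
        if infer_relation or "relation" not in df.columns:
            df["relation"] = inferred
        else:
            df["relation"] = df["relation"].astype(str).str.strip()
            bad = df["relation"] != inferred
            if bad.any():
                row = df[bad].iloc[0]
                raise ValueError(
                    f"relation label {row['relation']!r} for pair "
                    f"({row['gene_a']}, {row['gene_b']}) inconsistent with "
                    f"realized multiplicity {inferred[bad.to_numpy()].iloc[0]!r}"
                )
        self.df = df[["gene_a", "gene_b", "relation"]].reset_index(drop=True)

    @staticmethod
    def _infer(df: pd.DataFrame) -> pd.Series:
        na = df["gene_a"].map(df["gene_a"].value_counts())
        nb = df["gene_b"].map(df["gene_b"].value_counts())
        rel = np.where(
            (na == 1) & (nb == 1),
            "one_to_one",
            np.where((na > 1) & (nb > 1), "many_to_many", "one_to_many"),
        )
        return pd.Series(rel, index=df.index)

    def __len__(self) -> int:
        return len(self.df)

    def restrict(self, genes_a, genes_b) -> "OrthologMap":
        """Keep pairs whose genes exist in both given universes; relations
        are re-inferred on the restricted map."""
        sa, sb = set(genes_a), set(genes_b)
        sub = self.df[self.df["gene_a"].isin(sa) & self.df["gene_b"].isin(sb)]
        if len(sub) == 0:
            raise ValueError("no ortholog pair present in both datasets")
        return OrthologMap(sub.drop(columns="relation"), infer_relation=True)

    def __repr__(self) -> str:
        counts = self.df["relation"].value_counts().to_dict()
        return f"OrthologMap({len(self)} pairs, {counts})"


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style): term_id -> (term_name, members)."""

    terms: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)

    def __post_init__(self):
        for tid, (_, members) in self.terms.items():
            if len(members) == 0:
                raise ValueError(f"gene set {tid!r} has no members")

    def add(self, term_id: str, term_name: str, members) -> None:
        if term_id in self.terms:
            raise ValueError(f"duplicate term_id {term_id!r}")
        members = tuple(dict.fromkeys(str(m).strip() for m in members))
        if not members:
            raise ValueError(f"gene set {term_id!r} has no members")
        self.terms[term_id] = (term_name, members)

    def members(self, term_id: str) -> tuple[str, ...]:
        return self.terms[term_id][1]

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms.items())


# ---------------------------------------------------------------------------
# readers / writers


def read_count_matrix(path, format: str = "tsv") -> CountMatrix:
    """Read a count matrix from TSV or MatrixMarket.

    TSV dialect: first column gene id, header row of sample ids.
    MatrixMarket dialect: coordinate integer ``.mtx`` plus sidecar files
    with the same stem and suffixes ``.rownames`` / ``.colnames`` (one
    identifier per line, row/column order of the matrix).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return CountMatrix(df)
    if format == "mtx":
        rownames = path.with_suffix(".rownames")
        colnames = path.with_suffix(".colnames")
        for sidecar in (rownames, colnames):
            if not sidecar.exists():
                raise FileNotFoundError(
                    f"missing MatrixMarket sidecar {sidecar} for {path}"
                )
        mat = scipy.io.mmread(str(path))
        if scipy.sparse.issparse(mat):
            coo = mat.tocoo()
            neg = np.flatnonzero((coo.data < 0) | (coo.data != np.floor(coo.data)))
            if len(neg):
                i = neg[0]
                raise ValueError(
                    f"negative or non-integer MatrixMarket entry {coo.data[i]} "
                    f"at (row {coo.row[i] + 1}, col {coo.col[i] + 1})"
                )
            dense = np.asarray(coo.todense())
        else:
            dense = np.asarray(mat)
        genes = rownames.read_text().splitlines()
        samples = colnames.read_text().splitlines()
        if dense.shape != (len(genes), len(samples)):
            raise ValueError(
                f"matrix shape {dense.shape} inconsistent with sidecars "
                f"({len(genes)} rows, {len(samples)} cols)"
            )
        return CountMatrix(pd.DataFrame(dense, index=genes, columns=samples))
    raise ValueError(f"unknown count matrix format {format!r}")


def write_count_matrix(counts: CountMatrix, path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        counts.df.to_csv(path, sep="\t", index_label="gene_id")
    elif format == "mtx":
        sparse = scipy.sparse.coo_matrix(counts.values())
        scipy.io.mmwrite(str(path), sparse, field="integer")
        path.with_suffix(".rownames").write_text("\n".join(counts.gene_ids) + "\n")
        path.with_suffix(".colnames").write_text("\n".join(counts.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown count matrix format {format!r}")


def read_design(path) -> SampleDesign:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"design file {path} is empty")
    df = pd.read_csv(path, sep="\t")
    if len(df) == 0:
        raise ValueError(f"design file {path} has no data rows")
    return SampleDesign(df)


def read_ortholog_map(path) -> OrthologMap:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    return OrthologMap(df)


def read_gene_sets(path) -> GeneSetCollection:
    """Parse a GMT file: term_id <TAB> description <TAB> member [<TAB> member ...]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    coll = GeneSetCollection()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s), "
                    "need term_id, description and >=1 member"
                )
            coll.add(fields[0].strip(), fields[1].strip(), fields[2:])
    return coll


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    """Write a result table as TSV: one header row, ``.`` for missing values,
    no quoting of identifiers, deterministic column order (as given)."""
    df.to_csv(path, sep="\t", na_rep=MISSING, index=index)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, na_values=[MISSING])


def load_config(path) -> dict:
    """Load a YAML configuration file into a plain dict."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"configuration file {path} must contain a mapping")
    return cfg
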
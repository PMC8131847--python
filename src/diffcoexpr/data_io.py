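"""Readers and writers for every external representation the pipeline touches.

Expression matrices are tab-separated text with genes in rows and a header row
of sample identifiers.  Phenotypes are tab-separated tables with named columns
(``sample_id``, ``condition``, optionally ``survival_time`` and ``event``).
Gene sets use the standard GMT dialect (name, description, members, one set
per line).  Networks are exported as SIF, GraphML or plain TSV edge lists.

Missing expression values are rejected at load time rather than imputed: the
downstream correlation machinery assumes complete matrices, and silent
imputation would corrupt the tests built on them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONDITION_REFERENCE = "normal"
CONDITION_CONTRAST = "tumor"
_ALLOWED_CONDITIONS = (CONDITION_REFERENCE, CONDITION_CONTRAST)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes-by-samples abundance matrix with unique identifiers.

    Parameters
    ----------
    gene_ids
        Row identifiers, one per gene, no duplicates.
    sample_ids
        Column identifiers, one per sample, no duplicates.
    values
        Real-valued ``(n_genes, n_samples)`` array with no missing entries.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for label, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise ValueError(f"duplicate {label} identifier: {dup!r}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Return the sub-matrix restricted to ``genes`` (kept in given order)."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[rows])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        index = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in index]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        cols = [index[s] for s in samples]
        return ExpressionMatrix(list(self.gene_ids), list(samples), self.values[:, cols])


@dataclass
class PhenotypeTable:
    """Per-sample condition label plus optional survival (time, event) record.

    ``condition`` has exactly the two levels ``normal`` (reference) and
    ``tumor`` (contrast).  If ``survival_time`` is recorded for a sample its
    ``event`` indicator (0 censored, 1 death) must be recorded too.
    """

    frame: pd.DataFrame  # index: sample_id; columns: condition[, survival_time, event]

    def __post_init__(self) -> None:
        df = self.frame
        if "condition" not in df.columns:
            raise ValueError("phenotype table must have a 'condition' column")
        dup = _first_duplicate(list(df.index))
        if dup is not None:
            raise ValueError(f"duplicate sample identifier: {dup!r}")
        levels = sorted(set(df["condition"].astype(str)))
        bad = [lv for lv in levels if lv not in _ALLOWED_CONDITIONS]
        if bad:
            raise ValueError(
                f"condition must have the two levels {_ALLOWED_CONDITIONS}; "
                f"found levels {levels}"
            )
        has_time = "survival_time" in df.columns
        has_event = "event" in df.columns
        if has_time != has_event:
            raise ValueError(
                "survival_time and event columns must be present together"
            )
        if has_time:
            t = pd.to_numeric(df["survival_time"], errors="coerce")
            e = pd.to_numeric(df["event"], errors="coerce")
            both = t.notna() & e.notna()
            if ((t.notna()) != both).any():
                s = df.index[t.notna() & ~e.notna()][0]
                raise ValueError(f"sample {s!r} has survival_time but no event")
            if (t[both] < 0).any():
                raise ValueError("survival_time must be non-negative")
            if not set(e[both].unique()) <= {0.0, 1.0}:
                raise ValueError("event must be binary 0/1")
            self.frame = df.assign(survival_time=t, event=e)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.frame.index]

    def condition_of(self, sample_ids: Sequence[str]) -> np.ndarray:
        return self.frame.loc[list(sample_ids), "condition"].to_numpy(dtype=object)

    def samples_in_condition(self, condition: str) -> list[str]:
        if condition not in _ALLOWED_CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        mask = self.frame["condition"] == condition
        return [str(s) for s in self.frame.index[mask]]

    def trait_vector(self, sample_ids: Sequence[str]) -> np.ndarray:
        """0/1 coding of the condition (normal=0, tumor=1) for given samples."""
        cond = self.condition_of(sample_ids)
        return (cond == CONDITION_CONTRAST).astype(float)

    @property
    def has_survival(self) -> bool:
        return "survival_time" in self.frame.columns

    def survival_records(self) -> pd.DataFrame:
        """Rows with complete (time, event) records, indexed by sample."""
        if not self.has_survival:
            return pd.DataFrame(columns=["survival_time", "event"])
        df = self.frame[["survival_time", "event"]]
        return df[df["survival_time"].notna()]

    def validate_against(self, X: ExpressionMatrix) -> None:
        missing = set(X.sample_ids) - set(self.sample_ids)
        if missing:
            raise ValueError(f"samples without phenotype: {sorted(missing)[:5]}")


@dataclass
class GeneSetCollection:
    """Named gene sets with optional free-text descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: dict[str, list[str]] = {}
        for name, members in self.sets.items():
            uniq = list(dict.fromkeys(members))  # collapse duplicates, keep order
            if not uniq:
                raise ValueError(f"gene set {name!r} is empty")
            cleaned[name] = uniq
        self.sets = cleaned

    def __len__(self) -> int:
        return len(self.sets)


_EDGE_COLUMNS = ["gene_a", "gene_b", "weight", "sign", "annotation"]


@dataclass
class NetworkEdgeTable:
    """Undirected weighted edges; each edge stored once with gene_a < gene_b."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in _EDGE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"edge table missing columns {missing}")
        df = df[_EDGE_COLUMNS].reset_index(drop=True)
        if len(df) and (df["gene_a"] >= df["gene_b"]).any():
            bad = df[df["gene_a"] >= df["gene_b"]].iloc[0]
            raise ValueError(
                f"edges must satisfy gene_a < gene_b; got ({bad.gene_a!r}, {bad.gene_b!r})"
            )
        if len(df) and not np.all(np.isfinite(df["weight"].to_numpy(dtype=float))):
            raise ValueError("edge weights must be finite")
        if len(df) and not set(df["sign"]) <= {"+", "-"}:
            raise ValueError("edge sign must be '+' or '-'")
        self.frame = df

    def __len__(self) -> int:
        return len(self.frame)


def make_edge_table(
    edges: Iterable[tuple[str, str, float, str, str]]
) -> NetworkEdgeTable:
    """Build a :class:`NetworkEdgeTable`, canonicalising endpoint order."""
    rows = []
    for a, b, w, s, ann in edges:
        if a == b:
            raise ValueError(f"self-edge on {a!r}")
        if a > b:
            a, b = b, a
        rows.append((a, b, float(w), s, ann))
    rows.sort(key=lambda r: (r[0], r[1]))
    return NetworkEdgeTable(pd.DataFrame(rows, columns=_EDGE_COLUMNS))


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _first_duplicate(items: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


def read_expression(
    path: str | Path, delimiter: str = "\t", log2_transform: bool = False
) -> ExpressionMatrix:
    """Read a genes-in-rows expression table.

    The first row is the sample header, the first column holds gene
    identifiers.  Zero-variance genes are retained here; filtering them is an
    explicit separate step (:func:`diffcoexpr.network.filter_invariant_genes`).

    Parameters
    ----------
    path
        File to read.
    delimiter
        Column separator, tab by default.
    log2_transform
        Apply ``log2(x + 1)`` after loading.  Off by default; when enabled the
        transform is logged so runs stay auditable.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(delimiter)
    sample_ids = [str(s) for s in header[1:]]  # pandas would mangle duplicates
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str, skiprows=1, header=None)
    gene_ids = [str(g) for g in df.index]
    for label, ids in (("gene", gene_ids), ("sample", sample_ids)):
        dup = _first_duplicate(ids)
        if dup is not None:
            raise ValueError(f"{path.name}: duplicate {label} identifier {dup!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path.name}: non-numeric cell {df.iat[i, j]!r} at "
            f"gene {gene_ids[i]!r} (row {i + 2}), sample {sample_ids[j]!r} (column {j + 2})"
        )
    values = numeric.to_numpy(dtype=float)
    if log2_transform:
        if (values < 0).any():
            raise ValueError("log2 transform requires non-negative values")
        values = np.log2(values + 1.0)
        logger.info("applied log2(x+1) transform to %s", path.name)
    return ExpressionMatrix(gene_ids, sample_ids, values)


def write_expression(X: ExpressionMatrix, path: str | Path, delimiter: str = "\t") -> None:
    X.to_frame().to_csv(path, sep=delimiter, index_label="gene_id")


def read_phenotype(path: str | Path) -> PhenotypeTable:
    """Read a phenotype table with columns sample_id, condition[, survival_time, event].

    Extra columns are ignored with a logged warning; a third condition level is
    a hard error listing all levels found.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    required = {"sample_id", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path.name}: missing required columns {sorted(missing)}")
    keep = ["sample_id", "condition"]
    if "survival_time" in df.columns or "event" in df.columns:
        keep += [c for c in ("survival_time", "event") if c in df.columns]
    extra = [c for c in df.columns if c not in keep]
    if extra:
        logger.warning("%s: ignoring extra phenotype columns %s", path.name, extra)
    out = df[keep].set_index("sample_id")
    out["condition"] = out["condition"].astype(str).str.strip().str.lower()
    return PhenotypeTable(out)


def write_phenotype(pheno: PhenotypeTable, path: str | Path) -> None:
    pheno.frame.to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets in GMT format: name TAB description TAB member...

    Duplicate members within a set are collapsed; sets whose member list is
    empty after collapsing are dropped with a warning.  A line with fewer than
    three tab-separated fields is an error reported with its line number.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path.name}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            name, desc, *members = fields
            members = [m for m in members if m.strip()]
            if not members:
                logger.warning("%s:%d: dropping empty gene set %r", path.name, lineno, name)
                continue
            if name in sets:
                raise ValueError(f"{path.name}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = list(dict.fromkeys(members))
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------

def write_network(
    edges: NetworkEdgeTable, path: str | Path, dialect: str = "TSV"
) -> None:
    """Write an edge table in one of three dialects.

    SIF writes ``gene_a<TAB>cc<TAB>gene_b`` lines loadable by standard graph
    viewers; GraphML carries weight/sign/annotation as edge attributes; TSV
    writes all fields verbatim (and round-trips through
    :func:`read_network_tsv`).
    """
    dialect = dialect.upper()
    path = Path(path)
    if dialect == "SIF":
        with open(path, "w") as fh:
            for row in edges.frame.itertuples(index=False):
                fh.write(f"{row.gene_a}\tcc\t{row.gene_b}\n")
    elif dialect == "TSV":
        edges.frame.to_csv(path, sep="\t", index=False)
    elif dialect == "GRAPHML":
        import networkx as nx

        g = nx.Graph()
        for row in edges.frame.itertuples(index=False):
            g.add_edge(
                row.gene_a,
                row.gene_b,
                weight=float(row.weight),
                sign=str(row.sign),
                annotation=str(row.annotation),
            )
        nx.write_graphml(g, path)
        with open(path, "a") as fh:  # writers end files with a newline
            fh.write("\n")
    else:
        raise ValueError(f"unknown network dialect {dialect!r} (use SIF, GraphML or TSV)")


def read_network_tsv(path: str | Path) -> NetworkEdgeTable:
    df = pd.read_csv(
        path, sep="\t", dtype={"gene_a": str, "gene_b": str, "sign": str, "annotation": str}
    )
    if df.empty and list(df.columns) == _EDGE_COLUMNS:
        df = df.astype({"weight": float})
    df["annotation"] = df.get("annotation", pd.Series(dtype=str)).fillna("")
    return NetworkEdgeTable(df)
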
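"""Read/write adapters for the pipeline's plain-text formats.

All tabular formats are headered, tab-separated, UTF-8.  Gene sets use the
standard GMT layout (set name, description, then members).  Every writer
round-trips through its reader (write o read = identity).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .deg import CountMatrix

__all__ = [
    "read_counts_tsv", "write_counts_tsv",
    "read_deg_table", "write_deg_table",
    "read_gmt", "write_gmt",
    "read_edge_list", "write_edge_list",
    "read_annotations", "write_annotations",
    "read_expression_tsv", "write_expression_tsv",
    "read_pairs_tsv", "write_pairs_tsv",
    "read_truth_json", "write_truth_json",
]


def _check_unique_index(df: pd.DataFrame, path: Path | str) -> None:
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene ids: {dups[:10]}")


def read_counts_tsv(path: Path | str, groups: Mapping[str, str] | None = None) -> CountMatrix | pd.DataFrame:
    """Read a genes x samples count TSV (first column gene id, header row).

    With ``groups`` (sample id -> case/control) a CountMatrix is returned;
    without, the bare DataFrame.  Samples named ``*_case_*`` / ``*_control_*``
    are labelled automatically when ``groups`` is omitted and every column
    matches.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_unique_index(df, path)
    if groups is None:
        inferred = {}
        for c in df.columns:
            if "_case_" in c or c.endswith("_case") or c.startswith("case"):
                inferred[c] = "case"
            elif "_control_" in c or c.endswith("_control") or c.startswith("control"):
                inferred[c] = "control"
        if len(inferred) != len(df.columns):
            return df
        groups = inferred
    return CountMatrix(df, pd.Series(groups).reindex(df.columns))


def write_counts_tsv(m: CountMatrix | pd.DataFrame, path: Path | str) -> None:
    df = m.counts if isinstance(m, CountMatrix) else m
    df.to_csv(path, sep="\t", index_label="gene")


def read_deg_table(path: Path | str) -> pd.DataFrame:
    """Read a DEG table (gene, log2_fold_change, p_raw, p_adj)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_unique_index(df, path)
    missing = {"log2_fold_change", "p_raw", "p_adj"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in ("p_raw", "p_adj"):
        vals = df[col].dropna()
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"{path}: {col} outside [0, 1]")
    return df


def write_deg_table(t: pd.DataFrame, path: Path | str) -> None:
    t.to_csv(path, sep="\t", index_label="gene")


def read_gmt(path: Path | str) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{i}: GMT lines need name, description, >=1 member")
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{i}: duplicate gene-set name {name!r}")
            sets[name] = parts[2:]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: Path | str,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *map(str, members)]) + "\n")


def read_edge_list(path: Path | str) -> nx.Graph:
    """Two-column TSV of unordered pairs; reversed duplicates collapse."""
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    for a, b in zip(df.iloc[:, 0], df.iloc[:, 1], strict=True):
        if a == b:
            continue
        g.add_edge(str(a), str(b))
    return g


def write_edge_list(g: nx.Graph, path: Path | str) -> None:
    rows = sorted(tuple(sorted((str(a), str(b)))) for a, b in g.edges)
    pd.DataFrame(rows, columns=["gene_a", "gene_b"]).to_csv(path, sep="\t", index=False)


def read_annotations(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene", "term", "evidence", "aspect"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_annotations(t: pd.DataFrame, path: Path | str) -> None:
    t.to_csv(path, sep="\t", index=False)


def read_expression_tsv(path: Path | str) -> pd.DataFrame:
    """Gene x condition numeric table (stage RPKM or tissue TPM)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_unique_index(df, path)
    return df


def write_expression_tsv(t: pd.DataFrame, path: Path | str) -> None:
    t.to_csv(path, sep="\t", index_label="gene")


def read_pairs_tsv(path: Path | str) -> pd.DataFrame:
    """Two-column orthology pairs (source, target)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: an orthology table needs two columns")
    return df


def write_pairs_tsv(t: pd.DataFrame, path: Path | str) -> None:
    t.to_csv(path, sep="\t", index=False)


def write_truth_json(truth, path: Path | str) -> None:
    """Serialise a SyntheticTruth to JSON (sets become sorted lists)."""
    payload = {
        "true_deg_sets": {k: sorted(map(str, v)) for k, v in truth.true_deg_sets.items()},
        "true_shared_set": sorted(map(str, truth.true_shared_set)),
        "planted_activated_modules": sorted(truth.planted_activated_modules),
        "planted_inactivated_modules": sorted(truth.planted_inactivated_modules),
        "module_genes": {k: sorted(map(str, v)) for k, v in truth.module_genes.items()},
        "true_prenatal_max_genes": sorted(map(str, truth.true_prenatal_max_genes)),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def read_truth_json(path: Path | str) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
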
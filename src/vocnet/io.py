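"""Reading and writing emission matrices, annotation tables, graphs and partitions.

An emission matrix is a species × VOC table of non-negative intensities in
normalized counts per second (ncps).  Rows are samples (possibly replicate
measurements of the same species) or species; columns are protonated-mass
channels labelled like ``PM149``.  Species → family and VOC → chemical-class
annotations live in separate two-column tables so the matrix stays
rectangular.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "EmissionMatrix",
    "read_emission_matrix",
    "write_emission_matrix",
    "read_annotation_table",
    "write_annotation_table",
    "average_replicates",
    "write_graph",
    "read_graph",
    "write_edge_list",
    "read_edge_list",
    "write_partition",
    "read_partition",
]


class EmissionMatrixError(ValueError):
    """Malformed emission-matrix input (labels, shape or cell values)."""


@dataclass
class EmissionMatrix:
    """Species × VOC emission intensities with optional annotations.

    Parameters
    ----------
    data:
        DataFrame indexed by species (or sample) label with one column per
        VOC label.  All values must be finite and ≥ 0.
    family_of:
        Optional mapping species → botanical family.
    chem_class_of:
        Optional mapping VOC label → chemical-class code (e.g. ``Tp-f``,
        ``SC``, ``K/Ald``).
    """

    data: pd.DataFrame
    family_of: dict[str, str] = field(default_factory=dict)
    chem_class_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise EmissionMatrixError(f"duplicate species labels: {dup}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].unique().tolist()
            raise EmissionMatrixError(f"duplicate VOC labels: {dup}")
        values = self.data.to_numpy(dtype=float)
        if values.size and not np.isfinite(values).all():
            raise EmissionMatrixError("emission values must be finite")
        if values.size and (values < 0).any():
            raise EmissionMatrixError("emission values must be >= 0 ncps")

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def voc_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_species(self) -> int:
        return self.data.shape[0]

    @property
    def n_vocs(self) -> int:
        return self.data.shape[1]


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def read_emission_matrix(path: str | Path, delimiter: str | None = None) -> EmissionMatrix:
    """Read an emission matrix from delimited text.

    The first row holds VOC labels and the first column sample/species
    labels.  An optional second column headed ``family`` (case-insensitive)
    carries the family annotation.  The delimiter is auto-detected from the
    first line (tab if present, comma otherwise) unless given explicitly.
    Decimal points only; empty or non-numeric cells are rejected with the
    offending coordinate.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if delimiter is None:
        delimiter = _sniff_delimiter(first)
    header = [h.strip() for h in first.rstrip("\n").split(delimiter)][1:]
    voc_labels = header[1:] if header and header[0].lower() == "family" else header
    dup = sorted({v for v in voc_labels if voc_labels.count(v) > 1})
    if dup:
        raise EmissionMatrixError(f"{path}: duplicate VOC label(s): {dup}")
    raw = pd.read_csv(path, sep=delimiter, dtype=str, index_col=0, keep_default_na=False)
    family_of: dict[str, str] = {}
    if raw.shape[1] and raw.columns[0].strip().lower() == "family":
        family_of = dict(zip(raw.index, raw.iloc[:, 0]))
        raw = raw.iloc[:, 1:]
    def _cell(x: str) -> float:
        try:
            return float(x)  # correctly rounded, unlike the fast csv parser
        except ValueError:
            return float("nan")

    numeric = raw.apply(lambda col: col.map(_cell))
    bad = numeric.isna().to_numpy().nonzero()
    if bad[0].size:
        i, j = int(bad[0][0]), int(bad[1][0])
        raise EmissionMatrixError(
            f"{path}: non-numeric cell {raw.iat[i, j]!r} at row "
            f"{raw.index[i]!r}, column {raw.columns[j]!r}"
        )
    return EmissionMatrix(numeric, family_of=family_of)


def write_emission_matrix(
    em: EmissionMatrix, path: str | Path, delimiter: str = ",", include_family: bool = False
) -> None:
    """Write an emission matrix as delimited text (inverse of the reader)."""
    df = em.data
    if include_family and em.family_of:
        df = df.copy()
        df.insert(0, "family", [em.family_of.get(s, "") for s in df.index])
    # shortest round-trip decimal text so read(write(M)) == M bitwise
    df.to_csv(path, sep=delimiter, index_label="species",
              float_format=lambda v: np.format_float_positional(
                  np.float64(v), unique=True, trim="0"))


def read_annotation_table(path: str | Path, delimiter: str | None = None) -> dict[str, str]:
    """Read a two-column label → annotation table (header row required)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if delimiter is None:
        delimiter = _sniff_delimiter(first)
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise EmissionMatrixError(f"{path}: annotation table needs two columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_annotation_table(
    mapping: dict[str, str], path: str | Path, columns: tuple[str, str] = ("label", "annotation"),
    delimiter: str = "\t",
) -> None:
    pd.DataFrame(sorted(mapping.items()), columns=list(columns)).to_csv(
        path, sep=delimiter, index=False
    )


def average_replicates(raw: EmissionMatrix, reps: dict[str, str]) -> EmissionMatrix:
    """Collapse replicate rows to one mean row per species.

    ``reps`` maps each sample row label to its species.  The output keeps
    one row per species, ordered by first appearance of the species among
    the raw rows, each cell the arithmetic mean over that species'
    replicates.
    """
    missing = [s for s in raw.species_ids if s not in reps]
    if missing:
        raise EmissionMatrixError(f"sample rows without replicate mapping: {missing}")
    species_order: list[str] = []
    seen: set[str] = set()
    for sample in raw.species_ids:
        sp = reps[sample]
        if sp not in seen:
            seen.add(sp)
            species_order.append(sp)
    orphans = set(reps.values()) - seen
    if orphans:
        raise EmissionMatrixError(f"species with zero replicate rows: {sorted(orphans)}")
    grouped = raw.data.groupby([reps[s] for s in raw.species_ids], sort=False).mean()
    grouped = grouped.loc[species_order]
    fam = {sp: raw.family_of[s] for s, sp in reps.items() if s in raw.family_of}
    return EmissionMatrix(grouped, family_of=fam, chem_class_of=dict(raw.chem_class_of))


# -- graphs -----------------------------------------------------------------

def write_graph(g: nx.Graph, path: str | Path) -> None:
    """Write a graph as GraphML (edge ``weight`` / node ``layer`` preserved)."""
    nx.write_graphml(g, str(path))


def read_graph(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))


def write_edge_list(g: nx.Graph, path: str | Path) -> None:
    """Write a ``u v w`` whitespace-delimited weighted edge list."""
    with open(path, "w") as fh:
        for u, v, w in g.edges(data="weight", default=1):
            fh.write(f"{u} {v} {w}\n")


def read_edge_list(path: str | Path) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            u, v, w = line.split()
            g.add_edge(u, v, weight=float(w))
    return g


# -- partitions -------------------------------------------------------------

def write_partition(partition, path: str | Path) -> None:
    """Serialize a partition as JSON: membership plus provenance metadata."""
    payload = {
        "membership": {str(k): int(v) for k, v in partition.membership.items()},
        "metadata": {
            "algorithm": partition.algorithm,
            "seed": partition.seed,
            "parameters": partition.parameters,
            "modularity": partition.quality,
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_partition(path: str | Path):
    from .community import Partition

    with open(path) as fh:
        payload = json.load(fh)
    meta = payload.get("metadata", {})
    return Partition(
        membership=dict(payload["membership"]),
        algorithm=meta.get("algorithm", "unknown"),
        seed=meta.get("seed"),
        parameters=meta.get("parameters", {}),
        quality=meta.get("modularity"),
    )
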
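"""Readers and writers for fitness tables, interaction networks and results.

Fitness tables are TSV with a header row, first column the gene label and
``NA`` the missing-value token.  The double-mutant matrix is stored dense
with row and column labels; either triangle (or both) may be populated.
Interaction networks are plain two-column edge lists or BioGRID
tab-delimited exports (only rows whose experimental system type is
``physical`` are kept).  Result writers emit TSV sample/confidence tables,
GraphML and SIF network files, and a YAML run manifest whose replay
reproduces every output bit-identically.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .errors import InvalidInputError, PathAISError
from .model import (
    FitnessData,
    GeneSet,
    PathwayNetwork,
    PPIGraph,
    SampleEnsemble,
)
from .scoring import neutral_expectation

__all__ = [
    "read_fitness",
    "read_ppi",
    "write_fitness",
    "write_ppi",
    "write_results",
    "read_samples",
]

logger = logging.getLogger("pathais")

NA_TOKEN = "NA"


def _read_matrix(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN])
    except Exception as err:  # pandas raises many flavors on malformed input
        raise PathAISError(f"cannot parse matrix file {path}: {err}") from err
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_fitness(
    single_path: str | Path,
    double_path: str | Path,
    expected_path: str | Path | None = None,
    sigma2: float | str | Path = 0.0025,
    e_mode: str = "multiplicative",
) -> FitnessData:
    """Load single- and double-mutant fitness tables into a FitnessData.

    The gene universe is taken from the single-mutant table.  The D matrix
    is symmetrized: an entry present in only one triangle is mirrored;
    conflicting values are averaged with a warning.  When no expected-value
    table is given, E is computed from the neutral model.
    """
    try:
        singles = pd.read_csv(single_path, sep="\t", index_col=0, na_values=[NA_TOKEN])
    except Exception as err:
        raise PathAISError(f"cannot parse single-mutant table {single_path}: {err}") from err
    singles.index = singles.index.astype(str)
    genes = GeneSet(singles.index)
    S = singles.iloc[:, 0].to_numpy(dtype=float)

    ddf = _read_matrix(double_path)
    unknown = set(ddf.index) | set(ddf.columns)
    unknown -= set(genes)
    if unknown:
        raise InvalidInputError(
            f"double-mutant table labels not in single-mutant table: {sorted(unknown)}"
        )
    D = ddf.reindex(index=list(genes), columns=list(genes)).to_numpy(dtype=float)
    D = _symmetrize(D, genes)

    n = len(genes)
    if expected_path is not None:
        edf = _read_matrix(expected_path)
        E = edf.reindex(index=list(genes), columns=list(genes)).to_numpy(dtype=float)
        E = _symmetrize(E, genes)
    else:
        E = np.full((n, n), np.nan)
        for i in range(n):
            for j in range(i + 1, n):
                E[i, j] = E[j, i] = neutral_expectation(S[i], S[j], e_mode)

    if isinstance(sigma2, (str, Path)):
        sig = _read_matrix(sigma2).reindex(
            index=list(genes), columns=list(genes)
        ).to_numpy(dtype=float)
    else:
        sig = float(sigma2)
    return FitnessData(genes, S, D, E, sig)


def _symmetrize(M: np.ndarray, genes: GeneSet) -> np.ndarray:
    out = M.copy()
    n = out.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            a, b = out[i, j], out[j, i]
            if np.isfinite(a) and np.isfinite(b):
                if not np.isclose(a, b, rtol=0, atol=1e-12):
                    warnings.warn(
                        f"conflicting values for pair ({genes[i]}, {genes[j]}): "
                        f"{a} vs {b}; averaging",
                        stacklevel=3,
                    )
                    out[i, j] = out[j, i] = 0.5 * (a + b)
            elif np.isfinite(a):
                out[j, i] = a
            elif np.isfinite(b):
                out[i, j] = b
    return out


def read_ppi(path: str | Path, genes: GeneSet) -> PPIGraph:
    """Load an undirected scaffold from an edge list or BioGRID export.

    Rows with endpoints outside the gene set are dropped (counted in the
    log); self-loops are dropped with a warning; duplicates and reversed
    duplicates collapse to one undirected edge.  For the BioGRID dialect
    only physical-interaction rows are kept.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if "Experimental System Type" in first:
        df = pd.read_csv(path, sep="\t")
        df = df[df["Experimental System Type"].str.lower() == "physical"]
        pairs = list(
            zip(
                df["Official Symbol Interactor A"].astype(str),
                df["Official Symbol Interactor B"].astype(str),
            )
        )
    else:
        pairs = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split()
                if len(fields) < 2:
                    raise PathAISError(f"{path}:{ln}: expected two columns")
                pairs.append((fields[0], fields[1]))

    kept, self_loops, unknown = [], 0, 0
    for a, b in pairs:
        if a == b:
            self_loops += 1
            continue
        if a not in genes or b not in genes:
            unknown += 1
            continue
        kept.append((a, b))
    if self_loops:
        warnings.warn(f"dropped {self_loops} self-loop rows from {path}", stacklevel=2)
    if unknown:
        logger.info("dropped %d edges with endpoints outside the gene set", unknown)
    ppi = PPIGraph(genes, kept)
    if not ppi.edges:
        warnings.warn(f"no scaffold edges survived from {path}", stacklevel=2)
    return ppi


def write_fitness(fd: FitnessData, single_path: str | Path, double_path: str | Path,
                  expected_path: str | Path | None = None) -> None:
    """Write FitnessData back to the TSV dialect read_fitness consumes."""
    genes = list(fd.genes)
    pd.DataFrame({"fitness": fd.S}, index=genes).rename_axis("gene").to_csv(
        single_path, sep="\t", na_rep=NA_TOKEN
    )
    pd.DataFrame(fd.D, index=genes, columns=genes).rename_axis("gene").to_csv(
        double_path, sep="\t", na_rep=NA_TOKEN
    )
    if expected_path is not None:
        pd.DataFrame(fd.E, index=genes, columns=genes).rename_axis("gene").to_csv(
            expected_path, sep="\t", na_rep=NA_TOKEN
        )


def write_ppi(ppi: PPIGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in ppi.sorted_edges():
            fh.write(f"{a}\t{b}\n")


def write_results(
    e: SampleEnsemble,
    conf: dict[tuple[str, str], float],
    out_dir: str | Path,
    manifest_extra: dict | None = None,
) -> dict[str, Path]:
    """Write the full result file set for one run; returns the paths.

    Files: ``samples.tsv`` (one row per weighted network), ``edge_confidence.tsv``
    (source, target, confidence for both orientations of every scaffold
    edge), ``best_network.graphml`` / ``best_network.sif`` (per-pair
    maximal-confidence orientations, confidence as edge attribute), and
    ``manifest.yaml`` (seed, schedule and parameters for exact replay).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rows = []
    for k, smp in enumerate(e.samples):
        edges = ";".join(f"{u}->{v}" for u, v in smp.network.sorted_edges())
        rows.append({"sample": k, "log_weight": repr(float(smp.log_weight)), "edges": edges})
    paths["samples"] = out_dir / "samples.tsv"
    pd.DataFrame(rows, columns=["sample", "log_weight", "edges"]).to_csv(
        paths["samples"], sep="\t", index=False
    )

    paths["edge_confidence"] = out_dir / "edge_confidence.tsv"
    with open(paths["edge_confidence"], "w") as fh:
        fh.write("source\ttarget\tconfidence\n")
        for (u, v) in sorted(conf, key=lambda p: (e.scaffold.genes.index(p[0]),
                                                  e.scaffold.genes.index(p[1]))):
            fh.write(f"{u}\t{v}\t{conf[(u, v)]:.6f}\n")

    best = _max_confidence_network(e.scaffold, conf)
    g = nx.DiGraph()
    g.add_nodes_from(e.scaffold.genes)
    for u, v in best:
        g.add_edge(u, v, confidence=round(conf[(u, v)], 6))
    paths["graphml"] = out_dir / "best_network.graphml"
    nx.write_graphml(g, paths["graphml"])
    paths["sif"] = out_dir / "best_network.sif"
    with open(paths["sif"], "w") as fh:
        for u, v in best:
            fh.write(f"{u}\tdirected\t{v}\n")

    manifest = {
        "seed": e.seed,
        "K": len(e),
        "betas": [float(b) for b in e.schedule.betas],
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    paths["manifest"] = out_dir / "manifest.yaml"
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return paths


def _max_confidence_network(
    scaffold: PPIGraph, conf: dict[tuple[str, str], float]
) -> list[tuple[str, str]]:
    """Per scaffold pair, the orientation beating both the reverse and absence."""
    edges = []
    for a, b in scaffold.sorted_edges():
        fwd, rev = conf.get((a, b), 0.0), conf.get((b, a), 0.0)
        absent = 1.0 - fwd - rev
        if fwd >= rev and fwd > absent:
            edges.append((a, b))
        elif rev > fwd and rev > absent:
            edges.append((b, a))
    return edges


def read_samples(path: str | Path, genes: GeneSet) -> list[tuple[PathwayNetwork, float]]:
    """Parse a samples.tsv back into (network, log_weight) pairs."""
    df = pd.read_csv(
        path, sep="\t", keep_default_na=False,
        dtype={"log_weight": str, "edges": str},
    )
    out = []
    for _, row in df.iterrows():
        edges = []
        if row["edges"]:
            for token in str(row["edges"]).split(";"):
                u, v = token.split("->")
                edges.append((u, v))
        out.append((PathwayNetwork(genes, edges), float(row["log_weight"])))
    return out
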
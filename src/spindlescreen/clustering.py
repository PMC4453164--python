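"""Phenotypic clustering of differential-Z profiles.

Genes whose sensitized-background phenotype is strong enough (|Z_chTOG| > 1
for % multipolar or mean poles/cell) are clustered on their five-feature dZ
profiles by complete-linkage agglomeration.  The default metric is uncentred
Pearson distance (1 − Σxy/√(Σx²·Σy²)), under which the similarity cut of 0.7
corresponds to a merge-height cut of 0.3; city-block distance is available
behind a flag (its cut value is a free parameter).

Agglomeration is implemented directly (O(n³), fine for screen-sized gene
sets) so that tie-breaking is deterministic: among equally distant pairs the
pair whose clusters carry the lowest original gene indices merges first.
The merge list uses the scipy ``linkage`` layout, so scipy's tree utilities
apply downstream.

Tree exports: Cluster-3.0-compatible CDT + GTR files (viewable in TreeView)
and a Newick string of the gene tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list
from scipy.spatial.distance import cdist

from .screen_statistics import FEATURES

#: Feature column order of the dZ matrix, fixed and recorded in exports.
DZ_FEATURES = tuple(FEATURES)


@dataclass
class ClusterResult:
    labels: pd.Series          # gene -> cluster id (contiguous from 1)
    merges: np.ndarray         # scipy-style (n-1, 4) linkage matrix
    genes: list[str]
    cut: float
    metric: str
    linkage: str = "complete"

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) if len(self.labels) else 0


def filter_genes(scores: pd.DataFrame, z_min: float = 1.0) -> pd.DataFrame:
    """Build the dZ matrix of genes with a strong sensitized phenotype.

    Keeps genes with |Z_chTOG| strictly greater than ``z_min`` for
    ``pct_multipolar`` OR ``mean_poles``; returns a genes × features frame of
    their dZ values over all five features.  Genes missing any feature are
    dropped first, so the matrix has no missing entries.

    Raises ``ValueError`` if no gene passes.
    """
    pivot_z = scores.pivot(index="gene", columns="feature", values="Z_chTOG")
    pivot_dz = scores.pivot(index="gene", columns="feature", values="dZ")
    complete = pivot_dz.dropna().index.intersection(pivot_z.dropna().index)
    pivot_z, pivot_dz = pivot_z.loc[complete], pivot_dz.loc[complete]
    keep = (pivot_z["pct_multipolar"].abs() > z_min) | (pivot_z["mean_poles"].abs() > z_min)
    matrix = pivot_dz.loc[keep, list(DZ_FEATURES)]
    if matrix.empty:
        raise ValueError(f"no genes pass the |Z_chTOG| > {z_min} filter")
    return matrix.sort_index()


def pairwise_distance(matrix: pd.DataFrame | np.ndarray,
                      metric: str = "uncentred_pearson") -> np.ndarray:
    """Symmetric zero-diagonal distance matrix between gene profiles.

    ``uncentred_pearson``: d = 1 − Σxᵢyᵢ/√(Σxᵢ²·Σyᵢ²) (undefined, and an
    error, for an all-zero profile).  ``cityblock``: d = Σ|xᵢ−yᵢ|.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if metric == "uncentred_pearson":
        norms = np.sqrt((X**2).sum(axis=1))
        if np.any(norms <= 0):
            bad = list(np.nonzero(norms <= 0)[0])
            raise ValueError(f"uncentred Pearson undefined for all-zero rows {bad}")
        sim = (X @ X.T) / np.outer(norms, norms)
        D = 1.0 - sim
    elif metric == "cityblock":
        D = cdist(X, X, metric="cityblock")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, None)


def cluster_complete(distances: np.ndarray) -> np.ndarray:
    """Complete-linkage agglomeration with deterministic tie-breaking.

    Among pairs at the minimal complete-linkage distance, the pair whose
    clusters contain the smallest original row indices merges first.
    Returns a scipy-style linkage matrix: row i merges cluster ids
    ``(a, b)`` at height ``h`` into new cluster id ``n + i``.
    """
    D = np.asarray(distances, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    # active cluster id -> (member row indices, representative lowest index)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    cdist_active: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            cdist_active[(i, j)] = D[i, j]
    merges = np.zeros((max(n - 1, 0), 4))
    next_id = n
    for step in range(n - 1):
        best = None
        for (a, b), d in cdist_active.items():
            la, lb = min(members[a]), min(members[b])
            lo, hi = (la, lb) if la < lb else (lb, la)
            key = (d, lo, hi)
            if best is None or key < best[0]:
                best = (key, (a, b))
        (d, _, _), (a, b) = best
        merged = sorted(members[a] + members[b])
        merges[step] = [a, b, d, len(merged)]
        for pair in [p for p in cdist_active if a in p or b in p]:
            del cdist_active[pair]
        others = [c for c in members if c not in (a, b)]
        del members[a], members[b]
        for c in others:
            dc = max(D[np.ix_(merged, members[c])].max(), 0.0)
            lo, hi = (c, next_id) if c < next_id else (next_id, c)
            cdist_active[(lo, hi)] = dc
        members[next_id] = merged
        next_id += 1
    return merges


def cut_clusters(merges: np.ndarray, genes: list[str], similarity_cut: float = 0.7,
                 metric: str = "uncentred_pearson") -> ClusterResult:
    """Cut the tree into flat clusters.

    For the uncentred-Pearson metric the cut is a *similarity* in [0, 1]:
    clusters are the maximal subtrees whose merge heights are all
    ≤ 1 − similarity_cut.  For city-block the cut is a raw distance.
    Cluster ids are contiguous from 1 in order of first gene appearance;
    singletons are allowed.
    """
    if metric == "uncentred_pearson":
        if not 0.0 <= similarity_cut <= 1.0:
            raise ValueError("similarity cut must be in [0, 1]")
        # a cut of 0 disables the criterion: anti-correlated profiles have
        # similarity < 0 (distance > 1), and the [0, 1] cut scale treats 0 as
        # "retain no structure" (everything in one cluster)
        height_cut = np.inf if similarity_cut == 0.0 else 1.0 - similarity_cut
    else:
        if similarity_cut < 0:
            raise ValueError("distance cut must be >= 0")
        height_cut = similarity_cut
    n = len(genes)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    # replay merges with height <= cut; cluster ids >= n map to their members
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for step, (a, b, h, _) in enumerate(merges):
        ia, ib = int(a), int(b)
        merged = members[ia] + members[ib]
        members[n + step] = merged
        if h <= height_cut + 1e-12:
            root = merged[0]
            for m in merged[1:]:
                parent[find(m)] = find(root)
    raw = [find(i) for i in range(n)]
    seen: dict[int, int] = {}
    labels = []
    for r in raw:
        if r not in seen:
            seen[r] = len(seen) + 1
        labels.append(seen[r])
    return ClusterResult(labels=pd.Series(labels, index=list(genes), name="cluster"),
                         merges=np.asarray(merges, dtype=float), genes=list(genes),
                         cut=similarity_cut, metric=metric)


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def _leaf_order(merges: np.ndarray, n: int) -> list[int]:
    if n == 1:
        return [0]
    return [int(i) for i in leaves_list(np.asarray(merges, dtype=np.double))]


def to_newick(merges: np.ndarray, genes: list[str]) -> str:
    """Newick string of the gene tree with heights as node depths."""
    n = len(genes)
    if n == 1:
        return f"{genes[0]};"
    height = {i: 0.0 for i in range(n)}
    node = {i: genes[i] for i in range(n)}
    for step, (a, b, h, _) in enumerate(merges):
        ia, ib = int(a), int(b)
        la = max(h - height[ia], 0.0)
        lb = max(h - height[ib], 0.0)
        node[n + step] = f"({node[ia]}:{la:.6g},{node[ib]}:{lb:.6g})"
        height[n + step] = float(h)
    return node[n + len(merges) - 1] + ";"


def export_tree(result: ClusterResult, matrix: pd.DataFrame, outdir: str | Path,
                basename: str = "dz_clusters") -> dict[str, Path]:
    """Write CDT + GTR (Cluster 3.0 / TreeView) and Newick files.

    The CDT holds the dZ matrix in dendrogram leaf order with GID links into
    the GTR tree; re-reading the CDT reproduces the matrix.  GTR scores are
    similarities (1 − merge height), matching the uncentred-Pearson cut
    convention.  Returns the written paths.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        genes = result.genes
        n = len(genes)
        order = _leaf_order(result.merges, n)
        cdt_path = outdir / f"{basename}.cdt"
        gtr_path = outdir / f"{basename}.gtr"
        nwk_path = outdir / f"{basename}.nwk"

        cols = list(matrix.columns)
        with cdt_path.open("w") as fh:
            fh.write("GID\tNAME\tGWEIGHT\t" + "\t".join(cols) + "\n")
            fh.write("EWEIGHT\t\t\t" + "\t".join("1" for _ in cols) + "\n")
            for idx in order:
                gene = genes[idx]
                vals = "\t".join(f"{matrix.loc[gene, c]:.6g}" for c in cols)
                fh.write(f"GENE{idx}X\t{gene}\t1\t{vals}\n")

        with gtr_path.open("w") as fh:
            for step, (a, b, h, _) in enumerate(result.merges):
                def name(k: int) -> str:
                    return f"GENE{k}X" if k < n else f"NODE{k - n + 1}X"
                fh.write(f"NODE{step + 1}X\t{name(int(a))}\t{name(int(b))}\t{1.0 - h:.6g}\n")

        nwk_path.write_text(to_newick(result.merges, genes) + "\n")
    except OSError as exc:
        raise OSError(f"failed writing tree exports under {outdir}: {exc}") from exc
    return {"cdt": cdt_path, "gtr": gtr_path, "newick": nwk_path}


def read_cdt(path: str | Path) -> pd.DataFrame:
    """Read back a CDT written by :func:`export_tree` (gene-indexed matrix)."""
    df = pd.read_csv(path, sep="\t")
    df = df[df["GID"] != "EWEIGHT"]
    df = df[~df["GID"].isna()]
    df = df[df["GID"].str.startswith("GENE")]
    data_cols = [c for c in df.columns if c not in ("GID", "NAME", "GWEIGHT")]
    out = df.set_index("NAME")[data_cols].astype(float)
    out.index.name = "gene"
    return out
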
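"""Germplasm grouping: SNP p-distances, neighbor-joining tree, clustering.

The p-distance between two lines is the mean, over markers observed in both,
of |d_i - d_j| / 2 — the proportion of differing allele content. Trees are
built by Saitou-Nei neighbor joining (exact on additive metrics), delegated
to scikit-bio; negative branch lengths are kept as computed. Group
assignment either cuts an average-linkage dendrogram into k clusters or
loads curated labels from a two-column file.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .relatedness import compute_ibs


class PhyloError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise PhyloError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise PhyloError("distance matrix not symmetric")
        if (np.diag(self.values) != 0).any():
            raise PhyloError("distance matrix diagonal not zero")
        if (self.values < 0).any():
            raise PhyloError("negative distances")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", index_label="id")

    def to_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, name in enumerate(self.ids):
                row = " ".join(f"{v:.10f}" for v in self.values[i])
                fh.write(f"{name}  {row}\n")


@dataclass
class GroupAssignment:
    labels: dict[str, str]
    k: int
    source: str  # {"clustering", "user"}

    def __post_init__(self) -> None:
        if len(set(self.labels.values())) != self.k:
            raise PhyloError("label count does not match k")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for lid, lab in self.labels.items():
                fh.write(f"{lid}\t{lab}\n")


def p_distance_matrix(g) -> DistanceMatrix:
    """Pairwise p-distances; complement of IBS similarity."""
    ibs = compute_ibs(g)
    d = 1.0 - ibs.values
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    return DistanceMatrix(ibs.ids, d)


def nj_tree(d: DistanceMatrix):
    """Neighbor-joining tree as a scikit-bio TreeNode (unrooted, branch
    lengths as computed — negatives possible and kept)."""
    if len(d.ids) < 3:
        raise PhyloError("need at least 3 taxa for neighbor joining")
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj

    tree = nj(SkbioDM(d.values, ids=d.ids), neg_as_zero=False)
    return tree


def write_newick(tree, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path: str | Path):
    from skbio import TreeNode

    return TreeNode.read(str(path), format="newick")


def assign_groups(d: DistanceMatrix, k: int) -> GroupAssignment:
    """Average-linkage hierarchical clustering cut into k groups.

    Labels are "group_1".."group_k" ordered by cluster size descending
    (ties by first-seen line order), so the labeling is deterministic.
    """
    n = len(d.ids)
    if not (1 <= k <= n):
        raise PhyloError(f"need 1 <= k <= {n}, got {k}")
    if k == n:
        flat = np.arange(1, n + 1)
    else:
        Zl = linkage(squareform(d.values, checks=False), method="average")
        flat = fcluster(Zl, t=k, criterion="maxclust")
    sizes = pd.Series(flat).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], int(np.flatnonzero(flat == c)[0])))
    rename = {c: f"group_{i + 1}" for i, c in enumerate(order)}
    labels = {lid: rename[c] for lid, c in zip(d.ids, flat)}
    return GroupAssignment(labels=labels, k=len(set(flat)), source="clustering")


def load_groups(path: str | Path,
                expected_lines: list[str] | None = None) -> GroupAssignment:
    """Curated two-column (line id, label) assignment."""
    labels: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        if not raw.strip():
            continue
        parts = raw.split("\t") if "\t" in raw else raw.split()
        if len(parts) != 2:
            raise PhyloError(f"line {lineno}: expected two columns")
        lid, lab = parts
        if lid in labels:
            raise PhyloError(f"duplicate id {lid!r} at line {lineno}")
        labels[lid] = lab
    if expected_lines is not None:
        missing = [l for l in expected_lines if l not in labels]
        if missing:
            raise PhyloError(f"unlabeled lines: {missing[:5]}")
        unknown = [l for l in labels if l not in set(expected_lines)]
        if unknown:
            raise PhyloError(f"unknown ids in group file: {unknown[:5]}")
    return GroupAssignment(labels=labels, k=len(set(labels.values())),
                           source="user")
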
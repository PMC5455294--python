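"""Group-level ordination and clustering of centroid distance matrices.

UPGMA (unweighted pair-group method with arithmetic averages) builds the
ultrametric dendrograms relating species/population centroids, and classical
(Torgerson) multidimensional scaling embeds the distance matrix in the
plane. Both operate on the Mahalanobis distance matrices produced by the
discriminant module; UPGMA runs on D = sqrt(D²) by default (a flag selects
D², and the choice is recorded on the tree).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def _check_distance(dist: pd.DataFrame) -> pd.DataFrame:
    d = dist.astype(float)
    if d.shape[0] != d.shape[1] or list(d.index) != list(d.columns):
        raise ValueError("distance matrix must be square with matching labels")
    if d.isna().any().any():
        raise ValueError("distance matrix contains NaN")
    a = d.to_numpy()
    if not np.allclose(a, a.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(a), 0.0, atol=1e-8):
        raise ValueError("distance matrix must have a zero diagonal")
    return d


@dataclass
class UpgmaNode:
    label: str | None = None  # leaf name, None for internal
    height: float = 0.0
    children: tuple = ()

    @property
    def leaves(self) -> tuple[str, ...]:
        if self.label is not None:
            return (self.label,)
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves)
        return tuple(out)


@dataclass
class UpgmaTree:
    """Rooted ultrametric tree with merge history and Newick export."""

    root: UpgmaNode
    scale: str  # "D" or "D2" — which distances were clustered
    merges: list = field(default_factory=list)  # (labels_i, labels_j, height)

    @property
    def leaf_names(self) -> tuple[str, ...]:
        return tuple(sorted(self.root.leaves))

    def newick(self) -> str:
        def fmt(node: UpgmaNode) -> str:
            if node.label is not None:
                return f"'{node.label}'" if _needs_quotes(node.label) else node.label
            inner = ",".join(
                f"{fmt(c)}:{node.height - c.height:.10g}" for c in node.children
            )
            return f"({inner})"

        return fmt(self.root) + ";"

    def cophenetic_matrix(self) -> pd.DataFrame:
        names = self.leaf_names
        out = pd.DataFrame(0.0, index=names, columns=names)

        def walk(node: UpgmaNode):
            if node.label is not None:
                return
            for i, a in enumerate(node.children):
                for b in node.children[i + 1 :]:
                    for la in a.leaves:
                        for lb in b.leaves:
                            out.loc[la, lb] = out.loc[lb, la] = 2.0 * node.height
                walk(a)

        walk(self.root)
        return out


def _needs_quotes(label: str) -> bool:
    return any(ch in label for ch in " ()[]:;,'")


def upgma_tree(dist: pd.DataFrame, use_squared: bool = False) -> UpgmaTree:
    """UPGMA agglomeration of a distance matrix into an ultrametric tree.

    Proportional (size-weighted) arithmetic averaging of distances; merge
    heights are half the merge distance. When `use_squared` is False and the
    input is a squared-distance matrix (the Mahalanobis D² convention),
    pass `dist**0.5` or leave the caller's convention explicit — this
    function clusters the values it is given. Ties are broken by the
    lexicographically smallest pair of cluster leaf-label tuples, making the
    merge sequence deterministic and invariant to input row order.
    """
    d = _check_distance(dist)
    labels = list(d.index)
    if len(labels) < 2:
        raise ValueError("need at least 2 leaves")
    nodes = {i: UpgmaNode(label=lab) for i, lab in enumerate(labels)}
    sizes = {i: 1 for i in nodes}
    dd = {
        frozenset((i, j)): float(d.iloc[i, j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    }
    merges = []
    next_id = len(labels)
    while len(nodes) > 1:
        best = min(
            dd.items(),
            key=lambda kv: (
                kv[1],
                tuple(sorted(min(nodes[k].leaves for k in kv[0]))),
                tuple(sorted(max(nodes[k].leaves for k in kv[0]))),
            ),
        )
        (pair, dist_ij) = best
        i, j = sorted(pair, key=lambda k: nodes[k].leaves)
        hi = dist_ij / 2.0
        merged = UpgmaNode(height=hi, children=(nodes[i], nodes[j]))
        merges.append((nodes[i].leaves, nodes[j].leaves, hi))
        ni, nj = sizes[i], sizes[j]
        for k in list(nodes):
            if k in (i, j):
                continue
            dik = dd.pop(frozenset((i, k)))
            djk = dd.pop(frozenset((j, k)))
            dd[frozenset((next_id, k))] = (ni * dik + nj * djk) / (ni + nj)
        dd.pop(frozenset((i, j)))
        del nodes[i], nodes[j], sizes[i], sizes[j]
        nodes[next_id] = merged
        sizes[next_id] = ni + nj
        next_id += 1
    root = next(iter(nodes.values()))
    return UpgmaTree(root=root, scale="D2" if use_squared else "D", merges=merges)


def upgma_from_squared(dist_sq: pd.DataFrame, use_squared: bool = False) -> UpgmaTree:
    """Cluster a squared-distance (D²) matrix, on D by default."""
    d = _check_distance(dist_sq)
    return upgma_tree(d if use_squared else np.sqrt(d), use_squared=use_squared)


def classical_mds(dist: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) scaling of a distance matrix.

    Double-centres −½D², takes the top-k eigenvectors scaled by the square
    roots of their eigenvalues. Axis signs are fixed so each axis's
    largest-magnitude coordinate is positive. If fewer than k positive
    eigenvalues exist, the remaining axes are zero-padded with a warning.
    """
    d = _check_distance(dist)
    if d.shape[0] < 2:
        raise ValueError("classical MDS needs at least 2 objects")
    D2 = d.to_numpy() ** 2
    n = len(D2)
    J = np.eye(n) - np.ones((n, n)) / n
    Bmat = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh(Bmat)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = int(np.sum(evals > max(evals[0], 0.0) * 1e-12))
    if pos < k:
        warnings.warn(
            f"only {pos} positive eigenvalues; padding {k - pos} axes with zeros",
            stacklevel=2,
        )
    coords = np.zeros((n, k))
    m = min(k, pos)
    coords[:, :m] = evecs[:, :m] * np.sqrt(evals[:m])
    for j in range(m):
        if coords[np.argmax(np.abs(coords[:, j])), j] < 0:
            coords[:, j] = -coords[:, j]
    return pd.DataFrame(
        coords, index=d.index, columns=[f"dim{j + 1}" for j in range(k)]
    )
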
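"""Shared-allele (Dps) distances from SSR profiles and neighbor-joining trees.

The panel's relatedness structure is summarized from multilocus SSR
(microsatellite) profiles with the shared-allele distance

    Dps(a, b) = 1 - mean over co-scored loci of |alleles(a) & alleles(b)| / max(|a|, |b|)

(multiset intersection; loci missing in either profile are skipped).  A
pooled variant — total shared alleles over total comparable alleles across
loci — is available, as published usage varies.  Dps is symmetric and zero on
identical profiles but is not guaranteed to satisfy the triangle inequality.

Trees are built with the classic Saitou–Nei neighbor-joining agglomeration,
implemented here directly: Q-criterion minimization, standard branch-length
and distance-update formulas, deterministic tie-breaking on label order, and
negative branch lengths clamped to zero with the deficit moved to the sibling
edge.  NJ is exact on additive distance matrices.  Resistance phenotypes are
mapped onto tips as the set of HRAC classes each line resisted.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .phenotypes import HERBICIDE_BY_NAME, ResistanceCall

__all__ = [
    "SSRProfile",
    "DistanceMatrix",
    "TreeNode",
    "dps_distance",
    "distance_matrix",
    "neighbor_joining",
    "annotate_tree",
    "read_ssr_table",
    "write_phylip",
    "tree_path_distances",
    "tip_bipartitions",
]


@dataclass(frozen=True)
class SSRProfile:
    """Multilocus SSR profile: locus name -> allele labels (fragment sizes).

    Diploid loci carry at most two alleles; missing loci are simply absent.
    """

    genotype_id: str
    loci: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for locus, alleles in self.loci.items():
            if len(alleles) == 0:
                raise ValueError(f"{self.genotype_id}/{locus}: scored locus with no allele")
            if len(alleles) > 2:
                raise ValueError(f"{self.genotype_id}/{locus}: more than 2 alleles at a diploid locus")


def _shared(a: tuple[str, ...], b: tuple[str, ...]) -> tuple[int, int]:
    ca, cb = Counter(a), Counter(b)
    inter = sum((ca & cb).values())
    return inter, max(len(a), len(b))


def dps_distance(a: SSRProfile, b: SSRProfile, mode: str = "per_locus") -> float:
    """Shared-allele distance in [0, 1] between two profiles."""
    common = sorted(set(a.loci) & set(b.loci))
    if not common:
        raise ValueError(
            f"profiles {a.genotype_id} and {b.genotype_id} share no scored locus"
        )
    if mode == "per_locus":
        shares = []
        for locus in common:
            inter, denom = _shared(a.loci[locus], b.loci[locus])
            shares.append(inter / denom)
        return 1.0 - sum(shares) / len(shares)
    if mode == "pooled":
        inter_total = denom_total = 0
        for locus in common:
            inter, denom = _shared(a.loci[locus], b.loci[locus])
            inter_total += inter
            denom_total += denom
        return 1.0 - inter_total / denom_total
    raise ValueError(f"unknown Dps mode {mode!r}")


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < -1e-12):
            raise ValueError("distances must be non-negative")
        self.values = np.clip((self.values + self.values.T) / 2.0, 0.0, None)

    def __getitem__(self, pair) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])


def distance_matrix(profiles: Sequence[SSRProfile], mode: str = "per_locus") -> DistanceMatrix:
    n = len(profiles)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = dps_distance(profiles[i], profiles[j], mode)
    return DistanceMatrix([p.genotype_id for p in profiles], d)


# ---------------------------------------------------------------------------
# tree


@dataclass
class TreeNode:
    """Rooted representation of the (unrooted) NJ tree.

    ``children`` holds (child, branch_length) pairs; tips have a name and no
    children.
    """

    name: str = ""
    children: list = field(default_factory=list)
    annotation: Optional[frozenset] = None   # HRAC classes resisted, or None

    @property
    def is_tip(self) -> bool:
        return not self.children

    def tips(self) -> list["TreeNode"]:
        if self.is_tip:
            return [self]
        out = []
        for child, _ in self.children:
            out.extend(child.tips())
        return out

    def to_newick(self, include_annotations: bool = False) -> str:
        def render(node: "TreeNode", length: Optional[float]) -> str:
            if node.is_tip:
                label = node.name
                if include_annotations and node.annotation is not None:
                    label += "|" + ("S" if not node.annotation
                                    else "+".join(map(str, sorted(node.annotation))))
            else:
                inner = ",".join(render(c, l) for c, l in node.children)
                label = f"({inner})"
            return label if length is None else f"{label}:{length:.10g}"

        return render(self, None) + ";"


def neighbor_joining(D: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining, exact on additive matrices.

    Ties in the Q criterion are broken toward the pair whose (label-sorted)
    subtree names are lexicographically smallest, making the result
    deterministic.  Negative branch lengths are clamped to zero with the
    deficit moved onto the sibling branch (total split length preserved).
    """
    n = len(D.labels)
    if n < 2:
        raise ValueError("neighbor joining needs at least 2 taxa")
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in D.labels]
    keys: list[str] = list(D.labels)           # smallest tip label per subtree
    d = D.values.copy()
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
                tie_key = tuple(sorted((keys[active[ai]], keys[active[aj]])))
                cand = (q, tie_key, ai, aj)
                if best is None or cand[0] < best[0] - 1e-12 or (
                    abs(cand[0] - best[0]) <= 1e-12 and tie_key < best[1]
                ):
                    best = cand
        _, _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = dij / 2.0 + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new node to every other active node
        new_row = np.zeros(d.shape[0] + 1)
        for ak in range(m):
            k = active[ak]
            if k in (i, j):
                continue
            new_row[k] = max(0.0, (d[i, k] + d[j, k] - dij) / 2.0)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        active = [k for k in active if k not in (i, j)] + [d.shape[0] - 1]

    i, j = active
    half = d[i, j] / 2.0
    return TreeNode(children=[(nodes[i], half), (nodes[j], half)])


def tree_path_distances(root: TreeNode) -> DistanceMatrix:
    """Tip-to-tip path-length distances of a tree."""
    labels = sorted(t.name for t in root.tips())
    index = {lab: k for k, lab in enumerate(labels)}
    out = np.zeros((len(labels), len(labels)))

    def pairs(node: TreeNode) -> dict[str, float]:
        if node.is_tip:
            return {node.name: 0.0}
        child_maps = []
        for child, length in node.children:
            cm = pairs(child)
            child_maps.append({t: dd + length for t, dd in cm.items()})
        for a in range(len(child_maps)):
            for b in range(a + 1, len(child_maps)):
                for t1, d1 in child_maps[a].items():
                    for t2, d2 in child_maps[b].items():
                        out[index[t1], index[t2]] = out[index[t2], index[t1]] = d1 + d2
        merged: dict[str, float] = {}
        for cm in child_maps:
            merged.update(cm)
        return merged

    pairs(root)
    return DistanceMatrix(labels, out)


def tip_bipartitions(root: TreeNode) -> list[frozenset]:
    """Non-trivial tip bipartitions (one side each) induced by internal edges."""
    all_tips = frozenset(t.name for t in root.tips())
    parts: list[frozenset] = []

    def walk(node: TreeNode) -> frozenset:
        if node.is_tip:
            return frozenset([node.name])
        below = frozenset()
        for child, _ in node.children:
            below |= walk(child)
        if 1 < len(below) < len(all_tips) - 1:
            parts.append(below)
        return below

    walk(root)
    return parts


def annotate_tree(root: TreeNode, calls: Sequence[ResistanceCall]) -> pd.DataFrame:
    """Attach resisted-HRAC-class sets to tips; returns the tip table.

    Tips without any trial record keep ``annotation=None`` (class "unknown").
    The susceptible class is the empty set (drawn black in figures).
    """
    classes: dict[str, set[int]] = {}
    for c in calls:
        classes.setdefault(c.genotype_id, set())
        if c.resistant and c.herbicide in HERBICIDE_BY_NAME:
            classes[c.genotype_id].add(HERBICIDE_BY_NAME[c.herbicide].hrac_group)
    rows = []
    for tip in root.tips():
        if tip.name in classes:
            tip.annotation = frozenset(classes[tip.name])
            label = ("susceptible" if not tip.annotation
                     else "HRAC " + "+".join(map(str, sorted(tip.annotation))))
        else:
            tip.annotation = None
            label = "unknown"
        rows.append({"tip": tip.name, "resistance_class": label})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O


def read_ssr_table(path: str | Path) -> list[SSRProfile]:
    """Long-format SSR table: columns genotype_id, locus, allele."""
    df = pd.read_csv(path, sep=None, engine="python",
                     dtype={"genotype_id": str, "locus": str, "allele": str})
    profiles = []
    for gid, sub in df.groupby("genotype_id", sort=True):
        loci = {
            locus: tuple(sorted(g["allele"]))
            for locus, g in sub.groupby("locus", sort=True)
        }
        profiles.append(SSRProfile(genotype_id=str(gid), loci=loci))
    return profiles


def write_phylip(D: DistanceMatrix, path: str | Path) -> None:
    """Square PHYLIP distance-matrix format."""
    lines = [f"{len(D.labels):5d}"]
    for lab, row in zip(D.labels, D.values):
        name = lab[:10].ljust(10)
        lines.append(name + "  " + "  ".join(f"{v:.6f}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def plot_tree(root: TreeNode, path: str | Path, title: str = "") -> None:
    """Render a simple colored cladogram of the annotated tree (PNG/PDF)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {None: "grey", frozenset(): "black"}
    palette = ["tab:red", "tab:blue", "tab:green", "tab:orange", "tab:purple"]

    ys: dict[int, float] = {}
    segments = []
    labels = []
    counter = [0.0]

    def layout(node: TreeNode, x: float) -> float:
        if node.is_tip:
            y = counter[0]
            counter[0] += 1.0
            labels.append((x, y, node))
            return y
        child_ys = []
        for child, length in node.children:
            cy = layout(child, x + length)
            segments.append(((x, cy), (x + length, cy)))
            child_ys.append(cy)
        y = sum(child_ys) / len(child_ys)
        segments.append(((x, min(child_ys)), (x, max(child_ys))))
        return y

    layout(root, 0.0)
    fig, ax = plt.subplots(figsize=(8, max(3, 0.22 * len(labels))))
    for (x1, y1), (x2, y2) in segments:
        ax.plot([x1, x2], [y1, y2], color="0.3", lw=0.8)
    class_color: dict[frozenset, str] = {}
    for x, y, node in labels:
        ann = node.annotation
        if ann not in colors and ann is not None:
            class_color.setdefault(ann, palette[len(class_color) % len(palette)])
        col = colors.get(ann) or class_color[ann]
        ax.text(x, y, " " + node.name, va="center", fontsize=6, color=col)
    ax.set_axis_off()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
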
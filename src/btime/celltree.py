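"""Immune-cell differentiation trees and structured covariance priors.

Immune phenotypes measured by multiplex immunofluorescence are related by
marker gain along a differentiation pathway (e.g. CD3 -> CD3+CD8+ ->
CD3+CD8+CD69+).  A :class:`DifferentiationTree` records that pathway:
each cell type has a parent, a non-negative distance to its parent
(conventionally 1 for a functional change and 0.5 for recent activation,
but user-assignable), and an integer *level* in the pathway.  The tree
sits below a conceptual root at distance ``root_distance`` from the
first cell type.

From the tree, four structured prior covariance/correlation matrices
over the ``m`` modeled cell types are constructed:

* exponential decay — correlation ``exp(-d_st / zeta)`` in pathway
  distance ``d_st``;
* tree — covariance equal to the root distance of the lowest common
  ancestor (LCA) of the two cell types;
* scaled tree — the LCA matrix times a positive scalar;
* multi-level tree — a positively weighted sum of per-level binary
  co-ancestry indicator matrices.

Each tree-based construction has an optional *block* variant that zeroes
the covariance between cell types on different branches of the pathway.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "DifferentiationTree",
    "CovarianceStructure",
    "path_distance",
    "lca_root_distance",
    "build_expdecay_correlation",
    "build_tree_covariance",
    "build_scaled_tree_covariance",
    "level_indicator",
    "build_multilevel_covariance",
    "block_mask",
    "ensure_positive_definite",
    "matrix_to_frame",
    "nhs_tree",
    "simulation_tree",
]

#: minimum eigenvalue below which a constructed matrix is repaired by jitter
PSD_TOL = 1e-8


@dataclass(frozen=True)
class DifferentiationTree:
    """A rooted cell-type tree with per-edge distances and level labels.

    Parameters
    ----------
    nodes
        Cell-type names in the fixed order used for all matrices.
    parent
        Map node -> parent node; the single root maps to ``None``.
    edge_distance
        Map node -> non-negative distance to its parent (root: ignored).
    level
        Map node -> positive integer level in the differentiation path.
        A child's level must be >= its parent's.
    root_distance
        Distance from the conceptual root to the tree's first node.
    """

    nodes: tuple[str, ...]
    parent: Mapping[str, str | None]
    edge_distance: Mapping[str, float]
    level: Mapping[str, int]
    root_distance: float = 1.0
    _depth: dict[str, float] = field(init=False, repr=False, compare=False, default=None)

    def __init__(
        self,
        nodes: Sequence[str],
        parent: Mapping[str, str | None],
        edge_distance: Mapping[str, float],
        level: Mapping[str, int],
        root_distance: float = 1.0,
    ):
        object.__setattr__(self, "nodes", tuple(nodes))
        object.__setattr__(self, "parent", dict(parent))
        object.__setattr__(self, "edge_distance", dict(edge_distance))
        object.__setattr__(self, "level", dict(level))
        object.__setattr__(self, "root_distance", float(root_distance))
        self._validate()
        object.__setattr__(self, "_depth", self._compute_depths())

    # -- validation -------------------------------------------------------
    def _validate(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate cell-type names")
        node_set = set(self.nodes)
        if set(self.parent) != node_set:
            raise ValueError("parent map must cover exactly the declared nodes")
        roots = [n for n in self.nodes if self.parent[n] is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        if self.root_distance < 0:
            raise ValueError("root_distance must be non-negative")
        for n in self.nodes:
            p = self.parent[n]
            if p is None:
                continue
            if p not in node_set:
                raise ValueError(f"parent {p!r} of {n!r} is not a declared node")
            if self.edge_distance.get(n, -1.0) < 0:
                raise ValueError(f"edge distance of {n!r} must be >= 0")
            if self.level[n] < self.level[p]:
                raise ValueError(f"level of {n!r} is below its parent's")
        for n in self.nodes:
            if self.level[n] < 1:
                raise ValueError("levels must be positive integers")
        # acyclicity / connectedness: every node must reach the root
        root = roots[0]
        for n in self.nodes:
            seen = set()
            cur = n
            while cur is not None:
                if cur in seen:
                    raise ValueError("parent links form a cycle")
                seen.add(cur)
                cur = self.parent[cur]
            if root not in seen:
                raise ValueError(f"{n!r} is not connected to the root")

    def _compute_depths(self) -> dict[str, float]:
        depth: dict[str, float] = {}

        def rec(n: str) -> float:
            if n in depth:
                return depth[n]
            p = self.parent[n]
            d = self.root_distance if p is None else rec(p) + self.edge_distance[n]
            depth[n] = d
            return d

        for n in self.nodes:
            rec(n)
        return depth

    # -- basic queries ----------------------------------------------------
    @property
    def m(self) -> int:
        return len(self.nodes)

    @property
    def root(self) -> str:
        return next(n for n in self.nodes if self.parent[n] is None)

    @property
    def max_level(self) -> int:
        return max(self.level.values())

    def index(self, node: str) -> int:
        try:
            return self.nodes.index(node)
        except ValueError:
            raise KeyError(f"unknown cell type: {node!r}") from None

    def ancestors(self, node: str, inclusive: bool = True) -> list[str]:
        """Ancestors of ``node`` from itself (if inclusive) up to the root."""
        self.index(node)
        out: list[str] = []
        cur: str | None = node if inclusive else self.parent[node]
        while cur is not None:
            out.append(cur)
            cur = self.parent[cur]
        return out

    def depth(self, node: str) -> float:
        """Distance from the conceptual root to ``node`` (root_distance included)."""
        self.index(node)
        return self._depth[node]

    def same_branch(self, s: str, t: str) -> bool:
        """True when the two cell types share an ancestor below the root node.

        A node is on the same branch as its own ancestors/descendants; two
        distinct subtrees hanging off the root node are different branches.
        """
        anc_s, anc_t = set(self.ancestors(s)), set(self.ancestors(t))
        common = anc_s & anc_t
        return any(self.parent[a] is not None for a in common) or s in anc_t or t in anc_s

    # -- (de)serialization -------------------------------------------------
    @classmethod
    def from_json(cls, path_or_text: str) -> "DifferentiationTree":
        """Load a tree from a JSON file path or a JSON string.

        Expected shape::

            {"root_distance": 1,
             "nodes": [{"name": "CD3", "parent": null,
                        "edge_distance": 0, "level": 1}, ...]}
        """
        text = path_or_text
        if not path_or_text.lstrip().startswith("{"):
            with open(path_or_text) as fh:
                text = fh.read()
        obj = json.loads(text)
        nodes = [rec["name"] for rec in obj["nodes"]]
        return cls(
            nodes=nodes,
            parent={rec["name"]: rec.get("parent") for rec in obj["nodes"]},
            edge_distance={rec["name"]: float(rec.get("edge_distance", 0.0)) for rec in obj["nodes"]},
            level={rec["name"]: int(rec["level"]) for rec in obj["nodes"]},
            root_distance=float(obj.get("root_distance", 1.0)),
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "root_distance": self.root_distance,
                "nodes": [
                    {
                        "name": n,
                        "parent": self.parent[n],
                        "edge_distance": self.edge_distance.get(n, 0.0),
                        "level": self.level[n],
                    }
                    for n in self.nodes
                ],
            },
            indent=1,
        )


# ---------------------------------------------------------------------------
# pairwise tree quantities
# ---------------------------------------------------------------------------

def path_distance(tree: DifferentiationTree, s: str, t: str) -> float:
    """Sum of edge distances along the unique path between cell types s and t.

    This is the immune differentiation distance d_st used by the
    exponential-decay correlation; it is symmetric and zero iff ``s == t``.
    """
    if s == t:
        tree.index(s)
        return 0.0
    anc_s = tree.ancestors(s)
    anc_t_set = set(tree.ancestors(t))
    lca = next(a for a in anc_s if a in anc_t_set)

    def up(node: str) -> float:
        d = 0.0
        while node != lca:
            d += tree.edge_distance[node]
            node = tree.parent[node]
        return d

    return up(s) + up(t)


def lca_root_distance(tree: DifferentiationTree, s: str, t: str) -> float:
    """Root distance of the deepest common ancestor of s and t (tau_st).

    Ancestors are taken inclusively of the nodes themselves, so for a
    parent/child pair the LCA is the parent-side node of the pair and
    ``tau_ss`` is the root-to-s distance.  The root distance of the
    conceptual root is included.
    """
    anc_s = set(tree.ancestors(s))
    anc_t = set(tree.ancestors(t))
    common = anc_s & anc_t
    if not common:  # unreachable on a valid tree (root is common)
        return 0.0
    return max(tree.depth(a) for a in common)


def block_mask(tree: DifferentiationTree) -> np.ndarray:
    """Binary m x m mask: 1 where two cell types share a branch, else 0.

    The mask is 1 on the diagonal and for any ancestor/descendant pair;
    it is 0 exactly for pairs whose only common ancestor is the root node
    of the tree (cell types on opposite branches).
    """
    m = tree.m
    M = np.zeros((m, m))
    for a, s in enumerate(tree.nodes):
        for b, t in enumerate(tree.nodes):
            M[a, b] = 1.0 if tree.same_branch(s, t) else 0.0
    return M


# ---------------------------------------------------------------------------
# covariance constructions
# ---------------------------------------------------------------------------

def ensure_positive_definite(T: np.ndarray, tol: float = PSD_TOL) -> np.ndarray:
    """Return ``T`` unchanged if its minimum eigenvalue is >= ``tol``;
    otherwise add diagonal jitter ``(|lam_min| + tol) I`` and warn."""
    lam_min = float(np.linalg.eigvalsh(T)[0])
    if lam_min >= tol:
        return T
    warnings.warn(
        f"covariance matrix repaired: min eigenvalue {lam_min:.3g} < {tol:.0e}, "
        "adding diagonal jitter",
        stacklevel=2,
    )
    return T + (abs(lam_min) + tol) * np.eye(T.shape[0])


def build_expdecay_correlation(tree: DifferentiationTree, zeta: float) -> np.ndarray:
    """Correlation matrix Delta with entries exp(-d_st / zeta)."""
    if zeta <= 0:
        raise ValueError("zeta must be > 0")
    m = tree.m
    D = np.zeros((m, m))
    for a, s in enumerate(tree.nodes):
        for b in range(a + 1, m):
            D[a, b] = D[b, a] = path_distance(tree, s, tree.nodes[b])
    return np.exp(-D / zeta)


def build_tree_covariance(tree: DifferentiationTree, block: bool = False) -> np.ndarray:
    """LCA covariance matrix: T[s, t] = root distance of the deepest common
    ancestor of s and t; optionally zeroed across branches (block design)."""
    m = tree.m
    T = np.zeros((m, m))
    for a, s in enumerate(tree.nodes):
        for b in range(a, m):
            T[a, b] = T[b, a] = lca_root_distance(tree, s, tree.nodes[b])
    if block:
        T = T * block_mask(tree)
    return ensure_positive_definite(T)


def build_scaled_tree_covariance(
    tree: DifferentiationTree, lam: float, block: bool = False
) -> np.ndarray:
    """Scaled-tree covariance: ``lam`` times the LCA covariance matrix."""
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    return lam * build_tree_covariance(tree, block=block)


def level_indicator(tree: DifferentiationTree, lvl: int) -> np.ndarray:
    """Binary co-ancestry indicator B^(l) for one level of the pathway.

    ``B[s, t] = 1`` iff some node assigned to level ``lvl`` is an
    ancestor-or-self of both s and t — equivalently, both cell types carry
    the marker combination that defines some level-``lvl`` phenotype.
    """
    if not 1 <= lvl <= tree.max_level:
        raise ValueError(f"level {lvl} out of range 1..{tree.max_level}")
    level_nodes = [n for n in tree.nodes if tree.level[n] == lvl]
    m = tree.m
    anc = [set(tree.ancestors(n)) for n in tree.nodes]
    B = np.zeros((m, m))
    for a in range(m):
        for b in range(a, m):
            hit = any(v in anc[a] and v in anc[b] for v in level_nodes)
            B[a, b] = B[b, a] = 1.0 if hit else 0.0
    return B


def build_multilevel_covariance(
    tree: DifferentiationTree, omega: Sequence[float], block: bool = False
) -> np.ndarray:
    """Multi-level tree covariance: sum_l omega_l * B^(l).

    One positive weight per level of the differentiation path; each B^(l)
    is PSD (a union of all-ones co-ancestry blocks), so the weighted sum is
    PSD by construction.
    """
    omega = np.asarray(omega, dtype=float)
    if omega.shape != (tree.max_level,):
        raise ValueError(f"expected {tree.max_level} level weights, got {omega.shape}")
    if np.any(omega <= 0):
        raise ValueError("level weights must be > 0")
    T = sum(w * level_indicator(tree, l + 1) for l, w in enumerate(omega))
    if block:
        T = T * block_mask(tree)
    return ensure_positive_definite(T)


def matrix_to_frame(tree: DifferentiationTree, T: np.ndarray):
    """Wrap an m x m tree-derived matrix as a labeled table (cell-type
    header row and column), ready for ``.to_csv``."""
    import pandas as pd

    T = np.asarray(T)
    if T.shape != (tree.m, tree.m):
        raise ValueError(f"matrix shape {T.shape} does not match {tree.m} cell types")
    return pd.DataFrame(T, index=list(tree.nodes), columns=list(tree.nodes))


@dataclass(frozen=True)
class CovarianceStructure:
    """A named recipe for the prior covariance over cell-type coefficients.

    ``kind`` is one of ``unstructured``, ``expdecay``, ``tree``,
    ``scaled_tree``, ``multilevel_tree``; ``block`` selects the
    zero-across-branches variant of the tree-based recipes.
    """

    kind: str
    block: bool = False

    KINDS = ("unstructured", "expdecay", "tree", "scaled_tree", "multilevel_tree")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown covariance kind {self.kind!r}; pick from {self.KINDS}")
        if self.block and self.kind in ("unstructured", "expdecay"):
            raise ValueError(f"block design is not defined for {self.kind!r}")

    def n_params(self, tree: DifferentiationTree | None) -> int:
        """Number of free scalar structure parameters per covariance matrix."""
        if self.kind == "tree":
            return 0
        if self.kind in ("scaled_tree",):
            return 1
        if self.kind == "multilevel_tree":
            return tree.max_level
        if self.kind == "expdecay":
            # zeta is shared across T0/T1; per-matrix params are the m scales
            return tree.m
        return 0  # unstructured: full matrix sampled by Gibbs

    def build(
        self, tree: DifferentiationTree | None, params: np.ndarray | None = None
    ) -> np.ndarray:
        """Materialize the covariance matrix for one coefficient vector.

        For ``expdecay``, ``params`` is ``(zeta, sigma_1..sigma_m)`` (standard
        deviations, giving T = Sigma Delta Sigma); for ``scaled_tree`` it is
        ``(lambda,)``; for ``multilevel_tree`` the level weights.
        """
        if self.kind == "tree":
            return build_tree_covariance(tree, block=self.block)
        if self.kind == "scaled_tree":
            return build_scaled_tree_covariance(tree, float(params[0]), block=self.block)
        if self.kind == "multilevel_tree":
            return build_multilevel_covariance(tree, params, block=self.block)
        if self.kind == "expdecay":
            zeta, sig = float(params[0]), np.asarray(params[1:], dtype=float)
            Delta = build_expdecay_correlation(tree, zeta)
            return (sig[:, None] * Delta) * sig[None, :]
        raise ValueError("unstructured covariance is sampled, not built")


# ---------------------------------------------------------------------------
# reference trees
# ---------------------------------------------------------------------------

def nhs_tree() -> DifferentiationTree:
    """The seven-phenotype T-cell differentiation pathway (CD3/CD4/CD8/
    FOXP3/CD69 panel): distance 1 per functional change, 0.5 per recent
    activation; four levels."""
    nodes = [
        "CD3",
        "CD3+CD8+",
        "CD3+CD8+CD69+",
        "CD3+CD4+",
        "CD3+CD4+CD69+",
        "CD3+CD4+FOXP3+",
        "CD3+CD4+FOXP3+CD69+",
    ]
    parent = {
        "CD3": None,
        "CD3+CD8+": "CD3",
        "CD3+CD8+CD69+": "CD3+CD8+",
        "CD3+CD4+": "CD3",
        "CD3+CD4+CD69+": "CD3+CD4+",
        "CD3+CD4+FOXP3+": "CD3+CD4+",
        "CD3+CD4+FOXP3+CD69+": "CD3+CD4+FOXP3+",
    }
    edge = {
        "CD3": 0.0,
        "CD3+CD8+": 1.0,
        "CD3+CD8+CD69+": 0.5,
        "CD3+CD4+": 1.0,
        "CD3+CD4+CD69+": 0.5,
        "CD3+CD4+FOXP3+": 1.0,
        "CD3+CD4+FOXP3+CD69+": 0.5,
    }
    level = {
        "CD3": 1,
        "CD3+CD8+": 2,
        "CD3+CD8+CD69+": 4,
        "CD3+CD4+": 2,
        "CD3+CD4+CD69+": 4,
        "CD3+CD4+FOXP3+": 3,
        "CD3+CD4+FOXP3+CD69+": 4,
    }
    return DifferentiationTree(nodes, parent, edge, level, root_distance=1.0)


def simulation_tree() -> DifferentiationTree:
    """Differentiation pathway for the four simulated cell types M1..M4:
    a chain of successively rarer sub-populations with unit distances."""
    nodes = ["M1", "M2", "M3", "M4"]
    parent = {"M1": None, "M2": "M1", "M3": "M2", "M4": "M3"}
    edge = {"M1": 0.0, "M2": 1.0, "M3": 1.0, "M4": 1.0}
    level = {"M1": 1, "M2": 2, "M3": 3, "M4": 4}
    return DifferentiationTree(nodes, parent, edge, level, root_distance=1.0)
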
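"""Hierarchical geometric graph encoder for structures and pockets.

Residues are nodes; edges connect Cα pairs within a cutoff radius. Node
geometry carries inter-residue Euler angles (tau1..tau3, from orthonormal
frames built on N/CA/C when available, else consecutive Cα triples) and
side-chain torsions (chi1..chi4) with validity flags. Message passing
follows ``v_i <- UPDATE(v_i, sum_j MESSAGE(v_j, e_ij, F(G)))`` with a
residual update and a mean-over-nodes graph readout. All features are
distances and angles, so outputs are invariant to node permutations and
rigid motions by construction.

Hierarchy levels: ``amino_acid`` (distances only), ``backbone`` (+ Euler
angles), ``all_atom`` (+ side-chain torsions).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from ..autodiff import Tensor, astensor
from ..io_formats import Atom
from ..synthetic import dihedral_angle

LEVELS = ("amino_acid", "backbone", "all_atom")

_CHI_CHAINS = [
    ("N", "CA", "CB", "CG"),
    ("CA", "CB", "CG", "CD"),
    ("CB", "CG", "CD", "CE"),
    ("CG", "CD", "CE", "CZ"),
]


@dataclasses.dataclass
class ProteinGraph:
    """Residue graph with positions, edges and geometric node features."""

    n_nodes: int
    ca: np.ndarray                 # (n, 3) Cα positions
    edges: np.ndarray              # (m, 2) directed pairs, both directions
    edge_dist: np.ndarray          # (m,)
    cutoff: float
    tau: np.ndarray                # (n, 3) Euler angles to the next residue
    tau_valid: np.ndarray          # (n, 3) bool
    chi: np.ndarray                # (n, 4) side-chain torsions
    chi_valid: np.ndarray          # (n, 4) bool
    residue_types: np.ndarray | None = None  # (n,) ints, optional


def _residue_atoms(atoms: Sequence[Atom]) -> list[dict[str, np.ndarray]]:
    residues: dict[int, dict[str, np.ndarray]] = {}
    for a in atoms:
        residues.setdefault(a.residue_index, {})[a.name] = a.position
    if not residues:
        raise ValueError("no atoms")
    indices = sorted(residues)
    if indices != list(range(len(indices))):
        raise ValueError("residue indices must be contiguous from 0")
    return [residues[i] for i in indices]


def _frame(res: dict[str, np.ndarray], prev_ca, this_ca, next_ca
           ) -> np.ndarray | None:
    """Right-handed orthonormal frame for one residue, or None."""
    if all(k in res for k in ("N", "CA", "C")):
        origin, a, b = res["CA"], res["C"], res["N"]
    elif prev_ca is not None and next_ca is not None:
        origin, a, b = this_ca, next_ca, prev_ca
    else:
        return None
    e1 = a - origin
    n1 = np.linalg.norm(e1)
    if n1 < 1e-9:
        return None
    e1 = e1 / n1
    u = b - origin
    u = u - (u @ e1) * e1
    n2 = np.linalg.norm(u)
    if n2 < 1e-9:
        return None
    e2 = u / n2
    e3 = np.cross(e1, e2)
    return np.stack([e1, e2, e3])


def _euler_zyx(R: np.ndarray) -> tuple[float, float, float]:
    """Intrinsic z-y-x Euler angles of a rotation matrix, in (-π, π]."""
    sy = -R[2, 0]
    sy = min(1.0, max(-1.0, sy))
    t2 = math.asin(sy)
    if abs(sy) < 1.0 - 1e-9:
        t1 = math.atan2(R[1, 0], R[0, 0])
        t3 = math.atan2(R[2, 1], R[2, 2])
    else:  # gimbal lock: fold the free rotation into t1
        t1 = math.atan2(-R[0, 1], R[1, 1])
        t3 = 0.0
    return t1, t2, t3


def build_protein_graph(atoms: Sequence[Atom], cutoff: float = 10.0,
                        residue_types: np.ndarray | None = None) -> ProteinGraph:
    """Build the residue graph; every residue must have a Cα atom."""
    residues = _residue_atoms(atoms)
    n = len(residues)
    if n < 2:
        raise ValueError("need at least 2 residues")
    missing = [i for i, r in enumerate(residues) if "CA" not in r]
    if missing:
        raise ValueError(f"residues {missing} lack a CA atom")
    ca = np.array([r["CA"] for r in residues])

    diff = ca[:, None, :] - ca[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    adj = (dist <= cutoff) & ~np.eye(n, dtype=bool)
    src, dst = np.nonzero(adj)
    edges = np.stack([src, dst], axis=1)
    edge_dist = dist[src, dst]

    # Euler angles between neighboring residue frames
    tau = np.zeros((n, 3))
    tau_valid = np.zeros((n, 3), dtype=bool)
    frames: list[np.ndarray | None] = []
    for i, res in enumerate(residues):
        prev_ca = ca[i - 1] if i > 0 else None
        next_ca = ca[i + 1] if i < n - 1 else None
        frames.append(_frame(res, prev_ca, ca[i], next_ca))
    for i in range(n - 1):
        if frames[i] is not None and frames[i + 1] is not None:
            R = frames[i] @ frames[i + 1].T
            tau[i] = _euler_zyx(R)
            tau_valid[i] = True

    # side-chain torsions
    chi = np.zeros((n, 4))
    chi_valid = np.zeros((n, 4), dtype=bool)
    for i, res in enumerate(residues):
        for k, chain in enumerate(_CHI_CHAINS):
            if all(name in res for name in chain):
                pts = [res[name] for name in chain]
                if (min(np.linalg.norm(pts[j + 1] - pts[j]) for j in range(3))
                        > 1e-9):
                    chi[i, k] = dihedral_angle(*pts)
                    chi_valid[i, k] = True

    return ProteinGraph(n_nodes=n, ca=ca, edges=edges, edge_dist=edge_dist,
                        cutoff=cutoff, tau=tau, tau_valid=tau_valid,
                        chi=chi, chi_valid=chi_valid,
                        residue_types=residue_types)


def _scatter_sum(src: Tensor, index: np.ndarray, n: int) -> Tensor:
    """Sum rows of ``src`` into ``n`` buckets given by ``index``."""
    out_data = np.zeros((n,) + src.data.shape[1:])
    np.add.at(out_data, index, src.data)
    out = Tensor(out_data)
    out.requires_grad = src.requires_grad
    if out.requires_grad:
        out._parents = (src,)

        def _bw() -> None:
            src._accum(out.grad[index])

        out._backward = _bw
    return out


def _node_geometry(graph: ProteinGraph, level: str) -> np.ndarray:
    """Per-node geometric feature block for the chosen hierarchy level."""
    feats = [np.zeros((graph.n_nodes, 0))]
    if level in ("backbone", "all_atom"):
        feats.append(np.where(graph.tau_valid, np.sin(graph.tau), 0.0))
        feats.append(np.where(graph.tau_valid, np.cos(graph.tau), 0.0))
        feats.append(graph.tau_valid.astype(float))
    if level == "all_atom":
        feats.append(np.where(graph.chi_valid, np.sin(graph.chi), 0.0))
        feats.append(np.where(graph.chi_valid, np.cos(graph.chi), 0.0))
        feats.append(graph.chi_valid.astype(float))
    return np.concatenate(feats, axis=1)


def _geom_width(level: str) -> int:
    return {"amino_acid": 0, "backbone": 9, "all_atom": 21}[level]


class GraphEncoder:
    """Message-passing encoder producing one feature vector per graph."""

    def __init__(self, width: int = 32, n_layers: int = 2,
                 level: str = "all_atom", n_residue_types: int = 21,
                 seed: int = 0, n_radial: int = 8, cutoff: float = 10.0):
        if level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}")
        self.width = width
        self.n_layers = n_layers
        self.level = level
        self.cutoff = cutoff
        self.n_radial = n_radial
        rng = np.random.default_rng(seed)
        s = 1.0 / math.sqrt(width)
        self.embedding = Tensor(rng.normal(scale=s, size=(n_residue_types, width)),
                                requires_grad=True)
        msg_in = width + n_radial + _geom_width(level)
        self.layers = []
        for _ in range(n_layers):
            self.layers.append({
                "Wm1": Tensor(rng.normal(scale=1.0 / math.sqrt(msg_in),
                                         size=(msg_in, width)), requires_grad=True),
                "bm1": Tensor(np.zeros(width), requires_grad=True),
                "Wm2": Tensor(rng.normal(scale=s, size=(width, width)),
                              requires_grad=True),
                "bm2": Tensor(np.zeros(width), requires_grad=True),
                "Wu": Tensor(rng.normal(scale=1.0 / math.sqrt(2 * width),
                                        size=(2 * width, width)),
                             requires_grad=True),
                "bu": Tensor(np.zeros(width), requires_grad=True),
            })

    def trainable_parameters(self, policy: str = "full") -> list[Tensor]:
        if policy == "freeze":
            return []
        if policy in ("full", "lora"):  # no adapters here: lora == full
            params = [self.embedding]
            for layer in self.layers:
                params.extend(layer.values())
            return params
        raise ValueError(f"unknown training policy '{policy}'")

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {"embedding": self.embedding.data}
        for i, layer in enumerate(self.layers):
            for k, v in layer.items():
                out[f"layer{i}.{k}"] = v.data
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        self.embedding.data = np.array(state["embedding"])
        for i, layer in enumerate(self.layers):
            for k in layer:
                layer[k].data = np.array(state[f"layer{i}.{k}"])

    def checksum(self) -> float:
        return float(sum(np.abs(p.data).sum()
                         for p in self.trainable_parameters("full")))

    def _radial(self, dist: np.ndarray) -> np.ndarray:
        """Gaussian radial basis expansion of edge lengths."""
        centers = np.linspace(0.0, self.cutoff, self.n_radial)
        gamma = (self.n_radial / max(self.cutoff, 1e-9)) ** 2
        return np.exp(-gamma * (dist[:, None] - centers[None, :]) ** 2)

    def forward(self, graphs: Sequence[ProteinGraph] | ProteinGraph) -> Tensor:
        """Encode one graph or a batch; returns (B, width)."""
        if isinstance(graphs, ProteinGraph):
            graphs = [graphs]
        if any(g.n_nodes == 0 for g in graphs):
            raise ValueError("empty graph")
        # disjoint union of the batch
        offsets = np.cumsum([0] + [g.n_nodes for g in graphs])
        n_total = offsets[-1]
        types = np.concatenate([
            g.residue_types if g.residue_types is not None
            else np.zeros(g.n_nodes, dtype=int) for g in graphs])
        edges = np.concatenate([g.edges + off for g, off in
                                zip(graphs, offsets[:-1])]) \
            if any(len(g.edges) for g in graphs) else np.zeros((0, 2), dtype=int)
        dist = np.concatenate([g.edge_dist for g in graphs])
        geom = np.concatenate([_node_geometry(g, self.level) for g in graphs])

        h = self.embedding[types]
        if len(edges):
            src, dst = edges[:, 0], edges[:, 1]
            edge_feat = np.concatenate([self._radial(dist), geom[src]], axis=1)
            edge_feat_t = Tensor(edge_feat)
        for layer in self.layers:
            if len(edges):
                from ..autodiff import concat as _concat
                msg_in = _concat([h[src], edge_feat_t], axis=1)
                msg = (msg_in @ layer["Wm1"] + layer["bm1"]).relu()
                msg = msg @ layer["Wm2"] + layer["bm2"]
                agg = _scatter_sum(msg, dst, n_total)
            else:
                agg = Tensor(np.zeros((n_total, self.width)))
            upd_in = _cat2(h, agg)
            h = h + (upd_in @ layer["Wu"] + layer["bu"]).tanh()

        # mean readout per graph via a constant averaging matrix
        pool = np.zeros((len(graphs), n_total))
        for b, (lo, hi) in enumerate(zip(offsets[:-1], offsets[1:])):
            pool[b, lo:hi] = 1.0 / (hi - lo)
        return Tensor(pool) @ h


def _cat2(a: Tensor, b: Tensor) -> Tensor:
    from ..autodiff import concat as _concat
    return _concat([a, b], axis=1)


def gnn_encode(graph, state: GraphEncoder) -> np.ndarray:
    """Functional forward pass returning plain arrays."""
    out = state.forward(graph).data
    return out[0] if isinstance(graph, ProteinGraph) else out
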
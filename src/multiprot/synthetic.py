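"""Synthetic multi-modal protein corpora with a shared ground-truth latent.

Each generated protein owns a hidden latent vector ``z``; every modality
(sequence, 3D structure, structure tokens, binding pocket, keyword text)
and every task label is a deterministic or noisy readout of that same
``z``. This gives the statistical structure the alignment method
assumes — all modalities are noisy views of one underlying identity — so
cross-modal alignment (including emergent alignment between modalities
never paired in training) is recoverable in principle.

Construction notes
------------------
* Sequences are sampled from position-specific residue distributions
  ``softmax(c * W_pos z)``.
* Backbones are torsion-driven Cα chains (fixed 3.8 Å virtual bonds,
  segment-dependent bend/torsion angles selected by ``z``), with N, C,
  CB and CG satellites, Gaussian coordinate noise, and coordinates
  rounded to 3 decimals (PDB precision) so files round-trip exactly.
* Structure tokens discretize Cα pseudo-dihedrals of the *emitted*
  coordinates, so tokens always regenerate exactly from the structure.
* The pocket is the residue set whose Cα lies within a configured radius
  of a pseudo-ligand point placed from ``z``.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .io_formats import AMINO_ACIDS, Atom

GAP = "-"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class LatentProtein:
    id: str
    z: np.ndarray


@dataclasses.dataclass
class ProteinRecord:
    """One protein's id plus optional payload per modality and task labels."""

    id: str
    sequence: str
    structure: list[Atom] | None = None
    tokens: list[int] | None = None
    pocket_residues: list[int] | None = None  # 0-based residue indices
    pocket_atoms: list[Atom] | None = None
    text: list[str] | None = None
    labels: dict = dataclasses.field(default_factory=dict)

    def has(self, modality: str) -> bool:
        return {
            "sequence": self.sequence is not None,
            "structure": self.structure is not None,
            "tokens": self.tokens is not None,
            "pocket": self.pocket_residues is not None,
            "text": self.text is not None,
        }[modality]


@dataclasses.dataclass
class Corpus:
    records: list[ProteinRecord]
    latents: list[LatentProtein]
    config: "GeneratorConfig"

    def __len__(self) -> int:
        return len(self.records)

    def by_id(self) -> dict[str, ProteinRecord]:
        return {r.id: r for r in self.records}


@dataclasses.dataclass
class MSAFamily:
    reference: str
    similar: list[str]
    divergent: list[str]
    unrelated: list[str]

    @property
    def members(self) -> list[str]:
        return self.similar + self.divergent + self.unrelated


@dataclasses.dataclass
class GeneratorConfig:
    """Knobs of the corpus generator; every default is desk-scale."""

    length_range: tuple[int, int] = (30, 50)
    structure_noise: float = 0.3          # Å, σ of coordinate noise
    pocket_radius: float = 8.0            # Å
    token_vocab_size: int = 16
    text_vocab_size: int = 30
    n_keywords: int = 4
    text_concentration: float = 1.0       # sharpness of topic distributions
    missing_pocket_fraction: float = 0.1
    missing_text_fraction: float = 0.1
    residue_concentration: float = 3.0    # sharpness of sequence distributions
    n_classes: int = 4
    n_binary_labels: int = 8
    label_noise: float = 0.1
    segment_length: int = 8

    def validate(self) -> None:
        for name in ("missing_pocket_fraction", "missing_text_fraction"):
            frac = getattr(self, name)
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {frac}")
        if self.length_range[0] < 4:
            raise ValueError("minimum sequence length is 4 (token dihedrals)")
        if self.token_vocab_size < 2:
            raise ValueError("token_vocab_size must be >= 2")


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _place_next(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray,
                bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF-style placement of the next chain atom from three predecessors."""
    bc = p3 - p2
    bc /= np.linalg.norm(bc)
    n = np.cross(p2 - p1, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:  # collinear history: pick any perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(helper, bc)
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    d = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        bond * math.sin(angle) * math.sin(torsion),
    ])
    return p3 + d[0] * bc + d[1] * m + d[2] * n


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed dihedral in (-π, π] via the standard two-normal atan2 form."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    ang = math.atan2(y, x)
    if ang <= -math.pi:  # canonicalize -π to +π
        ang = math.pi
    return ang


_SEGMENT_GEOMETRY = {
    # bend angle, torsion (radians) of the Cα virtual chain
    "helix": (math.radians(89.0), math.radians(50.0)),
    "strand": (math.radians(120.0), math.radians(-170.0)),
    "coil": (math.radians(100.0), math.radians(80.0)),
}


def tokens_from_structure(ca_positions: np.ndarray, vocab_size: int) -> list[int]:
    """Discretize local Cα pseudo-dihedrals into ``vocab_size`` bins.

    Residue ``i`` takes the dihedral of the quadruple starting at
    ``clamp(i-1, 0, n-4)``, so the token string has the sequence length.
    """
    ca = np.asarray(ca_positions, dtype=float)
    n = len(ca)
    if n < 4:
        raise ValueError("need at least 4 residues for token dihedrals")
    out: list[int] = []
    for i in range(n):
        j = min(max(i - 1, 0), n - 4)
        ang = dihedral_angle(ca[j], ca[j + 1], ca[j + 2], ca[j + 3])
        # map (-π, π] onto bins 0..V-1
        frac = (ang + math.pi) / (2.0 * math.pi)
        out.append(min(int(frac * vocab_size), vocab_size - 1))
    return out


def pocket_from_structure(ca_positions: np.ndarray, ligand: np.ndarray,
                          radius: float) -> list[int]:
    d = np.linalg.norm(np.asarray(ca_positions) - np.asarray(ligand), axis=1)
    return [int(i) for i in np.nonzero(d <= radius)[0]]


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

class _World:
    """Fixed projection matrices shared by every protein of one corpus."""

    def __init__(self, d_z: int, config: GeneratorConfig, seed: int):
        rng = np.random.default_rng([int(seed), 104729])
        max_len = config.length_range[1]
        n_seg = max_len // config.segment_length + 2
        self.seq_maps = rng.normal(size=(max_len, len(AMINO_ACIDS), d_z))
        self.segment_maps = rng.normal(size=(n_seg, d_z)) / math.sqrt(d_z)
        self.pocket_map = rng.normal(size=d_z) / math.sqrt(d_z)
        self.ligand_map = rng.normal(size=(3, d_z))
        self.text_map = rng.normal(size=(config.text_vocab_size, d_z))
        self.class_map = rng.normal(size=(config.n_classes, d_z))
        self.binary_map = rng.normal(size=(config.n_binary_labels, d_z))
        self.regression_map = rng.normal(size=d_z) / math.sqrt(d_z)
        self.length_map = rng.normal(size=d_z) / math.sqrt(d_z)
        self.chi_map = rng.normal(size=d_z) / math.sqrt(d_z)


def _softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max())
    return e / e.sum()


def _build_backbone(z: np.ndarray, length: int, world: _World,
                    config: GeneratorConfig, rng: np.random.Generator
                    ) -> np.ndarray:
    """Torsion-driven Cα trace whose segment pattern is selected by z."""
    seg_len = config.segment_length
    kinds = []
    for k in range((length + seg_len - 1) // seg_len):
        u = float(world.segment_maps[k] @ z)
        kinds.append("helix" if u > 0.25 else "strand" if u < -0.25 else "coil")
    bond = 3.8
    ca = np.zeros((length, 3))
    ca[1] = [bond, 0.0, 0.0]
    if length > 2:
        ca[2] = ca[1] + bond * np.array([math.cos(math.radians(60)),
                                         math.sin(math.radians(60)), 0.0])
    for i in range(3, length):
        kind = kinds[i // seg_len]
        angle, torsion = _SEGMENT_GEOMETRY[kind]
        ca[i] = _place_next(ca[i - 3], ca[i - 2], ca[i - 1], bond, angle, torsion)
    if config.structure_noise > 0:
        ca = ca + rng.normal(scale=config.structure_noise, size=ca.shape)
    return ca


def _satellite_atoms(ca: np.ndarray, chi_seed: float) -> list[Atom]:
    """N, CA, C, CB, CG atoms per residue derived from the Cα trace."""
    n_res = len(ca)
    atoms: list[Atom] = []
    for i in range(n_res):
        prev_dir = ca[i] - ca[i - 1] if i > 0 else ca[i] - ca[i + 1]
        next_dir = ca[i + 1] - ca[i] if i < n_res - 1 else ca[i] - ca[i - 1]
        prev_u = prev_dir / max(np.linalg.norm(prev_dir), 1e-9)
        next_u = next_dir / max(np.linalg.norm(next_dir), 1e-9)
        n_pos = ca[i] - 1.45 * prev_u
        c_pos = ca[i] + 1.52 * next_u
        side = np.cross(prev_u, next_u)
        sn = np.linalg.norm(side)
        if sn < 1e-9:
            side = np.cross(prev_u, [0.0, 0.0, 1.0])
            sn = max(np.linalg.norm(side), 1e-9)
        side = side / sn
        cb_pos = ca[i] + 1.53 * side
        # CG twisted about the CA-CB axis by a z-dependent amount
        twist = chi_seed + 0.35 * i
        axis = side
        ref = np.cross(axis, prev_u)
        ref /= max(np.linalg.norm(ref), 1e-9)
        ref2 = np.cross(axis, ref)
        cg_dir = math.cos(twist) * ref + math.sin(twist) * ref2
        cg_pos = cb_pos + 1.52 * (0.6 * axis + 0.8 * cg_dir)
        for name, pos, elem in (("N", n_pos, "N"), ("CA", ca[i], "C"),
                                ("C", c_pos, "C"), ("CB", cb_pos, "C"),
                                ("CG", cg_pos, "C")):
            p = np.round(pos, 3)
            atoms.append(Atom(name=name, residue_index=i, element=elem,
                              x=float(p[0]), y=float(p[1]), z=float(p[2])))
    return atoms


def ca_positions(atoms: Sequence[Atom]) -> np.ndarray:
    """Cα coordinates ordered by residue index."""
    cas = sorted((a for a in atoms if a.name == "CA"),
                 key=lambda a: a.residue_index)
    return np.array([[a.x, a.y, a.z] for a in cas])


def generate_corpus(n: int, d_z: int, seed: int,
                    config: GeneratorConfig | None = None) -> Corpus:
    """Generate ``n`` proteins whose modalities all derive from a latent z."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if d_z < 1:
        raise ValueError("d_z must be >= 1")
    config = config or GeneratorConfig()
    config.validate()
    world = _World(d_z, config, seed)
    rng = np.random.default_rng([int(seed), 7919])

    records: list[ProteinRecord] = []
    latents: list[LatentProtein] = []
    lo, hi = config.length_range
    for idx in range(n):
        pid = f"P{idx:05d}"
        z = rng.normal(size=d_z)
        latents.append(LatentProtein(id=pid, z=z))

        # length: deterministic function of z within the configured range
        lfrac = 0.5 * (math.tanh(float(world.length_map @ z)) + 1.0)
        length = lo + int(round(lfrac * (hi - lo)))

        # sequence
        seq_chars = []
        for i in range(length):
            probs = _softmax(config.residue_concentration * (world.seq_maps[i] @ z))
            seq_chars.append(AMINO_ACIDS[rng.choice(len(AMINO_ACIDS), p=probs)])
        sequence = "".join(seq_chars)

        # structure
        ca = _build_backbone(z, length, world, config, rng)
        chi_seed = float(world.chi_map @ z)
        atoms = _satellite_atoms(ca, chi_seed)
        ca_final = ca_positions(atoms)

        # tokens from the emitted coordinates (modal consistency by design)
        tokens = tokens_from_structure(ca_final, config.token_vocab_size)

        # pocket
        c_idx = min(length - 1, max(0, int(
            0.5 * (math.tanh(float(world.pocket_map @ z)) + 1.0) * length)))
        offset = world.ligand_map @ z
        offset = 2.0 * offset / max(np.linalg.norm(offset), 1e-9)
        ligand = ca_final[c_idx] + offset
        pocket = pocket_from_structure(ca_final, ligand, config.pocket_radius)
        pocket_atoms = [a for a in atoms if a.residue_index in set(pocket)]

        # text keywords from a z-dependent topic distribution
        topic = _softmax(config.text_concentration * (world.text_map @ z))
        k = min(config.n_keywords, config.text_vocab_size)
        chosen = rng.choice(config.text_vocab_size, size=k, replace=False, p=topic)
        text = [f"kw{j:03d}" for j in chosen]

        # labels
        labels = {
            "class": int(np.argmax(world.class_map @ z)),
            "binary_vec": [int(v > 0) for v in world.binary_map @ z],
            "regression": float(world.regression_map @ z
                                + config.label_noise * rng.normal()),
            "binary": int(float(world.regression_map @ z) > 0),
        }

        records.append(ProteinRecord(
            id=pid, sequence=sequence, structure=atoms, tokens=tokens,
            pocket_residues=pocket, pocket_atoms=pocket_atoms, text=text,
            labels=labels))

    # missing-modality fractions honored exactly (floor)
    n_missing_pocket = int(config.missing_pocket_fraction * n)
    n_missing_text = int(config.missing_text_fraction * n)
    for i in rng.choice(n, size=n_missing_pocket, replace=False):
        records[i].pocket_residues = None
        records[i].pocket_atoms = None
    for i in rng.choice(n, size=n_missing_text, replace=False):
        records[i].text = None

    return Corpus(records=records, latents=latents, config=config)


# ---------------------------------------------------------------------------
# MSA family simulation
# ---------------------------------------------------------------------------

def generate_msa_family(length: int, n_similar: int = 50, n_divergent: int = 50,
                        n_unrelated: int = 1000, rate_similar: float = 0.05,
                        rate_divergent: float = 0.3, seed: int = 0,
                        gap_rate: float = 0.0) -> MSAFamily:
    """Simulate an aligned family around a random reference sequence.

    ``similar``/``divergent`` members substitute each site with the given
    probability, drawing replacements uniformly from the full alphabet
    (so the expected mismatch fraction is ``rate * 19/20``); ``unrelated``
    members are independent of the reference.
    """
    for name, cnt in (("n_similar", n_similar), ("n_divergent", n_divergent),
                      ("n_unrelated", n_unrelated)):
        if cnt < 0:
            raise ValueError(f"{name} must be >= 0")
    for name, rate in (("rate_similar", rate_similar),
                       ("rate_divergent", rate_divergent),
                       ("gap_rate", gap_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if rate_similar >= rate_divergent:
        raise ValueError("rate_similar must be < rate_divergent")

    rng = np.random.default_rng(seed)
    alphabet = np.array(list(AMINO_ACIDS))
    reference = "".join(alphabet[rng.integers(0, 20, size=length)])

    def mutate(rate: float) -> str:
        chars = list(reference)
        hits = rng.random(length) < rate
        subs = alphabet[rng.integers(0, 20, size=length)]
        for i in np.nonzero(hits)[0]:
            chars[i] = subs[i]
        if gap_rate > 0:
            gaps = rng.random(length) < gap_rate
            for i in np.nonzero(gaps)[0]:
                chars[i] = GAP
        return "".join(chars)

    similar = [mutate(rate_similar) for _ in range(n_similar)]
    divergent = [mutate(rate_divergent) for _ in range(n_divergent)]
    unrelated = ["".join(alphabet[rng.integers(0, 20, size=length)])
                 for _ in range(n_unrelated)]
    return MSAFamily(reference=reference, similar=similar,
                     divergent=divergent, unrelated=unrelated)


# ---------------------------------------------------------------------------
# Identity-threshold splitting
# ---------------------------------------------------------------------------

def sequence_identity(a: str, b: str) -> float:
    """Positional identity over the shorter length (alignment-free)."""
    m = min(len(a), len(b))
    if m == 0:
        raise ValueError("empty sequence")
    return sum(1 for x, y in zip(a[:m], b[:m]) if x == y) / m


def cluster_by_identity(sequences: Sequence[str], threshold: float) -> list[int]:
    """Greedy single-linkage clusters: components of identity >= threshold."""
    n = len(sequences)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if sequence_identity(sequences[i], sequences[j]) >= threshold:
                parent[find(i)] = find(j)
    roots: dict[int, int] = {}
    labels = []
    for i in range(n):
        r = find(i)
        labels.append(roots.setdefault(r, len(roots)))
    return labels


def split_by_identity(corpus: Corpus | Sequence[ProteinRecord],
                      threshold: float = 0.5, seed: int = 0,
                      fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
                      ) -> dict[str, set[str]]:
    """Cluster-aware train/validation/test id split.

    Whole clusters land in exactly one split; cluster order is shuffled by
    ``seed`` and each cluster goes to the split with the largest remaining
    deficit relative to its target fraction.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    records = corpus.records if isinstance(corpus, Corpus) else list(corpus)
    if not records:
        raise ValueError("empty corpus")
    labels = cluster_by_identity([r.sequence for r in records], threshold)
    clusters: dict[int, list[str]] = {}
    for rec, lab in zip(records, labels):
        clusters.setdefault(lab, []).append(rec.id)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(clusters))
    names = ("train", "val", "test")
    targets = {s: f * len(records) for s, f in zip(names, fractions)}
    counts = {s: 0 for s in names}
    splits: dict[str, set[str]] = {s: set() for s in names}
    cluster_list = list(clusters.values())
    for ci in order:
        ids = cluster_list[ci]
        deficit = {s: targets[s] - counts[s] for s in names}
        best = max(names, key=lambda s: deficit[s])
        splits[best].update(ids)
        counts[best] += len(ids)
    return splits
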
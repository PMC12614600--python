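"""Anchor-paired contrastive alignment of modality encoders.

The sequence modality is the anchor: every training pair couples it with
one other modality (structure graph, structure tokens, pocket, text).
The loss for a batch of unit embeddings A, B is the InfoNCE objective

    L = -(1/n) sum_i log[ exp(a_i·b_i / tau)
                          / sum_j exp(a_i·b_j / tau) ]

and the total per-step loss is the symmetric sum of both directions.
Training round-robins over the registered pair datasets in registration
order, drawing the next batch from each and applying one gradient update
per visit, so differently sized datasets are all consumed repeatedly.
Modalities never paired together still end up aligned through the shared
anchor (emergent alignment).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .autodiff import Adam, SGD, Tensor, astensor
from .encoders.graph import GraphEncoder, ProteinGraph, build_protein_graph
from .encoders.transformer import Transformer, TransformerConfig
from .heads import AttentionPoolParams, ProjectionParams, l2_normalize, project
from .io_formats import AMINO_ACIDS
from .synthetic import Corpus, GeneratorConfig, ProteinRecord

_NEG_INF = -1e30
ANCHOR = "sequence"
POLICIES = ("freeze", "full", "lora")


@dataclasses.dataclass
class SharedSpaceConfig:
    dim: int = 64
    temperature: float = 0.07
    trainable_temperature: bool = False

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.dim < 2:
            raise ValueError("shared dimension must be >= 2")


@dataclasses.dataclass
class SharedEmbedding:
    id: str | None
    modality: str
    vector: np.ndarray


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def _check_unit_rows(x: np.ndarray, tol: float = 1e-4) -> None:
    norms = np.linalg.norm(x, axis=-1)
    if np.any(np.abs(norms - 1.0) > tol):
        raise ValueError("embedding rows must be unit-norm")


def info_nce_loss(A, B, tau: float = 0.07):
    """One-directional InfoNCE over positionally paired unit embeddings."""
    if isinstance(tau, Tensor):
        if tau.data.item() <= 0:
            raise ValueError("temperature must be positive")
        inv_tau = tau ** -1.0
    else:
        if tau <= 0:
            raise ValueError("temperature must be positive")
        inv_tau = 1.0 / tau
    At, Bt = astensor(A), astensor(B)
    _check_unit_rows(At.data)
    _check_unit_rows(Bt.data)
    n = At.shape[0]
    logits = (At @ Bt.T) * inv_tau
    shifted = logits - Tensor(logits.data.max(axis=1, keepdims=True))
    lse = shifted.exp().sum(axis=1).log()
    diag = shifted[(np.arange(n), np.arange(n))]
    loss = (lse - diag).mean()
    return loss if isinstance(A, Tensor) or isinstance(B, Tensor) \
        else float(loss.data)


def symmetric_loss(A, B, tau: float = 0.07):
    """Bidirectional total loss: L(A,B) + L(B,A)."""
    fwd = info_nce_loss(astensor(A), astensor(B), tau)
    bwd = info_nce_loss(astensor(B), astensor(A), tau)
    total = fwd + bwd
    return total if isinstance(A, Tensor) or isinstance(B, Tensor) \
        else float(total.data)


# ---------------------------------------------------------------------------
# Tokenizers
# ---------------------------------------------------------------------------

_AA_INDEX = {c: i for i, c in enumerate(AMINO_ACIDS)}


def tokenize_sequence(seq: str) -> np.ndarray:
    return np.array([_AA_INDEX[c] for c in seq if c in _AA_INDEX], dtype=int)


def sequence_vocab() -> int:
    return len(AMINO_ACIDS) + 1  # + padding id


def tokenize_structure_tokens(tokens: Sequence[int]) -> np.ndarray:
    return np.asarray(tokens, dtype=int)


def make_text_tokenizer(text_vocab_size: int) -> Callable[[Sequence[str]], np.ndarray]:
    """Keywords -> ids; 0 is padding, 1 is the CLS slot, words start at 2."""

    def tok(keywords: Sequence[str]) -> np.ndarray:
        ids = [1]
        for kw in keywords:
            ids.append(int(kw[2:]) + 2)
        return np.array(ids, dtype=int)

    return tok


# ---------------------------------------------------------------------------
# Modality pipelines
# ---------------------------------------------------------------------------

class TransformerPipeline:
    """tokenize -> transformer -> pool -> project for one token modality."""

    def __init__(self, encoder: Transformer, tokenizer: Callable,
                 pad_id: int, pooler: str, projection: ProjectionParams,
                 policy: str, pool_params: AttentionPoolParams | None = None):
        if policy not in POLICIES:
            raise ValueError(f"unknown policy '{policy}'")
        if pooler not in ("attention", "mean", "cls"):
            raise ValueError(f"unknown pooler '{pooler}'")
        self.encoder = encoder
        self.tokenizer = tokenizer
        self.pad_id = pad_id
        self.pooler = pooler
        self.pool_params = pool_params
        self.projection = projection
        self.policy = policy

    def _batch(self, samples: Sequence) -> tuple[np.ndarray, np.ndarray]:
        toks = [self.tokenizer(s) for s in samples]
        L = max(len(t) for t in toks)
        tokens = np.full((len(toks), L), self.pad_id, dtype=int)
        mask = np.zeros((len(toks), L), dtype=bool)
        for i, t in enumerate(toks):
            tokens[i, :len(t)] = t
            mask[i, :len(t)] = True
        return tokens, mask

    def pooled(self, samples: Sequence) -> Tensor:
        tokens, mask = self._batch(samples)
        feats = self.encoder.forward(tokens, mask)  # (B, L, d)
        B, L, d = feats.shape
        maskf = mask.astype(float)
        if self.pooler == "cls":
            return feats[(np.arange(B), np.zeros(B, dtype=int))]
        if self.pooler == "mean":
            w = maskf / maskf.sum(axis=1, keepdims=True)
            return (Tensor(w[:, None, :]) @ feats).reshape(B, d)
        # attention: K=1 masked convolution scores, softmax on valid slots
        wvec = self.pool_params.score.weight.reshape(-1, 1)  # (d, 1)
        scores = (feats @ wvec).reshape(B, L) * Tensor(maskf)
        logits = scores + Tensor(np.where(mask, 0.0, _NEG_INF))
        shifted = logits - Tensor(logits.data.max(axis=1, keepdims=True))
        e = shifted.exp()
        weights = e / e.sum(axis=1, keepdims=True)
        return (weights.reshape(B, 1, L) @ feats).reshape(B, d)

    def encode(self, samples: Sequence) -> Tensor:
        return project(self.pooled(samples), self.projection)

    def trainable_parameters(self) -> list[Tensor]:
        params = self.encoder.trainable_parameters(self.policy)
        if self.pool_params is not None:
            params = params + self.pool_params.trainable_parameters()
        return params + self.projection.trainable_parameters()

    def checksum(self) -> float:
        return self.encoder.checksum()

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {f"enc.{k}": v for k, v in self.encoder.state_dict().items()}
        if self.pool_params is not None:
            out["pool.weight"] = self.pool_params.score.weight.data
        for i, p in enumerate(self.projection.trainable_parameters()):
            out[f"proj.{i}"] = p.data
        return out

    def load_state_dict(self, state: Mapping[str, np.ndarray]) -> None:
        self.encoder.load_state_dict(
            {k[4:]: v for k, v in state.items() if k.startswith("enc.")})
        if self.pool_params is not None:
            self.pool_params.score.weight.data = np.array(state["pool.weight"])
        for i, p in enumerate(self.projection.trainable_parameters()):
            p.data = np.array(state[f"proj.{i}"])


class GraphPipeline:
    """Geometric GNN with its internal mean readout, then projection."""

    def __init__(self, encoder: GraphEncoder, projection: ProjectionParams,
                 policy: str):
        if policy not in POLICIES:
            raise ValueError(f"unknown policy '{policy}'")
        self.encoder = encoder
        self.projection = projection
        self.policy = policy
        self.pooler = "none"

    def encode(self, samples: Sequence[ProteinGraph]) -> Tensor:
        return project(self.encoder.forward(list(samples)), self.projection)

    def trainable_parameters(self) -> list[Tensor]:
        return (self.encoder.trainable_parameters(self.policy)
                + self.projection.trainable_parameters())

    def checksum(self) -> float:
        return self.encoder.checksum()

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {f"enc.{k}": v for k, v in self.encoder.state_dict().items()}
        for i, p in enumerate(self.projection.trainable_parameters()):
            out[f"proj.{i}"] = p.data
        return out

    def load_state_dict(self, state: Mapping[str, np.ndarray]) -> None:
        self.encoder.load_state_dict(
            {k[4:]: v for k, v in state.items() if k.startswith("enc.")})
        for i, p in enumerate(self.projection.trainable_parameters()):
            p.data = np.array(state[f"proj.{i}"])


# ---------------------------------------------------------------------------
# The multi-modal model
# ---------------------------------------------------------------------------

class ModalityModel:
    """Registered modality pipelines sharing one contrastive latent space."""

    def __init__(self, config: SharedSpaceConfig):
        self.config = config
        self.pipelines: dict[str, TransformerPipeline | GraphPipeline] = {}
        self.tau: Tensor | float = (
            Tensor(np.array(config.temperature), requires_grad=True)
            if config.trainable_temperature else config.temperature)

    def register(self, name: str, pipeline) -> None:
        if name in self.pipelines:
            raise ValueError(f"modality '{name}' already registered")
        self.pipelines[name] = pipeline

    @property
    def modalities(self) -> list[str]:
        return list(self.pipelines)

    def _require(self, modality: str):
        if modality not in self.pipelines:
            raise KeyError(f"modality '{modality}' is not registered")
        return self.pipelines[modality]

    def encode(self, modality: str, samples: Sequence) -> Tensor:
        """Unit-row embedding matrix (n, l) for a batch of samples."""
        raw = self._require(modality).encode(samples)
        return astensor(l2_normalize(raw, axis=-1))

    def embed(self, sample, modality: str,
              protein_id: str | None = None) -> SharedEmbedding:
        vec = self.encode(modality, [sample]).data[0]
        return SharedEmbedding(id=protein_id, modality=modality, vector=vec)

    def pair_parameters(self, modality: str) -> list[Tensor]:
        """Parameters updated on a (anchor, modality) step."""
        params = list(self._require(ANCHOR).trainable_parameters())
        if modality != ANCHOR:
            params += self._require(modality).trainable_parameters()
        if isinstance(self.tau, Tensor):
            params.append(self.tau)
        # dedupe by identity while keeping order
        seen: set[int] = set()
        out = []
        for p in params:
            if id(p) not in seen:
                seen.add(id(p))
                out.append(p)
        return out


def save_model(model: ModalityModel, path) -> None:
    """Write all parameter arrays to an ``.npz`` checkpoint.

    The architecture itself is not serialized: rebuild the model with the
    same constructor arguments, then ``load_model`` restores the state.
    """
    flat: dict[str, np.ndarray] = {"tau": np.atleast_1d(
        model.tau.data if isinstance(model.tau, Tensor)
        else np.array(model.tau))}
    for name, pipe in model.pipelines.items():
        for k, v in pipe.state_dict().items():
            flat[f"{name}::{k}"] = v
    np.savez(Path(path), **flat)


def load_model(model: ModalityModel, path) -> ModalityModel:
    with np.load(Path(path), allow_pickle=False) as data:
        tau = float(data["tau"][0])
        if isinstance(model.tau, Tensor):
            model.tau.data = np.array(tau)
        else:
            model.tau = tau
        for name, pipe in model.pipelines.items():
            prefix = f"{name}::"
            pipe.load_state_dict({k[len(prefix):]: data[k] for k in data.files
                                  if k.startswith(prefix)})
    return model


# ---------------------------------------------------------------------------
# Pair datasets and training
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PairBatch:
    ids: list[str]
    anchor_samples: list
    other_samples: list
    modality: str

    def __len__(self) -> int:
        return len(self.ids)


class PairDataset:
    """Aligned (anchor, other-modality) samples for one pairing."""

    def __init__(self, modality: str, ids: Sequence[str],
                 anchor_samples: Sequence, other_samples: Sequence):
        if not (len(ids) == len(anchor_samples) == len(other_samples)):
            raise ValueError("misaligned pair dataset")
        if len(ids) == 0:
            raise ValueError("empty pair dataset")
        self.modality = modality
        self.ids = list(ids)
        self.anchor_samples = list(anchor_samples)
        self.other_samples = list(other_samples)
        self._order: np.ndarray | None = None
        self._cursor = 0

    def __len__(self) -> int:
        return len(self.ids)

    def next_batch(self, batch_size: int, rng: np.random.Generator) -> PairBatch:
        """Cycle through shuffled epochs independently of other datasets."""
        take: list[int] = []
        while len(take) < min(batch_size, len(self.ids)):
            if self._order is None or self._cursor >= len(self.ids):
                self._order = rng.permutation(len(self.ids))
                self._cursor = 0
            take.append(int(self._order[self._cursor]))
            self._cursor += 1
        return PairBatch(
            ids=[self.ids[i] for i in take],
            anchor_samples=[self.anchor_samples[i] for i in take],
            other_samples=[self.other_samples[i] for i in take],
            modality=self.modality)


def pocket_graph(record: ProteinRecord, cutoff: float = 10.0
                 ) -> ProteinGraph | None:
    """Graph over the pocket residue subset (reindexed contiguously)."""
    if record.pocket_residues is None or record.pocket_atoms is None:
        return None
    kept = sorted(set(record.pocket_residues))
    if len(kept) < 2:
        return None
    remap = {old: new for new, old in enumerate(kept)}
    atoms = [dataclasses.replace(a, residue_index=remap[a.residue_index])
             for a in record.pocket_atoms if a.residue_index in remap]
    types = np.array([_AA_INDEX[record.sequence[i]] for i in kept])
    return build_protein_graph(atoms, cutoff=cutoff, residue_types=types)


def structure_graph(record: ProteinRecord, cutoff: float = 10.0
                    ) -> ProteinGraph | None:
    if record.structure is None:
        return None
    types = np.array([_AA_INDEX[c] for c in record.sequence])
    return build_protein_graph(record.structure, cutoff=cutoff,
                               residue_types=types)


def build_pair_datasets(corpus: Corpus, modalities: Sequence[str],
                        ids: Iterable[str] | None = None,
                        cutoff: float = 10.0) -> dict[str, PairDataset]:
    """One PairDataset per non-anchor modality; records missing that
    modality are excluded from its dataset."""
    keep = set(ids) if ids is not None else None
    out: dict[str, PairDataset] = {}
    for modality in modalities:
        if modality == ANCHOR:
            continue
        rows_ids, anchors, others = [], [], []
        for rec in corpus.records:
            if keep is not None and rec.id not in keep:
                continue
            sample = modality_sample(rec, modality, cutoff)
            if sample is None:
                continue
            rows_ids.append(rec.id)
            anchors.append(rec.sequence)
            others.append(sample)
        out[modality] = PairDataset(modality, rows_ids, anchors, others)
    return out


def modality_sample(rec: ProteinRecord, modality: str, cutoff: float = 10.0):
    """The encoder-ready sample of one record for one modality, or None."""
    if modality == "sequence":
        return rec.sequence
    if modality == "structure":
        return structure_graph(rec, cutoff)
    if modality == "tokens":
        return rec.tokens
    if modality == "pocket":
        return pocket_graph(rec, cutoff)
    if modality == "text":
        return rec.text
    raise KeyError(f"unknown modality '{modality}'")


@dataclasses.dataclass
class TrainSchedule:
    steps: int = 1000
    batch_size: int = 32
    lr: float = 1e-3
    optimizer: str = "adam"   # or "sgd"
    momentum: float = 0.0
    seed: int = 0


def _make_optimizer(params, schedule: TrainSchedule):
    if schedule.optimizer == "adam":
        return Adam(params, lr=schedule.lr)
    if schedule.optimizer == "sgd":
        return SGD(params, lr=schedule.lr, momentum=schedule.momentum)
    raise ValueError(f"unknown optimizer '{schedule.optimizer}'")


def train_step(model: ModalityModel, batch: PairBatch, optimizer) -> float:
    """Forward, symmetric loss, one gradient update. Returns the loss."""
    A = model.encode(ANCHOR, batch.anchor_samples)
    B = model.encode(batch.modality, batch.other_samples)
    loss = symmetric_loss(A, B, model.tau)
    optimizer.zero_grad()
    loss.backward()
    optimizer.step()
    if isinstance(model.tau, Tensor):
        model.tau.data = np.maximum(model.tau.data, 1e-4)
    return float(loss.data)


def train(model: ModalityModel, datasets: dict[str, PairDataset],
          schedule: TrainSchedule) -> list[tuple[int, str, float]]:
    """Round-robin anchor-paired training; returns the (step, modality,
    loss) log."""
    if not datasets:
        raise ValueError("at least one pair dataset required")
    order = [m for m in model.modalities if m in datasets]
    if not order:
        raise ValueError("no registered modality has a pair dataset")
    rng = np.random.default_rng(schedule.seed)
    optimizers = {m: _make_optimizer(model.pair_parameters(m), schedule)
                  for m in order}
    log: list[tuple[int, str, float]] = []
    for step in range(schedule.steps):
        modality = order[step % len(order)]
        batch = datasets[modality].next_batch(schedule.batch_size, rng)
        loss = train_step(model, batch, optimizers[modality])
        log.append((step, modality, loss))
    return log


# ---------------------------------------------------------------------------
# Default desk-scale model construction
# ---------------------------------------------------------------------------

DEFAULT_POLICIES = {
    # mirrors the published training policy table; at desk scale there is
    # no pretrained anchor, so callers may override sequence -> "full".
    "sequence": "freeze",
    "structure": "full",
    "tokens": "full",
    "pocket": "full",
    "text": "lora",
}

DEFAULT_POOLERS = {
    "sequence": "attention",
    "tokens": "mean",
    "text": "cls",
}


def make_default_model(gen_config: GeneratorConfig,
                       shared: SharedSpaceConfig | None = None,
                       modalities: Sequence[str] = ("sequence", "structure",
                                                    "tokens", "text"),
                       policies: dict[str, str] | None = None,
                       d_model: int = 32, n_layers: int = 1, n_heads: int = 4,
                       text_layers: int | None = None,
                       gnn_width: int = 32, gnn_layers: int = 2,
                       gnn_level: str = "all_atom", cutoff: float = 10.0,
                       lora_rank: int = 4, seed: int = 0) -> ModalityModel:
    """Build a model with one pipeline per requested modality."""
    shared = shared or SharedSpaceConfig()
    pol = dict(DEFAULT_POLICIES)
    pol.update(policies or {})
    model = ModalityModel(shared)
    rng = np.random.default_rng([seed, 15485863])

    def next_seed() -> int:
        return int(rng.integers(2 ** 31))

    if "sequence" not in modalities:
        raise ValueError("the anchor (sequence) modality is required")

    for modality in modalities:
        if modality == "sequence":
            cfg = TransformerConfig(vocab_size=sequence_vocab(),
                                    d_model=d_model, n_layers=n_layers,
                                    n_heads=n_heads, d_ff=2 * d_model,
                                    max_len=max(gen_config.length_range[1], 64))
            enc = Transformer(cfg, seed=next_seed())
            pipe = TransformerPipeline(
                enc, tokenize_sequence, pad_id=len(AMINO_ACIDS),
                pooler=DEFAULT_POOLERS["sequence"],
                projection=ProjectionParams(d_model, shared.dim, "linear",
                                            seed=next_seed()),
                policy=pol["sequence"],
                pool_params=AttentionPoolParams.init(d_model, seed=next_seed()))
        elif modality == "tokens":
            vocab = gen_config.token_vocab_size + 1
            cfg = TransformerConfig(vocab_size=vocab, d_model=d_model,
                                    n_layers=n_layers, n_heads=n_heads,
                                    d_ff=2 * d_model,
                                    max_len=max(gen_config.length_range[1], 64))
            enc = Transformer(cfg, seed=next_seed())
            pipe = TransformerPipeline(
                enc, tokenize_structure_tokens,
                pad_id=gen_config.token_vocab_size,
                pooler=DEFAULT_POOLERS["tokens"],
                projection=ProjectionParams(d_model, shared.dim, "linear",
                                            seed=next_seed()),
                policy=pol["tokens"])
        elif modality == "text":
            vocab = gen_config.text_vocab_size + 2
            cfg = TransformerConfig(vocab_size=vocab, d_model=d_model,
                                    n_layers=text_layers
                                    if text_layers is not None else n_layers,
                                    n_heads=n_heads, d_ff=2 * d_model,
                                    max_len=gen_config.n_keywords + 2)
            enc = Transformer(cfg, seed=next_seed(),
                              lora_rank=lora_rank if pol["text"] == "lora"
                              else None)
            pipe = TransformerPipeline(
                enc, make_text_tokenizer(gen_config.text_vocab_size),
                pad_id=0, pooler=DEFAULT_POOLERS["text"],
                projection=ProjectionParams(d_model, shared.dim, "mlp",
                                            seed=next_seed()),
                policy=pol["text"])
        elif modality in ("structure", "pocket"):
            enc = GraphEncoder(width=gnn_width, n_layers=gnn_layers,
                               level=gnn_level, seed=next_seed(),
                               cutoff=cutoff)
            pipe = GraphPipeline(
                enc, ProjectionParams(gnn_width, shared.dim, "linear",
                                      seed=next_seed()),
                policy=pol[modality])
        else:
            raise KeyError(f"unknown modality '{modality}'")
        model.register(modality, pipe)
    return model
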
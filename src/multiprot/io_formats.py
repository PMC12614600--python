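"""Readers and writers for every on-disk format the package touches.

Formats
-------
* FASTA — sequences (20-letter amino-acid alphabet, uppercased on read).
* Minimal PDB — ``ATOM`` records only, one chain, one model. Residue
  indices are 1-based on disk and converted to 0-based at the parser
  boundary.
* Tab-delimited tables with a header row — token strings, keyword
  annotations, labels, manifests, metric tables.
* Embedding containers — a documented text layout (full 17-significant-
  digit decimals, lossless for doubles) plus an optional ``.npz`` binary
  layout with an id index.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


class FormatError(ValueError):
    """Raised on malformed input files; message carries the line number."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    """Parse a FASTA file into ``(id, sequence)`` records."""
    records: list[tuple[str, str]] = []
    name: str | None = None
    chunks: list[str] = []
    start_line = 0

    def flush(line_no: int) -> None:
        if name is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"line {start_line}: empty sequence for '{name}'")
        records.append((name, seq))

    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(i)
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FormatError(f"line {i}: empty FASTA header")
                chunks = []
                start_line = i
            else:
                if name is None:
                    raise FormatError(f"line {i}: sequence before any '>' header")
                up = line.upper()
                bad = set(up) - _AA_SET
                if bad:
                    raise FormatError(
                        f"line {i}: illegal residue character(s) {sorted(bad)}")
                chunks.append(up)
    flush(-1)
    if not records and name is None:
        raise FormatError("no FASTA records found (missing '>' header)")
    return records


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Minimal PDB (ATOM records, single chain/model)
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class Atom:
    """One ATOM record; ``residue_index`` is 0-based in memory."""

    name: str
    residue_index: int
    element: str
    x: float
    y: float
    z: float

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


def read_pdb_min(path) -> list[Atom]:
    atoms: list[Atom] = []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            if not raw.startswith("ATOM"):
                continue
            line = raw.rstrip("\n")
            if len(line) < 54:
                raise FormatError(f"line {i}: truncated ATOM record")
            try:
                name = line[12:16].strip()
                res_idx = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as exc:
                raise FormatError(f"line {i}: malformed ATOM fields: {exc}") from None
            element = line[76:78].strip() if len(line) >= 78 else name[:1]
            atoms.append(Atom(name=name, residue_index=res_idx - 1,
                              element=element, x=x, y=y, z=z))
    if not atoms:
        raise FormatError("no ATOM records found")
    return atoms


def write_pdb_min(path, atoms: Sequence[Atom], residue_name: str = "ALA") -> None:
    with open(path, "w") as fh:
        for serial, a in enumerate(atoms, start=1):
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            fh.write(
                f"ATOM  {serial:5d} {name:<4s}{residue_name:>4s} A"
                f"{a.residue_index + 1:4d}    "
                f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Tab-delimited tables
# ---------------------------------------------------------------------------

_PARSERS = {
    "str": str,
    "int": int,
    "float": float,
    "int_list": lambda s: [int(t) for t in s.split()] if s else [],
    "float_list": lambda s: [float(t) for t in s.split()] if s else [],
    "str_list": lambda s: s.split() if s else [],
}


def _format_cell(value) -> str:
    if isinstance(value, (list, tuple, np.ndarray)):
        return " ".join(_format_cell(v) for v in value)
    if isinstance(value, float):
        return repr(value)
    if isinstance(value, (np.floating,)):
        return repr(float(value))
    if isinstance(value, (np.integer,)):
        return str(int(value))
    return str(value)


def read_table(path, schema: dict[str, str]) -> list[dict]:
    """Read a header-row TSV; ``schema`` maps column name -> type name.

    Type names: str, int, float, int_list, float_list, str_list (lists are
    space-separated within a cell).
    """
    rows: list[dict] = []
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
        if not header_line:
            raise FormatError("empty table: missing header row")
        header = header_line.split("\t")
        if list(schema) != header:
            raise FormatError(
                f"schema mismatch: expected columns {list(schema)}, found {header}")
        parsers = [_PARSERS[schema[c]] for c in header]
        for i, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(header):
                raise FormatError(
                    f"line {i}: ragged row ({len(cells)} cells, expected {len(header)})")
            try:
                rows.append({c: p(v) for c, p, v in zip(header, parsers, cells)})
            except ValueError as exc:
                raise FormatError(f"line {i}: typed parse failed: {exc}") from None
    return rows


def write_table(path, rows: Iterable[dict], columns: Sequence[str]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(_format_cell(row[c]) for c in columns) + "\n")


# ---------------------------------------------------------------------------
# Embedding containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EmbeddingContainer:
    """Ordered (id, vector) rows in a common dimension with a modality tag."""

    dim: int
    modality: str
    model: str
    ids: list[str]
    vectors: np.ndarray  # (n, dim)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[1] != self.dim:
            raise ValueError(
                f"vectors must be (n, {self.dim}); got {self.vectors.shape}")
        if len(self.ids) != self.vectors.shape[0]:
            raise ValueError("ids and vectors disagree in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in embedding container")

    def lookup(self, protein_id: str) -> np.ndarray:
        return self.vectors[self.ids.index(protein_id)]

    def as_dict(self) -> dict[str, np.ndarray]:
        return {pid: self.vectors[i] for i, pid in enumerate(self.ids)}


def write_embeddings(path, container: EmbeddingContainer) -> None:
    """Write text (``.tsv``) or binary (``.npz``) depending on suffix."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(path, ids=np.array(container.ids), vectors=container.vectors,
                 meta=np.array([container.modality, container.model]))
        return
    with open(path, "w") as fh:
        fh.write(f"# dim={container.dim}\tmodality={container.modality}"
                 f"\tmodel={container.model}\n")
        for pid, vec in zip(container.ids, container.vectors):
            fh.write(pid + "\t" + "\t".join(f"{v:.17g}" for v in vec) + "\n")


def read_embeddings(path) -> EmbeddingContainer:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as data:
            ids = [str(i) for i in data["ids"]]
            vectors = data["vectors"]
            modality, model = (str(m) for m in data["meta"])
        return EmbeddingContainer(dim=vectors.shape[1], modality=modality,
                                  model=model, ids=ids, vectors=vectors)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise FormatError("embedding file missing '# dim=...' header")
        meta = dict(field.split("=", 1) for field in header[1:].split())
        dim = int(meta["dim"])
        ids: list[str] = []
        rows: list[list[float]] = []
        for i, raw in enumerate(fh, start=2):
            cells = raw.rstrip("\n").split("\t")
            if len(cells) != dim + 1:
                raise FormatError(
                    f"line {i}: dimension mismatch ({len(cells) - 1} values, "
                    f"expected {dim})")
            ids.append(cells[0])
            rows.append([float(v) for v in cells[1:]])
    return EmbeddingContainer(dim=dim, modality=meta.get("modality", ""),
                              model=meta.get("model", ""), ids=ids,
                              vectors=np.array(rows) if rows else
                              np.zeros((0, dim)))
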
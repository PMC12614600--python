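"""Persist synthetic corpora as plain-text files and read them back.

Layout under a corpus directory:

* ``sequences.fasta``
* ``structures/<id>.pdb`` (minimal ATOM records)
* ``tokens.tsv``, ``text.tsv``, ``pockets.tsv``, ``labels.tsv``
* ``manifest.tsv`` — per-protein 0/1 modality availability
"""

from __future__ import annotations

from pathlib import Path

from .io_formats import (read_fasta, read_pdb_min, read_table, write_fasta,
                         write_pdb_min, write_table)
from .synthetic import Corpus, GeneratorConfig, ProteinRecord

MODALITIES = ("sequence", "structure", "tokens", "pocket", "text")

_MANIFEST_SCHEMA = {"id": "str", **{m: "int" for m in MODALITIES}}
_LABEL_SCHEMA = {"id": "str", "class": "int", "binary": "int",
                 "regression": "float", "binary_vec": "int_list"}


def write_corpus(corpus: Corpus, directory) -> None:
    directory = Path(directory)
    (directory / "structures").mkdir(parents=True, exist_ok=True)
    write_fasta(directory / "sequences.fasta",
                [(r.id, r.sequence) for r in corpus.records])
    tokens_rows, text_rows, pocket_rows, label_rows, manifest = [], [], [], [], []
    for r in corpus.records:
        if r.structure is not None:
            write_pdb_min(directory / "structures" / f"{r.id}.pdb", r.structure)
        if r.tokens is not None:
            tokens_rows.append({"id": r.id, "tokens": r.tokens})
        if r.text is not None:
            text_rows.append({"id": r.id, "keywords": r.text})
        if r.pocket_residues is not None:
            pocket_rows.append({"id": r.id, "residues": r.pocket_residues})
        label_rows.append({"id": r.id, **{k: r.labels[k] for k in
                                          ("class", "binary", "regression",
                                           "binary_vec")}})
        manifest.append({"id": r.id,
                         **{m: int(r.has(m)) for m in MODALITIES}})
    write_table(directory / "tokens.tsv", tokens_rows, ["id", "tokens"])
    write_table(directory / "text.tsv", text_rows, ["id", "keywords"])
    write_table(directory / "pockets.tsv", pocket_rows, ["id", "residues"])
    write_table(directory / "labels.tsv", label_rows, list(_LABEL_SCHEMA))
    write_table(directory / "manifest.tsv", manifest, list(_MANIFEST_SCHEMA))


def read_corpus(directory, config: GeneratorConfig | None = None) -> Corpus:
    """Rebuild a Corpus (without hidden latents) from its directory."""
    directory = Path(directory)
    seqs = dict(read_fasta(directory / "sequences.fasta"))
    tokens = {row["id"]: row["tokens"] for row in
              read_table(directory / "tokens.tsv", {"id": "str",
                                                    "tokens": "int_list"})}
    text = {row["id"]: row["keywords"] for row in
            read_table(directory / "text.tsv", {"id": "str",
                                                "keywords": "str_list"})}
    pockets = {row["id"]: row["residues"] for row in
               read_table(directory / "pockets.tsv", {"id": "str",
                                                      "residues": "int_list"})}
    labels = {row["id"]: row for row in
              read_table(directory / "labels.tsv", _LABEL_SCHEMA)}
    manifest = read_table(directory / "manifest.tsv", _MANIFEST_SCHEMA)

    records = []
    for row in manifest:
        pid = row["id"]
        structure = None
        if row["structure"]:
            structure = read_pdb_min(directory / "structures" / f"{pid}.pdb")
        pocket_res = pockets.get(pid) if row["pocket"] else None
        pocket_atoms = None
        if pocket_res is not None and structure is not None:
            keep = set(pocket_res)
            pocket_atoms = [a for a in structure if a.residue_index in keep]
        lab = labels[pid]
        records.append(ProteinRecord(
            id=pid, sequence=seqs[pid], structure=structure,
            tokens=tokens.get(pid) if row["tokens"] else None,
            pocket_residues=pocket_res, pocket_atoms=pocket_atoms,
            text=text.get(pid) if row["text"] else None,
            labels={"class": lab["class"], "binary": lab["binary"],
                    "regression": lab["regression"],
                    "binary_vec": lab["binary_vec"]}))
    return Corpus(records=records, latents=[],
                  config=config or GeneratorConfig())
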
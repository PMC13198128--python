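"""Corpus input/output: the three protein modalities and their pairing.

A corpus is a set of :class:`ProteinRecord` objects.  Every record has an
amino-acid sequence; a subset additionally carries a backbone structure
(N/CA/C coordinates read from PDB files) and/or a free-text functional
description.  This module reads and validates the standard formats,
filters by sequence length, summarises the available sequence-structure
and sequence-text pairs in a :class:`CorpusManifest`, and tokenizes
sequences and texts for the encoders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import gemmi

__all__ = [
    "STANDARD_AAS",
    "SEQUENCE_ALPHABET",
    "PAD_ID",
    "BOS_ID",
    "EOS_ID",
    "UNK_ID",
    "SEQ_TOKEN_TO_ID",
    "SEQ_VOCAB_SIZE",
    "ProteinRecord",
    "BackboneStructure",
    "CorpusManifest",
    "TokenizedInput",
    "TextVocab",
    "normalize_sequence",
    "read_fasta",
    "write_fasta",
    "read_backbone",
    "write_backbone",
    "with_structure",
    "filter_by_length",
    "build_manifest",
    "manifest_from_metadata",
    "tokenize_sequence",
    "detokenize_sequence",
    "tokenize_text",
    "build_text_vocab",
    "load_corpus",
    "write_corpus_index",
]

STANDARD_AAS = "ACDEFGHIKLMNPQRSTVWY"
SEQUENCE_ALPHABET = STANDARD_AAS + "X"
#: ambiguous / rare residue codes collapsed onto X
_NONSTANDARD_TO_X = {"B", "Z", "U", "O", "J"}

PAD_ID, BOS_ID, EOS_ID, UNK_ID = 0, 1, 2, 3
SEQ_TOKEN_TO_ID = {aa: i + 4 for i, aa in enumerate(SEQUENCE_ALPHABET)}
SEQ_ID_TO_TOKEN = {i: aa for aa, i in SEQ_TOKEN_TO_ID.items()}
SEQ_VOCAB_SIZE = 4 + len(SEQUENCE_ALPHABET)

BACKBONE_ATOMS = ("N", "CA", "C")


class CorpusError(ValueError):
    """Raised for malformed or inconsistent corpus inputs."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class BackboneStructure:
    """Per-residue backbone coordinates in angstroms.

    coords has shape (n_residues, 3, 3): axis 1 indexes the N, CA, C
    atoms in that order.  ``mask[i]`` is True iff all three atoms of
    residue i are present; masked-out residues are excluded from all
    geometry.  Residue numbering from the source file is retained as
    metadata only; indexing is 0-based.
    """

    coords: np.ndarray
    mask: np.ndarray
    residue_numbers: tuple = ()

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "mask", mask)
        if coords.ndim != 3 or coords.shape[1:] != (3, 3):
            raise CorpusError(f"backbone coords must be (n, 3, 3), got {coords.shape}")
        if mask.shape != (coords.shape[0],):
            raise CorpusError("mask length must equal residue count")
        if not np.isfinite(coords[mask]).all():
            raise CorpusError("non-finite coordinates in unmasked residues")
        self._warn_on_broken_chain()

    def _warn_on_broken_chain(self):
        ca = self.coords[:, 1, :]
        ok = self.mask
        for i in range(len(ok) - 1):
            if ok[i] and ok[i + 1]:
                d = float(np.linalg.norm(ca[i + 1] - ca[i]))
                if not (2.0 < d < 5.0):
                    warnings.warn(
                        f"consecutive CA-CA distance {d:.2f} A between residues "
                        f"{i} and {i + 1} outside (2.0, 5.0) A",
                        stacklevel=3,
                    )

    def __len__(self) -> int:
        return int(self.coords.shape[0])


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: sequence plus optional structure, text and class label.

    The class label exists only for synthetic corpora, recording the
    latent class a generated record was drawn from.
    """

    id: str
    sequence: str
    structure: BackboneStructure | None = None
    text: str | None = None
    class_label: int | None = None

    def __post_init__(self):
        if not self.sequence:
            raise CorpusError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - set(SEQUENCE_ALPHABET)
        if bad:
            raise CorpusError(
                f"record {self.id!r}: characters {sorted(bad)} outside alphabet "
                f"(normalize with normalize_sequence first)"
            )
        if self.structure is not None and len(self.structure) != len(self.sequence):
            raise CorpusError(
                f"record {self.id!r}: structure has {len(self.structure)} residues "
                f"but sequence has {len(self.sequence)}"
            )


@dataclass(frozen=True)
class CorpusManifest:
    """Which records form sequence-text and sequence-structure pairs."""

    seq_text_ids: tuple
    seq_struct_ids: tuple

    @property
    def n_seq_text(self) -> int:
        return len(self.seq_text_ids)

    @property
    def n_seq_struct(self) -> int:
        return len(self.seq_struct_ids)


@dataclass(frozen=True)
class TokenizedInput:
    """Token ids with special-token bookkeeping for one modality."""

    token_ids: np.ndarray
    modality: str  # "sequence" | "text"
    bos_index: int | None
    eos_index: int
    pad_id: int = PAD_ID

    def __post_init__(self):
        object.__setattr__(self, "token_ids", np.asarray(self.token_ids, dtype=int))

    def __len__(self) -> int:
        return int(self.token_ids.shape[0])


# ---------------------------------------------------------------------------
# sequences


def normalize_sequence(raw: str, record_id: str = "?") -> str:
    """Uppercase and map non-standard residues (B, Z, U, O, J) to X."""
    seq = raw.upper().replace("-", "").replace("*", "")
    seq = "".join("X" if c in _NONSTANDARD_TO_X else c for c in seq)
    bad = set(seq) - set(SEQUENCE_ALPHABET)
    if bad:
        raise CorpusError(f"record {record_id!r}: unrecognised residue codes {sorted(bad)}")
    return seq


def read_fasta(path) -> list[ProteinRecord]:
    """Read a (possibly line-wrapped) multi-record FASTA into records.

    The header token before the first whitespace becomes the record id.
    Sequences are uppercased and non-standard residues mapped to X.
    """
    path = Path(path)
    text = path.read_text()
    # light structural validation: the first non-blank line must be a header
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise CorpusError(f"{path}:{lineno}: expected FASTA header line, got {line[:40]!r}")
            break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise CorpusError(f"{path}: record {rec.id!r} has an empty sequence body")
        records.append(ProteinRecord(id=rec.id, sequence=normalize_sequence(str(rec.seq), rec.id)))
    return records


def write_fasta(path, records: Sequence[ProteinRecord]) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# backbone structures (PDB)


def read_backbone(path, chain: str = "A") -> BackboneStructure:
    """Read N/CA/C coordinates for one chain of a PDB-format file.

    Residues are ordered by residue sequence number (insertion codes
    lexicographically after their base number); a residue missing any
    backbone atom is masked; altloc ambiguity resolves to the
    first-listed conformer.
    """
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise CorpusError(f"{path}: no model")
    model = st[0]
    ch = None
    for c in model:
        if c.name == chain:
            ch = c
            break
    if ch is None:
        raise CorpusError(f"{path}: chain {chain!r} not found")
    residues = [r for r in ch if r.het_flag == "A"]
    if not residues:
        raise CorpusError(f"{path}: chain {chain!r} has no ATOM records")
    residues.sort(key=lambda r: (r.seqid.num, r.seqid.icode or " "))
    n = len(residues)
    coords = np.zeros((n, 3, 3))
    mask = np.zeros(n, dtype=bool)
    numbers = []
    for i, res in enumerate(residues):
        numbers.append((res.seqid.num, res.seqid.icode.strip()))
        got = {}
        for atom in res:
            name = atom.name
            if name in BACKBONE_ATOMS and name not in got:  # first altloc wins
                got[name] = [atom.pos.x, atom.pos.y, atom.pos.z]
        if all(a in got for a in BACKBONE_ATOMS):
            coords[i] = [got[a] for a in BACKBONE_ATOMS]
            mask[i] = True
    return BackboneStructure(coords=coords, mask=mask, residue_numbers=tuple(numbers))


_AA1_TO_3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}


def write_backbone(path, structure: BackboneStructure, sequence: str | None = None, chain: str = "A") -> None:
    """Write a backbone-only PDB file (one chain, N/CA/C atoms)."""
    st = gemmi.Structure()
    st.name = "backbone"
    model = gemmi.Model("1")
    ch = gemmi.Chain(chain)
    for i in range(len(structure)):
        if not structure.mask[i]:
            continue
        res = gemmi.Residue()
        aa = sequence[i] if sequence is not None else "G"
        res.name = _AA1_TO_3.get(aa, "UNK")
        res.seqid = gemmi.SeqId(i + 1, " ")
        for j, name in enumerate(BACKBONE_ATOMS):
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element("N" if name == "N" else "C")
            x, y, z = structure.coords[i, j]
            atom.pos = gemmi.Position(float(x), float(y), float(z))
            atom.occ = 1.0
            res.add_atom(atom)
        ch.add_residue(res)
    model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def with_structure(record: ProteinRecord, structure: BackboneStructure) -> ProteinRecord:
    """Attach a backbone to a record; lengths must match exactly.

    Callers pairing a full sequence with a partially resolved structure
    must first crop the sequence to the resolved span; a length mismatch
    here is rejected with a diagnostic rather than silently aligned.
    """
    if len(structure) != len(record.sequence):
        raise CorpusError(
            f"record {record.id!r}: cannot pair sequence of length "
            f"{len(record.sequence)} with structure of length {len(structure)}"
        )
    return replace(record, structure=structure)


# ---------------------------------------------------------------------------
# filtering and pairing


def filter_by_length(records: Iterable[ProteinRecord], max_len: int = 300) -> list[ProteinRecord]:
    """Drop records whose sequence is strictly longer than ``max_len``.

    The default mirrors the pretraining corpus rule: proteins longer
    than 300 residues are excluded, 300 itself is kept.  Idempotent and
    order-preserving.
    """
    return [r for r in records if len(r.sequence) <= max_len]


def build_manifest(records: Sequence[ProteinRecord]) -> CorpusManifest:
    """Enumerate sequence-text and sequence-structure pairs in a corpus."""
    ids = [r.id for r in records]
    seen, dups = set(), []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise CorpusError(f"duplicate record ids: {sorted(set(dups))}")
    return CorpusManifest(
        seq_text_ids=tuple(r.id for r in records if r.text is not None),
        seq_struct_ids=tuple(r.id for r in records if r.structure is not None),
    )


def manifest_from_metadata(meta: pd.DataFrame) -> CorpusManifest:
    """Build a manifest from a metadata table (id, has_text, has_structure).

    Used for corpus-level accounting when the underlying files are not
    materialised, e.g. to check pair counts of a described corpus.
    """
    if meta["id"].duplicated().any():
        raise CorpusError(f"duplicate record ids: {sorted(meta.loc[meta['id'].duplicated(), 'id'])}")
    return CorpusManifest(
        seq_text_ids=tuple(meta.loc[meta["has_text"].astype(bool), "id"]),
        seq_struct_ids=tuple(meta.loc[meta["has_structure"].astype(bool), "id"]),
    )


# ---------------------------------------------------------------------------
# tokenization


def tokenize_sequence(sequence: str) -> TokenizedInput:
    """[BOS, residue ids..., EOS]; lowercase input is normalised first."""
    seq = normalize_sequence(sequence)
    ids = [BOS_ID] + [SEQ_TOKEN_TO_ID[c] for c in seq] + [EOS_ID]
    return TokenizedInput(token_ids=np.array(ids), modality="sequence", bos_index=0, eos_index=len(ids) - 1)


def detokenize_sequence(tok: TokenizedInput) -> str:
    ids = tok.token_ids
    return "".join(SEQ_ID_TO_TOKEN[int(i)] for i in ids if int(i) in SEQ_ID_TO_TOKEN)


@dataclass(frozen=True)
class TextVocab:
    """Corpus-built lowercase whitespace vocabulary with special tokens.

    Deliberately self-contained so desk-scale corpora need no external
    vocabulary; the tokenizer interface accepts any object with
    ``token_to_id``/``size`` so a pretrained subword tokenizer can be
    substituted at full scale.
    """

    token_to_id: dict

    @property
    def size(self) -> int:
        return 4 + len(self.token_to_id)

    def lookup(self, word: str) -> int:
        return self.token_to_id.get(word, UNK_ID)


def build_text_vocab(texts: Iterable[str]) -> TextVocab:
    words = sorted({w for t in texts for w in t.lower().split()})
    return TextVocab(token_to_id={w: i + 4 for i, w in enumerate(words)})


def tokenize_text(text: str, vocab: TextVocab) -> TokenizedInput:
    """Lowercased whitespace tokens mapped through the vocabulary, EOS last."""
    if not text or not text.strip():
        raise CorpusError("empty text")
    ids = [vocab.lookup(w) for w in text.lower().split()] + [EOS_ID]
    return TokenizedInput(token_ids=np.array(ids), modality="text", bos_index=None, eos_index=len(ids) - 1)


# ---------------------------------------------------------------------------
# corpus index files


def write_corpus_index(path, rows: Sequence[dict]) -> None:
    """Write the on-disk corpus index (id, fasta_path, pdb_path, chain, text)."""
    df = pd.DataFrame(rows, columns=["id", "fasta_path", "pdb_path", "chain", "text"])
    df.to_csv(path, sep="\t", index=False)


def load_corpus(index_path, class_labels: dict | None = None) -> list[ProteinRecord]:
    """Load records listed in a corpus index file.

    Each row names a FASTA file containing the record's sequence and,
    optionally, a PDB file (with chain) and a text description.
    """
    index_path = Path(index_path)
    df = pd.read_csv(index_path, sep="\t", dtype=str).fillna("")
    base = index_path.parent
    records = []
    for row in df.itertuples(index=False):
        fasta = base / row.fasta_path
        matches = [r for r in read_fasta(fasta) if r.id == row.id]
        if not matches:
            raise CorpusError(f"{fasta}: record {row.id!r} not found")
        rec = matches[0]
        if row.text:
            rec = replace(rec, text=row.text)
        if row.pdb_path:
            structure = read_backbone(base / row.pdb_path, chain=row.chain or "A")
            rec = with_structure(rec, structure)
        if class_labels and row.id in class_labels:
            rec = replace(rec, class_label=int(class_labels[row.id]))
        records.append(rec)
    return records
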
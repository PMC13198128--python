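"""Seeded tri-modal toy corpora with controlled cross-modal information.

Each generated record carries a latent class ``c`` and an instance code
``u`` (a short string of amino-acid letters).  The three modalities
share information by construction:

* the **sequence** contains a class-specific motif and the instance
  code flanked by ``X`` delimiters (X never occurs in the random
  background, so the code is locatable);
* the **text** contains a class keyword and the instance code spelled
  as per-character tokens (so unseen codes generalise);
* the **structure** is an idealised helix whose geometry (rise per
  residue) depends on the class only.

Hence sequence<->text share class- and instance-level information while
sequence<->structure share class-level information only: instance-level
retrieval is measurable for the text branch, class-level retrieval for
the structure branch, and structure<->text coupling can only arise
through the shared sequence anchor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus_io import (
    BackboneStructure,
    CorpusManifest,
    ProteinRecord,
    STANDARD_AAS,
    build_manifest,
)

__all__ = [
    "SyntheticSpec",
    "helix_backbone",
    "generate_corpus",
    "make_task_dataset",
    "make_pairing_dataset",
    "class_motifs",
    "TaskDataset",
    "TASK_IDS",
    "CLASS_KEYWORDS",
]

CLASS_KEYWORDS = (
    "kinase", "protease", "hydrolase", "transferase", "ligase", "isomerase",
    "oxidase", "reductase", "synthase", "phosphatase", "chaperone", "transporter",
)
_ADJECTIVES = ("putative", "conserved", "secreted", "membrane", "cytosolic", "thermostable")

TASK_IDS = ("binary_peptide", "regression_mic", "five_class_thermo", "pairwise_variant", "fitness")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic corpus generator.

    Helix geometry per class is a (rise A, turn deg, radius A) triple;
    the default grid varies the rise in 0.32 A increments, which keeps
    consecutive CA-CA distances inside the physical 2-5 A window while
    separating noiseless class geometries by >= 0.1 A.
    """

    n: int
    K: int = 8
    motif_len: int = 5
    id_code_len: int = 4
    structure_coverage: float = 0.5
    noise_sigma: float = 0.01
    background_length: tuple = (32, 32)  # fixed length: record length must not leak instance identity into structures
    helix_geometry: tuple = ()  # per-class (rise, turn_deg, radius); default grid if empty
    code_placement: str = "start"  # "start" | "random"
    motif_placement: str = "fixed"  # "fixed" (after the code block) | "random"
    seed: int = 0

    def __post_init__(self):
        if self.K < 2:
            raise ValueError("need at least two classes")
        if not (0.0 <= self.structure_coverage <= 1.0):
            raise ValueError("structure_coverage must be in [0, 1]")
        if not self.helix_geometry:
            grid = tuple((1.2 + 0.32 * c, 100.0, 2.3) for c in range(self.K))
            object.__setattr__(self, "helix_geometry", grid)
        if len(self.helix_geometry) != self.K:
            raise ValueError("helix_geometry must have one entry per class")
        if self.code_placement not in ("start", "random"):
            raise ValueError("code_placement must be 'start' or 'random'")
        if self.motif_placement not in ("fixed", "random"):
            raise ValueError("motif_placement must be 'fixed' or 'random'")
        for rise, turn, radius in self.helix_geometry:
            if rise <= 0 or turn <= 0 or radius <= 0:
                raise ValueError("helix geometry parameters must be positive")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def helix_backbone(
    L: int,
    rise: float,
    turn: float,
    radius: float,
    rng: np.random.Generator,
    noise_sigma: float = 0.0,
    random_pose: bool = True,
) -> BackboneStructure:
    """Idealised helical backbone of ``L`` residues.

    CA_i sits on a helix of the given rise (A/residue), turn (degrees
    per residue) and radius; N and C are placed at fixed offsets from
    CA in the local (tangent, radial) frame so the backbone frame is
    well defined.  Gaussian coordinate noise is added per atom, then a
    random global rigid pose is applied last.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if rise <= 0 or turn <= 0 or radius <= 0:
        raise ValueError("helix parameters must be positive")
    omega = math.radians(turn)
    i = np.arange(L)
    ca = np.stack([radius * np.cos(i * omega), radius * np.sin(i * omega), i * rise], axis=1)
    # local frame: unit tangent and inward radial direction
    tangent = np.stack([-radius * omega * np.sin(i * omega), radius * omega * np.cos(i * omega), np.full(L, rise)], axis=1)
    tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
    radial = np.stack([-np.cos(i * omega), -np.sin(i * omega), np.zeros(L)], axis=1)
    n_at = ca - 0.70 * tangent + 0.35 * radial
    c_at = ca + 0.70 * tangent + 0.35 * radial
    coords = np.stack([n_at, ca, c_at], axis=1)
    if noise_sigma > 0:
        coords = coords + rng.normal(0.0, noise_sigma, size=coords.shape)
    if random_pose:
        Q = _random_rotation(rng)
        t = rng.normal(0.0, 10.0, size=3)
        coords = coords @ Q.T + t
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # toy geometries may sit near the CA-CA bounds
        return BackboneStructure(coords=coords, mask=np.ones(L, dtype=bool))


def _distinct_motifs(rng: np.random.Generator, K: int, length: int, max_tries: int = 100):
    aas = list(STANDARD_AAS)
    for attempt in range(max_tries):
        motifs = ["".join(rng.choice(aas, size=length)) for _ in range(K)]
        if len(set(motifs)) == K:
            return motifs
        warnings.warn(f"motif collision on attempt {attempt + 1}; regenerating")
    raise RuntimeError("could not draw pairwise-distinct class motifs")


def _embed_spans(
    rng: np.random.Generator, background: list, spans: Sequence[str], max_tries: int = 200, lo_start: int = 0
):
    """Overwrite non-overlapping random spans of the background in place."""
    L = len(background)
    for _ in range(max_tries):
        starts = [int(rng.integers(lo_start, L - len(s) + 1)) for s in spans]
        intervals = sorted(zip(starts, [len(s) for s in spans]))
        if all(intervals[i][0] + intervals[i][1] <= intervals[i + 1][0] for i in range(len(intervals) - 1)):
            for start, span in zip(starts, spans):
                background[start : start + len(span)] = list(span)
            return starts
    raise RuntimeError("could not place non-overlapping spans; background too short")


def generate_corpus(spec: SyntheticSpec):
    """Generate records and their manifest.  Byte-identical under one seed."""
    rng = np.random.default_rng(spec.seed)
    aas = list(STANDARD_AAS)
    motifs = _distinct_motifs(rng, spec.K, spec.motif_len)
    n_struct = int(round(spec.structure_coverage * spec.n))
    struct_rows = set(rng.choice(spec.n, size=n_struct, replace=False).tolist()) if spec.n else set()

    codes: set = set()
    records = []
    for row in range(spec.n):
        c = int(rng.integers(spec.K))
        while True:
            code = "".join(rng.choice(aas, size=spec.id_code_len))
            if code not in codes:
                codes.add(code)
                break
        lo, hi = spec.background_length
        L = int(rng.integers(lo, hi + 1))
        background = list("".join(rng.choice(aas, size=L)))
        code_block = "X" + code + "X"
        if spec.code_placement == "start":
            # fixed-position code: the instance identity is position-wise
            # readable, so instance alignment generalises to unseen codes
            background[: len(code_block)] = list(code_block)
            if spec.motif_placement == "fixed":
                background[len(code_block) : len(code_block) + len(motifs[c])] = list(motifs[c])
            else:
                _embed_spans(rng, background, [motifs[c]], lo_start=len(code_block))
        else:
            _embed_spans(rng, background, [motifs[c], code_block])
        sequence = "".join(background)
        adj = _ADJECTIVES[int(rng.integers(len(_ADJECTIVES)))]
        kw = CLASS_KEYWORDS[c % len(CLASS_KEYWORDS)]
        text = f"{adj} {kw} protein accession " + " ".join(code.lower())
        structure = None
        if row in struct_rows:
            rise, turn, radius = spec.helix_geometry[c]
            structure = helix_backbone(len(sequence), rise, turn, radius, rng, noise_sigma=spec.noise_sigma)
        records.append(
            ProteinRecord(
                id=f"SYN{row:05d}", sequence=sequence, structure=structure, text=text, class_label=c
            )
        )
    return records, build_manifest(records)


# ---------------------------------------------------------------------------
# downstream task datasets


@dataclass(frozen=True)
class TaskDataset:
    """A labelled train/test split for one synthetic downstream task.

    ``train``/``test`` are lists of examples; the example layout is
    task-specific (see :func:`make_task_dataset`).
    """

    task: str
    train: tuple
    test: tuple
    seed: int


def _split(rng: np.random.Generator, examples: list, frac: float = 0.8):
    order = rng.permutation(len(examples))
    n_train = int(math.floor(frac * len(examples)))
    train = tuple(examples[i] for i in order[:n_train])
    test = tuple(examples[i] for i in order[n_train:])
    return train, test


def _mutate(rng: np.random.Generator, sequence: str, position: int) -> str:
    aas = [a for a in STANDARD_AAS if a != sequence[position]]
    return sequence[:position] + str(rng.choice(aas)) + sequence[position + 1 :]


def make_task_dataset(
    corpus: Sequence[ProteinRecord],
    task: str,
    rng: np.random.Generator,
    split_frac: float = 0.8,
    regression_noise: float = 0.1,
    variant_span: int | None = None,
) -> TaskDataset:
    """Derive a labelled task dataset from a synthetic corpus.

    Labels derive from the latent class: ``binary_peptide`` uses class
    parity; ``regression_mic`` targets an affine function of class plus
    Gaussian noise; ``five_class_thermo`` maps class mod 5 onto the
    five thermostability bins (structure records only);
    ``pairwise_variant`` pairs each wild type with a mutant in which
    either the motif span (pathogenic) or an equal-length background
    span (benign) is substituted (``variant_span`` overrides the span
    length; 1 gives single-site mutants);
    ``fitness`` scores fresh sequences by their motif-match count.
    Examples are ``(record, label)`` except ``pairwise_variant``
    (``(record, mutant_sequence, label)``).  Split is 80:20 by default
    (train size = floor(0.8 n)).
    """
    if task not in TASK_IDS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASK_IDS}")
    seed_used = int(rng.integers(2**31 - 1))
    local = np.random.default_rng(seed_used)
    motif_map = class_motifs(corpus)

    if task == "binary_peptide":
        examples = [(r, int(r.class_label % 2)) for r in corpus]
    elif task == "regression_mic":
        examples = [
            (r, 0.5 * r.class_label + 1.0 + (local.normal(0.0, regression_noise) if regression_noise > 0 else 0.0))
            for r in corpus
        ]
    elif task == "five_class_thermo":
        examples = [(r, int(r.class_label % 5)) for r in corpus if r.structure is not None]
    elif task == "pairwise_variant":
        # pathogenic mutants scramble the motif span, benign mutants an
        # equal-length background span, so both labels perturb the
        # sequence equally and only the motif's fate separates them
        examples = []
        span = variant_span
        for r in corpus:
            motif = motif_map[int(r.class_label)]
            start = r.sequence.find(motif)
            n_mut = len(motif) if span is None else span
            hit_motif = bool(local.integers(2)) and start >= 0
            if hit_motif:
                positions = list(range(start, start + n_mut))
            else:
                protected = set(range(start, start + len(motif))) | {
                    i for i, ch in enumerate(r.sequence) if ch == "X"
                }
                cands = [
                    i
                    for i in range(len(r.sequence) - n_mut + 1)
                    if not any(j in protected for j in range(i, i + n_mut))
                ]
                first = int(local.choice(cands))
                positions = list(range(first, first + n_mut))
            mutant = r.sequence
            for pos in positions:
                mutant = _mutate(local, mutant, pos)
            examples.append((r, mutant, int(hit_motif)))
    else:  # fitness
        examples = []
        aas = list(STANDARD_AAS)
        for r in corpus:
            motif = motif_map[int(r.class_label)]
            m = int(local.integers(0, 5))
            lo = max(len(r.sequence), (len(motif) + 1) * max(m, 1) + 10)
            background = list("".join(local.choice(aas, size=lo)))
            if m:
                _embed_spans(local, background, [motif] * m)
            examples.append(
                (ProteinRecord(id=f"{r.id}_fit", sequence="".join(background), class_label=r.class_label), float(m))
            )

    train, test = _split(local, examples, split_frac)
    return TaskDataset(task=task, train=train, test=test, seed=seed_used)


def _kmers(sequence: str, k: int):
    return {sequence[i : i + k] for i in range(len(sequence) - k + 1)}


def class_motifs(corpus: Sequence[ProteinRecord], motif_len: int = 5) -> dict:
    """Recover each class's motif as the unique k-mer shared by its records.

    The background is random and the instance codes are record-specific,
    so the class motif is (with overwhelming probability) the only
    ``motif_len``-mer common to all same-class sequences.  Ties are
    broken deterministically by sorted order.
    """
    by_class: dict = {}
    for r in corpus:
        if r.class_label is None:
            raise ValueError("class_motifs requires synthetic records with class labels")
        by_class.setdefault(int(r.class_label), []).append(r.sequence)
    motifs = {}
    for c, seqs in sorted(by_class.items()):
        common = _kmers(seqs[0], motif_len)
        for s in seqs[1:]:
            common &= _kmers(s, motif_len)
        common = {m for m in common if "X" not in m}
        if not common:
            raise ValueError(f"no shared {motif_len}-mer found for class {c}")
        motifs[c] = sorted(common)[0]
    return motifs


def make_pairing_dataset(corpus: Sequence[ProteinRecord], rng: np.random.Generator, set_size: int = 2, split_frac: float = 0.8):
    """Class-match pairing task (the anti-CRISPR-style set classifier).

    Each example is ``(records_tuple, label)`` where the tuple holds the
    query protein first and ``set_size - 1`` partner proteins; the label
    is 1 iff the first partner shares the query's class.
    """
    by_class: dict = {}
    for r in corpus:
        by_class.setdefault(int(r.class_label), []).append(r)
    classes = sorted(by_class)
    examples = []
    for r in corpus:
        same = bool(rng.integers(2))
        if same:
            partner = by_class[int(r.class_label)][int(rng.integers(len(by_class[int(r.class_label)])))]
        else:
            other = classes[int(rng.integers(len(classes)))]
            while other == int(r.class_label):
                other = classes[int(rng.integers(len(classes)))]
            partner = by_class[other][int(rng.integers(len(by_class[other])))]
        extras = [corpus[int(rng.integers(len(corpus)))] for _ in range(max(set_size - 2, 0))]
        examples.append(((r, partner, *extras), int(partner.class_label == r.class_label)))
    seed_used = int(rng.integers(2**31 - 1))
    local = np.random.default_rng(seed_used)
    train, test = _split(local, examples, split_frac)
    return TaskDataset(task="pairing", train=train, test=test, seed=seed_used)
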
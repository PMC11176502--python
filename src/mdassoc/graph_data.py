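"""Data containers, file IO and the synthetic benchmark generator.

Microbe-drug associations live in a binary matrix ``MD`` with microbes on
rows and drugs on columns; an entry is 1 exactly when the pair is a
curated association.  Microbe sequences come from FASTA; drug structural
similarity is consumed as a precomputed labeled square matrix (the
chemical-structure search that produces it is an external service, not
reimplemented here).

The synthetic generator plants a shared block (community) structure:
matched microbe/drug blocks are densely associated, microbes in the same
block descend from one ancestral sequence, and drugs in the same block
have high structural similarity.  Block membership therefore drives both
the association labels and every similarity source the pipeline fuses,
which is the statistical situation the method assumes.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

__all__ = [
    "AssociationMatrix",
    "SequenceRecord",
    "SyntheticConfig",
    "SyntheticDataset",
    "load_association_table",
    "write_association",
    "load_sequences",
    "write_sequences",
    "load_matrix",
    "write_matrix",
    "generate_synthetic",
]

NUCLEOTIDES = "ACGT"
_ALPHABET = frozenset("ACGTN")


@dataclass
class AssociationMatrix:
    """Binary microbe x drug association matrix with aligned id lists."""

    values: np.ndarray
    microbe_ids: list[str]
    drug_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("association matrix must be 2-D")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("association matrix entries must be 0 or 1")
        self.values = self.values.astype(np.int8)
        if self.values.shape != (len(self.microbe_ids), len(self.drug_ids)):
            raise ValueError("matrix shape does not match id lists")
        for ids, what in ((self.microbe_ids, "microbe"), (self.drug_ids, "drug")):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {what} ids")

    @property
    def n_microbes(self) -> int:
        return len(self.microbe_ids)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_associations(self) -> int:
        return int(self.values.sum())

    def pairs(self) -> list[tuple[int, int]]:
        """Index pairs of the known associations, row-major order."""
        rows, cols = np.nonzero(self.values)
        return list(zip(rows.tolist(), cols.tolist()))


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")
        seq = self.sequence.upper()
        bad = set(seq) - _ALPHABET
        if bad:
            raise ValueError(f"record {self.id!r} has non-nucleotide symbols {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the planted-block benchmark generator."""

    n_microbes: int = 120
    n_drugs: int = 180
    n_blocks: int = 4
    within_block_density: float = 0.3
    background_density: float = 0.02
    sequence_length: int = 200
    mutation_rate: float = 0.05
    similarity_noise: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if min(self.n_microbes, self.n_drugs, self.n_blocks, self.sequence_length) < 1:
            raise ValueError("counts must be positive")
        if self.n_blocks > min(self.n_microbes, self.n_drugs):
            raise ValueError("n_blocks exceeds the smaller entity count")
        for name in ("within_block_density", "background_density", "mutation_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        if self.within_block_density <= self.background_density:
            raise ValueError("within_block_density must exceed background_density")


@dataclass
class SyntheticDataset:
    associations: AssociationMatrix
    sequences: list[SequenceRecord]
    drug_similarity: "object"  # similarity.SimilarityMatrix; avoids an import cycle
    microbe_blocks: np.ndarray = field(default_factory=lambda: np.array([]))
    drug_blocks: np.ndarray = field(default_factory=lambda: np.array([]))


# ---------------------------------------------------------------------------
# association edge lists


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


_HEADER_TOKENS = {"microbe", "microbe_id", "drug", "drug_id", "source", "target", "label"}


def load_association_table(path) -> AssociationMatrix:
    """Read a microbe,drug edge list (TSV/CSV, optional header) into ``MD``.

    Ids keep first-appearance order; duplicate edges collapse to a single
    1-entry.  Malformed rows raise with their line number.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    delim = _sniff_delimiter(text[:4096])
    rows = list(csv.reader(io.StringIO(text), delimiter=delim))
    rows = [(lineno, row) for lineno, row in enumerate(rows, start=1) if any(f.strip() for f in row)]
    if rows and rows[0][1][0].strip().lower() in _HEADER_TOKENS:
        rows = rows[1:]
    if not rows:
        raise ValueError(f"{path}: no association rows")

    microbe_ids: list[str] = []
    drug_ids: list[str] = []
    m_index: dict[str, int] = {}
    d_index: dict[str, int] = {}
    edges: set[tuple[int, int]] = set()
    for lineno, row in rows:
        fields = [f.strip() for f in row]
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise ValueError(f"{path}:{lineno}: expected at least two non-empty columns")
        m, d = fields[0], fields[1]
        if m not in m_index:
            m_index[m] = len(microbe_ids)
            microbe_ids.append(m)
        if d not in d_index:
            d_index[d] = len(drug_ids)
            drug_ids.append(d)
        edges.add((m_index[m], d_index[d]))
    values = np.zeros((len(microbe_ids), len(drug_ids)), dtype=np.int8)
    for i, j in edges:
        values[i, j] = 1
    return AssociationMatrix(values, microbe_ids, drug_ids)


def write_association(assoc: AssociationMatrix, path) -> None:
    """Write the 1-entries of ``MD`` as a two-column TSV edge list."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["microbe", "drug"])
        for i, j in assoc.pairs():
            writer.writerow([assoc.microbe_ids[i], assoc.drug_ids[j]])


# ---------------------------------------------------------------------------
# sequences


def load_sequences(path) -> list[SequenceRecord]:
    """Read FASTA; sequences are uppercased, duplicate ids rejected."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        if len(rec.seq) == 0:
            raise ValueError(f"{path}: record {rec.id!r} has no sequence body")
        records.append(SequenceRecord(rec.id, str(rec.seq)))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_sequences(records, path) -> None:
    bio = [_BioRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# labeled square matrices


def load_matrix(path, *, cutoff: float = 0.01, kind: str = "structure"):
    """Read a labeled square similarity matrix from TSV.

    Entries strictly below ``cutoff`` (default 0.01, the usual reporting
    cut-off of chemical-structure search servers) are zeroed.  The matrix
    must be square, numeric, non-negative and symmetric within 1e-8.
    """
    import pandas as pd

    from .similarity import SimilarityMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: matrix is {df.shape[0]}x{df.shape[1]}, not square")
    try:
        values = df.to_numpy(dtype=np.float64)
    except (TypeError, ValueError) as err:
        raise ValueError(f"{path}: non-numeric cell: {err}") from None
    if np.isnan(values).any():
        raise ValueError(f"{path}: NaN entries are not allowed")
    if (values < 0).any():
        raise ValueError(f"{path}: negative entries are not allowed")
    if np.abs(values - values.T).max() > 1e-8:
        raise ValueError(f"{path}: matrix is not symmetric within 1e-8")
    values[values < cutoff] = 0.0
    return SimilarityMatrix(values, [str(x) for x in df.index], kind=kind)


def write_matrix(matrix, path) -> None:
    import pandas as pd

    pd.DataFrame(matrix.values, index=matrix.ids, columns=matrix.ids).to_csv(
        path, sep="\t", float_format="%.10g"
    )


# ---------------------------------------------------------------------------
# synthetic benchmark


def _block_assignments(n: int, n_blocks: int) -> np.ndarray:
    return np.sort(np.arange(n) % n_blocks)


def generate_synthetic(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a planted-block microbe-drug benchmark.

    Associations are Bernoulli(within_block_density) for same-block
    pairs and Bernoulli(background_density) otherwise.  Each microbe
    block has one random ancestral sequence; members carry iid per-base
    mutations at ``mutation_rate`` (a mutated base is redrawn from the
    other three).  Drug similarity is 1 for same-block pairs and 0
    otherwise, plus Gaussian noise (sd ``similarity_noise``), clipped to
    [0,1], symmetrized by averaging, unit diagonal.  Bit-reproducible
    from ``seed``.
    """
    from .similarity import SimilarityMatrix

    rng = np.random.default_rng(config.seed)
    mb = _block_assignments(config.n_microbes, config.n_blocks)
    db = _block_assignments(config.n_drugs, config.n_blocks)

    same_block = mb[:, None] == db[None, :]
    prob = np.where(same_block, config.within_block_density, config.background_density)
    values = (rng.random(prob.shape) < prob).astype(np.int8)

    width = max(3, len(str(config.n_microbes)))
    microbe_ids = [f"m{i:0{width}d}" for i in range(config.n_microbes)]
    dwidth = max(3, len(str(config.n_drugs)))
    drug_ids = [f"d{j:0{dwidth}d}" for j in range(config.n_drugs)]
    assoc = AssociationMatrix(values, microbe_ids, drug_ids)

    base = np.array(list(NUCLEOTIDES))
    ancestors = rng.integers(0, 4, size=(config.n_blocks, config.sequence_length))
    sequences = []
    for i, block in enumerate(mb):
        seq = ancestors[block].copy()
        mutate = rng.random(config.sequence_length) < config.mutation_rate
        # redraw uniformly over the 3 other bases
        shifts = rng.integers(1, 4, size=config.sequence_length)
        seq[mutate] = (seq[mutate] + shifts[mutate]) % 4
        sequences.append(SequenceRecord(microbe_ids[i], "".join(base[seq])))

    drug_same = (db[:, None] == db[None, :]).astype(np.float64)
    noise = rng.normal(0.0, config.similarity_noise, size=drug_same.shape)
    dss = np.clip(drug_same + noise, 0.0, 1.0)
    dss = (dss + dss.T) / 2.0
    np.fill_diagonal(dss, 1.0)
    drug_similarity = SimilarityMatrix(dss, drug_ids, kind="structure")

    return SyntheticDataset(assoc, sequences, drug_similarity, mb, db)
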
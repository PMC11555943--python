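"""Domain types and file IO for drug / side-effect frequency corpora.

The corpus couples three entity tables (drugs with SMILES and free-text
descriptions, side effects with ontology ids and word vectors, observed
frequency triplets) with the induced drug-by-side-effect frequency matrix
``A`` whose entries are 0 (no known association) or an ordinal class 1-5
(very rare ... very frequent).

All tables are plain TSV; matrices carry explicit id indexes so nothing
depends on row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DrugRecord",
    "SideEffectRecord",
    "FrequencyCorpus",
    "FrequencyMatrix",
    "PairSample",
    "CorpusError",
    "load_frequency_triplets",
    "load_drug_table",
    "load_ontology",
    "load_word_vectors",
    "build_frequency_matrix",
    "sample_negatives",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "write_corpus",
    "load_corpus",
]

FREQUENCY_CLASSES = (1, 2, 3, 4, 5)


class CorpusError(ValueError):
    """Raised on malformed corpus files or invariant violations."""


@dataclass
class DrugRecord:
    drug_id: str
    smiles: str
    description: str = ""


@dataclass
class SideEffectRecord:
    se_id: str
    term: str
    dotted_ids: list[str] = field(default_factory=list)
    word_vector: np.ndarray | None = None
    description: str = ""


@dataclass
class FrequencyCorpus:
    drugs: list[DrugRecord]
    side_effects: list[SideEffectRecord]
    triplets: list[tuple[str, str, int]]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        drug_ids = [d.drug_id for d in self.drugs]
        se_ids = [s.se_id for s in self.side_effects]
        if len(set(drug_ids)) != len(drug_ids):
            raise CorpusError("duplicate drug_id in corpus")
        if len(set(se_ids)) != len(se_ids):
            raise CorpusError("duplicate se_id in corpus")
        dset, sset = set(drug_ids), set(se_ids)
        seen: set[tuple[str, str]] = set()
        for d, s, y in self.triplets:
            if (d, s) in seen:
                raise CorpusError(f"duplicate triplet for pair ({d}, {s})")
            seen.add((d, s))
            if d not in dset:
                raise CorpusError(f"triplet references unknown drug_id {d!r}")
            if s not in sset:
                raise CorpusError(f"triplet references unknown se_id {s!r}")
            if y not in FREQUENCY_CLASSES:
                raise CorpusError(f"frequency {y!r} outside 1..5 for pair ({d}, {s})")

    @property
    def drug_ids(self) -> list[str]:
        return [d.drug_id for d in self.drugs]

    @property
    def se_ids(self) -> list[str]:
        return [s.se_id for s in self.side_effects]


@dataclass
class FrequencyMatrix:
    values: np.ndarray  # int matrix, entries in {0..5}
    row_ids: list[str]
    col_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise CorpusError("frequency matrix shape does not match id lists")
        if not np.isin(self.values, (0,) + FREQUENCY_CLASSES).all():
            raise CorpusError("frequency matrix entries must lie in {0,...,5}")
        self.row_index = {r: i for i, r in enumerate(self.row_ids)}
        self.col_index = {c: j for j, c in enumerate(self.col_ids)}

    def positives(self) -> list[tuple[str, str, int]]:
        ii, jj = np.nonzero(self.values)
        return [(self.row_ids[i], self.col_ids[j], int(self.values[i, j])) for i, j in zip(ii, jj)]


@dataclass
class PairSample:
    drug_id: str
    se_id: str
    k_hat: int  # association label, 0 or 1
    y_hat: int | None = None  # frequency class, present iff k_hat == 1

    def __post_init__(self) -> None:
        if self.k_hat not in (0, 1):
            raise CorpusError("k_hat must be 0 or 1")
        if (self.k_hat == 1) != (self.y_hat is not None):
            raise CorpusError("y_hat must be present exactly for positive samples")
        if self.y_hat is not None and self.y_hat not in FREQUENCY_CLASSES:
            raise CorpusError("y_hat outside 1..5")


# ---------------------------------------------------------------------- IO
def load_frequency_triplets(path: str | Path) -> list[tuple[str, str, int]]:
    """Read (drug_id, se_id, frequency) triplets from a 3-column TSV."""
    triplets: list[tuple[str, str, int]] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if lineno == 1 and line.split("\t")[:2] == ["drug_id", "se_id"]:
                continue  # optional header
            parts = line.split("\t")
            if len(parts) != 3:
                raise CorpusError(f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}")
            d, s, raw = parts
            try:
                y = int(raw)
            except ValueError:
                raise CorpusError(f"{path}:{lineno}: frequency {raw!r} is not an integer") from None
            if y not in FREQUENCY_CLASSES:
                raise CorpusError(f"{path}:{lineno}: frequency {y} outside 1..5")
            if (d, s) in seen:
                raise CorpusError(f"{path}:{lineno}: duplicate pair ({d}, {s})")
            seen.add((d, s))
            triplets.append((d, s, y))
    return triplets


def load_drug_table(path: str | Path) -> list[DrugRecord]:
    """Read drug_id<TAB>smiles<TAB>description rows (description optional)."""
    records: list[DrugRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if lineno == 1 and line.split("\t")[0] == "drug_id":
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise CorpusError(f"{path}:{lineno}: expected at least drug_id and smiles")
            records.append(DrugRecord(parts[0], parts[1], parts[2] if len(parts) > 2 else ""))
    return records


def _validate_dotted_id(dotted: str, where: str) -> str:
    segments = dotted.split(".")
    if not 1 <= len(segments) <= 4:
        raise CorpusError(f"{where}: dotted id {dotted!r} must have 1-4 segments")
    for seg in segments:
        if not seg.isdigit():
            raise CorpusError(f"{where}: non-numeric segment {seg!r} in dotted id {dotted!r}")
    return dotted


def load_ontology(path: str | Path) -> dict[str, list[str]]:
    """Read term<TAB>dotted_id rows into a term -> dotted-id list map.

    A term appearing on several rows belongs to several ontology nodes
    (DAG membership); segment counts above 4 are rejected.
    """
    term_map: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if lineno == 1 and line.split("\t")[0] == "term":
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise CorpusError(f"{path}:{lineno}: expected term<TAB>dotted_id")
            term, dotted = parts
            _validate_dotted_id(dotted, f"{path}:{lineno}")
            term_map.setdefault(term, []).append(dotted)
    return term_map


def load_word_vectors(path: str | Path) -> dict[str, np.ndarray]:
    """Read term + f floats per row; all rows must share one dimension."""
    vectors: dict[str, np.ndarray] = {}
    dim: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0] == "term":
                continue
            try:
                vec = np.array([float(x) for x in parts[1:]])
            except ValueError:
                raise CorpusError(f"{path}:{lineno}: non-numeric vector entry") from None
            if dim is None:
                dim = vec.size
            elif vec.size != dim:
                raise CorpusError(f"{path}:{lineno}: vector length {vec.size} != {dim}")
            vectors[parts[0]] = vec
    return vectors


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read an id-indexed matrix TSV (header row of column ids, first column row ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns]


def write_matrix_tsv(path: str | Path, values: np.ndarray, row_ids: list[str], col_ids: list[str]) -> None:
    df = pd.DataFrame(values, index=row_ids, columns=col_ids)
    # fixed float format keeps reruns byte-identical
    df.to_csv(path, sep="\t", float_format="%.10g")


# ----------------------------------------------------------- constructions
def build_frequency_matrix(corpus: FrequencyCorpus) -> FrequencyMatrix:
    """Assemble the n x m matrix A with A[i,j] = y for observed pairs, else 0."""
    n, m = len(corpus.drugs), len(corpus.side_effects)
    values = np.zeros((n, m), dtype=int)
    ridx = {d: i for i, d in enumerate(corpus.drug_ids)}
    cidx = {s: j for j, s in enumerate(corpus.se_ids)}
    for d, s, y in corpus.triplets:
        values[ridx[d], cidx[s]] = y
    return FrequencyMatrix(values, list(corpus.drug_ids), list(corpus.se_ids))


def sample_negatives(matrix: FrequencyMatrix, seed: int | np.random.Generator) -> list[PairSample]:
    """Draw |positives| unobserved cells uniformly without replacement.

    Mirrors the benchmark protocol of balancing every known association
    with one randomly chosen unrelated pair.  Deterministic for a fixed
    seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    zi, zj = np.nonzero(matrix.values == 0)
    n_pos = int((matrix.values > 0).sum())
    if n_pos == 0:
        raise CorpusError("matrix has no positive cells to balance")
    if zi.size < n_pos:
        raise CorpusError(f"only {zi.size} zero cells available for {n_pos} negatives")
    chosen = rng.choice(zi.size, size=n_pos, replace=False)
    return [PairSample(matrix.row_ids[zi[c]], matrix.col_ids[zj[c]], k_hat=0) for c in sorted(chosen)]


def positive_samples(matrix: FrequencyMatrix) -> list[PairSample]:
    return [PairSample(d, s, k_hat=1, y_hat=y) for d, s, y in matrix.positives()]


# -------------------------------------------------------------- round trip
def write_corpus(corpus: FrequencyCorpus, outdir: str | Path) -> None:
    """Write triplets.tsv, smiles.tsv, ontology.tsv, wordvec.tsv, texts.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "triplets.tsv", "w") as fh:
        fh.write("drug_id\tse_id\tfrequency\n")
        for d, s, y in corpus.triplets:
            fh.write(f"{d}\t{s}\t{y}\n")
    with open(outdir / "smiles.tsv", "w") as fh:
        fh.write("drug_id\tsmiles\tdescription\n")
        for d in corpus.drugs:
            fh.write(f"{d.drug_id}\t{d.smiles}\t{d.description}\n")
    with open(outdir / "ontology.tsv", "w") as fh:
        fh.write("term\tdotted_id\n")
        for s in corpus.side_effects:
            for dotted in s.dotted_ids:
                fh.write(f"{s.term}\t{dotted}\n")
    with open(outdir / "wordvec.tsv", "w") as fh:
        for s in corpus.side_effects:
            if s.word_vector is not None:
                vals = "\t".join(f"{x:.10g}" for x in s.word_vector)
                fh.write(f"{s.se_id}\t{vals}\n")
    with open(outdir / "texts.tsv", "w") as fh:
        fh.write("se_id\tterm\tdescription\n")
        for s in corpus.side_effects:
            fh.write(f"{s.se_id}\t{s.term}\t{s.description}\n")


def load_corpus(indir: str | Path) -> FrequencyCorpus:
    """Inverse of :func:`write_corpus`."""
    indir = Path(indir)
    drugs = load_drug_table(indir / "smiles.tsv")
    term_map = load_ontology(indir / "ontology.tsv") if (indir / "ontology.tsv").exists() else {}
    vectors = load_word_vectors(indir / "wordvec.tsv") if (indir / "wordvec.tsv").exists() else {}
    side_effects: list[SideEffectRecord] = []
    with open(indir / "texts.tsv") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or (lineno == 1 and line.startswith("se_id\t")):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise CorpusError(f"texts.tsv:{lineno}: expected se_id and term")
            se_id, term = parts[0], parts[1]
            desc = parts[2] if len(parts) > 2 else ""
            side_effects.append(
                SideEffectRecord(
                    se_id,
                    term,
                    dotted_ids=list(term_map.get(term, [])),
                    word_vector=vectors.get(se_id),
                    description=desc,
                )
            )
    triplets = load_frequency_triplets(indir / "triplets.tsv")
    return FrequencyCorpus(drugs, side_effects, triplets)
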
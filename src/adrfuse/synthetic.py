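"""Synthetic corpus generation with plantable latent structure.

A complete, self-consistent study corpus is generated from a low-rank
latent model: drug factors U (n x r) and side-effect factors V (m x r) are
standard normal, the raw affinity is U V^T plus Gaussian noise, the top
``sparsity`` fraction of cells become observed pairs, and observed values
are quantized into the five frequency classes by within-observed quantiles
(near-equal class counts by default; an optional ``skew`` parameter tilts
the class mass toward the middle classes the way real pharmacovigilance
data is imbalanced).

Every other input modality is derived from the same latent factors so that
each encoder has recoverable signal: chemical similarity is the cosine of
drug factors mapped to [0, 1]; the binary drug-disease matrix thresholds
affinities to disease prototypes; descriptions are built from latent-topic
word templates (entities close in latent space share vocabulary); word
vectors are noisy linear images of the side-effect factors.  Molecules are
drawn from a bundled list of drug-like SMILES with seeded substituent
edits, every output re-checked by the parser.

The latent factors are retained on the returned object to support
parameter-recovery assertions in tests.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus import (
    DrugRecord,
    FrequencyCorpus,
    SideEffectRecord,
    write_corpus,
    write_matrix_tsv,
)
from .molecule import InvalidMoleculeError, smiles_to_graph
from .similarity import SimilarityMatrix

__all__ = [
    "SyntheticSpec",
    "SyntheticCorpus",
    "BASE_SMILES",
    "generate_ontology",
    "generate_molecules",
    "generate_frequency_matrix",
    "generate_texts_and_attributes",
    "generate_corpus",
    "write_corpus_dir",
]

# Drug-like molecules spanning common pharmacophores (analgesics, amines,
# amino acids, heterocycles, beta-blockers, antibiotics, nucleobases).
BASE_SMILES: tuple[str, ...] = (
    "CC(=O)OC1=CC=CC=C1C(=O)O",          # aspirin
    "CC(=O)NC1=CC=C(C=C1)O",             # paracetamol
    "CC(C)CC1=CC=C(C=C1)C(C)C(=O)O",     # ibuprofen
    "CN1C=NC2=C1C(=O)N(C(=O)N2C)C",      # caffeine
    "Cn1c(=O)c2[nH]cnc2n(C)c1=O",        # theophylline
    "CN1CCCC1C2=CN=CC=C2",               # nicotine
    "COC1=CC2=CC(=CC=C2C=C1)C(C)C(=O)O", # naproxen
    "CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O",  # warfarin
    "CN1C(=O)CN=C(c2ccccc2)c2cc(Cl)ccc21",    # diazepam
    "CN(C)C(=N)NC(=N)N",                 # metformin
    "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1",    # atenolol
    "CC(C)NCC(O)COc1cccc2ccccc12",       # propranolol
    "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1",     # salbutamol
    "CC1(C)SC2C(NC(=O)Cc3ccccc3)C(=O)N2C1C(=O)O",          # penicillin G
    "CC1(C)SC2C(NC(=O)C(N)c3ccc(O)cc3)C(=O)N2C1C(=O)O",    # amoxicillin
    "Nc1ccc(S(N)(=O)=O)cc1",             # sulfanilamide
    "CCN(CC)CCCC(C)Nc1ccnc2cc(Cl)ccc12", # chloroquine
    "NCCc1ccc(O)c(O)c1",                 # dopamine
    "NCCc1c[nH]c2ccc(O)cc12",            # serotonin
    "NCCc1c[nH]cn1",                     # histamine
    "CNCC(O)c1ccc(O)c(O)c1",             # adrenaline
    "CC(=O)NCCc1c[nH]c2ccc(OC)cc12",     # melatonin
    "NC(Cc1c[nH]c2ccccc12)C(=O)O",       # tryptophan
    "NC(Cc1ccc(O)cc1)C(=O)O",            # tyrosine
    "NC(Cc1ccccc1)C(=O)O",               # phenylalanine
    "CC(C)CC(N)C(=O)O",                  # leucine
    "CC(C)C(N)C(=O)O",                   # valine
    "CC(N)C(=O)O",                       # alanine
    "OCC(N)C(=O)O",                      # serine
    "NC(CS)C(=O)O",                      # cysteine
    "CSCCC(N)C(=O)O",                    # methionine
    "NCCCCC(N)C(=O)O",                   # lysine
    "NC(=O)CCC(N)C(=O)O",                # glutamine
    "OC(=O)CC(O)(CC(=O)O)C(=O)O",        # citric acid
    "CC(O)C(=O)O",                       # lactic acid
    "CC(=O)C(=O)O",                      # pyruvic acid
    "OC(=O)CCC(=O)O",                    # succinic acid
    "OC(=O)/C=C/C(=O)O",                 # fumaric acid
    "OC(=O)c1ccccc1",                    # benzoic acid
    "OC(=O)c1ccccc1O",                   # salicylic acid
    "Oc1ccccc1",                         # phenol
    "Nc1ccccc1",                         # aniline
    "Cc1ccccc1",                         # toluene
    "OCC1OC(O)C(O)C(O)C1O",              # glucopyranose
    "OCC(O)CO",                          # glycerol
    "O=c1cc[nH]c(=O)[nH]1",              # uracil
    "Cc1c[nH]c(=O)[nH]c1=O",             # thymine
    "Nc1cc[nH]c(=O)n1",                  # cytosine
    "Nc1ncnc2[nH]cnc12",                 # adenine
    "Nc1nc2[nH]cnc2c(=O)[nH]1",          # guanine
    "c1c[nH]cn1",                        # imidazole
    "c1ccncc1",                          # pyridine
    "c1ccoc1",                           # furan
    "c1ccsc1",                           # thiophene
    "c1ccc2[nH]ccc2c1",                  # indole
    "c1ccc2ccccc2c1",                    # naphthalene
)

_EDIT_SUFFIXES = ("", "C", "CC", "O", "N", "Cl", "F", "CO", "C(C)C")

_TOPIC_WORDS = [
    ["receptor", "binding", "affinity", "agonist", "antagonist"],
    ["hepatic", "metabolism", "cytochrome", "clearance", "oxidation"],
    ["renal", "excretion", "tubular", "filtration", "urinary"],
    ["cardiac", "arrhythmia", "conduction", "ventricular", "rhythm"],
    ["neural", "synaptic", "transmission", "cortical", "signaling"],
    ["immune", "inflammatory", "cytokine", "histocompatibility", "response"],
    ["gastric", "mucosal", "absorption", "intestinal", "motility"],
    ["vascular", "endothelial", "pressure", "perfusion", "tone"],
    ["metabolic", "glycemic", "insulin", "lipid", "homeostasis"],
    ["respiratory", "bronchial", "airway", "pulmonary", "ventilation"],
    ["dermal", "cutaneous", "rash", "photosensitivity", "eruption"],
    ["hematologic", "platelet", "coagulation", "erythrocyte", "marrow"],
]


@dataclass
class SyntheticSpec:
    n_drugs: int = 100
    n_side_effects: int = 120
    latent_rank: int = 8
    sparsity: float = 0.1
    noise_sd: float = 0.3
    branching: tuple[int, ...] = (4, 4, 4, 4)
    # disease panel sized like real toxicogenomics resources: ~9 per drug
    n_diseases: int = 900
    word_dim: int = 32
    skew: float = 0.0  # 0 = balanced classes; >0 tilts mass to classes 3-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_rank < 1:
            raise ValueError("latent rank must be >= 1")
        if not 0.0 < self.sparsity < 1.0:
            raise ValueError("sparsity must lie in (0, 1)")
        if len(self.branching) > 4 or any(b < 1 for b in self.branching):
            raise ValueError("branching must give >= 1 children on at most 4 levels")

    def to_json(self) -> str:
        d = self.__dict__.copy()
        d["branching"] = list(self.branching)
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class SyntheticCorpus:
    corpus: FrequencyCorpus
    drug_factors: np.ndarray  # U (n x r)
    side_factors: np.ndarray  # V (m x r)
    drug_chem: SimilarityMatrix
    drug_disease: np.ndarray  # binary (n x n_diseases)
    disease_ids: list[str]
    spec: SyntheticSpec
    ontology: dict[str, list[str]] = field(default_factory=dict)


# ----------------------------------------------------------------- ontology
def generate_ontology(spec: SyntheticSpec, terms: list[str]) -> dict[str, list[str]]:
    """Assign each side-effect term one leaf of a dotted-id tree with the
    configured per-level branching factors."""
    levels = spec.branching
    leaves = [
        ".".join(f"{seg + 1:02d}" for seg in combo)
        for combo in itertools.product(*(range(b) for b in levels))
    ]
    if len(leaves) < len(terms):
        raise ValueError(f"ontology has {len(leaves)} leaves for {len(terms)} side effects")
    rng = np.random.default_rng(spec.seed + 1)
    chosen = rng.choice(len(leaves), size=len(terms), replace=False)
    return {t: [leaves[c]] for t, c in zip(terms, chosen)}


# ---------------------------------------------------------------- molecules
def generate_molecules(spec: SyntheticSpec) -> list[str]:
    """n_drugs valid SMILES: bundled drug-like scaffolds plus seeded
    substituent edits, each output verified by the molecular parser."""
    rng = np.random.default_rng(spec.seed + 2)
    out: list[str] = []
    for i in range(spec.n_drugs):
        base = BASE_SMILES[i % len(BASE_SMILES)]
        suffix = _EDIT_SUFFIXES[rng.integers(len(_EDIT_SUFFIXES))]
        candidate = base + suffix
        try:
            smiles_to_graph(candidate)
        except InvalidMoleculeError:
            candidate = base  # edit broke valence; keep the scaffold
        out.append(candidate)
    return out


# ----------------------------------------------------------- frequency data
def _quantize(raw: np.ndarray, skew: float) -> np.ndarray:
    """Map observed raw values into classes 1..5 by quantile bins."""
    weights = np.ones(5)
    if skew > 0:
        weights = np.array([1.0, 2.0, 4.0, 4.0, 2.0]) ** skew
    weights = weights / weights.sum()
    edges = np.quantile(raw, np.cumsum(weights)[:-1])
    return (np.searchsorted(edges, raw, side="right") + 1).astype(int)


def generate_frequency_matrix(spec: SyntheticSpec) -> tuple[list[tuple[int, int, int]], np.ndarray, np.ndarray]:
    """Latent-factor frequency triplets (drug index, SE index, class)."""
    rng = np.random.default_rng(spec.seed)
    n, m, r = spec.n_drugs, spec.n_side_effects, spec.latent_rank
    u = rng.standard_normal((n, r))
    v = rng.standard_normal((m, r))
    raw = u @ v.T + spec.noise_sd * rng.standard_normal((n, m))
    n_obs = int(round(spec.sparsity * n * m))
    flat = np.argsort(raw, axis=None)[::-1][:n_obs]  # top cells by raw value
    ii, jj = np.unravel_index(flat, raw.shape)
    labels = _quantize(raw[ii, jj], spec.skew)
    triplets = sorted(zip(ii.tolist(), jj.tolist(), labels.tolist()))
    return triplets, u, v


# ------------------------------------------------------ texts and attributes
def _latent_description(factors: np.ndarray, kind: str) -> str:
    """Deterministic description from a latent vector.

    Each latent dimension contributes its topic vocabulary with a token
    repetition count proportional to the dimension's magnitude and a
    sign-specific suffix, so latent neighbors share vocabulary in similar
    proportions.  The fixed opening sentence acts as an anchor: after the
    bag-of-words embedding is length-normalized, the ratio of topic tokens
    to anchor tokens still reflects the latent vector's overall magnitude.
    """
    parts = [f"Clinical summaries of this {kind} note the following recurring findings."]
    for t, val in enumerate(factors):
        words = _TOPIC_WORDS[t % len(_TOPIC_WORDS)]
        reps = int(round(2.0 * abs(val)))
        if reps == 0:
            continue
        suffix = "elevation" if val > 0 else "suppression"
        toks = " ".join(words[k % len(words)] + suffix for k in range(reps))
        parts.append(f"Reports emphasize {toks}.")
    return " ".join(parts)


def generate_texts_and_attributes(
    spec: SyntheticSpec, u: np.ndarray, v: np.ndarray, drug_ids: list[str]
) -> tuple[list[str], list[str], np.ndarray, SimilarityMatrix, np.ndarray]:
    """Descriptions, word vectors, chem similarity, binary disease matrix."""
    rng = np.random.default_rng(spec.seed + 3)
    drug_texts = [_latent_description(u[i], "drug") for i in range(spec.n_drugs)]
    se_texts = [_latent_description(v[j], "side effect") for j in range(spec.n_side_effects)]

    # chemical similarity: cosine of drug factors mapped onto [0, 1]
    norms = np.linalg.norm(u, axis=1, keepdims=True)
    unit = u / np.where(norms > 0, norms, 1.0)
    chem = (1.0 + unit @ unit.T) / 2.0
    np.fill_diagonal(chem, 1.0)
    chem_sim = SimilarityMatrix(np.clip(chem, 0.0, 1.0), list(drug_ids), "drug-chem")

    # binary drug-disease associations from disease prototypes in latent space
    prototypes = rng.standard_normal((spec.n_diseases, spec.latent_rank))
    affinity = u @ prototypes.T
    disease = (affinity > np.quantile(affinity, 0.7)).astype(int)

    # word vectors: noisy linear image of the side-effect factors
    projection = rng.standard_normal((spec.latent_rank, spec.word_dim)) / np.sqrt(spec.latent_rank)
    word_vectors = v @ projection + 0.1 * rng.standard_normal((spec.n_side_effects, spec.word_dim))
    return drug_texts, se_texts, word_vectors, chem_sim, disease


# ------------------------------------------------------------------ assembly
def generate_corpus(spec: SyntheticSpec) -> SyntheticCorpus:
    """Generate a complete corpus: molecules, ontology, texts, attribute
    matrices and frequency triplets, all from one latent model."""
    triplets_idx, u, v = generate_frequency_matrix(spec)
    drug_ids = [f"D{i:04d}" for i in range(spec.n_drugs)]
    se_ids = [f"S{j:04d}" for j in range(spec.n_side_effects)]
    terms = [f"adr_term_{j:04d}" for j in range(spec.n_side_effects)]
    smiles = generate_molecules(spec)
    ontology = generate_ontology(spec, terms)
    drug_texts, se_texts, word_vectors, chem_sim, disease = generate_texts_and_attributes(
        spec, u, v, drug_ids
    )
    drugs = [DrugRecord(drug_ids[i], smiles[i], drug_texts[i]) for i in range(spec.n_drugs)]
    side_effects = [
        SideEffectRecord(
            se_ids[j],
            terms[j],
            dotted_ids=list(ontology[terms[j]]),
            word_vector=word_vectors[j],
            description=se_texts[j],
        )
        for j in range(spec.n_side_effects)
    ]
    triplets = [(drug_ids[i], se_ids[j], y) for i, j, y in triplets_idx]
    corpus = FrequencyCorpus(drugs, side_effects, triplets)
    return SyntheticCorpus(
        corpus=corpus,
        drug_factors=u,
        side_factors=v,
        drug_chem=chem_sim,
        drug_disease=disease,
        disease_ids=[f"DIS{k:03d}" for k in range(spec.n_diseases)],
        spec=spec,
        ontology=ontology,
    )


def write_corpus_dir(syn: SyntheticCorpus, outdir: str | Path) -> None:
    """Write the full corpus directory: triplets.tsv, smiles.tsv,
    ontology.tsv, wordvec.tsv, texts.tsv, drug_chem.tsv, drug_disease.tsv,
    spec.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_corpus(syn.corpus, outdir)
    write_matrix_tsv(outdir / "drug_chem.tsv", syn.drug_chem.values, syn.corpus.drug_ids, list(syn.drug_chem.ids))
    write_matrix_tsv(outdir / "drug_disease.tsv", syn.drug_disease, syn.corpus.drug_ids, syn.disease_ids)
    (outdir / "spec.json").write_text(syn.spec.to_json() + "\n")
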
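"""Per-channel drug similarities and their consensus integration.

Four channels, each producing a score in [0, 1] for a drug pair:

* ``chem``  — Tanimoto coefficient between binary molecular fingerprints,
  |f_j AND f_k| / |f_j OR f_k|.
* ``tar``   — mean Gene Ontology Jaccard similarity over all cross pairs of
  the two drugs' target proteins.
* ``sub``   — Jaccard similarity of the drugs' substituent sets.
* ``thera`` — therapeutic similarity from WHO ATC codes: Jaccard of the
  level-l prefix sets for each of the five ATC levels, averaged.

The per-channel scores are fused into a single comprehensive similarity
S_com by one of three consensus rules: maximum, arithmetic mean, or
geometric mean over the enabled channels.  By the AM-GM inequality the
three always satisfy max >= mean >= gm for a fixed pair.

Scalar operations mirror the pairwise definitions; ``build_similarity_matrix``
computes all pairs at once with vectorized set-incidence algebra and agrees
with the scalar path to floating-point round-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import Dataset, DrugProfile, ProteinAnnotation

__all__ = [
    "CHANNELS",
    "INTEGRATION_METHODS",
    "ATC_LEVEL_PREFIXES",
    "SimilarityMatrix",
    "chem_similarity",
    "go_similarity",
    "target_similarity",
    "substituent_similarity",
    "therapeutic_similarity",
    "integrate",
    "build_similarity_matrix",
]

CHANNELS = ("chem", "tar", "sub", "thera")
INTEGRATION_METHODS = ("max", "mean", "gm")

# WHO ATC level boundaries: anatomical main group (1 char), therapeutic
# subgroup (3), pharmacological subgroup (4), chemical subgroup (5),
# chemical substance (7).
ATC_LEVEL_PREFIXES = (1, 3, 4, 5, 7)


def chem_similarity(f_j: np.ndarray, f_k: np.ndarray) -> float:
    """Tanimoto coefficient between two equal-length binary fingerprints.

    Returns 0.0 for two all-zero fingerprints (no evidence, not identity).
    """
    f_j = np.asarray(f_j)
    f_k = np.asarray(f_k)
    if f_j.shape != f_k.shape:
        raise ValueError(f"fingerprint length mismatch: {f_j.shape} vs {f_k.shape}")
    both = int(np.sum((f_j != 0) & (f_k != 0)))
    either = int(np.sum((f_j != 0) | (f_k != 0)))
    return both / either if either else 0.0


def _jaccard(a: Iterable, b: Iterable) -> float:
    a, b = set(a), set(b)
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def go_similarity(go_m: Iterable[str], go_n: Iterable[str]) -> float:
    """Overlap rate (Jaccard) of two proteins' GO term sets; 0 if both empty."""
    return _jaccard(go_m, go_n)


def substituent_similarity(sub_j: Iterable[str], sub_k: Iterable[str]) -> float:
    """Jaccard similarity of two drugs' substituent sets; 0 if both empty."""
    return _jaccard(sub_j, sub_k)


def target_similarity(
    drug_j: DrugProfile, drug_k: DrugProfile, proteins: Mapping[str, ProteinAnnotation]
) -> float:
    """Mean GO similarity over all cross pairs of the drugs' target proteins.

    Sum of go_similarity over the N_j * N_k target pairs divided by N_j * N_k.
    Proteins with no GO annotation contribute 0 to every pair they are in.
    """
    if not drug_j.targets or not drug_k.targets:
        raise ValueError(
            f"target similarity needs >=1 target per drug "
            f"({drug_j.drug_id}: {len(drug_j.targets)}, {drug_k.drug_id}: {len(drug_k.targets)})"
        )

    def terms(p: str) -> frozenset:
        ann = proteins.get(p)
        if ann is None:
            raise KeyError(f"target protein {p!r} has no annotation record")
        return ann.go_terms

    total = sum(
        go_similarity(terms(pm), terms(pn))
        for pm in drug_j.targets
        for pn in drug_k.targets
    )
    return total / (len(drug_j.targets) * len(drug_k.targets))


def therapeutic_similarity(atc_j: Iterable[str], atc_k: Iterable[str]) -> float:
    """ATC-based similarity: mean over the five levels of the Jaccard of
    level-l prefix sets of the two drugs' codes."""
    atc_j, atc_k = set(atc_j), set(atc_k)
    if not atc_j or not atc_k:
        raise ValueError("therapeutic similarity needs >=1 ATC code per drug")
    total = 0.0
    for nchar in ATC_LEVEL_PREFIXES:
        total += _jaccard({c[:nchar] for c in atc_j}, {c[:nchar] for c in atc_k})
    return total / len(ATC_LEVEL_PREFIXES)


def integrate(scores: Mapping[str, float] | Sequence[float], method: str) -> float:
    """Fuse per-channel scores into one comprehensive score.

    max -> maximum; mean -> arithmetic mean; gm -> n-th root of the product
    over the n enabled channels (0 if any channel scores 0).
    """
    values = np.asarray(
        list(scores.values()) if isinstance(scores, Mapping) else list(scores), dtype=float
    )
    if values.size == 0:
        raise ValueError("integrate requires at least one channel score")
    if np.any((values < 0) | (values > 1)):
        raise ValueError("channel scores must lie in [0, 1]")
    if method == "max":
        return float(values.max())
    if method == "mean":
        return float(values.mean())
    if method == "gm":
        return float(np.prod(values) ** (1.0 / values.size))
    raise ValueError(f"unknown integration method {method!r}; expected one of {INTEGRATION_METHODS}")


@dataclass
class SimilarityMatrix:
    """Symmetric drug x drug score matrix for one channel or an integration.

    Diagonal entries are fixed at 1.0: a drug is maximally similar to itself
    regardless of channel arithmetic, which also keeps similarity feature
    vectors free of 0/0 artifacts.
    """

    drug_ids: list[str]
    values: np.ndarray
    channel: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        d = len(self.drug_ids)
        if self.values.shape != (d, d):
            raise ValueError(f"matrix shape {self.values.shape} != ({d}, {d})")
        self._index = {d_id: i for i, d_id in enumerate(self.drug_ids)}

    def index(self, drug_id: str) -> int:
        try:
            return self._index[drug_id]
        except KeyError:
            raise KeyError(f"unknown drug id {drug_id!r}") from None

    def value(self, drug_j: str, drug_k: str) -> float:
        return float(self.values[self.index(drug_j), self.index(drug_k)])

    def row(self, drug_id: str) -> np.ndarray:
        return self.values[self.index(drug_id)]

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("drug_id\t" + "\t".join(self.drug_ids) + "\n")
            for i, drug_id in enumerate(self.drug_ids):
                row = "\t".join(format(v, ".10g") for v in self.values[i])
                fh.write(f"{drug_id}\t{row}\n")

    @classmethod
    def from_tsv(cls, path, channel: str = "unknown", meta: dict | None = None) -> "SimilarityMatrix":
        path = Path(path)
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            ids = header[1:]
            values = np.loadtxt(fh, usecols=range(1, len(ids) + 1), ndmin=2)
        return cls(drug_ids=ids, values=values, channel=channel, meta=meta or {})


# ---------------------------------------------------------------------------
# Vectorized all-pairs computation


def _incidence(sets: list[frozenset | set]) -> np.ndarray:
    """Rows: objects; columns: distinct elements; 0/1 membership."""
    elements = sorted(set().union(*sets)) if sets else []
    idx = {e: i for i, e in enumerate(elements)}
    M = np.zeros((len(sets), len(elements)), dtype=float)
    for r, s in enumerate(sets):
        for e in s:
            M[r, idx[e]] = 1.0
    return M


def _jaccard_matrix(M: np.ndarray) -> np.ndarray:
    """All-pairs Jaccard from a binary incidence matrix; 0/0 -> 0."""
    inter = M @ M.T
    sizes = M.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        J = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    return J


def _channel_matrix(dataset: Dataset, channel: str) -> np.ndarray:
    drugs = dataset.drugs
    if channel == "chem":
        for d in drugs:
            if d.fingerprint is None:
                raise ValueError(f"drug {d.drug_id!r} has no fingerprint (chem channel)")
        F = np.stack([d.fingerprint.astype(float) for d in drugs])
        return _jaccard_matrix(F)
    if channel == "tar":
        protein_ids = sorted(dataset.proteins)
        G = _incidence([dataset.proteins[p].go_terms for p in protein_ids])
        P = _jaccard_matrix(G)
        pidx = {p: i for i, p in enumerate(protein_ids)}
        M = np.zeros((len(drugs), len(protein_ids)))
        counts = np.zeros(len(drugs))
        for r, d in enumerate(drugs):
            if not d.targets:
                raise ValueError(f"drug {d.drug_id!r} has no targets (tar channel)")
            for t in d.targets:
                if t not in pidx:
                    raise KeyError(f"drug {d.drug_id!r}: unannotated target {t!r}")
                M[r, pidx[t]] = 1.0
            counts[r] = len(d.targets)
        return (M @ P @ M.T) / np.outer(counts, counts)
    if channel == "sub":
        return _jaccard_matrix(_incidence([d.substituents for d in drugs]))
    if channel == "thera":
        for d in drugs:
            if not d.atc_codes:
                raise ValueError(f"drug {d.drug_id!r} has no ATC codes (thera channel)")
        acc = np.zeros((len(drugs), len(drugs)))
        for nchar in ATC_LEVEL_PREFIXES:
            prefixes = [frozenset(c[:nchar] for c in d.atc_codes) for d in drugs]
            acc += _jaccard_matrix(_incidence(prefixes))
        return acc / len(ATC_LEVEL_PREFIXES)
    raise ValueError(f"unknown channel {channel!r}; expected one of {CHANNELS}")


def build_similarity_matrix(
    dataset: Dataset, channels: Iterable[str] = CHANNELS, method: str = "max"
) -> SimilarityMatrix:
    """Comprehensive similarity matrix over all drug pairs.

    Computes each enabled channel matrix, fuses them with ``method``, forces
    exact symmetry and a unit diagonal, and records the configuration in
    ``meta``.
    """
    channels = tuple(channels)
    if not channels:
        raise ValueError("at least one channel required")
    if method not in INTEGRATION_METHODS:
        raise ValueError(f"unknown integration method {method!r}")
    stack = np.stack([_channel_matrix(dataset, c) for c in channels])
    stack = np.clip(stack, 0.0, 1.0)
    if method == "max":
        V = stack.max(axis=0)
    elif method == "mean":
        V = stack.mean(axis=0)
    else:  # gm
        V = np.prod(stack, axis=0) ** (1.0 / len(channels))
    V = (V + V.T) / 2.0  # enforce exact symmetry against BLAS round-off
    np.fill_diagonal(V, 1.0)
    channel_tag = channels[0] if len(channels) == 1 else method
    return SimilarityMatrix(
        drug_ids=dataset.drug_ids,
        values=V,
        channel=channel_tag,
        meta={"channels": list(channels), "method": method},
    )
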
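"""Synthetic drug/side-effect datasets with planted cluster structure.

The generator emulates the statistical premise the whole pipeline rests on —
similar drugs share side-effects — without any real chemistry: drugs are
assigned round-robin to clusters; each cluster owns a prototype fingerprint,
a disjoint GO-term subpool (annotating a cluster-private protein panel), a
disjoint substituent subpool and an ATC first-level prefix.  A drug perturbs
its cluster prototypes (per-bit flip noise on the fingerprint, random draws
from the cluster pools elsewhere), so within-cluster similarity is high on
every channel and between-cluster similarity is low.

Side-effects are likewise assigned to clusters round-robin; true labels are
Bernoulli(p_in) for drugs in the side-effect's cluster and Bernoulli(p_out)
outside it.  A uniform ``mask_fraction`` of the true positive labels is then
hidden, turning those drugs into unlabeled candidates — the ground truth
needed to measure how often a negative-selection strategy picks an
undiscovered positive ("contamination").

Everything is reproducible from ``GeneratorConfig.seed`` via named
substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .io import (
    AnnotationTables,
    Dataset,
    FilterReport,
    assemble_dataset,
    write_dataset,
)
from ._rng import substream
from .negatives import GoldStandard

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "generate",
    "benchmark_config",
    "e2e_benchmark_config",
    "write_truth",
    "purity_report",
]

_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic world.

    Defaults are the desk-scale benchmark used throughout the test suite:
    200 drugs in 8 clusters, 30 side-effects, moderate fingerprint noise
    (theta=0.1), strong in-cluster label enrichment (p_in=0.7 vs
    p_out=0.05) and 20% of true positives masked.  ``fingerprint_length``
    defaults to the conventional 1024 bits; the benchmark shrinks it to 256
    purely for speed (see ``benchmark_config``).
    """

    n_drugs: int = 200
    n_side_effects: int = 30
    n_clusters: int = 8
    fingerprint_length: int = 1024
    bit_flip_prob: float = 0.1
    go_pool_size: int = 160
    go_terms_per_protein: int = 6
    targets_per_drug: int = 3
    proteins_per_cluster: int = 12
    substituent_pool_size: int = 80
    substituents_per_drug: int = 5
    atc_branching: int = 3
    p_in: float = 0.7
    p_out: float = 0.05
    mask_fraction: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.p_out < self.p_in <= 1.0):
            raise ValueError(f"need 0 <= p_out < p_in <= 1, got {self.p_out}, {self.p_in}")
        if not (0.0 <= self.mask_fraction < 1.0):
            raise ValueError("mask_fraction must be in [0, 1)")
        if not (0.0 <= self.bit_flip_prob <= 0.5):
            raise ValueError("bit_flip_prob must be in [0, 0.5]")
        counts = (
            self.n_drugs, self.n_side_effects, self.n_clusters, self.fingerprint_length,
            self.go_pool_size, self.go_terms_per_protein, self.targets_per_drug,
            self.proteins_per_cluster, self.substituent_pool_size,
            self.substituents_per_drug, self.atc_branching,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be positive")
        if self.n_clusters > self.n_drugs:
            raise ValueError("more clusters than drugs")
        if self.n_clusters > len(_LETTERS):
            raise ValueError(f"at most {len(_LETTERS)} clusters supported (ATC letters)")
        if self.go_pool_size // self.n_clusters < self.go_terms_per_protein:
            raise ValueError("per-cluster GO pool smaller than go_terms_per_protein")
        if self.targets_per_drug > self.proteins_per_cluster:
            raise ValueError("targets_per_drug exceeds proteins_per_cluster")
        if self.substituent_pool_size // self.n_clusters < self.substituents_per_drug:
            raise ValueError("per-cluster substituent pool smaller than substituents_per_drug")
        if self.atc_branching > 26:
            raise ValueError("atc_branching must be <= 26")


def benchmark_config(seed: int = 0) -> GeneratorConfig:
    """The default desk-scale benchmark (256-bit fingerprints for speed)."""
    return GeneratorConfig(fingerprint_length=256, seed=seed)


def e2e_benchmark_config(seed: int = 0) -> GeneratorConfig:
    """Benchmark variant for end-to-end classifier comparisons.

    Doubles the drug count (cluster size 50) so each side-effect has ~42
    positives and 5-fold training sets hold ~67 drugs.  This keeps the
    training size above the KNN default k=50: with fewer drugs the vote
    k' = min(k, training size) covers the whole training set, the classifier
    degenerates to a global majority vote that ignores the features, and any
    comparison between negative-selection strategies is vacuous.  The
    operating regime of the real task (positives per side-effect well above
    k) is preserved at the smallest size that clears the threshold.
    """
    return GeneratorConfig(n_drugs=400, fingerprint_length=256, seed=seed)


@dataclass
class SyntheticTruth:
    """Ground truth retained by the generator.

    ``masked_labels`` is what the pipeline sees; ``true_labels`` adds back
    the hidden positives; ``masked_pairs`` lists exactly the hidden cells.
    """

    drug_ids: list[str]
    side_effect_ids: list[str]
    clusters: dict[str, int]
    se_clusters: dict[str, int]
    true_labels: np.ndarray
    masked_labels: np.ndarray
    masked_pairs: list[tuple[str, str]] = field(default_factory=list)

    def masked_set(self) -> set[tuple[str, str]]:
        return set(self.masked_pairs)


def _partition(pool: list[str], n_clusters: int) -> list[list[str]]:
    """Split a pool into n roughly equal disjoint sub-pools."""
    bounds = np.linspace(0, len(pool), n_clusters + 1).astype(int)
    return [pool[bounds[i]: bounds[i + 1]] for i in range(n_clusters)]


def generate(config: GeneratorConfig) -> tuple[Dataset, SyntheticTruth, FilterReport]:
    """Draw one synthetic world and assemble it into a pipeline-ready Dataset.

    The generated tables are complete for all four channels, so assembly
    drops nothing; the returned dataset's labels are the *masked* matrix.
    """
    config.validate()
    seed = config.seed
    width = len(str(config.n_drugs - 1))
    drug_ids = [f"D{i:0{width}d}" for i in range(config.n_drugs)]
    se_width = len(str(config.n_side_effects - 1))
    se_ids = [f"SE{i:0{se_width}d}" for i in range(config.n_side_effects)]
    clusters = {d: i % config.n_clusters for i, d in enumerate(drug_ids)}
    se_clusters = {s: i % config.n_clusters for i, s in enumerate(se_ids)}

    # --- fingerprints: cluster prototype + per-bit flip noise
    rng = substream(seed, "fingerprint-prototypes")
    prototypes = rng.integers(0, 2, size=(config.n_clusters, config.fingerprint_length))
    rng = substream(seed, "fingerprint-noise")
    flips = rng.random((config.n_drugs, config.fingerprint_length)) < config.bit_flip_prob
    fingerprints = {
        d: np.asarray(
            (prototypes[clusters[d]] ^ flips[i]).astype(np.uint8)
        )
        for i, d in enumerate(drug_ids)
    }

    # --- proteins and GO annotations: cluster-private panels over disjoint GO sub-pools
    go_pool = [f"GO:{i:07d}" for i in range(config.go_pool_size)]
    go_subpools = _partition(go_pool, config.n_clusters)
    protein_go: dict[str, frozenset] = {}
    cluster_proteins: list[list[str]] = []
    rng = substream(seed, "protein-annotations")
    for c in range(config.n_clusters):
        panel = [f"C{c}P{j:02d}" for j in range(config.proteins_per_cluster)]
        cluster_proteins.append(panel)
        for p in panel:
            terms = rng.choice(
                go_subpools[c], size=config.go_terms_per_protein, replace=False
            )
            protein_go[p] = frozenset(terms)
    rng = substream(seed, "drug-targets")
    drug_targets = {
        d: frozenset(
            rng.choice(cluster_proteins[clusters[d]], size=config.targets_per_drug, replace=False)
        )
        for d in drug_ids
    }

    # --- substituents: disjoint cluster sub-pools
    sub_pool = [f"SUB{i:03d}" for i in range(config.substituent_pool_size)]
    sub_subpools = _partition(sub_pool, config.n_clusters)
    rng = substream(seed, "substituents")
    substituents = {
        d: frozenset(
            rng.choice(sub_subpools[clusters[d]], size=config.substituents_per_drug, replace=False)
        )
        for d in drug_ids
    }

    # --- ATC codes: cluster letter + random branches at the deeper levels
    rng = substream(seed, "atc")
    atc: dict[str, frozenset] = {}
    b = config.atc_branching
    for d in drug_ids:
        code = (
            _LETTERS[clusters[d]]
            + f"{rng.integers(1, b + 1):02d}"
            + _LETTERS[rng.integers(0, b)]
            + _LETTERS[rng.integers(0, b)]
            + f"{rng.integers(1, b + 1):02d}"
        )
        atc[d] = frozenset({code})

    # --- labels: Bernoulli(p_in) inside the side-effect's cluster, p_out outside
    rng = substream(seed, "labels")
    true_labels = np.zeros((config.n_drugs, config.n_side_effects), dtype=np.uint8)
    for j, s in enumerate(se_ids):
        probs = np.where(
            np.array([clusters[d] for d in drug_ids]) == se_clusters[s],
            config.p_in,
            config.p_out,
        )
        true_labels[:, j] = (rng.random(config.n_drugs) < probs).astype(np.uint8)

    # --- masking: hide a uniform fraction of the true positive cells
    pos_cells = np.argwhere(true_labels == 1)
    n_mask = round(config.mask_fraction * len(pos_cells))
    rng = substream(seed, "masking")
    chosen = rng.choice(len(pos_cells), size=n_mask, replace=False) if n_mask else []
    masked_labels = true_labels.copy()
    masked_pairs = []
    for idx in chosen:
        i, j = pos_cells[idx]
        masked_labels[i, j] = 0
        masked_pairs.append((drug_ids[i], se_ids[j]))
    masked_pairs.sort()

    pairs = {
        (drug_ids[i], se_ids[j]) for i, j in np.argwhere(masked_labels == 1)
    }
    tables = AnnotationTables(
        drug_targets=drug_targets,
        protein_go=protein_go,
        substituents=substituents,
        atc=atc,
        pairs=pairs,
    )
    dataset, report = assemble_dataset(fingerprints, tables, channels=("chem", "tar", "sub", "thera"))

    # assembly sorts lexicographically; zero-padded ids keep generation order,
    # but side-effects with zero unmasked positives may legitimately drop
    kept_se = set(dataset.side_effect_ids)
    keep_cols = [j for j, s in enumerate(se_ids) if s in kept_se]
    truth = SyntheticTruth(
        drug_ids=drug_ids,
        side_effect_ids=[se_ids[j] for j in keep_cols],
        clusters=clusters,
        se_clusters={s: se_clusters[s] for s in kept_se},
        true_labels=true_labels[:, keep_cols],
        masked_labels=masked_labels[:, keep_cols],
        masked_pairs=[(d, s) for d, s in masked_pairs if s in kept_se],
    )
    return dataset, truth, report


def write_truth(truth: SyntheticTruth, directory) -> None:
    """Persist ground truth beside the standard tables (TSV)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "clusters.tsv", "w", encoding="utf-8") as fh:
        fh.write("drug_id\tcluster\n")
        for d in truth.drug_ids:
            fh.write(f"{d}\t{truth.clusters[d]}\n")
    with open(directory / "masked_pairs.tsv", "w", encoding="utf-8") as fh:
        fh.write("drug_id\tside_effect_id\n")
        for d, s in truth.masked_pairs:
            fh.write(f"{d}\t{s}\n")
    with open(directory / "true_dsp.tsv", "w", encoding="utf-8") as fh:
        fh.write("drug_id\tside_effect_id\n")
        for i, d in enumerate(truth.drug_ids):
            for j in np.flatnonzero(truth.true_labels[i]):
                fh.write(f"{d}\t{truth.side_effect_ids[j]}\n")


def write_world(dataset: Dataset, truth: SyntheticTruth, directory) -> None:
    """Write the six pipeline tables plus the truth files."""
    write_dataset(dataset, directory)
    write_truth(truth, directory)


def purity_report(
    golds: Mapping[str, GoldStandard], truth: SyntheticTruth
) -> tuple[dict[str, float], float]:
    """Contamination of selected negatives by masked true positives.

    For each side-effect: the fraction of its selected negatives that are in
    fact hidden positives.  Returns the per-side-effect map and its mean.
    """
    masked = truth.masked_set()
    per_se: dict[str, float] = {}
    for se_id, gold in golds.items():
        if not gold.negatives:
            per_se[se_id] = 0.0
            continue
        bad = sum(1 for d in gold.negatives if (d, se_id) in masked)
        per_se[se_id] = bad / len(gold.negatives)
    mean = float(np.mean(list(per_se.values()))) if per_se else 0.0
    return per_se, mean
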
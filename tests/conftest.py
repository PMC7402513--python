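import numpy as np
import pytest

from sidefx import benchmark_config, build_similarity_matrix, generate
from sidefx.io import Dataset, DrugProfile


@pytest.fixture(scope="session")
def bench():
    """One draw of the default desk-scale benchmark world."""
    dataset, truth, report = generate(benchmark_config(seed=1))
    return dataset, truth, report


@pytest.fixture(scope="session")
def bench_dataset(bench):
    return bench[0]


@pytest.fixture(scope="session")
def bench_S(bench_dataset):
    return build_similarity_matrix(bench_dataset, method="max")


def make_scored_dataset(candidate_scores: dict, positives: list[str]):
    """A minimal dataset + similarity matrix with prescribed accumulative scores.

    One side-effect; ``positives`` are its labeled drugs; each candidate c
    has sum over positives of S(c, p) equal to candidate_scores[c] (spread
    evenly over the positives).
    """
    from sidefx.similarity import SimilarityMatrix

    drug_ids = sorted(set(candidate_scores) | set(positives))
    drugs = [DrugProfile(drug_id=d) for d in drug_ids]
    labels = np.array([[1 if d in set(positives) else 0] for d in drug_ids], dtype=np.uint8)
    dataset = Dataset(drugs=drugs, proteins={}, labels=labels, side_effect_ids=["SE0"])
    D = len(drug_ids)
    V = np.zeros((D, D))
    idx = {d: i for i, d in enumerate(drug_ids)}
    for c, total in candidate_scores.items():
        per_pos = total / len(positives)
        for p in positives:
            V[idx[c], idx[p]] = per_pos
            V[idx[p], idx[c]] = per_pos
    np.fill_diagonal(V, 1.0)
    S = SimilarityMatrix(drug_ids=drug_ids, values=V, channel="max")
    return dataset, S
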
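import numpy as np
import pytest

from asnet import AssemblageMatrix, OccupationRecord, SimilarityMatrix


def make_records(n, lat0=43.0, lon0=5.0, culture="RPC"):
    recs = []
    for i in range(n):
        recs.append(
            OccupationRecord(
                occupation_id=f"O{i + 1}",
                site_name=f"site {i + 1}",
                culture=culture if isinstance(culture, str) else culture[i],
                latitude=lat0 + 0.3 * i,
                longitude=lon0 + 0.2 * i,
                date_early=7800.0 - 50.0 * i,
                date_late=7600.0 - 50.0 * i,
                sequences=frozenset({1, 2}),
            )
        )
    return recs


def random_similarity(rng, n):
    """Random symmetric similarity matrix with unit diagonal."""
    A = rng.random((n, n))
    S = (A + A.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(ids=[f"O{i + 1}" for i in range(n)], S=S, index="BR")


@pytest.fixture
def counts_assemblage():
    values = np.array(
        [
            [5, 3, 0, 2],
            [4, 4, 1, 1],
            [0, 1, 7, 2],
        ],
        dtype=float,
    )
    return AssemblageMatrix(
        records=make_records(3),
        traits=["incised", "impressed", "cardial", "plain"],
        values=values,
        mode="counts",
    )


@pytest.fixture
def presence_assemblage():
    values = np.array(
        [
            [1, 1, 0, 0, 1],
            [0, 1, 1, 0, 1],
            [0, 0, 1, 1, 0],
        ],
        dtype=float,
    )
    return AssemblageMatrix(
        records=make_records(3),
        traits=[f"bead_{i}" for i in range(5)],
        values=values,
        mode="presence",
    )
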
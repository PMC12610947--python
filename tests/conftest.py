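import numpy as np
import pandas as pd
import pytest

from agerank.deg import ExpressionStudy


def make_study(
    values: np.ndarray,
    n_young: int,
    n_old: int,
    dataset_id: str = "D1",
    species: str = "human",
    tissue: str = "muscle",
    genes: "list[str] | None" = None,
    probes: "list[str] | None" = None,
) -> ExpressionStudy:
    """Wrap a raw matrix (probes x samples, young columns first) as a study."""
    values = np.asarray(values, dtype=float)
    n_probes = values.shape[0]
    probes = probes or [f"p{i}" for i in range(n_probes)]
    cols = [f"Y{i}" for i in range(n_young)] + [f"O{i}" for i in range(n_old)]
    age = pd.Series(["young"] * n_young + ["old"] * n_old, index=cols)
    p2g = pd.Series(genes, index=probes, name="gene") if genes is not None else None
    return ExpressionStudy(
        dataset_id=dataset_id,
        species=species,
        tissue=tissue,
        values=pd.DataFrame(values, index=probes, columns=cols),
        age_group=age,
        probe_to_gene=p2g,
    )


def make_lifespan(
    days,
    events=None,
    group: str = "A",
    batch: str = "batch1",
) -> pd.DataFrame:
    """Per-animal lifespan table from day/event arrays."""
    days = np.asarray(days, dtype=float)
    events = np.ones_like(days, dtype=int) if events is None else np.asarray(events, dtype=int)
    return pd.DataFrame(
        {
            "animal_id": [f"{group}-{i}" for i in range(len(days))],
            "group": group,
            "batch": batch,
            "plate": f"{group}-p1",
            "day": days,
            "event": events,
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def registry25():
    """Registry of 25 datasets over four species and six tissues."""
    species = ["human", "mouse", "rat", "dog"]
    tissues = ["muscle", "brain", "adipose", "immune", "heart", "liver"]
    return pd.DataFrame(
        {
            "dataset_id": [f"DS{i:02d}" for i in range(25)],
            "species": [species[i % 4] for i in range(25)],
            "tissue": [tissues[i % 6] for i in range(25)],
        }
    )


def deg_record(gene, dataset_id, direction, adjusted_p=0.01, tissue="muscle", species="human"):
    return {
        "gene": gene,
        "dataset_id": dataset_id,
        "direction": direction,
        "adjusted_p": adjusted_p,
        "tissue": tissue,
        "species": species,
    }
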
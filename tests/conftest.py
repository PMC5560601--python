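import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pcsig.diffexpr import Contrast, DEResult

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from pcsig.synth import CohortSpec, PlantedSet, generate_cohort


def make_design(groups: dict[str, int]) -> pd.DataFrame:
    ids, labels = [], []
    for g, n in groups.items():
        for i in range(1, n + 1):
            ids.append(f"{g}_{i}")
            labels.append(g)
    return pd.DataFrame({"sample_id": ids, "group": labels,
                         "study": "", "stage": ""}).set_index("sample_id",
                                                              drop=False)


def make_de_result(contrast: Contrast, up: set[str], down: set[str],
                   universe: list[str]) -> DEResult:
    """A DEResult with prescribed significant calls for logic tests."""
    rows = []
    for g in universe:
        if g in up:
            rows.append((2.0, 0.1, 8.0, 1e-6, 1e-5, "up", True))
        elif g in down:
            rows.append((-2.0, 0.1, -8.0, 1e-6, 1e-5, "down", True))
        else:
            rows.append((0.05, 0.1, 0.3, 0.8, 0.9, "up", False))
    table = pd.DataFrame(rows, index=pd.Index(universe, name="gene_symbol"),
                         columns=["log2FC", "s2", "t", "p", "adj_p",
                                  "direction", "significant"])
    return DEResult(contrast, table, d0=4.0, s0_2=0.1, residual_df=8.0)


@pytest.fixture(scope="session")
def planted_cohort():
    """A 4-group cohort (3/7/6/7 samples) with planted up/down sets."""
    spec = CohortSpec(
        n_genes=1200,
        planted=(
            PlantedSet("PC-down", 150, ("TPC", "BPC", "BMPC"), -1.5),
            PlantedSet("PC-up", 100, ("TPC", "BPC", "BMPC"), 1.5),
        ),
        n_ig_probesets=15,
        n_unannotated=40,
        seed=11,
    )
    matrix, annotation, design, truth = generate_cohort(spec)
    return {"spec": spec, "matrix": matrix, "annotation": annotation,
            "design": design, "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
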
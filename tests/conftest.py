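import numpy as np
import pandas as pd
import pytest

from phenodiet import yield_metrics as ymx
from phenodiet.synthetic import preset, simulate_survey


@pytest.fixture(scope="session")
def paper_cfg():
    return preset("paper_like")


@pytest.fixture(scope="session")
def paper_run(paper_cfg):
    """One fully analyzed paper-like survey (seed 1), shared across tests."""
    survey, truth = simulate_survey(paper_cfg, seed=1)
    ym = ymx.compute_yield(survey)
    dc = ymx.rank_filter_top_half(ym)
    sym = ymx.standardize(ym, dc.retained)
    dc = ymx.detect_core_diet(sym, dc)
    return {"survey": survey, "truth": truth, "ym": ym, "dc": dc, "sym": sym}


def make_yield_matrix(values: np.ndarray, n_rep: int = 2,
                      sites=None, substrates=None) -> ymx.YieldMatrix:
    """Build a YieldMatrix from an (isolate*rep) x substrate array.

    ``values`` has one row per (isolate, replicate) with replicates
    contiguous; water yields default to zero.
    """
    n_rows, n_sub = values.shape
    n_iso = n_rows // n_rep
    isolates = [f"I{i:02d}" for i in range(n_iso)]
    substrates = substrates or [f"S{j:02d}" for j in range(n_sub)]
    idx = pd.MultiIndex.from_tuples(
        [(iso, r + 1) for iso in isolates for r in range(n_rep)],
        names=["isolate_id", "replicate"],
    )
    vals = pd.DataFrame(values, index=idx, columns=substrates)
    water = pd.DataFrame(0.0, index=idx, columns=["PM1"])
    sub_plate = pd.Series("PM1", index=substrates)
    if sites is None:
        sites = ["A"] * n_iso
    site_labels = pd.Series(sites, index=isolates)
    return ymx.YieldMatrix(values=vals, water=water, substrate_plate=sub_plate,
                           site_labels=site_labels)
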
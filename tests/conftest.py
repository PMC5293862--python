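import warnings

import numpy as np
import pandas as pd
import pytest

from grassmet import simulate as sim

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def default_run():
    """One default-preset synthetic survey (10 populations x 6 genotypes x
    5 replicates, 12 batches), rendered once for the whole session."""
    spec = sim.default_design(seed=0)
    meta = sim.generate_design(spec)
    truth = sim.simulate_truth(spec)
    matrix, annot = sim.render_intensity_matrix(truth, meta, seed=0)
    return {"spec": spec, "meta": meta, "truth": truth,
            "matrix": matrix, "annot": annot}


@pytest.fixture(scope="session")
def clean_run():
    """Same design rendered without batch effects or RT drift — the
    technical-noise-only reference for calibration checks."""
    spec = sim.default_design(seed=0)
    meta = sim.generate_design(spec)
    truth = sim.simulate_truth(spec)
    matrix, annot = sim.render_intensity_matrix(
        truth, meta, seed=0, batch_location_sd=0.0, apply_rt_drift=False,
        n_outliers=0)
    return {"spec": spec, "meta": meta, "truth": truth,
            "matrix": matrix, "annot": annot}


def toy_annot(rows):
    """annot DataFrame from (peak_id, mz, rt) triples."""
    return pd.DataFrame([
        {"peak_id": pid, "mz": mz, "rt": rt, "rtmin": rt - 0.1,
         "rtmax": rt + 0.1, "mzmin": mz * (1 - 1e-5), "mzmax": mz * (1 + 1e-5),
         "adduct": "unknown", "isotope_links": ""}
        for pid, mz, rt in rows
    ])


@pytest.fixture
def make_annot():
    return toy_annot
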
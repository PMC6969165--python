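import numpy as np
import pandas as pd
import pytest

from pdpatterns.preprocess import AnalytePanel


def make_normalized_panel(values: np.ndarray, analytes=None, samples=None) -> AnalytePanel:
    """Wrap a log2-scale matrix as a normalized-state panel (test helper)."""
    n, p = values.shape
    analytes = list(analytes) if analytes is not None else [f"A{j:03d}" for j in range(p)]
    samples = list(samples) if samples is not None else [f"s{i:03d}" for i in range(n)]
    frame = pd.DataFrame(values, index=samples, columns=analytes)
    lloq = pd.Series(1.0, index=analytes)
    return AnalytePanel(values=frame, lloq=lloq, state="normalized")


def make_longitudinal(
    rng,
    n_subjects: int,
    analyte_effects,
    visits=("week4", "week16"),
    arm="apremilast",
    responses=("AR", "ANR"),
    subject_sd: float = 0.5,
    resid_sd: float = 0.5,
    baseline: float = 8.0,
):
    """Two-visit panel + metadata with per-(analyte, response) visit shifts.

    ``analyte_effects``: {analyte: {response: (shift_v0, shift_v1)}} added to
    the shared baseline on the log2 scale.
    """
    analytes = list(analyte_effects)
    rows, meta_rows = [], []
    half = n_subjects // len(responses)
    for i in range(n_subjects):
        resp = responses[min(i // half, len(responses) - 1)]
        sid = f"S{i:03d}"
        intercept = rng.normal(0.0, subject_sd)
        for v, visit in enumerate(visits):
            vals = []
            for a in analytes:
                shift = analyte_effects[a].get(resp, (0.0,) * len(visits))[v]
                vals.append(baseline + intercept + shift + rng.normal(0.0, resid_sd))
            rows.append((f"{sid}_{visit}", vals))
            meta_rows.append({"sample_id": f"{sid}_{visit}", "subject": sid,
                              "disease": "PSOR", "arm": arm, "response": resp,
                              "visit": visit, "age": 45.0, "gender": "F"})
    values = pd.DataFrame(dict(rows), index=analytes).T
    panel = AnalytePanel(values=values, lloq=pd.Series(1.0, index=analytes),
                         state="normalized")
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return panel, meta


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
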
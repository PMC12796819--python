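"""Shared constructors for hand-built designs and datasets."""

import numpy as np
import pandas as pd

from lfqminer.maxquant_io import ExperimentDesign
from lfqminer.preprocess import ExpressionDataset


def make_design(reps_per_cond):
    rows, i = [], 0
    for c, n in reps_per_cond.items():
        for r in range(1, n + 1):
            i += 1
            rows.append({"label": f"S{i:02d}", "condition": c, "replicate": r, "order": i})
    return ExperimentDesign(pd.DataFrame(rows))


def make_dataset(values, design, stage="filtered", ids=None):
    ids = ids or [f"p{i}" for i in range(len(values))]
    m = pd.DataFrame(np.asarray(values, float), columns=design.labels, index=ids)
    ann = pd.DataFrame({"gene_name": ids, "protein_ids": ids}, index=m.index)
    return ExpressionDataset(m, design, ann, stage=stage)


def dataset_from_mask(detected, design):
    """Raw-stage dataset whose missingness pattern is the given boolean matrix."""
    values = np.where(np.asarray(detected, bool), 1000.0, np.nan)
    return make_dataset(values, design, stage="raw")
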
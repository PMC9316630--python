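"""Access to the Wisconsin diagnostic breast-cancer dataset.

Uses the copy of the dataset bundled with scikit-learn (569 patients,
30 features, 212 malignant / 357 benign) and rearranges it into the
interval form used here: the ten ``worst`` features as centers, the ten
``se`` (standard-error) fields as radii.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import LabeledDataset, wdbc_to_intervals

__all__ = ["load_wdbc", "load_wdbc_table"]

_FEATURES = (
    "radius",
    "texture",
    "perimeter",
    "area",
    "smoothness",
    "compactness",
    "concavity",
    "concave points",
    "symmetry",
    "fractal dimension",
)


def load_wdbc_table() -> pd.DataFrame:
    """The worst/se/diagnosis columns of the diagnostic dataset."""
    from sklearn.datasets import load_breast_cancer

    bunch = load_breast_cancer()
    df = pd.DataFrame(bunch.data, columns=bunch.feature_names)
    out = {}
    for f in _FEATURES:
        key = f.replace(" ", "_")
        out[f"{key}_worst"] = df[f"worst {f}"].to_numpy()
        out[f"{key}_se"] = df[f"{f} error"].to_numpy()
    # sklearn encodes malignant as target 0
    out["diagnosis"] = np.where(bunch.target == 0, "M", "B")
    return pd.DataFrame(out)


def load_wdbc() -> LabeledDataset:
    """The diagnostic dataset as a 569 x 10 interval matrix with M/B labels."""
    return wdbc_to_intervals(load_wdbc_table())
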
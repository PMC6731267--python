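import numpy as np
import pandas as pd
import pytest

import ringtrack as rt


@pytest.fixture(scope="session")
def small_phantom():
    """A 12-nucleus noise-free phantom field with ground truth."""
    spec = rt.PhantomSpec(n_nuclei=12, field_size_px=(512, 512), seed=3)
    fov, truth = rt.generate_field(spec)
    return spec, fov, truth


@pytest.fixture(scope="session")
def small_phantom_analysed(small_phantom):
    spec, fov, truth = small_phantom
    table, mask, prov = rt.analyse_field(fov)
    return spec, fov, truth, table, mask


def match_table_to_truth(table: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Join accepted per-nucleus rows to ground truth by nearest centroid."""
    acc = table[table["accepted"].astype(bool)].copy()
    tr = truth.set_index("nucleus_id")
    matched = []
    for _, row in acc.iterrows():
        d = np.hypot(
            tr["centroid_row"] - row["centroid_row"],
            tr["centroid_col"] - row["centroid_col"],
        )
        k = d.idxmin()
        assert d.loc[k] <= tr.loc[k, "semi_axis_a"], "unmatched nucleus"
        matched.append(tr.loc[k, "true_phenotype"])
    acc["true_phenotype"] = matched
    return acc


def disc_mask(radius: int, pad: int = 4) -> np.ndarray:
    n = 2 * (radius + pad) + 1
    rr, cc = np.mgrid[:n, :n]
    c = radius + pad
    return (rr - c) ** 2 + (cc - c) ** 2 <= radius**2
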
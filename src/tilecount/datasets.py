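"""Packaged reference data."""

from importlib import resources

import pandas as pd

__all__ = ["load_field_counts"]


def load_field_counts() -> pd.DataFrame:
    """Seven-plant field validation table: per-side raw counts, raw totals,
    operator-average reference counts, and bias-corrected counts.

    Columns: plant_id, side_a, side_b, raw_total, reference, corrected.
    """
    with resources.files("tilecount.data").joinpath("field_counts.csv").open() as fh:
        return pd.read_csv(fh)
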
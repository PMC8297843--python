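"""Round-tripping the used-available table through CSV + JSON sidecar."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .preprocess import UsedAvailableTable

__all__ = ["read_table_csv", "write_table_csv"]


def write_table_csv(table: UsedAvailableTable, csv_path) -> None:
    csv_path = Path(csv_path)
    table.df.to_csv(csv_path, index=False)
    with open(csv_path.with_suffix(".scaling.json"), "w") as fh:
        json.dump(table.scaling_to_json(), fh, indent=1)


def read_table_csv(csv_path) -> UsedAvailableTable:
    """Read a table CSV; the scaling sidecar is ``<stem>.scaling.json`` or
    a ``scaling.json`` next to the CSV."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    sidecar = csv_path.with_suffix(".scaling.json")
    if not sidecar.exists():
        sidecar = csv_path.parent / "scaling.json"
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
        scaling = {k: (v["mean"], v["sd"])
                   for k, v in meta["scaling"].items()}
        reference = meta.get("reference_level", "conifer")
        cover_levels = meta.get("cover_levels", [])
    else:
        scaling = {}
        reference = "conifer"
        cover_levels = [c[len("cover_"):] for c in df.columns
                        if c.startswith("cover_")]
    return UsedAvailableTable(df=df, scaling=scaling,
                              reference_level=reference,
                              cover_levels=cover_levels)
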
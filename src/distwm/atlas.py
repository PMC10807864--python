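"""Per-area anatomical attribute table.

The atlas carries the static biology every normalization depends on: area
volume (mm^3), total neuron density (cells/mm^3), PV interneuron density
(cells/mm^3), the raw hierarchy score (dimensionless, possibly missing for
some areas) and an optional module label. Thalamic nuclei are flagged with
``is_thalamic``; all min-max normalizations use cortical areas only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["AreaAtlas", "ATLAS_COLUMNS"]

ATLAS_COLUMNS = ["name", "volume_mm3", "neuron_density", "pv_density",
                 "hierarchy_raw", "module", "is_thalamic"]


class AreaAtlas:
    """Immutable wrapper around the per-area attribute table.

    Parameters
    ----------
    table : pandas.DataFrame
        Must contain the columns in :data:`ATLAS_COLUMNS`; ``hierarchy_raw``
        and ``module`` may contain missing values (NaN / empty).
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in ATLAS_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"atlas table missing columns: {missing}")
        table = table.reset_index(drop=True).copy()
        table["is_thalamic"] = table["is_thalamic"].astype(bool)
        if table["name"].duplicated().any():
            dupes = table.loc[table["name"].duplicated(), "name"].tolist()
            raise ValueError(f"duplicate area names: {dupes}")
        if (table["volume_mm3"] <= 0).any():
            bad = table.loc[table["volume_mm3"] <= 0, "name"].tolist()
            raise ValueError(f"non-positive volume for areas: {bad}")
        for col in ("neuron_density", "pv_density"):
            if (table[col] < 0).any():
                bad = table.loc[table[col] < 0, "name"].tolist()
                raise ValueError(f"negative {col} for areas: {bad}")
        if table["hierarchy_raw"].isna().all():
            raise ValueError("at least one area must have a raw hierarchy value")
        self.table = table

    # -- basic accessors ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.table)

    @property
    def names(self) -> list[str]:
        return self.table["name"].tolist()

    @property
    def volumes(self) -> np.ndarray:
        return self.table["volume_mm3"].to_numpy(float)

    @property
    def neuron_density(self) -> np.ndarray:
        return self.table["neuron_density"].to_numpy(float)

    @property
    def pv_density(self) -> np.ndarray:
        return self.table["pv_density"].to_numpy(float)

    @property
    def hierarchy_raw(self) -> np.ndarray:
        """Raw hierarchy scores with NaN where unmeasured."""
        return self.table["hierarchy_raw"].to_numpy(float)

    @property
    def is_thalamic(self) -> np.ndarray:
        return self.table["is_thalamic"].to_numpy(bool)

    @property
    def pv_fraction_raw(self) -> np.ndarray:
        """PV cell density divided by total neuron density, per area."""
        d = self.neuron_density
        if (d == 0).any():
            bad = [n for n, z in zip(self.names, d == 0) if z]
            raise ValueError(f"zero neuron density for areas: {bad}")
        return self.pv_density / d

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown area {name!r}")

    def cortical(self) -> "AreaAtlas":
        """Sub-atlas of the cortical (non-thalamic) areas."""
        return AreaAtlas(self.table.loc[~self.is_thalamic])

    def thalamic_table(self) -> pd.DataFrame:
        return self.table.loc[self.is_thalamic].reset_index(drop=True)

    # -- CSV round trip ----------------------------------------------------

    @classmethod
    def from_csv(cls, path) -> "AreaAtlas":
        """Read the atlas CSV (empty cells = missing values)."""
        table = pd.read_csv(path)
        if "module" not in table.columns:
            table["module"] = pd.NA
        if "is_thalamic" in table.columns:
            table["is_thalamic"] = table["is_thalamic"].fillna(False).astype(bool)
        else:
            table["is_thalamic"] = False
        return cls(table)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def __repr__(self) -> str:
        n_th = int(self.is_thalamic.sum())
        return f"AreaAtlas({len(self)} areas, {n_th} thalamic)"
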
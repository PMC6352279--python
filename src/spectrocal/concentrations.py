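"""Reference concentration table (component x sample, mg/g) with missing entries.

The package ships a transcription of the published HPLC-UV reference
concentrations for the ten *Arnicae flos* samples (labelled A-J): fourteen
components -- five phenolic acids, the sesquiterpene-lactone fraction and
eight flavonoids -- each with a concentration in mg per g of dry material and
a reported standard deviation. Entries printed as "-" (not quantified) are
stored as missing and excluded from any calibration involving that component.

The SD column is stored but not used in modelling; the source labels it a
relative standard deviation while heading the column "SD", and the ambiguity
cannot be resolved from the printed material alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConcentrationTable",
    "ConcentrationFormatError",
    "load_concentration_table",
    "packaged_concentration_path",
]

N_COMPONENTS = 14


class ConcentrationFormatError(ValueError):
    """Raised for malformed concentration tables."""


@dataclass(frozen=True)
class ConcentrationTable:
    """Component x sample concentration matrix with missing-value support.

    Attributes
    ----------
    values : pandas.DataFrame
        Concentrations in mg/g; rows indexed by component index (1..14),
        columns by sample label; NaN marks a missing entry.
    sd : pandas.DataFrame
        Reported standard deviations, same shape; stored but unused in
        modelling.
    component_names : dict[int, str]
        Component index -> descriptive name.
    """

    values: pd.DataFrame
    sd: pd.DataFrame
    component_names: dict[int, str]

    def __post_init__(self) -> None:
        idx = list(self.values.index)
        if len(set(idx)) != len(idx):
            raise ConcentrationFormatError("duplicate component indices")
        with np.errstate(invalid="ignore"):
            if (self.values.to_numpy(dtype=float) < 0).any():
                raise ConcentrationFormatError("negative concentration")

    @property
    def components(self) -> list[int]:
        return [int(i) for i in self.values.index]

    @property
    def samples(self) -> list[str]:
        return [str(s) for s in self.values.columns]

    def component_series(self, component: int) -> pd.Series:
        """Concentrations of one component over all samples (NaN = missing)."""
        if component not in self.values.index:
            raise KeyError(f"unknown component index {component}")
        return self.values.loc[component]

    def concentration(self, component: int, sample: str) -> float:
        """Single entry in mg/g; NaN if the entry is missing."""
        return float(self.values.at[component, sample])

    def name_of(self, component: int) -> str:
        return self.component_names[int(component)]


def packaged_concentration_path() -> Path:
    """Path of the packaged reference concentration fixture."""
    return Path(
        resources.files("spectrocal.data") / "arnica_flos_concentrations.csv"
    )


def load_concentration_table(path=None) -> ConcentrationTable:
    """Load a concentration table from CSV.

    The file is long-form with columns ``component_index, component_name,
    sample, concentration_mg_g, sd``; empty strings mark missing entries.
    With no argument, the packaged reference table (14 components x 10
    samples) is loaded.
    """
    path = packaged_concentration_path() if path is None else Path(path)
    df = pd.read_csv(path, dtype={"sample": str})
    required = {"component_index", "component_name", "sample", "concentration_mg_g", "sd"}
    if not required.issubset(df.columns):
        raise ConcentrationFormatError(
            f"concentration file must have columns {sorted(required)}"
        )
    try:
        df["component_index"] = df["component_index"].astype(int)
    except (ValueError, TypeError) as exc:
        raise ConcentrationFormatError(f"malformed component index: {exc}") from exc
    for col in ("concentration_mg_g", "sd"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            comp = int(df.loc[bad, "component_index"].iloc[0])
            raise ConcentrationFormatError(
                f"component {comp}: cannot parse {col} value "
                f"{df.loc[bad, col].iloc[0]!r}"
            )
        df[col] = numeric
    names: dict[int, str] = {}
    for idx, grp in df.groupby("component_index"):
        uniq = grp["component_name"].unique()
        if len(uniq) != 1:
            raise ConcentrationFormatError(
                f"component {idx}: inconsistent names {list(uniq)}"
            )
        names[int(idx)] = str(uniq[0])
    samples = list(dict.fromkeys(df["sample"]))
    values = df.pivot(index="component_index", columns="sample", values="concentration_mg_g")
    sd = df.pivot(index="component_index", columns="sample", values="sd")
    values = values.reindex(columns=samples)
    sd = sd.reindex(columns=samples)
    with np.errstate(invalid="ignore"):
        neg = values.lt(0)
    if neg.any().any():
        first = int(values.index[neg.any(axis=1)][0])
        raise ConcentrationFormatError(f"component {first}: negative concentration")
    return ConcentrationTable(values=values, sd=sd, component_names=names)
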
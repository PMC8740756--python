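"""Yield quantification: per-milligram molecule counts, sediment/resin
mass correction, and spike-in library-preparation efficiency.

Impregnated blocks are drilled as a sediment+resin composite; the
sediment/resin mass ratio (dehydrated mass before impregnation divided by
drilled mass after) converts drilled mass to effective sediment mass so
yields are comparable to loose-sediment extractions. Library efficiency is
the conversion rate of a synthetic spike-in oligonucleotide of known copy
number added before library preparation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd


def sediment_resin_ratio(
    dehydrated_mass_mg: float, drilled_mass_mg: float
) -> tuple[float, bool]:
    """(ratio, flagged): dehydrated/drilled mass ratio.

    A ratio above 1 is physically suspect (it would imply the drilled
    composite weighs less than the sediment alone) and is returned
    unclamped but flagged.
    """
    if dehydrated_mass_mg <= 0 or drilled_mass_mg <= 0:
        raise ValueError("masses must be positive")
    ratio = dehydrated_mass_mg / drilled_mass_mg
    return ratio, ratio > 1.0


def molecules_per_mg(
    total_molecules: float, mass_mg: float, ratio: float = 1.0
) -> float:
    """Molecules per milligram of (effective) sediment:
    total / (mass × ratio)."""
    if total_molecules < 0:
        raise ValueError("total_molecules must be non-negative")
    effective = mass_mg * ratio
    if effective <= 0:
        raise ValueError("effective sediment mass must be positive")
    return total_molecules / effective


def library_efficiency(spike_recovered: float, spike_input: float) -> float:
    """Spike-in conversion rate (molecule-count ratio) in [0, 1]."""
    if spike_input <= 0:
        raise ValueError("spike_input must be positive")
    if spike_recovered < 0:
        raise ValueError("spike_recovered must be non-negative")
    if spike_recovered > spike_input:
        raise ValueError("recovered more spike-in copies than were added")
    return spike_recovered / spike_input


@dataclass
class LibraryQuant:
    """Per-sample quantification record."""

    sample_id: str
    total_molecules: float
    drilled_mass_mg: float
    sediment_resin_ratio: float
    spike_in_input: float
    spike_in_recovered: float

    def __post_init__(self) -> None:
        if not 0 < self.sediment_resin_ratio:
            raise ValueError("sediment_resin_ratio must be positive")

    @property
    def effective_sediment_mg(self) -> float:
        return self.drilled_mass_mg * self.sediment_resin_ratio

    @property
    def molecules_per_mg(self) -> float:
        return molecules_per_mg(
            self.total_molecules, self.drilled_mass_mg,
            self.sediment_resin_ratio,
        )

    @property
    def efficiency(self) -> float:
        return library_efficiency(self.spike_in_recovered, self.spike_in_input)


def quantify_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Add derived quantities to a quant table (see column names below)."""
    required = {"sample_id", "total_molecules", "drilled_mass_mg",
                "sediment_resin_ratio", "spike_in_input", "spike_in_recovered"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"quant table missing columns: {sorted(missing)}")
    out = df.copy()
    recs = [
        LibraryQuant(
            sample_id=str(r.sample_id),
            total_molecules=float(r.total_molecules),
            drilled_mass_mg=float(r.drilled_mass_mg),
            sediment_resin_ratio=float(r.sediment_resin_ratio),
            spike_in_input=float(r.spike_in_input),
            spike_in_recovered=float(r.spike_in_recovered),
        )
        for r in df.itertuples()
    ]
    out["effective_sediment_mg"] = [r.effective_sediment_mg for r in recs]
    out["molecules_per_mg"] = [r.molecules_per_mg for r in recs]
    out["efficiency"] = [r.efficiency for r in recs]
    return out


def quantify_tsv(path_in: str | Path, path_out: str | Path) -> pd.DataFrame:
    df = quantify_frame(pd.read_csv(path_in, sep="\t"))
    df.to_csv(path_out, sep="\t", index=False)
    return df
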
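"""SOM and carbonate content from loss-on-ignition mass measurements.

Loss-on-ignition (LOI) quantifies soil organic matter (SOM) as the mass
fraction lost when a dried sample is combusted at 550 degC.  A sequential
second combustion near 990 degC decomposes calcium carbonate, releasing CO2;
the extra mass loss between the two steps quantifies CaCO3 content.

Masses are in grams per crucible.  Drying metadata (60/70/105 degC oven or
freeze-drying) is carried as provenance only: the accepted drying procedures
all yield a fully dried sample, and the computation never depends on them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

__all__ = [
    "MassMeasurements",
    "compute_som",
    "compute_caco3",
    "process_mass_table",
    "CO2_TO_CACO3",
    "CO3_TO_CACO3",
]

#: Mass of CaCO3 per mass of CO2 evolved on decomposition (100.09/44.01).
CO2_TO_CACO3 = 100.0 / 44.0

#: Alternative factor on the carbonate-ion basis (mass CaCO3 per mass CO3).
CO3_TO_CACO3 = 1.36


@dataclass(frozen=True)
class MassMeasurements:
    """Crucible masses through a (sequential) LOI run.

    ``dry_mass`` is the post-drying, pre-combustion sample mass;
    ``mass_post_550`` the mass after the 550 degC organic-matter combustion;
    ``mass_post_990`` (optional) the mass after the ~990 degC carbonate step.
    """

    dry_mass: float
    mass_post_550: float
    mass_post_990: Optional[float] = None
    drying_procedure: str = ""  # provenance only; never enters a computation

    def __post_init__(self) -> None:
        if not self.dry_mass > 0:
            raise ValueError("dry_mass must be positive")
        if self.mass_post_550 > self.dry_mass:
            raise ValueError(
                f"mass after 550 degC ({self.mass_post_550} g) exceeds dry mass "
                f"({self.dry_mass} g): combustion cannot add mass"
            )
        if self.mass_post_550 < 0:
            raise ValueError("mass_post_550 cannot be negative")
        if self.mass_post_990 is not None and self.mass_post_990 > self.mass_post_550:
            raise ValueError(
                "mass after 990 degC exceeds mass after 550 degC: "
                "sequential combustion cannot add mass"
            )


def compute_som(m: MassMeasurements) -> float:
    """SOM content (%) as mass lost at 550 degC relative to dry mass."""
    return 100.0 * (m.dry_mass - m.mass_post_550) / m.dry_mass


def compute_caco3(m: MassMeasurements, stoich_factor: float = CO2_TO_CACO3) -> float:
    """CaCO3 content (%) from the sequential 550-990 degC mass loss.

    The mass lost between the two combustion steps is evolved CO2; the
    stoichiometric factor converts it to CaCO3 mass.  The default (100/44)
    is the CO2 basis; pass :data:`CO3_TO_CACO3` (1.36) for the
    carbonate-ion convention.
    """
    if m.mass_post_990 is None:
        raise ValueError("CaCO3 requires the post-990 degC mass")
    return 100.0 * (m.mass_post_550 - m.mass_post_990) / m.dry_mass * stoich_factor


def process_mass_table(
    table: pd.DataFrame, stoich_factor: float = CO2_TO_CACO3
) -> pd.DataFrame:
    """Append ``som`` (and ``caco3`` where possible) columns to a mass table.

    Expects columns ``dry_mass`` and ``mass_post_550``; ``mass_post_990`` is
    optional and may be missing per row.  Returns a copy with the computed
    columns appended; all other columns pass through unchanged.
    """
    required = {"dry_mass", "mass_post_550"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"mass table lacks column(s): {sorted(missing)}")
    out = table.copy()
    som = []
    caco3 = []
    has_990 = "mass_post_990" in table.columns
    for _, row in table.iterrows():
        m990 = row["mass_post_990"] if has_990 and pd.notna(row.get("mass_post_990")) else None
        m = MassMeasurements(row["dry_mass"], row["mass_post_550"], m990)
        som.append(compute_som(m))
        caco3.append(compute_caco3(m, stoich_factor) if m990 is not None else float("nan"))
    out["som"] = som
    if has_990:
        out["caco3"] = caco3
    return out
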
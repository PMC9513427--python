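"""Reverse-transcription reagent volume planning.

Given per-sample RNA concentrations (replicate measurements in ng/ul) and a
kit recipe expressed per ug of input RNA, compute for each sample the RNA
volume delivering the requested mass, the fixed kit-component volumes, and
water to bring the reaction to a fixed total volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass(frozen=True)
class RTRecipe:
    """Kit recipe: component volumes per ug RNA, plus the reaction scalars.

    Attributes
    ----------
    components : dict
        Maps component name to ul required per ug of input RNA
        (e.g. ``{"SuperMix": 4.0, "gDNARemover": 1.0}``).
    rna_mass_ug : float
        Total RNA mass per reaction, in ug.
    total_volume_ul : float
        Final reaction volume, in ul; water fills the remainder.
    """

    components: dict = field(default_factory=dict)
    rna_mass_ug: float = 1.0
    total_volume_ul: float = 20.0

    def __post_init__(self):
        if self.rna_mass_ug <= 0:
            raise ValueError("rna_mass_ug must be positive")
        if self.total_volume_ul <= 0:
            raise ValueError("total_volume_ul must be positive")
        if any(v < 0 for v in self.components.values()):
            raise ValueError("component volumes must be non-negative")

    @property
    def component_volumes(self) -> dict:
        """Per-reaction component volumes (ul) at this RNA mass."""
        return {name: per_ug * self.rna_mass_ug for name, per_ug in self.components.items()}


def average_concentration(conc_replicates) -> float:
    """Arithmetic mean of replicate concentration measurements, full precision.

    Rounding happens only at display; planning uses the exact mean so that
    e.g. replicates (163, 163, 164) give an RNA volume of
    2000/163.333... = 12.24 ul rather than 2000/163.33 = 12.25 ul.
    """
    reps = list(conc_replicates)
    if not reps:
        raise ValueError("at least one concentration replicate is required")
    if any(c <= 0 for c in reps):
        raise ValueError("concentrations must be positive")
    return sum(reps) / len(reps)


def plan_rt(conc_table: pd.DataFrame, recipe: RTRecipe) -> pd.DataFrame:
    """Build the per-sample reverse-transcription volume table.

    For each sample: ``rna_vol = round(1000 * rna_mass_ug / avg_conc, 2)``
    (half-to-even at 2 dp), each component at its per-ug volume times the RNA
    mass, and water as the exact remainder to ``total_volume_ul`` — so rows
    always sum to the total.

    Parameters
    ----------
    conc_table : DataFrame
        Columns ``sample`` and ``conc`` (one row per replicate measurement).
    recipe : RTRecipe

    Raises
    ------
    ValueError
        If any sample is too dilute: the RNA volume plus fixed component
        volumes exceed the total reaction volume (water would be negative).
    """
    if not {"sample", "conc"}.issubset(conc_table.columns):
        raise ValueError("concentration table needs 'sample' and 'conc' columns")
    comp_vols = recipe.component_volumes
    fixed = sum(comp_vols.values())
    rows = []
    # preserve first-appearance sample order
    order = conc_table["sample"].drop_duplicates().tolist()
    grouped = conc_table.groupby("sample", sort=False)["conc"]
    for sample in order:
        avg = average_concentration(grouped.get_group(sample).tolist())
        rna_vol = round(1000.0 * recipe.rna_mass_ug / avg, 2)
        water = recipe.total_volume_ul - rna_vol - fixed
        if water < 0:
            raise ValueError(
                f"sample {sample!r}: concentration {avg:.2f} ng/ul is too low — "
                f"RNA volume {rna_vol:.2f} ul + components {fixed:.2f} ul exceed "
                f"total {recipe.total_volume_ul:.2f} ul"
            )
        row = {"sample": sample, "avg_conc": avg, "rna_vol": rna_vol}
        row.update(comp_vols)
        row["water_vol"] = round(water, 10)
        row["total_vol"] = recipe.total_volume_ul
        rows.append(row)
    plan = pd.DataFrame(rows)
    plan.attrs["components"] = list(comp_vols)
    return plan
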
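"""Refractive-index to buoyant-density conversion and heavy/light pooling.

After isopycnic centrifugation each CsCl fraction's refractive index is read
on a refractometer and converted to buoyant density through an affine
calibration, rho = slope*RI - intercept. Fractions whose densities fall in
the heavy window (1.7296-1.7491 g/ml, enriched for 13C-labelled DNA) or the
light window (1.7123-1.7216 g/ml, unlabelled DNA) are pooled per vial;
fractions between the windows are discarded, as in standard SIP practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .sipsim import FRACTION_TABLE_COLUMNS

__all__ = [
    "PoolWindows",
    "PoolPair",
    "density_from_ri",
    "ri_from_density",
    "pool_fractions",
    "density_profile",
    "taxon_columns",
    "write_pools",
]

DEFAULT_RI_SLOPE = 10.9276
DEFAULT_RI_INTERCEPT = 13.593

#: CsCl refractive indices outside this range are physically implausible.
_PLAUSIBLE_RI = (1.3, 1.5)


def density_from_ri(ri, slope: float = DEFAULT_RI_SLOPE, intercept: float = DEFAULT_RI_INTERCEPT):
    """Buoyant density (g/ml) from a refractometer reading: slope*ri - intercept."""
    lo, hi = _PLAUSIBLE_RI
    try:
        out_of_range = bool(ri < lo) or bool(ri > hi)
    except ValueError:  # array input
        out_of_range = bool((ri < lo).any() or (ri > hi).any())
    if out_of_range:
        warnings.warn(f"refractive index outside plausible CsCl range {_PLAUSIBLE_RI}", stacklevel=2)
    return slope * ri - intercept


def ri_from_density(density, slope: float = DEFAULT_RI_SLOPE, intercept: float = DEFAULT_RI_INTERCEPT):
    """Inverse of :func:`density_from_ri`."""
    return (density + intercept) / slope


@dataclass(frozen=True)
class PoolWindows:
    """Closed density intervals defining the heavy and light DNA pools."""

    heavy: tuple = (1.7296, 1.7491)
    light: tuple = (1.7123, 1.7216)

    def __post_init__(self):
        for name, (lo, hi) in (("heavy", self.heavy), ("light", self.light)):
            if not lo <= hi:
                raise ValueError(f"{name} window inverted: {lo} > {hi}")
        if not self.heavy[0] > self.light[1]:
            raise ValueError("heavy window must lie strictly above the light window")


@dataclass
class PoolPair:
    """Per-vial pooled heavy/light taxon counts.

    A vial is usable only if at least one fraction fell in each window;
    an unusable vial is flagged explicitly, never silently dropped.
    """

    vial_id: str
    heavy_counts: pd.Series
    light_counts: pd.Series
    heavy_n: int
    light_n: int

    @property
    def usable(self) -> bool:
        return self.heavy_n >= 1 and self.light_n >= 1


def taxon_columns(table: pd.DataFrame):
    """Taxon count columns of a fraction table (everything non-fixed)."""
    return [c for c in table.columns if c not in FRACTION_TABLE_COLUMNS]


def pool_fractions(fractions: pd.DataFrame, windows: PoolWindows = PoolWindows()) -> PoolPair:
    """Pool one vial's fractions into heavy and light windows (inclusive bounds).

    Window endpoints are inclusive because the study's printed window
    bounds are themselves densities of pooled fractions.
    """
    vials = fractions["vial_id"].unique()
    if len(vials) != 1:
        raise ValueError(f"pool_fractions expects one vial, got {list(vials)}")
    taxa = taxon_columns(fractions)
    d = fractions["density_g_ml"]
    in_heavy = (d >= windows.heavy[0]) & (d <= windows.heavy[1])
    in_light = (d >= windows.light[0]) & (d <= windows.light[1])
    return PoolPair(
        vial_id=str(vials[0]),
        heavy_counts=fractions.loc[in_heavy, taxa].sum(),
        light_counts=fractions.loc[in_light, taxa].sum(),
        heavy_n=int(in_heavy.sum()),
        light_n=int(in_light.sum()),
    )


def density_profile(fractions: pd.DataFrame) -> pd.DataFrame:
    """Density vs retrieved-DNA profile, sorted by descending density."""
    if len(fractions) < 2:
        raise ValueError("density profile needs >= 2 fractions")
    return (
        fractions[["density_g_ml", "dna_ng"]]
        .sort_values("density_g_ml", ascending=False)
        .reset_index(drop=True)
    )


def write_pools(pools, path) -> None:
    """Write pooled counts as TSV (vial_id, pool, taxon, count)."""
    rows = []
    for p in pools:
        for pool_name, counts in (("heavy", p.heavy_counts), ("light", p.light_counts)):
            for taxon, count in counts.items():
                rows.append({"vial_id": p.vial_id, "pool": pool_name, "taxon": taxon, "count": int(count)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
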
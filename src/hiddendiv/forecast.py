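"""Ratio-based global species-richness forecast with uncertainty bounds.

The forecast scales a consensus species count E from a data set assumed to
cover a fraction 1/area_ratio of the group's global range.  New-phenotype
species (c of them in the data) are assumed proportional to area, adding
(area_ratio − 1)·c still to be found.  Unsequenced described species D are
split by range breadth: narrow endemics enter once (their hidden diversity
is not extrapolated), while pantropical and wide-ranging species are
multiplied by class-mean hidden-diversity ratios and by the area ratio:

    G = E + D_narrow + (area_ratio − 1)·c
          + area_ratio · (D_pantropical·R_pantropical + D_wide·R_wide)

With an area ratio of 4 this is the printed form
G = E + D_narrow + 3·c + 4·[D_pan·R_pan + D_wide·R_wide].  Note the
asymmetry: D_narrow (and E itself) are deliberately *not* scaled by area —
the uncertainty bounds absorb that conservatism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from ._util import round_half_up

__all__ = ["ForecastInputs", "ForecastResult", "compute_G", "compute_bounds", "sensitivity_table"]


@dataclass(frozen=True)
class ForecastInputs:
    """All scalars of the global-richness formula."""

    E: int
    c: int
    D_pantropical: int
    D_wide: int
    D_narrow: int
    R_pantropical: float
    R_wide: float
    area_ratio: float = 4.0
    uncertainty_fraction: float = 0.25
    E_low: int | None = None
    E_high: int | None = None
    area_ratio_low: float | None = None
    area_ratio_high: float | None = None
    scale_narrow: bool = False  # exploratory: also scale D_narrow by area_ratio

    def __post_init__(self) -> None:
        for name in ("E", "c", "D_pantropical", "D_wide", "D_narrow"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")
        for name in ("R_pantropical", "R_wide", "area_ratio"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be ≥ 1")
        if not 0 <= self.uncertainty_fraction < 1:
            raise ValueError("uncertainty_fraction must lie in [0, 1)")
        if self.E_low is not None and self.E_high is not None:
            if not self.E_low <= self.E <= self.E_high:
                raise ValueError("E bounds must bracket E")


@dataclass(frozen=True)
class ForecastResult:
    G_point: int
    G_raw: float
    components: dict[str, float] = field(hash=False)
    lower: int | None = None
    upper: int | None = None

    def __post_init__(self) -> None:
        total = sum(self.components.values())
        if abs(total - self.G_raw) > 1e-9:
            raise ValueError("components must sum to G_raw")
        if self.lower is not None and self.upper is not None:
            if not self.lower <= self.G_point <= self.upper:
                raise ValueError("bounds must bracket the point estimate")


def compute_G(inputs: ForecastInputs) -> ForecastResult:
    """Point forecast of global species richness.

    The half-up rounded integer is reported alongside the raw value and a
    component breakdown (consensus count, narrow unsequenced, new-species
    term, hidden-diversity term).
    """
    r = inputs.area_ratio
    narrow_term = float(inputs.D_narrow) * (r if inputs.scale_narrow else 1.0)
    new_term = (r - 1.0) * inputs.c
    hidden_term = r * (
        inputs.D_pantropical * inputs.R_pantropical + inputs.D_wide * inputs.R_wide
    )
    components = {
        "consensus_species": float(inputs.E),
        "narrow_unsequenced": narrow_term,
        "new_species": new_term,
        "hidden_diversity": hidden_term,
    }
    g_raw = sum(components.values())
    return ForecastResult(G_point=int(round_half_up(g_raw)), G_raw=g_raw, components=components)


def compute_bounds(
    inputs: ForecastInputs, result: ForecastResult, mode: str = "multiplicative"
) -> ForecastResult:
    """Attach a prediction range to a point forecast.

    ``multiplicative`` (default): G_point·(1 ∓ uncertainty_fraction),
    rounded half-up — applied to the already-rounded point estimate so a
    25% band on 2,356 gives exactly 1,767 and 2,945.  ``recompute``:
    re-evaluate the formula at (E_low, area_ratio_low) and
    (E_high, area_ratio_high).
    """
    if mode == "multiplicative":
        u = inputs.uncertainty_fraction
        lower = int(round_half_up(result.G_point * (1.0 - u)))
        upper = int(round_half_up(result.G_point * (1.0 + u)))
    elif mode == "recompute":
        needed = (inputs.E_low, inputs.E_high, inputs.area_ratio_low, inputs.area_ratio_high)
        if any(v is None for v in needed):
            raise ValueError("recompute mode needs E and area-ratio bounds")
        lo_in = _replace(inputs, E=inputs.E_low, area_ratio=inputs.area_ratio_low)
        hi_in = _replace(inputs, E=inputs.E_high, area_ratio=inputs.area_ratio_high)
        lower = compute_G(lo_in).G_point
        upper = compute_G(hi_in).G_point
    else:
        raise ValueError(f"unknown bounds mode {mode!r}")
    return ForecastResult(
        G_point=result.G_point,
        G_raw=result.G_raw,
        components=result.components,
        lower=lower,
        upper=upper,
    )


def _replace(inputs: ForecastInputs, **kw) -> ForecastInputs:
    import dataclasses

    return dataclasses.replace(inputs, **kw)


def sensitivity_table(
    inputs: ForecastInputs,
    area_ratios: Sequence[float] = (3.0, 4.0, 5.0),
    R_pantropical_values: Iterable[float] | None = None,
    R_wide_values: Iterable[float] | None = None,
) -> list[dict]:
    """Forecast over a grid of area ratios and hidden-diversity ratios.

    One row per grid point; G is affine in the area ratio and non-decreasing
    in every multiplicative input, so the table exposes how strongly the
    forecast leans on the sampled-fraction assumption.
    """
    if not area_ratios:
        raise ValueError("empty area-ratio grid")
    r_pans = list(R_pantropical_values) if R_pantropical_values else [inputs.R_pantropical]
    r_wides = list(R_wide_values) if R_wide_values else [inputs.R_wide]
    rows = []
    for ar in area_ratios:
        for rp in r_pans:
            for rw in r_wides:
                res = compute_G(
                    _replace(inputs, area_ratio=ar, R_pantropical=rp, R_wide=rw)
                )
                rows.append(
                    {
                        "area_ratio": ar,
                        "R_pantropical": rp,
                        "R_wide": rw,
                        "G_point": res.G_point,
                        "G_raw": res.G_raw,
                    }
                )
    return rows
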
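"""Trait summaries → per-root-order growth-model parameters.

Order statistics (min / median / max) of extracted architecture traits over
a sample of images, together with the elapsed observation time t (days),
are mapped to the parameter set of a CRootBox-family stochastic root growth
model, separately for primary, secondary and tertiary root orders.

The trait→parameter equations are kept in a declarative table
(``EQUATIONS``) so individual operand groupings can be revised in one line.
Trait tables arrive in mm / mm²; operands are converted to cm / cm² before
the equations are applied, and the radial growth rate a_r is reported in
mm·h⁻¹ as is conventional for that parameter.

Parameter semantics (lengths in cm unless noted):

=========  ==================================================================
l_b        unbranched zone at the base of an axis, before the first lateral
l_a        unbranched zone behind the tip (laterals never emerge there)
l_n        spacing between successive lateral branch sites
l_max      asymptotic maximal axis length (never surpassed)
r          initial elongation rate, cm·d⁻¹
delta_x    axial resolution of growth sub-segments
sigma      SD of the random angular change per unit length, cm⁻¹ convention
theta      lateral insertion angle, degrees
N          number of trials (tropism strength), dimensionless
a_i        initial axis radius
a_max      maximal axis radius
a_r        radius growth rate, mm·h⁻¹
=========  ==================================================================
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .trait_extraction import TraitRecord

__all__ = [
    "TraitSummary",
    "RootOrderContext",
    "RootTypeParameters",
    "PARAMETER_KEYS",
    "summarize_traits",
    "derive_root_type_parameters",
    "derive_all_orders",
    "validate_parameters",
    "write_parameters",
    "read_parameters",
]

PARAMETER_KEYS = (
    "l_b", "l_a", "l_n", "l_max", "r", "delta_x",
    "sigma", "theta", "N", "a_i", "a_max", "a_r",
)

#: Fixed axial resolution per root order (cm).
DELTA_X_BY_ORDER = {1: 0.5, 2: 0.1, 3: 0.1}

#: Traits the equations consume, mapped from trait-table column names.
OPERAND_TRAITS = {
    "NumberRoot": "number_of_root_tips",
    "RootLength": "total_root_length",
    "SurfaceArea": "surface_area",
    "Depth": "max_depth",
    "Diameter": "avg_diameter",
    "AverageRootOrientation": "avg_root_orientation",
}

# mm→cm conversion exponent per operand (lengths 1, areas 2, counts/angles 0).
_MM_TO_CM_POWER = {
    "NumberRoot": 0,
    "RootLength": 1,
    "SurfaceArea": 2,
    "Depth": 1,
    "Diameter": 1,
    "AverageRootOrientation": 0,
}

HOURS_PER_DAY = 24.0
MM_PER_CM = 10.0


@dataclass(frozen=True)
class RootOrderContext:
    """Root order 1 (primary), 2 (secondary) or 3 (tertiary)."""

    root_order: int

    def __post_init__(self) -> None:
        if self.root_order not in (1, 2, 3):
            raise ValueError(
                f"root_order must be 1, 2 or 3, got {self.root_order}"
            )

    @property
    def inverse_root_order(self) -> float:
        return 1.0 / self.root_order


@dataclass
class TraitSummary:
    """Per-trait {min, median, max} over a set of records, plus elapsed days.

    Values are stored in cm-based units ready for the parameter equations;
    ``orientation_sd`` is the sample SD (ddof=1) of per-record average
    orientations, in degrees.
    """

    stats: dict
    t: float
    orientation_sd: float
    n_records: int

    def op(self, trait: str, which: str) -> float:
        return self.stats[trait][which]


@dataclass
class RootTypeParameters:
    """One root order's growth-model parameter set."""

    l_b: float
    l_a: float
    l_n: float
    l_max: float
    r: float
    delta_x: float
    sigma: float
    theta: float
    N: int
    a_i: float
    a_max: float
    a_r: float
    root_order: int = 1

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in PARAMETER_KEYS}


def summarize_traits(records: list[TraitRecord], t: float) -> TraitSummary:
    """Order statistics of the equation operands over a record sample.

    Median uses the midpoint-of-two convention for even counts. Raises on
    empty input or non-positive elapsed time.
    """
    if not records:
        raise ValueError("need at least one trait record")
    if not t > 0:
        raise ValueError("elapsed time t must be > 0 days")
    stats = {}
    for operand, column in OPERAND_TRAITS.items():
        vals = np.asarray([getattr(rec, column) for rec in records], dtype=float)
        factor = MM_PER_CM ** _MM_TO_CM_POWER[operand]
        vals = vals / factor
        stats[operand] = {
            "min": float(np.min(vals)),
            "median": float(np.median(vals)),
            "max": float(np.max(vals)),
        }
    ori = np.asarray(
        [rec.avg_root_orientation for rec in records], dtype=float
    )
    ori_sd = float(np.std(ori, ddof=1)) if ori.size > 1 else 0.0
    return TraitSummary(stats=stats, t=float(t), orientation_sd=ori_sd,
                        n_records=len(records))


def _safe_div(num: float, den: float, operand: str) -> float:
    if den == 0:
        raise ZeroDivisionError(f"division by zero operand: {operand}")
    return num / den


# Declarative trait→parameter equation table. Each entry maps a summary s and
# an order context o to a value in the parameter's own unit. The printed
# source of these groupings lost its fraction bars, so each row is a single
# expression that can be revised independently (see docs/methods.md).
EQUATIONS = {
    "l_b": lambda s, o: _safe_div(
        s.op("RootLength", "min"), s.op("NumberRoot", "min"), "NumberRoot_min"
    ) * o.inverse_root_order,
    "l_a": lambda s, o: _safe_div(
        s.op("RootLength", "max") - s.op("RootLength", "median"),
        s.op("NumberRoot", "max"), "NumberRoot_max",
    ) * o.inverse_root_order,
    # The printed /100 in the l_n source is the mm²→cm² area conversion,
    # already applied to the SurfaceArea operand here.
    "l_n": lambda s, o: _safe_div(
        s.op("SurfaceArea", "median"),
        s.op("NumberRoot", "median"), "NumberRoot_median",
    ) * 5.0 / o.root_order**2,
    "l_max": lambda s, o: s.op("Depth", "max") * 1.2 / o.root_order**3,
    "r": lambda s, o: (
        (s.op("RootLength", "max") - s.op("RootLength", "min")) / s.t
    ) * 1.5 / o.root_order,
    "delta_x": lambda s, o: DELTA_X_BY_ORDER[o.root_order],
    "sigma": lambda s, o: s.orientation_sd,
    "theta": lambda s, o: s.op("AverageRootOrientation", "median"),
    "N": lambda s, o: o.root_order,
    "a_i": lambda s, o: _safe_div(
        s.op("Diameter", "min"), s.op("NumberRoot", "min"), "NumberRoot_min"
    ) / o.root_order**2,
    "a_max": lambda s, o: s.op("Diameter", "max") / (5.0 * o.root_order**2),
}


def derive_root_type_parameters(
    summary: TraitSummary, order: RootOrderContext
) -> RootTypeParameters:
    """Apply the equation table for one root order.

    a_r = (a_max − a_i)/t is evaluated after its operands and converted from
    cm·d⁻¹ to the conventional mm·h⁻¹. Negative derived lengths (possible if
    an operand grouping is mis-specified for a given sample) raise.
    """
    values = {name: eq(summary, order) for name, eq in EQUATIONS.items()}
    values["a_r"] = (
        (values["a_max"] - values["a_i"]) / summary.t
    ) * MM_PER_CM / HOURS_PER_DAY
    for name in ("l_b", "l_a", "l_n", "l_max", "r", "a_i", "a_max"):
        if values[name] < 0:
            raise ValueError(f"derived parameter {name} is negative: {values[name]}")
    values["N"] = int(values["N"])
    return RootTypeParameters(root_order=order.root_order, **values)


def derive_all_orders(
    summary: TraitSummary, n_orders: int = 3
) -> dict[int, RootTypeParameters]:
    if not 1 <= n_orders <= 3:
        raise ValueError("n_orders must be between 1 and 3")
    return {
        k: derive_root_type_parameters(summary, RootOrderContext(k))
        for k in range(1, n_orders + 1)
    }


def validate_parameters(params: RootTypeParameters) -> list[str]:
    """Consistency diagnostics; never mutates, never raises."""
    diags = []
    if params.l_b + params.l_a > params.l_max:
        diags.append(
            "branching zone empty: l_b + l_a "
            f"({params.l_b + params.l_a:.4g}) exceeds l_max ({params.l_max:.4g})"
        )
    if params.r <= 0:
        diags.append(f"elongation rate r not positive: {params.r:.4g}")
    if params.a_i > params.a_max:
        diags.append(
            f"initial radius a_i ({params.a_i:.4g}) exceeds a_max ({params.a_max:.4g})"
        )
    if not 0.0 <= params.theta <= 180.0:
        diags.append(f"insertion angle theta outside [0, 180]: {params.theta:.4g}")
    if params.delta_x <= 0:
        diags.append(f"delta_x not positive: {params.delta_x:.4g}")
    if params.N < 1:
        diags.append(f"tropism trial count N < 1: {params.N}")
    return diags


_UNITS = {
    "l_b": "cm", "l_a": "cm", "l_n": "cm", "l_max": "cm", "r": "cm/d",
    "delta_x": "cm", "sigma": "1/cm", "theta": "deg", "N": "trials",
    "a_i": "cm", "a_max": "cm", "a_r": "mm/h",
}


def write_parameters(params_by_order: dict[int, RootTypeParameters], path) -> None:
    orders = sorted(params_by_order)
    if orders != list(range(1, len(orders) + 1)):
        raise ValueError(f"orders must be contiguous from 1, got {orders}")
    doc = {
        "units": _UNITS,
        "orders": {
            str(k): params_by_order[k].as_dict() for k in orders
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


def read_parameters(path) -> dict[int, RootTypeParameters]:
    """Read a parameter JSON; strict about unknown/missing fields and signs."""
    with open(path) as fh:
        doc = json.load(fh)
    out = {}
    for key, vals in doc["orders"].items():
        order = int(key)
        unknown = set(vals) - set(PARAMETER_KEYS)
        if unknown:
            raise ValueError(f"unknown field(s) {sorted(unknown)} for order {order}")
        missing = set(PARAMETER_KEYS) - set(vals)
        if missing:
            raise ValueError(
                f"missing field(s) {sorted(missing)} for order {order}"
            )
        for name in ("l_b", "l_a", "l_n", "l_max", "r", "a_i", "a_max"):
            if vals[name] < 0:
                raise ValueError(
                    f"negative {name} for order {order}: {vals[name]}"
                )
        out[order] = RootTypeParameters(root_order=order, **{
            k: (int(vals[k]) if k == "N" else float(vals[k]))
            for k in PARAMETER_KEYS
        })
    orders = sorted(out)
    if orders != list(range(1, len(orders) + 1)):
        raise ValueError(f"orders must be contiguous from 1, got {orders}")
    return out
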
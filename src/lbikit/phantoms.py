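"""Liquid optical phantoms: design, coefficient calibration lines, class ranges.

Calibration phantoms are aqueous suspensions of Intralipid 20% (scatterer)
spiked with Naphthol Blue Black (NBB) ink (absorber).  The measured
calibration lines map composition to reference coefficients:

* reduced scattering  mu_s'* = -0.003272 + 2.985451 * C * 20%   (C = Intralipid %)
* absorption          mu_a*  = -0.0816 * A - 0.0624             (A = absorbance)

The absorbance line as printed returns negative values for non-negative
absorbance; the default policy therefore takes the magnitude and floors at
1e-10 (the inversion requires mu_a > 0), while ``literal`` mode keeps the raw
line for auditability.  Nominal coefficient levels are partitioned into
contiguous class ranges — midpoints between neighboring levels — which the
pre-classifier predicts and the constrained inversion uses as bound boxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .diffusion import MU_A_FLOOR
from .errors import AssignmentError, InvalidInputError
from .profiles import LBIParameters

#: The 4 x 14 factorial design of the calibration set.
DEFAULT_SCATTER_LEVELS_PCT = (3.12, 5.2, 7.28, 9.36)
DEFAULT_ABSORBER_LEVELS_PCT = tuple(np.round(np.arange(14) * 0.05, 2))  # 0 .. 0.65%

#: Published reduced-scattering class ranges for the four Intralipid levels
#: (lower, upper) in cm^-1; used by the ``literal_table1`` range policy.
TABLE1_MU_S_RANGES = ((0.1, 2.5), (2.6, 3.6), (3.7, 4.8), (4.9, 6.5))

#: Highest NBB level maps to this nominal absorption coefficient (cm^-1).
MU_A_AT_MAX_NBB = 0.70
MAX_NBB_PCT = 0.65


@dataclass(frozen=True)
class PhantomSpec:
    """Composition of one liquid phantom."""

    intralipid_pct: float
    nbb_pct: float
    absorbance: float | None = None  # measured, optional

    def __post_init__(self):
        if self.intralipid_pct <= 0:
            raise InvalidInputError("intralipid_pct must be > 0")
        if self.nbb_pct < 0:
            raise InvalidInputError("nbb_pct must be >= 0")


@dataclass(frozen=True)
class ClassRange:
    """One contiguous coefficient range with its nominal level."""

    label: int
    lower: float
    upper: float
    nominal: float

    def __post_init__(self):
        if not (self.lower < self.upper):
            raise InvalidInputError(f"empty class range [{self.lower}, {self.upper}]")
        if not (self.lower <= self.nominal <= self.upper):
            raise InvalidInputError("nominal level must lie inside its range")

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclass
class CalibrationSet:
    """Phantom reference matrix joining compositions, coefficients and LBI rows."""

    table: pd.DataFrame  # one row per phantom
    mu_a_classes: list[ClassRange]
    mu_s_classes: list[ClassRange]
    # fitted pre-classification models, attached by lbikit.fda.calibrate_preclassifier
    fda_mu_a: object | None = field(default=None, repr=False)
    fda_mu_s: object | None = field(default=None, repr=False)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def classes_json(self) -> dict:
        def dump(ranges):
            return [
                {"label": c.label, "lower": c.lower, "upper": c.upper, "nominal": c.nominal}
                for c in ranges
            ]

        return {"mu_a": dump(self.mu_a_classes), "mu_s_prime": dump(self.mu_s_classes)}


# ---------------------------------------------------------------------------
# Design and calibration lines
# ---------------------------------------------------------------------------

def design_phantom_grid(
    scatter_levels: Sequence[float] = DEFAULT_SCATTER_LEVELS_PCT,
    absorber_levels: Sequence[float] = DEFAULT_ABSORBER_LEVELS_PCT,
) -> list[PhantomSpec]:
    """Full factorial scattering x absorption phantom design."""
    if len(scatter_levels) == 0 or len(absorber_levels) == 0:
        raise InvalidInputError("level lists must be non-empty")
    return [
        PhantomSpec(intralipid_pct=s, nbb_pct=a)
        for s in scatter_levels
        for a in absorber_levels
    ]


def mu_s_from_intralipid(intralipid_pct: float) -> float:
    """Reduced scattering coefficient (cm^-1) of an Intralipid 20% dilution."""
    if intralipid_pct <= 0:
        raise InvalidInputError("intralipid_pct must be > 0")
    return max(-0.003272 + 2.985451 * intralipid_pct * 0.20, MU_A_FLOOR)


def mu_a_from_absorbance(absorbance: float, policy: str = "magnitude") -> float:
    """Absorption coefficient (cm^-1) from measured absorbance.

    ``magnitude`` (default): |−0.0816·A − 0.0624| floored at 1e-10, giving the
    positive coefficients the rest of the pipeline requires.  ``literal``:
    the raw calibration line, for audit.
    """
    if absorbance < 0:
        raise InvalidInputError("absorbance must be >= 0")
    raw = -0.0816 * absorbance - 0.0624
    if policy == "literal":
        return raw
    if policy == "magnitude":
        return max(abs(raw), MU_A_FLOOR)
    raise InvalidInputError(f"unknown policy {policy!r}")


def mu_a_from_nbb(nbb_pct: float) -> float:
    """Nominal absorption coefficient of an NBB level (linear, 0.65% -> 0.70 cm^-1)."""
    if nbb_pct < 0:
        raise InvalidInputError("nbb_pct must be >= 0")
    return max(nbb_pct * MU_A_AT_MAX_NBB / MAX_NBB_PCT, MU_A_FLOOR)


# ---------------------------------------------------------------------------
# Class ranges
# ---------------------------------------------------------------------------

def class_ranges(levels: Sequence[float], policy: str = "midpoint") -> list[ClassRange]:
    """Partition nominal coefficient levels into contiguous class ranges.

    ``midpoint``: interior boundaries halfway between neighboring levels; the
    first lower bound extends half the first step below (floored at 1e-10)
    and the last upper bound half the last step above.  ``literal_table1``:
    the four published reduced-scattering ranges (requires exactly 4 levels).
    """
    levels = [float(v) for v in levels]
    if any(b <= a for a, b in zip(levels, levels[1:])):
        raise InvalidInputError("levels must be strictly increasing")
    if policy == "literal_table1":
        if len(levels) != len(TABLE1_MU_S_RANGES):
            raise InvalidInputError("literal_table1 policy needs exactly 4 levels")
        return [
            ClassRange(label=i, lower=lo, upper=hi, nominal=lev)
            for i, ((lo, hi), lev) in enumerate(zip(TABLE1_MU_S_RANGES, levels))
        ]
    if policy != "midpoint":
        raise InvalidInputError(f"unknown range policy {policy!r}")
    if len(levels) < 2:
        raise InvalidInputError("midpoint policy needs >= 2 levels")
    out = []
    for i, lev in enumerate(levels):
        half_down = (lev - levels[i - 1]) / 2 if i > 0 else (levels[1] - lev) / 2
        half_up = (levels[i + 1] - lev) / 2 if i < len(levels) - 1 else (lev - levels[i - 1]) / 2
        lower = max(lev - half_down, MU_A_FLOOR)
        out.append(ClassRange(label=i, lower=lower, upper=lev + half_up, nominal=lev))
    return out


def merge_class_ranges(ranges: Sequence[ClassRange], groups: Sequence[Sequence[int]]) -> list[ClassRange]:
    """Merge contiguous class ranges into coarser classes.

    ``groups`` lists member labels per merged class; each merged range spans
    from the first member's lower bound to the last member's upper bound, with
    the nominal at the mean of member nominals.
    """
    by_label = {c.label: c for c in ranges}
    out = []
    for i, members in enumerate(groups):
        cs = [by_label[m] for m in members]
        out.append(
            ClassRange(
                label=i,
                lower=min(c.lower for c in cs),
                upper=max(c.upper for c in cs),
                nominal=float(np.mean([c.nominal for c in cs])),
            )
        )
    return out


def default_mu_a_groups(n_levels: int = 14) -> list[list[int]]:
    """Pairwise merge from the low end, keeping the two highest levels single.

    14 absorption levels collapse to 8 classes: six low pairs plus two
    high singletons.
    """
    if n_levels < 2:
        return [[i] for i in range(n_levels)]
    n_pairs = (n_levels - 2) // 2
    groups = [[2 * i, 2 * i + 1] for i in range(n_pairs)]
    groups += [[i] for i in range(2 * n_pairs, n_levels)]
    return groups


def assign_class(value: float, ranges: Sequence[ClassRange]) -> ClassRange:
    """The class range containing ``value`` (shared boundaries go to the lower class)."""
    for c in ranges:
        if c.contains(value):
            return c
    raise AssignmentError(
        f"value {value:g} falls outside all class ranges "
        f"[{ranges[0].lower:g}, {ranges[-1].upper:g}]"
    )


# ---------------------------------------------------------------------------
# Reference matrix
# ---------------------------------------------------------------------------

def build_reference_matrix(
    specs: Sequence[PhantomSpec],
    lbi_params: Sequence[LBIParameters],
    mu_a_range_policy: str = "midpoint",
    mu_s_range_policy: str = "midpoint",
    mu_a_groups: Sequence[Sequence[int]] | None = "default",
) -> CalibrationSet:
    """Join phantom specs with extracted LBI parameters into a CalibrationSet.

    Reference coefficients come from the calibration lines
    (:func:`mu_s_from_intralipid`, :func:`mu_a_from_nbb`); class partitions
    are built from the distinct nominal levels present in the design, with the
    absorption levels merged into 8 coarser classes by default.
    """
    if len(specs) != len(lbi_params):
        raise InvalidInputError("need exactly one LBIParameters row per phantom spec")
    rows = []
    for spec, p in zip(specs, lbi_params):
        mu_s = mu_s_from_intralipid(spec.intralipid_pct)
        mu_a = (
            mu_a_from_absorbance(spec.absorbance)
            if spec.absorbance is not None
            else mu_a_from_nbb(spec.nbb_pct)
        )
        rows.append(
            {
                "intralipid_pct": spec.intralipid_pct,
                "nbb_pct": spec.nbb_pct,
                "mu_a_star": mu_a,
                "mu_s_star": mu_s,
                **dict(zip(LBIParameters.FEATURE_NAMES, p.as_array())),
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["intralipid_pct", "nbb_pct"], kind="stable"
    ).reset_index(drop=True)

    mu_s_levels = sorted(df["mu_s_star"].unique())
    mu_a_levels = sorted(df["mu_a_star"].unique())
    if len(mu_s_levels) >= 2:
        mu_s_classes = class_ranges(mu_s_levels, mu_s_range_policy)
    else:
        lev = mu_s_levels[0]
        mu_s_classes = [ClassRange(0, max(lev * 0.5, MU_A_FLOOR), lev * 1.5, lev)]
    if len(mu_a_levels) >= 2:
        mu_a_classes = class_ranges(mu_a_levels, mu_a_range_policy)
        if mu_a_groups == "default":
            mu_a_groups = (
                default_mu_a_groups(len(mu_a_levels)) if len(mu_a_levels) == 14 else None
            )
        if mu_a_groups is not None:
            mu_a_classes = merge_class_ranges(mu_a_classes, mu_a_groups)
    else:
        lev = mu_a_levels[0]
        mu_a_classes = [ClassRange(0, max(lev * 0.5, MU_A_FLOOR), lev + 1.0, lev)]

    df["mu_a_class"] = [assign_class(v, mu_a_classes).label for v in df["mu_a_star"]]
    df["mu_s_class"] = [assign_class(v, mu_s_classes).label for v in df["mu_s_star"]]
    return CalibrationSet(table=df, mu_a_classes=mu_a_classes, mu_s_classes=mu_s_classes)
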
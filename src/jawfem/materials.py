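"""Hounsfield-to-elastic-property mapping and material tables.

Density follows the CT calibration regression rho(HU) = 0.0007*HU + 0.3489
(g/cm^3), floored at 0.01 g/cm^3 as a low-end value.  Young's modulus uses
the piecewise power law E = 5.05*rho^1.269 GPa below 1 g/cm^3 and
E = 9.11*rho^1.326 GPa at and above it (the boundary is assigned to the
high-density branch).  Heterogeneous models bin bone elements into
equal-width HU intervals; with four or more property classes the tooth
crowns receive dedicated enamel and dentine classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ParameterError
from .geometry import LabeledMesh

DENSITY_SLOPE = 0.0007      # g/cm^3 per HU
DENSITY_INTERCEPT = 0.3489  # g/cm^3
DENSITY_FLOOR = 0.01        # g/cm^3, arbitrary low-end value
E_LOW_COEF, E_LOW_EXP = 5.05, 1.269    # GPa, rho < 1
E_HIGH_COEF, E_HIGH_EXP = 9.11, 1.326  # GPa, rho >= 1

BONE_NU = 0.3
DEFAULT_ENAMEL = (80.0, 0.30)   # E GPa, nu — configurable published values
DEFAULT_DENTINE = (20.0, 0.31)


def hu_to_density(hu):
    """Density in g/cm^3 from a Hounsfield-like value (floored at 0.01)."""
    rho = DENSITY_SLOPE * np.asarray(hu, float) + DENSITY_INTERCEPT
    return np.maximum(rho, DENSITY_FLOOR)[()]


def density_to_modulus(rho):
    """Young's modulus in GPa from density in g/cm^3 (piecewise power law)."""
    rho = np.asarray(rho, float)
    if np.any(rho <= 0):
        raise ParameterError("density must be positive")
    low = E_LOW_COEF * rho ** E_LOW_EXP
    high = E_HIGH_COEF * rho ** E_HIGH_EXP
    return np.where(rho < 1.0, low, high)[()]


@dataclass(frozen=True)
class MaterialPoint:
    """One HU sample mapped through both regressions."""

    hu: float
    rho: float
    E: float
    nu: float

    def __post_init__(self):
        if self.rho <= 0 or self.E <= 0 or not (0 <= self.nu < 0.5):
            raise ParameterError("invalid material point")

    @classmethod
    def from_hu(cls, hu: float, nu: float = BONE_NU) -> "MaterialPoint":
        rho = float(hu_to_density(hu))
        return cls(hu=float(hu), rho=rho, E=float(density_to_modulus(rho)), nu=nu)


@dataclass
class MaterialTable:
    """Ordered property classes plus the per-element class map.

    ``classes`` rows are (E GPa, nu, label); ``hu_ranges`` records the HU
    interval each bone class covers (NaN bounds for non-binned classes).
    """

    classes: List[Tuple[float, float, str]]
    element_class: np.ndarray
    hu_ranges: List[Tuple[float, float]] = field(default_factory=list)

    def __post_init__(self):
        if len(self.classes) < 1:
            raise ParameterError("material table needs at least one class")
        E = np.array([c[0] for c in self.classes])
        if not np.all(np.isfinite(E)) or not np.all(E > 0):
            raise ParameterError("class moduli must be finite and positive")
        ec = np.asarray(self.element_class)
        if ec.min() < 0 or ec.max() >= len(self.classes):
            raise ParameterError("element_class out of range")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def element_modulus(self) -> np.ndarray:
        return np.array([c[0] for c in self.classes])[self.element_class]

    def element_nu(self) -> np.ndarray:
        return np.array([c[1] for c in self.classes])[self.element_class]

    def to_frame(self) -> pd.DataFrame:
        ranges = self.hu_ranges or [(np.nan, np.nan)] * self.n_classes
        return pd.DataFrame(
            {"class": range(self.n_classes),
             "label": [c[2] for c in self.classes],
             "E_GPa": [c[0] for c in self.classes],
             "nu": [c[1] for c in self.classes],
             "hu_lo": [r[0] for r in ranges],
             "hu_hi": [r[1] for r in ranges]})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def homogeneous_table(mesh: LabeledMesh, E: float = 20.0,
                      nu: float = BONE_NU) -> MaterialTable:
    """Single-property model: every element gets (E, nu)."""
    if E <= 0:
        raise ParameterError("modulus must be positive")
    if not (0 <= nu < 0.5):
        raise ParameterError("Poisson ratio must lie in [0, 0.5)")
    return MaterialTable(
        classes=[(float(E), float(nu), "homogeneous")],
        element_class=np.zeros(mesh.n_tets, dtype=int),
        hu_ranges=[(np.nan, np.nan)])


def bin_properties(mesh: LabeledMesh, n_classes: int,
                   schedule: str = "equal_width",
                   enamel: Tuple[float, float] = DEFAULT_ENAMEL,
                   dentine: Tuple[float, float] = DEFAULT_DENTINE,
                   homogeneous_E: float = 20.0) -> MaterialTable:
    """Build a 1..10-class material table from the element HU field.

    ``n_classes = 1`` reproduces the homogeneous 20 GPa model.  Otherwise
    bone elements are split into equal-width HU intervals between the
    mesh's min and max bone HU (``schedule='quantile'`` uses equal-count
    bins instead); each class takes E from the interval-midpoint HU via
    the two regressions, with nu = 0.3.  From four classes on, tooth-crown
    elements get dedicated enamel and dentine classes.
    """
    if not (1 <= n_classes <= 10):
        raise ParameterError("n_classes must lie in 1..10")
    if schedule not in ("equal_width", "quantile"):
        raise ParameterError(f"unknown binning schedule {schedule!r}")
    if n_classes == 1:
        return homogeneous_table(mesh, homogeneous_E, BONE_NU)

    region = mesh.element_region
    hu = mesh.element_hu
    teeth_dedicated = n_classes >= 4
    n_bone = n_classes - 2 if teeth_dedicated else n_classes
    bone_mask = region == "bone"
    bone_hu = hu[bone_mask] if teeth_dedicated else hu
    lo, hi = float(bone_hu.min()), float(bone_hu.max())
    if schedule == "equal_width":
        edges = np.linspace(lo, hi, n_bone + 1)
    else:
        edges = np.quantile(bone_hu, np.linspace(0, 1, n_bone + 1))
        edges[0], edges[-1] = lo, hi
    mids = 0.5 * (edges[:-1] + edges[1:])
    classes = [(float(density_to_modulus(hu_to_density(m))), BONE_NU,
                f"bone_{i}") for i, m in enumerate(mids)]
    hu_ranges = [(float(edges[i]), float(edges[i + 1])) for i in range(n_bone)]

    binned = np.clip(np.searchsorted(edges, hu, side="right") - 1, 0, n_bone - 1)
    element_class = binned.astype(int)
    if teeth_dedicated:
        classes.append((float(enamel[0]), float(enamel[1]), "enamel"))
        classes.append((float(dentine[0]), float(dentine[1]), "dentine"))
        hu_ranges += [(np.nan, np.nan), (np.nan, np.nan)]
        element_class[region == "enamel"] = n_bone
        element_class[region == "dentine"] = n_bone + 1
    return MaterialTable(classes=classes, element_class=element_class,
                         hu_ranges=hu_ranges)
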
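"""Independent rigid-body statics checks for FE reaction forces.

When both TMJ constraints act at single points on a common axis, the
moment of all applied loads about that axis must be balanced entirely by
the bite-point reaction: joint forces through the axis have no moment
about it.  This fixes one projection of the bite reaction exactly and
provides an oracle wholly independent of the finite-element solution
path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .errors import ParameterError


@dataclass
class StaticsCase:
    """Applied point forces plus the joint axis and bite point."""

    forces: List[Tuple[np.ndarray, np.ndarray]]  # (point mm, force N)
    axis_point: np.ndarray
    axis_dir: np.ndarray
    bite_point: np.ndarray

    def __post_init__(self):
        self.axis_dir = np.asarray(self.axis_dir, float)
        if not np.isclose(np.linalg.norm(self.axis_dir), 1.0, atol=1e-9):
            raise ParameterError("axis_dir must be a unit vector")
        self.axis_point = np.asarray(self.axis_point, float)
        self.bite_point = np.asarray(self.bite_point, float)


def axis_moment(case: StaticsCase) -> float:
    """Total moment of the applied forces about the axis, N.mm."""
    m = 0.0
    for p, F in case.forces:
        m += float(np.cross(np.asarray(p, float) - case.axis_point,
                            np.asarray(F, float)) @ case.axis_dir)
    return m


def bite_moment_arm(case: StaticsCase) -> float:
    """Perpendicular distance of the bite point from the axis, mm."""
    r = case.bite_point - case.axis_point
    r_perp = r - (r @ case.axis_dir) * case.axis_dir
    return float(np.linalg.norm(r_perp))


def bite_moment_direction(case: StaticsCase) -> np.ndarray:
    """Unit vector m such that a bite force F contributes (F.m)*arm of
    moment about the axis."""
    r = case.bite_point - case.axis_point
    r_perp = r - (r @ case.axis_dir) * case.axis_dir
    d = np.linalg.norm(r_perp)
    if d < 1e-12:
        raise ParameterError("bite point lies on the axis")
    return np.cross(case.axis_dir, r_perp / d)


def predicted_bite_component(moment: float, case: StaticsCase) -> float:
    """Bite-reaction component (along ``bite_moment_direction``) required
    to balance ``moment`` when all joint reactions act on the axis."""
    arm = bite_moment_arm(case)
    if arm < 1e-12:
        raise ParameterError("bite point lies on the axis")
    return -moment / arm


def loadcase_statics(nodal_forces: np.ndarray, coords: np.ndarray,
                     axis_point, axis_dir, bite_point) -> StaticsCase:
    """StaticsCase from an FE nodal load vector (nonzero rows only)."""
    nz = np.nonzero(np.linalg.norm(nodal_forces, axis=1) > 0)[0]
    forces = [(coords[i].copy(), nodal_forces[i].copy()) for i in nz]
    return StaticsCase(forces=forces, axis_point=axis_point,
                       axis_dir=axis_dir, bite_point=bite_point)
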
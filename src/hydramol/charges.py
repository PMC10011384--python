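"""Charge backends: per-atom partial charges and van der Waals radii.

All downstream modules consume :class:`ChargeResult` only, so a backend can
be swapped without touching the strength or energy code.  The default
``"eeq"`` backend is the package's electronegativity-equilibration solver.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from . import eeq
from .exceptions import ConfigurationError, ConformerError
from .io import MoleculeRecord

DEFAULT_BACKEND = "eeq"


@dataclass(frozen=True)
class ChargeResult:
    """Charges (e) and vdW radii (Angstrom) aligned to atom indices."""

    charges: np.ndarray
    radii: np.ndarray
    backend: str

    def __post_init__(self) -> None:
        if len(self.charges) != len(self.radii):
            raise ValueError("charges and radii must have equal length")
        if np.any(self.radii <= 0):
            raise ValueError("all radii must be strictly positive")


def _eeq_backend(record: MoleculeRecord) -> ChargeResult:
    charges = eeq.eeq_charges(
        record.elements, record.coordinates, total_charge=record.total_charge
    )
    radii = eeq.vdw_radii(record.elements, charges)
    return ChargeResult(charges=charges, radii=radii, backend=eeq.BACKEND_TAG)


_BACKENDS: dict[str, Callable[[MoleculeRecord], ChargeResult]] = {
    "eeq": _eeq_backend,
}


def register_backend(name: str, fn: Callable[[MoleculeRecord], ChargeResult]) -> None:
    """Register an alternative charge backend (used by tests and plugins)."""
    _BACKENDS[name] = fn


def compute_charges_radii(
    record: MoleculeRecord, backend: str = DEFAULT_BACKEND
) -> ChargeResult:
    """Populate partial charges and radii on the record's atom descriptors.

    Requires a 3D conformer with explicit hydrogens.  The result depends
    only on elements, coordinates and total charge (orientation-invariant).
    """
    if backend not in _BACKENDS:
        raise ConfigurationError(
            f"unknown charge backend {backend!r}; available: {sorted(_BACKENDS)}"
        )
    if record.mol.GetNumConformers() == 0:
        raise ConformerError(
            f"{record.identifier}: charges need a 3D conformer (run prepare_conformer)"
        )
    result = _BACKENDS[backend](record)
    total = float(record.total_charge)
    if abs(float(result.charges.sum()) - total) > 1e-6:
        raise ValueError(
            f"{record.identifier}: backend {backend!r} violated charge conservation"
        )
    if not record.atoms:
        from .io import perceive_features

        perceive_features(record)
    for desc, q, r in zip(record.atoms, result.charges, result.radii):
        desc.q = float(q)
        desc.r_vdw = float(r)
    return result
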
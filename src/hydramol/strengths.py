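"""Atomic hydrogen-bond donor/acceptor strengths and molecular aggregates.

A hydrogen's donor strength is ``sd = D (qH + dq)`` and a lone-pair atom's
acceptor strength is ``sa = A (qa + dq)``, where the corrective charge

    dq = T * sum(alpha) + T^2 * sum(beta) + T^3 * sum(gamma)

propagates neighbour partial charges through the first three topological
bond shells, attenuated by the bond reduction factor T.  With the default
coefficients the hydrogens and oxygen of an MMFF94-minimised water molecule
define strength 1.0, so values are read relative to water.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import MoleculeRecord


@dataclass(frozen=True)
class StrengthParams:
    """Calibration coefficients of the strength equations.

    Defaults are the published values for the reference charge model; use
    :func:`hydramol.model.calibrate_water` to derive the pair that closes
    the water calibration for the backend actually in use.
    """

    D: float = 63.7
    A: float = -4.4362
    T: float = 0.274

    def __post_init__(self) -> None:
        if not 0.0 < self.T < 1.0:
            raise ValueError(f"bond reduction factor T must be in (0, 1), got {self.T}")


@dataclass
class StrengthSet:
    """Per-atom strengths plus the molecular aggregates.

    ``sdx_mol`` sums X-H donor strengths (X any non-carbon heavy atom),
    ``sdc_mol`` sums C-H donor strengths, ``sd_mol`` their total, and
    ``sa_mol`` sums atomic acceptor strengths weighted by lone-pair count.
    """

    donor: dict[int, float] = field(default_factory=dict)
    acceptor: dict[int, float] = field(default_factory=dict)
    donor_heavy: dict[int, int] = field(default_factory=dict)  # H idx -> parent heavy idx
    sdx_mol: float = 0.0
    sdc_mol: float = 0.0
    sd_mol: float = 0.0
    sa_mol: float = 0.0


def delta_q(atom_index: int, record: MoleculeRecord, T: float = 0.274) -> float:
    """Corrective charge from the alpha/beta/gamma bond shells.

    Shells are defined by shortest topological distance (1, 2, 3 bonds);
    every atom, hydrogen or heavy, contributes once at its shortest
    distance, and atoms beyond three bonds contribute nothing.
    """
    charges = record.charges
    dists = record.distance_matrix()[atom_index]
    out = 0.0
    for shell in (1, 2, 3):
        out += (T ** shell) * float(charges[dists == shell].sum())
    return out


def donor_strength(
    hydrogen_index: int, record: MoleculeRecord, params: StrengthParams = StrengthParams()
) -> float:
    """Donor strength of one hydrogen; negative values are not clamped."""
    atom = record.mol.GetAtomWithIdx(hydrogen_index)
    if atom.GetAtomicNum() != 1:
        raise ValueError(
            f"{record.identifier}: atom {hydrogen_index} is {atom.GetSymbol()}, not H"
        )
    q_h = float(record.charges[hydrogen_index])
    return params.D * (q_h + delta_q(hydrogen_index, record, params.T))


def acceptor_strength(
    atom_index: int, record: MoleculeRecord, params: StrengthParams = StrengthParams()
) -> float:
    """Acceptor strength of a lone-pair-bearing atom."""
    desc = record.atoms[atom_index]
    if desc.n_LP < 1:
        raise ValueError(
            f"{record.identifier}: atom {atom_index} ({desc.element}) has no lone "
            "pairs and is not an acceptor"
        )
    q_a = float(record.charges[atom_index])
    return params.A * (q_a + delta_q(atom_index, record, params.T))


def molecular_strengths(
    record: MoleculeRecord, params: StrengthParams = StrengthParams()
) -> StrengthSet:
    """All per-atom strengths plus molecular aggregates.

    Donor aggregates are plain sums of atomic donor strengths; the acceptor
    aggregate weights each atomic strength by its lone-pair count.
    """
    out = StrengthSet()
    charges = record.charges  # raises if charges missing
    dm = record.distance_matrix()
    t = params.T
    # vectorised shell sums for all atoms at once
    dq = np.zeros(len(charges))
    for shell in (1, 2, 3):
        dq += (t ** shell) * ((dm == shell) @ charges)

    for desc in record.atoms:
        i = desc.index
        if desc.element == "H":
            sd = params.D * (charges[i] + dq[i])
            out.donor[i] = float(sd)
            heavy = record.mol.GetAtomWithIdx(i).GetNeighbors()
            if heavy:
                out.donor_heavy[i] = heavy[0].GetIdx()
            if heavy and heavy[0].GetAtomicNum() == 6:
                out.sdc_mol += float(sd)
            else:
                out.sdx_mol += float(sd)
        elif desc.n_LP >= 1:
            sa = params.A * (charges[i] + dq[i])
            out.acceptor[i] = float(sa)
            out.sa_mol += float(sa) * desc.n_LP
    out.sd_mol = out.sdx_mol + out.sdc_mol
    return out
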
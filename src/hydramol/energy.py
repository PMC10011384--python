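"""Hydration free energy: polar, apolar and acceptor-interaction terms.

The hydration free energy is an additive three-term model in kJ/mol:

    dG = dG_polar + dG_apolar + dG_interaction

* polar — donor/acceptor strengths weighted by hydrogen and lone-pair
  multiplicities raised to fitted exponents;
* apolar — constant + topological surface area + ring and pi-orbital counts;
* interaction — an empirical penalty for proximal acceptor pairs within
  three bonds of each other.

Higher-order charge corrections (hybridisation dipole, quadrupole, constant
offset) of the antecedent method are deliberately absent from the acceptor
strength; that simplification is part of this model's definition.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .exceptions import ValenceError
from .io import AtomDescriptor, MoleculeRecord, count_pi_and_rings, perceive_features
from .strengths import StrengthParams, StrengthSet, molecular_strengths

_HYB_NUMBER = {"sp1": 1, "sp2": 2, "sp3": 3}

#: free parameters fitted against the experimental hydration data (see docs).
_DEFAULTS = dict(
    exp_d=0.50, exp_a=0.34, g_d=0.908, g_a=-16.131,
    g_0=1.884, g_s=0.0467, g_r=-3.643, g_pi2=-1.174, g_pi1=-1.602,
    g_i=4.9996, F=0.514,
)

#: names of the free-energy parameters that move during fitting (D, A, T stay fixed).
FREE_PARAMETERS = tuple(_DEFAULTS)


@dataclass(frozen=True)
class ParameterSet:
    """All model parameters: three calibration constants and eleven free ones."""

    strength: StrengthParams = field(default_factory=StrengthParams)
    exp_d: float = _DEFAULTS["exp_d"]
    exp_a: float = _DEFAULTS["exp_a"]
    g_d: float = _DEFAULTS["g_d"]
    g_a: float = _DEFAULTS["g_a"]
    g_0: float = _DEFAULTS["g_0"]
    g_s: float = _DEFAULTS["g_s"]
    g_r: float = _DEFAULTS["g_r"]
    g_pi2: float = _DEFAULTS["g_pi2"]
    g_pi1: float = _DEFAULTS["g_pi1"]
    g_i: float = _DEFAULTS["g_i"]
    F: float = _DEFAULTS["F"]

    def free_values(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in FREE_PARAMETERS}

    def with_free(self, **kwargs: float) -> "ParameterSet":
        unknown = set(kwargs) - set(FREE_PARAMETERS)
        if unknown:
            raise ValueError(f"not free parameters: {sorted(unknown)}")
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        d = dict(d)
        sp = d.pop("strength", {})
        return cls(strength=StrengthParams(**sp), **d)


@dataclass(frozen=True)
class HydrationResult:
    """Energy contributions (kJ/mol) and the descriptor counts behind them."""

    dG_polar: float
    dG_apolar: float
    dG_interaction: float
    N_s: float
    N_r: int
    N_pi2: int
    N_pi1: int
    strengths: StrengthSet

    @property
    def dG_total(self) -> float:
        return self.dG_polar + self.dG_apolar + self.dG_interaction


def polar_term(
    strengths: StrengthSet,
    features: list[AtomDescriptor],
    params: ParameterSet = ParameterSet(),
    donor_scope: str = "xh-only",
    donor_aggregation: str = "mean",
) -> float:
    """Polar contribution in kJ/mol.

    The donor sum runs over hydrogen-bearing heavy atoms — by default only
    non-carbon ones, since C-H hydrogens are tracked but treated as
    apolar — each represented by the mean (or max) strength of its
    hydrogens times ``n_H ** exp_d``.  The acceptor sum runs over lone-pair
    atoms with ``n_LP ** exp_a`` multiplicity.
    """
    if donor_scope not in ("xh-only", "all-h"):
        raise ValueError(f"unknown donor_scope {donor_scope!r}")
    if donor_aggregation not in ("mean", "max"):
        raise ValueError(f"unknown donor_aggregation {donor_aggregation!r}")

    index = {d.index: d for d in features}
    per_heavy: dict[int, list[float]] = {}
    for h_idx, sd in strengths.donor.items():
        heavy_idx = strengths.donor_heavy.get(h_idx)
        if heavy_idx is None:
            continue
        per_heavy.setdefault(heavy_idx, []).append(sd)

    donor_sum = 0.0
    for heavy_idx, sds in sorted(per_heavy.items()):
        desc = index[heavy_idx]
        if donor_scope == "xh-only" and desc.element == "C":
            continue
        sd_i = max(sds) if donor_aggregation == "max" else float(np.mean(sds))
        donor_sum += sd_i * desc.n_H ** params.exp_d

    acceptor_sum = 0.0
    for atom_idx, sa in sorted(strengths.acceptor.items()):
        n_lp = index[atom_idx].n_LP
        assert n_lp >= 1, "acceptor map must only contain lone-pair atoms"
        acceptor_sum += sa * n_lp ** params.exp_a

    return params.g_d * donor_sum + params.g_a * acceptor_sum


def atomic_surface(r_vdw: float, n_l: int, hyb: str) -> float:
    """Topological surface contribution of one heavy atom, in Angstrom^2.

    ``4 pi r^2 (1 - n_l / (h + 1))`` with hybridisation number h = 1, 2, 3
    for sp1, sp2, sp3: the more heavy neighbours an atom has, the less of
    its sphere faces the solvent.
    """
    h = _HYB_NUMBER.get(hyb)
    if h is None:
        raise ValenceError(f"hybridisation {hyb!r} has no surface number")
    if n_l > h + 1:
        raise ValenceError(
            f"atom with {n_l} heavy neighbours exceeds its {hyb} capacity {h + 1}"
        )
    return 4.0 * np.pi * r_vdw ** 2 * (1.0 - n_l / (h + 1.0))


def surface_area(features: list[AtomDescriptor]) -> float:
    """Total topological surface N_s: sum over non-hydrogen atoms."""
    from .exceptions import ChargesMissingError

    total = 0.0
    for desc in features:
        if desc.element == "H":
            continue
        if desc.r_vdw is None:
            raise ChargesMissingError(
                f"atom {desc.index} has no vdW radius; run compute_charges_radii first"
            )
        total += atomic_surface(desc.r_vdw, desc.n_l, desc.hyb)
    return total


def apolar_term(
    features: list[AtomDescriptor],
    counts: tuple[int, int, int],
    params: ParameterSet = ParameterSet(),
) -> float:
    """Apolar contribution: constant + surface + ring + pi-orbital terms."""
    n_pi2, n_pi1, n_r = counts
    n_s = surface_area(features)
    return (
        params.g_0
        + params.g_s * n_s
        + params.g_r * n_r
        + params.g_pi2 * n_pi2
        + params.g_pi1 * n_pi1
    )


def interaction_term(
    strengths: StrengthSet,
    features: list[AtomDescriptor],
    record: MoleculeRecord,
    params: ParameterSet = ParameterSet(),
) -> float:
    """Proximal-acceptor interaction contribution in kJ/mol.

    Each acceptor j collects the lone-pair-weighted strengths
    ``a = sa * n_LP ** exp_a`` of acceptor atoms at topological distance
    1 and 2 (full weight) and 3 (attenuated by F); the ordered sum over
    origins means every unordered pair is visited from both ends.
    """
    idxs = sorted(strengths.acceptor)
    if len(idxs) < 2:
        return 0.0
    index = {d.index: d for d in features}
    a = np.array(
        [strengths.acceptor[i] * index[i].n_LP ** params.exp_a for i in idxs]
    )
    dm = record.distance_matrix()[np.ix_(idxs, idxs)]
    weight = np.zeros_like(dm, dtype=float)
    weight[(dm == 1) | (dm == 2)] = 1.0
    weight[dm == 3] = params.F
    return params.g_i * float(a @ weight @ a)


def total_hydration(
    record: MoleculeRecord,
    params: ParameterSet = ParameterSet(),
    donor_scope: str = "xh-only",
    donor_aggregation: str = "mean",
) -> HydrationResult:
    """All three contributions on a prepared record (conformer + charges)."""
    if not record.atoms:
        perceive_features(record)
    strengths = molecular_strengths(record, params.strength)
    counts = count_pi_and_rings(record)
    n_pi2, n_pi1, n_r = counts
    return HydrationResult(
        dG_polar=polar_term(strengths, record.atoms, params, donor_scope, donor_aggregation),
        dG_apolar=apolar_term(record.atoms, counts, params),
        dG_interaction=interaction_term(strengths, record.atoms, record, params),
        N_s=surface_area(record.atoms),
        N_r=n_r,
        N_pi2=n_pi2,
        N_pi1=n_pi1,
        strengths=strengths,
    )
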
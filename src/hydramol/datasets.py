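"""Packaged reference tables and the synthetic dataset generator.

The packaged tables store the printed values of the two published
structure-activity case studies (CDK2 aminothiazole inhibitors and
11beta-HSD1 pyrazolopyrimidine inhibitors) and the water-reference
constants; they are stored verbatim, never recomputed.

The synthetic generator enumerates small organic molecules from a seeded
fragment grammar and labels them with hydration free energies computed by
the model itself (plus optional Gaussian noise), which makes it the oracle
for parameter-recovery experiments: fitting at zero noise must recover the
generating parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .energy import ParameterSet, total_hydration
from .io import DEFAULT_SEED, MoleculeRecord, from_smiles
from .model import prepare_record

FIXTURE_NAMES = (
    "table1_cdk2_activities",
    "table2_cdk2_strengths",
    "table3_cdk2_correlations",
    "table4_hsd1_activities",
    "table5_hsd1_strengths",
    "table6_hsd1_correlations",
    "water_reference",
)


@dataclass(frozen=True)
class FixtureTable:
    """An immutable packaged table of printed values."""

    name: str
    rows: pd.DataFrame

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", self.rows.copy())


def load_fixture(name: str) -> FixtureTable:
    """Load a packaged table by its canonical name."""
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
    path = resources.files("hydramol.data").joinpath(f"{name}.csv")
    with resources.as_file(path) as p:
        frame = pd.read_csv(p, dtype={"id": str} if name != "water_reference" else None)
    return FixtureTable(name=name, rows=frame)


# -- synthetic molecule grammar ------------------------------------------------

_CHAINS = ["C", "CC", "CCC", "CCCC", "CC(C)C", "CCCCC"]
_SUBSTITUENTS = ["", "O", "N", "OC", "F", "Cl", "Br", "S", "C=O", "C(=O)C", "C#N"]
_AROMATICS = ["c1ccccc1", "c1ccncc1", "c1ccoc1", "c1ccsc1"]
_ARO_PREFIXES = ["", "C", "CC", "CCC", "O", "N", "OC", "F", "Cl"]


def _random_smiles(rng: np.random.Generator) -> str:
    """One molecule from the fragment grammar (always MMFF94-parameterised)."""
    if rng.random() < 0.25:
        core = _AROMATICS[rng.integers(len(_AROMATICS))]
        prefix = _ARO_PREFIXES[rng.integers(len(_ARO_PREFIXES))]
        return prefix + core
    chain = _CHAINS[rng.integers(len(_CHAINS))]
    sub = _SUBSTITUENTS[rng.integers(len(_SUBSTITUENTS))]
    return chain + sub


def generate_synthetic_dataset(
    n: int,
    seed: int,
    params: ParameterSet | None = None,
    noise_sd: float = 0.0,
    backend: str = "eeq",
) -> list[tuple[MoleculeRecord, float]]:
    """n prepared molecules labelled with model energies (+ Gaussian noise).

    Fully reproducible from ``seed``: both the molecule draw and the noise
    use one seeded generator, and conformers are embedded from per-molecule
    seeds derived from it.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params = params or ParameterSet()
    rng = np.random.default_rng(seed)
    out: list[tuple[MoleculeRecord, float]] = []
    seen: set[str] = set()
    while len(out) < n:
        smi = _random_smiles(rng)
        conf_seed = int(rng.integers(1, 2**31 - 1))
        noise = float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
        if smi in seen:
            continue
        seen.add(smi)
        rec = from_smiles(smi, f"syn{len(out)}")
        prepare_record(rec, seed=conf_seed, backend=backend)
        dg = total_hydration(rec, params).dG_total + noise
        out.append((rec, dg))
    return out


def write_dataset_csv(dataset: list[tuple[MoleculeRecord, float]], path) -> None:
    """Write a (id, smiles, dG) dataset in the fitting CSV dialect."""
    pd.DataFrame(
        [
            {"id": rec.identifier, "smiles": rec.smiles, "dg_exp_kj_mol": dg}
            for rec, dg in dataset
        ]
    ).to_csv(path, index=False)


KCAL_TO_KJ = 4.184


def read_dg_csv(path, unit: str = "kJ/mol") -> pd.DataFrame:
    """Read a user-supplied (id, smiles, dG) table, converting kcal if asked.

    External benchmark sets are not packaged; curate them to kJ/mol or
    kcal/mol entries only and drop compounds shared with the fitting set
    before use.
    """
    frame = pd.read_csv(path)
    required = {"id", "smiles", "dg_exp_kj_mol"}
    if not required <= set(frame.columns):
        from .exceptions import DataError

        raise DataError(f"{path}: expected columns {sorted(required)}")
    if unit == "kcal/mol":
        frame["dg_exp_kj_mol"] = frame["dg_exp_kj_mol"] * KCAL_TO_KJ
    elif unit != "kJ/mol":
        raise ValueError(f"unknown unit {unit!r}")
    return frame
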
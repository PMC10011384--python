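"""Water calibration and parameter fitting against experimental data.

The modelling surface follows the Model/Results convention: build a
:class:`HydrationModel` from prepared molecules and experimental hydration
free energies, call :meth:`HydrationModel.fit`, and read estimates,
diagnostics and the trial log off the returned
:class:`HydrationFitResults`.

Fitting minimises the mean absolute error with a seeded (1+1) evolution
strategy: a Gaussian proposal around the incumbent, accepted only on strict
improvement, with step-size adaptation and an early stop after a fixed
number of consecutive non-improving trials.  Geometry and charges do not
depend on the free-energy parameters, so every molecule is featurised once
and each trial is a cheap re-scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .charges import compute_charges_radii
from .energy import FREE_PARAMETERS, ParameterSet, total_hydration
from .exceptions import CalibrationError, DataError
from .io import (
    DEFAULT_SEED,
    MoleculeRecord,
    count_pi_and_rings,
    from_smiles,
    perceive_features,
    prepare_conformer,
)
from .strengths import StrengthParams, delta_q, molecular_strengths

logger = logging.getLogger(__name__)


def prepare_record(
    record: MoleculeRecord,
    seed: int = DEFAULT_SEED,
    backend: str = "eeq",
    preserve: bool = False,
) -> MoleculeRecord:
    """Conformer + features + charges in one step (no-op if already done)."""
    already = (
        record.mol.GetNumConformers() > 0
        and record.atoms
        and record.atoms[0].q is not None
    )
    if not already:
        prepare_conformer(record, seed=seed, preserve=preserve)
        perceive_features(record)
        compute_charges_radii(record, backend=backend)
    return record


def calibrate_water(
    backend: str = "eeq", seed: int = DEFAULT_SEED, T: float = 0.274
) -> tuple[float, float]:
    """Derive the strength calibration constants from the water reference.

    Water is built from SMILES ``O``, embedded from ``seed`` and minimised
    with MMFF94.  ``D`` is the reciprocal of the corrected hydrogen charge
    (mean over the two hydrogens) and ``A`` the reciprocal of the corrected
    oxygen charge, so that the water hydrogens and oxygen score exactly 1.0.
    """
    water = prepare_record(from_smiles("O", "water"), seed=seed, backend=backend)
    h_sums = []
    o_sum = None
    for desc in water.atoms:
        corrected = float(water.charges[desc.index]) + delta_q(desc.index, water, T)
        if desc.element == "H":
            h_sums.append(corrected)
        else:
            o_sum = corrected
    mean_h = float(np.mean(h_sums))
    if abs(mean_h) < 1e-12 or o_sum is None or abs(o_sum) < 1e-12:
        raise CalibrationError("degenerate corrected charges on the calibration water")
    return 1.0 / mean_h, 1.0 / o_sum


@dataclass
class _MoleculeCache:
    """Per-molecule featurisation that is invariant to the free parameters."""

    donor_mean: np.ndarray   # per donor heavy atom: mean sd of its hydrogens
    donor_max: np.ndarray
    donor_nh: np.ndarray
    donor_is_c: np.ndarray
    sa: np.ndarray           # per acceptor atom
    n_lp: np.ndarray
    w12: np.ndarray          # acceptor-pair masks at distance 1-2 and 3
    w3: np.ndarray
    n_s: float
    n_r: int
    n_pi2: int
    n_pi1: int


def _featurise(record: MoleculeRecord, strength: StrengthParams) -> _MoleculeCache:
    from .energy import surface_area

    strengths = molecular_strengths(record, strength)
    index = {d.index: d for d in record.atoms}
    per_heavy: dict[int, list[float]] = {}
    for h_idx, sd in strengths.donor.items():
        heavy = strengths.donor_heavy.get(h_idx)
        if heavy is not None:
            per_heavy.setdefault(heavy, []).append(sd)
    heavy_idx = sorted(per_heavy)
    acc_idx = sorted(strengths.acceptor)
    dm = record.distance_matrix()[np.ix_(acc_idx, acc_idx)] if acc_idx else np.zeros((0, 0))
    n_pi2, n_pi1, n_r = count_pi_and_rings(record)
    return _MoleculeCache(
        donor_mean=np.array([np.mean(per_heavy[i]) for i in heavy_idx]),
        donor_max=np.array([np.max(per_heavy[i]) for i in heavy_idx]),
        donor_nh=np.array([index[i].n_H for i in heavy_idx], dtype=float),
        donor_is_c=np.array([index[i].element == "C" for i in heavy_idx]),
        sa=np.array([strengths.acceptor[i] for i in acc_idx]),
        n_lp=np.array([index[i].n_LP for i in acc_idx], dtype=float),
        w12=((dm == 1) | (dm == 2)).astype(float),
        w3=(dm == 3).astype(float),
        n_s=surface_area(record.atoms),
        n_r=n_r,
        n_pi2=n_pi2,
        n_pi1=n_pi1,
    )


def _predict_cached(
    cache: _MoleculeCache,
    p: ParameterSet,
    donor_scope: str,
    donor_aggregation: str,
) -> float:
    sd = cache.donor_max if donor_aggregation == "max" else cache.donor_mean
    keep = ~cache.donor_is_c if donor_scope == "xh-only" else np.ones_like(cache.donor_is_c)
    donor = float((sd[keep] * cache.donor_nh[keep] ** p.exp_d).sum()) if keep.any() else 0.0
    acceptor = float((cache.sa * cache.n_lp ** p.exp_a).sum()) if cache.sa.size else 0.0
    polar = p.g_d * donor + p.g_a * acceptor
    apolar = (
        p.g_0 + p.g_s * cache.n_s + p.g_r * cache.n_r
        + p.g_pi2 * cache.n_pi2 + p.g_pi1 * cache.n_pi1
    )
    if cache.sa.size >= 2:
        a = cache.sa * cache.n_lp ** p.exp_a
        inter = p.g_i * float(a @ (cache.w12 + p.F * cache.w3) @ a)
    else:
        inter = 0.0
    return polar + apolar + inter


@dataclass
class HydrationFitResults:
    """Estimates and diagnostics of a hydration-energy fit."""

    model: "HydrationModel"
    best_params: ParameterSet
    best_mae: float
    n_trials: int
    trial_log: list[tuple[int, dict[str, float], float]]
    seed: int

    def predict(self, params: ParameterSet | None = None) -> np.ndarray:
        return self.model.predict(params or self.best_params)

    def summary(self) -> str:
        lines = [
            "Hydration free energy fit (MAE loss, (1+1)-ES search)",
            "=" * 56,
            f"molecules: {len(self.model.caches):>6d}    trials: {self.n_trials:>6d}"
            f"    seed: {self.seed}",
            f"best MAE:  {self.best_mae:10.4f} kJ/mol",
            "-" * 56,
            f"{'parameter':<10}{'initial':>12}{'fitted':>12}",
        ]
        init = self.model.params.free_values()
        for name, value in self.best_params.free_values().items():
            lines.append(f"{name:<10}{init[name]:>12.4f}{value:>12.4f}")
        return "\n".join(lines)


class HydrationModel:
    """Hydration free-energy model bound to a (molecule, dG_exp) dataset.

    Parameters
    ----------
    records : prepared or raw molecule records (raw ones are embedded and
        minimised here with the model seed)
    dg_exp : experimental hydration free energies in kJ/mol
    params : starting parameter set; its calibration constants D, A, T stay
        fixed during fitting
    """

    def __init__(
        self,
        records: list[MoleculeRecord],
        dg_exp: np.ndarray | list[float],
        params: ParameterSet | None = None,
        backend: str = "eeq",
        seed: int = DEFAULT_SEED,
        donor_scope: str = "xh-only",
        donor_aggregation: str = "mean",
    ) -> None:
        if len(records) == 0:
            raise ValueError("dataset is empty")
        if len(records) != len(dg_exp):
            raise ValueError("records and dg_exp differ in length")
        self.params = params or ParameterSet()
        self.donor_scope = donor_scope
        self.donor_aggregation = donor_aggregation
        self.caches: list[_MoleculeCache] = []
        self.records: list[MoleculeRecord] = []
        self.failures: list[tuple[str, str]] = []
        kept_dg = []
        for rec, dg in zip(records, dg_exp):
            try:
                if rec.atoms == [] or rec.atoms[0].q is None:
                    prepare_record(
                        rec, seed=seed, backend=backend,
                        preserve=rec.conformer_source == "as-provided",
                    )
                self.caches.append(_featurise(rec, self.params.strength))
                self.records.append(rec)
                kept_dg.append(float(dg))
            except Exception as exc:  # noqa: BLE001 - report, keep batch alive
                self.failures.append((rec.identifier, str(exc)))
                logger.warning("excluded %s: %s", rec.identifier, exc)
        if not self.records:
            raise DataError("no molecule in the dataset could be prepared")
        self.dg_exp = np.asarray(kept_dg)

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        smiles: str = "smiles",
        target: str = "dg_exp_kj_mol",
        identifier: str = "id",
        **kwargs,
    ) -> "HydrationModel":
        missing = {smiles, target} - set(frame.columns)
        if missing:
            raise DataError(f"dataset is missing columns: {sorted(missing)}")
        records = [
            from_smiles(row[smiles], str(row[identifier]) if identifier in frame else None)
            for _, row in frame.iterrows()
        ]
        return cls(records, frame[target].to_numpy(), **kwargs)

    def predict(self, params: ParameterSet | None = None) -> np.ndarray:
        p = params or self.params
        return np.array(
            [
                _predict_cached(c, p, self.donor_scope, self.donor_aggregation)
                for c in self.caches
            ]
        )

    def mae(self, params: ParameterSet | None = None) -> float:
        return float(np.mean(np.abs(self.predict(params) - self.dg_exp)))

    def fit(
        self,
        seed: int = 0,
        patience: int = 300,
        max_trials: int = 20000,
        free: tuple[str, ...] = FREE_PARAMETERS,
        bounds: dict[str, tuple[float, float]] | None = None,
        sigma0: float = 0.25,
    ) -> HydrationFitResults:
        """Minimise the MAE over the free parameters.

        Bounds default to a sign-preserving decade around each starting
        value.  The search stops after ``patience`` consecutive trials
        without strict improvement, or at ``max_trials``.
        """
        unknown = set(free) - set(FREE_PARAMETERS)
        if unknown:
            raise ValueError(f"cannot fit fixed/unknown parameters: {sorted(unknown)}")
        rng = np.random.default_rng(seed)
        start = self.params.free_values()
        names = list(free)
        x0 = np.array([start[n] for n in names])
        lo = np.empty_like(x0)
        hi = np.empty_like(x0)
        for i, n in enumerate(names):
            if bounds and n in bounds:
                lo[i], hi[i] = bounds[n]
            else:
                b = np.sort([x0[i] / 10.0, x0[i] * 10.0])
                lo[i], hi[i] = b
        scale = np.maximum(np.abs(x0), 1e-3)

        def evaluate(x: np.ndarray) -> tuple[ParameterSet, float]:
            p = self.params.with_free(**{n: float(v) for n, v in zip(names, x)})
            return p, self.mae(p)

        best_x = x0.copy()
        best_params, best_mae = evaluate(x0)
        trial_log = [(0, {n: float(v) for n, v in zip(names, x0)}, best_mae)]
        sigma = sigma0
        fails = 0
        trial = 0
        while trial + 1 < max_trials and fails < patience:
            trial += 1
            x = np.clip(best_x + sigma * scale * rng.standard_normal(len(names)), lo, hi)
            params, mae = evaluate(x)
            trial_log.append((trial, {n: float(v) for n, v in zip(names, x)}, mae))
            if mae < best_mae - 1e-12:
                best_x, best_params, best_mae = x, params, mae
                fails = 0
                sigma = min(sigma * 1.25, 1.0)
            else:
                fails += 1
                sigma = max(sigma * 0.985, 1e-4)
        return HydrationFitResults(
            model=self,
            best_params=best_params,
            best_mae=best_mae,
            n_trials=len(trial_log),
            trial_log=trial_log,
            seed=seed,
        )


def predict_hydration(
    records: list[MoleculeRecord],
    params: ParameterSet | None = None,
    backend: str = "eeq",
    seed: int = DEFAULT_SEED,
    donor_scope: str = "xh-only",
    donor_aggregation: str = "mean",
) -> pd.DataFrame:
    """Batch prediction: one row per molecule, failures listed separately.

    Returns a frame with the three energy terms, their total and the
    molecular strength aggregates; molecules that fail preparation get a
    row with the failure reason in ``error`` and NaN energies.
    """
    params = params or ParameterSet()
    rows = []
    for rec in records:
        try:
            prepare_record(
                rec, seed=seed, backend=backend,
                preserve=rec.conformer_source == "as-provided",
            )
            res = total_hydration(rec, params, donor_scope, donor_aggregation)
            rows.append(
                dict(
                    id=rec.identifier,
                    dG_polar=res.dG_polar,
                    dG_apolar=res.dG_apolar,
                    dG_interaction=res.dG_interaction,
                    dG_total=res.dG_total,
                    sdx_mol=res.strengths.sdx_mol,
                    sdc_mol=res.strengths.sdc_mol,
                    sd_mol=res.strengths.sd_mol,
                    sa_mol=res.strengths.sa_mol,
                    error="",
                )
            )
        except Exception as exc:  # noqa: BLE001 - batch robustness
            logger.warning("prediction failed for %s: %s", rec.identifier, exc)
            rows.append(dict(id=rec.identifier, error=str(exc)))
    return pd.DataFrame(rows)
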
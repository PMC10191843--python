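"""END/RAPID-style resampling uncertainties for refined structures.

The procedure perturbs each observed amplitude by a uniform random amount
within +/-(m|Fobs| - D|Fcalc|) — the local difference-map envelope — and
jitters the starting coordinates of the refinable (primary) component, then
re-refines.  Repeating this for n independent replicas yields a per-metric
spread whose standard deviation is reported as an upper-bound error: the
injected amplitude perturbation deliberately overestimates the true
experimental error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .crystal import AtomicModel, ReflectionSet, WeightingScheme
from .mixture import (
    MixtureRefinementResults,
    MultiComponentModel,
    RefinementConfig,
    RestraintSet,
    refine_primary,
)

__all__ = [
    "PerturbationConfig",
    "EnsembleResult",
    "perturb_structure_factors",
    "perturb_coordinates",
    "run_ensemble",
]

MetricFn = Callable[[MultiComponentModel], float]


@dataclass(frozen=True)
class PerturbationConfig:
    """Replica count, coordinate jitter and seeding for an ensemble run.

    ``coordinate_jitter`` is the standard deviation (angstrom, per axis) of
    the Gaussian displacement applied to the primary component's atoms; the
    amplitude perturbation width is set by the data themselves through the
    difference-map envelope.
    """

    n_replicas: int = 100
    coordinate_jitter: float = 0.05
    seed: int = 0
    weights: WeightingScheme = field(default_factory=WeightingScheme)

    def __post_init__(self) -> None:
        if self.n_replicas < 2:
            raise ValueError("n_replicas must be >= 2")
        if self.coordinate_jitter < 0:
            raise ValueError("coordinate_jitter must be >= 0")


def perturb_structure_factors(
    fobs: ReflectionSet,
    fcalc: ReflectionSet,
    weights: WeightingScheme,
    rng: np.random.Generator,
) -> ReflectionSet:
    """Resample amplitudes uniformly within +/-|m|Fobs| - D|Fcalc||.

    Perturbation applies to amplitudes only (phases belong to the model);
    results are clipped at zero since amplitudes are nonnegative.
    """
    fobs.assert_same_hkl(fcalc)
    m = np.broadcast_to(np.asarray(weights.m, float), fobs.amplitude.shape)
    D = np.broadcast_to(np.asarray(weights.D, float), fobs.amplitude.shape)
    width = np.abs(m * fobs.amplitude - D * fcalc.amplitude)
    shift = rng.uniform(-1.0, 1.0, size=len(fobs)) * width
    out = fobs.copy()
    out.amplitude = np.maximum(out.amplitude + shift, 0.0)
    return out


def perturb_coordinates(
    model: AtomicModel, amplitude: float, rng: np.random.Generator
) -> AtomicModel:
    """Isotropic Gaussian coordinate jitter (sd = amplitude, per axis)."""
    if amplitude < 0:
        raise ValueError("jitter amplitude must be >= 0")
    out = model.copy()
    if amplitude == 0:
        return out
    disp_cart = rng.normal(0.0, amplitude, size=(len(out), 3))
    disp_frac = model.cell.fractionalize(disp_cart)
    for atom, d in zip(out.atoms, disp_frac):
        atom.position = atom.position + d
    return out


@dataclass
class EnsembleResult:
    """Per-replica metric samples with their mean and standard deviation."""

    samples: pd.DataFrame          # columns: replica, metric, value
    mean: dict[str, float]
    sd: dict[str, float]
    n_replicas: int
    n_failures: int
    seed: int
    replica_results: list[MixtureRefinementResults] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, s in self.sd.items():
            if s < 0:
                raise ValueError(f"negative sd for metric {name!r}")

    def metric_samples(self, name: str) -> np.ndarray:
        return self.samples.loc[self.samples["metric"] == name, "value"].to_numpy()

    def to_csv(self, path: str | Path) -> None:
        self.samples.to_csv(path, index=False, float_format="%.6f",
                            lineterminator="\n")

    def summary_dict(self) -> dict:
        return {
            "n_replicas": self.n_replicas,
            "n_failures": self.n_failures,
            "seed": self.seed,
            "metrics": {
                name: {"mean": self.mean[name], "sd": self.sd[name]}
                for name in self.mean
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary_dict(), indent=2) + "\n")


def run_ensemble(
    mcm: MultiComponentModel,
    fobs: ReflectionSet,
    restraints: RestraintSet | None,
    metrics: Mapping[str, MetricFn],
    config: PerturbationConfig,
    refine_config: RefinementConfig | None = None,
    keep_models: bool = False,
) -> EnsembleResult:
    """Perturb -> refine -> measure, ``n_replicas`` times.

    Each replica draws from an independent RNG stream spawned from the
    master seed by replica index, so results do not depend on execution
    order.  Replicas whose refinement raises are excluded and counted; more
    than 20% failures aborts the run as unstable.
    """
    if not metrics:
        raise ValueError("at least one metric is required")
    # reference Fcalc for the perturbation envelope
    from .mixture import composite_structure_factors

    fcalc = composite_structure_factors(mcm, float(fobs.d.min()))
    # restrict to the observed hkl set (same cell, same limit => same grid)
    fobs.assert_same_hkl(fcalc)

    streams = np.random.SeedSequence(config.seed).spawn(config.n_replicas)
    rows = []
    kept_results: list[MixtureRefinementResults] = []
    n_failures = 0
    for i, ss in enumerate(streams):
        rng = np.random.Generator(np.random.PCG64(ss))
        try:
            fobs_i = perturb_structure_factors(fobs, fcalc, config.weights, rng)
            mcm_i = mcm.copy()
            prim = mcm_i.primary
            prim.model = perturb_coordinates(
                prim.model, config.coordinate_jitter, rng
            )
            result = refine_primary(mcm_i, fobs_i, restraints, refine_config)
            for name, fn in metrics.items():
                rows.append(
                    {"replica": i, "metric": name,
                     "value": float(fn(result.mcm_refined))}
                )
            if keep_models:
                kept_results.append(result)
        except (FloatingPointError, ValueError, RuntimeError):
            n_failures += 1
    if n_failures > 0.2 * config.n_replicas:
        raise RuntimeError(
            f"END/RAPID ensemble unstable: {n_failures}/{config.n_replicas} "
            "replica refinements failed"
        )
    samples = pd.DataFrame(rows, columns=["replica", "metric", "value"])
    mean = {
        name: float(samples.loc[samples["metric"] == name, "value"].mean())
        for name in metrics
    }
    sd = {}
    for name in metrics:
        v = samples.loc[samples["metric"] == name, "value"].to_numpy()
        # identical replicas have exactly zero spread (avoid the roundoff
        # residue of the mean subtraction)
        sd[name] = 0.0 if np.all(v == v[0]) else float(np.std(v, ddof=1))
    return EnsembleResult(
        samples=samples, mean=mean, sd=sd,
        n_replicas=config.n_replicas, n_failures=n_failures,
        seed=config.seed, replica_results=kept_results,
    )
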
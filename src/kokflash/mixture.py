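"""Multicomponent mixture refinement of a time-resolved crystallographic state.

A time point during the S3->S0 transition of photosystem II is a mixture of
reaction-center populations: a refinable "primary" intermediate advancing
through the transition, plus fixed-population components whose structures
are known endpoint states (the lagging S3-like and completed S0-like
populations).  The calculated structure factor is the population-weighted
complex sum of the per-component structure factors (the alternate-conformer
convention).  Only the primary component's coordinates and isotropic B
factors are refined, under harmonic bond/angle restraints; the fixed
components contribute one refinable group-B offset each so they can be
adjusted to the resolution of the dataset without moving.

The model/results split follows the statsmodels idiom:
``MixtureRefinement(fobs, mcm, restraints).fit()`` returns a
``MixtureRefinementResults`` carrying the refined model, R factors, the
target trajectory and a ``summary()`` table.  ``refine_primary`` is the
equivalent one-call functional surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .crystal import (
    AtomicModel,
    AtomLabel,
    MapGrid,
    ReflectionSet,
    UnitCell,
    WeightingScheme,
    difference_coefficients,
    direct_summation,
    hkl_grid,
    map_from_coefficients,
    sigma_normalize,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Component",
    "MultiComponentModel",
    "BondRestraint",
    "AngleRestraint",
    "RestraintSet",
    "RefinementConfig",
    "MixtureRefinement",
    "MixtureRefinementResults",
    "composite_structure_factors",
    "build_restraints",
    "refine_primary",
    "omit_map",
    "estimate_population",
]

_POP_TOL = 1e-9


@dataclass
class Component:
    model: AtomicModel
    population: float
    refinable: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if self.population < -_POP_TOL:
            raise ValueError(f"population must be >= 0, got {self.population}")
        if not self.label:
            self.label = self.model.component_tag or "component"


@dataclass
class MultiComponentModel:
    """Ordered components sharing one unit cell; exactly one is refinable."""

    components: list[Component]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("MultiComponentModel needs at least one component")
        pops = np.array([c.population for c in self.components])
        if abs(pops.sum() - 1.0) > _POP_TOL:
            raise ValueError(f"populations must sum to 1, got {pops.sum()!r}")
        n_ref = sum(c.refinable for c in self.components)
        if n_ref != 1:
            raise ValueError(f"exactly one component must be refinable, got {n_ref}")
        cell0 = self.cell
        for c in self.components:
            for attr in ("a", "b", "c", "alpha", "beta", "gamma"):
                if abs(getattr(c.model.cell, attr) - getattr(cell0, attr)) > 1e-8:
                    raise ValueError("all components must share one unit cell")
        labels = [c.label for c in self.components]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate component labels: {labels}")

    @property
    def cell(self) -> UnitCell:
        return self.components[0].model.cell

    @property
    def primary(self) -> Component:
        return next(c for c in self.components if c.refinable)

    @property
    def fixed(self) -> list[Component]:
        return [c for c in self.components if not c.refinable]

    def component(self, label: str) -> Component:
        for c in self.components:
            if c.label == label:
                return c
        raise KeyError(f"no component labelled {label!r}")

    def copy(self) -> "MultiComponentModel":
        return MultiComponentModel(
            [Component(c.model.copy(), c.population, c.refinable, c.label)
             for c in self.components]
        )

    def with_populations(self, pops: dict[str, float]) -> "MultiComponentModel":
        out = self.copy()
        for c in out.components:
            if c.label in pops:
                c.population = float(pops[c.label])
        return MultiComponentModel(out.components)  # re-validate


def composite_structure_factors(
    mcm: MultiComponentModel, resolution: float
) -> ReflectionSet:
    """Population-weighted complex sum of per-component structure factors."""
    hkl = hkl_grid(mcm.cell, resolution)
    F = np.zeros(len(hkl), dtype=complex)
    for comp in mcm.components:
        F += comp.population * _component_sf(comp.model, hkl)
    return ReflectionSet.from_complex(mcm.cell, hkl, F)


def _component_sf(model: AtomicModel, hkl: np.ndarray) -> np.ndarray:
    return direct_summation(
        model.cell, hkl,
        [a.element for a in model.atoms],
        model.positions_frac(),
        np.array([a.occupancy for a in model.atoms]),
        np.array([a.b_iso for a in model.atoms]),
    )


# --------------------------------------------------------------------------
# restraints

@dataclass(frozen=True)
class BondRestraint:
    atoms: tuple[AtomLabel, AtomLabel]
    ideal: float          # angstrom
    esd: float = 0.1      # angstrom


@dataclass(frozen=True)
class AngleRestraint:
    atoms: tuple[AtomLabel, AtomLabel, AtomLabel]  # vertex is the middle atom
    ideal: float          # degrees
    esd: float = 10.0     # degrees


@dataclass
class RestraintSet:
    bonds: list[BondRestraint] = field(default_factory=list)
    angles: list[AngleRestraint] = field(default_factory=list)

    def __post_init__(self) -> None:
        for r in list(self.bonds) + list(self.angles):
            if r.esd <= 0:
                raise ValueError("restraint esds must be > 0")

    def __len__(self) -> int:
        return len(self.bonds) + len(self.angles)

    def residuals(self, model: AtomicModel) -> np.ndarray:
        """Reduced residuals (deviation / esd) for every restraint."""
        cart = {a.label: model.cell.orthogonalize(a.position) for a in model.atoms}
        out = []
        for b in self.bonds:
            d = float(np.linalg.norm(cart[b.atoms[0]] - cart[b.atoms[1]]))
            out.append((d - b.ideal) / b.esd)
        for ang in self.angles:
            ri, rj, rk = (cart[l] for l in ang.atoms)
            theta = _angle_deg(ri, rj, rk)
            out.append((theta - ang.ideal) / ang.esd)
        return np.asarray(out)


def _angle_deg(ri: np.ndarray, rj: np.ndarray, rk: np.ndarray) -> float:
    u, v = ri - rj, rk - rj
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def build_restraints(
    model: AtomicModel,
    bonds: Sequence[tuple] = (),
    angles: Sequence[tuple] = (),
    bond_esd: float = 0.1,
    angle_esd: float = 10.0,
) -> RestraintSet:
    """Build bond/angle restraints from a topology.

    Each bond entry is ``(labelA, labelB)`` or ``(labelA, labelB, ideal)``;
    each angle entry ``(labelA, labelB, labelC)`` (vertex B) or the same
    plus an ideal in degrees.  Ideals default to the input model's geometry.
    The default esds (0.1 A bonds, 10 deg angles) are deliberately loose so
    atoms can follow the density while the overall shape is maintained.
    """
    cart = {a.label: model.cell.orthogonalize(a.position) for a in model.atoms}

    def resolve(label) -> AtomLabel:
        key = tuple(label)
        if key not in cart:
            raise ValueError(f"restraint references unknown atom {key!r}")
        return key  # type: ignore[return-value]

    bond_list = []
    for entry in bonds:
        la, lb = resolve(entry[0]), resolve(entry[1])
        ideal = float(entry[2]) if len(entry) > 2 else float(
            np.linalg.norm(cart[la] - cart[lb])
        )
        bond_list.append(BondRestraint((la, lb), ideal, bond_esd))
    angle_list = []
    for entry in angles:
        la, lb, lc = (resolve(entry[i]) for i in range(3))
        ideal = float(entry[3]) if len(entry) > 3 else _angle_deg(
            cart[la], cart[lb], cart[lc]
        )
        angle_list.append(AngleRestraint((la, lb, lc), ideal, angle_esd))
    return RestraintSet(bonds=bond_list, angles=angle_list)


# --------------------------------------------------------------------------
# refinement

@dataclass
class RefinementConfig:
    """Strategy and numerical settings for restrained least squares.

    The target is ``sum_h w_h (|Fobs| - |Fcalc|)^2 +
    lambda * sum_r ((delta_r)/esd_r)^2`` minimized over the primary
    component's fractional coordinates and per-atom isotropic B factors
    (bounded below by ``b_min``) plus one group-B offset per fixed
    component, using trust-region least squares with an analytic Jacobian.
    With the default inverse-variance data weights both terms are
    dimensionless reduced squares, so ``restraint_weight`` defaults to 1
    (restraints act as additional observations with their stated esds).
    ``max_cycles`` bounds the number of residual evaluations.
    """

    max_cycles: int = 100
    tol: float = 1e-10
    restraint_weight: float | None = None
    refine_xyz: bool = True
    refine_b: bool = True
    group_b: bool = True
    b_min: float = 2.0
    frozen_atoms: tuple = ()   # primary-atom labels exempt from refinement

    def __post_init__(self) -> None:
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")
        if self.restraint_weight is not None and self.restraint_weight < 0:
            raise ValueError("restraint_weight must be >= 0")


class MixtureRefinement:
    """Restrained least-squares refinement of the primary component.

    Parameters
    ----------
    fobs : observed amplitudes covering the refinement resolution range.
    mcm : multicomponent starting model (one refinable component).
    restraints : bond/angle restraints on the primary component.
    config : optimizer strategy; see :class:`RefinementConfig`.
    data_weights : per-reflection weights w_h.  Defaults to inverse-variance
        weights 1/sigma^2 when the data carry positive sigmas, else 1.
    """

    def __init__(
        self,
        fobs: ReflectionSet,
        mcm: MultiComponentModel,
        restraints: RestraintSet | None = None,
        config: RefinementConfig | None = None,
        data_weights: np.ndarray | None = None,
    ) -> None:
        self.fobs = fobs
        self.mcm = mcm
        self.restraints = restraints or RestraintSet()
        self.config = config or RefinementConfig()
        if data_weights is not None:
            self.weights = np.broadcast_to(
                np.asarray(data_weights, float), (len(fobs),)
            ).copy()
        elif fobs.sigma is not None and np.all(fobs.sigma > 0):
            self.weights = 1.0 / fobs.sigma**2
        else:
            self.weights = np.ones(len(fobs))
        self._prepare()

    # -- setup ------------------------------------------------------------
    def _prepare(self) -> None:
        mcm, fobs = self.mcm, self.fobs
        self.cell = mcm.cell
        self.hkl = fobs.hkl
        d = fobs.d
        self.s2 = 1.0 / (4.0 * d**2)
        prim = mcm.primary
        self.n_atoms = len(prim.model)
        self.p_primary = prim.population
        self.elements = [a.element for a in prim.model.atoms]
        self.occ = np.array([a.occupancy for a in prim.model.atoms])
        # per-atom occ * f(s) for the primary, independent of x and B
        from .crystal import FORM_FACTORS

        self._f0 = np.empty((len(self.hkl), self.n_atoms))
        for elem in set(self.elements):
            idx = [j for j, e in enumerate(self.elements) if e == elem]
            self._f0[:, idx] = FORM_FACTORS.evaluate(elem, self.s2)[:, None]
        self._f0 *= self.occ[None, :] * self.p_primary
        # fixed components: population-weighted base SFs (coordinates frozen)
        self.F_fixed0 = [
            c.population * _component_sf(c.model, self.hkl) for c in mcm.fixed
        ]
        # resolve restraints to primary atom indices
        index = {a.label: j for j, a in enumerate(prim.model.atoms)}
        for r in list(self.restraints.bonds) + list(self.restraints.angles):
            for lab in r.atoms:
                if lab not in index:
                    raise ValueError(
                        f"restraint references atom {lab!r} not in the primary component"
                    )
        self._bond_idx = [
            (index[b.atoms[0]], index[b.atoms[1]], b.ideal, b.esd)
            for b in self.restraints.bonds
        ]
        self._angle_idx = [
            (index[a.atoms[0]], index[a.atoms[1]], index[a.atoms[2]], a.ideal, a.esd)
            for a in self.restraints.angles
        ]
        self._orth = self.cell.orth
        # parameter columns held fixed (atoms exempt from refinement)
        index = {a.label: j for j, a in enumerate(prim.model.atoms)}
        frozen_cols: list[int] = []
        for lab in self.config.frozen_atoms:
            lab = tuple(lab)
            if lab not in index:
                raise ValueError(f"frozen atom {lab!r} not in the primary component")
            j = index[lab]
            off = 0
            if self.config.refine_xyz:
                frozen_cols += [3 * j, 3 * j + 1, 3 * j + 2]
                off = 3 * self.n_atoms
            if self.config.refine_b:
                frozen_cols.append(off + j)
        self._frozen_cols = frozen_cols

    # -- parameter packing -------------------------------------------------
    def _pack(self, frac: np.ndarray, b: np.ndarray, gb: np.ndarray) -> np.ndarray:
        parts = []
        if self.config.refine_xyz:
            parts.append(frac.ravel())
        if self.config.refine_b:
            parts.append(b)
        if self.config.group_b:
            parts.append(gb)
        return np.concatenate(parts) if parts else np.array([])

    def _unpack(self, x: np.ndarray):
        prim = self.mcm.primary.model
        frac0 = prim.positions_frac()
        b0 = np.array([a.b_iso for a in prim.atoms])
        n = self.n_atoms
        pos = 0
        if self.config.refine_xyz:
            frac = x[pos:pos + 3 * n].reshape(n, 3)
            pos += 3 * n
        else:
            frac = frac0
        if self.config.refine_b:
            b = x[pos:pos + n]
            pos += n
        else:
            b = b0
        if self.config.group_b:
            gb = x[pos:pos + len(self.mcm.fixed)]
        else:
            gb = np.zeros(len(self.mcm.fixed))
        return frac, b, gb

    # -- residuals and jacobian -------------------------------------------
    def _fcalc_terms(self, frac: np.ndarray, b: np.ndarray, gb: np.ndarray):
        phases = np.exp(2j * np.pi * (self.hkl @ frac.T))        # (nh, na)
        dw = np.exp(-np.outer(self.s2, b))                        # (nh, na)
        contrib = self._f0 * dw * phases                          # (nh, na) complex
        Fc = contrib.sum(axis=1)
        F_fixed_scaled = []
        for k, F0 in enumerate(self.F_fixed0):
            Fk = F0 * np.exp(-gb[k] * self.s2)
            F_fixed_scaled.append(Fk)
            Fc = Fc + Fk
        return Fc, contrib, F_fixed_scaled

    def _residuals(self, x: np.ndarray, lam: float) -> np.ndarray:
        """Weighted residual vector: data rows then restraint rows."""
        frac, b, gb = self._unpack(x)
        Fc, _, _ = self._fcalc_terms(frac, b, gb)
        r_data = np.sqrt(self.weights) * (np.abs(Fc) - self.fobs.amplitude)
        if lam > 0 and (self._bond_idx or self._angle_idx):
            r_rest = np.sqrt(lam) * self._restraint_residuals(frac)
            return np.concatenate([r_data, r_rest])
        return r_data

    def _jacobian(self, x: np.ndarray, lam: float) -> np.ndarray:
        frac, b, gb = self._unpack(x)
        Fc, contrib, F_fixed = self._fcalc_terms(frac, b, gb)
        amp = np.abs(Fc)
        u = Fc / np.where(amp > 1e-12, amp, 1e-12)
        sw = np.sqrt(self.weights)
        proj = np.conj(u)[:, None] * contrib                      # (nh, na)
        cols = []
        if self.config.refine_xyz:
            # d|F|/dx_ja = -2 pi h_a Im(conj(u) c_j)
            jx = -2.0 * np.pi * proj.imag[:, :, None] * self.hkl[:, None, :]
            cols.append(jx.reshape(len(amp), -1))
        if self.config.refine_b:
            cols.append(-self.s2[:, None] * proj.real)
        if self.config.group_b:
            cols.append(np.column_stack(
                [-self.s2 * (np.conj(u) * Fk).real for Fk in F_fixed]
            ) if F_fixed else np.zeros((len(amp), 0)))
        J_data = sw[:, None] * np.concatenate(cols, axis=1)
        if lam > 0 and (self._bond_idx or self._angle_idx):
            J_rest = np.sqrt(lam) * self._restraint_jacobian(frac)
            J = np.vstack([J_data, J_rest])
        else:
            J = J_data
        if self._frozen_cols:
            J[:, self._frozen_cols] = 0.0
        return J

    def _target_and_grad(self, x: np.ndarray, lam: float):
        """Scalar target (sum of squared residuals) and its gradient."""
        r = self._residuals(x, lam)
        J = self._jacobian(x, lam)
        return float(r @ r), 2.0 * (J.T @ r)

    def _restraint_residuals(self, frac: np.ndarray) -> np.ndarray:
        cart = frac @ self._orth.T
        res = []
        for i, j, ideal, esd in self._bond_idx:
            d = np.linalg.norm(cart[i] - cart[j])
            res.append((d - ideal) / esd)
        for i, j, k, ideal, esd in self._angle_idx:
            theta = _angle_deg(cart[i], cart[j], cart[k])
            res.append((theta - ideal) / esd)
        return np.asarray(res)

    def _restraint_jacobian(self, frac: np.ndarray) -> np.ndarray:
        """Rows: restraints; columns: the packed parameter vector."""
        n_params = (
            (3 * self.n_atoms if self.config.refine_xyz else 0)
            + (self.n_atoms if self.config.refine_b else 0)
            + (len(self.mcm.fixed) if self.config.group_b else 0)
        )
        n_rest = len(self._bond_idx) + len(self._angle_idx)
        J = np.zeros((n_rest, n_params))
        if not self.config.refine_xyz:
            return J
        cart = frac @ self._orth.T
        row = 0
        for i, j, ideal, esd in self._bond_idx:
            dvec = cart[i] - cart[j]
            d = max(np.linalg.norm(dvec), 1e-12)
            g = dvec / (d * esd)
            J[row, 3 * i:3 * i + 3] = g @ self._orth
            J[row, 3 * j:3 * j + 3] = -g @ self._orth
            row += 1
        for i, j, k, ideal, esd in self._angle_idx:
            u = cart[i] - cart[j]
            v = cart[k] - cart[j]
            nu, nv = np.linalg.norm(u), np.linalg.norm(v)
            cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
            sin = np.sqrt(max(1.0 - cosang**2, 1e-12))
            dcos_du = v / (nu * nv) - cosang * u / nu**2
            dcos_dv = u / (nu * nv) - cosang * v / nv**2
            fac = np.degrees(-1.0 / sin) / esd
            J[row, 3 * i:3 * i + 3] = fac * dcos_du @ self._orth
            J[row, 3 * k:3 * k + 3] = fac * dcos_dv @ self._orth
            J[row, 3 * j:3 * j + 3] = -fac * (dcos_du + dcos_dv) @ self._orth
            row += 1
        return J

    # -- public API --------------------------------------------------------
    def fit(self) -> "MixtureRefinementResults":
        cfg = self.config
        prim = self.mcm.primary.model
        frac0 = prim.positions_frac()
        b0 = np.array([a.b_iso for a in prim.atoms])
        gb0 = np.zeros(len(self.mcm.fixed))
        x0 = self._pack(frac0, b0, gb0)
        lam = 1.0 if cfg.restraint_weight is None else cfg.restraint_weight

        lb, ub = [], []
        if cfg.refine_xyz:
            lb += [-np.inf] * (3 * self.n_atoms)
            ub += [np.inf] * (3 * self.n_atoms)
        if cfg.refine_b:
            lb += [cfg.b_min] * self.n_atoms
            ub += [np.inf] * self.n_atoms
        if cfg.group_b:
            lb += [-200.0] * len(self.mcm.fixed)
            ub += [200.0] * len(self.mcm.fixed)

        def residuals(x):
            r = self._residuals(x, lam)
            if not np.all(np.isfinite(r)):
                raise FloatingPointError(
                    "non-finite refinement residuals (check for overlapping atoms)"
                )
            return r

        x_scale = []
        if cfg.refine_xyz:
            # ~0.1 A in fractional units
            x_scale += list(np.tile(0.1 / np.array(
                [self.cell.a, self.cell.b, self.cell.c]), self.n_atoms))
        if cfg.refine_b:
            x_scale += [5.0] * self.n_atoms
        if cfg.group_b:
            x_scale += [5.0] * len(self.mcm.fixed)

        if len(x0) == 0:
            # nothing refinable under this strategy: evaluate only
            t0 = float(np.sum(residuals(x0) ** 2))
            refined = self.mcm.copy()
            r = _r_factor(self.fobs, refined)
            return MixtureRefinementResults(
                model=self, mcm_refined=refined, r_before=r, r_after=r,
                target_trajectory=np.array([t0, t0]), converged=True,
                n_iterations=0, restraint_weight=lam,
                group_b_offsets=np.zeros(len(self.mcm.fixed)),
                message="no refinable parameters",
            )

        trajectory = [float(np.sum(residuals(x0) ** 2))]
        res = least_squares(
            residuals, x0, jac=lambda x: self._jacobian(x, lam),
            bounds=(np.asarray(lb), np.asarray(ub)) if lb else (-np.inf, np.inf),
            method="trf", x_scale=np.asarray(x_scale) if x_scale else 1.0,
            ftol=cfg.tol, xtol=1e-12, gtol=1e-12,
            max_nfev=cfg.max_cycles,
        )
        trajectory.append(float(2.0 * res.cost))
        frac, b, gb = self._unpack(res.x)

        refined = self.mcm.copy()
        rp = refined.primary.model
        for j, a in enumerate(rp.atoms):
            # structure factors are periodic in fractional coordinates, so
            # the optimizer may park an atom in a neighbouring cell
            a.position = frac[j] % 1.0
            a.b_iso = float(b[j])
        for k, comp in enumerate(refined.fixed):
            for a in comp.model.atoms:
                a.b_iso = float(max(a.b_iso + gb[k], 0.0))

        r_before = _r_factor(self.fobs, self.mcm)
        r_after = _r_factor(self.fobs, refined)
        return MixtureRefinementResults(
            model=self,
            mcm_refined=refined,
            r_before=r_before,
            r_after=r_after,
            target_trajectory=np.asarray(trajectory),
            converged=bool(res.status > 0),
            n_iterations=int(res.nfev),
            restraint_weight=lam,
            group_b_offsets=gb.copy(),
            message=str(res.message),
        )


def _r_factor(fobs: ReflectionSet, mcm: MultiComponentModel) -> float:
    fc = np.zeros(len(fobs.hkl), dtype=complex)
    for comp in mcm.components:
        fc += comp.population * _component_sf(comp.model, fobs.hkl)
    amp = np.abs(fc)
    denom = np.sum(amp**2)
    k = np.sum(fobs.amplitude * amp) / denom if denom > 0 else 1.0
    s = np.sum(fobs.amplitude)
    return float(np.sum(np.abs(fobs.amplitude - k * amp)) / s) if s > 0 else 0.0


@dataclass
class MixtureRefinementResults:
    """Refined mixture model with fit diagnostics."""

    model: MixtureRefinement
    mcm_refined: MultiComponentModel
    r_before: float
    r_after: float
    target_trajectory: np.ndarray
    converged: bool
    n_iterations: int
    restraint_weight: float
    group_b_offsets: np.ndarray
    message: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_after <= 1.0 + 1e-9:
            raise ValueError(f"R factor outside [0, 1]: {self.r_after}")
        if self.target_trajectory[-1] > self.target_trajectory[0] + 1e-9:
            raise ValueError("refinement increased the target")

    @property
    def primary_model(self) -> AtomicModel:
        return self.mcm_refined.primary.model

    def primary_rmsd(
        self, reference: AtomicModel, allow_origin_shift: bool = False
    ) -> float:
        """Coordinate RMSD (angstrom) of the primary against a reference
        model with identical atom ordering, using minimum-image fractional
        differences (positions are defined modulo the lattice).

        With ``allow_origin_shift`` the best uniform translation is removed
        first: in P1 the origin is arbitrary, so amplitude-only refinement
        of a model with no fixed components cannot (and need not) determine
        the absolute position.
        """
        cell = self.primary_model.cell
        df = self.primary_model.positions_frac() - reference.positions_frac()
        df -= np.round(df)
        if allow_origin_shift:
            df -= df.mean(axis=0)
            df -= np.round(df)
        dc = cell.orthogonalize(df)
        return float(np.sqrt(np.mean(np.sum(dc**2, axis=1))))

    def summary(self) -> str:
        rows = [
            ("n reflections", len(self.model.fobs)),
            ("n primary atoms", self.model.n_atoms),
            ("n restraints", len(self.model.restraints)),
            ("restraint weight", f"{self.restraint_weight:.4g}"),
            ("R before", f"{self.r_before:.4f}"),
            ("R after", f"{self.r_after:.4f}"),
            ("target initial", f"{self.target_trajectory[0]:.6g}"),
            ("target final", f"{self.target_trajectory[-1]:.6g}"),
            ("iterations", self.n_iterations),
            ("converged", self.converged),
        ]
        width = max(len(k) for k, _ in rows)
        lines = ["Mixture refinement results", "=" * 34]
        lines += [f"{k:<{width}} : {v}" for k, v in rows]
        pops = ", ".join(
            f"{c.label}={c.population:.3f}{'*' if c.refinable else ''}"
            for c in self.mcm_refined.components
        )
        lines.append(f"{'populations':<{width}} : {pops} (* refined)")
        return "\n".join(lines)


def refine_primary(
    mcm: MultiComponentModel,
    fobs: ReflectionSet,
    restraints: RestraintSet | None = None,
    config: RefinementConfig | None = None,
    data_weights: np.ndarray | None = None,
) -> MixtureRefinementResults:
    """One-call restrained refinement of the primary component."""
    return MixtureRefinement(fobs, mcm, restraints, config, data_weights).fit()


# --------------------------------------------------------------------------
# omit maps

def omit_map(
    mcm: MultiComponentModel,
    omit_selection: Sequence[AtomLabel],
    fobs: ReflectionSet,
    weights: WeightingScheme = WeightingScheme(),
    grid_spacing: float | None = None,
) -> MapGrid:
    """Sigma-normalized mFo-DFc map with atoms omitted from the primary.

    Fcalc is recomputed without the omitted atoms; no re-refinement is
    performed after the omission, matching the plain omit-coefficient
    convention.  Omitting atoms of a fixed component is rejected.
    """
    omit = [tuple(l) for l in omit_selection]
    prim_labels = {a.label for a in mcm.primary.model.atoms}
    for lab in omit:
        if lab not in prim_labels:
            raise ValueError(
                f"omit selection {lab!r} is not in the primary component"
            )
    partial = mcm.copy()
    partial.primary.model = partial.primary.model.without(omit)
    fc = np.zeros(len(fobs.hkl), dtype=complex)
    for comp in partial.components:
        fc += comp.population * _component_sf(comp.model, fobs.hkl)
    fcalc = ReflectionSet.from_complex(fobs.cell, fobs.hkl, fc)
    coeffs = difference_coefficients(fobs, fcalc, weights, kind="mFo-DFc")
    return sigma_normalize(map_from_coefficients(coeffs, grid_spacing=grid_spacing))


# --------------------------------------------------------------------------
# population estimation

def estimate_population(
    mcm_template: MultiComponentModel,
    scan_component: str,
    fobs: ReflectionSet,
    grid: Sequence[float],
    restraints: RestraintSet | None = None,
    config: RefinementConfig | None = None,
    hold: Sequence[str] = (),
) -> tuple[float, pd.DataFrame]:
    """Scan a component's population, re-refining at each grid point.

    The scanned component takes each grid fraction in turn; components named
    in ``hold`` keep their template fractions; the remainder is shared
    proportionally among the other components.  Returns the fraction with
    the lowest post-refinement R (ties resolved toward the smaller
    fraction) and the full R profile.  The primary is pre-refined once at
    the template populations; every grid point then starts from that common
    refined geometry, which is deterministic and avoids path-dependent
    bias from chaining refinements along the grid.
    """
    grid = sorted(float(g) for g in grid)
    if not grid:
        raise ValueError("population scan grid is empty")
    mcm_template.component(scan_component)  # existence check
    held = {lab: mcm_template.component(lab).population for lab in hold}
    others = [
        c.label for c in mcm_template.components
        if c.label != scan_component and c.label not in held
    ]
    other_sum = sum(mcm_template.component(l).population for l in others)
    pre = refine_primary(mcm_template, fobs, restraints, config)
    start_primary = pre.mcm_refined.primary.model
    rows = []
    for f in grid:
        rest = 1.0 - f - sum(held.values())
        if rest < -_POP_TOL:
            raise ValueError(
                f"grid fraction {f} leaves negative mass after held components"
            )
        rest = max(rest, 0.0)
        pops = {scan_component: f, **held}
        if others:
            if other_sum > 0:
                for lab in others:
                    pops[lab] = rest * mcm_template.component(lab).population / other_sum
            else:
                for lab in others:
                    pops[lab] = rest / len(others)
        mcm = mcm_template.with_populations(pops)
        mcm.primary.model = start_primary.copy()
        result = refine_primary(mcm, fobs, restraints, config)
        rows.append({"fraction": f, "r_factor": result.r_after})
    profile = pd.DataFrame(rows)
    best = float(profile.loc[profile["r_factor"].idxmin(), "fraction"])
    return best, profile


def estimate_ox_occupancy(
    mcm: MultiComponentModel,
    ox_label: AtomLabel,
    fobs: ReflectionSet,
    grid: Sequence[float],
    restraints: RestraintSet | None = None,
    config: RefinementConfig | None = None,
) -> tuple[float, pd.DataFrame]:
    """Scan the occupancy of one primary-component atom, re-refining each time.

    Because the composite Fcalc is linear in populations, scanning the
    occupancy of the Ox atom inside the primary is the same computation as
    splitting the primary into Ox-bearing and Ox-free variants and scanning
    the Ox-bearing population with the endpoint components held fixed; this
    parameterization simply avoids duplicating the primary model.  Ties
    resolve toward the smaller occupancy (conservative detection).

    The primary is pre-refined once at the template occupancy and every
    grid point starts from that common refined geometry (deterministic;
    no path dependence along the grid).  The estimate is reliable while
    the scanned atom's crystal-level signal (occupancy times primary
    population) stays above the amplitude noise; at small primary
    populations the R profile flattens and only an upper bound remains
    meaningful.
    """
    grid = sorted(float(g) for g in grid)
    if not grid:
        raise ValueError("occupancy scan grid is empty")
    if config is None:
        config = RefinementConfig(max_cycles=25, tol=1e-8)
    mcm.primary.model.atom(ox_label)  # raises if absent / not primary
    pre = refine_primary(mcm, fobs, restraints, config)
    start_primary = pre.mcm_refined.primary.model
    rows = []
    for q in grid:
        if not 0.0 <= q <= 1.0:
            raise ValueError(f"occupancy {q} outside [0, 1]")
        trial = mcm.copy()
        trial.primary.model = start_primary.copy()
        trial.primary.model.atom(ox_label).occupancy = q
        result = refine_primary(trial, fobs, restraints, config)
        rows.append({"fraction": q, "r_factor": result.r_after})
    profile = pd.DataFrame(rows)
    best = float(profile.loc[profile["r_factor"].idxmin(), "fraction"])
    return best, profile
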
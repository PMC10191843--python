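"""Minimal crystallographic engine for toy P1 cells.

Structure factors by direct summation over atoms with Gaussian scattering
factors and isotropic Debye-Waller damping, FFT map synthesis, weighted
difference coefficients (mFo-DFc, 2mFo-DFc), isomorphous Fo-Fo difference
maps, per-resolution-bin scaling to a reference dataset, and sigma
normalization of maps.  Everything works in space group P1: the algorithms
under test (mixture refinement, omit quantification, resampling errors) are
space-group-agnostic, and small P1 cells keep desk-scale problems honest.

Conventions, stated once:

* ``s = sin(theta)/lambda = 1/(2 d)``; the Debye-Waller factor is
  ``exp(-B s^2)``.
* ``F(h) = sum_j occ_j f_j(s) exp(-B_j s^2) exp(2 pi i h.x_j)`` with x_j
  fractional; density is ``rho(x) = (1/V) sum_h F(h) exp(-2 pi i h.x)``.
* Reflection lists are Friedel-unique (l>0, or l=0 & k>0, or l=k=0 & h>0),
  sorted lexicographically; F(-h) = conj(F(h)) is implied.
* F000 is always excluded from maps, so maps are zero-mean.
* Negative difference amplitudes are stored as a positive amplitude with
  the phase shifted by 180 degrees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "UnitCell",
    "Atom",
    "AtomicModel",
    "FormFactorTable",
    "ReflectionSet",
    "WeightingScheme",
    "MapGrid",
    "hkl_grid",
    "compute_structure_factors",
    "map_from_coefficients",
    "difference_coefficients",
    "fo_fo_difference",
    "scale_to_reference",
    "sigma_normalize",
    "read_model",
    "write_model",
]


# --------------------------------------------------------------------------
# unit cell

@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell (lengths in angstrom, angles in degrees)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")
        if self.volume <= 0:
            raise ValueError("cell volume must be positive")

    @property
    def orth(self) -> np.ndarray:
        """Orthogonalization matrix (columns are the cell vectors)."""
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = np.sin(np.radians(self.gamma))
        v = np.sqrt(max(1.0 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg, 0.0))
        return np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, self.c * v / sg],
            ]
        )

    @property
    def frac(self) -> np.ndarray:
        return np.linalg.inv(self.orth)

    @property
    def volume(self) -> float:
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        v = 1.0 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg
        return float(self.a * self.b * self.c * np.sqrt(max(v, 0.0)))

    def reciprocal_metric(self) -> np.ndarray:
        G = self.orth.T @ self.orth
        return np.linalg.inv(G)

    def d_spacings(self, hkl: np.ndarray) -> np.ndarray:
        """Resolution d (angstrom) of each (h,k,l) row."""
        Gstar = self.reciprocal_metric()
        h = np.atleast_2d(np.asarray(hkl, dtype=float))
        inv_d2 = np.einsum("ni,ij,nj->n", h, Gstar, h)
        return 1.0 / np.sqrt(inv_d2)

    def orthogonalize(self, frac_xyz: np.ndarray) -> np.ndarray:
        return np.asarray(frac_xyz) @ self.orth.T

    def fractionalize(self, cart_xyz: np.ndarray) -> np.ndarray:
        return np.asarray(cart_xyz) @ self.frac.T

    def to_gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)


# --------------------------------------------------------------------------
# atoms and models

AtomLabel = tuple[str, int, str, str]  # (chain, residue number, residue name, atom name)


@dataclass
class Atom:
    """One atom: element, fractional position, occupancy, isotropic B."""

    element: str
    position: np.ndarray  # fractional, shape (3,)
    occupancy: float = 1.0
    b_iso: float = 15.0
    label: AtomLabel = ("A", 1, "UNK", "X")

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy must lie in [0, 1], got {self.occupancy}")
        if self.b_iso < 0:
            raise ValueError(f"b_iso must be >= 0, got {self.b_iso}")
        if gemmi.Element(self.element).atomic_number == 0:
            raise ValueError(f"unknown element {self.element!r}")
        self.label = (str(self.label[0]), int(self.label[1]), str(self.label[2]), str(self.label[3]))


@dataclass
class AtomicModel:
    """An ordered collection of atoms in a unit cell."""

    cell: UnitCell
    atoms: list[Atom]
    component_tag: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("AtomicModel must contain at least one atom")
        labels = [a.label for a in self.atoms]
        if len(set(labels)) != len(labels):
            dupes = {l for l in labels if labels.count(l) > 1}
            raise ValueError(f"duplicate atom labels: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.atoms)

    def copy(self) -> "AtomicModel":
        return AtomicModel(
            cell=self.cell,
            atoms=[
                Atom(a.element, a.position.copy(), a.occupancy, a.b_iso, a.label)
                for a in self.atoms
            ],
            component_tag=self.component_tag,
        )

    def atom(self, label: AtomLabel) -> Atom:
        for a in self.atoms:
            if a.label == tuple(label):
                return a
        raise KeyError(f"no atom with label {label!r}")

    def find(self, **sel) -> list[Atom]:
        """Select atoms by label fields: chain=, resnum=, resname=, name=."""
        keys = {"chain": 0, "resnum": 1, "resname": 2, "name": 3}
        out = []
        for a in self.atoms:
            if all(a.label[keys[k]] == v for k, v in sel.items()):
                out.append(a)
        return out

    def positions_frac(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def positions_cart(self) -> np.ndarray:
        return self.cell.orthogonalize(self.positions_frac())

    def without(self, labels: set[AtomLabel] | list[AtomLabel]) -> "AtomicModel":
        labels = {tuple(l) for l in labels}
        kept = [a for a in self.atoms if a.label not in labels]
        if not kept:
            raise ValueError("omitting every atom leaves an empty model")
        m = self.copy()
        m.atoms = [a for a in m.atoms if a.label not in labels]
        return m


# --------------------------------------------------------------------------
# scattering factors

class FormFactorTable:
    """Gaussian scattering factors f(s) = sum_i a_i exp(-b_i s^2) + c.

    Coefficients come from the standard four-Gaussian International Tables
    parameterization shipped with gemmi; ``f(0)`` approximates the electron
    count of the neutral atom.
    """

    def __init__(self) -> None:
        self._cache: dict[str, tuple[np.ndarray, np.ndarray, float]] = {}

    def coefficients(self, element: str) -> tuple[np.ndarray, np.ndarray, float]:
        if element not in self._cache:
            el = gemmi.Element(element)
            if el.atomic_number == 0:
                raise ValueError(f"unknown element {element!r}")
            it92 = el.it92
            a = np.asarray(it92.a, dtype=float)
            b = np.asarray(it92.b, dtype=float)
            c = float(it92.c)
            f0 = a.sum() + c
            if abs(f0 - el.atomic_number) > 0.02 * el.atomic_number:
                raise ValueError(
                    f"form factors for {element}: f(0)={f0:.3f} deviates >2% "
                    f"from Z={el.atomic_number}"
                )
            self._cache[element] = (a, b, c)
        return self._cache[element]

    def evaluate(self, element: str, s2: np.ndarray) -> np.ndarray:
        """f(s) for an array of s^2 = (sin(theta)/lambda)^2 values."""
        a, b, c = self.coefficients(element)
        s2 = np.asarray(s2, dtype=float)
        return (a[None, :] * np.exp(-b[None, :] * s2[..., None])).sum(axis=-1) + c


FORM_FACTORS = FormFactorTable()


# --------------------------------------------------------------------------
# reflections

@dataclass
class ReflectionSet:
    """Friedel-unique reflections with amplitudes and optional phases.

    ``phase`` is in degrees; ``None`` means phases are unknown (observed
    data).  Rows are kept sorted lexicographically by (h, k, l).
    """

    cell: UnitCell
    hkl: np.ndarray          # (n, 3) int
    amplitude: np.ndarray    # (n,) float, >= 0
    sigma: np.ndarray | None = None
    phase: np.ndarray | None = None  # degrees

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        self.amplitude = np.asarray(self.amplitude, dtype=float).reshape(-1)
        n = len(self.hkl)
        if len(self.amplitude) != n:
            raise ValueError("hkl and amplitude length mismatch")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float).reshape(-1)
            if len(self.sigma) != n:
                raise ValueError("sigma length mismatch")
            if np.any(self.sigma < 0):
                raise ValueError("sigmas must be >= 0")
        if self.phase is not None:
            self.phase = np.asarray(self.phase, dtype=float).reshape(-1)
            if len(self.phase) != n:
                raise ValueError("phase length mismatch")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitudes must be >= 0")
        order = np.lexsort((self.hkl[:, 2], self.hkl[:, 1], self.hkl[:, 0]))
        self.hkl = self.hkl[order]
        self.amplitude = self.amplitude[order]
        if self.sigma is not None:
            self.sigma = self.sigma[order]
        if self.phase is not None:
            self.phase = self.phase[order]
        keys = [tuple(r) for r in self.hkl]
        if len(set(keys)) != n:
            raise ValueError("duplicate hkl indices")

    def __len__(self) -> int:
        return len(self.hkl)

    @property
    def d(self) -> np.ndarray:
        return self.cell.d_spacings(self.hkl)

    @property
    def s2(self) -> np.ndarray:
        """(sin(theta)/lambda)^2 = 1/(4 d^2)."""
        return 1.0 / (4.0 * self.d**2)

    def complex_values(self) -> np.ndarray:
        if self.phase is None:
            raise ValueError("reflection set has no phases")
        return self.amplitude * np.exp(1j * np.radians(self.phase))

    @classmethod
    def from_complex(
        cls, cell: UnitCell, hkl: np.ndarray, values: np.ndarray,
        sigma: np.ndarray | None = None,
    ) -> "ReflectionSet":
        return cls(
            cell=cell, hkl=hkl, amplitude=np.abs(values), sigma=sigma,
            phase=np.degrees(np.angle(values)),
        )

    def assert_same_hkl(self, other: "ReflectionSet") -> None:
        if len(self) != len(other) or not np.array_equal(self.hkl, other.hkl):
            mine = {tuple(r) for r in self.hkl}
            theirs = {tuple(r) for r in other.hkl}
            missing = sorted(mine ^ theirs)[:10]
            raise ValueError(
                f"hkl mismatch between reflection sets; first differing indices: {missing}"
            )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"h": self.hkl[:, 0], "k": self.hkl[:, 1], "l": self.hkl[:, 2],
             "d": self.d, "F": self.amplitude}
        )
        df["sigF"] = self.sigma if self.sigma is not None else 0.0
        if self.phase is not None:
            df["phase"] = self.phase
        return df

    def to_csv(self, path: str | Path) -> None:
        """Byte-stable CSV writer (fixed 6-decimal precision)."""
        df = self.to_frame()
        df.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")

    @classmethod
    def from_csv(cls, path: str | Path, cell: UnitCell) -> "ReflectionSet":
        df = pd.read_csv(path)
        for col in ("h", "k", "l", "F"):
            if col not in df:
                raise ValueError(f"reflection CSV missing column {col!r}")
        return cls(
            cell=cell,
            hkl=df[["h", "k", "l"]].to_numpy(dtype=int),
            amplitude=df["F"].to_numpy(dtype=float),
            sigma=df["sigF"].to_numpy(dtype=float) if "sigF" in df else None,
            phase=df["phase"].to_numpy(dtype=float) if "phase" in df else None,
        )

    def copy(self) -> "ReflectionSet":
        return ReflectionSet(
            cell=self.cell, hkl=self.hkl.copy(), amplitude=self.amplitude.copy(),
            sigma=None if self.sigma is None else self.sigma.copy(),
            phase=None if self.phase is None else self.phase.copy(),
        )


@dataclass(frozen=True)
class WeightingScheme:
    """Per-reflection difference-map weights m (figure of merit) and D (scale).

    Scalars broadcast over all reflections.  The refinement programs used on
    real data derive sigmaA-based weights internally; unit weights are the
    neutral default for synthetic data.
    """

    m: float | np.ndarray = 1.0
    D: float | np.ndarray = 1.0

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float)
        D = np.asarray(self.D, dtype=float)
        if np.any(m < 0) or np.any(m > 1):
            raise ValueError("m weights must lie in [0, 1]")
        if np.any(D <= 0):
            raise ValueError("D weights must be > 0")


# --------------------------------------------------------------------------
# structure factors

def hkl_grid(cell: UnitCell, resolution_limit: float) -> np.ndarray:
    """Friedel-unique (h,k,l) list complete to the resolution limit."""
    if resolution_limit <= 0:
        raise ValueError("resolution_limit must be > 0")
    Gstar = cell.reciprocal_metric()
    astar = np.sqrt(np.diag(Gstar))
    hmax = np.ceil(1.0 / (resolution_limit * astar)).astype(int)
    rng = [np.arange(-m, m + 1) for m in hmax]
    H, K, L = np.meshgrid(*rng, indexing="ij")
    hkl = np.column_stack([H.ravel(), K.ravel(), L.ravel()])
    hkl = hkl[np.any(hkl != 0, axis=1)]
    uniq = (hkl[:, 2] > 0) | ((hkl[:, 2] == 0) & (hkl[:, 1] > 0)) | (
        (hkl[:, 2] == 0) & (hkl[:, 1] == 0) & (hkl[:, 0] > 0)
    )
    hkl = hkl[uniq]
    d = cell.d_spacings(hkl)
    hkl = hkl[d >= resolution_limit]
    order = np.lexsort((hkl[:, 2], hkl[:, 1], hkl[:, 0]))
    return hkl[order]


def direct_summation(
    cell: UnitCell,
    hkl: np.ndarray,
    elements: list[str],
    positions_frac: np.ndarray,
    occupancy: np.ndarray,
    b_iso: np.ndarray,
) -> np.ndarray:
    """Complex F(h) = sum_j occ_j f_j(s) exp(-B_j s^2) exp(2 pi i h.x_j)."""
    d = cell.d_spacings(hkl)
    s2 = 1.0 / (4.0 * d**2)
    F = np.zeros(len(hkl), dtype=complex)
    phases = np.exp(2j * np.pi * (hkl @ np.asarray(positions_frac).T))  # (n_hkl, n_atoms)
    for elem in set(elements):
        idx = [j for j, e in enumerate(elements) if e == elem]
        f0 = FORM_FACTORS.evaluate(elem, s2)  # (n_hkl,)
        dw = np.exp(-np.outer(s2, b_iso[idx]))  # (n_hkl, n_sel)
        F += (f0[:, None] * dw * occupancy[idx][None, :] * phases[:, idx]).sum(axis=1)
    return F


def compute_structure_factors(
    model: AtomicModel, resolution_limit: float, sigma_frac: float = 0.0
) -> ReflectionSet:
    """Structure factors of a model by direct summation, with phases.

    ``sigma_frac`` fills the sigma column as a fraction of |F| (no noise is
    added; use the synthetic-data generator for that).
    """
    hkl = hkl_grid(model.cell, resolution_limit)
    F = direct_summation(
        model.cell, hkl,
        [a.element for a in model.atoms],
        model.positions_frac(),
        np.array([a.occupancy for a in model.atoms]),
        np.array([a.b_iso for a in model.atoms]),
    )
    sigma = sigma_frac * np.abs(F) if sigma_frac else None
    return ReflectionSet.from_complex(model.cell, hkl, F, sigma=sigma)


# --------------------------------------------------------------------------
# maps

@dataclass
class MapGrid:
    """Real-space density sampled on a regular grid over the unit cell."""

    cell: UnitCell
    values: np.ndarray  # (na, nb, nc) real
    f000_excluded: bool = True
    is_sigma_normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("map values must be a 3-d array")
        if self.f000_excluded and self.rms > 0:
            if abs(self.values.mean()) > 1e-6 * self.rms:
                raise ValueError("F000-excluded map must have zero mean")

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.values**2)))

    def interpolate(self, frac_xyz: np.ndarray) -> np.ndarray:
        """Trilinear interpolation with periodic wrapping (fractional coords)."""
        from scipy.ndimage import map_coordinates

        pts = np.atleast_2d(np.asarray(frac_xyz, dtype=float))
        coords = (pts % 1.0).T * np.array(self.values.shape)[:, None]
        return map_coordinates(self.values, coords, order=1, mode="grid-wrap")


def map_from_coefficients(
    coeffs: ReflectionSet, grid_spacing: float | None = None,
    resolution_limit: float | None = None,
) -> MapGrid:
    """Synthesize a real map from phased coefficients by inverse FFT.

    Default grid spacing is a third of the resolution limit (inferred from
    the finest d in the data when not given), comfortably finer than the
    Shannon limit of half the resolution.
    """
    if coeffs.phase is None:
        raise ValueError("map synthesis requires phases")
    d = coeffs.d
    res = resolution_limit if resolution_limit is not None else float(d.min())
    if grid_spacing is None:
        grid_spacing = res / 3.0
    if grid_spacing > res / 2.0 + 1e-12:
        raise ValueError(
            f"grid spacing {grid_spacing} coarser than half the resolution {res}"
        )
    cell = coeffs.cell
    dims = tuple(int(np.ceil(L / grid_spacing)) for L in (cell.a, cell.b, cell.c))
    grid = np.zeros(dims, dtype=complex)
    values = coeffs.complex_values()
    idx_pos = coeffs.hkl % np.array(dims)
    idx_neg = (-coeffs.hkl) % np.array(dims)
    grid[idx_pos[:, 0], idx_pos[:, 1], idx_pos[:, 2]] = values
    grid[idx_neg[:, 0], idx_neg[:, 1], idx_neg[:, 2]] = np.conj(values)
    rho = np.fft.fftn(grid).real / cell.volume
    return MapGrid(cell=cell, values=rho, f000_excluded=True)


def sigma_normalize(map_grid: MapGrid) -> MapGrid:
    """Divide a map by its cell-wide rms so contours are in sigma units."""
    rms = map_grid.rms
    if rms == 0:
        raise ValueError("cannot sigma-normalize a zero map")
    return MapGrid(
        cell=map_grid.cell, values=map_grid.values / rms,
        f000_excluded=map_grid.f000_excluded, is_sigma_normalized=True,
    )


def difference_coefficients(
    fobs: ReflectionSet,
    fcalc: ReflectionSet,
    weights: WeightingScheme = WeightingScheme(),
    kind: str = "mFo-DFc",
) -> ReflectionSet:
    """Weighted difference coefficients on the calculated phases.

    ``mFo-DFc``: (m|Fobs| - D|Fcalc|) exp(i phi_calc);
    ``2mFo-DFc``: (2m|Fobs| - D|Fcalc|) exp(i phi_calc).
    """
    if kind not in ("mFo-DFc", "2mFo-DFc"):
        raise ValueError(f"unknown coefficient kind {kind!r}")
    fobs.assert_same_hkl(fcalc)
    if fcalc.phase is None:
        raise ValueError("fcalc must carry phases")
    m = np.broadcast_to(np.asarray(weights.m, dtype=float), fobs.amplitude.shape)
    D = np.broadcast_to(np.asarray(weights.D, dtype=float), fobs.amplitude.shape)
    factor = 2.0 if kind == "2mFo-DFc" else 1.0
    amp = factor * m * fobs.amplitude - D * fcalc.amplitude
    values = amp * np.exp(1j * np.radians(fcalc.phase))
    return ReflectionSet.from_complex(fobs.cell, fobs.hkl, values)


def fo_fo_difference(
    fobs_t: ReflectionSet,
    fobs_ref: ReflectionSet,
    phases_from: AtomicModel,
    grid_spacing: float | None = None,
) -> MapGrid:
    """Isomorphous Fobs(t) - Fobs(ref) difference map with model phases."""
    keys_t = {tuple(r): i for i, r in enumerate(fobs_t.hkl)}
    keys_r = {tuple(r): i for i, r in enumerate(fobs_ref.hkl)}
    common = sorted(set(keys_t) & set(keys_r))
    if not common:
        raise ValueError("reflection sets share no hkl indices")
    it = np.array([keys_t[k] for k in common])
    ir = np.array([keys_r[k] for k in common])
    hkl = np.array(common)
    delta = fobs_t.amplitude[it] - fobs_ref.amplitude[ir]
    fc = direct_summation(
        phases_from.cell, hkl,
        [a.element for a in phases_from.atoms],
        phases_from.positions_frac(),
        np.array([a.occupancy for a in phases_from.atoms]),
        np.array([a.b_iso for a in phases_from.atoms]),
    )
    phi = np.angle(fc)
    values = delta * np.exp(1j * phi)
    coeffs = ReflectionSet.from_complex(fobs_t.cell, hkl, values)
    return map_from_coefficients(coeffs, grid_spacing=grid_spacing)


def scale_to_reference(
    dataset: ReflectionSet, reference: ReflectionSet, n_bins: int = 10
) -> ReflectionSet:
    """Scale a dataset to a reference on a per-resolution-bin basis.

    Bins are equal-count in s; within each bin the least-squares factor
    ``k_b = sum |F_ref||F| / sum |F|^2`` multiplies amplitudes and sigmas.
    Bins with too few reflections are merged with their neighbour.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    dataset.assert_same_hkl(reference)
    n = len(dataset)
    if n == 0:
        raise ValueError("empty reflection set")
    order = np.argsort(dataset.s2, kind="stable")
    edges = np.linspace(0, n, n_bins + 1).astype(int)
    edges = np.unique(edges)
    if len(edges) - 1 < n_bins:
        logger.info("scale_to_reference: merged empty bins (%d -> %d)",
                    n_bins, len(edges) - 1)
    scale = np.empty(n)
    for lo, hi in zip(edges[:-1], edges[1:]):
        idx = order[lo:hi]
        denom = np.sum(dataset.amplitude[idx] ** 2)
        if denom == 0:
            k = 1.0
        else:
            k = np.sum(reference.amplitude[idx] * dataset.amplitude[idx]) / denom
        scale[idx] = k
    out = dataset.copy()
    out.amplitude = out.amplitude * scale
    if out.sigma is not None:
        out.sigma = out.sigma * scale
    return out


def unit_cell_filter(cells: list[UnitCell], reference: UnitCell,
                     threshold: float = 0.01) -> list[bool]:
    """Validation check: flag cells within a fractional threshold of a
    reference on every axis length (the merging-stage 1% lattice filter)."""
    out = []
    ref = np.array([reference.a, reference.b, reference.c])
    for c in cells:
        dev = np.abs(np.array([c.a, c.b, c.c]) - ref) / ref
        out.append(bool(np.all(dev <= threshold)))
    return out


# --------------------------------------------------------------------------
# model file IO (PDB / mmCIF via gemmi)

def write_model(model: AtomicModel, path: str | Path) -> None:
    """Write a model as PDB or mmCIF (by extension: .pdb / .cif / .mmcif)."""
    st = gemmi.Structure()
    st.name = model.component_tag or "toy"
    st.cell = model.cell.to_gemmi()
    st.spacegroup_hm = "P 1"
    md = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for atom in model.atoms:
        chain_name, resnum, resname, atname = atom.label
        if chain_name not in chains:
            chains[chain_name] = gemmi.Chain(chain_name)
        chain = chains[chain_name]
        res = None
        for r in chain:
            if r.seqid.num == resnum and r.name == resname:
                res = r
                break
        if res is None:
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(resnum, " ")
            chain.add_residue(res)
            res = chain[-1]
        ga = gemmi.Atom()
        ga.name = atname
        ga.element = gemmi.Element(atom.element)
        cart = model.cell.orthogonalize(atom.position)
        ga.pos = gemmi.Position(*cart)
        ga.occ = atom.occupancy
        ga.b_iso = atom.b_iso
        res.add_atom(ga)
    for chain in chains.values():
        md.add_chain(chain)
    st.add_model(md)
    st.setup_entities()
    path = Path(path)
    if path.suffix.lower() in (".cif", ".mmcif"):
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))


def read_model(path: str | Path, component_tag: str = "") -> AtomicModel:
    """Read a PDB or mmCIF file into an AtomicModel (first model only)."""
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"malformed structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"structure file {path} contains no models")
    cell = UnitCell(st.cell.a, st.cell.b, st.cell.c,
                    st.cell.alpha, st.cell.beta, st.cell.gamma)
    atoms = []
    for chain in st[0]:
        for res in chain:
            for ga in res:
                frac = cell.fractionalize([ga.pos.x, ga.pos.y, ga.pos.z])
                atoms.append(
                    Atom(
                        element=ga.element.name,
                        position=np.asarray(frac) % 1.0,
                        occupancy=float(ga.occ),
                        b_iso=float(ga.b_iso),
                        label=(chain.name, res.seqid.num, res.name, ga.name),
                    )
                )
    if not atoms:
        raise ValueError(f"structure file {path} contains no atoms")
    return AtomicModel(cell=cell, atoms=atoms, component_tag=component_tag)
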
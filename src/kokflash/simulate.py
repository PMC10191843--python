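"""Ground-truth toy scenarios with the statistical structure of the real study.

The generator builds an abstracted analog of the oxygen-evolving complex
(OEC) in a small P1 cell: four Mn centers, a Ca, bridging oxygens including
the extra Ox bridge present in the S3-like state, terminal waters, a
Yz/His hydrogen-bonded pair, a proton-gate carboxylate dyad and two
channel waters.  Between the S3-like and S0-like endpoints an intermediate
is interpolated whose kinetic markers follow the qualitative windows of
the S3->S0 transition:

* Ox occupancy decays logistically (midpoint 1,000 us; ~0.95 at 250 us,
  ~0.18 at 2,000 us);
* the Mn1-Mn4 analog distance contracts from 5.14 to 4.90 A with a later
  midpoint (1,400 us), so contraction lags Ox loss;
* the Yz-His analog distance jumps from 2.6 to 2.8 A within tens of us
  and recovers around 600 us;
* the proton-gate dyad transiently elongates from 2.6 toward 3.2 A around
  1,200 us;
* a mobile channel water's B factor inflates to ~50 A^2 near 1,200 us and
  relaxes back to ~37 A^2, while a stable channel water stays at 37 A^2.

Each simulated time point is a Kok-style mixture (advancing primary,
lagging S3-like secondary, completed S0-like tertiary) with fractional
Gaussian amplitude noise, emitted together with a full truth record so
recovery tests can compare against the exact generating values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .crystal import (
    Atom,
    AtomicModel,
    AtomLabel,
    ReflectionSet,
    UnitCell,
    compute_structure_factors,
    read_model,
    write_model,
)
from .kok import (
    ComponentSplit,
    FlashProtocol,
    SStatePopulation,
    apply_noise_floor,
    assign_components,
    exponential_completion,
    propagate_flashes,
    transition_matrix,
)
from .mixture import Component, MultiComponentModel, RestraintSet, build_restraints

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "TRUTH_SPLIT_1200US",
    "make_oec_toy",
    "true_markers",
    "interpolate_intermediate",
    "simulate_timepoint",
    "emit_scenario",
    "load_timepoint",
    "default_topology",
    "default_restraints",
    "WATER_LABELS",
    "OX_LABEL",
    "MN1_LABEL",
    "MN4_LABEL",
    "YZ_LABEL",
    "HIS_LABEL",
    "GATE_A_LABEL",
    "GATE_B_LABEL",
]

# derived once from the printed component table: the 2F start is 65% S3,
# and the 1,200-us split 0.40/0.35/0.25 implies completed = 0.25/0.65
MISS_2F = 1.0 - np.sqrt(0.65)          # (1-m)^2 = 0.65
DEFAULT_COMPLETION_TAU_US = 1200.0 / np.log(0.65 / 0.40)

TRUTH_SPLIT_1200US = (0.40, 0.35, 0.25)

# canonical atom labels of the toy model
MN1_LABEL: AtomLabel = ("A", 601, "OEC", "MN1")
MN4_LABEL: AtomLabel = ("A", 601, "OEC", "MN4")
OX_LABEL: AtomLabel = ("A", 601, "OEC", "OX")
YZ_LABEL: AtomLabel = ("A", 161, "TYR", "OH")
HIS_LABEL: AtomLabel = ("A", 190, "HIS", "NE2")
GATE_A_LABEL: AtomLabel = ("A", 65, "GLU", "OE1")
GATE_B_LABEL: AtomLabel = ("A", 312, "GLU", "OE1")

# field-standard water names -> toy atom labels
WATER_LABELS: dict[str, AtomLabel] = {
    "W1": ("A", 901, "HOH", "O"),
    "W2": ("A", 902, "HOH", "O"),
    "W3": ("A", 903, "HOH", "O"),
    "W4": ("A", 904, "HOH", "O"),
    "W27": ("A", 927, "HOH", "O"),
    "W29": ("A", 929, "HOH", "O"),
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for a synthetic S3->S0 scenario."""

    time_grid_us: tuple[float, ...] = (50.0, 250.0, 500.0, 730.0, 1200.0, 2000.0, 4000.0)
    resolution: float = 2.0
    noise: float = 0.03                  # fractional amplitude sd per reflection
    miss: float = MISS_2F
    double_hit: float = 0.0
    completion_tau_us: float = DEFAULT_COMPLETION_TAU_US
    seed: int = 0
    cell_edge: float = 24.0
    ox_mid_us: float = 1000.0
    ox_width_log10: float = 0.2
    contraction_mid_us: float = 1400.0
    contraction_width_log10: float = 0.15
    yz_recovery_mid_us: float = 600.0
    gate_mid_us: float = 1200.0

    def __post_init__(self) -> None:
        grid = np.asarray(self.time_grid_us)
        if np.any(np.diff(grid) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")


@dataclass
class GroundTruth:
    """Generating values for one simulated time point."""

    delay_us: float
    split: dict[str, float]
    ox_occupancy: float
    markers: dict[str, float]
    seed: int
    true_primary: AtomicModel | None = None

    def to_jsonable(self) -> dict:
        return {
            "delay_us": self.delay_us,
            "split": self.split,
            "ox_occupancy": self.ox_occupancy,
            "markers": self.markers,
            "seed": self.seed,
        }


# --------------------------------------------------------------------------
# geometry of the toy OEC analog

def _unit(v) -> np.ndarray:
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)

_U_MN4 = _unit((2.710, 3.439, 2.691))    # Mn1 -> Mn4 direction
_U_YZ = _unit((1.0, 0.3, 0.2))           # Yz-OH -> His-NE2 direction
_U_GATE = _unit((2.0, 1.4, 0.9))         # gate dyad axis

_SHIFT_REF = np.array([-3.0, 0.0, -1.6])  # recenters the motif in the cell

S3_MN1_MN4 = 5.14
S0_MN1_MN4 = 4.90
YZ_BASE, YZ_OXIDIZED = 2.6, 2.8
GATE_BASE, GATE_PEAK = 2.6, 3.2
WATER_B_STABLE, WATER_B_PEAK = 37.0, 50.0


def _base_coordinates(mn1_mn4: float, yz_his: float, gate: float,
                      w27_b: float) -> list[tuple[str, AtomLabel, np.ndarray, float]]:
    """(element, label, cartesian position, b_iso) for every toy atom."""
    # metal frame patterned on the real Mn4CaO5(-Ox) cluster:
    # Mn1-Mn2 2.8, Mn2-Mn3 2.7, Mn1-Mn3 3.3, Mn3-Mn4 2.9, Mn1-Mn4 5.14 (S3)
    mn1 = np.zeros(3)
    mn2 = np.array([2.8, 0.0, 0.0])
    mn3 = np.array([2.043, 2.592, 0.0])
    mn4 = mn1_mn4 * _U_MN4
    mn4_s3 = S3_MN1_MN4 * _U_MN4  # static ligands are anchored to the S3 site
    ca = np.array([1.2, 0.6, 3.0])

    # oxo bridges (~1.7-2.1 A to their metals)
    o1 = np.array([1.4, 0.2, 1.0])                    # Mn1/Mn2/Ca
    o2 = mn2 + 1.8 * _unit((0.8, -1.2, -1.0))         # terminal oxo on Mn2
    o3 = np.array([1.4, 0.998, -1.0])                 # central mu3: Mn1/Mn2/Mn3
    w_dir = _unit(mn4_s3 - mn3)
    q_perp = _unit(np.cross(w_dir, (0.0, 0.0, 1.0)))
    o4 = (mn3 + mn4_s3) / 2.0 + 0.9 * q_perp          # Mn3/Mn4 bridge
    o5 = mn4_s3 + 1.9 * _unit(0.8 * _unit(mn1 - mn4_s3) - 0.6 * q_perp)  # dangler
    # Ox bridges Mn1 (1.9 A) and Ca (2.4 A), off the Mn1-Ca axis
    u_ca = _unit(ca)
    p_ca = _unit(np.cross(u_ca, (0.0, 1.0, 0.0)))
    ox = 1.366 * u_ca + 1.32 * p_ca

    # W1/W2 are Mn4 ligands and ride with it; W3/W4 ligate Ca and stay
    w1 = mn4 + 2.1 * _unit((0.5, 0.5, 0.85))
    w2 = mn4 + 2.1 * _unit((0.3, -0.7, 0.65))
    w3 = ca + 2.4 * _unit((-0.5, -1.0, 0.6))
    w4 = ca + 2.4 * _unit((-1.0, 0.6, 0.6))

    yz_oh = np.array([9.2, -2.8, 1.5])
    his_ne2 = yz_oh + yz_his * _U_YZ
    # phenol ring scaffold behind the OH (regular hexagon, C-C 1.39 A)
    cz = yz_oh - 1.4 * _U_YZ
    ring_center = cz - 1.39 * _U_YZ
    e2 = _unit(np.cross(_U_YZ, (0.0, 0.0, 1.0)))
    ring = []
    for name, k in (("CZ", 0), ("CE1", 1), ("CD1", 2), ("CG", 3),
                    ("CD2", 4), ("CE2", 5)):
        ang = k * np.pi / 3.0
        ring.append(
            (name, ring_center + 1.39 * (np.cos(ang) * _U_YZ + np.sin(ang) * e2))
        )

    gate_a = np.array([-4.0, 3.5, 2.0])
    gate_b = gate_a + gate * _U_GATE

    w27 = np.array([-3.0, -3.5, 1.0])
    w29 = np.array([-5.5, 0.5, 3.5])

    atoms: list[tuple[str, AtomLabel, np.ndarray, float]] = [
        ("Mn", MN1_LABEL, mn1, 20.0),
        ("Mn", ("A", 601, "OEC", "MN2"), mn2, 20.0),
        ("Mn", ("A", 601, "OEC", "MN3"), mn3, 20.0),
        ("Mn", MN4_LABEL, mn4, 20.0),
        ("Ca", ("A", 601, "OEC", "CA1"), ca, 20.0),
        ("O", ("A", 601, "OEC", "O1"), o1, 25.0),
        ("O", ("A", 601, "OEC", "O2"), o2, 25.0),
        ("O", ("A", 601, "OEC", "O3"), o3, 25.0),
        ("O", ("A", 601, "OEC", "O4"), o4, 25.0),
        ("O", ("A", 601, "OEC", "O5"), o5, 25.0),
        ("O", OX_LABEL, ox, 25.0),
        ("O", WATER_LABELS["W1"], w1, 30.0),
        ("O", WATER_LABELS["W2"], w2, 30.0),
        ("O", WATER_LABELS["W3"], w3, 30.0),
        ("O", WATER_LABELS["W4"], w4, 30.0),
        ("O", YZ_LABEL, yz_oh, 25.0),
        ("N", HIS_LABEL, his_ne2, 25.0),
        ("O", GATE_A_LABEL, gate_a, 25.0),
        ("O", GATE_B_LABEL, gate_b, 25.0),
        ("O", WATER_LABELS["W27"], w27, w27_b),
        ("O", WATER_LABELS["W29"], w29, WATER_B_STABLE),
    ]
    for name, pos in ring:
        atoms.append(("C", ("A", 161, "TYR", name), pos, 25.0))
    return atoms


def make_oec_toy(state: str, cell_edge: float = 24.0) -> AtomicModel:
    """Toy OEC analog in its S3-like or S0-like endpoint geometry.

    The S3-like state carries the Ox bridge and an elongated Mn1-Mn4
    analog distance of 5.14 A; the S0-like state has no Ox atom and a
    contracted distance of 4.90 A.
    """
    if state not in ("S3_like", "S0_like"):
        raise ValueError(f"unknown state {state!r}")
    mn1_mn4 = S3_MN1_MN4 if state == "S3_like" else S0_MN1_MN4
    atoms_raw = _base_coordinates(
        mn1_mn4, yz_his=YZ_BASE, gate=GATE_BASE, w27_b=WATER_B_STABLE
    )
    cell = UnitCell(cell_edge, cell_edge, cell_edge)
    shift = np.array([cell_edge, cell_edge, cell_edge]) / 2.0 + _SHIFT_REF
    atoms = []
    for elem, label, cart, b in atoms_raw:
        if state == "S0_like" and label == OX_LABEL:
            continue
        frac = cell.fractionalize(cart + shift) % 1.0
        atoms.append(Atom(element=elem, position=frac, occupancy=1.0,
                          b_iso=b, label=label))
    return AtomicModel(cell=cell, atoms=atoms, component_tag=state)


def _logistic_down(t_us: float, mid_us: float, width_log10: float) -> float:
    """1 at t<<mid, 0 at t>>mid, midpoint in log10-time."""
    if t_us <= 0:
        return 1.0
    z = (np.log10(t_us) - np.log10(mid_us)) / width_log10
    return float(1.0 / (1.0 + np.exp(np.clip(z, -50, 50))))


def _log_gauss_bump(t_us: float, mid_us: float, sigma_log10: float) -> float:
    if t_us <= 0:
        return 0.0
    z = (np.log10(t_us) - np.log10(mid_us)) / sigma_log10
    return float(np.exp(-z * z))


def true_markers(t_us: float, config: ScenarioConfig) -> dict[str, float]:
    """Closed-form generating values of every kinetic marker at time t."""
    ox_occ = _logistic_down(t_us, config.ox_mid_us, config.ox_width_log10)
    contraction = 1.0 - _logistic_down(
        t_us, config.contraction_mid_us, config.contraction_width_log10
    )
    mn1_mn4 = S3_MN1_MN4 - (S3_MN1_MN4 - S0_MN1_MN4) * contraction
    rise = 1.0 - np.exp(-t_us / 10.0)  # Yz oxidation within tens of us
    recovery = _logistic_down(t_us, config.yz_recovery_mid_us, 0.15)
    yz_his = YZ_BASE + (YZ_OXIDIZED - YZ_BASE) * rise * recovery
    gate = GATE_BASE + (GATE_PEAK - GATE_BASE) * _log_gauss_bump(
        t_us, config.gate_mid_us, 0.25
    )
    w27_b = WATER_B_STABLE + (WATER_B_PEAK - WATER_B_STABLE) * _log_gauss_bump(
        t_us, 1200.0, 0.25
    )
    return {
        "ox_occupancy": ox_occ,
        "mn1_mn4": float(mn1_mn4),
        "yz_his": float(yz_his),
        "gate_dyad": float(gate),
        "w27_b": float(w27_b),
        "w29_b": WATER_B_STABLE,
    }


def interpolate_intermediate(
    t_us: float, config: ScenarioConfig = ScenarioConfig()
) -> tuple[AtomicModel, float]:
    """The advancing intermediate's model and Ox occupancy at time t.

    At t=0 this is the S3-like geometry with Ox fully occupied; as t grows
    the markers follow the generator's kinetic laws and the model tends to
    the S0-like geometry with vanishing Ox occupancy.
    """
    m = true_markers(t_us, config)
    atoms_raw = _base_coordinates(
        m["mn1_mn4"], yz_his=m["yz_his"], gate=m["gate_dyad"], w27_b=m["w27_b"]
    )
    cell = UnitCell(config.cell_edge, config.cell_edge, config.cell_edge)
    shift = np.array([config.cell_edge] * 3) / 2.0 + _SHIFT_REF
    atoms = []
    for elem, label, cart, b in atoms_raw:
        occ = m["ox_occupancy"] if label == OX_LABEL else 1.0
        frac = cell.fractionalize(cart + shift) % 1.0
        atoms.append(Atom(element=elem, position=frac, occupancy=occ,
                          b_iso=b, label=label))
    model = AtomicModel(cell=cell, atoms=atoms, component_tag="primary")
    return model, m["ox_occupancy"]


# --------------------------------------------------------------------------
# restraint topology

def default_topology(model: AtomicModel, cutoff: float = 2.6) -> list[tuple]:
    """Bond topology: all atom pairs closer than the cutoff, excluding
    water-water and hydrogen-bond-like O/N-O/N contacts between residues."""
    cart = model.positions_cart()
    atoms = model.atoms
    pairs = []
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            d = np.linalg.norm(cart[i] - cart[j])
            if d >= cutoff:
                continue
            li, lj = atoms[i].label, atoms[j].label
            both_water = li[2] == "HOH" and lj[2] == "HOH"
            metals = {"Mn", "Ca"}
            covalent_or_metal = (
                atoms[i].element in metals or atoms[j].element in metals
                or li[:2] == lj[:2]  # same residue
            )
            if both_water or not covalent_or_metal:
                continue
            pairs.append((li, lj))
    return pairs


def default_restraints(model: AtomicModel) -> RestraintSet:
    """Bond restraints over the default topology with the loose 0.1 A esd."""
    return build_restraints(model, bonds=default_topology(model))


# --------------------------------------------------------------------------
# per-time-point simulation

def _truth_split(t_us: float, config: ScenarioConfig) -> ComponentSplit:
    initial = SStatePopulation.pure("S1")
    two_flash = propagate_flashes(
        initial, FlashProtocol(n_flashes=2, miss=config.miss,
                               double_hit=config.double_hit)
    )
    # final (third) flash treated as saturating for the component split
    after = transition_matrix(FlashProtocol(n_flashes=1, miss=0.0)) @ two_flash.as_array()
    after_pop = SStatePopulation(tuple(after))
    completed = exponential_completion(config.completion_tau_us)(t_us)
    split = assign_components(after_pop, completed, flash_index=3)
    return apply_noise_floor(split)


_COMPONENT_TAGS = {"primary": "primary", "S3": "s3", "S0": "s0"}


def simulate_timepoint(
    t_us: float, config: ScenarioConfig = ScenarioConfig()
) -> tuple[ReflectionSet, MultiComponentModel, GroundTruth]:
    """Noisy observed amplitudes, a starting-guess mixture model and the truth.

    Fobs is |sum_k p_k F_k| of the true component mixture plus fractional
    Gaussian noise.  The starting guess deliberately uses the S3-like
    geometry (Ox fully occupied) for the primary, so refinement has to move
    it; its component populations equal the truth split, mirroring how the
    real analysis fixes populations from independent kinetic data.
    """
    split = _truth_split(t_us, config)
    primary_true, ox_occ = interpolate_intermediate(t_us, config)
    s3 = make_oec_toy("S3_like", config.cell_edge)
    s0 = make_oec_toy("S0_like", config.cell_edge)

    label_map = {"S3->S0": ("primary", primary_true),
                 "S3": ("s3", s3), "S0": ("s0", s0)}
    true_components, guess_components = [], []
    for lab, frac in split.items():
        tag, model = label_map[lab]
        true_components.append(Component(model.copy(), frac, tag == "primary", tag))
        guess_model = s3.copy() if tag == "primary" else model.copy()
        guess_model.component_tag = tag
        guess_components.append(Component(guess_model, frac, tag == "primary", tag))
    truth_mcm = MultiComponentModel(true_components)
    guess_mcm = MultiComponentModel(guess_components)

    from .mixture import composite_structure_factors

    fcalc = composite_structure_factors(truth_mcm, config.resolution)
    rng = np.random.default_rng([config.seed, int(round(t_us * 10.0))])
    sigma = config.noise * fcalc.amplitude
    noisy = fcalc.amplitude + rng.normal(0.0, 1.0, len(fcalc)) * sigma
    fobs = ReflectionSet(
        cell=fcalc.cell, hkl=fcalc.hkl,
        amplitude=np.maximum(noisy, 0.0), sigma=sigma,
    )
    truth = GroundTruth(
        delay_us=t_us,
        split={label_map[lab][0]: frac for lab, frac in split.items()},
        ox_occupancy=ox_occ,
        markers=true_markers(t_us, config),
        seed=config.seed,
        true_primary=primary_true,
    )
    return fobs, guess_mcm, truth


# --------------------------------------------------------------------------
# scenario emission / loading

def emit_scenario(config: ScenarioConfig, out_dir: str | Path) -> Path:
    """Write a full scenario tree: one directory per time point plus the
    2F and 3F(200 ms) endpoint anchors, and a top-level manifest."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ValueError(f"cannot create output directory {out}: {exc}") from exc

    entries = []
    for t in config.time_grid_us:
        name = f"t{int(round(t)):07d}us"
        tdir = out / name
        tdir.mkdir(exist_ok=True)
        fobs, guess, truth = simulate_timepoint(t, config)
        fobs.to_csv(tdir / "reflections.csv")
        manifest = []
        for comp in guess.components:
            fname = f"{comp.label}.pdb"
            write_model(comp.model, tdir / fname)
            manifest.append({"label": comp.label, "population": comp.population,
                             "refinable": comp.refinable, "file": fname})
        (tdir / "components.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        (tdir / "truth.json").write_text(
            json.dumps(truth.to_jsonable(), indent=2, sort_keys=True) + "\n"
        )
        entries.append({"delay_us": t, "dir": name})

    endpoint_streams = {"endpoint_2F": 1000001, "endpoint_3F200ms": 1000002}
    for name, state in (("endpoint_2F", "S3_like"), ("endpoint_3F200ms", "S0_like")):
        edir = out / name
        edir.mkdir(exist_ok=True)
        model = make_oec_toy(state, config.cell_edge)
        write_model(model, edir / f"{state}.pdb")
        fobs = compute_structure_factors(model, config.resolution)
        rng = np.random.default_rng([config.seed, endpoint_streams[name]])
        sigma = config.noise * fobs.amplitude
        noisy = np.maximum(
            fobs.amplitude + rng.normal(0.0, 1.0, len(fobs)) * sigma, 0.0
        )
        ReflectionSet(cell=fobs.cell, hkl=fobs.hkl, amplitude=noisy,
                      sigma=sigma).to_csv(edir / "reflections.csv")
        entries.append({"state": state, "dir": name})

    cfg = asdict(config)
    cfg["time_grid_us"] = list(cfg["time_grid_us"])
    (out / "manifest.json").write_text(
        json.dumps({"config": cfg, "entries": entries}, indent=2, sort_keys=True)
        + "\n"
    )
    return out


def load_timepoint(tdir: str | Path) -> tuple[ReflectionSet, MultiComponentModel, dict]:
    """Read back one emitted time-point directory."""
    tdir = Path(tdir)
    truth = json.loads((tdir / "truth.json").read_text())
    manifest = json.loads((tdir / "components.json").read_text())
    components = []
    cell = None
    for entry in manifest:
        model = read_model(tdir / entry["file"], component_tag=entry["label"])
        cell = model.cell
        components.append(
            Component(model, entry["population"], entry["refinable"], entry["label"])
        )
    mcm = MultiComponentModel(components)
    fobs = ReflectionSet.from_csv(tdir / "reflections.csv", cell)
    return fobs, mcm, truth
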
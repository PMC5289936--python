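"""Synthetic symmetric molecules and orbital sets: the test-data supply.

Molecules are produced by orbit expansion: every operation of the target
group applied to seed positions, coincident images merged.  General
position seeds are drawn from a fixed quasi-random (plastic constant)
sequence so they never accidentally sit on a symmetry element; special
positions (on-axis metals, in-plane atoms, ...) must be requested
explicitly.  Gaussian coordinate noise emulates near-symmetric input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry_io import Atom, Molecule
from .masses import mass_of
from .point_group import generate_group_operations


@dataclass
class OrbitSeed:
    element: str
    position: np.ndarray
    mass: float | None = None
    special: bool = False  # seed deliberately placed on symmetry elements


# plastic-constant low-discrepancy sequence, offset to avoid special positions
_PLASTIC = 1.3247179572447460


def general_positions(count: int, radius: float = 3.0,
                      sequence_offset: int = 0) -> list[np.ndarray]:
    """Deterministic quasi-random general positions at increasing radii.

    ``sequence_offset`` advances the underlying low-discrepancy sequence;
    callers use it to step past seed sets that happen to fall within the
    geometric tolerance of a *higher* symmetry than intended.
    """
    out = []
    a1, a2 = 1.0 / _PLASTIC, 1.0 / _PLASTIC**2
    for k in range(count):
        i = k + 1 + sequence_offset * (count + 1)
        u = (0.13 + a1 * i) % 1.0
        v = (0.37 + a2 * i) % 1.0
        theta = math.acos(1 - 2 * (0.05 + 0.9 * u))
        phi = 2 * math.pi * v + 0.21
        r = radius * (1.0 + 0.35 * k)
        out.append(r * np.array([
            math.sin(theta) * math.cos(phi),
            math.sin(theta) * math.sin(phi),
            math.cos(theta),
        ]))
    return out


def generate_symmetric_molecule(
    label: str,
    seeds: list[OrbitSeed],
    noise_sigma: float = 0.0,
    rng_seed: int = 0,
    dedupe_tol: float = 1e-8,
) -> Molecule:
    """Orbit-expand seeds under ``label``; optionally add isotropic Gaussian
    coordinate noise.  With σ = 0 detection must return exactly ``label``
    (provided the seed set breaks any accidental higher symmetry)."""
    group = generate_group_operations(label)
    atoms: list[Atom] = []
    for seed in seeds:
        mass = seed.mass if seed.mass is not None else mass_of(seed.element)
        images: list[np.ndarray] = []
        for op in group.operations:
            p = op.matrix @ np.asarray(seed.position, dtype=float)
            if not any(np.linalg.norm(p - q) < dedupe_tol for q in images):
                images.append(p)
        if len(images) < len(group) and not seed.special:
            raise ValueError(
                f"seed at {seed.position} lies on a symmetry element of "
                f"{label} (orbit {len(images)} < {len(group)}); flag it as "
                "special if intended"
            )
        for p in images:
            atoms.append(Atom(seed.element, mass, p))
    mol = Molecule(atoms, comment=f"synthetic {label} orbit")
    if noise_sigma > 0:
        rng = np.random.default_rng(rng_seed)
        noisy = mol.positions + rng.normal(0.0, noise_sigma, (len(mol), 3))
        mol = mol.with_positions(noisy)
    return mol.recentered()


def default_orbit_molecule(
    label: str,
    n_seeds: int = 2,
    noise_sigma: float = 0.0,
    rng_seed: int = 0,
    max_attempts: int = 20,
) -> Molecule:
    """Convenience fixture: ``n_seeds`` general-position orbits of distinct
    elements.  Two orbits are enough to break the accidental extra symmetry
    a single orbit can carry (a lone C_n orbit is a regular polygon).

    A quasi-random seed set can still land within the geometric tolerance
    of a supergroup (e.g. two rings whose azimuth offset almost matches a
    mirror grid) — a detector honouring its tolerance then reports the
    higher group, which is correct behaviour but the wrong fixture.  The
    generator therefore verifies the ideal orbit detects as exactly
    ``label`` and advances the deterministic sequence until it does.
    """
    from .pipeline import detect  # deferred: avoids an import cycle

    elems = ["C", "N", "O", "F", "P", "S"]
    last = None
    for attempt in range(max_attempts):
        seeds = [
            OrbitSeed(elems[i % len(elems)], pos)
            for i, pos in enumerate(
                general_positions(n_seeds, sequence_offset=attempt))
        ]
        try:
            ideal = generate_symmetric_molecule(label, seeds)
            last = detect(ideal).label
        except ValueError:
            continue  # seed on a special position; step the sequence
        if last == label:
            if noise_sigma > 0:
                return generate_symmetric_molecule(
                    label, seeds, noise_sigma, rng_seed)
            return ideal
    raise RuntimeError(
        f"no robustly general seed set found for {label} "
        f"(last detection: {last})")


def generate_nanotube(
    n: int, rings: int = 4, radius: float = 3.0, pitch: float = 1.2,
    element: str = "C",
) -> Molecule:
    """Staggered ring stack with exact D_nd symmetry by construction.

    ``rings`` is rounded up to an even count; consecutive rings alternate a
    π/n azimuthal offset and the stack is centred on z = 0.
    """
    if n < 2:
        raise ValueError("rotational order must be at least 2")
    rings += rings % 2
    atoms = []
    z0 = -(rings - 1) / 2.0 * pitch
    for i in range(rings):
        offset = (i % 2) * math.pi / n
        z = z0 + i * pitch
        for k in range(n):
            phi = 2 * math.pi * k / n + offset
            atoms.append(Atom(element, mass_of(element),
                              np.array([radius * math.cos(phi),
                                        radius * math.sin(phi), z])))
    return Molecule(atoms, comment=f"synthetic D{n}d nanotube").recentered()


# --- reference geometries used across the test-suite ----------------------


def water() -> Molecule:
    d, half = 0.9572, math.radians(104.52 / 2)
    atoms = [
        Atom("O", mass_of("O"), np.zeros(3)),
        Atom("H", mass_of("H"),
             np.array([d * math.sin(half), 0.0, d * math.cos(half)])),
        Atom("H", mass_of("H"),
             np.array([-d * math.sin(half), 0.0, d * math.cos(half)])),
    ]
    return Molecule(atoms, "water (C2v)").recentered()


def ammonia() -> Molecule:
    d, theta = 1.012, math.radians(106.7)
    # pyramid: N apex on z, three H in a ring
    zh = d * math.cos(math.asin(math.sin(theta / 2) / math.sin(math.pi / 3)))
    rh = math.sqrt(max(d * d - zh * zh, 0.0))
    atoms = [Atom("N", mass_of("N"), np.array([0.0, 0.0, 0.0]))]
    for k in range(3):
        phi = 2 * math.pi * k / 3
        atoms.append(Atom("H", mass_of("H"),
                          np.array([rh * math.cos(phi), rh * math.sin(phi), -zh])))
    return Molecule(atoms, "ammonia (C3v)").recentered()


def methane() -> Molecule:
    d = 1.087 / math.sqrt(3)
    atoms = [Atom("C", mass_of("C"), np.zeros(3))]
    for sx, sy, sz in ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)):
        atoms.append(Atom("H", mass_of("H"), d * np.array([sx, sy, sz], float)))
    return Molecule(atoms, "methane (Td)").recentered()


def benzene() -> Molecule:
    rc, rh = 1.397, 1.397 + 1.084
    atoms = []
    for k in range(6):
        phi = 2 * math.pi * k / 6
        c, s = math.cos(phi), math.sin(phi)
        atoms.append(Atom("C", mass_of("C"), np.array([rc * c, rc * s, 0.0])))
        atoms.append(Atom("H", mass_of("H"), np.array([rh * c, rh * s, 0.0])))
    return Molecule(atoms, "benzene (D6h)").recentered()


def ferrocene() -> Molecule:
    """Staggered (D5d) ferrocene."""
    rc, rh, zc = 1.433, 2.25, 1.66
    atoms = [Atom("Fe", mass_of("Fe"), np.zeros(3))]
    for sz, offset in ((1, 0.0), (-1, math.pi / 5)):
        for k in range(5):
            phi = 2 * math.pi * k / 5 + offset
            c, s = math.cos(phi), math.sin(phi)
            atoms.append(Atom("C", mass_of("C"),
                              np.array([rc * c, rc * s, sz * zc])))
            atoms.append(Atom("H", mass_of("H"),
                              np.array([rh * c, rh * s, sz * zc])))
    return Molecule(atoms, "ferrocene (D5d)").recentered()


def h3_triangle(side: float = 1.0) -> Molecule:
    r = side / math.sqrt(3)
    atoms = [
        Atom("H", mass_of("H"),
             np.array([r * math.cos(2 * math.pi * k / 3),
                       r * math.sin(2 * math.pi * k / 3), 0.0]))
        for k in range(3)
    ]
    return Molecule(atoms, "H3 equilateral (D3h)").recentered()


def generate_test_orbitals(salcs, contamination: float, rng_seed: int = 0):
    """Orbitals built from SALC rows, each mixed with a ``contamination``
    squared-norm fraction drawn from the span of the *other* irreps.

    Returns (coefficients, truth) where truth[i] is the source irrep name.
    Implemented here to keep all synthetic data generation in one module;
    the heavy lifting lives in :mod:`symadapt.salc`.
    """
    if not 0 <= contamination < 0.5:
        raise ValueError("contamination must be in [0, 0.5)")
    rng = np.random.default_rng(rng_seed)
    # emit degenerate partners as adjacent tuples (copy-major ordering),
    # the layout degenerate orbitals arrive in from an SCF calculation
    rows = []
    names = []
    by_block: dict[tuple, dict[int, np.ndarray]] = {}
    block_order = []
    for sp in salcs:
        key = (sp.set_id, sp.l, sp.irrep_index)
        if key not in by_block:
            by_block[key] = {}
            block_order.append((key, sp.irrep))
        by_block[key][sp.component] = sp.coefficients
    for key, name in block_order:
        comps = by_block[key]
        dim = max(comps)
        for copy in range(comps[1].shape[0]):
            for k in range(1, dim + 1):
                rows.append(comps[k][copy])
                names.append(name)
    rows = np.asarray(rows)
    out = np.empty_like(rows)
    for i, (row, name) in enumerate(zip(rows, names)):
        others = rows[[j for j, nm in enumerate(names) if nm != name]]
        if contamination == 0 or len(others) == 0:
            out[i] = row
            continue
        mix = rng.normal(size=len(others)) @ others
        mix -= (mix @ row) * row
        norm = np.linalg.norm(mix)
        if norm < 1e-12:
            out[i] = row
            continue
        mix /= norm
        out[i] = math.sqrt(1 - contamination) * row + math.sqrt(contamination) * mix
    return out, names
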
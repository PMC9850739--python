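"""Classical force-field energy evaluation along scan geometries.

Evaluates the explicit (user-declared) topology of one chemical state on
gas-phase cluster geometries — the desk-scale stage that produces the
per-state diagonal energies of the EVB Hamiltonian.  Functional forms are
pinned to one explicit convention:

* harmonic bond      ½ k (r − r0)²
* Morse bond         De (1 − e^{−a(r − re)})²
* harmonic angle     ½ kθ (θ − θ0)²            (θ in radians internally)
* cosine torsion     (Vn/2)(1 + cos(nφ − γ))   (OPLS-style)
* Lennard-Jones 12-6 4ε[(σ/r)¹² − (σ/r)⁶]      (Lorentz–Berthelot mixing)
* Coulomb            f·q_i·q_j / r,  f = 138.935458 kJ·mol⁻¹·Å·e⁻²

Nonbonded exclusions follow the common OPLS-like policy: 1-2 and 1-3 pairs
excluded, 1-4 pairs scaled (0.5 by default for both LJ and Coulomb; both
factors configurable).  No cutoffs, no periodic boundary conditions.
Automatic atom typing is deliberately absent: topologies are always
explicit, read from a small YAML schema documented on
:func:`load_topology`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import networkx as nx
import numpy as np
import yaml

from .fitting import EnergyProfile
from .model import PESScan, measure_angle, measure_dihedral

__all__ = [
    "COULOMB_CONSTANT",
    "HarmonicBond",
    "MorseBond",
    "HarmonicAngle",
    "CosineTorsion",
    "NonbondedParams",
    "StateTopology",
    "TopologyError",
    "SingularGeometryError",
    "energy",
    "profile",
    "load_topology",
    "dump_topology",
]

#: Coulomb prefactor 1/(4πε0) in kJ·mol⁻¹·Å·e⁻².
COULOMB_CONSTANT = 138.935458


class TopologyError(ValueError):
    """A term references an atom the geometry does not have."""


class SingularGeometryError(ValueError):
    """Two interacting atoms coincide (r = 0)."""


@dataclass(frozen=True)
class HarmonicBond:
    i: int
    j: int
    k: float  # kJ/mol/Å²
    r0: float  # Å

    def __post_init__(self):
        _check_indices((self.i, self.j))
        if self.k < 0:
            raise ValueError("force constant must be >= 0")


@dataclass(frozen=True)
class MorseBond:
    i: int
    j: int
    De: float  # kJ/mol
    a: float  # 1/Å
    re: float  # Å

    def __post_init__(self):
        _check_indices((self.i, self.j))
        if self.De < 0:
            raise ValueError("well depth De must be >= 0")


@dataclass(frozen=True)
class HarmonicAngle:
    i: int
    j: int  # vertex
    k_atom: int
    k_theta: float  # kJ/mol/rad²
    theta0: float  # degrees

    def __post_init__(self):
        _check_indices((self.i, self.j, self.k_atom))
        if self.k_theta < 0:
            raise ValueError("force constant must be >= 0")


@dataclass(frozen=True)
class CosineTorsion:
    i: int
    j: int
    k_atom: int
    l: int
    Vn: float  # kJ/mol
    n: int
    gamma: float  # degrees

    def __post_init__(self):
        _check_indices((self.i, self.j, self.k_atom, self.l))
        if self.n < 1:
            raise ValueError("torsion multiplicity n must be a positive integer")


def _check_indices(idx: Sequence[int]) -> None:
    if any(i < 1 for i in idx):
        raise ValueError("atom indices are 1-based and must be >= 1")
    if len(set(idx)) != len(idx):
        raise ValueError("atom indices within a term must be distinct")


FFTerm = Union[HarmonicBond, MorseBond, HarmonicAngle, CosineTorsion]


@dataclass(frozen=True)
class NonbondedParams:
    """Per-atom Lennard-Jones ε (kJ/mol), σ (Å), and partial charge q (e)."""

    epsilon: float
    sigma: float
    q: float = 0.0

    def __post_init__(self):
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass(frozen=True)
class StateTopology:
    """Explicit force-field definition of one chemical state.

    ``nonbonded`` is either empty (bonded terms only) or one entry per atom
    of the geometries it will be evaluated on.  The bonded graph used for
    exclusions is implied by the bond terms.
    """

    label: str
    terms: tuple[FFTerm, ...]
    nonbonded: tuple[NonbondedParams, ...] = ()
    scale14_lj: float = 0.5
    scale14_coulomb: float = 0.5

    def bond_graph(self) -> "nx.Graph":
        g = nx.Graph()
        for t in self.terms:
            if isinstance(t, (HarmonicBond, MorseBond)):
                g.add_edge(t.i, t.j)
        return g

    def max_index(self) -> int:
        out = 0
        for t in self.terms:
            if isinstance(t, (HarmonicBond, MorseBond)):
                out = max(out, t.i, t.j)
            elif isinstance(t, HarmonicAngle):
                out = max(out, t.i, t.j, t.k_atom)
            else:
                out = max(out, t.i, t.j, t.k_atom, t.l)
        return out


def _positions(geometry) -> np.ndarray:
    """Accept an (N,3) array or CalculationRecord-style (element,x,y,z) rows."""
    geometry = list(geometry)
    if geometry and isinstance(geometry[0], (tuple, list)) and len(geometry[0]) == 4:
        return np.array([[x, y, z] for _el, x, y, z in geometry], dtype=float)
    return np.asarray(geometry, dtype=float).reshape(-1, 3)


def energy(top: StateTopology, geometry) -> float:
    """Total force-field energy of one geometry, kJ/mol."""
    pos = _positions(geometry)
    n = len(pos)
    if top.max_index() > n:
        raise TopologyError(
            f"topology references atom {top.max_index()} but geometry has {n} atoms"
        )
    if top.nonbonded and len(top.nonbonded) != n:
        raise TopologyError(
            f"nonbonded parameter list has {len(top.nonbonded)} entries for {n} atoms"
        )

    e = 0.0
    for t in top.terms:
        if isinstance(t, HarmonicBond):
            r = float(np.linalg.norm(pos[t.i - 1] - pos[t.j - 1]))
            e += 0.5 * t.k * (r - t.r0) ** 2
        elif isinstance(t, MorseBond):
            r = float(np.linalg.norm(pos[t.i - 1] - pos[t.j - 1]))
            e += t.De * (1.0 - math.exp(-t.a * (r - t.re))) ** 2
        elif isinstance(t, HarmonicAngle):
            theta = measure_angle(pos[t.i - 1], pos[t.j - 1], pos[t.k_atom - 1])
            e += 0.5 * t.k_theta * math.radians(theta - t.theta0) ** 2
        else:  # CosineTorsion
            phi = measure_dihedral(pos[t.i - 1], pos[t.j - 1], pos[t.k_atom - 1],
                                   pos[t.l - 1])
            e += 0.5 * t.Vn * (1.0 + math.cos(math.radians(t.n * phi - t.gamma)))

    if top.nonbonded:
        g = top.bond_graph()
        sep = dict(nx.all_pairs_shortest_path_length(g, cutoff=3)) if g.number_of_edges() else {}
        for i in range(n):
            for j in range(i + 1, n):
                d = sep.get(i + 1, {}).get(j + 1)
                if d is not None and d <= 2:
                    continue  # 1-2 and 1-3 excluded
                scale_lj = top.scale14_lj if d == 3 else 1.0
                scale_c = top.scale14_coulomb if d == 3 else 1.0
                r = float(np.linalg.norm(pos[i] - pos[j]))
                if r == 0.0:
                    raise SingularGeometryError(
                        f"atoms {i + 1} and {j + 1} coincide in a nonbonded pair"
                    )
                pi, pj = top.nonbonded[i], top.nonbonded[j]
                eps = math.sqrt(pi.epsilon * pj.epsilon)
                sig = 0.5 * (pi.sigma + pj.sigma)
                if eps > 0.0:
                    sr6 = (sig / r) ** 6
                    e += scale_lj * 4.0 * eps * (sr6 * sr6 - sr6)
                if pi.q != 0.0 and pj.q != 0.0:
                    e += scale_c * COULOMB_CONSTANT * pi.q * pj.q / r
    return e


def profile(top: StateTopology, scan: PESScan) -> EnergyProfile:
    """Force-field energies on the scan's coordinate grid, scan-point order."""
    energies = [energy(top, p.calculation.geometry) for p in scan.points]
    return EnergyProfile.from_arrays(scan.coordinate_values(), energies)


# ---------------------------------------------------------------------------
# topology config I/O
#
# YAML schema::
#
#     label: state1
#     terms:
#       - {type: harmonic_bond,  atoms: [1, 2], k: 2000.0, r0: 1.53}
#       - {type: morse_bond,     atoms: [1, 2], De: 350.0, a: 1.9, re: 1.53}
#       - {type: harmonic_angle, atoms: [1, 2, 3], k: 300.0, theta0: 109.5}
#       - {type: cosine_torsion, atoms: [1, 2, 3, 4], V: 10.0, n: 3, gamma: 0.0}
#     nonbonded:                      # optional; one entry per atom
#       - {epsilon: 0.3, sigma: 3.5, q: -0.1}
#     exclusions: {scale14_lj: 0.5, scale14_coulomb: 0.5}   # optional


def _term_from_dict(d: dict) -> FFTerm:
    kind = d.get("type")
    atoms = d.get("atoms", ())
    if kind == "harmonic_bond":
        return HarmonicBond(*atoms, k=float(d["k"]), r0=float(d["r0"]))
    if kind == "morse_bond":
        return MorseBond(*atoms, De=float(d["De"]), a=float(d["a"]), re=float(d["re"]))
    if kind == "harmonic_angle":
        return HarmonicAngle(*atoms, k_theta=float(d["k"]), theta0=float(d["theta0"]))
    if kind == "cosine_torsion":
        return CosineTorsion(*atoms, Vn=float(d["V"]), n=int(d["n"]),
                             gamma=float(d.get("gamma", 0.0)))
    raise TopologyError(f"unknown force-field term type {kind!r}")


def load_topology(source) -> StateTopology:
    """Read a :class:`StateTopology` from a YAML file path, text, or dict."""
    if isinstance(source, dict):
        doc = source
    else:
        text = source.read_text() if hasattr(source, "read_text") else str(source)
        try:
            with open(text) as fh:  # path-like string
                doc = yaml.safe_load(fh)
        except (OSError, ValueError):
            doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise TopologyError("topology document must be a mapping")
    terms = tuple(_term_from_dict(t) for t in doc.get("terms", ()))
    nonbonded = tuple(
        NonbondedParams(float(nb["epsilon"]), float(nb["sigma"]), float(nb.get("q", 0.0)))
        for nb in doc.get("nonbonded", ())
    )
    excl = doc.get("exclusions", {}) or {}
    return StateTopology(
        label=str(doc.get("label", "state")),
        terms=terms,
        nonbonded=nonbonded,
        scale14_lj=float(excl.get("scale14_lj", 0.5)),
        scale14_coulomb=float(excl.get("scale14_coulomb", 0.5)),
    )


def dump_topology(top: StateTopology) -> str:
    """Serialize a topology back to its YAML schema."""
    terms = []
    for t in top.terms:
        if isinstance(t, HarmonicBond):
            terms.append({"type": "harmonic_bond", "atoms": [t.i, t.j],
                          "k": t.k, "r0": t.r0})
        elif isinstance(t, MorseBond):
            terms.append({"type": "morse_bond", "atoms": [t.i, t.j],
                          "De": t.De, "a": t.a, "re": t.re})
        elif isinstance(t, HarmonicAngle):
            terms.append({"type": "harmonic_angle", "atoms": [t.i, t.j, t.k_atom],
                          "k": t.k_theta, "theta0": t.theta0})
        else:
            terms.append({"type": "cosine_torsion",
                          "atoms": [t.i, t.j, t.k_atom, t.l],
                          "V": t.Vn, "n": t.n, "gamma": t.gamma})
    doc = {"label": top.label, "terms": terms}
    if top.nonbonded:
        doc["nonbonded"] = [
            {"epsilon": nb.epsilon, "sigma": nb.sigma, "q": nb.q} for nb in top.nonbonded
        ]
    doc["exclusions"] = {"scale14_lj": top.scale14_lj,
                         "scale14_coulomb": top.scale14_coulomb}
    return yaml.safe_dump(doc, sort_keys=False)
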
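"""Two-state EVB coupling calibration and Morse fitting against PES scans.

The empirical valence bond (EVB) picture represents a reactive surface with
a 2×2 Hamiltonian: the classical force-field energies of the two chemical
states (reactant-like, product-like) sit on the diagonal, a coupling term
H12 off the diagonal, and the lower eigenvalue

    E_EVB = ½(E1+E2) − ½√((E1−E2)² + 4·H12²)

is the reactive ground-state surface.  This module identifies the two
states on a reference profile, anchors the state energies to it (zero of
energy at the state points), and calibrates H12 — constant or a single
Gaussian A·exp(−(r−r0)²/(2w²)) — by least squares so the EVB ground state
reproduces the reference energies.  A Morse potential fitter
V(r) = De(1−e^{−a(r−re)})² + V0 covers the classic dissociation-curve case.

All energies here are kJ/mol; profiles built from stored Hartree SCF
energies are converted exactly once, at construction.

The fitting surface follows the model/results idiom: build an
:class:`EVBCouplingModel` (or :class:`MorseModel`) from data, call
``fit()``, and read estimates, residual diagnostics, and ``summary()`` off
the returned result.  ``calibrate`` and ``fit_morse`` are thin functional
wrappers over the same machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .model import FittingRecord, PESScan, hartree_to_kjmol

__all__ = [
    "EnergyProfile",
    "EVBInput",
    "CouplingModel",
    "EVBCouplingModel",
    "EVBFitResult",
    "MorseParams",
    "MorseModel",
    "MorseFitResult",
    "StateIdentificationError",
    "CalibrationInfeasibleError",
    "NoWellError",
    "identify_states",
    "align_state",
    "evb_ground",
    "pointwise_coupling",
    "calibrate",
    "fit_morse",
    "to_fitting_record",
    "reference_profile_from_scan",
]


class StateIdentificationError(ValueError):
    """The reference profile exposes no usable reactant/product states."""


class CalibrationInfeasibleError(ValueError):
    """No grid point admits a real pointwise coupling; nothing to calibrate."""


class NoWellError(ValueError):
    """The profile has no interior minimum to fit a Morse well to."""


@dataclass(frozen=True)
class EnergyProfile:
    """Energies (kJ/mol) tabulated on a strictly increasing coordinate grid."""

    coordinates: tuple[float, ...]
    energies: tuple[float, ...]

    def __post_init__(self) -> None:
        r = np.asarray(self.coordinates, dtype=float)
        e = np.asarray(self.energies, dtype=float)
        if r.size != e.size or r.size < 2:
            raise ValueError("profile needs >= 2 (coordinate, energy) pairs of equal length")
        if not (np.all(np.isfinite(r)) and np.all(np.isfinite(e))):
            raise ValueError("profile values must be finite")
        if np.any(np.diff(r) <= 0):
            raise ValueError("profile coordinates must be strictly increasing")

    @classmethod
    def from_arrays(cls, coordinates, energies) -> "EnergyProfile":
        return cls(tuple(float(x) for x in coordinates), tuple(float(x) for x in energies))

    @property
    def r(self) -> np.ndarray:
        return np.asarray(self.coordinates, dtype=float)

    @property
    def e(self) -> np.ndarray:
        return np.asarray(self.energies, dtype=float)

    def __len__(self) -> int:
        return len(self.coordinates)

    def shifted(self, ds: float) -> "EnergyProfile":
        return EnergyProfile.from_arrays(self.r, self.e + ds)


def reference_profile_from_scan(scan: PESScan) -> EnergyProfile:
    """Scan coordinate grid + SCF energies converted Hartree → kJ/mol."""
    return EnergyProfile.from_arrays(
        scan.coordinate_values(), hartree_to_kjmol(scan.scf_energies())
    )


@dataclass(frozen=True)
class EVBInput:
    """Aligned state/reference profiles on one shared coordinate grid."""

    e1: EnergyProfile
    e2: EnergyProfile
    eref: EnergyProfile

    def __post_init__(self) -> None:
        if not (self.e1.coordinates == self.e2.coordinates == self.eref.coordinates):
            raise ValueError("all three profiles must share an identical coordinate grid")

    @property
    def r(self) -> np.ndarray:
        return self.eref.r


@dataclass(frozen=True)
class CouplingModel:
    """EVB off-diagonal term: constant A, or Gaussian A·exp(−(r−r0)²/(2w²))."""

    kind: str
    A: float
    r0: Optional[float] = None
    w: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "gaussian"):
            raise ValueError(f"unknown coupling kind {self.kind!r}")
        if self.kind == "gaussian":
            if self.r0 is None or self.w is None:
                raise ValueError("gaussian coupling needs r0 and w")
            if self.w <= 0:
                raise ValueError("gaussian width w must be > 0")

    def __call__(self, r) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        if self.kind == "constant":
            return np.full_like(r, self.A)
        return self.A * np.exp(-((r - self.r0) ** 2) / (2.0 * self.w**2))

    def parameter_items(self) -> list[tuple[str, float]]:
        if self.kind == "constant":
            return [("A", self.A)]
        return [("A", self.A), ("r0", self.r0), ("w", self.w)]


# ---------------------------------------------------------------------------
# elementary operations


def evb_ground(e1, e2, h12):
    """Lower eigenvalue of [[e1, h12], [h12, e2]] (kJ/mol), elementwise."""
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    h12 = np.asarray(h12, dtype=float)
    out = 0.5 * (e1 + e2) - 0.5 * np.sqrt((e1 - e2) ** 2 + 4.0 * h12**2)
    # zero coupling leaves the diagonal untouched: return min(e1, e2) exactly
    out = np.where(h12 == 0.0, np.minimum(e1, e2), out)
    return float(out) if out.ndim == 0 else out


def pointwise_coupling(e1, e2, eref):
    """Coupling magnitude that reproduces ``eref`` exactly at one point.

    Inverting the 2×2 ground-state relation gives h12 = √((e1−eref)(e2−eref)),
    real whenever the reference lies at or below both diagonal energies.
    Points where it does not are marked undefined (NaN), not raised.
    """
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    eref = np.asarray(eref, dtype=float)
    prod = (e1 - eref) * (e2 - eref)
    defined = (eref <= np.minimum(e1, e2)) & (prod >= 0.0)
    out = np.where(defined, np.sqrt(np.where(defined, prod, 0.0)), np.nan)
    return float(out) if out.ndim == 0 else out


def _local_minima(e: np.ndarray) -> list[int]:
    """Strict local minima including boundaries."""
    n = len(e)
    mins = []
    if e[0] < e[1]:
        mins.append(0)
    for i in range(1, n - 1):
        if e[i] < e[i - 1] and e[i] < e[i + 1]:
            mins.append(i)
    if e[n - 1] < e[n - 2]:
        mins.append(n - 1)
    return mins


def identify_states(eref: EnergyProfile, kind: str = "distance") -> tuple[int, int]:
    """Pick reactant/product grid indices on the reference profile.

    The reactant is the local minimum of lowest energy.  For bond-distance
    scans with exactly one local minimum, the product state is the point at
    maximum scan distance (the dissociated fragments); otherwise the product
    is the second-lowest distinct local minimum.
    """
    if len(eref) < 3:
        raise StateIdentificationError("need at least 3 points to identify states")
    e = eref.e
    mins = sorted(_local_minima(e), key=lambda i: (e[i], i))
    if not mins:
        raise StateIdentificationError("profile has no local minimum")
    reactant = mins[0]
    if kind == "distance" and len(mins) == 1:
        product = len(eref) - 1
    elif len(mins) >= 2:
        product = mins[1]
    else:
        raise StateIdentificationError(
            f"single-minimum profile on a {kind} scan: the maximum-distance rule "
            "applies to bond scans only; supply explicit anchors"
        )
    if reactant == product:
        raise StateIdentificationError("reactant and product states coincide")
    return reactant, product


def align_state(
    e: EnergyProfile, anchor_index: int, eref: EnergyProfile
) -> tuple[EnergyProfile, float]:
    """Shift a state profile to agree with the reference at its state point.

    Returns ``(e + shift, shift)`` with shift = Eref[anchor] − E[anchor], so
    the shifted profile matches the reference exactly at the anchor.  This
    generalizes the usual zero-of-energy convention (e.g. zero at the
    maximum-distance state of a bond scan).
    """
    shift = float(eref.e[anchor_index] - e.e[anchor_index])
    return e.shifted(shift), shift


# ---------------------------------------------------------------------------
# EVB coupling calibration (model → results)


@dataclass(frozen=True)
class EVBFitResult:
    """Calibrated coupling + diagnostics for one two-state EVB fit."""

    coupling: CouplingModel
    s1: float
    s2: float
    e_evb: EnergyProfile
    residuals: tuple[float, ...]
    max_abs_residual: float
    converged: bool
    objective: float
    anchors: tuple[int, int]
    n_iterations: int = 0

    def summary(self) -> str:
        lines = [
            "Two-state EVB coupling calibration",
            "==================================",
            f"coupling model : {self.coupling.kind}",
        ]
        for name, value in self.coupling.parameter_items():
            lines.append(f"  {name:<12s}: {value: .8g}")
        lines += [
            f"  s1 (shift)  : {self.s1: .8g} kJ/mol",
            f"  s2 (shift)  : {self.s2: .8g} kJ/mol",
            f"anchors (reactant, product): {self.anchors}",
            f"objective (sum sq. residual): {self.objective:.6g} (kJ/mol)^2",
            f"max |residual|: {self.max_abs_residual:.6g} kJ/mol",
            f"converged     : {self.converged}",
            f"n points      : {len(self.e_evb)}",
        ]
        return "\n".join(lines)


class EVBCouplingModel:
    """Calibrate the EVB off-diagonal coupling against a reference profile.

    Parameters
    ----------
    data
        Aligned state-1/state-2/reference profiles on one grid.  State
        profiles need not be pre-shifted; anchoring happens inside ``fit``.
    kind
        Coupling functional form, ``"constant"`` or ``"gaussian"``.
    coordinate_kind
        Scan coordinate type; drives the reactant/product identification
        rule (the maximum-distance product rule applies to bond scans).
    anchors
        Optional (reactant_index, product_index) override; when absent the
        states are identified from the reference profile's local minima.
    optimize_shifts
        Co-optimize the per-state energy shifts s1, s2 instead of keeping
        them fixed at their anchored values.
    """

    def __init__(
        self,
        data: EVBInput,
        kind: str = "constant",
        coordinate_kind: str = "distance",
        anchors: Optional[tuple[int, int]] = None,
        optimize_shifts: bool = False,
    ):
        if kind not in ("constant", "gaussian"):
            raise ValueError(f"unknown coupling kind {kind!r}")
        self.data = data
        self.kind = kind
        self.coordinate_kind = coordinate_kind
        self.anchors = anchors
        self.optimize_shifts = optimize_shifts

    # -- internals ---------------------------------------------------------

    def _prepare(self):
        data = self.data
        anchors = self.anchors
        if anchors is None:
            anchors = identify_states(data.eref, self.coordinate_kind)
        reactant, product = anchors
        _shifted1, s1 = align_state(data.e1, reactant, data.eref)
        _shifted2, s2 = align_state(data.e2, product, data.eref)
        return (reactant, product), s1, s2

    def _initial_guess(self, s1: float, s2: float) -> np.ndarray:
        r = self.data.r
        h = pointwise_coupling(self.data.e1.e + s1, self.data.e2.e + s2, self.data.eref.e)
        defined = np.isfinite(h)
        if not np.any(defined):
            raise CalibrationInfeasibleError(
                "no grid point admits a real pointwise coupling; the reference "
                "lies above both anchored states everywhere"
            )
        hd, rd = h[defined], r[defined]
        if self.kind == "constant":
            return np.array([float(np.median(hd))])
        peak = int(np.argmax(hd))
        a0 = float(hd[peak])
        r00 = float(rd[peak])
        wsum = float(np.sum(hd))
        if wsum > 0 and a0 > 0:
            w0 = math.sqrt(float(np.sum(hd * (rd - r00) ** 2)) / wsum)
        else:
            w0 = 0.0
        spacing = float(np.min(np.diff(r)))
        w0 = max(w0, 0.5 * spacing)
        return np.array([a0, r00, w0])

    def _unpack(self, theta: np.ndarray, s1: float, s2: float):
        if self.kind == "constant":
            coupling = CouplingModel("constant", float(theta[0]))
            k = 1
        else:
            coupling = CouplingModel("gaussian", float(theta[0]), float(theta[1]),
                                     float(max(theta[2], 1e-12)))
            k = 3
        if self.optimize_shifts:
            s1, s2 = float(theta[k]), float(theta[k + 1])
        return coupling, s1, s2

    def _residual_vector(self, theta: np.ndarray, s1: float, s2: float) -> np.ndarray:
        coupling, s1, s2 = self._unpack(theta, s1, s2)
        e_evb = evb_ground(self.data.e1.e + s1, self.data.e2.e + s2, coupling(self.data.r))
        return e_evb - self.data.eref.e

    # -- public API --------------------------------------------------------

    def fit(
        self,
        maxiter: int = 10_000,
        ftol: float = 1e-12,
        polish: bool = True,
    ) -> EVBFitResult:
        """Least-squares calibration of the coupling parameters.

        Deterministic: the initial guess comes from pointwise-coupling
        statistics (median for the constant model; peak height/location and
        second moment for the Gaussian), followed by bounded Nelder–Mead
        descent with a fixed iteration budget and, by default, a bounded
        least-squares polish.  Non-convergence within the budget is reported
        through ``converged=False``, never raised.
        """
        anchors, s1_0, s2_0 = self._prepare()
        theta0 = self._initial_guess(s1_0, s2_0)

        lo = [0.0] if self.kind == "constant" else [0.0, -np.inf, 1e-9]
        hi = [np.inf] if self.kind == "constant" else [np.inf, np.inf, np.inf]
        if self.optimize_shifts:
            theta0 = np.concatenate([theta0, [s1_0, s2_0]])
            lo += [-np.inf, -np.inf]
            hi += [np.inf, np.inf]

        def objective(theta):
            res = self._residual_vector(theta, s1_0, s2_0)
            return float(np.dot(res, res))

        nm = optimize.minimize(
            objective,
            theta0,
            method="Nelder-Mead",
            bounds=optimize.Bounds(np.array(lo), np.array(hi)),
            options={"maxiter": maxiter, "fatol": ftol, "xatol": 1e-12, "adaptive": True},
        )
        theta, n_iter, converged = nm.x, int(nm.nit), bool(nm.success)

        if polish:
            ls = optimize.least_squares(
                self._residual_vector,
                np.clip(theta, lo, hi),
                args=(s1_0, s2_0),
                bounds=(np.array(lo), np.array(hi)),
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000,
            )
            if float(np.dot(ls.fun, ls.fun)) <= objective(theta):
                theta = ls.x
                converged = converged or ls.status > 0

        coupling, s1, s2 = self._unpack(theta, s1_0, s2_0)
        e_evb_arr = evb_ground(self.data.e1.e + s1, self.data.e2.e + s2,
                               coupling(self.data.r))
        residuals = e_evb_arr - self.data.eref.e
        return EVBFitResult(
            coupling=coupling,
            s1=s1,
            s2=s2,
            e_evb=EnergyProfile.from_arrays(self.data.r, e_evb_arr),
            residuals=tuple(float(x) for x in residuals),
            max_abs_residual=float(np.max(np.abs(residuals))),
            converged=converged,
            objective=float(np.dot(residuals, residuals)),
            anchors=anchors,
            n_iterations=n_iter,
        )


def calibrate(
    data: EVBInput,
    model_kind: str = "constant",
    coordinate_kind: str = "distance",
    anchors: Optional[tuple[int, int]] = None,
    optimize_shifts: bool = False,
    **fit_options,
) -> EVBFitResult:
    """Functional wrapper: ``EVBCouplingModel(data, ...).fit(...)``."""
    model = EVBCouplingModel(data, model_kind, coordinate_kind, anchors, optimize_shifts)
    return model.fit(**fit_options)


# ---------------------------------------------------------------------------
# Morse fitting


@dataclass(frozen=True)
class MorseParams:
    """Morse well: depth De (kJ/mol), equilibrium distance re, width a."""

    De: float
    re: float
    a: float

    def __post_init__(self) -> None:
        if self.De <= 0 or self.re <= 0 or self.a <= 0:
            raise ValueError("Morse parameters De, re, a must all be > 0")

    def __call__(self, r, v0: float = 0.0) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        return self.De * (1.0 - np.exp(-self.a * (r - self.re))) ** 2 + v0


@dataclass(frozen=True)
class MorseFitResult:
    """Fitted Morse well + vertical offset V0 and residual diagnostics."""

    params: MorseParams
    v0: float
    fitted: EnergyProfile
    residuals: tuple[float, ...]
    max_abs_residual: float
    converged: bool

    def summary(self) -> str:
        return "\n".join([
            "Morse potential fit  V(r) = De(1 - exp(-a(r-re)))^2 + V0",
            "========================================================",
            f"  De: {self.params.De: .10g} kJ/mol",
            f"  re: {self.params.re: .10g}",
            f"  a : {self.params.a: .10g}",
            f"  V0: {self.v0: .10g} kJ/mol",
            f"max |residual|: {self.max_abs_residual:.6g} kJ/mol",
            f"converged     : {self.converged}",
            f"n points      : {len(self.fitted)}",
        ])


class MorseModel:
    """Least-squares Morse fit to a well-shaped energy profile."""

    def __init__(self, profile: EnergyProfile):
        self.profile = profile

    def _initial_guess(self) -> np.ndarray:
        r, e = self.profile.r, self.profile.e
        i0 = int(np.argmin(e))
        if i0 == 0 or i0 == len(e) - 1:
            raise NoWellError("profile minimum sits on the boundary: no interior well")
        v0 = float(e[i0])
        tail = float(np.mean(e[max(i0 + 1, len(e) - 3):]))
        de = max(tail - v0, 1e-6)
        # curvature k = V''(re) = 2 De a^2 from a parabola through the 3
        # points around the minimum (general, uneven grids included)
        x = r[i0 - 1 : i0 + 2] - r[i0]
        y = e[i0 - 1 : i0 + 2]
        coeffs = np.polyfit(x, y, 2)
        k = max(2.0 * float(coeffs[0]), 1e-8)
        a = math.sqrt(k / (2.0 * de))
        return np.array([de, float(r[i0]), a, v0])

    def fit(self) -> MorseFitResult:
        r, e = self.profile.r, self.profile.e
        i0 = int(np.argmin(e))
        if i0 == 0 or i0 == len(e) - 1 or not (e[-1] > e[i0]):
            raise NoWellError("profile has no interior minimum with a right tail above it")
        theta0 = self._initial_guess()

        def residual(theta):
            de, re_, a, v0 = theta
            return de * (1.0 - np.exp(-a * (r - re_))) ** 2 + v0 - e

        ls = optimize.least_squares(
            residual,
            theta0,
            bounds=([1e-12, 1e-12, 1e-12, -np.inf], [np.inf, np.inf, np.inf, np.inf]),
            xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=5000,
        )
        de, re_, a, v0 = (float(t) for t in ls.x)
        params = MorseParams(de, re_, a)
        fitted = params(r, v0)
        residuals = fitted - e
        return MorseFitResult(
            params=params,
            v0=v0,
            fitted=EnergyProfile.from_arrays(r, fitted),
            residuals=tuple(float(x) for x in residuals),
            max_abs_residual=float(np.max(np.abs(residuals))),
            converged=ls.status > 0,
        )


def fit_morse(profile: EnergyProfile) -> tuple[MorseParams, tuple[float, ...]]:
    """Functional wrapper returning (MorseParams, residuals)."""
    result = MorseModel(profile).fit()
    return result.params, result.residuals


# ---------------------------------------------------------------------------
# export back to the scan model


def to_fitting_record(
    result,
    method_source: str,
    coordinate_unit: str = "angstrom",
) -> FittingRecord:
    """Turn a fit result into a :class:`FittingRecord` for the knowledge graph.

    Accepts an :class:`EVBFitResult`, :class:`MorseFitResult`, or bare
    :class:`MorseParams`.  The numeric values round-trip losslessly through
    the record (and through the RDF mapping, which serializes shortest
    round-trip decimals).
    """
    if isinstance(result, EVBFitResult):
        params: list[tuple[str, float, str]] = []
        for name, value in result.coupling.parameter_items():
            unit = "kJ/mol" if name == "A" else coordinate_unit
            params.append((name, value, unit))
        params.append(("s1", result.s1, "kJ/mol"))
        params.append(("s2", result.s2, "kJ/mol"))
        return FittingRecord(
            method_name=f"EVB-2state-{result.coupling.kind}",
            method_source=method_source,
            parameters=tuple(params),
        )
    if isinstance(result, MorseFitResult):
        morse, v0 = result.params, result.v0
    elif isinstance(result, MorseParams):
        morse, v0 = result, 0.0
    else:
        raise TypeError(f"cannot build a fitting record from {type(result).__name__}")
    return FittingRecord(
        method_name="MorsePotential",
        method_source=method_source,
        parameters=(
            ("De", morse.De, "kJ/mol"),
            ("re", morse.re, coordinate_unit),
            ("a", morse.a, f"1/{coordinate_unit}"),
            ("V0", v0, "kJ/mol"),
        ),
    )
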
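"""Equilibrium competition-titration analysis.

A fluorescent protein-to-membrane FRET signal is titrated with a soluble
competitor (IP6). The intensity follows a single-site competitive
inhibition hyperbola

    F([I]) = dF_max * (1 - [I] / (IC50 + [I])) + C

and the half-displacement concentration IC50 is converted into a
mole-fraction partition coefficient

    K_x = (IC50 / K_I - 1) * [H2O] / [L]

where K_I is the protein-inhibitor dissociation constant, [H2O] the bulk
water concentration and [L] the accessible lipid concentration (outer
leaflets only, approximated as half the total lipid). The standard free
energy of membrane partitioning is dG0 = -R*T*ln(K_x).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import lmfit
import numpy as np

from .constants import (
    ACCESSIBLE_LIPID_FRACTION,
    DEFAULT_KI_UM,
    DEFAULT_TEMPERATURE_K,
    R_KCAL_PER_MOL_K,
    WATER_MOLARITY_M,
)
from .errors import (
    AlignmentError,
    DegenerateAmplitudeError,
    FitFailureError,
    InsufficientDataError,
    InvalidArgumentError,
    NonPositivePartitionError,
)

__all__ = [
    "TitrationPoint",
    "TitrationCurve",
    "CompetitionFit",
    "PartitioningInputs",
    "PartitioningResult",
    "accessible_lipid_concentration",
    "competition_model",
    "fit_competition_titration",
    "ic50_to_partition_coefficient",
    "partition_free_energy",
    "analyze_titration",
    "apply_titration_controls",
    "normalize_titration",
]


@dataclass(frozen=True)
class TitrationPoint:
    """One titration point: titrant concentration (uM for IP6, mM allowed
    for NaCl) and the measured fluorescence intensity (arbitrary units)."""

    titrant_conc: float
    fluorescence: float

    def __post_init__(self):
        if self.titrant_conc < 0:
            raise InvalidArgumentError("titrant_conc must be >= 0")
        if not math.isfinite(self.fluorescence):
            raise InvalidArgumentError("fluorescence must be finite")


@dataclass(frozen=True)
class TitrationCurve:
    """An ordered titration with its assay context."""

    points: tuple[TitrationPoint, ...]
    titrant_kind: str = "IP6"  # "IP6" or "NaCl"
    protein_conc: float = 1.0  # uM
    total_lipid_conc: float = 125.0  # uM
    composition_label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "points", tuple(self.points))
        concs = [p.titrant_conc for p in self.points]
        if any(b <= a for a, b in zip(concs, concs[1:])):
            raise InvalidArgumentError("titrant_conc must be strictly increasing")
        if self.protein_conc <= 0:
            raise InvalidArgumentError("protein_conc must be > 0")
        if self.titrant_kind not in ("IP6", "NaCl"):
            raise InvalidArgumentError(f"unknown titrant_kind {self.titrant_kind!r}")

    @property
    def titrant(self) -> np.ndarray:
        return np.array([p.titrant_conc for p in self.points], dtype=float)

    @property
    def fluorescence(self) -> np.ndarray:
        return np.array([p.fluorescence for p in self.points], dtype=float)

    def with_fluorescence(self, values: Sequence[float]) -> "TitrationCurve":
        if len(values) != len(self.points):
            raise InvalidArgumentError("replacement values length mismatch")
        pts = tuple(
            TitrationPoint(p.titrant_conc, float(v))
            for p, v in zip(self.points, values)
        )
        return replace(self, points=pts)

    @classmethod
    def from_arrays(cls, titrant, fluorescence, **kwargs) -> "TitrationCurve":
        pts = tuple(
            TitrationPoint(float(c), float(f))
            for c, f in zip(titrant, fluorescence)
        )
        return cls(points=pts, **kwargs)


@dataclass(frozen=True)
class CompetitionFit:
    """Least-squares parameters of the competitive-inhibition hyperbola."""

    ic50: float
    delta_f_max: float
    offset_c: float
    stderr: dict = field(default_factory=dict)
    residual_sum_of_squares: float = float("nan")

    def __post_init__(self):
        if self.ic50 <= 0:
            raise InvalidArgumentError("ic50 must be > 0")
        if self.delta_f_max < 0:
            raise InvalidArgumentError("delta_f_max must be >= 0")

    def predict(self, titrant) -> np.ndarray:
        return competition_model(
            np.asarray(titrant, dtype=float),
            self.delta_f_max,
            self.ic50,
            self.offset_c,
        )


@dataclass(frozen=True)
class PartitioningInputs:
    """Constants entering the IC50 -> K_x -> dG0 conversion."""

    k_i: float = DEFAULT_KI_UM  # uM
    water_molarity: float = WATER_MOLARITY_M  # M
    accessible_lipid: float = 62.5  # uM
    temperature: float = DEFAULT_TEMPERATURE_K  # K

    def __post_init__(self):
        for name in ("k_i", "water_molarity", "accessible_lipid", "temperature"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be > 0")


@dataclass(frozen=True)
class PartitioningResult:
    """Mole-fraction partition coefficient and its free energy."""

    kx: float
    delta_g: float  # kcal/mol
    gas_constant_used: float = R_KCAL_PER_MOL_K

    def __post_init__(self):
        if self.kx <= 0 or not math.isfinite(self.delta_g):
            raise InvalidArgumentError("kx must be > 0 with finite delta_g")

    @property
    def kx_millions(self) -> float:
        """K_x expressed in units of 10^6 (reporting convention)."""
        return self.kx / 1e6


def accessible_lipid_concentration(
    total_lipid: float,
    dilution_factor: float = 1.0,
    *,
    already_accessible: bool = False,
) -> float:
    """Accessible (outer-leaflet) lipid concentration in uM.

    Sonicated liposomes expose roughly half their lipid on the outer
    leaflet, so accessible lipid is approximated as one-half of the total;
    set ``already_accessible=True`` when the input is quoted as accessible
    lipid, in which case only the dilution is applied (e.g. equal-volume
    stopped-flow mixing has ``dilution_factor=2``).
    """
    if total_lipid < 0:
        raise InvalidArgumentError("total_lipid must be >= 0")
    if dilution_factor < 1:
        raise InvalidArgumentError("dilution_factor must be >= 1")
    halving = 1.0 if already_accessible else ACCESSIBLE_LIPID_FRACTION
    return total_lipid * halving / dilution_factor


def competition_model(titrant, delta_f_max, ic50, offset_c):
    """Single-site competitive-inhibition hyperbola F([I])."""
    titrant = np.asarray(titrant, dtype=float)
    return delta_f_max * (1.0 - titrant / (ic50 + titrant)) + offset_c


def fit_competition_titration(
    curve: TitrationCurve,
    init: Optional[dict] = None,
) -> CompetitionFit:
    """Fit (dF_max, IC50, C) to an IP6 competition titration.

    Initialisation: IC50 from the titrant concentration at the half signal
    drop, dF_max from the total signal span, C from the high-titrant
    plateau. All parameters are bounded below by zero.
    """
    if curve.titrant_kind != "IP6":
        raise InvalidArgumentError("competition fitting expects an IP6 titration")
    if len(curve.points) < 4:
        raise InsufficientDataError(
            f"need >= 4 points to fit, got {len(curve.points)}"
        )
    x = curve.titrant
    y = curve.fluorescence

    init = dict(init or {})
    f_first, f_last = float(y[0]), float(y[-1])
    guess_amp = max(f_first - f_last, 1e-12)
    guess_c = f_last
    half_level = f_last + 0.5 * guess_amp
    below = np.nonzero(y <= half_level)[0]
    guess_ic50 = float(x[below[0]]) if below.size else float(x[-1])
    if guess_ic50 <= 0:
        guess_ic50 = float(x[x > 0][0]) if np.any(x > 0) else 1.0

    params = lmfit.Parameters()
    params.add("delta_f_max", value=init.get("delta_f_max", guess_amp), min=0.0)
    params.add("ic50", value=init.get("ic50", guess_ic50), min=1e-12)
    params.add("offset_c", value=init.get("offset_c", guess_c), min=0.0
               if min(y) >= 0 else -np.inf)

    def residual(p):
        return competition_model(x, p["delta_f_max"], p["ic50"], p["offset_c"]) - y

    result = lmfit.minimize(residual, params, method="leastsq")
    if not result.success or not np.isfinite(result.params["ic50"].value):
        raise FitFailureError("competition fit did not converge", diagnostics=result)
    rss = float(np.sum(result.residual**2))
    stderr = {
        k: (v.stderr if v.stderr is not None else float("nan"))
        for k, v in result.params.items()
    }
    return CompetitionFit(
        ic50=float(result.params["ic50"].value),
        delta_f_max=float(result.params["delta_f_max"].value),
        offset_c=float(result.params["offset_c"].value),
        stderr=stderr,
        residual_sum_of_squares=rss,
    )


def ic50_to_partition_coefficient(
    ic50: float, inputs: PartitioningInputs
) -> float:
    """Mole-fraction partition coefficient K_x from a competition IC50.

    K_x = (IC50/K_I - 1) * [H2O]/[L], with [H2O] converted to uM so the
    concentration ratio is dimensionless.
    """
    if ic50 <= inputs.k_i:
        raise NonPositivePartitionError(
            f"IC50 ({ic50} uM) must exceed K_I ({inputs.k_i} uM)"
        )
    water_um = inputs.water_molarity * 1e6
    return (ic50 / inputs.k_i - 1.0) * water_um / inputs.accessible_lipid


def partition_free_energy(
    kx: float, temperature: float = DEFAULT_TEMPERATURE_K
) -> float:
    """Standard free energy of partitioning, dG0 = -R*T*ln(K_x), kcal/mol."""
    if kx <= 0:
        raise InvalidArgumentError("kx must be > 0")
    return -R_KCAL_PER_MOL_K * temperature * math.log(kx)


def analyze_titration(
    ic50: float, inputs: PartitioningInputs
) -> PartitioningResult:
    """IC50 -> (K_x, dG0) in one step."""
    kx = ic50_to_partition_coefficient(ic50, inputs)
    dg = partition_free_energy(kx, inputs.temperature)
    return PartitioningResult(kx=kx, delta_g=dg)


def _interp_control(control: TitrationCurve, grid: np.ndarray) -> np.ndarray:
    cx, cy = control.titrant, control.fluorescence
    if grid.min() < cx.min() - 1e-9 or grid.max() > cx.max() + 1e-9:
        raise AlignmentError(
            "control titrant range does not cover the raw curve's range"
        )
    return np.interp(grid, cx, cy)


def apply_titration_controls(
    raw: TitrationCurve,
    lipid_only_control: TitrationCurve,
    buffer_dilution_control: Optional[TitrationCurve] = None,
) -> TitrationCurve:
    """Correct a raw titration for titrant and dilution artifacts.

    The lipid-only control measures the titrant's direct effect on the
    acceptor fluorescence; its drift relative to its own first point is
    subtracted from the raw signal. For NaCl titrations, a second control
    measures fractional signal loss upon buffer addition; the corrected
    signal is divided by that control's profile normalised to its first
    point.
    """
    grid = raw.titrant
    ctrl = _interp_control(lipid_only_control, grid)
    corrected = raw.fluorescence - (ctrl - ctrl[0])
    if buffer_dilution_control is not None:
        frac = _interp_control(buffer_dilution_control, grid)
        if frac[0] == 0:
            raise DegenerateAmplitudeError("buffer control starts at zero signal")
        corrected = corrected / (frac / frac[0])
    return raw.with_fluorescence(corrected)


def normalize_titration(curve: TitrationCurve, fit: CompetitionFit) -> TitrationCurve:
    """Map fluorescence to (F - C)/dF_max so the curve spans ~1 -> ~0."""
    if fit.delta_f_max == 0:
        raise DegenerateAmplitudeError("delta_f_max is zero")
    return curve.with_fluorescence(
        (curve.fluorescence - fit.offset_c) / fit.delta_f_max
    )
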
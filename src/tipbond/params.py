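"""Parameter containers and published parameter sets for tip-link bond kinetics.

The central object is :class:`SlidingRebindingParams`, the full parameter
vector of the modified sliding-rebinding model of a cadherin binding
interface: a doubly bonded interface dissociates through Bell-type
force-accelerated pathways, but above a first critical force ``F_C1`` the
applied tension can reorient the interface and re-form bonds with
probability ``P_n`` instead of letting them rupture, which produces
catch-bond behaviour.  Mutant interfaces that have lost the pivot contact
cannot re-form bonds (``P_n = 0`` at every force) and behave as pure slip
bonds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

# Thermal energy at 298 K in pN * Angstrom (4.114 pN*nm).
KBT_ROOM = 41.14

# First critical force (slip -> catch transition) of the tip-link
# interface measured by force clamp; not a fitted quantity in the
# published parameter tables, so it is carried as a convention.
F_C1_DEFAULT = 58.0


@dataclass
class SlidingRebindingParams:
    """Kinetic parameters of the modified sliding-rebinding model.

    Parameters
    ----------
    k_minus1_0 : float
        Intrinsic (zero-force) single-bond off-rate, 1/s.
    x_beta : float
        Distance from the bound state to the transition state, Angstrom.
    k_plus1 : float
        Interface reorganisation rate, 1/s.
    k_plus2 : float
        Rebinding rate of the re-formed single-bond state, 1/s.
    F_C1, F_C2 : float
        Critical forces (pN) bracketing the catch regime: rebinding
        probability is 0 below ``F_C1``, rises to 1 at ``F_C2``.
    n : float
        Exponent sharpening the rebinding-probability switch.
    kBT : float
        Thermal energy, pN * Angstrom.
    variant : str
        ``"wt"`` or ``"mutant"``.  The mutant has lost the pivot and its
        rebinding probability is identically zero.
    """

    k_minus1_0: float
    x_beta: float
    k_plus1: float
    k_plus2: float = 0.0
    F_C1: float = F_C1_DEFAULT
    F_C2: float = math.inf
    n: float = 1.0
    kBT: float = KBT_ROOM
    variant: str = "wt"

    def __post_init__(self) -> None:
        for name in ("k_minus1_0", "k_plus1", "k_plus2", "x_beta"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.kBT <= 0:
            raise ValueError("kBT must be positive")
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not 0 <= self.F_C1 <= self.F_C2:
            raise ValueError("need 0 <= F_C1 <= F_C2")
        if self.variant not in ("wt", "mutant"):
            raise ValueError("variant must be 'wt' or 'mutant'")

    @property
    def is_mutant(self) -> bool:
        return self.variant == "mutant"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SlidingRebindingParams":
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SlidingRebindingParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class UnfoldingClassParams:
    """Bell-model unfolding kinetics of one step-height class.

    ``k_u0`` is the zero-force unfolding rate (1/s), ``x_beta_u`` the
    distance to the unfolding transition state (Angstrom) and
    ``step_height`` a label in nm identifying the class.
    """

    k_u0: float
    x_beta_u: float
    step_height: float = float("nan")

    def __post_init__(self) -> None:
        if self.k_u0 < 0 or self.x_beta_u < 0:
            raise ValueError("rates and distances must be >= 0")


# --- Published parameter sets -------------------------------------------
# Modified sliding-rebinding fits for the isolated Cdh23 EC1-2 /
# Pcdh15 EC1-2 binding interface (wild type and the deafness-associated
# R113G mutant).
INTERFACE_WT = SlidingRebindingParams(
    k_minus1_0=0.5, x_beta=1.0, k_plus1=2.8, k_plus2=30.2,
    F_C1=F_C1_DEFAULT, F_C2=100.0, n=2.3, variant="wt",
)
INTERFACE_MUTANT = SlidingRebindingParams(
    k_minus1_0=0.3, x_beta=0.6, k_plus1=0.6, variant="mutant",
)

# Fits for individual tip-links built from Cdh23 truncation variants
# (number of extracellular cadherin domains in the construct).
VARIANT_EC1_5 = SlidingRebindingParams(
    k_minus1_0=0.61, x_beta=1.2, k_plus1=0.9, k_plus2=29.4,
    F_C1=F_C1_DEFAULT, F_C2=108.4, n=1.2, variant="wt",
)
VARIANT_EC1_10 = SlidingRebindingParams(
    k_minus1_0=0.39, x_beta=1.0, k_plus1=0.9, k_plus2=7.8,
    F_C1=F_C1_DEFAULT, F_C2=99.0, n=1.9, variant="wt",
)
VARIANT_EC1_21 = SlidingRebindingParams(
    k_minus1_0=0.35, x_beta=0.7, k_plus1=1.2, k_plus2=0.8,
    F_C1=F_C1_DEFAULT, F_C2=72.0, n=3.8, variant="wt",
)
VARIANT_EC1_27 = SlidingRebindingParams(
    k_minus1_0=0.29, x_beta=0.6, k_plus1=0.5, k_plus2=0.5,
    F_C1=F_C1_DEFAULT, F_C2=86.8, n=3.0, variant="wt",
)

CDH23_VARIANTS = {
    "EC1-5": VARIANT_EC1_5,
    "EC1-10": VARIANT_EC1_10,
    "EC1-21": VARIANT_EC1_21,
    "EC1-27": VARIANT_EC1_27,
}

# Bell-model unfolding kinetics per step-height class for full-length
# Cdh23 EC1-27 (step height label, x_beta_u in Angstrom, k_u0 in 1/s).
UNFOLDING_CLASSES_EC1_27 = {
    "5nm": UnfoldingClassParams(k_u0=0.17, x_beta_u=2.3, step_height=4.2),
    "12nm": UnfoldingClassParams(k_u0=0.45, x_beta_u=1.0, step_height=13.2),
    "22nm": UnfoldingClassParams(k_u0=0.45, x_beta_u=1.8, step_height=22.4),
    "34nm": UnfoldingClassParams(k_u0=0.36, x_beta_u=0.7, step_height=33.6),
}

# Most probable unfolding step heights (nm) of the Cdh23 variants, from
# Gaussian fits to step-height distributions.
STEP_HEIGHT_MEANS = {
    "EC1-5": (5.2, 12.9, 22.6, 34.3),
    "EC1-10": (5.8, 12.2, 17.1, 34.4),
    "EC1-21": (3.7, 10.0, 24.6, 32.8),
    "EC1-27": (4.2, 13.2, 22.4, 33.6),
}

# Bell fits of the force-lifetime relation of the heterotetrameric
# tip-link complex: two slip regions flanking an ideal (force-insensitive)
# plateau.  tau0 in s, f_star in pN.
COMPLEX_SLIP1 = {"tau0": 31.8, "f_star": 24.5}
COMPLEX_SLIP2 = {"tau0": 8.4, "f_star": 231.3}
COMPLEX_IDEAL_TAU0 = 6.3

# Clamping forces used for the interface force-clamp series (pN).
INTERFACE_CLAMP_FORCES = (28.0, 41.0, 58.0, 80.0, 103.0, 119.0, 143.0)
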
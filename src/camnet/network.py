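"""Equilibrium binding networks for Ca2+/calmodulin (CaM) and MLCK.

CaM is treated as having two lumped Ca2+-binding sites, one per lobe (the
two EF hands of a lobe bind cooperatively and are collapsed into a single
site with a Hill-type stoichiometry ``h``).  A network state records which
lobes are Ca2+-loaded and whether MLCK is bound, giving the eight vertices
of a cube.  Three nested mechanisms are considered:

* **Model 1** (random): MLCK can bind CaM in every Ca2+-occupancy state.
* **Model 2** (partially ordered): MLCK binds only once the C-lobe is
  Ca2+-loaded.
* **Model 3** (fully ordered): MLCK binds only fully Ca2+-loaded CaM.

Free Ca2+ is *clamped* — an independent variable fixed by EGTA-buffered
calibration solutions — so the CaM conformer ensemble pre-equilibrates at
each Ca2+ level and MLCK binding reduces exactly to a bimolecular reaction
with an effective, Ca2+-dependent association constant.  All concentrations
are in uM; association constants in uM^-1 (lobe weights in uM^-h).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "BindingState",
    "ModelVariant",
    "ParameterSet",
    "Concentrations",
    "TitrationCurve",
    "MUTANTS",
    "enumerate_states",
    "effective_affinity",
    "fraction_bound",
    "fraction_bound_numeric_oracle",
    "limit_binding",
    "titration_curve",
]


@dataclass(frozen=True)
class BindingState:
    """One vertex of the binding cube.

    ``n_occupied``/``c_occupied`` flag Ca2+ loading of the N-/C-lobe site;
    ``mlck_bound`` flags the CaM-MLCK complex.
    """

    n_occupied: bool
    c_occupied: bool
    mlck_bound: bool


#: All eight states of the untruncated network.
ALL_STATES: tuple[BindingState, ...] = tuple(
    BindingState(n, c, m)
    for n in (False, True)
    for c in (False, True)
    for m in (False, True)
)


@dataclass(frozen=True)
class ModelVariant:
    """A mechanism (1-3) combined with a CaM mutant's lobe knockouts.

    Asp->Ala EF-hand mutations abolish Ca2+ binding of a lobe; a
    non-functional lobe can never be occupied, which truncates the cube
    further than the mechanism alone.
    """

    model_id: int
    n_lobe_functional: bool = True
    c_lobe_functional: bool = True

    def __post_init__(self) -> None:
        if self.model_id not in (1, 2, 3):
            raise ValueError(f"model_id must be 1, 2 or 3, got {self.model_id!r}")

    def admits_mlck(self, n_occupied: bool, c_occupied: bool) -> bool:
        """Whether the mechanism allows MLCK binding in this Ca2+ state."""
        if self.model_id == 1:
            return True
        if self.model_id == 2:
            return c_occupied
        return n_occupied and c_occupied

    def admits_state(self, state: BindingState) -> bool:
        if state.n_occupied and not self.n_lobe_functional:
            return False
        if state.c_occupied and not self.c_lobe_functional:
            return False
        if state.mlck_bound and not self.admits_mlck(
            state.n_occupied, state.c_occupied
        ):
            return False
        return True


#: Named CaM variants as (n_lobe_functional, c_lobe_functional) pairs.
#: "Nmut" is the N-lobe EF-hand knockout (D21A/D57A), "Cmut" the C-lobe
#: knockout (D94A/D130A), "quad" carries all four mutations.
MUTANTS: dict[str, tuple[bool, bool]] = {
    "WT": (True, True),
    "Nmut": (False, True),
    "Cmut": (True, False),
    "quad": (False, False),
}


def _default_mlck_assoc() -> dict[tuple[bool, bool], float]:
    # Reference MLCK association constants per Ca2+-occupancy state, uM^-1.
    # Apo (K9), C-only (K4) and fully loaded (K2) are literature reference
    # values; the N-only constant is not pinned by any printed limit and
    # defaults to the same magnitude as the single-lobe C-only constant.
    return {
        (False, False): 0.078,
        (False, True): 16.7,
        (True, False): 16.7,
        (True, True): 1000.0,
    }


@dataclass(frozen=True)
class ParameterSet:
    """Thermodynamically consistent parameterization of the network.

    The network is parameterized by *state weights* — the Boltzmann weight
    of each MLCK-free Ca2+-occupancy state relative to apo CaM — plus one
    MLCK association constant per Ca2+ state.  Every edge constant of the
    cube is a ratio of state weights, so detailed balance around each face
    holds by construction and the individually unprinted edge constants
    are never needed.

    Parameters
    ----------
    ca_assoc_N, ca_assoc_C
        Lumped association weight of the N-/C-lobe Ca2+ site (uM^-h): the
        weight of the singly loaded state at free Ca2+ ``x`` is
        ``ca_assoc * x**h``.  Defaults correspond to effective per-lobe
        dissociation constants of ~10 uM (N) and ~2 uM (C), so the
        predicted binding curve is flat below ~0.1 uM free Ca2+ and
        saturates by ~3 uM, as the measured titrations do.
    hill_exp
        Number of Ca2+ ions lumped per model site (h >= 1, default 2 —
        each lobe's cooperative EF-hand pair binds as a unit).
    mlck_assoc
        Mapping ``(n_occupied, c_occupied) -> K_M`` in uM^-1.
    """

    ca_assoc_N: float = 0.01
    ca_assoc_C: float = 0.25
    hill_exp: int = 2
    mlck_assoc: Mapping[tuple[bool, bool], float] = field(
        default_factory=_default_mlck_assoc
    )

    def __post_init__(self) -> None:
        if self.hill_exp < 1 or int(self.hill_exp) != self.hill_exp:
            raise ValueError("hill_exp must be a positive integer")
        if self.ca_assoc_N < 0 or self.ca_assoc_C < 0:
            raise ValueError("lobe association weights must be >= 0")
        missing = [
            s for s in ((n, c) for n in (False, True) for c in (False, True))
            if s not in self.mlck_assoc
        ]
        if missing:
            raise ValueError(f"mlck_assoc missing Ca states: {missing}")
        if any(v < 0 for v in self.mlck_assoc.values()):
            raise ValueError("MLCK association constants must be >= 0")

    # Named aliases used throughout the literature / this analysis.
    @property
    def k9(self) -> float:
        """Apo CaM - MLCK association constant, uM^-1."""
        return self.mlck_assoc[(False, False)]

    @property
    def k4(self) -> float:
        """C-lobe-loaded CaM - MLCK association constant, uM^-1."""
        return self.mlck_assoc[(False, True)]

    @property
    def k2(self) -> float:
        """Fully Ca2+-loaded CaM - MLCK association constant, uM^-1."""
        return self.mlck_assoc[(True, True)]

    @property
    def k6(self) -> float:
        """Alias of the C-lobe Ca2+ association weight, uM^-h."""
        return self.ca_assoc_C

    @classmethod
    def reference(cls) -> "ParameterSet":
        """The reference parameter set used for all numerical predictions."""
        return cls()

    def with_values(self, **kwargs) -> "ParameterSet":
        """Return a copy with named aliases or fields replaced."""
        alias_to_state = {"k9": (False, False), "k4": (False, True), "k2": (True, True)}
        mlck = dict(self.mlck_assoc)
        fields: dict = {}
        for key, val in kwargs.items():
            low = key.lower()
            if low in alias_to_state:
                mlck[alias_to_state[low]] = float(val)
            elif low == "k6":
                fields["ca_assoc_C"] = float(val)
            else:
                fields[key] = val
        return replace(self, mlck_assoc=mlck, **fields)

    def ca_state_weight(self, n_occupied: bool, c_occupied: bool, ca_free: float) -> float:
        """Boltzmann weight of an MLCK-free Ca2+-occupancy state (apo = 1)."""
        if ca_free < 0:
            raise ValueError("ca_free must be >= 0")
        w = 1.0
        xh = ca_free ** self.hill_exp
        if n_occupied:
            w *= self.ca_assoc_N * xh
        if c_occupied:
            w *= self.ca_assoc_C * xh
        return w


@dataclass(frozen=True)
class Concentrations:
    """Total protein concentrations and the clamped free Ca2+ level (uM)."""

    cam_tot: float
    mlck_tot: float
    ca_free: float = 0.0

    def __post_init__(self) -> None:
        if self.cam_tot < 0 or self.mlck_tot < 0 or self.ca_free < 0:
            raise ValueError("concentrations must be >= 0")


#: Concentrations of the main plate-reader experiment (Fig.-scale inputs):
#: 0.713 uM CaM with 0.0237 uM FRET reporter.
REFERENCE_CONCENTRATIONS = Concentrations(cam_tot=0.713, mlck_tot=0.0237)


def enumerate_states(variant: ModelVariant) -> frozenset[BindingState]:
    """All network states admissible under a mechanism + mutant.

    Model truncation removes MLCK-bound vertices whose Ca2+ state the
    mechanism forbids; lobe knockouts remove every vertex with the dead
    lobe occupied.
    """
    if not isinstance(variant, ModelVariant):
        raise TypeError("variant must be a ModelVariant")
    return frozenset(s for s in ALL_STATES if variant.admits_state(s))


def _ca_states(variant: ModelVariant) -> list[tuple[bool, bool]]:
    return [
        (n, c)
        for n in ((False, True) if variant.n_lobe_functional else (False,))
        for c in ((False, True) if variant.c_lobe_functional else (False,))
    ]


def effective_affinity(
    params: ParameterSet, variant: ModelVariant, ca_free: float
) -> float:
    """Effective bimolecular MLCK association constant at clamped free Ca2+.

    Because Ca2+ is clamped, MLCK sees a pre-equilibrated ensemble of CaM
    conformers and the network reduces exactly to one bimolecular reaction
    with

        K_eff(x) = sum_s w_s(x) K_M(s) / sum_s w_s(x)

    over admissible MLCK-free Ca2+ states ``s``, where K_M(s) = 0 in states
    the mechanism forbids MLCK to bind.  Returns uM^-1.
    """
    if ca_free < 0:
        raise ValueError("ca_free must be >= 0")
    num = 0.0
    den = 0.0
    for n, c in _ca_states(variant):
        w = params.ca_state_weight(n, c, ca_free)
        k = params.mlck_assoc[(n, c)] if variant.admits_mlck(n, c) else 0.0
        num += w * k
        den += w
    return num / den


def fraction_bound(k_eff: float, cam_tot: float, mlck_tot: float) -> float:
    """Closed-form equilibrium fraction of MLCK bound in a bimolecular reaction.

    For association constant K (uM^-1) and totals C, M (uM),

        F = 2 K C / (1 + K(C+M) + sqrt(1 + 2 K(C+M) + K^2 (C-M)^2)).

    This is the root of the binding quadratic written in a cancellation-free
    form; F = 0 when K = 0 or C = 0.
    """
    if k_eff < 0 or cam_tot < 0 or mlck_tot < 0:
        raise ValueError("k_eff, cam_tot and mlck_tot must be >= 0")
    if k_eff == 0.0 or cam_tot == 0.0:
        return 0.0
    s = k_eff * (cam_tot + mlck_tot)
    d = k_eff * (cam_tot - mlck_tot)
    return 2.0 * k_eff * cam_tot / (1.0 + s + math.sqrt(1.0 + 2.0 * s + d * d))


def fraction_bound_numeric_oracle(
    params: ParameterSet, variant: ModelVariant, conc: Concentrations
) -> float:
    """Fraction of MLCK bound from the full mass-action equilibrium.

    Independent verification route: state concentrations are weights times
    free-species concentrations, total CaM and total MLCK are conserved,
    free Ca2+ is clamped, and free MLCK is found by bracketed 1-D
    root-finding.  Agrees with ``fraction_bound(effective_affinity(...))``
    to solver precision.

    Raises
    ------
    RuntimeError
        If the root cannot be bracketed; the offending inputs are included
        in the message.
    """
    if conc.mlck_tot == 0.0 or conc.cam_tot == 0.0:
        return 0.0
    x = conc.ca_free
    sum_w = 0.0
    sum_kw = 0.0
    for n, c in _ca_states(variant):
        w = params.ca_state_weight(n, c, x)
        sum_w += w
        if variant.admits_mlck(n, c):
            sum_kw += w * params.mlck_assoc[(n, c)]
    if sum_kw == 0.0:
        return 0.0

    C, M = conc.cam_tot, conc.mlck_tot

    def residual(m_free: float) -> float:
        # apo, MLCK-free CaM concentration from CaM conservation
        cam_apo = C / (sum_w + m_free * sum_kw)
        return m_free + cam_apo * m_free * sum_kw - M

    lo, hi = 0.0, M
    if residual(lo) > 0 or residual(hi) < 0:
        raise RuntimeError(
            f"failed to bracket free MLCK for params={params}, "
            f"variant={variant}, conc={conc}"
        )
    m_free = brentq(residual, lo, hi, xtol=1e-300, rtol=8.9e-16, maxiter=200)
    cam_apo = C / (sum_w + m_free * sum_kw)
    bound = cam_apo * m_free * sum_kw  # sum of MLCK-bound state concentrations
    return bound / M


def limit_binding(
    params: ParameterSet,
    variant: ModelVariant,
    conc: Concentrations,
    end: str,
) -> float:
    """Fraction of MLCK bound in the zero- or saturating-Ca2+ limit.

    At ``end='low'`` (x -> 0) only the apo state carries weight, so the
    fraction is the bimolecular closed form with the apo constant K9 under
    Model 1 and *exactly* zero under Models 2 and 3 (structural zero).  At
    ``end='high'`` the fully occupied admissible state dominates; a
    mechanism that forbids MLCK binding there (Model 3 with a dead N-lobe,
    any model 2/3 with a dead C-lobe) again returns exactly zero.
    """
    if end not in ("low", "high"):
        raise ValueError("end must be 'low' or 'high'")
    if end == "low":
        n_occ, c_occ = False, False
    else:
        n_occ = variant.n_lobe_functional and params.ca_assoc_N > 0
        c_occ = variant.c_lobe_functional and params.ca_assoc_C > 0
    if not variant.admits_mlck(n_occ, c_occ):
        return 0.0
    k = params.mlck_assoc[(n_occ, c_occ)]
    return fraction_bound(k, conc.cam_tot, conc.mlck_tot)


@dataclass(frozen=True)
class TitrationCurve:
    """Fraction of MLCK bound versus clamped free Ca2+ at fixed totals."""

    ca_grid: tuple[float, ...]
    fraction_bound: tuple[float, ...]
    variant: ModelVariant
    params: ParameterSet
    conc: Concentrations
    structural_zero: bool = False

    def __post_init__(self) -> None:
        if len(self.ca_grid) != len(self.fraction_bound):
            raise ValueError("ca_grid and fraction_bound lengths differ")

    def to_frame(self, model_label: str | None = None, mutant_label: str = ""):
        import pandas as pd

        return pd.DataFrame(
            {
                "ca_free_uM": self.ca_grid,
                "fraction_bound": self.fraction_bound,
                "model": model_label or f"Model {self.variant.model_id}",
                "mutant": mutant_label,
            }
        )


def titration_curve(
    params: ParameterSet,
    variant: ModelVariant,
    cam_tot: float,
    mlck_tot: float,
    ca_grid: Sequence[float],
) -> TitrationCurve:
    """Predicted binding curve over a free-Ca2+ grid (uM, sorted ascending)."""
    grid = np.asarray(ca_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("ca_grid must be nonempty")
    if np.any(grid < 0):
        raise ValueError("ca_grid values must be >= 0")
    if np.any(np.diff(grid) < 0):
        raise ValueError("ca_grid must be sorted ascending")
    competent = any(
        variant.admits_mlck(n, c) for n, c in _ca_states(variant)
    )
    fractions = tuple(
        fraction_bound(effective_affinity(params, variant, x), cam_tot, mlck_tot)
        for x in grid
    )
    return TitrationCurve(
        ca_grid=tuple(float(x) for x in grid),
        fraction_bound=fractions,
        variant=variant,
        params=params,
        conc=Concentrations(cam_tot, mlck_tot, 0.0),
        structural_zero=not competent,
    )
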
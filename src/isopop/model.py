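"""Generative carbon-source labeling model of simplified yeast central carbon metabolism.

Cells grow on a mixture of uniformly labeled heavy (13C) and light (12C)
hexoses.  Every carbon of an amino acid is inherited from a metabolic
precursor (triose phosphates, acetyl-CoA, oxaloacetate, alpha-ketoglutarate,
erythrose-4-phosphate, or the intracellular CO2 pool), and every precursor
carbon traces back to one hexose "source unit" or to CO2 from air.  Within a
source unit all carbons share one label, so the number of independent units
feeding a fragment — not the pathway fluxes themselves — determines its mass
isotopomer distribution.

Four biochemical branch fractions are free:

* ``ap``  — anaplerotic (pyruvate carboxylation) vs TCA-turnover origin of
  oxaloacetate,
* ``rev`` — reverse (reductive) vs forward (oxidative) TCA origin of
  alpha-ketoglutarate,
* ``ppp`` — oxidative (single-unit) vs non-oxidative (two-unit) origin of
  erythrose-4-phosphate,
* ``co2`` — fraction of incorporated CO2 drawn from air rather than
  recaptured from intracellular decarboxylations.

Positional labeling patterns carry one of three per-carbon labels: light
sugar, heavy sugar, or air CO2.  Air carbons weigh like light carbons (the
measurement layer applies natural 13C abundance to both).  The TCA
interdependence (OAA <- AKG <- OAA) is resolved as the fixed point of the
linear stationary-isotopomer balance over all positional patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

# Per-carbon source labels.
LIGHT, HEAVY, AIR = 0, 1, 2
LABEL_NAMES = ("light", "heavy", "air")

#: Carbon counts of the modeled precursors.
PRECURSOR_CARBONS: Dict[str, int] = {
    "triose": 3,        # 3PG / PEP / pyruvate — one hexose half
    "acetyl_coa": 2,
    "oxaloacetate": 4,
    "alpha_ketoglutarate": 5,
    "e4p": 4,
    "co2": 1,
}

MAX_FIXED_POINT_ITER = 10_000
FIXED_POINT_TOL = 1e-10


class ModelError(RuntimeError):
    """Raised when the stationary isotopomer balance fails to resolve."""


class ConfigurationError(ValueError):
    """Raised for inconsistent amino-acid / fragment definitions."""


# --------------------------------------------------------------------------
# Parameter containers
# --------------------------------------------------------------------------


def _check_fraction(name: str, value: float) -> float:
    value = float(value)
    if not (0.0 <= value <= 1.0) or not np.isfinite(value):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
    return value


@dataclass(frozen=True)
class BiochemParams:
    """The four free metabolic branch fractions, each in [0, 1]."""

    ap: float = 0.9
    rev: float = 0.5
    ppp: float = 0.5
    co2: float = 0.1

    def __post_init__(self) -> None:
        for name in ("ap", "rev", "ppp", "co2"):
            object.__setattr__(self, name, _check_fraction(name, getattr(self, name)))

    def as_tuple(self) -> Tuple[float, float, float, float]:
        return (self.ap, self.rev, self.ppp, self.co2)


@dataclass(frozen=True)
class PopulationState:
    """One subpopulation: its light-sugar usage fraction plus branch params.

    ``usage12c`` is the fraction of consumed hexose molecules that are
    light (12C); ``1 - usage12c`` of the units are heavy.
    """

    usage12c: float
    biochem: BiochemParams = field(default_factory=BiochemParams)

    def __post_init__(self) -> None:
        object.__setattr__(self, "usage12c", _check_fraction("usage12c", self.usage12c))

    def as_vector(self) -> np.ndarray:
        return np.array([self.usage12c, *self.biochem.as_tuple()])

    @classmethod
    def from_vector(cls, vec: Sequence[float]) -> "PopulationState":
        u, ap, rev, ppp, co2 = (float(v) for v in vec)
        return cls(u, BiochemParams(ap=ap, rev=rev, ppp=ppp, co2=co2))


@dataclass(frozen=True)
class PopulationModel:
    """One or two weighted subpopulation states (canonical form).

    Canonical form: weights sum to 1, each weight > 0, and for two states
    the states are ordered by descending ``usage12c``.
    """

    states: Tuple[Tuple[float, PopulationState], ...]

    def __post_init__(self) -> None:
        states = tuple((float(w), s) for w, s in self.states)
        if len(states) not in (1, 2):
            raise ValueError("PopulationModel supports 1 or 2 states")
        total = sum(w for w, _ in states)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"state weights must sum to 1, got {total}")
        if any(w <= 0 for w, _ in states):
            raise ValueError("state weights must be positive")
        if len(states) == 2 and states[0][1].usage12c < states[1][1].usage12c:
            states = (states[1], states[0])
        object.__setattr__(self, "states", states)

    @classmethod
    def one_state(cls, state: PopulationState) -> "PopulationModel":
        return cls(((1.0, state),))

    @classmethod
    def two_state(
        cls, weight_a: float, state_a: PopulationState, state_b: PopulationState
    ) -> "PopulationModel":
        return cls(((weight_a, state_a), (1.0 - weight_a, state_b)))

    @property
    def n_states(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class PrecursorDistribution:
    """Distribution over positional labeling patterns of one precursor."""

    precursor: str
    patterns: Mapping[Tuple[int, ...], float]

    @property
    def n_carbons(self) -> int:
        return PRECURSOR_CARBONS[self.precursor]

    def heavy_count_distribution(self) -> np.ndarray:
        """Marginal distribution of the number of heavy carbons."""
        out = np.zeros(self.n_carbons + 1)
        for pattern, p in self.patterns.items():
            out[sum(1 for c in pattern if c == HEAVY)] += p
        return out


# --------------------------------------------------------------------------
# Pattern codes (base-3 integers, carbon 1 most significant)
# --------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _pattern_tuples(n: int) -> Tuple[Tuple[int, ...], ...]:
    tuples = []
    for code in range(3**n):
        t = []
        for k in range(n - 1, -1, -1):
            t.append((code // 3**k) % 3)
        tuples.append(tuple(t))
    return tuple(tuples)


def _code(pattern: Sequence[int]) -> int:
    c = 0
    for lab in pattern:
        c = c * 3 + lab
    return c


def _vector_to_patterns(vec: np.ndarray, n: int, tol: float = 0.0) -> Dict[Tuple[int, ...], float]:
    tuples = _pattern_tuples(n)
    return {tuples[i]: float(p) for i, p in enumerate(vec) if p > tol}


# --------------------------------------------------------------------------
# Static TCA transition matrices
#
# Atom mapping (canonical yeast biochemistry):
#   forward:  AKG(C1..C5) = (OAA C4, OAA C3, OAA C2, AcCoA C2, AcCoA C1);
#             OAA C1 is released as CO2 at isocitrate dehydrogenase.
#   reverse:  AKG C1 <- CO2 pool; AKG(C2..C5) <- succinate <- OAA(C1..C4).
#   turnover: AKG C1 released as CO2; OAA(C1..C4) <- succinate <- AKG(C2..C5).
# Succinate/fumarate are rotationally symmetric, so every arc through them
# averages a pattern with its reversal.
# --------------------------------------------------------------------------


def _build_static_maps():
    oaa_tuples = _pattern_tuples(4)
    akg_tuples = _pattern_tuples(5)

    akg_fwd = {lab: np.zeros((243, 81)) for lab in (LIGHT, HEAVY)}
    akg_rev = {lab: np.zeros((243, 81)) for lab in (LIGHT, HEAVY, AIR)}
    oaa_from_akg = np.zeros((81, 243))

    for o_idx, o in enumerate(oaa_tuples):
        for lab in (LIGHT, HEAVY):
            akg = (o[3], o[2], o[1], lab, lab)
            akg_fwd[lab][_code(akg), o_idx] += 1.0
        for lab in (LIGHT, HEAVY, AIR):
            for succ in (o, o[::-1]):
                akg = (lab,) + succ
                akg_rev[lab][_code(akg), o_idx] += 0.5

    for a_idx, a in enumerate(akg_tuples):
        succ = a[1:]
        for s in (succ, succ[::-1]):
            oaa_from_akg[_code(s), a_idx] += 0.5

    # OAA <- OAA one-turn kernels (turnover composed with each AKG source).
    k_fwd = {lab: oaa_from_akg @ akg_fwd[lab] for lab in akg_fwd}
    k_rev = {lab: oaa_from_akg @ akg_rev[lab] for lab in akg_rev}
    return akg_fwd, akg_rev, oaa_from_akg, k_fwd, k_rev


_AKG_FWD, _AKG_REV, _OAA_FROM_AKG, _K_FWD, _K_REV = _build_static_maps()
_IDENTITY_81 = np.eye(81)


# --------------------------------------------------------------------------
# Precursor solver
# --------------------------------------------------------------------------


def _co2_pool_probs(u: float, co2: float) -> np.ndarray:
    """(light, heavy, air) probabilities of one CO2-pool carbon.

    Recaptured CO2 carries the label of a decarboxylation donor, modeled as
    a fresh triose-unit draw (heavy w.p. 1 - usage12c).
    """
    h = 1.0 - u
    return np.array([(1.0 - co2) * u, (1.0 - co2) * h, co2])


def solve_precursor_arrays(state: PopulationState) -> Dict[str, np.ndarray]:
    """Stationary pattern-probability vectors, indexed by base-3 pattern code.

    Fast path used by the measurement operator; see
    :func:`solve_precursor_distributions` for the mapping-based API.
    """
    u = state.usage12c
    ap, rev, ppp, co2 = state.biochem.as_tuple()
    h = 1.0 - u
    co2_p = _co2_pool_probs(u, co2)

    triose = np.zeros(27)
    triose[_code((LIGHT,) * 3)] += u
    triose[_code((HEAVY,) * 3)] += h

    accoa = np.zeros(9)
    accoa[_code((LIGHT, LIGHT))] += u
    accoa[_code((HEAVY, HEAVY))] += h

    co2_vec = np.zeros(3)
    co2_vec[LIGHT], co2_vec[HEAVY], co2_vec[AIR] = co2_p

    e4p = np.zeros(81)
    for lab, p in ((LIGHT, u), (HEAVY, h)):
        e4p[_code((lab,) * 4)] += ppp * p
    for lab1, p1 in ((LIGHT, u), (HEAVY, h)):
        for lab2, p2 in ((LIGHT, u), (HEAVY, h)):
            e4p[_code((lab1, lab1, lab2, lab2))] += (1.0 - ppp) * p1 * p2

    # Anaplerotic OAA: one triose unit on C1..C3 plus one CO2-pool carbon on C4.
    ana = np.zeros(81)
    for t_lab, t_p in ((LIGHT, u), (HEAVY, h)):
        for c_lab in (LIGHT, HEAVY, AIR):
            ana[_code((t_lab, t_lab, t_lab, c_lab))] += t_p * co2_p[c_lab]

    # One-turn OAA <- OAA kernel (column-stochastic).
    kernel = (1.0 - rev) * (u * _K_FWD[LIGHT] + h * _K_FWD[HEAVY]) + rev * (
        co2_p[LIGHT] * _K_REV[LIGHT]
        + co2_p[HEAVY] * _K_REV[HEAVY]
        + co2_p[AIR] * _K_REV[AIR]
    )

    # OAA = ap * ana + (1 - ap) * kernel @ OAA  — exact linear solve.  The
    # kernel is column-stochastic, so the system is nonsingular for ap > 0;
    # flooring ap yields the correct ap -> 0 limit (turnover memory of the
    # anaplerotic entry composition) without the slow mixing an iterative
    # scheme would face near rev = 1.
    ap_eff = max(ap, 1e-9)
    try:
        oaa = np.linalg.solve(_IDENTITY_81 - (1.0 - ap_eff) * kernel, ap_eff * ana)
    except np.linalg.LinAlgError:  # pragma: no cover - stochastic kernel guard
        oaa = ana.copy()
        for _ in range(MAX_FIXED_POINT_ITER):
            new = ap_eff * ana + (1.0 - ap_eff) * (kernel @ oaa)
            if np.abs(new - oaa).sum() < FIXED_POINT_TOL:
                oaa = new
                break
            oaa = new
        else:
            raise ModelError("TCA isotopomer balance did not converge")
    oaa = np.clip(oaa, 0.0, None)
    oaa /= oaa.sum()

    m_akg = (1.0 - rev) * (u * _AKG_FWD[LIGHT] + h * _AKG_FWD[HEAVY]) + rev * (
        co2_p[LIGHT] * _AKG_REV[LIGHT]
        + co2_p[HEAVY] * _AKG_REV[HEAVY]
        + co2_p[AIR] * _AKG_REV[AIR]
    )
    akg = m_akg @ oaa

    return {
        "triose": triose,
        "acetyl_coa": accoa,
        "oxaloacetate": oaa,
        "alpha_ketoglutarate": akg,
        "e4p": e4p,
        "co2": co2_vec,
    }


def solve_precursor_distributions(
    state: PopulationState,
) -> Dict[str, PrecursorDistribution]:
    """Steady-state positional labeling distributions of all precursors."""
    arrays = solve_precursor_arrays(state)
    out = {}
    for name, vec in arrays.items():
        n = PRECURSOR_CARBONS[name]
        out[name] = PrecursorDistribution(name, _vector_to_patterns(vec, n, tol=0.0))
    return out


def iterate_precursor_fixed_point(
    state: PopulationState, tol: float = FIXED_POINT_TOL, max_iter: int = MAX_FIXED_POINT_ITER
) -> np.ndarray:
    """OAA pattern vector by explicit truncated-history iteration.

    Equivalent to unrolling the TCA recursion from the anaplerotic entry
    until the residual history weight falls below ``tol``.  Retained as an
    independent check of the direct linear solve.
    """
    u = state.usage12c
    ap, rev, ppp, co2 = state.biochem.as_tuple()
    h = 1.0 - u
    co2_p = _co2_pool_probs(u, co2)
    kernel = (1.0 - rev) * (u * _K_FWD[LIGHT] + h * _K_FWD[HEAVY]) + rev * (
        co2_p[LIGHT] * _K_REV[LIGHT]
        + co2_p[HEAVY] * _K_REV[HEAVY]
        + co2_p[AIR] * _K_REV[AIR]
    )
    ana = np.zeros(81)
    for t_lab, t_p in ((LIGHT, u), (HEAVY, h)):
        for c_lab in (LIGHT, HEAVY, AIR):
            ana[_code((t_lab, t_lab, t_lab, c_lab))] += t_p * co2_p[c_lab]
    oaa = ana.copy()
    for _ in range(max_iter):
        new = ap * ana + (1.0 - ap) * (kernel @ oaa)
        if np.abs(new - oaa).sum() < tol:
            return new
        oaa = new
    raise ModelError("TCA isotopomer balance did not converge")


# --------------------------------------------------------------------------
# Amino acid definitions
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AminoAcidDefinition:
    """Precursor composition and carbon map of one amino acid.

    ``precursors`` lists the precursor instances in order (with
    multiplicity); ``carbon_map`` assigns each amino-acid carbon position
    (1-based, in index order) to ``(instance_index, precursor_carbon)``.
    """

    name: str
    precursors: Tuple[str, ...]
    carbon_map: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        for inst, carbon in self.carbon_map:
            if not (0 <= inst < len(self.precursors)):
                raise ConfigurationError(
                    f"{self.name}: carbon mapped to missing precursor instance {inst}"
                )
            if not (1 <= carbon <= PRECURSOR_CARBONS[self.precursors[inst]]):
                raise ConfigurationError(
                    f"{self.name}: carbon {carbon} outside precursor "
                    f"{self.precursors[inst]}"
                )

    @property
    def n_carbons(self) -> int:
        return len(self.carbon_map)


def _aa(name, precursors, carbon_map):
    return AminoAcidDefinition(name, tuple(precursors), tuple(carbon_map))


#: Default amino-acid biosynthesis map (canonical S. cerevisiae routes on a
#: simplified network; config-overridable).  Carbon positions follow IUPAC
#: numbering with C1 = the alpha carboxyl.
DEFAULT_AMINO_ACIDS: Dict[str, AminoAcidDefinition] = {
    aa.name: aa
    for aa in [
        _aa("Ala", ["triose"], [(0, 1), (0, 2), (0, 3)]),
        _aa("Ser", ["triose"], [(0, 1), (0, 2), (0, 3)]),
        _aa("Gly", ["triose"], [(0, 1), (0, 2)]),
        # Val: 2 pyruvate - 1 CO2 (acetolactate route).
        _aa("Val", ["triose", "triose"], [(0, 1), (0, 2), (1, 2), (0, 3), (1, 3)]),
        # Leu: AcCoA + ketoisovalerate (2 pyruvate) - 2 CO2.
        _aa(
            "Leu",
            ["acetyl_coa", "triose", "triose"],
            [(0, 1), (0, 2), (1, 2), (2, 2), (1, 3), (2, 3)],
        ),
        # Ile: threonine backbone (OAA) + pyruvate - 1 CO2.
        _aa(
            "Ile",
            ["oxaloacetate", "triose"],
            [(0, 1), (0, 2), (1, 2), (0, 3), (0, 4), (1, 3)],
        ),
        _aa("Thr", ["oxaloacetate"], [(0, 1), (0, 2), (0, 3), (0, 4)]),
        _aa("Asp", ["oxaloacetate"], [(0, 1), (0, 2), (0, 3), (0, 4)]),
        _aa("Asn", ["oxaloacetate"], [(0, 1), (0, 2), (0, 3), (0, 4)]),
        # Met backbone only; the C1-metabolism methyl carbon is not modeled
        # and fragments containing it are excluded from the default panel.
        _aa("Met", ["oxaloacetate"], [(0, 1), (0, 2), (0, 3), (0, 4)]),
        _aa("Glu", ["alpha_ketoglutarate"], [(0, k) for k in range(1, 6)]),
        _aa("Gln", ["alpha_ketoglutarate"], [(0, k) for k in range(1, 6)]),
        _aa("Pro", ["alpha_ketoglutarate"], [(0, k) for k in range(1, 6)]),
        _aa(
            "Arg",
            ["alpha_ketoglutarate", "co2"],
            [(0, 1), (0, 2), (0, 3), (0, 4), (0, 5), (1, 1)],
        ),
        # Lys via the diaminopimelate stoichiometry (pyruvate + OAA - CO2).
        _aa(
            "Lys",
            ["oxaloacetate", "triose"],
            [(0, 1), (0, 2), (0, 3), (0, 4), (1, 3), (1, 2)],
        ),
        # Phe/Tyr: 2 PEP + E4P - 1 CO2 (shikimate route); instance 0 is the
        # side-chain PEP, instance 1 the ring PEP (its C1 lost as CO2).
        _aa(
            "Phe",
            ["triose", "triose", "e4p"],
            [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 1), (2, 2), (2, 3), (2, 4)],
        ),
        _aa(
            "Tyr",
            ["triose", "triose", "e4p"],
            [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 1), (2, 2), (2, 3), (2, 4)],
        ),
    ]
}


def amino_acid_isotopomer_distribution(
    aa: AminoAcidDefinition,
    precursors: Mapping[str, PrecursorDistribution],
) -> Dict[Tuple[int, ...], float]:
    """Joint distribution over per-carbon label tuples of one amino acid.

    Each precursor instance is drawn independently; carbons are rearranged
    by the amino acid's carbon map.
    """
    for p in aa.precursors:
        if p not in precursors:
            raise ConfigurationError(f"{aa.name}: missing precursor {p}")
    dist: Dict[Tuple[Tuple[int, ...], ...], float] = {(): 1.0}
    for p in aa.precursors:
        support = precursors[p].patterns
        dist = {
            combo + (pattern,): q * pr
            for combo, q in dist.items()
            for pattern, pr in support.items()
            if q * pr > 0.0
        }
    out: Dict[Tuple[int, ...], float] = {}
    for combo, q in dist.items():
        labels = tuple(combo[inst][carbon - 1] for inst, carbon in aa.carbon_map)
        out[labels] = out.get(labels, 0.0) + q
    return out


def fragment_carbon_mass_distribution(
    retained_positions: Sequence[int],
    aa_dist: Mapping[Tuple[int, ...], float],
) -> np.ndarray:
    """Marginal heavy-carbon-count distribution over retained positions.

    ``retained_positions`` are 1-based amino-acid carbon positions; air
    carbons weigh like light ones.
    """
    n_aa = len(next(iter(aa_dist)))
    for pos in retained_positions:
        if not (1 <= pos <= n_aa):
            raise ConfigurationError(f"retained position {pos} outside amino acid")
    out = np.zeros(len(retained_positions) + 1)
    for labels, p in aa_dist.items():
        k = sum(1 for pos in retained_positions if labels[pos - 1] == HEAVY)
        out[k] += p
    total = out.sum()
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ModelError(f"mass distribution sums to {total}")
    return out / total
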
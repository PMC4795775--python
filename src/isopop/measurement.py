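"""Predicted GC-MS mass isotopomer distributions for TBDMS amino-acid fragments.

The carbon-labeling model (:mod:`isopop.model`) yields the distribution of
heavy *source* carbons per fragment.  What GC-MS observes also reflects
tracer impurity (the heavy sugar is ~99% 13C) and natural heavy-isotope
abundance in every atom of the derivatized ion — including the silicon-rich
TBDMS groups, whose 29Si/30Si isotopes produce a sizable mass tail.  This
module builds the linear operator mapping heavy-source-carbon counts to
observed mass channels, assembles the default 29-fragment panel, and mixes
predictions across subpopulation states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import binom

from .model import (
    HEAVY,
    PRECURSOR_CARBONS,
    AminoAcidDefinition,
    ConfigurationError,
    DEFAULT_AMINO_ACIDS,
    PopulationModel,
    PopulationState,
    _pattern_tuples,
    solve_precursor_arrays,
)

#: Natural heavy-isotope abundances per atom, as mass-shift probabilities
#: (index = mass shift).  IUPAC standard values.
NATURAL_ABUNDANCE: Dict[str, np.ndarray] = {
    "C": np.array([1 - 0.0107, 0.0107]),
    "H": np.array([1 - 0.000115, 0.000115]),
    "N": np.array([1 - 0.00364, 0.00364]),
    "O": np.array([1 - 0.00038 - 0.00205, 0.00038, 0.00205]),
    "Si": np.array([1 - 0.04685 - 0.03092, 0.04685, 0.03092]),
    "S": np.array([1 - 0.0075 - 0.0425, 0.0075, 0.0425]),
}

#: Extra mass channels reported beyond the source-carbon count.  +2 covers
#: the 29Si/30Si (and 34S) heavy-isotope tail of the TBDMS groups, which
#: carries essentially all non-source isotope mass; further channels hold
#: <1e-3 abundance and no information.
EXTRA_CHANNELS = 2


@dataclass(frozen=True)
class TracerSpec:
    """Isotopic composition of the carbon sources.

    ``purity``: 13C fraction of each carbon in the heavy tracer (0.99 for
    commercial [U-13C]glucose).  ``light_nat``: 13C natural abundance of
    light-source (and air) carbons.
    """

    purity: float = 0.99
    light_nat: float = 0.0107

    def __post_init__(self) -> None:
        for name in ("purity", "light_nat"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")


@dataclass(frozen=True)
class FragmentDefinition:
    """One measurable derivatized amino-acid fragment.

    ``retained_positions`` are 1-based amino-acid carbon positions present
    in the ion.  ``nonsource_formula`` counts the atoms that are not
    amino-acid source carbons (derivatization carbons, H, N, O, S, Si).
    """

    fragment_id: str
    amino_acid: str
    retained_positions: Tuple[int, ...]
    nonsource_formula: Mapping[str, int]
    n_channels: int

    def __post_init__(self) -> None:
        if self.n_channels < self.n_source_carbons + 1:
            raise ConfigurationError(
                f"{self.fragment_id}: {self.n_channels} channels cannot hold "
                f"{self.n_source_carbons} source carbons"
            )
        for el, count in self.nonsource_formula.items():
            if el not in NATURAL_ABUNDANCE:
                raise ConfigurationError(f"{self.fragment_id}: unknown element {el}")
            if count < 0:
                raise ConfigurationError(f"{self.fragment_id}: negative {el} count")

    @property
    def n_source_carbons(self) -> int:
        return len(self.retained_positions)


@dataclass(frozen=True)
class FragmentPanel:
    """Ordered fragment collection with analysis-subset flags."""

    fragments: Tuple[FragmentDefinition, ...]
    shift_subset: Tuple[str, ...] = ()
    single_unit: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ids = [f.fragment_id for f in self.fragments]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate fragment ids in panel")
        known = set(ids)
        for fid in (*self.shift_subset, *self.single_unit):
            if fid not in known:
                raise ConfigurationError(f"subset references unknown fragment {fid}")

    @property
    def fragment_ids(self) -> Tuple[str, ...]:
        return tuple(f.fragment_id for f in self.fragments)

    def __len__(self) -> int:
        return len(self.fragments)

    def get(self, fragment_id: str) -> FragmentDefinition:
        for f in self.fragments:
            if f.fragment_id == fragment_id:
                return f
        raise KeyError(fragment_id)

    def subset(self, fragment_ids: Iterable[str]) -> "FragmentPanel":
        keep = set(fragment_ids)
        frags = tuple(f for f in self.fragments if f.fragment_id in keep)
        return FragmentPanel(
            frags,
            tuple(i for i in self.shift_subset if i in keep),
            tuple(i for i in self.single_unit if i in keep),
        )


@dataclass
class SampleMeasurement:
    """One sample's mass isotopomer distributions, one per panel fragment."""

    sample_id: str
    mids: Dict[str, np.ndarray]
    replicate: Optional[str] = None
    doublings: Optional[float] = None

    def concat(self, fragment_ids: Sequence[str]) -> np.ndarray:
        return np.concatenate([self.mids[fid] for fid in fragment_ids])

    def copy(self) -> "SampleMeasurement":
        return SampleMeasurement(
            self.sample_id,
            {k: v.copy() for k, v in self.mids.items()},
            self.replicate,
            self.doublings,
        )


# --------------------------------------------------------------------------
# Default panel construction
# --------------------------------------------------------------------------

#: Free amino-acid elemental formulas (C, H, N, O, S) and TBDMS group count.
_AA_FORMULAS: Dict[str, Tuple[Tuple[int, int, int, int, int], int]] = {
    "Ala": ((3, 7, 1, 2, 0), 2),
    "Gly": ((2, 5, 1, 2, 0), 2),
    "Val": ((5, 11, 1, 2, 0), 2),
    "Leu": ((6, 13, 1, 2, 0), 2),
    "Ile": ((6, 13, 1, 2, 0), 2),
    "Pro": ((5, 9, 1, 2, 0), 2),
    "Ser": ((3, 7, 1, 3, 0), 3),
    "Thr": ((4, 9, 1, 3, 0), 3),
    "Phe": ((9, 11, 1, 2, 0), 2),
    "Asp": ((4, 7, 1, 4, 0), 3),
    "Glu": ((5, 9, 1, 4, 0), 3),
    "Tyr": ((9, 11, 1, 3, 0), 3),
    "Lys": ((6, 14, 2, 2, 0), 3),
    "Arg": ((6, 14, 4, 2, 0), 3),
    "Met": ((5, 11, 1, 2, 1), 2),
}


def _formula(c: int, h: int, n: int, o: int, s: int, si: int) -> Dict[str, int]:
    out = {"C": c, "H": h, "N": n, "O": o, "S": s, "Si": si}
    return {el: cnt for el, cnt in out.items() if cnt > 0}


def make_fragment(amino_acid: str, kind: str) -> FragmentDefinition:
    """Build a standard TBDMS fragment ([M-57], [M-85], [M-159], f302).

    The derivatized molecule is AA + k TBDMS groups (each +C6H14Si net);
    [M-57] loses tBu, [M-85] additionally CO (amino-acid C1), [M-159] loses
    the whole COO-TBDMS group (C1, two O, one TBDMS).  f302 retains only
    C1-C2 with both backbone TBDMS groups.
    """
    (c, h, n, o, s), k = _AA_FORMULAS[amino_acid]
    n_aa = c  # amino-acid carbons
    if kind == "m57":
        retained = tuple(range(1, n_aa + 1))
        nonsource = _formula(6 * k - 4, h + 14 * k - 9, n, o, s, k)
    elif kind == "m85":
        retained = tuple(range(2, n_aa + 1))
        nonsource = _formula(6 * k - 4, h + 14 * k - 9, n, o - 1, s, k)
    elif kind == "m159":
        retained = tuple(range(2, n_aa + 1))
        nonsource = _formula(6 * k - 4 - 2, h + 14 * k - 15, n, o - 2, s, k - 1)
    elif kind == "f302":
        retained = (1, 2)
        nonsource = _formula(12, 30, 1, 2, 0, 2)
    else:
        raise ConfigurationError(f"unknown fragment kind {kind!r}")
    n_src = len(retained)
    return FragmentDefinition(
        fragment_id=f"{amino_acid}_{kind}",
        amino_acid=amino_acid,
        retained_positions=retained,
        nonsource_formula=nonsource,
        n_channels=n_src + EXTRA_CHANNELS + 1,
    )


#: The default fitting panel: 29 TBDMS fragments chosen for ease of
#: modeling, reproducibility and lack of interfering species.
_DEFAULT_PANEL_SPEC: Tuple[Tuple[str, str], ...] = tuple(
    (aa, kind)
    for aa, kinds in [
        ("Ala", ("m57", "m159")),
        ("Gly", ("m57", "m159")),
        ("Val", ("m57", "m85", "m159")),
        ("Leu", ("m57", "m159")),
        ("Ile", ("m57", "m159")),
        ("Pro", ("m57", "m159")),
        ("Ser", ("m57", "m159")),
        ("Thr", ("m57", "m159")),
        ("Phe", ("m57", "m159")),
        ("Asp", ("m57", "m85", "m159")),
        ("Glu", ("m57", "m159")),
        ("Tyr", ("m57", "m159")),
        ("Lys", ("m57", "m159")),
        ("Arg", ("m57",)),
    ]
    for kind in kinds
)

#: Fragments used for intermediate-mass (carbon-shift) analysis: built from
#: several source units, with no exposure to air-derived CO2 carbons.
_DEFAULT_SHIFT_SUBSET: Tuple[str, ...] = (
    "Val_m57",
    "Val_m85",
    "Val_m159",
    "Leu_m57",
    "Leu_m159",
    "Phe_m57",
    "Phe_m159",
    "Tyr_m57",
)


def _is_single_unit(
    frag: FragmentDefinition, amino_acids: Mapping[str, AminoAcidDefinition]
) -> bool:
    aa = amino_acids[frag.amino_acid]
    mapped = [aa.carbon_map[pos - 1] for pos in frag.retained_positions]
    instances = {inst for inst, _ in mapped}
    if len(instances) != 1:
        return False
    precursor = aa.precursors[next(iter(instances))]
    return precursor in ("triose", "acetyl_coa")


def default_panel(
    amino_acids: Mapping[str, AminoAcidDefinition] = DEFAULT_AMINO_ACIDS,
) -> FragmentPanel:
    """The standard 29-fragment fitting panel with its 8-fragment shift subset."""
    frags = tuple(make_fragment(aa, kind) for aa, kind in _DEFAULT_PANEL_SPEC)
    single = tuple(
        f.fragment_id for f in frags if _is_single_unit(f, amino_acids)
    )
    return FragmentPanel(frags, _DEFAULT_SHIFT_SUBSET, single)


# --------------------------------------------------------------------------
# Natural abundance / purity operator
# --------------------------------------------------------------------------


def _element_shift_distribution(formula: Mapping[str, int], max_shift: int) -> np.ndarray:
    """Mass-shift distribution of all non-source atoms (exact convolution)."""
    dist = np.array([1.0])
    for el, count in formula.items():
        atom = NATURAL_ABUNDANCE[el]
        for _ in range(count):
            dist = np.convolve(dist, atom)
            if len(dist) > max_shift + 1:
                # tail mass is kept in a running remainder by renormalizing
                # only at the very end; here we just truncate the carry.
                dist = dist[: max_shift + 1]
    return dist


def natural_abundance_operator(
    fragment: FragmentDefinition, tracer: TracerSpec = TracerSpec()
) -> np.ndarray:
    """Matrix mapping heavy-source-carbon count to the observed MID.

    Column ``j`` is the convolution of: binomial purity over the ``j``
    heavy source carbons (each stays 13C w.p. ``purity``), binomial natural
    abundance over the remaining light source carbons, and the natural
    isotope pattern of all non-source atoms.  Columns are truncated to the
    fragment's channel count and renormalized.
    """
    n = fragment.n_source_carbons
    n_ch = fragment.n_channels
    nonsource = _element_shift_distribution(fragment.nonsource_formula, n_ch - 1)
    op = np.zeros((n_ch, n + 1))
    for j in range(n + 1):
        heavy_part = binom.pmf(np.arange(j + 1), j, tracer.purity)
        light_part = binom.pmf(np.arange(n - j + 1), n - j, tracer.light_nat)
        col = np.convolve(np.convolve(heavy_part, light_part), nonsource)
        col = col[:n_ch]
        op[: len(col), j] = col / col.sum()
    return op


# --------------------------------------------------------------------------
# Forward prediction
# --------------------------------------------------------------------------


class MeasurementModel:
    """Precompiled forward operator: population model -> observed MIDs.

    Precomputes, per fragment, the natural-abundance operator and the
    heavy-count lookup tables of each precursor instance, so repeated
    prediction during fitting stays cheap.
    """

    def __init__(
        self,
        panel: Optional[FragmentPanel] = None,
        tracer: TracerSpec = TracerSpec(),
        amino_acids: Mapping[str, AminoAcidDefinition] = DEFAULT_AMINO_ACIDS,
    ) -> None:
        self.panel = panel if panel is not None else default_panel(amino_acids)
        self.tracer = tracer
        self.amino_acids = dict(amino_acids)
        self._na_ops: Dict[str, np.ndarray] = {}
        self._instances: Dict[str, Tuple[Tuple[str, np.ndarray, int], ...]] = {}
        self._slices: Dict[str, slice] = {}
        offset = 0
        for frag in self.panel.fragments:
            aa = self.amino_acids.get(frag.amino_acid)
            if aa is None:
                raise ConfigurationError(f"no amino acid map for {frag.amino_acid}")
            per_instance: Dict[int, List[int]] = {}
            for pos in frag.retained_positions:
                if not (1 <= pos <= aa.n_carbons):
                    raise ConfigurationError(
                        f"{frag.fragment_id}: retained position {pos} outside "
                        f"{aa.name}"
                    )
                inst, carbon = aa.carbon_map[pos - 1]
                per_instance.setdefault(inst, []).append(carbon)
            tables = []
            for inst, carbons in sorted(per_instance.items()):
                precursor = aa.precursors[inst]
                n_p = PRECURSOR_CARBONS[precursor]
                counts = np.array(
                    [
                        sum(1 for c in carbons if pat[c - 1] == HEAVY)
                        for pat in _pattern_tuples(n_p)
                    ]
                )
                tables.append((precursor, counts, len(carbons)))
            self._instances[frag.fragment_id] = tuple(tables)
            self._na_ops[frag.fragment_id] = natural_abundance_operator(frag, tracer)
            self._slices[frag.fragment_id] = slice(offset, offset + frag.n_channels)
            offset += frag.n_channels
        self.n_channels_total = offset

    # -- source-carbon level ------------------------------------------------

    def state_mass_distributions(self, state: PopulationState) -> Dict[str, np.ndarray]:
        """Per-fragment heavy-source-carbon count distributions for one state."""
        precursors = solve_precursor_arrays(state)
        cache: Dict[Tuple, np.ndarray] = {}
        out = {}
        for frag in self.panel.fragments:
            tables = self._instances[frag.fragment_id]
            key = tuple((p, counts.tobytes()) for p, counts, _ in tables)
            dist = cache.get(key)
            if dist is None:
                dist = np.array([1.0])
                for precursor, counts, m in tables:
                    inst_dist = np.bincount(
                        counts, weights=precursors[precursor], minlength=m + 1
                    )
                    dist = np.convolve(dist, inst_dist)
                cache[key] = dist
            out[frag.fragment_id] = dist
        return out

    # -- observed level -----------------------------------------------------

    def na_operator(self, fragment_id: str) -> np.ndarray:
        return self._na_ops[fragment_id]

    def pure_templates(self, fragment_id: str) -> Tuple[np.ndarray, np.ndarray]:
        """Observed MIDs of the pure-light and pure-heavy species."""
        op = self._na_ops[fragment_id]
        return op[:, 0], op[:, -1]

    def predict_state_concat(self, state: PopulationState) -> np.ndarray:
        out = np.empty(self.n_channels_total)
        mass = self.state_mass_distributions(state)
        for frag in self.panel.fragments:
            fid = frag.fragment_id
            out[self._slices[fid]] = self._na_ops[fid] @ mass[fid]
        return out

    def predict_concat(self, model: PopulationModel) -> np.ndarray:
        out = np.zeros(self.n_channels_total)
        for weight, state in model.states:
            out += weight * self.predict_state_concat(state)
        return out

    def predict(
        self,
        model: PopulationModel,
        sample_id: str = "prediction",
        replicate: Optional[str] = None,
        doublings: Optional[float] = None,
    ) -> SampleMeasurement:
        vec = self.predict_concat(model)
        mids = {fid: vec[self._slices[fid]].copy() for fid in self.panel.fragment_ids}
        return SampleMeasurement(sample_id, mids, replicate, doublings)

    def concat(self, measurement: SampleMeasurement) -> np.ndarray:
        return measurement.concat(self.panel.fragment_ids)


def predict_observed(
    panel: Optional[FragmentPanel],
    model: PopulationModel,
    tracer: TracerSpec = TracerSpec(),
    sample_id: str = "prediction",
) -> SampleMeasurement:
    """Predicted observed MIDs: weighted sum over states of the per-state
    prediction through the natural-abundance operator."""
    return MeasurementModel(panel, tracer).predict(model, sample_id=sample_id)


def theory_correlation(
    meas_a: SampleMeasurement,
    meas_b: SampleMeasurement,
    fragment_ids: Optional[Sequence[str]] = None,
) -> float:
    """Pearson correlation of two measurements over concatenated channels.

    Returns NaN when either concatenated vector has zero variance.
    """
    if fragment_ids is None:
        fragment_ids = sorted(set(meas_a.mids) & set(meas_b.mids))
    a = meas_a.concat(fragment_ids)
    b = meas_b.concat(fragment_ids)
    if len(a) != len(b):
        raise ValueError("channel counts differ between measurements")
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
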
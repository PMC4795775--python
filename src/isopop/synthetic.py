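"""Synthetic labeling-data generation with known ground truth.

Generates every experiment archetype the analysis is designed for — a
co-utilizing culture in a sugar mixture ("mix then grow"), pooled
single-utilizing cultures ("grow then mix"), general two-state mixtures,
and carbon-shift time courses with growth dilution — as forward-model
predictions plus replicate-level measurement noise.  Every sample carries
annotations sufficient to score inference error without reference to the
generator internals.

The default noise is additive truncated-Gaussian per channel with
sd = 0.005 absolute abundance, the scale of replicate standard errors in
careful GC-MS amino-acid measurements; a Dirichlet alternative sits behind
a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .measurement import MeasurementModel, SampleMeasurement, TracerSpec
from .model import BiochemParams, PopulationModel, PopulationState

#: 12C:13C culture ratios of the reference mixing designs, as the fraction
#: of light material: 1:0, 1:9, 1:3, 1:1, 3:1, 9:1, 0:1.
DEFAULT_MIX_RATIOS: Tuple[float, ...] = (1.0, 0.1, 0.25, 0.5, 0.75, 0.9, 0.0)

ARCHETYPES = (
    "mix_then_grow",
    "grow_then_mix",
    "two_state_general",
    "shift_timecourse",
    "coutilization_shift",
)


@dataclass(frozen=True)
class NoiseModel:
    """Replicate-level measurement noise on MID channels."""

    sd: float = 0.005
    renormalize: bool = True
    distribution: str = "gaussian"  # or "dirichlet"

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.distribution not in ("gaussian", "dirichlet"):
            raise ValueError("distribution must be 'gaussian' or 'dirichlet'")

    def apply(self, mids: Dict[str, np.ndarray], rng: np.random.Generator) -> Dict[str, np.ndarray]:
        if self.sd == 0:
            return {k: v.copy() for k, v in mids.items()}
        out = {}
        for fid, mid in mids.items():
            if self.distribution == "gaussian":
                noisy = mid + rng.normal(0.0, self.sd, size=mid.shape)
                noisy = np.clip(noisy, 0.0, None)
            else:
                # Dirichlet with concentration mid/sd: channel sd roughly
                # matches the Gaussian scale for mid-range abundances.
                alpha = np.clip(mid, 1e-6, None) / self.sd
                noisy = rng.dirichlet(alpha)
            if self.renormalize:
                total = noisy.sum()
                noisy = noisy / total if total > 0 else mid.copy()
            out[fid] = noisy
        return out


@dataclass(frozen=True)
class ScenarioSpec:
    """Declarative description of one synthetic experiment archetype."""

    archetype: str
    usages: Sequence[float] = DEFAULT_MIX_RATIOS  # one-state usage series
    ratios: Sequence[float] = DEFAULT_MIX_RATIOS  # grow-then-mix light fractions
    weight_a: float = 0.5
    usage_a: float = 1.0
    usage_b: float = 0.0
    stamps: Sequence[float] = (0.9, 2.0, 4.5, 9.0)
    usage_trajectory: Sequence[float] = (0.4, 0.55, 0.7, 0.84)
    biochem: BiochemParams = field(default_factory=BiochemParams)
    n_replicates: int = 3
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(
                f"unknown archetype {self.archetype!r}; expected one of {ARCHETYPES}"
            )
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def simulate_measurement(
    model: PopulationModel,
    noise: NoiseModel = NoiseModel(),
    measurement_model: Optional[MeasurementModel] = None,
    sample_id: str = "sim",
    replicate: Optional[str] = None,
    doublings: Optional[float] = None,
    seed: int = 0,
) -> SampleMeasurement:
    """Forward prediction plus measurement noise; with sd = 0 the output
    equals the prediction exactly.  Deterministic given ``seed``."""
    mm = measurement_model if measurement_model is not None else MeasurementModel()
    rng = np.random.default_rng(seed)
    pred = mm.predict(model, sample_id=sample_id, replicate=replicate, doublings=doublings)
    return SampleMeasurement(
        sample_id, noise.apply(pred.mids, rng), replicate=replicate, doublings=doublings
    )


def calibrate_noise(replicates: Sequence[SampleMeasurement]) -> NoiseModel:
    """Pooled per-channel sd estimated from replicate measurements."""
    if len(replicates) < 2:
        raise ValueError("noise calibration needs at least 2 replicates")
    variances = []
    for fid in replicates[0].mids:
        stack = np.stack([r.mids[fid] for r in replicates])
        variances.append(stack.var(axis=0, ddof=1))
    pooled = float(np.sqrt(np.mean(np.concatenate(variances))))
    return NoiseModel(sd=pooled)


# --------------------------------------------------------------------------
# Scenario construction
# --------------------------------------------------------------------------

Annotated = Tuple[SampleMeasurement, Dict[str, object]]


def _noisy(mm, model, spec, rng, sample_id, rep, doublings=None) -> SampleMeasurement:
    pred = mm.predict(model, sample_id=sample_id)
    mids = spec.noise.apply(pred.mids, rng)
    return SampleMeasurement(sample_id, mids, replicate=str(rep), doublings=doublings)


def make_scenario(
    spec: ScenarioSpec, measurement_model: Optional[MeasurementModel] = None
) -> List[Annotated]:
    """Generate all samples of one archetype with ground-truth annotations."""
    mm = measurement_model if measurement_model is not None else MeasurementModel()
    rng = np.random.default_rng(spec.seed)
    bio = spec.biochem
    out: List[Annotated] = []

    if spec.archetype == "mix_then_grow":
        for u in spec.usages:
            model = PopulationModel.one_state(PopulationState(u, bio))
            for rep in range(1, spec.n_replicates + 1):
                sid = f"mix_then_grow_u{u:g}"
                out.append(
                    (_noisy(mm, model, spec, rng, sid, rep),
                     {"n_states": 1, "usage12c": u})
                )

    elif spec.archetype == "grow_then_mix":
        light = PopulationState(1.0, bio)
        heavy = PopulationState(0.0, bio)
        for p in spec.ratios:
            if p >= 1.0:
                model, n_states = PopulationModel.one_state(light), 1
            elif p <= 0.0:
                model, n_states = PopulationModel.one_state(heavy), 1
            else:
                model, n_states = PopulationModel.two_state(p, light, heavy), 2
            for rep in range(1, spec.n_replicates + 1):
                sid = f"grow_then_mix_p{p:g}"
                truth = {
                    "n_states": n_states,
                    "p_light": p,
                    "minor_fraction": min(p, 1.0 - p),
                    "usage_a": 1.0,
                    "usage_b": 0.0,
                }
                out.append((_noisy(mm, model, spec, rng, sid, rep), truth))

    elif spec.archetype == "two_state_general":
        model = PopulationModel.two_state(
            spec.weight_a,
            PopulationState(spec.usage_a, bio),
            PopulationState(spec.usage_b, bio),
        )
        (w_a, s_a), (w_b, s_b) = model.states
        for rep in range(1, spec.n_replicates + 1):
            sid = f"two_state_w{w_a:g}_u{s_a.usage12c:g}_{s_b.usage12c:g}"
            truth = {
                "n_states": 2,
                "p_a": w_a,
                "usage_a": s_a.usage12c,
                "usage_b": s_b.usage12c,
                "delta_usage": abs(s_a.usage12c - s_b.usage12c),
                "minor_fraction": min(w_a, w_b),
            }
            out.append((_noisy(mm, model, spec, rng, sid, rep), truth))

    elif spec.archetype == "shift_timecourse":
        old = PopulationState(1.0, bio)   # pre-shift: light sugar
        new = PopulationState(0.0, bio)   # post-shift: heavy sugar
        for rep in range(1, spec.n_replicates + 1):
            model0 = PopulationModel.one_state(old)
            out.append(
                (_noisy(mm, model0, spec, rng, "shift_d0", rep, doublings=0.0),
                 {"old_fraction": 1.0, "doublings": 0.0})
            )
            for d in spec.stamps:
                p_old = 2.0 ** (-d)
                model = PopulationModel.two_state(p_old, old, new)
                sid = f"shift_d{d:g}"
                out.append(
                    (_noisy(mm, model, spec, rng, sid, rep, doublings=float(d)),
                     {"old_fraction": p_old, "doublings": float(d),
                      "new_usage12c": 0.0})
                )

    elif spec.archetype == "coutilization_shift":
        # Pre-growth on light sugar (raffinose analog), then a shift into a
        # heavy-glucose + light-galactose mixture that the population
        # co-utilizes, with the light share drifting along the trajectory.
        if len(spec.usage_trajectory) != len(spec.stamps):
            raise ValueError("usage_trajectory must match stamps")
        old_pred = mm.predict_state_concat(PopulationState(1.0, bio))
        interval_preds = [
            mm.predict_state_concat(PopulationState(u, bio))
            for u in spec.usage_trajectory
        ]
        stamps = [0.0, *map(float, spec.stamps)]
        for rep in range(1, spec.n_replicates + 1):
            out.append(
                (_noisy(mm, PopulationModel.one_state(PopulationState(1.0, bio)),
                        spec, rng, "coshift_d0", rep, doublings=0.0),
                 {"doublings": 0.0, "old_fraction": 1.0})
            )
            for t, d in enumerate(stamps[1:], start=1):
                total = 2.0 ** d
                vec = old_pred.copy()
                for i in range(1, t + 1):
                    vec += (2.0 ** stamps[i] - 2.0 ** stamps[i - 1]) * interval_preds[i - 1]
                vec /= total
                mids = {}
                offset = 0
                for frag in mm.panel.fragments:
                    mids[frag.fragment_id] = vec[offset : offset + frag.n_channels]
                    offset += frag.n_channels
                sid = f"coshift_d{d:g}"
                noisy = SampleMeasurement(
                    sid, spec.noise.apply(mids, rng), replicate=str(rep),
                    doublings=d,
                )
                truth = {
                    "doublings": d,
                    "old_fraction": 1.0 / total,
                    "interval_usage12c": float(spec.usage_trajectory[t - 1]),
                }
                out.append((noisy, truth))

    return out
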
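"""One-state / two-state model fitting and nested-model selection.

A sample's concatenated MID vector is fit with a single-population model
(5 free parameters: usage12c + 4 branch fractions) and a two-subpopulation
mixture (11 free: a weight plus 5 per state).  Goodness of fit is the
f statistic — the square root of the summed squared residuals between
measurement and theory, omitting the single most positive and single most
negative residual.  Because the models are nested, f_two <= f_one always;
the population is called two-state when log10(f_one / f_two) exceeds an
empirical threshold (default 0.2, roughly a 5% false-discovery rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .measurement import MeasurementModel, SampleMeasurement
from .model import BiochemParams, PopulationModel, PopulationState

F_FLOOR = 1e-12  # floor for f_two in the log ratio


class FittingError(RuntimeError):
    """Raised when the optimizer fails on every start."""


@dataclass(frozen=True)
class FitOptions:
    """Fitting and model-selection settings.

    ``threshold`` is the log10 f-ratio cutoff for calling two states.
    ``multistart`` local optimizations are launched from a seeded
    low-discrepancy point set (plus, for two states, the duplicated
    one-state solution).  ``omit_outliers`` applies the single-outlier
    omission rule when evaluating f.
    """

    threshold: float = 0.2
    multistart: int = 20
    seed: int = 0
    tol: float = 1e-9
    omit_outliers: bool = True
    omission_mode: str = "extremes"  # or "fragment_edges"
    weight_bounds: Tuple[float, float] = (0.01, 0.99)
    max_nfev: Optional[int] = 100

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.multistart < 1:
            raise ValueError("multistart must be >= 1")
        if self.omission_mode not in ("extremes", "fragment_edges"):
            raise ValueError("omission_mode must be 'extremes' or 'fragment_edges'")


@dataclass
class FitResult:
    """Best fit of one model family to one sample."""

    model: PopulationModel
    f: float
    residuals: Dict[str, np.ndarray]
    n_free_parameters: int
    start_objectives: List[float]

    @property
    def n_states(self) -> int:
        return self.model.n_states


@dataclass
class ModelSelection:
    """Nested-model comparison for one sample."""

    log10_f_ratio: float
    chosen: int
    one_state: FitResult
    two_state: FitResult

    @property
    def best(self) -> FitResult:
        return self.two_state if self.chosen == 2 else self.one_state


# --------------------------------------------------------------------------
# f statistic
# --------------------------------------------------------------------------


def f_from_residuals(residuals: np.ndarray, omit_outliers: bool = True) -> float:
    """sqrt of the summed squared residuals, optionally omitting the single
    most positive and single most negative residual."""
    r = np.asarray(residuals, dtype=float)
    if omit_outliers:
        if r.size < 3:
            raise ValueError("outlier omission needs at least 3 residuals")
        keep = np.ones(r.size, dtype=bool)
        keep[np.argmax(r)] = False
        keep[np.argmin(r)] = False
        r = r[keep]
    return float(np.sqrt(np.sum(r * r)))


def f_statistic(
    measurement: SampleMeasurement,
    prediction: SampleMeasurement,
    omit_outliers: bool = True,
    fragment_ids: Optional[Sequence[str]] = None,
    omission_mode: str = "extremes",
) -> float:
    """f value between a measurement and a prediction over shared fragments.

    ``omission_mode='extremes'`` drops the single most positive and most
    negative residual of the concatenated vector; ``'fragment_edges'``
    instead drops the first and last mass channel of every fragment.
    """
    if fragment_ids is None:
        fragment_ids = [fid for fid in measurement.mids if fid in prediction.mids]
        missing = set(measurement.mids) - set(prediction.mids)
        if missing:
            raise ValueError(f"prediction lacks fragments: {sorted(missing)}")
    if omit_outliers and omission_mode == "fragment_edges":
        parts = []
        for fid in fragment_ids:
            r = measurement.mids[fid] - prediction.mids[fid]
            parts.append(r[1:-1])
        res = np.concatenate(parts)
        return f_from_residuals(res, omit_outliers=False)
    res = measurement.concat(fragment_ids) - prediction.concat(fragment_ids)
    return f_from_residuals(res, omit_outliers)


# --------------------------------------------------------------------------
# Parameter vector <-> model
# --------------------------------------------------------------------------


def _vector_to_model(x: np.ndarray, n_states: int) -> PopulationModel:
    if n_states == 1:
        return PopulationModel.one_state(PopulationState.from_vector(x))
    w = float(x[0])
    return PopulationModel.two_state(
        w, PopulationState.from_vector(x[1:6]), PopulationState.from_vector(x[6:11])
    )


def _model_to_vector(model: PopulationModel) -> np.ndarray:
    if model.n_states == 1:
        return model.states[0][1].as_vector()
    (w, sa), (_, sb) = model.states
    return np.concatenate([[w], sa.as_vector(), sb.as_vector()])


def _bounds(n_states: int, weight_bounds: Tuple[float, float]):
    if n_states == 1:
        return np.zeros(5), np.ones(5)
    lo = np.zeros(11)
    hi = np.ones(11)
    lo[0], hi[0] = weight_bounds
    return lo, hi


# --------------------------------------------------------------------------
# Fitting
# --------------------------------------------------------------------------


def _start_points(
    n_params: int, n_starts: int, seed: int, lo: np.ndarray, hi: np.ndarray
) -> np.ndarray:
    sampler = qmc.Sobol(d=n_params, scramble=True, seed=seed)
    n_pow = 1 << (n_starts - 1).bit_length()  # Sobol balance needs powers of 2
    pts = sampler.random(n_pow)[:n_starts]
    return lo + pts * (hi - lo)


def fit_model(
    measurement: SampleMeasurement,
    n_states: int,
    options: FitOptions = FitOptions(),
    measurement_model: Optional[MeasurementModel] = None,
    seed_model: Optional[PopulationModel] = None,
) -> FitResult:
    """Bounded multistart least-squares fit of a 1- or 2-state model.

    The optimizer minimizes the plain residual sum of squares; each start's
    solution is then scored with the reported (outlier-omitting) f and the
    best start wins.  For two states, the duplicated one-state solution
    (computed internally when ``seed_model`` is not given) is included
    unoptimized among the candidates, which enforces f_two <= f_one.
    Deterministic given ``options.seed``.
    """
    if n_states not in (1, 2):
        raise ValueError("n_states must be 1 or 2")
    mm = measurement_model if measurement_model is not None else MeasurementModel()
    fragment_ids = mm.panel.fragment_ids
    missing = [fid for fid in fragment_ids if fid not in measurement.mids]
    if missing:
        raise ValueError(f"measurement lacks panel fragments: {missing}")
    y = mm.concat(measurement)

    def residual(x: np.ndarray) -> np.ndarray:
        if n_states == 1:
            pred = mm.predict_state_concat(PopulationState.from_vector(x))
        else:
            w = x[0]
            pred = w * mm.predict_state_concat(
                PopulationState.from_vector(x[1:6])
            ) + (1.0 - w) * mm.predict_state_concat(PopulationState.from_vector(x[6:11]))
        return y - pred

    n_params = 5 if n_states == 1 else 11
    lo, hi = _bounds(n_states, options.weight_bounds)
    starts = list(_start_points(n_params, options.multistart, options.seed, lo, hi))

    candidates: List[Tuple[np.ndarray, float]] = []  # (params, optimizer SSR)
    if n_states == 2:
        if seed_model is None:
            seed_model = fit_model(measurement, 1, options, mm).model
        if seed_model.n_states == 1:
            sv = seed_model.states[0][1].as_vector()
            seed_vec = np.concatenate([[0.5], sv, sv])
        else:
            seed_vec = _model_to_vector(seed_model)
        seed_vec = np.clip(seed_vec, lo, hi)
        starts.append(seed_vec)
        r = residual(seed_vec)
        candidates.append((seed_vec, float(r @ r)))  # unoptimized seed candidate

    failures = []
    for x0 in starts:
        try:
            sol = least_squares(
                residual,
                x0,
                bounds=(lo, hi),
                method="trf",
                xtol=options.tol,
                ftol=options.tol,
                gtol=options.tol,
                max_nfev=options.max_nfev,
            )
            candidates.append((sol.x, float(2.0 * sol.cost)))
        except Exception as exc:  # pragma: no cover - optimizer robustness
            failures.append(repr(exc))
    if not candidates:
        raise FittingError(f"all optimizer starts failed: {failures}")

    if options.omit_outliers and options.omission_mode == "fragment_edges":
        keep = np.ones(mm.n_channels_total, dtype=bool)
        offset = 0
        for frag in mm.panel.fragments:
            keep[offset] = False
            keep[offset + frag.n_channels - 1] = False
            offset += frag.n_channels

        def score(r: np.ndarray) -> float:
            return float(np.sqrt(np.sum(r[keep] ** 2)))

    else:

        def score(r: np.ndarray) -> float:
            return f_from_residuals(r, options.omit_outliers)

    scored = []
    for x, ssr in candidates:
        f = score(residual(x))
        scored.append((f, ssr, x))
    scored.sort(key=lambda t: t[0])
    best_f, _, best_x = scored[0]

    model = _vector_to_model(best_x, n_states)
    res_vec = residual(best_x)
    residuals = {}
    offset = 0
    for frag in mm.panel.fragments:
        residuals[frag.fragment_id] = res_vec[offset : offset + frag.n_channels]
        offset += frag.n_channels
    return FitResult(
        model=model,
        f=best_f,
        residuals=residuals,
        n_free_parameters=n_params,
        start_objectives=[s[1] for s in scored],
    )


def classify(
    one_state: FitResult,
    two_state: FitResult,
    options: FitOptions = FitOptions(),
) -> ModelSelection:
    """Call one vs two states from the log10 f-ratio (strict > threshold)."""
    ratio = float(np.log10(one_state.f / max(two_state.f, F_FLOOR))) if one_state.f > 0 else 0.0
    chosen = 2 if ratio > options.threshold else 1
    return ModelSelection(ratio, chosen, one_state, two_state)


def fit_both(
    measurement: SampleMeasurement,
    options: FitOptions = FitOptions(),
    measurement_model: Optional[MeasurementModel] = None,
) -> ModelSelection:
    """Fit one- and two-state models (two-state seeded from one-state) and
    classify."""
    mm = measurement_model if measurement_model is not None else MeasurementModel()
    one = fit_model(measurement, 1, options, mm)
    two = fit_model(measurement, 2, options, mm, seed_model=one.model)
    return classify(one, two, options)


# --------------------------------------------------------------------------
# Reporting
# --------------------------------------------------------------------------

REPORT_COLUMNS = [
    "sample",
    "replicate",
    "f_one",
    "f_two",
    "log10_f_ratio",
    "chosen_states",
    "p_a",
    "usage_a",
    "usage_b",
    "ap_a",
    "rev_a",
    "ppp_a",
    "co2_a",
    "ap_b",
    "rev_b",
    "ppp_b",
    "co2_b",
    "error",
]


def selection_row(sample: SampleMeasurement, sel: ModelSelection) -> Dict[str, object]:
    (w_a, s_a) = sel.two_state.model.states[0]
    (w_b, s_b) = sel.two_state.model.states[1]
    one = sel.one_state.model.states[0][1]
    row = {
        "sample": sample.sample_id,
        "replicate": sample.replicate,
        "f_one": sel.one_state.f,
        "f_two": sel.two_state.f,
        "log10_f_ratio": sel.log10_f_ratio,
        "chosen_states": sel.chosen,
        "error": "",
    }
    if sel.chosen == 2:
        row.update(
            p_a=w_a,
            usage_a=s_a.usage12c,
            usage_b=s_b.usage12c,
            ap_a=s_a.biochem.ap,
            rev_a=s_a.biochem.rev,
            ppp_a=s_a.biochem.ppp,
            co2_a=s_a.biochem.co2,
            ap_b=s_b.biochem.ap,
            rev_b=s_b.biochem.rev,
            ppp_b=s_b.biochem.ppp,
            co2_b=s_b.biochem.co2,
        )
    else:
        row.update(
            p_a=1.0,
            usage_a=one.usage12c,
            usage_b=np.nan,
            ap_a=one.biochem.ap,
            rev_a=one.biochem.rev,
            ppp_a=one.biochem.ppp,
            co2_a=one.biochem.co2,
            ap_b=np.nan,
            rev_b=np.nan,
            ppp_b=np.nan,
            co2_b=np.nan,
        )
    return row


def infer_report(
    measurements: Iterable[SampleMeasurement],
    options: FitOptions = FitOptions(),
    measurement_model: Optional[MeasurementModel] = None,
) -> pd.DataFrame:
    """Fit every sample x replicate and tabulate fitted characteristics.

    Per-sample failures are recorded in the ``error`` column rather than
    raised.  Deterministic given ``options.seed``.
    """
    mm = measurement_model if measurement_model is not None else MeasurementModel()
    rows = []
    for sample in measurements:
        try:
            sel = fit_both(sample, options, mm)
            rows.append(selection_row(sample, sel))
        except Exception as exc:
            rows.append(
                {
                    "sample": sample.sample_id,
                    "replicate": sample.replicate,
                    "error": f"{type(exc).__name__}: {exc}",
                }
            )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
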
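"""Delimited-text formats for MID tables, results tables, and run config.

MID tables travel as long-format CSV/TSV with columns
``sample_id, fragment_id, replicate, doublings, mass_shift, abundance``
(one channel per row); a converter to/from the wide ``m0..mK`` layout is
provided.  All writers emit a ``# isopop <version>`` header comment.
Fragment distributions whose channel sum deviates more than 5% from 1 are
rejected row-group-wise with a diagnostic; valid ones are renormalized on
read.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fitting import FitOptions
from .measurement import (
    FragmentDefinition,
    FragmentPanel,
    SampleMeasurement,
    TracerSpec,
    default_panel,
    make_fragment,
)
from .synthetic import NoiseModel

SUM_TOLERANCE = 0.05  # accepted deviation of a fragment's channel sum from 1

MID_COLUMNS = ["sample_id", "fragment_id", "replicate", "doublings", "mass_shift", "abundance"]


class DataError(ValueError):
    """Raised when an input table is unusable (no valid rows)."""


def _header(extra: str = "") -> str:
    return f"# isopop {__version__}{(' ' + extra) if extra else ''}\n"


# --------------------------------------------------------------------------
# MID tables
# --------------------------------------------------------------------------


def write_mid_table(
    measurements: Sequence[SampleMeasurement],
    path: Union[str, Path],
    sep: str = ",",
) -> None:
    rows = []
    for meas in measurements:
        for fid, mid in meas.mids.items():
            for k, abundance in enumerate(mid):
                rows.append(
                    {
                        "sample_id": meas.sample_id,
                        "fragment_id": fid,
                        "replicate": meas.replicate if meas.replicate is not None else "",
                        "doublings": meas.doublings if meas.doublings is not None else "",
                        "mass_shift": k,
                        "abundance": repr(float(abundance)),
                    }
                )
    df = pd.DataFrame(rows, columns=MID_COLUMNS)
    with open(path, "w") as fh:
        fh.write(_header("mid-table"))
        df.to_csv(fh, sep=sep, index=False)


def read_mid_table(
    path: Union[str, Path], sep: str = ","
) -> Tuple[List[SampleMeasurement], List[str]]:
    """Read and validate a long-format MID table.

    Returns (measurements, diagnostics).  Fragment groups with non-numeric
    abundances or channel sums off by more than 5% are dropped with a
    per-group diagnostic; the read fails only if nothing valid remains.
    """
    try:
        df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    except Exception as exc:
        raise DataError(f"cannot read MID table {path}: {exc}") from exc
    missing = [c for c in MID_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"MID table {path} lacks columns: {missing}")

    diagnostics: List[str] = []
    measurements: Dict[Tuple[str, str], SampleMeasurement] = {}
    for (sample_id, replicate), sample_group in df.groupby(
        ["sample_id", "replicate"], dropna=False, sort=False
    ):
        rep = None if (pd.isna(replicate) or replicate == "") else str(replicate)
        doublings = None
        dval = sample_group["doublings"].iloc[0]
        if not (pd.isna(dval) or str(dval) == ""):
            try:
                doublings = float(dval)
            except ValueError:
                diagnostics.append(f"{sample_id}/{rep}: bad doublings {dval!r}")
        mids = {}
        for fid, frag_group in sample_group.groupby("fragment_id", sort=False):
            try:
                shifts = frag_group["mass_shift"].astype(int).to_numpy()
                abund = frag_group["abundance"].astype(float).to_numpy()
            except (TypeError, ValueError):
                diagnostics.append(f"{sample_id}/{rep}/{fid}: non-numeric abundance")
                continue
            order = np.argsort(shifts)
            shifts, abund = shifts[order], abund[order]
            if not np.array_equal(shifts, np.arange(len(shifts))):
                diagnostics.append(f"{sample_id}/{rep}/{fid}: non-contiguous mass shifts")
                continue
            if np.any(abund < 0):
                diagnostics.append(f"{sample_id}/{rep}/{fid}: negative abundance")
                continue
            total = abund.sum()
            if abs(total - 1.0) > SUM_TOLERANCE:
                diagnostics.append(
                    f"{sample_id}/{rep}/{fid}: channel sum {total:.4f} deviates "
                    f">{SUM_TOLERANCE:.0%} from 1; rejected"
                )
                continue
            mids[str(fid)] = abund / total
        if mids:
            measurements[(str(sample_id), rep)] = SampleMeasurement(
                str(sample_id), mids, replicate=rep, doublings=doublings
            )
        else:
            diagnostics.append(f"{sample_id}/{rep}: no valid fragments")
    if not measurements:
        raise DataError(f"MID table {path}: no valid measurements ({diagnostics})")
    return list(measurements.values()), diagnostics


def mid_long_to_wide(df: pd.DataFrame) -> pd.DataFrame:
    """Convert a long MID frame to the wide ``m0..mK`` layout."""
    wide = df.pivot_table(
        index=["sample_id", "fragment_id", "replicate", "doublings"],
        columns="mass_shift",
        values="abundance",
        aggfunc="first",
        dropna=False,
    )
    wide.columns = [f"m{int(c)}" for c in wide.columns]
    return wide.reset_index()


def mid_wide_to_long(df: pd.DataFrame) -> pd.DataFrame:
    """Convert a wide ``m0..mK`` MID frame to the long layout."""
    m_cols = [c for c in df.columns if c.startswith("m") and c[1:].isdigit()]
    id_cols = [c for c in df.columns if c not in m_cols]
    long = df.melt(id_vars=id_cols, value_vars=m_cols, var_name="mass_shift", value_name="abundance")
    long["mass_shift"] = long["mass_shift"].str[1:].astype(int)
    long = long.dropna(subset=["abundance"])
    return long.sort_values([*id_cols, "mass_shift"]).reset_index(drop=True)


# --------------------------------------------------------------------------
# Results tables
# --------------------------------------------------------------------------


def write_results(results: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a fit-results table (one-state rows leave state-B columns empty)."""
    if results.empty:
        raise ValueError("refusing to write an empty results table")
    with open(path, "w") as fh:
        fh.write(_header("results"))
        results.to_csv(fh, index=False, float_format="%.6g")


def read_results(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Declarative run settings loadable from a YAML config file."""

    panel: FragmentPanel = field(default_factory=default_panel)
    tracer: TracerSpec = field(default_factory=TracerSpec)
    fit_options: FitOptions = field(default_factory=FitOptions)
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    output_dir: Path = Path(".")


def panel_from_config(entries: Sequence[dict]) -> FragmentPanel:
    """Build a panel from config entries.

    Each entry is either ``{amino_acid, kind}`` (standard TBDMS fragment)
    or a full fragment dict with ``fragment_id, amino_acid,
    retained_positions, nonsource_formula, n_channels``.
    """
    frags = []
    shift, single = [], []
    for entry in entries:
        if "retained_positions" in entry:
            frag = FragmentDefinition(
                fragment_id=entry["fragment_id"],
                amino_acid=entry["amino_acid"],
                retained_positions=tuple(entry["retained_positions"]),
                nonsource_formula=dict(entry["nonsource_formula"]),
                n_channels=int(entry["n_channels"]),
            )
        else:
            frag = make_fragment(entry["amino_acid"], entry["kind"])
        frags.append(frag)
        if entry.get("shift_subset"):
            shift.append(frag.fragment_id)
        if entry.get("single_unit"):
            single.append(frag.fragment_id)
    return FragmentPanel(tuple(frags), tuple(shift), tuple(single))


def load_config(path: Union[str, Path]) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig()
    if "panel" in raw:
        cfg.panel = panel_from_config(raw["panel"])
    if "tracer" in raw:
        cfg.tracer = TracerSpec(**raw["tracer"])
    if "fit_options" in raw:
        fo = raw["fit_options"]
        if "weight_bounds" in fo:
            fo["weight_bounds"] = tuple(fo["weight_bounds"])
        cfg.fit_options = FitOptions(**fo)
    if "noise" in raw:
        cfg.noise = NoiseModel(**raw["noise"])
    cfg.seed = int(raw.get("seed", 0))
    cfg.output_dir = Path(raw.get("output_dir", "."))
    return cfg
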
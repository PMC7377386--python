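"""Results assembly: stratified tables, figure-ready series, run manifests.

The package is headless: it emits delimited tables and long-format series
suitable for external plotting, each referencing the run manifest that
produced it. Display rounding mirrors the field's convention for these
quantities: probabilities to 6 decimal places, NNT to the nearest integer.
"""
from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .decision_model import RiskEstimate
from .errors import ConfigurationError
from .tableio import read_table, write_table

try:  # package version for provenance
    from importlib.metadata import version as _version

    _PKG_VERSION = _version("sepsis-nnt")
except Exception:  # pragma: no cover
    _PKG_VERSION = "unknown"

PROB_DECIMALS = 6

RESULT_COLUMNS = [
    "gender", "age_band", "p_infection", "p_sepsis", "p_infection_given_sepsis",
    "p_ab_given_infection", "p_sepsis_no_ab", "p_sepsis_ab",
    "p_sepsis_no_ab_lo", "p_sepsis_no_ab_hi", "p_sepsis_ab_lo", "p_sepsis_ab_hi",
    "nnt", "nnt_lo", "nnt_hi", "missing",
]


@dataclass
class RunManifest:
    """Provenance for one pipeline run; every artefact references its digest."""

    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    package_version: str = _PKG_VERSION
    input_digests: Dict[str, str] = field(default_factory=dict)
    created: str = field(default_factory=lambda: dt.datetime.now().isoformat(timespec="seconds"))

    @property
    def digest(self) -> str:
        payload = json.dumps(
            {
                "config": self.config,
                "seeds": self.seeds,
                "package_version": self.package_version,
                "input_digests": self.input_digests,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({**dataclasses.asdict(self), "digest": self.digest}, fh, indent=2)

    @staticmethod
    def digest_of_file(path) -> str:
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(65536), b""):
                h.update(chunk)
        return h.hexdigest()[:12]


def _round_nnt(v: float):
    if v is None or not np.isfinite(v):
        return np.inf if v == np.inf else v
    return int(round(v))


def render_results_table(
    estimates: Mapping[tuple, "RiskEstimate"],
    prob_sets: Optional[Mapping[tuple, object]] = None,
    expected_strata: Optional[Sequence[tuple]] = None,
    path=None,
    manifest: Optional[RunManifest] = None,
) -> pd.DataFrame:
    """Stratified results table, one row per (gender, age band).

    Medians of the Monte Carlo draws are shown for the derived
    probabilities and the NNT (with its 95% uncertainty interval); input
    probabilities come from ``prob_sets`` when given. Expected strata with
    no estimate yield a blank, flagged row. An empty estimate set renders a
    header-only table.
    """
    keys = list(expected_strata) if expected_strata is not None else sorted(estimates)
    rows = []
    for key in keys:
        est = estimates.get(key)
        base = {"gender": key[0], "age_band": key[1]}
        if est is None or isinstance(est, Exception):
            rows.append({**base, "missing": True})
            continue
        ps = prob_sets.get(key) if prob_sets else None
        row = dict(base, missing=False)
        if ps is not None:
            for c in ("p_infection", "p_sepsis", "p_infection_given_sepsis", "p_ab_given_infection"):
                row[c] = round(getattr(ps, c), PROB_DECIMALS)
        use_median = bool(est.median)
        for q, col in (("p_sepsis_no_ab", "p_sepsis_no_ab"), ("p_sepsis_ab", "p_sepsis_ab")):
            central = est.median[q] if use_median else getattr(est, q)
            row[col] = round(central, PROB_DECIMALS)
            if use_median:
                row[f"{col}_lo"] = round(est.ui_low[q], PROB_DECIMALS)
                row[f"{col}_hi"] = round(est.ui_high[q], PROB_DECIMALS)
        row["nnt"] = _round_nnt(est.median["nnt"] if use_median else est.nnt.value)
        if use_median:
            row["nnt_lo"] = _round_nnt(est.ui_low["nnt"])
            row["nnt_hi"] = _round_nnt(est.ui_high["nnt"])
        rows.append(row)
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if path is not None:
        write_table(out, path, manifest.digest if manifest else None)
    return out


def parse_results_table(path) -> pd.DataFrame:
    return read_table(path)


def figure_series(
    estimates: Mapping[tuple, "RiskEstimate"],
    axis: str,
    band_order: Optional[Sequence[str]] = None,
    quantities: Sequence[str] = ("p_sepsis_no_ab", "p_sepsis_ab", "nnt"),
) -> pd.DataFrame:
    """Long-format series (central + UI per stratum) for external plotting.

    ``axis`` is the stratification dimension to put on the x axis: 'age',
    'frailty' or 'infection_type'. Stratum keys are tuples
    ``(gender, age_band[, extra])`` where ``extra`` is the frailty category
    or infection type when present. Probability panels are flagged for a
    log scale.
    """
    pos = {"age": 1, "frailty": 2, "infection_type": 2}.get(axis)
    if pos is None:
        raise ConfigurationError(f"axis: must be age, frailty or infection_type, got {axis!r}")
    rows = []
    for key, est in sorted(estimates.items()):
        if isinstance(est, Exception):
            continue
        if pos >= len(key):
            raise ConfigurationError(
                f"axis {axis!r} absent from stratification key {key!r}"
            )
        for q in quantities:
            rows.append(
                {
                    "gender": key[0],
                    "age_band": key[1],
                    "axis_value": key[pos],
                    "quantity": q,
                    "central": est.median.get(q, np.nan),
                    "ui_low": est.ui_low.get(q, np.nan),
                    "ui_high": est.ui_high.get(q, np.nan),
                    "log_scale": q != "nnt",
                }
            )
    out = pd.DataFrame(rows)
    if band_order is not None and len(out):
        out["age_band"] = pd.Categorical(out["age_band"], categories=list(band_order), ordered=True)
        out = out.sort_values(["quantity", "gender", "age_band"]).reset_index(drop=True)
    return out
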
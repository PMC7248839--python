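"""Reading rate tables, writing fit reports and run configuration."""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import laws
from .errors import ConfigError, InputError
from .fitting import FitResult, RateDataset, TransitivityCurve
from .units import UnitSystem, canonical_energy_unit

logger = logging.getLogger(__name__)

__all__ = ["read_rate_table", "write_report", "write_curve", "RunConfig"]

_TEMP_COLS = {"t", "t_k", "temp", "temperature", "temperature_k"}
_BETA_COLS = {"beta", "coldness"}
_RATE_COLS = {"k", "rate", "rate_constant", "k_s"}


def read_rate_table(path, units: UnitSystem | None = None) -> RateDataset:
    """Read a delimited (T_K or beta, k) table into a :class:`RateDataset`.

    The file must have a header naming a temperature column (``T_K``,
    ``temperature``, ...) or a coldness column (``beta``) plus a rate column
    (``k``, ``rate``); '#' lines are comments.  Rows with non-positive or
    non-finite rates are rejected with their row numbers logged; duplicate
    beta values are averaged in ln k with a warning.
    """
    units = units or UnitSystem()
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#",
                         skip_blank_lines=True)
    except Exception as exc:
        raise InputError(f"could not parse {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise InputError("expected at least two columns (T_K or beta, k)")
    colmap = {str(c).strip().lower(): c for c in df.columns}
    temp_col = next((colmap[c] for c in colmap if c in _TEMP_COLS), None)
    beta_col = next((colmap[c] for c in colmap if c in _BETA_COLS), None)
    rate_col = next((colmap[c] for c in colmap if c in _RATE_COLS), None)
    if rate_col is None or (temp_col is None and beta_col is None):
        raise InputError(
            "header must name a rate column (k/rate) and a temperature "
            "(T_K/temperature) or coldness (beta) column; got "
            f"{list(df.columns)}"
        )
    x = pd.to_numeric(df[beta_col if beta_col is not None else temp_col],
                      errors="coerce").to_numpy(dtype=float)
    k = pd.to_numeric(df[rate_col], errors="coerce").to_numpy(dtype=float)

    bad = ~np.isfinite(x) | ~np.isfinite(k) | (k <= 0)
    if np.any(bad):
        rows = (np.flatnonzero(bad) + 2).tolist()  # 1-based incl. header
        logger.warning("rejected %d rows with missing or non-positive rates "
                       "(file rows %s)", int(bad.sum()), rows)
    x, k = x[~bad], k[~bad]
    if x.size < 3:
        raise InputError("fewer than 3 valid rows after validation")

    beta = x if beta_col is not None else np.asarray(units.beta(x))
    order = np.argsort(beta)
    beta, lnk = beta[order], np.log(k[order])
    uniq, inverse, counts = np.unique(beta, return_inverse=True,
                                      return_counts=True)
    if np.any(counts > 1):
        logger.warning("averaged ln k over %d duplicated beta values",
                       int(np.sum(counts > 1)))
        sums = np.zeros(uniq.size)
        np.add.at(sums, inverse, lnk)
        lnk = sums / counts
        beta = uniq
    return RateDataset(beta=beta, k=np.exp(lnk), units=units)


def report_dict(result: FitResult, units: UnitSystem | None = None, *,
                timestamp: bool = True) -> dict:
    """Deterministically ordered report mapping for a fit result.

    Super-Arrhenius deformed fits (d > 0, eps_act > 0) gain a
    ``thermal_limits`` block with eps_dagger, T_dagger and beta_dagger.
    """
    units = units or UnitSystem()
    report = {
        "law": result.law,
        "params": result.params,
        "stderr": result.stderr,
        "rss": result.rss,
        "n_obs": result.n_obs,
        "n_params": result.n_params,
        "aicc": result.aicc,
    }
    if result.zeta is not None:
        report["zeta"] = result.zeta
    d = result.params.get("d")
    eps = result.params.get("eps_act")
    if result.law == "am" and d is not None and eps is not None \
            and d > 0 and eps > 0:
        lims = laws.thermal_limits(
            laws.AMParams(A=result.params.get("A", 1.0), eps_act=eps, d=d),
            units,
        )
        report["thermal_limits"] = {
            "eps_dagger": lims.eps_dagger,
            "T_dagger": lims.T_dagger,
            "beta_dagger": lims.beta_dagger,
        }
    if result.breakpoint is not None:
        report["breakpoint"] = result.breakpoint
    if result.profile is not None:
        report["zeta_profile"] = result.profile
    report["config"] = result.config
    if timestamp:
        report["timestamp"] = _dt.datetime.now(_dt.timezone.utc).isoformat()
    return report


def write_report(result: FitResult, path=None,
                 units: UnitSystem | None = None, *,
                 timestamp: bool = True) -> dict:
    """Write (or return) the JSON fit report; field order is deterministic."""
    report = report_dict(result, units, timestamp=timestamp)
    if path is not None:
        try:
            with open(path, "w") as fh:
                json.dump(report, fh, indent=2, allow_nan=True)
                fh.write("\n")
        except OSError as exc:
            raise InputError(f"cannot write report to {path}: {exc}") from exc
    return report


def write_curve(curve: TransitivityCurve, path) -> None:
    """Export a transitivity curve as CSV (beta, T_K, Ea, gamma, valid)."""
    curve.to_frame().to_csv(path, index=False)


_DERIVATIVE_METHODS = ("spline", "central", "window")
_LAWS = ("arrhenius", "am", "vft", "fg", "zeta")


@dataclass
class RunConfig:
    """Validated run configuration; flags > config file > defaults."""

    input: str | None = None
    units: str = "kJ/mol"
    law: str = "am"
    zeta: float | None = None
    method: str = "spline"
    window: int | None = None
    seed: int = 0
    output: str | None = None
    verbosity: str = "WARNING"
    optimizer: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.units = canonical_energy_unit(self.units)
        if self.law not in _LAWS:
            raise ConfigError(f"law must be one of {_LAWS}")
        if self.method not in _DERIVATIVE_METHODS:
            raise ConfigError(f"method must be one of {_DERIVATIVE_METHODS}")
        if self.zeta is not None and self.zeta < 0:
            raise ConfigError("zeta must be >= 0")
        if int(self.seed) != self.seed:
            raise ConfigError("seed must be an integer")
        self.seed = int(self.seed)
        if self.verbosity not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ConfigError("verbosity must be a standard logging level")
        if not isinstance(self.optimizer, dict):
            raise ConfigError("optimizer settings must be a mapping")

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        try:
            with open(path) as fh:
                data = json.load(fh)
        except (OSError, json.JSONDecodeError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a JSON object")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def merged(self, **overrides) -> "RunConfig":
        data = asdict(self)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return RunConfig(**data)

    def unit_system(self) -> UnitSystem:
        return UnitSystem(energy_unit=self.units)

    def to_dict(self) -> dict:
        return asdict(self)
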
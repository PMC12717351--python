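"""Parameter files, random fixtures and result serialization.

Parameter files are flat key-value text (``key = value`` or
``key: value``, ``#`` comments), with keys named exactly after the
fields of :class:`~soceeo.params.ToyModelParams`.  A packaged baseline
file ships with the library; random parameter fixtures for property
testing are sampled log-uniformly around it.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .params import ParameterError, ToyModelParams

log = logging.getLogger("soceeo")

_REQUIRED = (
    "alpha", "beta", "eps_e", "d_e", "input_rate", "k_u", "ell_s", "v_u", "y",
)
_OPTIONAL = ("c0", "d_fixed", "m_e_fixed")


def parse_params_text(text: str, source: str = "<string>") -> ToyModelParams:
    """Parse flat key-value parameter text; collects all problems at once."""
    values: dict[str, float] = {}
    problems: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        for sep in ("=", ":"):
            if sep in line:
                key, _, val = line.partition(sep)
                break
        else:
            problems.append(f"{source}:{lineno}: not a key-value line: {raw!r}")
            continue
        key = key.strip()
        if key not in _REQUIRED + _OPTIONAL:
            problems.append(f"{source}:{lineno}: unknown key {key!r}")
            continue
        try:
            values[key] = float(val.strip())
        except ValueError:
            problems.append(f"{source}:{lineno}: {key}: not a number: {val.strip()!r}")
    missing = [k for k in _REQUIRED if k not in values]
    problems.extend(f"{source}: missing key {k!r}" for k in missing)
    if problems:
        raise ParameterError(problems)
    try:
        return ToyModelParams(**values)
    except ParameterError as err:
        raise ParameterError([f"{source}: {p}" for p in err.problems]) from None


def load_params(path: str | Path) -> ToyModelParams:
    """Load and validate a parameter file."""
    path = Path(path)
    return parse_params_text(path.read_text(), source=str(path))


def save_params(params: ToyModelParams, path: str | Path) -> None:
    path = Path(path)
    lines = [f"{k} = {v!r}" for k, v in params.as_dict().items() if v is not None]
    path.write_text("\n".join(lines) + "\n")


def baseline_params() -> ToyModelParams:
    """The packaged baseline parameter set (synthetic; see file header)."""
    ref = importlib.resources.files("soceeo.data") / "baseline_synthetic.params"
    return parse_params_text(ref.read_text(), source="baseline_synthetic.params")


@dataclass(frozen=True)
class FixtureConfig:
    """Sampling configuration for random parameter fixtures.

    ``ranges`` maps field names to (lo, hi) bounds for log-uniform
    sampling; defaults are one decade around the packaged baseline,
    capped so fractions stay in their admissible intervals.  Sets
    violating the positive-optimum condition ``y*v_u > eps_e*d_e`` are
    rejected and resampled.
    """

    seed: int = 0
    n_sets: int = 100
    ranges: dict = field(default_factory=dict)
    max_attempts_factor: int = 100

    def resolved_ranges(self) -> dict[str, tuple[float, float]]:
        base = baseline_params().as_dict()
        caps = {"alpha": 1.0, "beta": 0.5, "y": 1.0}
        out = {}
        for key in _REQUIRED + ("c0",):
            if key in self.ranges:
                lo, hi = self.ranges[key]
            else:
                v = base[key]
                lo, hi = v / np.sqrt(10.0), v * np.sqrt(10.0)
            if key == "eps_e":
                lo = max(lo, 1.0 + 1e-9)
            hi = min(hi, caps.get(key, np.inf))
            lo = min(lo, hi)
            if lo <= 0 or hi <= 0:
                raise ValueError(f"ranges for {key} must be positive")
            out[key] = (float(lo), float(hi))
        return out


def generate_fixtures(config: FixtureConfig) -> list[ToyModelParams]:
    """Draw ``n_sets`` feasible random parameter sets, reproducibly.

    Raises when the rejection rate exceeds 99% (ranges incompatible
    with ``y*v_u > eps_e*d_e``).
    """
    rng = np.random.default_rng(config.seed)
    ranges = config.resolved_ranges()
    out: list[ToyModelParams] = []
    attempts = 0
    max_attempts = config.max_attempts_factor * config.n_sets
    while len(out) < config.n_sets:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"rejection rate too high ({len(out)}/{attempts} accepted); "
                "widen y/v_u or narrow eps_e/d_e ranges"
            )
        attempts += 1
        draw = {
            k: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            for k, (lo, hi) in ranges.items()
        }
        if not draw["y"] * draw["v_u"] > draw["eps_e"] * draw["d_e"]:
            continue
        out.append(ToyModelParams(**draw))
    log.debug("fixtures: %d accepted out of %d draws", len(out), attempts)
    return out


def write_results(result, path: str | Path, format: str = "csv") -> Path:
    """Serialize a result object (sweep, trajectory, dataclass, dict, frame).

    CSV output is plain and round-trippable at full precision; JSON
    output embeds parameter provenance where the object carries it.
    """
    path = Path(path)
    frame = getattr(result, "frame", None)
    if format == "csv":
        if frame is None:
            if isinstance(result, pd.DataFrame):
                frame = result
            else:
                raise TypeError(f"cannot write {type(result).__name__} as CSV")
        frame.to_csv(path, index=False, float_format="%.17g")
    elif format == "json":
        payload = _jsonable(result)
        if isinstance(payload, dict):
            from . import __version__

            payload.setdefault("_software_version", f"soceeo {__version__}")
        path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    else:
        raise ValueError("format must be 'csv' or 'json'")
    return path


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj
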
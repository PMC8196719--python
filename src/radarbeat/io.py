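"""File formats and fixture generation.

Interchange format is plain CSV with a one-line header comment declaring
the sample rate, unit and column schema::

    # radarbeat-csv fs=100.0 unit=m schema=t,x
    t,x
    0.00,0.000123
    ...

Two schemas exist: ``t,x`` for a displacement (or any scalar) series and
``t,i,q`` for radar baseband.  Reference beat times are plain text, one
time in seconds per line.  ``make_fixture`` materializes named simulation
presets (scene + ground-truth beats + config snapshot) deterministically
per seed.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .signals import IQBaseband, SampledSignal
from .simulate import (
    ChestScene,
    HeartModelParams,
    RadarParams,
    RespModelParams,
    ScenarioParams,
    simulate_scene,
)

__all__ = [
    "read_signal_csv",
    "write_signal_csv",
    "read_beat_times",
    "write_beat_times",
    "FIXTURE_PRESETS",
    "make_fixture",
]

_MAGIC = "# radarbeat-csv"
#: Relative timestamp jitter tolerated before sampling is declared non-uniform.
_JITTER_REL = 1e-6


def write_signal_csv(path: str | Path, signal: SampledSignal | IQBaseband) -> None:
    """Write a displacement series (``t,x``) or baseband pair (``t,i,q``)."""
    path = Path(path)
    t = signal.times
    if isinstance(signal, IQBaseband):
        header = f"{_MAGIC} fs={signal.fs!r} unit=V schema=t,i,q\n"
        frame = pd.DataFrame({"t": t, "i": signal.i_values, "q": signal.q_values})
    else:
        unit = signal.unit or "a.u."
        header = f"{_MAGIC} fs={signal.fs!r} unit={unit} schema=t,x\n"
        frame = pd.DataFrame({"t": t, "x": signal.values})
    with path.open("w") as fh:
        fh.write(header)
        frame.to_csv(fh, index=False, float_format="%.10g")


def _parse_header(line: str, path: Path) -> dict:
    if not line.startswith(_MAGIC):
        raise ValueError(
            f"{path}: missing '{_MAGIC}' header line declaring fs, unit and schema"
        )
    fields = {}
    for token in line[len(_MAGIC) :].split():
        if "=" not in token:
            raise ValueError(f"{path}: malformed header token {token!r}")
        key, value = token.split("=", 1)
        fields[key] = value
    for required in ("fs", "schema"):
        if required not in fields:
            raise ValueError(f"{path}: header lacks required field '{required}'")
    return fields


def _check_uniform(t: np.ndarray, fs: float, path: Path) -> None:
    expected = t[0] + np.arange(t.size) / fs
    bad = np.flatnonzero(np.abs(t - expected) > _JITTER_REL / fs)
    if bad.size:
        row = int(bad[0]) + 3  # 1-based, after header + column line
        raise ValueError(
            f"{path}: non-uniform sampling at row {row}: t={t[bad[0]]!r}, "
            f"expected {expected[bad[0]]!r} for fs={fs}"
        )


def read_signal_csv(path: str | Path) -> SampledSignal | IQBaseband:
    """Read a radarbeat CSV, dispatching on the declared schema.

    Validates the header, finiteness and sampling uniformity (timestamp
    jitter beyond 1e-6 of a sample period is an error naming the first
    offending row).
    """
    path = Path(path)
    with path.open() as fh:
        header = _parse_header(fh.readline(), path)
        frame = pd.read_csv(fh)
    fs = float(header["fs"])
    schema = header["schema"]
    if list(frame.columns) != schema.split(","):
        raise ValueError(
            f"{path}: columns {list(frame.columns)} do not match declared schema {schema!r}"
        )
    if frame.isna().any().any():
        col = frame.columns[frame.isna().any()][0]
        raise ValueError(f"{path}: NaN value in column {col!r}")
    t = frame["t"].to_numpy(dtype=float)
    if t.size == 0:
        raise ValueError(f"{path}: no samples")
    _check_uniform(t, fs, path)
    if schema == "t,x":
        return SampledSignal(
            frame["x"].to_numpy(dtype=float), fs=fs, unit=header.get("unit", ""), t0=float(t[0])
        )
    if schema == "t,i,q":
        return IQBaseband(
            frame["i"].to_numpy(dtype=float),
            frame["q"].to_numpy(dtype=float),
            fs=fs,
            t0=float(t[0]),
        )
    raise ValueError(f"{path}: unknown schema {schema!r}")


def write_beat_times(path: str | Path, times: np.ndarray) -> None:
    Path(path).write_text("".join(f"{t:.6f}\n" for t in np.asarray(times, dtype=float)))


def read_beat_times(path: str | Path) -> np.ndarray:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    values = np.array([float(ln) for ln in lines if ln and not ln.startswith("#")])
    if values.size and np.any(np.diff(values) <= 0):
        raise ValueError(f"{path}: beat times must be strictly increasing")
    return values


_TABLE_RESP = RespModelParams(Kb=10e-3, T=2.5, Ti=1.25, Te=1.25, tau=0.8)

#: Named fixture presets: (respiration params or None, target SNR dB or None).
FIXTURE_PRESETS: dict[str, tuple[RespModelParams | None, float | None]] = {
    "table2-snr0": (_TABLE_RESP, 0.0),
    "table2-snr-10": (_TABLE_RESP, -10.0),
    "table2-snr-20": (_TABLE_RESP, -20.0),
    "table2-snr-30": (_TABLE_RESP, -30.0),
    # 20 s of quiet 15 bpm breathing over a 60 bpm heartbeat, the structure
    # of a supine recording segment
    "supine-like-20s": (RespModelParams(), -20.0),
    "heartbeat-only": (None, None),
}


def make_fixture(name: str, seed: int, outdir: str | Path) -> dict[str, Path]:
    """Write a deterministic scene fixture: baseband CSV, truth, config.

    Returns a mapping with keys ``scene`` (``t,i,q`` CSV),
    ``displacement`` (``t,x`` CSV), ``beats`` (truth beat times) and
    ``config`` (YAML snapshot).
    """
    if name not in FIXTURE_PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(FIXTURE_PRESETS)}"
        )
    resp_p, snr = FIXTURE_PRESETS[name]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(seed)
    scen = ScenarioParams(
        target_snr=snr,
        seed=seed,
        resp_phase=float(rng.uniform(0.0, resp_p.T)) if resp_p is not None else 0.0,
    )
    heart_p = HeartModelParams()
    radar = RadarParams()
    scene = simulate_scene(
        heart_p,
        resp_p or RespModelParams(),
        scen,
        radar=radar,
        include_respiration=resp_p is not None,
    )
    paths = {
        "scene": outdir / f"{name}-scene.csv",
        "displacement": outdir / f"{name}-displacement.csv",
        "beats": outdir / f"{name}-beats.txt",
        "config": outdir / f"{name}-config.yaml",
    }
    write_signal_csv(paths["scene"], scene.iq)
    write_signal_csv(paths["displacement"], scene.displacement)
    write_beat_times(paths["beats"], scene.true_beat_times)
    RunConfig(
        scenario=scen, heart=heart_p, resp=scene.resp_params, radar=radar
    ).to_yaml(paths["config"])
    return paths
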
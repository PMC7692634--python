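"""Readers and writers for the thermogram, STD and truth text formats.

Fixed dialect everywhere: UTF-8, LF line endings, comma delimiter,
``.`` decimal point, floats written with 12 significant digits so that
write -> read round-trips are value-exact at that precision.

Thermogram file::

    # cell_volume_ml=1.4
    # cell_conc_uM=20
    # syringe_conc_uM=250
    # temperature_C=25
    injection_index,injection_volume_uL,heat_ucal
    1,8,-3.21706...

STD file: columns ``proton,sat_time_s,i_off,i_on,overlap_group``
(overlap_group empty when the peak is resolved).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

from .itc import Thermogram, TitrationProtocol
from .std import StdSeries

__all__ = ["ParseError", "read_thermogram", "write_thermogram",
           "read_std_series", "write_std_series",
           "read_truth", "write_truth", "RunConfig"]

_FLOAT = "{:.12g}".format

_THERMO_HEADER_KEYS = ("cell_volume_ml", "cell_conc_uM", "syringe_conc_uM", "temperature_C")
_THERMO_COLUMNS = "injection_index,injection_volume_uL,heat_ucal"
_STD_COLUMNS = "proton,sat_time_s,i_off,i_on,overlap_group"


class ParseError(ValueError):
    """Malformed input file; message names the offending line number."""


def _parse_float(tok: str, path: str, lineno: int, what: str) -> float:
    tok = tok.strip()
    if "," in tok:
        raise ParseError(f"{path}:{lineno}: locale-style decimal comma in {what}: {tok!r}")
    try:
        v = float(tok)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: cannot parse {what}: {tok!r}") from None
    if not math.isfinite(v):
        raise ParseError(f"{path}:{lineno}: non-finite {what}: {tok!r}")
    return v


def write_thermogram(tg: Thermogram, path) -> None:
    p = tg.protocol
    lines = [
        f"# cell_volume_ml={_FLOAT(p.cell_volume * 1e3)}",
        f"# cell_conc_uM={_FLOAT(p.cell_conc * 1e6)}",
        f"# syringe_conc_uM={_FLOAT(p.syringe_conc * 1e6)}",
        f"# temperature_C={_FLOAT(p.temperature - 273.15)}",
        _THERMO_COLUMNS,
    ]
    for i, (v, q) in enumerate(zip(p.injection_volumes, tg.heats), start=1):
        lines.append(f"{i},{_FLOAT(v * 1e6)},{_FLOAT(q)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def read_thermogram(path) -> Thermogram:
    path = str(path)
    text = Path(path).read_text(encoding="utf-8")
    header: Dict[str, float] = {}
    rows = []
    saw_columns = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if saw_columns:
                raise ParseError(f"{path}:{lineno}: header line after data started")
            body = line.lstrip("#").strip()
            if "=" not in body:
                raise ParseError(f"{path}:{lineno}: malformed header line (need key=value)")
            key, val = body.split("=", 1)
            key = key.strip()
            if key not in _THERMO_HEADER_KEYS:
                raise ParseError(f"{path}:{lineno}: unknown header key {key!r}")
            header[key] = _parse_float(val, path, lineno, key)
            continue
        if not saw_columns:
            if line != _THERMO_COLUMNS:
                raise ParseError(f"{path}:{lineno}: expected column line {_THERMO_COLUMNS!r}")
            missing = [k for k in _THERMO_HEADER_KEYS if k not in header]
            if missing:
                raise ParseError(f"{path}:{lineno}: missing header key(s): {', '.join(missing)}")
            saw_columns = True
            continue
        parts = line.split(",")
        if len(parts) != 3:
            raise ParseError(f"{path}:{lineno}: expected 3 comma-separated fields, got {len(parts)}")
        idx = _parse_float(parts[0], path, lineno, "injection_index")
        if idx != len(rows) + 1:
            raise ParseError(f"{path}:{lineno}: injection_index must be {len(rows) + 1}, got {parts[0]!r}")
        vol = _parse_float(parts[1], path, lineno, "injection_volume_uL")
        heat = _parse_float(parts[2], path, lineno, "heat_ucal")
        rows.append((vol, heat))
    if not saw_columns:
        raise ParseError(f"{path}: no column line found")
    if len(rows) < 2:
        raise ParseError(f"{path}: need at least 2 injections, found {len(rows)}")
    protocol = TitrationProtocol(
        cell_volume=header["cell_volume_ml"] * 1e-3,
        cell_conc=header["cell_conc_uM"] * 1e-6,
        syringe_conc=header["syringe_conc_uM"] * 1e-6,
        injection_volumes=tuple(v * 1e-6 for v, _ in rows),
        temperature=header["temperature_C"] + 273.15,
    )
    return Thermogram(protocol=protocol, heats=tuple(q for _, q in rows))


def write_std_series(series: StdSeries, path) -> None:
    lines = [_STD_COLUMNS]
    for p in series.proton_labels:
        grp = series.group_of(p) or ""
        for t, on in zip(series.sat_times, series.i_on[p]):
            on_txt = "" if math.isnan(on) else _FLOAT(on)
            lines.append(f"{p},{_FLOAT(t)},{_FLOAT(series.i_off[p])},{on_txt},{grp}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def read_std_series(path) -> StdSeries:
    path = str(path)
    text = Path(path).read_text(encoding="utf-8")
    lines = [l for l in text.splitlines()]
    cells = {}   # proton -> {t: (i_off, i_on)}
    groups: Dict[str, set] = {}
    saw_columns = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if not saw_columns:
            if line != _STD_COLUMNS:
                raise ParseError(f"{path}:{lineno}: expected column line {_STD_COLUMNS!r}")
            saw_columns = True
            continue
        parts = line.split(",")
        if len(parts) != 5:
            raise ParseError(f"{path}:{lineno}: expected 5 comma-separated fields, got {len(parts)}")
        proton = parts[0].strip()
        if not proton:
            raise ParseError(f"{path}:{lineno}: empty proton label")
        t = _parse_float(parts[1], path, lineno, "sat_time_s")
        i_off = _parse_float(parts[2], path, lineno, "i_off")
        i_on = math.nan if parts[3].strip() == "" else _parse_float(parts[3], path, lineno, "i_on")
        grp = parts[4].strip()
        d = cells.setdefault(proton, {})
        if t in d:
            raise ParseError(f"{path}:{lineno}: duplicate cell ({proton!r}, {t})")
        d[t] = (i_off, i_on)
        if grp:
            groups.setdefault(grp, set()).add(proton)
    if not cells:
        raise ParseError(f"{path}: no data rows")
    times = sorted({t for d in cells.values() for t in d})
    labels = tuple(cells)
    i_off = {}
    i_on = {}
    for p in labels:
        offs = {off for off, _ in cells[p].values()}
        if len(offs) != 1:
            raise ParseError(f"{path}: proton {p!r} has inconsistent i_off values")
        i_off[p] = offs.pop()
        i_on[p] = tuple(cells[p][t][1] if t in cells[p] else math.nan for t in times)
    return StdSeries(proton_labels=labels, sat_times=tuple(times),
                     i_off=i_off, i_on=i_on, overlap_groups=groups)


def write_truth(truth: dict, path) -> None:
    """Flat key=value truth sidecar (12 significant digits for floats)."""
    lines = []
    for k, v in truth.items():
        if isinstance(v, float):
            lines.append(f"{k}={_FLOAT(v)}")
        else:
            lines.append(f"{k}={v}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def read_truth(path) -> dict:
    path = str(path)
    out = {}
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if "=" not in line:
            raise ParseError(f"{path}:{lineno}: malformed truth line (need key=value)")
        k, v = line.split("=", 1)
        try:
            out[k.strip()] = int(v)
        except ValueError:
            try:
                out[k.strip()] = float(v)
            except ValueError:
                out[k.strip()] = v.strip()
    return out


_CONFIG_KEYS = {"input", "output", "scheme", "seed", "bootstrap", "method",
                "reference_time", "exclude_first", "verbosity", "units"}


@dataclass
class RunConfig:
    """Flat key=value run configuration; unknown keys are rejected."""

    input: Optional[str] = None
    output: Optional[str] = None
    scheme: str = "double_dependent"
    seed: int = 0
    bootstrap: int = 0
    method: str = "single_time"
    reference_time: float = 0.6
    exclude_first: bool = False
    verbosity: int = 0
    units: str = "uM"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = str(path)
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ParseError(f"{path}:{lineno}: malformed config line (need key=value)")
            k, v = (x.strip() for x in line.split("=", 1))
            if k not in _CONFIG_KEYS:
                raise ParseError(f"{path}:{lineno}: unknown config key {k!r}")
            kwargs[k] = v
        defaults = cls()
        for k, v in kwargs.items():
            cur = getattr(defaults, k)
            if isinstance(cur, bool):
                kwargs[k] = v.lower() in ("1", "true", "yes", "on")
            elif isinstance(cur, int):
                kwargs[k] = int(v)
            elif isinstance(cur, float):
                kwargs[k] = float(v)
        return cls(**kwargs)

    def to_file(self, path) -> None:
        lines = []
        for k in sorted(_CONFIG_KEYS):
            v = getattr(self, k)
            if v is None:
                continue
            lines.append(f"{k}={v}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
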
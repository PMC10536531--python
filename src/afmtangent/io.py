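"""Reading and writing force curves as delimited text.

Supported layouts (comment lines starting with '#' are ignored; comma,
tab or whitespace delimited):

* two columns ``h F`` — force-indentation data, SI (m, N) or nm/nN;
* two columns ``z d`` — raw piezo displacement and deflection (both m),
  read with :func:`read_raw_curve` together with a spring constant.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .curves import ForceCurve, RawCurve

__all__ = ["read_force_curve", "write_force_curve", "read_raw_curve"]

#: nm -> m and nN -> N
_NM = 1e-9


def _read_two_columns(path) -> np.ndarray:
    """Parse a two-column file: '#' comments, comma/tab/space delimiters,
    optional single header row."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            fields = text.replace(",", " ").replace(";", " ").split()
            try:
                parsed = [float(v) for v in fields]
            except ValueError:
                if not rows and lineno <= 2:  # header row
                    continue
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric value in {text!r}"
                ) from None
            if len(parsed) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected two columns, "
                    f"found {len(parsed)}"
                )
            rows.append(parsed)
    if not rows:
        raise ValueError(f"{path}: no data rows found")
    return np.asarray(rows, dtype=float)


def read_force_curve(path, units: str = "si") -> ForceCurve:
    """Read a two-column force-indentation file.

    units="si" expects meters and newtons; units="nm-nN" converts from
    nanometers and nanonewtons.
    """
    if units not in ("si", "nm-nN"):
        raise ValueError("units must be 'si' or 'nm-nN'")
    values = _read_two_columns(path)
    h, F = values[:, 0], values[:, 1]
    if units == "nm-nN":
        h, F = h * _NM, F * _NM
    order = np.argsort(h, kind="stable")
    return ForceCurve(h=h[order], F=F[order])


def write_force_curve(curve: ForceCurve, path, header: str | None = None) -> None:
    """Write a force curve as CSV (SI units) with an optional '#' header."""
    path = Path(path)
    with path.open("w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# h_m,F_N\n")
        np.savetxt(fh, np.column_stack([curve.h, curve.F]), delimiter=",")


def read_raw_curve(path, spring_constant: float) -> RawCurve:
    """Read a two-column piezo-displacement/deflection file (meters)."""
    values = _read_two_columns(path)
    return RawCurve(z=values[:, 0], d=values[:, 1], k=spring_constant)
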